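import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from keyscore import (
    KeyEvent,
    Performance,
    Template,
    TemplateGroup,
    build_default_keymap,
)


@pytest.fixture(scope="session")
def keymap():
    return build_default_keymap()


def make_events(pairs, duration=100.0):
    """Build KeyEvents from (key_index, press_ms) pairs."""
    return [KeyEvent(k, t, t + duration) for k, t in pairs]


def make_performance(pairs, duration=100.0, **ids):
    defaults = dict(
        participant_id="P01", task_id="task1", trial_id="001", condition="right"
    )
    defaults.update(ids)
    return Performance(events=tuple(make_events(pairs, duration)), **defaults)


@pytest.fixture
def melody_template():
    """Four-sound template: C4, the C-major triad, D4, E4 at a steady pulse."""
    return Template(
        template_id="tiny_melody",
        register_start_index=0,
        groups=(
            TemplateGroup((12,), 0.0),
            TemplateGroup((12, 16, 19), 1.0),
            TemplateGroup((14,), 2.0),
            TemplateGroup((16,), 3.0),
        ),
    )


@pytest.fixture
def mono_template():
    """Five isochronous single notes C4..G4."""
    return Template(
        template_id="mono",
        register_start_index=0,
        groups=tuple(TemplateGroup((12 + i,), float(i)) for i in range(5)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
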