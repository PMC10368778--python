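"""Rhythmic accuracy: proportion-based deviance against an expected timing.

Adapted from the rhythm-reproduction scoring of the tapping battery
literature: onsets (one per chord group — only the first keypress of a
simultaneous structure counts) are converted to proportions of the whole
performance span, anchored at the first and last onset, and each interior
note's absolute proportion error is expressed relative to the expected
duration of its preceding inter-note interval.  The score is the mean of
those per-note deviances, in percent; 0 means timing exactly proportional to
the template (the measure is invariant to tempo and to a global shift).

A trial is eligible only when its chord-collapsed onset count equals the
template's group count — with more or fewer keypresses there is no
one-to-one note correspondence to score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .encoding import DEFAULT_SIMULTANEITY_MS, group_simultaneous
from .io import KeyEvent, Performance, Template

__all__ = [
    "RhythmScore",
    "collapse_to_onsets",
    "check_eligibility",
    "rhythm_deviance",
    "score_rhythm",
]

Denominator = Literal["preceding", "succeeding"]


@dataclass(frozen=True)
class RhythmScore:
    """Eligibility flag, onset count, per-note deviances and their mean (%)."""

    eligible: bool
    n_onsets: int
    per_note_deviance: tuple[float, ...]
    mean_deviance_pct: float | None

    def __post_init__(self) -> None:
        if self.mean_deviance_pct is not None and not (
            self.eligible and self.n_onsets >= 3
        ):
            raise ValueError("mean deviance requires eligibility and >= 3 onsets")


def collapse_to_onsets(
    events: Sequence[KeyEvent], threshold_ms: float = DEFAULT_SIMULTANEITY_MS
) -> np.ndarray:
    """One onset per chord group: the press time of the group's first event."""
    groups = group_simultaneous(events, threshold_ms=threshold_ms)
    return np.array([g.anchor_time for g in groups], dtype=float)


def check_eligibility(onsets: Sequence[float], template: Template) -> bool:
    """True iff the performance has exactly as many onset groups as the template."""
    return len(onsets) == template.n_groups


def rhythm_deviance(
    onsets: Sequence[float],
    expected_onsets: Sequence[float],
    denominator: Denominator = "preceding",
) -> RhythmScore:
    """Per-note proportion deviance of measured onsets against expected ones.

    With expected proportions ``p_i = (e_i − e_1)/(e_n − e_1)`` and measured
    proportions ``q_i = (t_i − t_1)/(t_n − t_1)``, each interior note i
    (endpoints are pinned to 0 and 1 by construction) scores
    ``|q_i − p_i| / (p_i − p_{i−1})`` — the error relative to the expected
    preceding interval (``succeeding`` divides by ``p_{i+1} − p_i`` instead).
    The summary is ``100 × mean`` over interior notes.

    Requires equal counts (eligibility); with fewer than 3 onsets there are
    no interior notes and the mean is missing.
    """
    t = np.asarray(onsets, dtype=float)
    e = np.asarray(expected_onsets, dtype=float)
    if t.shape != e.shape:
        raise ValueError(
            f"onset count {t.size} does not match expected count {e.size}; "
            "check eligibility first"
        )
    if np.any(np.diff(e) <= 0):
        raise ValueError("expected onsets must be strictly increasing")
    n = t.size
    if n < 3:
        return RhythmScore(
            eligible=True, n_onsets=n, per_note_deviance=(), mean_deviance_pct=None
        )
    if t[-1] == t[0]:
        raise ValueError("measured performance spans zero time")
    p = (e - e[0]) / (e[-1] - e[0])
    q = (t - t[0]) / (t[-1] - t[0])
    interior = np.arange(1, n - 1)
    if denominator == "preceding":
        widths = p[interior] - p[interior - 1]
    elif denominator == "succeeding":
        widths = p[interior + 1] - p[interior]
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    dev = np.abs(q[interior] - p[interior]) / widths
    return RhythmScore(
        eligible=True,
        n_onsets=n,
        per_note_deviance=tuple(dev),
        mean_deviance_pct=float(100.0 * dev.mean()),
    )


def score_rhythm(
    performance: Performance,
    template: Template,
    threshold_ms: float = DEFAULT_SIMULTANEITY_MS,
    denominator: Denominator = "preceding",
) -> RhythmScore:
    """Collapse chords, check eligibility, then score proportion deviance.

    Ineligible trials (onset count ≠ template group count) return
    ``eligible=False`` and no score.  The performance must already have
    passed through :func:`keyscore.io.drop_incomplete_events`.
    """
    if performance.n_incomplete:
        raise ValueError(
            "performance contains incomplete events; apply drop_incomplete_events first"
        )
    onsets = collapse_to_onsets(performance.events, threshold_ms=threshold_ms)
    if not check_eligibility(onsets, template):
        return RhythmScore(
            eligible=False,
            n_onsets=int(onsets.size),
            per_note_deviance=(),
            mean_deviance_pct=None,
        )
    return rhythm_deviance(onsets, template.expected_onsets(), denominator=denominator)
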