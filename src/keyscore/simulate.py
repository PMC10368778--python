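"""Synthetic performance generator: the test bed for every scoring stage.

Emulates the raw materials of an in-scanner keyboard study without any real
participant data: template-conditioned performances with insertion /
omission / substitution errors and Gaussian timing jitter, chord asynchrony,
AAF scale cohorts with injected post-target slowing, two-component Gaussian
latency mixtures, and framewise-displacement series with controlled spike
counts.  Every generator is deterministic under a seed; cohort generators
derive one independent sub-stream per participant so simulations are
reproducible trial-wise.

What it does NOT emulate: expressive timing (rubato), velocity dynamics,
hand biomechanics, or the serial structure of real pianistic errors — slips
here are independent across notes, drawn from neighbouring keys (±1 or ±2
semitones) to mirror realistic near-misses and the AAF alteration sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .aaf import ScaleSpec, build_scale_template
from .encoding import DEFAULT_SIMULTANEITY_MS, KeyMap, build_default_keymap
from .io import KeyEvent, Performance, Template

__all__ = [
    "SimulationConfig",
    "LatencyMixtureSpec",
    "DEFAULT_AAF_SCALES",
    "simulate_performance",
    "simulate_aaf_cohort",
    "simulate_latencies",
    "simulate_fd_series",
]

# the eight scales of the AAF task, playable with the right hand in the
# 25-key register: F major, F# minor, G major, G minor, A minor, Bb major,
# B minor, C major
DEFAULT_AAF_SCALES: tuple[ScaleSpec, ...] = (
    ScaleSpec(5, "major"),
    ScaleSpec(6, "natural_minor"),
    ScaleSpec(7, "major"),
    ScaleSpec(7, "natural_minor"),
    ScaleSpec(9, "natural_minor"),
    ScaleSpec(10, "major"),
    ScaleSpec(11, "natural_minor"),
    ScaleSpec(12, "major"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Error and timing processes of a simulated performance.

    Rates are per expected note (insertions: per between-note slot); timing
    parameters are in milliseconds.  ``base_ioi_ms`` sets the tempo — the
    template's mean inter-onset interval is scaled to it (500 ms ≈ 120
    quarter notes/min).
    """

    substitution_rate: float = 0.0
    omission_rate: float = 0.0
    insertion_rate: float = 0.0
    onset_jitter_sd_ms: float = 0.0
    chord_asynchrony_sd_ms: float = 0.0
    base_ioi_ms: float = 500.0
    slowing_delta_ms: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "insertion_rate"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {r}")
        if not 0.0 <= self.omission_rate <= 1.0:
            raise ValueError(f"omission_rate must be in [0, 1], got {self.omission_rate}")
        if self.substitution_rate + self.omission_rate > 1.0:
            raise ValueError("substitution_rate + omission_rate must be <= 1")
        if self.onset_jitter_sd_ms < 0 or self.chord_asynchrony_sd_ms < 0:
            raise ValueError("jitter/asynchrony SDs must be non-negative")
        if self.base_ioi_ms <= 0:
            raise ValueError("base_ioi_ms must be positive")


@dataclass(frozen=True)
class LatencyMixtureSpec:
    """Two-component Gaussian latency model of the key→sound chain.

    Defaults reproduce the measured device latency distribution: a fast mode
    near 8.77 ms carrying ~82% of events and a slow mode near 12.67 ms with
    the remaining ~18%.
    """

    means_ms: tuple[float, float] = (8.77, 12.67)
    sds_ms: tuple[float, float] = (0.5, 0.5)
    weights: tuple[float, float] = (0.82, 0.18)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sds_ms):
            raise ValueError("component SDs must be positive")
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError(f"weights must sum to 1, got {self.weights}")
        if any(not 0 <= w <= 1 for w in self.weights):
            raise ValueError("weights must lie within [0, 1]")


def _resolve_rng(
    config_seed: int | None, rng: np.random.Generator | None
) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(config_seed)


def _neighbour_key(key: int, n_keys: int, rng: np.random.Generator) -> int:
    offsets = [o for o in (-2, -1, 1, 2) if 0 <= key + o < n_keys]
    return key + int(rng.choice(offsets))


def simulate_performance(
    template: Template,
    config: SimulationConfig,
    keymap: KeyMap | None = None,
    rng: np.random.Generator | None = None,
    participant_id: str = "sim",
    task_id: str = "task1",
    trial_id: str = "t1",
    condition: str = "right",
    threshold_ms: float = DEFAULT_SIMULTANEITY_MS,
) -> Performance:
    """Generate one noisy rendition of a template.

    Per expected note, independently: omitted with probability
    ``omission_rate``; else substituted by a uniformly chosen neighbouring
    key (±1 or ±2 semitones within the register) with probability
    ``substitution_rate``.  After each expected group an extra uniform-key
    insertion appears with probability ``insertion_rate``, midway to the next
    onset.  Group onsets are the template onsets scaled to ``base_ioi_ms``
    mean spacing plus i.i.d. Gaussian jitter; non-first chord members lag the
    group onset by half-normal asynchrony truncated strictly below the
    simultaneity window so chords never split.
    """
    if template.n_groups == 0:
        raise ValueError("cannot simulate from an empty template")
    keymap = keymap or build_default_keymap()
    rng = _resolve_rng(config.seed, rng)

    e = np.asarray(template.expected_onsets(), dtype=float)
    if e.size > 1:
        scale = config.base_ioi_ms / float(np.diff(e).mean())
        onsets = (e - e[0]) * scale
        gap_after = np.append(np.diff(onsets), config.base_ioi_ms)
    else:
        onsets = np.zeros(1)
        gap_after = np.array([config.base_ioi_ms])
    onsets = onsets + rng.normal(0.0, config.onset_jitter_sd_ms, size=onsets.size) \
        if config.onset_jitter_sd_ms > 0 else onsets

    duration = 0.8 * config.base_ioi_ms
    raw: list[tuple[float, int, int]] = []  # (press, key, velocity)
    for gi, group in enumerate(template.groups):
        t0 = float(onsets[gi])
        for mi, key in enumerate(group.key_indices):
            if rng.random() < config.omission_rate:
                continue
            if rng.random() < config.substitution_rate:
                key = _neighbour_key(key, keymap.n_keys, rng)
            t = t0
            if mi > 0:
                if config.chord_asynchrony_sd_ms > 0:
                    asyn = abs(rng.normal(0.0, config.chord_asynchrony_sd_ms))
                    t = t0 + min(asyn, 0.97 * threshold_ms)
                else:
                    t = t0 + 1e-9 * mi  # preserve deterministic ordering
            raw.append((t, key, int(rng.integers(55, 85))))
        if rng.random() < config.insertion_rate:
            extra_key = int(rng.integers(0, keymap.n_keys))
            t = t0 + 0.5 * float(gap_after[gi])
            raw.append((t, extra_key, int(rng.integers(55, 85))))

    raw.sort()
    shift = -raw[0][0] if raw and raw[0][0] < 0 else 0.0
    events = tuple(
        KeyEvent(key, t + shift, t + shift + duration, vel) for t, key, vel in raw
    )
    return Performance(
        participant_id=participant_id,
        task_id=task_id,
        trial_id=trial_id,
        condition=condition,
        events=tuple(events),
    )


def _inject_slowing(
    performance: Performance, target_position: int, delta_ms: float
) -> Performance:
    """Add ``delta_ms`` to each of the 3 inter-onset intervals after the target.

    For single-note groups this shifts the press of onset k+i by i·delta
    (i = 1..3) and everything later by 3·delta.
    """
    if delta_ms == 0:
        return performance
    shifted = []
    for j, ev in enumerate(performance.events, start=1):
        add = delta_ms * min(max(j - target_position, 0), 3)
        shifted.append(
            replace(
                ev,
                press_time=ev.press_time + add,
                release_time=ev.release_time + add,
            )
        )
    return replace(performance, events=tuple(shifted))


def simulate_aaf_cohort(
    n_participants: int,
    trials_per_participant: int = 24,
    slowing_delta_ms: float = 0.0,
    config: SimulationConfig | None = None,
    seed: int | None = None,
    keymap: KeyMap | None = None,
) -> tuple[list[Performance], pd.DataFrame]:
    """Simulate an AAF scale cohort and its trial manifest.

    Each participant cycles through the eight scales (default 24 trials = 3
    repetitions); exactly half the trials (rounded down) carry altered
    feedback on one target keypress at a position drawn uniformly from 5–12,
    alteration ±1 or ±2 semitones, with ``slowing_delta_ms`` added to each of
    the 3 post-target inter-onset intervals.  The manifest records
    ``participant, trial, target_position, alteration_semitones, feedback``.

    Per-participant sub-streams are spawned deterministically from ``seed``,
    so any participant's data are reproducible independently of cohort size.
    """
    if n_participants < 2:
        raise ValueError("a cohort needs at least 2 participants")
    config = config or SimulationConfig()
    keymap = keymap or build_default_keymap()
    templates = [build_scale_template(s, keymap, ioi=1.0) for s in DEFAULT_AAF_SCALES]

    streams = np.random.SeedSequence(seed).spawn(n_participants)
    performances: list[Performance] = []
    manifest_rows: list[dict] = []
    n_altered = trials_per_participant // 2
    for pi, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pid = f"P{pi + 1:02d}"
        altered_slots = set(
            rng.choice(trials_per_participant, size=n_altered, replace=False).tolist()
        )
        for ti in range(trials_per_participant):
            template = templates[ti % len(templates)]
            trial = f"{ti + 1:03d}"
            perf = simulate_performance(
                template,
                config,
                keymap=keymap,
                rng=rng,
                participant_id=pid,
                task_id="task2",
                trial_id=trial,
                condition="standard",
            )
            if ti in altered_slots:
                target = int(rng.integers(5, 13))
                alteration = int(rng.choice([-2, -1, 1, 2]))
                perf = replace(
                    _inject_slowing(perf, target, slowing_delta_ms),
                    condition="altered",
                )
                manifest_rows.append(
                    {
                        "participant": pid,
                        "trial": trial,
                        "target_position": target,
                        "alteration_semitones": alteration,
                        "feedback": "altered",
                    }
                )
            else:
                manifest_rows.append(
                    {
                        "participant": pid,
                        "trial": trial,
                        "target_position": pd.NA,
                        "alteration_semitones": pd.NA,
                        "feedback": "standard",
                    }
                )
            performances.append(perf)
    manifest = pd.DataFrame(manifest_rows)
    return performances, manifest


def simulate_latencies(
    spec: LatencyMixtureSpec | None = None,
    n: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Draw ``n`` key→sound latencies from the two-Gaussian mixture."""
    if n < 1:
        raise ValueError("n must be at least 1")
    spec = spec or LatencyMixtureSpec()
    rng = np.random.default_rng(seed)
    component = rng.choice(2, size=n, p=list(spec.weights))
    means = np.asarray(spec.means_ms)[component]
    sds = np.asarray(spec.sds_ms)[component]
    return rng.normal(means, sds)


def simulate_fd_series(
    n_volumes: int,
    n_spikes: int,
    spike_magnitude: float = 2.6,
    seed: int | None = None,
    baseline_mean_mm: float = 0.12,
) -> np.ndarray:
    """Framewise-displacement series with exactly ``n_spikes`` values above
    ``spike_magnitude``.

    Baseline volumes follow a small half-normal motion profile (typical of a
    compliant participant, ~0.1 mm); spike volumes exceed the magnitude by a
    positive half-normal excess.
    """
    if n_spikes > n_volumes:
        raise ValueError("n_spikes cannot exceed n_volumes")
    rng = np.random.default_rng(seed)
    fd = np.abs(rng.normal(0.0, baseline_mean_mm * np.sqrt(np.pi / 2), size=n_volumes))
    fd = np.minimum(fd, 0.9 * spike_magnitude)
    if n_spikes > 0:
        where = rng.choice(n_volumes, size=n_spikes, replace=False)
        fd[where] = spike_magnitude + 1e-6 + np.abs(rng.normal(0.0, 0.2, size=n_spikes))
    return fd
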