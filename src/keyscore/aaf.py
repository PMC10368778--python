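"""Scale templates and the altered-auditory-feedback slowing analysis.

In the altered-auditory-feedback (AAF) paradigm a performer plays heptatonic
scales, ascending then descending, while on half the trials the sound of one
target key is shifted by one or two semitones — an error-like event without
an actual motor error.  The behavioural index of performance monitoring is
post-error slowing: mean inter-press time over the three keys after the
first altered target, compared with the three keys before it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .encoding import DEFAULT_SIMULTANEITY_MS, KeyMap
from .io import Performance, Template, TemplateGroup
from .rhythm import collapse_to_onsets

__all__ = [
    "ScaleSpec",
    "AAFTrial",
    "AAFTrialResult",
    "MAJOR_STEPS",
    "NATURAL_MINOR_STEPS",
    "build_scale_template",
    "post_error_intervals",
    "post_error_slowing_summary",
]

# semitone step patterns, tonic to octave
MAJOR_STEPS = (2, 2, 1, 2, 2, 2, 1)
NATURAL_MINOR_STEPS = (2, 1, 2, 2, 1, 2, 2)

Mode = Literal["major", "natural_minor"]
Window = Literal["into-target", "strict-pre"]
Turnaround = Literal["double", "single"]


@dataclass(frozen=True)
class ScaleSpec:
    """A heptatonic scale on the keyboard: tonic key and mode.

    Direction is fixed — ascending tonic→octave then descending back.
    """

    tonic_key_index: int
    mode: Mode

    def steps(self) -> tuple[int, ...]:
        if self.mode == "major":
            return MAJOR_STEPS
        if self.mode == "natural_minor":
            return NATURAL_MINOR_STEPS
        raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class AAFTrial:
    """One scale trial with its feedback manipulation metadata."""

    performance: Performance
    feedback: Literal["standard", "altered"]
    target_position: int | None = None  # 1-based ordinal of the altered keypress
    alteration_semitones: int | None = None

    def __post_init__(self) -> None:
        if self.feedback == "standard":
            if self.target_position is not None or self.alteration_semitones is not None:
                raise ValueError("standard-feedback trials carry no alteration fields")
        else:
            if self.target_position is None or self.alteration_semitones is None:
                raise ValueError("altered trials need target_position and alteration")
            if abs(self.alteration_semitones) not in (1, 2):
                raise ValueError(
                    f"alteration must be ±1 or ±2 semitones, got {self.alteration_semitones}"
                )


@dataclass(frozen=True)
class AAFTrialResult:
    """Mean inter-press interval over the 3-key windows around the target."""

    mean_before_ms: float
    mean_after_ms: float

    @property
    def delta_ms(self) -> float:
        return self.mean_after_ms - self.mean_before_ms


def build_scale_template(
    spec: ScaleSpec,
    keymap: KeyMap,
    ioi: float = 1.0,
    turnaround: Turnaround = "double",
) -> Template:
    """Errorless template for a scale: ascent, turnaround, descent.

    Default turnaround presses the octave twice (end of ascent and start of
    descent), giving 16 single-note isochronous groups; ``single`` presses it
    once (15 groups).  Raises when the octave falls outside the keymap.
    """
    tonic = spec.tonic_key_index
    if tonic < 0 or tonic + 12 >= keymap.n_keys:
        raise ValueError(
            f"octave of tonic key {tonic} (key {tonic + 12}) outside the "
            f"{keymap.n_keys}-key register"
        )
    ascent = [tonic]
    for step in spec.steps():
        ascent.append(ascent[-1] + step)
    assert ascent[-1] == tonic + 12
    descent = list(reversed(ascent))
    keys = ascent + (descent if turnaround == "double" else descent[1:])
    groups = tuple(
        TemplateGroup(key_indices=(k,), expected_onset=i * ioi)
        for i, k in enumerate(keys)
    )
    return Template(
        template_id=f"scale_{spec.mode}_{tonic}",
        register_start_index=keymap.register_start_index,
        groups=groups,
    )


def post_error_intervals(
    performance: Performance,
    target_position: int,
    threshold_ms: float = DEFAULT_SIMULTANEITY_MS,
    window: Window = "into-target",
) -> AAFTrialResult:
    """Mean inter-onset interval over 3 intervals before and after the target.

    With the target at onset ordinal k (1-based, chord-collapsed), the
    default ``into-target`` window takes before = intervals k−3→k−2, k−2→k−1,
    k−1→k (the last completes at the target press, before the altered sound
    is heard) and after = k→k+1, k+1→k+2, k+2→k+3.  The ``strict-pre``
    variant uses intervals k−4→k−3 … k−2→k−1 instead, requiring one more
    preceding onset.
    """
    onsets = collapse_to_onsets(performance.events, threshold_ms=threshold_ms)
    k = target_position
    need_before = 4 if window == "into-target" else 5
    if k < need_before:
        raise ValueError(
            f"target position {k} leaves fewer than 3 {window} intervals before it"
        )
    if onsets.size < k + 3:
        raise ValueError(
            f"only {onsets.size} onsets: fewer than 3 intervals after target {k}"
        )
    iois = np.diff(onsets)  # iois[i] = interval onset i+1 -> i+2 (1-based)
    if window == "into-target":
        before = iois[k - 4 : k - 1]
    elif window == "strict-pre":
        before = iois[k - 5 : k - 2]
    else:
        raise ValueError(f"unknown window {window!r}")
    after = iois[k - 1 : k + 2]
    assert before.size == 3 and after.size == 3
    return AAFTrialResult(
        mean_before_ms=float(before.mean()), mean_after_ms=float(after.mean())
    )


def post_error_slowing_summary(
    results: Iterable[tuple[str, AAFTrialResult]] | Mapping[str, Sequence[AAFTrialResult]],
) -> pd.DataFrame:
    """Per-participant mean before/after intervals over altered trials.

    Accepts ``(participant_id, result)`` pairs or a mapping participant →
    results.  Returns a tidy frame with columns ``participant``,
    ``mean_before_ms``, ``mean_after_ms``, ``delta_ms``, ``n_trials`` —
    one row per participant, ready for a one-way repeated-measures ANOVA of
    before vs after.
    """
    if isinstance(results, Mapping):
        pairs = [(p, r) for p, rs in results.items() for r in rs]
    else:
        pairs = list(results)
    if not pairs:
        raise ValueError("no trial results to summarize")
    df = pd.DataFrame(
        {
            "participant": [p for p, _ in pairs],
            "before": [r.mean_before_ms for _, r in pairs],
            "after": [r.mean_after_ms for _, r in pairs],
        }
    )
    out = df.groupby("participant", sort=True).agg(
        mean_before_ms=("before", "mean"),
        mean_after_ms=("after", "mean"),
        n_trials=("before", "size"),
    )
    out["delta_ms"] = out["mean_after_ms"] - out["mean_before_ms"]
    return out.reset_index()[
        ["participant", "mean_before_ms", "mean_after_ms", "delta_ms", "n_trials"]
    ]
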