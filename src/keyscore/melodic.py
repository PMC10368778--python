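"""Melodic accuracy: Levenshtein distance and the similarity ratio.

The melodic score of a trial is ``1 − L_distance / L_sum`` where
``L_distance`` is the minimum number of single-character insertions,
omissions and substitutions (each cost 1) turning the encoded performance
into the encoded errorless template, and ``L_sum`` is the sum of the two
string lengths.  1 means a perfect reproduction; 0 means no similarity.

The dynamic program is implemented here rather than taken from a string
library: common library ``ratio`` functions weight substitutions as 2
(indel-only distance), which is a different statistic.  That convention is
available as ``compat_indel2`` for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

from .encoding import DEFAULT_SIMULTANEITY_MS, KeyMap, encode_performance, encode_template
from .io import Performance, Template

__all__ = [
    "MelodicScore",
    "levenshtein_distance",
    "indel2_distance",
    "levenshtein_ratio",
    "score_melodic",
]


@dataclass(frozen=True)
class MelodicScore:
    """Edit distance, joint length and the resulting similarity ratio."""

    distance: int
    len_sum: int
    ratio: float


def _edit_distance(a: str, b: str, sub_cost: int) -> int:
    # two-row Wagner–Fischer
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        curr = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                curr[j] = prev[j - 1]
            else:
                curr[j] = min(prev[j] + 1, curr[j - 1] + 1, prev[j - 1] + sub_cost)
        prev = curr
    return prev[len(b)]


def levenshtein_distance(a: str, b: str) -> int:
    """Minimum number of unit-cost insertions, deletions and substitutions."""
    return _edit_distance(a, b, sub_cost=1)


def indel2_distance(a: str, b: str) -> int:
    """Edit distance with substitutions weighted 2 (insert+delete).

    This is the convention behind many library ``ratio`` functions; equal to
    ``len(a) + len(b) − 2·LCS(a, b)``.
    """
    return _edit_distance(a, b, sub_cost=2)


def levenshtein_ratio(a: str, b: str, compat_indel2: bool = False) -> float:
    """Similarity ratio ``1 − distance/(len(a)+len(b))``, clamped to [0, 1].

    Undefined (raises) when both strings are empty: no performance compared
    against no template is meaningless.
    """
    len_sum = len(a) + len(b)
    if len_sum == 0:
        raise ValueError("levenshtein_ratio is undefined for two empty strings")
    d = indel2_distance(a, b) if compat_indel2 else levenshtein_distance(a, b)
    return min(1.0, max(0.0, 1.0 - d / len_sum))


def score_melodic(
    performance: Performance,
    template: Template,
    keymap: KeyMap,
    threshold_ms: float = DEFAULT_SIMULTANEITY_MS,
    separated: bool = True,
    compat_indel2: bool = False,
) -> MelodicScore:
    """Score a trial's melodic accuracy against an errorless template.

    Both sides are encoded with identical settings — ``separated=True`` for
    polyphonic material, ``False`` for strictly monophonic material such as
    scales — and compared including any separator characters (produced
    identically on both sides, they cancel at the perfect-match point).

    The performance must already have passed through
    :func:`keyscore.io.drop_incomplete_events`.
    """
    if performance.n_missing_press:
        raise ValueError(
            "performance contains events with missing press_time; "
            "apply drop_incomplete_events first"
        )
    enc_perf = encode_performance(
        performance.events, keymap, threshold_ms=threshold_ms, separated=separated
    )
    enc_tmpl = encode_template(template, keymap, separated=separated)
    len_sum = len(enc_perf.text) + len(enc_tmpl.text)
    if len_sum == 0:
        raise ValueError("empty performance and empty template: ratio undefined")
    d = (
        indel2_distance(enc_perf.text, enc_tmpl.text)
        if compat_indel2
        else levenshtein_distance(enc_perf.text, enc_tmpl.text)
    )
    ratio = min(1.0, max(0.0, 1.0 - d / len_sum))
    return MelodicScore(distance=d, len_sum=len_sum, ratio=ratio)
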