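"""Keypress → character-string encoding.

Each key of the instrument maps to one printable character; keypresses whose
onsets fall within a short simultaneity window (default 30 ms, strict) form a
chord group whose characters are sorted alphabetically; groups are joined by
single spaces when polyphony is expected, or concatenated for strictly
monophonic material (scales).  The same rules encode both performances and
errorless templates, so the convention cancels at the perfect-match point of
the melodic comparison.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .io import KeyEvent, Template

__all__ = [
    "KeyMap",
    "ChordGroup",
    "EncodedPerformance",
    "EXTENDED_ALPHABET",
    "DEFAULT_SIMULTANEITY_MS",
    "build_default_keymap",
    "build_extended_keymap",
    "group_simultaneous",
    "encode_performance",
    "encode_template",
]

DEFAULT_SIMULTANEITY_MS = 30.0

# A–Z, a–z, 0–9, then 12 punctuation marks: enough for all 74 keys of a
# six-octave instrument.
EXTENDED_ALPHABET = (
    string.ascii_uppercase + string.ascii_lowercase + string.digits + ".,?!+-=/*@#$"
)
assert len(EXTENDED_ALPHABET) == 74

GroupingRule = Literal["anchor", "pairwise"]


@dataclass(frozen=True)
class KeyMap:
    """Ordered key → character map in ascending chromatic order."""

    register_start_index: int
    characters: str

    def __post_init__(self) -> None:
        if len(set(self.characters)) != len(self.characters):
            raise ValueError("keymap characters must be pairwise distinct")
        if " " in self.characters:
            raise ValueError("the space separator cannot be a keymap character")
        for ch in self.characters:
            if not ch.isprintable():
                raise ValueError(f"non-printable keymap character: {ch!r}")

    @property
    def n_keys(self) -> int:
        return len(self.characters)

    def char_for(self, key_index: int) -> str:
        if not 0 <= key_index < self.n_keys:
            raise KeyError(
                f"key_index {key_index} not covered by keymap of {self.n_keys} keys"
            )
        return self.characters[key_index]


@dataclass(frozen=True)
class ChordGroup:
    """Events treated as one simultaneous sound structure.

    ``anchor_time`` is the press time of the group's first event; every
    member presses strictly less than the simultaneity threshold after it.
    """

    events: tuple[KeyEvent, ...]
    anchor_time: float


@dataclass(frozen=True)
class EncodedPerformance:
    """A performance rendered as a character string.

    When ``separated`` each space-delimited token is one chord group with its
    characters in ascending order; otherwise groups are concatenated.
    """

    text: str
    separated: bool


def build_default_keymap() -> KeyMap:
    """The 25-key C3–C5 register mapped to capital letters A–Y.

    Key 0 (C3) → 'A', key 12 (C4) → 'M', key 24 (C5) → 'Y'.
    """
    return KeyMap(register_start_index=0, characters=string.ascii_uppercase[:25])


def build_extended_keymap(n_keys: int, register_start_index: int = 0) -> KeyMap:
    """A keymap for up to 74 keys (six octaves) drawn from the extended alphabet.

    Characters are taken in order A–Z, a–z, 0–9, then ``.,?!+-=/*@#$``.
    """
    if n_keys < 1:
        raise ValueError(f"n_keys must be positive, got {n_keys}")
    if n_keys > len(EXTENDED_ALPHABET):
        raise ValueError(
            f"alphabet exhausted: {n_keys} keys requested, "
            f"{len(EXTENDED_ALPHABET)} characters available"
        )
    return KeyMap(
        register_start_index=register_start_index,
        characters=EXTENDED_ALPHABET[:n_keys],
    )


def group_simultaneous(
    events: Sequence[KeyEvent],
    threshold_ms: float = DEFAULT_SIMULTANEITY_MS,
    rule: GroupingRule = "anchor",
) -> list[ChordGroup]:
    """Partition press-time-sorted events into chord groups.

    Under the default ``anchor`` rule an event joins the current group iff its
    press time is strictly less than ``threshold_ms`` after the group's FIRST
    event; the ``pairwise`` rule instead chains on the gap to the previous
    event (which can extend a group without bound).  Order is preserved and
    every event lands in exactly one group.
    """
    times = []
    for ev in events:
        if ev.press_time is None:
            raise ValueError("all events must have a press_time for grouping")
        times.append(ev.press_time)
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("events must be sorted by press_time")

    groups: list[ChordGroup] = []
    current: list[KeyEvent] = []
    anchor = 0.0
    for ev, t in zip(events, times):
        reference = (
            anchor if (rule == "anchor" or not current) else current[-1].press_time
        )
        if current and t - reference < threshold_ms:
            current.append(ev)
        else:
            if current:
                groups.append(ChordGroup(tuple(current), anchor))
            current = [ev]
            anchor = t
    if current:
        groups.append(ChordGroup(tuple(current), anchor))
    return groups


def _encode_tokens(tokens: Iterable[str], separated: bool) -> EncodedPerformance:
    text = (" " if separated else "").join(tokens)
    return EncodedPerformance(text=text, separated=separated)


def encode_performance(
    events: Sequence[KeyEvent],
    keymap: KeyMap,
    threshold_ms: float = DEFAULT_SIMULTANEITY_MS,
    separated: bool = True,
    rule: GroupingRule = "anchor",
) -> EncodedPerformance:
    """Encode a keypress stream as a character string.

    Each chord group becomes one token with its characters sorted ascending;
    an empty event list encodes to the empty string.
    """
    groups = group_simultaneous(events, threshold_ms=threshold_ms, rule=rule)
    tokens = [
        "".join(sorted(keymap.char_for(ev.key_index) for ev in g.events))
        for g in groups
    ]
    return _encode_tokens(tokens, separated)


def encode_template(
    template: Template, keymap: KeyMap, separated: bool = True
) -> EncodedPerformance:
    """Encode an errorless template with the same rules as performances.

    Each template group is one token (templates state simultaneity
    explicitly, so no time window is involved).
    """
    tokens = [
        "".join(sorted(keymap.char_for(k) for k in g.key_indices))
        for g in template.groups
    ]
    return _encode_tokens(tokens, separated)
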