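"""Domain types and file I/O for keypress logs, templates and score tables.

The on-disk formats are deliberately plain text:

* keypress log — UTF-8 TSV with header
  ``participant\ttask\ttrial\tcondition\tkey_index\tpress_ms\trelease_ms\tvelocity``;
  an empty field means *missing*.  Times are milliseconds, trial-relative
  (no ``t=0`` convention is assumed; downstream scoring re-anchors).
* template — JSON object ``{"template_id", "register_start_index",
  "groups": [{"keys": [int, ...], "onset": number}, ...]}``.
* score table — TSV, one :class:`ScoreRecord` per row.
* latency samples / framewise-displacement series — one value per line.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "KeyEvent",
    "Performance",
    "TemplateGroup",
    "Template",
    "ScoreRecord",
    "LogParseError",
    "read_keypress_log",
    "write_keypress_log",
    "drop_incomplete_events",
    "read_template",
    "write_template",
    "read_score_table",
    "write_score_table",
    "read_latency_samples",
    "read_fd_series",
]

LOG_COLUMNS = (
    "participant",
    "task",
    "trial",
    "condition",
    "key_index",
    "press_ms",
    "release_ms",
    "velocity",
)


class LogParseError(ValueError):
    """A keypress log row could not be parsed; the message names the line."""


@dataclass(frozen=True)
class KeyEvent:
    """One keypress: key position, press/release times in ms, MIDI velocity.

    ``press_time`` or ``release_time`` may be ``None`` (missing in the log);
    such events survive reading so the dropped fraction can be reported, and
    are removed by :func:`drop_incomplete_events` before scoring.
    """

    key_index: int
    press_time: float | None
    release_time: float | None
    velocity: int | None = None

    def __post_init__(self) -> None:
        if self.key_index < 0:
            raise ValueError(f"key_index must be non-negative, got {self.key_index}")
        if self.press_time is not None and self.press_time < 0:
            raise ValueError(f"press_time must be non-negative, got {self.press_time}")
        if (
            self.press_time is not None
            and self.release_time is not None
            and self.release_time < self.press_time
        ):
            raise ValueError(
                f"release_time {self.release_time} precedes press_time {self.press_time}"
            )
        if self.velocity is not None and not (0 <= self.velocity <= 127):
            raise ValueError(f"velocity must be in [0, 127], got {self.velocity}")

    @property
    def complete(self) -> bool:
        return self.press_time is not None and self.release_time is not None


@dataclass(frozen=True)
class Performance:
    """An ordered stream of key events for one (participant, task, trial).

    Events with a press time are non-decreasing in press time; events with a
    missing press time are tolerated on read (flagged via
    :attr:`n_missing_press`) and keep their input position.
    """

    participant_id: str
    task_id: str
    trial_id: str
    condition: str
    events: tuple[KeyEvent, ...]

    def __post_init__(self) -> None:
        last = -math.inf
        for ev in self.events:
            if ev.press_time is not None:
                if ev.press_time < last:
                    raise ValueError(
                        "events must be non-decreasing in press_time "
                        f"({ev.press_time} after {last})"
                    )
                last = ev.press_time

    @property
    def n_missing_press(self) -> int:
        return sum(1 for ev in self.events if ev.press_time is None)

    @property
    def n_incomplete(self) -> int:
        return sum(1 for ev in self.events if not ev.complete)

    def press_times(self) -> list[float]:
        return [ev.press_time for ev in self.events if ev.press_time is not None]


@dataclass(frozen=True)
class TemplateGroup:
    """One expected sound: the keys struck together and their shared onset."""

    key_indices: tuple[int, ...]
    expected_onset: float

    def __post_init__(self) -> None:
        if len(self.key_indices) == 0:
            raise ValueError("template group must contain at least one key")
        if len(set(self.key_indices)) != len(self.key_indices):
            raise ValueError(f"duplicate key indices in group: {self.key_indices}")


@dataclass(frozen=True)
class Template:
    """Errorless reference performance: ordered key groups with onsets.

    Onset units are arbitrary but consistent (the rhythm score works on
    proportions, so only ratios matter); onsets must be strictly increasing.
    """

    template_id: str
    register_start_index: int
    groups: tuple[TemplateGroup, ...]

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise ValueError("a template must contain at least one group")
        onsets = [g.expected_onset for g in self.groups]
        for a, b in zip(onsets, onsets[1:]):
            if not b > a:
                raise ValueError(
                    f"template onsets must be strictly increasing, got {a} then {b}"
                )

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_expected_keypresses(self) -> int:
        return sum(len(g.key_indices) for g in self.groups)

    def expected_onsets(self) -> list[float]:
        return [g.expected_onset for g in self.groups]


@dataclass(frozen=True)
class ScoreRecord:
    """One scored trial, ready for the behavioural statistics layer."""

    participant_id: str
    trial_id: str
    condition: str
    melodic_ratio: float | None
    rhythm_eligible: bool
    rhythm_deviance_pct: float | None
    n_events_dropped: int = 0

    def __post_init__(self) -> None:
        if not self.rhythm_eligible and self.rhythm_deviance_pct is not None:
            raise ValueError("rhythm_deviance_pct must be missing when ineligible")


# ---------------------------------------------------------------------------
# keypress logs


def _parse_optional_float(text: str, what: str, lineno: int) -> float | None:
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise LogParseError(f"line {lineno}: cannot parse {what} {text!r}") from None


def _parse_optional_int(text: str, what: str, lineno: int) -> int | None:
    if text == "":
        return None
    try:
        return int(text)
    except ValueError:
        raise LogParseError(f"line {lineno}: cannot parse {what} {text!r}") from None


def read_keypress_log(path: str | Path, keymap_size: int) -> list[Performance]:
    """Read a TSV keypress log into one :class:`Performance` per trial.

    Rows with ``key_index`` outside ``[0, keymap_size)`` are rejected with an
    error naming the offending line, as are malformed rows and unknown
    columns.  Missing press/release fields are preserved (the events are
    retained and flagged) so that the dropped fraction can be reported after
    :func:`drop_incomplete_events`.

    Events are ordered stably by press time within each trial: input order
    breaks ties, and an event with a missing press time stays directly after
    its predecessor.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(LOG_COLUMNS):
            unknown = [c for c in header if c not in LOG_COLUMNS]
            if unknown:
                raise LogParseError(f"unknown column(s) in header: {unknown}")
            raise LogParseError(
                f"header mismatch: expected {list(LOG_COLUMNS)}, got {header}"
            )
        trials: dict[tuple[str, str, str, str], list[tuple[float, int, KeyEvent]]] = {}
        order: list[tuple[str, str, str, str]] = []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if line == "":
                continue
            parts = line.split("\t")
            if len(parts) != len(LOG_COLUMNS):
                raise LogParseError(
                    f"line {lineno}: expected {len(LOG_COLUMNS)} fields, got {len(parts)}"
                )
            participant, task, trial, condition = parts[:4]
            key_index = _parse_optional_int(parts[4], "key_index", lineno)
            if key_index is None:
                raise LogParseError(f"line {lineno}: key_index is required")
            if not 0 <= key_index < keymap_size:
                raise LogParseError(
                    f"line {lineno}: key_index {key_index} outside keymap "
                    f"[0, {keymap_size - 1}]; row rejected"
                )
            press = _parse_optional_float(parts[5], "press_ms", lineno)
            release = _parse_optional_float(parts[6], "release_ms", lineno)
            velocity = _parse_optional_int(parts[7], "velocity", lineno)
            try:
                event = KeyEvent(key_index, press, release, velocity)
            except ValueError as exc:
                raise LogParseError(f"line {lineno}: {exc}") from None
            key = (participant, task, trial, condition)
            if key not in trials:
                trials[key] = []
                order.append(key)
            bucket = trials[key]
            # sort key: carry the last seen press time forward for missing-press
            # events so a stable sort keeps them after their predecessor
            anchor = press if press is not None else (bucket[-1][0] if bucket else -math.inf)
            bucket.append((anchor, len(bucket), event))

    performances = []
    for participant, task, trial, condition in order:
        rows = sorted(trials[(participant, task, trial, condition)], key=lambda r: (r[0], r[1]))
        performances.append(
            Performance(
                participant_id=participant,
                task_id=task,
                trial_id=trial,
                condition=condition,
                events=tuple(ev for _, _, ev in rows),
            )
        )
    return performances


def write_keypress_log(performances: Iterable[Performance], path: str | Path) -> None:
    """Write performances back to the TSV log dialect (inverse of reading)."""
    path = Path(path)

    def fmt(x: float | int | None) -> str:
        if x is None:
            return ""
        if isinstance(x, float) and x.is_integer():
            return str(int(x))
        return str(x)

    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(LOG_COLUMNS) + "\n")
        for perf in performances:
            for ev in perf.events:
                fh.write(
                    "\t".join(
                        [
                            perf.participant_id,
                            perf.task_id,
                            perf.trial_id,
                            perf.condition,
                            str(ev.key_index),
                            fmt(ev.press_time),
                            fmt(ev.release_time),
                            fmt(ev.velocity),
                        ]
                    )
                    + "\n"
                )


def drop_incomplete_events(performance: Performance) -> tuple[Performance, int]:
    """Remove events missing a press or release time; return the count removed.

    Ordering of the remaining events is preserved.
    """
    kept = tuple(ev for ev in performance.events if ev.complete)
    n_dropped = len(performance.events) - len(kept)
    return replace(performance, events=kept), n_dropped


# ---------------------------------------------------------------------------
# templates


def read_template(path: str | Path) -> Template:
    with Path(path).open("r", encoding="utf-8") as fh:
        obj = json.load(fh)
    try:
        groups = tuple(
            TemplateGroup(tuple(int(k) for k in g["keys"]), float(g["onset"]))
            for g in obj["groups"]
        )
        return Template(
            template_id=str(obj["template_id"]),
            register_start_index=int(obj["register_start_index"]),
            groups=groups,
        )
    except KeyError as exc:
        raise ValueError(f"template JSON missing field {exc}") from None


def write_template(template: Template, path: str | Path) -> None:
    obj = {
        "template_id": template.template_id,
        "register_start_index": template.register_start_index,
        "groups": [
            {"keys": list(g.key_indices), "onset": g.expected_onset}
            for g in template.groups
        ],
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# score tables


_SCORE_COLUMNS = (
    "participant",
    "trial",
    "condition",
    "melodic_ratio",
    "rhythm_eligible",
    "rhythm_deviance_pct",
    "n_events_dropped",
)


def write_score_table(records: Iterable[ScoreRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_SCORE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.participant_id,
                        r.trial_id,
                        r.condition,
                        "" if r.melodic_ratio is None else repr(r.melodic_ratio),
                        str(int(r.rhythm_eligible)),
                        ""
                        if r.rhythm_deviance_pct is None
                        else repr(r.rhythm_deviance_pct),
                        str(r.n_events_dropped),
                    ]
                )
                + "\n"
            )


def read_score_table(path: str | Path) -> list[ScoreRecord]:
    records = []
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(_SCORE_COLUMNS):
            raise ValueError(f"score table header mismatch: {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(_SCORE_COLUMNS):
                raise ValueError(f"line {lineno}: wrong field count")
            records.append(
                ScoreRecord(
                    participant_id=parts[0],
                    trial_id=parts[1],
                    condition=parts[2],
                    melodic_ratio=None if parts[3] == "" else float(parts[3]),
                    rhythm_eligible=bool(int(parts[4])),
                    rhythm_deviance_pct=None if parts[5] == "" else float(parts[5]),
                    n_events_dropped=int(parts[6]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# one-value-per-line series


def _read_series(path: str | Path) -> list[float]:
    values = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise ValueError(f"line {lineno}: cannot parse value {text!r}") from None
    return values


def read_latency_samples(path: str | Path) -> list[float]:
    """Read latency samples in milliseconds, one per line."""
    return _read_series(path)


def read_fd_series(path: str | Path) -> list[float]:
    """Read a framewise-displacement series in mm, one value per volume."""
    return _read_series(path)
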