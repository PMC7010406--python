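"""Trial-log I/O: a diff-stable TSV format with a commented metadata header.

One file per behavioral session.  Header lines are ``# key: value`` pairs
(format version, subject/session labels, injection phase and treatment, the
target layout); the body is one tab-separated row per trial.  Timestamps are
integer milliseconds from session start; touch coordinates are written with
two fixed decimals; missing values (e.g. no touch on a no-hit trial) are
``NA``.  Writing is deterministic, so write -> read -> write is
byte-idempotent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .task_engine import TargetLayout, TaskMode

FORMAT_VERSION = 1

COLUMNS = (
    "trial_index",
    "block_id",
    "task_mode",
    "cue_target",
    "cue_onset_ms",
    "release_prev_ms",
    "touch_ms",
    "touch_x",
    "touch_y",
    "raw_outcome",
)


class Phase(str, Enum):
    PRE = "PRE"
    POST = "POST"


class Treatment(str, Enum):
    ANISOMYCIN = "ANISOMYCIN"
    MUSCIMOL = "MUSCIMOL"
    SALINE = "SALINE"
    NONE = "NONE"


class RawOutcome(str, Enum):
    HIT = "HIT"
    NO_HIT = "NO_HIT"


class SessionValidationError(ValueError):
    """A session log violated the documented schema; names the offense."""


@dataclass(frozen=True)
class TrialRecord:
    """Raw events of one trial (one reach attempt)."""

    trial_index: int
    block_id: int
    task_mode: TaskMode
    cue_target: int
    cue_onset_ms: int
    release_prev_ms: Optional[int]
    touch_ms: Optional[int]
    touch_x: Optional[float]
    touch_y: Optional[float]
    raw_outcome: RawOutcome

    def __post_init__(self) -> None:
        if (
            self.release_prev_ms is not None
            and self.touch_ms is not None
            and self.release_prev_ms > self.touch_ms
        ):
            raise SessionValidationError(
                f"trial {self.trial_index}: release_prev_ms "
                f"({self.release_prev_ms}) > touch_ms ({self.touch_ms})"
            )


@dataclass
class SessionLog:
    """An ordered trial stream plus session metadata."""

    monkey_id: str
    session_id: str
    phase: Phase
    treatment: Treatment
    day_offset: int
    layout: TargetLayout
    trials: list[TrialRecord] = field(default_factory=list)

    def validate(self) -> None:
        if not self.trials:
            raise SessionValidationError("no trials")
        prev_index = None
        for t in self.trials:
            if t.cue_target not in self.layout.target_ids:
                raise SessionValidationError(
                    f"trial {t.trial_index}: unknown target ID {t.cue_target}"
                )
            if prev_index is not None and t.trial_index <= prev_index:
                raise SessionValidationError(
                    f"trial_index not strictly increasing at {t.trial_index}"
                )
            prev_index = t.trial_index

    def to_frame(self) -> pd.DataFrame:
        """Trials as a DataFrame (enums as strings, missing values as NaN)."""
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "trial_index": t.trial_index,
                    "block_id": t.block_id,
                    "task_mode": t.task_mode.value,
                    "cue_target": t.cue_target,
                    "cue_onset_ms": t.cue_onset_ms,
                    "release_prev_ms": t.release_prev_ms,
                    "touch_ms": t.touch_ms,
                    "touch_x": t.touch_x,
                    "touch_y": t.touch_y,
                    "raw_outcome": t.raw_outcome.value,
                }
            )
        return pd.DataFrame(rows, columns=list(COLUMNS))


def _fmt_opt_int(v: Optional[int]) -> str:
    return "NA" if v is None else str(int(v))


def _fmt_opt_float(v: Optional[float]) -> str:
    return "NA" if v is None else f"{v:.2f}"


def write_session(log: SessionLog, path: Union[str, Path]) -> None:
    """Write a validated session log as deterministic TSV text."""
    log.validate()
    lines = [
        f"# format_version: {FORMAT_VERSION}",
        f"# monkey_id: {log.monkey_id}",
        f"# session_id: {log.session_id}",
        f"# phase: {log.phase.value}",
        f"# treatment: {log.treatment.value}",
        f"# day_offset: {log.day_offset}",
        "# layout_centers: "
        + ";".join(f"{x:.2f},{y:.2f}" for x, y in log.layout.centers),
        f"# layout_half_width: {log.layout.half_width:.2f}",
        "\t".join(COLUMNS),
    ]
    for t in log.trials:
        lines.append(
            "\t".join(
                (
                    str(t.trial_index),
                    str(t.block_id),
                    t.task_mode.value,
                    str(t.cue_target),
                    str(int(t.cue_onset_ms)),
                    _fmt_opt_int(t.release_prev_ms),
                    _fmt_opt_int(t.touch_ms),
                    _fmt_opt_float(t.touch_x),
                    _fmt_opt_float(t.touch_y),
                    t.raw_outcome.value,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_opt_int(s: str, line_no: int, col: str) -> Optional[int]:
    if s == "NA":
        return None
    try:
        return int(s)
    except ValueError:
        raise SessionValidationError(f"line {line_no}: column {col}: not an integer: {s!r}")


def _parse_opt_float(s: str, line_no: int, col: str) -> Optional[float]:
    if s == "NA":
        return None
    try:
        v = float(s)
    except ValueError:
        raise SessionValidationError(f"line {line_no}: column {col}: not a number: {s!r}")
    if math.isnan(v):
        raise SessionValidationError(f"line {line_no}: column {col}: NaN not allowed")
    return v


def read_session(path: Union[str, Path]) -> SessionLog:
    """Read and fully validate a session log; malformed rows are reported
    with their 1-based line numbers."""
    path = Path(path)
    text = path.read_text()
    meta: dict[str, str] = {}
    header_cols: Optional[list[str]] = None
    trials: list[TrialRecord] = []
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
            continue
        fields = line.split("\t")
        if header_cols is None:
            header_cols = fields
            missing = set(COLUMNS) - set(header_cols)
            if missing:
                raise SessionValidationError(
                    f"line {line_no}: missing column(s): {', '.join(sorted(missing))}"
                )
            continue
        if len(fields) != len(header_cols):
            raise SessionValidationError(
                f"line {line_no}: expected {len(header_cols)} fields, got {len(fields)}"
            )
        row = dict(zip(header_cols, fields))
        try:
            trial = TrialRecord(
                trial_index=int(row["trial_index"]),
                block_id=int(row["block_id"]),
                task_mode=TaskMode(row["task_mode"]),
                cue_target=int(row["cue_target"]),
                cue_onset_ms=int(row["cue_onset_ms"]),
                release_prev_ms=_parse_opt_int(row["release_prev_ms"], line_no, "release_prev_ms"),
                touch_ms=_parse_opt_int(row["touch_ms"], line_no, "touch_ms"),
                touch_x=_parse_opt_float(row["touch_x"], line_no, "touch_x"),
                touch_y=_parse_opt_float(row["touch_y"], line_no, "touch_y"),
                raw_outcome=RawOutcome(row["raw_outcome"]),
            )
        except SessionValidationError as exc:
            raise SessionValidationError(f"line {line_no}: {exc}") from None
        except ValueError as exc:
            raise SessionValidationError(f"line {line_no}: {exc}") from None
        trials.append(trial)

    if "format_version" not in meta:
        raise SessionValidationError("missing '# format_version' header")
    if int(meta["format_version"]) != FORMAT_VERSION:
        raise SessionValidationError(
            f"unsupported format_version {meta['format_version']}"
        )
    try:
        centers = tuple(
            tuple(float(v) for v in pair.split(","))
            for pair in meta["layout_centers"].split(";")
        )
        layout = TargetLayout(centers=centers, half_width=float(meta["layout_half_width"]))
    except KeyError as exc:
        raise SessionValidationError(f"missing layout header: {exc}") from None

    log = SessionLog(
        monkey_id=meta.get("monkey_id", ""),
        session_id=meta.get("session_id", ""),
        phase=Phase(meta.get("phase", "PRE")),
        treatment=Treatment(meta.get("treatment", "NONE")),
        day_offset=int(meta.get("day_offset", 0)),
        layout=layout,
        trials=trials,
    )
    log.validate()
    return log


DEFAULT_COLUMN_MAP = {c: c for c in COLUMNS}


def read_table_adapter(
    path: Union[str, Path],
    column_map: Optional[dict[str, str]] = None,
    *,
    layout: Optional[TargetLayout] = None,
    monkey_id: str = "",
    session_id: str = "",
    phase: Phase = Phase.PRE,
    treatment: Treatment = Treatment.NONE,
    day_offset: int = 0,
) -> SessionLog:
    """Import a deposited spreadsheet-style trial table (CSV or XLSX).

    ``column_map`` maps this package's trial-log column names to the columns
    of the deposited table; the deposited schema is not hard-coded.  Rows are
    validated exactly as in :func:`read_session`.
    """
    path = Path(path)
    column_map = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    missing = [src for src in column_map.values() if src not in df.columns]
    if missing:
        raise SessionValidationError(
            f"input table lacks mapped column(s): {', '.join(missing)}"
        )
    trials = []
    for i, row in df.iterrows():
        def get(col: str):
            v = row[column_map[col]]
            return None if pd.isna(v) else v

        trials.append(
            TrialRecord(
                trial_index=int(get("trial_index")),
                block_id=int(get("block_id")),
                task_mode=TaskMode(str(get("task_mode"))),
                cue_target=int(get("cue_target")),
                cue_onset_ms=int(get("cue_onset_ms")),
                release_prev_ms=None if get("release_prev_ms") is None else int(get("release_prev_ms")),
                touch_ms=None if get("touch_ms") is None else int(get("touch_ms")),
                touch_x=None if get("touch_x") is None else float(get("touch_x")),
                touch_y=None if get("touch_y") is None else float(get("touch_y")),
                raw_outcome=RawOutcome(str(get("raw_outcome"))),
            )
        )
    log = SessionLog(
        monkey_id=monkey_id,
        session_id=session_id,
        phase=phase,
        treatment=treatment,
        day_offset=day_offset,
        layout=layout if layout is not None else TargetLayout(),
        trials=trials,
    )
    log.validate()
    return log
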