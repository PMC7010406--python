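"""Trial classification: RT/MT derivation, endpoint assignment, error
taxonomy, predictive labeling, exclusions, and per-movement summaries.

Definitions follow the study conventions:

* MT is the interval from release of contact on one target to touch of the
  next.
* RT in the Random task is cue onset to touch; in the Repeating task it is
  the inter-touch interval minus the 400 ms cue delay, so anticipatory
  reaches yield negative RTs.
* A correct response with RT < 150 ms is predictive.
* Touches between targets count as touches to the nearest target; a CORRECT
  response requires landing inside the correct target's acceptance radius.
* An accuracy error is a reach in the correct direction (along the
  horizontal target row) ending outside the correct target; a direction
  error is a reach in the opposite direction; zero horizontal displacement
  is OTHER_ERROR.
* A correct response immediately following an error or a miss is CORRECTIVE
  (the repeated target is predictable) and excluded, as are no-hit trials
  and Random-task trials with RT < 150 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .session_io import Phase, RawOutcome, SessionLog, TrialRecord
from .task_engine import TargetLayout, TaskConfig, TaskMode, DEFAULT_CUE_DELAY_MS

Movement = tuple[int, int]

PREDICTIVE_THRESHOLD_MS = 150
RESPONSE_WINDOW_MS = 800


class ResponseClass(str, Enum):
    CORRECT = "CORRECT"
    ACCURACY_ERROR = "ACCURACY_ERROR"
    DIRECTION_ERROR = "DIRECTION_ERROR"
    OTHER_ERROR = "OTHER_ERROR"
    NO_HIT = "NO_HIT"
    CORRECTIVE = "CORRECTIVE"


ERROR_CLASSES = frozenset(
    {
        ResponseClass.ACCURACY_ERROR,
        ResponseClass.DIRECTION_ERROR,
        ResponseClass.OTHER_ERROR,
        ResponseClass.NO_HIT,
    }
)


class ExclusionReason(str, Enum):
    CORRECTIVE = "corrective"
    NO_HIT = "no_hit"
    FAST_RANDOM = "fast_random"
    NO_MOVEMENT = "no_movement"  # first trial of a block / zero-length reach


@dataclass
class ClassifiedTrial:
    """A trial after RT/MT derivation, endpoint assignment and labeling."""

    trial_index: int
    block_id: int
    task_mode: TaskMode
    cue_target: int
    movement: Optional[Movement]
    rt_ms: Optional[float]
    mt_ms: Optional[float]
    assigned_target: Optional[int]
    inside_target: bool
    response_class: ResponseClass
    predictive: bool
    included: bool = True
    exclusion_reason: Optional[ExclusionReason] = None


def derive_rt_mt(
    trial: TrialRecord,
    prev_touch_ms: Optional[float],
    config: TaskConfig,
) -> tuple[Optional[float], Optional[float]]:
    """RT and MT for one trial from its raw timestamps.

    RT(RANDOM) = touch - cue onset; RT(REPEATING) = (touch - previous touch)
    - cue delay, which may be negative for anticipations.  MT = touch -
    release of previous contact; missing release leaves MT undefined while
    the trial remains RT-classifiable.
    """
    if trial.touch_ms is None:
        return None, None
    if config.mode is TaskMode.RANDOM:
        rt: Optional[float] = float(trial.touch_ms - trial.cue_onset_ms)
    else:
        if prev_touch_ms is None:
            rt = None
        else:
            if prev_touch_ms > trial.touch_ms:
                raise ValueError("previous touch after current touch")
            rt = float(trial.touch_ms - prev_touch_ms) - config.cue_delay_ms
    mt = (
        float(trial.touch_ms - trial.release_prev_ms)
        if trial.release_prev_ms is not None
        else None
    )
    return rt, mt


def classify_predictive(rt_ms: float, threshold_ms: float = PREDICTIVE_THRESHOLD_MS) -> bool:
    """True iff RT is strictly below the predictive cutoff (negative RTs,
    i.e. anticipations, are predictive)."""
    return rt_ms < threshold_ms


def assign_touch_to_target(xy, layout: TargetLayout) -> tuple[int, bool]:
    """Nearest-center assignment with ties broken toward the lower ID."""
    return layout.nearest_target(xy)


def classify_response(
    from_target: Optional[int],
    to_target: int,
    assigned_target: Optional[int],
    inside_target: bool,
    touch_x: Optional[float],
    layout: TargetLayout,
) -> ResponseClass:
    """Error taxonomy for one reach (CORRECTIVE relabeling happens later).

    Direction is judged on the horizontal axis only, since the targets form
    a horizontal row.  With no origin target the reach cannot be classified
    directionally; a wrong endpoint then falls to OTHER_ERROR.
    """
    if assigned_target is None or touch_x is None:
        return ResponseClass.NO_HIT
    if assigned_target == to_target and inside_target:
        return ResponseClass.CORRECT
    if from_target is None:
        return ResponseClass.OTHER_ERROR
    intended = np.sign(layout.center_x(to_target) - layout.center_x(from_target))
    actual = np.sign(touch_x - layout.center_x(from_target))
    if actual == 0 or intended == 0:
        return ResponseClass.OTHER_ERROR
    return ResponseClass.ACCURACY_ERROR if actual == intended else ResponseClass.DIRECTION_ERROR


def classify_session(
    log: SessionLog,
    *,
    predictive_threshold_ms: float = PREDICTIVE_THRESHOLD_MS,
    response_window_ms: float = RESPONSE_WINDOW_MS,
    cue_delays: Optional[dict[TaskMode, int]] = None,
) -> pd.DataFrame:
    """Classify every trial of a session; returns one row per trial.

    The hand's position is tracked as the target nearest to each actual
    touch; the first trial of each block (and any zero-length reach, where
    the hand already rests on the cued target) has no defined movement and
    is excluded from movement analyses.
    """
    cue_delays = dict(DEFAULT_CUE_DELAY_MS) if cue_delays is None else cue_delays
    layout = log.layout

    rows: list[ClassifiedTrial] = []
    last_touch_ms: Optional[int] = None
    hand_target: Optional[int] = None
    prev_block: Optional[int] = None

    for t in log.trials:
        delay = cue_delays[t.task_mode]
        block_start = t.block_id != prev_block
        prev_block = t.block_id

        no_touch = (
            t.raw_outcome is RawOutcome.NO_HIT
            or t.touch_ms is None
            or t.touch_ms > t.cue_onset_ms + response_window_ms
        )

        # RT / MT
        rt: Optional[float]
        mt: Optional[float]
        if no_touch:
            rt, mt = None, None
        elif t.task_mode is TaskMode.RANDOM:
            rt = float(t.touch_ms - t.cue_onset_ms)
            mt = float(t.touch_ms - t.release_prev_ms) if t.release_prev_ms is not None else None
        else:
            rt = (
                float(t.touch_ms - last_touch_ms) - delay
                if last_touch_ms is not None
                else None
            )
            mt = float(t.touch_ms - t.release_prev_ms) if t.release_prev_ms is not None else None

        # endpoint assignment
        if no_touch or t.touch_x is None:
            assigned, inside = None, False
        else:
            assigned, inside = layout.nearest_target((t.touch_x, t.touch_y))

        movement: Optional[Movement] = None
        if not block_start and hand_target is not None and hand_target != t.cue_target:
            movement = (hand_target, t.cue_target)

        response = classify_response(
            movement[0] if movement else hand_target,
            t.cue_target,
            assigned,
            inside,
            t.touch_x if not no_touch else None,
            layout,
        )
        predictive = rt is not None and classify_predictive(rt, predictive_threshold_ms)

        rows.append(
            ClassifiedTrial(
                trial_index=t.trial_index,
                block_id=t.block_id,
                task_mode=t.task_mode,
                cue_target=t.cue_target,
                movement=movement,
                rt_ms=rt,
                mt_ms=mt,
                assigned_target=assigned,
                inside_target=inside,
                response_class=response,
                predictive=predictive,
            )
        )

        if not no_touch:
            last_touch_ms = t.touch_ms
            hand_target = assigned

    _relabel_corrective(rows)
    apply_exclusions(rows)

    df = pd.DataFrame(
        {
            "trial_index": [r.trial_index for r in rows],
            "block_id": [r.block_id for r in rows],
            "task_mode": [r.task_mode.value for r in rows],
            "cue_target": [r.cue_target for r in rows],
            "from_target": [r.movement[0] if r.movement else np.nan for r in rows],
            "to_target": [r.movement[1] if r.movement else np.nan for r in rows],
            "rt_ms": [np.nan if r.rt_ms is None else r.rt_ms for r in rows],
            "mt_ms": [np.nan if r.mt_ms is None else r.mt_ms for r in rows],
            "assigned_target": [np.nan if r.assigned_target is None else r.assigned_target for r in rows],
            "inside_target": [r.inside_target for r in rows],
            "response_class": [r.response_class.value for r in rows],
            "predictive": [r.predictive for r in rows],
            "included": [r.included for r in rows],
            "exclusion_reason": [
                "" if r.exclusion_reason is None else r.exclusion_reason.value for r in rows
            ],
        }
    )
    df["phase"] = log.phase.value
    df["session_id"] = log.session_id
    return df


def _relabel_corrective(rows: list[ClassifiedTrial]) -> None:
    """Relabel a CORRECT trial as CORRECTIVE when the immediately preceding
    trial was any error or a miss (the erroneous trial is repeated, so the
    target is predictable).  Applied before exclusions; looks back exactly
    one trial."""
    for prev, cur in zip(rows, rows[1:]):
        if cur.response_class is ResponseClass.CORRECT and prev.response_class in ERROR_CLASSES:
            cur.response_class = ResponseClass.CORRECTIVE


def apply_exclusions(rows: list[ClassifiedTrial]) -> list[ClassifiedTrial]:
    """Set inclusion flags: corrective responses, no-hit trials, fast
    (<150 ms RT) Random-task trials, and trials without a defined movement
    are excluded; everything else is analyzed."""
    for r in rows:
        reason: Optional[ExclusionReason] = None
        if r.response_class is ResponseClass.CORRECTIVE:
            reason = ExclusionReason.CORRECTIVE
        elif r.response_class is ResponseClass.NO_HIT:
            reason = ExclusionReason.NO_HIT
        elif r.task_mode is TaskMode.RANDOM and r.rt_ms is not None and r.rt_ms < PREDICTIVE_THRESHOLD_MS:
            reason = ExclusionReason.FAST_RANDOM
        elif r.movement is None:
            reason = ExclusionReason.NO_MOVEMENT
        r.exclusion_reason = reason
        r.included = reason is None
    return rows


@dataclass
class MovementSummary:
    """Per-movement counts and timing for one task mode and phase.

    ``mean_rt_ms``/``mean_mt_ms`` (and the retained per-trial value arrays
    used by the t-tests) cover included CORRECT responses.
    """

    movement: Movement
    task_mode: TaskMode
    phase: Phase
    n_included: int
    n_correct: int
    n_accuracy_err: int
    n_direction_err: int
    n_other_err: int
    n_predictive: int
    n_nonpredictive: int
    mean_rt_ms: float
    mean_mt_ms: float
    rt_values: np.ndarray = field(default_factory=lambda: np.array([]))
    mt_values: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_errors(self) -> int:
        return self.n_accuracy_err + self.n_direction_err + self.n_other_err

    @property
    def error_rate(self) -> float:
        return self.n_errors / self.n_included

    @property
    def predictive_rate(self) -> Optional[float]:
        return self.n_predictive / self.n_correct if self.n_correct else None


def summarize_by_movement(classified: pd.DataFrame) -> list[MovementSummary]:
    """One summary per (movement, task mode) over included trials; movements
    with zero included trials are omitted with a warning."""
    inc = classified[classified["included"]]
    summaries: list[MovementSummary] = []
    seen_empty = (
        classified[~classified["included"] & classified["from_target"].notna()]
        .groupby(["task_mode", "from_target", "to_target"])
        .size()
    )
    phase = Phase(classified["phase"].iloc[0]) if len(classified) else Phase.PRE

    for (mode, f, to), g in inc.groupby(["task_mode", "from_target", "to_target"], sort=True):
        correct = g[g["response_class"] == ResponseClass.CORRECT.value]
        n_pred = int(correct["predictive"].sum())
        rt_vals = correct["rt_ms"].dropna().to_numpy(float)
        mt_vals = correct["mt_ms"].dropna().to_numpy(float)
        summaries.append(
            MovementSummary(
                movement=(int(f), int(to)),
                task_mode=TaskMode(mode),
                phase=phase,
                n_included=len(g),
                n_correct=len(correct),
                n_accuracy_err=int((g["response_class"] == ResponseClass.ACCURACY_ERROR.value).sum()),
                n_direction_err=int((g["response_class"] == ResponseClass.DIRECTION_ERROR.value).sum()),
                n_other_err=int((g["response_class"] == ResponseClass.OTHER_ERROR.value).sum()),
                n_predictive=n_pred,
                n_nonpredictive=len(correct) - n_pred,
                mean_rt_ms=float(rt_vals.mean()) if rt_vals.size else float("nan"),
                mean_mt_ms=float(mt_vals.mean()) if mt_vals.size else float("nan"),
                rt_values=rt_vals,
                mt_values=mt_vals,
            )
        )
    covered = {(s.task_mode.value, float(s.movement[0]), float(s.movement[1])) for s in summaries}
    for key in seen_empty.index:
        if key not in covered:
            warnings.warn(
                f"movement {int(key[1])}->{int(key[2])} ({key[0]}): no included trials; omitted",
                stacklevel=2,
            )
    return summaries


def summaries_to_frame(summaries: Sequence[MovementSummary]) -> pd.DataFrame:
    """Summaries as a flat table (per-trial value arrays are not exported)."""
    return pd.DataFrame(
        {
            "from_target": [s.movement[0] for s in summaries],
            "to_target": [s.movement[1] for s in summaries],
            "task_mode": [s.task_mode.value for s in summaries],
            "phase": [s.phase.value for s in summaries],
            "n_included": [s.n_included for s in summaries],
            "n_correct": [s.n_correct for s in summaries],
            "n_accuracy_err": [s.n_accuracy_err for s in summaries],
            "n_direction_err": [s.n_direction_err for s in summaries],
            "n_other_err": [s.n_other_err for s in summaries],
            "n_predictive": [s.n_predictive for s in summaries],
            "n_nonpredictive": [s.n_nonpredictive for s in summaries],
            "mean_rt_ms": [s.mean_rt_ms for s in summaries],
            "mean_mt_ms": [s.mean_mt_ms for s in summaries],
        }
    )
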