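"""Deterministic state machine for the Random and Repeating reaching tasks.

Five touch targets sit in a horizontal row, numbered 1-5 from left to right.
In the Random task the next cued target is drawn pseudo-randomly (excluding
the target just hit, so every trial is a nonzero movement) and appears 100 ms
after the previous correct touch.  In the Repeating task targets follow a
fixed three-element sequence (e.g. 5-3-1) and appear 400 ms after the
previous correct touch, a delay that allows anticipatory (predictive)
responses.  The subject must touch the cued target within an 800 ms response
window; after an error or a miss the same target is cued again.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np

#: The three repeating sequences used in the study design.
PAPER_SEQUENCES: tuple[tuple[int, int, int], ...] = ((5, 3, 1), (1, 2, 4), (2, 3, 4))

N_TARGETS = 5


class TaskMode(str, Enum):
    RANDOM = "RANDOM"
    REPEATING = "REPEATING"


class Outcome(str, Enum):
    """Per-trial outcome as seen by the task scheduler."""

    CORRECT = "CORRECT"
    ERROR = "ERROR"
    NO_HIT = "NO_HIT"


class ConfigurationError(ValueError):
    """Raised when a task configuration or state is internally inconsistent."""


@dataclass(frozen=True)
class TargetLayout:
    """Geometry of the five touch targets.

    Parameters
    ----------
    centers : tuple of (x, y)
        Target centers in screen units, ordered by target ID 1..5.  The x
        coordinates must be strictly increasing (targets run left to right).
    half_width : float
        Acceptance radius: a touch within this distance of a center counts
        as landing inside that target.
    """

    centers: tuple[tuple[float, float], ...] = (
        (0.0, 0.0),
        (100.0, 0.0),
        (200.0, 0.0),
        (300.0, 0.0),
        (400.0, 0.0),
    )
    half_width: float = 30.0

    def __post_init__(self) -> None:
        if len(self.centers) != N_TARGETS:
            raise ConfigurationError(
                f"layout must have exactly {N_TARGETS} targets, got {len(self.centers)}"
            )
        if self.half_width <= 0:
            raise ConfigurationError("half_width must be positive")
        xs = [c[0] for c in self.centers]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ConfigurationError("target x coordinates must be strictly increasing")
        spacing = min(b - a for a, b in zip(xs, xs[1:]))
        if spacing <= 2 * self.half_width:
            raise ConfigurationError(
                "targets overlap: inter-center spacing must exceed 2 x half_width"
            )

    @property
    def target_ids(self) -> tuple[int, ...]:
        return tuple(range(1, N_TARGETS + 1))

    def center(self, target_id: int) -> np.ndarray:
        if not 1 <= target_id <= N_TARGETS:
            raise ConfigurationError(f"unknown target ID {target_id}")
        return np.asarray(self.centers[target_id - 1], dtype=float)

    def center_x(self, target_id: int) -> float:
        return self.centers[target_id - 1][0]

    def nearest_target(self, xy) -> tuple[int, bool]:
        """Assign a touch to the target with the nearest center (touches
        between targets count as touches to the closest one); ties break
        toward the lower target ID.  ``inside`` is True when the touch lies
        within the acceptance radius of that target."""
        xy = np.asarray(xy, dtype=float)
        dists = np.hypot(
            *(np.asarray(self.centers, dtype=float) - xy).T
        )
        idx = int(np.argmin(dists))  # first occurrence -> lower ID on ties
        return idx + 1, bool(dists[idx] <= self.half_width)


# Default cue delays by mode (ms after the previous correct touch).
DEFAULT_CUE_DELAY_MS = {TaskMode.RANDOM: 100, TaskMode.REPEATING: 400}


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of one task block.

    ``cue_delay_ms`` defaults to 100 ms for Random and 400 ms for Repeating.
    ``predictive_threshold_ms`` is the RT cutoff below which a correct
    response is classified as predictive (anticipatory).
    """

    mode: TaskMode
    sequence: Optional[tuple[int, int, int]] = None
    cue_delay_ms: Optional[int] = None
    response_window_ms: int = 800
    predictive_threshold_ms: int = 150

    def __post_init__(self) -> None:
        mode = TaskMode(self.mode)
        object.__setattr__(self, "mode", mode)
        if self.cue_delay_ms is None:
            object.__setattr__(self, "cue_delay_ms", DEFAULT_CUE_DELAY_MS[mode])
        if self.cue_delay_ms < 0:
            raise ConfigurationError("cue_delay_ms must be >= 0")
        if mode is TaskMode.REPEATING:
            if self.sequence is None:
                raise ConfigurationError("REPEATING mode requires a sequence")
            seq = tuple(int(t) for t in self.sequence)
            object.__setattr__(self, "sequence", seq)
            if len(seq) != 3:
                raise ConfigurationError("sequence must have exactly 3 elements")
            if any(not 1 <= t <= N_TARGETS for t in seq):
                raise ConfigurationError(f"sequence contains invalid target IDs: {seq}")
            # consecutive entries (cyclically) must differ, else a zero movement
            for a, b in zip(seq, seq[1:] + seq[:1]):
                if a == b:
                    raise ConfigurationError("sequence has equal consecutive entries")
        elif self.sequence is not None:
            raise ConfigurationError("RANDOM mode takes no sequence")


@dataclass
class TaskState:
    """Mutable scheduler state for one block.

    ``rng`` drives the pseudo-random target order in RANDOM mode and is the
    only source of randomness, so the cue stream is reproducible from the
    seed.
    """

    current_cued_target: int
    previous_correct_target: Optional[int] = None
    sequence_position: int = 0
    pending_repeat: bool = False
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))


def _draw_random_target(rng: np.random.Generator, exclude: Optional[int]) -> int:
    candidates = [t for t in range(1, N_TARGETS + 1) if t != exclude]
    return int(candidates[rng.integers(len(candidates))])


def initial_state(
    config: TaskConfig,
    rng: np.random.Generator,
    start_target: Optional[int] = None,
) -> TaskState:
    """State for the first trial of a block.

    The first cue is ``start_target`` if given, else the first sequence
    element (REPEATING) or a seeded uniform draw over all five targets
    (RANDOM).
    """
    if start_target is None:
        if config.mode is TaskMode.REPEATING:
            start_target = config.sequence[0]
        else:
            start_target = _draw_random_target(rng, exclude=None)
    if config.mode is TaskMode.REPEATING and start_target not in config.sequence:
        raise ConfigurationError(
            f"start target {start_target} not in sequence {config.sequence}"
        )
    pos = config.sequence.index(start_target) if config.mode is TaskMode.REPEATING else 0
    return TaskState(
        current_cued_target=int(start_target),
        previous_correct_target=None,
        sequence_position=pos,
        pending_repeat=False,
        rng=rng,
    )


def next_cue(
    state: TaskState, config: TaskConfig, last_outcome: Outcome
) -> tuple[TaskState, int]:
    """Advance the scheduler after a trial and return the next cued target.

    After an error or a miss the same target is cued again; after a correct
    response the Repeating task advances cyclically through its sequence and
    the Random task draws uniformly from the four targets other than the one
    just hit.
    """
    last_outcome = Outcome(last_outcome)
    if last_outcome is not Outcome.CORRECT:
        state.pending_repeat = True
        return state, state.current_cued_target

    just_hit = state.current_cued_target
    if config.mode is TaskMode.REPEATING:
        pos = (state.sequence_position + 1) % 3
        target = config.sequence[pos]
        state.sequence_position = pos
    else:
        target = _draw_random_target(state.rng, exclude=just_hit)
    state.previous_correct_target = just_hit
    state.current_cued_target = target
    state.pending_repeat = False
    return state, target


def cue_onset_time(previous_touch_ms: float, config: TaskConfig) -> float:
    """Cue appears ``cue_delay_ms`` after the previous (correct) touch."""
    if not np.isfinite(previous_touch_ms):
        raise ValueError("previous_touch_ms must be finite")
    return previous_touch_ms + config.cue_delay_ms


def is_within_window(cue_onset_ms: float, touch_ms: float, config: TaskConfig) -> bool:
    """True iff the touch lands no later than cue onset + response window.

    Touches *before* cue onset are within the window: in the Repeating task
    the subject may move to the next target in the sequence before the cue
    appears (an anticipation, yielding a negative RT).
    """
    if not (np.isfinite(cue_onset_ms) and np.isfinite(touch_ms)):
        raise ValueError("timestamps must be finite")
    return touch_ms <= cue_onset_ms + config.response_window_ms
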