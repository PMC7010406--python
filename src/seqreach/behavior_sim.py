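"""Generative model of reaching behavior on the two-task paradigm.

An agent is parameterized per movement (an ordered ``(from_target,
to_target)`` pair): the probability of responding predictively (from memory,
RT below the 150 ms threshold) versus under visual guidance, truncated-normal
RT and MT distributions, isotropic endpoint noise plus a signed bias along
the movement direction (undershoot when negative), and small probabilities of
a direction error (aiming at the nearest target on the opposite side of the
origin) or of not responding at all.

Injection scenarios shift these generative parameters per phase:
a protein-synthesis-inhibitor scenario (anisomycin) degrades only the
memory-guided Repeating task, a muscimol scenario degrades both tasks
indiscriminately, and a saline scenario changes nothing.  Deltas act on
generative parameters, never on derived statistics, so parameter-recovery
tests against the analysis pipeline are non-circular.

Accuracy errors (endpoints outside the correct target but in the correct
direction) are emergent from bias + noise; the exact per-movement correct
probability implied by the parameters is available in closed form via
:func:`expected_correct_prob` (offset circular Gaussian -> noncentral
chi-square), which the ground-truth sidecar records for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .task_engine import (
    Outcome,
    TargetLayout,
    TaskConfig,
    TaskMode,
    ConfigurationError,
    initial_state,
    next_cue,
)
from .session_io import Phase, RawOutcome, SessionLog, Treatment, TrialRecord

Movement = tuple[int, int]


@dataclass(frozen=True)
class MovementParams:
    """Generative parameters for one movement.

    ``rt_predictive``/``rt_cued``/``mt`` are (location, scale) of truncated
    normal distributions in ms.  Predictive RTs are truncated below the
    150 ms threshold (and above minus the cue delay, so the touch follows the
    previous one); cued RTs live in [150 ms, response window].
    """

    p_predictive: float = 0.0
    rt_predictive: tuple[float, float] = (50.0, 60.0)
    rt_cued: tuple[float, float] = (350.0, 90.0)
    mt: tuple[float, float] = (160.0, 30.0)
    endpoint_sigma: float = 12.0
    undershoot_bias: float = 0.0
    p_direction_error: float = 0.0
    p_no_hit: float = 0.005
    dwell_ms: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_predictive", "p_direction_error", "p_no_hit"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.p_predictive + self.p_no_hit > 1.0:
            raise ConfigurationError("p_predictive + p_no_hit must be <= 1")
        for name in ("rt_predictive", "rt_cued", "mt"):
            if getattr(self, name)[1] < 0:
                raise ConfigurationError(f"{name} scale must be >= 0")
        if self.endpoint_sigma < 0:
            raise ConfigurationError("endpoint_sigma must be >= 0")


@dataclass(frozen=True)
class AgentParams:
    """A default parameter set plus per-movement overrides.

    ``p_fast_random`` is the small probability of an anticipatory (guessed)
    touch in the Random task, where the upcoming target cannot be known;
    such trials are excluded downstream by the fast-Random rule.
    """

    default: MovementParams = MovementParams()
    overrides: Mapping[Movement, MovementParams] = field(default_factory=dict)
    p_fast_random: float = 0.02

    def params_for(self, movement: Optional[Movement]) -> MovementParams:
        if movement is not None and movement in self.overrides:
            return self.overrides[movement]
        return self.default


class Scenario(str, Enum):
    ANISOMYCIN = "ANISOMYCIN"
    MUSCIMOL = "MUSCIMOL"
    SALINE = "SALINE"


class EffectScope(str, Enum):
    REPEATING_ONLY = "REPEATING_ONLY"
    BOTH_TASKS = "BOTH_TASKS"
    NONE = "NONE"


@dataclass(frozen=True)
class EffectDeltas:
    """Post-injection shifts applied to a movement's generative parameters."""

    d_p_predictive: float = 0.0  # subtracted from p_predictive
    sigma_multiplier: float = 1.0
    d_undershoot_bias: float = 0.0
    d_p_direction_error: float = 0.0
    d_rt_ms: float = 0.0  # added to the cued-RT location
    d_mt_ms: float = 0.0

    def is_null(self) -> bool:
        return (
            self.d_p_predictive == 0.0
            and self.sigma_multiplier == 1.0
            and self.d_undershoot_bias == 0.0
            and self.d_p_direction_error == 0.0
            and self.d_rt_ms == 0.0
            and self.d_mt_ms == 0.0
        )


_REQUIRED_SCOPE = {
    Scenario.ANISOMYCIN: EffectScope.REPEATING_ONLY,
    Scenario.MUSCIMOL: EffectScope.BOTH_TASKS,
    Scenario.SALINE: EffectScope.NONE,
}


@dataclass(frozen=True)
class InjectionEffect:
    scenario: Scenario
    scope: EffectScope
    default: EffectDeltas = EffectDeltas()
    overrides: Mapping[Movement, EffectDeltas] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = _REQUIRED_SCOPE[Scenario(self.scenario)]
        if EffectScope(self.scope) is not required:
            raise ConfigurationError(
                f"{self.scenario} requires scope {required.value}, got {self.scope}"
            )
        if self.scenario is Scenario.SALINE:
            if not self.default.is_null() or any(
                not d.is_null() for d in self.overrides.values()
            ):
                raise ConfigurationError("SALINE effect must have all-zero deltas")

    def applies_to(self, mode: TaskMode) -> bool:
        if self.scope is EffectScope.NONE:
            return False
        if self.scope is EffectScope.BOTH_TASKS:
            return True
        return mode is TaskMode.REPEATING

    def deltas_for(self, movement: Optional[Movement]) -> EffectDeltas:
        if movement is not None and movement in self.overrides:
            return self.overrides[movement]
        return self.default


def apply_deltas(mp: MovementParams, d: EffectDeltas) -> MovementParams:
    return replace(
        mp,
        p_predictive=float(np.clip(mp.p_predictive - d.d_p_predictive, 0.0, 1.0)),
        rt_cued=(mp.rt_cued[0] + d.d_rt_ms, mp.rt_cued[1]),
        mt=(mp.mt[0] + d.d_mt_ms, mp.mt[1]),
        endpoint_sigma=mp.endpoint_sigma * d.sigma_multiplier,
        undershoot_bias=mp.undershoot_bias + d.d_undershoot_bias,
        p_direction_error=float(np.clip(mp.p_direction_error + d.d_p_direction_error, 0.0, 1.0)),
    )


# ---------------------------------------------------------------------------
# sampling helpers


def _truncnorm_draw(
    rng: np.random.Generator, loc: float, scale: float, lo: float, hi: float
) -> float:
    """Rejection-sampled truncated normal (bounds are generous, so this is
    fast); degenerate scale returns the clipped location."""
    if scale == 0:
        return float(np.clip(loc, lo, hi))
    for _ in range(10_000):
        v = rng.normal(loc, scale)
        if lo <= v <= hi:
            return float(v)
    # pathological bounds: fall back to inverse-cdf sampling
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return float(sps.truncnorm.ppf(rng.random(), a, b, loc=loc, scale=scale))


def _opposite_side_target(
    from_target: int, aim_target: int, layout: TargetLayout
) -> Optional[int]:
    """Nearest target strictly on the opposite side of the origin target,
    or None when no target lies on that side."""
    dx = layout.center_x(aim_target) - layout.center_x(from_target)
    if dx == 0:
        return None
    candidates = [
        t
        for t in layout.target_ids
        if (layout.center_x(t) - layout.center_x(from_target)) * dx < 0
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda t: abs(layout.center_x(t) - layout.center_x(from_target)))


def generate_touch(
    from_target: Optional[int],
    aim_target: int,
    layout: TargetLayout,
    params: MovementParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int, bool]:
    """Sample a touch endpoint for one reach.

    With probability ``p_direction_error`` the aim is replaced by the nearest
    target strictly on the opposite side of the origin (skipped when no such
    target exists or the movement has no defined direction).  The endpoint is
    the aimed center, displaced by ``undershoot_bias`` along the movement
    direction, plus isotropic Gaussian noise of scale ``endpoint_sigma``.
    Accuracy errors are emergent, not drawn.

    Returns ``(xy, actual_aim, is_direction_error)``.
    """
    actual_aim = aim_target
    is_direction_error = False
    if (
        from_target is not None
        and from_target != aim_target
        and params.p_direction_error > 0
        and rng.random() < params.p_direction_error
    ):
        opp = _opposite_side_target(from_target, aim_target, layout)
        if opp is not None:
            actual_aim = opp
            is_direction_error = True

    center = layout.center(actual_aim)
    if from_target is not None and from_target != actual_aim:
        direction = center - layout.center(from_target)
        unit = direction / np.linalg.norm(direction)
    else:
        unit = np.zeros(2)
    xy = center + params.undershoot_bias * unit + params.endpoint_sigma * rng.standard_normal(2)
    return xy, actual_aim, is_direction_error


def _p_inside_offset(sigma: float, offset: float, half_width: float) -> float:
    """P(|Z| <= half_width) for Z ~ N(offset*e, sigma^2 I_2): noncentral
    chi-square with 2 df."""
    if sigma == 0:
        return float(abs(offset) <= half_width)
    return float(sps.ncx2.cdf((half_width / sigma) ** 2, 2, (offset / sigma) ** 2))


def expected_correct_prob(
    params: MovementParams, layout: TargetLayout, movement: Movement
) -> float:
    """Exact P(touch lands inside the correct target | a touch occurs).

    Because inter-target spacing exceeds twice the acceptance radius, landing
    inside the correct target implies it is also the nearest, so this equals
    the probability of a CORRECT classification among hit trials.
    """
    from_t, to_t = movement
    hw = layout.half_width
    opp = _opposite_side_target(from_t, to_t, layout)
    p_dir = params.p_direction_error if opp is not None else 0.0

    p_inside_direct = _p_inside_offset(params.endpoint_sigma, params.undershoot_bias, hw)
    if opp is not None and p_dir > 0:
        # endpoint mean when aiming at the opposite-side target
        c_to, c_from, c_opp = layout.center(to_t), layout.center(from_t), layout.center(opp)
        u = (c_opp - c_from) / np.linalg.norm(c_opp - c_from)
        mean = c_opp + params.undershoot_bias * u
        d = float(np.linalg.norm(mean - c_to))
        p_inside_via_opp = _p_inside_offset(params.endpoint_sigma, d, hw)
    else:
        p_inside_via_opp = 0.0
    return (1 - p_dir) * p_inside_direct + p_dir * p_inside_via_opp


# ---------------------------------------------------------------------------
# session simulation


@dataclass
class GroundTruth:
    """Generative truth recorded alongside a simulated session.

    ``per_movement`` maps ``(task_mode, from_target, to_target)`` to draw
    tallies and the effective (possibly injection-shifted) parameters used,
    including the closed-form expected correct probability.
    """

    phase: Phase
    scenario: Optional[Scenario]
    per_movement: dict[tuple[TaskMode, int, int], dict] = field(default_factory=dict)

    def _entry(self, key: tuple[TaskMode, int, int], mp: MovementParams,
               layout: TargetLayout, p_predictive: float) -> dict:
        if key not in self.per_movement:
            self.per_movement[key] = {
                "n_trials": 0,
                "n_predictive_drawn": 0,
                "n_direction_drawn": 0,
                "n_no_hit_drawn": 0,
                "n_correct": 0,
                # the anticipation probability actually used: p_predictive in
                # the Repeating task, the small guess rate in the Random task
                "p_predictive": p_predictive,
                "p_direction_error": mp.p_direction_error,
                "expected_correct_prob": expected_correct_prob(mp, layout, key[1:]),
            }
        return self.per_movement[key]

    def to_dict(self) -> dict:
        return {
            "phase": self.phase.value,
            "scenario": self.scenario.value if self.scenario else None,
            "per_movement": {
                f"{mode.value}:{a}->{b}": dict(v)
                for (mode, a, b), v in sorted(
                    self.per_movement.items(), key=lambda kv: (kv[0][0].value, kv[0][1], kv[0][2])
                )
            },
        }


def simulate_session(
    task_configs: Sequence[TaskConfig],
    layout: TargetLayout,
    agent: AgentParams,
    effect: Optional[InjectionEffect] = None,
    phase: Phase = Phase.PRE,
    n_trials: int = 2000,
    seed: int = 0,
    block_length_range: tuple[int, int] = (200, 500),
    monkey_id: str = "SIM",
    session_id: Optional[str] = None,
    day_offset: Optional[int] = None,
) -> tuple[SessionLog, GroundTruth]:
    """Simulate one behavioral session of alternating task blocks.

    Blocks cycle through ``task_configs`` with lengths drawn uniformly from
    ``block_length_range`` (the final block is truncated at ``n_trials``).
    In the POST phase with a non-null ``effect``, movements in blocks the
    effect's scope covers are generated from shifted parameters.  The same
    seed reproduces the identical log byte for byte.
    """
    if n_trials <= 0:
        raise ConfigurationError("n_trials must be positive")
    if not task_configs:
        raise ConfigurationError("at least one TaskConfig block is required")
    if block_length_range[0] < 1 or block_length_range[0] > block_length_range[1]:
        raise ConfigurationError(f"bad block_length_range {block_length_range}")
    phase = Phase(phase)

    rng = np.random.default_rng(seed)
    truth = GroundTruth(phase=phase, scenario=effect.scenario if effect else None)
    trials: list[TrialRecord] = []

    t_ref = 0  # timestamp anchoring the next cue (last touch, or timeout)
    last_touch_ms: Optional[int] = None
    hand_target: Optional[int] = None
    trial_index = 0
    block_id = 0

    param_cache: dict[tuple[TaskMode, Optional[Movement]], MovementParams] = {}

    def effective_params(mode: TaskMode, movement: Optional[Movement]) -> MovementParams:
        key = (mode, movement)
        if key not in param_cache:
            mp = agent.params_for(movement)
            if phase is Phase.POST and effect is not None and effect.applies_to(mode):
                mp = apply_deltas(mp, effect.deltas_for(movement))
            param_cache[key] = mp
        return param_cache[key]

    while trial_index < n_trials:
        config = task_configs[block_id % len(task_configs)]
        block_len = int(rng.integers(block_length_range[0], block_length_range[1] + 1))
        block_len = min(block_len, n_trials - trial_index)
        state = initial_state(config, rng)

        for k in range(block_len):
            cue = state.current_cued_target
            cue_onset = t_ref + config.cue_delay_ms
            # the first trial of a block has no defined movement, matching
            # the classification layer's convention
            movement: Optional[Movement] = (
                (hand_target, cue)
                if k > 0 and hand_target is not None and hand_target != cue
                else None
            )
            mp = effective_params(config.mode, movement)
            p_pred_used = (
                mp.p_predictive if config.mode is TaskMode.REPEATING else agent.p_fast_random
            )
            entry = (
                truth._entry(
                    (config.mode, movement[0], movement[1]), mp, layout, p_pred_used
                )
                if movement is not None
                else None
            )
            if entry is not None:
                entry["n_trials"] += 1

            u = rng.random()
            if u < mp.p_no_hit:
                if entry is not None:
                    entry["n_no_hit_drawn"] += 1
                trials.append(
                    TrialRecord(
                        trial_index=trial_index,
                        block_id=block_id,
                        task_mode=config.mode,
                        cue_target=cue,
                        cue_onset_ms=int(cue_onset),
                        release_prev_ms=None,
                        touch_ms=None,
                        touch_x=None,
                        touch_y=None,
                        raw_outcome=RawOutcome.NO_HIT,
                    )
                )
                t_ref = cue_onset + config.response_window_ms
                outcome = Outcome.NO_HIT
            else:
                p_pred = (
                    mp.p_predictive
                    if config.mode is TaskMode.REPEATING
                    else agent.p_fast_random
                )
                predictive = u < mp.p_no_hit + (1 - mp.p_no_hit) * p_pred
                if predictive:
                    loc, scale = mp.rt_predictive
                    rt = _truncnorm_draw(
                        rng, loc, scale, -config.cue_delay_ms + 1,
                        config.predictive_threshold_ms - 1,
                    )
                    if entry is not None:
                        entry["n_predictive_drawn"] += 1
                else:
                    loc, scale = mp.rt_cued
                    rt = _truncnorm_draw(
                        rng, loc, scale, config.predictive_threshold_ms + 1,
                        config.response_window_ms - 1,
                    )
                touch_ms = int(round(cue_onset + rt))

                if predictive and config.mode is TaskMode.RANDOM:
                    # anticipatory guess: the random target cannot be known
                    candidates = [t for t in layout.target_ids if t != hand_target]
                    aim = int(candidates[rng.integers(len(candidates))])
                else:
                    aim = cue
                xy, _, dir_err = generate_touch(hand_target, aim, layout, mp, rng)
                xy = np.round(xy, 2)
                if dir_err and entry is not None:
                    entry["n_direction_drawn"] += 1
                assigned, inside = layout.nearest_target(xy)
                outcome = (
                    Outcome.CORRECT if (assigned == cue and inside) else Outcome.ERROR
                )
                if outcome is Outcome.CORRECT and entry is not None:
                    entry["n_correct"] += 1

                if hand_target is None or last_touch_ms is None:
                    release: Optional[int] = None
                else:
                    mt = _truncnorm_draw(rng, mp.mt[0], mp.mt[1], 20.0, 600.0)
                    release = int(round(touch_ms - mt))
                    lower = int(last_touch_ms + mp.dwell_ms)
                    release = max(min(release, touch_ms), min(lower, touch_ms))
                trials.append(
                    TrialRecord(
                        trial_index=trial_index,
                        block_id=block_id,
                        task_mode=config.mode,
                        cue_target=cue,
                        cue_onset_ms=int(cue_onset),
                        release_prev_ms=release,
                        touch_ms=touch_ms,
                        touch_x=float(xy[0]),
                        touch_y=float(xy[1]),
                        raw_outcome=RawOutcome.HIT,
                    )
                )
                t_ref = touch_ms
                last_touch_ms = touch_ms
                hand_target = assigned

            state, _ = next_cue(state, config, outcome)
            trial_index += 1
        block_id += 1

    treatment = Treatment(effect.scenario.value) if effect is not None else Treatment.NONE
    log = SessionLog(
        monkey_id=monkey_id,
        session_id=session_id if session_id is not None else f"sim-{seed}",
        phase=phase,
        treatment=treatment,
        day_offset=day_offset if day_offset is not None else (-1 if phase is Phase.PRE else 1),
        layout=layout,
        trials=trials,
    )
    return log, truth


# ---------------------------------------------------------------------------
# presets

# Endpoint noise scales solving P(inside target | sigma, zero bias) for the
# observed pre-injection correct rates on the showcase movements
# (acceptance radius 30 screen units): 96% and 93% correct.
_SIGMA_CORRECT_96 = 11.8237
_SIGMA_CORRECT_93 = 13.0085

# Predictive fractions on the most affected movement, pre vs post.
_PRED_PRE = 0.924
_PRED_POST = 0.353

# Cued-RT location shift calibrated so that the post-pre difference of the
# included-correct mean RT (a predictive/cued mixture) equals the observed
# +140.23 ms; the predictive fraction collapse alone over-shifts the mixture,
# hence the negative component delta.
_D_RT_CUED = -66.39
_D_MT = 45.82

_PRESET_TASKS = [
    TaskConfig(mode=TaskMode.RANDOM),
    TaskConfig(mode=TaskMode.REPEATING, sequence=(5, 3, 1)),
    TaskConfig(mode=TaskMode.RANDOM),
    TaskConfig(mode=TaskMode.REPEATING, sequence=(1, 2, 4)),
]


def preset_task_configs() -> list[TaskConfig]:
    """The alternating block structure used by the presets: Random blocks
    interleaved with the two trained sequences (5-3-1 and 1-2-4)."""
    return list(_PRESET_TASKS)


def paper_preset(name: str) -> tuple[AgentParams, Optional[InjectionEffect]]:
    """Named generative scenarios calibrated to the study's summary numbers.

    ``anisomycin_session2_N``: Repeating-only deficit.  Movement 1->5 turns
    accuracy-error dominated (~45% errors from undershoot + widened noise),
    movement 2->4 gains an 18% direction-error rate, movement 3->1 keeps its
    baseline error rate, predictive responding collapses 92.4% -> 35.3% on
    every sequence movement, and RT/MT shift so the included-trial means rise
    by ~140 ms and ~46 ms.  Base rates for movements without printed values
    are interpolations and are flagged as such in the sidecar metadata.

    ``muscimol``: indiscriminate deficit in both tasks.  ``saline``: explicit
    null effect.  ``null``: the saline agent with no injection metadata.
    """
    base_agent = AgentParams(
        default=MovementParams(
            p_predictive=_PRED_PRE,
            endpoint_sigma=_SIGMA_CORRECT_96,
        ),
        overrides={
            (2, 4): MovementParams(
                p_predictive=_PRED_PRE, endpoint_sigma=_SIGMA_CORRECT_93
            ),
        },
    )
    if name == "anisomycin_session2_N":
        common = dict(d_p_predictive=_PRED_PRE - _PRED_POST, d_rt_ms=_D_RT_CUED, d_mt_ms=_D_MT)
        effect = InjectionEffect(
            scenario=Scenario.ANISOMYCIN,
            scope=EffectScope.REPEATING_ONLY,
            default=EffectDeltas(
                sigma_multiplier=1.8, d_undershoot_bias=-12.0,
                d_p_direction_error=0.02, **common,
            ),
            overrides={
                # accuracy-error showcase: undershoot "short of" the target
                (1, 5): EffectDeltas(
                    sigma_multiplier=1.4, d_undershoot_bias=-22.14, **common
                ),
                # direction-error showcase: 18% of reaches go the wrong way
                (2, 4): EffectDeltas(
                    sigma_multiplier=1.4, d_undershoot_bias=-8.0,
                    d_p_direction_error=0.18, **common,
                ),
                # the one movement whose error rate does not change
                (3, 1): EffectDeltas(**common),
                # moderately affected movement
                (1, 2): EffectDeltas(
                    sigma_multiplier=1.35, d_undershoot_bias=-8.0, **common
                ),
            },
        )
        return base_agent, effect
    if name == "muscimol":
        effect = InjectionEffect(
            scenario=Scenario.MUSCIMOL,
            scope=EffectScope.BOTH_TASKS,
            default=EffectDeltas(
                d_p_predictive=0.4, sigma_multiplier=2.0, d_undershoot_bias=-15.0,
                d_p_direction_error=0.05, d_rt_ms=60.0, d_mt_ms=80.0,
            ),
        )
        return base_agent, effect
    if name == "saline":
        return base_agent, InjectionEffect(scenario=Scenario.SALINE, scope=EffectScope.NONE)
    if name == "null":
        return base_agent, None
    raise ConfigurationError(f"unknown preset {name!r}")
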