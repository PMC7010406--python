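"""Pre/post statistical contrasts per movement, Holm-Bonferroni control,
strongest/weakest-movement selection, and population aggregation.

Per movement and task, the pipeline runs a 2x2 Pearson chi-square on correct
vs. error counts and on predictive vs. non-predictive counts (among correct
responses), and Welch t-tests on per-trial RT and MT.  Multiple comparisons
are corrected within a family of one test kind x one task x one session
(i.e. across the movements) with the Holm step-down procedure.  Per session,
the movement with the largest increase in Repeating-task error rate is the
strongest-effect movement and the smallest increase the weakest; population
analysis averages these movements' pre/post rates across sessions (with the
same movement identities in the Random task) and applies paired t-tests.

Choices the study description leaves open are config-exposed: the chi-square
is uncorrected Pearson by default (``correction=True`` adds Yates), the
t-test is Welch by default (``equal_var=True`` pools), and tests are
two-sided throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .metrics import MovementSummary, Movement
from .session_io import Phase
from .task_engine import TaskMode


class NotComputableError(ValueError):
    """A test's preconditions (margins, sample size, variance) fail."""


class TestKind(str, Enum):
    CHI2_ERROR = "CHI2_ERROR"
    CHI2_PREDICTIVE = "CHI2_PREDICTIVE"
    TTEST_RT = "TTEST_RT"
    TTEST_MT = "TTEST_MT"


@dataclass
class TestResult:
    movement: Movement
    task_mode: TaskMode
    test_kind: TestKind
    statistic: float
    df: float
    p_raw: float
    significant_adjusted: bool
    alpha: float
    computable: bool = True
    note: str = ""


def chi2_2x2(
    pre: tuple[int, int], post: tuple[int, int], *, correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table of (successes, failures) per phase.

    Continuity correction is off by default.  A zero margin leaves the test
    undefined and raises :class:`NotComputableError`.
    """
    table = np.array([pre, post], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise NotComputableError("zero margin in 2x2 table")
    stat, p, df, _ = sps.chi2_contingency(table, correction=correction)
    return float(stat), int(df), float(p)


def holm_bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Holm step-down rejection flags, returned in input order.

    Sorted ascending, p_(i) is compared with alpha/(m - i + 1); rejection
    stops at the first failure.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p_values must be nonempty")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=alpha, method="holm")
    return [bool(r) for r in reject]


def ttest_two_sample(
    pre_values: Sequence[float],
    post_values: Sequence[float],
    *,
    equal_var: bool = False,
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test (Welch by default) on per-trial values."""
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.size < 2 or post.size < 2:
        raise NotComputableError("each sample needs n >= 2")
    if pre.std(ddof=1) == 0 and post.std(ddof=1) == 0:
        raise NotComputableError("both samples are degenerate (zero variance)")
    res = sps.ttest_ind(pre, post, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def ttest_paired(diffs: Sequence[float]) -> tuple[float, int, float]:
    """One-sample two-sided t-test of session-level differences against 0."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise NotComputableError("need >= 2 differences")
    if d.std(ddof=1) == 0:
        raise NotComputableError("zero variance of differences")
    res = sps.ttest_1samp(d, 0.0)
    return float(res.statistic), int(d.size - 1), float(res.pvalue)


@dataclass
class SessionEffect:
    """Per-movement pre/post deltas for one injection session."""

    session_id: str
    d_error_rate: dict[tuple[TaskMode, Movement], float] = field(default_factory=dict)
    d_predictive_rate: dict[tuple[TaskMode, Movement], float] = field(default_factory=dict)
    d_mean_rt_ms: dict[tuple[TaskMode, Movement], float] = field(default_factory=dict)
    d_mean_mt_ms: dict[tuple[TaskMode, Movement], float] = field(default_factory=dict)
    strongest_movement: Optional[Movement] = None
    weakest_movement: Optional[Movement] = None

    def to_dict(self) -> dict:
        def flat(d):
            return {f"{m.value}:{a}->{b}": v for (m, (a, b)), v in sorted(d.items())}

        return {
            "session_id": self.session_id,
            "d_error_rate": flat(self.d_error_rate),
            "d_predictive_rate": flat(self.d_predictive_rate),
            "d_mean_rt_ms": flat(self.d_mean_rt_ms),
            "d_mean_mt_ms": flat(self.d_mean_mt_ms),
            "strongest_movement": list(self.strongest_movement) if self.strongest_movement else None,
            "weakest_movement": list(self.weakest_movement) if self.weakest_movement else None,
        }


def _select_extreme(
    deltas: dict[Movement, float], order: Sequence[Movement], largest: bool
) -> Optional[Movement]:
    """Arg-extreme with ties broken toward the earlier movement in
    ``order`` (sequence order)."""
    best: Optional[Movement] = None
    best_v = None
    for m in order:
        if m not in deltas:
            continue
        v = deltas[m]
        if best is None or (v > best_v if largest else v < best_v):
            best, best_v = m, v
    return best


def session_contrast(
    pre: Sequence[MovementSummary],
    post: Sequence[MovementSummary],
    alpha: float = 0.05,
    *,
    session_id: str = "",
    chi2_correction: bool = False,
    equal_var: bool = False,
    movement_order: Optional[Sequence[Movement]] = None,
) -> tuple[list[TestResult], SessionEffect]:
    """All per-movement contrasts between the pre and post phase of one
    session, Holm-corrected within each (test kind, task) family.

    Movements present in only one phase are skipped with a warning.  Tests
    whose preconditions fail (zero margins, degenerate samples) are reported
    as not-computable with ``significant_adjusted=False`` and do not enter
    the Holm family.
    """
    pre_by = {(s.task_mode, s.movement): s for s in pre}
    post_by = {(s.task_mode, s.movement): s for s in post}
    for key in sorted(set(pre_by) ^ set(post_by), key=lambda k: (k[0].value, k[1])):
        warnings.warn(
            f"movement {key[1]} ({key[0].value}) present in only one phase; skipped",
            stacklevel=2,
        )
    keys = sorted(set(pre_by) & set(post_by), key=lambda k: (k[0].value, k[1]))

    results: list[TestResult] = []
    effect = SessionEffect(session_id=session_id)

    for mode, movement in keys:
        s_pre, s_post = pre_by[(mode, movement)], post_by[(mode, movement)]

        specs = [
            (
                TestKind.CHI2_ERROR,
                lambda a=s_pre, b=s_post: chi2_2x2(
                    (a.n_correct, a.n_errors), (b.n_correct, b.n_errors),
                    correction=chi2_correction,
                ),
            ),
            (
                TestKind.CHI2_PREDICTIVE,
                lambda a=s_pre, b=s_post: chi2_2x2(
                    (a.n_predictive, a.n_nonpredictive),
                    (b.n_predictive, b.n_nonpredictive),
                    correction=chi2_correction,
                ),
            ),
            (
                TestKind.TTEST_RT,
                lambda a=s_pre, b=s_post: ttest_two_sample(
                    a.rt_values, b.rt_values, equal_var=equal_var
                ),
            ),
            (
                TestKind.TTEST_MT,
                lambda a=s_pre, b=s_post: ttest_two_sample(
                    a.mt_values, b.mt_values, equal_var=equal_var
                ),
            ),
        ]
        for kind, run in specs:
            try:
                stat, df, p = run()
                results.append(
                    TestResult(movement, mode, kind, stat, df, p, False, alpha)
                )
            except NotComputableError as exc:
                results.append(
                    TestResult(
                        movement, mode, kind, float("nan"), float("nan"),
                        float("nan"), False, alpha, computable=False, note=str(exc),
                    )
                )

        effect.d_error_rate[(mode, movement)] = s_post.error_rate - s_pre.error_rate
        if s_pre.predictive_rate is not None and s_post.predictive_rate is not None:
            effect.d_predictive_rate[(mode, movement)] = (
                s_post.predictive_rate - s_pre.predictive_rate
            )
        effect.d_mean_rt_ms[(mode, movement)] = s_post.mean_rt_ms - s_pre.mean_rt_ms
        effect.d_mean_mt_ms[(mode, movement)] = s_post.mean_mt_ms - s_pre.mean_mt_ms

    # Holm correction within each family = one test kind x one task
    for kind in TestKind:
        for mode in TaskMode:
            family = [
                r for r in results
                if r.test_kind is kind and r.task_mode is mode and r.computable
            ]
            if not family:
                continue
            flags = holm_bonferroni([r.p_raw for r in family], alpha)
            for r, flag in zip(family, flags):
                r.significant_adjusted = flag

    rep_deltas = {
        m: v for (mode, m), v in effect.d_error_rate.items() if mode is TaskMode.REPEATING
    }
    order = list(movement_order) if movement_order is not None else sorted(rep_deltas)
    effect.strongest_movement = _select_extreme(rep_deltas, order, largest=True)
    effect.weakest_movement = _select_extreme(rep_deltas, order, largest=False)
    return results, effect


def test_results_to_frame(results: Sequence[TestResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "from_target": [r.movement[0] for r in results],
            "to_target": [r.movement[1] for r in results],
            "task_mode": [r.task_mode.value for r in results],
            "test_kind": [r.test_kind.value for r in results],
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p_raw": [r.p_raw for r in results],
            "significant_adjusted": [r.significant_adjusted for r in results],
            "alpha": [r.alpha for r in results],
            "computable": [r.computable for r in results],
            "note": [r.note for r in results],
        }
    )


@dataclass
class GroupStats:
    """Cross-session mean +/- SE of a rate, pre and post, with the paired
    t-test of the post-pre differences.  Rates are fractions in [0, 1]."""

    n_sessions: int
    pre_mean: float
    pre_se: float
    post_mean: float
    post_se: float
    t_statistic: float = float("nan")
    df: int = 0
    p_value: float = float("nan")
    computable: bool = True
    note: str = ""


def _group_stats(pre_vals: list[float], post_vals: list[float]) -> GroupStats:
    pre = np.asarray(pre_vals, float)
    post = np.asarray(post_vals, float)
    n = pre.size

    def se(x):
        return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")

    gs = GroupStats(
        n_sessions=n,
        pre_mean=float(pre.mean()),
        pre_se=se(pre),
        post_mean=float(post.mean()),
        post_se=se(post),
    )
    try:
        gs.t_statistic, gs.df, gs.p_value = ttest_paired(post - pre)
    except NotComputableError as exc:
        gs.computable = False
        gs.note = str(exc)
    return gs


@dataclass
class PopulationSummary:
    """Cross-session aggregates for the strongest/weakest-effect movements.

    Error rates are aggregated for those movements in the Repeating task and
    for the same movement identities in the Random task; predictive rates
    are Repeating-only (predictive responding is undefined under random
    cueing).
    """

    error_repeating_strongest: GroupStats
    error_repeating_weakest: GroupStats
    error_random_strongest: Optional[GroupStats]
    error_random_weakest: Optional[GroupStats]
    predictive_repeating_strongest: GroupStats
    predictive_repeating_weakest: GroupStats

    def to_dict(self) -> dict:
        out = {}
        for name, gs in self.__dict__.items():
            out[name] = None if gs is None else dict(gs.__dict__)
        return out


def population_summary(
    effects: Sequence[SessionEffect],
    summaries_by_session: dict[str, dict[Phase, Sequence[MovementSummary]]],
) -> PopulationSummary:
    """Aggregate strongest/weakest-movement rates across injection sessions.

    ``summaries_by_session`` maps each effect's session_id to its PRE and
    POST movement summaries.  Requires at least two sessions.
    """
    if len(effects) < 2:
        raise NotComputableError("population analysis needs >= 2 sessions")

    collected: dict[tuple[str, str, str], tuple[list[float], list[float]]] = {}

    def add(key, pre_v, post_v):
        pre_l, post_l = collected.setdefault(key, ([], []))
        pre_l.append(pre_v)
        post_l.append(post_v)

    for eff in effects:
        phases = summaries_by_session[eff.session_id]
        by_key = {
            ph: {(s.task_mode, s.movement): s for s in phases[ph]} for ph in (Phase.PRE, Phase.POST)
        }
        for which, movement in (("strongest", eff.strongest_movement), ("weakest", eff.weakest_movement)):
            if movement is None:
                raise NotComputableError(f"session {eff.session_id}: no {which} movement")
            rep_pre = by_key[Phase.PRE].get((TaskMode.REPEATING, movement))
            rep_post = by_key[Phase.POST].get((TaskMode.REPEATING, movement))
            if rep_pre is None or rep_post is None:
                raise NotComputableError(
                    f"session {eff.session_id}: movement {movement} missing in a phase"
                )
            add(("error", "REPEATING", which), rep_pre.error_rate, rep_post.error_rate)
            if rep_pre.predictive_rate is not None and rep_post.predictive_rate is not None:
                add(
                    ("predictive", "REPEATING", which),
                    rep_pre.predictive_rate,
                    rep_post.predictive_rate,
                )
            ran_pre = by_key[Phase.PRE].get((TaskMode.RANDOM, movement))
            ran_post = by_key[Phase.POST].get((TaskMode.RANDOM, movement))
            if ran_pre is not None and ran_post is not None:
                add(("error", "RANDOM", which), ran_pre.error_rate, ran_post.error_rate)
            else:
                warnings.warn(
                    f"session {eff.session_id}: movement {movement} absent from the "
                    "Random task; session dropped from the Random aggregate",
                    stacklevel=2,
                )

    def stats_for(key) -> Optional[GroupStats]:
        if key not in collected:
            return None
        return _group_stats(*collected[key])

    return PopulationSummary(
        error_repeating_strongest=stats_for(("error", "REPEATING", "strongest")),
        error_repeating_weakest=stats_for(("error", "REPEATING", "weakest")),
        error_random_strongest=stats_for(("error", "RANDOM", "strongest")),
        error_random_weakest=stats_for(("error", "RANDOM", "weakest")),
        predictive_repeating_strongest=stats_for(("predictive", "REPEATING", "strongest")),
        predictive_repeating_weakest=stats_for(("predictive", "REPEATING", "weakest")),
    )
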