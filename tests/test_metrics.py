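"""Classification layer: RT/MT formulas, endpoint assignment, error
taxonomy, exclusions, and summary count identities."""

import numpy as np
import pytest

from seqreach.behavior_sim import AgentParams, MovementParams
from seqreach.metrics import (
    ExclusionReason,
    ResponseClass,
    assign_touch_to_target,
    classify_predictive,
    classify_response,
    classify_session,
    derive_rt_mt,
    summaries_to_frame,
    summarize_by_movement,
)
from seqreach.session_io import Phase, RawOutcome, SessionLog, TrialRecord, Treatment
from seqreach.task_engine import TargetLayout, TaskConfig, TaskMode

from conftest import make_session


class TestDeriveRtMt:
    @pytest.mark.parametrize(
        "mode, cue_onset, prev_touch, release, touch, exp_rt, exp_mt",
        [
            # Repeating anticipation: (1250 - 1000) - 400 = -150
            (TaskMode.REPEATING, 1400, 1000, 1100, 1250, -150.0, 150.0),
            # Random: touch - cue onset
            (TaskMode.RANDOM, 1100, 1000, None, 1400, 300.0, None),
            # MT = touch - release
            (TaskMode.RANDOM, 1100, 1000, 1100, 1350, 250.0, 250.0),
        ],
    )
    def test_formulas(self, mode, cue_onset, prev_touch, release, touch, exp_rt, exp_mt):
        config = TaskConfig(
            mode=mode, sequence=(5, 3, 1) if mode is TaskMode.REPEATING else None
        )
        trial = TrialRecord(
            0, 0, mode, 3, cue_onset, release, touch, 200.0, 0.0, RawOutcome.HIT
        )
        rt, mt = derive_rt_mt(trial, prev_touch, config)
        assert rt == exp_rt
        assert mt == exp_mt

    def test_missing_release_leaves_trial_rt_classifiable(self):
        config = TaskConfig(mode=TaskMode.REPEATING, sequence=(5, 3, 1))
        trial = TrialRecord(
            0, 0, TaskMode.REPEATING, 3, 1400, None, 1600, 200.0, 0.0, RawOutcome.HIT
        )
        rt, mt = derive_rt_mt(trial, 1000, config)
        assert rt == 200.0 and mt is None


class TestPredictiveCutoff:
    @pytest.mark.parametrize(
        "rt, expected", [(100, True), (149.9, True), (150, False), (-50, True), (700, False)]
    )
    def test_strictly_below_150(self, rt, expected):
        assert classify_predictive(rt) is expected


class TestAssignment:
    def test_center_touch(self, layout):
        assert assign_touch_to_target(layout.center(3), layout) == (3, True)

    def test_midpoint_tie_breaks_to_lower_id(self, layout):
        assert assign_touch_to_target((150.0, 0.0), layout) == (2, False)

    def test_between_targets_counts_to_closest(self, layout):
        assert assign_touch_to_target((205.0, 4.0), layout) == (3, True)

    def test_agrees_with_brute_force(self, layout):
        """Nearest-center assignment equals an explicit distance scan over
        all five targets on random points."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            xy = rng.uniform((-80, -80), (480, 80))
            got = assign_touch_to_target(xy, layout)
            dists = [
                (float(np.hypot(xy[0] - c[0], xy[1] - c[1])), tid)
                for tid, c in zip(layout.target_ids, layout.centers)
            ]
            best = min(dists)
            assert got == (best[1], best[0] <= layout.half_width)


class TestResponseTaxonomy:
    @pytest.mark.parametrize(
        "from_t, to_t, assigned, inside, touch_x, expected",
        [
            (5, 3, 3, True, 200.0, ResponseClass.CORRECT),
            # correct direction, wrong endpoint: accuracy error
            (1, 5, 4, False, 340.0, ResponseClass.ACCURACY_ERROR),
            # opposite direction: direction error
            (2, 4, 1, True, 10.0, ResponseClass.DIRECTION_ERROR),
            # zero horizontal displacement: neither taxon
            (2, 4, 2, False, 100.0, ResponseClass.OTHER_ERROR),
            # inside the wrong target in the correct direction
            (1, 5, 3, True, 205.0, ResponseClass.ACCURACY_ERROR),
        ],
    )
    def test_examples(self, layout, from_t, to_t, assigned, inside, touch_x, expected):
        assert classify_response(from_t, to_t, assigned, inside, touch_x, layout) is expected


def _repeating_log(rows):
    """Hand-built Repeating-task session (sequence 5-3-1, 400 ms delay)."""
    trials = [
        TrialRecord(i, 0, TaskMode.REPEATING, cue, onset, release, touch, x, y, outcome)
        for i, (cue, onset, release, touch, x, y, outcome) in enumerate(rows)
    ]
    return SessionLog(
        monkey_id="N", session_id="fix", phase=Phase.PRE,
        treatment=Treatment.NONE, day_offset=-1, layout=TargetLayout(), trials=trials,
    )


class TestCorrectiveAndExclusions:
    def test_correct_after_error_is_corrective_and_excluded(self, layout):
        log = _repeating_log(
            [
                # trial 0: block start, correct touch of 5
                (5, 400, None, 700, 400.0, 0.0, RawOutcome.HIT),
                # trial 1: 5->3 accuracy error (lands outside 3, rightward)
                (3, 1100, 800, 1400, 240.0, 0.0, RawOutcome.HIT),
                # trial 2: repeat of 3, correct -> corrective
                (3, 1800, 1500, 2100, 200.0, 0.0, RawOutcome.HIT),
                # trial 3: 3->1 correct
                (1, 2500, 2200, 2800, 0.0, 0.0, RawOutcome.HIT),
            ]
        )
        df = classify_session(log)
        assert df.loc[1, "response_class"] == ResponseClass.ACCURACY_ERROR.value
        assert df.loc[2, "response_class"] == ResponseClass.CORRECTIVE.value
        assert not df.loc[2, "included"]
        assert df.loc[2, "exclusion_reason"] == ExclusionReason.CORRECTIVE.value
        assert df.loc[3, "included"]

    def test_correct_after_no_hit_is_corrective(self, layout):
        log = _repeating_log(
            [
                (5, 400, None, 700, 400.0, 0.0, RawOutcome.HIT),
                (3, 1100, None, None, None, None, RawOutcome.NO_HIT),
                (3, 2300, 2000, 2500, 200.0, 0.0, RawOutcome.HIT),
            ]
        )
        df = classify_session(log)
        assert df.loc[1, "response_class"] == ResponseClass.NO_HIT.value
        assert df.loc[1, "exclusion_reason"] == ExclusionReason.NO_HIT.value
        assert df.loc[2, "response_class"] == ResponseClass.CORRECTIVE.value

    def test_fast_random_trial_excluded_fast_repeating_kept(self):
        random_trials = [
            TrialRecord(0, 0, TaskMode.RANDOM, 3, 100, None, 350, 200.0, 0.0, RawOutcome.HIT),
            # RT = 120 ms < 150 in the Random task -> excluded
            TrialRecord(1, 0, TaskMode.RANDOM, 5, 450, 380, 570, 400.0, 0.0, RawOutcome.HIT),
        ]
        log = SessionLog(
            "N", "r", Phase.PRE, Treatment.NONE, -1, TargetLayout(), random_trials
        )
        df = classify_session(log)
        assert df.loc[1, "exclusion_reason"] == ExclusionReason.FAST_RANDOM.value

        rep = _repeating_log(
            [
                (5, 400, None, 700, 400.0, 0.0, RawOutcome.HIT),
                # inter-touch 520 ms -> RT = 120 ms: predictive, included
                (3, 1100, 900, 1220, 200.0, 0.0, RawOutcome.HIT),
            ]
        )
        df = classify_session(rep)
        assert df.loc[1, "included"] and df.loc[1, "predictive"]
        assert df.loc[1, "rt_ms"] == 120.0

    def test_block_start_has_no_movement(self, task_configs, layout, quiet_agent):
        log, _ = make_session(task_configs, layout, quiet_agent, n_trials=300, seed=2)
        df = classify_session(log)
        first_of_block = df.groupby("block_id").head(1)
        assert first_of_block["from_target"].isna().all()
        assert (~first_of_block["included"]).all()


class TestSummaries:
    def test_counting_identities_small_fixture(self):
        rows = []
        t = 400
        # block start: correct 5
        rows.append((5, t, None, t + 300, 400.0, 0.0, RawOutcome.HIT))
        # 8 correct 5->3 responses (6 predictive), 2 accuracy errors
        prev = t + 300
        for i in range(10):
            onset = prev + 400
            if i < 2:
                touch_xy, touch = (245.0, 0.0), onset + 300  # accuracy error
            elif i < 8:
                touch_xy, touch = (200.0, 0.0), onset + 100  # predictive correct
            else:
                touch_xy, touch = (200.0, 0.0), onset + 300  # cued correct
            rows.append((3, onset, prev + 100, touch, *touch_xy, RawOutcome.HIT))
            # bounce back to 5 so every analysed movement is 5->3; these
            # returns follow an error twice (corrective) -> not counted
            onset2 = touch + 400
            rows.append((5, onset2, touch + 100, onset2 + 200, 400.0, 0.0, RawOutcome.HIT))
            prev = onset2 + 200
        log = _repeating_log(rows)
        summaries = summarize_by_movement(classify_session(log))
        s = next(s for s in summaries if s.movement == (5, 3))
        assert s.n_included == 10
        assert s.n_correct == 8 and s.n_accuracy_err == 2
        assert s.n_predictive == 6 and s.n_nonpredictive == 2
        assert s.n_included == s.n_correct + s.n_errors
        assert abs(s.error_rate - 0.2) < 1e-12

    def test_zero_included_movement_omitted_with_warning(self):
        log = _repeating_log(
            [
                (5, 400, None, 700, 400.0, 0.0, RawOutcome.HIT),
                # 5->3 error landing inside target 4
                (3, 1100, 800, 1400, 310.0, 0.0, RawOutcome.HIT),
                # repeat of 3 from target 4, correct -> corrective, so
                # movement 4->3 ends up with zero included trials
                (3, 1800, 1500, 2100, 200.0, 0.0, RawOutcome.HIT),
            ]
        )
        df = classify_session(log)
        with pytest.warns(UserWarning, match="4->3"):
            summaries = summarize_by_movement(df)
        assert all(s.movement != (4, 3) for s in summaries)

    def test_partition_and_identities_on_simulated_session(self, task_configs, layout):
        agent = AgentParams(
            default=MovementParams(
                p_predictive=0.6, endpoint_sigma=16.0, p_direction_error=0.05,
                p_no_hit=0.02,
            )
        )
        log, _ = make_session(task_configs, layout, agent, n_trials=1000, seed=5)
        df = classify_session(log)
        # every trial exactly one class; included + excluded = total
        assert len(df) == 1000
        assert df["response_class"].notna().all()
        assert df["included"].sum() + (~df["included"]).sum() == 1000
        assert (df["included"] == (df["exclusion_reason"] == "")).all()
        for s in summarize_by_movement(df):
            assert s.n_included == s.n_correct + s.n_errors
            assert s.n_predictive + s.n_nonpredictive == s.n_correct

    def test_direction_error_rate_recovers_generative_probability(self, layout):
        """On movement 2->4 with direction-error probability p, the observed
        direction-error rate converges to p (3 binomial SEs)."""
        p = 0.1
        agent = AgentParams(
            default=MovementParams(p_predictive=0.5, endpoint_sigma=5.0, p_direction_error=p)
        )
        configs = [TaskConfig(mode=TaskMode.REPEATING, sequence=(1, 2, 4))]
        log, _ = make_session(
            configs, layout, agent, n_trials=3000, seed=11, block_length_range=(3000, 3000)
        )
        summaries = summarize_by_movement(classify_session(log))
        s = next(s for s in summaries if s.movement == (2, 4))
        rate = s.n_direction_err / s.n_included
        assert abs(rate - p) < 3 * np.sqrt(p * (1 - p) / s.n_included)

    def test_raising_threshold_never_decreases_predictive_count(self, task_configs, layout, quiet_agent):
        log, _ = make_session(task_configs, layout, quiet_agent, n_trials=600, seed=6)
        counts = []
        for thr in (50, 150, 300, 800):
            df = classify_session(log, predictive_threshold_ms=thr)
            counts.append(int(df.loc[df["included"], "predictive"].sum()))
        assert counts == sorted(counts)

    def test_summaries_export_flat_table(self, task_configs, layout, quiet_agent):
        log, _ = make_session(task_configs, layout, quiet_agent, n_trials=300, seed=7)
        summaries = summarize_by_movement(classify_session(log))
        frame = summaries_to_frame(summaries)
        assert len(frame) == len(summaries)
        assert (frame["n_predictive"] + frame["n_nonpredictive"] == frame["n_correct"]).all()
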