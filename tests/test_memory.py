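"""Recognition scoring, in/out-region memory effects, memorability, saccades."""

import numpy as np
import pandas as pd
import pytest

from regioncode.memory import (
    SaccadeThresholds,
    detect_saccades,
    in_out_memory_comparison,
    matched_memorability_comparison,
    memorability_behavior_comparison,
    score_recognition,
    select_memorability_neurons,
)
from regioncode.synthetic import (
    GroundTruth,
    SyntheticConfig,
    generate_gaze_trace,
    generate_memory_session,
)


def _trials(rows):
    out = []
    for i, (old, resp, rt) in enumerate(rows):
        out.append(dict(trial_id=i, stimulus_id=f"s{i}", phase="recognition",
                        old_flag=old, response=resp, rt_s=rt, onset_s=2.0 * i))
    return pd.DataFrame(out)


class TestScoreRecognition:
    def test_all_old_answered_six(self):
        t = _trials([(True, 6, 1.0)] * 5)
        out = score_recognition(t)
        assert out.hit_rate == 1.0 and out.mean_confidence == 6.0

    def test_hand_counted_toy_table(self):
        # 6 old: 6,5,4,3,2,6 -> 4 hits; 4 new: 1,1,5,2 -> 3 correct rejections
        rows = [(True, r, 1.0) for r in (6, 5, 4, 3, 2, 6)] + \
               [(False, r, 1.0) for r in (1, 1, 5, 2)]
        out = score_recognition(_trials(rows))
        assert out.hit_rate == pytest.approx(4 / 6)
        assert out.accuracy == pytest.approx(0.7)

    def test_rt_over_five_seconds_excluded(self):
        rows = [(True, 6, 1.0)] * 30 + [(True, 2, 6.0)]
        out = score_recognition(_trials(rows))
        assert out.n_excluded_rt == 1
        assert out.hit_rate == 1.0  # the slow miss never enters scoring

    def test_hit_plus_miss_rates_sum_to_one(self, rng):
        rows = [(True, int(rng.integers(1, 7)), float(rng.uniform(0.5, 2)))
                for _ in range(40)]
        out = score_recognition(_trials(rows))
        old = out.table[out.table.old_flag]
        miss_rate = (old.response < 4).mean()
        assert out.hit_rate + miss_rate == pytest.approx(1.0)

    def test_no_recognition_trials_rejected(self):
        t = _trials([(True, 6, 1.0)])
        t["phase"] = "learning"
        with pytest.raises(ValueError):
            score_recognition(t)


def _session_outcomes(n_sessions, beta_region, seed=5, n_cat=10, n_per=8):
    """Simulated sessions plus the planted in-region stimulus ids."""
    from regioncode.synthetic import generate_stimulus_set

    cfg = SyntheticConfig(n_categories=n_cat, n_per_category=n_per, seed=seed,
                          memory_beta_region=beta_region)
    stim = generate_stimulus_set(cfg)
    rng = cfg.rng(stream=40)
    d = np.linalg.norm(stim.coords - [0.5, 0.5], axis=1)
    truth = GroundTruth(kind="region", region_center=(0.5, 0.5),
                        region_width=0.25,
                        memorability=rng.beta(4, 4, size=len(stim)),
                        in_region=d <= 0.5)
    in_ids = stim.stimulus_id[truth.in_region]
    units = []
    for _ in range(n_sessions):
        s = generate_memory_session(stim, truth, cfg, rng=rng)
        units.append((score_recognition(s), in_ids))
    return units, truth, stim


class TestInOutComparison:
    def test_region_boost_detected_across_sessions(self):
        units, _, _ = _session_outcomes(50, beta_region=1.0)
        res = in_out_memory_comparison(units)
        assert res["n_units"] >= 40
        assert res["hit_test"].statistic > 0
        assert res["hit_test"].p_value < 0.01

    def test_null_generator_calibrated(self):
        # type-I over independent 20-session experiments stays near alpha
        rejections = 0
        n_exp = 25
        for k in range(n_exp):
            units, _, _ = _session_outcomes(20, beta_region=0.0, seed=100 + k)
            res = in_out_memory_comparison(units)
            rejections += res["hit_test"].p_value < 0.05
        assert rejections / n_exp <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_exp)

    def test_all_in_region_unit_dropped(self):
        units, truth, stim = _session_outcomes(1, beta_region=0.0)
        outcome, _ = units[0]
        res = in_out_memory_comparison([(outcome, stim.stimulus_id)])
        assert res["n_units"] == 0

    def test_low_hit_rate_sessions_excluded(self):
        units, _, _ = _session_outcomes(5, beta_region=0.0)
        forced = [(type(o)(table=o.table, hit_rate=0.4, accuracy=o.accuracy,
                           mean_confidence=o.mean_confidence), ids)
                  for o, ids in units]
        assert in_out_memory_comparison(forced)["n_units"] == 0


class TestMemorability:
    def test_beta_mem_raises_high_group_hit_rate(self):
        from regioncode.synthetic import generate_stimulus_set

        cfg = SyntheticConfig(n_categories=10, n_per_category=8, seed=6,
                              memory_beta_mem=2.0)
        stim = generate_stimulus_set(cfg)
        rng = cfg.rng(stream=41)
        truth = GroundTruth(kind="null",
                            memorability=rng.beta(4, 4, size=len(stim)))
        scores = dict(zip(stim.stimulus_id, truth.memorability))
        outcomes = [score_recognition(
            generate_memory_session(stim, truth, cfg, rng=rng))
            for _ in range(50)]
        res = memorability_behavior_comparison(outcomes, scores)
        assert res["hit_test"].statistic > 0 and res["hit_test"].p_value < 0.01

    def test_identical_scores_rejected(self):
        units, _, stim = _session_outcomes(2, beta_region=0.0)
        scores = {s: 0.5 for s in stim.stimulus_id}
        with pytest.raises(ValueError):
            memorability_behavior_comparison([u[0] for u in units], scores)

    def test_select_memorability_neurons_recovery_and_null(self, rng):
        scores = rng.beta(4, 4, 200)
        planted = 5.0 + 4.0 * scores + rng.normal(0, 0.5, 200)
        nulls = rng.normal(5, 1, size=(120, 200))
        out = select_memorability_neurons(np.vstack([planted, nulls]), scores)
        assert bool(out.selected[0]) and out.sign[0] == 1
        null_rate = out.selected[1:].mean()
        assert null_rate <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / 120)

    def test_constant_rate_neuron_not_selectable(self, rng):
        out = select_memorability_neurons(np.ones((1, 50)), rng.beta(4, 4, 50))
        assert not out.selected[0]

    def test_matched_band_excludes_hand_built_outlier(self):
        # in-region scores 0.45..0.55 (SD 0.05 -> band +-0.1); out 0.9 excluded
        rows = []
        scores = {}
        in_scores = [0.45, 0.5, 0.55]
        for i, sc in enumerate(in_scores + [0.45, 0.9]):
            sid = f"s{i}"
            rows.append(dict(trial_id=i, stimulus_id=sid, phase="recognition",
                             old_flag=True, response=6, rt_s=1.0, onset_s=i))
            scores[sid] = sc
        # pad with new trials so accuracy is defined
        outcome = score_recognition(pd.DataFrame(rows))
        outcome = type(outcome)(table=outcome.table, hit_rate=0.9,
                                accuracy=outcome.accuracy,
                                mean_confidence=outcome.mean_confidence)
        in_ids = [f"s{i}" for i in range(3)]
        res = matched_memorability_comparison([(outcome, in_ids)], scores)
        table = res["per_unit"]
        assert len(table) == 1
        # only s3 (0.45) survives matching; all responses 6 -> hit rates equal
        assert table.hit_in[0] == 1.0 and table.hit_out[0] == 1.0

    def test_matched_equal_scores_keep_everything(self):
        units, truth, stim = _session_outcomes(10, beta_region=1.0)
        scores = {s: 0.5 for s in stim.stimulus_id}
        res_matched = matched_memorability_comparison(units, scores)
        res_plain = in_out_memory_comparison(units)
        pd.testing.assert_frame_equal(res_matched["per_unit"],
                                      res_plain["per_unit"])


class TestSaccades:
    def test_constant_gaze_single_fixation(self):
        t = np.arange(0, 0.5, 0.002)
        sac, fix = detect_saccades(t, np.zeros_like(t), np.zeros_like(t))
        assert sac == [] and len(fix) == 1

    def test_two_degree_step_is_one_saccade(self):
        trace = generate_gaze_trace([(0.0, 0.0), (2.0, 0.0)], [0.3, 0.3],
                                    jitter_deg=0.0)
        sac, fix = detect_saccades(trace.t, trace.x, trace.y)
        assert len(sac) == 1 and len(fix) == 2

    def test_subthreshold_deflection_ignored(self):
        trace = generate_gaze_trace([(0.0, 0.0), (0.05, 0.0)], [0.2, 0.2],
                                    jitter_deg=0.0)
        sac, _ = detect_saccades(trace.t, trace.x, trace.y)
        assert sac == []

    def test_planted_trace_round_trip_agreement(self, rng):
        centers = rng.uniform(-5, 5, size=(6, 2))
        trace = generate_gaze_trace(centers, [0.25] * 6, rng=rng)
        sac, fix = detect_saccades(trace.t, trace.x, trace.y)
        # interval agreement: fraction of planted saccade time covered by
        # detected saccades and vice versa
        def coverage(planted, detected):
            tot = cov = 0.0
            for p0, p1 in planted:
                tot += p1 - p0
                for d0, d1 in detected:
                    cov += max(0.0, min(p1, d1) - max(p0, d0))
            return cov / tot
        assert len(sac) == len(trace.planted_saccades)
        assert coverage(trace.planted_saccades, sac) >= 0.9

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            detect_saccades([0.0, 0.002], [0, 0], [0, 0])
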