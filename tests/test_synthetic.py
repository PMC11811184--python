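"""Synthetic-data generator: structure, determinism, and model recovery."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

import statsmodels.api as sm

from regioncode.synthetic import (
    GroundTruth,
    SyntheticConfig,
    generate_gaze_trace,
    generate_memory_session,
    generate_neuron,
    generate_stimulus_set,
)

RESP = (0.25, 1.25)


class TestStimulusSet:
    def test_full_size_structure(self, full_config):
        s = generate_stimulus_set(full_config)
        assert len(s) == 500
        assert len(s.categories) == 50
        assert s.coords.min() >= 0 and s.coords.max() <= 1

    def test_within_category_tighter_than_between(self, stimuli):
        d = squareform(pdist(stimuli.coords))
        same = stimuli.category[:, None] == stimuli.category[None, :]
        iu = np.triu_indices(len(stimuli), 1)
        assert d[iu][same[iu]].mean() < d[iu][~same[iu]].mean()

    def test_degenerate_single_category(self):
        s = generate_stimulus_set(SyntheticConfig(n_categories=1,
                                                  n_per_category=2, seed=0))
        assert len(s) == 2 and len(s.categories) == 1

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_categories=0)

    def test_seed_determinism_byte_identical(self, small_config):
        a = generate_stimulus_set(small_config)
        b = generate_stimulus_set(small_config)
        np.testing.assert_array_equal(a.coords, b.coords)
        np.testing.assert_array_equal(a.features, b.features)

    def test_features_project_to_coords(self, stimuli):
        # the 2D structure is linearly recoverable from the features
        sol, *_ = np.linalg.lstsq(stimuli.features, stimuli.coords - 0.5,
                                  rcond=None)
        recon = stimuli.features @ sol
        assert np.corrcoef(recon[:, 0], stimuli.coords[:, 0])[0, 1] > 0.99


class TestNeuron:
    def test_null_neuron_mean_rate(self, stimuli, small_config):
        cfg = SyntheticConfig(n_categories=10, n_per_category=8,
                              n_trials_per_stimulus=7, seed=3)
        rec = generate_neuron(GroundTruth.null(), stimuli, cfg)
        rates = rec.rates(RESP)
        se = np.sqrt(cfg.baseline_rate / len(rates))
        assert abs(rates.mean() - cfg.baseline_rate) < 3 * se

    def test_region_neuron_in_beats_far(self, full_config):
        stim = generate_stimulus_set(full_config)
        truth = GroundTruth.region((0.5, 0.5), 0.08)
        rec = generate_neuron(truth, stim, full_config)
        r = rec.stimulus_rates(RESP, stim)
        d = np.linalg.norm(stim.coords - [0.5, 0.5], axis=1)
        assert r[d <= 0.08].mean() > r[d > 0.24].mean()

    def test_region_truth_flags_match_distance(self, stimuli, small_config):
        truth = GroundTruth.region((0.5, 0.5), 0.1)
        rec = generate_neuron(truth, stimuli, small_config)
        d = np.linalg.norm(stimuli.coords - [0.5, 0.5], axis=1)
        np.testing.assert_array_equal(rec.truth.in_region, d <= 0.2)

    def test_axis_neuron_rate_tracks_projection(self, full_config):
        stim = generate_stimulus_set(full_config)
        rng = np.random.default_rng(9)
        w = rng.normal(size=stim.features.shape[1])
        rec = generate_neuron(GroundTruth.axis(w), stim, full_config)
        r = rec.stimulus_rates(RESP, stim)
        rho, p = pearsonr(r, stim.features @ w)
        assert rho > 0 and p < 1e-6

    def test_category_neuron_boosts_selected(self, stimuli, small_config):
        sel = (stimuli.categories[0], stimuli.categories[3])
        rec = generate_neuron(GroundTruth.category(sel), stimuli, small_config)
        r = rec.stimulus_rates(RESP, stimuli)
        m = np.isin(stimuli.category, sel)
        assert r[m].mean() > r[~m].mean() + 10

    def test_kind_validation(self):
        with pytest.raises(ValueError):
            GroundTruth(kind="sparkly")


class TestMemorySession:
    def _sessions(self, stimuli, n, **kw):
        cfg = SyntheticConfig(n_categories=10, n_per_category=8, seed=7, **kw)
        truth = GroundTruth.region((0.5, 0.5), 0.25)
        rng = cfg.rng(stream=30)
        mem = rng.beta(4, 4, size=len(stimuli))
        d = np.linalg.norm(stimuli.coords - [0.5, 0.5], axis=1)
        truth = GroundTruth(kind="region", region_center=(0.5, 0.5),
                            region_width=0.25, memorability=mem,
                            in_region=d <= 0.5)
        return [generate_memory_session(stimuli, truth, cfg, rng=rng)
                for _ in range(n)], truth

    def test_learning_shows_each_stimulus_once(self, stimuli, small_config):
        truth = GroundTruth.null()
        s = generate_memory_session(stimuli, truth, small_config)
        learn = s[s.phase == "learning"]
        assert learn.stimulus_id.is_unique
        assert len(learn) == len(stimuli) // 2

    def test_null_betas_equalize_in_out_hit_rates(self, stimuli):
        sessions, truth = self._sessions(stimuli, 60, memory_beta_region=0.0)
        diffs = []
        for s in sessions:
            rec = s[s.phase == "recognition"]
            old = rec[rec.old_flag.astype(bool)]
            hit = old.response.astype(int) >= 4
            inside = old.stimulus_id.isin(
                stimuli.stimulus_id[truth.in_region])
            diffs.append(hit[inside].mean() - hit[~inside].mean())
        t = np.mean(diffs) / (np.std(diffs, ddof=1) / np.sqrt(len(diffs)))
        assert abs(t) < 3.5

    def test_region_boost_raises_in_region_hit_rate(self, stimuli):
        sessions, truth = self._sessions(stimuli, 50, memory_beta_region=1.0)
        from regioncode.stats import group_comparison
        ins, outs = [], []
        for s in sessions:
            rec = s[s.phase == "recognition"]
            old = rec[rec.old_flag.astype(bool)]
            hit = old.response.astype(int) >= 4
            inside = old.stimulus_id.isin(stimuli.stimulus_id[truth.in_region])
            ins.append(hit[inside].mean())
            outs.append(hit[~inside].mean())
        res = group_comparison(ins, outs, paired=True)
        assert res.statistic > 0 and res.p_value < 0.01

    def test_logistic_coefficients_recoverable(self, full_config):
        # refit the generative hit model on ~1e4 simulated old trials
        stim = generate_stimulus_set(full_config)
        cfg = SyntheticConfig(seed=11, memory_beta_mem=1.5,
                              memory_beta_region=1.0)
        rng = cfg.rng(stream=31)
        mem = rng.beta(4, 4, size=len(stim))
        d = np.linalg.norm(stim.coords - [0.5, 0.5], axis=1)
        truth = GroundTruth(kind="region", region_center=(0.5, 0.5),
                            region_width=0.25, memorability=mem,
                            in_region=d <= 0.5)
        idx = {s: i for i, s in enumerate(stim.stimulus_id)}
        X, y = [], []
        for _ in range(45):  # 45 sessions x ~250 old trials
            s = generate_memory_session(stim, truth, cfg, rng=rng)
            rec = s[s.phase == "recognition"]
            old = rec[rec.old_flag.astype(bool)]
            for sid, resp in zip(old.stimulus_id, old.response):
                i = idx[sid]
                X.append([1.0, mem[i], float(truth.in_region[i])])
                y.append(int(resp) >= 4)
        fit = sm.Logit(np.array(y, float), np.array(X)).fit(disp=0)
        truth_beta = [cfg.memory_beta0, cfg.memory_beta_mem,
                      cfg.memory_beta_region]
        for est, se, b in zip(fit.params, fit.bse, truth_beta):
            assert abs(est - b) < 2.5 * se

    def test_empty_learning_set_rejected(self, stimuli, small_config):
        tiny = generate_stimulus_set(SyntheticConfig(n_categories=1,
                                                     n_per_category=2, seed=0))
        one = type(tiny)(stimulus_id=tiny.stimulus_id[:1],
                         category=tiny.category[:1], coords=tiny.coords[:1])
        with pytest.raises(ValueError):
            generate_memory_session(one, GroundTruth.null(), small_config)


class TestGaze:
    def test_single_segment_has_no_saccade(self):
        trace = generate_gaze_trace([(0.0, 0.0)], [0.5])
        assert trace.planted_saccades == []
        assert len(trace.planted_fixations) == 1

    def test_two_segments_one_saccade(self):
        trace = generate_gaze_trace([(0.0, 0.0), (2.0, 0.0)], [0.3, 0.3])
        assert len(trace.planted_saccades) == 1

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_gaze_trace([(0, 0), (1, 1)], [0.2, 0.0])
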