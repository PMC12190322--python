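"""PSTH arithmetic, z-scores, and temporal-deviation permutation tests."""

import numpy as np
import pytest
from itertools import combinations

from schema_mux.binning import align_counts
from schema_mux.data import SpikeTrainSet, eligible_trials, reward_flag
from schema_mux.selectivity import (
    InsufficientData,
    characterize_units,
    compute_psth,
    condition_selectivity_test,
    delta_zscore,
    responsiveness_test,
    selective_fraction,
    smooth_uniform,
    zscore_by_condition,
)
from schema_mux.simulate import generate_trial_sequence

from conftest import build_trials


class TestSmoothing:
    def test_single_spike_spreads_over_five_interior_bins(self):
        trace = np.zeros(20)
        trace[10] = 1.0
        sm = smooth_uniform(trace, 5)
        np.testing.assert_allclose(sm[8:13], 0.2)
        assert sm.sum() == pytest.approx(1.0)

    def test_constant_trace_is_fixed_point(self):
        trace = np.full(30, 7.5)
        np.testing.assert_allclose(smooth_uniform(trace), trace)

    def test_edge_bins_average_truncated_support(self):
        trace = np.zeros(10)
        trace[0] = 1.0
        sm = smooth_uniform(trace, 5)
        # first bin sees only bins {0,1,2}: 1/3
        assert sm[0] == pytest.approx(1 / 3)


class TestPsth:
    def test_constant_rate_unit_gives_flat_trace(self):
        rng = np.random.default_rng(0)
        trials = build_trials(list(rng.integers(1, 9, 150)))
        t_end = trials["t_unpoke"].max() + 1
        spikes = SpikeTrainSet(
            "s", {"u": np.sort(rng.uniform(0, t_end, rng.poisson(20 * t_end)))}
        )
        ac = align_counts(spikes, trials, "unpoke", (-1.0, 0.0), 0.05)
        trace = compute_psth(ac)["all"][0]
        assert abs(trace.mean() - 20.0) < 1.5
        assert trace.std() < 3.0

    def test_empty_condition_absent(self):
        trials = build_trials([1, 2, 3])
        ac = align_counts(SpikeTrainSet("s", {"u": []}), trials, "unpoke")
        masks = {"a": np.array([True, True, True]), "b": np.array([False, False, False])}
        out = compute_psth(ac, masks)
        assert "a" in out and "b" not in out


class TestZScores:
    def test_planted_doubling_on_rewarded_only(self):
        rng = np.random.default_rng(1)
        n = 400
        is_rew = rng.random(n) < 0.5
        base = rng.poisson(10, n).astype(float)
        resp = np.where(is_rew, rng.poisson(20, n), rng.poisson(10, n)).astype(float)
        z_rew, z_non = zscore_by_condition(resp, base, is_rew)
        assert z_rew > 1.0
        assert abs(z_non) < 0.5

    def test_silent_unit_degenerate(self):
        z = zscore_by_condition(np.zeros(20), np.zeros(20), np.arange(20) < 10)
        assert np.isnan(z[0]) and np.isnan(z[1])

    def test_delta_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(2)
        resp = rng.poisson(12, 100).astype(float)
        base = rng.poisson(10, 100).astype(float)
        is_rew = rng.random(100) < 0.4
        assert delta_zscore(resp, base, is_rew) == pytest.approx(
            -delta_zscore(resp, base, ~is_rew), abs=1e-12
        )

    def test_identical_condition_responses_give_zero_delta(self):
        resp = np.tile([3.0, 5.0], 20)
        base = np.tile([2.0, 4.0], 20)
        is_rew = np.arange(40) % 4 < 2  # both conditions see the 3,5 pattern
        # conditions see identical response distributions
        assert delta_zscore(resp, base, is_rew) == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        resp = rng.poisson(15, 80).astype(float)
        base = rng.poisson(10, 80).astype(float)
        is_rew = rng.random(80) < 0.5
        d1 = delta_zscore(resp, base, is_rew)
        d2 = delta_zscore(3.0 * resp, 3.0 * base, is_rew)
        assert d1 == pytest.approx(d2, abs=1e-9)


class TestResponsivenessTest:
    def test_burst_unit_detected(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(0.4, size=(200, 30))
        counts[:, 20:22] += rng.poisson(1.2, size=(200, 2))  # 100 ms burst, 3x
        assert responsiveness_test(counts, n_perm=1000, seed=0) <= 0.01

    def test_p_floor_is_one_over_nperm_plus_one(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(0.2, size=(100, 30))
        counts[:, 15] += 20  # overwhelming locked response
        assert responsiveness_test(counts, n_perm=1000, seed=0) == pytest.approx(1 / 1001)

    def test_homogeneous_unit_not_flagged(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(0.5, size=(100, 30))
        assert responsiveness_test(counts, n_perm=500, seed=1) > 0.05

    def test_too_few_trials_signalled(self):
        with pytest.raises(InsufficientData):
            responsiveness_test(np.ones((5, 10)), n_perm=100, seed=0)


class TestConditionSelectivity:
    def test_planted_gain_detected(self):
        rng = np.random.default_rng(7)
        is_rew = np.arange(300) % 2 == 0
        counts = rng.poisson(np.where(is_rew[:, None], 0.8, 0.4), size=(300, 10))
        assert condition_selectivity_test(counts, is_rew, n_perm=500, seed=0) <= 0.05

    def test_exact_enumeration_matches_independent_oracle(self):
        # <= 8 trials: package's exhaustive mode vs a naive re-enumeration
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = int(rng.integers(6, 9))
            counts = rng.poisson(1.0, size=(n, 6))
            is_rew = np.zeros(n, bool)
            is_rew[: n // 2] = True
            p_pkg = condition_selectivity_test(counts, is_rew, exact=True)

            def stat(mask):
                f1 = counts[mask].cumsum(axis=1).sum(axis=0) / mask.sum()
                f0 = counts[~mask].cumsum(axis=1).sum(axis=0) / (~mask).sum()
                return np.abs(f1 - f0).max()

            d_obs = stat(is_rew)
            hits = total = 0
            for combo in combinations(range(n), int(is_rew.sum())):
                m = np.zeros(n, bool)
                m[list(combo)] = True
                hits += stat(m) >= d_obs - 1e-12
                total += 1
            assert p_pkg == pytest.approx(hits / total)

    def test_null_labels_give_uniform_p(self):
        rng = np.random.default_rng(9)
        pvals = []
        for i in range(60):
            counts = rng.poisson(0.6, size=(40, 12))
            is_rew = rng.permutation(np.arange(40) % 2 == 0)
            pvals.append(condition_selectivity_test(counts, is_rew, n_perm=200, seed=i))
        fpr = np.mean(np.asarray(pvals) <= 0.05)
        assert fpr <= 0.12  # coarse check; full calibration in acceptance suite

    def test_empty_condition_signalled(self):
        with pytest.raises(InsufficientData):
            condition_selectivity_test(np.ones((10, 5)), np.zeros(10, bool))


class TestPopulationSummary:
    def test_selective_fraction_partition(self, nm_expert_session):
        import pandas as pd

        units = pd.DataFrame(
            {
                "p_responsive": [0.01, 0.01, 0.01, 0.9],
                "p_nm": [0.01, 0.9, 0.01, 0.01],
                "p_ci": [0.9, 0.01, 0.01, 0.01],
            }
        )
        frac = selective_fraction(units, alpha=0.05)
        assert frac["nm_only"] == 0.25
        assert frac["ci_only"] == 0.25
        assert frac["both"] == 0.25
        assert frac["neither"] == 0.25  # unit 4 fails responsiveness
        assert frac["nm_only"] + frac["ci_only"] + frac["both"] + frac["neither"] == 1.0

    def test_all_null_pvalues_give_all_neither(self):
        import pandas as pd

        units = pd.DataFrame(
            {"p_responsive": [1.0] * 5, "p_nm": [1.0] * 5, "p_ci": [1.0] * 5}
        )
        frac = selective_fraction(units, alpha=0.05)
        assert (frac["nm_only"], frac["ci_only"], frac["both"], frac["neither"]) == (
            0.0,
            0.0,
            0.0,
            1.0,
        )

    def test_characterize_recovers_planted_units(self, nm_expert_session):
        from schema_mux.selectivity import SelectivityParams

        s = nm_expert_session
        df = characterize_units(
            s["spikes"], s["trials"], SelectivityParams(n_permutations=200), seed=0
        )
        truth = s["model"].nm_selective_mask
        rec = df["selective_nm"].to_numpy()
        assert rec[truth].mean() >= 0.9  # planted units found
        assert rec[~truth].mean() <= 0.15  # few false positives
        # delta-z sign tracks the planted gain direction
        sel = truth & rec
        signs_ok = np.sign(df["delta_z_nm"].to_numpy()[sel]) == np.sign(
            np.log(s["model"].nm_gain[sel])
        )
        assert signs_ok.mean() >= 0.95
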