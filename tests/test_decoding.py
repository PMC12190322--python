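"""Confusion matrices, rule templates, permutation tests, residualization."""

import numpy as np
import pytest
from sklearn.svm import SVC

from schema_mux.decoding import (
    ConfusionMatrix,
    _balanced_weights,
    _standardize,
    binary_rule_decoder,
    diagonal_ratio,
    loo_confusion,
    loo_predictions,
    make_template,
    residualize_choice,
    template_permutation_test,
    template_similarity,
)
from schema_mux.simulate import AgentPolicy, generate_trial_sequence, simulate_choices


def _uniform_confusion():
    return ConfusionMatrix(np.full((16, 16), 1 / 16), np.full(16, 10))


def _identity_confusion():
    return ConfusionMatrix(np.eye(16), np.full(16, 10))


def _block_confusion(kind):
    """Row mass spread uniformly over the template's off-diagonal 1-cells."""
    t = make_template(kind).matrix.astype(float)
    np.fill_diagonal(t, 0.0)
    return ConfusionMatrix(t / t.sum(axis=1, keepdims=True), np.full(16, 10))


class TestLooConfusion:
    def test_separable_two_classes_give_identity_block(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (20, 4)), rng.normal(5, 0.3, (20, 4))])
        labels = np.array([0] * 20 + [8] * 20)
        conf = loo_confusion(X, labels)
        assert conf.matrix[0, 0] == 1.0
        assert conf.matrix[8, 8] == 1.0

    def test_pure_noise_yields_chance_diagonal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(320, 12))
        labels = np.repeat(np.arange(16), 20)
        conf = loo_confusion(X, labels)
        assert abs(np.nanmean(np.diag(conf.matrix)) - 1 / 16) < 0.03

    def test_duplicating_every_trial_preserves_confusion(self):
        # well-separated classes: all held-out points sit far from the
        # margin, so duplicating every trial cannot move any prediction
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 5), scale=0.5) + np.repeat(np.arange(3)[:, None] * 4.0, 10, axis=0)
        labels = np.repeat([0, 5, 11], 10)
        c1 = loo_confusion(X, labels)
        c2 = loo_confusion(np.vstack([X, X]), np.concatenate([labels, labels]))
        np.testing.assert_allclose(c1.matrix[c1.counts > 0], c2.matrix[c2.counts > 0], atol=1e-6)

    def test_single_trial_class_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(21, 4))
        X[:10] += 4
        labels = np.array([0] * 10 + [1] * 10 + [2])
        with pytest.warns(UserWarning, match="single-trial"):
            conf = loo_confusion(X, labels)
        assert conf.counts[2] == 0

    def test_matches_naive_per_trial_refit_loop(self):
        # independent oracle: plain SVC refit for every held-out trial
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 6)) + np.repeat(np.arange(3)[:, None], 10, axis=0) * 1.5
        labels = np.repeat([1, 6, 14], 10)
        Xs = _standardize(X)
        weights = _balanced_weights(labels)
        naive = np.empty(30, dtype=int)
        for i in range(30):
            m = np.arange(30) != i
            clf = SVC(kernel="linear", C=1.0, class_weight=weights)
            clf.fit(Xs[m], labels[m])
            naive[i] = clf.predict(Xs[i : i + 1])[0]
        conf = loo_confusion(X, labels)
        tally = np.zeros((16, 16))
        for t, p in zip(labels, naive):
            tally[t, p] += 1
        expected = tally[[1, 6, 14]] / 10
        np.testing.assert_allclose(conf.matrix[[1, 6, 14]], expected, atol=1e-9)


class TestTemplates:
    @pytest.mark.parametrize(
        "kind, row_sum", [("nonmatch", 8), ("cueid", 8), ("both_rules", 4)]
    )
    def test_row_sums(self, kind, row_sum):
        t = make_template(kind).matrix
        assert (t.sum(axis=1) == row_sum).all()
        np.testing.assert_array_equal(t, t.T)
        assert (np.diag(t) == 1).all()

    def test_both_rules_is_elementwise_and(self):
        nm = make_template("nonmatch").matrix
        ci = make_template("cueid").matrix
        np.testing.assert_array_equal(make_template("both_rules").matrix, nm & ci)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_template("diagonal")


class TestTemplateSimilarity:
    @pytest.mark.parametrize("kind", ["nonmatch", "cueid", "both_rules"])
    def test_block_confusion_scores_one(self, kind):
        assert template_similarity(_block_confusion(kind), make_template(kind)) == pytest.approx(1.0)

    def test_identity_scores_zero(self):
        assert template_similarity(_identity_confusion(), make_template("nonmatch")) == pytest.approx(0.0)

    def test_uniform_scores_zero(self):
        assert template_similarity(_uniform_confusion(), make_template("cueid")) == pytest.approx(0.0)

    def test_bounded_for_random_row_stochastic_matrices(self):
        rng = np.random.default_rng(5)
        tmpl = make_template("nonmatch")
        for _ in range(50):
            P = rng.dirichlet(np.ones(16), size=16)
            s = template_similarity(ConfusionMatrix(P, np.full(16, 5)), tmpl)
            assert -1.0 - 1e-9 <= s <= 1.0 + 1e-9


class TestTemplatePermutation:
    def test_aligned_blocks_hit_p_floor(self):
        conf = _block_confusion("nonmatch")
        s, p = template_permutation_test(conf, make_template("nonmatch"), n_perm=1000, seed=0)
        assert s == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1001)

    def test_uniform_confusion_is_never_significant(self):
        _, p = template_permutation_test(_uniform_confusion(), make_template("cueid"), n_perm=500, seed=1)
        assert p == 1.0  # score is 0 under every relabeling

    def test_all_ones_template_is_permutation_invariant(self):
        tmpl = make_template("nonmatch")
        tmpl.matrix = np.ones((16, 16), dtype=int)
        conf = _block_confusion("nonmatch")
        _, p = template_permutation_test(conf, tmpl, n_perm=200, seed=2)
        assert p == 1.0


class TestDiagonalRatio:
    def test_uniform_gives_one(self):
        assert diagonal_ratio(_uniform_confusion()) == pytest.approx(1.0)

    def test_identity_gives_infinity(self):
        assert diagonal_ratio(_identity_confusion()) == np.inf

    def test_configuration_coding_raises_ratio(self):
        # pure cue-identity coding confuses same-odor partners as much as
        # itself; adding configuration coding empties the side diagonal
        ci_only = np.zeros((16, 16))
        for i in range(16):
            ci_only[i, i] = ci_only[i, (i + 8) % 16] = 0.5
        mixed = np.eye(16) * 0.8
        for i in range(16):
            mixed[i, (i + 8) % 16] = 0.2
        r_ci = diagonal_ratio(ConfusionMatrix(ci_only, np.full(16, 5)))
        r_mixed = diagonal_ratio(ConfusionMatrix(mixed, np.full(16, 5)))
        assert r_ci == pytest.approx(1.0)
        assert r_mixed > r_ci


class TestBinaryRuleDecoder:
    def test_separable_toy_reaches_perfect_accuracy_and_floor_p(self):
        rng = np.random.default_rng(6)
        trials = generate_trial_sequence(40, seed=6)
        trials, _ = simulate_choices(trials, AgentPolicy(), seed=6)
        from schema_mux.data import eligible_trials, reward_flag

        elig = eligible_trials(trials)
        flag = reward_flag(elig, "nonmatch_rule").to_numpy()
        X = rng.normal(size=(len(elig), 2), scale=0.1)
        X[flag] += 5.0
        res = binary_rule_decoder(X, trials, "nonmatch_rule", n_perm=200, seed=0)
        assert res.accuracy == 1.0
        assert res.p_value == pytest.approx(1 / 201)

    def test_shuffled_labels_not_significant(self):
        rng = np.random.default_rng(7)
        trials = generate_trial_sequence(60, seed=7)
        trials, _ = simulate_choices(trials, AgentPolicy(), seed=7)
        X = rng.normal(size=(59, 8))  # features carry no label information
        res = binary_rule_decoder(X, trials, "nonmatch_rule", n_perm=200, seed=1)
        assert res.p_value > 0.05

    def test_single_class_rejected(self):
        trials = generate_trial_sequence(30, seed=8, p_repeat=1e-6)  # all nonmatch
        X = np.random.default_rng(8).normal(size=(29, 3))
        with pytest.raises(ValueError, match="per class"):
            binary_rule_decoder(X, trials, "nonmatch_rule", n_perm=10)


class TestResidualizeChoice:
    def test_choice_indicator_feature_becomes_zero(self):
        choices = np.array(["go", "nogo"] * 10)
        X = (choices == "go").astype(float)[:, None]
        resid = residualize_choice(X, choices)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_choice_independent_feature_only_centered(self):
        rng = np.random.default_rng(9)
        choices = np.array(["go"] * 10 + ["nogo"] * 10)
        X = np.tile(rng.normal(size=(10, 3)), (2, 1))  # identical across groups
        resid = residualize_choice(X, choices)
        np.testing.assert_allclose(resid, X - X.mean(axis=0), atol=1e-9)

    def test_residuals_orthogonal_to_choice(self):
        rng = np.random.default_rng(10)
        choices = rng.choice(["go", "nogo"], 50)
        X = rng.normal(size=(50, 6)) + 2.0 * (choices == "go")[:, None]
        resid = residualize_choice(X, choices)
        go = (choices == "go").astype(float)
        np.testing.assert_allclose(resid.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(go @ resid, 0.0, atol=1e-9)

    def test_only_orthogonal_signal_survives(self):
        # rule signal aligned with choice is removed; orthogonal signal stays
        rng = np.random.default_rng(11)
        n = 80
        rule = np.tile([0, 1], n // 2)
        choice_str = np.where(rule == 1, "go", "nogo")  # choice == rule here
        orthogonal = rng.normal(size=n)
        X = np.column_stack([rule * 3.0, orthogonal])
        resid = residualize_choice(X, choice_str)
        assert np.abs(resid[:, 0]).max() < 1e-9
        assert np.corrcoef(resid[:, 1], orthogonal - orthogonal.mean())[0, 1] > 0.95

    def test_all_same_choice_warns_and_centers(self):
        X = np.random.default_rng(12).normal(size=(10, 2))
        with pytest.warns(UserWarning, match="identical"):
            resid = residualize_choice(X, np.array(["go"] * 10))
        np.testing.assert_allclose(resid, X - X.mean(axis=0))


class TestRecoveryFromPlantedStructure:
    def test_nm_scenario_matches_nonmatch_template_only(self, nm_expert_features):
        trials, X, labels = nm_expert_features
        conf = loo_confusion(X, labels, seed=0)
        s_nm, p_nm = template_permutation_test(conf, make_template("nonmatch"), n_perm=1000, seed=0)
        s_ci, p_ci = template_permutation_test(conf, make_template("cueid"), n_perm=1000, seed=0)
        assert p_nm <= 0.01
        assert p_ci > 0.05
        assert s_nm > s_ci

    def test_nm_scenario_binary_decoders(self, nm_expert_features):
        trials, X, _ = nm_expert_features
        nm = binary_rule_decoder(X, trials, "nonmatch_rule", n_perm=0)
        assert nm.accuracy >= 0.9
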