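"""Pseudo-ensembles, linear embedding, centroid distances, dendrograms."""

import io as _io

import numpy as np
import pytest

from schema_mux.binning import response_rates
from schema_mux.geometry import (
    build_pseudoensemble,
    centroid_distances,
    contrast_distance,
    distance_permutation_test,
    embed_population,
    linkage_leaf_order,
    linkage_to_newick,
    trial_type_index,
    ward_linkage,
)
from schema_mux.simulate import Scenario, make_scenario

from conftest import build_trials


def _session_pair(seed, n_trials=200, n_units=15, name="nm_expert"):
    s = make_scenario(
        Scenario(name, n_sessions=1, n_trials_per_session=n_trials, n_units=n_units, seed=seed)
    )[0]
    return s["trials"], response_rates(s["spikes"], s["trials"])


class TestPseudoEnsemble:
    def test_columns_standardized_over_included_trials(self):
        pe = build_pseudoensemble([_session_pair(0)], n_per_type=4, seed=1)
        np.testing.assert_allclose(pe.matrix.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(pe.matrix.std(axis=0), 1.0, atol=1e-9)
        counts = np.bincount(pe.labels, minlength=16)
        assert set(counts[counts > 0]) == {4}

    def test_two_identical_sessions_double_unit_count(self):
        pair = _session_pair(2)
        pe1 = build_pseudoensemble([pair], n_per_type=3, seed=5)
        pe2 = build_pseudoensemble([pair, pair], n_per_type=3, seed=5)
        assert pe2.n_units == 2 * pe1.n_units
        # same subsample seed, same session: the two column blocks agree
        np.testing.assert_allclose(pe2.matrix[:, : pe1.n_units], pe2.matrix[:, pe1.n_units :])

    def test_zero_variance_unit_dropped_with_warning(self):
        trials, feats = _session_pair(3)
        feats = feats.copy()
        feats["dead"] = 0.0
        with pytest.warns(UserWarning, match="zero-variance"):
            pe = build_pseudoensemble([(trials, feats)], n_per_type=3, seed=0)
        assert not any(u.endswith("dead") for u in pe.unit_ids)

    def test_missing_type_strict_mode_raises(self):
        trials, feats = _session_pair(4, n_trials=40)
        with pytest.raises(ValueError, match="dropped"):
            build_pseudoensemble([(trials, feats)], n_per_type=30, seed=0, strict=True)


class TestEmbedding:
    def test_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 10))
        np.testing.assert_array_equal(
            embed_population(X, "linear-fallback"), embed_population(X, "linear-fallback")
        )

    def test_rotation_leaves_distances_unchanged(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 8))
        q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
        d1 = np.linalg.norm(
            embed_population(X, "linear-fallback")[:, None]
            - embed_population(X, "linear-fallback")[None], axis=2
        )
        d2 = np.linalg.norm(
            embed_population(X @ q, "linear-fallback")[:, None]
            - embed_population(X @ q, "linear-fallback")[None], axis=2
        )
        np.testing.assert_allclose(d1, d2, atol=1e-8)

    def test_planted_two_cluster_structure_separates(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 12), scale=0.5)
        X[:30] += 4.0  # cluster offset on every unit
        coords = embed_population(X, "linear-fallback")
        a, b = coords[:30], coords[30:]
        between = np.linalg.norm(a.mean(0) - b.mean(0))
        within = np.mean([np.linalg.norm(p - a.mean(0)) for p in a])
        assert between > within

    def test_rank_deficient_padded_with_warning(self):
        X = np.outer(np.arange(10.0), [1.0, 2.0, 3.0])  # rank 1
        with pytest.warns(UserWarning, match="rank"):
            coords = embed_population(X, "linear-fallback", dims=3)
        assert coords.shape == (10, 3)
        np.testing.assert_allclose(coords[:, 1:], 0.0)


class TestCentroidDistances:
    def test_self_distance_zero_and_symmetry(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(80, 3))
        labels = np.repeat(np.arange(8), 10)
        dist, _ = centroid_distances(coords, labels)
        np.testing.assert_allclose(np.diag(dist), 0.0)
        np.testing.assert_allclose(dist, dist.T)
        assert (dist >= 0).all()

    def test_unit_variance_clouds_at_plus_minus_one(self):
        # centroids at +/-1 with pooled within-type variance exactly 1
        coords = np.array([[0.0], [2.0], [-2.0], [0.0]])
        labels = np.array([0, 0, 1, 1])
        dist, _ = centroid_distances(coords, labels)
        assert dist[0, 1] == pytest.approx(2.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(60, 3))
        labels = np.repeat(np.arange(6), 10)
        d1, _ = centroid_distances(coords, labels)
        d2, _ = centroid_distances(coords * np.array([2.0, 5.0, 0.3]), labels)
        np.testing.assert_allclose(d1, d2, atol=1e-9)

    def test_singleton_type_excluded(self):
        coords = np.vstack([np.random.default_rng(0).normal(size=(10, 2)), [[9.0, 9.0]]])
        labels = np.array([0] * 5 + [1] * 5 + [2])
        with pytest.warns(UserWarning, match="singleton"):
            dist, kept = centroid_distances(coords, labels)
        assert dist.shape == (2, 2)
        assert 2 not in kept


class TestWardLinkage:
    def test_three_leaf_worked_example(self):
        dist = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0]], dtype=float)
        linkage = ward_linkage(dist)
        assert sorted(linkage[0, :2].astype(int).tolist()) == [0, 1]

    def test_label_order_invariance_of_topology(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(6, 2))
        pts[:3] += 10
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        perm = np.array([3, 1, 5, 0, 2, 4])
        z1 = ward_linkage(d)
        z2 = ward_linkage(d[np.ix_(perm, perm)])
        order1 = {frozenset(perm[np.asarray(g)]) for g in _leaf_sets(z2, 6)}
        order2 = {frozenset(np.asarray(g)) for g in _leaf_sets(z1, 6)}
        assert order1 == order2

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ward_linkage(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_newick_export_parses(self):
        import skbio

        dist = np.array([[0, 1, 9], [1, 0, 9], [9, 9, 0]], dtype=float)
        nwk = linkage_to_newick(ward_linkage(dist), ["a", "b", "c"])
        tree = skbio.TreeNode.read(_io.StringIO(nwk))
        assert {t.name for t in tree.tips()} == {"a", "b", "c"}

    def test_leaf_order_covers_all_leaves(self):
        rng = np.random.default_rng(11)
        d = np.abs(rng.normal(size=(5, 5)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        assert sorted(linkage_leaf_order(ward_linkage(d))) == list(range(5))


def _leaf_sets(linkage, n):
    """Leaf membership of every internal node (topology fingerprint)."""
    sets = {i: [i] for i in range(n)}
    out = []
    for k, (a, b, *_rest) in enumerate(linkage):
        merged = sets[int(a)] + sets[int(b)]
        sets[n + k] = merged
        out.append(merged)
    return out


class TestContrasts:
    def test_identical_coordinates_give_zero(self):
        coords = np.zeros((64, 3))
        labels = np.repeat(np.arange(16), 4)
        assert contrast_distance(coords, labels, "nm_config") == pytest.approx(0.0, abs=1e-6)

    def test_planted_nm_separation_dominates(self):
        rng = np.random.default_rng(12)
        labels = np.repeat(np.arange(16), 6)
        coords = rng.normal(size=(96, 3))
        coords[labels >= 8, 0] += 8.0  # configuration axis only
        nm = contrast_distance(coords, labels, "nm_config")
        ci = contrast_distance(coords, labels, "ci_reward")
        assert nm > ci

    def test_permutation_floor_on_separated_clusters(self):
        rng = np.random.default_rng(13)
        labels = np.repeat(np.arange(16), 6)
        coords = rng.normal(size=(96, 3), scale=0.1)
        coords[labels >= 8, 0] += 20.0
        obs, null_mean, p = distance_permutation_test(
            coords, labels, "nm_config", n_perm=1000, seed=0
        )
        assert p == pytest.approx(1 / 1001)
        assert obs > null_mean

    def test_p_equals_one_when_observed_below_every_null(self):
        # same-odor pairs coincide exactly, other odors are spread out:
        # shuffling labels can only increase the match/nonmatch contrast
        rng = np.random.default_rng(14)
        labels = np.repeat(np.arange(16), 4)
        odor_pos = rng.normal(size=(8, 3), scale=10.0)
        coords = odor_pos[labels % 8]  # same-odor pairs coincide exactly
        _, _, p = distance_permutation_test(coords, labels, "nm_config", n_perm=300, seed=1)
        assert p == 1.0


class TestFullGeometryPipeline:
    def test_unit_permutation_invariance(self):
        trials, feats = _session_pair(15)
        pe = build_pseudoensemble([(trials, feats)], n_per_type=4, seed=3)
        perm = np.random.default_rng(16).permutation(pe.n_units)
        c1 = embed_population(pe.matrix, "linear-fallback")
        c2 = embed_population(pe.matrix[:, perm], "linear-fallback")
        d1, _ = centroid_distances(c1, pe.labels)
        d2, _ = centroid_distances(c2, pe.labels)
        np.testing.assert_allclose(d1, d2, atol=1e-7)
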