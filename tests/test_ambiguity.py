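import numpy as np
import pytest

from stillsmerge import ambiguity as amb
from stillsmerge.ambiguity import (
    CorrelationTable,
    assign_hands,
    apply_reindexing,
    build_correlation_table,
    cc_through_origin,
    functional_and_gradient,
    minimize_functional,
)
from stillsmerge.geometry import reindex
from tests.conftest import correct_with_truth, dense_config
from stillsmerge.simulate import generate_dataset


class TestCCThroughOrigin:
    def test_proportional_inputs_score_one(self):
        x = np.array([1.0, 2.0, 5.0])
        assert cc_through_origin(x, 2.0 * x) == pytest.approx(1.0, abs=1e-12)
        assert cc_through_origin(np.array([3.0, 7.0]), np.array([3.0, 7.0])) == 1.0

    def test_negative_radicand_reassigned_zero(self):
        # anticorrelated pair: through-origin residuals exceed the total SS
        assert cc_through_origin(np.array([1.0, 2.0]), np.array([2.0, 1.0])) == 0.0

    def test_fixed_four_point_table_frozen_value(self):
        """Hand evaluation of the through-origin formula in exact rational
        arithmetic gives 0.997455458298288 for this table."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.1, 3.9, 6.2, 7.8])
        assert cc_through_origin(x, y) == pytest.approx(0.997455458298288, abs=1e-12)

    def test_symmetric_in_inputs(self, rng):
        for _ in range(20):
            x = rng.exponential(1.0, size=6)
            y = rng.exponential(1.0, size=6)
            assert cc_through_origin(x, y) == pytest.approx(cc_through_origin(y, x), abs=1e-14)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(50):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            v = cc_through_origin(x, y)
            assert 0.0 <= v <= 1.0

    def test_insufficient_overlap(self):
        with pytest.raises(ValueError, match="insufficient"):
            cc_through_origin(np.array([1.0]), np.array([1.0]))


class TestCorrelationTable:
    def test_self_correlation_is_one(self, small_dataset):
        images, _ = small_dataset
        table = build_correlation_table(images[:6], d_min=1.8)
        assert np.allclose(np.diag(table.r_same), 1.0)

    def test_same_hand_noiseless_pairs_correlate_perfectly(self, small_dataset):
        images, truth = small_dataset
        table = build_correlation_table(images, d_min=1.8)
        hands = np.array(truth.hands)
        same = (hands[:, None] == hands[None, :]) & table.mask_same
        np.fill_diagonal(same, False)
        assert np.all(table.r_same[same] > 1 - 1e-9)

    def test_swapping_hand_exchanges_same_and_cross(self, small_dataset):
        images, _ = small_dataset
        sub = [images[0], images[1]]
        t1 = build_correlation_table(sub, d_min=1.8)
        # reindex image 1 in a copy
        import copy
        b = copy.deepcopy(images[1])
        b.apply_reindex()
        t2 = build_correlation_table([images[0], b], d_min=1.8)
        assert t2.r_same[0, 1] == pytest.approx(t1.r_cross[0, 1], abs=1e-12)
        assert t2.r_cross[0, 1] == pytest.approx(t1.r_same[0, 1], abs=1e-12)


def random_table(rng, n=12) -> CorrelationTable:
    r = rng.uniform(0, 1, (n, n))
    rp = rng.uniform(0, 1, (n, n))
    r = (r + r.T) / 2
    rp = (rp + rp.T) / 2
    mask = np.ones((n, n), bool)
    np.fill_diagonal(mask, False)
    ns = np.full((n, n), 10)
    return CorrelationTable(r, rp, ns, ns, mask, mask.copy())


class TestFunctional:
    def test_gradient_matches_finite_differences(self, rng):
        table = random_table(rng)
        X = rng.uniform(0, 1, (table.n_images, 2))
        f0, g = functional_and_gradient(X, table)
        eps = 1e-6
        for idx in [(0, 0), (3, 1), (7, 0)]:
            Xp = X.copy()
            Xp[idx] += eps
            fp, _ = functional_and_gradient(Xp, table)
            assert (fp - f0) / eps == pytest.approx(g[idx], rel=1e-4, abs=1e-6)

    def test_invariant_under_simultaneous_hand_swap(self, rng):
        """Swapping one image's vector components while exchanging its same-
        and cross-hand correlations leaves the objective unchanged."""
        table = random_table(rng)
        X = rng.uniform(0, 1, (table.n_images, 2))
        f0, _ = functional_and_gradient(X, table)
        c = 4
        r = table.r_same.copy()
        rp = table.r_cross.copy()
        r[c, :], rp[c, :] = table.r_cross[c, :].copy(), table.r_same[c, :].copy()
        r[:, c], rp[:, c] = table.r_cross[:, c].copy(), table.r_same[:, c].copy()
        r[c, c] = table.r_same[c, c]
        rp[c, c] = table.r_cross[c, c]
        swapped = CorrelationTable(r, rp, table.n_shared_same, table.n_shared_cross,
                                   table.mask_same, table.mask_cross)
        Xs = X.copy()
        Xs[c] = X[c, ::-1]
        f1, _ = functional_and_gradient(Xs, swapped)
        assert f1 == pytest.approx(f0, rel=1e-12)

    def test_descent_property_over_seeds(self, rng):
        table = random_table(rng, n=15)
        for seed in range(20):
            _, info = minimize_functional(table, seed=seed)
            assert info["objective_final"] <= info["objective_initial"]

    def test_single_hand_limit_collapses_to_one_cluster(self):
        n = 10
        r = np.ones((n, n))
        rp = np.zeros((n, n))
        mask = ~np.eye(n, dtype=bool)
        ns = np.full((n, n), 10)
        table = CorrelationTable(r, rp, ns, ns, mask, mask.copy())
        X, info = minimize_functional(table, seed=1)
        assert info["objective_final"] < 1e-6
        V = X / np.linalg.norm(X, axis=1, keepdims=True)
        assert np.all(V @ V[0] > 0.999)  # all vectors share one direction


class TestHandAssignment:
    def test_two_ideal_clusters_are_separated(self):
        X = np.vstack([np.tile([1.0, 0.05], (6, 1)), np.tile([0.05, 1.0], (4, 1))])
        hands, info = assign_hands(X)
        assert set(hands[:6]) == {"A"} and set(hands[6:]) == {"B"}
        assert not info["ambiguous"]

    def test_single_cluster_all_hand_a(self):
        X = np.tile([0.7, 0.7], (8, 1)) + 1e-3 * np.arange(8)[:, None]
        hands, _ = assign_hands(X)
        assert set(hands) == {"A"}

    def test_invariant_under_global_rotation(self):
        X = np.vstack([np.tile([1.0, 0.0], (6, 1)), np.tile([0.0, 1.0], (4, 1))])
        theta = 0.4
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        h1, _ = assign_hands(X)
        h2, _ = assign_hands(X @ R.T)
        assert np.array_equal(h1, h2)


class TestApplyReindexing:
    def test_involution_restores_dataset(self, small_dataset):
        import copy
        images, _ = small_dataset
        sub = copy.deepcopy(images[:4])
        before = [im.hkl.copy() for im in sub]
        labels = np.array(["A", "B", "B", "A"])
        apply_reindexing(sub, labels)
        apply_reindexing(sub, labels)
        for im, h in zip(sub, before):
            assert np.array_equal(im.hkl, h)

    def test_hand_a_untouched_hand_b_mapped(self, small_dataset):
        import copy
        images, _ = small_dataset
        sub = copy.deepcopy(images[:2])
        before_a = sub[0].hkl.copy()
        before_b = sub[1].hkl.copy()
        apply_reindexing(sub, np.array(["A", "B"]))
        assert np.array_equal(sub[0].hkl, before_a)
        assert np.array_equal(sub[1].hkl, reindex(before_b))

    def test_reindexed_pairs_prefer_same_hand_correlation(self, small_dataset):
        """After resolution, same-hand correlations dominate cross-hand ones
        for the overwhelming majority of well-overlapping pairs."""
        import copy
        images, truth = small_dataset
        sub = copy.deepcopy(images)
        table = build_correlation_table(sub, d_min=1.8)
        X, _ = minimize_functional(table, seed=1)
        hands, _ = assign_hands(X)
        apply_reindexing(sub, hands)
        t2 = build_correlation_table(sub, d_min=1.8)
        mask = t2.mask_same & t2.mask_cross & (t2.n_shared_same >= 10)
        iu = np.triu_indices(len(sub), 1)
        m = mask[iu]
        frac = np.mean(t2.r_same[iu][m] >= t2.r_cross[iu][m])
        assert frac >= 0.99


class TestRecovery:
    def test_mixed_set_recovered_up_to_global_swap(self):
        cfg = dense_config()
        images, truth = generate_dataset(30, 0.5, seed=21, config=cfg)
        correct_with_truth(images, truth)
        table = build_correlation_table(images, d_min=1.8)
        X, info = minimize_functional(table, seed=1)
        hands, _ = assign_hands(X)
        th = np.array(truth.hands)
        acc = max((hands == th).mean(), (hands != th).mean())
        assert acc == 1.0
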