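"""Evaluation statistics, each checked against an independent oracle:
brute-force separators, closed-form noise ratios, exhaustive permutation
nulls, hand-computed Welch/Pearson formulas."""

import itertools

import numpy as np
import pytest

from ctxmotif.evaluation import (
    classify_windows, cross_seed_reliability, distance_manifold_r2,
    group_ttest, pearson_r, step_distance_permutation, step_distances,
)


class TestClassifyWindows:
    def test_widely_separated_blobs_classify_perfectly(self, rng):
        a = rng.standard_normal((200, 2))
        b = rng.standard_normal((200, 2)) + 20.0
        X = np.vstack([a, b])
        y = np.array(["HC"] * 200 + ["SZ"] * 200)
        assert classify_windows(X, y, X, y) == 1.0

    def test_coin_flip_labels_score_at_chance(self, rng):
        X = rng.standard_normal((4000, 4))
        y = rng.choice(["HC", "SZ"], size=4000)
        acc = classify_windows(X[:2000], y[:2000], X[2000:], y[2000:])
        assert 0.45 <= acc <= 0.55

    def test_matches_brute_force_max_margin_separator(self):
        """8 fixed separable 2-D points: enumerate all linear separators
        induced by point pairs (plus margin maximization on a direction grid)
        and compare accuracies."""
        X = np.array([[0.0, 0.0], [1.0, 0.5], [0.5, 1.0], [0.2, 0.4],
                      [3.0, 3.0], [4.0, 2.5], [3.5, 4.0], [2.8, 3.6]])
        y = np.array(["HC"] * 4 + ["SZ"] * 4)
        best_acc = 0.0
        for theta in np.linspace(0, np.pi, 721):
            d = np.array([np.cos(theta), np.sin(theta)])
            proj = X @ d
            for cut in (proj[:, None] + proj[None, :]).ravel() / 2:
                pred = np.where(proj > cut, "SZ", "HC")
                acc = max((pred == y).mean(), (pred != y).mean())
                best_acc = max(best_acc, acc)
        assert classify_windows(X, y, X, y) == pytest.approx(best_acc)

    def test_single_class_training_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="single class"):
            classify_windows(X, np.array(["HC"] * 4), X, np.array(["HC"] * 4))

    def test_nearly_invariant_to_consistent_rotation(self, rng):
        X = rng.standard_normal((300, 2))
        y = np.where(X[:, 0] + 0.3 * rng.standard_normal(300) > 0, "SZ", "HC")
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        acc1 = classify_windows(X[:200], y[:200], X[200:], y[200:])
        XR = X @ R.T
        acc2 = classify_windows(XR[:200], y[:200], XR[200:], y[200:])
        assert abs(acc1 - acc2) < 0.02


class TestCrossSeedReliability:
    def test_affine_copies_are_perfectly_predictable(self, rng):
        A = rng.standard_normal((500, 2))
        theta = 0.7
        R = 3.0 * np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
        B = A @ R.T + np.array([1.0, -2.0])
        assert cross_seed_reliability([A, B]) == pytest.approx(1.0, abs=1e-10)

    def test_independent_spaces_score_near_zero(self, rng):
        spaces = [rng.standard_normal((5000, 2)) for _ in range(2)]
        assert cross_seed_reliability(spaces) < 0.01

    def test_known_noise_ratio_recovers_expected_r2(self, rng):
        """B = 2A + eps: per-dimension R^2 should equal 1 - Var(eps)/Var(B)."""
        A = rng.standard_normal((20000, 2))
        eps = 0.5 * rng.standard_normal((20000, 2))
        B = 2.0 * A + eps
        expected = 1.0 - eps.var() / B.var()
        _, pairs = cross_seed_reliability([A, B], return_pairs=True)
        assert pairs[(0, 1)] == pytest.approx(expected, abs=0.02)

    def test_averages_over_all_ordered_pairs(self, rng):
        A = rng.standard_normal((100, 2))
        spaces = [A, A @ np.array([[0.0, 1.0], [-1.0, 0.0]]), rng.standard_normal((100, 2))]
        mean, pairs = cross_seed_reliability(spaces, return_pairs=True)
        assert len(pairs) == 6
        assert mean == pytest.approx(np.mean(list(pairs.values())))

    def test_row_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="row counts"):
            cross_seed_reliability([rng.standard_normal((10, 2)),
                                    rng.standard_normal((11, 2))])


class TestDistanceManifold:
    def test_identical_spaces_have_unit_r2(self, rng):
        Z = rng.standard_normal((40, 3))
        assert distance_manifold_r2(Z, Z, n_pairs=None) == pytest.approx(1.0)

    def test_independent_spaces_have_near_zero_r2(self, rng):
        Z = rng.standard_normal((600, 2))
        F = rng.standard_normal((600, 5))
        assert distance_manifold_r2(Z, F, n_pairs=100_000, pair_seed=1) < 0.01

    def test_all_pairs_of_six_windows_match_hand_computation(self):
        Z = np.array([[0.0, 0], [1, 0], [0, 2], [3, 1], [2, 2], [1, 4]])
        F = np.array([[1.0, 1], [0, 3], [2, 0], [1, 2], [4, 1], [0, 0]])
        dz, df = [], []
        for i, j in itertools.combinations(range(6), 2):
            dz.append(np.linalg.norm(Z[i] - Z[j]))
            df.append(np.linalg.norm(F[i] - F[j]))
        r = np.corrcoef(dz, df)[0, 1]
        assert distance_manifold_r2(Z, F, n_pairs=None) == pytest.approx(r**2, abs=1e-10)

    def test_requesting_too_many_pairs_rejected(self, rng):
        Z = rng.standard_normal((5, 2))
        with pytest.raises(ValueError, match="exceeds"):
            distance_manifold_r2(Z, Z, n_pairs=11)

    def test_sampled_pair_indices_are_valid_and_distinct(self, rng):
        # large n with subsampling: the answer should approximate the full one
        Z = rng.standard_normal((200, 2))
        F = Z + 0.1 * rng.standard_normal((200, 2))
        full = distance_manifold_r2(Z, F, n_pairs=None)
        sub = distance_manifold_r2(Z, F, n_pairs=5000, pair_seed=3)
        assert sub == pytest.approx(full, abs=0.05)


class TestStepDistances:
    def test_constant_trajectory_has_zero_steps(self):
        assert step_distances({"s": np.zeros((10, 2))})["s"] == 0.0

    def test_one_dimensional_arithmetic(self):
        assert step_distances({"s": np.array([0.0, 1.0, 3.0])})["s"] == pytest.approx(1.5)

    def test_scaling_homogeneity(self, rng):
        traj = rng.standard_normal((30, 2))
        base = step_distances({"s": traj})["s"]
        assert step_distances({"s": -2.5 * traj})["s"] == pytest.approx(2.5 * base)

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            step_distances({"s": np.ones((1, 2))})


class TestStepPermutation:
    def test_exhaustive_null_matches_enumeration_oracle(self, rng):
        """6 subjects, 3 SZ: all C(6,3)=20 label assignments enumerated
        independently."""
        steps = rng.uniform(0.5, 2.0, size=6)
        dx = np.array(["SZ", "SZ", "SZ", "HC", "HC", "HC"])
        res = step_distance_permutation(steps, dx, n_permutations="exhaustive")
        diffs = [steps[list(c)].mean() - np.delete(steps, list(c)).mean()
                 for c in itertools.combinations(range(6), 3)]
        assert len(diffs) == 20
        assert res.null_mean == pytest.approx(np.mean(diffs), abs=1e-3)
        assert res.null_sd == pytest.approx(np.std(diffs), abs=1e-3)
        expected_z = (res.observed_difference - np.mean(diffs)) / np.std(diffs)
        assert res.z_score == pytest.approx(expected_z, abs=1e-3)

    def test_complete_separation_gives_strongly_negative_z(self, rng):
        steps = np.concatenate([rng.uniform(0.1, 0.4, 20), rng.uniform(1.0, 1.5, 20)])
        dx = np.array(["SZ"] * 20 + ["HC"] * 20)
        res = step_distance_permutation(steps, dx, n_permutations=5000,
                                        permutation_seed=0)
        assert res.z_score <= -3.0

    def test_null_z_is_approximately_standard_normal(self):
        """200 same-distribution cohorts: z should have ~zero mean and unit sd."""
        zs = []
        for sim in range(200):
            rng = np.random.default_rng(1000 + sim)
            steps = rng.gamma(4.0, 0.25, size=40)
            dx = np.array(["SZ"] * 20 + ["HC"] * 20)
            res = step_distance_permutation(steps, dx, n_permutations=1000,
                                            permutation_seed=sim)
            zs.append(res.z_score)
        assert abs(np.mean(zs)) < 0.2
        assert 0.8 <= np.std(zs) <= 1.2

    def test_deterministic_given_seed_and_invariant_fields(self, rng):
        steps = rng.uniform(0.5, 2.0, size=12)
        dx = np.array(["SZ"] * 6 + ["HC"] * 6)
        a = step_distance_permutation(steps, dx, 500, permutation_seed=7)
        b = step_distance_permutation(steps, dx, 500, permutation_seed=7)
        assert a == b
        assert a.z_score == pytest.approx((a.observed_difference - a.null_mean) / a.null_sd)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            step_distance_permutation([1.0, 2.0], ["SZ", "SZ"])


class TestTTest:
    def test_identical_groups_give_zero_t_unit_p(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p = group_ttest(a, a.copy())
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_swapping_groups_negates_t(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        t_ab, p_ab = group_ttest(a, b)
        t_ba, p_ba = group_ttest(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_matches_welch_formula_by_hand(self):
        a = np.array([4.1, 5.2, 6.3, 5.5, 4.9])
        b = np.array([3.0, 3.8, 2.9, 3.4, 3.3])
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        expected_t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        t, p = group_ttest(a, b)
        assert t == pytest.approx(expected_t)
        assert 0.0 < p < 0.05

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            group_ttest([1.0, 1.0], [2.0, 2.0])


class TestPearson:
    def test_exact_linear_relationship(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula_on_fixed_table(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        xc, yc = x - x.mean(), y - y.mean()
        expected = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert pearson_r(x, y)[0] == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
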