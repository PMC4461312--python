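from itertools import permutations

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from commsize import mantel, procrustes, protest


def _rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, s], [-s, c]])


def _brute_force_mantel(D1, D2):
    """Exact Mantel reference: r over all joint relabellings of D2."""
    n = D1.shape[0]
    iu = np.triu_indices(n, k=1)
    v1 = D1[iu]
    rs = []
    for perm in permutations(range(n)):
        p = np.asarray(perm)
        rs.append(pearsonr(v1, D2[np.ix_(p, p)][iu]).statistic)
    r_obs = rs[0]  # identity permutation first
    p_exact = np.mean(np.asarray(rs) >= r_obs - 1e-12)
    return r_obs, p_exact


class TestMantel:
    def test_self_comparison_is_one(self, rng):
        D = squareform(rng.uniform(0.1, 1.0, size=10))
        res = mantel(D, D, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_perfect_reversal_is_minus_one(self):
        D1 = squareform(np.array([1.0, 2.0, 3.0]))
        D2 = squareform(np.array([3.0, 2.0, 1.0]))
        assert mantel(D1, D2, 99, 0).r == pytest.approx(-1.0, abs=1e-12)

    def test_three_sample_r_and_p_match_enumeration(self):
        D1 = squareform(np.array([1.0, 2.0, 3.0]))
        D2 = squareform(np.array([1.0, 3.0, 2.0]))
        res = mantel(D1, D2, n_permutations=999, seed=3)
        r_ref, p_ref = _brute_force_mantel(D1, D2)
        assert res.r == pytest.approx(0.5, abs=1e-12)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        # Monte-Carlo estimate of the enumerated p (3 sigma binomial slack)
        se = np.sqrt(p_ref * (1 - p_ref) / 999)
        assert res.p_value == pytest.approx(p_ref, abs=max(3 * se, 0.02))

    @pytest.mark.parametrize("n", [4, 5])
    def test_small_n_matches_enumeration(self, n, rng):
        D1 = squareform(rng.uniform(0.1, 1.0, size=n * (n - 1) // 2))
        D2 = squareform(rng.uniform(0.1, 1.0, size=n * (n - 1) // 2))
        res = mantel(D1, D2, n_permutations=1999, seed=n)
        r_ref, p_ref = _brute_force_mantel(D1, D2)
        assert res.r == pytest.approx(r_ref, abs=1e-10)
        se = np.sqrt(p_ref * (1 - p_ref) / 1999)
        assert res.p_value == pytest.approx(p_ref, abs=max(3 * se, 0.02))

    def test_symmetric_in_arguments(self, rng):
        D1 = squareform(rng.uniform(0.1, 1.0, size=15))
        D2 = squareform(rng.uniform(0.1, 1.0, size=15))
        assert mantel(D1, D2, 9, 0).r == pytest.approx(mantel(D2, D1, 9, 0).r)

    def test_invariant_to_common_relabelling(self, rng):
        D1 = squareform(rng.uniform(0.1, 1.0, size=15))
        D2 = squareform(rng.uniform(0.1, 1.0, size=15))
        p = rng.permutation(6)
        r1 = mantel(D1, D2, 9, 0).r
        r2 = mantel(D1[np.ix_(p, p)], D2[np.ix_(p, p)], 9, 0).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_dimension_mismatch_raises(self, rng):
        D1 = squareform(rng.uniform(0.1, 1.0, size=6))
        D2 = squareform(rng.uniform(0.1, 1.0, size=10))
        with pytest.raises(ValueError, match="dimension"):
            mantel(D1, D2)

    def test_zero_variance_flagged_undefined(self, rng):
        D1 = squareform(np.ones(6))
        D2 = squareform(rng.uniform(0.1, 1.0, size=6))
        assert mantel(D1, D2, 9, 0).undefined

    def test_agrees_with_scikit_bio(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        D1 = squareform(rng.uniform(0.1, 1.0, size=28))
        D2 = squareform(rng.uniform(0.1, 1.0, size=28))
        r_ref, _, _ = skbio_stats.mantel(
            skbio_stats.DistanceMatrix(D1),
            skbio_stats.DistanceMatrix(D2),
            permutations=0,
            alternative="greater",
        )
        assert mantel(D1, D2, 9, 0).r == pytest.approx(r_ref, abs=1e-10)


def _oracle_procrustes_ss(X, Y):
    """Grid + local search over angle/reflection with analytic scale/shift."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)

    def ss_at(theta, reflect):
        R = _rot(theta)
        if reflect:
            R = R @ np.diag([1.0, -1.0])
        Yr = Yc @ R
        c = np.sum(Xc * Yr) / np.sum(Yr**2)  # optimal dilation
        return float(np.sum((Xc - c * Yr) ** 2))

    best = np.inf
    for reflect in (False, True):
        grid = np.linspace(0, 2 * np.pi, 721)
        vals = [ss_at(t, reflect) for t in grid]
        t0 = grid[int(np.argmin(vals))]
        res = minimize_scalar(
            lambda t: ss_at(t, reflect), bracket=(t0 - 0.02, t0, t0 + 0.02)
        )
        best = min(best, float(res.fun))
    return best


class TestProcrustes:
    def test_similarity_transform_is_exact(self, rng):
        X = rng.normal(size=(7, 2))
        Y = 2.0 * X @ _rot(np.pi / 2) + np.array([3.0, -1.0])
        _, _, ss = procrustes(X, Y)
        assert ss <= 1e-10

    def test_reflection_is_permitted(self, rng):
        X = rng.normal(size=(7, 2))
        Y = X @ np.diag([1.0, -1.0])
        _, _, ss = procrustes(X, Y)
        assert ss <= 1e-10

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_best_fit_residual_matches_numeric_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(5, 2))
        Y = rng.normal(size=(5, 2))
        _, _, ss = procrustes(X, Y, scaling="best-fit")
        assert ss == pytest.approx(_oracle_procrustes_ss(X, Y), abs=1e-6)

    def test_rotation_is_orthogonal_and_transform_consistent(self, rng):
        X = rng.normal(size=(6, 2))
        Y = rng.normal(size=(6, 2))
        transform, fitted, _ = procrustes(X, Y, scaling="best-fit")
        R = transform.rotation
        assert np.allclose(R.T @ R, np.eye(2), atol=1e-10)
        assert abs(abs(np.linalg.det(R)) - 1.0) < 1e-10
        # applying the transform reproduces the fitted configuration
        assert np.allclose(transform.apply(Y) - X.mean(axis=0), fitted, atol=1e-10)

    def test_degenerate_configuration_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            procrustes(np.zeros((4, 2)), np.ones((4, 2)))

    def test_matches_scipy_disparity(self, rng):
        from scipy.spatial import procrustes as scipy_procrustes

        X = rng.normal(size=(8, 2))
        Y = rng.normal(size=(8, 2))
        _, _, ss = procrustes(X, Y, scaling="symmetric")
        _, _, disparity = scipy_procrustes(X, Y)
        assert ss == pytest.approx(disparity, abs=1e-10)


class TestProtest:
    def test_perfect_fit_has_unit_concordance_and_small_p(self, rng):
        X = rng.normal(size=(10, 2))
        Y = 0.5 * X @ _rot(1.1) + 4.0
        res = protest(X, Y, n_permutations=999, seed=0)
        assert res.concordance == pytest.approx(1.0, abs=1e-10)
        assert res.p_value <= 0.01

    def test_concordance_invariant_under_independent_similarities(self, rng):
        X = rng.normal(size=(8, 2))
        Y = rng.normal(size=(8, 2))
        base = protest(X, Y, 9, 0).concordance
        X2 = 3.0 * X @ _rot(0.3) - 2.0
        Y2 = 0.2 * Y @ (_rot(2.0) @ np.diag([1, -1])) + 11.0
        assert protest(X2, Y2, 9, 0).concordance == pytest.approx(base, abs=1e-10)

    def test_three_point_p_matches_enumeration(self, rng):
        X = rng.normal(size=(3, 2))
        Y = rng.normal(size=(3, 2))
        res = protest(X, Y, n_permutations=999, seed=5)
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        Xs = Xc / np.linalg.norm(Xc)
        Ys = Yc / np.linalg.norm(Yc)
        stats = []
        for perm in permutations(range(3)):
            s = np.linalg.svd(Ys[list(perm)].T @ Xs, compute_uv=False)
            stats.append(min(s.sum() ** 2, 1.0))
        p_exact = np.mean(np.asarray(stats) >= stats[0] - 1e-12)
        se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert res.concordance == pytest.approx(stats[0], abs=1e-12)
        assert res.p_value == pytest.approx(p_exact, abs=max(3 * se, 0.02))

    def test_degenerate_configuration_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            protest(np.ones((4, 2)), np.ones((4, 2)))
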