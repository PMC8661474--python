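"""Spearman matrix, partial correlations and non-rejection rates."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from nrrnet import (
    NRRConfig,
    ValidationError,
    nonrejection_rate,
    nrr_histogram,
    nrr_matrix,
    partial_correlation,
    spearman_matrix,
)
from nrrnet.association import NRRMatrix, _partials_from_corr


# ---------------------------------------------------------------------------
# independent brute-force oracle


def oracle_partial(data, i, j, Q):
    """Regression-residual definition of the partial correlation."""
    X = np.column_stack([np.ones(data.shape[0])] + [data[:, q] for q in Q])
    ri = data[:, i] - X @ np.linalg.lstsq(X, data[:, i], rcond=None)[0]
    rj = data[:, j] - X @ np.linalg.lstsq(X, data[:, j], rcond=None)[0]
    return float(np.corrcoef(ri, rj)[0, 1])


def oracle_nrr_exhaustive(data, i, j, orders, alpha):
    """Average of Fisher-z non-rejection indicators over ALL conditioning sets."""
    n, p = data.shape
    crit = stats.norm.ppf(1 - alpha / 2)
    others = [k for k in range(p) if k not in (i, j)]
    decisions = []
    for q in orders:
        for Q in itertools.combinations(others, q):
            r = oracle_partial(data, i, j, Q)
            if abs(r) >= 1 or not math.isfinite(r):
                decisions.append(False)
            else:
                z = math.sqrt(n - q - 3) * math.atanh(r)
                decisions.append(abs(z) <= crit)
    return decisions


class TestSpearman:
    def test_monotone_columns(self):
        data = np.column_stack([[1, 2, 3], [10, 20, 30], [3, 2, 1]])
        rho = spearman_matrix(data).rho
        assert rho[0, 1] == pytest.approx(1.0)
        assert rho[0, 2] == pytest.approx(-1.0)

    def test_classical_d2_formula(self):
        data = np.column_stack([[1, 2, 3, 4, 5], [2, 1, 4, 3, 5]])
        assert spearman_matrix(data).rho[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_equals_scipy_spearmanr(self, rng):
        data = rng.standard_normal((15, 5))
        data[3, 2] = data[4, 2]  # introduce a tie
        rho = spearman_matrix(data).rho
        ref = stats.spearmanr(data).statistic
        np.testing.assert_allclose(rho, ref, atol=1e-12)

    def test_constant_column_zeroed(self, caplog):
        data = np.column_stack([[1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4], [4, 2, 1, 3]])
        with caplog.at_level("WARNING"):
            rho = spearman_matrix(data).rho
        assert rho[0, 1] == 0.0 and rho[0, 2] == 0.0 and rho[0, 0] == 1.0

    def test_invariants(self, rng):
        rho = spearman_matrix(rng.standard_normal((10, 6))).rho
        np.testing.assert_allclose(rho, rho.T)
        np.testing.assert_allclose(np.diag(rho), 1.0)
        assert (np.abs(rho) <= 1).all()


class TestPartialCorrelation:
    def test_zero_order_is_pearson(self, rng):
        data = rng.standard_normal((30, 4))
        got = partial_correlation(data, 0, 2, [])
        assert got == pytest.approx(np.corrcoef(data[:, 0], data[:, 2])[0, 1], abs=1e-12)

    def test_equicorrelated_closed_form(self):
        corr = np.full((3, 3), 0.5)
        np.fill_diagonal(corr, 1.0)
        idx = np.array([[0, 1, 2]])
        r = _partials_from_corr(corr, idx)[0]
        assert r == pytest.approx(1 / 3, abs=1e-12)

    def test_matches_regression_residual_identity(self, rng):
        data = rng.standard_normal((40, 6))
        for Q in ([3], [2, 4], [2, 3, 5]):
            got = partial_correlation(data, 0, 1, Q)
            assert got == pytest.approx(oracle_partial(data, 0, 1, Q), abs=1e-10)

    def test_validates_arguments(self, rng):
        data = rng.standard_normal((10, 4))
        with pytest.raises(ValidationError):
            partial_correlation(data, 1, 1, [])
        with pytest.raises(ValidationError):
            partial_correlation(data, 0, 1, [0])
        with pytest.raises(ValidationError):
            partial_correlation(rng.standard_normal((5, 4)), 0, 1, [2, 3])

    def test_singular_submatrix_errors(self, rng):
        data = rng.standard_normal((20, 4))
        data[:, 3] = data[:, 2]  # exact collinearity in the conditioning set
        with pytest.raises(ValidationError, match="singular"):
            partial_correlation(data, 0, 1, [2, 3])


class TestNonRejectionRate:
    def test_exact_copy_always_rejected(self, rng):
        data = rng.standard_normal((30, 6))
        data[:, 1] = 2.0 * data[:, 0] + 1.0
        cfg = NRRConfig(mode="exhaustive", q_policy="fixed", q=1, seed=0)
        assert nonrejection_rate(data, 0, 1, cfg) == 0.0

    def test_exhaustive_equals_bruteforce(self, rng):
        """Exhaustive mode reproduces the enumeration oracle decision-for-decision."""
        data = rng.standard_normal((40, 8))
        data[:, 1] += 0.8 * data[:, 0]
        cfg = NRRConfig(mode="exhaustive", q_policy="uniform", q_max=2, seed=0)
        for (i, j) in [(0, 1), (2, 5), (3, 7)]:
            expected = oracle_nrr_exhaustive(data, i, j, [1, 2], cfg.alpha)
            assert nonrejection_rate(data, i, j, cfg) == pytest.approx(
                np.mean(expected), abs=1e-12
            )

    def test_null_calibration_quick(self, rng):
        """Under iid Gaussian data the mean NRR sits near 1 - alpha."""
        vals = []
        for s in range(3):
            data = np.random.default_rng(100 + s).standard_normal((100, 8))
            cfg = NRRConfig(q_policy="fixed", q=1, n_tests=50, seed=s)
            m = nrr_matrix(data, cfg)
            vals.append(np.nanmean(m.nrr))
        assert 0.90 <= np.mean(vals) <= 0.99

    def test_config_validation(self, rng):
        data = rng.standard_normal((10, 5))
        with pytest.raises(ValidationError, match="infeasible"):
            nonrejection_rate(data, 0, 1, NRRConfig(q_policy="fixed", q=8))
        with pytest.raises(ValidationError):
            NRRConfig(alpha=1.5)
        with pytest.raises(ValidationError):
            NRRConfig(q_policy="fixed")  # fixed policy needs q


class TestNRRMatrix:
    def test_two_features(self, rng):
        data = rng.standard_normal((20, 3))
        m = nrr_matrix(data, NRRConfig(q_policy="fixed", q=1, n_tests=20, seed=1))
        assert np.isnan(m.nrr[0, 0])
        assert m.nrr[0, 1] == m.nrr[1, 0]

    def test_same_seed_identical(self, rng):
        data = rng.standard_normal((25, 6))
        cfg = NRRConfig(n_tests=30, seed=7)
        m1 = nrr_matrix(data, cfg)
        m2 = nrr_matrix(data, cfg)
        np.testing.assert_array_equal(m1.nrr, m2.nrr)

    def test_affine_rescaling_invariance(self, rng):
        data = rng.standard_normal((30, 5))
        cfg = NRRConfig(n_tests=40, seed=3)
        m1 = nrr_matrix(data, cfg)
        m2 = nrr_matrix(data * [2.0, 0.5, 10.0, 1.0, 3.0] + [1, -2, 0, 5, 7], cfg)
        np.testing.assert_allclose(m1.nrr, m2.nrr)

    def test_permutation_equivariance_exhaustive(self, rng):
        data = rng.standard_normal((20, 5))
        cfg = NRRConfig(mode="exhaustive", q_policy="fixed", q=1, seed=0)
        m = nrr_matrix(data, cfg).nrr
        perm = np.array([3, 1, 4, 0, 2])
        mp = nrr_matrix(data[:, perm], cfg).nrr
        np.testing.assert_allclose(mp, m[np.ix_(perm, perm)])

    def test_strong_direct_edge_low_nrr(self):
        rng = np.random.default_rng(42)
        z = rng.standard_normal((39, 1))
        data = np.hstack([z, 0.8 * z + 0.4 * rng.standard_normal((39, 1)),
                          rng.standard_normal((39, 8))])
        cfg = NRRConfig(n_tests=100, q_max=3, seed=5)
        m = nrr_matrix(data, cfg)
        assert m.nrr[0, 1] <= 0.1


class TestHistogram:
    def test_counts_conserved(self, rng):
        p = 9
        vals = rng.random((p, p))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, np.nan)
        h = nrr_histogram(NRRMatrix([f"f{i}" for i in range(p)], vals), n_bins=10)
        assert h["count"].sum() == p * (p - 1) // 2

    def test_point_mass_single_bin(self):
        p = 4
        vals = np.full((p, p), 0.5)
        np.fill_diagonal(vals, np.nan)
        h = nrr_histogram(NRRMatrix([f"f{i}" for i in range(p)], vals), n_bins=10)
        assert (h["count"] > 0).sum() == 1
        assert h.loc[h["count"] > 0, "bin_low"].iloc[0] == 0.5

    def test_bin_edges_uniform(self):
        vals = np.full((3, 3), 0.25)
        np.fill_diagonal(vals, np.nan)
        h = nrr_histogram(NRRMatrix(["a", "b", "c"], vals), n_bins=4)
        np.testing.assert_allclose(h["bin_low"], [0, 0.25, 0.5, 0.75])
        np.testing.assert_allclose(h["bin_high"], [0.25, 0.5, 0.75, 1.0])
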