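"""Tetrachoric estimation and PCA communalities."""

import numpy as np
import pytest
from scipy import stats

from scdpaf.communality import (
    DegenerateRetentionError,
    TetrachoricCommunality,
    TetrachoricMatrix,
    communalities,
    tetrachoric_matrix,
    weighted_tetrachoric,
)

from conftest import bivariate_binary_sample


def grid_oracle_rho(w11, w10, w01, w00, nodes=96):
    """Brute-force tetrachoric oracle, independent of the estimator: the
    orthant mass P(X>h, Y>k; rho) is evaluated by Gauss-Legendre
    integration of the conditional-normal decomposition on a dense rho
    grid, and the (monotone) crossing with the observed joint proportion
    is linearly interpolated."""
    tot = w11 + w10 + w01 + w00
    px, py, p11 = (w11 + w10) / tot, (w11 + w01) / tot, w11 / tot
    h, k = stats.norm.ppf(1 - px), stats.norm.ppf(1 - py)
    xs, ws = np.polynomial.legendre.leggauss(nodes)
    x = (xs + 1) / 2 * 10.0 + h
    w = ws * 5.0 * stats.norm.pdf(x)
    grid = np.linspace(-0.999, 0.999, 2001)
    z = (k - grid[:, None] * x[None, :]) / np.sqrt(1 - grid[:, None] ** 2)
    vals = (w[None, :] * stats.norm.sf(z)).sum(axis=1) - p11
    if vals[0] >= 0:
        return grid[0]
    if vals[-1] <= 0:
        return grid[-1]
    i = int(np.searchsorted(vals > 0, True))
    r0, r1, v0, v1 = grid[i - 1], grid[i], vals[i - 1], vals[i]
    return r0 + (0 - v0) / (v1 - v0) * (r1 - r0)


class TestWeightedTetrachoric:
    def test_independence_gives_zero(self):
        # joint mass equal to product of margins, encoded as weights
        x = np.array([1, 1, 0, 0], float)
        y = np.array([1, 0, 1, 0], float)
        w = np.array([0.12, 0.28, 0.18, 0.42])  # px=0.4, py=0.3, p11=px*py
        assert weighted_tetrachoric(x, y, w) == pytest.approx(0.0, abs=1e-6)

    def test_perfect_concordance_clips_at_one(self):
        x = np.array([1, 1, 0, 0], float)
        assert weighted_tetrachoric(x, x.copy()) == pytest.approx(1.0, abs=1e-5)

    def test_degenerate_margin_errors(self):
        with pytest.raises(ValueError):
            weighted_tetrachoric(np.ones(4), np.array([1, 0, 1, 0], float))

    def test_recovers_latent_correlation(self, rng):
        x, y = bivariate_binary_sample(rng, 100_000, rho=0.5, px=0.3, py=0.2)
        assert weighted_tetrachoric(x, y) == pytest.approx(0.5, abs=0.02)

    def test_matches_grid_oracle_on_random_tables(self, rng):
        for _ in range(8):
            cells = rng.uniform(0.5, 30.0, size=4)
            n = 40
            x = np.repeat([1, 1, 0, 0], n // 4).astype(float)
            y = np.repeat([1, 0, 1, 0], n // 4).astype(float)
            w = np.repeat(cells, n // 4) / (n // 4)
            est = weighted_tetrachoric(x, y, w)
            assert est == pytest.approx(grid_oracle_rho(*cells), abs=1e-3)

    def test_zero_cell_continuity_correction(self):
        # one empty cell: estimate is finite and inside the open interval
        x = np.array([1, 1, 0, 0, 0], float)
        y = np.array([1, 1, 1, 0, 0], float)
        r = weighted_tetrachoric(x, y)
        assert -1 < r < 1 and r > 0.5  # strong but not perfect association


class TestTetrachoricMatrix:
    def test_two_factors_match_pairwise_value(self, rng):
        x, y = bivariate_binary_sample(rng, 20_000, rho=0.4, px=0.4, py=0.3)
        m = tetrachoric_matrix({"a": x, "b": y}, ["a", "b"])
        assert m.rho[0, 1] == pytest.approx(weighted_tetrachoric(x, y), abs=1e-12)
        assert m.rho.shape == (2, 2)

    def test_independent_factors_near_zero(self, rng):
        data = {f"f{i}": (rng.random(30_000) < 0.3).astype(float) for i in range(4)}
        m = tetrachoric_matrix(data, list(data))
        off = m.rho[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_pairwise_complete_counts(self, rng):
        x = (rng.random(1000) < 0.4).astype(float)
        y = (rng.random(1000) < 0.4).astype(float)
        y[:300] = np.nan
        m = tetrachoric_matrix({"a": x, "b": y}, ["a", "b"])
        assert m.pair_n[0, 1] == 700

    def test_known_matrix_recovery(self, rng):
        """9-factor one-common-factor structure recovered elementwise."""
        from scdpaf.synthetic import one_factor_latent_corr

        comm = np.linspace(0.3, 0.7, 9)
        R = one_factor_latent_corr(comm)
        L = np.linalg.cholesky(R)
        z = rng.standard_normal((60_000, 9)) @ L.T
        p = np.linspace(0.1, 0.5, 9)
        data = {
            f"f{i}": (z[:, i] > stats.norm.ppf(1 - p[i])).astype(float)
            for i in range(9)
        }
        m = tetrachoric_matrix(data, list(data))
        assert np.abs(m.rho - R).max() < 0.04


class TestCommunalities:
    def _equicorr(self, p=9, rho=0.5):
        m = np.full((p, p), rho)
        np.fill_diagonal(m, 1.0)
        return TetrachoricMatrix(
            factors=[f"f{i}" for i in range(p)], rho=m,
            pair_n=np.ones((p, p)), pair_weight=np.ones((p, p)),
        )

    def test_equicorrelation_closed_form(self):
        cs = communalities(self._equicorr())
        assert cs.n_retained == 1
        assert np.allclose(cs.communality, 5.0 / 9.0, atol=1e-12)
        assert cs.eigenvalues[0] == pytest.approx(5.0)

    def test_identity_matrix_degenerate_under_kaiser(self):
        m = self._equicorr(rho=0.0)
        with pytest.raises(DegenerateRetentionError):
            communalities(m)

    def test_retain_all_gives_unit_communality(self):
        cs = communalities(self._equicorr(), retention=9)
        assert np.allclose(cs.communality, 1.0, atol=1e-10)

    def test_sum_equals_retained_eigenvalues(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((9, 3))
        m = a @ a.T + np.eye(9)
        d = 1 / np.sqrt(np.diag(m))
        m = m * np.outer(d, d)
        tm = TetrachoricMatrix(
            factors=[f"f{i}" for i in range(9)], rho=m,
            pair_n=np.ones((9, 9)), pair_weight=np.ones((9, 9)),
        )
        cs = communalities(tm)
        assert cs.communality.sum() == pytest.approx(
            cs.eigenvalues[: cs.n_retained].sum(), rel=1e-10
        )

    def test_permutation_equivariance(self, rng):
        a = rng.standard_normal((6, 2))
        m = a @ a.T + np.eye(6)
        d = 1 / np.sqrt(np.diag(m))
        m = m * np.outer(d, d)
        perm = rng.permutation(6)
        tm1 = TetrachoricMatrix(
            factors=[f"f{i}" for i in range(6)], rho=m,
            pair_n=np.ones((6, 6)), pair_weight=np.ones((6, 6)),
        )
        tm2 = TetrachoricMatrix(
            factors=[f"f{i}" for i in perm], rho=m[np.ix_(perm, perm)],
            pair_n=np.ones((6, 6)), pair_weight=np.ones((6, 6)),
        )
        c1 = communalities(tm1).as_dict()
        c2 = communalities(tm2).as_dict()
        for k in c1:
            assert c1[k] == pytest.approx(c2[k], abs=1e-10)


class TestEstimator:
    def test_weighted_reduces_to_unweighted(self, rng):
        x, y = bivariate_binary_sample(rng, 5000, rho=0.6, px=0.4, py=0.35)
        z, _ = bivariate_binary_sample(rng, 5000, rho=0.0, px=0.3, py=0.3)
        import pandas as pd

        df = pd.DataFrame({"a": x, "b": y, "c": z})
        e1 = TetrachoricCommunality(retention=1).fit(df)
        e2 = TetrachoricCommunality(retention=1).fit(df, sample_weight=np.full(5000, 3.7))
        assert np.allclose(e1.rho_, e2.rho_, atol=1e-12)
        assert np.allclose(e1.communalities_, e2.communalities_, atol=1e-12)

    def test_sklearn_param_interface(self):
        est = TetrachoricCommunality(retention=2)
        assert est.get_params()["retention"] == 2
        est.set_params(retention="kaiser")
        assert est.retention == "kaiser"

    def test_generator_truth_communalities_recovered(self, rng):
        """Sampling from the paper-like latent structure recovers the
        structure's own PCA communalities."""
        from scdpaf.communality import communalities as comm_of
        from scdpaf.synthetic import one_factor_latent_corr

        comm_target = np.array([0.66, 0.40, 0.71, 0.56, 0.64, 0.40, 0.59, 0.58, 0.58])
        R = one_factor_latent_corr(comm_target)
        truth = comm_of(
            TetrachoricMatrix(
                factors=[f"f{i}" for i in range(9)], rho=R,
                pair_n=np.ones((9, 9)), pair_weight=np.ones((9, 9)),
            )
        ).communality
        L = np.linalg.cholesky(R)
        z = rng.standard_normal((100_000, 9)) @ L.T
        p = np.array([0.05, 0.10, 0.52, 0.19, 0.15, 0.31, 0.33, 0.51, 0.18])
        import pandas as pd

        df = pd.DataFrame(
            {f"f{i}": (z[:, i] > stats.norm.ppf(1 - p[i])).astype(float)
             for i in range(9)}
        )
        est = TetrachoricCommunality().fit(df)
        assert np.abs(est.communalities_ - truth).max() < 0.05
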