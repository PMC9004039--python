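"""Weighted tetrachoric correlations and PCA communalities.

The tetrachoric correlation of two binary indicators is the correlation
of the latent bivariate normal assumed to underlie them: thresholds are
the inverse-normal of the (weighted) margins and rho is the value at
which the bivariate-normal orthant mass equals the weighted joint
proportion.  Communality is the shared-variance fraction of each factor
from a principal component analysis of the tetrachoric matrix: the sum
of squared loadings over the retained components (Kaiser rule by
default: eigenvalue > 1).

By design only the survey weights enter these estimates - no strata or
clusters - matching how communality is computed in the attributable-
fraction literature this package supports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "weighted_tetrachoric",
    "tetrachoric_matrix",
    "communalities",
    "TetrachoricMatrix",
    "CommunalitySet",
    "TetrachoricCommunality",
    "DegenerateRetentionError",
]

RHO_CLIP = 1.0 - 1e-6


class DegenerateRetentionError(ValueError):
    """Raised when the retention rule keeps no component."""


def _bvn_upper_orthant(h: float, k: float, rho: float) -> float:
    """P(X > h, Y > k) for standard bivariate normal with correlation rho."""
    # P(X>h, Y>k) = 1 - Phi(h) - Phi(k) + Phi2(h, k)
    mvn = stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]], allow_singular=True
    )
    return 1.0 - stats.norm.cdf(h) - stats.norm.cdf(k) + float(mvn.cdf([h, k]))


def weighted_tetrachoric(
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    zero_cell_correction: float = 0.5,
) -> float:
    """Maximum-likelihood tetrachoric correlation of two weighted binaries.

    Pairs with a missing value in either variable are dropped.  If any of
    the four weighted cells is empty, ``zero_cell_correction`` times the
    mean weight is added to every cell (the standard continuity
    correction) before solving.  The estimate is clipped to
    ``+/-(1 - 1e-6)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    d = ~(np.isnan(x) | np.isnan(y))
    if not d.any():
        raise ValueError("no pairwise-complete observations")
    x, y, w = x[d], y[d], w[d]
    xb, yb = x.astype(bool), y.astype(bool)

    cells = np.array(
        [
            w[xb & yb].sum(),
            w[xb & ~yb].sum(),
            w[~xb & yb].sum(),
            w[~xb & ~yb].sum(),
        ]
    )
    if (cells[0] + cells[1]) == 0 or (cells[2] + cells[3]) == 0 \
            or (cells[0] + cells[2]) == 0 or (cells[1] + cells[3]) == 0:
        raise ValueError("a margin is all-0 or all-1; tetrachoric undefined")
    # perfect concordance/discordance attains the boundary; sporadic zero
    # cells get the continuity correction instead
    if cells[1] == 0 and cells[2] == 0:
        return RHO_CLIP
    if cells[0] == 0 and cells[3] == 0:
        return -RHO_CLIP
    if np.any(cells == 0):
        cells = cells + zero_cell_correction * w.mean()
    tot = cells.sum()
    px = (cells[0] + cells[1]) / tot  # P(x=1)
    py = (cells[0] + cells[2]) / tot
    p11 = cells[0] / tot

    h = stats.norm.ppf(1.0 - px)
    k = stats.norm.ppf(1.0 - py)

    def g(rho: float) -> float:
        return _bvn_upper_orthant(h, k, rho) - p11

    lo, hi = -RHO_CLIP, RHO_CLIP
    glo, ghi = g(lo), g(hi)
    # orthant mass is increasing in rho; handle boundary attainment
    if glo >= 0:
        return lo
    if ghi <= 0:
        return hi
    rho = optimize.brentq(g, lo, hi, xtol=1e-10)
    return float(np.clip(rho, -RHO_CLIP, RHO_CLIP))


@dataclass
class TetrachoricMatrix:
    factors: list[str]
    rho: np.ndarray
    pair_n: np.ndarray
    pair_weight: np.ndarray
    psd_repaired: bool = False


def _nearest_psd(a: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped PSD repair, rescaled back to unit diagonal."""
    vals, vecs = np.linalg.eigh(a)
    if vals.min() >= 0:
        return a
    vals = np.clip(vals, eps, None)
    b = (vecs * vals) @ vecs.T
    dinv = 1.0 / np.sqrt(np.diag(b))
    return b * np.outer(dinv, dinv)


def tetrachoric_matrix(
    records,
    factors: list[str],
    weights: np.ndarray | None = None,
    zero_cell_correction: float = 0.5,
) -> TetrachoricMatrix:
    """Pairwise-complete weighted tetrachoric matrix of several factors.

    ``records`` is a DataFrame (or dict of arrays) of {0, 1, NaN} columns.
    Pairs are estimated on pairwise-complete cases (factor availability
    differs by survey year); the result is symmetrized by construction
    and repaired to the nearest unit-diagonal PSD matrix if an eigenvalue
    is negative (flagged on the result).
    """
    if len(factors) < 2:
        raise ValueError("need at least two factors")
    cols = {f: np.asarray(records[f], dtype=float) for f in factors}
    n = len(next(iter(cols.values())))
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    p = len(factors)
    rho = np.eye(p)
    pair_n = np.zeros((p, p), dtype=int)
    pair_w = np.zeros((p, p))
    failures = []
    for i in range(p):
        pair_n[i, i] = int((~np.isnan(cols[factors[i]])).sum())
        for j in range(i + 1, p):
            xi, xj = cols[factors[i]], cols[factors[j]]
            d = ~(np.isnan(xi) | np.isnan(xj))
            pair_n[i, j] = pair_n[j, i] = int(d.sum())
            pair_w[i, j] = pair_w[j, i] = float(w[d].sum())
            try:
                r = weighted_tetrachoric(
                    xi, xj, w, zero_cell_correction=zero_cell_correction
                )
            except ValueError:
                failures.append((factors[i], factors[j]))
                continue
            rho[i, j] = rho[j, i] = r
    if failures:
        raise ValueError(f"tetrachoric undefined for pairs: {failures}")
    repaired = np.linalg.eigvalsh(rho).min() < 0
    if repaired:
        rho = _nearest_psd(rho)
    return TetrachoricMatrix(
        factors=list(factors), rho=rho, pair_n=pair_n,
        pair_weight=pair_w, psd_repaired=repaired,
    )


@dataclass
class CommunalitySet:
    factors: list[str]
    communality: np.ndarray
    eigenvalues: np.ndarray  # descending
    n_retained: int
    retention_rule: str
    loadings: np.ndarray  # p x n_retained

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.factors, self.communality))


def communalities(
    matrix: TetrachoricMatrix,
    retention: str | int = "kaiser",
) -> CommunalitySet:
    """PCA communalities of a correlation matrix.

    Components are retained by the Kaiser rule (eigenvalue > 1) or, if an
    integer is given, as a fixed count.  The communality of factor i is
    the sum over retained components of its squared loading, where the
    loading is eigenvector element times sqrt(eigenvalue).
    """
    rho = matrix.rho
    vals, vecs = np.linalg.eigh(rho)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if retention == "kaiser":
        m = int((vals > 1.0).sum())
        rule = "kaiser"
        if m == 0:
            raise DegenerateRetentionError(
                "Kaiser rule retains no component (largest eigenvalue "
                f"{vals[0]:.4f} <= 1, e.g. mutually independent factors); "
                "pass a fixed component count instead"
            )
    else:
        m = int(retention)
        rule = f"fixed-{m}"
        if m < 1 or m > len(vals):
            raise DegenerateRetentionError(f"cannot retain {m} components")
    load = vecs[:, :m] * np.sqrt(np.clip(vals[:m], 0.0, None))
    comm = (load**2).sum(axis=1)
    comm = np.clip(comm, 0.0, 1.0)
    return CommunalitySet(
        factors=list(matrix.factors), communality=comm, eigenvalues=vals,
        n_retained=m, retention_rule=rule, loadings=load,
    )


class TetrachoricCommunality(BaseEstimator):
    """Estimator chaining the weighted tetrachoric matrix and PCA.

    Parameters
    ----------
    retention : "kaiser" or int, default "kaiser"
        Component-retention rule for the communalities.
    zero_cell_correction : float, default 0.5
        Continuity-correction mass (times the mean weight) added to every
        cell of a 2x2 with an empty cell.

    Attributes (after :meth:`fit`)
    ------------------------------
    rho_ : (p, p) tetrachoric correlation matrix
    eigenvalues_ : descending eigenvalues of ``rho_``
    communalities_ : per-factor shared-variance fractions
    n_components_ : number of retained components
    feature_names_in_ : factor names
    """

    def __init__(self, retention="kaiser", zero_cell_correction: float = 0.5):
        self.retention = retention
        self.zero_cell_correction = zero_cell_correction

    def fit(self, X, y=None, sample_weight=None):
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            data = X
        else:
            X = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(X.shape[1])]
            data = {n: X[:, i] for i, n in enumerate(names)}
        mat = tetrachoric_matrix(
            data, names, weights=sample_weight,
            zero_cell_correction=self.zero_cell_correction,
        )
        cset = communalities(mat, retention=self.retention)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)
        self.matrix_ = mat
        self.rho_ = mat.rho
        self.eigenvalues_ = cset.eigenvalues
        self.communalities_ = cset.communality
        self.loadings_ = cset.loadings
        self.n_components_ = cset.n_retained
        self.result_ = cset
        return self
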