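"""Relative risks for a binary outcome under a complex survey design.

Two routes are provided, matching the two ways a survey analyst obtains
a relative risk:

* :func:`unadjusted_rr` - the ratio of weighted risks from a 2x2 table,
  with a design-based (Taylor-linearized) CI for log RR.
* :class:`ModifiedPoissonRR` / :func:`adjusted_rr` - modified Poisson
  regression: a log-link working-Poisson model of the binary outcome
  with survey weights, whose exponentiated coefficients are relative
  risks; variances come from a cluster-robust sandwich aggregated to
  PSUs within strata.  The log-binomial family is available behind the
  ``family`` switch but fails to converge far more often at common
  exposure prevalences, which is why modified Poisson is the default.

Covariates are entered as reference-coded dummies with each covariate's
most frequent category as the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .survey import SurveyDesign, Weighted2x2, weighted_2x2

__all__ = [
    "RREstimate",
    "ModifiedPoissonRR",
    "unadjusted_rr",
    "adjusted_rr",
    "stratified_rr",
    "interaction_test",
    "ConvergenceError",
]

Z95 = float(stats.norm.ppf(0.975))


class ConvergenceError(RuntimeError):
    """Raised when the risk regression fails to converge."""


@dataclass(frozen=True)
class RREstimate:
    factor: str
    rr: float
    ci_low: float
    ci_high: float
    log_se: float
    model: str  # "weighted_2x2" or "modified_poisson"
    adjustment: tuple[str, ...] = ()
    n_analytic: int = 0
    stratum: str = "all"
    one_sided: bool = False

    def __post_init__(self):
        if not self.one_sided and not (self.ci_low <= self.rr <= self.ci_high):
            raise ValueError("CI does not bracket the point estimate")


def unadjusted_rr(table: Weighted2x2, factor: str = "", stratum: str = "all") -> RREstimate:
    """Risk ratio from weighted 2x2 masses with a linearized log-RR CI.

    ``rr = (w11/(w11+w10)) / (w01/(w01+w00))``.  A zero case cell with
    positive margin yields rr 0 or inf with a one-sided CI flag; both
    risks zero is undefined and raises.
    """
    m1 = table.w11 + table.w10
    m0 = table.w01 + table.w00
    if m1 <= 0 or m0 <= 0:
        raise ValueError("an exposure margin has no mass")
    r1 = table.w11 / m1
    r0 = table.w01 / m0
    if r1 == 0 and r0 == 0:
        raise ValueError("relative risk undefined: no cases in either arm")
    if r1 == 0 or r0 == 0:
        rr = 0.0 if r1 == 0 else np.inf
        return RREstimate(
            factor=factor, rr=rr, ci_low=0.0, ci_high=np.inf,
            log_se=np.nan, model="weighted_2x2",
            n_analytic=table.n11 + table.n10 + table.n01 + table.n00,
            stratum=stratum, one_sided=True,
        )
    rr = r1 / r0
    # linearized score of log rr = log(A/m1) - log(B/m0)
    x, y, d = table.exposure, table.outcome, table.domain
    w = table.design.weights
    xb = np.where(d, x, 0.0)
    yb = np.where(d, y, 0.0)
    A = table.w11
    B = table.w01
    # influence of obs i on log rr: z_i = w d [ x(y - r1)/A - (1-x)(y - r0)/B ]
    z = w * d * (xb * (yb - r1) / A - (1 - xb) * (yb - r0) / B)
    var = table.design.linearized_covariance(z)
    se = float(np.sqrt(max(var, 0.0)))
    return RREstimate(
        factor=factor, rr=float(rr),
        ci_low=float(rr * np.exp(-Z95 * se)),
        ci_high=float(rr * np.exp(Z95 * se)),
        log_se=se, model="weighted_2x2",
        n_analytic=table.n11 + table.n10 + table.n01 + table.n00,
        stratum=stratum,
    )


def _reference_code(records: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Dummy-code categoricals dropping each one's most frequent level."""
    parts = []
    for c in covariates:
        s = records[c]
        if s.dtype.kind in "fiu" and s.nunique(dropna=True) > 12:
            parts.append(s.astype(float).rename(c).to_frame())
            continue
        ref = s.mode(dropna=True).iloc[0]
        dums = pd.get_dummies(s.astype("category"), prefix=c, dtype=float)
        dums = dums.drop(columns=[f"{c}_{ref}"])
        parts.append(dums)
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=records.index)


def _design_sandwich(
    X: np.ndarray, resid_score: np.ndarray, info: np.ndarray, design: SurveyDesign
) -> np.ndarray:
    """Cluster-robust covariance: bread from the information, meat from
    stratified between-PSU score totals."""
    bread = np.linalg.inv(info)
    meat = design.linearized_covariance(resid_score)
    return bread @ meat @ bread


class ModifiedPoissonRR(BaseEstimator):
    """Log-link risk regression with design-based sandwich variance.

    Scikit-learn estimator interface: ``fit(X, y, sample_weight=...,
    strata=..., psu=...)`` where ``X`` is a numeric design matrix
    (DataFrame columns become coefficient names; an intercept is added).
    Exponentiated coefficients are relative risks.

    Parameters
    ----------
    family : {"poisson", "binomial"}
        Working family; "poisson" (default) is the modified Poisson
        estimator, "binomial" the log-binomial model.
    alpha : float, default 0.05
        CI level is ``1 - alpha`` (Wald, on the log scale).

    Attributes
    ----------
    params_, cov_, bse_ : coefficient vector, covariance, SEs (log scale)
    rr_ : exponentiated coefficients
    conf_int_ : (k, 2) CI bounds on the RR scale
    feature_names_in_ : column names including "const"
    """

    def __init__(self, family: str = "poisson", alpha: float = 0.05,
                 max_iter: int = 200):
        self.family = family
        self.alpha = alpha
        self.max_iter = max_iter

    def fit(self, X, y, sample_weight=None, strata=None, psu=None):
        if isinstance(X, pd.DataFrame):
            names = ["const"] + list(X.columns)
            Xm = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
        else:
            X = np.asarray(X, dtype=float)
            names = ["const"] + [f"x{i}" for i in range(X.shape[1])]
            Xm = np.column_stack([np.ones(len(X)), X])
        y = np.asarray(y, dtype=float)
        n = len(y)
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        if strata is None:
            strata = np.zeros(n, dtype=int)
        if psu is None:
            psu = np.arange(n)  # each respondent its own cluster
        design = SurveyDesign(np.asarray(strata), np.asarray(psu), w)

        if self.family == "poisson":
            fam = sm.families.Poisson(link=sm.families.links.Log())
        elif self.family == "binomial":
            fam = sm.families.Binomial(link=sm.families.links.Log())
        else:
            raise ValueError("family must be 'poisson' or 'binomial'")
        model = sm.GLM(y, Xm, family=fam, var_weights=w)
        try:
            res = model.fit(maxiter=self.max_iter, tol=1e-10)
        except Exception as exc:  # perfect separation, step failures
            raise ConvergenceError(f"risk regression failed: {exc}") from exc
        if not res.converged:
            raise ConvergenceError("risk regression did not converge")

        mu = res.fittedvalues
        if self.family == "poisson":
            # information X' diag(w mu) X; score_i = w (y - mu) x
            info = Xm.T @ (Xm * (w * mu)[:, None])
            score = (w * (y - mu))[:, None] * Xm
        else:
            v = mu * (1 - mu)
            deriv = mu  # d mu / d eta for log link
            wk = w * deriv**2 / np.clip(v, 1e-12, None)
            info = Xm.T @ (Xm * wk[:, None])
            score = (w * (y - mu) * deriv / np.clip(v, 1e-12, None))[:, None] * Xm
        cov = _design_sandwich(Xm, score, info, design)

        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = Xm.shape[1] - 1
        self.params_ = np.asarray(res.params)
        self.cov_ = cov
        self.bse_ = np.sqrt(np.diag(cov))
        self.rr_ = np.exp(self.params_)
        zq = stats.norm.ppf(1 - self.alpha / 2)
        self.conf_int_ = np.exp(
            np.column_stack(
                [self.params_ - zq * self.bse_, self.params_ + zq * self.bse_]
            )
        )
        self.n_obs_ = n
        self.design_df_ = design.variance_df
        self._result = res
        return self

    def predict(self, X):
        """Predicted outcome risk."""
        if isinstance(X, pd.DataFrame):
            Xm = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
        else:
            X = np.asarray(X, dtype=float)
            Xm = np.column_stack([np.ones(len(X)), X])
        return np.exp(Xm @ self.params_)

    def term_index(self, name: str) -> int:
        idx = np.where(self.feature_names_in_ == name)[0]
        if len(idx) == 0:
            raise KeyError(f"no coefficient named {name!r}")
        return int(idx[0])

    def wald_test(self, names: list[str]) -> tuple[float, int, float]:
        """Joint Wald chi-square test that the named coefficients are zero."""
        idx = [self.term_index(n) for n in names]
        b = self.params_[idx]
        C = self.cov_[np.ix_(idx, idx)]
        try:
            stat = float(b @ np.linalg.solve(C, b))
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"aliased interaction terms: {names}") from exc
        df = len(idx)
        return stat, df, float(stats.chi2.sf(stat, df))


def _complete_case(
    records: pd.DataFrame, cols: list[str]
) -> np.ndarray:
    mask = np.ones(len(records), dtype=bool)
    for c in cols:
        mask &= records[c].notna().to_numpy()
    return mask


def adjusted_rr(
    records: pd.DataFrame,
    factor: str,
    covariates: list[str],
    design: SurveyDesign,
    outcome: str = "scd",
    family: str = "poisson",
    stratum: str = "all",
) -> RREstimate:
    """Covariate-adjusted relative risk for one factor.

    Complete cases on the factor, outcome and covariates; categoricals
    reference-coded at their most frequent level; SEs from the stratified
    cluster sandwich.
    """
    cols = [factor, outcome] + list(covariates)
    mask = _complete_case(records, cols)
    if not mask.any():
        raise ValueError(f"no complete cases for factor {factor!r}")
    sub = records.loc[mask]
    d = design.subset(mask)
    Xcov = _reference_code(sub, list(covariates))
    X = pd.concat(
        [sub[factor].astype(float).rename(factor).to_frame(), Xcov], axis=1
    )
    est = ModifiedPoissonRR(family=family).fit(
        X, sub[outcome].to_numpy(float),
        sample_weight=d.weights, strata=d.strata, psu=d.psu,
    )
    i = est.term_index(factor)
    return RREstimate(
        factor=factor, rr=float(est.rr_[i]),
        ci_low=float(est.conf_int_[i, 0]), ci_high=float(est.conf_int_[i, 1]),
        log_se=float(est.bse_[i]), model="modified_poisson",
        adjustment=tuple(covariates), n_analytic=int(mask.sum()),
        stratum=stratum,
    )


def stratified_rr(
    records: pd.DataFrame,
    factor: str,
    covariates: list[str],
    design: SurveyDesign,
    stratifier: str,
    outcome: str = "scd",
    min_n: int = 50,
    family: str = "poisson",
) -> list[RREstimate]:
    """One adjusted RR per level of ``stratifier`` (excluded from the
    adjustment set).  Levels with fewer than ``min_n`` complete cases are
    skipped."""
    covs = [c for c in covariates if c != stratifier]
    out: list[RREstimate] = []
    for level in pd.unique(records[stratifier].dropna()):
        mask = (records[stratifier] == level).to_numpy()
        sub = records.loc[mask]
        cc = _complete_case(sub, [factor, outcome] + covs)
        if cc.sum() < min_n:
            continue
        out.append(
            adjusted_rr(
                sub, factor, covs, design.subset(mask),
                outcome=outcome, family=family, stratum=str(level),
            )
        )
    return out


@dataclass(frozen=True)
class InteractionTest:
    statistic: float
    df: int
    p_value: float
    cell_rrs: dict = field(default_factory=dict)


def interaction_test(
    records: pd.DataFrame,
    factor: str,
    modifier: str,
    covariates: list[str],
    design: SurveyDesign,
    outcome: str = "scd",
    family: str = "poisson",
) -> InteractionTest:
    """Joint Wald test of factor x modifier product terms.

    The model contains the factor, reference-coded modifier and covariate
    dummies, and one product term per non-reference modifier level; the
    test is the joint Wald chi-square on the product block with the
    design-based covariance.  Also reports the factor RR within each
    modifier level implied by the fitted coefficients.
    """
    if records[modifier].dropna().nunique() < 2:
        raise ValueError(f"modifier {modifier!r} is constant")
    cols = [factor, outcome, modifier] + list(covariates)
    mask = _complete_case(records, cols)
    sub = records.loc[mask]
    d = design.subset(mask)

    mod = sub[modifier]
    ref = mod.mode(dropna=True).iloc[0]
    mod_dums = pd.get_dummies(mod.astype("category"), prefix=modifier, dtype=float)
    mod_dums = mod_dums.drop(columns=[f"{modifier}_{ref}"])
    fvec = sub[factor].astype(float)
    inter = mod_dums.mul(fvec, axis=0)
    inter.columns = [f"{factor}:{c}" for c in mod_dums.columns]
    Xcov = _reference_code(sub, [c for c in covariates if c != modifier])
    X = pd.concat(
        [fvec.rename(factor).to_frame(), mod_dums, inter, Xcov], axis=1
    )
    est = ModifiedPoissonRR(family=family).fit(
        X, sub[outcome].to_numpy(float),
        sample_weight=d.weights, strata=d.strata, psu=d.psu,
    )
    stat, df, p = est.wald_test(list(inter.columns))
    base = est.params_[est.term_index(factor)]
    cell = {str(ref): float(np.exp(base))}
    for c in inter.columns:
        level = c.split(f"{factor}:{modifier}_", 1)[1]
        cell[level] = float(np.exp(base + est.params_[est.term_index(c)]))
    return InteractionTest(statistic=stat, df=df, p_value=p, cell_rrs=cell)


def rr_from_records(
    records: pd.DataFrame,
    factor: str,
    design: SurveyDesign,
    outcome: str = "scd",
    stratum: str = "all",
) -> RREstimate:
    """Convenience: complete-case weighted 2x2 then :func:`unadjusted_rr`."""
    t = weighted_2x2(
        records[factor].to_numpy(float), records[outcome].to_numpy(float), design
    )
    return unadjusted_rr(t, factor=factor, stratum=stratum)
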