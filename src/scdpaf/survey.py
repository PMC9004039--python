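"""Design-based estimation for stratified, clustered, weighted surveys.

Point estimates are Horvitz-Thompson ratio estimators; variances use
stratified between-PSU Taylor linearization, the standard complex-survey
estimator (what SAS's SURVEY procedures and R's `survey` package compute
by default).  Domain (subpopulation) analyses keep the full design and
zero the out-of-domain score contributions, so that PSUs with no domain
members still contribute their (zero) totals to the variance.

A stratum with a single PSU has no within-stratum degrees of freedom.
The default "adjust" policy centers such a stratum's PSU total at the
grand mean of PSU totals (mirroring ``options(survey.lonely.psu="adjust")``
in R); "fail" raises instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurveyDesign",
    "WeightedProportion",
    "Weighted2x2",
    "weighted_proportion",
    "weighted_2x2",
    "rao_scott_chisq",
    "scd_probability_by_age_sex",
    "EmptyDomainError",
    "LonelyPSUError",
]


class EmptyDomainError(ValueError):
    """Raised when an estimation domain contains no observations."""


class LonelyPSUError(ValueError):
    """Raised under the 'fail' policy when a stratum has a single PSU."""


@dataclass
class SurveyDesign:
    """Stratum / PSU / weight triplet shared by all estimators.

    ``strata`` and ``psu`` are per-respondent labels; PSU labels are
    interpreted within stratum (the variance estimator keys on the pair).
    Weights must be finite and strictly positive.
    """

    strata: np.ndarray
    psu: np.ndarray
    weights: np.ndarray
    lonely_psu: str = "adjust"

    def __post_init__(self) -> None:
        self.strata = np.asarray(self.strata)
        self.psu = np.asarray(self.psu)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.weights)
        if len(self.strata) != n or len(self.psu) != n:
            raise ValueError("strata, psu and weights must have equal length")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValueError("weights must be finite and > 0")
        if self.lonely_psu not in ("adjust", "fail"):
            raise ValueError("lonely_psu must be 'adjust' or 'fail'")
        # integer codes for fast groupbys
        self._strat_codes, self._strat_uniq = pd.factorize(self.strata)
        pair = pd.MultiIndex.from_arrays([self.strata, self.psu])
        self._psu_codes, psu_uniq = pd.factorize(pair)
        self._psu_stratum = pd.factorize(psu_uniq.get_level_values(0))[0]
        # map psu -> stratum code consistent with _strat_codes
        lookup = {s: i for i, s in enumerate(self._strat_uniq)}
        self._psu_stratum = np.array(
            [lookup[s] for s in psu_uniq.get_level_values(0)]
        )

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def n_psus(self) -> int:
        return int(self._psu_codes.max()) + 1

    @property
    def n_strata(self) -> int:
        return len(self._strat_uniq)

    @property
    def variance_df(self) -> int:
        """Design degrees of freedom: (#PSUs) - (#strata)."""
        return self.n_psus - self.n_strata

    def subset(self, mask: np.ndarray) -> "SurveyDesign":
        mask = np.asarray(mask, dtype=bool)
        return SurveyDesign(
            self.strata[mask], self.psu[mask], self.weights[mask], self.lonely_psu
        )

    def linearized_covariance(self, scores: np.ndarray) -> np.ndarray:
        """Stratified between-PSU covariance of a total of ``scores``.

        ``scores`` holds the per-respondent linearized contributions
        (already weight-multiplied), shape (n,) or (n, k).  Returns the
        (k, k) covariance of the estimated total.
        """
        z = np.asarray(scores, dtype=float)
        squeeze = z.ndim == 1
        if squeeze:
            z = z[:, None]
        k = z.shape[1]
        npsu = self.n_psus
        # PSU totals
        totals = np.zeros((npsu, k))
        np.add.at(totals, self._psu_codes, z)
        strat_of_psu = self._psu_stratum
        nh = np.bincount(strat_of_psu, minlength=self.n_strata)
        strat_mean = np.zeros((self.n_strata, k))
        np.add.at(strat_mean, strat_of_psu, totals)
        strat_mean /= nh[:, None]

        lonely = nh == 1
        if np.any(lonely) and self.lonely_psu == "fail":
            bad = [str(self._strat_uniq[i]) for i in np.where(lonely)[0]]
            raise LonelyPSUError(f"single-PSU strata: {bad}")
        center = strat_mean[strat_of_psu]
        if np.any(lonely):
            grand = totals.mean(axis=0)
            center = np.where(lonely[strat_of_psu, None], grand, center)
        dev = totals - center
        factor = np.where(lonely, 1.0, nh / np.maximum(nh - 1, 1))
        cov = (dev * factor[strat_of_psu, None]).T @ dev
        return cov[0, 0] if squeeze and k == 1 else cov


@dataclass(frozen=True)
class WeightedProportion:
    estimate: float
    se: float
    n_unweighted: int
    sum_weights: float

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        zq = stats.norm.ppf(0.5 + level / 2)
        return (self.estimate - zq * self.se, self.estimate + zq * self.se)


def weighted_proportion(
    x: np.ndarray,
    design: SurveyDesign,
    domain: np.ndarray | None = None,
) -> WeightedProportion:
    """Design-weighted proportion of a binary indicator over a domain.

    ``p = sum(w x) / sum(w)`` over the domain, with the Taylor-linearized
    SE of the ratio estimator computed over the full design (out-of-domain
    scores are zero).
    """
    x = np.asarray(x, dtype=float)
    n = len(design)
    if len(x) != n:
        raise ValueError("indicator length does not match design")
    d = np.ones(n, dtype=bool) if domain is None else np.asarray(domain, dtype=bool)
    if not d.any():
        raise EmptyDomainError("estimation domain is empty")
    if np.any(np.isnan(x[d])):
        raise ValueError("indicator has missing values inside the domain")
    w = design.weights
    wd = w * d
    sw = wd.sum()
    p = float((wd * np.where(d, x, 0.0)).sum() / sw)
    # linearized score of the ratio p = sum(w d x)/sum(w d)
    z = wd * (np.where(d, x, 0.0) - p) / sw
    var = design.linearized_covariance(z)
    return WeightedProportion(
        estimate=p,
        se=float(np.sqrt(max(var, 0.0))),
        n_unweighted=int(d.sum()),
        sum_weights=float(sw),
    )


@dataclass
class Weighted2x2:
    """Weighted exposure x outcome table with its design handle.

    Cell convention: ``w11`` exposed cases, ``w10`` exposed non-cases,
    ``w01`` unexposed cases, ``w00`` unexposed non-cases.  The complete-
    case domain mask and per-respondent vectors are retained so that
    downstream ratio estimators can linearize their variances on the full
    design.
    """

    w11: float
    w10: float
    w01: float
    w00: float
    n11: int
    n10: int
    n01: int
    n00: int
    design: SurveyDesign = field(repr=False)
    exposure: np.ndarray = field(repr=False)
    outcome: np.ndarray = field(repr=False)
    domain: np.ndarray = field(repr=False)

    @property
    def exposure_prevalence(self) -> float:
        tot = self.w11 + self.w10 + self.w01 + self.w00
        return (self.w11 + self.w10) / tot

    @property
    def has_empty_margin(self) -> bool:
        return (self.w11 + self.w10) == 0 or (self.w01 + self.w00) == 0


def weighted_2x2(
    exposure: np.ndarray,
    outcome: np.ndarray,
    design: SurveyDesign,
) -> Weighted2x2:
    """Complete-case weighted 2x2 masses of exposure against outcome."""
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if len(x) != len(design) or len(y) != len(design):
        raise ValueError("exposure/outcome length does not match design")
    d = ~(np.isnan(x) | np.isnan(y))
    if not d.any():
        raise EmptyDomainError("no complete cases for the 2x2 table")
    w = design.weights
    xb = np.where(d, x, 0.0).astype(bool)
    yb = np.where(d, y, 0.0).astype(bool)

    def mass(mx, my):
        m = d & (xb == mx) & (yb == my)
        return float(w[m].sum()), int(m.sum())

    w11, n11 = mass(True, True)
    w10, n10 = mass(True, False)
    w01, n01 = mass(False, True)
    w00, n00 = mass(False, False)
    return Weighted2x2(
        w11=w11, w10=w10, w01=w01, w00=w00,
        n11=n11, n10=n10, n01=n01, n00=n00,
        design=design, exposure=x, outcome=y, domain=d,
    )


@dataclass(frozen=True)
class RaoScottResult:
    statistic: float  # second-order adjusted F statistic
    df_num: float
    df_den: float
    p_value: float
    pearson_chi2: float
    mean_deff: float


def rao_scott_chisq(
    row: np.ndarray,
    col: np.ndarray,
    design: SurveyDesign,
) -> RaoScottResult:
    """Second-order Rao-Scott adjusted Pearson test of independence.

    The Pearson statistic of the weighted r x c table is corrected by the
    eigenvalues of the generalized-design-effect matrix (Satterthwaite
    second-order correction) and referred to an F distribution with the
    design degrees of freedom, as in SAS SURVEYFREQ and R ``svychisq``.
    Observations missing either variable are dropped as a domain.
    """
    row = np.asarray(row)
    col = np.asarray(col)
    rmiss = pd.isna(row)
    cmiss = pd.isna(col)
    d = ~(rmiss | cmiss)
    if not d.any():
        raise EmptyDomainError("no complete cases for the crosstab")
    ri, rlev = pd.factorize(row[d])
    ci, clev = pd.factorize(col[d])
    R, C = len(rlev), len(clev)
    if R < 2 or C < 2:
        raise ValueError("crosstab margins are degenerate (need >=2 levels)")
    n = int(d.sum())
    w = design.weights
    sw = w[d].sum()

    cell = ri * C + ci
    K = R * C
    # weighted cell proportions
    phat = np.zeros(K)
    np.add.at(phat, cell, w[d])
    phat /= sw
    prow = phat.reshape(R, C).sum(axis=1)
    pcol = phat.reshape(R, C).sum(axis=0)
    p0 = np.outer(prow, pcol).ravel()
    if np.any(prow <= 0) or np.any(pcol <= 0):
        raise ValueError("crosstab has an empty margin")

    X2 = n * float(((phat - p0) ** 2 / p0).sum())

    # design covariance of the K cell proportions (ratio linearization)
    ind = np.zeros((len(design), K))
    ind[np.where(d)[0], cell] = 1.0
    z = (design.weights[:, None] * np.where(d[:, None], 1.0, 0.0)
         * (ind - phat[None, :])) / sw
    Vhat = design.linearized_covariance(z)

    # contrasts h_ij = p_ij - p_i+ p_+j for i<R-1, j<C-1; Jacobian H
    dfree = (R - 1) * (C - 1)
    H = np.zeros((dfree, K))
    for a in range(R - 1):
        for b in range(C - 1):
            t = a * (C - 1) + b
            for i in range(R):
                for j in range(C):
                    k = i * C + j
                    val = 0.0
                    if i == a and j == b:
                        val += 1.0
                    if i == a:
                        val -= pcol[b]
                    if j == b:
                        val -= prow[a]
                    H[t, k] = val
    V0 = (np.diag(p0) - np.outer(p0, p0)) / n  # SRS multinomial covariance
    Vh = H @ Vhat @ H.T
    V0h = H @ V0 @ H.T
    # generalized design effects
    delta = np.linalg.eigvals(np.linalg.solve(V0h, Vh)).real
    delta = np.clip(delta, 1e-12, None)
    dbar = delta.mean()
    a2 = float((delta**2).sum() / (dfree * dbar**2) - 1.0)
    nu = dfree / (1.0 + a2)
    F = X2 / (dbar * dfree)  # second-order: X2/(dbar*(1+a2)) / nu == this
    df_den = nu * max(design.variance_df, 1)
    p = float(stats.f.sf(F, nu, df_den))
    return RaoScottResult(
        statistic=float(F), df_num=float(nu), df_den=float(df_den),
        p_value=p, pearson_chi2=X2, mean_deff=float(dbar),
    )


def scd_probability_by_age_sex(
    records: pd.DataFrame,
    design: SurveyDesign,
    outcome: str = "scd",
    sex_col: str = "sex",
    age_col: str = "age_group",
) -> pd.DataFrame:
    """Weighted outcome probability per (sex, age-group) cell.

    Cells with no respondents are omitted.  Returns a tidy frame with the
    estimate, SE and unweighted n per cell.
    """
    y = records[outcome].to_numpy(dtype=float)
    base = ~np.isnan(y)
    out = []
    for sex in pd.unique(records[sex_col].dropna()):
        for age in pd.unique(records[age_col].dropna()):
            dom = base & (records[sex_col] == sex).to_numpy() & (
                records[age_col] == age
            ).to_numpy()
            if not dom.any():
                continue
            wp = weighted_proportion(y, design, domain=dom)
            out.append(
                dict(sex=sex, age_group=age, estimate=wp.estimate,
                     se=wp.se, n=wp.n_unweighted)
            )
    df = pd.DataFrame(out)
    return df.sort_values(["sex", "age_group"]).reset_index(drop=True)
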