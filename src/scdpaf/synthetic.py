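"""BRFSS-like synthetic survey microdata with known ground truth.

The generator emulates the statistical structure the estimation modules
assume, so every stage of the pipeline has a recoverable truth:

* nine correlated binary risk factors drawn by thresholding a latent
  multivariate normal at the inverse-normal of the target prevalences
  (a Gaussian-copula / tetrachoric model);
* age-confounded factors via a latent mean shift per standardized age
  score, with thresholds re-solved so the superpopulation marginals stay
  at their targets;
* a binary cognitive-decline outcome following a *log-link* risk model,
  so the configured relative risks are exactly the estimand of the
  modified Poisson module (no noncollapsibility slack); configs whose
  maximal lattice risk would exceed 1 are rejected at load;
* a stratified, clustered design with informative weights: respondents
  enter the file with an age-dependent inclusion probability and carry
  its inverse (times lognormal noise) as their weight, so weighting
  demonstrably matters;
* module availability by survey year and state-coverage fraction, plus
  item-level "Don't know"/"Refused" nonresponse.

Raw question responses are emitted in the recode module's catalog codes,
so generated files exercise the full recode -> estimate path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import published
from .recode import AGE_GROUPS, FACTORS

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "paper_like_config",
    "recovery_config",
    "generate",
    "apply_availability",
    "simulate_clustered_crosstab",
]

#: Superpopulation age-group shares for ages 45+ (approximating the
#: weighted age distribution of the target survey population).
AGE_SHARES = np.array([0.1336, 0.1699, 0.1532, 0.1593, 0.1275, 0.0990, 0.0733, 0.0842])
AGE_SHARES = AGE_SHARES / AGE_SHARES.sum()

_DEMOGRAPHICS = {
    "race": (
        ["WHITE", "BLACK", "HISPANIC", "ASIAN_PI", "AIAN", "MULTIRACIAL", "OTHER"],
        [0.753, 0.111, 0.086, 0.025, 0.009, 0.012, 0.004],
    ),
    "marital": (
        ["MARRIED", "DIV_SEP", "WIDOWED", "NEVER_MARRIED", "UNMARRIED_COUPLE"],
        [0.602, 0.175, 0.129, 0.075, 0.019],
    ),
    "income": (
        ["LT_15K", "15_25K", "25_35K", "35_50K", "GE_50K"],
        [0.112, 0.168, 0.103, 0.138, 0.479],
    ),
    "employment": (
        ["EMPLOYED", "SELF_EMPLOYED", "OUT_OF_WORK", "HOMEMAKER", "STUDENT",
         "RETIRED", "UNABLE"],
        [0.368, 0.083, 0.041, 0.059, 0.002, 0.344, 0.103],
    ),
}

FACTOR_ITEMS = {
    "limited_education": ("EDUCA",),
    "deafness": ("DEAF",),
    "social_isolation": ("EMTSUPRT", "LMTSOCAL"),
    "depression": ("ADDEPEV",),
    "smoking": ("SMOKE100", "SMOKDAY"),
    "physical_inactivity": ("EXERANY",),
    "obesity": ("BMICAT",),
    "hypertension": ("BPHIGH",),
    "diabetes": ("DIABETE",),
}

YEARS = (2015, 2016, 2017, 2018)


def _age_scores() -> np.ndarray:
    """Standardized score per age group under the superpopulation shares."""
    idx = np.arange(len(AGE_GROUPS), dtype=float)
    mu = (AGE_SHARES * idx).sum()
    sd = np.sqrt((AGE_SHARES * (idx - mu) ** 2).sum())
    return (idx - mu) / sd


def one_factor_latent_corr(target_communalities: np.ndarray) -> np.ndarray:
    """Unit-diagonal correlation matrix with a single common factor whose
    loadings are sqrt of the target shared-variance fractions."""
    lam = np.sqrt(np.asarray(target_communalities, dtype=float))
    r = np.outer(lam, lam)
    np.fill_diagonal(r, 1.0)
    return r


@dataclass
class SyntheticConfig:
    """Full parameterization of one synthetic survey."""

    n: int
    prevalences: dict[str, float]
    rrs: dict[str, float]  # conditional RRs of the log-risk outcome model
    latent_corr: np.ndarray
    baseline_risk: float  # outcome risk, oldest group, no factors
    age_factor_shift: dict[str, float]  # latent shift per sd of age
    age_rr: np.ndarray  # outcome risk multiplier per age group, max 1
    sex_female: float = 0.537
    n_strata: int = 48
    psus_per_stratum: int = 6
    weight_sigma: float = 0.3  # lognormal noise on top of inverse-inclusion
    age_inclusion: np.ndarray = field(
        default_factory=lambda: np.array([0.60, 0.65, 0.70, 0.75, 0.85, 0.90, 0.95, 1.0])
    )
    availability: dict[str, tuple[int, ...]] = field(default_factory=dict)
    coverage: dict[str, float] = field(default_factory=dict)
    item_nonresponse: dict[str, float] = field(default_factory=dict)
    scd_dk_rate: float = 0.007
    scd_refused_rate: float = 0.002
    income_missing_rate: float = 0.12
    seed: int = 0

    def __post_init__(self):
        self.latent_corr = np.asarray(self.latent_corr, dtype=float)
        self.age_rr = np.asarray(self.age_rr, dtype=float)
        self.age_inclusion = np.asarray(self.age_inclusion, dtype=float)
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        p = np.array([self.prevalences[f] for f in FACTORS])
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("prevalences must lie strictly in (0, 1)")
        r = self.latent_corr
        if r.shape != (len(FACTORS), len(FACTORS)):
            raise ValueError("latent_corr must be 9x9")
        if not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1.0):
            raise ValueError("latent_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(r).min() < -1e-10:
            raise ValueError("latent_corr must be positive semi-definite")
        if len(self.age_rr) != len(AGE_GROUPS):
            raise ValueError("age_rr must have one multiplier per age group")
        # maximal risk over the factor lattice: all rr>1 factors on,
        # at the most at-risk age group
        max_mult = float(self.age_rr.max())
        lattice = np.prod([max(self.rrs[f], 1.0) for f in FACTORS])
        max_risk = self.baseline_risk * lattice * max_mult
        if max_risk > 1.0:
            raise ValueError(
                f"log-link risk model exceeds 1 on the factor lattice "
                f"(max attainable risk {max_risk:.3f}); lower baseline_risk"
            )
        if not 0 < self.baseline_risk < 1:
            raise ValueError("baseline_risk must be in (0, 1)")

    # -- derived truth ------------------------------------------------
    def delta(self) -> np.ndarray:
        return np.array([self.age_factor_shift.get(f, 0.0) for f in FACTORS])

    def true_tetrachoric(self) -> np.ndarray:
        """Latent correlation of the *marginal* factor pairs: the common
        age score adds shared variance on top of ``latent_corr``."""
        d = self.delta()
        sd = np.sqrt(1.0 + d**2)
        sigma = (self.latent_corr + np.outer(d, d)) / np.outer(sd, sd)
        np.fill_diagonal(sigma, 1.0)
        return sigma

    def thresholds(self) -> np.ndarray:
        """Latent thresholds giving the target superpopulation marginals
        after the age shift (solved over the discrete age mixture)."""
        a = _age_scores()
        t = np.empty(len(FACTORS))
        for i, f in enumerate(FACTORS):
            p = self.prevalences[f]
            d = self.delta()[i]

            def cdf(th):
                return float((AGE_SHARES * stats.norm.cdf(th - d * a)).sum()) - (1 - p)

            t[i] = optimize.brentq(cdf, -8, 8, xtol=1e-12)
        return t

    def implied_scd_marginal(self, n_mc: int = 200_000, seed: int | None = None) -> float:
        """Superpopulation outcome prevalence by Monte-Carlo integration."""
        rng = np.random.default_rng(self.seed + 1 if seed is None else seed)
        age = rng.choice(len(AGE_GROUPS), size=n_mc, p=AGE_SHARES)
        x = _draw_factors(self, age, rng)
        risk = _risk(self, x, age)
        return float(risk.mean())


@dataclass
class TruthRecord:
    """The generator's ground truth, for recovery tests."""

    prevalences: dict[str, float]
    rrs: dict[str, float]
    tetrachoric: np.ndarray
    baseline_risk: float
    age_rr: np.ndarray
    scd_marginal: float
    factor_counts: dict[str, dict[str, int]]
    n: int


def paper_like_config(n: int = 100_000, seed: int = 0, **overrides) -> SyntheticConfig:
    """Default study conditions: published all-adults prevalences and
    communality structure, published adjusted RRs as conditional truths.

    The baseline risk is set near the largest value the log-link lattice
    constraint admits; the implied outcome marginal is therefore below
    the survey's observed prevalence (see the methods note), a deliberate
    trade-off that keeps the configured RRs exact estimands.
    """
    panel = published.PANELS[("adjusted", "all")]
    unadj = published.PANELS[("unadjusted", "all")]
    prev = {f: unadj[f][1] / 100.0 for f in FACTORS}
    rrs = {f: panel[f][0] for f in FACTORS}
    comm = np.array([unadj[f][2] / 100.0 for f in FACTORS])
    a = _age_scores()
    cfg = dict(
        n=n,
        prevalences=prev,
        rrs=rrs,
        latent_corr=one_factor_latent_corr(comm),
        baseline_risk=0.0185,
        age_factor_shift={
            "limited_education": 0.15,
            "deafness": 0.30,
            "social_isolation": 0.10,
            "depression": -0.20,
            "smoking": -0.25,
            "physical_inactivity": 0.25,
            "obesity": 0.05,
            "hypertension": 0.35,
            "diabetes": 0.30,
        },
        age_rr=np.exp(0.35 * (a - a.max())),
        availability={
            "deafness": (2016, 2017, 2018),
            "social_isolation": (2015, 2016, 2017),
        },
        coverage={
            "deafness": 0.62,
            "social_isolation": 0.17,
            "hypertension": 0.61,
            "obesity": 0.94,
        },
        item_nonresponse={
            "limited_education": 0.003,
            "deafness": 0.003,
            "social_isolation": 0.01,
            "depression": 0.004,
            "smoking": 0.006,
            "physical_inactivity": 0.002,
            "obesity": 0.0,
            "hypertension": 0.002,
            "diabetes": 0.002,
        },
        seed=seed,
    )
    cfg.update(overrides)
    return SyntheticConfig(**cfg)


def recovery_config(n: int = 50_000, seed: int = 0, **overrides) -> SyntheticConfig:
    """Parameter-recovery conditions: the paper-like model with full item
    availability and no nonresponse, isolating the estimators."""
    return paper_like_config(
        n=n, seed=seed, availability={}, coverage={}, item_nonresponse={},
        scd_dk_rate=0.0, scd_refused_rate=0.0, income_missing_rate=0.0,
        **overrides,
    )


# ---------------------------------------------------------------------
# sampling internals

def _draw_factors(cfg: SyntheticConfig, age_idx: np.ndarray, rng) -> np.ndarray:
    n = len(age_idx)
    L = np.linalg.cholesky(cfg.latent_corr + 1e-12 * np.eye(len(FACTORS)))
    z = rng.standard_normal((n, len(FACTORS))) @ L.T
    a = _age_scores()[age_idx]
    z = z + np.outer(a, cfg.delta())
    return (z > cfg.thresholds()[None, :]).astype(np.int8)


def _risk(cfg: SyntheticConfig, x: np.ndarray, age_idx: np.ndarray) -> np.ndarray:
    logrr = np.log([cfg.rrs[f] for f in FACTORS])
    eta = x @ logrr
    return cfg.baseline_risk * np.exp(eta) * cfg.age_rr[age_idx]


def _choice(rng, codes, probs, n):
    return np.asarray(codes, dtype=object)[rng.choice(len(codes), size=n, p=probs)]


def _rawify(cfg: SyntheticConfig, x: np.ndarray, rng) -> dict[str, np.ndarray]:
    """Invert the coding rules: emit raw catalog codes consistent with the
    binary factor values (sub-categories drawn at plausible shares)."""
    n = x.shape[0]
    raw: dict[str, np.ndarray] = {}
    get = {f: x[:, i].astype(bool) for i, f in enumerate(FACTORS)}

    edu = np.empty(n, dtype=object)
    yes = get["limited_education"]
    edu[yes] = _choice(rng, ["NEVER_OR_KINDERGARTEN", "GRADES_1_8"], [0.1, 0.9], yes.sum())
    edu[~yes] = _choice(
        rng, ["GRADES_9_11", "GRADE_12_OR_GED", "COLLEGE_1_3", "COLLEGE_4_PLUS"],
        [0.08, 0.34, 0.30, 0.28], (~yes).sum(),
    )
    raw["EDUCA"] = edu

    raw["DEAF"] = np.where(get["deafness"], "YES", "NO").astype(object)

    sup = np.empty(n, dtype=object)
    art = np.empty(n, dtype=object)
    yes = get["social_isolation"]
    n_yes = yes.sum()
    via_arthritis = rng.random(n_yes) < 0.25
    sup_yes = _choice(rng, ["NEVER", "RARELY"], [0.4, 0.6], n_yes)
    sup_yes[via_arthritis] = _choice(
        rng, ["ALWAYS", "USUALLY", "SOMETIMES"], [0.3, 0.4, 0.3], via_arthritis.sum()
    )
    art_yes = _choice(
        rng, ["A_LITTLE", "NOT_LIMITED", "NO_ARTHRITIS"], [0.2, 0.2, 0.6], n_yes
    )
    art_yes[via_arthritis] = "A_LOT"
    sup[yes], art[yes] = sup_yes, art_yes
    sup[~yes] = _choice(rng, ["ALWAYS", "USUALLY", "SOMETIMES"], [0.5, 0.3, 0.2], (~yes).sum())
    art[~yes] = _choice(
        rng, ["A_LITTLE", "NOT_LIMITED", "NO_ARTHRITIS"], [0.15, 0.25, 0.6], (~yes).sum()
    )
    raw["EMTSUPRT"], raw["LMTSOCAL"] = sup, art

    raw["ADDEPEV"] = np.where(get["depression"], "YES", "NO").astype(object)

    s100 = np.empty(n, dtype=object)
    sday = np.full(n, np.nan, dtype=object)
    yes = get["smoking"]
    s100[yes] = "YES"
    sday[yes] = _choice(rng, ["EVERY_DAY", "SOME_DAYS"], [0.78, 0.22], yes.sum())
    former = rng.random((~yes).sum()) < 0.45  # former smokers answer NOT_AT_ALL
    s100_no = np.where(former, "YES", "NO").astype(object)
    sday_no = np.full((~yes).sum(), np.nan, dtype=object)
    sday_no[former] = "NOT_AT_ALL"
    s100[~yes], sday[~yes] = s100_no, sday_no
    raw["SMOKE100"], raw["SMOKDAY"] = s100, sday

    raw["EXERANY"] = np.where(get["physical_inactivity"], "NO", "YES").astype(object)

    bmi = np.empty(n, dtype=object)
    yes = get["obesity"]
    bmi[yes] = "OBESE"
    bmi[~yes] = _choice(
        rng, ["UNDERWEIGHT", "HEALTHY", "OVERWEIGHT"], [0.03, 0.40, 0.57], (~yes).sum()
    )
    raw["BMICAT"] = bmi

    bp = np.empty(n, dtype=object)
    yes = get["hypertension"]
    bp[yes] = "YES"
    bp[~yes] = _choice(
        rng, ["NO", "BORDERLINE", "YES_PREGNANCY_ONLY"], [0.86, 0.11, 0.03], (~yes).sum()
    )
    raw["BPHIGH"] = bp

    dia = np.empty(n, dtype=object)
    yes = get["diabetes"]
    dia[yes] = "YES"
    dia[~yes] = _choice(
        rng, ["NO", "PREDIABETES", "YES_PREGNANCY_ONLY"], [0.90, 0.08, 0.02], (~yes).sum()
    )
    raw["DIABETE"] = dia
    return raw


def generate(config: SyntheticConfig, seed: int | None = None):
    """Draw one synthetic survey file.

    Returns ``(raw, truth)`` where ``raw`` is a respondent-level frame in
    raw catalog codes (ready for :func:`scdpaf.recode.build_analytic_set`)
    and ``truth`` is the :class:`TruthRecord` oracle.  Fully reproducible
    from the seed.
    """
    cfg = config if seed is None else replace(config, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    # informative sampling: sample age distribution ~ shares * inclusion
    incl = cfg.age_inclusion
    q = AGE_SHARES * incl
    q = q / q.sum()
    age_idx = rng.choice(len(AGE_GROUPS), size=n, p=q)
    base_w = 1.0 / incl[age_idx]
    noise = rng.lognormal(-cfg.weight_sigma**2 / 2.0, cfg.weight_sigma, n)
    weights = base_w * noise

    strata = rng.integers(cfg.n_strata, size=n)
    psu = rng.integers(cfg.psus_per_stratum, size=n)
    sex = np.where(rng.random(n) < cfg.sex_female, "FEMALE", "MALE").astype(object)
    year = rng.choice(YEARS, size=n)

    x = _draw_factors(cfg, age_idx, rng)
    risk = _risk(cfg, x, age_idx)
    y = (rng.random(n) < risk).astype(np.int8)

    raw = _rawify(cfg, x, rng)

    # module availability (years + state coverage), then item nonresponse
    factor_missing = np.zeros((n, len(FACTORS)), dtype=bool)
    for i, f in enumerate(FACTORS):
        unavailable = np.zeros(n, dtype=bool)
        years = cfg.availability.get(f)
        if years is not None:
            unavailable |= ~np.isin(year, list(years))
        cov = cfg.coverage.get(f)
        if cov is not None:
            unavailable |= rng.random(n) >= cov
        nr = cfg.item_nonresponse.get(f, 0.0)
        nr_mask = (rng.random(n) < nr) & ~unavailable if nr > 0 else np.zeros(n, bool)
        if nr_mask.any():
            # nonresponse shows up as DK/Refused on all the factor's items
            code = np.where(rng.random(nr_mask.sum()) < 0.7, "DONT_KNOW", "REFUSED")
            for item in FACTOR_ITEMS[f]:
                raw[item][nr_mask] = code
        for item in FACTOR_ITEMS[f]:
            raw[item][unavailable] = np.nan
        factor_missing[:, i] = unavailable | nr_mask

    scd = np.where(y == 1, "YES", "NO").astype(object)
    u = rng.random(n)
    scd[u < cfg.scd_dk_rate] = "DONT_KNOW"
    scd[(u >= cfg.scd_dk_rate) & (u < cfg.scd_dk_rate + cfg.scd_refused_rate)] = "REFUSED"

    demo = {}
    for name, (codes, probs) in _DEMOGRAPHICS.items():
        p = np.asarray(probs, dtype=float)
        demo[name] = _choice(rng, codes, p / p.sum(), n)
    if cfg.income_missing_rate > 0:
        inc_miss = rng.random(n) < cfg.income_missing_rate
        demo["income"][inc_miss] = np.nan
    veteran = np.where(rng.random(n) < 0.15, "YES", "NO").astype(object)

    df = pd.DataFrame(
        {
            "respondent_id": np.arange(n),
            "survey_year": year,
            "_STSTR": strata,
            "_PSU": psu,
            "_LLCPWT": weights,
            "sex": sex,
            "age_group": np.asarray(AGE_GROUPS, dtype=object)[age_idx],
            "veteran": veteran,
            **demo,
            "CIMEMLOS": scd,
            **raw,
        }
    )

    counts = {}
    scd_answered = (scd == "YES") | (scd == "NO")
    for i, f in enumerate(FACTORS):
        miss = factor_missing[:, i]
        counts[f] = {
            "yes": int((x[:, i].astype(bool) & ~miss).sum()),
            "no": int((~x[:, i].astype(bool) & ~miss).sum()),
            "missing": int(miss.sum()),
        }
    counts["scd"] = {
        "yes": int((y.astype(bool) & scd_answered).sum()),
        "no": int((~y.astype(bool) & scd_answered).sum()),
        "missing": int((~scd_answered).sum()),
    }

    truth = TruthRecord(
        prevalences=dict(cfg.prevalences),
        rrs=dict(cfg.rrs),
        tetrachoric=cfg.true_tetrachoric(),
        baseline_risk=cfg.baseline_risk,
        age_rr=cfg.age_rr.copy(),
        scd_marginal=cfg.implied_scd_marginal(),
        factor_counts=counts,
        n=n,
    )
    return df, truth


def apply_availability(records: pd.DataFrame, mask: dict[str, tuple[int, ...]]) -> pd.DataFrame:
    """Blank a factor's raw items for survey years outside its mask.

    ``mask`` maps factor name to the tuple of years the factor is
    available; factors not in the mask are untouched.  Returns a copy.
    """
    out = records.copy()
    year = out["survey_year"].to_numpy()
    for f, years in mask.items():
        unavailable = ~np.isin(year, list(years))
        for item in FACTOR_ITEMS[f]:
            if item in out:
                col = out[item].to_numpy(dtype=object)
                col[unavailable] = np.nan
                out[item] = col
    return out


def simulate_clustered_crosstab(
    n: int,
    rng: np.random.Generator,
    n_strata: int = 50,
    psus_per_stratum: int = 4,
    col_probs=(0.3, 0.3, 0.25, 0.15),
    row_prob: float = 0.5,
    cluster_concentration: float = 60.0,
    row_concentration: float = 60.0,
    weight_sigma: float = 0.3,
):
    """A null sex-by-category table with genuine cluster correlation.

    Category shares vary by PSU (Dirichlet around ``col_probs``) and the
    binary row probability varies by PSU (Beta around ``row_prob``),
    *independently* of each other, so row and column are independent both
    within PSU and marginally - a true null for association tests - while
    both margins carry cluster correlation, giving a design effect above
    one that a classical Pearson test would ignore.  Returns
    (row, col, design).
    """
    from .survey import SurveyDesign

    strata = rng.integers(n_strata, size=n)
    psu = rng.integers(psus_per_stratum, size=n)
    psu_key = strata * psus_per_stratum + psu
    n_psu = n_strata * psus_per_stratum
    alpha = np.asarray(col_probs) * cluster_concentration
    psu_probs = rng.dirichlet(alpha, size=n_psu)
    u = rng.random(n)
    cum = np.cumsum(psu_probs[psu_key], axis=1)
    col = (u[:, None] > cum).sum(axis=1)
    pr = rng.beta(
        row_prob * row_concentration, (1 - row_prob) * row_concentration, size=n_psu
    )
    row = (rng.random(n) < pr[psu_key]).astype(int)
    w = rng.lognormal(-weight_sigma**2 / 2, weight_sigma, n)
    return row, col, SurveyDesign(strata, psu, w)
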