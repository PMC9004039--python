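"""Recode raw BRFSS-style questionnaire responses into analysis variables.

Each of the nine modifiable risk factors becomes a tri-state indicator
(1 = yes, 0 = no, NaN = missing), the cognitive-decline outcome becomes
{1, 0, NaN}, and respondents below 45 or with a missing outcome are
dropped from the analytic set.  "Don't know" and "Refused" responses map
to missing; an unrecognized response code raises, so instrument drift
surfaces instead of silently becoming missingness.

Raw responses use canonical string codes (see ``CATALOG``); missing
items are NaN/None.  Column names follow the BRFSS variables the items
come from (CIMEMLOS, EDUCA, DEAF, EMTSUPRT, LMTSOCAL, ADDEPEV, SMOKE100,
SMOKDAY, EXERANY, BMICAT, BPHIGH, DIABETE).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "CodingError",
    "EmptyAnalyticSetError",
    "RiskFactorSpec",
    "RISK_FACTOR_SPECS",
    "FACTORS",
    "code_scd",
    "code_factor",
    "code_social_isolation",
    "recode_dataframe",
    "build_analytic_set",
    "specs_with_availability",
]

YES, NO = "YES", "NO"
DONT_KNOW, REFUSED = "DONT_KNOW", "REFUSED"
NONRESPONSE = {DONT_KNOW, REFUSED}

FACTORS = [
    "limited_education",
    "deafness",
    "social_isolation",
    "depression",
    "smoking",
    "physical_inactivity",
    "obesity",
    "hypertension",
    "diabetes",
]

AGE_GROUPS = ["45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80+"]

#: Allowed substantive codes per question id (nonresponse codes are
#: accepted everywhere).
CATALOG: dict[str, set[str]] = {
    "CIMEMLOS": {YES, NO},
    "EDUCA": {
        "NEVER_OR_KINDERGARTEN", "GRADES_1_8", "GRADES_9_11",
        "GRADE_12_OR_GED", "COLLEGE_1_3", "COLLEGE_4_PLUS",
    },
    "DEAF": {YES, NO},
    "EMTSUPRT": {"ALWAYS", "USUALLY", "SOMETIMES", "RARELY", "NEVER"},
    "LMTSOCAL": {"A_LOT", "A_LITTLE", "NOT_LIMITED", "NO_ARTHRITIS"},
    "ADDEPEV": {YES, NO},
    "SMOKE100": {YES, NO},
    "SMOKDAY": {"EVERY_DAY", "SOME_DAYS", "NOT_AT_ALL"},
    "EXERANY": {YES, NO},
    "BMICAT": {"UNDERWEIGHT", "HEALTHY", "OVERWEIGHT", "OBESE"},
    "BPHIGH": {YES, "YES_PREGNANCY_ONLY", "BORDERLINE", NO},
    "DIABETE": {YES, "YES_PREGNANCY_ONLY", "PREDIABETES", NO},
}


class CodingError(ValueError):
    """Unknown response code; names the respondent and item."""

    def __init__(self, respondent, item, code):
        super().__init__(
            f"respondent {respondent!r}: unknown code {code!r} for item {item!r}"
        )
        self.respondent, self.item, self.code = respondent, item, code


class EmptyAnalyticSetError(ValueError):
    """All respondents were excluded."""


def _is_missing(code) -> bool:
    return code is None or (isinstance(code, float) and np.isnan(code))


def _check(code, item: str, respondent="?"):
    """Validate a raw code; returns None for absent/nonresponse codes."""
    if _is_missing(code):
        return None
    if code in NONRESPONSE:
        return None
    if code not in CATALOG[item]:
        raise CodingError(respondent, item, code)
    return code


def code_scd(answers: dict, respondent="?") -> float:
    """Outcome coding: YES -> 1, NO -> 0, don't-know/refused/absent -> NaN."""
    code = _check(answers.get("CIMEMLOS"), "CIMEMLOS", respondent)
    if code is None:
        return np.nan
    return 1.0 if code == YES else 0.0


def _yes_no(code: str | None, yes_codes: set[str]) -> float:
    if code is None:
        return np.nan
    return 1.0 if code in yes_codes else 0.0


def _code_education(a, r):
    return _yes_no(_check(a.get("EDUCA"), "EDUCA", r),
                   {"NEVER_OR_KINDERGARTEN", "GRADES_1_8"})


def _code_deafness(a, r):
    return _yes_no(_check(a.get("DEAF"), "DEAF", r), {YES})


def code_social_isolation(support, arthritis_limit, respondent="?") -> float:
    """Combined rule over the support and arthritis-limitation items.

    Yes if support is never/rarely OR arthritis limits social activities
    a lot; no if support is always/usually/sometimes; otherwise missing
    (in particular when the support item is unanswered and the arthritis
    item gives no positive signal).
    """
    s = _check(support, "EMTSUPRT", respondent)
    a = _check(arthritis_limit, "LMTSOCAL", respondent)
    if a == "A_LOT":
        return 1.0
    if s in ("NEVER", "RARELY"):
        return 1.0
    if s in ("ALWAYS", "USUALLY", "SOMETIMES"):
        return 0.0
    return np.nan


def _code_social(a, r):
    return code_social_isolation(a.get("EMTSUPRT"), a.get("LMTSOCAL"), r)


def _code_depression(a, r):
    return _yes_no(_check(a.get("ADDEPEV"), "ADDEPEV", r), {YES})


def _code_smoking(a, r):
    """Yes iff >=100 lifetime cigarettes AND currently smoking every day
    or some days; a definite 'no' on either component suffices for no."""
    s100 = _check(a.get("SMOKE100"), "SMOKE100", r)
    sday = _check(a.get("SMOKDAY"), "SMOKDAY", r)
    if s100 == NO or sday == "NOT_AT_ALL":
        return 0.0
    if s100 == YES and sday in ("EVERY_DAY", "SOME_DAYS"):
        return 1.0
    return np.nan


def _code_inactivity(a, r):
    code = _check(a.get("EXERANY"), "EXERANY", r)
    if code is None:
        return np.nan
    return 1.0 if code == NO else 0.0  # inactive = did NOT exercise


def _code_obesity(a, r):
    return _yes_no(_check(a.get("BMICAT"), "BMICAT", r), {"OBESE"})


def _code_hypertension(a, r):
    # pregnancy-only and borderline/pre-hypertension count as NO
    return _yes_no(_check(a.get("BPHIGH"), "BPHIGH", r), {YES})


def _code_diabetes(a, r):
    # gestational-only and borderline/pre-diabetes count as NO
    return _yes_no(_check(a.get("DIABETE"), "DIABETE", r), {YES})


@dataclass(frozen=True)
class RiskFactorSpec:
    """Name, source items, coding rule and availability of one factor."""

    name: str
    questions: tuple[str, ...]
    coder: Callable = field(repr=False)
    years_available: frozenset[int] = frozenset({2015, 2016, 2017, 2018})


RISK_FACTOR_SPECS: dict[str, RiskFactorSpec] = {
    "limited_education": RiskFactorSpec("limited_education", ("EDUCA",), _code_education),
    "deafness": RiskFactorSpec(
        "deafness", ("DEAF",), _code_deafness, frozenset({2016, 2017, 2018})
    ),
    "social_isolation": RiskFactorSpec(
        "social_isolation", ("EMTSUPRT", "LMTSOCAL"), _code_social,
        frozenset({2015, 2016, 2017}),
    ),
    "depression": RiskFactorSpec("depression", ("ADDEPEV",), _code_depression),
    "smoking": RiskFactorSpec("smoking", ("SMOKE100", "SMOKDAY"), _code_smoking),
    "physical_inactivity": RiskFactorSpec(
        "physical_inactivity", ("EXERANY",), _code_inactivity
    ),
    "obesity": RiskFactorSpec("obesity", ("BMICAT",), _code_obesity),
    "hypertension": RiskFactorSpec("hypertension", ("BPHIGH",), _code_hypertension),
    "diabetes": RiskFactorSpec("diabetes", ("DIABETE",), _code_diabetes),
}


def specs_with_availability(
    availability: dict[str, tuple[int, ...]] | None,
) -> dict[str, RiskFactorSpec]:
    """Risk-factor specs with custom year availability.

    Factors named in ``availability`` get those years; all others are
    treated as available every year (pass ``{}`` for a fully available
    instrument, e.g. with synthetic data generated without year masks).
    """
    availability = availability or {}
    out = {}
    for name, spec in RISK_FACTOR_SPECS.items():
        years = availability.get(name)
        if years is None:
            years = {2015, 2016, 2017, 2018}
        out[name] = RiskFactorSpec(name, spec.questions, spec.coder, frozenset(years))
    return out


def code_factor(answers: dict, spec: RiskFactorSpec, survey_year: int | None = None,
                respondent="?") -> float:
    """Apply one factor's coding rule to a respondent's answers.

    Outside the factor's available years the result is missing regardless
    of any recorded answer (module availability, not respondent
    nonresponse).
    """
    if survey_year is not None and survey_year not in spec.years_available:
        return np.nan
    return spec.coder(answers, respondent)


DESIGN_COLS = ["_STSTR", "_PSU", "_LLCPWT"]
DEMOGRAPHIC_COLS = ["sex", "age_group", "race", "marital", "income",
                    "employment", "veteran"]


def recode_dataframe(
    raw: pd.DataFrame,
    specs: dict[str, RiskFactorSpec] | None = None,
) -> pd.DataFrame:
    """Vectorized recode of a raw respondent table.

    Returns a frame with respondent_id, survey_year, design columns,
    demographics, ``scd`` and the nine factor columns in {1, 0, NaN}.
    """
    specs = specs or RISK_FACTOR_SPECS
    rid = raw["respondent_id"] if "respondent_id" in raw else raw.index
    out = pd.DataFrame({"respondent_id": np.asarray(rid)})
    for c in ["survey_year"] + DESIGN_COLS + [c for c in DEMOGRAPHIC_COLS if c in raw]:
        if c in raw:
            out[c] = raw[c].to_numpy()

    answers = raw.to_dict("records")
    ids = out["respondent_id"].tolist()
    out["scd"] = [code_scd(a, r) for a, r in zip(answers, ids)]
    years = raw["survey_year"].tolist() if "survey_year" in raw else [None] * len(raw)
    for name, spec in specs.items():
        out[name] = [
            code_factor(a, spec, survey_year=yr, respondent=r)
            for a, yr, r in zip(answers, years, ids)
        ]
    return out


def build_analytic_set(
    raw: pd.DataFrame,
    specs: dict[str, RiskFactorSpec] | None = None,
    min_age_group: str = "45-49",
) -> tuple[pd.DataFrame, dict]:
    """Recode and apply the study's inclusion rules.

    Drops respondents younger than 45 (age group below ``min_age_group``)
    and those with a missing outcome; factor-level missingness is
    retained for per-estimator complete-case handling.  Returns the
    analytic frame and an audit dict whose exclusion counts plus the
    analytic n add up to the input n.
    """
    coded = recode_dataframe(raw, specs)
    n0 = len(coded)
    if "age_group" in coded:
        age_ok = coded["age_group"].isin(AGE_GROUPS).to_numpy()
    else:
        age_ok = np.ones(n0, dtype=bool)
    n_age = int((~age_ok).sum())
    coded = coded.loc[age_ok]
    scd_ok = coded["scd"].notna().to_numpy()
    n_scd = int((~scd_ok).sum())
    coded = coded.loc[scd_ok].reset_index(drop=True)
    if len(coded) == 0:
        raise EmptyAnalyticSetError("all respondents excluded")
    audit = {
        "n_input": n0,
        "excluded_age_under_45": n_age,
        "excluded_scd_missing": n_scd,
        "n_analytic": len(coded),
    }
    return coded, audit
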