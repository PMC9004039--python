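"""End-to-end orchestration: recode -> survey -> RR -> communality -> PAF.

Two entry paths:

* :func:`run_pipeline` - full microdata analysis of a raw respondent CSV
  (or frame): analytic-set construction, weighted descriptives, per-factor
  prevalences, unadjusted and adjusted relative risks, tetrachoric/PCA
  communalities, and the assembled PAF panels per population stratum
  (all adults / women / men), each serialized as tidy CSV with an audit
  log of every exclusion.

* :func:`replay_panel` - the PAF calculus applied to an already-estimated
  (factor, prevalence, rr, communality) table, so published table panels
  can be reproduced without any microdata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import recode as rc
from .communality import TetrachoricCommunality
from .paf import PAFTable, build_paf_table
from .rr import adjusted_rr, rr_from_records
from .survey import (
    SurveyDesign,
    rao_scott_chisq,
    scd_probability_by_age_sex,
    weighted_proportion,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "replay_panel"]

DEFAULT_COVARIATES = ["age_group", "race", "income", "employment", "marital", "veteran"]


@dataclass
class RunConfig:
    """Pipeline settings; mirrors the CLI options."""

    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    factors: list[str] = field(default_factory=lambda: list(rc.FACTORS))
    strata_labels: dict[str, str] = field(
        default_factory=lambda: {"all": "", "women": "FEMALE", "men": "MALE"}
    )
    retention: str | int = "kaiser"
    availability: dict[str, tuple[int, ...]] | None = None
    lonely_psu: str = "adjust"
    min_stratum_n: int = 50
    out_dir: str | None = None


@dataclass
class PipelineResult:
    analytic: pd.DataFrame
    descriptives: pd.DataFrame
    scd_by_age_sex: pd.DataFrame
    prevalences: dict[str, dict[str, float]]
    rr_unadjusted: dict[str, dict[str, object]]
    rr_adjusted: dict[str, dict[str, object]]
    communalities: dict[str, dict[str, float]]
    paf_tables: dict[tuple[str, str], PAFTable]
    audit: dict


def _design_of(frame: pd.DataFrame, lonely_psu: str) -> SurveyDesign:
    return SurveyDesign(
        frame["_STSTR"].to_numpy(),
        frame["_PSU"].to_numpy(),
        frame["_LLCPWT"].to_numpy(dtype=float),
        lonely_psu=lonely_psu,
    )


def _descriptives(analytic: pd.DataFrame, design: SurveyDesign) -> pd.DataFrame:
    """Weighted category shares by sex plus a design-adjusted chi-square
    per characteristic (the demographic-table shape)."""
    rows = []
    chars = ["age_group", "race", "marital", "income", "employment", "veteran"]
    sexes = ["MALE", "FEMALE"]
    for char in chars:
        if char not in analytic:
            continue
        try:
            test = rao_scott_chisq(
                analytic["sex"].to_numpy(), analytic[char].to_numpy(), design
            )
            pval = test.p_value
        except ValueError:
            pval = np.nan
        values = analytic[char].dropna().unique()
        base = analytic[char].notna().to_numpy()
        for level in sorted(map(str, values)):
            lvl_mask = (analytic[char].astype(str) == level).to_numpy()
            for sex in sexes:
                dom = base & (analytic["sex"] == sex).to_numpy()
                if not dom.any():
                    continue
                wp = weighted_proportion(lvl_mask.astype(float), design, domain=dom)
                rows.append(
                    dict(characteristic=char, level=level, sex=sex,
                         weighted_pct=100 * wp.estimate, se_pct=100 * wp.se,
                         n=int((lvl_mask & dom).sum()), p_value=pval)
                )
    scd = analytic["scd"].to_numpy(float)
    for sex in sexes + ["ALL"]:
        dom = None if sex == "ALL" else (analytic["sex"] == sex).to_numpy()
        wp = weighted_proportion(scd, design, domain=dom)
        rows.append(
            dict(characteristic="scd", level="yes", sex=sex,
                 weighted_pct=100 * wp.estimate, se_pct=100 * wp.se,
                 n=wp.n_unweighted, p_value=np.nan)
        )
    return pd.DataFrame(rows)


def run_pipeline(
    raw: pd.DataFrame,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full analysis on a raw respondent table."""
    config = config or RunConfig()
    specs = rc.specs_with_availability(config.availability) \
        if config.availability is not None else None
    analytic, audit = rc.build_analytic_set(raw, specs=specs)
    design = _design_of(analytic, config.lonely_psu)

    descriptives = _descriptives(analytic, design)
    by_age_sex = scd_probability_by_age_sex(analytic, design)

    strata_masks: dict[str, np.ndarray] = {}
    for label, sex_value in config.strata_labels.items():
        if sex_value:
            strata_masks[label] = (analytic["sex"] == sex_value).to_numpy()
        else:
            strata_masks[label] = np.ones(len(analytic), dtype=bool)

    prevalences: dict[str, dict[str, float]] = {}
    rr_un: dict[str, dict[str, object]] = {}
    rr_adj: dict[str, dict[str, object]] = {}
    comms: dict[str, dict[str, float]] = {}
    paf_tables: dict[tuple[str, str], PAFTable] = {}

    for label, mask in strata_masks.items():
        if mask.sum() < config.min_stratum_n:
            audit.setdefault("skipped_strata", []).append(label)
            continue
        sub = analytic.loc[mask].reset_index(drop=True)
        subdesign = design.subset(mask)

        prev = {}
        for f in config.factors:
            x = sub[f].to_numpy(float)
            dom = ~np.isnan(x)
            prev[f] = weighted_proportion(x, subdesign, domain=dom).estimate
        prevalences[label] = prev

        rr_un[label] = {
            f: rr_from_records(sub, f, subdesign, stratum=label)
            for f in config.factors
        }
        rr_adj[label] = {
            f: adjusted_rr(sub, f, config.covariates, subdesign, stratum=label)
            for f in config.factors
        }

        # communality: weights only, by design (no strata/PSUs)
        est = TetrachoricCommunality(retention=config.retention).fit(
            sub[config.factors], sample_weight=sub["_LLCPWT"].to_numpy(float)
        )
        comm = dict(zip(config.factors, est.communalities_))
        comms[label] = comm

        for kind, rrs in (("unadjusted", rr_un[label]), ("adjusted", rr_adj[label])):
            paf_tables[(kind, label)] = build_paf_table(
                {f: rrs[f].rr for f in config.factors},
                prev, comm, stratum=label, estimate_kind=kind,
                adjustment=tuple(config.covariates) if kind == "adjusted" else (),
                factors=config.factors,
            )

    result = PipelineResult(
        analytic=analytic, descriptives=descriptives, scd_by_age_sex=by_age_sex,
        prevalences=prevalences, rr_unadjusted=rr_un, rr_adjusted=rr_adj,
        communalities=comms, paf_tables=paf_tables, audit=audit,
    )
    if config.out_dir:
        _serialize(result, Path(config.out_dir))
    return result


def _rr_frame(rr_maps: dict[str, dict[str, object]]) -> pd.DataFrame:
    rows = []
    for label, d in rr_maps.items():
        for f, e in d.items():
            rows.append(
                dict(stratum=label, factor=f, rr=e.rr, ci_low=e.ci_low,
                     ci_high=e.ci_high, log_se=e.log_se, model=e.model,
                     n=e.n_analytic)
            )
    return pd.DataFrame(rows)


def _serialize(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.descriptives.to_csv(out / "descriptives.csv", index=False)
    result.scd_by_age_sex.to_csv(out / "scd_by_age_sex.csv", index=False)
    _rr_frame(result.rr_unadjusted).to_csv(out / "rr_unadjusted.csv", index=False)
    _rr_frame(result.rr_adjusted).to_csv(out / "rr_adjusted.csv", index=False)
    pd.DataFrame(result.communalities).to_csv(out / "communalities.csv")
    panels = pd.concat(
        [t.to_frame() for t in result.paf_tables.values()],
        keys=[f"{k}_{s}" for k, s in result.paf_tables], names=["panel"],
    )
    panels.to_csv(out / "paf_panels.csv")
    (out / "audit.json").write_text(json.dumps(result.audit, indent=2, default=str))


def replay_panel(
    inputs: pd.DataFrame,
    stratum: str = "all",
    estimate_kind: str = "unadjusted",
    percent: bool = True,
) -> PAFTable:
    """PAF calculus on an already-estimated panel.

    ``inputs`` needs columns factor, prevalence, rr, communality; with
    ``percent=True`` prevalence and communality are percentages (the
    printed-table convention), otherwise fractions.
    """
    df = inputs.loc[inputs["factor"] != "overall"]
    scale = 100.0 if percent else 1.0
    return build_paf_table(
        dict(zip(df["factor"], df["rr"].astype(float))),
        dict(zip(df["factor"], df["prevalence"].astype(float) / scale)),
        dict(zip(df["factor"], df["communality"].astype(float) / scale)),
        stratum=stratum, estimate_kind=estimate_kind,
        factors=list(df["factor"]),
    )
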