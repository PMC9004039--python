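"""Published reference panels for the 2015-2018 BRFSS analysis of nine
modifiable risk factors for subjective cognitive decline.

These are the printed per-factor relative risks, weighted prevalences,
communalities, attributable fractions and communality-weighted
attributable fractions (all on the percent scale, two decimals) for the
six published population panels: {unadjusted, adjusted} x {all adults,
women, men}.  They serve as *replay inputs* to the PAF calculus - the
underlying survey microdata are not redistributed - and as ground-truth
parameters for the synthetic-data generator.

Column order per factor: (rr, prevalence_pct, communality_pct, paf_pct,
weighted_paf_pct).  The last two columns are the published derived values
kept for validation; only the first three are inputs to the calculus.
"""

from __future__ import annotations

import pandas as pd

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

# (estimate_kind, stratum) -> {factor: (rr, prev%, comm%, paf%, wpaf%),
#                              "overall": (paf%, wpaf%)}
PANELS: dict[tuple[str, str], dict] = {
    ("unadjusted", "all"): {
        "limited_education": (1.60, 4.78, 66.19, 2.81, 0.85),
        "deafness": (2.60, 9.66, 39.81, 13.38, 4.05),
        "social_isolation": (3.39, 52.38, 70.97, 55.60, 16.82),
        "depression": (4.17, 18.76, 56.15, 37.30, 11.29),
        "smoking": (1.71, 15.46, 64.26, 9.90, 3.00),
        "physical_inactivity": (1.76, 30.76, 39.83, 18.87, 5.71),
        "obesity": (1.27, 32.97, 59.06, 8.25, 2.50),
        "hypertension": (1.62, 50.99, 57.99, 23.95, 7.25),
        "diabetes": (1.67, 17.76, 57.65, 10.57, 3.20),
        "overall": (89.31, 54.66),
    },
    ("unadjusted", "women"): {
        "limited_education": (1.61, 4.49, 58.99, 2.66, 0.78),
        "deafness": (2.68, 7.46, 48.90, 11.12, 3.28),
        "social_isolation": (3.23, 55.70, 69.20, 55.41, 16.31),
        "depression": (4.31, 22.92, 57.33, 43.12, 12.70),
        "smoking": (1.88, 14.41, 65.83, 11.27, 3.32),
        "physical_inactivity": (1.79, 32.25, 41.35, 20.23, 5.96),
        "obesity": (1.40, 32.08, 64.84, 11.35, 3.34),
        "hypertension": (1.59, 49.57, 58.25, 22.52, 6.63),
        "diabetes": (1.74, 16.73, 59.35, 10.98, 3.23),
        "overall": (90.51, 55.55),
    },
    ("unadjusted", "men"): {
        "limited_education": (1.60, 5.11, 26.67, 2.96, 1.01),
        "deafness": (2.54, 12.22, 20.30, 15.82, 5.38),
        "social_isolation": (3.65, 47.68, 71.96, 55.82, 19.00),
        "depression": (4.33, 13.94, 39.75, 31.72, 10.80),
        "smoking": (1.54, 16.68, 50.75, 8.29, 2.82),
        "physical_inactivity": (1.73, 29.03, 35.75, 17.53, 5.97),
        "obesity": (1.15, 33.93, 48.34, 4.85, 1.65),
        "hypertension": (1.65, 52.63, 57.98, 25.55, 8.70),
        "diabetes": (1.59, 18.95, 54.94, 10.05, 3.42),
        "overall": (88.12, 58.75),
    },
    ("adjusted", "all"): {
        "limited_education": (1.12, 4.78, 66.19, 0.59, 0.20),
        "deafness": (2.01, 9.66, 39.81, 8.87, 2.96),
        "social_isolation": (2.46, 52.38, 70.97, 43.28, 14.44),
        "depression": (3.12, 18.76, 56.15, 28.47, 9.50),
        "smoking": (1.20, 15.46, 64.26, 2.97, 0.99),
        "physical_inactivity": (1.32, 30.76, 39.83, 8.92, 2.98),
        "obesity": (1.14, 32.97, 59.06, 4.32, 1.44),
        "hypertension": (1.28, 50.99, 57.99, 12.57, 4.20),
        "diabetes": (1.28, 17.76, 57.65, 4.78, 1.59),
        "overall": (74.13, 38.30),
    },
    ("adjusted", "women"): {
        "limited_education": (1.18, 4.49, 58.99, 0.79, 0.26),
        "deafness": (2.09, 7.46, 48.90, 7.50, 2.44),
        "social_isolation": (2.48, 55.70, 69.20, 45.21, 14.72),
        "depression": (3.26, 22.92, 57.33, 34.08, 11.09),
        "smoking": (1.29, 14.41, 65.83, 4.00, 1.30),
        "physical_inactivity": (1.32, 32.25, 41.35, 9.45, 3.07),
        "obesity": (1.14, 32.08, 64.84, 4.37, 1.42),
        "hypertension": (1.26, 49.57, 58.25, 11.33, 3.69),
        "diabetes": (1.32, 16.73, 59.35, 5.10, 1.66),
        "overall": (76.81, 39.65),
    },
    ("adjusted", "men"): {
        "limited_education": (1.05, 5.11, 26.67, 0.28, 0.11),
        "deafness": (1.93, 12.22, 20.30, 10.16, 3.86),
        "social_isolation": (2.47, 47.68, 71.96, 41.20, 15.66),
        "depression": (3.23, 13.94, 39.75, 23.68, 9.00),
        "smoking": (1.11, 16.68, 50.75, 1.86, 0.71),
        "physical_inactivity": (1.32, 29.03, 35.75, 8.50, 3.23),
        "obesity": (1.13, 33.93, 48.34, 4.14, 1.58),
        "hypertension": (1.32, 52.63, 57.98, 14.44, 5.49),
        "diabetes": (1.24, 18.95, 54.94, 4.37, 1.66),
        "overall": (71.68, 41.30),
    },
}

#: Published weighted SCD prevalence (percent) overall and by sex.
SCD_PREVALENCE_PCT = {"all": 10.86, "women": 10.60, "men": 11.15}


def panel_frame(estimate_kind: str, stratum: str) -> pd.DataFrame:
    """Return one published panel as a tidy DataFrame (percent scale).

    Columns: factor, rr, prevalence, communality, paf, weighted_paf; one
    extra row ``factor='overall'`` holds the two published overall cells.
    """
    key = (estimate_kind, stratum)
    if key not in PANELS:
        raise KeyError(
            f"no published panel {key}; choose estimate_kind in "
            "{'unadjusted','adjusted'} and stratum in {'all','women','men'}"
        )
    panel = PANELS[key]
    recs = []
    for f in FACTORS:
        rr, prev, comm, paf, wpaf = panel[f]
        recs.append(
            dict(factor=f, rr=rr, prevalence=prev, communality=comm,
                 paf=paf, weighted_paf=wpaf)
        )
    ov_paf, ov_wpaf = panel["overall"]
    recs.append(
        dict(factor="overall", rr=float("nan"), prevalence=float("nan"),
             communality=float("nan"), paf=ov_paf, weighted_paf=ov_wpaf)
    )
    return pd.DataFrame.from_records(recs)


def panel_inputs(estimate_kind: str, stratum: str):
    """Replay inputs (fractions/ratios) for :func:`scdpaf.paf.build_paf_table`.

    Returns ``(rrs, prevalences, communalities)`` dicts keyed by factor.
    """
    panel = PANELS[(estimate_kind, stratum)]
    rrs = {f: panel[f][0] for f in FACTORS}
    prev = {f: panel[f][1] / 100.0 for f in FACTORS}
    comm = {f: panel[f][2] / 100.0 for f in FACTORS}
    return rrs, prev, comm
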