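"""Population-attributable-fraction calculus.

Implements Levin's formula per risk factor, the multiplicative combination
of per-factor PAFs into an overall PAF, communality discounting of that
overall value, and proportional apportionment of the discounted overall
back onto the individual factors.  All arithmetic is done on fractions;
percentages appear only at the reporting boundary (rounded half-even to
two decimals, the convention of the published tables this calculus
replays).

Notation, following the dementia-prevention literature:

    PAF_i   = p_i (RR_i - 1) / (1 + p_i (RR_i - 1))        (Levin)
    overall = 1 - prod_i (1 - PAF_i)
    wPAF    = 1 - prod_i (1 - (1 - c_i) PAF_i)             (communality-weighted)
    wPAF_i  = PAF_i / sum_j PAF_j * wPAF                   (apportionment)

where p_i is the exposure prevalence, RR_i the relative risk and c_i the
communality (shared variance) of factor i.  Negative PAFs (RR < 1) are
propagated, never truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "levin_paf",
    "combine_paf",
    "weighted_overall_paf",
    "apportion_weighted_paf",
    "build_paf_table",
    "PAFRow",
    "PAFTable",
]


def levin_paf(p: float, rr: float) -> float:
    """Levin's attributable fraction ``p(rr-1) / (1 + p(rr-1))``.

    Parameters
    ----------
    p : float
        Exposure prevalence as a fraction in [0, 1].
    rr : float
        Relative risk, strictly positive.  ``rr < 1`` yields a negative
        (protective) attributable fraction.
    """
    p = float(p)
    rr = float(rr)
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"prevalence must be in [0, 1], got {p}")
    if not (rr > 0.0 and np.isfinite(rr)):
        raise ValueError(f"relative risk must be positive and finite, got {rr}")
    excess = p * (rr - 1.0)
    return excess / (1.0 + excess)


def combine_paf(pafs: Iterable[float]) -> float:
    """Overall PAF of several factors: ``1 - prod(1 - paf_i)``.

    The multiplicative form assumes the factors act independently on the
    residual (unattributed) fraction; a zero contribution is the
    multiplicative identity.
    """
    arr = np.asarray(list(pafs), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one PAF")
    if np.any(arr >= 1.0):
        raise ValueError("each PAF must be < 1")
    return 1.0 - float(np.prod(1.0 - arr))


def weighted_overall_paf(pafs: Sequence[float], communalities: Sequence[float]) -> float:
    """Overall PAF with each factor discounted by its communality.

    Each factor enters with weight ``1 - c_i`` so that variance shared
    with other factors is not double counted:
    ``1 - prod(1 - (1 - c_i) paf_i)``.
    """
    paf = np.asarray(list(pafs), dtype=float)
    c = np.asarray(list(communalities), dtype=float)
    if paf.shape != c.shape:
        raise ValueError(f"length mismatch: {paf.size} PAFs vs {c.size} communalities")
    if np.any((c < 0.0) | (c > 1.0)):
        raise ValueError("communalities must be in [0, 1]")
    if np.any(paf >= 1.0):
        raise ValueError("each PAF must be < 1")
    return 1.0 - float(np.prod(1.0 - (1.0 - c) * paf))


def apportion_weighted_paf(pafs: Sequence[float], overall_weighted: float) -> np.ndarray:
    """Split the overall weighted PAF across factors by unweighted-PAF share.

    ``wpaf_i = (paf_i / sum_j paf_j) * overall_weighted``; the outputs sum
    to ``overall_weighted`` exactly.
    """
    paf = np.asarray(list(pafs), dtype=float)
    total = paf.sum()
    if total == 0.0:
        raise ValueError("cannot apportion: PAFs sum to zero")
    return paf / total * float(overall_weighted)


@dataclass(frozen=True)
class PAFRow:
    """One factor's line of a PAF table (all quantities as fractions)."""

    factor: str
    prevalence: float
    rr: float
    paf: float
    communality: float
    weighted_paf: float


@dataclass
class PAFTable:
    """One population panel: per-factor rows plus the two overall cells."""

    stratum: str
    rows: list[PAFRow]
    overall_paf: float
    overall_weighted_paf: float
    estimate_kind: str = "unadjusted"
    adjustment: tuple[str, ...] = field(default_factory=tuple)

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        """Tidy frame; with ``percent=True`` values are half-even rounded
        to two decimals on the percentage scale (the reporting convention)."""

        def rep(x: float) -> float:
            if not percent:
                return x
            return float(np.round(100.0 * x, 2))  # numpy rounds half-even

        recs = [
            {
                "stratum": self.stratum,
                "factor": r.factor,
                "prevalence": rep(r.prevalence),
                "rr": round(r.rr, 2) if percent else r.rr,
                "communality": rep(r.communality),
                "paf": rep(r.paf),
                "weighted_paf": rep(r.weighted_paf),
            }
            for r in self.rows
        ]
        recs.append(
            {
                "stratum": self.stratum,
                "factor": "overall",
                "prevalence": np.nan,
                "rr": np.nan,
                "communality": np.nan,
                "paf": rep(self.overall_paf),
                "weighted_paf": rep(self.overall_weighted_paf),
            }
        )
        return pd.DataFrame.from_records(recs)


def build_paf_table(
    rrs: Mapping[str, float],
    prevalences: Mapping[str, float],
    communalities: Mapping[str, float],
    stratum: str = "all",
    estimate_kind: str = "unadjusted",
    adjustment: Sequence[str] = (),
    factors: Sequence[str] | None = None,
) -> PAFTable:
    """Assemble a full PAF panel from per-factor inputs.

    Inputs are fractions (prevalence, communality) and ratios (rr), keyed
    by factor name.  All three mappings must cover the same factors.
    """
    if factors is None:
        factors = list(rrs)
    missing = [
        f
        for f in factors
        if f not in rrs or f not in prevalences or f not in communalities
    ]
    if missing:
        raise ValueError(f"missing inputs for factors: {missing}")

    pafs = [levin_paf(prevalences[f], rrs[f]) for f in factors]
    overall = combine_paf(pafs)
    woverall = weighted_overall_paf(pafs, [communalities[f] for f in factors])
    wpafs = apportion_weighted_paf(pafs, woverall)
    rows = [
        PAFRow(
            factor=f,
            prevalence=float(prevalences[f]),
            rr=float(rrs[f]),
            paf=pafs[i],
            communality=float(communalities[f]),
            weighted_paf=float(wpafs[i]),
        )
        for i, f in enumerate(factors)
    ]
    return PAFTable(
        stratum=stratum,
        rows=rows,
        overall_paf=overall,
        overall_weighted_paf=woverall,
        estimate_kind=estimate_kind,
        adjustment=tuple(adjustment),
    )
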