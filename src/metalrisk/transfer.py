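"""Soil-to-plant transfer factors, correlation structure and guideline
compliance.

The transfer factor TF = C_plant / C_soil measures uptake efficiency: high
TF means the metal is weakly retained by soil and readily translocated.
Summaries use the sample (n-1) standard deviation, which reproduces the
published per-metal spread.

Pearson correlations between wastewater metals are computed pairwise on
complete observations (listwise deletion would discard too much with only
a handful of sites); pairs with fewer than three complete observations or
zero variance are reported as missing with a reason rather than NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConcentrationTable, WaterQualityTable
from .indices import DomainError
from .references import ReferenceSet


def transfer_factor(c_plant: float, c_soil: float) -> float:
    """TF = plant concentration / soil concentration (both mg/kg dw)."""
    for name, v in (("c_plant", c_plant), ("c_soil", c_soil)):
        if not (math.isfinite(v) and v > 0):
            raise DomainError(f"{name} must be positive and finite, got {v!r}")
    return c_plant / c_soil


def summarize_tf(tfs) -> dict[str, float]:
    """Mean, sample (n-1) standard deviation, min and max of TF values."""
    tfs = [float(t) for t in tfs]
    if not tfs:
        raise DomainError("cannot summarise an empty transfer-factor list")
    arr = np.asarray(tfs)
    return {
        "mean": float(arr.mean()),
        "std": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


@dataclass
class TransferResult:
    """Per-(site, metal) transfer factors plus per-metal summaries."""

    tf: pd.DataFrame
    summary: pd.DataFrame  # columns mean, std, min, max

    def ranking(self) -> list[str]:
        """Metals ordered by decreasing mean TF."""
        return list(self.summary["mean"].sort_values(ascending=False).index)


def transfer_table(plant: ConcentrationTable, soil: ConcentrationTable) -> TransferResult:
    """Transfer factors for every (site, metal) present in both tables."""
    metals = [m for m in plant.analytes if m in soil.analytes]
    sites = [s for s in plant.sites if s in soil.sites]
    if not metals or not sites:
        raise DomainError("plant and soil tables share no sites or analytes")
    tf = pd.DataFrame(index=sites, columns=metals, dtype=float)
    for site in sites:
        for metal in metals:
            cp, cs = plant.data.at[site, metal], soil.data.at[site, metal]
            if pd.isna(cp) or pd.isna(cs):
                continue
            tf.at[site, metal] = transfer_factor(cp, cs)
    rows = {m: summarize_tf(tf[m].dropna().tolist()) for m in metals if tf[m].notna().any()}
    summary = pd.DataFrame.from_dict(rows, orient="index")[["mean", "std", "min", "max"]]
    return TransferResult(tf=tf, summary=summary)


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Pearson correlations between analytes."""

    analytes: list[str]
    r: pd.DataFrame
    n: pd.DataFrame
    missing: dict[tuple[str, str], str] = field(default_factory=dict)

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.analytes):
            for b in self.analytes[i + 1 :]:
                rows.append(
                    {
                        "analyte_a": a,
                        "analyte_b": b,
                        "r": self.r.at[a, b],
                        "n": self.n.at[a, b],
                        "note": self.missing.get((a, b), ""),
                    }
                )
        return pd.DataFrame(rows)


def pearson_matrix(table: ConcentrationTable, min_pairs: int = 3) -> CorrelationMatrix:
    """Pairwise Pearson r over complete site pairs per analyte pair.

    A pair with fewer than ``min_pairs`` complete observations or zero
    variance is recorded in ``missing`` with a reason instead of being
    propagated as NaN.
    """
    analytes = table.analytes
    r = pd.DataFrame(np.eye(len(analytes)), index=analytes, columns=analytes)
    n = pd.DataFrame(0, index=analytes, columns=analytes, dtype=int)
    missing: dict[tuple[str, str], str] = {}
    for a in analytes:
        n.at[a, a] = int(table.data[a].notna().sum())
    for i, a in enumerate(analytes):
        for b in analytes[i + 1 :]:
            paired = table.data[[a, b]].dropna()
            n.at[a, b] = n.at[b, a] = len(paired)
            if len(paired) < min_pairs:
                missing[(a, b)] = f"only {len(paired)} complete pairs (need {min_pairs})"
                r.at[a, b] = r.at[b, a] = np.nan
                continue
            if paired[a].nunique() == 1 or paired[b].nunique() == 1:
                missing[(a, b)] = "zero variance"
                r.at[a, b] = r.at[b, a] = np.nan
                continue
            rho = stats.pearsonr(paired[a], paired[b]).statistic
            r.at[a, b] = r.at[b, a] = float(rho)
    return CorrelationMatrix(analytes=analytes, r=r, n=n, missing=missing)


# ---------------------------------------------------------------------------
# guideline and discharge-standard compliance


def guideline_exceedance(value: float, limit) -> tuple[float, str]:
    """Ratio of a concentration to a guideline limit, with a verdict.

    Scalar limits return (value/limit, "exceeds"|"within").  Interval
    limits return the ratio against the upper bound and a verdict
    below/within/above the interval.
    """
    if not (math.isfinite(value) and value > 0):
        raise DomainError(f"value must be positive, got {value!r}")
    if isinstance(limit, (tuple, list)):
        lo, hi = float(limit[0]), float(limit[1])
        if not (lo > 0 and hi > 0 and lo <= hi):
            raise DomainError(f"invalid guideline interval {limit!r}")
        ratio = value / hi
        verdict = "below" if value < lo else ("above" if value > hi else "within")
        return ratio, verdict
    limit = float(limit)
    if not limit > 0:
        raise DomainError(f"guideline limit must be positive, got {limit!r}")
    ratio = value / limit
    return ratio, ("exceeds" if ratio > 1 else "within")


def exceedance_table(
    values: pd.Series, refs: ReferenceSet, authorities: list[str]
) -> pd.DataFrame:
    """Tidy exceedance report for per-metal values against each authority."""
    rows = []
    for authority in authorities:
        limits = refs.guidelines.get(authority, {})
        for metal, value in values.items():
            if metal not in limits or pd.isna(value):
                continue
            ratio, verdict = guideline_exceedance(float(value), limits[metal])
            rows.append(
                {
                    "analyte": metal,
                    "authority": authority,
                    "value": float(value),
                    "limit": limits[metal],
                    "ratio": ratio,
                    "verdict": verdict,
                }
            )
    return pd.DataFrame(rows)


def water_quality_compliance(table: WaterQualityTable) -> pd.DataFrame:
    """Per-site, per-parameter verdicts against the discharge standard.

    Interval standards (pH, DO) yield below/within/above; scalar upper
    limits yield within/above.  Parameters without a standard are skipped.
    """
    rows = []
    for site in table.sites:
        for param in table.parameters:
            if param not in table.standard:
                continue
            value = float(table.data.at[site, param])
            limit = table.standard[param]
            if isinstance(limit, (tuple, list)):
                lo, hi = limit
                verdict = "below" if value < lo else ("above" if value > hi else "within")
            else:
                verdict = "above" if value > limit else "within"
            rows.append(
                {"site": site, "parameter": param, "value": value, "standard": limit, "verdict": verdict}
            )
    return pd.DataFrame(rows)
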