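"""Soil pollution indices and their band classifications.

Four classic single-site indices are implemented:

* geo-accumulation index  I_geo = log2(Cm / (1.5 Bm)), Mueller's seven
  contamination classes;
* enrichment factor       EF = (Cm/Fe)_sample / (Bm/Fe)_background, with Fe
  as the default conservative reference metal;
* contamination factor    CF = Cm / Bm;
* pollution load index    PLI = geometric mean of a site's CFs.

Band edges follow the conventional tables.  Where the published tables
leave boundary values unassigned, a documented closure is adopted so that
every classifier is a total partition of the real line:

* I_geo bands are left-closed, [k-1, k) for classes 1-6, class 0 below 0;
* EF: [5, 20] "Significantly" keeps its printed closed upper edge, so
  (20, 40] is "Very Strongly" and (40, inf) "Extremely";
* CF: the standard Hakanson "Moderate" band fills [1, 3); [3, 6] keeps its
  printed closed edges, (6, inf) is "Very Strongly".

Two EF summaries are reported: the five-band category and a boolean
anthropogenic-influence flag (EF > 1.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ConcentrationTable
from .references import ReferenceSet


class DomainError(ValueError):
    """An index was evaluated outside its mathematical domain."""


# ---------------------------------------------------------------------------
# band tables: (lower, upper, lower_closed, upper_closed, label)

_INF = math.inf

BAND_TABLES: dict[str, list[tuple[float, float, bool, bool, str]]] = {
    "igeo": [
        (-_INF, 0.0, False, False, "almost uncontaminated"),
        (0.0, 1.0, True, False, "uncontaminated to rather polluted"),
        (1.0, 2.0, True, False, "somewhat contaminated"),
        (2.0, 3.0, True, False, "moderately to deeply contaminated"),
        (3.0, 4.0, True, False, "deeply contaminated"),
        (4.0, 5.0, True, False, "strongly to extremely contaminated"),
        (5.0, _INF, True, True, "extremely contaminated"),
    ],
    "ef": [
        (-_INF, 2.0, False, False, "No or minimal"),
        (2.0, 5.0, True, False, "Moderately"),
        (5.0, 20.0, True, True, "Significantly"),
        (20.0, 40.0, False, True, "Very Strongly"),
        (40.0, _INF, False, True, "Extremely"),
    ],
    "cf": [
        (-_INF, 1.0, False, False, "No or minimal"),
        (1.0, 3.0, True, False, "Moderate"),
        (3.0, 6.0, True, True, "Significantly considerable"),
        (6.0, _INF, False, True, "Very Strongly"),
    ],
    "pli": [
        (-_INF, 1.0, False, False, "no pollution load"),
        (1.0, _INF, True, True, "pollution load present"),
    ],
    "er": [
        (-_INF, 40.0, False, False, "Low"),
        (40.0, 80.0, True, False, "Moderate"),
        (80.0, 160.0, True, False, "Considerable"),
        (160.0, 320.0, True, False, "High"),
        (320.0, _INF, True, True, "Very high"),
    ],
    # the published PERI scale has no counterpart of the ER "High" band:
    # Considerable jumps to Very high at 600
    "peri": [
        (-_INF, 150.0, False, False, "Low"),
        (150.0, 300.0, True, False, "Moderate"),
        (300.0, 600.0, True, False, "Considerable"),
        (600.0, _INF, True, True, "Very high"),
    ],
    "hq": [
        (-_INF, 1.0, False, False, "no adverse effects expected"),
        (1.0, _INF, True, True, "potential adverse effects"),
    ],
    "hi": [
        (-_INF, 1.0, False, False, "no adverse effects expected"),
        (1.0, _INF, True, True, "potential adverse effects"),
    ],
    "cancer_risk": [
        (-_INF, 1e-6, False, False, "acceptable"),
        (1e-6, 1e-4, True, True, "tolerable"),
        (1e-4, _INF, False, True, "harmful"),
    ],
}

#: I_geo class numbers aligned with the igeo band table rows
IGEO_CLASS_NUMBERS = (0, 1, 2, 3, 4, 5, 6)


def classify_index(value: float, scheme: str) -> str:
    """Map a value to its unique band label under ``scheme``.

    Total over the reals: every finite value maps to exactly one band.
    """
    try:
        bands = BAND_TABLES[scheme]
    except KeyError:
        raise DomainError(f"unknown classification scheme {scheme!r}") from None
    if not math.isfinite(value):
        raise DomainError(f"cannot classify non-finite value {value!r}")
    for lo, hi, lo_closed, hi_closed, label in bands:
        above = value > lo or (lo_closed and value == lo)
        below = value < hi or (hi_closed and value == hi)
        if above and below:
            return label
    raise AssertionError(f"band tables for {scheme!r} do not partition the line")  # pragma: no cover


def igeo_class(value: float) -> int:
    """Mueller class number (0-6) of a geo-accumulation index value."""
    label = classify_index(value, "igeo")
    for number, (_, _, _, _, band_label) in zip(IGEO_CLASS_NUMBERS, BAND_TABLES["igeo"]):
        if band_label == label:
            return number
    raise AssertionError  # pragma: no cover


# ---------------------------------------------------------------------------
# scalar indices


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
            raise DomainError(f"{name} must be a positive finite number, got {value!r}")


def igeo(cm: float, bm: float) -> float:
    """Geo-accumulation index log2(cm / (1.5 bm)); the 1.5 buffers natural
    background fluctuation."""
    _require_positive(cm=cm, bm=bm)
    return math.log2(cm / (1.5 * bm))


def enrichment_factor(cm: float, fe_sample: float, bm: float, fe_background: float) -> float:
    """Double ratio (cm/fe_sample) / (bm/fe_background); invariant to any
    common rescaling of numerator or denominator pairs."""
    _require_positive(cm=cm, fe_sample=fe_sample, bm=bm, fe_background=fe_background)
    return (cm / fe_sample) / (bm / fe_background)


def contamination_factor(cm: float, bm: float) -> float:
    """CF = cm / bm."""
    _require_positive(cm=cm, bm=bm)
    return cm / bm


def pli(cfs) -> float:
    """Pollution load index: geometric mean of contamination factors,
    computed in log space for overflow safety."""
    cfs = list(cfs)
    if not cfs:
        raise DomainError("PLI needs at least one contamination factor")
    for i, cf in enumerate(cfs):
        if not (math.isfinite(cf) and cf > 0):
            raise DomainError(f"contamination factor #{i} must be positive, got {cf!r}")
    return float(math.exp(np.mean(np.log(cfs))))


# ---------------------------------------------------------------------------
# table drivers


@dataclass
class IndexResult:
    """Per-site/per-analyte values and band labels for one index scheme.

    For site-level schemes (pli, peri, hi) the analyte dimension collapses
    and ``values`` is indexed by site only.
    """

    scheme: str
    values: pd.DataFrame | pd.Series
    bands: pd.DataFrame | pd.Series
    metadata: dict = field(default_factory=dict)

    def to_tidy(self) -> pd.DataFrame:
        """Long-form frame: site, analyte (if any), value, band."""
        if isinstance(self.values, pd.Series):
            out = pd.DataFrame(
                {"site": self.values.index, "value": self.values.values, "band": self.bands.values}
            )
            return out
        rows = []
        for site in self.values.index:
            for analyte in self.values.columns:
                v = self.values.at[site, analyte]
                if pd.isna(v):
                    continue
                rows.append(
                    {
                        "site": site,
                        "analyte": analyte,
                        "value": v,
                        "band": self.bands.at[site, analyte],
                    }
                )
        return pd.DataFrame(rows)


def _covered_analytes(table: ConcentrationTable, constants: dict) -> list[str]:
    return [a for a in table.analytes if a in constants]


def igeo_table(soil: ConcentrationTable, refs: ReferenceSet) -> IndexResult:
    """Geo-accumulation index for every covered (site, analyte) cell."""
    analytes = _covered_analytes(soil, refs.background)
    values = pd.DataFrame(index=soil.sites, columns=analytes, dtype=float)
    for site in soil.sites:
        for analyte in analytes:
            cm = soil.data.at[site, analyte]
            if pd.isna(cm):
                continue
            values.at[site, analyte] = igeo(cm, refs.background[analyte])
    bands = values.map(lambda v: classify_index(v, "igeo") if pd.notna(v) else pd.NA)
    skipped = [a for a in soil.analytes if a not in analytes]
    return IndexResult("igeo", values, bands, {"skipped_analytes": skipped})


def enrichment_table(
    soil: ConcentrationTable, refs: ReferenceSet, reference_metal: str = "Fe"
) -> IndexResult:
    """Enrichment factors normalised against ``reference_metal`` (default Fe)."""
    if reference_metal not in soil.analytes:
        raise DomainError(f"reference metal {reference_metal!r} absent from the soil table")
    if reference_metal not in refs.background:
        raise DomainError(f"no background for reference metal {reference_metal!r}")
    analytes = [
        a for a in _covered_analytes(soil, refs.background) if a != reference_metal
    ]
    values = pd.DataFrame(index=soil.sites, columns=analytes, dtype=float)
    for site in soil.sites:
        fe_s = soil.data.at[site, reference_metal]
        if pd.isna(fe_s):
            continue
        for analyte in analytes:
            cm = soil.data.at[site, analyte]
            if pd.isna(cm):
                continue
            values.at[site, analyte] = enrichment_factor(
                cm, fe_s, refs.background[analyte], refs.background[reference_metal]
            )
    bands = values.map(lambda v: classify_index(v, "ef") if pd.notna(v) else pd.NA)
    anthropogenic = values.map(lambda v: bool(v > 1.5) if pd.notna(v) else pd.NA)
    return IndexResult(
        "ef",
        values,
        bands,
        {"reference_metal": reference_metal, "anthropogenic_flag": anthropogenic},
    )


def contamination_table(soil: ConcentrationTable, refs: ReferenceSet) -> IndexResult:
    analytes = _covered_analytes(soil, refs.background)
    values = pd.DataFrame(index=soil.sites, columns=analytes, dtype=float)
    for site in soil.sites:
        for analyte in analytes:
            cm = soil.data.at[site, analyte]
            if pd.isna(cm):
                continue
            values.at[site, analyte] = contamination_factor(cm, refs.background[analyte])
    bands = values.map(lambda v: classify_index(v, "cf") if pd.notna(v) else pd.NA)
    return IndexResult("cf", values, bands, {})


def pli_table(
    soil: ConcentrationTable, refs: ReferenceSet, analytes: list[str] | None = None
) -> IndexResult:
    """Per-site PLI over all analytes with a configured background (default)."""
    cf_result = contamination_table(soil, refs)
    if analytes is None:
        analytes = list(cf_result.values.columns)
    values = pd.Series(index=soil.sites, dtype=float, name="pli")
    for site in soil.sites:
        cfs = [
            cf_result.values.at[site, a]
            for a in analytes
            if a in cf_result.values.columns and pd.notna(cf_result.values.at[site, a])
        ]
        if cfs:
            values.at[site] = pli(cfs)
    bands = values.map(lambda v: classify_index(v, "pli") if pd.notna(v) else pd.NA)
    return IndexResult("pli", values, bands, {"analytes": analytes})
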