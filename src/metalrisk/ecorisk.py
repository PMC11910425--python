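"""Hakanson ecological risk: per-metal risk factor and site-level index.

The ecological risk factor weights a metal's contamination factor by its
biological toxic-response factor, ER = Tr x (Cm / Bm); the potential
ecological risk index PERI is the per-site sum of ER over the assessed
metals.  Metals without a configured toxic-response factor (here Fe and Mn)
are excluded, as is conventional.

``back_compute_concentration`` inverts the chain (Cm = ER x Bm / Tr); it is
the basis of the packaged fixture, which reconstructs per-site soil
concentrations from a published ER table.
"""

from __future__ import annotations

import math

import pandas as pd

from .containers import ConcentrationTable
from .indices import DomainError, IndexResult, classify_index
from .references import ReferenceSet


def ecological_risk_factor(cm: float, bm: float, tr: float) -> float:
    """ER = tr * (cm / bm)."""
    for name, v in (("cm", cm), ("bm", bm), ("tr", tr)):
        if not (math.isfinite(v) and v > 0):
            raise DomainError(f"{name} must be positive and finite, got {v!r}")
    return tr * (cm / bm)


def peri(er_values) -> float:
    """Potential ecological risk index: arithmetic sum of ER values."""
    er_values = list(er_values)
    if not er_values:
        raise DomainError("PERI needs at least one ecological risk factor")
    for i, er in enumerate(er_values):
        if not (math.isfinite(er) and er >= 0):
            raise DomainError(f"ER #{i} must be finite and non-negative, got {er!r}")
    return float(sum(er_values))


def classify_ecological(value: float, scheme: str) -> str:
    """Band label for an ER or PERI value (scheme 'er' or 'peri')."""
    if scheme not in ("er", "peri"):
        raise DomainError(f"scheme must be 'er' or 'peri', got {scheme!r}")
    if not (math.isfinite(value) and value >= 0):
        raise DomainError(f"{scheme} value must be non-negative, got {value!r}")
    return classify_index(value, scheme)


def back_compute_concentration(er: float, bm: float, tr: float) -> float:
    """Invert the ecological-risk chain: Cm = er * bm / tr.

    Exact round trip with :func:`ecological_risk_factor`; used to rebuild
    concentrations from published ER tables.
    """
    if not (math.isfinite(er) and er >= 0):
        raise DomainError(f"er must be finite and non-negative, got {er!r}")
    for name, v in (("bm", bm), ("tr", tr)):
        if not (math.isfinite(v) and v > 0):
            raise DomainError(f"{name} must be positive and finite, got {v!r}")
    return er * bm / tr


def ecological_risk_table(soil: ConcentrationTable, refs: ReferenceSet) -> tuple[IndexResult, IndexResult]:
    """Per-(site, metal) ER plus per-site PERI for all covered metals.

    Returns ``(er_result, peri_result)``.  Only analytes with both a
    background and a toxic-response factor contribute.
    """
    analytes = [
        a for a in soil.analytes if a in refs.background and a in refs.toxic_response
    ]
    er_values = pd.DataFrame(index=soil.sites, columns=analytes, dtype=float)
    for site in soil.sites:
        for analyte in analytes:
            cm = soil.data.at[site, analyte]
            if pd.isna(cm):
                continue
            er_values.at[site, analyte] = ecological_risk_factor(
                cm, refs.background[analyte], refs.toxic_response[analyte]
            )
    er_bands = er_values.map(lambda v: classify_index(v, "er") if pd.notna(v) else pd.NA)
    skipped = [a for a in soil.analytes if a not in analytes]
    er_result = IndexResult("er", er_values, er_bands, {"skipped_analytes": skipped})

    peri_values = pd.Series(index=soil.sites, dtype=float, name="peri")
    for site in soil.sites:
        row = er_values.loc[site].dropna()
        if len(row):
            peri_values.at[site] = peri(row.tolist())
    peri_bands = peri_values.map(lambda v: classify_index(v, "peri") if pd.notna(v) else pd.NA)
    peri_result = IndexResult("peri", peri_values, peri_bands, {"analytes": analytes})
    return er_result, peri_result
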