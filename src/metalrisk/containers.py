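"""Validated tabular containers for site-by-analyte measurements.

Three compartments are modelled: riverbank ``soil`` and ``plant`` tissue
(both mg/kg dry weight) and ``wastewater`` (mg/L).  A
:class:`ConcentrationTable` holds strictly positive concentrations for one
compartment, with missing cells stored as genuinely absent (``NaN``), never
as zero or a sentinel.  :class:`WaterQualityTable` carries the wastewater
physicochemical panel (pH, EC, DO, COD, TDS) together with the discharge
standard it is judged against.

All identifiers are case-normalised on construction: metal names to element
style (``"cd"`` -> ``"Cd"``), site labels to upper case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COMPARTMENTS = ("soil", "plant", "wastewater")

#: required unit per compartment; units are declared, never inferred
UNIT_FOR_COMPARTMENT = {"soil": "mg/kg", "plant": "mg/kg", "wastewater": "mg/L"}

WATER_QUALITY_PARAMETERS = ("pH", "EC", "DO", "COD", "TDS")

#: Bangladeshi effluent-discharge standard (BECR 2023): interval for pH and
#: DO, single upper limits for EC (mS/cm), COD and TDS (mg/L).
BECR_DISCHARGE_STANDARD: dict[str, float | tuple[float, float]] = {
    "pH": (6.0, 9.0),
    "EC": 1.2,
    "DO": (4.5, 8.0),
    "COD": 125.0,
    "TDS": 2100.0,
}


class ValidationError(ValueError):
    """A table or constant violates a domain invariant."""


class ParseError(ValueError):
    """A CSV cell could not be interpreted as a concentration."""


def normalize_metal(name: str) -> str:
    """Case-normalise a metal identifier to element-symbol style."""
    return str(name).strip().capitalize()


def normalize_site(name: str) -> str:
    """Case-normalise a site identifier (upper case, stripped)."""
    return str(name).strip().upper()


@dataclass
class ConcentrationTable:
    """Positive concentrations for one compartment, sites x analytes.

    Parameters
    ----------
    compartment : {"soil", "plant", "wastewater"}
    unit : str
        ``"mg/kg"`` for soil/plant, ``"mg/L"`` for wastewater.  Must match
        the compartment; no automatic conversion is attempted.
    data : pandas.DataFrame
        Sites on the index, analytes on the columns.  ``NaN`` marks a
        missing cell; every stored value must be finite and > 0.
    parse_log : list of str
        Human-readable notes accumulated while reading (missing cells,
        dropped rows).  Empty for tables built in memory.
    """

    compartment: str
    unit: str
    data: pd.DataFrame
    parse_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"unknown compartment {self.compartment!r}; expected one of {COMPARTMENTS}"
            )
        expected = UNIT_FOR_COMPARTMENT[self.compartment]
        if self.unit != expected:
            raise ValidationError(
                f"compartment {self.compartment!r} requires unit {expected!r}, got {self.unit!r}"
            )
        df = self.data.copy()
        df.index = [normalize_site(s) for s in df.index]
        df.columns = [normalize_metal(c) for c in df.columns]
        if len(set(df.index)) != len(df.index):
            dupes = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate site identifiers after normalisation: {dupes}")
        if len(set(df.columns)) != len(df.columns):
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate analyte identifiers after normalisation: {dupes}")
        df = df.astype(float)
        for site in df.index:
            for analyte in df.columns:
                v = df.at[site, analyte]
                if pd.isna(v):
                    continue
                if not math.isfinite(v) or v <= 0:
                    raise ValidationError(
                        f"non-positive or non-finite concentration {v!r} at "
                        f"site {site!r}, analyte {analyte!r}"
                    )
        self.data = df

    @property
    def sites(self) -> list[str]:
        return list(self.data.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.data.columns)

    def value(self, site: str, analyte: str) -> float:
        """Return one cell; KeyError if absent, NaN if recorded missing."""
        return float(self.data.at[normalize_site(site), normalize_metal(analyte)])

    def means(self) -> pd.Series:
        """Per-analyte mean over sites, skipping missing cells."""
        return self.data.mean(axis=0, skipna=True)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "site"
        # repr-precision floats so a write/read round trip is lossless
        out.to_csv(path, float_format=None)

    @classmethod
    def from_csv(cls, path, compartment: str, unit: str | None = None) -> "ConcentrationTable":
        return load_concentration_table(path, compartment, unit)


def load_concentration_table(path, compartment: str, unit: str | None = None) -> ConcentrationTable:
    """Read a ``site,<analyte>,...`` CSV into a validated ConcentrationTable.

    Empty cells are recorded as missing and listed in ``parse_log``; a
    non-numeric cell raises :class:`ParseError` naming the offending
    row/column; a zero or negative value raises :class:`ValidationError`.
    """
    if unit is None:
        unit = UNIT_FOR_COMPARTMENT.get(compartment)
        if unit is None:
            raise ValidationError(f"unknown compartment {compartment!r}")
    raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    log: list[str] = []
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for site in raw.index:
        for col in raw.columns:
            cell = raw.at[site, col].strip() if isinstance(raw.at[site, col], str) else raw.at[site, col]
            if cell == "" or cell is None:
                numeric.at[site, col] = np.nan
                log.append(f"missing cell: site {site!r}, analyte {col!r}")
                continue
            try:
                numeric.at[site, col] = float(cell)
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"non-numeric cell {cell!r} at site {site!r}, analyte {col!r} in {path}"
                ) from exc
    return ConcentrationTable(compartment=compartment, unit=unit, data=numeric, parse_log=log)


@dataclass
class WaterQualityTable:
    """Per-site wastewater physicochemical panel plus a discharge standard.

    ``data`` has sites on the index and the parameters pH (unitless),
    EC (mS/cm), DO, COD, TDS (mg/L) on the columns.  ``standard`` maps a
    parameter to either a single permitted upper limit or a
    ``(lower, upper)`` interval.
    """

    data: pd.DataFrame
    standard: dict = field(default_factory=lambda: dict(BECR_DISCHARGE_STANDARD))

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = [normalize_site(s) for s in df.index]
        df = df.astype(float)
        if "pH" in df.columns:
            bad = df["pH"][(df["pH"] <= 0) | (df["pH"] >= 14)]
            if len(bad):
                raise ValidationError(f"pH out of (0, 14) at sites {list(bad.index)}")
        for col in df.columns:
            if col == "pH":
                continue
            bad = df[col][df[col] < 0]
            if len(bad):
                raise ValidationError(f"negative {col} at sites {list(bad.index)}")
        for param, lim in self.standard.items():
            if isinstance(lim, (tuple, list)):
                lo, hi = lim
                if lo > hi:
                    raise ValidationError(f"standard interval for {param} has lower > upper")
        self.data = df

    @property
    def sites(self) -> list[str]:
        return list(self.data.index)

    @property
    def parameters(self) -> list[str]:
        return list(self.data.columns)
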