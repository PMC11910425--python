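"""Registry of reference constants: geochemical backgrounds, toxicity factors,
reference doses, slope factors, guideline limits and USEPA exposure profiles.

The packaged defaults target the eight metals assessed at the study site
(Cr, Cd, Ni, Cu, Zn, Pb, Fe, Mn):

* geochemical baseline — global average-shale concentrations;
* Hakanson biological toxic-response factors (Cr 2, Cd 30, Ni 5, Cu 5,
  Zn 1, Pb 5);
* chronic oral slope factors, gastrointestinal absorption fractions and
  inhalation unit risks for the IARC-listed carcinogens Pb, Cr, Cd, Ni;
* a documented standard USEPA-style reference-dose table (oral, dermal,
  inhalation), config-overridable — dermal RfDs follow the convention
  RfD_dermal = RfD_oral x ABS_GI where an absorption fraction is published;
* soil guideline limits (Germany, Netherlands, Sweden, FAO) and edible-plant
  limits (FAO/WHO, BFSA 2013).

Every constant can be overlaid from a YAML config; provenance (``default``
vs ``user``) is retained per key for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import yaml

from .containers import ValidationError, normalize_metal

#: global average-shale metal concentrations, mg/kg
AVERAGE_SHALE_BACKGROUND = {
    "Cr": 90.0,
    "Cd": 0.3,
    "Ni": 68.0,
    "Cu": 45.0,
    "Zn": 95.0,
    "Pb": 20.0,
    "Fe": 47200.0,
    "Mn": 850.0,
}

#: Hakanson biological toxic-response factors (dimensionless)
TOXIC_RESPONSE_FACTORS = {"Cr": 2.0, "Cd": 30.0, "Ni": 5.0, "Cu": 5.0, "Zn": 1.0, "Pb": 5.0}

#: chronic oral cancer slope factors, (mg kg^-1 day^-1)^-1
CSF_ORAL = {"Pb": 0.0085, "Cr": 4.1, "Cd": 6.3, "Ni": 0.84}

#: gastrointestinal absorption fractions (dimensionless, (0, 1])
ABS_GI = {"Pb": 1.0, "Cr": 0.013, "Cd": 0.025, "Ni": 0.04}

#: chronic inhalation unit risks, (ug m^-3)^-1
INHALATION_UNIT_RISK = {"Pb": 1.2e-5, "Cr": 1.2e-3, "Cd": 1.8e-3, "Ni": 2.6e-4}

# Standard chronic reference doses, mg kg^-1 day^-1.  Oral values are the
# USEPA IRIS/RSL figures commonly used in soil HQ screening; dermal values
# apply the gastrointestinal-absorption adjustment where one is published,
# otherwise fall back to the oral value; inhalation values are RfC-derived.
RFD_ORAL = {
    "Cr": 3.0e-3,
    "Cd": 1.0e-3,
    "Ni": 2.0e-2,
    "Cu": 4.0e-2,
    "Zn": 3.0e-1,
    "Pb": 3.5e-3,
    "Fe": 7.0e-1,
    "Mn": 1.4e-1,
}
RFD_DERMAL = {
    "Cr": 3.0e-3 * 0.013,
    "Cd": 1.0e-3 * 0.025,
    "Ni": 2.0e-2 * 0.04,
    "Cu": 4.0e-2,
    "Zn": 3.0e-1,
    "Pb": 3.5e-3 * 1.0,
    "Fe": 7.0e-1,
    "Mn": 1.4e-1,
}
RFD_INHALATION = {
    "Cr": 2.86e-5,
    "Cd": 1.0e-3,
    "Ni": 2.06e-2,
    "Cu": 4.02e-2,
    "Zn": 3.0e-1,
    "Pb": 3.52e-3,
    "Fe": 7.0e-1,
    "Mn": 1.43e-5,
}

#: guideline limits, mg/kg; tuples are (lower, upper) intervals
GUIDELINE_LIMITS: dict[str, dict[str, float | tuple[float, float]]] = {
    # soil guideline values
    "Germany": {"Cr": 60.0, "Cd": 1.0, "Ni": 50.0, "Cu": 40.0, "Zn": 150.0, "Pb": 70.0},
    "Netherlands": {"Cr": 30.0, "Cd": 0.5, "Ni": 15.0, "Cu": 40.0, "Zn": 100.0, "Pb": 40.0},
    "Sweden": {"Cr": 60.0, "Cd": 0.4, "Ni": 30.0, "Cu": 40.0, "Zn": (100.0, 150.0), "Pb": 40.0},
    "FAO": {"Cr": 100.0, "Cd": 1.0, "Ni": 50.0, "Cu": 100.0, "Zn": 200.0, "Pb": 50.0},
    # edible-plant guideline values
    "FAO/WHO": {
        "Cr": 2.30,
        "Cd": 0.20,
        "Ni": 2.70,
        "Cu": 10.0,
        "Zn": 50.0,
        "Pb": 0.30,
        "Fe": 425.0,
        "Mn": 500.0,
    },
    "BFSA": {"Cr": 1.0, "Cd": 0.20, "Ni": 1.0, "Pb": 0.30},
}

ROUTES = ("ingestion", "dermal", "inhalation")


@dataclass
class ExposureProfile:
    """USEPA residential-soil exposure parameters for one receptor.

    Units: IngR mg/day; EF days/year; ED years; BW kg; AT days;
    CF kg/mg; AF mg/cm^2; SA cm^2; InhR m^3/day; PEF m^3/kg; ET h/day.
    """

    receptor: str
    ingestion_rate: float
    exposure_frequency_days: float
    exposure_duration_years: float
    body_weight: float
    averaging_time_days: float
    unit_conversion_factor: float
    adherence_factor: float
    skin_area: float
    dermal_absorption: float
    inhalation_rate: float
    particle_emission_factor: float
    exposure_time_hours: float

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if name == "receptor":
                continue
            if not value > 0:
                raise ValidationError(f"exposure parameter {name} must be positive, got {value}")
        if self.exposure_frequency_days > 366:
            raise ValidationError("exposure frequency cannot exceed 366 days/year")
        if not 0 < self.dermal_absorption <= 1:
            raise ValidationError("dermal absorption fraction must lie in (0, 1]")

    @classmethod
    def adult(cls) -> "ExposureProfile":
        return cls(
            receptor="adult",
            ingestion_rate=100.0,
            exposure_frequency_days=350.0,
            exposure_duration_years=30.0,
            body_weight=70.0,
            averaging_time_days=365.0 * 70.0,
            unit_conversion_factor=1e-6,
            adherence_factor=0.07,
            skin_area=5700.0,
            dermal_absorption=0.01,
            inhalation_rate=20.0,
            particle_emission_factor=1.36e9,
            exposure_time_hours=24.0,
        )

    @classmethod
    def child(cls) -> "ExposureProfile":
        return cls(
            receptor="child",
            ingestion_rate=200.0,
            exposure_frequency_days=350.0,
            exposure_duration_years=6.0,
            body_weight=15.0,
            averaging_time_days=365.0 * 70.0,
            unit_conversion_factor=1e-6,
            adherence_factor=0.2,
            skin_area=1600.0,
            dermal_absorption=0.001,
            inhalation_rate=20.0,
            particle_emission_factor=1.36e9,
            exposure_time_hours=24.0,
        )

    def with_noncancer_averaging_time(self) -> "ExposureProfile":
        """Copy with the conventional non-carcinogenic AT = ED x 365 days."""
        return replace(self, averaging_time_days=self.exposure_duration_years * 365.0)


@dataclass
class ReferenceSet:
    """Per-metal constants consumed by every index and risk module."""

    background: dict[str, float] = field(default_factory=lambda: dict(AVERAGE_SHALE_BACKGROUND))
    toxic_response: dict[str, float] = field(default_factory=lambda: dict(TOXIC_RESPONSE_FACTORS))
    rfd: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "ingestion": dict(RFD_ORAL),
            "dermal": dict(RFD_DERMAL),
            "inhalation": dict(RFD_INHALATION),
        }
    )
    csf_ing: dict[str, float] = field(default_factory=lambda: dict(CSF_ORAL))
    iur: dict[str, float] = field(default_factory=lambda: dict(INHALATION_UNIT_RISK))
    abs_gi: dict[str, float] = field(default_factory=lambda: dict(ABS_GI))
    guidelines: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in GUIDELINE_LIMITS.items()}
    )
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for block_name, block in [
            ("background", self.background),
            ("toxic_response", self.toxic_response),
            ("csf_ing", self.csf_ing),
            ("iur", self.iur),
            ("abs_gi", self.abs_gi),
        ]:
            for metal, value in block.items():
                if not value > 0:
                    raise ValidationError(
                        f"{block_name}[{metal}] must be strictly positive, got {value}"
                    )
        for metal, value in self.abs_gi.items():
            if not 0 < value <= 1:
                raise ValidationError(f"abs_gi[{metal}] must lie in (0, 1], got {value}")
        for route, table in self.rfd.items():
            if route not in ROUTES:
                raise ValidationError(f"unknown exposure route {route!r}")
            for metal, value in table.items():
                if not value > 0:
                    raise ValidationError(f"rfd[{route}][{metal}] must be positive, got {value}")
        if not self.provenance:
            self.provenance = {
                f"{block}.{key}": "default"
                for block, mapping in self._blocks().items()
                for key in mapping
            }

    def _blocks(self) -> dict[str, dict]:
        return {
            "background": self.background,
            "toxic_response": self.toxic_response,
            "csf_ing": self.csf_ing,
            "iur": self.iur,
            "abs_gi": self.abs_gi,
        }


def load_reference_set(path=None, overrides: dict | None = None) -> ReferenceSet:
    """Packaged defaults overlaid by a YAML config (or an overrides dict).

    Unknown metal keys are retained with a warning; a non-positive constant
    raises.  Per-constant provenance records whether the value came from
    the defaults or the user config.
    """
    config: dict = {}
    if path is not None:
        with open(path) as fh:
            config = yaml.safe_load(fh) or {}
    if overrides:
        config.update(overrides)

    refs = ReferenceSet()
    known = set(AVERAGE_SHALE_BACKGROUND)
    for block_name in ("background", "toxic_response", "csf_ing", "iur", "abs_gi"):
        user_block = config.get(block_name) or {}
        target = getattr(refs, block_name)
        for metal, value in user_block.items():
            metal = normalize_metal(metal)
            if metal not in known:
                warnings.warn(
                    f"reference constant for unknown metal {metal!r} in block "
                    f"{block_name!r}: retained",
                    stacklevel=2,
                )
            target[metal] = float(value)
            refs.provenance[f"{block_name}.{metal}"] = "user"
    for route, table in (config.get("rfd") or {}).items():
        if route not in ROUTES:
            raise ValidationError(f"unknown exposure route {route!r} in rfd block")
        for metal, value in table.items():
            metal = normalize_metal(metal)
            refs.rfd[route][metal] = float(value)
            refs.provenance[f"rfd.{route}.{metal}"] = "user"
    for authority, table in (config.get("guidelines") or {}).items():
        dest = refs.guidelines.setdefault(authority, {})
        for analyte, limit in table.items():
            dest[normalize_metal(analyte)] = (
                tuple(limit) if isinstance(limit, (list, tuple)) else float(limit)
            )
            refs.provenance[f"guidelines.{authority}.{normalize_metal(analyte)}"] = "user"
    # re-validate after the overlay
    return ReferenceSet(
        background=refs.background,
        toxic_response=refs.toxic_response,
        rfd=refs.rfd,
        csf_ing=refs.csf_ing,
        iur=refs.iur,
        abs_gi=refs.abs_gi,
        guidelines=refs.guidelines,
        provenance=refs.provenance,
    )


def validate_alignment(conc, refs: ReferenceSet, needed: list[str]) -> dict[str, dict[str, bool]]:
    """Report, per analyte, which requested constant blocks cover it.

    Downstream stages consult this report to *skip* uncovered analytes
    rather than fail.  ``needed`` names ReferenceSet blocks, e.g.
    ``["background", "toxic_response"]``.  Report-only: never raises.
    """
    report: dict[str, dict[str, bool]] = {}
    blocks = {
        "background": refs.background,
        "toxic_response": refs.toxic_response,
        "csf_ing": refs.csf_ing,
        "iur": refs.iur,
        "abs_gi": refs.abs_gi,
        "rfd": {m for table in refs.rfd.values() for m in table},
    }
    for analyte in conc.analytes:
        row = {}
        for block_name in needed:
            covered = analyte in blocks.get(block_name, {})
            row[block_name] = covered
        report[analyte] = row
    return report
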