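"""USEPA three-route human exposure model for metal-contaminated soil.

Chronic daily intake (CDI, mg kg^-1 day^-1) is computed for incidental
ingestion, dermal contact and inhalation of resuspended particulates;
non-carcinogenic hazard is CDI / RfD per metal and route, aggregated into a
hazard index; carcinogenic risk applies oral slope factors (ingestion,
dermal with the gastrointestinal-absorption adjustment) and the inhalation
unit risk, aggregated into a total lifetime risk.

Two equation conventions are supported:

* ``default`` — the standard USEPA forms: inhalation CDI divides by the
  particle emission factor, and ingestion CR excludes the dermal adherence
  factor;
* ``literal`` — reproduces the source report's printed equations verbatim
  (inhalation CDI with the exposure frequency squared and the mass
  conversion factor in place of PEF; ingestion CR including AF).

The dermal slope factor is defined as CSF_oral / ABS_GI, so the dermal-risk
product CSF_d x ABS_GI algebraically reduces to CSF_oral; the reduction is
applied directly and surfaced in the aggregation notes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .containers import ConcentrationTable
from .indices import DomainError, classify_index
from .references import ExposureProfile, ReferenceSet


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
            raise DomainError(f"{name} must be positive and finite, got {value!r}")


# ---------------------------------------------------------------------------
# chronic daily intake


def cdi_ingestion(cs: float, profile: ExposureProfile) -> float:
    """CDI_ing = CS x IngR x EF x ED / (BW x AT) x CF."""
    _check_positive(cs=cs)
    p = profile
    return (
        cs
        * p.ingestion_rate
        * p.exposure_frequency_days
        * p.exposure_duration_years
        / (p.body_weight * p.averaging_time_days)
        * p.unit_conversion_factor
    )


def cdi_dermal(cs: float, profile: ExposureProfile) -> float:
    """CDI_dermal = CS x SA x AF x ABS_d x EF x ED / (BW x AT) x CF."""
    _check_positive(cs=cs)
    p = profile
    return (
        cs
        * p.skin_area
        * p.adherence_factor
        * p.dermal_absorption
        * p.exposure_frequency_days
        * p.exposure_duration_years
        / (p.body_weight * p.averaging_time_days)
        * p.unit_conversion_factor
    )


def cdi_inhalation(cs: float, profile: ExposureProfile, literal: bool = False) -> float:
    """Inhalation CDI.

    Default: CS x InhR x EF x ED / (BW x AT x PEF) — the particle emission
    factor converts the soil concentration to an airborne one.  Literal
    mode reproduces the source report's printed equation, which repeats EF
    and applies the mass conversion factor instead of PEF; the two differ
    by exactly the factor EF x CF x PEF.
    """
    _check_positive(cs=cs)
    p = profile
    if literal:
        return (
            cs
            * p.inhalation_rate
            * p.exposure_frequency_days
            * p.exposure_duration_years
            * p.exposure_frequency_days
            / (p.body_weight * p.averaging_time_days)
            * p.unit_conversion_factor
        )
    return (
        cs
        * p.inhalation_rate
        * p.exposure_frequency_days
        * p.exposure_duration_years
        / (p.body_weight * p.averaging_time_days * p.particle_emission_factor)
    )


# ---------------------------------------------------------------------------
# non-carcinogenic hazard


def hazard_quotient(cdi: float, rfd: float) -> float:
    """HQ = CDI / RfD; 1 is the adverse-effect threshold."""
    if not (math.isfinite(rfd) and rfd > 0):
        raise DomainError(f"reference dose must be positive, got {rfd!r}")
    if not (math.isfinite(cdi) and cdi >= 0):
        raise DomainError(f"CDI must be non-negative, got {cdi!r}")
    return cdi / rfd


def hazard_index(hqs, composition: str | None = None) -> tuple[float, str]:
    """Sum of hazard quotients; returns (HI, composition note)."""
    hqs = list(hqs)
    if not hqs:
        raise DomainError("hazard index needs at least one hazard quotient")
    for i, hq in enumerate(hqs):
        if not (math.isfinite(hq) and hq >= 0):
            raise DomainError(f"HQ #{i} must be non-negative, got {hq!r}")
    return float(sum(hqs)), composition or f"sum of {len(hqs)} hazard quotients"


# ---------------------------------------------------------------------------
# carcinogenic risk


def cr_ingestion(cs: float, profile: ExposureProfile, csf_ing: float, literal: bool = False) -> float:
    """Ingestion cancer risk CDI_ing x CSF_oral.

    Literal mode additionally multiplies by the dermal adherence factor,
    as printed in the source report; default excludes it, consistent with
    the ingestion CDI.
    """
    _check_positive(cs=cs, csf_ing=csf_ing)
    risk = cdi_ingestion(cs, profile) * csf_ing
    if literal:
        risk *= profile.adherence_factor
    return risk


def cr_dermal(cs: float, profile: ExposureProfile, csf_ing: float, abs_gi: float = 1.0) -> float:
    """Dermal cancer risk.

    With CSF_dermal = CSF_oral / ABS_GI, the product CSF_d x ABS_GI in the
    dermal-risk equation reduces to CSF_oral, so the result is
    CDI_dermal x CSF_oral and is invariant to ABS_GI.  The argument is
    validated but only enters through the (cancelling) reduction.
    """
    _check_positive(cs=cs, csf_ing=csf_ing)
    if not 0 < abs_gi <= 1:
        raise DomainError(f"abs_gi must lie in (0, 1], got {abs_gi!r}")
    csf_dermal = csf_ing / abs_gi
    return cdi_dermal(cs, profile) * csf_dermal * abs_gi


def cr_inhalation(cs: float, profile: ExposureProfile, iur: float) -> float:
    """Inhalation cancer risk CS x ET x EF x ED x IUR x 10^3 / (PEF x 24 x AT).

    The 10^3 converts mg/kg soil to ug/m^3 air through PEF so the
    inhalation unit risk (per ug/m^3) applies.
    """
    _check_positive(cs=cs, iur=iur)
    p = profile
    return (
        cs
        * p.exposure_time_hours
        * p.exposure_frequency_days
        * p.exposure_duration_years
        * iur
        * 1e3
        / (p.particle_emission_factor * 24.0 * p.averaging_time_days)
    )


def cr_total(crs, composition: str | None = None) -> tuple[float, str]:
    """Total carcinogenic risk: sum of route/metal risks, with a note."""
    crs = list(crs)
    if not crs:
        raise DomainError("total cancer risk needs at least one constituent risk")
    for i, cr in enumerate(crs):
        if not (math.isfinite(cr) and 0 <= cr < 1):
            raise DomainError(f"CR #{i} must lie in [0, 1), got {cr!r}")
    return float(sum(crs)), composition or f"sum of {len(crs)} route/metal risks"


def classify_cancer_risk(value: float) -> str:
    """Band a lifetime cancer risk: acceptable < 1e-6 <= tolerable <= 1e-4 < harmful."""
    if not (math.isfinite(value) and value >= 0):
        raise DomainError(f"cancer risk must be non-negative, got {value!r}")
    return classify_index(value, "cancer_risk")


# ---------------------------------------------------------------------------
# table driver


@dataclass
class RiskBreakdown:
    """CDI / HQ / CR per metal and route for one receptor, with aggregates.

    ``hi`` is the hazard index under the declared composition (dermal-only,
    matching the published aggregation); ``hi_all_routes`` sums every
    computed HQ.  ``cr_total`` sums every computed CR.
    """

    receptor: str
    cdi: pd.DataFrame
    hq: pd.DataFrame
    cr: pd.DataFrame
    hi: float
    hi_all_routes: float
    cr_total: float
    aggregation_note: dict = field(default_factory=dict)
    mode: str = "default"

    def __post_init__(self) -> None:
        for frame, name in ((self.cdi, "cdi"), (self.hq, "hq"), (self.cr, "cr")):
            vals = frame.values.ravel()
            if any(v < 0 for v in vals if pd.notna(v)):
                raise DomainError(f"negative value in {name} table")
        if any(v >= 1 for v in self.cr.values.ravel() if pd.notna(v)):
            raise DomainError("carcinogenic risk must be < 1")


def assess_health_risk(
    soil: ConcentrationTable,
    refs: ReferenceSet,
    profiles: tuple[ExposureProfile, ...] | None = None,
    literal_equations: bool = False,
    noncancer_averaging_time: str = "printed",
) -> dict[str, RiskBreakdown]:
    """Full three-route assessment from per-metal mean soil concentrations.

    ``noncancer_averaging_time``: ``"printed"`` keeps AT = 365 x 70 days for
    both endpoint classes (as tabulated in the source report);
    ``"ed365"`` uses the conventional non-carcinogenic AT = ED x 365.
    """
    if profiles is None:
        profiles = (ExposureProfile.adult(), ExposureProfile.child())
    if noncancer_averaging_time not in ("printed", "ed365"):
        raise DomainError("noncancer_averaging_time must be 'printed' or 'ed365'")
    means = soil.means().dropna()
    routes = ["ingestion", "dermal", "inhalation"]
    mode = "literal" if literal_equations else "default"
    out: dict[str, RiskBreakdown] = {}
    for profile in profiles:
        nc_profile = (
            profile.with_noncancer_averaging_time()
            if noncancer_averaging_time == "ed365"
            else profile
        )
        metals = list(means.index)
        cdi = pd.DataFrame(index=routes, columns=metals, dtype=float)
        hq = pd.DataFrame(index=routes, columns=metals, dtype=float)
        cr = pd.DataFrame(index=routes, columns=metals, dtype=float)
        for metal in metals:
            cs = float(means[metal])
            nc_cdis = {
                "ingestion": cdi_ingestion(cs, nc_profile),
                "dermal": cdi_dermal(cs, nc_profile),
                "inhalation": cdi_inhalation(cs, nc_profile, literal=literal_equations),
            }
            for route in routes:
                cdi.at[route, metal] = nc_cdis[route]
                rfd = refs.rfd.get(route, {}).get(metal)
                if rfd is not None:
                    hq.at[route, metal] = hazard_quotient(nc_cdis[route], rfd)
            if metal in refs.csf_ing:
                cr.at["ingestion", metal] = cr_ingestion(
                    cs, profile, refs.csf_ing[metal], literal=literal_equations
                )
                cr.at["dermal", metal] = cr_dermal(
                    cs, profile, refs.csf_ing[metal], refs.abs_gi.get(metal, 1.0)
                )
            if metal in refs.iur:
                cr.at["inhalation", metal] = cr_inhalation(cs, profile, refs.iur[metal])

        dermal_hqs = hq.loc["dermal"].dropna()
        hi_dermal, hi_note = hazard_index(
            dermal_hqs.tolist(), f"dermal route, metals {list(dermal_hqs.index)}"
        )
        all_hqs = [v for v in hq.values.ravel() if pd.notna(v)]
        hi_all, _ = hazard_index(all_hqs, "all routes")
        all_crs = [v for v in cr.values.ravel() if pd.notna(v)]
        crt, cr_note = cr_total(
            all_crs, f"all routes, carcinogens {sorted(set(refs.csf_ing) | set(refs.iur))}"
        )
        out[profile.receptor] = RiskBreakdown(
            receptor=profile.receptor,
            cdi=cdi,
            hq=hq,
            cr=cr,
            hi=hi_dermal,
            hi_all_routes=hi_all,
            cr_total=crt,
            aggregation_note={
                "hi": hi_note,
                "hi_all_routes": "all computed routes and metals",
                "cr_total": cr_note,
                "dermal_csf_reduction": "CSF_dermal = CSF_oral/ABS_GI, so CSF_d x ABS_GI = CSF_oral",
                "noncancer_averaging_time": noncancer_averaging_time,
            },
            mode=mode,
        )
    return out
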