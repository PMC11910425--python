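"""One-call end-to-end assessment and its serialisable report.

``run_full_assessment`` executes every stage whose inputs are available —
pollution indices, ecological risk, human health risk, transfer factors,
wastewater correlations, guideline exceedance and discharge compliance —
and records per-stage status (run/skipped with a reason) so partial inputs
never silently drop results.  The report serialises losslessly to JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import pandas as pd

from . import ecorisk, exposure, indices, transfer
from .containers import ConcentrationTable, WaterQualityTable
from .references import ExposureProfile, ReferenceSet, validate_alignment


class NothingRunnableError(RuntimeError):
    """No assessment stage had sufficient inputs."""


def _frame_to_jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return {
            "index": list(obj.index),
            "columns": list(obj.columns),
            "data": [[None if pd.isna(v) else v for v in row] for row in obj.values.tolist()],
        }
    if isinstance(obj, pd.Series):
        return {"index": list(obj.index), "data": [None if pd.isna(v) else v for v in obj.values]}
    if isinstance(obj, dict):
        return {str(k): _frame_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_frame_to_jsonable(v) for v in obj]
    if isinstance(obj, float) and pd.isna(obj):
        return None
    return obj


@dataclass
class AssessmentReport:
    """Structured results of one pipeline run, JSON-serialisable."""

    results: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)  # stage -> {"status", "reason"}
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return _frame_to_jsonable(
            {"results": self.results, "stages": self.stages, "metadata": self.metadata}
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @property
    def stages_run(self) -> list[str]:
        return [s for s, v in self.stages.items() if v["status"] == "run"]

    @property
    def stages_skipped(self) -> list[str]:
        return [s for s, v in self.stages.items() if v["status"] == "skipped"]


def _index_result_payload(result: indices.IndexResult) -> dict:
    return {
        "values": result.values,
        "bands": result.bands,
        "metadata": {
            k: v for k, v in result.metadata.items() if not isinstance(v, pd.DataFrame)
        },
    }


def run_full_assessment(
    soil: ConcentrationTable | None = None,
    plant: ConcentrationTable | None = None,
    wastewater: ConcentrationTable | None = None,
    wq: WaterQualityTable | None = None,
    refs: ReferenceSet | None = None,
    profiles: tuple[ExposureProfile, ...] | None = None,
    literal_equations: bool = False,
    noncancer_averaging_time: str = "printed",
) -> AssessmentReport:
    """Run every stage with available inputs; skip (and log) the rest.

    Raises :class:`NothingRunnableError`, with the alignment report
    attached, if no stage can run at all.
    """
    refs = refs or ReferenceSet()
    report = AssessmentReport()
    rep_stages = report.stages
    results = report.results

    def skip(stage: str, reason: str) -> None:
        rep_stages[stage] = {"status": "skipped", "reason": reason}

    def ran(stage: str) -> None:
        rep_stages[stage] = {"status": "run", "reason": ""}

    if soil is not None and len(soil.sites):
        alignment = validate_alignment(soil, refs, ["background", "toxic_response", "rfd"])
        results["alignment"] = alignment

        results["igeo"] = _index_result_payload(indices.igeo_table(soil, refs))
        results["cf"] = _index_result_payload(indices.contamination_table(soil, refs))
        results["pli"] = _index_result_payload(indices.pli_table(soil, refs))
        ran("pollution_indices")
        try:
            ef = indices.enrichment_table(soil, refs)
            results["ef"] = _index_result_payload(ef)
            results["ef"]["anthropogenic_flag"] = ef.metadata["anthropogenic_flag"]
        except indices.DomainError as exc:
            skip("enrichment_factor", str(exc))
        else:
            ran("enrichment_factor")

        er_result, peri_result = ecorisk.ecological_risk_table(soil, refs)
        results["er"] = _index_result_payload(er_result)
        results["peri"] = _index_result_payload(peri_result)
        ran("ecological_risk")

        breakdowns = exposure.assess_health_risk(
            soil,
            refs,
            profiles=profiles,
            literal_equations=literal_equations,
            noncancer_averaging_time=noncancer_averaging_time,
        )
        results["health_risk"] = {
            receptor: {
                "cdi": b.cdi,
                "hq": b.hq,
                "cr": b.cr,
                "hi": b.hi,
                "hi_all_routes": b.hi_all_routes,
                "cr_total": b.cr_total,
                "cr_total_band": exposure.classify_cancer_risk(b.cr_total),
                "aggregation_note": b.aggregation_note,
                "mode": b.mode,
            }
            for receptor, b in breakdowns.items()
        }
        ran("health_risk")

        soil_auth = [a for a in ("Germany", "Netherlands", "Sweden", "FAO") if a in refs.guidelines]
        results["soil_exceedance"] = transfer.exceedance_table(soil.means(), refs, soil_auth)
        ran("soil_exceedance")
    else:
        for stage in (
            "pollution_indices",
            "enrichment_factor",
            "ecological_risk",
            "health_risk",
            "soil_exceedance",
        ):
            skip(stage, "no soil table provided")

    if plant is not None and soil is not None:
        tf_result = transfer.transfer_table(plant, soil)
        results["transfer"] = {"tf": tf_result.tf, "summary": tf_result.summary}
        ran("transfer_factors")
    else:
        skip("transfer_factors", "needs both plant and soil tables")

    if plant is not None:
        plant_auth = [a for a in ("FAO/WHO", "BFSA") if a in refs.guidelines]
        results["plant_exceedance"] = transfer.exceedance_table(plant.means(), refs, plant_auth)
        ran("plant_exceedance")
    else:
        skip("plant_exceedance", "no plant table provided")

    if wastewater is not None and len(wastewater.sites) >= 3:
        corr = transfer.pearson_matrix(wastewater)
        results["correlation"] = {
            "r": corr.r,
            "n": corr.n,
            "missing": {f"{a}~{b}": why for (a, b), why in corr.missing.items()},
        }
        ran("correlation")
    else:
        skip(
            "correlation",
            "no wastewater table provided" if wastewater is None else "fewer than 3 sites",
        )

    if wq is not None:
        results["water_quality"] = transfer.water_quality_compliance(wq)
        ran("water_quality")
    else:
        skip("water_quality", "no physicochemical table provided")

    if not report.stages_run:
        alignment = (
            validate_alignment(soil, refs, ["background"]) if soil is not None else {}
        )
        raise NothingRunnableError(f"no stage had sufficient inputs; alignment: {alignment}")

    config_fingerprint = hashlib.sha256(
        json.dumps(
            {
                "background": refs.background,
                "toxic_response": refs.toxic_response,
                "literal_equations": literal_equations,
                "noncancer_averaging_time": noncancer_averaging_time,
            },
            sort_keys=True,
        ).encode()
    ).hexdigest()
    report.metadata = {
        "config_hash": config_fingerprint,
        "equation_mode": "literal" if literal_equations else "default",
        "noncancer_averaging_time": noncancer_averaging_time,
        "constant_provenance": dict(refs.provenance),
        "stages_run": report.stages_run,
        "stages_skipped": report.stages_skipped,
    }
    return report
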