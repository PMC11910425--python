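"""Packaged reference tables for a river-adjacent industrial study site.

Five sampling sites (S1-S5), eight metals.  The primary anchors are the
published per-site ecological-risk factors (six metals), the per-site
soil-to-plant transfer factors (eight metals), the wastewater
physicochemical panel, and per-metal summary statistics for soil and grass.

The per-site soil fixture is *reconstructed*: for Cr, Cd, Ni, Cu, Zn and Pb
it inverts the ecological-risk chain (Cm = ER x Bm / Tr) with average-shale
backgrounds, which reproduces the published concentration extremes exactly
(Pb 109.52, Cd 35.1 mg/kg) and the published means to within 0.5%.  Fe and
Mn have no toxic-response factor and hence no ER row to invert; their
per-site values are SYNTHETIC interior points anchored to the published
min/max/mean and must not be read as measurements.

The per-site grass fixture is likewise derived: plant = soil x published
transfer factor, which reproduces the published grass concentration ranges
to transfer-factor rounding.
"""

from __future__ import annotations

import pandas as pd

from .containers import (
    BECR_DISCHARGE_STANDARD,
    ConcentrationTable,
    WaterQualityTable,
)
from .ecorisk import back_compute_concentration
from .references import AVERAGE_SHALE_BACKGROUND, TOXIC_RESPONSE_FACTORS

SITES = ["S1", "S2", "S3", "S4", "S5"]
METALS = ["Cr", "Cd", "Ni", "Cu", "Zn", "Pb", "Fe", "Mn"]

#: published per-site ecological risk factors (dimensionless)
_ER_ROWS = {
    "S1": [0.89, 3242.00, 10.65, 4.60, 50.87, 27.38],
    "S2": [1.60, 3510.00, 10.79, 9.51, 29.47, 20.62],
    "S3": [2.24, 1464.00, 10.02, 8.42, 22.69, 17.98],
    "S4": [1.44, 1599.00, 0.89, 3.62, 21.13, 15.55],
    "S5": [1.56, 1139.00, 1.01, 3.63, 20.88, 19.60],
}
_ER_METALS = ["Cr", "Cd", "Ni", "Cu", "Zn", "Pb"]

#: published per-site risk index (sum of the six ER values)
_RISK_INDEX = {"S1": 3336.39, "S2": 3581.98, "S3": 1525.36, "S4": 1641.63, "S5": 1185.68}

# SYNTHETIC per-site Fe and Mn values: endpoints are the published range,
# interior points chosen so the site mean equals the published mean.
_FE_SYNTHETIC = {"S1": 2096.71, "S2": 2157.62, "S3": 2120.00, "S4": 2145.00, "S5": 2151.22}
_MN_SYNTHETIC = {"S1": 121.64, "S2": 355.44, "S3": 130.00, "S4": 155.00, "S5": 157.87}

#: published per-metal soil summary (mean, sd), mg/kg
SOIL_SUMMARY = {
    "Cr": (69.55, 21.77),
    "Cd": (21.90, 10.99),
    "Ni": (90.76, 71.13),
    "Cu": (53.58, 25.23),
    "Zn": (2755.63, 1207.36),
    "Pb": (80.90, 17.74),
    "Fe": (2134.11, 24.52),
    "Mn": (183.99, 97.03),
}

#: published grass summary: (min, max, mean, sd), mg/kg dry weight
GRASS_SUMMARY = {
    "Cr": (1.246, 27.232, 15.450, 12.025),
    "Cd": (4.89, 15.72, 11.224, 4.992),
    "Ni": (1.223, 16.954, 11.714, 6.191),
    "Cu": (9.995, 41.558, 23.231, 12.741),
    "Zn": (1425.97, 2320.75, 1955.77, 361.727),
    "Pb": (10.254, 38.88, 22.316, 12.762),
    "Fe": (915.16, 1994.55, 1560.19, 523.891),
    "Mn": (49.248, 172.716, 96.162, 49.385),
}

#: published per-site soil-to-plant transfer factors
_TF_ROWS = {
    "S1": [0.549, 0.443, 0.093, 0.556, 0.295, 0.355, 0.897, 0.228],
    "S2": [0.052, 0.193, 0.079, 0.150, 0.800, 0.220, 0.495, 0.316],
    "S3": [0.270, 1.074, 0.124, 0.548, 1.077, 0.452, 0.924, 1.107],
    "S4": [0.356, 0.898, 0.101, 0.884, 0.893, 0.165, 0.911, 0.877],
    "S5": [0.018, 0.429, 1.106, 0.306, 1.007, 0.150, 0.430, 0.516],
}

#: published per-receptor hazard quotients, route -> metal -> (adult, child)
HAZARD_QUOTIENTS = {
    "ingestion": {
        "Cr": (3.0e-2, 3.0e-1),
        "Cd": (3.0e-2, 2.8e-1),
        "Ni": (6.2e-3, 5.8e-2),
        "Cu": (1.8e-3, 1.7e-2),
        "Zn": (1.3e-2, 1.2e-1),
        "Pb": (3.2e-2, 3.0e-1),
    },
    "inhalation": {
        "Cr": (6.4e-3, 3.0e-2),
        "Cd": (6.0e-3, 2.8e-2),
        "Ni": (1.2e-3, 5.8e-3),
        "Cu": (3.7e-4, 1.7e-3),
        "Zn": (1.3e-2, 5.9e-2),
        "Pb": (6.3e-3, 3.0e-2),
    },
    "dermal": {
        "Cr": (6.34, 4.74),
        "Cd": (11.97, 8.96),
        "Ni": (0.09, 0.07),
        "Cu": (0.02, 0.02),
        "Zn": (0.25, 0.19),
        "Pb": (0.84, 0.63),
    },
}

#: published per-receptor carcinogenic risks, route -> metal -> (adult, child)
CANCER_RISKS = {
    "ingestion": {
        "Cr": (2.73e-5, 1.76e-4),
        "Cd": (1.32e-5, 3.53e-4),
        "Ni": (7.31e-6, 1.95e-4),
        "Pb": (6.59e-8, 1.76e-6),
    },
    "inhalation": {
        "Cr": (5.89e-7, 5.89e-7),
        "Cd": (2.78e-8, 2.78e-8),
        "Ni": (1.66e-8, 1.66e-8),
        "Pb": (6.85e-7, 6.85e-7),
    },
    "dermal": {
        "Cr": (2.03e-8, 7.58e-8),
        "Cd": (1.89e-8, 7.06e-8),
        "Ni": (1.67e-8, 6.24e-8),
        "Pb": (3.76e-9, 1.41e-8),
    },
}

#: published aggregates: dermal-route hazard index and all-route total CR
PUBLISHED_AGGREGATES = {
    "hi_adult": 19.51,
    "hi_child": 14.61,
    "cr_total_child": 7.273e-4,
}

#: published wastewater metal correlations (Pearson r, n = 5 sites)
WASTEWATER_CORRELATIONS = {
    ("Cu", "Zn"): 0.92,
    ("Cu", "Fe"): 0.90,
    ("Zn", "Fe"): 0.66,
    ("Cu", "Mn"): 0.86,
    ("Zn", "Mn"): 0.87,
    ("Fe", "Mn"): 0.67,
    ("Cr", "Cu"): 0.63,
    ("Cr", "Zn"): 0.62,
    ("Cr", "Fe"): 0.57,
    ("Ni", "Cr"): 0.43,
    ("Ni", "Cu"): 0.45,
    ("Cd", "Cr"): -0.34,
    ("Cd", "Zn"): -0.39,
}

_WQ_ROWS = {
    "S1": [7.62, 1.17, 0.41, 189.0, 602.0],
    "S2": [7.35, 2.17, 0.47, 293.0, 585.0],
    "S3": [7.42, 2.14, 0.34, 308.0, 510.0],
    "S4": [7.89, 2.16, 0.40, 524.0, 570.0],
    "S5": [7.59, 2.19, 0.35, 255.0, 630.0],
}


def ecological_risk_reference() -> pd.DataFrame:
    """Published per-site ecological risk factors, sites x six metals."""
    return pd.DataFrame.from_dict(_ER_ROWS, orient="index", columns=_ER_METALS)


def risk_index_reference() -> pd.Series:
    """Published per-site risk index (PERI) column."""
    return pd.Series(_RISK_INDEX, name="risk_index")


def transfer_factor_reference() -> pd.DataFrame:
    """Published per-site soil-to-plant transfer factors, sites x metals."""
    return pd.DataFrame.from_dict(_TF_ROWS, orient="index", columns=METALS)


def soil_fixture() -> ConcentrationTable:
    """Per-site soil concentrations reconstructed from the ER table.

    Cr/Cd/Ni/Cu/Zn/Pb invert the ecological-risk chain against
    average-shale backgrounds; Fe/Mn columns are synthetic (see module
    docstring).
    """
    er = ecological_risk_reference()
    data = pd.DataFrame(index=SITES, columns=METALS, dtype=float)
    for site in SITES:
        for metal in _ER_METALS:
            data.at[site, metal] = back_compute_concentration(
                er.at[site, metal],
                AVERAGE_SHALE_BACKGROUND[metal],
                TOXIC_RESPONSE_FACTORS[metal],
            )
        data.at[site, "Fe"] = _FE_SYNTHETIC[site]
        data.at[site, "Mn"] = _MN_SYNTHETIC[site]
    return ConcentrationTable(compartment="soil", unit="mg/kg", data=data)


def grass_fixture() -> ConcentrationTable:
    """Per-site grass concentrations derived as soil x published TF."""
    soil = soil_fixture()
    tf = transfer_factor_reference()
    data = soil.data * tf
    return ConcentrationTable(compartment="plant", unit="mg/kg", data=data)


def water_quality_fixture() -> WaterQualityTable:
    """Published wastewater physicochemical panel with the BECR standard."""
    data = pd.DataFrame.from_dict(
        _WQ_ROWS, orient="index", columns=["pH", "EC", "DO", "COD", "TDS"]
    )
    return WaterQualityTable(data=data, standard=dict(BECR_DISCHARGE_STANDARD))


def soil_means() -> pd.Series:
    """Published per-metal mean soil concentrations, mg/kg."""
    return pd.Series({m: v[0] for m, v in SOIL_SUMMARY.items()})


def hazard_quotient_table(receptor: str) -> pd.DataFrame:
    """Published HQ values for one receptor, route x metal."""
    idx = {"adult": 0, "child": 1}[receptor]
    return pd.DataFrame(
        {route: {m: v[idx] for m, v in table.items()} for route, table in HAZARD_QUOTIENTS.items()}
    ).T


def cancer_risk_table(receptor: str) -> pd.DataFrame:
    """Published CR values for one receptor, route x metal."""
    idx = {"adult": 0, "child": 1}[receptor]
    return pd.DataFrame(
        {route: {m: v[idx] for m, v in table.items()} for route, table in CANCER_RISKS.items()}
    ).T
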