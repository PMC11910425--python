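"""USEPA exposure model: CDIs, hazard quotients/index, cancer risks."""

import dataclasses

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metalrisk import (
    DomainError,
    ExposureProfile,
    ReferenceSet,
    assess_health_risk,
    cdi_dermal,
    cdi_ingestion,
    cdi_inhalation,
    classify_cancer_risk,
    cr_dermal,
    cr_ingestion,
    cr_inhalation,
    cr_total,
    hazard_index,
    hazard_quotient,
)
from metalrisk.datasets import (
    PUBLISHED_AGGREGATES,
    cancer_risk_table,
    hazard_quotient_table,
)

ADULT = ExposureProfile.adult()
CHILD = ExposureProfile.child()
conc = st.floats(min_value=1e-3, max_value=1e5, allow_nan=False)


class TestChronicDailyIntake:
    def test_ingestion_cancellation(self):
        # cs chosen so numerator equals BW x AT
        p = ADULT
        cs = p.body_weight * p.averaging_time_days / (
            p.ingestion_rate * p.exposure_frequency_days * p.exposure_duration_years * p.unit_conversion_factor
        )
        assert cdi_ingestion(cs, p) == pytest.approx(1.0, rel=1e-12)

    def test_ingestion_mean_lead(self):
        # frozen from direct arithmetic on the published adult parameters
        assert cdi_ingestion(80.90, ADULT) == pytest.approx(4.7495e-5, rel=1e-4)

    def test_dermal_mean_chromium(self):
        # frozen from direct arithmetic: 69.55*5700*0.07*0.01*350*30/(70*25550)*1e-6
        assert cdi_dermal(69.55, ADULT) == pytest.approx(1.6292e-6, rel=1e-4)

    def test_inhalation_mean_lead_default_convention(self):
        # frozen from direct arithmetic: 80.90*20*350*30/(70*25550*1.36e9)
        assert cdi_inhalation(80.90, ADULT) == pytest.approx(6.9847e-9, rel=1e-4)

    def test_inhalation_literal_mode_differs_by_documented_factor(self):
        p = ADULT
        expected_factor = p.exposure_frequency_days * p.unit_conversion_factor * p.particle_emission_factor
        ratio = cdi_inhalation(50.0, p, literal=True) / cdi_inhalation(50.0, p)
        assert ratio == pytest.approx(expected_factor, rel=1e-9)

    def test_inhalation_decreases_with_pef(self):
        big_pef = dataclasses.replace(ADULT, particle_emission_factor=1e15)
        assert cdi_inhalation(50.0, big_pef) < cdi_inhalation(50.0, ADULT) / 1e3

    @given(cs=conc, k=st.floats(min_value=0.1, max_value=10))
    def test_linearity_in_concentration(self, cs, k):
        for fn in (cdi_ingestion, cdi_dermal, cdi_inhalation):
            assert fn(k * cs, ADULT) == pytest.approx(k * fn(cs, ADULT), rel=1e-9)

    def test_nonpositive_concentration_rejected(self):
        for fn in (cdi_ingestion, cdi_dermal, cdi_inhalation):
            with pytest.raises(DomainError):
                fn(0.0, ADULT)

    def test_zero_dermal_absorption_unconstructible(self):
        with pytest.raises(Exception):
            dataclasses.replace(ADULT, dermal_absorption=0.0)


class TestHazard:
    def test_quotient_threshold_and_scaling(self):
        assert hazard_quotient(2e-3, 2e-3) == 1.0
        assert hazard_quotient(0.0, 1e-3) == 0.0
        assert hazard_quotient(4e-3, 2e-3) == 2.0
        with pytest.raises(DomainError):
            hazard_quotient(1.0, 0.0)

    @pytest.mark.parametrize(
        "receptor, expected", [("adult", 19.51), ("child", 14.61)]
    )
    def test_published_dermal_hazard_index(self, receptor, expected):
        hqs = hazard_quotient_table(receptor).loc["dermal"].dropna()
        hi, note = hazard_index(hqs.tolist(), "dermal route")
        assert hi == pytest.approx(expected, abs=5e-3)
        assert note == "dermal route"

    def test_zeros_and_empty(self):
        assert hazard_index([0.0, 0.0, 0.0])[0] == 0.0
        with pytest.raises(DomainError):
            hazard_index([])


class TestCancerRisk:
    def test_ingestion_child_chromium(self):
        # frozen from direct arithmetic: 69.55*200*350*6*1e-6*4.1/(15*25550)
        assert cr_ingestion(69.55, CHILD, 4.1) == pytest.approx(3.125e-4, rel=1e-3)

    def test_ingestion_literal_mode_adds_adherence_factor(self):
        default = cr_ingestion(69.55, ADULT, 4.1)
        literal = cr_ingestion(69.55, ADULT, 4.1, literal=True)
        assert literal == pytest.approx(default * ADULT.adherence_factor, rel=1e-12)

    def test_dermal_reduces_to_oral_slope_factor(self):
        base = cdi_dermal(69.55, ADULT) * 4.1
        assert cr_dermal(69.55, ADULT, 4.1, abs_gi=1.0) == pytest.approx(base, rel=1e-12)

    @given(abs_gi=st.floats(min_value=1e-3, max_value=1.0))
    def test_dermal_invariant_to_gi_absorption(self, abs_gi):
        # CSF_dermal = CSF_oral / ABS_GI cancels the ABS_GI product
        assert cr_dermal(10.0, ADULT, 4.1, abs_gi) == pytest.approx(
            cr_dermal(10.0, ADULT, 4.1, 1.0), rel=1e-12
        )

    def test_dermal_adult_chromium(self):
        # frozen from direct arithmetic (cdi_dermal x CSF)
        assert cr_dermal(69.55, ADULT, 4.1) == pytest.approx(6.680e-6, rel=1e-3)

    def test_inhalation_adult_chromium(self):
        # frozen: 69.55*24*350*30*0.0012*1e3/(1.36e9*24*25550)
        assert cr_inhalation(69.55, ADULT, 0.0012) == pytest.approx(2.522e-8, rel=1e-3)

    @given(k=st.floats(min_value=1.5, max_value=5))
    def test_inhalation_scales_with_duration(self, k):
        longer = dataclasses.replace(ADULT, exposure_duration_years=ADULT.exposure_duration_years * k)
        assert cr_inhalation(50.0, longer, 1e-3) == pytest.approx(
            k * cr_inhalation(50.0, ADULT, 1e-3), rel=1e-9
        )

    def test_total_of_published_child_risks(self):
        crs = cancer_risk_table("child").stack().tolist()
        assert len(crs) == 12
        total, _ = cr_total(crs, "all routes")
        assert total == pytest.approx(PUBLISHED_AGGREGATES["cr_total_child"], rel=5e-4)
        assert classify_cancer_risk(total) == "harmful"

    def test_total_edge_cases(self):
        total, _ = cr_total([1e-6])
        assert total == 1e-6
        assert classify_cancer_risk(total) == "tolerable"
        with pytest.raises(DomainError):
            cr_total([])
        with pytest.raises(DomainError):
            cr_total([1.5])

    @pytest.mark.parametrize(
        "value, band",
        [(9e-7, "acceptable"), (5e-5, "tolerable"), (7.273e-4, "harmful")],
    )
    def test_risk_bands(self, value, band):
        assert classify_cancer_risk(value) == band


@pytest.fixture(scope="module")
def breakdowns(soil):
    return assess_health_risk(soil, ReferenceSet())


class TestAssessmentDriver:

    def test_aggregates_are_exact_sums(self, breakdowns):
        for b in breakdowns.values():
            dermal = b.hq.loc["dermal"].dropna()
            assert b.hi == pytest.approx(float(dermal.sum()), rel=1e-15)
            all_crs = [v for v in b.cr.values.ravel() if pd.notna(v)]
            assert b.cr_total == pytest.approx(sum(all_crs), rel=1e-15)
            assert b.hi_all_routes >= b.hi

    def test_all_values_nonnegative_and_risks_below_one(self, breakdowns):
        for b in breakdowns.values():
            for frame in (b.cdi, b.hq, b.cr):
                vals = [v for v in frame.values.ravel() if pd.notna(v)]
                assert all(v >= 0 for v in vals)
            assert all(v < 1 for v in b.cr.values.ravel() if pd.notna(v))

    def test_carcinogens_only_where_slope_factors_exist(self, breakdowns):
        refs = ReferenceSet()
        cr = breakdowns["adult"].cr
        assert pd.isna(cr.at["ingestion", "Cu"])  # no slope factor for Cu
        assert pd.notna(cr.at["ingestion", "Cr"])
        assert set(refs.csf_ing) == {"Pb", "Cr", "Cd", "Ni"}

    def test_literal_mode_recorded_and_differs(self, soil):
        default = assess_health_risk(soil, ReferenceSet())["adult"]
        literal = assess_health_risk(soil, ReferenceSet(), literal_equations=True)["adult"]
        assert literal.mode == "literal"
        p = ExposureProfile.adult()
        factor = p.exposure_frequency_days * p.unit_conversion_factor * p.particle_emission_factor
        assert literal.cdi.at["inhalation", "Pb"] == pytest.approx(
            default.cdi.at["inhalation", "Pb"] * factor, rel=1e-9
        )
        assert literal.cr.at["ingestion", "Cr"] == pytest.approx(
            default.cr.at["ingestion", "Cr"] * p.adherence_factor, rel=1e-9
        )

    def test_noncancer_averaging_time_option(self, soil):
        printed = assess_health_risk(soil, ReferenceSet())["adult"]
        ed365 = assess_health_risk(soil, ReferenceSet(), noncancer_averaging_time="ed365")["adult"]
        # AT shrinks from 70y to 30y for the adult, so HQs scale up by 70/30
        assert ed365.hq.at["dermal", "Cd"] == pytest.approx(
            printed.hq.at["dermal", "Cd"] * 70.0 / 30.0, rel=1e-9
        )
        # carcinogenic risks keep the lifetime averaging time
        assert ed365.cr.at["ingestion", "Cr"] == pytest.approx(
            printed.cr.at["ingestion", "Cr"], rel=1e-12
        )
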