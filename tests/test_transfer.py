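"""Transfer factors, Pearson correlations and compliance checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metalrisk import (
    ConcentrationTable,
    DomainError,
    guideline_exceedance,
    pearson_matrix,
    summarize_tf,
    transfer_factor,
    transfer_table,
    water_quality_compliance,
)
from metalrisk.datasets import transfer_factor_reference

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


class TestTransferFactor:
    def test_identity(self):
        assert transfer_factor(7.0, 7.0) == 1.0

    def test_site_three_zinc(self):
        # published grass maximum over the ER-inverted soil value
        assert transfer_factor(2320.75, 2155.55) == pytest.approx(1.077, rel=5e-3)

    @given(cp=positive, cs=positive)
    def test_round_trip(self, cp, cs):
        assert cs * transfer_factor(cp, cs) == pytest.approx(cp, rel=1e-12)

    def test_halving_soil_doubles_tf(self):
        assert transfer_factor(10.0, 5.0) == pytest.approx(2 * transfer_factor(10.0, 10.0))

    def test_domain_error(self):
        with pytest.raises(DomainError):
            transfer_factor(1.0, 0.0)


class TestSummaries:
    CR_COLUMN = [0.549, 0.052, 0.270, 0.356, 0.018]

    def test_published_chromium_column(self):
        s = summarize_tf(self.CR_COLUMN)
        assert s["mean"] == pytest.approx(0.249, abs=5e-4)
        assert s["min"] == 0.018
        assert s["max"] == 0.549
        # the published spread is the sample (n-1) estimator
        assert s["std"] == pytest.approx(0.220, abs=5e-4)

    def test_constant_list(self):
        s = summarize_tf([0.3, 0.3, 0.3])
        assert s["mean"] == pytest.approx(0.3)
        assert s["std"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            summarize_tf([])


class TestTransferTable:
    def test_fixture_recovers_published_factors(self, grass, soil):
        result = transfer_table(grass, soil)
        reference = transfer_factor_reference()
        # plant fixture is soil x published TF, so recovery is exact
        pd.testing.assert_frame_equal(
            result.tf, reference, check_exact=False, rtol=1e-9
        )
        assert result.summary["mean"]["Cr"] == pytest.approx(0.249, abs=5e-4)

    def test_mean_ranking_matches_published_means(self, grass, soil):
        ranking = transfer_table(grass, soil).ranking()
        assert ranking[:2] == ["Zn", "Fe"]
        assert set(ranking[2:4]) == {"Mn", "Cd"}
        assert ranking[4:] == ["Cu", "Ni", "Pb", "Cr"]

    def test_summary_orderings(self, grass, soil):
        summary = transfer_table(grass, soil).summary
        assert (summary["min"] <= summary["mean"]).all()
        assert (summary["mean"] <= summary["max"]).all()


def _ww_table(data: dict) -> ConcentrationTable:
    return ConcentrationTable("wastewater", "mg/L", pd.DataFrame(data))


class TestPearsonMatrix:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        table = _ww_table({"Cu": x, "Zn": [2 * v for v in x], "Pb": [10 - v for v in x]})
        corr = pearson_matrix(table)
        assert corr.r.at["Cu", "Zn"] == pytest.approx(1.0)
        assert corr.r.at["Cu", "Pb"] == pytest.approx(-1.0)
        assert (np.diag(corr.r.values) == 1.0).all()

    def test_symmetry_and_bounds_random(self):
        rng = np.random.default_rng(7)
        table = _ww_table({m: rng.lognormal(0, 0.5, 30) for m in ("Cr", "Cu", "Zn", "Pb")})
        corr = pearson_matrix(table)
        assert np.allclose(corr.r.values, corr.r.values.T)
        assert (corr.r.abs().values <= 1.0 + 1e-12).all()

    def test_oracle_equivalence_two_pass(self):
        """Matches an independently coded two-pass covariance expression."""
        rng = np.random.default_rng(99)
        x, y = rng.lognormal(0, 1, 50), rng.lognormal(0, 1, 50)
        table = _ww_table({"Cu": x, "Zn": y})
        r = pearson_matrix(table).r.at["Cu", "Zn"]
        xc, yc = x - x.mean(), y - y.mean()
        oracle = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert r == pytest.approx(oracle, rel=1e-10)

    @given(
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=-5, max_value=5),
    )
    def test_positive_affine_invariance(self, a, b):
        rng = np.random.default_rng(3)
        x, y = rng.lognormal(0, 0.5, 20), rng.lognormal(0, 0.5, 20)
        base = pearson_matrix(_ww_table({"Cu": x, "Zn": y})).r.at["Cu", "Zn"]
        shifted = np.clip(a * x + b, 1e-9, None)  # keep positive for the container
        transformed = pearson_matrix(_ww_table({"Cu": shifted, "Zn": y})).r.at["Cu", "Zn"]
        if (a * x + b > 0).all():
            assert transformed == pytest.approx(base, rel=1e-9)

    def test_insufficient_pairs_reported_not_nan_propagated(self):
        df = pd.DataFrame(
            {"Cu": [1.0, 2.0, np.nan, np.nan], "Zn": [np.nan, 4.0, 5.0, 6.0]},
            index=["S1", "S2", "S3", "S4"],
        )
        table = ConcentrationTable("wastewater", "mg/L", df)
        corr = pearson_matrix(table)
        assert ("Cu", "Zn") in corr.missing
        assert "complete pairs" in corr.missing[("Cu", "Zn")]

    def test_zero_variance_reported(self):
        table = _ww_table({"Cu": [2.0, 2.0, 2.0, 2.0], "Zn": [1.0, 2.0, 3.0, 4.0]})
        corr = pearson_matrix(table)
        assert corr.missing[("Cu", "Zn")] == "zero variance"


class TestGuidelineExceedance:
    def test_published_zinc_and_cadmium_ratios(self):
        ratio, verdict = guideline_exceedance(2755.63, 200.0)
        assert ratio == pytest.approx(13.78, abs=5e-3)
        assert verdict == "exceeds"
        ratio, verdict = guideline_exceedance(21.90, 1.0)
        assert ratio == pytest.approx(21.9)
        assert verdict == "exceeds"

    def test_boundary_not_exceeding(self):
        ratio, verdict = guideline_exceedance(50.0, 50.0)
        assert ratio == 1.0
        assert verdict == "within"

    @pytest.mark.parametrize(
        "value, expected", [(90.0, "below"), (120.0, "within"), (200.0, "above")]
    )
    def test_interval_verdicts(self, value, expected):
        _, verdict = guideline_exceedance(value, (100.0, 150.0))
        assert verdict == expected

    def test_invalid_limit(self):
        with pytest.raises(DomainError):
            guideline_exceedance(1.0, 0.0)


class TestWaterQualityCompliance:
    def test_fixture_verdicts(self, water_quality):
        report = water_quality_compliance(water_quality)
        by = report.set_index(["site", "parameter"])["verdict"]
        assert (by.xs("pH", level="parameter") == "within").all()
        assert (by.xs("COD", level="parameter") == "above").all()
        assert (by.xs("DO", level="parameter") == "below").all()
        # only site S1 sits inside the conductivity limit
        ec = by.xs("EC", level="parameter")
        assert ec["S1"] == "within"
        assert (ec.drop("S1") == "above").all()

    def test_unknown_parameter_skipped(self, water_quality):
        from metalrisk import WaterQualityTable

        table = WaterQualityTable(
            data=water_quality.data.assign(turbidity=1.0), standard=water_quality.standard
        )
        report = water_quality_compliance(table)
        assert "turbidity" not in set(report["parameter"])
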