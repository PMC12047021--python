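"""Exposure-design arithmetic: PEC conversion, MEC censoring policies,
worst-case scaling, spiking plans, recovery/persistence accounting, and
the bundled case-study exposure table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixrisk import errors
from mixrisk import exposure as exp


class TestPecFromRate:
    @pytest.mark.parametrize("rate, depth, density, expected", [
        (0.75, 5.0, 1.5, 1.0),        # exact cancellation
        (4.32, 5.0, 1.5, 5.76),       # mass balance; glyphosate-scale rate
        (1.0, 10.0, 1.5, 2.0 / 3.0),  # doubled depth halves the concentration
        (1.0, 5.0, 1.5, 4.0 / 3.0),
    ])
    def test_mass_balance(self, rate, depth, density, expected):
        assert exp.pec_from_rate(rate, depth, density) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(errors.DomainError):
            exp.pec_from_rate(1.0, 0.0, 1.5)
        with pytest.raises(errors.DomainError):
            exp.pec_from_rate(1.0, 5.0, -1.0)

    @given(rate=st.floats(1e-3, 1e2), c=st.floats(0.1, 10))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_linear_in_rate_inverse_in_depth_density(self, rate, c):
        base = exp.pec_from_rate(rate)
        assert exp.pec_from_rate(rate * c) == pytest.approx(base * c)
        assert exp.pec_from_rate(rate, depth_cm=5.0 * c) == pytest.approx(base / c)
        assert exp.pec_from_rate(rate, bulk_density_g_cm3=1.5 * c) == pytest.approx(base / c)


class TestMecFromMonitoring:
    def test_odd_and_even_medians(self):
        assert exp.mec_from_monitoring([0.1, 0.3, 0.5]) == pytest.approx(0.3)
        assert exp.mec_from_monitoring([0.2, 0.4]) == pytest.approx(0.3)

    def test_censoring_policies(self):
        conc = [0.5, 0.01, 0.01]
        flags = [False, True, True]
        assert exp.mec_from_monitoring(conc, flags) == pytest.approx(0.5)
        assert exp.mec_from_monitoring(conc, flags, policy="half_loq",
                                       loq=0.01) == pytest.approx(0.005)
        assert exp.mec_from_monitoring(conc, flags, policy="zero") == pytest.approx(0.0)

    def test_no_detects_is_undefined(self):
        with pytest.raises(errors.UndefinedMECError):
            exp.mec_from_monitoring([0.01, 0.01], [True, True])
        with pytest.raises(errors.UndefinedMECError):
            exp.mec_from_monitoring([])


class TestScaleWorstCase:
    @pytest.mark.parametrize("pec, expected", [
        (0.438, 2.190),   # chlorantraniliprole
        (0.290, 1.45),    # acetamiprid
        (0.0, 0.0),
    ])
    def test_exact_multiplication(self, pec, expected):
        assert exp.scale_worst_case(pec) == pytest.approx(expected, abs=1e-12)

    def test_errors(self):
        with pytest.raises(errors.DomainError):
            exp.scale_worst_case(-0.1)
        with pytest.raises(errors.DomainError):
            exp.scale_worst_case(1.0, factor=-5)


class TestSpikingPlan:
    def test_acetone_submass_and_volume(self):
        plan = exp.build_spiking_plan("PEC", {"boscalid": 0.396}, soil_mass_g=25.0)
        assert plan.spiked_submass_g == pytest.approx(2.0)      # 25 g × 8%
        assert plan.acetone_volume_ml == pytest.approx(0.25)    # 2 g / (8 g/ml)
        # mass on the total dry soil: 0.396 mg/kg × 25 g
        assert plan.masses_mg["boscalid"] == pytest.approx(0.396 * 25 / 1000)
        assert plan.carriers["boscalid"] == "acetone"

    def test_water_carrier_for_glyphosate_and_ampa(self):
        plan = exp.build_spiking_plan("MEC", {"Glyphosate": 0.793, "AMPA": 1.91},
                                      soil_mass_g=25.0)
        assert plan.carriers == {"Glyphosate": "water", "AMPA": "water"}
        assert plan.target_moisture_fraction_whc == pytest.approx(0.5)

    def test_zero_concentration_still_listed(self):
        plan = exp.build_spiking_plan("MEC", {"a": 0.0, "b": 1.0}, soil_mass_g=10.0)
        assert plan.masses_mg["a"] == 0.0
        assert set(plan.carriers) == {"a", "b"}

    def test_unknown_carrier_rejected(self):
        with pytest.raises(errors.InvalidConfigError):
            exp.build_spiking_plan("MEC", {"a": 1.0}, 10.0, carriers={"a": "oil"})


class TestRecovery:
    def test_low_recovery_category(self):
        rec = exp.recovery_report("p", nominal=1.0, measured_initial=0.5,
                                  measured_final=0.4)
        assert rec.recovery_percent == pytest.approx(50.0)
        assert rec.category == "low"
        assert rec.persistence_percent == pytest.approx(80.0)

    @pytest.mark.parametrize("recovery, category", [
        (79.999, "low"), (80.0, "nominal-range"), (100.0, "nominal-range"),
        (120.0, "nominal-range"), (120.001, "high"),
    ])
    def test_category_boundaries_closed_on_nominal_range(self, recovery, category):
        assert exp.recovery_category(recovery) == category

    def test_expected_residual_first_order(self):
        assert exp.expected_residual_fraction(174.0, 28.0) == pytest.approx(0.894, abs=5e-4)
        assert exp.expected_residual_fraction(28.0, 28.0) == pytest.approx(0.5)

    def test_persistent_compound_with_fast_loss_is_anomalous(self):
        # persistence 17% against a 174-day half-life (expected residual 89%)
        rec = exp.recovery_report("lambda-cyhalothrin", nominal=0.1,
                                  measured_initial=0.3, measured_final=0.051,
                                  dt50_days=174.0)
        assert rec.persistence_percent == pytest.approx(17.0)
        assert rec.expected_residual_fraction == pytest.approx(0.894, abs=5e-4)
        assert rec.anomaly

    def test_consistent_decay_not_anomalous(self):
        rec = exp.recovery_report("p", 1.0, 0.9, 0.8, dt50_days=174.0)
        assert not rec.anomaly

    def test_zero_initial_flags_record(self):
        rec = exp.recovery_report("p", 1.0, 0.0, 0.0, dt50_days=30.0)
        assert rec.persistence_percent is None
        assert rec.anomaly

    def test_background_subtraction(self):
        rec = exp.recovery_report("AMPA", nominal=1.0, measured_initial=1.1,
                                  measured_final=1.0, background=0.1)
        assert rec.recovery_percent == pytest.approx(100.0)


class TestCaseStudyTable:
    def test_shape(self, table1):
        assert len(table1) == 55
        assert table1["css"].nunique() == 11
        assert (table1.groupby("css").size() == 5).all()

    def test_worst_case_identity(self, table1):
        """5PEC = 5 × PEC within one printed ulp of the PEC column; exact
        for the large self-consistent majority of rows."""
        diffs = (table1["pec_mg_kg"] * 5 - table1["five_pec_mg_kg"]).abs()
        assert (diffs <= 5 * 1e-3 + 1e-9).all()
        assert (diffs < 1e-9).sum() >= 46

    def test_exposure_sets(self, table1):
        sets = exp.exposure_sets_from_table(table1)
        assert set(sets) == set(table1["css"])
        pt = sets["PT"]
        assert pt.level("PEC")["Glyphosate"] == pytest.approx(5.760)
        assert pt.level("5PEC")["Glyphosate"] == pytest.approx(28.80)

    def test_from_pec_builds_exact_worst_case(self):
        es = exp.ExposureSet.from_pec("x", {"a": 0.1}, {"a": 0.438})
        assert es.five_pec["a"] == pytest.approx(0.438 * 5, abs=1e-15)
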