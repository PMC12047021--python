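"""Reproduction-test statistics: Kruskal-Wallis, Dunn's comparisons,
validity criteria, control gating and the full-test analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import jar_frame
from mixrisk import errors
from mixrisk import stats as mst
from mixrisk import synthetic as syn


class TestKruskalWallis:
    def test_worked_example_h(self):
        """Three fully separated untied groups of three give H = 7.2."""
        r = mst.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert r.statistic == pytest.approx(7.2)
        assert r.df == 2
        assert r.method == "exact"
        assert r.pvalue == pytest.approx(6 / 1680)  # complete separations

    def test_identical_groups(self):
        r = mst.kruskal_wallis([[5, 5, 5], [5, 5, 5]])
        assert r.statistic == 0.0
        assert r.pvalue == 1.0

    def test_matches_scipy_with_ties(self):
        groups = [[1, 2, 2, 3], [2, 3, 3, 4], [4, 4, 5, 5]]
        ours = mst.kruskal_wallis(groups, method="asymptotic")
        h_ref, p_ref = sps.kruskal(*groups)
        assert ours.statistic == pytest.approx(h_ref)
        assert ours.pvalue == pytest.approx(p_ref)

    def test_monotone_transform_invariance(self):
        groups = [[0.1, 0.5, 0.9], [1.2, 2.0, 0.7], [3.0, 2.5, 0.8]]
        base = mst.kruskal_wallis(groups)
        transformed = mst.kruskal_wallis([np.exp(g) for g in [np.array(x) for x in groups]])
        assert transformed.statistic == pytest.approx(base.statistic)
        assert transformed.pvalue == pytest.approx(base.pvalue)

    def test_input_contracts(self):
        with pytest.raises(errors.InvalidDesignError):
            mst.kruskal_wallis([[1, 2, 3]])
        with pytest.raises(errors.InvalidDesignError):
            mst.kruskal_wallis([[1, 2], []])


class TestDunn:
    def test_closed_form_z_untied(self):
        """Complete separation of 5 vs 5: mean-rank difference 5, pooled
        variance N(N+1)/12, z = 5/√(110/12 × 2/5)."""
        comps = mst.dunn_posthoc([[10, 11, 12, 13, 14], [1, 2, 3, 4, 5]],
                                 method="asymptotic")
        z_expected = -5.0 / np.sqrt(110 / 12 * (1 / 5 + 1 / 5))
        assert comps[0].z == pytest.approx(z_expected)
        assert comps[0].significant

    def test_exact_p_complete_separation(self):
        comps = mst.dunn_posthoc([[10, 11, 12, 13, 14], [1, 2, 3, 4, 5]])
        assert comps[0].pvalue == pytest.approx(2 / 252)  # two of C(10,5) splits

    def test_identical_to_control(self):
        comps = mst.dunn_posthoc([[1, 2, 3], [1, 2, 3]])
        assert comps[0].z == pytest.approx(0.0)
        assert comps[0].pvalue == 1.0
        assert not comps[0].significant

    def test_swapping_groups_flips_sign_only(self):
        a, b = [1, 5, 9, 12], [3, 4, 10, 11]
        fwd = mst.dunn_posthoc([a, b], method="asymptotic")[0]
        rev = mst.dunn_posthoc([b, a], method="asymptotic")[0]
        assert fwd.z == pytest.approx(-rev.z)
        assert fwd.pvalue == pytest.approx(rev.pvalue)

    def test_adjustment_never_decreases_and_preserves_order(self):
        rng = np.random.default_rng(4)
        groups = [list(rng.normal(loc, 1, 5)) for loc in (0, 0.5, 1.5, 3.0)]
        comps = mst.dunn_posthoc(groups, adjust="holm")
        raw = [c.pvalue for c in comps]
        adj = [c.p_adjusted for c in comps]
        assert all(a >= r - 1e-15 for a, r in zip(adj, raw))
        assert np.argsort(raw).tolist() == np.argsort(adj).tolist()
        none = mst.dunn_posthoc(groups, adjust="none")
        assert [c.p_adjusted for c in none] == [c.pvalue for c in none]

    def test_empty_group_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            comps = mst.dunn_posthoc([[1, 2, 3], [], [4, 5, 6]],
                                     labels=["ctrl", "empty", "t"])
        assert [c.group for c in comps] == ["t"]


class TestValidity:
    def test_clean_controls_pass(self, control_jars):
        rep = mst.validity_check(control_jars)
        assert rep.survival_ok and rep.juveniles_ok and rep.cv_ok
        assert rep.overall

    def test_low_juvenile_mean_fails(self, control_jars):
        jars = control_jars.assign(juveniles=[90, 95, 85, 92, 88])
        rep = mst.validity_check(jars)
        assert not rep.juveniles_ok and rep.survival_ok
        assert not rep.overall

    def test_high_cv_fails(self, control_jars):
        jars = control_jars.assign(juveniles=[100, 200, 300, 50, 150])
        rep = mst.validity_check(jars)
        cv = np.std([100, 200, 300, 50, 150], ddof=1) / 160 * 100
        assert rep.cv_juveniles_percent == pytest.approx(cv)
        assert not rep.cv_ok

    @pytest.mark.parametrize("survival, ok", [(8, False), (9, True)])
    def test_survival_threshold_strict(self, control_jars, survival, ok):
        jars = control_jars.assign(adults_surviving=survival)  # exactly 0.8 fails
        assert mst.validity_check(jars).survival_ok is ok

    def test_juvenile_threshold_strict(self, control_jars):
        assert not mst.validity_check(control_jars.assign(juveniles=100)).juveniles_ok
        assert mst.validity_check(control_jars.assign(juveniles=101)).juveniles_ok

    def test_requires_two_jars(self, control_jars):
        with pytest.raises(errors.InvalidDesignError):
            mst.validity_check(control_jars.iloc[:1])


class TestControlGate:
    def test_identical_controls_use_solvent(self, control_jars):
        neg = control_jars.assign(treatment=syn.NEGATIVE_CONTROL)
        gate = mst.control_gate(neg, control_jars)
        assert gate.control_used == "solvent"

    def test_strong_separation_keeps_both(self, control_jars):
        neg = control_jars.assign(treatment=syn.NEGATIVE_CONTROL)
        shifted = control_jars.assign(
            juveniles=(control_jars["juveniles"] * 0.5).astype(int))
        gate = mst.control_gate(neg, shifted)
        assert gate.control_used == "both"
        assert any("retained" in w for w in gate.warnings)

    def test_missing_solvent_falls_back(self, control_jars):
        neg = control_jars.assign(treatment=syn.NEGATIVE_CONTROL)
        gate = mst.control_gate(neg, None)
        assert gate.control_used == "negative"
        assert gate.warnings


class TestPercentOfControl:
    def test_arithmetic(self):
        assert mst.percent_of_control(20, 200) == pytest.approx(10.0)
        assert mst.percent_of_control(200, 200) == pytest.approx(100.0)

    def test_zero_control_undefined(self):
        with pytest.raises(errors.DomainError):
            mst.percent_of_control(10, 0)


class TestAnalyzeTest:
    def _jars(self, effect_juveniles):
        return jar_frame({
            syn.NEGATIVE_CONTROL: [420, 460, 500, 480, 450],
            syn.SOLVENT_CONTROL: [430, 470, 490, 455, 445],
            "MEC": [440, 450, 465, 480, 430],
            "PEC": effect_juveniles,
        })

    def test_strong_effect_detected(self):
        reports = self._strong = mst.analyze_test(self._jars([20, 35, 10, 25, 15]))
        rep = reports["reproduction"]
        table = rep.table.set_index("treatment")
        assert rep.valid
        assert rep.control_used == "solvent"
        assert bool(table.loc["PEC", "significant"])
        assert not bool(table.loc["MEC", "significant"])
        assert table.loc["PEC", "percent_of_control"] < 10

    def test_null_mostly_quiet(self):
        reports = mst.analyze_test(self._jars([435, 465, 485, 455, 440]))
        assert reports["reproduction"].omnibus.pvalue > 0.05

    def test_missing_sizes_skips_size_endpoint(self):
        jars = self._jars([20, 35, 10, 25, 15])
        jars["adult_sizes"] = [[] for _ in range(len(jars))]
        with pytest.warns(UserWarning, match="size"):
            reports = mst.analyze_test(jars)
        assert "size" not in reports
        assert {"survival", "reproduction"} <= set(reports)

    def test_invalid_controls_flagged_but_analyzed(self):
        jars = self._jars([20, 35, 10, 25, 15])
        low = jars["treatment"].isin([syn.SOLVENT_CONTROL, syn.NEGATIVE_CONTROL])
        jars.loc[low, "juveniles"] = [60, 70, 65, 75, 68, 62, 72, 66, 74, 69]
        reports = mst.analyze_test(jars)
        assert not reports["reproduction"].valid
        assert any("non-reportable" in w for w in reports["reproduction"].warnings)

    def test_requires_treatments(self, control_jars):
        with pytest.raises(errors.InvalidDesignError):
            mst.analyze_test(control_jars)
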