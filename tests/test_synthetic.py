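"""Generator behavior: determinism, dose-response algebra, distributional
targets of the simulated monitoring and reproduction-test tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixrisk import errors
from mixrisk import synthetic as syn


class TestDoseResponse:
    @pytest.mark.parametrize("tu, tu50, slope, lam, expected", [
        (0.0, 1.0, 2.0, 1.0, 0.0),           # no exposure, no inhibition
        (1.0, 1.0, 2.0, 1.0, 0.5),           # half-maximal at tu50 by construction
        (2.0, 6.0, 1.0, 3.0, 0.5),           # λ·tu = tu50
        (3.0, 1.0, 2.0, 1.0, 9.0 / 10.0),    # hand evaluation: 9/(1+9)
    ])
    def test_closed_form(self, tu, tu50, slope, lam, expected):
        assert syn.dose_response(tu, tu50, slope, lam) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(errors.DomainError):
            syn.dose_response(-0.1, 1.0, 2.0)
        with pytest.raises(errors.DomainError):
            syn.dose_response(1.0, 0.0, 2.0)
        with pytest.raises(errors.DomainError):
            syn.dose_response(1.0, 1.0, 2.0, synergy_lambda=0.0)

    @given(tu=st.floats(0, 50), delta=st.floats(0, 10),
           lam=st.floats(0.1, 10), slope=st.floats(0.2, 5))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_monotone_in_tu_and_lambda(self, tu, delta, lam, slope):
        f = syn.dose_response(tu, 1.0, slope, lam)
        assert 0.0 <= f <= 1.0
        assert syn.dose_response(tu + delta, 1.0, slope, lam) >= f - 1e-12
        assert syn.dose_response(tu, 1.0, slope, lam * 1.5) >= f - 1e-12


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(errors.InvalidConfigError):
            syn.SimConfig(n_samples_per_site=0)
        with pytest.raises(errors.InvalidConfigError):
            syn.SimConfig(detect_freq_range=(0.9, 0.2))
        with pytest.raises(errors.InvalidConfigError):
            syn.SimConfig(juvenile_dispersion=0)
        with pytest.raises(errors.InvalidConfigError):
            # NOEC would land at/above the EC50
            syn.SimConfig(tu50=3.0, noec_effect_level=0.5)

    def test_noec_position_on_curve(self):
        config = syn.SimConfig()
        truth = syn.draw_true_state(config)
        # single-substance inhibition at the NOEC equals the configured level
        tu_at_noec = truth.noec / truth.ec50
        f = syn.dose_response(tu_at_noec[0], config.tu50, config.slope)
        assert f == pytest.approx(config.noec_effect_level)
        assert np.all(truth.noec < truth.ec50)


class TestMonitoring:
    def test_certain_detection(self):
        config = syn.SimConfig(n_sites=1, n_pesticides=2, n_samples_per_site=10,
                               detect_freq_range=(1.0, 1.0), seed=1)
        df = syn.gen_monitoring(config)
        assert len(df) == 20
        assert not df["below_loq"].any()
        assert (df["concentration"] >= config.loq).all()

    def test_never_detected(self):
        config = syn.SimConfig(n_sites=1, n_pesticides=2, n_samples_per_site=10,
                               detect_freq_range=(0.0, 0.0), seed=1)
        df = syn.gen_monitoring(config)
        assert df["below_loq"].all()
        assert (df["concentration"] == config.loq).all()  # censoring sentinel

    def test_determinism(self):
        config = syn.SimConfig(n_sites=2, n_pesticides=3, seed=42)
        pd.testing.assert_frame_equal(syn.gen_monitoring(config),
                                      syn.gen_monitoring(config))
        pd.testing.assert_frame_equal(syn.gen_ecotox_db(config),
                                      syn.gen_ecotox_db(config))

    def test_substream_isolation(self):
        """Adding pesticides must not perturb existing pesticides' draws."""
        a = syn.gen_monitoring(syn.SimConfig(n_sites=1, n_pesticides=3, seed=7))
        b = syn.gen_monitoring(syn.SimConfig(n_sites=1, n_pesticides=5, seed=7))
        sub_a = a[a["pesticide"] == "pest_01"].reset_index(drop=True)
        sub_b = b[b["pesticide"] == "pest_01"].reset_index(drop=True)
        pd.testing.assert_frame_equal(sub_a, sub_b)


class TestEcotoxDb:
    def test_invariants(self, small_sim, small_truth):
        df = syn.gen_ecotox_db(small_sim, small_truth)
        assert len(df) >= 2 * small_sim.n_pesticides
        assert (df["value"] > 0).all()
        for pest, sub in df.groupby("pesticide"):
            assert "NOEC" in set(sub["endpoint_type"])
            assert sub["species"].nunique() >= 2
            noec = sub.loc[sub["endpoint_type"] == "NOEC", "value"].min()
            ec50 = sub.loc[sub["endpoint_type"].isin(["EC50", "LC50"]), "value"].min()
            assert noec < ec50


class TestReproductionTest:
    def _levels(self, truth, tu=0.0):
        concs = {p: tu / len(truth.pesticides) * e
                 for p, e in zip(truth.pesticides, truth.ec50)}
        zeros = {p: 0.0 for p in truth.pesticides}
        return {syn.NEGATIVE_CONTROL: zeros, syn.SOLVENT_CONTROL: zeros,
                "T1": concs}

    def test_missing_controls_rejected(self, small_sim, small_truth):
        with pytest.raises(errors.InvalidDesignError):
            syn.gen_reproduction_test({"T1": {p: 0.0 for p in small_truth.pesticides}},
                                      small_truth, small_sim)

    def test_null_mean_recovery(self, small_truth):
        """At zero toxic units the juvenile mean converges to the control
        mean (within 2% at 10^4 replicates)."""
        config = syn.SimConfig(n_sites=1, n_pesticides=3, n_replicates=10_000, seed=5)
        truth = syn.draw_true_state(config)
        jars = syn.gen_reproduction_test(self._levels(truth, tu=0.0), truth, config)
        mean = jars[jars["treatment"] == "T1"]["juveniles"].mean()
        assert mean == pytest.approx(config.control_juvenile_mean, rel=0.02)

    def test_mean_scales_with_inhibition(self):
        """Mean juveniles at toxic-unit load TU approaches
        control_mean × (1 − f(TU))."""
        config = syn.SimConfig(n_sites=1, n_pesticides=3, n_replicates=10_000, seed=5)
        truth = syn.draw_true_state(config)
        tu = 0.8
        f = syn.dose_response(tu, config.tu50, config.slope)
        jars = syn.gen_reproduction_test(self._levels(truth, tu=tu), truth, config)
        mean = jars[jars["treatment"] == "T1"]["juveniles"].mean()
        assert mean == pytest.approx(config.control_juvenile_mean * (1 - f), rel=0.02)

    def test_adults_within_binomial_support(self, small_sim, small_truth):
        jars = syn.gen_reproduction_test(self._levels(small_truth, 2.0),
                                         small_truth, small_sim)
        assert jars["adults_surviving"].between(0, small_sim.n_introduced).all()
        assert (jars["juveniles"] >= 0).all()
        for row in jars.itertuples():
            assert len(row.adult_sizes) <= row.adults_surviving

    def test_synergy_increases_inhibition(self):
        """At a fixed sub-maximal TU, λ = 3 depresses reproduction more
        than λ = 1."""
        means = {}
        for lam in (1.0, 3.0):
            config = syn.SimConfig(n_sites=1, n_pesticides=3, n_replicates=400,
                                   synergy_lambda=lam, seed=9)
            truth = syn.draw_true_state(config)
            jars = syn.gen_reproduction_test(self._levels(truth, tu=0.5),
                                             truth, config)
            means[lam] = jars[jars["treatment"] == "T1"]["juveniles"].mean()
        assert means[3.0] < means[1.0]

    def test_determinism(self, small_sim, small_truth):
        a = syn.gen_reproduction_test(self._levels(small_truth, 1.0),
                                      small_truth, small_sim, site="x")
        b = syn.gen_reproduction_test(self._levels(small_truth, 1.0),
                                      small_truth, small_sim, site="x")
        pd.testing.assert_frame_equal(a, b)


def test_write_dataset_sidecar(tmp_path, small_sim):
    import json

    paths = syn.write_dataset(tmp_path, small_sim)
    sidecar = json.loads((tmp_path / "params.json").read_text())
    assert sidecar["config"]["seed"] == small_sim.seed
    assert len(sidecar["true_state"]["ec50_mg_kg"]) == small_sim.n_pesticides
    for name in ("monitoring", "ecotox", "pesticide_info"):
        assert (tmp_path / f"{name}.csv").exists(), paths
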