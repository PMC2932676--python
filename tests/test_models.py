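"""Cell-model interface: baselines, scaling, derivatives, integration."""

import numpy as np
import pytest

from cardioreg import models, protocols


@pytest.mark.parametrize("model_id,p", [("tnnp", 16), ("lr1", 6),
                                        ("bernus", 8)])
def test_baseline_parameters_roster(model_id, p):
    ps = models.baseline_parameters(model_id)
    assert len(ps.values) == p
    assert np.all(ps.values > 0)
    assert np.all(ps.scale_factors == 1.0)
    spec = models.get_model(model_id)
    assert len(spec.parameter_names) == p
    assert spec.state_names.count("V") == 1


def test_tnnp_parameter_names():
    ps = models.baseline_parameters("tnnp")
    assert ps.names == ("G_Na", "G_CaL", "G_to", "G_Kr", "G_Ks", "G_K1",
                        "G_pK", "G_bNa", "G_bCa", "K_pCa", "K_NaK", "K_NCX",
                        "K_up", "K_leak", "K_rel1", "K_rel2")


def test_unknown_model_rejected():
    with pytest.raises(KeyError, match="unknown model"):
        models.baseline_parameters("noble1962")


class TestScaleParameters:
    def test_identity(self):
        base = models.baseline_parameters("lr1")
        scaled = models.scale_parameters(base, np.ones(6))
        np.testing.assert_array_equal(scaled.values, base.values)

    def test_round_trip_factors(self):
        base = models.baseline_parameters("tnnp")
        rng = np.random.default_rng(0)
        f = np.exp(0.3 * rng.standard_normal(16))
        scaled = models.scale_parameters(base, f)
        np.testing.assert_allclose(scaled.scale_factors, f, rtol=1e-12)
        np.testing.assert_allclose(scaled.values, base.values * f, rtol=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.nan, np.inf])
    def test_invalid_factor_named(self, bad):
        base = models.baseline_parameters("lr1")
        f = np.ones(6)
        f[2] = bad
        with pytest.raises(ValueError, match="G_K"):
            models.scale_parameters(base, f)

    def test_wrong_length(self):
        base = models.baseline_parameters("lr1")
        with pytest.raises(ValueError):
            models.scale_parameters(base, np.ones(5))


class TestDerivatives:
    def test_lr1_settles_to_equilibrium(self):
        """After 10 s quiescence the resting state is an equilibrium."""
        p = models.baseline_parameters("lr1")
        spec = protocols.ProtocolSpec(protocol_id="quiescence",
                                      quiescence_duration=10000.0,
                                      stim_amplitude=0.0, dt_sample=5.0,
                                      dt_max=5.0)
        tr = protocols.run_protocol("lr1", p, spec)
        dy = models.evaluate_derivatives("lr1", tr.final_state, p)
        assert np.max(np.abs(dy)) < 1e-6

    def test_deterministic(self):
        p = models.baseline_parameters("tnnp")
        state = models.get_model("tnnp").initial_state
        d1 = models.evaluate_derivatives("tnnp", state, p, stim=10.0)
        d2 = models.evaluate_derivatives("tnnp", state, p, stim=10.0)
        np.testing.assert_array_equal(d1, d2)

    def test_stimulus_enters_voltage_balance(self):
        """dV/dt with a stimulus equals dV/dt without it plus the stimulus
        (current balance in pA/pF)."""
        for mid in ("lr1", "tnnp", "bernus"):
            p = models.baseline_parameters(mid)
            state = models.get_model(mid).initial_state
            d0 = models.evaluate_derivatives(mid, state, p, stim=0.0)
            d1 = models.evaluate_derivatives(mid, state, p, stim=20.0)
            assert d1[0] - d0[0] == pytest.approx(20.0, abs=1e-9)

    def test_nonfinite_state_rejected(self):
        p = models.baseline_parameters("lr1")
        state = models.get_model("lr1").initial_state.copy()
        state[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            models.evaluate_derivatives("lr1", state, p)

    def test_mismatched_model_rejected(self):
        p = models.baseline_parameters("lr1")
        state = models.get_model("tnnp").initial_state
        with pytest.raises(ValueError):
            models.evaluate_derivatives("tnnp", state, p)


class TestIntegration:
    @pytest.mark.parametrize("model_id", ["lr1", "tnnp", "bernus"])
    def test_gates_stay_in_unit_interval(self, model_id):
        p = models.baseline_parameters(model_id)
        spec = protocols.ProtocolSpec(protocol_id="paced", n_beats=3,
                                      stim_amplitude=52.0)
        tr = protocols.run_protocol(model_id, p, spec)
        mspec = models.get_model(model_id)
        # reconstruct sampled gate values from the trace's state samples
        # via a fresh run capturing the full state matrix
        T, S, _, _, status = models._integrate(
            model_id, mspec.initial_state, p, mspec.Ko_default, 3000.0,
            np.arange(3) * 1000.0, 1.0, 52.0, 0.5, 0.002, 2.0, 0.15, 6e-6)
        assert status == 0
        for g in mspec.gate_indices:
            assert S[:, g].min() >= -1e-12
            # the ten Tusscher Ca-dependent inactivation gate fCa has a
            # steady state of (1 + 0.1 + 0.2 + 0.23)/1.46 ~ 1.048 by its
            # published formulation, so it may exceed 1 slightly at rest
            hi = 1.048 if mspec.state_names[g] == "fCa" else 1.0 + 1e-12
            assert S[:, g].max() <= hi
        assert tr.voltage.max() > 0  # sanity: the cell fired

    def test_tnnp_apd_converges_under_pre_pacing(self, tnnp_steady_trace):
        """Beat-to-beat APD change < 0.1% at the configured pre-pacing."""
        from cardioreg.features import action_potential_features
        tr = tnnp_steady_trace
        n = tr.n_beats
        a1 = action_potential_features(tr, n - 2)["APD"]
        a2 = action_potential_features(tr, n - 1)["APD"]
        assert abs(a2 - a1) / a2 < 1e-3

    def test_trace_deterministic(self):
        p = models.baseline_parameters("bernus")
        spec = protocols.ProtocolSpec(protocol_id="paced", n_beats=2,
                                      stim_amplitude=40.0)
        t1 = protocols.run_protocol("bernus", p, spec)
        t2 = protocols.run_protocol("bernus", p, spec)
        np.testing.assert_array_equal(t1.voltage, t2.voltage)
        np.testing.assert_array_equal(t1.final_state, t2.final_state)

    def test_apd_stable_under_tolerance_halving(self):
        """APD of the baseline TNNP beat moves < 0.1 ms when the step
        controller's tolerances are halved."""
        from cardioreg.features import action_potential_features
        p = models.baseline_parameters("tnnp")
        apds = []
        for dv, dca in ((0.15, 6e-6), (0.075, 3e-6)):
            spec = protocols.ProtocolSpec(protocol_id="paced", n_beats=3,
                                          stim_amplitude=52.0,
                                          dv_max=dv, dca_max=dca)
            tr = protocols.run_protocol("tnnp", p, spec)
            apds.append(action_potential_features(tr, 2)["APD"])
        assert abs(apds[0] - apds[1]) < 0.1
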