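"""Protocol searches against analytic surrogates and the live models."""

import numpy as np
import pytest

from cardioreg import models, protocols
from cardioreg.protocols import (ProtocolSpec, bisect_threshold,
                                 detect_alternans, max_centered_slope,
                                 scan_alternans)


class TestProtocolSpec:
    def test_rejects_bad_timing(self):
        with pytest.raises(ValueError):
            ProtocolSpec(bcl=1.0, stim_duration=2.0)
        with pytest.raises(ValueError):
            ProtocolSpec(n_beats=0)
        with pytest.raises(ValueError):
            ProtocolSpec(Ko=-1.0)

    def test_unknown_protocol(self):
        with pytest.raises(ValueError, match="unknown protocol"):
            ProtocolSpec(protocol_id="dynamic_restitution")


class TestRunProtocol:
    def test_no_stimulus_no_ap(self):
        p = models.baseline_parameters("tnnp")
        spec = ProtocolSpec(protocol_id="paced", n_beats=3,
                            stim_amplitude=0.0)
        tr = protocols.run_protocol("tnnp", p, spec)
        assert tr.voltage.max() < -40.0

    def test_quiescence_returns_concentrations(self):
        """60 s of quiescence yields the resting Ca/Na/K levels."""
        p = models.baseline_parameters("tnnp")
        spec = ProtocolSpec(protocol_id="quiescence",
                            quiescence_duration=60000.0,
                            stim_amplitude=0.0, dt_sample=5.0, dt_max=5.0)
        tr = protocols.run_protocol("tnnp", p, spec)
        assert tr.time[-1] == pytest.approx(60000.0, abs=5.0)
        assert 1e-6 < tr.Cai[-1] < 1e-3      # sub-uM diastolic Ca (mM)
        assert 5.0 < tr.Nai[-1] < 20.0
        assert 120.0 < tr.Ki[-1] < 150.0

    def test_trace_invariants(self, tnnp_steady_trace):
        tr = tnnp_steady_trace
        assert np.all(np.diff(tr.time) > 0)
        assert len(tr.beat_boundaries) == 40
        assert np.all(np.diff(tr.beat_boundaries) > 0)


class TestStimulationThreshold:
    def test_matches_fine_grid_on_analytic_surrogate(self):
        theta = 17.3

        def probe(a):
            return a >= theta

        found = bisect_threshold(probe, 2.0, 80.0, tol=0.1)
        # brute-force reference on a fine grid
        grid = np.arange(2.0, 80.0, 0.01)
        ref = grid[np.argmax([probe(a) for a in grid])]
        assert abs(found - ref) <= 0.1

    def test_bracket_violations(self):
        with pytest.raises(ValueError, match="upper bound subthreshold"):
            bisect_threshold(lambda a: False, 2.0, 80.0)
        with pytest.raises(ValueError, match="lower bracket"):
            bisect_threshold(lambda a: True, 2.0, 80.0)

    def test_invariant_to_bracket_width(self):
        p = models.baseline_parameters("tnnp")
        t1 = protocols.find_stimulation_threshold("tnnp", p, lo=2.0, hi=80.0)
        t2 = protocols.find_stimulation_threshold("tnnp", p, lo=10.0, hi=40.0)
        assert abs(t1 - t2) <= 0.2  # both within tol of the true threshold

    def test_model_threshold_bracketed(self):
        """The search converges to a value that behaves like a threshold."""
        p = models.baseline_parameters("lr1")
        audit = []
        thr = protocols.find_stimulation_threshold("lr1", p, audit=audit)
        fired = {round(a, 4): f for a, f in audit}
        assert all(not f for a, f in audit if a < thr - 0.1)
        assert all(f for a, f in audit if a > thr + 0.1)


class TestAlternans:
    @staticmethod
    def _map_runner(bcl, n_beats=10, apd0=200.0):
        """Iterate the restitution map APD_{n+1} = f(BCL - APD_n)."""
        def f(di):
            return 130.0 + 120.0 / (1.0 + np.exp(-(di - 60.0) / 20.0))
        apds = []
        apd = apd0
        for _ in range(n_beats):
            di = bcl - apd
            if di < 5.0:
                apds.append(np.nan)
                di = 5.0
                apd = f(di)
                continue
            apd = f(di)
            apds.append(apd)
        return apds

    def test_surrogate_matches_map_iteration(self):
        """Detected threshold within one grid step of direct map iteration."""
        found = scan_alternans(self._map_runner, 350.0, 150.0, 5.0)
        # brute force: iterate the same map on the same grid directly
        ref = 150.0 - 5.0
        for bcl in np.arange(350.0, 147.5, -5.0):
            apds = self._map_runner(bcl)
            if detect_alternans(apds):
                ref = bcl
                break
        assert found == pytest.approx(ref, abs=5.0)
        assert found > 150.0  # the map does alternate inside the grid

    def test_constant_apd_gives_sentinel(self):
        found = scan_alternans(lambda bcl: [250.0] * 10, 350.0, 150.0, 5.0)
        assert found == 145.0

    def test_detection_resolution_matches_grid(self):
        """A cell alternating below 285 ms but not at it reports 280 ms."""
        def runner(bcl):
            if bcl <= 280.0:
                return [200.0, 210.0, 200.0, 210.0, 200.0, 210.0]
            return [205.0] * 6
        assert scan_alternans(runner, 350.0, 150.0, 5.0) == 280.0

    def test_capture_loss_stops_scan(self):
        calls = []

        def runner(bcl):
            calls.append(bcl)
            if bcl < 300.0:
                return [np.nan] * 10
            return [250.0] * 10

        found = scan_alternans(runner, 350.0, 150.0, 5.0)
        assert found == 145.0
        assert min(calls) == 295.0  # scan stopped at capture loss


class TestRestitution:
    def test_exponential_surrogate_matches_closed_form(self):
        """APD(DI) = a - b exp(-DI/tau): max slope = (b/tau) e^(-DImin/tau)."""
        a, b, tau = 300.0, 150.0, 80.0
        di = np.arange(20.0, 400.0, 10.0)
        apd = a - b * np.exp(-di / tau)
        slope = max_centered_slope(di, apd)
        expected = (b / tau) * np.exp(-(di[1]) / tau)  # centered at 2nd point
        assert slope == pytest.approx(expected, rel=0.05)

    def test_flat_surrogate_zero_slope(self):
        di = np.linspace(20, 400, 15)
        assert max_centered_slope(di, np.full_like(di, 250.0)) == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            max_centered_slope([10, 20], [100, 110])

    def test_tnnp_baseline_slope_positive(self, tnnp_steady_trace):
        p = models.baseline_parameters("tnnp")
        slope, di, apd = protocols.restitution_max_slope(
            "tnnp", p, initial_state=tnnp_steady_trace.final_state)
        assert slope is not None and 0.0 < slope < 5.0
        assert len(di) >= 3
        assert np.all(np.diff(apd[np.argsort(di)]) > -30)  # broadly restitutive
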