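"""Integrator: smoothing, loading conventions, outcomes, round trips."""

import numpy as np
import pytest

from osmotip import (
    exp_relax,
    initial_state,
    run,
    stall_pressure,
    standard_lilium,
    steady_state_summary,
)


class TestExpRelax:
    def test_halves_gap_per_half_time(self):
        assert exp_relax(0.0, 1.0, dt=0.5, half_time=0.5) == \
            pytest.approx(0.5)
        assert exp_relax(0.0, 1.0, dt=1.0, half_time=0.5) == \
            pytest.approx(0.75)

    def test_fixed_point(self):
        assert exp_relax(2.0, 2.0, dt=0.4, half_time=0.3) == 2.0

    def test_rejects_nonpositive_times(self):
        with pytest.raises(ValueError):
            exp_relax(0.0, 1.0, dt=0.0, half_time=0.5)
        with pytest.raises(ValueError):
            exp_relax(0.0, 1.0, dt=0.1, half_time=0.0)


class TestInitialState:
    def test_stall_pressure_reference(self, params):
        # 4*alpha*G*L_wall^2/(K*r^2) at L_wall = K*r/(2*G)
        assert stall_pressure(params) == pytest.approx(0.3781, rel=1e-3)

    def test_equilibrium_loading_is_stationary(self, params):
        # loaded at stall pressure: the film does not yield, no flux
        s = initial_state(params, loading="equilibrium")
        assert s.L == 500.0
        assert s.pi_internal(params) - params.Pi_o == pytest.approx(
            stall_pressure(params), rel=1e-9)

    def test_isotonic_loading_has_no_osmotic_difference(self, params):
        s = initial_state(params, loading="isotonic")
        assert s.pi_internal(params) == pytest.approx(params.Pi_o, rel=1e-9)

    def test_steady_loading_holds_without_drift(self, params):
        tc = run(params, duration=400.0, loading="steady")
        s = tc.trailing_summary()
        assert s.dL_dt == pytest.approx(0.2, rel=1e-6)
        assert s.L_wall == pytest.approx(0.25, rel=1e-6)
        assert s.max_drift < 1e-9

    def test_unknown_loading_rejected(self, params):
        with pytest.raises(ValueError):
            initial_state(params, loading="bogus")


class TestOutcomes:
    def test_baseline_settles_near_calibration(self, baseline_tc):
        s = baseline_tc.trailing_summary(tol=0.01)
        assert s.steady
        assert s.dL_dt * 60 == pytest.approx(12.0, rel=0.10)
        assert s.dP == pytest.approx(0.427, rel=0.05)

    def test_burst_trajectory_reports_zero_pressures(self, params):
        p = params.replace(alpha=0.0)
        tc = run(p, duration=200.0, loading="steady")
        assert tc.outcome == "burst"
        assert tc.burst_time is not None
        assert tc["dP_MPa"][-1] == 0.0 and tc["dPi_MPa"][-1] == 0.0
        with pytest.raises(ValueError):
            steady_state_summary(tc)

    def test_arrest_outcome(self, params):
        p = params.replace(alpha=params.alpha * 20)
        tc = run(p, duration=1500.0, loading="steady")
        assert tc.outcome == "arrest"


class TestReproducibilityAndRoundTrip:
    def test_bit_identical_reruns(self, params):
        a = run(params, duration=300.0)
        b = run(params, duration=300.0)
        for col in a.data:
            assert np.array_equal(a.data[col], b.data[col])

    def test_dt_halving_changes_summary_under_1pct(self, baseline_tc):
        fine = run(standard_lilium(dt=0.2), duration=2000.0)
        s4 = baseline_tc.trailing_summary(tol=0.01)
        s2 = fine.trailing_summary(tol=0.01)
        for field in ("dL_dt", "dPi", "dP", "L_wall", "dVwall_dt"):
            a, b = getattr(s4, field), getattr(s2, field)
            assert abs(a - b) / abs(a) < 0.01

    def test_csv_round_trip(self, params, tmp_path):
        tc = run(params, duration=200.0)
        path = tmp_path / "tc.csv"
        tc.to_csv(path)
        frame = tc.frame_from_csv(path)
        for col in tc.data:
            assert np.allclose(frame[col].to_numpy(), tc.data[col],
                               rtol=1e-9, atol=1e-12)

    def test_metadata_sidecar(self, params, tmp_path):
        import json

        tc = run(params, duration=200.0)
        path = tmp_path / "tc.json"
        tc.write_metadata(path)
        meta = json.loads(path.read_text())
        assert meta["outcome"] == tc.outcome
        assert meta["parameters"]["r"] == params.r
        assert meta["sensor"] == "dPi-dP->dVwall/dt"
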