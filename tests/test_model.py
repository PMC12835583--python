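"""Core circulation model: elastance shape, pressure/flow algebra,
conservation, and steady-state simulation behavior."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from rvcirc.model import (
    ModelParameters,
    SimulationError,
    compartment_pressures,
    elastance,
    junction_flows,
    rhs,
    simulate,
)


def make_params(**over):
    base = dict(
        Rval_T=0.05, Rval_P=0.006, R_PA=0.1, R_PC=0.1, R_PV=0.12,
        C_PA=0.5, C_PC=1.2, C_PV=0.9,
        Emax=1.2, Emin=0.017, tmax=0.17, tmin=0.42,
        V0_PA=14.0, V0_PC=30.0, V0_PV=17.0,
        P_RA=4.0, P_LA=10.0, T=0.85,
    )
    base.update(over)
    return ModelParameters(**base)


class TestElastance:
    def test_anchor_points(self):
        p = make_params()
        assert elastance(0.0, p) == pytest.approx(p.Emin)
        assert elastance(p.tmax, p) == pytest.approx(p.Emax)
        assert elastance((p.tmin + p.T) / 2, p) == pytest.approx(p.Emin)

    def test_raised_cosine_midpoint(self):
        # halfway up the activation ramp the raised cosine sits exactly at
        # the mean of the elastance extremes
        p = make_params()
        assert elastance(p.tmax / 2, p) == pytest.approx((p.Emin + p.Emax) / 2)

    @given(st.floats(0.0, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_and_periodic(self, t):
        p = make_params()
        e = elastance(t, p)
        assert p.Emin - 1e-12 <= e <= p.Emax + 1e-12
        assert elastance(t + p.T, p) == pytest.approx(e, abs=1e-12)

    def test_continuity_at_phase_joints(self):
        p = make_params()
        for joint in (p.tmax, p.tmin):
            lo = elastance(joint - 1e-9, p)
            hi = elastance(joint + 1e-9, p)
            assert lo == pytest.approx(hi, abs=1e-5)

    def test_invalid_timing_rejected(self):
        with pytest.raises(ValueError):
            make_params(tmax=0.5, tmin=0.4)
        with pytest.raises(ValueError):
            make_params(tmin=0.9, T=0.85)


class TestPressureFlowAlgebra:
    def test_unstressed_volume_gives_zero_pressure(self):
        p = make_params()
        _, P_PA, _, _ = compartment_pressures(
            (100.0, p.V0_PA, 50.0, 40.0), 0.0, p)
        assert P_PA == pytest.approx(0.0)

    def test_rv_pressure_is_elastance_times_volume(self):
        p = make_params(Emax=0.5, Emin=0.4)
        P_RV, *_ = compartment_pressures((100.0, 20.0, 50.0, 40.0), p.tmax, p)
        assert P_RV == pytest.approx(0.5 * 100.0)

    def test_linear_compliance(self):
        p = make_params(C_PC=2.0)
        _, _, P_PC, _ = compartment_pressures(
            (100.0, 20.0, p.V0_PC + 10.0, 40.0), 0.0, p)
        assert P_PC == pytest.approx(5.0)

    def test_tricuspid_diode_blocks_systolic_backflow(self):
        p = make_params(P_RA=5.0)
        q = junction_flows((50.0, 30.0, 20.0, 12.0), p)
        assert q[0] == 0.0

    def test_ohm_analog(self):
        p = make_params(R_PA=5.0)
        q = junction_flows((0.0, 20.0, 10.0, 10.5), p)
        assert q[2] == pytest.approx(2.0)

    def test_venous_segment_permits_reverse_flow(self):
        # only the valves are diodes; vascular segments are ungated
        p = make_params(P_LA=10.0)
        q = junction_flows((0.0, 20.0, 15.0, 8.0), p)
        assert q[4] < 0.0


class TestRHS:
    def test_conservation_identity(self):
        # total-volume rate equals inflow minus outflow of the whole chain
        p = make_params()
        rng = np.random.default_rng(7)
        for _ in range(25):
            s = rng.uniform([50, 5, 20, 10], [200, 40, 80, 50])
            t = rng.uniform(0, p.T)
            d = rhs(t, s, p)
            q = junction_flows(compartment_pressures(s, t, p), p)
            assert np.sum(d) == pytest.approx(q[0] - q[4], rel=1e-12)

    def test_hand_computed_filling_state(self):
        # diastole (t in the plateau), atrial pressure above RV pressure:
        # every flow and derivative follows by hand from the circuit algebra
        p = make_params(Emin=0.02, P_RA=4.0, P_LA=10.0)
        t = 0.8 * p.T                      # diastolic plateau, E = Emin
        s = (100.0, p.V0_PA + 10.0, p.V0_PC + 24.0, p.V0_PV + 10.8)
        P = compartment_pressures(s, t, p)
        assert P[0] == pytest.approx(2.0)   # 0.02 * 100
        assert P[1] == pytest.approx(20.0)  # 10 / 0.5
        assert P[2] == pytest.approx(20.0)  # 24 / 1.2
        assert P[3] == pytest.approx(12.0)  # 10.8 / 0.9
        d = rhs(t, s, p)
        q_t = (4.0 - 2.0) / p.Rval_T        # 40 mL/s through tricuspid
        q_pc = (20.0 - 12.0) / p.R_PC       # 80 mL/s capillary -> veins
        q_pv = (12.0 - 10.0) / p.R_PV       # 16.67 mL/s veins -> LA
        assert d[0] == pytest.approx(q_t)        # pulmonic valve shut
        assert d[1] == pytest.approx(0.0)        # P_PA == P_PC
        assert d[2] == pytest.approx(0.0 - q_pc)
        assert d[3] == pytest.approx(q_pc - q_pv)

    def test_equal_flows_give_zero_derivatives(self):
        # contrived pressures with equal gradients/resistance ratios
        p = make_params(Rval_T=1.0, Rval_P=1.0, R_PA=1.0, R_PC=1.0, R_PV=1.0,
                        P_RA=50.0, P_LA=0.0)
        pres = (40.0, 30.0, 20.0, 10.0)
        q = junction_flows(pres, p)
        assert np.allclose(np.diff(q), 0.0)
        # with equal flows everywhere the volume derivatives all vanish
        d = [qi - qo for qi, qo in zip(q[:-1], q[1:])]
        assert np.allclose(d, 0.0)


class TestSimulate:
    def test_periodic_steady_state_balances_valve_flows(self, baseline_params):
        s = simulate(baseline_params)
        assert s.periodicity_error < 1e-3
        # filling and ejection throughput agree at steady state
        assert s.cycle_mean(s.Q_val_T) == pytest.approx(
            s.cycle_mean(s.Q_val_P), rel=0.01)
        # chain throughput conservation
        assert s.cycle_mean(s.Q_val_P) == pytest.approx(
            s.cycle_mean(s.Q_PV), rel=0.01)

    def test_valve_flows_nonnegative(self, baseline_params):
        s = simulate(baseline_params)
        assert s.Q_val_T.min() >= -1e-9
        assert s.Q_val_P.min() >= -1e-9

    def test_output_grid_and_metadata(self, baseline_params):
        s = simulate(baseline_params, n_out=150)
        assert len(s.t) == 150
        assert s.t[0] == 0.0 and s.t[-1] == pytest.approx(baseline_params.T)
        assert s.cycles_run == 40

    def test_increasing_rpa_raises_mean_pa_pressure(self, baseline_params):
        means = []
        for f in (0.5, 0.75, 1.0, 1.5, 2.0):
            p = replace(baseline_params, R_PA=baseline_params.R_PA * f)
            s = simulate(p, stop_tol=1e-6)
            means.append(s.cycle_mean(s.P_PA))
        assert np.all(np.diff(means) > 0)

    def test_increasing_emax_raises_esp_and_lowers_esv(self, baseline_params):
        esp, esv = [], []
        for f in (0.6, 0.8, 1.0, 1.3, 1.6):
            p = replace(baseline_params, Emax=baseline_params.Emax * f)
            s = simulate(p, stop_tol=1e-6)
            i = int(np.argmin(s.V_RV))
            esv.append(s.V_RV[i])
            esp.append(s.P_RV[i])
        assert np.all(np.diff(esp) > 0)
        assert np.all(np.diff(esv) < 0)

    def test_resistor_chain_limit(self):
        # nearly constant elastance and huge compliances: the circulation
        # degenerates to a resistor chain driven by the atrial gradient
        p = make_params(Emin=0.2, Emax=0.2000001, tmax=0.2, tmin=0.5,
                        C_PA=500.0, C_PC=500.0, C_PV=500.0,
                        P_RA=20.0, P_LA=5.0)
        s = simulate(p, n_cycles=300)
        R_tot = p.Rval_T + p.Rval_P + p.R_PA + p.R_PC + p.R_PV
        q_expected = (p.P_RA - p.P_LA) / R_tot
        assert s.cycle_mean(s.Q_PV) == pytest.approx(q_expected, rel=0.05)

    def test_n_cycles_validation(self, baseline_params):
        with pytest.raises(ValueError):
            simulate(baseline_params, n_cycles=1)

    def test_blow_up_reports_parameters(self, baseline_params):
        p = replace(baseline_params, Emax=baseline_params.Emax)
        with pytest.raises(SimulationError) as exc:
            simulate(p, pressure_ceiling=1.0)
        assert exc.value.params is p

    def test_serialization_round_trip(self, baseline_params, tmp_path):
        path = tmp_path / "params.json"
        baseline_params.to_json(path)
        back = ModelParameters.from_json(path)
        assert back == baseline_params

    def test_trace_csv_header(self, baseline_params, tmp_path):
        s = simulate(baseline_params, n_out=50)
        out = tmp_path / "traces.csv"
        s.write_csv(out)
        header = out.read_text().splitlines()[0]
        assert header == "t,P_RV,P_PA,P_PC,P_PV,Q_val_T,Q_val_P,Q_PA,Q_PC,Q_PV,V_RV"
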