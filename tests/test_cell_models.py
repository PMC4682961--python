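"""Unit tests for the single-cell layer."""

import numpy as np
import pytest

from eadclump import constants
from eadclump.cell_models import (CURRENT_NAMES, CompositeUnit,
                                  FibroblastParams, FibroblastState,
                                  MyocyteParams, MyocyteState,
                                  ParameterError, Trace, fibroblast_current,
                                  gap_current, initial_state, ionic_currents,
                                  ionic_rhs, make_ead_parameters,
                                  simulate_cell, step_composite)
from eadclump.cell_models._cell_loops import step_unit
from eadclump.protocols import single_cell_pacing


class TestMyocyteParams:
    def test_defaults(self):
        p = MyocyteParams()
        assert p.membrane_capacitance == 185.0
        assert np.all(p.multiplier_vector() == 1.0)

    def test_roster(self):
        assert len(CURRENT_NAMES) == 14
        assert "I_CaL" in CURRENT_NAMES and "I_pCa" in CURRENT_NAMES

    @pytest.mark.parametrize("bad", [{"I_CaL": 0.0}, {"I_CaL": -1.0},
                                     {"I_bogus": 1.0}])
    def test_invalid_multipliers(self, bad):
        with pytest.raises(ParameterError):
            MyocyteParams(multipliers=bad)

    def test_negative_capacitance(self):
        with pytest.raises(ParameterError):
            MyocyteParams(membrane_capacitance=-1.0)


class TestMakeEadParameters:
    def test_type1_defaults(self):
        p = make_ead_parameters("type-I")
        assert p.multipliers == {"I_CaL": 4.0, "I_Kr": 0.21}

    def test_type2_lower_gkr(self):
        p = make_ead_parameters("type-II")
        assert p.multipliers["I_CaL"] == 4.0
        assert p.multipliers["I_Kr"] < 0.21

    def test_identity_multipliers_are_control(self, control_rest):
        p = make_ead_parameters("type-I", 1.0, 1.0)
        i_ctrl, dy_ctrl = ionic_rhs(control_rest, MyocyteParams())
        i_id, dy_id = ionic_rhs(control_rest, p)
        assert i_ctrl == i_id
        np.testing.assert_array_equal(dy_ctrl, dy_id)

    def test_rejects_nonpositive(self):
        with pytest.raises(ParameterError):
            make_ead_parameters("type-I", -4.0, 0.21)
        with pytest.raises(ParameterError):
            make_ead_parameters("type-III")


class TestIonicRhs:
    def test_rest_balance(self, control_rest):
        # after 10 s quiescence the net membrane current nearly vanishes
        i_ion, _ = ionic_rhs(control_rest, MyocyteParams())
        assert abs(i_ion) < 0.05

    def test_multiplier_scales_single_current(self, control_rest):
        state = control_rest.copy()
        state.vm = -20.0   # I_Kr conducts here
        base = ionic_currents(state, MyocyteParams())
        doubled = ionic_currents(state, MyocyteParams(multipliers={"I_Kr": 2.0}))
        assert doubled["I_Kr"] == pytest.approx(2.0 * base["I_Kr"], rel=1e-12)
        for name in CURRENT_NAMES:
            if name != "I_Kr":
                assert doubled[name] == base[name]

    def test_all_derivatives_finite(self, control_rest):
        _, dy = ionic_rhs(control_rest, MyocyteParams())
        assert np.all(np.isfinite(dy))


class TestGapCurrent:
    def test_equal_potentials(self):
        assert gap_current(-80.0, -80.0, 8.0) == 0.0

    def test_direct_evaluation(self):
        # 8 nS x 30 mV = 240 pA
        assert gap_current(0.0, -30.0, 8.0) == pytest.approx(240.0)

    def test_uncoupled(self):
        for vm, vf in [(-80, 0), (20, -35), (0, 0)]:
            assert gap_current(vm, vf, 0.0) == 0.0

    def test_negative_ggap_rejected(self):
        with pytest.raises(ParameterError):
            gap_current(0.0, 0.0, -1.0)


class TestFibroblastCurrent:
    def test_zero_at_rest(self):
        p = FibroblastParams.constant(e_rest=-35.0)
        assert fibroblast_current(-35.0, p) == 0.0

    def test_piecewise_low_branch(self):
        # Vf below -20 mV -> 2 nS; 2 nS x 10 mV = 20 pA
        p = FibroblastParams.piecewise(e_rest=-35.0)
        assert fibroblast_current(-25.0, p) == pytest.approx(20.0)

    def test_constant_model(self):
        p = FibroblastParams.constant(e_rest=-30.0, gf=4.0)
        assert fibroblast_current(0.0, p) == pytest.approx(120.0)

    def test_piecewise_breakpoint(self):
        p = FibroblastParams.piecewise(e_rest=-35.0)
        assert p.conductance(-20.001) == 2.0
        assert p.conductance(-20.0) == 4.0

    def test_invalid(self):
        with pytest.raises(ParameterError):
            FibroblastParams(e_rest=-35.0, gf_low=0.0)


class TestStepComposite:
    def test_rest_stability(self, control_rest):
        unit = CompositeUnit(state=MyocyteState(control_rest.y.copy()))
        tr = simulate_cell(unit, single_cell_pacing(pcl=-1.0), 1000.0)
        assert abs(tr.vm[-1] - tr.vm[0]) < 1.0

    def test_gap_charge_antisymmetry(self, ead_rest):
        """Cm * dVm(gap part) == -Cf * dVf(gap part), machine precision."""
        params = make_ead_parameters("type-I")
        mult = params.multiplier_vector()
        cm, cf = 185.0, 6.3
        ef, ggap, dt = -35.0, 8.0, constants.DT
        y0 = ead_rest.y.copy()
        y0[0] = -20.0          # make the gap current sizeable
        vf0 = -35.0
        y_c = y0.copy()
        vf_c = step_unit(y_c, vf0, True, mult, cm, cf, ef, 4.0, 4.0, ggap,
                         dt, 0.0)
        y_u = y0.copy()
        step_unit(y_u, vf0, True, mult, cm, cf, ef, 4.0, 4.0, 0.0, dt, 0.0)
        dvm_gap = y_c[0] - y_u[0]
        dvf_gap = vf_c - (vf0 + dt * (0.0 - 4.0 * (vf0 - ef)) / cf)
        assert cm * dvm_gap == pytest.approx(-cf * dvf_gap, rel=1e-12)

    def test_fixed_point_when_potentials_equal(self, ead_rest):
        # with Vm == Vf == Ef both coupling currents vanish exactly and the
        # fibroblast potential is a fixed point of the update
        params = make_ead_parameters("type-I")
        y0 = ead_rest.y.copy()
        y0[0] = -35.0
        vf = step_unit(y0, -35.0, True, params.multiplier_vector(), 185.0,
                       6.3, -35.0, 4.0, 4.0, 8.0, constants.DT, 0.0)
        assert vf == -35.0

    def test_dt_validation(self, control_rest):
        unit = CompositeUnit(state=MyocyteState(control_rest.y.copy()))
        with pytest.raises(ParameterError):
            step_composite(unit, dt=-0.02)

    def test_ggap_zero_bitwise_identical(self, ead_rest):
        params = make_ead_parameters("type-I")
        proto = single_cell_pacing(pcl=1000.0)
        iso = CompositeUnit(state=MyocyteState(ead_rest.y.copy()),
                            params=params)
        coupled = CompositeUnit(state=MyocyteState(ead_rest.y.copy()),
                                params=params,
                                fib_state=FibroblastState(vf=-35.0),
                                fib_params=FibroblastParams.constant(-35.0),
                                g_gap=0.0)
        tr_iso = simulate_cell(iso, proto, 3000.0)
        tr_cpl = simulate_cell(coupled, proto, 3000.0)
        np.testing.assert_array_equal(tr_iso.vm, tr_cpl.vm)

    def test_fibroblast_relaxation_time_constant(self):
        """With I_gap = 0, V_f -> E_f monotonically with tau = C_f/G_f."""
        p = FibroblastParams.constant(e_rest=-35.0, gf=4.0)
        dt, vf, ef = 0.002, 0.0, p.e_rest
        tau = p.capacitance / p.gf_low   # ms
        vals = [vf]
        for _ in range(int(round(tau / dt))):
            vf = vf + dt * (0.0 - p.gf_low * (vf - ef)) / p.capacitance
            vals.append(vf)
        vals = np.array(vals)
        assert np.all(np.diff(vals) < 0)                  # monotone toward Ef
        expected = ef + (0.0 - ef) * np.exp(-1.0)         # one time constant
        assert vf == pytest.approx(expected, rel=2e-3)


class TestSimulateCell:
    def test_control_five_normal_aps(self, control_paced_trace):
        from eadclump.analysis import classify_ap, detect_aps
        tr = control_paced_trace
        sel = tr.time < 5050.0   # five pacing pulses fall in this window
        aps = detect_aps(tr.time[sel], tr.vm[sel], resting_vm=-88.0)
        assert len(aps) == 5
        assert all(classify_ap(a) == "normal" for a in aps)
        assert all(not a.eads for a in aps)

    def test_type1_growing_eads(self, type1_single_trace):
        from eadclump.analysis import detect_aps
        tr = type1_single_trace
        aps = detect_aps(tr.time, tr.vm, resting_vm=-88.0)
        assert len(aps) == 1
        amps = aps[0].ead_amplitudes
        assert len(amps) >= 2
        assert np.all(np.diff(amps) > 0)      # grow until repolarization
        assert aps[0].repolarized

    def test_fibroblast_suppresses_eads(self, composite_traces):
        from eadclump.analysis import detect_aps

        def total_ead(tr):
            aps = detect_aps(tr.time, tr.vm, resting_vm=-88.0)
            return sum(a.ead_amplitudes.sum() for a in aps)

        assert total_ead(composite_traces[-35.0]) < 0.5 * total_ead(
            composite_traces["isolated"])

    def test_state_valid_after_15s_pacing(self, control_rest):
        """Gates stay in [0,1] and concentrations positive over >= 15 s of
        pacing at dt = 0.02 ms."""
        from eadclump.cell_models._cell_loops import simulate_unit_loop
        y = control_rest.y.copy()
        simulate_unit_loop(y, 0.0, False, np.ones(14), 185.0, 6.3, 0.0,
                           4.0, 4.0, 0.0, constants.DT, 15000.0,
                           constants.STIM_AMPLITUDE,
                           constants.STIM_DURATION_CELL, 1000.0, 50.0, 1.0)
        MyocyteState(y).validate()

    def test_dt_convergence_apd(self, control_rest):
        """Halving dt changes the APD90 of one paced AP by < 1%."""
        from eadclump.analysis import detect_aps

        apds = {}
        for dt in (constants.DT, constants.DT / 2.0):
            unit = CompositeUnit(state=MyocyteState(control_rest.y.copy()))
            proto = single_cell_pacing(pcl=1000.0)
            proto.n_pulses = 1
            tr = simulate_cell(unit, proto, 900.0, dt=dt, sample_ms=0.5)
            ap = detect_aps(tr.time, tr.vm, resting_vm=-88.0)[0]
            apds[dt] = ap.t_end - ap.t_up
        assert abs(apds[constants.DT] - apds[constants.DT / 2.0]) \
            < 0.01 * apds[constants.DT / 2.0]


class TestTrace:
    def test_csv_roundtrip(self, tmp_path):
        tr = Trace(time=np.arange(5.0), vm=np.linspace(-88, 40, 5),
                   vf=np.linspace(-35, -30, 5))
        path = tmp_path / "trace.csv"
        tr.to_csv(path)
        back = Trace.from_csv(path)
        np.testing.assert_allclose(back.vm, tr.vm)
        np.testing.assert_allclose(back.vf, tr.vf)

    def test_state_validation(self):
        y = initial_state()
        y[9] = 1.5
        with pytest.raises(Exception):
            MyocyteState(y).validate()


class TestTraceH5:
    def test_h5_group_roundtrip(self, tmp_path):
        import h5py
        from eadclump.io import write_trace_h5
        path = tmp_path / "traces.h5"
        t = np.arange(4.0)
        write_trace_h5(path, t, t * 2.0, vf=t - 35.0, group="cell0",
                       metadata={"pcl": 1000.0})
        with h5py.File(path) as fh:
            np.testing.assert_allclose(fh["cell0/vm_mv"][:], t * 2.0)
            np.testing.assert_allclose(fh["cell0/vf_mv"][:], t - 35.0)
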