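"""Tests for AP/EAD classification, CV, PVC counting, and spectra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eadclump.analysis import (activation_time, averaged_power_spectrum,
                               classify_ap, conduction_velocity, count_pvcs,
                               detect_aps, index_peaks)


def synthetic_ap(plateau_ms=300.0, eads=(), rest=-88.0, peak=40.0,
                 dt_ms=1.0, total_ms=1000.0):
    """Piecewise AP-like signal with optional (time, amplitude) EAD bumps."""
    t = np.arange(0.0, total_ms, dt_ms)
    v = np.full_like(t, rest)
    up = 50.0
    rise = (t >= up) & (t < up + 2.0)
    v[rise] = np.interp(t[rise], [up, up + 2.0], [rest, peak])
    plateau = (t >= up + 2.0) & (t < up + plateau_ms)
    frac = (t[plateau] - (up + 2.0)) / plateau_ms
    v[plateau] = peak - frac * (peak - rest)
    for t0, amp in eads:
        bump = amp * np.exp(-0.5 * ((t - t0) / 8.0) ** 2)
        v = v + np.where((t > up + 2.0) & (t < up + plateau_ms), bump, 0.0)
    return t, v


class TestDetectAps:
    def test_flat_trace_empty(self):
        t = np.arange(0.0, 500.0)
        assert detect_aps(t, np.full_like(t, -88.0)) == []

    def test_nan_rejected(self):
        t = np.arange(0.0, 10.0)
        v = np.full_like(t, -88.0)
        v[3] = np.nan
        with pytest.raises(ValueError):
            detect_aps(t, v)

    def test_synthetic_single_ap(self):
        t, v = synthetic_ap()
        aps = detect_aps(t, v, resting_vm=-88.0)
        assert len(aps) == 1
        assert aps[0].repolarized
        assert aps[0].v_peak == pytest.approx(40.0, abs=1.0)

    def test_control_paced_beats(self, control_paced_trace):
        tr = control_paced_trace
        aps = detect_aps(tr.time, tr.vm, resting_vm=-88.0)
        assert len(aps) == 15
        assert all(a.repolarized for a in aps)

    def test_type2_elevated_final(self, type2_single_trace):
        tr = type2_single_trace
        aps = detect_aps(tr.time, tr.vm, resting_vm=-88.0)
        assert len(aps) == 1
        ap = aps[0]
        assert not ap.repolarized
        assert ap.v_final > -78.0   # elevated above rest


class TestDetectEads:
    def test_monotonic_repolarization_no_eads(self):
        t, v = synthetic_ap()
        aps = detect_aps(t, v, resting_vm=-88.0)
        assert aps[0].eads == []

    def test_synthetic_damped_oscillation_decreasing(self):
        t, v = synthetic_ap(plateau_ms=600.0,
                            eads=[(150.0, 30.0), (250.0, 20.0),
                                  (350.0, 12.0), (450.0, 6.0)],
                            total_ms=1200.0)
        aps = detect_aps(t, v, resting_vm=-88.0)
        amps = aps[0].ead_amplitudes
        assert len(amps) >= 3
        assert np.all(np.diff(amps) < 0)

    def test_type1_nondecreasing(self, type1_single_trace):
        tr = type1_single_trace
        ap = detect_aps(tr.time, tr.vm, resting_vm=-88.0)[0]
        amps = ap.ead_amplitudes
        assert len(amps) >= 1
        assert np.all(np.diff(amps) >= 0)

    def test_amplitudes_nonnegative(self, type1_paced_trace):
        tr = type1_paced_trace
        for ap in detect_aps(tr.time, tr.vm, resting_vm=-88.0):
            assert np.all(ap.ead_amplitudes >= 0)


class TestClassifyAp:
    def test_control_normal(self, control_paced_trace):
        tr = control_paced_trace
        ap = detect_aps(tr.time, tr.vm, resting_vm=-88.0)[0]
        assert classify_ap(ap) == "normal"

    def test_type1_from_study_parameters(self, type1_single_trace):
        tr = type1_single_trace
        ap = detect_aps(tr.time, tr.vm, resting_vm=-88.0)[0]
        assert classify_ap(ap) == "type-I"

    def test_type2_default_parameters(self, type2_single_trace):
        tr = type2_single_trace
        ap = detect_aps(tr.time, tr.vm, resting_vm=-88.0)[0]
        assert classify_ap(ap) == "type-II"

    def test_time_shift_invariance(self, type1_single_trace):
        tr = type1_single_trace
        ap0 = detect_aps(tr.time, tr.vm, resting_vm=-88.0)[0]
        ap1 = detect_aps(tr.time + 1234.5, tr.vm, resting_vm=-88.0)[0]
        assert classify_ap(ap0) == classify_ap(ap1)
        assert len(ap0.eads) == len(ap1.eads)

    def test_resample_invariance(self, type1_single_trace):
        tr = type1_single_trace
        t2 = np.arange(tr.time[0], tr.time[-1], tr.sample_ms / 2.0)
        v2 = np.interp(t2, tr.time, tr.vm)
        ap0 = detect_aps(tr.time, tr.vm, resting_vm=-88.0)[0]
        ap2 = detect_aps(t2, v2, resting_vm=-88.0)[0]
        assert classify_ap(ap0) == classify_ap(ap2)


class TestConductionVelocity:
    def test_nominal_cable(self, cv_cable_run):
        at = cv_cable_run["act"]
        cv = conduction_velocity(at[150], at[350], 200 * 0.02)
        assert cv == pytest.approx(65.0, abs=2.0)

    def test_zero_distance_error(self):
        with pytest.raises(ValueError):
            conduction_velocity(10.0, 12.0, 0.0)

    def test_not_activated_error(self):
        with pytest.raises(ValueError):
            conduction_velocity(10.0, np.nan, 1.0)
        t = np.arange(100.0)
        with pytest.raises(ValueError):
            activation_time(t, np.full_like(t, -88.0))

    def test_sqrt_d_scaling(self, cv_by_dscale):
        cv0 = cv_by_dscale[1.0]
        for alpha in (0.25, 0.49):
            ratio = cv_by_dscale[alpha] / cv0
            assert ratio == pytest.approx(np.sqrt(alpha), rel=0.10)

    def test_quarter_d_half_cv(self, cv_by_dscale):
        assert cv_by_dscale[0.25] == pytest.approx(0.5 * cv_by_dscale[1.0],
                                                   rel=0.10)


def pulse_train_trace(total_ms, activation_times, dt=1.0):
    """Square AP-like pulses at the given activation times."""
    t = np.arange(0.0, total_ms, dt)
    v = np.full_like(t, -88.0)
    for t0 in activation_times:
        v[(t >= t0) & (t < t0 + 200.0)] = 10.0
    return t, v


class TestCountPvcs:
    def test_all_attributed_is_zero(self):
        pulses = np.arange(50.0, 5000.0, 1000.0)
        t, v = pulse_train_trace(5000.0, pulses + 30.0)
        rep = count_pvcs(t, np.vstack([v, v]), pulses, max_dist_cm=5.0)
        assert rep.n == 0

    def test_ectopic_counted_once_across_sensors(self):
        pulses = np.arange(50.0, 5000.0, 1000.0)
        ect = 2600.0
        t, v1 = pulse_train_trace(5000.0, list(pulses + 30.0) + [ect])
        _, v2 = pulse_train_trace(5000.0, list(pulses + 35.0) + [ect + 20.0])
        rep = count_pvcs(t, np.vstack([v1, v2]), pulses, max_dist_cm=5.0)
        assert rep.n == 1          # merged within 50 ms

    def test_distinct_episodes(self):
        pulses = np.arange(50.0, 8000.0, 1000.0)
        t, v = pulse_train_trace(8000.0, list(pulses + 30.0)
                                 + [2600.0, 5600.0])
        rep = count_pvcs(t, v[None, :], pulses, max_dist_cm=5.0)
        assert rep.n == 2

    def test_window_additivity(self):
        pulses = np.arange(50.0, 10000.0, 1000.0)
        t, v = pulse_train_trace(10000.0, list(pulses + 30.0)
                                 + [2600.0, 5600.0, 8600.0])
        full = count_pvcs(t, v[None, :], pulses, max_dist_cm=5.0,
                          window=(0.0, 10000.0))
        a = count_pvcs(t, v[None, :], pulses, max_dist_cm=5.0,
                       window=(0.0, 5000.0))
        b = count_pvcs(t, v[None, :], pulses, max_dist_cm=5.0,
                       window=(5000.0 + 1e-6, 10000.0))
        assert full.n == a.n + b.n


class TestSpectra:
    def test_pure_sinusoid_peak(self):
        t = np.arange(0.0, 10000.0, 1.0)          # 10 s at 1 kHz
        x = np.sin(2 * np.pi * 5.0 * t / 1000.0)
        traces = np.vstack([x] * 4)
        sp = averaged_power_spectrum(t, traces)
        fpk = max(sp.peaks, key=lambda p: p[1])[0]
        assert fpk == pytest.approx(5.0, abs=0.11)
        assert sp.classification == "periodic"
        assert sp.fundamental == pytest.approx(5.0, abs=0.11)

    def test_parseval(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 8000.0, 1.0)
        x = rng.normal(size=t.size)
        sp = averaged_power_spectrum(t, x[None, :])
        df = sp.freqs[1] - sp.freqs[0]
        total = np.sum(sp.power) * df
        assert total == pytest.approx(np.var(x), rel=0.01)

    def test_pacing_fundamental_1hz(self):
        pulses = np.arange(50.0, 15000.0, 1000.0)
        t, v = pulse_train_trace(15000.0, pulses)
        sp = averaged_power_spectrum(t, np.vstack([v] * 4),
                                     window=(1000.0, 15000.0))
        assert sp.classification == "periodic"
        assert sp.fundamental == pytest.approx(1.0, abs=0.05)

    def test_two_tone_signal(self):
        w1, w2 = 2.73, 3.64
        t = np.arange(0.0, 20000.0, 1.0)
        ts = t / 1000.0
        x = (np.sin(2 * np.pi * w1 * ts) + 0.8 * np.sin(2 * np.pi * w2 * ts)
             + 0.3 * np.sin(2 * np.pi * (w1 + w2) * ts)
             + 0.2 * np.sin(2 * np.pi * (w2 - w1) * ts))
        sp = averaged_power_spectrum(t, np.vstack([x] * 4),
                                     peak_rel_prominence=1e-4)
        assert sp.classification == "quasiperiodic"
        got = sorted(sp.bases)
        assert got[0] == pytest.approx(w1, rel=0.02)
        assert got[1] == pytest.approx(w2, rel=0.02)


class TestIndexPeaks:
    def test_harmonics_periodic(self):
        cls, bases, table = index_peaks([2.0, 4.0, 6.0])
        assert cls == "periodic"
        assert bases[0] == pytest.approx(2.0)
        assert [row[1] for row in table] == [1, 2, 3]

    def test_single_peak_periodic(self):
        cls, bases, _ = index_peaks([4.38])
        assert cls == "periodic"
        assert bases == (4.38,)

    def test_study_quasiperiodic_set(self):
        w1, w2 = 2.73, 3.64
        peaks = [w2 - w1, w1, w2, w1 + w2, 2 * w2 - w1]
        powers = [0.04, 1.0, 0.8, 0.1, 0.05]  # combination lines are weak
        cls, bases, table = index_peaks(peaks, powers=powers)
        assert cls == "quasiperiodic"
        assert sorted(bases)[0] == pytest.approx(w1, rel=0.02)
        assert sorted(bases)[1] == pytest.approx(w2, rel=0.02)
        for _, _, _, resid in table:
            assert abs(resid) <= 0.02 * min(bases)

    def test_empty(self):
        assert index_peaks([])[0] == "other"

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10_000))
    def test_planted_two_tone_recovery(self, seed):
        """Recover planted incommensurate bases across 100 seeded draws."""
        rng = np.random.default_rng(seed)
        w1 = rng.uniform(2.0, 3.0)
        ratio = rng.uniform(1.25, 1.45)
        # keep away from low-order rationals (ratio tolerance used by the
        # classifier)
        if any(abs(ratio - p / q) <= 0.021 for q in range(1, 7)
               for p in range(1, 12)):
            return
        w2 = w1 * ratio
        peaks = sorted({w1, w2, w1 + w2, w2 - w1})
        cls, bases, _ = index_peaks(peaks)
        assert cls == "quasiperiodic"
        got = sorted(bases)
        assert abs(got[0] - w1) < 0.02 * w1
        assert abs(got[1] - w2) < 0.02 * w2
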