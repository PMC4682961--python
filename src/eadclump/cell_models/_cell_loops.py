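"""Jitted time-stepping loops for single cells and composites."""

import numpy as np
from numba import njit

from ._ord_kernel import step_cell

GF_BREAKPOINT = -20.0


@njit(cache=True, error_model="numpy")
def settle_loop(y, mult, t_ms, dt):
    n = int(round(t_ms / dt))
    for _ in range(n):
        step_cell(y, mult, dt, 0.0)


@njit(cache=True, error_model="numpy")
def step_unit(y, vf, has_fib, mult, cm, cf, ef, gf_lo, gf_hi, ggap, dt, i_stim):
    """One forward-Euler step of a myocyte(-fibroblast) unit.

    Returns the updated fibroblast potential (unchanged when absent).
    I_gap is evaluated from the pre-step potentials on both sides, which
    keeps the gap charge transfer exactly antisymmetric:
    Cm * dVm_gap = -dt * I_gap = -Cf * dVf_gap.
    """
    igap = 0.0
    if has_fib:
        igap = ggap * (y[0] - vf)
    step_cell(y, mult, dt, igap / cm + i_stim)
    if has_fib:
        gf = gf_lo if vf < GF_BREAKPOINT else gf_hi
        i_f = gf * (vf - ef)
        vf = vf + dt * (igap - i_f) / cf
    return vf


@njit(cache=True, error_model="numpy")
def simulate_unit_loop(y, vf0, has_fib, mult, cm, cf, ef, gf_lo, gf_hi, ggap,
                       dt, duration, amp, pulse_dur, pcl, first, sample_ms,
                       n_pulses=-1):
    """Pace a unit for ``duration`` ms; sample Vm (and Vf) every ``sample_ms``.

    ``n_pulses`` < 0 means unlimited; ``pcl`` <= 0 delivers a single pulse.
    """
    n_steps = int(round(duration / dt))
    sps = max(1, int(round(sample_ms / dt)))
    n_samp = n_steps // sps
    out_t = np.empty(n_samp)
    out_v = np.empty(n_samp)
    out_vf = np.empty(n_samp)
    vf = vf0
    k = 0
    for i in range(n_steps):
        t = i * dt
        if k < n_samp and i % sps == 0:
            out_t[k] = t
            out_v[k] = y[0]
            out_vf[k] = vf
            k += 1
        i_stim = 0.0
        if t >= first:
            if pcl > 0.0:
                pulse_idx = int((t - first) // pcl)
                in_pulse = (t - first) % pcl < pulse_dur
            else:
                pulse_idx = 0
                in_pulse = t - first < pulse_dur
            if in_pulse and (n_pulses < 0 or pulse_idx < n_pulses):
                i_stim = amp
        vf = step_unit(y, vf, has_fib, mult, cm, cf, ef, gf_lo, gf_hi, ggap,
                       dt, i_stim)
    return out_t, out_v, out_vf
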