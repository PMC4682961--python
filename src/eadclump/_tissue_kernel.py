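"""Jitted monodomain stepping kernel.

Voltage-only rate factors are linearly interpolated from the table built
by :func:`eadclump.cell_models.build_tables`; the remaining (state
dependent) model terms are evaluated analytically by ``cell_assemble`` —
the same function the single-cell path uses, so the two paths share one
set of model equations.
"""

import numpy as np
from numba import njit

from .cell_models._ord_kernel import (N_CURRENTS, N_VGATES, TAB_ERL, TAB_MISC,
                                      TAB_WIDTH, VGATE_STATES, _rl_decay,
                                      cell_assemble)

GF_BREAKPOINT = -20.0


@njit(cache=True, fastmath=True, error_model="numpy")
def laplacian(v, dmap, obst, dx, out):
    """Conservative face-flux form of div(D grad V), mV/ms.

    Face diffusivity is the arithmetic mean of the two sites' D; faces on
    the domain boundary or touching an obstacle site carry zero flux.
    """
    ny, nx = v.shape
    inv_dx2 = 1.0 / (dx * dx)
    for iy in range(ny):
        for ix in range(nx):
            if obst[iy, ix]:
                out[iy, ix] = 0.0
                continue
            vc = v[iy, ix]
            dc = dmap[iy, ix]
            acc = 0.0
            if ix > 0 and not obst[iy, ix - 1]:
                acc += 0.5 * (dc + dmap[iy, ix - 1]) * (v[iy, ix - 1] - vc)
            if ix < nx - 1 and not obst[iy, ix + 1]:
                acc += 0.5 * (dc + dmap[iy, ix + 1]) * (v[iy, ix + 1] - vc)
            if iy > 0 and not obst[iy - 1, ix]:
                acc += 0.5 * (dc + dmap[iy - 1, ix]) * (v[iy - 1, ix] - vc)
            if iy < ny - 1 and not obst[iy + 1, ix]:
                acc += 0.5 * (dc + dmap[iy + 1, ix]) * (v[iy + 1, ix] - vc)
            out[iy, ix] = acc * inv_dx2


@njit(cache=True, fastmath=True, error_model="numpy")
def run_steps(n_steps, v, ys, vf, typ, mult_table, dmap, obst,
              fib, ef, gf_lo, gf_hi, ggap, stim_field,
              dt, dx, cm, cf, lap, tab, vmin, inv_dv):
    """Advance the whole grid by ``n_steps`` with a fixed stimulus field.

    ``stim_field`` is the per-site stimulus current density (uA/uF; 0 where
    no stimulus), entering as dV/dt = D lap(V) - (I_ion + I_gap/C_m + I_stim).
    """
    ny, nx = v.shape
    nv = tab.shape[0]
    tv = np.empty(TAB_WIDTH)
    misc = tv[TAB_MISC:]
    currents = np.empty(N_CURRENTS)
    dother = np.empty(9)
    sd_inf = np.empty(3)
    sd_tau = np.empty(3)
    inv_cm = 1.0 / cm
    inv_cf = 1.0 / cf
    for _ in range(n_steps):
        laplacian(v, dmap, obst, dx, lap)
        for iy in range(ny):
            base = iy * nx
            for ix in range(nx):
                if obst[iy, ix]:
                    continue
                i = base + ix
                y = ys[i]
                vc = v[iy, ix]
                x = (vc - vmin) * inv_dv
                if x < 0.0:
                    x = 0.0
                elif x > nv - 2:
                    x = float(nv - 2)
                i0 = int(x)
                w = x - i0
                row0 = tab[i0]
                row1 = tab[i0 + 1]
                for k in range(TAB_WIDTH):
                    tv[k] = row0[k] + w * (row1[k] - row0[k])
                y[0] = vc
                iion = cell_assemble(y, mult_table[typ[i]], misc, currents,
                                     dother, sd_inf, sd_tau)
                igap = 0.0
                if fib[i]:
                    vfi = vf[i]
                    igap = ggap[i] * (vc - vfi)
                    gf = gf_lo[i] if vfi < GF_BREAKPOINT else gf_hi[i]
                    vf[i] = vfi + dt * (igap - gf * (vfi - ef[i])) * inv_cf
                v[iy, ix] = vc + dt * (lap[iy, ix]
                                       - (iion + igap * inv_cm + stim_field[iy, ix]))
                for k in range(8):
                    y[1 + k] += dt * dother[k]
                for g in range(N_VGATES):
                    s = VGATE_STATES[g]
                    gi = tv[g]
                    y[s] = gi + (y[s] - gi) * tv[TAB_ERL + g]
                y[26] = sd_inf[0] + (y[26] - sd_inf[0]) * _rl_decay(dt / sd_tau[0])
                y[32] = sd_inf[1] + (y[32] - sd_inf[1]) * _rl_decay(dt / sd_tau[1])
                y[33] = sd_inf[2] + (y[33] - sd_inf[2]) * _rl_decay(dt / sd_tau[2])
                y[34] += dt * dother[8]
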