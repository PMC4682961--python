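"""Shared test helpers (importable from any test module)."""

import numpy as np

from eadclump import constants
from eadclump.protocols import cable_end_pacing
from eadclump.tissue_solver import (ActivationMapRecorder, TissueGrid,
                                    run_simulation)


def measure_cable_cv(d_scale: float, nx: int = 300, duration: float = 500.0,
                     i1: int = 100, i2: int = 250, dx: float = constants.DX,
                     dt: float = constants.DT) -> float:
    """CV on a control cable with globally scaled diffusion."""
    grid = TissueGrid(ny=1, nx=nx, dx=dx,
                      diffusion_scale=np.full((1, nx), d_scale))
    act = ActivationMapRecorder(every_ms=0.25)
    run_simulation(grid, cable_end_pacing(pcl=1000.0), duration,
                   recorders=[act], dt=dt)
    at = act.act_time[0]
    return (i2 - i1) * dx / (at[i2] - at[i1]) * 1000.0


def random_grid(ny, nx, obstacle_frac=0.2, het_d=True, seed=0):
    """Random heterogeneous grid for diffusion-operator property tests."""
    r = np.random.default_rng(seed)
    dscale = r.uniform(0.1, 1.0, (ny, nx)) if het_d else np.ones((ny, nx))
    obst = r.random((ny, nx)) < obstacle_frac
    return TissueGrid(ny=ny, nx=nx, diffusion_scale=dscale, obstacle=obst)
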