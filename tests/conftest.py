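"""Shared (mostly session-scoped) simulation fixtures.

The expensive tissue runs are computed once per session and shared
between the unit suites and the acceptance tests.
"""

import numpy as np
import pytest

from eadclump import constants
from eadclump.cell_models import (CompositeUnit, FibroblastParams,
                                  FibroblastState, MyocyteParams, MyocyteState,
                                  make_ead_parameters, resting_state,
                                  simulate_cell)
from eadclump.protocols import cable_end_pacing, single_cell_pacing
from eadclump.tissue_solver import (ActivationMapRecorder, PointTraceRecorder,
                                    TissueGrid, run_simulation)


@pytest.fixture(scope="session")
def control_rest():
    """Control myocyte state after 10 s of unstimulated integration."""
    return resting_state()


@pytest.fixture(scope="session")
def ead_rest():
    """Type-I EAD myocyte rested state."""
    return resting_state(make_ead_parameters("type-I"))


def _unit(rest, params, ef=None, g_gap=8.0):
    if ef is None:
        return CompositeUnit(state=MyocyteState(rest.y.copy()), params=params)
    return CompositeUnit(state=MyocyteState(rest.y.copy()), params=params,
                         fib_state=FibroblastState(vf=ef),
                         fib_params=FibroblastParams.constant(ef), g_gap=g_gap)


@pytest.fixture(scope="session")
def control_paced_trace(control_rest):
    """Control cell paced at PCL 1000 ms for 15 s (1 ms sampling)."""
    unit = _unit(control_rest, MyocyteParams())
    return simulate_cell(unit, single_cell_pacing(pcl=1000.0), 15000.0)


@pytest.fixture(scope="session")
def type1_paced_trace(ead_rest):
    """(G_CaL x4, G_Kr x0.21) cell paced at PCL 1000 ms for 12 s."""
    unit = _unit(ead_rest, make_ead_parameters("type-I"))
    return simulate_cell(unit, single_cell_pacing(pcl=1000.0), 12000.0)


@pytest.fixture(scope="session")
def type1_single_trace(ead_rest):
    """Type-I cell, one stimulus, 4 s observation (single-AP phenotype)."""
    unit = _unit(ead_rest, make_ead_parameters("type-I"))
    proto = single_cell_pacing(pcl=1000.0)
    proto.n_pulses = 1
    return simulate_cell(unit, proto, 4000.0)


@pytest.fixture(scope="session")
def type2_single_trace():
    params = make_ead_parameters("type-II")
    unit = _unit(resting_state(params), params)
    proto = single_cell_pacing(pcl=1000.0)
    proto.n_pulses = 1
    return simulate_cell(unit, proto, 4000.0)


@pytest.fixture(scope="session")
def composite_traces(ead_rest):
    """12-s paced traces: isolated EAD cell and fibroblast-coupled at
    E_f = -35 / -30 mV (G_gap = 8 nS)."""
    params = make_ead_parameters("type-I")
    proto = single_cell_pacing(pcl=1000.0)
    out = {}
    for label, ef in (("isolated", None), (-35.0, -35.0), (-30.0, -30.0)):
        out[label] = simulate_cell(_unit(ead_rest, params, ef=ef), proto,
                                   12000.0)
    return out


@pytest.fixture(scope="session")
def cv_cable_run():
    """Planar wave on a 448-site control cable at nominal parameters."""
    grid = TissueGrid(ny=1, nx=448)
    proto = cable_end_pacing(pcl=1000.0)
    act = ActivationMapRecorder(every_ms=0.5)
    rec = PointTraceRecorder([(0, 150), (0, 350)], every_ms=0.5)
    run_simulation(grid, proto, duration=500.0, recorders=[act, rec])
    return {"grid": grid, "act": act.act_time[0], "rec": rec}


from _helpers import measure_cable_cv  # noqa: E402


@pytest.fixture(scope="session")
def cv_by_dscale():
    """CV at several global D scalings (shared by monotonicity and
    sqrt-D-scaling tests).

    Measured at refined resolution (dx = dt/2 of nominal) so the lattice
    discretization of the narrow upstroke does not distort the continuum
    sqrt(D) scaling at the lowest D.
    """
    return {a: measure_cable_cv(a, nx=600, duration=400.0, i1=200, i2=500,
                                dx=0.01, dt=0.01)
            for a in (1.0, 0.7, 0.49, 0.4, 0.25)}


@pytest.fixture(scope="session")
def strip_runs():
    """Reduced-scale 2D strip PVC counts for the threshold orderings.

    Keys: (band_half_cm, d_ratio, p_f) -> PVCReport.
    """
    from eadclump.analysis import count_pvcs
    from eadclump.cli_experiments import (STRIP_DURATION_MS, strip_grid,
                                          strip_sensors)

    proto = cable_end_pacing(pcl=1000.0)
    configs = [(1.6, 1.0, 0.0), (2.4, 1.0, 0.0), (2.4, 0.2, 0.0),
               (2.4, 1.0, 15.0), (2.4, 1.0, 30.0), (2.4, 1.0, 60.0)]
    out = {}
    for half, d, pf in configs:
        grid = strip_grid(band_half_cm=half, d_ratio=d, p_f=pf, seed=3)
        rec = PointTraceRecorder(strip_sensors(grid), every_ms=1.0)
        run_simulation(grid, proto, STRIP_DURATION_MS, recorders=[rec])
        diag = float(np.hypot(*grid.extent_cm))
        out[(half, d, pf)] = count_pvcs(
            rec.time, rec.vm, proto.pulse_times(STRIP_DURATION_MS),
            max_dist_cm=diag)
    return out


@pytest.fixture(scope="session")
def cable_pattern_counts():
    """PVC counts for the four 280-cell cable patterns (10 s, PCL 1000)."""
    from eadclump.cli_experiments import ExperimentSpec, run_experiment

    bundle = run_experiment(ExperimentSpec("fig12", duration_ms=10000.0))
    return bundle["n_pvcs"]
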