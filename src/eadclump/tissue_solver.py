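"""Explicit monodomain reaction-diffusion solver on 1D cables and 2D grids.

The voltage field obeys dV/dt = div(D grad V) - (I_ion + I_gap/C_m + I_stim)
with a conservative face-averaged 5-point discretization, no-flux boundary
conditions on the domain edges, and zero-flux faces around inexcitable
obstacle sites (equivalent to D = 0 there).  One grid point represents one
cell (dx = 0.02 cm).
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import constants
from ._tissue_kernel import laplacian as _laplacian_jit
from ._tissue_kernel import run_steps as _run_steps
from .cell_models import (FibroblastParams, MyocyteParams, build_tables,
                          resting_state)

__all__ = [
    "TissueGrid", "TissueState", "InstabilityError", "diffusion_term",
    "step_tissue", "run_simulation", "PointTraceRecorder", "SnapshotRecorder",
    "ActivationMapRecorder", "RunOutput",
]


class InstabilityError(RuntimeError):
    """Numerical blow-up, annotated with the offending site and time."""

    def __init__(self, site: Tuple[int, int], t: float):
        self.site = site
        self.t = t
        super().__init__(f"non-finite Vm at site (iy={site[0]}, ix={site[1]}), "
                         f"t = {t:.2f} ms")


@dataclass
class TissueGrid:
    """Geometry and per-site composition of a tissue domain.

    ``cell_types`` lists the distinct myocyte parameter sets present;
    ``type_id`` holds, per site, an index into that list.  Fibroblast
    attachment is stored as parallel per-site arrays so the solver kernel
    can read it directly.
    """

    ny: int
    nx: int
    dx: float = constants.DX
    d0: float = constants.D0
    cell_types: List[MyocyteParams] = field(default_factory=lambda: [MyocyteParams()])
    type_id: Optional[np.ndarray] = None          # (ny, nx) int
    diffusion_scale: Optional[np.ndarray] = None  # (ny, nx) float in [0, 1]
    obstacle: Optional[np.ndarray] = None         # (ny, nx) bool
    fib_mask: Optional[np.ndarray] = None         # (ny, nx) bool
    fib_ef: Optional[np.ndarray] = None
    fib_gf_low: Optional[np.ndarray] = None
    fib_gf_high: Optional[np.ndarray] = None
    fib_ggap: Optional[np.ndarray] = None
    cm: float = constants.CM_MYOCYTE
    cf: float = constants.CF_FIBROBLAST

    def __post_init__(self) -> None:
        shape = (self.ny, self.nx)
        if self.type_id is None:
            self.type_id = np.zeros(shape, dtype=np.int64)
        self.type_id = np.asarray(self.type_id, dtype=np.int64)
        if self.diffusion_scale is None:
            self.diffusion_scale = np.ones(shape)
        self.diffusion_scale = np.asarray(self.diffusion_scale, dtype=float)
        if self.obstacle is None:
            self.obstacle = np.zeros(shape, dtype=bool)
        self.obstacle = np.asarray(self.obstacle, dtype=bool)
        if self.fib_mask is None:
            self.fib_mask = np.zeros(shape, dtype=bool)
        for name in ("fib_ef", "fib_gf_low", "fib_gf_high", "fib_ggap"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(shape))
        self._validate()

    def _validate(self) -> None:
        shape = (self.ny, self.nx)
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        for name in ("type_id", "diffusion_scale", "obstacle", "fib_mask",
                     "fib_ef", "fib_gf_low", "fib_gf_high", "fib_ggap"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if self.diffusion_scale.min() < 0 or self.diffusion_scale.max() > 1:
            raise ValueError("diffusion scales must lie in [0, 1]")
        if self.type_id.min() < 0 or self.type_id.max() >= len(self.cell_types):
            raise ValueError("type_id out of range of cell_types")
        if np.any(self.fib_mask & self.obstacle):
            raise ValueError("obstacle sites cannot carry fibroblasts")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_sites(self) -> int:
        return self.ny * self.nx

    @property
    def extent_cm(self) -> Tuple[float, float]:
        """Physical size (Lx, Ly) in cm."""
        return (self.nx * self.dx, self.ny * self.dx)

    def attach_fibroblasts(self, mask: np.ndarray, params: FibroblastParams,
                           ggap: float = constants.GGAP_DEFAULT) -> None:
        """Attach one fibroblast (shared params) to every site in ``mask``."""
        mask = np.asarray(mask, dtype=bool)
        if np.any(mask & self.obstacle):
            raise ValueError("cannot attach fibroblasts to obstacle sites")
        if ggap < 0:
            raise ValueError("G_gap must be non-negative")
        self.fib_mask = self.fib_mask | mask
        self.fib_ef[mask] = params.e_rest
        self.fib_gf_low[mask] = params.gf_low
        self.fib_gf_high[mask] = params.gf_high
        self.fib_ggap[mask] = ggap

    def add_cell_type(self, params: MyocyteParams) -> int:
        """Register a myocyte parameter set; returns its type id."""
        self.cell_types.append(params)
        return len(self.cell_types) - 1

    def mult_table(self) -> np.ndarray:
        return np.stack([p.multiplier_vector() for p in self.cell_types])

    def describe(self) -> Dict:
        return {
            "ny": self.ny, "nx": self.nx, "dx": self.dx, "d0": self.d0,
            "n_cell_types": len(self.cell_types),
            "n_obstacles": int(self.obstacle.sum()),
            "n_fibroblasts": int(self.fib_mask.sum()),
        }


# cached 10-s rested states, keyed by the multiplier vector
_REST_CACHE: Dict[Tuple[float, ...], np.ndarray] = {}


def _rested_vector(params: MyocyteParams) -> np.ndarray:
    key = tuple(params.multiplier_vector())
    if key not in _REST_CACHE:
        _REST_CACHE[key] = resting_state(params).y
    return _REST_CACHE[key].copy()


@dataclass
class TissueState:
    """Per-site myocyte states, fibroblast potentials, and the clock."""

    v: np.ndarray        # (ny, nx) mV
    states: np.ndarray   # (ny*nx, N_STATES)
    vf: np.ndarray       # (ny*nx,) mV
    t: float = 0.0

    @classmethod
    def from_grid(cls, grid: TissueGrid) -> "TissueState":
        """Initialize every site from its cell type's 10-s rested state;
        attached fibroblasts start at their resting potential E_f."""
        n = grid.n_sites
        states = np.empty((n, 35))
        flat_type = grid.type_id.ravel()
        for tid in range(len(grid.cell_types)):
            y = _rested_vector(grid.cell_types[tid])
            states[flat_type == tid] = y
        v = states[:, 0].reshape(grid.shape).copy()
        vf = np.where(grid.fib_mask.ravel(), grid.fib_ef.ravel(), 0.0)
        return cls(v=v, states=states, vf=vf, t=0.0)

    def copy(self) -> "TissueState":
        return TissueState(self.v.copy(), self.states.copy(), self.vf.copy(), self.t)


def diffusion_term(vm_field: np.ndarray, grid: TissueGrid) -> np.ndarray:
    """Reference (vectorized numpy) evaluation of div(D grad V), mV/ms.

    Matches the solver kernel: conservative face fluxes with arithmetic-
    mean face diffusivity, no-flux domain boundaries, zero-flux obstacle
    faces.  Reduces to the standard 5-point stencil for uniform D.
    """
    vm_field = np.asarray(vm_field, dtype=float)
    if vm_field.shape != grid.shape:
        raise ValueError(f"field shape {vm_field.shape} != grid shape {grid.shape}")
    d = grid.diffusion_scale * grid.d0
    act = ~grid.obstacle
    acc = np.zeros(grid.shape)
    # x faces
    dface = 0.5 * (d[:, 1:] + d[:, :-1]) * (act[:, 1:] & act[:, :-1])
    flux = dface * (vm_field[:, 1:] - vm_field[:, :-1])
    acc[:, :-1] += flux
    acc[:, 1:] -= flux
    # y faces
    dface = 0.5 * (d[1:, :] + d[:-1, :]) * (act[1:, :] & act[:-1, :])
    flux = dface * (vm_field[1:, :] - vm_field[:-1, :])
    acc[:-1, :] += flux
    acc[1:, :] -= flux
    out = acc / grid.dx ** 2
    out[grid.obstacle] = 0.0
    return out


_TABLE_CACHE: Dict[float, tuple] = {}


def _tables(dt: float) -> tuple:
    if dt not in _TABLE_CACHE:
        _TABLE_CACHE[dt] = build_tables(dt)
    return _TABLE_CACHE[dt]


class _KernelArgs:
    """Flattened, kernel-ready views of a grid (built once per run)."""

    def __init__(self, grid: TissueGrid, dt: float):
        self.grid = grid
        self.dt = dt
        self.mult_table = grid.mult_table()
        self.dmap = np.ascontiguousarray(grid.diffusion_scale * grid.d0)
        self.obst = np.ascontiguousarray(grid.obstacle)
        self.typ = np.ascontiguousarray(grid.type_id.ravel())
        self.fib = np.ascontiguousarray(grid.fib_mask.ravel())
        self.ef = np.ascontiguousarray(grid.fib_ef.ravel())
        self.gf_lo = np.ascontiguousarray(grid.fib_gf_low.ravel())
        self.gf_hi = np.ascontiguousarray(grid.fib_gf_high.ravel())
        self.ggap = np.ascontiguousarray(grid.fib_ggap.ravel())
        self.lap = np.zeros(grid.shape)
        self.tables = _tables(dt)

    def advance(self, state: TissueState, n_steps: int,
                stim_field: np.ndarray) -> None:
        tab, vmin, inv_dv = self.tables
        _run_steps(n_steps, state.v, state.states, state.vf, self.typ,
                   self.mult_table, self.dmap, self.obst, self.fib, self.ef,
                   self.gf_lo, self.gf_hi, self.ggap, stim_field,
                   self.dt, self.grid.dx, self.grid.cm, self.grid.cf, self.lap,
                   tab, vmin, inv_dv)
        state.t += n_steps * self.dt
        bad = np.argwhere(~np.isfinite(state.v))
        if bad.size:
            raise InstabilityError((int(bad[0, 0]), int(bad[0, 1])), state.t)


def step_tissue(state: TissueState, grid: TissueGrid, dt: float = constants.DT,
                stim_field: Optional[np.ndarray] = None,
                n_steps: int = 1) -> TissueState:
    """Advance ``state`` in place by ``n_steps`` forward-Euler steps."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if stim_field is None:
        stim_field = np.zeros(grid.shape)
    _KernelArgs(grid, dt).advance(state, n_steps, stim_field)
    return state


# ---------------------------------------------------------------------------
# recorders


class PointTraceRecorder:
    """Record Vm (optionally Vf) at a set of sites every ``every_ms``."""

    def __init__(self, sites: Sequence[Tuple[int, int]], every_ms: float = 1.0,
                 record_vf: bool = False, name: str = "traces"):
        self.sites = [tuple(s) for s in sites]
        self.every_ms = every_ms
        self.record_vf = record_vf
        self.name = name
        self.times: List[float] = []
        self._vm: List[np.ndarray] = []
        self._vf: List[np.ndarray] = []

    def sample(self, state: TissueState, grid: TissueGrid, t: float) -> None:
        self.times.append(t)
        self._vm.append(np.array([state.v[iy, ix] for iy, ix in self.sites]))
        if self.record_vf:
            nx = grid.nx
            self._vf.append(np.array([state.vf[iy * nx + ix]
                                      for iy, ix in self.sites]))

    @property
    def time(self) -> np.ndarray:
        return np.asarray(self.times)

    @property
    def vm(self) -> np.ndarray:
        """(n_sites, n_samples) array."""
        return np.asarray(self._vm).T

    @property
    def vf(self) -> np.ndarray:
        return np.asarray(self._vf).T


class SnapshotRecorder:
    """Store full Vm fields every ``every_ms`` (20 ms matches the study's
    frame cadence)."""

    def __init__(self, every_ms: float = 20.0, name: str = "snapshots"):
        self.every_ms = every_ms
        self.name = name
        self.times: List[float] = []
        self.fields: List[np.ndarray] = []

    def sample(self, state: TissueState, grid: TissueGrid, t: float) -> None:
        self.times.append(t)
        self.fields.append(state.v.copy())


class ActivationMapRecorder:
    """First upward crossing of ``threshold`` per site (linear interpolation
    between samples); NaN where never activated."""

    def __init__(self, threshold: float = -40.0, every_ms: float = 1.0,
                 name: str = "activation"):
        self.threshold = threshold
        self.every_ms = every_ms
        self.name = name
        self.act_time: Optional[np.ndarray] = None
        self._prev_v: Optional[np.ndarray] = None
        self._prev_t: float = 0.0

    def sample(self, state: TissueState, grid: TissueGrid, t: float) -> None:
        v = state.v
        if self.act_time is None:
            self.act_time = np.full(v.shape, np.nan)
        else:
            crossing = ((self._prev_v < self.threshold) & (v >= self.threshold)
                        & np.isnan(self.act_time))
            if np.any(crossing):
                with np.errstate(divide="ignore", invalid="ignore"):
                    frac = (self.threshold - self._prev_v) / (v - self._prev_v)
                tx = self._prev_t + frac * (t - self._prev_t)
                self.act_time[crossing] = tx[crossing]
        self._prev_v = v.copy()
        self._prev_t = t


@dataclass
class RunOutput:
    """Everything a simulation run produced."""

    recorders: Dict[str, object]
    state: TissueState
    metadata: Dict

    def __getitem__(self, name: str):
        return self.recorders[name]


def run_simulation(grid: TissueGrid, protocol, duration: float,
                   recorders: Sequence = (), dt: float = constants.DT,
                   state: Optional[TissueState] = None,
                   seed: Optional[int] = None) -> RunOutput:
    """Run the pacing/stepping loop; fully deterministic for a given
    (grid, protocol, initial state).

    ``protocol`` must provide ``edge_times(duration)`` (sorted stimulus
    on/off boundaries, ms) and ``stimulus_field(grid, t)`` returning the
    per-site current-density field active in the window starting at ``t``.
    Protocols with a runtime trigger (S1-S2) may additionally expose
    ``poll(state, grid, t)``, called at every sample instant.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    ka = _KernelArgs(grid, dt)
    if state is None:
        state = TissueState.from_grid(grid)
    sample_ms = min([r.every_ms for r in recorders], default=1.0)
    for r in recorders:
        if abs(r.every_ms / sample_ms - round(r.every_ms / sample_ms)) > 1e-9:
            raise ValueError("recorder cadences must be integer multiples "
                             "of the smallest cadence")
    t0 = state.t
    t_end = t0 + duration
    dynamic = hasattr(protocol, "poll")
    wall0 = _time.time()

    def _timeline() -> np.ndarray:
        samples = np.arange(t0, t_end + 1e-9, sample_ms)
        edges = np.asarray(protocol.edge_times(t_end), dtype=float)
        edges = edges[(edges > t0) & (edges < t_end)]
        tl = np.unique(np.round(np.concatenate([samples, edges]) / dt) * dt)
        return tl

    timeline = _timeline()
    idx = 0
    while idx < len(timeline):
        t = timeline[idx]
        # sample recorders at their cadence
        for r in recorders:
            k = (t - t0) / r.every_ms
            if abs(k - round(k)) < 1e-6:
                r.sample(state, grid, t)
        if dynamic and protocol.poll(state, grid, t):
            timeline = _timeline()   # trigger fired: stimulus edges changed
            idx = int(np.searchsorted(timeline, t, side="left"))
        if idx + 1 >= len(timeline):
            break
        t_next = timeline[idx + 1]
        n = int(round((t_next - t) / dt))
        if n > 0:
            ka.advance(state, n, protocol.stimulus_field(grid, t))
        idx += 1

    metadata = {
        "grid": grid.describe(),
        "protocol": getattr(protocol, "describe", lambda: str(protocol))(),
        "duration_ms": duration, "dt_ms": dt, "seed": seed,
        "wall_s": round(_time.time() - wall0, 3),
    }
    return RunOutput(recorders={r.name: r for r in recorders}, state=state,
                     metadata=metadata)


def write_manifest(path, output: RunOutput) -> None:
    with open(path, "w") as fh:
        json.dump(output.metadata, fh, indent=2, default=str)
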