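"""Myocyte-fibroblast composite unit: coupled stepping and paced runs."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .. import constants
from . import _cell_loops
from .fibroblast import FibroblastParams, FibroblastState
from .myocyte import (MyocyteParams, MyocyteState, NumericalStateError,
                      ParameterError)


@dataclass
class Trace:
    """Uniformly sampled membrane-potential recording."""

    time: np.ndarray            # ms
    vm: np.ndarray              # mV
    vf: Optional[np.ndarray] = None

    @property
    def sample_ms(self) -> float:
        return float(self.time[1] - self.time[0])

    def to_csv(self, path) -> None:
        cols = [self.time, self.vm]
        header = "time_ms,Vm_mV"
        if self.vf is not None:
            cols.append(self.vf)
            header += ",Vf_mV"
        np.savetxt(path, np.column_stack(cols), delimiter=",",
                   header=header, comments="")

    @classmethod
    def from_csv(cls, path) -> "Trace":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        vf = data[:, 2] if data.shape[1] > 2 else None
        return cls(time=data[:, 0], vm=data[:, 1], vf=vf)


@dataclass
class CompositeUnit:
    """One myocyte, optionally gap-coupled to one passive fibroblast."""

    state: MyocyteState
    params: MyocyteParams = field(default_factory=MyocyteParams)
    fib_state: Optional[FibroblastState] = None
    fib_params: Optional[FibroblastParams] = None
    g_gap: float = constants.GGAP_DEFAULT

    def __post_init__(self) -> None:
        if (self.fib_state is None) != (self.fib_params is None):
            raise ParameterError("fibroblast state and params must come together")
        if self.g_gap < 0:
            raise ParameterError("G_gap must be non-negative")
        if self.fib_state is None:
            self.g_gap = 0.0

    @property
    def has_fibroblast(self) -> bool:
        return self.fib_state is not None

    def copy(self) -> "CompositeUnit":
        return CompositeUnit(
            state=self.state.copy(), params=self.params,
            fib_state=self.fib_state.copy() if self.fib_state else None,
            fib_params=self.fib_params, g_gap=self.g_gap)

    def _fib_args(self):
        if self.has_fibroblast:
            fp = self.fib_params
            return (True, self.fib_state.vf, fp.capacitance, fp.e_rest,
                    fp.gf_low, fp.gf_high, self.g_gap)
        return (False, 0.0, 1.0, 0.0, 1.0, 1.0, 0.0)


def step_composite(unit: CompositeUnit, dt: float = constants.DT,
                   i_stim: float = 0.0) -> CompositeUnit:
    """One forward-Euler step; returns the advanced copy of ``unit``."""
    if dt <= 0:
        raise ParameterError("dt must be positive")
    new = unit.copy()
    has_fib, vf, cf, ef, gf_lo, gf_hi, ggap = new._fib_args()
    vf = _cell_loops.step_unit(
        new.state.y, vf, has_fib, new.params.multiplier_vector(),
        new.params.membrane_capacitance, cf, ef, gf_lo, gf_hi, ggap, dt, i_stim)
    if has_fib:
        new.fib_state.vf = vf
    if not np.all(np.isfinite(new.state.y)):
        raise NumericalStateError("non-finite state after step")
    return new


def simulate_cell(unit: CompositeUnit, protocol, duration: float,
                  dt: float = constants.DT,
                  sample_ms: float = constants.SAMPLE_MS) -> Trace:
    """Pace a composite unit and record Vm (and Vf when present).

    ``protocol`` provides ``amplitude`` (uA/uF), ``pulse_duration`` (ms),
    ``pcl`` (ms; <= 0 disables pacing) and ``first_pulse`` (ms); its
    spatial region, if any, is ignored for a single cell.
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    work = unit.copy()
    has_fib, vf, cf, ef, gf_lo, gf_hi, ggap = work._fib_args()
    t, vm, vf_arr = _cell_loops.simulate_unit_loop(
        work.state.y, vf, has_fib, work.params.multiplier_vector(),
        work.params.membrane_capacitance, cf, ef, gf_lo, gf_hi, ggap,
        dt, duration, protocol.amplitude, protocol.pulse_duration,
        protocol.pcl, protocol.first_pulse, sample_ms,
        -1 if getattr(protocol, "n_pulses", None) is None
        else protocol.n_pulses)
    if not np.all(np.isfinite(vm)):
        raise NumericalStateError("non-finite Vm during simulation")
    return Trace(time=t, vm=vm, vf=vf_arr if has_fib else None)
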