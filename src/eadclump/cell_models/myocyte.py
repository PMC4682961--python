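"""Myocyte parameter/state containers and the single-cell current interface."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .. import constants
from . import _ord_kernel as _k

#: names of the 14 membrane currents, in roster order
CURRENT_NAMES: Tuple[str, ...] = _k.CURRENT_ORDER

BASE_MODEL_ID = "ORd2011-endo/INa-TP06"


class ParameterError(ValueError):
    """Invalid model parameter."""


class NumericalStateError(RuntimeError):
    """A current or state variable became non-finite."""


@dataclass
class MyocyteParams:
    """Conductance multipliers and capacitance of one myocyte.

    ``multipliers`` maps current names (subset of :data:`CURRENT_NAMES`)
    to positive scale factors relative to the control model.
    """

    membrane_capacitance: float = constants.CM_MYOCYTE
    multipliers: Dict[str, float] = field(default_factory=dict)
    base_model: str = BASE_MODEL_ID

    def __post_init__(self) -> None:
        if self.membrane_capacitance <= 0:
            raise ParameterError("membrane_capacitance must be positive")
        unknown = set(self.multipliers) - set(CURRENT_NAMES)
        if unknown:
            raise ParameterError(f"unknown current name(s): {sorted(unknown)}")
        for name, m in self.multipliers.items():
            if not np.isfinite(m) or m <= 0:
                raise ParameterError(f"multiplier for {name} must be positive, got {m}")

    def multiplier_vector(self) -> np.ndarray:
        """Multipliers as a length-14 array in roster order."""
        vec = np.ones(_k.N_CURRENTS)
        for name, m in self.multipliers.items():
            vec[CURRENT_NAMES.index(name)] = m
        return vec


@dataclass
class MyocyteState:
    """Full state vector of one myocyte (view helpers included)."""

    y: np.ndarray

    @classmethod
    def initial(cls) -> "MyocyteState":
        return cls(_k.initial_state())

    @property
    def vm(self) -> float:
        return float(self.y[0])

    @vm.setter
    def vm(self, value: float) -> None:
        self.y[0] = value

    @property
    def concentrations(self) -> np.ndarray:
        return self.y[1:9]

    @property
    def gates(self) -> np.ndarray:
        return self.y[9:34]

    def copy(self) -> "MyocyteState":
        return MyocyteState(self.y.copy())

    def validate(self, vm_bounds: Tuple[float, float] = (-150.0, 100.0)) -> None:
        """Raise :class:`NumericalStateError` on an invalid state."""
        if not np.all(np.isfinite(self.y)):
            raise NumericalStateError("non-finite state variable")
        if not vm_bounds[0] < self.vm < vm_bounds[1]:
            raise NumericalStateError(f"Vm = {self.vm:.2f} mV out of bounds")
        g = self.gates
        if np.any(g < -1e-9) or np.any(g[:17] > 1.0 + 1e-9):
            raise NumericalStateError("gating variable out of [0, 1]")
        if np.any(self.concentrations <= 0):
            raise NumericalStateError("non-positive ionic concentration")


def make_ead_parameters(ap_type: str = "type-I",
                        g_cal_mult: float | None = None,
                        g_kr_mult: float | None = None) -> MyocyteParams:
    """Parameters of an EAD-capable cell.

    The reduced repolarization reserve is produced by scaling I_CaL up and
    I_Kr down.  Defaults: type-I -> (4, 0.21); type-II -> (4, 0.12), the
    lower I_Kr giving decaying EAD oscillations that relax to an elevated
    potential.
    """
    if ap_type not in ("type-I", "type-II"):
        raise ParameterError(f"unknown AP type: {ap_type!r}")
    if g_cal_mult is None:
        g_cal_mult = constants.GCAL_EAD
    if g_kr_mult is None:
        g_kr_mult = constants.GKR_TYPE1 if ap_type == "type-I" else constants.GKR_TYPE2
    if g_cal_mult <= 0 or g_kr_mult <= 0:
        raise ParameterError("conductance multipliers must be positive")
    return MyocyteParams(multipliers={"I_CaL": float(g_cal_mult),
                                      "I_Kr": float(g_kr_mult)})


def ionic_currents(state: MyocyteState, params: MyocyteParams) -> Dict[str, float]:
    """All 14 membrane currents (uA/uF), each scaled by its multiplier."""
    cur = np.empty(_k.N_CURRENTS)
    dy = np.empty(_k.N_STATES)
    _k.cell_rhs(state.y, params.multiplier_vector(), cur, dy)
    return dict(zip(CURRENT_NAMES, cur.tolist()))


def ionic_rhs(state: MyocyteState, params: MyocyteParams):
    """Total membrane current and state derivatives.

    Returns
    -------
    i_ion : float
        Sum of the 14 scaled currents, uA/uF.
    dy : ndarray
        Time derivative of the full state vector (``dy[0]`` is the
        contribution of I_ion alone, without stimulus or coupling terms).
    """
    cur = np.empty(_k.N_CURRENTS)
    dy = np.empty(_k.N_STATES)
    i_ion = _k.cell_rhs(state.y, params.multiplier_vector(), cur, dy)
    if not np.isfinite(i_ion) or not np.all(np.isfinite(dy)):
        bad = [n for n, c in zip(CURRENT_NAMES, cur) if not np.isfinite(c)]
        raise NumericalStateError(
            f"non-finite ionic current(s): {bad or 'state derivatives'}")
    return i_ion, dy


def resting_state(params: MyocyteParams | None = None,
                  t_ms: float = 10000.0, dt: float = constants.DT) -> MyocyteState:
    """Quiescent state after ``t_ms`` of unstimulated integration."""
    if params is None:
        params = MyocyteParams()
    y = _k.initial_state()
    mult = params.multiplier_vector()
    _settle(y, mult, t_ms, dt)
    return MyocyteState(y)


def _settle(y: np.ndarray, mult: np.ndarray, t_ms: float, dt: float) -> None:
    from ._cell_loops import settle_loop

    settle_loop(y, mult, t_ms, dt)
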