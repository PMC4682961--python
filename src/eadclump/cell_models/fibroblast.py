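"""Passive (MacCannell-type) fibroblast and the gap-junction current."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import constants
from .myocyte import ParameterError


@dataclass
class FibroblastParams:
    """Passive fibroblast membrane parameters.

    The membrane current is ``I_f = G_f(V_f) (V_f - E_f)`` with either a
    constant conductance (``gf_low == gf_high``) or the two-level piecewise
    model that switches at ``V_f = -20 mV``.
    """

    e_rest: float
    capacitance: float = constants.CF_FIBROBLAST
    gf_low: float = constants.GF_FIBROBLAST
    gf_high: float = constants.GF_FIBROBLAST

    #: fixed piecewise breakpoint, mV
    BREAKPOINT = constants.GF_BREAKPOINT_MV

    def __post_init__(self) -> None:
        if self.capacitance <= 0:
            raise ParameterError("fibroblast capacitance must be positive")
        if self.gf_low <= 0 or self.gf_high <= 0:
            raise ParameterError("fibroblast conductance must be positive")
        if not np.isfinite(self.e_rest):
            raise ParameterError("E_f must be finite")

    @classmethod
    def constant(cls, e_rest: float,
                 gf: float = constants.GF_FIBROBLAST) -> "FibroblastParams":
        return cls(e_rest=e_rest, gf_low=gf, gf_high=gf)

    @classmethod
    def piecewise(cls, e_rest: float) -> "FibroblastParams":
        """Voltage-dependent conductance: 2 nS below -20 mV, 4 nS above."""
        return cls(e_rest=e_rest, gf_low=constants.GF_PIECEWISE_LOW,
                   gf_high=constants.GF_PIECEWISE_HIGH)

    @property
    def is_piecewise(self) -> bool:
        return self.gf_low != self.gf_high

    def conductance(self, vf: float) -> float:
        """G_f in nS at membrane potential ``vf``."""
        return self.gf_low if vf < self.BREAKPOINT else self.gf_high


@dataclass
class FibroblastState:
    vf: float

    def copy(self) -> "FibroblastState":
        return FibroblastState(self.vf)


def fibroblast_current(vf: float, params: FibroblastParams) -> float:
    """Fibroblast membrane current I_f = G_f(V_f)(V_f - E_f), pA."""
    return params.conductance(vf) * (vf - params.e_rest)


def gap_current(vm: float, vf: float, ggap: float) -> float:
    """Gap-junctional current I_gap = G_gap (V_m - V_f), pA.

    The same current is subtracted from the myocyte and added to the
    fibroblast, so the charge transfer is antisymmetric.
    """
    if ggap < 0:
        raise ParameterError("G_gap must be non-negative")
    return ggap * (vm - vf)
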