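"""Stimulation programs and sensor placement.

Sign convention: stimulus amplitudes are negative (inward) and enter the
voltage equation as dV/dt = ... - I_stim, so the default -150 uA/uF pulse
depolarizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import constants

__all__ = [
    "Rect", "StimulusProtocol", "S1S2Spec", "S1S2Protocol",
    "asymmetric_pacing", "cable_end_pacing", "single_cell_pacing",
    "s1s2_cross_field", "place_sensors",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in cm: origin (x0, y0) and extent (w, h)."""

    x0: float
    y0: float
    w: float
    h: float

    def site_mask(self, grid) -> np.ndarray:
        """Boolean mask of sites whose centers fall inside the rectangle."""
        xs = (np.arange(grid.nx) + 0.5) * grid.dx
        ys = (np.arange(grid.ny) + 0.5) * grid.dx
        in_x = (xs >= self.x0) & (xs < self.x0 + self.w)
        in_y = (ys >= self.y0) & (ys < self.y0 + self.h)
        return np.outer(in_y, in_x)


def _default_pacing_region(grid) -> Rect:
    """0.14 x 3 cm^2 abutting the lower-right boundary (x = Lx edge, y = 0)."""
    lx, _ = grid.extent_cm
    return Rect(x0=lx - 0.14, y0=0.0, w=0.14, h=3.0)


@dataclass
class StimulusProtocol:
    """Periodic rectangular-region current pulses.

    ``region=None`` resolves to the default lower-right pacing rectangle
    at mask time.  ``pcl <= 0`` or ``n_pulses=1`` gives a single pulse.
    """

    region: Optional[Rect] = None
    amplitude: float = constants.STIM_AMPLITUDE        # uA/uF
    pulse_duration: float = constants.STIM_DURATION    # ms
    pcl: float = 1000.0                                # ms
    first_pulse: float = constants.FIRST_PULSE_MS      # ms
    n_pulses: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pulse_duration <= 0:
            raise ValueError("pulse duration must be positive")
        if self.pcl > 0 and self.pulse_duration >= self.pcl:
            raise ValueError("pulse duration must be shorter than the PCL")

    def pulse_times(self, t_end: float) -> np.ndarray:
        """Onset times of all pulses delivered before ``t_end``."""
        if self.pcl <= 0:
            times = np.array([self.first_pulse])
        else:
            times = self.first_pulse + self.pcl * np.arange(
                int(np.ceil((t_end - self.first_pulse) / self.pcl)) + 1)
        times = times[times < t_end]
        if self.n_pulses is not None:
            times = times[:self.n_pulses]
        return times

    def edge_times(self, t_end: float) -> np.ndarray:
        on = self.pulse_times(t_end)
        return np.sort(np.concatenate([on, on + self.pulse_duration]))

    def is_active(self, t: float) -> bool:
        for p in self.pulse_times(t + self.pulse_duration + 1e-9):
            if p <= t < p + self.pulse_duration:
                return True
        return False

    def site_mask(self, grid) -> np.ndarray:
        region = self.region or _default_pacing_region(grid)
        mask = region.site_mask(grid)
        if not mask.any():
            raise ValueError("stimulus region does not intersect the domain")
        return mask

    def stimulus_field(self, grid, t: float) -> np.ndarray:
        field_ = np.zeros(grid.shape)
        if self.is_active(t + 1e-9):
            field_[self.site_mask(grid)] = self.amplitude
        return field_

    def describe(self) -> dict:
        return {"kind": "periodic", "amplitude": self.amplitude,
                "pulse_duration": self.pulse_duration, "pcl": self.pcl,
                "first_pulse": self.first_pulse, "n_pulses": self.n_pulses,
                "region": None if self.region is None else vars(self.region)}

    def schedule_rows(self, t_end: float) -> List[Tuple[float, str]]:
        """(pulse time, region id) rows for audit export."""
        return [(float(t), "pacing") for t in self.pulse_times(t_end)]


def asymmetric_pacing(pcl: float = 1000.0, region: Optional[Rect] = None,
                      amplitude: float = constants.STIM_AMPLITUDE,
                      duration: float = constants.STIM_DURATION,
                      first_pulse: float = constants.FIRST_PULSE_MS,
                      ) -> StimulusProtocol:
    """The study's 2D pacing: 0.14 x 3 cm^2 pulses on the lower-right edge."""
    return StimulusProtocol(region=region, amplitude=amplitude,
                            pulse_duration=duration, pcl=pcl,
                            first_pulse=first_pulse)


def cable_end_pacing(pcl: float = 1000.0,
                     amplitude: float = constants.STIM_AMPLITUDE,
                     duration: float = constants.STIM_DURATION,
                     first_pulse: float = constants.FIRST_PULSE_MS,
                     width_cm: float = 0.14) -> StimulusProtocol:
    """Pace a cable from its left end (first ``width_cm`` of sites)."""
    return StimulusProtocol(region=Rect(0.0, 0.0, width_cm, 1e9),
                            amplitude=amplitude, pulse_duration=duration,
                            pcl=pcl, first_pulse=first_pulse)


def single_cell_pacing(pcl: float = 1000.0,
                       amplitude: float = constants.STIM_AMPLITUDE,
                       duration: float = constants.STIM_DURATION_CELL,
                       first_pulse: float = constants.FIRST_PULSE_MS,
                       ) -> StimulusProtocol:
    """Single-cell pacing: same amplitude as tissue, 0.5 ms pulse."""
    return StimulusProtocol(region=None, amplitude=amplitude,
                            pulse_duration=duration, pcl=pcl,
                            first_pulse=first_pulse)


@dataclass
class S1S2Spec:
    """Cross-field spiral initiation settings.

    S1 is a planar pulse along the left edge; S2 covers the bottom half of
    the domain (orthogonal to S1) and is delivered either at the fixed
    ``s2_time`` or, by default, when the S1 repolarization tail crosses
    mid-domain (trigger monitored at the domain center).
    """

    s1_amplitude: float = constants.STIM_AMPLITUDE
    s1_duration: float = constants.STIM_DURATION
    s1_time: float = constants.FIRST_PULSE_MS
    s1_width_cm: float = 0.1
    s2_amplitude: float = constants.STIM_AMPLITUDE
    s2_duration: float = constants.STIM_DURATION
    s2_time: Optional[float] = None
    s2_region: Optional[Rect] = None
    trigger_threshold: float = -60.0     # mV, repolarization at the monitor site


class S1S2Protocol:
    """Runtime S1-S2 protocol bound to a grid geometry."""

    def __init__(self, grid, spec: S1S2Spec):
        self.spec = spec
        lx, ly = grid.extent_cm
        self._s1_region = Rect(0.0, 0.0, spec.s1_width_cm, ly)
        self._s2_region = spec.s2_region or Rect(0.0, 0.0, lx, ly / 2.0)
        self.s2_time = spec.s2_time
        self._monitor = (grid.ny // 2, grid.nx // 2)
        self._monitor_activated = False

    def poll(self, state, grid, t: float) -> bool:
        """Trigger check; returns True when the S2 time was just fixed."""
        if self.s2_time is not None:
            return False
        v = state.v[self._monitor]
        if not self._monitor_activated:
            if v > -30.0:
                self._monitor_activated = True
            return False
        if v < self.spec.trigger_threshold:
            self.s2_time = t
            return True
        return False

    def edge_times(self, t_end: float) -> np.ndarray:
        edges = [self.spec.s1_time, self.spec.s1_time + self.spec.s1_duration]
        if self.s2_time is not None:
            edges += [self.s2_time, self.s2_time + self.spec.s2_duration]
        return np.asarray(sorted(edges))

    def stimulus_field(self, grid, t: float) -> np.ndarray:
        field_ = np.zeros(grid.shape)
        tq = t + 1e-9
        sp = self.spec
        if sp.s1_time <= tq < sp.s1_time + sp.s1_duration:
            field_[self._s1_region.site_mask(grid)] += sp.s1_amplitude
        if (self.s2_time is not None
                and self.s2_time <= tq < self.s2_time + sp.s2_duration):
            field_[self._s2_region.site_mask(grid)] += sp.s2_amplitude
        return field_

    def describe(self) -> dict:
        return {"kind": "s1s2", "s1_time": self.spec.s1_time,
                "s2_time": self.s2_time,
                "trigger_threshold": self.spec.trigger_threshold}

    def schedule_rows(self, t_end: float) -> List[Tuple[float, str]]:
        rows = [(self.spec.s1_time, "S1")]
        if self.s2_time is not None:
            rows.append((float(self.s2_time), "S2"))
        return rows


def s1s2_cross_field(grid, spec: Optional[S1S2Spec] = None) -> S1S2Protocol:
    """Build the cross-field initiation protocol for ``grid``."""
    if grid.ny < 2:
        raise ValueError("S1-S2 cross-field requires a 2D grid")
    return S1S2Protocol(grid, spec or S1S2Spec())


# ---------------------------------------------------------------------------
# sensors

CORNER_INSET_CM = 0.5


def place_sensors(grid, scheme: str, center_cm: Optional[Tuple[float, float]] = None,
                  radius_cm: Optional[float] = None, margin_cm: float = 0.2,
                  n_ring: int = 32) -> List[Tuple[int, int]]:
    """Sensor sites for trace recording.

    Schemes: ``four-corners`` (one sensor per quadrant, inset 0.5 cm),
    ``clump-ring`` (``n_ring`` sites on a circle of radius R + margin),
    ``cable-every-site``.  Sensors landing on obstacles are relocated to
    the nearest non-obstacle site.
    """
    if scheme == "four-corners":
        m = int(round(CORNER_INSET_CM / grid.dx))
        sites = [(m, m), (m, grid.nx - 1 - m),
                 (grid.ny - 1 - m, m), (grid.ny - 1 - m, grid.nx - 1 - m)]
    elif scheme == "clump-ring":
        if center_cm is None:
            lx, ly = grid.extent_cm
            center_cm = (lx / 2.0, ly / 2.0)
        if radius_cm is None:
            raise ValueError("clump-ring scheme needs radius_cm")
        r = radius_cm + margin_cm
        sites = []
        for k in range(n_ring):
            th = 2.0 * np.pi * k / n_ring
            x = center_cm[0] + r * np.cos(th)
            y = center_cm[1] + r * np.sin(th)
            ix = int(np.clip(round(x / grid.dx - 0.5), 0, grid.nx - 1))
            iy = int(np.clip(round(y / grid.dx - 0.5), 0, grid.ny - 1))
            if (iy, ix) not in sites:
                sites.append((iy, ix))
    elif scheme == "cable-every-site":
        sites = [(iy, ix) for iy in range(grid.ny) for ix in range(grid.nx)]
    else:
        raise ValueError(f"unknown sensor scheme: {scheme!r}")
    return [_off_obstacle(grid, s) for s in sites]


def _off_obstacle(grid, site: Tuple[int, int]) -> Tuple[int, int]:
    iy, ix = site
    if not grid.obstacle[iy, ix]:
        return site
    free = np.argwhere(~grid.obstacle)
    d2 = (free[:, 0] - iy) ** 2 + (free[:, 1] - ix) ** 2
    iy2, ix2 = free[np.argmin(d2)]
    return (int(iy2), int(ix2))
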