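"""Feature extraction and statistics.

AP/EAD detection and type-I/type-II classification, conduction velocity,
PVC counting at sensor sites, and averaged power spectra with periodic /
quasiperiodic peak indexing.

Conventions (all configurable): AP upstroke at the -40 mV upward crossing
(with a -60 mV re-arm hysteresis so EAD oscillations are not re-counted
as upstrokes), repolarization complete at 90% return toward the resting
potential, EAD prominence threshold 1 mV, type-II elevation margin 10 mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks, periodogram

__all__ = [
    "APFeature", "PVCReport", "SpectrumResult", "detect_aps", "detect_eads",
    "classify_ap", "activation_time", "conduction_velocity", "count_pvcs",
    "averaged_power_spectrum", "index_peaks",
]

UPSTROKE_MV = -40.0
REARM_MV = -60.0
REPOL_FRACTION = 0.9
EAD_PROMINENCE_MV = 1.0
ELEVATION_MARGIN_MV = 10.0
RESTING_VM = -88.0
MERGE_WINDOW_MS = 50.0
CV_MIN_CM_S = 20.0


@dataclass
class APFeature:
    """One action potential and its EAD content."""

    t_up: float
    t_peak: float
    v_peak: float
    t_end: float
    repolarized: bool
    v_final: float
    eads: List[Tuple[float, float, float]] = field(default_factory=list)
    # each EAD: (time of local max, Vm at max, amplitude above preceding min)

    @property
    def ead_amplitudes(self) -> np.ndarray:
        return np.array([a for _, _, a in self.eads])


def _upstroke_indices(vm: np.ndarray, threshold: float, rearm: float) -> List[int]:
    """Upward threshold crossings, re-armed only after Vm falls below
    ``rearm`` (EAD oscillations during a plateau are not new upstrokes)."""
    idx = []
    armed = vm[0] < threshold
    for i in range(1, len(vm)):
        if armed and vm[i - 1] < threshold <= vm[i]:
            idx.append(i)
            armed = False
        elif not armed and vm[i] < rearm:
            armed = True
    return idx


def detect_eads(time: np.ndarray, vm: np.ndarray, i_peak: int, i_end: int,
                prominence: float = EAD_PROMINENCE_MV,
                ) -> List[Tuple[float, float, float]]:
    """Depolarizing oscillations between the AP peak and repolarization.

    An EAD is a local minimum followed by a local maximum with the stated
    prominence; its amplitude is (max - preceding min).
    """
    seg = vm[i_peak:i_end + 1]
    if seg.size < 3:
        return []
    maxima, _ = find_peaks(seg, prominence=prominence)
    minima, _ = find_peaks(-seg, prominence=prominence)
    eads = []
    for p in maxima:
        prev = minima[minima < p]
        if prev.size == 0:
            continue
        amp = float(seg[p] - seg[prev[-1]])
        eads.append((float(time[i_peak + p]), float(seg[p]), amp))
    return eads


def detect_aps(time: np.ndarray, vm: np.ndarray,
               threshold: float = UPSTROKE_MV,
               repol_fraction: float = REPOL_FRACTION,
               resting_vm: Optional[float] = None,
               ead_prominence: float = EAD_PROMINENCE_MV) -> List[APFeature]:
    """Segment a uniformly sampled trace into APs with features."""
    time = np.asarray(time, dtype=float)
    vm = np.asarray(vm, dtype=float)
    if vm.size != time.size or vm.size < 2:
        raise ValueError("need a uniformly sampled trace")
    if not np.all(np.isfinite(vm)):
        raise ValueError("trace contains non-finite samples")
    rest = float(vm.min()) if resting_vm is None else resting_vm

    ups = _upstroke_indices(vm, threshold, REARM_MV)
    aps: List[APFeature] = []
    for k, i_up in enumerate(ups):
        # the AP span ends just before the next upstroke crossing
        i_stop = ups[k + 1] - 1 if k + 1 < len(ups) else len(vm) - 1
        seg = vm[i_up:i_stop + 1]
        i_peak = i_up + int(np.argmax(seg))
        v_peak = float(vm[i_peak])
        v90 = v_peak - repol_fraction * (v_peak - rest)
        below = np.nonzero(vm[i_peak:i_stop + 1] <= v90)[0]
        if below.size:
            i_end = i_peak + int(below[0])
            repolarized = True
        else:
            i_end = i_stop
            repolarized = False
        aps.append(APFeature(
            t_up=float(time[i_up]), t_peak=float(time[i_peak]), v_peak=v_peak,
            t_end=float(time[i_end]), repolarized=repolarized,
            v_final=float(vm[i_stop]),
            eads=detect_eads(time, vm, i_peak, i_end, ead_prominence)))
    return aps


def classify_ap(ap: APFeature, resting_vm: float = RESTING_VM,
                elevation_margin: float = ELEVATION_MARGIN_MV) -> str:
    """'normal', 'type-I', 'type-II', or 'other'.

    Growing EAD amplitudes with full repolarization -> type-I; decaying
    EADs with the final potential elevated above rest -> type-II.
    """
    amps = ap.ead_amplitudes
    if amps.size == 0:
        return "normal" if ap.repolarized else "other"
    elevated = ap.v_final > resting_vm + elevation_margin
    if amps.size == 1:
        growing = True   # a single oscillation cannot decay
    else:
        growing = float(np.polyfit(np.arange(amps.size), amps, 1)[0]) >= 0.0
    if growing and ap.repolarized:
        return "type-I"
    if not growing and elevated:
        return "type-II"
    return "other"


def activation_time(time: np.ndarray, vm: np.ndarray,
                    threshold: float = UPSTROKE_MV) -> float:
    """First upward crossing of ``threshold``, linearly interpolated.

    Raises ValueError if the site never activates.
    """
    vm = np.asarray(vm, dtype=float)
    cross = np.nonzero((vm[:-1] < threshold) & (vm[1:] >= threshold))[0]
    if cross.size == 0:
        raise ValueError("site never activated")
    i = int(cross[0])
    frac = (threshold - vm[i]) / (vm[i + 1] - vm[i])
    return float(time[i] + frac * (time[i + 1] - time[i]))


def conduction_velocity(t_a: float, t_b: float, distance_cm: float) -> float:
    """CV = distance / activation-time difference, cm/s."""
    if distance_cm <= 0:
        raise ValueError("distance must be positive")
    dt = t_b - t_a
    if not np.isfinite(dt) or dt <= 0:
        raise ValueError("sites not activated by the same forward wave")
    return distance_cm / dt * 1000.0


@dataclass
class PVCReport:
    """Ectopic activation episodes not attributable to pacing."""

    n: int
    events: List[Tuple[float, int]]       # (episode time, first sensor index)
    pulse_times: np.ndarray
    window: Tuple[float, float]

    def __post_init__(self) -> None:
        assert self.n == len(self.events)


def count_pvcs(time: np.ndarray, traces: np.ndarray,
               pulse_times: Sequence[float], max_dist_cm: float,
               window: Optional[Tuple[float, float]] = None,
               cv_min: float = CV_MIN_CM_S,
               merge_ms: float = MERGE_WINDOW_MS) -> PVCReport:
    """Count PVC episodes seen by a set of sensors.

    For each sensor and pacing pulse, the first activation within the
    conduction-delay window (``max_dist_cm / cv_min``) after the pulse is
    attributed to pacing.  All remaining activations are ectopic; ectopic
    hits across sensors within ``merge_ms`` of each other are merged into
    one wavefront episode.  N = number of episodes inside ``window``.
    """
    time = np.asarray(time, dtype=float)
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    pulse_times = np.asarray(pulse_times, dtype=float)
    if window is None:
        window = (float(time[0]), float(time[-1]))
    delay_max = max_dist_cm / cv_min * 1000.0   # ms

    ectopic: List[Tuple[float, int]] = []
    for s in range(traces.shape[0]):
        ups = _upstroke_indices(traces[s], UPSTROKE_MV, REARM_MV)
        t_acts = [float(time[i]) for i in ups]
        attributed = np.zeros(len(t_acts), dtype=bool)
        for p in pulse_times:
            for k, t_act in enumerate(t_acts):
                if attributed[k]:
                    continue
                if p <= t_act <= p + delay_max:
                    attributed[k] = True
                    break       # one paced arrival per pulse per sensor
        ectopic.extend((t, s) for k, t in enumerate(t_acts) if not attributed[k])

    ectopic.sort()
    episodes: List[Tuple[float, int]] = []
    last_t = -np.inf
    for t, s in ectopic:
        if t - last_t > merge_ms:
            episodes.append((t, s))
        last_t = t
    episodes = [(t, s) for t, s in episodes if window[0] <= t <= window[1]]
    return PVCReport(n=len(episodes), events=episodes,
                     pulse_times=pulse_times, window=window)


@dataclass
class SpectrumResult:
    """Averaged power spectrum with detected and indexed peaks."""

    freqs: np.ndarray
    power: np.ndarray
    peaks: List[Tuple[float, float]]        # (Hz, power)
    classification: str                     # periodic | quasiperiodic | other
    bases: Tuple[float, ...]                # (w1,) or (w1, w2), Hz
    index_table: List[Tuple[float, int, int, float]]
    # rows: (peak Hz, n1, n2, residual Hz)

    @property
    def fundamental(self) -> Optional[float]:
        return self.bases[0] if self.bases else None


def averaged_power_spectrum(time: np.ndarray, traces: np.ndarray,
                            window: Optional[Tuple[float, float]] = None,
                            taper: Optional[str] = None,
                            peak_rel_prominence: float = 1e-3,
                            max_order: int = 4,
                            tol: float = 0.02) -> SpectrumResult:
    """Mean-removed periodograms averaged across sensor traces.

    ``window`` restricts the analysis to (t0, t1) ms; a >= 5 s window is
    recommended for ~0.2 Hz resolution.  Peaks are detected on the
    averaged spectrum with a prominence relative to its maximum, then
    indexed by :func:`index_peaks`.
    """
    time = np.asarray(time, dtype=float)
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if window is not None:
        sel = (time >= window[0]) & (time <= window[1])
        time, traces = time[sel], traces[:, sel]
    fs = 1000.0 / (time[1] - time[0])   # Hz
    win = "hann" if taper == "hann" else "boxcar"
    power = None
    for s in range(traces.shape[0]):
        f, p = periodogram(traces[s], fs=fs, window=win, detrend="constant")
        power = p if power is None else power + p
    power = power / traces.shape[0]

    prom = peak_rel_prominence * float(power.max())
    pk, _ = find_peaks(power, prominence=prom)
    pk = pk[f[pk] > 0]
    peaks = [(float(f[i]), float(power[i])) for i in pk]
    # index only the dominant peaks: weak harmonic tails truncate noisily,
    # and spectral-leakage sidelobes shadow the main lines (drop peaks
    # within 5% of a stronger one)
    strongest: List[Tuple[float, float]] = []
    for fp, pw in sorted(peaks, key=lambda p: -p[1]):
        if len(strongest) >= 8:
            break
        if all(abs(fp - fk) > 0.05 * fk for fk, _ in strongest):
            strongest.append((fp, pw))
    classification, bases, table = index_peaks(
        [fp for fp, _ in strongest], max_order=max_order, tol=tol,
        powers=[pw for _, pw in strongest])
    return SpectrumResult(freqs=f, power=power, peaks=peaks,
                          classification=classification, bases=bases,
                          index_table=table)


def _fit_two_base(freqs: np.ndarray, assign: np.ndarray) -> Tuple[float, float]:
    """Least-squares (w1, w2) given integer assignments (n1, n2) per peak."""
    a = assign.astype(float)
    ata = a.T @ a
    atb = a.T @ freqs
    w = np.linalg.solve(ata, atb)
    return float(w[0]), float(w[1])


def index_peaks(peak_freqs: Sequence[float], max_order: int = 4,
                tol: float = 0.02, powers: Optional[Sequence[float]] = None):
    """Classify a peak set as periodic / quasiperiodic / other.

    Periodic: one base explains every peak as an integer harmonic and the
    fundamental itself carries substantial power (>= 10% of the strongest
    peak when ``powers`` are given; without powers, the harmonic ladder
    must instead be essentially gap-free).  This keeps sparse combination
    sets such as {w2-w1, w1, w2, w1+w2} — whose indices against the weak
    difference frequency would be {1, 3, 4, 7} — out of the periodic
    class even when the printed base ratio happens to be rational.
    Quasiperiodic: all peaks fit n1*w1 + n2*w2 with |n| <= ``max_order``;
    among valid base pairs the most parsimonious assignment (minimal sum
    of |n|, ties resolved toward the strongest peaks) wins, and the bases
    are refined by least squares.  Returns (classification, bases, index
    table with residuals in Hz).
    """
    order = np.argsort([float(f) for f in peak_freqs])
    freqs = np.array([float(peak_freqs[i]) for i in order])
    pw = (np.array([float(powers[i]) for i in order])
          if powers is not None else None)
    keep = freqs > 0
    freqs = freqs[keep]
    if pw is not None:
        pw = pw[keep]
    if freqs.size == 0:
        return "other", (), []
    if freqs.size == 1:
        w1 = freqs[0]
        return "periodic", (w1,), [(w1, 1, 0, 0.0)]

    # one-base indexing: candidate bases from each peak / small integer,
    # largest candidates first so the true fundamental wins
    candidates = sorted({f / k for f in freqs for k in range(1, max_order + 1)},
                        reverse=True)
    for w1 in candidates:
        ns = np.round(freqs / w1).astype(int)
        if np.any(ns < 1) or ns.min() != 1:
            continue
        resid = freqs - ns * w1
        if not np.all(np.abs(resid) <= tol * w1):
            continue
        if pw is not None:
            base_power = pw[ns == 1].max()
            if base_power < 0.2 * pw.max():
                continue
        else:
            gaps = np.diff(np.unique(ns))
            if gaps.max(initial=1) > 2 or np.sum(gaps == 2) > 1:
                continue
        w1 = float(np.sum(ns * freqs) / np.sum(ns * ns))  # refine
        resid = freqs - np.round(freqs / w1) * w1
        table = [(float(f), int(round(f / w1)), 0, float(r))
                 for f, r in zip(freqs, resid)]
        return "periodic", (w1,), table

    # two-base indexing over peak pairs; among valid base pairs keep the
    # most parsimonious assignment (minimal sum |n1| + |n2|), which picks
    # the dominant pair rather than e.g. (w2 - w1, w1)
    best_solution = None
    for ia in range(freqs.size):
        for ib in range(ia + 1, freqs.size):
            wa, wb = freqs[ia], freqs[ib]
            assign = np.zeros((freqs.size, 2), dtype=int)
            ok = True
            cost = 0
            for k, fp in enumerate(freqs):
                # among in-tolerance combos prefer the lowest order; raw
                # residual minimization would favor accidental high-order
                # exact matches on the quantized frequency grid
                best = None
                for n1 in range(-max_order, max_order + 1):
                    for n2 in range(-max_order, max_order + 1):
                        if n1 == 0 and n2 == 0:
                            continue
                        r = abs(fp - (n1 * wa + n2 * wb))
                        if r > tol * wa:
                            continue
                        key_ = (abs(n1) + abs(n2), r)
                        if best is None or key_ < best[0]:
                            best = (key_, n1, n2)
                if best is None:
                    ok = False
                    break
                assign[k] = (best[1], best[2])
                cost += abs(best[1]) + abs(best[2])
            if not ok:
                continue
            w1, w2 = _fit_two_base(freqs, assign)
            if w1 <= 0 or w2 <= 0:
                continue
            if pw is not None:
                rank = -(pw[ia] + pw[ib])      # prefer dominant base peaks
            else:
                rank = -wa                     # prefer the larger first base
            key = (cost, rank)
            if best_solution is None or key < best_solution[0]:
                best_solution = (key, w1, w2, assign.copy())
    if best_solution is not None:
        _, w1, w2, assign = best_solution
        table = [(float(fp), int(n1), int(n2),
                  float(fp - n1 * w1 - n2 * w2))
                 for fp, (n1, n2) in zip(freqs, assign)]
        return "quasiperiodic", (w1, w2), table

    return "other", (), []
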