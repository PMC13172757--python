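"""Tap segmentation and the four item-3.4-aligned kinematic features.

From a conditioned aperture waveform the module extracts tap cycles (peak
detection with a refractory interval against double counts) and computes:

* **V** — tapping velocity, the mean absolute first derivative of the
  aperture trace, in aperture units per second;
* **Δa** (``delta_a``) — amplitude decrement, the ordinary least-squares
  slope of per-cycle amplitude on cycle index, in units per cycle (the
  sequence effect);
* **aCoV** — amplitude variability, sample SD over mean of the per-cycle
  amplitudes;
* **ifCoV** — rhythm variability, sample SD over mean of the instantaneous
  frequencies if_i = 1/Δt_i, where Δt_i is the interval between consecutive
  tap peaks.

Both coefficients of variation use the sample (n−1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import peak_prominences

from .errors import InsufficientCyclesError, InvalidArgumentError
from .landmarks import DistanceWaveform

#: Minimum number of detected cycles for features to be emitted.
MIN_CYCLES = 5
#: Refractory interval between accepted peaks (s); 0.2 s caps credible
#: tapping at 5 Hz and suppresses double counts from residual ripple.
DEFAULT_REFRACTORY_S = 0.2
#: Peak prominence threshold as a fraction of the global trace range.
DEFAULT_MIN_PROMINENCE_FRAC = 0.1


@dataclass(frozen=True)
class TapCycleSet:
    """Ordered tap events of one recording.

    Peaks and valleys alternate; with n peaks there are n−1 interior
    valleys and n−1 inter-peak intervals.  Per-cycle amplitude A_i is the
    peak height minus the mean of its adjacent valleys (one-sided at the
    trace ends).
    """

    peak_times: np.ndarray
    valley_times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.peak_times, float)
        v = np.asarray(self.valley_times, float)
        a = np.asarray(self.amplitudes, float)
        if a.shape != p.shape:
            raise InvalidArgumentError("one amplitude per peak required")
        if v.size != max(p.size - 1, 0):
            raise InvalidArgumentError("expected one valley between consecutive peaks")
        if p.size >= 2 and not np.all((v > p[:-1]) & (v < p[1:])):
            raise InvalidArgumentError("peaks and valleys must alternate")
        if np.any(a <= 0):
            raise InvalidArgumentError("cycle amplitudes must be positive")

    @property
    def n_cycles(self) -> int:
        return int(np.asarray(self.peak_times).size)

    @property
    def intervals(self) -> np.ndarray:
        """Inter-tap intervals Δt_i between consecutive peaks (s)."""
        return np.diff(np.asarray(self.peak_times, float))

    @property
    def instantaneous_frequencies(self) -> np.ndarray:
        """if_i = 1/Δt_i (Hz)."""
        dt = self.intervals
        if np.any(dt <= 0):
            raise InvalidArgumentError("non-positive inter-tap interval")
        return 1.0 / dt


@dataclass(frozen=True)
class KinematicFeatures:
    """The (V, Δa, aCoV, ifCoV) quadruple for one recording."""

    V: float
    delta_a: float
    aCoV: float
    ifCoV: float
    n_cycles: int
    qc_pass: bool


def _plateau_left_maxima(d: np.ndarray) -> list[int]:
    """Indices of strict local maxima; plateaus resolve to their leftmost sample."""
    n = d.size
    out: list[int] = []
    i = 1
    while i < n - 1:
        if d[i] > d[i - 1]:
            j = i
            while j + 1 < n and d[j + 1] == d[i]:
                j += 1
            if j < n - 1 and d[j + 1] < d[i]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return out


def detect_taps(w: DistanceWaveform, refractory_s: float = DEFAULT_REFRACTORY_S,
                min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
                require_conditioned: bool = True) -> TapCycleSet:
    """Segment the waveform into tap cycles.

    Candidate peaks are local maxima with prominence at least
    ``min_prominence_frac`` of the global range.  Candidates are then kept
    greedily in decreasing height order (leftmost first on equal height),
    discarding any candidate within ``refractory_s`` of an already kept
    peak, so accepted peaks are pairwise spaced by more than the refractory
    interval.  The valley between consecutive peaks is the minimum sample
    (leftmost on ties).
    """
    if require_conditioned and not any(
        p.startswith("butterworth") for p in w.provenance
    ):
        raise InvalidArgumentError(
            "detect_taps expects a conditioned waveform (low-pass in provenance); "
            "pass require_conditioned=False to override"
        )
    d = np.asarray(w.d, float)
    t = np.asarray(w.t, float)
    rng = float(d.max() - d.min()) if d.size else 0.0
    candidates = _plateau_left_maxima(d) if rng > 0 else []
    if candidates:
        prom = peak_prominences(d, candidates)[0]
        candidates = [c for c, p in zip(candidates, prom)
                      if p >= min_prominence_frac * rng]

    kept: list[int] = []
    for c in sorted(candidates, key=lambda i: (-d[i], i)):
        if all(abs(t[c] - t[k]) > refractory_s for k in kept):
            kept.append(c)
    kept.sort()

    if len(kept) < MIN_CYCLES:
        raise InsufficientCyclesError(
            f"{len(kept)} peaks detected; at least {MIN_CYCLES} cycles required"
        )

    peaks = np.asarray(kept)
    valleys = np.empty(peaks.size - 1, dtype=int)
    for i in range(peaks.size - 1):
        lo, hi = peaks[i] + 1, peaks[i + 1]
        valleys[i] = lo + int(np.argmin(d[lo:hi]))

    amps = np.empty(peaks.size)
    for i, p in enumerate(peaks):
        adj = []
        if i > 0:
            adj.append(d[valleys[i - 1]])
        if i < valleys.size:
            adj.append(d[valleys[i]])
        amps[i] = d[p] - float(np.mean(adj))

    return TapCycleSet(peak_times=t[peaks], valley_times=t[valleys], amplitudes=amps)


def compute_velocity(w: DistanceWaveform) -> float:
    """Mean absolute first derivative of the aperture trace (units/s)."""
    if len(w) < 2:
        raise InvalidArgumentError("velocity requires at least 2 samples")
    return float(np.mean(np.abs(np.diff(w.d))) * w.sample_rate_hz)


def compute_amplitude_decrement(cycles: TapCycleSet) -> float:
    """OLS slope of cycle amplitude A_i on 0-based cycle index (units/cycle)."""
    a = np.asarray(cycles.amplitudes, float)
    if a.size < MIN_CYCLES:
        raise InsufficientCyclesError(f"need ≥{MIN_CYCLES} cycles, got {a.size}")
    return float(np.polyfit(np.arange(a.size), a, 1)[0])


def compute_acov(cycles: TapCycleSet) -> float:
    """Amplitude coefficient of variation σA/μA (sample SD)."""
    a = np.asarray(cycles.amplitudes, float)
    if a.size < MIN_CYCLES:
        raise InsufficientCyclesError(f"need ≥{MIN_CYCLES} cycles, got {a.size}")
    mu = float(np.mean(a))
    if mu <= 0:
        raise InvalidArgumentError("mean amplitude must be positive")
    return float(np.std(a, ddof=1) / mu)


def compute_ifcov(cycles: TapCycleSet) -> float:
    """Rhythm coefficient of variation σif/μif over if_i = 1/Δt_i (sample SD)."""
    f = cycles.instantaneous_frequencies
    if f.size < MIN_CYCLES - 1:
        raise InsufficientCyclesError(f"need ≥{MIN_CYCLES - 1} intervals, got {f.size}")
    return float(np.std(f, ddof=1) / np.mean(f))


def extract_features(w: DistanceWaveform, refractory_s: float = DEFAULT_REFRACTORY_S,
                     min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
                     qc_pass: bool = True) -> KinematicFeatures:
    """Run tap detection and all four features on a conditioned waveform."""
    cycles = detect_taps(w, refractory_s=refractory_s,
                         min_prominence_frac=min_prominence_frac)
    return KinematicFeatures(
        V=compute_velocity(w),
        delta_a=compute_amplitude_decrement(cycles),
        aCoV=compute_acov(cycles),
        ifCoV=compute_ifcov(cycles),
        n_cycles=cycles.n_cycles,
        qc_pass=qc_pass,
    )
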