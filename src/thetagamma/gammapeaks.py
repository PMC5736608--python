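"""Gamma-burst peak detection, peak-triggered averages, and peak-phase
histograms.

Peaks are local maxima of the gamma-bandpassed voltage. To avoid picking
several peaks within one theta cycle, maxima are retained greedily in
descending amplitude with a symmetric 100-ms exclusion zone, so surviving
peak times are pairwise separated by at least 100 ms.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .circstats import resultant_vector
from .cfc import N_BINS, BIN_CENTERS, _BIN_WIDTH
from .errors import InsufficientDataError
from .sigproc import FilteredTrace, LfpRecording, PhaseSeries, bandpass_zero_phase

__all__ = [
    "GammaPeakSet",
    "TriggeredAverage",
    "detect_peaks",
    "triggered_average",
    "peak_phase_histogram",
]


@dataclass
class GammaPeakSet:
    peak_times: np.ndarray          # s, strictly increasing
    peak_amplitudes: np.ndarray     # filtered voltage at each peak
    band: tuple[float, float]
    min_separation: float = 0.1     # s
    source_region: str = ""


@dataclass
class TriggeredAverage:
    lags_s: np.ndarray
    mean_raw: np.ndarray            # raw-LFP average across windows
    mean_theta: np.ndarray          # theta-filtered overlay of the same windows
    n_used: int
    n_dropped: int


def detect_peaks(
    filtered: FilteredTrace, min_separation: float = 0.1,
    envelope_threshold: float | None = None,
) -> GammaPeakSet:
    """Local maxima of the filtered voltage, thinned to >= 100-ms spacing.

    Candidates are sorted by descending amplitude (ties: earlier wins) and
    kept when no already-kept peak lies within ``min_separation``. Edge
    (transient) samples never produce peaks. ``envelope_threshold``
    optionally discards candidates whose amplitude is below the given value
    (off by default).
    """
    x = filtered.samples
    if x.size / filtered.rate < 0.2:
        raise InsufficientDataError("trace shorter than 200 ms")
    idx, _ = sps.find_peaks(x)
    lo, hi = filtered.n_edge, x.size - filtered.n_edge
    idx = idx[(idx >= lo) & (idx < hi)]
    if envelope_threshold is not None:
        idx = idx[x[idx] >= envelope_threshold]
    # Greedy highest-first retention with symmetric exclusion.
    order = np.lexsort((idx, -x[idx]))
    min_gap = int(round(min_separation * filtered.rate))
    kept: list[int] = []
    for i in idx[order]:
        pos = bisect.bisect_left(kept, i)
        if pos > 0 and i - kept[pos - 1] < min_gap:
            continue
        if pos < len(kept) and kept[pos] - i < min_gap:
            continue
        kept.insert(pos, int(i))
    kept_arr = np.array(kept, dtype=int)
    return GammaPeakSet(
        peak_times=filtered.t0 + kept_arr / filtered.rate,
        peak_amplitudes=x[kept_arr] if kept_arr.size else np.array([]),
        band=filtered.band, min_separation=min_separation,
        source_region=filtered.region,
    )


def triggered_average(
    peaks: GammaPeakSet, lfp: LfpRecording,
    half_window: float = 0.1, theta_band: tuple[float, float] = (4.0, 12.0),
) -> TriggeredAverage:
    """Average of 200-ms raw-LFP windows centered on gamma peaks.

    Peaks whose full +/-100-ms window falls outside the trace are dropped
    (and counted). The same windows of the theta-bandpassed trace are
    averaged as an overlay for phase-alignment display.
    """
    half = int(round(half_window * lfp.rate))
    centers = np.round((peaks.peak_times - lfp.t0) * lfp.rate).astype(int)
    ok = (centers >= half) & (centers < lfp.samples.size - half)
    n_dropped = int((~ok).sum())
    centers = centers[ok]
    if centers.size == 0:
        raise InsufficientDataError("no peak has a full window inside the trace")
    offsets = np.arange(-half, half + 1)
    windows = lfp.samples[centers[:, None] + offsets[None, :]]
    theta = bandpass_zero_phase(lfp, theta_band).samples
    theta_windows = theta[centers[:, None] + offsets[None, :]]
    return TriggeredAverage(
        lags_s=offsets / lfp.rate,
        mean_raw=windows.mean(axis=0),
        mean_theta=theta_windows.mean(axis=0),
        n_used=int(centers.size), n_dropped=n_dropped,
    )


def peak_phase_histogram(
    peaks: GammaPeakSet, theta_phase: PhaseSeries,
) -> tuple[np.ndarray, float, float, int]:
    """Theta-phase distribution of gamma peak times.

    Returns (histogram over the 100 standard phase bins, normalized to sum
    to 1; circular mean direction; MRL; number of peaks used). Peaks outside
    the phase-series support are ignored.
    """
    phases = theta_phase.at_times(peaks.peak_times)
    phases = phases[np.isfinite(phases)]
    if phases.size == 0:
        raise InsufficientDataError("no peaks fall inside the phase series")
    idx = np.floor((phases + np.pi) / _BIN_WIDTH).astype(int)
    np.clip(idx, 0, N_BINS - 1, out=idx)
    hist = np.bincount(idx, minlength=N_BINS).astype(float)
    hist /= hist.sum()
    z = resultant_vector(phases)
    return hist, float(np.angle(z)), float(abs(z)), int(phases.size)
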