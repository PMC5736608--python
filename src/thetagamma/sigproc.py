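"""Spectral front end: zero-phase FIR bandpass, Hilbert phase, Morlet power.

Conventions fixed here and used throughout the package:

* Phase is the angle of the analytic signal of a bandpassed trace, wrapped to
  (-pi, pi], with 0 at the oscillation peak (cosine convention) and +/-pi at
  the trough.
* The Morlet wavelet at frequency f is a complex exponential under a Gaussian
  envelope with sigma_t = n_cycles / (2 pi f), n_cycles = 2 by default,
  truncated at +/-5 sigma_t, and L1-normalized so that a unit-amplitude
  cosine at f yields power ~= 1. Power is the squared magnitude of the
  convolution.
* Filtering is a windowed-sinc (Hamming) linear-phase FIR applied forward and
  backward, so the net group delay is zero and stopband attenuation doubles
  (in dB). The `numtaps` samples nearest each edge are contaminated by
  transients and flagged via ``n_edge``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, InsufficientDataError

__all__ = [
    "LfpRecording",
    "FilteredTrace",
    "PhaseSeries",
    "WaveletPower",
    "bandpass_zero_phase",
    "instantaneous_phase",
    "morlet_kernel",
    "morlet_power",
]


@dataclass
class LfpRecording:
    """A continuous LFP trace.

    Attributes
    ----------
    samples : voltage in microvolts, 1-d float array.
    rate : sampling rate in Hz.
    region : recording site label ("mPFC", "dHPC", "vHPC", ...).
    t0 : time of the first sample in seconds from session start.
    """

    samples: np.ndarray
    rate: float
    region: str = ""
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ConfigError("LFP samples must be a 1-d array")
        if not self.rate > 0:
            raise ConfigError(f"sampling rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ConfigError("LFP contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate


@dataclass
class FilteredTrace:
    """A bandpassed trace plus bookkeeping of edge transients."""

    samples: np.ndarray
    rate: float
    band: tuple[float, float]
    n_edge: int
    region: str = ""
    t0: float = 0.0

    def valid_slice(self) -> slice:
        return slice(self.n_edge, self.samples.size - self.n_edge)


@dataclass
class PhaseSeries:
    """Instantaneous wrapped phase of a bandpassed trace.

    phase 0 marks the oscillation peak; +/-pi the trough.
    """

    phase: np.ndarray
    band: tuple[float, float]
    rate: float
    n_edge: int = 0
    t0: float = 0.0

    def __post_init__(self):
        self.phase = np.asarray(self.phase, dtype=float)

    def valid_slice(self) -> slice:
        return slice(self.n_edge, self.phase.size - self.n_edge)

    def at_times(self, times) -> np.ndarray:
        """Phase at arbitrary times by nearest-sample lookup.

        Times outside the series support (including flagged edges) return NaN.
        """
        times = np.asarray(times, dtype=float)
        idx = np.round((times - self.t0) * self.rate).astype(int)
        out = np.full(times.shape, np.nan)
        ok = (idx >= self.n_edge) & (idx < self.phase.size - self.n_edge)
        out[ok] = self.phase[idx[ok]]
        return out


@dataclass
class WaveletPower:
    """Time x frequency wavelet power (microvolt^2 per sample).

    ``n_edge`` holds, per frequency row, the number of samples at each edge
    inside the cone of influence (kernel half-width).
    """

    power: np.ndarray  # (n_freqs, n_samples)
    freqs: np.ndarray
    rate: float
    n_cycles: float = 2.0
    n_edge: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    t0: float = 0.0

    def band_mean(self, band: tuple[float, float]) -> tuple[np.ndarray, int]:
        """Mean power across frequency rows inside ``band`` (inclusive).

        Returns the per-sample mean and the widest cone-of-influence edge
        among the contributing rows.
        """
        low, high = band
        rows = (self.freqs >= low) & (self.freqs <= high)
        if not rows.any():
            raise ConfigError(f"no wavelet frequencies inside band {band}")
        return self.power[rows].mean(axis=0), int(self.n_edge[rows].max())


def _design_fir(rate: float, band: tuple[float, float], numtaps: int | None):
    low, high = band
    if not (0.0 < low < high < rate / 2.0):
        raise ConfigError(
            f"band {band} must satisfy 0 < low < high < Nyquist ({rate / 2} Hz)"
        )
    if numtaps is None:
        # Default order: 3 cycles of the band's low edge.
        numtaps = int(round(3.0 * rate / low))
    numtaps = int(numtaps) | 1  # odd length -> symmetric, integer delay
    h = sps.firwin(numtaps, [low, high], pass_zero=False, fs=rate, window="hamming")
    return h


def bandpass_zero_phase(
    lfp: LfpRecording, band: tuple[float, float], numtaps: int | None = None
) -> FilteredTrace:
    """Zero-phase bandpass via forward-backward FIR filtering.

    The default filter order is 3 cycles of the band's low edge; for narrow
    bands (e.g. the 0.5-Hz comodulogram bands) pass an explicit ``numtaps``
    of about ``3.3 * rate / transition_width``.
    """
    h = _design_fir(lfp.rate, band, numtaps)
    n = h.size
    if lfp.samples.size <= 3 * n:
        raise InsufficientDataError(
            f"trace of {lfp.samples.size} samples too short for a "
            f"{n}-tap filter (need > {3 * n})"
        )
    x = lfp.samples - lfp.samples.mean()
    y = sps.fftconvolve(x, h, mode="same")
    y = sps.fftconvolve(y[::-1], h, mode="same")[::-1]
    return FilteredTrace(
        samples=y, rate=lfp.rate, band=(float(band[0]), float(band[1])),
        n_edge=n, region=lfp.region, t0=lfp.t0,
    )


def instantaneous_phase(filtered: FilteredTrace) -> PhaseSeries:
    """Instantaneous phase of a bandpassed trace via the Hilbert transform.

    Phase 0 falls on local maxima of the filtered voltage (cosine
    convention). Raises on (near-)constant input, whose phase is undefined.
    """
    x = np.asarray(filtered.samples, dtype=float)
    if x.size < 2 or np.std(x) < 1e-12 * max(1.0, np.abs(x).max()) or np.std(x) == 0.0:
        raise InsufficientDataError("phase undefined for constant input")
    analytic = sps.hilbert(x)
    return PhaseSeries(
        phase=np.angle(analytic), band=filtered.band, rate=filtered.rate,
        n_edge=filtered.n_edge, t0=filtered.t0,
    )


def morlet_kernel(freq: float, rate: float, n_cycles: float = 2.0) -> np.ndarray:
    """Complex Morlet kernel at ``freq``: exp(2*pi*i*f*t) * Gaussian(sigma_t).

    sigma_t = n_cycles / (2 pi f); support +/-5 sigma_t; scaled so a
    unit-amplitude cosine at ``freq`` gives |convolution| ~= 1.
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * rate))
    t = np.arange(-half, half + 1) / rate
    envelope = np.exp(-(t**2) / (2.0 * sigma_t**2))
    kernel = envelope * np.exp(2j * np.pi * freq * t)
    # L1 normalization of the envelope; factor 2 folds in the negative
    # frequency half lost by complex demodulation of a real cosine.
    return kernel * (2.0 / envelope.sum())


def morlet_power(
    lfp: LfpRecording, freqs, n_cycles: float = 2.0
) -> WaveletPower:
    """Morlet wavelet power at each requested frequency.

    Power is the squared magnitude of the complex convolution of the trace
    with the kernel of :func:`morlet_kernel`. Per-frequency edge samples
    within the kernel half-width are flagged (cone of influence).
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if freqs.size == 0:
        raise ConfigError("empty frequency vector")
    if np.any(np.diff(freqs) <= 0):
        raise ConfigError("frequencies must be strictly increasing")
    if freqs[0] <= 0 or freqs[-1] >= lfp.rate / 2.0:
        raise ConfigError(
            f"frequencies must lie in (0, Nyquist={lfp.rate / 2} Hz)"
        )
    x = lfp.samples - lfp.samples.mean()
    power = np.empty((freqs.size, x.size))
    n_edge = np.empty(freqs.size, dtype=int)
    for i, f in enumerate(freqs):
        k = morlet_kernel(f, lfp.rate, n_cycles)
        conv = sps.fftconvolve(x, k, mode="same")
        power[i] = np.abs(conv) ** 2
        n_edge[i] = k.size // 2
    return WaveletPower(
        power=power, freqs=freqs, rate=lfp.rate, n_cycles=n_cycles,
        n_edge=n_edge, t0=lfp.t0,
    )
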