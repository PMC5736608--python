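"""Cross-frequency coupling: phase-binned power, weighted MRL, comodulograms,
and n:m phase-phase coupling.

The coupling statistic follows the classical weighted mean resultant length
recipe: theta phase is binned into 100 bins of pi/50 rad (3.6 deg), the mean
gamma power in each bin is used as the weight of the bin-center phasor, and

    MRL = | sum_k w_k exp(i c_k) | / sum_k w_k

ranges from 0 (power independent of phase) to 1 (all power in one bin). For
power modulated as 1 + m cos(phase - phi0), MRL = m/2 with mean direction
phi0, which anchors the analytic tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .circstats import resultant_vector
from .errors import ConfigError, InsufficientDataError
from .sigproc import (
    LfpRecording,
    PhaseSeries,
    bandpass_zero_phase,
    instantaneous_phase,
    morlet_power,
)

__all__ = [
    "N_BINS",
    "BIN_CENTERS",
    "PacResult",
    "Comodulogram",
    "PhasePhaseResult",
    "phase_binned_amplitude",
    "weighted_mrl",
    "pac",
    "surrogate_mrl",
    "comodulogram",
    "phase_phase_mrl",
]

N_BINS = 100
_BIN_WIDTH = 2.0 * np.pi / N_BINS  # pi/50
BIN_CENTERS = -np.pi + _BIN_WIDTH * (np.arange(N_BINS) + 0.5)

MIN_PAC_DURATION_S = 10.0


@dataclass
class PacResult:
    """Phase-power coupling for one (phase band, amplitude band) pair."""

    bin_centers: np.ndarray
    bin_power: np.ndarray       # mean power per bin; NaN where a bin is empty
    mrl: float
    mean_direction: float       # rad
    phase_band: tuple[float, float]
    amp_band: tuple[float, float]
    phase_region: str = ""
    amp_region: str = ""
    n_samples: int = 0
    n_empty_bins: int = 0


@dataclass
class Comodulogram:
    phase_centers: np.ndarray   # Hz
    amp_freqs: np.ndarray       # Hz
    mrl_matrix: np.ndarray      # (n_phase_centers, n_amp_freqs)
    phase_bandwidth: float = 0.5

    def argmax(self) -> tuple[float, float]:
        """(phase_center_hz, amp_freq_hz) of the strongest coupling."""
        i, j = np.unravel_index(np.nanargmax(self.mrl_matrix),
                                self.mrl_matrix.shape)
        return float(self.phase_centers[i]), float(self.amp_freqs[j])


@dataclass
class PhasePhaseResult:
    n_values: np.ndarray
    m_values: np.ndarray
    mrl_matrix: np.ndarray      # (len(n_values), len(m_values))

    def value(self, n: int, m: int) -> float:
        i = int(np.nonzero(self.n_values == n)[0][0])
        j = int(np.nonzero(self.m_values == m)[0][0])
        return float(self.mrl_matrix[i, j])


def phase_binned_amplitude(phase, power):
    """Mean power in each of 100 phase bins of width pi/50.

    Returns (bin_means, bin_counts); bins with no samples get NaN means.
    """
    phase = np.asarray(phase, dtype=float)
    power = np.asarray(power, dtype=float)
    if phase.shape != power.shape:
        raise ValueError(
            f"phase and power lengths differ: {phase.size} vs {power.size}"
        )
    if phase.size == 0:
        raise InsufficientDataError("empty phase/power series")
    idx = np.floor((phase + np.pi) / _BIN_WIDTH).astype(int)
    np.clip(idx, 0, N_BINS - 1, out=idx)  # phase == +pi lands in the last bin
    counts = np.bincount(idx, minlength=N_BINS)
    sums = np.bincount(idx, weights=power, minlength=N_BINS)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def weighted_mrl(bin_power, bin_centers=None) -> tuple[float, float]:
    """Power-weighted mean resultant length over the phase-bin centers.

    NaN entries (empty bins) are ignored. Raises when every usable weight is
    zero.
    """
    w = np.asarray(bin_power, dtype=float)
    c = BIN_CENTERS if bin_centers is None else np.asarray(bin_centers, float)
    if w.shape != c.shape:
        raise ValueError("bin_power and bin_centers must align")
    ok = np.isfinite(w)
    if not ok.any() or w[ok].sum() <= 0:
        raise InsufficientDataError("all phase-bin weights are zero or empty")
    z = resultant_vector(c[ok], w[ok])
    return float(abs(z)), float(np.angle(z))


def _epoch_mask(n: int, rate: float, t0: float, epochs) -> np.ndarray:
    """Boolean sample mask for a list of [t_start, t_end) intervals."""
    if epochs is None:
        return np.ones(n, dtype=bool)
    mask = np.zeros(n, dtype=bool)
    for t_start, t_end in epochs:
        i0 = max(int(np.ceil((t_start - t0) * rate)), 0)
        i1 = min(int(np.ceil((t_end - t0) * rate)), n)
        if i1 > i0:
            mask[i0:i1] = True
    return mask


def _pac_from_samples(phase, power, phase_band, amp_band,
                      phase_region="", amp_region="") -> PacResult:
    means, counts = phase_binned_amplitude(phase, power)
    mrl, direction = weighted_mrl(means)
    return PacResult(
        bin_centers=BIN_CENTERS.copy(), bin_power=means, mrl=mrl,
        mean_direction=direction, phase_band=tuple(phase_band),
        amp_band=tuple(amp_band), phase_region=phase_region,
        amp_region=amp_region, n_samples=int(phase.size),
        n_empty_bins=int((counts == 0).sum()),
    )


def pac(
    phase_lfp: LfpRecording,
    amp_lfp: LfpRecording,
    phase_band: tuple[float, float] = (4.0, 12.0),
    amp_band: tuple[float, float] = (30.0, 70.0),
    epochs=None,
    min_duration: float = MIN_PAC_DURATION_S,
    amp_freq_step: float = 1.0,
    power_method: str = "wavelet",
) -> PacResult:
    """Theta-phase -> gamma-power coupling between two recordings.

    Phase comes from a zero-phase bandpass of ``phase_lfp`` plus the Hilbert
    transform; amplitude-band power is the mean Morlet power across the
    1-Hz-spaced frequencies inside ``amp_band`` of ``amp_lfp`` (or, with
    ``power_method="hilbert"``, the squared Hilbert envelope of the
    bandpassed trace). Epochs (list of [t_start, t_end) in seconds) are
    concatenated before binning; filter/wavelet edge samples are excluded.
    """
    if phase_lfp.rate != amp_lfp.rate:
        raise ConfigError("phase and amplitude recordings must share a rate")
    if phase_lfp.samples.size != amp_lfp.samples.size:
        raise ConfigError("phase and amplitude recordings must be time-aligned")
    phs = instantaneous_phase(bandpass_zero_phase(phase_lfp, phase_band))
    if power_method == "wavelet":
        freqs = np.arange(amp_band[0], amp_band[1] + amp_freq_step / 2,
                          amp_freq_step)
        wav = morlet_power(amp_lfp, freqs)
        power, amp_edge = wav.band_mean(amp_band)
    elif power_method == "hilbert":
        filt = bandpass_zero_phase(amp_lfp, amp_band)
        power = np.abs(hilbert(filt.samples)) ** 2
        amp_edge = filt.n_edge
    else:
        raise ConfigError(f"unknown power_method {power_method!r}")

    n = phs.phase.size
    edge = max(phs.n_edge, int(amp_edge))
    valid = np.zeros(n, dtype=bool)
    valid[edge:n - edge] = True
    valid &= _epoch_mask(n, phase_lfp.rate, phase_lfp.t0, epochs)
    n_valid = int(valid.sum())
    if n_valid / phase_lfp.rate < min_duration:
        raise InsufficientDataError(
            f"{n_valid / phase_lfp.rate:.2f} s of usable data; a PAC estimate "
            f"requires at least {min_duration} s"
        )
    return _pac_from_samples(
        phs.phase[valid], power[valid], phase_band, amp_band,
        phase_region=phase_lfp.region, amp_region=amp_lfp.region,
    )


def surrogate_mrl(
    phase, power, rate: float, n_surrogates: int = 200,
    min_shift_s: float = 1.0, rng=None,
) -> np.ndarray:
    """Null MRL distribution from circular time shifts of power vs phase.

    Each surrogate rotates the power series by a uniform shift in
    [min_shift_s, T - min_shift_s], destroying phase-power alignment while
    preserving both marginals and autocorrelations.
    """
    phase = np.asarray(phase, float)
    power = np.asarray(power, float)
    rng = np.random.default_rng(rng)
    n = phase.size
    lo = int(min_shift_s * rate)
    hi = n - lo
    if hi <= lo:
        raise InsufficientDataError("series too short for 1-s time shifts")
    out = np.empty(n_surrogates)
    for i in range(n_surrogates):
        shift = int(rng.integers(lo, hi))
        means, _ = phase_binned_amplitude(phase, np.roll(power, shift))
        out[i] = weighted_mrl(means)[0]
    return out


def comodulogram(
    phase_lfp: LfpRecording,
    amp_lfp: LfpRecording,
    epochs=None,
    phase_centers=None,
    phase_bandwidth: float = 0.5,
    amp_freqs=None,
    min_duration: float = MIN_PAC_DURATION_S,
) -> Comodulogram:
    """MRL matrix over (low-frequency phase center) x (wavelet amp frequency).

    Phase bands are ``phase_bandwidth``-wide (default 0.5 Hz) centered at
    4-20 Hz in 0.5-Hz steps; amplitude frequencies default to 30-150 Hz in
    1-Hz steps. Narrow phase bands use a FIR with transition width of half
    the bandwidth, so roughly ``6.6 * rate / bandwidth`` taps.
    """
    if phase_centers is None:
        phase_centers = np.arange(4.0, 20.0 + 0.25, 0.5)
    else:
        phase_centers = np.asarray(phase_centers, dtype=float)
    if amp_freqs is None:
        amp_freqs = np.arange(30.0, 151.0, 1.0)
    else:
        amp_freqs = np.asarray(amp_freqs, dtype=float)
    if phase_lfp.rate != amp_lfp.rate or (
            phase_lfp.samples.size != amp_lfp.samples.size):
        raise ConfigError("recordings must be time-aligned at a common rate")

    wav = morlet_power(amp_lfp, amp_freqs)
    n = phase_lfp.samples.size
    rate = phase_lfp.rate
    numtaps = int(np.ceil(3.3 * rate / (phase_bandwidth / 2.0))) | 1
    base_mask = _epoch_mask(n, rate, phase_lfp.t0, epochs)

    matrix = np.full((phase_centers.size, amp_freqs.size), np.nan)
    for i, fc in enumerate(phase_centers):
        band = (fc - phase_bandwidth / 2.0, fc + phase_bandwidth / 2.0)
        phs = instantaneous_phase(
            bandpass_zero_phase(phase_lfp, band, numtaps=numtaps))
        for j in range(amp_freqs.size):
            edge = max(phs.n_edge, int(wav.n_edge[j]))
            valid = np.zeros(n, dtype=bool)
            valid[edge:n - edge] = True
            valid &= base_mask
            if valid.sum() / rate < min_duration:
                raise InsufficientDataError(
                    f"phase band {band}: usable data below {min_duration} s"
                )
            means, _ = phase_binned_amplitude(
                phs.phase[valid], wav.power[j][valid])
            matrix[i, j] = weighted_mrl(means)[0]
    return Comodulogram(
        phase_centers=phase_centers, amp_freqs=amp_freqs,
        mrl_matrix=matrix, phase_bandwidth=phase_bandwidth,
    )


def phase_phase_mrl(
    theta_phase: PhaseSeries,
    gamma_phase: PhaseSeries,
    n_grid=range(1, 5),
    m_grid=range(1, 17),
) -> PhasePhaseResult:
    """n:m phase-phase coupling matrix.

    Entry (n, m) is the resultant length of the wrapped per-sample
    difference n*phi_theta - m*phi_gamma; a consistent value (MRL near 1)
    indicates m cycles of the fast oscillator per n cycles of the slow one.
    """
    a = np.asarray(theta_phase.phase, float)
    b = np.asarray(gamma_phase.phase, float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("empty phase series")
    if a.size != b.size:
        raise ValueError("phase series must have equal length")
    n_values = np.asarray(list(n_grid), dtype=int)
    m_values = np.asarray(list(m_grid), dtype=int)
    za = np.exp(1j * a)
    zb = np.exp(-1j * b)
    matrix = np.empty((n_values.size, m_values.size))
    for i, nv in enumerate(n_values):
        zn = za**nv
        for j, mv in enumerate(m_values):
            matrix[i, j] = np.abs(np.mean(zn * zb**mv))
    return PhasePhaseResult(n_values=n_values, m_values=m_values,
                            mrl_matrix=matrix)
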