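"""Synthetic LFP/spike session generator with known coupling ground truth.

The generator emulates the dual-site recording geometry of a rodent working
memory experiment: a ventral-hippocampal (vHPC) trace carrying a theta
oscillation, and a medial-prefrontal (mPFC) trace carrying a lagged copy of
theta plus slow (30-70 Hz) and fast (80-120 Hz) gamma carriers whose *power*
is modulated by vHPC theta phase:

    P_gamma(t) proportional to 1 + m * cos(theta_phase(t) - preferred_phase)

i.e. the carrier envelope is ``gamma_amp * sqrt(1 + m cos(...))``. Modulating
power (rather than amplitude) with a raised cosine makes the power-weighted
mean resultant length analytically m/2, which the test suite exploits.

Spike trains are inhomogeneous Poisson processes locked to the slow-gamma
carrier phase with von Mises intensity, so the mean rate stays at the
baseline regardless of the concentration kappa.

Everything is driven by a single ``numpy.random.default_rng`` seed; identical
(config, seed) pairs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import special

from .errors import ConfigError
from .sigproc import LfpRecording, PhaseSeries
from .circstats import wrap_angle

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "gen_lfp_pair",
    "gen_spike_trains",
    "gen_session",
]


@dataclass
class SyntheticConfig:
    """Generative parameters of a synthetic session.

    Defaults describe the study conditions the pipeline is built for: 8-Hz
    theta, gamma bands 30-70 and 80-120 Hz, 2 kHz sampling, 20 trials of
    paired 1.5-s sample/choice center-arm epochs, pink (1/f) background
    noise, and ~80% correct performance.
    """

    f_theta: float = 8.0          # Hz
    theta_freq_jitter: float = 0.05  # fractional slow wander of theta freq;
                                     # aperiodicity lets time-shift surrogates
                                     # destroy coupling as in real recordings
    theta_amp: float = 1.0        # a.u. (interpreted as ~100 uV scale)
    slow_gamma_band: tuple[float, float] = (30.0, 70.0)
    fast_gamma_band: tuple[float, float] = (80.0, 120.0)
    mod_depth_slow: float = 0.3   # power-modulation depth, in [0, 1]
    mod_depth_fast: float = 0.3
    preferred_phase_slow: float = 0.0        # rad, 0 = theta peak
    preferred_phase_fast: float = np.pi / 2  # rad
    gamma_amp: float = 0.5        # carrier base amplitude, a.u.
    mpfc_theta_amp: float = 0.15  # mPFC theta amplitude, a.u. (weak volume-
                                  # conducted/local theta relative to vHPC)
    noise_exponent: float = 1.0   # 1/f^exponent background
    noise_amp: float = 0.1        # noise RMS, a.u.
    inter_region_theta_lag: float = 0.5  # rad, mPFC theta lags vHPC
    spike_baseline_rate: float = 5.0     # Hz
    spike_kappa: float = 1.0             # von Mises concentration
    frac_unlocked: float = 0.25          # fraction of units with kappa = 0
    n_trials: int = 20
    phase_effect: float = 0.0     # choice - sample slow-gamma depth difference
    p_correct: float = 0.8        # Bernoulli probability of a correct trial
    duration_per_epoch: float = 1.5      # s
    sample_rate: float = 2000.0   # Hz
    seed: int = 0

    def validate(self) -> None:
        for name, band in (("slow_gamma_band", self.slow_gamma_band),
                           ("fast_gamma_band", self.fast_gamma_band)):
            lo, hi = band
            if not lo < hi:
                raise ConfigError(f"{name} must be ordered low < high, got {band}")
        if self.slow_gamma_band[1] > self.fast_gamma_band[0]:
            raise ConfigError("slow and fast gamma bands must not overlap")
        for name, m in (("mod_depth_slow", self.mod_depth_slow),
                        ("mod_depth_fast", self.mod_depth_fast)):
            if not 0.0 <= m <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {m}")
        if self.sample_rate <= 2.0 * self.fast_gamma_band[1]:
            raise ConfigError(
                f"sample_rate {self.sample_rate} must exceed twice the highest "
                f"band edge ({self.fast_gamma_band[1]} Hz)"
            )
        if self.duration_per_epoch < 1.0:
            raise ConfigError("duration_per_epoch must be >= 1 s")
        if self.f_theta <= 0 or self.theta_amp < 0 or self.noise_amp < 0:
            raise ConfigError("f_theta must be positive and amplitudes nonnegative")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        if not 0.0 <= self.frac_unlocked <= 1.0:
            raise ConfigError("frac_unlocked must be in [0, 1]")
        if not 0.0 <= self.theta_freq_jitter < 0.5:
            raise ConfigError("theta_freq_jitter must be in [0, 0.5)")


@dataclass
class SyntheticGroundTruth:
    """Generative values recorded alongside each synthetic dataset."""

    config: dict
    seed: int
    # per-band scalars for a plain pair; per-epoch arrays for sessions
    depth_slow: float | np.ndarray = np.nan
    depth_fast: float = np.nan
    preferred_phase_slow: float = np.nan
    preferred_phase_fast: float = np.nan
    # spikes
    unit_psi: np.ndarray = field(default_factory=lambda: np.array([]))
    unit_kappa: np.ndarray = field(default_factory=lambda: np.array([]))
    # trials
    correct: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


def _one_over_f_noise(rng, n: int, rate: float, exponent: float, amp: float):
    """Gaussian noise spectrally shaped to 1/f^exponent, RMS = amp."""
    if amp == 0.0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x * (amp / sd) if sd > 0 else x


def _carrier_phase(rng, n: int, rate: float, f_center: float, f_theta: float):
    """Cumulative carrier phase with +/-10% frequency jitter per theta cycle.

    A piecewise-constant instantaneous frequency, redrawn once per theta
    cycle, keeps the carrier phase continuous while giving the band a
    realistic spectral width.
    """
    cycle_samples = max(int(round(rate / f_theta)), 1)
    n_cycles = n // cycle_samples + 2
    jitter = rng.uniform(-0.1, 0.1, size=n_cycles)
    centers = cycle_samples * (np.arange(n_cycles) + 0.5)
    # Linear interpolation between per-cycle draws keeps the instantaneous
    # frequency continuous (no clicks) while spreading the band.
    f_inst = np.interp(np.arange(n), centers, f_center * (1.0 + jitter))
    return 2.0 * np.pi * np.cumsum(f_inst) / rate


def _band_center(band):
    return 0.5 * (band[0] + band[1])


def gen_lfp_pair(
    config: SyntheticConfig,
    seed: int | None = None,
    duration: float | None = None,
    depth_slow_profile: np.ndarray | None = None,
):
    """Generate a (vHPC, mPFC) LFP pair with known coupling.

    vHPC = theta cosine + 1/f noise. mPFC = lagged theta + two gamma
    carriers whose power follows ``1 + m cos(theta_phase - preferred)`` +
    1/f noise. ``depth_slow_profile`` optionally replaces the scalar slow
    depth with a per-sample array (used for trial-structured sessions).

    Returns (vhpc, mpfc, truth); ``truth`` additionally carries the slow
    carrier's wrapped phase as ``truth.slow_carrier_phase`` for spike
    generation.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    if duration is None:
        duration = config.duration_per_epoch
    if not np.isfinite(duration) or duration <= 0:
        raise ConfigError(f"duration must be finite and positive, got {duration}")
    rng = np.random.default_rng(seed)
    n = int(round(duration * config.sample_rate))
    if config.theta_freq_jitter > 0:
        # Slow frequency wander: independent per-second draws, linearly
        # interpolated, so theta is narrowband but aperiodic.
        n_sec = int(np.ceil(duration)) + 2
        jit = rng.uniform(-config.theta_freq_jitter,
                          config.theta_freq_jitter, size=n_sec)
        centers = config.sample_rate * (np.arange(n_sec) + 0.5)
        f_inst = np.interp(np.arange(n), centers,
                           config.f_theta * (1.0 + jit))
        theta_phase = 2.0 * np.pi * np.cumsum(f_inst) / config.sample_rate
    else:
        t = np.arange(n) / config.sample_rate
        theta_phase = 2.0 * np.pi * config.f_theta * t

    vhpc = config.theta_amp * np.cos(theta_phase)
    vhpc = vhpc + _one_over_f_noise(rng, n, config.sample_rate,
                                    config.noise_exponent, config.noise_amp)

    mpfc = config.mpfc_theta_amp * np.cos(
        theta_phase - config.inter_region_theta_lag
    )
    if depth_slow_profile is None:
        m_slow = np.full(n, config.mod_depth_slow)
    else:
        m_slow = np.asarray(depth_slow_profile, dtype=float)
        if m_slow.shape != (n,):
            raise ConfigError("depth_slow_profile must have one entry per sample")
        if m_slow.min() < 0 or m_slow.max() > 1:
            raise ConfigError("depth profile values must be in [0, 1]")

    band_specs = [
        (config.slow_gamma_band, m_slow, config.preferred_phase_slow),
        (config.fast_gamma_band, np.full(n, config.mod_depth_fast),
         config.preferred_phase_fast),
    ]
    carrier_phases = []
    for band, depth, pref in band_specs:
        phi = _carrier_phase(rng, n, config.sample_rate,
                             _band_center(band), config.f_theta)
        carrier_phases.append(phi)
        envelope = config.gamma_amp * np.sqrt(
            1.0 + depth * np.cos(theta_phase - pref)
        )
        mpfc = mpfc + envelope * np.cos(phi)
    mpfc = mpfc + _one_over_f_noise(rng, n, config.sample_rate,
                                    config.noise_exponent, config.noise_amp)

    truth = SyntheticGroundTruth(
        config=asdict(config), seed=int(seed),
        depth_slow=(config.mod_depth_slow if depth_slow_profile is None
                    else m_slow),
        depth_fast=config.mod_depth_fast,
        preferred_phase_slow=config.preferred_phase_slow,
        preferred_phase_fast=config.preferred_phase_fast,
    )
    truth.slow_carrier_phase = PhaseSeries(
        phase=wrap_angle(carrier_phases[0]), band=config.slow_gamma_band,
        rate=config.sample_rate,
    )
    truth.theta_phase = PhaseSeries(
        phase=wrap_angle(theta_phase), band=(4.0, 12.0),
        rate=config.sample_rate,
    )
    vhpc_rec = LfpRecording(vhpc, config.sample_rate, region="vHPC")
    mpfc_rec = LfpRecording(mpfc, config.sample_rate, region="mPFC")
    return vhpc_rec, mpfc_rec, truth


def gen_spike_trains(
    config: SyntheticConfig,
    gamma_phase: PhaseSeries,
    n_units: int,
    seed: int,
):
    """Inhomogeneous Poisson units phase-locked to a gamma phase series.

    Intensity r(t) = r0 * exp(kappa cos(phase(t) - psi)) / I0(kappa), so the
    phase-averaged rate equals the baseline r0. The first
    ``round(frac_unlocked * n_units)`` units get kappa = 0 (uniform phases).
    Spikes are drawn per sample (Bernoulli with p = r dt), valid while
    r0 / rate stays well below 1.
    """
    config.validate()
    if config.spike_baseline_rate <= 0:
        raise ConfigError("spike_baseline_rate must be positive")
    from .spiketools import SpikeTrain  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    phase = gamma_phase.phase
    dt = 1.0 / gamma_phase.rate
    n_unlocked = int(round(config.frac_unlocked * n_units))
    psis = wrap_angle(rng.uniform(-np.pi, np.pi, size=n_units))
    kappas = np.full(n_units, float(config.spike_kappa))
    kappas[:n_unlocked] = 0.0

    trains = []
    for i in range(n_units):
        kappa, psi = kappas[i], psis[i]
        rate_t = (config.spike_baseline_rate
                  * np.exp(kappa * np.cos(phase - psi)) / special.i0(kappa))
        p = np.clip(rate_t * dt, 0.0, 1.0)
        idx = np.nonzero(rng.random(phase.size) < p)[0]
        times = gamma_phase.t0 + idx / gamma_phase.rate
        trains.append(SpikeTrain(
            unit_id=f"u{i:03d}", times=times,
            l_ratio=float(rng.uniform(0.01, 0.09)),
            isolation_distance=float(rng.uniform(12.0, 40.0)),
            region="mPFC", stereotrode_id=f"st{i // 2:02d}",
        ))
    truth = SyntheticGroundTruth(
        config=asdict(config), seed=int(seed),
        unit_psi=psis, unit_kappa=kappas,
    )
    return trains, truth


def gen_session(
    config: SyntheticConfig,
    seed: int,
    n_units: int = 8,
    delay_s: float = 10.0,
    light: str = "off",
    opsin: str = "none",
):
    """A trial-structured session: LFP pair, spike trains, trial table, truth.

    The session is ``2 * n_trials`` back-to-back center-arm epochs
    (sample then choice per trial) on one continuous time axis. The
    slow-gamma modulation depth is ``mod_depth_slow`` in sample epochs and
    ``mod_depth_slow + phase_effect`` (clipped to [0, 1]) in choice epochs of
    *correct* trials. Correct flags are Bernoulli(p_correct).

    Returns (lfps, spike_trains, trials, truth) where ``lfps`` maps region
    labels to recordings and ``trials`` is a DataFrame with one row per
    epoch.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n_ep = 2 * config.n_trials
    ep_len = config.duration_per_epoch
    n_per_ep = int(round(ep_len * config.sample_rate))

    correct = rng.random(config.n_trials) < config.p_correct
    depth_epochs = np.empty(n_ep)
    rows = []
    for trial in range(config.n_trials):
        for j, phase_name in enumerate(("sample", "choice")):
            k = 2 * trial + j
            depth = config.mod_depth_slow
            if phase_name == "choice" and correct[trial]:
                depth = float(np.clip(depth + config.phase_effect, 0.0, 1.0))
            depth_epochs[k] = depth
            rows.append({
                "trial_id": trial, "phase": phase_name,
                "t_start_s": k * ep_len, "t_end_s": (k + 1) * ep_len,
                "correct": bool(correct[trial]), "delay_s": delay_s,
                "light": light, "opsin": opsin,
            })
    trials = pd.DataFrame(rows)

    profile = np.repeat(depth_epochs, n_per_ep)
    lfp_seed = int(rng.integers(0, 2**31 - 1))
    spike_seed = int(rng.integers(0, 2**31 - 1))
    vhpc, mpfc, truth = gen_lfp_pair(
        config, seed=lfp_seed, duration=n_ep * ep_len,
        depth_slow_profile=profile,
    )
    trains, spike_truth = gen_spike_trains(
        config, truth.slow_carrier_phase, n_units, seed=spike_seed,
    )
    truth.unit_psi = spike_truth.unit_psi
    truth.unit_kappa = spike_truth.unit_kappa
    truth.correct = correct
    truth.depth_slow = depth_epochs
    truth.seed = int(seed)
    return {"vHPC": vhpc, "mPFC": mpfc}, trains, trials, truth
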