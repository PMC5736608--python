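"""Generator tests: determinism, construction guarantees, spectral sanity,
and spike-locking ground-truth recovery."""

import numpy as np
import pytest
from scipy import signal as sps

from thetagamma import (
    SyntheticConfig,
    gen_lfp_pair,
    gen_session,
    gen_spike_trains,
    kappa_from_r,
)
from thetagamma.circstats import circ_mean, circ_r, wrap_angle
from thetagamma.errors import ConfigError
from thetagamma.sigproc import PhaseSeries, bandpass_zero_phase, morlet_power
from thetagamma.spiketools import phase_locking


def _phase_ramp(freq, duration, rate=1000.0):
    ph = wrap_angle(2 * np.pi * freq * np.arange(int(duration * rate)) / rate)
    return PhaseSeries(ph, (30.0, 70.0), rate)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"slow_gamma_band": (70.0, 30.0)},
        {"slow_gamma_band": (30.0, 90.0)},       # overlaps fast band
        {"mod_depth_slow": 1.5},
        {"sample_rate": 200.0},                  # below 2x fast band edge
        {"duration_per_epoch": 0.2},
        {"n_trials": 0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SyntheticConfig(**kwargs).validate()


class TestLfpPair:
    def test_same_seed_is_bit_identical(self):
        config = SyntheticConfig()
        a = gen_lfp_pair(config, seed=3, duration=4.0)
        b = gen_lfp_pair(config, seed=3, duration=4.0)
        assert a[0].samples.tobytes() == b[0].samples.tobytes()
        assert a[1].samples.tobytes() == b[1].samples.tobytes()
        c = gen_lfp_pair(config, seed=4, duration=4.0)
        assert a[1].samples.tobytes() != c[1].samples.tobytes()

    def test_zero_modulation_gives_flat_envelope(self):
        """With m=0 and no noise, the slow-gamma envelope is constant over
        theta phase (no residual modulation above a few percent)."""
        config = SyntheticConfig(mod_depth_slow=0.0, mod_depth_fast=0.0,
                                 noise_amp=0.0)
        _, mpfc, _ = gen_lfp_pair(config, seed=1, duration=20.0)
        filt = bandpass_zero_phase(mpfc, config.slow_gamma_band)
        sl = filt.valid_slice()
        env = np.abs(sps.hilbert(filt.samples))[sl]
        assert env.std() / env.mean() < 0.1

    def test_full_modulation_envelope_peaks_at_theta_peak(self):
        config = SyntheticConfig(mod_depth_slow=1.0, preferred_phase_slow=0.0,
                                 mod_depth_fast=0.0, noise_amp=0.0)
        _, mpfc, truth = gen_lfp_pair(config, seed=1, duration=20.0)
        theta_phase = truth.theta_phase.phase
        filt = bandpass_zero_phase(mpfc, config.slow_gamma_band)
        sl = filt.valid_slice()
        env = np.abs(sps.hilbert(filt.samples))[sl]
        ph = theta_phase[sl]
        near_peak = env[np.abs(ph) < 0.3].mean()
        near_trough = env[np.abs(ph) > np.pi - 0.3].mean()
        assert near_peak > 3.0 * near_trough

    def test_vhpc_wavelet_argmax_at_theta(self):
        config = SyntheticConfig(noise_amp=0.0)
        vhpc, _, _ = gen_lfp_pair(config, seed=2, duration=10.0)
        freqs = np.arange(1.0, 151.0, 1.0)
        wav = morlet_power(vhpc, freqs)
        profile = wav.power[:, 4000:-4000].mean(axis=1)
        assert abs(freqs[int(np.argmax(profile))] - config.f_theta) <= 1.0


class TestSpikeTrains:
    def test_unlocked_units_have_uniform_phases(self):
        """kappa=0 units fail the Rayleigh test at roughly the nominal rate."""
        config = SyntheticConfig(spike_baseline_rate=20.0, spike_kappa=0.0,
                                 frac_unlocked=1.0)
        phase = _phase_ramp(50.0, 60.0)
        n_reject = 0
        n_units = 40
        trains, _ = gen_spike_trains(config, phase, n_units, seed=11)
        for tr in trains:
            if phase_locking(tr, phase).rayleigh_p < 0.05:
                n_reject += 1
        assert n_reject <= 7  # ~alpha * 40 = 2 expected; generous binomial bound

    def test_locked_unit_phase_recovery(self):
        config = SyntheticConfig(spike_baseline_rate=50.0, spike_kappa=4.0,
                                 frac_unlocked=0.0)
        phase = _phase_ramp(50.0, 200.0)
        trains, truth = gen_spike_trains(config, phase, 2, seed=5)
        for tr, psi in zip(trains, truth.unit_psi):
            phases = phase.at_times(tr.times)
            assert tr.n_spikes > 5000
            err = np.degrees(abs(wrap_angle(circ_mean(phases) - psi)))
            assert err < 5.0

    @pytest.mark.parametrize("kappa", [1.0, 2.0, 4.0])
    def test_locking_concentration_recovery(self, kappa):
        """Estimated kappa (MRL inversion) within 20% of truth at ~1e4 spikes."""
        config = SyntheticConfig(spike_baseline_rate=50.0, spike_kappa=kappa,
                                 frac_unlocked=0.0)
        phase = _phase_ramp(50.0, 200.0)
        trains, truth = gen_spike_trains(config, phase, 1, seed=int(kappa * 10))
        phases = phase.at_times(trains[0].times)
        est = kappa_from_r(circ_r(phases))
        assert abs(est - kappa) / kappa < 0.2

    def test_mean_rate_is_poisson_baseline(self):
        config = SyntheticConfig(spike_baseline_rate=10.0, spike_kappa=2.0,
                                 frac_unlocked=0.0)
        phase = _phase_ramp(50.0, 100.0)
        trains, _ = gen_spike_trains(config, phase, 1, seed=3)
        n = trains[0].n_spikes
        assert abs(n - 1000) < 4 * np.sqrt(1000)

    def test_nonpositive_rate_rejected(self):
        config = SyntheticConfig(spike_baseline_rate=-1.0)
        with pytest.raises(ConfigError):
            gen_spike_trains(config, _phase_ramp(50.0, 2.0), 1, seed=0)


class TestSession:
    def test_trial_table_bookkeeping(self):
        config = SyntheticConfig(n_trials=20, sample_rate=1000.0)
        _, _, trials, _ = gen_session(config, seed=9)
        assert len(trials) == 40
        assert set(trials["phase"]) == {"sample", "choice"}
        assert (trials.groupby("trial_id")["phase"].count() == 2).all()
        assert (trials["t_start_s"] < trials["t_end_s"]).all()

    def test_zero_phase_effect_keeps_depths_equal(self):
        config = SyntheticConfig(phase_effect=0.0, sample_rate=1000.0)
        _, _, _, truth = gen_session(config, seed=9)
        assert np.unique(truth.depth_slow).size == 1

    def test_phase_effect_raises_correct_choice_depth(self):
        config = SyntheticConfig(phase_effect=0.2, sample_rate=1000.0,
                                 n_trials=10)
        _, _, trials, truth = gen_session(config, seed=9)
        choice = trials["phase"] == "choice"
        correct = trials["correct"]
        boosted = truth.depth_slow[(choice & correct).to_numpy()]
        base = truth.depth_slow[(~choice | ~correct).to_numpy()]
        assert np.allclose(boosted, config.mod_depth_slow + 0.2)
        assert np.allclose(base, config.mod_depth_slow)

    def test_session_determinism(self):
        config = SyntheticConfig(n_trials=4, sample_rate=1000.0)
        a = gen_session(config, seed=1)
        b = gen_session(config, seed=1)
        assert a[0]["mPFC"].samples.tobytes() == b[0]["mPFC"].samples.tobytes()
        assert all(x.times.tobytes() == y.times.tobytes()
                   for x, y in zip(a[1], b[1]))
        assert a[2].equals(b[2])
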