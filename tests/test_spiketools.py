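"""Spike-tool tests: quality gating, phase locking, CCG analytics, and the
firing-rate-versus-coupling quartile analysis."""

import numpy as np
import pytest

from thetagamma.circstats import wrap_angle
from thetagamma.errors import ConfigError, InsufficientDataError
from thetagamma.sigproc import PhaseSeries
from thetagamma.spiketools import (
    SpikeTrain,
    ccg,
    filter_units,
    firing_vs_coupling_quartiles,
    phase_locking,
)


def _unit(uid, times, l_ratio=0.05, iso=20.0, stereo=""):
    return SpikeTrain(uid, np.asarray(times, float), l_ratio, iso,
                      stereotrode_id=stereo)


class TestFilterUnits:
    def test_boundary_values_kept(self):
        kept, report = filter_units([_unit("a", [1.0], l_ratio=0.1, iso=10.0)])
        assert len(kept) == 1
        assert report.loc[0, "kept"]

    def test_violations_reported_by_criterion(self):
        units = [
            _unit("bad_l", [1.0], l_ratio=0.2, iso=50.0),
            _unit("bad_iso", [1.0], l_ratio=0.05, iso=5.0),
            _unit("good", [1.0]),
        ]
        kept, report = filter_units(units)
        assert [u.unit_id for u in kept] == ["good"]
        assert report.set_index("unit_id").loc["bad_l", "reason"] == "l_ratio"
        assert (report.set_index("unit_id").loc["bad_iso", "reason"]
                == "isolation_distance")

    def test_missing_metric_excluded_not_kept(self):
        u = SpikeTrain("m", np.array([1.0]), l_ratio=None,
                       isolation_distance=20.0)
        kept, report = filter_units([u])
        assert not kept
        assert report.loc[0, "reason"] == "missing"

    def test_bookkeeping_counts(self, rng):
        units = [_unit(f"u{i}", [1.0]) for i in range(7)]
        units += [_unit(f"v{i}", [1.0], l_ratio=0.5) for i in range(3)]
        kept, report = filter_units(units)
        assert len(kept) == 7
        assert (~report["kept"]).sum() == 3


class TestPhaseLocking:
    def _ramp(self, freq=50.0, duration=60.0, rate=1000.0):
        ph = wrap_angle(2 * np.pi * freq * np.arange(int(duration * rate)) / rate)
        return PhaseSeries(ph, (30.0, 70.0), rate)

    def test_point_mass_spikes(self):
        phase = self._ramp()
        times = 1.0 + 0.02 * np.arange(50)  # carrier period -> same phase
        pl = phase_locking(_unit("p", times), phase)
        assert pl.mrl > 0.999
        assert pl.rayleigh_p < 1e-6
        assert pl.locked

    def test_too_few_spikes_flagged(self):
        phase = self._ramp(duration=5.0)
        with pytest.raises(InsufficientDataError):
            phase_locking(_unit("few", [1.0, 2.0]), phase)

    def test_uniform_type_one_error(self, rng):
        """Uniformly firing units trip the Rayleigh test near the alpha rate."""
        phase = self._ramp(duration=20.0)
        n_reject = 0
        n_units = 300
        for _ in range(n_units):
            times = np.sort(rng.uniform(0.5, 19.5, size=100))
            if phase_locking(_unit("x", times), phase).rayleigh_p < 0.05:
                n_reject += 1
        assert 0.02 <= n_reject / n_units <= 0.10


class TestCcg:
    def test_identical_trains_scalar_is_one(self):
        times = np.arange(0.5, 99.5, 0.1)  # ISIs 100 ms >> 1 ms
        c = ccg(_unit("a", times), _unit("b", times.copy()), T=100.0)
        assert c.scalar_ccg == 1.0
        assert c.C12 == times.size

    def test_shifted_train_moves_the_peak(self, rng):
        # Irregular ISIs (>= 60 ms) so only the +5 ms lag repeats.
        times = np.cumsum(rng.uniform(0.06, 0.2, 800))
        times = times[times < 99.0]
        c = ccg(_unit("a", times), _unit("b", times + 0.005), T=100.0)
        assert c.scalar_ccg == 0.0
        peak_lag = c.lags_ms[int(np.argmax(c.values))]
        assert abs(peak_lag - 5.0) <= 0.5

    def test_c12_matches_bruteforce_double_loop(self, rng):
        t1 = np.sort(rng.uniform(0, 20, 400))
        t2 = np.sort(rng.uniform(0, 20, 300))
        c = ccg(_unit("a", t1), _unit("b", t2), T=20.0)
        brute = sum(abs(x - y) <= 1e-3 for x in t1 for y in t2)
        assert c.C12 == brute

    def test_symmetry_and_mirrored_lags(self, rng):
        t1 = np.sort(rng.uniform(0, 50, 1000))
        t2 = np.sort(rng.uniform(0, 50, 800))
        ab = ccg(_unit("a", t1), _unit("b", t2), T=50.0)
        ba = ccg(_unit("b", t2), _unit("a", t1), T=50.0)
        assert ab.scalar_ccg == ba.scalar_ccg
        np.testing.assert_allclose(ab.values, ba.values[::-1])

    def test_independent_poisson_expectation(self, rng):
        """Independent 10-Hz trains give E[CCG] = 0.002 sqrt(f1 f2) = 0.02."""
        vals = [
            ccg(_unit("a", np.sort(rng.uniform(0, 500, 5000))),
                _unit("b", np.sort(rng.uniform(0, 500, 5000))), T=500.0
                ).scalar_ccg
            for _ in range(20)
        ]
        assert np.mean(vals) == pytest.approx(0.02, abs=0.003)

    def test_geometric_mean_normalization_softens_rate_dependence(self, rng):
        """Common thinning of perfectly synchronous trains leaves the scalar
        at 1 (rate cancels exactly); for independent Poisson trains the
        normalized statistic scales as sqrt(f1 f2) where the raw coincidence
        count scales as f1 f2."""
        base = np.arange(0.5, 199.5, 0.05)
        keep = rng.random(base.size) < 0.5
        common = base[keep]
        c = ccg(_unit("a", common), _unit("b", common.copy()), T=200.0)
        assert c.scalar_ccg == 1.0

        full_s, full_c, thin_s, thin_c = [], [], [], []
        for _ in range(30):
            t1 = np.sort(rng.uniform(0, 200, 4000))
            t2 = np.sort(rng.uniform(0, 200, 4000))
            cf = ccg(_unit("a", t1), _unit("b", t2), T=200.0)
            k1 = t1[rng.random(t1.size) < 0.5]
            k2 = t2[rng.random(t2.size) < 0.5]
            ct = ccg(_unit("a", k1), _unit("b", k2), T=200.0)
            full_s.append(cf.scalar_ccg); full_c.append(cf.C12)
            thin_s.append(ct.scalar_ccg); thin_c.append(ct.C12)
        assert np.mean(thin_c) == pytest.approx(np.mean(full_c) / 4, rel=0.15)
        assert np.mean(thin_s) == pytest.approx(np.mean(full_s) / 2, rel=0.15)

    def test_same_unit_and_empty_train_rejected(self):
        t = np.array([1.0, 2.0])
        with pytest.raises(ConfigError):
            ccg(_unit("a", t), _unit("a", t), T=10.0)
        with pytest.raises(InsufficientDataError):
            ccg(_unit("a", t), _unit("b", []), T=10.0)

    def test_same_stereotrode_pairs_refused_by_default(self):
        a = _unit("a", [1.0, 2.0], stereo="st01")
        b = _unit("b", [1.5, 2.5], stereo="st01")
        with pytest.raises(ConfigError):
            ccg(a, b, T=10.0)
        assert ccg(a, b, T=10.0, allow_same_stereotrode=True).C12 == 0


class TestQuartiles:
    def _simulate(self, rng, slope, n_epochs=40, n_units=12, n_animals=3,
                  noise=1.0):
        couplings = rng.uniform(0.05, 0.35, n_epochs)
        rates = (5.0 + slope * couplings[None, :]
                 + noise * rng.standard_normal((n_units, n_epochs)))
        animals = [f"m{i % n_animals}" for i in range(n_units)]
        return couplings, np.clip(rates, 0.01, None), animals

    def test_constant_rates_give_zero_slope(self):
        couplings = np.linspace(0.1, 0.3, 16)
        rates = np.full((4, 16), 7.0)
        res = firing_vs_coupling_quartiles(couplings, rates,
                                           ["a", "a", "b", "b"])
        np.testing.assert_allclose(res.quartile_mean_z, 0.0)
        assert res.slope == 0.0

    def test_positive_link_recovered_across_seeds(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            c, r, a = self._simulate(rng, slope=20.0)
            res = firing_vs_coupling_quartiles(c, r, a)
            hits += res.slope > 0
        assert hits >= 19

    def test_null_link_ci_covers_zero(self):
        covered = 0
        n_sims = 200
        for seed in range(n_sims):
            rng = np.random.default_rng(10_000 + seed)
            c, r, a = self._simulate(rng, slope=0.0)
            res = firing_vs_coupling_quartiles(c, r, a)
            covered += res.slope_ci[0] <= 0.0 <= res.slope_ci[1]
        assert 0.90 <= covered / n_sims <= 0.99

    def test_quartile_labels_balanced(self, rng):
        c, r, a = self._simulate(rng, slope=0.0, n_epochs=40)
        res = firing_vs_coupling_quartiles(c, r, a)
        counts = np.bincount(res.epoch_quartiles - 1)
        assert np.all(counts == 10)

    def test_degenerate_couplings_rejected(self):
        rates = np.ones((2, 12))
        with pytest.raises(InsufficientDataError):
            firing_vs_coupling_quartiles(np.full(12, 0.2), rates, ["a", "a"])
        with pytest.raises(InsufficientDataError):
            firing_vs_coupling_quartiles(np.arange(6), np.ones((2, 6)),
                                         ["a", "a"])
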