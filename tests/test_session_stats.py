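"""Session-statistics tests: epoch selection and pooling, parametric and
circular tests, the accuracy correlation, and the end-to-end pipeline."""

import json

import numpy as np
import pandas as pd
import pytest

from thetagamma import (
    SyntheticConfig,
    accuracy_correlation,
    anova_two_way,
    gen_session,
    paired_t,
    run_pipeline,
    unpaired_t,
)
from thetagamma.errors import ConfigError, InsufficientDataError
from thetagamma.io import save_session
from thetagamma.session_stats import (
    epoch_coupling_series,
    prepare_coupling_signals,
    select_epochs,
)


@pytest.fixture(scope="module")
def session():
    config = SyntheticConfig(phase_effect=0.2, sample_rate=1000.0)
    return config, gen_session(config, seed=42)


@pytest.fixture(scope="module")
def signals(session):
    config, (lfps, _, _, _) = session
    return prepare_coupling_signals(lfps["vHPC"], lfps["mPFC"],
                                    (4.0, 12.0), config.slow_gamma_band)


class TestEpochSelection:
    def test_single_trial_contributes_one_epoch_per_phase(self, session,
                                                          signals):
        _, (_, _, trials, _) = session
        one = trials[trials["trial_id"] == 3]
        assert len(one) == 2
        picked = select_epochs(trials, {"trial_id": 3, "phase": "sample"})
        assert len(picked) == 1

    def test_empty_selector_error_names_selector(self, session):
        _, (_, _, trials, _) = session
        with pytest.raises(InsufficientDataError, match="left_arm"):
            select_epochs(trials, {"phase": "left_arm"})

    def test_all_incorrect_session_correct_selector_fails(self, session,
                                                          signals):
        _, (_, _, trials, _) = session
        sad = trials.copy()
        sad["correct"] = False
        with pytest.raises(InsufficientDataError):
            epoch_coupling_series(signals, sad,
                                  {"phase": "choice", "correct": True})

    def test_pooled_epochs_and_per_epoch_values(self, session, signals):
        _, (_, _, trials, _) = session
        ec = epoch_coupling_series(signals, trials, {"phase": "sample"})
        assert ec.n_epochs_used == 20
        assert len(ec.per_epoch) == 20
        assert 0.0 <= ec.pooled.mrl <= 1.0
        assert np.all((ec.per_epoch["mrl"] >= 0) & (ec.per_epoch["mrl"] <= 1))


class TestParametricTests:
    def test_identical_paired_vectors(self):
        t, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_paired_t_matches_closed_form(self, rng):
        """t = mean(d) sqrt(n) / sd(d) for the paired differences d."""
        a = rng.normal(0, 1, 30)
        d = 0.7 + 0.3 * rng.standard_normal(30)
        t, p = paired_t(a + d, a)
        expected = d.mean() * np.sqrt(30) / d.std(ddof=1)
        assert t == pytest.approx(expected, rel=1e-10)

    def test_unpaired_t_basic(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(2, 1, 40)
        t, p = unpaired_t(a, b)
        assert t < 0 and p < 1e-6

    def test_additive_design_has_no_interaction(self):
        rows = []
        for la, ea in (("off", 0.0), ("on", 1.0)):
            for lb, eb in (("ctrl", 0.0), ("arch", 2.0)):
                for r in range(5):
                    rows.append({"light": la, "opsin": lb,
                                 "y": 1.0 + ea + eb + 0.001 * r})
        out = anova_two_way(pd.DataFrame(rows), "y", "light", "opsin")
        assert out["light:opsin"]["F"] == pytest.approx(0.0, abs=1e-6)
        assert out["light"]["p"] < 1e-6

    def test_balanced_anova_sums_of_squares_decompose(self, rng):
        rows = []
        for la in ("off", "on"):
            for lb in ("ctrl", "arch"):
                for _ in range(6):
                    rows.append({"light": la, "opsin": lb,
                                 "y": rng.standard_normal()})
        df = pd.DataFrame(rows)
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        fit = smf.ols("y ~ C(light) * C(opsin)", data=df).fit()
        tab = anova_lm(fit, typ=2)
        ss_total = ((df["y"] - df["y"].mean()) ** 2).sum()
        assert tab["sum_sq"].sum() == pytest.approx(ss_total, rel=1e-9)

    def test_small_cells_rejected(self):
        df = pd.DataFrame({"a": ["x", "x", "y"], "b": ["u", "v", "u"],
                           "y": [1.0, 2.0, 3.0]})
        with pytest.raises((InsufficientDataError, ConfigError)):
            anova_two_way(df, "y", "a", "b")


class TestAccuracyCorrelation:
    def test_perfect_linear_relation(self):
        x = np.linspace(0.1, 0.3, 8)
        y = np.linspace(0.5, 0.9, 8)
        res = accuracy_correlation(x, y, ["a"] * 4 + ["b"] * 4)
        assert res.r_session == pytest.approx(1.0)

    def test_constant_accuracy_rejected(self):
        with pytest.raises(InsufficientDataError):
            accuracy_correlation([0.1, 0.2, 0.3], [0.8, 0.8, 0.8],
                                 ["a", "a", "b"])

    def test_sampling_interval_coverage_at_moderate_n(self, rng):
        """r-hat falls inside the Fisher 95% sampling interval of the true
        rho = -0.45 in ~95% of draws at n = 33 sessions."""
        rho, n, sims = -0.45, 33, 500
        z = np.arctanh(rho)
        half = 1.96 / np.sqrt(n - 3)
        covered = 0
        for _ in range(sims):
            x = rng.standard_normal(n)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            acc = 0.5 + 0.1 * (y - y.min()) / (np.ptp(y) + 1e-9)
            res = accuracy_correlation(x, acc, ["a"] * 17 + ["b"] * 16)
            covered += abs(np.arctanh(res.r_session) - z) <= half
        assert covered / sims >= 0.93


class TestPipeline:
    @pytest.fixture(scope="class")
    def session_dirs(self, tmp_path_factory):
        root = tmp_path_factory.mktemp("sessions")
        config = SyntheticConfig(phase_effect=0.25, sample_rate=1000.0)
        dirs = []
        for s in range(3):
            data = gen_session(config, seed=500 + s)
            d = root / f"sess{s}"
            save_session(d, *data)
            dirs.append(d)
        return dirs

    def test_report_structure_and_effect_direction(self, session_dirs,
                                                   tmp_path):
        report = run_pipeline(session_dirs, out_dir=tmp_path)
        assert set(report["sessions"]) == {"sess0", "sess1", "sess2"}
        group = report["group"]["choice_vs_sample_correct"]
        assert group["mean_diff"] > 0
        for sess in report["sessions"].values():
            conds = sess["conditions"]
            assert conds["choice_correct"]["mrl"] > conds["sample_correct"]["mrl"]
            assert sess["n_epochs_total"] == 40

    def test_report_is_deterministic(self, session_dirs, tmp_path):
        r1 = run_pipeline(session_dirs, out_dir=tmp_path / "a")
        r2 = run_pipeline(session_dirs, out_dir=tmp_path / "b")
        b1 = (tmp_path / "a" / "report.json").read_bytes()
        b2 = (tmp_path / "b" / "report.json").read_bytes()
        assert b1 == b2
        assert json.loads(b1)["sessions"].keys() == r1["sessions"].keys()
        assert r1 == r2

    def test_missing_choice_rows_raise(self, session_dirs, tmp_path):
        import shutil
        broken = tmp_path / "broken"
        shutil.copytree(session_dirs[0], broken)
        trials = pd.read_csv(broken / "trials.csv")
        trials = trials[trials["phase"] == "sample"]
        trials.to_csv(broken / "trials.csv", index=False)
        with pytest.raises(InsufficientDataError, match="choice"):
            run_pipeline([broken])
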