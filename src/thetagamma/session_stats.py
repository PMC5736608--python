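"""Trial/epoch orchestration and behavior-linked session statistics.

This module turns a trial table plus the dual-site LFPs into per-condition
coupling estimates and the group-level tests used to relate coupling to
behavior: sample-vs-choice paired contrasts, session-accuracy correlations
(with animal-indicator regression for repeated measures), delay and
light-by-opsin condition contrasts, and the circular group tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from . import __version__ as _pkg_version
from .cfc import MIN_PAC_DURATION_S, PacResult, _pac_from_samples, pac
from .circstats import rayleigh_test, watson_williams_test  # noqa: F401 (re-export)
from .errors import ConfigError, InsufficientDataError
from .gammapeaks import detect_peaks, peak_phase_histogram
from .io import load_session
from .sigproc import (
    LfpRecording,
    bandpass_zero_phase,
    instantaneous_phase,
    morlet_power,
)
from .spiketools import filter_units, phase_locking

__all__ = [
    "EpochCoupling",
    "AccuracyCorrelation",
    "select_epochs",
    "epoch_coupling_series",
    "paired_t",
    "unpaired_t",
    "anova_two_way",
    "paired_and_group_tests",
    "accuracy_correlation",
    "rayleigh_test",
    "watson_williams_test",
    "run_pipeline",
]

MIN_EPOCH_S = 0.5


@dataclass
class EpochCoupling:
    """Pooled PAC for one condition plus per-epoch values for paired tests."""

    pooled: PacResult
    per_epoch: pd.DataFrame     # trial_id, phase, t_start_s, t_end_s, mrl, ...
    n_epochs_used: int
    n_epochs_dropped: int
    selector: str


@dataclass
class AccuracyCorrelation:
    r_session: float
    p_session: float
    r_animal: float | None
    p_animal: float | None
    regression_p: float | None  # coupling coefficient p with animal indicators
    n_sessions: int
    n_animals: int


def select_epochs(trials: pd.DataFrame, selector) -> pd.DataFrame:
    """Rows of the trial table matching ``selector``.

    ``selector`` is either a mapping of column -> required value (e.g.
    ``{"phase": "choice", "correct": True}``) or a callable returning a
    boolean mask. Raises naming the selector when nothing matches.
    """
    if callable(selector):
        mask = np.asarray(selector(trials), dtype=bool)
        label = getattr(selector, "__name__", "callable")
    else:
        mask = np.ones(len(trials), dtype=bool)
        for col, val in selector.items():
            mask &= (trials[col] == val).to_numpy()
        label = str(selector)
    picked = trials.loc[mask]
    if picked.empty:
        raise InsufficientDataError(f"no epochs match selector {label}")
    return picked


def prepare_coupling_signals(
    phase_lfp: LfpRecording, amp_lfp: LfpRecording,
    phase_band=(4.0, 12.0), amp_band=(30.0, 70.0), amp_freq_step: float = 1.0,
):
    """Precompute the phase series and band power shared by all conditions."""
    if phase_lfp.rate != amp_lfp.rate or (
            phase_lfp.samples.size != amp_lfp.samples.size):
        raise ConfigError("recordings must be time-aligned at a common rate")
    phs = instantaneous_phase(bandpass_zero_phase(phase_lfp, phase_band))
    freqs = np.arange(amp_band[0], amp_band[1] + amp_freq_step / 2,
                      amp_freq_step)
    power, amp_edge = morlet_power(amp_lfp, freqs).band_mean(amp_band)
    edge = max(phs.n_edge, int(amp_edge))
    return {
        "phase": phs.phase, "power": power, "edge": edge,
        "rate": phase_lfp.rate, "t0": phase_lfp.t0,
        "phase_band": tuple(phase_band), "amp_band": tuple(amp_band),
        "phase_region": phase_lfp.region, "amp_region": amp_lfp.region,
    }


def epoch_coupling_series(
    signals: dict, trials: pd.DataFrame, selector,
    min_epoch_s: float = MIN_EPOCH_S, min_total_s: float = MIN_PAC_DURATION_S,
) -> EpochCoupling:
    """Pooled + per-epoch coupling for the epochs picked by ``selector``.

    Samples of all selected epochs are concatenated for the pooled estimate
    (which must clear the minimum PAC duration); each epoch additionally
    gets its own MRL for paired statistics. Epochs shorter than
    ``min_epoch_s`` are dropped and counted.
    """
    picked = select_epochs(trials, selector)
    rate, t0, edge = signals["rate"], signals["t0"], signals["edge"]
    phase, power = signals["phase"], signals["power"]
    n = phase.size

    rows, phases_cat, powers_cat = [], [], []
    n_dropped = 0
    for _, row in picked.iterrows():
        if row["t_end_s"] - row["t_start_s"] < min_epoch_s:
            n_dropped += 1
            continue
        i0 = max(int(np.ceil((row["t_start_s"] - t0) * rate)), edge)
        i1 = min(int(np.ceil((row["t_end_s"] - t0) * rate)), n - edge)
        if i1 <= i0:
            n_dropped += 1
            continue
        seg_phase, seg_power = phase[i0:i1], power[i0:i1]
        res = _pac_from_samples(seg_phase, seg_power,
                                signals["phase_band"], signals["amp_band"])
        rows.append({
            "trial_id": row["trial_id"], "phase": row["phase"],
            "t_start_s": row["t_start_s"], "t_end_s": row["t_end_s"],
            "mrl": res.mrl, "mean_direction": res.mean_direction,
            "n_samples": res.n_samples,
        })
        phases_cat.append(seg_phase)
        powers_cat.append(seg_power)
    if not rows:
        raise InsufficientDataError(
            f"all epochs for selector {selector} were shorter than "
            f"{min_epoch_s} s")
    pooled_phase = np.concatenate(phases_cat)
    if pooled_phase.size / rate < min_total_s:
        raise InsufficientDataError(
            f"{pooled_phase.size / rate:.2f} s pooled for selector {selector}; "
            f"PAC requires >= {min_total_s} s")
    pooled = _pac_from_samples(
        pooled_phase, np.concatenate(powers_cat),
        signals["phase_band"], signals["amp_band"],
        phase_region=signals["phase_region"], amp_region=signals["amp_region"],
    )
    return EpochCoupling(
        pooled=pooled, per_epoch=pd.DataFrame(rows),
        n_epochs_used=len(rows), n_epochs_dropped=n_dropped,
        selector=str(selector),
    )


def paired_t(values_a, values_b) -> tuple[float, float]:
    """Paired t-test; identical vectors give (0, 1) rather than NaN."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    if a.size < 2:
        raise InsufficientDataError("paired t-test needs n >= 2")
    d = a - b
    if np.allclose(d, d[0]) and np.isclose(d[0], 0.0):
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def unpaired_t(values_a, values_b) -> tuple[float, float]:
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("unpaired t-test needs n >= 2 per group")
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


def anova_two_way(table: pd.DataFrame, dv: str, factor_a: str, factor_b: str):
    """Two-way ANOVA (main effects + interaction), Type II sums of squares.

    Type II is exact for balanced designs and remains well-defined for the
    mildly unbalanced trial counts produced by behavior. Returns a dict
    keyed by effect name with (F, p, df_num, df_den).
    """
    for factor in (factor_a, factor_b):
        if table[factor].nunique() < 2:
            raise ConfigError(f"factor {factor} needs >= 2 levels")
    counts = table.groupby([factor_a, factor_b], observed=True)[dv].count()
    if (counts < 2).any():
        raise InsufficientDataError("each design cell needs n >= 2")
    model = smf.ols(
        f"{dv} ~ C({factor_a}) * C({factor_b})", data=table).fit()
    tab = anova_lm(model, typ=2)
    df_den = float(tab.loc["Residual", "df"])
    out = {}
    for name, label in ((f"C({factor_a})", factor_a),
                        (f"C({factor_b})", factor_b),
                        (f"C({factor_a}):C({factor_b})",
                         f"{factor_a}:{factor_b}")):
        out[label] = {
            "F": float(tab.loc[name, "F"]), "p": float(tab.loc[name, "PR(>F)"]),
            "df_num": float(tab.loc[name, "df"]), "df_den": df_den,
        }
    return out


def paired_and_group_tests(values_a=None, values_b=None, design="paired",
                           table=None, dv=None, factors=None):
    """Dispatch to the paired t, unpaired t, or two-way ANOVA."""
    if design == "paired":
        return paired_t(values_a, values_b)
    if design == "unpaired":
        return unpaired_t(values_a, values_b)
    if design == "two_way":
        return anova_two_way(table, dv, *factors)
    raise ConfigError(f"unknown design {design!r}")


def accuracy_correlation(
    session_couplings, session_accuracies, animal_ids,
) -> AccuracyCorrelation:
    """Correlation between per-session coupling strength and choice accuracy.

    Session-level: plain Pearson r over sessions. Animal-level: Pearson r of
    per-animal means (when >= 3 animals). With several sessions per animal
    the honest p-value comes from an OLS of accuracy on coupling with animal
    indicator covariates, reported as ``regression_p``.
    """
    x = np.asarray(session_couplings, float)
    y = np.asarray(session_accuracies, float)
    animals = np.asarray(animal_ids)
    if x.size != y.size or x.size != animals.size:
        raise ValueError("inputs must align per session")
    if x.size < 3:
        raise InsufficientDataError("need >= 3 sessions")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("accuracies must lie in [0, 1]")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InsufficientDataError("zero variance in coupling or accuracy")
    r, p = stats.pearsonr(x, y)

    df = pd.DataFrame({"coupling": x, "accuracy": y,
                       "animal": animals.astype(str)})
    means = df.groupby("animal")[["coupling", "accuracy"]].mean()
    r_a = p_a = None
    if len(means) >= 3 and means["coupling"].std() > 0 and (
            means["accuracy"].std() > 0):
        r_a, p_a = stats.pearsonr(means["coupling"], means["accuracy"])
        r_a, p_a = float(r_a), float(p_a)
    reg_p = None
    if df["animal"].nunique() >= 2:
        fit = smf.ols("accuracy ~ coupling + C(animal)", data=df).fit()
        reg_p = float(fit.pvalues["coupling"])
    return AccuracyCorrelation(
        r_session=float(r), p_session=float(p), r_animal=r_a, p_animal=p_a,
        regression_p=reg_p, n_sessions=int(x.size),
        n_animals=int(df["animal"].nunique()),
    )


def _analyze_one_session(
    lfps: dict, trains, trials: pd.DataFrame,
    phase_region: str, amp_region: str,
    phase_band, amp_band,
):
    if phase_region not in lfps or amp_region not in lfps:
        raise ConfigError(
            f"session lacks required regions {phase_region}/{amp_region}; "
            f"found {sorted(lfps)}")
    signals = prepare_coupling_signals(
        lfps[phase_region], lfps[amp_region], phase_band, amp_band)

    conditions = {}
    for name, sel in (
        ("sample_correct", {"phase": "sample", "correct": True}),
        ("choice_correct", {"phase": "choice", "correct": True}),
    ):
        ec = epoch_coupling_series(signals, trials, sel)
        conditions[name] = ec

    # Gamma peaks of the amplitude-region slow-gamma voltage vs theta phase.
    filt = bandpass_zero_phase(lfps[amp_region], amp_band)
    peaks = detect_peaks(filt)
    theta_phase = instantaneous_phase(
        bandpass_zero_phase(lfps[phase_region], phase_band))
    _, peak_dir, peak_mrl, n_peaks = peak_phase_histogram(peaks, theta_phase)

    # Unit phase locking to the amplitude-band oscillation.
    gamma_phase = instantaneous_phase(filt)
    kept, report = filter_units(trains)
    locking = []
    n_flagged = 0
    for u in kept:
        try:
            pl = phase_locking(u, gamma_phase)
        except InsufficientDataError:
            n_flagged += 1
            continue
        locking.append({
            "unit_id": pl.unit_id, "n_spikes": pl.n_spikes,
            "mrl": pl.mrl, "pref_phase_deg": float(np.degrees(pl.preferred_phase)),
            "rayleigh_p": pl.rayleigh_p, "locked": bool(pl.locked),
        })
    n_trials = int(trials["trial_id"].nunique())
    accuracy = float(
        trials.drop_duplicates("trial_id")["correct"].mean())
    return {
        "n_trials": n_trials,
        "n_epochs_total": int(len(trials)),
        "accuracy": accuracy,
        "conditions": {
            name: {
                "mrl": ec.pooled.mrl,
                "mean_direction_deg": float(
                    np.degrees(ec.pooled.mean_direction)),
                "n_epochs_used": ec.n_epochs_used,
                "n_epochs_dropped": ec.n_epochs_dropped,
            } for name, ec in conditions.items()
        },
        "per_epoch_mrl": {
            name: ec.per_epoch["mrl"].tolist()
            for name, ec in conditions.items()
        },
        "gamma_peaks": {
            "n_peaks": int(n_peaks),
            "mean_direction_deg": float(np.degrees(peak_dir)),
            "mrl": peak_mrl,
        },
        "units": {
            "n_input": len(trains), "n_kept": len(kept),
            "n_flagged_low_count": n_flagged,
            "n_locked": int(sum(l["locked"] for l in locking)),
            "locking": locking,
        },
    }


def run_pipeline(
    data_dirs, out_dir=None,
    phase_region: str = "vHPC", amp_region: str = "mPFC",
    phase_band=(4.0, 12.0), amp_band=(30.0, 70.0),
    animal_ids=None,
) -> dict:
    """Run the full analysis over one or more session directories.

    Each directory must hold the standard container (LFP float32+JSON,
    spikes.csv, trials.csv). Per session: condition-wise pooled PAC
    (sample/choice, correct trials), gamma-peak phase statistics, and unit
    phase locking. Across sessions: paired t-test of choice vs sample
    pooled coupling and, when >= 3 sessions with variable accuracy, the
    accuracy correlation. The JSON report is byte-reproducible for
    identical inputs (sorted keys, no timestamps).
    """
    if isinstance(data_dirs, (str, Path)):
        data_dirs = [data_dirs]
    sessions = {}
    for d in data_dirs:
        d = Path(d)
        lfps, trains, trials, _ = load_session(d)
        try:
            sessions[d.name] = _analyze_one_session(
                lfps, trains, trials, phase_region, amp_region,
                phase_band, amp_band)
        except (ConfigError, InsufficientDataError) as exc:
            raise type(exc)(f"session {d.name}: {exc}") from exc

    report = {
        "version": _pkg_version,
        "params": {
            "phase_region": phase_region, "amp_region": amp_region,
            "phase_band": list(phase_band), "amp_band": list(amp_band),
        },
        "sessions": sessions,
        "group": {},
    }
    names = sorted(sessions)
    if len(names) >= 2:
        sample = [sessions[s]["conditions"]["sample_correct"]["mrl"]
                  for s in names]
        choice = [sessions[s]["conditions"]["choice_correct"]["mrl"]
                  for s in names]
        t, p = paired_t(choice, sample)
        report["group"]["choice_vs_sample_correct"] = {
            "t": t, "p": p, "n_sessions": len(names),
            "mean_diff": float(np.mean(choice) - np.mean(sample)),
            "significant": bool(p < 0.05 and np.mean(choice) > np.mean(sample)),
        }
    if len(names) >= 3:
        couplings = [sessions[s]["conditions"]["choice_correct"]["mrl"]
                     for s in names]
        accs = [sessions[s]["accuracy"] for s in names]
        if animal_ids is None:
            animal_ids = ["a0"] * len(names)
        try:
            ac = accuracy_correlation(couplings, accs, animal_ids)
            report["group"]["accuracy_correlation"] = {
                "r_session": ac.r_session, "p_session": ac.p_session,
                "r_animal": ac.r_animal, "p_animal": ac.p_animal,
                "regression_p": ac.regression_p,
            }
        except InsufficientDataError:
            report["group"]["accuracy_correlation"] = None

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=1))
    return report
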