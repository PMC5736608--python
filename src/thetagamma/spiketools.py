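"""Single-unit tools: quality filtering, spike-phase locking, normalized
cross-correlograms, and firing-rate-versus-coupling quartile analysis.

The cross-correlogram statistic is

    CCG = C12 / (T * sqrt(f1 * f2))

where C12 counts spike pairs within +/-1 ms (inclusive), T is the segment
duration, and f1, f2 are the mean rates. Dividing by T puts C12 in
coincidences per second; the geometric-mean rate normalization removes the
first-order dependence on firing rates, so independent Poisson trains give
an expected value of 0.002 * sqrt(f1 f2) irrespective of T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .circstats import circ_mean, circ_r, rayleigh_test
from .errors import ConfigError, InsufficientDataError
from .sigproc import PhaseSeries

__all__ = [
    "SpikeTrain",
    "CcgCurve",
    "PhaseLocking",
    "QuartileResult",
    "filter_units",
    "phase_locking",
    "ccg",
    "firing_vs_coupling_quartiles",
]

L_RATIO_MAX = 0.1
ISOLATION_MIN = 10.0
COINCIDENCE_S = 1e-3
CCG_BIN_S = 0.5e-3
CCG_MAX_LAG_S = 0.05


@dataclass
class SpikeTrain:
    unit_id: str
    times: np.ndarray           # s, nondecreasing
    l_ratio: float | None = None
    isolation_distance: float | None = None
    region: str = ""
    stereotrode_id: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ConfigError(f"unit {self.unit_id}: spike times not sorted")

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass
class CcgCurve:
    lags_ms: np.ndarray         # bin centers, +/-50 ms in 0.5-ms bins
    values: np.ndarray          # per-bin counts / (T sqrt(f1 f2))
    scalar_ccg: float           # C12 / (T sqrt(f1 f2)), |dt| <= 1 ms
    peak_height: float          # max value over bins covering [-0.5, 0.5] ms
    f1: float
    f2: float
    T: float
    C12: int


@dataclass
class PhaseLocking:
    unit_id: str
    mrl: float
    preferred_phase: float      # rad
    rayleigh_z: float
    rayleigh_p: float
    n_spikes: int

    @property
    def locked(self) -> bool:
        return self.rayleigh_p < 0.05


@dataclass
class QuartileResult:
    quartile_mean_z: np.ndarray         # group mean z-rate per quartile (4,)
    per_animal: pd.DataFrame            # animal x quartile means
    slope: float                        # z-rate per quartile step
    slope_p: float
    slope_ci: tuple[float, float]
    epoch_quartiles: np.ndarray = field(default_factory=lambda: np.array([]))


def filter_units(
    units, l_ratio_max: float = L_RATIO_MAX, isolation_min: float = ISOLATION_MIN,
):
    """Keep units with L-ratio <= 0.1 and isolation distance >= 10 (inclusive).

    Units missing either metric are excluded with reason "missing". Returns
    (kept_units, report DataFrame with unit_id / kept / reason columns).
    """
    kept, rows = [], []
    for u in units:
        reasons = []
        if u.l_ratio is None or u.isolation_distance is None:
            reasons.append("missing")
        else:
            if u.l_ratio > l_ratio_max:
                reasons.append("l_ratio")
            if u.isolation_distance < isolation_min:
                reasons.append("isolation_distance")
        ok = not reasons
        if ok:
            kept.append(u)
        rows.append({"unit_id": u.unit_id, "kept": ok,
                     "reason": "+".join(reasons) if reasons else ""})
    return kept, pd.DataFrame(rows)


def phase_locking(
    spikes: SpikeTrain, phase: PhaseSeries, min_spikes: int = 10,
) -> PhaseLocking:
    """Phase locking of one unit to an oscillation.

    Spike phases are read off the phase series by nearest-sample lookup;
    the unweighted MRL, preferred (mean) phase, and Rayleigh test of
    nonuniformity are returned. Units with fewer than ``min_spikes`` spikes
    inside the phase support raise and should be flagged/excluded upstream.
    """
    phases = phase.at_times(spikes.times)
    phases = phases[np.isfinite(phases)]
    if phases.size == 0:
        raise InsufficientDataError(
            f"unit {spikes.unit_id}: no spikes inside the phase support")
    if phases.size < min_spikes:
        raise InsufficientDataError(
            f"unit {spikes.unit_id}: only {phases.size} spikes in support "
            f"(need >= {min_spikes})")
    z, p = rayleigh_test(phases, min_n=min_spikes)
    return PhaseLocking(
        unit_id=spikes.unit_id, mrl=circ_r(phases),
        preferred_phase=circ_mean(phases), rayleigh_z=z, rayleigh_p=p,
        n_spikes=int(phases.size),
    )


def _count_pairs_within(t1: np.ndarray, t2: np.ndarray, tol: float) -> int:
    """Number of (i, j) pairs with |t1[i] - t2[j]| <= tol (t2 sorted)."""
    left = np.searchsorted(t2, t1 - tol, side="left")
    right = np.searchsorted(t2, t1 + tol, side="right")
    return int((right - left).sum())


def ccg(
    train1: SpikeTrain, train2: SpikeTrain, T: float,
    max_lag: float = CCG_MAX_LAG_S, bin_width: float = CCG_BIN_S,
    allow_same_stereotrode: bool = False,
) -> CcgCurve:
    """Normalized spike cross-correlogram of two units over [0, T].

    The scalar statistic counts coincidences within +/-1 ms inclusive; the
    lag-resolved curve histograms t2 - t1 into 0.5-ms bins over +/-50 ms
    with the identical 1/(T sqrt(f1 f2)) normalization per bin. Pairs
    sharing a (non-empty) stereotrode label are rejected by default:
    spike-detection shadowing on a common electrode biases near-zero lags.
    """
    if train1.unit_id == train2.unit_id:
        raise ConfigError("CCG requires two distinct units")
    if (not allow_same_stereotrode
            and train1.stereotrode_id == train2.stereotrode_id
            and train1.stereotrode_id != ""):
        raise ConfigError(
            f"units {train1.unit_id}/{train2.unit_id} share stereotrode "
            f"{train1.stereotrode_id}")
    t1 = train1.times[(train1.times >= 0) & (train1.times <= T)]
    t2 = train2.times[(train2.times >= 0) & (train2.times <= T)]
    if t1.size == 0 or t2.size == 0:
        raise InsufficientDataError("empty spike train: firing rate undefined")
    f1, f2 = t1.size / T, t2.size / T
    norm = T * np.sqrt(f1 * f2)
    c12 = _count_pairs_within(t1, t2, COINCIDENCE_S)

    n_bins = int(round(2 * max_lag / bin_width))
    edges = -max_lag + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    # Histogram all lags t2 - t1 within +/-max_lag, spike by spike.
    left = np.searchsorted(t2, t1 - max_lag, side="left")
    right = np.searchsorted(t2, t1 + max_lag, side="right")
    for i in range(t1.size):
        if right[i] > left[i]:
            lags = t2[left[i]:right[i]] - t1[i]
            counts += np.histogram(lags, bins=edges)[0]
    values = counts / norm
    centers_ms = 1e3 * (edges[:-1] + bin_width / 2.0)
    central = np.abs(centers_ms) <= 0.5 * 1e3 * bin_width  # bins in [-0.5, 0.5] ms
    return CcgCurve(
        lags_ms=centers_ms, values=values,
        scalar_ccg=float(c12 / norm),
        peak_height=float(values[central].max()) if central.any() else np.nan,
        f1=float(f1), f2=float(f2), T=float(T), C12=c12,
    )


def firing_vs_coupling_quartiles(
    epoch_couplings, epoch_rates, unit_animal_ids,
) -> QuartileResult:
    """Firing-rate modulation across coupling-strength quartiles.

    Epochs are ranked by their coupling value and split into within-session
    quartiles (Q1 lowest .. Q4 highest). Each unit's per-epoch rate is
    z-scored across epochs, averaged per quartile, then averaged within and
    across animals. Significance comes from an OLS regression of the
    animal-level quartile means on the quartile index with animal indicator
    covariates; regressing at the animal level respects the unit-within-
    animal hierarchy and keeps the confidence interval honestly calibrated.

    Parameters
    ----------
    epoch_couplings : (n_epochs,) coupling value per epoch.
    epoch_rates : (n_units, n_epochs) firing rate per unit per epoch, Hz.
    unit_animal_ids : (n_units,) animal label per unit.
    """
    couplings = np.asarray(epoch_couplings, dtype=float)
    rates = np.atleast_2d(np.asarray(epoch_rates, dtype=float))
    animals = np.asarray(unit_animal_ids)
    n_units, n_epochs = rates.shape
    if couplings.size != n_epochs:
        raise ValueError("epoch_rates columns must match epoch_couplings")
    if n_epochs < 8:
        raise InsufficientDataError(
            f"need >= 8 epochs for a quartile split, got {n_epochs}")
    if np.unique(couplings).size < 4:
        raise InsufficientDataError(
            "quartiles undefined: fewer than 4 distinct coupling values")
    if animals.size != n_units:
        raise ValueError("unit_animal_ids must have one entry per unit")

    order = np.argsort(couplings, kind="stable")
    ranks = np.empty(n_epochs, dtype=int)
    ranks[order] = np.arange(n_epochs)
    quartiles = ranks * 4 // n_epochs  # 0..3, balanced within one epoch

    mu = rates.mean(axis=1, keepdims=True)
    sd = rates.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (rates - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    rows = []
    for u in range(n_units):
        for q in range(4):
            rows.append({
                "unit": u, "animal": str(animals[u]), "quartile": q + 1,
                "z_rate": float(z[u, quartiles == q].mean()),
            })
    df = pd.DataFrame(rows)
    per_animal = df.pivot_table(index="animal", columns="quartile",
                                values="z_rate", aggfunc="mean")
    quartile_mean_z = per_animal.mean(axis=0).to_numpy()

    df_animal = (df.groupby(["animal", "quartile"], as_index=False)
                 ["z_rate"].mean())
    if df["z_rate"].abs().max() == 0.0:
        slope, slope_p, ci = 0.0, 1.0, (0.0, 0.0)
    else:
        formula = ("z_rate ~ quartile + C(animal)"
                   if df_animal["animal"].nunique() > 1
                   else "z_rate ~ quartile")
        fit = smf.ols(formula, data=df_animal).fit()
        slope = float(fit.params["quartile"])
        slope_p = float(fit.pvalues["quartile"])
        lo, hi = fit.conf_int().loc["quartile"]
        ci = (float(lo), float(hi))
    return QuartileResult(
        quartile_mean_z=quartile_mean_z, per_animal=per_animal,
        slope=slope, slope_p=slope_p, slope_ci=ci,
        epoch_quartiles=quartiles + 1,
    )
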