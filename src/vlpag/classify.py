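"""Unit classification: waveform features, firing-rate clustering, cue screening.

Units are partitioned into low- and high-firing-rate classes (LFR/HFR,
proxies for putative glutamatergic vs. GABAergic identity) by k-means
(k = 2) on baseline firing rate, waveform half-duration and amplitude
ratio, then screened for cue-evoked excitation:

* onset — firing increase in the first 1 s cue interval vs. a 2 s pre-cue
  baseline, paired two-tailed t-test per cue at p < 0.017 (Bonferroni for
  three cues);
* ramping — no first-interval response but a last-interval increase at the
  same threshold, LFR class;
* hfr_cue_responsive — last-interval increase in an HFR unit;
* nonresponsive — everything else.

The screen requires a mean increase in addition to significance (it looks
for excitatory responses), and every unit receives exactly one label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .session import CUES, Session, Trial, UnitRecord, WaveformFeatures, cue_of

__all__ = [
    "TestResult",
    "ScreenResult",
    "CUE_ALPHA",
    "waveform_features",
    "baseline_firing_rate",
    "cluster_units",
    "screen_cue_responsive",
    "classify_population",
]

#: Bonferroni-corrected per-cue screening threshold (0.05 / 3 cues).
CUE_ALPHA = 0.05 / 3


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    df: float | None = None
    name: str = ""


def waveform_features(
    samples: np.ndarray,
    sample_times_ms: np.ndarray,
    baseline_rate: float = 0.0,
) -> WaveformFeatures:
    """Summarize a mean waveform (mV vs. ms, depolarization positive).

    half_duration = (time of after-hyperpolarization trough − time of peak
    depolarization) / 2; amplitude_ratio = (n − p)/(n + p) with n the
    maximal depolarization and p the initial hyperpolarization magnitude.
    """
    w = np.asarray(samples, dtype=float)
    t = np.asarray(sample_times_ms, dtype=float)
    if w.size < 3 or np.ptp(w) == 0:
        raise ValueError("flat or degenerate waveform")
    i_peak = int(np.argmax(w))
    n = w[i_peak]
    if i_peak == 0 or i_peak == w.size - 1:
        raise ValueError("waveform peak at boundary; no initial trough or after-trough")
    p = abs(min(np.min(w[:i_peak]), 0.0))
    i_trough = i_peak + int(np.argmin(w[i_peak:]))
    half_duration = (t[i_trough] - t[i_peak]) / 2.0
    if half_duration <= 0:
        raise ValueError("no after-hyperpolarization trough following the peak")
    return WaveformFeatures(
        half_duration=half_duration,
        amplitude_ratio=(n - p) / (n + p),
        baseline_rate=baseline_rate,
    )


def _window_rate(spikes: np.ndarray, t0: float, t1: float) -> float:
    return np.count_nonzero((spikes >= t0) & (spikes < t1)) / (t1 - t0)


def baseline_firing_rate(
    unit: UnitRecord, trials: list[Trial], baseline_window: float = 2.0
) -> float:
    """Mean rate over all trials' pre-cue baseline windows (spikes/s)."""
    if not trials:
        raise ValueError("need >= 1 trial")
    rates = [
        _window_rate(unit.spike_times, t.cue_on - baseline_window, t.cue_on)
        for t in trials
    ]
    return float(np.mean(rates))


def cluster_units(
    features: pd.DataFrame,
    k: int = 2,
    seed: int = 0,
    standardize: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """K-means (k = 2) on (baseline_rate, half_duration, amplitude_ratio).

    ``features`` needs columns unit_id, baseline_rate, half_duration,
    amplitude_ratio.  Features are standardized to unit variance before
    clustering (configurable); the lower-mean-rate cluster is labeled LFR.
    Returns (assignments, feature_tests) where feature_tests reports a
    one-way ANOVA per feature across the two clusters — the analogue of
    asking which features actually drive cluster membership.
    """
    cols = ["baseline_rate", "half_duration", "amplitude_ratio"]
    X = features[cols].to_numpy(dtype=float)
    if X.shape[0] < k or np.unique(X[:, 0]).size < 2:
        raise ValueError("need >= 2 units with distinct baseline rates")
    Xs = X.copy()
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xs = (X - X.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Xs)
    labels = km.labels_
    order = np.argsort([X[labels == c, 0].mean() for c in range(k)])
    names = {int(order[0]): "LFR", int(order[-1]): "HFR"}
    assignments = pd.DataFrame({
        "unit_id": features["unit_id"].to_numpy(),
        "cluster": [names[int(c)] for c in labels],
    })
    centroids = {
        names[int(c)]: X[labels == c].mean(axis=0) for c in range(k)
    }
    for i, col in enumerate(cols):
        assignments[f"centroid_{col}"] = [
            centroids[cl][i] for cl in assignments["cluster"]
        ]
    tests = []
    for i, col in enumerate(cols):
        groups = [X[labels == c, i] for c in range(k)]
        f, p = stats.f_oneway(*groups)
        tests.append({"feature": col, "F": float(f), "p": float(p)})
    return assignments, pd.DataFrame(tests)


@dataclass
class ScreenResult:
    """Per-cue paired t-tests of baseline vs. cue-interval firing for one unit."""

    unit_id: str
    interval: str  # "first_1s" or "last_1s"
    per_cue: dict[str, TestResult]
    increases: dict[str, bool]
    responsive: bool
    warnings: list[str]


def screen_cue_responsive(
    unit: UnitRecord,
    trials: list[Trial],
    interval: str = "first_1s",
    baseline_window: float = 2.0,
    alpha: float = CUE_ALPHA,
    cue_duration: float = 10.0,
) -> ScreenResult:
    """Screen one unit for excitatory cue responses in the given interval.

    For each cue (uncertainty trial types collapsed) a paired two-tailed
    t-test compares per-trial baseline rate (2 s pre-cue) with per-trial
    rate in the first or last 1 s cue interval.  The unit is responsive if
    any cue shows an increase at p < alpha.
    """
    if interval not in ("first_1s", "last_1s"):
        raise ValueError("interval must be 'first_1s' or 'last_1s'")
    per_cue: dict[str, TestResult] = {}
    increases: dict[str, bool] = {}
    warns: list[str] = []
    responsive = False
    for cue in CUES:
        cue_trials = [t for t in trials if cue_of(t.trial_type) == cue]
        if len(cue_trials) < 2:
            raise ValueError(f"need >= 2 trials for cue {cue!r}")
        base = np.array([
            _window_rate(unit.spike_times, t.cue_on - baseline_window, t.cue_on)
            for t in cue_trials
        ])
        if interval == "first_1s":
            win = [(t.cue_on, t.cue_on + 1.0) for t in cue_trials]
        else:
            win = [(t.cue_on + cue_duration - 1.0, t.cue_on + cue_duration)
                   for t in cue_trials]
        rate = np.array([_window_rate(unit.spike_times, a, b) for a, b in win])
        diffs = rate - base
        increase = bool(diffs.mean() > 0)
        if np.allclose(diffs, diffs[0]):
            warns.append(f"{cue}: zero-variance differences, test undefined")
            per_cue[cue] = TestResult(np.nan, np.nan, len(diffs) - 1, "paired t")
            increases[cue] = increase
            continue
        t_stat, p = stats.ttest_rel(rate, base)
        per_cue[cue] = TestResult(float(t_stat), float(p), len(diffs) - 1, "paired t")
        increases[cue] = increase
        if increase and p < alpha:
            responsive = True
    if warns:
        warnings.warn(f"unit {unit.unit_id}: " + "; ".join(warns), stacklevel=2)
    return ScreenResult(unit.unit_id, interval, per_cue, increases, responsive, warns)


def classify_population(
    session: Session,
    clusters: pd.DataFrame,
    alpha: float = CUE_ALPHA,
) -> pd.DataFrame:
    """Label every unit onset / ramping / hfr_cue_responsive / nonresponsive.

    Precedence: first-interval responsive => onset; else last-interval
    responsive and LFR => ramping; else last-interval responsive and HFR =>
    hfr_cue_responsive; else nonresponsive.  (Empirically the recorded
    onset population fell entirely in the LFR class; that is verified
    downstream, not enforced here.)
    """
    cluster_of = dict(zip(clusters["unit_id"], clusters["cluster"]))
    rows = []
    for unit in session.units:
        first = screen_cue_responsive(
            unit, session.trials, "first_1s", alpha=alpha,
            cue_duration=session.design.cue_duration)
        last = screen_cue_responsive(
            unit, session.trials, "last_1s", alpha=alpha,
            cue_duration=session.design.cue_duration)
        cl = cluster_of[unit.unit_id]
        if first.responsive:
            label = "onset"
        elif last.responsive and cl == "LFR":
            label = "ramping"
        elif last.responsive and cl == "HFR":
            label = "hfr_cue_responsive"
        else:
            label = "nonresponsive"
        row = {"unit_id": unit.unit_id, "cluster": cl, "label": label}
        for cue in CUES:
            row[f"first_t_{cue}"] = first.per_cue[cue].statistic
            row[f"first_p_{cue}"] = first.per_cue[cue].pvalue
            row[f"last_t_{cue}"] = last.per_cue[cue].statistic
            row[f"last_p_{cue}"] = last.per_cue[cue].pvalue
        rows.append(row)
    return pd.DataFrame(rows)
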