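"""Conditioned-suppression measures: nose-poke rates and suppression ratios.

Fear output is quantified by suppression of rewarded nose poking, as the
ratio (baseline poke rate − cue poke rate)/(baseline poke rate + cue poke
rate): 1 indicates complete suppression (high fear), 0 no suppression, with
gradations between.  The ratio is computed for the entire 10 s cue (total
fear) and for each 1 s cue interval (interval fear), all against the same
pre-cue baseline rate; post-cue 500 ms windows are scored the same way for
the post-cue regressions.

A 0/0 ratio (no pokes in baseline or cue window) is undefined; it is
returned as NaN and counted, never imputed as zero — a silent zero would
bias toward "no fear".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .session import CUES, BehaviorRecord, Session, Trial, cue_of

__all__ = [
    "SuppressionMeasures",
    "poke_rate",
    "suppression_ratio",
    "trial_suppression",
    "compute_suppression",
    "discrimination_summary",
]


def poke_rate(pokes: BehaviorRecord | np.ndarray, window: tuple[float, float]) -> float:
    """Event rate (pokes/s) in the half-open window [t0, t1)."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError(f"window must satisfy t1 > t0, got [{t0}, {t1})")
    times = pokes.poke_times if isinstance(pokes, BehaviorRecord) else np.asarray(pokes)
    count = int(np.count_nonzero((times >= t0) & (times < t1)))
    return count / (t1 - t0)


def suppression_ratio(baseline_rate: float, cue_rate: float) -> float:
    """(b − c)/(b + c); NaN when both rates are zero (undefined, not 'no fear')."""
    if baseline_rate < 0 or cue_rate < 0:
        raise ValueError("rates must be >= 0")
    denom = baseline_rate + cue_rate
    if denom == 0.0:
        return float("nan")
    return (baseline_rate - cue_rate) / denom


def _postcue_windows(design) -> list[tuple[float, float]]:
    """500 ms windows covering the 5 s post-cue period, relative to cue offset."""
    n = int(round(5.0 / 0.5))
    return [(0.5 * k, 0.5 * (k + 1)) for k in range(n)]


def trial_suppression(
    session: Session,
    trial: Trial,
    baseline_window: float = 10.0,
    include_postcue: bool = True,
) -> tuple[float, float, np.ndarray, np.ndarray | None]:
    """Per-trial (baseline_rate, total_ratio, ten interval ratios[, post-cue ratios]).

    The baseline window is the ``baseline_window`` seconds immediately
    preceding cue onset; it must not reach back into the previous trial's
    shock window.
    """
    design = session.design
    b0 = trial.cue_on - baseline_window
    if b0 < 0:
        raise ValueError(f"trial {trial.index}: baseline window precedes session start")
    prev = [t for t in session.trials if t.index < trial.index]
    if prev:
        last = max(prev, key=lambda t: t.index)
        if last.shock_on is not None and b0 < last.shock_on + design.shock_duration:
            raise ValueError(
                f"trial {trial.index}: baseline window overlaps trial "
                f"{last.index} shock window"
            )
    pokes = session.behavior
    b = poke_rate(pokes, (b0, trial.cue_on))
    total = suppression_ratio(b, poke_rate(pokes, (trial.cue_on, trial.cue_off)))
    n_int = int(round(design.cue_duration))
    intervals = np.array([
        suppression_ratio(b, poke_rate(pokes, (trial.cue_on + k, trial.cue_on + k + 1)))
        for k in range(n_int)
    ])
    post = None
    if include_postcue:
        post = np.array([
            suppression_ratio(
                b, poke_rate(pokes, (trial.cue_off + w0, trial.cue_off + w1)))
            for w0, w1 in _postcue_windows(design)
        ])
    return b, total, intervals, post


@dataclass
class SuppressionMeasures:
    """Per-trial suppression for one session.

    ``intervals`` is (n_trials, 10) over the 1 s cue intervals; ``postcue``
    is (n_trials, 10) over the 500 ms post-cue windows (the 2.0–2.5 s shock
    window is included here and excluded by the regression stage).
    Undefined ratios are NaN.
    """

    trial_index: np.ndarray
    trial_type: list[str]
    baseline_rate: np.ndarray
    total: np.ndarray
    intervals: np.ndarray
    postcue: np.ndarray | None
    baseline_window: float

    def total_ratio(self, trial_index: int) -> float:
        pos = int(np.flatnonzero(self.trial_index == trial_index)[0])
        return float(self.total[pos])

    @property
    def n_undefined(self) -> int:
        n = int(np.isnan(self.total).sum()) + int(np.isnan(self.intervals).sum())
        if self.postcue is not None:
            n += int(np.isnan(self.postcue).sum())
        return n

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "trial": self.trial_index,
            "trial_type": self.trial_type,
            "baseline_rate": self.baseline_rate,
            "total_ratio": self.total,
        })
        for k in range(self.intervals.shape[1]):
            df[f"interval_{k + 1}"] = self.intervals[:, k]
        if self.postcue is not None:
            for k in range(self.postcue.shape[1]):
                df[f"postcue_{k + 1}"] = self.postcue[:, k]
        return df

    def cue_mean(self, cue: str, column: str = "total") -> float:
        """NaN-excluding mean of a measure over trials of one cue."""
        mask = np.array([cue_of(tt) == cue for tt in self.trial_type])
        vals = {"total": self.total}.get(column)
        if vals is None:
            raise KeyError(column)
        return float(np.nanmean(vals[mask]))


def compute_suppression(
    session: Session,
    baseline_window: float = 10.0,
    include_postcue: bool = True,
) -> SuppressionMeasures:
    """Suppression measures for every trial of a session."""
    rows = [
        trial_suppression(session, t, baseline_window, include_postcue)
        for t in session.trials
    ]
    return SuppressionMeasures(
        trial_index=np.array([t.index for t in session.trials]),
        trial_type=[t.trial_type for t in session.trials],
        baseline_rate=np.array([r[0] for r in rows]),
        total=np.array([r[1] for r in rows]),
        intervals=np.vstack([r[2] for r in rows]),
        postcue=np.vstack([r[3] for r in rows]) if include_postcue else None,
        baseline_window=baseline_window,
    )


def discrimination_summary(
    measures: list[SuppressionMeasures],
    bonferroni_intervals: bool = True,
) -> dict:
    """Cross-session discrimination: per-cue means, SEMs and paired t-tests.

    Sessions are the statistical unit: each contributes its per-cue mean
    ratio (undefined trials excluded and counted).  Pairwise paired t-tests
    are run for the total-cue ratio and for each 1 s interval; the interval
    tests carry a Bonferroni-corrected threshold 0.05/n_intervals.
    """
    if len(measures) < 2:
        raise ValueError("need >= 2 sessions for a discrimination summary")
    n_int = measures[0].intervals.shape[1]
    per_cue_total = {cue: [] for cue in CUES}
    per_cue_int = {cue: [] for cue in CUES}
    n_undefined = 0
    for m in measures:
        n_undefined += m.n_undefined
        types = np.array([cue_of(tt) for tt in m.trial_type])
        for cue in CUES:
            mask = types == cue
            per_cue_total[cue].append(np.nanmean(m.total[mask]))
            per_cue_int[cue].append(np.nanmean(m.intervals[mask], axis=0))
    totals = {cue: np.array(v) for cue, v in per_cue_total.items()}
    ints = {cue: np.vstack(v) for cue, v in per_cue_int.items()}
    summary = pd.DataFrame({
        "cue": list(CUES),
        "mean_total_ratio": [np.nanmean(totals[c]) for c in CUES],
        "sem_total_ratio": [stats.sem(totals[c], nan_policy="omit") for c in CUES],
    })
    pairs = [("danger", "uncertainty"), ("uncertainty", "safety"), ("danger", "safety")]
    rows = []
    for a, b in pairs:
        t, p = stats.ttest_rel(totals[a], totals[b], nan_policy="omit")
        rows.append({"pair": f"{a}_vs_{b}", "interval": "total",
                     "t": float(t), "p": float(p)})
        for k in range(n_int):
            t, p = stats.ttest_rel(ints[a][:, k], ints[b][:, k], nan_policy="omit")
            rows.append({"pair": f"{a}_vs_{b}", "interval": k + 1,
                         "t": float(t), "p": float(p)})
    tests = pd.DataFrame(rows)
    tests["alpha"] = np.where(
        tests["interval"].eq("total"), 0.05,
        0.05 / n_int if bonferroni_intervals else 0.05,
    )
    tests["significant"] = tests["p"] < tests["alpha"]
    interval_means = pd.DataFrame({
        "interval": np.arange(1, n_int + 1),
        **{f"mean_{c}": np.nanmean(ints[c], axis=0) for c in CUES},
        **{f"sem_{c}": stats.sem(ints[c], axis=0, nan_policy="omit") for c in CUES},
    })
    return {
        "summary": summary,
        "interval_means": interval_means,
        "tests": tests,
        "n_sessions": len(measures),
        "n_undefined_ratios": n_undefined,
    }
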