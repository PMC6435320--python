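"""Population-level analyses of normalized firing.

Covers the sliding-window departure analysis (when does population firing
to one cue separate from another), the rate-of-increase that follows it,
categorization of per-unit firing patterns over the three cues with a
1000-shuffle chance distribution, single-unit bias tests (Pearson
correlation + exact sign test), the chi-square comparison of proportions,
and the nose-poke-cessation control (is cue-evoked firing merely a
poke-cessation signal?).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classify import TestResult
from .session import Session, Trial, UnitRecord

__all__ = [
    "DepartureResult",
    "PatternCounts",
    "CessationResult",
    "ORDERINGS",
    "sliding_departure",
    "rate_of_increase",
    "categorize_pattern",
    "shuffle_pattern_null",
    "bias_tests",
    "chisq_proportions",
    "poke_cessation_control",
]

logger = logging.getLogger(__name__)

_CUE_KEYS = ("d", "u", "s")
#: The six strict orderings of danger/uncertainty/safety firing.
ORDERINGS = tuple(
    ">".join(perm) for perm in itertools.permutations(_CUE_KEYS)
)


# ---------------------------------------------------------------------------
# Sliding-window departure
# ---------------------------------------------------------------------------

@dataclass
class DepartureResult:
    comparison: tuple[str, str]
    window_starts: np.ndarray
    pvalues: np.ndarray
    departure_time_p05: float | None
    departure_time_bonferroni: float | None
    bonferroni_threshold: float
    n_windows: int
    bonferroni_divisor: int


def sliding_departure(
    pop_z_a: np.ndarray,
    pop_z_b: np.ndarray,
    comparison: tuple[str, str] = ("a", "b"),
    bin_width: float = 0.1,
    window: float = 1.0,
    step: float = 0.1,
    span: float = 10.0,
    alpha: float = 0.05,
    bonferroni_divisor: int | None = None,
    n_comparisons: int = 2,
) -> DepartureResult:
    """Slide a 1 s window across the cue in 100 ms steps; paired t per window.

    ``pop_z_a``/``pop_z_b`` are (units × bins) Z time series aligned to cue
    onset covering ``span`` seconds.  The departure time is the start of the
    first window whose across-unit paired t-test falls below threshold.
    The Bonferroni divisor defaults to windows × ``n_comparisons`` and is
    overridable (reported analyses have used a fixed divisor of 200).
    """
    a = np.atleast_2d(np.asarray(pop_z_a, dtype=float))
    b = np.atleast_2d(np.asarray(pop_z_b, dtype=float))
    if a.shape != b.shape or a.shape[0] < 2:
        raise ValueError("need >= 2 units with aligned bins in both populations")
    w_bins = int(round(window / bin_width))
    s_bins = int(round(step / bin_width))
    n_bins = int(round(span / bin_width))
    starts, pvals = [], []
    for lo in range(0, n_bins - w_bins + 1, s_bins):
        wa = a[:, lo:lo + w_bins].mean(axis=1)
        wb = b[:, lo:lo + w_bins].mean(axis=1)
        if np.allclose(wa - wb, (wa - wb)[0]):
            p = 1.0 if np.allclose(wa, wb) else 0.0
        else:
            _, p = stats.ttest_rel(wa, wb)
        starts.append(lo * bin_width)
        pvals.append(float(p))
    starts = np.array(starts)
    pvals = np.array(pvals)
    divisor = bonferroni_divisor if bonferroni_divisor is not None \
        else len(starts) * n_comparisons
    thr = alpha / divisor

    def first_below(threshold):
        hits = np.flatnonzero(pvals < threshold)
        return float(starts[hits[0]]) if hits.size else None

    return DepartureResult(
        comparison=comparison,
        window_starts=starts,
        pvalues=pvals,
        departure_time_p05=first_below(alpha),
        departure_time_bonferroni=first_below(thr),
        bonferroni_threshold=thr,
        n_windows=len(starts),
        bonferroni_divisor=divisor,
    )


def rate_of_increase(
    pop_z: np.ndarray,
    departure_time: float | None,
    bin_width: float = 0.1,
    window: float = 1.0,
    span: float = 10.0,
) -> float:
    """(Z in last 1 s window − Z in departure window) / time between them.

    ``pop_z`` is (units × bins) over the cue; returns NaN (flagged
    undefined) when no departure exists or it coincides with the last
    window.
    """
    if departure_time is None:
        return float("nan")
    last_start = span - window
    dt = last_start - departure_time
    if dt <= 0:
        return float("nan")
    z = np.atleast_2d(pop_z).mean(axis=0)
    w = int(round(window / bin_width))
    lo_dep = int(round(departure_time / bin_width))
    lo_last = int(round(last_start / bin_width))
    return float((z[lo_last:lo_last + w].mean() - z[lo_dep:lo_dep + w].mean()) / dt)


# ---------------------------------------------------------------------------
# Firing-pattern categorization and shuffle null
# ---------------------------------------------------------------------------

def categorize_pattern(danger: float, uncertainty: float, safety: float) -> str:
    """Strict ordering label, e.g. ``'d>u>s'``.

    Ties (measure-zero for continuous Z) are broken deterministically by
    the fixed priority danger > uncertainty > safety and logged.
    """
    vals = {"d": danger, "u": uncertainty, "s": safety}
    if not all(np.isfinite(v) for v in vals.values()):
        raise ValueError("pattern values must be finite")
    if len({danger, uncertainty, safety}) < 3:
        logger.info("tie in pattern values %s; broken by d>u>s priority", vals)
    priority = {"d": 0, "u": 1, "s": 2}
    keys = sorted(vals, key=lambda k: (-vals[k], priority[k]))
    return ">".join(keys)


@dataclass
class PatternCounts:
    """Observed per-ordering counts vs. a shuffle (chance) distribution."""

    observed: dict[str, int]
    shuffle_summary: pd.DataFrame  # per ordering: median, q25, q75, whiskers
    n_units: int
    n_shuffles: int
    exceeds_chance: dict[str, bool] = field(default_factory=dict)


def shuffle_pattern_null(
    values: np.ndarray,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> PatternCounts:
    """Chance distribution of ordering counts by within-unit shuffling.

    ``values`` is (units × 3) mean Z to (danger, uncertainty, safety).  Each
    shuffle permutes the three values within every unit, re-categorizes and
    re-counts.  Whiskers are the most extreme points within 1.5 IQR of the
    quartiles (box-plot convention); an observed count above the upper
    whisker is flagged as exceeding chance.
    """
    vals = np.atleast_2d(np.asarray(values, dtype=float))
    n_units = vals.shape[0]
    if n_units < 1:
        raise ValueError("need >= 1 unit")
    rng = np.random.default_rng(seed)

    def count(matrix):
        c = dict.fromkeys(ORDERINGS, 0)
        for row in matrix:
            c[categorize_pattern(*row)] += 1
        return c

    observed = count(vals)
    shuffled = np.zeros((n_shuffles, len(ORDERINGS)), dtype=int)
    for i in range(n_shuffles):
        perm = vals[np.arange(n_units)[:, None], rng.permuted(
            np.tile(np.arange(3), (n_units, 1)), axis=1)]
        c = count(perm)
        shuffled[i] = [c[o] for o in ORDERINGS]
    q25, med, q75 = np.percentile(shuffled, [25, 50, 75], axis=0)
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    lo_whisk = np.array([
        shuffled[:, j][shuffled[:, j] >= lo_fence[j]].min()
        for j in range(len(ORDERINGS))
    ])
    hi_whisk = np.array([
        shuffled[:, j][shuffled[:, j] <= hi_fence[j]].max()
        for j in range(len(ORDERINGS))
    ])
    summary = pd.DataFrame({
        "ordering": ORDERINGS,
        "observed": [observed[o] for o in ORDERINGS],
        "median": med, "q25": q25, "q75": q75,
        "whisker_low": lo_whisk, "whisker_high": hi_whisk,
    })
    exceeds = {
        o: observed[o] > hi_whisk[j] for j, o in enumerate(ORDERINGS)
    }
    return PatternCounts(observed, summary, n_units, n_shuffles, exceeds)


# ---------------------------------------------------------------------------
# Bias tests and proportions
# ---------------------------------------------------------------------------

def bias_tests(x: np.ndarray, y: np.ndarray) -> dict:
    """Pearson R² (with p) plus an exact two-tailed sign test on x − y.

    Ties are excluded from the sign test; if everything ties, the sign-test
    p is NaN (undefined).  Zero variance in either input leaves the
    correlation NaN-flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        r2, p_r = float("nan"), float("nan")
    else:
        r, p_r = stats.pearsonr(x, y)
        r2 = float(r**2)
    diffs = x - y
    pos = int(np.sum(diffs > 0))
    neg = int(np.sum(diffs < 0))
    n_eff = pos + neg
    p_sign = float(stats.binomtest(pos, n_eff, 0.5).pvalue) if n_eff else float("nan")
    return {
        "r_squared": r2, "p_correlation": float(p_r),
        "n_positive": pos, "n_negative": neg, "n_ties": int(x.size - n_eff),
        "p_sign": p_sign, "n": int(x.size),
    }


def chisq_proportions(
    a_successes: int, n1: int, b_successes: int, n2: int,
    correction: bool = False,
) -> TestResult:
    """Pearson chi-square on the 2×2 table of two proportions.

    No continuity correction by default (Yates available by flag); raises
    on a zero marginal.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be > 0")
    table = np.array([
        [a_successes, n1 - a_successes],
        [b_successes, n2 - b_successes],
    ])
    if np.any(table < 0):
        raise ValueError("successes cannot exceed group size")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in the 2x2 table")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=correction)
    return TestResult(float(chi2), float(p), float(dof), "pearson chi-square")


# ---------------------------------------------------------------------------
# Nose-poke-cessation control
# ---------------------------------------------------------------------------

@dataclass
class CessationResult:
    gap_onsets: np.ndarray
    pre_rates: np.ndarray
    post_rates: np.ndarray
    test: TestResult | None
    gap_threshold: float
    conventions: dict


def poke_cessation_control(
    unit: UnitRecord,
    session: Session,
    gap_threshold: float = 5.0,
    pre_window: float = 2.0,
    post_window: float = 2.0,
) -> CessationResult:
    """Firing around spontaneous poke-cessation onsets in inter-trial intervals.

    A cessation epoch is a poke-free gap >= ``gap_threshold`` seconds lying
    entirely inside an ITI (outside any cue/trace/shock footprint and its
    peri-event analysis windows); the gap onset is the final poke before
    the gap.  Firing in [onset, onset + post_window) is compared to
    [onset − pre_window, onset) by paired t-test.  Empty result (logged)
    when no gaps qualify.
    """
    design = session.design
    pokes = session.behavior.poke_times
    conventions = {
        "gap_threshold": gap_threshold, "pre_window": pre_window,
        "post_window": post_window,
    }
    # ITI exclusion zones: pre-cue baseline through post-shock settling
    zones = [
        (t.cue_on - 12.0, t.end(design) + 2.0) for t in session.trials
    ]

    def in_iti(t0, t1):
        return all(t1 <= z0 or t0 >= z1 for z0, z1 in zones) and t0 >= 0 \
            and t1 <= session.session_span

    onsets = []
    for i in range(pokes.size - 1):
        gap = pokes[i + 1] - pokes[i]
        if gap >= gap_threshold and in_iti(pokes[i] - pre_window,
                                           pokes[i] + gap_threshold):
            onsets.append(pokes[i])
    if not onsets:
        logger.info("unit %s: no qualifying poke-cessation gaps", unit.unit_id)
        return CessationResult(np.empty(0), np.empty(0), np.empty(0), None,
                               gap_threshold, conventions)
    onsets = np.array(onsets)
    spikes = unit.spike_times
    pre = np.array([
        np.count_nonzero((spikes >= t - pre_window) & (spikes < t)) / pre_window
        for t in onsets
    ])
    post = np.array([
        np.count_nonzero((spikes >= t) & (spikes < t + post_window)) / post_window
        for t in onsets
    ])
    test = None
    if onsets.size >= 2 and not np.allclose(post - pre, (post - pre)[0]):
        t_stat, p = stats.ttest_rel(post, pre)
        test = TestResult(float(t_stat), float(p), onsets.size - 1, "paired t")
    return CessationResult(onsets, pre, post, test, gap_threshold, conventions)
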