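"""Peri-event histograms and the two Z-normalization schemes.

Whole-epoch scheme: per unit, firing is binned at 100 ms from 10 s before
cue onset to 12 s after cue offset (320 bins for the 10 s cue), averaged
across trials per trial type, converted to differential firing by
subtracting that type's 2 s pre-cue baseline mean, and then Z-scored with
a single mean/SD pooled over all trial types × bins.  Because phasic
excitation contributes to the pooled mean, baseline Z sits below zero for
responsive units.

Per-interval scheme: differential firing in one interval of interest is
computed for each of the session's 32 trials (against that trial's own 2 s
pre-cue baseline) and Z-scored across the 32 trials — maximizing the
spread of firing within a single interval for trial-by-trial regression.

Both schemes use the population SD (divide by N).
"""

from __future__ import annotations

import numpy as np

from .session import Session, SessionDesign, Trial, UnitRecord

__all__ = [
    "NormalizationError",
    "psth_bin_edges",
    "trial_psth",
    "mean_psth",
    "differential_mean_psth",
    "zscore_unit",
    "interval_trial_z",
    "smooth_psth",
    "cue_interval_window",
    "postcue_interval_window",
]

PRE_CUE = 10.0  # s of pre-cue history in the PSTH
POST_OFF = 12.0  # s after cue offset
BASELINE = 2.0  # s of pre-cue baseline for differential firing


class NormalizationError(ValueError):
    """Raised when a unit cannot be normalized (zero variance)."""


def psth_bin_edges(design: SessionDesign, bin_width: float = 0.1) -> np.ndarray:
    """Bin edges relative to cue onset, −10 s to cue_offset + 12 s."""
    span = PRE_CUE + design.cue_duration + POST_OFF
    n = int(round(span / bin_width))
    return -PRE_CUE + bin_width * np.arange(n + 1)


def trial_psth(
    unit: UnitRecord,
    trial: Trial,
    design: SessionDesign,
    bin_width: float = 0.1,
    session_span: float | None = None,
) -> np.ndarray:
    """Firing rate (spikes/s) per half-open 100 ms bin for one trial."""
    edges = trial.cue_on + psth_bin_edges(design, bin_width)
    if edges[0] < 0 or (session_span is not None and edges[-1] > session_span):
        raise ValueError(f"trial {trial.index}: PSTH window exceeds the recording")
    counts, _ = np.histogram(unit.spike_times, bins=edges)
    return counts / bin_width


def mean_psth(
    unit: UnitRecord,
    trials: list[Trial],
    design: SessionDesign,
    bin_width: float = 0.1,
) -> np.ndarray:
    if not trials:
        raise ValueError("need >= 1 trial")
    return np.mean([trial_psth(unit, t, design, bin_width) for t in trials], axis=0)


def differential_mean_psth(
    unit: UnitRecord,
    trials: list[Trial],
    design: SessionDesign,
    bin_width: float = 0.1,
) -> np.ndarray:
    """Mean PSTH minus the trial-type's 2 s pre-cue baseline mean rate."""
    m = mean_psth(unit, trials, design, bin_width)
    edges = psth_bin_edges(design, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2
    baseline_bins = (centers > -BASELINE) & (centers < 0)
    return m - m[baseline_bins].mean()


def zscore_unit(diff_psths: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Whole-epoch Z: one mean/SD pooled over all trial types × bins.

    Output satisfies mean 0, SD 1 over the pooled domain; raises
    :class:`NormalizationError` for a zero pooled SD (constant-rate unit),
    in which case the unit should be excluded and logged.
    """
    pooled = np.concatenate(list(diff_psths.values()))
    mu = pooled.mean()
    sd = pooled.std(ddof=0)
    if sd == 0:
        raise NormalizationError("zero pooled SD; unit cannot be Z-scored")
    return {tt: (v - mu) / sd for tt, v in diff_psths.items()}


def cue_interval_window(interval: int, design: SessionDesign) -> tuple[float, float]:
    """1 s cue interval ``interval`` (0-based) relative to cue onset."""
    n = int(round(design.cue_duration))
    if not 0 <= interval < n:
        raise ValueError(f"cue interval must be in [0, {n})")
    return float(interval), float(interval + 1)


def postcue_interval_window(interval: int, design: SessionDesign) -> tuple[float, float]:
    """500 ms post-cue interval ``interval`` (0-based, 0–9) relative to cue onset."""
    if not 0 <= interval < 10:
        raise ValueError("post-cue interval must be in [0, 10)")
    off = design.cue_duration
    return off + 0.5 * interval, off + 0.5 * (interval + 1)


def interval_trial_z(
    unit: UnitRecord,
    trials: list[Trial],
    window: tuple[float, float],
    baseline_window: float = BASELINE,
) -> np.ndarray:
    """Per-trial Z of differential firing in one interval, across all trials.

    ``window`` is (t0, t1) relative to cue onset.  Each trial's differential
    firing is its rate in the window minus its own 2 s pre-cue baseline
    rate; the resulting per-trial values are Z-scored (population SD)
    across the session's trials.
    """
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("window must satisfy t1 > t0")
    diffs = []
    for t in trials:
        spikes = unit.spike_times
        rate = np.count_nonzero(
            (spikes >= t.cue_on + w0) & (spikes < t.cue_on + w1)) / (w1 - w0)
        base = np.count_nonzero(
            (spikes >= t.cue_on - baseline_window) & (spikes < t.cue_on)
        ) / baseline_window
        diffs.append(rate - base)
    diffs = np.asarray(diffs)
    sd = diffs.std(ddof=0)
    if sd == 0:
        raise NormalizationError(
            f"unit {unit.unit_id}: zero across-trial SD in interval {window}")
    return (diffs - diffs.mean()) / sd


def smooth_psth(psth: np.ndarray, width: int = 5) -> np.ndarray:
    """Centered moving average that conserves total area.

    Each input bin's mass is redistributed over the (boundary-truncated)
    kernel support, so the bin sum is preserved exactly; width 1 is the
    identity.
    """
    if width < 1:
        raise ValueError("width must be >= 1 bin")
    x = np.asarray(psth, dtype=float)
    if width == 1:
        return x.copy()
    n = x.size
    h = (width - 1) // 2
    out = np.zeros(n)
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + (width - h))
        out[lo:hi] += x[i] / (hi - lo)
    return out
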