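"""Synthetic session generator.

Emulates the statistical structure the downstream analyses assume, so the
whole pipeline runs at desk scale with no recorded data:

* randomized trial sequences with the exact 6/6/10/10 type composition and
  inter-trial intervals drawn from a truncated exponential with the stated
  3.5 min mean (configurable shorter);
* nose-poke trains that are homogeneous Poisson at a baseline rate outside
  cues and suppressed during cues so that measured suppression ratios
  converge to the nonlinear targets danger 0.80 > uncertainty 0.53 >>
  safety 0.03;
* spike trains from inhomogeneous Poisson processes (exact thinning) with
  onset-type (sharp first-second response decaying over the cue),
  ramping-type (rising over the cue, sustained through the 2 s delay,
  optionally truncated after shock), high-firing-rate (HFR) cue-responsive,
  and nonresponsive intensity profiles.

Trial-level suppression noise (``trial_noise_sd``) injects within-cue
behavioral variance so the interval-fear, total-fear and probability
regressors are not collinear in synthetic data; the trial-by-trial
regression downstream requires it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .session import (
    CUES,
    SHOCKED_TYPES,
    TRIAL_TYPES,
    BehaviorRecord,
    Session,
    SessionDesign,
    Trial,
    UnitRecord,
    WaveformFeatures,
    cue_of,
    default_design,
)

__all__ = [
    "BehaviorSpec",
    "UnitSpec",
    "CohortSpec",
    "LatentFear",
    "make_trial_sequence",
    "draw_trial_fear",
    "simulate_pokes",
    "simulate_unit",
    "simulate_session",
    "simulate_cohort",
    "ratio_to_rate",
    "DEFAULT_PROFILES",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class BehaviorSpec:
    """Target behavior: baseline poke rate and per-cue suppression.

    Defaults reproduce the study's session-mean suppression ratios
    (danger 0.80, uncertainty 0.53, safety 0.03) around a 1 poke/s baseline.
    ``trial_noise_sd`` is the SD (ratio units) of Gaussian trial-level
    jitter applied to the target ratio before it is mapped to a cue poke
    rate; ``within_cue_profile`` optionally scales the per-trial ratio in
    each 1 s cue interval.
    """

    baseline_poke_rate: float = 1.0
    target_suppression: dict[str, float] = field(
        default_factory=lambda: {"danger": 0.80, "uncertainty": 0.53, "safety": 0.03}
    )
    within_cue_profile: np.ndarray | None = None
    trial_noise_sd: float = 0.25
    rho_floor: float = -0.8

    def validate(self) -> None:
        if self.baseline_poke_rate <= 0:
            raise ValueError("baseline_poke_rate must be > 0")
        if not -1.0 < self.rho_floor <= 0.0:
            raise ValueError("rho_floor must lie in (-1, 0]")
        for cue, rho in self.target_suppression.items():
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"target suppression for {cue!r} outside [-1, 1]")


def ratio_to_rate(baseline: float, rho: float) -> float:
    """Invert the suppression ratio: cue rate with ratio ``rho`` vs ``baseline``.

    From (b − c)/(b + c) = rho:  c = b (1 − rho)/(1 + rho).  rho = 1 maps to
    a zero cue rate; rho must be > −1 for a finite rate.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"suppression ratio {rho} outside [-1, 1]")
    if rho >= 1.0:
        return 0.0
    return baseline * (1.0 - rho) / (1.0 + rho)


@dataclass
class UnitSpec:
    """Intensity model of one synthetic unit.

    ``profile`` selects the shape of cue-evoked modulation:

    * ``onset`` — modulation (probability_gain·p + fear_gain·fear) ×
      exp(−t/onset_decay_tau) from cue onset, confined to the cue;
    * ``ramping`` — modulation × max(0, (t − ramp_start)/(shock_time −
      ramp_start)), rising over the cue, sustained through the delay and
      truncated back to baseline after the (actual or scheduled) shock when
      ``post_cue_behavior == 'truncate_after_shock'``;
    * ``hfr`` — step modulation over the last cue second and the delay,
      on a high baseline;
    * ``nonresponsive`` — homogeneous baseline only.

    Negative intensities (possible when fear_gain couples to a negative
    trial ratio) are clipped to zero before sampling.
    """

    profile: str = "nonresponsive"
    baseline_rate: float = 3.0
    probability_gain: float = 0.0
    fear_gain: float = 0.0
    onset_decay_tau: float = 1.5
    ramp_start: float = 2.0
    post_cue_behavior: str = "truncate_after_shock"
    zero_shock_window: bool = True
    half_duration: float = 0.25
    amplitude_ratio: float = 0.0

    def validate(self, design: SessionDesign) -> None:
        if self.profile not in ("onset", "ramping", "hfr", "nonresponsive"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if not 0.0 <= self.ramp_start < design.cue_duration:
            raise ValueError("ramp_start must lie in [0, cue_duration)")
        if self.onset_decay_tau <= 0:
            raise ValueError("onset_decay_tau must be > 0")


@dataclass
class CohortSpec:
    """Unit composition of a simulated cohort.

    ``n_units`` maps profile name -> count; nonresponsive units are drawn
    from a low/high baseline-rate mixture (``hfr_fraction`` high) so the
    two firing-rate classes are both populated.
    """

    n_units: dict[str, int] = field(
        default_factory=lambda: {"onset": 10, "ramping": 5, "hfr": 2, "nonresponsive": 33}
    )
    n_sessions: int = 1
    hfr_fraction_nonresponsive: float = 0.2

    def validate(self) -> None:
        if any(n < 0 for n in self.n_units.values()):
            raise ValueError("unit counts must be >= 0")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")


# Per-profile defaults: LFR baselines ~3 spikes/s, HFR ~15 spikes/s; gains
# sized so evoked responses are a few-fold over baseline (qualitative match
# to the recorded onset/ramping examples; no quantitative values exist).
# Ramping units weight probability and fear equally — the recorded ramping
# population's last-interval probability and total-fear betas are of
# comparable size.
DEFAULT_PROFILES: dict[str, UnitSpec] = {
    "onset": UnitSpec(profile="onset", baseline_rate=3.0, probability_gain=12.0),
    "ramping": UnitSpec(profile="ramping", baseline_rate=3.0, probability_gain=8.0,
                        fear_gain=8.0),
    # hfr gain sized for reliable detection by the paired screen at six
    # danger trials (paired d ~ 2 at a 15 Hz baseline needs ~12 Hz)
    "hfr": UnitSpec(profile="hfr", baseline_rate=15.0, probability_gain=12.0),
    "nonresponsive": UnitSpec(profile="nonresponsive", baseline_rate=3.0),
}


# ---------------------------------------------------------------------------
# Trial sequence
# ---------------------------------------------------------------------------

def make_trial_sequence(
    design: SessionDesign,
    seed,
    min_iti: float = 20.0,
) -> list[Trial]:
    """Randomized trial order with exact type counts and truncated-exponential ITIs.

    The inter-trial interval (previous trial end to next cue onset) is
    ``min_iti + Exponential(mean_iti - min_iti)``; the first cue onset is
    drawn the same way from session start.  ``min_iti`` must leave room for
    the 10 s pre-cue behavioral baseline.
    """
    rng = _rng(seed)
    if min_iti >= design.mean_iti:
        raise ValueError("min_iti must be < design.mean_iti")
    if min_iti <= 12.5:
        raise ValueError("min_iti must exceed 12.5 s (pre-cue baseline + shock clearance)")
    types = [tt for tt in TRIAL_TYPES for _ in range(design.trial_counts.get(tt, 0))]
    order = rng.permutation(len(types))
    trials: list[Trial] = []
    t = 0.0
    for i, j in enumerate(order, start=1):
        iti = min_iti + rng.exponential(design.mean_iti - min_iti)
        cue_on = t + iti
        cue_off = cue_on + design.cue_duration
        trial_type = types[j]
        shock_on = cue_off + design.trace_to_shock if trial_type in SHOCKED_TYPES else None
        trials.append(Trial(index=i, trial_type=trial_type, cue_on=cue_on,
                            cue_off=cue_off, shock_on=shock_on))
        t = cue_on + design.shock_time + design.shock_duration
    return trials


def session_span_for(trials: list[Trial], design: SessionDesign, pad: float = 15.0) -> float:
    """Span covering all trials plus post-cue analysis room (>= 12 s after offset)."""
    if not trials:
        return pad
    last = trials[-1]
    return max(last.end(design), last.cue_off + 12.0) + pad


# ---------------------------------------------------------------------------
# Nose pokes
# ---------------------------------------------------------------------------

def _poisson_times(rng, rate: float, t0: float, t1: float) -> np.ndarray:
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


@dataclass
class LatentFear:
    """Per-trial latent fear state (the suppression target each trial realizes).

    Units with ``fear_gain != 0`` couple to this shared state, while the
    analysis only ever sees the measured suppression ratio — a noisy proxy
    — exactly as recorded neurons share a fear state with behavior without
    access to the measured ratio itself.
    """

    trial_index: np.ndarray
    rho: np.ndarray

    def total_ratio(self, trial_index: int) -> float:
        pos = int(np.flatnonzero(self.trial_index == trial_index)[0])
        return float(self.rho[pos])


def draw_trial_fear(trials: list[Trial], spec: BehaviorSpec, seed) -> LatentFear:
    """Draw each trial's latent suppression target: clip(target + noise)."""
    spec.validate()
    rng = _rng(seed)
    rho = np.array([
        np.clip(
            spec.target_suppression[cue_of(t.trial_type)]
            + rng.normal(0.0, spec.trial_noise_sd),
            spec.rho_floor, 1.0,
        )
        for t in trials
    ])
    return LatentFear(np.array([t.index for t in trials]), rho)


def simulate_pokes(
    trials: list[Trial],
    spec: BehaviorSpec,
    seed,
    design: SessionDesign | None = None,
    session_span: float | None = None,
    latent: LatentFear | None = None,
) -> BehaviorRecord:
    """Poisson nose pokes: baseline rate outside cues, ratio-implied rate inside.

    For each trial the latent suppression target rho (drawn here unless a
    shared ``latent`` state is supplied) is inverted to a cue poke rate
    b(1 − rho)/(1 + rho), optionally scaled per 1 s interval by
    ``within_cue_profile``.  The floor on rho bounds the implied rate.
    """
    spec.validate()
    rng = _rng(seed)
    design = design or default_design()
    span = session_span if session_span is not None else session_span_for(trials, design)
    if latent is None:
        latent = draw_trial_fear(trials, spec, rng)
    base = _poisson_times(rng, spec.baseline_poke_rate, 0.0, span)
    # carve out cue windows from the baseline train, refill at suppressed rates
    keep = np.ones(base.size, dtype=bool)
    refill = []
    n_int = int(round(design.cue_duration))
    for trial in trials:
        keep &= ~((base >= trial.cue_on) & (base < trial.cue_off))
        rho_trial = latent.total_ratio(trial.index)
        for k in range(n_int):
            rho_k = rho_trial
            if spec.within_cue_profile is not None:
                rho_k = float(np.clip(rho_trial * spec.within_cue_profile[k], -1.0, 1.0))
            rate = ratio_to_rate(spec.baseline_poke_rate, rho_k)
            refill.append(_poisson_times(rng, rate, trial.cue_on + k, trial.cue_on + k + 1))
    times = np.sort(np.concatenate([base[keep]] + refill))
    return BehaviorRecord(times)


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

def _modulation(spec: UnitSpec, trial: Trial, design: SessionDesign, fear: float):
    """Return (window, mod_fn, mod_max) for one trial, or None if unmodulated.

    ``mod_fn`` maps absolute times inside ``window`` to an additive rate on
    top of baseline (may be negative when fear couples negatively; total
    intensity is clipped at zero by the sampler).
    """
    gain = spec.probability_gain * design.cue_probability(trial.trial_type) \
        + spec.fear_gain * fear
    shock_time = trial.cue_on + design.shock_time
    if spec.profile == "nonresponsive" or gain == 0.0:
        return None
    if spec.profile == "onset":
        window = (trial.cue_on, trial.cue_off)

        def mod(t):
            return gain * np.exp(-(t - trial.cue_on) / spec.onset_decay_tau)

    elif spec.profile == "ramping":
        start = trial.cue_on + spec.ramp_start
        end = shock_time if spec.post_cue_behavior == "truncate_after_shock" \
            else trial.cue_off + design.trace_to_shock
        window = (start, end)
        denom = design.shock_time - spec.ramp_start

        def mod(t):
            return gain * np.clip((t - start) / denom, 0.0, 1.0)

    elif spec.profile == "hfr":
        window = (trial.cue_off - 1.0, shock_time)

        def mod(t):
            return gain * np.ones_like(t)

    else:  # pragma: no cover - guarded by validate
        raise ValueError(spec.profile)
    return window, mod, abs(gain)


def simulate_unit(
    trials: list[Trial],
    spec: UnitSpec,
    seed,
    design: SessionDesign | None = None,
    behavior=None,
    session_span: float | None = None,
    unit_id: str = "unit",
    subject_id: str = "",
    session_id: str = "",
) -> UnitRecord:
    """Spike times from an inhomogeneous Poisson process (exact thinning).

    Outside modulated windows the process is homogeneous at
    ``spec.baseline_rate``; inside, candidates are drawn at the bounding
    rate and thinned by intensity/bound.  If ``spec.fear_gain != 0`` the
    per-trial fear value is taken from ``behavior`` — any object exposing
    ``total_ratio(trial_index)``: a :class:`LatentFear` state (preferred;
    see :func:`simulate_session`) or measured
    :class:`vlpag.suppression.SuppressionMeasures`.
    """
    design = design or default_design()
    spec.validate(design)
    if spec.fear_gain != 0.0 and behavior is None:
        raise ValueError("fear_gain != 0 requires per-trial behavior (SuppressionMeasures)")
    rng = _rng(seed)
    span = session_span if session_span is not None else session_span_for(trials, design)
    base = _poisson_times(rng, spec.baseline_rate, 0.0, span)
    keep = np.ones(base.size, dtype=bool)
    extra = []
    for trial in trials:
        fear = behavior.total_ratio(trial.index) if behavior is not None else 0.0
        m = _modulation(spec, trial, design, fear)
        if m is None:
            continue
        (w0, w1), mod, mod_max = m
        # replace the baseline train inside the window with a thinned train
        keep &= ~((base >= w0) & (base < w1))
        bound = spec.baseline_rate + mod_max
        cand = _poisson_times(rng, bound, w0, w1)
        if cand.size:
            lam = np.clip(spec.baseline_rate + mod(cand), 0.0, None)
            cand = cand[rng.uniform(size=cand.size) < lam / bound]
        extra.append(cand)
    times = np.concatenate([base[keep]] + extra) if extra else base[keep]
    if spec.zero_shock_window:
        for trial in trials:
            if trial.shock_on is not None:
                times = times[~((times >= trial.shock_on)
                                & (times < trial.shock_on + design.shock_duration))]
    times = np.sort(times)
    waveform = WaveformFeatures(
        half_duration=spec.half_duration,
        amplitude_ratio=spec.amplitude_ratio,
        baseline_rate=spec.baseline_rate,
    )
    return UnitRecord(unit_id=unit_id, spike_times=times, waveform=waveform,
                      subject_id=subject_id, session_id=session_id)


# ---------------------------------------------------------------------------
# Whole sessions and cohorts
# ---------------------------------------------------------------------------

def _draw_waveform(rng, hfr: bool) -> tuple[float, float]:
    half = float(np.clip(rng.normal(0.25, 0.05), 0.08, 0.6))
    ratio = float(np.clip(rng.normal(0.1 if hfr else -0.1, 0.2), -0.9, 0.9))
    return half, ratio


def simulate_session(
    design: SessionDesign,
    behavior_spec: BehaviorSpec,
    unit_specs: list[UnitSpec],
    seed,
    min_iti: float = 20.0,
    session_id: str = "synthetic",
    subject_id: str = "synthetic",
) -> Session:
    """One full synthetic session: trials, pokes, then units.

    Units with nonzero fear_gain couple to the session's latent per-trial
    fear state — the same state that drives poke suppression — so neural
    'fear' signals track trial-level behavior, not cue identity alone,
    while the analysis only observes the measured (noisy) ratios.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    r_trials, r_fear, r_pokes, r_units = [np.random.default_rng(s) for s in ss.spawn(4)]
    trials = make_trial_sequence(design, r_trials, min_iti=min_iti)
    span = session_span_for(trials, design)
    latent = draw_trial_fear(trials, behavior_spec, r_fear)
    behavior = simulate_pokes(trials, behavior_spec, r_pokes, design=design,
                              session_span=span, latent=latent)
    session = Session(design=design, trials=trials, behavior=behavior, units=[],
                      session_span=span, session_id=session_id, subject_id=subject_id)
    for i, spec in enumerate(unit_specs):
        session.units.append(
            simulate_unit(
                trials, spec, r_units, design=design,
                behavior=latent if spec.fear_gain != 0.0 else None,
                session_span=span, unit_id=f"u{i:03d}",
                subject_id=subject_id, session_id=session_id,
            )
        )
    return session


def simulate_cohort(
    cohort: CohortSpec,
    design: SessionDesign | None = None,
    behavior_spec: BehaviorSpec | None = None,
    seed=0,
    min_iti: float = 20.0,
    profiles: dict[str, UnitSpec] | None = None,
) -> tuple[list[Session], pd.DataFrame]:
    """Sessions plus ground-truth labels for recovery tests.

    Returns ``(sessions, labels)`` where labels has one row per unit with
    its planted profile and firing-rate class (LFR/HFR).
    """
    cohort.validate()
    design = design or default_design()
    behavior_spec = behavior_spec or BehaviorSpec()
    profiles = profiles or DEFAULT_PROFILES
    ss = np.random.SeedSequence(seed)
    sessions, rows = [], []
    for s_idx, child in enumerate(ss.spawn(cohort.n_sessions)):
        rng = np.random.default_rng(child)
        specs, truth = [], []
        for profile, n in cohort.n_units.items():
            for _ in range(n):
                base_spec = profiles[profile]
                hfr = profile == "hfr"
                if profile == "nonresponsive":
                    hfr = rng.uniform() < cohort.hfr_fraction_nonresponsive
                rate = float(np.clip(
                    rng.normal(15.0, 2.0) if hfr else rng.normal(3.0, 1.0), 0.5, None))
                half, ratio = _draw_waveform(rng, hfr)
                specs.append(replace(base_spec, baseline_rate=rate,
                                     half_duration=half, amplitude_ratio=ratio))
                truth.append((profile, "HFR" if hfr else "LFR", rate))
        session_id = f"synthetic-{s_idx:02d}"
        session = simulate_session(
            design, behavior_spec, specs, seed=child.spawn(1)[0],
            min_iti=min_iti, session_id=session_id,
        )
        sessions.append(session)
        for unit, (profile, cls, rate) in zip(session.units, truth):
            rows.append({"session_id": session_id, "unit_id": unit.unit_id,
                         "profile": profile, "rate_class": cls,
                         "nominal_baseline_rate": rate})
    return sessions, pd.DataFrame(rows)
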