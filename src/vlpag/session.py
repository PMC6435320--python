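"""Data model and plain-text I/O for fear-discrimination recording sessions.

A session is one recording day of three-cue Pavlovian fear discrimination:
three 10 s auditory cues predict foot shock with probability 1.00 (danger),
0.375 (uncertainty) or 0.00 (safety); shock (0.5 s) arrives 2 s after cue
offset on danger and uncertainty-shock trials.  A session bundles the trial
schedule, the animal's nose-poke timestamps (reward seeking, suppressed by
fear) and the spike timestamps of each recorded single unit.

Times are seconds from session start as 64-bit floats; all analysis windows
are half-open ``[t0, t1)``.  Trial indices are 1-based.

On disk a session is a directory bundle of diffable plain-text files:
``manifest.json`` (design, ids, span), ``trials.csv``, ``pokes.csv`` and
``units/<unit_id>.csv`` + ``units/<unit_id>.meta.json``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_TYPES",
    "CUES",
    "SHOCKED_TYPES",
    "SessionDesign",
    "Trial",
    "BehaviorRecord",
    "WaveformFeatures",
    "UnitRecord",
    "Session",
    "SchemaError",
    "cue_of",
    "default_design",
    "validate_session",
    "save_session",
    "load_session",
    "load_worked_example",
]

#: Trial types in canonical (regression-table) order.
TRIAL_TYPES = ("danger", "uncertainty_shock", "uncertainty_omission", "safety")

#: Cue identities (uncertainty trial types share one cue).
CUES = ("danger", "uncertainty", "safety")

#: Trial types on which a foot shock is delivered.
SHOCKED_TYPES = ("danger", "uncertainty_shock")


class SchemaError(ValueError):
    """A session file violated the documented schema or an invariant."""


def cue_of(trial_type: str) -> str:
    """Map a trial type to its cue identity (collapses the uncertainty types)."""
    if trial_type in ("uncertainty_shock", "uncertainty_omission"):
        return "uncertainty"
    if trial_type in ("danger", "safety"):
        return trial_type
    raise ValueError(f"unknown trial type: {trial_type!r}")


@dataclass
class SessionDesign:
    """Parameters of the discrimination schedule.

    Defaults are the study conditions: 10 s cues, shock 0.5 s beginning 2 s
    after cue offset, 32 trials (6 danger, 6 uncertainty-shock,
    10 uncertainty-omission, 10 safety), mean inter-trial interval 3.5 min,
    shock probabilities 1.00 / 0.375 / 0.00.
    """

    cue_duration: float = 10.0
    trace_to_shock: float = 2.0
    shock_duration: float = 0.5
    trial_counts: dict[str, int] = field(
        default_factory=lambda: {
            "danger": 6,
            "uncertainty_shock": 6,
            "uncertainty_omission": 10,
            "safety": 10,
        }
    )
    mean_iti: float = 210.0
    shock_probabilities: dict[str, float] = field(
        default_factory=lambda: {"danger": 1.0, "uncertainty": 0.375, "safety": 0.0}
    )

    @property
    def n_trials(self) -> int:
        return sum(self.trial_counts.values())

    @property
    def shock_time(self) -> float:
        """Shock onset relative to cue onset."""
        return self.cue_duration + self.trace_to_shock

    def cue_probability(self, trial_type: str) -> float:
        return self.shock_probabilities[cue_of(trial_type)]

    def validate(self) -> list[str]:
        problems: list[str] = []
        for name in ("cue_duration", "trace_to_shock", "shock_duration", "mean_iti"):
            if getattr(self, name) <= 0:
                problems.append(f"design.{name} must be > 0")
        for tt, n in self.trial_counts.items():
            if tt not in TRIAL_TYPES:
                problems.append(f"design.trial_counts has unknown type {tt!r}")
            elif n < 0:
                problems.append(f"design.trial_counts[{tt!r}] must be >= 0")
        for cue, p in self.shock_probabilities.items():
            if cue not in CUES:
                problems.append(f"design.shock_probabilities has unknown cue {cue!r}")
            elif not 0.0 <= p <= 1.0:
                problems.append(f"design.shock_probabilities[{cue!r}] not in [0, 1]")
        n_us = self.trial_counts.get("uncertainty_shock", 0)
        n_uo = self.trial_counts.get("uncertainty_omission", 0)
        if n_us + n_uo > 0:
            realized = n_us / (n_us + n_uo)
            if abs(realized - self.shock_probabilities.get("uncertainty", np.nan)) > 1e-9:
                problems.append(
                    "design: uncertainty_shock/(uncertainty_shock+uncertainty_omission)"
                    f" = {realized} != shock_probabilities['uncertainty']"
                )
        return problems


def default_design(**overrides) -> SessionDesign:
    """The study's default 32-trial design, with optional field overrides."""
    return dataclasses.replace(SessionDesign(), **overrides)


@dataclass
class Trial:
    index: int  # 1-based
    trial_type: str
    cue_on: float
    cue_off: float
    shock_on: float | None = None

    def validate(self, design: SessionDesign) -> list[str]:
        problems = []
        if self.trial_type not in TRIAL_TYPES:
            problems.append(f"trial {self.index}: unknown type {self.trial_type!r}")
            return problems
        if abs((self.cue_off - self.cue_on) - design.cue_duration) > 1e-9:
            problems.append(f"trial {self.index}: cue_off - cue_on != cue_duration")
        shocked = self.trial_type in SHOCKED_TYPES
        if shocked and self.shock_on is None:
            problems.append(f"trial {self.index}: {self.trial_type} trial missing shock_on")
        if not shocked and self.shock_on is not None:
            problems.append(f"trial {self.index}: {self.trial_type} trial has shock_on")
        if self.shock_on is not None and abs(
            self.shock_on - (self.cue_off + design.trace_to_shock)
        ) > 1e-9:
            problems.append(f"trial {self.index}: shock_on != cue_off + trace_to_shock")
        return problems

    def end(self, design: SessionDesign) -> float:
        """End of the trial's event footprint (cue + trace + shock)."""
        return self.cue_on + design.shock_time + design.shock_duration


@dataclass
class BehaviorRecord:
    """Nose-poke timestamps for one session (sorted, seconds)."""

    poke_times: np.ndarray

    def __post_init__(self):
        self.poke_times = np.asarray(self.poke_times, dtype=float)

    def validate(self, span: float) -> list[str]:
        problems = []
        if np.any(np.diff(self.poke_times) < 0):
            problems.append("behavior: poke_times not nondecreasing")
        if self.poke_times.size and (
            self.poke_times[0] < 0 or self.poke_times[-1] > span
        ):
            problems.append("behavior: poke outside session span")
        return problems


@dataclass
class WaveformFeatures:
    """Mean-waveform summary used for unit classification.

    ``half_duration`` is half the time (ms) from peak depolarization to the
    trough of the after-hyperpolarization; ``amplitude_ratio`` is
    (n − p)/(n + p) where n is the maximal depolarization and p the initial
    hyperpolarization magnitude; ``baseline_rate`` is spikes/s.
    """

    half_duration: float
    amplitude_ratio: float
    baseline_rate: float

    def validate(self) -> list[str]:
        problems = []
        if self.half_duration <= 0:
            problems.append("waveform: half_duration must be > 0")
        if not -1.0 <= self.amplitude_ratio <= 1.0:
            problems.append("waveform: amplitude_ratio not in [-1, 1]")
        if self.baseline_rate < 0:
            problems.append("waveform: baseline_rate must be >= 0")
        return problems


@dataclass
class UnitRecord:
    unit_id: str
    spike_times: np.ndarray
    waveform: WaveformFeatures
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)

    def validate(self, span: float) -> list[str]:
        problems = []
        if np.any(np.diff(self.spike_times) < 0):
            problems.append(f"unit {self.unit_id}: spike_times not nondecreasing")
        if self.spike_times.size and (
            self.spike_times[0] < 0 or self.spike_times[-1] > span
        ):
            problems.append(f"unit {self.unit_id}: spike outside session span")
        problems += [f"unit {self.unit_id}: {p}" for p in self.waveform.validate()]
        return problems


@dataclass
class Session:
    design: SessionDesign
    trials: list[Trial]
    behavior: BehaviorRecord
    units: list[UnitRecord]
    session_span: float
    session_id: str = "session"
    subject_id: str = ""

    def trials_of(self, *trial_types: str) -> list[Trial]:
        return [t for t in self.trials if t.trial_type in trial_types]

    def trials_of_cue(self, cue: str) -> list[Trial]:
        return [t for t in self.trials if cue_of(t.trial_type) == cue]


def validate_session(session: Session) -> list[str]:
    """Return a report of violated invariants (empty report = valid session)."""
    problems = list(session.design.validate())
    counts = {tt: 0 for tt in TRIAL_TYPES}
    prev: Trial | None = None
    for trial in session.trials:
        problems += trial.validate(session.design)
        if trial.trial_type in counts:
            counts[trial.trial_type] += 1
        if prev is not None:
            if trial.cue_on < prev.end(session.design):
                problems.append(
                    f"trials {prev.index} and {trial.index} overlap or are out of order"
                )
        if trial.end(session.design) > session.session_span + 1e-9:
            problems.append(f"trial {trial.index}: extends beyond session span")
        prev = trial
    for tt in TRIAL_TYPES:
        want = session.design.trial_counts.get(tt, 0)
        if counts[tt] != want:
            problems.append(f"trial count for {tt}: {counts[tt]} != design {want}")
    problems += session.behavior.validate(session.session_span)
    for unit in session.units:
        problems += unit.validate(session.session_span)
    return problems


# ---------------------------------------------------------------------------
# Plain-text session bundle I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # full round-trip precision for float64


def save_session(session: Session, path: str | Path) -> None:
    """Write a session bundle; ``load_session`` inverts it exactly."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "session_id": session.session_id,
        "subject_id": session.subject_id,
        "session_span": session.session_span,
        "unit_ids": [u.unit_id for u in session.units],
        "design": {
            "cue_duration": session.design.cue_duration,
            "trace_to_shock": session.design.trace_to_shock,
            "shock_duration": session.design.shock_duration,
            "trial_counts": session.design.trial_counts,
            "mean_iti": session.design.mean_iti,
            "shock_probabilities": session.design.shock_probabilities,
        },
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    trials = pd.DataFrame(
        {
            "index": [t.index for t in session.trials],
            "trial_type": [t.trial_type for t in session.trials],
            "cue_on": [t.cue_on for t in session.trials],
            "cue_off": [t.cue_off for t in session.trials],
            "shock_on": [t.shock_on for t in session.trials],
        }
    )
    trials.to_csv(path / "trials.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame({"time": session.behavior.poke_times}).to_csv(
        path / "pokes.csv", index=False, float_format=_FLOAT_FMT
    )
    units_dir = path / "units"
    units_dir.mkdir(exist_ok=True)
    for unit in session.units:
        pd.DataFrame({"time": unit.spike_times}).to_csv(
            units_dir / f"{unit.unit_id}.csv", index=False, float_format=_FLOAT_FMT
        )
        meta = {
            "unit_id": unit.unit_id,
            "subject_id": unit.subject_id,
            "session_id": unit.session_id,
            "waveform": {
                "half_duration": unit.waveform.half_duration,
                "amplitude_ratio": unit.waveform.amplitude_ratio,
                "baseline_rate": unit.waveform.baseline_rate,
            },
        }
        (units_dir / f"{unit.unit_id}.meta.json").write_text(json.dumps(meta, indent=1))


def _read_times(csv_path: Path, what: str) -> np.ndarray:
    df = pd.read_csv(csv_path, float_precision="round_trip")
    if list(df.columns) != ["time"]:
        raise SchemaError(f"{csv_path}: expected single column 'time' for {what}")
    return df["time"].to_numpy(dtype=float)


def load_session(path: str | Path) -> Session:
    """Load and validate a session bundle written by :func:`save_session`."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no session manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    d = manifest["design"]
    design = SessionDesign(
        cue_duration=float(d["cue_duration"]),
        trace_to_shock=float(d["trace_to_shock"]),
        shock_duration=float(d["shock_duration"]),
        trial_counts={k: int(v) for k, v in d["trial_counts"].items()},
        mean_iti=float(d["mean_iti"]),
        shock_probabilities={k: float(v) for k, v in d["shock_probabilities"].items()},
    )
    tdf = pd.read_csv(path / "trials.csv", float_precision="round_trip")
    required = {"index", "trial_type", "cue_on", "cue_off", "shock_on"}
    if not required.issubset(tdf.columns):
        raise SchemaError(f"trials.csv missing columns {sorted(required - set(tdf.columns))}")
    trials = []
    for line, row in enumerate(tdf.itertuples(index=False), start=2):
        shock_on = None if pd.isna(row.shock_on) else float(row.shock_on)
        trial = Trial(
            index=int(row.index),
            trial_type=str(row.trial_type),
            cue_on=float(row.cue_on),
            cue_off=float(row.cue_off),
            shock_on=shock_on,
        )
        bad = trial.validate(design)
        if bad:
            raise SchemaError(f"trials.csv line {line}: " + "; ".join(bad))
        trials.append(trial)
    behavior = BehaviorRecord(_read_times(path / "pokes.csv", "pokes"))
    units = []
    for unit_id in manifest["unit_ids"]:
        meta = json.loads((path / "units" / f"{unit_id}.meta.json").read_text())
        wf = meta["waveform"]
        units.append(
            UnitRecord(
                unit_id=str(meta["unit_id"]),
                spike_times=_read_times(path / "units" / f"{unit_id}.csv", "spikes"),
                waveform=WaveformFeatures(
                    half_duration=float(wf["half_duration"]),
                    amplitude_ratio=float(wf["amplitude_ratio"]),
                    baseline_rate=float(wf["baseline_rate"]),
                ),
                subject_id=str(meta.get("subject_id", "")),
                session_id=str(meta.get("session_id", "")),
            )
        )
    session = Session(
        design=design,
        trials=trials,
        behavior=behavior,
        units=units,
        session_span=float(manifest["session_span"]),
        session_id=str(manifest.get("session_id", "session")),
        subject_id=str(manifest.get("subject_id", "")),
    )
    problems = validate_session(session)
    if problems:
        raise SchemaError("invalid session: " + "; ".join(problems))
    return session


def load_worked_example() -> pd.DataFrame:
    """The packaged 32-trial example regression input for a first-interval fit.

    Columns: ``trial`` (1-based), ``trial_type``, ``z_firing``, ``constant``,
    ``interval_fear``, ``total_fear``, ``probability``.  The probability column
    carries the programmed shock probabilities 1.00 / 0.375 / 0.00.
    """
    from importlib.resources import files

    with files("vlpag.fixtures").joinpath("worked_example_regression.csv").open() as fh:
        return pd.read_csv(fh)
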