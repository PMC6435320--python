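"""End-to-end pipeline: simulate -> behavior -> classify -> normalize ->
population -> regress -> report.

Each stage writes plain CSV tables into the output directory; the report
stage adds a provenance block (config hash, seed, package versions) and
figure-level summary plots.  The whole run is deterministic given the
seed: identical configuration and seed reproduce byte-identical tables.
Per-unit exclusions (zero-variance normalization, skipped intervals,
undefined ratios) are logged and aggregated in the report, since unit
bookkeeping is part of the analysis contract.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cls
from . import normalize as norm
from . import population as pop
from . import regression as reg
from . import suppression as sup
from . import synth
from .session import CUES, Session, default_design, save_session

__all__ = ["PipelineConfig", "run_pipeline", "export_report", "config_hash"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; serialized into every output directory."""

    out_dir: str = "vlpag_out"
    seed: int = 0
    # design
    mean_iti: float = 210.0
    min_iti: float = 20.0
    # synthetic cohort
    n_onset: int = 10
    n_ramping: int = 5
    n_hfr: int = 2
    n_nonresponsive: int = 23
    n_sessions: int = 2
    baseline_poke_rate: float = 1.0
    trial_noise_sd: float = 0.15
    # analysis
    behavioral_baseline_window: float = 10.0
    neural_baseline_window: float = 2.0
    screen_alpha: float = cls.CUE_ALPHA
    u_assign: float = 0.375
    tuning_grid: tuple = reg.TUNING_GRID
    departure_bonferroni_divisor: int | None = None
    cessation_gap_threshold: float = 5.0
    save_sessions: bool = False
    make_figures: bool = True

    @classmethod
    def from_yaml(cls_, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls_)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls_(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tuning_grid"] = list(self.tuning_grid)
        return d

    def validate(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if not 12.5 < self.min_iti < self.mean_iti:
            raise ValueError("need 12.5 < min_iti < mean_iti")
        if self.behavioral_baseline_window <= self.neural_baseline_window:
            raise ValueError("behavioral baseline should exceed the neural baseline")


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig):
    design = default_design(mean_iti=config.mean_iti)
    cohort = synth.CohortSpec(
        n_units={
            "onset": config.n_onset, "ramping": config.n_ramping,
            "hfr": config.n_hfr, "nonresponsive": config.n_nonresponsive,
        },
        n_sessions=config.n_sessions,
    )
    behavior = synth.BehaviorSpec(
        baseline_poke_rate=config.baseline_poke_rate,
        trial_noise_sd=config.trial_noise_sd,
    )
    sessions, truth = synth.simulate_cohort(
        cohort, design, behavior, seed=config.seed, min_iti=config.min_iti)
    return sessions, truth


def _stage_behavior(config, sessions):
    measures = [
        sup.compute_suppression(s, config.behavioral_baseline_window) for s in sessions
    ]
    table = pd.concat(
        [m.to_frame().assign(session_id=s.session_id)
         for s, m in zip(sessions, measures)],
        ignore_index=True,
    )
    summary = sup.discrimination_summary(measures) if len(measures) >= 2 else None
    return measures, table, summary


def _stage_classify(config, sessions):
    rows = []
    for s in sessions:
        for u in s.units:
            rows.append({
                "session_id": s.session_id,
                "unit_id": f"{s.session_id}/{u.unit_id}",
                "baseline_rate": cls.baseline_firing_rate(
                    u, s.trials, config.neural_baseline_window),
                "half_duration": u.waveform.half_duration,
                "amplitude_ratio": u.waveform.amplitude_ratio,
            })
    features = pd.DataFrame(rows)
    clusters, feature_tests = cls.cluster_units(features, seed=config.seed)
    labels = []
    for s in sessions:
        local = clusters.copy()
        local["unit_id"] = local["unit_id"].str.split("/").str[-1]
        mask = clusters["unit_id"].str.startswith(s.session_id + "/")
        session_clusters = local[mask.to_numpy()]
        lab = cls.classify_population(s, session_clusters, alpha=config.screen_alpha)
        lab.insert(0, "session_id", s.session_id)
        labels.append(lab)
    labels = pd.concat(labels, ignore_index=True)
    labels["unit_key"] = labels["session_id"] + "/" + labels["unit_id"]
    return features, clusters, feature_tests, labels


def _stage_normalize(config, sessions, labels):
    """Whole-epoch Z per unit (cue trial types collapsed to three cues)."""
    z_records, excluded = {}, []
    for s in sessions:
        for u in s.units:
            key = f"{s.session_id}/{u.unit_id}"
            diff = {}
            for cue in CUES:
                trials = s.trials_of_cue(cue)
                diff[cue] = norm.differential_mean_psth(u, trials, s.design)
            try:
                z_records[key] = norm.zscore_unit(diff)
            except norm.NormalizationError as exc:
                excluded.append({"unit_key": key, "reason": str(exc)})
                logger.warning("normalization excluded %s: %s", key, exc)
    return z_records, pd.DataFrame(excluded)


def _cue_bins(design, z):
    """Bins covering the 10 s cue from a whole-epoch Z series."""
    lo = int(round(norm.PRE_CUE / 0.1))
    hi = lo + int(round(design.cue_duration / 0.1))
    return z[lo:hi]


def _stage_population(config, sessions, labels, z_records):
    design = sessions[0].design
    out = {}
    departures, patterns, biases = [], [], []
    for label, interval_name in (("onset", "first"), ("ramping", "last")):
        keys = labels.loc[labels["label"] == label, "unit_key"]
        keys = [k for k in keys if k in z_records]
        if len(keys) < 2:
            logger.info("population stage: <2 %s units; panels omitted", label)
            continue
        z_cue = {
            cue: np.vstack([_cue_bins(design, z_records[k][cue]) for k in keys])
            for cue in CUES
        }
        for cue_a in ("danger", "uncertainty"):
            dep = pop.sliding_departure(
                z_cue[cue_a], z_cue["safety"], comparison=(cue_a, "safety"),
                span=design.cue_duration,
                bonferroni_divisor=config.departure_bonferroni_divisor,
            )
            roi = pop.rate_of_increase(z_cue[cue_a], dep.departure_time_p05,
                                       span=design.cue_duration)
            departures.append({
                "population": label, "comparison": f"{cue_a}_vs_safety",
                "departure_time_p05": dep.departure_time_p05,
                "departure_time_bonferroni": dep.departure_time_bonferroni,
                "bonferroni_divisor": dep.bonferroni_divisor,
                "n_windows": dep.n_windows, "rate_of_increase": roi,
            })
        sl = slice(0, 10) if interval_name == "first" else slice(-10, None)
        vals = np.column_stack([
            [z_cue[cue][i, sl].mean() for i in range(len(keys))] for cue in CUES
        ])
        counts = pop.shuffle_pattern_null(vals, seed=config.seed)
        df = counts.shuffle_summary.copy()
        df.insert(0, "population", label)
        patterns.append(df)
        for (a, ai), (b, bi) in (((("danger"), 0), (("uncertainty"), 1)),
                                 ((("uncertainty"), 1), (("safety"), 2))):
            res = pop.bias_tests(vals[:, ai], vals[:, bi])
            biases.append({"population": label, "pair": f"{a}_vs_{b}",
                           "interval": interval_name, **res})
    out["departure"] = pd.DataFrame(departures)
    out["patterns"] = pd.concat(patterns, ignore_index=True) if patterns else pd.DataFrame()
    out["bias_tests"] = pd.DataFrame(biases)
    # poke-cessation control over labeled (responsive) units
    cess = []
    by_key = {f"{s.session_id}/{u.unit_id}": (s, u) for s in sessions for u in s.units}
    for _, row in labels.iterrows():
        if row["label"] not in ("onset", "ramping"):
            continue
        s, u = by_key[row["unit_key"]]
        r = pop.poke_cessation_control(u, s, config.cessation_gap_threshold)
        cess.append({
            "unit_key": row["unit_key"], "population": row["label"],
            "n_gaps": r.gap_onsets.size,
            "t": r.test.statistic if r.test else np.nan,
            "p": r.test.pvalue if r.test else np.nan,
            "significant": bool(r.test and r.test.pvalue < 0.05),
        })
    out["cessation"] = pd.DataFrame(cess)
    return out


def _stage_regress(config, sessions, labels, measures):
    design = sessions[0].design
    by_session = {s.session_id: (s, m) for s, m in zip(sessions, measures)}
    betas_all, tuning_rows, corr_rows, excluded = [], [], [], []
    postcue_prob_betas = {"onset": {}, "ramping": {}}
    tuning_units = {"onset": {}, "ramping": {}}
    n_int = int(round(design.cue_duration))
    for _, row in labels.iterrows():
        if row["label"] not in ("onset", "ramping"):
            continue
        label = row["label"]
        s, m = by_session[row["session_id"]]
        unit = next(u for u in s.units if u.unit_id == row["unit_id"])
        key = row["unit_key"]
        try:
            z_cue = {
                i: norm.interval_trial_z(
                    unit, s.trials, norm.cue_interval_window(i, design),
                    config.neural_baseline_window)
                for i in range(n_int)
            }
            z_post = {
                i: norm.interval_trial_z(
                    unit, s.trials, norm.postcue_interval_window(i, design),
                    config.neural_baseline_window)
                for i in reg.POSTCUE_INTERVALS
            }
        except norm.NormalizationError as exc:
            excluded.append({"unit_key": key, "reason": str(exc)})
            continue
        sweep = reg.interval_sweep(s, m, z_cue, u_assign=config.u_assign,
                                   unit_id=key)
        sweep.insert(0, "population", label)
        sweep.insert(1, "epoch", "cue")
        betas_all.append(sweep)
        post = reg.postcue_regression(s, m, z_post, u_assign=config.u_assign,
                                      unit_id=key)
        if not post.empty:
            post.insert(0, "population", label)
            post.insert(1, "epoch", "postcue")
            betas_all.append(post)
            prob = post[post["regressor"] == "probability"].set_index("interval")["beta"]
            if len(prob) == len(reg.POSTCUE_INTERVALS):
                postcue_prob_betas[label][key] = prob
        tuning_interval = 0 if label == "onset" else n_int - 1
        tuning_units[label][key] = (s, m, z_cue[tuning_interval], tuning_interval)
    betas = pd.concat(betas_all, ignore_index=True) if betas_all else pd.DataFrame()
    # population tuning curves (per label, pooled across sessions)
    tuning_tables = []
    for label, units in tuning_units.items():
        if not units:
            continue
        builders = {
            key: (lambda u, _t=t: reg.build_regressors(
                _t[0], _t[1], _t[2], _t[3], u_assign=u, unit_id=key))
            for key, t in units.items()
        }
        curve = reg.tuning_from_builders(builders, config.tuning_grid)
        tuning_tables.append(pd.DataFrame({
            "population": label, "u_assign": curve.u_assign,
            "mean_probability_beta": curve.mean_beta,
            "peak": curve.peak, "n_units": len(units),
        }))
    tuning = pd.concat(tuning_tables, ignore_index=True) if tuning_tables else pd.DataFrame()
    # post-cue beta correlation matrices + proportion comparison
    corr_summary = {}
    for label, mapping in postcue_prob_betas.items():
        if len(mapping) < 3:
            continue
        frame = pd.DataFrame(mapping).T
        frame.columns = list(reg.POSTCUE_INTERVALS)
        mat = reg.beta_correlation_matrix(frame)
        corr_summary[label] = mat
        long = mat.cross_block.assign(population=label)
        corr_rows.append(long)
    corr = pd.concat(corr_rows, ignore_index=True) if corr_rows else pd.DataFrame()
    chisq = None
    if {"onset", "ramping"} <= set(corr_summary):
        a, b = corr_summary["onset"], corr_summary["ramping"]
        n_cells = len(a.cross_block)
        chisq = pop.chisq_proportions(
            a.n_significant_05, n_cells, b.n_significant_05, n_cells)
    return betas, tuning, corr, corr_summary, chisq, pd.DataFrame(excluded)


# ---------------------------------------------------------------------------
# Orchestration and report
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; write tables under ``config.out_dir``; return results."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1))
    results: dict = {"config": config, "config_hash": config_hash(config)}
    stage = "simulate"
    try:
        sessions, truth = _stage_simulate(config)
        results["sessions"], results["truth"] = sessions, truth
        _write(truth, out / "ground_truth.csv")
        if config.save_sessions:
            for s in sessions:
                save_session(s, out / "sessions" / s.session_id)

        stage = "behavior"
        measures, sup_table, disc = _stage_behavior(config, sessions)
        results["suppression"] = measures
        _write(sup_table, out / "suppression.csv")
        if disc is not None:
            _write(disc["summary"], out / "discrimination_summary.csv")
            _write(disc["tests"], out / "discrimination_tests.csv")
            _write(disc["interval_means"], out / "discrimination_intervals.csv")
            results["discrimination"] = disc

        stage = "classify"
        features, clusters, feature_tests, labels = _stage_classify(config, sessions)
        results.update(features=features, clusters=clusters, labels=labels)
        _write(labels.drop(columns=["unit_key"]), out / "labels.csv")
        _write(feature_tests, out / "cluster_feature_tests.csv")

        stage = "normalize"
        z_records, z_excluded = _stage_normalize(config, sessions, labels)
        results["z_records"] = z_records
        if not z_excluded.empty:
            _write(z_excluded, out / "normalization_exclusions.csv")

        stage = "population"
        pop_out = _stage_population(config, sessions, labels, z_records)
        results["population"] = pop_out
        for name in ("departure", "patterns", "bias_tests", "cessation"):
            _write(pop_out[name], out / f"{name}.csv")

        stage = "regress"
        betas, tuning, corr, corr_summary, chisq, reg_excluded = _stage_regress(
            config, sessions, labels, measures)
        results.update(betas=betas, tuning=tuning, beta_corr=corr,
                       beta_corr_summary=corr_summary, corr_chisq=chisq)
        _write(betas, out / "betas.csv")
        _write(tuning, out / "tuning.csv")
        _write(corr, out / "beta_corr.csv")
        if not betas.empty:
            cue_betas = betas[betas["epoch"] == "cue"]
            summaries = []
            for pop_name, grp in cue_betas.groupby("population"):
                s = reg.population_interval_summary(grp)
                s.insert(0, "population", pop_name)
                summaries.append(s)
            if summaries:
                _write(pd.concat(summaries, ignore_index=True),
                       out / "beta_interval_summary.csv")

        stage = "report"
        export_report(results, out, make_figures=config.make_figures)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results


def export_report(results: dict, out_dir: str | Path, make_figures: bool = True) -> None:
    """Summary JSON with provenance, plus figure-level plots of the tables."""
    out = Path(out_dir)
    config = results["config"]
    labels = results.get("labels")
    counts = labels["label"].value_counts().to_dict() if labels is not None else {}
    summary = {
        "provenance": {
            "config_hash": results["config_hash"],
            "seed": config.seed,
            "versions": _versions(),
        },
        "n_sessions": len(results.get("sessions", [])),
        "n_units": int(len(labels)) if labels is not None else 0,
        "label_counts": counts,
        "notes": [],
    }
    if results.get("tuning") is not None and len(results["tuning"]):
        for pop_name, grp in results["tuning"].groupby("population"):
            summary[f"tuning_peak_{pop_name}"] = float(grp["peak"].iloc[0])
    else:
        summary["notes"].append("tuning panels omitted: no labeled population")
    if results.get("corr_chisq") is not None:
        summary["corr_proportion_chisq"] = {
            "chi2": results["corr_chisq"].statistic,
            "p": results["corr_chisq"].pvalue,
        }
    (out / "report.json").write_text(json.dumps(summary, indent=1, default=str))
    if make_figures:
        _figures(results, out)


def _versions() -> dict:
    import scipy
    import sklearn
    import statsmodels

    return {
        "vlpag": "0.1.0", "numpy": np.__version__, "scipy": scipy.__version__,
        "pandas": pd.__version__, "statsmodels": statsmodels.__version__,
        "sklearn": sklearn.__version__,
    }


def _figures(results: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    disc = results.get("discrimination")
    if disc is not None:
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
        s = disc["summary"]
        ax1.bar(s["cue"], s["mean_total_ratio"], yerr=s["sem_total_ratio"],
                color=["firebrick", "purple", "steelblue"])
        ax1.set_ylabel("suppression ratio (10 s cue)")
        im = disc["interval_means"]
        for cue, color in zip(CUES, ("firebrick", "purple", "steelblue")):
            ax2.errorbar(im["interval"], im[f"mean_{cue}"], im[f"sem_{cue}"],
                         label=cue, color=color)
        ax2.set_xlabel("1 s cue interval")
        ax2.legend()
        fig.tight_layout()
        fig.savefig(figdir / "discrimination.png", dpi=120)
        plt.close(fig)
    tuning = results.get("tuning")
    if tuning is not None and len(tuning):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for pop_name, grp in tuning.groupby("population"):
            ax.plot(grp["u_assign"], grp["mean_probability_beta"], "-o", label=pop_name)
        ax.axvline(results["config"].u_assign, ls="--", color="gray",
                   label="programmed u")
        ax.set_xlabel("uncertainty probability assignment")
        ax.set_ylabel("mean probability beta")
        ax.legend()
        fig.tight_layout()
        fig.savefig(figdir / "tuning.png", dpi=120)
        plt.close(fig)
    betas = results.get("betas")
    if betas is not None and len(betas):
        cue_betas = betas[betas["epoch"] == "cue"]
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
        for ax, pop_name in zip(axes, ("onset", "ramping")):
            sub = cue_betas[cue_betas["population"] == pop_name]
            if sub.empty:
                ax.set_title(f"{pop_name}: omitted (no units)")
                continue
            g = sub.groupby(["interval", "regressor"])["beta"].mean().unstack()
            g.plot(ax=ax, marker="o", legend=ax is axes[0])
            ax.set_title(pop_name)
            ax.set_xlabel("1 s cue interval")
        axes[0].set_ylabel("mean beta")
        fig.tight_layout()
        fig.savefig(figdir / "betas_by_interval.png", dpi=120)
        plt.close(fig)
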