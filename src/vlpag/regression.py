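"""Trial-by-trial regression of single-unit firing on fear output and threat.

For one unit and one time interval, the 32 trials of a session are ordered
by type and each contributes one row: normalized firing (response),
a constant, the interval-fear suppression ratio (that trial, that
interval), the total-fear suppression ratio (that trial, whole 10 s cue)
and the cue's programmed shock probability.  Ordinary least squares yields
a beta per regressor; the beta for probability versus the betas for fear
measures the degree to which firing tracks threat probability rather than
fear output.

The threat-tuning sweep refits the regression nine times with the
uncertainty cue's probability assignment varied over 0–1 in 0.125 steps
(danger fixed at 1, safety at 0); the mean probability beta across units
per assignment forms a tuning curve whose peak locates the probability the
population is tuned to.

Post-cue regression uses 500 ms intervals over the 5 s after cue offset,
drops the total-fear regressor (it samples only the cue period) and skips
the 2.0–2.5 s shock interval — nine interval fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .session import TRIAL_TYPES, Session, cue_of
from .suppression import SuppressionMeasures

__all__ = [
    "RankError",
    "RegressorMatrix",
    "BetaCoefficients",
    "TuningCurve",
    "BetaCorrelationMatrix",
    "TUNING_GRID",
    "DELAY_INTERVALS",
    "POSTSHOCK_INTERVALS",
    "POSTCUE_INTERVALS",
    "build_regressors",
    "matrix_from_frame",
    "fit_ols",
    "fit_worked_example",
    "interval_sweep",
    "population_interval_summary",
    "tuning_sweep",
    "tuning_from_builders",
    "postcue_regression",
    "beta_correlation_matrix",
    "pairs_regression",
]

#: Uncertainty-probability assignments of the tuning sweep.
TUNING_GRID = tuple(np.round(np.arange(0.0, 1.001, 0.125), 3))

#: Post-cue 500 ms intervals (0-based): delay 0–3, shock 4 (excluded), post-shock 5–9.
DELAY_INTERVALS = (0, 1, 2, 3)
SHOCK_INTERVAL = 4
POSTSHOCK_INTERVALS = (5, 6, 7, 8, 9)
POSTCUE_INTERVALS = DELAY_INTERVALS + POSTSHOCK_INTERVALS

DEFAULT_SUBSET = ("interval_fear", "total_fear", "probability")


class RankError(ValueError):
    """Design matrix is rank deficient (collinear or constant regressors)."""


@dataclass
class RegressorMatrix:
    """One unit × interval design: 32 rows ordered by trial type."""

    frame: pd.DataFrame
    subset: tuple[str, ...]
    unit_id: str = ""
    interval: object = None
    u_assign: float = 0.375

    @property
    def columns(self) -> list[str]:
        return ["constant", *self.subset]

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.columns].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["z_firing"].to_numpy(dtype=float)

    def check_rank(self) -> None:
        X = self.X
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            bad = []
            for j, col in enumerate(self.columns):
                reduced = np.delete(X, j, axis=1)
                if np.linalg.matrix_rank(reduced) == rank:
                    bad.append(col)
            raise RankError(f"design matrix rank deficient; collinear columns: {bad}")


def _type_order(frame: pd.DataFrame) -> pd.DataFrame:
    key = {tt: i for i, tt in enumerate(TRIAL_TYPES)}
    return frame.sort_values(
        by=["trial_type", "trial"], key=lambda s: s.map(key) if s.name == "trial_type" else s,
        kind="stable",
    ).reset_index(drop=True)


def _probability(trial_type: str, u_assign: float) -> float:
    return {"danger": 1.0, "uncertainty": u_assign, "safety": 0.0}[cue_of(trial_type)]


def build_regressors(
    session: Session,
    suppression: SuppressionMeasures,
    z_firing: np.ndarray,
    interval: int,
    u_assign: float = 0.375,
    subset: tuple[str, ...] = DEFAULT_SUBSET,
    epoch: str = "cue",
    unit_id: str = "",
) -> RegressorMatrix:
    """Assemble the design for one unit × interval.

    ``z_firing`` is the per-trial normalized firing for the interval,
    aligned with ``session.trials`` order; ``interval`` is the 0-based 1 s
    cue interval (epoch 'cue') or 500 ms post-cue interval (epoch
    'postcue', where interval fear comes from the matching post-cue
    suppression window).
    """
    if epoch not in ("cue", "postcue"):
        raise ValueError("epoch must be 'cue' or 'postcue'")
    if epoch == "cue":
        ifear = suppression.intervals[:, interval]
    else:
        if suppression.postcue is None:
            raise ValueError("suppression measures lack post-cue windows")
        ifear = suppression.postcue[:, interval]
    frame = pd.DataFrame({
        "trial": suppression.trial_index,
        "trial_type": suppression.trial_type,
        "z_firing": np.asarray(z_firing, dtype=float),
        "constant": 1.0,
        "interval_fear": ifear,
        "total_fear": suppression.total,
        "probability": [
            _probability(tt, u_assign) for tt in suppression.trial_type
        ],
    })
    frame = _type_order(frame)
    matrix = RegressorMatrix(frame=frame, subset=tuple(subset), unit_id=unit_id,
                             interval=interval, u_assign=u_assign)
    matrix.check_rank()
    return matrix


def matrix_from_frame(
    frame: pd.DataFrame,
    subset: tuple[str, ...] = DEFAULT_SUBSET,
    **meta,
) -> RegressorMatrix:
    """Wrap an already-assembled regression table (e.g. the packaged example)."""
    matrix = RegressorMatrix(frame=frame.copy(), subset=tuple(subset), **meta)
    matrix.check_rank()
    return matrix


@dataclass
class BetaCoefficients:
    """Per-regressor OLS output for one unit × interval."""

    table: pd.DataFrame  # index: regressor; columns: beta, se, t, p
    unit_id: str = ""
    interval: object = None
    u_assign: float = 0.375
    subset: tuple[str, ...] = DEFAULT_SUBSET

    def beta(self, regressor: str) -> float:
        return float(self.table.loc[regressor, "beta"])

    def p(self, regressor: str) -> float:
        return float(self.table.loc[regressor, "p"])


def fit_ols(matrix: RegressorMatrix) -> BetaCoefficients:
    """Ordinary least squares with intercept; classical t-based p values.

    Standard errors come from the residual variance with n − k degrees of
    freedom — the standard output of any textbook OLS routine.
    """
    matrix.check_rank()
    X, y = matrix.X, matrix.y
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than regressors")
    fit = sm.OLS(y, X).fit()
    table = pd.DataFrame({
        "beta": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues,
    }, index=matrix.columns)
    if not np.all(np.isfinite(table["beta"])):
        raise RankError("non-finite coefficients; design nearly singular")
    return BetaCoefficients(table=table, unit_id=matrix.unit_id,
                            interval=matrix.interval, u_assign=matrix.u_assign,
                            subset=matrix.subset)


def fit_worked_example() -> BetaCoefficients:
    """Fit the packaged 32-trial example regression input."""
    from .session import load_worked_example

    return fit_ols(matrix_from_frame(load_worked_example()))


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def interval_sweep(
    session: Session,
    suppression: SuppressionMeasures,
    z_by_interval: dict[int, np.ndarray],
    u_assign: float = 0.375,
    subset: tuple[str, ...] = DEFAULT_SUBSET,
    epoch: str = "cue",
    unit_id: str = "",
) -> pd.DataFrame:
    """Fit every interval for one unit; failed intervals are logged and skipped.

    Returns a long DataFrame (unit_id, interval, regressor, beta, se, t, p).
    """
    rows = []
    for interval, z in z_by_interval.items():
        try:
            matrix = build_regressors(session, suppression, z, interval,
                                      u_assign=u_assign, subset=subset,
                                      epoch=epoch, unit_id=unit_id)
            betas = fit_ols(matrix)
        except (RankError, ValueError) as exc:
            import logging

            logging.getLogger(__name__).warning(
                "unit %s interval %s skipped: %s", unit_id, interval, exc)
            continue
        for reg in betas.table.index:
            rows.append({
                "unit_id": unit_id, "interval": interval, "regressor": reg,
                **betas.table.loc[reg].to_dict(),
            })
    return pd.DataFrame(rows)


def population_interval_summary(
    betas: pd.DataFrame,
    n_tests: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Population mean ± SEM beta per regressor per interval with one-sample t.

    ``betas`` is the long frame from :func:`interval_sweep` over many
    units.  The one-sample t against zero carries a Bonferroni-corrected
    threshold alpha / n_tests (0.005 for ten intervals).
    """
    rows = []
    for (interval, reg), grp in betas.groupby(["interval", "regressor"]):
        vals = grp["beta"].to_numpy()
        t, p = (np.nan, np.nan)
        if vals.size >= 2 and np.std(vals) > 0:
            t, p = stats.ttest_1samp(vals, 0.0)
        rows.append({
            "interval": interval, "regressor": reg,
            "mean_beta": vals.mean(), "sem_beta": stats.sem(vals) if vals.size > 1 else np.nan,
            "t": float(t), "p": float(p), "n_units": vals.size,
            "alpha_corrected": alpha / n_tests,
            "significant": bool(p < alpha / n_tests) if np.isfinite(p) else False,
        })
    return pd.DataFrame(rows)


@dataclass
class TuningCurve:
    u_assign: np.ndarray
    mean_beta: np.ndarray
    per_unit: pd.DataFrame  # unit_id × u_assign probability betas
    peak: float = field(init=False)

    def __post_init__(self):
        self.peak = float(self.u_assign[int(np.argmax(self.mean_beta))])


def tuning_from_builders(
    builders: dict[str, callable],
    grid=TUNING_GRID,
) -> TuningCurve:
    """Tuning curve from per-unit matrix builders (u_assign -> RegressorMatrix)."""
    records = {}
    for unit_id, build in builders.items():
        records[unit_id] = {
            u: fit_ols(build(u)).beta("probability") for u in grid
        }
    per_unit = pd.DataFrame(records).T
    per_unit.index.name = "unit_id"
    mean_beta = per_unit.mean(axis=0).to_numpy()
    return TuningCurve(u_assign=np.asarray(grid, dtype=float),
                       mean_beta=mean_beta, per_unit=per_unit)


def tuning_sweep(
    session: Session,
    suppression: SuppressionMeasures,
    unit_z: dict[str, np.ndarray],
    interval: int = 0,
    grid=TUNING_GRID,
    subset: tuple[str, ...] = DEFAULT_SUBSET,
    epoch: str = "cue",
) -> TuningCurve:
    """Nine-assignment threat-tuning curve for a set of units in one interval.

    ``unit_z`` maps unit_id to the per-trial Z firing for ``interval``.
    The curve's value at the programmed assignment (0.375) equals the base
    regression's probability beta by construction.
    """
    builders = {
        uid: (lambda u, _z=z, _uid=uid: build_regressors(
            session, suppression, _z, interval, u_assign=u, subset=subset,
            epoch=epoch, unit_id=_uid))
        for uid, z in unit_z.items()
    }
    return tuning_from_builders(builders, grid)


def postcue_regression(
    session: Session,
    suppression: SuppressionMeasures,
    z_by_interval: dict[int, np.ndarray],
    u_assign: float = 0.375,
    unit_id: str = "",
) -> pd.DataFrame:
    """Nine post-cue 500 ms interval fits: constant + interval fear + probability.

    The total-fear regressor is omitted (it samples only the cue period)
    and the shock interval (2.0–2.5 s post-offset) is excluded.
    """
    z = {i: z_by_interval[i] for i in POSTCUE_INTERVALS if i in z_by_interval}
    return interval_sweep(
        session, suppression, z, u_assign=u_assign,
        subset=("interval_fear", "probability"), epoch="postcue", unit_id=unit_id,
    )


# ---------------------------------------------------------------------------
# Beta correlation matrix and pairs analysis
# ---------------------------------------------------------------------------

@dataclass
class BetaCorrelationMatrix:
    intervals: tuple[int, ...]
    r_squared: pd.DataFrame
    pvalues: pd.DataFrame
    cross_block: pd.DataFrame  # delay × post-shock cells
    n_significant_05: int
    n_significant_bonferroni: int
    bonferroni_alpha: float


def beta_correlation_matrix(
    probability_betas: pd.DataFrame,
    bonferroni_alpha: float = 0.05 / 5,
) -> BetaCorrelationMatrix:
    """Interval × interval Pearson R² of per-unit probability betas.

    ``probability_betas`` is units × post-cue intervals (columns are the
    nine interval ids).  The delay × post-shock block (4 × 5 = 20 cells)
    is the quantity of interest: its significant-cell counts at p < 0.05
    and at the Bonferroni threshold (0.05/5, five tests per interval) are
    reported.  Degenerate (zero-variance) columns yield NaN cells.
    """
    if probability_betas.shape[0] < 3:
        raise ValueError("need >= 3 units")
    cols = tuple(probability_betas.columns)
    n = len(cols)
    r2 = np.full((n, n), np.nan)
    pv = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            x = probability_betas.iloc[:, i].to_numpy(dtype=float)
            y = probability_betas.iloc[:, j].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r, p = stats.pearsonr(x, y)
            r2[i, j], pv[i, j] = r**2, p
    r2_df = pd.DataFrame(r2, index=cols, columns=cols)
    pv_df = pd.DataFrame(pv, index=cols, columns=cols)
    delay = [c for c in cols if c in DELAY_INTERVALS]
    post = [c for c in cols if c in POSTSHOCK_INTERVALS]
    cells = []
    for d in delay:
        for s in post:
            cells.append({
                "delay_interval": d, "postshock_interval": s,
                "r_squared": r2_df.loc[d, s], "p": pv_df.loc[d, s],
            })
    cross = pd.DataFrame(cells)
    finite = cross["p"].to_numpy()
    return BetaCorrelationMatrix(
        intervals=cols, r_squared=r2_df, pvalues=pv_df, cross_block=cross,
        n_significant_05=int(np.nansum(finite < 0.05)),
        n_significant_bonferroni=int(np.nansum(finite < bonferroni_alpha)),
        bonferroni_alpha=bonferroni_alpha,
    )


def pairs_regression(
    onset_z: np.ndarray,
    ramping_z: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-interval simple regression: ramping unit firing predicts onset firing.

    ``onset_z``/``ramping_z`` are (trials × intervals) per-trial Z for two
    units recorded in the same session, aligned on trials.  Each interval
    is fit with an intercept; the independence criterion flags intervals
    with a significant (p < alpha), *negative* beta.  Zero-variance
    predictor intervals are skipped.
    """
    onset_z = np.atleast_2d(np.asarray(onset_z, dtype=float))
    ramping_z = np.atleast_2d(np.asarray(ramping_z, dtype=float))
    if onset_z.shape != ramping_z.shape:
        raise ValueError("units must share trial × interval shape")
    rows = []
    for k in range(onset_z.shape[1]):
        x, y = ramping_z[:, k], onset_z[:, k]
        if np.std(x) == 0:
            continue
        X = np.column_stack([np.ones_like(x), x])
        fit = sm.OLS(y, X).fit()
        beta, p = float(fit.params[1]), float(fit.pvalues[1])
        rows.append({
            "interval": k, "beta": beta, "p": p,
            "negative_significant": bool(p < alpha and beta < 0),
        })
    return pd.DataFrame(rows)
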