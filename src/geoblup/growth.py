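"""Stage 1: per-individual logistic growth fits and extrapolation.

Each phenotyped individual carries a short series of repeated measures
(five time points in the motivating design).  A three-parameter logistic
mean

    E(y_it) = alpha_i / (1 + beta_i * exp(-gamma_i * t))

is fitted to each series by nonlinear least squares, separately per
individual; with five observations this leaves two error degrees of
freedom per individual.  Residual variance is then pooled across
individuals (sigma2 = total RSS / total error df = RSS/(2n) in the
five-point design) and the fits are re-evaluated with the residual
variance fixed at the pooled value to extrapolate each trait to a target
time beyond the last measurement, together with a delta-method standard
error.  The squared standard error is treated downstream as a *known*
within-individual error variance.

Fixing the residual variance does not move the least-squares optimum: the
second pass changes only the parameter covariance (pooled_variance *
(J'J)^-1), hence the prediction standard errors, never the predictions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "PhenotypeSeries",
    "LogisticFit",
    "Stage1Result",
    "logistic_mean",
    "fit_logistic",
    "pooled_variance",
    "predict_target",
    "run_stage1",
    "series_from_long",
]


def logistic_mean(t, alpha, beta, gamma):
    """alpha / (1 + beta * exp(-gamma * t)), computed in log space for stability."""
    t = np.asarray(t, dtype=float)
    if beta <= 0:
        return np.full_like(t, alpha / (1.0 + beta))
    # log(1 + beta*exp(-gamma*t)) without overflow
    log_denom = np.logaddexp(0.0, math.log(beta) - gamma * t)
    return alpha * np.exp(-log_denom)


def _jacobian(t, alpha, beta, gamma):
    """Analytic Jacobian of the logistic mean wrt (alpha, beta, gamma)."""
    t = np.asarray(t, dtype=float)
    b = max(beta, 1e-300)
    u = math.log(b) - gamma * t
    log_denom = np.logaddexp(0.0, u)
    d_alpha = np.exp(-log_denom)
    core = np.exp(u - 2.0 * log_denom)  # beta*exp(-gamma t) / denom^2
    d_beta = -(alpha / b) * core
    d_gamma = alpha * t * core
    return np.column_stack([d_alpha, d_beta, d_gamma])


@dataclass(frozen=True)
class PhenotypeSeries:
    """Repeated measures (t, y) for one individual; times strictly increasing."""

    individual_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.values, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and values must be matching 1-d arrays")
        if len(t) < 4:
            raise ValueError(
                f"individual {self.individual_id!r}: need >= 4 observations for a "
                f"3-parameter fit with error df, got {len(t)}"
            )
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"individual {self.individual_id!r}: times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError(f"individual {self.individual_id!r}: non-finite observation")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", y)


@dataclass(frozen=True)
class LogisticFit:
    individual_id: str
    alpha: float
    beta: float
    gamma: float
    rss: float
    error_df: int
    converged: bool
    message: str = ""

    @property
    def params(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])


@dataclass(frozen=True)
class Stage1Result:
    """Extrapolated traits with known within-individual error variances.

    ``table`` has one row per individual: prediction at the target time,
    its standard error, and error_variance = se**2.
    """

    table: pd.DataFrame
    pooled_variance: float
    pooled_df: int
    target_time: float
    n_individuals: int
    failures: tuple[str, ...] = ()

    @property
    def predictions(self) -> pd.Series:
        return self.table["prediction"]

    @property
    def error_variances(self) -> pd.Series:
        return self.table["error_variance"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    @classmethod
    def from_csv(cls, path, target_time: float = np.nan) -> "Stage1Result":
        table = pd.read_csv(path, index_col=0)
        table.index = table.index.map(str)
        return cls(
            table=table,
            pooled_variance=float("nan"),
            pooled_df=0,
            target_time=target_time,
            n_individuals=len(table),
        )


def _starting_points(t: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Deterministic multi-start policy derived from the data, plus a fixed grid."""
    ymax = float(np.max(y))
    ymin = float(np.min(y))
    span = max(t[-1] - t[0], 1.0)
    starts: list[np.ndarray] = []
    if ymax > 0:
        a0 = 1.05 * ymax
        y0 = y[0] if y[0] > 0 else max(ymin, 1e-3 * ymax)
        b0 = max(a0 / max(y0, 1e-12) - 1.0, 1e-3)
        # log-slope of y/(a0 - y) between first and last point approximates gamma
        with np.errstate(divide="ignore", invalid="ignore"):
            lo = np.log(np.clip(y / np.clip(a0 - y, 1e-9, None), 1e-9, None))
        g0 = (lo[-1] - lo[0]) / span
        if not np.isfinite(g0) or g0 <= 0:
            g0 = 2.0 / span
        starts.append(np.array([a0, b0, g0]))
    base = abs(ymax) if ymax != 0 else 1.0
    for fa in (1.1, 2.0):
        for b in (1.0, 9.0):
            for fg in (1.0, 4.0):
                starts.append(np.array([fa * base, b, fg / span]))
    return starts


def fit_logistic(series: PhenotypeSeries) -> LogisticFit:
    """Nonlinear least-squares logistic fit for one individual.

    Deterministic given the fixed multi-start policy.  Non-convergence of
    every start returns the best attempt flagged ``converged=False``.
    """
    t, y = series.times, series.values
    if np.ptp(y) == 0:
        # degenerate flat series: boundary fit y == alpha/(1+beta) everywhere
        return LogisticFit(
            series.individual_id,
            alpha=float(y[0]),
            beta=0.0 if y[0] != 0 else 1e-12,
            gamma=0.0,
            rss=0.0,
            error_df=len(t) - 3,
            converged=False,
            message="constant series; boundary fit",
        )

    def resid(p):
        return logistic_mean(t, *p) - y

    def jac(p):
        return _jacobian(t, *p)

    best = None
    lb = np.array([-np.inf, 1e-12, -np.inf])
    ub = np.array([np.inf, np.inf, np.inf])
    for x0 in _starting_points(t, y):
        x0 = np.clip(x0, lb + 1e-12, None)
        try:
            sol = least_squares(resid, x0, jac=jac, bounds=(lb, ub),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400)
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(f"logistic fit failed for individual {series.individual_id!r}")
    rss = float(2.0 * best.cost)
    return LogisticFit(
        series.individual_id,
        alpha=float(best.x[0]),
        beta=float(best.x[1]),
        gamma=float(best.x[2]),
        rss=rss,
        error_df=len(t) - 3,
        converged=bool(best.success),
        message=str(best.message),
    )


def pooled_variance(fits: list[LogisticFit]) -> float:
    """(sum of RSS) / (sum of error df) across individuals.

    With five observations per individual this is RSS/(2n): each individual
    contributes two error degrees of freedom.
    """
    if not fits:
        raise ValueError("no fits to pool")
    total_df = sum(f.error_df for f in fits)
    if total_df <= 0:
        raise ValueError("no residual degrees of freedom to pool")
    return float(sum(f.rss for f in fits) / total_df)


def predict_target(
    series: PhenotypeSeries,
    fit: LogisticFit,
    pooled_var: float,
    target_time: float,
) -> tuple[float, float]:
    """Extrapolated mean at ``target_time`` and its delta-method standard error.

    The parameter covariance is ``pooled_var * (J'J)^-1`` with J the Jacobian
    at the least-squares optimum (the residual variance fixed at the pooled
    estimate), and se^2 = grad' Cov grad with grad the mean-function gradient
    at the target time.  A singular J'J yields se = inf (flagged downstream).
    """
    p = fit.params
    pred = float(logistic_mean(target_time, *p))
    if pooled_var == 0:
        return pred, 0.0
    J = _jacobian(series.times, *p)
    JtJ = J.T @ J
    grad = _jacobian(np.array([target_time]), *p)[0]
    try:
        cov_grad = np.linalg.solve(JtJ, grad)
    except np.linalg.LinAlgError:
        return pred, float("inf")
    var = float(pooled_var * grad @ cov_grad)
    if var < 0:
        var = 0.0
    return pred, float(np.sqrt(var))


def run_stage1(series_list: list[PhenotypeSeries], target_time: float) -> Stage1Result:
    """Two-pass stage-1 procedure over all phenotyped individuals.

    Pass 1 fits each series and pools the residual variance; pass 2
    re-evaluates each fit with the pooled variance fixed to extrapolate to
    ``target_time`` with a standard error.  Individuals whose prediction
    variance is singular are reported in ``failures`` and excluded from
    the output table.
    """
    if not series_list:
        raise ValueError("no phenotype series supplied")
    fits = [fit_logistic(s) for s in series_list]
    sigma2 = pooled_variance(fits)
    rows = []
    failures = []
    for s, f in zip(series_list, fits):
        pred, se = predict_target(s, f, sigma2, target_time)
        if not np.isfinite(se):
            failures.append(s.individual_id)
            warnings.warn(
                f"individual {s.individual_id!r}: singular prediction variance; excluded",
                stacklevel=2,
            )
            continue
        if not f.converged:
            failures_note = f.message
        rows.append(
            {
                "individual": s.individual_id,
                "prediction": pred,
                "se": se,
                "error_variance": se**2,
                "alpha": f.alpha,
                "beta": f.beta,
                "gamma": f.gamma,
                "rss": f.rss,
                "converged": f.converged,
            }
        )
    table = pd.DataFrame(rows).set_index("individual")
    return Stage1Result(
        table=table,
        pooled_variance=sigma2,
        pooled_df=sum(f.error_df for f in fits),
        target_time=float(target_time),
        n_individuals=len(series_list),
        failures=tuple(failures),
    )


def series_from_long(phenotypes: pd.DataFrame) -> list[PhenotypeSeries]:
    """Long-format table (individual, time, value) -> list of PhenotypeSeries."""
    required = {"individual", "time", "value"}
    if not required.issubset(phenotypes.columns):
        raise ValueError(f"phenotype table needs columns {sorted(required)}")
    out = []
    for ind, grp in phenotypes.groupby("individual", sort=False):
        grp = grp.sort_values("time")
        out.append(
            PhenotypeSeries(str(ind), grp["time"].to_numpy(float), grp["value"].to_numpy(float))
        )
    return out
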