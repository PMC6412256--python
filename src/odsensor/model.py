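"""Ordinary least squares on the log design matrix, diagnostics, and CV.

The regression is

    yhat_i = beta0 + beta1 x1(i) + ... + beta9 x9(i)

fitted by a rank-revealing least-squares solve on log-transformed data, so
predicted OD is ``exp(yhat)``.  Goodness of fit is

    R^2 = 1 - sum_i (y_i - yhat_i)^2 / sum_i (y_i - ybar)^2

over whatever prediction set is being scored (training rows, or pooled
held-out predictions under cross-validation, where R^2 may be negative).
Diagnostics cover residual autocorrelation against a +-2/sqrt(N) whiteness
band and a one-sample Kolmogorov-Smirnov normality check on standardised
residuals.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .features import DESIGN_COLUMNS

__all__ = [
    "FitResult",
    "DiagnosticsReport",
    "CVResult",
    "fit_ols",
    "r_squared",
    "predict_od",
    "predict_log",
    "residual_autocorrelation",
    "ks_normality",
    "whiteness_bound",
    "diagnose",
    "cross_validate",
    "plot_diagnostics",
]

log = logging.getLogger(__name__)

N_PREDICTORS = 9


@dataclass
class FitResult:
    beta: np.ndarray              # (10,) intercept first
    fitted: np.ndarray            # yhat per training row
    residuals: np.ndarray         # y - yhat
    r_squared: float
    n: int
    rank: int
    experiment_ids: list[str] = field(default_factory=list)
    log_offset: float = 0.0

    @property
    def full_rank(self) -> bool:
        return self.rank == N_PREDICTORS + 1

    def to_json(self, path) -> None:
        payload = {
            "beta": self.beta.tolist(),
            "r_squared": self.r_squared,
            "n": self.n,
            "rank": self.rank,
            "experiment_ids": self.experiment_ids,
            "log_offset": self.log_offset,
            "transform": "natural-log",
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            beta=np.asarray(payload["beta"], dtype=float),
            fitted=np.array([]),
            residuals=np.array([]),
            r_squared=payload["r_squared"],
            n=payload["n"],
            rank=payload["rank"],
            experiment_ids=list(payload.get("experiment_ids", [])),
            log_offset=float(payload.get("log_offset", 0.0)),
        )


@dataclass
class DiagnosticsReport:
    lags: list[int]
    autocorrelation: list[float]
    whiteness_bound: float
    ks_statistic: float
    ks_p: float
    residual_mean: float
    low_power: bool
    fitted: list[float] = field(default_factory=list)
    residuals: list[float] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class CVResult:
    scheme: str
    predictions: pd.DataFrame     # experiment_id, time_h, response, prediction, residual
    r_squared: float
    fold_betas: list[np.ndarray]
    seed: int | None = None


def _design_arrays(rows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = rows[DESIGN_COLUMNS].to_numpy(dtype=float)
    y = rows["response"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("response contains missing values; supply OD for training rows")
    return np.column_stack([np.ones(len(X)), X]), y


def fit_ols(rows: pd.DataFrame, log_offset: float = 0.0) -> FitResult:
    """Least-squares fit of the 9-predictor log model with intercept.

    Needs rows from at least two experiments for full rank: the baseline
    columns x4..x6 are constant within a single experiment and collinear
    with the intercept otherwise.  Rank deficiency yields the minimum-norm
    solution and a warning, not an error.
    """
    if len(rows) < 2:
        raise ValueError(f"need at least 2 rows to fit, got {len(rows)}")
    A, y = _design_arrays(rows)
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn(
            f"design matrix is rank deficient (rank {rank} < {A.shape[1]}); "
            "returning the minimum-norm solution — typically caused by "
            "single-experiment data (baseline columns x4..x6 constant)",
            stacklevel=2,
        )
    fitted = A @ beta
    resid = y - fitted
    return FitResult(
        beta=beta,
        fitted=fitted,
        residuals=resid,
        r_squared=r_squared(y, fitted),
        n=len(y),
        rank=int(rank),
        experiment_ids=sorted(set(rows["experiment_id"])) if "experiment_id" in rows else [],
        log_offset=log_offset,
    )


def r_squared(observed, predicted) -> float:
    """Coefficient of determination on the (log) response scale."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-D arrays")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("observed values are constant; R^2 undefined")
    ss_res = float(((obs - pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def predict_log(fit: FitResult, rows: pd.DataFrame) -> np.ndarray:
    """Linear prediction on the log scale for design rows."""
    X = rows[DESIGN_COLUMNS].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(X)), X]) @ fit.beta


def predict_od(fit: FitResult, rows: pd.DataFrame) -> np.ndarray:
    """Back-transformed optical-density prediction, strictly positive."""
    return np.exp(predict_log(fit, rows))


def whiteness_bound(n: int) -> float:
    """Approximate 95% band +-2/sqrt(n) for autocorrelations of white noise."""
    if n < 1:
        raise ValueError("n must be positive")
    return 2.0 / np.sqrt(n)


def residual_autocorrelation(residuals, max_lag: int = 20) -> tuple[list[int], list[float]]:
    """Biased sample autocorrelation of an ordered residual sequence.

    r(l) = sum_t (e_t - ebar)(e_{t+l} - ebar) / sum_t (e_t - ebar)^2.
    """
    e = np.asarray(residuals, dtype=float)
    n = e.size
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if n <= max_lag:
        raise ValueError(f"need more residuals ({n}) than lags ({max_lag})")
    e = e - e.mean()
    denom = float((e**2).sum())
    if denom == 0.0:
        raise ValueError("constant residuals; autocorrelation undefined")
    lags = list(range(1, max_lag + 1))
    acf = [float((e[:-l] * e[l:]).sum() / denom) for l in lags]
    return lags, acf


def ks_normality(residuals) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test of standardised residuals vs N(0,1).

    The residuals are centred and scaled by their sample standard deviation
    first; because those are estimated, the nominal p-value is approximate
    (anti-conservative — the Lilliefors caveat).
    """
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 residuals")
    sd = e.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero residual variance")
    z = (e - e.mean()) / sd
    stat, p = stats.kstest(z, "norm")
    return float(stat), float(p)


def diagnose(residuals, fitted=None, max_lag: int = 20) -> DiagnosticsReport:
    """Assemble the full diagnostics bundle for a residual sequence."""
    e = np.asarray(residuals, dtype=float)
    max_lag = min(max_lag, e.size - 1)
    lags, acf = residual_autocorrelation(e, max_lag=max_lag)
    stat, p = ks_normality(e)
    low_power = e.size < 5
    if low_power:
        log.warning("normality test on %d residuals has very low power", e.size)
    return DiagnosticsReport(
        lags=lags,
        autocorrelation=acf,
        whiteness_bound=whiteness_bound(e.size),
        ks_statistic=stat,
        ks_p=p,
        residual_mean=float(e.mean()),
        low_power=low_power,
        fitted=[] if fitted is None else list(map(float, fitted)),
        residuals=list(map(float, e)),
    )


def cross_validate(
    rows: pd.DataFrame,
    scheme: str = "loeo",
    seed: int | None = None,
    log_offset: float = 0.0,
) -> CVResult:
    """Cross-validate the regression.

    ``loeo`` holds out one whole experiment per fold (the primary
    prediction-performance scheme); ``loo`` shuffles the rows with ``seed``
    and leaves out one row at a time (used for residual autocorrelation on
    a randomly ordered sequence).  The pooled R^2 is computed over all
    held-out predictions at once, not averaged over folds.
    """
    scheme = scheme.lower()
    if scheme not in ("loeo", "loo"):
        raise ValueError(f"unknown scheme {scheme!r}; expected 'loeo' or 'loo'")
    rows = rows.reset_index(drop=True)

    if scheme == "loeo":
        experiments = list(dict.fromkeys(rows["experiment_id"]))
        if len(experiments) < 2:
            raise ValueError("leave-one-experiment-out needs >= 2 experiments")
        folds = [rows.index[rows["experiment_id"] == e].to_numpy() for e in experiments]
        order = np.concatenate(folds)
    else:
        if len(rows) < 3:
            raise ValueError("leave-one-out needs >= 3 rows")
        if seed is None:
            raise ValueError("leave-one-out requires a shuffle seed")
        order = np.random.default_rng(seed).permutation(len(rows))
        log.info("loo row order shuffled with seed %d", seed)
        folds = [np.array([i]) for i in order]

    preds = np.full(len(rows), np.nan)
    fold_betas = []
    for hold in folds:
        train = rows.drop(index=hold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # near-boundary folds may be low rank
            fit = fit_ols(train, log_offset=log_offset)
        preds[hold] = predict_log(fit, rows.loc[hold])
        fold_betas.append(fit.beta)

    out = rows.loc[order, ["experiment_id", "time_h", "response"]].copy()
    out["prediction"] = preds[order]
    out["residual"] = out["response"] - out["prediction"]
    y = rows["response"].to_numpy(dtype=float)
    pooled = r_squared(y[order], preds[order])
    return CVResult(
        scheme=scheme, predictions=out.reset_index(drop=True),
        r_squared=pooled, fold_betas=fold_betas, seed=seed,
    )


def plot_diagnostics(report: DiagnosticsReport, cv: CVResult | None, path) -> None:
    """Write the three diagnostic panels (residual-vs-fitted, ACF, series)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
    if report.fitted:
        axes[0].scatter(report.fitted, report.residuals, s=12, alpha=0.6)
    axes[0].axhline(0.0, color="k", lw=0.8)
    axes[0].set(xlabel="fitted (log OD)", ylabel="residual", title="residuals vs fitted")

    axes[1].stem(report.lags, report.autocorrelation)
    for sign in (1, -1):
        axes[1].axhline(sign * report.whiteness_bound, color="r", ls="--", lw=0.8)
    axes[1].set(xlabel="lag", ylabel="autocorrelation", title="residual ACF")

    if cv is not None:
        idx = np.arange(len(cv.predictions))
        axes[2].plot(idx, np.exp(cv.predictions["response"]), "o", ms=3, label="measured OD")
        axes[2].plot(idx, np.exp(cv.predictions["prediction"]), "x", ms=3, label="predicted OD")
        axes[2].legend(fontsize=8)
    axes[2].set(xlabel="measurement", ylabel="OD", title="held-out predictions")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
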