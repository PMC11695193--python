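"""Gaussian-process Bayesian optimization with Expected Improvement.

A from-scratch minimizer for expensive black-box objectives (here:
validation RMSE of a trained model as a function of its
hyperparameters).  The surrogate is an exact GP with a Matern-5/2 kernel
on standardized objective values; the length-scale is picked by
marginal-likelihood grid search.  The acquisition (EI for minimization)
is maximized over seeded uniform candidates in the unit cube, which
sidesteps gradient ascent on integer-valued dimensions.

The loop follows the classic recipe: evaluate ``init_points`` random
configurations, then repeat ``n_iter`` times: fit the surrogate, propose
the EI argmax, evaluate, append to the history.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "Parameter",
    "SearchSpace",
    "TrialRecord",
    "GPSurrogate",
    "gp_fit",
    "gp_predict",
    "expected_improvement",
    "propose_next",
    "optimize",
    "default_bcbl_space",
]


# ---------------------------------------------------------------------------
# search space


@dataclass(frozen=True)
class Parameter:
    """One search dimension: bounds, scale (linear/log), kind (continuous/integer)."""

    name: str
    low: float
    high: float
    scale: str = "linear"
    kind: str = "continuous"

    def __post_init__(self) -> None:
        if self.low >= self.high:
            raise ValueError(f"{self.name}: lower bound must be < upper bound")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"{self.name}: scale must be linear or log")
        if self.scale == "log" and self.low <= 0:
            raise ValueError(f"{self.name}: log scale requires positive bounds")
        if self.kind not in ("continuous", "integer"):
            raise ValueError(f"{self.name}: kind must be continuous or integer")

    def decode(self, u: float) -> float:
        """Map a unit-cube coordinate to a parameter value."""
        if self.scale == "log":
            value = math.exp(
                math.log(self.low) + u * (math.log(self.high) - math.log(self.low))
            )
        else:
            value = self.low + u * (self.high - self.low)
        if self.kind == "integer":
            return int(round(value))
        return value


@dataclass
class SearchSpace:
    """Ordered collection of parameters defining the unit search cube."""

    parameters: list[Parameter]

    @property
    def dim(self) -> int:
        return len(self.parameters)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.parameters]

    def decode(self, u: np.ndarray) -> dict:
        u = np.asarray(u, float)
        return {p.name: p.decode(float(ui)) for p, ui in zip(self.parameters, u)}


def default_bcbl_space() -> SearchSpace:
    """Default hyperparameter ranges for the CNN-BiLSTM regressor."""
    return SearchSpace(
        [
            Parameter("conv_filters", 16, 128, kind="integer"),
            Parameter("conv_kernel", 2, 5, kind="integer"),
            Parameter("bilstm_units", 16, 128, kind="integer"),
            Parameter("dense1_units", 8, 64, kind="integer"),
            Parameter("dense2_units", 8, 64, kind="integer"),
            Parameter("learning_rate", 1e-4, 1e-2, scale="log"),
            Parameter("batch_size", 16, 64, kind="integer"),
        ]
    )


@dataclass
class TrialRecord:
    """One evaluated point of the optimization history."""

    iteration: int
    phase: str  # "init" or "bo"
    u: np.ndarray  # unit-cube coordinates
    params: dict  # decoded values
    objective: float
    failed: bool = False


# ---------------------------------------------------------------------------
# GP surrogate


def _matern52(X1: np.ndarray, X2: np.ndarray, length_scale: float) -> np.ndarray:
    d = np.sqrt(
        np.maximum(
            ((X1[:, None, :] - X2[None, :, :]) ** 2).sum(-1), 0.0
        )
    )
    a = math.sqrt(5.0) * d / length_scale
    return (1.0 + a + a * a / 3.0) * np.exp(-a)


@dataclass
class GPSurrogate:
    """Exact GP regression state on standardized objective values."""

    X: np.ndarray
    y_raw: np.ndarray
    y_mean: float
    y_sd: float
    length_scale: float
    signal_variance: float = 1.0
    jitter: float = 1e-6
    chol: tuple = field(default=None, repr=False)
    alpha: np.ndarray = field(default=None, repr=False)


_LS_GRID = np.logspace(-1.0, 0.7, 12)


def gp_fit(points: np.ndarray, values: np.ndarray, length_scales=None, jitter: float = 1e-6) -> GPSurrogate:
    """Fit an exact Matern-5/2 GP to (points in the unit cube, values).

    Values are z-scored internally; the kernel length-scale is chosen by
    log-marginal-likelihood over a small fixed grid.
    """
    X = np.atleast_2d(np.asarray(points, float))
    y = np.asarray(values, float).ravel()
    if len(X) != len(y) or len(y) < 1:
        raise ValueError("need >= 1 matching points and values")
    if not np.all(np.isfinite(y)):
        raise ValueError("objective values must be finite")
    y_mean = float(y.mean())
    y_sd = float(y.std())
    if y_sd == 0.0 or len(y) < 2:
        y_sd = 1.0
    yz = (y - y_mean) / y_sd

    grid = _LS_GRID if length_scales is None else np.atleast_1d(length_scales)
    best_ls, best_ll = None, -np.inf
    n = len(yz)
    for ls in grid:
        K = _matern52(X, X, ls) + jitter * np.eye(n)
        try:
            L = cholesky(K, lower=True)
        except np.linalg.LinAlgError:
            continue
        a = cho_solve((L, True), yz)
        ll = -0.5 * yz @ a - np.log(np.diag(L)).sum() - 0.5 * n * math.log(2 * math.pi)
        if ll > best_ll:
            best_ll, best_ls = ll, float(ls)
    if best_ls is None:
        raise np.linalg.LinAlgError("no length-scale produced a positive-definite kernel")

    K = _matern52(X, X, best_ls) + jitter * np.eye(n)
    L = cholesky(K, lower=True)
    alpha = cho_solve((L, True), yz)
    return GPSurrogate(
        X=X, y_raw=y, y_mean=y_mean, y_sd=y_sd, length_scale=best_ls,
        jitter=jitter, chol=(L, True), alpha=alpha,
    )


def gp_predict(surrogate: GPSurrogate, query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and sd (original units) at query points."""
    Q = np.atleast_2d(np.asarray(query, float))
    Ks = _matern52(Q, surrogate.X, surrogate.length_scale)
    mu_z = Ks @ surrogate.alpha
    v = cho_solve(surrogate.chol, Ks.T)
    var_z = np.maximum(surrogate.signal_variance - np.einsum("ij,ji->i", Ks, v), 0.0)
    mu = mu_z * surrogate.y_sd + surrogate.y_mean
    sd = np.sqrt(var_z) * surrogate.y_sd
    return mu, sd


# ---------------------------------------------------------------------------
# acquisition


def expected_improvement(mu, sigma, best_so_far) -> np.ndarray:
    """EI for minimization: E[max(0, best - Y)], Y ~ N(mu, sigma^2).

    With z = (best - mu)/sigma:  EI = (best - mu) Phi(z) + sigma phi(z);
    when sigma = 0 it degenerates to max(0, best - mu).
    """
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be nonnegative")
    imp = best_so_far - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, imp / np.where(sigma > 0, sigma, 1.0), 0.0)
    ei = np.where(
        sigma > 0,
        imp * norm.cdf(z) + sigma * norm.pdf(z),
        np.maximum(imp, 0.0),
    )
    return np.maximum(ei, 0.0)


def propose_next(
    surrogate: GPSurrogate,
    space: SearchSpace,
    rng: np.random.Generator,
    n_candidates: int = 2048,
) -> tuple[np.ndarray, float]:
    """EI argmax over seeded uniform candidates in the unit cube.

    Ties (e.g. EI identically zero) break to the lowest candidate index.
    Returns (unit-cube point, its EI).
    """
    cand = rng.uniform(size=(n_candidates, space.dim))
    mu, sd = gp_predict(surrogate, cand)
    best = float(surrogate.y_raw.min())
    ei = expected_improvement(mu, sd, best)
    k = int(np.argmax(ei))
    return cand[k], float(ei[k])


# ---------------------------------------------------------------------------
# the optimization loop


def optimize(
    objective,
    space: SearchSpace,
    init_points: int = 10,
    n_iter: int = 50,
    seed: int = 0,
    stop_on_small_ei: bool = False,
    ei_threshold: float = 1e-6,
    ei_patience: int = 5,
) -> tuple[TrialRecord, list[TrialRecord]]:
    """Minimize ``objective(params_dict)`` over the search space.

    Phase 1 evaluates ``init_points`` seeded uniform configurations;
    phase 2 loops ``n_iter`` times (fit surrogate, propose EI argmax,
    evaluate, append).  A trial that raises is recorded as failed with a
    large penalty value and the loop continues.  Returns the incumbent
    best record and the full history (length init_points + n_iter unless
    the optional small-EI stop triggers).
    """
    rng = np.random.default_rng(seed)
    history: list[TrialRecord] = []

    def evaluate(u: np.ndarray, phase: str) -> TrialRecord:
        params = space.decode(u)
        failed = False
        try:
            value = float(objective(params))
            if not np.isfinite(value):
                raise ValueError(f"objective returned non-finite value {value}")
        except Exception as exc:  # noqa: BLE001 - failed trials are recorded, not fatal
            finite = [t.objective for t in history if not t.failed]
            value = (max(finite) + 10.0 * (max(finite) - min(finite) + 1.0)) if finite else 1e6
            failed = True
            logger.warning("trial failed (%s); recording penalty %.3g", exc, value)
        rec = TrialRecord(len(history), phase, np.asarray(u, float), params, value, failed)
        history.append(rec)
        return rec

    for _ in range(init_points):
        evaluate(rng.uniform(size=space.dim), "init")

    small_ei_run = 0
    for _ in range(n_iter):
        X = np.stack([t.u for t in history])
        y = np.array([t.objective for t in history])
        surrogate = gp_fit(X, y)
        u_next, ei = propose_next(surrogate, space, rng)
        evaluate(u_next, "bo")
        if stop_on_small_ei:
            small_ei_run = small_ei_run + 1 if ei < ei_threshold else 0
            if small_ei_run >= ei_patience:
                logger.info("EI below %.1e for %d iterations; stopping", ei_threshold, ei_patience)
                break

    best = min(history, key=lambda t: t.objective)
    return best, history


def history_frame(history: list[TrialRecord]) -> pd.DataFrame:
    """History as a tidy table: iteration, phase, param_*, objective."""
    rows = []
    for t in history:
        row = {"iteration": t.iteration, "phase": t.phase, "objective": t.objective,
               "failed": t.failed}
        row.update({f"param_{k}": v for k, v in t.params.items()})
        rows.append(row)
    return pd.DataFrame(rows)
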