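"""Bayesian optimization of training hyperparameters.

A Gaussian-process surrogate (Matern 5/2 kernel with automatic
relevance determination, hyperparameters fit by marginal-likelihood
maximization) models the objective over a mixed search space
(log-scaled continuous, linear continuous, and integer parameters);
candidates are proposed by maximizing closed-form expected improvement
(EI) over a random pool with local refinement.  The loop minimizes: by
default the objective is a validation error.

The default :func:`default_search_space` mirrors the training
hyperparameter search used for the CNNs: learning rate on a log scale
in [1e-5, 0.999], integer mini-batch in [16, 256], momentum in [0, 1];
solver (SGDM) and the L2 penalty are fixed settings, not searched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
import warnings

logger = logging.getLogger(__name__)

__all__ = [
    "Parameter",
    "SearchSpace",
    "GPPosterior",
    "BOResult",
    "default_search_space",
    "expected_improvement",
    "propose_next",
    "bo_search",
]

_FAILED_EVAL_PENALTY = 1e6


@dataclass(frozen=True)
class Parameter:
    """One search dimension: bounds plus scale ('linear'|'log'|'integer')."""

    name: str
    lower: float
    upper: float
    scale: str = "linear"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"parameter {self.name!r}: lower must be < upper")
        if self.scale not in ("linear", "log", "integer"):
            raise ValueError(f"parameter {self.name!r}: unknown scale {self.scale!r}")
        if self.scale == "log" and self.lower <= 0:
            raise ValueError(f"parameter {self.name!r}: log scale needs lower > 0")

    def to_internal(self, value: float) -> float:
        return float(np.log(value)) if self.scale == "log" else float(value)

    def from_internal(self, value: float) -> float:
        if self.scale == "log":
            out = float(np.exp(value))
        else:
            out = float(value)
        out = min(max(out, self.lower), self.upper)
        return float(round(out)) if self.scale == "integer" else out

    @property
    def internal_bounds(self) -> tuple[float, float]:
        if self.scale == "log":
            return float(np.log(self.lower)), float(np.log(self.upper))
        return float(self.lower), float(self.upper)


@dataclass
class SearchSpace:
    """Ordered set of free parameters plus fixed (non-searched) settings."""

    parameters: list[Parameter]
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.parameters:
            raise ValueError("search space has no free parameters")

    @property
    def dim(self) -> int:
        return len(self.parameters)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Uniform internal-space samples, shape (n, dim)."""
        lo = np.array([p.internal_bounds[0] for p in self.parameters])
        hi = np.array([p.internal_bounds[1] for p in self.parameters])
        return lo + (hi - lo) * rng.uniform(size=(n, self.dim))

    def decode(self, x: np.ndarray) -> dict:
        conf = {
            p.name: p.from_internal(v) for p, v in zip(self.parameters, np.atleast_1d(x))
        }
        conf.update(self.fixed)
        return conf


def default_search_space() -> SearchSpace:
    return SearchSpace(
        parameters=[
            Parameter("learning_rate", 1e-5, 0.999, "log"),
            Parameter("mini_batch", 16, 256, "integer"),
            Parameter("momentum", 0.0, 1.0, "linear"),
        ],
        fixed={"solver": "sgdm", "regularization": "l2"},
    )


class GPPosterior:
    """Gaussian-process posterior over observed (internal-space) points."""

    def __init__(self, X: np.ndarray, y: np.ndarray, seed: int = 0):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float)
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        dim = self.X.shape[1]
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
            length_scale=np.ones(dim), length_scale_bounds=(1e-2, 1e2), nu=2.5
        ) + WhiteKernel(1e-6, (1e-10, 1e-1))
        self._y_mean = float(self.y.mean())
        self._y_scale = float(self.y.std()) or 1.0
        self.gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=False, n_restarts_optimizer=2, random_state=seed
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.gp.fit(self.X, (self.y - self._y_mean) / self._y_scale)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predictive mean and standard deviation (original scale)."""
        mu, sd = self.gp.predict(np.atleast_2d(X), return_std=True)
        return mu * self._y_scale + self._y_mean, np.maximum(sd * self._y_scale, 0.0)

    @property
    def best_observed(self) -> float:
        return float(self.y.min())


def expected_improvement(
    pred_mean: np.ndarray, pred_sd: np.ndarray, best_so_far: float
) -> np.ndarray:
    """Closed-form EI for minimization.

    With ``z = (best - mean) / sd``:
    ``EI = sd * (z * Phi(z) + phi(z))``; the degenerate ``sd = 0`` case
    collapses to ``max(0, best - mean)``.
    """

    mean = np.asarray(pred_mean, dtype=float)
    sd = np.asarray(pred_sd, dtype=float)
    if np.any(sd < 0):
        raise ValueError("pred_sd must be >= 0")
    improvement = best_so_far - mean
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = np.where(sd > 0, improvement / np.where(sd > 0, sd, 1.0), 0.0)
        # past +-40 sd the Gaussian terms are numerically exact limits
        zc = np.clip(z, -40.0, 40.0)
        ei = sd * (zc * norm.cdf(zc) + norm.pdf(zc))
        ei = np.where(np.abs(z) > 40.0, np.maximum(improvement, 0.0), ei)
        ei = np.where(sd > 0, ei, np.maximum(improvement, 0.0))
    out = np.maximum(ei, 0.0)
    return out if out.ndim else float(out)


def propose_next(
    posterior: GPPosterior,
    space: SearchSpace,
    rng: np.random.Generator,
    pool_size: int = 2048,
) -> np.ndarray:
    """EI-maximizing internal-space candidate.

    Evaluates EI on a random pool of ``pool_size`` in-bounds candidates
    and locally refines the best one with L-BFGS-B; the refined point is
    kept only if it does not lower EI.
    """

    if len(posterior.X) < 2:
        raise ValueError("posterior needs at least 2 observations")
    pool = space.sample(rng, pool_size)
    mu, sd = posterior.predict(pool)
    ei = expected_improvement(mu, sd, posterior.best_observed)
    best_idx = int(np.argmax(ei))
    x0, ei0 = pool[best_idx], float(ei[best_idx])

    def neg_ei(x: np.ndarray) -> float:
        m, s = posterior.predict(x[None, :])
        return -float(expected_improvement(m, s, posterior.best_observed)[0])

    bounds = [p.internal_bounds for p in space.parameters]
    res = minimize(neg_ei, x0, method="L-BFGS-B", bounds=bounds)
    if res.success and -res.fun >= ei0:
        return np.asarray(res.x)
    return x0


@dataclass
class BOResult:
    """Best configuration/value plus the full evaluation history."""

    best_config: dict
    best_value: float
    history: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.history) and self.best_value != self.history["objective"].min():
            raise ValueError("best_value must equal the history minimum")


def bo_search(
    objective,
    space: SearchSpace,
    budget: int,
    seed: int = 0,
    n_initial: int = 3,
) -> BOResult:
    """Minimize a configuration -> value objective under a fixed budget.

    The first ``min(n_initial, budget)`` evaluations come from a random
    initial design; the rest from EI proposals.  Non-finite objective
    values are recorded as failed evaluations with a large penalty.
    Reproducible under ``seed``.
    """

    if budget < 3:
        raise ValueError(f"budget must be >= 3, got {budget}")
    rng = np.random.default_rng(seed)
    X: list[np.ndarray] = []
    values: list[float] = []
    rows: list[dict] = []

    def evaluate(x: np.ndarray, iteration: int) -> None:
        conf = space.decode(x)
        raw = objective(conf)
        val = float(raw)
        if not np.isfinite(val):
            logger.warning("objective returned non-finite at %s; penalized", conf)
            val = _FAILED_EVAL_PENALTY
        X.append(np.asarray(x, dtype=float))
        values.append(val)
        row = {"iteration": iteration, **{k: conf[k] for k in conf}, "objective": val}
        rows.append(row)

    n_init = min(max(n_initial, 2), budget)
    for i, x in enumerate(space.sample(rng, n_init)):
        evaluate(x, i + 1)
    for i in range(n_init, budget):
        posterior = GPPosterior(np.stack(X), np.array(values), seed=seed)
        x = propose_next(posterior, space, rng)
        evaluate(x, i + 1)

    history = pd.DataFrame(rows)
    best_idx = int(np.argmin(values))
    return BOResult(
        best_config=space.decode(X[best_idx]),
        best_value=float(values[best_idx]),
        history=history,
    )
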