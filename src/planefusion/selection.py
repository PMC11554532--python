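"""IGNDO wrapper feature selection and serial feature fusion.

The selector runs GNDO over a continuous position vector with one
component per feature column (box bounds [-4, 4]).  A position maps to
per-feature scores through the logistic function; the active subset
during the search is ``score >= 0.5``, and each candidate subset is
scored by the hold-out error of a fast inner classifier (wrapper
selection).  At termination the best position's scores are binarized
through a binary-cross-entropy-derived scalar threshold:

``CE = -(1/D) * sum_j [ b_j log p_j + (1 - b_j) log(1 - p_j) ]`` with
``b_j = 1`` iff ``p_j >= 0.5``, and the final mask keeps feature ``j``
iff ``p_j >= CE``.  A confident, self-consistent score vector thus
yields a small threshold and a mask close to its own binarization;
an all-zero mask falls back to the 0.5 rule.

Two independently selected feature blocks (one per CNN) are then fused
by serial (columnwise) concatenation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .gndo import Bounds, GNDOConfig, gndo_minimize
from .train_extract import DataError, FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FitnessSpec",
    "SelectionResult",
    "position_to_scores",
    "compute_cross_entropy",
    "threshold_select",
    "igndo_select",
    "serial_fuse",
    "IGNDOSelector",
]

_EPS = 1e-12
_POSITION_BOUND = 4.0


@dataclass
class FitnessSpec:
    """Inner evaluator used to score a candidate feature subset.

    ``evaluator`` currently supports ``"nearest_centroid"`` — fast,
    deterministic under the fixed hold-out split, and monotone in
    feature informativeness.  ``validation_fraction`` of rows is held
    out once per run.
    """

    evaluator: str = "nearest_centroid"
    validation_fraction: float = 0.3
    score_penalty: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction < 1:
            raise ValueError(
                f"validation_fraction must be in (0, 1), got {self.validation_fraction}"
            )
        if self.score_penalty < 0:
            raise ValueError(f"score_penalty must be >= 0, got {self.score_penalty}")
        if self.evaluator != "nearest_centroid":
            raise ValueError(f"unknown evaluator {self.evaluator!r}")


@dataclass
class SelectionResult:
    """Per-feature scores, scalar threshold, and the resulting mask."""

    scores: np.ndarray
    threshold: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.scores.shape != self.mask.shape:
            raise ValueError("scores and mask must have equal shapes")

    @property
    def selected_width(self) -> int:
        return int(self.mask.sum())

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    def to_json(self, path: str | Path, scores_file: str | None = None) -> None:
        doc = {
            "scores_file": scores_file,
            "threshold": self.threshold,
            "selected_indices": self.selected_indices.tolist(),
            "width": self.selected_width,
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def position_to_scores(position: np.ndarray) -> np.ndarray:
    """Logistic map from continuous positions to scores strictly in (0, 1)."""
    position = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(position)):
        raise ValueError("position contains non-finite components")
    return 1.0 / (1.0 + np.exp(-position))


def compute_cross_entropy(scores: np.ndarray) -> float:
    """Scalar binary cross-entropy of a score vector against its own
    0.5-binarization, after clipping scores to [eps, 1 - eps]."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    p = np.clip(scores, _EPS, 1.0 - _EPS)
    b = (p >= 0.5).astype(float)
    return float(-np.mean(b * np.log(p) + (1.0 - b) * np.log(1.0 - p)))


def threshold_select(scores: np.ndarray, threshold: float) -> SelectionResult:
    """Keep feature j iff ``score_j >= threshold``; fall back to the 0.5
    rule (with a warning) when nothing survives."""
    scores = np.asarray(scores, dtype=float)
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    mask = scores >= threshold
    if not mask.any():
        logger.warning(
            "threshold %.4g selected no features; falling back to the 0.5 rule",
            threshold,
        )
        mask = scores >= 0.5
    return SelectionResult(scores=scores, threshold=float(threshold), mask=mask)


def _holdout_split(
    n: int, labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified fixed hold-out split for the wrapper fitness."""
    val: list[np.ndarray] = []
    train: list[np.ndarray] = []
    for cls in np.unique(labels):
        members = rng.permutation(np.flatnonzero(labels == cls))
        n_val = max(1, int(round(len(members) * fraction)))
        n_val = min(n_val, len(members) - 1) if len(members) > 1 else n_val
        val.append(members[:n_val])
        train.append(members[n_val:])
    return np.concatenate(train), np.concatenate(val)


class _NearestCentroidFitness:
    """Wrapper fitness: hold-out error of a nearest-centroid classifier
    on the cross-entropy-thresholded column subset of a position.

    The candidate subset is the same thresholded mask the selector emits
    (``score >= CE(scores)``), so the search optimizes exactly the
    quantity that defines the final selection.  A small continuous
    score-mass term ``score_penalty * mean(scores)`` breaks the ties
    that a pure 0-1 error leaves everywhere and pushes uninformative
    scores away from the threshold; error remains the dominant term
    (dropping a useful feature costs far more than its mass saves).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, spec: FitnessSpec):
        rng = np.random.default_rng(spec.seed)
        tr, va = _holdout_split(len(X), y, spec.validation_fraction, rng)
        self.X_train, self.y_train = X[tr], y[tr]
        self.X_val, self.y_val = X[va], y[va]
        self.classes = np.unique(y)
        self.score_penalty = spec.score_penalty

    def error(self, mask: np.ndarray) -> float:
        if not mask.any():
            return 1.0 + 1e-3  # worse than always-wrong: discourage empty masks
        Xt = self.X_train[:, mask]
        Xv = self.X_val[:, mask]
        centroids = np.stack([Xt[self.y_train == c].mean(axis=0) for c in self.classes])
        d2 = ((Xv[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        pred = self.classes[np.argmin(d2, axis=1)]
        return float(np.mean(pred != self.y_val))

    def __call__(self, position: np.ndarray) -> float:
        scores = position_to_scores(position)
        mask = scores >= compute_cross_entropy(scores)
        return self.error(mask) + self.score_penalty * float(scores.mean())


def igndo_select(
    features: FeatureMatrix,
    fitness: FitnessSpec | None = None,
    config: GNDOConfig | None = None,
) -> SelectionResult:
    """Select informative feature columns with the IGNDO wrapper.

    Runs :func:`~planefusion.gndo.gndo_minimize` over D-dimensional
    positions in [-4, 4]; candidate subsets during the search and the
    returned mask both come from the cross-entropy threshold applied to
    a position's logistic scores (see :class:`_NearestCentroidFitness`).
    """

    fitness = fitness or FitnessSpec()
    config = config or GNDOConfig()
    X, y = features.values, features.labels
    if X.shape[1] < 2:
        raise DataError("feature selection needs at least 2 columns")
    if len(np.unique(y)) < 2:
        raise DataError("feature selection needs at least 2 classes")
    objective = _NearestCentroidFitness(X, y, fitness)
    D = X.shape[1]
    bounds = Bounds(np.full(D, -_POSITION_BOUND), np.full(D, _POSITION_BOUND))
    best, _trace = gndo_minimize(objective, bounds, config)
    scores = position_to_scores(best.position)
    ce = compute_cross_entropy(scores)
    return threshold_select(scores, ce)


def serial_fuse(block_a: FeatureMatrix, block_b: FeatureMatrix) -> FeatureMatrix:
    """Columnwise (serial) concatenation of two feature blocks.

    Requires equal row counts and identical label vectors; width of the
    fused block is ``width_a + width_b`` with a's columns first.
    """

    if len(block_a.values) != len(block_b.values):
        raise DataError(
            f"row mismatch: {len(block_a.values)} vs {len(block_b.values)}"
        )
    if not np.array_equal(block_a.labels, block_b.labels):
        raise DataError("label vectors differ between blocks")
    fused = np.concatenate([block_a.values, block_b.values], axis=1)
    source = "+".join(s for s in (block_a.source_model, block_b.source_model) if s)
    return FeatureMatrix(fused, block_a.labels.copy(), list(block_a.class_names), source)


class IGNDOSelector:
    """sklearn-style selector: fit runs the IGNDO search, transform masks.

    Fitted attributes: ``scores_`` (per-feature logistic scores of the
    best position), ``threshold_`` (scalar cross-entropy), ``mask_``
    (boolean), ``n_features_selected_``.
    """

    def __init__(
        self,
        population_size: int = 20,
        max_iterations: int = 200,
        validation_fraction: float = 0.3,
        seed: int = 0,
    ):
        self.population_size = population_size
        self.max_iterations = max_iterations
        self.validation_fraction = validation_fraction
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {
            "population_size": self.population_size,
            "max_iterations": self.max_iterations,
            "validation_fraction": self.validation_fraction,
            "seed": self.seed,
        }

    def set_params(self, **params) -> "IGNDOSelector":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray) -> "IGNDOSelector":
        fm = FeatureMatrix(
            np.asarray(X, dtype=float),
            np.asarray(y),
            [str(c) for c in np.unique(y)],
        )
        result = igndo_select(
            fm,
            FitnessSpec(validation_fraction=self.validation_fraction, seed=self.seed),
            GNDOConfig(
                population_size=self.population_size,
                max_iterations=self.max_iterations,
                seed=self.seed,
            ),
        )
        self.scores_ = result.scores
        self.threshold_ = result.threshold
        self.mask_ = result.mask
        self.n_features_selected_ = result.selected_width
        return self

    def get_support(self) -> np.ndarray:
        if not hasattr(self, "mask_"):
            raise RuntimeError("IGNDOSelector is not fitted")
        return self.mask_

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X)[:, self.get_support()]

    def fit_transform(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.fit(X, y).transform(X)
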