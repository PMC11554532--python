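"""Dataset splitting, CNN training and GAP deep-feature extraction.

The workflow mirrors common ultrasound-plane studies: a stratified
50/50 train/test split of a folder-per-class image dataset, training of
a residual CNN with SGDM under cross-entropy loss, then extraction of
the global-average-pooling activations of the trained network as a
``FeatureMatrix`` (samples x gap_width) for downstream selection,
fusion and shallow classification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from ._engine import NumpyNetwork, TrainingDivergence
from .model_zoo import ModelGraph

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "SplitSpec",
    "FeatureMatrix",
    "DataError",
    "split_dataset",
    "load_image_folder",
    "train_model",
    "extract_features",
    "CNNFeatureExtractor",
]


class DataError(ValueError):
    """Problem with input data (empty class, mismatched labels...)."""


@dataclass
class TrainConfig:
    """SGDM training hyperparameters.

    Defaults are the Bayesian-optimization-selected values used for the
    published models: learning rate 2.74e-4, mini-batch 128, momentum
    0.699, L2 weight 1e-6.  ``max_epochs`` defaults to 50 with early
    stopping on a 10% validation slice (patience 10).
    """

    learning_rate: float = 0.000274
    mini_batch: int = 128
    momentum: float = 0.699
    l2_weight: float = 1e-6
    max_epochs: int = 50
    seed: int = 0
    val_fraction: float = 0.1
    patience: int = 10
    warmup_epochs: int = 3

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if not 0 <= self.momentum < 1:
            raise ValueError(f"momentum must be in [0, 1), got {self.momentum}")
        if self.mini_batch < 1:
            raise ValueError(f"mini_batch must be >= 1, got {self.mini_batch}")


@dataclass
class SplitSpec:
    """Stratified split specification; train gets the ceil of odd counts."""

    train_fraction: float = 0.5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")


@dataclass
class FeatureMatrix:
    """Deep features: samples x width values with per-sample class labels."""

    values: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    source_model: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.ndim != 2:
            raise DataError(f"values must be 2-D, got shape {self.values.shape}")
        if len(self.values) != len(self.labels):
            raise DataError(
                f"{len(self.values)} feature rows but {len(self.labels)} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("feature matrix contains non-finite values")

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path, binary_sidecar: bool = True) -> None:
        path = Path(path)
        width = self.width
        cols = [f"f{j + 1:04d}" for j in range(width)]
        df = pd.DataFrame(self.values, columns=cols)
        df["label"] = self.labels
        df.to_csv(path, index=False)
        if binary_sidecar:
            np.save(path.with_suffix(".npy"), self.values.astype(np.float32))

    @classmethod
    def from_csv(cls, path: str | Path, class_names: list[str] | None = None) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy()
        names = class_names or [str(c) for c in sorted(np.unique(labels))]
        return cls(df.to_numpy(), labels, names)


def split_dataset(labels, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test index split.

    Per class, the train side receives ``ceil(n_class * fraction)``
    members (so a 1386-image class splits 693/693 and a 1281-image class
    641/640 at the default 0.5).  Deterministic under ``spec.seed``;
    train and test indices are disjoint and exhaustive.
    """

    labels = np.asarray(labels)
    if labels.size == 0:
        raise DataError("cannot split an empty label vector")
    rng = np.random.default_rng(spec.seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    if spec.stratified:
        for cls in np.unique(labels):
            members = np.flatnonzero(labels == cls)
            if len(members) == 0:
                raise DataError(f"class {cls!r} has no samples")
            members = rng.permutation(members)
            n_train = math.ceil(len(members) * spec.train_fraction)
            train_idx.append(members[:n_train])
            test_idx.append(members[n_train:])
    else:
        perm = rng.permutation(len(labels))
        n_train = math.ceil(len(labels) * spec.train_fraction)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    train = np.sort(np.concatenate(train_idx))
    test = np.sort(np.concatenate(test_idx))
    return train, test


def load_image_folder(
    root: str | Path, image_size: int = 224
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Load a folder-per-class image dataset.

    Images are read grayscale, bilinearly resized to
    ``image_size x image_size``, replicated to 3 channels and scaled to
    [0, 1].  Returns ``(images NHWC, labels, class_names)`` with classes
    in sorted name order.
    """

    root = Path(root)
    if not root.is_dir():
        raise DataError(f"dataset root {root} does not exist")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise DataError(f"no class folders under {root}")
    images, labels, names = [], [], []
    for ci, cdir in enumerate(class_dirs):
        names.append(cdir.name)
        files = sorted(
            f for f in cdir.iterdir() if f.suffix.lower() in (".png", ".jpg", ".jpeg")
        )
        if not files:
            raise DataError(f"class folder {cdir.name!r} contains no images")
        for f in files:
            with Image.open(f) as im:
                arr = np.asarray(
                    im.convert("L").resize((image_size, image_size), Image.BILINEAR),
                    dtype=np.float32,
                )
            images.append(np.repeat(arr[:, :, None], 3, axis=2) / 255.0)
            labels.append(ci)
    return np.stack(images), np.asarray(labels), names


def train_model(
    graph: ModelGraph,
    images: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig | None = None,
) -> tuple[NumpyNetwork, pd.DataFrame]:
    """Train a model graph with SGDM under cross-entropy loss.

    A ``val_fraction`` slice is held out for early stopping (patience
    ``config.patience``); the mini-batch shrinks to the dataset size
    when the data is smaller than ``config.mini_batch``.  Returns the
    trained network and a per-epoch loss trace ``(epoch, loss,
    val_loss)``.
    """

    config = config or TrainConfig()
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DataError("training requires at least 2 classes")
    rng = np.random.default_rng(config.seed)
    net = NumpyNetwork(graph, rng)

    n = len(images)
    n_val = int(round(n * config.val_fraction))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        tr_idx, val_idx = perm, perm[:0]
    batch = min(config.mini_batch, len(tr_idx))

    trace = []
    best_val = np.inf
    stall = 0
    for epoch in range(1, config.max_epochs + 1):
        # linear warmup guards the no-batchnorm stacks against early
        # ReLU die-off from large first updates
        if config.warmup_epochs > 0 and epoch <= config.warmup_epochs:
            lr = config.learning_rate * epoch / (config.warmup_epochs + 1)
        else:
            lr = config.learning_rate
        order = rng.permutation(tr_idx)
        losses = []
        for start in range(0, len(order), batch):
            sel = order[start : start + batch]
            loss, grads = net.loss_and_grads(images[sel], labels[sel])
            if not np.isfinite(loss):
                raise TrainingDivergence(
                    f"non-finite loss at epoch {epoch}; try a lower learning rate"
                )
            net.sgd_step(grads, lr, config.momentum, config.l2_weight)
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        if len(val_idx):
            probs = net.forward(images[val_idx], training=False)
            val_loss = float(
                -np.mean(np.log(probs[np.arange(len(val_idx)), labels[val_idx]] + 1e-12))
            )
        else:
            val_loss = epoch_loss
        trace.append({"epoch": epoch, "loss": epoch_loss, "val_loss": val_loss})
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                logger.info("early stop at epoch %d (val loss stalled)", epoch)
                break
    return net, pd.DataFrame(trace)


def extract_features(
    model: NumpyNetwork,
    images: np.ndarray,
    labels: np.ndarray | None = None,
    class_names: list[str] | None = None,
    source_model: str = "",
) -> FeatureMatrix:
    """Extract GAP-layer activations as a ``FeatureMatrix``.

    Output has shape ``(n_images, gap_width)`` with row order equal to
    input order; an empty image set yields a ``0 x gap_width`` matrix.
    """

    images = np.asarray(images, dtype=np.float32)
    if len(images) and images.shape[1:] != tuple(model.graph.input_shape):
        raise DataError(
            f"images of shape {images.shape[1:]} incompatible with model input "
            f"{model.graph.input_shape}"
        )
    feats = model.gap_features(images)
    if labels is None:
        labels = np.zeros(len(images), dtype=np.int64)
    names = class_names or [str(c) for c in sorted(np.unique(labels))] or ["0"]
    return FeatureMatrix(feats, labels, names, source_model=source_model)


class CNNFeatureExtractor:
    """sklearn-style transformer: train a residual CNN, emit GAP features.

    Parameters
    ----------
    builder : callable
        One of the model builders (``build_three_residual_model`` /
        ``build_four_residual_model``).
    num_classes : int or None
        Inferred from ``y`` at fit time when None.
    input_shape : tuple
        ``(h, w, c)`` expected image shape.
    width_scale : float
        Uniform channel-width scale passed to the builder.
    config : TrainConfig or None
        Training hyperparameters (defaults used when None).
    """

    def __init__(
        self,
        builder,
        num_classes: int | None = None,
        input_shape: tuple[int, int, int] = (224, 224, 3),
        width_scale: float = 1.0,
        config: TrainConfig | None = None,
    ):
        self.builder = builder
        self.num_classes = num_classes
        self.input_shape = input_shape
        self.width_scale = width_scale
        self.config = config

    def get_params(self, deep: bool = True) -> dict:
        return {
            "builder": self.builder,
            "num_classes": self.num_classes,
            "input_shape": self.input_shape,
            "width_scale": self.width_scale,
            "config": self.config,
        }

    def set_params(self, **params) -> "CNNFeatureExtractor":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CNNFeatureExtractor":
        y = np.asarray(y)
        k = self.num_classes or int(len(np.unique(y)))
        self.graph_ = self.builder(k, self.input_shape, width_scale=self.width_scale)
        self.network_, self.loss_trace_ = train_model(
            self.graph_, np.asarray(X, dtype=np.float32), y, self.config
        )
        self.gap_width_ = self.network_.report.gap_width
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "network_"):
            raise RuntimeError("CNNFeatureExtractor is not fitted")
        return self.network_.gap_features(np.asarray(X, dtype=np.float32)).astype(np.float64)

    def fit_transform(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.fit(X, y).transform(X)
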