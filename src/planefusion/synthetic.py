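"""Synthetic test-data generators.

Stands in for the real ultrasound-plane datasets so that every pipeline
stage is exercisable offline:

* :func:`generate_plane_images` emits a folder-per-class PNG dataset
  whose classes are distinct geometric motifs under a fan-shaped scan
  mask with multiplicative Rayleigh speckle — a filled ellipse
  (abdomen-like), a ring (skull-like), a bright bar (femur-like) and
  pure speckle ("no plane").  Motif position and scale are jittered per
  image so the task is non-trivial; realism beyond speckle texture and
  class separability is a non-goal.
* :func:`generate_feature_matrix` emits a feature matrix with a known
  ("planted") set of class-informative columns, emulating GAP deep
  features with ground truth, so feature-selection recovery is
  directly measurable.

All generators are bitwise reproducible under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .train_extract import FeatureMatrix

__all__ = [
    "ImageSetSpec",
    "PlantedFeatureSpec",
    "generate_plane_images",
    "generate_feature_matrix",
    "write_fixture_bundle",
    "DEFAULT_CLASS_MOTIFS",
]

DEFAULT_CLASS_MOTIFS = {
    "abdominal_circumference": "ellipse",
    "biparietal_diameter": "ring",
    "femur_length": "bar",
    "no_plane": "speckle",
}


@dataclass
class ImageSetSpec:
    """Specification of a synthetic plane-like image set."""

    class_names: list[str] = field(
        default_factory=lambda: list(DEFAULT_CLASS_MOTIFS)
    )
    images_per_class: int = 50
    image_size: int = 64
    speckle_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.images_per_class < 1:
            raise ValueError("images_per_class must be >= 1")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.speckle_strength < 0:
            raise ValueError("speckle_strength must be >= 0")
        unknown = [c for c in self.class_names if c not in DEFAULT_CLASS_MOTIFS]
        if unknown:
            raise ValueError(
                f"unknown class names {unknown}; known: {sorted(DEFAULT_CLASS_MOTIFS)}"
            )


@dataclass
class PlantedFeatureSpec:
    """Specification of a feature matrix with planted informative columns."""

    n_samples: int = 300
    n_features: int = 100
    informative: tuple[int, ...] = tuple(range(10))
    effect_size: float = 2.0
    n_classes: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        self.informative = tuple(int(j) for j in self.informative)
        if any(j < 0 or j >= self.n_features for j in self.informative):
            raise ValueError("informative indices must lie in [0, n_features)")
        if len(set(self.informative)) != len(self.informative):
            raise ValueError("informative indices must be unique")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


def _fan_mask(size: int) -> np.ndarray:
    """Ultrasound-like sector: apex at top center, opening downward."""
    yy, xx = np.mgrid[0:size, 0:size]
    y = yy / (size - 1)
    x = (xx - (size - 1) / 2) / ((size - 1) / 2)
    r = np.hypot(x, y * 1.2)
    angle_ok = np.abs(np.arctan2(x, np.maximum(y, 1e-9))) < np.deg2rad(45)
    return (angle_ok & (r > 0.12) & (r < 1.15)).astype(float)


def _motif(kind: str, size: int, rng: np.random.Generator) -> np.ndarray:
    """Render one jittered motif template in [0, 1]."""
    yy, xx = np.mgrid[0:size, 0:size]
    cy = size * (0.55 + rng.uniform(-0.10, 0.10))
    cx = size * (0.50 + rng.uniform(-0.10, 0.10))
    scale = 1.0 + rng.uniform(-0.15, 0.15)
    base = np.full((size, size), 0.18)
    if kind == "ellipse":
        ry, rx = 0.22 * size * scale, 0.28 * size * scale
        d = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
        base = base + 0.75 * (d <= 1.0)
    elif kind == "ring":
        ry, rx = 0.24 * size * scale, 0.26 * size * scale
        d = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
        base = base + 0.8 * (np.abs(d - 1.0) < 0.18)
    elif kind == "bar":
        theta = rng.uniform(-0.3, 0.3)
        u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
        v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
        base = base + 0.8 * ((np.abs(u) < 0.32 * size * scale) & (np.abs(v) < 0.05 * size))
    elif kind == "speckle":
        pass  # background speckle only
    else:
        raise ValueError(f"unknown motif kind {kind!r}")
    return np.clip(base, 0.0, 1.0)


def render_image(
    kind: str, size: int, speckle_strength: float, rng: np.random.Generator
) -> np.ndarray:
    """One 8-bit grayscale image: motif x fan mask x Rayleigh speckle."""
    template = _motif(kind, size, rng)
    if speckle_strength > 0:
        # Rayleigh(sigma=1) multiplicative speckle, normalized to unit mean
        noise = rng.rayleigh(scale=1.0, size=template.shape) / np.sqrt(np.pi / 2)
        speckled = template * (1.0 + speckle_strength * (noise - 1.0))
    else:
        speckled = template
    img = np.clip(speckled * _fan_mask(size), 0.0, 1.0)
    return (img * 255).round().astype(np.uint8)


def generate_plane_images(spec: ImageSetSpec, out_dir: str | Path) -> list[Path]:
    """Write a folder-per-class PNG dataset; returns the file paths."""
    out_dir = Path(out_dir)
    rng = np.random.default_rng(spec.seed)
    paths = []
    for cname in spec.class_names:
        cdir = out_dir / cname
        cdir.mkdir(parents=True, exist_ok=True)
        kind = DEFAULT_CLASS_MOTIFS[cname]
        for i in range(spec.images_per_class):
            img = render_image(kind, spec.image_size, spec.speckle_strength, rng)
            path = cdir / f"{cname}_{i:04d}.png"
            Image.fromarray(img, mode="L").save(path)
            paths.append(path)
    return paths


def generate_feature_matrix(
    spec: PlantedFeatureSpec,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Feature matrix with planted class-informative columns.

    Noise columns are standard normal.  Informative columns are
    *class-selective*, the way GAP deep-feature channels tend to be:
    column ``j`` is elevated by ``effect_size`` within-class SDs for
    exactly one class (classes assigned round-robin over the informative
    columns), so with at least as many informative columns as classes
    every class is covered and every informative column carries signal
    no other column fully duplicates.  Classes are balanced.  Returns
    the matrix and the planted ground-truth index set.
    """

    rng = np.random.default_rng(spec.seed)
    n, d, k = spec.n_samples, spec.n_features, spec.n_classes
    labels = np.sort(np.arange(n) % k)
    X = rng.standard_normal((n, d))
    for pos, j in enumerate(spec.informative):
        X[labels == (pos % k), j] += spec.effect_size
    class_names = [f"class_{c}" for c in range(k)]
    fm = FeatureMatrix(X, labels, class_names, source_model="planted")
    return fm, np.asarray(spec.informative, dtype=int)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(
    out_dir: str | Path,
    image_spec: ImageSetSpec | None = None,
    feature_spec: PlantedFeatureSpec | None = None,
    force: bool = False,
) -> dict:
    """Emit a complete miniature experiment (images + features + config)
    plus a JSON manifest of every file with its sha256 checksum.

    Refuses to overwrite an existing bundle unless ``force`` is set.
    """

    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(
            f"{manifest_path} already exists; pass force=True to overwrite"
        )
    image_spec = image_spec or ImageSetSpec(images_per_class=5, image_size=32)
    feature_spec = feature_spec or PlantedFeatureSpec(n_samples=60, n_features=20, informative=(0, 1, 2))
    out_dir.mkdir(parents=True, exist_ok=True)

    image_paths = generate_plane_images(image_spec, out_dir / "images")
    fm, truth = generate_feature_matrix(feature_spec)
    features_path = out_dir / "features.csv"
    fm.to_csv(features_path, binary_sidecar=False)
    config_path = out_dir / "config.json"
    config_path.write_text(
        json.dumps(
            {
                "image_spec": {**image_spec.__dict__},
                "feature_spec": {
                    **{k: (list(v) if isinstance(v, tuple) else v) for k, v in feature_spec.__dict__.items()}
                },
                "planted_informative": truth.tolist(),
            },
            indent=1,
        )
    )
    files = sorted(image_paths) + [features_path, config_path]
    manifest = {
        "seed": {"images": image_spec.seed, "features": feature_spec.seed},
        "files": {
            str(p.relative_to(out_dir)): _checksum(p) for p in files
        },
    }
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
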