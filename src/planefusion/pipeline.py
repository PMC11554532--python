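"""End-to-end orchestration of the classification framework.

The full run mirrors the study design: stratified 50/50 split, training
of both residual CNNs on the train half, GAP feature extraction on the
held-out half, independent IGNDO selection on each feature block,
serial fusion, and shallow-NN classification of five feature sets —
(1) raw 3-block features, (2) raw 4-block features, (3) selected
3-block, (4) selected 4-block, (5) fused — scored by stratified k-fold
cross-validation, followed by the paired accuracy-difference t-test
between two classifier families across the five experiments.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classify_eval import (
    ClassifierSpec,
    MetricsReport,
    TTestReport,
    kfold_cv,
    paired_diff_ttest,
)
from .gndo import GNDOConfig
from .model_zoo import build_four_residual_model, build_three_residual_model
from .selection import FitnessSpec, igndo_select, serial_fuse
from .synthetic import (
    ImageSetSpec,
    PlantedFeatureSpec,
    generate_feature_matrix,
    generate_plane_images,
)
from .train_extract import (
    FeatureMatrix,
    SplitSpec,
    TrainConfig,
    extract_features,
    load_image_folder,
    split_dataset,
    train_model,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_full_pipeline", "PipelineError"]

EXPERIMENTS = (
    "three_rb",
    "four_rb",
    "selected_three_rb",
    "selected_four_rb",
    "fused",
)


class PipelineError(RuntimeError):
    """Stage-named pipeline failure carrying a partial-artifact manifest."""

    def __init__(self, stage: str, message: str, artifacts: dict | None = None):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.artifacts = artifacts or {}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one input source must be set: ``dataset_path``
    (folder-per-class images), ``synthetic_spec`` (synthetic images), or
    ``planted_spec`` (two planted feature matrices standing in for the
    two CNNs' extracted features, so the selection/fusion/classification
    stages run under known ground truth without CNN training).  ``seed``
    feeds every stochastic stage (split, CNN init/batching, GNDO, CV
    folds).
    """

    dataset_path: str | None = None
    synthetic_spec: ImageSetSpec | None = None
    planted_spec: PlantedFeatureSpec | None = None
    image_size: int = 64
    width_scale: float = 1.0 / 8.0
    train: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            learning_rate=0.001, max_epochs=20, mini_batch=32
        )
    )
    gndo: GNDOConfig = field(default_factory=lambda: GNDOConfig(population_size=10, max_iterations=15))
    fitness: FitnessSpec = field(default_factory=FitnessSpec)
    classifier_families: tuple[str, ...] = ("medium", "trilayered")
    ttest_pair: tuple[str, str] = ("medium", "trilayered")
    cv_folds: int = 10
    output_dir: str = "runs"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(doc)
        if "train" in kwargs:
            kwargs["train"] = TrainConfig(**kwargs["train"])
        if "gndo" in kwargs:
            kwargs["gndo"] = GNDOConfig(**kwargs["gndo"])
        if "fitness" in kwargs:
            kwargs["fitness"] = FitnessSpec(**kwargs["fitness"])
        if "synthetic_spec" in kwargs and kwargs["synthetic_spec"] is not None:
            kwargs["synthetic_spec"] = ImageSetSpec(**kwargs["synthetic_spec"])
        if "planted_spec" in kwargs and kwargs["planted_spec"] is not None:
            kwargs["planted_spec"] = PlantedFeatureSpec(**kwargs["planted_spec"])
        for key in ("classifier_families", "ttest_pair"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def validate(self) -> None:
        sources = [self.dataset_path, self.synthetic_spec, self.planted_spec]
        if sum(s is not None for s in sources) != 1:
            raise ValueError(
                "exactly one of dataset_path, synthetic_spec, planted_spec "
                "must be provided"
            )
        if self.dataset_path is not None and not Path(self.dataset_path).is_dir():
            raise ValueError(f"dataset path {self.dataset_path!r} does not exist")


@dataclass
class RunReport:
    """Artifacts and metrics of the five experiments plus the t-test."""

    artifacts: dict
    metrics: dict  # experiment -> family -> MetricsReport
    ttest: TTestReport | None
    selected_widths: dict
    fused_width: int

    def accuracy_table(self) -> dict:
        return {
            exp: {fam: rep.accuracy for fam, rep in by_family.items()}
            for exp, by_family in self.metrics.items()
        }

    def to_json(self, path: str | Path) -> None:
        doc = {
            "artifacts": {k: str(v) for k, v in self.artifacts.items()},
            "selected_widths": self.selected_widths,
            "fused_width": self.fused_width,
            "metrics": {
                exp: {
                    fam: {
                        k: (np.asarray(v).tolist() if k == "confusion" else v)
                        for k, v in dataclasses.asdict(rep).items()
                    }
                    for fam, rep in by_family.items()
                }
                for exp, by_family in self.metrics.items()
            },
        }
        if self.ttest is not None:
            tdoc = dataclasses.asdict(self.ttest)
            tdoc["diffs"] = np.asarray(self.ttest.diffs).tolist()
            tdoc["interval"] = list(self.ttest.interval)
            doc["ttest"] = tdoc
        Path(path).write_text(json.dumps(doc, indent=1))


def _derive_seed(seed: int, offset: int) -> int:
    return int((seed * 1000003 + offset) % (2**31 - 1))


def run_full_pipeline(config: RunConfig) -> RunReport:
    """Execute the five-experiment pipeline; see the module docstring."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    def fail(stage: str, exc: Exception):
        raise PipelineError(stage, str(exc), artifacts) from exc

    feature_blocks: dict[str, FeatureMatrix] = {}
    if config.planted_spec is not None:
        # feature-level entry: two planted blocks stand in for the two
        # CNNs' GAP features; selection onward runs unchanged
        try:
            for tag, offset in (("three_rb", 3), ("four_rb", 4)):
                spec = dataclasses.replace(
                    config.planted_spec, seed=_derive_seed(config.seed, offset)
                )
                fm, truth = generate_feature_matrix(spec)
                fm.source_model = tag
                fm_path = out_dir / f"features_{tag}.csv"
                fm.to_csv(fm_path, binary_sidecar=False)
                artifacts[f"features_{tag}"] = fm_path
                artifacts[f"planted_truth_{tag}"] = out_dir / f"truth_{tag}.json"
                Path(artifacts[f"planted_truth_{tag}"]).write_text(
                    json.dumps(truth.tolist())
                )
                feature_blocks[tag] = fm
        except Exception as exc:
            fail("planted_features", exc)
        return _select_fuse_classify(config, out_dir, artifacts, feature_blocks)

    # --- data -----------------------------------------------------------
    try:
        if config.dataset_path is not None:
            data_dir = Path(config.dataset_path)
        else:
            data_dir = out_dir / "synthetic_images"
            spec = dataclasses.replace(
                config.synthetic_spec,
                image_size=config.image_size,
                seed=_derive_seed(config.seed, 1),
            )
            generate_plane_images(spec, data_dir)
        artifacts["dataset"] = data_dir
        images, labels, class_names = load_image_folder(data_dir, config.image_size)
    except PipelineError:
        raise
    except Exception as exc:
        fail("data", exc)

    # --- split ----------------------------------------------------------
    try:
        split = SplitSpec(train_fraction=0.5, seed=_derive_seed(config.seed, 2))
        train_idx, test_idx = split_dataset(labels, split)
        artifacts["split"] = out_dir / "split.json"
        Path(artifacts["split"]).write_text(
            json.dumps({"train": train_idx.tolist(), "test": test_idx.tolist()})
        )
    except Exception as exc:
        fail("split", exc)

    # --- train CNNs and extract GAP features on the held-out half -------
    for tag, builder in (
        ("three_rb", build_three_residual_model),
        ("four_rb", build_four_residual_model),
    ):
        try:
            graph = builder(
                len(class_names),
                (config.image_size, config.image_size, 3),
                width_scale=config.width_scale,
            )
            tcfg = dataclasses.replace(
                config.train, seed=_derive_seed(config.seed, 3 if tag == "three_rb" else 4)
            )
            net, trace = train_model(graph, images[train_idx], labels[train_idx], tcfg)
            trace_path = out_dir / f"loss_{tag}.csv"
            trace.to_csv(trace_path, index=False)
            artifacts[f"loss_{tag}"] = trace_path
            fm = extract_features(
                net, images[test_idx], labels[test_idx], class_names, source_model=tag
            )
            fm_path = out_dir / f"features_{tag}.csv"
            fm.to_csv(fm_path, binary_sidecar=False)
            artifacts[f"features_{tag}"] = fm_path
            feature_blocks[tag] = fm
            logger.info("%s trained; GAP width %d", tag, fm.width)
        except Exception as exc:
            fail(f"train_extract:{tag}", exc)

    return _select_fuse_classify(config, out_dir, artifacts, feature_blocks)


def _select_fuse_classify(
    config: RunConfig,
    out_dir: Path,
    artifacts: dict,
    feature_blocks: dict[str, FeatureMatrix],
) -> RunReport:
    """Selection, fusion, classification and t-test over two blocks."""

    def fail(stage: str, exc: Exception):
        raise PipelineError(stage, str(exc), artifacts) from exc

    # --- IGNDO selection on each block ----------------------------------
    selected: dict[str, FeatureMatrix] = {}
    selected_widths: dict[str, int] = {}
    for tag in ("three_rb", "four_rb"):
        try:
            fm = feature_blocks[tag]
            gcfg = dataclasses.replace(
                config.gndo, seed=_derive_seed(config.seed, 5 if tag == "three_rb" else 6)
            )
            fspec = dataclasses.replace(
                config.fitness, seed=_derive_seed(config.seed, 7)
            )
            result = igndo_select(fm, fspec, gcfg)
            sel_path = out_dir / f"selection_{tag}.json"
            result.to_json(sel_path)
            artifacts[f"selection_{tag}"] = sel_path
            selected[tag] = FeatureMatrix(
                fm.values[:, result.mask],
                fm.labels,
                fm.class_names,
                source_model=f"{tag}:selected",
            )
            selected_widths[tag] = result.selected_width
        except Exception as exc:
            fail(f"select:{tag}", exc)

    # --- serial fusion ---------------------------------------------------
    try:
        fused = serial_fuse(selected["three_rb"], selected["four_rb"])
        fused_path = out_dir / "features_fused.csv"
        fused.to_csv(fused_path, binary_sidecar=False)
        artifacts["features_fused"] = fused_path
    except Exception as exc:
        fail("fuse", exc)

    # --- classification of the five experiments -------------------------
    experiment_data = {
        "three_rb": feature_blocks["three_rb"],
        "four_rb": feature_blocks["four_rb"],
        "selected_three_rb": selected["three_rb"],
        "selected_four_rb": selected["four_rb"],
        "fused": fused,
    }
    metrics: dict[str, dict[str, MetricsReport]] = {}
    for exp, fm in experiment_data.items():
        metrics[exp] = {}
        for family in config.classifier_families:
            try:
                spec = ClassifierSpec(family=family, seed=_derive_seed(config.seed, 8))
                metrics[exp][family] = kfold_cv(
                    spec, fm, k=config.cv_folds, seed=_derive_seed(config.seed, 9)
                )
            except Exception as exc:
                fail(f"classify:{exp}:{family}", exc)

    # --- t-test between the configured pair ------------------------------
    ttest = None
    fam_a, fam_b = config.ttest_pair
    if fam_a in config.classifier_families and fam_b in config.classifier_families:
        acc_a = [metrics[exp][fam_a].accuracy for exp in EXPERIMENTS]
        acc_b = [metrics[exp][fam_b].accuracy for exp in EXPERIMENTS]
        high, low = (
            (acc_a, acc_b)
            if np.mean(acc_a) >= np.mean(acc_b)
            else (acc_b, acc_a)
        )
        try:
            ttest = paired_diff_ttest(np.array(high), np.array(low))
        except Exception as exc:
            fail("ttest", exc)

    report = RunReport(
        artifacts=artifacts,
        metrics=metrics,
        ttest=ttest,
        selected_widths=selected_widths,
        fused_width=fused.width,
    )
    report_path = out_dir / "run_report.json"
    report.to_json(report_path)
    artifacts["report"] = report_path
    return report
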