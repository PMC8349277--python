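"""End-to-end pipelines tying segmentation, features, classification and
metrics together, with reproducible seeding and provenance hashing.

Thermogram pipeline:  image -> body segmentation -> left/right ROI split ->
per-side Gabor energy vectors -> bilateral asymmetry signature -> repeated
stratified SVM experiment.

Mammogram pipeline:  pre-segmented ROI -> difference-of-Gaussians denoise ->
GLCM/Haralick features -> repeated stratified ensemble experiment.

Per-image failures are quarantined (recorded in a failure list) rather than
aborting a batch; every artifact embeds a hash of the configuration that
produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import gabor, glcm, io_formats, metrics, segmentation
from .classification import (
    ClassifierConfig,
    EnsembleConfig,
    ExperimentProtocol,
    run_experiment,
    save_model,
    train_base_classifier,
    train_ensemble,
)
from .errors import BreastAsymError, ContractError
from .io_formats import DatasetManifest, ImageGrid, PixelKind
from .synthetic import ThermoScene

logger = logging.getLogger("breastasym")

__all__ = [
    "PipelineConfig",
    "thermo_signature",
    "mammo_features",
    "compute_feature_table",
    "scenes_to_feature_table",
    "task_labels",
    "run_task_experiment",
    "run_pipeline",
]

TASKS = ("normal_vs_abnormal", "benign_vs_malignant")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    modality: str = "thermo"  # {thermo, mammo}
    task: str = "normal_vs_abnormal"
    seed: int = 0
    segmentation: segmentation.SegmentationConfig = segmentation.SegmentationConfig()
    gabor: gabor.GaborBankConfig = gabor.GaborBankConfig()
    glcm: glcm.GLCMConfig = glcm.GLCMConfig()
    classifier: ClassifierConfig = ClassifierConfig()
    ensemble: EnsembleConfig | None = None
    protocol: ExperimentProtocol = ExperimentProtocol()

    def __post_init__(self) -> None:
        if self.modality not in ("thermo", "mammo"):
            raise ContractError(f"unknown modality {self.modality!r}")
        if self.task not in TASKS:
            raise ContractError(f"unknown task {self.task!r}; valid: {TASKS}")
        if self.modality == "mammo" and self.ensemble is None:
            # Haralick features live on mixed scales, so the mammogram branch
            # standardizes and uses the variance-scaled kernel width.
            object.__setattr__(
                self,
                "ensemble",
                EnsembleConfig(
                    rule="majority",
                    base=ClassifierConfig(gamma="scale", standardize=True),
                ),
            )

    @classmethod
    def from_mapping(cls, data: Mapping) -> "PipelineConfig":
        """Build from a (YAML/JSON-loaded) nested mapping; absent keys keep defaults."""
        kwargs: dict = {}
        for key in ("modality", "task", "seed"):
            if key in data:
                kwargs[key] = data[key]
        section_types = {
            "segmentation": segmentation.SegmentationConfig,
            "gabor": gabor.GaborBankConfig,
            "glcm": glcm.GLCMConfig,
            "classifier": ClassifierConfig,
            "protocol": ExperimentProtocol,
        }
        for key, typ in section_types.items():
            if key in data and data[key] is not None:
                section = dict(data[key])
                for tup_key in ("frequencies", "orientations", "dog_sigmas", "crop"):
                    if tup_key in section and isinstance(section[tup_key], list):
                        section[tup_key] = tuple(section[tup_key])
                kwargs[key] = typ(**section)
        if data.get("ensemble") is not None:
            section = dict(data["ensemble"])
            if "base" in section and isinstance(section["base"], Mapping):
                section["base"] = ClassifierConfig(**section["base"])
            kwargs["ensemble"] = EnsembleConfig(**section)
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for provenance."""

        def _plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [_plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        blob = json.dumps(_plain(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# per-image feature extraction
# ---------------------------------------------------------------------------

def thermo_signature(
    image: ImageGrid | np.ndarray,
    seg_config: segmentation.SegmentationConfig | None = None,
    bank_config: gabor.GaborBankConfig | None = None,
    bank: Sequence[gabor.GaborFilterSpec] | None = None,
) -> dict[str, float]:
    """Segment a bilateral thermogram and return its asymmetry signature
    as named features ``d_f{freq}_o{deg}``."""
    seg_config = seg_config or segmentation.SegmentationConfig()
    bank_config = bank_config or gabor.GaborBankConfig()
    if bank is None:
        bank = gabor.build_filter_bank(bank_config)
    pair = segmentation.segment_and_split(image, seg_config)
    left = gabor.extract_feature_vector(
        pair.left_roi, pair.left_mask, bank, bank_config.energy_mode, side="left"
    )
    right = gabor.extract_feature_vector(
        pair.right_roi, pair.right_mask, bank, bank_config.energy_mode, side="right"
    )
    sig = gabor.asymmetry_signature(left, right)
    names = gabor.feature_names(bank_config, prefix="d")
    return dict(zip(names, sig.values.tolist()))


def mammo_features(
    image: ImageGrid | np.ndarray,
    config: glcm.GLCMConfig | None = None,
    mask: np.ndarray | None = None,
) -> dict[str, float]:
    """Denoise a pre-segmented mammogram ROI and return its Haralick features."""
    config = config or glcm.GLCMConfig()
    arr = image.values if isinstance(image, ImageGrid) else np.asarray(image, dtype=float)
    denoised = glcm.dog_denoise(arr, *config.dog_sigmas)
    return glcm.glcm_feature_vector(denoised, mask, config)


# ---------------------------------------------------------------------------
# batch feature tables
# ---------------------------------------------------------------------------

def _load_record_image(path: Path) -> ImageGrid:
    if path.suffix.lower() in (".txt", ".csv", ".dat"):
        return io_formats.read_temperature_matrix(path)
    return io_formats.read_image(path)


def compute_feature_table(
    manifest: DatasetManifest, root: str | Path, config: PipelineConfig
) -> tuple[pd.DataFrame, list[dict]]:
    """Extract features for every manifest record; quarantine failures.

    Returns (feature dataframe with id/label columns, failure records)."""
    root = Path(root)
    bank = gabor.build_filter_bank(config.gabor) if config.modality == "thermo" else None
    rows: list[tuple[str, str, dict[str, float]]] = []
    failures: list[dict] = []
    for rec in manifest.records:
        t0 = time.perf_counter()
        try:
            grid = _load_record_image(root / rec.path)
            if config.modality == "thermo":
                feats = thermo_signature(grid, config.segmentation, config.gabor, bank)
            else:
                feats = mammo_features(grid, config.glcm)
            rows.append((rec.subject_id, rec.label, feats))
            logger.info(
                "features %s label=%s dt=%.3fs", rec.path, rec.label, time.perf_counter() - t0
            )
        except (BreastAsymError, OSError) as exc:
            failures.append({"path": rec.path, "stage": "features", "error": str(exc)})
            logger.warning("quarantined %s: %s", rec.path, exc)
    if not rows:
        raise ContractError("no image yielded features; see the failure manifest")
    names = sorted(rows[0][2].keys())
    df = pd.DataFrame(
        [[rid, label] + [feats[n] for n in names] for rid, label, feats in rows],
        columns=["id", "label"] + names,
    )
    return df, failures


def scenes_to_feature_table(
    scenes: Sequence[ThermoScene], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """In-memory thermo feature table straight from generated scenes."""
    config = config or PipelineConfig()
    bank = gabor.build_filter_bank(config.gabor)
    rows = []
    for i, scene in enumerate(scenes):
        feats = thermo_signature(scene.grid, config.segmentation, config.gabor, bank)
        rows.append([f"S{i:04d}", scene.label] + [feats[n] for n in sorted(feats)])
    feature_names = sorted(gabor.feature_names(config.gabor, prefix="d"))
    return pd.DataFrame(rows, columns=["id", "label"] + feature_names)


def task_labels(labels: Sequence[str], task: str) -> tuple[np.ndarray, np.ndarray, str]:
    """Map three-class manifest labels onto a binary task.

    Returns (row selector, mapped labels, positive label)."""
    labels = np.asarray(labels, dtype=object)
    if task == "normal_vs_abnormal":
        keep = np.ones(len(labels), dtype=bool)
        mapped = np.where(labels == "normal", "normal", "abnormal")
        return keep, mapped, "abnormal"
    keep = np.isin(labels, ("benign", "malignant"))
    return keep, labels.copy(), "malignant"


def run_task_experiment(
    features: pd.DataFrame, config: PipelineConfig
) -> tuple[list[metrics.MetricsReport], metrics.AggregateReport]:
    """Run the repeated-split experiment for the configured binary task."""
    keep, mapped, positive = task_labels(features["label"].tolist(), config.task)
    if keep.sum() < 4:
        raise ContractError(f"too few samples for task {config.task}")
    X = features.loc[keep, [c for c in features.columns if c not in ("id", "label")]].to_numpy(
        dtype=float
    )
    y = mapped[keep]
    clf_config = config.ensemble if config.ensemble is not None else config.classifier
    protocol = dataclasses.replace(config.protocol, seed=config.protocol.seed or config.seed)
    return run_experiment(X, y, clf_config, protocol, positive=positive)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    config: PipelineConfig, manifest_path: str | Path, root: str | Path, out_dir: str | Path
) -> dict[str, Path]:
    """Run the configured modality end to end, writing all artifacts.

    Artifacts: ``features.csv``, ``model.joblib`` (fitted on all kept
    samples), ``metrics.json``, ``failures.json`` and ``run.log`` under
    ``out_dir``.  Identical config + seed give identical metrics artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        t0 = time.perf_counter()
        logger.info("run start modality=%s task=%s config_hash=%s", config.modality, config.task, chash)
        manifest = io_formats.read_manifest(manifest_path)
        features, failures = compute_feature_table(manifest, root, config)
        t_feat = time.perf_counter()
        logger.info("features done n=%d dt=%.2fs", len(features), t_feat - t0)

        features_path = out / "features.csv"
        with open(features_path, "w") as fh:
            fh.write(f"# config_hash={chash}\n")
            features.to_csv(fh, index=False, float_format="%.6g")

        reports, agg = run_task_experiment(features, config)
        t_exp = time.perf_counter()
        logger.info("experiment done iterations=%d dt=%.2fs", len(reports), t_exp - t_feat)

        metrics_path = out / "metrics.json"
        metrics.report_to_json(
            reports,
            agg,
            metrics_path,
            extra={"config_hash": chash, "modality": config.modality, "task": config.task},
        )

        keep, mapped, _ = task_labels(features["label"].tolist(), config.task)
        X = features.loc[
            keep, [c for c in features.columns if c not in ("id", "label")]
        ].to_numpy(dtype=float)
        y = mapped[keep]
        if config.ensemble is not None:
            model = train_ensemble(X, y, config.ensemble)
        else:
            model = train_base_classifier(X, y, config.classifier)
        model_path = out / "model.joblib"
        save_model(model, model_path)

        failures_path = out / "failures.json"
        failures_path.write_text(
            json.dumps({"config_hash": chash, "failures": failures}, indent=2) + "\n"
        )
        logger.info("run done dt=%.2fs", time.perf_counter() - t0)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return {
        "features": features_path,
        "metrics": metrics_path,
        "model": model_path,
        "failures": failures_path,
        "log": out / "run.log",
    }
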