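"""End-to-end orchestration: phantoms -> preprocess -> CBO-Otsu segmentation
-> nodule extraction -> LBP features -> DenseNet-style classification ->
metrics -> optional IoT transmission.

A run is driven by one :class:`PipelineConfig` and produces a JSON-ready
report holding per-image thresholds, nodule tables, predictions with their
display messages, the metrics report, and every seed/config used — enough
to re-execute the run exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import classify, evaluate, features, iot, phantom, preprocess, segment
from .cbo import CBOConfig


@dataclass(frozen=True)
class SourceConfig:
    """Either a manifest to load or a phantom dataset to generate in memory."""

    manifest_path: str | None = None
    images_root: str = "."
    n_phantoms: int = 240
    class_balance: float = 0.5
    phantom: phantom.PhantomSpec = field(default_factory=phantom.PhantomSpec)
    split_fractions: tuple[float, float, float] = (0.70, 0.10, 0.20)


@dataclass(frozen=True)
class SegmentConfig:
    k: int = 1
    population: int = 20
    iterations: int = 40
    min_area: int = 20
    foreground_label: int | None = None  # default: top class


@dataclass(frozen=True)
class IoTConfig:
    enabled: bool = False
    endpoint: str = "https://api.thingspeak.com/update"
    api_key: str = ""
    field_mapping: dict[str, str] = field(default_factory=lambda: dict(iot.DEFAULT_FIELD_MAPPING))
    min_interval_seconds: float = 15.0
    policy: str = "reject"


@dataclass(frozen=True)
class PipelineConfig:
    source: SourceConfig = field(default_factory=SourceConfig)
    preprocessing: tuple[str, ...] = ("equalize",)  # any order of "equalize", "median"
    median_window: int = 3
    segmentation: SegmentConfig = field(default_factory=SegmentConfig)
    lbp: features.LBPConfig = field(default_factory=features.LBPConfig)
    densenet: classify.DenseNetConfig = field(default_factory=classify.DenseNetConfig)
    train: classify.TrainConfig = field(default_factory=classify.TrainConfig)
    pretrained_weights: str | None = None
    train_enabled: bool = True
    iot: IoTConfig = field(default_factory=IoTConfig)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        if "source" in d:
            src = dict(d["source"])
            if "phantom" in src:
                src["phantom"] = phantom.PhantomSpec(**src["phantom"])
            if "split_fractions" in src:
                src["split_fractions"] = tuple(src["split_fractions"])
            d["source"] = SourceConfig(**src)
        if "segmentation" in d:
            d["segmentation"] = SegmentConfig(**d["segmentation"])
        if "lbp" in d:
            d["lbp"] = features.LBPConfig(**d["lbp"])
        if "densenet" in d:
            d["densenet"] = classify.DenseNetConfig(**d["densenet"])
        if "train" in d:
            d["train"] = classify.TrainConfig(**d["train"])
        if "iot" in d:
            d["iot"] = IoTConfig(**d["iot"])
        if "preprocessing" in d:
            d["preprocessing"] = tuple(d["preprocessing"])
        return PipelineConfig(**d)

    @staticmethod
    def from_json(text: str) -> "PipelineConfig":
        return PipelineConfig.from_dict(json.loads(text))


class StageError(RuntimeError):
    """Wraps a failure with the stage name and image identifier."""

    def __init__(self, stage: str, image_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {image_id!r}: {cause}")
        self.stage, self.image_id, self.cause = stage, image_id, cause


def _preprocess_image(image: np.ndarray, config: PipelineConfig) -> np.ndarray:
    for step in config.preprocessing:
        if step == "equalize":
            image = preprocess.equalize(image)
        elif step == "median":
            image = preprocess.median_filter(image, config.median_window)
        else:
            raise ValueError(f"unknown preprocessing step {step!r}")
    return image


def _load_or_generate(config: PipelineConfig):
    """Return (ids, images, labels) for the configured source."""
    src = config.source
    if src.manifest_path is not None:
        manifest = phantom.load_manifest(src.manifest_path)
        root = Path(src.images_root)
        images = [preprocess.read_image(root / p) for p in manifest["image_path"]]
        return list(manifest["image_path"]), images, list(manifest["label"]), manifest
    labels_n = round(src.n_phantoms * src.class_balance)
    labels = np.array([phantom.MALIGNANT] * labels_n + [phantom.BENIGN] * (src.n_phantoms - labels_n))
    rng = np.random.default_rng(config.seed)
    rng.shuffle(labels)
    ids, images = [], []
    for i, lab in enumerate(labels):
        spec_i = phantom.spec_for_class(src.phantom, lab, phantom._child_seed(config.seed, i))
        img, _, _ = phantom.generate_phantom(spec_i)
        ids.append(f"phantom_{i:04d}")
        images.append(img)
    import pandas as pd

    manifest = pd.DataFrame(
        {"image_path": ids, "label": labels, "split": "unassigned", "fold": pd.NA}
    )
    return ids, images, list(labels), manifest


def run_pipeline(config: PipelineConfig, transport=None) -> dict:
    """Execute the full pipeline and return the run report.

    ``transport`` overrides the IoT transport (tests pass a mock); when
    ``config.iot.enabled`` is false no transmission is attempted at all.
    """
    t0 = time.time()
    report: dict = {"config": json.loads(config.to_json()), "stages": {}}

    ids, images, labels, manifest = _load_or_generate(config)
    manifest = phantom.split_dataset(manifest, config.source.split_fractions, seed=config.seed)
    report["stages"]["ingest"] = {"n_images": len(images)}

    pre_images = []
    for image_id, img in zip(ids, images):
        try:
            pre_images.append(_preprocess_image(img, config))
        except Exception as exc:
            raise StageError("preprocess", image_id, exc) from exc

    # classifier: train on the train/val splits or load pretrained weights
    y = np.array([1 if lab == phantom.MALIGNANT else 0 for lab in labels])
    splits = manifest["split"].to_numpy()
    if config.pretrained_weights is not None:
        model = classify.load_model(config.pretrained_weights)
        history = None
    elif config.train_enabled:
        model = classify.build_densenet(replace(config.densenet, seed=config.seed))
        tr = splits == "train"
        va = splits == "val"
        X_tr = np.stack([pre_images[i] for i in np.flatnonzero(tr)])
        X_va = np.stack([pre_images[i] for i in np.flatnonzero(va)]) if va.any() else None
        try:
            history = classify.fit_arrays(
                model, X_tr, y[tr], replace(config.train, seed=config.seed),
                X_va, y[va] if va.any() else None,
            )
        except Exception as exc:
            raise StageError("train", "<train split>", exc) from exc
    else:
        raise ValueError("training disabled and no pretrained_weights supplied")

    seg_cfg = config.segmentation
    test_idx = np.flatnonzero(splits == "test")
    predictions, nodule_tables, thresholds_per_image = [], {}, {}
    for i in test_idx:
        image_id = ids[i]
        img = pre_images[i]
        try:
            cbo_cfg = CBOConfig(
                n=seg_cfg.population, dims=seg_cfg.k,
                bounds=tuple((0.0, 254.0) for _ in range(seg_cfg.k)),
                max_iters=seg_cfg.iterations, seed=config.seed + int(i),
            )
            thr = segment.cbo_multilevel_threshold(img, k=seg_cfg.k, config=cbo_cfg)
            label_img = segment.apply_thresholds(img, thr)
            fg = seg_cfg.foreground_label if seg_cfg.foreground_label is not None else seg_cfg.k
            regions = segment.extract_nodules(
                label_img, fg, seg_cfg.min_area, intensity_image=img, exclude_border=True
            )
        except Exception as exc:
            raise StageError("segment", image_id, exc) from exc
        try:
            feats = (
                features.feature_vector(img, regions[0], config.lbp).tolist() if regions else None
            )
        except Exception as exc:
            raise StageError("features", image_id, exc) from exc
        try:
            pred = classify.predict(model, img)
        except Exception as exc:
            raise StageError("classify", image_id, exc) from exc
        thresholds_per_image[image_id] = [int(t) for t in thr]
        nodule_tables[image_id] = segment.regions_to_records(regions)
        predictions.append(
            {
                "image_id": image_id,
                "true_label": labels[i],
                "label": pred.label,
                "probabilities": list(pred.probabilities),
                "message": pred.message,
                "lbp_features": feats,
            }
        )

    true_test = [labels[i] for i in test_idx]
    pred_test = [p["label"] for p in predictions]
    scores = [p["probabilities"][1] for p in predictions]
    counts = evaluate.confusion(true_test, pred_test)
    try:
        _, auc = evaluate.roc(scores, true_test)
    except ValueError:
        auc = None
    metrics_report = evaluate.metrics(counts, auc=auc)

    report["thresholds"] = thresholds_per_image
    report["nodules"] = nodule_tables
    report["predictions"] = predictions
    report["metrics"] = metrics_report.as_dict()
    report["metrics_percent"] = metrics_report.as_dict(percentages=True)
    report["confusion"] = {"TP": counts.TP, "TN": counts.TN, "FP": counts.FP, "FN": counts.FN}
    if history is not None:
        report["training_history"] = history.to_dict(orient="list")

    if config.iot.enabled:
        if transport is None:
            transport = iot.HTTPTransport(config.iot.endpoint)
        update = iot.format_channel_update(
            metrics_report, config.iot.field_mapping, config.iot.api_key
        )
        status = iot.Transmitter(
            transport, config.iot.min_interval_seconds, config.iot.policy
        ).transmit(update)
        report["transmission_status"] = status.status
        report["transmission_entry_id"] = status.entry_id
    else:
        report["transmission_status"] = "disabled"

    report["elapsed_seconds"] = time.time() - t0
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=str))
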