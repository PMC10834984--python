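"""End-to-end orchestration: the model/results facade and the stage runner.

The central objects follow the familiar model/results split:

>>> records = simulate.generate_dataset(seed=7)
>>> model = SiftCnnModel.from_records(records, config)   # signals -> images
>>> res = model.fit()                                    # SMOTE + CNN training
>>> report = res.evaluate(test_images, test_labels)      # MetricReport
>>> print(res.summary())

``SiftCnnModel`` holds the prepared CNN inputs (rendered, keypoint-overlaid
images) and the configuration; ``fit`` balances classes with SMOTE and trains
the convolutional classifier, returning a ``SiftCnnResults`` that carries the
fitted network, its training history and evaluation/prediction methods.

Cross-validation helpers construct a fresh model inside each training
partition, so oversampling and fitting never see test data.

``run_stage`` provides the file-based stage pipeline used by the CLI
(generate -> preprocess -> render -> features -> balance -> train ->
evaluate), writing a manifest JSON per stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnn as cnn_mod
from .balance import FeatureDataset, smote
from .config import PipelineConfig
from .evaluate import (
    MetricReport,
    basic_metrics,
    confusion_matrix,
    holdout_cv,
    kfold_cv,
    rmse,
)
from .features import detect_and_describe, overlay_keypoints
from .preprocess import preprocess_record
from .render import SignalImage, render_segment
from .simulate import CLASSES, generate_dataset

STAGES = (
    "generate", "preprocess", "render", "features", "balance", "train", "evaluate",
)


def prepare_images(records, config: PipelineConfig, with_descriptors: bool = False):
    """Records -> denoised/normalised/segmented -> rendered -> keypoint-overlaid.

    Returns ``(images, labels, meta)`` where ``images`` is (N, H, W, 3) uint8,
    ``labels`` an array of class names, and ``meta`` one dict per image
    (parent id, segment index, keypoint count, and — with
    ``with_descriptors`` — the keypoints and descriptor matrix).
    """
    r, s = config.render, config.sift
    value_range = (0.0, 1.0) if r.y_scale == "global" else None
    images, labels, meta = [], [], []
    for record in records:
        segments = preprocess_record(
            record, config.preprocess.denoise_window, config.preprocess.n_segments
        )
        for seg in segments:
            img = render_segment(
                seg, r.width, r.height, r.line_width, r.pad, value_range
            )
            row = {
                "parent_id": seg.parent_id,
                "segment_index": seg.segment_index,
                "label": seg.label,
            }
            if s.fusion == "overlay" or with_descriptors:
                keypoints, descriptors = detect_and_describe(
                    img,
                    n_octaves=s.n_octaves,
                    n_intervals=s.n_intervals,
                    base_sigma=s.base_sigma,
                    contrast_threshold=s.contrast_threshold,
                    edge_ratio=s.edge_ratio,
                )
                row["n_keypoints"] = len(keypoints)
                if with_descriptors:
                    row["keypoints"] = keypoints
                    row["descriptors"] = descriptors
                if s.fusion == "overlay":
                    img = overlay_keypoints(img, keypoints)
            images.append(img.pixels)
            labels.append(seg.label)
            meta.append(row)
    return np.stack(images), np.asarray(labels), meta


def _derive_seeds(seed: int, n: int) -> list[int]:
    return [int(v) % 2**31 for v in np.random.SeedSequence(seed).generate_state(n)]


class SiftCnnModel:
    """Classification model over prepared signal images.

    Parameters
    ----------
    images
        (N, H, W, 3) uint8 rasters (keypoint-overlaid renderings).
    labels
        Class name per image.
    config
        Pipeline configuration; only the ``smote`` and ``cnn`` sections are
        used at fit time.
    """

    def __init__(self, images, labels, config: PipelineConfig | None = None,
                 class_names=CLASSES):
        self.images = np.asarray(images)
        self.labels = np.asarray(labels)
        if self.images.ndim != 4 or self.images.shape[0] != self.labels.shape[0]:
            raise ValueError("images must be (N, H, W, 3) matching labels")
        self.config = config or PipelineConfig()
        self.class_names = tuple(class_names)
        self.meta: list = []

    @classmethod
    def from_records(cls, records, config: PipelineConfig | None = None) -> "SiftCnnModel":
        config = config or PipelineConfig()
        images, labels, meta = prepare_images(records, config)
        obj = cls(images, labels, config)
        obj.meta = meta
        return obj

    def _as_float(self) -> np.ndarray:
        x = self.images.astype(np.float32)
        return x / 255.0 if self.images.dtype == np.uint8 else x

    def fit(self, seed: int | None = None) -> "SiftCnnResults":
        """Balance classes with SMOTE, then train the CNN on all rows."""
        seed = self.config.seed if seed is None else seed
        smote_seed, init_seed, train_seed = _derive_seeds(seed, 3)

        x = self._as_float()
        n, h, w, c = x.shape
        dataset = FeatureDataset(x.reshape(n, -1), self.labels)
        balanced = smote(dataset, self.config.smote.k_neighbors, smote_seed)
        xb = balanced.features.reshape(-1, h, w, c)
        onehot = labels_to_onehot(balanced.labels, self.class_names)

        spec = self.config.cnn_spec((h, w, c))
        network = cnn_mod.build_model(spec, init_seed)
        trained = cnn_mod.train(network, xb, onehot, spec, train_seed)
        return SiftCnnResults(self, trained, balanced.class_counts(), seed)


def labels_to_onehot(labels, class_names=CLASSES) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_names)}
    out = np.zeros((len(labels), len(class_names)), dtype=np.float32)
    for i, lab in enumerate(labels):
        out[i, index[lab]] = 1.0
    return out


@dataclass
class SiftCnnResults:
    """Fitted classifier: estimates, training diagnostics and evaluation."""

    model: SiftCnnModel
    trained: cnn_mod.TrainedModel
    balanced_counts: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def history(self) -> dict:
        return self.trained.history

    def predict(self, images):
        """(probability matrix, predicted class names) for raw uint8 images."""
        x = np.asarray(images).astype(np.float32)
        if np.asarray(images).dtype == np.uint8:
            x /= 255.0
        probs, idx = cnn_mod.predict(self.trained, x)
        names = np.asarray(self.model.class_names)[idx]
        return probs, names

    def evaluate(self, images, labels) -> MetricReport:
        """Full metric stack on a labelled image set (incl. RMSE)."""
        probs, pred = self.predict(images)
        cm = confusion_matrix(np.asarray(labels), pred, list(self.model.class_names))
        report = basic_metrics(cm)
        report.rmse = rmse(labels_to_onehot(labels, self.model.class_names), probs)
        return report

    def summary(self) -> str:
        spec = self.trained.spec
        lines = [
            "SIFT-CNN classification results",
            "=" * 46,
            f"classes:          {', '.join(self.model.class_names)}",
            f"training images:  {sum(self.balanced_counts.values())} "
            f"(after SMOTE: {self.balanced_counts})",
            f"input shape:      {spec.input_shape}",
            f"epochs / batch:   {spec.epochs} / {spec.batch_size}",
            f"optimizer:        Adam (lr={spec.learning_rate})",
            "-" * 46,
            "layers:",
        ]
        for row in self.trained.network.summary():
            desc = ", ".join(f"{k}={v}" for k, v in row.items() if k != "type")
            lines.append(f"  {row['type']:<10s} {desc}")
        if self.history["loss"]:
            lines += [
                "-" * 46,
                f"final training loss:     {self.history['loss'][-1]:.4f}",
                f"final training accuracy: {self.history['accuracy'][-1]:.4f}",
            ]
        return "\n".join(lines)


def _cv_functions(config: PipelineConfig, seed: int):
    """train/eval closures for the CV harnesses; a fresh model per partition."""
    counter = {"i": 0}

    def train_fn(train_data):
        images, labels = train_data
        counter["i"] += 1
        fold_seed = _derive_seeds(seed, counter["i"] + 1)[-1]
        return SiftCnnModel(images, labels, config).fit(seed=fold_seed)

    def eval_fn(results: SiftCnnResults, test_data):
        images, labels = test_data
        return results.evaluate(images, labels)

    return train_fn, eval_fn


def holdout_evaluate(images, labels, config: PipelineConfig, seed: int | None = None):
    """Stratified hold-out: SMOTE and training inside the training split only."""
    seed = config.seed if seed is None else seed
    train_fn, eval_fn = _cv_functions(config, seed)
    return holdout_cv(
        np.asarray(images), np.asarray(labels),
        config.eval.test_fraction, seed, train_fn, eval_fn,
    )


def kfold_evaluate(images, labels, config: PipelineConfig, seed: int | None = None):
    """Stratified k-fold CV; returns (per-fold reports, mean/SD summary)."""
    seed = config.seed if seed is None else seed
    train_fn, eval_fn = _cv_functions(config, seed)
    return kfold_cv(
        np.asarray(images), np.asarray(labels),
        config.eval.k_folds, seed, train_fn, eval_fn,
    )


# --------------------------------------------------------------------------
# File-based stage pipeline (used by the CLI)
# --------------------------------------------------------------------------


def _write_manifest(outdir: Path, stage: str, config: PipelineConfig,
                    inputs: list, outputs: list, counts: dict) -> dict:
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "config_hash": config.hash(),
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
        "counts": counts,
    }
    mdir = outdir / "manifests"
    mdir.mkdir(parents=True, exist_ok=True)
    (mdir / f"{stage}.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the '{produced_by}' stage first"
        )
    return path


def _load_image_manifest(outdir: Path, config: PipelineConfig):
    source = "features" if config.sift.fusion == "overlay" else "render"
    name = "overlaid" if source == "features" else "images"
    manifest = _require(outdir / f"{name}_manifest.csv", source)
    frame = pd.read_csv(manifest)
    images, labels = [], []
    for _, row in frame.iterrows():
        img = SignalImage.load(
            row["path"], row["label"], (row["parent_id"], int(row["segment_index"]))
        )
        images.append(img.pixels)
        labels.append(row["label"])
    return np.stack(images), np.asarray(labels), frame


def run_stage(stage: str, config: PipelineConfig) -> dict:
    """Run one pipeline stage (or ``run-all``), writing artifacts + manifest."""
    if stage == "run-all":
        manifest = {}
        for name in STAGES:
            manifest[name] = run_stage(name, config)
        return manifest
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return _STAGE_FNS[stage](outdir, config)


def _stage_generate(outdir: Path, config: PipelineConfig) -> dict:
    d = config.data
    records = generate_dataset(
        counts=d.counts, seed=config.seed, n_samples=d.n_samples,
        sampling_rate=d.sampling_rate, noise_sd=d.noise_sd,
    )
    from .simulate import write_signal_table

    path = outdir / "records.csv.gz"
    write_signal_table(records, path)
    counts = {label: sum(r.label == label for r in records) for label in CLASSES}
    counts["records"] = len(records)
    return _write_manifest(outdir, "generate", config, [], [path], counts)


def _read_records(outdir: Path, config: PipelineConfig):
    from .simulate import read_signal_table

    path = _require(outdir / "records.csv.gz", "generate")
    return read_signal_table(path, config.data.sampling_rate)


def _stage_preprocess(outdir: Path, config: PipelineConfig) -> dict:
    records = _read_records(outdir, config)
    rows, matrices = [], []
    for record in records:
        for seg in preprocess_record(
            record, config.preprocess.denoise_window, config.preprocess.n_segments
        ):
            rows.append((seg.parent_id, seg.segment_index, seg.label))
            matrices.append(seg.samples)
    path = outdir / "segments.npz"
    np.savez_compressed(
        path,
        samples=np.stack(matrices),
        parent_id=np.array([r[0] for r in rows]),
        segment_index=np.array([r[1] for r in rows]),
        label=np.array([r[2] for r in rows]),
    )
    manifest_csv = outdir / "segments_manifest.csv"
    pd.DataFrame(rows, columns=["parent_id", "segment_index", "label"]).to_csv(
        manifest_csv, index=False
    )
    return _write_manifest(
        outdir, "preprocess", config,
        [outdir / "records.csv.gz"], [path, manifest_csv],
        {"segments": len(rows), "segment_length": int(matrices[0].size)},
    )


def _iter_segments(outdir: Path):
    from .preprocess import Segment

    data = np.load(_require(outdir / "segments.npz", "preprocess"), allow_pickle=False)
    for i in range(data["samples"].shape[0]):
        yield Segment(
            str(data["parent_id"][i]),
            str(data["label"][i]),
            int(data["segment_index"][i]),
            data["samples"][i],
        )


def _stage_render(outdir: Path, config: PipelineConfig) -> dict:
    r = config.render
    value_range = (0.0, 1.0) if r.y_scale == "global" else None
    img_dir = outdir / "images"
    img_dir.mkdir(exist_ok=True)
    rows = []
    for seg in _iter_segments(outdir):
        img = render_segment(seg, r.width, r.height, r.line_width, r.pad, value_range)
        path = img_dir / img.filename()
        img.save(path)
        rows.append((seg.parent_id, seg.segment_index, seg.label, str(path)))
    manifest_csv = outdir / "images_manifest.csv"
    pd.DataFrame(
        rows, columns=["parent_id", "segment_index", "label", "path"]
    ).to_csv(manifest_csv, index=False)
    return _write_manifest(
        outdir, "render", config, [outdir / "segments.npz"],
        [manifest_csv], {"images": len(rows)},
    )


def _stage_features(outdir: Path, config: PipelineConfig) -> dict:
    s = config.sift
    frame = pd.read_csv(_require(outdir / "images_manifest.csv", "render"))
    over_dir = outdir / "overlaid"
    over_dir.mkdir(exist_ok=True)
    kp_rows, desc_blocks, out_rows = [], [], []
    for _, row in frame.iterrows():
        img = SignalImage.load(
            row["path"], row["label"], (row["parent_id"], int(row["segment_index"]))
        )
        keypoints, descriptors = detect_and_describe(
            img, s.n_octaves, s.n_intervals, s.base_sigma,
            s.contrast_threshold, s.edge_ratio,
        )
        for kp in keypoints:
            kp_rows.append(
                (img.filename(), kp.x, kp.y, kp.sigma, kp.orientation, kp.response)
            )
        desc_blocks.append(descriptors)
        out = overlay_keypoints(img, keypoints) if s.fusion == "overlay" else img
        path = over_dir / out.filename()
        out.save(path)
        out_rows.append(
            (row["parent_id"], row["segment_index"], row["label"], str(path))
        )
    kp_csv = outdir / "keypoints.csv"
    pd.DataFrame(
        kp_rows, columns=["image", "x", "y", "sigma", "orientation", "response"]
    ).to_csv(kp_csv, index=False)
    desc = (
        np.concatenate(desc_blocks) if desc_blocks else np.zeros((0, 128), np.float32)
    )
    desc_bin = outdir / "descriptors.bin"
    desc.astype("<f4").tofile(desc_bin)
    (outdir / "descriptors.json").write_text(json.dumps(
        {"n": int(desc.shape[0]), "d": 128, "dtype": "float32",
         "byte_order": "little-endian", "layout": "row-major"}, indent=2,
    ))
    manifest_csv = outdir / "overlaid_manifest.csv"
    pd.DataFrame(
        out_rows, columns=["parent_id", "segment_index", "label", "path"]
    ).to_csv(manifest_csv, index=False)
    return _write_manifest(
        outdir, "features", config, [outdir / "images_manifest.csv"],
        [kp_csv, desc_bin, manifest_csv],
        {"images": len(out_rows), "keypoints": len(kp_rows)},
    )


def _stage_balance(outdir: Path, config: PipelineConfig) -> dict:
    images, labels, _ = _load_image_manifest(outdir, config)
    n = images.shape[0]
    flat = images.reshape(n, -1).astype(np.float32) / 255.0
    smote_seed = _derive_seeds(config.seed, 3)[0]
    balanced = smote(
        FeatureDataset(flat, labels), config.smote.k_neighbors, smote_seed
    )
    path = outdir / "balanced.npz"
    np.savez_compressed(
        path, features=balanced.features, labels=balanced.labels,
        synthetic=balanced.synthetic, shape=np.array(images.shape[1:]),
    )
    manifest_csv = outdir / "balanced_manifest.csv"
    pd.DataFrame({
        "row": np.arange(balanced.n),
        "label": balanced.labels,
        "provenance": np.where(balanced.synthetic, "synthetic", "original"),
    }).to_csv(manifest_csv, index=False)
    counts = {str(k): int(v) for k, v in balanced.class_counts().items()}
    return _write_manifest(
        outdir, "balance", config, [], [path, manifest_csv], counts,
    )


def _stage_train(outdir: Path, config: PipelineConfig) -> dict:
    images, labels, _ = _load_image_manifest(outdir, config)
    from .evaluate import stratified_split

    train_idx, test_idx = stratified_split(
        labels, config.eval.test_fraction, config.seed
    )
    model = SiftCnnModel(images[train_idx], labels[train_idx], config)
    results = model.fit(seed=config.seed)

    ckpt = outdir / "model.npz"
    cnn_mod_save(results.trained, ckpt)
    (outdir / "history.json").write_text(json.dumps(results.history, indent=2))
    (outdir / "split.json").write_text(json.dumps(
        {"train": train_idx.tolist(), "test": test_idx.tolist()}
    ))
    return _write_manifest(
        outdir, "train", config, [], [ckpt, outdir / "history.json"],
        {"train": int(train_idx.size), "test": int(test_idx.size),
         "epochs": config.cnn.epochs},
    )


def _stage_evaluate(outdir: Path, config: PipelineConfig) -> dict:
    ckpt = _require(outdir / "model.npz", "train")
    split = json.loads(_require(outdir / "split.json", "train").read_text())
    images, labels, _ = _load_image_manifest(outdir, config)
    trained = cnn_mod_load(ckpt)
    model = SiftCnnModel(images, labels, config)
    results = SiftCnnResults(model, trained)
    test_idx = np.asarray(split["test"])
    report = results.evaluate(images[test_idx], labels[test_idx])
    path = outdir / "metrics.json"
    path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    return _write_manifest(
        outdir, "evaluate", config, [ckpt], [path],
        {k: round(v, 6) for k, v in report.to_dict().items()},
    )


def cnn_mod_save(trained: cnn_mod.TrainedModel, path) -> None:
    """Checkpoint a trained network (weights + spec + history) as .npz."""
    import dataclasses as dc

    arrays = {}
    for i, layer in enumerate(trained.network.layers):
        for j, p in enumerate(layer.params):
            arrays[f"p_{i}_{j}"] = p
    arrays["spec_json"] = np.frombuffer(
        json.dumps(dc.asdict(trained.spec)).encode(), dtype=np.uint8
    )
    arrays["history_json"] = np.frombuffer(
        json.dumps(trained.history).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def cnn_mod_load(path) -> cnn_mod.TrainedModel:
    data = np.load(path)
    spec_dict = json.loads(bytes(data["spec_json"]).decode())
    spec_dict["input_shape"] = tuple(spec_dict["input_shape"])
    spec = cnn_mod.CnnSpec(**spec_dict)
    network = cnn_mod.build_model(spec, seed=0)
    for i, layer in enumerate(network.layers):
        for j, p in enumerate(layer.params):
            p[...] = data[f"p_{i}_{j}"]
    history = json.loads(bytes(data["history_json"]).decode())
    return cnn_mod.TrainedModel(network, history, spec)


_STAGE_FNS = {
    "generate": _stage_generate,
    "preprocess": _stage_preprocess,
    "render": _stage_render,
    "features": _stage_features,
    "balance": _stage_balance,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
}
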