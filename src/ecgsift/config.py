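"""Pipeline configuration: every tunable of every stage, with lossless
YAML/JSON round-tripping and strict (unknown-key-rejecting) parsing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cnn import CnnSpec


@dataclass
class DataConfig:
    counts: dict = field(default_factory=lambda: {"ARR": 96, "CHF": 30, "NSR": 36})
    n_samples: int = 65_535
    sampling_rate: float = 128.0
    noise_sd: float = 0.02


@dataclass
class PreprocessConfig:
    denoise_window: int = 5
    n_segments: int = 6


@dataclass
class RenderConfig:
    width: int = 200
    height: int = 200
    line_width: int = 1
    pad: int = 2
    y_scale: str = "per_segment"  # or "global"

    def __post_init__(self) -> None:
        if self.y_scale not in ("per_segment", "global"):
            raise ValueError(f"y_scale must be per_segment|global, got {self.y_scale!r}")


@dataclass
class SiftConfig:
    n_octaves: int = 4
    n_intervals: int = 3
    base_sigma: float = 1.6
    contrast_threshold: float = 0.03
    edge_ratio: float = 10.0
    fusion: str = "overlay"  # or "passthrough" (raw rendering fed to the CNN)

    def __post_init__(self) -> None:
        if self.fusion not in ("overlay", "passthrough"):
            raise ValueError(f"fusion must be overlay|passthrough, got {self.fusion!r}")


@dataclass
class HogConfig:
    cell_px: int = 8
    block_cells: int = 2
    stride_cells: int = 1
    n_bins: int = 9


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    space: str = "pixels"  # feature space SMOTE runs in

    def __post_init__(self) -> None:
        if self.space != "pixels":
            raise ValueError("only pixel-space SMOTE is implemented")


@dataclass
class CnnConfig:
    n_blocks: int = 3
    filters: int = 32
    kernel: int = 3
    dense_units: int = 64
    dropout: float = 0.5
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3


@dataclass
class EvalConfig:
    k_folds: int = 5
    test_fraction: float = 0.2


_SECTIONS = {
    "data": DataConfig,
    "preprocess": PreprocessConfig,
    "render": RenderConfig,
    "sift": SiftConfig,
    "hog": HogConfig,
    "smote": SmoteConfig,
    "cnn": CnnConfig,
    "eval": EvalConfig,
}


def _build(cls, payload: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**payload)


@dataclass
class PipelineConfig:
    """Master configuration: one section per stage plus seed and output dir."""

    seed: int = 0
    outdir: str = "ecgsift_out"
    data: DataConfig = field(default_factory=DataConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    render: RenderConfig = field(default_factory=RenderConfig)
    sift: SiftConfig = field(default_factory=SiftConfig)
    hog: HogConfig = field(default_factory=HogConfig)
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    @classmethod
    def smoke(cls, outdir: str = "ecgsift_out", seed: int = 0) -> "PipelineConfig":
        """Reduced-scale configuration for desk-scale end-to-end runs:
        50 x 50 renders (3 SIFT octaves fit that size) and 10 epochs
        (training on the synthetic classes converges within a few epochs)."""
        cfg = cls(seed=seed, outdir=outdir)
        cfg.render.width = cfg.render.height = 50
        cfg.sift.n_octaves = 3
        cfg.cnn.epochs = 10
        return cfg

    def cnn_spec(self, input_shape: tuple[int, int, int] | None = None) -> CnnSpec:
        shape = input_shape or (self.render.height, self.render.width, 3)
        c = self.cnn
        return CnnSpec(
            input_shape=shape,
            n_blocks=c.n_blocks,
            filters=c.filters,
            kernel=c.kernel,
            dropout=c.dropout,
            dense_units=c.dense_units,
            epochs=c.epochs,
            batch_size=c.batch_size,
            learning_rate=c.learning_rate,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        sections = {}
        for name, section_cls in _SECTIONS.items():
            if name in payload:
                sections[name] = _build(section_cls, payload.pop(name))
        known = {"seed", "outdir"}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload, **sections)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        elif path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        else:
            raise ValueError(f"unsupported config format: {path.suffix}")

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        payload = (
            json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        )
        return cls.from_dict(payload)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
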