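"""Run configuration: validated parameter groups, YAML round trip.

Defaults are the published operating point of the pipeline (patch 256,
stride 28, alpha=1, delta=5 mm, 50-voxel cluster threshold, Adagrad at
learning rate 0.01).  :func:`desk_profile` returns a scaled-down profile
suitable for CPU-scale experiments on the synthetic phantom.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range values in a config file."""


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"config field '{name}': {msg}")


@dataclass
class PreprocessGroup:
    tophat_radius_px: int = 50          # structuring-element radius; > largest mass radius
    delta_mm: float = 5.0               # RBF scale (variance delta^2)
    candidate_percentile: float = 99.5  # top-hat response percentile for candidate detection
    min_separation_mm: float = 10.0     # candidate thinning distance (2*delta)
    constraint_floor: float = 1.0       # constraint value on slices with no candidate
    enable_tophat: bool = True
    enable_constraint: bool = True

    def validate(self) -> None:
        _check(self.tophat_radius_px >= 1, "tophat_radius_px", "must be >= 1")
        _check(self.delta_mm > 0, "delta_mm", "must be > 0")
        _check(50 < self.candidate_percentile < 100, "candidate_percentile", "must lie in (50, 100)")
        _check(self.min_separation_mm > 0, "min_separation_mm", "must be > 0")
        _check(0 < self.constraint_floor <= 1, "constraint_floor", "must lie in (0, 1]")


@dataclass
class PatchGroup:
    patch_size: int = 256
    stride: int = 28
    per_class_n: int = 512   # balanced draws per class per epoch (before augmentation)
    augment: bool = True

    def validate(self) -> None:
        _check(self.patch_size >= 1, "patch_size", "must be >= 1")
        _check(1 <= self.stride <= self.patch_size, "stride", "must satisfy 1 <= stride <= patch_size")
        _check(self.per_class_n >= 1, "per_class_n", "must be >= 1")


@dataclass
class ArchitectureGroup:
    hidden_channels: int = 32
    dilations: tuple[int, ...] = (1, 1, 2, 4, 8, 16, 1)
    kernel_size: int = 3
    out_channels: int = 2

    def validate(self) -> None:
        _check(self.hidden_channels >= 1, "hidden_channels", "must be >= 1")
        _check(len(self.dilations) >= 1, "dilations", "must be non-empty")
        _check(all(d >= 1 for d in self.dilations), "dilations", "must all be >= 1")
        _check(self.kernel_size % 2 == 1 and self.kernel_size >= 1, "kernel_size", "must be odd >= 1")
        _check(self.out_channels == 2, "out_channels", "two-class dense prediction requires 2")


@dataclass
class TrainingGroup:
    batch_size: int = 150
    batches_per_epoch: int = 1000
    epochs: int = 1000
    learning_rate: float = 0.01
    alpha: float = 1.0
    smooth_eps: float = 1e-6

    def validate(self) -> None:
        _check(self.batch_size >= 1, "batch_size", "must be >= 1")
        _check(self.batches_per_epoch >= 1, "batches_per_epoch", "must be >= 1")
        _check(self.epochs >= 1, "epochs", "must be >= 1")
        _check(self.learning_rate >= 0, "learning_rate", "must be >= 0")
        _check(self.alpha > 0, "alpha", "must be > 0")
        _check(self.smooth_eps >= 0, "smooth_eps", "must be >= 0")


@dataclass
class PostprocessGroup:
    threshold: float = 0.5
    min_cluster_voxels: int = 50
    connectivity: int = 26
    median_window: int = 3
    cluster_mode: str = "3d"  # "3d" (voxels in volumes) or "2d" (per slice)

    def validate(self) -> None:
        _check(0 < self.threshold < 1, "threshold", "must lie in (0, 1)")
        _check(self.min_cluster_voxels >= 1, "min_cluster_voxels", "must be >= 1")
        _check(self.connectivity in (6, 18, 26), "connectivity", "must be one of 6, 18, 26")
        _check(self.median_window >= 3 and self.median_window % 2 == 1, "median_window", "must be odd >= 3")
        _check(self.cluster_mode in ("3d", "2d"), "cluster_mode", "must be '3d' or '2d'")


@dataclass
class EvaluationGroup:
    match_rule: str = "any_overlap"  # or "overlap_fraction", "centroid"
    overlap_fraction: float = 0.3
    n_froc_thresholds: int = 20

    def validate(self) -> None:
        _check(
            self.match_rule in ("any_overlap", "overlap_fraction", "centroid"),
            "match_rule", "must be any_overlap | overlap_fraction | centroid",
        )
        _check(0 < self.overlap_fraction <= 1, "overlap_fraction", "must lie in (0, 1]")
        _check(self.n_froc_thresholds >= 2, "n_froc_thresholds", "must be >= 2")


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    seed: int = 0
    pixel_spacing_mm: float = 0.1
    slice_spacing_mm: float = 1.0
    normalize_on_load: bool = True
    preprocessing: PreprocessGroup = field(default_factory=PreprocessGroup)
    patching: PatchGroup = field(default_factory=PatchGroup)
    architecture: ArchitectureGroup = field(default_factory=ArchitectureGroup)
    training: TrainingGroup = field(default_factory=TrainingGroup)
    postprocessing: PostprocessGroup = field(default_factory=PostprocessGroup)
    evaluation: EvaluationGroup = field(default_factory=EvaluationGroup)

    def validate(self) -> None:
        _check(self.seed >= 0, "seed", "must be >= 0")
        _check(self.pixel_spacing_mm > 0, "pixel_spacing_mm", "must be > 0")
        _check(self.slice_spacing_mm > 0, "slice_spacing_mm", "must be > 0")
        for g in ("preprocessing", "patching", "architecture", "training", "postprocessing", "evaluation"):
            getattr(self, g).validate()


_GROUPS: dict[str, type] = {
    "preprocessing": PreprocessGroup,
    "patching": PatchGroup,
    "architecture": ArchitectureGroup,
    "training": TrainingGroup,
    "postprocessing": PostprocessGroup,
    "evaluation": EvaluationGroup,
}


def _build_group(cls: type, data: dict[str, Any], group: str) -> Any:
    known = {f.name: f for f in fields(cls)}
    for key in data:
        if key not in known:
            raise ConfigError(f"unknown key '{group}.{key}'")
    kwargs = dict(data)
    if "dilations" in kwargs and kwargs["dilations"] is not None:
        kwargs["dilations"] = tuple(kwargs["dilations"])
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config file; unspecified fields take documented defaults.

    Unknown keys and out-of-range values are rejected with the offending
    field named.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    cfg = config_from_dict(data)
    cfg.validate()
    return cfg


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    top_fields = {f.name for f in fields(RunConfig)}
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key not in top_fields:
            raise ConfigError(f"unknown key '{key}'")
        if key in _GROUPS:
            if not isinstance(value, dict):
                raise ConfigError(f"config group '{key}' must be a mapping")
            kwargs[key] = _build_group(_GROUPS[key], value, key)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    d = dataclasses.asdict(cfg)
    d["architecture"]["dilations"] = list(d["architecture"]["dilations"])
    return d


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    """Serialize a RunConfig to YAML; load_config(save_config(c)) == c."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
    return path


def desk_profile(seed: int = 0) -> RunConfig:
    """Scaled-down profile for CPU-scale phantom experiments.

    Patch 64 / stride 16 on the (16, 128, 128) desk phantom, 15 epochs of
    30 sixteen-patch batches; architecture and loss are unchanged from the
    full-scale defaults.
    """
    return RunConfig(
        seed=seed,
        preprocessing=PreprocessGroup(tophat_radius_px=35),
        patching=PatchGroup(patch_size=64, stride=16, per_class_n=60),
        training=TrainingGroup(batch_size=16, batches_per_epoch=30, epochs=15),
    )
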