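"""Configuration objects for simulation and pipeline runs.

Both configs are plain dataclasses that round-trip losslessly through
YAML so a run is fully described by one human-readable file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

DEFAULT_REGION_FRACTIONS = {"kinematic": 0.06, "visual": 0.06, "centrality": 0.04}


class InvalidConfigError(ValueError):
    """A configuration violates its invariants."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n_synergies, n_objects, n_raters, n_subjects : int
        Sizes of the rating instrument and the cohort.
    grid_shape : tuple of int
        Shape of the shared volumetric grid.
    voxel_size_mm : float
        Isotropic voxel size recorded in the volume affine.
    noise_sd : float
        SD of additive Gaussian noise, independent across subjects.
    effect_scale : float
        Multiplier on every planted (noiseless) signal component.
    region_fractions : dict
        Fraction of in-mask voxels assigned to each planted region;
        the remainder is pure-noise ("null") territory.
    n_rating_clusters : int
        Number of latent object clusters structuring the ratings.
    subject_jitter : float
        Half-width of the uniform per-subject signal-scale jitter.
    n_visual_features : int
        Width of the synthetic visual feature matrix.
    seed : int
        Base seed; every generator derives its stream from it.
    """

    n_synergies: int = 54
    n_objects: int = 33
    n_raters: int = 87
    n_subjects: int = 25
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    noise_sd: float = 1.0
    noise_smooth_vox: float = 1.5
    effect_scale: float = 1.0
    region_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_FRACTIONS)
    )
    buffer_vox: int = 4
    n_rating_clusters: int = 4
    cluster_strength: float = 0.0
    subject_jitter: float = 0.1
    n_visual_features: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        self.validate()

    def validate(self) -> None:
        for name in ("n_synergies", "n_objects", "n_raters", "n_subjects"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if len(self.grid_shape) != 3 or any(g < 1 for g in self.grid_shape):
            raise InvalidConfigError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if self.voxel_size_mm <= 0:
            raise InvalidConfigError("voxel_size_mm must be positive")
        if self.noise_sd < 0 or self.effect_scale < 0:
            raise InvalidConfigError("noise_sd and effect_scale must be nonnegative")
        if self.noise_smooth_vox < 0:
            raise InvalidConfigError("noise_smooth_vox must be nonnegative")
        if any(f < 0 for f in self.region_fractions.values()):
            raise InvalidConfigError("region fractions must be nonnegative")
        if sum(self.region_fractions.values()) > 1.0 + 1e-12:
            raise InvalidConfigError("region fractions must sum to <= 1")
        if self.n_rating_clusters < 1 or self.n_rating_clusters > self.n_objects:
            raise InvalidConfigError("n_rating_clusters must be in [1, n_objects]")
        if not 0.0 <= self.cluster_strength <= 1.0:
            raise InvalidConfigError("cluster_strength must lie in [0, 1]")
        if self.buffer_vox < 0:
            raise InvalidConfigError("buffer_vox must be nonnegative")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SynthConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


@dataclass
class InferenceConfig:
    """Group-inference knobs shared across pipeline stages."""

    n_perm: int = 1000
    alpha: float = 0.05
    tfce_h: float = 2.0
    tfce_e: float = 0.5
    tfce_steps: int = 100
    fwhm_mm: float = 6.0
    height_p: float = 0.001
    fdr_q: float = 0.05


@dataclass
class SearchlightConfigSection:
    radius: float = 3.0
    min_voxels: int = 10
    comparison: str = "spearman"


@dataclass
class RunConfig:
    """End-to-end pipeline configuration: paths, stage toggles, and seeds."""

    out_dir: str = "synkin_out"
    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    searchlight: SearchlightConfigSection = field(default_factory=SearchlightConfigSection)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "simulate": True,
            "space": True,
            "encode": True,
            "searchlight": True,
            "group": True,
            "compare": True,
            "amplitude": True,
        }
    )

    def to_dict(self) -> dict[str, Any]:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "synth": self.synth.to_dict(),
            "searchlight": asdict(self.searchlight),
            "inference": asdict(self.inference),
            "stages": dict(self.stages),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        return cls(
            out_dir=d.get("out_dir", "synkin_out"),
            seed=int(d.get("seed", 0)),
            synth=SynthConfig.from_dict(d.get("synth", {})),
            searchlight=SearchlightConfigSection(**d.get("searchlight", {})),
            inference=InferenceConfig(**d.get("inference", {})),
            stages=dict(d.get("stages", {})) or cls().stages,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
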