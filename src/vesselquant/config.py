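"""Configuration objects for the quantification pipeline.

Every tunable parameter of the pipeline lives in a small frozen dataclass so
that a whole run is reproducible from (config, seed).  Configs can be loaded
from JSON or YAML files; unspecified fields keep their defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml


@dataclass(frozen=True)
class FoldThresholdConfig:
    """Parameters of the dark-fold threshold rule.

    The threshold is half the lightness of the first predominant peak of the
    smoothed L* histogram, scanning from L*=0 upward.  A peak is predominant
    when its smoothed height is at least ``prominence_fraction`` of the
    global maximum.
    """

    n_bins: int = 101
    smoothing_window: int = 5
    prominence_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")
        if not 0.0 < self.prominence_fraction < 1.0:
            raise ValueError("prominence_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ColorMask:
    """Spherical inclusion region in L*a*b* used to pick out blood residue.

    ``center`` is an L*a*b* triple; a pixel is inside the mask when its
    Euclidean distance to the center is at most ``radius``.  The default is
    tuned to the synthetic generator's blood color.
    """

    center: tuple[float, float, float] = (35.0, 45.0, 25.0)
    radius: float = 12.0

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if len(self.center) != 3:
            raise ValueError("center must be an L*a*b* triple")


@dataclass(frozen=True)
class DbscanConfig:
    """Density-clustering parameters for the dust/dirt cleanup.

    ``R`` is the neighbourhood radius in pixels (Euclidean, on pixel
    centers); a pixel is a core pixel when its R-circle contains at least
    ``min_pxs`` foreground pixels, itself included.
    """

    R: float = 3.0
    min_pxs: int = 9

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.min_pxs < 1:
            raise ValueError("min_pxs must be >= 1")


@dataclass(frozen=True)
class KmeansConfig:
    """k-means settings for the color clustering stage.

    k=3 groups the pixels into smooth-muscle fiber, extracellular matrix and
    (white) background.  Multiple random restarts are run and the model with
    the lowest cost J is kept.
    """

    k: int = 3
    n_restarts: int = 10
    max_iter: int = 300
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for the Monte-Carlo permutation test."""

    m: int = 100_000
    statistic: str = "mean_difference"
    tail: str = "two_tailed"
    seed: int = 0
    n_workers: int = 1
    chunk_size: int = 10_000
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        if self.statistic not in {"mean_difference", "median_difference", "F"}:
            raise ValueError(f"unknown statistic: {self.statistic!r}")
        if self.tail not in {"two_tailed", "one_tailed"}:
            raise ValueError(f"unknown tail: {self.tail!r}")


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of all stage configurations for an end-to-end run."""

    fold: FoldThresholdConfig = field(default_factory=FoldThresholdConfig)
    blood: ColorMask = field(default_factory=ColorMask)
    dbscan: DbscanConfig = field(default_factory=DbscanConfig)
    kmeans: KmeansConfig = field(default_factory=KmeansConfig)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Short stable hash of the full configuration, for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, key):
            sub = dict(d.get(key, {}))
            if klass is ColorMask and "center" in sub:
                sub["center"] = tuple(sub["center"])
            return klass(**sub)

        return cls(
            fold=build(FoldThresholdConfig, "fold"),
            blood=build(ColorMask, "blood"),
            dbscan=build(DbscanConfig, "dbscan"),
            kmeans=build(KmeansConfig, "kmeans"),
            permutation=build(PermutationConfig, "permutation"),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a JSON or YAML file (by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yml", ".yaml"}:
            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        return cls.from_dict(data)
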