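"""Reproducible experiment runs: seeded pipelines with manifest files.

Each run reads a flat ``key = value`` config, executes one named
experiment and writes CSV tables plus a JSON manifest recording the
resolved configuration, its hash, the seeds used and the package version —
enough to reproduce every artifact byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .augment import (
    AugmentationConfig,
    SubcriticalGammaWarning,
    apply_zeta_mixup,
    mixup_pairwise,
)
from .batch import LabeledBatch
from .intrinsic_dim import id_vs_gamma
from .manifolds import SHAPES, ManifoldSpec, make_manifold
from .realism import realism_report

__all__ = ["ExperimentConfig", "run_demo2d", "run_suite", "load_config"]

EXPERIMENTS = ("demo2d", "id-curve", "realism", "augment", "generate")


class ConfigError(ValueError):
    """Malformed or incomplete experiment configuration."""


@dataclass
class ExperimentConfig:
    """Everything one experiment run depends on."""

    experiment: str
    shape: str = "crescents"
    sample_count: int = 512
    ambient_dim: int = 2
    noise_sd: float = 0.1
    gamma_grid: Sequence[float] = (2.4, 4.0, 6.0)
    group_size: Optional[int] = None
    k_values: Sequence[int] = (8,)
    threshold_ratio: float = 0.05
    mixup_alpha: float = 1.0
    replicate_seeds: Sequence[int] = (0,)
    output_dir: Path = Path("runs")
    paper_scale: bool = False

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ConfigError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )
        if self.shape not in SHAPES:
            raise ConfigError(f"unknown shape {self.shape!r}")
        if not self.gamma_grid:
            raise ConfigError("gamma_grid must be nonempty")
        self.output_dir = Path(self.output_dir)

    def manifold_spec(self, seed: int) -> ManifoldSpec:
        n = self.sample_count
        if self.paper_scale and self.shape == "helix":
            n = 8192
        return ManifoldSpec(
            name=self.shape,
            sample_count=n,
            ambient_dim=self.ambient_dim,
            noise_sd=self.noise_sd,
            class_count=1 if self.shape == "helix" else 2,
            seed=seed,
        )

    def canonical_dict(self) -> Dict[str, Any]:
        d = {
            "experiment": self.experiment,
            "shape": self.shape,
            "sample_count": self.sample_count,
            "ambient_dim": self.ambient_dim,
            "noise_sd": self.noise_sd,
            "gamma_grid": list(map(float, self.gamma_grid)),
            "group_size": self.group_size,
            "k_values": list(map(int, self.k_values)),
            "threshold_ratio": self.threshold_ratio,
            "mixup_alpha": self.mixup_alpha,
            "replicate_seeds": list(map(int, self.replicate_seeds)),
            "paper_scale": self.paper_scale,
        }
        return d


_LIST_KEYS = {"gamma_grid": float, "k_values": int, "replicate_seeds": int}
_SCALAR_KEYS = {
    "experiment": str,
    "shape": str,
    "sample_count": int,
    "ambient_dim": int,
    "noise_sd": float,
    "group_size": int,
    "threshold_ratio": float,
    "mixup_alpha": float,
    "output_dir": Path,
    "paper_scale": lambda v: v.lower() in ("1", "true", "yes"),
}


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse a flat ``key = value`` config file (lists comma-separated).

    Unknown keys are errors — silent typos would quietly change what a
    run reproduces.
    """
    kwargs: Dict[str, Any] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key in _LIST_KEYS:
            cast = _LIST_KEYS[key]
            kwargs[key] = tuple(cast(v.strip()) for v in value.split(","))
        elif key in _SCALAR_KEYS:
            kwargs[key] = _SCALAR_KEYS[key](value)
        else:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
    if "experiment" not in kwargs:
        raise ConfigError(f"{path}: missing required key 'experiment'")
    if kwargs["experiment"] in ("demo2d", "id-curve", "augment"):
        if "gamma_grid" not in kwargs:
            raise ConfigError(
                f"{path}: missing required key 'gamma_grid' for "
                f"experiment {kwargs['experiment']!r}"
            )
    return ExperimentConfig(**kwargs)


def _write_manifest(config: ExperimentConfig, outdir: Path, files: List[str]) -> Path:
    payload = config.canonical_dict()
    blob = json.dumps(payload, sort_keys=True).encode()
    manifest = {
        "config": payload,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seeds": list(map(int, config.replicate_seeds)),
        "version": __version__,
        "artifacts": files,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _augment_once(
    batch: LabeledBatch, gamma: float, seed: int, group_size: Optional[int] = None
) -> LabeledBatch:
    cfg = AugmentationConfig(
        gamma=gamma, group_size=group_size, seed=seed, allow_subcritical=True
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SubcriticalGammaWarning)
        return apply_zeta_mixup(batch, cfg)


def run_demo2d(config: ExperimentConfig) -> List[Path]:
    """Augmentation demo on a 2-D manifold.

    Writes the original point table, one table per gamma in the grid, and
    one pairwise-mixup table; every table has the same row count and the
    run is fully determined by the first replicate seed.
    """
    if config.shape not in ("crescents", "spirals"):
        raise ConfigError("demo2d runs on 'crescents' or 'spirals'")
    seed = int(config.replicate_seeds[0])
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    batch = make_manifold(config.manifold_spec(seed))
    written: List[Path] = []

    def _save(b: LabeledBatch, name: str) -> None:
        p = outdir / f"{name}.csv"
        b.to_csv(p)
        written.append(p)

    _save(batch, "vanilla")
    for g in config.gamma_grid:
        _save(_augment_once(batch, float(g), seed), f"zeta_gamma_{g:g}")
    _save(
        mixup_pairwise(batch, alpha=config.mixup_alpha,
                       rng=np.random.default_rng(seed)),
        "mixup",
    )
    _write_manifest(config, outdir, [p.name for p in written])
    return written


def run_id_curve(config: ExperimentConfig) -> Path:
    """Local-ID-versus-gamma table across replicate seeds."""
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    k_values = (8, 128) if config.paper_scale else tuple(config.k_values)
    frames = []
    for seed in config.replicate_seeds:
        batch = make_manifold(config.manifold_spec(int(seed)))
        curves = id_vs_gamma(
            batch,
            config.gamma_grid,
            k_values=k_values,
            threshold_ratio=config.threshold_ratio,
            seed=int(seed),
            mixup_alpha=config.mixup_alpha,
        )
        for k, curve in curves.items():
            df = curve.to_frame()
            df.insert(0, "seed", int(seed))
            frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    path = outdir / "id_curve.csv"
    table.to_csv(path, index=False)
    _write_manifest(config, outdir, [path.name])
    return path


def run_realism(config: ExperimentConfig, gamma: float = 2.8) -> Path:
    """Oracle realism/label-correctness comparison on the blobs fixture.

    Writes a per-sample table (method, seed, entropy, cross_entropy) and a
    per-method summary; returns the summary path.
    """
    from .realism import oracle_score

    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    sample_frames = []
    for seed in config.replicate_seeds:
        spec = ManifoldSpec(
            name="blobs",
            sample_count=config.sample_count,
            ambient_dim=config.ambient_dim,
            noise_sd=0.0,
            class_count=2,
            seed=int(seed),
        )
        batch = make_manifold(spec)
        rng = np.random.default_rng(int(seed))
        methods = {
            "zeta-mixup": _augment_once(batch, gamma, int(seed)),
            "mixup": mixup_pairwise(batch, alpha=config.mixup_alpha, rng=rng),
        }
        df = realism_report(batch, methods, spec)
        df.insert(0, "seed", int(seed))
        frames.append(df)
        for method, b in methods.items():
            s = oracle_score(b, spec)
            sample_frames.append(
                pd.DataFrame(
                    {
                        "method": method,
                        "seed": int(seed),
                        "entropy": s.entropy,
                        "cross_entropy": s.cross_entropy,
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    path = outdir / "realism.csv"
    table.to_csv(path, index=False)
    samples_path = outdir / "realism_samples.csv"
    pd.concat(sample_frames, ignore_index=True).to_csv(samples_path, index=False)
    _write_manifest(config, outdir, [path.name, samples_path.name])
    return path


def run_suite(config: ExperimentConfig) -> List[Path]:
    """Dispatch on ``config.experiment`` and return the written artifacts."""
    if config.experiment == "demo2d":
        return run_demo2d(config)
    if config.experiment == "id-curve":
        return [run_id_curve(config)]
    if config.experiment == "realism":
        return [run_realism(config)]
    if config.experiment == "generate":
        outdir = config.output_dir
        outdir.mkdir(parents=True, exist_ok=True)
        batch = make_manifold(config.manifold_spec(int(config.replicate_seeds[0])))
        path = outdir / f"{config.shape}.csv"
        batch.to_csv(path)
        _write_manifest(config, outdir, [path.name])
        return [path]
    if config.experiment == "augment":
        outdir = config.output_dir
        outdir.mkdir(parents=True, exist_ok=True)
        seed = int(config.replicate_seeds[0])
        batch = make_manifold(config.manifold_spec(seed))
        out = _augment_once(
            batch, float(config.gamma_grid[0]), seed, config.group_size
        )
        path = outdir / "augmented.csv"
        out.to_csv(path)
        _write_manifest(config, outdir, [path.name])
        return [path]
    raise ConfigError(f"unknown experiment {config.experiment!r}")
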