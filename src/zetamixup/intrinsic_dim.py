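"""Local intrinsic dimensionality via PCA on k-nearest neighborhoods.

For each point the k nearest neighbors (Euclidean, excluding the point
itself) are collected, their covariance eigendecomposed, and the local ID
is the number of eigenvalues exceeding a fixed fraction of the largest one
(the Fukunaga–Olsen significant-eigenvalue rule, default 5%).  Averaging
the per-point estimates over a dataset gives a scalar summary of how much
of the ambient space the data locally occupy — off-manifold augmentation
inflates it, manifold-faithful augmentation does not.

:func:`id_vs_gamma` traces this summary along a grid of the ζ-mixup
exponent gamma, next to the unaugmented data and the pairwise-mixup output,
reproducing the ID-versus-gamma diagnostic at any problem size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .augment import (
    AugmentationConfig,
    SubcriticalGammaWarning,
    apply_zeta_mixup,
    mixup_pairwise,
)
from .batch import LabeledBatch

__all__ = ["LocalIDProfile", "IDCurve", "local_id", "id_vs_gamma"]


@dataclass(frozen=True)
class LocalIDProfile:
    """Per-point integer ID estimates with their mean/sd summary."""

    per_point_id: np.ndarray
    k: int
    threshold_ratio: float

    @property
    def mean_id(self) -> float:
        return float(np.mean(self.per_point_id))

    @property
    def sd_id(self) -> float:
        return float(np.std(self.per_point_id))

    @property
    def n_points(self) -> int:
        return int(self.per_point_id.size)


def local_id(
    points: np.ndarray, k: int, threshold_ratio: float = 0.05
) -> LocalIDProfile:
    """Fukunaga–Olsen local ID estimate for every point.

    Parameters
    ----------
    points
        ``(N, D)`` coordinates.
    k
        Neighborhood size; must satisfy ``2 <= k < N``.
    threshold_ratio
        An eigenvalue is significant if strictly larger than this fraction
        of the neighborhood's largest eigenvalue.

    Notes
    -----
    The covariance is centered at the neighborhood mean.  Round-off
    negative eigenvalues are clamped to zero before thresholding, and a
    fully degenerate (zero-variance) neighborhood is assigned ID 1 so the
    estimate stays within ``[1, min(k, D)]``.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2:
        raise ValueError(f"points must be 2-D, got shape {pts.shape}")
    n, d = pts.shape
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of points {n}")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if not 0.0 < threshold_ratio < 1.0:
        raise ValueError("threshold_ratio must lie in (0, 1)")

    nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
    _, idx = nn.kneighbors(pts)
    neigh = pts[idx[:, 1:]]  # (N, k, D), query point excluded
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nkd,nke->nde", centered, centered) / k
    eig = np.linalg.eigvalsh(cov)  # ascending
    eig = np.clip(eig, 0.0, None)
    largest = eig[:, -1]
    counts = np.sum(eig > threshold_ratio * largest[:, None], axis=1)
    counts = np.where(largest > 0.0, counts, 1)  # degenerate neighborhood
    return LocalIDProfile(
        per_point_id=counts.astype(np.int64), k=k, threshold_ratio=threshold_ratio
    )


@dataclass
class IDCurve:
    """Mean local ID along a gamma grid plus the two reference profiles."""

    gamma_grid: np.ndarray
    k: int
    threshold_ratio: float
    profiles: List[LocalIDProfile]
    raw_profile: LocalIDProfile
    mixup_profile: LocalIDProfile

    def to_frame(self) -> pd.DataFrame:
        """Long-format summary: one row per (method, gamma)."""
        rows = [
            {
                "method": "vanilla",
                "gamma": np.nan,
                "k": self.k,
                "mean_id": self.raw_profile.mean_id,
                "sd_id": self.raw_profile.sd_id,
                "n_points": self.raw_profile.n_points,
            },
            {
                "method": "mixup",
                "gamma": np.nan,
                "k": self.k,
                "mean_id": self.mixup_profile.mean_id,
                "sd_id": self.mixup_profile.sd_id,
                "n_points": self.mixup_profile.n_points,
            },
        ]
        for g, p in zip(self.gamma_grid, self.profiles):
            rows.append(
                {
                    "method": "zeta-mixup",
                    "gamma": float(g),
                    "k": self.k,
                    "mean_id": p.mean_id,
                    "sd_id": p.sd_id,
                    "n_points": p.n_points,
                }
            )
        return pd.DataFrame(rows)


def id_vs_gamma(
    batch: LabeledBatch,
    gamma_grid: Sequence[float],
    k_values: Iterable[int] = (8,),
    threshold_ratio: float = 0.05,
    seed: int = 0,
    mixup_alpha: float = 1.0,
    include_original: bool = False,
) -> Dict[int, IDCurve]:
    """Local ID of augmented batches as a function of gamma, per k.

    For each gamma the whole batch is ζ-mixed (T = m) and the local ID of
    the output measured; the unaugmented batch ("vanilla") and a pairwise
    mixup output (lam ~ Beta(alpha, alpha)) provide the reference
    profiles.  ``include_original`` measures the union of original and
    augmented points instead of the augmented points alone.
    """
    grid = np.asarray(list(gamma_grid), dtype=np.float64)
    if grid.size == 0:
        raise ValueError("gamma_grid must be nonempty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("gamma_grid must be strictly increasing")

    rng = np.random.default_rng(seed)
    mix = mixup_pairwise(batch, alpha=mixup_alpha, rng=rng)
    aug_points = []
    for g in grid:
        cfg = AugmentationConfig(gamma=float(g), seed=0, allow_subcritical=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SubcriticalGammaWarning)
            out = apply_zeta_mixup(batch, cfg, rng=rng)
        aug_points.append(out.features)

    def _measure(points: np.ndarray, k: int) -> LocalIDProfile:
        if include_original:
            points = np.vstack([batch.features, points])
        return local_id(points, k=k, threshold_ratio=threshold_ratio)

    curves: Dict[int, IDCurve] = {}
    for k in k_values:
        curves[k] = IDCurve(
            gamma_grid=grid,
            k=k,
            threshold_ratio=threshold_ratio,
            profiles=[_measure(p, k) for p in aug_points],
            raw_profile=local_id(batch.features, k=k, threshold_ratio=threshold_ratio),
            mixup_profile=_measure(mix.features, k),
        )
    return curves
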