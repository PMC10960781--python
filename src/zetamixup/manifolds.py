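"""Seeded low-intrinsic-dimension synthetic datasets.

Four controlled fixtures whose geometry is known in closed form:

* ``crescents`` — two interleaving half-annulus arcs in the plane (the
  standard two-moons construction), 1-D manifolds in a 2-D ambient space;
* ``spirals`` — two Archimedean spiral arms offset by pi;
* ``helix`` — a 1-D helix, either in R^3 directly or pushed through a
  seeded random orthonormal map into R^12 (distances preserved);
* ``blobs`` — a Gaussian mixture whose exact Bayes posterior is available
  in closed form, serving as the oracle for realism scoring.

Noise, when requested, is isotropic Gaussian added to the noiseless
manifold coordinates.  Generation is stratified (class counts differ by at
most one) and fully determined by the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Callable, Dict

import numpy as np
from sklearn.datasets import make_moons

from .batch import LabeledBatch, one_hot_encode

__all__ = [
    "ManifoldSpec",
    "make_crescents",
    "make_spirals",
    "make_helix",
    "make_blobs",
    "make_manifold",
    "reference_spec",
    "SHAPES",
]


class ManifoldSpecError(ValueError):
    """Spec parameters incompatible with the requested shape."""


@dataclass(frozen=True)
class ManifoldSpec:
    """Parameters of one synthetic distribution.

    ``shape_params`` carries shape-specific geometry (spiral pitch, helix
    turns, blob means/covariance); unspecified entries fall back to the
    defaults documented in each generator.
    """

    name: str
    sample_count: int = 512
    ambient_dim: int = 2
    intrinsic_dim: int = 1
    noise_sd: float = 0.1
    class_count: int = 2
    seed: int = 0
    shape_params: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.intrinsic_dim > self.ambient_dim:
            raise ManifoldSpecError("intrinsic_dim cannot exceed ambient_dim")
        if self.sample_count < self.class_count or self.class_count < 1:
            raise ManifoldSpecError("need sample_count >= class_count >= 1")
        if self.noise_sd < 0:
            raise ManifoldSpecError("noise_sd must be >= 0")

    def with_(self, **kwargs: Any) -> "ManifoldSpec":
        return replace(self, **kwargs)


def _class_sizes(n: int, k: int) -> np.ndarray:
    """Stratified allocation: sizes differ by at most one."""
    sizes = np.full(k, n // k, dtype=int)
    sizes[: n % k] += 1
    return sizes


def make_crescents(spec: ManifoldSpec) -> LabeledBatch:
    """Two interleaving crescents (two-moons) with Gaussian noise.

    Class 0 lies on the upper unit half-circle, class 1 on a lower
    half-circle shifted so the arcs interlock; points are evenly spaced
    along each arc before noise.
    """
    if spec.ambient_dim != 2:
        raise ManifoldSpecError("crescents live in a 2-D ambient space")
    if spec.class_count != 2:
        raise ManifoldSpecError("crescents have exactly 2 classes")
    n1, n0 = _class_sizes(spec.sample_count, 2)
    noise = spec.noise_sd if spec.noise_sd > 0 else None
    x, y = make_moons(
        n_samples=(n0, n1), noise=noise, random_state=spec.seed, shuffle=False
    )
    return LabeledBatch(features=x, labels=one_hot_encode(y, 2))


def make_spirals(spec: ManifoldSpec) -> LabeledBatch:
    """Two interleaving Archimedean spiral arms offset by pi.

    Arm c traces ``r = a * theta`` at angles ``theta + c*pi`` for theta
    evenly spaced on [pitch_lo, pitch_hi] (defaults [0.5*pi, 3*pi],
    a = 0.25), then isotropic Gaussian noise of sd ``noise_sd`` is added.
    """
    if spec.ambient_dim != 2:
        raise ManifoldSpecError("spirals live in a 2-D ambient space")
    if spec.class_count != 2:
        raise ManifoldSpecError("spirals have exactly 2 classes")
    a = spec.shape_params.get("pitch", 0.25)
    t_lo = spec.shape_params.get("theta_min", 0.5 * np.pi)
    t_hi = spec.shape_params.get("theta_max", 3.0 * np.pi)
    rng = np.random.default_rng(spec.seed)
    sizes = _class_sizes(spec.sample_count, 2)
    pts, labels = [], []
    for c, n_c in enumerate(sizes):
        theta = np.linspace(t_lo, t_hi, n_c)
        r = a * theta
        ang = theta + c * np.pi
        arm = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        pts.append(arm)
        labels.append(np.full(n_c, c))
    x = np.vstack(pts)
    if spec.noise_sd > 0:
        x = x + rng.normal(scale=spec.noise_sd, size=x.shape)
    return LabeledBatch(features=x, labels=one_hot_encode(np.concatenate(labels), 2))


def _random_orthonormal_map(d_in: int, d_out: int, rng: np.random.Generator) -> np.ndarray:
    """Columns of Q span a random d_in-subspace of R^d_out; Q^T Q = I."""
    g = rng.normal(size=(d_out, d_in))
    q, r = np.linalg.qr(g)
    # fix signs so the map is unique given the Gaussian draw
    return q * np.sign(np.diag(r))


def make_helix(spec: ManifoldSpec) -> LabeledBatch:
    """Points on a 1-D helix in R^3 or embedded isometrically in R^12.

    The base curve is ``(cos t, sin t, t / (2*pi))`` over ``turns`` full
    revolutions (default 3) with evenly spaced t, so every point sits at
    unit distance from the helix axis.  For a 12-D ambient space the 3-D
    coordinates are pushed through a seeded random orthonormal linear map,
    which preserves all pairwise distances.  Noise defaults to 0.
    """
    if spec.ambient_dim not in (3, 12):
        raise ManifoldSpecError("helix supports ambient_dim 3 or 12")
    turns = spec.shape_params.get("turns", 3.0)
    pitch = spec.shape_params.get("pitch", 1.0 / (2.0 * np.pi))
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, 2.0 * np.pi * turns, spec.sample_count)
    x3 = np.column_stack([np.cos(t), np.sin(t), pitch * t])
    if spec.ambient_dim == 12:
        q = _random_orthonormal_map(3, 12, rng)
        x = x3 @ q.T
    else:
        x = x3
    if spec.noise_sd > 0:
        x = x + rng.normal(scale=spec.noise_sd, size=x.shape)
    labels = np.ones((spec.sample_count, 1))  # single-class manifold
    return LabeledBatch(features=x, labels=labels)


def make_blobs(spec: ManifoldSpec) -> LabeledBatch:
    """Equal-prior Gaussian mixture with known means and covariance.

    ``shape_params['means']`` is a (K, D) array (default two classes at
    +/-(3, 0)); ``shape_params['covariance']`` a shared (D, D) covariance
    (default identity).  Allocation is stratified, so with N divisible by K
    every class receives exactly N/K points.  The generating spec is what
    the Bayes oracle in realism scoring reads its parameters from.
    """
    if spec.class_count < 2:
        raise ManifoldSpecError("blobs need at least 2 classes")
    means = np.asarray(
        spec.shape_params.get(
            "means", np.array([[3.0] + [0.0] * (spec.ambient_dim - 1),
                               [-3.0] + [0.0] * (spec.ambient_dim - 1)])
        ),
        dtype=np.float64,
    )
    if means.shape != (spec.class_count, spec.ambient_dim):
        raise ManifoldSpecError(
            f"means must have shape ({spec.class_count}, {spec.ambient_dim})"
        )
    cov = np.asarray(
        spec.shape_params.get("covariance", np.eye(spec.ambient_dim)),
        dtype=np.float64,
    )
    if cov.shape != (spec.ambient_dim, spec.ambient_dim):
        raise ManifoldSpecError("covariance has the wrong shape")
    # the zero matrix is allowed as a degenerate limit (points at the means)
    if np.any(cov) and np.linalg.matrix_rank(cov) < spec.ambient_dim:
        raise ManifoldSpecError("covariance must be full rank (or exactly zero)")
    rng = np.random.default_rng(spec.seed)
    sizes = _class_sizes(spec.sample_count, spec.class_count)
    chol = np.linalg.cholesky(cov) if np.any(cov) else np.zeros_like(cov)
    pts, labels = [], []
    for c, n_c in enumerate(sizes):
        z = rng.normal(size=(n_c, spec.ambient_dim))
        pts.append(means[c] + z @ chol.T)
        labels.append(np.full(n_c, c))
    return LabeledBatch(
        features=np.vstack(pts),
        labels=one_hot_encode(np.concatenate(labels), spec.class_count),
    )


SHAPES: Dict[str, Callable[[ManifoldSpec], LabeledBatch]] = {
    "crescents": make_crescents,
    "spirals": make_spirals,
    "helix": make_helix,
    "blobs": make_blobs,
}


def reference_spec(name: str, seed: int = 0, **overrides: Any) -> ManifoldSpec:
    """The canonical study conditions for each shape.

    Crescents and spirals: 512 samples in 2-D with noise sd 0.1.  Helix:
    8192 noiseless points in R^3 (pass ``ambient_dim=12`` for the embedded
    variant).  Blobs: 512 samples from the two-class mixture at +/-(3, 0).
    """
    base = {
        "crescents": dict(ambient_dim=2, sample_count=512, noise_sd=0.1,
                          class_count=2, intrinsic_dim=1),
        "spirals": dict(ambient_dim=2, sample_count=512, noise_sd=0.1,
                        class_count=2, intrinsic_dim=1),
        "helix": dict(ambient_dim=3, sample_count=8192, noise_sd=0.0,
                      class_count=1, intrinsic_dim=1),
        "blobs": dict(ambient_dim=2, sample_count=512, noise_sd=0.0,
                      class_count=2, intrinsic_dim=2),
    }
    if name not in base:
        raise ManifoldSpecError(f"unknown shape {name!r}")
    params = {**base[name], **overrides}
    return ManifoldSpec(name=name, seed=seed, **params)


def make_manifold(spec: ManifoldSpec) -> LabeledBatch:
    """Dispatch on ``spec.name``."""
    try:
        fn = SHAPES[spec.name]
    except KeyError:
        raise ManifoldSpecError(
            f"unknown shape {spec.name!r}; choose from {sorted(SHAPES)}"
        ) from None
    return fn(spec)
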