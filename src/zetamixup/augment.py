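"""ζ-mixup: convex combination of T >= 2 samples with p-series weights.

Classic mixup interpolates a random *pair* of samples,

    x_hat = lam * x_i + (1 - lam) * x_j,      lam in [0, 1],

and the same combination of their one-hot labels.  ζ-mixup generalizes this
to a whole group of T samples: given a random ordering ``s`` of the group
(a permutation of 1..T), sample i receives weight

    w_i = s_i ** (-gamma) / C,     C = sum_{j=1..T} j ** (-gamma),

i.e. normalized terms of a p-series, with C the T-truncated Riemann zeta
value at gamma.  For every ``gamma >= gamma_min`` (the root of
``zeta(gamma) = 2``) the largest weight exceeds the sum of all others, so
each synthetic sample stays in the locality of one original sample while
drawing mass from up to min(T, K) classes.  At T = 2 and
``gamma = log2(lam / (1 - lam))`` the scheme reduces exactly to mixup.

The module also ships the pairwise-mixup and Dirichlet-weight baselines the
ζ-mixup weighting is compared against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, special

from .batch import LabeledBatch

__all__ = [
    "AugmentationConfig",
    "MixingWeights",
    "WeightMatrix",
    "canonical_weights",
    "sample_weight_matrix",
    "apply_zeta_mixup",
    "mixup_pairwise",
    "dirichlet_mixing",
    "gamma_min",
    "gamma_from_lambda",
    "SubcriticalGammaWarning",
]

#: row sums of every weight matrix must match 1 to this tolerance
WEIGHT_SUM_ATOL = 1e-12


class SubcriticalGammaWarning(UserWarning):
    """gamma below the dominance threshold: the largest weight no longer
    provably exceeds the sum of the rest (see :func:`gamma_min`)."""


class InvalidGroupSizeError(ValueError):
    """Mixing group must contain at least two samples."""


def canonical_weights(group_size: int, gamma: float) -> np.ndarray:
    """Normalized p-series weights ``(1, 2^-gamma, ..., T^-gamma) / C``.

    The returned vector is the weight profile in rank order: the sample
    ranked first by the (random) ordering receives ``weights[0]``, and so
    on.  Entries are strictly decreasing for ``gamma > 0`` and sum to 1.
    """
    if group_size < 2:
        raise InvalidGroupSizeError(f"group size must be >= 2, got {group_size}")
    if not np.isfinite(gamma):
        raise ValueError(f"gamma must be finite, got {gamma}")
    ranks = np.arange(1, group_size + 1, dtype=np.float64)
    # exponentiate first, normalize after: the ratio is immune to the
    # magnitude of the unnormalized terms
    terms = ranks ** (-float(gamma))
    return terms / terms.sum()


@dataclass(frozen=True)
class MixingWeights:
    """One realized weight vector: a rank profile pushed through an ordering.

    ``order`` is the rank (1-based) assigned to each of the T samples;
    ``weights[i] == order[i] ** -gamma / normalizer``.
    """

    gamma: float
    order: np.ndarray
    weights: np.ndarray
    normalizer: float

    @classmethod
    def draw(
        cls, group_size: int, gamma: float, rng: np.random.Generator
    ) -> "MixingWeights":
        base = canonical_weights(group_size, gamma)
        ranks = rng.permutation(group_size)  # 0-based ranks
        terms = np.arange(1, group_size + 1, dtype=np.float64) ** (-float(gamma))
        return cls(
            gamma=float(gamma),
            order=ranks + 1,
            weights=base[ranks],
            normalizer=float(terms.sum()),
        )


@dataclass(frozen=True)
class WeightMatrix:
    """Row-stochastic ``m x m`` matrix; each row is an independently
    permuted copy of :func:`canonical_weights`."""

    entries: np.ndarray
    gamma: float
    seed: Optional[int] = None


def sample_weight_matrix(
    batch_size: int,
    gamma: float,
    rng: np.random.Generator,
    n_rows: Optional[int] = None,
) -> WeightMatrix:
    """Draw a weight matrix of ``n_rows`` (default ``batch_size``) rows.

    Each row applies an independent uniform-random ordering to the samples,
    so repeated draws explore the T! distinct weight assignments.
    """
    if batch_size < 2:
        raise InvalidGroupSizeError(f"batch size must be >= 2, got {batch_size}")
    base = canonical_weights(batch_size, gamma)
    rows = batch_size if n_rows is None else int(n_rows)
    entries = np.empty((rows, batch_size), dtype=np.float64)
    for r in range(rows):
        entries[r] = base[rng.permutation(batch_size)]
    return WeightMatrix(entries=entries, gamma=float(gamma))


@dataclass
class AugmentationConfig:
    """Hyperparameters of one ζ-mixup application.

    Parameters
    ----------
    gamma
        p-series exponent; larger values keep synthetic samples closer to
        one original sample.  Values below ``gamma_min()`` (~1.72865) void
        the single-dominant-weight guarantee and require
        ``allow_subcritical``.
    group_size
        T, the number of samples mixed per output; ``None`` mixes the whole
        batch (T = m), the default in practice.
    seed
        Seed for the permutation generator when no generator is passed.
    outputs_per_input
        Emit this many synthetic samples per original sample (k·m rows).
    """

    gamma: float
    group_size: Optional[int] = None
    seed: int = 0
    allow_subcritical: bool = False
    outputs_per_input: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.gamma):
            raise ValueError(f"gamma must be finite, got {self.gamma}")
        if self.group_size is not None and self.group_size < 2:
            raise InvalidGroupSizeError(
                f"group_size must be >= 2, got {self.group_size}"
            )
        if self.outputs_per_input < 1:
            raise ValueError("outputs_per_input must be >= 1")


def gamma_min(tolerance: float = 1e-10) -> float:
    """Dominance threshold: the root of ``zeta(gamma) = 2`` on (1, inf).

    For any gamma at or above this value the largest p-series weight
    exceeds the sum of all remaining weights for every group size T (the
    truncated tail is smaller than the infinite one).  The Riemann zeta
    function is strictly decreasing on (1, inf), so the root (~1.72865)
    is unique.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    return float(
        optimize.brentq(
            lambda g: special.zeta(g, 1) - 2.0, 1.1, 3.0, xtol=tolerance
        )
    )


def gamma_from_lambda(lam: float) -> float:
    """Exponent at which T = 2 ζ-mixup equals mixup with mixing ratio lam.

    Solving ``1 / (1 + 2^-gamma) = lam`` gives
    ``gamma = log2(lam / (1 - lam))``; the canonical 2-sample weights then
    equal ``(lam, 1 - lam)`` exactly.
    """
    if not 0.0 < lam < 1.0:
        raise ValueError(f"lambda must lie strictly inside (0, 1), got {lam}")
    return float(np.log2(lam / (1.0 - lam)))


def _check_gamma(gamma: float, allow_subcritical: bool) -> None:
    if gamma < gamma_min(1e-10):
        if not allow_subcritical:
            raise ValueError(
                f"gamma={gamma} is below the dominance threshold "
                f"{gamma_min(1e-10):.5f}; pass allow_subcritical=True to "
                "mix without the single-dominant-weight guarantee"
            )
        warnings.warn(
            f"gamma={gamma} < {gamma_min(1e-10):.5f}: the largest mixing "
            "weight may no longer dominate the rest",
            SubcriticalGammaWarning,
            stacklevel=3,
        )


def _group_slices(m: int, group_size: int) -> list[tuple[int, int]]:
    """Contiguous group boundaries; a trailing singleton is absorbed into
    the previous group so every group has >= 2 samples."""
    bounds = list(range(0, m, group_size)) + [m]
    if bounds[-1] - bounds[-2] == 1:
        bounds.pop(-2)
    return list(zip(bounds[:-1], bounds[1:]))


def apply_zeta_mixup(
    batch: LabeledBatch,
    config: AugmentationConfig,
    rng: Optional[np.random.Generator] = None,
    permutations: Optional[np.ndarray] = None,
) -> LabeledBatch:
    """Synthesize a new batch by p-series-weighted averaging.

    Features and labels are transformed by the same row-stochastic weight
    matrix: ``X_out = W X`` and ``Y_out = W Y``, one independently permuted
    weight row per output sample.  When ``group_size`` is smaller than the
    batch, the batch is globally shuffled, split into contiguous groups of
    that size, and mixed within each group; output rows are returned in the
    original sample order.

    ``permutations`` pins the random orderings for reproducibility tests:
    an ``(n_out, T)`` integer array (or a single length-T vector applied to
    every row) of 0-based ranks, only valid when the whole batch forms one
    group.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = batch.n_samples
    t = m if config.group_size is None else min(config.group_size, m)
    _check_gamma(config.gamma, config.allow_subcritical)

    k_out = config.outputs_per_input
    feats = np.empty((k_out * m, batch.ambient_dim), dtype=np.float64)
    labs = np.empty((k_out * m, batch.class_count), dtype=np.float64)

    if permutations is not None:
        if t != m:
            raise ValueError("pinned permutations require a single whole-batch group")
        perms = np.atleast_2d(np.asarray(permutations, dtype=np.intp))
        if perms.shape[1] != m:
            raise ValueError(f"each permutation must have length {m}")
        base = canonical_weights(m, config.gamma)
        w = base[perms]
        if perms.shape[0] == 1:
            w = np.repeat(w, k_out * m, axis=0)
        return LabeledBatch(features=w @ batch.features, labels=w @ batch.labels)

    if t == m:
        order = np.arange(m)
    else:
        order = rng.permutation(m)

    for rep in range(k_out):
        out_block = slice(rep * m, (rep + 1) * m)
        x = batch.features[order]
        y = batch.labels[order]
        xo = np.empty_like(x)
        yo = np.empty_like(y)
        for lo, hi in _group_slices(m, t):
            w = sample_weight_matrix(hi - lo, config.gamma, rng).entries
            xo[lo:hi] = w @ x[lo:hi]
            yo[lo:hi] = w @ y[lo:hi]
        # undo the global shuffle: output row i is the sample synthesized
        # in original sample i's slot
        inv = np.argsort(order)
        feats[out_block] = xo[inv]
        labs[out_block] = yo[inv]
    return LabeledBatch(features=feats, labels=labs)


def mixup_pairwise(
    batch: LabeledBatch,
    lam: Optional[float] = None,
    alpha: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    partner_permutation: Optional[np.ndarray] = None,
) -> LabeledBatch:
    """Classic pairwise mixup baseline.

    Every sample is paired with a random permutation partner and blended as
    ``lam * x_i + (1 - lam) * x_j``.  Pass either a fixed ``lam`` in
    [0, 1] or a Beta concentration ``alpha`` (one lam drawn per output row;
    ``alpha=1`` makes lam uniform on [0, 1]).
    """
    if (lam is None) == (alpha is None):
        raise ValueError("pass exactly one of lam= or alpha=")
    if rng is None:
        rng = np.random.default_rng(0)
    m = batch.n_samples
    if lam is not None:
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {lam}")
        lams = np.full(m, float(lam))
    else:
        if alpha <= 0:
            raise ValueError(f"alpha must be positive, got {alpha}")
        lams = rng.beta(alpha, alpha, size=m)
    if partner_permutation is None:
        partner = rng.permutation(m)
    else:
        partner = np.asarray(partner_permutation, dtype=np.intp)
    lcol = lams[:, None]
    feats = lcol * batch.features + (1.0 - lcol) * batch.features[partner]
    labs = lcol * batch.labels + (1.0 - lcol) * batch.labels[partner]
    return LabeledBatch(features=feats, labels=labs)


def dirichlet_mixing(
    batch: LabeledBatch,
    concentration: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> LabeledBatch:
    """Whole-batch mixing with Dirichlet weights (ablation baseline).

    Each output row is a convex combination of the entire batch with
    weights drawn from ``Dirichlet(concentration)``; the symmetric all-ones
    concentration is the multivariate generalization of the Beta(1, 1)
    mixup law.  Unlike the p-series weights no single sample dominates, so
    outputs collapse toward the batch mean.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    m = batch.n_samples
    if concentration is None:
        concentration = np.ones(m)
    concentration = np.asarray(concentration, dtype=np.float64)
    if concentration.shape != (m,):
        raise ValueError(f"concentration must have shape ({m},)")
    if np.any(concentration <= 0):
        raise ValueError("concentration entries must be positive")
    w = rng.dirichlet(concentration, size=m)
    return LabeledBatch(features=w @ batch.features, labels=w @ batch.labels)
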