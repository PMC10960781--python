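"""Oracle-based realism and label-correctness scoring.

Judging whether a synthetic sample is "realistic" needs a referee that
knows the true class structure.  On the Gaussian-mixture (blobs) fixture
that referee is available in closed form: the exact Bayes posterior
``P(class | x)``.  Two per-sample scores follow:

* **realism** — the entropy of the oracle posterior at the synthetic
  point, in nats.  Points on a class's high-density region get a confident
  posterior and entropy near 0; points between classes (off the manifold)
  are ambiguous and score high.
* **label correctness** — the cross entropy between the oracle posterior
  (the target distribution q) and the soft label the augmentation assigned
  (the predicted distribution p).  A confident oracle paired with a
  wrong-class soft label scores high.

Lower is better for both.  The oracle is an interface: any callable
mapping points to posterior rows can replace the Bayes oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from .batch import LabeledBatch
from .manifolds import ManifoldSpec

__all__ = [
    "OracleScore",
    "bayes_posterior",
    "prediction_entropy",
    "label_cross_entropy",
    "oracle_score",
    "realism_report",
]

#: probabilities are floored at this value inside logarithms
PROB_FLOOR = 1e-12


class OracleUnavailableError(ValueError):
    """The closed-form oracle needs a Gaussian-mixture (blobs) spec."""


def _check_rows(p: np.ndarray, what: str) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    rows = np.atleast_2d(p)
    if np.any(rows < 0) or np.any(np.abs(rows.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError(f"{what} must be valid probability rows")
    return p


def bayes_posterior(points: np.ndarray, spec: ManifoldSpec) -> np.ndarray:
    """Exact Gaussian-mixture class posteriors under equal priors.

    With class-conditional densities ``N(x; mu_k, Sigma)`` and equal
    priors, ``P(k | x) = softmax_k log N(x; mu_k, Sigma)``; computed in
    log space for numerical stability.
    """
    if spec.name != "blobs":
        raise OracleUnavailableError(
            f"closed-form oracle requires a 'blobs' spec, got {spec.name!r}"
        )
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    means = np.asarray(
        spec.shape_params.get(
            "means",
            np.array([[3.0] + [0.0] * (spec.ambient_dim - 1),
                      [-3.0] + [0.0] * (spec.ambient_dim - 1)]),
        ),
        dtype=np.float64,
    )
    cov = np.asarray(
        spec.shape_params.get("covariance", np.eye(spec.ambient_dim)),
        dtype=np.float64,
    )
    logp = np.column_stack(
        [multivariate_normal.logpdf(pts, mean=mu, cov=cov) for mu in means]
    )
    post = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
    return post


def prediction_entropy(posterior: np.ndarray) -> Union[float, np.ndarray]:
    """Shannon entropy of each probability row, in nats (0 log 0 = 0)."""
    p = _check_rows(posterior, "posterior")
    rows = np.atleast_2d(p)
    terms = np.where(rows > 0, rows * np.log(np.clip(rows, PROB_FLOOR, None)), 0.0)
    h = -terms.sum(axis=1)
    return float(h[0]) if p.ndim == 1 else h


def label_cross_entropy(
    assigned_label: np.ndarray,
    oracle_posterior: np.ndarray,
    oracle_as_target: bool = True,
) -> Union[float, np.ndarray]:
    """Cross entropy between oracle posterior and assigned soft label, nats.

    Default orientation treats the oracle posterior as the target q and
    the assigned label as the prediction p, ``CE = -sum_k q_k log p_k``,
    so a confident oracle facing a wrong label is penalized heavily.
    ``oracle_as_target=False`` swaps the roles.  Probabilities inside the
    log are floored at 1e-12 to keep exact zeros finite.
    """
    p = _check_rows(assigned_label, "assigned label")
    q = _check_rows(oracle_posterior, "oracle posterior")
    pr, qr = np.atleast_2d(p), np.atleast_2d(q)
    if pr.shape != qr.shape:
        raise ValueError(f"shape mismatch: {pr.shape} vs {qr.shape}")
    target, pred = (qr, pr) if oracle_as_target else (pr, qr)
    ce = -(target * np.log(np.clip(pred, PROB_FLOOR, None))).sum(axis=1)
    return float(ce[0]) if p.ndim == 1 else ce


@dataclass(frozen=True)
class OracleScore:
    """Per-sample realism (entropy) and label-correctness (CE) scores."""

    entropy: np.ndarray
    cross_entropy: np.ndarray
    oracle_posterior: np.ndarray


def oracle_score(
    batch: LabeledBatch,
    spec: ManifoldSpec,
    oracle_as_target: bool = True,
) -> OracleScore:
    """Score every sample of a batch against the Bayes oracle."""
    post = bayes_posterior(batch.features, spec)
    return OracleScore(
        entropy=np.asarray(prediction_entropy(post)),
        cross_entropy=np.asarray(
            label_cross_entropy(batch.labels, post, oracle_as_target=oracle_as_target)
        ),
        oracle_posterior=post,
    )


def realism_report(
    batch: Optional[LabeledBatch],
    augmented: Union[LabeledBatch, Mapping[str, LabeledBatch]],
    spec: ManifoldSpec,
    entropy_cutoff: float = 0.1,
) -> pd.DataFrame:
    """Summary table of realism and label correctness per method.

    One row per augmented batch (plus an ``original`` row when ``batch``
    is given): mean/median oracle entropy, mean/median cross entropy, and
    the mean cross entropy restricted to high-realism samples whose oracle
    entropy falls below ``entropy_cutoff`` nats.  Lower is better
    throughout.
    """
    batches: Dict[str, LabeledBatch] = {}
    if batch is not None:
        batches["original"] = batch
    if isinstance(augmented, LabeledBatch):
        batches["augmented"] = augmented
    else:
        batches.update(augmented)

    rows = []
    for method, b in batches.items():
        s = oracle_score(b, spec)
        low = s.entropy < entropy_cutoff
        rows.append(
            {
                "method": method,
                "n": b.n_samples,
                "mean_entropy": float(np.mean(s.entropy)),
                "median_entropy": float(np.median(s.entropy)),
                "mean_ce": float(np.mean(s.cross_entropy)),
                "median_ce": float(np.median(s.cross_entropy)),
                "n_low_entropy": int(low.sum()),
                "mean_ce_low_entropy": float(np.mean(s.cross_entropy[low]))
                if low.any()
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
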