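# Methods

## The augmentation model

A labeled batch is a feature matrix `X ∈ R^{m×D}` with row-stochastic soft
labels `Y ∈ R^{m×K}`. ζ-mixup synthesizes one output per input row as

    x̂ = Σ_i w_i x_i,   ŷ = Σ_i w_i y_i,   w_i = s_i^(−γ) / C,

where `s` is a uniform-random permutation of `1..T` (drawn independently
for every output row) and `C = Σ_{j≤T} j^(−γ)` normalizes the truncated
*p*-series. Weights are computed in double precision and normalized after
exponentiation. Because the `w_i` are a convex combination, label rows stay
probability vectors with support bounded by `min(T, K)`, and synthesized
features stay inside the convex hull of the group.

Two analytic facts anchor the design. First, the single-dominant-weight
threshold: in the `T → ∞` limit, `w_1 > Σ_{i≥2} w_i` reduces to
`ζ(γ) < 2`, whose boundary `γ_min = 1.72865` is found by bracketing root
search (`scipy.optimize.brentq` on `scipy.special.zeta`, tolerance 1e-10 by
default); truncation only shrinks the tail, so dominance holds for every
finite `T` once `γ ≥ γ_min`. The test suite re-derives the root with an
independent Euler–Maclaurin tail-corrected series. Second, exact reduction
to pairwise mixup: at `T = 2`, `w = (1/(1+2^(−γ)), …)`, so
`γ = log2(λ/(1−λ))` reproduces mixup's `(λ, 1−λ)` bitwise up to rounding.

`γ` below the threshold is permitted only with `allow_subcritical=True`
and emits a `SubcriticalGammaWarning`, since the locality guarantee is
void there (the equivalence map sends `λ < 2/3` below the threshold, so
sub-critical use is legitimate — just not locality-preserving).

### Group handling and baselines

The default group is the whole batch (`T = m`), matching how the operator
is used as a drop-in batch transform. When `T < m` is requested the batch
is globally shuffled, split into contiguous groups of `T`, and mixed within
groups; a trailing singleton is absorbed into the previous group because a
group of one cannot be mixed. Outputs are returned in the original row
order, and `outputs_per_input=k` emits `k·m` rows by repeating the draw.

Two baselines ship alongside: pairwise mixup (fixed `λ` or
`λ ~ Beta(α, α)`; `α = 1` gives the uniform law) and whole-batch Dirichlet
mixing (`Dirichlet(1,…,1)` is the multivariate generalization of that
uniform law, and its expected maximum weight `≈ H_m/m` shows why it has no
dominant sample). When `α` is given, mixup draws one `λ` per output row
rather than one per batch; per-row draws give better-conditioned
statistics at the problem sizes used here, and the fixed-`λ` path covers
the per-batch convention.

## Synthetic manifolds

The generators produce the controlled fixtures every diagnostic runs on;
all are seeded, stratified (class counts differ by at most one), and
deterministic given their spec.

* **crescents** — the standard two-moons construction
  (`sklearn.datasets.make_moons`): two unit-radius interleaving
  half-circles, default 512 samples, isotropic Gaussian noise σ = 0.1.
* **spirals** — two Archimedean arms `r = 0.25·θ`, `θ ∈ [0.5π, 3π]`,
  offset by π; same defaults. The pitch and angular extent are package
  defaults chosen to keep the arms interleaved at σ = 0.1 while remaining
  separable; they are conventions, not fitted values.
* **helix** — `(cos t, sin t, t/2π)` over 3 turns with evenly spaced `t`
  (even spacing keeps k-NN neighborhoods well conditioned for ID
  estimation), 8192 points by default, noiseless. The ℝ¹² variant pushes
  the 3-D coordinates through a seeded random orthonormal map (QR of a
  Gaussian matrix, sign-fixed), which preserves all pairwise distances and
  avoids trivially degenerate axes.
* **blobs** — an equal-prior Gaussian mixture (default two classes at
  (±3, 0), unit covariance) whose exact posterior is available in closed
  form; it exists so that realism scoring has an analytically perfect
  referee.

What these fixtures do **not** emulate: image-like correlation structure,
heavy-tailed noise, class imbalance, label noise, or high ambient
dimension beyond 12. Passing diagnostics here show the operators behave as
designed on clean low-dimensional manifolds; they do not certify behavior
on any particular real dataset.

## Local intrinsic dimensionality

Per point: take the `k` nearest neighbors (Euclidean, query point
excluded), form the neighborhood covariance centered at the neighborhood
mean, and count eigenvalues strictly larger than 5% of the largest
(Fukunaga–Olsen rule; ties at exactly the threshold do not count).
Negative round-off eigenvalues are clamped to zero first; a zero-variance
neighborhood is assigned ID 1 so estimates stay in `[1, min(k, D)]`. The
estimate is scale- and rotation-invariant, which the suite asserts
directly.

`id_vs_gamma` measures the augmented output of the whole-batch operator at
each grid `γ`, next to the unaugmented batch and a mixup output. Default
problem sizes are 1024 helix points with `k = 8` (the `--paper-scale` flag
restores 8192 points and `k ∈ {8, 128}`); curves are averaged over
replicate seeds because single-seed means move by a few hundredths.

A known limitation, visible in the suite: at moderate `γ` (≈ 2–3) the
second-ranked weight is still ≈ 0.15, so whole-batch ζ-mixup outputs form
a locally 3-D shell around the shrunk manifold. With `k = 8` the
Fukunaga–Olsen count then saturates at the ambient dimension, just as
mixup's chord cloud does — slightly above it, in fact, because mixup's
`Beta(1,1)` endpoint mass leaves a fraction of its outputs near the
manifold. The clean separation between the methods appears from `γ ≈ 4`
upward, where the suite asserts it; the mean-ID curve is non-increasing in
`γ` throughout.

## Realism and label correctness

On the blob fixture the exact Bayes posterior `P(class | x)` (computed in
log space with `logsumexp`) referees two per-sample scores, both in nats
and both lower-is-better:

* **realism** — posterior entropy at the synthetic point, in
  `[0, ln K]`;
* **label correctness** — cross entropy `−Σ_k q_k log p_k` with the
  oracle posterior as target `q` and the assigned soft label as prediction
  `p`. This orientation penalizes a confident oracle facing a wrong label;
  the reverse orientation is available via `oracle_as_target=False`.
  Probabilities inside logarithms are floored at 1e-12, so a one-hot label
  that denies a class the oracle gives mass ε costs `≈ 27.6·ε` nats — the
  reason "perfect" labels on a moderately separated mixture still score a
  small positive CE.

`realism_report` summarizes mean/median of both scores per method, plus
mean CE restricted to samples with oracle entropy below 0.1 nats (the
high-realism subset). The ordering ζ-mixup < mixup on both means is
asserted across 10 seeds by sign test.

## Numerical and design choices

* Labels supplied as probability rows are validated (nonnegative, sums
  within 1e-9 of 1) but never re-normalized; re-normalizing would mask
  caller bugs. Integer labels are one-hot encoded.
* All randomness flows through `numpy.random.Generator`; every public
  operation is reproducible from an explicit seed, and experiment runs
  write a JSON manifest (config hash, seeds, version) sufficient to
  reproduce artifacts byte for byte.
* Experiment configs are flat `key = value` files with a closed schema;
  unknown keys are errors.
* Problem sizes in the default test and experiment runs (512–1024 points,
  5–10 replicate seeds) are chosen so the full suite executes in seconds
  while keeping Monte-Carlo standard errors well inside the asserted
  margins; the generators scale to the full-size fixtures via
  `reference_spec`/`--paper-scale`.
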