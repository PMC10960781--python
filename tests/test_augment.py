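"""Batch-level mixing operators: ζ-mixup, pairwise mixup, Dirichlet."""

from contextlib import nullcontext

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zetamixup import (
    AugmentationConfig,
    LabeledBatch,
    SubcriticalGammaWarning,
    apply_zeta_mixup,
    canonical_weights,
    dirichlet_mixing,
    gamma_from_lambda,
    mixup_pairwise,
    sample_weight_matrix,
)
from zetamixup.augment import InvalidGroupSizeError


def brute_force_mix(x, y, rank_rows, gamma):
    """Per-element weighted sum, the oracle for apply_zeta_mixup."""
    t = x.shape[0]
    c = sum((r + 1.0) ** -gamma for r in range(t))
    xo = np.zeros_like(x)
    yo = np.zeros_like(y)
    for j in range(rank_rows.shape[0]):
        for i in range(t):
            w = (rank_rows[j, i] + 1.0) ** -gamma / c
            xo[j] += w * x[i]
            yo[j] += w * y[i]
    return xo, yo


class TestWeightMatrix:
    def test_two_sample_rows_are_the_two_permutations(self, rng):
        w = canonical_weights(2, 3.0)
        mat = sample_weight_matrix(2, 3.0, rng, n_rows=50).entries
        for row in mat:
            assert np.allclose(row, w) or np.allclose(row, w[::-1])

    def test_all_six_patterns_occur_at_three(self):
        patterns = set()
        for seed in range(200):
            mat = sample_weight_matrix(3, 2.8, np.random.default_rng(seed))
            for row in mat.entries:
                patterns.add(tuple(np.round(row, 12)))
        assert len(patterns) == 6  # T! distinct orderings

    def test_deterministic_given_seed(self):
        a = sample_weight_matrix(5, 2.4, np.random.default_rng(42)).entries
        b = sample_weight_matrix(5, 2.4, np.random.default_rng(42)).entries
        np.testing.assert_array_equal(a, b)

    def test_distinct_seeds_differ(self):
        a = sample_weight_matrix(16, 2.4, np.random.default_rng(0)).entries
        b = sample_weight_matrix(16, 2.4, np.random.default_rng(1)).entries
        assert not np.array_equal(a, b)

    def test_rows_are_stochastic_permutations_of_canonical(self, rng):
        base = canonical_weights(7, 2.2)
        mat = sample_weight_matrix(7, 2.2, rng).entries
        np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-12)
        for row in mat:
            np.testing.assert_allclose(np.sort(row)[::-1], base, rtol=1e-14)

    def test_tiny_batch_rejected(self, rng):
        with pytest.raises(InvalidGroupSizeError):
            sample_weight_matrix(1, 2.4, rng)


class TestApplyZetaMixup:
    def test_identical_inputs_are_fixed_points(self):
        x = np.tile([1.5, -2.0], (4, 1))
        y = np.tile([0.0, 1.0], (4, 1))
        out = apply_zeta_mixup(
            LabeledBatch(features=x, labels=y), AugmentationConfig(gamma=2.8)
        )
        np.testing.assert_allclose(out.features, x, atol=1e-12)
        np.testing.assert_allclose(out.labels, y, atol=1e-12)

    def test_pinned_three_sample_hand_computation(self):
        x = np.arange(6.0).reshape(3, 2)
        b = LabeledBatch(features=x, labels=np.array([0, 1, 2]), class_count=3)
        # ranks (2, 1, 3) on the three samples
        out = apply_zeta_mixup(
            b, AugmentationConfig(gamma=2.0), permutations=np.array([1, 0, 2])
        )
        c = 1 + 2.0**-2 + 3.0**-2
        expected = (2.0**-2 * x[0] + x[1] + 3.0**-2 * x[2]) / c
        np.testing.assert_allclose(out.features[0], expected, atol=1e-14)

    @pytest.mark.parametrize("m", [2, 3, 4, 5])
    def test_matches_brute_force_on_small_batches(self, m, random_batch_factory):
        b = random_batch_factory(m=m, d=3, k=3, seed=m)
        ranks = np.vstack(
            [np.random.default_rng(100 + j).permutation(m) for j in range(m)]
        )
        out = apply_zeta_mixup(
            b, AugmentationConfig(gamma=2.8), permutations=ranks
        )
        xo, yo = brute_force_mix(b.features, b.labels, ranks, 2.8)
        np.testing.assert_allclose(out.features, xo, atol=1e-13)
        np.testing.assert_allclose(out.labels, yo, atol=1e-13)

    def test_reduces_to_mixup_at_two_samples(self, rng):
        b = LabeledBatch(
            features=rng.normal(size=(2, 5)), labels=np.array([0, 1]), class_count=2
        )
        for lam in rng.uniform(0.01, 0.99, size=20):
            g = gamma_from_lambda(lam)
            ctx = pytest.warns(SubcriticalGammaWarning) if g < 1.72865 else nullcontext()
            with ctx:
                z = apply_zeta_mixup(
                    b,
                    AugmentationConfig(gamma=g, allow_subcritical=True),
                    permutations=np.array([[0, 1], [1, 0]]),
                )
            m = mixup_pairwise(b, lam=lam, partner_permutation=np.array([1, 0]))
            np.testing.assert_allclose(z.features, m.features, atol=1e-12)
            np.testing.assert_allclose(z.labels, m.labels, atol=1e-12)

    def test_subcritical_gamma_requires_opt_in(self, random_batch_factory):
        b = random_batch_factory()
        with pytest.raises(ValueError, match="dominance threshold"):
            apply_zeta_mixup(b, AugmentationConfig(gamma=1.5))
        with pytest.warns(SubcriticalGammaWarning):
            apply_zeta_mixup(
                b, AugmentationConfig(gamma=1.5, allow_subcritical=True)
            )

    def test_group_mixing_preserves_counts_and_label_support(self):
        rng = np.random.default_rng(5)
        m, k = 23, 6
        b = LabeledBatch(
            features=rng.normal(size=(m, 4)),
            labels=rng.integers(0, k, size=m),
            class_count=k,
        )
        t = 5
        out = apply_zeta_mixup(b, AugmentationConfig(gamma=2.4, group_size=t, seed=9))
        assert out.n_samples == m
        np.testing.assert_allclose(out.labels.sum(axis=1), 1.0, atol=1e-9)
        # each output row draws from at most min(T+1, K) classes (the
        # trailing singleton is absorbed, so one group may have T+1 members)
        support = (out.labels > 0).sum(axis=1)
        assert support.max() <= min(t + 1, k)

    def test_outputs_per_input_scales_row_count(self, random_batch_factory):
        b = random_batch_factory(m=6)
        out = apply_zeta_mixup(
            b, AugmentationConfig(gamma=2.8, outputs_per_input=3)
        )
        assert out.n_samples == 18

    def test_deterministic_given_config_seed(self, random_batch_factory):
        b = random_batch_factory(m=8, seed=3)
        a = apply_zeta_mixup(b, AugmentationConfig(gamma=2.8, seed=11))
        c = apply_zeta_mixup(b, AugmentationConfig(gamma=2.8, seed=11))
        np.testing.assert_array_equal(a.features, c.features)
        d = apply_zeta_mixup(b, AugmentationConfig(gamma=2.8, seed=12))
        assert not np.array_equal(a.features, d.features)


class TestMixupPairwise:
    def test_lambda_one_is_identity(self, random_batch_factory):
        b = random_batch_factory(m=6, seed=0)
        out = mixup_pairwise(b, lam=1.0, rng=np.random.default_rng(0))
        np.testing.assert_allclose(out.features, b.features, atol=1e-15)

    def test_half_mixes_labels_symmetrically(self):
        b = LabeledBatch(
            features=np.array([[0.0], [1.0]]), labels=np.array([0, 1]), class_count=2
        )
        out = mixup_pairwise(b, lam=0.5, partner_permutation=np.array([1, 0]))
        np.testing.assert_allclose(out.labels, [[0.5, 0.5], [0.5, 0.5]])

    def test_soft_label_entries_follow_lambda(self):
        b = LabeledBatch(
            features=np.zeros((2, 1)), labels=np.array([0, 1]), class_count=2
        )
        out = mixup_pairwise(b, lam=0.53, partner_permutation=np.array([1, 0]))
        np.testing.assert_allclose(out.labels[0], [0.53, 0.47])

    def test_lambda_out_of_range_rejected(self, random_batch_factory):
        with pytest.raises(ValueError):
            mixup_pairwise(random_batch_factory(), lam=1.2)

    def test_exactly_one_lambda_source(self, random_batch_factory):
        with pytest.raises(ValueError):
            mixup_pairwise(random_batch_factory(), lam=0.5, alpha=1.0)
        with pytest.raises(ValueError):
            mixup_pairwise(random_batch_factory())


class TestDirichletMixing:
    def test_large_concentration_collapses_to_batch_mean(self, random_batch_factory):
        b = random_batch_factory(m=6, seed=1)
        out = dirichlet_mixing(
            b, concentration=np.full(6, 1e7), rng=np.random.default_rng(0)
        )
        np.testing.assert_allclose(
            out.features, np.tile(b.features.mean(axis=0), (6, 1)), atol=1e-2
        )

    def test_two_sample_marginal_matches_mixup_lambda_law(self):
        # Dirichlet(1, 1) first coordinate is uniform on [0, 1]
        rng = np.random.default_rng(0)
        draws = rng.dirichlet([1.0, 1.0], size=4000)[:, 0]
        from scipy.stats import kstest

        assert kstest(draws, "uniform").pvalue > 0.01

    def test_no_dominant_sample_in_large_batches(self):
        # E[max of Dirichlet(1,...,1)_128] ~ H_128/128 ~ 0.042 << 0.5
        rng = np.random.default_rng(1)
        maxima = rng.dirichlet(np.ones(128), size=500).max(axis=1)
        assert maxima.mean() < 0.1

    def test_output_is_convex_combination(self, random_batch_factory):
        b = random_batch_factory(m=5, seed=2)
        out = dirichlet_mixing(b, rng=np.random.default_rng(3))
        np.testing.assert_allclose(out.labels.sum(axis=1), 1.0, atol=1e-9)
        assert out.n_samples == 5

    def test_nonpositive_concentration_rejected(self, random_batch_factory):
        with pytest.raises(ValueError):
            dirichlet_mixing(random_batch_factory(m=4), concentration=np.zeros(4))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    m=st.integers(2, 8),
    d=st.integers(1, 5),
    k=st.integers(1, 4),
    gamma=st.floats(1.73, 10.0),
    seed=st.integers(0, 2**16),
)
def test_conservation_and_support_properties(m, d, k, gamma, seed):
    """Every output label row is a probability row supported on at most
    min(T, K) classes, and features stay inside the batch convex hull's
    bounding box."""
    r = np.random.default_rng(seed)
    b = LabeledBatch(
        features=r.normal(size=(m, d)),
        labels=r.integers(0, k, size=m),
        class_count=k,
    )
    out = apply_zeta_mixup(b, AugmentationConfig(gamma=gamma, seed=seed))
    np.testing.assert_allclose(out.labels.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(out.labels >= 0)
    assert (out.labels > 0).sum(axis=1).max() <= min(m, k)
    assert np.all(out.features <= b.features.max(axis=0) + 1e-9)
    assert np.all(out.features >= b.features.min(axis=0) - 1e-9)
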