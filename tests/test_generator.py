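"""Neighborhood sigmoid, banded length sampling, and point generation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import cdist
from scipy.stats import kstest

import esomgen as eg
from esomgen.datasets import DataTable
from esomgen.generator import GenerationConfig, band_counts


class TestNeighborhoodProbability:
    @pytest.mark.parametrize("c", [0.1, 0.5, 1.0, 3.7, 250.0])
    def test_half_at_distance_c(self, c):
        assert eg.neighborhood_probability(c, c) == pytest.approx(0.5, abs=1e-12)

    def test_zero_distance_value(self):
        assert eg.neighborhood_probability(0.0, 1.0) == pytest.approx(
            1.0 / (1.0 + np.exp(-10.0)), rel=1e-12
        )

    def test_far_distance_vanishes(self):
        assert eg.neighborhood_probability(100.0, 1.0) < 1e-12

    @given(st.floats(0.0, 2.0), st.floats(0.0, 2.0), st.floats(0.1, 5.0))
    def test_monotone_decreasing(self, d1, d2, c):
        lo, hi = sorted((d1, d2))
        p_lo, p_hi = eg.neighborhood_probability(lo, c), eg.neighborhood_probability(hi, c)
        assert p_lo >= p_hi
        if hi - lo > 1e-6 * c:  # strict once the gap is resolvable in floats
            assert p_lo > p_hi

    def test_band_limits_are_sigmoid_inversions(self):
        """The 0.72 / 1.22 band limits are (rounded) solutions of p = 0.95 / 0.10."""
        invert = lambda p: 1.0 + np.log(1.0 / p - 1.0) / 10.0
        assert invert(0.95) == pytest.approx(1 - np.log(19) / 10)
        assert abs(invert(0.95) - 0.72) < 0.02  # 0.7056, printed as 0.72
        assert abs(invert(0.10) - 1.22) < 0.005  # 1.2197, printed as 1.22
        # and the limits map back to the stated probability bands
        assert eg.neighborhood_probability(0.72, 1.0) > 0.90
        assert eg.neighborhood_probability(1.22, 1.0) == pytest.approx(0.10, abs=0.01)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            eg.neighborhood_probability(1.0, 0.0)


class TestDirections:
    def test_unit_norm(self, rng):
        v = eg.sample_directions(500, 7, seed=1)
        np.testing.assert_allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-12)

    def test_one_dimension_signs(self):
        v = eg.sample_directions(200, 1, seed=2)
        assert set(np.unique(v)) <= {-1.0, 1.0}

    def test_isotropy(self):
        v = eg.sample_directions(100_000, 3, seed=3)
        assert np.all(np.abs(v.mean(axis=0)) < 0.02)


class TestLengths:
    def test_exact_band_counts_1000(self):
        lengths = eg.sample_lengths(1000, c=1.0, seed=4)
        assert lengths.size == 1000
        counts = (
            int(np.sum(lengths <= 0.72)),
            int(np.sum((lengths > 0.72) & (lengths <= 1.22))),
            int(np.sum(lengths > 1.22)),
        )
        assert counts == (800, 150, 50)

    def test_band_counts_rounding_rule(self):
        assert band_counts(1000, (0.80, 0.15)) == (800, 150, 50)
        assert band_counts(1, (0.80, 0.15)) == (1, 0, 0)
        assert band_counts(7, (0.80, 0.15)) == (6, 1, 0)

    def test_single_length_in_band_a(self):
        lengths = eg.sample_lengths(1, c=2.0, seed=5)
        assert lengths.size == 1
        assert 0 < lengths[0] <= 0.72 * 2.0

    def test_all_lengths_bounded(self):
        c = 3.3
        lengths = eg.sample_lengths(997, c=c, seed=6)
        assert np.all(lengths > 0)
        assert np.all(lengths <= 2.0 * c)

    def test_lengths_scale_with_c(self):
        a = eg.sample_lengths(100, c=1.0, seed=7)
        b = eg.sample_lengths(100, c=2.0, seed=7)
        np.testing.assert_allclose(b, 2.0 * a)

    def test_piecewise_uniform_cdf(self):
        """Normalized seed distances follow the three-band mixture law."""
        lengths = eg.sample_lengths(100_000, c=1.0, seed=8)

        def mixture_cdf(x):
            x = np.asarray(x, dtype=float)
            cdf = np.where(
                x <= 0.72,
                0.80 * x / 0.72,
                np.where(
                    x <= 1.22,
                    0.80 + 0.15 * (x - 0.72) / 0.50,
                    0.95 + 0.05 * np.clip(x - 1.22, 0, None) / 0.78,
                ),
            )
            return np.clip(cdf, 0.0, 1.0)

        assert kstest(lengths, mixture_cdf).pvalue > 0.01


class TestGenerateData:
    def test_tenfold_counts_and_labels(self, hepta_genset, hepta):
        assert hepta_genset.generated.n == 10 * hepta.n == 2120
        orig_counts = np.bincount(hepta.labels)
        gen_counts = np.bincount(hepta_genset.generated.labels)
        assert np.array_equal(gen_counts, 10 * orig_counts)

    def test_generated_within_two_c_of_seed(self, hepta_genset, small_radius):
        c = 0.4 * small_radius.radius
        seeds = hepta_genset.original.values[hepta_genset.seed_index]
        dist = np.linalg.norm(hepta_genset.generated.values - seeds, axis=1)
        assert np.all(dist <= 2.0 * c + 1e-12)

    def test_no_generated_row_equals_an_original(self, hepta_genset):
        gap = cdist(hepta_genset.generated.values, hepta_genset.original.values).min()
        assert gap > 0.0

    def test_seed_blocks_in_copy_order(self, hepta_genset, hepta):
        assert np.array_equal(
            hepta_genset.seed_index, np.tile(np.arange(hepta.n), 10)
        )

    def test_deterministic(self, hepta, small_radius):
        config = GenerationConfig(seed=5)
        a = eg.generate_data(hepta, small_radius.radius, config)
        b = eg.generate_data(hepta, small_radius.radius, config)
        assert np.array_equal(a.generated.values, b.generated.values)

    def test_unlabeled_treated_as_one_class(self, rng):
        data = DataTable(rng.normal(size=(8, 2)))
        genset = eg.generate_data(data, 1.0, GenerationConfig(gen_per_data=3, seed=0))
        assert np.all(genset.generated.labels == 1)
        assert genset.generated.n == 24

    def test_class_limits_not_broken(self, hepta_genset, hepta):
        """Generated points in bands A+B stay nearest to their inherited
        class center: augmentation must not blur class boundaries."""
        centers = np.array(
            [[0, 0, 0], [3, 0, 0], [-3, 0, 0], [0, 3, 0], [0, -3, 0], [0, 0, 3], [0, 0, -3]],
            dtype=float,
        )
        n_ab = band_counts(hepta_genset.generated.n, (0.80, 0.15))
        ab = slice(0, n_ab[0] + n_ab[1])
        points = hepta_genset.generated.values[ab]
        labels = hepta_genset.generated.labels[ab]
        nearest = cdist(points, centers).argmin(axis=1) + 1
        assert (nearest == labels).mean() >= 0.99

    def test_invalid_radius_rejected(self, hepta):
        with pytest.raises(ValueError):
            eg.generate_data(hepta, 0.0)


class TestAugmentToSize:
    def test_leukemia_balancing_arithmetic(self, rng):
        """Printed transcriptomics group sizes balanced to the largest group."""
        sizes = {1: 108, 2: 266, 3: 163, 4: 15}  # healthy, AML, CLL, APL
        labels = np.concatenate([np.full(n, cls) for cls, n in sizes.items()])
        data = DataTable(rng.normal(size=(labels.size, 5)), labels)
        genset = eg.augment_to_size(
            data, 1.0, {cls: 266 for cls in sizes}, GenerationConfig(seed=1)
        )
        additions = {
            cls: int(np.sum(genset.generated.labels == cls)) for cls in sizes
        }
        assert additions == {1: 158, 2: 0, 3: 103, 4: 251}
        pooled = genset.pooled()
        assert all(np.sum(pooled.labels == cls) == 266 for cls in sizes)

    def test_targets_at_current_sizes_generate_nothing(self, hepta, small_radius):
        targets = {int(c): int(n) for c, n in zip(*np.unique(hepta.labels, return_counts=True))}
        genset = eg.augment_to_size(hepta, small_radius.radius, targets)
        assert genset.generated.n == 0

    def test_single_class_one_extra_point(self, rng):
        data = DataTable(rng.normal(size=(5, 3)), np.ones(5, dtype=int))
        genset = eg.augment_to_size(data, 1.0, {1: 6}, GenerationConfig(seed=2))
        assert genset.generated.n == 1
        assert genset.seed_index[0] == 0  # cycling starts at the first row

    def test_target_below_current_rejected(self, hepta, small_radius):
        with pytest.raises(ValueError):
            eg.augment_to_size(hepta, small_radius.radius, {1: 10})

    def test_seed_cycling_order(self, rng):
        data = DataTable(rng.normal(size=(3, 2)), np.ones(3, dtype=int))
        genset = eg.augment_to_size(data, 1.0, {1: 10}, GenerationConfig(seed=3))
        assert list(genset.seed_index) == [0, 1, 2, 0, 1, 2, 0]

    def test_label_mismatch_message(self, rng):
        data = DataTable(rng.normal(size=(4, 2)))
        data.labels = np.array([1, 1])  # deliberately inconsistent
        with pytest.raises(ValueError, match="Unequal number of cases"):
            eg.generate_data(data, 1.0)
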