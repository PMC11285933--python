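"""Design-generation checks: containment, stratification, determinism,
closed-form point values and the pick-freeze assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvgsa import samplers
from cvgsa.samplers import (SAMPLER_IDS, build_pick_freeze, korobov_generator,
                            load_design, pick_freeze_design, sample,
                            sample_golden, sample_lattice, sample_lhs,
                            sample_sobol, sample_uniform, save_design,
                            scale_to_bounds)

GOLDEN = (np.sqrt(5) - 1) / 2  # frac of the reciprocal golden ratio


def star_discrepancy_1d(x: np.ndarray) -> float:
    """Exact 1-D star discrepancy (brute force over the sorted points)."""
    x = np.sort(x)
    n = x.size
    i = np.arange(1, n + 1)
    return max(np.max(np.abs(x - i / n)), np.max(np.abs(x - (i - 1) / n)))


@pytest.mark.parametrize("method", SAMPLER_IDS)
class TestCommonProperties:
    def test_unit_cube_containment(self, method):
        pts = sample(method, 257, 5, seed=3).values
        assert pts.shape == (257, 5)
        assert pts.min() >= 0.0 and pts.max() < 1.0

    def test_reproducible_for_fixed_seed(self, method):
        a = sample(method, 64, 4, seed=9).values
        b = sample(method, 64, 4, seed=9).values
        np.testing.assert_array_equal(a, b)

    def test_invalid_sizes_rejected(self, method):
        with pytest.raises(ValueError):
            sample(method, 0, 3)
        with pytest.raises(ValueError):
            sample(method, 8, 0)


def test_unknown_sampler_rejected():
    with pytest.raises(ValueError):
        sample("halton", 8, 2)


class TestUniform:
    def test_column_means_near_half(self):
        # CLT bound: |mean - 0.5| < 3 sigma / sqrt(N)
        N = 4096
        pts = sample_uniform(N, 3, seed=0).values
        bound = 3 * np.sqrt(1 / 12) / np.sqrt(N)
        assert np.all(np.abs(pts.mean(axis=0) - 0.5) < bound)


class TestLatinHypercube:
    @given(N=st.integers(1, 40), n=st.integers(1, 6),
           seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_exact_stratification(self, N, n, seed):
        pts = sample_lhs(N, n, seed=seed).values
        strata = np.floor(pts * N).astype(int)
        for j in range(n):
            counts = np.bincount(strata[:, j], minlength=N)
            assert np.all(counts == 1)

    def test_single_point(self):
        pts = sample_lhs(1, 2, seed=5).values
        assert pts.shape == (1, 2) and 0 <= pts.min() and pts.max() < 1


class TestGolden:
    def test_one_dimensional_closed_form(self):
        pts = sample_golden(3, 1).values.ravel()
        expected = np.mod(np.arange(1, 4) * GOLDEN, 1.0)
        np.testing.assert_allclose(pts, expected, atol=1e-12)
        np.testing.assert_allclose(expected, [0.6180339887, 0.2360679775,
                                              0.8541019662], atol=1e-9)

    def test_lower_discrepancy_than_uniform(self):
        # brute-force oracle: the additive recurrence beats the median of
        # 100 i.i.d. uniform draws at N=64
        d_golden = star_discrepancy_1d(sample_golden(64, 1).values.ravel())
        d_uniform = [star_discrepancy_1d(sample_uniform(64, 1, seed=s).values.ravel())
                     for s in range(100)]
        assert d_golden < np.median(d_uniform)

    def test_seeded_shift_is_rotation(self):
        base = sample_golden(32, 3).values
        shifted = sample_golden(32, 3, seed=11).values
        u = np.random.default_rng(11).random(3)
        np.testing.assert_allclose(shifted, np.mod(base + u, 1.0), atol=1e-12)


class TestLattice:
    def test_unit_generator_grid(self):
        pts = sample_lattice(4, 1, generator=[1]).values.ravel()
        np.testing.assert_allclose(np.sort(pts), [0.0, 0.25, 0.5, 0.75])

    def test_cranley_patterson_shift(self):
        u = np.random.default_rng(13).random(1)
        pts = sample_lattice(4, 1, generator=[1], seed=13).values.ravel()
        np.testing.assert_allclose(np.sort(pts),
                                   np.sort(np.mod([0, 0.25, 0.5, 0.75] + u, 1.0)))

    def test_generator_is_deterministic_function_of_size(self):
        assert korobov_generator(89, 4) == korobov_generator(89, 4)
        z = korobov_generator(89, 4)
        assert z[0] == 1 and all(0 <= v < 89 for v in z)

    def test_wrong_generator_length(self):
        with pytest.raises(ValueError):
            sample_lattice(8, 3, generator=[1, 2])


class TestSobol:
    def test_first_points_match_direction_number_recurrence(self):
        pts = sample_sobol(5, 1).values.ravel()
        np.testing.assert_allclose(pts, [0.0, 0.5, 0.75, 0.25, 0.375])

    def test_prefix_property(self):
        a = sample_sobol(8, 3).values
        b = sample_sobol(16, 3).values
        np.testing.assert_array_equal(a, b[:8])

    def test_scrambled_needs_seed_for_reproducibility(self):
        a = sample_sobol(16, 2, seed=4, scramble=True).values
        b = sample_sobol(16, 2, seed=4, scramble=True).values
        np.testing.assert_array_equal(a, b)


class TestScaleToBounds:
    def test_identity_and_midpoint(self):
        dm = sample_uniform(16, 2, seed=0)
        same = scale_to_bounds(dm, np.array([[0.0, 1.0], [0.0, 1.0]]))
        np.testing.assert_allclose(same.values, dm.values)
        mid = scale_to_bounds(
            samplers.DesignMatrix(np.full((1, 1), 0.5), "uniform"),
            np.array([[2.0, 4.0]]))
        assert mid.values[0, 0] == 3.0

    def test_containment_and_validation(self):
        dm = sample_sobol(64, 3)
        b = np.array([[1.0, 2.0], [-5.0, 5.0], [0.1, 0.2]])
        scaled = scale_to_bounds(dm, b)
        assert np.all(scaled.values >= b[:, 0]) and np.all(scaled.values < b[:, 1])
        with pytest.raises(ValueError):
            scale_to_bounds(dm, b[:2])
        with pytest.raises(ValueError):
            scale_to_bounds(scaled, b)  # already scaled


class TestPickFreeze:
    def test_column_substitution_by_definition(self):
        A = np.array([[1.0, 2.0], [3.0, 4.0]])
        B = np.array([[5.0, 6.0], [7.0, 8.0]])
        pf = build_pick_freeze(A, B)
        np.testing.assert_array_equal(pf.AB[0], [[5, 2], [7, 4]])
        np.testing.assert_array_equal(pf.AB[1], [[1, 6], [3, 8]])

    def test_identical_matrices_give_identical_hybrids(self):
        A = np.arange(12.0).reshape(4, 3)
        pf = build_pick_freeze(A, A)
        for ab in pf.AB:
            np.testing.assert_array_equal(ab, A)

    def test_evaluation_row_count(self):
        pf = pick_freeze_design("sobol", 10, 2, seed=0)
        assert pf.n_evaluations == 10 * (2 + 2)
        assert pf.stacked().shape == (40, 2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_pick_freeze(np.zeros((3, 2)), np.zeros((4, 2)))

    @pytest.mark.parametrize("method", SAMPLER_IDS)
    def test_a_b_distinct_and_substitution_local(self, method):
        pf = pick_freeze_design(method, 32, 3, seed=7)
        assert not np.array_equal(pf.A, pf.B)
        for i, ab in enumerate(pf.AB):
            diff_cols = [j for j in range(3)
                         if not np.array_equal(ab[:, j], pf.A[:, j])]
            assert diff_cols == [i]
            np.testing.assert_array_equal(ab[:, i], pf.B[:, i])

    def test_scaled_system_respects_bounds(self):
        b = np.array([[1.0, 3.0], [10.0, 20.0]])
        pf = pick_freeze_design("lhs", 50, 2, seed=1, bounds=b)
        stacked = pf.stacked()
        assert np.all(stacked >= b[:, 0]) and np.all(stacked <= b[:, 1])

    def test_bit_reproducible(self):
        a = pick_freeze_design("uniform", 16, 3, seed=5)
        b = pick_freeze_design("uniform", 16, 3, seed=5)
        np.testing.assert_array_equal(a.stacked(), b.stacked())


def test_design_csv_roundtrip(tmp_path):
    dm = scale_to_bounds(sample_lattice(16, 2, seed=3),
                         np.array([[0.0, 2.0], [1.0, 4.0]]))
    path = tmp_path / "design.csv"
    save_design(dm, path)
    back = load_design(path)
    np.testing.assert_allclose(back.values, dm.values)
    assert back.method == "lattice" and back.seed == 3 and not back.unit_cube
    np.testing.assert_allclose(back.bounds, dm.bounds)
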