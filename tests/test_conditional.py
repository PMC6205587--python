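"""Conditional densities, DREMI scores, DREVI surfaces."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tides.conditional import (ConditionalDensity, conditional_density, dremi,
                               dremi_from_data, drevi_surface, rescale_denoise)
from tides.density import DensityGrid, diffusion_kde


def make_grid(values, lo=0.0, hi=1.0):
    values = np.asarray(values, dtype=float)
    ranges = np.array([[lo, hi]] * values.ndim)
    widths = (hi - lo) / np.array(values.shape)
    values = values / (values.sum() * np.prod(widths))
    return DensityGrid(values=values, ranges=ranges)


def make_cond(columns, state="rescaled"):
    """Conditional density directly from a list of column distributions."""
    values = np.asarray(columns, dtype=float)
    m_cond, m_z = values.shape
    return ConditionalDensity(
        values=values, column_mass=np.full(m_cond, 1.0 / m_cond),
        empty=np.zeros(m_cond, dtype=bool), z_centers=np.linspace(0, 1, m_z),
        cond_centers=(np.linspace(0, 1, m_cond),), state=state)


class TestConditionalDensity:
    def test_columns_sum_to_one(self, gauss2d):
        cond = conditional_density(diffusion_kde(gauss2d, m=32), response_axis=1)
        sums = cond.values.sum(axis=-1)
        np.testing.assert_allclose(sums[~cond.empty], 1.0, atol=1e-9)

    def test_factorized_joint_gives_marginal_columns(self):
        px = np.array([0.1, 0.4, 0.3, 0.2])
        pz = np.array([0.25, 0.5, 0.15, 0.10])
        joint = make_grid(np.outer(px, pz))
        cond = conditional_density(joint, response_axis=1)
        for col in cond.values[~cond.empty]:
            np.testing.assert_allclose(col, pz, atol=1e-6)

    def test_zero_mass_column_flagged_empty(self):
        vals = np.ones((4, 4))
        vals[2] = 0.0
        cond = conditional_density(make_grid(vals), response_axis=1)
        assert cond.empty[2]
        assert np.all(cond.values[2] == 0)

    def test_all_empty_rejected(self):
        grid = make_grid(np.ones((4, 4)))
        grid.values = np.zeros((4, 4))
        with pytest.raises(ValueError):
            conditional_density(grid, response_axis=1)


class TestRescaleDenoise:
    def test_rescaled_columns_peak_at_exactly_one(self, gauss2d):
        cond = conditional_density(diffusion_kde(gauss2d, m=32), response_axis=1)
        scaled = rescale_denoise(cond, epsilon=0.0)
        peaks = scaled.values[~scaled.empty].max(axis=-1)
        assert np.all(peaks == 1.0)

    def test_epsilon_zero_is_identity_denoise(self):
        cond = make_cond([[0.2, 0.8], [0.6, 0.4]], state="raw")
        out = rescale_denoise(cond, epsilon=0.0)
        np.testing.assert_allclose(out.values, [[0.25, 1.0], [1.0, 2 / 3]])

    def test_epsilon_one_keeps_only_maxima(self):
        cond = make_cond([[0.2, 0.8], [0.6, 0.4]], state="raw")
        out = rescale_denoise(cond, epsilon=1.0)
        np.testing.assert_array_equal(out.values, [[0.0, 1.0], [1.0, 0.0]])

    def test_requires_raw_state(self):
        cond = make_cond([[0.2, 0.8]] * 2, state="rescaled")
        with pytest.raises(ValueError, match="raw"):
            rescale_denoise(cond)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 1000), st.floats(0.0, 1.0))
    def test_no_value_survives_below_epsilon(self, seed, epsilon):
        vals = np.random.default_rng(seed).random((6, 8)) + 1e-9
        cond = conditional_density(make_grid(vals), response_axis=1)
        out = rescale_denoise(cond, epsilon=epsilon)
        kept = out.values[(out.values > 0)]
        assert np.all(kept >= epsilon) if kept.size else True


class TestDremi:
    def test_two_disjoint_column_types_give_one_bit(self):
        cols = [[1.0, 1.0, 0.0, 0.0], [1.0, 1.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, 1.0], [0.0, 0.0, 1.0, 1.0]]
        score = dremi(make_cond(cols))
        assert score.value == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_monotone_map_reaches_conditional_entropy(self):
        """A strictly monotone deterministic response: every column is a
        point mass at a distinct z, so the score equals H_c(Z)."""
        m = 64
        cols = np.zeros((m, m))
        cols[np.arange(m), np.arange(m)] = 1.0  # z = f(y), monotone
        score = dremi(make_cond(cols))
        assert score.h_z_given == 0.0
        assert abs(score.value - score.h_z) <= 0.1 * score.h_z

    def test_independent_markers_score_near_zero(self, independent_cells):
        score = dremi_from_data(independent_cells.marker("X"),
                                independent_cells.marker("Y"), bins=128)
        assert score.value < 0.05

    def test_bin_permutation_invariance(self):
        rng = np.random.default_rng(4)
        cols = rng.random((8, 16))
        perm = rng.permutation(16)
        s1 = dremi(make_cond(cols))
        s2 = dremi(make_cond(cols[:, perm]))
        assert s1.value == pytest.approx(s2.value, abs=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            cols = rng.random((10, 32))
            s = dremi(make_cond(cols))
            assert 0.0 <= s.value <= np.log2(32) + 1e-9

    def test_added_noise_does_not_increase_score(self):
        """Data-processing sanity: noisier responses carry less information."""
        from tides.simulate import EdgeModulationSpec, constant_coupling, simulate_transient_edge

        means = []
        for noise in (0.15, 0.8):
            vals = [dremi_from_data(
                (c := simulate_transient_edge(
                    3000, EdgeModulationSpec(coupling=constant_coupling(1.0), noise_sd=noise),
                    seed=s)).marker("X"), c.marker("Y"), bins=64).value
                for s in range(3)]
            means.append(np.mean(vals))
        assert means[1] <= means[0]

    def test_raw_state_rejected(self):
        cond = make_cond([[0.5, 0.5]] * 3, state="raw")
        with pytest.raises(ValueError):
            dremi(cond)

    def test_too_few_columns_rejected(self):
        cond = make_cond([[0.5, 0.5], [0.4, 0.6]])
        cond.empty[1] = True
        with pytest.raises(ValueError, match="2 non-empty"):
            dremi(cond)


class TestDreviSurface:
    def _cond3(self, values):
        m = values.shape
        return ConditionalDensity(
            values=values, column_mass=np.full(m[:2], 1.0 / (m[0] * m[1])),
            empty=np.zeros(m[:2], dtype=bool), z_centers=np.linspace(0, 1, m[2]),
            cond_centers=(np.linspace(0, 1, m[0]), np.linspace(0, 1, m[1])))

    def test_constant_response_gives_flat_surface(self):
        m = 16
        vals = np.zeros((m, m, m))
        vals[:, :, 5] = 1.0  # z always at bin 5
        surf = drevi_surface(self._cond3(vals), smoothing_span=5)
        c = np.linspace(0, 1, m)[5]
        np.testing.assert_allclose(surf.values, c, atol=1e-12)

    def test_linear_response_recovered(self):
        """Z = 0.5*Y + 0.2 noiselessly: surface follows the line in y."""
        from tides.density import diffusion_kde

        rng = np.random.default_rng(6)
        t = rng.uniform(0, 1, 4000)
        y = rng.uniform(0, 1, 4000)
        z = 0.5 * y + 0.2
        joint = diffusion_kde(np.column_stack([t, y, z]), m=32)
        cond = conditional_density(joint, response_axis=2)
        surf = drevi_surface(cond, smoothing_span=1)
        y_centers = cond.cond_centers[1]
        z_bin = (joint.ranges[2, 1] - joint.ranges[2, 0]) / 32
        interior = slice(6, 26)
        expected = 0.5 * y_centers[interior] + 0.2
        # compare along y for a mid-pseudotime row
        assert np.max(np.abs(surf.values[16, interior] - expected)) <= z_bin

    def test_factorized_joint_gives_flat_surface(self):
        rng = np.random.default_rng(7)
        vals = np.einsum("i,j,k->ijk", rng.random(8) + 0.5, rng.random(8) + 0.5,
                         rng.random(8) + 0.5)
        grid = make_grid(vals)
        cond = conditional_density(grid, response_axis=2)
        surf = drevi_surface(cond, smoothing_span=1)
        assert surf.values.max() - surf.values.min() <= 1e-6

    def test_smoothing_preserves_constants(self):
        m = 24
        vals = np.zeros((m, m, 8))
        vals[:, :, 3] = 1.0
        s1 = drevi_surface(self._cond3(vals), smoothing_span=1)
        s5 = drevi_surface(self._cond3(vals), smoothing_span=5)
        np.testing.assert_allclose(s1.values, s5.values, atol=1e-12)

    def test_span_larger_than_grid_rejected(self):
        vals = np.ones((4, 4, 4))
        with pytest.raises(ValueError, match="span"):
            drevi_surface(self._cond3(vals), smoothing_span=10)
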