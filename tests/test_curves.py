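"""TIDES curves: slicing, scoring, smoothing, averaging, binned baseline."""

import numpy as np
import pytest

from tides.conditional import dremi
from tides.curves import (TidesCurve, average_tides, binned_dremi_baseline,
                          rescaled_conditional_3d, smooth_curve, tides_curve,
                          tides_slice)


@pytest.fixture(scope="module")
def cond3d(transient_cells):
    return rescaled_conditional_3d(transient_cells, "X", "Y", bins=32, tail_trim=50)


class TestTidesSlice:
    def test_slice_at_grid_node_equals_plane(self, cond3d):
        t_centers = cond3d.cond_centers[0]
        sl = tides_slice(cond3d, t_centers[10], epsilon=0.0)
        np.testing.assert_allclose(sl.values, cond3d.values[10], atol=1e-12)

    def test_slice_midway_is_mean_of_planes(self, cond3d):
        t_centers = cond3d.cond_centers[0]
        mid = 0.5 * (t_centers[4] + t_centers[5])
        sl = tides_slice(cond3d, mid, epsilon=0.0)
        np.testing.assert_allclose(sl.values, 0.5 * (cond3d.values[4] + cond3d.values[5]),
                                   atol=1e-12)

    def test_constant_conditional_gives_identical_slices(self, cond3d):
        from dataclasses import replace

        flat = replace(cond3d, values=np.broadcast_to(cond3d.values[8],
                                                      cond3d.values.shape).copy(),
                       column_mass=np.broadcast_to(cond3d.column_mass[8],
                                                   cond3d.column_mass.shape).copy())
        t_centers = flat.cond_centers[0]
        s1 = tides_slice(flat, t_centers[2] + 0.003, epsilon=0.9)
        s2 = tides_slice(flat, t_centers[20] + 0.007, epsilon=0.9)
        np.testing.assert_allclose(s1.values, s2.values, atol=1e-12)

    def test_extrapolation_rejected(self, cond3d):
        with pytest.raises(ValueError, match="outside"):
            tides_slice(cond3d, 99.0)

    def test_slice_score_matches_direct_plane_dremi(self, cond3d):
        """DREMI of the slice at a node equals 2D-DREMI of that plane."""
        t_centers = cond3d.cond_centers[0]
        idx = 6
        sl = tides_slice(cond3d, t_centers[idx], epsilon=0.9)
        direct = sl.values.copy()
        plane = cond3d.values[idx].copy()
        plane[plane < 0.9] = 0.0
        np.testing.assert_allclose(direct, plane, atol=1e-12)
        assert dremi(sl).value >= 0.0


class TestTidesCurve:
    def test_stationary_coupling_gives_flat_curve(self, stationary_cells):
        curve = tides_curve(stationary_cells, "X", "Y")
        spread = curve.scores.max() - curve.scores.min()
        assert spread <= 0.25 * curve.scores.mean()

    def test_transient_coupling_concentrates_early(self, transient_cells):
        curve = smooth_curve(tides_curve(transient_cells, "X", "Y"))
        t, s = curve.t_values, curve.scores
        low = s[t <= np.quantile(t, 0.25)].mean()
        high = s[t >= np.quantile(t, 0.75)].mean()
        assert low >= 3.0 * max(high, 1e-12)

    def test_independent_markers_score_low_everywhere(self, independent_cells,
                                                      stationary_cells):
        # with pure rescaling the score is calibrated: uncoupled markers
        # stay below 0.05 bits at every pseudotime
        calibrated = tides_curve(independent_cells, "X", "Y", epsilon=0.0)
        assert np.all(calibrated.scores < 0.05)
        # the hard 0.9 denoise leaves a positive noise floor, but it stays
        # far below the level of a genuinely coupled edge
        noisy = tides_curve(independent_cells, "X", "Y")
        coupled = tides_curve(stationary_cells, "X", "Y")
        assert noisy.scores.mean() < 0.3 * coupled.scores.mean()

    def test_default_location_count_is_twice_bins(self, transient_cells):
        curve = tides_curve(transient_cells, "X", "Y", bins=64)
        assert curve.t_values.size == 128

    def test_deterministic_under_repetition(self, transient_cells):
        c1 = tides_curve(transient_cells, "X", "Y", bins=32)
        c2 = tides_curve(transient_cells, "X", "Y", bins=32)
        np.testing.assert_array_equal(c1.scores, c2.scores)

    def test_too_few_cells_rejected(self, transient_cells):
        small = transient_cells.subset(np.arange(transient_cells.n_cells) < 200)
        with pytest.raises(ValueError, match="500"):
            tides_curve(small, "X", "Y")


class TestSmoothCurve:
    def _curve(self, scores):
        scores = np.asarray(scores, dtype=float)
        return TidesCurve(t_values=np.linspace(0, 1, scores.size), scores=scores)

    def test_constant_curve_unchanged(self):
        out = smooth_curve(self._curve(np.full(64, 1.7)))
        np.testing.assert_allclose(out.scores, 1.7, atol=1e-12)

    def test_total_variation_does_not_increase(self):
        rng = np.random.default_rng(8)
        raw = self._curve(rng.random(128))
        out = smooth_curve(raw)
        tv = lambda v: np.abs(np.diff(v)).sum()
        assert tv(out.scores) <= tv(raw.scores)

    def test_spike_spreads_and_peak_decreases(self):
        scores = np.zeros(64)
        scores[32] = 1.0
        out = smooth_curve(self._curve(scores), sigma=0.05)
        assert out.scores.max() < 1.0
        assert out.scores[30] > 0 and out.scores[34] > 0
        # Gaussian decay away from the spike
        assert out.scores[32] > out.scores[35] > out.scores[40]

    def test_literal_value_distance_mode_runs(self):
        rng = np.random.default_rng(9)
        out = smooth_curve(self._curve(rng.random(32) + 0.5), mode="literal")
        assert out.scores.shape == (32,)


class TestAverageTides:
    def _curve(self, scores):
        scores = np.asarray(scores, dtype=float)
        return TidesCurve(t_values=np.linspace(0, 1, scores.size), scores=scores)

    def test_single_curve_is_itself(self):
        c = self._curve(np.arange(8.0))
        np.testing.assert_array_equal(average_tides([c]).scores, c.scores)

    def test_mean_of_scaled_pair(self):
        c = self._curve(np.arange(1.0, 9.0))
        c2 = TidesCurve(t_values=c.t_values, scores=2.0 * c.scores)
        np.testing.assert_allclose(average_tides([c, c2]).scores, 1.5 * c.scores)

    def test_mean_of_identical_curves(self):
        c = self._curve(np.random.default_rng(10).random(16))
        np.testing.assert_allclose(average_tides([c] * 4).scores, c.scores)

    def test_mismatched_grids_rejected(self):
        a = self._curve(np.ones(8))
        b = TidesCurve(t_values=np.linspace(0, 2, 8), scores=np.ones(8))
        with pytest.raises(ValueError, match="grids"):
            average_tides([a, b])


class TestBinnedBaseline:
    def test_zero_overlap_is_disjoint_partition(self, transient_cells):
        t = transient_cells.pseudotime
        out = binned_dremi_baseline(transient_cells, "X", "Y", n_bins=4, overlap=0.0,
                                    bins=32)
        # window widths equal spacing of centers -> every cell in exactly one window
        centers = out.center.to_numpy()
        width = centers[1] - centers[0]
        counts = np.zeros(len(t), dtype=int)
        for i, c in enumerate(centers):
            in_win = (t >= c - width / 2) & (t < c + width / 2)
            if i == len(centers) - 1:
                in_win |= t == t.max()
            counts += in_win
        assert counts.min() == 1 and counts.max() == 1

    def test_stationary_edge_agrees_with_tides(self, stationary_cells):
        """With a stationary coupling and a common denoise setting the
        windowed scores track the TIDES curve."""
        curve = smooth_curve(tides_curve(stationary_cells, "X", "Y"))
        out = binned_dremi_baseline(stationary_cells, "X", "Y", epsilon=0.9)
        interp = np.interp(out.center, curve.t_values, curve.scores)
        rel = np.abs(out.score.to_numpy() - interp).mean() / interp.mean()
        assert rel <= 0.30

    def test_transient_edge_defeats_binned_scores(self, transient_cells):
        curve = smooth_curve(tides_curve(transient_cells, "X", "Y"))
        out = binned_dremi_baseline(transient_cells, "X", "Y")
        assert np.nanmax(out.score) < 0.5 * curve.scores.max()

    def test_small_windows_flagged_not_scored(self, transient_cells):
        out = binned_dremi_baseline(transient_cells, "X", "Y", n_bins=4, overlap=0.0,
                                    bins=32, min_cells=10**6)
        assert out.flagged.all() and out.score.isna().all()


class TestPeakRecovery:
    @pytest.mark.parametrize("t_star", [0.3, 0.5, 0.8])
    def test_smoothed_argmax_near_generative_peak(self, t_star):
        from tides.simulate import EdgeModulationSpec, simulate_transient_edge, unimodal_coupling

        hits = 0
        for seed in range(5):
            cells = simulate_transient_edge(
                5000, EdgeModulationSpec(coupling=unimodal_coupling(peak=t_star)), seed=seed)
            curve = smooth_curve(tides_curve(cells, "X", "Y"))
            argmax = curve.t_values[np.argmax(curve.scores)]
            hits += abs(argmax - t_star) <= 0.05
        assert hits >= 4
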