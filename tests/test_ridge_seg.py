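import numpy as np
import pytest

from vitalridge.config import GraphWeightConfig, ScenarioConfig, Trajectory
from vitalridge.ridge_seg import (
    assign_weights,
    estimate_vitals,
    path_to_estimate,
    segmentation_estimate,
    shortest_path,
    smooth_path,
    spectral_magnitude_estimate,
    vertical_gradients,
)
from vitalridge.series import DataError

from conftest import synthetic_spectrogram, tone_spectrogram


def monotone_path_cost(g: np.ndarray, rows: list[int], w_min: float) -> float:
    """Cost of a column-to-column path including the terminal edges."""
    cost = 2.0 * w_min
    for c in range(len(rows) - 1):
        cost += 2.0 - (g[rows[c], c] + g[rows[c + 1], c + 1]) + w_min
    return cost


def brute_force_min_cost(g: np.ndarray, w_min: float) -> float:
    """Oracle: exhaustive enumeration of all monotone paths (row step <= 1)."""
    n_rows, n_cols = g.shape

    def extend(path):
        if len(path) == n_cols:
            yield path
            return
        for dr in (-1, 0, 1):
            r = path[-1] + dr
            if 0 <= r < n_rows:
                yield from extend(path + [r])

    best = np.inf
    for r0 in range(n_rows):
        for path in extend([r0]):
            best = min(best, monotone_path_cost(g, path, w_min))
    return best


class TestVerticalGradients:
    def test_constant_image_all_zeros(self):
        g = vertical_gradients(np.full((5, 4), 3.0), "dark-to-bright")
        np.testing.assert_array_equal(g, 0.0)

    @pytest.mark.parametrize("polarity", ["dark-to-bright", "bright-to-dark", "intensity-ridge"])
    def test_output_in_unit_interval(self, polarity):
        rng = np.random.default_rng(0)
        g = vertical_gradients(rng.uniform(0, 10, (6, 8)), polarity)
        assert g.min() >= 0.0 and g.max() <= 1.0

    def test_bright_row_edge_location(self):
        """Single bright row: the dark-to-bright gradient peaks just below it."""
        img = np.zeros((7, 3))
        img[4, :] = 1.0
        g = vertical_gradients(img, "dark-to-bright")
        assert np.all(np.argmax(g, axis=0) == 3)

    def test_intensity_ridge_peaks_on_the_row(self):
        img = np.zeros((7, 3))
        img[4, :] = 1.0
        g = vertical_gradients(img, "intensity-ridge")
        assert np.all(np.argmax(g, axis=0) == 4)

    def test_single_row_rejected(self):
        with pytest.raises(DataError):
            vertical_gradients(np.ones((1, 5)), "dark-to-bright")


class TestAssignWeights:
    def test_limit_weights(self):
        cfg = GraphWeightConfig(mode="gradient")
        graph = assign_weights(np.ones((2, 2)), cfg)
        pixel = graph.weights[: graph.weights.size - 4]  # exclude terminal edges
        np.testing.assert_allclose(pixel, cfg.w_min)
        graph0 = assign_weights(np.zeros((2, 2)), cfg)
        pixel0 = graph0.weights[: graph0.weights.size - 4]
        np.testing.assert_allclose(pixel0, 2.0 + cfg.w_min)

    def test_all_weights_positive(self):
        rng = np.random.default_rng(1)
        graph = assign_weights(rng.uniform(0, 1, (5, 6)))
        assert np.all(graph.weights > 0)

    def test_weight_decreasing_in_gradient(self):
        """Raising any node's gradient never increases an incident weight."""
        rng = np.random.default_rng(2)
        g = rng.uniform(0, 0.9, (4, 5))
        g2 = g.copy()
        g2[2, 2] += 0.1
        w1 = assign_weights(g).weights
        w2 = assign_weights(g2).weights
        assert np.all(w2 <= w1 + 1e-12)

    def test_terminal_edges_at_w_min(self):
        cfg = GraphWeightConfig(w_min=1e-4)
        graph = assign_weights(np.zeros((3, 4)), cfg)
        np.testing.assert_allclose(graph.weights[-6:], 1e-4)


class TestShortestPath:
    def test_single_column_picks_strongest_row(self):
        g = np.array([[0.1], [0.9], [0.3]])
        path = shortest_path(assign_weights(g))
        assert path.tolist() == [1]

    def test_uniform_image_gives_topmost_row(self):
        """All weights equal: the tie-break settles on the lowest row index."""
        path = shortest_path(assign_weights(np.full((4, 5), 0.5)))
        assert path.tolist() == [0] * 5

    def test_bright_ridge_is_followed(self):
        g = np.zeros((6, 8))
        ridge = [1, 1, 2, 3, 3, 2, 1, 1]
        for c, r in enumerate(ridge):
            g[r, c] = 1.0
        path = shortest_path(assign_weights(g))
        assert path.tolist() == ridge

    @pytest.mark.parametrize("shape", [(2, 2), (3, 4), (4, 3), (5, 5)])
    def test_cost_matches_exhaustive_enumeration(self, shape):
        """Dijkstra's path cost equals the brute-force minimum over all
        monotone column-to-column paths, on 25 random images per shape."""
        cfg = GraphWeightConfig()
        rng = np.random.default_rng(hash(shape) % (2**31))
        for _ in range(25):
            g = rng.uniform(0, 1, shape)
            path = shortest_path(assign_weights(g, cfg))
            got = monotone_path_cost(g, path.tolist(), cfg.w_min)
            want = brute_force_min_cost(g, cfg.w_min)
            assert got == pytest.approx(want, abs=1e-10)

    def test_path_row_step_bounded(self):
        rng = np.random.default_rng(3)
        path = shortest_path(assign_weights(rng.uniform(0, 1, (10, 20))))
        assert np.all(np.abs(np.diff(path)) <= 1)

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        g = rng.uniform(0, 1, (8, 12))
        p1 = shortest_path(assign_weights(g))
        p2 = shortest_path(assign_weights(g))
        np.testing.assert_array_equal(p1, p2)


class TestSmoothPath:
    def test_k1_identity(self):
        p = np.array([3, 1, 4, 1, 5])
        np.testing.assert_array_equal(smooth_path(p, 1), p)

    def test_hand_median(self):
        out = smooth_path(np.array([70, 100, 70]), 3)
        assert out[1] == 70

    def test_monotone_unchanged(self):
        p = np.arange(20)
        np.testing.assert_array_equal(smooth_path(p, 5), p)

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            smooth_path(np.array([1, 2, 3]), 2)


class TestPathToEstimate:
    def test_constant_row_maps_to_axis_value(self):
        spec = synthetic_spectrogram(np.ones((5, 4)))
        est = path_to_estimate(np.full(4, 2), spec)
        np.testing.assert_allclose(est.bpm, spec.freq_axis_bpm[2])
        np.testing.assert_array_equal(est.times, spec.time_axis_s)

    def test_estimate_bounded_by_axis(self):
        spec = synthetic_spectrogram(np.random.default_rng(0).uniform(0, 1, (6, 7)))
        est = segmentation_estimate(spec)
        assert np.all(est.bpm >= spec.freq_axis_bpm[0])
        assert np.all(est.bpm <= spec.freq_axis_bpm[-1])

    def test_length_mismatch_rejected(self):
        spec = synthetic_spectrogram(np.ones((5, 4)))
        with pytest.raises(DataError):
            path_to_estimate(np.zeros(3, dtype=int), spec)


class TestSpectralMagnitude:
    def test_clean_tone_constant_72(self):
        spec = tone_spectrogram(72.0)
        est = spectral_magnitude_estimate(spec)
        np.testing.assert_allclose(est.bpm, 72.0)

    def test_tie_broken_toward_lower_bpm(self):
        mags = np.zeros((5, 2))
        mags[1, :] = 1.0
        mags[3, :] = 1.0
        est = spectral_magnitude_estimate(synthetic_spectrogram(mags))
        spec = synthetic_spectrogram(mags)
        np.testing.assert_allclose(est.bpm, spec.freq_axis_bpm[1])

    def test_all_zero_column_is_missing(self):
        mags = np.ones((4, 3))
        mags[:, 1] = 0.0
        est = spectral_magnitude_estimate(synthetic_spectrogram(mags))
        assert np.isnan(est.bpm[1])
        assert np.isfinite(est.bpm[[0, 2]]).all()


class TestEstimateVitals:
    def test_clean_radar_within_one_bin(self, radar_cfg):
        from vitalridge.synthgen import displacement_to_phase, simulate_displacement

        cfg = ScenarioConfig(duration_s=120.0, seed=0)
        disp, truth = simulate_displacement(cfg)
        phase = displacement_to_phase(disp, radar_cfg)
        est, spec = estimate_vitals(phase, band="HR")
        assert np.all(np.abs(est.bpm - 72.0) <= 0.75 + 1e-9)

    def test_cross_modality_agreement(self, radar_cfg):
        """Radar and rPPG pipelines agree within one frequency bin on the
        same clean scenario."""
        from vitalridge.synthgen import displacement_to_phase, simulate_displacement, simulate_rppg

        cfg = ScenarioConfig(duration_s=120.0, seed=0)
        disp, _ = simulate_displacement(cfg)
        phase = displacement_to_phase(disp, radar_cfg)
        trace, _ = simulate_rppg(cfg)
        est_r, _ = estimate_vitals(phase, band="HR")
        est_v, _ = estimate_vitals(trace, band="HR")
        n = min(est_r.bpm.size, est_v.bpm.size)
        assert np.max(np.abs(est_r.bpm[:n] - est_v.bpm[:n])) <= 0.75 + 1e-9

    def test_method_switch_preserves_spectrogram(self, radar_cfg):
        from vitalridge.synthgen import displacement_to_phase, simulate_displacement

        cfg = ScenarioConfig(duration_s=60.0, seed=1, noise_sd_mm=0.1)
        disp, _ = simulate_displacement(cfg)
        phase = displacement_to_phase(disp, radar_cfg)
        _, spec_a = estimate_vitals(phase, band="HR", method="segmentation")
        _, spec_b = estimate_vitals(phase, band="HR", method="spectral-magnitude")
        np.testing.assert_array_equal(spec_a.magnitudes, spec_b.magnitudes)

    def test_segmentation_is_spectrogram_function(self):
        """The estimator depends on the spectrogram only."""
        spec = tone_spectrogram(90.0)
        a = segmentation_estimate(spec)
        b = segmentation_estimate(spec)
        np.testing.assert_array_equal(a.bpm, b.bpm)


def test_exponential_weight_mode_runs():
    cfg = GraphWeightConfig(mode="exponential", sigma_i=0.5, sigma_p=2.0, radius=1.8)
    g = np.random.default_rng(7).uniform(0, 1, (5, 6))
    path = shortest_path(assign_weights(g, cfg))
    assert path.size == 6
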