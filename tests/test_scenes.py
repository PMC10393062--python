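"""Synthetic scene generators: ground truth, conservation, determinism."""

import math

import numpy as np
import pytest

from optorecruit.junctions import linearity_index
from optorecruit.scenes import (
    SceneConfig,
    membrane_fraction_series,
    ratio_excess_series,
    simulate_junction,
    simulate_morphology_sequence,
    simulate_mosaic_monolayer,
    simulate_recruitment_stack,
    simulate_resistance_trace,
)

from .oracles import arc_length_quadrature


class TestSceneConfigValidation:
    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(tau_on=-1.0)

    def test_nonfinite_rate_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(bleach_rate=float("nan"))

    def test_stim_window_outside_recording_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(n_frames=10, frame_interval=1.0, stim_windows=((5.0, 20.0),))

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(stim_windows=((10.0, 50.0), (40.0, 80.0)))

    def test_recruit_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(recruit_fraction=1.5)


class TestRecruitmentStack:
    def test_ratio_matches_closed_form(self, recruitment_scene, recruitment_rois):
        """Noiseless stack: ROI-mean ratio equals the analytic kinetics."""
        config, stack, truth = recruitment_scene
        mem = recruitment_rois["membrane"]
        cyt = recruitment_rois["cytosol"]
        measured = stack.channel("prey")[:, mem].mean(axis=1) / stack.channel("prey")[
            :, cyt
        ].mean(axis=1)
        # closed form within the single ON window: R(t)−1 = target·(1−exp(−t/τ))
        gain = truth.extras["n_cell_px"] / truth.extras["n_membrane_px"]
        r = config.recruit_fraction
        target = gain * r / (1 - r)
        a, b = config.stim_windows[0]
        t = stack.times
        in_win = (t >= a) & (t < b)
        analytic = 1 + target * (1 - np.exp(-(t[in_win] - a) / config.tau_on))
        np.testing.assert_allclose(measured[in_win], analytic, rtol=1e-9)
        np.testing.assert_allclose(measured, truth.true_ratio_series, rtol=1e-9)

    def test_prey_signal_conserved(self, recruitment_scene):
        _, stack, _ = recruitment_scene
        sums = stack.channel("prey").sum(axis=(1, 2))
        assert np.abs(sums / sums[0] - 1.0).max() <= 1e-9

    def test_zero_recruitment_constant_prey(self):
        stack, _ = simulate_recruitment_stack(SceneConfig(recruit_fraction=0.0))
        prey = stack.channel("prey")
        assert np.array_equal(prey[0], prey[-1])

    def test_bleaching_scales_all_signal(self):
        cfg = SceneConfig(recruit_fraction=0.0, bleach_rate=0.01)
        stack, _ = simulate_recruitment_stack(cfg)
        sums = stack.data.sum(axis=(1, 2, 3))
        expected = sums[0] * np.exp(-0.01 * stack.times)
        np.testing.assert_allclose(sums, expected, rtol=1e-9)

    def test_determinism_same_seed(self):
        cfg = SceneConfig(noise_model=("gaussian", 0.5), seed=11)
        a, _ = simulate_recruitment_stack(cfg)
        b, _ = simulate_recruitment_stack(cfg)
        assert np.array_equal(a.data, b.data)

    def test_different_seed_differs(self):
        a, _ = simulate_recruitment_stack(SceneConfig(noise_model=("gaussian", 0.5), seed=1))
        b, _ = simulate_recruitment_stack(SceneConfig(noise_model=("gaussian", 0.5), seed=2))
        assert not np.array_equal(a.data, b.data)

    def test_t_half_tau_identity(self, recruitment_scene):
        config, _, truth = recruitment_scene
        assert truth.true_t_half_on == math.log(2.0) * config.tau_on
        assert truth.true_t_half_off == math.log(2.0) * config.tau_off

    def test_masks_disjoint(self, recruitment_scene):
        _, _, truth = recruitment_scene
        assert not np.any(truth.membrane_mask & truth.cytosol_mask)

    def test_fraction_series_plateaus_at_recruit_fraction(self):
        cfg = SceneConfig(tau_on=2.0, stim_windows=((0.0, 240.0),), n_frames=96)
        f = membrane_fraction_series(cfg, geometry_gain=6.0)
        assert f[0] == 0.0
        # last frame sits at t = 237.5 s ≈ 119 τ_on into the window
        assert f[-1] == pytest.approx(cfg.recruit_fraction, rel=1e-6)

    def test_ratio_excess_off_phase_decays_with_tau_off(self):
        cfg = SceneConfig(stim_windows=((0.0, 100.0),), n_frames=96)
        g = ratio_excess_series(cfg, geometry_gain=6.0)
        t = np.arange(96) * cfg.frame_interval
        k0 = np.searchsorted(t, 100.0)
        decay = g[k0:] / g[k0]
        expected = np.exp(-(t[k0:] - t[k0]) / cfg.tau_off)
        np.testing.assert_allclose(decay, expected, rtol=1e-9)


class TestMorphologySequence:
    def test_constant_profile_constant_area(self):
        movie, truth = simulate_morphology_sequence(np.ones(5), n_cells=1, seed=0)
        areas = truth.true_area_series
        assert np.all(areas == areas[0])

    def test_linear_growth_recovered_from_masks(self):
        movie, truth = simulate_morphology_sequence(
            np.linspace(1.0, 1.15, 8), n_cells=1, base_radius=50.0, seed=2
        )
        ratio = truth.true_area_series[-1, 0] / truth.true_area_series[0, 0]
        assert ratio == pytest.approx(1.15, rel=0.01)

    def test_truth_counted_from_emitted_pixels(self):
        movie, truth = simulate_morphology_sequence(
            np.linspace(1.0, 1.1, 3), n_cells=1, seed=3
        )
        for k in range(3):
            assert truth.true_area_series[k, 0] == np.count_nonzero(movie.data[k, 0])

    def test_edge_touching_cell_flagged(self):
        _, truth = simulate_morphology_sequence(
            np.ones(2), n_cells=2, image_shape=(160, 160), base_radius=50.0, seed=0
        )
        assert len(truth.edge_touching) >= 1

    def test_shrinkage_below_one_px_rejected(self):
        with pytest.raises(ValueError):
            simulate_morphology_sequence(np.array([1.0, 1e-6]), base_radius=50.0)


class TestJunctionScene:
    def test_straight_paths_have_unit_linearity(self):
        paths, truth = simulate_junction(tortuosity=0.0, n_corners=3, seed=0)
        for p in paths:
            assert linearity_index(p).linearity_index == pytest.approx(1.0, abs=1e-12)

    def test_semicircle_arc_over_chord_is_half_pi(self):
        paths, truth = simulate_junction(shape="semicircle", n_corners=2, seed=0)
        assert truth.true_arc_length / truth.true_chord_polygon_perimeter == pytest.approx(
            math.pi / 2, rel=1e-6
        )

    def test_sine_path_arc_length_matches_quadrature_oracle(self):
        paths, truth = simulate_junction(
            tortuosity=5.0, n_corners=2, length=100.0, sine_period=50.0, seed=4
        )
        p0, p1 = truth.extras["corners"]

        def curve(s):
            chord = p1 - p0
            t_hat = chord / np.linalg.norm(chord)
            n_hat = np.array([-t_hat[1], t_hat[0]])
            clen = np.linalg.norm(chord)
            off = 5.0 * np.sin(2 * np.pi * s * clen / 50.0)
            return p0 + np.outer(s, chord) + np.outer(off, n_hat)

        oracle = arc_length_quadrature(curve)
        assert truth.true_arc_length == pytest.approx(oracle, rel=1e-3)
        # the emitted polyline is a coarser sampling of the same curve
        assert linearity_index(paths[0]).junction_perimeter == pytest.approx(
            oracle, rel=5e-3
        )


class TestMosaicScene:
    def test_identical_masks_full_overlap(self):
        stack, truth = simulate_mosaic_monolayer(overlap_fraction=1.0)
        a = stack.data[0, 0] > 0
        b = stack.data[0, 1] > 0
        assert np.array_equal(a, b)
        assert truth.true_overlap_series[0] == a.sum()

    def test_disjoint_masks_zero_overlap(self):
        stack, truth = simulate_mosaic_monolayer(overlap_fraction=0.0)
        assert truth.true_overlap_series[0] == 0.0

    def test_requested_fraction_within_two_percent(self):
        _, truth = simulate_mosaic_monolayer(overlap_fraction=0.30)
        assert truth.extras["overlap_fraction_measured"] == pytest.approx(0.30, abs=0.006)

    def test_growth_series_counted_from_masks(self):
        stack, truth = simulate_mosaic_monolayer(
            overlap_fraction=0.3, growth_factor=1.2, n_frames=5
        )
        inter = (stack.data[:, 0] > 0) & (stack.data[:, 1] > 0)
        np.testing.assert_array_equal(
            truth.true_overlap_series, inter.sum(axis=(1, 2)).astype(float)
        )
        assert truth.true_overlap_series[-1] / truth.true_overlap_series[0] == pytest.approx(
            1.2, rel=0.02
        )


class TestResistanceScene:
    def test_zero_amplitude_flat(self):
        tr = simulate_resistance_trace(amplitude=0.0)
        assert np.all(tr.resistance == 1000.0)

    def test_default_sampling_every_ten_seconds(self):
        tr = simulate_resistance_trace()
        assert np.all(np.diff(tr.time) == 10.0)

    def test_relaxation_after_window(self):
        tr = simulate_resistance_trace(
            baseline=0.0, amplitude=100.0, stim_windows=((100.0, 200.0),),
            relax_tau=50.0, duration=600.0,
        )
        after = tr.time >= 200.0
        expected = 100.0 * np.exp(-(tr.time[after] - 200.0) / 50.0)
        np.testing.assert_allclose(tr.resistance[after], expected, rtol=1e-9)

    def test_seeded_noise_reproducible(self):
        a = simulate_resistance_trace(noise_sigma=3.0, seed=5)
        b = simulate_resistance_trace(noise_sigma=3.0, seed=5)
        assert np.array_equal(a.resistance, b.resistance)
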