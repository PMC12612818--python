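"""Synthetic co-culture generator: walks, rendering, determinism, calibration."""

import numpy as np
import pytest

from trichotrack.config import Calibration, ConfigError, SimulationConfig
from trichotrack.metrics import compute_metrics
from trichotrack.segmentation import segment_stack
from trichotrack.simulate import (FLAGELLATE, body_mask, render_frames,
                                  render_probability_maps, simulate_movie,
                                  simulate_tracks, write_movie)
from trichotrack.tracking import Spot, Track


def small_cfg(**kw):
    base = dict(field_width_px=96, field_height_px=96, n_frames=8,
                n_flagellates=3, n_bacteria=3, seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateTracks:
    def test_zero_speed_distribution_is_a_fixed_point(self):
        cfg = small_cfg(flagellate_speed_dist=(0.0, 0.0),
                        bacteria_speed_dist=(0.0, 0.0))
        for t in simulate_tracks(cfg):
            assert np.allclose(t.positions, t.positions[0])

    def test_zero_turning_noise_gives_straight_tracks(self, cal):
        cfg = small_cfg(field_width_px=4000, field_height_px=4000,
                        flagellate_turn_sd_rad=0.0, n_bacteria=0,
                        flagellate_speed_dist=(10.0, 0.2))
        for t in simulate_tracks(cfg):
            track = Track(track_id=t.cell_id,
                          spots=[Spot(frame=int(f), x_px=x, y_px=y)
                                 for f, (x, y) in zip(t.frames, t.positions)])
            m = compute_metrics(track, cal)
            assert m.confinement_ratio == pytest.approx(1.0, abs=1e-9)

    def test_positions_stay_in_bounds_with_reflection(self):
        cfg = small_cfg(field_width_px=32, field_height_px=32, n_frames=200,
                        flagellate_speed_dist=(30.0, 0.5), n_bacteria=0)
        for t in simulate_tracks(cfg):
            assert t.positions[:, 0].min() >= 0
            assert t.positions[:, 0].max() <= cfg.field_width_px - 1
            assert t.positions[:, 1].min() >= 0
            assert t.positions[:, 1].max() <= cfg.field_height_px - 1
            assert np.all(np.diff(t.frames) == 1)

    def test_step_length_matches_drawn_speed(self):
        cfg = small_cfg(field_width_px=5000, field_height_px=5000, n_bacteria=0)
        for t in simulate_tracks(cfg):
            measured = t.measured_mean_speed_um_s(cfg.pixel_size_um,
                                                  cfg.frame_interval_s)
            assert measured == pytest.approx(t.true_mean_speed_um_s, rel=1e-9)

    def test_population_median_converges_at_n200(self):
        """Empirical median of per-cell speeds within 5% of the configured 10."""
        cfg = small_cfg(field_width_px=5000, field_height_px=5000,
                        n_flagellates=200, n_bacteria=0,
                        flagellate_speed_dist=(10.0, 0.35), seed=123)
        speeds = [t.true_mean_speed_um_s for t in simulate_tracks(cfg)
                  if t.cell_class == FLAGELLATE]
        assert np.median(speeds) == pytest.approx(10.0, rel=0.05)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            small_cfg(pixel_size_um=0)
        with pytest.raises(ConfigError):
            small_cfg(n_frames=0)
        with pytest.raises(ConfigError):
            small_cfg(frame_interval_s=-1)


class TestRendering:
    def test_empty_scene_is_background_plus_noise(self):
        cfg = small_cfg(n_flagellates=0, n_bacteria=0, noise_sd=0.0)
        frames = render_frames(simulate_tracks(cfg), cfg)
        assert np.all(frames == round(cfg.background_level))

    def test_noise_free_stationary_scene_is_time_invariant(self):
        cfg = small_cfg(n_flagellates=1, n_bacteria=0, noise_sd=0.0,
                        flagellate_speed_dist=(0.0, 0.0))
        frames = render_frames(simulate_tracks(cfg), cfg)
        assert all(np.array_equal(frames[0], f) for f in frames)

    def test_seed_determinism_bit_identical(self):
        a = simulate_movie(small_cfg(seed=77))
        b = simulate_movie(small_cfg(seed=77))
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(a.probability_maps, b.probability_maps)
        for ta, tb in zip(a.truth, b.truth):
            assert np.array_equal(ta.positions, tb.positions)

    def test_default_filters_keep_flagellates_and_reject_bacteria(self, seg_params):
        """At default calibration the chain retains flagellate footprints
        (area <= 40 px) and yields no retained bacterial detection."""
        cfg = SimulationConfig(field_width_px=128, field_height_px=128,
                               n_frames=4, n_flagellates=1, n_bacteria=0,
                               noise_sd=0.0, classifier_noise_sd=0.0,
                               flagellate_speed_dist=(0.0, 0.0), seed=5)
        movie = simulate_movie(cfg)
        res = segment_stack(movie.frames, seg_params)
        kept = res.particles[res.particles["retained"]]
        assert len(kept) == cfg.n_frames          # one particle per frame
        assert (kept["area_px"] <= 40).all()
        cfg_b = SimulationConfig(field_width_px=128, field_height_px=128,
                                 n_frames=4, n_flagellates=0, n_bacteria=20,
                                 noise_sd=0.0, classifier_noise_sd=0.0, seed=6)
        movie_b = simulate_movie(cfg_b)
        res_b = segment_stack(movie_b.frames, seg_params)
        assert int(res_b.particles["retained"].sum()) == 0


class TestProbabilityMaps:
    def test_noise_free_maps_zero_outside_flagellates(self):
        cfg = small_cfg(n_bacteria=0, classifier_noise_sd=0.0)
        truth = simulate_tracks(cfg)
        maps = render_probability_maps(truth, cfg)
        shape = (cfg.field_height_px, cfg.field_width_px)
        for f in range(cfg.n_frames):
            inside = np.zeros(shape, bool)
            for t in truth:
                inside |= body_mask(t, f, cfg, shape)
            outside_vals = maps[f][~inside]
            # soft 1-px edges extend one pixel beyond the half-coverage mask
            from scipy.ndimage import binary_dilation
            strict_outside = ~binary_dilation(inside, iterations=2)
            assert maps[f][strict_outside].max() == 0

    def test_empty_scene_maps_all_zero(self):
        cfg = small_cfg(n_flagellates=0, n_bacteria=0, classifier_noise_sd=0.0)
        maps = render_probability_maps(simulate_tracks(cfg), cfg)
        assert not maps.any()

    def test_flagellate_interiors_brighter_than_bacterial_interiors(self):
        cfg = SimulationConfig(field_width_px=256, field_height_px=256,
                               n_frames=5, n_flagellates=6, n_bacteria=30, seed=3)
        movie = simulate_movie(cfg)
        shape = (cfg.field_height_px, cfg.field_width_px)
        flag_vals, bact_vals = [], []
        for f in range(cfg.n_frames):
            for t in movie.truth:
                mask = body_mask(t, f, cfg, shape)
                if not mask.any():
                    # sub-resolution body: fall back to the nearest pixel
                    x, y = t.positions[f]
                    mask = np.zeros(shape, bool)
                    mask[int(round(y)), int(round(x))] = True
                vals = movie.probability_maps[f][mask]
                (flag_vals if t.cell_class == FLAGELLATE else bact_vals).extend(vals)
        assert np.mean(flag_vals) > np.mean(bact_vals)


class TestMovieIO:
    def test_write_movie_round_trips(self, tmp_path):
        import pandas as pd
        import tifffile
        movie = simulate_movie(small_cfg(seed=8))
        paths = write_movie(movie, tmp_path)
        frames = tifffile.imread(paths["frames"])
        assert np.array_equal(frames, movie.frames)
        maps = tifffile.imread(paths["probability_maps"])
        assert np.array_equal(maps, movie.probability_maps)
        truth = pd.read_csv(paths["truth"])
        assert set(truth.columns) == {"cell_id", "cell_class", "frame",
                                      "x_px", "y_px"}
        assert len(truth) == len(movie.truth) * movie.config.n_frames
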