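"""Segmentation chain: operator semantics, threshold oracle, particle filters."""

import numpy as np
import pytest

from trichotrack.config import ConfigError, SegmentationParams
from trichotrack.segmentation import (UnimodalHistogramError, filter_particles,
                                      frame_histogram, gaussian_smooth,
                                      label_and_measure, minimum_threshold,
                                      segment_stack, subtract_constant,
                                      temporal_blur, to_uint8)
from trichotrack.segmentation import ParticleRecord


# --- independent step-by-step oracle of the histogram-minimum algorithm ----

def minimum_threshold_oracle(hist):
    """Literal plain-Python smoothing loop; kept free of the implementation."""
    h = [float(v) for v in hist]

    def peaks(v):
        return [i for i in range(1, 255) if v[i - 1] < v[i] > v[i + 1]]

    iterations = 0
    while len(peaks(h)) != 2:
        assert iterations < 10_000, "oracle: histogram never became bimodal"
        h = [(h[max(i - 1, 0)] + h[i] + h[min(i + 1, 255)]) / 3.0
             for i in range(256)]
        iterations += 1
    p1, p2 = peaks(h)
    valley = h[p1 + 1:p2]
    lo = min(valley)
    lows = [p1 + 1 + i for i, v in enumerate(valley) if v == lo]
    return (lows[0] + lows[-1]) // 2


def random_bimodal_histogram(rng):
    c1 = rng.integers(20, 100)
    c2 = rng.integers(c1 + 60, 240)
    s1, s2 = rng.uniform(3, 15, size=2)
    n1, n2 = rng.integers(500, 5000, size=2)
    x = np.concatenate([rng.normal(c1, s1, n1), rng.normal(c2, s2, n2)])
    return np.bincount(np.clip(np.round(x), 0, 255).astype(int), minlength=256)


class TestToUint8:
    def test_uint8_identity(self):
        stack = np.arange(12, dtype=np.uint8).reshape(3, 4)
        assert to_uint8(stack) is stack

    def test_ramp_rescaled(self):
        ramp = np.linspace(0, 65535, 256).astype(np.uint16)
        out = to_uint8(ramp)
        assert out[0] == 0 and out[-1] == 255
        assert np.all(np.diff(out.astype(int)) >= 0)

    def test_constant_maps_to_zero(self):
        assert np.all(to_uint8(np.full((4, 4), 7.0)) == 0)


class TestSubtract:
    @pytest.mark.parametrize("pixel,sub,expected", [(50, 50, 0), (49, 50, 0),
                                                    (200, 50, 150), (130, 0, 130)])
    def test_clamped_subtraction(self, pixel, sub, expected):
        out = subtract_constant(np.full((2, 2), pixel, dtype=np.uint8), sub)
        assert out.dtype == np.uint8
        assert np.all(out == expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            subtract_constant(np.zeros((2, 2), np.uint8), 300)


class TestGaussianSmooth:
    def test_sigma_zero_identity(self):
        img = np.random.default_rng(0).integers(0, 255, (3, 16, 16)).astype(np.uint8)
        assert np.array_equal(gaussian_smooth(img, 0), img.astype(float))

    def test_dc_preserved_on_constant(self):
        img = np.full((1, 32, 32), 80.0)
        assert np.allclose(gaussian_smooth(img, 2.0), 80.0)

    def test_impulse_kernel_sums_to_one(self):
        img = np.zeros((1, 65, 65))
        img[0, 32, 32] = 1.0
        out = gaussian_smooth(img, 2.0)
        assert abs(out.sum() - 1.0) < 1e-6

    def test_negative_sigma_rejected(self):
        with pytest.raises(ConfigError):
            gaussian_smooth(np.zeros((2, 2)), -1.0)


class TestMinimumThreshold:
    def test_two_delta_histogram(self):
        h = np.zeros(256)
        h[10], h[200] = 1000, 800
        t = minimum_threshold(h)
        assert 10 < t < 200
        assert t == minimum_threshold_oracle(h)

    def test_symmetric_triangular_peaks_valley_centred(self):
        h = np.zeros(256)
        for w in range(-20, 21):
            h[60 + w] += 21 - abs(w)
            h[180 + w] += 21 - abs(w)
        assert abs(minimum_threshold(h) - 120) <= 1

    def test_single_bin_raises(self):
        h = np.zeros(256)
        h[100] = 50
        with pytest.raises(UnimodalHistogramError):
            minimum_threshold(h)

    def test_never_bimodal_raises(self):
        # strictly monotone histogram: smoothing never creates two peaks
        h = np.arange(256, dtype=float) + 1
        with pytest.raises(UnimodalHistogramError):
            minimum_threshold(h, max_iter=200)

    def test_matches_oracle_on_random_bimodal_mixtures(self, rng):
        for _ in range(100):
            h = random_bimodal_histogram(rng)
            assert minimum_threshold(h) == minimum_threshold_oracle(h)


class TestLabelAndMeasure:
    def test_filled_disc_is_circular(self):
        yy, xx = np.mgrid[0:25, 0:25]
        disc = (xx - 12) ** 2 + (yy - 12) ** 2 <= 100
        recs = label_and_measure(disc)
        assert len(recs) == 1
        assert recs[0].circularity >= 0.9
        assert recs[0].area_px == disc.sum()
        assert abs(recs[0].centroid_x_px - 12) < 1e-9

    def test_thin_line_far_less_circular_than_disc(self):
        line = np.zeros((5, 12), bool)
        line[2, 2:10] = True
        (rec,) = label_and_measure(line)
        # crofton-4 perimeter of the 1x8 line: direct computation
        assert rec.circularity == pytest.approx(0.3949495798730258, abs=1e-12)
        long_rod = np.zeros((5, 20), bool)
        long_rod[2, 2:18] = True
        (rod,) = label_and_measure(long_rod)
        assert rod.circularity < 0.25  # elongated rods fall below the filter

    def test_empty_frame(self):
        assert label_and_measure(np.zeros((8, 8), bool)) == []

    def test_connectivity_modes(self):
        img = np.zeros((4, 4), bool)
        img[0, 0] = img[1, 1] = True  # diagonal touch
        assert len(label_and_measure(img, connectivity=4)) == 2
        assert len(label_and_measure(img, connectivity=8)) == 1


def _rec(area, circ):
    return ParticleRecord(frame=0, label=1, centroid_x_px=0, centroid_y_px=0,
                          area_px=area, perimeter_px=1.0, circularity=circ)


class TestFilterParticles:
    @pytest.mark.parametrize("area,circ,kept", [
        (41, 0.9, False),   # "area larger than 40 pixels" excluded
        (40, 0.25, True),   # boundary values retained under strict reading
        (20, 0.24, False),  # "circularity was less than 0.25" excluded
        (20, 0.9, True),
    ])
    def test_strict_boundary_semantics(self, area, circ, kept):
        out = filter_particles([_rec(area, circ)], 40, 0.25)
        assert (len(out) == 1) is kept

    def test_empty_and_idempotent_never_grows(self, rng):
        assert filter_particles([]) == []
        parts = [_rec(int(a), float(c)) for a, c in
                 zip(rng.integers(1, 80, 50), rng.uniform(0, 1, 50))]
        once = filter_particles(parts)
        assert len(once) <= len(parts)
        assert filter_particles(once) == once


class TestTemporalBlur:
    def test_zero_stack(self):
        assert np.all(temporal_blur(np.zeros((4, 8, 8))) == 0)

    def test_sigma_zero_identity(self):
        m = np.random.default_rng(1).random((3, 6, 6)) > 0.5
        assert np.array_equal(temporal_blur(m, (0, 0, 0)), m.astype(float))

    def test_single_event_symmetric_in_xyt(self):
        stack = np.zeros((9, 9, 9))
        stack[4, 4, 4] = 1.0
        out = temporal_blur(stack, (1.0, 1.0, 1.0))
        assert np.allclose(out, out[::-1], atol=1e-12)          # t symmetry
        assert np.allclose(out, out[:, ::-1], atol=1e-12)       # y symmetry
        assert np.allclose(out, out[:, :, ::-1], atol=1e-12)    # x symmetry
        assert 0 <= out.min() and out.max() <= 1

    def test_negative_sigma_rejected(self):
        with pytest.raises(ConfigError):
            temporal_blur(np.zeros((2, 4, 4)), (-1, 0, 0))


class TestChain:
    def test_chain_on_synthetic_maps_retains_only_flagellates(
            self, small_movie, seg_params):
        res = segment_stack(small_movie.probability_maps, seg_params)
        parts = res.particles
        assert len(parts) > 0
        kept = parts[parts["retained"]]
        assert (kept["area_px"] <= seg_params.max_area_px).all()
        assert (kept["circularity"] >= seg_params.min_circularity).all()
        assert res.blurred.shape == small_movie.probability_maps.shape
        assert res.blurred.min() >= 0 and res.blurred.max() <= 1

    def test_cell_free_frames_use_fallback_and_yield_nothing(self, seg_params):
        stack = np.full((3, 64, 64), 20, dtype=np.uint8)
        res = segment_stack(stack, seg_params)
        assert len(res.particles) == 0
        assert not res.retained_masks.any()

    def test_histogram_binning_of_float_frames(self):
        h = frame_histogram(np.array([[0.4, 254.6], [300.0, -5.0]]))
        assert h[0] == 2 and h[255] == 2 and h.sum() == 4
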