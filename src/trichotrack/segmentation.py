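"""Probability-map post-processing: the published operator chain.

Chain order is fixed: 8-bit conversion -> constant subtraction -> per-frame
Gaussian smoothing -> histogram-minimum global threshold -> connected-
component measurement -> area/circularity particle filter -> 3-D Gaussian
blur of the retained-particle mask to ease tracking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .config import ConfigError, SegmentationParams


class UnimodalHistogramError(RuntimeError):
    """Histogram never became bimodal within the smoothing-iteration cap."""


@dataclass(frozen=True)
class ParticleRecord:
    """One segmented connected component in one frame."""

    frame: int
    label: int
    centroid_x_px: float
    centroid_y_px: float
    area_px: int
    perimeter_px: float
    circularity: float  # min(1, 4*pi*area/perimeter^2), ImageJ convention


def to_uint8(stack: np.ndarray) -> np.ndarray:
    """Linear min-max rescale to [0, 255]; identity for uint8 input.

    A constant-valued stack maps to all zeros (degenerate but not an error).
    """
    stack = np.asarray(stack)
    if stack.dtype == np.uint8:
        return stack
    lo = float(stack.min())
    hi = float(stack.max())
    if hi == lo:
        return np.zeros(stack.shape, dtype=np.uint8)
    scaled = (stack.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.clip(np.round(scaled), 0, 255).astype(np.uint8)


def subtract_constant(stack: np.ndarray, subtract_value: int) -> np.ndarray:
    """Per-pixel max(v - subtract_value, 0) with unsigned 8-bit semantics."""
    if not 0 <= subtract_value <= 255:
        raise ConfigError("subtract_value must be in [0, 255]")
    stack = np.asarray(stack)
    out = stack.astype(np.int16) - int(subtract_value)
    return np.clip(out, 0, 255).astype(np.uint8)


def gaussian_smooth(stack: np.ndarray, sigma: float) -> np.ndarray:
    """Per-frame 2-D Gaussian filter; float output to avoid pre-threshold quantization."""
    if sigma < 0:
        raise ConfigError("sigma must be >= 0")
    stack = np.asarray(stack, dtype=np.float64)
    if sigma == 0:
        return stack.copy()
    if stack.ndim == 2:
        return ndimage.gaussian_filter(stack, sigma)
    return ndimage.gaussian_filter(stack, sigma=(0, sigma, sigma))


def minimum_threshold(histogram: np.ndarray, max_iter: int = 10_000) -> int:
    """Histogram-minimum global threshold (iterative-smoothing valley finder).

    The 256-bin histogram is repeatedly smoothed with a 3-point moving mean
    (edge bins replicated) until exactly two strict local maxima remain; the
    returned threshold is the midpoint of the lowest-valued plateau between
    them.  Raises :class:`UnimodalHistogramError` if the histogram never
    becomes bimodal within ``max_iter`` smoothing passes.
    """
    h = np.asarray(histogram, dtype=np.float64)
    if h.ndim != 1 or len(h) != 256:
        raise ValueError("histogram must be a 256-bin count vector")
    if np.count_nonzero(h) < 2:
        raise UnimodalHistogramError("histogram has fewer than two nonzero bins")

    def peaks(v: np.ndarray) -> np.ndarray:
        interior = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
        return np.flatnonzero(interior) + 1

    it = 0
    pk = peaks(h)
    while len(pk) != 2:
        if it >= max_iter:
            raise UnimodalHistogramError(
                f"histogram did not become bimodal within {max_iter} iterations")
        padded = np.concatenate(([h[0]], h, [h[-1]]))
        h = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0
        it += 1
        pk = peaks(h)
    p1, p2 = int(pk[0]), int(pk[1])
    valley = h[p1 + 1:p2]
    lows = np.flatnonzero(valley == valley.min()) + p1 + 1
    return int((lows[0] + lows[-1]) // 2)


def frame_histogram(frame: np.ndarray) -> np.ndarray:
    """256-bin histogram of a (possibly float) frame rounded into 8-bit bins."""
    vals = np.clip(np.round(np.asarray(frame, dtype=np.float64)), 0, 255)
    return np.bincount(vals.astype(np.intp).ravel(), minlength=256)[:256]


def label_and_measure(binary: np.ndarray, connectivity: int = 8,
                      frame: int = 0) -> list[ParticleRecord]:
    """Connected components with centroid, area, Crofton perimeter, circularity.

    Circularity follows the ImageJ convention 4*pi*area/perimeter^2, capped
    at 1 (the Crofton estimator can push compact shapes slightly above 1).
    """
    if connectivity not in (4, 8):
        raise ConfigError("connectivity must be 4 or 8")
    binary = np.asarray(binary, dtype=bool)
    lab = measure.label(binary, connectivity=1 if connectivity == 4 else 2)
    records: list[ParticleRecord] = []
    for rp in measure.regionprops(lab):
        # perimeter on the padded crop: identical to the full-frame value
        # for an isolated component, much cheaper for many particles
        crop = np.pad(rp.image, 1)
        perim = float(measure.perimeter_crofton(crop, directions=4))
        if perim <= 0:  # single isolated pixel groups always have perim > 0
            continue
        area = int(rp.area)
        circ = min(1.0, 4.0 * np.pi * area / perim ** 2)
        cy, cx = rp.centroid
        records.append(ParticleRecord(frame=frame, label=int(rp.label),
                                      centroid_x_px=float(cx), centroid_y_px=float(cy),
                                      area_px=area, perimeter_px=perim,
                                      circularity=circ))
    return records


def filter_particles(particles: list[ParticleRecord], max_area_px: int = 40,
                     min_circularity: float = 0.25) -> list[ParticleRecord]:
    """Retain particles with area <= max_area_px and circularity >= min_circularity.

    Strict reading of the published exclusions ("larger than 40 pixels",
    "less than 0.25"): boundary values are kept.
    """
    return [p for p in particles
            if p.area_px <= max_area_px and p.circularity >= min_circularity]


def temporal_blur(mask_stack: np.ndarray,
                  sigma: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> np.ndarray:
    """Separable 3-D Gaussian over (x, y, frame); float output in [0, 1]."""
    sx, sy, st = sigma
    if min(sx, sy, st) < 0:
        raise ConfigError("temporal_blur sigmas must be >= 0")
    stack = np.asarray(mask_stack, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("mask stack must be (frames, height, width)")
    if sx == sy == st == 0:
        return stack.copy()
    return ndimage.gaussian_filter(stack, sigma=(st, sy, sx))


def particles_to_frame(particles: list[ParticleRecord],
                       labelled: np.ndarray) -> np.ndarray:
    """Binary frame containing only the listed particles of a labelled image."""
    keep = np.zeros(int(labelled.max()) + 1, dtype=bool)
    for p in particles:
        keep[p.label] = True
    return keep[labelled]


@dataclass
class SegmentationResult:
    """Output of the full chain on one stack."""

    particles: pd.DataFrame       # all measured particles with retained flag
    retained_masks: np.ndarray    # (T, H, W) bool, retained particles only
    blurred: np.ndarray           # (T, H, W) float, 3-D blurred masks
    thresholds: list[int | None]  # per-frame threshold actually applied


def _particles_df(rows: list[tuple[ParticleRecord, bool]]) -> pd.DataFrame:
    cols = ["frame", "label", "x_px", "y_px", "area_px", "perimeter_px",
            "circularity", "retained"]
    data = [(p.frame, p.label, p.centroid_x_px, p.centroid_y_px, p.area_px,
             p.perimeter_px, p.circularity, ret) for p, ret in rows]
    return pd.DataFrame(data, columns=cols)


def segment_stack(stack: np.ndarray,
                  params: SegmentationParams = SegmentationParams()) -> SegmentationResult:
    """Run the full chain on an image stack (probability maps or raw frames).

    Thresholds are computed per frame by default (ImageJ's frame-wise stack
    behaviour); ``params.per_stack_threshold`` switches to one threshold
    from the pooled histogram.  Frames whose histogram never becomes bimodal
    use ``params.fallback_threshold`` when set, else the error propagates.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    stack8 = to_uint8(stack)
    sub = subtract_constant(stack8, params.subtract_value)
    smooth = gaussian_smooth(sub, params.gaussian_sigma)

    def threshold_of(hist: np.ndarray) -> int | None:
        try:
            return minimum_threshold(hist)
        except UnimodalHistogramError:
            if params.fallback_threshold is not None:
                return params.fallback_threshold
            raise

    global_thr: int | None = None
    if params.per_stack_threshold:
        global_thr = threshold_of(frame_histogram(smooth))

    rows: list[tuple[ParticleRecord, bool]] = []
    retained_masks = np.zeros(smooth.shape, dtype=bool)
    thresholds: list[int | None] = []
    for t in range(smooth.shape[0]):
        thr = global_thr if params.per_stack_threshold else threshold_of(
            frame_histogram(smooth[t]))
        thresholds.append(thr)
        binary = smooth[t] > thr
        parts = label_and_measure(binary, params.connectivity, frame=t)
        retained = filter_particles(parts, params.max_area_px, params.min_circularity)
        retained_set = {p.label for p in retained}
        rows += [(p, p.label in retained_set) for p in parts]
        if retained:
            lab = measure.label(binary, connectivity=1 if params.connectivity == 4 else 2)
            retained_masks[t] = particles_to_frame(retained, lab)
    blurred = temporal_blur(retained_masks, params.temporal_sigma)
    return SegmentationResult(particles=_particles_df(rows),
                              retained_masks=retained_masks,
                              blurred=blurred, thresholds=thresholds)
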