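"""Synthetic co-culture movie generator with per-cell ground truth.

Cells move as persistent random walks: each cell draws a speed once from
its class's log-normal speed distribution, then at every frame its heading
receives Gaussian turning noise and it advances one fixed-length step.
Flagellates are rendered as oriented ellipses, bacteria as capsules
(rods with hemispherical caps); both with ~1 px soft anti-aliased edges.
A separate "probability map" stack mimics the output of a pixel classifier
trained on the protist class only: flagellate bodies near 255 with
distance-tapered edges, bacteria and background near 0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

from .config import ConfigError, SimulationConfig

FLAGELLATE = "flagellate"
BACTERIUM = "bacterium"


@dataclass
class GroundTruthTrack:
    """True trajectory of one simulated cell.

    positions[k] = (x_px, y_px) at frame ``frames[k]``; headings are the
    instantaneous motion directions used when rendering oriented bodies.
    """

    cell_id: int
    cell_class: str
    frames: np.ndarray          # (n,) int
    positions: np.ndarray       # (n, 2) float, columns (x, y)
    headings: np.ndarray        # (n,) float, radians
    speed_um_s: float           # per-cell speed drawn from the class distribution

    @property
    def true_mean_speed_um_s(self) -> float:
        return self.speed_um_s

    def measured_mean_speed_um_s(self, pixel_size_um: float,
                                 frame_interval_s: float) -> float:
        """Mean speed recomputed from the stored positions (sanity check)."""
        steps = np.linalg.norm(np.diff(self.positions, axis=0), axis=1)
        if len(steps) == 0:
            return 0.0
        return float(steps.mean()) * pixel_size_um / frame_interval_s


@dataclass
class SyntheticMovie:
    """Rendered frames + probability maps + the ground truth behind them."""

    frames: np.ndarray            # (T, H, W) uint8
    probability_maps: np.ndarray  # (T, H, W) uint8
    truth: list[GroundTruthTrack]
    config: SimulationConfig

    def flagellate_tracks(self) -> list[GroundTruthTrack]:
        return [t for t in self.truth if t.cell_class == FLAGELLATE]

    def bacteria_tracks(self) -> list[GroundTruthTrack]:
        return [t for t in self.truth if t.cell_class == BACTERIUM]


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - a, 2 * np.pi)


def _walk_class(rng: np.random.Generator, cfg: SimulationConfig, n_cells: int,
                cell_class: str, speed_dist: tuple[float, float],
                turn_sd: float, id_offset: int) -> list[GroundTruthTrack]:
    w = cfg.field_width_px - 1.0
    h = cfg.field_height_px - 1.0
    median, sigma = speed_dist
    tracks: list[GroundTruthTrack] = []
    for i in range(n_cells):
        if median > 0:
            speed = float(np.exp(rng.normal(np.log(median), sigma)))
        else:
            speed = 0.0
        step = speed * cfg.frame_interval_s / cfg.pixel_size_um
        pos = np.empty((cfg.n_frames, 2))
        head = np.empty(cfg.n_frames)
        x = rng.uniform(0, w)
        y = rng.uniform(0, h)
        theta = rng.uniform(-np.pi, np.pi)
        for t in range(cfg.n_frames):
            pos[t] = (x, y)
            head[t] = theta
            if t == cfg.n_frames - 1:
                break
            if step == 0:
                continue  # no motion: heading (direction of motion) is frozen
            if turn_sd > 0:
                theta = float(_wrap_angle(np.asarray(theta + rng.normal(0, turn_sd))))
            x += step * np.cos(theta)
            y += step * np.sin(theta)
            # reflective boundaries: fold position back in, mirror the heading
            if x < 0 or x > w:
                x = abs(x) if x < 0 else 2 * w - x
                x = min(max(x, 0.0), w)
                theta = float(_wrap_angle(np.asarray(np.pi - theta)))
            if y < 0 or y > h:
                y = abs(y) if y < 0 else 2 * h - y
                y = min(max(y, 0.0), h)
                theta = -theta
        tracks.append(GroundTruthTrack(
            cell_id=id_offset + i, cell_class=cell_class,
            frames=np.arange(cfg.n_frames), positions=pos, headings=head,
            speed_um_s=speed))
    return tracks


def simulate_tracks(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> list[GroundTruthTrack]:
    """Simulate persistent-random-walk ground-truth tracks for both classes.

    A fresh generator is seeded from ``config.seed`` unless ``rng`` is given,
    so identical configs give bit-identical trajectories.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tracks = _walk_class(rng, config, config.n_flagellates, FLAGELLATE,
                         config.flagellate_speed_dist,
                         config.flagellate_turn_sd_rad, id_offset=0)
    tracks += _walk_class(rng, config, config.n_bacteria, BACTERIUM,
                          config.bacteria_speed_dist,
                          config.bacteria_turn_sd_rad,
                          id_offset=config.n_flagellates)
    return tracks


def _paint_soft(canvas: np.ndarray, coverage_fn, cx: float, cy: float,
                radius_px: float, amplitude: float) -> None:
    """Add ``amplitude * coverage`` over a bounding box around (cx, cy).

    ``coverage_fn(dx, dy)`` returns per-pixel coverage in [0, 1]; dx, dy are
    offsets of pixel centres from the cell centre.
    """
    h, w = canvas.shape
    r = int(np.ceil(radius_px + 2))
    x0, x1 = max(int(np.floor(cx)) - r, 0), min(int(np.ceil(cx)) + r + 1, w)
    y0, y1 = max(int(np.floor(cy)) - r, 0), min(int(np.ceil(cy)) + r + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    cov = coverage_fn(xx - cx, yy - cy)
    canvas[y0:y1, x0:x1] += amplitude * cov


def _ellipse_coverage(dx, dy, a, b, theta):
    """Soft coverage of a rotated ellipse with semi-axes (a, b) px."""
    c, s = np.cos(theta), np.sin(theta)
    u = (dx * c + dy * s) / a
    v = (-dx * s + dy * c) / b
    rho = np.sqrt(u * u + v * v)
    # approximate signed distance to the boundary, tapered over ~1 px
    dist = (1.0 - rho) * b
    return np.clip(dist + 0.5, 0.0, 1.0)


def _capsule_coverage(dx, dy, half_len, half_width, theta):
    """Soft coverage of a capsule (segment of half-length half_len, radius half_width)."""
    c, s = np.cos(theta), np.sin(theta)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    du = np.maximum(np.abs(u) - half_len, 0.0)
    dist = half_width - np.sqrt(du * du + v * v)
    return np.clip(dist + 0.5, 0.0, 1.0)


def _body_radius_px(track_class: str, cfg: SimulationConfig) -> float:
    p = cfg.pixel_size_um
    if track_class == FLAGELLATE:
        return max(cfg.flagellate_axes_um) / p
    return (cfg.bacteria_dims_um[0] / 2) / p


def body_mask(track: GroundTruthTrack, frame: int, cfg: SimulationConfig,
              shape: tuple[int, int]) -> np.ndarray:
    """Boolean footprint of one cell at one frame (coverage >= 0.5)."""
    canvas = np.zeros(shape, dtype=float)
    _render_cell(canvas, track, frame, cfg, amplitude=1.0)
    return canvas >= 0.5


def _render_cell(canvas: np.ndarray, track: GroundTruthTrack, frame: int,
                 cfg: SimulationConfig, amplitude: float) -> None:
    x, y = track.positions[frame]
    theta = track.headings[frame]
    p = cfg.pixel_size_um
    if track.cell_class == FLAGELLATE:
        a, b = cfg.flagellate_axes_um[0] / p, cfg.flagellate_axes_um[1] / p
        _paint_soft(canvas, lambda dx, dy: _ellipse_coverage(dx, dy, a, b, theta),
                    x, y, a, amplitude)
    else:
        length, width = cfg.bacteria_dims_um[0] / p, cfg.bacteria_dims_um[1] / p
        half_len = max((length - width) / 2, 0.0)
        _paint_soft(canvas,
                    lambda dx, dy: _capsule_coverage(dx, dy, half_len, width / 2, theta),
                    x, y, half_len + width / 2, amplitude)


def render_frames(truth: Sequence[GroundTruthTrack], config: SimulationConfig,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Render the raw phase-contrast-like stack: both classes over noisy background."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    shape = (config.n_frames, config.field_height_px, config.field_width_px)
    stack = np.empty(shape, dtype=np.uint8)
    for t in range(config.n_frames):
        canvas = np.full(shape[1:], float(config.background_level))
        for track in truth:
            amp = (config.flagellate_intensity if track.cell_class == FLAGELLATE
                   else config.bacteria_intensity)
            _render_cell(canvas, track, t, config, amp)
        if config.noise_sd > 0:
            canvas += rng.normal(0, config.noise_sd, size=canvas.shape)
        stack[t] = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
    return stack


def render_probability_maps(truth: Sequence[GroundTruthTrack],
                            config: SimulationConfig,
                            rng: np.random.Generator | None = None) -> np.ndarray:
    """Render the classifier stand-in: flagellate bodies near 255, rest near 0."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    shape = (config.n_frames, config.field_height_px, config.field_width_px)
    stack = np.empty(shape, dtype=np.uint8)
    flagellates = [t for t in truth if t.cell_class == FLAGELLATE]
    for t in range(config.n_frames):
        canvas = np.zeros(shape[1:], dtype=float)
        for track in flagellates:
            _render_cell(canvas, track, t, config, amplitude=255.0)
        if config.classifier_noise_sd > 0:
            canvas += rng.normal(0, config.classifier_noise_sd, size=canvas.shape)
        stack[t] = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
    return stack


def simulate_movie(config: SimulationConfig) -> SyntheticMovie:
    """Full generator: tracks, raw frames and probability maps from one seed."""
    truth = simulate_tracks(config)
    frames = render_frames(truth, config)
    maps = render_probability_maps(truth, config)
    return SyntheticMovie(frames=frames, probability_maps=maps,
                          truth=truth, config=config)


# ---------------------------------------------------------------------------
# I/O

def write_movie(movie: SyntheticMovie, out_dir: str | Path) -> dict[str, Path]:
    """Write frames/maps as multi-frame 8-bit TIFF and truth as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "frames": out / "frames.tif",
        "probability_maps": out / "probability_maps.tif",
        "truth": out / "ground_truth.csv",
    }
    tifffile.imwrite(paths["frames"], movie.frames)
    tifffile.imwrite(paths["probability_maps"], movie.probability_maps)
    with open(paths["truth"], "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["cell_id", "cell_class", "frame", "x_px", "y_px"])
        for tr in movie.truth:
            for f, (x, y) in zip(tr.frames, tr.positions):
                wr.writerow([tr.cell_id, tr.cell_class, int(f),
                             f"{x:.6f}", f"{y:.6f}"])
    return paths
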