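"""Evaluation of detections and tracks against simulation ground truth.

These measurements quantify the two claims the synthetic study is designed
to test: the segmentation chain is *selective* (retained particles are
flagellates, bacteria do not survive) and the linker is *accurate*
(consecutive spots in a predicted track belong to the same true cell).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import FLAGELLATE, GroundTruthTrack, SyntheticMovie
from .tracking import Track


def _truth_positions(truth: list[GroundTruthTrack], frame: int) -> np.ndarray:
    return np.array([t.positions[frame] for t in truth], dtype=float)


@dataclass
class SelectivityReport:
    n_retained: int
    n_matched_flagellate: int
    purity: float                 # fraction of retained particles on a flagellate
    n_bacteria: int
    n_bacteria_detected: int      # bacteria producing >= 1 retained particle
    bacteria_survival: float


def selectivity(movie: SyntheticMovie, particles: pd.DataFrame,
                match_radius_px: float | None = None) -> SelectivityReport:
    """Attribute each retained particle to its nearest true cell.

    A particle counts for a flagellate if its nearest ground-truth cell
    within ``match_radius_px`` (default: one flagellate major semi-axis in
    px) is a flagellate; a bacterium "survives" the filters if at least
    one retained particle is nearest to it within the same radius.
    """
    cfg = movie.config
    if match_radius_px is None:
        match_radius_px = max(cfg.flagellate_axes_um) / cfg.pixel_size_um
    truth = movie.truth
    classes = np.array([t.cell_class for t in truth])
    retained = particles[particles["retained"]]
    n_matched_flag = 0
    detected_bacteria: set[int] = set()
    for frame, grp in retained.groupby("frame"):
        pos = _truth_positions(truth, int(frame))
        if len(pos) == 0:
            continue
        pts = grp[["x_px", "y_px"]].to_numpy()
        d = np.linalg.norm(pts[:, None, :] - pos[None, :, :], axis=2)
        nearest = d.argmin(axis=1)
        within = d[np.arange(len(pts)), nearest] <= match_radius_px
        for j, cell, ok in zip(range(len(pts)), nearest, within):
            if not ok:
                continue
            if classes[cell] == FLAGELLATE:
                n_matched_flag += 1
            else:
                detected_bacteria.add(truth[cell].cell_id)
    n_ret = len(retained)
    n_bact = sum(c != FLAGELLATE for c in classes)
    return SelectivityReport(
        n_retained=n_ret,
        n_matched_flagellate=n_matched_flag,
        purity=n_matched_flag / n_ret if n_ret else float("nan"),
        n_bacteria=n_bact,
        n_bacteria_detected=len(detected_bacteria),
        bacteria_survival=len(detected_bacteria) / n_bact if n_bact else 0.0,
    )


def link_accuracy(movie: SyntheticMovie, tracks: list[Track],
                  match_radius_px: float | None = None) -> float:
    """Fraction of predicted frame-to-frame links joining the same true cell.

    Each spot is matched to the nearest ground-truth cell within the radius;
    a link is correct when both endpoints match the same cell.  Links with
    an unmatchable endpoint count as incorrect.
    """
    cfg = movie.config
    if match_radius_px is None:
        match_radius_px = max(cfg.flagellate_axes_um) / cfg.pixel_size_um
    truth = movie.truth
    n_links = 0
    n_correct = 0
    for tr in tracks:
        ids = []
        for s in tr.spots:
            pos = _truth_positions(truth, s.frame)
            if len(pos) == 0:
                ids.append(None)
                continue
            d = np.linalg.norm(pos - np.array([s.x_px, s.y_px]), axis=1)
            j = int(d.argmin())
            ids.append(truth[j].cell_id if d[j] <= match_radius_px else None)
        for a, b in zip(ids[:-1], ids[1:]):
            n_links += 1
            if a is not None and a == b:
                n_correct += 1
    return n_correct / n_links if n_links else float("nan")


def recovered_vs_true_speeds(movie: SyntheticMovie,
                             metric_table: pd.DataFrame) -> pd.DataFrame:
    """Side table of configured/true/recovered speed medians for reporting."""
    true_speeds = [t.true_mean_speed_um_s for t in movie.flagellate_tracks()]
    return pd.DataFrame({
        "quantity": ["configured_median", "true_median", "recovered_median"],
        "um_s": [movie.config.flagellate_speed_dist[0],
                 float(np.median(true_speeds)) if true_speeds else float("nan"),
                 float(metric_table["mean_speed_um_s"].median())
                 if len(metric_table) else float("nan")],
    })
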