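"""Validation experiments run by the analysis drivers and the acceptance suite.

Each function executes a complete, self-contained study on synthetic data
with known ground truth and returns plain dictionaries of measured
quantities.  Problem sizes are the analysis-scale defaults documented in
:mod:`trichotrack.scenarios`.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Any

import numpy as np

from .config import LinkingParams, SegmentationParams, SimulationConfig
from .config import Calibration, default_link_distance
from .evaluate import link_accuracy, selectivity
from .metrics import metrics_table
from .rout import rout_trim
from .scenarios import ANALYSIS_BASE, child_seed, selectivity_scene
from .segmentation import segment_stack
from .simulate import simulate_movie
from .stats import kruskal_wallis, unpaired_t
from .tracking import detect_spots, link_spots

DEFAULT_SEG = SegmentationParams(fallback_threshold=255)


def _track_one_movie(cfg: SimulationConfig, seg_params: SegmentationParams,
                     linking: LinkingParams, use_probability_maps: bool = True):
    movie = simulate_movie(cfg)
    stack = movie.probability_maps if use_probability_maps else movie.frames
    seg = segment_stack(stack, seg_params)
    tracks = link_spots(detect_spots(seg.particles), linking)
    return movie, seg, tracks


def speed_recovery_experiment(seed: int,
                              medians_um_s: dict[str, float] = {
                                  "monoculture": 6.6, "coculture": 10.2},
                              n_fields: int = 8,
                              base: SimulationConfig = ANALYSIS_BASE,
                              ) -> dict[str, Any]:
    """Recover configured per-condition median speeds through the full pipeline.

    Simulates ``n_fields`` fields per condition (20 flagellates each, so
    ~160 cells per condition), runs probability-map segmentation, linking
    and metrics, and compares recovered median speeds between conditions
    with Kruskal-Wallis.
    """
    cal = Calibration(base.pixel_size_um, base.frame_interval_s)
    linking = LinkingParams(max_link_dist_px=default_link_distance(base))
    out: dict[str, Any] = {"conditions": {}}
    speeds_by_cond = {}
    for ci, (cond, median) in enumerate(sorted(medians_um_s.items())):
        speeds = []
        acc = []
        n_cells = 0
        for field in range(n_fields):
            cfg = replace(base,
                          flagellate_speed_dist=(median, base.flagellate_speed_dist[1]),
                          seed=child_seed(seed, 10 + ci, field))
            movie, seg, tracks = _track_one_movie(cfg, DEFAULT_SEG, linking)
            met = metrics_table(tracks, cal)
            speeds.extend(met["mean_speed_um_s"].tolist())
            acc.append(link_accuracy(movie, tracks))
            n_cells += cfg.n_flagellates
        speeds = np.asarray(speeds)
        speeds_by_cond[cond] = speeds
        out["conditions"][cond] = {
            "configured_median_um_s": median,
            "recovered_median_um_s": float(np.median(speeds)),
            "relative_error": float(abs(np.median(speeds) - median) / median),
            "n_tracks": int(len(speeds)),
            "n_simulated_cells": n_cells,
            "link_accuracy": float(np.mean(acc)),
        }
    groups = [speeds_by_cond[c] for c in sorted(speeds_by_cond)]
    kw = kruskal_wallis(*groups, labels=sorted(speeds_by_cond))
    out["kruskal_wallis"] = {"H": kw.statistic, "p_value": kw.p_value}
    return out


def selectivity_experiment(seed: int, n_flagellates: int = 15,
                           n_frames: int = 15,
                           base: SimulationConfig = ANALYSIS_BASE,
                           ) -> dict[str, Any]:
    """Segmentation selectivity on the 10x-bacteria stress scene (raw frames)."""
    cfg = replace(selectivity_scene(seed, n_flagellates, base), n_frames=n_frames)
    linking = LinkingParams(max_link_dist_px=default_link_distance(cfg))
    movie, seg, tracks = _track_one_movie(cfg, DEFAULT_SEG, linking,
                                          use_probability_maps=False)
    rep = selectivity(movie, seg.particles)
    return {
        "n_flagellates": cfg.n_flagellates,
        "n_bacteria": cfg.n_bacteria,
        "n_retained_particles": rep.n_retained,
        "purity": rep.purity,
        "bacteria_survival": rep.bacteria_survival,
        "link_accuracy": link_accuracy(movie, tracks),
    }


def rout_behaviour_experiment(seed: int, reps: int = 200, n: int = 1000,
                              q: float = 0.01) -> dict[str, Any]:
    """False-flag rate on clean normal samples and power on a 10-RSDR spike."""
    rng = np.random.default_rng(child_seed(seed, 50))
    fractions = []
    detected = 0
    for _ in range(reps):
        x = rng.normal(0.0, 1.0, n)
        clean = rout_trim(x, q=q)
        fractions.append(len(clean.outliers) / n)
        spiked = x.copy()
        spiked[0] = clean.robust_center + 10.0 * max(clean.rsdr, 1e-12)
        detected += 0 in rout_trim(spiked, q=q).outlier_indices
    return {"reps": reps, "n": n, "q": q,
            "mean_flagged_fraction": float(np.mean(fractions)),
            "spike_detection_rate": detected / reps}


def type_i_calibration_experiment(seed: int, reps: int = 2000,
                                  alpha: float = 0.05) -> dict[str, Any]:
    """Null rejection rates of Kruskal-Wallis (n=50/group) and Student's t (n=3)."""
    rng_kw = np.random.default_rng(child_seed(seed, 60))
    rej_kw = sum(kruskal_wallis(rng_kw.normal(0, 1, 50),
                                rng_kw.normal(0, 1, 50)).p_value < alpha
                 for _ in range(reps))
    rng_t = np.random.default_rng(child_seed(seed, 61))
    rej_t = sum(unpaired_t(rng_t.normal(0, 1, 3),
                           rng_t.normal(0, 1, 3)).p_value < alpha
                for _ in range(reps))
    return {"reps": reps, "alpha": alpha,
            "kruskal_wallis_rejection_rate": rej_kw / reps,
            "student_t_rejection_rate": rej_t / reps}
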