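"""End-to-end orchestration: simulate -> segment -> track -> metrics -> trim -> compare.

A run is fully described by a :class:`RunConfig` (parseable from YAML via
:func:`validate_config`); re-running with the same config and seed
reproduces every output byte-identically.  Each stage writes its artifacts
under the output directory and the run closes with a JSON manifest
(config hash, seed, per-stage row counts, output checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import (Calibration, ConfigError, LinkingParams,
                     SegmentationParams, SimulationConfig, build_config,
                     default_link_distance)
from .metrics import condition_summary, metrics_table
from .rout import rout_trim
from .scenarios import (ANALYSIS_BASE, DEFAULT_CONDITIONS,
                        DEFAULT_REPLICATES, DEFAULT_TIMEPOINTS_H, study_grid)
from .segmentation import segment_stack
from .simulate import simulate_movie
from .stats import kruskal_wallis
from .tracking import detect_spots, link_spots, track_table

log = logging.getLogger("trichotrack")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str = "results/run"
    conditions: tuple[tuple[str, float], ...] = tuple(sorted(DEFAULT_CONDITIONS.items()))
    timepoints_h: tuple[float, ...] = DEFAULT_TIMEPOINTS_H
    replicates: int = DEFAULT_REPLICATES
    simulation: SimulationConfig = ANALYSIS_BASE
    segmentation: SegmentationParams = SegmentationParams(fallback_threshold=255)
    linking: LinkingParams | None = None  # None: radius derived from calibration
    rout_q: float = 0.01
    trim_metric: str = "mean_speed_um_s"

    def __post_init__(self):
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if not 0 < self.rout_q < 1:
            raise ConfigError("rout q must be in (0, 1)")

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.simulation.pixel_size_um,
                           self.simulation.frame_interval_s)

    def linking_params(self) -> LinkingParams:
        if self.linking is not None:
            return self.linking
        radius = default_link_distance(self.simulation)
        log.info("derived default: max_link_dist_px = %.2f "
                 "(1.5x expected max per-frame step)", radius)
        return LinkingParams(max_link_dist_px=radius)


_SECTIONS = {"simulation": SimulationConfig, "segmentation": SegmentationParams,
             "linking": LinkingParams}
_SCALARS = {"seed", "out_dir", "conditions", "timepoints_h", "replicates",
            "rout_q", "trim_metric"}


def validate_config(raw: str | Mapping[str, Any]) -> RunConfig:
    """Parse and validate a YAML document (or mapping) into a RunConfig.

    Unknown keys anywhere are errors; derived defaults that get filled in
    (e.g. the linking radius) are logged.
    """
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError("configuration must be a mapping")
    unknown = sorted(set(raw) - _SCALARS - set(_SECTIONS))
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")
    kwargs: dict[str, Any] = {k: raw[k] for k in _SCALARS & set(raw)}
    if "conditions" in kwargs:
        if not isinstance(kwargs["conditions"], Mapping):
            raise ConfigError("conditions must map name -> median speed (um/s)")
        kwargs["conditions"] = tuple(sorted(
            (str(k), float(v)) for k, v in kwargs["conditions"].items()))
    if "timepoints_h" in kwargs:
        kwargs["timepoints_h"] = tuple(float(t) for t in kwargs["timepoints_h"])
    for section, cls in _SECTIONS.items():
        if section in raw:
            defaults = dataclasses.asdict(RunConfig().simulation) \
                if section == "simulation" else {}
            merged = {**defaults, **dict(raw[section] or {})}
            kwargs[section] = build_config(cls, merged, section)
    cfg = RunConfig(**kwargs)
    log.info("validated config: %s", config_digest(cfg))
    return cfg


def config_digest(cfg: RunConfig) -> str:
    """Hash of the scientific configuration (output location excluded)."""
    d = dataclasses.asdict(cfg)
    d.pop("out_dir", None)
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.9g")


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute all stages over the condition x timepoint x replicate grid.

    Returns the manifest (also written as ``manifest.json``).  Stage
    failures abort with the failing condition/timepoint named.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cal = cfg.calibration
    linking = cfg.linking_params()
    grid = study_grid(cfg.seed, conditions=dict(cfg.conditions),
                      timepoints_h=cfg.timepoints_h,
                      replicates=cfg.replicates, base=cfg.simulation)

    all_particles, all_tracks, all_metrics = [], [], []
    for cond, tp, rep, sim_cfg in grid:
        stage = f"{cond}/t{tp:g}h/rep{rep}"
        try:
            movie = simulate_movie(sim_cfg)
            seg = segment_stack(movie.probability_maps, cfg.segmentation)
            spots = detect_spots(seg.particles)
            tracks = link_spots(spots, linking)
            met = metrics_table(tracks, cal)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failed at {stage}: {exc}") from exc
        for df in (seg.particles, met):
            df.insert(0, "replicate", rep)
            df.insert(0, "timepoint_h", tp)
            df.insert(0, "condition", cond)
        tt = track_table(tracks)
        tt.insert(0, "replicate", rep)
        tt.insert(0, "timepoint_h", tp)
        tt.insert(0, "condition", cond)
        all_particles.append(seg.particles)
        all_tracks.append(tt)
        all_metrics.append(met)
        log.info("%s: %d retained particles, %d tracks", stage,
                 int(seg.particles["retained"].sum()), len(tracks))

    particles = pd.concat(all_particles, ignore_index=True)
    tracks_df = pd.concat(all_tracks, ignore_index=True)
    metrics = pd.concat(all_metrics, ignore_index=True)

    # ROUT trimming, per metric distribution per condition x timepoint
    trimmed_parts, outlier_rows = [], []
    if len(metrics):
        for (cond, tp), grp in metrics.groupby(["condition", "timepoint_h"]):
            res = rout_trim(grp[cfg.trim_metric].to_numpy(), q=cfg.rout_q)
            keep_mask = np.ones(len(grp), dtype=bool)
            keep_mask[res.outlier_indices] = False
            trimmed_parts.append(grp.iloc[keep_mask.nonzero()[0]])
            for v in res.outliers:
                outlier_rows.append({"condition": cond, "timepoint_h": tp,
                                     "metric": cfg.trim_metric, "value": v,
                                     "robust_center": res.robust_center,
                                     "rsdr": res.rsdr, "q": res.q})
    trimmed = (pd.concat(trimmed_parts, ignore_index=True)
               if trimmed_parts else metrics.iloc[0:0])
    outliers = pd.DataFrame(outlier_rows, columns=[
        "condition", "timepoint_h", "metric", "value",
        "robust_center", "rsdr", "q"])

    # per-timepoint Kruskal-Wallis across conditions on the trimmed metric
    comparisons = []
    for tp in cfg.timepoints_h:
        sub = trimmed[trimmed["timepoint_h"] == tp]
        groups = [g[cfg.trim_metric].dropna().to_numpy()
                  for _, g in sub.groupby("condition", sort=True)]
        labels = sorted(sub["condition"].unique())
        if len(groups) >= 2 and all(len(g) for g in groups) and \
                sum(len(g) for g in groups) >= 3:
            r = kruskal_wallis(*groups, labels=labels)
            comparisons.append({"timepoint_h": tp, "test": r.test_name,
                                "statistic": r.statistic, "p_value": r.p_value,
                                "df": r.df, "n": sum(r.group_sizes)})
        else:
            comparisons.append({"timepoint_h": tp, "test": "kruskal_wallis",
                                "statistic": float("nan"),
                                "p_value": float("nan"), "df": float("nan"),
                                "n": int(sum(len(g) for g in groups))})
    comparisons_df = pd.DataFrame(comparisons)
    summary = condition_summary(trimmed) if len(trimmed) else pd.DataFrame(
        columns=["condition", "timepoint_h", "metric", "n",
                 "mean", "median", "q1", "q3"])

    files = {"particles.csv": particles, "tracks.csv": tracks_df,
             "metrics.csv": metrics, "metrics_trimmed.csv": trimmed,
             "outliers.csv": outliers, "comparisons.csv": comparisons_df,
             "summary.csv": summary}
    checksums = {}
    for name, df in files.items():
        _write_csv(df, out / name)
        checksums[name] = _sha256(out / name)

    manifest: dict[str, Any] = {
        "package": "trichotrack",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": config_digest(cfg),
        "grid": [{"condition": c, "timepoint_h": tp, "replicate": r}
                 for c, tp, r, _ in grid],
        "row_counts": {name: int(len(df)) for name, df in files.items()},
        "n_tracks": int(metrics["track_id"].count()) if len(metrics) else 0,
        "empty_result": bool(len(metrics) == 0),
        "outputs": checksums,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
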