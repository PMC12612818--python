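"""Per-track motility statistics in pixel/frame and calibrated units.

The eight reported metrics, with positions p_1..p_N at frames f_1..f_N and
steps d_i = ||p_{i+1} - p_i||:

    duration                 = f_N - f_1                       [frames]
    total distance           = sum d_i                         [px]
    max distance             = max_i ||p_i - p_1||             [px]
    mean speed               = total / duration                [px/frame]
    confinement ratio        = net / total                     (net = ||p_N - p_1||)
    mean straight-line speed = net / duration                  [px/frame]
    linearity of forward
      progression            = straight-line speed / mean speed
    mean directional change  = mean |angle between successive
      rate                     displacements| / frame interval [rad/s]

Physical units: speed[um/s] = speed[px/frame] * pixel_size_um / frame_interval_s.
Confinement and linearity are identical algebraically; both are reported
because both appear in the standard tracker output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .config import Calibration
from .tracking import Track


class UndefinedMetricsError(ValueError):
    """Track too short to carry motility metrics (fewer than 2 spots)."""


@dataclass(frozen=True)
class TrackMetricSet:
    track_id: int
    n_spots: int
    duration_frames: int
    total_distance_px: float
    max_distance_px: float
    net_distance_px: float
    mean_speed_px_frame: float
    straight_line_speed_px_frame: float
    confinement_ratio: float            # NaN for zero-total-distance tracks
    linearity_forward_progression: float
    mean_directional_change_rad_frame: float  # NaN when no measurable turn
    # calibrated
    duration_s: float
    total_distance_um: float
    max_distance_um: float
    mean_speed_um_s: float
    straight_line_speed_um_s: float
    mean_directional_change_rad_s: float


def compute_metrics(track: Track, cal: Calibration) -> TrackMetricSet:
    """All eight metrics for one track; raises on tracks with < 2 spots.

    Zero-total-distance tracks get NaN confinement/linearity (0/0 is
    undefined and such tracks are excluded from group summaries).  Turning
    angles skip zero-length steps; a track with no pair of consecutive
    non-zero steps gets NaN directional change rate.
    """
    pos = track.positions
    frm = track.frames
    if len(pos) < 2:
        raise UndefinedMetricsError(
            f"track {track.track_id} has {len(pos)} spot(s); metrics undefined")
    steps = np.diff(pos, axis=0)
    d = np.linalg.norm(steps, axis=1)
    duration = int(frm[-1] - frm[0])
    total = float(d.sum())
    net = float(np.linalg.norm(pos[-1] - pos[0]))
    max_dist = float(np.linalg.norm(pos - pos[0], axis=1).max())
    mean_speed = total / duration
    sl_speed = net / duration
    if total > 0:
        confinement = net / total
        linearity = sl_speed / mean_speed
    else:
        confinement = math.nan
        linearity = math.nan

    nz = d > 0
    angles = []
    prev = None
    for i in range(len(steps)):
        if not nz[i]:
            continue
        if prev is not None:
            cross = prev[0] * steps[i][1] - prev[1] * steps[i][0]
            dot = prev[0] * steps[i][0] + prev[1] * steps[i][1]
            angles.append(abs(math.atan2(cross, dot)))
        prev = steps[i]
    mdc_frame = float(np.mean(angles)) if angles else math.nan

    px, dt = cal.pixel_size_um, cal.frame_interval_s
    return TrackMetricSet(
        track_id=track.track_id,
        n_spots=len(pos),
        duration_frames=duration,
        total_distance_px=total,
        max_distance_px=max_dist,
        net_distance_px=net,
        mean_speed_px_frame=mean_speed,
        straight_line_speed_px_frame=sl_speed,
        confinement_ratio=confinement,
        linearity_forward_progression=linearity,
        mean_directional_change_rad_frame=mdc_frame,
        duration_s=duration * dt,
        total_distance_um=total * px,
        max_distance_um=max_dist * px,
        mean_speed_um_s=mean_speed * px / dt,
        straight_line_speed_um_s=sl_speed * px / dt,
        mean_directional_change_rad_s=mdc_frame / dt,
    )


def metrics_table(tracks: list[Track], cal: Calibration) -> pd.DataFrame:
    """One row of metrics per track (tracks with < 2 spots are rejected)."""
    rows = [compute_metrics(t, cal) for t in tracks]
    cols = [f.name for f in fields(TrackMetricSet)]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in rows], columns=cols)


SUMMARY_METRICS = (
    "mean_speed_um_s", "total_distance_um", "max_distance_um",
    "duration_frames", "confinement_ratio", "linearity_forward_progression",
    "straight_line_speed_um_s", "mean_directional_change_rad_s",
)


def condition_summary(metrics: pd.DataFrame,
                      group_cols: tuple[str, ...] = ("condition", "timepoint_h"),
                      value_cols: tuple[str, ...] = SUMMARY_METRICS) -> pd.DataFrame:
    """Per-group n / median / mean / quartiles for each metric.

    NaN metric values (undefined confinement on stationary tracks, etc.)
    are excluded per metric.  Groups present in the grouping columns but
    empty for a metric are flagged with n = 0 rather than dropped.
    """
    rows = []
    for keys, grp in metrics.groupby(list(group_cols), sort=True, dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for col in value_cols:
            vals = grp[col].dropna().to_numpy() if col in grp else np.array([])
            row = dict(zip(group_cols, keys))
            row["metric"] = col
            row["n"] = len(vals)
            if len(vals):
                row["mean"] = float(np.mean(vals))
                row["median"] = float(np.median(vals))
                row["q1"] = float(np.percentile(vals, 25))
                row["q3"] = float(np.percentile(vals, 75))
            else:
                row.update(mean=math.nan, median=math.nan, q1=math.nan, q3=math.nan)
            rows.append(row)
    return pd.DataFrame(rows)
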