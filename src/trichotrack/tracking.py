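"""Frame-to-frame spot linking: deterministic greedy nearest-neighbour.

Stands in for a TrackMate-style tracker.  Within each consecutive frame
pair, candidate links inside the linking radius are taken in ascending
distance order (ties broken by lower current-frame label, then lower
next-frame label), each spot used at most once.  Unmatched spots seed new
tracks; optional gap closing lets a track end claim a spot up to
``max_gap_frames`` later within a radius scaled by the frame gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigError, LinkingParams


@dataclass(frozen=True)
class Spot:
    frame: int
    x_px: float
    y_px: float
    source_label: int = 0


@dataclass
class Track:
    track_id: int
    spots: list[Spot] = field(default_factory=list)

    @property
    def frames(self) -> np.ndarray:
        return np.array([s.frame for s in self.spots], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        return np.array([(s.x_px, s.y_px) for s in self.spots], dtype=float)


def detect_spots(particles: pd.DataFrame) -> list[Spot]:
    """Default detection path: retained-particle centroids become spots."""
    kept = particles[particles["retained"]] if "retained" in particles else particles
    return [Spot(frame=int(r.frame), x_px=float(r.x_px), y_px=float(r.y_px),
                 source_label=int(r.label))
            for r in kept.itertuples(index=False)]


def detect_spots_from_blurred(blurred: np.ndarray, floor: float = 0.05,
                              min_separation_px: int = 2) -> list[Spot]:
    """Alternate path: per-frame local maxima of the 3-D blurred stack."""
    from skimage.feature import peak_local_max

    spots: list[Spot] = []
    for t in range(blurred.shape[0]):
        peaks = peak_local_max(blurred[t], min_distance=min_separation_px,
                               threshold_abs=floor, exclude_border=False)
        for i, (y, x) in enumerate(peaks):
            spots.append(Spot(frame=t, x_px=float(x), y_px=float(y), source_label=i))
    return spots


def _greedy_pairs(ends: list[tuple[int, float, float]],
                  nxt: list[tuple[int, float, float]],
                  radius: float) -> list[tuple[int, int]]:
    """Greedy ascending-distance assignment between two labelled point sets.

    Each side is a list of (label, x, y).  Ties broken by (distance,
    current label, next label).  Returns matched (end_label, next_label).
    """
    cand = []
    for la, xa, ya in ends:
        for lb, xb, yb in nxt:
            d = math.hypot(xa - xb, ya - yb)
            if d <= radius:
                cand.append((d, la, lb))
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for d, la, lb in cand:
        if la in used_a or lb in used_b:
            continue
        used_a.add(la)
        used_b.add(lb)
        pairs.append((la, lb))
    return pairs


def link_spots(spots: list[Spot],
               params: LinkingParams = LinkingParams()) -> list[Track]:
    """Link spots into tracks with greedy nearest-neighbour assignment.

    Tracks shorter than ``params.min_track_spots`` are discarded at the end.
    """
    if params.max_link_dist_px <= 0:
        raise ConfigError("max_link_dist_px must be > 0")
    by_frame: dict[int, list[Spot]] = {}
    for s in spots:
        by_frame.setdefault(int(s.frame), []).append(s)
    if not by_frame:
        return []

    tracks: list[list[Spot]] = []
    open_tracks: list[int] = []  # indices into tracks with a live end

    frames = range(min(by_frame), max(by_frame) + 1)
    for f in frames:
        frame_spots = by_frame.get(f, [])
        unmatched = dict(enumerate(frame_spots))
        # gap = 0 first, then increasing gaps up to max_gap_frames
        for gap in range(params.max_gap_frames + 1):
            if not unmatched:
                break
            end_frame = f - 1 - gap
            radius = params.max_link_dist_px * (gap + 1)
            ends = [(ti, tracks[ti][-1].x_px, tracks[ti][-1].y_px)
                    for ti in open_tracks if tracks[ti][-1].frame == end_frame]
            nxt = [(j, s.x_px, s.y_px) for j, s in unmatched.items()]
            for ti, j in _greedy_pairs(ends, nxt, radius):
                tracks[ti].append(unmatched.pop(j))
        for j in sorted(unmatched):
            tracks.append([unmatched[j]])
        # prune ends too old to ever link again
        open_tracks = [ti for ti in range(len(tracks))
                       if tracks[ti][-1].frame >= f - params.max_gap_frames]

    out = []
    tid = 0
    for spots_list in tracks:
        if len(spots_list) >= params.min_track_spots:
            out.append(Track(track_id=tid, spots=spots_list))
            tid += 1
    return out


def track_table(tracks: list[Track]) -> pd.DataFrame:
    """Long-format table (track_id, frame, x_px, y_px); CSV round-trip safe."""
    rows = [(t.track_id, s.frame, s.x_px, s.y_px)
            for t in tracks for s in t.spots]
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px"])


def tracks_from_table(table: pd.DataFrame) -> list[Track]:
    """Inverse of :func:`track_table`."""
    out = []
    for tid, grp in table.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        spots = [Spot(frame=int(r.frame), x_px=float(r.x_px), y_px=float(r.y_px))
                 for r in grp.itertuples(index=False)]
        out.append(Track(track_id=int(tid), spots=spots))
    return out


def write_tracks_csv(tracks: list[Track], path: str | Path) -> None:
    track_table(tracks).to_csv(path, index=False, float_format="%.6f")


def read_tracks_csv(path: str | Path) -> list[Track]:
    return tracks_from_table(pd.read_csv(path))
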