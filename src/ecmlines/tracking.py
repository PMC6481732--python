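"""Nuclear detection, track linking, and migration metrics.

Nuclei are detected per frame as thresholded connected components with
intensity-weighted (sub-pixel) centroids, then linked frame-to-frame by a
globally optimal assignment that minimizes total squared displacement with
a hard per-step displacement gate. From each track:

- speed = total tracked path length / total tracking duration (µm/h)
- persistence = net displacement / total path length, in [0, 1]

Tracks of cells that divided or barely moved are excluded before analysis
(the exclusion rules can be switched off wholesale, as is appropriate for
perturbation experiments where poorly migrating cells are the phenotype).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Track",
    "FilterRules",
    "detect_nuclei",
    "link_tracks",
    "track_metrics",
    "filter_tracks",
    "tracks_df",
]


@dataclass
class Track:
    """Time-ordered nucleus centroids (t in minutes, x/y in µm)."""

    id: int
    t_min: list[float] = dc_field(default_factory=list)
    x_um: list[float] = dc_field(default_factory=list)
    y_um: list[float] = dc_field(default_factory=list)
    divided: bool = False
    non_migratory: bool = False
    truncated: bool = False

    @property
    def n_frames(self) -> int:
        return len(self.t_min)

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x_um, self.y_um])


def detect_nuclei(
    frame: np.ndarray,
    threshold: float,
    min_area_px: int = 4,
    pixel_size_um: float = 1.0,
    smooth_sigma_px: float = 1.0,
) -> np.ndarray:
    """Detect nuclei in one frame; returns an (N, 2) array of (x, y) µm.

    The frame is Gaussian-smoothed before thresholding to suppress
    single-pixel noise; each accepted connected component contributes one
    intensity-weighted mean position (sub-pixel).
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel frame")
    smoothed = ndimage.gaussian_filter(img, smooth_sigma_px) if smooth_sigma_px > 0 else img
    binary = smoothed > threshold
    labels, n = ndimage.label(binary)
    if n == 0:
        return np.zeros((0, 2))
    areas = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= min_area_px) + 1
    if keep.size == 0:
        return np.zeros((0, 2))
    coms = ndimage.center_of_mass(img, labels, index=keep)  # (row, col) indices
    # pixel centers sit at (index + 0.5) · pixel_size
    pts = (np.array([(c, r) for r, c in coms], dtype=float) + 0.5) * pixel_size_um
    return pts


def link_tracks(
    detections: list[np.ndarray],
    max_disp_um: float = 30.0,
    frame_times_min: list[float] | None = None,
    division_radius_um: float | None = None,
) -> list[Track]:
    """Link per-frame detection lists into tracks.

    Frame-to-frame correspondence is the optimal bipartite assignment
    minimizing total squared displacement, with any pair farther than
    ``max_disp_um`` forbidden. Unmatched detections start new tracks;
    unmatched track ends terminate. A new track appearing within
    ``division_radius_um`` (default 20 µm, about two nucleus diameters) of
    a live track marks that track as divided (one-to-two proximity event).
    """
    if len(detections) < 2:
        raise ValueError("need at least 2 frames of detections")
    if frame_times_min is None:
        frame_times_min = list(range(len(detections)))
    if division_radius_um is None:
        division_radius_um = 20.0

    BIG = 1e12
    tracks: list[Track] = []
    live: dict[int, int] = {}  # detection index in current frame -> track list index

    def _start(fi: int, pt: np.ndarray) -> int:
        tr = Track(id=len(tracks))
        tr.t_min.append(float(frame_times_min[fi]))
        tr.x_um.append(float(pt[0]))
        tr.y_um.append(float(pt[1]))
        tracks.append(tr)
        return len(tracks) - 1

    for j, pt in enumerate(np.asarray(detections[0], dtype=float)):
        live[j] = _start(0, pt)

    for fi in range(1, len(detections)):
        prev_pts = np.asarray(detections[fi - 1], dtype=float)
        cur_pts = np.asarray(detections[fi], dtype=float)
        new_live: dict[int, int] = {}
        matched_cur: set[int] = set()
        if len(live) and len(cur_pts):
            prev_idx = sorted(live.keys())
            P = prev_pts[prev_idx]
            d2 = ((P[:, None, :] - cur_pts[None, :, :]) ** 2).sum(axis=2)
            cost = np.where(d2 <= max_disp_um**2, d2, BIG)
            ri, ci = linear_sum_assignment(cost)
            for r, c in zip(ri, ci):
                if cost[r, c] >= BIG:
                    continue
                ti = live[prev_idx[r]]
                tracks[ti].t_min.append(float(frame_times_min[fi]))
                tracks[ti].x_um.append(float(cur_pts[c, 0]))
                tracks[ti].y_um.append(float(cur_pts[c, 1]))
                new_live[c] = ti
                matched_cur.add(c)
        # unmatched detections: new tracks, with division flagging
        for c in range(len(cur_pts)):
            if c in matched_cur:
                continue
            pt = cur_pts[c]
            for c2, ti in new_live.items():
                d = np.hypot(pt[0] - cur_pts[c2, 0], pt[1] - cur_pts[c2, 1])
                if d <= division_radius_um:
                    tracks[ti].divided = True
                    break
            new_live[c] = _start(fi, pt)
        # unmatched previous tracks that started before the last frame end truncated
        for j, ti in live.items():
            if ti not in new_live.values():
                tracks[ti].truncated = True
        live = new_live
    return tracks


def track_metrics(track: Track) -> tuple[float, float | None]:
    """Speed (µm/h) and persistence of one track.

    Speed is the summed step length over the tracked duration; persistence
    is the start-to-end distance divided by the summed step length (null
    for a zero-length path). Raises for tracks shorter than 2 frames.
    """
    if track.n_frames < 2:
        raise ValueError("track needs at least 2 frames")
    pos = track.positions()
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    path = float(steps.sum())
    duration_h = (track.t_min[-1] - track.t_min[0]) / 60.0
    if duration_h <= 0:
        raise ValueError("track duration must be positive")
    speed = path / duration_h
    if path == 0.0:
        return speed, None
    persistence = float(np.linalg.norm(pos[-1] - pos[0]) / path)
    if persistence > 1.0 - 1e-12:
        persistence = 1.0  # collinear same-direction steps up to float rounding
    return speed, persistence


@dataclass(frozen=True)
class FilterRules:
    """Track exclusion rules.

    ``min_duration_fraction`` — minimum tracked fraction of the session;
    ``non_migratory_path_um`` — minimum total path length (default two
    nucleus diameters, 20 µm); ``exclude_divided`` — drop tracks flagged as
    division events. Set all off (`FilterRules.disabled()`) to analyze every
    track, as in perturbation studies.
    """

    min_duration_fraction: float = 0.9
    non_migratory_path_um: float = 20.0
    exclude_divided: bool = True

    @staticmethod
    def disabled() -> "FilterRules":
        return FilterRules(0.0, 0.0, False)


def filter_tracks(
    tracks: list[Track],
    rules: FilterRules = FilterRules(),
    session_duration_min: float | None = None,
) -> list[Track]:
    """Apply the exclusion rules; returns the retained tracks.

    With all rules disabled the input is returned unchanged.
    """
    if (
        rules.min_duration_fraction <= 0
        and rules.non_migratory_path_um <= 0
        and not rules.exclude_divided
    ):
        return list(tracks)
    if session_duration_min is None:
        session_duration_min = max(
            (t.t_min[-1] - t.t_min[0]) for t in tracks if t.n_frames >= 2
        )
    kept = []
    for t in tracks:
        if t.n_frames < 2:
            continue
        if rules.exclude_divided and t.divided:
            continue
        dur = t.t_min[-1] - t.t_min[0]
        if session_duration_min > 0 and dur < rules.min_duration_fraction * session_duration_min:
            continue
        path = float(np.linalg.norm(np.diff(t.positions(), axis=0), axis=1).sum())
        if path < rules.non_migratory_path_um:
            t.non_migratory = True
            continue
        kept.append(t)
    return kept


def tracks_df(tracks: list[Track]) -> pd.DataFrame:
    """Long-format track table (one row per track point)."""
    rows = []
    for t in tracks:
        for i in range(t.n_frames):
            rows.append(
                {
                    "track_id": t.id,
                    "t_min": t.t_min[i],
                    "x_um": t.x_um[i],
                    "y_um": t.y_um[i],
                    "divided": t.divided,
                    "truncated": t.truncated,
                }
            )
    return pd.DataFrame(rows)
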