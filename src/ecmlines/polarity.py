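"""Cell polarity readouts: MTOC orientation and position, active-protrusion
detection, kymographs, and FRET ratio images.

MTOC orientation is the axis-folded angle ([0, 90]°) between the
nucleus→MTOC vector and the pattern axis; a cell is scored "aligned" when
that angle is ≤ 45°. MTOC position (front / middle / back) projects the
MTOC onto the leading-edge axis through the nucleus centroid and compares
it against the nucleus extent along that axis; the leading-edge direction
comes from annotation or synthetic ground truth, never inference.

Protrusions are detected as localized outward boundary gain of a cell mask
across frames, accumulated into angular bins about the centroid — an
algorithmic stand-in for identifying ruffling edges by eye.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .morphometrics import relative_orientation

__all__ = [
    "MtocRecord",
    "ProtrusionRecord",
    "Kymograph",
    "mtoc_orientation",
    "mtoc_position_class",
    "detect_protrusions",
    "kymograph",
    "fret_ratio",
]


@dataclass(frozen=True)
class MtocRecord:
    cell_label: int
    orientation_deg: float  # [0, 90]
    aligned: bool  # orientation <= 45
    position_class: str | None = None  # 'front' | 'middle' | 'back'


@dataclass(frozen=True)
class ProtrusionRecord:
    cell_label: int
    angle_deg: float  # (−180, 180], relative to the pattern axis
    activity: float  # summed boundary gain (px)
    span_deg: float  # angular arc covered


@dataclass(frozen=True)
class Kymograph:
    data: np.ndarray  # (samples along segment, n frames)
    endpoints_px: tuple[tuple[float, float], tuple[float, float]]
    pixel_size_um: float
    frame_interval_min: float


def mtoc_orientation(
    mtoc_xy: tuple[float, float],
    nucleus_centroid_xy: tuple[float, float],
    pattern_axis_deg: float = 0.0,
    cell_label: int = 0,
) -> MtocRecord:
    """Axis-folded MTOC orientation and alignment flag."""
    dx = mtoc_xy[0] - nucleus_centroid_xy[0]
    dy = mtoc_xy[1] - nucleus_centroid_xy[1]
    if dx == 0.0 and dy == 0.0:
        raise ValueError("MTOC coincides with nucleus centroid")
    ang = math.degrees(math.atan2(dy, dx))
    rel = relative_orientation(ang, pattern_axis_deg)
    return MtocRecord(cell_label, rel, rel <= 45.0)


def mtoc_position_class(
    mtoc_xy: tuple[float, float],
    nucleus_points_xy: np.ndarray,
    leading_edge_deg: float | None,
) -> str:
    """Classify the MTOC as front / middle / back of the nucleus.

    ``nucleus_points_xy`` is an (N, 2) array of nucleus pixel/vertex
    coordinates; ``leading_edge_deg`` is the direction toward the leading
    edge. The MTOC and nucleus are projected onto that axis through the
    nucleus centroid: beyond the nucleus front boundary → front, behind the
    rear boundary → back, else middle.
    """
    if leading_edge_deg is None:
        raise ValueError("leading-edge direction is required")
    pts = np.asarray(nucleus_points_xy, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("nucleus_points_xy must be a non-empty (N, 2) array")
    c = pts.mean(axis=0)
    u = np.array(
        [math.cos(math.radians(leading_edge_deg)), math.sin(math.radians(leading_edge_deg))]
    )
    proj = (pts - c) @ u
    front, back = proj.max(), proj.min()
    s = (np.asarray(mtoc_xy, dtype=float) - c) @ u
    if s > front:
        return "front"
    if s < back:
        return "back"
    return "middle"


def detect_protrusions(
    mask_stack: np.ndarray,
    centroid_xy: tuple[float, float] | None = None,
    pattern_axis_deg: float = 0.0,
    bins: int = 36,
    min_frames: int = 3,
    min_gain_px: float = 20.0,
    cell_label: int = 0,
) -> list[ProtrusionRecord]:
    """Detect active protrusions from a single-cell mask time series.

    For each consecutive frame pair, pixels gained by the mask that touch
    the previous boundary are binned by angle about the cell centroid. A
    protrusion is a maximal contiguous (wrapping) run of bins that are
    active (positive gain) in at least ``min_frames`` frame pairs, with
    total summed gain ≥ ``min_gain_px``. The reported angle is the
    gain-weighted circular mean of the run, relative to the pattern axis.
    """
    stack = np.asarray(mask_stack).astype(bool)
    if stack.ndim != 3 or stack.shape[0] < 3:
        raise ValueError("need a (T, H, W) mask stack with at least 3 frames")
    if not stack.any():
        raise ValueError("empty mask stack")
    if centroid_xy is None:
        r, c = ndimage.center_of_mass(stack[0])
        centroid_xy = (c, r)
    cx, cy = centroid_xy

    gain_per_bin = np.zeros(bins)
    frames_per_bin = np.zeros(bins, dtype=int)
    vec_x = np.zeros(bins)
    vec_y = np.zeros(bins)
    bin_width = 360.0 / bins
    for t in range(stack.shape[0] - 1):
        prev, cur = stack[t], stack[t + 1]
        boundary = prev & ~ndimage.binary_erosion(prev)
        near_boundary = ndimage.binary_dilation(boundary, iterations=2)
        gained = cur & ~prev & near_boundary
        rr, cc = np.nonzero(gained)
        if rr.size == 0:
            continue
        ang = np.degrees(np.arctan2(rr - cy, cc - cx))
        idx = np.floor(((ang + 180.0) % 360.0) / bin_width).astype(int) % bins
        counts = np.bincount(idx, minlength=bins).astype(float)
        gain_per_bin += counts
        frames_per_bin += counts > 0
        rad = np.radians(ang)
        np.add.at(vec_x, idx, np.cos(rad))
        np.add.at(vec_y, idx, np.sin(rad))

    active = (frames_per_bin >= min_frames) & (gain_per_bin > 0)
    if not active.any():
        return []
    # maximal wrapping runs of contiguous active bins
    runs = _wrapping_runs(active)
    out = []
    for run in runs:
        total = gain_per_bin[run].sum()
        if total < min_gain_px:
            continue
        mean_ang = math.degrees(math.atan2(vec_y[run].sum(), vec_x[run].sum()))
        rel = (mean_ang - pattern_axis_deg + 180.0) % 360.0 - 180.0
        if rel == -180.0:
            rel = 180.0
        out.append(
            ProtrusionRecord(
                cell_label=cell_label,
                angle_deg=rel,
                activity=float(total),
                span_deg=len(run) * bin_width,
            )
        )
    return out


def _wrapping_runs(active: np.ndarray) -> list[list[int]]:
    n = active.size
    if active.all():
        return [list(range(n))]
    runs, cur = [], []
    for i in range(n):
        if active[i]:
            cur.append(i)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    # merge a run ending at n−1 with one starting at 0 (wrap)
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == n - 1:
        runs[0] = runs.pop() + runs[0]
    return runs


def kymograph(
    stack: np.ndarray,
    p0_px: tuple[float, float],
    p1_px: tuple[float, float],
    width_px: int = 1,
    pixel_size_um: float = 1.0,
    frame_interval_min: float = 10.0,
) -> Kymograph:
    """Space–time intensity matrix along a fixed segment of a time-lapse.

    Column f is the intensity profile along the segment (p0→p1, (x, y)
    pixel coordinates) at frame f, averaged over ``width_px`` parallel
    lines offset perpendicular to the segment.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("need a (T, H, W) stack")
    T, H, W = stack.shape
    x0, y0 = p0_px
    x1, y1 = p1_px
    for x, y in ((x0, y0), (x1, y1)):
        if not (0 <= x <= W - 1 and 0 <= y <= H - 1):
            raise ValueError("segment endpoint outside image")
    length = math.hypot(x1 - x0, y1 - y0)
    n_samples = max(2, int(round(length)) + 1)
    s = np.linspace(0.0, 1.0, n_samples)
    xs = x0 + s * (x1 - x0)
    ys = y0 + s * (y1 - y0)
    # unit normal for width averaging
    if length > 0:
        nx, ny = -(y1 - y0) / length, (x1 - x0) / length
    else:
        nx, ny = 0.0, 0.0
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    data = np.zeros((n_samples, T))
    for f in range(T):
        prof = np.zeros(n_samples)
        for off in offsets:
            coords = np.vstack([ys + off * ny, xs + off * nx])  # (row, col)
            prof += ndimage.map_coordinates(stack[f], coords, order=1, mode="nearest")
        data[:, f] = prof / len(offsets)
    return Kymograph(
        data=data,
        endpoints_px=((x0, y0), (x1, y1)),
        pixel_size_um=pixel_size_um,
        frame_interval_min=frame_interval_min,
    )


def fret_ratio(
    donor: np.ndarray,
    acceptor: np.ndarray,
    background: float | tuple[float, float] = 0.0,
    mask_threshold: float = 0.0,
    median_size: int = 3,
) -> np.ndarray:
    """Pixel-by-pixel acceptor/donor FRET ratio image.

    Both channels are background subtracted; a binary mask is taken by
    thresholding the background-subtracted acceptor channel; the ratio is
    computed inside the mask (NaN outside) and smoothed with a median
    filter (3×3 by default) computed over in-mask neighbours to remove hot
    pixels. Pixels whose donor signal is non-positive after subtraction
    are set to NaN and counted in a warning.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if donor.shape != acceptor.shape:
        raise ValueError("donor and acceptor must have the same shape")
    if np.isscalar(background):
        bg_d = bg_a = float(background)
    else:
        bg_d, bg_a = (float(background[0]), float(background[1]))
    d = donor - bg_d
    a = acceptor - bg_a
    mask = a > mask_threshold
    ratio = np.full(donor.shape, np.nan, dtype=np.float32)
    bad = mask & (d <= 0)
    good = mask & (d > 0)
    ratio[good] = (a[good] / d[good]).astype(np.float32)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} masked pixels had non-positive donor signal")
    # in-mask median filter: NaNs outside the mask are ignored per window
    pad = median_size // 2
    padded = np.pad(ratio, pad, constant_values=np.nan)
    windows = np.lib.stride_tricks.sliding_window_view(padded, (median_size, median_size))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        med = np.nanmedian(windows, axis=(-2, -1))
    out = np.where(mask, med, np.nan).astype(np.float32)
    out[~good & mask & bad] = np.nan
    return out
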