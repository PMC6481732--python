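"""Cell segmentation and per-cell shape features.

Cells are segmented from the cytosol (phalloidin) channel by background
filtering, thresholding and connected-component labelling, then quantified
with moment-based shape descriptors: area, ellipse-equivalent aspect ratio
and axial orientation. Orientation is reported relative to the pattern
axis as an angle folded into [0, 90]° — 0° means the cell's long axis runs
along the printed lines.

Angle convention: degrees from the +x (column) axis toward +y (row), i.e.
measured in the image frame; axial values in (−90, 90].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import filters, measure, morphology

__all__ = [
    "CellRecord",
    "segment_cells",
    "measure_cells",
    "measure_cells_df",
    "relative_orientation",
    "orientation_from_regionprops",
]


@dataclass(frozen=True)
class CellRecord:
    """Per-cell morphometrics."""

    label: int
    area_um2: float
    centroid_xy_um: tuple[float, float]
    aspect_ratio: float
    orientation_deg: float  # axial, (−90, 90], image frame
    relative_orientation_deg: float | None  # [0, 90] vs pattern axis
    outline_xy_um: np.ndarray  # closed polygon, (N, 2)
    degenerate: bool = False


def segment_cells(
    image: np.ndarray,
    threshold: float | None = None,
    min_area_um2: float = 50.0,
    pixel_size_um: float = 1.0,
    connectivity: int = 2,
    background_filter: str | None = "gaussian",
    filter_sigma_um: float = 25.0,
) -> np.ndarray:
    """Label cells in a single-channel image.

    A large-scale background estimate (Gaussian high-pass or rolling-ball)
    is removed first, then the image is thresholded — at ``threshold`` if
    given (the fixed-manual-threshold workflow), else by Otsu's method —
    and 8-connected components smaller than ``min_area_um2`` are dropped.
    Labels are dense from 1.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if background_filter == "gaussian":
        img = img - filters.gaussian(img, sigma=filter_sigma_um / pixel_size_um)
    elif background_filter == "rolling_ball":
        from skimage import restoration

        img = img - restoration.rolling_ball(img, radius=filter_sigma_um / pixel_size_um)
    elif background_filter is not None:
        raise ValueError(f"unknown background_filter {background_filter!r}")
    if threshold is None:
        thr = filters.threshold_otsu(img)
    else:
        thr = float(threshold)
        if not (np.min(img) <= thr <= np.max(img)):
            raise ValueError("threshold outside image intensity range")
    binary = img > thr
    min_px = max(1, int(round(min_area_um2 / pixel_size_um**2)))
    binary = morphology.remove_small_objects(binary, max_size=min_px - 1, connectivity=connectivity)
    labels = measure.label(binary, connectivity=connectivity)
    return labels


def orientation_from_regionprops(orientation_rad: float) -> float:
    """Convert a regionprops orientation to degrees from the +x axis.

    ``regionprops`` reports the angle between the row axis and the major
    axis; this maps it to the package convention (from +x toward +y,
    axial in (−90, 90]).
    """
    deg = 90.0 - math.degrees(orientation_rad)
    return fold_axial(deg)


def fold_axial(angle_deg: float) -> float:
    """Fold any angle into the axial range (−90, 90]."""
    a = (angle_deg + 90.0) % 180.0 - 90.0
    if a == -90.0:
        a = 90.0
    return a


def measure_cells(
    labels: np.ndarray,
    pixel_size_um: float = 1.0,
    pattern_axis_deg: float | None = 0.0,
) -> list[CellRecord]:
    """Moment-based shape features for every labelled cell.

    Area is the pixel count scaled by the pixel area; orientation is the
    principal-axis angle of the second central moments; aspect ratio is the
    ratio of ellipse-equivalent major to minor axis lengths. A degenerate
    region (single pixel or collinear pixels) gets its minor axis floored
    at one pixel and is flagged.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    records = []
    for rp in measure.regionprops(np.asarray(labels)):
        major = rp.axis_major_length
        minor = rp.axis_minor_length
        degenerate = minor < 1.0
        if degenerate:
            minor = 1.0
            major = max(major, 1.0)
        orient = orientation_from_regionprops(rp.orientation)
        rel = (
            relative_orientation(orient, pattern_axis_deg)
            if pattern_axis_deg is not None
            else None
        )
        cy, cx = rp.centroid
        contours = measure.find_contours(
            np.pad(rp.image.astype(float), 1), 0.5
        )
        outline = max(contours, key=len) if contours else np.zeros((0, 2))
        # contour is (row, col) in padded local frame -> global (x, y) µm
        r0, c0 = rp.bbox[0], rp.bbox[1]
        outline_xy = np.column_stack(
            [
                (outline[:, 1] - 1 + c0) * pixel_size_um,
                (outline[:, 0] - 1 + r0) * pixel_size_um,
            ]
        )
        records.append(
            CellRecord(
                label=int(rp.label),
                area_um2=float(rp.area) * pixel_size_um**2,
                centroid_xy_um=(cx * pixel_size_um, cy * pixel_size_um),
                aspect_ratio=float(major / minor),
                orientation_deg=orient,
                relative_orientation_deg=rel,
                outline_xy_um=outline_xy,
                degenerate=degenerate,
            )
        )
    return records


def measure_cells_df(
    labels: np.ndarray,
    pixel_size_um: float = 1.0,
    pattern_axis_deg: float | None = 0.0,
) -> pd.DataFrame:
    """:func:`measure_cells` as a tidy table (one row per cell)."""
    recs = measure_cells(labels, pixel_size_um, pattern_axis_deg)
    return pd.DataFrame(
        {
            "label": [r.label for r in recs],
            "area_um2": [r.area_um2 for r in recs],
            "centroid_x_um": [r.centroid_xy_um[0] for r in recs],
            "centroid_y_um": [r.centroid_xy_um[1] for r in recs],
            "aspect_ratio": [r.aspect_ratio for r in recs],
            "orientation_deg": [r.orientation_deg for r in recs],
            "relative_orientation_deg": [r.relative_orientation_deg for r in recs],
            "degenerate": [r.degenerate for r in recs],
        }
    )


def relative_orientation(orientation_deg: float, pattern_axis_deg: float) -> float:
    """Axial angle between an orientation and the pattern axis, in [0, 90]°."""
    d = abs(orientation_deg - pattern_axis_deg) % 180.0
    return min(d, 180.0 - d)
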