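"""Randomized line-array pattern fields modeling fibrous ECM.

A pattern field is a rectangle seeded with ``density`` line elements. Each
line starts from an initiation point drawn uniformly over the field and is
extended bidirectionally, at an angle drawn uniformly within ``±dispersion``
of the pattern axis, until it meets the field boundary (a full chord).
Dispersion controls alignment (±5° = most aligned, ±90° = isotropic),
density the number of lines, and line width the printed feature size.

Coordinates are micrometres with the origin at the top-left corner of the
field, x to the right and y downward (image convention). Angles are degrees
from the +x axis; axial quantities are reported in (−90, 90].
"""

from __future__ import annotations

import csv
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, box

__all__ = [
    "LineElement",
    "PatternField",
    "RasterMask",
    "ArrayLayout",
    "STANDARD_DISPERSIONS_DEG",
    "STANDARD_DENSITIES",
    "STANDARD_MASK_WIDTHS_UM",
    "OPTICAL_REDUCTION_FACTOR",
    "generate_field",
    "clip_line_to_field",
    "rasterize_field",
    "coverage_fraction",
    "optical_reduction",
    "export_layout",
    "read_layout_svg",
    "field_seed",
]

#: Angular-dispersion half-widths of the printed screening array (degrees).
STANDARD_DISPERSIONS_DEG = (5.0, 15.0, 30.0, 45.0, 60.0, 90.0)
#: Line counts per field of the printed screening array.
STANDARD_DENSITIES = (50, 100, 200, 400, 800)
#: Chrome photomask line widths (µm) before stepper reduction.
STANDARD_MASK_WIDTHS_UM = (2.5, 3.5, 5.0, 10.0)
#: Optical reduction factor of the projection stepper (mask → substrate).
OPTICAL_REDUCTION_FACTOR = 5.0


@dataclass(frozen=True)
class LineElement:
    """One line of a pattern field.

    ``origin`` is the initiation point (µm), ``angle_deg`` the direction
    relative to the +x axis, ``width_um`` the stroke width, and
    ``endpoints`` the chord through the origin clipped to the field.
    """

    origin: tuple[float, float]
    angle_deg: float
    width_um: float
    endpoints: tuple[tuple[float, float], tuple[float, float]]

    @property
    def length_um(self) -> float:
        (x0, y0), (x1, y1) = self.endpoints
        return math.hypot(x1 - x0, y1 - y0)


@dataclass(frozen=True)
class PatternField:
    """A generated array of line elements plus the parameters that made it."""

    width_um: float
    height_um: float
    dispersion_deg: float
    density: int
    line_width_um: float
    seed: int
    pattern_axis_deg: float = 0.0
    lines: tuple[LineElement, ...] = dc_field(default=())

    def angles(self) -> np.ndarray:
        return np.array([ln.angle_deg for ln in self.lines], dtype=float)


@dataclass(frozen=True)
class RasterMask:
    """Binary raster of a field; pixel centers at ``(i+0.5, j+0.5)·pixel_size``."""

    pixels: np.ndarray  # 2-D bool, [row, col]
    pixel_size_um: float


@dataclass(frozen=True)
class ArrayLayout:
    """Grid of pattern fields on a regular pitch (a digital stamp layout)."""

    rows: int
    cols: int
    pitch_um: float
    fields: tuple[PatternField | None, ...]  # row-major; None = fiducial slot

    def __post_init__(self) -> None:
        if len(self.fields) != self.rows * self.cols:
            raise ValueError("fields length must equal rows*cols")

    @property
    def extent_um(self) -> tuple[float, float]:
        return (self.cols * self.pitch_um, self.rows * self.pitch_um)


def field_seed(root_seed: int, field_index: int) -> int:
    """Derive the per-field seed from a layout root seed.

    Splitting rule: ``SeedSequence([root_seed, field_index])`` hashed to one
    32-bit word, so any single field is reproducible in isolation.
    """
    return int(np.random.SeedSequence([int(root_seed), int(field_index)]).generate_state(1)[0])


def clip_line_to_field(
    origin: tuple[float, float],
    angle_deg: float,
    field_size: tuple[float, float],
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Maximal chord through ``origin`` at ``angle_deg`` inside the field rectangle.

    Returns the two endpoints ordered by (x, y) for determinism. Raises
    ``ValueError`` if the origin lies outside the field.
    """
    w, h = float(field_size[0]), float(field_size[1])
    if w <= 0 or h <= 0:
        raise ValueError("field size must be positive")
    x0, y0 = float(origin[0]), float(origin[1])
    if not (0.0 <= x0 <= w and 0.0 <= y0 <= h):
        raise ValueError(f"origin {origin} outside field {field_size}")
    theta = math.radians(angle_deg)
    dx, dy = math.cos(theta), math.sin(theta)
    # extend well past the diagonal in both directions, then intersect
    reach = 2.0 * math.hypot(w, h)
    probe = LineString(
        [(x0 - reach * dx, y0 - reach * dy), (x0 + reach * dx, y0 + reach * dy)]
    )
    chord = probe.intersection(box(0.0, 0.0, w, h))
    if chord.is_empty:  # origin on a corner tangent; degenerate zero-length chord
        return ((x0, y0), (x0, y0))
    coords = list(chord.coords)
    p0, p1 = (coords[0], coords[-1])
    if (p1[0], p1[1]) < (p0[0], p0[1]):
        p0, p1 = p1, p0
    return ((float(p0[0]), float(p0[1])), (float(p1[0]), float(p1[1])))


def generate_field(
    density: int,
    dispersion_deg: float,
    line_width_um: float,
    field_size: tuple[float, float] = (700.0, 700.0),
    seed: int = 0,
    pattern_axis_deg: float = 0.0,
) -> PatternField:
    """Generate a random line-array field.

    ``density`` initiation points are drawn i.i.d. uniform over the field;
    each line's angle is drawn uniform on ``pattern_axis ± dispersion`` and
    the line is clipped to the field bounds. Deterministic given ``seed``.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    if not (0.0 < dispersion_deg <= 90.0):
        raise ValueError("dispersion_deg must be in (0, 90]")
    if line_width_um <= 0:
        raise ValueError("line_width_um must be > 0")
    w, h = float(field_size[0]), float(field_size[1])
    if w <= 0 or h <= 0:
        raise ValueError("field size must be positive")

    rng = np.random.default_rng(seed)
    xs = rng.uniform(0.0, w, size=density)
    ys = rng.uniform(0.0, h, size=density)
    rel = rng.uniform(-dispersion_deg, dispersion_deg, size=density)
    lines = []
    for x, y, a in zip(xs, ys, rel):
        ang = pattern_axis_deg + float(a)
        ends = clip_line_to_field((float(x), float(y)), ang, (w, h))
        lines.append(
            LineElement(
                origin=(float(x), float(y)),
                angle_deg=float(a),  # stored relative to the pattern axis
                width_um=float(line_width_um),
                endpoints=ends,
            )
        )
    return PatternField(
        width_um=w,
        height_um=h,
        dispersion_deg=float(dispersion_deg),
        density=int(density),
        line_width_um=float(line_width_um),
        seed=int(seed),
        pattern_axis_deg=float(pattern_axis_deg),
        lines=tuple(lines),
    )


def rasterize_field(field: PatternField, pixel_size_um: float) -> RasterMask:
    """Rasterize a field: a pixel is set iff its center is within ``w/2`` of a line.

    Overlapping lines union (no stacking).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    px = float(pixel_size_um)
    n_rows = max(1, int(round(field.height_um / px)))
    n_cols = max(1, int(round(field.width_um / px)))
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    half = 0.5 * field.line_width_um
    for ln in field.lines:
        (x0, y0), (x1, y1) = ln.endpoints
        # bounding box in pixel indices, expanded by the half-width
        c0 = max(0, int((min(x0, x1) - half) / px) - 1)
        c1 = min(n_cols, int((max(x0, x1) + half) / px) + 2)
        r0 = max(0, int((min(y0, y1) - half) / px) - 1)
        r1 = min(n_rows, int((max(y0, y1) + half) / px) + 2)
        if c0 >= c1 or r0 >= r1:
            continue
        cols = (np.arange(c0, c1) + 0.5) * px
        rows = (np.arange(r0, r1) + 0.5) * px
        cx, cy = np.meshgrid(cols, rows)
        d2 = _point_segment_dist2(cx, cy, x0, y0, x1, y1)
        mask[r0:r1, c0:c1] |= d2 <= half * half
    return RasterMask(pixels=mask, pixel_size_um=px)


def _point_segment_dist2(px_x, px_y, x0, y0, x1, y1):
    vx, vy = x1 - x0, y1 - y0
    seg2 = vx * vx + vy * vy
    if seg2 == 0.0:
        return (px_x - x0) ** 2 + (px_y - y0) ** 2
    t = np.clip(((px_x - x0) * vx + (px_y - y0) * vy) / seg2, 0.0, 1.0)
    qx = x0 + t * vx
    qy = y0 + t * vy
    return (px_x - qx) ** 2 + (px_y - qy) ** 2


def coverage_fraction(
    mask: RasterMask, saturation_threshold: float = 0.99
) -> tuple[float, bool]:
    """Fraction of set pixels, plus a flag for effectively uniform coverage.

    Fields whose summed line area exceeds the field area print as a uniform
    protein region; the ``saturated`` flag marks that regime.
    """
    if mask.pixels.size == 0:
        raise ValueError("empty mask grid")
    frac = float(np.count_nonzero(mask.pixels)) / mask.pixels.size
    return frac, frac >= saturation_threshold


def optical_reduction(
    mask_widths_um: Sequence[float], factor: float = OPTICAL_REDUCTION_FACTOR
) -> np.ndarray:
    """Substrate feature widths produced from photomask widths by projection.

    The stepper demagnifies mask features by ``factor`` (5× by default), so
    e.g. a 2.5 µm chrome line prints as a 0.5 µm substrate line.
    """
    if factor <= 0:
        raise ValueError("reduction factor must be > 0")
    widths = np.asarray(mask_widths_um, dtype=float)
    if np.any(widths <= 0):
        raise ValueError("mask widths must be > 0")
    return widths / float(factor)


# ---------------------------------------------------------------------------
# layout export

_SVG_NS = "http://www.w3.org/2000/svg"


def export_layout(layout: ArrayLayout, svg_path, csv_path) -> None:
    """Write the layout as an SVG 1.1 drawing plus a per-field metadata CSV.

    SVG user units are micrometres; each field becomes a ``<g>`` with one
    stroked ``<line>`` per line element (stroke width = physical line width).
    CSV columns: field_id, row, col, dispersion_deg, density, line_width_um,
    seed.
    """
    ext_w, ext_h = layout.extent_um
    ET.register_namespace("", _SVG_NS)
    root = ET.Element(
        "svg",
        {
            "xmlns": _SVG_NS,
            "version": "1.1",
            "width": f"{ext_w}",
            "height": f"{ext_h}",
            "viewBox": f"0 0 {ext_w} {ext_h}",
        },
    )
    rows_out = []
    for idx, fld in enumerate(layout.fields):
        r, c = divmod(idx, layout.cols)
        if fld is None:
            continue
        gid = f"field-{r}-{c}"
        g = ET.SubElement(
            root,
            "g",
            {
                "id": gid,
                "transform": f"translate({c * layout.pitch_um},{r * layout.pitch_um})",
            },
        )
        for ln in fld.lines:
            (x0, y0), (x1, y1) = ln.endpoints
            ET.SubElement(
                g,
                "line",
                {
                    "x1": f"{x0:.4f}",
                    "y1": f"{y0:.4f}",
                    "x2": f"{x1:.4f}",
                    "y2": f"{y1:.4f}",
                    "stroke": "black",
                    "stroke-width": f"{ln.width_um}",
                    "stroke-linecap": "round",
                },
            )
        rows_out.append(
            {
                "field_id": gid,
                "row": r,
                "col": c,
                "dispersion_deg": fld.dispersion_deg,
                "density": fld.density,
                "line_width_um": fld.line_width_um,
                "seed": fld.seed,
            }
        )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(svg_path, xml_declaration=True, encoding="unicode")
    with open(csv_path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=[
                "field_id",
                "row",
                "col",
                "dispersion_deg",
                "density",
                "line_width_um",
                "seed",
            ],
        )
        writer.writeheader()
        writer.writerows(rows_out)


def read_layout_svg(svg_path) -> dict[str, list[tuple[tuple[float, float], tuple[float, float]]]]:
    """Parse an exported layout SVG back into per-field segment lists.

    Returns ``{field_id: [((x1, y1), (x2, y2)), ...]}`` in field-local µm.
    Intended for round-trip validation of :func:`export_layout`.
    """
    tree = ET.parse(Path(svg_path))
    out: dict[str, list] = {}
    for g in tree.getroot().iter(f"{{{_SVG_NS}}}g"):
        segs = []
        for ln in g.iter(f"{{{_SVG_NS}}}line"):
            segs.append(
                (
                    (float(ln.get("x1")), float(ln.get("y1"))),
                    (float(ln.get("x2")), float(ln.get("y2"))),
                )
            )
        out[g.get("id")] = segs
    return out
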