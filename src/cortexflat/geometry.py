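"""Polygon and curve primitives for lesion mapping.

Areas use the shoelace formula; Boolean operations are delegated to shapely
with vertices snapped to a fine precision grid so that near-degenerate edges
do not produce sliver artifacts. Contour interpolation supports straight
(linear) edges and parameterized Catmull-Rom splines, the two schemes used
for estimating the mediolateral lesion extent between measured slices.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon as ShapelyPolygon

log = logging.getLogger(__name__)

__all__ = [
    "ContourStyle",
    "signed_area",
    "polygon_area",
    "to_shapely",
    "polygon_intersection",
    "catmull_rom",
    "densify_edge",
    "interpolate_contour",
]

#: grid to which vertices are snapped before Boolean operations
SNAP_GRID = 1e-9

_HEX_COLOR = re.compile(r"^#[0-9a-fA-F]{6}$")
_BORDER_STYLES = ("solid", "dashed", "dotted")


@dataclass(frozen=True)
class ContourStyle:
    """Rendering style of a mapped lesion overlay."""

    border_color: str = "#d62728"
    fill_color: str = "#d62728"
    border_style: str = "solid"
    border_width: float = 1.0
    fill_alpha: float = 0.4
    dpi: float = 150.0

    def __post_init__(self):
        for name in ("border_color", "fill_color"):
            value = getattr(self, name)
            if not _HEX_COLOR.match(value):
                raise ValueError(f"{name} must be a #rrggbb hex triplet, got {value!r}")
        if self.border_style not in _BORDER_STYLES:
            raise ValueError(f"border_style must be one of {_BORDER_STYLES}")
        if self.dpi <= 0:
            raise ValueError("dpi must be > 0")
        if not 0.0 <= self.fill_alpha <= 1.0:
            raise ValueError("fill_alpha must be in [0, 1]")


def _vertices(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError("polygon must be an (N, 2) array of vertices")
    return v


def signed_area(p) -> float:
    """Signed shoelace area (positive for anticlockwise in a y-up frame)."""
    v = _vertices(p)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(p) -> float:
    """Absolute polygon area; 0 (with a warning) for degenerate input."""
    v = _vertices(p)
    if len(v) < 3:
        log.warning("polygon with %d vertices is degenerate; area = 0", len(v))
        return 0.0
    return abs(signed_area(v))


def to_shapely(p, repair: bool = True) -> ShapelyPolygon:
    """Convert a vertex ring to a (snapped, valid) shapely polygon.

    Non-simple rings are repaired to the union of their even-odd pieces,
    with a warning.
    """
    v = _vertices(p)
    poly = ShapelyPolygon(v)
    poly = shapely.set_precision(poly, SNAP_GRID)
    if not poly.is_valid:
        if not repair:
            raise ValueError("self-intersecting polygon")
        log.warning("self-intersecting polygon; repairing via make_valid")
        fixed = shapely.make_valid(poly)
        parts: list = []

        def collect(g):
            if g.geom_type == "Polygon":
                parts.append(g)
            elif hasattr(g, "geoms"):
                for sub in g.geoms:
                    collect(sub)

        collect(fixed)
        poly = shapely.union_all(parts) if parts else ShapelyPolygon()
    return poly


def polygon_intersection(a, b) -> list[np.ndarray]:
    """Boolean intersection a ∩ b as a list of disjoint simple polygons.

    Intersections of two simple (hole-free) polygons are themselves hole-free,
    so each piece is returned as its exterior ring, an (N, 2) array without
    the repeated closing vertex.
    """
    inter = to_shapely(a).intersection(to_shapely(b))
    geoms = list(inter.geoms) if hasattr(inter, "geoms") else [inter]
    pieces = []
    for geom in geoms:
        if geom.geom_type == "Polygon" and not geom.is_empty and geom.area > 0:
            pieces.append(np.asarray(geom.exterior.coords)[:-1])
    return pieces


# ---------------------------------------------------------------------------
# Catmull-Rom splines

def _catmull_rom_segment(p0, p1, p2, p3, alpha, ts):
    """Evaluate the parameterized Catmull-Rom segment p1→p2 at knot times ts.

    Uses the pyramidal (Barry-Goldman) recursion with knot spacing
    t_{i+1} - t_i = |p_{i+1} - p_i|^alpha. Zero-length outer intervals
    (duplicated phantom endpoints) are handled by their exact limit: when
    p0 == p1 the affine combination of the two coincident points is that
    point for any parameter value.
    """

    def dt(a, b):
        return float(np.hypot(*(b - a))) ** alpha

    t0 = 0.0
    t1 = t0 + dt(p0, p1)
    t2 = t1 + dt(p1, p2)
    t3 = t2 + dt(p2, p3)
    ts = np.asarray(ts, dtype=float)[:, None]

    def lerp(pa, pb, ta, tb):
        if tb - ta < 1e-30:
            return np.broadcast_to(np.asarray(pb, dtype=float), (len(ts), 2)).copy()
        w = (ts - ta) / (tb - ta)
        return (1 - w) * pa + w * pb

    a1 = lerp(p0, p1, t0, t1)
    a2 = lerp(p1, p2, t1, t2)
    a3 = lerp(p2, p3, t2, t3)
    b1 = lerp(a1, a2, t0, t2)
    b2 = lerp(a2, a3, t1, t3)
    return lerp(b1, b2, t1, t2), t1, t2


def catmull_rom(points, alpha: float = 0.5, n_insert: int = 0) -> np.ndarray:
    """Densify an open polyline with a parameterized Catmull-Rom spline.

    Inserts ``n_insert`` spline points between each adjacent pair of control
    points; all input points are retained, in order. ``alpha`` selects the
    parameterization (0 uniform, 0.5 centripetal — the cusp-free default,
    1 chordal). Endpoints are clamped by duplicating the first and last
    control points. Coincident adjacent control points yield a degenerate
    segment, which is skipped with a warning.
    """
    pts = _vertices(points)
    if len(pts) < 2:
        raise ValueError("need at least 2 control points")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if n_insert < 0:
        raise ValueError("n_insert must be >= 0")
    if n_insert == 0:
        return pts.copy()

    padded = np.vstack([pts[0], pts, pts[-1]])
    out = [pts[0]]
    for i in range(len(pts) - 1):
        p0, p1, p2, p3 = padded[i], padded[i + 1], padded[i + 2], padded[i + 3]
        if np.hypot(*(p2 - p1)) < 1e-30:
            log.warning("coincident control points at segment %d; skipped", i)
            out.append(p2)
            continue
        # interior knot times of the segment
        t1 = np.hypot(*(p1 - p0)) ** alpha
        t2 = t1 + np.hypot(*(p2 - p1)) ** alpha
        ts = np.linspace(t1, t2, n_insert + 2)[1:-1]
        seg, _, _ = _catmull_rom_segment(p0, p1, p2, p3, alpha, ts)
        out.extend(seg)
        out.append(p2)
    return np.asarray(out)


def densify_edge(points, method: str = "linear", alpha: float = 0.5,
                 n_insert: int = 0) -> np.ndarray:
    """Densify one lesion edge polyline with the chosen interpolation."""
    pts = _vertices(points)
    if method == "linear" or n_insert == 0 or len(pts) < 2:
        return pts.copy()
    if method != "spline":
        raise ValueError("method must be 'linear' or 'spline'")
    return catmull_rom(pts, alpha=alpha, n_insert=n_insert)


def interpolate_contour(medial_edge, lateral_edge, method: str = "linear",
                        alpha: float = 0.5, n_insert: int = 0) -> np.ndarray:
    """Close the two lesion edges into one polygon ring.

    Both edges must be ordered by ascending anteroposterior coordinate; each
    is densified independently, then combined anticlockwise: medial edge in
    ascending order followed by the lateral edge in descending order. If
    spline overshoot produces a self-intersecting ring, the contour falls
    back to linear interpolation with a warning.
    """
    med = densify_edge(medial_edge, method, alpha, n_insert)
    lat = densify_edge(lateral_edge, method, alpha, n_insert)
    ring = np.vstack([med, lat[::-1]])
    if method == "spline" and len(ring) >= 3:
        if not ShapelyPolygon(ring).is_valid:
            log.warning("spline contour self-intersects; falling back to linear")
            return interpolate_contour(medial_edge, lateral_edge, "linear")
    return ring
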