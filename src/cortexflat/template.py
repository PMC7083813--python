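"""Unfolded-cortex templates: parsing, validation and synthesis.

A template is a 2D flat map of the mouse cerebral cortex in which every
coronal level becomes a horizontal line stacked along the anteroposterior
(AP) axis. It is stored as a plain SVG file plus a JSON file of reference
cortical surface lengths per coronal atlas plate.

SVG conventions
---------------
* each cytoarchitectonic region is a unique *closed* path labeled with the
  prefix ``A_`` (label = ``id`` attribute, falling back to
  ``inkscape:label``);
* the bregma level of the AP axis is given either by an ``ap_zero``
  attribute on the ``<svg>`` element or by a rectangle labeled ``ap_zero``
  (its y position); the drawing-units-per-millimetre constant ``r`` likewise
  by a ``units_per_mm`` attribute or a rectangle of that name (its width).
  Attributes take precedence over rectangles when both are present;
* the rhinal fissure is a path labeled ``rhinal_fissure``;
* any other object (labels, axes, frames) is kept for visualization but
  ignored by all computations.

Axis conventions: template y increases posteriorly, so a bregma-relative
coordinate MB (mm, anterior positive) maps to ``y = ap_zero − r·MB``;
x increases medially → laterally (midline at small x).
"""

from __future__ import annotations

import json
import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from shapely.geometry import Polygon as ShapelyPolygon

from . import _svg
from ._svg import flatten_cubic_bezier  # noqa: F401  (public re-export)
from .geometry import polygon_area, to_shapely

log = logging.getLogger(__name__)

__all__ = [
    "TemplateError",
    "AtlasPlate",
    "AtlasLengths",
    "Template",
    "parse_template",
    "atlas_length_at",
    "rhinal_x_at",
    "generate_synthetic_template",
    "flatten_cubic_bezier",
]

_INKSCAPE_NS = "{http://www.inkscape.org/namespaces/inkscape}"


class TemplateError(ValueError):
    """Invalid template SVG or atlas-lengths file."""


# ---------------------------------------------------------------------------
# atlas reference lengths

@dataclass(frozen=True)
class AtlasPlate:
    """Reference surface lengths of one coronal atlas plate.

    ``ap_mm`` is the bregma-relative anteroposterior coordinate (anterior
    positive); lengths are measured along the pial surface from the medial
    reference point.
    """

    ap_mm: float
    medial_to_rhinal_mm: float
    medial_to_lateral_mm: float


@dataclass(frozen=True)
class AtlasLengths:
    """Ordered (anterior → posterior) reference lengths for all plates."""

    plates: tuple[AtlasPlate, ...]

    def __post_init__(self):
        if not self.plates:
            raise TemplateError("atlas must contain at least one plate")
        plates = tuple(sorted(self.plates, key=lambda p: -p.ap_mm))
        object.__setattr__(self, "plates", plates)
        aps = [p.ap_mm for p in plates]
        if len(set(aps)) != len(aps):
            raise TemplateError("atlas plate AP coordinates must be unique")
        for p in plates:
            if p.medial_to_rhinal_mm <= 0 or p.medial_to_lateral_mm <= 0:
                raise TemplateError(f"plate at {p.ap_mm} mm has non-positive length")
            if p.medial_to_lateral_mm < p.medial_to_rhinal_mm:
                raise TemplateError(
                    f"plate at {p.ap_mm} mm: medial_to_lateral < medial_to_rhinal")

    @classmethod
    def from_json(cls, text: str, key_map: dict[str, str] | None = None
                  ) -> "AtlasLengths":
        """Load from JSON: an array of objects with keys ``ap``,
        ``medial_to_rhinal`` and ``medial_to_lateral`` (millimetres).

        ``key_map`` remaps these canonical keys to the ones actually present,
        e.g. ``{"ap": "bregma"}``, so files with a different field layout can
        be loaded without conversion.
        """
        keys = {"ap": "ap", "medial_to_rhinal": "medial_to_rhinal",
                "medial_to_lateral": "medial_to_lateral"}
        if key_map:
            keys.update(key_map)
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as exc:
            raise TemplateError(f"atlas JSON is not valid JSON: {exc}") from exc
        if not isinstance(raw, list):
            raise TemplateError("atlas JSON must be an array of plate objects")
        plates = []
        for i, entry in enumerate(raw):
            try:
                plates.append(AtlasPlate(
                    ap_mm=float(entry[keys["ap"]]),
                    medial_to_rhinal_mm=float(entry[keys["medial_to_rhinal"]]),
                    medial_to_lateral_mm=float(entry[keys["medial_to_lateral"]]),
                ))
            except (KeyError, TypeError, ValueError) as exc:
                raise TemplateError(f"atlas JSON entry {i} is malformed: {exc}") from exc
        return cls(tuple(plates))

    def to_json(self) -> str:
        return json.dumps(
            [{"ap": p.ap_mm, "medial_to_rhinal": p.medial_to_rhinal_mm,
              "medial_to_lateral": p.medial_to_lateral_mm} for p in self.plates],
            indent=1,
        )

    @property
    def ap_values(self) -> np.ndarray:
        return np.array([p.ap_mm for p in self.plates])

    @property
    def plate_spacing_mm(self) -> float:
        aps = self.ap_values
        if len(aps) < 2:
            return 0.0
        return float(np.median(np.abs(np.diff(aps))))

    @property
    def ap_range(self) -> tuple[float, float]:
        """(posterior-most, anterior-most) AP coordinate, plus half a plate
        spacing of slack at each end."""
        half = 0.5 * self.plate_spacing_mm
        aps = self.ap_values
        return float(aps.min() - half), float(aps.max() + half)


def atlas_length_at(atlas: AtlasLengths, mb: float,
                    which: str = "medial_to_rhinal") -> float:
    """Reference surface length (mm) at AP coordinate ``mb``.

    The plate whose AP coordinate is nearest to ``mb`` supplies the length
    (plates are ~0.2 mm apart, mirroring the manual assignment of a section
    to its atlas plate); ties go to the anterior plate. ``mb`` outside the
    atlas AP span (± half a plate spacing) is a hard error.
    """
    if which not in ("medial_to_rhinal", "medial_to_lateral"):
        raise ValueError("which must be 'medial_to_rhinal' or 'medial_to_lateral'")
    lo, hi = atlas.ap_range
    if not lo <= mb <= hi:
        raise TemplateError(
            f"AP coordinate {mb} mm outside the template span [{lo:.3f}, {hi:.3f}] mm")
    aps = atlas.ap_values
    dist = np.abs(aps - mb)
    best = np.flatnonzero(dist == dist.min())
    # plates sorted anterior->posterior, so the first minimum is the anterior one
    plate = atlas.plates[int(best[0])]
    return getattr(plate, f"{which}_mm")


# ---------------------------------------------------------------------------
# template

@dataclass
class Template:
    """Parsed unfolded-cortex template.

    ``regions`` maps region id (``A_`` prefix stripped) to its closed polygon
    in template drawing units; ``decorations`` holds the flattened outlines of
    every other SVG object, kept only for rendering.
    """

    regions: dict[str, np.ndarray]
    ap_zero: float
    units_per_mm: float
    rhinal_fissure: np.ndarray
    atlas_lengths: AtlasLengths
    decorations: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        if self.units_per_mm <= 0:
            raise TemplateError("units_per_mm must be > 0")
        if not self.regions:
            raise TemplateError("template defines no 'A_' region paths")
        for rid, poly in self.regions.items():
            if len(poly) < 3:
                raise TemplateError(f"region {rid!r} has fewer than 3 vertices")
            if not ShapelyPolygon(poly).is_valid:
                raise TemplateError(f"region {rid!r} polygon is not simple")
            if polygon_area(poly) <= 0:
                raise TemplateError(f"region {rid!r} has zero area")
        fissure = np.asarray(self.rhinal_fissure, dtype=float)
        if fissure.ndim != 2 or len(fissure) < 2:
            raise TemplateError("rhinal_fissure must be a polyline of >= 2 points")
        self.rhinal_fissure = fissure
        y_lo, y_hi = fissure[:, 1].min(), fissure[:, 1].max()
        for p in self.atlas_lengths.plates:
            y = self.mb_to_y(p.ap_mm)
            if not y_lo - 1e-6 <= y <= y_hi + 1e-6:
                raise TemplateError(
                    "rhinal fissure does not span the AP extent of the atlas "
                    f"(plate at {p.ap_mm} mm maps to y={y:.3f}, fissure covers "
                    f"[{y_lo:.3f}, {y_hi:.3f}])")

    # -- coordinate conversions ---------------------------------------------
    def mb_to_y(self, mb: float) -> float:
        """Template y of a bregma-relative AP coordinate (anterior above)."""
        return self.ap_zero - self.units_per_mm * mb

    def y_to_mb(self, y) -> float:
        return (self.ap_zero - np.asarray(y)) / self.units_per_mm

    # -- derived geometry ----------------------------------------------------
    @cached_property
    def region_shapes(self) -> dict[str, ShapelyPolygon]:
        return {rid: to_shapely(poly) for rid, poly in self.regions.items()}

    @cached_property
    def cortex_shape(self):
        import shapely
        return shapely.union_all(list(self.region_shapes.values()))

    @property
    def cortex_area_mm2(self) -> float:
        return self.cortex_shape.area / self.units_per_mm ** 2

    def region_area_mm2(self, region_id: str) -> float:
        return self.region_shapes[region_id].area / self.units_per_mm ** 2

    @cached_property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) over regions, fissure and decorations."""
        pts = [poly for poly in self.regions.values()]
        pts.append(self.rhinal_fissure)
        pts.extend(self.decorations)
        allp = np.vstack(pts)
        return (float(allp[:, 0].min()), float(allp[:, 1].min()),
                float(allp[:, 0].max()), float(allp[:, 1].max()))

    @property
    def midline_x(self) -> float:
        """Template x of the midline: the medial edge of the cortex."""
        return min(float(np.min(p[:, 0])) for p in self.regions.values())


def rhinal_x_at(template: Template, y: float) -> float:
    """Mediolateral (x) position of the rhinal fissure at template ordinate y.

    Linear interpolation along the fissure polyline; y outside the polyline
    extent is a hard error.
    """
    fissure = template.rhinal_fissure
    ys = fissure[:, 1]
    lo, hi = float(ys.min()), float(ys.max())
    if not lo - 1e-9 <= y <= hi + 1e-9:
        raise TemplateError(
            f"y={y} outside the rhinal fissure extent [{lo:.3f}, {hi:.3f}]")
    order = np.argsort(ys, kind="stable")
    return float(np.interp(y, ys[order], fissure[order, 0]))


# ---------------------------------------------------------------------------
# SVG parsing

def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _label(el: ET.Element) -> str | None:
    return el.get("id") or el.get(_INKSCAPE_NS + "label")


def _rect_outline(el: ET.Element, m: np.ndarray) -> np.ndarray:
    x = float(el.get("x", 0.0))
    y = float(el.get("y", 0.0))
    w = float(el.get("width", 0.0))
    h = float(el.get("height", 0.0))
    corners = np.array([[x, y], [x + w, y], [x + w, y + h], [x, y + h], [x, y]])
    return _svg.apply_transform(m, corners)


def _walk(el: ET.Element, m: np.ndarray, sink: dict, tolerance: float) -> None:
    m = _svg.compose(m, _svg.parse_transform(el.get("transform")))
    tag = _local(el.tag)
    label = _label(el)
    if tag == "path":
        d = el.get("d", "")
        subpaths = _svg.parse_path(d)
        if label and label.startswith("A_"):
            rid = label[2:]
            if not subpaths:
                raise TemplateError(f"region {label!r} has empty path data")
            if len(subpaths) > 1:
                log.warning("region %r has %d subpaths; using the first",
                            label, len(subpaths))
            sub = subpaths[0]
            pts = _svg.flatten_subpath(sub, tolerance, m)
            closed = sub.closed or (
                len(pts) > 2 and np.hypot(*(pts[0] - pts[-1])) < 1e-6)
            if not closed:
                raise TemplateError(f"region path {label!r} is not closed")
            if np.hypot(*(pts[0] - pts[-1])) < 1e-12 and len(pts) > 1:
                pts = pts[:-1]
            if rid in sink["regions"]:
                raise TemplateError(f"duplicate region id {rid!r}")
            sink["regions"][rid] = pts
        elif label == "rhinal_fissure":
            if not subpaths:
                raise TemplateError("rhinal_fissure path has empty path data")
            sink["fissure"] = _svg.flatten_subpath(subpaths[0], tolerance, m)
        else:
            for sub in subpaths:
                sink["decorations"].append(_svg.flatten_subpath(sub, tolerance, m))
    elif tag == "rect":
        if label == "ap_zero":
            origin = _svg.apply_transform(
                m, np.array([float(el.get("x", 0.0)), float(el.get("y", 0.0))]))
            sink["rect_ap_zero"] = float(origin[1])
        elif label == "units_per_mm":
            w = float(el.get("width", 0.0))
            vec = _svg.apply_transform(m, np.array([w, 0.0])) - _svg.apply_transform(
                m, np.zeros(2))
            sink["rect_units_per_mm"] = float(np.hypot(*vec))
        else:
            sink["decorations"].append(_rect_outline(el, m))
    elif tag == "line":
        pts = np.array([[float(el.get("x1", 0.0)), float(el.get("y1", 0.0))],
                        [float(el.get("x2", 0.0)), float(el.get("y2", 0.0))]])
        sink["decorations"].append(_svg.apply_transform(m, pts))
    elif tag in ("polyline", "polygon"):
        nums = [float(v) for v in
                el.get("points", "").replace(",", " ").split()]
        if len(nums) >= 4:
            pts = np.array(nums, dtype=float).reshape(-1, 2)
            if tag == "polygon":
                pts = np.vstack([pts, pts[:1]])
            sink["decorations"].append(_svg.apply_transform(m, pts))
    # text and unknown elements are ignored entirely
    for child in el:
        _walk(child, m, sink, tolerance)


def parse_template(svg_text: str, atlas_json: str | AtlasLengths,
                   bezier_tolerance: float = 0.01,
                   atlas_key_map: dict[str, str] | None = None) -> Template:
    """Parse a template SVG plus its atlas-lengths JSON into a Template.

    Region paths (``A_`` prefix) are flattened to polygons with de Casteljau
    subdivision at ``bezier_tolerance`` (template units). ``ap_zero`` and
    ``units_per_mm`` are resolved from ``<svg>`` element attributes first,
    then from the equally named rectangles; missing both is a hard error.
    """
    try:
        root = ET.fromstring(svg_text)
    except ET.ParseError as exc:
        raise TemplateError(f"template SVG is not well-formed XML: {exc}") from exc
    if _local(root.tag) != "svg":
        raise TemplateError("root element is not <svg>")

    sink: dict = {"regions": {}, "fissure": None, "decorations": [],
                  "rect_ap_zero": None, "rect_units_per_mm": None}
    _walk(root, _svg.identity_transform(), sink, bezier_tolerance)

    def resolve(attr_name: str, rect_key: str) -> float:
        attr = root.get(attr_name)
        if attr is not None:
            try:
                return float(attr)
            except ValueError as exc:
                raise TemplateError(f"svg attribute {attr_name!r} is not numeric") from exc
        if sink[rect_key] is not None:
            return sink[rect_key]
        raise TemplateError(
            f"{attr_name} missing: provide an svg-element attribute or a "
            f"rectangle labeled {attr_name!r}")

    units_per_mm = resolve("units_per_mm", "rect_units_per_mm")
    ap_zero = resolve("ap_zero", "rect_ap_zero")
    if sink["fissure"] is None:
        raise TemplateError("template has no path labeled 'rhinal_fissure'")

    atlas = (atlas_json if isinstance(atlas_json, AtlasLengths)
             else AtlasLengths.from_json(atlas_json, key_map=atlas_key_map))
    return Template(
        regions=sink["regions"],
        ap_zero=ap_zero,
        units_per_mm=units_per_mm,
        rhinal_fissure=sink["fissure"],
        atlas_lengths=atlas,
        decorations=sink["decorations"],
    )


# ---------------------------------------------------------------------------
# synthetic templates

def generate_synthetic_template(
    n_regions: int,
    ap_span: tuple[float, float] = (3.20, -4.96),
    units_per_mm: float = 10.0,
    seed: int = 0,
    n_plates: int = 40,
    medial_to_rhinal_mm: float = 6.0,
    medial_to_lateral_mm: float = 8.0,
    grid: tuple[int, int] | None = None,
    jitter: float = 0.02,
) -> tuple[str, str]:
    """Emit a synthetic template (SVG text, atlas-lengths JSON).

    The map is a grid of rectangular regions of exactly known area spanning
    the full mediolateral extent, with the rhinal fissure drawn through the
    per-plate medial→rhinal lengths. Defaults mirror a real mouse template:
    40 coronal plates from +3.20 to −4.96 mm bregma (~0.21 mm apart), a
    6 mm medial→rhinal surface length with ±``jitter`` relative per-plate
    variation (seeded, emulating plate-to-plate atlas differences), and
    cortex extending 2 mm lateral to the fissure. Output is deterministic
    per seed and round-trips through :func:`parse_template`.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    ap_max, ap_min = max(ap_span), min(ap_span)
    if ap_max == ap_min:
        raise ValueError("ap_span must be a nonempty interval")
    r = float(units_per_mm)
    rng = np.random.default_rng(seed)

    aps = np.linspace(ap_max, ap_min, n_plates)
    mr = medial_to_rhinal_mm * (1.0 + jitter * rng.uniform(-1, 1, n_plates))
    ml = mr + (medial_to_lateral_mm - medial_to_rhinal_mm)

    ap_zero = r * ap_max  # y = ap_zero - r*mb, so y=0 at the anterior edge
    height = r * (ap_max - ap_min)
    width = r * medial_to_lateral_mm

    if grid is None:
        n_cols = math.ceil(math.sqrt(n_regions))
        n_rows = math.ceil(n_regions / n_cols)
    else:
        n_cols, n_rows = grid
        if n_cols * n_rows < n_regions:
            raise ValueError("grid too small for n_regions")
    cell_w, cell_h = width / n_cols, height / n_rows

    def fmt(v: float) -> str:
        return f"{v:.9f}".rstrip("0").rstrip(".")

    parts = [
        '<svg xmlns="http://www.w3.org/2000/svg" '
        f'width="{fmt(width)}" height="{fmt(height)}" '
        f'viewBox="0 0 {fmt(width)} {fmt(height)}" '
        f'ap_zero="{fmt(ap_zero)}" units_per_mm="{fmt(r)}">'
    ]
    for i in range(n_regions):
        row, col = divmod(i, n_cols)
        x0, y0 = col * cell_w, row * cell_h
        d = (f"M {fmt(x0)} {fmt(y0)} L {fmt(x0 + cell_w)} {fmt(y0)} "
             f"L {fmt(x0 + cell_w)} {fmt(y0 + cell_h)} L {fmt(x0)} {fmt(y0 + cell_h)} Z")
        parts.append(f'<path id="A_R{i:02d}" d="{d}" fill="none" stroke="black"/>')

    # rhinal fissure through the per-plate medial->rhinal x, extended by half
    # a plate spacing at both ends so every valid MB lies within its extent
    ys = ap_zero - r * aps
    xs = r * mr
    spacing = abs(aps[1] - aps[0]) if n_plates > 1 else (ap_max - ap_min)
    fpts = [(xs[0], ys[0] - r * spacing / 2)]
    fpts += list(zip(xs, ys))
    fpts.append((xs[-1], ys[-1] + r * spacing / 2))
    d = "M " + " L ".join(f"{fmt(x)} {fmt(y)}" for x, y in fpts)
    parts.append(f'<path id="rhinal_fissure" d="{d}" fill="none" stroke="gray"/>')

    # decorative objects: midline and an outer frame (ignored by computation)
    parts.append(f'<line id="midline" x1="0" y1="0" x2="0" y2="{fmt(height)}" '
                 'stroke="black"/>')
    parts.append(f'<rect id="frame" x="0" y="0" width="{fmt(width)}" '
                 f'height="{fmt(height)}" fill="none" stroke="silver"/>')
    parts.append("</svg>")
    svg_text = "\n".join(parts)

    atlas = AtlasLengths(tuple(
        AtlasPlate(round(float(a), 6), round(float(b), 6), round(float(c), 6))
        for a, b, c in zip(aps, mr, ml)))
    return svg_text, atlas.to_json()
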