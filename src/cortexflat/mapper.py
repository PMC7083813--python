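"""The four-step lesion mapping: normalize, translate, interpolate, quantify.

1. **Normalization** corrects each slice for tissue shrinkage / brain-size
   differences: the measured inter-reference distance (medial reference
   point → rhinal fissure, i.e. M1+M2+M3, or M1+M2 when the lesion crosses
   the fissure and M3 is negative) is compared with the atlas surface length
   at the slice's AP level, and M2 / M3 are rescaled by
   ``atlas / measured``. M1 is dropped: the lesion is localized laterally.
2. **Translation** places each slice on the template: ``y = ap_zero − r·MB``;
   the lateral lesion edge sits at ``rhinal_x(y) − r·M3_adj`` (the rhinal
   fissure is the lateral reference point) and the medial edge a further
   ``r·M2_adj`` medially.
3. **Interpolation** closes the per-slice edges into a single anticlockwise
   polygon (medial edge in ascending MB order, lateral edge descending),
   optionally densified with a Catmull-Rom spline.
4. **Quantification** intersects the lesion polygon with every region of the
   template and reports absolute (mm²) and fractional damage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import densify_edge, to_shapely
from .importer import MeasurementSet, SliceMeasurement
from .template import AtlasLengths, Template, atlas_length_at, rhinal_x_at

log = logging.getLogger(__name__)

__all__ = [
    "MapperError",
    "AdjustedSlice",
    "LesionContour",
    "QuantificationResult",
    "normalize_slice",
    "translate",
    "map_lesion",
    "quantify",
]

#: plausible range of the shrinkage-correction ratio; values outside it are
#: usually measurement or atlas-assignment errors
RATIO_PLAUSIBLE = (0.25, 4.0)


class MapperError(ValueError):
    """Measurements incompatible with the template."""


@dataclass(frozen=True)
class AdjustedSlice:
    """One slice after shrinkage normalization (all distances in atlas mm)."""

    mb: float
    m2_adj: float
    m3_adj: float
    scale_ratio: float
    m1_adj: float = 0.0

    def __post_init__(self):
        if self.scale_ratio <= 0:
            raise MapperError(f"scale_ratio must be > 0, got {self.scale_ratio}")
        if self.m2_adj <= 0:
            raise MapperError(f"m2_adj must be > 0, got {self.m2_adj}")


@dataclass
class LesionContour:
    """Closed lesion polygon in template coordinates for one day.

    The two edges are kept separately (both ordered by ascending MB); the
    full ring is the medial edge followed by the lateral edge reversed,
    which is anticlockwise under the template's axis convention.
    """

    medial: np.ndarray
    lateral: np.ndarray
    day: int = 1
    method: str = "linear"
    alpha: float = 0.5
    n_insert: int = 0
    dummy_medial: np.ndarray | None = None
    dummy_lateral: np.ndarray | None = None

    @property
    def vertices(self) -> np.ndarray:
        """The closed ring (first vertex not repeated)."""
        return np.vstack([self.medial, self.lateral[::-1]])

    @property
    def is_degenerate(self) -> bool:
        return len(self.vertices) < 3 or len(self.medial) < 2


@dataclass(frozen=True)
class QuantificationResult:
    """Per-region and total lesion load for one day.

    ``per_region`` maps region id → (area_mm2, percent_of_region); regions
    the lesion does not touch are omitted but still count in the cortex
    total denominator.
    """

    per_region: dict[str, tuple[float, float]]
    total_area_mm2: float
    total_percent_of_cortex: float
    cortex_area_mm2: float
    day: int = 1

    def region_area(self, region_id: str) -> float:
        return self.per_region.get(region_id, (0.0, 0.0))[0]

    def region_percent(self, region_id: str) -> float:
        return self.per_region.get(region_id, (0.0, 0.0))[1]


# ---------------------------------------------------------------------------
# step 1: normalization

def normalize_slice(s: SliceMeasurement, atlas: AtlasLengths) -> AdjustedSlice:
    """Rescale one slice's M2/M3 to atlas millimetres.

    The inter-reference distance D is M1+M2+M3 when the lateral lesion edge
    lies medial to the rhinal fissure (M3 >= 0), and M1+M2 when the lesion
    crosses the fissure (M3 < 0, with M2 then measured medial edge →
    fissure). The correction ratio is the atlas medial→rhinal length at MB
    divided by D; M2 and M3 are multiplied by it. M1 is not carried forward
    — the two lateral distances suffice to localize the lesion.
    """
    if s.m3 >= 0:
        d = s.m1 + s.m2 + s.m3
    else:
        d = s.m1 + s.m2
    if d <= 0:
        raise MapperError(f"slice at MB={s.mb}: inter-reference distance {d} <= 0")
    ratio = atlas_length_at(atlas, s.mb, "medial_to_rhinal") / d
    if not RATIO_PLAUSIBLE[0] <= ratio <= RATIO_PLAUSIBLE[1]:
        log.warning("slice at MB=%.3f: implausible scale ratio %.3f", s.mb, ratio)
    return AdjustedSlice(mb=s.mb, m2_adj=s.m2 * ratio, m3_adj=s.m3 * ratio,
                         scale_ratio=ratio, m1_adj=s.m1 * ratio)


# ---------------------------------------------------------------------------
# step 2: translation

def translate(adj: list[AdjustedSlice], t: Template, anchor: str = "fissure"
              ) -> tuple[np.ndarray, np.ndarray]:
    """Convert adjusted slices to the two lesion edges in template units.

    Returns (medial_edge, lateral_edge), both (N, 2) and ordered by
    ascending MB. The default ``anchor='fissure'`` places the lateral edge
    at ``rhinal_x(y) − r·M3_adj`` (rhinal fissure as the lateral reference
    point); ``anchor='midline'`` is the alternative reading that anchors the
    medial edge at ``midline + r·M1_adj``. A medial edge falling medial to
    the cortex boundary is clipped to it with a warning.
    """
    if not adj:
        raise MapperError("no slices to translate")
    if anchor not in ("fissure", "midline"):
        raise ValueError("anchor must be 'fissure' or 'midline'")
    r = t.units_per_mm
    ordered = sorted(adj, key=lambda a: a.mb)
    medial, lateral = [], []
    midline = t.midline_x
    for a in ordered:
        y = t.mb_to_y(a.mb)
        if anchor == "fissure":
            lat_x = rhinal_x_at(t, y) - r * a.m3_adj
            med_x = lat_x - r * a.m2_adj
        else:
            med_x = midline + r * a.m1_adj
            lat_x = med_x + r * a.m2_adj
        if med_x < midline:
            log.warning("slice at MB=%.3f: medial edge clipped to the cortex "
                        "boundary (x=%.3f < midline %.3f)", a.mb, med_x, midline)
            med_x = midline
        medial.append((med_x, y))
        lateral.append((lat_x, y))
    return np.asarray(medial), np.asarray(lateral)


# ---------------------------------------------------------------------------
# steps 3+4: contour assembly and quantification

def map_lesion(ms: MeasurementSet, t: Template, method: str = "linear",
               alpha: float = 0.5, n_insert: int = 0,
               anchor: str = "fissure") -> LesionContour:
    """Run normalization → translation → interpolation for one set."""
    adj = [normalize_slice(s, t.atlas_lengths) for s in ms.slices]
    medial, lateral = translate(adj, t, anchor=anchor)
    if len(medial) < 2:
        log.warning("single-slice set: lesion contour is degenerate")
        return LesionContour(medial=medial, lateral=lateral, day=ms.day,
                             method=method, alpha=alpha, n_insert=n_insert)
    med_d = densify_edge(medial, method, alpha, n_insert)
    lat_d = densify_edge(lateral, method, alpha, n_insert)
    if method == "spline":
        from shapely.geometry import Polygon as ShapelyPolygon
        ring = np.vstack([med_d, lat_d[::-1]])
        if not ShapelyPolygon(ring).is_valid:
            log.warning("spline contour self-intersects; falling back to linear")
            med_d, lat_d, method = medial, lateral, "linear"
    return LesionContour(medial=med_d, lateral=lat_d, day=ms.day,
                         method=method, alpha=alpha, n_insert=n_insert)


def quantify(c: LesionContour, t: Template) -> QuantificationResult:
    """Intersect the lesion with every template region.

    Areas are reported in mm² (template-unit areas divided by r²); each
    region's percentage is the intersected fraction of that region, and the
    cortex total is the summed intersection over the whole-cortex area.
    """
    r2 = t.units_per_mm ** 2
    cortex_area = t.cortex_area_mm2
    if c.is_degenerate:
        log.warning("degenerate contour: all-zero quantification")
        return QuantificationResult({}, 0.0, 0.0, cortex_area, day=c.day)
    lesion = to_shapely(c.vertices)
    per_region: dict[str, tuple[float, float]] = {}
    total = 0.0
    for rid, shape in t.region_shapes.items():
        inter = lesion.intersection(shape).area
        if inter > 0.0:
            area_mm2 = inter / r2
            percent = 100.0 * inter / shape.area
            per_region[rid] = (area_mm2, percent)
            total += area_mm2
    if not per_region:
        log.warning("lesion contour lies entirely outside the cortex")
    total_percent = 100.0 * total / cortex_area if cortex_area > 0 else 0.0
    return QuantificationResult(per_region=per_region, total_area_mm2=total,
                                total_percent_of_cortex=total_percent,
                                cortex_area_mm2=cortex_area, day=c.day)
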