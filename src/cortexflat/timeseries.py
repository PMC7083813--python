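"""Multi-day lesion series: per-day quantification and contour transitions.

When the same lesion is measured on several days, each day maps to its own
contour and quantification. For visualizing the evolution between two days,
the two contours are first brought to equal vertex counts by inserting
*dummy points* on existing edges of the sparser contour (which leaves its
area unchanged), then blended vertex-wise by linear interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .importer import MeasurementSet
from .mapper import LesionContour, QuantificationResult, map_lesion, quantify
from .template import Template

log = logging.getLogger(__name__)

__all__ = [
    "LesionSeries",
    "align_contours",
    "interpolate_transition",
    "strip_dummies",
    "series_table",
]


@dataclass
class LesionSeries:
    """Per-day (contour, quantification) entries mapped on one template."""

    entries: dict[int, tuple[LesionContour, QuantificationResult]]
    template: Template

    def __post_init__(self):
        if not self.entries:
            raise ValueError("series must contain at least one day")
        if any(d < 1 for d in self.entries):
            raise ValueError("days must be >= 1")
        self.entries = dict(sorted(self.entries.items()))

    @property
    def days(self) -> list[int]:
        return list(self.entries)

    @classmethod
    def from_measurement_sets(cls, sets, template: Template, **map_kwargs
                              ) -> "LesionSeries":
        """Map and quantify each MeasurementSet (one per day)."""
        entries = {}
        for ms in sets:
            if ms.day in entries:
                raise ValueError(f"duplicate day {ms.day} in series")
            contour = map_lesion(ms, template, **map_kwargs)
            entries[ms.day] = (contour, quantify(contour, template))
        return cls(entries=entries, template=template)


# ---------------------------------------------------------------------------
# contour alignment for transitions

def _pad_edge(points: np.ndarray, dummy: np.ndarray | None, target: int
              ) -> tuple[np.ndarray, np.ndarray]:
    """Insert dummy points on the longest current segments until the edge
    has ``target`` vertices. Insertions are segment midpoints, so they are
    collinear with existing vertices and preserve the polygon's area."""
    pts = [np.asarray(p, dtype=float) for p in points]
    marks = list(dummy) if dummy is not None else [False] * len(pts)
    while len(pts) < target:
        seg_len = [float(np.hypot(*(pts[i + 1] - pts[i])))
                   for i in range(len(pts) - 1)]
        i = int(np.argmax(seg_len))
        pts.insert(i + 1, 0.5 * (pts[i] + pts[i + 1]))
        marks.insert(i + 1, True)
    return np.asarray(pts), np.asarray(marks, dtype=bool)


def align_contours(a: LesionContour, b: LesionContour
                   ) -> tuple[LesionContour, LesionContour]:
    """Equalize vertex counts of two contours edge by edge.

    Medial is matched with medial and lateral with lateral; the edge with
    fewer vertices gains dummy points spread over its longest segments, so
    corresponding vertices stay monotone in arc length on both contours.
    Original vertices are preserved; dummy points are flagged on the
    returned contours (``dummy_medial`` / ``dummy_lateral``) so they can be
    dropped once the transition rendering is done.
    """
    out = []
    n_med = max(len(a.medial), len(b.medial))
    n_lat = max(len(a.lateral), len(b.lateral))
    for c in (a, b):
        med, dmed = _pad_edge(c.medial, c.dummy_medial, n_med)
        lat, dlat = _pad_edge(c.lateral, c.dummy_lateral, n_lat)
        out.append(replace(c, medial=med, lateral=lat,
                           dummy_medial=dmed, dummy_lateral=dlat))
    return out[0], out[1]


def interpolate_transition(a: LesionContour, b: LesionContour, tau: float
                           ) -> LesionContour:
    """Vertex-wise blend (1−tau)·a + tau·b of two aligned contours."""
    if len(a.medial) != len(b.medial) or len(a.lateral) != len(b.lateral):
        raise ValueError("contours must be aligned (equal vertex counts); "
                         "call align_contours first")
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must be in [0, 1]")
    return LesionContour(
        medial=(1 - tau) * a.medial + tau * b.medial,
        lateral=(1 - tau) * a.lateral + tau * b.lateral,
        day=a.day, method=a.method, alpha=a.alpha, n_insert=a.n_insert)


def strip_dummies(c: LesionContour) -> LesionContour:
    """Remove flagged dummy points after the transition visualization."""
    med = c.medial[~c.dummy_medial] if c.dummy_medial is not None else c.medial
    lat = c.lateral[~c.dummy_lateral] if c.dummy_lateral is not None else c.lateral
    return replace(c, medial=med, lateral=lat, dummy_medial=None,
                   dummy_lateral=None)


# ---------------------------------------------------------------------------
# tabulation

def series_table(s: LesionSeries) -> pd.DataFrame:
    """Long-format table: one row per (day, affected region), plus one TOTAL
    row per day carrying the summed area and the percent of the whole
    cortex. Columns: day, region, area_mm2, percent."""
    rows = []
    for day, (_, result) in s.entries.items():
        for rid in sorted(result.per_region):
            area, pct = result.per_region[rid]
            rows.append({"day": day, "region": rid, "area_mm2": area,
                         "percent": pct})
        rows.append({"day": day, "region": "TOTAL",
                     "area_mm2": result.total_area_mm2,
                     "percent": result.total_percent_of_cortex})
    return pd.DataFrame(rows, columns=["day", "region", "area_mm2", "percent"])
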