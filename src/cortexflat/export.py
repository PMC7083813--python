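"""Result serialization and map rendering.

Quantification results go to RFC-4180 CSV; the unfolded map with the lesion
overlay is rendered to TIFF (uncompressed RGB raster) and PDF (vector) from
one shared scene description, and both are bundled into a ZIP. Time-series
get a static per-region chart plus numbered PNG transition frames.

Rendering is physically scaled: one template millimetre maps to
``dpi / 25.4`` raster pixels, and outputs are byte-deterministic for fixed
inputs (no timestamps are embedded).
"""

from __future__ import annotations

import io
import logging
import zipfile
from dataclasses import dataclass

import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure
from matplotlib.patches import Polygon as MplPolygon
from PIL import Image

from .geometry import ContourStyle
from .mapper import LesionContour, QuantificationResult
from .template import Template
from .timeseries import LesionSeries, align_contours, interpolate_transition

log = logging.getLogger(__name__)

__all__ = [
    "results_csv",
    "render_map",
    "render_frames",
    "chart_png",
    "bundle_zip",
    "MapRender",
]

_LINESTYLES = {"solid": "-", "dashed": "--", "dotted": ":"}
#: fixed ZIP member timestamp (DOS epoch) for reproducible archives
_ZIP_DATE = (1980, 1, 1, 0, 0, 0)


# ---------------------------------------------------------------------------
# CSV

def _fmt(v: float) -> str:
    return f"{v:.2f}"


def results_csv(q) -> str:
    """Serialize quantification results to CSV text.

    Accepts a single :class:`QuantificationResult` or a long-format series
    table (DataFrame with day/region/area_mm2/percent columns). Header is
    ``day,region,area_mm2,percent``; per-region rows are followed by a
    ``TOTAL`` row per day carrying the summed area and the percent of the
    whole cortex. Floats are printed with 2 decimals, LF line endings.
    """
    lines = ["day,region,area_mm2,percent"]
    if isinstance(q, QuantificationResult):
        for rid in sorted(q.per_region):
            area, pct = q.per_region[rid]
            lines.append(f"{q.day},{rid},{_fmt(area)},{_fmt(pct)}")
        lines.append(f"{q.day},TOTAL,{_fmt(q.total_area_mm2)},"
                     f"{_fmt(q.total_percent_of_cortex)}")
    else:
        for _, row in q.iterrows():
            lines.append(f"{int(row['day'])},{row['region']},"
                         f"{_fmt(row['area_mm2'])},{_fmt(row['percent'])}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# map rendering

@dataclass(frozen=True)
class MapRender:
    """Rendered map payloads (bytes) in the supported formats."""

    png: bytes
    tiff: bytes
    pdf: bytes

    def bundle(self) -> bytes:
        return bundle_zip({"map.tiff": self.tiff, "map.pdf": self.pdf})


def _scene_figure(t: Template, contours: list[LesionContour],
                  style: ContourStyle) -> Figure:
    xmin, ymin, xmax, ymax = t.bounds
    r = t.units_per_mm
    width_in = (xmax - xmin) / r / 25.4
    height_in = (ymax - ymin) / r / 25.4
    fig = Figure(figsize=(width_in, height_in), dpi=style.dpi)
    ax = fig.add_axes((0.0, 0.0, 1.0, 1.0))
    ax.set_axis_off()
    ax.set_xlim(xmin, xmax)
    ax.set_ylim(ymax, ymin)  # anterior (small y) at the top, as drawn in SVG

    for deco in t.decorations:
        ax.plot(deco[:, 0], deco[:, 1], color="#aaaaaa", linewidth=0.6)
    ax.plot(t.rhinal_fissure[:, 0], t.rhinal_fissure[:, 1], color="#666666",
            linewidth=0.8, linestyle="--")
    for poly in t.regions.values():
        closed = np.vstack([poly, poly[:1]])
        ax.plot(closed[:, 0], closed[:, 1], color="#222222", linewidth=0.6)

    for c in contours:
        verts = c.vertices
        if len(verts) < 3:
            continue
        # border_width 0 suppresses the outline entirely
        edge = style.border_color if style.border_width > 0 else "none"
        ax.add_patch(MplPolygon(
            verts, closed=True, facecolor=style.fill_color,
            alpha=None, edgecolor=edge,
            linewidth=style.border_width,
            linestyle=_LINESTYLES[style.border_style],
            antialiased=False, zorder=3))
        # apply fill transparency only to the face, keeping the border solid
        patch = ax.patches[-1]
        fc = patch.get_facecolor()
        patch.set_facecolor((fc[0], fc[1], fc[2], style.fill_alpha))
    return fig


def render_map(t: Template, contours: list[LesionContour] | None = None,
               style: ContourStyle | None = None) -> MapRender:
    """Render the unfolded map with lesion overlays.

    All template SVG objects, including purely decorative ones, are drawn;
    lesions are filled and outlined per ``style``. Returns PNG/TIFF/PDF
    payloads; ``MapRender.bundle()`` zips TIFF+PDF for download-style export.
    """
    style = style or ContourStyle()
    contours = contours or []
    fig = _scene_figure(t, contours, style)
    canvas = FigureCanvasAgg(fig)

    png_buf = io.BytesIO()
    fig.savefig(png_buf, format="png", dpi=style.dpi,
                metadata={"Software": None})
    canvas.draw()
    rgba = np.asarray(canvas.buffer_rgba())
    tiff_buf = io.BytesIO()
    Image.fromarray(rgba[..., :3], mode="RGB").save(
        tiff_buf, format="TIFF", compression=None)
    pdf_buf = io.BytesIO()
    fig.savefig(pdf_buf, format="pdf", dpi=style.dpi,
                metadata={"CreationDate": None, "Producer": None,
                          "Creator": None})
    return MapRender(png=png_buf.getvalue(), tiff=tiff_buf.getvalue(),
                     pdf=pdf_buf.getvalue())


# ---------------------------------------------------------------------------
# time series

def chart_png(table, style: ContourStyle | None = None) -> bytes:
    """Static line chart of percent affected per region across days."""
    style = style or ContourStyle()
    fig = Figure(figsize=(6, 4), dpi=style.dpi)
    ax = fig.add_subplot(111)
    for region, group in table.groupby("region"):
        ax.plot(group["day"], group["percent"], marker="o", label=region,
                linewidth=2 if region == "TOTAL" else 1)
    ax.set_xlabel("day")
    ax.set_ylabel("% of region affected")
    ax.legend(fontsize=7, ncols=2)
    FigureCanvasAgg(fig)
    buf = io.BytesIO()
    fig.savefig(buf, format="png", metadata={"Software": None})
    return buf.getvalue()


def render_frames(series: LesionSeries, style: ContourStyle | None = None,
                  steps_per_transition: int = 10) -> list[bytes]:
    """PNG frames of the lesion evolving between consecutive days.

    Each consecutive day pair contributes ``steps_per_transition`` linearly
    interpolated frames (dummy points are added to the sparser contour for
    the blend and do not alter its area); the final day's contour closes the
    sequence. With a single day, one frame is returned.
    """
    style = style or ContourStyle()
    days = series.days
    contours = [series.entries[d][0] for d in days]
    frames: list[bytes] = []

    def frame_of(contour):
        return render_map(series.template, [contour], style).png

    if len(contours) == 1:
        return [frame_of(contours[0])]
    for a, b in zip(contours[:-1], contours[1:]):
        a2, b2 = align_contours(a, b)
        for tau in np.linspace(0.0, 1.0, steps_per_transition, endpoint=False):
            frames.append(frame_of(interpolate_transition(a2, b2, float(tau))))
    frames.append(frame_of(contours[-1]))
    return frames


# ---------------------------------------------------------------------------
# bundling

def bundle_zip(members: dict[str, bytes | str]) -> bytes:
    """Deterministic ZIP of named payloads (fixed timestamps)."""
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(members):
            data = members[name]
            if isinstance(data, str):
                data = data.encode("utf-8")
            info = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, data)
    return buf.getvalue()
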