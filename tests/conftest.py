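"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from matplotlib.path import Path as MplPath

from cortexflat import generate_synthetic_template, parse_template, rhinal_x_at

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def flat_template():
    """4x4-region template with a straight vertical rhinal fissure,
    r = 10, ap_zero = 0 (AP span 0 to -4 mm), no per-plate jitter."""
    svg, atlas = generate_synthetic_template(
        16, ap_span=(0.0, -4.0), units_per_mm=10.0, seed=0, n_plates=21,
        medial_to_rhinal_mm=6.0, medial_to_lateral_mm=8.0, grid=(4, 4),
        jitter=0.0)
    return parse_template(svg, atlas)


@pytest.fixture(scope="session")
def jittered_template():
    """Template with the realistic defaults (AP +3.20 to -4.96, 40 plates,
    2% per-plate variation of the medial->rhinal length)."""
    svg, atlas = generate_synthetic_template(16, seed=1)
    return parse_template(svg, atlas)


# ---------------------------------------------------------------------------
# independent geometry oracles

def monte_carlo_area(vertices, n_points, rng):
    """Rejection-sampling area estimate of a polygon inside its bbox."""
    v = np.asarray(vertices, dtype=float)
    lo, hi = v.min(axis=0), v.max(axis=0)
    pts = rng.uniform(lo, hi, size=(n_points, 2))
    inside = MplPath(v).contains_points(pts)
    bbox_area = float(np.prod(hi - lo))
    return bbox_area * inside.mean()


def raster_intersection_area(a, b, n_cells=1200):
    """Fine-grid rasterization estimate of area(a ∩ b)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    lo = np.minimum(a.min(axis=0), b.min(axis=0))
    hi = np.maximum(a.max(axis=0), b.max(axis=0))
    xs = np.linspace(lo[0], hi[0], n_cells, endpoint=False)
    ys = np.linspace(lo[1], hi[1], n_cells, endpoint=False)
    dx, dy = (hi[0] - lo[0]) / n_cells, (hi[1] - lo[1]) / n_cells
    gx, gy = np.meshgrid(xs + dx / 2, ys + dy / 2)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = MplPath(a).contains_points(pts) & MplPath(b).contains_points(pts)
    return inside.sum() * dx * dy


def random_star_polygon(rng, n_vertices=12, center=(0.0, 0.0), radius=1.0):
    """Random star-shaped (hence simple) polygon around a centre."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(0.4, 1.0, n_vertices) * radius
    cx, cy = center
    return np.column_stack([cx + radii * np.cos(angles),
                            cy + radii * np.sin(angles)])


# ---------------------------------------------------------------------------
# synthetic lesions with known ground truth

def ellipse_ring(center, semi_axes, n=256):
    """Dense polygon approximation of an ellipse (template units)."""
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + semi_axes[0] * np.cos(th),
                            center[1] + semi_axes[1] * np.sin(th)])


def sample_lesion_measurements(template, lesion_ring, spacing_mm, rng,
                               shrink_range=(0.85, 0.95)):
    """Convert a painted lesion polygon into per-slice MB/M1/M2/M3 rows.

    Mimics the histology measurement procedure: at every ``spacing_mm`` AP
    step covered by the lesion, the horizontal chord of the lesion polygon
    gives the medial/lateral edges; distances are expressed relative to the
    midline and the rhinal fissure and multiplied by a per-slice shrinkage
    factor (the normalization step must undo it). Returns CSV text.
    """
    from shapely.geometry import LineString, Polygon as ShapelyPolygon

    poly = ShapelyPolygon(lesion_ring)
    r = template.units_per_mm
    y_lo, y_hi = poly.bounds[1], poly.bounds[3]
    mb_hi = float(template.y_to_mb(y_lo))
    mb_lo = float(template.y_to_mb(y_hi))
    rows = []
    mb = mb_lo + spacing_mm / 2
    xmin_b, _, xmax_b, _ = poly.bounds
    while mb < mb_hi:
        y = template.mb_to_y(mb)
        chord = LineString([(xmin_b - 1, y), (xmax_b + 1, y)]).intersection(poly)
        if not chord.is_empty and chord.length > 1e-9:
            x0, x1 = chord.bounds[0], chord.bounds[2]
            fx = rhinal_x_at(template, y)
            s = rng.uniform(*shrink_range)
            m1 = s * (x0 - template.midline_x) / r
            m2 = s * (x1 - x0) / r
            m3 = s * (fx - x1) / r
            rows.append(f"{mb},{m1},{m2},{m3}")
        mb += spacing_mm
    return "\n".join(rows)
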