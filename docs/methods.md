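# Methods

This note documents the model, the conventions and the numerical choices
behind `cortexflat`, and what the synthetic validation does and does not
establish.

## The unfolded-map model

The cortex of one hemisphere is represented as a 2D sheet in which every
coronal level is a horizontal line: the along-surface (mediolateral)
distance of a point from the midline becomes its x coordinate, and the
anteroposterior (AP) position its y coordinate. The template stores this
flattening once — labeled region polygons, the rhinal fissure polyline, the
AP origin (`ap_zero`) and the drawing-units-per-millimetre constant r — and
every lesion is mapped into that fixed frame.

Axis conventions (asserted by the tests against the synthetic template):

* y increases posteriorly; MB (mm, anterior positive) maps to
  `y = ap_zero − r·MB`, so anterior lies at the top of a map drawn in SVG
  coordinates;
* x increases medial → lateral, midline at the smallest x.

The model assumes the lesion is, per slice, a single contiguous
mediolateral interval (one medial and one lateral edge); per-slice
multi-focal lesions are out of scope, as in the manual unfolding procedure
the method automates.

## Measurement model and normalization

Each slice is measured along the pial surface: M1 (medial reference point →
medial lesion edge), M2 (medial → lateral lesion edge), M3 (lateral edge →
rhinal fissure; negative when the lesion passes the fissure, in which case
M2 stops at the fissure), plus the slice's AP coordinate MB. Histological
processing shrinks tissue, and individual brains differ in size, so the
measured inter-reference distance

    D = M1 + M2 + M3   (M3 ≥ 0)        D = M1 + M2   (M3 < 0)

is compared against the atlas reference length L(MB) for the same span and
M2, M3 are multiplied by ρ = L(MB)/D. Two consequences the test suite
exercises: scaling all of a slice's measurements by k > 0 cancels exactly
(the map is invariant to uniform shrinkage), and measurements that already
equal atlas distances map with ρ = 1. Ratios outside [0.25, 4] are almost
certainly data errors and are flagged, not rejected.

The translation step anchors the lesion laterally on the rhinal fissure:
lateral edge at `rh(y) − r·M3′`, medial edge `r·M2′` further medially. An
alternative reading that anchors the medial edge at the midline using
`r·M1′` exists in the literature describing this workflow; it conflicts
with M1 being dropped by the normalization step and with the fissure's role
as the lateral reference, so the fissure-anchored form is the default and
the midline-anchored one is available behind `map_lesion(..., anchor="midline")`.

L(MB) is taken from the nearest atlas plate (ties anterior): plates are
~0.2 mm apart and this matches the manual practice of assigning a section
to its closest plate. No interpolation between plates is attempted.

The direction of the MRI half-voxel AP shift (slice coordinates refer to
slice centres) is not anatomically fixed by convention; the default is
anterior (+slice_depth/2) and the sign is a parameter of
`apply_mri_shift`. The shift is recorded on the measurement set and a
second application is an error.

## Geometry

* **Bezier flattening.** Template paths are flattened by de Casteljau
  midpoint subdivision until both inner control points lie within the
  flatness tolerance of the chord. Default tolerance: 0.01 template units —
  at the conventional r = 10 that is 0.001 mm, an order below the 0.01-mm
  AP placement precision the pipeline maintains. The emitted polyline
  deviates from the true curve by at most about twice the tolerance
  (property-tested against dense Bernstein evaluation).
* **Catmull-Rom.** Contour edges are densified with the parameterized
  (Barry-Goldman) Catmull-Rom recursion; α = 0.5 (centripetal) by default
  because it is the cusp- and self-intersection-free member of the family.
  Endpoints are clamped by duplicating the terminal control points; the
  zero-length knot interval this creates is resolved by its exact limit
  (the affine combination of two coincident points is that point).
  Coincident adjacent control points skip the degenerate segment with a
  warning. Each lesion edge is splined separately and the ring closed
  afterwards; if spline overshoot ever self-intersects the ring, the
  contour falls back to linear interpolation as a whole, with a warning
  (per-segment repair of a closed ring is ill-defined when a crossing spans
  segments).
* **Boolean operations.** Region/lesion intersections are delegated to
  shapely (GEOS), with vertices snapped to a 1e-9 template-unit grid first
  so near-degenerate edges cannot produce sliver artifacts. The snap bounds
  exact-arithmetic comparisons: intersection areas are reproduced to
  ~perimeter × 1e-9, which the tests treat as "exact to 1e-6 area units".
  Intersections of two hole-free polygons are hole-free, so pieces are
  returned as exterior rings.
* **Orientation.** The assembled contour (medial edge ascending MB, lateral
  edge descending) has positive shoelace area under the y-posterior axis
  convention.

## Time series

Per-day measurement sets map independently; the per-day table reports each
affected region and a TOTAL row. For transition rendering between two days
the sparser contour receives *dummy points* — midpoints of its currently
longest segments, per edge (medial matched with medial, lateral with
lateral) — until vertex counts match. Insertions lie on existing edges, so
the contour's area is provably unchanged, correspondence stays monotone in
arc length, and the flags allow the dummies to be stripped afterwards. The
blend is a vertex-wise convex combination. The original tool's exact
dummy-placement rule is not published; this placement is the package's own
documented choice, and the evolution export is a numbered PNG frame
sequence plus a static chart rather than an in-browser-encoded video.

## Rendering and exports

TIFF (uncompressed RGB) and PDF are drawn from one scene description; one
template millimetre maps to dpi/25.4 raster pixels exactly (figure size is
derived from the template bounds), which the tests verify by counting fill
pixels of a known-area lesion. Lesion fills are drawn without antialiasing
and above the template line work; `border_width = 0` suppresses the
outline. No timestamps are embedded in PNG/PDF/ZIP payloads, so all
exports are byte-deterministic for fixed inputs. Result CSV uses
`day,region,area_mm2,percent` with two decimals; full precision is kept
internally.

## Synthetic templates and what the tests show

`generate_synthetic_template` emits a grid of rectangular regions of
exactly known area spanning the full mediolateral extent, a rhinal fissure
polyline drawn through per-plate medial→rhinal lengths, and a consistent
atlas-length JSON. Defaults mirror the real mouse template: 40 plates from
+3.20 to −4.96 mm bregma (~0.21 mm spacing), r = 10, a 6-mm medial→rhinal
length with ±2 % seeded per-plate variation, cortex extending 2 mm lateral
to the fissure. The generator is deterministic per seed and round-trips
through the parser.

The validation pipeline paints an elliptical ground-truth lesion
(1.8 × 1.2 mm semi-axes) on this template, samples it into slice
measurements at 0.2-mm spacing with per-slice shrinkage factors drawn from
[0.85, 0.95] (a realistic histology range), and maps it back: total area is
recovered within ~3.5 % and every region's percentage within ~2.5 points.
Problem sizes used throughout the validation — 50 polygons × 10⁶
Monte-Carlo points for the area oracle, 50 pairs against a 1200²-cell
rasterization for intersections, 100 random lesions for conservation — run
in seconds on one CPU.

What this does *not* show: recovery quality on the published atlas-derived
template (curved region boundaries, non-straight fissure), robustness to
operator error in identifying lesion edges (the dominant error source in
practice), or behaviour on multi-focal lesions. Rectangular synthetic
regions make region-boundary effects milder than curved cytoarchitectonic
boundaries would be; the residual recovery error here is dominated by tip
truncation (no measurement slice falls beyond the first/last section, as in
the manual procedure) and chord-vs-arc discretization, both of which shrink
with slice spacing.

## Degenerate inputs and edge behaviour

Single-slice sets produce a degenerate contour and an all-zero
quantification with a warning, not an error. A medial edge that would cross
the midline is clipped to the cortex boundary. Lesions wholly outside the
cortex quantify to zero with a warning. Duplicate MB values are rejected at
import (the contour needs one edge pair per level), `.xls` workbooks are
rejected with a pointer to `.xlsx`/CSV, and measurement files are parsed
locale-independently (decimal point only).
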