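"""Normalization, translation, end-to-end mapping and quantification."""

import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cortexflat import (AtlasLengths, SliceMeasurement, map_lesion,
                        normalize_slice, quantify, read_measurements,
                        translate)
from cortexflat.geometry import signed_area
from cortexflat.mapper import AdjustedSlice, LesionContour, MapperError
from cortexflat.template import parse_template

from conftest import monte_carlo_area, random_star_polygon

ATLAS_ONE = AtlasLengths.from_json(json.dumps(
    [{"ap": -1.0, "medial_to_rhinal": 4.0, "medial_to_lateral": 6.0}]))


def vertical_fissure_template(fissure_x=100.0, r=10.0, mr=None):
    """ap_zero = 0, straight fissure at the given x."""
    mr = fissure_x / r if mr is None else mr
    svg = f"""<svg xmlns="http://www.w3.org/2000/svg" ap_zero="0" units_per_mm="{r}">
      <path id="A_CTX" d="M 0 0 L {fissure_x + 20} 0 L {fissure_x + 20} 40 L 0 40 Z"/>
      <path id="rhinal_fissure" d="M {fissure_x} -5 L {fissure_x} 45"/>
    </svg>"""
    atlas = json.dumps([
        {"ap": -mb, "medial_to_rhinal": mr, "medial_to_lateral": mr + 2}
        for mb in np.arange(0.5, 4.0, 0.5)])
    return parse_template(svg, atlas)


class TestNormalize:
    def test_identity_scaling(self):
        adj = normalize_slice(SliceMeasurement(-1.0, 1.0, 2.0, 1.0), ATLAS_ONE)
        assert adj.scale_ratio == pytest.approx(1.0)
        assert adj.m2_adj == pytest.approx(2.0)
        assert adj.m3_adj == pytest.approx(1.0)

    def test_shrinkage_doubles(self):
        atlas = AtlasLengths.from_json(json.dumps(
            [{"ap": -1.0, "medial_to_rhinal": 8.0, "medial_to_lateral": 10.0}]))
        adj = normalize_slice(SliceMeasurement(-1.0, 1.0, 2.0, 1.0), atlas)
        assert adj.scale_ratio == pytest.approx(2.0)
        assert adj.m2_adj == pytest.approx(4.0)
        assert adj.m3_adj == pytest.approx(2.0)

    def test_fissure_crossing_uses_m1_plus_m2(self):
        atlas = AtlasLengths.from_json(json.dumps(
            [{"ap": -1.0, "medial_to_rhinal": 8.0, "medial_to_lateral": 10.0}]))
        adj = normalize_slice(SliceMeasurement(-1.0, 3.0, 1.0, -0.5), atlas)
        assert adj.scale_ratio == pytest.approx(2.0)  # D = 3 + 1 = 4
        assert adj.m2_adj == pytest.approx(2.0)
        assert adj.m3_adj == pytest.approx(-1.0)

    def test_implausible_ratio_warns(self, caplog):
        atlas = AtlasLengths.from_json(json.dumps(
            [{"ap": -1.0, "medial_to_rhinal": 100.0, "medial_to_lateral": 101.0}]))
        with caplog.at_level("WARNING"):
            normalize_slice(SliceMeasurement(-1.0, 1.0, 2.0, 1.0), atlas)
        assert any("implausible" in r.message for r in caplog.records)


class TestTranslate:
    def test_stated_convention(self):
        t = vertical_fissure_template()
        adj = [AdjustedSlice(mb=-1.0, m2_adj=2.0, m3_adj=1.0, scale_ratio=1.0)]
        med, lat = translate(adj, t)
        assert np.allclose(lat[0], [90.0, 10.0])
        assert np.allclose(med[0], [70.0, 10.0])

    def test_zero_m3_lands_on_fissure(self):
        t = vertical_fissure_template()
        adj = [AdjustedSlice(mb=-1.0, m2_adj=2.0, m3_adj=0.0, scale_ratio=1.0)]
        _, lat = translate(adj, t)
        assert np.allclose(lat[0], [100.0, 10.0])

    def test_negative_m3_lands_beyond_fissure(self):
        t = vertical_fissure_template()
        adj = [AdjustedSlice(mb=-1.0, m2_adj=2.0, m3_adj=-1.0, scale_ratio=1.0)]
        _, lat = translate(adj, t)
        assert np.allclose(lat[0], [110.0, 10.0])

    def test_medial_overshoot_clipped_to_midline(self, caplog):
        t = vertical_fissure_template()
        adj = [AdjustedSlice(mb=-1.0, m2_adj=15.0, m3_adj=0.0, scale_ratio=1.0)]
        with caplog.at_level("WARNING"):
            med, _ = translate(adj, t)
        assert med[0][0] == t.midline_x


class TestMapLesion:
    def csv_rows(self, t, mb_values, m1=2.0, m2=2.0):
        rows = []
        for mb in mb_values:
            from cortexflat import atlas_length_at
            mr = atlas_length_at(t.atlas_lengths, mb)
            rows.append(f"{mb},{m1},{m2},{mr - m1 - m2}")
        return "\n".join(rows)

    def test_identity_case_matches_hand_computed_coordinates(self, flat_template):
        t = flat_template
        ms = read_measurements(self.csv_rows(t, [-2.0, -1.0]))
        c = map_lesion(ms, t)
        r = t.units_per_mm
        # lateral edge at fissure - r*m3, medial at lateral - r*m2
        for (x, y), mb in zip(c.lateral, [-2.0, -1.0]):
            assert y == pytest.approx(t.mb_to_y(mb))
            assert x == pytest.approx(60.0 - r * (6.0 - 4.0))
        for (x, _), _ in zip(c.medial, [-2.0, -1.0]):
            assert x == pytest.approx(40.0 - r * 2.0)

    def test_row_order_invariance(self, flat_template):
        rows = self.csv_rows(flat_template, [-2.0, -1.0, -3.0])
        fwd = map_lesion(read_measurements(rows), flat_template)
        rev = map_lesion(read_measurements("\n".join(rows.splitlines()[::-1])),
                         flat_template)
        assert np.allclose(fwd.vertices, rev.vertices)

    def test_assembled_polygon_is_anticlockwise(self, flat_template):
        ms = read_measurements(self.csv_rows(flat_template, [-3.0, -2.0, -1.0]))
        c = map_lesion(ms, flat_template)
        assert signed_area(c.vertices) > 0

    def test_scale_invariance_per_slice(self, flat_template):
        """Multiplying one slice's m1,m2,m3 by k>0 leaves the contour
        unchanged when m3 >= 0 (normalization cancels k)."""
        base = self.csv_rows(flat_template, [-2.0, -1.5, -1.0])
        lines = base.splitlines()
        mb, m1, m2, m3 = (float(v) for v in lines[1].split(","))
        for k in (0.5, 0.9, 2.7):
            lines_k = list(lines)
            lines_k[1] = f"{mb},{m1 * k},{m2 * k},{m3 * k}"
            c0 = map_lesion(read_measurements(base), flat_template)
            ck = map_lesion(read_measurements("\n".join(lines_k)), flat_template)
            assert np.allclose(c0.vertices, ck.vertices)

    @given(st.floats(0.3, 3.0))
    def test_scale_invariance_property(self, k):
        t = vertical_fissure_template()
        s = SliceMeasurement(-1.0, 1.0, 2.0, 7.0)
        sk = SliceMeasurement(-1.0, 1.0 * k, 2.0 * k, 7.0 * k)
        a = normalize_slice(s, t.atlas_lengths)
        b = normalize_slice(sk, t.atlas_lengths)
        assert b.m2_adj == pytest.approx(a.m2_adj)
        assert b.m3_adj == pytest.approx(a.m3_adj)

    def test_single_slice_quantifies_to_zero(self, flat_template, caplog):
        ms = read_measurements(self.csv_rows(flat_template, [-2.0]))
        with caplog.at_level("WARNING"):
            c = map_lesion(ms, flat_template)
            q = quantify(c, flat_template)
        assert q.total_area_mm2 == 0.0
        assert q.per_region == {}

    def test_ap_placement_matches_input_mb(self, jittered_template):
        """Converted back through (ap_zero - y)/r the contour reproduces the
        input MB to well within 0.01 mm."""
        t = jittered_template
        mbs = [-3.0, -1.6, -0.2, 1.4, 2.8]
        ms = read_measurements(self.csv_rows(t, mbs))
        c = map_lesion(ms, t)
        recovered = t.y_to_mb(c.medial[:, 1])
        assert np.max(np.abs(recovered - np.array(mbs))) < 0.01


class TestQuantify:
    def test_lesion_equal_to_region_is_100_percent(self, flat_template):
        t = flat_template
        poly = t.regions["R05"]
        ys = np.unique(poly[:, 1])
        xs = np.unique(poly[:, 0])
        med = np.array([[xs[0], ys[1]], [xs[0], ys[0]]])
        lat = np.array([[xs[1], ys[1]], [xs[1], ys[0]]])
        c = LesionContour(medial=med, lateral=lat)
        q = quantify(c, t)
        assert q.region_percent("R05") == pytest.approx(100.0)
        assert q.total_area_mm2 == pytest.approx(t.region_area_mm2("R05"))

    def test_half_of_two_adjacent_regions(self):
        svg, atlas = __import__("cortexflat").generate_synthetic_template(
            2, ap_span=(0.0, -1.0), units_per_mm=10.0, grid=(2, 1),
            medial_to_rhinal_mm=1.0, medial_to_lateral_mm=2.0, jitter=0.0,
            n_plates=6)
        t = parse_template(svg, atlas)
        # lesion 2 mm wide x 0.5 mm tall: lower half of both unit squares
        c = LesionContour(medial=np.array([[0.0, 5.0], [0.0, 10.0]]),
                          lateral=np.array([[20.0, 5.0], [20.0, 10.0]]))
        q = quantify(c, t)
        assert q.region_percent("R00") == pytest.approx(50.0)
        assert q.region_percent("R01") == pytest.approx(50.0)
        assert q.total_area_mm2 == pytest.approx(1.0)

    def test_outside_cortex_is_all_zero(self, flat_template, caplog):
        c = LesionContour(medial=np.array([[-50.0, 0.0], [-50.0, 10.0]]),
                          lateral=np.array([[-40.0, 0.0], [-40.0, 10.0]]))
        with caplog.at_level("WARNING"):
            q = quantify(c, flat_template)
        assert q.total_area_mm2 == 0.0

    def test_per_region_areas_match_monte_carlo(self, flat_template):
        rng = np.random.default_rng(21)
        t = flat_template
        lesion = random_star_polygon(rng, n_vertices=14, center=(40, 20),
                                     radius=18)
        c = LesionContour(medial=lesion[:8], lateral=lesion[8:][::-1])
        q = quantify(c, t)
        r2 = t.units_per_mm ** 2
        checked = 0
        for rid, (area, _) in q.per_region.items():
            if area < 0.05:
                continue
            inter = __import__("cortexflat").polygon_intersection(
                lesion, t.regions[rid])
            mc = sum(monte_carlo_area(p, 400_000, rng) for p in inter) / r2
            assert area == pytest.approx(mc, rel=0.03)
            checked += 1
        assert checked >= 3

    def test_conservation_and_totals(self, flat_template):
        rng = np.random.default_rng(13)
        t = flat_template
        lesion = random_star_polygon(rng, n_vertices=16, center=(35, 18),
                                     radius=16)
        c = LesionContour(medial=lesion[:8], lateral=lesion[8:][::-1])
        q = quantify(c, t)
        from cortexflat.geometry import to_shapely
        direct = to_shapely(lesion).intersection(t.cortex_shape).area / t.units_per_mm**2
        assert q.total_area_mm2 == pytest.approx(direct, rel=1e-6)
        assert q.total_percent_of_cortex == pytest.approx(
            100 * q.total_area_mm2 / t.cortex_area_mm2)

    def test_monotone_in_lesion_size(self, flat_template):
        t = flat_template
        small = LesionContour(medial=np.array([[20.0, 10.0], [20.0, 25.0]]),
                              lateral=np.array([[50.0, 10.0], [50.0, 25.0]]))
        big = LesionContour(medial=np.array([[15.0, 5.0], [15.0, 30.0]]),
                            lateral=np.array([[60.0, 5.0], [60.0, 30.0]]))
        qs, qb = quantify(small, t), quantify(big, t)
        for rid, (area, _) in qs.per_region.items():
            assert qb.region_area(rid) >= area - 1e-12
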