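"""Region geometry oracles: analytic annulus areas on circular islets,
nearest-boundary de-overlap, exocrine placement, and brute-force
cell-to-region assignment agreement."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Point, Polygon, box

from isletrings import RingSpec, TissueConfig, generate_tissue
from isletrings.io import write_geojson, geometry_to_feature
from isletrings.regions import (
    RegionAnnotation,
    assign_cells,
    load_idi_regions,
    make_peri_islet,
    make_ring_set,
    sample_exocrine,
    segment_islets,
)

TISSUE = box(0, 0, 4000, 4000)


def circle(cx, cy, r):
    return Point(cx, cy).buffer(r, quad_segs=64)


class TestSegmentIslets:
    def test_blank_channel_gives_no_islets(self):
        assert segment_islets(np.zeros((500, 500), np.uint8), 0.325) == []

    def test_single_islet_recovered_with_high_iou(self, default_tissue):
        stack, gt = default_tissue
        polys = segment_islets(stack["INS"], stack.pixel_size_um)
        assert len(polys) == len(gt.islet_polygons)
        for true_poly in gt.islet_polygons:
            best = max(polys, key=lambda p: p.intersection(true_poly).area)
            iou = best.intersection(true_poly).area / best.union(true_poly).area
            assert iou >= 0.90

    def test_segmented_islets_disjoint(self, default_tissue):
        stack, _ = default_tissue
        polys = segment_islets(stack["INS"], stack.pixel_size_um)
        for i, a in enumerate(polys):
            for b in polys[i + 1:]:
                assert a.intersection(b).area == 0.0


class TestIdiLoading:
    def test_empty_collection_gives_empty_list(self, tmp_path):
        path = tmp_path / "idi.geojson"
        write_geojson([], path)
        assert load_idi_regions(path) == []

    def test_round_trip_is_vertex_exact(self, tmp_path):
        poly = Polygon([(0, 0), (100, 0), (100, 80), (0, 80)])
        path = tmp_path / "idi.geojson"
        write_geojson([geometry_to_feature(poly, {"classification": "Islet-IDI"})], path)
        (loaded,) = load_idi_regions(path)
        assert list(loaded.exterior.coords) == list(poly.exterior.coords)

    def test_idi_overlapping_ici_raises(self, tmp_path):
        idi = Polygon([(0, 0), (100, 0), (100, 80), (0, 80)])
        path = tmp_path / "idi.geojson"
        write_geojson([geometry_to_feature(idi, {"classification": "Islet-IDI"})], path)
        with pytest.raises(ValueError, match="overlaps"):
            load_idi_regions(path, ici_polygons=[circle(50, 40, 30)])


class TestPeriIslet:
    def test_annulus_area_matches_analytic_formula(self):
        islet = circle(2000, 2000, 100)
        (peri,) = make_peri_islet([islet], 10.0, TISSUE)
        assert peri.area_um2 == pytest.approx(np.pi * (110**2 - 100**2), rel=0.01)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            make_peri_islet([circle(0, 0, 50)], 0.0, TISSUE)

    def test_close_islets_split_on_equidistant_line(self):
        # boundaries 12 um apart: collars overlap and must be de-overlapped
        a, b = circle(1000, 1000, 50), circle(1112, 1000, 50)
        peri = make_peri_islet([a, b], 10.0, TISSUE)
        assert len(peri) == 2
        inter = peri[0].polygon.intersection(peri[1].polygon)
        assert inter.area < 1e-6
        annulus = np.pi * (60**2 - 50**2)
        assert peri[0].area_um2 + peri[1].area_um2 < 2 * annulus
        # sampled points sit with the nearer islet (0.5 um slack)
        for reg, own, other in ((peri[0], a, b), (peri[1], b, a)):
            pts = shapely.points(*np.meshgrid(np.arange(940, 1180, 4.0),
                                              np.arange(940, 1060, 4.0))).ravel()
            inside = shapely.within(pts, reg.polygon)
            for p in pts[inside]:
                assert p.distance(own.exterior) <= p.distance(other.exterior) + 0.5

    def test_tissue_clipping(self):
        islet = circle(30, 2000, 25)  # tissue edge cuts the collar
        (peri,) = make_peri_islet([islet], 10.0, box(20, 0, 4000, 4000))
        assert peri.polygon.bounds[0] >= 20 - 1e-6
        assert peri.area_um2 < np.pi * (35**2 - 25**2)


class TestRingSet:
    def test_ring_areas_match_analytic_annuli(self):
        islet = circle(2000, 2000, 50)
        rings = make_ring_set([islet], RingSpec(), TISSUE)
        assert len(rings) == 8
        by_class = {r.region_class: r for r in rings}
        assert by_class["ring_1"].area_um2 == pytest.approx(np.pi * (75**2 - 50**2), rel=0.01)
        assert by_class["ring_8"].area_um2 == pytest.approx(np.pi * (250**2 - 225**2), rel=0.01)

    def test_ring_areas_telescope_to_full_collar(self):
        islet = circle(2000, 2000, 70)
        rings = make_ring_set([islet], RingSpec(), TISSUE)
        total = sum(r.area_um2 for r in rings)
        assert total == pytest.approx(np.pi * (270**2 - 70**2), rel=0.01)

    def test_rings_of_neighbouring_islets_disjoint(self):
        a, b = circle(1000, 1000, 50), circle(1200, 1000, 50)  # 100 um apart
        rings = make_ring_set([a, b], RingSpec(), TISSUE)
        ra = [r for r in rings if r.parent_islet_id == 0]
        rb = [r for r in rings if r.parent_islet_id == 1]
        for x in ra:
            for y in rb:
                assert x.polygon.intersection(y.polygon).area < 1e-6

    def test_rings_exclude_all_islet_interiors(self):
        a, b = circle(1000, 1000, 50), circle(1180, 1000, 40)
        rings = make_ring_set([a, b], RingSpec(), TISSUE)
        for r in rings:
            assert r.polygon.intersection(a).area < 1e-6
            assert r.polygon.intersection(b).area < 1e-6

    def test_peri_islet_lies_within_first_ring_footprint(self):
        islet = circle(2000, 2000, 60)
        (peri,) = make_peri_islet([islet], 10.0, TISSUE)
        rings = make_ring_set([islet], RingSpec(), TISSUE)
        ring1 = next(r for r in rings if r.region_class == "ring_1")
        outside = peri.polygon.difference(ring1.polygon.union(islet)).area
        assert outside < 1e-3 * peri.area_um2


class TestExocrine:
    def test_zero_regions(self):
        rng = np.random.default_rng(0)
        assert sample_exocrine(TISSUE, [], [], 0, 500, rng) == []

    def test_default_layout_on_large_tissue(self):
        tissue = box(0, 0, 10000, 10000)
        islets = [circle(2000 + 1500 * i, 2000 + 1200 * j, 80)
                  for i in range(4) for j in range(4)]
        peri = make_peri_islet(islets, 10.0, tissue)
        rng = np.random.default_rng(7)
        squares = sample_exocrine(tissue, islets, peri, 15, 500, rng)
        assert len(squares) == 15
        polys = [s.polygon for s in squares]
        for i, a in enumerate(polys):
            assert tissue.contains(a)
            for b in polys[i + 1:]:
                assert not a.intersects(b)
            for obst in islets + [p.polygon for p in peri]:
                assert not a.intersects(obst)

    def test_seeded_placement_reproducible(self):
        tissue = box(0, 0, 8000, 8000)
        islets = [circle(3000, 3000, 100)]
        peri = make_peri_islet(islets, 10.0, tissue)
        s1 = sample_exocrine(tissue, islets, peri, 10, 400, np.random.default_rng(3))
        s2 = sample_exocrine(tissue, islets, peri, 10, 400, np.random.default_rng(3))
        for a, b in zip(s1, s2):
            assert a.polygon.equals(b.polygon)

    def test_infeasible_placement_reports_achieved_count(self):
        with pytest.raises(RuntimeError, match="placed only"):
            sample_exocrine(box(0, 0, 1200, 1200), [], [], 10, 500,
                            np.random.default_rng(0))


class TestAssignCells:
    def _regions(self):
        islet = circle(1000, 1000, 50)
        regs = [RegionAnnotation(0, "islet_ICI", islet, parent_islet_id=0)]
        regs += make_peri_islet([islet], 10.0, TISSUE, start_region_id=1)
        regs += make_ring_set([islet], RingSpec(), TISSUE, start_region_id=2)
        return regs

    def test_boundary_centroid_goes_to_inner_ring(self):
        regs = self._regions()
        ring1 = next(r for r in regs if r.region_class == "ring_1")
        vx, vy = ring1.polygon.exterior.coords[10]
        cells = pd.DataFrame({"cell_id": [1], "x_um": [vx], "y_um": [vy]})
        out = assign_cells(cells, regs)
        ring_rows = out[out["region_class"].str.startswith("ring_")]
        assert list(ring_rows["region_class"]) == ["ring_1"]

    def test_cell_outside_all_regions_unassigned(self):
        out = assign_cells(pd.DataFrame({"cell_id": [1], "x_um": [3900.0], "y_um": [3900.0]}),
                           self._regions())
        assert out.empty

    def test_assignment_invariant_under_region_order(self):
        regs = self._regions()
        rng = np.random.default_rng(0)
        cells = pd.DataFrame({
            "cell_id": np.arange(200),
            "x_um": rng.uniform(700, 1300, 200),
            "y_um": rng.uniform(700, 1300, 200),
        })
        a = assign_cells(cells, regs)
        shuffled = [regs[i] for i in rng.permutation(len(regs))]
        b = assign_cells(cells, shuffled)
        key = ["cell_id", "region_id"]
        assert a.sort_values(key, ignore_index=True).equals(b.sort_values(key, ignore_index=True))

    def test_agreement_with_brute_force_point_in_polygon(self):
        islets = [circle(1000, 1000, 60), circle(1500, 1200, 45)]
        regs = [RegionAnnotation(i, "islet_ICI", p, parent_islet_id=i)
                for i, p in enumerate(islets)]
        regs += make_peri_islet(islets, 10.0, TISSUE, start_region_id=2)
        regs += make_ring_set(islets, RingSpec(), TISSUE, start_region_id=4)
        rng = np.random.default_rng(1)
        n = 1000
        cells = pd.DataFrame({
            "cell_id": np.arange(n),
            "x_um": rng.uniform(600, 1900, n),
            "y_um": rng.uniform(600, 1700, n),
        })
        fast = assign_cells(cells, regs)
        # brute force: covers() over every (cell, region) pair, then the
        # same family-resolution rules applied independently
        rows = []
        for _, c in cells.iterrows():
            pt = Point(c["x_um"], c["y_um"])
            hits = [r for r in regs if r.polygon.covers(pt)]
            islet_hits = sorted((r for r in hits if r.region_class.startswith("islet")),
                                key=lambda r: r.region_id)
            if islet_hits:
                rows.append((c["cell_id"], islet_hits[0].region_id))
                continue
            peri_hits = sorted((r for r in hits if r.region_class == "peri_islet"),
                               key=lambda r: r.region_id)
            if peri_hits:
                rows.append((c["cell_id"], peri_hits[0].region_id))
            ring_hits = sorted((r for r in hits if r.region_class.startswith("ring_")),
                               key=lambda r: (int(r.region_class.split("_")[1]), r.region_id))
            if ring_hits:
                rows.append((c["cell_id"], ring_hits[0].region_id))
        brute = pd.DataFrame(rows, columns=["cell_id", "region_id"]).astype(int)
        fast_pairs = set(map(tuple, fast[["cell_id", "region_id"]].to_numpy()))
        brute_pairs = set(map(tuple, brute.to_numpy()))
        assert fast_pairs == brute_pairs
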