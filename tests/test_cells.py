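"""Exclusion regions, coordinate mapping, and panel merging."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

import serialign as sa
from serialign.cells import points_excluded, save_regions_geojson
from serialign.errors import ArgumentError, IntegrityError


def make_table(xy, phenotypes=None, slide_id="slide1", panel_id="panel1", prefix=None):
    xy = np.atleast_2d(np.asarray(xy, float))
    n = len(xy)
    prefix = prefix or slide_id
    return pd.DataFrame({
        "cell_id": [f"{prefix}_c{i}" for i in range(n)],
        "x": xy[:, 0], "y": xy[:, 1],
        "phenotype": phenotypes if phenotypes is not None else ["other"] * n,
        "panel_id": panel_id, "slide_id": slide_id,
    })


UNIT_SQUARE = sa.ExclusionRegion(Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]), "sq")


class TestPointExcluded:
    @pytest.mark.parametrize("point,expected", [
        ((0.5, 0.5), True),  # interior
        ((2.0, 2.0), False),  # exterior
        ((0.0, 0.5), True),  # boundary counts as excluded
        ((0.0, 0.0), True),  # vertex
    ])
    def test_unit_square_membership(self, point, expected):
        assert sa.point_excluded(point, [UNIT_SQUARE]) is expected

    def test_invalid_polygon_rejected_at_load(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(IntegrityError, match="self-intersecting"):
            sa.ExclusionRegion(bowtie, "bowtie")

    def test_matches_ray_casting_oracle(self, rng):
        def inside_oracle(p, verts):
            # even-odd ray casting, independent of shapely
            x, y = p
            hit = False
            for i in range(len(verts)):
                x1, y1 = verts[i]
                x2, y2 = verts[(i + 1) % len(verts)]
                if (y1 > y) != (y2 > y):
                    xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
                    if x < xint:
                        hit = not hit
            return hit

        for _ in range(5):
            hull_pts = rng.uniform(0, 100, (12, 2))
            poly = Polygon(hull_pts).convex_hull
            region = sa.ExclusionRegion(poly, "hull")
            verts = list(poly.exterior.coords)[:-1]
            pts = rng.uniform(-20, 120, (300, 2))
            mine = points_excluded(pts, [region])
            oracle = np.array([inside_oracle(p, verts) for p in pts])
            np.testing.assert_array_equal(mine, oracle)

    def test_geojson_roundtrip(self, tmp_path):
        path = tmp_path / "regions.geojson"
        save_regions_geojson([UNIT_SQUARE], path)
        loaded = sa.load_regions_geojson(path)
        assert len(loaded) == 1 and loaded[0].label == "sq"
        assert loaded[0].polygon.equals(UNIT_SQUARE.polygon)


class TestTransformCells:
    def test_identity_preserves_everything(self, rng):
        table = make_table(rng.uniform(0, 100, (30, 2)))
        out = sa.transform_cells(table, sa.CompositeTransform())
        pd.testing.assert_frame_equal(out, table)

    def test_known_rotation(self):
        table = make_table([(1.0, 0.0)])
        t = sa.CompositeTransform(sa.RigidTransform(np.pi / 2, (0, 0), (0, 0)))
        out = sa.transform_cells(table, t)
        assert out.loc[0, "x"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "y"] == pytest.approx(1.0)

    def test_non_coordinate_fields_bit_exact(self, rng, tmp_path):
        table = make_table(rng.uniform(0, 500, (50, 2)),
                           phenotypes=list(rng.choice(["CK", "CD8"], 50)))
        field = sa.BSplineField.zeros((0, 0), (500, 500), 3)
        field.coefficients[:] = rng.normal(0, 30, field.coefficients.shape)
        t = sa.CompositeTransform(sa.RigidTransform(0.1, (0, 0), (5, 5)), field)
        out = sa.transform_cells(table, t)
        assert len(out) == len(table)
        for col in ("cell_id", "phenotype", "panel_id", "slide_id"):
            assert (out[col] == table[col]).all()
        # round-trip through serialization gives identical coordinates
        path = tmp_path / "t.json"
        sa.save_transform(t, path)
        out2 = sa.transform_cells(table, sa.load_transform(path))
        np.testing.assert_array_equal(out[["x", "y"]], out2[["x", "y"]])


class TestMergePanels:
    def test_twelve_distinct_phenotypes(self, rng):
        # panels of 7 and 7 labels sharing 2 -> 12 in the merged table
        labels1 = [f"p{i}" for i in range(7)]
        labels2 = [f"p{i}" for i in range(5, 12)]
        t1 = make_table(rng.uniform(0, 100, (70, 2)),
                        phenotypes=list(np.repeat(labels1, 10)), slide_id="slide1")
        t2 = make_table(rng.uniform(0, 100, (70, 2)),
                        phenotypes=list(np.repeat(labels2, 10)), slide_id="slide2")
        merged, summary = sa.merge_panels(t1, t2)
        assert merged["phenotype"].nunique() == 12
        assert summary["n_merged"] == 140

    def test_no_regions_counts_add(self, rng):
        t1 = make_table(rng.uniform(0, 10, (25, 2)), slide_id="slide1")
        t2 = make_table(rng.uniform(0, 10, (35, 2)), slide_id="slide2")
        merged, _ = sa.merge_panels(t1, t2)
        assert len(merged) == 60

    def test_full_cover_region_empties_output(self, rng):
        t1 = make_table(rng.uniform(0, 10, (20, 2)), slide_id="slide1")
        t2 = make_table(rng.uniform(0, 10, (20, 2)), slide_id="slide2")
        everything = sa.ExclusionRegion(
            Polygon([(-1, -1), (11, -1), (11, 11), (-1, 11)]), "all")
        merged, summary = sa.merge_panels(t1, t2, [everything])
        assert len(merged) == 0 and summary["n_dropped"] == 40

    def test_duplicate_ids_rejected(self, rng):
        t1 = make_table(rng.uniform(0, 10, (5, 2)), slide_id="s")
        t2 = make_table(rng.uniform(0, 10, (5, 2)), slide_id="s")
        with pytest.raises(IntegrityError, match="duplicate"):
            sa.merge_panels(t1, t2)

    def test_count_matches_exclusion_oracle(self, rng):
        t1 = make_table(rng.uniform(0, 100, (120, 2)), slide_id="slide1")
        t2 = make_table(rng.uniform(0, 100, (80, 2)), slide_id="slide2")
        poly = Polygon(rng.uniform(20, 80, (10, 2))).convex_hull
        region = sa.ExclusionRegion(poly, "hole")
        merged, _ = sa.merge_panels(t1, t2, [region])
        all_xy = np.vstack([t1[["x", "y"]], t2[["x", "y"]]])
        n_excluded = int(points_excluded(all_xy, [region]).sum())
        assert len(merged) == 200 - n_excluded

    def test_filtering_is_idempotent(self, rng):
        t1 = make_table(rng.uniform(0, 100, (60, 2)), slide_id="slide1")
        t2 = make_table(rng.uniform(0, 100, (60, 2)), slide_id="slide2")
        region = sa.ExclusionRegion(
            Polygon([(10, 10), (60, 10), (60, 60), (10, 60)]), "r")
        merged, _ = sa.merge_panels(t1, t2, [region])
        s1 = merged[merged.slide_id == "slide1"]
        s2 = merged[merged.slide_id == "slide2"]
        merged2, summary2 = sa.merge_panels(s1, s2, [region])
        assert len(merged2) == len(merged) and summary2["n_dropped"] == 0


class TestCommonMarkerCheck:
    def test_identical_tables_fully_match(self, rng):
        xy = rng.uniform(0, 100, (40, 2))
        t1 = make_table(xy, phenotypes=["CK"] * 40, slide_id="slide1")
        t2 = make_table(xy, phenotypes=["CK"] * 40, slide_id="slide2")
        assert sa.common_marker_check(t1, t2, "CK", radius=1.0) == (1.0, 1.0)

    def test_absent_marker_rejected(self, rng):
        t1 = make_table(rng.uniform(0, 10, (5, 2)), phenotypes=["CK"] * 5)
        t2 = make_table(rng.uniform(0, 10, (5, 2)), phenotypes=["CD8"] * 5,
                        slide_id="slide2")
        with pytest.raises(ArgumentError, match="absent"):
            sa.common_marker_check(t1, t2, "CK", radius=5.0)

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        a = rng.uniform(0, 500, (150, 2))
        b = rng.uniform(0, 500, (200, 2))
        t1 = make_table(a, phenotypes=["CK"] * 150, slide_id="slide1")
        t2 = make_table(b, phenotypes=["CK"] * 200, slide_id="slide2")
        radius = 25.0
        frac12, frac21 = sa.common_marker_check(t1, t2, "CK", radius)
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
        assert frac12 == pytest.approx((d.min(axis=1) <= radius).mean())
        assert frac21 == pytest.approx((d.min(axis=0) <= radius).mean())
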