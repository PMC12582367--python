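"""Cell tables, exclusion regions, and panel integration.

A cell table is a pandas DataFrame with columns
``cell_id, x, y, phenotype, panel_id, slide_id`` — coordinates in µm in the
owning slide's physical space, one mutually exclusive phenotype per cell.
Integration transforms slide-1 cells into slide-2 space through the fitted
composite transform, drops every cell falling in a non-alignable region
(tears, folds, control tissue), and concatenates the two panels.

Exclusion regions are polygons in target-slide (slide-2) µm coordinates,
accepted as GeoJSON (QuPath-exportable).  Boundary points count as excluded:
a cell whose membership is ambiguous is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import json
import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, shape

from .errors import ArgumentError, IntegrityError

REQUIRED_COLUMNS = ["cell_id", "x", "y", "phenotype", "panel_id", "slide_id"]


@dataclass
class ExclusionRegion:
    """A non-alignable tissue polygon in target-slide µm coordinates."""

    polygon: Polygon
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.polygon.exterior.coords) - 1 < 3:
            raise IntegrityError(f"region {self.label!r}: polygon needs >= 3 vertices")
        if not self.polygon.is_valid:
            raise IntegrityError(f"region {self.label!r}: self-intersecting polygon")


def validate_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise IntegrityError(f"cell table missing columns: {missing}")
    xy = df[["x", "y"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise IntegrityError("cell table has non-finite coordinates")
    if (df["phenotype"].astype(str).str.len() == 0).any():
        raise IntegrityError("cell table has empty phenotype labels")
    if df.duplicated(subset=["slide_id", "cell_id"]).any():
        raise IntegrityError("duplicate (slide_id, cell_id) in cell table")
    return df


def read_cell_table(path) -> pd.DataFrame:
    return validate_cell_table(pd.read_csv(path))


def write_cell_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_regions_geojson(path) -> list[ExclusionRegion]:
    """Load exclusion polygons from a GeoJSON FeatureCollection (µm coordinates)."""
    with open(path) as fh:
        gj = json.load(fh)
    features = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    regions = []
    for i, feat in enumerate(features):
        geom = shape(feat["geometry"] if "geometry" in feat else feat)
        label = str(feat.get("properties", {}).get("label", f"region_{i}"))
        if geom.geom_type == "Polygon":
            regions.append(ExclusionRegion(geom, label))
        elif geom.geom_type == "MultiPolygon":
            regions.extend(ExclusionRegion(g, f"{label}_{j}")
                           for j, g in enumerate(geom.geoms))
        else:
            raise IntegrityError(f"unsupported geometry type {geom.geom_type!r} in {path}")
    return regions


def save_regions_geojson(regions: list[ExclusionRegion], path) -> None:
    features = [{
        "type": "Feature",
        "properties": {"label": r.label},
        "geometry": json.loads(shapely.to_geojson(r.polygon)),
    } for r in regions]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def point_excluded(point, regions: list[ExclusionRegion]) -> bool:
    """True iff the µm point lies inside or on the boundary of any region."""
    return bool(points_excluded(np.atleast_2d(np.asarray(point, float)), regions)[0])


def points_excluded(points: np.ndarray, regions: list[ExclusionRegion]) -> np.ndarray:
    """Vectorized membership mask; boundary counts as excluded."""
    pts = shapely.points(points[:, 0], points[:, 1])
    mask = np.zeros(len(points), dtype=bool)
    for region in regions:
        mask |= shapely.covers(region.polygon, pts)
    return mask


def transform_cells(cells: pd.DataFrame, transform) -> pd.DataFrame:
    """Map slide-1 cell coordinates into slide-2 space; all other fields kept."""
    validate_cell_table(cells)
    out = cells.copy()
    xy = transform.apply(cells[["x", "y"]].to_numpy(dtype=float))
    out["x"] = xy[:, 0]
    out["y"] = xy[:, 1]
    return out


def merge_panels(cells_1_transformed: pd.DataFrame, cells_2: pd.DataFrame,
                 regions: list[ExclusionRegion] | None = None,
                 ) -> tuple[pd.DataFrame, dict]:
    """Concatenate both panels (slide-2 space), dropping cells in excluded regions.

    Both slides' cells are filtered symmetrically, since regions mark tissue
    that is non-alignable for the *pair*.  Returns the merged table and a
    per-region summary of kept/dropped counts.
    """
    validate_cell_table(cells_1_transformed)
    validate_cell_table(cells_2)
    regions = regions or []
    both = pd.concat([cells_1_transformed, cells_2], ignore_index=True)
    if both.duplicated(subset=["slide_id", "cell_id"]).any():
        raise IntegrityError("duplicate (slide_id, cell_id) across the two panels")
    dropped_per_region: dict[str, int] = {}
    keep = np.ones(len(both), dtype=bool)
    if regions:
        pts = both[["x", "y"]].to_numpy(dtype=float)
        geoms = shapely.points(pts[:, 0], pts[:, 1])
        for region in regions:
            inside = shapely.covers(region.polygon, geoms)
            dropped_per_region[region.label] = int(inside.sum())
            keep &= ~inside
    merged = both.loc[keep].reset_index(drop=True)
    summary = {
        "n_input_1": int(len(cells_1_transformed)),
        "n_input_2": int(len(cells_2)),
        "n_merged": int(len(merged)),
        "n_dropped": int(len(both) - len(merged)),
        "dropped_per_region": dropped_per_region,
        "phenotypes": sorted(merged["phenotype"].astype(str).unique().tolist()),
    }
    return merged, summary


def common_marker_check(cells_1_transformed: pd.DataFrame, cells_2: pd.DataFrame,
                        marker: str, radius: float) -> tuple[float, float]:
    """Fraction of marker⁺ cells with a marker⁺ partner within ``radius`` µm.

    A structure shared by both panels (e.g. Cytokeratin) should coincide
    after alignment; a low matched fraction flags a failed registration.
    Returns (slide1→slide2 fraction, slide2→slide1 fraction).
    """
    from scipy.spatial import cKDTree

    if radius <= 0:
        raise ArgumentError("radius must be positive")
    a = cells_1_transformed.loc[cells_1_transformed["phenotype"] == marker,
                                ["x", "y"]].to_numpy(dtype=float)
    b = cells_2.loc[cells_2["phenotype"] == marker, ["x", "y"]].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ArgumentError(f"marker {marker!r} absent from one of the tables")
    ta, tb = cKDTree(a), cKDTree(b)
    d_ab, _ = tb.query(a, k=1)
    d_ba, _ = ta.query(b, k=1)
    return float((d_ab <= radius).mean()), float((d_ba <= radius).mean())
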