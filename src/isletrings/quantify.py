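"""Per-region and whole-tissue marker quantification, and density maps.

For every region the cell count, per-marker positive counts, positive
percentages (0-100 scale; undefined for empty regions) and densities
(positives per mm^2 of region area) are tabulated. Density maps grid the
macrophage centroids, convert to cells/mm^2 and apply Gaussian smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage as ndi
from shapely.geometry.base import BaseGeometry

from .regions import RegionAnnotation

MARKER_KEYS = ("insulin", "cd68", "hla2", "cd68_hla2", "insulin_hla2")
UM2_PER_MM2 = 1e6


def _stats_row(region_id, region_class, parent, area_um2, sub: pd.DataFrame) -> dict:
    n = len(sub)
    row = {
        "region_id": region_id,
        "region_class": region_class,
        "parent_islet_id": parent,
        "area_um2": area_um2,
        "n_cells": n,
    }
    area_mm2 = area_um2 / UM2_PER_MM2
    for m in MARKER_KEYS:
        npos = int(sub[f"{m}_pos"].sum()) if n else 0
        row[f"n_{m}"] = npos
        row[f"pct_{m}"] = 100.0 * npos / n if n else np.nan
        row[f"density_{m}"] = npos / area_mm2 if area_mm2 > 0 else np.nan
    return row


def region_stats(assignments: pd.DataFrame, calls: pd.DataFrame,
                 regions: list[RegionAnnotation]) -> pd.DataFrame:
    """One row of counts/percentages/densities per region.

    Empty regions keep ``n_cells = 0`` with missing percentages (0/0 is
    undefined and must not enter group statistics as a zero).
    """
    if not assignments.empty:
        unknown = set(assignments["cell_id"]) - set(calls["cell_id"])
        if unknown:
            raise ValueError(f"assignments reference unknown cell_ids, e.g. {sorted(unknown)[:5]}")
    merged = assignments.merge(calls, on="cell_id", how="left") if not assignments.empty else assignments
    rows = []
    for r in regions:
        sub = merged[merged["region_id"] == r.region_id] if not merged.empty else merged
        rows.append(_stats_row(r.region_id, r.region_class, r.parent_islet_id, r.area_um2, sub))
    return pd.DataFrame(rows)


def whole_tissue_stats(calls: pd.DataFrame, tissue_area_um2: float) -> pd.Series:
    """Counts, percentages and densities over the entire tissue section."""
    row = _stats_row(-1, "tissue", None, tissue_area_um2, calls)
    return pd.Series(row)


def pooled_stats(stats: pd.DataFrame, region_class: str | list[str]) -> pd.Series:
    """Pool counts over all regions of one class and recompute percentages."""
    classes = [region_class] if isinstance(region_class, str) else list(region_class)
    sub = stats[stats["region_class"].isin(classes)]
    out = {"region_class": "+".join(classes), "n_regions": len(sub),
           "area_um2": float(sub["area_um2"].sum()), "n_cells": int(sub["n_cells"].sum())}
    area_mm2 = out["area_um2"] / UM2_PER_MM2
    for m in MARKER_KEYS:
        npos = int(sub[f"n_{m}"].sum())
        out[f"n_{m}"] = npos
        out[f"pct_{m}"] = 100.0 * npos / out["n_cells"] if out["n_cells"] else np.nan
        out[f"density_{m}"] = npos / area_mm2 if area_mm2 > 0 else np.nan
    return pd.Series(out)


@dataclass
class DensityMap:
    """Smoothed macrophage density grid (CD68+ cells per mm^2).

    ``grid[iy, ix]`` covers the square with lower corner
    ``origin + (ix, iy) * grid_spacing_um``; pixels outside the tissue
    polygon are NaN.
    """

    grid: np.ndarray
    grid_spacing_um: float
    smoothing_bandwidth_um: float
    origin_um: tuple[float, float]


def density_map(calls: pd.DataFrame, centroids: pd.DataFrame, tissue_polygon: BaseGeometry,
                grid_spacing_um: float = 50.0, bandwidth_um: float = 100.0,
                marker: str = "cd68") -> DensityMap:
    """Grid the positive-cell centroids and smooth into a density surface."""
    if grid_spacing_um <= 0:
        raise ValueError("grid_spacing_um must be positive")
    minx, miny, maxx, maxy = tissue_polygon.bounds
    nx = max(1, int(np.ceil((maxx - minx) / grid_spacing_um)))
    ny = max(1, int(np.ceil((maxy - miny) / grid_spacing_um)))
    xcol = "centroid_x_um" if "centroid_x_um" in centroids.columns else "x_um"
    ycol = "centroid_y_um" if "centroid_y_um" in centroids.columns else "y_um"
    merged = centroids.merge(calls, on="cell_id")
    pos = merged[merged[f"{marker}_pos"]]
    counts, _, _ = np.histogram2d(
        pos[ycol].to_numpy(), pos[xcol].to_numpy(), bins=(ny, nx),
        range=((miny, miny + ny * grid_spacing_um), (minx, minx + nx * grid_spacing_um)),
    )
    density = counts / (grid_spacing_um**2 / UM2_PER_MM2)
    if bandwidth_um > 0:
        density = ndi.gaussian_filter(density, bandwidth_um / grid_spacing_um)
    xs = minx + (np.arange(nx) + 0.5) * grid_spacing_um
    ys = miny + (np.arange(ny) + 0.5) * grid_spacing_um
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(tissue_polygon, gx.ravel(), gy.ravel()).reshape(ny, nx)
    density = density.astype(np.float64)
    density[~inside] = np.nan
    return DensityMap(density, grid_spacing_um, bandwidth_um, (minx, miny))
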