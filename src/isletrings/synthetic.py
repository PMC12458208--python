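"""Seeded synthetic multiplex-IF pancreas sections with known ground truth.

The generator emulates the statistical structure a whole-slide islet
analysis rests on: islet-shaped insulin-positive regions, a hard-core point
pattern of cells whose macrophage (CD68+) probability depends on the
distance zone relative to the nearest islet, and per-islet HLA-II
expression fractions for macrophages and beta cells drawn from a Gaussian
copula with a controlled Spearman rank correlation.

Every draw flows from one integer seed through :class:`numpy.random.SeedSequence`,
so identical configurations reproduce bit-identical images and tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import Polygon, box
from shapely.strtree import STRtree
from skimage.draw import polygon as draw_polygon

from .config import TissueConfig
from .io import ChannelStack, geometry_to_feature, write_geojson

#: margin added to the nucleus radius for the rendered marker footprints (um)
MARKER_DISK_MARGIN_UM = 5.0
INSULIN_DISK_MARGIN_UM = 4.0
SOFT_EDGE_UM = 0.6
PERI_ZONE_WIDTH_UM = 10.0
RING_WIDTH_UM = 25.0
N_RINGS = 8


class InfeasibleGeometryError(RuntimeError):
    """Raised when the requested islets cannot be placed disjointly."""


@dataclass
class GroundTruthTissue:
    """Generator-side record of the true tissue content.

    ``cells`` has one row per cell with columns ``cell_id, x_um, y_um,
    nucleus_radius_um, cell_type, insulin_pos, cd68_pos, hla2_pos, zone,
    parent_islet_id`` (parent is -1 outside every islet collar).
    """

    cells: pd.DataFrame
    islet_polygons: list[Polygon]
    islet_labels: list[str]  # "ICI" or "IDI", aligned with islet_polygons
    tissue_polygon: Polygon
    config: TissueConfig

    @property
    def n_islets(self) -> int:
        return len(self.islet_polygons)

    def ici_polygons(self) -> list[Polygon]:
        return [p for p, lab in zip(self.islet_polygons, self.islet_labels) if lab == "ICI"]


# ---------------------------------------------------------------------------
# geometry sampling


def tissue_polygon_for(config: TissueConfig) -> Polygon:
    h_um, w_um = config.image_size_um
    m = config.tissue_margin_um
    return box(m, m, w_um - m, h_um - m)


def _harmonic_polygon(cx: float, cy: float, r0: float, irregularity: float,
                      rng: np.random.Generator, n_vertices: int = 96) -> Polygon:
    """Circle of radius ``r0`` perturbed by low-order radial harmonics."""
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    h = np.zeros_like(theta)
    if irregularity > 0:
        orders = np.arange(2, 6)
        amps = rng.uniform(0.2, 1.0, size=orders.size)
        amps /= amps.sum()  # |h| <= 1
        phases = rng.uniform(0, 2 * np.pi, size=orders.size)
        for k, a, p in zip(orders, amps, phases):
            h += a * np.cos(k * theta + p)
    r = r0 * (1.0 + irregularity * h)
    return Polygon(np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)]))


def sample_islet_polygons(config: TissueConfig, rng: np.random.Generator
                          ) -> tuple[list[Polygon], list[str]]:
    """Place ``n_islets`` disjoint islet polygons and draw ICI/IDI labels.

    Raises
    ------
    InfeasibleGeometryError
        If disjoint placement fails after a bounded number of attempts.
    """
    if config.n_islets == 0:
        return [], []
    h_um, w_um = config.image_size_um
    lo, hi = config.islet_radius_um_range
    margin = config.islet_margin_um
    centers: list[tuple[float, float]] = []
    radii_eff: list[float] = []
    polys: list[Polygon] = []
    max_attempts = 500 * config.n_islets
    attempts = 0
    while len(polys) < config.n_islets:
        if attempts >= max_attempts:
            raise InfeasibleGeometryError(
                f"placed {len(polys)}/{config.n_islets} islets after {attempts} attempts; "
                "reduce n_islets or islet radii"
            )
        attempts += 1
        r0 = rng.uniform(lo, hi)
        r_eff = r0 * (1.0 + config.islet_shape_irregularity)
        x0, x1 = margin + r_eff, w_um - margin - r_eff
        y0, y1 = margin + r_eff, h_um - margin - r_eff
        if x1 <= x0 or y1 <= y0:
            raise InfeasibleGeometryError("image too small for the requested islet radii and margin")
        cx, cy = rng.uniform(x0, x1), rng.uniform(y0, y1)
        ok = True
        for (px, py), pr in zip(centers, radii_eff):
            if math.hypot(cx - px, cy - py) < r_eff + pr + config.islet_gap_um:
                ok = False
                break
        if not ok:
            continue
        centers.append((cx, cy))
        radii_eff.append(r_eff)
        polys.append(_harmonic_polygon(cx, cy, r0, config.islet_shape_irregularity, rng))
    labels = ["ICI" if rng.random() < config.ici_fraction else "IDI" for _ in polys]
    return polys, labels


# ---------------------------------------------------------------------------
# cell sampling


def _hardcore_points(n: int, bounds: tuple[float, float, float, float], spacing: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Dart-throwing with a hard-core minimum distance, on a neighbour grid."""
    x0, y0, x1, y1 = bounds
    cell = spacing
    nx = max(1, int((x1 - x0) / cell) + 1)
    ny = max(1, int((y1 - y0) / cell) + 1)
    grid: dict[tuple[int, int], list[int]] = {}
    pts = np.empty((n, 2))
    placed = 0
    sp2 = spacing * spacing
    max_attempts = 200 * n
    attempts = 0
    batch = max(1024, n)
    while placed < n and attempts < max_attempts:
        cand = rng.uniform([x0, y0], [x1, y1], size=(batch, 2))
        for cx, cy in cand:
            attempts += 1
            if placed >= n or attempts >= max_attempts:
                break
            gi, gj = int((cx - x0) / cell), int((cy - y0) / cell)
            ok = True
            for ii in range(gi - 1, gi + 2):
                for jj in range(gj - 1, gj + 2):
                    for k in grid.get((ii, jj), ()):
                        dx = pts[k, 0] - cx
                        dy = pts[k, 1] - cy
                        if dx * dx + dy * dy < sp2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                pts[placed] = (cx, cy)
                grid.setdefault((gi, gj), []).append(placed)
                placed += 1
    if placed < n:
        raise InfeasibleGeometryError(
            f"hard-core placement saturated at {placed}/{n} points; lower the density or spacing"
        )
    return pts


def sample_hla2_fractions(n: int, rank_correlation: float, mean_mac: float, mean_beta: float,
                          concentration: float, rng: np.random.Generator
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-islet (macrophage HLA-II fraction, beta HLA-II fraction) pairs.

    Latent bivariate normal with Pearson rho = 2 sin(pi * rho_S / 6), pushed
    through Beta marginals with the requested means, so the Spearman
    correlation of the pair targets ``rank_correlation`` exactly.
    """
    rho = 2.0 * math.sin(math.pi * rank_correlation / 6.0)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(n)
    u1, u2 = stats.norm.cdf(z1), stats.norm.cdf(z2)

    def _marginal(u: np.ndarray, mean: float) -> np.ndarray:
        if mean <= 0.0:
            return np.zeros_like(u)
        if mean >= 1.0:
            return np.ones_like(u)
        a, b = mean * concentration, (1.0 - mean) * concentration
        return stats.beta.ppf(u, a, b)

    return _marginal(u1, mean_mac), _marginal(u2, mean_beta)


def _zone_from_distance(dist: np.ndarray, inside: np.ndarray, has_peri: bool) -> np.ndarray:
    """Zone labels from boundary distance (um) and islet containment."""
    zone = np.full(dist.shape, "exocrine", dtype=object)
    reach = N_RINGS * RING_WIDTH_UM
    near = (dist > 0) & (dist <= reach) & ~inside
    k = np.minimum(np.ceil(dist[near] / RING_WIDTH_UM).astype(int), N_RINGS)
    zone[near] = np.array([f"ring{i}" for i in k], dtype=object)
    boundary = (dist == 0) & ~inside
    zone[boundary] = "ring1"
    if has_peri:
        zone[(~inside) & (dist <= PERI_ZONE_WIDTH_UM)] = "peri"
    zone[inside] = "islet"
    return zone


def sample_cells(islets: list[Polygon], islet_labels: list[str], config: TissueConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Sample the ground-truth cell table for a tissue with placed islets."""
    tissue = tissue_polygon_for(config)
    area_mm2 = tissue.area / 1e6
    n = int(rng.poisson(config.cell_density_per_mm2 * area_mm2))
    if n == 0:
        return _empty_cells_frame()
    x0, y0, x1, y1 = tissue.bounds
    pts = _hardcore_points(n, (x0, y0, x1, y1), config.min_spacing_um, rng)

    # distance to the nearest islet boundary and containment, exact via shapely
    inside = np.zeros(n, dtype=bool)
    parent = np.full(n, -1, dtype=int)
    dist = np.full(n, np.inf)
    if islets:
        points = shapely.points(pts[:, 0], pts[:, 1])
        tree = STRtree(islets)
        hit_pt, hit_islet = tree.query(points, predicate="within")
        inside[hit_pt] = True
        parent[hit_pt] = hit_islet
        dist[hit_pt] = 0.0
        out = ~inside
        if out.any():
            nearest = tree.nearest(points[out])
            d = shapely.distance(points[out], np.asarray(islets, dtype=object)[nearest])
            dist[out] = d
            reach = N_RINGS * RING_WIDTH_UM
            par = np.where(d <= reach, nearest, -1)
            parent[out] = par

    has_peri = "peri" in config.zone_macrophage_fraction
    zone = _zone_from_distance(dist, inside, has_peri)

    # CD68 (macrophage) labels per zone
    p_cd68 = np.array([config.zone_macrophage_fraction[z] for z in zone])
    cd68 = rng.random(n) < p_cd68

    # beta cells inside insulin-containing islets
    is_ici_parent = np.zeros(n, dtype=bool)
    if islets:
        ici_ids = {i for i, lab in enumerate(islet_labels) if lab == "ICI"}
        is_ici_parent = np.array([p in ici_ids for p in parent])
    beta = inside & is_ici_parent & ~cd68 & (rng.random(n) < config.beta_fraction_in_ici)

    # per-islet HLA-II fractions from the copula
    p_mac_islet, p_beta_islet = sample_hla2_fractions(
        len(islets), config.coexpression_rank_correlation,
        config.hla2_fraction_macrophage, config.hla2_fraction_beta,
        config.hla2_islet_concentration, rng,
    )
    p_hla2 = np.zeros(n)
    periislet_mac = cd68 & (parent >= 0) & (dist <= PERI_ZONE_WIDTH_UM)
    p_hla2[cd68] = config.hla2_fraction_macrophage
    if len(islets):
        p_hla2[periislet_mac] = p_mac_islet[parent[periislet_mac]]
        p_hla2[beta] = p_beta_islet[parent[beta]]
    hla2 = rng.random(n) < p_hla2

    cell_type = np.where(cd68, "macrophage", np.where(beta, "beta", "other"))
    radii = rng.uniform(*config.nucleus_radius_um_range, size=n)
    return pd.DataFrame({
        "cell_id": np.arange(n),
        "x_um": pts[:, 0],
        "y_um": pts[:, 1],
        "nucleus_radius_um": radii,
        "cell_type": cell_type,
        "insulin_pos": beta,
        "cd68_pos": cd68,
        "hla2_pos": hla2,
        "zone": zone,
        "parent_islet_id": parent,
    })


def _empty_cells_frame() -> pd.DataFrame:
    return pd.DataFrame({
        "cell_id": pd.Series(dtype=int), "x_um": pd.Series(dtype=float),
        "y_um": pd.Series(dtype=float), "nucleus_radius_um": pd.Series(dtype=float),
        "cell_type": pd.Series(dtype=object), "insulin_pos": pd.Series(dtype=bool),
        "cd68_pos": pd.Series(dtype=bool), "hla2_pos": pd.Series(dtype=bool),
        "zone": pd.Series(dtype=object), "parent_islet_id": pd.Series(dtype=int),
    })


# ---------------------------------------------------------------------------
# rendering


def _paint_blob(img: np.ndarray, cx_px: float, cy_px: float, rx_px: float, ry_px: float,
                angle: float, amp: float, soft_px: float) -> None:
    """Max-blend a soft-edged ellipse into ``img`` (row = y, col = x)."""
    reach = max(rx_px, ry_px) + soft_px + 1.0
    r0, r1 = int(cy_px - reach), int(cy_px + reach) + 2
    c0, c1 = int(cx_px - reach), int(cx_px + reach) + 2
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, img.shape[0]), min(c1, img.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx = xx - cx_px
    dy = yy - cy_px
    ca, sa = math.cos(angle), math.sin(angle)
    xr = dx * ca + dy * sa
    yr = -dx * sa + dy * ca
    rho = np.sqrt((xr / rx_px) ** 2 + (yr / ry_px) ** 2)
    s = soft_px / max(rx_px, ry_px)
    prof = np.clip((1.0 + s - rho) / s, 0.0, 1.0)
    patch = img[r0:r1, c0:c1]
    np.maximum(patch, (amp * prof).astype(patch.dtype), out=patch)


def _rasterize_polygon(poly: Polygon, shape_px: tuple[int, int], px: float):
    ext = np.asarray(poly.exterior.coords)
    rr, cc = draw_polygon(ext[:, 1] / px, ext[:, 0] / px, shape=shape_px)
    return rr, cc


def render_channels(cells: pd.DataFrame, islets: list[Polygon], islet_labels: list[str],
                    config: TissueConfig, rng: np.random.Generator) -> ChannelStack:
    """Render the four stain channels from the ground-truth cell table."""
    shape_px = tuple(config.image_size_px)
    px = config.pixel_size_um
    soft_px = SOFT_EDGE_UM / px
    channels: dict[str, np.ndarray] = {}

    n = len(cells)
    cx = cells["x_um"].to_numpy() / px
    cy = cells["y_um"].to_numpy() / px
    r_n = cells["nucleus_radius_um"].to_numpy() / px
    axis_ratio = rng.uniform(0.85, 1.0, size=n)
    angles = rng.uniform(0, np.pi, size=n)

    masks = {
        "DAPI": np.ones(n, dtype=bool),
        "INS": cells["insulin_pos"].to_numpy(),
        "CD68": cells["cd68_pos"].to_numpy(),
        "HLAII": cells["hla2_pos"].to_numpy(),
    }
    radii = {
        "DAPI": r_n,
        "INS": r_n + INSULIN_DISK_MARGIN_UM / px,
        "CD68": r_n + MARKER_DISK_MARGIN_UM / px,
        "HLAII": r_n + MARKER_DISK_MARGIN_UM / px,
    }

    def _bg_noise(model) -> np.ndarray:
        # chunked draws keep the float64 staging buffer small
        img = np.empty(shape_px, dtype=np.float32)
        step = 1024
        for r0 in range(0, shape_px[0], step):
            r1 = min(r0 + step, shape_px[0])
            img[r0:r1] = rng.normal(model.bg_mean, model.bg_sd, size=(r1 - r0, shape_px[1]))
        return img

    for ch_name, model in config.intensity_model.items():
        img = _bg_noise(model)
        ici_mask = None
        bg_copy = None
        if ch_name == "INS":
            # insulin signal is confined to insulin-containing islets: the
            # diffuse fill covers the islet and the bright beta-cell stain
            # is clipped at the islet boundary
            ici_mask = np.zeros(shape_px, dtype=bool)
            for poly, lab in zip(islets, islet_labels):
                if lab != "ICI":
                    continue
                rr, cc = _rasterize_polygon(poly, shape_px, px)
                ici_mask[rr, cc] = True
            bg_copy = img.copy()
            if model.fill_mean > 0 and ici_mask.any():
                img[ici_mask] = model.fill_mean + rng.normal(
                    0, model.bg_sd, size=int(ici_mask.sum()))
        sel = np.flatnonzero(masks[ch_name])
        amps = np.clip(rng.normal(model.fg_mean, model.fg_sd, size=n), 0, 255)
        rad = radii[ch_name]
        elliptic = ch_name == "DAPI"
        for i in sel:
            if elliptic:
                q = math.sqrt(axis_ratio[i])
                rx, ry = rad[i] * q, rad[i] / q
            else:
                rx = ry = rad[i]
            _paint_blob(img, cx[i], cy[i], rx, ry, angles[i], amps[i], soft_px)
        if ici_mask is not None:
            np.copyto(img, bg_copy, where=~ici_mask)
            del bg_copy
        np.rint(img, out=img)
        np.clip(img, 0, 255, out=img)
        channels[ch_name] = img.astype(np.uint8)
        del img
    return ChannelStack(channels=channels, pixel_size_um=px)


# ---------------------------------------------------------------------------
# top-level


def generate_tissue(config: TissueConfig) -> tuple[ChannelStack, GroundTruthTissue]:
    """Generate one synthetic section: rendered channels plus ground truth.

    Deterministic given ``config`` (including its seed): two calls return
    bit-identical pixel data and cell tables.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    islet_rng, cell_rng, render_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    islets, labels = sample_islet_polygons(config, islet_rng)
    cells = sample_cells(islets, labels, config, cell_rng)
    stack = render_channels(cells, islets, labels, config, render_rng)
    gt = GroundTruthTissue(
        cells=cells, islet_polygons=islets, islet_labels=labels,
        tissue_polygon=tissue_polygon_for(config), config=config,
    )
    return stack, gt


def write_ground_truth(gt: GroundTruthTissue, cells_csv, regions_geojson) -> None:
    """Write the cell table as CSV and true regions as GeoJSON."""
    gt.cells.to_csv(cells_csv, index=False)
    features = [
        geometry_to_feature(poly, {"classification": f"Islet-{lab}", "islet_id": int(i)})
        for i, (poly, lab) in enumerate(zip(gt.islet_polygons, gt.islet_labels))
    ]
    features.append(geometry_to_feature(gt.tissue_polygon, {"classification": "Tissue"}))
    write_geojson(features, regions_geojson)
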