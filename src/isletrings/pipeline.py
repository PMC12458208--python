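"""End-to-end orchestration: simulate -> detect -> classify -> regions ->
quantify -> statistics, with reproducibility metadata.

`analyze_tissue` is the in-memory workhorse; `run_pipeline` adds file
output and a hashed manifest. `run_group_experiment` simulates donor
cohorts per disease group, pools per-region observations and runs the
group-statistics battery.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import quantify as _quantify
from . import regions as _regions
from .config import (
    DetectionParams,
    ExocrineSpec,
    PipelineConfig,
    RingSpec,
    _tissue_from_dict,
)
from .detect import segment_cells
from .group_stats import compare_groups, spearman_with_ci, two_way_ring_analysis
from .io import ChannelStack, write_ome_tiff
from .metrics import match_points, score_detection
from .synthetic import GroundTruthTissue, generate_tissue, write_ground_truth

log = logging.getLogger("isletrings")


def build_classifier(features: pd.DataFrame, gt: GroundTruthTissue, stack: ChannelStack,
                     seg, seed: int, min_per_class: int = 20) -> _classify.ClassifierModel:
    """Random-trees classifiers fit on ground-truth labels of matched cells.

    Plays the role of the interactively trained object classifiers; the
    generator's truth stands in for the annotator. Markers whose matched
    training set lacks ``min_per_class`` examples of either class fall back
    to the intensity-midpoint threshold rule.
    """
    floors = _classify.calibrate_channel_floors(stack, seg)
    t_idx, d_idx = match_points(
        gt.cells[["x_um", "y_um"]].to_numpy(),
        features[["centroid_x_um", "centroid_y_um"]].to_numpy(),
    )
    feats = features.iloc[d_idx].reset_index(drop=True)
    midpoints = _classify.midpoint_thresholds(gt.config.intensity_model)
    rules: dict[str, object] = {}
    for marker in _classify.MARKERS:
        labels = gt.cells[f"{marker}_pos"].to_numpy()[t_idx]
        n_pos = int(labels.sum())
        n_neg = int(len(labels) - n_pos)
        if min(n_pos, n_neg) < min_per_class:
            log.info("classifier %s: %d pos / %d neg matched, using midpoint threshold",
                     marker, n_pos, n_neg)
            rules[marker] = midpoints[marker]
        else:
            rules[marker] = _classify.train_marker_classifier(feats, labels, marker, seed=seed)
    return _classify.ClassifierModel(markers=rules, channel_floors=floors)


@dataclass
class AnalysisResult:
    features: pd.DataFrame
    calls: pd.DataFrame
    regions: list[_regions.RegionAnnotation]
    assignments: pd.DataFrame
    stats: pd.DataFrame
    whole_tissue: pd.Series
    density: _quantify.DensityMap
    detection_score: dict = field(default_factory=dict)


def analyze_tissue(stack: ChannelStack, gt: GroundTruthTissue, detection: DetectionParams,
                   rings: RingSpec, exocrine: ExocrineSpec, seed: int,
                   classifier: str = "train-on-groundtruth") -> AnalysisResult:
    """Run detection through quantification on one section."""
    t0 = time.time()
    seg, features = segment_cells(stack, detection)
    log.info("detected %d cells in %.1fs", seg.n_cells, time.time() - t0)

    if classifier == "train-on-groundtruth":
        model = build_classifier(features, gt, stack, seg, seed)
    elif classifier == "midpoint-threshold":
        model = _classify.ClassifierModel(
            markers=_classify.midpoint_thresholds(gt.config.intensity_model),
            channel_floors=_classify.calibrate_channel_floors(stack, seg),
        )
    else:
        raise ValueError(f"unknown classifier mode {classifier!r}")
    calls = _classify.classify_cells(features, model)

    ici = _regions.segment_islets(stack["INS"], stack.pixel_size_um)
    idi = [p for p, lab in zip(gt.islet_polygons, gt.islet_labels) if lab == "IDI"]
    islets = ici + idi
    region_list: list[_regions.RegionAnnotation] = []
    rid = 0
    for i, poly in enumerate(islets):
        cls = "islet_ICI" if i < len(ici) else "islet_IDI"
        region_list.append(_regions.RegionAnnotation(rid, cls, poly, parent_islet_id=i))
        rid += 1
    if islets:
        peri = _regions.make_peri_islet(islets, rings.peri_islet_width_um,
                                        gt.tissue_polygon, start_region_id=rid)
        rid += len(peri)
        ring_regs = _regions.make_ring_set(islets, rings, gt.tissue_polygon, start_region_id=rid)
        rid += len(ring_regs)
        region_list += peri + ring_regs
    if exocrine.n_regions > 0:
        exo_rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
        peri_only = [r for r in region_list if r.region_class == "peri_islet"]
        exo = _regions.sample_exocrine(gt.tissue_polygon, islets, peri_only,
                                       exocrine.n_regions, exocrine.side_um, exo_rng,
                                       start_region_id=rid)
        region_list += exo

    assignments = _regions.assign_cells(features, region_list)
    stats = _quantify.region_stats(assignments, calls, region_list)
    whole = _quantify.whole_tissue_stats(calls, gt.tissue_polygon.area)
    density = _quantify.density_map(calls, features, gt.tissue_polygon)
    score = score_detection(gt.cells[["x_um", "y_um"]].to_numpy(),
                            features[["centroid_x_um", "centroid_y_um"]].to_numpy())
    return AnalysisResult(
        features=features, calls=calls, regions=region_list, assignments=assignments,
        stats=stats, whole_tissue=whole, density=density,
        detection_score={"precision": score.precision, "recall": score.recall, "f1": score.f1},
    )


def islet_coexpression_table(stats: pd.DataFrame, min_cells: int = 1) -> pd.DataFrame:
    """Per-islet marker fractions for correlation analyses.

    For each insulin-containing islet: percent CD68+ and CD68+HLA-II+ cells
    over the islet plus its peri-islet collar, and percent HLA-II+ beta
    (insulin+) cells within the islet.
    """
    islets = stats[stats["region_class"] == "islet_ICI"].set_index("parent_islet_id")
    peri = stats[stats["region_class"] == "peri_islet"].set_index("parent_islet_id")
    rows = []
    for pid, isl in islets.iterrows():
        p = peri.loc[pid] if pid in peri.index else None
        n_cells = isl["n_cells"] + (p["n_cells"] if p is not None else 0)
        n_cd68 = isl["n_cd68"] + (p["n_cd68"] if p is not None else 0)
        n_both = isl["n_cd68_hla2"] + (p["n_cd68_hla2"] if p is not None else 0)
        if n_cells < min_cells or isl["n_insulin"] == 0:
            continue
        rows.append({
            "islet_id": pid,
            "pct_cd68": 100.0 * n_cd68 / n_cells,
            "pct_cd68_hla2": 100.0 * n_both / n_cells,
            "pct_beta_hla2": 100.0 * isl["n_insulin_hla2"] / isl["n_insulin"],
        })
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate one section, analyze it, and write all outputs + manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest_files: dict[str, str] = {}

    def _record(name: str, path: Path):
        manifest_files[name] = _sha256(path)

    t0 = time.time()
    tissue_cfg = config.tissue
    if tissue_cfg.seed != config.seed:
        tissue_cfg = _tissue_from_dict({**asdict(tissue_cfg), "seed": config.seed})
    stack, gt = generate_tissue(tissue_cfg)
    timings["simulate"] = time.time() - t0

    image_path = out / "image.ome.tif"
    write_ome_tiff(stack, image_path)
    write_ground_truth(gt, out / "ground_truth_cells.csv", out / "ground_truth_regions.geojson")
    for name in ("image.ome.tif", "ground_truth_cells.csv", "ground_truth_regions.geojson"):
        _record(name, out / name)

    t0 = time.time()
    result = analyze_tissue(stack, gt, config.detection, config.rings, config.exocrine,
                            seed=config.seed, classifier=config.classifier)
    timings["analyze"] = time.time() - t0

    result.features.to_csv(out / "cells.csv", index=False)
    result.calls.to_csv(out / "calls.csv", index=False)
    result.assignments.to_csv(out / "assignments.csv", index=False)
    result.stats.to_csv(out / "region_stats.csv", index=False)
    _regions.regions_to_geojson(result.regions, out / "regions.geojson")
    summary = {
        "whole_tissue": {k: (None if pd.isna(v) else v) for k, v in
                         result.whole_tissue.drop("parent_islet_id").items()},
        "detection": result.detection_score,
        "seed": config.seed,
        "group_label": config.group_label,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    import tifffile
    tifffile.imwrite(out / "density_map.tif", result.density.grid.astype(np.float32))
    _density_overlay_png(result.density, out / "density_map.png")
    for name in ("cells.csv", "calls.csv", "assignments.csv", "region_stats.csv",
                 "regions.geojson", "summary.json", "density_map.tif", "density_map.png"):
        _record(name, out / name)

    manifest = {
        "seed": config.seed,
        "config": pipeline_config_dict(config),
        "files": manifest_files,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _density_overlay_png(density: _quantify.DensityMap, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(density.grid, origin="upper", cmap="inferno")
    fig.colorbar(im, ax=ax, label="CD68+ cells / mm$^2$")
    ax.set_title("Macrophage density")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pipeline_config_dict(cfg: PipelineConfig) -> dict:
    return asdict(cfg)


def run_group_experiment(group_configs: dict[str, PipelineConfig],
                         donors_per_group: int = 5) -> dict:
    """Simulate donor cohorts per group, pool observations, run statistics.

    Returns a report with the pooled observation table, whole-tissue and
    peri-islet group comparisons, the ring-profile two-way ANOVA and the
    per-islet co-expression correlation (pooled over groups' ICIs).
    """
    donor_rows = []
    region_rows = []
    coexpr_frames = []
    for glabel, cfg in group_configs.items():
        seeds = np.random.SeedSequence(cfg.seed).generate_state(donors_per_group) % (2**31)
        for d, dseed in enumerate(seeds):
            tcfg = _tissue_from_dict({**asdict(cfg.tissue), "seed": int(dseed)})
            stack, gt = generate_tissue(tcfg)
            res = analyze_tissue(stack, gt, cfg.detection, cfg.rings, cfg.exocrine,
                                 seed=int(dseed), classifier=cfg.classifier)
            donor_rows.append({
                "group": glabel, "donor": d,
                "pct_cd68": res.whole_tissue["pct_cd68"],
                "density_cd68": res.whole_tissue["density_cd68"],
            })
            st = res.stats.copy()
            st["group"] = glabel
            st["donor"] = d
            region_rows.append(st)
            co = islet_coexpression_table(st)
            if not co.empty:
                co["group"] = glabel
                coexpr_frames.append(co)
    donors = pd.DataFrame(donor_rows)
    obs = pd.concat(region_rows, ignore_index=True)
    report: dict = {"donor_table": donors, "region_table": obs}

    if len(group_configs) < 2:
        log.info("single group: omnibus statistics skipped")
        return report

    report["whole_tissue_pct"] = compare_groups(
        {g: sub["pct_cd68"].to_numpy() for g, sub in donors.groupby("group")})
    report["whole_tissue_density"] = compare_groups(
        {g: sub["density_cd68"].to_numpy() for g, sub in donors.groupby("group")})
    peri = obs[(obs["region_class"] == "peri_islet") & obs["pct_cd68"].notna()]
    if peri.groupby("group").size().min() >= 3:
        report["peri_islet_pct"] = compare_groups(
            {g: sub["pct_cd68"].to_numpy() for g, sub in peri.groupby("group")})
    ringobs = obs[(obs["region_class"].str.startswith("ring_") |
                   obs["region_class"].isin(("islet_ICI", "islet_IDI")))
                  & obs["pct_cd68"].notna()].copy()
    ringobs["ring"] = np.where(ringobs["region_class"].str.startswith("ring_"),
                               ringobs["region_class"], "islet")
    try:
        report["ring_profile"] = two_way_ring_analysis(
            ringobs.rename(columns={"pct_cd68": "value"}))
    except ValueError as err:
        log.info("ring-profile ANOVA skipped: %s", err)
    if coexpr_frames:
        co = pd.concat(coexpr_frames, ignore_index=True)
        co = co[co["pct_beta_hla2"].notna()]
        if len(co) >= 4:
            report["coexpression"] = spearman_with_ci(
                co["pct_cd68_hla2"].to_numpy(), co["pct_beta_hla2"].to_numpy())
    return report
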