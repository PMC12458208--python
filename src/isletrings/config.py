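"""Configuration objects for the simulation and analysis pipeline.

All physical quantities are in micrometres (lengths), square micrometres
(areas), cells per square millimetre (densities) and 8-bit grey levels
(intensities). Zone labels follow the region vocabulary used throughout the
package: ``islet``, optionally ``peri`` (the 0-10 um collar), ``ring1`` ..
``ring8`` (25 um annular bands) and ``exocrine`` (beyond the last ring).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

ZONE_LABELS = ("islet", "ring1", "ring2", "ring3", "ring4", "ring5", "ring6", "ring7", "ring8", "exocrine")
OPTIONAL_ZONE_LABELS = ZONE_LABELS + ("peri",)

#: CD68+ fraction per zone. Values are the insulin-containing-islet profile of
#: the most infiltrated disease group (islet 6.2%, first ring 13.6%, 0-10 um
#: collar 19.6%, exocrine 7.9%), with a gentle decline over the outer rings.
DEFAULT_ZONE_MACROPHAGE_FRACTION = {
    "islet": 0.062,
    "peri": 0.196,
    "ring1": 0.136,
    "ring2": 0.105,
    "ring3": 0.100,
    "ring4": 0.095,
    "ring5": 0.090,
    "ring6": 0.088,
    "ring7": 0.085,
    "ring8": 0.082,
    "exocrine": 0.079,
}


@dataclass
class IntensityModel:
    """Gaussian foreground/background intensity model for one channel.

    ``fg_mean``/``fg_sd`` describe the per-cell stain level of positive
    cells, ``bg_mean``/``bg_sd`` the per-pixel background, and ``fill_mean``
    an optional diffuse fill rendered over whole islet polygons (used for
    the insulin channel, where islets carry low-grade diffuse signal on top
    of the bright beta-cell stain).
    """

    fg_mean: float
    fg_sd: float
    bg_mean: float
    bg_sd: float
    fill_mean: float = 0.0

    def validate(self) -> None:
        for name in ("fg_mean", "bg_mean", "fill_mean"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"intensity {name}={v} outside [0, 255]")
        if self.fg_sd < 0 or self.bg_sd < 0:
            raise ValueError("intensity sd must be non-negative")


def default_intensity_model() -> dict[str, IntensityModel]:
    return {
        "DAPI": IntensityModel(fg_mean=180.0, fg_sd=15.0, bg_mean=8.0, bg_sd=3.0),
        "INS": IntensityModel(fg_mean=150.0, fg_sd=12.0, bg_mean=6.0, bg_sd=2.0, fill_mean=25.0),
        "CD68": IntensityModel(fg_mean=160.0, fg_sd=12.0, bg_mean=6.0, bg_sd=2.0),
        "HLAII": IntensityModel(fg_mean=150.0, fg_sd=12.0, bg_mean=6.0, bg_sd=2.0),
    }


@dataclass
class TissueConfig:
    """Parameters of one synthetic pancreas section."""

    image_size_px: tuple[int, int] = (4000, 4000)
    pixel_size_um: float = 0.325
    n_islets: int = 12
    islet_radius_um_range: tuple[float, float] = (30.0, 90.0)
    islet_shape_irregularity: float = 0.15
    ici_fraction: float = 0.8
    cell_density_per_mm2: float = 2500.0
    nucleus_radius_um_range: tuple[float, float] = (2.2, 3.2)
    min_spacing_um: float = 7.0
    zone_macrophage_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ZONE_MACROPHAGE_FRACTION)
    )
    hla2_fraction_macrophage: float = 0.33
    hla2_fraction_beta: float = 0.15
    hla2_islet_concentration: float = 20.0
    beta_fraction_in_ici: float = 0.65
    coexpression_rank_correlation: float = 0.74
    intensity_model: dict[str, IntensityModel] = field(default_factory=default_intensity_model)
    seed: int = 0

    # geometric margins (um): tissue rectangle inset from the image border,
    # islet clearance from the tissue border, islet-islet clearance
    tissue_margin_um: float = 100.0
    islet_margin_um: float = 200.0
    islet_gap_um: float = 25.0

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_islets < 0:
            raise ValueError("n_islets must be non-negative")
        lo, hi = self.islet_radius_um_range
        if not (0 < lo <= hi):
            raise ValueError("islet_radius_um_range must be positive and ordered")
        if not 0 <= self.islet_shape_irregularity <= 1:
            raise ValueError("islet_shape_irregularity must lie in [0, 1]")
        for name in ("ici_fraction", "hla2_fraction_macrophage", "hla2_fraction_beta", "beta_fraction_in_ici"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not -1 <= self.coexpression_rank_correlation <= 1:
            raise ValueError("coexpression_rank_correlation outside [-1, 1]")
        if self.cell_density_per_mm2 <= 0:
            raise ValueError("cell_density_per_mm2 must be positive")
        nlo, nhi = self.nucleus_radius_um_range
        if not (0 < nlo <= nhi):
            raise ValueError("nucleus_radius_um_range must be positive and ordered")
        if self.min_spacing_um < 1.5 * nlo:
            raise ValueError(
                f"min_spacing_um={self.min_spacing_um} below 1.5x min nucleus radius ({1.5 * nlo:.2f})"
            )
        unknown = set(self.zone_macrophage_fraction) - set(OPTIONAL_ZONE_LABELS)
        if unknown:
            raise ValueError(f"unknown zone labels: {sorted(unknown)}")
        missing = set(ZONE_LABELS) - set(self.zone_macrophage_fraction)
        if missing:
            raise ValueError(f"zone_macrophage_fraction missing zones: {sorted(missing)}")
        for zone, frac in self.zone_macrophage_fraction.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"zone fraction {zone}={frac} outside [0, 1]")
        for model in self.intensity_model.values():
            model.validate()

    @property
    def image_size_um(self) -> tuple[float, float]:
        h, w = self.image_size_px
        return h * self.pixel_size_um, w * self.pixel_size_um


@dataclass
class DetectionParams:
    """Nucleus detection and cell expansion parameters."""

    smoothing_sigma_um: float = 1.5
    nucleus_threshold: float | str = "auto"
    min_nucleus_area_um2: float = 10.0
    max_nucleus_area_um2: float = 400.0
    watershed_split: bool = True
    cell_expansion_um: float = 5.0
    #: h-maxima suppression depth for watershed markers, in grey levels on
    #: the smoothed nuclear signal.
    split_marker_h: float = 10.0

    def validate(self) -> None:
        if self.smoothing_sigma_um < 0:
            raise ValueError("smoothing_sigma_um must be non-negative")
        if self.min_nucleus_area_um2 >= self.max_nucleus_area_um2:
            raise ValueError("min_nucleus_area_um2 must be below max_nucleus_area_um2")
        if self.min_nucleus_area_um2 <= 0:
            raise ValueError("min_nucleus_area_um2 must be positive")
        if self.cell_expansion_um < 0:
            raise ValueError("cell_expansion_um must be non-negative")
        if isinstance(self.nucleus_threshold, str):
            if self.nucleus_threshold != "auto":
                raise ValueError("nucleus_threshold must be a number or 'auto'")
        elif not 0 <= float(self.nucleus_threshold) <= 255:
            raise ValueError("nucleus_threshold outside [0, 255]")


@dataclass
class RingSpec:
    """Peri-islet collar and concentric-ring geometry."""

    peri_islet_width_um: float = 10.0
    n_rings: int = 8
    ring_width_um: float = 25.0

    def validate(self) -> None:
        if self.peri_islet_width_um <= 0:
            raise ValueError("peri_islet_width_um must be positive")
        if self.n_rings < 1:
            raise ValueError("n_rings must be positive")
        if self.ring_width_um <= 0:
            raise ValueError("ring_width_um must be positive")

    @property
    def reach_um(self) -> float:
        """Outer radius of the last ring measured from the islet boundary."""
        return self.n_rings * self.ring_width_um


@dataclass
class ExocrineSpec:
    n_regions: int = 15
    side_um: float = 500.0

    def validate(self) -> None:
        if self.n_regions < 0:
            raise ValueError("n_regions must be non-negative")
        if self.side_um <= 0:
            raise ValueError("side_um must be positive")


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end pipeline run."""

    tissue: TissueConfig = field(default_factory=TissueConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    rings: RingSpec = field(default_factory=RingSpec)
    exocrine: ExocrineSpec = field(default_factory=ExocrineSpec)
    #: "train-on-groundtruth" (random-trees classifiers fit on ground-truth
    #: labels of matched detections) or a path to a serialized model.
    classifier: str = "train-on-groundtruth"
    output_dir: str = "isletrings-run"
    group_label: str = "t1d_ici"
    seed: int = 0

    def validate(self) -> None:
        self.tissue.validate()
        self.detection.validate()
        self.rings.validate()
        self.exocrine.validate()


# ---------------------------------------------------------------------------
# YAML round-trip


def _config_to_dict(cfg) -> dict:
    d = asdict(cfg)
    return d


def save_config(cfg, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh, sort_keys=False)


def _tissue_from_dict(d: dict) -> TissueConfig:
    d = dict(d)
    if "intensity_model" in d:
        d["intensity_model"] = {k: IntensityModel(**v) for k, v in d["intensity_model"].items()}
    for key in ("image_size_px", "islet_radius_um_range", "nucleus_radius_um_range"):
        if key in d:
            d[key] = tuple(d[key])
    return TissueConfig(**d)


def load_tissue_config(path) -> TissueConfig:
    with open(path) as fh:
        cfg = _tissue_from_dict(yaml.safe_load(fh))
    cfg.validate()
    return cfg


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    cfg = PipelineConfig(
        tissue=_tissue_from_dict(d.get("tissue", {})),
        detection=DetectionParams(**d.get("detection", {})),
        rings=RingSpec(**d.get("rings", {})),
        exocrine=ExocrineSpec(**d.get("exocrine", {})),
        classifier=d.get("classifier", "train-on-groundtruth"),
        output_dir=d.get("output_dir", "isletrings-run"),
        group_label=d.get("group_label", "t1d_ici"),
        seed=int(d.get("seed", 0)),
    )
    cfg.validate()
    return cfg
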