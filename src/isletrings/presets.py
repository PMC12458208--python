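"""Recovery presets: study conditions for parameter-recovery benchmarks.

These configurations encode the published group-level values for macrophage
infiltration in human pancreas sections — whole-tissue CD68+ percentages
and densities per disease group, the islet/peri-islet/ring CD68+ profile of
the insulin-containing-islet (ICI) group in type 1 diabetes, the fraction
of macrophages highly expressing HLA-II, and the islet-level co-expression
rank correlations. The synthetic generator is configured with these values
as ground truth and the pipeline must recover them.
"""

from __future__ import annotations

from .config import DetectionParams, TissueConfig

#: whole-tissue mean percent CD68+ cells and CD68+ density (cells/mm^2)
GROUP_WHOLE_TISSUE = {
    "t1d": {"pct_cd68": 8.6, "density_cd68": 856.3},
    "aab": {"pct_cd68": 3.2, "density_cd68": 312.8},
    "nd": {"pct_cd68": 1.5, "density_cd68": 136.6},
}

#: zone-wise percent CD68+ cells, type 1 diabetes ICI profile
T1D_ICI_ZONES = {
    "islet": 6.2,
    "peri": 19.6,
    "ring1": 13.6,
    "exocrine": 7.9,
}

#: percent of CD68+ cells highly expressing HLA-II
T1D_HLA2 = {
    "peri_macrophage": 49.2,
    "whole_tissue_macrophage": 33.1,
}

#: islet-level Spearman rank correlations with percent HLA-II+ beta cells
COEXPRESSION = {
    "strong": 0.74,  # percent CD68+HLA-II+ cells, islet + peri-islet
    "weak": 0.28,    # percent CD68+ cells, islet + peri-islet
}

#: mean percent HLA-II+ beta cells used for the copula's second marginal
BETA_HLA2_MEAN = 0.15

ALL_ZONE_KEYS = ("islet", "ring1", "ring2", "ring3", "ring4",
                 "ring5", "ring6", "ring7", "ring8", "exocrine")

#: outer-ring profile: near the first-ring level, declining gently toward
#: the exocrine value (only islet, ring 1, the 0-10 um collar and exocrine
#: means are published; the intermediate rings interpolate between them)
T1D_ICI_RING_DECLINE = {
    "ring2": 0.105, "ring3": 0.100, "ring4": 0.095, "ring5": 0.090,
    "ring6": 0.088, "ring7": 0.085, "ring8": 0.082,
}


def whole_tissue_config(group: str = "t1d", seed: int = 0,
                        size_px: int = 5200) -> TissueConfig:
    """One section with a uniform CD68+ probability at the group's
    whole-tissue mean, and the total cell density implied by the group's
    printed percentage and absolute CD68+ density."""
    prof = GROUP_WHOLE_TISSUE[group]
    p = prof["pct_cd68"] / 100.0
    total_density = prof["density_cd68"] / p
    return TissueConfig(
        image_size_px=(size_px, size_px),
        pixel_size_um=0.325,
        n_islets=6,
        islet_radius_um_range=(40.0, 80.0),
        ici_fraction=1.0,
        cell_density_per_mm2=total_density,
        nucleus_radius_um_range=(2.0, 2.9),
        min_spacing_um=6.0,
        zone_macrophage_fraction={z: p for z in ALL_ZONE_KEYS},
        hla2_fraction_macrophage=T1D_HLA2["whole_tissue_macrophage"] / 100.0,
        seed=seed,
    )


def dense_detection_params() -> DetectionParams:
    """Detection settings for the high-density whole-tissue sections."""
    return DetectionParams(smoothing_sigma_um=1.0)


def zone_recovery_config(seed: int = 0, peri_band: bool = True,
                         n_islets: int = 350, size_px: int = 9230,
                         pixel_size_um: float = 0.65,
                         density: float = 3500.0) -> TissueConfig:
    """A many-islet section carrying the T1D ICI zone profile.

    With ``peri_band`` the 0-10 um collar gets its own published CD68+
    probability (19.6%); without it the whole 0-25 um first ring is
    homogeneous at the published ring-1 value (13.6%). The two variants are
    needed because the collar is a sub-band of ring 1 and both printed
    values cannot hold on one tissue simultaneously.
    """
    zones = {
        "islet": T1D_ICI_ZONES["islet"] / 100.0,
        "ring1": T1D_ICI_ZONES["ring1"] / 100.0,
        "exocrine": T1D_ICI_ZONES["exocrine"] / 100.0,
        **T1D_ICI_RING_DECLINE,
    }
    if peri_band:
        zones["peri"] = T1D_ICI_ZONES["peri"] / 100.0
    return TissueConfig(
        image_size_px=(size_px, size_px),
        pixel_size_um=pixel_size_um,
        n_islets=n_islets,
        islet_radius_um_range=(35.0, 85.0),
        ici_fraction=1.0,
        cell_density_per_mm2=density,
        zone_macrophage_fraction=zones,
        hla2_fraction_macrophage=T1D_HLA2["peri_macrophage"] / 100.0,
        hla2_fraction_beta=BETA_HLA2_MEAN,
        seed=seed,
    )
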