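"""Shared fixtures: one small synthetic section reused across the suite.

The default section is ~1 x 1 mm at 0.325 um/px with four insulin-containing
islets and ~1,500 cells, big enough to exercise every pipeline stage but
cheap enough to share session-wide.
"""

import numpy as np
import pytest

from isletrings import (
    DetectionParams,
    ExocrineSpec,
    RingSpec,
    TissueConfig,
    generate_tissue,
)
from isletrings.pipeline import analyze_tissue


@pytest.fixture(scope="session")
def default_config() -> TissueConfig:
    return TissueConfig(
        image_size_px=(3000, 3000),
        n_islets=4,
        islet_radius_um_range=(40, 70),
        ici_fraction=1.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def default_tissue(default_config):
    return generate_tissue(default_config)


@pytest.fixture(scope="session")
def default_analysis(default_tissue):
    stack, gt = default_tissue
    return analyze_tissue(stack, gt, DetectionParams(), RingSpec(),
                          ExocrineSpec(n_regions=2, side_um=200), seed=1)


@pytest.fixture(scope="session")
def cells_only_tissue():
    """A large ground-truth cell table sampled without rendering an image.

    ~10 mm^2 of tissue at the default density with a uniform CD68+
    probability of 0.086, for statistical convergence checks.
    """
    from isletrings.synthetic import sample_cells, sample_islet_polygons, GroundTruthTissue, tissue_polygon_for

    zones = {z: 0.086 for z in ("islet", "ring1", "ring2", "ring3", "ring4",
                                "ring5", "ring6", "ring7", "ring8", "exocrine")}
    cfg = TissueConfig(
        image_size_px=(10800, 10800),
        n_islets=8,
        islet_radius_um_range=(40, 80),
        ici_fraction=1.0,
        zone_macrophage_fraction=zones,
        seed=5,
    )
    rng = np.random.default_rng(5)
    islets, labels = sample_islet_polygons(cfg, rng)
    cells = sample_cells(islets, labels, cfg, rng)
    return GroundTruthTissue(cells=cells, islet_polygons=islets, islet_labels=labels,
                             tissue_polygon=tissue_polygon_for(cfg), config=cfg)
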