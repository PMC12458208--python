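"""Per-cell marker classification (insulin, CD68, HLA-II) and composites.

Two model families are supported behind one interface: plain intensity
thresholds on a chosen compartment (fully deterministic, used for oracle
tests and quick runs) and seeded random-trees ensembles over all
per-compartment channel means (the analogue of trained object
classifiers). Data-driven per-channel minimum-intensity floors veto
positive calls whose compartment mean does not clear the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import morphology

from .config import IntensityModel
from .detect import Segmentation
from .io import ChannelStack

MARKERS = ("insulin", "cd68", "hla2")
MARKER_CHANNELS = {"insulin": "INS", "cd68": "CD68", "hla2": "HLAII"}
COMPARTMENTS = ("nucleus", "cell", "cytoplasm")
#: dilation added around nuclei when defining background pixels (um)
BACKGROUND_EXCLUSION_UM = 5.0
BACKGROUND_PERCENTILE = 99.5


@dataclass
class ThresholdRule:
    """Call a marker positive when ``<channel>_<compartment>_mean > threshold``."""

    threshold: float
    compartment: str = "cell"

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ValueError("threshold outside [0, 255]")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")


@dataclass
class TreeEnsembleRule:
    """A fitted random-trees classifier over all per-compartment means."""

    model: RandomForestClassifier
    feature_columns: list[str]
    compartment: str = "cell"  # compartment used for the floor veto


@dataclass
class ClassifierModel:
    markers: dict[str, ThresholdRule | TreeEnsembleRule]
    channel_floors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(MARKERS) - set(self.markers)
        if missing:
            raise ValueError(f"no model for markers: {sorted(missing)}")


def feature_columns(channel_names) -> list[str]:
    return [f"{ch}_{comp}_mean" for ch in channel_names for comp in COMPARTMENTS]


def calibrate_channel_floors(stack: ChannelStack, seg: Segmentation,
                             percentile: float = BACKGROUND_PERCENTILE) -> dict[str, float]:
    """Per-channel minimum-intensity floor from background pixels.

    Background is everything outside the detected nuclei dilated by
    5 um; the floor is the 99.5th percentile of background intensity, so a
    cell whose compartment mean does not exceed it cannot be called
    positive.
    """
    fg = seg.nuclei_labels > 0
    if fg.any():
        background = ~morphology.dilate(fg, BACKGROUND_EXCLUSION_UM / seg.pixel_size_um)
    else:
        background = np.ones_like(fg)
    if not background.any():
        return {ch: 0.0 for ch in stack.channel_names}
    return {
        ch: float(np.percentile(stack[ch][background], percentile))
        for ch in stack.channel_names
    }


def midpoint_thresholds(intensity_model: dict[str, IntensityModel],
                        compartment: str = "cell") -> dict[str, ThresholdRule]:
    """Threshold rules at the midpoint of a generator's fg/bg means."""
    rules = {}
    for marker, ch in MARKER_CHANNELS.items():
        m = intensity_model[ch]
        rules[marker] = ThresholdRule((m.fg_mean + m.bg_mean) / 2.0, compartment)
    return rules


def train_marker_classifier(features: pd.DataFrame, labels: np.ndarray, marker: str,
                            seed: int = 0, n_estimators: int = 50,
                            max_depth: int = 8) -> TreeEnsembleRule:
    """Fit a seeded random-trees ensemble for one marker.

    ``labels`` is a boolean array aligned with ``features`` rows. Both
    classes must be represented.
    """
    labels = np.asarray(labels, dtype=bool)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        missing = "positive" if True not in classes else "negative"
        raise ValueError(f"training set for {marker!r} has no {missing} examples")
    channels = sorted({c.rsplit("_", 2)[0] for c in features.columns if c.endswith("_mean")})
    cols = feature_columns(channels)
    X = features[cols].to_numpy(dtype=np.float64)
    # degenerate cytoplasm means are imputed with the whole-cell mean
    for i, col in enumerate(cols):
        if col.endswith("cytoplasm_mean"):
            fallback = features[col.replace("cytoplasm", "cell")].to_numpy(dtype=np.float64)
            nan = np.isnan(X[:, i])
            X[nan, i] = fallback[nan]
    rf = RandomForestClassifier(n_estimators=n_estimators, max_depth=max_depth, random_state=seed)
    rf.fit(X, labels)
    return TreeEnsembleRule(model=rf, feature_columns=cols)


def _predict_marker(features: pd.DataFrame, rule) -> np.ndarray:
    if isinstance(rule, ThresholdRule):
        raise AssertionError("handled by caller")
    X = features[rule.feature_columns].to_numpy(dtype=np.float64)
    for i, col in enumerate(rule.feature_columns):
        if col.endswith("cytoplasm_mean"):
            fallback = features[col.replace("cytoplasm", "cell")].to_numpy(dtype=np.float64)
            nan = np.isnan(X[:, i])
            X[nan, i] = fallback[nan]
    return rule.model.predict(X).astype(bool)


def classify_cells(features: pd.DataFrame, model: ClassifierModel) -> pd.DataFrame:
    """Marker and composite calls for every cell in the feature table."""
    calls = pd.DataFrame({"cell_id": features["cell_id"].to_numpy()})
    for marker in MARKERS:
        rule = model.markers[marker]
        ch = MARKER_CHANNELS[marker]
        floor_col = f"{ch}_{rule.compartment}_mean"
        if floor_col not in features.columns:
            raise ValueError(f"feature column {floor_col!r} missing")
        comp_mean = features[floor_col].to_numpy(dtype=np.float64)
        bad = np.isnan(comp_mean)
        if isinstance(rule, ThresholdRule):
            if bad.any():
                ids = features.loc[bad, "cell_id"].tolist()
                raise ValueError(f"missing {floor_col} for cells {ids[:10]}")
            pos = comp_mean > rule.threshold
        else:
            pos = _predict_marker(features, rule)
        floor = model.channel_floors.get(ch)
        if floor is not None:
            pos = pos & (comp_mean > floor)
        calls[f"{marker}_pos"] = pos
    calls["cd68_hla2_pos"] = calls["cd68_pos"] & calls["hla2_pos"]
    calls["insulin_hla2_pos"] = calls["insulin_pos"] & calls["hla2_pos"]
    return calls
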