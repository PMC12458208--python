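"""Recovery metrics against generator ground truth.

Detections are matched to true cells greedily by increasing distance
within a fixed matching radius (one-to-one), the standard convention for
point-detection benchmarking in microscopy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

DEFAULT_MATCH_RADIUS_UM = 5.0


def match_points(true_xy: np.ndarray, det_xy: np.ndarray,
                 radius_um: float = DEFAULT_MATCH_RADIUS_UM) -> tuple[np.ndarray, np.ndarray]:
    """Greedy one-to-one matching; returns (true_idx, det_idx) pairs."""
    true_xy = np.asarray(true_xy, dtype=float).reshape(-1, 2)
    det_xy = np.asarray(det_xy, dtype=float).reshape(-1, 2)
    if len(true_xy) == 0 or len(det_xy) == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    tree = cKDTree(det_xy)
    pairs = tree.query_ball_point(true_xy, r=radius_um)
    cand = [
        (np.hypot(*(true_xy[gi] - det_xy[di])), gi, di)
        for gi, dis in enumerate(pairs) for di in dis
    ]
    cand.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    t_idx, d_idx = [], []
    for _, gi, di in cand:
        if gi in used_t or di in used_d:
            continue
        used_t.add(gi)
        used_d.add(di)
        t_idx.append(gi)
        d_idx.append(di)
    return np.asarray(t_idx, dtype=int), np.asarray(d_idx, dtype=int)


@dataclass
class DetectionScore:
    n_true: int
    n_detected: int
    n_matched: int

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else 0.0

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_true if self.n_true else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def score_detection(true_xy: np.ndarray, det_xy: np.ndarray,
                    radius_um: float = DEFAULT_MATCH_RADIUS_UM) -> DetectionScore:
    t_idx, _ = match_points(true_xy, det_xy, radius_um)
    return DetectionScore(n_true=len(true_xy), n_detected=len(det_xy), n_matched=len(t_idx))


def call_accuracy(gt_cells: pd.DataFrame, features: pd.DataFrame, calls: pd.DataFrame,
                  radius_um: float = DEFAULT_MATCH_RADIUS_UM) -> dict[str, float]:
    """Per-marker call accuracy over matched (true cell, detection) pairs."""
    true_xy = gt_cells[["x_um", "y_um"]].to_numpy()
    det_xy = features[["centroid_x_um", "centroid_y_um"]].to_numpy()
    t_idx, d_idx = match_points(true_xy, det_xy, radius_um)
    merged = calls.set_index("cell_id").loc[features["cell_id"].to_numpy()[d_idx]]
    out = {}
    for marker in ("insulin", "cd68", "hla2"):
        truth = gt_cells[f"{marker}_pos"].to_numpy()[t_idx]
        pred = merged[f"{marker}_pos"].to_numpy()
        out[marker] = float(np.mean(truth == pred)) if len(truth) else float("nan")
    return out
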