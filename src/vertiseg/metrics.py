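"""Per-vertebra segmentation accuracy and detection accounting.

Segmentation quality is reported per instance as the Dice coefficient, the
signed (ds) and unsigned (du) mean surface distances in mm, and the symmetric
Hausdorff distance (HD).  ds/du are averaged over the *predicted* surface
(directed); predicted surface voxels lying inside the reference contribute a
negative distance to ds, so a positive mean ds indicates over-segmentation.

Detection accounting matches predicted to reference instances greedily by
maximum voxel overlap, each instance used at most once; unmatched reference
instances are false negatives, unmatched predictions false positives, and
F1 = 2TP / (2TP + FP + FN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import LabelMap

__all__ = [
    "MatchReport",
    "MetricsRow",
    "dice",
    "surface_distances",
    "match_instances",
    "f1_from_counts",
    "detection_rates",
    "summarize",
]

_CONN6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class MetricsRow:
    dice: float
    ds: float
    du: float
    hd: float


@dataclass
class MatchReport:
    pairs: list[tuple[int, int]]  # (predicted label, reference label)
    tp: int
    fp: int
    fn: int

    @property
    def f1(self) -> float:
        return f1_from_counts(self.tp, self.fp, self.fn)


def f1_from_counts(tp: int, fp: int, fn: int) -> float:
    """F1 = 2TP / (2TP + FP + FN)."""
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 1.0


def detection_rates(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """FP and FN percentages of all accounted instances (TP + FP + FN)."""
    n = tp + fp + fn
    if n == 0:
        return 0.0, 0.0
    return 100.0 * fp / n, 100.0 * fn / n


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one face-adjacent background voxel
    (the volume border counts as background)."""
    eroded = ndimage.binary_erosion(mask, structure=_CONN6, border_value=0)
    return mask & ~eroded


def surface_distances(
    pred: np.ndarray, ref: np.ndarray, spacing=(1.0, 1.0, 1.0)
) -> tuple[float, float, float]:
    """Signed/unsigned mean surface distance and Hausdorff distance (mm).

    du is the mean over predicted surface voxels of the Euclidean distance to
    the nearest reference surface voxel; ds applies a negative sign where the
    predicted surface voxel lies inside the reference; HD is the maximum of
    the two directed maxima.
    """
    pred = np.asarray(pred, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    if pred.shape != ref.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {ref.shape}")
    if not pred.any() or not ref.any():
        raise ValueError("both masks must be nonempty")
    spacing = np.asarray(spacing, dtype=float)
    pred_surf_idx = np.argwhere(_surface_voxels(pred))
    pred_surf = pred_surf_idx * spacing
    ref_surf = np.argwhere(_surface_voxels(ref)) * spacing
    d_pred, _ = cKDTree(ref_surf).query(pred_surf)
    inside = ref[tuple(pred_surf_idx.T)]
    du = float(d_pred.mean())
    ds = float(np.where(inside, -d_pred, d_pred).mean())
    d_ref, _ = cKDTree(pred_surf).query(ref_surf)
    hd = float(max(d_pred.max(), d_ref.max()))
    return ds, du, hd


def match_instances(pred: LabelMap, ref: LabelMap) -> MatchReport:
    """Greedy one-to-one matching of predicted to reference instances.

    Candidate pairs are ranked by descending voxel overlap; each predicted and
    each reference instance is used at most once.  Matched pairs (overlap > 0)
    are true positives.
    """
    if pred.values.shape != ref.values.shape:
        raise ValueError("prediction and reference are on different grids")
    p = pred.values.astype(np.int64)
    r = ref.values.astype(np.int64)
    n_p = int(p.max()) + 1
    n_r = int(r.max()) + 1
    overlap = np.bincount((p * n_r + r).ravel(), minlength=n_p * n_r).reshape(n_p, n_r)
    pred_labels = set(int(l) for l in pred.labels)
    ref_labels = set(int(l) for l in ref.labels)
    cand = [
        (int(overlap[i, j]), i, j)
        for i in pred_labels
        for j in ref_labels
        if overlap[i, j] > 0
    ]
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    pairs: list[tuple[int, int]] = []
    used_p: set[int] = set()
    used_r: set[int] = set()
    for _, i, j in cand:
        if i in used_p or j in used_r:
            continue
        pairs.append((i, j))
        used_p.add(i)
        used_r.add(j)
    tp = len(pairs)
    fp = len(pred_labels) - tp
    fn = len(ref_labels) - tp
    return MatchReport(pairs=pairs, tp=tp, fp=fp, fn=fn)


def summarize(rows: list[MetricsRow]) -> pd.DataFrame:
    """Mean ± sd and median per metric over a set of per-instance rows."""
    if not rows:
        raise ValueError("no metric rows to summarize")
    df = pd.DataFrame([vars(r) for r in rows])
    return pd.DataFrame(
        {
            "mean": df.mean(),
            "sd": df.std(ddof=0),
            "median": df.median(),
        }
    )
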