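"""Model-based determination of vertebra centers.

Patch-wise center predictions are accumulated as weighted votes.  The number
of vertebrae in the volume of interest is unknown, so weighted k-means is run
for a range of cluster counts k and the best k is selected with a clustering
score CS(k) built from the anatomy of inter-vertebral spacing:

* one Gaussian ``G_i^dst`` per neighboring center pair i (counted from the
  bottom) models the z-projected distance ``D_i`` of that pair,
* one Gaussian ``G^diff`` models the difference ``D_{i+1} - D_i`` of
  consecutive distances, which is far more stationary across spine levels
  than the distances themselves.

For every window of three consecutive centers the two pair densities and the
difference density are multiplied; CS(k) is the minimum of these products
(the worst-matching window), and

    k_opti = argmax_{k in [3, 19]} CS(k).

The distances themselves drift systematically from lumbar to upper thoracic
levels, which is why a per-level family of Gaussians is used instead of one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "CenterVote",
    "DistanceModel",
    "ClusterResult",
    "fit_distance_model",
    "clustering_score",
    "weighted_kmeans",
    "select_k",
]

#: lower bound on fitted standard deviations (mm), prevents infinite densities
SIGMA_FLOOR_MM = 0.5

#: number of neighboring-pair distance Gaussians in the full model
N_PAIRS = 17

#: k search range of the cluster-count selection
K_RANGE = (3, 19)


@dataclass(frozen=True)
class CenterVote:
    """A single predicted vertebra center with its confidence weight."""

    position: np.ndarray  # (z, y, x) mm
    weight: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,):
            raise ValueError("vote position must be a 3-vector")
        if not self.weight > 0:
            raise ValueError("vote weight must be positive")


@dataclass
class DistanceModel:
    """Per-level pair-distance Gaussians plus one distance-difference Gaussian.

    ``pair_gaussians[i]`` is the ``(mu, sigma)`` of the z-distance of the
    (i+1)-th neighboring center pair from the bottom; ``diff_gaussian`` is the
    ``(mu, sigma)`` of consecutive distance differences pooled over all levels.
    """

    pair_gaussians: list[tuple[float, float]]
    diff_gaussian: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.pair_gaussians:
            raise ValueError("at least one pair Gaussian is required")
        self.pair_gaussians = [(float(m), max(float(s), SIGMA_FLOOR_MM)) for m, s in self.pair_gaussians]
        m, s = self.diff_gaussian
        self.diff_gaussian = (float(m), max(float(s), SIGMA_FLOOR_MM))

    def pair(self, i: int) -> tuple[float, float]:
        """Gaussian for the i-th pair (0-based); levels beyond the fitted
        range reuse the top-most fitted Gaussian."""
        return self.pair_gaussians[min(i, len(self.pair_gaussians) - 1)]

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {"pairs": [[m, s] for m, s in self.pair_gaussians], "diff": list(self.diff_gaussian)},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, source: str | Path) -> "DistanceModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls([tuple(x) for x in d["pairs"]], tuple(d["diff"]))


@dataclass
class ClusterResult:
    kopti: int
    centers: np.ndarray  # (kopti, 3) mm, sorted by z
    score_by_k: dict[int, float]


def _gauss(x: float, mu: float, sigma: float, peak_normalized: bool = False) -> float:
    z = (x - mu) / sigma
    val = np.exp(-0.5 * z * z)
    if not peak_normalized:
        val /= sigma * np.sqrt(2.0 * np.pi)
    return float(val)


def fit_distance_model(
    training_center_lists: Sequence[np.ndarray],
    n_pairs: int = N_PAIRS,
) -> DistanceModel:
    """Fit the distance model by per-pair maximum likelihood.

    Parameters
    ----------
    training_center_lists : sequence of (n_i, 3) arrays
        Ordered (bottom-to-top) body centers in mm, one array per training scan.
    n_pairs : int
        Number of neighboring-pair Gaussians to fit (17 covers an 18-vertebra
        lumbar + thoracic stack).

    Every pair index 1..n_pairs must be observed in at least two scans; the
    MLE is the sample mean and the biased sample standard deviation, floored
    at ``SIGMA_FLOOR_MM``.  The difference Gaussian is fitted to all
    consecutive-gap differences pooled across scans and levels.
    """
    per_pair: list[list[float]] = [[] for _ in range(n_pairs)]
    diffs: list[float] = []
    for centers in training_center_lists:
        centers = np.asarray(centers, dtype=float)
        z = np.sort(centers[:, 0]) if centers.ndim == 2 else np.sort(centers)
        gaps = np.diff(z)
        for i, g in enumerate(gaps[:n_pairs]):
            per_pair[i].append(float(g))
        diffs.extend(np.diff(gaps).tolist())
    pairs = []
    for i, samples in enumerate(per_pair):
        if len(samples) < 2:
            raise ValueError(f"pair index {i + 1} has {len(samples)} sample(s); need >= 2")
        mu = float(np.mean(samples))
        sigma = float(np.std(samples))  # biased MLE sd
        pairs.append((mu, max(sigma, SIGMA_FLOOR_MM)))
    if len(diffs) < 2:
        raise ValueError("need at least 2 consecutive-gap differences to fit the diff Gaussian")
    diff = (float(np.mean(diffs)), max(float(np.std(diffs)), SIGMA_FLOOR_MM))
    return DistanceModel(pairs, diff)


def _sort_centers(centers: np.ndarray) -> np.ndarray:
    centers = np.asarray(centers, dtype=float)
    order = np.lexsort((centers[:, 2], centers[:, 1], centers[:, 0]))
    return centers[order]


def clustering_score(
    centers: np.ndarray,
    model: DistanceModel,
    peak_normalized: bool = False,
) -> float:
    """CS(k): the worst three-consecutive-center window score.

    Centers are z-sorted internally (ties broken by y then x).  For each window
    of three consecutive centers with z-gaps ``D_i`` and ``D_{i+1}`` the score
    is ``G_i(D_i) * G_{i+1}(D_{i+1}) * G_diff(D_{i+1} - D_i)``; the minimum
    over all windows is returned.  Requires k >= 3.
    """
    centers = _sort_centers(np.asarray(centers, dtype=float))
    k = len(centers)
    if k < 3:
        raise ValueError(f"clustering score is undefined for k={k} < 3")
    gaps = np.diff(centers[:, 0])
    scores = []
    for i in range(k - 2):
        m1, s1 = model.pair(i)
        m2, s2 = model.pair(i + 1)
        md, sd = model.diff_gaussian
        scores.append(
            _gauss(gaps[i], m1, s1, peak_normalized)
            * _gauss(gaps[i + 1], m2, s2, peak_normalized)
            * _gauss(gaps[i + 1] - gaps[i], md, sd, peak_normalized)
        )
    return float(min(scores))


def weighted_kmeans(votes: Sequence[CenterVote], k: int, seed: int = 0) -> np.ndarray:
    """Confidence-weighted k-means on vote positions.

    Initialization is weighted probabilistic farthest-point (k-means++)
    seeding with a fixed seed, so results are reproducible.  Returns the
    ``(k, 3)`` cluster centers (unsorted).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(votes) < k:
        raise ValueError(f"need at least k={k} votes, got {len(votes)}")
    X = np.array([v.position for v in votes])
    w = np.array([v.weight for v in votes])
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError("fewer distinct vote positions than k")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(X, sample_weight=w)
    return km.cluster_centers_


def select_k(
    votes: Sequence[CenterVote],
    model: DistanceModel,
    k_range: tuple[int, int] = K_RANGE,
    exclusion_mask=None,
    seed: int = 0,
    peak_normalized: bool = False,
) -> ClusterResult:
    """Pick the vertebra count by maximizing CS(k) over weighted k-means runs.

    ``exclusion_mask`` is an optional binary mask on a grid (any object with
    ``values``, ``spacing``, ``origin`` and ``mm_to_voxel``): votes falling on
    a positive mask voxel (e.g. inside the segmented pelvis) are treated as
    outliers and removed before clustering.
    """
    votes = list(votes)
    if exclusion_mask is not None:
        kept = []
        mvals = np.asarray(exclusion_mask.values)
        for v in votes:
            idx = np.rint(exclusion_mask.mm_to_voxel(v.position)).astype(int)
            inside = all(0 <= idx[a] < mvals.shape[a] for a in range(3))
            if inside and mvals[tuple(idx)] > 0:
                continue
            kept.append(v)
        votes = kept
    if len(votes) < 3:
        raise ValueError("fewer than 3 votes remain after exclusion")

    lo, hi = k_range
    lo = max(lo, K_RANGE[0])
    hi = min(hi, K_RANGE[1])
    n_distinct = np.unique(np.array([v.position for v in votes]), axis=0).shape[0]
    score_by_k: dict[int, float] = {}
    best_k, best_score, best_centers = None, -np.inf, None
    for k in range(lo, hi + 1):
        if k > n_distinct:
            score_by_k[k] = -np.inf
            continue
        centers = _sort_centers(weighted_kmeans(votes, k, seed=seed))
        cs = clustering_score(centers, model, peak_normalized=peak_normalized)
        score_by_k[k] = cs
        if cs > best_score:
            best_k, best_score, best_centers = k, cs, centers
    if best_k is None:
        raise ValueError("no feasible k in the requested range")
    return ClusterResult(kopti=best_k, centers=best_centers, score_by_k=score_by_k)
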