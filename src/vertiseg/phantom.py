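"""Synthetic spine phantoms and synthetic center votes.

The phantom emulates the geometry that drives every downstream stage: a
bottom-to-top stack of vertebra-like objects, each an axis-aligned ellipsoidal
body plus a thin posterior process, with Gaussian-distributed inter-center
z-spacing, two-level CT-like intensities and additive Gaussian noise.
Optional deformations reproduce the two clinically relevant failure inputs:
collapsed (flattened) vertebrae and fused adjacent vertebrae.

The intensity model is deliberately simple (piecewise constant + noise): it is
sufficient to train and exercise the segmentation network, not to look like a
radiometrically realistic CT scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import LabelMap, Volume
from .center_model import CenterVote

__all__ = [
    "PhantomSpec",
    "generate_spine_phantom",
    "spine_phantom_with_centers",
    "generate_center_votes",
]

#: working-grid voxel size, (z, y, x) mm
DEFAULT_SPACING = (2.0, 0.977, 0.977)


@dataclass
class PhantomSpec:
    """Parameters of a synthetic spine.

    Distances are in millimeters.  ``collapse_indices`` lists 1-based vertebra
    indices (bottom to top) whose z-extent is reduced to 40% of nominal;
    ``fuse_pairs`` lists adjacent 1-based index pairs ``(i, i+1)`` bridged by a
    bony connection so their union is 26-connected.
    """

    n_vertebrae: int = 5
    body_radii: tuple[float, float, float] = (12.0, 15.0, 15.0)  # (z, y, x) mm
    process_length: float = 15.0
    spacing_mean: float = 30.0
    spacing_sd: float = 2.0
    intensity_levels: tuple[float, float] = (40.0, 400.0)  # (soft tissue, bone)
    noise_sd: float = 20.0
    collapse_indices: frozenset[int] = field(default_factory=frozenset)
    fuse_pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    seed: int = 0
    voxel_spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        self.collapse_indices = frozenset(self.collapse_indices)
        self.fuse_pairs = frozenset(tuple(p) for p in self.fuse_pairs)
        self.validate()

    def validate(self) -> None:
        if not 3 <= self.n_vertebrae <= 18:
            raise ValueError(
                f"n_vertebrae must be in [3, 18], got {self.n_vertebrae}"
            )
        for i, j in self.fuse_pairs:
            if j != i + 1 or not 1 <= i < self.n_vertebrae:
                raise ValueError(f"fuse_pairs must be adjacent index pairs, got {(i, j)}")
        for i in self.collapse_indices:
            if not 1 <= i <= self.n_vertebrae:
                raise ValueError(f"collapse index {i} outside 1..{self.n_vertebrae}")
        # non-fused neighbors must not touch
        if self.spacing_mean <= 2 * self.body_radii[0] and len(self.fuse_pairs) < self.n_vertebrae - 1:
            raise ValueError(
                "spacing_mean must exceed twice the body z-radius for non-fused pairs"
            )


def _paint_ellipsoid(lab: np.ndarray, center_vox: np.ndarray, radii_vox: np.ndarray, value: int) -> None:
    lo = np.maximum(np.floor(center_vox - radii_vox).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(center_vox + radii_vox).astype(int) + 2, lab.shape)
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d = (
        ((zz - center_vox[0]) / radii_vox[0]) ** 2
        + ((yy - center_vox[1]) / radii_vox[1]) ** 2
        + ((xx - center_vox[2]) / radii_vox[2]) ** 2
    )
    region = lab[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    region[(d <= 1.0) & (region == 0)] = value


def _paint_box(lab: np.ndarray, lo: np.ndarray, hi: np.ndarray, value: int) -> None:
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, lab.shape)
    if np.any(hi <= lo):
        return
    region = lab[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    region[region == 0] = value


def spine_phantom_with_centers(
    spec: PhantomSpec,
) -> tuple[Volume, LabelMap, np.ndarray]:
    """Generate a phantom and also return the true body centers (mm, z-sorted).

    Same contract as :func:`generate_spine_phantom`; the extra return value is
    the ``(n, 3)`` array of ellipsoid centers in (z, y, x) mm, bottom to top.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sp = np.asarray(spec.voxel_spacing, dtype=float)
    rz, ry, rx = spec.body_radii

    gaps = rng.normal(spec.spacing_mean, spec.spacing_sd, size=spec.n_vertebrae - 1)
    gaps = np.clip(gaps, 2.05 * rz, None)  # keep non-fused neighbors separated
    z_centers = np.concatenate([[0.0], np.cumsum(gaps)])

    margin = 10.0  # mm of padding around the stack
    z0 = -(rz + margin)
    z_extent = z_centers[-1] + 2 * (rz + margin)
    y_extent = 2 * ry + spec.process_length + 2 * margin
    x_extent = 2 * rx + 2 * margin
    shape = tuple(int(np.ceil(e / s)) for e, s in zip((z_extent, y_extent, x_extent), sp))

    # body center position in voxels; anterior body sits at low y
    yc = (ry + margin) / sp[1]
    xc = shape[2] / 2.0
    lab = np.zeros(shape, dtype=np.int32)
    centers_mm = np.empty((spec.n_vertebrae, 3))
    proc_half_vox = 1  # 3-voxel-thick posterior process (thin in z and x)
    for i in range(spec.n_vertebrae):
        label = i + 1
        radii = np.array([rz, ry, rx])
        if label in spec.collapse_indices:
            radii[0] *= 0.4  # z-extent <= 50% of nominal
        cz = (z_centers[i] - z0) / sp[0]
        cvox = np.array([cz, yc, xc])
        _paint_ellipsoid(lab, cvox, radii / sp, label)
        # posterior process: thin box from body edge in +y
        y_from = int(round(yc + 0.6 * ry / sp[1]))
        y_to = int(round(yc + (ry + spec.process_length) / sp[1]))
        z_half = max(proc_half_vox, 1)
        _paint_box(
            lab,
            np.array([int(round(cz)) - z_half, y_from, int(round(xc)) - proc_half_vox]),
            np.array([int(round(cz)) + z_half + 1, y_to, int(round(xc)) + proc_half_vox + 1]),
            label,
        )
        centers_mm[i] = np.array([cz, yc, xc]) * sp
    # fusion bridges between adjacent bodies
    for i, j in sorted(spec.fuse_pairs):
        cz_i = (z_centers[i - 1] - z0) / sp[0]
        cz_j = (z_centers[j - 1] - z0) / sp[0]
        _paint_box(
            lab,
            np.array([int(np.floor(cz_i)), int(round(yc)) - 3, int(round(xc)) - 3]),
            np.array([int(np.ceil(cz_j)) + 1, int(round(yc)) + 4, int(round(xc)) + 4]),
            int(i),
        )

    soft, bone = spec.intensity_levels
    values = np.full(shape, soft, dtype=np.float32)
    values[lab > 0] = bone
    values += rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    spacing = tuple(sp)
    return (
        Volume(values, spacing),
        LabelMap(lab, spacing),
        centers_mm,
    )


def generate_spine_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMap]:
    """Generate a synthetic spine CT-like volume and its instance label map.

    The label map contains exactly ``spec.n_vertebrae`` instances labeled
    1..n bottom to top; the volume carries elevated intensity inside labeled
    voxels plus additive Gaussian noise.  Identical specs (including seed)
    produce bit-identical output.
    """
    vol, lm, _ = spine_phantom_with_centers(spec)
    return vol, lm


def _default_confidence_sampler(rng: np.random.Generator, n: int) -> np.ndarray:
    # emulates the spread of visibility fractions seen across overlapping patches
    return rng.uniform(0.1, 1.0, size=n)


def generate_center_votes(
    centers: Sequence[Sequence[float]] | np.ndarray,
    votes_per_center: int,
    position_sd: float,
    confidence_model: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int = 0,
) -> list[CenterVote]:
    """Simulate accumulated per-patch center predictions around true centers.

    Each vote is an isotropic Gaussian perturbation (sd ``position_sd`` mm) of a
    true center with a confidence weight in (0, 1] drawn from
    ``confidence_model`` (default: uniform on [0.1, 1]).
    """
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 2 or centers.shape[1] != 3:
        raise ValueError("centers must be an (n, 3) array of (z, y, x) mm points")
    if centers.shape[0] < 3:
        raise ValueError("need at least 3 centers")
    if votes_per_center <= 0:
        raise ValueError("votes_per_center must be positive")
    if confidence_model is None:
        confidence_model = _default_confidence_sampler
    rng = np.random.default_rng(seed)
    votes: list[CenterVote] = []
    for c in centers:
        pos = c + rng.normal(0.0, position_sd, size=(votes_per_center, 3))
        w = np.clip(np.asarray(confidence_model(rng, votes_per_center), dtype=float), 1e-9, 1.0)
        votes.extend(CenterVote(position=p, weight=float(wi)) for p, wi in zip(pos, w))
    return votes
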