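"""Three-label encoding of instance maps and vertebral-body centers.

Each vertebra instance is split into an inner *body* (the part surviving a
morphological erosion with the 6-connected unit ball) and a one-shell
*boundary* (the eroded-away remainder).  Training the segmentation network on
this {background, body, boundary} encoding keeps neighboring vertebrae
separable: bodies of adjacent instances can never touch.

The localization target of a vertebra is the center of mass of its *vertebral
body*, obtained by a morphological opening that removes the thin posterior
processes before the center of mass is taken.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import BACKGROUND, BODY, BOUNDARY, LabelMap, ThreeLabelMap

__all__ = [
    "encode_three_label",
    "merge_foreground",
    "vertebral_body_center",
    "all_body_centers",
    "ball_6",
    "anisotropic_ellipsoid",
]


def ball_6(radius: int = 1) -> np.ndarray:
    """Discrete ball of the given radius in the city-block (6-connected) metric."""
    r = int(radius)
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (np.abs(zz) + np.abs(yy) + np.abs(xx)) <= r


def anisotropic_ellipsoid(r_z: int, r_inplane: int) -> np.ndarray:
    """Ellipsoidal structuring element with distinct z and in-plane radii."""
    rz, rp = max(int(r_z), 0), max(int(r_inplane), 1)
    zz, yy, xx = np.mgrid[-rz : rz + 1, -rp : rp + 1, -rp : rp + 1]
    rz_eff = max(rz, 1e-9)
    return (zz / rz_eff) ** 2 + (yy / rp) ** 2 + (xx / rp) ** 2 <= 1.0


def encode_three_label(lm: LabelMap, erosion_radius: int = 1) -> ThreeLabelMap:
    """Convert an instance label map to the {background, body, boundary} map.

    Each instance is eroded independently with the 6-connected ball of the
    given radius; the surviving core becomes *body*, the remainder *boundary*.
    Instances thin enough to be annihilated by the erosion become
    boundary-only.  Body and boundary partition the original foreground
    exactly.
    """
    if erosion_radius < 1:
        raise ValueError("erosion_radius must be >= 1")
    out = np.zeros(lm.values.shape, dtype=np.int8)
    structure = ball_6(1)
    objects = ndimage.find_objects(lm.values)
    for label, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        # pad so the erosion sees background beyond the bounding box
        pad = erosion_radius
        slc = tuple(
            slice(max(s.start - pad, 0), min(s.stop + pad, dim))
            for s, dim in zip(slc, lm.values.shape)
        )
        inst = lm.values[slc] == label
        body = ndimage.binary_erosion(inst, structure=structure, iterations=erosion_radius)
        region = out[slc]
        region[inst] = BOUNDARY
        region[body] = BODY
    return ThreeLabelMap(out, lm.spacing, lm.origin, erosion_radius=erosion_radius)


def merge_foreground(tlm: ThreeLabelMap) -> np.ndarray:
    """Binary foreground mask: body ∪ boundary."""
    return tlm.values != BACKGROUND


def vertebral_body_center(
    instance_mask: np.ndarray,
    opening_radius: tuple[int, int] = (1, 3),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Center of mass (mm) of the vertebral body of one instance.

    A morphological opening with an ellipsoidal element of radius
    ``opening_radius = (r_z, r_inplane)`` voxels removes processes thinner
    than twice the in-plane radius; the center of mass of the opened mask is
    returned in mm.  If the opening empties the mask (degenerate instance),
    the center of mass of the unopened mask is used instead.
    """
    instance_mask = np.asarray(instance_mask, dtype=bool)
    if not instance_mask.any():
        raise ValueError("instance mask is empty")
    se = anisotropic_ellipsoid(*opening_radius)
    opened = ndimage.binary_opening(instance_mask, structure=se)
    target = opened if opened.any() else instance_mask
    com_vox = np.asarray(ndimage.center_of_mass(target))
    return np.asarray(origin) + com_vox * np.asarray(spacing)


def all_body_centers(
    lm: LabelMap, opening_radius: tuple[int, int] = (1, 3)
) -> dict[int, np.ndarray]:
    """Vertebral-body centers (mm) for every instance, keyed by label."""
    centers: dict[int, np.ndarray] = {}
    for label, slc in enumerate(ndimage.find_objects(lm.values), start=1):
        if slc is None:
            continue
        sub = lm.values[slc] == label
        origin_off = np.asarray(lm.origin) + np.array([s.start for s in slc]) * np.asarray(lm.spacing)
        centers[label] = vertebral_body_center(
            sub, opening_radius=opening_radius, spacing=lm.spacing, origin=tuple(origin_off)
        )
    return centers
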