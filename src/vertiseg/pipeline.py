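"""End-to-end scan segmentation.

``segment_scan`` runs the full chain: resample to the working grid,
intensity normalization, VOI cropping, patch-wise network inference,
stitching, vote accumulation, model-based center determination, watershed
instance separation, boundary recovery, missed-vertebra recovery, island and
hole cleanup, and relabeling — returning the instance map on the original
scan grid.

``postprocess_instances`` exposes the post-network half of the chain on its
own, so it can be driven by ground-truth three-label maps and simulated
votes (the oracle shortcut used throughout the test suite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import SimpleITK as sitk

from .core import LabelMap, ThreeLabelMap, Volume, _from_sitk, _to_sitk
from .center_model import CenterVote, DistanceModel, K_RANGE, select_k
from .instance import (
    InstanceSegmentation,
    fill_islands_holes,
    recover_boundary,
    recover_missing,
    refine_centers,
    relabel_bottom_to_top,
    signed_distance_map,
    split_watershed,
)
from .patching import LocalizationTarget, build_patch_grid, stitch_predictions, DEFAULT_PATCH_SIZE
from .preprocess import (
    DEFAULT_CROP_SIZE,
    NormStats,
    WORKING_SPACING,
    clip_and_normalize,
    crop_voi,
    resample_to_working_grid,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "postprocess_instances", "segment_scan"]


@dataclass
class PipelineConfig:
    """Everything needed to run ``segment_scan``."""

    checkpoint: str | Path | None = None
    distance_model: DistanceModel | str | Path | None = None
    norm_stats: NormStats | None = None
    crop_size: tuple[int, int, int] = DEFAULT_CROP_SIZE
    patch_size: tuple[int, int, int] = DEFAULT_PATCH_SIZE
    overlap_fraction: float = 0.5
    target_spacing: tuple[float, float, float] = WORKING_SPACING
    loc_gate_fraction: float = 0.15
    mean_vertebra_volume: float | None = None
    min_vote_confidence: float = 0.01
    k_range: tuple[int, int] = K_RANGE
    seed: int = 0

    def resolve_distance_model(self) -> DistanceModel:
        if isinstance(self.distance_model, DistanceModel):
            return self.distance_model
        if self.distance_model is None:
            raise ValueError("no distance model configured")
        return DistanceModel.from_json(self.distance_model)


def _snap_to_mask(seeds_vox: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Move any seed falling outside the mask to the nearest mask voxel."""
    from scipy import ndimage

    seeds_vox = np.asarray(seeds_vox, dtype=int)
    outside = [i for i, s in enumerate(seeds_vox) if not mask[tuple(s)]]
    if not outside:
        return seeds_vox
    _, idx = ndimage.distance_transform_edt(~mask, return_indices=True)
    out = seeds_vox.copy()
    for i in outside:
        out[i] = idx[(slice(None),) + tuple(seeds_vox[i])]
    return out


def postprocess_instances(
    tlm: ThreeLabelMap,
    votes: Sequence[CenterVote],
    distance_model: DistanceModel,
    seed: int = 0,
    k_range: tuple[int, int] = K_RANGE,
    exclusion_mask=None,
) -> InstanceSegmentation:
    """From stitched three-label output plus center votes to instances.

    Runs k selection, center refinement, seeded watershed on the body label,
    boundary recovery, missed-vertebra recovery, per-instance island/hole
    cleanup, and bottom-to-top relabeling.
    """
    result = select_k(votes, distance_model, k_range=k_range, exclusion_mask=exclusion_mask, seed=seed)
    log.info("selected k=%d (CS=%.3g)", result.kopti, result.score_by_k[result.kopti])

    body = tlm.body_mask
    dmap = signed_distance_map(body, tlm.spacing)
    seeds = np.rint([tlm.mm_to_voxel(c) for c in result.centers]).astype(int)
    seeds = np.clip(seeds, 0, np.asarray(body.shape) - 1)
    seeds = refine_centers(seeds, dmap)
    seeds = _snap_to_mask(seeds, body)

    labels = split_watershed(body, seeds, dmap=dmap)
    labels = recover_boundary(labels, tlm)
    seg = InstanceSegmentation(
        labels=LabelMap(labels, tlm.spacing, tlm.origin),
        provenance={l: "clustered" for l in range(1, result.kopti + 1)},
    )
    seg = recover_missing(seg, tlm, distance_model)
    log.info("instances after recovery: k=%d", seg.k)

    values = seg.labels.values.copy()
    for lab in [int(l) for l in seg.labels.labels]:
        mask = values == lab
        cleaned = fill_islands_holes(mask)
        values[mask & ~cleaned] = 0
        values[cleaned & (values == 0)] = lab
    final = relabel_bottom_to_top(LabelMap(values, tlm.spacing, tlm.origin))
    return InstanceSegmentation(labels=final, provenance=seg.provenance)


def _labels_to_reference_grid(lm: LabelMap, ref: Volume) -> LabelMap:
    """Nearest-neighbor resample of a label map onto a reference scan grid."""
    img = _to_sitk(lm)
    out = sitk.Resample(
        img,
        size=tuple(int(n) for n in ref.shape[::-1]),
        transform=sitk.Transform(),
        interpolator=sitk.sitkNearestNeighbor,
        outputOrigin=tuple(ref.origin[::-1]),
        outputSpacing=tuple(ref.spacing[::-1]),
        outputDirection=img.GetDirection(),
        defaultPixelValue=0,
    )
    arr, spacing, origin = _from_sitk(out)
    return LabelMap(arr.astype(np.int32), spacing, origin)


def segment_scan(
    ct: Volume,
    cfg: PipelineConfig,
    predictor: Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, LocalizationTarget]] | None = None,
    pelvis_mask: LabelMap | None = None,
    bottom_plane: int | None = None,
) -> InstanceSegmentation:
    """Segment all vertebrae in a CT scan.

    ``predictor`` maps a ``(D, H, W)`` patch and its VOI voxel origin to
    ``(class probabilities, localization target)``; when omitted it is built
    from the configured checkpoint (the origin is then ignored).
    ``pelvis_mask`` / ``bottom_plane`` select the VOI anchor (falling back to
    the scan bottom when neither is given).
    """
    if predictor is None:
        if cfg.checkpoint is None:
            raise ValueError("no checkpoint configured and no predictor supplied")
        from .nn import load_checkpoint, predict_patch

        model, meta = load_checkpoint(cfg.checkpoint)
        predictor = lambda patch, origin: predict_patch(model, patch)  # noqa: E731
        if cfg.mean_vertebra_volume is None and meta.get("mean_vertebra_volume"):
            cfg.mean_vertebra_volume = float(meta["mean_vertebra_volume"])
        if cfg.norm_stats is None and meta.get("norm_stats"):
            cfg.norm_stats = NormStats(**meta["norm_stats"])
    distance_model = cfg.resolve_distance_model()

    work = resample_to_working_grid(ct, cfg.target_spacing)
    work = clip_and_normalize(work, ref=cfg.norm_stats)
    if pelvis_mask is not None:
        pelvis_work = resample_to_working_grid(pelvis_mask, cfg.target_spacing, is_labels=True)
        anchor: LabelMap | int | None = pelvis_work
        exclusion = pelvis_work
    else:
        anchor = bottom_plane
        exclusion = None
    voi, voi_spec = crop_voi(work, anchor=anchor, crop_size=cfg.crop_size)
    grid = build_patch_grid(voi_spec, cfg.patch_size, cfg.overlap_fraction)
    log.info("VOI %s from %s; %d patches", voi_spec.size, voi_spec.source, len(grid))

    from .nn.train import passes_volume_gate

    blocks: list[np.ndarray] = []
    votes: list[CenterVote] = []
    for origin in grid.origins:
        patch = voi.values[grid.patch_slices(origin)]
        probs, tgt = predictor(patch, origin)
        blocks.append(probs)
        fg = int((np.argmax(probs, axis=0) > 0).sum())
        if cfg.mean_vertebra_volume is not None and not passes_volume_gate(
            fg, cfg.mean_vertebra_volume, cfg.loc_gate_fraction
        ):
            continue
        center_mm = voi.voxel_to_mm(np.asarray(origin, dtype=float) + np.asarray(grid.patch_size) / 2.0)
        for off, conf in zip(tgt.offsets, tgt.confidences):
            if conf >= cfg.min_vote_confidence:
                votes.append(CenterVote(position=center_mm + off, weight=float(conf)))
    log.info("accumulated %d votes", len(votes))

    tlm = stitch_predictions(blocks, grid, spacing=voi.spacing, origin=voi.origin)
    seg = postprocess_instances(
        tlm, votes, distance_model, seed=cfg.seed, k_range=cfg.k_range, exclusion_mask=exclusion
    )

    # embed the VOI result into the working grid, then return to the scan grid
    full = np.zeros(work.shape, dtype=np.int32)
    full[voi_spec.slices()] = seg.labels.values
    on_work = LabelMap(full, work.spacing, work.origin)
    on_scan = _labels_to_reference_grid(on_work, ct)
    return InstanceSegmentation(labels=on_scan, provenance=seg.provenance)
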