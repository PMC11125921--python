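"""Training loops for the two network branches.

The segmentation branch is trained first with a macro-averaged soft Dice
loss over the three classes.  The localization head is trained afterwards
with a mean-squared-error loss on the 1x12 target while the shared encoder
stays frozen; only patches whose *predicted* foreground reaches at least a
fraction (default 15%) of the average vertebra volume are used, since a
patch with little vertebra content carries no useful location signal.

Patch-level augmentation applies a random rotation (default +-15 degrees per
axis) and random isotropic scaling (default +-25%) jointly to the intensity
patch, the label patch and the offset vectors, so geometric targets stay
consistent with the transformed image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from ..patching import LocalizationTarget
from .layers import Layer, softmax_channels
from .model import VertebraNet

__all__ = [
    "TrainConfig",
    "Adam",
    "soft_dice_loss",
    "mse_loss",
    "augment_patch",
    "train_segmentation",
    "train_localization",
    "predict_patch",
    "mean_vertebra_volume",
]

DICE_EPS = 1e-5


@dataclass
class TrainConfig:
    batch_size: int = 32
    aug_rotation_deg: float = 15.0
    aug_scale: float = 0.25
    augment: bool = True
    seg_lr: float = 1e-3
    seg_epochs: int = 20
    loc_lr: float = 1e-4
    loc_epochs: int = 400
    loc_gate_fraction: float = 0.15
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.loc_gate_fraction < 1.0:
            raise ValueError("loc_gate_fraction must be in (0, 1)")


class Adam:
    """Adam optimizer over a list of (layer, param-name) handles."""

    def __init__(self, params: list[tuple[Layer, str]], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(l.params[k]) for l, k in params]
        self.v = [np.zeros_like(l.params[k]) for l, k in params]

    def step(self) -> None:
        self.t += 1
        for i, (l, k) in enumerate(self.params):
            g = l.grads.get(k)
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            l.params[k] = (l.params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)


def to_onehot(labels: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """(N, D, H, W) int -> (N, C, D, H, W) float32 one-hot."""
    eye = np.eye(n_classes, dtype=np.float32)
    return np.moveaxis(eye[labels], -1, 1)


def soft_dice_loss(probs: np.ndarray, onehot: np.ndarray, eps: float = DICE_EPS
                   ) -> tuple[float, np.ndarray]:
    """Macro-averaged soft Dice loss and its gradient w.r.t. the probabilities.

    Per class c: dice_c = (2 * sum(p_c t_c) + eps) / (sum(p_c) + sum(t_c) + eps),
    pooled over batch and space; loss = 1 - mean_c dice_c.
    """
    C = probs.shape[1]
    axes = (0, 2, 3, 4)
    inter = (probs * onehot).sum(axis=axes)
    psum = probs.sum(axis=axes)
    tsum = onehot.sum(axis=axes)
    dice = (2 * inter + eps) / (psum + tsum + eps)
    loss = float(1.0 - dice.mean())
    # d(loss)/d(p_c) = -1/C * (2 t_c (psum+tsum+eps) - (2 inter + eps)) / (psum+tsum+eps)^2
    denom = (psum + tsum + eps)[None, :, None, None, None]
    num = 2 * onehot * denom - (2 * inter + eps)[None, :, None, None, None]
    dprobs = -(num / denom**2) / C
    return loss, dprobs.astype(np.float32)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    s = (dprobs * probs).sum(axis=1, keepdims=True)
    return (probs * (dprobs - s)).astype(np.float32)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 * diff / diff.size).astype(np.float32)


def augment_patch(
    patch: np.ndarray,
    labels: np.ndarray | None,
    offsets_mm: np.ndarray | None,
    rng: np.random.Generator,
    rotation_deg: float = 15.0,
    scale_frac: float = 0.25,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Jointly rotate and scale a patch, its labels and its offset vectors.

    The rotation is drawn per axis in ``+-rotation_deg`` and applied in
    physical (mm) space about the patch center; scaling is isotropic in
    ``1 +- scale_frac``.  Offsets transform as ``s * R @ offset``.
    """
    angles = np.deg2rad(rng.uniform(-rotation_deg, rotation_deg, size=3))
    s = 1.0 + rng.uniform(-scale_frac, scale_frac)
    ca = np.cos(angles)
    sa = np.sin(angles)
    Rz = np.array([[1, 0, 0], [0, ca[0], -sa[0]], [0, sa[0], ca[0]]])
    Ry = np.array([[ca[1], 0, sa[1]], [0, 1, 0], [-sa[1], 0, ca[1]]])
    Rx = np.array([[ca[2], -sa[2], 0], [sa[2], ca[2], 0], [0, 0, 1]])
    R = Rz @ Ry @ Rx
    S = np.diag(spacing)
    M = np.linalg.inv(S) @ (s * R) @ S  # voxel-space forward map
    M_inv = np.linalg.inv(M)
    center = (np.asarray(patch.shape, dtype=float) - 1) / 2.0
    offset = center - M_inv @ center
    out = ndimage.affine_transform(patch, M_inv, offset=offset, order=1, mode="nearest")
    lab_out = None
    if labels is not None:
        lab_out = ndimage.affine_transform(labels, M_inv, offset=offset, order=0, mode="constant")
    off_out = None
    if offsets_mm is not None:
        off_out = (s * (R @ np.asarray(offsets_mm, dtype=float).T)).T
    return out.astype(np.float32), lab_out, off_out


def _split_train_val(n: int, val_fraction: float, rng: np.random.Generator):
    idx = rng.permutation(n)
    n_val = max(1, int(round(n * val_fraction))) if n > 1 else 0
    return idx[n_val:], idx[:n_val]


def train_segmentation(
    model: VertebraNet,
    dataset: Sequence[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
) -> dict:
    """Train the segmentation branch; keeps the epoch state with the best
    validation soft-Dice loss.  Returns the loss history."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(cfg.seed)
    train_idx, val_idx = _split_train_val(len(dataset), cfg.val_fraction, rng)
    if train_idx.size == 0:
        train_idx = np.arange(len(dataset))
    opt = Adam(model.seg_parameters(), lr=cfg.seg_lr)
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = model.state_dict()
    n_classes = model.cfg.n_classes

    def run_batch(indices, train: bool) -> float:
        patches, targets = [], []
        for i in indices:
            p, t = dataset[i]
            if train and cfg.augment:
                p, t, _ = augment_patch(
                    p, t, None, rng, cfg.aug_rotation_deg, cfg.aug_scale
                )
            patches.append(p)
            targets.append(t)
        x = np.stack(patches)[:, None].astype(np.float32)
        onehot = to_onehot(np.stack(targets).astype(np.int64), n_classes)
        logits, _ = model.forward(x, train=train)
        probs = softmax_channels(logits)
        loss, dprobs = soft_dice_loss(probs, onehot)
        if train:
            model.backward_seg(softmax_backward(probs, dprobs))
            opt.step()
        return loss

    for epoch in range(cfg.seg_epochs):
        order = rng.permutation(train_idx)
        losses = [
            run_batch(order[i : i + cfg.batch_size], train=True)
            for i in range(0, len(order), cfg.batch_size)
        ]
        history["train_loss"].append(float(np.mean(losses)))
        if val_idx.size:
            vlosses = [
                run_batch(val_idx[i : i + cfg.batch_size], train=False)
                for i in range(0, len(val_idx), cfg.batch_size)
            ]
            vloss = float(np.mean(vlosses))
        else:
            vloss = history["train_loss"][-1]
        history["val_loss"].append(vloss)
        if vloss < best_val:
            best_val = vloss
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return history


def passes_volume_gate(fg_voxels: int, mean_vertebra_volume: float, fraction: float = 0.15) -> bool:
    """Volume gate for the localization pathway.

    A patch qualifies when its (predicted) foreground reaches at least the
    given fraction of the average vertebra volume; the threshold itself is
    included.
    """
    return fg_voxels >= fraction * mean_vertebra_volume


def mean_vertebra_volume(label_maps) -> float:
    """Average instance voxel count over a collection of label maps."""
    counts = []
    for lm in label_maps:
        values = lm.values if hasattr(lm, "values") else np.asarray(lm)
        c = np.bincount(values.ravel())
        counts.extend(c[1:][c[1:] > 0].tolist())
    if not counts:
        raise ValueError("no instances in the provided label maps")
    return float(np.mean(counts))


def train_localization(
    model: VertebraNet,
    dataset: Sequence[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
    mean_vertebra_volume: float,
) -> dict:
    """Train the regression head on gated patches with MSE; encoder frozen.

    A patch enters training only if its predicted foreground volume is at
    least ``cfg.loc_gate_fraction`` of the average vertebra volume.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    gated = []
    for p, vec in dataset:
        probs, _ = model.predict(p[None, None].astype(np.float32))
        fg = int((np.argmax(probs[0], axis=0) > 0).sum())
        if passes_volume_gate(fg, mean_vertebra_volume, cfg.loc_gate_fraction):
            gated.append((p, np.asarray(vec, dtype=np.float32).reshape(12)))
    if not gated:
        raise ValueError("the volume gate excluded every patch")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.head_parameters(), lr=cfg.loc_lr)
    history = {"train_loss": [], "n_gated": len(gated)}
    for epoch in range(cfg.loc_epochs):
        order = rng.permutation(len(gated))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            batch = [gated[j] for j in order[i : i + cfg.batch_size]]
            x = np.stack([b[0] for b in batch])[:, None].astype(np.float32)
            y = np.stack([b[1] for b in batch])
            _, pred = model.forward(x, train=True)
            loss, dvec = mse_loss(pred, y)
            model.backward_loc(dvec)
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
    return history


def predict_patch(model: VertebraNet, patch: np.ndarray
                  ) -> tuple[np.ndarray, LocalizationTarget]:
    """Evaluation-mode prediction for a single ``(D, H, W)`` patch.

    Returns the ``(3, D, H, W)`` class probabilities and the localization
    target with confidences clipped to [0, 1].
    """
    patch = np.asarray(patch, dtype=np.float32)
    if patch.shape != tuple(model.cfg.patch_size):
        raise ValueError(f"patch shape {patch.shape} != model patch size {model.cfg.patch_size}")
    probs, vec = model.predict(patch[None, None])
    tgt = LocalizationTarget.from_vector(vec[0])
    tgt.confidences = np.clip(tgt.confidences, 0.0, 1.0)
    return probs[0], tgt
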