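"""The combined localization and segmentation network.

One network, two outputs: a 4-tier 3D U-Net style encoder/decoder produces
the three-class segmentation (background / body / boundary) of a volume
patch, and a small regression head consumes the shared encoder's bottleneck
feature map to predict the 1x12 localization vector (three center offsets
plus three confidences).  The encoder is shared because object appearance is
informative for both tasks; the segmentation path uses instance
normalization and Leaky ReLU, the head uses batch normalization and Leaky
ReLU, matching their respective batch statistics regimes.

Segmentation weights are initialized with the Kaiming normal scheme, the
regression head with the Kaiming uniform scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .layers import (
    BatchNorm1d,
    Conv3d,
    InstanceNorm3d,
    Layer,
    LeakyReLU,
    Linear,
    MaxPool2x,
    Upsample2x,
    softmax_channels,
)

__all__ = ["ModelConfig", "VertebraNet", "build_model", "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    tiers: int = 4
    base_channels: int = 16
    leaky_slope: float = 0.01
    head_conv_channels: int = 8
    fc_widths: tuple[int, ...] = (256, 128, 64)
    patch_size: tuple[int, int, int] = (32, 48, 48)
    n_classes: int = 3
    loc_outputs: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        f = 2 ** (self.tiers - 1)
        if any(p % f for p in self.patch_size):
            raise ValueError(
                f"patch size {self.patch_size} must be divisible by {f} per axis for {self.tiers} tiers"
            )

    @property
    def channels(self) -> list[int]:
        return [self.base_channels * 2**t for t in range(self.tiers)]

    @property
    def bottleneck_voxels(self) -> int:
        f = 2 ** (self.tiers - 1)
        return int(np.prod([p // f for p in self.patch_size]))


class _Block:
    """A sequential run of layers with mirrored backward."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, d: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            d = l.backward(d)
        return d


def _conv_block(c_in: int, c_out: int, rng, slope: float) -> _Block:
    return _Block(
        [
            Conv3d(c_in, c_out, 3, rng, init="kaiming_normal", leaky_slope=slope),
            InstanceNorm3d(c_out),
            LeakyReLU(slope),
            Conv3d(c_out, c_out, 3, rng, init="kaiming_normal", leaky_slope=slope),
            InstanceNorm3d(c_out),
            LeakyReLU(slope),
        ]
    )


class VertebraNet:
    """Shared-encoder segmentation + localization network (numpy backend)."""

    def __init__(self, cfg: ModelConfig) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.channels
        T = cfg.tiers
        s = cfg.leaky_slope

        self.enc = [_conv_block(1 if t == 0 else ch[t - 1], ch[t], rng, s) for t in range(T)]
        self.pools = [MaxPool2x() for _ in range(T - 1)]
        self.ups = [Upsample2x() for _ in range(T - 1)]
        # dec[t] consumes concat(upsampled deeper, skip at tier t), t = T-2 .. 0
        self.dec = [_conv_block(ch[t + 1] + ch[t], ch[t], rng, s) for t in range(T - 1)]
        self.final = Conv3d(ch[0], cfg.n_classes, 1, rng, init="kaiming_normal", leaky_slope=s)

        # regression head on the bottleneck (Kaiming uniform init)
        self.head_conv = Conv3d(ch[-1], cfg.head_conv_channels, 1, rng, init="kaiming_uniform", leaky_slope=s)
        self.head_act = LeakyReLU(s)
        n_in = cfg.head_conv_channels * cfg.bottleneck_voxels
        widths = list(cfg.fc_widths) + [cfg.loc_outputs]
        self.fcs: list[Layer] = []
        for i, n_out in enumerate(widths):
            self.fcs.append(Linear(n_in, n_out, rng, init="kaiming_uniform", leaky_slope=s))
            if i < len(widths) - 1:
                self.fcs.append(BatchNorm1d(n_out))
                self.fcs.append(LeakyReLU(s))
            n_in = n_out

        self._cache: dict = {}

    # ---- parameter bookkeeping -------------------------------------------

    def _seg_layers(self) -> list[Layer]:
        out: list[Layer] = []
        for b in self.enc + self.dec:
            out.extend(b.layers)
        out.append(self.final)
        return out

    def _head_layers(self) -> list[Layer]:
        return [self.head_conv, self.head_act, *self.fcs]

    def seg_parameters(self) -> list[tuple[Layer, str]]:
        return [(l, k) for l in self._seg_layers() for k in l.params]

    def head_parameters(self) -> list[tuple[Layer, str]]:
        return [(l, k) for l in self._head_layers() for k in l.params]

    def parameters(self) -> list[tuple[Layer, str]]:
        return self.seg_parameters() + self.head_parameters()

    def n_parameters(self) -> int:
        return sum(l.params[k].size for l, k in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, (l, k) in enumerate(self.parameters()):
            state[f"p{i}_{k}"] = l.params[k].copy()
        for j, l in enumerate(self._head_layers()):
            if isinstance(l, BatchNorm1d):
                state[f"bn{j}_mean"] = l.running_mean.copy()
                state[f"bn{j}_var"] = l.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, (l, k) in enumerate(self.parameters()):
            l.params[k] = np.asarray(state[f"p{i}_{k}"]).copy()
        for j, l in enumerate(self._head_layers()):
            if isinstance(l, BatchNorm1d):
                l.running_mean = np.asarray(state[f"bn{j}_mean"]).copy()
                l.running_var = np.asarray(state[f"bn{j}_var"]).copy()

    # ---- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Both branch outputs from one pass.

        Parameters: ``x`` is ``(N, 1, D, H, W)``.  Returns segmentation
        *logits* ``(N, 3, D, H, W)`` and the raw ``(N, 12)`` localization
        output.
        """
        T = self.cfg.tiers
        feats = []
        h = x.astype(np.float32)
        for t in range(T):
            h = self.enc[t].forward(h, train)
            feats.append(h)
            if t < T - 1:
                h = self.pools[t].forward(h, train)
        bottleneck = feats[-1]

        y = bottleneck
        for t in range(T - 2, -1, -1):
            u = self.ups[t].forward(y, train)
            cat = np.concatenate([u, feats[t]], axis=1)
            y = self.dec[t].forward(cat, train)
        logits = self.final.forward(y, train)

        hb = self.head_act.forward(self.head_conv.forward(bottleneck, train), train)
        v = hb.reshape(hb.shape[0], -1)
        for l in self.fcs:
            v = l.forward(v, train)

        if train:
            self._cache = {"bottleneck_shape": bottleneck.shape}
        return logits, v

    def backward_seg(self, dlogits: np.ndarray) -> None:
        """Backprop the segmentation branch (decoder + encoder)."""
        T = self.cfg.tiers
        ch = self.cfg.channels
        dy = self.final.backward(dlogits)
        dskips: dict[int, np.ndarray] = {}
        for t in range(0, T - 1):
            dcat = self.dec[t].backward(dy)
            du, dskips[t] = dcat[:, : ch[t + 1]], dcat[:, ch[t + 1] :]
            dy = self.ups[t].backward(du)
        g = dy  # gradient at the bottleneck feature map
        for t in range(T - 1, -1, -1):
            gin = self.enc[t].backward(g)
            if t > 0:
                g = self.pools[t - 1].backward(gin) + dskips[t - 1]

    def backward_loc(self, dvec: np.ndarray) -> None:
        """Backprop the regression head only (shared encoder stays frozen)."""
        d = dvec
        for l in reversed(self.fcs):
            d = l.backward(d)
        d = d.reshape(self._cache["bottleneck_shape"][0], self.cfg.head_conv_channels, *self._bneck_spatial())
        d = self.head_conv.backward(self.head_act.backward(d))

    def _bneck_spatial(self) -> tuple[int, int, int]:
        f = 2 ** (self.cfg.tiers - 1)
        return tuple(p // f for p in self.cfg.patch_size)

    def predict(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Evaluation-mode forward: class probabilities and 1x12 vector."""
        logits, v = self.forward(x, train=False)
        return softmax_channels(logits), v


def build_model(cfg: ModelConfig) -> VertebraNet:
    """Construct the network; same config (incl. seed) gives identical weights."""
    return VertebraNet(cfg)


def save_checkpoint(
    model: VertebraNet,
    path: str | Path,
    norm_stats: dict | None = None,
    mean_vertebra_volume: float | None = None,
) -> None:
    """Persist weights plus the config and data statistics needed to apply them."""
    path = Path(path)
    meta = {
        "config": {**asdict(model.cfg), "fc_widths": list(model.cfg.fc_widths),
                   "patch_size": list(model.cfg.patch_size)},
        "norm_stats": norm_stats,
        "mean_vertebra_volume": mean_vertebra_volume,
    }
    np.savez_compressed(path, __meta__=json.dumps(meta), **model.state_dict())


def load_checkpoint(path: str | Path) -> tuple[VertebraNet, dict]:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        cfg_d = meta["config"]
        cfg_d["fc_widths"] = tuple(cfg_d["fc_widths"])
        cfg_d["patch_size"] = tuple(cfg_d["patch_size"])
        cfg = ModelConfig(**cfg_d)
        model = VertebraNet(cfg)
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model, meta
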