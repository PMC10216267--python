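"""Encoder-decoder segmentation network (En-DeNet) and its training loop.

A UNet-shaped model: a pluggable encoder (default ``tiny5``, a plain
5-stage conv encoder; an ``effnet-b3-style`` inverted-bottleneck encoder is
selectable, without any pretrained weights) feeding a decoder of
``encoder_depth`` blocks, each of two 3x3 convolutions, with channel counts
(256, 128, 64, 32, 16) by default and skip connections joining encoder
stage ``i`` to decoder block ``depth - i``.  The output layer is a 1x1
convolution with sigmoid activation, producing a per-pixel foreground
probability map.

Training uses Adam (lr 0.001, weight decay 1e-8) with the combined
BCE + 0.2 * DiceLoss objective and a reduce-on-plateau schedule: when the
validation loss has not improved for 5 consecutive epochs the learning rate
is cut to one tenth; training stops when the rate falls below 1e-6 or after
``max_epochs`` (200 by default).

Post-processing: probability maps are binarized at 0.5 (ties map to
foreground) and connected components smaller than ``min_area`` pixels are
cleared (8-connectivity; strictly-smaller rule, so a component of exactly
``min_area`` pixels survives).  The 1024-pixel default is defined at
512x512 scale and should be scaled by the area ratio for other resolutions
(``scaled_min_area``).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from skimage.morphology import remove_small_objects

from . import nn
from .dataprep import merge_masks
from .losses import LossConfig, combined_loss_and_dlogits, dice_coefficient
from .phantomgen import load_sample

__all__ = [
    "SegModelConfig",
    "SegTrainConfig",
    "SegModel",
    "PlateauScheduler",
    "build_endenet",
    "train_segmentation",
    "predict_probabilities",
    "binarize",
    "clear_fragments",
    "scaled_min_area",
    "union_ensemble",
    "manifest_to_seg_arrays",
    "save_seg_model",
    "load_seg_model",
]


@dataclasses.dataclass(frozen=True)
class SegModelConfig:
    encoder: str = "tiny5"  # or "effnet-b3-style"
    encoder_depth: int = 5
    decoder_channels: tuple[int, ...] = (256, 128, 64, 32, 16)
    in_channels: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.encoder not in ("tiny5", "effnet-b3-style"):
            raise ValueError(f"unknown encoder {self.encoder!r}")
        if len(self.decoder_channels) != self.encoder_depth:
            raise ValueError("decoder_channels length must equal encoder_depth")
        if any(a <= b for a, b in zip(self.decoder_channels,
                                      self.decoder_channels[1:])):
            raise ValueError("decoder channels must be strictly decreasing")
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 or 2")


@dataclasses.dataclass(frozen=True)
class SegTrainConfig:
    lr: float = 1e-3
    weight_decay: float = 1e-8
    plateau_factor: float = 0.1
    plateau_patience: int = 5
    min_lr: float = 1e-6
    max_epochs: int = 200
    batch_size: int = 16

    def __post_init__(self):
        if min(self.lr, self.weight_decay, self.min_lr) < 0 or self.max_epochs < 1:
            raise ValueError("training parameters must be positive")
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau_factor must be in (0, 1)")


class PlateauScheduler:
    """Reduce-on-plateau: multiply the rate by ``factor`` once the monitored
    loss has gone ``patience`` consecutive checks without strict improvement.
    ``exhausted`` turns True when a reduction pushes the rate below
    ``min_lr``."""

    def __init__(self, initial_lr: float, factor: float = 0.1, patience: int = 5,
                 min_lr: float = 1e-6):
        self.lr = initial_lr
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0
        self.exhausted = False

    def step(self, val_loss: float) -> float:
        if val_loss < self.best:
            self.best = val_loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.lr *= self.factor
                self.bad_epochs = 0
                if self.lr < self.min_lr:
                    self.exhausted = True
        return self.lr


def _conv_block(cin, cout, rng, name):
    return [nn.Conv2d(cin, cout, 3, 3, rng, name=f"{name}.c1"),
            nn.BatchNorm2d(cout, name=f"{name}.b1"), nn.ReLU(),
            nn.Conv2d(cout, cout, 3, 3, rng, name=f"{name}.c2"),
            nn.BatchNorm2d(cout, name=f"{name}.b2"), nn.ReLU()]


def _mbconv_block(cin, cout, rng, name, expand=2):
    mid = cin * expand
    return [nn.Conv2d(cin, mid, 1, 1, rng, name=f"{name}.e"),
            nn.BatchNorm2d(mid, name=f"{name}.be"), nn.ReLU(),
            nn.Conv2d(mid, mid, 3, 3, rng, name=f"{name}.d"),
            nn.BatchNorm2d(mid, name=f"{name}.bd"), nn.ReLU(),
            nn.Conv2d(mid, cout, 1, 1, rng, name=f"{name}.p"),
            nn.BatchNorm2d(cout, name=f"{name}.bp"), nn.ReLU()]


class SegModel:
    """Built encoder-decoder network; maps (N, C, H, W) to (N, H, W) sigmoid
    probabilities.  H and W must be divisible by ``2 ** encoder_depth``."""

    def __init__(self, cfg: SegModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d = cfg.encoder_depth
        enc_channels = tuple(reversed(cfg.decoder_channels))
        block = _conv_block if cfg.encoder == "tiny5" else _mbconv_block
        self.enc_blocks, self.pools = [], []
        cin = cfg.in_channels
        for i, c in enumerate(enc_channels):
            self.enc_blocks.append(nn.Sequential(block(cin, c, rng, f"enc{i}")))
            self.pools.append(nn.MaxPool2())
            cin = c
        self.dec_up, self.dec_blocks = [], []
        self._skip_channels = list(reversed(enc_channels))  # per decoder block
        for i, c in enumerate(cfg.decoder_channels):
            self.dec_up.append(nn.Upsample2())
            self.dec_blocks.append(nn.Sequential(
                _conv_block(cin + self._skip_channels[i], c, rng, f"dec{i}")))
            cin = c
        self.final_conv = nn.Conv2d(cin, 1, 1, 1, rng, name="out")
        self.sigmoid = nn.Sigmoid()
        self.trained = False

    @property
    def decoder_block_count(self) -> int:
        return len(self.dec_blocks)

    def parameters(self):
        ps = []
        for b in self.enc_blocks + self.dec_blocks:
            ps.extend(b.parameters())
        ps.extend(self.final_conv.parameters())
        return ps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Probability maps (N, H, W) for inputs (N, C, H, W)."""
        d = self.cfg.encoder_depth
        n, c, h, w = x.shape
        if h % (2 ** d) or w % (2 ** d):
            raise ValueError(f"H and W must be divisible by {2 ** d}")
        skips = []
        hcur = x
        for blk, pool in zip(self.enc_blocks, self.pools):
            hcur = blk.forward(hcur, train=train)
            skips.append(hcur)
            hcur = pool.forward(hcur, train=train)
        for i, (up, dblk) in enumerate(zip(self.dec_up, self.dec_blocks)):
            hcur = up.forward(hcur, train=train)
            skip = skips[d - 1 - i]
            hcur = np.concatenate([skip, hcur], axis=1)
            hcur = dblk.forward(hcur, train=train)
        z = self.final_conv.forward(hcur, train=train)
        p = self.sigmoid.forward(z, train=train)
        return p[:, 0]

    def backward_from_dlogits(self, dz: np.ndarray) -> None:
        """Backprop from the gradient w.r.t. the pre-sigmoid logit map."""
        d = self.cfg.encoder_depth
        dh = self.final_conv.backward(dz[:, None, :, :])
        skip_grads = [None] * d
        for i in range(d - 1, -1, -1):
            dh = self.dec_blocks[i].backward(dh)
            sc = self._skip_channels[i]
            skip_grads[d - 1 - i] = dh[:, :sc]
            dh = self.dec_up[i].backward(dh[:, sc:])
        for i in range(d - 1, -1, -1):
            dh = self.pools[i].backward(dh)
            dh = dh + skip_grads[i]
            dh = self.enc_blocks[i].backward(dh, need_dx=i > 0)

    def state(self) -> dict[str, np.ndarray]:
        d: dict[str, np.ndarray] = {}
        blocks = {f"enc{i}": b for i, b in enumerate(self.enc_blocks)}
        blocks.update({f"dec{i}": b for i, b in enumerate(self.dec_blocks)})
        for bname, b in blocks.items():
            for j, layer in enumerate(b.layers):
                for p in layer.parameters():
                    d[f"{bname}.l{j}.{p.name}"] = p.data
                if isinstance(layer, nn.BatchNorm2d):
                    d[f"{bname}.l{j}.rm"] = layer.running_mean
                    d[f"{bname}.l{j}.rv"] = layer.running_var
        d["out.weight"] = self.final_conv.weight.data
        d["out.bias"] = self.final_conv.bias.data
        return d

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        blocks = {f"enc{i}": b for i, b in enumerate(self.enc_blocks)}
        blocks.update({f"dec{i}": b for i, b in enumerate(self.dec_blocks)})
        for bname, b in blocks.items():
            for j, layer in enumerate(b.layers):
                for p in layer.parameters():
                    p.data = state[f"{bname}.l{j}.{p.name}"].astype(np.float32)
                if isinstance(layer, nn.BatchNorm2d):
                    layer.running_mean = state[f"{bname}.l{j}.rm"].astype(np.float32)
                    layer.running_var = state[f"{bname}.l{j}.rv"].astype(np.float32)
        self.final_conv.weight.data = state["out.weight"].astype(np.float32)
        self.final_conv.bias.data = state["out.bias"].astype(np.float32)


def build_endenet(cfg: SegModelConfig = SegModelConfig()) -> SegModel:
    """Construct the segmentation model with deterministic initialization."""
    return SegModel(cfg)


def manifest_to_seg_arrays(manifest, split: str | None = None,
                           target: str = "liver",
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Images (N,H,W,D) and binary target masks (N,H,W) from a manifest."""
    records = manifest.records
    if split is not None:
        records = records[records["split"] == split]
    xs, ms = [], []
    for _, rec in records.iterrows():
        s = load_sample(rec, root=manifest.root)
        xs.append(s.image if s.image.ndim == 3 else s.image[..., None])
        ms.append(s.liver_mask if target == "liver" else s.tumor_mask)
    return np.stack(xs).astype(np.float32), np.stack(ms).astype(np.float32)


def _as_seg_arrays(data, target="liver"):
    if isinstance(data, tuple):
        x, m = data
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        return x, np.asarray(m, dtype=np.float32)
    return manifest_to_seg_arrays(data, target=target)


def train_segmentation(model: SegModel, train_data, val_data,
                       loss_cfg: LossConfig = LossConfig(),
                       train_cfg: SegTrainConfig = SegTrainConfig(),
                       seed: int = 0, target: str = "liver",
                       ) -> tuple[SegModel, dict]:
    """Train with Adam + plateau schedule; returns the model and a history
    dict with per-epoch train/val losses, learning rates and val Dice."""
    xtr, mtr = _as_seg_arrays(train_data, target)
    xva, mva = _as_seg_arrays(val_data, target)
    if len(xtr) == 0 or len(xva) == 0:
        raise ValueError("train and validation sets must be non-empty")
    xtr_n = np.ascontiguousarray(xtr.transpose(0, 3, 1, 2))
    xva_n = np.ascontiguousarray(xva.transpose(0, 3, 1, 2))

    opt = nn.Adam(model.parameters(), lr=train_cfg.lr,
                  weight_decay=train_cfg.weight_decay)
    sched = PlateauScheduler(train_cfg.lr, train_cfg.plateau_factor,
                             train_cfg.plateau_patience, train_cfg.min_lr)
    rng = np.random.default_rng(seed)
    history = {"epoch": [], "train_loss": [], "val_loss": [], "val_dice": [],
               "lr": []}

    for epoch in range(1, train_cfg.max_epochs + 1):
        order = rng.permutation(len(xtr_n))
        ep_loss = 0.0
        for i in range(0, len(order), train_cfg.batch_size):
            idx = order[i:i + train_cfg.batch_size]
            probs = model.forward(xtr_n[idx], train=True)
            loss, dz = combined_loss_and_dlogits(probs, mtr[idx], loss_cfg)
            model.backward_from_dlogits(dz.astype(np.float32))
            opt.step()
            opt.zero_grad()
            ep_loss += loss * len(idx)
        ep_loss /= len(order)

        # validation pass
        val_loss, val_dice = 0.0, 0.0
        for i in range(0, len(xva_n), train_cfg.batch_size):
            sl = slice(i, i + train_cfg.batch_size)
            probs = model.forward(xva_n[sl], train=False)
            loss, _ = combined_loss_and_dlogits(probs, mva[sl], loss_cfg)
            nsl = len(mva[sl])
            val_loss += loss * nsl
            val_dice += sum(dice_coefficient(binarize(p), m)
                            for p, m in zip(probs, mva[sl]))
        val_loss /= len(xva_n)
        val_dice /= len(xva_n)

        history["epoch"].append(epoch)
        history["train_loss"].append(float(ep_loss))
        history["val_loss"].append(float(val_loss))
        history["val_dice"].append(float(val_dice))
        history["lr"].append(opt.lr)

        opt.lr = sched.step(val_loss)
        if sched.exhausted:
            break
    model.trained = True
    return model, history


def predict_probabilities(model: SegModel, images: np.ndarray,
                          batch_size: int = 16) -> np.ndarray:
    """Probability maps (N, H, W) for (N, H, W, D) or (N, H, W) inputs."""
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[..., None]
    xn = np.ascontiguousarray(x.transpose(0, 3, 1, 2))
    return np.concatenate([model.forward(xn[i:i + batch_size])
                           for i in range(0, len(xn), batch_size)])


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Pixel is foreground iff its probability >= threshold."""
    return np.asarray(prob_map) >= threshold


def scaled_min_area(shape, base_area: int = 1024, base_size: int = 512) -> int:
    """Scale the 512x512-scale area threshold by the actual image area."""
    h, w = shape[:2]
    return max(1, round(base_area * (h * w) / (base_size * base_size)))


def clear_fragments(mask: np.ndarray, min_area: int = 1024) -> np.ndarray:
    """Remove 8-connected components with area strictly below ``min_area``."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any() or min_area <= 1:
        return mask
    # max_size removes components of area <= its value, hence min_area - 1
    # implements the strictly-smaller-than rule
    return remove_small_objects(mask, max_size=min_area - 1, connectivity=2)


def union_ensemble(masks: list[np.ndarray]) -> np.ndarray:
    """Pixel-wise OR of several model predictions."""
    return merge_masks(masks)


def save_seg_model(model: SegModel, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "model.json").write_text(json.dumps(dataclasses.asdict(model.cfg)))
    np.savez(d / "params.npz", **model.state())


def load_seg_model(directory: str | Path) -> SegModel:
    d = Path(directory)
    cfgd = json.loads((d / "model.json").read_text())
    cfgd["decoder_channels"] = tuple(cfgd["decoder_channels"])
    model = SegModel(SegModelConfig(**cfgd))
    blobs = np.load(d / "params.npz")
    model.load_state({k: blobs[k] for k in blobs.files})
    model.trained = True
    return model
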