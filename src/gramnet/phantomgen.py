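"""Synthetic CT-like liver phantoms.

Every other module in this package is exercised on these phantoms: a 2-D
grayscale slice containing an elliptical "liver" on a darker background,
with zero or more circular "tumors" strictly inside the liver that are
hypodense (darker, negative contrast) or hyperdense (brighter, positive
contrast) relative to the surrounding parenchyma.  Gaussian noise and mild
smoothing give soft edges; intensities are quantized to 8 bits so a sample
written as PNG reads back bit-identically.

The class label follows the convention used throughout the package:
``malignant`` iff the tumor mask is non-empty, ``benign`` otherwise.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "PhantomConfig",
    "PhantomSample",
    "generate_phantom",
    "generate_dataset",
    "load_sample",
    "BENIGN",
    "MALIGNANT",
]

BENIGN = "benign"
MALIGNANT = "malignant"

#: default split sizes mirroring the reference dataset bookkeeping
DEFAULT_N_TRAIN = 2346
DEFAULT_N_TEST = 392


class PhantomConfigError(ValueError):
    """Raised for invalid phantom configurations."""


@dataclasses.dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the phantom distribution.

    Attributes
    ----------
    image_size:
        Pixels per side (square images). 128 keeps generation and training
        desk-scale; 512 matches full-resolution CT slices.
    liver_axes:
        Range of ellipse semi-axes as a fraction of ``image_size``.
    n_tumors:
        Inclusive integer range of tumor count per slice. The default
        (0, 2) yields roughly one-third tumor-free (benign) slices,
        comparable to the tumor prevalence of public liver CT collections.
    tumor_radius:
        Tumor radius range as a fraction of ``image_size``.
    tumor_contrast:
        Signed intensity offset range relative to parenchyma; negative is
        hypodense (darker), positive hyperdense (brighter).
    noise_sd:
        Standard deviation of additive Gaussian noise (clipped to [0,1]).
    channels:
        1 or 2. The second channel is a smoothed contrast-stretched copy
        standing in for a perfusion-style auxiliary channel.
    seed:
        Base RNG seed; together with the sample index it fully determines
        a sample.
    """

    image_size: int = 128
    liver_axes: tuple[float, float] = (0.22, 0.38)
    n_tumors: tuple[int, int] = (0, 2)
    tumor_radius: tuple[float, float] = (0.04, 0.10)
    tumor_contrast: tuple[float, float] = (-0.35, -0.15)
    noise_sd: float = 0.03
    background: float = 0.15
    parenchyma: float = 0.60
    channels: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 32:
            raise PhantomConfigError("image_size must be >= 32")
        if self.channels not in (1, 2):
            raise PhantomConfigError("channels must be 1 or 2")
        if not (0 < self.liver_axes[0] <= self.liver_axes[1] < 0.5):
            raise PhantomConfigError("liver_axes must satisfy 0 < lo <= hi < 0.5")
        if not (0 <= self.n_tumors[0] <= self.n_tumors[1]):
            raise PhantomConfigError("n_tumors range invalid")
        if self.tumor_radius[1] >= self.liver_axes[0]:
            raise PhantomConfigError("tumor radius must be below the minimum liver semi-axis")
        lo, hi = self.tumor_contrast
        if lo > hi:
            raise PhantomConfigError("tumor_contrast range invalid")
        if min(abs(lo), abs(hi)) <= 2.0 * self.noise_sd or lo * hi <= 0:
            raise PhantomConfigError(
                "|tumor_contrast| must exceed 2*noise_sd (tumors must be separable)")
        if self.noise_sd < 0:
            raise PhantomConfigError("noise_sd must be >= 0")


@dataclasses.dataclass
class PhantomSample:
    """One phantom: image, liver/tumor masks and a class label."""

    image: np.ndarray  # (H, W) or (H, W, 2) float32 in [0, 1]
    liver_mask: np.ndarray  # (H, W) bool
    tumor_mask: np.ndarray  # (H, W) bool
    label: str  # BENIGN or MALIGNANT

    def __post_init__(self):
        if self.tumor_mask[~self.liver_mask].any():
            raise ValueError("tumor_mask must be contained in liver_mask")


def _quantize(img: np.ndarray) -> np.ndarray:
    """Snap to the 8-bit grid so PNG round-trips are exact."""
    return (np.round(np.clip(img, 0.0, 1.0) * 255.0) / 255.0).astype(np.float32)


def generate_phantom(cfg: PhantomConfig, index: int) -> PhantomSample:
    """Generate the ``index``-th phantom of the distribution ``cfg``.

    Deterministic: the same ``(cfg.seed, index)`` always yields a
    bit-identical sample.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, int(index)])
    n = cfg.image_size

    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    cy = n * (0.5 + rng.uniform(-0.06, 0.06))
    cx = n * (0.5 + rng.uniform(-0.06, 0.06))
    a = n * rng.uniform(*cfg.liver_axes)  # semi-axis along x
    b = n * rng.uniform(*cfg.liver_axes)  # semi-axis along y
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    xr = (xx - cx) * ct + (yy - cy) * st
    yr = -(xx - cx) * st + (yy - cy) * ct
    liver = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0

    tumor = np.zeros((n, n), dtype=bool)
    img = np.full((n, n), cfg.background, dtype=np.float64)
    img[liver] = cfg.parenchyma

    k = int(rng.integers(cfg.n_tumors[0], cfg.n_tumors[1] + 1))
    for _ in range(k):
        r = n * rng.uniform(*cfg.tumor_radius)
        # center must keep the whole disc inside the liver ellipse
        interior = ndimage.distance_transform_edt(liver) > r + 1.0
        cand = np.flatnonzero(interior)
        if cand.size == 0:
            continue
        pos = cand[rng.integers(cand.size)]
        ty, tx = divmod(pos, n)
        disc = (xx - tx) ** 2 + (yy - ty) ** 2 <= r ** 2
        contrast = rng.uniform(*cfg.tumor_contrast)
        img[disc] = cfg.parenchyma + contrast
        tumor |= disc

    img = ndimage.gaussian_filter(img, sigma=0.7)
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = _quantize(img)

    if cfg.channels == 2:
        # smoothed, contrast-stretched auxiliary channel
        aux = ndimage.gaussian_filter(img.astype(np.float64), sigma=2.0)
        lo, hi = aux.min(), aux.max()
        aux = (aux - lo) / (hi - lo) if hi > lo else np.zeros_like(aux)
        img = np.stack([img, _quantize(aux)], axis=-1)

    label = MALIGNANT if tumor.any() else BENIGN
    return PhantomSample(image=img, liver_mask=liver, tumor_mask=tumor, label=label)


def _save_mask(mask: np.ndarray, path: Path) -> None:
    Image.fromarray((mask.astype(np.uint8) * 255)).save(path)


def _save_image(img: np.ndarray, path: Path, path2: Path | None = None) -> None:
    if img.ndim == 2:
        Image.fromarray(np.round(img * 255).astype(np.uint8)).save(path)
    else:
        Image.fromarray(np.round(img[..., 0] * 255).astype(np.uint8)).save(path)
        Image.fromarray(np.round(img[..., 1] * 255).astype(np.uint8)).save(path2)


def generate_dataset(cfg: PhantomConfig, n_train: int = DEFAULT_N_TRAIN,
                     n_test: int = DEFAULT_N_TEST, out_dir: str | Path = ".",
                     ) -> "pd.DataFrame":
    """Write ``n_train + n_test`` phantoms as PNGs plus a CSV manifest.

    Returns the manifest as a DataFrame with columns
    (id, image_path, liver_mask_path, tumor_mask_path, label, split); the
    same table is written to ``out_dir/manifest.csv``.  Paths in the
    manifest are relative to ``out_dir``.
    """
    if n_train < 0 or n_test < 0:
        raise ValueError("n_train and n_test must be >= 0")
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_train + n_test):
        split = "train" if i < n_train else "test"
        sample = generate_phantom(cfg, i)
        sid = f"ph{i:05d}"
        img_p = f"{sid}_img.png"
        img2_p = f"{sid}_img2.png" if cfg.channels == 2 else ""
        liv_p = f"{sid}_liver.png"
        tum_p = f"{sid}_tumor.png"
        _save_image(sample.image, out / img_p, (out / img2_p) if img2_p else None)
        _save_mask(sample.liver_mask, out / liv_p)
        _save_mask(sample.tumor_mask, out / tum_p)
        row = {"id": sid, "image_path": img_p, "liver_mask_path": liv_p,
               "tumor_mask_path": tum_p, "label": sample.label, "split": split}
        if img2_p:
            row["image2_path"] = img2_p
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_sample(record: dict | pd.Series, root: str | Path = ".") -> PhantomSample:
    """Read one manifest record back into a :class:`PhantomSample`."""
    root = Path(root)
    img = np.asarray(Image.open(root / record["image_path"]), dtype=np.float32) / 255.0
    img2_path = record.get("image2_path", "")
    if isinstance(img2_path, str) and img2_path:
        img2 = np.asarray(Image.open(root / img2_path), dtype=np.float32) / 255.0
        img = np.stack([img, img2], axis=-1)
    liver = np.asarray(Image.open(root / record["liver_mask_path"])) > 127
    tumor = np.asarray(Image.open(root / record["tumor_mask_path"])) > 127
    return PhantomSample(image=img, liver_mask=liver, tumor_mask=tumor,
                         label=str(record["label"]))
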