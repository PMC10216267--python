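"""Dataset bookkeeping and preprocessing.

Covers the pipeline steps between raw slices and model input: merging
per-structure masks into one, dropping slices with no liver, resizing by a
factor of 0.25 with per-image min-max normalization to [0, 1], deterministic
(optionally stratified) train/val/test splitting, and seed-controlled joint
augmentation of images and masks.

Two split presets ship: ``SEGMENTATION_SPLIT`` (63/17/20) and
``CLASSIFICATION_SPLIT`` (72/8/20), the latter being the default for the
modular classifier. A plain k-fold driver is also provided, since protocols
based on either a fixed split or cross-validation are both in common use.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

from .phantomgen import PhantomSample

__all__ = [
    "DatasetManifest",
    "SplitRatios",
    "SEGMENTATION_SPLIT",
    "CLASSIFICATION_SPLIT",
    "merge_masks",
    "filter_empty_slices",
    "preprocess_image",
    "preprocess_mask",
    "split_dataset",
    "augment",
    "kfold_indices",
    "load_dicom_series",
    "load_nifti_slices",
]

_VALID_SPLITS = {"train", "val", "test", "unassigned"}

MANIFEST_COLUMNS = ["id", "image_path", "liver_mask_path", "tumor_mask_path",
                    "label", "split"]


@dataclasses.dataclass
class DatasetManifest:
    """Tabular index of dataset records plus the directory they live in."""

    records: pd.DataFrame
    root: Path = Path(".")
    provenance: str = ""

    def __post_init__(self):
        self.root = Path(self.root)
        if len(self.records):
            if self.records["id"].duplicated().any():
                raise ValueError("manifest ids must be unique")
            bad = set(self.records["split"]) - _VALID_SPLITS
            if bad:
                raise ValueError(f"invalid split tags: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest(
            self.records[self.records["split"] == split].reset_index(drop=True),
            root=self.root, provenance=self.provenance)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "") -> "DatasetManifest":
        path = Path(path)
        df = pd.read_csv(path, dtype={"id": str})
        if not len(df):
            df = pd.DataFrame(columns=MANIFEST_COLUMNS)
        return cls(df, root=path.parent, provenance=provenance or str(path))

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


@dataclasses.dataclass(frozen=True)
class SplitRatios:
    """Train/val/test fractions; must sum to 1."""

    train: float
    val: float
    test: float

    def __post_init__(self):
        for v in (self.train, self.val, self.test):
            if not (0.0 <= v <= 1.0):
                raise ValueError("each ratio must be in [0, 1]")
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("ratios must sum to 1")


SEGMENTATION_SPLIT = SplitRatios(0.63, 0.17, 0.20)
CLASSIFICATION_SPLIT = SplitRatios(0.72, 0.08, 0.20)


def merge_masks(masks: list[np.ndarray]) -> np.ndarray:
    """Pixel-wise logical OR of same-shaped binary masks."""
    if not masks:
        raise ValueError("need at least one mask")
    out = np.asarray(masks[0]).astype(bool)
    for m in masks[1:]:
        m = np.asarray(m)
        if m.shape != out.shape:
            raise ValueError(f"mask shape {m.shape} != {out.shape}")
        out = out | m.astype(bool)
    return out


def filter_empty_slices(manifest: DatasetManifest) -> DatasetManifest:
    """Drop records whose liver mask contains no foreground, keeping order."""
    keep = []
    for _, rec in manifest.records.iterrows():
        p = manifest.root / rec["liver_mask_path"]
        if not p.exists():
            raise FileNotFoundError(f"liver mask missing for record {rec['id']}: {p}")
        mask = np.asarray(Image.open(p)) > 127
        keep.append(bool(mask.any()))
    out = manifest.records[np.asarray(keep, dtype=bool)].reset_index(drop=True) \
        if len(manifest) else manifest.records
    return DatasetManifest(out, root=manifest.root, provenance=manifest.provenance)


def preprocess_image(image: np.ndarray, resize_factor: float = 0.25,
                     normalize: bool = True) -> np.ndarray:
    """Resize (bilinear) by ``resize_factor`` and min-max normalize to [0, 1].

    Constant images normalize to all zeros.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    if resize_factor != 1.0:
        h, w = image.shape[:2]
        out_shape = (max(1, round(h * resize_factor)), max(1, round(w * resize_factor)))
        image = _sk_resize(image, out_shape + image.shape[2:], order=1,
                           anti_aliasing=False, preserve_range=True)
    if normalize:
        lo, hi = image.min(), image.max()
        image = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image)
    return image.astype(np.float32)


def preprocess_mask(mask: np.ndarray, resize_factor: float = 0.25) -> np.ndarray:
    """Resize a binary mask with nearest-neighbour interpolation (stays binary)."""
    mask = np.asarray(mask).astype(bool)
    if resize_factor == 1.0:
        return mask
    h, w = mask.shape
    out_shape = (max(1, round(h * resize_factor)), max(1, round(w * resize_factor)))
    return _sk_resize(mask.astype(np.float64), out_shape, order=0,
                      anti_aliasing=False, preserve_range=True) > 0.5


def _allocate(n: int, ratios: SplitRatios) -> tuple[int, int, int]:
    """Largest-remainder allocation of n items to the three splits."""
    raw = np.array([n * ratios.train, n * ratios.val, n * ratios.test])
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    return int(base[0]), int(base[1]), int(base[2])


def split_dataset(manifest: DatasetManifest, ratios: SplitRatios = CLASSIFICATION_SPLIT,
                  seed: int = 0, stratified: bool = True) -> DatasetManifest:
    """Assign train/val/test tags; disjoint, exhaustive, seed-deterministic.

    When ``stratified``, each class is allocated to the splits separately so
    per-class proportions are honored to the nearest integer.
    """
    df = manifest.records.copy()
    rng = np.random.default_rng(seed)
    if stratified and len(df):
        classes = df["label"].unique()
        if len(df) < len(classes):
            raise ValueError("fewer samples than classes under stratification")
        groups = [np.flatnonzero((df["label"] == c).to_numpy()) for c in sorted(classes)]
    else:
        groups = [np.arange(len(df))]
    tags = np.empty(len(df), dtype=object)
    for idx in groups:
        idx = idx.copy()
        rng.shuffle(idx)
        ntr, nva, nte = _allocate(len(idx), ratios)
        tags[idx[:ntr]] = "train"
        tags[idx[ntr:ntr + nva]] = "val"
        tags[idx[ntr + nva:]] = "test"
    df["split"] = tags
    return DatasetManifest(df, root=manifest.root, provenance=manifest.provenance)


def _translate(arr: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer shift with zero fill (no wrap-around)."""
    out = np.zeros_like(arr)
    h, w = arr.shape[:2]
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    yo = slice(max(-dy, 0), max(-dy, 0) + (ys.stop - ys.start))
    xo = slice(max(-dx, 0), max(-dx, 0) + (xs.stop - xs.start))
    out[ys, xs] = arr[yo, xo]
    return out


def _apply_transform(sample: PhantomSample, rng: np.random.Generator) -> PhantomSample:
    img = sample.image.copy()
    liver = sample.liver_mask.copy()
    tumor = sample.tumor_mask.copy()

    flips = (rng.random() < 0.5, rng.random() < 0.5)
    k = int(rng.integers(0, 4))
    dy, dx = (int(v) for v in rng.integers(-3, 4, size=2))

    def geo(a):
        if flips[0]:
            a = a[::-1, ...]
        if flips[1]:
            a = a[:, ::-1, ...]
        a = np.rot90(a, k, axes=(0, 1))
        return _translate(a, dy, dx)

    img = geo(img)
    liver = geo(liver)
    tumor = geo(tumor)
    # intensity jitter on the image only; masks untouched
    scale = rng.uniform(0.9, 1.1)
    shift = rng.uniform(-0.05, 0.05)
    img = np.clip(img * scale + shift, 0.0, 1.0).astype(np.float32)
    return PhantomSample(image=img, liver_mask=liver, tumor_mask=tumor,
                         label=sample.label)


def augment(records: list[PhantomSample], factor: int, seed: int = 0,
            ) -> list[PhantomSample]:
    """Expand each sample into ``factor`` versions (the first is the original).

    The same geometric transform (flips, 90-degree rotations, small
    translations) is applied jointly to the image and both masks; intensity
    jitter touches the image only. Deterministic for a fixed seed.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    out: list[PhantomSample] = []
    for i, sample in enumerate(records):
        out.append(sample)
        for k in range(1, factor):
            rng = np.random.default_rng([seed, i, k])
            out.append(_apply_transform(sample, rng))
    return out


def kfold_indices(n: int, k: int, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic k-fold partition: list of (train_idx, test_idx)."""
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    return [(np.concatenate([f for j, f in enumerate(folds) if j != i]), folds[i])
            for i in range(k)]


# ---------------------------------------------------------------------------
# thin real-data loaders (layouts with one DICOM file per slice, or a NIfTI
# volume plus mask volume); untested against the real collections by default


def load_dicom_series(directory: str | Path) -> list[np.ndarray]:
    """Read a directory of per-slice DICOM files, sorted by instance number."""
    import pydicom

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        files = [p for p in sorted(Path(directory).iterdir()) if p.is_file()]
    slices = []
    for f in files:
        ds = pydicom.dcmread(str(f))
        slices.append((int(getattr(ds, "InstanceNumber", 0)),
                       ds.pixel_array.astype(np.float32)))
    slices.sort(key=lambda t: t[0])
    return [a for _, a in slices]


def load_nifti_slices(image_path: str | Path, mask_path: str | Path,
                      ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Slice a NIfTI volume + mask volume along the last axis into 2-D pairs."""
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(image_path)).dataobj).astype(np.float32)
    msk = np.asanyarray(nib.load(str(mask_path)).dataobj)
    if vol.shape != msk.shape:
        raise ValueError("image and mask volumes differ in shape")
    return [(vol[..., z], msk[..., z] > 0) for z in range(vol.shape[-1])]
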