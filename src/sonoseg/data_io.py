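"""Indexing, splitting, preprocessing and augmentation of slice/mask pairs.

The on-disk layout is one folder per patient, each containing 2-D MRI slice
images (PNG or TIFF) and, for every slice, a binary mask file named with the
slice's basename plus a ``_mask`` suffix (the layout of the Kaggle-curated
TCGA-LGG collection).  Masks are binarized on load; images are scaled to the
unit interval by the fixed 8-bit dtype range so that intensities stay
comparable across slices, which the downstream z-score stage relies on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff")
TARGET_SIZE = 256
MASK_THRESHOLD = 127  # 8-bit masks may store 255 for foreground


@dataclass
class SlicePair:
    """One MRI slice and its binary mask, keyed by patient and slice index."""

    patient_id: str
    slice_index: int
    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape[:2]:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape[:2]} differ in size"
            )


@dataclass
class DatasetSplit:
    train_ids: tuple
    val_ids: tuple
    test_ids: tuple
    seed: int

    def partition_of(self, patient_id: str) -> str:
        for name, ids in (("train", self.train_ids), ("val", self.val_ids), ("test", self.test_ids)):
            if patient_id in ids:
                return name
        raise KeyError(patient_id)


@dataclass
class AugmentationConfig:
    """Training-time augmentation; each transform has its own Bernoulli gate.

    Only the flip probability is fixed by protocol (0.5); the other gates
    default to 0.5 and every magnitude is configurable.
    """

    flip_probability: float = 0.5
    rotation_probability: float = 0.5
    rotation_limit_degrees: float = 7.0
    elastic_probability: float = 0.5
    elastic_amplitude: float = 10.0  # displacement in pixels
    elastic_sigma: float = 4.0  # smoothing width of the displacement field
    noise_probability: float = 0.5
    noise_sd: float = 0.02
    intensity_shift_probability: float = 0.5
    intensity_shift_limit: float = 0.10
    motion_blur_probability: float = 0.5
    motion_blur_sizes: tuple = (3, 4, 5, 6, 7)
    motion_blur_directions: tuple = ("horizontal", "vertical", "diagonal")

    def __post_init__(self):
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must lie in [0, 1]")
        if not set(self.motion_blur_sizes) <= set(range(3, 8)):
            raise ValueError("motion_blur_sizes must be a subset of {3,...,7}")


# ---------------------------------------------------------------------------
# Indexing
# ---------------------------------------------------------------------------

_TRAILING_INT = re.compile(r"(\d+)$")


def _slice_index(stem: str) -> int:
    m = _TRAILING_INT.search(stem)
    return int(m.group(1)) if m else 0


def index_dataset(root_dir) -> pd.DataFrame:
    """Index per-patient folders into a (patient_id, slice, image, mask) table.

    Mask files are recognized strictly by the ``_mask`` basename suffix; an
    image without its mask partner is a contract violation and raises.
    """
    root = Path(root_dir)
    records = []
    patient_dirs = sorted(d for d in root.iterdir() if d.is_dir()) if root.is_dir() else []
    for pdir in patient_dirs:
        files = sorted(
            f for f in pdir.iterdir() if f.suffix.lower() in IMAGE_EXTENSIONS
        )
        masks = {f.stem[: -len("_mask")]: f for f in files if f.stem.endswith("_mask")}
        images = [f for f in files if not f.stem.endswith("_mask")]
        for img in images:
            mask = masks.pop(img.stem, None)
            if mask is None:
                raise FileNotFoundError(f"image without a _mask partner: {img}")
            records.append(
                {
                    "patient_id": pdir.name,
                    "slice_index": _slice_index(img.stem),
                    "image_path": str(img),
                    "mask_path": str(mask),
                }
            )
        if masks:
            orphan = sorted(masks.values())[0]
            raise FileNotFoundError(f"mask without an image partner: {orphan}")
    if not records:
        raise FileNotFoundError(f"no patients found under {root}")
    table = pd.DataFrame.from_records(records)
    return table.sort_values(["patient_id", "slice_index"], kind="stable").reset_index(drop=True)


def write_manifest(index: pd.DataFrame, path, split: DatasetSplit | None = None) -> None:
    """Write the index (optionally with split assignment) as a CSV manifest."""
    out = index.copy()
    if split is not None:
        out["split"] = [split.partition_of(p) for p in out["patient_id"]]
    out.to_csv(path, index=False)


def load_pair(row) -> SlicePair:
    """Load one indexed record from disk, binarizing the mask (>127 -> 1)."""
    image = np.asarray(iio.imread(row["image_path"]))
    mask = np.asarray(iio.imread(row["mask_path"]))
    if mask.ndim == 3:
        mask = mask[..., 0]
    mask = (mask > MASK_THRESHOLD).astype(np.uint8)
    return SlicePair(row["patient_id"], int(row["slice_index"]), image, mask)


# ---------------------------------------------------------------------------
# Patient-wise split
# ---------------------------------------------------------------------------


def split_patients(
    index: pd.DataFrame,
    fractions: Sequence[float] = (0.90, 0.05, 0.05),
    seed: int = 0,
) -> DatasetSplit:
    """Patient-level train/val/test split (no slice-level leakage).

    Counts are floored from the fractions; any remainder is assigned to the
    test partition, so 110 patients at (0.90, 0.05, 0.05) give 99/5/6.
    Deterministic for a given seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    patients = sorted(index["patient_id"].unique())
    n = len(patients)
    if n < 3:
        raise ValueError(f"need at least 3 patients to split, got {n}")
    n_train = int(np.floor(n * fractions[0]))
    n_val = int(np.floor(n * fractions[1]))
    n_test = n - n_train - n_val
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [patients[i] for i in order]
    return DatasetSplit(
        train_ids=tuple(sorted(shuffled[:n_train])),
        val_ids=tuple(sorted(shuffled[n_train : n_train + n_val])),
        test_ids=tuple(sorted(shuffled[n_train + n_val :])),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def _crop_pad(arr: np.ndarray, size: int) -> np.ndarray:
    """Center-crop larger inputs, zero-pad smaller ones, per spatial axis."""
    for axis in (0, 1):
        n = arr.shape[axis]
        if n > size:
            start = (n - size) // 2
            arr = arr.take(range(start, start + size), axis=axis)
        elif n < size:
            before = (size - n) // 2
            after = size - n - before
            pad = [(0, 0)] * arr.ndim
            pad[axis] = (before, after)
            arr = np.pad(arr, pad)
    return arr


def preprocess(image: np.ndarray, size: int = TARGET_SIZE) -> np.ndarray:
    """Scale an 8-bit slice to [0,1] and center-crop/zero-pad to size x size.

    The divisor is the fixed dtype range (255), not a per-image min-max, so
    absolute intensities remain comparable between slices.  Already-float
    unit-interval inputs pass through unscaled, making the op idempotent.
    """
    if image.size == 0:
        raise ValueError("zero-sized input image")
    arr = np.asarray(image)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 255.0
    else:
        arr = np.clip(arr.astype(np.float32), 0.0, 1.0)
    return _crop_pad(arr, size)


def preprocess_mask(mask: np.ndarray, size: int = TARGET_SIZE) -> np.ndarray:
    """Crop/pad a binary mask to the network size without rescaling values."""
    if mask.size == 0:
        raise ValueError("zero-sized input mask")
    return _crop_pad((np.asarray(mask) > 0).astype(np.uint8), size)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def _linear_kernel(size: int, direction: str) -> np.ndarray:
    k = np.zeros((size, size), dtype=np.float32)
    if direction == "horizontal":
        k[size // 2, :] = 1.0
    elif direction == "vertical":
        k[:, size // 2] = 1.0
    elif direction == "diagonal":
        np.fill_diagonal(k, 1.0)
    else:
        raise ValueError(f"unknown motion-blur direction {direction!r}")
    return k / k.sum()


def augment(pair: SlicePair, config: AugmentationConfig, rng: np.random.Generator) -> SlicePair:
    """Apply the training-time augmentation stack to a preprocessed pair.

    Geometric transforms (flip, rotation, elastic) act on image and mask with
    the same parameters, the mask resampled nearest-neighbour so it stays
    binary; photometric transforms (noise, intensity shift, motion blur)
    touch the image only.  Each transform fires independently through its own
    Bernoulli gate; with every gate closed the pair is returned unchanged.
    """
    from scipy import ndimage

    image = pair.image.astype(np.float32)
    mask = pair.mask.astype(np.uint8)

    if rng.random() < config.flip_probability:
        image = image[:, ::-1].copy()
        mask = mask[:, ::-1].copy()

    if rng.random() < config.rotation_probability:
        angle = rng.uniform(-config.rotation_limit_degrees, config.rotation_limit_degrees)
        image = ndimage.rotate(image, angle, axes=(0, 1), reshape=False, order=1, mode="constant")
        mask = ndimage.rotate(mask, angle, axes=(0, 1), reshape=False, order=0, mode="constant")

    if rng.random() < config.elastic_probability:
        h, w = mask.shape
        dr = ndimage.gaussian_filter(rng.standard_normal((h, w)), config.elastic_sigma)
        dc = ndimage.gaussian_filter(rng.standard_normal((h, w)), config.elastic_sigma)
        for d in (dr, dc):
            peak = np.abs(d).max()
            if peak > 0:
                d *= config.elastic_amplitude / peak
        rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        coords = [rows + dr, cols + dc]
        if image.ndim == 3:
            image = np.stack(
                [ndimage.map_coordinates(image[..., c], coords, order=1) for c in range(image.shape[2])],
                axis=-1,
            )
        else:
            image = ndimage.map_coordinates(image, coords, order=1)
        mask = ndimage.map_coordinates(mask, coords, order=0)

    if rng.random() < config.noise_probability:
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape).astype(np.float32)

    if rng.random() < config.intensity_shift_probability:
        image = image + rng.uniform(-config.intensity_shift_limit, config.intensity_shift_limit)

    if rng.random() < config.motion_blur_probability:
        size = int(rng.choice(config.motion_blur_sizes))
        direction = str(rng.choice(config.motion_blur_directions))
        kernel = _linear_kernel(size, direction)
        if image.ndim == 3:
            image = np.stack(
                [ndimage.convolve(image[..., c], kernel, mode="nearest") for c in range(image.shape[2])],
                axis=-1,
            )
        else:
            image = ndimage.convolve(image, kernel, mode="nearest")

    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    mask = (mask > 0).astype(np.uint8)
    return SlicePair(pair.patient_id, pair.slice_index, image, mask)
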