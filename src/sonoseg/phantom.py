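"""Synthetic brain-slice phantoms with ground-truth tumor masks.

The generator emulates the statistical structure of FLAIR slices from the
low-grade-glioma collection: an elliptical "brain" of intermediate intensity
on a dark background, with an optional hyperintense tumor disk whose support
is the ground-truth mask.  Tumor boundaries can be jittered sinusoidally so
that small/complex-region behaviour downstream is exercisable.  Datasets are
written in the exact per-patient ``_mask``-suffix layout that
:func:`sonoseg.data_io.index_dataset` reads.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .data_io import SlicePair


@dataclass
class PhantomParams:
    """Controls for one synthetic slice.

    Intensities are on the unit interval and ordered
    tumor_level > brain_level > background_level, emulating FLAIR
    hyperintensity of the lesion.
    """

    image_size: int = 128
    brain_axes: tuple = None  # ellipse semi-axes (rows, cols); default 0.42/0.36 of size
    background_level: float = 0.05
    brain_level: float = 0.45
    tumor_level: float = 0.85
    tumor_center: tuple = None  # (row, col); default center of the image
    tumor_radius: float = 12.0
    boundary_jitter: float = 0.0  # fractional sinusoidal radius perturbation
    jitter_lobes: int = 7
    texture_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if not self.tumor_level > self.brain_level > self.background_level:
            raise ValueError("require tumor_level > brain_level > background_level")
        if self.brain_axes is None:
            self.brain_axes = (0.42 * self.image_size, 0.36 * self.image_size)
        if self.tumor_center is None:
            self.tumor_center = (self.image_size / 2.0, self.image_size / 2.0)
        r, c = self.tumor_center
        if not (0 <= r < self.image_size and 0 <= c < self.image_size):
            raise ValueError(f"tumor_center {self.tumor_center} outside the image")


def generate_phantom(params: PhantomParams) -> SlicePair:
    """Render one phantom slice and its exact tumor mask, deterministic per seed.

    The image is brain ellipse + tumor disk + Gaussian texture, clipped to
    [0,1]; the mask is precisely the tumor support, clipped to the brain.
    """
    n = params.image_size
    rng = np.random.default_rng(params.seed)
    rows, cols = np.mgrid[0:n, 0:n].astype(np.float64)
    cr = cc = (n - 1) / 2.0
    ar, ac = params.brain_axes
    brain = ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2 <= 1.0

    image = np.full((n, n), params.background_level, dtype=np.float64)
    image[brain] = params.brain_level

    mask = np.zeros((n, n), dtype=np.uint8)
    if params.tumor_radius > 0:
        tr, tc = params.tumor_center
        dist = np.hypot(rows - tr, cols - tc)
        radius = np.full((n, n), float(params.tumor_radius))
        if params.boundary_jitter > 0:
            theta = np.arctan2(rows - tr, cols - tc)
            phase = rng.uniform(0, 2 * np.pi)
            radius = radius * (
                1.0 + params.boundary_jitter * np.sin(params.jitter_lobes * theta + phase)
            )
        tumor = (dist <= radius) & brain  # lesions live inside the brain
        image[tumor] = params.tumor_level
        mask[tumor] = 1

    if params.texture_sd > 0:
        image = image + rng.normal(0.0, params.texture_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    rgb = np.repeat(image[..., None], 3, axis=-1)
    return SlicePair("phantom", 0, rgb, mask)


def generate_dataset(
    n_patients: int,
    slices_per_patient: int,
    out_dir,
    seed: int = 0,
    image_size: int = 128,
    tumor_fraction: float = 0.7,
) -> pd.DataFrame:
    """Write a phantom dataset in the per-patient ``_mask`` layout.

    A `tumor_fraction` of slices (deterministically chosen per seed) carry a
    lesion of randomized position/size/jitter; the rest are tumor-free.
    Returns a manifest DataFrame with per-file SHA-256 checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    records = []
    for p in range(n_patients):
        pid = f"phantom_{p:03d}"
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        for s in range(slices_per_patient):
            has_tumor = rng.random() < tumor_fraction
            margin = 0.25 * image_size
            params = PhantomParams(
                image_size=image_size,
                tumor_center=(
                    rng.uniform(margin, image_size - margin),
                    rng.uniform(margin, image_size - margin),
                ),
                tumor_radius=rng.uniform(0.06, 0.16) * image_size if has_tumor else 0.0,
                boundary_jitter=float(rng.choice([0.0, 0.15, 0.3])),
                texture_sd=0.03,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            pair = generate_phantom(params)
            img8 = (pair.image * 255.0 + 0.5).astype(np.uint8)
            mask8 = pair.mask * np.uint8(255)
            img_path = pdir / f"{pid}_{s}.png"
            mask_path = pdir / f"{pid}_{s}_mask.png"
            iio.imwrite(img_path, img8)
            iio.imwrite(mask_path, mask8)
            records.append(
                {
                    "patient_id": pid,
                    "slice_index": s,
                    "image_path": str(img_path),
                    "mask_path": str(mask_path),
                    "image_sha256": hashlib.sha256(img_path.read_bytes()).hexdigest(),
                    "mask_sha256": hashlib.sha256(mask_path.read_bytes()).hexdigest(),
                }
            )
    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
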