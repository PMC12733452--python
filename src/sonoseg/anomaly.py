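"""Z-score and morphological analysis of predicted lesion masks.

Turns an image + predicted mask into region-level descriptors and severity
labels that drive the sensory back-ends.  Intensities inside the predicted
lesion are scored in standard deviations relative to "normal brain" — the
Otsu-thresholded brain foreground minus the predicted lesion — and each
8-connected component gets area, centroid, perimeter-based shape complexity
and z statistics.  Coordinates are row-major, 0-based, origin top-left.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from skimage import filters, measure

SEVERITY_LEVELS = ("none", "moderate", "high")
DEFAULT_Z_MODERATE = 2.0
DEFAULT_Z_HIGH = 3.0
MIN_REGION_AREA = 5  # px; suppresses rasterization speckle


@dataclass
class RegionFeatures:
    """Descriptors of one 8-connected lesion component."""

    region_id: int
    area: int
    centroid: tuple  # (row, col)
    mean_intensity: float
    max_intensity: float
    perimeter: float  # count of pixel edges bordering background
    complexity: float  # perimeter^2 / (4 pi area); >= 1 for a disk
    mean_zscore: float
    max_zscore: float
    severity: str = "none"


@dataclass
class AnomalyReport:
    regions: list
    reference_mean: float
    reference_sd: float
    image_shape: tuple
    z_moderate: float = DEFAULT_Z_MODERATE
    z_high: float = DEFAULT_Z_HIGH

    def to_json(self) -> str:
        payload = asdict(self)
        payload["regions"] = [asdict(r) for r in self.regions]
        return json.dumps(payload, indent=2, default=float)


def brain_foreground(image: np.ndarray) -> np.ndarray:
    """Otsu-thresholded brain support of a unit-interval grayscale image."""
    gray = image.mean(axis=-1) if image.ndim == 3 else image
    flat = gray.ravel()
    if np.allclose(flat, flat[0]):
        return np.ones_like(gray, dtype=bool)
    return gray > filters.threshold_otsu(gray)


def zscore_map(image: np.ndarray, reference_mask: np.ndarray) -> np.ndarray:
    """Standardize intensities against the normal-tissue reference region.

    z(p) = (I(p) - mu_ref) / sigma_ref; a constant reference (sigma = 0)
    yields an all-zero map with a warning rather than dividing by zero.
    """
    gray = image.mean(axis=-1) if image.ndim == 3 else image
    ref = np.asarray(reference_mask, dtype=bool)
    if ref.sum() < 2:
        raise ValueError("reference region too small (< 2 pixels)")
    vals = gray[ref].astype(np.float64)
    mu = float(vals.mean())
    sd = float(vals.std())
    if sd <= 1e-12 * max(1.0, abs(mu)):
        warnings.warn("constant reference region: z-score map is identically zero")
        return np.zeros_like(gray, dtype=np.float32)
    return ((gray - mu) / sd).astype(np.float32)


def _edge_perimeter(component: np.ndarray) -> int:
    """Count pixel edges between the component and background (4-adjacency)."""
    padded = np.pad(component.astype(np.int8), 1)
    edges = 0
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        edges += int(np.sum((padded == 1) & (np.roll(padded, shift, axis=(0, 1)) == 0)))
    return edges


def extract_regions(
    mask: np.ndarray,
    image: np.ndarray,
    z_grid: np.ndarray,
    min_area: int = MIN_REGION_AREA,
) -> list:
    """Per-component features of a binary mask (8-connected components).

    Components below `min_area` pixels are dropped as speckle.  The result
    is sorted by descending area (ties by region id).
    """
    mask = np.asarray(mask).astype(bool)
    gray = image.mean(axis=-1) if image.ndim == 3 else image
    if mask.shape != gray.shape or mask.shape != z_grid.shape:
        raise ValueError("mask, image and z_grid must share a shape")
    labels = measure.label(mask, connectivity=2)
    regions = []
    for rid in range(1, labels.max() + 1):
        comp = labels == rid
        area = int(comp.sum())
        if area < min_area:
            continue
        rows, cols = np.nonzero(comp)
        perim = _edge_perimeter(comp)
        regions.append(
            RegionFeatures(
                region_id=rid,
                area=area,
                centroid=(float(rows.mean()), float(cols.mean())),
                mean_intensity=float(gray[comp].mean()),
                max_intensity=float(gray[comp].max()),
                perimeter=float(perim),
                complexity=float(perim**2 / (4.0 * np.pi * area)),
                mean_zscore=float(z_grid[comp].mean()),
                max_zscore=float(z_grid[comp].max()),
            )
        )
    regions.sort(key=lambda r: (-r.area, r.region_id))
    return regions


def classify_severity(
    region: RegionFeatures,
    thresholds: tuple = (DEFAULT_Z_MODERATE, DEFAULT_Z_HIGH),
) -> str:
    """Severity ladder on the region's max z-score: high >= z_high,
    moderate >= z_moderate, else none."""
    z_moderate, z_high = thresholds
    if not z_high > z_moderate > 0:
        raise ValueError(f"require z_high > z_moderate > 0, got {thresholds}")
    if region.max_zscore >= z_high:
        return "high"
    if region.max_zscore >= z_moderate:
        return "moderate"
    return "none"


def analyze(
    image: np.ndarray,
    predicted_mask: np.ndarray,
    thresholds: tuple = (DEFAULT_Z_MODERATE, DEFAULT_Z_HIGH),
    min_area: int = MIN_REGION_AREA,
) -> AnomalyReport:
    """Full stage-1 analysis: reference stats, z map, regions, severities."""
    gray = image.mean(axis=-1) if image.ndim == 3 else image
    mask = np.asarray(predicted_mask).astype(bool)
    reference = brain_foreground(image) & ~mask
    if reference.sum() < 2:  # lesion covers the whole brain: fall back
        reference = ~mask if (~mask).sum() >= 2 else np.ones_like(mask)
    z = zscore_map(image, reference)
    regions = extract_regions(mask, image, z, min_area=min_area)
    for r in regions:
        r.severity = classify_severity(r, thresholds)
    return AnomalyReport(
        regions=regions,
        reference_mean=float(gray[reference].mean()),
        reference_sd=float(gray[reference].std()),
        image_shape=tuple(mask.shape),
        z_moderate=thresholds[0],
        z_high=thresholds[1],
    )
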