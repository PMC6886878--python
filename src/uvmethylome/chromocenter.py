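"""Chromocenter-occupancy quantification from DAPI nucleus images.

Arabidopsis heterochromatin condenses into DAPI-bright chromocenters.  From
a z-max projected grayscale image, nuclei are segmented by Otsu thresholding
and connected components; within each nucleus, chromocenter spots are pixels
brighter than the nucleus mean + k·sd.  Chromocenter occupancy (CO) is the
percentage of the nucleus surface covered by its bright spots; per-spot
relative intensity and relative surface are reported against whole-nucleus
values.  All thresholds are relative, so the measurements are invariant to
uniform intensity rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .stats import TestResult, mann_whitney

__all__ = [
    "NucleusMeasurement",
    "project_zmax",
    "segment_nuclei",
    "detect_chromocenters",
    "chromocenter_occupancy",
    "relative_metrics",
    "measure_image",
    "compare_groups",
]


@dataclass
class NucleusMeasurement:
    nucleus_id: int
    nucleus_area: int
    nucleus_mean_intensity: float
    centroid: tuple[float, float] = (0.0, 0.0)  # (row, col)
    spot_areas: list[int] = field(default_factory=list)
    spot_mean_intensities: list[float] = field(default_factory=list)

    @property
    def spot_count(self) -> int:
        return len(self.spot_areas)

    @property
    def total_spot_area(self) -> int:
        return int(sum(self.spot_areas))

    @property
    def co(self) -> float:
        """Chromocenter occupancy, percent of nucleus surface."""
        return chromocenter_occupancy(self.total_spot_area, self.nucleus_area)

    @property
    def relative_spot_intensities(self) -> list[float]:
        return [i / self.nucleus_mean_intensity for i in self.spot_mean_intensities]

    @property
    def relative_spot_surfaces(self) -> list[float]:
        return [a / self.nucleus_area for a in self.spot_areas]


def project_zmax(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a (z, y, x) stack; a single 2D image
    is returned unchanged."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack
    if stack.ndim != 3:
        raise ValueError(f"expected 2D image or 3D stack, got ndim={stack.ndim}")
    return stack.max(axis=0)


def segment_nuclei(image: np.ndarray, min_area_px: int = 200) -> np.ndarray:
    """Label nuclei by global Otsu threshold + connected components; blobs
    smaller than ``min_area_px`` are discarded.  A blank image yields zero
    nuclei."""
    image = np.asarray(image, dtype=float)
    if image.max() == image.min():
        return np.zeros(image.shape, dtype=int)
    mask = image > threshold_otsu(image)
    labels = measure.label(mask, connectivity=2)
    out = np.zeros_like(labels)
    next_id = 0
    for region in measure.regionprops(labels):
        if region.area >= min_area_px:
            next_id += 1
            out[labels == region.label] = next_id
    return out


def detect_chromocenters(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    k: float = 2.0,
    min_spot_px: int = 4,
) -> np.ndarray:
    """Label chromocenter spots inside one nucleus mask.

    Spot pixels are nucleus pixels with intensity above the nucleus mean +
    k·sd; connected components of at least ``min_spot_px`` pixels are kept.
    """
    image = np.asarray(image, dtype=float)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    vals = image[nucleus_mask]
    if vals.size == 0:
        return np.zeros(image.shape, dtype=int)
    cutoff = vals.mean() + k * vals.std()
    spot_mask = nucleus_mask & (image > cutoff)
    labels = measure.label(spot_mask, connectivity=2)
    out = np.zeros_like(labels)
    next_id = 0
    for region in measure.regionprops(labels):
        if region.area >= min_spot_px:
            next_id += 1
            out[labels == region.label] = next_id
    return out


def chromocenter_occupancy(total_spot_area: float, nucleus_area: float) -> float:
    """CO (%) = 100 × total bright-spot surface / nucleus surface."""
    if nucleus_area <= 0:
        raise ValueError("nucleus area must be positive")
    return 100.0 * total_spot_area / nucleus_area


def relative_metrics(
    image: np.ndarray, nucleus_mask: np.ndarray, spot_labels: np.ndarray
) -> dict:
    """Per-spot mean intensity / nucleus mean and per-spot area / nucleus
    area."""
    image = np.asarray(image, dtype=float)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    nuc_mean = float(image[nucleus_mask].mean())
    nuc_area = int(nucleus_mask.sum())
    rel_int, rel_surf = [], []
    for sid in range(1, int(spot_labels.max()) + 1):
        spot = spot_labels == sid
        rel_int.append(float(image[spot].mean()) / nuc_mean)
        rel_surf.append(int(spot.sum()) / nuc_area)
    return {"relative_intensities": rel_int, "relative_surfaces": rel_surf}


def measure_image(
    image_or_stack: np.ndarray,
    min_area_px: int = 200,
    k: float = 2.0,
    min_spot_px: int = 4,
) -> list[NucleusMeasurement]:
    """Full quantification of one image (or stack): project, segment nuclei,
    detect chromocenters and collect per-nucleus measurements."""
    image = project_zmax(image_or_stack)
    nuclei = segment_nuclei(image, min_area_px)
    out = []
    for nid in range(1, int(nuclei.max()) + 1):
        mask = nuclei == nid
        spots = detect_chromocenters(image, mask, k=k, min_spot_px=min_spot_px)
        ys, xs = np.nonzero(mask)
        m = NucleusMeasurement(
            nucleus_id=nid,
            nucleus_area=int(mask.sum()),
            nucleus_mean_intensity=float(np.asarray(image, dtype=float)[mask].mean()),
            centroid=(float(ys.mean()), float(xs.mean())),
        )
        for sid in range(1, int(spots.max()) + 1):
            spot = spots == sid
            m.spot_areas.append(int(spot.sum()))
            m.spot_mean_intensities.append(float(np.asarray(image, dtype=float)[spot].mean()))
        out.append(m)
    return out


def compare_groups(co_a, co_b) -> TestResult:
    """Mann-Whitney U test between two groups of CO values (e.g. genotypes
    or time points)."""
    return mann_whitney(co_a, co_b)
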