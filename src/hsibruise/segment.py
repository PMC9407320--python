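"""Morphological segmentation (MSM) of PC2 score images and the Otsu baseline.

The MSM pipeline binarizes the PC2 score image inside the fruit by Otsu's
threshold, removes small speckle components, applies binary opening then
closing with a disc, and derives the bruise boundary as the morphological
gradient (dilation minus erosion) of the cleaned mask.  A sample is called
BRUISED when the cleaned mask retains at least ``decision_min_area`` pixels,
otherwise NORMAL — the non-zero-pixel triage rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, dilation, disk, erosion, opening

from .cube import NIR, FruitMask, HyperspectralCube, SpectralRegion, crop_spectral
from .pca import fit_pca, score_image

NORMAL = "NORMAL"
BRUISED = "BRUISED"


@dataclass
class MSMParams:
    min_object_area: int = 50  # speckle components below this are noise
    se_radius_filter: int = 3  # disc radius for opening/closing
    se_radius_gradient: int = 1  # disc radius for the morphological gradient
    polarity: str = "auto"  # dark_bruise | bright_bruise | auto
    decision_min_area: int = 50  # BRUISED iff cleaned mask has >= this many px

    def __post_init__(self) -> None:
        if self.se_radius_filter < 1 or self.se_radius_gradient < 1:
            raise ValueError("structuring-element radii must be >= 1")
        if self.min_object_area < 0 or self.decision_min_area < 0:
            raise ValueError("areas must be >= 0")
        if self.polarity not in ("dark_bruise", "bright_bruise", "auto"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass
class SegmentationResult:
    bruise_mask: np.ndarray
    boundary: np.ndarray
    pixel_count: int
    verdict: str


def _binarize(pc2: np.ndarray, fruit: np.ndarray, polarity: str) -> np.ndarray:
    """Otsu-threshold the score image within the fruit and pick the bruise side.

    ``auto`` polarity takes the side occupying the smaller fruit-area
    fraction: a bruise is a local anomaly, while the PC sign is arbitrary.
    Constant images yield an empty mask.
    """
    values = pc2[fruit]
    if np.ptp(values) == 0:
        return np.zeros_like(fruit)
    t = threshold_otsu(values, nbins=256)
    bright = fruit & (pc2 > t)
    dark = fruit & (pc2 <= t) & fruit
    if polarity == "bright_bruise":
        return bright
    if polarity == "dark_bruise":
        return dark
    return bright if bright.sum() <= dark.sum() else dark


def _remove_small(binary: np.ndarray, min_area: int) -> np.ndarray:
    """Drop 8-connected components with fewer than ``min_area`` pixels."""
    if min_area <= 1 or not binary.any():
        return binary
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_area) + 1
    return np.isin(labels, keep)


def _verdict(count: int, params: MSMParams) -> str:
    return BRUISED if count >= params.decision_min_area else NORMAL


def msm_segment(
    pc2: np.ndarray, fruit: FruitMask, params: MSMParams | None = None
) -> SegmentationResult:
    """Run the full morphological segmentation pipeline on a PC2 image."""
    params = params or MSMParams()
    if pc2.shape != fruit.mask.shape:
        raise ValueError("score image and fruit mask shapes differ")
    if not fruit.mask.any():
        raise ValueError("empty fruit mask")
    binary = _binarize(pc2, fruit.mask, params.polarity)
    binary = _remove_small(binary, params.min_object_area)
    se = disk(params.se_radius_filter)
    cleaned = closing(opening(binary, se), se).astype(bool)
    se_g = disk(params.se_radius_gradient)
    boundary = dilation(cleaned, se_g) & ~erosion(cleaned, se_g)
    count = int(cleaned.sum())
    return SegmentationResult(cleaned, boundary, count, _verdict(count, params))


def otsu_segment(
    pc2: np.ndarray,
    fruit: FruitMask,
    polarity: str = "auto",
    params: MSMParams | None = None,
) -> SegmentationResult:
    """Plain Otsu binarization within the fruit, no morphological cleanup."""
    params = params or MSMParams(polarity=polarity)
    if not fruit.mask.any():
        raise ValueError("empty fruit mask")
    binary = _binarize(pc2, fruit.mask, polarity)
    se_g = disk(params.se_radius_gradient)
    boundary = dilation(binary, se_g) & ~erosion(binary, se_g)
    count = int(binary.sum())
    return SegmentationResult(binary, boundary, count, _verdict(count, params))


def triage(
    cube: HyperspectralCube,
    mask: FruitMask,
    params: MSMParams | None = None,
    region: SpectralRegion = NIR,
) -> tuple[str, SegmentationResult]:
    """NORMAL/BRUISED decision for one calibrated cube.

    Crops to the NIR region, fits a per-sample PCA on the fruit pixels,
    takes the PC2 score image and segments it with the MSM.
    """
    nir = crop_spectral(cube, region)
    p = fit_pca(nir, mask, n_components=2)
    pc2 = score_image(nir, mask, p, component=1)
    result = msm_segment(pc2, mask, params)
    return result.verdict, result
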