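"""Hyperspectral cube container and spectral/spatial primitives.

A cube is a (rows, cols, bands) array with a strictly increasing wavelength
axis in nm.  Raw sensor cubes are converted to relative reflectance with a
white (high-reflectance standard) and dark (shutter-closed) reference:

    R(r, c, λ) = (T(r, c, λ) − T_d(λ)) / (T_w(λ) − T_d(λ))

All spatial coordinates follow the (row, col) convention, origin top-left,
0-based; rectangles are half-open ``(row0, row1, col0, col1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu


@dataclass
class SpectralRegion:
    """Inclusive wavelength window in nm."""

    name: str
    lo_nm: float
    hi_nm: float


#: The three analysis regions: visible, near-infrared, and their union.
VIS = SpectralRegion("VIS", 425.0, 780.0)
NIR = SpectralRegion("NIR", 781.0, 1000.0)
VIS_NIR = SpectralRegion("VIS_NIR", 425.0, 1000.0)

REGIONS: Mapping[str, SpectralRegion] = {r.name: r for r in (VIS, NIR, VIS_NIR)}


@dataclass
class HyperspectralCube:
    """Reflectance or raw-intensity cube indexed (row, col, band)."""

    data: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (row, col, band)")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength vector length {len(self.wavelengths)} does not match "
                f"band dimension {self.data.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class CalibrationFrames:
    """White and dark reference frames.

    Either may be a full cube, a single spatial frame with a trailing
    band axis of length 1, or a per-band vector; anything broadcastable
    to the raw cube's shape is accepted.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)


@dataclass
class FruitMask:
    """Binary fruit-pixel mask, True on fruit."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("fruit mask must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def calibrate(raw: HyperspectralCube, frames: CalibrationFrames) -> HyperspectralCube:
    """Convert raw intensities to relative reflectance.

    Applies R = (T − T_d)/(T_w − T_d) per pixel per band.  Raises if the
    white–dark difference is non-positive anywhere (a dead band), naming
    the first offending band.
    """
    denom = np.broadcast_to(frames.white - frames.dark, raw.data.shape)
    bad = ~np.all(denom > 0, axis=(0, 1))
    if np.any(bad):
        b = int(np.argmax(bad))
        raise ValueError(
            f"white - dark is not strictly positive at band {b} "
            f"({raw.wavelengths[b]:.1f} nm)"
        )
    refl = (raw.data - frames.dark) / (frames.white - frames.dark)
    if not np.all(np.isfinite(refl)):
        raise ValueError("calibration produced non-finite reflectance")
    return HyperspectralCube(
        refl.astype(raw.data.dtype, copy=False),
        raw.wavelengths.copy(),
        dict(raw.meta, calibrated=True),
    )


def crop_spectral(cube: HyperspectralCube, region: SpectralRegion) -> HyperspectralCube:
    """Retain exactly the bands with lo_nm <= λ <= hi_nm, order preserved."""
    keep = (cube.wavelengths >= region.lo_nm) & (cube.wavelengths <= region.hi_nm)
    if not keep.any():
        raise ValueError(
            f"region {region.name} [{region.lo_nm}, {region.hi_nm}] nm contains "
            "no band of the cube"
        )
    return HyperspectralCube(
        cube.data[:, :, keep], cube.wavelengths[keep], dict(cube.meta, region=region.name)
    )


def nearest_band(cube: HyperspectralCube, target_nm: float) -> int:
    """Index of the band whose center is closest to ``target_nm``.

    Ties between two equidistant bands resolve to the lower index.  A target
    farther than one grid spacing outside the span is rejected.
    """
    if cube.n_bands == 0:
        raise ValueError("empty cube")
    dev = np.abs(cube.wavelengths - target_nm)
    idx = int(np.argmin(dev))  # argmin returns the first (lower) index on ties
    spacing = (
        float(np.max(np.diff(cube.wavelengths))) if cube.n_bands > 1 else np.inf
    )
    if dev[idx] > spacing:
        raise ValueError(
            f"target {target_nm} nm is more than one band spacing "
            f"({spacing:.2f} nm) from the nearest band ({cube.wavelengths[idx]:.2f} nm)"
        )
    return idx


def extract_roi_spectrum(
    cube: HyperspectralCube, rect: tuple[int, int, int, int]
) -> np.ndarray:
    """Mean spectrum over a half-open (row0, row1, col0, col1) rectangle."""
    r0, r1, c0, c1 = rect
    rows, cols, _ = cube.shape
    if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
        raise ValueError(f"rectangle {rect} empty or outside image bounds {rows}x{cols}")
    return cube.data[r0:r1, c0:c1, :].mean(axis=(0, 1))


def make_fruit_mask(
    cube: HyperspectralCube, reference_nm: float = 782.0
) -> FruitMask:
    """Segment the fruit from the background on a single high-SNR band.

    Otsu-thresholds the band nearest ``reference_nm``, fills holes and keeps
    the largest bright connected component.  The fruit must be brighter than
    the background at that band (true for any reflectance-calibrated fruit
    scene over a dark background).
    """
    band = cube.data[:, :, nearest_band(cube, reference_nm)].astype(float)
    if np.ptp(band) == 0:
        raise ValueError("no fruit found: reference band is constant")
    t = threshold_otsu(band, nbins=256)
    bright = band > t
    if not bright.any():
        raise ValueError("no fruit found: no pixel above threshold")
    labels, n = ndimage.label(bright)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        bright = labels == (1 + int(np.argmax(sizes)))
    return FruitMask(ndimage.binary_fill_holes(bright))
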