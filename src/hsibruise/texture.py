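"""Two-band ratio images and GLCM texture features of the bruise region.

The ratio image K_{a/b} = J_a / J_b divides the reflectance images at two
wavelengths pixel-wise, cancelling any multiplicative brightness field that
is common to both bands (curvature shading, residual illumination).  Gray
level co-occurrence matrices of the quantized ratio image over the bruise
region yield five Haralick statistics per direction; together with the mean
bruise reflectance at the three characteristic bands and the mean ratio-image
gray, they form the 24-element feature vector of the multispectral analysis
method (MAM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cube import FruitMask, HyperspectralCube, nearest_band
from .pca import BandSelection
from .segment import BRUISED, SegmentationResult

#: GLCM direction name -> (row, col) offset at unit distance.
DIRECTIONS = {
    "0": (0, 1),
    "45": (-1, 1),
    "90": (-1, 0),
    "135": (-1, -1),
}

HARALICK_NAMES = ("energy", "entropy", "contrast", "correlation", "idm")


@dataclass
class RatioImage:
    values: np.ndarray
    a_nm: float
    b_nm: float
    valid_mask: np.ndarray  # mask minus denominator-guard exclusions
    n_guarded: int = 0  # pixels excluded by the denominator guard


@dataclass
class GLCMParams:
    levels: int = 16
    distance: int = 1

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 gray levels")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")


@dataclass
class FeatureVector:
    """MAM input: 3 band reflectances + mean ratio gray + 20 GLCM statistics."""

    band_wavelengths: np.ndarray
    spectra: np.ndarray  # mean bruise reflectance at the 3 bands
    mean_gray: float
    texture: dict = field(default_factory=dict)  # {direction: {stat: value}}

    def names(self) -> list[str]:
        out = [f"r{w:.0f}" for w in self.band_wavelengths]
        out.append("mean_gray")
        for d in DIRECTIONS:
            out.extend(f"{stat}_{d}" for stat in HARALICK_NAMES)
        return out

    def to_array(self) -> np.ndarray:
        vals = [*self.spectra, self.mean_gray]
        for d in DIRECTIONS:
            vals.extend(self.texture[d][s] for s in HARALICK_NAMES)
        arr = np.asarray(vals, dtype=float)
        assert arr.shape == (24,)
        return arr


def band_ratio(
    cube: HyperspectralCube,
    a_nm: float,
    b_nm: float,
    mask: FruitMask,
    guard: float = 1e-6,
) -> RatioImage:
    """Pixel-wise J_a / J_b on the mask; off-mask pixels are 0.

    Pixels whose denominator magnitude falls below ``guard`` times the
    masked median of |J_b| are excluded from the valid mask and counted in
    ``n_guarded`` rather than allowed to produce infinities.
    """
    if a_nm == b_nm:
        raise ValueError("ratio needs two distinct wavelengths")
    ja = cube.data[:, :, nearest_band(cube, a_nm)].astype(float)
    jb = cube.data[:, :, nearest_band(cube, b_nm)].astype(float)
    m = mask.mask
    if not m.any():
        raise ValueError("empty mask")
    eps = guard * float(np.median(np.abs(jb[m])))
    valid = m & (np.abs(jb) > eps)
    out = np.zeros_like(ja)
    out[valid] = ja[valid] / jb[valid]
    return RatioImage(out, a_nm, b_nm, valid, int(m.sum() - valid.sum()))


def quantize(image: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Linear min-max binning of masked pixels into gray levels 1..levels.

    A constant image maps entirely to level 1; off-mask pixels are 0.
    """
    if levels < 2:
        raise ValueError("need at least 2 levels")
    if not mask.any():
        raise ValueError("empty mask")
    vals = image[mask]
    lo, hi = float(vals.min()), float(vals.max())
    q = np.zeros(image.shape, dtype=int)
    if hi == lo:
        q[mask] = 1
        return q
    scaled = (image[mask] - lo) / (hi - lo)  # in [0, 1]
    q[mask] = np.minimum((scaled * levels).astype(int), levels - 1) + 1
    return q


def glcm(
    qimage: np.ndarray,
    mask: np.ndarray,
    direction: str | tuple[int, int],
    distance: int = 1,
    levels: int | None = None,
) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix of a quantized image.

    Counts ordered level pairs (q[p], q[p + d·offset]) for pixel pairs with
    BOTH endpoints inside the mask, in the given offset direction and its
    opposite (symmetric GLCM), then normalizes the matrix to sum 1.
    """
    dr, dc = DIRECTIONS[direction] if isinstance(direction, str) else direction
    dr, dc = dr * distance, dc * distance
    levels = levels or int(qimage[mask].max())
    rows, cols = qimage.shape

    # overlap windows of the image with itself shifted by (dr, dc)
    r0, r1 = max(0, -dr), min(rows, rows - dr)
    c0, c1 = max(0, -dc), min(cols, cols - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError("offset larger than image: no valid pixel pair")
    src = qimage[r0:r1, c0:c1]
    dst = qimage[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    pair_ok = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    if not pair_ok.any():
        raise ValueError("no pixel pair with both endpoints in the mask")
    a = src[pair_ok] - 1
    b = dst[pair_ok] - 1
    P = np.zeros((levels, levels), dtype=float)
    np.add.at(P, (a, b), 1.0)
    np.add.at(P, (b, a), 1.0)  # opposite offset: symmetric matrix
    return P / P.sum()


def haralick(P: np.ndarray) -> dict[str, float]:
    """Five Haralick statistics of a normalized co-occurrence matrix.

    energy = Σ p², entropy = −Σ p log₂ p (with 0·log 0 := 0),
    contrast = Σ (i−j)² p, correlation = Σ (i−μ_i)(j−μ_j) p / (σ_i σ_j)
    (0 when either marginal is degenerate), idm = Σ p / (1 + (i−j)²).
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1] or np.any(P < 0):
        raise ValueError("P must be a square non-negative matrix")
    if not np.isclose(P.sum(), 1.0, atol=1e-8):
        raise ValueError(f"P must be normalized to sum 1 (got {P.sum():.6f})")
    G = P.shape[0]
    i, j = np.meshgrid(np.arange(G), np.arange(G), indexing="ij")
    energy = float((P**2).sum())
    nz = P > 0
    entropy = float(-(P[nz] * np.log2(P[nz])).sum())
    contrast = float((((i - j) ** 2) * P).sum())
    mu_i = float((i * P).sum())
    mu_j = float((j * P).sum())
    var_i = float((((i - mu_i) ** 2) * P).sum())
    var_j = float((((j - mu_j) ** 2) * P).sum())
    if var_i > 0 and var_j > 0:
        correlation = float(
            (((i - mu_i) * (j - mu_j) * P).sum()) / np.sqrt(var_i * var_j)
        )
    else:
        correlation = 0.0
    idm = float((P / (1.0 + (i - j) ** 2)).sum())
    return {
        "energy": energy,
        "entropy": entropy,
        "contrast": contrast,
        "correlation": correlation,
        "idm": idm,
    }


def mam_features(
    cube: HyperspectralCube,
    seg: SegmentationResult,
    bands: BandSelection,
    fruit: FruitMask | None = None,
    glcm_params: GLCMParams | None = None,
) -> FeatureVector:
    """Assemble the 24-element MAM feature vector for one bruised sample.

    Mean bruise-mask reflectance at the three characteristic bands, the mean
    gray of the first/last-band ratio image over the bruise, and the five
    Haralick statistics of its 16-level GLCM in the four standard directions,
    computed over the bruise-mask bounding box.
    """
    if seg.verdict != BRUISED:
        raise ValueError("triage first: MAM features are defined for BRUISED samples")
    if len(bands.wavelengths_nm) != 3:
        raise ValueError("MAM uses exactly 3 characteristic bands")
    glcm_params = glcm_params or GLCMParams()
    bruise = seg.bruise_mask
    fruit = fruit or FruitMask(bruise)

    spectra = np.array(
        [
            float(cube.data[bruise, nearest_band(cube, w)].mean())
            for w in bands.wavelengths_nm
        ]
    )

    ratio = band_ratio(cube, bands.wavelengths_nm[0], bands.wavelengths_nm[-1], fruit)
    region = bruise & ratio.valid_mask
    if not region.any():
        raise ValueError("bruise region empty after denominator guard")
    mean_gray = float(ratio.values[region].mean())

    # bounding box of the bruise keeps GLCM windows small and well-populated
    rr, cc = np.nonzero(region)
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    if min(r1 - r0, c1 - c0) <= glcm_params.distance:
        raise ValueError("bruise region smaller than the GLCM pair distance")
    window = ratio.values[r0:r1, c0:c1]
    wmask = region[r0:r1, c0:c1]
    q = quantize(window, wmask, glcm_params.levels)
    texture = {
        d: haralick(glcm(q, wmask, d, glcm_params.distance, glcm_params.levels))
        for d in DIRECTIONS
    }
    return FeatureVector(
        band_wavelengths=np.asarray(bands.wavelengths_nm, dtype=float),
        spectra=spectra,
        mean_gray=mean_gray,
        texture=texture,
    )
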