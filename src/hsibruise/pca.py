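"""Region-restricted PCA over fruit pixels and characteristic-band selection.

The fruit-pixel spectra of a calibrated cube are mean-centered and projected
onto principal components.  PC score images map each component back to the
image plane; the loading (weight-coefficient) curve of a component shows
which wavelengths drive it, and its local extrema — together with the region
interval endpoints — are the candidate characteristic bands for a reduced
multispectral system.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from sklearn.decomposition import PCA

from .cube import FruitMask, HyperspectralCube, SpectralRegion, crop_spectral


@dataclass
class PCAResult:
    """Loadings (band x component, unit columns), variance shares and mean."""

    loadings: np.ndarray
    explained: np.ndarray
    mean_spectrum: np.ndarray
    wavelengths: np.ndarray
    region: str

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class BandSelection:
    """Characteristic bands: interval endpoints plus loading-curve extrema."""

    wavelengths_nm: np.ndarray
    indices: np.ndarray
    source_pc: int


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    # PCA signs are arbitrary; orient each column so its largest-|.| element
    # is positive, which makes results reproducible across solvers.
    out = loadings.copy()
    for k in range(out.shape[1]):
        j = int(np.argmax(np.abs(out[:, k])))
        if out[j, k] < 0:
            out[:, k] = -out[:, k]
    return out


def _masked_spectra(cube: HyperspectralCube, mask: FruitMask) -> np.ndarray:
    if mask.mask.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube spatial shape")
    X = cube.data[mask.mask, :].astype(float)
    if X.shape[0] == 0:
        raise ValueError("mask selects no pixels")
    return X


def fit_pca(
    cube: HyperspectralCube,
    mask: FruitMask,
    region: SpectralRegion | None = None,
    n_components: int = 3,
) -> PCAResult:
    """PCA of the mean-centered fruit-pixel spectra of one cube."""
    if region is not None:
        cube = crop_spectral(cube, region)
    X = _masked_spectra(cube, mask)
    if X.shape[0] < n_components:
        raise ValueError(
            f"{X.shape[0]} masked pixels cannot support {n_components} components"
        )
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("zero-variance data: PCA undefined")
    p = PCA(n_components=n_components, svd_solver="full")
    p.fit(X)
    return PCAResult(
        loadings=_fix_signs(p.components_.T),
        explained=p.explained_variance_ratio_.copy(),
        mean_spectrum=p.mean_.copy(),
        wavelengths=cube.wavelengths.copy(),
        region=region.name if region is not None else cube.meta.get("region", "FULL"),
    )


def fit_pca_pooled(
    samples: Sequence[tuple[HyperspectralCube, FruitMask]],
    region: SpectralRegion | None = None,
    n_components: int = 3,
) -> PCAResult:
    """PCA pooled over the fruit pixels of several cubes.

    Accumulates streaming first and second moments band-by-band, so cohorts
    far larger than memory can be pooled; the eigendecomposition of the
    pooled covariance gives loadings and variance shares.  Used for the
    cohort-level weight curve that drives band selection.
    """
    s1 = s2 = None
    n = 0
    wavelengths = None
    region_name = region.name if region is not None else "FULL"
    for cube, mask in samples:
        if region is not None:
            cube = crop_spectral(cube, region)
        X = _masked_spectra(cube, mask)
        if wavelengths is None:
            wavelengths = cube.wavelengths.copy()
            s1 = np.zeros(X.shape[1])
            s2 = np.zeros((X.shape[1], X.shape[1]))
        s1 += X.sum(axis=0)
        s2 += X.T @ X
        n += X.shape[0]
    if n < n_components:
        raise ValueError("fewer pooled pixels than components")
    mean = s1 / n
    cov = s2 / n - np.outer(mean, mean)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    total = evals.sum()
    if total <= 0:
        raise ValueError("zero-variance data: PCA undefined")
    return PCAResult(
        loadings=_fix_signs(evecs[:, order[:n_components]]),
        explained=evals[:n_components] / total,
        mean_spectrum=mean,
        wavelengths=wavelengths,
        region=region_name,
    )


def score_image(
    cube: HyperspectralCube, mask: FruitMask, pca: PCAResult, component: int
) -> np.ndarray:
    """Per-pixel projection onto one component; off-mask pixels are 0.

    The cube must already be cropped to the region the PCA was fitted on.
    """
    if not 0 <= component < pca.n_components:
        raise ValueError(f"component {component} out of range (fitted {pca.n_components})")
    if cube.n_bands != pca.loadings.shape[0]:
        raise ValueError(
            f"cube has {cube.n_bands} bands but PCA was fitted on "
            f"{pca.loadings.shape[0]} (crop to region {pca.region!r} first)"
        )
    img = np.zeros(cube.shape[:2], dtype=float)
    X = cube.data[mask.mask, :].astype(float) - pca.mean_spectrum
    img[mask.mask] = X @ pca.loadings[:, component]
    return img


def _smooth(curve: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return curve.astype(float)
    window = min(window, len(curve))
    pad = window // 2
    padded = np.pad(curve.astype(float), pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")[: len(curve)]


def select_characteristic_bands(
    pca: PCAResult,
    component: int = 1,
    smoothing: int = 5,
    min_prominence: float = 0.10,
    max_interior: int = 3,
) -> BandSelection:
    """Interval endpoints plus prominent interior extrema of a loading curve.

    The loading curve is box-smoothed (``smoothing`` bands), then interior
    local maxima and minima with prominence at least ``min_prominence`` times
    the curve range are kept; if more than ``max_interior`` survive, the most
    prominent ones win.  The first and last band of the region are always
    included, so a monotone curve yields exactly the two endpoints.
    """
    if not 0 <= component < pca.n_components:
        raise ValueError(f"component {component} out of range")
    curve = pca.loadings[:, component]
    if len(curve) < 3:
        raise ValueError("loading curve must span at least 3 bands")
    smoothed = _smooth(curve, smoothing)
    rng = float(np.ptp(smoothed))
    threshold = min_prominence * rng if rng > 0 else np.inf
    interior: list[tuple[float, int]] = []
    for sign in (1.0, -1.0):
        peaks, props = find_peaks(sign * smoothed, prominence=threshold)
        for p, prom in zip(peaks, props["prominences"]):
            if 0 < p < len(curve) - 1:
                interior.append((float(prom), int(p)))
    interior.sort(key=lambda t: (-t[0], t[1]))
    chosen = sorted({p for _, p in interior[:max_interior]})
    indices = np.array(sorted({0, len(curve) - 1, *chosen}))
    return BandSelection(
        wavelengths_nm=pca.wavelengths[indices],
        indices=indices,
        source_pc=component,
    )
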