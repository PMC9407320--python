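"""Synthetic hyperspectral loquat phantoms with ground truth.

Each phantom emulates a push-broom reflectance scene of a single fruit on a
dark background: a 176-band cube on the 397.5–1014 nm grid, an elliptical
fruit with a smooth reflectance spectrum, an optional circular bruise whose
reflectance is depressed in a Gaussian NIR band (plus a weaker visible
browning band), lamp illumination with a planar gradient and vignette, and
band-dependent additive noise that grows outside 425–1000 nm (the low-SNR
detector edges).

Two multiplicative spatial fields play distinct roles:

* the **lamp field** is shared with the emitted white reference, so Eq.-(1)
  style calibration removes it exactly;
* the **curvature shading** of the fruit surface is absent from the flat
  white panel and therefore survives calibration — exactly as on real curved
  fruit.  It makes overall brightness the first principal component of the
  calibrated fruit spectra, leaving the bruise contrast to PC2, and gives
  two-band ratio images a genuine illumination term to cancel.

Grade severity is encoded by the depression depth δ: 0 for SOUND and
strictly increasing through grades I–IV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np

from .cube import CalibrationFrames, HyperspectralCube

#: Grade labels in severity order.
GRADES = ("SOUND", "I", "II", "III", "IV")

#: Default per-grade NIR reflectance depression depth δ (dimensionless).
DEFAULT_DEPRESSION: Mapping[str, float] = {
    "SOUND": 0.0,
    "I": 0.05,
    "II": 0.10,
    "III": 0.16,
    "IV": 0.24,
}

#: Per-sample spread of δ in a generated cohort (absolute standard deviation).
DELTA_JITTER_SD = 0.008


def default_grid() -> np.ndarray:
    """The acquisition wavelength grid: 176 bands spanning 397.5–1014 nm."""
    return np.linspace(397.5, 1014.0, 176)


def base_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth sound-tissue reflectance curve in (0, 1), higher in NIR than blue.

    Sum of two broad Gaussians: a dominant NIR plateau (fruit flesh/water
    scattering) and a smaller green-yellow carotenoid shoulder.  Deliberately
    gentle in the NIR so band-level structure added by the bruise model stays
    localized at its own center wavelength.
    """
    wl = np.asarray(wavelengths, dtype=float)
    return (
        0.10
        + 0.50 * np.exp(-(((wl - 880.0) / 320.0) ** 2))
        + 0.08 * np.exp(-(((wl - 550.0) / 80.0) ** 2))
    )


@dataclass
class PhantomConfig:
    """Scene parameters for one synthetic fruit."""

    rows: int = 120
    cols: int = 120
    wavelengths: np.ndarray = field(default_factory=default_grid)
    fruit_center: tuple[float, float] | None = None  # default: image center
    fruit_axes: tuple[float, float] = (46.0, 38.0)  # ellipse semi-axes, px
    bruise_center: tuple[float, float] | None = None  # default: offset from center
    bruise_radius: float = 12.0
    grade: str = "SOUND"
    depression: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEPRESSION)
    )
    delta_override: float | None = None  # per-sample δ, overrides the grade table
    depression_center_nm: float = 900.0
    depression_width_nm: float = 120.0
    vis_center_nm: float = 560.0  # weak browning band in the visible
    vis_width_nm: float = 60.0
    vis_fraction: float = 0.3  # δ_vis = vis_fraction · δ
    illum_gradient: float = 0.2  # fractional lamp brightness slope
    illum_angle: float = 0.0  # gradient direction, radians
    shading_amplitude: float = 0.25  # curvature dome depth at the fruit rim
    white_scale: float = 1.0  # overall lamp intensity (exposure)
    background_reflectance: float = 0.02
    dark_level: float = 0.05
    noise_sigma_core: float = 0.005  # additive noise inside 425–1000 nm
    noise_sigma_edge: float = 0.025  # additive noise outside 425–1000 nm
    seed: int = 0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r}; expected one of {GRADES}")
        deltas = [self.depression[g] for g in GRADES]
        if deltas[0] != 0.0 or not np.all(np.diff(deltas) > 0):
            raise ValueError(
                "depression must be 0 for SOUND and strictly increasing with grade"
            )
        if self.noise_sigma_edge < self.noise_sigma_core:
            raise ValueError("noise_sigma_edge must be >= noise_sigma_core")

    @property
    def delta(self) -> float:
        if self.grade == "SOUND":
            return 0.0
        if self.delta_override is not None:
            return float(self.delta_override)
        return float(self.depression[self.grade])


@dataclass
class PhantomTruth:
    """Ground truth for one phantom: masks, grade and the noise-free cube."""

    bruise_mask: np.ndarray
    fruit_mask: np.ndarray
    grade: str
    clean_cube: HyperspectralCube  # shaded reflectance (what calibration recovers)

    def __post_init__(self) -> None:
        if np.any(self.bruise_mask & ~self.fruit_mask):
            raise ValueError("bruise mask escapes fruit mask")
        if (self.grade == "SOUND") != (not self.bruise_mask.any()):
            raise ValueError("grade SOUND must coincide with an empty bruise mask")


def _grids(config: PhantomConfig):
    r = np.arange(config.rows, dtype=float)[:, None]
    c = np.arange(config.cols, dtype=float)[None, :]
    return r, c


def _fruit_geometry(config: PhantomConfig):
    r, c = _grids(config)
    r0, c0 = config.fruit_center or ((config.rows - 1) / 2.0, (config.cols - 1) / 2.0)
    a, b = config.fruit_axes
    rho2 = ((r - r0) / a) ** 2 + ((c - c0) / b) ** 2
    return (r0, c0), rho2


def generate_phantom(
    config: PhantomConfig,
) -> tuple[HyperspectralCube, CalibrationFrames, PhantomTruth]:
    """Render one raw phantom cube plus calibration frames and ground truth.

    The raw signal model is ``lamp(r,c) · refl(r,c,λ) + dark + noise`` with
    ``refl = shading(r,c) · base_spectrum(λ) · bruise_factor(λ)`` on the fruit
    and a small constant background reflectance elsewhere.  The white frame is
    ``lamp · 1 + dark``, so calibrating the raw cube with the emitted frames
    recovers the shaded reflectance (stored as ``truth.clean_cube``) up to
    noise.  Fully deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    wl = config.wavelengths
    rows, cols = config.rows, config.cols

    (fr0, fc0), rho2 = _fruit_geometry(config)
    fruit = rho2 <= 1.0

    delta = config.delta
    if delta > 0:
        br0, bc0 = config.bruise_center or (fr0 - 10.0, fc0 + 12.0)
        r, c = _grids(config)
        bruise = (r - br0) ** 2 + (c - bc0) ** 2 <= config.bruise_radius**2
        if np.any(bruise & ~fruit):
            raise ValueError("bruise disc escapes the fruit ellipse")
    else:
        bruise = np.zeros((rows, cols), dtype=bool)

    # spectral factors
    base = base_spectrum(wl)
    g_nir = np.exp(-(((wl - config.depression_center_nm) / config.depression_width_nm) ** 2))
    g_vis = np.exp(-(((wl - config.vis_center_nm) / config.vis_width_nm) ** 2))
    bruise_factor = 1.0 - delta * g_nir - config.vis_fraction * delta * g_vis

    # curvature shading: dome over the fruit, 1 off-fruit
    shading = np.where(fruit, 1.0 - config.shading_amplitude * rho2, 1.0)

    refl = np.empty((rows, cols, len(wl)), dtype=np.float32)
    refl[:] = config.background_reflectance
    refl[fruit, :] = (shading[fruit, None] * base[None, :]).astype(np.float32)
    refl[bruise, :] = (shading[bruise, None] * (base * bruise_factor)[None, :]).astype(
        np.float32
    )
    clean = HyperspectralCube(refl.copy(), wl.copy(), {"grade": config.grade})

    # lamp field: planar gradient x radial vignette, strictly positive
    r, c = _grids(config)
    gx = np.cos(config.illum_angle) * config.illum_gradient
    gy = np.sin(config.illum_angle) * config.illum_gradient
    plane = 1.0 + gx * (c / cols - 0.5) + gy * (r / rows - 0.5)
    d2 = ((r - (rows - 1) / 2) / rows) ** 2 + ((c - (cols - 1) / 2) / cols) ** 2
    lamp = config.white_scale * plane * (1.0 - 0.5 * config.illum_gradient * d2)
    if np.any(lamp <= 0):
        raise ValueError("lamp field not strictly positive; reduce illum_gradient")

    sigma = np.where(
        (wl < 425.0) | (wl > 1000.0), config.noise_sigma_edge, config.noise_sigma_core
    )
    noise = rng.standard_normal((rows, cols, len(wl))) * sigma

    dark = np.full(len(wl), config.dark_level)
    raw = (lamp[:, :, None] * refl + dark + noise).astype(np.float32)
    white = (lamp[:, :, None] + dark).astype(np.float32)  # lamp · 1 + dark

    cube = HyperspectralCube(raw, wl.copy(), {"grade": config.grade, "seed": config.seed})
    frames = CalibrationFrames(white=white, dark=dark)
    truth = PhantomTruth(bruise, fruit, config.grade, clean)
    return cube, frames, truth


def _jittered_config(template: PhantomConfig, grade: str, seed_seq: np.random.SeedSequence) -> PhantomConfig:
    rng = np.random.default_rng(seed_seq)
    a = template.fruit_axes[0] * rng.uniform(0.9, 1.1)
    b = template.fruit_axes[1] * rng.uniform(0.9, 1.1)
    radius = rng.uniform(9.0, 15.0)
    fr0 = (template.rows - 1) / 2.0
    fc0 = (template.cols - 1) / 2.0
    # place the bruise center inside the ellipse shrunk by the disc radius
    theta = rng.uniform(0, 2 * np.pi)
    frac = rng.uniform(0.0, 0.55)
    br0 = fr0 + frac * (a - radius - 3.0) * np.cos(theta)
    bc0 = fc0 + frac * (b - radius - 3.0) * np.sin(theta)
    delta = None
    if grade != "SOUND":
        d0 = template.depression[grade]
        delta = float(
            np.clip(d0 + rng.normal(0.0, DELTA_JITTER_SD), 0.5 * d0, 1.5 * d0)
        )
    return replace(
        template,
        fruit_center=(fr0, fc0),
        fruit_axes=(a, b),
        bruise_center=(br0, bc0),
        bruise_radius=radius,
        grade=grade,
        delta_override=delta,
        illum_gradient=rng.uniform(0.10, 0.25),
        illum_angle=rng.uniform(0, 2 * np.pi),
        shading_amplitude=rng.uniform(0.18, 0.30),
        white_scale=rng.uniform(0.9, 1.1),
        seed=int(seed_seq.generate_state(1, dtype=np.uint32)[0] % (2**31)),
    )


def iter_dataset(
    n_per_grade: int | Mapping[str, int],
    template: PhantomConfig | None = None,
    seed: int = 0,
) -> Iterator[tuple[str, HyperspectralCube, CalibrationFrames, PhantomTruth]]:
    """Stream a jittered phantom cohort, one sample at a time.

    ``n_per_grade`` is either a single count applied to all five grades or a
    mapping from grade label to count (grades absent from the mapping are
    skipped).  Samples are yielded grouped by grade, each with an id like
    ``"II_03"``.  Per-sample fruit size, bruise position/radius, illumination,
    exposure and δ are jittered with independent sub-seeds spawned from the
    master seed, so the same seed always reproduces the same cohort.
    """
    template = template or PhantomConfig()
    if isinstance(n_per_grade, Mapping):
        counts = {g: int(n_per_grade.get(g, 0)) for g in GRADES}
    else:
        counts = {g: int(n_per_grade) for g in GRADES}
    master = np.random.SeedSequence(seed)
    children = iter(master.spawn(sum(counts.values())))
    for grade in GRADES:
        for i in range(counts[grade]):
            cfg = _jittered_config(template, grade, next(children))
            cube, frames, truth = generate_phantom(cfg)
            yield f"{grade}_{i:03d}", cube, frames, truth


def generate_dataset(
    n_per_grade: int | Mapping[str, int],
    template: PhantomConfig | None = None,
    seed: int = 0,
) -> list[tuple[str, HyperspectralCube, CalibrationFrames, PhantomTruth]]:
    """Materialize :func:`iter_dataset` as a list (small cohorts only)."""
    return list(iter_dataset(n_per_grade, template, seed))
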