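import numpy as np
import pytest

import hsibruise as hb


def _prepared(grade: str, seed: int):
    """Phantom + calibrated reflectance + detected fruit mask."""
    cube, frames, truth = hb.generate_phantom(hb.PhantomConfig(grade=grade, seed=seed))
    refl = hb.calibrate(cube, frames)
    fruit = hb.make_fruit_mask(refl)
    return {"raw": cube, "frames": frames, "truth": truth, "refl": refl, "fruit": fruit}


@pytest.fixture(scope="session")
def sound_sample():
    return _prepared("SOUND", seed=21)


@pytest.fixture(scope="session")
def grade1_sample():
    return _prepared("I", seed=22)


@pytest.fixture(scope="session")
def grade4_sample():
    return _prepared("IV", seed=23)


@pytest.fixture(scope="session")
def graded_clean_cubes():
    """One clean (noise-free) truth cube per grade, default geometry."""
    out = {}
    for i, grade in enumerate(hb.GRADES):
        _, _, truth = hb.generate_phantom(hb.PhantomConfig(grade=grade, seed=31 + i))
        out[grade] = truth
    return out


@pytest.fixture(scope="session")
def small_cube():
    """Tiny deterministic cube for I/O and spectral-arithmetic tests."""
    rng = np.random.default_rng(5)
    wl = np.linspace(400.0, 1000.0, 25)
    data = rng.uniform(0.1, 0.9, size=(8, 9, 25)).astype(np.float32)
    return hb.HyperspectralCube(data, wl, {"description": "toy cube"})
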