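"""Ratio images, quantization, GLCM / Haralick statistics and MAM features."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import hsibruise as hb
from hsibruise.pca import BandSelection
from hsibruise.segment import BRUISED, SegmentationResult
from hsibruise.texture import (
    DIRECTIONS,
    GLCMParams,
    band_ratio,
    glcm,
    haralick,
    mam_features,
    quantize,
)


def _cube(arrays, wavelengths):
    data = np.stack(arrays, axis=-1).astype(float)
    return hb.HyperspectralCube(data, np.asarray(wavelengths, dtype=float))


def _seg(mask):
    return SegmentationResult(mask, np.zeros_like(mask), int(mask.sum()), BRUISED)


class TestBandRatio:
    def test_identity_and_substitution(self):
        full = hb.FruitMask(np.ones((4, 4), dtype=bool))
        same = _cube([np.full((4, 4), 3.0)] * 2, [700, 900])
        np.testing.assert_allclose(band_ratio(same, 700, 900, full).values, 1.0)
        two_four = _cube([np.full((4, 4), 2.0), np.full((4, 4), 4.0)], [700, 900])
        np.testing.assert_allclose(band_ratio(two_four, 700, 900, full).values, 0.5)

    def test_equal_wavelengths_rejected(self):
        cube = _cube([np.ones((3, 3))] * 2, [700, 900])
        with pytest.raises(ValueError):
            band_ratio(cube, 700, 700, hb.FruitMask(np.ones((3, 3), dtype=bool)))

    def test_exact_invariance_to_band_independent_illumination(self, grade4_sample):
        refl = grade4_sample["refl"]
        fruit = grade4_sample["fruit"]
        base = band_ratio(refl, 782.0, 999.3, fruit)
        field = np.random.default_rng(0).uniform(0.5, 2.0, refl.shape[:2])
        lit = hb.HyperspectralCube(
            refl.data * field[:, :, None], refl.wavelengths
        )
        again = band_ratio(lit, 782.0, 999.3, fruit)
        np.testing.assert_array_equal(base.valid_mask, again.valid_mask)
        # invariance is exact in real arithmetic; floats agree to a few ulps
        np.testing.assert_allclose(again.values, base.values, rtol=1e-12, atol=0)

    def test_ratio_flattens_illumination_on_phantom(self, grade4_sample):
        # mirrors the motivation for ratio imaging: the curvature shading that
        # survives calibration cancels in K_a/b, so the sound region is far
        # more uniform in the ratio image than in either band alone
        refl, truth = grade4_sample["refl"], grade4_sample["truth"]
        sound = truth.fruit_mask & ~truth.bruise_mask
        ratio = band_ratio(refl, 782.0, 999.3, hb.FruitMask(truth.fruit_mask))
        ja = refl.data[:, :, hb.nearest_band(refl, 782.0)]
        cov = lambda v: v.std() / abs(v.mean())
        assert cov(ratio.values[sound]) < cov(ja[sound])

    def test_denominator_guard_reported(self):
        ja = np.ones((3, 3))
        jb = np.ones((3, 3))
        jb[0, 0] = 0.0
        cube = _cube([ja, jb], [700, 900])
        r = band_ratio(cube, 700, 900, hb.FruitMask(np.ones((3, 3), dtype=bool)))
        assert r.n_guarded == 1 and not r.valid_mask[0, 0]
        assert np.all(np.isfinite(r.values))


class TestQuantize:
    def test_two_level_and_constant(self):
        img = np.array([[0.0, 1.0], [1.0, 0.0]])
        mask = np.ones((2, 2), dtype=bool)
        q = quantize(img, mask, 2)
        assert set(q.ravel()) == {1, 2}
        qc = quantize(np.full((2, 2), 5.0), mask, 8)
        assert np.all(qc == 1)

    def test_ramp_matches_explicit_bin_edges(self):
        img = np.linspace(0.0, 1.0, 64).reshape(8, 8)
        mask = np.ones((8, 8), dtype=bool)
        q = quantize(img, mask, 8)
        # oracle: explicit bin-edge computation on [min, max]
        edges = np.linspace(0.0, 1.0, 9)
        expected = np.digitize(img.ravel(), edges[1:-1], right=False) + 1
        np.testing.assert_array_equal(q.ravel(), expected)


class TestGlcm:
    def test_checkerboard_horizontal_all_off_diagonal(self):
        q = np.array([[1, 2], [2, 1]])
        mask = np.ones((2, 2), dtype=bool)
        P = glcm(q, mask, "0", levels=2)
        assert P[0, 0] == 0 and P[1, 1] == 0
        assert P[0, 1] == pytest.approx(0.5) and P[1, 0] == pytest.approx(0.5)

    def test_symmetric_and_normalized(self):
        rng = np.random.default_rng(3)
        q = rng.integers(1, 9, size=(12, 12))
        mask = rng.random((12, 12)) > 0.2
        for d in DIRECTIONS:
            P = glcm(q, mask, d, levels=8)
            np.testing.assert_allclose(P, P.T, atol=0)
            assert P.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("direction", list(DIRECTIONS))
    def test_matches_double_loop_pair_counting_oracle(self, direction):
        rng = np.random.default_rng(7)
        q = rng.integers(1, 5, size=(5, 5))
        mask = rng.random((5, 5)) > 0.15
        P = glcm(q, mask, direction, levels=4)
        dr, dc = DIRECTIONS[direction]
        counts = np.zeros((4, 4))
        for r in range(5):  # oracle: explicit pair enumeration, both offsets
            for c in range(5):
                for sr, sc in ((dr, dc), (-dr, -dc)):
                    rr, cc = r + sr, c + sc
                    if 0 <= rr < 5 and 0 <= cc < 5 and mask[r, c] and mask[rr, cc]:
                        counts[q[r, c] - 1, q[rr, cc] - 1] += 1
        np.testing.assert_allclose(P, counts / counts.sum(), atol=1e-12)

    def test_no_valid_pair_rejected(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True  # isolated pixel: no neighbor pair
        with pytest.raises(ValueError):
            glcm(np.ones((3, 3), dtype=int), mask, "0")


class TestHaralick:
    def test_degenerate_single_cell(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0
        h = haralick(P)
        assert h["energy"] == 1.0 and h["entropy"] == 0.0
        assert h["contrast"] == 0.0 and h["idm"] == 1.0
        assert h["correlation"] == 0.0  # degenerate marginals

    def test_uniform_closed_form(self):
        G = 8
        h = haralick(np.full((G, G), 1.0 / G**2))
        assert h["energy"] == pytest.approx(1.0 / G**2)
        assert h["entropy"] == pytest.approx(2 * np.log2(G))

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(11)
        P = rng.random((4, 4))
        P = (P + P.T) / 2
        P /= P.sum()
        h = haralick(P)
        # oracle: naive double loops over all cells
        e = s = con = idm = 0.0
        mu_i = mu_j = 0.0
        for i in range(4):
            for j in range(4):
                p = P[i, j]
                e += p * p
                s -= p * np.log2(p) if p > 0 else 0.0
                con += (i - j) ** 2 * p
                idm += p / (1 + (i - j) ** 2)
                mu_i += i * p
                mu_j += j * p
        vi = sum((i - mu_i) ** 2 * P[i, j] for i in range(4) for j in range(4))
        vj = sum((j - mu_j) ** 2 * P[i, j] for i in range(4) for j in range(4))
        corr = sum(
            (i - mu_i) * (j - mu_j) * P[i, j] for i in range(4) for j in range(4)
        ) / np.sqrt(vi * vj)
        assert h["energy"] == pytest.approx(e)
        assert h["entropy"] == pytest.approx(s)
        assert h["contrast"] == pytest.approx(con)
        assert h["idm"] == pytest.approx(idm)
        assert h["correlation"] == pytest.approx(corr)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            haralick(np.full((3, 3), 1.0))

    def test_shift_invariance_via_quantization(self):
        rng = np.random.default_rng(13)
        img = rng.random((10, 10))
        mask = np.ones((10, 10), dtype=bool)
        q1 = quantize(img, mask, 16)
        q2 = quantize(img + 3.7, mask, 16)  # min-max binning absorbs shifts
        np.testing.assert_array_equal(q1, q2)


class TestMamFeatures:
    def _bands(self, wl):
        return BandSelection(
            wavelengths_nm=np.asarray(wl, dtype=float),
            indices=np.arange(3),
            source_pc=1,
        )

    def test_constant_cube(self):
        data = np.full((20, 20, 4), 0.6)
        cube = hb.HyperspectralCube(data, [700.0, 800.0, 900.0, 1000.0])
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        fv = mam_features(
            cube, _seg(mask), self._bands([700, 800, 1000]),
            hb.FruitMask(np.ones((20, 20), dtype=bool)),
        )
        np.testing.assert_allclose(fv.spectra, 0.6)
        assert fv.mean_gray == pytest.approx(1.0)
        for d in DIRECTIONS:
            assert fv.texture[d]["contrast"] == 0.0

    def test_vector_layout_and_round_trip(self, grade4_sample):
        refl, fruit, truth = (
            grade4_sample["refl"],
            grade4_sample["fruit"],
            grade4_sample["truth"],
        )
        fv = mam_features(
            refl, _seg(truth.bruise_mask), self._bands([782, 944.3, 999.3]), fruit
        )
        arr = fv.to_array()
        assert arr.shape == (24,) and np.all(np.isfinite(arr))
        names = fv.names()
        assert len(names) == 24 and names[3] == "mean_gray"
        assert names[4:9] == [f"{s}_0" for s in
                              ("energy", "entropy", "contrast", "correlation", "idm")]

    def test_spectra_match_masked_mean_oracle(self, grade4_sample):
        refl, fruit, truth = (
            grade4_sample["refl"],
            grade4_sample["fruit"],
            grade4_sample["truth"],
        )
        fv = mam_features(
            refl, _seg(truth.bruise_mask), self._bands([782, 944.3, 999.3]), fruit
        )
        for k, w in enumerate((782.0, 944.3, 999.3)):
            total, n = 0.0, 0  # explicit per-pixel loop oracle
            band = hb.nearest_band(refl, w)
            rows, cols = np.nonzero(truth.bruise_mask)
            for r, c in zip(rows, cols):
                total += refl.data[r, c, band]
                n += 1
            assert fv.spectra[k] == pytest.approx(total / n, rel=1e-6)

    def test_requires_bruised_verdict(self, grade4_sample):
        seg = SegmentationResult(
            np.zeros((120, 120), dtype=bool), np.zeros((120, 120), dtype=bool), 0, "NORMAL"
        )
        with pytest.raises(ValueError, match="triage"):
            mam_features(
                grade4_sample["refl"], seg, self._bands([782, 944.3, 999.3])
            )

    def test_mean_gray_monotone_in_grade_on_clean_cubes(self, graded_clean_cubes):
        grades = ("I", "II", "III", "IV")
        gray = []
        for g in grades:
            truth = graded_clean_cubes[g]
            ratio = band_ratio(
                truth.clean_cube, 782.0, 999.3, hb.FruitMask(truth.fruit_mask)
            )
            gray.append(ratio.values[truth.bruise_mask].mean())
        rho, _ = spearmanr(np.arange(4), gray)
        assert abs(rho) == 1.0
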