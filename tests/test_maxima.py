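"""Maxima detection (prominence semantics) and linescan FWHM sizing with QC."""

import math

import numpy as np
import pytest
from scipy import ndimage

from memcrowd import (
    Image2D,
    PointPattern,
    RegionOfInterest,
    RenderSpec,
    find_maxima,
    fit_linescan,
    gen_csr,
    maxima_density,
    maxima_size,
    render_image,
)

PX = 25.0
EIGHT = np.ones((3, 3))


def _image(arr):
    return Image2D(np.asarray(arr, dtype=float), PX)


def brute_force_maxima(values, prominence):
    """Independent exhaustive prominence scan (threshold descent).

    For every plateau that is a local maximum, the saddle is the highest
    threshold at which the connected component of {pixels >= t} containing
    the plateau also contains a strictly higher pixel.
    """
    values = np.asarray(values, dtype=float)
    uniq = np.unique(values)[::-1]
    vmin = values.min()
    results = []
    for v in uniq:
        labelled, n = ndimage.label(values == v, structure=EIGHT)
        for i in range(1, n + 1):
            region = labelled == i
            ring = ndimage.binary_dilation(region, structure=EIGHT) & ~region
            if ring.any() and (values[ring] > v).any():
                continue  # not a local maximum plateau
            prom = v - vmin
            for t in uniq[uniq < v]:
                comp, _ = ndimage.label(values >= t, structure=EIGHT)
                comp_id = comp[region].max()
                if (values[comp == comp_id] > v).any():
                    prom = v - t
                    break
            if prom >= prominence:
                rows, cols = np.nonzero(region)
                results.append((rows.mean(), cols.mean(), v))
    return results


class TestFindMaxima:
    def test_isolated_impulse(self):
        arr = np.zeros((9, 9))
        arr[4, 6] = 10.0
        pat = find_maxima(_image(arr), prominence=5.0)
        assert len(pat) == 1
        np.testing.assert_allclose(pat.points[0], [(6 + 0.5) * PX, (4 + 0.5) * PX])

    def test_well_separated_spots(self):
        img = np.zeros((64, 64))
        yy, xx = np.mgrid[:64, :64]
        for cy, cx in [(16, 16), (48, 48)]:  # 10 sigma apart for sigma ~ 2.3 px
            img += 100.0 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.3**2))
        pat = find_maxima(_image(img), prominence=50.0)
        assert len(pat) == 2
        got = sorted(map(tuple, np.round(pat.points / PX - 0.5)))
        assert got == [(16.0, 16.0), (48.0, 48.0)]

    def test_plateau_centroid(self):
        arr = np.zeros((8, 8))
        arr[3:5, 3:5] = 7.0  # 2x2 plateau
        pat = find_maxima(_image(arr), prominence=2.0)
        assert len(pat) == 1
        np.testing.assert_allclose(pat.points[0], [4.0 * PX, 4.0 * PX])

    def test_nonpositive_prominence_rejected(self, random_image):
        with pytest.raises(ValueError):
            find_maxima(random_image, prominence=0.0)

    def test_translation_equivariant_and_offset_invariant(self):
        rng = np.random.default_rng(8)
        base = np.zeros((40, 40))
        base[8:32, 8:32] = rng.integers(0, 10, size=(24, 24)).astype(float)
        p1 = find_maxima(_image(base), prominence=3.0)
        shifted = np.roll(base, (2, 5), axis=(0, 1))
        p2 = find_maxima(_image(shifted + 11.0), prominence=3.0)
        assert len(p1) == len(p2)
        moved = p1.points + np.array([5 * PX, 2 * PX])
        np.testing.assert_allclose(
            np.sort(moved, axis=0), np.sort(p2.points, axis=0), atol=1e-9
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("prominence", [2.0, 4.0])
    def test_matches_exhaustive_prominence_scan(self, seed, prominence):
        # distinct pixel values so the prominence of every peak is unambiguous
        # (tie/plateau conventions are exercised by the dedicated tests above)
        rng = np.random.default_rng(seed)
        arr = rng.integers(0, 12, size=(16, 16)).astype(float)
        arr += rng.permutation(arr.size).reshape(arr.shape) / (10.0 * arr.size)
        expected = brute_force_maxima(arr, prominence)
        pat = find_maxima(_image(arr), prominence=prominence)
        assert len(pat) == len(expected)
        exp_pts = np.array([[(c + 0.5) * PX, (r + 0.5) * PX] for r, c, _ in expected])
        got = pat.points[np.lexsort(pat.points.T)]
        want = exp_pts[np.lexsort(exp_pts.T)]
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_detected_count_matches_planted_at_low_density(self):
        # lambda = 3 per um^2, isolated 80 nm spots, fixed seed
        extra = math.sqrt(80.0**2 - 65.0**2) / 2.3548
        planted = gen_csr(3.0, (10000.0, 10000.0), seed=21)
        img = render_image(
            planted, RenderSpec(intensity_per_molecule=1000.0), extra_sigma_nm=extra, seed=22
        )
        pat = find_maxima(img)
        assert abs(len(pat) - len(planted)) / len(planted) <= 0.05


class TestFitLinescan:
    def _profile_image(self, amp, mu, sigma, offset):
        """Embed a horizontal Gaussian ridge so every linescan row is the profile."""
        x = np.arange(61, dtype=float)
        profile = amp * np.exp(-((x - mu) ** 2) / (2 * sigma**2)) + offset
        return Image2D(np.tile(profile, (61, 1)), PX)

    def test_recovers_own_model_exactly(self):
        img = self._profile_image(100.0, 30.0, 3.0, 0.0)
        fit = fit_linescan(img, ((30 + 0.5) * PX, (30 + 0.5) * PX), orientation="horizontal")
        assert fit.amplitude == pytest.approx(100.0, abs=1e-6)
        assert fit.centre_px == pytest.approx(15.0, abs=1e-6)  # centred in the scan
        assert fit.sigma_px == pytest.approx(3.0, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.fwhm_nm == pytest.approx(2 * math.sqrt(2 * math.log(2)) * 3.0 * PX, rel=1e-6)
        assert fit.qc_pass

    def test_off_centre_peak_fails_qc(self):
        # the scan covers columns 15..45, so an image peak at column 18 sits
        # at profile position 3, outside the middle third [10, 20]
        img = self._profile_image(100.0, 18.0, 3.0, 0.0)
        fit = fit_linescan(img, ((30 + 0.5) * PX, (30 + 0.5) * PX), orientation="horizontal")
        assert fit.centre_px == pytest.approx(3.0, abs=1e-3)
        assert not fit.qc_pass
        assert fit.reason == "non-centred peak"

    def test_low_r2_fails_qc(self):
        rng = np.random.default_rng(0)
        x = np.arange(61, dtype=float)
        profile = 10.0 * np.exp(-((x - 30.0) ** 2) / 18.0) + rng.normal(0, 6.0, 61)
        img = Image2D(np.tile(profile, (61, 1)), PX)
        fit = fit_linescan(img, ((30 + 0.5) * PX, (30 + 0.5) * PX), orientation="horizontal")
        assert fit.r2 < 0.8
        assert not fit.qc_pass
        assert fit.reason == "R2 below 0.8"

    def test_out_of_bounds_fails_qc_without_raising(self):
        img = Image2D(np.ones((61, 61)), PX)
        fit = fit_linescan(img, (2 * PX, 30 * PX), orientation="horizontal")
        assert not fit.qc_pass
        assert fit.reason == "out-of-bounds"


class TestMaximaSize:
    @pytest.mark.parametrize("fwhm_nm", [60.0, 80.0, 120.0, 160.0, 200.0])
    def test_round_trip_sizing(self, fwhm_nm):
        extra = (
            math.sqrt(max(fwhm_nm**2 - 65.0**2, 0.0)) / 2.3548 if fwhm_nm > 65 else 0.0
        )
        target = math.hypot(65.0, 2.3548 * extra)
        pts = PointPattern(np.array([[1500.0, 1500.0]]), (3000.0, 3000.0))
        img = render_image(pts, RenderSpec(noise=False), extra_sigma_nm=extra)
        pat = find_maxima(img, prominence=img.pixels.max() / 2)
        mean_size, table = maxima_size(img, pat)
        assert len(table) == 1
        assert mean_size == pytest.approx(target, rel=0.05)

    def test_best_orientation_selected(self):
        # anisotropic spot: clean Gaussian horizontally, distorted vertically
        x = np.arange(61, dtype=float)
        profile = 100.0 * np.exp(-((x - 30.0) ** 2) / (2 * 3.0**2))
        img = np.tile(profile, (61, 1))
        rng = np.random.default_rng(4)
        img += rng.normal(0, 1.0, img.shape) * np.abs(np.arange(61) - 30)[:, None] / 10
        image = Image2D(np.clip(img, 0, None), PX)
        pat = PointPattern(np.array([[(30 + 0.5) * PX, (30 + 0.5) * PX]]), (61 * PX, 61 * PX))
        _, table = maxima_size(image, pat)
        assert table.loc[0, "orientation"] == "horizontal"

    def test_all_failing_qc_gives_nan(self):
        img = Image2D(np.ones((61, 61)), PX)
        pat = PointPattern(np.array([[30 * PX, 30 * PX]]), (61 * PX, 61 * PX))
        mean_size, table = maxima_size(img, pat)
        assert math.isnan(mean_size)
        assert not table["qc_pass"].any()


class TestMaximaDensity:
    def test_forced_arithmetic(self):
        img = Image2D(np.ones((80, 80)), PX)  # 2 um x 2 um = 4 um^2
        roi = RegionOfInterest.full(img)
        pts = np.column_stack([np.linspace(100, 1900, 44), np.linspace(100, 1900, 44)])
        pat = PointPattern(pts, (2000.0, 2000.0))
        assert maxima_density(pat, roi) == pytest.approx(11.0)

    def test_zero_maxima(self):
        img = Image2D(np.ones((80, 80)), PX)
        pat = PointPattern(np.empty((0, 2)), (2000.0, 2000.0))
        assert maxima_density(pat, RegionOfInterest.full(img)) == 0.0

    def test_csr_density_estimate_within_3_se(self):
        lam, area = 11.0, 100.0  # per um^2, um^2
        pat = gen_csr(lam, (10000.0, 10000.0), seed=17)
        img = Image2D(np.ones((400, 400)), PX)
        est = maxima_density(pat, RegionOfInterest.full(img))
        se = math.sqrt(lam / area)
        assert abs(est - lam) <= 3 * se
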