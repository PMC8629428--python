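"""Ground-truth generators, PSF rendering, and the label-physics distortions."""

import math

import numpy as np
import pytest
from scipy import stats

from memcrowd import (
    PointPattern,
    RegionOfInterest,
    RenderSpec,
    SceneSpec,
    apply_quenching,
    apply_shielding,
    csr_nn_cdf,
    find_maxima,
    gen_clustered,
    gen_coupled_crowds,
    gen_csr,
    linear_fit,
    maxima_size,
    nn_distances,
    render_image,
    roi_mean_intensity,
    segment_sheets,
    sheet_intensity_table,
    simulate_scene,
)

WIN = (10000.0, 10000.0)


class TestGenCsr:
    def test_poisson_count(self):
        pat = gen_csr(10.0, WIN, seed=0)
        assert abs(len(pat) - 1000) <= 3 * math.sqrt(1000)

    def test_zero_density_empty(self):
        assert len(gen_csr(0.0, WIN, seed=0)) == 0

    def test_deterministic_under_seed(self):
        a = gen_csr(10.0, WIN, seed=5)
        b = gen_csr(10.0, WIN, seed=5)
        np.testing.assert_array_equal(a.points, b.points)


class TestGenClustered:
    def test_degenerate_cluster_molecules_coincide_with_centres(self):
        spec = SceneSpec(molecules_per_cluster=1, cluster_sigma_nm=0.0, seed=3)
        centres, mols = gen_clustered(spec)
        np.testing.assert_allclose(
            np.sort(mols.points, axis=0), np.sort(centres.points, axis=0)
        )

    def test_expected_molecule_count(self):
        spec = SceneSpec(seed=4)
        centres, mols = gen_clustered(spec)
        expected = len(centres) * spec.molecules_per_cluster
        # some offspring fall off the window edge
        assert 0.97 * expected <= len(mols) <= expected

    def test_rendered_cluster_size_matches_convolution_law(self):
        # measured FWHM ~ sqrt(psf^2 + (2.355 sigma_cluster)^2)
        spec = SceneSpec(
            window_um=(2.0, 2.0),
            cluster_density_per_um2=0.5,
            cluster_sigma_nm=20.0,
            molecules_per_cluster=3000,  # dense enough to render a smooth blob
            seed=8,
        )
        centres, mols = gen_clustered(spec)
        render = RenderSpec(noise=False, intensity_per_molecule=1.0)
        img = render_image(mols, render)
        pat = find_maxima(img, prominence=img.pixels.max() / 3)
        mean_size, _ = maxima_size(img, pat)
        expected = math.hypot(65.0, 2.3548 * spec.cluster_sigma_nm)
        assert mean_size == pytest.approx(expected, rel=0.10)


class TestGenCoupledCrowds:
    def test_uncoupled_crowds_are_csr(self):
        spec = SceneSpec(window_um=(20.0, 20.0), crowd_density_per_um2=25.0,
                         coupling_p=0.0, seed=10)
        centres, _ = gen_clustered(spec)
        crowds = gen_coupled_crowds(centres, spec)
        d = nn_distances(crowds, margin_nm=500.0)
        ks = stats.kstest(d, lambda r: csr_nn_cdf(crowds.density_per_um2, r))
        assert ks.statistic < 0.02

    def test_full_coupling_zero_distance_coincides(self):
        spec = SceneSpec(coupling_p=1.0, binding_distance_nm=0.0, seed=11)
        centres, _ = gen_clustered(spec)
        crowds = gen_coupled_crowds(centres, spec)
        d = nn_distances(crowds, centres)
        np.testing.assert_allclose(d, 0.0, atol=1e-9)

    def test_full_coupling_concentrates_at_binding_distance(self):
        spec = SceneSpec(coupling_p=1.0, binding_distance_nm=100.0, seed=12)
        centres, _ = gen_clustered(spec)
        crowds = gen_coupled_crowds(centres, spec)
        d = nn_distances(crowds, centres)
        assert np.median(d) <= 100.0 + 1e-9  # nearest cluster can only be closer
        assert (d <= 100.0 + 1e-9).mean() > 0.99

    def test_coupling_without_clusters_rejected(self):
        spec = SceneSpec(coupling_p=0.5, seed=1)
        empty = PointPattern(np.empty((0, 2)), spec.window_nm)
        with pytest.raises(ValueError):
            gen_coupled_crowds(empty, spec)


class TestRenderImage:
    def test_integrated_intensity_per_molecule(self):
        pts = PointPattern(np.array([[1000.0, 1000.0]]), (2000.0, 2000.0))
        img = render_image(pts, RenderSpec(noise=False))
        assert img.pixels.sum() == pytest.approx(10.0, abs=1e-3)

    def test_round_trip_psf_size(self):
        pts = PointPattern(np.array([[1500.0, 1500.0]]), (3000.0, 3000.0))
        img = render_image(pts, RenderSpec(noise=False))
        pat = find_maxima(img, prominence=img.pixels.max() / 2)
        mean_size, _ = maxima_size(img, pat)
        assert mean_size == pytest.approx(65.0, rel=0.05)

    def test_no_molecules_no_noise_all_zero(self):
        pts = PointPattern(np.empty((0, 2)), (2000.0, 2000.0))
        img = render_image(pts, RenderSpec(noise=False))
        assert not img.pixels.any()

    def test_noise_deterministic_under_seed(self):
        pts = PointPattern(np.array([[500.0, 500.0]]), (1000.0, 1000.0))
        a = render_image(pts, RenderSpec(), seed=3)
        b = render_image(pts, RenderSpec(), seed=3)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestQuenching:
    def _pair(self, gap_nm):
        return PointPattern(
            np.array([[100.0, 100.0], [100.0 + gap_nm, 100.0]]), (1000.0, 1000.0)
        )

    def test_zero_q_unchanged(self):
        out = apply_quenching(self._pair(3.0), np.array([5.0, 5.0]), 0.0)
        np.testing.assert_array_equal(out, [5.0, 5.0])

    def test_total_quenching_of_close_pair(self):
        out = apply_quenching(self._pair(3.0), np.array([5.0, 5.0]), 1.0, 5.0)
        np.testing.assert_array_equal(out, [0.0, 0.0])

    def test_distant_pair_untouched(self):
        out = apply_quenching(self._pair(50.0), np.array([5.0, 5.0]), 1.0, 5.0)
        np.testing.assert_array_equal(out, [5.0, 5.0])

    def test_total_intensity_non_increasing_in_density(self):
        totals = []
        for density in (50.0, 200.0, 800.0):
            pat = gen_csr(density, (3000.0, 3000.0), seed=21)
            intens = np.ones(len(pat))
            out = apply_quenching(pat, intens, 0.5, quench_radius_nm=30.0)
            totals.append(out.sum() / len(pat))  # per-molecule mean emission
        assert totals[0] > totals[1] > totals[2]

    def test_never_increases_intensity(self):
        pat = gen_csr(500.0, (2000.0, 2000.0), seed=2)
        intens = np.full(len(pat), 7.0)
        out = apply_quenching(pat, intens, 0.3, 20.0)
        assert np.all(out <= intens)


class TestShielding:
    def test_zero_p_all_survive(self):
        spec = SceneSpec(seed=5)
        centres, mols = gen_clustered(spec)
        out = apply_shielding(mols, centres, 0.0, 50.0, seed=1)
        assert len(out) == len(mols)

    def test_full_shielding_within_radius_empties_pattern(self):
        centres = PointPattern(np.array([[500.0, 500.0]]), (1000.0, 1000.0))
        labels = PointPattern(
            np.array([[490.0, 500.0], [510.0, 505.0]]), (1000.0, 1000.0)
        )
        out = apply_shielding(labels, centres, 1.0, 50.0, seed=1)
        assert len(out) == 0

    def test_never_increases_count(self):
        spec = SceneSpec(seed=6)
        centres, mols = gen_clustered(spec)
        out = apply_shielding(mols, centres, 0.4, 60.0, seed=2)
        assert len(out) <= len(mols)

    def test_shielding_lowers_label_vs_reference_regression_slope(self):
        # mimic the epitope-accessibility readout: the label channel dims
        # relative to the reference channel as shielding increases
        slopes = []
        for shield_p in (0.0, 0.4, 0.8):
            xs, ys = [], []
            for seed in range(6):
                spec = SceneSpec(window_um=(3.0, 3.0), seed=100 + seed)
                centres, mols = gen_clustered(spec)
                render = RenderSpec(noise=False)
                ref_img = render_image(mols, render)
                kept = apply_shielding(mols, centres, shield_p, 60.0, seed=200 + seed)
                lab_img = render_image(kept, render)
                xs.append(ref_img.pixels.mean())
                ys.append(lab_img.pixels.mean())
            slopes.append(linear_fit(xs, ys).slope)
        assert slopes[0] > slopes[1] > slopes[2]


class TestSceneEndToEnd:
    def test_scene_bit_reproducible(self):
        a = simulate_scene(SceneSpec(window_um=(2.0, 2.0), seed=9))
        b = simulate_scene(SceneSpec(window_um=(2.0, 2.0), seed=9))
        np.testing.assert_array_equal(a.image_clusters.pixels, b.image_clusters.pixels)
        np.testing.assert_array_equal(a.image_crowds.pixels, b.image_crowds.pixels)

    def test_coupling_increases_rsdm_pcc_and_shortens_cross_distances(self):
        from memcrowd import pcc

        rsdms, pccs, medians = [], [], []
        for coupling in (0.0, 0.5, 1.0):
            scene = simulate_scene(SceneSpec(window_um=(5.0, 5.0),
                                             coupling_p=coupling, seed=42))
            roi = RegionOfInterest.full(scene.image_crowds)
            rsdms.append(
                roi_mean_intensity(
                    scene.image_crowds, roi, scene.render.background_intensity
                ).rsdm
            )
            pccs.append(pcc(scene.image_clusters, scene.image_crowds, roi))
            clusters = find_maxima(scene.image_clusters)
            crowds = find_maxima(scene.image_crowds, presmooth_sigma_px=0.5)
            medians.append(float(np.median(nn_distances(crowds, clusters, 200.0))))
        assert rsdms[0] < rsdms[1] < rsdms[2]
        assert pccs[0] < pccs[1] < pccs[2]
        assert medians[0] > medians[1] > medians[2]
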