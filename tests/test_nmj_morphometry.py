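import numpy as np
import pytest
from skimage.draw import disk

from habit.errors import InvalidInputError, NoNmjDetectedError
from habit.nmj_morphometry import (
    MorphometryParams,
    NmjImage,
    count_boutons,
    measure_geometry,
    quantify_nmj,
    segment_nmj,
    skeletonize_and_graph,
)
from habit.synthetic_data import NmjSimConfig, generate_nmj_image, render_scene, sample_scene


class TestSegmentation:
    def test_noiseless_two_level_image_recovered_exactly(self):
        img = np.zeros((60, 80))
        img[20:30, 10:70] = 1.0
        mask = segment_nmj(img, MorphometryParams(smooth_sigma_px=0, min_area_um2=0.5), 0.5)
        np.testing.assert_array_equal(mask, img > 0.5)

    def test_small_second_component_removed(self):
        img = np.zeros((60, 80))
        img[20:30, 10:70] = 1.0
        img[50, 75] = 1.0  # one-pixel speck
        mask = segment_nmj(img, MorphometryParams(smooth_sigma_px=0), 0.5)
        assert not mask[50, 75] and mask[25, 40]

    def test_largest_component_kept(self):
        img = np.zeros((60, 80))
        img[5:10, 5:75] = 1.0   # 350 px
        img[40:55, 10:30] = 1.0  # 300 px
        mask = segment_nmj(img, MorphometryParams(smooth_sigma_px=0, min_area_um2=1.0), 0.5)
        assert mask[7, 40] and not mask[47, 20]

    def test_all_dark_image_raises(self):
        with pytest.raises(NoNmjDetectedError):
            segment_nmj(np.zeros((40, 40)), MorphometryParams(), 0.25)

    def test_noisy_mask_overlaps_ground_truth(self, rng):
        cfg = NmjSimConfig(seed=3)
        scene = sample_scene(cfg, np.random.default_rng(3))
        clean = render_scene(scene, cfg.pixel_size_um, cfg.shape, 0.0)
        truth = clean.membrane_channel > 0.5
        noisy = render_scene(scene, cfg.pixel_size_um, cfg.shape, 0.2, rng)  # SNR 5
        mask = segment_nmj(noisy.membrane_channel, MorphometryParams(), cfg.pixel_size_um)
        jaccard = (mask & truth).sum() / (mask | truth).sum()
        assert jaccard >= 0.95


class TestSkeletonGraph:
    def test_straight_bar_topology(self):
        bar = np.zeros((20, 120), bool)
        bar[8:13, 10:110] = True
        sg = skeletonize_and_graph(bar)
        assert sg.n_branching_points == 0
        assert sg.n_endpoints == 2
        assert sg.n_branches == 1

    def test_t_junction_topology(self):
        t = np.zeros((100, 100), bool)
        t[50:55, 10:90] = True
        t[10:50, 48:53] = True
        sg = skeletonize_and_graph(t)
        assert sg.n_branching_points == 1
        assert sg.n_endpoints == 3
        assert sg.n_branches == 3

    def test_single_pixel_degenerate_graph(self):
        m = np.zeros((10, 10), bool)
        m[5, 5] = True
        sg = skeletonize_and_graph(m)
        assert sg.graph.number_of_nodes() == 1
        assert sg.n_branches == 0
        assert sg.total_length_px == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(InvalidInputError):
            skeletonize_and_graph(np.zeros((5, 5), bool))

    def test_generated_side_branch_count_recovered(self):
        for seed in (0, 1):
            cfg = NmjSimConfig(seed=seed, n_side_branches=3, noise_sigma=0.0, n_boutons=0)
            image, truth = generate_nmj_image(cfg)
            mask = image.membrane_channel > 0.5
            sg = skeletonize_and_graph(mask, prune_spurs_px=4)
            assert sg.n_branching_points == truth.branching_points == 3
            assert sg.n_branches == truth.branches == 7


class TestGeometry:
    def test_straight_bar_length(self):
        bar = np.zeros((20, 120), bool)
        bar[8:13, 10:110] = True  # 100 px long
        sg = skeletonize_and_graph(bar)
        length, _, _ = measure_geometry(bar, sg, 0.5)
        # thinning shortens each end by roughly the tube half-width
        assert length == pytest.approx(50.0, abs=3.0)

    def test_filled_disk_area(self):
        m = np.zeros((60, 60), bool)
        rr, cc = disk((30, 30), 20)
        m[rr, cc] = True
        _, area, _ = measure_geometry(m, skeletonize_and_graph(m), 1.0)
        assert area == pytest.approx(np.pi * 20**2, rel=0.02)

    def test_square_perimeter(self):
        m = np.zeros((60, 60), bool)
        m[5:55, 5:55] = True
        _, _, perim = measure_geometry(m, skeletonize_and_graph(m), 1.0)
        # contour tracing cuts the four corners slightly
        assert perim == pytest.approx(4 * 50, abs=2.0)

    def test_area_scales_with_pixel_size(self):
        m = np.ones((10, 10), bool)
        sg = skeletonize_and_graph(m)
        _, area_1, _ = measure_geometry(m, sg, 1.0)
        _, area_2, _ = measure_geometry(m, sg, 0.5)
        assert area_1 == pytest.approx(4 * area_2)


class TestBoutonCounting:
    def _scene(self, n_boutons, spacing=20.0):
        cfg = NmjSimConfig(seed=5, n_boutons=n_boutons,
                           min_bouton_spacing_px=spacing, noise_sigma=0.0)
        image, truth = generate_nmj_image(cfg)
        return image, truth

    def test_blank_channel_counts_zero(self):
        image, _ = self._scene(0)
        mask = image.membrane_channel > 0.5
        assert count_boutons(np.zeros_like(mask, float), mask,
                             MorphometryParams(), 0.25) == 0

    def test_well_separated_disks_counted_exactly(self):
        image, truth = self._scene(10, spacing=20.0)
        mask = image.membrane_channel > 0.5
        n = count_boutons(image.vesicle_channel, mask, MorphometryParams(), 0.25)
        assert n == truth.boutons == 10

    def test_closer_than_min_distance_merges(self):
        # two unit disks 3 px apart with a 2 um (8 px) suppression radius
        img = np.zeros((60, 60))
        mask = np.zeros((60, 60), bool)
        for cx in (28, 33):
            rr, cc = disk((30, cx), 3)
            img[rr, cc] = 1.0
        mask[25:36, 20:42] = True
        params = MorphometryParams(bouton_min_distance_um=2.0)
        assert count_boutons(img, mask, params, 0.25) == 1


class TestQuantifyAndInvariances:
    def test_ground_truth_recovered_within_tolerances(self):
        image, truth = generate_nmj_image(NmjSimConfig(seed=11))
        res = quantify_nmj(image)
        assert res.boutons == truth.boutons
        assert res.branching_points == truth.branching_points
        assert res.branches == truth.branches
        assert res.length_um == pytest.approx(truth.length_um, rel=0.05)
        assert res.area_um2 == pytest.approx(truth.area_um2, rel=0.05)
        assert res.branching_points <= res.branches

    def test_all_dark_image_propagates_error(self):
        img = NmjImage(np.zeros((40, 40)), np.zeros((40, 40)), 0.25)
        with pytest.raises(NoNmjDetectedError):
            quantify_nmj(img)

    def test_rotation_and_flip_invariance(self):
        image, _ = generate_nmj_image(NmjSimConfig(seed=2))
        base = quantify_nmj(image)
        for op in (np.rot90, np.flipud, np.fliplr):
            tr = NmjImage(op(image.membrane_channel).copy(),
                          op(image.vesicle_channel).copy(), image.pixel_size_um)
            res = quantify_nmj(tr)
            assert res.boutons == base.boutons
            assert res.branches == base.branches
            assert res.branching_points == base.branching_points
            assert res.length_um == pytest.approx(base.length_um, rel=0.01)
            assert res.area_um2 == pytest.approx(base.area_um2, rel=0.01)
            assert res.perimeter_um == pytest.approx(base.perimeter_um, rel=0.01)

    def test_resolution_doubling_stability(self):
        # render the identical physical scene at two pixel sizes
        cfg = NmjSimConfig(seed=7, noise_sigma=0.0)
        scene = sample_scene(cfg, np.random.default_rng(7))
        params = MorphometryParams(threshold=0.5)
        coarse = quantify_nmj(
            render_scene(scene, 0.25, (320, 320)), params)
        fine = quantify_nmj(
            render_scene(scene, 0.125, (640, 640)), params)
        assert fine.boutons == coarse.boutons
        assert fine.branching_points == coarse.branching_points
        assert fine.length_um == pytest.approx(coarse.length_um, rel=0.03)
        assert fine.area_um2 == pytest.approx(coarse.area_um2, rel=0.03)
        assert fine.perimeter_um == pytest.approx(coarse.perimeter_um, rel=0.03)
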