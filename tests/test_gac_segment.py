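import numpy as np
import pytest

from histofuse.gac_segment import (DegenerateRegionError, GACConfig,
                                   LevelSetState, chan_vese_energy,
                                   contour_length, dice, evolve_step,
                                   extract_roi, init_level_set,
                                   postprocess_mask, region_means, segment)
from histofuse.imaging_io import RasterImage
from histofuse.synthetic import generate_disk_image


def two_level_image(shape=(16, 16), radius=5, fg=1.0, bg=0.0):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.hypot(yy - (h - 1) / 2, xx - (w - 1) / 2) < radius
    return RasterImage(pixels=np.where(mask, fg, bg)), mask


class TestInitLevelSet:
    def test_circle_signed_distance_values(self):
        cfg = GACConfig(radius=20.0)
        state = init_level_set((64, 64), cfg)
        assert state.phi[31, 31] == pytest.approx(20.0, abs=1.0)
        assert state.phi[0, 0] < 0

    def test_checkerboard_alternates_sign(self):
        state = init_level_set((32, 32), GACConfig(init="checkerboard",
                                                   checker_period=8))
        assert state.phi[4, 4] > 0
        assert state.phi[4, 12] < 0

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            init_level_set((32, 32), GACConfig(radius=40.0))

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            init_level_set((4, 4), GACConfig())

    def test_circle_contour_length_near_2_pi_r(self):
        """Marching-squares length of the zero level ~ circumference."""
        state = init_level_set((64, 64), GACConfig(radius=20.0))
        assert contour_length(state.phi) == pytest.approx(2 * np.pi * 20, rel=0.1)


class TestRegionMeans:
    def test_matched_partition_gives_zero_one(self):
        img, mask = two_level_image()
        state = LevelSetState(phi=np.where(mask, 1.0, -1.0))
        m1, m2 = region_means(img, state)
        assert (m1, m2) == (0.0, 1.0)

    def test_constant_image_gives_equal_means(self):
        img = RasterImage(pixels=np.full((16, 16), 0.3))
        state = init_level_set((16, 16), GACConfig(radius=5))
        m1, m2 = region_means(img, state)
        assert m1 == pytest.approx(0.3) and m2 == pytest.approx(0.3)

    def test_matches_per_pixel_accumulation_oracle(self, rng):
        img = RasterImage(pixels=rng.uniform(0, 1, size=(16, 16)))
        phi = rng.normal(size=(16, 16))
        state = LevelSetState(phi=phi)
        acc_in, n_in, acc_out, n_out = 0.0, 0, 0.0, 0
        for i in range(16):
            for j in range(16):
                if phi[i, j] > 0:
                    acc_in += img.pixels[i, j]; n_in += 1
                else:
                    acc_out += img.pixels[i, j]; n_out += 1
        m1, m2 = region_means(img, state)
        assert m1 == pytest.approx(acc_out / n_out, abs=1e-12)
        assert m2 == pytest.approx(acc_in / n_in, abs=1e-12)

    def test_empty_region_rejected(self):
        img = RasterImage(pixels=np.zeros((8, 8)))
        with pytest.raises(DegenerateRegionError):
            region_means(img, LevelSetState(phi=np.ones((8, 8))))


class TestEnergy:
    def test_perfect_partition_beta_zero_gives_zero(self):
        img, mask = two_level_image()
        state = LevelSetState(phi=np.where(mask, 1.0, -1.0))
        assert chan_vese_energy(img, state, beta=0.0) == pytest.approx(0.0, abs=1e-12)

    def test_beta_scales_pure_length_term(self):
        img, mask = two_level_image()
        state = LevelSetState(phi=np.where(mask, 1.0, -1.0))
        length = contour_length(state.phi)
        assert length > 0
        assert chan_vese_energy(img, state, beta=2.5) == pytest.approx(
            2.5 * length, abs=1e-10)

    def test_matches_direct_summation_oracle(self, rng):
        img = RasterImage(pixels=rng.uniform(0, 1, size=(8, 8)))
        phi = rng.normal(size=(8, 8))
        state = LevelSetState(phi=phi)
        inside = phi > 0
        m2 = img.pixels[inside].mean()
        m1 = img.pixels[~inside].mean()
        data = 0.0
        for i in range(8):
            for j in range(8):
                m = m2 if inside[i, j] else m1
                data += (img.pixels[i, j] - m) ** 2
        beta = 0.7
        expected = data + beta * contour_length(phi)
        assert chan_vese_energy(img, state, beta) == pytest.approx(expected, abs=1e-10)


class TestEvolveStep:
    def test_perfect_partition_is_fixed_point_of_sign_pattern(self):
        img, mask = two_level_image()
        phi = np.where(mask, 1.0, -1.0).astype(float)
        state = LevelSetState(phi=phi)
        new = evolve_step(img, state, GACConfig(beta=0.0))
        np.testing.assert_array_equal(new.inside, mask)
        assert new.iteration == 1

    def test_force_sign_moves_contour_toward_bright_region(self):
        """1-D profile: a contour inside a bright plateau must expand toward
        the plateau boundary (phi increases on bright pixels outside)."""
        profile = np.zeros((3, 16))
        profile[:, 6:14] = 1.0          # bright block
        img = RasterImage(pixels=profile)
        phi = -np.ones((3, 16))
        phi[:, 8:10] = 1.0              # contour strictly inside the block
        state = LevelSetState(phi=phi)
        new = evolve_step(img, state, GACConfig(beta=0.0, backtrack=False, dt=2.0))
        dphi = new.phi - phi
        assert dphi[1, 10] > 0          # bright pixel outside -> pulled inside
        assert dphi[1, 2] < 0           # dark pixel outside -> pushed out further

    def test_energy_trace_non_increasing_on_noisy_disks(self):
        for seed in range(5):
            img, _ = generate_disk_image(seed=seed)
            res = segment(img)
            trace = np.asarray(res.state.energy_trace)
            rel_increase = np.diff(trace) / np.maximum(np.abs(trace[:-1]), 1.0)
            assert np.all(rel_increase <= 1e-6)


class TestSegment:
    def test_noisy_disk_recovered_with_high_dice(self):
        img, truth = generate_disk_image(seed=3)
        res = segment(img)
        assert res.converged
        assert dice(res.mask, truth) >= 0.95

    def test_inverted_contrast_disk_still_found(self):
        """Dark lesion on bright ground: polarity picks the minority region."""
        img, truth = generate_disk_image(fg=0.2, bg=0.8, seed=4)
        res = segment(img)
        assert dice(res.mask, truth) >= 0.95

    def test_constant_image_signalled_not_silent(self):
        img = RasterImage(pixels=np.full((32, 32), 0.5))
        with pytest.raises(DegenerateRegionError):
            segment(img)

    def test_region_means_exactness_on_result(self):
        img, _ = generate_disk_image(seed=5)
        res = segment(img)
        assert res.m2 == pytest.approx(img.pixels[res.mask].mean(), abs=1e-12)
        assert res.m1 == pytest.approx(img.pixels[~res.mask].mean(), abs=1e-12)

    def test_final_energy_not_above_initial(self):
        img, _ = generate_disk_image(seed=6)
        res = segment(img)
        assert res.final_energy <= res.state.energy_trace[0] + 1e-9

    def test_length_penalty_smooths_boundary(self):
        """beta=0 contours are never smoother (perimeter^2/area) than beta=0.5."""
        ratios = {0.0: [], 0.5: []}
        for seed in range(5):
            img, _ = generate_disk_image(seed=seed, sigma=0.08)
            for beta in ratios:
                res = segment(img, GACConfig(beta=beta))
                per = contour_length(res.state.phi)
                ratios[beta].append(per ** 2 / res.mask.sum())
        assert np.mean(ratios[0.5]) <= np.mean(ratios[0.0]) + 1e-9


class TestPostprocessMask:
    def test_small_component_removed(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[4:20, 4:20] = True      # large blob
        mask[28:30, 28:30] = True    # tiny blob
        out = postprocess_mask(mask, min_area_fraction=0.02)
        from skimage.measure import label
        assert label(out).max() == 1

    def test_interior_hole_filled(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[2:14, 2:14] = True
        mask[7, 7] = False
        assert postprocess_mask(mask)[7, 7]

    def test_clean_mask_unchanged(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[3:12, 3:12] = True
        np.testing.assert_array_equal(postprocess_mask(mask), mask)

    def test_empty_result_signalled(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[0, 0] = True
        from histofuse.gac_segment import EmptySegmentationError
        with pytest.raises(EmptySegmentationError):
            postprocess_mask(mask, min_area_fraction=0.5)


class TestExtractRoi:
    def test_full_mask_is_identity(self, random_rgb):
        out = extract_roi(random_rgb, np.ones((8, 8), dtype=bool))
        np.testing.assert_array_equal(out.pixels, random_rgb.pixels)

    def test_half_mask_zeroes_other_half(self, random_gray):
        mask = np.zeros((8, 8), dtype=bool)
        mask[:, :4] = True
        out = extract_roi(random_gray, mask)
        np.testing.assert_array_equal(out.pixels[:, :4], random_gray.pixels[:, :4])
        np.testing.assert_array_equal(out.pixels[:, 4:], 0.0)

    def test_nonzero_support_equals_mask(self, rng):
        img = RasterImage(pixels=rng.uniform(0.1, 1.0, size=(8, 8, 3)),
                          color_mode="rgb")
        mask = rng.uniform(size=(8, 8)) > 0.5
        out = extract_roi(img, mask)
        np.testing.assert_array_equal(out.pixels.sum(axis=2) > 0, mask)

    def test_shape_mismatch_rejected(self, random_gray):
        with pytest.raises(ValueError):
            extract_roi(random_gray, np.ones((4, 4), dtype=bool))
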