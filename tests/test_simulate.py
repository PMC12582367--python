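"""Synthetic slide generation and validation statistics."""

import numpy as np
import pytest

import serialign as sa
from serialign.errors import ArgumentError

SPACING = 16.0


class TestGenerator:
    def test_zero_cells_background_only(self):
        image, cells = sa.generate_synthetic_dapi(0, 120, 100, SPACING, seed=1)
        assert len(cells) == 0
        assert np.isfinite(image.pixels).all()

    def test_seed_reproducibility(self):
        a_img, a_cells = sa.generate_synthetic_dapi(400, 150, 120, SPACING, seed=5)
        b_img, b_cells = sa.generate_synthetic_dapi(400, 150, 120, SPACING, seed=5)
        np.testing.assert_array_equal(a_img.pixels, b_img.pixels)
        assert a_cells.equals(b_cells)

    def test_exact_cell_count_within_extent(self):
        image, cells = sa.generate_synthetic_dapi(500, 200, 160, SPACING, seed=9)
        assert len(cells) == 500
        ext = image.physical_extent
        assert ((cells.x >= 0) & (cells.x < ext[0])).all()
        assert ((cells.y >= 0) & (cells.y < ext[1])).all()

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ArgumentError):
            sa.generate_synthetic_dapi(10, 0, 10, SPACING, seed=0)


class TestSimulateSerialSlide:
    def test_zero_deformation_identity(self, small_slide):
        image, _ = small_slide
        pair = sa.simulate_serial_slide(image, max_displacement=0.0, seed=2)
        np.testing.assert_allclose(pair.deformed.pixels, image.pixels, atol=1e-6)

    def test_control_displacements_respect_bound(self, small_slide):
        image, _ = small_slide
        pair = sa.simulate_serial_slide(image, max_displacement=1000.0,
                                        mesh_size=3, seed=3)
        coeffs = pair.ground_truth.bspline.coefficients
        assert np.abs(coeffs).max() <= 1000.0
        assert coeffs.shape == (2, 6, 6)  # mesh 3 + cubic order

    def test_landmarks_consistent_with_ground_truth(self, sim_pair):
        mapped = sim_pair.ground_truth.apply(sim_pair.landmarks_original)
        np.testing.assert_allclose(mapped, sim_pair.landmarks_deformed, atol=1e-6)
        assert len(sim_pair.landmarks_original) >= 100

    def test_landmarks_lie_on_tissue(self, sim_pair):
        from skimage.filters import threshold_otsu

        image = sim_pair.original
        idx = np.rint(image.physical_to_index(sim_pair.landmarks_original)).astype(int)
        values = image.pixels[idx[:, 1], idx[:, 0]]
        assert (values > threshold_otsu(image.pixels)).all()


class TestMisalignmentErrors:
    def test_identical_lists_are_zero(self, rng):
        pts = rng.uniform(0, 100, (30, 2))
        result = sa.misalignment_errors(pts, pts)
        np.testing.assert_array_equal(result.errors, 0.0)

    def test_three_four_five(self):
        result = sa.misalignment_errors([(0.0, 0.0)], [(3.0, 4.0)])
        assert result.errors[0] == pytest.approx(5.0)

    def test_matches_independent_distance_oracle(self, rng):
        a = rng.uniform(-100, 100, (100, 2))
        b = rng.uniform(-100, 100, (100, 2))
        result = sa.misalignment_errors(a, b)
        oracle = [((ax - bx) ** 2 + (ay - by) ** 2) ** 0.5
                  for (ax, ay), (bx, by) in zip(a, b)]
        np.testing.assert_allclose(result.errors, oracle, rtol=1e-12)
        assert result.median == pytest.approx(np.median(oracle))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ArgumentError):
            sa.misalignment_errors([(0, 0)], [(1, 1), (2, 2)])


class TestNearestNeighbor:
    def test_single_target(self, rng):
        ref = rng.uniform(0, 10, (20, 2))
        target = np.array([[5.0, 5.0]])
        d = sa.nearest_neighbor_distances(ref, target)
        np.testing.assert_allclose(d, np.linalg.norm(ref - target, axis=1))

    def test_coincident_cell_has_zero_distance(self, rng):
        targets = rng.uniform(0, 10, (15, 2))
        d = sa.nearest_neighbor_distances(targets[[3]], targets)
        assert d[0] == 0.0

    def test_matches_exhaustive_scan(self, rng):
        ref = rng.uniform(0, 1000, (300, 2))
        tgt = rng.uniform(0, 1000, (400, 2))
        fast = sa.nearest_neighbor_distances(ref, tgt)
        slow = np.linalg.norm(ref[:, None, :] - tgt[None, :, :], axis=2).min(axis=1)
        np.testing.assert_allclose(fast, slow, rtol=1e-12)

    def test_empty_targets_rejected(self, rng):
        with pytest.raises(ArgumentError):
            sa.nearest_neighbor_distances(rng.uniform(0, 1, (5, 2)), np.empty((0, 2)))


class TestBootstrapMedianCI:
    def test_constant_data_degenerate_interval(self):
        assert sa.bootstrap_median_ci([5.0, 5.0, 5.0, 5.0], seed=0) == (5.0, 5.0, 5.0)

    def test_seeded_repeatability(self, rng):
        v = rng.normal(size=100)
        assert sa.bootstrap_median_ci(v, seed=7) == sa.bootstrap_median_ci(v, seed=7)

    def test_interval_brackets_median(self, rng):
        v = rng.exponential(size=200)
        med, lo, hi = sa.bootstrap_median_ci(v, seed=3)
        assert lo <= med <= hi

    def test_empty_rejected(self):
        with pytest.raises(ArgumentError):
            sa.bootstrap_median_ci([])


class TestValidateAlignment:
    def test_ground_truth_scores_zero(self, sim_pair):
        result = sa.validate_alignment(sim_pair, sim_pair.ground_truth, seed=4)
        assert result.errors.max() < 1e-6

    def test_identity_fit_on_pure_translation(self, small_slide):
        image, _ = small_slide
        shift = sa.RigidTransform(0.0, (0, 0), (50.0, 0.0))
        pair = sa.simulate_serial_slide(image, max_displacement=0.0, rigid=shift, seed=6)
        result = sa.validate_alignment(pair, sa.CompositeTransform(), seed=6)
        assert result.median == pytest.approx(50.0, abs=1e-9)
        assert result.ci_low <= result.median <= result.ci_high

    def test_difficulty_monotone_in_max_displacement(self, small_slide):
        image, _ = small_slide
        medians = []
        for max_disp in (100.0, 500.0, 1000.0):
            pair = sa.simulate_serial_slide(image, max_disp, mesh_size=3, seed=8)
            medians.append(sa.validate_alignment(pair, sa.CompositeTransform(),
                                                 seed=8).median)
        assert medians[0] <= medians[1] <= medians[2]


def test_tear_clipping_does_not_hurt_accuracy(sim_pair, fitted):
    """Excluding a painted non-alignable region never worsens the median error."""
    pair = sim_pair
    composite = fitted["composite"]
    # paint a tear into the deformed slide where tissue actually maps
    torn = pair.deformed.pixels.copy()
    target_pts = pair.ground_truth.apply(pair.landmarks_original)
    cx, cy = np.median(target_pts, axis=0)
    half = 300.0
    idx = pair.deformed.physical_to_index(np.array([[cx - half, cy - half],
                                                    [cx + half, cy + half]]))
    c0, r0 = np.floor(idx[0]).astype(int)
    c1, r1 = np.ceil(idx[1]).astype(int)
    torn[max(r0, 0):r1, max(c0, 0):c1] = 0.0
    torn_image = sa.RasterImage(torn, pair.deformed.spacing, pair.deformed.origin)

    settings = sa.OptimizerSettings(seed=55)
    rigid, _ = sa.fit_rigid(pair.original, torn_image, settings)
    comp_torn, _ = sa.fit_bspline(pair.original, torn_image, rigid, 6, settings)
    errors = np.linalg.norm(comp_torn.apply(pair.landmarks_original)
                            - pair.landmarks_deformed, axis=1)
    in_tear = ((target_pts[:, 0] >= cx - half) & (target_pts[:, 0] <= cx + half)
               & (target_pts[:, 1] >= cy - half) & (target_pts[:, 1] <= cy + half))
    assert 0 < in_tear.sum() < len(errors)
    assert np.median(errors[~in_tear]) <= np.median(errors) + 1e-9
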