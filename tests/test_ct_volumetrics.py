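"""Distribution volumetrics: thresholding, shape metrics, curves, projections."""

import math
import warnings

import numpy as np
import pytest

from ablaquant.calibration import fit_two_point
from ablaquant.ct_volumetrics import (
    ConcentrationVolume,
    CtVolume,
    average_curves,
    cumulative_volume_curve,
    max_concentration_projection,
    necrosis_to_distribution_ratio,
    segment_distribution,
    to_concentration,
)
from conftest import brute_force_distribution_metrics


def conc_volume(grid, spacing=(1.0, 1.0, 1.0)):
    return ConcentrationVolume(grid=np.asarray(grid, float), spacing=spacing)


def ball_mask(radius, shape=None, center=None):
    shape = shape or (2 * radius + 1,) * 3
    center = center or tuple((n - 1) / 2 for n in shape)
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    return (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= radius**2


class TestToConcentration:
    def test_uniform_grids_recover_the_standards(self, reference_model):
        for hu, expected in ((reference_model.hu_zero, 0.0), (reference_model.hu_hundred, 1.0)):
            ct = CtVolume(grid=np.full((4, 4, 4), hu), spacing=(1, 1, 1))
            conc = to_concentration(ct, reference_model)
            assert np.allclose(conc.grid, expected)

    def test_embedded_ellipsoid_reads_exact_concentration(self, reference_model):
        grid = np.full((20, 20, 20), reference_model.hu_zero)
        inc = ball_mask(5, shape=(20, 20, 20))
        grid[inc] = reference_model.hu_zero + 0.60 * (
            reference_model.hu_hundred - reference_model.hu_zero
        )
        ct = CtVolume(grid=grid, spacing=(0.5, 0.5, 0.5))
        conc = to_concentration(ct, reference_model)
        assert np.allclose(conc.grid[inc], 0.60)
        assert np.allclose(conc.grid[~inc], 0.0)

    def test_voxels_outside_tissue_are_not_evaluated(self, reference_model):
        ct = CtVolume(grid=np.zeros((3, 3, 3)), spacing=(1, 1, 1))
        tissue = np.zeros((3, 3, 3), bool)
        tissue[1, 1, 1] = True
        conc = to_concentration(ct, reference_model, tissue)
        assert conc.evaluated.sum() == 1

    def test_shape_mismatch_rejected(self, reference_model):
        ct = CtVolume(grid=np.zeros((3, 3, 3)), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="shape"):
            to_concentration(ct, reference_model, np.ones((2, 2, 2), bool))


class TestSegmentDistribution:
    def test_empty_distribution_warns_and_returns_zero_volume(self):
        with pytest.warns(UserWarning, match="empty distribution"):
            res = segment_distribution(conc_volume(np.full((4, 4, 4), 0.05)), lower=0.2)
        assert res.volume_ul == 0.0
        assert math.isnan(res.aspect_ratio)

    def test_single_voxel_is_degenerate_but_defined(self):
        grid = np.zeros((5, 5, 5))
        grid[2, 2, 2] = 0.9
        res = segment_distribution(conc_volume(grid), lower=0.2)
        assert res.radius_of_gyration_mm == 0.0
        assert res.aspect_ratio == 0.0
        assert res.volume_ul == 1.0

    def test_solid_ball_aspect_ratio_is_three_quarters(self):
        # mean distance to centroid of a uniform solid ball is 3R/4 and the
        # effective radius is R, so the literal formula gives 0.75
        mask = ball_mask(20)
        res = segment_distribution(conc_volume(np.where(mask, 0.6, 0.0)), lower=0.2)
        assert res.aspect_ratio == pytest.approx(0.75, abs=0.01)
        vol, cen, rg, ar = brute_force_distribution_metrics(res.mask, (1.0, 1.0, 1.0))
        assert res.volume_ul == pytest.approx(vol, rel=1e-12)
        assert res.radius_of_gyration_mm == pytest.approx(rg, rel=1e-12)
        assert res.aspect_ratio == pytest.approx(ar, rel=1e-12)

    def test_rod_matches_exhaustive_summation(self):
        grid = np.zeros((1, 1, 101))
        grid[0, 0, :] = 0.5
        res = segment_distribution(conc_volume(grid), lower=0.2)
        vol, cen, rg, ar = brute_force_distribution_metrics(res.mask, (1.0, 1.0, 1.0))
        # mean |i - 50| over i=0..100 computed independently
        assert rg == pytest.approx(sum(abs(i - 50) for i in range(101)) / 101)
        assert res.radius_of_gyration_mm == pytest.approx(rg, rel=1e-12)
        assert res.aspect_ratio == pytest.approx(ar, rel=1e-12)
        assert res.centroid_mm == pytest.approx(cen, rel=1e-12)

    def test_random_small_masks_match_brute_force(self, rng):
        # oracle equivalence on anisotropic spacing, ~10^3-10^4 voxels
        spacing = (0.5, 0.8, 1.1)
        grid = rng.uniform(0, 1, (20, 20, 25))
        res = segment_distribution(conc_volume(grid, spacing), lower=0.5)
        vol, cen, rg, ar = brute_force_distribution_metrics(res.mask, spacing)
        assert res.volume_ul == pytest.approx(vol, rel=1e-12)
        assert res.centroid_mm == pytest.approx(cen, rel=1e-12)
        assert res.radius_of_gyration_mm == pytest.approx(rg, rel=1e-12)
        assert res.aspect_ratio == pytest.approx(ar, rel=1e-12)

    def test_disconnected_components_all_counted(self):
        grid = np.zeros((10, 10, 10))
        grid[1, 1, 1] = grid[8, 8, 8] = grid[1, 8, 1] = 0.9
        res = segment_distribution(conc_volume(grid), lower=0.2)
        assert res.n_components == 3
        assert res.volume_ul == 3.0

    def test_upper_cut_excludes_air_bubble_artifacts(self):
        grid = np.full((6, 6, 6), 0.5)
        grid[0, 0, 0] = 3.4  # air-bubble artifact, impossible concentration
        with_cut = segment_distribution(conc_volume(grid), lower=0.2, upper=1.2)
        without = segment_distribution(conc_volume(grid), lower=0.2)
        assert without.volume_ul - with_cut.volume_ul == 1.0

    def test_rotation_and_axis_permutation_invariance(self, rng):
        grid = (rng.uniform(0, 1, (12, 14, 16)) > 0.6) * 0.7
        spacing = (0.5, 0.7, 0.9)
        base = segment_distribution(conc_volume(grid, spacing), lower=0.2)
        rotated = np.transpose(grid, (2, 0, 1))
        perm_spacing = (spacing[2], spacing[0], spacing[1])
        res = segment_distribution(conc_volume(rotated, perm_spacing), lower=0.2)
        assert res.volume_ul == pytest.approx(base.volume_ul, abs=1e-9)
        assert res.aspect_ratio == pytest.approx(base.aspect_ratio, abs=1e-9)

    def test_monotone_in_lower_threshold(self, rng):
        grid = rng.uniform(0, 1, (10, 10, 10))
        cv = conc_volume(grid)
        vols = [segment_distribution(cv, lower=t).volume_ul for t in (0.1, 0.3, 0.5, 0.7)]
        assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_volume_conservation_across_bands(self, rng):
        grid = rng.uniform(0, 1.5, (12, 12, 12))
        cv = conc_volume(grid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mid = segment_distribution(cv, lower=0.2, upper=1.2).volume_ul
            below = (grid < 0.2).sum() * 1.0
            above = (grid > 1.2).sum() * 1.0
        assert mid + below + above == pytest.approx(grid.size * 1.0)

    def test_resolution_consistency_on_ellipsoid(self, reference_model):
        def metrics(spacing):
            n = int(round(18 / spacing))
            coords = [(np.arange(n) + 0.5) * spacing - 9.0] * 3
            zz, yy, xx = np.meshgrid(*coords, indexing="ij")
            mask = (zz / 4.0) ** 2 + (yy / 3.5) ** 2 + (xx / 3.0) ** 2 <= 1
            cv = conc_volume(np.where(mask, 0.6, 0.0), (spacing,) * 3)
            return segment_distribution(cv, lower=0.2)

        coarse, fine = metrics(0.5), metrics(0.25)
        assert fine.volume_ul == pytest.approx(coarse.volume_ul, rel=0.02)
        assert abs(fine.aspect_ratio - coarse.aspect_ratio) < 0.02


class TestCurves:
    def test_uniform_block_gives_step_curve(self):
        cv = conc_volume(np.full((5, 5, 4), 0.5))
        curve = cumulative_volume_curve(cv)
        assert curve.volume_at(0.0) == 100.0
        assert curve.volume_at(0.5) == 100.0
        assert curve.volume_at(0.51) == 0.0
        assert curve.thresholds[-1] == pytest.approx(1.2)

    def test_consistent_with_segmentation_at_threshold(self, rng):
        cv = conc_volume(rng.uniform(0, 1.3, (10, 10, 10)))
        curve = cumulative_volume_curve(cv)
        for lower in (0.2, 0.4, 0.8):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                seg = segment_distribution(cv, lower=lower)
            assert curve.volume_at(lower) == seg.volume_ul

    def test_nested_shell_phantom(self):
        # 200 voxels at 0.3 of which an inner 50 are raised to 0.8
        grid = np.zeros((10, 10, 10))
        flat = grid.reshape(-1)
        flat[:200] = 0.3
        flat[:50] = 0.8
        curve = cumulative_volume_curve(conc_volume(grid))
        assert curve.volume_at(0.2) == 200.0
        assert curve.volume_at(0.5) == 50.0

    def test_curve_non_increasing(self, rng):
        cv = conc_volume(rng.uniform(0, 1.4, (8, 8, 8)))
        curve = cumulative_volume_curve(cv)
        assert np.all(np.diff(curve.volumes_ul) <= 0)

    def test_average_curves_matches_independent_mean(self, rng):
        curves = [cumulative_volume_curve(conc_volume(rng.uniform(0, 1, (6, 6, 6)))) for _ in range(6)]
        avg = average_curves(curves)
        expected = sum(c.volumes_ul for c in curves) / 6
        assert np.allclose(avg.volumes_ul, expected)
        same = average_curves([curves[0], curves[0]])
        assert np.array_equal(same.volumes_ul, curves[0].volumes_ul)

    def test_mismatched_grids_rejected(self):
        a = cumulative_volume_curve(conc_volume(np.full((3, 3, 3), 0.5)))
        b = cumulative_volume_curve(conc_volume(np.full((3, 3, 3), 2.0)))
        with pytest.raises(ValueError, match="mismatched"):
            average_curves([a, b])


class TestProjections:
    def test_uniform_volume_projects_uniformly(self):
        proj = max_concentration_projection(conc_volume(np.full((4, 5, 6), 0.3)), axis=0)
        assert proj.image.shape == (5, 6)
        assert np.allclose(proj.image, 0.3)
        assert np.allclose(proj.banded, 0.2)  # floored to the 20% band

    def test_single_hot_voxel_appears_in_every_axis(self):
        grid = np.zeros((4, 5, 6))
        grid[1, 2, 3] = 0.9
        for axis in (0, 1, 2):
            proj = max_concentration_projection(conc_volume(grid), axis=axis)
            assert proj.image.max() == 0.9
            assert (proj.image == 0.9).sum() == 1

    def test_matches_exhaustive_scan(self, rng):
        grid = rng.uniform(0, 1.3, (7, 8, 9))
        cv = conc_volume(grid)
        for axis in (0, 1, 2):
            proj = max_concentration_projection(cv, axis=axis)
            moved = np.moveaxis(grid, axis, 0)
            expected = np.array(
                [[max(moved[:, j, k]) for k in range(moved.shape[2])] for j in range(moved.shape[1])]
            )
            assert np.allclose(proj.image, expected)
        assert np.all(proj.banded <= 1.0)


class TestRatio:
    @pytest.mark.parametrize(
        "nec, dist, expected",
        [(100.0, 100.0, 1.0), (326.5, 320.9, 326.5 / 320.9), (0.0, 50.0, 0.0)],
    )
    def test_ratio_values(self, nec, dist, expected):
        assert necrosis_to_distribution_ratio(nec, dist) == pytest.approx(expected)

    def test_zero_distribution_volume_undefined(self):
        with pytest.raises(ValueError, match="> 0"):
            necrosis_to_distribution_ratio(10.0, 0.0)
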