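"""Artifact detection: TV cost, cost curves, STS masks, preliminary MAR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from rmar import (
    CTImage,
    artifact_image,
    build_masks,
    cost_curve,
    preliminary_mar,
    segment_metal,
    select_optimal,
    select_worst,
    sts_flags,
    sts_mask,
    tv_cost,
)
from rmar.core import VMISeries
from rmar.detect import CostCurve


def tv_cost_bruteforce(f, exclude=None):
    """Double-loop reference implementation of the TV cost."""
    total = 0.0
    for i in range(f.shape[0] - 1):
        for j in range(f.shape[1] - 1):
            if exclude is not None and (
                exclude[i, j] or exclude[i + 1, j] or exclude[i, j + 1]
            ):
                continue
            total += np.sqrt(
                (f[i + 1, j] - f[i, j]) ** 2 + (f[i, j + 1] - f[i, j]) ** 2
            )
    return total


def sts_bruteforce(a, support, delta):
    """Reference row-wise sort/median/compare implementation."""
    flags = np.zeros_like(support)
    for i in range(a.shape[0]):
        vals = sorted(a[i, support[i]])
        if len(vals) < 3:
            continue
        med = float(np.median(vals))
        for j in range(a.shape[1]):
            if support[i, j] and abs(a[i, j] - med) > delta:
                flags[i, j] = True
    return flags


class TestTVCost:
    def test_constant_image_is_zero(self):
        assert tv_cost(np.full((7, 9), 42.0)) == 0.0

    def test_hand_evaluated_2x2(self):
        # only pixel (0,0) has both forward neighbours:
        # sqrt((0-0)^2 + (1-0)^2) = 1
        assert tv_cost(np.array([[0.0, 1.0], [0.0, 1.0]])) == pytest.approx(1.0)

    def test_transpose_symmetry(self, rng):
        f = rng.normal(size=(11, 11))
        assert tv_cost(f) == pytest.approx(tv_cost(f.T), rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        f=hnp.arrays(
            float,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=16),
            elements=st.floats(-1000, 4000),
        )
    )
    def test_matches_bruteforce(self, f):
        assert tv_cost(f) == pytest.approx(tv_cost_bruteforce(f), abs=1e-9)

    def test_exclusion_matches_bruteforce(self, rng):
        f = rng.normal(size=(20, 20)) * 100
        ex = rng.random((20, 20)) < 0.2
        assert tv_cost(f, exclude=ex) == pytest.approx(
            tv_cost_bruteforce(f, ex), abs=1e-9
        )

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            tv_cost(np.zeros((1, 5)))


class TestCostCurve:
    def test_identical_images_normalize_to_one(self, rng):
        img = CTImage(rng.normal(size=(8, 8)))
        curve = cost_curve([img, img.copy(), img.copy()], [70, 100, 140])
        np.testing.assert_allclose(curve.normalized_costs, 1.0)

    def test_max_is_always_one(self, rng):
        imgs = [CTImage(rng.normal(size=(8, 8)) * s) for s in (1, 5, 2)]
        curve = cost_curve(imgs, [70, 100, 140])
        assert curve.normalized_costs.max() == pytest.approx(1.0)

    def test_amplitude_rescaling_leaves_curve_unchanged(self, rng):
        imgs = [rng.normal(size=(8, 8)) * s for s in (1, 5, 2)]
        c1 = cost_curve([CTImage(i) for i in imgs], [70, 100, 140])
        c2 = cost_curve([CTImage(3.7 * i) for i in imgs], [70, 100, 140])
        np.testing.assert_allclose(c1.normalized_costs, c2.normalized_costs)

    def test_selection_pattern(self):
        # cost pattern with minimum at 100 keV and maximum at 70 keV
        curve = CostCurve(np.array([70, 80, 100, 120, 140.0]),
                          np.array([1.0, 0.6, 0.3, 0.4, 0.5]))
        assert select_optimal(curve) == 100.0
        assert select_worst(curve) == 70.0

    def test_tie_rules(self):
        curve = CostCurve(np.array([70, 100, 140.0]), np.ones(3))
        assert select_optimal(curve) == 140.0  # tie -> higher energy
        assert select_worst(curve) == 70.0  # tie -> lower energy

    def test_single_entry_curve_rejected(self):
        with pytest.raises(ValueError):
            CostCurve(np.array([70.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            cost_curve([CTImage(np.zeros((4, 4)))], [70.0])


class TestSTS:
    def test_example_row_flags_outliers(self):
        row = np.array([[0, 0, 0, 50.0, 0, -40.0, 0, 0, 0]])
        support = np.ones_like(row, dtype=bool)
        flags = sts_flags(row, support, delta_hu=10.0)
        np.testing.assert_array_equal(
            flags, [[False, False, False, True, False, True, False, False, False]]
        )

    def test_matches_bruteforce_on_random_rows(self, rng):
        a = rng.normal(size=(40, 30)) * 30
        support = rng.random((40, 30)) < 0.8
        got = sts_flags(a, support, delta_hu=10.0)
        np.testing.assert_array_equal(got, sts_bruteforce(a, support, 10.0))

    def test_all_zero_artifact_empty_mask(self):
        a = np.zeros((16, 16))
        assert not sts_mask(a, np.ones((16, 16), bool)).any()

    def test_huge_delta_empty_mask(self, rng):
        a = rng.normal(size=(16, 16)) * 100
        assert not sts_mask(a, np.ones((16, 16), bool), delta_hu=1e9).any()

    def test_rows_with_few_support_pixels_skipped(self):
        a = np.array([[100.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
        support = np.array([[True, True, False], [True, True, True]])
        flags = sts_flags(a, support, delta_hu=10.0)
        assert not flags[0].any()  # 2 support pixels: skipped
        assert flags[1, 0]

    def test_empty_support_rejected(self):
        with pytest.raises(ValueError, match="support"):
            sts_flags(np.zeros((4, 4)), np.zeros((4, 4), bool))

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            sts_flags(np.zeros((4, 4)), np.ones((4, 4), bool), delta_hu=0.0)


class TestSegmentMetal:
    def test_rod_mask_matches_simulator_geometry(self, rod_study):
        mask = segment_metal(rod_study.sim.at(140.0))
        truth = rod_study.phantom.metal
        # agreement up to a one-pixel morphological boundary
        assert (mask & truth).sum() / truth.sum() > 0.7
        from skimage.morphology import dilation, disk

        assert not (mask & ~dilation(truth, disk(2))).any()

    def test_all_water_image_empty(self):
        img = CTImage(np.zeros((32, 32)))
        with pytest.warns(UserWarning, match="no metal"):
            mask = segment_metal(img)
        assert not mask.any()

    def test_low_threshold_rejected(self):
        with pytest.raises(ValueError, match="1000"):
            segment_metal(CTImage(np.zeros((4, 4))), threshold_hu=500.0)


class TestPreliminaryMAR:
    def test_empty_metal_mask_rejected(self):
        img = CTImage(np.zeros((32, 32)))
        with pytest.raises(ValueError, match="metal"):
            preliminary_mar(img, np.zeros((32, 32), bool))

    def test_non_square_rejected(self):
        img = CTImage(np.zeros((16, 32)))
        metal = np.zeros((16, 32), bool)
        metal[8, 16] = True
        with pytest.raises(ValueError, match="square"):
            preliminary_mar(img, metal)

    def test_moves_image_toward_ground_truth(self, rod_study):
        """The coarse correction reduces the RMS error to the artifact-free
        truth even though its interpolation residue is high-frequency."""
        from rmar.detect import _support_mask

        metal = rod_study.phantom.metal
        body = _support_mask(rod_study.sim.at(140.0)) & ~metal
        for e in (70.0, 140.0):
            im = rod_study.sim.at(e)
            corr = preliminary_mar(im, metal)
            tr = rod_study.truth.at(e).pixels
            rms_in = np.sqrt(((im.pixels - tr)[body] ** 2).mean())
            rms_out = np.sqrt(((corr.pixels - tr)[body] ** 2).mean())
            assert rms_out < rms_in

    def test_far_roi_close_to_uniform_value(self, rod_study):
        """Away from the rods the coarse correction stays near truth."""
        im = rod_study.sim.at(70.0)
        corr = preliminary_mar(im, rod_study.phantom.metal)
        n = im.shape[0]
        # ROI near the top of the water disc, far from the rod axis
        roi = corr.pixels[n // 4 - 5 : n // 4 + 5, n // 2 - 5 : n // 2 + 5]
        assert abs(roi.mean() - 15.0) < 15.0


class TestArtifactImage:
    def test_identity_correction_gives_zero(self, rng):
        im = CTImage(rng.normal(size=(8, 8)))
        art = artifact_image(im, im.copy(), np.zeros((8, 8), bool))
        np.testing.assert_array_equal(art.pixels, 0.0)

    def test_decomposition_algebra_off_metal(self, rng):
        im = CTImage(rng.normal(size=(8, 8)))
        corr = CTImage(rng.normal(size=(8, 8)))
        metal = np.zeros((8, 8), bool)
        metal[2, 2] = True
        art = artifact_image(im, corr, metal)
        recon = art.pixels + corr.pixels
        assert art.pixels[2, 2] == 0.0
        np.testing.assert_allclose(recon[~metal], im.pixels[~metal], atol=1e-12)

    def test_low_energy_artifacts_cost_more(self, rod_study):
        """70 keV artifact image outweighs 140 keV on the rod phantom."""
        metal = rod_study.phantom.metal
        costs = {}
        for e in (70.0, 140.0):
            im = rod_study.sim.at(e)
            art = artifact_image(im, preliminary_mar(im, metal), metal)
            costs[e] = tv_cost(art, exclude=metal)
        assert costs[70.0] > costs[140.0]


class TestBuildMasks:
    def test_partition_of_support(self, rod_result):
        m = rod_result.masks
        combined = m.artifact | m.artifact_free | m.metal
        in_support_metal = m.metal & m.support
        np.testing.assert_array_equal(
            m.artifact | m.artifact_free | in_support_metal, m.support
        )
        assert not (m.artifact & m.artifact_free).any()
        assert not (m.artifact & m.metal).any()

    def test_covers_strong_true_artifacts(self, rod_study, rod_result):
        worst = rod_result.report["worst_kev"]
        diff = rod_study.sim.at(worst).pixels - rod_study.truth.at(worst).pixels
        strong = (
            (np.abs(diff) > 25.0)
            & ~rod_study.phantom.metal
            & rod_result.masks.support
        )
        covered = (rod_result.masks.artifact & strong).sum() / strong.sum()
        assert covered >= 0.8

    def test_artifact_free_series_yields_sparse_mask(self, rod_study):
        """Metal present but no streaks: f_M1 stays a sliver of the body."""
        metal = rod_study.phantom.metal
        clean = []
        for im in rod_study.truth:
            px = im.pixels.copy()
            px[metal] = 8000.0
            clean.append(CTImage(px, im.spacing, im.energy_kev))
        masks = build_masks(VMISeries(clean))
        assert masks.artifact.sum() < 0.01 * masks.support.sum()

    def test_no_metal_rejected(self, rod_study):
        with pytest.raises(ValueError, match="no metal"):
            build_masks(rod_study.truth)
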