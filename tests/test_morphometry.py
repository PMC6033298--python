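import math

import numpy as np
import pytest

from histostep import morphometry, synth
from histostep.morphometry import (
    NucleusContour,
    PhansalkarParams,
    WatershedParams,
    binarize,
    measure,
    phansalkar_threshold,
    split_touching,
    trace_contours,
)
from histostep.synth import sample_nonoverlapping_nuclei


def naive_threshold(mu, sigma, p=2.0, q=10.0, k=0.25, r=0.5):
    return mu * (1.0 + p * math.exp(-q * mu) + k * (sigma / r - 1.0))


class TestPhansalkarThreshold:
    def test_zero_mean_zero_threshold(self):
        assert phansalkar_threshold(0.0, 0.37) == 0.0

    def test_unit_mean_sigma_equals_r(self):
        expected = 1.0 + 2.0 * math.exp(-10.0)
        assert phansalkar_threshold(1.0, 0.5) == pytest.approx(expected, abs=1e-15)

    def test_hand_evaluated_point(self):
        expected = 0.5 * (1.0 + 2.0 * math.exp(-5.0) - 0.125)
        assert phansalkar_threshold(0.5, 0.25) == pytest.approx(expected, abs=1e-15)

    def test_oracle_grid(self):
        rng = np.random.default_rng(0)
        mu = rng.uniform(0, 1, (20, 20))
        sigma = rng.uniform(0, 0.5, (20, 20))
        got = phansalkar_threshold(mu, sigma)
        for i in range(20):
            for j in range(20):
                assert got[i, j] == pytest.approx(naive_threshold(mu[i, j], sigma[i, j]), abs=1e-12)

    def test_zero_r_rejected(self):
        with pytest.raises(ValueError):
            PhansalkarParams(r=0.0)


def brute_force_binarize(img, params):
    """Per-pixel double-loop oracle with edge replication and a disk window."""
    r = params.window_radius
    padded = np.pad(img, r, mode="edge")
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = yy**2 + xx**2 <= r**2
    out = np.zeros_like(img, dtype=bool)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            window = padded[i : i + 2 * r + 1, j : j + 2 * r + 1][disk]
            mu = window.mean()
            sd = window.std()
            t = naive_threshold(mu, sd, params.p, params.q, params.k, params.r)
            out[i, j] = img[i, j] > t
    return out


class TestBinarize:
    def test_all_zero_map(self):
        mask = binarize(np.zeros((32, 32)), PhansalkarParams(window_radius=5))
        assert not mask.any()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        img = rng.uniform(0, 1, (11, 11))
        params = PhansalkarParams(window_radius=3)
        np.testing.assert_array_equal(binarize(img, params), brute_force_binarize(img, params))

    def test_nucleus_footprint_iou(self, desk_threshold_params):
        spec = synth.NucleusSpec(center=(32, 32), semi_axes=(8, 6), hematoxylin_amount=0.7)
        truth = synth.render_patch([spec], background_eosin=0.25, shape=(64, 64))
        from histostep.stains import normalized_hematoxylin

        mask = binarize(normalized_hematoxylin(truth.patch), desk_threshold_params)
        footprint = synth._ellipse_mask((64, 64), spec)
        iou = (mask & footprint).sum() / (mask | footprint).sum()
        assert iou >= 0.9

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((8, 8)), PhansalkarParams(window_radius=10))


def disk_mask(shape, center, radius):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestSplitTouching:
    def test_two_disjoint_blobs(self):
        mask = disk_mask((64, 64), (16, 16), 6) | disk_mask((64, 64), (48, 48), 6)
        labels = split_touching(mask, WatershedParams(min_seed_separation=3))
        assert labels.max() == 2

    def test_single_blob_no_spurious_split(self):
        mask = disk_mask((48, 48), (24, 24), 10)
        labels = split_touching(mask, WatershedParams(min_seed_separation=3))
        assert labels.max() == 1

    def test_twenty_percent_overlap_resolved(self):
        # Two equal circles of radius 10 overlapping by 20% of the radius.
        r = 10
        d = int(round(2 * r - 0.2 * r))
        mask = disk_mask((64, 96), (32, 30), r) | disk_mask((64, 96), (32, 30 + d), r)
        labels = split_touching(mask, WatershedParams(min_seed_separation=7))
        assert labels.max() == 2

    def test_empty_mask(self):
        labels = split_touching(np.zeros((16, 16), dtype=bool))
        assert labels.max() == 0


class TestTraceContours:
    def test_empty_mask(self):
        assert trace_contours(np.zeros((8, 8), dtype=int)) == []

    def test_solid_square(self):
        labels = np.zeros((5, 5), dtype=int)
        labels[1:4, 1:4] = 1
        contours = trace_contours(labels)
        assert len(contours) == 1
        assert contours[0].area == 9
        # The 3x3 square's outer boundary is its 8 border pixels.
        assert len(contours[0].boundary) == 8

    def test_boundary_is_closed_chain(self):
        mask = disk_mask((32, 32), (16, 16), 7).astype(int)
        (contour,) = trace_contours(mask)
        pts = contour.boundary
        for a, b in zip(pts, np.roll(pts, -1, axis=0)):
            assert np.abs(a - b).max() <= 1  # Moore neighbors, incl. last -> first

    def test_area_matches_pixel_count_oracle(self):
        rng = np.random.default_rng(5)
        mask = np.zeros((40, 40), dtype=bool)
        for _ in range(3):
            mask |= disk_mask((40, 40), rng.integers(8, 32, 2), rng.integers(3, 6))
        from scipy import ndimage as ndi

        labels, _ = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
        contours = trace_contours(labels)
        for c in contours:
            assert c.area == int((labels == c.label).sum())
        assert sum(c.area for c in contours) == int(mask.sum())

    def test_isolated_pixel(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[2, 2] = 1
        (contour,) = trace_contours(labels)
        assert contour.area == 1
        assert len(contour.boundary) == 1


class TestMeasure:
    def test_white_patch(self):
        m = measure(np.ones((64, 64, 3)))
        assert m.count == 0 and m.total_area == 0

    def test_recovers_count(self, separated_nuclei_patch, desk_threshold_params, desk_watershed_params):
        m = measure(separated_nuclei_patch.patch, desk_threshold_params, desk_watershed_params)
        assert m.count == separated_nuclei_patch.true_count

    def test_total_area_within_15_percent(
        self, separated_nuclei_patch, desk_threshold_params, desk_watershed_params
    ):
        m = measure(separated_nuclei_patch.patch, desk_threshold_params, desk_watershed_params)
        truth = separated_nuclei_patch.true_total_area
        assert abs(m.total_area - truth) / truth <= 0.15

    def test_monotone_under_added_nucleus(self, desk_threshold_params, desk_watershed_params):
        rng = np.random.default_rng(13)
        nuclei = sample_nonoverlapping_nuclei(rng, 6, (4.0, 6.0), (96, 96))
        base = synth.render_patch(nuclei[:5], shape=(96, 96))
        more = synth.render_patch(nuclei, shape=(96, 96))
        m0 = measure(base.patch, desk_threshold_params, desk_watershed_params)
        m1 = measure(more.patch, desk_threshold_params, desk_watershed_params)
        assert m1.count >= m0.count
        assert m1.total_area >= m0.total_area

    def test_rotation_invariance(
        self, separated_nuclei_patch, desk_threshold_params, desk_watershed_params
    ):
        patch = separated_nuclei_patch.patch
        m = measure(patch, desk_threshold_params, desk_watershed_params)
        mr = measure(np.rot90(patch).copy(), desk_threshold_params, desk_watershed_params)
        assert mr.count == m.count
        assert mr.total_area == m.total_area

    def test_invariants_hold(self, separated_nuclei_patch, desk_threshold_params, desk_watershed_params):
        m = measure(separated_nuclei_patch.patch, desk_threshold_params, desk_watershed_params)
        assert m.count == len(m.contours)
        assert m.total_area == sum(c.area for c in m.contours)
        assert all(isinstance(c, NucleusContour) and c.area >= 1 for c in m.contours)
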