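"""Density-map rendering and NMS peak detection against independent oracles."""

import math

import numpy as np
import pytest

from probcell import AnnotationSet, DensityMap, kernel_value, nms_detect, render_density_map
from probcell.density import read_density_map, write_density_map


def brute_force_nms(values, min_distance, threshold):
    """Independent NMS oracle: explicit neighbourhood scan + greedy selection.

    Candidates are voxels attaining the maximum of their exclusive
    ``min_distance`` ball; they are scanned in (descending value, ascending
    index) order with explicit pairwise distance checks.
    """
    values = np.asarray(values, dtype=float)
    shape = values.shape
    r = int(math.ceil(min_distance))
    candidates = []
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                v = values[i, j, k]
                if v <= threshold:
                    continue
                is_max = True
                for a in range(max(0, i - r), min(shape[0], i + r + 1)):
                    for b in range(max(0, j - r), min(shape[1], j + r + 1)):
                        for c in range(max(0, k - r), min(shape[2], k + r + 1)):
                            if (a - i) ** 2 + (b - j) ** 2 + (c - k) ** 2 < min_distance ** 2:
                                if values[a, b, c] > v:
                                    is_max = False
                    if not is_max:
                        break
                if is_max:
                    candidates.append(((i, j, k), v))
    candidates.sort(key=lambda t: (-t[1], t[0]))
    accepted = []
    for (i, j, k), v in candidates:
        ok = all(
            (i - a) ** 2 + (j - b) ** 2 + (k - c) ** 2 >= min_distance ** 2
            for (a, b, c) in accepted
        )
        if ok:
            accepted.append((i, j, k))
    return sorted(accepted)


class TestKernel:
    def test_printed_formula_value(self):
        assert kernel_value(0.0, 4.0) == pytest.approx(0.0997356, abs=1e-7)

    def test_far_tail_negligible(self):
        assert kernel_value(40.0, 4.0) < 1e-20

    def test_analytic_ratio_at_one_sigma(self):
        for sigma in (2.0, 4.0, 6.0):
            ratio = kernel_value(sigma, sigma) / kernel_value(0.0, sigma)
            assert ratio == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_strictly_decreasing_in_distance(self):
        s = np.linspace(0, 20, 200)
        v = kernel_value(s, 3.0)
        assert (np.diff(v) < 0).all()

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            kernel_value(1.0, 0.0)


class TestRenderDensityMap:
    def test_isolated_annotation_peaks_at_one(self):
        ann = AnnotationSet([[16.5, 16.5, 16.5]], (32, 32, 32))  # a voxel center
        dm = render_density_map(ann, sigma=4.0, compounding="K_max")
        assert dm.values[16, 16, 16] == pytest.approx(1.0)
        assert dm.values.argmax() == np.ravel_multi_index((16, 16, 16), dm.shape)

    def test_coincident_annotations_sum_vs_max(self):
        # two annotations at the same offset from one voxel center
        single = render_density_map(
            AnnotationSet([[16.5, 16.5, 16.5]], (32, 32, 32)), 4.0, "K_sum"
        )
        # uniqueness forbids exact duplicates; emulate by doubling the kernel
        both_sum = render_density_map(
            AnnotationSet([[16.5, 16.5, 16.5], [16.5, 16.5, 16.500001]], (32, 32, 32)),
            4.0,
            "K_sum",
        )
        both_max = render_density_map(
            AnnotationSet([[16.5, 16.5, 16.5], [16.5, 16.5, 16.500001]], (32, 32, 32)),
            4.0,
            "K_max",
        )
        assert both_sum.values[16, 16, 16] == pytest.approx(
            2 * single.values[16, 16, 16], rel=1e-5
        )
        assert both_max.values[16, 16, 16] == pytest.approx(
            single.values[16, 16, 16], rel=1e-5
        )

    def test_cutoff_zero_beyond_16um(self, small_annotations, small_kmax_dm):
        centers = np.stack(
            np.meshgrid(*[np.arange(32) + 0.5] * 3, indexing="ij"), axis=-1
        )
        dmin = np.full((32, 32, 32), np.inf)
        for c in small_annotations.coords:
            d = np.linalg.norm(centers - c, axis=-1)
            dmin = np.minimum(dmin, d)
        assert (small_kmax_dm.values[dmin > 16.0] == 0).all()
        assert (small_kmax_dm.values[dmin <= 15.0] > 0).all()

    def test_kmax_equals_per_annotation_maximum_oracle(self, small_annotations):
        dm = render_density_map(small_annotations, 4.0, "K_max", peak_normalized=False)
        singles = [
            render_density_map(
                AnnotationSet([c], (32, 32, 32)), 4.0, "K_max", peak_normalized=False
            ).values
            for c in small_annotations.coords
        ]
        oracle = np.maximum.reduce(singles)
        np.testing.assert_allclose(dm.values, oracle, rtol=1e-6)

    def test_empty_annotations_all_zero(self):
        dm = render_density_map(AnnotationSet(np.empty((0, 3)), (20, 20, 20)), 4.0)
        assert (dm.values == 0).all()

    def test_permutation_invariance(self, small_annotations):
        a = render_density_map(small_annotations, 3.0, "K_sum")
        flipped = AnnotationSet(small_annotations.coords[::-1], (32, 32, 32))
        b = render_density_map(flipped, 3.0, "K_sum")
        np.testing.assert_array_equal(a.values, b.values)

    def test_kmax_peak_floor_regardless_of_neighbors(self):
        # annotations closer than sigma: K_max keeps every peak near 1
        ann = AnnotationSet([[10.2, 10.7, 10.1], [14.9, 10.7, 10.1]], (24, 24, 24))
        dm = render_density_map(ann, 4.0, "K_max")
        d = math.sqrt(3) / 2
        floor = math.exp(-(d ** 2) / (2 * 16.0))
        for c in ann.coords:
            vox = tuple(np.floor(c).astype(int))
            assert dm.values[vox] >= floor - 1e-6


class TestNmsDetect:
    def test_single_kernel_single_proposal(self):
        ann = AnnotationSet([[12.3, 11.8, 13.1]], (24, 24, 24))
        dm = render_density_map(ann, 4.0, "K_max")
        props = nms_detect(dm, threshold=0.0)
        assert len(props) == 1
        assert np.linalg.norm(props.coords[0] - ann.coords[0]) <= math.sqrt(3)

    def test_close_pair_suppressed_to_one(self):
        ann = AnnotationSet([[12.5, 12.4, 12.6], [12.5, 12.4, 15.6]], (24, 24, 24))
        dm = render_density_map(ann, 4.0, "K_max")
        props = nms_detect(dm, min_distance=4.0)
        assert len(props) == 1

    def test_threshold_zero_returns_superset(self, rng):
        noisy = DensityMap(
            np.abs(rng.normal(0.2, 0.15, size=(24, 24, 24))).astype(np.float32),
            sigma=4.0,
        )
        n0 = len(nms_detect(noisy, threshold=0.0))
        for thr in (0.1, 0.3, 0.5):
            assert n0 >= len(nms_detect(noisy, threshold=thr))

    def test_pairwise_spacing_invariant(self, rng):
        noisy = DensityMap(rng.random((24, 24, 24)).astype(np.float32), sigma=4.0)
        props = nms_detect(noisy, min_distance=4.0, threshold=0.2)
        d = np.linalg.norm(props.coords[:, None] - props.coords[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert (d >= 4.0).all()

    @pytest.mark.parametrize("case", range(6))
    def test_matches_brute_force_oracle(self, case, rng):
        if case < 3:  # smooth rendered maps
            n = 3 + case
            coords = rng.uniform(2, 22, size=(n, 3))
            dm = render_density_map(AnnotationSet(coords, (24, 24, 24)), 3.0)
            values = dm.values
        else:  # rough random maps
            values = rng.random((14, 14, 14)).astype(np.float32)
            dm = DensityMap(values, sigma=4.0)
        threshold = 0.0 if case % 2 else 0.25
        props = nms_detect(dm, min_distance=4.0, threshold=threshold)
        got = sorted(tuple(int(v) for v in c - 0.5) for c in props.coords)
        assert got == brute_force_nms(values, 4.0, threshold)

    def test_well_separated_gt_recovered_exactly(self, small_annotations, small_kmax_dm):
        props = nms_detect(small_kmax_dm, threshold=0.0)
        assert len(props) == len(small_annotations)
        d = np.linalg.norm(
            props.coords[:, None] - small_annotations.coords[None], axis=-1
        ).min(axis=1)
        assert (d <= math.sqrt(3)).all()

    def test_empty_map_empty_result(self):
        dm = DensityMap(np.zeros((16, 16, 16), np.float32), sigma=4.0)
        assert len(nms_detect(dm)) == 0


def test_density_map_tiff_roundtrip(tmp_path, small_kmax_dm):
    write_density_map(tmp_path / "dm.tif", small_kmax_dm)
    back = read_density_map(tmp_path / "dm.tif")
    np.testing.assert_array_equal(back.values, small_kmax_dm.values)
    assert back.sigma == small_kmax_dm.sigma
    assert back.compounding == small_kmax_dm.compounding
    assert back.peak_normalized == small_kmax_dm.peak_normalized
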