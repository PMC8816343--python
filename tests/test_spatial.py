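"""Empty-space distances, probabilistic replicates, envelopes, summaries."""

import numpy as np
import pytest

from probcell import (
    ProposalSet,
    StructureScene,
    cdf_envelopes,
    cell_structure_distances,
    deterministic_subset,
    empty_space_distances,
    probabilistic_esd,
    probabilistic_replicates,
    significance_level,
    summary_statistics,
)
from probcell.spatial import default_grid, kde_cdf


def brute_force_esd(structure, tissue):
    """Exhaustive nearest-foreground search (independent of the EDT)."""
    fg = np.argwhere(structure).astype(float)
    out = []
    for v in np.argwhere(tissue & ~structure):
        out.append(np.sqrt(((fg - v) ** 2).sum(axis=1)).min())
    return np.sort(np.asarray(out))


def _plane_scene(shape=(20, 20, 20), z0=7):
    structure = np.zeros(shape, dtype=bool)
    structure[:, :, z0] = True
    tissue = np.ones(shape, dtype=bool)
    structure &= tissue
    return StructureScene(structure, tissue)


class TestEmptySpaceDistances:
    def test_plane_structure_closed_form(self):
        scene = _plane_scene()
        esd = empty_space_distances(scene)
        # distances from voxels at plane offset dz are exactly |dz|
        expected = np.concatenate(
            [np.full(400, abs(z - 7)) for z in range(20) if z != 7]
        )
        assert np.sort(esd).tolist() == np.sort(expected).tolist()

    def test_matches_exhaustive_search(self, rng):
        structure = rng.random((20, 20, 20)) < 0.01
        structure[0, 0, 0] = True  # ensure nonempty
        tissue = np.ones((20, 20, 20), dtype=bool)
        scene = StructureScene(structure, tissue)
        np.testing.assert_allclose(
            np.sort(empty_space_distances(scene)),
            brute_force_esd(structure, tissue),
            rtol=1e-12,
        )

    def test_structure_equals_tissue_empty_sample(self):
        scene = StructureScene(np.ones((8, 8, 8), bool), np.ones((8, 8, 8), bool))
        assert empty_space_distances(scene).size == 0

    def test_empty_structure_rejected(self):
        scene = StructureScene(np.zeros((8, 8, 8), bool), np.ones((8, 8, 8), bool))
        with pytest.raises(ValueError):
            empty_space_distances(scene)


class TestCellDistances:
    def test_cell_on_structure_zero(self):
        scene = _plane_scene()
        d = cell_structure_distances(np.array([[5.5, 5.5, 7.5]]), scene)
        assert d[0] == 0.0

    def test_cell_near_plane_distance(self):
        scene = _plane_scene()
        d = cell_structure_distances(np.array([[10.2, 10.7, 14.6]]), scene)
        assert d[0] == pytest.approx(7.0, abs=np.sqrt(3) / 2)

    def test_outside_tissue_excluded_with_warning(self):
        structure = np.zeros((16, 16, 16), bool)
        structure[8, 8, 8] = True
        tissue = np.zeros((16, 16, 16), bool)
        tissue[2:14, 2:14, 2:14] = True
        structure &= tissue
        scene = StructureScene(structure, tissue)
        with pytest.warns(UserWarning):
            d = cell_structure_distances(
                np.array([[0.5, 0.5, 0.5], [8.5, 8.5, 9.5]]), scene
            )
        assert d.shape == (1,)


class TestProbabilisticSampling:
    def test_alpha_formula(self):
        # 2 / (T + 1); the printed two-decimal value for T = 50 is 0.04
        assert significance_level(50) == pytest.approx(2 / 51)
        assert round(significance_level(50), 2) == 0.04
        assert significance_level(99) == pytest.approx(0.02)

    def test_deterministic_subset_inclusive_at_half(self):
        props = ProposalSet(
            np.array([[1.0, 1, 1], [2.0, 2, 2], [3.0, 3, 3]]),
            probabilities=[1.0, 0.5, 0.49],
        )
        kept = deterministic_subset(props)
        assert len(kept) == 2

    def test_replicate_inclusion_expectation(self):
        props = ProposalSet(
            np.array([[1.0, 1, 1], [5.0, 5, 5]]), probabilities=[0.9, 0.02]
        )
        reps = probabilistic_replicates(props, T=50, seed=0)
        counts = np.zeros(2)
        for r in reps:
            for c in r.coords:
                counts[int(c[0] > 2)] += 1
        # expected p * T = 45 and 1
        assert abs(counts[0] - 45) <= 10
        assert counts[1] <= 6

    def test_unit_probability_always_included(self):
        props = ProposalSet(np.array([[1.0, 1, 1]]), probabilities=[1.0])
        reps = probabilistic_replicates(props, T=20, seed=1)
        assert all(len(r) == 1 for r in reps)

    def test_inclusion_frequency_converges(self):
        probs = np.array([0.1, 0.35, 0.62, 0.9])
        props = ProposalSet(np.arange(12, dtype=float).reshape(4, 3) * 3,
                            probabilities=probs)
        T = 2000
        reps = probabilistic_replicates(props, T=T, seed=7)
        freq = np.zeros(4)
        base = props.coords
        for r in reps:
            for c in r.coords:
                freq[np.where((base == c).all(axis=1))[0][0]] += 1
        np.testing.assert_allclose(freq / T, probs, atol=0.03)

    def test_probabilistic_esd_poisson_mean_and_support(self):
        esd = np.array([0.0, 1.0, 2.0, 3.0, 5.0, 8.0])
        sizes, pooled = [], set()
        for s in range(300):
            draw = probabilistic_esd(esd, 40, seed=s)
            sizes.append(draw.size)
            pooled.update(draw.tolist())
        assert np.mean(sizes) == pytest.approx(40, abs=1.5)
        assert pooled <= set(esd.tolist())

    def test_missing_probabilities_rejected(self):
        props = ProposalSet(np.array([[1.0, 1, 1]]))
        with pytest.raises(ValueError):
            deterministic_subset(props)
        with pytest.raises(ValueError):
            probabilistic_replicates(props)


class TestEnvelopes:
    def test_identical_replicates_collapse(self, rng):
        sample = rng.exponential(3.0, size=200)
        grid = default_grid([sample])
        lower, upper, _ = cdf_envelopes([sample, sample.copy(), sample.copy()], grid)
        np.testing.assert_array_equal(lower, upper)

    def test_every_replicate_inside_envelope(self, rng):
        reps = [rng.exponential(3.0, size=100) for _ in range(10)]
        grid = default_grid(reps)
        lower, upper, cdfs = cdf_envelopes(reps, grid)
        assert (cdfs >= lower - 1e-12).all()
        assert (cdfs <= upper + 1e-12).all()
        assert (lower <= upper).all()

    def test_cdfs_monotone_and_bounded(self, rng):
        sample = rng.gamma(2.0, 2.0, size=400)
        grid = default_grid([sample])
        cdf = kde_cdf(sample, grid)
        assert (np.diff(cdf) >= -1e-12).all()
        assert cdf.min() >= 0 and cdf.max() <= 1

    def test_shifted_replicate_orders_envelope(self, rng):
        base = rng.exponential(3.0, size=300)
        shifted = base + 2.0
        grid = default_grid([base, shifted])
        lower, upper, _ = cdf_envelopes([base, shifted], grid)
        np.testing.assert_allclose(upper, kde_cdf(base, grid), atol=1e-12)
        np.testing.assert_allclose(lower, kde_cdf(shifted, grid), atol=1e-12)

    def test_short_replicates_skipped(self, rng):
        reps = [rng.exponential(3.0, size=50), np.array([1.0]),
                rng.exponential(3.0, size=50)]
        grid = default_grid(reps)
        with pytest.warns(UserWarning):
            _, _, cdfs = cdf_envelopes(reps, grid)
        assert cdfs.shape[0] == 2


class TestSummaryStatistics:
    def test_density_unit_conversion(self):
        structure = np.zeros((100, 100, 100), bool)
        structure[50, 50, 50] = True
        scene = StructureScene(structure, np.ones((100, 100, 100), bool))
        cells = np.random.default_rng(0).uniform(0, 100, size=(100, 3))
        stats = summary_statistics(cells, scene)
        assert stats["density_cells_per_mm3"] == pytest.approx(1e5)

    def test_cells_on_structure_fully_adjacent(self):
        scene = _plane_scene()
        cells = np.array([[3.5, 4.5, 7.5], [10.5, 11.5, 7.5]])
        stats = summary_statistics(cells, scene)
        assert stats["cell_adjacency_pct"] == 100.0

    def test_adjacency_strictly_below_4um(self):
        scene = _plane_scene()
        # voxel center exactly 4.0 um from the plane's voxel centers
        cells = np.array([[10.2, 10.2, 11.5]])
        d = cell_structure_distances(cells, scene)
        assert d[0] == pytest.approx(4.0)
        stats = summary_statistics(cells, scene)
        assert stats["cell_adjacency_pct"] == 0.0
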