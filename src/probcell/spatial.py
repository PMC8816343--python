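"""Point-process characterization of cells relative to segmented structures.

The empty-space distance (ESD) of a structure (e.g. sinusoids or arteries) is
the distance from every tissue background voxel to its nearest structure
voxel; its CDF describes how much volume is available to cells at each
distance.  Comparing the CDF of *cell* distances against the ESD CDF tests
for spatial preference: a cell CDF above the ESD baseline at short distances
indicates attraction to the structure, below it avoidance.

Probabilistic analysis propagates detection uncertainty: each of T replicates
includes every proposal independently with its calibrated probability p, and
the replicate ESD resamples w ~ Pois(N) distances from the empirical ESD
pool.  Pointwise min/max of the replicate CDFs form Monte Carlo envelopes
with significance level alpha = 2 / (T + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import ndtr
from scipy.stats import gaussian_kde

from .points import ProposalSet

__all__ = [
    "StructureScene",
    "SpatialResult",
    "empty_space_distances",
    "cell_structure_distances",
    "deterministic_subset",
    "probabilistic_replicates",
    "probabilistic_esd",
    "kde_cdf",
    "cdf_envelopes",
    "summary_statistics",
    "significance_level",
]

DEFAULT_REPLICATES = 50
DEFAULT_ADJACENCY = 4.0


def significance_level(T: int) -> float:
    """Monte Carlo envelope significance, ``alpha = 2 / (T + 1)``."""
    if T < 1:
        raise ValueError("at least one replicate required")
    return 2.0 / (T + 1)


@dataclass
class StructureScene:
    """Binary structure mask within a tissue mask, both 1 um isotropic."""

    structure_mask: np.ndarray
    tissue_mask: np.ndarray
    name: str = "structure"

    def __post_init__(self) -> None:
        self.structure_mask = np.asarray(self.structure_mask).astype(bool)
        self.tissue_mask = np.asarray(self.tissue_mask).astype(bool)
        if self.structure_mask.shape != self.tissue_mask.shape:
            raise ValueError("structure and tissue masks must share one shape")
        if not self.tissue_mask.any():
            raise ValueError("tissue mask is empty")
        if (self.structure_mask & ~self.tissue_mask).any():
            raise ValueError("structure must be contained in tissue")

    @property
    def background(self) -> np.ndarray:
        """Tissue voxels outside the structure (the ESD sampling domain)."""
        return self.tissue_mask & ~self.structure_mask


def _distance_map(scene: StructureScene) -> np.ndarray:
    if not scene.structure_mask.any():
        raise ValueError("structure mask is empty")
    return ndimage.distance_transform_edt(~scene.structure_mask)


def empty_space_distances(scene: StructureScene) -> np.ndarray:
    """ESD sample: distance of every background voxel to the structure (um)."""
    dist = _distance_map(scene)
    return dist[scene.background]


def cell_structure_distances(cells, scene: StructureScene) -> np.ndarray:
    """Distance of each cell to the nearest structure voxel center.

    Cells inside the structure get 0; cells outside the tissue are excluded
    with a warning.
    """
    coords = np.atleast_2d(np.asarray(getattr(cells, "coords", cells), dtype=float))
    if coords.size == 0:
        return np.empty(0)
    dist = _distance_map(scene)
    vox = np.floor(coords).astype(int)
    vox = np.clip(vox, 0, np.asarray(dist.shape) - 1)
    inside = scene.tissue_mask[tuple(vox.T)]
    if not inside.all():
        warnings.warn(
            f"{int((~inside).sum())} cell(s) outside the tissue mask excluded",
            stacklevel=2,
        )
    return dist[tuple(vox[inside].T)]


def deterministic_subset(proposals: ProposalSet) -> ProposalSet:
    """Proposals with p >= 0.5 (inclusive), the deterministic analysis set."""
    if proposals.probabilities is None:
        raise ValueError("proposals carry no probabilities")
    keep = proposals.probabilities >= 0.5
    return ProposalSet(
        proposals.coords[keep],
        proposals.peak_values[keep],
        proposals.probabilities[keep],
    )


def probabilistic_replicates(
    proposals: ProposalSet,
    T: int = DEFAULT_REPLICATES,
    seed: int = 0,
) -> list[ProposalSet]:
    """T replicate cell sets, each including proposal i with probability p_i."""
    if proposals.probabilities is None:
        raise ValueError("proposals carry no probabilities")
    if T < 1:
        raise ValueError("T must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(T)
    out = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        keep = rng.random(len(proposals)) < proposals.probabilities
        out.append(
            ProposalSet(
                proposals.coords[keep],
                proposals.peak_values[keep],
                proposals.probabilities[keep],
            )
        )
    return out


def probabilistic_esd(esd_sample: np.ndarray, n_cells: int, seed: int = 0) -> np.ndarray:
    """Replicate ESD: draw w ~ Pois(n_cells) distances with replacement."""
    esd_sample = np.asarray(esd_sample, dtype=float)
    if esd_sample.size == 0:
        raise ValueError("empty ESD sample")
    if n_cells < 0:
        raise ValueError("n_cells must be nonnegative")
    rng = np.random.default_rng(seed)
    w = rng.poisson(n_cells)
    return rng.choice(esd_sample, size=w, replace=True)


def kde_cdf(sample: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """CDF of a Gaussian KDE (Scott bandwidth) evaluated on ``grid``.

    The KDE CDF is the mean of Gaussian CDFs centered on the sample points;
    values are clipped to [0, 1].
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < 2:
        raise ValueError("need at least two distances for a KDE")
    bw = gaussian_kde(sample).factor * sample.std(ddof=1)
    if bw == 0:
        return (grid[:, None] >= sample[None, :]).mean(axis=1)
    z = (np.asarray(grid, dtype=float)[:, None] - sample[None, :]) / bw
    return np.clip(ndtr(z).mean(axis=1), 0.0, 1.0)


def empirical_cdf(sample: np.ndarray, grid: np.ndarray) -> np.ndarray:
    sample = np.asarray(sample, dtype=float)
    return (grid[:, None] >= sample[None, :]).mean(axis=1) if sample.size else np.zeros(
        len(grid)
    )


def default_grid(samples, step: float = 0.5) -> np.ndarray:
    """Shared evaluation grid: 0 to the maximum observed distance, 0.5 um steps."""
    dmax = max((float(np.max(s)) for s in samples if len(s)), default=1.0)
    return np.arange(0.0, dmax + step, step)


def cdf_envelopes(replicate_samples, grid: np.ndarray):
    """Pointwise (lower, upper) envelope of per-replicate KDE CDFs.

    Replicates with fewer than two distances are skipped with a warning.
    Returns ``(lower, upper, cdfs)`` where ``cdfs`` stacks the per-replicate
    curves actually used.
    """
    curves = []
    for i, sample in enumerate(replicate_samples):
        sample = np.asarray(sample, dtype=float)
        if sample.size < 2:
            warnings.warn(f"replicate {i} has < 2 distances; skipped", stacklevel=2)
            continue
        curves.append(kde_cdf(sample, grid))
    if len(curves) < 2:
        raise ValueError("need at least two usable replicates for envelopes")
    cdfs = np.vstack(curves)
    return cdfs.min(axis=0), cdfs.max(axis=0), cdfs


def summary_statistics(
    cells,
    scene: StructureScene,
    adjacency_um: float = DEFAULT_ADJACENCY,
) -> dict:
    """Density and adjacency summaries.

    * ``density_cells_per_mm3``: cells per mm^3 of tissue;
    * ``cell_adjacency_pct``: % of cells at structure distance < 4 um (strict);
    * ``volume_adjacency_pct``: % of background voxels with ESD < 4 um.
    """
    tissue_voxels = int(scene.tissue_mask.sum())
    if tissue_voxels == 0:
        raise ValueError("tissue volume is zero")
    coords = np.atleast_2d(np.asarray(getattr(cells, "coords", cells), dtype=float))
    n_cells = 0 if coords.size == 0 else coords.shape[0]
    tissue_mm3 = tissue_voxels * 1e-9  # 1 um^3 voxels
    cell_dist = cell_structure_distances(cells, scene) if n_cells else np.empty(0)
    esd = empty_space_distances(scene)
    return {
        "n_cells": int(n_cells),
        "density_cells_per_mm3": n_cells / tissue_mm3,
        "cell_adjacency_pct": float(
            100.0 * (cell_dist < adjacency_um).mean() if cell_dist.size else 0.0
        ),
        "volume_adjacency_pct": float(100.0 * (esd < adjacency_um).mean()),
    }


@dataclass
class SpatialResult:
    """Bundle of a full spatial analysis (deterministic + probabilistic)."""

    grid: np.ndarray
    esd_cdf: np.ndarray
    cell_cdf: np.ndarray
    esd_envelope: tuple[np.ndarray, np.ndarray] | None
    cell_envelope: tuple[np.ndarray, np.ndarray] | None
    summaries: dict
    T: int
    alpha: float
    replicate_summaries: list[dict] = field(default_factory=list)


def analyze_scene(
    proposals: ProposalSet,
    scene: StructureScene,
    T: int = DEFAULT_REPLICATES,
    seed: int = 0,
    adjacency_um: float = DEFAULT_ADJACENCY,
) -> SpatialResult:
    """End-to-end spatial analysis of probabilistic proposals against a scene."""
    det = deterministic_subset(proposals)
    esd = empty_space_distances(scene)
    cell_dist = cell_structure_distances(det, scene)
    grid = default_grid([esd, cell_dist])
    esd_cdf = kde_cdf(esd, grid)
    cell_cdf = kde_cdf(cell_dist, grid) if cell_dist.size >= 2 else empirical_cdf(
        cell_dist, grid
    )
    replicates = probabilistic_replicates(proposals, T=T, seed=seed)
    rep_seeds = np.random.SeedSequence((seed, 1)).generate_state(T)
    rep_cell = [cell_structure_distances(r, scene) for r in replicates]
    rep_esd = [
        probabilistic_esd(esd, len(r), seed=int(s % (2 ** 31)))
        for r, s in zip(replicates, rep_seeds)
    ]
    cell_env = cdf_envelopes(rep_cell, grid)[:2]
    esd_env = cdf_envelopes(rep_esd, grid)[:2]
    rep_summaries = [summary_statistics(r, scene, adjacency_um) for r in replicates]
    return SpatialResult(
        grid=grid,
        esd_cdf=esd_cdf,
        cell_cdf=cell_cdf,
        esd_envelope=esd_env,
        cell_envelope=cell_env,
        summaries=summary_statistics(det, scene, adjacency_um),
        T=T,
        alpha=significance_level(T),
        replicate_summaries=rep_summaries,
    )
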