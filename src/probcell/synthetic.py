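"""Seeded synthetic volumes, annotations, and structure masks.

The generator emulates the statistical structure the detection pipeline
assumes in a GFP-reporter bone-marrow volume: blob-like fluorescent cells
(isotropic Gaussian intensity profiles with per-cell amplitude variation)
over a dark background with additive Gaussian noise, and tubular vessel-like
structures (random cylinders) inside a tissue mask.  It deliberately omits
microscope physics — no PSF anisotropy, autofluorescence, or attenuation —
so it probes the pipeline's logic, not its robustness to real optics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .points import AnnotationSet
from .spatial import StructureScene

__all__ = [
    "SynthConfig",
    "sample_coordinates",
    "render_volume",
    "render_structures",
    "attraction_scenario",
    "make_sample",
]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic sample.

    Defaults describe a desk-scale volume: a 64^3 um field with 35 cells of
    ~4 um radius (Gaussian blobs, sigma 3 um) spaced at least 9 um apart,
    unit amplitude jittered +-30 %, additive Gaussian noise of SD 0.15
    (optionally depth-varying), and 2 tubular structures of 5 um radius.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    n_cells: int = 35
    min_spacing: float = 9.0
    blob_sigma: float = 3.0
    amplitude: float = 1.0
    amplitude_jitter: float = 0.3
    background: float = 0.0
    noise_sd: float = 0.15
    noise_spatial: bool = False
    n_tubes: int = 2
    tube_radius: float = 5.0
    edge_margin: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if min(self.shape) < 16:
            raise ValueError("volume must be at least 16 voxels per axis")
        if self.min_spacing < 0:
            raise ValueError("spacing must be nonnegative")


def sample_coordinates(config: SynthConfig, rng=None) -> AnnotationSet:
    """Dart-throwing: uniform cell coordinates with enforced pairwise spacing.

    Points are uniform over the interior (an ``edge_margin`` um shell is left
    empty); candidates closer than ``min_spacing`` to an accepted point are
    rejected.  The retry budget is ``10^4 * n_cells``; exhausting it raises,
    suggesting a lower density.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if config.n_cells == 0:
        return AnnotationSet(np.empty((0, 3)), config.shape)
    lo = config.edge_margin
    hi = np.asarray(config.shape, dtype=float) - config.edge_margin
    if (hi <= lo).any():
        raise ValueError("edge margin leaves no interior")
    accepted: list[np.ndarray] = []
    budget = 10_000 * config.n_cells
    spacing2 = config.min_spacing ** 2
    for _ in range(budget):
        cand = rng.uniform(lo, hi)
        if accepted:
            d2 = ((np.asarray(accepted) - cand) ** 2).sum(axis=1)
            if (d2 <= spacing2).any():
                continue
        accepted.append(cand)
        if len(accepted) == config.n_cells:
            break
    else:
        raise RuntimeError(
            "dart-throwing budget exhausted: requested density infeasible for "
            "the spacing; lower n_cells or min_spacing"
        )
    return AnnotationSet(np.asarray(accepted), config.shape)


def render_volume(
    annotations: AnnotationSet, config: SynthConfig, rng=None
) -> np.ndarray:
    """Noisy intensity volume: sum of Gaussian blobs + background + noise.

    Per-cell amplitudes are jittered uniformly by ``+-amplitude_jitter``.
    With ``noise_spatial`` the noise SD ramps linearly from 0.5x to 1.5x of
    ``noise_sd`` along the first axis (depth), emulating depth-dependent
    degradation.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    shape = config.shape
    vol = np.full(shape, float(config.background))
    s2 = 2.0 * config.blob_sigma ** 2
    reach = int(np.ceil(4 * config.blob_sigma))
    for c in annotations.coords:
        amp = config.amplitude * (
            1.0 + rng.uniform(-config.amplitude_jitter, config.amplitude_jitter)
        )
        lo = [max(0, int(np.floor(c[a] - reach))) for a in range(3)]
        hi = [min(shape[a], int(np.ceil(c[a] + reach))) for a in range(3)]
        axes = [np.arange(lo[a], hi[a]) + 0.5 - c[a] for a in range(3)]
        d2 = (
            axes[0][:, None, None] ** 2
            + axes[1][None, :, None] ** 2
            + axes[2][None, None, :] ** 2
        )
        vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amp * np.exp(-d2 / s2)
    if config.noise_sd > 0:
        noise = rng.normal(0.0, 1.0, size=shape)
        if config.noise_spatial:
            ramp = np.linspace(0.5, 1.5, shape[0])[:, None, None]
            noise *= config.noise_sd * ramp
        else:
            noise *= config.noise_sd
        vol += noise
    return vol.astype(np.float32)


def render_structures(config: SynthConfig, rng=None) -> StructureScene:
    """Random tubular structures (cylinders) inside a tissue mask.

    The tissue mask is the full volume minus a 2-voxel shell; each tube is an
    infinite cylinder of ``tube_radius`` through a random interior point with
    a random orientation, clipped to the tissue.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    shape = config.shape
    tissue = np.zeros(shape, dtype=bool)
    tissue[2:-2, 2:-2, 2:-2] = True
    centers = (
        np.stack(
            np.meshgrid(*[np.arange(s) + 0.5 for s in shape], indexing="ij"), axis=-1
        )
    )
    structure = np.zeros(shape, dtype=bool)
    for _ in range(config.n_tubes):
        point = rng.uniform(0.25, 0.75, size=3) * np.asarray(shape)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        rel = centers - point
        along = rel @ direction
        radial2 = (rel ** 2).sum(axis=-1) - along ** 2
        structure |= radial2 <= config.tube_radius ** 2
    structure &= tissue
    return StructureScene(structure, tissue, name="tubes")


def attraction_scenario(
    scene: StructureScene,
    n_cells: int,
    strength: float,
    seed: int = 0,
) -> AnnotationSet:
    """Cells placed with attraction toward the structure.

    Background voxels are sampled without replacement with weight
    ``exp(-distance / strength)``; ``strength -> inf`` recovers uniform
    placement over the background.  Coordinates are jittered uniformly within
    the chosen voxel.
    """
    if strength < 0:
        raise ValueError("strength must be nonnegative")
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    dist = ndimage.distance_transform_edt(~scene.structure_mask)
    bg = scene.background
    idx = np.argwhere(bg)
    d = dist[bg]
    if strength == 0:
        # degenerate limit: only the voxels hugging the structure are eligible
        w = (d == d.min()).astype(float)
    elif np.isinf(strength):
        w = np.ones_like(d)
    else:
        w = np.exp(-d / strength)
    w = w / w.sum()
    if n_cells > idx.shape[0]:
        raise ValueError("more cells requested than background voxels")
    chosen = rng.choice(idx.shape[0], size=n_cells, replace=False, p=w)
    coords = idx[chosen] + rng.uniform(0.0, 1.0, size=(n_cells, 3))
    return AnnotationSet(coords, scene.tissue_mask.shape)


def make_sample(config: SynthConfig):
    """Convenience bundle: ``(annotations, volume, scene)`` for one seed."""
    annotations = sample_coordinates(config)
    volume = render_volume(annotations, config)
    scene = render_structures(config) if config.n_tubes else None
    return annotations, volume, scene
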