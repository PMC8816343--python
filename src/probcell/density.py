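"""Ground-truth density maps and non-maximum-suppression peak detection.

A density map (DM) turns point-wise cell annotations into a smooth regression
target: every annotation deposits an isotropic Gaussian kernel, and kernels
from different annotations are compounded either by summation (``K_sum``, the
classical choice) or by the voxel-wise maximum (``K_max``).  ``K_max`` keeps
each cell's peak at a fixed, known amplitude regardless of how crowded its
neighbourhood is, which is what makes threshold-free peak detection reliable.

Detection is the inverse operation: non-maximum suppression (NMS) picks local
maxima of a DM in descending order of value while suppressing any candidate
closer than a minimum distance (4 um, the average cell radius) to an already
accepted peak.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .points import AnnotationSet, ProposalSet

__all__ = [
    "kernel_value",
    "DensityMap",
    "render_density_map",
    "nms_detect",
    "write_density_map",
    "read_density_map",
]

#: default kernel cutoff radius l_g in um: contributions beyond it are dropped
DEFAULT_CUTOFF = 16.0
#: default NMS suppression radius in um (average cell radius)
DEFAULT_MIN_DISTANCE = 4.0


def kernel_value(s, sigma: float):
    """Normalized 1-D Gaussian ``G_sigma(s) = exp(-s^2 / 2 sigma^2) / (sigma sqrt(2 pi))``.

    ``s`` is a (nonnegative) Euclidean distance in um; scalar or array.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    s = np.asarray(s, dtype=float)
    if (s < 0).any():
        raise ValueError("distances must be nonnegative")
    out = np.exp(-(s ** 2) / (2.0 * sigma ** 2)) / (sigma * math.sqrt(2.0 * math.pi))
    return float(out) if out.ndim == 0 else out


@dataclass
class DensityMap:
    """A 3D density map on a 1 um isotropic grid.

    ``values[i, j, k]`` is the density at the voxel centered on
    ``(i+0.5, j+0.5, k+0.5)`` um.  ``peak_normalized`` maps are divided by
    ``G_sigma(0)`` so an isolated annotation peaks at ~1, making detection
    thresholds expressible as a fraction (0..1) of a single-kernel peak.
    """

    values: np.ndarray
    sigma: float
    compounding: str = "K_max"
    peak_normalized: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("density map must be 3D")
        if self.compounding not in ("K_sum", "K_max"):
            raise ValueError("compounding must be 'K_sum' or 'K_max'")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def _voxel_centers_1d(lo: int, hi: int) -> np.ndarray:
    return np.arange(lo, hi, dtype=float) + 0.5


def render_density_map(
    annotations: AnnotationSet,
    sigma: float,
    compounding: str = "K_max",
    cutoff: float = DEFAULT_CUTOFF,
    peak_normalized: bool = True,
) -> DensityMap:
    """Render the ground-truth DM of an annotation set.

    Per voxel, kernels of all annotations within ``cutoff`` (inclusive) of the
    voxel center are combined by sum (``K_sum``) or maximum (``K_max``);
    voxels farther than ``cutoff`` from every annotation are exactly zero.
    An empty annotation set yields an all-zero map.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if compounding not in ("K_sum", "K_max"):
        raise ValueError("compounding must be 'K_sum' or 'K_max'")
    shape = annotations.volume_shape
    values = np.zeros(shape, dtype=np.float64)
    for c in annotations.coords:
        # bounding window of voxels whose centers may lie within the cutoff
        lo = [max(0, int(math.floor(c[a] - cutoff - 0.5))) for a in range(3)]
        hi = [min(shape[a], int(math.ceil(c[a] + cutoff + 0.5))) for a in range(3)]
        if any(l >= h for l, h in zip(lo, hi)):
            continue
        axes = [_voxel_centers_1d(lo[a], hi[a]) - c[a] for a in range(3)]
        d2 = (
            axes[0][:, None, None] ** 2
            + axes[1][None, :, None] ** 2
            + axes[2][None, None, :] ** 2
        )
        contrib = np.exp(-d2 / (2.0 * sigma ** 2)) / (sigma * math.sqrt(2.0 * math.pi))
        contrib[d2 > cutoff ** 2] = 0.0
        region = values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        if compounding == "K_sum":
            region += contrib
        else:
            np.maximum(region, contrib, out=region)
    if peak_normalized:
        values /= kernel_value(0.0, sigma)
    return DensityMap(values.astype(np.float32), sigma, compounding, peak_normalized)


def _ball_footprint(radius: float) -> np.ndarray:
    """Boolean footprint of integer offsets with 0 < ||d|| < radius (exclusive)."""
    r = int(math.ceil(radius))
    ax = np.arange(-r, r + 1)
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    fp = d2 < radius ** 2
    return fp


def local_maxima_mask(values: np.ndarray, min_distance: float) -> np.ndarray:
    """Voxels that attain the maximum of their exclusive ``min_distance`` ball."""
    fp = _ball_footprint(min_distance)
    filt = ndimage.maximum_filter(values, footprint=fp, mode="constant", cval=-np.inf)
    return values >= filt


def nms_candidates(values: np.ndarray, min_distance: float):
    """Local-maximum candidates sorted by descending value.

    Ties are broken by ascending lexicographic voxel index so the greedy
    selection is deterministic and independent of scan order.  Returns
    ``(idx, vals)``.
    """
    values = np.asarray(values, dtype=float)
    mask = local_maxima_mask(values, min_distance)
    idx = np.argwhere(mask)
    if idx.shape[0] == 0:
        return idx, np.empty(0)
    vals = values[tuple(idx.T)]
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], -vals))
    return idx[order], vals[order]


def greedy_select(idx: np.ndarray, vals: np.ndarray, min_distance: float,
                  threshold: float) -> ProposalSet:
    """Greedy spacing enforcement over pre-sorted candidates above threshold."""
    keep = vals > threshold
    idx, vals = idx[keep], vals[keep]
    if idx.shape[0] == 0:
        return ProposalSet(np.empty((0, 3)), np.empty(0))
    accepted: list[np.ndarray] = []
    accepted_vals: list[float] = []
    min_d2 = min_distance ** 2
    for pt, v in zip(idx.astype(float), vals):
        if accepted:
            d2 = ((np.asarray(accepted) - pt) ** 2).sum(axis=1)
            if (d2 < min_d2).any():
                continue
        accepted.append(pt)
        accepted_vals.append(float(v))
    coords = np.asarray(accepted) + 0.5  # voxel centers
    return ProposalSet(coords, np.asarray(accepted_vals))


def nms_detect(
    dm: DensityMap,
    min_distance: float = DEFAULT_MIN_DISTANCE,
    threshold: float = 0.0,
) -> ProposalSet:
    """Detect cell proposals on a DM by non-maximum suppression.

    Candidate peaks are the local maxima of the map within the (exclusive)
    ``min_distance`` ball; they are visited in descending order of value (ties
    broken by lexicographically smallest voxel index) and accepted unless an
    already accepted peak lies closer than ``min_distance``.  Only candidates
    strictly above ``threshold`` are considered; on a peak-normalized map the
    threshold is a fraction of an isolated kernel's peak, on a raw map it is
    rescaled by ``G_sigma(0)`` so the meaning is unchanged.  Accepted proposals
    are reported at their peak voxel center and carry the peak value.
    """
    if min_distance <= 0:
        raise ValueError("min_distance must be positive")
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    thr = threshold if dm.peak_normalized else threshold * kernel_value(0.0, dm.sigma)
    idx, vals = nms_candidates(dm.values, min_distance)
    return greedy_select(idx, vals, min_distance, thr)


def write_density_map(path: str | Path, dm: DensityMap, voxel_size_um: float = 1.0) -> None:
    """Write a DM as a 32-bit float TIFF stack plus a JSON metadata sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, dm.values.astype(np.float32))
    meta = {
        "sigma_um": dm.sigma,
        "compounding": dm.compounding,
        "peak_normalized": dm.peak_normalized,
        "voxel_size_um": voxel_size_um,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_density_map(path: str | Path) -> DensityMap:
    import tifffile

    path = Path(path)
    values = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return DensityMap(
        values,
        sigma=float(meta["sigma_um"]),
        compounding=meta["compounding"],
        peak_normalized=bool(meta["peak_normalized"]),
    )
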