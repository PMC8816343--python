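"""Volume normalization, overlapped tiling, and global reconstruction.

Large microscopy volumes do not fit a regression CNN in one piece, so they are
cut into overlapping input patches of side ``l_in``.  The network output patch
``l_out = l_in - 2 * conv_margin`` discards a border of convolution-affected
voxels.  Under the ``M_conv`` strategy the whole output patch is kept as the
reconstruction tile; under ``M_peak`` an extra peak margin (4 voxels, the NMS
radius) is cropped per side so that a peak detected near a patch border — whose
true maximum may lie in the neighbouring patch — is attributed to exactly one
tile.  Interior tiles are mutually adjacent; tiles at the sample border are
shifted inward, so their cores may overlap, in which case ownership goes to the
tile with the lexicographically smallest origin.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .points import ProposalSet

__all__ = [
    "TilingPlan",
    "normalize_and_resample",
    "plan_tiles",
    "extract_patch",
    "tile_output_patches",
    "reconstruct_global",
]

#: supplementary M_peak margin per side, in voxels (= um); equals the NMS radius
PEAK_MARGIN = 4


def normalize_and_resample(
    volume: np.ndarray,
    voxel_size_um=(1.0, 1.0, 1.0),
    l_pad=(0, 0, 0),
    *,
    is_mask: bool = False,
) -> np.ndarray:
    """Gaussian-normalize, resample to 1 um isotropic, and zero-pad a volume.

    Normalization (subtract mean, divide by SD, computed before resampling) is
    skipped for masks, which are resampled with nearest-neighbour interpolation
    instead of trilinear.  ``l_pad`` voxels of zeros are added on every face.
    """
    volume = np.asarray(volume)
    voxel_size = np.broadcast_to(np.asarray(voxel_size_um, dtype=float), (3,))
    if (voxel_size <= 0).any():
        raise ValueError("voxel sizes must be positive")
    l_pad = np.broadcast_to(np.asarray(l_pad, dtype=int), (3,))
    if not is_mask:
        vol = volume.astype(np.float64)
        sd = vol.std()
        if sd == 0:
            raise ValueError("constant volume: intensity SD is zero")
        vol = (vol - vol.mean()) / sd
    else:
        vol = volume.astype(np.float32)
    if not np.allclose(voxel_size, 1.0):
        target = np.round(np.array(vol.shape) * voxel_size).astype(int)
        zoom = target / np.array(vol.shape)
        vol = ndimage.zoom(vol, zoom, order=0 if is_mask else 1)
    out = np.pad(vol, [(p, p) for p in l_pad])
    return out.astype(volume.dtype if is_mask else np.float32)


@dataclass
class TilingPlan:
    """Geometry of a tiled decomposition of one sample volume.

    ``tile_origins`` are the origins of the output *core* tiles, expressed in
    the unpadded sample frame (voxels at 1 um).  The input patch for a core at
    origin ``o`` starts at ``o - conv_margin - peak_margin`` in the sample
    frame, i.e. at ``o - conv_margin - peak_margin + l_pad`` in the padded one.
    """

    sample_shape: tuple[int, int, int]
    l_in: tuple[int, int, int]
    conv_margin: tuple[int, int, int]
    margin_mode: str
    peak_margin: tuple[int, int, int]
    l_pad: tuple[int, int, int]
    tile_origins: np.ndarray = field(repr=False)
    axis_origins: tuple[tuple[int, ...], ...] = field(repr=False)

    @property
    def l_out(self) -> tuple[int, ...]:
        return tuple(i - 2 * m for i, m in zip(self.l_in, self.conv_margin))

    @property
    def l_out_tile(self) -> tuple[int, ...]:
        return tuple(o - 2 * p for o, p in zip(self.l_out, self.peak_margin))

    @property
    def n_tiles(self) -> int:
        return len(self.tile_origins)

    def core_bounds(self, t: int) -> tuple[np.ndarray, np.ndarray]:
        """Half-open [lo, hi) core region of tile ``t`` in the sample frame."""
        lo = np.asarray(self.tile_origins[t], dtype=int)
        hi = np.minimum(lo + np.asarray(self.l_out_tile), np.asarray(self.sample_shape))
        return lo, hi

    def input_origin_padded(self, t: int) -> np.ndarray:
        """Origin of tile ``t``'s input patch in the padded frame."""
        lo = np.asarray(self.tile_origins[t], dtype=int)
        return lo - np.asarray(self.conv_margin) - np.asarray(self.peak_margin) + np.asarray(self.l_pad)

    def output_origin_sample(self, t: int) -> np.ndarray:
        """Origin of tile ``t``'s output patch (l_out) in the sample frame."""
        return np.asarray(self.tile_origins[t], dtype=int) - np.asarray(self.peak_margin)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "sample_shape": list(self.sample_shape),
            "l_in": list(self.l_in),
            "l_out": list(self.l_out),
            "l_out_tile": list(self.l_out_tile),
            "conv_margin": list(self.conv_margin),
            "peak_margin": list(self.peak_margin),
            "l_pad": list(self.l_pad),
            "margin_mode": self.margin_mode,
            "tile_origins": self.tile_origins.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _axis_origins(extent: int, step: int) -> tuple[int, ...]:
    """Core-tile origins along one axis: stride ``step``, final origin shifted
    inward so the core never exceeds the sample (border overlap permitted)."""
    if extent <= step:
        return (0,)
    origins = list(range(0, extent - step, step))
    origins.append(extent - step)
    return tuple(origins)


def plan_tiles(
    sample_shape,
    l_in,
    conv_margin,
    margin_mode: str = "M_peak",
    peak_margin: int | tuple = PEAK_MARGIN,
    l_pad=None,
) -> TilingPlan:
    """Lay out core tiles covering ``sample_shape`` for the given geometry.

    ``l_out = l_in - 2 * conv_margin``; ``M_peak`` additionally crops
    ``peak_margin`` voxels per side for the core tile, ``M_conv`` keeps the
    whole output patch as core.  Interior cores are adjacent (stride =
    ``l_out_tile``); the final core per axis is shifted inward.
    """
    if margin_mode not in ("M_conv", "M_peak"):
        raise ValueError("margin_mode must be 'M_conv' or 'M_peak'")
    sample_shape = tuple(int(s) for s in np.broadcast_to(np.asarray(sample_shape), (3,)))
    l_in = tuple(int(s) for s in np.broadcast_to(np.asarray(l_in), (3,)))
    conv_margin = tuple(int(s) for s in np.broadcast_to(np.asarray(conv_margin), (3,)))
    pk = 0 if margin_mode == "M_conv" else peak_margin
    peak_margin = tuple(int(s) for s in np.broadcast_to(np.asarray(pk), (3,)))
    if min(sample_shape) < 1:
        raise ValueError("sample_shape must be at least 1 voxel per axis")
    l_out_tile = [i - 2 * (c + p) for i, c, p in zip(l_in, conv_margin, peak_margin)]
    if min(l_out_tile) < 1:
        raise ValueError("l_in too small for the requested margins")
    if l_pad is None:
        l_pad = tuple(c + p for c, p in zip(conv_margin, peak_margin))
    l_pad = tuple(int(s) for s in np.broadcast_to(np.asarray(l_pad), (3,)))
    if any(lp < c + p for lp, c, p in zip(l_pad, conv_margin, peak_margin)):
        raise ValueError("l_pad must cover conv_margin + peak_margin per side")
    axis_origins = tuple(
        _axis_origins(sample_shape[a], l_out_tile[a]) for a in range(3)
    )
    origins = np.asarray(list(itertools.product(*axis_origins)), dtype=int)
    return TilingPlan(
        sample_shape=sample_shape,
        l_in=l_in,
        conv_margin=conv_margin,
        margin_mode=margin_mode,
        peak_margin=peak_margin,
        l_pad=l_pad,
        tile_origins=origins,
        axis_origins=axis_origins,
    )


def extract_patch(padded_volume: np.ndarray, plan: TilingPlan, t: int) -> np.ndarray:
    """Slice tile ``t``'s input patch (side ``l_in``) out of the padded volume."""
    o = plan.input_origin_padded(t)
    sl = tuple(slice(o[a], o[a] + plan.l_in[a]) for a in range(3))
    patch = padded_volume[sl]
    if patch.shape != tuple(plan.l_in):
        raise ValueError("input patch exceeds the padded volume; increase l_pad")
    return patch


def tile_output_patches(dm_values: np.ndarray, plan: TilingPlan):
    """Yield ``(t, output_patch)`` for a density map given in the sample frame.

    Used when the "prediction" is an already rendered sample-level DM (e.g.
    detection on ground-truth maps): the output patch is the l_out region the
    network would have produced for tile ``t``, zero-padded outside the sample.
    """
    pad = max(max(plan.peak_margin), 1)
    padded = np.pad(np.asarray(dm_values), pad)
    for t in range(plan.n_tiles):
        o = plan.output_origin_sample(t) + pad
        sl = tuple(slice(o[a], o[a] + plan.l_out[a]) for a in range(3))
        yield t, padded[sl]


def reconstruct_global(
    per_tile_proposals: dict[int, ProposalSet] | list[ProposalSet],
    plan: TilingPlan,
) -> ProposalSet:
    """Merge patch-local proposals into one sample-frame proposal set.

    A proposal (given in its tile's output-patch frame, um) is kept iff it
    falls inside its tile's half-open core region; where border cores overlap,
    the tile with the lexicographically smallest origin owns the point.
    """
    if not isinstance(per_tile_proposals, dict):
        per_tile_proposals = dict(enumerate(per_tile_proposals))
    kept_coords, kept_peaks, kept_probs = [], [], []
    have_probs = None
    for t, props in per_tile_proposals.items():
        if len(props) == 0:
            continue
        local = np.atleast_2d(props.coords)
        if (local < 0).any() or (local >= np.asarray(plan.l_out, dtype=float)).any():
            raise ValueError(f"tile {t}: proposal outside its output patch")
        global_coords = local + plan.output_origin_sample(t)
        lo, hi = plan.core_bounds(t)
        inside = ((global_coords >= lo) & (global_coords < hi)).all(axis=1)
        owner = _owner_tile_index(global_coords, plan)
        keep = inside & (owner == t)
        if not keep.any():
            continue
        kept_coords.append(global_coords[keep])
        kept_peaks.append(props.peak_values[keep])
        if props.probabilities is not None:
            kept_probs.append(props.probabilities[keep])
            have_probs = True if have_probs is None else have_probs
        else:
            have_probs = False
    if not kept_coords:
        return ProposalSet(np.empty((0, 3)), np.empty(0))
    coords = np.concatenate(kept_coords)
    peaks = np.concatenate(kept_peaks)
    probs = np.concatenate(kept_probs) if have_probs else None
    return ProposalSet(coords, peaks, probs)


def _owner_tile_index(global_coords: np.ndarray, plan: TilingPlan) -> np.ndarray:
    """Flat index of the lex-smallest tile whose core contains each point."""
    size = plan.l_out_tile
    axis_idx = []
    for a in range(3):
        origins = np.asarray(plan.axis_origins[a])
        x = global_coords[:, a]
        # first (smallest-origin) interval [o, o + size) containing x
        contains = (x[:, None] >= origins[None, :]) & (
            x[:, None] < origins[None, :] + size[a]
        )
        # clip cores at the sample boundary for the single-tile case
        contains |= (x[:, None] >= origins[None, :]) & (
            x[:, None] < min(plan.sample_shape[a], origins[-1] + size[a])
        ) & (np.arange(len(origins))[None, :] == len(origins) - 1)
        idx = np.argmax(contains, axis=1)
        idx[~contains.any(axis=1)] = -1
        axis_idx.append(idx)
    strides = (
        len(plan.axis_origins[1]) * len(plan.axis_origins[2]),
        len(plan.axis_origins[2]),
        1,
    )
    flat = axis_idx[0] * strides[0] + axis_idx[1] * strides[1] + axis_idx[2]
    flat[(axis_idx[0] < 0) | (axis_idx[1] < 0) | (axis_idx[2] < 0)] = -1
    return flat
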