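"""Point containers: ground-truth annotations and detected cell proposals.

Coordinates are continuous positions in micrometres in a 0-based axis system.
Voxel (i, j, k) of a 1 um isotropic grid covers the half-open cell
[i, i+1) x [j, j+1) x [k, k+1) um, so its center sits at (i+0.5, j+0.5, k+0.5).
All distances between grid locations and points are measured between voxel
centers and the continuous coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AnnotationSet", "ProposalSet", "read_points_csv", "write_points_csv"]


@dataclass
class AnnotationSet:
    """Ground-truth cell coordinates within one sample volume.

    Parameters
    ----------
    coords
        ``(n, 3)`` array of continuous positions in um.
    volume_shape
        Extent of the sample grid in voxels at 1 um isotropic resolution.
    sample_id
        Free-form identifier of the sample the annotations belong to.
    """

    coords: np.ndarray
    volume_shape: tuple[int, int, int]
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.size == 0:
            self.coords = np.empty((0, 3), dtype=float)
        if self.coords.shape[1] != 3:
            raise ValueError("annotation coordinates must be (n, 3)")
        self.volume_shape = tuple(int(s) for s in self.volume_shape)
        shape = np.asarray(self.volume_shape, dtype=float)
        if len(self) and ((self.coords < 0).any() or (self.coords >= shape).any()):
            raise ValueError("annotations must lie within [0, volume_shape) um")
        if len(self) > 1:
            # uniqueness of annotated locations
            uniq = np.unique(self.coords, axis=0)
            if uniq.shape[0] != self.coords.shape[0]:
                raise ValueError("annotation coordinates must be unique")

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass
class ProposalSet:
    """Detected cell coordinates with peak values and optional probabilities."""

    coords: np.ndarray
    peak_values: np.ndarray = field(default=None)
    probabilities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.size == 0:
            self.coords = np.empty((0, 3), dtype=float)
        if self.coords.shape[1] != 3:
            raise ValueError("proposal coordinates must be (n, 3)")
        if self.peak_values is None:
            self.peak_values = np.full(len(self), np.nan)
        self.peak_values = np.asarray(self.peak_values, dtype=float).ravel()
        if self.peak_values.shape[0] != len(self):
            raise ValueError("one peak value per proposal required")
        if self.probabilities is not None:
            self.probabilities = np.asarray(self.probabilities, dtype=float).ravel()
            if self.probabilities.shape[0] != len(self):
                raise ValueError("one probability per proposal required")
            if ((self.probabilities < 0) | (self.probabilities > 1)).any():
                raise ValueError("probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def with_probabilities(self, probabilities: np.ndarray) -> "ProposalSet":
        return ProposalSet(self.coords.copy(), self.peak_values.copy(), probabilities)


def write_points_csv(path: str | Path, points, *, with_peak: bool | None = None) -> None:
    """Write an :class:`AnnotationSet` or :class:`ProposalSet` to CSV.

    The on-disk schema is ``x_um,y_um,z_um[,peak,probability]``, one row per
    point, coordinates in the global (unpadded) sample frame.
    """
    coords = np.atleast_2d(np.asarray(points.coords, dtype=float))
    if coords.size == 0:
        coords = np.empty((0, 3))
    data = {"x_um": coords[:, 0], "y_um": coords[:, 1], "z_um": coords[:, 2]}
    peaks = getattr(points, "peak_values", None)
    if peaks is not None and (with_peak or (with_peak is None and np.isfinite(peaks).any())):
        data["peak"] = peaks
    probs = getattr(points, "probabilities", None)
    if probs is not None:
        data["probability"] = probs
    pd.DataFrame(data).to_csv(path, index=False)


def read_points_csv(path: str | Path, *, volume_shape=None, sample_id: str | None = None):
    """Read a point CSV; returns an AnnotationSet if ``volume_shape`` is given,
    else a ProposalSet (peak/probability columns are optional)."""
    df = pd.read_csv(path)
    for col in ("x_um", "y_um", "z_um"):
        if col not in df.columns:
            raise ValueError(f"point CSV misses required column {col!r}")
    coords = df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    if volume_shape is not None:
        return AnnotationSet(coords, tuple(volume_shape), sample_id or Path(path).stem)
    peaks = df["peak"].to_numpy(dtype=float) if "peak" in df.columns else None
    probs = df["probability"].to_numpy(dtype=float) if "probability" in df.columns else None
    return ProposalSet(coords, peaks, probs)
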