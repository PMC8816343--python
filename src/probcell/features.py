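"""Summary-statistic features around cell proposals, and proposal labeling.

Each proposal is described by statistics of the predicted density map (and,
when available, the aleatoric and epistemic uncertainty maps) inside nested
cubic windows of side 4, 8, 16, and 32 um centered on the proposal.  Per map
and window, 14 statistics are collected:

* five percentiles taken uniformly from the 1st to the 99th
  ({1, 25.5, 50, 74.5, 99});
* the fraction of voxels above five thresholds, uniformly spaced over a
  per-map range (by default fractions 0.1..0.9 of the map's global maximum;
  fixed absolute ranges can be configured instead);
* the first four moments: mean, SD, skewness, and excess kurtosis (the last
  two defined as 0 for constant windows).

The feature vector length is therefore ``n_maps * 4 * 14`` (56 for a DM-only
detector, 168 with both uncertainty maps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .evaluation import hungarian_match, DEFAULT_T_MATCH
from .points import AnnotationSet, ProposalSet

__all__ = ["FeatureLayout", "extract_features", "proposal_feature_matrix",
           "label_proposals"]

PERCENTILES = (1.0, 25.5, 50.0, 74.5, 99.0)
DEFAULT_WINDOW_SIZES = (4, 8, 16, 32)
N_STATS = 14


@dataclass
class FeatureLayout:
    """Descriptor of a feature vector's composition (for persistence checks)."""

    maps: tuple[str, ...]
    window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES
    threshold_mode: str = "relative"  # relative to each map's global max
    threshold_ranges: dict = field(default_factory=dict)  # per-map absolute ranges

    @property
    def length(self) -> int:
        return len(self.maps) * len(self.window_sizes) * N_STATS

    def to_dict(self) -> dict:
        return {
            "maps": list(self.maps),
            "window_sizes": list(self.window_sizes),
            "threshold_mode": self.threshold_mode,
            "threshold_ranges": self.threshold_ranges,
        }


def _window(values: np.ndarray, coord: np.ndarray, size: int) -> np.ndarray:
    """Cubic window of side ``size`` um centered on ``coord``, clipped at the
    volume border (only available voxels are used)."""
    center = np.floor(coord).astype(int)
    half = size // 2
    lo = np.maximum(center - half, 0)
    hi = np.minimum(center + half + (size % 2), np.asarray(values.shape))
    return values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]


def _window_stats(win: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    flat = win.ravel().astype(np.float64)
    pct = np.percentile(flat, PERCENTILES)
    exceed = (flat[None, :] > thresholds[:, None]).mean(axis=1)
    mean = flat.mean()
    sd = flat.std()
    if sd > 0:
        skew = stats.skew(flat)
        kurt = stats.kurtosis(flat)
    else:
        skew = kurt = 0.0  # degenerate-window convention
    return np.concatenate([pct, exceed, [mean, sd, skew, kurt]])


def extract_features(
    dm,
    uncertainty=None,
    coord=None,
    window_sizes=DEFAULT_WINDOW_SIZES,
    layout: FeatureLayout | None = None,
) -> tuple[np.ndarray, FeatureLayout]:
    """Feature vector for one proposal coordinate.

    ``dm`` is a DensityMap (or bare 3D array); ``uncertainty`` an optional
    UncertaintyMaps.  Returns ``(vector, layout)``.
    """
    coord = np.asarray(coord, dtype=float)
    values = np.asarray(getattr(dm, "values", dm), dtype=np.float64)
    if (coord < 0).any() or (coord >= np.asarray(values.shape)).any():
        raise ValueError("proposal coordinate lies outside the map")
    maps = {"DM": values}
    if uncertainty is not None:
        maps["u_a"] = np.asarray(uncertainty.aleatoric, dtype=np.float64)
        maps["u_e"] = np.asarray(uncertainty.epistemic, dtype=np.float64)
    if layout is None:
        layout = FeatureLayout(maps=tuple(maps), window_sizes=tuple(window_sizes))
    feats = []
    for name in layout.maps:
        vol = maps[name]
        if layout.threshold_mode == "relative":
            vmax = vol.max()
            thresholds = np.linspace(0.1, 0.9, 5) * (vmax if vmax > 0 else 1.0)
        else:
            lo, hi = layout.threshold_ranges[name]
            thresholds = np.linspace(lo, hi, 5)
        for size in layout.window_sizes:
            feats.append(_window_stats(_window(vol, coord, size), thresholds))
    vec = np.concatenate(feats)
    if not np.isfinite(vec).all():
        raise ValueError("non-finite feature encountered")
    return vec, layout


def proposal_feature_matrix(
    dm, proposals: ProposalSet, uncertainty=None,
    window_sizes=DEFAULT_WINDOW_SIZES, layout: FeatureLayout | None = None,
) -> tuple[np.ndarray, FeatureLayout]:
    """Stack feature vectors for every proposal in a set."""
    rows = []
    for coord in np.atleast_2d(proposals.coords):
        vec, layout = extract_features(dm, uncertainty, coord, window_sizes, layout)
        rows.append(vec)
    if not rows:
        lay = layout or FeatureLayout(
            maps=("DM",) if uncertainty is None else ("DM", "u_a", "u_e"),
            window_sizes=tuple(window_sizes),
        )
        return np.empty((0, lay.length)), lay
    return np.vstack(rows), layout


def write_feature_matrix(path, features: np.ndarray, layout: FeatureLayout) -> None:
    """Persist a feature matrix as CSV with a JSON layout-descriptor sidecar."""
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    pd.DataFrame(np.atleast_2d(features)).to_csv(path, index=False)
    path.with_suffix(".json").write_text(json.dumps(layout.to_dict(), indent=2))


def read_feature_matrix(path) -> tuple[np.ndarray, FeatureLayout]:
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    features = pd.read_csv(path).to_numpy(dtype=float)
    meta = json.loads(path.with_suffix(".json").read_text())
    layout = FeatureLayout(
        maps=tuple(meta["maps"]),
        window_sizes=tuple(meta["window_sizes"]),
        threshold_mode=meta["threshold_mode"],
        threshold_ranges=meta["threshold_ranges"],
    )
    return features, layout


def label_proposals(
    proposals: ProposalSet,
    gt: AnnotationSet,
    t_match: float = DEFAULT_T_MATCH,
) -> np.ndarray:
    """Binary training labels: 1 iff a proposal is Hungarian-matched to a GT
    annotation within ``t_match``; each GT labels at most one proposal."""
    labels = np.zeros(len(proposals), dtype=int)
    match = hungarian_match(gt, proposals)
    for _, pi, dist in match.pairs:
        if dist <= t_match:
            labels[int(pi)] = 1
    return labels
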