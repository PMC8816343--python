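"""End-to-end detection chains and the staged pipeline runner.

The library-level chains are:

* :func:`detect_on_density_volume` — tile a sample-frame density map, run NMS
  per output patch, reconstruct globally (used for detection on ground-truth
  maps and for threshold sweeps);
* :func:`predict_volume` — tile a raw intensity volume, run the regressor per
  patch (optionally with Monte Carlo dropout), assemble sample-frame density
  and uncertainty maps, detect, and reconstruct;
* :func:`classify_proposals` — features + classifier probabilities for a
  reconstructed proposal set.

:func:`run_pipeline` exposes the same chains as file-to-file stages
(simulate | densify | train | detect | classify | evaluate | spatial) with a
JSON provenance record per stage; the CLI is a thin wrapper around it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__ as _version
from .density import (
    DensityMap,
    greedy_select,
    nms_candidates,
    nms_detect,
    render_density_map,
)
from .evaluation import evaluate_detections
from .points import AnnotationSet, ProposalSet, read_points_csv, write_points_csv
from .tiling import (
    TilingPlan,
    extract_patch,
    normalize_and_resample,
    plan_tiles,
    reconstruct_global,
    tile_output_patches,
)

__all__ = [
    "detect_on_density_volume",
    "detection_threshold_sweep",
    "predict_volume",
    "classify_proposals",
    "RunConfig",
    "run_pipeline",
]


def detect_on_density_volume(
    dm: DensityMap,
    plan: TilingPlan,
    min_distance: float = 4.0,
    threshold: float = 0.0,
) -> ProposalSet:
    """Per-patch NMS on a sample-frame DM, reconstructed globally."""
    per_tile = {}
    for t, patch in tile_output_patches(dm.values, plan):
        patch_dm = DensityMap(patch, dm.sigma, dm.compounding, dm.peak_normalized)
        per_tile[t] = nms_detect(patch_dm, min_distance, threshold)
    return reconstruct_global(per_tile, plan)


def detection_threshold_sweep(
    dm: DensityMap,
    plan: TilingPlan,
    thresholds,
    min_distance: float = 4.0,
) -> dict[float, ProposalSet]:
    """As :func:`detect_on_density_volume` for several thresholds, computing
    the per-tile peak candidates only once."""
    tiles = [
        (t, nms_candidates(patch, min_distance))
        for t, patch in tile_output_patches(dm.values, plan)
    ]
    out = {}
    for thr in thresholds:
        per_tile = {
            t: greedy_select(idx, vals, min_distance, thr)
            for t, (idx, vals) in tiles
        }
        out[thr] = reconstruct_global(per_tile, plan)
    return out


def predict_volume(
    volume: np.ndarray,
    model,
    plan: TilingPlan | None = None,
    mc: bool = False,
    mc_samples: int | None = None,
    seed: int = 0,
    min_distance: float = 4.0,
    threshold: float = 0.0,
    l_in: int = 40,
    margin_mode: str = "M_peak",
    normalized: bool = False,
    voxel_size_um=(1.0, 1.0, 1.0),
):
    """Run the regressor over a whole volume.

    ``volume`` is a raw intensity grid in the sample frame; it is normalized,
    resampled to 1 um, padded, tiled, regressed patch-by-patch (Monte Carlo
    dropout when ``mc``), assembled into sample-frame density / uncertainty
    maps (core regions of each tile), then NMS proposals are detected per
    output patch and reconstructed globally.

    Returns ``(proposals, dm, uncertainty)`` in the sample frame.
    """
    from .nn import UncertaintyMaps, predict

    if plan is None:
        plan = plan_tiles(volume.shape, l_in, model.conv_margin,
                          margin_mode=margin_mode)
    padded = (
        np.pad(np.asarray(volume, dtype=np.float32),
               [(p, p) for p in plan.l_pad])
        if normalized
        else normalize_and_resample(volume, voxel_size_um, plan.l_pad)
    )
    shape = plan.sample_shape
    dm_global = np.zeros(shape, dtype=np.float32)
    ua_global = np.zeros(shape, dtype=np.float32)
    ue_global = np.zeros(shape, dtype=np.float32)
    per_tile = {}
    for t in range(plan.n_tiles):
        patch = extract_patch(padded, plan, t)
        dm_t, u_t = predict(model, patch, mc=mc, mc_samples=mc_samples,
                            seed=(seed + 1009 * t) % (2 ** 31))
        lo, hi = plan.core_bounds(t)
        off = lo - plan.output_origin_sample(t)
        sl_core = tuple(slice(lo[a], hi[a]) for a in range(3))
        sl_patch = tuple(slice(off[a], off[a] + hi[a] - lo[a]) for a in range(3))
        dm_global[sl_core] = dm_t.values[sl_patch]
        ua_global[sl_core] = u_t.aleatoric[sl_patch]
        ue_global[sl_core] = u_t.epistemic[sl_patch]
        per_tile[t] = nms_detect(dm_t, min_distance, threshold)
    proposals = reconstruct_global(per_tile, plan)
    dm = DensityMap(dm_global, model.config.sigma, model.config.compounding, True)
    return proposals, dm, UncertaintyMaps(aleatoric=ua_global, epistemic=ue_global)


def classify_proposals(
    proposals: ProposalSet,
    dm: DensityMap,
    classifier,
    uncertainty=None,
) -> ProposalSet:
    """Attach calibrated probabilities to proposals via the feature classifier."""
    from .classifiers import predict_probabilities
    from .features import proposal_feature_matrix

    if len(proposals) == 0:
        return proposals.with_probabilities(np.empty(0))
    feats, _ = proposal_feature_matrix(dm, proposals, uncertainty,
                                       layout=classifier.layout)
    return proposals.with_probabilities(predict_probabilities(classifier, feats))


# ---------------------------------------------------------------------------
# staged runner


@dataclass
class RunConfig:
    """File-level configuration for :func:`run_pipeline` stages."""

    out_dir: str = "."
    volume: str | None = None
    annotations: str | None = None
    structure_mask: str | None = None
    tissue_mask: str | None = None
    model: str | None = None
    classifier: str | None = None
    proposals: str | None = None
    predictions: str | None = None
    sigma: float = 4.0
    compounding: str = "K_max"
    min_distance: float = 4.0
    threshold: float = 0.0
    t_match: float = 4.0
    l_in: int = 40
    margin_mode: str = "M_peak"
    mc: bool = True
    mc_samples: int = 50
    replicates: int = 50
    seed: int = 0
    synth: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)

    @staticmethod
    def from_json(path: str | Path) -> "RunConfig":
        return RunConfig(**json.loads(Path(path).read_text()))


def _provenance(config: RunConfig, stage: str) -> dict:
    blob = json.dumps(
        {k: v for k, v in vars(config).items()}, sort_keys=True, default=str
    )
    return {
        "stage": stage,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.seed,
        "version": _version,
    }


def run_pipeline(config: RunConfig, stage: str) -> dict:
    """Execute one pipeline stage, writing artifacts plus a provenance record.

    Returns a dict of the output paths written.
    """
    import tifffile

    from .density import read_density_map, write_density_map

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def _need(attr: str, producer: str) -> Path:
        value = getattr(config, attr)
        if value is None or not Path(value).exists():
            raise FileNotFoundError(
                f"stage '{stage}' needs '{attr}' "
                f"(missing upstream artifact; run stage '{producer}' first)"
            )
        return Path(value)

    if stage == "simulate":
        from .synthetic import SynthConfig, make_sample

        synth = SynthConfig(**{**config.synth, "seed": config.seed})
        annotations, volume, scene = make_sample(synth)
        tifffile.imwrite(out_dir / "volume.tif", volume)
        write_points_csv(out_dir / "annotations.csv", annotations)
        outputs = {"volume": str(out_dir / "volume.tif"),
                   "annotations": str(out_dir / "annotations.csv")}
        if scene is not None:
            tifffile.imwrite(out_dir / "structure.tif",
                             scene.structure_mask.astype(np.uint8))
            tifffile.imwrite(out_dir / "tissue.tif",
                             scene.tissue_mask.astype(np.uint8))
            outputs["structure_mask"] = str(out_dir / "structure.tif")
            outputs["tissue_mask"] = str(out_dir / "tissue.tif")
    elif stage == "densify":
        vol_path = _need("volume", "simulate")
        shape = tifffile.imread(vol_path).shape
        ann = read_points_csv(_need("annotations", "simulate"), volume_shape=shape)
        dm = render_density_map(ann, config.sigma, config.compounding)
        write_density_map(out_dir / "density.tif", dm)
        outputs = {"density": str(out_dir / "density.tif")}
    elif stage == "train":
        outputs = _stage_train(config, out_dir)
    elif stage == "detect":
        from .nn import load_model

        volume = tifffile.imread(_need("volume", "simulate"))
        model = load_model(_need("model", "train"))
        proposals, dm, unc = predict_volume(
            volume, model, mc=config.mc, mc_samples=config.mc_samples,
            seed=config.seed, min_distance=config.min_distance,
            threshold=config.threshold, l_in=config.l_in,
            margin_mode=config.margin_mode,
        )
        write_points_csv(out_dir / "proposals.csv", proposals, with_peak=True)
        write_density_map(out_dir / "predicted_density.tif", dm)
        tifffile.imwrite(out_dir / "aleatoric.tif", unc.aleatoric)
        tifffile.imwrite(out_dir / "epistemic.tif", unc.epistemic)
        outputs = {"proposals": str(out_dir / "proposals.csv"),
                   "predicted_density": str(out_dir / "predicted_density.tif"),
                   "aleatoric": str(out_dir / "aleatoric.tif"),
                   "epistemic": str(out_dir / "epistemic.tif")}
    elif stage == "classify":
        from .classifiers import ClassifierModel
        from .nn import UncertaintyMaps

        proposals = read_points_csv(_need("proposals", "detect"))
        dm = read_density_map(_need("predictions", "detect"))
        clf = ClassifierModel.load(_need("classifier", "train"))
        unc = None
        pred_dir = Path(config.predictions).parent
        if (pred_dir / "aleatoric.tif").exists():
            unc = UncertaintyMaps(
                aleatoric=tifffile.imread(pred_dir / "aleatoric.tif"),
                epistemic=tifffile.imread(pred_dir / "epistemic.tif"),
            )
        classified = classify_proposals(proposals, dm, clf, unc)
        write_points_csv(out_dir / "proposals_probabilistic.csv", classified,
                         with_peak=True)
        outputs = {"proposals": str(out_dir / "proposals_probabilistic.csv")}
    elif stage == "evaluate":
        gt = np.atleast_2d(read_points_csv(_need("annotations", "simulate")).coords)
        pred = read_points_csv(_need("proposals", "detect or classify"))
        if pred.probabilities is not None:
            # detection counts use the p >= 0.5 positives; calibration is
            # scored over all proposals with their probabilities
            from .evaluation import calibration_scores, hungarian_match
            from .spatial import deterministic_subset

            report = evaluate_detections(
                gt, deterministic_subset(pred), t_match=config.t_match
            )
            report.brier, report.nll = calibration_scores(
                hungarian_match(gt, pred), pred.probabilities, config.t_match
            )
        else:
            report = evaluate_detections(gt, pred, t_match=config.t_match)
        (out_dir / "score_report.json").write_text(
            json.dumps(report.to_dict(), indent=2)
        )
        outputs = {"score_report": str(out_dir / "score_report.json")}
    elif stage == "spatial":
        import pandas as pd

        from .spatial import StructureScene, analyze_scene

        proposals = read_points_csv(_need("proposals", "classify"))
        scene = StructureScene(
            tifffile.imread(_need("structure_mask", "simulate")),
            tifffile.imread(_need("tissue_mask", "simulate")),
        )
        result = analyze_scene(proposals, scene, T=config.replicates,
                               seed=config.seed)
        summary = {
            "alpha": result.alpha,
            "T": result.T,
            "deterministic": result.summaries,
            "probabilistic_mean": {
                k: float(np.mean([r[k] for r in result.replicate_summaries]))
                for k in result.summaries
            },
            "probabilistic_sd": {
                k: float(np.std([r[k] for r in result.replicate_summaries]))
                for k in result.summaries
            },
        }
        (out_dir / "spatial_summary.json").write_text(json.dumps(summary, indent=2))
        pd.DataFrame({
            "distance_um": result.grid,
            "esd_cdf": result.esd_cdf,
            "cell_cdf": result.cell_cdf,
            "esd_lower": result.esd_envelope[0],
            "esd_upper": result.esd_envelope[1],
            "cell_lower": result.cell_envelope[0],
            "cell_upper": result.cell_envelope[1],
        }).to_csv(out_dir / "spatial_curves.csv", index=False)
        outputs = {"spatial_summary": str(out_dir / "spatial_summary.json"),
                   "spatial_curves": str(out_dir / "spatial_curves.csv")}
    else:
        raise ValueError(
            f"unknown stage {stage!r}; expected one of simulate, densify, "
            "train, detect, classify, evaluate, spatial"
        )
    record = _provenance(config, stage)
    record["outputs"] = outputs
    (out_dir / f"provenance_{stage}.json").write_text(json.dumps(record, indent=2))
    return outputs


def _stage_train(config: RunConfig, out_dir: Path) -> dict:
    """Train a regressor (and RF classifier) from simulated samples on disk."""
    import tifffile

    from .classifiers import fit_classifier
    from .features import label_proposals, proposal_feature_matrix
    from .nn import RegressorConfig, save_model, train_regressor

    tcfg = dict(config.train)
    sample_dirs = [Path(p) for p in tcfg.pop("samples", [])]
    if not sample_dirs and config.volume:
        sample_dirs = [Path(config.volume).parent]
    patch_size = int(tcfg.pop("patch_size", 32))
    n_patches = int(tcfg.pop("patches_per_sample", 10))
    fit_rf = bool(tcfg.pop("fit_classifier", False))
    reg_cfg = RegressorConfig(**{**tcfg, "sigma": config.sigma,
                                 "compounding": config.compounding,
                                 "seed": config.seed})
    pairs = []
    samples = []
    rng = np.random.default_rng(config.seed)
    for d in sample_dirs:
        volume = tifffile.imread(d / "volume.tif")
        ann = read_points_csv(d / "annotations.csv", volume_shape=volume.shape)
        dm = render_density_map(ann, config.sigma, config.compounding)
        norm = normalize_and_resample(volume, (1, 1, 1),
                                      (reg_cfg.conv_margin,) * 3)
        samples.append((volume, ann, dm))
        pairs.extend(
            training_patches(norm, dm.values, reg_cfg.conv_margin, patch_size,
                             n_patches, rng)
        )
    n_val = max(1, len(pairs) // 5)
    model, log = train_regressor(reg_cfg, pairs[n_val:], pairs[:n_val])
    save_model(model, out_dir / "model.npz")
    import pandas as pd

    pd.DataFrame(log).to_csv(out_dir / "training_log.csv", index=False)
    outputs = {"model": str(out_dir / "model.npz"),
               "training_log": str(out_dir / "training_log.csv")}
    if fit_rf:
        feats, labels, layout = [], [], None
        for volume, ann, _ in samples:
            props, dm_hat, unc = predict_volume(
                volume, model, mc=config.mc, mc_samples=config.mc_samples,
                seed=config.seed, l_in=config.l_in,
                margin_mode=config.margin_mode,
            )
            f, layout = proposal_feature_matrix(dm_hat, props, unc, layout=layout)
            feats.append(f)
            labels.append(label_proposals(props, ann, config.t_match))
        clf = fit_classifier(np.vstack(feats), np.concatenate(labels),
                             kind="rf", seed=config.seed, layout=layout)
        clf.save(out_dir / "classifier.joblib")
        outputs["classifier"] = str(out_dir / "classifier.joblib")
    return outputs


def training_patches(norm_padded: np.ndarray, dm_values: np.ndarray,
                     conv_margin: int, patch_size: int, n_patches: int, rng):
    """Random (x, y) training pairs from one normalized+padded volume and its
    sample-frame GT density map."""
    pairs = []
    shape = np.asarray(dm_values.shape)
    out_size = patch_size - 2 * conv_margin
    if (shape < out_size).any():
        raise ValueError("volume smaller than one output patch")
    for _ in range(n_patches):
        lo = np.array([rng.integers(0, s - out_size + 1) for s in shape])
        x = norm_padded[
            lo[0]:lo[0] + patch_size,
            lo[1]:lo[1] + patch_size,
            lo[2]:lo[2] + patch_size,
        ]
        y = dm_values[
            lo[0]:lo[0] + out_size,
            lo[1]:lo[1] + out_size,
            lo[2]:lo[2] + out_size,
        ]
        pairs.append((np.asarray(x, dtype=np.float32),
                      np.asarray(y, dtype=np.float32)))
    return pairs
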