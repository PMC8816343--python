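"""Train a small heteroscedastic regressor and calibrate its detections.

A deliberately tiny run (one training volume, few epochs, few Monte Carlo
samples) that walks the full chain: simulate -> density targets -> train ->
tile + MC-dropout predict -> threshold-free NMS -> RF probabilities ->
evaluation.  Expect a few minutes on one CPU; quality improves with the
benchmark-scale settings used in the test suite (3 volumes, 64 epochs).
"""

import numpy as np

import probcell as pc
from probcell.classifiers import fit_classifier
from probcell.evaluation import calibration_scores, evaluate_detections, hungarian_match
from probcell.features import label_proposals, proposal_feature_matrix
from probcell.nn import RegressorConfig, train_regressor
from probcell.pipeline import classify_proposals, predict_volume, training_patches
from probcell.tiling import normalize_and_resample

rng = np.random.default_rng(0)

def make(seed):
    cfg = pc.SynthConfig(seed=seed, n_tubes=0)
    ann = pc.sample_coordinates(cfg)
    return ann, pc.render_volume(ann, cfg)

train_ann, train_vol = make(1)
test_ann, test_vol = make(2)

dm = pc.render_density_map(train_ann, sigma=4.0, compounding="K_max")
norm = normalize_and_resample(train_vol, (1, 1, 1), (8, 8, 8))
pairs = training_patches(norm, dm.values, 8, 32, 12, rng)

cfg = RegressorConfig(base_channels=4, bayes=True, epochs=32, warmup_epochs=12,
                      seed=0, mc_samples=8)
model, log = train_regressor(cfg, pairs[2:], pairs[:2], val_every=4)
print(f"trained {len(log)} epochs; selected epoch {model.best_epoch} "
      f"(val F1 {max(e.get('val_f1', 0) for e in log):.2f})")

# proposals + features from the training volume teach the RF what a cell
# looks like in the predicted maps
props, dm_hat, unc = predict_volume(train_vol, model, mc=True, mc_samples=8,
                                    seed=0, l_in=88, threshold=0.0)
feats, layout = proposal_feature_matrix(dm_hat, props, unc)
labels = label_proposals(props, train_ann)
clf = fit_classifier(feats, labels, "rf", seed=0, layout=layout)

# held-out volume: detect, calibrate, evaluate
props, dm_hat, unc = predict_volume(test_vol, model, mc=True, mc_samples=8,
                                    seed=1, l_in=88, threshold=0.0)
props = classify_proposals(props, dm_hat, clf, unc)
positives = pc.deterministic_subset(props)
report = evaluate_detections(test_ann, positives)
brier, nll = calibration_scores(hungarian_match(test_ann, props),
                                props.probabilities)
print(f"{len(props)} threshold-free proposals -> {len(positives)} cells at "
      f"p >= 0.5 (ground truth: {len(test_ann)})")
print(f"detection: precision {report.precision:.2f} recall {report.recall:.2f} "
      f"F1 {report.f1:.2f}")
print(f"calibration: Brier {brier:.3f}, NLL {nll:.3f} "
      "(0 = perfectly calibrated)")
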