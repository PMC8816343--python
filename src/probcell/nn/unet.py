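"""3D encoder-decoder density-map regressors.

Two variants share one backbone: a deterministic network trained with an L2
loss, and a heteroscedastic ("Bayes") variant whose final layer has two heads,
the density map and a per-voxel aleatoric variance, trained with the
attenuated loss ``sum (y - yhat)^2 / u_a + 0.5 log u_a``.  Epistemic
uncertainty is obtained at inference by Monte Carlo dropout: spatial dropout
(rate 0.2) stays active on every convolutional block except the output layer,
several stochastic passes are drawn, the density and aleatoric outputs are
averaged, and the per-voxel standard deviation of the density samples is the
epistemic map.

The backbone follows a two-level U-Net: C -> MP -> 2C -> MP -> 4C -> UP ->
2C -> UP -> C -> head, where each block is residual with two 3x3x3
convolutions (shortcuts use a 1x1x1 projection when the channel count
changes) and skip connections concatenate encoder features into the decoder.
Convolutions are zero-padded, and the output is cropped by a configurable
convolutional margin per side before any loss or detection is computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import ops
from ..density import DensityMap, nms_detect

__all__ = [
    "RegressorConfig",
    "DensityRegressor",
    "UncertaintyMaps",
    "l2_loss",
    "aleatoric_loss",
    "predict",
    "train_regressor",
    "save_model",
    "load_model",
]

#: floor applied to the aleatoric variance inside the loss (it is singular at 0)
UA_FLOOR = 1e-6
#: additive variance floor in the model head (u = ReLU(raw) + floor); bounds the
#: 1/u gradient amplification of the attenuated loss at desk scale
UA_MODEL_FLOOR = 1e-2


@dataclass
class RegressorConfig:
    """Hyperparameters of the density regressor.

    ``base_channels`` scales the channel widths (C/2C/4C); 16 reproduces the
    reference 16/32/64 architecture, smaller values give desk-scale models.
    """

    base_channels: int = 16
    bayes: bool = False
    dropout_rate: float = 0.2
    mc_samples: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 4
    epochs: int = 50
    seed: int = 0
    conv_margin: int = 8
    sigma: float = 4.0
    compounding: str = "K_max"
    #: epochs trained with plain L2 before enabling the attenuated loss; the
    #: heteroscedastic term otherwise lets the mean drift while the variance
    #: head absorbs the residual. None -> a quarter of the schedule (Bayes only)
    warmup_epochs: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")


@dataclass
class UncertaintyMaps:
    """Aleatoric and epistemic uncertainty grids aligned to a predicted DM."""

    aleatoric: np.ndarray
    epistemic: np.ndarray

    def __post_init__(self) -> None:
        self.aleatoric = np.asarray(self.aleatoric, dtype=np.float32)
        self.epistemic = np.asarray(self.epistemic, dtype=np.float32)
        if self.aleatoric.shape != self.epistemic.shape:
            raise ValueError("uncertainty maps must share one shape")


def l2_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Sum of squared voxel residuals."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError("shape mismatch between target and prediction")
    return float(((y - y_hat) ** 2).sum())


def aleatoric_loss(y: np.ndarray, y_hat: np.ndarray, u_a: np.ndarray) -> float:
    """Heteroscedastic loss ``sum (y - yhat)^2 / u_a + 0.5 ln u_a``.

    ``u_a`` is clamped to a small positive floor; a clamped voxel is reported
    through a logged warning rather than an error.
    """
    import warnings

    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    u_a = np.asarray(u_a, dtype=np.float64)
    if not (y.shape == y_hat.shape == u_a.shape):
        raise ValueError("shape mismatch between target, prediction, and variance")
    if (u_a < UA_FLOOR).any():
        warnings.warn("aleatoric variance clamped to floor", stacklevel=2)
    u = np.clip(u_a, UA_FLOOR, None)
    return float((((y - y_hat) ** 2) / u + 0.5 * np.log(u)).sum())


# ---------------------------------------------------------------------------
# backbone


def _block_params(rng, prefix, c_in, q, params):
    params[f"{prefix}.W1"] = ops.he_init(rng, q, c_in)
    params[f"{prefix}.b1"] = np.zeros(q, dtype=np.float32)
    params[f"{prefix}.W2"] = ops.he_init(rng, q, q)
    params[f"{prefix}.b2"] = np.zeros(q, dtype=np.float32)
    if c_in != q:
        params[f"{prefix}.Wp"] = (
            rng.normal(0.0, np.sqrt(2.0 / c_in), size=(q, c_in)).astype(np.float32)
        )
        params[f"{prefix}.bp"] = np.zeros(q, dtype=np.float32)


def _block_forward(x, params, prefix):
    y1, c1 = ops.conv3d_forward(x, params[f"{prefix}.W1"], params[f"{prefix}.b1"])
    a1, m1 = ops.relu_forward(y1)
    y2, c2 = ops.conv3d_forward(a1, params[f"{prefix}.W2"], params[f"{prefix}.b2"])
    a2, m2 = ops.relu_forward(y2)
    if f"{prefix}.Wp" in params:
        s, cs = ops.proj1x1_forward(x, params[f"{prefix}.Wp"], params[f"{prefix}.bp"])
    else:
        s, cs = x, None
    out, mo = ops.relu_forward(a2 + s)
    return out, (c1, m1, c2, m2, cs, mo)


def _block_backward(dout, cache, params, prefix, grads):
    c1, m1, c2, m2, cs, mo = cache
    dz = ops.relu_backward(dout, mo)
    dy2 = ops.relu_backward(dz, m2)
    da1, dW2, db2 = ops.conv3d_backward(dy2, c2)
    dy1 = ops.relu_backward(da1, m1)
    dx, dW1, db1 = ops.conv3d_backward(dy1, c1)
    grads[f"{prefix}.W1"] = grads.get(f"{prefix}.W1", 0) + dW1
    grads[f"{prefix}.b1"] = grads.get(f"{prefix}.b1", 0) + db1
    grads[f"{prefix}.W2"] = grads.get(f"{prefix}.W2", 0) + dW2
    grads[f"{prefix}.b2"] = grads.get(f"{prefix}.b2", 0) + db2
    if cs is not None:
        dxs, dWp, dbp = ops.proj1x1_backward(dz, cs)
        grads[f"{prefix}.Wp"] = grads.get(f"{prefix}.Wp", 0) + dWp
        grads[f"{prefix}.bp"] = grads.get(f"{prefix}.bp", 0) + dbp
        dx = dx + dxs
    else:
        dx = dx + dz
    return dx


class DensityRegressor:
    """The network: parameters, forward/backward passes, and prediction."""

    def __init__(self, config: RegressorConfig):
        self.config = config
        self.n_out = 2 if config.bayes else 1
        rng = np.random.default_rng(config.seed)
        C = config.base_channels
        p: dict[str, np.ndarray] = {}
        _block_params(rng, "enc0", 1, C, p)
        _block_params(rng, "enc1", C, 2 * C, p)
        _block_params(rng, "bott", 2 * C, 4 * C, p)
        _block_params(rng, "dec1", 6 * C, 2 * C, p)
        _block_params(rng, "dec0", 3 * C, C, p)
        p["head.W"] = ops.he_init(rng, self.n_out, C)
        p["head.b"] = np.zeros(self.n_out, dtype=np.float32)
        if config.bayes:
            p["head.b"][1] = 1.0  # start the variance head away from the ReLU floor
        self.params = p

    @property
    def conv_margin(self) -> int:
        return self.config.conv_margin

    def forward(self, x: np.ndarray, dropout_rng=None):
        """One pass. ``x`` is (D, H, W); dropout is active iff a rng is given.
        Returns the uncropped (n_out, D, H, W) output and the backward cache."""
        x = np.asarray(x, dtype=self.params["head.W"].dtype)
        if x.ndim != 3:
            raise ValueError("input patch must be 3D")
        if any(s % 4 for s in x.shape):
            raise ValueError("input dims must be divisible by 4 (two pooling levels)")
        rate = self.config.dropout_rate
        masks = {}

        def drop(a, name):
            if dropout_rng is None or rate == 0.0:
                return a
            m = ops.spatial_dropout_mask(dropout_rng, a.shape[0], rate)
            masks[name] = m
            return a * m

        p = self.params
        a = x[None]
        e0, ce0 = _block_forward(a, p, "enc0")
        e0d = drop(e0, "enc0")
        p0, cp0 = ops.maxpool2_forward(e0d)
        e1, ce1 = _block_forward(p0, p, "enc1")
        e1d = drop(e1, "enc1")
        p1, cp1 = ops.maxpool2_forward(e1d)
        b, cb = _block_forward(p1, p, "bott")
        bd = drop(b, "bott")
        u1 = ops.upsample2_forward(bd)
        cat1 = np.concatenate([u1, e1d], axis=0)
        d1, cd1 = _block_forward(cat1, p, "dec1")
        d1d = drop(d1, "dec1")
        u0 = ops.upsample2_forward(d1d)
        cat0 = np.concatenate([u0, e0d], axis=0)
        d0, cd0 = _block_forward(cat0, p, "dec0")
        d0d = drop(d0, "dec0")
        out, ch = ops.conv3d_forward(d0d, p["head.W"], p["head.b"])
        cache = (ce0, cp0, ce1, cp1, cb, cd1, cd0, ch, masks,
                 e0.shape[0], b.shape[0], d1.shape[0])
        return out, cache

    def backward(self, dout: np.ndarray, cache) -> dict:
        """Gradients of a scalar loss wrt all parameters, given d(loss)/d(out)."""
        (ce0, cp0, ce1, cp1, cb, cd1, cd0, ch, masks, c_e0, c_b, c_d1) = cache
        p = self.params
        grads: dict[str, np.ndarray] = {}

        def undrop(g, name):
            return g * masks[name] if name in masks else g

        dd0d, dWh, dbh = ops.conv3d_backward(dout, ch)
        grads["head.W"], grads["head.b"] = dWh, dbh
        dd0 = undrop(dd0d, "dec0")
        dcat0 = _block_backward(dd0, cd0, p, "dec0", grads)
        du0, de0d_a = dcat0[: dcat0.shape[0] - c_e0], dcat0[dcat0.shape[0] - c_e0:]
        dd1d = ops.upsample2_backward(du0)
        dd1 = undrop(dd1d, "dec1")
        dcat1 = _block_backward(dd1, cd1, p, "dec1", grads)
        du1, de1d_a = dcat1[:c_b], dcat1[c_b:]
        dbd = ops.upsample2_backward(du1)
        db_ = undrop(dbd, "bott")
        dp1 = _block_backward(db_, cb, p, "bott", grads)
        de1d_b = ops.maxpool2_backward(dp1, cp1)
        de1 = undrop(de1d_a + de1d_b, "enc1")
        dp0 = _block_backward(de1, ce1, p, "enc1", grads)
        de0d_b = ops.maxpool2_backward(dp0, cp0)
        de0 = undrop(de0d_a + de0d_b, "enc0")
        _block_backward(de0, ce0, p, "enc0", grads)
        return grads

    def output(self, x: np.ndarray, dropout_rng=None):
        """Cropped (by conv_margin) density / variance prediction for one patch.
        Returns ``(y_hat, u_a)`` with ``u_a = None`` for the deterministic net."""
        out, _ = self.forward(x, dropout_rng)
        m = self.conv_margin
        sl = (slice(None), slice(m, out.shape[1] - m), slice(m, out.shape[2] - m),
              slice(m, out.shape[3] - m)) if m else (slice(None),)
        out = out[sl]
        y_hat = out[0]
        u_a = (
            np.maximum(out[1], 0.0) + UA_MODEL_FLOOR if self.config.bayes else None
        )
        return y_hat, u_a


def predict(
    model: DensityRegressor,
    x: np.ndarray,
    mc: bool = False,
    mc_samples: int | None = None,
    seed: int = 0,
) -> tuple[DensityMap, UncertaintyMaps]:
    """Predict the DM (and uncertainty maps) for one input patch.

    ``mc=False`` runs a single deterministic pass (dropout off, epistemic map
    zero).  ``mc=True`` draws ``mc_samples`` stochastic passes with dropout
    active: the density and aleatoric maps are voxel-wise means, the epistemic
    map is the voxel-wise SD of the density samples.  Seeded and repeatable.
    """
    cfg = model.config
    if mc:
        n = cfg.mc_samples if mc_samples is None else int(mc_samples)
        if n < 2:
            raise ValueError("mc_samples must be >= 2 for epistemic sampling")
        rng = np.random.default_rng(seed)
        ys, uas = [], []
        for _ in range(n):
            y_hat, u_a = model.output(x, dropout_rng=rng)
            ys.append(y_hat)
            uas.append(u_a)
        ys = np.stack(ys)
        y_mean = ys.mean(axis=0)
        u_e = ys.std(axis=0)
        u_a = np.stack(uas).mean(axis=0) if cfg.bayes else np.zeros_like(y_mean)
    else:
        y_mean, u_a = model.output(x)
        if u_a is None:
            u_a = np.zeros_like(y_mean)
        u_e = np.zeros_like(y_mean)
    dm = DensityMap(y_mean, sigma=cfg.sigma, compounding=cfg.compounding,
                    peak_normalized=True)
    return dm, UncertaintyMaps(aleatoric=u_a, epistemic=u_e)


# ---------------------------------------------------------------------------
# training


def _loss_and_grad(model: DensityRegressor, x, y, dropout_rng, l2_only=False):
    """Loss and d(loss)/d(uncropped output) for one (x, y) pair.

    ``l2_only`` trains the density head with the plain L2 loss and leaves the
    variance head untouched (warm-up phase of the heteroscedastic model).
    """
    out, cache = model.forward(x, dropout_rng)
    m = model.conv_margin
    d, h, w = out.shape[1:]
    crop = (slice(m, d - m), slice(m, h - m), slice(m, w - m)) if m else ()
    y = np.asarray(y, dtype=np.float32)
    y_hat = out[(0,) + tuple(crop)]
    if y_hat.shape != y.shape:
        raise ValueError("target shape must equal the cropped output shape")
    r = y_hat - y
    dout = np.zeros_like(out)
    if model.config.bayes and not l2_only:
        u_raw = out[(1,) + tuple(crop)]
        u = np.maximum(u_raw, 0.0) + UA_MODEL_FLOOR
        loss = float(((r ** 2) / u + 0.5 * np.log(u)).sum())
        dout[(0,) + tuple(crop)] = 2.0 * r / u
        du = (-(r ** 2) / u ** 2 + 0.5 / u) * (u_raw > 0)
        dout[(1,) + tuple(crop)] = du
    else:
        loss = float((r ** 2).sum())
        dout[(0,) + tuple(crop)] = 2.0 * r
    return loss, cache, dout


def _validation_f1(model, val_pairs, thresholds, match_radius=4.0):
    """Best detection F1 over a threshold grid, pooled over validation pairs."""
    from ..evaluation import hungarian_match, classify_detections, detection_scores
    from ..points import AnnotationSet

    counts = {t: [0, 0, 0] for t in thresholds}
    for x, y in val_pairs:
        y_hat, _ = model.output(x)
        dm_pred = DensityMap(y_hat, model.config.sigma, model.config.compounding, True)
        dm_gt = DensityMap(y, model.config.sigma, model.config.compounding, True)
        gt_props = nms_detect(dm_gt, threshold=0.5)
        gt = AnnotationSet(
            np.clip(gt_props.coords, 0, np.array(y.shape) - 1e-6), y.shape
        ) if len(gt_props) else AnnotationSet(np.empty((0, 3)), y.shape)
        for t in thresholds:
            props = nms_detect(dm_pred, threshold=t)
            tp, fp, fn = classify_detections(
                hungarian_match(gt, props), t_match=match_radius
            )
            counts[t][0] += tp
            counts[t][1] += fp
            counts[t][2] += fn
    best_t, best_f1 = thresholds[0], -1.0
    for t in thresholds:
        _, _, f1 = detection_scores(*counts[t])
        if f1 > best_f1:
            best_t, best_f1 = t, f1
    return best_f1, best_t


def train_regressor(config: RegressorConfig, train_pairs, val_pairs=None,
                    val_every: int = 1):
    """Train a regressor on ``(x, y)`` patch pairs with Adam.

    Model selection keeps the epoch with the highest pooled validation F1
    (NMS detections on predicted patches, Hungarian-matched at 4 um against
    peaks of the target patches); without a validation set the final epoch is
    kept.  Returns ``(model, log)`` where ``log`` is a list of per-epoch dicts
    (epoch, mean training loss, validation F1, selected threshold).
    """
    train_pairs = list(train_pairs)
    if not train_pairs:
        raise ValueError("training set is empty")
    model = DensityRegressor(config)
    warmup_epochs = config.warmup_epochs
    if warmup_epochs is None:
        warmup_epochs = config.epochs // 4 if config.bayes else 0
    opt = ops.Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    thresholds = tuple(np.round(np.arange(0.1, 1.0, 0.1), 2))
    log: list[dict] = []
    best = {"f1": -1.0, "params": None, "threshold": None, "epoch": None}
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_pairs))
        losses = []
        warm = epoch < warmup_epochs
        if epoch == warmup_epochs and warmup_epochs > 0:
            # fresh optimizer state and a gentler step for the attenuated loss
            opt = ops.Adam(model.params, lr=config.learning_rate * 0.3)
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            grads_sum: dict[str, np.ndarray] = {}
            for i in batch:
                x, y = train_pairs[i]
                drop_rng = rng if config.dropout_rate > 0 else None
                loss, cache, dout = _loss_and_grad(model, x, y, drop_rng,
                                                   l2_only=warm)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch}"
                    )
                losses.append(loss)
                g = model.backward(dout, cache)
                for k, v in g.items():
                    grads_sum[k] = grads_sum.get(k, 0) + v / len(batch)
            opt.step(model.params, grads_sum)
        entry = {"epoch": epoch, "loss": float(np.mean(losses))}
        if val_pairs and (epoch % val_every == 0 or epoch == config.epochs - 1):
            f1, thr = _validation_f1(model, val_pairs, thresholds)
            entry["val_f1"] = f1
            entry["val_threshold"] = thr
            if f1 >= best["f1"]:
                best = {"f1": f1, "threshold": thr, "epoch": epoch,
                        "params": {k: v.copy() for k, v in model.params.items()}}
        log.append(entry)
    if best["params"] is not None:
        model.params = best["params"]
        model.best_threshold = best["threshold"]
        model.best_epoch = best["epoch"]
    return model, log


def save_model(model: DensityRegressor, path: str | Path) -> None:
    """Persist parameters (npz) with a JSON config sidecar."""
    path = Path(path)
    np.savez(path, **model.params)
    cfg = asdict(model.config)
    cfg["best_threshold"] = getattr(model, "best_threshold", None)
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))


def load_model(path: str | Path) -> DensityRegressor:
    path = Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    best_threshold = cfg.pop("best_threshold", None)
    model = DensityRegressor(RegressorConfig(**cfg))
    with np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path) as data:
        model.params = {k: data[k] for k in data.files}
    if best_threshold is not None:
        model.best_threshold = best_threshold
    return model
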