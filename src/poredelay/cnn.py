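"""LeNet-style convolutional classifier for trace images, with Grad-CAM.

Architecture (two classes: 0 = delay, 1 = non-delay):

    conv(16 filters, 5x5, valid) -> ReLU -> maxpool 2x2
    conv(32 filters, 5x5, valid) -> ReLU -> maxpool 2x2
    flatten -> FC(64) -> ReLU -> FC(2)

Implemented directly on NumPy: im2col convolutions, hand-derived backprop,
Adam, softmax cross-entropy, early stopping on validation loss.  Training
images are standardized by the training-set mean and standard deviation; the
constants are stored on the model and reused at inference and Grad-CAM time.

Grad-CAM: gradients of the target-class logit with respect to the last
convolutional layer's post-ReLU activation maps; channel weights are the
spatially averaged gradients; the heatmap is the rectified weighted sum,
bilinearly upsampled to the input resolution and max-normalized.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, DataError, TrainingError
from .images import TraceImage, render_dataset

__all__ = [
    "CnnSpec",
    "TrainConfig",
    "ModelHandle",
    "Saliency",
    "train",
    "predict",
    "grad_cam",
    "resolution_sweep",
    "CLASS_NAMES",
]

CLASS_NAMES = ("delayed", "non_delayed")  # class 0 = delay, class 1 = non-delay
LABEL_TO_CLASS = {"delayed": 0, "non_delayed": 1}


@dataclass(frozen=True)
class CnnSpec:
    conv_filters: tuple[int, int] = (16, 32)
    kernel_size: int = 5
    pool_size: int = 2
    fc_units: int = 64
    n_classes: int = 2
    input_resolution: int = 56

    def validate(self) -> None:
        if self.n_classes != 2:
            raise ConfigurationError("the classifier is binary (n_classes = 2)")
        if self.spatial_sizes()[-1] < 1:
            raise ConfigurationError(
                f"input resolution {self.input_resolution} collapses below 1 px "
                "after two conv/pool stages"
            )

    def spatial_sizes(self) -> tuple[int, int, int, int]:
        """(after conv1, after pool1, after conv2, after pool2) edge lengths."""
        k, p = self.kernel_size, self.pool_size
        c1 = self.input_resolution - k + 1
        p1 = c1 // p
        c2 = p1 - k + 1
        p2 = c2 // p
        return c1, p1, c2, p2

    @property
    def flat_features(self) -> int:
        return self.conv_filters[1] * self.spatial_sizes()[-1] ** 2

    @property
    def n_parameters(self) -> int:
        f1, f2 = self.conv_filters
        k = self.kernel_size
        return (
            (k * k * 1 + 1) * f1
            + (k * k * f1 + 1) * f2
            + (self.flat_features + 1) * self.fc_units
            + (self.fc_units + 1) * self.n_classes
        )


@dataclass(frozen=True)
class TrainConfig:
    epochs_max: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    early_stop_patience: int = 5
    min_delta: float = 1e-4
    seed: int = 0


@dataclass
class Saliency:
    heatmap: np.ndarray
    target_class: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# layer primitives


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, Ho*Wo, C*k*k) patch matrix."""
    b, c, h, w = x.shape
    v = sliding_window_view(x, (k, k), axis=(2, 3))  # (B, C, Ho, Wo, k, k)
    ho, wo = v.shape[2], v.shape[3]
    return (
        v.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho * wo, c * k * k),
        ho,
        wo,
    )


def _conv_forward(x, W, bias, k):
    cols, ho, wo = _im2col(x, k)
    out = cols @ W + bias  # (B, P, F)
    b = x.shape[0]
    return out.reshape(b, ho, wo, -1).transpose(0, 3, 1, 2), cols


def _conv_backward(dout, cols, W, x_shape, k, need_dx=True):
    b, f = dout.shape[0], dout.shape[1]
    dflat = dout.transpose(0, 2, 3, 1).reshape(b, -1, f)
    ckk = cols.shape[2]
    dW = cols.reshape(-1, ckk).T @ dflat.reshape(-1, f)
    db = dflat.sum(axis=(0, 1))
    dx = None
    if need_dx:
        c_in, h, w = x_shape[1], x_shape[2], x_shape[3]
        pad = k - 1
        dpad = np.pad(dout, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        cols_d, ho2, wo2 = _im2col(dpad, k)  # (B, H*W, F*k*k)
        Wr = (
            W.reshape(c_in, k, k, f)[:, ::-1, ::-1, :]
            .transpose(3, 1, 2, 0)
            .reshape(f * k * k, c_in)
        )
        dx = (cols_d @ Wr).reshape(b, h, w, c_in).transpose(0, 3, 1, 2)
    return dW, db, dx


def _pool_forward(x, p):
    b, c, h, w = x.shape
    hc, wc = h - h % p, w - w % p
    xc = x[:, :, :hc, :wc]
    r = (
        xc.reshape(b, c, hc // p, p, wc // p, p)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(b, c, hc // p, wc // p, p * p)
    )
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape, p)


def _pool_backward(dout, cache):
    idx, x_shape, p = cache
    b, c, h, w = x_shape
    hc, wc = h - h % p, w - w % p
    scat = np.zeros((b, c, hc // p, wc // p, p * p), dtype=dout.dtype)
    np.put_along_axis(scat, idx[..., None], dout[..., None], axis=-1)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, :, :hc, :wc] = (
        scat.reshape(b, c, hc // p, wc // p, p, p)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(b, c, hc, wc)
    )
    return dx


def _init_params(spec: CnnSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    k = spec.kernel_size
    f1, f2 = spec.conv_filters

    def he(fan_in, shape):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(np.float32)

    return {
        "Wc1": he(k * k, (k * k, f1)),
        "bc1": np.zeros(f1, dtype=np.float32),
        "Wc2": he(f1 * k * k, (f1 * k * k, f2)),
        "bc2": np.zeros(f2, dtype=np.float32),
        "Wf1": he(spec.flat_features, (spec.flat_features, spec.fc_units)),
        "bf1": np.zeros(spec.fc_units, dtype=np.float32),
        "Wf2": he(spec.fc_units, (spec.fc_units, spec.n_classes)),
        "bf2": np.zeros(spec.n_classes, dtype=np.float32),
    }


def _forward(params, x, spec: CnnSpec, keep_cache=False):
    k, p = spec.kernel_size, spec.pool_size
    c1, cols1 = _conv_forward(x, params["Wc1"], params["bc1"], k)
    r1 = np.maximum(c1, 0)
    p1, pc1 = _pool_forward(r1, p)
    c2, cols2 = _conv_forward(p1, params["Wc2"], params["bc2"], k)
    r2 = np.maximum(c2, 0)
    p2, pc2 = _pool_forward(r2, p)
    flat = p2.reshape(x.shape[0], -1)
    h_pre = flat @ params["Wf1"] + params["bf1"]
    h = np.maximum(h_pre, 0)
    logits = h @ params["Wf2"] + params["bf2"]
    if not keep_cache:
        return logits, None
    cache = {
        "x": x, "c1": c1, "cols1": cols1, "p1": p1, "pc1": pc1,
        "c2": c2, "cols2": cols2, "r2": r2, "pc2": pc2,
        "flat": flat, "h": h,
    }
    return logits, cache


def _backward(dlogits, cache, params, spec: CnnSpec, upto_conv2=False):
    k = spec.kernel_size
    grads = {}
    grads["Wf2"] = cache["h"].T @ dlogits
    grads["bf2"] = dlogits.sum(axis=0)
    dh = (dlogits @ params["Wf2"].T) * (cache["h"] > 0)
    grads["Wf1"] = cache["flat"].T @ dh
    grads["bf1"] = dh.sum(axis=0)
    dflat = dh @ params["Wf1"].T
    b = dlogits.shape[0]
    f2 = spec.conv_filters[1]
    s = spec.spatial_sizes()[-1]
    dp2 = dflat.reshape(b, f2, s, s)
    dr2 = _pool_backward(dp2, cache["pc2"])  # grad w.r.t. post-ReLU conv2 maps
    if upto_conv2:
        return dr2
    dc2 = dr2 * (cache["c2"] > 0)
    grads["Wc2"], grads["bc2"], dp1 = _conv_backward(
        dc2, cache["cols2"], params["Wc2"], cache["p1"].shape, k, need_dx=True
    )
    dr1 = _pool_backward(dp1, cache["pc1"])
    dc1 = dr1 * (cache["c1"] > 0)
    grads["Wc1"], grads["bc1"], _ = _conv_backward(
        dc1, cache["cols1"], params["Wc1"], cache["x"].shape, k, need_dx=False
    )
    return grads


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model handle


@dataclass
class ModelHandle:
    spec: CnnSpec
    params: dict[str, np.ndarray]
    train_history: list[dict]
    norm_mean: float
    norm_sd: float
    train_config: TrainConfig | None = None

    FORMAT = "poredelay-cnn-v1"

    def save(self, path) -> None:
        meta = {
            "format": self.FORMAT,
            "spec": asdict(self.spec),
            "train_config": asdict(self.train_config) if self.train_config else None,
            "history": self.train_history,
            "norm_mean": self.norm_mean,
            "norm_sd": self.norm_sd,
        }
        np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "ModelHandle":
        with np.load(path) as z:
            meta = json.loads(bytes(z["_meta"]).decode())
            if meta.get("format") != cls.FORMAT:
                raise DataError(f"unknown model format {meta.get('format')!r}")
            params = {k: z[k] for k in z.files if k != "_meta"}
        spec = CnnSpec(
            conv_filters=tuple(meta["spec"]["conv_filters"]),
            kernel_size=meta["spec"]["kernel_size"],
            pool_size=meta["spec"]["pool_size"],
            fc_units=meta["spec"]["fc_units"],
            n_classes=meta["spec"]["n_classes"],
            input_resolution=meta["spec"]["input_resolution"],
        )
        tc = meta.get("train_config")
        return cls(
            spec=spec,
            params=params,
            train_history=meta["history"],
            norm_mean=meta["norm_mean"],
            norm_sd=meta["norm_sd"],
            train_config=TrainConfig(**tc) if tc else None,
        )

    def standardize(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[-1] != self.spec.input_resolution:
            raise DataError(
                f"image resolution {x.shape[-1]} != model resolution "
                f"{self.spec.input_resolution}"
            )
        return (x - self.norm_mean) / self.norm_sd


def _as_class_vector(labels) -> np.ndarray:
    out = []
    for l in labels:
        if isinstance(l, str):
            if l not in LABEL_TO_CLASS:
                raise DataError(f"unknown label {l!r}")
            out.append(LABEL_TO_CLASS[l])
        else:
            out.append(int(l))
    return np.asarray(out, dtype=np.int64)


def train(
    train_images: np.ndarray,
    train_labels,
    val_images: np.ndarray,
    val_labels,
    spec: CnnSpec = CnnSpec(),
    cfg: TrainConfig = TrainConfig(),
) -> ModelHandle:
    """Train the classifier; returns a handle with history and norm constants.

    Minimizes two-class cross-entropy with Adam; early stopping restores the
    parameters of the best validation-loss epoch.  A fixed ``cfg.seed`` fixes
    initialization and batch order.
    """
    spec.validate()
    y_tr = _as_class_vector(train_labels)
    y_va = _as_class_vector(val_labels)
    if len(set(y_tr.tolist())) < 2 or len(set(y_va.tolist())) < 2:
        raise DataError("training and validation sets must contain both classes")

    x_tr = np.asarray(train_images, dtype=np.float32)
    mean = float(x_tr.mean())
    sd = float(x_tr.std())
    if sd == 0:
        raise DataError("training images are constant; cannot standardize")

    handle = ModelHandle(spec, {}, [], mean, sd, cfg)
    x_tr = handle.standardize(train_images)
    x_va = handle.standardize(val_images)

    rng = np.random.default_rng(cfg.seed)
    params = _init_params(spec, rng)
    m_state = {k: np.zeros_like(v) for k, v in params.items()}
    v_state = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t_step = 0

    n = x_tr.shape[0]
    best_loss = np.inf
    best_params = None
    patience_left = cfg.early_stop_patience
    history: list[dict] = []

    for epoch in range(1, cfg.epochs_max + 1):
        order = rng.permutation(n)
        tr_loss = 0.0
        tr_correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            logits, cache = _forward(params, xb, spec, keep_cache=True)
            probs = _softmax(logits)
            tr_loss += float(-np.log(probs[np.arange(len(yb)), yb] + 1e-12).sum())
            tr_correct += int((probs.argmax(axis=1) == yb).sum())
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            grads = _backward(dlogits.astype(np.float32), cache, params, spec)
            t_step += 1
            for key in params:
                g = grads[key].astype(np.float32)
                m_state[key] = beta1 * m_state[key] + (1 - beta1) * g
                v_state[key] = beta2 * v_state[key] + (1 - beta2) * g * g
                mhat = m_state[key] / (1 - beta1**t_step)
                vhat = v_state[key] / (1 - beta2**t_step)
                params[key] = params[key] - cfg.learning_rate * mhat / (
                    np.sqrt(vhat) + eps
                )

        val_logits, _ = _forward(params, x_va, spec)
        val_probs = _softmax(val_logits)
        val_loss = float(
            -np.log(val_probs[np.arange(len(y_va)), y_va] + 1e-12).mean()
        )
        val_acc = float((val_probs.argmax(axis=1) == y_va).mean())
        history.append(
            {
                "epoch": epoch,
                "train_loss": tr_loss / n,
                "train_acc": tr_correct / n,
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if val_loss < best_loss - cfg.min_delta:
            best_loss = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            patience_left = cfg.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    handle.params = best_params if best_params is not None else params
    handle.train_history = history
    return handle


def predict(model: ModelHandle, images: np.ndarray, batch_size: int = 256):
    """Class probabilities and hard labels for a stack of images.

    Returns ``(probs, classes)`` where probs is (n, 2) summing to 1 per row
    and classes are integers (0 = delayed, 1 = non-delayed).  The ROC score
    for the delay class is ``probs[:, 0]``.
    """
    if not model.params:
        raise TrainingError("model has no trained parameters")
    x = model.standardize(images)
    chunks = []
    for start in range(0, x.shape[0], batch_size):
        logits, _ = _forward(model.params, x[start : start + batch_size], model.spec)
        chunks.append(_softmax(logits))
    probs = np.concatenate(chunks, axis=0)
    return probs, probs.argmax(axis=1)


def grad_cam(model: ModelHandle, image, target_class: int) -> Saliency:
    """Grad-CAM saliency for one image at the last convolutional layer."""
    if not model.params:
        raise TrainingError("Grad-CAM requires a trained model")
    if target_class not in (0, 1):
        raise ConfigurationError("target_class must be 0 (delay) or 1 (non-delay)")
    pixels = image.pixels if isinstance(image, TraceImage) else np.asarray(image)
    x = model.standardize(pixels)
    logits, cache = _forward(model.params, x, model.spec, keep_cache=True)
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    dA = _backward(dlogits, cache, model.params, model.spec, upto_conv2=True)[0]
    A = cache["r2"][0]  # (F2, h, w) post-ReLU activation maps
    weights = dA.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * A).sum(axis=0), 0.0)

    res = model.spec.input_resolution
    from scipy.ndimage import map_coordinates

    h, w = cam.shape
    rows = np.linspace(0, h - 1, res)
    cols = np.linspace(0, w - 1, res)
    grid = np.meshgrid(rows, cols, indexing="ij")
    heat = map_coordinates(cam, grid, order=1)
    peak = heat.max()
    if peak <= 0:
        return Saliency(np.zeros((res, res)), target_class, degenerate=True)
    return Saliency(heat / peak, target_class, degenerate=False)


def resolution_sweep(
    train_events,
    val_events,
    test_events,
    resolutions,
    spec: CnnSpec = CnnSpec(),
    cfg: TrainConfig = TrainConfig(),
):
    """Train one model per input resolution and tabulate full metric sets.

    Returns ``(metrics, radar)`` DataFrames indexed by resolution; the radar
    table is the per-metric min-max scaling used for radar-plot comparison.
    """
    import pandas as pd

    from .stats import compute_metrics, confusion, minmax_radar

    if len(resolutions) < 2:
        raise DataError("resolution sweep needs >= 2 resolutions")
    y_test = [ev.label for ev in test_events]
    rows = {}
    for res in resolutions:
        sp = replace(spec, input_resolution=int(res))
        xtr, _ = render_dataset(train_events, res)
        xva, _ = render_dataset(val_events, res)
        xte, _ = render_dataset(test_events, res)
        model = train(xtr, [e.label for e in train_events],
                      xva, [e.label for e in val_events], sp, cfg)
        probs, classes = predict(model, xte)
        preds = [CLASS_NAMES[c] for c in classes]
        ms = compute_metrics(
            confusion(y_test, preds), scores=probs[:, 0], score_labels=y_test
        )
        rows[int(res)] = ms.to_dict()
    metrics = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    metrics.index.name = "resolution"
    radar, _ = minmax_radar(metrics)
    return metrics, radar
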