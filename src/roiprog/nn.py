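"""The convolutional core: shared 3D backbone, softmax head, training loop.

The backbone is the reusable unit of both network stages: five 3x3x3
convolutional layers with ReLU (channels 16, 32, 64, 64, 64 by default), a
stride-2 max-pool after each of the first four layers and a global average
pool after the fifth, mapping a 32^3 patch to a 64-dimensional feature vector
(spatial chain 32 -> 16 -> 8 -> 4 -> 2 -> 1). Convolutions use same-padding
with stride 1, which is the only padding convention under which that chain
closes without cropping. A single fully-connected layer maps the concatenated
branch features to 2 logits with softmax; the positive-class probability is
the network's continuous output score.

The single-ROI network (SRNet) is the K=1 special case of the multi-ROI
network (MRNet): K parallel branches evaluate ONE shared backbone parameter
set on K ROI patches, and the FC input grows to K x 64. Training minimizes
the binary cross-entropy L = -[y log F(M) + (1 - y) log(1 - F(M))] (in its
equivalent two-logit softmax form) with mini-batch Adam; every stochastic
choice (init, split, shuffling) consumes an explicit seed, so runs are
exactly reproducible.

Everything here is plain numpy with hand-written backprop: forward caches per
layer, column-matrix (im2col) convolutions, tie-splitting max-pool gradients.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seeds import derive_seed

__all__ = [
    "BackboneSpec",
    "BackboneParams",
    "MRNetParams",
    "TrainConfig",
    "TrainReport",
    "build_backbone",
    "build_mrnet",
    "backbone_forward",
    "feature_map_sizes",
    "forward_probs",
    "predict_proba",
    "cross_entropy",
    "train_classifier",
    "count_parameters",
    "save_model",
    "load_model",
    "stratified_split",
]

_EPS = 1e-7  # probability clip before log


# --------------------------------------------------------------------------
# specs and parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BackboneSpec:
    """Architecture of the shared feature extractor.

    ``channels`` lists the output channels of each conv layer; a stride-2
    max-pool follows every layer except the last, which is followed by a
    global average pool, so the feature length equals ``channels[-1]``.
    """

    channels: tuple[int, ...] = (16, 32, 64, 64, 64)
    kernel: tuple[int, int, int] = (3, 3, 3)
    n_conv_layers: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(int(c) for c in self.channels))
        n = self.n_conv_layers if self.n_conv_layers is not None else len(self.channels)
        object.__setattr__(self, "n_conv_layers", int(n))
        if len(self.channels) != self.n_conv_layers:
            raise ValueError(
                f"channels list has {len(self.channels)} entries for "
                f"{self.n_conv_layers} conv layers")
        if any(c < 1 for c in self.channels):
            raise ValueError("all channel counts must be >= 1")
        if len(self.kernel) != 3 or any(k < 1 or k % 2 == 0 for k in self.kernel):
            raise ValueError("kernel must be 3 odd extents")

    @property
    def n_pools(self) -> int:
        return self.n_conv_layers - 1

    @property
    def feature_length(self) -> int:
        return self.channels[-1]

    @classmethod
    def reduced(cls) -> "BackboneSpec":
        """A narrow variant for small (16^3) patches and quick screening."""
        return cls(channels=(4, 8, 16, 16, 16))


def feature_map_sizes(spec: BackboneSpec, input_size: int) -> list[int]:
    """Spatial edge length after each conv(+pool) stage, ending at the GAP.

    Same-padding convs preserve size; each of the ``n_pools`` max-pools
    halves it; the final entry (1) is the global average pool output.
    """
    sizes = [int(input_size)]
    s = int(input_size)
    for _ in range(spec.n_pools):
        if s < 2 or s % 2:
            raise ValueError(
                f"input size {input_size} does not survive {spec.n_pools} "
                f"stride-2 pools")
        s //= 2
        sizes.append(s)
    sizes.append(1)
    return sizes


@dataclass
class BackboneParams:
    """Weights of one backbone (the unit shared across MRNet branches)."""

    spec: BackboneSpec
    weights: dict[str, np.ndarray]
    init_seed: int

    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights.values()))


@dataclass
class MRNetParams:
    """K parameter-shared branches plus the concatenating FC head.

    ``backbone`` is a single parameter set evaluated by every branch;
    ``fc_w`` maps the concatenated K x feature_length vector to 2 logits.
    The branch order is ``selected_rois`` and is part of the model contract
    (the FC weights are order-sensitive).
    """

    spec: BackboneSpec
    backbone: dict[str, np.ndarray]
    fc_w: np.ndarray
    fc_b: np.ndarray
    selected_rois: tuple[int, ...]
    init_seed: int

    @property
    def k(self) -> int:
        return len(self.selected_rois)

    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.backbone.values())
                   + self.fc_w.size + self.fc_b.size)

    def copy(self) -> "MRNetParams":
        return MRNetParams(
            spec=self.spec,
            backbone={k: v.copy() for k, v in self.backbone.items()},
            fc_w=self.fc_w.copy(), fc_b=self.fc_b.copy(),
            selected_rois=self.selected_rois, init_seed=self.init_seed)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 8
    epochs: int = 10
    seed: int = 0
    validation_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass
class TrainReport:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_auc: float = float("nan")
    n_train: int = 0
    n_val: int = 0


# --------------------------------------------------------------------------
# initialization
# --------------------------------------------------------------------------

def _init_weights(spec: BackboneSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    kd, kh, kw = spec.kernel
    weights: dict[str, np.ndarray] = {}
    c_in = 1
    for i, c_out in enumerate(spec.channels, start=1):
        fan_in = c_in * kd * kh * kw
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU
        weights[f"W{i}"] = rng.normal(0.0, std, size=(c_out, c_in, kd, kh, kw)
                                      ).astype(np.float32)
        weights[f"b{i}"] = np.zeros(c_out, dtype=np.float32)
        c_in = c_out
    return weights


def build_backbone(spec: BackboneSpec, init_seed: int = 0) -> BackboneParams:
    """Allocate backbone parameters with seeded He-normal initialization."""
    rng = np.random.default_rng(init_seed)
    return BackboneParams(spec=spec, weights=_init_weights(spec, rng),
                          init_seed=int(init_seed))


def build_mrnet(selected_rois, spec: BackboneSpec | None = None,
                init_seed: int = 0) -> MRNetParams:
    """Build a K-branch model over ``selected_rois`` (K=1 is an SRNet)."""
    spec = spec or BackboneSpec()
    rois = tuple(int(r) for r in selected_rois)
    if len(rois) < 1:
        raise ValueError("need at least one selected ROI")
    if len(set(rois)) != len(rois):
        raise ValueError(f"selected ROI labels must be distinct, got {rois}")
    rng = np.random.default_rng(init_seed)
    backbone = _init_weights(spec, rng)
    fc_in = len(rois) * spec.feature_length
    std = np.sqrt(2.0 / fc_in)
    fc_w = rng.normal(0.0, std, size=(fc_in, 2)).astype(np.float32)
    fc_b = np.zeros(2, dtype=np.float32)
    return MRNetParams(spec=spec, backbone=backbone, fc_w=fc_w, fc_b=fc_b,
                       selected_rois=rois, init_seed=int(init_seed))


def build_srnet(roi_label: int, spec: BackboneSpec | None = None,
                init_seed: int = 0) -> MRNetParams:
    return build_mrnet([roi_label], spec=spec, init_seed=init_seed)


def count_parameters(spec: BackboneSpec, k: int = 0) -> int:
    """Closed-form parameter count: conv kernels + biases (+ FC if k >= 1)."""
    kd, kh, kw = spec.kernel
    c_in, total = 1, 0
    for c_out in spec.channels:
        total += kd * kh * kw * c_in * c_out + c_out
        c_in = c_out
    if k >= 1:
        total += k * spec.feature_length * 2 + 2
    return total


# --------------------------------------------------------------------------
# layer forward/backward primitives (float32 throughout)
# --------------------------------------------------------------------------

def _im2col(x: np.ndarray, kd: int) -> np.ndarray:
    # x: (B, C, D, H, W) -> (B*D*H*W, C*kd^3) with same padding
    B, C, D, H, Wd = x.shape
    p = kd // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kd, kd, kd), axis=(2, 3, 4))
    return win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
        B * D * H * Wd, C * kd**3)


def _conv3d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    # x: (B, Cin, D, H, W); same padding, stride 1
    B, Cin, D, H, Wd = x.shape
    kd = W.shape[2]
    cols = _im2col(x, kd)
    out = cols @ W.reshape(W.shape[0], -1).T + b
    out = out.reshape(B, D, H, Wd, -1).transpose(0, 4, 1, 2, 3)
    return np.ascontiguousarray(out), cols


def _conv3d_backward(dout: np.ndarray, cols: np.ndarray, W: np.ndarray,
                     x_shape: tuple):
    B, Cin, D, H, Wd = x_shape
    Cout, _, kd, _, _ = W.shape
    dmat = dout.transpose(0, 2, 3, 4, 1).reshape(-1, Cout)
    dW = (dmat.T @ cols).reshape(W.shape)
    db = dmat.sum(axis=0)
    # dx is the same-padded convolution of dout with the spatially flipped,
    # channel-transposed kernel; reuse the im2col machinery
    Wrot = W[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
    dcols = _im2col(dout, kd)
    dx = (dcols @ Wrot.reshape(Cin, -1).T).reshape(B, D, H, Wd, Cin)
    dx = np.ascontiguousarray(dx.transpose(0, 4, 1, 2, 3))
    return dx, dW.astype(np.float32), db.astype(np.float32)


def _maxpool2_forward(x: np.ndarray):
    B, C, D, H, W = x.shape
    xr = x.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2)
    out = xr.max(axis=(3, 5, 7))
    return out, xr


def _maxpool2_backward(dout: np.ndarray, xr: np.ndarray, pooled: np.ndarray):
    # split gradient evenly across tied maxima (subgradient choice)
    out_e = dout[:, :, :, None, :, None, :, None]
    mask = xr == pooled[:, :, :, None, :, None, :, None]
    counts = mask.sum(axis=(3, 5, 7), keepdims=True)
    dxr = mask * (out_e / counts)
    B, C, D2, _, H2, _, W2, _ = xr.shape
    return dxr.reshape(B, C, D2 * 2, H2 * 2, W2 * 2).astype(np.float32)


def _backbone_forward_batch(weights: dict, spec: BackboneSpec, x: np.ndarray,
                            need_cache: bool = False):
    """x: (B, 1, s, s, s) -> features (B, C_last); optional backprop cache."""
    cache = []
    sizes = [x.shape[2]]
    for i in range(1, spec.n_conv_layers + 1):
        W, b = weights[f"W{i}"], weights[f"b{i}"]
        z, cols = _conv3d_forward(x, W, b)
        a = np.maximum(z, 0.0)
        relu_mask = z > 0
        if i <= spec.n_pools:
            pooled, xr = _maxpool2_forward(a)
        else:
            pooled, xr = a, None
        if need_cache:
            cache.append({"x_shape": x.shape, "cols": cols,
                          "relu_mask": relu_mask, "xr": xr,
                          "pooled": pooled})
        else:
            del cols
        x = pooled
        sizes.append(x.shape[2])
    spatial = x.shape[2] * x.shape[3] * x.shape[4]
    feats = x.mean(axis=(2, 3, 4))  # global average pool
    gap_info = (x.shape, spatial)
    return feats, cache, gap_info, sizes


def _backbone_backward_batch(weights: dict, spec: BackboneSpec,
                             dfeats: np.ndarray, cache: list, gap_info):
    pre_gap_shape, spatial = gap_info
    grads: dict[str, np.ndarray] = {}
    d = (dfeats[:, :, None, None, None] / spatial) * \
        np.ones(pre_gap_shape, dtype=np.float32)
    for i in range(spec.n_conv_layers, 0, -1):
        c = cache[i - 1]
        if c["xr"] is not None:
            d = _maxpool2_backward(d, c["xr"], c["pooled"])
        d = d * c["relu_mask"]
        d, dW, db = _conv3d_backward(d, c["cols"], weights[f"W{i}"],
                                     c["x_shape"])
        grads[f"W{i}"] = dW
        grads[f"b{i}"] = db
    return grads


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# public forward passes
# --------------------------------------------------------------------------

def _as_patch_array(patch) -> np.ndarray:
    data = getattr(patch, "data", patch)
    return np.asarray(data, dtype=np.float32)


def backbone_forward(params, patch, return_sizes: bool = False):
    """Feature vector of one patch; deterministic given params and patch.

    ``params`` may be a :class:`BackboneParams` or an :class:`MRNetParams`
    (whose shared backbone is used). With ``return_sizes`` the per-stage
    spatial edge lengths are returned too.
    """
    if isinstance(params, MRNetParams):
        weights, spec = params.backbone, params.spec
    else:
        weights, spec = params.weights, params.spec
    x = _as_patch_array(patch)
    if x.ndim != 3 or len(set(x.shape)) != 1:
        raise ValueError(f"expected a cubic 3D patch, got shape {x.shape}")
    feature_map_sizes(spec, x.shape[0])  # raises if pooling schedule fails
    feats, _, _, sizes = _backbone_forward_batch(
        weights, spec, x[None, None], need_cache=False)
    vec = feats[0]
    if return_sizes:
        # last conv layer has no pool, so its entry repeats; the global
        # average pool then collapses the map to a single voxel
        return vec, sizes[:-1] + [1]
    return vec


def forward_probs(model: MRNetParams, X: np.ndarray) -> np.ndarray:
    """Class probabilities for a stack of subjects.

    X: (B, K, s, s, s) with branch order matching ``model.selected_rois``.
    Returns (B, 2) softmax probabilities.
    """
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 4:
        X = X[None]
    B, K = X.shape[:2]
    if K != model.k:
        raise ValueError(f"model expects {model.k} patches per subject, got {K}")
    s = X.shape[2]
    flat = X.reshape(B * K, 1, s, s, s)
    feats, _, _, _ = _backbone_forward_batch(model.backbone, model.spec, flat)
    concat = feats.reshape(B, K * model.spec.feature_length)
    logits = concat @ model.fc_w + model.fc_b
    return _softmax(logits)


def predict_proba(model: MRNetParams, X: np.ndarray,
                  batch_size: int = 64) -> np.ndarray:
    """Positive-class probability per subject, evaluated in mini-batches."""
    X = np.asarray(X, dtype=np.float32)
    out = np.empty(X.shape[0], dtype=np.float64)
    for i in range(0, X.shape[0], batch_size):
        out[i:i + batch_size] = forward_probs(model, X[i:i + batch_size])[:, 1]
    return out


def cross_entropy(label: int, p: float) -> float:
    """Binary cross-entropy −[y log p + (1−y) log(1−p)], p clipped to ±1e-7."""
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    p = float(np.clip(p, _EPS, 1.0 - _EPS))
    return float(-(label * np.log(p) + (1 - label) * np.log1p(-p)))


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def stratified_split(y: np.ndarray, validation_fraction: float, seed: int):
    """Per-class random split; both splits keep >= 1 sample of each class."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(idx.size)]
        n_val = int(round(validation_fraction * idx.size))
        n_val = min(max(n_val, 1), idx.size - 1)
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def _batch_loss_and_grads(model: MRNetParams, Xb: np.ndarray, yb: np.ndarray):
    B, K = Xb.shape[:2]
    s = Xb.shape[2]
    flat = Xb.reshape(B * K, 1, s, s, s)
    feats, cache, gap_info, _ = _backbone_forward_batch(
        model.backbone, model.spec, flat, need_cache=True)
    concat = feats.reshape(B, K * model.spec.feature_length)
    logits = concat @ model.fc_w + model.fc_b
    probs = _softmax(logits)
    p_pos = np.clip(probs[:, 1], _EPS, 1.0 - _EPS)
    loss = float(np.mean(-(yb * np.log(p_pos) + (1 - yb) * np.log1p(-p_pos))))
    onehot = np.zeros_like(probs)
    onehot[np.arange(B), yb] = 1.0
    dlogits = ((probs - onehot) / B).astype(np.float32)
    grads = {
        "fc_w": (concat.T @ dlogits).astype(np.float32),
        "fc_b": dlogits.sum(axis=0).astype(np.float32),
    }
    dconcat = dlogits @ model.fc_w.T
    dfeats = dconcat.reshape(B * K, model.spec.feature_length)
    bgrads = _backbone_backward_batch(model.backbone, model.spec, dfeats,
                                      cache, gap_info)
    for k, v in bgrads.items():
        grads[k] = v  # branch gradients already summed over the B*K batch
    return loss, grads


class _Adam:
    def __init__(self, keys, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: 0.0 for k in keys}
        self.v = {k: 0.0 for k in keys}
        self.t = 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)
                          ).astype(np.float32)


def _eval_loss(model: MRNetParams, X, y, batch_size=64) -> float:
    p = predict_proba(model, X, batch_size=batch_size)
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(np.mean(-(y * np.log(p) + (1 - y) * np.log1p(-p))))


def train_classifier(model: MRNetParams, X: np.ndarray, y: np.ndarray,
                     cfg: TrainConfig) -> tuple[MRNetParams, TrainReport]:
    """Mini-batch Adam training of a (possibly multi-branch) patch classifier.

    ``X`` is (N, K, s, s, s) with patches already standardized; ``y`` holds
    the binary labels (subjects with unknown outcome must be excluded
    upstream). The stratified validation split, shuffling and updates are all
    derived from ``cfg.seed``; the same config reproduces the same weights.
    """
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 4:
        X = X[:, None]
    y = np.asarray(y, dtype=np.int64)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of subjects")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(
            f"training needs both classes 0 and 1, got labels {classes.tolist()}")

    model = model.copy()
    tr_idx, va_idx = stratified_split(y, cfg.validation_fraction,
                                     derive_seed(cfg.seed, "split"))
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xva, yva = X[va_idx], y[va_idx]

    params = dict(model.backbone)
    params["fc_w"] = model.fc_w
    params["fc_b"] = model.fc_b
    opt = _Adam(params.keys(), cfg.learning_rate)
    report = TrainReport(n_train=len(tr_idx), n_val=len(va_idx))

    n = Xtr.shape[0]
    for epoch in range(cfg.epochs):
        rng = np.random.default_rng(derive_seed(cfg.seed, "epoch", epoch))
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            loss, grads = _batch_loss_and_grads(model, Xtr[sel], ytr[sel])
            opt.step(params, grads)
            # params dict aliases model arrays except fc which Adam mutates
            model.backbone.update({k: params[k] for k in model.backbone})
            model.fc_w = params["fc_w"]
            model.fc_b = params["fc_b"]
            losses.append(loss)
        report.train_loss.append(float(np.mean(losses)))
        report.val_loss.append(_eval_loss(model, Xva, yva))

    from .screening import compute_auc  # local import to avoid module cycle
    report.val_auc = compute_auc(predict_proba(model, Xva), yva)
    return model, report


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_model(model: MRNetParams, path: str | Path,
               train_config: TrainConfig | None = None) -> Path:
    """Single-file checkpoint: spec, parameters, seeds, training config."""
    path = Path(path)
    meta = {
        "channels": list(model.spec.channels),
        "kernel": list(model.spec.kernel),
        "selected_rois": list(model.selected_rois),
        "init_seed": model.init_seed,
        "train_config": (vars(train_config) if train_config else None),
    }
    arrays = {f"backbone_{k}": v for k, v in model.backbone.items()}
    arrays["fc_w"] = model.fc_w
    arrays["fc_b"] = model.fc_b
    np.savez(path, meta=json.dumps(meta), **arrays)
    # np.savez appends .npz when absent
    return path if str(path).endswith(".npz") else Path(str(path) + ".npz")


def load_model(path: str | Path) -> MRNetParams:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        backbone = {k[len("backbone_"):]: z[k] for k in z.files
                    if k.startswith("backbone_")}
        fc_w, fc_b = z["fc_w"], z["fc_b"]
    spec = BackboneSpec(channels=tuple(meta["channels"]),
                        kernel=tuple(meta["kernel"]))
    return MRNetParams(spec=spec, backbone=backbone, fc_w=fc_w, fc_b=fc_b,
                       selected_rois=tuple(meta["selected_rois"]),
                       init_seed=int(meta["init_seed"]))
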