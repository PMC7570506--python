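"""Compact numpy CNNs for per-pixel patch classification.

Two architectures are provided, matching the two spectral-spatial modelling
strategies:

* **2-D CNN** on PCA score patches (``k x k x d``):
  Conv(20 maps, 5x5, stride 2) → ReLU → MaxPool(2, stride 2) → Dropout →
  FC(C) → Softmax.
* **3-D CNN** on raw spectral patches (``k x k x bands``):
  Conv3D(10 maps, 3x3x10, stride 1) → BatchNorm → ReLU → Dropout →
  FC(C) → Softmax.

Both train with minibatch SGD (momentum 0.9, defaults lr 0.01, 100 epochs,
batch 1024), seeded Glorot-uniform initialization and a seeded shuffler, so
a run is bit-reproducible from its seed.  Convolution is the first layer in
both stacks, so its input gradient is never needed and the im2col matrix of
the training set can be computed once and reused across epochs (bounded by
a configurable memory cap).

All shape arithmetic follows ``out = floor((in - f) / stride) + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from hsipix.core_io import Hypercube, LabelImage
from hsipix.patches import PatchSet, iter_patch_batches

__all__ = ["Cnn2DSpec", "Cnn3DSpec", "TrainConfig", "TrainedNetwork",
           "build", "train", "predict_map", "evaluate_patches"]


def _conv_out(n: int, f: int, s: int) -> int:
    return (n - f) // s + 1


# ---------------------------------------------------------------------------
# Specs


@dataclass
class Cnn2DSpec:
    """2-D score-patch network: Conv → ReLU → MaxPool → Dropout → FC → Softmax."""

    k: int                      # patch window (odd)
    d: int                      # feature depth (number of PCs)
    n_classes: int
    n_filters: int = 20
    filter_size: int = 5
    stride: int = 2
    pool_size: int = 2
    pool_stride: int = 2
    dropout: float = 0.5

    def shape_report(self) -> list[dict]:
        oh = _conv_out(self.k, self.filter_size, self.stride)
        if oh < 1:
            raise ValueError(
                f"conv layer collapses: k={self.k}, filter {self.filter_size}, "
                f"stride {self.stride} gives nonpositive output size {oh}")
        ph = _conv_out(oh, self.pool_size, self.pool_stride)
        if ph < 1:
            raise ValueError(
                f"pool layer collapses: input {oh}, pool {self.pool_size}, "
                f"stride {self.pool_stride} gives nonpositive output size {ph}")
        conv_params = self.filter_size ** 2 * self.d * self.n_filters + self.n_filters
        fc_in = ph * ph * self.n_filters
        fc_params = fc_in * self.n_classes + self.n_classes
        return [
            {"layer": "input", "shape": (self.k, self.k, self.d), "params": 0},
            {"layer": "conv", "shape": (oh, oh, self.n_filters), "params": conv_params},
            {"layer": "relu", "shape": (oh, oh, self.n_filters), "params": 0},
            {"layer": "maxpool", "shape": (ph, ph, self.n_filters), "params": 0},
            {"layer": "dropout", "shape": (fc_in,), "params": 0},
            {"layer": "fc", "shape": (self.n_classes,), "params": fc_params},
            {"layer": "softmax", "shape": (self.n_classes,), "params": 0},
        ]


@dataclass
class Cnn3DSpec:
    """3-D spectral-patch network: Conv3D → BN → ReLU → Dropout → FC → Softmax."""

    k: int
    n_bands: int
    n_classes: int
    n_filters: int = 10
    filter_spatial: int = 3
    filter_spectral: int = 10
    stride: int = 1
    dropout: float = 0.5

    def shape_report(self) -> list[dict]:
        oh = _conv_out(self.k, self.filter_spatial, self.stride)
        ob = _conv_out(self.n_bands, self.filter_spectral, self.stride)
        if oh < 1 or ob < 1:
            raise ValueError(
                f"conv3d layer collapses: ({self.k},{self.k},{self.n_bands}) with "
                f"filter ({self.filter_spatial},{self.filter_spatial},"
                f"{self.filter_spectral}) gives output ({oh},{oh},{ob})")
        conv_params = (self.filter_spatial ** 2 * self.filter_spectral
                       * self.n_filters + self.n_filters)
        fc_in = oh * oh * ob * self.n_filters
        fc_params = fc_in * self.n_classes + self.n_classes
        return [
            {"layer": "input", "shape": (self.k, self.k, self.n_bands), "params": 0},
            {"layer": "conv3d", "shape": (oh, oh, ob, self.n_filters), "params": conv_params},
            {"layer": "batchnorm", "shape": (oh, oh, ob, self.n_filters),
             "params": 2 * self.n_filters},
            {"layer": "relu", "shape": (oh, oh, ob, self.n_filters), "params": 0},
            {"layer": "dropout", "shape": (fc_in,), "params": 0},
            {"layer": "fc", "shape": (self.n_classes,), "params": fc_params},
            {"layer": "softmax", "shape": (self.n_classes,), "params": 0},
        ]


@dataclass
class TrainConfig:
    """SGD training protocol; the seed controls init and shuffling."""

    learning_rate: float = 0.01
    epochs: int = 100
    batch_size: int = 1024
    momentum: float = 0.9
    seed: int = 0
    validation: Optional[PatchSet] = None
    val_every: int = 1                      # epochs between validation passes
    cols_cache_bytes: int = 2_000_000_000   # im2col cache cap for the train set

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


# ---------------------------------------------------------------------------
# im2col


def _im2col_2d(x: np.ndarray, f: int, s: int) -> np.ndarray:
    """(N, k, k, d) → (N, P, f*f*d) patch-column matrix."""
    v = np.lib.stride_tricks.sliding_window_view(x, (f, f), axis=(1, 2))
    v = v[:, ::s, ::s]                       # (N, oh, ow, d, f, f)
    N, oh, ow = v.shape[:3]
    # channel-last inside each column: (f, f, d)
    v = v.transpose(0, 1, 2, 4, 5, 3).reshape(N, oh * ow, -1)
    return np.ascontiguousarray(v)


def _im2col_3d(x: np.ndarray, f: int, fb: int, s: int) -> np.ndarray:
    """(N, k, k, bands) → (N, P, f*f*fb) with the band axis convolved too."""
    v = np.lib.stride_tricks.sliding_window_view(x, (f, f, fb), axis=(1, 2, 3))
    v = v[:, ::s, ::s, ::s]                  # (N, oh, ow, ob, f, f, fb)
    N, oh, ow, ob = v.shape[:4]
    v = v.reshape(N, oh * ow * ob, -1)
    return np.ascontiguousarray(v)


# ---------------------------------------------------------------------------
# Network


class _Network:
    """Weights + forward/backward for either architecture."""

    def __init__(self, spec: Union[Cnn2DSpec, Cnn3DSpec], rng: np.random.Generator):
        self.spec = spec
        self.report = spec.shape_report()
        self.is_3d = isinstance(spec, Cnn3DSpec)
        if self.is_3d:
            L = spec.filter_spatial ** 2 * spec.filter_spectral
        else:
            L = spec.filter_size ** 2 * spec.d
        F = spec.n_filters
        # FC input size from the report (the dropout entry carries it flattened)
        self.fc_in = int(np.prod([r for r in self.report if r["layer"] == "dropout"][0]["shape"]))
        C = spec.n_classes
        self.W1 = self._glorot(rng, (L, F))
        self.b1 = np.zeros(F, dtype=np.float32)
        self.W2 = self._glorot(rng, (self.fc_in, C))
        self.b2 = np.zeros(C, dtype=np.float32)
        if self.is_3d:
            self.gamma = np.ones(F, dtype=np.float32)
            self.beta = np.zeros(F, dtype=np.float32)
            self.run_mean = np.zeros(F, dtype=np.float32)
            self.run_var = np.ones(F, dtype=np.float32)
        self._vel = {}

    @staticmethod
    def _glorot(rng: np.random.Generator, shape: tuple) -> np.ndarray:
        limit = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-limit, limit, size=shape).astype(np.float32)

    # -- columns -----------------------------------------------------------

    def im2col(self, patches: np.ndarray) -> np.ndarray:
        x = patches.astype(np.float32, copy=False)
        if self.is_3d:
            return _im2col_3d(x, self.spec.filter_spatial,
                              self.spec.filter_spectral, self.spec.stride)
        return _im2col_2d(x, self.spec.filter_size, self.spec.stride)

    # -- forward -----------------------------------------------------------

    def forward(self, cols: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Columns → class probabilities; caches intermediates when training."""
        N, P, L = cols.shape
        z1 = (cols.reshape(N * P, L) @ self.W1).reshape(N, P, -1) + self.b1
        cache = {"cols": cols}
        if self.is_3d:
            if training:
                mu = z1.mean(axis=(0, 1))
                var = z1.var(axis=(0, 1))
                self.run_mean = 0.9 * self.run_mean + 0.1 * mu.astype(np.float32)
                self.run_var = 0.9 * self.run_var + 0.1 * var.astype(np.float32)
            else:
                mu, var = self.run_mean, self.run_var
            inv = (1.0 / np.sqrt(var + 1e-5)).astype(np.float32)
            # fused affine: gamma * (z - mu) * inv + beta
            scale = self.gamma * inv
            cache.update(z_pre=z1, mu=mu, inv=inv)
            z1 = z1 * scale + (self.beta - mu * scale)
        relu = np.maximum(z1, 0.0)
        cache["relu_mask"] = z1 > 0
        flat = relu.reshape(N, -1)
        if training and self.spec.dropout > 0:
            keep = np.float32(1.0 - self.spec.dropout)
            drop = rng.random(flat.shape, dtype=np.float32) < keep
            flat = flat * drop / keep
            cache["drop"] = drop
            cache["keep"] = keep
        cache["flat"] = flat
        logits = flat @ self.W2 + self.b2
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        self._cache = cache if training else None
        return probs

    def backward(self, probs: np.ndarray, y_idx: np.ndarray) -> dict:
        """Cross-entropy gradient w.r.t. all parameters (conv dX skipped:
        convolution is the first layer)."""
        c = self._cache
        N = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(N), y_idx] -= 1.0
        dlogits /= N
        grads = {"W2": c["flat"].T @ dlogits, "b2": dlogits.sum(axis=0)}
        dflat = dlogits @ self.W2.T
        if "drop" in c:
            dflat = dflat * c["drop"] / c["keep"]
        P = c["relu_mask"].shape[1]
        dz1 = dflat.reshape(N, P, -1) * c["relu_mask"]
        if self.is_3d:
            m = N * P
            inv = c["inv"]
            xhat = (c["z_pre"] - c["mu"]) * inv
            grads["gamma"] = (dz1 * xhat).sum(axis=(0, 1))
            grads["beta"] = dz1.sum(axis=(0, 1))
            dxhat = dz1 * self.gamma
            dz1 = (inv / m) * (m * dxhat - dxhat.sum(axis=(0, 1))
                               - xhat * (dxhat * xhat).sum(axis=(0, 1)))
        cols = c["cols"]
        L = cols.shape[2]
        grads["W1"] = cols.reshape(N * P, L).T @ dz1.reshape(N * P, -1)
        grads["b1"] = dz1.sum(axis=(0, 1))
        return grads

    def sgd_step(self, grads: dict, lr: float, momentum: float) -> None:
        for name, g in grads.items():
            v = self._vel.get(name)
            if v is None:
                v = np.zeros_like(g, dtype=np.float32)
            v = momentum * v - lr * g.astype(np.float32)
            self._vel[name] = v
            param = getattr(self, name)
            setattr(self, name, (param + v).astype(np.float32))

    def params(self) -> dict:
        names = ["W1", "b1", "W2", "b2"]
        if self.is_3d:
            names += ["gamma", "beta", "run_mean", "run_var"]
        return {n: getattr(self, n) for n in names}


class _Pooled2D(_Network):
    """2-D variant with the max-pool layer between ReLU and dropout."""

    def forward(self, cols: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        N, P, L = cols.shape
        spec: Cnn2DSpec = self.spec
        oh = _conv_out(spec.k, spec.filter_size, spec.stride)
        z1 = ((cols.reshape(N * P, L) @ self.W1) + self.b1
              ).reshape(N, oh, oh, spec.n_filters)
        relu = np.maximum(z1, 0.0)
        p, s = spec.pool_size, spec.pool_stride
        v = np.lib.stride_tricks.sliding_window_view(relu, (p, p), axis=(1, 2))
        v = v[:, ::s, ::s]                            # (N, ph, pw, F, p, p)
        ph, pw = v.shape[1], v.shape[2]
        vflat = v.reshape(N, ph, pw, spec.n_filters, p * p)
        arg = vflat.argmax(axis=-1)
        pooled = np.take_along_axis(vflat, arg[..., None], axis=-1)[..., 0]
        cache = {"cols": cols, "relu_mask": z1 > 0, "arg": arg,
                 "conv_shape": (oh, oh)}
        flat = pooled.reshape(N, -1)
        if training and spec.dropout > 0:
            keep = np.float32(1.0 - spec.dropout)
            drop = rng.random(flat.shape, dtype=np.float32) < keep
            flat = flat * drop / keep
            cache["drop"] = drop
            cache["keep"] = keep
        cache["flat"] = flat
        logits = flat @ self.W2 + self.b2
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        self._cache = cache if training else None
        return probs

    def backward(self, probs: np.ndarray, y_idx: np.ndarray) -> dict:
        c = self._cache
        spec: Cnn2DSpec = self.spec
        N = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(N), y_idx] -= 1.0
        dlogits /= N
        grads = {"W2": c["flat"].T @ dlogits, "b2": dlogits.sum(axis=0)}
        dflat = dlogits @ self.W2.T
        if "drop" in c:
            dflat = dflat * c["drop"] / c["keep"]
        oh, ow = c["conv_shape"]
        F = spec.n_filters
        arg = c["arg"]                                 # (N, ph, pw, F)
        ph, pw = arg.shape[1], arg.shape[2]
        dpool = dflat.reshape(N, ph, pw, F)
        # scatter pooled gradients back to the argmax positions
        p, s = spec.pool_size, spec.pool_stride
        drelu = np.zeros((N, oh, ow, F), dtype=np.float32)
        ni, pi, pj, fi = np.indices(arg.shape, sparse=False)
        ri = pi * s + arg // p
        ci = pj * s + arg % p
        np.add.at(drelu, (ni, ri, ci, fi), dpool)
        dz1 = drelu * c["relu_mask"]
        dz1 = dz1.reshape(N, oh * ow, F)
        cols = c["cols"]
        L = cols.shape[2]
        grads["W1"] = cols.reshape(N * oh * ow, L).T @ dz1.reshape(N * oh * ow, F)
        grads["b1"] = dz1.sum(axis=(0, 1))
        return grads


# ---------------------------------------------------------------------------
# Public API


@dataclass
class TrainedNetwork:
    """Fitted network with spec, class names, seed, and training history."""

    net: _Network
    class_ids: np.ndarray
    class_names: Sequence[str]
    seed: int
    history: dict = field(default_factory=dict)

    @property
    def spec(self):
        return self.net.spec

    def _eval_batch_size(self) -> int:
        # keep the im2col footprint of one inference batch near 64 MB
        probe = self.net.im2col(np.zeros((1,) + self._patch_shape(), np.float32))
        per_sample = probe.shape[1] * probe.shape[2] * 4
        return max(32, int(64e6 // per_sample))

    def _patch_shape(self) -> tuple:
        s = self.spec
        depth = s.n_bands if self.net.is_3d else s.d
        return (s.k, s.k, depth)

    def predict_proba_patches(self, patches: np.ndarray,
                              batch_size: Optional[int] = None) -> np.ndarray:
        batch_size = batch_size or self._eval_batch_size()
        out = []
        for start in range(0, len(patches), batch_size):
            cols = self.net.im2col(patches[start:start + batch_size])
            out.append(self.net.forward(cols, training=False))
        return np.concatenate(out, axis=0)

    def predict_patches(self, patches: np.ndarray) -> np.ndarray:
        return self.class_ids[np.argmax(self.predict_proba_patches(patches), axis=1)]

    def history_frame(self):
        """Training curves as a DataFrame (CSV-exportable)."""
        import pandas as pd

        h = self.history
        return pd.DataFrame({"iteration": np.arange(1, len(h["train_loss"]) + 1),
                             "train_loss": h["train_loss"],
                             "train_accuracy": h["train_acc"]})

    def save(self, path) -> None:
        spec = self.spec
        meta = dict(spec.__dict__)
        np.savez_compressed(
            path, _kind=np.asarray("3d" if self.net.is_3d else "2d"),
            _seed=self.seed, _class_ids=self.class_ids,
            _class_names=np.asarray(list(self.class_names), dtype=object),
            _spec=np.asarray(list(meta.items()), dtype=object),
            _hist_train_loss=np.asarray(self.history.get("train_loss", [])),
            _hist_train_acc=np.asarray(self.history.get("train_acc", [])),
            _hist_val_acc=np.asarray(self.history.get("val_acc", [])),
            _hist_val_loss=np.asarray(self.history.get("val_loss", [])),
            **self.net.params())

    @staticmethod
    def load(path) -> "TrainedNetwork":
        with np.load(path, allow_pickle=True) as z:
            kind = str(z["_kind"])
            spec_items = {k: v for k, v in z["_spec"]}
            def num(x):
                f = float(x)
                return int(f) if f == int(f) and "." not in str(x) else f
            spec_kw = {k: num(v) for k, v in spec_items.items()}
            spec = Cnn3DSpec(**spec_kw) if kind == "3d" else Cnn2DSpec(**spec_kw)
            tn = build(spec, seed=0)
            for name in tn.net.params():
                setattr(tn.net, name, z[name])
            tn.class_ids = z["_class_ids"]
            tn.class_names = list(z["_class_names"])
            tn.seed = int(z["_seed"])
            tn.history = {"train_loss": z["_hist_train_loss"],
                          "train_acc": z["_hist_train_acc"],
                          "val_acc": z["_hist_val_acc"],
                          "val_loss": z["_hist_val_loss"]}
            return tn


def build(spec: Union[Cnn2DSpec, Cnn3DSpec], seed: int = 0) -> TrainedNetwork:
    """Instantiate an untrained network; ``.net.report`` is the shape report.

    Raises at build time if any layer's output dimension is nonpositive.
    """
    spec.shape_report()  # validates
    rng = np.random.default_rng(seed)
    net = _Pooled2D(spec, rng) if isinstance(spec, Cnn2DSpec) else _Network(spec, rng)
    return TrainedNetwork(net=net, class_ids=np.arange(1, spec.n_classes + 1),
                          class_names=[], seed=seed)


def train(network: TrainedNetwork, train_patches: PatchSet,
          config: TrainConfig, class_names: Sequence[str] = ()) -> TrainedNetwork:
    """Minibatch SGD training, deterministic given ``config.seed``.

    History records per-iteration training loss/accuracy and per-epoch
    validation metrics when a validation PatchSet is supplied.  The final
    model is the last epoch's (fixed-epoch protocol, no early stopping).
    """
    labels = np.asarray(train_patches.labels)
    if labels.min() < 1:
        raise ValueError("training labels must be in 1..C (0 is background)")
    class_ids = np.unique(labels)
    C = network.spec.n_classes
    if class_ids.size > C:
        raise ValueError(f"{class_ids.size} classes exceed the network's {C} outputs")
    y_idx_all = np.searchsorted(class_ids, labels)
    rng = np.random.default_rng(config.seed)
    net = network.net
    n = train_patches.n

    # Convolution is the first layer: its im2col columns never change, so
    # compute them once for the whole training set when they fit the cap.
    cols_all = None
    probe = net.im2col(train_patches.patches[:1])
    cols_bytes = probe.shape[1] * probe.shape[2] * 4 * n
    if cols_bytes <= config.cols_cache_bytes:
        cols_all = np.empty((n,) + probe.shape[1:], dtype=np.float32)
        for start in range(0, n, 4096):
            stop = min(start + 4096, n)
            cols_all[start:stop] = net.im2col(train_patches.patches[start:stop])

    hist = {"train_loss": [], "train_acc": [], "val_acc": [], "val_loss": []}
    val = config.validation
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            cols = cols_all[sel] if cols_all is not None \
                else net.im2col(train_patches.patches[sel])
            y_idx = y_idx_all[sel]
            probs = net.forward(cols, training=True, rng=rng)
            loss = -np.log(np.clip(probs[np.arange(len(sel)), y_idx], 1e-12, None)).mean()
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}: training diverged "
                    f"(try a smaller learning rate than {config.learning_rate})")
            grads = net.backward(probs, y_idx)
            net.sgd_step(grads, config.learning_rate, config.momentum)
            hist["train_loss"].append(float(loss))
            hist["train_acc"].append(float((probs.argmax(1) == y_idx).mean()))
        if val is not None and ((epoch + 1) % max(config.val_every, 1) == 0
                                or epoch == config.epochs - 1):
            vp = network.predict_proba_patches(val.patches)
            v_idx = np.searchsorted(class_ids, val.labels)
            hist["val_loss"].append(float(
                -np.log(np.clip(vp[np.arange(val.n), v_idx], 1e-12, None)).mean()))
            hist["val_acc"].append(float((vp.argmax(1) == v_idx).mean()))
    network.class_ids = class_ids
    network.class_names = list(class_names)
    network.seed = config.seed
    network.history = hist
    return network


def predict_map(network: TrainedNetwork, stack_or_cube, mask: np.ndarray = None,
                k: Optional[int] = None, class_names: Sequence[str] = (),
                batch_size: Optional[int] = None) -> tuple[LabelImage, np.ndarray]:
    """Classify every foreground pixel of a stack or cube.

    Returns the classification map (background 0) and the per-pixel class
    probability stack ``(x, y, C)``.  Patches are streamed in batches so
    the full 3-D patch set is never materialized.
    """
    if isinstance(stack_or_cube, Hypercube):
        stack = stack_or_cube.data
        mask = stack_or_cube.mask if mask is None else mask
    else:
        stack = np.asarray(stack_or_cube)
    if mask is None:
        raise ValueError("a foreground mask is required")
    spec = network.spec
    depth = spec.n_bands if network.net.is_3d else spec.d
    if stack.shape[2] != depth:
        raise ValueError(
            f"stack depth {stack.shape[2]} does not match network input depth {depth}")
    k = spec.k if k is None else k
    if k != spec.k:
        raise ValueError(f"k={k} does not match the network's window {spec.k}")
    batch_size = batch_size or network._eval_batch_size()
    labels_img = np.zeros(stack.shape[:2], dtype=np.int32)
    probs_img = np.zeros(stack.shape[:2] + (spec.n_classes,), dtype=np.float32)
    for batch, centers in iter_patch_batches(stack, mask, k, batch_size=batch_size):
        cols = network.net.im2col(batch)
        probs = network.net.forward(cols, training=False)
        labels_img[centers[:, 0], centers[:, 1]] = network.class_ids[probs.argmax(1)]
        probs_img[centers[:, 0], centers[:, 1]] = probs
    names = list(class_names) or list(network.class_names)
    return LabelImage(labels=labels_img, class_names=names), probs_img


def evaluate_patches(network: TrainedNetwork, patchset: PatchSet) -> float:
    """Fraction of patches assigned their true label."""
    pred = network.predict_patches(patchset.patches)
    return float((pred == patchset.labels).mean())
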