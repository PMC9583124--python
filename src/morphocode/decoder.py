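"""CNN decoder: architecture, training protocol, prediction, evaluation.

The decoder maps preprocessed 80x80 grayscale patterns to categorical
probabilities over the dictionary.  Architecture: two convolution blocks
(3x3 valid convolution, 2x2 max pooling, ReLU), then a ReLU fully-connected
layer and a softmax output layer; Glorot-normal initialization, categorical
cross-entropy loss, Adam optimization, and early stopping on a stratified
validation split with best-weight restoration.

The network is implemented directly on numpy (forward and backward passes,
Adam updates), which keeps training bit-reproducible from a seed.  Training
sets here are small (tens to hundreds of 80x80 images), where this is fast
enough; scikit-learn supplies the evaluation metrics only.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field

import numpy as np
from sklearn.metrics import (
    confusion_matrix,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)

__all__ = [
    "DecoderSpec",
    "DecoderModel",
    "EvalReport",
    "train_decoder",
    "predict_proba",
    "evaluate",
]


# ---------------------------------------------------------------------------
# minimal layer engine (shared with the ensemble stacker and CA decoder)

class Dense:
    def __init__(self, n_in, n_out, rng, init="glorot_normal"):
        limit = np.sqrt(6.0 / (n_in + n_out))
        scale = np.sqrt(2.0 / (n_in + n_out))
        if init == "glorot_uniform":
            w = rng.uniform(-limit, limit, size=(n_in, n_out))
        else:
            w = rng.normal(0.0, scale, size=(n_in, n_out))
        self.w = w.astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, g):
        self.gw = self._x.T @ g
        self.gb = g.sum(axis=0)
        return g @ self.w.T

    params = property(lambda self: [self.w, self.b])
    grads = property(lambda self: [self.gw, self.gb])


class Conv3x3:
    """Valid 3x3 convolution on NHWC tensors (stride 1)."""

    def __init__(self, c_in, c_out, rng, ksize=3, init="glorot_normal"):
        fan_in, fan_out = ksize * ksize * c_in, ksize * ksize * c_out
        scale = np.sqrt(2.0 / (fan_in + fan_out))
        self.k = ksize
        self.w = rng.normal(0.0, scale, size=(ksize, ksize, c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    def forward(self, x, train=False):
        self._x = x
        b_, h, w_, _ = x.shape
        k = self.k
        ho, wo = h - k + 1, w_ - k + 1
        out = np.zeros((b_, ho, wo, self.w.shape[-1]), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                out += x[:, i : i + ho, j : j + wo, :] @ self.w[i, j]
        return out + self.b

    def backward(self, g):
        x = self._x
        k = self.k
        b_, ho, wo, _ = g.shape
        self.gw = np.empty_like(self.w)
        gx = np.zeros_like(x)
        gf = g.reshape(-1, g.shape[-1])
        for i in range(k):
            for j in range(k):
                patch = x[:, i : i + ho, j : j + wo, :].reshape(-1, x.shape[-1])
                self.gw[i, j] = patch.T @ gf
                gx[:, i : i + ho, j : j + wo, :] += g @ self.w[i, j].T
        self.gb = gf.sum(axis=0)
        return gx

    params = property(lambda self: [self.w, self.b])
    grads = property(lambda self: [self.gw, self.gb])


class MaxPool2:
    def forward(self, x, train=False):
        b, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        x = x[:, : ho * 2, : wo * 2, :]
        self._shape = x.shape
        xr = x.reshape(b, ho, 2, wo, 2, c)
        out = xr.max(axis=(2, 4))
        self._mask = xr == out[:, :, None, :, None, :]
        return out

    def backward(self, g):
        gr = self._mask * g[:, :, None, :, None, :]
        return gr.reshape(self._shape).astype(np.float32)

    params = property(lambda self: [])
    grads = property(lambda self: [])


class ReLU:
    def forward(self, x, train=False):
        self._m = x > 0
        return x * self._m

    def backward(self, g):
        return g * self._m

    params = property(lambda self: [])
    grads = property(lambda self: [])


class Flatten:
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)

    params = property(lambda self: [])
    grads = property(lambda self: [])


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def update(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


class Sequential:
    """Softmax classifier over a stack of layers, trained with Adam + CE."""

    def __init__(self, layers):
        self.layers = layers

    def logits(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def predict_proba(self, x, batch=256):
        out = []
        for i in range(0, len(x), batch):
            out.append(softmax(self.logits(x[i : i + batch].astype(np.float32))))
        return np.concatenate(out) if out else np.empty((0,))

    @property
    def parameters(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self):
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self):
        return [p.copy() for p in self.parameters]

    def set_weights(self, weights):
        for p, w in zip(self.parameters, weights):
            p[...] = w

    def loss(self, x, y_onehot):
        p = self.predict_proba(x)
        return float(-np.mean(np.sum(y_onehot * np.log(np.clip(p, 1e-12, 1.0)), axis=1)))

    def fit(
        self,
        x,
        y,
        n_classes,
        rng,
        lr=1e-3,
        batch_size=32,
        max_epochs=100,
        patience=10,
        min_delta=1e-4,
        val_fraction=0.1,
    ):
        x = x.astype(np.float32)
        y = np.asarray(y)
        eye = np.eye(n_classes, dtype=np.float32)
        # stratified validation split for early stopping
        val_idx = []
        if val_fraction > 0:
            for c in range(n_classes):
                idx = np.flatnonzero(y == c)
                idx = idx[rng.permutation(len(idx))]
                k = max(1, int(round(val_fraction * len(idx)))) if len(idx) > 1 else 0
                val_idx.extend(idx[:k])
        val_idx = np.asarray(sorted(val_idx), dtype=int)
        tr_idx = np.setdiff1d(np.arange(len(y)), val_idx)
        xtr, ytr = x[tr_idx], y[tr_idx]
        xval, yval = x[val_idx], y[val_idx]
        monitor_val = len(val_idx) > 0
        opt = Adam(self.parameters, lr=lr)
        best = np.inf
        best_w = self.get_weights()
        wait = 0
        history = []
        for _ in range(max_epochs):
            order = rng.permutation(len(xtr))
            for i in range(0, len(xtr), batch_size):
                bidx = order[i : i + batch_size]
                xb, yb = xtr[bidx], eye[ytr[bidx]]
                p = softmax(self.logits(xb, train=True))
                g = (p - yb) / len(xb)
                for layer in reversed(self.layers):
                    g = layer.backward(g)
                opt.update(self.parameters, self.gradients)
            mon = self.loss(xval, eye[yval]) if monitor_val else self.loss(xtr, eye[ytr])
            history.append(mon)
            if mon < best - min_delta:
                best = mon
                best_w = self.get_weights()
                wait = 0
            else:
                wait += 1
                if wait >= patience:
                    break
        self.set_weights(best_w)
        return history


# ---------------------------------------------------------------------------
# decoder spec / model

@dataclass(frozen=True)
class DecoderSpec:
    """CNN hyperparameters.  Output width must equal the dictionary size."""

    n_classes: int
    input_side: int = 80
    conv_filters: tuple[int, int] = (32, 64)
    kernel_size: int = 3
    fc_width: int = 128
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    min_delta: float = 1e-4
    val_fraction: float = 0.1


def _build_cnn(spec: DecoderSpec, rng: np.random.Generator) -> Sequential:
    c1, c2 = spec.conv_filters
    k = spec.kernel_size
    side = spec.input_side
    s1 = (side - k + 1) // 2           # after conv1 + pool
    s2 = (s1 - k + 1) // 2             # after conv2 + pool
    return Sequential(
        [
            Conv3x3(1, c1, rng, ksize=k),
            MaxPool2(),
            ReLU(),
            Conv3x3(c1, c2, rng, ksize=k),
            MaxPool2(),
            ReLU(),
            Flatten(),
            Dense(s2 * s2 * c2, spec.fc_width, rng),
            ReLU(),
            Dense(spec.fc_width, spec.n_classes, rng),
        ]
    )


@dataclass
class DecoderModel:
    net: Sequential
    spec: DecoderSpec
    seed: int
    train_digest: str = ""
    history: list = dc_field(default_factory=list)

    def param_digest(self) -> str:
        h = hashlib.sha256()
        for p in self.net.parameters:
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()[:16]


def train_decoder(train_set, spec: DecoderSpec, rng_seed: int) -> DecoderModel:
    """Train the CNN to the early-stopping point; reproducible from the seed."""
    if spec.n_classes != train_set.n_classes:
        raise ValueError(
            f"spec output width {spec.n_classes} != dictionary size {train_set.n_classes}"
        )
    rng = np.random.default_rng(rng_seed)
    net = _build_cnn(spec, rng)
    x = train_set.images[..., None]
    history = net.fit(
        x,
        train_set.labels,
        n_classes=spec.n_classes,
        rng=rng,
        lr=spec.learning_rate,
        batch_size=spec.batch_size,
        max_epochs=spec.max_epochs,
        patience=spec.patience,
        min_delta=spec.min_delta,
        val_fraction=spec.val_fraction,
    )
    return DecoderModel(
        net=net, spec=spec, seed=rng_seed, train_digest=train_set.digest(), history=history
    )


def predict_proba(model: DecoderModel, images: np.ndarray) -> np.ndarray:
    """Categorical probabilities, one row per image; rows sum to 1."""
    images = np.asarray(images)
    if images.ndim == 2:
        images = images[None]
    side = model.spec.input_side
    if images.shape[1:] != (side, side):
        raise ValueError(f"expected {side}x{side} preprocessed images, got {images.shape[1:]}")
    return model.net.predict_proba(images[..., None].astype(np.float32))


@dataclass
class EvalReport:
    accuracy: float
    precision: np.ndarray       # per class
    recall: np.ndarray          # per class
    confusion: np.ndarray       # (n_classes, n_classes)
    roc_curves: list            # per class: (fpr, tpr)
    macro_auc: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "confusion": self.confusion.tolist(),
            "macro_auc": self.macro_auc,
        }

    def confusion_csv(self) -> str:
        """Confusion matrix as CSV (rows = true class, columns = predicted)."""
        return "\n".join(",".join(str(v) for v in row) for row in self.confusion)


def evaluate(model, test_set) -> EvalReport:
    """Accuracy, per-class precision/recall, confusion, one-vs-rest ROC/AUC.

    The macro AUC is the unweighted mean of the per-class one-vs-rest AUCs
    (each class's ROC computed against all others, then averaged).
    """
    if len(test_set) == 0:
        raise ValueError("empty test set")
    probs = (
        predict_proba(model, test_set.images)
        if isinstance(model, DecoderModel)
        else model.predict_proba(test_set.images)
    )
    y = test_set.labels
    pred = probs.argmax(axis=1)
    n = test_set.n_classes
    labels = np.arange(n)
    cm = confusion_matrix(y, pred, labels=labels)
    acc = float(np.trace(cm)) / len(y)
    prec = precision_score(y, pred, labels=labels, average=None, zero_division=0)
    rec = recall_score(y, pred, labels=labels, average=None, zero_division=0)
    curves, aucs = [], []
    for c in range(n):
        y_bin = (y == c).astype(int)
        if y_bin.min() == y_bin.max():  # class absent: ROC undefined
            continue
        fpr, tpr, _ = roc_curve(y_bin, probs[:, c])
        curves.append((fpr, tpr))
        aucs.append(roc_auc_score(y_bin, probs[:, c]))
    return EvalReport(
        accuracy=acc,
        precision=prec,
        recall=rec,
        confusion=cm,
        roc_curves=curves,
        macro_auc=float(np.mean(aucs)) if aucs else float("nan"),
    )
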