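"""Minimal CPU neural-network primitives for the compact reference backbone.

Plain-numpy layers (3x3 same-padding convolution via im2col, ReLU, 2x2
average pooling, linear) with hand-written backward passes, a decoupled
weight-decay Adam optimizer (AdamW), and a numerically stable softmax
cross-entropy. Everything is deterministic given the initialisation seed
and data order; there is no threading, no GPU, no framework dependency.

Array convention: activations are (N, C, H, W) float32/float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


# ---------------------------------------------------------------------------
# layers


def conv3x3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """3x3 convolution, stride 1, zero padding 1 ("same").

    x: (N, C, H, W); w: (F, C, 3, 3); b: (F,). Returns (out, cache).
    """
    n, c, h, wd = x.shape
    f = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    # (N, C, H, W, 3, 3) -> (N*H*W, C*9)
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, c * 9)
    out = cols @ w.reshape(f, c * 9).T + b
    out = out.reshape(n, h, wd, f).transpose(0, 3, 1, 2)
    return out, (cols, x.shape, w)


def conv3x3_backward(dout: np.ndarray, cache):
    cols, x_shape, w = cache
    n, c, h, wd = x_shape
    f = w.shape[0]
    dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * wd, f)
    dw = (dflat.T @ cols).reshape(w.shape)
    db = dflat.sum(axis=0)
    # dx = "full" correlation of dout with the flipped, transposed kernel
    w_t = np.ascontiguousarray(w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
    dx, _ = conv3x3_forward(dout, w_t, np.zeros(c, dtype=w.dtype))
    return dx, dw, db


def relu_forward(x: np.ndarray):
    out = np.maximum(x, 0.0)
    return out, (x > 0.0)


def relu_backward(dout: np.ndarray, mask) -> np.ndarray:
    return dout * mask


def absval_forward(x: np.ndarray):
    """Magnitude activation |x| (scattering-style modulus nonlinearity).

    With zero-mean random filters the signed conv responses are symmetric;
    the modulus keeps their energy, which makes an untrained backbone a far
    stronger random-feature extractor than a half-discarding ReLU would be.
    Subgradient 0 at x = 0.
    """
    return np.abs(x), np.sign(x)


def absval_backward(dout: np.ndarray, sign) -> np.ndarray:
    return dout * sign


def avgpool2_forward(x: np.ndarray):
    """2x2 average pooling, stride 2; a trailing odd row/column is dropped."""
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    v = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
    return v.mean(axis=(3, 5)), (x.shape,)


def avgpool2_backward(dout: np.ndarray, cache) -> np.ndarray:
    (x_shape,) = cache
    n, c, h, w = x_shape
    h2, w2 = h // 2, w // 2
    dx = np.zeros(x_shape, dtype=dout.dtype)
    up = np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0
    dx[:, :, : h2 * 2, : w2 * 2] = up
    return dx


def linear_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    return x @ w.T + b, (x, w)


def linear_backward(dout: np.ndarray, cache):
    x, w = cache
    return dout @ w, dout.T @ x, dout.sum(axis=0)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. logits.

    y: integer class indices, shape (N,).
    """
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -log_probs[np.arange(n), y].mean()
    grad = softmax(logits)
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


# ---------------------------------------------------------------------------
# optimizer


class AdamW:
    """Adam with decoupled weight decay (decay applied to weights only)."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float,
        weight_decay: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            p = self.params[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            if self.weight_decay and k.endswith(".w"):
                update = update + self.weight_decay * p
            p -= self.lr * update


# ---------------------------------------------------------------------------
# the compact backbone


#: channel plan of the four conv blocks
_BLOCK_CHANNELS = (16, 32, 64, 64)
#: stem output spatial size: 224 / 8 = 28
STEM_SIZE = 28
STEM_POOL = 8


def he_init(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class CompactCNN:
    """~4-block CPU-trainable CNN over stem-pooled 28x28 grayscale inputs.

    The fixed (parameter-free) stem averages the three replicated channels
    and 8x8-average-pools the 224x224 input to 28x28, preserving brightfield
    shape information while making desk-scale training practical. Blocks:
    conv3x3 -> modulus (-> avgpool2 after blocks 1-3), widths 16/32/64/64;
    the feature vector is the flattened 64 x 3 x 3 block-4 output (576
    dims); the head is a single linear layer over it. The stem centres each
    frame at its median so the (bright, near-constant) background maps to
    ~0 and filter responses are signal-driven.

    In the linear-probing regime the backbone stays at its seed-fixed random
    initialisation and acts as a frozen random-feature extractor; in the
    fine-tuning regime all parameters train.
    """

    N_FEATURES = 64 * 3 * 3

    def __init__(self, n_classes: int, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
        self.n_classes = n_classes
        self.params: dict[str, np.ndarray] = {}
        c_in = 1
        for i, c_out in enumerate(_BLOCK_CHANNELS):
            self.params[f"conv{i}.w"] = he_init(rng, (c_out, c_in, 3, 3))
            self.params[f"conv{i}.b"] = np.zeros(c_out, dtype=np.float32)
            c_in = c_out
        # zero-initialized head: the probe's objective is convex, and a zero
        # start avoids a random-logit noise floor in early epochs
        self.params["head.w"] = np.zeros(
            (n_classes, self.N_FEATURES), dtype=np.float32
        )
        self.params["head.b"] = np.zeros(n_classes, dtype=np.float32)
        # frozen per-feature affine set once from training data (never
        # optimized); identity until set_feature_norm is called
        self.params["featnorm.mean"] = np.zeros(self.N_FEATURES, dtype=np.float32)
        self.params["featnorm.std"] = np.ones(self.N_FEATURES, dtype=np.float32)

    # -- parameter bookkeeping ------------------------------------------
    @property
    def backbone_keys(self) -> list[str]:
        return [k for k in self.params if k.startswith("conv")]

    @property
    def head_keys(self) -> list[str]:
        return [k for k in self.params if k.startswith("head")]

    @property
    def trainable_keys(self) -> list[str]:
        return self.backbone_keys + self.head_keys

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load(self, snap: dict[str, np.ndarray]) -> None:
        for k, v in snap.items():
            self.params[k] = v.copy()

    # -- forward / backward ---------------------------------------------
    @staticmethod
    def stem(x: np.ndarray) -> np.ndarray:
        """(N, 224, 224, 3) model inputs -> (N, 1, 28, 28) pooled gray."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        n, h, w, c = x.shape
        g = x.mean(axis=3)
        hp, wp = h // STEM_POOL, w // STEM_POOL
        g = g[:, : hp * STEM_POOL, : wp * STEM_POOL]
        g = g.reshape(n, hp, STEM_POOL, wp, STEM_POOL).mean(axis=(2, 4))
        g = g - np.median(g, axis=(1, 2), keepdims=True)
        return g[:, None, :, :].astype(np.float32)

    def features(self, s: np.ndarray, with_cache: bool = False):
        """Standardized conv-block features from stem output s (N,1,28,28).

        The final per-feature affine (featnorm) is a frozen statistic set
        once by :meth:`set_feature_norm`; it keeps the linear head
        well-conditioned and is never optimized.
        """
        caches = []
        h = s
        for i in range(len(_BLOCK_CHANNELS)):
            h, c_conv = conv3x3_forward(
                h, self.params[f"conv{i}.w"], self.params[f"conv{i}.b"]
            )
            h, c_act = absval_forward(h)
            if i < 3:
                h, c_pool = avgpool2_forward(h)
            else:
                c_pool = None
            caches.append((c_conv, c_act, c_pool))
        raw = h.reshape(h.shape[0], -1)
        feats = (raw - self.params["featnorm.mean"]) / self.params["featnorm.std"]
        if with_cache:
            return feats, (caches, h.shape)
        return feats

    def set_feature_norm(self, s: np.ndarray, batch: int = 512) -> None:
        """Fix featnorm statistics from (training) stem tensors."""
        self.params["featnorm.mean"] = np.zeros(self.N_FEATURES, dtype=np.float32)
        self.params["featnorm.std"] = np.ones(self.N_FEATURES, dtype=np.float32)
        raw = np.concatenate(
            [self.features(s[i : i + batch]) for i in range(0, len(s), batch)]
        )
        self.params["featnorm.mean"] = raw.mean(axis=0).astype(np.float32)
        self.params["featnorm.std"] = (raw.std(axis=0) + 1e-6).astype(np.float32)

    def features_backward(self, dfeats: np.ndarray, cache) -> dict[str, np.ndarray]:
        caches, h_shape = cache
        grads: dict[str, np.ndarray] = {}
        dh = (dfeats / self.params["featnorm.std"]).reshape(h_shape)
        for i in reversed(range(len(_BLOCK_CHANNELS))):
            c_conv, c_act, c_pool = caches[i]
            if c_pool is not None:
                dh = avgpool2_backward(dh, c_pool)
            dh = absval_backward(dh, c_act)
            dh, dw, db = conv3x3_backward(dh, c_conv)
            grads[f"conv{i}.w"] = dw
            grads[f"conv{i}.b"] = db
        return grads

    def logits_from_features(self, feats: np.ndarray, with_cache: bool = False):
        out, cache = linear_forward(
            feats, self.params["head.w"], self.params["head.b"]
        )
        return (out, cache) if with_cache else out

    def predict_proba_from_stem(self, s: np.ndarray) -> np.ndarray:
        return softmax(self.logits_from_features(self.features(s)))
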