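"""Capsule-network forward mathematics, a tiny trainable model, and Grad-CAM.

The capsule head sits on top of a pluggable convolutional backbone: a
feature tensor ``F`` (H x W x C) is refined by a 1x1 convolution, reshaped
into N primary capsule vectors of dimension d, squashed, routed to K class
capsules of dimension d' by dynamic routing (softmax-normalized agreement
logits), and finally classified by a dense ReLU head with dropout — the
class scores come from the dense head, not from capsule norms.

Everything is plain numpy.  :class:`TinyCapsNet` is a small, fully
trainable instantiation (two strided conv layers as backbone) used to
exercise the capsule math end-to-end on phantom images; its backward pass
is hand-derived.  Gradients flow through the prediction vectors and squash
nonlinearities; the routing coupling coefficients are treated as constants
(stop-gradient), as is standard for dynamic routing.

Grad-CAM weights the backbone's last convolutional activation by the
spatially pooled gradient of a class logit, ReLUs and min-max normalizes
the result, and binarizes it with Otsu's threshold on the 256-bin heatmap
histogram (a constant heatmap yields an all-background mask).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.transform import resize as _sk_resize

from .imaging import GrayImage

log = logging.getLogger(__name__)

DEFAULT_EPS = 1e-7


class CapsConfigError(ValueError):
    pass


class NumericError(FloatingPointError):
    pass


@dataclass(frozen=True)
class CapsuleConfig:
    n_primary: int
    primary_dim: int = 8
    n_classes: int = 3
    class_dim: int = 16
    routing_iters: int = 3
    eps: float = DEFAULT_EPS

    def __post_init__(self) -> None:
        if min(self.n_primary, self.primary_dim, self.n_classes, self.class_dim) < 1:
            raise CapsConfigError("capsule dimensions must be >= 1")
        if self.routing_iters < 1:
            raise CapsConfigError("routing_iters must be >= 1")
        if self.eps <= 0:
            raise CapsConfigError("eps must be positive")


# --------------------------------------------------------------------------
# squashing
# --------------------------------------------------------------------------

def squash(u: np.ndarray, eps: float = DEFAULT_EPS, axis: int = -1) -> np.ndarray:
    """Squashing nonlinearity: v = (|u|^2 / (1+|u|^2)) * u / (|u| + eps).

    Scales the norm into [0, 1) while preserving direction; the zero vector
    maps to itself thanks to eps.
    """
    u = np.asarray(u, dtype=float)
    norm = np.linalg.norm(u, axis=axis, keepdims=True)
    scale = (norm ** 2) / (1.0 + norm ** 2) / (norm + eps)
    return scale * u


def _squash_backward(s: np.ndarray, dv: np.ndarray) -> np.ndarray:
    """Vector-Jacobian product of the (eps-free) squash at pre-activation s.

    With n = |s| and a(n) = n / (1 + n^2) so that v = a(n) s:
    ds = a dv + a'(n)/n (s . dv) s,  a'(n) = (1 - n^2) / (1 + n^2)^2.
    The map is quadratic near the origin, so the Jacobian vanishes there.
    """
    n = np.linalg.norm(s, axis=-1, keepdims=True)
    small = n < 1e-12
    n_safe = np.where(small, 1.0, n)
    a = n_safe / (1.0 + n_safe ** 2)
    aprime = (1.0 - n_safe ** 2) / (1.0 + n_safe ** 2) ** 2
    dot = np.sum(s * dv, axis=-1, keepdims=True)
    ds = a * dv + (aprime / n_safe) * dot * s
    return np.where(small, 0.0, ds)


# --------------------------------------------------------------------------
# primary capsules
# --------------------------------------------------------------------------

def primary_capsules(
    feature: np.ndarray,
    conv_w: np.ndarray,
    conv_b: np.ndarray,
    primary_dim: int,
    eps: float = DEFAULT_EPS,
) -> np.ndarray:
    """Refine the feature tensor and reshape it into squashed capsules.

    ``feature`` is H x W x C; ``conv_w`` (C x C') with bias ``conv_b`` is
    the 1x1 refining convolution.  The refined tensor is reshaped into
    N = H*W*(C'/d) capsules of dimension d and squashed row-wise.
    """
    f = np.asarray(feature, dtype=float)
    if f.ndim != 3:
        raise CapsConfigError("feature tensor must be H x W x C")
    refined = f @ conv_w + conv_b
    cprime = refined.shape[-1]
    if cprime % primary_dim != 0:
        raise CapsConfigError(
            f"refined channel count {cprime} not divisible by capsule dim {primary_dim}")
    u = refined.reshape(-1, primary_dim)
    return squash(u, eps=eps)


# --------------------------------------------------------------------------
# dynamic routing
# --------------------------------------------------------------------------

@dataclass
class RoutingState:
    """All intermediates of the final routing iteration."""

    logits: np.ndarray        # b_ij, N x K
    couplings: np.ndarray     # c_ij, N x K; rows sum to 1
    predictions: np.ndarray   # u_hat_ij, N x K x d'
    pre_activations: np.ndarray  # s_j, K x d'
    outputs: np.ndarray       # v_j, K x d'
    transform: np.ndarray     # W_ij, N x K x d x d'


def _row_softmax(b: np.ndarray) -> np.ndarray:
    e = np.exp(b - b.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def route(
    u: np.ndarray,
    w: np.ndarray,
    cfg: CapsuleConfig,
) -> tuple[np.ndarray, RoutingState]:
    """Dynamic routing of N primary capsules to K class capsules.

    Per iteration: couplings c = row-softmax of the logits b (initialized
    to zero, so the first iteration couples uniformly with 1/K); weighted
    sum s_j = sum_i c_ij u_hat_ij; output v_j = squash(s_j); agreement
    update b_ij += u_hat_ij . v_j (skipped after the last iteration).
    """
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    if not np.all(np.isfinite(w)) or not np.all(np.isfinite(u)):
        raise NumericError("non-finite values in routing inputs")
    n, d = u.shape
    if w.shape[:2] != (n, cfg.n_classes) or w.shape[2] != d or w.shape[3] != cfg.class_dim:
        raise CapsConfigError(
            f"transform shape {w.shape} inconsistent with capsules {(n, d)} "
            f"and config (K={cfg.n_classes}, d'={cfg.class_dim})")

    u_hat = np.einsum("nd,nkde->nke", u, w)
    b = np.zeros((n, cfg.n_classes))
    c = s = v = None
    for it in range(cfg.routing_iters):
        c = _row_softmax(b)
        s = np.einsum("nk,nke->ke", c, u_hat)
        v = squash(s, eps=cfg.eps)
        if it < cfg.routing_iters - 1:
            b = b + np.einsum("nke,ke->nk", u_hat, v)
    state = RoutingState(logits=b, couplings=c, predictions=u_hat,
                         pre_activations=s, outputs=v, transform=w)
    return v, state


# --------------------------------------------------------------------------
# dense head
# --------------------------------------------------------------------------

@dataclass
class HeadParams:
    w1: np.ndarray   # D x (K*d')
    b1: np.ndarray   # D
    w2: np.ndarray   # K x D
    b2: np.ndarray   # K
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        d_hid, d_in = self.w1.shape
        if self.b1.shape != (d_hid,) or self.w2.shape[1] != d_hid \
                or self.b2.shape != (self.w2.shape[0],):
            raise CapsConfigError("head parameter shapes inconsistent")
        if not 0 <= self.dropout_rate < 1:
            raise CapsConfigError("dropout_rate must lie in [0, 1)")


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


def head_forward(
    v_class: np.ndarray,
    params: HeadParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten the class-capsule matrix and classify it.

    h = ReLU(W1 z + b1), dropout on h only when training, logits
    p = W2 h~ + b2; returns (logits, softmax probabilities).
    """
    z = np.asarray(v_class, dtype=float).ravel()
    if z.size != params.w1.shape[1]:
        raise CapsConfigError(
            f"flattened capsule size {z.size} does not match head input "
            f"{params.w1.shape[1]}")
    h = np.maximum(params.w1 @ z + params.b1, 0.0)
    if training and params.dropout_rate > 0:
        if rng is None:
            rng = np.random.default_rng()
        mask = rng.random(h.size) >= params.dropout_rate
        h = h * mask / (1.0 - params.dropout_rate)
    logits = params.w2 @ h + params.b2
    return logits, _softmax(logits)


# --------------------------------------------------------------------------
# small convolution helpers (im2col)
# --------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, int, int]:
    h, w, c = x.shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    cols = np.empty((oh * ow, k * k * c))
    idx = 0
    for i in range(oh):
        for j in range(ow):
            patch = x[i * stride:i * stride + k, j * stride:j * stride + k, :]
            cols[idx] = patch.ravel()
            idx += 1
    return cols, oh, ow


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int], k: int, stride: int) -> np.ndarray:
    h, w, c = shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    dx = np.zeros(shape)
    idx = 0
    for i in range(oh):
        for j in range(ow):
            dx[i * stride:i * stride + k, j * stride:j * stride + k, :] += \
                dcols[idx].reshape(k, k, c)
            idx += 1
    return dx


# --------------------------------------------------------------------------
# the tiny trainable model
# --------------------------------------------------------------------------

class TinyCapsNet:
    """A small capsule classifier for phantom-image experiments.

    Backbone: two 3x3 stride-2 valid convolutions with ReLU; the second
    activation map is the Grad-CAM target layer.  A 1x1 refining
    convolution feeds the primary capsule layer; routing and the dense head
    follow the module-level operations exactly.
    """

    def __init__(
        self,
        input_size: int = 32,
        conv_channels: tuple[int, int] = (8, 16),
        refined_channels: int = 16,
        primary_dim: int = 8,
        class_dim: int = 8,
        hidden: int = 32,
        n_classes: int = 3,
        routing_iters: int = 2,
        dropout_rate: float = 0.0,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        c1, c2 = conv_channels
        if refined_channels % primary_dim != 0:
            raise CapsConfigError("refined channels must be divisible by primary_dim")
        self.input_size = input_size
        self.stride = 2
        self.k = 3
        s1 = (input_size - self.k) // self.stride + 1
        s2 = (s1 - self.k) // self.stride + 1
        self.map_size = s2
        n_primary = s2 * s2 * (refined_channels // primary_dim)
        self.cfg = CapsuleConfig(
            n_primary=n_primary, primary_dim=primary_dim, n_classes=n_classes,
            class_dim=class_dim, routing_iters=routing_iters)

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "conv1_w": he((self.k * self.k * 1, c1), self.k * self.k),
            "conv1_b": np.zeros(c1),
            "conv2_w": he((self.k * self.k * c1, c2), self.k * self.k * c1),
            "conv2_b": np.zeros(c2),
            "refine_w": he((c2, refined_channels), c2),
            "refine_b": np.zeros(refined_channels),
            "route_w": rng.normal(0.0, 0.1, size=(n_primary, n_classes, primary_dim, class_dim)),
            "head_w1": he((hidden, n_classes * class_dim), n_classes * class_dim),
            "head_b1": np.zeros(hidden),
            "head_w2": he((n_classes, hidden), hidden),
            "head_b2": np.zeros(n_classes),
        }
        self.dropout_rate = dropout_rate
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> dict:
        """Full forward pass on one image (H x W floats in [0, 1])."""
        p = self.params
        x3 = np.asarray(x, dtype=float).reshape(self.input_size, self.input_size, 1)

        cols1, oh1, ow1 = _im2col(x3, self.k, self.stride)
        pre1 = cols1 @ p["conv1_w"] + p["conv1_b"]
        act1 = np.maximum(pre1, 0.0).reshape(oh1, ow1, -1)

        cols2, oh2, ow2 = _im2col(act1, self.k, self.stride)
        pre2 = cols2 @ p["conv2_w"] + p["conv2_b"]
        act2 = np.maximum(pre2, 0.0).reshape(oh2, ow2, -1)   # Grad-CAM target

        refined = act2 @ p["refine_w"] + p["refine_b"]
        prim_pre = refined.reshape(-1, self.cfg.primary_dim)
        u = squash(prim_pre, eps=self.cfg.eps)

        v, state = route(u, p["route_w"], self.cfg)

        head = HeadParams(p["head_w1"], p["head_b1"], p["head_w2"], p["head_b2"],
                          dropout_rate=self.dropout_rate)
        z = v.ravel()
        hpre = p["head_w1"] @ z + p["head_b1"]
        h = np.maximum(hpre, 0.0)
        if training and self.dropout_rate > 0:
            if rng is None:
                rng = np.random.default_rng()
            mask = (rng.random(h.size) >= self.dropout_rate).astype(float)
            h_used = h * mask / (1.0 - self.dropout_rate)
        else:
            mask = None
            h_used = h
        logits = p["head_w2"] @ h_used + p["head_b2"]
        probs = _softmax(logits)

        return {
            "x3": x3, "cols1": cols1, "pre1": pre1, "act1": act1,
            "cols2": cols2, "pre2": pre2, "act2": act2,
            "refined": refined, "prim_pre": prim_pre, "u": u,
            "v": v, "state": state, "z": z, "hpre": hpre, "h": h,
            "mask": mask, "h_used": h_used, "logits": logits, "probs": probs,
        }

    # -- backward ----------------------------------------------------------

    def backward(self, cache: dict, dlogits: np.ndarray,
                 want_input_grad: bool = False) -> tuple[dict, np.ndarray]:
        """Gradients of a scalar with given logit gradient.

        Returns (parameter gradients, gradient w.r.t. the conv2 activation
        map) — the latter is what Grad-CAM pools.
        """
        p = self.params
        g = {}
        g["head_b2"] = dlogits
        g["head_w2"] = np.outer(dlogits, cache["h_used"])
        dh_used = p["head_w2"].T @ dlogits
        if cache["mask"] is not None:
            dh = dh_used * cache["mask"] / (1.0 - self.dropout_rate)
        else:
            dh = dh_used
        dh = dh * (cache["hpre"] > 0)
        g["head_b1"] = dh
        g["head_w1"] = np.outer(dh, cache["z"])
        dz = p["head_w1"].T @ dh
        dv = dz.reshape(self.cfg.n_classes, self.cfg.class_dim)

        state = cache["state"]
        ds = _squash_backward(state.pre_activations, dv)            # K x d'
        du_hat = state.couplings[:, :, None] * ds[None, :, :]       # N x K x d'
        g["route_w"] = np.einsum("nd,nke->nkde", cache["u"], du_hat)
        du = np.einsum("nke,nkde->nd", du_hat, p["route_w"])

        dprim = _squash_backward(cache["prim_pre"], du)
        drefined = dprim.reshape(cache["refined"].shape)
        g["refine_w"] = np.einsum("hwc,hwf->cf", cache["act2"], drefined)
        g["refine_b"] = drefined.sum(axis=(0, 1))
        dact2 = np.einsum("hwf,cf->hwc", drefined, p["refine_w"])   # Grad-CAM gradient

        dpre2 = (dact2 * (cache["pre2"].reshape(dact2.shape) > 0)).reshape(-1, dact2.shape[-1])
        g["conv2_w"] = cache["cols2"].T @ dpre2
        g["conv2_b"] = dpre2.sum(axis=0)
        dcols2 = dpre2 @ p["conv2_w"].T
        dact1 = _col2im(dcols2, cache["act1"].shape, self.k, self.stride)
        dpre1 = (dact1.reshape(-1, dact1.shape[-1]) * (cache["pre1"] > 0))
        g["conv1_w"] = cache["cols1"].T @ dpre1
        g["conv1_b"] = dpre1.sum(axis=0)
        return g, dact2

    # -- training ----------------------------------------------------------

    def loss_and_grads(self, x: np.ndarray, label: int,
                       training: bool = True,
                       rng: np.random.Generator | None = None) -> tuple[float, dict]:
        cache = self.forward(x, training=training, rng=rng)
        probs = cache["probs"]
        loss = -float(np.log(probs[label] + 1e-12))
        dlogits = probs.copy()
        dlogits[label] -= 1.0
        grads, _ = self.backward(cache, dlogits)
        return loss, grads

    def _adam_step(self, grads: dict, lr: float,
                   beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, gk in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * gk
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * gk ** 2
            mhat = self._adam_m[k] / (1 - beta1 ** t)
            vhat = self._adam_v[k] / (1 - beta2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def train_epoch(self, images: np.ndarray, labels: np.ndarray,
                    lr: float, rng: np.random.Generator,
                    batch_size: int = 8) -> float:
        """One shuffled minibatch epoch (Adam); returns the mean loss."""
        n = len(images)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            batch = order[start:start + batch_size]
            acc = None
            for idx in batch:
                loss, grads = self.loss_and_grads(images[idx], int(labels[idx]),
                                                  training=True, rng=rng)
                losses.append(loss)
                if acc is None:
                    acc = grads
                else:
                    for k in acc:
                        acc[k] += grads[k]
            for k in acc:
                acc[k] /= len(batch)
            self._adam_step(acc, lr)
        return float(np.mean(losses))

    def predict(self, x: np.ndarray) -> tuple[int, np.ndarray]:
        cache = self.forward(x, training=False)
        return int(np.argmax(cache["probs"])), cache["probs"]

    def accuracy(self, images: np.ndarray, labels: np.ndarray) -> float:
        hits = sum(self.predict(im)[0] == int(y) for im, y in zip(images, labels))
        return hits / len(images)

    # -- serialization -----------------------------------------------------

    def save_weights(self, path) -> None:
        np.savez(path, **self.params)

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            for k in self.params:
                self.params[k] = data[k]


def tiny_train(
    model,
    images: np.ndarray,
    labels: np.ndarray,
    epochs: int = 50,
    lr: float = 2e-3,
    patience: int = 5,
    lr_patience: int = 3,
    lr_factor: float = 0.5,
    min_delta: float = 1e-6,
    seed: int = 0,
) -> tuple[object, list[float]]:
    """Fit a model with early stopping and learning-rate reduction on plateau.

    Stops once the epoch loss has failed to improve ``patience`` times in a
    row; the learning rate halves after ``lr_patience`` non-improving
    epochs.  Deterministic under a fixed seed.  The model only needs a
    ``train_epoch(images, labels, lr, rng)`` method returning the epoch
    loss.
    """
    if len(images) == 0:
        raise ValueError("cannot train on an empty dataset")
    rng = np.random.default_rng(seed)
    best = np.inf
    stall = 0
    history: list[float] = []
    for _ in range(epochs):
        loss = model.train_epoch(np.asarray(images), np.asarray(labels), lr, rng)
        history.append(loss)
        if loss < best - min_delta:
            best = loss
            stall = 0
        else:
            stall += 1
            if stall % lr_patience == 0:
                lr *= lr_factor
            if stall >= patience:
                break
    return model, history


# --------------------------------------------------------------------------
# Grad-CAM + Otsu
# --------------------------------------------------------------------------

def otsu_mask(heatmap: np.ndarray) -> tuple[float | None, np.ndarray]:
    """Binarize a [0, 1] heatmap at Otsu's threshold of its 256-bin histogram.

    A constant heatmap has no Otsu separation: the tie rule is
    all-background (threshold None).
    """
    hm = np.asarray(heatmap, dtype=float)
    if np.ptp(hm) == 0:
        return None, np.zeros_like(hm, dtype=bool)
    thr = float(threshold_otsu(hm, nbins=256))
    return thr, hm >= thr


def gradcam(model: TinyCapsNet, img: GrayImage, target_class: int) -> tuple[np.ndarray, np.ndarray]:
    """Grad-CAM heatmap and Otsu binary mask for one image and class.

    heatmap = ReLU(sum_c alpha_c A_c), min-max normalized to [0, 1] and
    bilinearly upsampled to the image size, where A is the activation of
    the last backbone convolution and alpha its spatially averaged logit
    gradient.  All-zero gradients produce an all-zero heatmap and an empty
    mask (with a warning).
    """
    x = img.pixels.astype(float) / 255.0
    cache = model.forward(x, training=False)
    dlogits = np.zeros(model.cfg.n_classes)
    dlogits[target_class] = 1.0
    _, dact = model.backward(cache, dlogits)

    alpha = dact.mean(axis=(0, 1))
    cam = np.maximum((cache["act2"] * alpha).sum(axis=-1), 0.0)
    if cam.max() > 0:
        cam = (cam - cam.min()) / (cam.max() - cam.min())
    else:
        log.warning("all-zero Grad-CAM gradients: empty heatmap and mask")
        cam = np.zeros_like(cam)
    heat = _sk_resize(cam, img.pixels.shape, order=1, preserve_range=True,
                      anti_aliasing=False)
    heat = np.clip(heat, 0.0, 1.0)
    _, mask = otsu_mask(heat)
    return heat, mask
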