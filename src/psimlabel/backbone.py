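"""Compact CAM-capable multi-label CNN, weighted BCE loss, ensemble, fine-tuning.

The classifier is a three-block strided convolutional network ending in
global average pooling and a single linear layer, so class activation maps
(CAMs) exist exactly as the CAM construction requires: the map for class c is
the final-stage feature maps weighted by class c's output-layer weights.
Forward and backward passes are written directly on numpy (im2col), with an
AdamW optimizer; everything is seeded and reproducible on one CPU.

The loss is a weighted binary cross-entropy for tri-valued labels
{1, 0, -1}: per-class effective-sample weights alpha_s^c equalize classes
with different numbers of non-ignore cells, alpha_P^c/alpha_N^c rebalance
positives vs negatives within a class, ignore cells (-1) contribute exactly
zero, and a view weight alpha(v) = omega up-weights samples from the target
view position.  The view position itself is trained as an auxiliary
(L+1)-th sigmoid output and is excluded from atlas and pSim computations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synthgen import LabeledImageSet

__all__ = [
    "LossWeights",
    "TrainConfig",
    "SmallCNN",
    "EnsembleModel",
    "TrainingDivergedError",
    "compute_loss_weights",
    "weighted_bce_loss",
    "compute_cam",
    "augment",
    "train_member",
    "build_ensemble",
    "finetune",
]

PROB_EPS = 1e-7  # probabilities clamped to [eps, 1-eps] before logs


class TrainingDivergedError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# loss weights and weighted BCE


@dataclass
class LossWeights:
    """Per-class weights of the tri-valued weighted BCE loss.

    alpha_s^c = (|P^m|+|N^m|)/(|P^c|+|N^c|) with m the class holding the most
    non-ignore cells; alpha_P^c = (|P^c|+|N^c|)/|P^c| and symmetrically for
    alpha_N^c.  Classes missing one side entirely are disabled (their loss
    contribution is zero) and flagged in ``enabled``.
    """

    alpha_s: np.ndarray
    alpha_P: np.ndarray
    alpha_N: np.ndarray
    omega: float
    pos_counts: np.ndarray
    neg_counts: np.ndarray
    m_index: int
    enabled: np.ndarray  # bool per class

    @classmethod
    def unit(cls, n_labels: int) -> "LossWeights":
        ones = np.ones(n_labels)
        return cls(ones, ones.copy(), ones.copy(), 1.0, ones.copy(), ones.copy(), 0,
                   np.ones(n_labels, dtype=bool))


def compute_loss_weights(train_labels: np.ndarray, omega: float = 1.0) -> LossWeights:
    """Derive the loss weights from a {1, 0, -1} label matrix.

    Ignore cells (-1) are excluded from every count.  A class with no
    positives or no negatives cannot define alpha_P/alpha_N; it is disabled
    with a warning and its alphas set to safe placeholders.
    """
    t = np.asarray(train_labels)
    pos = (t == 1).sum(axis=0).astype(float)
    neg = (t == 0).sum(axis=0).astype(float)
    tot = pos + neg
    if not (tot > 0).any():
        raise ValueError("no label has any non-ignore cells")
    m = int(np.argmax(tot))
    enabled = (pos > 0) & (neg > 0)
    if not enabled.all():
        bad = np.flatnonzero(~enabled).tolist()
        warnings.warn(
            f"labels {bad} lack positive or negative examples; their loss contribution is disabled",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_s = np.where(tot > 0, tot[m] / tot, 0.0)
        alpha_P = np.where(pos > 0, tot / pos, 0.0)
        alpha_N = np.where(neg > 0, tot / neg, 0.0)
    return LossWeights(alpha_s, alpha_P, alpha_N, float(omega), pos, neg, m, enabled)


def weighted_bce_loss(y, t, v, weights: LossWeights, eps: float = PROB_EPS) -> float:
    """Weighted BCE for one sample: -alpha(v) * sum_c alpha_s^c *
    [alpha_P^c t^c ln y^c + alpha_N^c (1-t^c) ln(1-y^c)], ignore cells inert.

    ``v`` is truthy for the target view (weight omega) and falsy otherwise.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t)
    if y.shape != t.shape:
        raise ValueError("y and t must have the same length")
    yc = np.clip(y, eps, 1.0 - eps)
    is_pos = (t == 1)
    is_neg = (t == 0)
    active = weights.enabled & (is_pos | is_neg)
    term = np.zeros_like(yc)
    term[is_pos & active] = (weights.alpha_P * np.log(yc))[is_pos & active]
    term[is_neg & active] = (weights.alpha_N * np.log(1.0 - yc))[is_neg & active]
    alpha_v = weights.omega if v else 1.0
    return float(-alpha_v * np.sum(weights.alpha_s * term))


def _batch_loss_grad(probs, t, view, weights: LossWeights, view_probs=None, view_target=None):
    """Mean weighted BCE over a batch plus d(loss)/d(logits); the auxiliary
    view head adds plain BCE.  Returns (loss, dlogits, dview_logits)."""
    n = probs.shape[0]
    y = np.clip(probs, PROB_EPS, 1.0 - PROB_EPS)
    is_pos = (t == 1) & weights.enabled
    is_neg = (t == 0) & weights.enabled
    alpha_v = np.where(view.astype(bool), weights.omega, 1.0)[:, None]
    term = np.where(is_pos, weights.alpha_P * np.log(y), 0.0) \
        + np.where(is_neg, weights.alpha_N * np.log(1.0 - y), 0.0)
    loss = float(-(alpha_v * weights.alpha_s * term).sum() / n)
    # d/dlogit of -[aP t ln y + aN (1-t) ln(1-y)] with y = sigmoid(z)
    dz = np.where(is_pos, -weights.alpha_P * (1.0 - y), 0.0) \
        + np.where(is_neg, weights.alpha_N * y, 0.0)
    dz = alpha_v * weights.alpha_s * dz / n
    dview = None
    if view_probs is not None:
        vp = np.clip(view_probs, PROB_EPS, 1.0 - PROB_EPS)
        vt = view_target.astype(float)
        loss += float(-(vt * np.log(vp) + (1 - vt) * np.log(1 - vp)).sum() / n)
        dview = (vp - vt)[:, None] / n
    return loss, dz, dview


# ---------------------------------------------------------------------------
# im2col convolution primitives (3x3 kernels, stride 2, pad 1)


def _im2col(x: np.ndarray, stride: int = 2):
    """x: (N, C, H, W) -> cols (N, C*9, Ho*Wo) for a 3x3 pad-1 kernel."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    view = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]           # (N, C, Ho, Wo, 3, 3)
    ho, wo = view.shape[2], view.shape[3]
    cols = view.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * 9, ho * wo)
    return np.ascontiguousarray(cols), (ho, wo)


def _col2im(dcols: np.ndarray, x_shape, stride: int = 2):
    """Scatter-add column gradients back to input shape (3x3 pad-1 kernel)."""
    n, c, h, w = x_shape
    ho = (h + 2 - 3) // stride + 1
    wo = (w + 2 - 3) // stride + 1
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    d = dcols.reshape(n, c, 3, 3, ho, wo)
    for ki in range(3):
        for kj in range(3):
            dxp[:, :, ki:ki + stride * ho:stride, kj:kj + stride * wo:stride] += d[:, :, ki, kj]
    return dxp[:, :, 1:h + 1, 1:w + 1]


def _conv_forward(x, W, b, stride=2):
    cols, (ho, wo) = _im2col(x, stride)
    out = np.einsum("oi,nip->nop", W, cols, optimize=True) + b[None, :, None]
    return out.reshape(x.shape[0], W.shape[0], ho, wo), cols


def _conv_backward(dout, cols, x_shape, W, stride=2):
    n = dout.shape[0]
    dflat = dout.reshape(n, W.shape[0], -1)
    dW = np.einsum("nop,nip->oi", dflat, cols, optimize=True)
    db = dflat.sum(axis=(0, 2))
    dcols = np.einsum("oi,nop->nip", W, dflat, optimize=True)
    dx = _col2im(dcols, x_shape, stride)
    return dx, dW, db


def _sigmoid(z):
    out = np.empty_like(z)
    np.negative(np.abs(z), out=out)
    np.exp(out, out=out)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + out[pos])
    out[~pos] = out[~pos] / (1.0 + out[~pos])
    return out


# ---------------------------------------------------------------------------
# the model


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings (AdamW).  The default profile is the
    desk-scale one; :meth:`full_scale_profile` restores the full-scale settings
    (batch 144, lr 1e-4) used with DenseNet-121-class backbones."""

    learning_rate: float = 3e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    weight_decay: float = 1e-5
    batch_size: int = 32
    epochs: int = 4
    augmentation: bool = False
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("learning_rate", "beta1", "beta2", "epsilon", "weight_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >=1 and epochs >=0")

    @classmethod
    def full_scale_profile(cls, **overrides) -> "TrainConfig":
        base = dict(learning_rate=1e-4, beta1=0.9, beta2=0.999, epsilon=1e-8,
                    weight_decay=1e-5, batch_size=144, epochs=4, augmentation=True)
        base.update(overrides)
        return cls(**base)


class SmallCNN:
    """Three stride-2 conv blocks + GAP + linear head; n_labels pathology
    sigmoid outputs plus one auxiliary view output.

    Satisfies the classifier contract needed downstream: ``predict_proba``,
    ``feature_maps`` (final conv activations, C x h x w) and
    ``class_weights`` (the final linear layer's row for an output), which
    together define CAMs.
    """

    def __init__(self, n_labels: int, image_size=(64, 64), channels=(16, 32, 64), seed: int = 0):
        self.n_labels = int(n_labels)
        self.image_size = tuple(image_size)
        self.channels = tuple(channels)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        c1, c2, c3 = channels
        def he(fan_in, shape):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float64)
        self.params = {
            "W1": he(9, (c1, 9)), "b1": np.zeros(c1),
            "W2": he(c1 * 9, (c2, c1 * 9)), "b2": np.zeros(c2),
            "W3": he(c2 * 9, (c3, c2 * 9)), "b3": np.zeros(c3),
            "Wfc": he(c3, (self.n_labels + 1, c3)), "bfc": np.zeros(self.n_labels + 1),
        }
        h, w = self.image_size
        self.fmap_shape = (c3, h // 8, w // 8)

    # -- forward / backward ------------------------------------------------

    def _forward(self, x, want_cache=False):
        p = self.params
        z1, cols1 = _conv_forward(x[:, None, :, :], p["W1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        z2, cols2 = _conv_forward(a1, p["W2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        z3, cols3 = _conv_forward(a2, p["W3"], p["b3"])
        a3 = np.maximum(z3, 0.0)                      # feature maps
        gap = a3.mean(axis=(2, 3))
        logits = gap @ p["Wfc"].T + p["bfc"]
        probs = _sigmoid(logits)
        cache = None
        if want_cache:
            cache = dict(x=x, cols1=cols1, a1=a1, cols2=cols2, a2=a2,
                         cols3=cols3, a3=a3, gap=gap)
        return probs, a3, cache

    def _backward(self, dlogits, cache):
        p = self.params
        n = dlogits.shape[0]
        grads = {}
        grads["Wfc"] = dlogits.T @ cache["gap"]
        grads["bfc"] = dlogits.sum(axis=0)
        dgap = dlogits @ p["Wfc"]
        c3, fh, fw = cache["a3"].shape[1:]
        da3 = np.broadcast_to(dgap[:, :, None, None] / (fh * fw), cache["a3"].shape).copy()
        da3[cache["a3"] <= 0] = 0.0
        a2 = cache["a2"]
        da2, grads["W3"], grads["b3"] = _conv_backward(da3, cache["cols3"], a2.shape, p["W3"])
        da2[a2 <= 0] = 0.0
        a1 = cache["a1"]
        da1, grads["W2"], grads["b2"] = _conv_backward(da2, cache["cols2"], a1.shape, p["W2"])
        da1[a1 <= 0] = 0.0
        x4 = cache["x"][:, None, :, :]
        _, grads["W1"], grads["b1"] = _conv_backward(da1, cache["cols1"], x4.shape, p["W1"])
        return grads

    # -- public contract ---------------------------------------------------

    def predict_proba(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Sigmoid probabilities, shape (N, n_labels+1); last column = view."""
        images = np.asarray(images, dtype=np.float64)
        single = images.ndim == 2
        if single:
            images = images[None]
        out = np.empty((len(images), self.n_labels + 1))
        for lo in range(0, len(images), batch_size):
            probs, _, _ = self._forward(images[lo:lo + batch_size])
            out[lo:lo + batch_size] = probs
        return out[0] if single else out

    def feature_maps(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Final conv-stage activations, shape (N, C, h, w) (or (C, h, w))."""
        images = np.asarray(images, dtype=np.float64)
        single = images.ndim == 2
        if single:
            images = images[None]
        out = np.empty((len(images),) + self.fmap_shape)
        for lo in range(0, len(images), batch_size):
            _, fmaps, _ = self._forward(images[lo:lo + batch_size])
            out[lo:lo + batch_size] = fmaps
        return out[0] if single else out

    def class_weights(self, c: int) -> np.ndarray:
        if not 0 <= c < self.n_labels + 1:
            raise IndexError(f"output index {c} out of range")
        return self.params["Wfc"][c].copy()

    def copy(self) -> "SmallCNN":
        m = SmallCNN(self.n_labels, self.image_size, self.channels, self.seed)
        m.params = {k: v.copy() for k, v in self.params.items()}
        return m

    # -- serialization -----------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = dict(kind="SmallCNN", n_labels=self.n_labels,
                        image_size=list(self.image_size), channels=list(self.channels),
                        seed=self.seed, format_version=1)
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
        np.savez(d / "weights.npz", **self.params)

    @classmethod
    def load(cls, directory) -> "SmallCNN":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        m = cls(manifest["n_labels"], tuple(manifest["image_size"]),
                tuple(manifest["channels"]), manifest["seed"])
        with np.load(d / "weights.npz") as z:
            m.params = {k: z[k].copy() for k in z.files}
        return m


def compute_cam(model, image: np.ndarray, c: int) -> np.ndarray:
    """Raw (unnormalized) class activation map for pathology label c:
    CAM(i,j) = sum_k w_{c,k} * F_k(i,j)."""
    if not 0 <= c < model.n_labels:
        raise IndexError(f"label index {c} out of range for {model.n_labels} pathology labels")
    fmap = model.feature_maps(image)
    return np.tensordot(model.class_weights(c), fmap, axes=1)


def compute_cams_batch(model, images: np.ndarray, c: int) -> np.ndarray:
    """Vectorized :func:`compute_cam` over a stack of images."""
    if not 0 <= c < model.n_labels:
        raise IndexError(f"label index {c} out of range")
    fmaps = model.feature_maps(images)
    return np.tensordot(fmaps, model.class_weights(c), axes=([1], [0]))


# ---------------------------------------------------------------------------
# augmentation


def augment(image: np.ndarray, rng, *, crop_size=None, max_rotation: float = 10.0,
            max_scale: float = 1.10, flip_prob: float = 0.01, enabled: bool = True) -> np.ndarray:
    """Geometric training augmentation: rotation in [-10, 10] degrees,
    scaling up to 110%, random crop back to ``crop_size``, horizontal flip
    with probability 0.01.  Disabled -> identity."""
    from skimage.transform import rescale, rotate

    if not enabled:
        return image
    h, w = image.shape
    ch, cw = crop_size if crop_size is not None else (h, w)
    if h < ch or w < cw:
        raise ValueError("image smaller than crop size")
    out = image.astype(np.float64)
    angle = rng.uniform(-max_rotation, max_rotation)
    if max_rotation > 0:
        out = rotate(out, angle, mode="edge", order=1)
    scale = rng.uniform(1.0, max_scale)
    if scale > 1.0:
        out = rescale(out, scale, order=1, mode="edge", anti_aliasing=False)
    hh, ww = out.shape
    r0 = rng.integers(0, hh - ch + 1)
    c0 = rng.integers(0, ww - cw + 1)
    out = out[r0:r0 + ch, c0:c0 + cw]
    if rng.random() < flip_prob:
        out = out[:, ::-1]
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# training


class _AdamW:
    def __init__(self, params, cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1 ** self.t
        bc2 = 1.0 - c.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + c.epsilon)
            params[k] -= c.learning_rate * (update + c.weight_decay * params[k])


def _dataset_loss(model: SmallCNN, data: LabeledImageSet, weights: LossWeights) -> float:
    probs = model.predict_proba(data.images)
    loss, _, _ = _batch_loss_grad(probs[:, :model.n_labels], data.train_labels,
                                  data.view, weights,
                                  view_probs=probs[:, -1], view_target=data.view)
    return loss


def train_member(data: LabeledImageSet, omega: float, config: TrainConfig,
                 val_data: LabeledImageSet | None = None,
                 model: SmallCNN | None = None) -> SmallCNN:
    """Train one classifier on tri-valued labels with view weight omega.

    With ``epochs == 0`` the initialized model is returned unchanged.  Raises
    :class:`TrainingDivergedError` if the loss becomes non-finite.
    """
    if data.n_images == 0:
        raise ValueError("empty training set")
    weights = compute_loss_weights(data.train_labels, omega)
    if model is None:
        model = SmallCNN(data.n_labels, data.images.shape[1:], seed=config.rng_seed)
    opt = _AdamW(model.params, config)
    rng = np.random.default_rng(config.rng_seed + 1)
    n = data.n_images
    x_all = data.images.astype(np.float64)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            xb = x_all[idx]
            if config.augmentation:
                xb = np.stack([augment(im, rng) for im in xb])
            tb = data.train_labels[idx]
            vb = data.view[idx]
            probs, _, cache = model._forward(xb, want_cache=True)
            loss, dz, dview = _batch_loss_grad(
                probs[:, :model.n_labels], tb, vb, weights,
                view_probs=probs[:, -1], view_target=vb)
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"loss became {loss} at step {opt.t}")
            dlogits = np.concatenate([dz, dview], axis=1)
            grads = model._backward(dlogits, cache)
            opt.step(model.params, grads)
    if val_data is not None and config.epochs > 0:
        val_loss = _dataset_loss(model, val_data, weights)
        if not np.isfinite(val_loss):
            raise TrainingDivergedError("validation loss non-finite after training")
    return model


@dataclass
class EnsembleModel:
    """Unweighted-average ensemble of classifiers trained with different
    view weights omega; the ensemble probability is the arithmetic mean of
    member probabilities."""

    members: list
    member_omegas: list = field(default_factory=list)

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble needs at least one member")

    @property
    def n_labels(self) -> int:
        return self.members[0].n_labels

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        preds = [m.predict_proba(images) for m in self.members]
        return np.mean(preds, axis=0)

    def member_cams(self, images: np.ndarray, c: int) -> list:
        """One raw CAM stack (N, h, w) per member for pathology label c."""
        return [compute_cams_batch(m, images, c) for m in self.members]

    def copy(self) -> "EnsembleModel":
        return EnsembleModel([m.copy() for m in self.members], list(self.member_omegas))

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(self.members):
            m.save(d / f"member{i}")
        manifest = dict(kind="EnsembleModel", n_members=len(self.members),
                        member_omegas=list(map(float, self.member_omegas)), format_version=1)
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "EnsembleModel":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        members = [SmallCNN.load(d / f"member{i}") for i in range(manifest["n_members"])]
        return cls(members, manifest["member_omegas"])


def _val_auroc(model: SmallCNN, val: LabeledImageSet) -> float:
    from .stats import auroc

    probs = model.predict_proba(val.images)[:, :model.n_labels]
    scores = []
    for c in range(model.n_labels):
        mask = val.train_labels[:, c] >= 0
        labels = val.train_labels[mask, c]
        if labels.min(initial=1) == labels.max(initial=0):
            continue
        scores.append(auroc(probs[mask, c], labels))
    return float(np.mean(scores)) if scores else 0.5


def _val_accuracy(model: SmallCNN, val: LabeledImageSet, cut: float = 0.5) -> float:
    probs = model.predict_proba(val.images)[:, :model.n_labels]
    mask = val.train_labels >= 0
    pred = (probs >= cut).astype(int)
    return float((pred[mask] == val.train_labels[mask]).mean())


def build_ensemble(data: LabeledImageSet, omegas, config: TrainConfig,
                   val_fraction: float = 0.2,
                   val_data: LabeledImageSet | None = None) -> EnsembleModel:
    """Train one member per omega and keep the validation-AUROC-best and the
    validation-accuracy-best (probability cut 0.5) as the ensemble.

    When one member tops both criteria and other candidates exist, the
    accuracy slot takes the runner-up so the ensemble keeps two distinct
    models.
    """
    omegas = list(omegas)
    if not omegas:
        raise ValueError("need at least one omega")
    if val_data is None:
        rng = np.random.default_rng(config.rng_seed + 97)
        n_val = max(1, int(round(val_fraction * data.n_images)))
        perm = rng.permutation(data.n_images)
        val_data = data.subset(perm[:n_val])
        train_data = data.subset(perm[n_val:])
    else:
        train_data = data
    members, aurocs, accs = [], [], []
    for i, om in enumerate(omegas):
        cfg = TrainConfig(**{**_cfg_dict(config), "rng_seed": config.rng_seed + i})
        m = train_member(train_data, om, cfg, val_data=val_data)
        members.append(m)
        aurocs.append(_val_auroc(m, val_data))
        accs.append(_val_accuracy(m, val_data))
    if not any(np.isfinite(aurocs)):
        raise RuntimeError("all candidate members degenerate")
    i_auroc = int(np.argmax(aurocs))
    i_acc = int(np.argmax(accs))
    if i_acc == i_auroc and len(members) > 1:
        order = np.argsort(accs)[::-1]
        i_acc = int(order[1]) if order[0] == i_acc else int(order[0])
    picked = [i_auroc] if i_acc == i_auroc else [i_auroc, i_acc]
    return EnsembleModel([members[i] for i in picked], [omegas[i] for i in picked])


def _cfg_dict(cfg: TrainConfig) -> dict:
    return {f: getattr(cfg, f) for f in TrainConfig.__dataclass_fields__}


def finetune(ensemble: EnsembleModel, original_data: LabeledImageSet,
             autolabeled: LabeledImageSet | None, learning_rate: float,
             test_ids=None, epochs: int = 1,
             config: TrainConfig | None = None) -> EnsembleModel:
    """Continue training every member on original + auto-labeled data at a
    very small learning rate; ``learning_rate == 0`` returns a numerically
    identical ensemble.  Raises if auto-labeled ids overlap the test set."""
    if test_ids and autolabeled is not None:
        leak = set(autolabeled.ids) & set(test_ids)
        if leak:
            raise ValueError(f"auto-labeled set overlaps the test set: {sorted(leak)[:5]}...")
    out = ensemble.copy()
    if learning_rate == 0 or epochs == 0:
        return out
    union = original_data if autolabeled is None or autolabeled.n_images == 0 \
        else original_data.concat(autolabeled)
    base = config or TrainConfig()
    for i, (member, om) in enumerate(zip(out.members, out.member_omegas)):
        cfg = TrainConfig(**{**_cfg_dict(base), "learning_rate": learning_rate,
                             "epochs": epochs, "rng_seed": base.rng_seed + 1000 + i})
        train_member(union, om, cfg, model=member)
    return out
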