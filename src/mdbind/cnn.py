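"""2D-CNN classification of contact-map images with vanilla-gradient saliency.

The classifier mirrors a deliberately small architecture: two 1x1-kernel
convolutions (16 and 32 filters), each followed by 2x2 max-pooling and ReLU,
then fully connected layers of 512 and 128 units (dropout 0.5 each) and a
K-way softmax head.  With 1x1 kernels a convolution is a per-pixel linear map,
so the whole network -- forward, parameter gradients and the input gradients
that saliency needs -- is written directly in NumPy.  Training uses Adam on
cross-entropy and is deterministic given the seed (single-threaded kernels).

Saliency follows vanilla-gradient pixel attribution: the absolute gradient of
the *pre-softmax* class score with respect to each input pixel, symmetrized
because contact matrices are symmetric, then masked by the contact map of the
most populated structural cluster and aggregated over structural-domain pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ImageDataset
from .io import DomainAnnotation

__all__ = [
    "CNNSpec",
    "ContactCNN",
    "LinearSoftmaxModel",
    "TrainResult",
    "SaliencyResult",
    "build_model",
    "train_classifier",
    "evaluate",
    "vanilla_gradient_saliency",
    "mask_and_aggregate",
]


@dataclass
class CNNSpec:
    """Architecture and optimization settings for the contact-map classifier."""

    n_input: int                  # image side N
    n_classes: int
    conv_filters: tuple[int, int] = (16, 32)
    fc_sizes: tuple[int, int] = (512, 128)
    dropout: float = 0.5
    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("classification needs K >= 2 classes")
        if self.n_input < 8:
            raise ValueError("input side must be >= 8 for two 2x2 pools")

    @property
    def pooled_side(self) -> tuple[int, int]:
        s1 = self.n_input // 2
        return s1, s1 // 2

    @property
    def flatten_size(self) -> int:
        _, s2 = self.pooled_side
        return s2 * s2 * self.conv_filters[1]


@dataclass
class TrainResult:
    epochs_run: int
    train_loss: list[float]
    train_accuracy: list[float]
    val_loss: list[float]
    val_accuracy: list[float]
    confusion: np.ndarray         # (K, K) counts, rows = true class
    accuracy: float               # %, final validation
    loss: float                   # final validation cross-entropy


@dataclass
class SaliencyResult:
    raw: np.ndarray                       # (N, N) |d logit / d pixel|, symmetrized
    masked: np.ndarray | None = None      # raw * representative contact map
    domain_table: pd.DataFrame | None = None
    target_class: int | None = None


def _maxpool(x: np.ndarray) -> tuple[np.ndarray, tuple]:
    """2x2 max pool (floor division; trailing row/col dropped). Channels-last."""
    b, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, : h2 * 2, : w2 * 2, :]
    windows = (
        xc.reshape(b, h2, 2, w2, 2, c)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(b, h2, w2, c, 4)
    )
    idx = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
    return out, (idx, (b, h, w, c))


def _maxpool_backward(grad: np.ndarray, cache: tuple) -> np.ndarray:
    idx, (b, h, w, c) = cache
    h2, w2 = h // 2, w // 2
    gwin = np.zeros((b, h2, w2, c, 4))
    np.put_along_axis(gwin, idx[..., None], grad[..., None], axis=-1)
    gx = np.zeros((b, h, w, c))
    gx[:, : h2 * 2, : w2 * 2, :] = (
        gwin.reshape(b, h2, w2, c, 2, 2)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(b, h2 * 2, w2 * 2, c)
    )
    return gx


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ContactCNN:
    """The contact-map classifier with hand-written forward/backward passes."""

    def __init__(self, spec: CNNSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        f1, f2 = spec.conv_filters
        d1, d2 = spec.fc_sizes
        flat = spec.flatten_size

        def he(rng, n_in, shape):
            return rng.normal(scale=np.sqrt(2.0 / n_in), size=shape)

        self.params = {
            "w_conv1": he(rng, 1, (1, f1)),
            "b_conv1": np.zeros(f1),
            "w_conv2": he(rng, f1, (f1, f2)),
            "b_conv2": np.zeros(f2),
            "w_fc1": he(rng, flat, (flat, d1)),
            "b_fc1": np.zeros(d1),
            "w_fc2": he(rng, d1, (d1, d2)),
            "b_fc2": np.zeros(d2),
            "w_out": he(rng, d2, (d2, spec.n_classes)),
            "b_out": np.zeros(spec.n_classes),
        }
        self.trained = False
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ---------------------------------------------------------------- forward

    def forward(self, images: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> tuple[np.ndarray, dict]:
        """Pre-softmax class scores for a batch of (B, N, N) images."""
        p = self.params
        x = images[..., None]                               # (B, N, N, 1)
        cache: dict = {"x": x}

        a1 = x @ p["w_conv1"] + p["b_conv1"]                # 1x1 conv
        p1, cache["pool1"] = _maxpool(a1)
        r1 = np.maximum(p1, 0.0)
        cache["r1_mask"] = p1 > 0

        a2 = r1 @ p["w_conv2"] + p["b_conv2"]
        cache["r1"] = r1
        p2, cache["pool2"] = _maxpool(a2)
        r2 = np.maximum(p2, 0.0)
        cache["r2_mask"] = p2 > 0

        flat = r2.reshape(images.shape[0], -1)
        cache["flat"] = flat
        h1 = flat @ p["w_fc1"] + p["b_fc1"]
        g1 = np.maximum(h1, 0.0)
        cache["g1_mask"] = h1 > 0
        if train and self.spec.dropout > 0:
            keep = 1.0 - self.spec.dropout
            m1 = (rng.random(g1.shape) < keep) / keep
            g1 = g1 * m1
            cache["drop1"] = m1
        cache["g1"] = g1

        h2 = g1 @ p["w_fc2"] + p["b_fc2"]
        g2 = np.maximum(h2, 0.0)
        cache["g2_mask"] = h2 > 0
        if train and self.spec.dropout > 0:
            keep = 1.0 - self.spec.dropout
            m2 = (rng.random(g2.shape) < keep) / keep
            g2 = g2 * m2
            cache["drop2"] = m2
        cache["g2"] = g2

        logits = g2 @ p["w_out"] + p["b_out"]
        return logits, cache

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(images)
        return _softmax(logits)

    # --------------------------------------------------------------- backward

    def backward(self, cache: dict, dlogits: np.ndarray,
                 want_input_grad: bool = False) -> tuple[dict, np.ndarray | None]:
        """Gradients of a scalar objective given d(objective)/d(logits)."""
        p = self.params
        grads: dict = {}

        g2 = cache["g2"]
        grads["w_out"] = g2.T @ dlogits
        grads["b_out"] = dlogits.sum(axis=0)
        dg2 = dlogits @ p["w_out"].T
        if "drop2" in cache:
            dg2 = dg2 * cache["drop2"]
        dh2 = dg2 * cache["g2_mask"]

        g1 = cache["g1"]
        grads["w_fc2"] = g1.T @ dh2
        grads["b_fc2"] = dh2.sum(axis=0)
        dg1 = dh2 @ p["w_fc2"].T
        if "drop1" in cache:
            dg1 = dg1 * cache["drop1"]
        dh1 = dg1 * cache["g1_mask"]

        flat = cache["flat"]
        grads["w_fc1"] = flat.T @ dh1
        grads["b_fc1"] = dh1.sum(axis=0)
        dflat = dh1 @ p["w_fc1"].T

        b = flat.shape[0]
        s2 = self.spec.pooled_side[1]
        f2 = self.spec.conv_filters[1]
        dr2 = dflat.reshape(b, s2, s2, f2)
        dp2 = dr2 * cache["r2_mask"]
        da2 = _maxpool_backward(dp2, cache["pool2"])

        r1 = cache["r1"]
        grads["w_conv2"] = np.tensordot(r1, da2, axes=([0, 1, 2], [0, 1, 2]))
        grads["b_conv2"] = da2.sum(axis=(0, 1, 2))
        dr1 = da2 @ p["w_conv2"].T
        dp1 = dr1 * cache["r1_mask"]
        da1 = _maxpool_backward(dp1, cache["pool1"])

        x = cache["x"]
        grads["w_conv1"] = np.tensordot(x, da1, axes=([0, 1, 2], [0, 1, 2]))
        grads["b_conv1"] = da1.sum(axis=(0, 1, 2))

        dinput = None
        if want_input_grad:
            dinput = (da1 @ p["w_conv1"].T)[..., 0]
        return grads, dinput

    def input_gradient(self, image: np.ndarray, target: int) -> np.ndarray:
        """d(pre-softmax score of ``target``)/d(pixel), one image."""
        logits, cache = self.forward(image[None])
        dlogits = np.zeros_like(logits)
        dlogits[0, target] = 1.0
        _, dinput = self.backward(cache, dlogits, want_input_grad=True)
        return dinput[0]

    def _adam_step(self, grads: dict) -> None:
        self._adam_t += 1
        lr, b1, b2, eps = self.spec.learning_rate, 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = self._adam_m[k] / (1 - b1 ** self._adam_t)
            vhat = self._adam_v[k] / (1 - b2 ** self._adam_t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


class LinearSoftmaxModel:
    """Single linear layer + softmax, used as an analytic saliency oracle.

    Its input gradient for class k is exactly the weight map of class k, which
    pins down the attribution machinery independently of the CNN.
    """

    def __init__(self, weights: np.ndarray, bias: np.ndarray | None = None):
        self.weights = np.asarray(weights, float)       # (K, N, N)
        self.bias = np.zeros(self.weights.shape[0]) if bias is None else bias
        self.trained = True

    def forward(self, images: np.ndarray, **_):
        logits = np.tensordot(images, self.weights, axes=([1, 2], [1, 2])) + self.bias
        return logits, None

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return _softmax(self.forward(images)[0])

    def input_gradient(self, image: np.ndarray, target: int) -> np.ndarray:
        return self.weights[target].copy()


def build_model(spec: CNNSpec) -> ContactCNN:
    """Instantiate the classifier; shapes are validated by a forward pass."""
    model = ContactCNN(spec)
    probe = np.zeros((1, spec.n_input, spec.n_input))
    logits, _ = model.forward(probe)
    if logits.shape != (1, spec.n_classes):
        raise RuntimeError("internal shape error in model construction")
    return model


def _cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    probs = _softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(probs[np.arange(n), labels] + 1e-12))
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


def train_classifier(model: ContactCNN, dataset: ImageDataset,
                     epochs: int | None = None, seed: int = 0,
                     early_stop_accuracy: float | None = None) -> TrainResult:
    """Train on the stratified split; per-epoch metrics and final confusion.

    ``early_stop_accuracy`` (fraction, e.g. 0.99) stops once the validation
    accuracy reaches that level, keeping the epoch budget an upper bound.
    Raises on divergent (NaN) loss, naming the epoch.
    """
    if dataset.train_idx is None or dataset.val_idx is None:
        raise ValueError("dataset has no train/validation split")
    epochs = model.spec.epochs if epochs is None else epochs
    rng = np.random.default_rng(seed)
    xtr = dataset.images[dataset.train_idx]
    ytr = np.asarray(dataset.labels)[dataset.train_idx]
    xval = dataset.images[dataset.val_idx]
    yval = np.asarray(dataset.labels)[dataset.val_idx]

    hist = {k: [] for k in ("train_loss", "train_acc", "val_loss", "val_acc")}
    bs = model.spec.batch_size
    epochs_run = 0
    for epoch in range(epochs):
        order = rng.permutation(len(xtr))
        losses, correct = [], 0
        for start in range(0, len(order), bs):
            batch = order[start:start + bs]
            logits, cache = model.forward(xtr[batch], train=True, rng=rng)
            loss, dlogits = _cross_entropy(logits, ytr[batch])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch + 1}")
            grads, _ = model.backward(cache, dlogits)
            model._adam_step(grads)
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == ytr[batch]).sum())
        hist["train_loss"].append(float(np.mean(losses)))
        hist["train_acc"].append(correct / len(xtr))

        vlogits, _ = model.forward(xval)
        vloss, _ = _cross_entropy(vlogits, yval)
        vacc = float((vlogits.argmax(axis=1) == yval).mean())
        hist["val_loss"].append(vloss)
        hist["val_acc"].append(vacc)
        epochs_run = epoch + 1
        if early_stop_accuracy is not None and vacc >= early_stop_accuracy:
            break

    model.trained = True
    confusion, accuracy, loss = evaluate(model, xval, yval)
    return TrainResult(
        epochs_run=epochs_run,
        train_loss=hist["train_loss"], train_accuracy=hist["train_acc"],
        val_loss=hist["val_loss"], val_accuracy=hist["val_acc"],
        confusion=confusion, accuracy=accuracy, loss=loss,
    )


def evaluate(model, images: np.ndarray, labels: np.ndarray
             ) -> tuple[np.ndarray, float, float]:
    """Confusion matrix (rows = true class), accuracy (%) and mean loss."""
    if len(images) == 0:
        raise ValueError("empty evaluation split")
    labels = np.asarray(labels)
    logits, _ = model.forward(images)
    loss, _ = _cross_entropy(logits, labels)
    pred = logits.argmax(axis=1)
    k = logits.shape[1]
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(labels, pred):
        confusion[t, p] += 1
    accuracy = 100.0 * np.trace(confusion) / confusion.sum()
    return confusion, float(accuracy), float(loss)


def vanilla_gradient_saliency(model, image: np.ndarray, target: int) -> SaliencyResult:
    """|d(pre-softmax target score)/d pixel|, symmetrized as (M + M.T)/2."""
    if not getattr(model, "trained", False):
        raise ValueError("saliency requires a trained classifier")
    grad = model.input_gradient(np.asarray(image, float), target)
    raw = np.abs(grad)
    raw = 0.5 * (raw + raw.T)
    return SaliencyResult(raw=raw, target_class=target)


def mask_and_aggregate(saliency: SaliencyResult, representative_map: np.ndarray,
                       annotation: DomainAnnotation,
                       residue_ids: np.ndarray | None = None) -> SaliencyResult:
    """Mask the raw map by the representative contacts; sum per domain pair.

    The table covers the upper triangle (including the diagonal) of the masked
    map; residues outside every annotated domain are pooled under
    ``"unassigned"``.  When domains tile the sequence, the table total equals
    the total masked attribution.
    """
    raw = saliency.raw
    if raw.shape != representative_map.shape:
        raise ValueError("saliency map and representative contact map shapes differ")
    n = raw.shape[0]
    if residue_ids is None:
        residue_ids = np.arange(1, n + 1)
    masked = raw * (representative_map > 0)
    domains = [annotation.domain_of(int(r)) or "unassigned" for r in residue_ids]
    totals: dict[tuple[str, str], float] = {}
    for i in range(n):
        for j in range(i, n):
            if masked[i, j] == 0.0:
                continue
            key = tuple(sorted((domains[i], domains[j])))
            totals[key] = totals.get(key, 0.0) + float(masked[i, j])
    table = pd.DataFrame(
        [(a, b, v) for (a, b), v in totals.items()],
        columns=["domain_a", "domain_b", "attribution"],
    ).sort_values("attribution", ascending=False, ignore_index=True)
    return SaliencyResult(raw=raw, masked=masked, domain_table=table,
                          target_class=saliency.target_class)
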