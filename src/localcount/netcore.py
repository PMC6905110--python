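"""Runnable counting networks: construction, forward passes, training.

Four variants share the same AlexNet-like stack (equal weight counts):

``tasselnet``
    patch network, padded convs; input 64x64, target = count in the patch.
``tasselnet_ctx``
    patch network with all conv padding removed; input 94x94 (the 64x64
    window plus a 15 px context annulus), target = count in the central
    64x64 window only.
``tasselnetv2``
    fully convolutional form of ``tasselnet_ctx``: per-layer padding on
    conv1-conv5 accumulates to 15 input-pixel zero paddings, conv6 strides 2,
    and one forward pass over the whole image emits every local count at
    stride 16.
``tasselnetv2_del_c``
    same network as ``tasselnetv2`` but the regression target is the count
    in the whole 94x94 receptive field instead of its central 64x64 window —
    the ablation that removes the context margin.

Every convolution is followed by batch normalization and ReLU except the
final 1x1 count layer, whose raw output is used in training and clamped to
zero from below at inference. Weights use He ("improved Xavier")
initialization; optimization is plain SGD on an L1 (optionally L2) loss over
local counts, with the learning rate cut when validation MAE stagnates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import arch
from .arch import NetworkSpec
from .countmap import RawCountGrid, image_count, merge_normalize
from .engine import BatchNorm2d, Conv2d, MaxPool2d, ReLU, Sequential, SGD
from .errors import GeometryError, ValidationError
from .targets import DotAnnotation, LocalCountMap, density_from_dots, local_counts

__all__ = [
    "ModelVariant",
    "Model",
    "TrainConfig",
    "TrainedModel",
    "VARIANT_NAMES",
    "build_model",
    "forward_patch",
    "forward_image",
    "predict_count",
    "targets_for_variant",
    "train",
    "weight_parameter_count",
    "total_parameter_count",
]

STRIDE = 16
GAUSSIAN_SIGMA = 4.0


@dataclass(frozen=True)
class ModelVariant:
    """Geometry contract of one network variant."""

    name: str
    spec: NetworkSpec
    patch_input: int            # expected patch side for forward_patch
    window: int                 # regression-target window side
    context: int                # context margin around the window
    pad: int                    # zero padding around the input image
    fully_convolutional: bool

    @property
    def origin_offset(self) -> int:
        return self.context - self.pad


def _variants() -> Dict[str, ModelVariant]:
    return {
        "tasselnet": ModelVariant(
            "tasselnet", arch.tasselnet_spec(), 64, 64, 0, 0, False),
        "tasselnet_ctx": ModelVariant(
            "tasselnet_ctx", arch.tasselnet_ctx_spec(), 94, 64, 15, 15, False),
        "tasselnetv2": ModelVariant(
            "tasselnetv2", arch.tasselnetv2_spec(), 94, 64, 15, 15, True),
        "tasselnetv2_del_c": ModelVariant(
            "tasselnetv2_del_c", arch.tasselnetv2_spec(), 94, 94, 0, 15, True),
    }


VARIANT_NAMES = tuple(_variants())


def _build_net(spec: NetworkSpec, rng: np.random.Generator) -> Sequential:
    layers: List = []
    n = len(spec.layers)
    for i, l in enumerate(spec.layers):
        if l.kind == "maxpool":
            layers.append(MaxPool2d(l.kernel[0], l.stride))
            continue
        layers.append(Conv2d(l.in_channels, l.out_channels, l.kernel,
                             l.stride, l.padding, rng))
        if i < n - 1:  # final count layer stays raw
            layers.append(BatchNorm2d(l.out_channels))
            layers.append(ReLU())
    return Sequential(layers)


class Model:
    """A variant plus its live weights and per-channel normalization means."""

    def __init__(self, variant: ModelVariant, net: Sequential,
                 means: Optional[np.ndarray] = None):
        self.variant = variant
        self.net = net
        self.means = (np.zeros(3, dtype=np.float32) if means is None
                      else np.asarray(means, dtype=np.float32))
        self._patch_net: Optional[Sequential] = None

    def preprocess(self, image: np.ndarray) -> np.ndarray:
        """(H, W, 3) image -> (1, 3, H, W) float32, [0,1]-scaled, mean-subtracted."""
        img = np.asarray(image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise GeometryError(f"expected an (H, W, 3) image, got {img.shape}")
        x = img.astype(np.float32)
        if img.dtype == np.uint8:
            x /= 255.0
        x -= self.means[None, None, :]
        return np.ascontiguousarray(x.transpose(2, 0, 1))[None]

    def patch_net(self) -> Sequential:
        """Padding-stripped twin sharing weight arrays (for patch inference)."""
        if not any(isinstance(l, Conv2d) and l.padding for l in self.net.layers):
            return self.net
        if self._patch_net is None:
            twins: List = []
            for l in self.net.layers:
                if isinstance(l, Conv2d):
                    twin = Conv2d(l.cin, l.cout, (l.kh, l.kw), l.stride, 0)
                    twin.W = l.W  # shared storage, not a copy
                    twin.b = l.b
                    twins.append(twin)
                elif isinstance(l, BatchNorm2d):
                    twin = BatchNorm2d(l.c, l.eps, l.momentum)
                    twin.gamma, twin.beta = l.gamma, l.beta
                    twin.running_mean, twin.running_var = l.running_mean, l.running_var
                    twins.append(twin)
                elif isinstance(l, MaxPool2d):
                    twins.append(MaxPool2d(l.k, l.k))
                else:
                    twins.append(ReLU())
            self._patch_net = Sequential(twins)
        return self._patch_net


def build_model(variant_name: str, seed: int) -> Model:
    """Deterministically initialized model for a named variant."""
    variants = _variants()
    if variant_name not in variants:
        raise ValidationError(
            f"unknown variant {variant_name!r}; valid names: "
            f"{', '.join(variants)}")
    variant = variants[variant_name]
    net = _build_net(variant.spec, np.random.default_rng(seed))
    return Model(variant, net)


def weight_parameter_count(model: Model) -> int:
    """Convolution weights only — the headline capacity figure."""
    return sum(l.W.size for l in model.net.layers if isinstance(l, Conv2d))


def total_parameter_count(model: Model) -> int:
    """Weights plus biases and batch-norm affine parameters."""
    n = 0
    for l in model.net.layers:
        for p in l.parameters().values():
            n += p.size
    return n


# --------------------------------------------------------------------------
# Forward passes
# --------------------------------------------------------------------------

def forward_patch(model: Model, patch: np.ndarray,
                  allow_geometry_mismatch: bool = False) -> float:
    """Map one patch to one non-negative local count (inference mode).

    The patch side must equal the variant's expected input (64 for the
    no-context network, 94 otherwise). Feeding a mismatched patch — e.g.
    context-sized patches to a context-free model, the information-asymmetry
    probe — must be requested explicitly via ``allow_geometry_mismatch``;
    the center output cell is returned in that case.
    """
    img = np.asarray(patch)
    e = model.variant.patch_input
    if img.shape[:2] != (e, e) and not allow_geometry_mismatch:
        raise GeometryError(
            f"variant {model.variant.name!r} expects {e}x{e} patches, got "
            f"{img.shape[0]}x{img.shape[1]} (pass allow_geometry_mismatch "
            "to override)")
    x = model.preprocess(img)
    # FCN variants drop their padding for patch evaluation so the patch sees
    # exactly the receptive field; patch variants run their own stack as-is.
    net = model.patch_net() if model.variant.fully_convolutional else model.net
    y = net.forward(x, training=False)
    h, w = y.shape[2], y.shape[3]
    return float(max(0.0, y[0, 0, h // 2, w // 2]))


def _patch_positions(variant: ModelVariant, image_hw: Tuple[int, int]) -> Tuple[int, int]:
    h, w = image_hw
    extent = variant.window + 2 * variant.context
    gh = (h + 2 * variant.pad - extent) // STRIDE + 1
    gw = (w + 2 * variant.pad - extent) // STRIDE + 1
    if gh < 1 or gw < 1:
        raise GeometryError(
            f"image {h}x{w} too small for variant {variant.name!r}")
    return gh, gw


def _extract_patches(model: Model, image: np.ndarray) -> Tuple[np.ndarray, Tuple[int, int]]:
    """Dense stride-16 patches over the zero-padded canvas, as one batch."""
    v = model.variant
    x = model.preprocess(image)[0]  # (3, H, W)
    p = v.pad
    if p:
        x = np.pad(x, ((0, 0), (p, p), (p, p)))
    gh, gw = _patch_positions(v, image.shape[:2])
    e = v.patch_input
    out = np.empty((gh * gw, 3, e, e), dtype=np.float32)
    k = 0
    for i in range(gh):
        for j in range(gw):
            out[k] = x[:, STRIDE * i:STRIDE * i + e, STRIDE * j:STRIDE * j + e]
            k += 1
    return out, (gh, gw)


def forward_image(model: Model, image: np.ndarray,
                  batch_size: int = 64) -> RawCountGrid:
    """All local counts of one image, as a RawCountGrid (inference mode).

    Fully convolutional variants run the image through the network once;
    patch variants crop the dense stride-16 patch lattice and forward it in
    batches — the two routes agree on interior cells by construction.
    """
    v = model.variant
    img = np.asarray(image)
    if v.fully_convolutional:
        y = model.net.forward(model.preprocess(img), training=False)
        grid = np.maximum(y[0, 0], 0.0).astype(np.float64)
    else:
        patches, (gh, gw) = _extract_patches(model, img)
        preds = np.empty(len(patches), dtype=np.float64)
        net = model.net
        for s in range(0, len(patches), batch_size):
            y = net.forward(patches[s:s + batch_size], training=False)
            preds[s:s + len(y)] = y[:, 0].mean(axis=(1, 2))
        grid = np.maximum(preds, 0.0).reshape(gh, gw)
    return RawCountGrid(grid, v.window, STRIDE, v.origin_offset, img.shape[:2])


def predict_count(model: Model, image: np.ndarray) -> float:
    """Image-level count: forward pass, merge-normalize, integrate."""
    return image_count(merge_normalize(forward_image(model, image)))


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimization settings. ``batch_size`` counts images for fully
    convolutional variants and patches for patch variants."""

    learning_rate: float = 0.1
    batch_size: int = 4
    epochs: int = 30
    split: float = 0.9
    seed: int = 0
    loss: str = "l1"            # "l1" | "l2" on local counts
    lr_factor: float = 0.1
    patience: int = 10
    min_lr: float = 1e-4

    def __post_init__(self) -> None:
        if not 0.0 < self.split < 1.0:
            raise ValidationError(f"split must be in (0, 1), got {self.split}")
        if self.loss not in ("l1", "l2"):
            raise ValidationError(f"loss must be 'l1' or 'l2', got {self.loss!r}")


@dataclass
class TrainedModel:
    model: Model
    history: List[dict]
    config: TrainConfig
    best_val_mae: float


def targets_for_variant(dots: DotAnnotation, variant: ModelVariant,
                        sigma: float = GAUSSIAN_SIGMA) -> LocalCountMap:
    """Ground-truth local-count grid matching a variant's output geometry."""
    density = density_from_dots(dots, sigma)
    return local_counts(density, variant.window, STRIDE, variant.pad,
                        variant.context)


def _loss_grad(pred: np.ndarray, target: np.ndarray, kind: str):
    diff = pred - target
    n = diff.size
    if kind == "l1":
        return float(np.abs(diff).mean()), np.sign(diff).astype(np.float32) / n
    return float((diff ** 2).mean()), (2.0 * diff / n).astype(np.float32)


def train(model: Model, data: Sequence[Tuple[np.ndarray, DotAnnotation]],
          config: TrainConfig) -> TrainedModel:
    """Fit a model on (image, dots) pairs; returns best-validation weights.

    The split, per-channel mean subtraction, target construction and the
    epoch loop all draw their randomness from ``config.seed``, so a run is
    exactly reproducible. Validation is scored as image-level MAE through the
    full merge-normalize pipeline, which also drives the
    reduce-on-plateau learning-rate schedule and best-weight selection.
    """
    if len(data) < 2:
        raise ValidationError("training needs at least two (image, dots) pairs")
    rng = np.random.default_rng(config.seed)
    idx = rng.permutation(len(data))
    n_train = max(1, min(len(data) - 1, int(round(config.split * len(data)))))
    train_set = [data[i] for i in idx[:n_train]]
    val_set = [data[i] for i in idx[n_train:]]

    imgs = [np.asarray(im) for im, _ in train_set]
    model.means[...] = np.mean(
        [im.astype(np.float64).mean(axis=(0, 1)) / (255.0 if im.dtype == np.uint8 else 1.0)
         for im in imgs], axis=0).astype(np.float32)

    v = model.variant
    targets = [targets_for_variant(dots, v).values.astype(np.float32)
               for _, dots in train_set]

    # geometry check before the first optimization step
    hw = imgs[0].shape[:2]
    expected = _patch_positions(v, hw)
    if v.fully_convolutional:
        out_hw = arch.output_shape(v.spec, hw)
        if out_hw != targets[0].shape:
            raise GeometryError(
                f"network output grid {out_hw} does not match target grid "
                f"{targets[0].shape}")
    if targets[0].shape != expected:
        raise GeometryError(
            f"target grid {targets[0].shape} does not match the variant "
            f"lattice {expected}")

    if v.fully_convolutional:
        xs = np.stack([model.preprocess(im)[0] for im in imgs])
        ys = np.stack(targets)[:, None]        # (N, 1, gh, gw)
        n_items = len(xs)
    else:
        patch_list, tgt_list = [], []
        for im, t in zip(imgs, targets):
            patches, _ = _extract_patches(model, im)
            patch_list.append(patches)
            tgt_list.append(t.reshape(-1))
        xs = np.concatenate(patch_list)
        ys = np.concatenate(tgt_list).astype(np.float32)[:, None, None, None]
        n_items = len(xs)

    opt = SGD(model.net, config.learning_rate)
    history: List[dict] = []
    best_mae = np.inf
    best_state = model.net.state_dict()
    stale = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n_items)
        losses = []
        for s in range(0, n_items, config.batch_size):
            sel = order[s:s + config.batch_size]
            x, t = xs[sel], ys[sel]
            y = model.net.forward(x, training=True)
            if not v.fully_convolutional:
                t = np.broadcast_to(t, y.shape)
            loss, dy = _loss_grad(y, t, config.loss)
            model.net.backward(dy)
            opt.step()
            losses.append(loss)
        val_pairs = [(predict_count(model, im), len(d)) for im, d in val_set]
        val_mae = float(np.mean([abs(p - g) for p, g in val_pairs]))
        history.append({
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": float(np.mean(losses)),
            "val_mae": val_mae,
        })
        if val_mae < best_mae - 1e-6:
            best_mae = val_mae
            best_state = model.net.state_dict()
            stale = 0
        else:
            stale += 1
            if stale >= config.patience and opt.lr > config.min_lr:
                opt.lr = max(config.min_lr, opt.lr * config.lr_factor)
                stale = 0
    model.net.load_state_dict(best_state)
    return TrainedModel(model, history, config, float(best_mae))
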