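"""U-Net segmentation estimator with transfer-learning support.

`UNetSegmenter` is a scikit-learn style estimator: hyperparameters in
``__init__``, learned state in ``fit``-set attributes with trailing
underscores, `get_params`/`set_params` via `BaseEstimator`.  ``X`` is a
stack of RGB images ``(n, H, W, 3)`` (uint8 or floats in [0, 255]) and
``y`` a stack of binary masks ``(n, H, W)``.

The training protocol follows the transfer-learning segmentation recipe
this package implements: binary focal loss, Adam, data augmentation
restricted to horizontal and vertical flips, and an optional pretrained
state that the weights are initialised from (the source-domain model of
the transfer-learning structure).  Training is fully deterministic given
the seed.

Backbone presets
----------------
``tiny``   2 downsampling stages, base width 8   (CPU-trainable in minutes)
``small``  2 downsampling stages, base width 16
``large``  3 downsampling stages, base width 16

All presets are capacity variants of the same encoder-decoder; parameter
count grows strictly from tiny to large.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator

from ._nn import Adam, UNetCore, focal_loss_and_grad
from .metrics import FocalLossParams, binarize, compare_masks

__all__ = [
    "BACKBONES",
    "BackboneSpec",
    "TrainingConfig",
    "ModelState",
    "UNetSegmenter",
    "build_model",
    "train",
    "predict_masks",
    "reset_weights",
    "augment_pair",
]

#: name -> (depth, base_width)
BACKBONES: dict[str, tuple[int, int]] = {
    "tiny": (2, 8),
    "small": (2, 16),
    "large": (3, 16),
}


@dataclass(frozen=True)
class BackboneSpec:
    """Architecture choice for the encoder-decoder."""

    name: str = "tiny"
    input_size: int = 64
    base_width: int | None = None  # None -> preset default

    def __post_init__(self) -> None:
        if self.name not in BACKBONES:
            raise ValueError(f"unknown backbone {self.name!r}; choose from {sorted(BACKBONES)}")
        depth = BACKBONES[self.name][0]
        if self.input_size % (2**depth):
            raise ValueError(f"input_size must be divisible by {2**depth}")

    @property
    def depth(self) -> int:
        return BACKBONES[self.name][0]

    @property
    def width(self) -> int:
        return self.base_width or BACKBONES[self.name][1]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation protocol for one training run.

    Defaults follow the full-scale protocol (100 epochs of Adam at 1e-5,
    flips-only augmentation); desk-scale runs override epochs and
    learning rate — see woundseg.benchmark.
    """

    epochs: int = 100
    learning_rate: float = 1e-5
    batch_size: int = 8
    loss: FocalLossParams = field(default_factory=FocalLossParams)
    horizontal_flip: bool = True
    vertical_flip: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class ModelState:
    """Serializable snapshot of a model: architecture + weights + origin."""

    backbone: BackboneSpec
    weights: dict[str, np.ndarray]
    provenance: str = ""

    def copy(self) -> "ModelState":
        return ModelState(
            backbone=self.backbone,
            weights={k: v.copy() for k, v in self.weights.items()},
            provenance=self.provenance,
        )

    def save(self, path: str | Path) -> None:
        """Weights as .npz plus a JSON sidecar with the architecture."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.weights)
        sidecar = {
            "backbone": self.backbone.name,
            "input_size": self.backbone.input_size,
            "base_width": self.backbone.base_width,
            "provenance": self.provenance,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ModelState":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as npz:
            weights = {k: npz[k].copy() for k in npz.files}
        spec = BackboneSpec(
            name=sidecar["backbone"],
            input_size=sidecar["input_size"],
            base_width=sidecar["base_width"],
        )
        return cls(backbone=spec, weights=weights, provenance=sidecar.get("provenance", ""))


def augment_pair(
    image: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
    horizontal: bool = True, vertical: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the same random flips to an image and its mask.

    Each enabled axis is flipped independently with probability 0.5.
    """
    if image.shape[:2] != mask.shape:
        raise ValueError(f"image {image.shape[:2]} and mask {mask.shape} misaligned")
    if horizontal and rng.random() < 0.5:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if vertical and rng.random() < 0.5:
        image, mask = image[::-1, :], mask[::-1, :]
    return image, mask


def _resize_image(img: np.ndarray, size: int) -> np.ndarray:
    if img.shape[0] == size and img.shape[1] == size:
        return np.asarray(img, dtype=np.float32)
    out = _sk_resize(img.astype(np.float64), (size, size), order=1,
                     preserve_range=True, anti_aliasing=True)
    return out.astype(np.float32)


def _resize_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if mask.shape == shape:
        return mask
    out = _sk_resize(mask.astype(np.float64), shape, order=0, preserve_range=True,
                     anti_aliasing=False)
    return (out > 0.5).astype(mask.dtype)


class UNetSegmenter(BaseEstimator):
    """Binary segmentation with a small U-Net trained on focal loss.

    Parameters
    ----------
    backbone : str
        One of "tiny", "small", "large" (see module docstring).
    input_size : int
        Side of the square working resolution; inputs of other sizes are
        resized (bilinear for images, nearest for masks) and predictions
        are returned at the original resolution.
    base_width : int or None
        Override the preset's base channel count.
    epochs, learning_rate, batch_size : optimisation protocol.
    alpha, gamma, beta : focal-loss parameters (beta is inert).
    horizontal_flip, vertical_flip : augmentation switches.
    threshold : probability threshold used by :meth:`predict`.
    pretrained : ModelState or None
        Weights to start training from (transfer learning); architecture
        must match.
    seed : int
        Seeds weight init, shuffling and augmentation; fixes the run.

    Attributes
    ----------
    state_ : ModelState           weights after fitting
    history_ : dict[str, list]    per-epoch training loss (and val F1/IoU
                                  when validation data is passed to fit)
    n_parameters_ : int
    """

    def __init__(self, backbone: str = "tiny", input_size: int = 64,
                 base_width: int | None = None, epochs: int = 100,
                 learning_rate: float = 1e-5, batch_size: int = 8,
                 alpha: float = 0.25, gamma: float = 2.0, beta: float = 1.0,
                 horizontal_flip: bool = True, vertical_flip: bool = True,
                 threshold: float = 0.5, pretrained: ModelState | None = None,
                 seed: int = 0) -> None:
        self.backbone = backbone
        self.input_size = input_size
        self.base_width = base_width
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.alpha = alpha
        self.gamma = gamma
        self.beta = beta
        self.horizontal_flip = horizontal_flip
        self.vertical_flip = vertical_flip
        self.threshold = threshold
        self.pretrained = pretrained
        self.seed = seed

    # -- construction -------------------------------------------------------

    def _spec(self) -> BackboneSpec:
        return BackboneSpec(name=self.backbone, input_size=self.input_size,
                            base_width=self.base_width)

    def _build_core(self) -> UNetCore:
        spec = self._spec()
        core = UNetCore(in_channels=3, base_width=spec.width, depth=spec.depth,
                        seed=self.seed)
        if self.pretrained is not None:
            if (self.pretrained.backbone.name, self.pretrained.backbone.width,
                    self.pretrained.backbone.depth) != (spec.name, spec.width, spec.depth):
                raise ValueError(
                    f"pretrained backbone {self.pretrained.backbone} does not match {spec}"
                )
            core.set_weights(self.pretrained.weights)
        return core

    def load_state(self, state: ModelState) -> "UNetSegmenter":
        """Adopt an existing state for inference without fitting."""
        self.backbone = state.backbone.name
        self.input_size = state.backbone.input_size
        self.base_width = state.backbone.base_width
        core = UNetCore(in_channels=3, base_width=state.backbone.width,
                        depth=state.backbone.depth, seed=self.seed)
        core.set_weights(state.weights)
        self._core = core
        self.state_ = state.copy()
        self.n_parameters_ = core.n_parameters()
        self.history_ = {"loss": []}
        return self

    # -- fitting ------------------------------------------------------------

    @staticmethod
    def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(f"X must be (n, H, W, 3), got {X.shape}")
        if len(X) == 0:
            raise ValueError("training set is empty")
        if y.ndim != 3 or y.shape != X.shape[:3]:
            raise ValueError(f"y must be (n, H, W) aligned with X, got {y.shape}")
        return X, y

    def _prepare(self, X: np.ndarray, y: np.ndarray | None = None):
        size = self.input_size
        imgs = np.stack([_resize_image(x, size) for x in X]) / 255.0
        # per-image, per-channel standardization: removes global gain and
        # most gamma variability so the net sees relative contrast only
        mean = imgs.mean(axis=(1, 2), keepdims=True)
        std = imgs.std(axis=(1, 2), keepdims=True)
        imgs = (imgs - mean) / np.maximum(std, 1e-6)
        if y is None:
            return imgs.astype(np.float32), None
        masks = np.stack([_resize_mask(np.asarray(m) > 0, (size, size)) for m in y])
        return imgs.astype(np.float32), masks.astype(np.float32)

    def fit(self, X, y, X_val=None, y_val=None) -> "UNetSegmenter":
        X, y = self._validate_xy(X, y)
        core = self._build_core()
        imgs, masks = self._prepare(X, y)
        opt = Adam(lr=self.learning_rate)
        rng = np.random.default_rng([self.seed, 0x5AFE])
        loss_params = FocalLossParams(alpha=self.alpha, gamma=self.gamma, beta=self.beta)

        history: dict[str, list] = {"loss": []}
        if X_val is not None:
            history["val_f1"] = []
            history["val_iou"] = []

        n = len(imgs)
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = np.empty((len(idx), self.input_size, self.input_size, 3), np.float32)
                yb = np.empty((len(idx), self.input_size, self.input_size), np.float32)
                for k, i in enumerate(idx):
                    xi, yi = augment_pair(imgs[i], masks[i], rng,
                                          horizontal=self.horizontal_flip,
                                          vertical=self.vertical_flip)
                    xb[k], yb[k] = xi, yi
                z, cache = core.forward(xb, want_cache=True)
                loss, dz = focal_loss_and_grad(yb, z, loss_params.alpha, loss_params.gamma)
                grads = core.backward(cache, dz)
                opt.step(core.params, grads)
                losses.append(loss)
            history["loss"].append(float(np.mean(losses)))
            if X_val is not None:
                f1s, ious = self._val_metrics(core, X_val, y_val)
                history["val_f1"].append(f1s)
                history["val_iou"].append(ious)

        self._core = core
        self.state_ = ModelState(backbone=self._spec(), weights=core.get_weights(),
                                 provenance="fit")
        self.history_ = history
        self.n_parameters_ = core.n_parameters()
        return self

    def _val_metrics(self, core: UNetCore, X_val, y_val) -> tuple[float, float]:
        imgs, _ = self._prepare(np.asarray(X_val))
        z = core.forward(imgs)
        probs = 1.0 / (1.0 + np.exp(-z.astype(np.float64)))
        f1s, ious = [], []
        for prob, truth in zip(probs, np.asarray(y_val)):
            pred = _resize_mask(binarize(prob, self.threshold), truth.shape)
            rep = compare_masks(pred, truth > 0)
            f1s.append(rep.f1)
            ious.append(rep.iou)
        return float(np.mean(f1s)), float(np.mean(ious))

    # -- inference ----------------------------------------------------------

    def _require_fitted(self) -> UNetCore:
        core = getattr(self, "_core", None)
        if core is None:
            raise RuntimeError("model has no trained weights; call fit() or load_state()")
        return core

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel foreground probabilities at the working resolution."""
        core = self._require_fitted()
        X = np.asarray(X)
        if X.ndim == 3:
            X = X[None]
        imgs, _ = self._prepare(X)
        out = []
        for start in range(0, len(imgs), 32):
            z = core.forward(imgs[start : start + 32])
            out.append(1.0 / (1.0 + np.exp(-z.astype(np.float64))))
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        """Binary masks at the resolution of the input images."""
        X = np.asarray(X)
        squeeze = X.ndim == 3
        if squeeze:
            X = X[None]
        probs = self.predict_proba(X)
        masks = [
            _resize_mask(binarize(p, self.threshold), x.shape[:2])
            for p, x in zip(probs, X)
        ]
        out = np.stack(masks).astype(np.uint8)
        return out[0] if squeeze else out

    def score(self, X, y) -> float:
        """Mean per-image F1 against reference masks."""
        preds = self.predict(X)
        return float(np.mean([compare_masks(p, t > 0).f1 for p, t in zip(preds, np.asarray(y))]))


# ---------------------------------------------------------------------------
# module-level operations (thin wrappers over the estimator)


def build_model(spec: BackboneSpec, seed: int = 0, provenance: str = "init") -> ModelState:
    """Freshly initialised (untrained) model state for a backbone spec."""
    core = UNetCore(in_channels=3, base_width=spec.width, depth=spec.depth, seed=seed)
    return ModelState(backbone=spec, weights=core.get_weights(), provenance=provenance)


def _samples_to_xy(samples) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.pixels for s in samples])
    if any(s.truth_mask is None for s in samples):
        raise ValueError("all training samples must carry masks")
    y = np.stack([s.truth_mask for s in samples])
    return X, y


def train(state: ModelState, train_samples, val_samples, cfg: TrainingConfig,
          provenance: str = "trained") -> tuple[ModelState, dict]:
    """Train from a starting state; returns the new state and history."""
    X, y = _samples_to_xy(train_samples)
    est = UNetSegmenter(
        backbone=state.backbone.name, input_size=state.backbone.input_size,
        base_width=state.backbone.base_width, epochs=cfg.epochs,
        learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
        alpha=cfg.loss.alpha, gamma=cfg.loss.gamma, beta=cfg.loss.beta,
        horizontal_flip=cfg.horizontal_flip, vertical_flip=cfg.vertical_flip,
        pretrained=state, seed=cfg.seed,
    )
    if val_samples:
        Xv, yv = _samples_to_xy(val_samples)
        est.fit(X, y, X_val=Xv, y_val=yv)
    else:
        est.fit(X, y)
    new_state = est.state_
    new_state.provenance = provenance
    return new_state, est.history_


def predict_masks(state: ModelState, images, threshold: float = 0.5) -> np.ndarray:
    """Binary masks for a stack of images using a saved state."""
    est = UNetSegmenter(threshold=threshold).load_state(state)
    return est.predict(np.asarray(images))


def reset_weights(state: ModelState, pretrained: ModelState) -> ModelState:
    """Restore a model to a pretrained configuration (same architecture)."""
    if (state.backbone.name, state.backbone.width, state.backbone.depth) != (
        pretrained.backbone.name, pretrained.backbone.width, pretrained.backbone.depth
    ):
        raise ValueError("backbone specs differ; cannot restore weights")
    out = pretrained.copy()
    out.provenance = pretrained.provenance
    return out
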