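"""Two-module ocular model: pixel-wise segmentation + blink classifier.

Both modules sit on the shared multi-scale feature encoder in
:mod:`oculotrace.features`: the segmentation head is a small MLP applied
per pixel (4 exclusive classes: background, sclera, iris, pupil), the
blink head is an MLP over pooled encoder maps (3 states: open, closing,
closed).  Training is CPU-scale and deterministic under the config seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier

from . import features as F
from .synth import AnnotatedFrame, BLINK_STATES

_SEG_CLASSES = np.array([0, 1, 2, 3])
_BLINK_IDX = {s: i for i, s in enumerate(BLINK_STATES)}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training configuration.

    ``base_channels`` and ``depth`` size the segmentation head's hidden
    layers (widths ``base_channels * (depth, ..., 1)``), so the
    parameter count grows monotonically with ``base_channels``.
    ``blink_head='attached'`` feeds the blink MLP pooled encoder maps;
    ``'detached'`` pools the raw image instead (ablation mode).
    """

    input_size: tuple[int, int] = (100, 100)
    n_classes: int = 4
    base_channels: int = 8
    depth: int = 2
    blink_head: str = "attached"
    seed: int = 0
    epochs: int = 8
    blink_epochs: int = 40
    batch_size: int = 512
    learning_rate: float = 1e-3
    pixels_per_class: int = 50
    val_frames: int = 8

    def __post_init__(self) -> None:
        if self.blink_head not in ("attached", "detached"):
            raise ValueError(f"blink_head must be attached|detached, got {self.blink_head!r}")
        if self.base_channels < 1 or self.depth < 1:
            raise ValueError("base_channels and depth must be >= 1")
        if self.n_classes != 4:
            raise ValueError("segmentation head is defined for 4 exclusive classes")

    @property
    def seg_hidden(self) -> tuple[int, ...]:
        return tuple(self.base_channels * k for k in range(self.depth, 0, -1))

    @property
    def blink_hidden(self) -> tuple[int, ...]:
        return (8 * self.base_channels, 4 * self.base_channels)


@dataclass
class SegmentationOutput:
    """Per-pixel class probabilities (H x W x 4 simplex) and argmax map."""

    prob: np.ndarray
    label_map: np.ndarray


@dataclass
class BlinkPrediction:
    """Blink-state probabilities over (open, closing, closed) + argmax label."""

    probs: np.ndarray
    label: str


class _Standardizer:
    """Feature-wise mean/scale fitted on training pixels."""

    def __init__(self) -> None:
        self.mean: Optional[np.ndarray] = None
        self.scale: Optional[np.ndarray] = None

    def fit(self, x: np.ndarray) -> None:
        self.mean = x.mean(axis=0)
        self.scale = x.std(axis=0)
        self.scale[self.scale < 1e-9] = 1.0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        if self.mean is None:
            return x
        return (x - self.mean) / self.scale


class SegBlinkModel:
    """Handle bundling the shared encoder config and both MLP heads."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.seg_mlp = MLPClassifier(
            hidden_layer_sizes=cfg.seg_hidden,
            learning_rate_init=cfg.learning_rate,
            batch_size=cfg.batch_size,
            random_state=cfg.seed,
        )
        self.blink_mlp = MLPClassifier(
            hidden_layer_sizes=cfg.blink_hidden,
            learning_rate_init=cfg.learning_rate,
            batch_size=min(cfg.batch_size, 128),
            random_state=cfg.seed + 1,
        )
        self.seg_scaler = _Standardizer()
        self.blink_scaler = _Standardizer()
        # Materialize deterministic initial weights for both heads; the
        # tiny dummy batch triggers sklearn's batch-size clipping warning.
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            dummy = np.zeros((len(_SEG_CLASSES), F.N_PIXEL_FEATURES))
            self.seg_mlp.partial_fit(dummy, _SEG_CLASSES, classes=_SEG_CLASSES)
            n_blink = len(self._blink_x(np.zeros(cfg.input_size)))
            bdummy = np.zeros((3, n_blink))
            self.blink_mlp.partial_fit(bdummy, np.arange(3), classes=np.arange(3))

    # -- introspection ----------------------------------------------------
    @property
    def n_parameters(self) -> int:
        """Trainable parameter count over both heads."""
        n = 0
        for mlp in (self.seg_mlp, self.blink_mlp):
            n += sum(w.size for w in mlp.coefs_) + sum(b.size for b in mlp.intercepts_)
        return n

    # -- inference --------------------------------------------------------
    def _check_input(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image)
        if image.shape != self.cfg.input_size:
            raise ValueError(
                f"input size {image.shape} != configured {self.cfg.input_size}; "
                "resize upstream"
            )
        return image

    def predict_masks(self, image: np.ndarray) -> SegmentationOutput:
        """Segment one grayscale frame into the 4 exclusive classes."""
        image = self._check_input(image)
        h, w = image.shape
        x = self.seg_scaler(F.pixel_features(image))
        prob = self.seg_mlp.predict_proba(x).reshape(h, w, self.cfg.n_classes)
        return SegmentationOutput(prob=prob, label_map=prob.argmax(axis=2).astype(np.uint8))

    def predict_masks_batch(self, images: Sequence[np.ndarray]) -> list[SegmentationOutput]:
        return [self.predict_masks(im) for im in images]

    def _blink_x(self, image: np.ndarray) -> np.ndarray:
        if self.cfg.blink_head == "attached":
            return F.blink_features(image)
        # Detached ablation head: pool the raw image, no encoder smoothing.
        img = np.asarray(image, dtype=float)
        p = F.BLINK_POOL
        ye = np.linspace(0, img.shape[0], p + 1).astype(int)
        xe = np.linspace(0, img.shape[1], p + 1).astype(int)
        pooled = np.add.reduceat(np.add.reduceat(img, ye[:-1], 0), xe[:-1], 1)
        return (pooled / np.outer(np.diff(ye), np.diff(xe))).ravel() / 255.0

    def predict_blink(self, image: np.ndarray) -> BlinkPrediction:
        """Classify the blink state of one grayscale frame."""
        image = self._check_input(image)
        x = self.blink_scaler(self._blink_x(image)[None, :])
        probs = self.blink_mlp.predict_proba(x)[0]
        return BlinkPrediction(probs=probs, label=BLINK_STATES[int(probs.argmax())])


def build_model(cfg: ModelConfig = ModelConfig()) -> SegBlinkModel:
    """Build a model with deterministic initialization under ``cfg.seed``."""
    return SegBlinkModel(cfg)


# ---------------------------------------------------------------------------
# Training


def _sample_pixels(
    frames: Sequence[AnnotatedFrame], per_class: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Class-balanced pixel sample (features, labels) across frames."""
    xs, ys = [], []
    for fr in frames:
        feats = F.pixel_features(fr.image)
        labels = fr.label_mask.ravel()
        for c in _SEG_CLASSES:
            idx = np.nonzero(labels == c)[0]
            if len(idx) == 0:
                continue
            take = rng.choice(idx, size=min(per_class, len(idx)), replace=False)
            xs.append(feats[take])
            ys.append(labels[take])
    return np.concatenate(xs), np.concatenate(ys)


def train_segmentation(
    model: SegBlinkModel,
    split,
    epochs: Optional[int] = None,
) -> tuple[SegBlinkModel, pd.DataFrame]:
    """Train the segmentation head on an annotated split.

    Logs per-epoch train/val loss and val mIoU; the weights of the best
    validation epoch are retained.  Fixed config seed => reproducible
    history.  ``split`` is a ``DatasetSplit`` of ``AnnotatedFrame``s.
    """
    from .metrics import compute_miou  # local import avoids a cycle

    cfg = model.cfg
    epochs = cfg.epochs if epochs is None else epochs
    train, val = list(split.train), list(split.val)
    if not train:
        raise ValueError("empty training set")
    for i, fr in enumerate(train):
        if getattr(fr, "label_mask", None) is None:
            raise ValueError(f"training frame {i} has no segmentation mask")

    rng = np.random.default_rng(cfg.seed)
    x_train, y_train = _sample_pixels(train, cfg.pixels_per_class, rng)
    model.seg_scaler.fit(x_train)
    x_train = model.seg_scaler(x_train)
    if val:
        x_val, y_val = _sample_pixels(val, cfg.pixels_per_class, rng)
        x_val = model.seg_scaler(x_val)
        miou_frames = val[: cfg.val_frames]
    else:
        x_val = y_val = None
        miou_frames = train[: cfg.val_frames]

    history = []
    best = (np.inf, None)
    for epoch in range(epochs):
        order = rng.permutation(len(x_train))
        model.seg_mlp.partial_fit(x_train[order], y_train[order], classes=_SEG_CLASSES)
        train_loss = float(model.seg_mlp.loss_)
        if x_val is not None:
            val_loss = float(
                log_loss(y_val, model.seg_mlp.predict_proba(x_val), labels=_SEG_CLASSES)
            )
        else:
            val_loss = train_loss
        ious = [
            compute_miou(fr.label_mask, model.predict_masks(fr.image).label_map)[1]
            for fr in miou_frames
        ]
        val_miou = float(np.mean(ious)) if ious else float("nan")
        history.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss, "val_miou": val_miou}
        )
        if val_loss < best[0]:
            best = (
                val_loss,
                (
                    copy.deepcopy(model.seg_mlp.coefs_),
                    copy.deepcopy(model.seg_mlp.intercepts_),
                ),
            )
    if best[1] is not None:
        model.seg_mlp.coefs_, model.seg_mlp.intercepts_ = best[1]
    return model, pd.DataFrame(history)


def train_blink(
    model: SegBlinkModel,
    frames: Sequence[AnnotatedFrame],
    epochs: Optional[int] = None,
    val_frames: Sequence[AnnotatedFrame] = (),
) -> tuple[SegBlinkModel, pd.DataFrame]:
    """Train the blink head on frames carrying blink labels.

    All three blink states must be present in the training frames.
    """
    cfg = model.cfg
    epochs = cfg.blink_epochs if epochs is None else epochs
    counts = {s: sum(1 for fr in frames if fr.blink == s) for s in BLINK_STATES}
    missing = [s for s, c in counts.items() if c == 0]
    if missing:
        raise ValueError(f"blink classes missing from training set: {missing}; counts={counts}")

    x = np.stack([model._blink_x(fr.image) for fr in frames])
    y = np.array([_BLINK_IDX[fr.blink] for fr in frames])
    model.blink_scaler.fit(x)
    x = model.blink_scaler(x)
    if len(val_frames):
        xv = model.blink_scaler(np.stack([model._blink_x(fr.image) for fr in val_frames]))
        yv = np.array([_BLINK_IDX[fr.blink] for fr in val_frames])
    else:
        xv = yv = None

    rng = np.random.default_rng(cfg.seed + 17)
    history = []
    for epoch in range(epochs):
        order = rng.permutation(len(x))
        model.blink_mlp.partial_fit(x[order], y[order], classes=np.arange(3))
        row = {
            "epoch": epoch,
            "train_loss": float(model.blink_mlp.loss_),
            "train_acc": float((model.blink_mlp.predict(x) == y).mean()),
        }
        if xv is not None:
            row["val_acc"] = float((model.blink_mlp.predict(xv) == yv).mean())
        history.append(row)
    return model, pd.DataFrame(history)


def export_portable(model: SegBlinkModel, path) -> None:
    """Export both heads + encoder config as a portable weight bundle.

    The bundle is a plain ``.npz`` of arrays and JSON metadata, loadable
    by the numpy-only runtime in :mod:`oculotrace.runtime`; portable
    predictions agree with the native model to < 1e-4.
    """
    from .runtime import save_portable

    save_portable(model, path)
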