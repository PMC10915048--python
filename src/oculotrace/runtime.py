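"""Portable inference runtime: numpy-only forward pass over exported weights.

The exported bundle (``.npz``) holds the MLP weights of both heads, the
feature standardization constants, and the encoder configuration; this
module re-implements inference with plain numpy so a deployment needs
neither the training stack nor scikit-learn.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import features as F
from .synth import BLINK_STATES


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _mlp_forward(x: np.ndarray, weights: list[np.ndarray], biases: list[np.ndarray]) -> np.ndarray:
    for w, b in zip(weights[:-1], biases[:-1]):
        x = np.maximum(x @ w + b, 0.0)  # relu hidden layers
    return _softmax(x @ weights[-1] + biases[-1])


def save_portable(model, path: str | Path) -> Path:
    """Serialize a trained :class:`~oculotrace.model.SegBlinkModel`."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for head, mlp, scaler in (
        ("seg", model.seg_mlp, model.seg_scaler),
        ("blink", model.blink_mlp, model.blink_scaler),
    ):
        for i, (w, b) in enumerate(zip(mlp.coefs_, mlp.intercepts_)):
            arrays[f"{head}_w{i}"] = w
            arrays[f"{head}_b{i}"] = b
        arrays[f"{head}_n_layers"] = np.array(len(mlp.coefs_))
        if scaler.mean is not None:
            arrays[f"{head}_mean"] = scaler.mean
            arrays[f"{head}_scale"] = scaler.scale
    meta = {
        "format": "oculotrace-portable-v1",
        "input_size": list(model.cfg.input_size),
        "n_classes": model.cfg.n_classes,
        "blink_head": model.cfg.blink_head,
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path


class PortableModel:
    """Exported model reloaded for numpy-only inference."""

    def __init__(self, arrays: dict, meta: dict):
        self.meta = meta
        self.input_size = tuple(meta["input_size"])
        self.n_classes = int(meta["n_classes"])
        self.blink_head = meta["blink_head"]
        self._heads = {}
        for head in ("seg", "blink"):
            n = int(arrays[f"{head}_n_layers"])
            ws = [arrays[f"{head}_w{i}"] for i in range(n)]
            bs = [arrays[f"{head}_b{i}"] for i in range(n)]
            mean = arrays.get(f"{head}_mean")
            scale = arrays.get(f"{head}_scale")
            self._heads[head] = (ws, bs, mean, scale)

    @classmethod
    def load(cls, path: str | Path) -> "PortableModel":
        path = Path(path)
        if not path.exists():
            raise IOError(f"portable model not found: {path}")
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
        meta = json.loads(bytes(arrays.pop("meta_json")).decode())
        if meta.get("format") != "oculotrace-portable-v1":
            raise ValueError(f"unrecognized portable bundle format: {meta.get('format')}")
        return cls(arrays, meta)

    def _apply(self, head: str, x: np.ndarray) -> np.ndarray:
        ws, bs, mean, scale = self._heads[head]
        if mean is not None:
            x = (x - mean) / scale
        return _mlp_forward(x, ws, bs)

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Segmentation probabilities, shape (H, W, n_classes)."""
        image = np.asarray(image)
        if image.shape != self.input_size:
            raise ValueError(f"input size {image.shape} != {self.input_size}")
        h, w = image.shape
        return self._apply("seg", F.pixel_features(image)).reshape(h, w, self.n_classes)

    def predict_label_map(self, image: np.ndarray) -> np.ndarray:
        return self.predict_proba(image).argmax(axis=2).astype(np.uint8)

    def predict_blink_proba(self, image: np.ndarray) -> np.ndarray:
        """Blink-state probabilities over (open, closing, closed)."""
        image = np.asarray(image)
        if image.shape != self.input_size:
            raise ValueError(f"input size {image.shape} != {self.input_size}")
        if self.blink_head == "attached":
            x = F.blink_features(image)
        else:
            img = image.astype(float)
            p = F.BLINK_POOL
            ye = np.linspace(0, img.shape[0], p + 1).astype(int)
            xe = np.linspace(0, img.shape[1], p + 1).astype(int)
            pooled = np.add.reduceat(np.add.reduceat(img, ye[:-1], 0), xe[:-1], 1)
            x = (pooled / np.outer(np.diff(ye), np.diff(xe))).ravel() / 255.0
        return self._apply("blink", x[None, :])[0]

    def predict_blink_label(self, image: np.ndarray) -> str:
        return BLINK_STATES[int(self.predict_blink_proba(image).argmax())]
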