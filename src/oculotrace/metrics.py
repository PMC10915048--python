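"""Evaluation metrics: IoU/mIoU, center MAE/RMSE, blink F1/AUC/ACC,
trace Pearson correlation, and an FPS micro-benchmark.

All metric functions are pure and operate on arrays, so each can be
checked against brute-force arithmetic on small fixtures.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score

from .synth import CLASS_NAMES


@dataclass
class EvalReport:
    """Aggregated evaluation results for one model/dataset pairing."""

    iou: dict = field(default_factory=dict)  # class name -> IoU, plus "mean"
    mae: Optional[float] = None
    rmse: Optional[float] = None
    blink: dict = field(default_factory=dict)  # per-class f1/auc + "acc"
    pearson_r: dict = field(default_factory=dict)  # axis -> r
    n: dict = field(default_factory=dict)  # metric -> sample count
    flags: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        lines = []
        if self.iou:
            lines.append("IoU: " + ", ".join(f"{k}={v:.4f}" for k, v in self.iou.items()))
        if self.mae is not None:
            lines.append(f"center MAE={self.mae:.4f} px, RMSE={self.rmse:.4f} px")
        if self.blink:
            lines.append("blink: " + json.dumps(self.blink))
        if self.pearson_r:
            lines.append(
                "trace r: " + ", ".join(f"{k}={v:.4f}" for k, v in self.pearson_r.items())
            )
        return "\n".join(lines)


def compute_iou(gt_mask: np.ndarray, pred_mask: np.ndarray) -> float:
    """Intersection-over-union of two binary masks.

    Both-empty masks score 1 (perfect agreement on absence).
    """
    gt = np.asarray(gt_mask).astype(bool)
    pred = np.asarray(pred_mask).astype(bool)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    union = np.logical_or(gt, pred).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(gt, pred).sum() / union)


def compute_miou(
    gt_labels: np.ndarray,
    pred_labels: np.ndarray,
    classes: Sequence[int] = (1, 2, 3),
) -> tuple[dict, float]:
    """Per-class binary IoU on exclusive label maps, plus the unweighted
    mean over ``classes`` (background excluded by default).

    A class absent from both maps scores 1 and is flagged with an
    ``"(absent)"`` suffix in the returned dict key.
    """
    gt = np.asarray(gt_labels)
    pred = np.asarray(pred_labels)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    per_class: dict[str, float] = {}
    values = []
    for c in classes:
        name = CLASS_NAMES[c] if c < len(CLASS_NAMES) else str(c)
        gt_c, pred_c = gt == c, pred == c
        value = compute_iou(gt_c, pred_c)
        if not gt_c.any() and not pred_c.any():
            name = f"{name} (absent)"
        per_class[name] = value
        values.append(value)
    return per_class, float(np.mean(values))


def compute_center_errors(
    true_centers: np.ndarray, pred_centers: np.ndarray
) -> tuple[float, float]:
    """(MAE, RMSE) over per-pair Euclidean center distances."""
    t = np.atleast_2d(np.asarray(true_centers, dtype=float))
    p = np.atleast_2d(np.asarray(pred_centers, dtype=float))
    if t.shape != p.shape:
        raise ValueError(f"length/shape mismatch: {t.shape} vs {p.shape}")
    if len(t) < 1:
        raise ValueError("need at least one center pair")
    d = np.linalg.norm(t - p, axis=1)
    return float(d.mean()), float(np.sqrt((d**2).mean()))


def blink_scores(
    true_labels: Sequence[str], pred_probs: np.ndarray, classes: Sequence[str] = ("open", "closing", "closed")
) -> dict:
    """Per-class F1 and one-vs-rest AUC, plus overall accuracy.

    ``pred_probs`` columns follow ``classes``.  F1 uses the argmax
    label; AUC uses the class probability.  A truth containing a single
    class has no defined AUC and raises.
    """
    true_labels = list(true_labels)
    probs = np.asarray(pred_probs, dtype=float)
    if probs.ndim != 2 or probs.shape != (len(true_labels), len(classes)):
        raise ValueError(
            f"pred_probs shape {probs.shape} incompatible with "
            f"{len(true_labels)} labels x {len(classes)} classes"
        )
    present = sorted(set(true_labels))
    if len(present) < 2:
        raise ValueError(
            f"AUC undefined: truth contains a single class {present}"
        )
    pred_labels = [classes[i] for i in probs.argmax(axis=1)]
    out: dict[str, dict | float] = {}
    y_true = np.asarray(true_labels)
    for j, c in enumerate(classes):
        f1 = f1_score(y_true == c, np.asarray(pred_labels) == c, zero_division=0)
        if c in present:
            auc = roc_auc_score((y_true == c).astype(int), probs[:, j])
        else:
            auc = float("nan")
        out[c] = {"f1": float(f1), "auc": float(auc)}
    out["acc"] = float(accuracy_score(y_true, pred_labels))
    out["macro_f1"] = float(
        np.mean([out[c]["f1"] for c in classes if c in present])
    )
    return out


def trace_correlation(
    true_xy: np.ndarray, pred_xy: np.ndarray
) -> dict[str, tuple[float, float]]:
    """Pearson r (and p-value) per axis between two (n, 2) center series.

    Constant series make the correlation undefined and raise rather
    than returning NaN.
    """
    t = np.asarray(true_xy, dtype=float)
    p = np.asarray(pred_xy, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    if len(t) < 3:
        raise ValueError(f"need >= 3 samples, got {len(t)}")
    out = {}
    for axis, name in enumerate(("x", "y")):
        if np.ptp(t[:, axis]) == 0 or np.ptp(p[:, axis]) == 0:
            raise ValueError(f"constant {name}-series: Pearson r undefined")
        r, pval = stats.pearsonr(t[:, axis], p[:, axis])
        out[name] = (float(r), float(pval))
    return out


def fps_benchmark(
    portable_model_path,
    iterations: int = 3000,
    batch: int = 1,
    warmup: int = 20,
    seed: int = 0,
) -> dict:
    """Wall-clock inference throughput of an exported portable model.

    Runs ``warmup`` discarded passes, then times ``iterations`` passes
    of batch size ``batch`` on random inputs.  Reports overall fps plus
    per-iteration min/median latency and a hardware string.  Utility
    only -- numbers depend on the host.
    """
    import platform

    from .runtime import PortableModel

    model = PortableModel.load(portable_model_path)
    h, w = model.input_size
    rng = np.random.default_rng(seed)
    images = rng.integers(0, 256, size=(batch, h, w)).astype(np.uint8)
    for _ in range(warmup):
        model.predict_proba(images[0])
    times = np.empty(iterations)
    t_all = time.perf_counter()
    for i in range(iterations):
        t0 = time.perf_counter()
        for b in range(batch):
            model.predict_proba(images[b])
        times[i] = time.perf_counter() - t0
    total = time.perf_counter() - t_all
    return {
        "fps": iterations * batch / total,
        "iterations": iterations,
        "batch": batch,
        "latency_min_s": float(times.min()),
        "latency_median_s": float(np.median(times)),
        "hardware": f"{platform.machine()} / {platform.processor() or 'cpu'}",
    }
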