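"""End-to-end demo workflow: synthesize, train, trace, evaluate.

Canonical desk-scale study conditions live here so the CLI demo, the
test suite and downstream scripts exercise one and the same experiment:
a 2,000-frame training corpus and a 20 s, 25 fps jerk-nystagmus
sequence with two scheduled blinks.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from .datasetio import split_dataset, SplitSpec
from .metrics import (
    EvalReport,
    blink_scores,
    compute_center_errors,
    compute_miou,
    trace_correlation,
)
from .model import ModelConfig, build_model, train_blink, train_segmentation
from .synth import EyeSceneParams, NystagmusWaveform, generate_dataset, generate_sequence
from .tracking import build_trace, export_trace, plot_trace, pupil_center_from_frame

# Canonical demo conditions: a brisk horizontal-dominant jerk nystagmus
# (slow-phase velocity 20 deg/s right, 18 deg/s up, 1.5 beats/s) around
# a slightly eccentric baseline, recorded 20 s at 25 fps with two blinks.
DEMO_WAVEFORM = NystagmusWaveform(
    baseline=(-5.0, 4.0),
    slow_phase_velocity=(20.0, -18.0),
    beat_frequency=1.5,
    duration=20.0,
    fps=25.0,
)
DEMO_BLINK_SCHEDULE = ((100, 112), (300, 312))
DEMO_TRAIN_FRAMES = 2000


def train_demo_model(
    n_frames: int = DEMO_TRAIN_FRAMES,
    seed: int = 0,
    epochs: int = 6,
    cfg: Optional[ModelConfig] = None,
):
    """Generate a corpus, split it 80/10/10, train both heads.

    Returns (model, split, histories dict).
    """
    frames = generate_dataset(n_frames, seed=seed)
    split = split_dataset(frames, SplitSpec())
    cfg = cfg or ModelConfig(seed=seed, epochs=epochs)
    model = build_model(cfg)
    model, seg_hist = train_segmentation(model, split)
    model, blink_hist = train_blink(model, split.train, val_frames=split.val)
    return model, split, {"segmentation": seg_hist, "blink": blink_hist}


def evaluate_on_split(model, split) -> EvalReport:
    """Held-out evaluation: mIoU, center MAE/RMSE, blink scores."""
    report = EvalReport()
    ious, true_c, pred_c = [], [], []
    for fr in split.test:
        out = model.predict_masks(fr.image)
        per_class, miou = compute_miou(fr.label_mask, out.label_map)
        ious.append([per_class, miou])
        if fr.pupil_center is not None:
            center, _ = pupil_center_from_frame(out.label_map)
            if center is not None:
                true_c.append(fr.pupil_center)
                pred_c.append(center)
    keys = ["sclera", "iris", "pupil"]
    for k in keys:
        vals = [d.get(k, d.get(f"{k} (absent)")) for d, _ in ious]
        report.iou[k] = float(np.mean(vals))
    report.iou["mean"] = float(np.mean([m for _, m in ious]))
    report.n["iou"] = len(ious)
    report.mae, report.rmse = compute_center_errors(np.array(true_c), np.array(pred_c))
    report.n["center"] = len(true_c)
    probs = np.stack([model.predict_blink(fr.image).probs for fr in split.test])
    report.blink = blink_scores([fr.blink for fr in split.test], probs)
    report.n["blink"] = len(split.test)
    return report


def trace_experiment(
    model=None,
    seed: int = 0,
    waveform: NystagmusWaveform = DEMO_WAVEFORM,
    blink_schedule=DEMO_BLINK_SCHEDULE,
    oracle_masks: bool = False,
    scene: Optional[EyeSceneParams] = None,
) -> dict:
    """Render a nystagmus sequence and correlate the extracted trace
    against the analytic ground-truth centers.

    Returns {"trace": NystagmusTrace, "truth": (n, 2) array,
    "pearson": {axis: (r, p)}}.
    """
    scene = scene or EyeSceneParams(noise_sd=4.0, seed=seed + 1000)
    seq = generate_sequence(waveform, scene, blink_schedule=blink_schedule)
    truth = np.array([scene.gaze_to_pixel(fr.gaze) for fr in seq])
    trace = build_trace(
        seq, model=model, oracle_masks=oracle_masks, fps=waveform.fps
    )
    return {
        "trace": trace,
        "truth": truth,
        "pearson": trace_correlation(truth, trace.xy),
    }


def demo_end_to_end(workdir: str | Path, seed: int = 0, n_frames: int = DEMO_TRAIN_FRAMES) -> dict:
    """Full workflow: corpus -> training -> fresh-sequence trace -> report.

    Writes the trace CSV, the trace plot, and a JSON summary into
    ``workdir`` and returns the summary dict.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    try:
        model, split, histories = train_demo_model(n_frames=n_frames, seed=seed)
    except Exception as exc:
        raise RuntimeError(f"demo failed in stage 'train': {exc}") from exc
    try:
        report = evaluate_on_split(model, split)
    except Exception as exc:
        raise RuntimeError(f"demo failed in stage 'evaluate': {exc}") from exc
    try:
        oracle = trace_experiment(seed=seed, oracle_masks=True)
        modeled = trace_experiment(model=model, seed=seed)
        export_trace(modeled["trace"], workdir / "trace.csv")
        plot_trace(modeled["trace"], workdir / "trace.png")
    except Exception as exc:
        raise RuntimeError(f"demo failed in stage 'trace': {exc}") from exc

    report.pearson_r = {
        f"oracle_{ax}": r for ax, (r, _) in oracle["pearson"].items()
    }
    report.pearson_r.update({f"model_{ax}": r for ax, (r, _) in modeled["pearson"].items()})
    report.n["trace"] = len(modeled["trace"])
    summary = json.loads(report.to_json())
    summary["seed"] = seed
    summary["n_train_frames"] = n_frames
    (workdir / "report.json").write_text(json.dumps(summary, indent=2))
    return summary
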