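# oculotrace

Video-oculography (VOG) toolkit for extracting horizontal and vertical
nystagmus traces from single-eye video, built around three cooperating
parts:

1. **Ocular segmentation + blink classification** — a lightweight
   two-headed model on a shared multi-scale encoder labels every pixel
   of a 100×100 grayscale eye frame as background, sclera, iris or
   pupil, and classifies the frame's blink state as *open* (iris fully
   visible), *closing* (iris partially covered by an eyelid) or
   *closed* (iris invisible).
2. **Pupil-center tracking** — the segmented pupil region (iris as
   fallback) is reduced to a sub-pixel center by a direct least-squares
   ellipse fit on its outer boundary; eyelid-clipped boundary pixels are
   excluded from the fit.  Closed-eye frames are gated out and filled by
   linear interpolation, yielding a gap-free (x, y)-vs-time trace.
3. **Synthetic ground truth** — a procedural eye renderer (parabolic
   eyelid arcs, iris disk, concentric pupil, additive noise, optional
   illumination gradient and specular highlight) produces frames with
   exact per-pixel class masks, analytic pupil centers and blink
   labels, plus a sawtooth jerk-nystagmus waveform simulator to drive
   whole sequences.  Every stage of the pipeline is therefore testable
   against known ground truth, with no clinical data required.

Involuntary rhythmic eye movements (nystagmus) carry diagnostic
information in acute vertigo — their axis and direction help separate
central from peripheral causes at the bedside.  This package targets
researchers and engineers who need a desk-scale, fully reproducible
version of that measurement chain: segment, classify blinks, fit, gate,
interpolate, plot, evaluate.

## Core quantities

- Segmentation quality: per-class intersection-over-union
  IoU = |GT ∩ P| / |GT ∪ P| and its unweighted mean (mIoU) over
  {sclera, iris, pupil}.
- Tracking quality: MAE = (1/n) Σ‖ĉᵢ − cᵢ‖ and
  RMSE = √((1/n) Σ‖ĉᵢ − cᵢ‖²) over Euclidean center distances (pixels).
- Blink quality: per-class F1 and one-vs-rest AUC, overall accuracy.
- Trace fidelity: Pearson r per axis between extracted and true
  pupil-center time series.

## Worked example

```python
from oculotrace.pipeline import (
    train_demo_model, evaluate_on_split, trace_experiment,
)

# 2,000 rendered frames, 80/10/10 split, both heads trained (CPU, ~20 s)
model, split, hist = train_demo_model(seed=1)
report = evaluate_on_split(model, split)
print(report.summary())

# 20 s, 25 fps jerk-nystagmus sequence with two blinks
oracle = trace_experiment(seed=1, oracle_masks=True)
modeled = trace_experiment(model=model, seed=1)
print({ax: round(r, 4) for ax, (r, _) in oracle["pearson"].items()})
print({ax: round(r, 4) for ax, (r, _) in modeled["pearson"].items()})
```

prints (seed 1):

```
IoU: sclera=0.9994, iris=0.9830, pupil=0.9866, mean=0.9896
center MAE=0.2651 px, RMSE=0.4485 px
blink: {... "acc": 0.945, "macro_f1": 0.9362}
{'x': 0.9996, 'y': 0.999}
{'x': 0.9992, 'y': 0.9979}
```

Reading: on held-out synthetic frames the trained model segments all
three ocular classes at IoU ≈ 0.99 and locates the pupil center to
about a quarter pixel; the model-free (ground-truth-mask) trace of the
nystagmus sequence correlates with the analytic gaze trajectory at
r ≥ 0.999 per axis — the residual is rasterization — and the trained
model's trace stays above r = 0.997 through two interpolated blinks.

The same workflow is available from the shell:

```bash
oculotrace demo --workdir out/ --seed 1          # end-to-end, writes report.json
oculotrace synth --n 500 --seed 1 --out corpus/  # annotated corpus (PNG+CSV)
oculotrace trace --input corpus/ --oracle-masks --out traces/
```

Every run writes a `run_manifest.json` (effective config + seed +
versions) beside its outputs; the manifest reproduces the run exactly.

## Layout

- `oculotrace.synth` — renderer, waveform simulator, dataset generator
- `oculotrace.datasetio` — frame extraction, SSIM dedup (threshold 0.8),
  resizing to 100×100, 80/10/10 splitting, corpus round-trip
- `oculotrace.features` / `oculotrace.model` — shared encoder and the
  two trainable heads
- `oculotrace.runtime` — numpy-only inference over exported weight bundles
- `oculotrace.tracking` — ellipse fit, center extraction, interpolation,
  trace export/plot
- `oculotrace.metrics` — IoU/mIoU, MAE/RMSE, blink scores, Pearson r,
  FPS micro-benchmark
- `oculotrace.cli` / `oculotrace.pipeline` — subcommands and the
  end-to-end demo

See `docs/methods.md` for the model, the geometry, parameter defaults
and known limitations.
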