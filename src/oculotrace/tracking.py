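"""Pupil-center time series extraction.

Per frame: take the segmented pupil region (iris as fallback), fit an
ellipse to its outer boundary, use the ellipse center as the pupil
position; gate out closed-eye frames; linearly interpolate the gaps;
emit a finalized (x, y)-vs-time nystagmus trace with CSV export and a
two-panel plot.

All coordinates are raw image pixels (x rightward, y downward); no
degree calibration is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import EllipseModel

from .synth import (
    AnnotatedFrame,
    BLINK_CLOSED,
    CLASS_IRIS,
    CLASS_PUPIL,
)

DEFAULT_MIN_AREA = 20  # pixels, at 100x100 resolution


@dataclass(frozen=True)
class EllipseParams:
    """Fitted ellipse: center (pixels), semi-axes a >= b, rotation
    theta in [0, pi)."""

    center: tuple[float, float]
    axes: tuple[float, float]
    theta: float


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """Outer boundary pixels of a binary region, as (x, y) coordinates."""
    eroded = ndimage.binary_erosion(mask, border_value=0)
    ys, xs = np.nonzero(mask & ~eroded)
    return np.column_stack([xs, ys]).astype(float)


def _moment_ellipse(mask: np.ndarray) -> EllipseParams:
    """Centroid + second-moment axes fallback for degenerate fits."""
    ys, xs = np.nonzero(mask)
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    cov = np.cov(np.vstack([dx, dy])) if len(xs) > 1 else np.zeros((2, 2))
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    # Solid-ellipse relation: semi-axis = 2 * sqrt(eigenvalue).
    b, a = 2.0 * np.sqrt(np.maximum(evals, 0.0))
    vx, vy = evecs[:, 1]
    theta = math.atan2(vy, vx) % math.pi
    return EllipseParams(
        center=(float(cx), float(cy)),
        axes=(float(max(a, 0.5)), float(max(b, 0.5))),
        theta=float(theta),
    )


def fit_ellipse(mask: np.ndarray) -> EllipseParams:
    """Fit an ellipse to a binary region's outer boundary.

    Uses a direct least-squares conic fit on the boundary pixels; falls
    back to the image-moment centroid (axes from second moments) when
    the boundary has fewer than 6 points or the fit degenerates.  The
    returned center is always finite.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot fit an ellipse to an empty mask")
    pts = _boundary_points(mask)
    if len(pts) < 6:
        return _moment_ellipse(mask)
    model = EllipseModel.from_estimate(pts)
    if not model:
        return _moment_ellipse(mask)
    (cx, cy), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not all(np.isfinite([cx, cy, a, b, theta])):
        return _moment_ellipse(mask)
    if a <= 0 or b <= 0:
        return _moment_ellipse(mask)
    # Reject fits that run away from the region (near-degenerate conics).
    ys, xs = np.nonzero(mask)
    if not (xs.min() - 2 <= cx <= xs.max() + 2 and ys.min() - 2 <= cy <= ys.max() + 2):
        return _moment_ellipse(mask)
    if a < b:
        a, b = b, a
        theta += math.pi / 2
    return EllipseParams(
        center=(float(cx), float(cy)),
        axes=(float(a), float(b)),
        theta=float(theta % math.pi),
    )


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labeled, n = ndimage.label(mask)
    if n <= 1:
        return mask.astype(bool)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    return labeled == (1 + int(np.argmax(sizes)))


def _kasa_circle(xs: np.ndarray, ys: np.ndarray) -> tuple[float, float, float]:
    """Algebraic least-squares circle fit (Kasa): center and radius."""
    a = np.column_stack([xs, ys, np.ones_like(xs)])
    b = xs**2 + ys**2
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    return float(cx), float(cy), float(np.sqrt(max(r2, 0.0)))


def _occlusion_aware_center(
    region: np.ndarray,
    background: np.ndarray,
    min_free_points: int = 10,
    min_free_fraction: float = 0.25,
) -> Optional[tuple[float, float]]:
    """Region center from the unoccluded part of its boundary.

    Boundary pixels touching the background class sit on an eyelid clip
    edge, not on the true region outline, and are excluded.  An
    unclipped region gets the full direct ellipse fit; a clipped one
    gets a least-squares circle fit on the free arc, which stays stable
    on partial arcs where an unconstrained conic fit drifts.  Returns
    ``None`` when the free arc is too short to constrain the fit or the
    fitted radius is inconsistent with the region's extent -- such a
    measurement would be dominated by occlusion bias.
    """
    h, w = region.shape
    eroded = ndimage.binary_erosion(region, border_value=0)
    boundary = region & ~eroded
    occluded = ndimage.binary_dilation(background, structure=np.ones((3, 3)))
    free = boundary & ~occluded
    n_free, n_total = int(free.sum()), int(boundary.sum())
    if n_free == n_total:
        # No clipping: plain outer-boundary fit.
        return fit_ellipse(region).center
    if n_free < min_free_points or n_free < min_free_fraction * n_total:
        return None
    ys, xs = np.nonzero(free)
    cx, cy, r = _kasa_circle(xs.astype(float), ys.astype(float))
    if not all(np.isfinite([cx, cy, r])):
        return None
    if not (0 <= cx < w and 0 <= cy < h) or r > max(h, w) / 2:
        return None
    # Under-constrained slivers betray themselves two ways: the fitted
    # radius falls below the region's visible half-width, and the free
    # points subtend too little arc around the fitted center.
    rys, rxs = np.nonzero(region)
    x_extent = rxs.max() - rxs.min() + 1
    if r < 0.45 * x_extent:
        return None
    bin_width = math.pi / 15  # 12-degree angular bins
    angles = np.arctan2(ys - cy, xs - cx)
    covered = np.unique(((angles + math.pi) // bin_width).astype(int)).size
    if covered * 12 < 96:
        return None
    return (cx, cy)


def pupil_center_from_frame(
    label_map: np.ndarray, min_area: int = DEFAULT_MIN_AREA
) -> tuple[Optional[tuple[float, float]], str]:
    """Extract the pupil center from a segmentation label map.

    Prefers the pupil-class region when its area reaches ``min_area``;
    falls back to the iris region (annulus + pupil footprint) otherwise;
    returns ``(None, "none")`` when neither yields a usable fit.  Only
    the largest connected component is fitted, and eyelid-clipped
    boundary pixels are excluded from the fit (a region whose free
    boundary arc is too short gives an absent center rather than a
    heavily biased one).  Absence is a value, not an error.
    """
    label_map = np.asarray(label_map)
    background = label_map == 0
    pupil = label_map == CLASS_PUPIL
    if pupil.sum() >= min_area:
        center = _occlusion_aware_center(_largest_component(pupil), background)
        if center is not None:
            return center, "pupil"
    iris = (label_map == CLASS_IRIS) | pupil
    if iris.sum() >= min_area:
        center = _occlusion_aware_center(_largest_component(iris), background)
        if center is not None:
            return center, "iris"
    return None, "none"


@dataclass
class TracePoint:
    """One frame of the pupil-center trace."""

    frame_index: int
    time: float
    center: Optional[tuple[float, float]]
    blink: str
    provenance: str  # "measured" | "interpolated"
    source: str = "none"  # "pupil" | "iris" | "none"


@dataclass
class NystagmusTrace:
    """Finalized per-frame pupil-center time series."""

    points: list[TracePoint]
    fps: float
    axis_note: str = "image pixels; x rightward, y downward"

    def __len__(self) -> int:
        return len(self.points)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of centers; finalized traces have no NaNs."""
        return np.array(
            [p.center if p.center is not None else (np.nan, np.nan) for p in self.points]
        )

    def to_dataframe(self) -> pd.DataFrame:
        xy = self.xy
        return pd.DataFrame(
            {
                "frame": [p.frame_index for p in self.points],
                "time": [p.time for p in self.points],
                "x": xy[:, 0],
                "y": xy[:, 1],
                "blink": [p.blink for p in self.points],
                "provenance": [p.provenance for p in self.points],
            }
        )


def interpolate_closed(points: Sequence[TracePoint]) -> list[TracePoint]:
    """Fill absent centers by per-coordinate linear interpolation.

    Interior gaps are interpolated between the nearest flanking measured
    points; leading/trailing gaps hold the nearest measured value.
    Filled points are flagged ``interpolated``.
    """
    measured_idx = [i for i, p in enumerate(points) if p.center is not None]
    if not measured_idx:
        raise ValueError("no valid frames: every point has an absent center")
    mi = np.array(measured_idx, dtype=float)
    mx = np.array([points[i].center[0] for i in measured_idx])
    my = np.array([points[i].center[1] for i in measured_idx])
    out = []
    for i, p in enumerate(points):
        if p.center is not None:
            out.append(
                TracePoint(p.frame_index, p.time, p.center, p.blink, "measured", p.source)
            )
        else:
            cx = float(np.interp(i, mi, mx))
            cy = float(np.interp(i, mi, my))
            out.append(
                TracePoint(p.frame_index, p.time, (cx, cy), p.blink, "interpolated", p.source)
            )
    return out


def build_trace(
    frames: Sequence[Union[AnnotatedFrame, np.ndarray]],
    model=None,
    oracle_masks: bool = False,
    fps: float = 25.0,
    min_area: int = DEFAULT_MIN_AREA,
) -> NystagmusTrace:
    """Run the full per-frame pipeline and return a finalized trace.

    For each frame: segment (or pass the ground-truth mask through when
    ``oracle_masks``), classify the blink state, extract the pupil
    center unless the eye is closed, then interpolate the gaps.

    ``frames`` may be :class:`AnnotatedFrame` objects (required for
    ``oracle_masks``) or raw grayscale images (model required).
    """
    if len(frames) == 0:
        raise ValueError("empty frame sequence")
    if not oracle_masks and model is None:
        raise ValueError("need a trained model unless oracle_masks=True")

    raw: list[TracePoint] = []
    for i, fr in enumerate(frames):
        try:
            if oracle_masks:
                if not isinstance(fr, AnnotatedFrame):
                    raise ValueError("oracle_masks requires AnnotatedFrame inputs")
                label_map, blink = fr.label_mask, fr.blink
            else:
                image = fr.image if isinstance(fr, AnnotatedFrame) else np.asarray(fr)
                label_map = model.predict_masks(image).label_map
                blink = model.predict_blink(image).label
            if blink == BLINK_CLOSED:
                center, source = None, "none"
            else:
                center, source = pupil_center_from_frame(label_map, min_area=min_area)
        except ValueError:
            raise
        except Exception as exc:
            raise RuntimeError(f"trace extraction failed at frame {i}: {exc}") from exc
        raw.append(TracePoint(i, i / fps, center, blink, "measured", source))

    return NystagmusTrace(points=interpolate_closed(raw), fps=fps)


def export_trace(trace: NystagmusTrace, path: str | Path) -> Path:
    """Write the trace as CSV (frame, time, x, y, blink, provenance)."""
    path = Path(path)
    trace.to_dataframe().to_csv(path, index=False, float_format="%.6f")
    return path


def read_trace(path: str | Path, fps: Optional[float] = None) -> NystagmusTrace:
    """Read a trace CSV written by :func:`export_trace`."""
    df = pd.read_csv(path)
    points = [
        TracePoint(
            int(r["frame"]), float(r["time"]), (float(r["x"]), float(r["y"])),
            str(r["blink"]), str(r["provenance"]),
        )
        for _, r in df.iterrows()
    ]
    if fps is None:
        fps = 1.0 / (points[1].time - points[0].time) if len(points) > 1 else 25.0
    return NystagmusTrace(points=points, fps=float(fps))


def plot_trace(trace: NystagmusTrace, path: str | Path) -> Path:
    """Two stacked panels (x vs t, y vs t); interpolated spans shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = trace.to_dataframe()
    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
    for ax, col, label in zip(axes, ("x", "y"), ("horizontal (x)", "vertical (y)")):
        ax.plot(df["time"], df[col], lw=1.0, color="tab:blue")
        interp = df["provenance"] == "interpolated"
        ax.plot(
            df["time"][interp], df[col][interp], ".", ms=3, color="tab:red",
            label="interpolated",
        )
        ax.set_ylabel(f"{label} [px]")
        ax.legend(loc="upper right", fontsize=8)
    axes[1].set_xlabel("time [s]")
    fig.suptitle("Pupil-center trace")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
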