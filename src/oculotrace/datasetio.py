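"""Corpus construction: frame extraction, SSIM dedup, resizing, splitting.

Turns frame containers (multi-page TIFF stacks or directories of image
files) into deduplicated, resized, split corpora, and round-trips
annotated corpora to disk as PNG images + PNG label masks + a CSV/JSON
manifest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from skimage.metrics import structural_similarity
from skimage.transform import resize as _sk_resize

from .synth import AnnotatedFrame, BLINK_STATES

TARGET_SIZE = (100, 100)
SSIM_THRESHOLD = 0.8

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg")


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def extract_frames(video_path: str | Path, stride: int = 1) -> list[np.ndarray]:
    """Extract grayscale frames from a frame container in temporal order.

    Accepts a multi-page TIFF stack or a directory of image files
    (sorted by name).  Returns every ``stride``-th frame starting from
    the first, i.e. ``ceil(total / stride)`` frames.
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    path = Path(video_path)
    if not path.exists():
        raise IOError(f"no such frame container: {path}")
    if path.is_dir():
        files = sorted(
            f for f in path.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise IOError(f"no image frames found in directory {path}")
        frames = []
        for i, f in enumerate(files):
            try:
                frames.append(_to_grayscale(np.asarray(Image.open(f))))
            except Exception as exc:  # pragma: no cover - corrupt input
                raise IOError(f"failed to read frame {i} ({f.name}): {exc}") from exc
    elif path.suffix.lower() in (".tif", ".tiff"):
        try:
            stack = tifffile.imread(path)
        except Exception as exc:
            raise IOError(f"failed to read TIFF stack {path}: {exc}") from exc
        if stack.ndim == 2:
            stack = stack[None]
        frames = [_to_grayscale(stack[i]) for i in range(stack.shape[0])]
    else:
        raise IOError(
            f"unsupported frame container {path.suffix!r}; use a multi-page "
            "TIFF stack or a directory of image files"
        )
    return frames[::stride]


def write_frames(frames: Sequence[np.ndarray], path: str | Path) -> Path:
    """Write frames as a lossless multi-page TIFF stack."""
    path = Path(path)
    stack = np.stack([np.asarray(f, dtype=np.uint8) for f in frames])
    tifffile.imwrite(path, stack, photometric="minisblack")
    return path


def dedup_frames_ssim(
    frames: Sequence[np.ndarray], threshold: float = SSIM_THRESHOLD
) -> list[int]:
    """Greedy near-duplicate removal by structural similarity.

    The first frame is always kept; each subsequent frame is kept iff
    its SSIM against the most recently kept frame is below ``threshold``
    (low similarity = informative).  Returns kept indices, strictly
    increasing.
    """
    if len(frames) == 0:
        return []
    shape = np.asarray(frames[0]).shape
    kept = [0]
    last = np.asarray(frames[0])
    for i in range(1, len(frames)):
        cur = np.asarray(frames[i])
        if cur.shape != shape:
            raise ValueError(
                f"frame {i} shape {cur.shape} != first frame shape {shape}"
            )
        s = structural_similarity(last, cur, data_range=255)
        if s < threshold:
            kept.append(i)
            last = cur
    return kept


def resize_frame(
    image: np.ndarray,
    target: tuple[int, int] = TARGET_SIZE,
    is_mask: bool = False,
) -> np.ndarray:
    """Resize to ``target`` (height, width).

    Images use bilinear interpolation with anti-aliasing; label masks
    use nearest-neighbor so no interpolated class values appear.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot resize an empty image")
    if image.shape[:2] == tuple(target):
        return image.copy()
    if is_mask:
        out = _sk_resize(
            image, target, order=0, preserve_range=True, anti_aliasing=False
        )
        return out.astype(image.dtype)
    out = _sk_resize(image, target, order=1, preserve_range=True, anti_aliasing=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class SplitSpec:
    """Train/val/test split rule: train = floor(0.8 N), remainder halved
    with the odd leftover frame assigned to test.  With
    ``shuffle_seed=None`` the split follows source order."""

    train_fraction: float = 0.8
    val_fraction: float = 0.1
    test_fraction: float = 0.1
    shuffle_seed: Optional[int] = None

    def __post_init__(self) -> None:
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")

    def sizes(self, n: int) -> tuple[int, int, int]:
        n_train = math.floor(self.train_fraction * n)
        rem = n - n_train
        n_val = rem // 2
        n_test = rem - n_val
        return n_train, n_val, n_test


@dataclass
class DatasetSplit:
    """Disjoint train/val/test partition of a corpus."""

    train: list
    val: list
    test: list
    source_tag: str = ""

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.val), len(self.test)


def split_dataset(frames: Sequence, spec: SplitSpec = SplitSpec(), source_tag: str = "") -> DatasetSplit:
    """Partition a corpus into train/val/test per the 80/10/10 rule."""
    n = len(frames)
    if n < 3:
        raise ValueError(f"need at least 3 frames to split, got {n}")
    order = np.arange(n)
    if spec.shuffle_seed is not None:
        order = np.random.default_rng(spec.shuffle_seed).permutation(n)
    n_train, n_val, n_test = spec.sizes(n)
    items = [frames[i] for i in order]
    return DatasetSplit(
        train=items[:n_train],
        val=items[n_train : n_train + n_val],
        test=items[n_train + n_val :],
        source_tag=source_tag,
    )


# ---------------------------------------------------------------------------
# Corpus round-trip: PNG images + PNG masks + CSV manifest.

_MANIFEST_NAME = "manifest.json"
_FRAMES_CSV = "frames.csv"


def write_corpus(frames: Sequence[AnnotatedFrame], directory: str | Path) -> Path:
    """Write an annotated corpus: images/, masks/, frames.csv, manifest.json."""
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    (directory / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, fr in enumerate(frames):
        img_name = f"frame_{i:05d}.png"
        Image.fromarray(fr.image, mode="L").save(directory / "images" / img_name)
        Image.fromarray(fr.label_mask, mode="L").save(directory / "masks" / img_name)
        cx, cy = ("", "") if fr.pupil_center is None else (
            f"{fr.pupil_center[0]:.4f}",
            f"{fr.pupil_center[1]:.4f}",
        )
        rows.append(
            {
                "index": i,
                "image": f"images/{img_name}",
                "mask": f"masks/{img_name}",
                "center_x": cx,
                "center_y": cy,
                "blink": fr.blink,
                "gaze_x": f"{fr.gaze[0]:.4f}",
                "gaze_y": f"{fr.gaze[1]:.4f}",
                "seed": fr.seed,
            }
        )
    pd.DataFrame(rows).to_csv(directory / _FRAMES_CSV, index=False)
    manifest = {
        "format": "oculotrace-corpus-v1",
        "n_frames": len(frames),
        "frames_csv": _FRAMES_CSV,
    }
    (directory / _MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))
    return directory


def read_corpus(directory: str | Path) -> list[AnnotatedFrame]:
    """Read a corpus written by :func:`write_corpus` (lossless round-trip)."""
    directory = Path(directory)
    manifest_path = directory / _MANIFEST_NAME
    if not manifest_path.exists():
        raise IOError(f"missing manifest {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    table = pd.read_csv(
        directory / manifest["frames_csv"], dtype={"center_x": str, "center_y": str}
    )
    frames = []
    for _, row in table.iterrows():
        idx = row["index"]
        img_path = directory / str(row["image"])
        mask_path = directory / str(row["mask"])
        if not img_path.exists():
            raise IOError(f"frame {idx}: missing image {img_path}")
        if not mask_path.exists():
            raise IOError(f"frame {idx}: missing mask {mask_path}")
        blink = str(row["blink"])
        if blink not in BLINK_STATES:
            raise ValueError(f"frame {idx}: invalid blink label {blink!r}")
        cx, cy = row["center_x"], row["center_y"]
        has_center = isinstance(cx, str) and cx.strip() != "" and cx != "nan"
        try:
            center = (float(cx), float(cy)) if has_center else None
            gaze = (float(row["gaze_x"]), float(row["gaze_y"]))
            seed = int(row["seed"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"frame {idx}: corrupt manifest row: {exc}") from exc
        frames.append(
            AnnotatedFrame(
                image=np.asarray(Image.open(img_path), dtype=np.uint8),
                label_mask=np.asarray(Image.open(mask_path), dtype=np.uint8),
                pupil_center=center,
                blink=blink,
                gaze=gaze,
                seed=seed,
            )
        )
    return frames
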