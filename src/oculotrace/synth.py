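"""Procedural single-eye frame renderer with exact ground truth.

Renders 100x100 grayscale eye images built from a simple parametric
geometry -- an eye opening bounded by two parabolic eyelid arcs, an iris
disk, and a concentric pupil disk -- together with the per-pixel class
mask, the analytic (sub-pixel) pupil center, and a three-state blink
label.  A sawtooth jerk-nystagmus waveform simulator drives multi-frame
sequences with scheduled blinks.

Coordinate convention (used package-wide): origin at the top-left pixel,
x increases rightward, y increases downward, pixel centers at integer
coordinates.  Gaze angles map linearly to pixel displacement of the
pupil center: +-40 degrees -> +-``gaze_gain_px`` pixels per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

# Exclusive per-pixel classes.
CLASS_BACKGROUND = 0
CLASS_SCLERA = 1
CLASS_IRIS = 2
CLASS_PUPIL = 3
CLASS_NAMES = ("background", "sclera", "iris", "pupil")

# Blink states.
BLINK_OPEN = "open"
BLINK_CLOSING = "closing"
BLINK_CLOSED = "closed"
BLINK_STATES = (BLINK_OPEN, BLINK_CLOSING, BLINK_CLOSED)

GAZE_SPAN_DEG = 40.0  # gaze angles live in [-40, +40] per axis

# Base gray levels (fraction of full scale) for each rendered structure.
_GRAY_SKIN = 0.55
_GRAY_SCLERA = 0.92
_GRAY_IRIS = 0.35
_GRAY_PUPIL = 0.06
_GRAY_SPECULAR = 0.98


@dataclass(frozen=True)
class EyeSceneParams:
    """Parameters of one rendered eye scene.

    Attributes
    ----------
    image_size : (height, width) in pixels.
    gaze : (theta_x, theta_y) gaze angles in degrees, clamped to
        [-40, +40] on each axis.
    aperture : eyelid opening fraction in [0, 1]; 1 is fully open,
        0 fully closed.  The upper lid sweeps down across the opening
        as the aperture decreases, the lower lid stays put.
    iris_radius : iris disk radius in pixels.
    pupil_ratio : pupil radius as a fraction of the iris radius, in (0, 1).
    noise_sd : additive Gaussian pixel noise, in 8-bit gray levels.
    illum_gradient : strength of a vertical multiplicative illumination
        gradient (0 disables it).
    specular : draw one small specular highlight disk on the iris.
    seed : RNG seed; identical params + seed give a bit-identical frame.
    gaze_gain_px : pixel displacement of the pupil center at +-40 deg.
    """

    image_size: tuple[int, int] = (100, 100)
    gaze: tuple[float, float] = (0.0, 0.0)
    aperture: float = 1.0
    iris_radius: float = 18.0
    pupil_ratio: float = 0.45
    noise_sd: float = 6.0
    illum_gradient: float = 0.0
    specular: bool = True
    seed: int = 0
    gaze_gain_px: float = 25.0
    # Eyelid geometry: parabolic arcs spanning +-opening_halfwidth around
    # the eye center, with apex height lid_height at full aperture.
    opening_halfwidth: float = 45.0
    lid_height: float = 38.0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 10 or w < 10:
            raise ValueError(f"image_size too small: {self.image_size}")
        if not (0.0 <= self.aperture <= 1.0):
            raise ValueError(f"aperture must be in [0, 1], got {self.aperture}")
        if not (0.0 < self.pupil_ratio < 1.0):
            raise ValueError(
                f"pupil_ratio must be in (0, 1), got {self.pupil_ratio}"
            )
        if self.iris_radius <= 0:
            raise ValueError(f"iris_radius must be positive, got {self.iris_radius}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        # Clamp gaze to the renderable span rather than erroring.
        gx = float(np.clip(self.gaze[0], -GAZE_SPAN_DEG, GAZE_SPAN_DEG))
        gy = float(np.clip(self.gaze[1], -GAZE_SPAN_DEG, GAZE_SPAN_DEG))
        object.__setattr__(self, "gaze", (gx, gy))

    @property
    def center(self) -> tuple[float, float]:
        """Geometric eye-opening center (x, y) in pixels."""
        h, w = self.image_size
        return ((w - 1) / 2.0, (h - 1) / 2.0)

    def gaze_to_pixel(self, gaze: Optional[tuple[float, float]] = None) -> tuple[float, float]:
        """Map gaze angles to the analytic pupil-center pixel position."""
        gx, gy = self.gaze if gaze is None else gaze
        cx0, cy0 = self.center
        scale = self.gaze_gain_px / GAZE_SPAN_DEG
        return (cx0 + gx * scale, cy0 + gy * scale)


@dataclass
class AnnotatedFrame:
    """One rendered frame with exact ground truth.

    ``pupil_center`` is the analytic center of the rendered pupil disk
    (sub-pixel), or ``None`` when the pupil is fully occluded by the
    eyelids.  ``gaze`` is kept so sequences can recover the analytic
    center even for occluded frames via ``EyeSceneParams.gaze_to_pixel``.
    """

    image: np.ndarray  # uint8, H x W
    label_mask: np.ndarray  # uint8, H x W, values in {0, 1, 2, 3}
    pupil_center: Optional[tuple[float, float]]
    blink: str
    gaze: tuple[float, float] = (0.0, 0.0)
    seed: int = 0


def _lid_curves(p: EyeSceneParams, xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper and lower eyelid y-coordinates at each x (NaN outside span)."""
    cx0, cy0 = p.center
    u = (xs - cx0) / p.opening_halfwidth
    h = 1.0 - u * u
    h[h < 0] = np.nan
    lower = cy0 + p.lid_height * h
    upper = cy0 + p.lid_height * (1.0 - 2.0 * p.aperture) * h
    return upper, lower


def render_eye_frame(params: EyeSceneParams) -> AnnotatedFrame:
    """Render one eye frame and its exact ground truth.

    Geometry: the eye opening is the region strictly between two
    parabolic eyelid arcs; the sclera is the opening minus the iris
    footprint; the iris is its disk clipped by the opening, minus the
    pupil; the pupil is a concentric disk clipped by the opening.
    The blink label follows iris visibility: ``open`` when every pixel
    of the iris footprint lies inside the opening, ``closed`` when none
    does, ``closing`` otherwise.

    Raises
    ------
    ValueError
        If the iris cannot fit inside the fully open eye aperture
        (invalid geometry).
    """
    h, w = params.image_size
    ys, xs = np.mgrid[0:h, 0:w].astype(float)

    upper, lower = _lid_curves(params, xs[0])
    # Opening: strictly between the lids (empty at aperture 0).
    opening = (xs[0][None, :] == xs[0][None, :])  # all True, right shape
    with np.errstate(invalid="ignore"):
        opening = (ys > upper[None, :]) & (ys < lower[None, :])

    cx, cy = params.gaze_to_pixel()
    rr2 = (xs - cx) ** 2 + (ys - cy) ** 2
    iris_disk = rr2 <= params.iris_radius**2
    pupil_disk = rr2 <= (params.pupil_ratio * params.iris_radius) ** 2

    if not iris_disk.any():
        raise ValueError("iris disk rasterizes to zero pixels")
    _validate_iris_fits(params)

    label = np.zeros((h, w), dtype=np.uint8)
    label[opening] = CLASS_SCLERA
    label[opening & iris_disk] = CLASS_IRIS
    label[opening & pupil_disk] = CLASS_PUPIL

    visible = int((iris_disk & opening).sum())
    total = int(iris_disk.sum())
    if visible == 0:
        blink = BLINK_CLOSED
    elif visible == total:
        blink = BLINK_OPEN
    else:
        blink = BLINK_CLOSING

    pupil_center = (cx, cy) if (label == CLASS_PUPIL).any() else None

    # Appearance: paint gray levels, then highlight, gradient and noise.
    img = np.full((h, w), _GRAY_SKIN)
    img[label == CLASS_SCLERA] = _GRAY_SCLERA
    img[label == CLASS_IRIS] = _GRAY_IRIS
    img[label == CLASS_PUPIL] = _GRAY_PUPIL
    if params.specular:
        sx = cx - 0.35 * params.iris_radius
        sy = cy - 0.35 * params.iris_radius
        spec = ((xs - sx) ** 2 + (ys - sy) ** 2 <= 2.0**2) & iris_disk & opening
        img[spec] = _GRAY_SPECULAR
    if params.illum_gradient:
        _, cy0 = params.center
        img *= 1.0 + params.illum_gradient * (ys - cy0) / h

    rng = np.random.default_rng(params.seed)
    img = img * 255.0 + rng.normal(0.0, params.noise_sd, size=(h, w))
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return AnnotatedFrame(
        image=image,
        label_mask=label,
        pupil_center=pupil_center,
        blink=blink,
        gaze=params.gaze,
        seed=params.seed,
    )


def _validate_iris_fits(params: EyeSceneParams) -> None:
    """Error out when the iris is larger than the fully open eye opening."""
    h, w = params.image_size
    centered = replace(params, gaze=(0.0, 0.0), aperture=1.0)
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    upper, lower = _lid_curves(centered, xs[0])
    with np.errstate(invalid="ignore"):
        opening = (ys > upper[None, :]) & (ys < lower[None, :])
    cx, cy = centered.gaze_to_pixel()
    disk = (xs - cx) ** 2 + (ys - cy) ** 2 <= params.iris_radius**2
    if (disk & ~opening).any():
        raise ValueError(
            f"iris_radius={params.iris_radius} does not fit inside the fully "
            "open eye aperture (invalid geometry)"
        )


@dataclass(frozen=True)
class NystagmusWaveform:
    """Sawtooth jerk-nystagmus gaze trajectory parameters.

    The slow phase drifts linearly at ``slow_phase_velocity`` (deg/s,
    per axis, signed by ``direction_sign``) and an instantaneous fast
    phase resets the position to ``baseline`` every ``1/beat_frequency``
    seconds.  When ``slow_phase_velocity`` is zero on an axis, the
    per-beat excursion ``amplitude`` defines the drift instead
    (velocity = amplitude * beat_frequency).
    """

    baseline: tuple[float, float] = (0.0, 0.0)
    slow_phase_velocity: tuple[float, float] = (0.0, 0.0)
    beat_frequency: float = 2.0
    amplitude: tuple[float, float] = (0.0, 0.0)
    direction_sign: tuple[int, int] = (1, 1)
    duration: float = 1.0
    fps: float = 25.0

    def __post_init__(self) -> None:
        if self.beat_frequency <= 0:
            raise ValueError(f"beat_frequency must be > 0, got {self.beat_frequency}")
        if self.fps <= 0 or self.duration <= 0:
            raise ValueError("fps and duration must be positive")
        if any(a < 0 for a in self.amplitude):
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if round(self.duration * self.fps) < 1:
            raise ValueError("duration * fps must cover at least one sample")

    def axis_velocity(self, axis: int) -> float:
        """Effective signed slow-phase velocity (deg/s) on one axis."""
        v = self.slow_phase_velocity[axis]
        if v == 0.0:
            v = self.amplitude[axis] * self.beat_frequency
        return self.direction_sign[axis] * v


def simulate_nystagmus_waveform(w: NystagmusWaveform) -> np.ndarray:
    """Sample the sawtooth gaze trajectory.

    Returns an array of shape (n, 3) with columns (t seconds,
    theta_x deg, theta_y deg), n = round(duration * fps), samples spaced
    1/fps apart starting at t = 0.  Positions are clamped to the
    renderable +-40 degree span.
    """
    n = int(round(w.duration * w.fps))
    t = np.arange(n) / w.fps
    period = 1.0 / w.beat_frequency
    phase = np.mod(t, period)
    out = np.empty((n, 3))
    out[:, 0] = t
    for axis in (0, 1):
        pos = w.baseline[axis] + w.axis_velocity(axis) * phase
        out[:, 1 + axis] = np.clip(pos, -GAZE_SPAN_DEG, GAZE_SPAN_DEG)
    return out


def generate_sequence(
    w: NystagmusWaveform,
    scene: EyeSceneParams,
    blink_schedule: Sequence[tuple[int, int]] = (),
) -> list[AnnotatedFrame]:
    """Render one frame per waveform sample, with scheduled blinks.

    Within each (start_frame, end_frame) blink interval (inclusive) the
    aperture ramps from the scene's value down to 0 at the midpoint and
    back, so a long enough interval traverses
    open -> closing -> closed -> closing -> open.
    """
    samples = simulate_nystagmus_waveform(w)
    n = len(samples)
    schedule = sorted(tuple(iv) for iv in blink_schedule)
    prev_end = -1
    for s, e in schedule:
        if not (0 <= s <= e < n):
            raise ValueError(f"blink interval ({s}, {e}) outside sequence of {n} frames")
        if s <= prev_end:
            raise ValueError(f"blink intervals overlap at frame {s}")
        prev_end = e

    frames: list[AnnotatedFrame] = []
    for i in range(n):
        aperture = scene.aperture
        for s, e in schedule:
            if s <= i <= e:
                tt = 0.5 if e == s else (i - s) / (e - s)
                aperture = scene.aperture * abs(1.0 - 2.0 * tt)
                break
        p = replace(
            scene,
            gaze=(float(samples[i, 1]), float(samples[i, 2])),
            aperture=aperture,
            seed=scene.seed + i,
        )
        frames.append(render_eye_frame(p))
    return frames


DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "gaze_x": (-GAZE_SPAN_DEG, GAZE_SPAN_DEG),
    "gaze_y": (-GAZE_SPAN_DEG, GAZE_SPAN_DEG),
    "aperture": (0.0, 1.0),
    "iris_radius": (14.0, 20.0),
    "pupil_ratio": (0.3, 0.6),
    "noise_sd": (2.0, 10.0),
    "illum_gradient": (0.0, 0.25),
}


def generate_dataset(
    n: int,
    seed: int,
    param_ranges: Optional[dict[str, tuple[float, float]]] = None,
    base: Optional[EyeSceneParams] = None,
) -> list[AnnotatedFrame]:
    """Draw ``n`` i.i.d. annotated frames with uniformly sampled params.

    ``param_ranges`` overrides entries of :data:`DEFAULT_PARAM_RANGES`;
    a degenerate range (v, v) pins a parameter.  Reproducible under
    ``seed``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    ranges = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        unknown = set(param_ranges) - set(ranges)
        if unknown:
            raise ValueError(f"unknown parameter ranges: {sorted(unknown)}")
        ranges.update(param_ranges)
    for k, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"empty range for {k}: ({lo}, {hi})")

    base = base or EyeSceneParams()
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n):
        draw = {k: rng.uniform(lo, hi) for k, (lo, hi) in ranges.items()}
        p = replace(
            base,
            gaze=(draw["gaze_x"], draw["gaze_y"]),
            aperture=float(draw["aperture"]),
            iris_radius=float(draw["iris_radius"]),
            pupil_ratio=float(draw["pupil_ratio"]),
            noise_sd=float(draw["noise_sd"]),
            illum_gradient=float(draw["illum_gradient"]),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        frames.append(render_eye_frame(p))
    return frames
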