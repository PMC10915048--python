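"""Renderer and waveform ground-truth contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oculotrace.synth import (
    BLINK_CLOSED,
    BLINK_CLOSING,
    BLINK_OPEN,
    CLASS_IRIS,
    CLASS_PUPIL,
    EyeSceneParams,
    NystagmusWaveform,
    generate_dataset,
    generate_sequence,
    render_eye_frame,
    simulate_nystagmus_waveform,
)


class TestRenderEyeFrame:
    def test_centered_open_eye(self):
        """Full aperture, centered gaze: open label, pupil at image center."""
        f = render_eye_frame(EyeSceneParams(noise_sd=0.0))
        assert f.blink == BLINK_OPEN
        assert f.pupil_center == pytest.approx((49.5, 49.5))

    def test_fully_closed_eye(self):
        f = render_eye_frame(EyeSceneParams(aperture=0.0))
        assert f.blink == BLINK_CLOSED
        assert (f.label_mask == CLASS_IRIS).sum() == 0
        assert (f.label_mask == CLASS_PUPIL).sum() == 0
        assert f.pupil_center is None

    def test_extreme_horizontal_gaze_displacement(self):
        """+40 deg horizontal gaze displaces the center by gaze_gain_px."""
        p = EyeSceneParams(gaze=(40.0, 0.0), noise_sd=0.0)
        f = render_eye_frame(p)
        assert f.pupil_center[0] == pytest.approx(49.5 + p.gaze_gain_px)
        assert f.pupil_center[1] == pytest.approx(49.5)

    def test_determinism_bit_identical(self):
        p = EyeSceneParams(gaze=(7.0, -12.0), aperture=0.8, seed=123)
        a, b = render_eye_frame(p), render_eye_frame(p)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.label_mask, b.label_mask)

    def test_label_mask_is_exclusive_partition(self):
        f = render_eye_frame(EyeSceneParams(gaze=(10.0, -5.0), aperture=0.7))
        assert set(np.unique(f.label_mask)) <= {0, 1, 2, 3}

    def test_pupil_inside_iris_footprint(self):
        f = render_eye_frame(EyeSceneParams(gaze=(15.0, 10.0)))
        pupil = f.label_mask == CLASS_PUPIL
        # every pupil pixel is within iris_radius of the analytic center
        ys, xs = np.nonzero(pupil)
        cx, cy = f.pupil_center
        d = np.hypot(xs - cx, ys - cy)
        assert (d <= 18.0).all()

    def test_open_means_unclipped_iris(self):
        """Open label: the rendered iris footprint equals the full disk."""
        p = EyeSceneParams(gaze=(5.0, -3.0), noise_sd=0.0)
        f = render_eye_frame(p)
        assert f.blink == BLINK_OPEN
        h, w = p.image_size
        ys, xs = np.mgrid[0:h, 0:w].astype(float)
        cx, cy = p.gaze_to_pixel()
        disk = (xs - cx) ** 2 + (ys - cy) ** 2 <= p.iris_radius**2
        footprint = (f.label_mask == CLASS_IRIS) | (f.label_mask == CLASS_PUPIL)
        assert np.array_equal(disk, footprint)

    def test_closed_iff_no_iris_pixels(self):
        for aperture in (0.0, 0.1, 0.35, 0.6, 1.0):
            f = render_eye_frame(EyeSceneParams(aperture=aperture))
            footprint = ((f.label_mask == CLASS_IRIS) | (f.label_mask == CLASS_PUPIL)).sum()
            assert (f.blink == BLINK_CLOSED) == (footprint == 0)

    def test_gaze_clamped_to_span(self):
        p = EyeSceneParams(gaze=(60.0, -75.0))
        assert p.gaze == (40.0, -40.0)

    def test_oversized_iris_rejected(self):
        with pytest.raises(ValueError, match="invalid geometry|fit"):
            render_eye_frame(EyeSceneParams(iris_radius=40.0))

    def test_gaze_linearity_recoverable(self):
        """Center displacement is affine in gaze; 5 frames pin the map."""
        gazes = [(0, 0), (10, 0), (0, 10), (-20, 5), (15, -25)]
        centers = []
        for g in gazes:
            f = render_eye_frame(EyeSceneParams(gaze=g, noise_sd=0.0))
            centers.append(f.pupil_center)
        a = np.column_stack([np.array(gazes, float), np.ones(len(gazes))])
        coef, res, *_ = np.linalg.lstsq(a, np.array(centers), rcond=None)
        fitted = a @ coef
        assert np.allclose(fitted, centers, atol=1e-9)


class TestNystagmusWaveform:
    def test_constant_trace_at_baseline(self):
        w = NystagmusWaveform(baseline=(3.0, -2.0), duration=2.0, fps=10.0)
        s = simulate_nystagmus_waveform(w)
        assert len(s) == 20
        assert np.allclose(s[:, 1], 3.0) and np.allclose(s[:, 2], -2.0)

    def test_position_before_reset_equals_velocity_times_period(self):
        w = NystagmusWaveform(
            slow_phase_velocity=(10.0, 0.0), beat_frequency=1.0, duration=3.0, fps=25.0
        )
        s = simulate_nystagmus_waveform(w)
        # last sample of each period sits at v * (T - 1/fps)
        for k in (24, 49, 74):
            assert s[k, 1] == pytest.approx(10.0 * (1.0 - 1 / 25.0))

    def test_sampled_mean_over_integer_periods(self):
        """Closed form: mean of v * (k/fps mod T) = v (T - 1/fps) / 2."""
        w = NystagmusWaveform(
            baseline=(2.0, 0.0), slow_phase_velocity=(8.0, 0.0),
            beat_frequency=2.0, duration=3.0, fps=20.0,
        )
        s = simulate_nystagmus_waveform(w)
        expected = 2.0 + 8.0 * (0.5 - 1 / 20.0) / 2.0
        assert s[:, 1].mean() == pytest.approx(expected)

    @pytest.mark.parametrize("bf,duration", [(1.6, 5.2), (1.7, 5.0), (0.9, 7.0)])
    def test_reset_count_matches_beat_frequency(self, bf, duration):
        """Fast-phase resets observed in [0, D) number floor(D * bf)."""
        w = NystagmusWaveform(
            slow_phase_velocity=(10.0, 0.0), beat_frequency=bf,
            duration=duration, fps=50.0,
        )
        s = simulate_nystagmus_waveform(w)
        resets = int((np.diff(s[:, 1]) < 0).sum())
        assert resets == int(np.floor(duration * bf))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            NystagmusWaveform(beat_frequency=0.0)
        with pytest.raises(ValueError):
            NystagmusWaveform(fps=-1.0)
        with pytest.raises(ValueError):
            NystagmusWaveform(amplitude=(-1.0, 0.0))

    def test_positions_stay_in_renderable_span(self):
        w = NystagmusWaveform(
            baseline=(30.0, -30.0), slow_phase_velocity=(50.0, -50.0),
            beat_frequency=0.5, duration=4.0, fps=30.0,
        )
        s = simulate_nystagmus_waveform(w)
        assert (np.abs(s[:, 1:]) <= 40.0).all()


class TestGenerateSequence:
    def test_frame_count_and_all_open(self):
        w = NystagmusWaveform(duration=1.0, fps=25.0)
        frames = generate_sequence(w, EyeSceneParams())
        assert len(frames) == 25
        assert all(f.blink == "open" for f in frames)

    def test_blink_interval_traverses_states(self, nystagmus_sequence):
        frames, _, _ = nystagmus_sequence
        window = [f.blink for f in frames[10:15]]
        assert BLINK_CLOSED in window
        assert window[0] != BLINK_CLOSED and window[-1] != BLINK_CLOSED
        assert BLINK_CLOSING in window[: window.index(BLINK_CLOSED)]
        assert BLINK_CLOSING in window[window.index(BLINK_CLOSED) :]

    def test_frame_matches_single_render_at_sample(self):
        """Composition identity: frame i equals a lone render at sample i."""
        from dataclasses import replace

        w = NystagmusWaveform(
            slow_phase_velocity=(12.0, -6.0), beat_frequency=2.0, duration=0.4, fps=25.0
        )
        scene = EyeSceneParams(seed=5)
        frames = generate_sequence(w, scene)
        s = simulate_nystagmus_waveform(w)
        i = 7
        lone = render_eye_frame(
            replace(scene, gaze=(s[i, 1], s[i, 2]), seed=scene.seed + i)
        )
        assert np.array_equal(frames[i].image, lone.image)
        assert frames[i].pupil_center == lone.pupil_center

    def test_overlapping_blinks_rejected(self):
        w = NystagmusWaveform(duration=1.0, fps=25.0)
        with pytest.raises(ValueError, match="overlap"):
            generate_sequence(w, EyeSceneParams(), blink_schedule=[(2, 8), (5, 12)])

    def test_out_of_range_blink_rejected(self):
        w = NystagmusWaveform(duration=1.0, fps=25.0)
        with pytest.raises(ValueError, match="outside"):
            generate_sequence(w, EyeSceneParams(), blink_schedule=[(20, 30)])


class TestGenerateDataset:
    def test_reproducible_under_seed(self):
        a = generate_dataset(10, seed=21)
        b = generate_dataset(10, seed=21)
        for x, y in zip(a, b):
            assert np.array_equal(x.image, y.image)
            assert x.blink == y.blink

    def test_pinned_aperture_gives_all_open(self):
        frames = generate_dataset(
            20, seed=3,
            param_ranges={"aperture": (1.0, 1.0), "gaze_x": (-5, 5), "gaze_y": (-5, 5)},
        )
        assert all(f.blink == "open" for f in frames)

    def test_blink_classes_all_represented(self, small_corpus):
        from collections import Counter

        counts = Counter(f.blink for f in small_corpus)
        n = len(small_corpus)
        for state in ("open", "closing", "closed"):
            assert 0.05 < counts[state] / n < 0.95

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="empty range"):
            generate_dataset(5, seed=0, param_ranges={"aperture": (0.8, 0.2)})

    def test_zero_frames_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(0, seed=0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    gx=st.floats(-40, 40), gy=st.floats(-40, 40),
    aperture=st.floats(0, 1), seed=st.integers(0, 2**16),
)
def test_partition_property(gx, gy, aperture, seed):
    """Every pixel has exactly one class; blink label is consistent."""
    f = render_eye_frame(
        EyeSceneParams(gaze=(gx, gy), aperture=aperture, seed=seed)
    )
    assert f.label_mask.shape == f.image.shape
    assert f.label_mask.max() <= 3
    footprint = ((f.label_mask == CLASS_IRIS) | (f.label_mask == CLASS_PUPIL)).sum()
    assert (f.blink == BLINK_CLOSED) == (footprint == 0)
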