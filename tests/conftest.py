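"""Shared fixtures: small corpora and a desk-scale trained model.

Everything is generated procedurally at test time; the session-scoped
model is trained once on a small corpus and reused by the model,
tracking and CLI tests.  The acceptance tests train their own
full-size model.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from oculotrace import (
    EyeSceneParams,
    ModelConfig,
    NystagmusWaveform,
    build_model,
    generate_dataset,
    generate_sequence,
    split_dataset,
    train_blink,
    train_segmentation,
)

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_corpus():
    """400 frames drawn from the default parameter ranges, seed 7."""
    return generate_dataset(400, seed=7)


@pytest.fixture(scope="session")
def small_split(small_corpus):
    return split_dataset(small_corpus)


@pytest.fixture(scope="session")
def trained_model(small_split):
    """Both heads trained at reduced scale (300 frames, few epochs)."""
    model = build_model(ModelConfig(seed=3, epochs=8))
    model, _ = train_segmentation(model, small_split)
    model, _ = train_blink(model, small_split.train, val_frames=small_split.val)
    return model


@pytest.fixture(scope="session")
def nystagmus_sequence():
    """4 s sawtooth sequence with one blink, plus its scene params."""
    w = NystagmusWaveform(
        baseline=(-5.0, 4.0),
        slow_phase_velocity=(20.0, -18.0),
        beat_frequency=2.0,
        duration=4.0,
        fps=25.0,
    )
    scene = EyeSceneParams(noise_sd=4.0, seed=42)
    frames = generate_sequence(w, scene, blink_schedule=[(10, 14)])
    return frames, scene, w
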