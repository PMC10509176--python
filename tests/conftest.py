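"""Shared fixtures: synthetic utterances and cohort tables with known truth."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from phonoscope.assembly import extract_all
from phonoscope.audio_io import frame_signal
from phonoscope.synth import UtteranceSpec, random_pause_schedule, synth_utterance
from phonoscope.temporal import detect_speech_activity


@pytest.fixture(scope="session")
def short_utterance():
    """12 s utterance with 4 known pauses, plus its ground truth."""
    rng = np.random.default_rng(42)
    schedule = random_pause_schedule(12.0, 4, 0.6, 0.1, rng)
    spec = UtteranceSpec(duration_s=12.0, pause_schedule=schedule, seed=42)
    return synth_utterance(spec)


@pytest.fixture(scope="session")
def short_features(short_utterance):
    sample, _ = short_utterance
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return extract_all(sample)


@pytest.fixture(scope="session")
def framed(short_utterance):
    sample, _ = short_utterance
    return frame_signal(sample, 0.025, 0.010)


@pytest.fixture(scope="session")
def pause_analysis(short_utterance, framed):
    sample, _ = short_utterance
    return detect_speech_activity(sample, framed)
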