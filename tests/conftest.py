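"""Shared fixtures: synthetic stimuli and their extracted features.

Extraction over a full 30 s stimulus is the most expensive operation in
the suite, so clips and their feature vectors are session-scoped and
reused across test modules.
"""

import numpy as np
import pytest

import beatwalk as bw


@pytest.fixture(scope="session")
def metronome_clip():
    """The study's standard stimulus: 30 s metronome at 130 BPM."""
    return bw.make_metronome(bw.StimulusSpec())


@pytest.fixture(scope="session")
def metronome_loudness(metronome_clip):
    return bw.subband_loudness(metronome_clip)


@pytest.fixture(scope="session")
def clip_p3():
    """Standard-length stimulus with period-3 loudness modulation."""
    clip, annotation = bw.make_modulated_stimulus(
        bw.StimulusSpec(mod_period=3, mod_depth=0.5, seed=7)
    )
    return clip, annotation


@pytest.fixture(scope="session")
def vector_p3(clip_p3):
    clip, _ = clip_p3
    return bw.extract_song_features(clip, nominal_tempo=130.0)


@pytest.fixture(scope="session")
def vector_p4():
    clip, _ = bw.make_modulated_stimulus(
        bw.StimulusSpec(mod_period=4, mod_depth=0.5, seed=7)
    )
    return bw.extract_song_features(clip, nominal_tempo=130.0)


@pytest.fixture(scope="session")
def vector_unmodulated():
    clip, _ = bw.make_modulated_stimulus(
        bw.StimulusSpec(mod_depth=0.0, seed=7)
    )
    return bw.extract_song_features(clip, nominal_tempo=130.0)


@pytest.fixture(scope="session")
def tone_clip_440():
    """A 2 s pure A4 tone."""
    sr = 22050
    t = np.arange(int(2.0 * sr)) / sr
    return bw.AudioClip(samples=0.5 * np.sin(2 * np.pi * 440.0 * t), sample_rate=sr)
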