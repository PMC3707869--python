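"""beatwalk: sonic-feature extraction and gait analysis for
beat-synchronized walking studies.

The package covers the full analysis chain of a music-entrainment walking
experiment: synthetic stimulus and sensor generators, a 190-dimensional
sonic feature extractor (frame -> beat -> song levels), IMU-derived gait
metrics with metronome-relative normalization, a nested cross-validated
feature-selection regression for per-song walking speed, and
activating/relaxing group statistics.
"""

from importlib import resources

import pandas as pd

from .audio import AudioClip, read_wav, write_wav
from .beats import BEAT_FEATURE_NAMES, BeatFeatureMatrix, BeatGrid, track_beats
from .frames import note_evidence, note_grid, subband_loudness
from .gait import (
    GaitResult,
    TrialRecord,
    classify_sync,
    normalize_speeds,
    walking_speed,
    walking_tempo,
)
from .model import CVReport, RegressionModel, final_model, fit_linear, nested_cv, preselect_pairs
from .songlevel import (
    FEATURE_NAMES,
    N_SONG_FEATURES,
    REGISTRY,
    SongFeatureVector,
    extract_song_features,
    periodicity_evidence,
    song_vector,
)
from .stats import GroupAssignment, extreme_groups, feature_ttests, ratings_tests, speed_anova
from .synth import (
    PlantedModelSpec,
    StimulusSpec,
    WalkSpec,
    make_metronome,
    make_modulated_stimulus,
    simulate_speed_dataset,
    simulate_walk_trial,
)

__version__ = "0.1.0"


def table1_labels() -> pd.DataFrame:
    """The study's 52-song catalogue with activating/relaxing rank labels."""
    with resources.files("beatwalk.data").joinpath("table1_labels.csv").open() as fh:
        return pd.read_csv(fh, index_col="song_id")
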