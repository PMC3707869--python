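"""Synthetic study inputs: stimuli, sensor traces, planted datasets, ratings.

The walking study this package analyzes used copyrighted commercial
recordings and human participants, so none of its raw data can ship.
This module generates stand-ins with known ground truth for every input
the pipeline consumes:

* beat-locked audio (metronomes and chord stimuli whose per-beat loudness
  is modulated at a chosen metrical period of 2, 3, 4 or 6 beats),
* circular-path walking trials (hip heading at 50 Hz, foot acceleration
  with one burst per stride),
* song x feature tables with a planted sparse linear speed model,
* bipolar-adjective rating tables with planted group shifts.

All randomness flows from the single integer ``seed`` of each spec, so
every generated fixture is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio import AudioClip
from .beats import default_beat_count
from .errors import InvalidSpecError
from .frames import note_grid
from .gait import TrialRecord
from .songlevel import FEATURE_NAMES, N_SONG_FEATURES

ALLOWED_MOD_PERIODS = (None, 2, 3, 4, 6)

#: Default per-participant stride-burst amplitude (m/s^2).
BURST_AMPLITUDE = 10.0
GRAVITY = 9.81


@dataclass
class StimulusSpec:
    """Specification of a beat-locked synthetic stimulus.

    ``n_beats`` defaults to the number of complete inter-beat intervals
    strictly inside the clip — 64 for the standard 30 s at 130 BPM.
    ``mod_period`` modulates the per-beat amplitude with a cosine of the
    given period (in beats) and relative depth ``mod_depth``.
    """

    tempo: float = 130.0
    duration: float = 30.0
    n_beats: int | None = None
    mod_period: int | None = None
    mod_depth: float = 0.0
    notes_per_beat: int = 1
    subdivisions: int = 1  # extra equal ticks per beat (for comb tests)
    sample_rate: int = 22050
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tempo <= 0 or self.duration <= 0:
            raise InvalidSpecError("tempo and duration must be positive")
        if self.mod_period not in ALLOWED_MOD_PERIODS:
            raise InvalidSpecError(
                f"mod_period must be one of {ALLOWED_MOD_PERIODS}"
            )
        if not 0.0 <= self.mod_depth <= 1.0:
            raise InvalidSpecError("mod_depth must lie in [0, 1]")
        if self.notes_per_beat not in (1, 2, 3):
            raise InvalidSpecError("notes_per_beat must be 1, 2 or 3")
        if self.n_beats is None:
            self.n_beats = default_beat_count(self.duration, self.tempo)

    @property
    def ibi(self) -> float:
        return 60.0 / self.tempo

    @property
    def beat_times(self) -> np.ndarray:
        return np.arange(self.n_beats) * self.ibi


@dataclass
class WalkSpec:
    """Specification of a simulated circular-path walking trial."""

    speed: float = 1.4  # m/s
    cadence: float = 130.0  # steps per minute
    radius: float = 7.5  # m (15 m diameter circle)
    duration: float = 30.0  # s
    sample_rate: float = 50.0  # Hz
    heading_noise_sd: float = 0.0  # radians
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InvalidSpecError("radius must be positive")
        if self.speed < 0 or self.cadence <= 0:
            raise InvalidSpecError("speed must be >= 0 and cadence > 0")


@dataclass
class PlantedModelSpec:
    """A sparse linear speed model planted in an otherwise-noise table."""

    n_songs: int = 52
    true_feature_ids: tuple[int, ...] = (1, 2, 3, 4)  # registry ids (1-based)
    # defaults give each planted feature a marginal speed correlation of
    # ~0.45-0.54, clearly identifiable at n=52 (the chance-level pairwise
    # multiple correlation there is ~0.33)
    coefficients: tuple[float, ...] = (3.0, -3.0, 2.5, -2.5)
    intercept: float = 100.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        ids = tuple(self.true_feature_ids)
        if len(set(ids)) != len(ids):
            raise InvalidSpecError("true_feature_ids must be distinct")
        if any(not 1 <= i <= N_SONG_FEATURES for i in ids):
            raise InvalidSpecError("true_feature_ids outside feature registry")
        if len(self.coefficients) != len(ids):
            raise InvalidSpecError("one coefficient per planted feature required")
        if self.n_songs < len(ids) + 2:
            raise InvalidSpecError(
                "n_songs must be at least number of planted features + 2"
            )


def _tick(sample_rate: int, length_s: float = 0.010, ramp_s: float = 0.002,
          freq: float = 1000.0) -> np.ndarray:
    """A short 1 kHz pip with linear ramps; broadband enough for onsets."""
    n = max(4, int(round(length_s * sample_rate)))
    t = np.arange(n) / sample_rate
    pip = np.sin(2 * np.pi * freq * t)
    ramp = max(2, int(round(ramp_s * sample_rate)))
    env = np.ones(n)
    env[:ramp] = np.linspace(0.0, 1.0, ramp)
    env[-ramp:] = np.linspace(1.0, 0.0, ramp)
    return pip * env


def make_metronome(spec: StimulusSpec) -> AudioClip:
    """A metronome: exactly ``n_beats`` ticks at k * 60/tempo, silence between.

    Deterministic given the spec (the tick is a fixed 1 kHz pip).
    """
    n_samples = int(round(spec.duration * spec.sample_rate))
    samples = np.zeros(n_samples)
    tick = _tick(spec.sample_rate)
    for t in spec.beat_times:
        i = int(round(t * spec.sample_rate))
        j = min(n_samples, i + len(tick))
        samples[i:j] += tick[: j - i]
    clip = AudioClip(samples=samples, sample_rate=spec.sample_rate,
                     nominal_tempo=spec.tempo)
    clip.annotation = {
        "kind": "metronome",
        "tempo": spec.tempo,
        "n_beats": int(spec.n_beats),
        "beat_times": spec.beat_times.tolist(),
    }
    return clip


def make_modulated_stimulus(spec: StimulusSpec) -> tuple[AudioClip, dict]:
    """A music-like stimulus: per-beat chords with metrical loudness modulation.

    Each beat carries ``notes_per_beat`` tones drawn (seeded) from the
    52-note grid; the per-beat amplitude is scaled by
    ``1 + mod_depth * cos(2*pi*k/mod_period)``.  With ``mod_depth=0``
    every beat is acoustically identical.  Returns the clip plus a
    ground-truth annotation (true modulation period, beat times, note
    frequencies).  Music-like stimuli get a 50 ms fade-in and a 100 ms
    fade-out.
    """
    rng = np.random.default_rng(spec.seed)
    grid = note_grid()
    # choose notes from the middle of the grid so all harmonics stay in band
    candidates = grid[8:40]
    freqs = np.sort(rng.choice(candidates, size=spec.notes_per_beat, replace=False))
    n_samples = int(round(spec.duration * spec.sample_rate))
    samples = np.zeros(n_samples)
    sub_offsets = np.arange(spec.subdivisions) * spec.ibi / spec.subdivisions
    amps = np.ones(spec.n_beats)
    if spec.mod_period is not None:
        k = np.arange(spec.n_beats)
        amps = 1.0 + spec.mod_depth * np.cos(2 * np.pi * k / spec.mod_period)
    ramp = max(2, int(round(0.005 * spec.sample_rate)))

    def _chord(amp: float) -> np.ndarray:
        # louder beats ring longer: sustain scales with the beat amplitude,
        # so the modulation shapes the within-beat loudness pattern and not
        # just its overall level
        frac = float(np.clip(0.45 * amp, 0.15, 0.90))
        n_tone = int(round(frac * spec.ibi * spec.sample_rate))
        env = np.ones(n_tone)
        env[:ramp] = np.linspace(0.0, 1.0, min(ramp, n_tone))
        env[-ramp:] = np.linspace(1.0, 0.0, min(ramp, n_tone))
        t_tone = np.arange(n_tone) / spec.sample_rate
        wave = env * sum(np.sin(2 * np.pi * f * t_tone) for f in freqs)
        return amp * wave / max(1, spec.notes_per_beat)

    for k, t in enumerate(spec.beat_times):
        tone = _chord(amps[k])
        for off in sub_offsets:
            i = int(round((t + off) * spec.sample_rate))
            j = min(n_samples, i + len(tone))
            if i < n_samples:
                samples[i:j] += tone[: j - i]
    # fades as applied to the study's musical excerpts
    fade_in = int(round(0.050 * spec.sample_rate))
    fade_out = int(round(0.100 * spec.sample_rate))
    samples[:fade_in] *= np.linspace(0.0, 1.0, fade_in)
    samples[-fade_out:] *= np.linspace(1.0, 0.0, fade_out)
    clip = AudioClip(samples=samples, sample_rate=spec.sample_rate,
                     nominal_tempo=spec.tempo)
    annotation = {
        "kind": "modulated",
        "tempo": spec.tempo,
        "n_beats": int(spec.n_beats),
        "beat_times": spec.beat_times.tolist(),
        "mod_period": spec.mod_period,
        "mod_depth": spec.mod_depth,
        "note_freqs": freqs.tolist(),
        "beat_amplitudes": amps.tolist(),
        "subdivisions": spec.subdivisions,
        "seed": spec.seed,
    }
    clip.annotation = annotation
    return clip, annotation


def simulate_walk_trial(
    spec: WalkSpec,
    participant_id: str = "p01",
    stimulus_id: str = "s01",
    stimulus_kind: str = "song",
) -> TrialRecord:
    """Simulate hip-heading and foot-acceleration streams for one trial.

    The heading advances at angular rate speed/radius plus zero-mean
    Gaussian noise and is wrapped to [0, 2*pi) — consumers must unwrap.
    The foot acceleration carries one Gaussian burst per stride (stride
    rate = cadence/2) on top of gravity plus sensor noise.
    """
    rng = np.random.default_rng(spec.seed)
    # include the endpoint sample so the recorded span equals the duration
    n = int(round(spec.duration * spec.sample_rate)) + 1
    t = np.arange(n) / spec.sample_rate
    theta0 = rng.uniform(0.0, 2 * np.pi)
    heading_true = theta0 + (spec.speed / spec.radius) * t
    noise = (
        rng.normal(0.0, spec.heading_noise_sd, size=n)
        if spec.heading_noise_sd > 0
        else np.zeros(n)
    )
    heading = np.mod(heading_true + noise, 2 * np.pi)

    stride_period = 120.0 / spec.cadence  # s per stride (2 steps = 1 stride)
    burst_times = np.arange(0.25, spec.duration, stride_period)
    acc_z = np.full(n, GRAVITY)
    width = 0.030  # s
    for bt in burst_times:
        acc_z += BURST_AMPLITUDE * np.exp(-0.5 * ((t - bt) / width) ** 2)
    acc_noise_sd = 0.05
    acc = np.column_stack(
        [
            rng.normal(0.0, acc_noise_sd, size=n),
            rng.normal(0.0, acc_noise_sd, size=n),
            acc_z + rng.normal(0.0, acc_noise_sd, size=n),
        ]
    )
    return TrialRecord(
        participant_id=participant_id,
        stimulus_id=stimulus_id,
        stimulus_kind=stimulus_kind,
        time_s=t,
        heading=heading,
        foot_acc=acc,
        sample_rate=spec.sample_rate,
        ground_truth={
            "speed": spec.speed,
            "cadence": spec.cadence,
            "distance": spec.speed * spec.duration,
            "radius": spec.radius,
            "seed": spec.seed,
        },
    )


def simulate_speed_dataset(
    spec: PlantedModelSpec,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Song x feature table with a planted sparse linear speed model.

    Features are independent standard normal draws; the speed of song i is
    ``intercept + sum_j coeff_j * feature_ij + N(0, noise_sd)``.  Columns
    are the full 190-entry song-feature registry names.
    """
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.n_songs, N_SONG_FEATURES))
    idx = np.array(spec.true_feature_ids) - 1
    speeds = spec.intercept + X[:, idx] @ np.asarray(spec.coefficients)
    if spec.noise_sd > 0:
        speeds = speeds + rng.normal(0.0, spec.noise_sd, size=spec.n_songs)
    features = pd.DataFrame(
        X,
        columns=list(FEATURE_NAMES),
        index=[f"s{i + 1:02d}" for i in range(spec.n_songs)],
    )
    features.index.name = "song_id"
    return features, speeds


def simulate_ratings(
    song_ids: list[str],
    activating: list[str],
    relaxing: list[str],
    shifted_adjectives: tuple[str, ...] = (
        "good-bad",
        "tender-aggressive",
        "soft-loud",
        "slow-fast",
        "stuttering-flowing",
    ),
    shift: float = 25.0,
    rating_sd: float = 8.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean bipolar-adjective ratings (0-100) with planted group shifts.

    Activating songs are shifted toward the second adjective of each
    shifted pair (+shift/2) and relaxing songs toward the first
    (-shift/2), except for ``stuttering-flowing`` where the direction is
    reversed (activating music reads as stuttering, the first adjective).
    """
    from .stats import ADJECTIVE_PAIRS

    rng = np.random.default_rng(seed)
    base = rng.normal(50.0, rating_sd, size=(len(song_ids), len(ADJECTIVE_PAIRS)))
    df = pd.DataFrame(base, index=song_ids, columns=ADJECTIVE_PAIRS)
    df.index.name = "song_id"
    for adj in shifted_adjectives:
        direction = -1.0 if adj == "stuttering-flowing" else 1.0
        df.loc[df.index.isin(activating), adj] += direction * shift / 2.0
        df.loc[df.index.isin(relaxing), adj] -= direction * shift / 2.0
    return df.clip(0.0, 100.0)


def write_annotation(annotation: dict, path) -> None:
    """Write a ground-truth annotation as a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump(annotation, fh, indent=2)
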