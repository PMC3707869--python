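"""Beat-level analysis: beat grid location and the 47 per-beat features.

Every stimulus in the study design has a known nominal tempo (130 BPM), so
the tracker only fits the *phase* of a rigid beat grid: the phase is chosen
to maximize the summed onset strength at the grid points.  The tracker also
emits two scalar "oscillator" outputs measuring how much onset energy sits
at the binary (2x) and ternary (3x) subdivisions of the beat, i.e. the
resonance of the onset envelope with combs at twice and three times the
beat rate.

Per beat the 47 features are, in registry order:

* 7 beat-onset loudness growths (total + 6 subbands),
* 3 beat-event descriptors (onset position, event length, event skewness),
* 21 beat-period loudness statistics (mean, sd, temporal centroid for each
  of the 7 loudness series),
* 10 pitch descriptors (onset position of the most salient note, then
  frequency/chroma/salience of the top-3 notes in the inter-beat interval),
* 6 cosine similarities between feature sub-vectors of consecutive beats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import skew as _skew

from .audio import AudioClip
from .frames import (
    LoudnessSeries,
    NoteEvidenceSeries,
    chroma_of,
    subband_loudness,
)

SERIES_NAMES = ("total", "b1", "b2", "b3", "b4", "b5", "b6")

#: Registry of the 47 beat-level feature names, in fixed column order.
BEAT_FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"onset_growth_{s}" for s in SERIES_NAMES)
    + ("event_position", "event_length", "event_skewness")
    + tuple(
        f"{s}_{stat}" for s in SERIES_NAMES for stat in ("mean", "sd", "centroid")
    )
    + (
        "note_onset_pos",
        "note1_freq",
        "note1_chroma",
        "note1_salience",
        "note2_freq",
        "note2_chroma",
        "note2_salience",
        "note3_freq",
        "note3_chroma",
        "note3_salience",
    )
    + (
        "sim_onset_growth",
        "sim_band_mean",
        "sim_band_sd",
        "sim_band_centroid",
        "sim_note_freq",
        "sim_chroma_freq",
    )
)
assert len(BEAT_FEATURE_NAMES) == 47

#: Onset search window half-width around the nominal beat time (s).
ONSET_WINDOW_S = 0.070
#: Relative salience floor below which a note is "not found" in an IBI.
SALIENCE_REL_FLOOR = 0.55


@dataclass
class BeatGrid:
    """Beat times plus tempo and the 2x/3x comb-resonance outputs."""

    beat_times: np.ndarray
    tempo: float
    oscillator_2x: float
    oscillator_3x: float

    @property
    def ibi(self) -> float:
        return 60.0 / self.tempo

    def __len__(self) -> int:
        return len(self.beat_times)


@dataclass
class BeatFeatureMatrix:
    """Per-beat table of the 47 named beat-level features."""

    values: np.ndarray  # (n_beats, 47)
    names: tuple[str, ...]
    grid: BeatGrid

    def __post_init__(self) -> None:
        if self.values.shape[1] != 47 or len(self.names) != 47:
            raise ValueError("beat feature matrix must have exactly 47 columns")

    def pattern(self, name: str) -> np.ndarray:
        """The per-beat sequence ('feature pattern') of one feature."""
        return self.values[:, self.names.index(name)]


def default_beat_count(duration: float, tempo: float) -> int:
    """Number of complete inter-beat intervals strictly inside the clip.

    For the study's standard 30 s / 130 BPM stimulus this is 64.
    """
    ibi = 60.0 / tempo
    return int(np.floor(duration / ibi - 1e-9))


def onset_strength(loudness: LoudnessSeries) -> np.ndarray:
    """Half-wave rectified forward difference of the total loudness."""
    total = loudness.loudness[:, 0]
    env = np.maximum(np.diff(total, prepend=total[:1]), 0.0)
    return env


def track_beats(
    clip: AudioClip,
    nominal_tempo: float,
    loudness: LoudnessSeries | None = None,
) -> BeatGrid:
    """Fit the phase of a rigid beat grid at the nominal tempo.

    The grid phase (within one inter-beat interval) is chosen to maximize
    the summed onset strength at the grid points.  A clip with no energy
    yields a grid anchored at t=0 and zero oscillator outputs.
    """
    if loudness is None:
        loudness = subband_loudness(clip)
    env = onset_strength(loudness)
    times = loudness.frame_times
    ibi = 60.0 / nominal_tempo
    n_beats = default_beat_count(clip.duration, nominal_tempo)

    def env_at(t: np.ndarray) -> np.ndarray:
        return np.interp(t, times, env)

    if env.max() <= 0.0:
        beat_times = np.arange(n_beats) * ibi
        return BeatGrid(beat_times, nominal_tempo, 0.0, 0.0)

    phase_step = 0.001  # 1 ms phase resolution
    # centered range: a grid locking slightly before t=0 stays near 0
    # instead of wrapping a whole beat forward
    phases = np.arange(-ibi / 2, ibi / 2, phase_step)
    scores = np.array(
        [env_at(phi + np.arange(n_beats) * ibi).sum() for phi in phases]
    )
    phase = phases[int(np.argmax(scores))]
    beat_times = phase + np.arange(n_beats) * ibi

    peak = env.max()
    osc = {}
    for m in (2, 3):
        offsets = [(j * ibi / m) for j in range(1, m)]
        vals = [env_at(beat_times + off) for off in offsets]
        osc[m] = float(np.mean(vals) / peak)
    return BeatGrid(beat_times, nominal_tempo, osc[2], osc[3])


def _frames_in(times: np.ndarray, start: float, stop: float) -> np.ndarray:
    return np.flatnonzero((times >= start - 1e-12) & (times < stop - 1e-12))


def beat_onset_features(
    loudness: LoudnessSeries, grid: BeatGrid, window: float = ONSET_WINDOW_S
) -> np.ndarray:
    """Max forward loudness difference in a +/-window around each beat; (n, 7)."""
    out = np.zeros((len(grid), 7))
    diffs = np.diff(loudness.loudness, axis=0)
    dtimes = loudness.frame_times[1:]
    for b, t in enumerate(grid.beat_times):
        idx = np.flatnonzero((dtimes >= t - window) & (dtimes <= t + window))
        if idx.size:
            out[b] = np.maximum(diffs[idx].max(axis=0), 0.0)
    return out


def beat_event_features(
    loudness: LoudnessSeries, grid: BeatGrid, window: float = ONSET_WINDOW_S
) -> np.ndarray:
    """Onset position, event length, event skewness per beat; (n, 3).

    The beat event is the contiguous run of total-loudness frames around
    the onset peak that stay above half the peak value.  Skewness is the
    third standardized moment of the loudness samples in that run; beats
    with no event above threshold report zeros.
    """
    total = loudness.loudness[:, 0]
    times = loudness.frame_times
    hop = loudness.hop
    out = np.zeros((len(grid), 3))
    for b, t in enumerate(grid.beat_times):
        t_next = t + grid.ibi
        win = np.flatnonzero((times >= t - window) & (times <= t + window))
        if win.size == 0 or total[win].max() <= 0.0:
            continue
        peak_i = win[int(np.argmax(total[win]))]
        peak_val = total[peak_i]
        out[b, 0] = times[peak_i] - t
        # expand around the peak while above half the peak, inside the IBI
        half = 0.5 * peak_val
        span = np.flatnonzero((times >= t - window) & (times < t_next))
        lo = hi = int(np.searchsorted(span, peak_i))
        while lo > 0 and total[span[lo - 1]] >= half:
            lo -= 1
        while hi < span.size - 1 and total[span[hi + 1]] >= half:
            hi += 1
        event = total[span[lo : hi + 1]]
        out[b, 1] = len(event) * hop
        if len(event) >= 3 and np.ptp(event) > 0:
            out[b, 2] = _skew(event)
    return out


def beat_period_features(loudness: LoudnessSeries, grid: BeatGrid) -> np.ndarray:
    """Mean, sd and temporal centroid of each loudness series per IBI; (n, 21).

    The centroid is the loudness-weighted mean of the normalized frame
    position in [0, 1] within the inter-beat interval; a uniform pattern
    gives 0.5, and an all-zero interval reports the neutral 0.5.
    """
    times = loudness.frame_times
    out = np.zeros((len(grid), 21))
    for b, t in enumerate(grid.beat_times):
        idx = _frames_in(times, t, t + grid.ibi)
        if idx.size == 0:
            out[b, 2::3] = 0.5
            continue
        block = loudness.loudness[idx]  # (m, 7)
        if idx.size > 1:
            tau = (times[idx] - times[idx[0]]) / (times[idx[-1]] - times[idx[0]])
        else:
            tau = np.array([0.5])
        for s in range(7):
            col = block[:, s]
            mass = col.sum()
            out[b, 3 * s] = col.mean()
            out[b, 3 * s + 1] = col.std()
            out[b, 3 * s + 2] = (tau @ col) / mass if mass > 0 else 0.5
    return out


def beat_pitch_features(
    evidence: NoteEvidenceSeries,
    grid: BeatGrid,
    rel_floor: float = SALIENCE_REL_FLOOR,
) -> np.ndarray:
    """Top-3 note descriptors per IBI; (n, 10).

    Notes are ranked by within-IBI mean salience; notes below
    ``rel_floor`` times the top salience count as not found and their
    frequency/chroma/salience slots are zero-filled.  Ties are broken in
    favor of the lower frequency.  Column 0 is the onset position (s,
    relative to the beat) of the most salient note, defined as the first
    frame where its salience reaches half its within-IBI maximum.
    """
    times = evidence.frame_times
    gridf = evidence.note_grid
    out = np.zeros((len(grid), 10))
    for b, t in enumerate(grid.beat_times):
        idx = _frames_in(times, t, t + grid.ibi)
        if idx.size == 0:
            continue
        block = evidence.evidence[idx]  # (m, 52)
        mean_sal = block.mean(axis=0)
        top = mean_sal.max()
        if top <= 0:
            continue
        found = np.flatnonzero(mean_sal >= rel_floor * top)
        # sort by salience desc, frequency asc on ties
        order = found[np.lexsort((gridf[found], -mean_sal[found]))]
        best = order[0]
        series = block[:, best]
        onset_i = int(np.argmax(series >= 0.5 * series.max()))
        out[b, 0] = times[idx[onset_i]] - t
        for slot, note in enumerate(order[:3]):
            f = gridf[note]
            out[b, 1 + 3 * slot] = f
            out[b, 2 + 3 * slot] = chroma_of(f)
            out[b, 3 + 3 * slot] = mean_sal[note]
    return out


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _fold_to_octave(freq: np.ndarray) -> np.ndarray:
    """Map frequencies onto one chromatic octave anchored at A4 (440 Hz)."""
    out = np.zeros_like(freq, dtype=float)
    pos = freq > 0
    out[pos] = 440.0 * 2.0 ** (chroma_of(freq[pos]) / 12.0)
    return out


def beat_similarity_features(
    onset: np.ndarray, period: np.ndarray, pitch: np.ndarray
) -> np.ndarray:
    """Six cosine similarities between consecutive beats; (n, 6).

    Compared sub-vectors: subband onset growths, subband means, subband
    sds, subband centroids, top-3 note frequencies, and the same
    frequencies folded onto the chromatic octave.  The first beat copies
    the second beat's values so the matrix stays rectangular.
    """
    n = onset.shape[0]
    if n < 2:
        raise ValueError("similarity features require at least 2 beats")
    out = np.zeros((n, 6))
    band_means = period[:, [3 * s for s in range(1, 7)]]
    band_sds = period[:, [3 * s + 1 for s in range(1, 7)]]
    band_cents = period[:, [3 * s + 2 for s in range(1, 7)]]
    note_freqs = pitch[:, [1, 4, 7]]
    chroma_freqs = _fold_to_octave(note_freqs)
    for b in range(1, n):
        out[b, 0] = _cosine(onset[b - 1, 1:], onset[b, 1:])
        out[b, 1] = _cosine(band_means[b - 1], band_means[b])
        out[b, 2] = _cosine(band_sds[b - 1], band_sds[b])
        out[b, 3] = _cosine(band_cents[b - 1], band_cents[b])
        out[b, 4] = _cosine(note_freqs[b - 1], note_freqs[b])
        out[b, 5] = _cosine(chroma_freqs[b - 1], chroma_freqs[b])
    out[0] = out[1]
    return out


def beat_feature_matrix(
    loudness: LoudnessSeries, evidence: NoteEvidenceSeries, grid: BeatGrid
) -> BeatFeatureMatrix:
    """Assemble the full (n_beats, 47) beat-level feature matrix."""
    onset = beat_onset_features(loudness, grid)
    event = beat_event_features(loudness, grid)
    period = beat_period_features(loudness, grid)
    pitch = beat_pitch_features(evidence, grid)
    sim = beat_similarity_features(onset, period, pitch)
    values = np.concatenate([onset, event, period, pitch, sim], axis=1)
    return BeatFeatureMatrix(values=values, names=BEAT_FEATURE_NAMES, grid=grid)
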