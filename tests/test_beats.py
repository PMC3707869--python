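"""Beat tracking and the 47 beat-level features."""

import numpy as np
import pytest

import beatwalk as bw
from beatwalk.beats import (
    BEAT_FEATURE_NAMES,
    BeatGrid,
    beat_event_features,
    beat_feature_matrix,
    beat_period_features,
    beat_pitch_features,
    beat_similarity_features,
    default_beat_count,
)
from beatwalk.frames import LoudnessSeries, note_evidence, subband_loudness


def _uniform_loudness(value=1.0, duration=5.0, hop=0.005):
    times = np.arange(0.015, duration, hop)
    return LoudnessSeries(
        frame_times=times, loudness=np.full((len(times), 7), value), hop=hop
    )


def _grid(n_beats=8, tempo=120.0):
    return BeatGrid(np.arange(n_beats) * 60.0 / tempo + 0.1, tempo, 0.0, 0.0)


class TestTrackBeats:
    def test_recovers_metronome_ticks_within_10ms(self, metronome_clip):
        grid = bw.track_beats(metronome_clip, 130.0)
        true = np.array(metronome_clip.annotation["beat_times"])
        assert len(grid) == 64
        assert np.abs(grid.beat_times - true).max() < 0.010

    def test_standard_convention_is_64_beats(self):
        assert default_beat_count(30.0, 130.0) == 64

    def test_silent_clip_gives_zero_oscillators(self):
        clip = bw.AudioClip(samples=np.zeros(22050 * 2), sample_rate=22050)
        grid = bw.track_beats(clip, 130.0)
        assert grid.oscillator_2x == 0.0 and grid.oscillator_3x == 0.0
        assert grid.beat_times[0] == 0.0

    @pytest.mark.parametrize("subdiv,closer", [(2, "2x"), (3, "3x")])
    def test_subdivided_beats_excite_matching_oscillator(self, subdiv, closer):
        clip, _ = bw.make_modulated_stimulus(
            bw.StimulusSpec(subdivisions=subdiv, seed=3)
        )
        grid = bw.track_beats(clip, 130.0)
        if closer == "2x":
            assert grid.oscillator_2x > grid.oscillator_3x
        else:
            assert grid.oscillator_3x > grid.oscillator_2x


class TestOnsetAndEventFeatures:
    def test_silence_gives_zero_growth(self):
        loud = _uniform_loudness(0.0)
        out = bw.beats.beat_onset_features(loud, _grid())
        assert np.all(out == 0.0)

    def test_broadband_tick_gives_positive_growth(self, metronome_clip,
                                                  metronome_loudness):
        grid = bw.track_beats(metronome_clip, 130.0, loudness=metronome_loudness)
        out = bw.beats.beat_onset_features(metronome_loudness, grid)
        assert out.shape == (64, 7)
        # beat 0 sits at the clip edge where the rise precedes the first
        # frame; every interior tick must show positive total growth
        assert np.all(out[1:, 0] > 0.0)

    def test_delayed_tick_shifts_event_position(self):
        # loudness bump 30 ms after the nominal beat time
        hop = 0.005
        times = np.arange(0.0, 4.0, hop)
        total = np.zeros(len(times))
        grid = _grid(n_beats=6, tempo=120.0)
        for t in grid.beat_times:
            total += np.exp(-0.5 * ((times - (t + 0.030)) / 0.008) ** 2)
        loud = LoudnessSeries(
            frame_times=times, loudness=np.tile(total[:, None], (1, 7)), hop=hop
        )
        out = beat_event_features(loud, grid)
        np.testing.assert_allclose(out[:, 0], 0.030, atol=0.006)

    def test_event_length_monotone_in_sustain(self):
        hop = 0.005
        times = np.arange(0.0, 4.0, hop)
        grid = _grid(n_beats=6, tempo=120.0)
        lengths = []
        for sustain in (0.05, 0.15, 0.30):
            total = np.zeros(len(times))
            for t in grid.beat_times:
                total += ((times >= t) & (times < t + sustain)).astype(float)
            loud = LoudnessSeries(
                frame_times=times, loudness=np.tile(total[:, None], (1, 7)), hop=hop
            )
            lengths.append(beat_event_features(loud, grid)[2, 1])
        assert lengths[0] < lengths[1] < lengths[2]

    def test_symmetric_event_has_zero_skewness(self):
        hop = 0.005
        times = np.arange(0.0, 4.0, hop)
        grid = _grid(n_beats=6, tempo=120.0)
        total = np.zeros(len(times))
        for t in grid.beat_times:
            total += np.maximum(0.0, 1.0 - np.abs(times - t - 0.05) / 0.05)
        loud = LoudnessSeries(
            frame_times=times, loudness=np.tile(total[:, None], (1, 7)), hop=hop
        )
        out = beat_event_features(loud, grid)
        np.testing.assert_allclose(out[2, 2], 0.0, atol=0.15)


class TestPeriodFeatures:
    def test_constant_loudness_sd_zero_centroid_half(self):
        out = beat_period_features(_uniform_loudness(2.0), _grid())
        means, sds, cents = out[:, 0::3], out[:, 1::3], out[:, 2::3]
        np.testing.assert_allclose(means, 2.0)
        np.testing.assert_allclose(sds, 0.0, atol=1e-12)
        np.testing.assert_allclose(cents, 0.5, atol=1e-12)

    def test_front_loaded_loudness_pulls_centroid_early(self):
        hop = 0.005
        times = np.arange(0.0, 5.0, hop)
        grid = _grid()
        ibi = grid.ibi
        vals = np.zeros((len(times), 7))
        for t in grid.beat_times:
            first_half = (times >= t) & (times < t + ibi / 2)
            vals[first_half] = 1.0
        loud = LoudnessSeries(frame_times=times, loudness=vals, hop=hop)
        out = beat_period_features(loud, grid)
        assert np.all(out[:-1, 2] < 0.5)

    def test_count_is_21(self):
        assert beat_period_features(_uniform_loudness(), _grid()).shape[1] == 21


class TestPitchFeatures:
    def test_single_note_fills_only_first_slot(self, tone_clip_440):
        ev = note_evidence(tone_clip_440)
        grid = BeatGrid(np.arange(4) * 0.46 + 0.1, 130.0, 0.0, 0.0)
        out = beat_pitch_features(ev, grid)
        assert out.shape == (4, 10)
        np.testing.assert_allclose(out[:, 1], 440.0, rtol=1e-6)  # note1 freq
        assert np.all(out[:, 2] == 0)  # chroma A
        assert np.all(out[:, 3] > 0)  # note1 salience
        assert np.all(out[:, 7] == 0.0) and np.all(out[:, 9] == 0.0)  # no 3rd note

    def test_equal_salience_ties_broken_low_frequency_first(self):
        from beatwalk.frames import NoteEvidenceSeries, note_grid

        g = note_grid()
        times = np.arange(0.0, 2.0, 0.02)
        evid = np.zeros((len(times), 52))
        evid[:, [5, 15, 25]] = 1.0  # three exactly equal notes
        series = NoteEvidenceSeries(frame_times=times, evidence=evid, note_grid=g)
        grid = BeatGrid(np.array([0.0, 0.5, 1.0, 1.5]), 120.0, 0.0, 0.0)
        out = beat_pitch_features(series, grid)
        np.testing.assert_allclose(out[:, 1], g[5])
        np.testing.assert_allclose(out[:, 4], g[15])
        np.testing.assert_allclose(out[:, 7], g[25])

    def test_silence_gives_all_zero(self):
        from beatwalk.frames import NoteEvidenceSeries, note_grid

        times = np.arange(0.0, 2.0, 0.02)
        series = NoteEvidenceSeries(
            frame_times=times, evidence=np.zeros((len(times), 52)),
            note_grid=note_grid(),
        )
        out = beat_pitch_features(series, _grid(n_beats=3))
        assert np.all(out == 0.0)


class TestSimilarityFeatures:
    def test_identical_beats_give_unit_similarity(self):
        onset = np.tile(np.arange(1.0, 8.0), (5, 1))
        period = np.tile(np.arange(1.0, 22.0), (5, 1))
        pitch = np.tile(np.linspace(100, 1000, 10), (5, 1))
        out = beat_similarity_features(onset, period, pitch)
        np.testing.assert_allclose(out, 1.0, atol=1e-12)

    def test_zero_vectors_give_zero_similarity(self):
        out = beat_similarity_features(
            np.zeros((3, 7)), np.zeros((3, 21)), np.zeros((3, 10))
        )
        assert np.all(out == 0.0)

    def test_alternating_beats_alternate_similarity(self):
        # subband growth direction flips every beat -> sim_onset alternates
        n = 8
        onset = np.zeros((n, 7))
        onset[0::2, 1:4] = 1.0
        onset[1::2, 4:7] = 1.0
        out = beat_similarity_features(
            onset, np.ones((n, 21)), np.ones((n, 10))
        )
        sims = out[1:, 0]
        assert np.all(sims == pytest.approx([0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]))
        # contrast: identical consecutive beats would give 1, so the
        # alternation is visible against the constant columns
        assert np.all(out[1:, 1] == 1.0)

    def test_first_beat_copies_second(self):
        rng = np.random.default_rng(0)
        out = beat_similarity_features(
            rng.random((4, 7)), rng.random((4, 21)), rng.random((4, 10))
        )
        np.testing.assert_array_equal(out[0], out[1])


class TestBeatFeatureMatrix:
    def test_registry_has_47_named_columns(self):
        assert len(BEAT_FEATURE_NAMES) == 47
        assert len(set(BEAT_FEATURE_NAMES)) == 47

    def test_matrix_invariants_on_real_stimulus(self, clip_p3):
        clip, _ = clip_p3
        loud = subband_loudness(clip)
        notes = note_evidence(clip)
        grid = bw.track_beats(clip, 130.0, loudness=loud)
        m = beat_feature_matrix(loud, notes, grid)
        assert m.values.shape == (64, 47)
        sims = m.values[:, 41:47]
        assert np.all(sims >= -1.0) and np.all(sims <= 1.0)
        # loudness statistics are non-negative
        assert np.all(m.values[:, 10:31] >= 0.0)
        # chroma columns (note1/2/3 pitch class) in 0..11
        chroma_cols = m.values[:, [33, 36, 39]]
        assert np.all((chroma_cols >= 0) & (chroma_cols <= 11))

    def test_unmodulated_stimulus_rows_nearly_identical(self):
        # identical beats; residual spread is frame-grid quantization only
        # (the 5/20 ms frame hops are incommensurate with the 461.5 ms IBI)
        clip, _ = bw.make_modulated_stimulus(bw.StimulusSpec(mod_depth=0.0, seed=5))
        loud = subband_loudness(clip)
        notes = note_evidence(clip)
        grid = bw.track_beats(clip, 130.0, loudness=loud)
        m = beat_feature_matrix(loud, notes, grid)
        mid = m.values[4:-4]
        idx = {n: i for i, n in enumerate(BEAT_FEATURE_NAMES)}
        # consecutive identical beats: all six similarities ~1
        assert m.values[4:-4, 41:47].min() > 0.995
        # note identities are bit-stable
        freq_cols = [idx[f"note{k}_freq"] for k in (1, 2, 3)]
        assert np.all(np.ptp(mid[:, freq_cols], axis=0) == 0.0)
        # loudness statistics within quantization tolerance
        series = ("total", "b1", "b2", "b3", "b4", "b5", "b6")
        means = mid[:, [idx[f"{s}_mean"] for s in series]]
        assert (np.ptp(means, axis=0) / means.max(axis=0)).max() < 0.15
        cents = mid[:, [idx[f"{s}_centroid"] for s in series]]
        assert np.ptp(cents, axis=0).max() < 0.08
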