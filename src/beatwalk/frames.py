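"""Frame-level audio analysis.

Two analyses run over the waveform:

* **Subband loudness** — 30 ms Hann-windowed frames hopped every 5 ms are
  decomposed by six triangular band filters (center frequencies ~118, 298,
  570, 983, 1609 and 2559 Hz) applied to the magnitude-squared spectrum.
  Loudness is defined as band energy raised to the power 0.25; a seventh
  "total" series is the fourth root of the summed band energies.

* **Note evidence** — 150 ms frames hopped every 20 ms yield, per frame, a
  salience for each of the 52 equal-tempered note frequencies between
  0.1 and 2 kHz.  Salience is a harmonic sum: spectral magnitude at the
  fundamental plus half the magnitude at harmonics 2 and 3, each taken as
  the maximum within +/- one quarter-tone of the target frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import EmptySeriesError
from .audio import AudioClip

#: Triangular filter center frequencies (Hz) for the six subbands.
BAND_CENTERS = (118.0, 298.0, 570.0, 983.0, 1609.0, 2559.0)

LOUDNESS_FRAME_S = 0.030
LOUDNESS_HOP_S = 0.005
NOTE_FRAME_S = 0.150
NOTE_HOP_S = 0.020

#: Harmonic weights for the salience sum (fundamental, 2nd, 3rd harmonic).
HARMONIC_WEIGHTS = (1.0, 0.5, 0.5)

QUARTER_TONE = 2.0 ** (1.0 / 24.0)


@dataclass
class LoudnessSeries:
    """Per-frame loudness: column 0 = total, columns 1..6 = subbands.

    Frame times refer to window *centers*, so a loudness value is located
    at the instant its Hann-weighted energy is concentrated on.
    """

    frame_times: np.ndarray  # seconds (window centers), 5 ms hop
    loudness: np.ndarray  # (n_frames, 7), units energy**0.25
    hop: float = LOUDNESS_HOP_S

    def __len__(self) -> int:
        return len(self.frame_times)


@dataclass
class NoteEvidenceSeries:
    """Per-frame pitch saliences aligned to the 52-note grid."""

    frame_times: np.ndarray  # seconds (window centers), 20 ms hop
    evidence: np.ndarray  # (n_frames, 52)
    note_grid: np.ndarray  # 52 frequencies in Hz
    hop: float = NOTE_HOP_S

    def __len__(self) -> int:
        return len(self.frame_times)


@lru_cache(maxsize=1)
def note_grid() -> np.ndarray:
    """The 52 equal-tempered note frequencies strictly inside (100, 2000) Hz.

    Frequencies are 440 * 2**(k/12) for the integers k whose frequency
    falls in the open interval; relative to A4 = 440 Hz that is
    k = -25..26, i.e. ~103.83 Hz up to ~1975.53 Hz.
    """
    k = np.arange(-60, 61)
    freqs = 440.0 * 2.0 ** (k / 12.0)
    grid = freqs[(freqs > 100.0) & (freqs < 2000.0)]
    return np.ascontiguousarray(grid)


def chroma_of(freq: float | np.ndarray) -> np.ndarray:
    """Pitch class 0..11 (0 = A) of a frequency; vectorized."""
    freq = np.asarray(freq, dtype=float)
    with np.errstate(divide="ignore"):
        cls = np.round(12.0 * np.log2(np.where(freq > 0, freq, 1.0) / 440.0))
    return (cls.astype(int)) % 12


def _frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    """Stack overlapping frames (n_frames, frame_len); at least one frame."""
    n = (len(x) - frame_len) // hop + 1
    if n < 1:
        raise EmptySeriesError(
            f"signal of {len(x)} samples shorter than one {frame_len}-sample frame"
        )
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


def _triangular_weights(freqs: np.ndarray) -> np.ndarray:
    """(6, n_bins) triangular filter bank over FFT bin frequencies.

    Vertices sit at the neighboring band centers; the outer edges are
    extended geometrically by the mean adjacent center ratio so the bank
    covers the band gaplessly.
    """
    centers = np.asarray(BAND_CENTERS)
    ratio = (centers[-1] / centers[0]) ** (1.0 / (len(centers) - 1))
    edges = np.concatenate([[centers[0] / ratio], centers, [centers[-1] * ratio]])
    weights = np.zeros((len(centers), len(freqs)))
    for b in range(len(centers)):
        lo, mid, hi = edges[b], edges[b + 1], edges[b + 2]
        rising = (freqs >= lo) & (freqs <= mid)
        falling = (freqs > mid) & (freqs <= hi)
        weights[b, rising] = (freqs[rising] - lo) / (mid - lo)
        weights[b, falling] = (hi - freqs[falling]) / (hi - mid)
    return weights


def subband_loudness(clip: AudioClip) -> LoudnessSeries:
    """Total + six subband loudness series on 30 ms / 5 ms frames.

    Loudness is band energy ** 0.25, so scaling the waveform by ``a``
    scales every loudness value by ``sqrt(a)``.
    """
    sr = clip.sample_rate
    frame_len = int(round(LOUDNESS_FRAME_S * sr))
    hop = max(1, int(round(LOUDNESS_HOP_S * sr)))
    frames = _frame_signal(clip.samples, frame_len, hop)
    window = np.hanning(frame_len)
    n_fft = int(2 ** np.ceil(np.log2(frame_len)))
    spectrum = np.fft.rfft(frames * window, n=n_fft, axis=1)
    # amplitude calibration: a unit-amplitude sine reads ~1 at its bin
    power = np.abs(spectrum * (2.0 / window.sum())) ** 2
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sr)
    weights = _triangular_weights(freqs)
    band_energy = power @ weights.T  # (n_frames, 6)
    total_energy = band_energy.sum(axis=1, keepdims=True)
    loudness = np.concatenate([total_energy, band_energy], axis=1) ** 0.25
    times = (np.arange(len(frames)) * hop + frame_len / 2) / sr
    return LoudnessSeries(frame_times=times, loudness=loudness, hop=hop / sr)


def note_evidence(clip: AudioClip) -> NoteEvidenceSeries:
    """Saliences for the 52-note grid on 150 ms / 20 ms frames."""
    sr = clip.sample_rate
    frame_len = int(round(NOTE_FRAME_S * sr))
    hop = max(1, int(round(NOTE_HOP_S * sr)))
    frames = _frame_signal(clip.samples, frame_len, hop)
    window = np.hanning(frame_len)
    n_fft = int(2 ** np.ceil(np.log2(frame_len)))
    mag = np.abs(np.fft.rfft(frames * window, n=n_fft, axis=1)) * (2.0 / window.sum())
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sr)
    grid = note_grid()
    evidence = np.zeros((len(frames), len(grid)))
    nyquist = freqs[-1]
    for j, f0 in enumerate(grid):
        for h, w in zip((1, 2, 3), HARMONIC_WEIGHTS):
            target = h * f0
            if target / QUARTER_TONE > nyquist:
                break
            lo = np.searchsorted(freqs, target / QUARTER_TONE)
            hi = np.searchsorted(freqs, target * QUARTER_TONE, side="right")
            if hi > lo:
                evidence[:, j] += w * mag[:, lo:hi].max(axis=1)
    times = (np.arange(len(frames)) * hop + frame_len / 2) / sr
    return NoteEvidenceSeries(
        frame_times=times, evidence=evidence, note_grid=grid, hop=hop / sr
    )
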