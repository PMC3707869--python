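"""Audio container and WAV I/O.

The pipeline operates on mono floating-point waveforms.  Stereo input is
mixed down by channel averaging, since every sonic-feature definition is
single-channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile


@dataclass
class AudioClip:
    """A sampled waveform plus metadata.

    Parameters
    ----------
    samples
        1-D float array of amplitudes (mono).
    sample_rate
        Sampling frequency in Hz.
    nominal_tempo
        Optional nominal tempo of the stimulus in BPM (study stimuli are
        all 130 BPM by design).
    """

    samples: np.ndarray
    sample_rate: int
    nominal_tempo: float | None = None
    annotation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim == 2:  # stereo -> mono
            samples = samples.mean(axis=1)
        if samples.ndim != 1:
            raise ValueError("samples must be 1-D (mono) or 2-D (frames x channels)")
        self.samples = samples

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


def read_wav(path) -> AudioClip:
    """Read a WAV file into a mono float64 :class:`AudioClip`.

    Integer PCM is rescaled to [-1, 1); float WAVs are taken as-is.
    """
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return AudioClip(samples=data, sample_rate=int(rate))


def write_wav(path, clip: AudioClip, subtype: str = "float32") -> None:
    """Write a clip to WAV as float32 (default) or 16-bit PCM."""
    if subtype == "float32":
        wavfile.write(path, clip.sample_rate, clip.samples.astype(np.float32))
    elif subtype == "pcm16":
        scaled = np.clip(clip.samples, -1.0, 1.0)
        wavfile.write(path, clip.sample_rate, (scaled * 32767).astype(np.int16))
    else:
        raise ValueError(f"unsupported WAV subtype: {subtype!r}")
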