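"""Gait metrics from wearable-sensor streams.

Walking speed comes from the hip sensor's heading angle (relative to
magnetic north): on a circular path of radius r the walked distance is
d = |theta_end - theta_start| * r on the *unwrapped* heading, and speed is
d divided by the trial duration.  Walking tempo comes from the foot
acceleration norm: the cadence peak of a zero-padded DFT with 0.5
strides/min bin resolution, doubled because one foot strikes once per
stride (two steps).  Trials are classed as synchronized / double / half /
other by comparing walking tempo against the stimulus tempo, and only
synchronized trials enter the per-song speed table, normalized so each
participant's mean metronome speed is 100 units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoPeakError, UnusableTrialError

#: Plausible stride-rate band (strides per minute) searched for the cadence peak.
STRIDE_BAND = (30.0, 120.0)
#: DFT bin resolution in strides per minute.
DFT_RESOLUTION_SPM = 0.5
#: Default synchronization tolerance in steps per minute.
SYNC_TOL_SPM = 2.0


@dataclass
class TrialRecord:
    """One participant x stimulus sensor recording (50 Hz streams)."""

    participant_id: str
    stimulus_id: str
    stimulus_kind: str  # "song" | "metronome"
    time_s: np.ndarray
    heading: np.ndarray  # radians vs magnetic north, wrapped to [0, 2*pi)
    foot_acc: np.ndarray  # (n, 3) m/s^2
    sample_rate: float = 50.0
    ground_truth: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        """Recorded time span (first to last sample) in seconds."""
        return float(self.time_s[-1] - self.time_s[0])


@dataclass
class GaitResult:
    """Derived per-trial gait quantities."""

    distance: float  # m
    speed: float  # m/s
    tempo: float | None  # steps per minute; None if no cadence peak
    sync_class: str  # sync | double | half | other


def walking_speed(
    heading: np.ndarray,
    radius: float,
    duration: float,
    time_s: np.ndarray | None = None,
) -> tuple[float, float]:
    """Distance and speed from the hip heading angle on a circular path.

    The heading is unwrapped before applying d = |dtheta| * r, so
    multi-lap walks are measured correctly.  Gaps longer than 1 s in the
    time stamps make the trial unusable.
    """
    if duration <= 0 or radius <= 0:
        raise ValueError("duration and radius must be positive")
    heading = np.asarray(heading, dtype=float)
    if time_s is not None and len(time_s) > 1:
        if np.max(np.diff(time_s)) > 1.0:
            raise UnusableTrialError("heading stream has a gap longer than 1 s")
    theta = np.unwrap(heading)
    distance = abs(theta[-1] - theta[0]) * radius
    return distance, distance / duration


def walking_tempo(
    foot_acc: np.ndarray,
    sample_rate: float,
    stride_band: tuple[float, float] = STRIDE_BAND,
) -> float:
    """Cadence in steps per minute from the foot acceleration norm.

    The acceleration norm is de-meaned and zero-padded so the DFT bin
    width equals 0.5 strides/min; the spectral peak inside the plausible
    stride band is doubled to convert strides to steps.
    """
    acc = np.asarray(foot_acc, dtype=float)
    if acc.ndim == 2:
        signal = np.linalg.norm(acc, axis=1)
    else:
        signal = acc
    if len(signal) < 10 * sample_rate:
        raise NoPeakError("need at least 10 s of acceleration signal")
    signal = signal - signal.mean()
    if not np.any(np.abs(signal) > 1e-12):
        raise NoPeakError("flat acceleration signal has no cadence peak")
    # bin width (Hz) = DFT_RESOLUTION_SPM / 60  ->  n = fs * 120 at 0.5 SPM
    n_fft = int(round(sample_rate * 60.0 / DFT_RESOLUTION_SPM))
    while n_fft < len(signal):
        n_fft *= 2
    mag = np.abs(np.fft.rfft(signal, n=n_fft))
    freqs_spm = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate) * 60.0
    band = (freqs_spm >= stride_band[0]) & (freqs_spm <= stride_band[1])
    if not band.any() or mag[band].max() <= 1e-12:
        raise NoPeakError("no spectral peak in the stride band")
    stride_rate = freqs_spm[band][int(np.argmax(mag[band]))]
    return 2.0 * stride_rate


def classify_sync(
    tempo_walk: float, tempo_stim: float, tol: float = SYNC_TOL_SPM
) -> str:
    """Classify a trial as sync / double / half / other (exactly one class)."""
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if abs(tempo_walk - tempo_stim) <= tol:
        return "sync"
    if abs(tempo_walk - 2.0 * tempo_stim) <= tol:
        return "double"
    if abs(tempo_walk - 0.5 * tempo_stim) <= tol:
        return "half"
    return "other"


def analyze_trial(
    record: TrialRecord, radius: float, tol: float = SYNC_TOL_SPM,
    stimulus_tempo: float = 130.0,
) -> GaitResult:
    """Full per-trial analysis: speed, cadence and synchronization class."""
    distance, speed = walking_speed(
        record.heading, radius, record.duration, time_s=record.time_s
    )
    try:
        tempo = walking_tempo(record.foot_acc, record.sample_rate)
        sync_class = classify_sync(tempo, stimulus_tempo, tol=tol)
    except NoPeakError:
        tempo, sync_class = None, "other"
    return GaitResult(distance=distance, speed=speed, tempo=tempo, sync_class=sync_class)


def normalize_speeds(
    trials: list[tuple[TrialRecord, GaitResult]],
    return_trials: bool = False,
):
    """Per-song mean normalized walking speeds (metronome baseline = 100).

    Only synchronized ("acceptable") trials contribute.  Per participant,
    every acceptable song-trial speed is divided by the participant's mean
    speed over acceptable metronome trials and scaled by 100; the song
    speed v_s is the mean of those normalized values over participants.
    Participants with no acceptable metronome trial are excluded with a
    warning.

    Returns a DataFrame indexed by song id with columns ``v_s`` and
    ``n_trials``; with ``return_trials=True`` also a per-trial DataFrame
    including the normalized metronome speeds.
    """
    rows = []
    for record, result in trials:
        rows.append(
            {
                "participant_id": record.participant_id,
                "stimulus_id": record.stimulus_id,
                "kind": record.stimulus_kind,
                "speed": result.speed,
                "sync_class": result.sync_class,
            }
        )
    df = pd.DataFrame(rows)
    acceptable = df[df["sync_class"] == "sync"].copy()
    normalized = []
    for pid, group in acceptable.groupby("participant_id"):
        metro = group[group["kind"] == "metronome"]
        if metro.empty or metro["speed"].mean() <= 0:
            warnings.warn(
                f"participant {pid!r} has no acceptable metronome trial; excluded",
                stacklevel=2,
            )
            continue
        factor = metro["speed"].mean()
        g = group.copy()
        g["normalized"] = 100.0 * g["speed"] / factor
        normalized.append(g)
    if normalized:
        norm_df = pd.concat(normalized, ignore_index=True)
    else:
        norm_df = pd.DataFrame(
            columns=[*df.columns, "normalized"]
        )
    songs = norm_df[norm_df["kind"] == "song"]
    table = songs.groupby("stimulus_id")["normalized"].agg(["mean", "size"])
    table.columns = ["v_s", "n_trials"]
    table.index.name = "song_id"
    if return_trials:
        return table, norm_df
    return table


def write_trial_csv(record: TrialRecord, path) -> None:
    """Write a trial's sensor streams as CSV (time_s, heading_rad, acc_x/y/z)."""
    df = pd.DataFrame(
        {
            "time_s": record.time_s,
            "heading_rad": record.heading,
            "acc_x": record.foot_acc[:, 0],
            "acc_y": record.foot_acc[:, 1],
            "acc_z": record.foot_acc[:, 2],
        }
    )
    df.to_csv(path, index=False)


def read_trial_csv(
    path,
    participant_id: str,
    stimulus_id: str,
    stimulus_kind: str,
    sample_rate: float = 50.0,
) -> TrialRecord:
    """Read a sensor-trace CSV written by :func:`write_trial_csv`."""
    df = pd.read_csv(path)
    return TrialRecord(
        participant_id=participant_id,
        stimulus_id=stimulus_id,
        stimulus_kind=stimulus_kind,
        time_s=df["time_s"].to_numpy(),
        heading=df["heading_rad"].to_numpy(),
        foot_acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(),
        sample_rate=sample_rate,
    )
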