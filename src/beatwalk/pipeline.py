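"""Run orchestration: configuration, stage functions, and the full pipeline.

Each stage is a plain function over a :class:`RunConfig`; the CLI module
is a thin wrapper around these.  Every output file records the config
hash and master seed for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gait, model, stats, synth
from .audio import read_wav, write_wav
from .songlevel import FEATURE_NAMES, REGISTRY, TABLE2_ALIASES, extract_song_features

log = logging.getLogger("beatwalk")

#: Playlist positions (1-based) of the metronome sequences in a 58-stimulus run.
METRONOME_POSITIONS = (1, 12, 23, 34, 45, 58)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; round-trips losslessly through YAML."""

    stimuli_dir: str = "stimuli"
    trials_dir: str = "trials"
    output_dir: str = "output"
    # study constants
    radius: float = 7.5  # m
    duration: float = 30.0  # s
    tempo: float = 130.0  # BPM
    audio_sample_rate: int = 22050
    sensor_sample_rate: float = 50.0
    sync_tol: float = 2.0  # SPM
    # synthetic cohort
    n_songs: int = 52
    n_participants: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("radius", "duration", "tempo", "audio_sample_rate",
                     "sensor_sample_rate", "sync_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config constant {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def provenance(self) -> dict:
        return {"config_hash": self.config_hash, "seed": self.seed}


def _timer(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s started", stage)
            return self

        def __exit__(self, *exc):
            log.info("stage %s finished in %.2f s", stage, time.perf_counter() - self.t0)

    return _T()


def run_simulate(config: RunConfig) -> dict:
    """Generate the synthetic cohort: stimuli WAVs, trial CSVs, ratings.

    Song stimuli get per-song metrical modulation settings and a latent
    "activation" effect on walking speed; metronome sequences occupy the
    study's fixed playlist positions.  Walking cadence equals the
    stimulus tempo (synchronized cohort) with a few detuned trials.
    """
    rng = np.random.default_rng(config.seed)
    stim_dir = Path(config.stimuli_dir)
    trial_dir = Path(config.trials_dir)
    out_dir = Path(config.output_dir)
    for d in (stim_dir, trial_dir, out_dir):
        d.mkdir(parents=True, exist_ok=True)

    song_ids = [f"s{i + 1:02d}" for i in range(config.n_songs)]
    periods = [None, 2, 3, 4, 6]
    with _timer("simulate-stimuli"):
        for i, sid in enumerate(song_ids):
            spec = synth.StimulusSpec(
                tempo=config.tempo,
                duration=config.duration,
                mod_period=periods[i % len(periods)],
                mod_depth=float(rng.uniform(0.2, 0.8)),
                notes_per_beat=int(rng.integers(1, 4)),
                sample_rate=config.audio_sample_rate,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            clip, annotation = synth.make_modulated_stimulus(spec)
            write_wav(stim_dir / f"{sid}.wav", clip)
            synth.write_annotation(annotation, stim_dir / f"{sid}.json")
        metro = synth.make_metronome(
            synth.StimulusSpec(
                tempo=config.tempo, duration=config.duration,
                sample_rate=config.audio_sample_rate,
            )
        )
        write_wav(stim_dir / "metronome.wav", metro)
        synth.write_annotation(metro.annotation, stim_dir / "metronome.json")

    # latent per-song speed effect (% of metronome baseline)
    song_effect = rng.normal(100.0, 5.0, size=config.n_songs)
    with _timer("simulate-trials"):
        manifest = []
        for p in range(config.n_participants):
            pid = f"p{p + 1:02d}"
            base_speed = float(rng.uniform(1.2, 1.6))
            n_metro = len(METRONOME_POSITIONS)
            total = config.n_songs + n_metro
            if total == 58:
                positions = METRONOME_POSITIONS
            else:  # scale the study layout to the playlist length
                positions = tuple(
                    sorted({max(1, round(p * total / 58)) for p in METRONOME_POSITIONS})
                )
            playlist = [f"m{k + 1}" for k in range(len(positions))]
            order = rng.permutation(config.n_songs)
            stimuli = []
            songs_iter = iter(order)
            m_i = 0
            for pos in range(1, total + 1):
                if m_i < len(positions) and pos == positions[m_i]:
                    stimuli.append((playlist[m_i], "metronome", 100.0))
                    m_i += 1
                else:
                    s = next(songs_iter)
                    stimuli.append((song_ids[s], "song", song_effect[s]))
            for stim_id, kind, effect in stimuli:
                cadence = config.tempo
                if rng.random() < 0.03:  # occasional non-synchronized trial
                    cadence = config.tempo * float(rng.choice([0.5, 2.0, 0.77]))
                speed = base_speed * effect / 100.0 * float(rng.normal(1.0, 0.01))
                spec = synth.WalkSpec(
                    speed=speed, cadence=cadence, radius=config.radius,
                    duration=config.duration,
                    sample_rate=config.sensor_sample_rate,
                    heading_noise_sd=0.005,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                record = synth.simulate_walk_trial(
                    spec, participant_id=pid, stimulus_id=stim_id,
                    stimulus_kind=kind,
                )
                path = trial_dir / f"{pid}_{stim_id}.csv"
                gait.write_trial_csv(record, path)
                manifest.append(
                    {"participant_id": pid, "stimulus_id": stim_id,
                     "kind": kind, "file": path.name}
                )
        pd.DataFrame(manifest).to_csv(trial_dir / "manifest.csv", index=False)

    groups_true = np.argsort(song_effect)
    ratings = synth.simulate_ratings(
        song_ids,
        activating=[song_ids[i] for i in groups_true[-10:]],
        relaxing=[song_ids[i] for i in groups_true[:10]],
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    ratings.to_csv(out_dir / "ratings.csv")
    return {"songs": song_ids, "provenance": config.provenance()}


def run_extract(config: RunConfig) -> pd.DataFrame:
    """Extract the 190 song features from every WAV in the stimuli dir."""
    stim_dir = Path(config.stimuli_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, index = [], []
    wavs = sorted(stim_dir.glob("*.wav"))
    if not wavs:
        log.warning("no WAV files found in %s", stim_dir)
    with _timer("extract"):
        for path in wavs:
            try:
                clip = read_wav(path)
            except Exception as exc:  # unreadable file: log and skip
                log.warning("skipping unreadable WAV %s: %s", path.name, exc)
                continue
            vec = extract_song_features(clip, nominal_tempo=config.tempo)
            rows.append(vec.values)
            index.append(path.stem)
    features = pd.DataFrame(rows, index=index, columns=list(FEATURE_NAMES))
    features.index.name = "stimulus_id"
    features.to_csv(out_dir / "features.csv")
    registry = [asdict(e) for e in REGISTRY]
    with open(out_dir / "feature_registry.json", "w") as fh:
        json.dump({"registry": registry, "aliases": TABLE2_ALIASES,
                   **config.provenance()}, fh, indent=2)
    return features


def run_gait(config: RunConfig) -> pd.DataFrame:
    """Per-trial gait analysis and the per-song normalized SpeedTable."""
    trial_dir = Path(config.trials_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(trial_dir / "manifest.csv")
    analyzed = []
    results_rows = []
    with _timer("gait"):
        for _, row in manifest.iterrows():
            path = trial_dir / row["file"]
            if not path.exists():
                log.warning("missing sensor file %s; trial excluded", path.name)
                continue
            record = gait.read_trial_csv(
                path, row["participant_id"], row["stimulus_id"], row["kind"],
                sample_rate=config.sensor_sample_rate,
            )
            result = gait.analyze_trial(
                record, radius=config.radius, tol=config.sync_tol,
                stimulus_tempo=config.tempo,
            )
            analyzed.append((record, result))
            results_rows.append(
                {"participant_id": record.participant_id,
                 "stimulus_id": record.stimulus_id, "kind": record.stimulus_kind,
                 "distance": result.distance, "speed": result.speed,
                 "tempo": result.tempo, "sync_class": result.sync_class}
            )
    pd.DataFrame(results_rows).to_csv(out_dir / "gait_results.csv", index=False)
    table = gait.normalize_speeds(analyzed)
    table.to_csv(out_dir / "speeds.csv")
    return table


def run_model(config: RunConfig, features: pd.DataFrame, speeds: pd.Series) -> dict:
    """Nested CV + final model on aligned song features and speeds."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    common = [s for s in speeds.index if s in features.index]
    X = features.loc[common]
    y = speeds.loc[common].to_numpy(dtype=float)
    with _timer("model"):
        report = model.nested_cv(X, y, seed=config.seed)
        final = model.final_model(X, y, report)
    payload = {
        "cv": report.to_dict(),
        "final_model": {
            "feature_ids": list(final.feature_ids),
            "coefficients": final.coefficients.tolist(),
            "intercept": final.intercept,
        },
        "songs": common,
        **config.provenance(),
    }
    with open(out_dir / "model_report.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    return payload


def run_stats(
    config: RunConfig,
    speeds: pd.Series | pd.DataFrame,
    features: pd.DataFrame | None = None,
    ratings: pd.DataFrame | None = None,
    feature_names: list | None = None,
) -> dict:
    """Group construction plus ANOVA / t-tests / Mann-Whitney comparisons."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups = stats.extreme_groups(speeds)
    report: dict = {
        "groups": {"activating": list(groups.activating),
                   "relaxing": list(groups.relaxing),
                   "neutral": list(groups.neutral)},
        "anova": stats.speed_anova(speeds, groups),
        **config.provenance(),
    }
    if features is not None:
        names = feature_names or [
            n for n in TABLE2_ALIASES.values() if n in features.columns
        ] or list(features.columns)
        tt = stats.feature_ttests(features, groups, feature_names=names)
        report["feature_ttests"] = tt.reset_index().to_dict(orient="records")
    else:
        report["feature_ttests"] = None
        log.info("no features provided; feature t-tests skipped")
    if ratings is not None:
        rt = stats.ratings_tests(ratings, groups)
        report["ratings_tests"] = rt.reset_index().to_dict(orient="records")
    else:
        report["ratings_tests"] = None
        log.info("no ratings provided; rating tests skipped")
    with open(out_dir / "stats_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


def run_all(config: RunConfig, simulate: bool = True) -> dict:
    """Full reproducible run: simulate -> extract -> gait -> model -> stats.

    The model stage needs at least 20 songs and is skipped with a notice
    below that.  Deterministic given the config seed.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if simulate:
        run_simulate(config)
    features = run_extract(config)
    table = run_gait(config)
    song_features = features.loc[[i for i in features.index if i in table.index]]
    speeds = table["v_s"]
    if len(speeds) >= 20:
        model_report = run_model(config, song_features, speeds)
    else:
        model_report = None
        log.info("fewer than 20 songs; model stage skipped")
    ratings_path = out_dir / "ratings.csv"
    ratings = (
        pd.read_csv(ratings_path, index_col="song_id")
        if ratings_path.exists()
        else None
    )
    try:
        stats_report = run_stats(config, table, features=song_features, ratings=ratings)
    except Exception as exc:
        stats_report = None
        log.info("stats stage skipped: %s", exc)
    report = {
        "model": model_report,
        "stats": stats_report,
        "n_songs": int(len(speeds)),
        **config.provenance(),
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
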