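"""End-to-end orchestration: simulate → preprocess → measure → analyse.

Stages are pure functions of (config, inputs); a fixed seed yields
byte-identical outputs. The on-disk layout of a run directory is::

    markers/P###.tsv      raw marker recordings (simulated or imported)
    timeline.csv          song spans on the session clock
    tempo.csv             per-song tempo (BPM)
    participants.csv      factors, musician flag, exclusion flags
    truth.csv             simulation ground truth (simulated runs only)
    measures.csv          long-format (participant, song, measure, value)
    anova_<measure>.csv   effect tables
    cell_means_<measure>.csv
    provenance.json       config hash, package version, row counts
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .entrainment import EntrainmentParams, TempoSpec, entrainment_for_trajectory, metrical_periods
from .kinematics import vigour_for_trajectories
from .mocap_io import (
    SessionTimeline,
    read_marker_tsv,
    read_participants_csv,
    read_tempo_csv,
    read_timeline_csv,
    write_marker_tsv,
    write_participants_csv,
    write_timeline_csv,
)
from .preprocess import POSITION_CUTOFF_HZ, TooShortError, preprocess_recording
from .stats import filter_cohort, mixed_anova, musician_ttests, song8_anova
from .synthetic import CohortSimSpec, participant_motion_specs, _participant_rows, make_timeline, simulate_participant_recording

logger = logging.getLogger("headsway")

__all__ = [
    "RunConfig",
    "measures_for_recording",
    "cohort_measures",
    "simulate_to_dir",
    "measure_dir",
    "analyze_measures",
    "run_full_pipeline",
]


@dataclasses.dataclass
class RunConfig:
    """Run-level parameters; serialises losslessly to/from YAML."""

    input_dir: str = "."
    output_dir: str = "run"
    cutoff_hz: float = POSITION_CUTOFF_HZ
    zero_triplet_is_missing: bool = False
    window_s: float = 10.0
    hop_s: float = 5.0
    max_lag_s: float = 2.0
    tolerance: float = 0.05
    peak_threshold: float = 0.25
    alpha: float = 0.05
    mauchly_trigger_p: float = 0.05
    seed: int = 0

    def entrainment_params(self) -> EntrainmentParams:
        return EntrainmentParams(
            self.window_s, self.hop_s, self.max_lag_s, self.tolerance, self.peak_threshold
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def measures_for_recording(
    rec,
    timeline: SessionTimeline,
    tempo_specs: list[TempoSpec],
    cutoff_hz: float = POSITION_CUTOFF_HZ,
    params: EntrainmentParams = EntrainmentParams(),
    measures: tuple[str, ...] = ("vigour", "entrainment"),
) -> list[dict]:
    """Per-song vigour and entrainment rows for one marker recording.

    Songs too short for a single analysis window are skipped for
    entrainment (logged), matching the no-fallback windowing contract.
    """
    tempo_by_song = {t.song_index: t for t in tempo_specs}
    trajectories = preprocess_recording(rec, timeline, cutoff_hz)
    rows = []
    vigours = vigour_for_trajectories(trajectories) if "vigour" in measures else {}
    for song_index, traj in trajectories.items():
        if "vigour" in measures:
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "song_index": song_index,
                    "measure_name": "vigour",
                    "value": vigours[song_index],
                }
            )
        if "entrainment" in measures:
            tempo = tempo_by_song[song_index]
            metre = metrical_periods(tempo.tempo_bpm)
            try:
                score = entrainment_for_trajectory(traj, metre, params)
            except TooShortError:
                logger.warning(
                    "participant %s song %d shorter than one window; skipped",
                    rec.participant_id,
                    song_index,
                )
                continue
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "song_index": song_index,
                    "measure_name": "entrainment",
                    "value": score.proportion,
                }
            )
    return rows


def cohort_measures(
    spec: CohortSimSpec,
    params: EntrainmentParams = EntrainmentParams(),
    measures: tuple[str, ...] = ("vigour", "entrainment"),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and compute its measure table without materialising
    all recordings at once (participants are processed one by one).

    Returns ``(measure_table, participants, truth)`` where the measure table
    rows carry the between-subject factors already joined in.
    """
    rng = np.random.default_rng(spec.seed)
    participants = _participant_rows(spec, rng)
    song_specs, truth = participant_motion_specs(spec, participants, rng)
    timeline = make_timeline(spec)
    tempo_specs = [
        TempoSpec(i, tempo_bpm=bpm) for i, bpm in enumerate(spec.song_tempi_bpm, start=1)
    ]
    rows: list[dict] = []
    for specs, pid in zip(song_specs, participants["participant_id"]):
        rec = simulate_participant_recording(spec, specs, pid, rng)
        rows.extend(measures_for_recording(rec, timeline, tempo_specs, params=params, measures=measures))
    table = pd.DataFrame(rows).merge(
        participants[["participant_id", "concert_status", "listener_preference"]],
        on="participant_id",
    )
    return table, participants, truth


# ---------------------------------------------------------------------------
# Directory-level stages
# ---------------------------------------------------------------------------


def simulate_to_dir(spec: CohortSimSpec, out_dir) -> None:
    """Write a complete synthetic fixture directory in the mocap_io formats."""
    out = Path(out_dir)
    (out / "markers").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    participants = _participant_rows(spec, rng)
    song_specs, truth = participant_motion_specs(spec, participants, rng)
    timeline = make_timeline(spec)
    for specs, pid in zip(song_specs, participants["participant_id"]):
        rec = simulate_participant_recording(spec, specs, pid, rng)
        write_marker_tsv(rec, out / "markers" / f"{pid}.tsv")
    write_timeline_csv(timeline, out / "timeline.csv")
    pd.DataFrame(
        {
            "song_index": range(1, spec.n_songs + 1),
            "tempo_bpm": spec.song_tempi_bpm,
        }
    ).to_csv(out / "tempo.csv", index=False)
    write_participants_csv(participants, out / "participants.csv")
    truth.to_csv(out / "truth.csv", index=False)
    logger.info("simulated %d participants into %s", len(participants), out)


def measure_dir(config: RunConfig) -> pd.DataFrame:
    """Read a fixture directory and compute the long measure table."""
    ind = Path(config.input_dir)
    timeline = read_timeline_csv(ind / "timeline.csv")
    tempi = read_tempo_csv(ind / "tempo.csv")
    tempo_specs = [
        TempoSpec(int(r.song_index), tempo_bpm=float(r.tempo_bpm)) for r in tempi.itertuples()
    ]
    participants = read_participants_csv(ind / "participants.csv")
    rows: list[dict] = []
    for pid in participants["participant_id"]:
        rec = read_marker_tsv(
            ind / "markers" / f"{pid}.tsv", config.zero_triplet_is_missing
        )
        rows.extend(
            measures_for_recording(
                rec, timeline, tempo_specs, config.cutoff_hz, config.entrainment_params()
            )
        )
    table = pd.DataFrame(rows).merge(
        participants[["participant_id", "concert_status", "listener_preference"]],
        on="participant_id",
    )
    return table


def analyze_measures(
    measures: pd.DataFrame,
    participants: pd.DataFrame,
    out_dir,
    mauchly_trigger_p: float = 0.05,
) -> dict:
    """Cohort filter + the full ANOVA/t-test battery; writes CSV reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kept, removal_counts = filter_cohort(participants)
    logger.info("cohort filter: kept %d, removed %s", len(kept), removal_counts)
    measures = measures[measures["participant_id"].isin(kept["participant_id"])]
    reports = {"removal_counts": removal_counts, "n_included": len(kept)}
    songs_1_7 = [s for s in sorted(measures["song_index"].unique()) if s <= 7]
    last_song = int(measures["song_index"].max())
    for measure_name in sorted(measures["measure_name"].unique()):
        rep = mixed_anova(measures, measure_name, songs_1_7, mauchly_trigger_p)
        rep.to_frame().to_csv(out / f"anova_{measure_name}.csv", index=False)
        rep.cell_means.to_csv(out / f"cell_means_{measure_name}.csv", index=False)
        reports[f"anova_{measure_name}"] = rep
        if last_song > 7:
            rep8 = song8_anova(measures, measure_name, last_song)
            rep8.to_frame().to_csv(out / f"anova_{measure_name}_song8.csv", index=False)
            rep8.cell_means.to_csv(out / f"cell_means_{measure_name}_song8.csv", index=False)
            reports[f"anova_{measure_name}_song8"] = rep8
    if "musician" in kept.columns and kept["musician"].nunique() == 2:
        tt = musician_ttests(measures, kept)
        pd.DataFrame([dataclasses.asdict(r) for r in tt]).to_csv(
            out / "musician_ttests.csv", index=False
        )
        reports["musician_ttests"] = tt
    return reports


def run_full_pipeline(config: RunConfig, spec: CohortSimSpec | None = None) -> dict:
    """simulate (optional) → measure → analyse, with a provenance record."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if spec is not None:
        simulate_to_dir(spec, config.input_dir)
    measures = measure_dir(config)
    measures.to_csv(out / "measures.csv", index=False)
    participants = read_participants_csv(Path(config.input_dir) / "participants.csv")
    reports = analyze_measures(measures, participants, out, config.mauchly_trigger_p)
    provenance = {
        "config_digest": config.digest(),
        "package_version": __version__,
        "n_participants": int(participants.shape[0]),
        "n_included": reports["n_included"],
        "n_measure_rows": int(measures.shape[0]),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    return reports
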