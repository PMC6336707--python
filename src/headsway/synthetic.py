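"""Synthetic concert cohorts with known vigour and entrainment ground truth.

The generator emulates the recording setup the analysis expects: a rigid
4-marker head rig sampled at 90 Hz, writing the same marker/timeline/tempo/
participant formats as real exports. Head-centre motion is composed of

* an *entrained* component — a single-axis sinusoid along the
  anterior–posterior axis (head nodding) at a chosen metrical level of the
  song's beat, active on a contiguous leading fraction of each song;
* slow postural *drift* — low-frequency sinusoids (period well above the
  2 s autocorrelation lag range) on the horizontal axes;
* broadband measurement *noise* — white Gaussian, independent per marker;
* *occlusion gaps* — Poisson-arriving missing spans, independent per marker,
  never covering the first or last sample so gap-filling stays defined.

Cohort simulation applies multiplicative speed factors and additive
entrained-fraction shifts per factor level of the 2 × 2 design (live/album ×
fan/neutral, default cell sizes 15/9/17/8), plus lognormal per-participant
random effects, and emits the ground truth in a sidecar table so parameter
recovery can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .entrainment import METRICAL_MULTIPLIERS, TempoSpec
from .mocap_io import (
    CONCERT_LEVELS,
    EXCLUSION_FLAGS,
    PREFERENCE_LEVELS,
    MarkerRecording,
    SessionTimeline,
    SongSpan,
)

__all__ = [
    "MARKER_OFFSETS_MM",
    "MotionSimSpec",
    "CohortSimSpec",
    "CohortData",
    "simulate_marker_recording",
    "simulate_cohort",
    "make_timeline",
]

#: fixed rigid-body offsets of the four markers from the head centre (mm):
#: front of head, top of head, left and right temples
MARKER_OFFSETS_MM = np.array(
    [
        [0.0, 90.0, 20.0],
        [0.0, 0.0, 100.0],
        [-70.0, 0.0, 10.0],
        [70.0, 0.0, 10.0],
    ]
)

_AP_AXIS = 1  # anterior–posterior (nodding) axis index


@dataclass(frozen=True)
class MotionSimSpec:
    """Parameters of one participant's simulated head motion."""

    duration_s: float
    beat_period_s: float
    sample_rate_hz: float = 90.0
    entrained_fraction: float = 0.0
    metrical_level: str = "quarter"
    oscillation_amplitude_mm: float = 10.0
    drift_amplitude_mm: float = 15.0
    drift_period_s: float = 30.0
    noise_sd_mm: float = 0.5
    gap_rate_per_min: float = 2.0
    gap_length_range_s: tuple[float, float] = (0.1, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        checks = {
            "duration_s": self.duration_s > 0,
            "beat_period_s": self.beat_period_s > 0,
            "sample_rate_hz": self.sample_rate_hz > 0,
            "entrained_fraction": 0.0 <= self.entrained_fraction <= 1.0,
            "oscillation_amplitude_mm": self.oscillation_amplitude_mm >= 0,
            "drift_amplitude_mm": self.drift_amplitude_mm >= 0,
            "drift_period_s": self.drift_period_s > 0,
            "noise_sd_mm": self.noise_sd_mm >= 0,
            "gap_rate_per_min": self.gap_rate_per_min >= 0,
            "gap_length_range_s": 0 < self.gap_length_range_s[0] <= self.gap_length_range_s[1],
            "metrical_level": self.metrical_level in METRICAL_MULTIPLIERS,
        }
        numeric = [
            self.duration_s, self.beat_period_s, self.sample_rate_hz,
            self.entrained_fraction, self.oscillation_amplitude_mm,
            self.drift_amplitude_mm, self.drift_period_s, self.noise_sd_mm,
            self.gap_rate_per_min, *self.gap_length_range_s,
        ]
        if not np.all(np.isfinite(numeric)):
            raise ValueError("all simulation parameters must be finite")
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid simulation specification: {', '.join(bad)}")

    @property
    def oscillation_period_s(self) -> float:
        return self.beat_period_s * METRICAL_MULTIPLIERS[self.metrical_level]


def _head_centre_path(
    spec: MotionSimSpec, timeline: SessionTimeline, rng: np.random.Generator
) -> np.ndarray:
    n = int(round(spec.duration_s * spec.sample_rate_hz))
    t = np.arange(n) / spec.sample_rate_hz
    pos = np.zeros((n, 3))
    # slow postural drift on the two horizontal axes, random phases
    phases = rng.uniform(0, 2 * np.pi, size=2)
    for ax, ph in zip((0, _AP_AXIS), phases):
        pos[:, ax] += spec.drift_amplitude_mm * np.sin(
            2 * np.pi * t / spec.drift_period_s + ph
        )
    # beat-locked nodding on a contiguous leading fraction of every song
    period = spec.oscillation_period_s
    for span in timeline:
        active_end = span.start_s + spec.entrained_fraction * span.duration_s
        mask = (t >= span.start_s) & (t < active_end)
        pos[mask, _AP_AXIS] += spec.oscillation_amplitude_mm * np.sin(
            2 * np.pi * (t[mask] - span.start_s) / period
        )
    return pos


def _insert_gaps(
    positions: np.ndarray, spec: MotionSimSpec, rng: np.random.Generator
) -> np.ndarray:
    """Knock out Poisson-arriving spans per marker; endpoints stay present."""
    n = positions.shape[0]
    if spec.gap_rate_per_min == 0 or n <= 2:
        return positions
    rate = spec.gap_rate_per_min * spec.duration_s / 60.0
    lo, hi = spec.gap_length_range_s
    for m in range(4):
        for _ in range(rng.poisson(rate)):
            length = int(round(rng.uniform(lo, hi) * spec.sample_rate_hz))
            length = max(length, 1)
            start = rng.integers(1, max(n - 1 - length, 2))
            positions[start : min(start + length, n - 1), m, :] = np.nan
    return positions


def simulate_marker_recording(
    spec: MotionSimSpec,
    timeline: SessionTimeline,
    participant_id: str = "sim",
    rng: np.random.Generator | None = None,
) -> MarkerRecording:
    """Four rigid-body marker series riding on the simulated head centre."""
    if timeline.total_end_s > spec.duration_s + 1e-9:
        raise ValueError("timeline extends past the simulated duration")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    centre = _head_centre_path(spec, timeline, rng)
    positions = centre[:, None, :] + MARKER_OFFSETS_MM[None, :, :]
    if spec.noise_sd_mm > 0:
        positions = positions + rng.normal(0.0, spec.noise_sd_mm, size=positions.shape)
    positions = _insert_gaps(positions, spec, rng)
    return MarkerRecording(
        participant_id=participant_id,
        sample_rate_hz=spec.sample_rate_hz,
        positions=positions,
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

DEFAULT_CELL_SIZES = {
    ("live", "fan"): 15,
    ("live", "neutral"): 9,
    ("album", "fan"): 17,
    ("album", "neutral"): 8,
}

#: typical rock-song tempi; quarter-note periods 0.45–0.75 s
DEFAULT_TEMPI_BPM = (120.0, 96.0, 132.0, 80.0, 108.0, 120.0, 90.0, 112.0)
#: typical radio-rock song lengths, seconds
DEFAULT_DURATIONS_S = (232.0, 248.0, 221.0, 264.0, 212.0, 255.0, 240.0, 228.0)


@dataclass(frozen=True)
class CohortSimSpec:
    """Study-design-level simulation parameters for a full 2 × 2 cohort."""

    cell_sizes: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_CELL_SIZES)
    )
    song_tempi_bpm: tuple[float, ...] = DEFAULT_TEMPI_BPM
    song_durations_s: tuple[float, ...] = DEFAULT_DURATIONS_S
    #: multiplicative speed (amplitude) factors per factor level
    vigour_effect: dict[str, float] = field(
        default_factory=lambda: {"live": 1.9, "album": 1.0, "fan": 1.8, "neutral": 1.0}
    )
    #: additive shifts of the entrained fraction per factor level
    entrainment_effect: dict[str, float] = field(
        default_factory=lambda: {"live": 0.0, "album": 0.0, "fan": 0.03, "neutral": 0.0}
    )
    base_entrained_fraction: float = 0.05
    base_oscillation_amplitude_mm: float = 2.5
    base_drift_amplitude_mm: float = 6.0
    #: postural-drift period; keep well below the song duration so per-song
    #: summaries average over many drift cycles (songs stay exchangeable)
    drift_period_s: float = 30.0
    #: sigma of the lognormal per-participant speed multiplier
    between_participant_sd: float = 0.3
    #: SD of the additive per-participant entrained-fraction jitter
    entrain_between_sd: float = 0.05
    noise_sd_mm: float = 0.5
    gap_rate_per_min: float = 2.0
    inter_song_gap_s: float = 2.0
    n_musicians: int = 25
    exclusion_pattern: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.cell_sizes.values()):
            raise ValueError("every design cell needs at least one participant")
        if len(self.song_tempi_bpm) != len(self.song_durations_s):
            raise ValueError("tempi and durations must have equal length")
        if any(x <= 0 for x in self.song_tempi_bpm + self.song_durations_s):
            raise ValueError("tempi and durations must be positive")
        for key in CONCERT_LEVELS + PREFERENCE_LEVELS:
            if key not in self.vigour_effect or key not in self.entrainment_effect:
                raise ValueError(f"effect maps must cover factor level {key!r}")

    @property
    def n_songs(self) -> int:
        return len(self.song_tempi_bpm)


@dataclass
class CohortData:
    """Everything a downstream analysis needs, plus the ground truth."""

    recordings: list[MarkerRecording]
    timeline: SessionTimeline
    tempo_specs: list[TempoSpec]
    participants: pd.DataFrame
    truth: pd.DataFrame  # per participant × song ground-truth parameters


def make_timeline(spec: CohortSimSpec) -> SessionTimeline:
    songs = []
    cursor = spec.inter_song_gap_s
    for i, dur in enumerate(spec.song_durations_s, start=1):
        songs.append(SongSpan(i, f"song{i}", cursor, cursor + dur))
        cursor += dur + spec.inter_song_gap_s
    return SessionTimeline(songs)


def _participant_rows(spec: CohortSimSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    pid = 0
    for (concert, pref), n_cell in spec.cell_sizes.items():
        for _ in range(n_cell):
            pid += 1
            rows.append(
                {
                    "participant_id": f"P{pid:03d}",
                    "concert_status": concert,
                    "listener_preference": pref,
                    "musician": False,
                    "years_training": 0.0,
                    **{flag: False for flag in EXCLUSION_FLAGS},
                }
            )
    df = pd.DataFrame(rows)
    n = len(df)
    musicians = rng.permutation(n)[: min(spec.n_musicians, n)]
    df.loc[musicians, "musician"] = True
    df.loc[musicians, "years_training"] = np.round(rng.uniform(1, 20, size=len(musicians)), 1)
    if spec.exclusion_pattern:
        extra = []
        for flag, count in spec.exclusion_pattern.items():
            if flag not in EXCLUSION_FLAGS:
                raise ValueError(f"unknown exclusion flag {flag!r}")
            for _ in range(count):
                pid += 1
                cell = list(spec.cell_sizes)[rng.integers(len(spec.cell_sizes))]
                extra.append(
                    {
                        "participant_id": f"P{pid:03d}",
                        "concert_status": cell[0],
                        "listener_preference": cell[1],
                        "musician": bool(rng.integers(2)),
                        "years_training": 0.0,
                        **{f: f == flag for f in EXCLUSION_FLAGS},
                    }
                )
        df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)
    return df


def participant_motion_specs(
    spec: CohortSimSpec, participants: pd.DataFrame, rng: np.random.Generator
) -> tuple[list[list[MotionSimSpec]], pd.DataFrame]:
    """Per-participant, per-song motion specs plus the ground-truth table."""
    timeline = make_timeline(spec)
    total_duration = timeline.total_end_s + spec.inter_song_gap_s
    all_specs: list[list[MotionSimSpec]] = []
    truth_rows = []
    for row in participants.itertuples():
        speed_mult = (
            spec.vigour_effect[row.concert_status]
            * spec.vigour_effect[row.listener_preference]
            * float(np.exp(rng.normal(0.0, spec.between_participant_sd)))
        )
        frac = (
            spec.base_entrained_fraction
            + spec.entrainment_effect[row.concert_status]
            + spec.entrainment_effect[row.listener_preference]
            + rng.normal(0.0, spec.entrain_between_sd)
        )
        frac = float(np.clip(frac, 0.0, 1.0))
        song_specs = []
        for i, bpm in enumerate(spec.song_tempi_bpm, start=1):
            ms = MotionSimSpec(
                duration_s=total_duration,
                beat_period_s=60.0 / bpm,
                entrained_fraction=frac,
                oscillation_amplitude_mm=spec.base_oscillation_amplitude_mm * speed_mult,
                drift_amplitude_mm=spec.base_drift_amplitude_mm * speed_mult,
                drift_period_s=spec.drift_period_s,
                noise_sd_mm=spec.noise_sd_mm,
                gap_rate_per_min=spec.gap_rate_per_min,
            )
            song_specs.append(ms)
            truth_rows.append(
                {
                    "participant_id": row.participant_id,
                    "song_index": i,
                    "speed_multiplier": speed_mult,
                    "entrained_fraction": frac,
                    "oscillation_amplitude_mm": ms.oscillation_amplitude_mm,
                    "beat_period_s": ms.beat_period_s,
                }
            )
        all_specs.append(song_specs)
    return all_specs, pd.DataFrame(truth_rows)


def simulate_participant_recording(
    spec: CohortSimSpec,
    song_specs: list[MotionSimSpec],
    participant_id: str,
    rng: np.random.Generator,
) -> MarkerRecording:
    """One recording covering the whole session, each song at its own tempo."""
    timeline = make_timeline(spec)
    base = song_specs[0]
    n = int(round(base.duration_s * base.sample_rate_hz))
    t = np.arange(n) / base.sample_rate_hz
    centre = np.zeros((n, 3))
    phases = rng.uniform(0, 2 * np.pi, size=2)
    for ax, ph in zip((0, _AP_AXIS), phases):
        centre[:, ax] += base.drift_amplitude_mm * np.sin(
            2 * np.pi * t / base.drift_period_s + ph
        )
    for span, ms in zip(timeline, song_specs):
        active_end = span.start_s + ms.entrained_fraction * span.duration_s
        mask = (t >= span.start_s) & (t < active_end)
        centre[mask, _AP_AXIS] += ms.oscillation_amplitude_mm * np.sin(
            2 * np.pi * (t[mask] - span.start_s) / ms.oscillation_period_s
        )
    positions = centre[:, None, :] + MARKER_OFFSETS_MM[None, :, :]
    if base.noise_sd_mm > 0:
        positions = positions + rng.normal(0.0, base.noise_sd_mm, size=positions.shape)
    positions = _insert_gaps(positions, replace(base, seed=0), rng)
    return MarkerRecording(
        participant_id=participant_id,
        sample_rate_hz=base.sample_rate_hz,
        positions=positions,
    )


def simulate_cohort(spec: CohortSimSpec) -> CohortData:
    """Materialise a full cohort (recordings, timeline, tempi, metadata, truth).

    Recordings for realistic song lengths are large; prefer
    :func:`headsway.pipeline.cohort_measures` when only the derived measures
    are needed.
    """
    rng = np.random.default_rng(spec.seed)
    participants = _participant_rows(spec, rng)
    song_specs, truth = participant_motion_specs(spec, participants, rng)
    recordings = [
        simulate_participant_recording(spec, specs, pid, rng)
        for specs, pid in zip(song_specs, participants["participant_id"])
    ]
    timeline = make_timeline(spec)
    tempo_specs = [
        TempoSpec(i, tempo_bpm=bpm) for i, bpm in enumerate(spec.song_tempi_bpm, start=1)
    ]
    return CohortData(recordings, timeline, tempo_specs, participants, truth)
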