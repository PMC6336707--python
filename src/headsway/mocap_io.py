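"""Reading, writing and segmenting optical motion-capture exports.

The canonical on-disk formats are deliberately plain text:

* **Marker TSV** — one file per participant. A short header declares the
  participant id, sample rate, session start time and marker names; the body
  has one row per frame with a frame index followed by three tab-separated
  coordinate columns (mm) per marker. Missing samples (marker occlusions)
  are written as empty fields by default; readers can alternatively treat a
  ``0,0,0`` triplet as the missing-data sentinel, a convention used by some
  capture-software exports.
* **Timeline / tempo / participant tables** — headered CSV, read and written
  through pandas.

All in-memory containers are small dataclasses wrapping numpy arrays (with
``NaN`` marking missing samples) or pandas DataFrames.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MARKER_NAMES",
    "MarkerRecording",
    "SessionTimeline",
    "SongSpan",
    "FormatError",
    "SegmentationError",
    "read_marker_tsv",
    "write_marker_tsv",
    "read_timeline_csv",
    "write_timeline_csv",
    "read_tempo_csv",
    "write_tempo_csv",
    "read_participants_csv",
    "write_participants_csv",
    "segment_songs",
]

#: Canonical head-rig marker order: front of head, top of head, two temples.
MARKER_NAMES = ("front", "top", "left_temple", "right_temple")

EXCLUSION_FLAGS = (
    "abnormal_hearing",
    "movement_restriction",
    "prior_song_exposure",
    "no_followup",
)

CONCERT_LEVELS = ("live", "album")
PREFERENCE_LEVELS = ("fan", "neutral")


class FormatError(ValueError):
    """A marker/table file violates the documented dialect."""


class SegmentationError(ValueError):
    """A requested song span falls outside the recorded time range."""


@dataclass
class MarkerRecording:
    """Raw 4-marker head recording for one participant.

    ``positions`` has shape ``(n_frames, 4, 3)`` in millimetres; missing
    samples are NaN (all three coordinates of a marker at a frame).
    """

    participant_id: str
    sample_rate_hz: float
    positions: np.ndarray
    start_time_s: float = 0.0
    marker_names: tuple[str, ...] = MARKER_NAMES

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (4, 3):
            raise ValueError(
                f"positions must have shape (n_frames, 4, 3), got {self.positions.shape}"
            )
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        if len(self.marker_names) != 4:
            raise ValueError("exactly four marker names expected")
        finite = self.positions[~np.isnan(self.positions)]
        if finite.size and not np.all(np.isfinite(finite)):
            raise ValueError("positions must be finite where present")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        """Session-clock timestamp of each frame (frame k at start + k/rate)."""
        return self.start_time_s + np.arange(self.n_frames) / self.sample_rate_hz

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_frames, 4): True where a marker sample is missing."""
        return np.isnan(self.positions).any(axis=2)


@dataclass(frozen=True)
class SongSpan:
    song_index: int
    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(f"song {self.song_index}: end_s must exceed start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SessionTimeline:
    """Ordered, non-overlapping song spans on the session clock."""

    songs: list[SongSpan] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for span in self.songs:
            if span.start_s < prev_end:
                raise ValueError("song spans must be non-overlapping and increasing")
            prev_end = span.end_s

    def __iter__(self):
        return iter(self.songs)

    def __len__(self) -> int:
        return len(self.songs)

    @property
    def total_end_s(self) -> float:
        return self.songs[-1].end_s if self.songs else 0.0


# ---------------------------------------------------------------------------
# Marker TSV dialect
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.6f"  # lossless well past the sub-mm precision of optical capture


def write_marker_tsv(rec: MarkerRecording, path) -> None:
    """Write a recording in the documented TSV dialect (missing = empty fields)."""
    buf = io.StringIO()
    buf.write(f"PARTICIPANT\t{rec.participant_id}\n")
    buf.write(f"SAMPLE_RATE\t{rec.sample_rate_hz:g}\n")
    buf.write(f"START_TIME\t{rec.start_time_s:g}\n")
    buf.write("MARKER_NAMES\t" + "\t".join(rec.marker_names) + "\n")
    cols = ["frame"]
    for name in rec.marker_names:
        cols += [f"{name}_x", f"{name}_y", f"{name}_z"]
    buf.write("\t".join(cols) + "\n")
    flat = rec.positions.reshape(rec.n_frames, 12)
    for k in range(rec.n_frames):
        cells = [str(k)]
        row = flat[k]
        for v in row:
            cells.append("" if np.isnan(v) else _FLOAT_FMT % v)
        buf.write("\t".join(cells) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_marker_tsv(path, zero_triplet_is_missing: bool = False) -> MarkerRecording:
    """Parse a marker TSV file into a :class:`MarkerRecording`.

    Parameters
    ----------
    path : path-like
    zero_triplet_is_missing : bool
        Treat an exact ``0,0,0`` coordinate triplet as the missing-data
        sentinel (some capture exports use it instead of empty fields).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    header: dict[str, list[str]] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split("\t")
        key = parts[0]
        if key in {"PARTICIPANT", "SAMPLE_RATE", "START_TIME", "MARKER_NAMES"}:
            header[key] = parts[1:]
            i += 1
        else:
            break
    for key in ("SAMPLE_RATE", "MARKER_NAMES"):
        if key not in header:
            raise FormatError(f"{path}: missing required header line {key!r}")
    marker_names = tuple(header["MARKER_NAMES"])
    if set(marker_names) != set(MARKER_NAMES):
        raise FormatError(
            f"{path}: unknown marker names {marker_names!r} (expected {MARKER_NAMES!r})"
        )
    sample_rate = float(header["SAMPLE_RATE"][0])
    start_time = float(header.get("START_TIME", ["0"])[0])
    participant = header.get("PARTICIPANT", ["unknown"])[0]

    if i >= len(lines) or not lines[i].startswith("frame"):
        raise FormatError(f"{path}: line {i + 1}: expected column-header row")
    i += 1

    rows = []
    prev_frame = -1
    for lineno, line in enumerate(lines[i:], start=i + 1):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != 13:
            raise FormatError(
                f"{path}: line {lineno}: expected 13 columns, found {len(cells)}"
            )
        try:
            frame = int(cells[0])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: bad frame index {cells[0]!r}") from exc
        if frame <= prev_frame:
            raise FormatError(f"{path}: line {lineno}: non-monotone frame index {frame}")
        prev_frame = frame
        vals = np.empty(12)
        for j, cell in enumerate(cells[1:]):
            if cell == "":
                vals[j] = np.nan
            else:
                try:
                    vals[j] = float(cell)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: non-numeric cell {cell!r}"
                    ) from exc
        rows.append(vals)
    positions = np.asarray(rows).reshape(len(rows), 4, 3)
    # a marker is missing if any of its three coordinates is absent
    partial = np.isnan(positions).any(axis=2)
    positions[partial] = np.nan
    if zero_triplet_is_missing:
        zero = (positions == 0.0).all(axis=2)
        positions[zero] = np.nan
    # reorder columns to canonical marker order
    order = [marker_names.index(m) for m in MARKER_NAMES]
    positions = positions[:, order, :]
    return MarkerRecording(
        participant_id=participant,
        sample_rate_hz=sample_rate,
        positions=positions,
        start_time_s=start_time,
    )


# ---------------------------------------------------------------------------
# Timeline / tempo / participant tables (headered CSV)
# ---------------------------------------------------------------------------


def write_timeline_csv(timeline: SessionTimeline, path) -> None:
    pd.DataFrame(
        [
            {"song_index": s.song_index, "label": s.label, "start_s": s.start_s, "end_s": s.end_s}
            for s in timeline
        ]
    ).to_csv(path, index=False)


def read_timeline_csv(path) -> SessionTimeline:
    df = pd.read_csv(path)
    required = {"song_index", "label", "start_s", "end_s"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: timeline CSV must have columns {sorted(required)}")
    return SessionTimeline(
        [
            SongSpan(int(r.song_index), str(r.label), float(r.start_s), float(r.end_s))
            for r in df.itertuples()
        ]
    )


def write_tempo_csv(tempi: pd.DataFrame, path) -> None:
    """Tempo table: columns song_index, tempo_bpm."""
    tempi.to_csv(path, index=False)


def read_tempo_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"song_index", "tempo_bpm"}.issubset(df.columns):
        raise FormatError(f"{path}: tempo CSV must have song_index and tempo_bpm columns")
    return df


def write_participants_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_participants_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant_id", "concert_status", "listener_preference"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: participant CSV must have columns {sorted(required)}")
    if df["participant_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate participant_id")
    bad = set(df["concert_status"]) - set(CONCERT_LEVELS)
    bad |= set(df["listener_preference"]) - set(PREFERENCE_LEVELS)
    if bad:
        raise FormatError(f"{path}: unknown factor levels {sorted(bad)}")
    for flag in EXCLUSION_FLAGS:
        if flag in df.columns:
            df[flag] = df[flag].astype(bool)
        else:
            df[flag] = False
    if "musician" in df.columns:
        df["musician"] = df["musician"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def segment_songs(
    values: np.ndarray,
    sample_rate_hz: float,
    timeline: SessionTimeline,
    start_time_s: float = 0.0,
) -> dict[int, np.ndarray]:
    """Split a time-indexed array into half-open per-song spans.

    Frame ``k`` carries timestamp ``start_time_s + k / sample_rate_hz``; a
    frame belongs to a song iff ``start_s <= t < end_s``, so adjacent songs
    never share a frame. Frames between songs are discarded.
    """
    values = np.asarray(values)
    n = values.shape[0]
    out: dict[int, np.ndarray] = {}
    for span in timeline:
        # smallest k with t_k >= start_s, and with t_k >= end_s
        lo = int(np.ceil((span.start_s - start_time_s) * sample_rate_hz - 1e-9))
        hi = int(np.ceil((span.end_s - start_time_s) * sample_rate_hz - 1e-9))
        if lo < 0 or hi > n:
            raise SegmentationError(
                f"song {span.song_index} span [{span.start_s}, {span.end_s}) outside "
                f"recording range [{start_time_s}, {start_time_s + n / sample_rate_hz})"
            )
        out[span.song_index] = values[lo:hi]
    return out


def shifted(rec: MarkerRecording, offset: np.ndarray) -> MarkerRecording:
    """Return a copy of ``rec`` with all markers rigidly translated by ``offset``."""
    return replace(rec, positions=rec.positions + np.asarray(offset, float))
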