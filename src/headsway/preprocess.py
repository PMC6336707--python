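"""Raw marker recordings → clean per-song head-centre trajectories.

The fixed pipeline order is: trim edge gaps → linear gap-fill per marker →
zero-phase 6 Hz Butterworth low-pass → average the four markers into a head
centre → segment into songs → per-song mean-centring. Both downstream
measures (vigour, entrainment) are invariant to absolute location, so the
centring step is a convention, not a quantitative choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal

from .mocap_io import MarkerRecording, SessionTimeline, segment_songs

__all__ = [
    "HeadTrajectory",
    "EdgeGapError",
    "TooShortError",
    "UnresolvableFrameError",
    "trim_edge_gaps",
    "gap_fill_linear",
    "lowpass_position",
    "head_center",
    "normalize_trajectory",
    "preprocess_recording",
]

POSITION_CUTOFF_HZ = 6.0  #: jitter-removal cutoff applied to marker positions


class EdgeGapError(ValueError):
    """A gap touches the first or last sample, so interpolation is undefined."""


class TooShortError(ValueError):
    """Series too short for the requested filter or derivative."""


class UnresolvableFrameError(ValueError):
    """A frame has no marker data at all, so no head centre exists."""


@lru_cache(maxsize=None)
def butter_coeffs(cutoff_hz: float, sample_rate_hz: float, order: int = 2):
    """Second-order Butterworth low-pass coefficients (cached per cutoff/rate)."""
    return signal.butter(order, cutoff_hz, fs=sample_rate_hz)


@dataclass
class HeadTrajectory:
    """Clean single-point head-centre series for one participant and song."""

    participant_id: str
    song_index: int
    sample_rate_hz: float
    positions: np.ndarray  # (n_frames, 3), mm, no missing samples

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_frames, 3)")
        if self.positions.shape[0] < 2:
            raise ValueError("trajectory needs at least 2 frames")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("trajectory must be finite everywhere")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sample_rate_hz


def trim_edge_gaps(rec: MarkerRecording) -> MarkerRecording:
    """Trim to the span on which every marker has bounding observed samples.

    Linear gap-filling needs a present sample on each side of every gap, so
    the recording is cut to ``[max_k first-seen(marker k), min_k last-seen]``.
    The start time is advanced accordingly so session timestamps stay valid.
    """
    present = ~rec.missing_mask()  # (n, 4)
    if not present.any(axis=0).all():
        raise EdgeGapError("a marker is never observed; cannot trim")
    first = max(int(np.argmax(present[:, m])) for m in range(4))
    last = min(int(rec.n_frames - 1 - np.argmax(present[::-1, m])) for m in range(4))
    if last <= first:
        raise EdgeGapError("markers share no common observed span")
    return MarkerRecording(
        participant_id=rec.participant_id,
        sample_rate_hz=rec.sample_rate_hz,
        positions=rec.positions[first : last + 1],
        start_time_s=rec.start_time_s + first / rec.sample_rate_hz,
        marker_names=rec.marker_names,
    )


def gap_fill_linear(series: np.ndarray) -> np.ndarray:
    """Fill interior NaN runs by straight lines between bounding samples.

    ``series`` is (n,) or (n, d); each column is interpolated independently.
    Raises :class:`EdgeGapError` if the first or last sample is missing.
    """
    arr = np.asarray(series, dtype=float)
    cols = arr.reshape(arr.shape[0], -1).copy()
    idx = np.arange(cols.shape[0])
    for j in range(cols.shape[1]):
        col = cols[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        if miss[0] or miss[-1]:
            raise EdgeGapError("gap touches series edge; trim the recording first")
        col[miss] = np.interp(idx[miss], idx[~miss], col[~miss])
    return cols.reshape(arr.shape)


def lowpass_position(
    series: np.ndarray, sample_rate_hz: float, cutoff_hz: float = POSITION_CUTOFF_HZ
) -> np.ndarray:
    """Zero-phase second-order Butterworth low-pass, applied per column.

    Forward-backward filtering (``filtfilt``) keeps the output free of phase
    lag so that period estimates downstream are unbiased.
    """
    if not 0 < cutoff_hz < sample_rate_hz / 2:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    arr = np.asarray(series, dtype=float)
    b, a = butter_coeffs(cutoff_hz, sample_rate_hz)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if arr.shape[0] <= padlen:
        raise TooShortError(f"series of {arr.shape[0]} frames too short for filtfilt")
    return signal.filtfilt(b, a, arr, axis=0)


def head_center(positions: np.ndarray) -> np.ndarray:
    """Per-frame mean of the available marker positions, (n, 4, 3) → (n, 3).

    After gap filling, missing markers only occur where the recording was
    trimmed; whatever subset is present at a frame is averaged.
    """
    pos = np.asarray(positions, dtype=float)
    nan_mask = np.isnan(pos)
    if not nan_mask.any():
        return pos.mean(axis=1)
    available = ~nan_mask.any(axis=2)
    if not available.any(axis=1).all():
        raise UnresolvableFrameError("frame with zero available markers")
    with np.errstate(invalid="ignore"):
        return np.nanmean(pos, axis=1)


def normalize_trajectory(traj: HeadTrajectory) -> HeadTrajectory:
    """Express position relative to the song-mean head position (per axis)."""
    centred = traj.positions - traj.positions.mean(axis=0, keepdims=True)
    return HeadTrajectory(traj.participant_id, traj.song_index, traj.sample_rate_hz, centred)


def preprocess_recording(
    rec: MarkerRecording,
    timeline: SessionTimeline,
    cutoff_hz: float = POSITION_CUTOFF_HZ,
    zero_triplet_is_missing: bool = False,  # kept for config symmetry; read-side option
) -> dict[int, HeadTrajectory]:
    """Run the full preprocessing pipeline; returns song_index → trajectory."""
    rec = trim_edge_gaps(rec)
    filled = gap_fill_linear(rec.positions.reshape(rec.n_frames, 12)).reshape(
        rec.n_frames, 4, 3
    )
    smoothed = lowpass_position(filled.reshape(rec.n_frames, 12), rec.sample_rate_hz, cutoff_hz)
    centre = head_center(smoothed.reshape(rec.n_frames, 4, 3))
    segments = segment_songs(centre, rec.sample_rate_hz, timeline, rec.start_time_s)
    out: dict[int, HeadTrajectory] = {}
    for song_index, seg in segments.items():
        traj = HeadTrajectory(rec.participant_id, song_index, rec.sample_rate_hz, seg)
        out[song_index] = normalize_trajectory(traj)
    return out
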