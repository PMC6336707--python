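"""Degree of rhythmic entrainment from windowed autocorrelation.

A song's beat period (from its tempo, or from rater tap times) defines a
three-level metrical hierarchy: quarter note = one beat period, half note =
two, whole note = four. Head-centre position is analysed in 10-s windows
hopped by 5 s; within each window the normalised autocorrelation of each
mean-removed axis is computed over lags 0–2 s, and the window's movement
period is the lag of the first qualifying autocorrelation peak on the axis
with the strongest such peak. A window counts as entrained when its period
lies within 5% (relative) of any metrical level, and the degree of
entrainment is the entrained fraction of windows: 0.0 (never period-locked)
to 1.0 (every window period-locked).

The period-extraction rule (first local maximum above a height threshold,
default 0.25, strongest axis wins) is a documented reconstruction — standard
practice for autocorrelation-based tempo trackers — and every threshold is
exposed as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import HeadTrajectory, TooShortError

__all__ = [
    "METRICAL_MULTIPLIERS",
    "TempoSpec",
    "MetricalPeriods",
    "WindowPeriodEstimate",
    "EntrainmentScore",
    "EntrainmentParams",
    "beat_period_from_taps",
    "metrical_periods",
    "windowed_autocorrelation",
    "estimate_window_period",
    "score_entrainment",
    "entrainment_for_trajectory",
]

#: metrical hierarchy relative to the beat (quarter note)
METRICAL_MULTIPLIERS = {"quarter": 1.0, "half": 2.0, "whole": 4.0}


@dataclass(frozen=True)
class TempoSpec:
    """A song's tempo, as BPM or as per-rater tap times (seconds)."""

    song_index: int
    tempo_bpm: float | None = None
    tap_times_s: tuple[tuple[float, ...], ...] = ()

    def __post_init__(self) -> None:
        if self.tempo_bpm is None and not self.tap_times_s:
            raise ValueError("need tempo_bpm or tap times")
        if self.tempo_bpm is not None and not self.tempo_bpm > 0:
            raise ValueError("tempo_bpm must be positive")


@dataclass(frozen=True)
class MetricalPeriods:
    """Beat period plus the derived quarter/half/whole-note target periods."""

    beat_period_s: float

    def __post_init__(self) -> None:
        if not self.beat_period_s > 0:
            raise ValueError("beat period must be positive")

    @property
    def levels(self) -> dict[str, float]:
        return {k: m * self.beat_period_s for k, m in METRICAL_MULTIPLIERS.items()}


@dataclass(frozen=True)
class WindowPeriodEstimate:
    window_start_s: float
    period_s: float | None
    peak_height: float = 0.0
    matched_level: str = "none"


@dataclass(frozen=True)
class EntrainmentScore:
    participant_id: str
    song_index: int
    n_windows: int
    n_entrained: int
    level_counts: dict[str, int] = field(default_factory=dict)

    @property
    def proportion(self) -> float:
        return self.n_entrained / self.n_windows


@dataclass(frozen=True)
class EntrainmentParams:
    """Windowing and detection parameters for the entrainment statistic."""

    window_s: float = 10.0
    hop_s: float = 5.0
    max_lag_s: float = 2.0
    tolerance: float = 0.05  # relative period tolerance against each level
    peak_threshold: float = 0.25  # minimum normalised-acf height for a peak

    def __post_init__(self) -> None:
        if not (self.window_s > 0 and self.hop_s > 0 and self.max_lag_s > 0):
            raise ValueError("window, hop and max lag must be positive")
        if not 0 <= self.tolerance:
            raise ValueError("tolerance must be nonnegative")


def beat_period_from_taps(spec: TempoSpec) -> MetricalPeriods:
    """Beat period from BPM, or the cross-rater mean inter-tap interval."""
    if spec.tempo_bpm is not None:
        return MetricalPeriods(60.0 / spec.tempo_bpm)
    rater_means = []
    for taps in spec.tap_times_s:
        taps = np.asarray(taps, dtype=float)
        if taps.size < 2:
            raise ValueError("each rater needs at least 2 taps")
        intervals = np.diff(taps)
        if (intervals <= 0).any():
            raise ValueError("tap times must be strictly increasing")
        rater_means.append(intervals.mean())
    return MetricalPeriods(float(np.mean(rater_means)))


def metrical_periods(tempo_bpm: float) -> MetricalPeriods:
    return MetricalPeriods(60.0 / tempo_bpm)


def windowed_autocorrelation(
    traj: HeadTrajectory, params: EntrainmentParams = EntrainmentParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window, per-axis normalised autocorrelation of head position.

    Returns ``(window_starts_s, acf)`` with ``acf`` of shape
    ``(n_windows, 3, n_lags)`` where lag ``l`` spans 0 … round(max_lag × rate)
    inclusive (so a whole-note period sitting exactly at the lag limit is
    still on the grid). Each window and axis is mean-removed and normalised
    by its lag-0 autocovariance; a constant axis yields zeros beyond lag 0.

    Window count is ``floor((duration − window) / hop) + 1``; a song shorter
    than one window raises :class:`TooShortError`.
    """
    rate = traj.sample_rate_hz
    win_n = int(round(params.window_s * rate))
    hop_n = int(round(params.hop_s * rate))
    max_lag_n = int(round(params.max_lag_s * rate))
    n = traj.n_frames
    if n < win_n:
        raise TooShortError(
            f"song of {n / rate:.1f} s shorter than the {params.window_s:.0f} s window"
        )
    n_windows = (n - win_n) // hop_n + 1
    starts = np.arange(n_windows) * hop_n
    acf = np.zeros((n_windows, 3, max_lag_n + 1))
    for w, s0 in enumerate(starts):
        seg = traj.positions[s0 : s0 + win_n]  # (win_n, 3)
        x = seg - seg.mean(axis=0, keepdims=True)
        denom = (x * x).sum(axis=0)  # per-axis lag-0 autocovariance
        safe = denom > 0
        acf[w, safe, 0] = 1.0
        for lag in range(1, max_lag_n + 1):
            num = (x[: win_n - lag] * x[lag:]).sum(axis=0)
            acf[w, safe, lag] = num[safe] / denom[safe]
    return starts / rate, acf


def _first_qualifying_peak(acf_1d: np.ndarray, threshold: float) -> tuple[int | None, float]:
    """Lag and height of the first local acf maximum above ``threshold``.

    Interior lags must exceed both neighbours; the final lag on the grid only
    its left neighbour (so a period sitting exactly at the lag limit remains
    detectable).
    """
    n = acf_1d.shape[0]
    for lag in range(1, n):
        h = acf_1d[lag]
        if h < threshold:
            continue
        left = acf_1d[lag - 1]
        right = acf_1d[lag + 1] if lag + 1 < n else -np.inf
        if h > left and (lag == n - 1 or h > right):
            return lag, float(h)
    return None, 0.0


def estimate_window_period(
    acf_axes: np.ndarray,
    sample_rate_hz: float,
    window_start_s: float = 0.0,
    peak_threshold: float = 0.25,
) -> WindowPeriodEstimate:
    """Movement period of one window from its per-axis autocorrelations.

    Each axis contributes the lag of its first qualifying peak; the window's
    period comes from the axis whose peak is highest. ``period_s = None``
    when no axis shows a qualifying peak (no periodicity detected).
    """
    acf_axes = np.atleast_2d(acf_axes)
    best_lag, best_h = None, -np.inf
    for axis_acf in acf_axes:
        lag, h = _first_qualifying_peak(axis_acf, peak_threshold)
        if lag is not None and h > best_h:
            best_lag, best_h = lag, h
    if best_lag is None:
        return WindowPeriodEstimate(window_start_s, None)
    return WindowPeriodEstimate(window_start_s, best_lag / sample_rate_hz, best_h)


def _match_level(period_s: float, metre: MetricalPeriods, tolerance: float) -> str:
    """Nearest metrical level within tolerance, 'none' otherwise.

    Ties on relative error resolve to the shorter level (quarter first).
    """
    best = "none"
    best_err = np.inf
    for name in ("quarter", "half", "whole"):
        target = metre.levels[name]
        err = abs(period_s - target) / target
        if err <= tolerance and err < best_err:
            best, best_err = name, err
    return best


def score_entrainment(
    estimates: Sequence[WindowPeriodEstimate],
    metre: MetricalPeriods,
    tolerance: float = 0.05,
    participant_id: str = "",
    song_index: int = 0,
) -> EntrainmentScore:
    """Count period-matched windows and form the entrainment proportion."""
    if not estimates:
        raise ValueError("need at least one window estimate")
    level_counts = {k: 0 for k in METRICAL_MULTIPLIERS}
    n_entrained = 0
    for est in estimates:
        if est.period_s is None:
            continue
        level = _match_level(est.period_s, metre, tolerance)
        if level != "none":
            n_entrained += 1
            level_counts[level] += 1
    return EntrainmentScore(
        participant_id, song_index, len(estimates), n_entrained, level_counts
    )


def entrainment_for_trajectory(
    traj: HeadTrajectory,
    metre: MetricalPeriods,
    params: EntrainmentParams = EntrainmentParams(),
) -> EntrainmentScore:
    """Full per-song entrainment statistic for one head trajectory."""
    starts, acf = windowed_autocorrelation(traj, params)
    estimates = [
        estimate_window_period(acf[w], traj.sample_rate_hz, starts[w], params.peak_threshold)
        for w in range(acf.shape[0])
    ]
    return score_entrainment(
        estimates, metre, params.tolerance, traj.participant_id, traj.song_index
    )
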