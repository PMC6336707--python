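import numpy as np
import pandas as pd
import pytest

from headsway.mocap_io import SessionTimeline, SongSpan
from headsway.preprocess import HeadTrajectory
from headsway.synthetic import MotionSimSpec, simulate_marker_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def one_song_timeline():
    return SessionTimeline([SongSpan(1, "song1", 0.0, 60.0)])


def make_sinusoid_trajectory(
    period_s: float,
    duration_s: float = 60.0,
    amplitude_mm: float = 10.0,
    sample_rate_hz: float = 90.0,
    axis: int = 1,
    participant_id: str = "sim",
    song_index: int = 1,
) -> HeadTrajectory:
    """Noiseless single-axis sinusoidal head trajectory."""
    t = np.arange(int(round(duration_s * sample_rate_hz))) / sample_rate_hz
    pos = np.zeros((t.size, 3))
    pos[:, axis] = amplitude_mm * np.sin(2 * np.pi * t / period_s)
    return HeadTrajectory(participant_id, song_index, sample_rate_hz, pos)


@pytest.fixture
def entrained_recording(one_song_timeline):
    """Noiseless full-song quarter-note nodding at 120 BPM."""
    spec = MotionSimSpec(
        duration_s=60.0,
        beat_period_s=0.5,
        entrained_fraction=1.0,
        oscillation_amplitude_mm=10.0,
        drift_amplitude_mm=0.0,
        noise_sd_mm=0.0,
        gap_rate_per_min=0.0,
        seed=7,
    )
    return simulate_marker_recording(spec, one_song_timeline)


def make_measure_table(
    rng: np.random.Generator,
    cell_sizes=None,
    n_songs: int = 8,
    measure_name: str = "vigour",
    concert_shift: float = 0.0,
    pref_shift: float = 0.0,
    song_effects=None,
    subject_sd: float = 1.0,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Long-format measure table simulated at the level of derived measures."""
    if cell_sizes is None:
        cell_sizes = {("live", "fan"): 15, ("live", "neutral"): 9,
                      ("album", "fan"): 17, ("album", "neutral"): 8}
    if song_effects is None:
        song_effects = np.zeros(n_songs)
    rows = []
    pid = 0
    for (concert, pref), n in cell_sizes.items():
        for _ in range(n):
            pid += 1
            base = (
                10.0
                + (concert_shift if concert == "live" else 0.0)
                + (pref_shift if pref == "fan" else 0.0)
                + rng.normal(0, subject_sd)
            )
            vals = base + np.asarray(song_effects) + rng.normal(0, noise_sd, n_songs)
            for j, v in enumerate(vals, start=1):
                rows.append(
                    {
                        "participant_id": f"P{pid:03d}",
                        "concert_status": concert,
                        "listener_preference": pref,
                        "song_index": j,
                        "measure_name": measure_name,
                        "value": v,
                    }
                )
    return pd.DataFrame(rows)
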