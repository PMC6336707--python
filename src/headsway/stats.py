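"""Statistical layer: cohort filtering and the mixed-design ANOVA family.

The design is a 2 × 2 × 7 split-plot: between-subjects factors
concert_status (live vs album playback) and listener_preference (fan vs
neutral), within-subjects factor song (1–7), with song 8 analysed separately
in a 2 × 2 between-subjects ANOVA because it is familiar to fans.

The split-plot decomposition is computed directly from sum-coded design
matrices with Type-III (partial) sums of squares, which handles the unequal
cell sizes (15/9/17/8). Between-subject effects are tested against the
subject-within-groups stratum (denominator df = N − 4); within-subject
effects against the song × subject stratum (df = (N − 4)(k − 1)), with
Mauchly's sphericity test on the pooled within-cell covariance and a
Greenhouse–Geisser correction of the degrees of freedom whenever Mauchly's
p falls below the trigger threshold (default 0.05).

Effect size is partial eta-squared, ηp² = SS_effect / (SS_effect +
SS_error), equivalently F·df_num / (F·df_num + df_den). Cell summaries carry
the mean and one standard error of the mean (SEM = SD/√n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mocap_io import EXCLUSION_FLAGS

__all__ = [
    "EffectResult",
    "AnovaReport",
    "filter_cohort",
    "mixed_anova",
    "song8_anova",
    "bonferroni_pairwise",
    "musician_ttests",
    "summarize_cells",
]

MAUCHLY_TRIGGER_P = 0.05


@dataclass
class EffectResult:
    """One ANOVA effect: F, (possibly corrected) df, p and partial eta²."""

    name: str
    ss: float
    df_num: float
    df_den: float
    F: float
    p: float
    partial_eta_sq: float
    stratum: str  # "between" or "within"
    epsilon: float | None = None
    mauchly_W: float | None = None
    mauchly_p: float | None = None
    gg_corrected: bool = False
    p_uncorrected: float | None = None


@dataclass
class AnovaReport:
    measure: str
    effects: dict[str, EffectResult]
    cell_means: pd.DataFrame
    n_subjects: int
    error_ss: dict[str, float] = field(default_factory=dict)

    def effect(self, name: str) -> EffectResult:
        return self.effects[name]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.effects.values():
            rows.append(
                {
                    "effect": e.name,
                    "F": e.F,
                    "df_num": e.df_num,
                    "df_den": e.df_den,
                    "p": e.p,
                    "partial_eta_sq": e.partial_eta_sq,
                    "gg_corrected": e.gg_corrected,
                    "epsilon": e.epsilon,
                    "mauchly_W": e.mauchly_W,
                    "mauchly_p": e.mauchly_p,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort filtering
# ---------------------------------------------------------------------------


def filter_cohort(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop participants carrying any exclusion flag.

    Returns the retained table and the per-reason removal counts (a
    participant excluded for several reasons counts once per reason).
    """
    counts: dict[str, int] = {}
    drop = np.zeros(len(table), dtype=bool)
    for flag in EXCLUSION_FLAGS:
        if flag in table.columns:
            col = table[flag].to_numpy(dtype=bool)
            counts[flag] = int(col.sum())
            drop |= col
        else:
            counts[flag] = 0
    kept = table.loc[~drop].reset_index(drop=True)
    if kept.empty:
        import warnings

        warnings.warn("all participants excluded", stacklevel=2)
    return kept, counts


# ---------------------------------------------------------------------------
# Design-matrix helpers (sum coding; Type-III partial SS)
# ---------------------------------------------------------------------------


def _sum_code_two_level(values: pd.Series, levels: tuple[str, str]) -> np.ndarray:
    """+1 for the first level, −1 for the second."""
    arr = np.where(values.to_numpy() == levels[0], 1.0, -1.0)
    return arr


def _song_contrasts(k: int) -> np.ndarray:
    """Sum-coded (deviation) contrasts for a k-level factor: (k, k-1)."""
    c = np.zeros((k, k - 1))
    c[:-1, :] = np.eye(k - 1)
    c[-1, :] = -1.0
    return c


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float(y @ y)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def _partial_ss(y: np.ndarray, terms: dict[str, np.ndarray]) -> tuple[dict[str, float], float]:
    """Type-III SS per term: RSS without the term minus RSS of the full model.

    Sums of squares below the round-off floor of ``y`` are clamped to exact
    zero so degenerate inputs (all values equal) give F = 0, not noise ratios.
    """
    tol = 1e-10 * max(float(y @ y), 1.0)
    X_full = np.hstack(list(terms.values()))
    rss_full = _rss(y, X_full)
    if rss_full < tol:
        rss_full = 0.0
    ss = {}
    for name in terms:
        X_red = np.hstack([m for t, m in terms.items() if t != name]) if len(terms) > 1 else np.zeros(
            (y.shape[0], 0)
        )
        val = max(_rss(y, X_red) - rss_full, 0.0)
        ss[name] = 0.0 if val < tol else val
    return ss, rss_full


def _f_and_p(ss_eff: float, df_num: float, ss_err: float, df_err: float) -> tuple[float, float]:
    if ss_err == 0.0:
        return (np.inf, 0.0) if ss_eff > 0 else (0.0, 1.0)
    F = (ss_eff / df_num) / (ss_err / df_err)
    return float(F), float(sps.f.sf(F, df_num, df_err))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1, k) orthonormal rows, each orthogonal to the unit vector."""
    helmert = np.zeros((k - 1, k))
    for i in range(k - 1):
        helmert[i, : i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1.0)
        helmert[i] /= np.linalg.norm(helmert[i])
    return helmert


def _sphericity(Y: np.ndarray, cells: np.ndarray) -> tuple[float, float, float]:
    """Greenhouse–Geisser epsilon and Mauchly's test from pooled covariance.

    ``Y`` is subjects × k within-subject scores; ``cells`` assigns each
    subject to a between-subjects cell. The covariance is pooled within
    cells (error df N − g), projected through orthonormal contrasts.
    Returns (epsilon, mauchly_W, mauchly_p).
    """
    n, k = Y.shape
    uniq = np.unique(cells)
    g = len(uniq)
    d = n - g
    S = np.zeros((k, k))
    for c in uniq:
        yc = Y[cells == c]
        yc = yc - yc.mean(axis=0, keepdims=True)
        S += yc.T @ yc
    S /= d
    M = _orthonormal_contrasts(k)
    T = M @ S @ M.T
    f = k - 1
    eps = np.trace(T) ** 2 / (f * np.trace(T @ T))
    eps = float(np.clip(eps, 1.0 / f, 1.0))
    eigs = np.linalg.eigvalsh(T)
    if np.any(eigs <= 0):
        return eps, 0.0, 0.0
    logW = float(np.sum(np.log(eigs)) - f * np.log(np.mean(eigs)))
    W = float(np.exp(logW))
    # chi-square approximation with Box's second-order term, as in the
    # standard repeated-measures references (and R's mauchly.test)
    corr = 1.0 - (2 * f**2 + f + 2) / (6.0 * f * d)
    chi2 = -d * corr * logW
    w2 = (
        (f + 2) * (f - 1) * (f - 2) * (2 * f**3 + 6 * f**2 + 3 * k + 2)
        / (288.0 * (d * f * corr) ** 2)
    )
    dof = f * (f + 1) / 2 - 1
    p1 = sps.chi2.sf(chi2, dof)
    p2 = sps.chi2.sf(chi2, dof + 4)
    p = float(p1 + w2 * (p2 - p1))
    return eps, W, p


def _between_terms(a: np.ndarray, b: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "intercept": np.ones((a.shape[0], 1)),
        "concert_status": a[:, None],
        "listener_preference": b[:, None],
        "concert_status * listener_preference": (a * b)[:, None],
    }


def _eta(ss_eff: float, ss_err: float) -> float:
    return ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0


def _wide_measures(
    measures: pd.DataFrame, measure_name: str, songs: list[int]
) -> tuple[pd.DataFrame, np.ndarray]:
    sub = measures[
        (measures["measure_name"] == measure_name) & (measures["song_index"].isin(songs))
    ]
    try:
        wide = sub.pivot(
            index=["participant_id", "concert_status", "listener_preference"],
            columns="song_index",
            values="value",
        )
    except ValueError as exc:  # duplicate (participant, song) rows
        raise ValueError(f"duplicate rows in measure table for {measure_name}") from exc
    if wide.isna().any().any() or wide.shape[1] != len(songs):
        missing = wide.columns[wide.isna().any()].tolist() or "songs"
        raise ValueError(
            f"incomplete within-subject data for {measure_name}: missing cells in {missing}"
        )
    wide = wide[songs]
    return wide.reset_index(), wide.to_numpy()


# ---------------------------------------------------------------------------
# Mixed (split-plot) ANOVA for songs 1–7
# ---------------------------------------------------------------------------


def mixed_anova(
    measures: pd.DataFrame,
    measure_name: str,
    songs: list[int] | None = None,
    mauchly_trigger_p: float = MAUCHLY_TRIGGER_P,
) -> AnovaReport:
    """2 × 2 × k split-plot ANOVA on a long-format measure table.

    ``measures`` columns: participant_id, concert_status, listener_preference,
    song_index, measure_name, value. Every included participant must have all
    ``songs`` (no imputation).
    """
    if songs is None:
        songs = list(range(1, 8))
    meta, Y = _wide_measures(measures, measure_name, songs)
    n, k = Y.shape
    a = _sum_code_two_level(meta["concert_status"], ("live", "album"))
    b = _sum_code_two_level(meta["listener_preference"], ("fan", "neutral"))
    cells = np.char.add(meta["concert_status"].to_numpy().astype(str),
                        meta["listener_preference"].to_numpy().astype(str))
    g = len(np.unique(cells))

    effects: dict[str, EffectResult] = {}

    # --- between-subjects stratum: tests on subject means ------------------
    m = Y.mean(axis=1)
    terms = _between_terms(a, b)
    ss_b, rss_b = _partial_ss(m, terms)
    df_den_b = n - g
    for name in ("concert_status", "listener_preference", "concert_status * listener_preference"):
        # SS on subject means scale by k to match the split-plot decomposition
        ss_eff, ss_err = k * ss_b[name], k * rss_b
        F, p = _f_and_p(ss_eff, 1.0, ss_err, df_den_b)
        effects[name] = EffectResult(
            name, ss_eff, 1.0, float(df_den_b), float(F), p, _eta(ss_eff, ss_err), "between"
        )

    # --- within-subjects stratum: song and song × between interactions -----
    W = Y - m[:, None]  # subject-mean deviations, (n, k)
    w_long = W.ravel()  # subject-major order
    Cs = _song_contrasts(k)  # (k, k-1)
    song_cols = np.tile(Cs, (n, 1))  # row (i, j) -> contrasts of song j
    rep = np.repeat(np.arange(n), k)
    w_terms = {
        "song": song_cols,
        "song * concert_status": song_cols * a[rep, None],
        "song * listener_preference": song_cols * b[rep, None],
        "song * concert_status * listener_preference": song_cols * (a * b)[rep, None],
    }
    ss_w, rss_w = _partial_ss(w_long, w_terms)
    df_err_w = (n - g) * (k - 1)
    eps, mW, mp = _sphericity(Y, cells)
    correct = mp < mauchly_trigger_p
    for name, ss_eff in ss_w.items():
        df_num = float(k - 1)
        F, p_raw = _f_and_p(ss_eff, df_num, rss_w, df_err_w)
        if correct and np.isfinite(F):
            p = float(sps.f.sf(F, eps * df_num, eps * df_err_w))
            df_rep = (eps * df_num, eps * df_err_w)
        else:
            p, df_rep = p_raw, (df_num, float(df_err_w))
        effects[name] = EffectResult(
            name,
            ss_eff,
            df_rep[0],
            df_rep[1],
            float(F),
            p,
            _eta(ss_eff, rss_w),
            "within",
            epsilon=eps,
            mauchly_W=mW,
            mauchly_p=mp,
            gg_corrected=correct,
            p_uncorrected=p_raw,
        )

    long_sub = measures[
        (measures["measure_name"] == measure_name) & (measures["song_index"].isin(songs))
    ]
    return AnovaReport(
        measure=measure_name,
        effects=effects,
        cell_means=summarize_cells(long_sub),
        n_subjects=n,
        error_ss={"between": k * rss_b, "within": rss_w},
    )


def song8_anova(
    measures: pd.DataFrame, measure_name: str, song_index: int = 8
) -> AnovaReport:
    """2 × 2 between-subjects ANOVA on a single song's values."""
    sub = measures[
        (measures["measure_name"] == measure_name) & (measures["song_index"] == song_index)
    ]
    if sub["participant_id"].duplicated().any():
        raise ValueError("one value per participant expected")
    y = sub["value"].to_numpy(dtype=float)
    a = _sum_code_two_level(sub["concert_status"], ("live", "album"))
    b = _sum_code_two_level(sub["listener_preference"], ("fan", "neutral"))
    n = len(y)
    g = len(sub.groupby(["concert_status", "listener_preference"]))
    ss, rss = _partial_ss(y, _between_terms(a, b))
    df_den = n - g
    effects = {}
    for name in ("concert_status", "listener_preference", "concert_status * listener_preference"):
        F, p = _f_and_p(ss[name], 1.0, rss, df_den)
        effects[name] = EffectResult(
            name, ss[name], 1.0, float(df_den), float(F), p, _eta(ss[name], rss), "between"
        )
    return AnovaReport(
        measure=measure_name,
        effects=effects,
        cell_means=summarize_cells(sub),
        n_subjects=n,
        error_ss={"between": rss},
    )


# ---------------------------------------------------------------------------
# Pairwise comparisons, t-tests, summaries
# ---------------------------------------------------------------------------


def bonferroni_pairwise(p_values) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, p · m) over the m comparisons."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if p.size == 0:
        raise ValueError("need at least one comparison")
    return np.minimum(p * p.size, 1.0)


@dataclass(frozen=True)
class TTestResult:
    outcome: str
    t: float
    df: int
    p: float
    mean_musician: float
    mean_non_musician: float


def musician_ttests(measures: pd.DataFrame, participants: pd.DataFrame) -> list[TTestResult]:
    """Pooled-variance independent-samples t-tests, musicians vs non-musicians.

    Four outcomes: vigour mean of songs 1–7, vigour song 8, entrainment mean
    of songs 1–7, entrainment song 8. Pooled variance gives the conventional
    integer df n1 + n2 − 2.
    """
    flags = participants.set_index("participant_id")["musician"].astype(bool)
    results = []
    for measure_name in ("vigour", "entrainment"):
        sub = measures[measures["measure_name"] == measure_name]
        mean17 = (
            sub[sub["song_index"].isin(range(1, 8))]
            .groupby("participant_id")["value"]
            .mean()
        )
        s8 = sub[sub["song_index"] == 8].set_index("participant_id")["value"]
        for label, series in ((f"{measure_name}_songs_1_7", mean17), (f"{measure_name}_song_8", s8)):
            is_mus = flags.reindex(series.index).to_numpy()
            x = series.to_numpy()[is_mus]
            z = series.to_numpy()[~is_mus]
            if len(x) < 2 or len(z) < 2:
                raise ValueError(f"{label}: each group needs at least 2 participants")
            df = len(x) + len(z) - 2
            sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(z) - 1) * z.var(ddof=1)) / df
            diff = x.mean() - z.mean()
            if sp2 == 0.0:
                t = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
            else:
                t = diff / np.sqrt(sp2 * (1 / len(x) + 1 / len(z)))
            p = float(2 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
            results.append(
                TTestResult(
                    label, float(t), len(x) + len(z) - 2, float(p), float(x.mean()), float(z.mean())
                )
            )
    return results


def summarize_cells(measures: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Mean ± SEM per factor level and per 2 × 2 cell, pooled over subjects.

    Each participant contributes one value (their song-mean) so the SEM
    reflects between-subject variability. A single-subject level reports
    SEM as NaN (not estimable).
    """
    per_subj = (
        measures.groupby(["participant_id", "concert_status", "listener_preference"])[value_col]
        .mean()
        .reset_index()
    )

    def _agg(df: pd.DataFrame, by: list[str], grouping: str) -> pd.DataFrame:
        out = (
            df.groupby(by)[value_col]
            .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
            .reset_index()
        )
        out["sem"] = out["sd"] / np.sqrt(out["n"])
        out.insert(0, "grouping", grouping)
        levels = out[by].astype(str).agg(" / ".join, axis=1)
        out.insert(1, "level", levels)
        return out.drop(columns=by + ["sd"])

    parts = [
        _agg(per_subj, ["concert_status"], "concert_status"),
        _agg(per_subj, ["listener_preference"], "listener_preference"),
        _agg(per_subj, ["concert_status", "listener_preference"], "cell"),
    ]
    return pd.concat(parts, ignore_index=True)
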