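import numpy as np
import pandas as pd
import pytest

from headsway.stats import (
    bonferroni_pairwise,
    filter_cohort,
    mixed_anova,
    musician_ttests,
    song8_anova,
    summarize_cells,
)

from conftest import make_measure_table


def _split_plot_fixture() -> pd.DataFrame:
    """Fixed unbalanced split-plot dataset with group and song effects and a
    deliberately non-spherical (heteroscedastic-across-songs) error.

    The expected ANOVA results frozen in ``R_ORACLE`` below were computed for
    exactly this dataset with an independent reference implementation
    (R, car::Anova type-III with a repeated-measures idesign, including
    Mauchly's test and the Greenhouse–Geisser adjustment).
    """
    rng = np.random.default_rng(20260927)
    cells = [("live", "fan", 15), ("live", "neutral", 9), ("album", "fan", 17),
             ("album", "neutral", 8)]
    song_fx = np.array([0.0, 0.5, -0.3, 0.8, 0.2, -0.6, 0.4])
    rows = []
    pid = 0
    for c, p, n in cells:
        for _ in range(n):
            pid += 1
            subj = rng.normal(0, 1.0)
            base = 2.0 + (0.8 if c == "live" else 0) + (0.6 if p == "fan" else 0)
            noise = rng.normal(0, 0.3 + 0.25 * np.arange(7))
            vals = base + subj + song_fx + (0.2 * song_fx if p == "fan" else 0) + noise
            for j, v in enumerate(vals, start=1):
                rows.append(
                    dict(participant_id=f"P{pid:03d}", concert_status=c,
                         listener_preference=p, song_index=j,
                         measure_name="vigour", value=v)
                )
    return pd.DataFrame(rows)


# effect -> (SS, F, p reported after GG when triggered, epsilon, mauchly_W)
R_ORACLE = {
    "concert_status": (27.1399985, 3.03492, 0.088323, None, None),
    "listener_preference": (15.9502836, 1.78363, 0.188420, None, None),
    "concert_status * listener_preference": (4.9494657, 0.55347, 0.460770, None, None),
    "song": (80.5139068, 9.63573, 7.163422e-07, 0.6389107799, 0.09134893655),
    "song * concert_status": (8.7478309, 1.04692, 0.3830581450, 0.6389107799, 0.09134893655),
    "song * listener_preference": (16.9590584, 2.02962, 0.0952825796, 0.6389107799, 0.09134893655),
    "song * concert_status * listener_preference": (
        22.8356374, 2.73292, 0.0326912400, 0.6389107799, 0.09134893655),
}
R_ERROR_SS = {"between": 402.4162480, "within": 376.0092966}


class TestMixedAnovaAgainstReference:
    def test_all_effects_match_reference_implementation(self):
        rep = mixed_anova(_split_plot_fixture(), "vigour")
        assert set(rep.effects) == set(R_ORACLE)
        for name, (ss, F, p, eps, W) in R_ORACLE.items():
            e = rep.effects[name]
            assert e.ss == pytest.approx(ss, rel=1e-6), name
            assert e.F == pytest.approx(F, rel=1e-5), name
            assert e.p == pytest.approx(p, rel=1e-4), name
            if eps is not None:
                assert e.gg_corrected  # Mauchly p ~1e-13 triggers the correction
                assert e.epsilon == pytest.approx(eps, rel=1e-6)
                assert e.mauchly_W == pytest.approx(W, rel=1e-6)
                assert e.mauchly_p < 1e-10
        assert rep.error_ss["between"] == pytest.approx(R_ERROR_SS["between"], rel=1e-6)
        assert rep.error_ss["within"] == pytest.approx(R_ERROR_SS["within"], rel=1e-6)

    def test_between_effect_dfs_for_table1_cell_sizes(self, rng):
        rep = mixed_anova(make_measure_table(rng, n_songs=7), "vigour")
        for name in ("concert_status", "listener_preference",
                     "concert_status * listener_preference"):
            assert rep.effects[name].df_num == 1
            assert rep.effects[name].df_den == 45  # 49 subjects - 4 cells

    def test_eta_squared_identity_on_every_row(self, rng):
        """ηp² must equal F·df_num / (F·df_num + df_den) on the uncorrected df."""
        rep = mixed_anova(
            make_measure_table(rng, concert_shift=2.0, song_effects=np.arange(8) * 0.3),
            "vigour",
        )
        for e in rep.effects.values():
            df_num = 1.0 if e.stratum == "between" else 6.0
            df_den = 45.0 if e.stratum == "between" else 270.0
            assert e.partial_eta_sq == pytest.approx(
                e.F * df_num / (e.F * df_num + df_den), rel=1e-9
            )

    def test_incomplete_design_rejected(self, rng):
        table = make_measure_table(rng, n_songs=7)
        table = table[
            ~((table["participant_id"] == "P001") & (table["song_index"] == 3))
        ]
        with pytest.raises(ValueError, match="incomplete"):
            mixed_anova(table, "vigour")

    def test_compound_symmetric_data_rarely_triggers_correction(self, rng):
        """Under exchangeable songs (compound symmetry) the correction stays
        off in ≥90% of replicates (Mauchly fires at ~α), and epsilon sits near
        its null sampling mean — well above the 1/(k−1) floor, though below 1
        because the Greenhouse–Geisser estimator is biased downward at
        finite n (n=49, k=7)."""
        eps_vals = []
        trigger_off = 0
        n_rep = 60
        for _ in range(n_rep):
            rep = mixed_anova(make_measure_table(rng, n_songs=7), "vigour")
            e = rep.effects["song"]
            eps_vals.append(e.epsilon)
            trigger_off += not e.gg_corrected
        assert trigger_off / n_rep >= 0.9
        assert np.mean(eps_vals) >= 0.8  # null sampling mean ≈ 0.87 ≫ floor 0.167
        assert min(eps_vals) > 1 / 6


class TestSphericityAgainstPingouin:
    def test_epsilon_and_mauchly_match_pingouin_single_group(self, rng):
        import pingouin as pg

        from headsway.stats import _sphericity

        Y = rng.normal(size=(30, 5)) * np.array([1.0, 1.3, 0.7, 2.0, 1.1])
        cells = np.zeros(30, dtype=int)
        eps, W, p = _sphericity(Y, cells)
        df = pd.DataFrame(Y)
        assert eps == pytest.approx(pg.epsilon(df, correction="gg"), rel=1e-9)
        spher = pg.sphericity(df)
        assert W == pytest.approx(spher.W, rel=1e-9)
        assert p == pytest.approx(spher.pval, rel=1e-6)


class TestSong8Anova:
    def test_matches_statsmodels_type3_on_unbalanced_data(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        table = make_measure_table(rng, n_songs=8, concert_shift=1.5, pref_shift=-0.8)
        rep = song8_anova(table, "vigour")
        sub = table[(table["song_index"] == 8) & (table["measure_name"] == "vigour")]
        ols = smf.ols(
            "value ~ C(concert_status, Sum) * C(listener_preference, Sum)", data=sub
        ).fit()
        sm_tab = sm.stats.anova_lm(ols, typ=3)
        pairs = {
            "concert_status": "C(concert_status, Sum)",
            "listener_preference": "C(listener_preference, Sum)",
            "concert_status * listener_preference":
                "C(concert_status, Sum):C(listener_preference, Sum)",
        }
        for mine, theirs in pairs.items():
            assert rep.effects[mine].F == pytest.approx(sm_tab.loc[theirs, "F"], rel=1e-8)
            assert rep.effects[mine].p == pytest.approx(sm_tab.loc[theirs, "PR(>F)"], rel=1e-8)
        assert rep.effects["concert_status"].df_den == 45

    def test_all_equal_values_give_zero_f(self, rng):
        table = make_measure_table(rng, n_songs=8, subject_sd=0.0, noise_sd=0.0)
        rep = song8_anova(table, "vigour")
        for e in rep.effects.values():
            assert e.F == 0.0


class TestFilterCohort:
    def _participants(self, rng, pattern=None):
        from headsway.synthetic import CohortSimSpec, _participant_rows

        spec = CohortSimSpec(exclusion_pattern=pattern, seed=1)
        return _participant_rows(spec, rng)

    def test_study_flag_pattern_retains_49(self, rng):
        pattern = {"abnormal_hearing": 1, "movement_restriction": 1,
                   "prior_song_exposure": 3, "no_followup": 6}
        table = self._participants(rng, pattern)
        assert len(table) == 60
        kept, counts = filter_cohort(table)
        assert len(kept) == 49
        assert counts == pattern | {}

    def test_no_flags_leaves_table_unchanged(self, rng):
        table = self._participants(rng)
        kept, counts = filter_cohort(table)
        assert len(kept) == len(table)
        assert all(v == 0 for v in counts.values())

    def test_all_flagged_warns_and_returns_empty(self, rng):
        table = self._participants(rng)
        table["no_followup"] = True
        with pytest.warns(UserWarning):
            kept, _ = filter_cohort(table)
        assert kept.empty


class TestBonferroni:
    @pytest.mark.parametrize(
        "pvals, expected",
        [([0.01, 0.02, 0.04], [0.03, 0.06, 0.12]), ([0.5, 0.6, 0.7], [1.0, 1.0, 1.0]),
         ([0.03], [0.03])],
    )
    def test_examples(self, pvals, expected):
        np.testing.assert_allclose(bonferroni_pairwise(pvals), expected)

    def test_never_below_raw_never_above_one(self, rng):
        p = rng.uniform(size=20)
        adj = bonferroni_pairwise(p)
        assert (adj >= p).all() and (adj <= 1.0).all()


class TestMusicianTTests:
    def _measures_with_flags(self, rng, shift=0.0, noise=1.0, n_mus=25, n_non=24):
        rows, flags = [], []
        for i in range(n_mus + n_non):
            musician = i < n_mus
            flags.append({"participant_id": f"P{i:03d}", "musician": musician})
            base = 10.0 + (shift if musician else 0.0) + rng.normal(0, noise)
            for measure in ("vigour", "entrainment"):
                for song in range(1, 9):
                    rows.append(
                        {"participant_id": f"P{i:03d}", "song_index": song,
                         "measure_name": measure, "value": base + rng.normal(0, 0.1)}
                    )
        return pd.DataFrame(rows), pd.DataFrame(flags)

    def test_pooled_df_is_47_for_25_vs_24(self, rng):
        measures, flags = self._measures_with_flags(rng)
        for res in musician_ttests(measures, flags):
            assert res.df == 47

    def test_identical_groups_give_t_zero_p_one(self, rng):
        measures, flags = self._measures_with_flags(rng, noise=0.0)
        measures["value"] = 5.0
        for res in musician_ttests(measures, flags):
            assert res.t == pytest.approx(0.0, abs=1e-12)
            assert res.p == pytest.approx(1.0)

    def test_three_sd_separation_detected(self, rng):
        """Groups 3 pooled SDs apart at n=25/24: p < 0.001 in ≥99% of runs."""
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            measures, flags = self._measures_with_flags(rng, shift=3.0, noise=1.0)
            hits += all(r.p < 0.001 for r in musician_ttests(measures, flags))
        assert hits / n_rep >= 0.99

    def test_tiny_group_rejected(self, rng):
        measures, flags = self._measures_with_flags(rng, n_mus=1, n_non=48)
        with pytest.raises(ValueError):
            musician_ttests(measures, flags)


class TestSummaries:
    def test_mean_and_sem_example(self):
        table = pd.DataFrame(
            {"participant_id": ["a", "b", "c"], "concert_status": ["live"] * 3,
             "listener_preference": ["fan"] * 3, "song_index": [1, 1, 1],
             "measure_name": ["vigour"] * 3, "value": [1.0, 2.0, 3.0]}
        )
        out = summarize_cells(table)
        row = out[(out["grouping"] == "concert_status")].iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sem"] == pytest.approx(1.0 / np.sqrt(3))

    def test_constant_values_give_zero_sem(self):
        table = pd.DataFrame(
            {"participant_id": list("abcd"), "concert_status": ["live"] * 4,
             "listener_preference": ["fan"] * 4, "song_index": [1] * 4,
             "measure_name": ["vigour"] * 4, "value": [7.0] * 4}
        )
        assert (summarize_cells(table)["sem"] == 0).all()

    def test_single_value_sem_not_available(self):
        table = pd.DataFrame(
            {"participant_id": ["a"], "concert_status": ["live"],
             "listener_preference": ["fan"], "song_index": [1],
             "measure_name": ["vigour"], "value": [7.0]}
        )
        assert summarize_cells(table)["sem"].isna().all()
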