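"""Synthetic study generator: counts, determinism, moments, direction."""

import numpy as np
import pandas as pd
import pytest

from riskframe.simulate import (
    GeneratorTruth,
    gen_choices,
    gen_cpt_choices,
    gen_endowment,
    gen_hormones,
    simulate_study,
    t_change_from_panel,
)


class TestTruthValidation:
    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            GeneratorTruth(sigma_subject=(-0.1, 0.2, 0.2, 0.2))

    def test_invalid_correlation_rejected(self):
        bad = np.eye(4)
        bad[0, 1] = 0.5  # asymmetric
        with pytest.raises(ValueError):
            GeneratorTruth(correlation=bad)

    def test_nonpsd_correlation_rejected(self):
        bad = np.eye(4)
        bad[0, 1] = bad[1, 0] = 0.9
        bad[0, 2] = bad[2, 0] = 0.9
        bad[1, 2] = bad[2, 1] = -0.9
        with pytest.raises(ValueError):
            GeneratorTruth(correlation=bad)


class TestChoices:
    def test_record_count(self, games):
        truth = GeneratorTruth(n_subjects=40)
        choices = gen_choices(truth, games, seed=1)
        assert len(choices) == 40 * len(games) * 2  # 800 for Table-1 games

    def test_null_coefficients_give_half_risky_share(self, games):
        truth = GeneratorTruth(
            n_subjects=100, a=(0, 0), b=(0, 0), delta_a=(0, 0),
            delta_b=(0, 0), sigma_subject=(0, 0, 0, 0),
            correlation=np.eye(4),
        )
        choices = gen_choices(truth, games, seed=2)
        share = choices["choice"].mean()
        assert abs(share - 0.5) < 3 * np.sqrt(0.25 / len(choices))

    def test_positive_framing_share_increases_with_t_change(self, games):
        """Under the default (published-regime) truth, subjects with larger
        testosterone changes take more positive-framing risks."""
        from scipy.stats import spearmanr

        truth = GeneratorTruth(n_subjects=200)
        choices = gen_choices(truth, games, seed=3)
        pos = choices[choices["framing"] == "positive"]
        per = pos.groupby(["subject_id", "treatment"]).agg(
            share=("choice", "mean"), t=("t_change", "first")
        )
        rho, _ = spearmanr(per["t"], per["share"])
        assert rho > 0

    def test_empty_games_rejected(self):
        with pytest.raises(ValueError):
            gen_choices(GeneratorTruth(n_subjects=2), [], seed=1)


class TestHormones:
    def test_deterministic_under_seed(self):
        truth = GeneratorTruth(n_subjects=10)
        a = gen_hormones(truth, seed=5)
        b = gen_hormones(truth, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_large_sample_moments_match_study(self):
        truth = GeneratorTruth(n_subjects=10_000)
        panel = gen_hormones(truth, seed=6)
        t1 = panel.query(
            "treatment == 'testosterone' and timepoint == 'T1'"
        )["testosterone"]
        assert t1.mean() == pytest.approx(33.76, rel=0.02)
        t0 = panel.query(
            "treatment == 'testosterone' and timepoint == 'T0'"
        )["testosterone"]
        assert t0.mean() == pytest.approx(18.53, rel=0.02)

    def test_placebo_t_change_near_zero(self):
        truth = GeneratorTruth(n_subjects=2000)
        panel = gen_hormones(truth, seed=7)
        tch = t_change_from_panel(panel)
        placebo = tch[tch["treatment"] == "placebo"]["t_change"]
        assert abs(placebo.mean()) < 0.05

    def test_cortisol_declines_in_both_arms(self):
        truth = GeneratorTruth(n_subjects=500)
        panel = gen_hormones(truth, seed=8)
        by = panel.groupby(["treatment", "timepoint"])["cortisol"].mean()
        for arm in ("placebo", "testosterone"):
            assert by[arm]["T1"] < by[arm]["T0"]

    def test_concentrations_positive(self):
        panel = gen_hormones(GeneratorTruth(n_subjects=500), seed=9)
        assert (panel["testosterone"] > 0).all()
        assert (panel["cortisol"] > 0).all()

    def test_absolute_t_change_definition(self):
        panel = gen_hormones(GeneratorTruth(n_subjects=5), seed=10)
        rel = t_change_from_panel(panel, "relative")
        ab = t_change_from_panel(panel, "absolute")
        wide = panel.pivot_table(index=["subject_id", "treatment"],
                                 columns="timepoint", values="testosterone")
        merged = rel.merge(ab, on=["subject_id", "treatment"],
                           suffixes=("_rel", "_abs"))
        np.testing.assert_allclose(
            merged["t_change_abs"],
            (wide["T1"] - wide["T0"]).to_numpy(),
        )
        with pytest.raises(ValueError):
            t_change_from_panel(panel, "percent")


class TestEndowmentGenerator:
    def test_record_count(self):
        truth = GeneratorTruth(n_subjects=7)
        records = gen_endowment(truth, n_items_per_type=3, seed=11)
        # subjects x items x 2 roles x 2 sessions
        assert len(records) == 7 * 6 * 2 * 2

    def test_degenerate_truth_gives_wta_equal_wtp(self):
        truth = GeneratorTruth(
            n_subjects=4, mu_type_hedonic=0.0, mu_type_utilitarian=0.0,
            endow_sigma_item=0.0, endow_sigma_subject=0.0,
            endow_sigma_resid=0.0, endow_b=0.0,
        )
        records = gen_endowment(truth, n_items_per_type=2, seed=12)
        wide = records.pivot_table(
            index=["subject_id", "treatment", "item_id"], columns="role",
            values="value",
        )
        np.testing.assert_allclose(wide["WTA"], wide["WTP"], rtol=1e-12)

    def test_goods_type_ordering(self):
        truth = GeneratorTruth(
            n_subjects=200, mu_type_hedonic=np.log(2.0),
            mu_type_utilitarian=np.log(1.4),
        )
        records = gen_endowment(truth, n_items_per_type=5, seed=13)
        wide = records.pivot_table(
            index=["subject_id", "treatment", "item_id", "goods_type"],
            columns="role", values="value",
        ).reset_index()
        wide["ratio"] = wide["WTA"] / wide["WTP"]
        means = wide.groupby("goods_type")["ratio"].mean()
        assert means["hedonic"] > means["utilitarian"]


class TestCPTChoices:
    def test_count_and_determinism(self, games):
        a = gen_cpt_choices(games, alpha=(0.8, 0.8), c=(0.7, 0.7), phi=1.0,
                            n_subjects=6, seed=14, n_repeats=2)
        b = gen_cpt_choices(games, alpha=(0.8, 0.8), c=(0.7, 0.7), phi=1.0,
                            n_subjects=6, seed=14, n_repeats=2)
        assert len(a) == 6 * len(games) * 2
        pd.testing.assert_frame_equal(a, b)


class TestSimulateStudy:
    def test_all_frames_share_one_hormone_panel(self, games):
        sim = simulate_study(GeneratorTruth(n_subjects=6), seed=15,
                             games=games, n_items_per_type=2)
        tmap = t_change_from_panel(sim["hormones"]).set_index(
            ["subject_id", "treatment"])["t_change"]
        sample = sim["choices"].drop_duplicates(["subject_id", "treatment"])
        for _, row in sample.iterrows():
            assert row["t_change"] == pytest.approx(
                tmap.loc[(row["subject_id"], row["treatment"])]
            )
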