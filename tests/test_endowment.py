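"""Endowment analysis: ratios, tests, multilevel fits, hormone ANOVA."""

import numpy as np
import pandas as pd
import pytest

from riskframe.endowment import (
    EndowmentModel,
    EndowmentParams,
    build_ratios,
    hormone_anova,
)
from riskframe.endowment import test_endowment as endowment_ttest
from riskframe.sampling import SamplerConfig
from riskframe.simulate import (
    GeneratorTruth,
    gen_endowment,
    gen_hormones,
    t_change_from_panel,
)


def _bid_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["subject_id", "treatment", "item_id", "goods_type", "role",
                 "value"],
    )


class TestBuildRatios:
    def test_equal_bids_give_unit_ratios(self):
        rows = []
        for s in ("s1", "s2"):
            for i in ("h1", "u1"):
                gt = "hedonic" if i.startswith("h") else "utilitarian"
                rows += [(s, "placebo", i, gt, "WTA", 12.0),
                         (s, "placebo", i, gt, "WTP", 12.0)]
        ratios, report = build_ratios(_bid_frame(rows))
        assert (ratios["ratio"] == 1.0).all()
        assert report.excluded_subjects == []

    def test_simple_ratio(self):
        rows = [("s1", "placebo", "h1", "hedonic", "WTA", 15.0),
                ("s1", "placebo", "h1", "hedonic", "WTP", 10.0)]
        ratios, _ = build_ratios(_bid_frame(rows))
        assert ratios["ratio"].iloc[0] == pytest.approx(1.5)

    def test_repeated_presentations_averaged(self):
        rows = [("s1", "placebo", "h1", "hedonic", "WTA", 10.0),
                ("s1", "placebo", "h1", "hedonic", "WTA", 20.0),
                ("s1", "placebo", "h1", "hedonic", "WTP", 10.0)]
        ratios, _ = build_ratios(_bid_frame(rows))
        assert ratios["ratio"].iloc[0] == pytest.approx(1.5)

    def test_heavy_zero_bidder_excluded(self):
        rows = []
        for j in range(10):
            val = 0.0 if j < 4 else 10.0  # 40% zeros
            rows += [("s1", "placebo", f"h{j}", "hedonic", "WTA", val),
                     ("s1", "placebo", f"h{j}", "hedonic", "WTP", 10.0)]
        for j in range(10):
            rows += [("s2", "placebo", f"h{j}", "hedonic", "WTA", 12.0),
                     ("s2", "placebo", f"h{j}", "hedonic", "WTP", 10.0)]
        ratios, report = build_ratios(_bid_frame(rows))
        assert report.excluded_subjects == ["s1"]
        assert set(ratios["subject_id"]) == {"s2"}

    def test_zero_wtp_cell_dropped_and_counted(self):
        rows = [("s1", "placebo", "h1", "hedonic", "WTA", 15.0),
                ("s1", "placebo", "h1", "hedonic", "WTP", 0.0),
                ("s1", "placebo", "h2", "hedonic", "WTA", 15.0),
                ("s1", "placebo", "h2", "hedonic", "WTP", 10.0)] + [
                ("s1", "placebo", f"x{j}", "hedonic", "WTP", 5.0)
                for j in range(20)]  # keep zero fraction below threshold
        ratios, report = build_ratios(_bid_frame(rows))
        assert report.dropped_cells_zero_wtp == 1
        assert len(ratios) == 1

    def test_unmatched_cells_reported(self):
        rows = [("s1", "placebo", "h1", "hedonic", "WTA", 15.0),
                ("s1", "placebo", "h2", "hedonic", "WTA", 15.0),
                ("s1", "placebo", "h2", "hedonic", "WTP", 10.0)]
        ratios, report = build_ratios(_bid_frame(rows))
        assert len(report.unmatched_cells) == 1
        assert report.unmatched_cells[0][2] == "h1"


class TestTTest:
    def test_all_unit_ratios_degenerate(self):
        res = endowment_ttest(np.ones(10))
        assert res.t == 0.0
        assert res.p_value == 0.5
        assert res.degenerate

    def test_statistic_matches_oracle_formula(self):
        rng = np.random.default_rng(6)
        x = rng.lognormal(0.3, 0.4, 40)
        res = endowment_ttest(x)
        oracle = (x.mean() - 1.0) / (x.std(ddof=1) / np.sqrt(len(x)))
        assert res.t == pytest.approx(oracle, rel=1e-10)

    def test_power_at_moderate_effect(self):
        rng = np.random.default_rng(7)
        x = rng.lognormal(0.5, 0.3, 500)
        res = endowment_ttest(x)
        assert res.p_value < 1e-3
        assert res.bayes_factor > 100

    def test_minimum_sample(self):
        with pytest.raises(ValueError):
            endowment_ttest(np.array([1.5]))


class TestLoglikeOracle:
    def test_matches_bruteforce_normal_sum(self, endowment_panel):
        records = endowment_panel["records"]
        small = records[records["item_id"].isin(["h01", "u01"])]
        model = EndowmentModel(small, variant="item+subject",
                               t_change=endowment_panel["t_change"])
        rng = np.random.default_rng(1)
        params = EndowmentParams(
            mu0=0.4,
            mu_ind={s: rng.normal(0, 0.3) for s in model.subjects},
            g_item={i: rng.normal(0, 0.2) for i in model.items},
            sigma_resid=0.35,
        )
        total = 0.0
        for _, row in model.ratios.iterrows():
            m = (params.mu0 + params.mu_ind[row["subject_id"]]
                 + params.g_item[row["item_id"]])
            r = np.log(row["ratio"]) - m
            total += (-0.5 * (r / 0.35) ** 2 - np.log(0.35)
                      - 0.5 * np.log(2 * np.pi))
        assert model.loglike(params) == pytest.approx(total, abs=1e-8)


class TestScaleInvariance:
    def test_ratios_and_posterior_invariant_to_currency_units(
        self, endowment_panel
    ):
        records = endowment_panel["records"]
        scaled = records.copy()
        scaled["value"] = scaled["value"] * 100.0
        r1, _ = build_ratios(records)
        r2, _ = build_ratios(scaled)
        np.testing.assert_allclose(r1["ratio"], r2["ratio"], rtol=1e-12)
        t1, t2 = endowment_ttest(r1), endowment_ttest(r2)
        assert t1.t == pytest.approx(t2.t, rel=1e-12)
        # same ratio table (up to float rounding) and same seed => the
        # mu0 posteriors agree within Monte-Carlo error
        cfg = SamplerConfig(chains=1, draws=150, warmup=200)
        f1 = EndowmentModel(records).fit(cfg, seed=5, check_convergence=False)
        f2 = EndowmentModel(scaled).fit(cfg, seed=5, check_convergence=False)
        assert f1.draws("mu0").mean() == pytest.approx(
            f2.draws("mu0").mean(), abs=0.05
        )


class TestFits:
    def test_wta_equals_wtp_concentrates_ratio_at_one(self):
        rng = np.random.default_rng(8)
        rows = []
        for s in range(8):
            for j in range(6):
                gt = "hedonic" if j < 3 else "utilitarian"
                v = float(rng.lognormal(3, 0.5))
                rows += [(f"s{s}", "placebo", f"i{j}", gt, "WTA", v),
                         (f"s{s}", "placebo", f"i{j}", gt, "WTP", v)]
        model = EndowmentModel(_bid_frame(rows))
        res = model.fit(SamplerConfig(chains=2, draws=300, warmup=300),
                        seed=6, check_convergence=False)
        mean, lo, hi = res.overall_ratio_hdi()
        assert lo <= 1.0 <= hi
        assert abs(np.log(mean)) < 0.1

    def test_goods_type_ordering_recovered(self, endowment_panel):
        model = EndowmentModel(endowment_panel["records"],
                               variant="goods_type")
        res = model.fit(SamplerConfig(chains=2, draws=400, warmup=400),
                        seed=7, check_convergence=False)
        # generator default: hedonic log(2.0) > utilitarian log(1.4)
        assert res.prob_hedonic_gt_utilitarian() > 0.95
        # mu_type estimates the per-type mean log ratio of this cohort
        mt = res.draws("mu_type")
        logmean = np.log(
            model.ratios.groupby("goods_type")["ratio"].apply(
                lambda r: np.exp(np.mean(np.log(r)))
            )
        )
        assert mt[:, 0].mean() == pytest.approx(logmean["hedonic"], abs=0.05)
        assert mt[:, 1].mean() == pytest.approx(logmean["utilitarian"],
                                                abs=0.05)

    def test_variant_validation(self, endowment_panel):
        with pytest.raises(ValueError, match="variant"):
            EndowmentModel(endowment_panel["records"], variant="bogus")
        with pytest.raises(ValueError, match="t_change"):
            EndowmentModel(endowment_panel["records"],
                           variant="item+subject+T")


class TestHormoneAnova:
    def test_constant_panel_gives_null_effects(self):
        rows = []
        for s in range(6):
            for tr in ("placebo", "testosterone"):
                for tp in ("T0", "T1"):
                    rows.append(
                        {"subject_id": f"s{s}", "treatment": tr,
                         "timepoint": tp, "testosterone": 20.0}
                    )
        res = hormone_anova(pd.DataFrame(rows), posthoc=False)
        assert (res["anova"]["F"] == 0.0).all()
        assert (res["anova"]["np2"] == 0.0).all()

    def test_partial_eta_squared_bounded(self):
        truth = GeneratorTruth(n_subjects=12)
        panel = gen_hormones(truth, seed=31)
        res = hormone_anova(panel, posthoc=False)
        assert ((res["anova"]["np2"] >= 0) & (res["anova"]["np2"] <= 1)).all()

    def test_interaction_detected_at_study_moments(self):
        """A panel drawn at the study's printed hormone moments shows a
        strong treatment-by-time interaction."""
        truth = GeneratorTruth(n_subjects=39)
        panel = gen_hormones(truth, seed=32)
        res = hormone_anova(panel)
        aov = res["anova"].set_index("Source")
        inter = aov.loc["treatment * timepoint"]
        assert inter["p_unc"] < 1e-3
        assert inter["np2"] > 0.3

    def test_unbalanced_panel_rejected(self):
        truth = GeneratorTruth(n_subjects=6)
        panel = gen_hormones(truth, seed=33)
        with pytest.raises(ValueError, match="cell"):
            hormone_anova(panel.iloc[:-2])

    def test_missing_values_rejected(self):
        truth = GeneratorTruth(n_subjects=6)
        panel = gen_hormones(truth, seed=34)
        panel.loc[0, "testosterone"] = np.nan
        with pytest.raises(ValueError):
            hormone_anova(panel)
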