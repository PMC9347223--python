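"""Framing-choice model: likelihood oracle, summaries, small fits."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from riskframe.framing import (
    ChoiceRecord,
    FramingChoiceModel,
    FramingCoefficients,
    PosteriorSummary,
    effect_size,
    linear_predictor,
    summarize_posterior,
)
from riskframe.prospect import CPTParams, gap, log_gap
from riskframe.sampling import SamplerConfig
from riskframe.simulate import GeneratorTruth, gen_choices


class TestLinearPredictor:
    def test_all_zero_coefficients_give_half(self, games_by_key):
        rec = ChoiceRecord("s1", "placebo", "g3", "positive", 1, t_change=0.5)
        eta = linear_predictor(
            rec, FramingCoefficients(), CPTParams.published_defaults(),
            games_by_key,
        )
        assert eta == 0.0
        assert expit(eta) == 0.5

    def test_intercept_only(self, games_by_key):
        coefs = FramingCoefficients(a=(-2.10, 0.0))
        rec = ChoiceRecord("s1", "placebo", "g3", "positive", 0, t_change=0.0)
        eta = linear_predictor(
            rec, coefs, CPTParams.published_defaults(), games_by_key
        )
        # sigmoid(-2.10) by independent arithmetic
        assert expit(eta) == pytest.approx(0.10909682119561293, rel=1e-10)
        assert expit(eta) == pytest.approx(0.109, abs=5e-4)

    def test_linear_in_t_change(self, games_by_key):
        cpt = CPTParams.published_defaults()
        coefs = FramingCoefficients(
            a=(-1.0, -2.0), b=(0.6, 0.6), delta_a=(0.2, -0.4),
            delta_b=(0.3, 0.0),
        )
        lg = log_gap(gap(games_by_key[("g2", "positive")], cpt))
        etas = [
            linear_predictor(
                ChoiceRecord("s", "t", "g2", "positive", 1, t_change=t),
                coefs, cpt, games_by_key,
            )
            for t in (0.0, 1.0, 2.0)
        ]
        slope = coefs.delta_a[0] + coefs.delta_b[0] * lg
        assert etas[1] - etas[0] == pytest.approx(slope, rel=1e-10)
        assert etas[2] - etas[1] == pytest.approx(slope, rel=1e-10)

    def test_unknown_game_rejected(self, games_by_key):
        rec = ChoiceRecord("s1", "placebo", "g99", "positive", 1)
        with pytest.raises(KeyError):
            linear_predictor(
                rec, FramingCoefficients(), CPTParams.published_defaults(),
                games_by_key,
            )


class TestLoglikeOracle:
    def test_matches_bruteforce_bernoulli_sum(self, games, games_by_key):
        """Model log-likelihood equals a record-by-record Bernoulli-logit sum
        computed independently from the CPT primitives."""
        truth = GeneratorTruth(n_subjects=5)
        choices = gen_choices(truth, games, seed=17)
        model = FramingChoiceModel(choices, games)
        assert model._design.n_obs <= 100

        rng = np.random.default_rng(0)
        cpt = CPTParams.published_defaults()
        for _ in range(3):
            coefs = FramingCoefficients(
                a=tuple(rng.normal(size=2)), b=tuple(rng.normal(size=2)),
                delta_a=tuple(rng.normal(size=2)),
                delta_b=tuple(rng.normal(size=2)),
                subject_offsets=rng.normal(size=(5, 4)) * 0.5,
            )
            # brute force: per record, sigmoid of the linear predictor
            total = 0.0
            for _, row in choices.iterrows():
                s_i = list(model.subjects).index(row["subject_id"])
                eta = linear_predictor(
                    ChoiceRecord(
                        row["subject_id"], row["treatment"], row["game_id"],
                        row["framing"], int(row["choice"]),
                        float(row["t_change"]),
                    ),
                    coefs, cpt, games_by_key, subject_index=s_i,
                )
                p = expit(eta)
                total += np.log(p if row["choice"] == 1 else 1 - p)
            assert model.loglike(coefs) == pytest.approx(total, abs=1e-8)


class TestSummaries:
    def test_degenerate_draws_match_published_odds(self):
        rows = summarize_posterior({"x": np.full(100, -2.10)})
        assert rows[0].odds == pytest.approx(0.12, abs=5e-3)
        assert rows[0].sd == 0.0

    def test_zero_draws(self):
        (row,) = summarize_posterior({"x": np.zeros(10)})
        assert row.odds == 1.0
        assert row.sd == 0.0

    def test_positive_beta_odds(self):
        (row,) = summarize_posterior({"x": np.full(50, 0.63)})
        # the published table prints 1.87 from unrounded posterior means
        assert row.odds == pytest.approx(1.87, abs=0.01)

    def test_odds_equals_exp_mean_exactly(self):
        rng = np.random.default_rng(4)
        draws = {f"p{i}": rng.normal(size=500) for i in range(5)}
        for row in summarize_posterior(draws):
            assert row.odds == pytest.approx(np.exp(row.mean), abs=1e-12)

    def test_hdi_brackets_mean_for_unimodal(self):
        rng = np.random.default_rng(5)
        (row,) = summarize_posterior({"x": rng.normal(1.0, 0.3, 100_000)})
        assert row.hdi_low <= row.mean <= row.hdi_high
        # normal 94% HDI is mean +/- 1.881 sd
        assert row.hdi_low == pytest.approx(1.0 - 1.881 * 0.3, abs=0.02)

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize_posterior({"x": np.array([])})


class TestEffectSize:
    @pytest.mark.parametrize(
        "mean, sd, expected, tol",
        [
            (0.24, 0.23, 1.04, 0.02),
            (0.27, 0.13, 2.077, 0.001),
            (0.0, 1.0, 0.0, 1e-12),
        ],
    )
    def test_values(self, mean, sd, expected, tol):
        s = PosteriorSummary("x", mean, sd, np.exp(mean), 0, 0)
        assert effect_size(s) == pytest.approx(expected, abs=tol)

    def test_zero_sd_rejected(self):
        s = PosteriorSummary("x", 1.0, 0.0, np.e, 1, 1)
        with pytest.raises(ValueError):
            effect_size(s)


class TestDesignValidation:
    def test_both_framings_required(self, games):
        truth = GeneratorTruth(n_subjects=4)
        choices = gen_choices(truth, games, seed=1)
        positive_only = choices[choices["framing"] == "positive"]
        with pytest.raises(ValueError, match="framing"):
            FramingChoiceModel(positive_only, games)

    def test_nonbinary_choice_rejected(self, games):
        truth = GeneratorTruth(n_subjects=4)
        choices = gen_choices(truth, games, seed=1)
        choices.loc[0, "choice"] = 2
        with pytest.raises(ValueError, match="binary"):
            FramingChoiceModel(choices, games)

    def test_hierarchical_needs_two_subjects(self, games):
        truth = GeneratorTruth(n_subjects=1)
        choices = gen_choices(truth, games, seed=1)
        with pytest.raises(ValueError, match="subjects"):
            FramingChoiceModel(choices, games, variant="hierarchical")

    def test_unknown_variant_rejected(self, games):
        truth = GeneratorTruth(n_subjects=4)
        choices = gen_choices(truth, games, seed=1)
        with pytest.raises(ValueError, match="variant"):
            FramingChoiceModel(choices, games, variant="fancy")


@pytest.fixture(scope="module")
def small_framing_fit(games, small_study, small_sampler):
    model = FramingChoiceModel(small_study["choices"], games)
    return model.fit(small_sampler, seed=23, check_convergence=False)


class TestSmallFit:
    def test_posterior_probabilities_in_unit_interval(self, small_framing_fit):
        p = small_framing_fit.predict_proba()
        assert np.all((p > 0) & (p < 1))

    def test_gamewise_predicted_share_tracks_observed(self, small_framing_fit):
        """Posterior-mean risky probability per game stays within sampling
        noise of the observed game-level risky share."""
        res = small_framing_fit
        df = res.model.choices.copy()
        df["p"] = res.predict_proba()
        by_game = df.groupby(["game_id", "framing"]).agg(
            observed=("choice", "mean"), predicted=("p", "mean"),
            n=("choice", "size"),
        )
        # binomial noise at n ~ 24 per game
        se = np.sqrt(0.25 / by_game["n"])
        assert (np.abs(by_game.observed - by_game.predicted) < 4 * se + 0.05).all()

    def test_summary_has_table_layout(self, small_framing_fit):
        s = small_framing_fit.summary()
        assert "Shift (intercept) negative framing" in s.index
        assert "delta beta (positive framing)" in s.index
        assert list(s.columns) == ["mean", "sd", "odds", "hdi 3%", "hdi 97%"]
        np.testing.assert_allclose(s["odds"], np.exp(s["mean"]), rtol=1e-12)

    def test_correlation_matrix_valid(self, small_framing_fit):
        corr = small_framing_fit.coefficients().correlation
        assert corr.shape == (4, 4)
        np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-8)
        assert np.linalg.eigvalsh(corr).min() > -1e-8


class TestDegenerateRegimes:
    def test_no_heterogeneity_shrinks_subject_scales(self, games):
        """Subject-effect scale posteriors concentrate near zero when the
        generator has no subject heterogeneity."""
        truth = GeneratorTruth(
            n_subjects=14, sigma_subject=(0.0, 0.0, 0.0, 0.0),
            correlation=np.eye(4),
        )
        choices = gen_choices(truth, games, seed=3)
        model = FramingChoiceModel(choices, games)
        res = model.fit(SamplerConfig(chains=2, draws=300, warmup=300),
                        seed=8, check_convergence=False)
        sig = res.idata.posterior["sigma_subject"].values.reshape(-1, 4)
        # clearly below the Half-Normal(1) prior mean (~0.80)
        assert np.all(sig.mean(axis=0) < 0.7)
        assert sig.mean() < 0.5

    def test_zero_t_change_leaves_delta_at_prior(self, games):
        """With no testosterone variation the delta coefficients carry no
        information and their posterior spread stays at the prior scale."""
        truth = GeneratorTruth(n_subjects=10)
        choices = gen_choices(truth, games, seed=4)
        choices["t_change"] = 0.0
        model = FramingChoiceModel(choices, games, variant="pooled+T")
        res = model.fit(SamplerConfig(chains=2, draws=400, warmup=400),
                        seed=9, check_convergence=False)
        for name in ("delta_a_positive", "delta_b_negative"):
            draws = res.population_draws()[name]
            # prior is Normal(0, 2)
            assert abs(draws.mean()) < 0.6
            assert 1.3 < draws.std() < 2.7
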