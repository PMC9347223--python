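"""Hierarchical Bayesian choice model for framed gambles with a hormone covariate.

The model is a Bernoulli-logit regression on the log-compressed
subjective-value gap between the risky and the sure option,

    logit p(risky) = Intercept_F + Beta_F * logGap,

with framing-specific intercept and slope that both shift linearly with the
within-session change in serum testosterone:

    Intercept_F = a_F + delta_a_F * Tchange + u_int[subject, F]
    Beta_F      = b_F + delta_b_F * Tchange + u_slope[subject, F]

Subject-level intercepts and slopes for both framings form a 4-vector drawn
from a zero-mean multivariate normal whose covariance is estimated
(Cholesky-parameterised), so risk attitudes may correlate across framings and
between shift and sensitivity.  CPT curvature parameters are held fixed
(see :mod:`riskframe.cpt`); the softmax sensitivity phi is absorbed into the
intercept/slope reparameterisation.

Four variants support model comparison: ``pooled`` (a_F, b_F only),
``pooled+T`` (adds the testosterone shifts), ``hierarchical`` (adds
independent subject effects, no covariate) and ``hierarchical+T+covariance``
(the full model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit

from .prospect import (
    NEGATIVE,
    POSITIVE,
    CPTParams,
    Game,
    gap,
    log_gap,
)
from .sampling import NUTSResult, SamplerConfig, sample_nuts

__all__ = [
    "ChoiceRecord",
    "FramingCoefficients",
    "PosteriorSummary",
    "FramingChoiceModel",
    "FramingChoiceResults",
    "linear_predictor",
    "summarize_posterior",
    "effect_size",
    "compare_models",
    "VARIANTS",
    "TABLE_LABELS",
]

VARIANTS = ("pooled", "pooled+T", "hierarchical", "hierarchical+T+covariance")

#: Row labels used in the published-style posterior summary table.
TABLE_LABELS = {
    "a_negative": "Shift (intercept) negative framing",
    "a_positive": "Shift (intercept) positive framing",
    "b_negative": "beta (negative framing)",
    "b_positive": "beta (positive framing)",
    "delta_a_negative": "delta shift (negative framing)",
    "delta_a_positive": "delta shift (positive framing)",
    "delta_b_negative": "delta beta (negative framing)",
    "delta_b_positive": "delta beta (positive framing)",
}


@dataclass(frozen=True)
class ChoiceRecord:
    """One decision: a subject's risky/sure choice in one game and session."""

    subject_id: str
    treatment: str
    game_id: str
    framing: str
    choice: int
    t_change: float = 0.0

    def __post_init__(self) -> None:
        if self.choice not in (0, 1):
            raise ValueError(f"choice must be 0 (sure) or 1 (risky), got {self.choice}")
        if self.framing not in (POSITIVE, NEGATIVE):
            raise ValueError(f"unknown framing {self.framing!r}")


@dataclass
class FramingCoefficients:
    """Population coefficients (positive, negative) plus subject structure."""

    a: tuple[float, float] = (0.0, 0.0)
    b: tuple[float, float] = (0.0, 0.0)
    delta_a: tuple[float, float] = (0.0, 0.0)
    delta_b: tuple[float, float] = (0.0, 0.0)
    #: per-subject deviations, shape (n_subjects, 4) ordered
    #: (int_pos, slope_pos, int_neg, slope_neg)
    subject_offsets: np.ndarray | None = None
    #: 4x4 correlation matrix of the subject-effect vector
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.correlation is not None:
            C = np.asarray(self.correlation, float)
            if C.shape != (4, 4) or not np.allclose(C, C.T):
                raise ValueError("correlation must be a symmetric 4x4 matrix")
            if not np.allclose(np.diag(C), 1.0):
                raise ValueError("correlation must have unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise ValueError("correlation must be positive semi-definite")

    def for_framing(self, framing: str) -> tuple[float, float, float, float]:
        i = 0 if framing == POSITIVE else 1
        return self.a[i], self.b[i], self.delta_a[i], self.delta_b[i]


@dataclass(frozen=True)
class PosteriorSummary:
    """One row of a Table-2-style posterior summary."""

    parameter: str
    mean: float
    sd: float
    odds: float
    hdi_low: float
    hdi_high: float
    hdi_mass: float = 0.94


def linear_predictor(
    record: ChoiceRecord,
    coefs: FramingCoefficients,
    cpt: CPTParams,
    games: Mapping[tuple[str, str], Game],
    subject_index: int | None = None,
) -> float:
    """Logit-scale score of the risky option for one choice record."""
    key = (record.game_id, record.framing)
    if key not in games:
        raise KeyError(f"game {key} not in game table")
    a, b, da, db = coefs.for_framing(record.framing)
    u_int = u_slope = 0.0
    if coefs.subject_offsets is not None and subject_index is not None:
        off = 0 if record.framing == POSITIVE else 2
        u_int = float(coefs.subject_offsets[subject_index, off])
        u_slope = float(coefs.subject_offsets[subject_index, off + 1])
    lg = log_gap(gap(games[key], cpt))
    intercept = a + u_int + da * record.t_change
    slope = b + u_slope + db * record.t_change
    return float(intercept + slope * lg)


# --------------------------------------------------------------------------
# internal design container

_OFFDIAG = [(1, 0), (2, 0), (2, 1), (3, 0), (3, 1), (3, 2)]


class _Design:
    """Pre-computed arrays for the likelihood/gradient of one dataset."""

    def __init__(self, choices: pd.DataFrame, games: Mapping, cpt: CPTParams,
                 variant: str):
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        self.variant = variant
        self.hierarchical = variant.startswith("hierarchical")
        self.include_t = "+T" in variant or variant == "hierarchical+T+covariance"
        self.covariance = "covariance" in variant

        required = {"subject_id", "game_id", "framing", "choice"}
        missing = required - set(choices.columns)
        if missing:
            raise ValueError(f"choices missing columns: {sorted(missing)}")
        framings = set(choices["framing"])
        bad = framings - {POSITIVE, NEGATIVE}
        if bad:
            raise ValueError(f"unknown framing labels: {sorted(bad)}")
        if framings != {POSITIVE, NEGATIVE}:
            raise ValueError("both framings must be present")

        self.y = choices["choice"].to_numpy(dtype=float)
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("choice must be binary (0 = sure, 1 = risky)")
        self.n_obs = len(choices)

        subjects = pd.Index(sorted(choices["subject_id"].astype(str).unique()))
        self.subjects = subjects
        self.n_subjects = len(subjects)
        if self.hierarchical and self.n_subjects < 2:
            raise ValueError("hierarchical variants need >= 2 subjects")
        self.s_idx = subjects.get_indexer(choices["subject_id"].astype(str))

        lg = np.empty(self.n_obs)
        for i, (gid, fr) in enumerate(
            zip(choices["game_id"].astype(str), choices["framing"])
        ):
            key = (gid, fr)
            if key not in games:
                raise KeyError(f"game {key} not found in game table")
            lg[i] = log_gap(gap(games[key], cpt))
        self.lg = lg

        if self.include_t:
            if "t_change" not in choices.columns:
                raise ValueError("t_change column required for +T variants")
            self.t = choices["t_change"].to_numpy(dtype=float)
            if not np.all(np.isfinite(self.t)):
                raise ValueError("t_change must be finite (impute first)")
        else:
            self.t = np.zeros(self.n_obs)

        is_pos = (choices["framing"] == POSITIVE).to_numpy()
        f = np.where(is_pos, 0, 1)
        # population design: [a_pos, a_neg, b_pos, b_neg, (da_pos, da_neg,
        # db_pos, db_neg)]
        cols = [is_pos * 1.0, ~is_pos * 1.0, is_pos * lg, ~is_pos * lg]
        self.pop_names = ["a_positive", "a_negative", "b_positive", "b_negative"]
        if self.include_t:
            cols += [is_pos * self.t, ~is_pos * self.t,
                     is_pos * self.t * lg, ~is_pos * self.t * lg]
            self.pop_names += ["delta_a_positive", "delta_a_negative",
                               "delta_b_positive", "delta_b_negative"]
        self.X = np.column_stack(cols)
        self.n_pop = self.X.shape[1]

        # subject-effect design: 4-vector (int_pos, slope_pos, int_neg, slope_neg)
        G = np.zeros((self.n_obs, 4))
        G[np.arange(self.n_obs), 2 * f] = 1.0
        G[np.arange(self.n_obs), 2 * f + 1] = lg
        self.G = G

        # parameter packing
        self.i_beta = slice(0, self.n_pop)
        k = self.n_pop
        if self.hierarchical:
            self.i_d = slice(k, k + 4)
            k += 4
            if self.covariance:
                self.i_w = slice(k, k + 6)
                k += 6
            else:
                self.i_w = None
            self.i_z = slice(k, k + 4 * self.n_subjects)
            k += 4 * self.n_subjects
        self.ndim = k

    # -- parameter unpacking helpers -------------------------------------
    def _chol(self, theta: np.ndarray) -> np.ndarray:
        W = np.zeros((4, 4))
        W[np.diag_indices(4)] = np.exp(np.clip(theta[self.i_d], -15.0, 15.0))
        if self.covariance:
            for (i, j), w in zip(_OFFDIAG, theta[self.i_w]):
                W[i, j] = w
        return W

    def eta(self, theta: np.ndarray) -> np.ndarray:
        eta = self.X @ theta[self.i_beta]
        if self.hierarchical:
            W = self._chol(theta)
            Z = theta[self.i_z].reshape(self.n_subjects, 4)
            U = Z @ W.T
            eta = eta + np.sum(self.G * U[self.s_idx], axis=1)
        return eta

    def pointwise_loglik(self, theta: np.ndarray) -> np.ndarray:
        eta = self.eta(theta)
        # y*eta - softplus(eta), stable
        return self.y * eta - np.logaddexp(0.0, eta)

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        grad = np.zeros_like(theta)
        beta = theta[self.i_beta]
        eta = self.X @ beta
        if self.hierarchical:
            W = self._chol(theta)
            Z = theta[self.i_z].reshape(self.n_subjects, 4)
            U = Z @ W.T
            eta = eta + np.sum(self.G * U[self.s_idx], axis=1)

        loglik = float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))
        r = self.y - expit(eta)

        # priors: beta ~ N(0, 2)
        logp = loglik - float(np.sum(beta**2)) / 8.0
        grad[self.i_beta] = self.X.T @ r - beta / 4.0

        if self.hierarchical:
            d = theta[self.i_d]
            sig = np.exp(np.clip(d, -15.0, 15.0))
            Gs = np.zeros((self.n_subjects, 4))
            np.add.at(Gs, self.s_idx, r[:, None] * self.G)
            gradW = Gs.T @ Z
            # z ~ N(0, 1)
            logp += -0.5 * float(np.sum(Z**2))
            grad[self.i_z] = (Gs @ W - Z).ravel()
            # scales: sigma = exp(d) ~ HalfNormal(1), log-jacobian d
            logp += float(np.sum(-0.5 * sig**2 + d))
            grad[self.i_d] = np.diag(gradW) * sig - sig**2 + 1.0
            if self.covariance:
                w = theta[self.i_w]
                # off-diagonal Cholesky entries ~ N(0, 0.5)
                logp += -float(np.sum(w**2)) / (2 * 0.25)
                grad[self.i_w] = (
                    np.array([gradW[i, j] for i, j in _OFFDIAG]) - w / 0.25
                )
        return logp, grad


def _games_mapping(games: Iterable[Game] | Mapping) -> dict[tuple[str, str], Game]:
    if isinstance(games, Mapping):
        return dict(games)
    return {(g.game_id, g.framing): g for g in games}


class FramingChoiceModel:
    """Bernoulli-logit choice model on the log-gap with hormone covariate.

    Parameters
    ----------
    choices : DataFrame
        Long format with columns ``subject_id, treatment, game_id, framing,
        choice`` and (for +T variants) ``t_change``.
    games : iterable of Game or mapping (game_id, framing) -> Game
    cpt : CPTParams, optional
        Fixed CPT curvature; defaults to the published framing-specific
        estimates.
    variant : str
        One of ``pooled``, ``pooled+T``, ``hierarchical``,
        ``hierarchical+T+covariance``.
    """

    def __init__(self, choices: pd.DataFrame, games, cpt: CPTParams | None = None,
                 variant: str = "hierarchical+T+covariance"):
        self.cpt = cpt or CPTParams.published_defaults()
        self.games = _games_mapping(games)
        self.choices = choices.reset_index(drop=True)
        self.variant = variant
        self._design = _Design(self.choices, self.games, self.cpt, variant)

    @classmethod
    def from_frames(cls, choices: pd.DataFrame, games_frame: pd.DataFrame,
                    **kwargs) -> "FramingChoiceModel":
        from .io import games_from_frame

        return cls(choices, games_from_frame(games_frame), **kwargs)

    @property
    def subjects(self) -> pd.Index:
        return self._design.subjects

    def loglike(self, coefs: FramingCoefficients) -> float:
        """Bernoulli log-likelihood at a parameter point (no priors).

        ``coefs.subject_offsets`` (if given) must be ordered like
        :attr:`subjects`.
        """
        d = self._design
        a, b = np.asarray(coefs.a), np.asarray(coefs.b)
        da, db = np.asarray(coefs.delta_a), np.asarray(coefs.delta_b)
        beta = np.concatenate([a, b, da, db]) if d.include_t else np.concatenate([a, b])
        # design columns are ordered (pos, neg) within each block
        eta = d.X @ beta
        if coefs.subject_offsets is not None:
            U = np.asarray(coefs.subject_offsets, float)
            if U.shape != (d.n_subjects, 4):
                raise ValueError(
                    f"subject_offsets must have shape ({d.n_subjects}, 4)"
                )
            eta = eta + np.sum(d.G * U[d.s_idx], axis=1)
        return float(np.sum(d.y * eta - np.logaddexp(0.0, eta)))

    def fit(self, config: SamplerConfig | None = None, *, seed: int,
            check_convergence: bool = True) -> "FramingChoiceResults":
        """Sample the posterior with NUTS and wrap it in a results object."""
        config = config or SamplerConfig()
        d = self._design
        raw = sample_nuts(d.logp_grad, d.ndim, config=config, seed=seed,
                          jitter=0.5)
        idata = self._to_inference_data(raw)
        res = FramingChoiceResults(self, idata, raw, config)
        if check_convergence and not res.converged:
            import warnings

            warnings.warn(
                f"framing model ({self.variant}) did not converge: "
                f"max R-hat {res.max_rhat:.3f}, "
                f"{raw.n_divergent} divergent transitions",
                stacklevel=2,
            )
        return res

    def _to_inference_data(self, raw: NUTSResult) -> az.InferenceData:
        d = self._design
        draws = raw.draws
        post: dict[str, np.ndarray] = {}
        for k, name in enumerate(d.pop_names):
            post[name] = draws[:, :, k]
        coords: dict = {}
        dims: dict = {}
        if d.hierarchical:
            sig = np.exp(draws[:, :, d.i_d])
            post["sigma_subject"] = sig
            dims["sigma_subject"] = ["effect"]
            coords["effect"] = ["int_pos", "slope_pos", "int_neg", "slope_neg"]
            nc, nd = draws.shape[:2]
            Z = draws[:, :, d.i_z].reshape(nc, nd, d.n_subjects, 4)
            W = np.zeros((nc, nd, 4, 4))
            W[..., np.arange(4), np.arange(4)] = sig
            if d.covariance:
                wvals = draws[:, :, d.i_w]
                for k, (i, j) in enumerate(_OFFDIAG):
                    W[..., i, j] = wvals[..., k]
            U = np.einsum("cdsk,cdjk->cdsj", Z, W)
            post["subject_offset"] = U
            dims["subject_offset"] = ["subject", "effect"]
            coords["subject"] = list(d.subjects)
            # implied correlation matrix of the subject-effect vector
            cov = np.einsum("cdik,cdjk->cdij", W, W)
            sd = np.sqrt(np.einsum("cdii->cdi", cov))
            corr = cov / (sd[..., :, None] * sd[..., None, :])
            post["corr_subject"] = corr
            dims["corr_subject"] = ["effect", "effect2"]
            coords["effect2"] = coords["effect"]

        # pointwise log-likelihood for LOO / model comparison
        nc, nd = draws.shape[:2]
        ll = np.empty((nc, nd, d.n_obs))
        for c in range(nc):
            for i in range(nd):
                ll[c, i] = d.pointwise_loglik(draws[c, i])
        idata = az.from_dict(
            posterior=post,
            log_likelihood={"choice": ll},
            sample_stats={
                "diverging": raw.diverging,
                "energy": raw.energy,
                "acceptance_rate": raw.accept_rate,
                "tree_depth": raw.tree_depth,
            },
            coords=coords,
            dims={**dims, "choice": ["obs"]},
            observed_data={"y": d.y},
        )
        return idata


class FramingChoiceResults:
    """Posterior draws, diagnostics and summaries for a fitted framing model."""

    def __init__(self, model: FramingChoiceModel, idata: az.InferenceData,
                 raw: NUTSResult, config: SamplerConfig):
        self.model = model
        self.idata = idata
        self.raw = raw
        self.config = config

    # -- diagnostics ------------------------------------------------------
    @property
    def population_names(self) -> list[str]:
        return list(self.model._design.pop_names)

    @property
    def max_rhat(self) -> float:
        r = az.rhat(self.idata, var_names=self.population_names)
        return float(max(float(r[v].max()) for v in r.data_vars))

    @property
    def n_divergent(self) -> int:
        return self.raw.n_divergent

    @property
    def converged(self) -> bool:
        return (
            self.max_rhat < self.config.rhat_threshold
            and self.n_divergent < 0.01 * self.raw.draws.shape[0] * self.raw.draws.shape[1]
        )

    def diagnostics(self) -> dict:
        ess = az.ess(self.idata, var_names=self.population_names)
        return {
            "max_rhat": self.max_rhat,
            "n_divergent": self.n_divergent,
            "min_ess": float(min(float(ess[v].min()) for v in ess.data_vars)),
            "converged": self.converged,
        }

    # -- draws ------------------------------------------------------------
    def population_draws(self) -> dict[str, np.ndarray]:
        """Flattened posterior draws of the population coefficients."""
        post = self.idata.posterior
        return {
            name: post[name].values.reshape(-1) for name in self.population_names
        }

    def coefficients(self) -> FramingCoefficients:
        """Posterior-mean coefficients."""
        m = {k: float(v.mean()) for k, v in self.population_draws().items()}
        post = self.idata.posterior
        offs = corr = None
        if "subject_offset" in post:
            offs = post["subject_offset"].mean(("chain", "draw")).values
            corr = post["corr_subject"].mean(("chain", "draw")).values
            # posterior-mean of correlations is not exactly a correlation
            # matrix; renormalise the diagonal
            dd = np.sqrt(np.diag(corr))
            corr = corr / np.outer(dd, dd)
        return FramingCoefficients(
            a=(m["a_positive"], m["a_negative"]),
            b=(m["b_positive"], m["b_negative"]),
            delta_a=(m.get("delta_a_positive", 0.0), m.get("delta_a_negative", 0.0)),
            delta_b=(m.get("delta_b_positive", 0.0), m.get("delta_b_negative", 0.0)),
            subject_offsets=offs,
            correlation=corr,
        )

    # -- summaries --------------------------------------------------------
    def summary(self, hdi_mass: float = 0.94, table_labels: bool = True
                ) -> pd.DataFrame:
        """Posterior summary table (mean, SD, odds, HDI bounds)."""
        rows = summarize_posterior(self.population_draws(), hdi_mass=hdi_mass)
        df = pd.DataFrame(
            [
                {
                    "parameter": (
                        TABLE_LABELS.get(r.parameter, r.parameter)
                        if table_labels else r.parameter
                    ),
                    "mean": r.mean,
                    "sd": r.sd,
                    "odds": r.odds,
                    f"hdi {50 * (1 - hdi_mass):g}%": r.hdi_low,
                    f"hdi {50 * (1 + hdi_mass):g}%": r.hdi_high,
                }
                for r in rows
            ]
        ).set_index("parameter")
        return df

    def effect_sizes(self) -> pd.Series:
        """Standardised effects (posterior mean / posterior SD) per parameter."""
        rows = summarize_posterior(self.population_draws())
        return pd.Series({r.parameter: effect_size(r) for r in rows})

    def hdi(self, hdi_mass: float = 0.94) -> dict[str, tuple[float, float]]:
        out = {}
        for name, dr in self.population_draws().items():
            lo, hi = az.hdi(dr, hdi_prob=hdi_mass)
            out[name] = (float(lo), float(hi))
        return out

    # -- prediction -------------------------------------------------------
    def predict_proba(self) -> np.ndarray:
        """Posterior-mean probability of the risky choice per observation."""
        d = self.model._design
        nc, nd = self.raw.draws.shape[:2]
        p = np.zeros(d.n_obs)
        for c in range(nc):
            for i in range(nd):
                p += expit(d.eta(self.raw.draws[c, i]))
        return p / (nc * nd)

    def auc(self) -> float:
        """ROC-AUC of posterior-mean probabilities against observed choices."""
        from sklearn.metrics import roc_auc_score

        return float(roc_auc_score(self.model._design.y, self.predict_proba()))

    # -- counterfactuals ---------------------------------------------------
    def risk_vs_testosterone(self, **kwargs):
        from .counterfactual import risk_vs_testosterone

        return risk_vs_testosterone(self, **kwargs)

    def risk_vs_gain(self, **kwargs):
        from .counterfactual import risk_vs_gain

        return risk_vs_gain(self, **kwargs)


# --------------------------------------------------------------------------
# module-level summary operations


def summarize_posterior(
    draws: Mapping[str, np.ndarray] | np.ndarray,
    hdi_mass: float = 0.94,
) -> list[PosteriorSummary]:
    """Mean, SD, odds = exp(mean) and HDI for each named draw vector.

    ``draws`` may be a mapping name -> 1-d array, or a single array (named
    ``"parameter"``).
    """
    if not isinstance(draws, Mapping):
        draws = {"parameter": np.asarray(draws)}
    if not 0 < hdi_mass < 1:
        raise ValueError("hdi_mass must be in (0, 1)")
    out = []
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float).reshape(-1)
        if arr.size == 0:
            raise ValueError(f"empty draws for {name!r}")
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        if arr.size > 1 and sd > 0:
            lo, hi = az.hdi(arr, hdi_prob=hdi_mass)
        else:
            lo = hi = mean
        out.append(
            PosteriorSummary(
                parameter=name, mean=mean, sd=sd, odds=float(np.exp(mean)),
                hdi_low=float(lo), hdi_high=float(hi), hdi_mass=hdi_mass,
            )
        )
    return out


def effect_size(summary: PosteriorSummary) -> float:
    """Standardised effect: posterior mean relative to posterior SD."""
    if summary.sd <= 0:
        raise ValueError("effect size undefined for sd = 0")
    return summary.mean / summary.sd


def compare_models(
    fits: Mapping[str, FramingChoiceResults],
) -> pd.DataFrame:
    """Rank fitted variants by PSIS-LOO and attach ROC-AUC per fit.

    All fits must share the same observation set.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    ys = [f.model._design.y for f in fits.values()]
    for y in ys[1:]:
        if y.shape != ys[0].shape or not np.array_equal(y, ys[0]):
            raise ValueError("fits do not share the same observation set")
    cmp = az.compare(
        {name: f.idata for name, f in fits.items()},
        ic="loo", method="stacking",
    )
    cmp = cmp.copy()
    cmp["roc_auc"] = pd.Series({name: f.auc() for name, f in fits.items()})
    return cmp
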