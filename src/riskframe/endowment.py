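"""Endowment-effect analysis: WTA/WTP ratios, tests, and multilevel models.

The endowment effect is the systematic excess of the minimum selling price
(willingness to accept, WTA) over the maximum buying price (willingness to
pay, WTP) for the same item.  The analysis works on the log ratio

    log(WTA/WTP)[subject, item] = mu0 + mu_ind + g_item (+ b * Tchange)

with crossed subject and item effects, a Gaussian residual, and a log link
so every parameter lives on the whole real line.  Three variants mirror the
study's hypotheses: the overall ratio (``item+subject``), goods-type means
(``goods_type``: hedonic vs utilitarian), and the testosterone covariate with
partially pooled per-item shifts (``item+subject+T``).

The module also provides the frequentist companions: a one-sided one-sample
t-test of mean ratio = 1 with a default-prior Bayes factor, and the 2x2
repeated-measures ANOVA (treatment x time) on hormone panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from .framing import PosteriorSummary, summarize_posterior
from .sampling import NUTSResult, SamplerConfig, sample_nuts

__all__ = [
    "EndowmentRecord",
    "EndowmentParams",
    "ExclusionReport",
    "EndowmentTest",
    "build_ratios",
    "test_endowment",
    "EndowmentModel",
    "EndowmentResults",
    "fit_endowment_model",
    "hormone_anova",
    "ENDOWMENT_VARIANTS",
]

ENDOWMENT_VARIANTS = ("item+subject", "goods_type", "item+subject+T")
GOODS_TYPES = ("hedonic", "utilitarian")


def _exp(x):
    # overflow-safe exp for log-scale parameters explored during warmup
    return np.exp(np.clip(x, -15.0, 15.0))


def _sum_zero_basis(n: int) -> np.ndarray:
    # orthonormal basis of the sum-to-zero subspace (Helmert contrasts),
    # shape (n, n-1); removes the unidentified mean direction of a group
    # effect so the intercept absorbs it
    from scipy.linalg import helmert

    return helmert(n).T

#: A subject whose zero bids exceed this fraction of their bids is excluded.
ZERO_BID_THRESHOLD = 0.3


@dataclass(frozen=True)
class EndowmentRecord:
    """One bid: a subject values one item in one role in one session."""

    subject_id: str
    treatment: str
    item_id: str
    goods_type: str
    role: str
    value: float

    def __post_init__(self) -> None:
        if self.role not in ("WTA", "WTP"):
            raise ValueError(f"role must be WTA or WTP, got {self.role!r}")
        if self.goods_type not in GOODS_TYPES:
            raise ValueError(f"unknown goods_type {self.goods_type!r}")
        if not (np.isfinite(self.value) and self.value >= 0):
            raise ValueError(f"value must be finite and >= 0, got {self.value}")


@dataclass
class EndowmentParams:
    """Point parameters of the log-ratio model (used by the oracle check)."""

    mu0: float = 0.0
    mu_ind: dict = field(default_factory=dict)
    g_item: dict = field(default_factory=dict)
    mu_type: dict = field(default_factory=dict)
    b: float = 0.0
    sigma_resid: float = 1.0


@dataclass
class ExclusionReport:
    """Bookkeeping of rows removed while building ratios."""

    excluded_subjects: list = field(default_factory=list)
    zero_fraction: dict = field(default_factory=dict)
    dropped_cells_zero_wtp: int = 0
    unmatched_cells: list = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"{len(self.excluded_subjects)} subject(s) excluded "
            f"(> {ZERO_BID_THRESHOLD:.0%} zero bids): {self.excluded_subjects}; "
            f"{self.dropped_cells_zero_wtp} cell(s) dropped for zero WTP; "
            f"{len(self.unmatched_cells)} unmatched cell(s)"
        )


def _check_columns(records: pd.DataFrame) -> None:
    required = {"subject_id", "treatment", "item_id", "goods_type", "role", "value"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"endowment records missing columns: {sorted(missing)}")


def apply_zero_bid_exclusion(
    records: pd.DataFrame, threshold: float = ZERO_BID_THRESHOLD
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop subjects who gave a zero bid on more than ``threshold`` of items.

    An item counts against a subject if any of their bids (either role, any
    session) for that item is zero.
    """
    _check_columns(records)
    report = ExclusionReport()
    frac = (
        records.assign(is_zero=records["value"] == 0)
        .groupby(["subject_id", "item_id"])["is_zero"].any()
        .groupby("subject_id").mean()
    )
    report.zero_fraction = frac.to_dict()
    excluded = frac[frac > threshold].index.tolist()
    report.excluded_subjects = sorted(excluded)
    kept = records[~records["subject_id"].isin(excluded)].copy()
    return kept, report


def build_ratios(
    records: pd.DataFrame, zero_threshold: float = ZERO_BID_THRESHOLD
) -> tuple[pd.DataFrame, ExclusionReport]:
    """WTA/WTP ratios per subject x item x treatment cell.

    Repeated presentations of the same role within a cell are averaged before
    the ratio is taken, so the pairing works whether each item appears once
    per role or in a randomised single-role schedule.  Cells with a zero WTP
    (undefined ratio) and cells missing one role are reported, never silently
    dropped.
    """
    kept, report = apply_zero_bid_exclusion(records, zero_threshold)
    keys = ["subject_id", "treatment", "item_id", "goods_type"]
    wide = kept.pivot_table(
        index=keys, columns="role", values="value", aggfunc="mean"
    )
    for role in ("WTA", "WTP"):
        if role not in wide.columns:
            wide[role] = np.nan
    unmatched = wide[wide["WTA"].isna() | wide["WTP"].isna()]
    report.unmatched_cells = [tuple(ix) for ix in unmatched.index]
    wide = wide.dropna(subset=["WTA", "WTP"])
    zero_wtp = wide["WTP"] == 0
    report.dropped_cells_zero_wtp = int(zero_wtp.sum())
    wide = wide[~zero_wtp]
    ratios = wide.reset_index()
    ratios["ratio"] = ratios["WTA"] / ratios["WTP"]
    return ratios, report


@dataclass(frozen=True)
class EndowmentTest:
    """One-sided one-sample test of mean WTA/WTP ratio against 1."""

    t: float
    p_value: float
    df: float
    bayes_factor: float
    n: int
    mean_ratio: float
    degenerate: bool = False


def test_endowment(ratios, popmean: float = 1.0) -> EndowmentTest:
    """One-tailed t-test (H1: mean ratio > ``popmean``) with JZS Bayes factor."""
    import pingouin as pg

    x = np.asarray(
        ratios["ratio"] if isinstance(ratios, pd.DataFrame) else ratios,
        dtype=float,
    )
    if x.size < 2:
        raise ValueError("need at least 2 ratios")
    if np.std(x, ddof=1) == 0:
        # all ratios identical: t undefined by the usual formula; report the
        # degenerate boundary case (t = 0, p = 0.5 when exactly at popmean)
        at_null = bool(np.isclose(x.mean(), popmean))
        return EndowmentTest(
            t=0.0 if at_null else np.inf * np.sign(x.mean() - popmean),
            p_value=0.5 if at_null else (0.0 if x.mean() > popmean else 1.0),
            df=float(x.size - 1), bayes_factor=np.nan, n=x.size,
            mean_ratio=float(x.mean()), degenerate=True,
        )
    res = pg.ttest(x, popmean, alternative="greater")
    tval = float(res["T"].iloc[0])
    return EndowmentTest(
        t=tval,
        p_value=float(res["p_val"].iloc[0]),
        df=float(res["dof"].iloc[0]),
        bayes_factor=float(pg.bayesfactor_ttest(tval, x.size, paired=True)),
        n=x.size,
        mean_ratio=float(x.mean()),
    )


# --------------------------------------------------------------------------
# multilevel Bayesian log-ratio models


class _EndowDesign:
    """Arrays and parameter layout for one endowment model variant."""

    def __init__(self, ratios: pd.DataFrame, variant: str):
        if variant not in ENDOWMENT_VARIANTS:
            raise ValueError(f"variant must be one of {ENDOWMENT_VARIANTS}")
        self.variant = variant
        self.y = np.log(ratios["ratio"].to_numpy(dtype=float))
        self.n_obs = len(ratios)
        self.subjects = pd.Index(sorted(ratios["subject_id"].astype(str).unique()))
        self.items = pd.Index(sorted(ratios["item_id"].astype(str).unique()))
        if len(self.subjects) < 2 or len(self.items) < 2:
            raise ValueError("need >= 2 subjects and >= 2 items")
        self.s_idx = self.subjects.get_indexer(ratios["subject_id"].astype(str))
        self.i_idx = self.items.get_indexer(ratios["item_id"].astype(str))
        self.types = pd.Index(GOODS_TYPES)
        self.g_idx = self.types.get_indexer(ratios["goods_type"].astype(str))
        if (self.g_idx < 0).any():
            bad = sorted(set(ratios["goods_type"]) - set(GOODS_TYPES))
            raise ValueError(f"unknown goods_type labels: {bad}")
        self.with_t = variant == "item+subject+T"
        if self.with_t:
            if "t_change" not in ratios.columns:
                raise ValueError("t_change column required for the +T variant")
            self.t = ratios["t_change"].to_numpy(dtype=float)
            if not np.all(np.isfinite(self.t)):
                raise ValueError("t_change must be finite (impute first)")

        S, J = len(self.subjects), len(self.items)
        k = 0
        if variant == "goods_type":
            self.i_mu_type = slice(0, 2)
            k = 2
        else:
            # centered parameterisation: the crossed effects are data-rich
            # here (dozens of observations per subject and per item), where
            # centering mixes far better than the non-centered form
            # the intercept is sampled as the *cohort* mean mu_tot (what
            # the likelihood identifies) while the group-effect means ubar,
            # vbar are separate prior-coupled scalars; the population-level
            # mu0 = mu_tot - ubar - vbar is reconstructed per draw.  This
            # decomposition is exact and removes the intercept/group-mean
            # see-saw that stalls mixing in crossed-intercept models.
            self.i_mu_tot = slice(0, 1)
            k = 1
            self.i_ubar = slice(k, k + 1); k += 1
            self.i_vbar = slice(k, k + 1); k += 1
            self.i_lsig_ind = slice(k, k + 1); k += 1
            self.i_lsig_item = slice(k, k + 1); k += 1
            self.i_w_ind = slice(k, k + S - 1); k += S - 1
            self.i_w_item = slice(k, k + J - 1); k += J - 1
            self.P_ind = _sum_zero_basis(S)
            self.P_item = _sum_zero_basis(J)
            if self.with_t:
                # per-item shifts stay non-centered: their scale can sit
                # near zero (no testosterone effect), where centering funnels
                self.i_b0 = slice(k, k + 1); k += 1
                self.i_lsig_b = slice(k, k + 1); k += 1
                self.i_z_b = slice(k, k + J); k += J
        self.i_lsig_r = slice(k, k + 1)
        k += 1
        self.ndim = k

    def mean(self, theta: np.ndarray) -> np.ndarray:
        if self.variant == "goods_type":
            return theta[self.i_mu_type][self.g_idx]
        u_ind = self.P_ind @ theta[self.i_w_ind]
        u_item = self.P_item @ theta[self.i_w_item]
        m = theta[self.i_mu_tot][0] + u_ind[self.s_idx] + u_item[self.i_idx]
        if self.with_t:
            b_item = (
                theta[self.i_b0][0]
                + _exp(theta[self.i_lsig_b][0]) * theta[self.i_z_b]
            )
            m = m + b_item[self.i_idx] * self.t
        return m

    def pointwise_loglik(self, theta: np.ndarray) -> np.ndarray:
        sig_r = _exp(theta[self.i_lsig_r][0])
        resid = self.y - self.mean(theta)
        return -0.5 * (resid / sig_r) ** 2 - np.log(sig_r) - 0.5 * np.log(2 * np.pi)

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        grad = np.zeros_like(theta)
        lsig_r = theta[self.i_lsig_r][0]
        sig_r = _exp(lsig_r)
        m = self.mean(theta)
        resid = self.y - m
        rs = resid / sig_r**2  # d loglik / d mean
        loglik = float(-0.5 * np.sum((resid / sig_r) ** 2)) - self.n_obs * lsig_r
        logp = loglik
        # residual scale ~ HalfNormal(1), log-parameterised
        logp += -0.5 * sig_r**2 + lsig_r
        grad[self.i_lsig_r] = (
            float(np.sum((resid / sig_r) ** 2)) - self.n_obs - sig_r**2 + 1.0
        )

        if self.variant == "goods_type":
            mu_type = theta[self.i_mu_type]
            logp += -0.5 * float(np.sum(mu_type**2))
            g = np.zeros(2)
            np.add.at(g, self.g_idx, rs)
            grad[self.i_mu_type] = g - mu_type
            return logp, grad

        S, J = len(self.subjects), len(self.items)
        mu_tot = theta[self.i_mu_tot][0]
        ubar = theta[self.i_ubar][0]
        vbar = theta[self.i_vbar][0]
        # prior N(0, 1) on mu0 = mu_tot - ubar - vbar
        mu0 = mu_tot - ubar - vbar
        logp += -0.5 * mu0**2
        grad[self.i_mu_tot] = float(np.sum(rs)) - mu0

        acc_s = np.zeros(S)
        np.add.at(acc_s, self.s_idx, rs)
        acc_i = np.zeros(J)
        np.add.at(acc_i, self.i_idx, rs)

        # group effects decomposed as mean + sum-to-zero deviations:
        # mean ~ N(0, sigma^2/n), deviations u = P w with w ~ N(0, sigma^2 I);
        # together these reproduce u_full ~ N(0, sigma^2 I_n).
        # sigma ~ HalfNormal(0.5)
        for acc, P, n_grp, bar, sl_bar, sl_w, sl_s in (
            (acc_s, self.P_ind, S, ubar, self.i_ubar, self.i_w_ind,
             self.i_lsig_ind),
            (acc_i, self.P_item, J, vbar, self.i_vbar, self.i_w_item,
             self.i_lsig_item),
        ):
            w = theta[sl_w]
            lsig = theta[sl_s][0]
            sig = _exp(lsig)
            ssq = float(np.sum(w**2)) + n_grp * bar**2
            logp += -0.5 * ssq / sig**2 - n_grp * lsig
            grad[sl_w] = P.T @ acc - w / sig**2
            # the group mean touches only priors: mu0's and its own
            grad[sl_bar] = mu0 - n_grp * bar / sig**2
            logp += -2.0 * sig**2 + lsig
            grad[sl_s] = ssq / sig**2 - n_grp - 4.0 * sig**2 + 1.0

        if self.with_t:
            b0 = theta[self.i_b0][0]
            lsig_b = theta[self.i_lsig_b][0]
            sig_b = _exp(lsig_b)
            z_b = theta[self.i_z_b]
            rt = rs * self.t
            acc_bt = np.zeros(J)
            np.add.at(acc_bt, self.i_idx, rt)
            # b_item = b0 + sigma_b * z_b; b0 ~ N(0,1); sigma_b ~ HalfNormal(0.5)
            logp += -0.5 * b0**2 - 0.5 * float(np.sum(z_b**2))
            logp += -2.0 * sig_b**2 + lsig_b
            grad[self.i_b0] = float(np.sum(rt)) - b0
            grad[self.i_z_b] = sig_b * acc_bt - z_b
            grad[self.i_lsig_b] = (
                sig_b * float(np.dot(acc_bt, z_b)) - 4.0 * sig_b**2 + 1.0
            )
        return logp, grad


class EndowmentModel:
    """Multilevel Bayesian model of log WTA/WTP ratios.

    Accepts raw bid records (long format, one row per bid) and builds the
    ratio table internally, or a prebuilt ratio table via ``from_ratios``.
    """

    def __init__(self, records: pd.DataFrame, variant: str = "item+subject",
                 zero_threshold: float = ZERO_BID_THRESHOLD,
                 t_change: pd.DataFrame | None = None):
        ratios, report = build_ratios(records, zero_threshold)
        if t_change is not None:
            ratios = ratios.merge(t_change, on=["subject_id", "treatment"],
                                  how="left")
        self._init_from_ratios(ratios, variant, report)

    @classmethod
    def from_ratios(cls, ratios: pd.DataFrame, variant: str = "item+subject"
                    ) -> "EndowmentModel":
        self = cls.__new__(cls)
        self._init_from_ratios(ratios.copy(), variant, ExclusionReport())
        return self

    def _init_from_ratios(self, ratios, variant, report):
        if (ratios["ratio"] <= 0).any():
            raise ValueError("ratios must be positive for the log link")
        self.ratios = ratios.reset_index(drop=True)
        self.variant = variant
        self.exclusions = report
        self._design = _EndowDesign(self.ratios, variant)

    @property
    def items(self) -> pd.Index:
        return self._design.items

    @property
    def subjects(self) -> pd.Index:
        return self._design.subjects

    def loglike(self, params: EndowmentParams) -> float:
        """Gaussian log-likelihood of the log-ratios at a parameter point."""
        d = self._design
        if self.variant == "goods_type":
            m = np.array([params.mu_type[t] for t in d.types])[d.g_idx]
        else:
            m = (
                params.mu0
                + np.array([params.mu_ind.get(s, 0.0) for s in d.subjects])[d.s_idx]
                + np.array([params.g_item.get(i, 0.0) for i in d.items])[d.i_idx]
            )
            if d.with_t:
                m = m + params.b * d.t
        resid = np.log(self.ratios["ratio"].to_numpy()) - m
        s = params.sigma_resid
        return float(
            np.sum(-0.5 * (resid / s) ** 2 - np.log(s) - 0.5 * np.log(2 * np.pi))
        )

    def fit(self, config: SamplerConfig | None = None, *, seed: int,
            check_convergence: bool = True) -> "EndowmentResults":
        config = config or SamplerConfig()
        d = self._design
        raw = sample_nuts(d.logp_grad, d.ndim, config=config, seed=seed,
                          jitter=0.5)
        idata = self._to_inference_data(raw)
        res = EndowmentResults(self, idata, raw, config)
        if check_convergence and not res.converged:
            import warnings

            warnings.warn(
                f"endowment model ({self.variant}) did not converge: "
                f"max R-hat {res.max_rhat:.3f}",
                stacklevel=2,
            )
        return res

    def _to_inference_data(self, raw: NUTSResult) -> az.InferenceData:
        d = self._design
        dr = raw.draws
        post: dict[str, np.ndarray] = {}
        dims: dict = {}
        coords: dict = {}
        if self.variant == "goods_type":
            post["mu_type"] = dr[:, :, d.i_mu_type]
            dims["mu_type"] = ["goods_type"]
            coords["goods_type"] = list(GOODS_TYPES)
        else:
            mu_tot = dr[:, :, d.i_mu_tot][:, :, 0]
            ubar = dr[:, :, d.i_ubar][:, :, 0]
            vbar = dr[:, :, d.i_vbar][:, :, 0]
            post["mu0"] = mu_tot - ubar - vbar
            post["sigma_subject"] = _exp(dr[:, :, d.i_lsig_ind][:, :, 0])
            post["sigma_item"] = _exp(dr[:, :, d.i_lsig_item][:, :, 0])
            post["mu_ind"] = ubar[:, :, None] + np.einsum(
                "sw,cdw->cds", d.P_ind, dr[:, :, d.i_w_ind])
            post["g_item"] = vbar[:, :, None] + np.einsum(
                "jw,cdw->cdj", d.P_item, dr[:, :, d.i_w_item])
            post["item_ratio"] = np.exp(post["mu0"][:, :, None] + post["g_item"])
            dims.update(
                mu_ind=["subject"], g_item=["item"], item_ratio=["item"]
            )
            coords["subject"] = list(d.subjects)
            coords["item"] = list(d.items)
            if d.with_t:
                post["b"] = dr[:, :, d.i_b0][:, :, 0]
                post["sigma_b"] = _exp(dr[:, :, d.i_lsig_b][:, :, 0])
                post["b_item"] = (
                    post["b"][:, :, None]
                    + post["sigma_b"][:, :, None] * dr[:, :, d.i_z_b]
                )
                dims["b_item"] = ["item"]
        post["sigma_resid"] = np.exp(dr[:, :, d.i_lsig_r][:, :, 0])

        nc, nd = dr.shape[:2]
        ll = np.empty((nc, nd, d.n_obs))
        for c in range(nc):
            for i in range(nd):
                ll[c, i] = d.pointwise_loglik(dr[c, i])
        return az.from_dict(
            posterior=post,
            log_likelihood={"log_ratio": ll},
            sample_stats={"diverging": raw.diverging, "energy": raw.energy},
            coords=coords,
            dims={**dims, "log_ratio": ["obs"]},
        )


def fit_endowment_model(records: pd.DataFrame, variant: str = "item+subject",
                        config: SamplerConfig | None = None, *, seed: int,
                        **kwargs) -> "EndowmentResults":
    """Convenience wrapper: build the model from bid records and fit it."""
    return EndowmentModel(records, variant=variant, **kwargs).fit(
        config, seed=seed
    )


class EndowmentResults:
    """Posterior draws and summaries for a fitted endowment model."""

    def __init__(self, model: EndowmentModel, idata: az.InferenceData,
                 raw: NUTSResult, config: SamplerConfig):
        self.model = model
        self.idata = idata
        self.raw = raw
        self.config = config

    @property
    def _scalar_names(self) -> list[str]:
        names = ["sigma_resid"]
        if self.model.variant == "goods_type":
            names.append("mu_type")
        else:
            names += ["mu0", "sigma_subject", "sigma_item"]
            if self.model.variant == "item+subject+T":
                names += ["b", "sigma_b"]
        return names

    @property
    def max_rhat(self) -> float:
        r = az.rhat(self.idata, var_names=self._scalar_names)
        return float(max(float(r[v].max()) for v in r.data_vars))

    @property
    def converged(self) -> bool:
        return (
            self.max_rhat < self.config.rhat_threshold
            and self.raw.n_divergent
            < 0.01 * self.raw.draws.shape[0] * self.raw.draws.shape[1]
        )

    def draws(self, name: str) -> np.ndarray:
        arr = self.idata.posterior[name].values
        return arr.reshape(-1, *arr.shape[2:])

    def summary(self, hdi_mass: float = 0.94) -> pd.DataFrame:
        named = {}
        for n in self._scalar_names:
            if n == "mu_type":
                for i, t in enumerate(GOODS_TYPES):
                    named[f"mu_type[{t}]"] = self.draws("mu_type")[:, i]
            else:
                named[n] = self.draws(n)
        rows = summarize_posterior(named, hdi_mass=hdi_mass)
        return pd.DataFrame(
            [
                {
                    "parameter": r.parameter, "mean": r.mean, "sd": r.sd,
                    "odds": r.odds, "hdi_low": r.hdi_low, "hdi_high": r.hdi_high,
                }
                for r in rows
            ]
        ).set_index("parameter")

    def overall_ratio_hdi(self, hdi_mass: float = 0.94) -> tuple[float, float, float]:
        """Posterior mean and HDI of exp(mu0), the population WTA/WTP ratio."""
        r = np.exp(self.draws("mu0"))
        lo, hi = az.hdi(r, hdi_prob=hdi_mass)
        return float(r.mean()), float(lo), float(hi)

    def item_ratios(self, hdi_mass: float = 0.94) -> pd.DataFrame:
        """Per-item posterior ratio exp(mu0 + g_item) with HDI."""
        arr = self.draws("item_ratio")
        rows = []
        items = list(self.model.items)
        types = self.model.ratios.drop_duplicates("item_id").set_index(
            "item_id")["goods_type"]
        for j, item in enumerate(items):
            lo, hi = az.hdi(arr[:, j], hdi_prob=hdi_mass)
            rows.append(
                {
                    "item_id": item, "goods_type": types.get(item),
                    "ratio_mean": float(arr[:, j].mean()),
                    "hdi_low": float(lo), "hdi_high": float(hi),
                }
            )
        return pd.DataFrame(rows).set_index("item_id")

    def item_shifts(self, hdi_mass: float = 0.95) -> pd.DataFrame:
        """Per-item testosterone shift posteriors (the Fig-10-style readout).

        Uses 95% intervals by default, wider than the 94% used for the choice
        model, matching how the two analyses are reported.
        """
        if self.model.variant != "item+subject+T":
            raise ValueError("item shifts require the item+subject+T variant")
        arr = self.draws("b_item")
        items = list(self.model.items)
        types = self.model.ratios.drop_duplicates("item_id").set_index(
            "item_id")["goods_type"]
        rows = []
        for j, item in enumerate(items):
            lo, hi = az.hdi(arr[:, j], hdi_prob=hdi_mass)
            rows.append(
                {
                    "item_id": item, "goods_type": types.get(item),
                    "shift_mean": float(arr[:, j].mean()),
                    "hdi_low": float(lo), "hdi_high": float(hi),
                    "contains_zero": bool(lo <= 0 <= hi),
                }
            )
        return pd.DataFrame(rows).set_index("item_id")

    def prob_hedonic_gt_utilitarian(self) -> float:
        """Posterior P(ratio_hedonic > ratio_utilitarian) (goods_type variant)."""
        if self.model.variant != "goods_type":
            raise ValueError("requires the goods_type variant")
        mt = self.draws("mu_type")
        return float(np.mean(mt[:, 0] > mt[:, 1]))


# --------------------------------------------------------------------------
# hormone ANOVA


def hormone_anova(panel: pd.DataFrame, dv: str = "testosterone",
                  posthoc: bool = True) -> dict:
    """2x2 repeated-measures ANOVA (treatment x time) with partial eta squared.

    ``panel`` is long format with columns subject_id, treatment, timepoint and
    the dependent hormone column.  The panel must be complete (impute first);
    an unbalanced panel is rejected.
    """
    import pingouin as pg

    required = {"subject_id", "treatment", "timepoint", dv}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel missing columns: {sorted(missing)}")
    counts = panel.groupby(["subject_id", "treatment", "timepoint"]).size()
    cells = counts.groupby("subject_id").size()
    if (cells != 4).any() or (counts != 1).any():
        raise ValueError(
            "panel must have exactly one value per subject x treatment x "
            "timepoint cell (impute missing values first)"
        )
    if panel[dv].isna().any():
        raise ValueError("panel contains missing values; impute first")
    if panel[dv].nunique() == 1:
        # degenerate constant panel: every effect is exactly null
        aov = pd.DataFrame(
            {
                "Source": ["treatment", "timepoint", "treatment * timepoint"],
                "F": [0.0, 0.0, 0.0],
                "p_unc": [1.0, 1.0, 1.0],
                "np2": [0.0, 0.0, 0.0],
            }
        )
        return {"anova": aov}
    # dv column must not collide with factor level labels (e.g. a hormone
    # named like a treatment arm), so rename it for the ANOVA call
    work = panel.rename(columns={dv: "hormone_value"})
    aov = pg.rm_anova(
        data=work, dv="hormone_value", within=["treatment", "timepoint"],
        subject="subject_id", detailed=True, effsize="np2",
    )
    out = {"anova": aov}
    if posthoc:
        out["posthoc"] = pg.pairwise_tests(
            data=work, dv="hormone_value", within=["treatment", "timepoint"],
            subject="subject_id", padjust="bonf",
        )
    return out
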