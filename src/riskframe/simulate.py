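"""Synthetic study generator: framed choices, hormone panels, endowment bids.

Emulates the crossover design the models assume: 40 men, two sessions
(placebo / testosterone, order counterbalanced), ten framed games per session
(five probability levels x two framings), serum testosterone and cortisol at
two time points per session, and WTA/WTP bids for hedonic and utilitarian
items (each item rated in both roles in each session).

Default generating values are the published posterior means of the framing
model and the printed hormone moments, so simulated cohorts resemble the
fitted regime.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .prospect import CPTParams, Game, gap, log_gap

__all__ = ["GeneratorTruth", "gen_choices", "gen_hormones", "gen_endowment",
           "simulate_study", "t_change_from_panel"]

PLACEBO = "placebo"
TESTOSTERONE = "testosterone"

#: serum moments (mean, sd): {treatment: {timepoint: (mean, sd)}}
_TESTO_MOMENTS = {
    TESTOSTERONE: {"T0": (18.53, 6.04), "T1": (33.76, 11.9)},
    PLACEBO: {"T0": (18.69, 5.44), "T1": (19.0, 6.38)},
}
_CORTISOL_MOMENTS = {
    TESTOSTERONE: {"T0": (427.30, 97.87), "T1": (273.74, 80.67)},
    PLACEBO: {"T0": (441.68, 120.25), "T1": (282.65, 88.12)},
}


def _default_correlation() -> np.ndarray:
    # modest coupling of intercepts across framings, and of slopes
    C = np.eye(4)
    C[0, 2] = C[2, 0] = 0.3   # int_pos ~ int_neg
    C[1, 3] = C[3, 1] = 0.3   # slope_pos ~ slope_neg
    return C


@dataclass
class GeneratorTruth:
    """Generating parameters of the synthetic study.

    Tuples are ordered (positive, negative) framing.  Endowment log-ratio
    means are per goods type; the overall mu0 is their average.
    """

    # framing-choice population coefficients (published posterior means)
    a: tuple[float, float] = (-0.98, -2.10)
    b: tuple[float, float] = (0.63, 0.63)
    delta_a: tuple[float, float] = (0.24, -0.44)
    delta_b: tuple[float, float] = (0.27, -0.02)
    # subject heterogeneity of (int_pos, slope_pos, int_neg, slope_neg)
    sigma_subject: tuple[float, float, float, float] = (0.5, 0.15, 0.5, 0.15)
    correlation: np.ndarray = field(default_factory=_default_correlation)
    cpt: CPTParams = field(default_factory=CPTParams.published_defaults)
    # hormones: serum moments and within-session test-retest correlation
    testosterone_moments: dict = field(default_factory=lambda: _TESTO_MOMENTS)
    cortisol_moments: dict = field(default_factory=lambda: _CORTISOL_MOMENTS)
    hormone_retest_corr: float = 0.8
    # endowment: log WTA/WTP ratio structure
    mu_type_hedonic: float = float(np.log(2.0))
    mu_type_utilitarian: float = float(np.log(1.4))
    endow_sigma_item: float = 0.2
    endow_sigma_subject: float = 0.3
    endow_sigma_resid: float = 0.25
    endow_b: float = 0.0
    # WTP (price) side of the bids
    log_price_mean: float = float(np.log(20.0))
    log_price_sd: float = 0.6
    wtp_noise_sd: float = 0.3
    n_subjects: int = 40

    def __post_init__(self) -> None:
        self.correlation = np.asarray(self.correlation, dtype=float)
        if any(s < 0 for s in self.sigma_subject):
            raise ValueError("sigma_subject entries must be >= 0")
        C = self.correlation
        if C.shape != (4, 4) or not np.allclose(C, C.T):
            raise ValueError("correlation must be symmetric 4x4")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("correlation must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("correlation must be positive semi-definite")
        for s in (self.endow_sigma_item, self.endow_sigma_subject,
                  self.endow_sigma_resid, self.wtp_noise_sd):
            if s < 0:
                raise ValueError("noise SDs must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @property
    def mu0(self) -> float:
        return 0.5 * (self.mu_type_hedonic + self.mu_type_utilitarian)

    def subject_cov(self) -> np.ndarray:
        s = np.asarray(self.sigma_subject)
        return self.correlation * np.outer(s, s)


def _subject_ids(n: int) -> list[str]:
    return [f"s{i + 1:03d}" for i in range(n)]


def gen_hormones(truth: GeneratorTruth, n_subjects: int | None = None, *,
                 seed: int) -> pd.DataFrame:
    """Hormone panel: subject x session x timepoint serum concentrations.

    Baseline and post-application values are drawn jointly (bivariate normal
    with the configured test-retest correlation) and floored at the assay
    detection scale, so concentrations stay positive and the placebo arm has
    near-zero average change.
    """
    n = n_subjects or truth.n_subjects
    rng = np.random.default_rng(seed)
    subjects = _subject_ids(n)
    rho = truth.hormone_retest_corr
    rows = []
    for si, subject in enumerate(subjects):
        # counterbalanced crossover: even-index subjects get testosterone first
        order = (
            [TESTOSTERONE, PLACEBO] if si % 2 == 0 else [PLACEBO, TESTOSTERONE]
        )
        for session, treatment in enumerate(order, start=1):
            m0, s0 = truth.testosterone_moments[treatment]["T0"]
            m1, s1 = truth.testosterone_moments[treatment]["T1"]
            z0, z1 = rng.standard_normal(2)
            t0 = m0 + s0 * z0
            t1 = m1 + s1 * (rho * z0 + np.sqrt(1 - rho**2) * z1)
            c0m, c0s = truth.cortisol_moments[treatment]["T0"]
            c1m, c1s = truth.cortisol_moments[treatment]["T1"]
            z0c, z1c = rng.standard_normal(2)
            c0 = c0m + c0s * z0c
            c1 = c1m + c1s * (rho * z0c + np.sqrt(1 - rho**2) * z1c)
            for tp, tval, cval in (("T0", t0, c0), ("T1", t1, c1)):
                rows.append(
                    {
                        "subject_id": subject,
                        "session": session,
                        "treatment": treatment,
                        "timepoint": tp,
                        "testosterone": max(tval, 0.09),
                        "cortisol": max(cval, 0.054),
                    }
                )
    return pd.DataFrame(rows)


def t_change_from_panel(hormones: pd.DataFrame,
                        definition: str = "relative") -> pd.DataFrame:
    """Per subject x treatment testosterone change from a hormone panel.

    ``relative`` gives (T1 - T0) / T0 (the default covariate); ``absolute``
    gives T1 - T0.
    """
    if definition not in ("relative", "absolute"):
        raise ValueError("definition must be 'relative' or 'absolute'")
    wide = hormones.pivot_table(
        index=["subject_id", "treatment"], columns="timepoint",
        values="testosterone", aggfunc="mean",
    )
    if not {"T0", "T1"} <= set(wide.columns):
        raise ValueError("panel must contain T0 and T1 timepoints")
    delta = wide["T1"] - wide["T0"]
    if definition == "relative":
        delta = delta / wide["T0"]
    return delta.rename("t_change").reset_index()


def gen_choices(truth: GeneratorTruth, games: list[Game], *, seed: int,
                hormones: pd.DataFrame | None = None,
                t_change_definition: str = "relative") -> pd.DataFrame:
    """Simulate framed risky/sure choices for the whole cohort.

    For each subject a 4-vector of (intercept, slope) deviations per framing
    is drawn from the configured multivariate normal; each subject x
    treatment x game cell then yields one Bernoulli choice from the
    logit(log-gap) rule with the subject's testosterone change.
    """
    if not games:
        raise ValueError("games must be nonempty")
    rng = np.random.default_rng(seed)
    n = truth.n_subjects
    subjects = _subject_ids(n)
    if hormones is None:
        hormones = gen_hormones(truth, n, seed=int(rng.integers(0, 2**31 - 1)))
    tch = t_change_from_panel(hormones, t_change_definition)
    tmap = tch.set_index(["subject_id", "treatment"])["t_change"]

    cov = truth.subject_cov()
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(4))
    U = rng.standard_normal((n, 4)) @ L.T

    lg = {(g.game_id, g.framing): log_gap(gap(g, truth.cpt)) for g in games}

    rows = []
    for si, subject in enumerate(subjects):
        for treatment in (PLACEBO, TESTOSTERONE):
            t = float(tmap.loc[(subject, treatment)])
            for g in games:
                i = 0 if g.framing == "positive" else 1
                off = 0 if g.framing == "positive" else 2
                intercept = truth.a[i] + truth.delta_a[i] * t + U[si, off]
                slope = truth.b[i] + truth.delta_b[i] * t + U[si, off + 1]
                eta = intercept + slope * lg[(g.game_id, g.framing)]
                p = 1.0 / (1.0 + np.exp(-eta))
                rows.append(
                    {
                        "subject_id": subject,
                        "treatment": treatment,
                        "game_id": g.game_id,
                        "framing": g.framing,
                        "choice": int(rng.random() < p),
                        "t_change": t,
                    }
                )
    return pd.DataFrame(rows)


def gen_cpt_choices(games: list[Game], *, alpha: tuple[float, float],
                    c: tuple[float, float], phi: float,
                    n_subjects: int, seed: int,
                    subject_sd: tuple[float, float, float] = (0.1, 0.1, 0.2),
                    use_log_transform: bool = True,
                    n_repeats: int = 1) -> pd.DataFrame:
    """Choices from the pure CPT softmax rule (no intercept, no hormones).

    Subject-level curvature and sensitivity are drawn on the transformed
    scales the hierarchical re-estimation model uses (log for alpha and phi,
    log of the distance above the weighting-function floor for c), with the
    given deviation SDs, so the generated cohort matches the fitted model's
    population structure.  ``n_repeats`` repeats the whole game set per
    subject (multiple presentations).
    """
    from .prospect import C_MIN, CPTParams

    rng = np.random.default_rng(seed)
    rows = []
    for si in range(n_subjects):
        za, zc, zp = rng.standard_normal(3)
        a_s = tuple(np.exp(np.log(a) + subject_sd[0] * za) for a in alpha)
        c_s = tuple(
            C_MIN + np.exp(np.log(cc - C_MIN) + subject_sd[1] * zc) for cc in c
        )
        phi_s = float(np.exp(np.log(phi) + subject_sd[2] * zp))
        params = CPTParams(alpha=a_s, c=c_s, lam=1.0, phi=phi_s)
        for _rep in range(n_repeats):
            for g in games:
                gp = gap(g, params)
                x = log_gap(gp) if use_log_transform else gp
                p = 1.0 / (1.0 + np.exp(-phi_s * x))
                rows.append(
                    {
                        "subject_id": f"s{si + 1:03d}",
                        "game_id": g.game_id,
                        "framing": g.framing,
                        "choice": int(rng.random() < p),
                    }
                )
    return pd.DataFrame(rows)


def gen_endowment(truth: GeneratorTruth, n_subjects: int | None = None,
                  n_items_per_type: int = 10, *, seed: int,
                  hormones: pd.DataFrame | None = None,
                  t_change_definition: str = "relative") -> pd.DataFrame:
    """Simulate WTA/WTP bids per subject x item x session.

    log WTP is an item base price plus noise; log WTA adds the endowment
    log-ratio (overall + goods-type + item + subject effects + the
    testosterone term) plus residual noise.  Both roles are emitted for every
    item in every session.
    """
    if n_items_per_type < 1:
        raise ValueError("n_items_per_type must be >= 1")
    n = n_subjects or truth.n_subjects
    rng = np.random.default_rng(seed)
    subjects = _subject_ids(n)
    if hormones is None:
        hormones = gen_hormones(truth, n, seed=int(rng.integers(0, 2**31 - 1)))
    tch = t_change_from_panel(hormones, t_change_definition)
    tmap = tch.set_index(["subject_id", "treatment"])["t_change"]

    items = [("h%02d" % (j + 1), "hedonic") for j in range(n_items_per_type)]
    items += [("u%02d" % (j + 1), "utilitarian") for j in range(n_items_per_type)]
    g_item = {iid: rng.normal(0.0, truth.endow_sigma_item) for iid, _ in items}
    base_price = {
        iid: rng.normal(truth.log_price_mean, truth.log_price_sd)
        for iid, _ in items
    }
    mu_ind = {s: rng.normal(0.0, truth.endow_sigma_subject) for s in subjects}
    mu_type = {
        "hedonic": truth.mu_type_hedonic - truth.mu0,
        "utilitarian": truth.mu_type_utilitarian - truth.mu0,
    }

    sessions = hormones[["subject_id", "session", "treatment"]].drop_duplicates()
    rows = []
    for subject in subjects:
        subj_sessions = sessions[sessions["subject_id"] == subject]
        for _, sess in subj_sessions.iterrows():
            t = float(tmap.loc[(subject, sess["treatment"])])
            for iid, gtype in items:
                log_wtp = (
                    base_price[iid]
                    + rng.normal(0.0, truth.wtp_noise_sd)
                )
                log_ratio = (
                    truth.mu0 + mu_type[gtype] + g_item[iid] + mu_ind[subject]
                    + truth.endow_b * t
                    + rng.normal(0.0, truth.endow_sigma_resid)
                )
                for role, val in (("WTP", log_wtp), ("WTA", log_wtp + log_ratio)):
                    rows.append(
                        {
                            "subject_id": subject,
                            "treatment": sess["treatment"],
                            "session": int(sess["session"]),
                            "item_id": iid,
                            "goods_type": gtype,
                            "role": role,
                            "value": float(np.exp(val)),
                        }
                    )
    return pd.DataFrame(rows)


def simulate_study(truth: GeneratorTruth | None = None, *, seed: int,
                   games: list[Game] | None = None,
                   n_items_per_type: int = 10) -> dict[str, pd.DataFrame]:
    """Generate every input the pipeline consumes, sharing one hormone panel."""
    from .io import load_packaged_games

    truth = truth or GeneratorTruth()
    games = games or load_packaged_games()
    rng = np.random.default_rng(seed)
    s_h, s_c, s_e = (int(x) for x in rng.integers(0, 2**31 - 1, size=3))
    hormones = gen_hormones(truth, seed=s_h)
    choices = gen_choices(truth, games, seed=s_c, hormones=hormones)
    endowment = gen_endowment(
        truth, n_items_per_type=n_items_per_type, seed=s_e, hormones=hormones
    )
    return {
        "hormones": hormones,
        "choices": choices,
        "endowment": endowment,
        "truth": truth,
    }
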