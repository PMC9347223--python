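"""Posterior counterfactual curves from a fitted framing-choice model.

Two sweeps mirror the exploratory questions the model is built for:

* :func:`risk_vs_testosterone` — probability of the risky choice as a
  function of the testosterone change, at fixed subjective-value gaps
  (default 1, 15 and 150 euro in value-function units);
* :func:`risk_vs_gain` — probability of the risky choice as a function of
  the subjective-value gap, at fixed testosterone changes (default 0%, 60%
  and 200% relative change).

Curves are computed per posterior draw for a typical subject (zero
subject-level offsets) and then summarised by the pointwise mean and HDI, so
posterior uncertainty propagates into the bands.  Gap levels are
value-function differences *before* the signed log1p compression; the
compression is applied before multiplying the slope, exactly as in the
fitted choice rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit

from .prospect import NEGATIVE, POSITIVE, log_gap

__all__ = ["CounterfactualGrid", "risk_vs_testosterone", "risk_vs_gain",
           "plot_counterfactual"]

DEFAULT_GAP_LEVELS = (1.0, 15.0, 150.0)
DEFAULT_T_LEVELS = (0.0, 0.6, 2.0)


@dataclass
class CounterfactualGrid:
    """Posterior mean curves with HDI bands over a swept variable."""

    fixed_dimension: str            # "gap" or "t_change"
    fixed_levels: tuple
    sweep_values: np.ndarray
    framing: str
    mean: np.ndarray                # (n_levels, n_sweep)
    hdi_low: np.ndarray
    hdi_high: np.ndarray
    hdi_mass: float = 0.94

    def __post_init__(self) -> None:
        if np.any(np.diff(self.sweep_values) <= 0):
            raise ValueError("sweep grid must be strictly increasing")
        for arr in (self.mean, self.hdi_low, self.hdi_high):
            if np.any((arr <= 0) | (arr >= 1)):
                raise ValueError("probabilities must lie strictly in (0, 1)")

    def to_frame(self) -> pd.DataFrame:
        sweep_name = "t_change" if self.fixed_dimension == "gap" else "gap"
        rows = []
        for i, level in enumerate(self.fixed_levels):
            for j, x in enumerate(self.sweep_values):
                rows.append(
                    {
                        "framing": self.framing,
                        self.fixed_dimension: level,
                        sweep_name: float(x),
                        "p_risky_mean": float(self.mean[i, j]),
                        "hdi_low": float(self.hdi_low[i, j]),
                        "hdi_high": float(self.hdi_high[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def _population_draws(results, framing: str):
    draws = results.population_draws()
    i = "positive" if framing == POSITIVE else "negative"
    if framing not in (POSITIVE, NEGATIVE):
        raise ValueError(f"unknown framing {framing!r}")
    n = draws[f"a_{i}"].size
    if n == 0:
        raise ValueError("empty posterior draws")
    zeros = np.zeros(n)
    return (
        draws[f"a_{i}"],
        draws[f"b_{i}"],
        draws.get(f"delta_a_{i}", zeros),
        draws.get(f"delta_b_{i}", zeros),
    )


def _summarise(p_draws: np.ndarray, hdi_mass: float):
    # p_draws: (n_draws, n_levels, n_sweep)
    mean = p_draws.mean(axis=0)
    lo = np.empty_like(mean)
    hi = np.empty_like(mean)
    for i in range(mean.shape[0]):
        for j in range(mean.shape[1]):
            l, h = az.hdi(p_draws[:, i, j], hdi_prob=hdi_mass)
            lo[i, j], hi[i, j] = l, h
    return mean, lo, hi


def risk_vs_testosterone(
    results,
    gap_levels: tuple = DEFAULT_GAP_LEVELS,
    t_grid: np.ndarray | None = None,
    framing: str = POSITIVE,
    hdi_mass: float = 0.94,
) -> CounterfactualGrid:
    """p(risky) as a function of testosterone change at fixed gap levels.

    ``gap_levels`` are signed subjective-value differences in value-function
    units; each is log-compressed before entering the linear predictor.
    """
    if t_grid is None:
        t_grid = np.linspace(0.0, 2.0, 41)
    t_grid = np.asarray(t_grid, dtype=float)
    a, b, da, db = _population_draws(results, framing)
    lg = np.array([log_gap(g) for g in gap_levels])
    # (draws, levels, sweep)
    intercept = a[:, None, None] + da[:, None, None] * t_grid[None, None, :]
    slope = b[:, None, None] + db[:, None, None] * t_grid[None, None, :]
    p = expit(intercept + slope * lg[None, :, None])
    mean, lo, hi = _summarise(p, hdi_mass)
    return CounterfactualGrid(
        fixed_dimension="gap", fixed_levels=tuple(gap_levels),
        sweep_values=t_grid, framing=framing,
        mean=mean, hdi_low=lo, hdi_high=hi, hdi_mass=hdi_mass,
    )


def risk_vs_gain(
    results,
    t_levels: tuple = DEFAULT_T_LEVELS,
    gain_grid: np.ndarray | None = None,
    framing: str = POSITIVE,
    hdi_mass: float = 0.94,
) -> CounterfactualGrid:
    """p(risky) as a function of the subjective-value gap at fixed t_change.

    ``t_levels`` are relative testosterone changes (0.6 = +60%).
    """
    if gain_grid is None:
        gain_grid = np.linspace(0.0, 200.0, 41)
    gain_grid = np.asarray(gain_grid, dtype=float)
    a, b, da, db = _population_draws(results, framing)
    t_levels_arr = np.asarray(t_levels, dtype=float)
    lg = log_gap(gain_grid)
    intercept = a[:, None, None] + da[:, None, None] * t_levels_arr[None, :, None]
    slope = b[:, None, None] + db[:, None, None] * t_levels_arr[None, :, None]
    p = expit(intercept + slope * np.asarray(lg)[None, None, :])
    mean, lo, hi = _summarise(p, hdi_mass)
    return CounterfactualGrid(
        fixed_dimension="t_change", fixed_levels=tuple(t_levels),
        sweep_values=gain_grid, framing=framing,
        mean=mean, hdi_low=lo, hdi_high=hi, hdi_mass=hdi_mass,
    )


def plot_counterfactual(grid: CounterfactualGrid, ax=None):
    """Line-plus-band plot of a counterfactual grid (one line per level)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sweep_name = "t_change" if grid.fixed_dimension == "gap" else "gap (euro)"
    for i, level in enumerate(grid.fixed_levels):
        (line,) = ax.plot(
            grid.sweep_values, grid.mean[i],
            label=f"{grid.fixed_dimension}={level:g}",
        )
        ax.fill_between(
            grid.sweep_values, grid.hdi_low[i], grid.hdi_high[i],
            alpha=0.2, color=line.get_color(),
        )
    ax.set_xlabel(sweep_name)
    ax.set_ylabel("p(risky choice)")
    ax.set_title(f"{grid.framing} framing ({grid.hdi_mass:.0%} HDI)")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax
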