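"""Readers, writers and validation for the study's tabular inputs.

All interchange is plain CSV.  The dialects:

* ``games.csv`` — game_id, framing, p_risky, risky_payoff, sure_payoff with
  payoff *magnitudes* (loss tables print positive numbers); the loader signs
  them by framing.  A packaged fixture carries the study's ten games.
* ``choices.csv`` — subject_id, treatment, game_id, framing, choice
  (1 = risky), optional t_change.
* ``hormones.csv`` — subject_id, session, treatment, timepoint (T0/T1),
  testosterone, cortisol.
* ``endowment.csv`` — subject_id, treatment, session, item_id, goods_type,
  role (WTA/WTP), value.

Validation collects *all* problems found in a file into a single
:class:`ValidationError` so callers (and tests) can assert on the list.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .prospect import FRAMINGS, Game

__all__ = [
    "ValidationError",
    "load_games",
    "load_packaged_games",
    "games_from_frame",
    "games_to_frame",
    "load_choices",
    "load_hormones",
    "impute_hormones",
    "load_endowment",
    "write_frame",
]


class ValidationError(ValueError):
    """Input validation failure carrying the full list of problems."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            f"{len(self.errors)} validation error(s):\n  - "
            + "\n  - ".join(self.errors)
        )


def _require_columns(df: pd.DataFrame, required: set[str], what: str,
                     errors: list[str]) -> bool:
    missing = sorted(required - set(df.columns))
    if missing:
        errors.append(f"{what}: missing columns {missing}")
        return False
    return True


# -- games ------------------------------------------------------------------


def games_from_frame(df: pd.DataFrame) -> list[Game]:
    """Build signed games from a magnitudes table, validating exhaustively."""
    errors: list[str] = []
    required = {"game_id", "framing", "p_risky", "risky_payoff", "sure_payoff"}
    if not _require_columns(df, required, "games", errors):
        raise ValidationError(errors)
    dupes = df.duplicated(subset=["game_id", "framing"])
    for _, row in df[dupes].iterrows():
        errors.append(
            f"games: duplicate game_id {row['game_id']!r} ({row['framing']})"
        )
    games: list[Game] = []
    for i, row in df.iterrows():
        problems = []
        if row["framing"] not in FRAMINGS:
            problems.append(f"unknown framing {row['framing']!r}")
        try:
            p = float(row["p_risky"])
            if not 0 <= p <= 1:
                problems.append(f"p_risky {p} outside [0, 1]")
        except (TypeError, ValueError):
            problems.append(f"malformed p_risky {row['p_risky']!r}")
        try:
            rp, sp = float(row["risky_payoff"]), float(row["sure_payoff"])
            if rp < 0 or sp < 0:
                problems.append("payoff magnitudes must be non-negative")
        except (TypeError, ValueError):
            problems.append("malformed payoff")
        if problems:
            errors.extend(f"games row {i}: {p}" for p in problems)
            continue
        games.append(
            Game.from_magnitudes(
                str(row["game_id"]), row["framing"], p, rp, sp
            )
        )
    if errors:
        raise ValidationError(errors)
    return games


def games_to_frame(games: list[Game]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "game_id": [g.game_id for g in games],
            "framing": [g.framing for g in games],
            "p_risky": [g.p_risky for g in games],
            "risky_payoff": [abs(g.risky.payoff) for g in games],
            "sure_payoff": [abs(g.sure_payoff) for g in games],
        }
    )


def load_games(path) -> list[Game]:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(
            ["games: empty file, missing columns ['framing', 'game_id', "
             "'p_risky', 'risky_payoff', 'sure_payoff']"]
        ) from None
    return games_from_frame(df)


def load_packaged_games() -> list[Game]:
    """The study's ten framed games (five probability levels x two framings)."""
    with resources.files("riskframe.data").joinpath("games.csv").open() as fh:
        return games_from_frame(pd.read_csv(fh))


# -- choices ----------------------------------------------------------------


def load_choices(path, games: list[Game] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    errors: list[str] = []
    required = {"subject_id", "treatment", "game_id", "framing", "choice"}
    if not _require_columns(df, required, "choices", errors):
        raise ValidationError(errors)
    bad_choice = ~df["choice"].isin([0, 1])
    for i in df.index[bad_choice]:
        errors.append(f"choices row {i}: choice {df.loc[i, 'choice']!r} not binary")
    bad_framing = ~df["framing"].isin(FRAMINGS)
    for i in df.index[bad_framing]:
        errors.append(f"choices row {i}: unknown framing {df.loc[i, 'framing']!r}")
    if games is not None:
        known = {(g.game_id, g.framing) for g in games}
        keys = list(zip(df["game_id"].astype(str), df["framing"]))
        for i, key in enumerate(keys):
            if key not in known and not bad_framing.iloc[i]:
                errors.append(f"choices row {i}: unknown game {key}")
    if errors:
        raise ValidationError(errors)
    return df


# -- hormones ---------------------------------------------------------------


def impute_hormones(panel: pd.DataFrame,
                    hormones: tuple[str, ...] = ("testosterone", "cortisol")
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Replace missing hormone values with the treatment-group (x timepoint)
    mean, returning the imputed panel and a log of what was filled."""
    panel = panel.copy()
    log: list[str] = []
    for col in hormones:
        if col not in panel.columns:
            continue
        missing = panel[col].isna()
        if not missing.any():
            continue
        means = panel.groupby(["treatment", "timepoint"])[col].transform("mean")
        for i in panel.index[missing]:
            log.append(
                f"{col}: subject {panel.loc[i, 'subject_id']} "
                f"{panel.loc[i, 'treatment']}/{panel.loc[i, 'timepoint']} "
                f"imputed with group mean {means.loc[i]:.3f}"
            )
        panel.loc[missing, col] = means[missing]
    return panel, log


def load_hormones(path, impute: bool = True
                  ) -> tuple[pd.DataFrame, list[str]]:
    df = pd.read_csv(path)
    errors: list[str] = []
    required = {"subject_id", "session", "treatment", "timepoint", "testosterone"}
    if not _require_columns(df, required, "hormones", errors):
        raise ValidationError(errors)
    bad_tp = ~df["timepoint"].isin(["T0", "T1"])
    for i in df.index[bad_tp]:
        errors.append(
            f"hormones row {i}: timepoint {df.loc[i, 'timepoint']!r} "
            "must be T0 or T1"
        )
    if errors:
        raise ValidationError(errors)
    log: list[str] = []
    if impute:
        df, log = impute_hormones(df)
    return df, log


# -- endowment --------------------------------------------------------------


def load_endowment(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    errors: list[str] = []
    required = {"subject_id", "treatment", "item_id", "goods_type", "role", "value"}
    if not _require_columns(df, required, "endowment", errors):
        raise ValidationError(errors)
    bad_role = ~df["role"].isin(["WTA", "WTP"])
    for i in df.index[bad_role]:
        errors.append(f"endowment row {i}: role {df.loc[i, 'role']!r}")
    bad_type = ~df["goods_type"].isin(["hedonic", "utilitarian"])
    for i in df.index[bad_type]:
        errors.append(
            f"endowment row {i}: goods_type {df.loc[i, 'goods_type']!r}"
        )
    vals = pd.to_numeric(df["value"], errors="coerce")
    bad_val = vals.isna() | (vals < 0)
    for i in df.index[bad_val]:
        errors.append(f"endowment row {i}: bad value {df.loc[i, 'value']!r}")
    if errors:
        raise ValidationError(errors)
    return df


def write_frame(df: pd.DataFrame, path) -> None:
    """CSV writer used by the pipeline (round-trip safe for declared fields)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
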