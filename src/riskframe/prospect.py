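"""Cumulative-prospect-theory primitives for framed binary gambles.

The choice setting is a two-option game: a risky prospect (payoff ``x`` with
probability ``p``, else nothing) against a sure payoff.  Games are *framed*:
under positive framing both payoffs are gains, under negative framing both are
losses.  The subjective value of a prospect is ``V(x, p) = v(x) * w(p)`` where
``v`` is a power value function (steeper for losses by the loss-aversion
multiplier ``lam``) and ``w`` is the one-parameter inverse-S probability
weighting function of Tversky & Kahneman (1992).

Because the payoff gaps in this design span hundreds of euros, the
subjective-value difference between the two options is compressed with a
signed ``log1p`` transform (:func:`log_gap`) before it enters any choice rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Prospect",
    "Game",
    "CPTParams",
    "value_function",
    "weight",
    "prospect_value",
    "gap",
    "log_gap",
    "choice_probability",
    "C_MIN",
]

#: Lower bound on the weighting-function curvature.  Below roughly 0.28 the
#: one-parameter form loses monotonicity on (0, 1); 0.3 keeps a margin.
C_MIN = 0.3

POSITIVE = "positive"
NEGATIVE = "negative"
FRAMINGS = (POSITIVE, NEGATIVE)


@dataclass(frozen=True)
class Prospect:
    """A simple prospect: receive ``payoff`` with ``probability``, else 0.

    ``payoff`` is a signed euro amount (losses are negative).
    """

    payoff: float
    probability: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.payoff):
            raise ValueError(f"payoff must be finite, got {self.payoff}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(
                f"probability must be in [0, 1], got {self.probability}"
            )


@dataclass(frozen=True)
class Game:
    """One framed binary gamble: a risky prospect against a sure payoff.

    Payoffs are stored *signed*: a negative-framing game carries negative
    payoffs even though source tables print loss magnitudes as positive
    numbers (use :meth:`from_magnitudes` for such rows).
    """

    game_id: str
    framing: str
    risky: Prospect
    sure_payoff: float

    def __post_init__(self) -> None:
        if self.framing not in FRAMINGS:
            raise ValueError(
                f"framing must be one of {FRAMINGS}, got {self.framing!r}"
            )
        sign_ok = (
            min(self.risky.payoff, self.sure_payoff) >= 0
            if self.framing == POSITIVE
            else max(self.risky.payoff, self.sure_payoff) <= 0
        )
        if not sign_ok:
            raise ValueError(
                f"game {self.game_id}: {self.framing} framing requires "
                f"{'non-negative' if self.framing == POSITIVE else 'non-positive'}"
                f" payoffs, got risky={self.risky.payoff}, sure={self.sure_payoff}"
            )

    @classmethod
    def from_magnitudes(
        cls, game_id: str, framing: str, p_risky: float,
        risky_payoff: float, sure_payoff: float,
    ) -> "Game":
        """Build a game from *unsigned* payoff magnitudes (table dialect)."""
        if risky_payoff < 0 or sure_payoff < 0:
            raise ValueError(
                f"game {game_id}: magnitudes must be non-negative"
            )
        s = 1.0 if framing == POSITIVE else -1.0
        return cls(
            game_id=str(game_id),
            framing=framing,
            risky=Prospect(payoff=s * risky_payoff, probability=p_risky),
            sure_payoff=s * sure_payoff,
        )

    @property
    def p_risky(self) -> float:
        return self.risky.probability

    @property
    def sure(self) -> Prospect:
        return Prospect(payoff=self.sure_payoff, probability=1.0)


@dataclass(frozen=True)
class CPTParams:
    """CPT parameters with framing-specific curvature.

    alpha : value-function curvature per framing (positive, negative)
    c     : weighting-function curvature per framing
    lam   : loss-aversion multiplier; 1 by default because pure-gain /
            pure-loss games cannot identify it separately from the
            loss-frame slope (kept for mixed-gamble extensions)
    phi   : choice sensitivity of the softmax rule
    """

    alpha: tuple[float, float] = (0.67, 0.96)
    c: tuple[float, float] = (0.82, 0.87)
    lam: float = 1.0
    phi: float = 1.0

    def __post_init__(self) -> None:
        for a in self.alpha:
            if not a > 0:
                raise ValueError(f"alpha must be > 0, got {self.alpha}")
        for cc in self.c:
            if cc < C_MIN:
                raise ValueError(
                    f"c must be >= {C_MIN} (monotonicity), got {self.c}"
                )
        if not self.lam > 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")
        if self.phi < 0:
            raise ValueError(f"phi must be >= 0, got {self.phi}")

    def alpha_for(self, framing: str) -> float:
        return self.alpha[0] if framing == POSITIVE else self.alpha[1]

    def c_for(self, framing: str) -> float:
        return self.c[0] if framing == POSITIVE else self.c[1]

    @classmethod
    def published_defaults(cls) -> "CPTParams":
        """Framing-specific estimates from the external-dataset refit."""
        return cls(alpha=(0.67, 0.96), c=(0.82, 0.87), lam=1.0, phi=1.0)


def value_function(x, alpha: float, lam: float = 1.0):
    """Power value function: ``x**alpha`` for gains, ``-lam*(-x)**alpha`` losses.

    Vectorised over ``x``.  Zero maps to zero.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("payoff must be finite")
    if not alpha > 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if not lam > 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    out = np.where(
        x > 0,
        np.power(np.abs(x), alpha),
        -lam * np.power(np.abs(x), alpha),
    )
    out = np.where(x == 0, 0.0, out)
    return out if out.ndim else float(out)


def weight(p, c: float):
    """One-parameter probability weighting ``p**c / (p**c + (1-p)**c)**(1/c)``.

    Inverse-S shaped for ``c < 1``: small probabilities are overweighted,
    large ones underweighted.  Requires ``c >= C_MIN`` so the function stays
    nondecreasing on [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probability must be in [0, 1]")
    if c < C_MIN:
        raise ValueError(f"c must be >= {C_MIN}, got {c}")
    pc = np.power(p, c)
    qc = np.power(1.0 - p, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = pc / np.power(pc + qc, 1.0 / c)
    # exact endpoints (0**c/0**(1/c) style indeterminacies)
    out = np.where(p == 0.0, 0.0, out)
    out = np.where(p == 1.0, 1.0, out)
    return out if out.ndim else float(out)


def prospect_value(prospect: Prospect, alpha: float, c: float,
                   lam: float = 1.0) -> float:
    """Subjective value ``v(x) * w(p)`` of a simple prospect."""
    return float(
        value_function(prospect.payoff, alpha, lam) * weight(prospect.probability, c)
    )


def gap(game: Game, params: CPTParams) -> float:
    """Signed subjective-value difference, risky minus sure.

    Positive values favour the risky option.  Uses the framing-specific
    ``alpha`` and ``c`` from ``params``.
    """
    a = params.alpha_for(game.framing)
    c = params.c_for(game.framing)
    v_risky = prospect_value(game.risky, a, c, params.lam)
    v_sure = value_function(game.sure_payoff, a, params.lam)  # w(1) = 1
    return float(v_risky - v_sure)


def log_gap(g):
    """Signed log1p compression: ``sign(g) * log(1 + |g|)``.

    Odd and strictly increasing; approximately the identity near zero.
    """
    g = np.asarray(g, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("gap must be finite")
    out = np.sign(g) * np.log1p(np.abs(g))
    return out if out.ndim else float(out)


def choice_probability(v_a, v_b, phi: float):
    """Softmax probability of choosing option A over B.

    ``p = 1 / (1 + exp(-phi * (v_a - v_b)))`` — evaluated in the numerically
    stable sigmoid form; equal values give exactly 0.5.
    """
    if phi < 0:
        raise ValueError(f"phi must be >= 0, got {phi}")
    from scipy.special import expit

    d = np.asarray(v_a, dtype=float) - np.asarray(v_b, dtype=float)
    out = expit(phi * d)
    return out if out.ndim else float(out)
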