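"""Closed-form expected payoff matrix of the Space Dilemma.

Players either compete (midpoint) or cooperate by a symmetric offset Delta into
opposite hemifields.  Integrating over the uniform target gives the expected
per-trial payoffs

    R(Delta)        = 3/8 + Delta/2 - Delta^2            (mutual cooperation)
    T(Delta, alpha) = alpha*(3/8 + Delta/2 - Delta^2/8)
                      + (1-alpha)*(3/8 - 5*Delta^2/8)     (temptation)
    S(Delta, alpha) = alpha*(3/8 - 5*Delta^2/8)
                      + (1-alpha)*(3/8 + Delta/2 - Delta^2/8)  (sucker)
    P               = 3/8                                 (mutual competition)

R and P are independent of the redistribution factor alpha because equally
placed players win equally often.  A Monte-Carlo oracle through the game engine
checks the algebra, and classification helpers locate the game in
prisoner's-dilemma territory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .game import FixedAgent, Context, play_block

__all__ = [
    "PayoffMatrix", "analytic_payoffs", "mc_payoffs", "optimal_delta",
    "ipd_gap", "ipd_boundary", "classify_dilemma", "payoff_grid",
]


@dataclass(frozen=True)
class PayoffMatrix:
    delta: float
    alpha: float
    R: float
    T: float
    S: float
    P: float


def _check_delta(delta: float) -> float:
    delta = float(delta)
    if not 0.0 <= delta <= 0.5:
        raise ValueError(f"delta {delta} outside [0, 0.5]")
    return delta


def analytic_payoffs(delta: float, alpha: float) -> PayoffMatrix:
    """Expected payoffs for all four pure strategy pairings at offset ``delta``."""
    delta = _check_delta(delta)
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    coop_win = 3.0 / 8.0 + delta / 2.0 - delta**2 / 8.0
    coop_lose = 3.0 / 8.0 - 5.0 * delta**2 / 8.0
    R = 3.0 / 8.0 + delta / 2.0 - delta**2
    T = alpha * coop_win + (1.0 - alpha) * coop_lose
    S = alpha * coop_lose + (1.0 - alpha) * coop_win
    return PayoffMatrix(delta, float(alpha), R, T, S, 3.0 / 8.0)


def mc_payoffs(delta1: float, delta2: float, alpha: float,
               n_trials: int = 10000, seed: int | None = None) -> dict:
    """Monte-Carlo expected payoffs via the game engine.

    Player 1 sits at 0.5 - delta1, player 2 at 0.5 + delta2 (delta = 0 means
    competing at the midpoint).  Returns per-player estimates and standard
    errors of the mean.
    """
    _check_delta(delta1)
    _check_delta(delta2)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ctx = Context("custom", float(alpha), 0.5)
    block = play_block(FixedAgent(0.5 - delta1), FixedAgent(0.5 + delta2),
                       ctx, n_trials=n_trials, seed=seed)
    out = {}
    for player in (1, 2):
        r = block.rewards(player)
        out[f"payoff{player}"] = float(r.mean())
        out[f"se{player}"] = float(r.std(ddof=1) / np.sqrt(n_trials))
    return out


def optimal_delta(method: str = "calculus", step: float = 1e-4) -> float:
    """Cooperation offset maximizing the mutual-cooperation payoff R.

    ``calculus`` solves dR/dDelta = 1/2 - 2*Delta = 0; ``grid`` scans
    [0, 0.5] at the given step.
    """
    if method == "calculus":
        return 0.25
    if method == "grid":
        grid = np.arange(0.0, 0.5 + step / 2, step)
        R = 3.0 / 8.0 + grid / 2.0 - grid**2
        return float(grid[np.argmax(R)])
    raise ValueError(f"unknown method {method!r}")


def ipd_gap(delta: float, alpha: float) -> float:
    """Signed gap 2R - (T + S); the alpha terms in T + S cancel exactly."""
    m = analytic_payoffs(delta, alpha)
    return 2.0 * m.R - (m.T + m.S)


def ipd_boundary(alpha: float = 1.0) -> float:
    """The positive Delta where 2R = T + S (iterated-dilemma payoff boundary).

    The boundary is context-independent; ``alpha`` is accepted only so the
    cancellation can be exercised numerically.
    """
    return float(brentq(lambda d: ipd_gap(d, alpha), 1e-9, 0.5, xtol=1e-12))


@dataclass(frozen=True)
class DilemmaFlags:
    strong_pd: bool       # T > R > P > S
    iterated_pd: bool     # 2R > T + S
    gap: float            # signed 2R - (T + S)


def classify_dilemma(delta: float, alpha: float) -> DilemmaFlags:
    """Payoff-ordering flags at the given offset and redistribution factor."""
    if not 0.0 < delta < 0.5:
        raise ValueError(f"delta {delta} outside (0, 0.5)")
    m = analytic_payoffs(delta, alpha)
    strong = m.T > m.R > m.P > m.S
    gap = 2.0 * m.R - (m.T + m.S)
    return DilemmaFlags(bool(strong), bool(gap > 0), float(gap))


def payoff_grid(deltas, alphas):
    """Tidy payoff table over a (delta, alpha) grid, for CSV export."""
    import pandas as pd

    rows = []
    for a in alphas:
        for d in deltas:
            m = analytic_payoffs(d, a)
            rows.append((m.delta, m.alpha, m.R, m.T, m.S, m.P))
    return pd.DataFrame(rows, columns=["delta", "alpha", "R", "T", "S", "P"])
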