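"""The Space Dilemma environment.

Two players each pick a position on the unit line, a target is drawn uniformly
at random, and the player closer to the target wins a reward R = 1 - min(d1, d2)
that a context-dependent redistribution factor ``alpha`` splits between winner
(alpha * R) and loser ((1 - alpha) * R).  Positions are mirrored into a
"cooperation space" theta = |x - 0.5| / 0.5, where 0 is the competitive midpoint
and 1 the fully cooperative edge of either hemifield.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: redistribution factor per social context
CONTEXT_ALPHAS = {"cooperative": 0.5, "competitive": 2.0, "intermediate": 1.0}
#: initial belief mean (in cooperation space) per social context
CONTEXT_PRIOR_MEANS = {"cooperative": 1.0, "competitive": 0.0, "intermediate": 0.5}
#: fixed block order used in the experiment
DEFAULT_BLOCK_ORDER = ("cooperative", "competitive", "intermediate")

SESSION_COLUMNS = [
    "dyad_id", "block_index", "context_label", "alpha", "trial",
    "x1", "x2", "target", "d1", "d2", "winner", "R", "r1", "r2",
]


@dataclass(frozen=True)
class Context:
    """A social context: redistribution factor plus the matching prior belief."""

    label: str
    alpha: float
    prior_mean: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")

    @classmethod
    def from_label(cls, label: str) -> "Context":
        if label not in CONTEXT_ALPHAS:
            raise ValueError(f"unknown context label {label!r}")
        return cls(label, CONTEXT_ALPHAS[label], CONTEXT_PRIOR_MEANS[label])


def default_contexts(order: Sequence[str] = DEFAULT_BLOCK_ORDER) -> list[Context]:
    """The three standard contexts in the given block order."""
    return [Context.from_label(lbl) for lbl in order]


def to_coop_space(x: float) -> float:
    """Map a physical position in [0, 1] to cooperativeness theta = |x-0.5|/0.5."""
    x = float(x)
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"position {x} outside [0, 1]")
    return abs(x - 0.5) / 0.5


def coop_side(x: float) -> str:
    """Hemifield tag of a physical position; x = 0.5 is tagged 'right'."""
    return "left" if x < 0.5 else "right"


def from_coop_space(theta: float, side: str = "right") -> float:
    """Inverse of :func:`to_coop_space` given a hemifield tag."""
    theta = float(theta)
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta {theta} outside [0, 1]; clip before mapping back")
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return 0.5 - 0.5 * theta if side == "left" else 0.5 + 0.5 * theta


@dataclass(frozen=True)
class TrialOutcome:
    """One resolved trial: positions, target, distances, winner and rewards."""

    x1: float
    x2: float
    target: float
    d1: float
    d2: float
    winner: str  # 'player1' | 'player2' | 'tie'
    R: float
    r1: float
    r2: float


def resolve_trial(x1: float, x2: float, target: float, alpha: float) -> TrialOutcome:
    """Resolve a trial: the strictly closer player wins alpha*R, the loser
    (1-alpha)*R; an exact tie splits R in half irrespective of alpha."""
    for name, v in (("x1", x1), ("x2", x2), ("target", target)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    d1 = abs(x1 - target)
    d2 = abs(x2 - target)
    R = 1.0 - min(d1, d2)
    if d1 < d2:
        winner, r1, r2 = "player1", alpha * R, (1.0 - alpha) * R
    elif d2 < d1:
        winner, r1, r2 = "player2", (1.0 - alpha) * R, alpha * R
    else:
        winner, r1, r2 = "tie", R / 2.0, R / 2.0
    return TrialOutcome(x1, x2, target, d1, d2, winner, R, r1, r2)


@dataclass
class Block:
    """One block: a context and its ordered trial outcomes."""

    context: Context
    trials: list[TrialOutcome] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def positions(self, player: int) -> np.ndarray:
        key = "x1" if player == 1 else "x2"
        return np.array([getattr(t, key) for t in self.trials])

    def thetas(self, player: int) -> np.ndarray:
        return np.array([to_coop_space(x) for x in self.positions(player)])

    def rewards(self, player: int) -> np.ndarray:
        key = "r1" if player == 1 else "r2"
        return np.array([getattr(t, key) for t in self.trials])

    def wins(self, player: int) -> np.ndarray:
        """Win indicator per trial; ties count as wins for both players."""
        me = f"player{player}"
        return np.array([t.winner in (me, "tie") for t in self.trials])

    def targets(self) -> np.ndarray:
        return np.array([t.target for t in self.trials])


@dataclass
class SessionLog:
    """A dyad's full session: ordered blocks of trials across contexts."""

    dyad_id: str
    blocks: list[Block] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return sum(len(b) for b in self.blocks)

    def cumulative_reward(self, player: int) -> float:
        return float(sum(b.rewards(player).sum() for b in self.blocks))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bi, block in enumerate(self.blocks):
            for ti, t in enumerate(block.trials):
                rows.append((self.dyad_id, bi, block.context.label,
                             block.context.alpha, ti, t.x1, t.x2, t.target,
                             t.d1, t.d2, t.winner, t.R, t.r1, t.r2))
        return pd.DataFrame(rows, columns=SESSION_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SessionLog":
        missing = set(SESSION_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"session frame missing columns: {sorted(missing)}")
        dyads = df["dyad_id"].unique()
        if len(dyads) != 1:
            raise ValueError(f"expected a single dyad per frame, got {list(dyads)}")
        blocks = []
        for bi, sub in df.sort_values(["block_index", "trial"]).groupby("block_index"):
            label = sub["context_label"].iloc[0]
            ctx = Context(label, float(sub["alpha"].iloc[0]),
                          CONTEXT_PRIOR_MEANS.get(label, 0.5))
            trials = [TrialOutcome(r.x1, r.x2, r.target, r.d1, r.d2, r.winner,
                                   r.R, r.r1, r.r2)
                      for r in sub.itertuples()]
            blocks.append(Block(ctx, trials))
        return cls(str(dyads[0]), blocks)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "SessionLog":
        return cls.from_frame(pd.read_csv(path))


def play_block(agent1, agent2, context: Context, n_trials: int = 60,
               seed: int | np.random.Generator | None = None) -> Block:
    """Closed-loop simulation of one block.

    Agents expose ``choose(rng) -> physical position`` and
    ``observe(outcome, role)``; targets are i.i.d. uniform.  Draw order per
    trial is fixed (x1, x2, target) so a seed reproduces the block exactly.
    Out-of-range agent choices are clipped to [0, 1] and logged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    block = Block(context)
    for t in range(n_trials):
        xs = []
        for i, agent in enumerate((agent1, agent2), start=1):
            x = float(agent.choose(rng))
            if not 0.0 <= x <= 1.0:
                logger.warning("agent %d returned out-of-range position %.4f "
                               "on trial %d; clipped", i, x, t)
                x = float(np.clip(x, 0.0, 1.0))
            xs.append(x)
        target = float(rng.uniform())
        outcome = resolve_trial(xs[0], xs[1], target, context.alpha)
        agent1.observe(outcome, role=1)
        agent2.observe(outcome, role=2)
        block.trials.append(outcome)
    return block


class FixedAgent:
    """Degenerate agent that always plays the same physical position."""

    def __init__(self, x: float):
        self.x = float(x)

    def choose(self, rng) -> float:  # noqa: ARG002 - uniform contract
        return self.x

    def observe(self, outcome, role) -> None:
        pass
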