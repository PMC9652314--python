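"""Synthetic dyads and cohorts with the structure the analysis assumes.

A dyad is two generative zoo agents playing the standard session: three
60-trial blocks in the fixed context order cooperative -> competitive ->
intermediate, starting on opposite hemifields.  Cohorts sample per-player
parameters from configurable ranges.  Behavioural summaries mirror the
standard descriptive analyses: per-block competitiveness, inter-player
distance, and the reciprocation table built by binning co-player position
changes (toward the midpoint = increase in competition) into small/large
increases of cooperation/competition and averaging the player's next-trial
change within each bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .game import (Block, Context, DEFAULT_BLOCK_ORDER, SessionLog,
                   default_contexts, play_block)
from .models import ModelAgent, get_spec

__all__ = [
    "AgentConfig", "generate_dyad", "Cohort", "sample_cohort",
    "BehaviouralSummary", "behavioural_summary",
]


@dataclass(frozen=True)
class AgentConfig:
    model_id: str
    params: dict
    side: str = "right"

    def build(self) -> ModelAgent:
        return ModelAgent(self.model_id, self.params, self.side)


def generate_dyad(model1: str, params1: dict, model2: str, params2: dict,
                  contexts: list[Context] | None = None, n_trials: int = 60,
                  seed: int | None = None,
                  dyad_id: str = "dyad000") -> SessionLog:
    """Simulate a full closed-loop session for one dyad.

    Agents start on opposite hemifields (which player takes the left side is
    randomized by the seed) and keep their side across blocks; beliefs reset
    at each block start.  Fully reproducible from the seed.
    """
    ss = np.random.SeedSequence(seed)
    side_rng = np.random.default_rng(ss.spawn(1)[0])
    sides = ("left", "right") if side_rng.uniform() < 0.5 else ("right", "left")
    agent1 = ModelAgent(model1, params1, sides[0])
    agent2 = ModelAgent(model2, params2, sides[1])
    if contexts is None:
        contexts = default_contexts()
    session = SessionLog(dyad_id)
    for ctx, child in zip(contexts, ss.spawn(len(contexts))):
        agent1.start_block(ctx)
        agent2.start_block(ctx)
        session.blocks.append(play_block(
            agent1, agent2, ctx, n_trials=n_trials,
            seed=np.random.default_rng(child)))
    return session


@dataclass
class Cohort:
    sessions: list[SessionLog]
    params: pd.DataFrame  # one row per (dyad, player) with generating values

    def __len__(self) -> int:
        return len(self.sessions)


def sample_cohort(n_dyads: int = 25, seed: int | None = None,
                  model_id: str = "B6", ranges: dict | None = None,
                  n_trials: int = 60,
                  contexts: list[Context] | None = None) -> Cohort:
    """Independent dyads with per-player parameters sampled from ``ranges``."""
    from .inference import DEFAULT_B6_RANGES, _sample_params

    if n_dyads < 1:
        raise ValueError("n_dyads must be >= 1")
    spec = get_spec(model_id)
    if ranges is None:
        if model_id != "B6":
            raise ValueError(f"sampling ranges are required for {model_id}")
        ranges = dict(DEFAULT_B6_RANGES)
    ss = np.random.SeedSequence(seed)
    sessions, rows = [], []
    for d, child in enumerate(ss.spawn(n_dyads)):
        prng, srng = child.spawn(2)
        rng = np.random.default_rng(prng)
        p1 = _sample_params(spec, ranges, rng)
        p2 = _sample_params(spec, ranges, rng)
        dyad_id = f"dyad{d:03d}"
        sessions.append(generate_dyad(
            model_id, p1, model_id, p2, contexts=contexts, n_trials=n_trials,
            seed=int(srng.generate_state(1)[0] % 2**31), dyad_id=dyad_id))
        for player, p in ((1, p1), (2, p2)):
            rows.append({"dyad_id": dyad_id, "player": player,
                         "model_id": model_id, **p})
    return Cohort(sessions, pd.DataFrame(rows))


# --------------------------------------------------------------------------
# Behavioural summaries


@dataclass
class BehaviouralSummary:
    per_block: pd.DataFrame      # context, mean theta, competitiveness, distance
    reciprocation: pd.DataFrame  # context x deviation bin -> mean own response


def _median_split_bins(co_dev: np.ndarray) -> np.ndarray:
    """Four ordered bins of co-player theta changes: large/small increases in
    competition (negative dev) then small/large increases in cooperation.

    Within each sign, a rank-based median split keeps group sizes within one.
    Zero changes count as (small) increases in cooperation.
    """
    labels = np.empty(len(co_dev), dtype=object)
    for sign, (lo_lab, hi_lab) in ((-1, ("comp_small", "comp_large")),
                                   (1, ("coop_small", "coop_large"))):
        idx = np.where(co_dev < 0 if sign < 0 else co_dev >= 0)[0]
        if idx.size == 0:
            continue
        order = idx[np.argsort(np.abs(co_dev[idx]), kind="stable")]
        half = idx.size // 2
        labels[order[:half]] = lo_lab
        labels[order[half:]] = hi_lab
    return labels


BIN_ORDER = ["comp_large", "comp_small", "coop_small", "coop_large"]


def behavioural_summary(session: SessionLog) -> BehaviouralSummary:
    """Descriptive per-block statistics and the reciprocation table.

    Competitiveness is the mean distance from the closest edge,
    (1 - theta) / 2 in physical units; reciprocation relates the co-player's
    change in cooperativeness on trial t-1 to the player's change on trial t,
    pooled over both players serving as the focal player.
    """
    block_rows, recip_rows = [], []
    for block in session.blocks:
        th1, th2 = block.thetas(1), block.thetas(2)
        x1, x2 = block.positions(1), block.positions(2)
        block_rows.append({
            "context": block.context.label,
            "alpha": block.context.alpha,
            "mean_theta": float(np.mean(np.concatenate([th1, th2]))),
            "competitiveness": float(np.mean(
                (1.0 - np.concatenate([th1, th2])) / 2.0)),
            "mean_distance": float(np.mean(np.abs(x1 - x2))),
            "dyad_reward": float(block.rewards(1).sum()
                                 + block.rewards(2).sum()),
        })
        for own, co in ((th1, th2), (th2, th1)):
            own_dev = np.diff(own)
            co_dev = np.diff(co)
            if len(co_dev) < 2:
                continue
            bins = _median_split_bins(co_dev[:-1])   # co change on t-1
            response = own_dev[1:]                   # own change on t
            for b, r in zip(bins, response):
                recip_rows.append({"context": block.context.label,
                                   "bin": b, "own_next_dev": float(r)})
    recip = (pd.DataFrame(recip_rows)
             .groupby(["context", "bin"], as_index=False)
             .agg(mean_own_dev=("own_next_dev", "mean"),
                  n=("own_next_dev", "size")))
    recip["bin"] = pd.Categorical(recip["bin"], categories=BIN_ORDER,
                                  ordered=True)
    recip = recip.sort_values(["context", "bin"]).reset_index(drop=True)
    return BehaviouralSummary(pd.DataFrame(block_rows), recip)
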