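"""Model-based trial regressors and fMRI design-file export.

For each block the table carries, per trial:

* ``PriorPos`` — the expected co-player position under the belief *prior* to
  the reveal (aligned to trial onset),
* ``Pcoop`` — the player's change in cooperativeness at response (0 on the
  first trial),
* ``absPE`` / ``signPE`` — magnitude (KL divergence, prior vs posterior) and
  direction of the social prediction error, aligned to the co-player reveal,
* ``Rew`` / ``Win`` — allocated reward and a +/-1 win indicator at target
  reveal.

All parametric columns are z-scored within block (the +/-1 columns after
construction).  Event timings emulate the task's trial structure: a 4-s
response sweep, a 1-1.5-s reveal, a 1.5-s target epoch and 2-2.5-s
inter-trial intervals.  Export writes one three-column (onset, duration,
weight) stick-function file per regressor.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .game import Block
from .inference import session_features  # noqa: F401  (re-export convenience)
from .models import BlockFeatures, compute_block_features
from .game import to_coop_space

logger = logging.getLogger(__name__)

__all__ = [
    "build_regressor_table", "bin_pe_trials", "simulate_event_timings",
    "export_ev_files", "PARAMETRIC_COLUMNS", "EV_FILES",
]

PARAMETRIC_COLUMNS = ["PriorPos", "Pcoop", "absPE", "signPE", "Rew", "Win"]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd < 1e-12:
        logger.warning("degenerate regressor (zero variance); left at zero")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def block_features(block: Block, player: int) -> BlockFeatures:
    """Run the Bayesian learner over one block for one player."""
    theta_self = block.thetas(player)
    theta_co = block.thetas(3 - player)
    theta_target = np.array([to_coop_space(x) for x in block.targets()])
    return compute_block_features(theta_self, theta_co, theta_target,
                                  block.wins(player), block.context)


def build_regressor_table(block: Block, player: int = 1,
                          features: BlockFeatures | None = None) -> pd.DataFrame:
    """Trial-by-trial parametric regressors for one player's block.

    Raw quantities are kept in ``*_raw`` columns; the plain columns are
    z-scored within the block.
    """
    if features is None:
        features = block_features(block, player)
    n = features.n
    pcoop = np.diff(features.theta_self, prepend=features.theta_self[0])
    raw = {
        "PriorPos": features.belief_mean,
        "Pcoop": pcoop,
        "absPE": features.kld_mag,
        "signPE": features.kld_sgn.astype(float),
        "Rew": block.rewards(player),
        "Win": np.where(block.wins(player), 1.0, -1.0),
    }
    table = pd.DataFrame({"trial": np.arange(n)})
    for name, values in raw.items():
        table[f"{name}_raw"] = values
        table[name] = _zscore(np.asarray(values, dtype=float))
    return table


def bin_pe_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Partition trials into four prediction-error groups.

    Sign first (positive = co-player more cooperative than expected), then a
    rank-based median split on the unsigned magnitude within each sign, so
    within-sign group sizes differ by at most one.  If one sign is absent the
    result degenerates to two groups and a warning is logged.
    """
    sign = table["signPE_raw"].to_numpy()
    mag = table["absPE_raw"].to_numpy()
    labels = np.empty(len(table), dtype=object)
    present = 0
    for s, (lo, hi) in ((1, ("PE+", "PE++")), (-1, ("PE-", "PE--"))):
        idx = np.where(sign == s)[0]
        if idx.size == 0:
            continue
        present += 1
        order = idx[np.argsort(mag[idx], kind="stable")]
        half = idx.size // 2
        labels[order[:half]] = lo
        labels[order[half:]] = hi
    if present < 2:
        logger.warning("only one prediction-error sign present; "
                       "binning degenerates to two groups")
    out = table[["trial"]].copy()
    out["pe_bin"] = labels
    return out


def simulate_event_timings(n_trials: int, seed: int | None = None,
                           positions: np.ndarray | None = None) -> pd.DataFrame:
    """Synthetic event onsets for one block, in seconds.

    The response bar sweeps the space in 4 s, so the response onset is
    trial onset + 4 * position when positions are supplied (uniform in
    [0, 4] s otherwise); the co-player reveal follows the full 4-s sweep and
    lasts 1-1.5 s, the target epoch 1.5 s, and inter-trial intervals are
    2-2.5 s.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    if positions is None:
        rt = rng.uniform(0.0, 4.0, n_trials)
    else:
        positions = np.asarray(positions, dtype=float)
        if len(positions) != n_trials:
            raise ValueError("positions length must equal n_trials")
        rt = 4.0 * positions
    reveal_dur = rng.uniform(1.0, 1.5, n_trials)
    iti = rng.uniform(2.0, 2.5, n_trials)
    target_dur = np.full(n_trials, 1.5)

    trial_onset = np.empty(n_trials)
    t = 0.0
    for i in range(n_trials):
        trial_onset[i] = t
        t += 4.0 + reveal_dur[i] + target_dur[i] + iti[i]
    reveal_onset = trial_onset + 4.0
    return pd.DataFrame({
        "trial": np.arange(n_trials),
        "trial_onset": trial_onset,
        "response_onset": trial_onset + rt,
        "reveal_onset": reveal_onset,
        "reveal_duration": reveal_dur,
        "target_onset": reveal_onset + reveal_dur,
        "target_duration": target_dur,
        "iti": iti,
    })


#: regressor -> (timing column for onsets, weight column or None for sticks)
EV_FILES = {
    "trial": ("trial_onset", None),
    "response": ("response_onset", None),
    "reveal": ("reveal_onset", None),
    "target": ("target_onset", None),
    "priorpos": ("trial_onset", "PriorPos"),
    "pcoop": ("response_onset", "Pcoop"),
    "abspe": ("reveal_onset", "absPE"),
    "signpe": ("reveal_onset", "signPE"),
    "rew": ("target_onset", "Rew"),
    "win": ("target_onset", "Win"),
}


def export_ev_files(table: pd.DataFrame, timing: pd.DataFrame,
                    directory, prefix: str = "ev") -> list[Path]:
    """Write one three-column (onset, duration, weight) file per regressor.

    Four unmodulated stick regressors mark the trial events; six parametric
    sticks carry the z-scored trial quantities, each aligned to its event.
    """
    if len(table) != len(timing):
        raise ValueError("table and timing must align trial-for-trial")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, (onset_col, weight_col) in EV_FILES.items():
        onsets = timing[onset_col].to_numpy()
        weights = (np.ones(len(table)) if weight_col is None
                   else table[weight_col].to_numpy())
        out = np.column_stack([onsets, np.zeros(len(table)), weights])
        path = directory / f"{prefix}_{name}.txt"
        np.savetxt(path, out, fmt="%.6f", delimiter="\t")
        paths.append(path)
    return paths
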