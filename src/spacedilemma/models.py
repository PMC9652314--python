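"""The behavioural model zoo: 18 models in three families.

Every model maps the trial state to a predicted choice mean in cooperation
space; the realized choice is Gaussian around that mean with SD equal to the
inverse of a Precision parameter.

* Simple models S1-S4 react to the co-player's last observed position or its
  last change.
* Bayesian models B1-B8 reciprocate the *expected* co-player position given by
  the grid Bayesian learner, optionally scaled by a tit-for-tat factor that a
  social-risk sensitivity (q_risk) discounts in riskier contexts
  (social risk = 2*alpha - 1), plus an additive social bias.  B4/B5 add a
  (useless, by design) belief over the random target; B7/B8 add a learned
  expectation of betrayal.
* Reward models R1-R6 shift the previous choice toward cooperation after a win
  and toward competition after a loss (R2/R4/R6: along/against the previous
  movement direction).

For likelihood evaluation R1-R4 propagate the model's own predicted previous
choice; R5/R6 anchor on the participant's observed previous choice.  During
generative simulation every model uses realized quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import beliefs
from .beliefs import (BeliefState, DISCREPANCY_GRID, SIGMA_FLOOR, SIGMA_PRIOR,
                      belief_mean, init_belief, kld, kld_sign, update_belief)
from .game import Context, TrialOutcome, coop_side, from_coop_space, to_coop_space

__all__ = [
    "ParamSpec", "ModelSpec", "MODEL_SPECS", "MODEL_IDS", "get_spec",
    "social_risk", "titxtat_factor", "sample_choice",
    "BlockFeatures", "compute_block_features", "predict_means",
    "ModelAgent",
]


@dataclass(frozen=True)
class ParamSpec:
    """One named, box-bounded model parameter.

    ``log_scale`` marks parameters optimized (and sampled) on a log10 scale;
    ``start_lower``/``start_upper`` bound the random multi-start inits (a
    sub-box of the feasible region where realistic fits live).
    """

    name: str
    lower: float
    upper: float
    log_scale: bool = False
    start_lower: float | None = None
    start_upper: float | None = None

    @property
    def start_bounds(self) -> tuple[float, float]:
        lo = self.lower if self.start_lower is None else self.start_lower
        hi = self.upper if self.start_upper is None else self.start_upper
        return lo, hi


_PRECISION = ParamSpec("precision", 1e-3, 10000.0, log_scale=True,
                       start_lower=1.0, start_upper=1000.0)
_SOCIAL_BIAS = ParamSpec("social_bias", -1000.0, 1000.0,
                         start_lower=-2.0, start_upper=2.0)
_TITXTAT = ParamSpec("titxtat", 0.0, 2.0)
_Q_RISK = ParamSpec("q_risk", 0.0, 10.0, start_lower=0.0, start_upper=3.0)
_TARGET_BIAS = ParamSpec("target_bias", -1000.0, 1000.0,
                         start_lower=-2.0, start_upper=2.0)
_BETRAYAL = ParamSpec("betrayal_sensitivity", 0.0, 10.0,
                      start_lower=0.0, start_upper=3.0)
_SHIFT_WIN = ParamSpec("shift_win", 0.0, 10.0, start_lower=0.0, start_upper=1.0)
_SHIFT_LOSE = ParamSpec("shift_lose", 0.0, 10.0, start_lower=0.0, start_upper=1.0)


@dataclass(frozen=True)
class ModelSpec:
    model_id: str
    family: str  # 'simple' | 'bayesian' | 'reward'
    params: tuple[ParamSpec, ...]

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.params)

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.params)

    def validate(self, params: dict) -> None:
        if set(params) != set(self.param_names):
            raise ValueError(
                f"{self.model_id} expects parameters {self.param_names}, "
                f"got {tuple(sorted(params))}")
        for spec in self.params:
            v = params[spec.name]
            if not spec.lower <= v <= spec.upper:
                raise ValueError(
                    f"{self.model_id}: {spec.name}={v} outside "
                    f"[{spec.lower}, {spec.upper}]")


def _spec(model_id, family, *params):
    return ModelSpec(model_id, family, (_PRECISION, *params))


MODEL_SPECS: dict[str, ModelSpec] = {s.model_id: s for s in [
    _spec("S1", "simple"),
    _spec("S2", "simple", _SOCIAL_BIAS),
    ModelSpec("S3", "simple", (_PRECISION,
                               replace(_SOCIAL_BIAS, name="social_bias_cooperative"),
                               replace(_SOCIAL_BIAS, name="social_bias_competitive"),
                               replace(_SOCIAL_BIAS, name="social_bias_intermediate"))),
    _spec("S4", "simple", _SOCIAL_BIAS, _TITXTAT),
    _spec("B1", "bayesian"),
    _spec("B2", "bayesian", _SOCIAL_BIAS),
    _spec("B3", "bayesian", _SOCIAL_BIAS, _TITXTAT),
    _spec("B4", "bayesian", _SOCIAL_BIAS, _TITXTAT, _TARGET_BIAS),
    _spec("B5", "bayesian", _SOCIAL_BIAS, _TARGET_BIAS, _Q_RISK),
    _spec("B6", "bayesian", _SOCIAL_BIAS, _TITXTAT, _Q_RISK),
    _spec("B7", "bayesian", _SOCIAL_BIAS, _TITXTAT, _Q_RISK, _BETRAYAL),
    _spec("B8", "bayesian", _SOCIAL_BIAS, _TITXTAT, _Q_RISK, _BETRAYAL),
    _spec("R1", "reward", _SHIFT_WIN, _SHIFT_LOSE),
    _spec("R2", "reward", _SHIFT_WIN, _SHIFT_LOSE),
    _spec("R3", "reward", _SHIFT_WIN, _SHIFT_LOSE, _SOCIAL_BIAS, _TITXTAT),
    _spec("R4", "reward", _SHIFT_WIN, _SHIFT_LOSE, _SOCIAL_BIAS, _TITXTAT),
    _spec("R5", "reward", _SHIFT_WIN, _SHIFT_LOSE),
    _spec("R6", "reward", _SHIFT_WIN, _SHIFT_LOSE),
]}

MODEL_IDS = tuple(MODEL_SPECS)


def get_spec(model_id: str) -> ModelSpec:
    try:
        return MODEL_SPECS[model_id]
    except KeyError:
        raise ValueError(f"unknown model id {model_id!r}") from None


def param_table():
    """Machine-readable table of every model's parameters and bounds."""
    import pandas as pd

    rows = [(s.model_id, s.family, p.name, p.lower, p.upper, p.log_scale)
            for s in MODEL_SPECS.values() for p in s.params]
    return pd.DataFrame(rows, columns=["model_id", "family", "parameter",
                                       "lower", "upper", "log_scale"])


def social_risk(alpha: float) -> float:
    """Social risk of a context: 2*alpha - 1 (0 when the reward is shared)."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return 2.0 * alpha - 1.0


def titxtat_factor(params: dict, alpha: float, model_id: str,
                   betrayal: float = 0.0) -> float:
    """Context-discounted tit-for-tat multiplier.

    B5 uses numerator 1; B6-B8 use the TitXTat parameter.  B7 inflates the
    social risk by betrayal_sensitivity * expected betrayal.
    """
    if model_id not in ("B5", "B6", "B7", "B8"):
        raise ValueError(f"{model_id} has no tit-for-tat factor")
    risk = social_risk(alpha)
    if model_id == "B7":
        risk = risk + params["betrayal_sensitivity"] * betrayal
    denom = 1.0 + params["q_risk"] * risk
    if denom <= 0:
        raise ValueError(f"non-positive tit-for-tat denominator {denom}")
    numer = 1.0 if model_id == "B5" else params["titxtat"]
    return numer / denom


def sample_choice(mean: float, precision: float, rng: np.random.Generator) -> float:
    """Draw a realized choice: Normal(mean, SD = 1/precision) clipped to [0, 1].

    Clipping applies to simulation only; likelihood evaluation uses the
    unbounded Gaussian.
    """
    if precision <= 0:
        raise ValueError("precision must be positive")
    return float(np.clip(rng.normal(mean, 1.0 / precision), 0.0, 1.0))


# --------------------------------------------------------------------------
# Per-block, parameter-free trial features shared by fitting and regressors


@dataclass
class BlockFeatures:
    """Everything a model needs about one player's block, precomputed once.

    All sequences are length n (trials).  Belief-derived quantities are
    parameter-free: the learner's prior and likelihood widths are fixed by the
    data, so they can be shared across all parameter evaluations of a fit.
    """

    context: Context
    theta_self: np.ndarray       # own choices in cooperation space
    theta_co: np.ndarray         # co-player choices in cooperation space
    win: np.ndarray              # own win indicator (ties count as wins)
    belief_mean: np.ndarray      # E[P(theta_co)] *before* each trial's reveal
    target_mean: np.ndarray      # E[target belief] before each trial
    betrayal: np.ndarray         # expected betrayal b(t) before each trial
    kld_mag: np.ndarray          # KL(prior || posterior) at each reveal
    kld_sgn: np.ndarray          # +/-1 direction of each belief update
    prior_sd: np.ndarray         # SD of the belief before each reveal

    @property
    def n(self) -> int:
        return len(self.theta_self)

    def to_frame(self):
        """Belief trajectory and trial features as a tidy frame."""
        import pandas as pd

        return pd.DataFrame({
            "trial": np.arange(self.n),
            "theta_self": self.theta_self,
            "theta_co": self.theta_co,
            "win": self.win,
            "belief_mean": self.belief_mean,
            "target_mean": self.target_mean,
            "betrayal": self.betrayal,
            "kld_mag": self.kld_mag,
            "kld_sgn": self.kld_sgn,
            "prior_sd": self.prior_sd,
        })


def _belief_sd(state: BeliefState) -> float:
    m = belief_mean(state)
    grid, pdf = state.grid, state.posterior_pdf
    var = float(((grid - m) ** 2 * pdf).sum() * (grid[1] - grid[0]))
    return float(np.sqrt(max(var, 0.0)))


def compute_block_features(theta_self, theta_co, theta_target, win,
                           context: Context) -> BlockFeatures:
    """Run the Bayesian learners over one block and collect trial features."""
    theta_self = np.asarray(theta_self, dtype=float)
    theta_co = np.asarray(theta_co, dtype=float)
    theta_target = np.asarray(theta_target, dtype=float)
    win = np.asarray(win, dtype=bool)
    n = len(theta_self)
    if not (len(theta_co) == len(theta_target) == len(win) == n):
        raise ValueError("feature inputs must share the same length")

    co_belief = init_belief(context.prior_mean)
    tgt_belief = init_belief(0.5)
    bet_belief = init_belief(0.0, grid=DISCREPANCY_GRID)
    bet_history: list[float] = []

    m = np.empty(n)
    mt = np.empty(n)
    b = np.empty(n)
    kmag = np.empty(n)
    ksgn = np.empty(n, dtype=int)
    psd = np.empty(n)
    for t in range(n):
        m[t] = belief_mean(co_belief)
        mt[t] = belief_mean(tgt_belief)
        b[t] = max(0.0, belief_mean(bet_belief))
        psd[t] = _belief_sd(co_belief)
        # reveal: observe the co-player, the target, and the discrepancy
        co_belief = update_belief(co_belief, theta_co[t])
        kmag[t] = kld(co_belief.prior_pdf, co_belief.posterior_pdf)
        ksgn[t] = kld_sign(co_belief.prior_pdf, co_belief.posterior_pdf)
        tgt_belief = update_belief(tgt_belief, theta_target[t])
        disc = float(np.clip(m[t] - theta_co[t], -1.0, 1.0))
        sigma = SIGMA_PRIOR if len(bet_history) < 2 else max(
            float(np.std(bet_history, ddof=1)), SIGMA_FLOOR)
        bet_history.append(disc)
        bet_belief = _update_with_sigma(bet_belief, disc, sigma, bet_history)
    return BlockFeatures(context, theta_self, theta_co, win, m, mt, b,
                         kmag, ksgn, psd)


def _update_with_sigma(state: BeliefState, obs: float, sigma: float,
                       history: list[float]) -> BeliefState:
    """Grid update with an externally supplied likelihood sigma (betrayal
    tracking pools discrepancies rather than raw positions)."""
    grid = state.grid
    log_prior = np.log(np.maximum(state.posterior_pdf, beliefs.DENSITY_FLOOR))
    log_like = -0.5 * ((grid - obs) / sigma) ** 2
    post = np.exp(log_prior + log_like - (log_prior + log_like).max())
    post /= post.sum() * (grid[1] - grid[0])
    return BeliefState(grid, state.posterior_pdf.copy(), post, sigma,
                       list(history))


# --------------------------------------------------------------------------
# Predicted choice means


def _social_bias(params: dict, context: Context) -> float:
    if "social_bias" in params:
        return params["social_bias"]
    return params[f"social_bias_{context.label}"]


def predict_means(model_id: str, params: dict, f: BlockFeatures) -> np.ndarray:
    """Predicted choice mean per trial (theta units), NaN at trial 1.

    Means are not clipped: the likelihood is an unbounded Gaussian.  R1-R4
    recurse through their own fitted previous prediction; R5/R6 use the
    observed previous choice.
    """
    spec = get_spec(model_id)
    spec.validate(params)
    n = f.n
    mean = np.full(n, np.nan)
    ctx = f.context
    prev_co = f.theta_co[:-1]          # theta_co(t-1) aligned to trials 1..n-1
    prev_self = f.theta_self[:-1]
    prev_win = f.win[:-1]

    if model_id == "S1":
        mean[1:] = prev_co
    elif model_id in ("S2", "S3"):
        dco = np.diff(f.theta_co, prepend=f.theta_co[0])  # delta is 0 at t=0
        mean[1:] = _social_bias(params, ctx) + prev_self + dco[:-1]
    elif model_id == "S4":
        mean[1:] = params["social_bias"] + params["titxtat"] * prev_co
    elif model_id == "B1":
        mean[1:] = f.belief_mean[1:]
    elif model_id == "B2":
        mean[1:] = f.belief_mean[1:] + params["social_bias"]
    elif model_id == "B3":
        mean[1:] = (params["titxtat"] * f.belief_mean[1:]
                    + params["social_bias"])
    elif model_id == "B4":
        mean[1:] = (params["titxtat"] * f.belief_mean[1:]
                    + params["social_bias"]
                    + params["target_bias"] * f.target_mean[1:])
    elif model_id == "B5":
        fac = titxtat_factor(params, ctx.alpha, "B5")
        mean[1:] = (fac * f.belief_mean[1:] + params["social_bias"]
                    + params["target_bias"] * f.target_mean[1:])
    elif model_id == "B6":
        fac = titxtat_factor(params, ctx.alpha, "B6")
        mean[1:] = fac * f.belief_mean[1:] + params["social_bias"]
    elif model_id == "B7":
        risk = (social_risk(ctx.alpha)
                + params["betrayal_sensitivity"] * f.betrayal[1:])
        denom = 1.0 + params["q_risk"] * risk
        if np.any(denom <= 0):
            raise ValueError("non-positive tit-for-tat denominator in B7")
        mean[1:] = (params["titxtat"] / denom * f.belief_mean[1:]
                    + params["social_bias"])
    elif model_id == "B8":
        fac = titxtat_factor(params, ctx.alpha, "B8")
        mean[1:] = (fac * f.belief_mean[1:] + params["social_bias"]
                    - params["betrayal_sensitivity"] * f.betrayal[1:])
    elif model_id in ("R1", "R2"):
        step_mag = np.where(prev_win, params["shift_win"], -params["shift_lose"])
        if model_id == "R2":
            flips = np.where(prev_win, 1.0, -1.0)
            step_mag = np.cumprod(flips) * np.abs(step_mag)
        pred = f.theta_self[0] + np.cumsum(step_mag)
        mean[1:] = pred
    elif model_id == "R3":
        shift = np.where(prev_win, params["shift_win"], -params["shift_lose"])
        mean[1:] = (params["social_bias"] + params["titxtat"] * prev_co + shift)
    elif model_id == "R4":
        base = params["social_bias"] + params["titxtat"] * prev_co
        pred_prev2, pred_prev1 = f.theta_self[0], f.theta_self[0]
        for t in range(1, n):
            direction = 1.0 if pred_prev1 >= pred_prev2 else -1.0
            mag = params["shift_win"] if prev_win[t - 1] else params["shift_lose"]
            sgn = direction if prev_win[t - 1] else -direction
            mean[t] = base[t - 1] + sgn * mag
            pred_prev2, pred_prev1 = pred_prev1, mean[t]
    elif model_id == "R5":
        mean[1:] = prev_self + np.where(prev_win, params["shift_win"],
                                        -params["shift_lose"])
    elif model_id == "R6":
        dself = np.diff(f.theta_self, prepend=f.theta_self[0])[:-1]
        direction = np.where(dself >= 0, 1.0, -1.0)
        mag = np.where(prev_win, params["shift_win"], params["shift_lose"])
        sgn = np.where(prev_win, direction, -direction)
        mean[1:] = prev_self + sgn * mag
    else:  # pragma: no cover - registry guards this
        raise ValueError(f"unknown model id {model_id!r}")
    return mean


# --------------------------------------------------------------------------
# Generative agents


@dataclass
class AgentState:
    """Mutable per-block state of a generative agent."""

    context: Context
    co_belief: BeliefState
    target_belief: BeliefState
    betrayal_belief: BeliefState
    betrayal_history: list[float] = field(default_factory=list)
    own_history: list[float] = field(default_factory=list)     # own theta
    co_history: list[float] = field(default_factory=list)      # co theta
    win_history: list[bool] = field(default_factory=list)
    expected_co: float = 0.5      # belief mean cached before the next trial
    expected_target: float = 0.5
    expected_betrayal: float = 0.0


class ModelAgent:
    """A zoo model playing the game generatively.

    The agent chooses in cooperation space (mean from its model, Gaussian
    noise with SD 1/precision, clipped to [0, 1]) and maps the choice to its
    hemifield.  All reward models anchor on the *realized* previous choice
    during simulation.
    """

    def __init__(self, model_id: str, params: dict, side: str = "right"):
        self.spec = get_spec(model_id)
        self.spec.validate(params)
        self.model_id = model_id
        self.params = dict(params)
        if side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        self.side = side
        self.state: AgentState | None = None

    def start_block(self, context: Context) -> None:
        self.state = AgentState(
            context=context,
            co_belief=init_belief(context.prior_mean),
            target_belief=init_belief(0.5),
            betrayal_belief=init_belief(0.0, grid=DISCREPANCY_GRID),
            expected_co=belief_mean(init_belief(context.prior_mean)),
            expected_target=belief_mean(init_belief(0.5)),
        )

    # -- choice -----------------------------------------------------------

    def predict_next_mean(self) -> float:
        """Model-predicted mean for the upcoming trial given current state."""
        s = self.state
        if s is None:
            raise RuntimeError("start_block must be called before choosing")
        if not s.own_history:
            return s.context.prior_mean  # history-free first trial
        p, ctx = self.params, s.context
        mid = self.model_id
        th_prev = s.co_history[-1]
        own_prev = s.own_history[-1]
        if mid == "S1":
            return th_prev
        if mid in ("S2", "S3"):
            dco = (s.co_history[-1] - s.co_history[-2]
                   if len(s.co_history) >= 2 else 0.0)
            return _social_bias(p, ctx) + own_prev + dco
        if mid == "S4":
            return p["social_bias"] + p["titxtat"] * th_prev
        if mid == "B1":
            return s.expected_co
        if mid == "B2":
            return s.expected_co + p["social_bias"]
        if mid == "B3":
            return p["titxtat"] * s.expected_co + p["social_bias"]
        if mid == "B4":
            return (p["titxtat"] * s.expected_co + p["social_bias"]
                    + p["target_bias"] * s.expected_target)
        if mid == "B5":
            return (titxtat_factor(p, ctx.alpha, "B5") * s.expected_co
                    + p["social_bias"] + p["target_bias"] * s.expected_target)
        if mid == "B6":
            return (titxtat_factor(p, ctx.alpha, "B6") * s.expected_co
                    + p["social_bias"])
        if mid == "B7":
            fac = titxtat_factor(p, ctx.alpha, "B7", betrayal=s.expected_betrayal)
            return fac * s.expected_co + p["social_bias"]
        if mid == "B8":
            return (titxtat_factor(p, ctx.alpha, "B8") * s.expected_co
                    + p["social_bias"]
                    - p["betrayal_sensitivity"] * s.expected_betrayal)
        # reward family: realized previous choice during simulation
        won = s.win_history[-1]
        shift = p["shift_win"] if won else -p["shift_lose"]
        if mid in ("R1", "R5"):
            return own_prev + shift
        if mid in ("R2", "R6"):
            dself = (s.own_history[-1] - s.own_history[-2]
                     if len(s.own_history) >= 2 else 0.0)
            direction = 1.0 if dself >= 0 else -1.0
            mag = p["shift_win"] if won else p["shift_lose"]
            return own_prev + (direction if won else -direction) * mag
        if mid in ("R3", "R4"):
            base = p["social_bias"] + p["titxtat"] * th_prev
            if mid == "R3":
                return base + shift
            dself = (s.own_history[-1] - s.own_history[-2]
                     if len(s.own_history) >= 2 else 0.0)
            direction = 1.0 if dself >= 0 else -1.0
            mag = p["shift_win"] if won else p["shift_lose"]
            return base + (direction if won else -direction) * mag
        raise ValueError(f"unknown model id {mid!r}")  # pragma: no cover

    def choose(self, rng: np.random.Generator) -> float:
        theta = sample_choice(self.predict_next_mean(),
                              self.params["precision"], rng)
        return from_coop_space(theta, self.side)

    # -- learning ---------------------------------------------------------

    def observe(self, outcome: TrialOutcome, role: int) -> None:
        s = self.state
        own_x = outcome.x1 if role == 1 else outcome.x2
        co_x = outcome.x2 if role == 1 else outcome.x1
        won = outcome.winner in (f"player{role}", "tie")
        own_theta = to_coop_space(own_x)
        co_theta = to_coop_space(co_x)
        tgt_theta = to_coop_space(outcome.target)

        disc = float(np.clip(s.expected_co - co_theta, -1.0, 1.0))
        sigma = SIGMA_PRIOR if len(s.betrayal_history) < 2 else max(
            float(np.std(s.betrayal_history, ddof=1)), SIGMA_FLOOR)
        s.betrayal_history.append(disc)
        s.betrayal_belief = _update_with_sigma(
            s.betrayal_belief, disc, sigma, s.betrayal_history)
        s.expected_betrayal = max(0.0, belief_mean(s.betrayal_belief))

        s.co_belief = update_belief(s.co_belief, co_theta)
        s.expected_co = belief_mean(s.co_belief)
        s.target_belief = update_belief(s.target_belief, tgt_theta)
        s.expected_target = belief_mean(s.target_belief)

        s.own_history.append(own_theta)
        s.co_history.append(co_theta)
        s.win_history.append(won)
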