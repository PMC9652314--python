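"""Maximum-likelihood fitting and BIC model comparison for the model zoo.

The per-trial log-likelihood follows the study's objective verbatim,

    LL(choice) = log(sqrt(Precision / 2 pi))
                 - 0.5 * ((choice - prediction) * Precision)^2

whose exponent corresponds to a Gaussian with SD = 1/Precision while the
normalizer corresponds to SD = 1/sqrt(Precision); an optional
``consistent=True`` mode uses the fully self-consistent Gaussian
(normalizer Precision / sqrt(2 pi)) instead.  The first trial of every block
is excluded from every model's likelihood so all models are scored on the
same trials.

Fitting is bounded multi-start local optimization (L-BFGS-B, precision on a
log10 scale); comparison uses BIC = k log(n) - 2 LL with LL summed over
participants and n = likelihood trials x participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .game import SessionLog, to_coop_space
from .models import (BlockFeatures, ModelSpec, compute_block_features,
                     get_spec, predict_means)

__all__ = [
    "trial_loglik", "session_features", "ParticipantFit", "fit_participant",
    "FitResult", "model_bic", "compare_models",
    "RecoveryReport", "recover_parameters",
    "DEFAULT_B6_REFERENCE", "DEFAULT_B6_RANGES",
]


def trial_loglik(choice, mean, precision: float, consistent: bool = False):
    """Per-trial log-likelihood of a choice under a model prediction."""
    if precision <= 0:
        raise ValueError("precision must be positive")
    choice = np.asarray(choice, dtype=float)
    mean = np.asarray(mean, dtype=float)
    quad = -0.5 * ((choice - mean) * precision) ** 2
    if consistent:
        return np.log(precision) - 0.5 * np.log(2 * np.pi) + quad
    return 0.5 * np.log(precision / (2 * np.pi)) + quad


def session_features(session: SessionLog, player: int) -> list[BlockFeatures]:
    """Precompute the per-block trial features for one player of a dyad."""
    if player not in (1, 2):
        raise ValueError("player must be 1 or 2")
    feats = []
    for block in session.blocks:
        theta_self = block.thetas(player)
        theta_co = block.thetas(3 - player)
        theta_target = np.array([to_coop_space(x) for x in block.targets()])
        feats.append(compute_block_features(
            theta_self, theta_co, theta_target, block.wins(player),
            block.context))
    return feats


def _negative_loglik(model_id: str, params: dict, feats: list[BlockFeatures],
                     consistent: bool) -> float:
    total = 0.0
    for f in feats:
        mean = predict_means(model_id, params, f)
        ll = trial_loglik(f.theta_self[1:], mean[1:], params["precision"],
                          consistent=consistent)
        total += float(ll.sum())
    return -total


def _n_loglik_trials(feats: list[BlockFeatures]) -> int:
    return sum(f.n - 1 for f in feats)


@dataclass
class ParticipantFit:
    model_id: str
    params: dict
    loglik: float
    n_trials: int          # trials entering the likelihood
    n_starts: int
    n_converged: int
    start_logliks: np.ndarray = field(repr=False, default=None)


def _to_internal(spec: ModelSpec, params: dict) -> np.ndarray:
    return np.array([np.log10(params[p.name]) if p.log_scale else params[p.name]
                     for p in spec.params])


def _from_internal(spec: ModelSpec, x: np.ndarray) -> dict:
    return {p.name: (10.0 ** xi if p.log_scale else float(xi))
            for p, xi in zip(spec.params, x)}


def _internal_bounds(spec: ModelSpec) -> list[tuple[float, float]]:
    return [(np.log10(p.lower), np.log10(p.upper)) if p.log_scale
            else (p.lower, p.upper) for p in spec.params]


def _draw_start(spec: ModelSpec, rng: np.random.Generator) -> np.ndarray:
    x = []
    for p in spec.params:
        lo, hi = p.start_bounds
        if p.log_scale:
            x.append(rng.uniform(np.log10(lo), np.log10(hi)))
        else:
            x.append(rng.uniform(lo, hi))
    return np.array(x)


def fit_participant(model_id: str, feats: list[BlockFeatures] | SessionLog,
                    player: int = 1, n_starts: int = 20,
                    seed: int | None = None,
                    consistent: bool = False) -> ParticipantFit:
    """Fit one model to one participant by bounded multi-start ML.

    ``feats`` may be a precomputed feature list or a :class:`SessionLog`
    (then ``player`` selects whose choices are fitted).  Deterministic given
    (seed, n_starts).
    """
    if isinstance(feats, SessionLog):
        feats = session_features(feats, player)
    spec = get_spec(model_id)
    rng = np.random.default_rng(seed)
    bounds = _internal_bounds(spec)

    def objective(x):
        params = _from_internal(spec, x)
        try:
            nll = _negative_loglik(model_id, params, feats, consistent)
        except (ValueError, FloatingPointError):
            return 1e12
        return nll if np.isfinite(nll) else 1e12

    best = None
    start_lls = []
    n_converged = 0
    for _ in range(n_starts):
        x0 = _draw_start(spec, rng)
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        start_lls.append(-res.fun)
        if np.isfinite(res.fun):
            n_converged += int(res.success)
            if best is None or res.fun < best.fun:
                best = res
    if best is None or best.fun >= 1e12:
        raise RuntimeError(
            f"all {n_starts} optimizer starts failed for {model_id}; "
            f"start objectives: {[-v for v in start_lls]}")
    return ParticipantFit(model_id, _from_internal(spec, best.x),
                          float(-best.fun), _n_loglik_trials(feats),
                          n_starts, n_converged, np.array(start_lls))


@dataclass
class FitResult:
    """Zoo-level bookkeeping: summed LL and BIC for one model."""

    model_id: str
    k: int
    n: int                 # likelihood trials x participants
    loglik: float
    bic: float
    participant_fits: list[ParticipantFit] = field(repr=False,
                                                   default_factory=list)


def model_bic(fits: list[ParticipantFit]) -> FitResult:
    """Combine per-participant fits of one model: LL summed over participants,
    BIC = k log(n) - 2 LL with k the model's parameter count."""
    ids = {f.model_id for f in fits}
    if len(ids) != 1:
        raise ValueError(f"fits mix models: {sorted(ids)}")
    counts = {f.n_trials for f in fits}
    if len(counts) != 1:
        raise ValueError(f"participants have mismatched trial counts: {counts}")
    model_id = fits[0].model_id
    k = get_spec(model_id).k
    n = fits[0].n_trials * len(fits)
    ll = float(sum(f.loglik for f in fits))
    return FitResult(model_id, k, n, ll, k * np.log(n) - 2.0 * ll, list(fits))


def compare_models(features_by_participant: list[list[BlockFeatures]],
                   model_ids, n_starts: int = 20, seed: int | None = None,
                   consistent: bool = False) -> pd.DataFrame:
    """Fit each model to every participant and rank by summed BIC.

    Returns a table (model_id, k, n, loglik, bic, rank); rank 1 = lowest BIC.
    """
    model_ids = list(model_ids)
    if len(model_ids) < 1:
        raise ValueError("at least one model id required")
    ss = np.random.SeedSequence(seed)
    rows = []
    for model_id, child in zip(model_ids, ss.spawn(len(model_ids))):
        seeds = child.generate_state(len(features_by_participant)) % (2**31)
        fits = [fit_participant(model_id, feats, n_starts=n_starts,
                                seed=int(s), consistent=consistent)
                for feats, s in zip(features_by_participant, seeds)]
        res = model_bic(fits)
        rows.append((res.model_id, res.k, res.n, res.loglik, res.bic))
    table = pd.DataFrame(rows, columns=["model_id", "k", "n", "loglik", "bic"])
    table["rank"] = table["bic"].rank(method="min").astype(int)
    return table.sort_values("rank").reset_index(drop=True)


# --------------------------------------------------------------------------
# Parameter recovery

#: reference parameter set for recovery runs (a plausible mid-range player)
DEFAULT_B6_REFERENCE = {"precision": 20.0, "social_bias": 0.1,
                        "titxtat": 0.8, "q_risk": 0.5}
#: behaviourally plausible sampling ranges for the random generating sets;
#: precision is sampled log-uniformly.  Sets are additionally constrained so
#: the fully-cooperative prediction titxtat + social_bias stays within the
#: space (see _params_identifiable): outside that regime the position bounds
#: censor the simulated choices (whole blocks pinned at an edge) and the
#: generating parameters are unrecoverable in principle.
DEFAULT_B6_RANGES = {"precision": (10.0, 100.0), "social_bias": (0.05, 0.5),
                     "titxtat": (0.3, 0.9), "q_risk": (0.0, 2.0)}


def _params_identifiable(params: dict) -> bool:
    """Reject generating sets whose noise-free predictions leave [0, 1].

    The fully cooperative prediction is titxtat + social_bias (belief mean 1,
    zero social risk); the most competitive one is bounded below by
    social_bias.  Outside this regime the position bounds censor the
    simulated choices (whole blocks pinned at an edge) and the generating
    parameters are unrecoverable regardless of the fitting procedure.
    """
    if "titxtat" not in params or "social_bias" not in params:
        return True
    return (params["titxtat"] + params["social_bias"] <= 0.95
            and params["social_bias"] >= 0.05)


@dataclass
class RecoveryReport:
    model_id: str
    fits: pd.DataFrame      # one row per fit: dataset, rep, gen_*, rec_*, loglik
    stats: pd.DataFrame     # per parameter: spearman, pearson, bias, rmse

    @property
    def n_fits(self) -> int:
        return len(self.fits)


def _sample_params(spec: ModelSpec, ranges: dict,
                   rng: np.random.Generator, max_tries: int = 1000) -> dict:
    for _ in range(max_tries):
        out = {}
        for p in spec.params:
            lo, hi = ranges[p.name]
            if p.log_scale:
                out[p.name] = float(10 ** rng.uniform(np.log10(lo),
                                                      np.log10(hi)))
            else:
                out[p.name] = float(rng.uniform(lo, hi))
        if _params_identifiable(out):
            return out
    raise RuntimeError("could not sample an identifiable parameter set; "
                       "check the configured ranges")


def recover_parameters(model_id: str = "B6", seed: int | None = None,
                       reference_params: dict | None = None,
                       ranges: dict | None = None,
                       n_random: int = 5, n_reps: int = 10,
                       n_starts: int = 20,
                       n_trials: int = 60) -> RecoveryReport:
    """The recovery protocol: simulate dyads from known parameters, refit.

    One dataset is generated from the reference set and ``n_random`` more from
    parameter sets sampled within ``ranges``; each dataset (a dyad playing
    ``n_trials`` trials in each of the three contexts, both agents sharing the
    generating parameters) is refitted ``n_reps`` times with fresh optimizer
    starts.  The default design yields (1 + 5) x 10 = 60 fits.
    """
    from .synth import generate_dyad  # local import avoids a module cycle

    spec = get_spec(model_id)
    if reference_params is None:
        if model_id != "B6":
            raise ValueError("a reference parameter set is required for "
                             f"{model_id}")
        reference_params = dict(DEFAULT_B6_REFERENCE)
    if ranges is None:
        if model_id != "B6":
            raise ValueError(f"sampling ranges are required for {model_id}")
        ranges = dict(DEFAULT_B6_RANGES)
    spec.validate(reference_params)

    ss = np.random.SeedSequence(seed)
    sample_rng = np.random.default_rng(ss.spawn(1)[0])
    param_sets = [dict(reference_params)]
    param_sets += [_sample_params(spec, ranges, sample_rng)
                   for _ in range(n_random)]

    rows = []
    for d, gen in enumerate(param_sets):
        sim_seed, *fit_seeds = ss.spawn(1 + n_reps)
        session = generate_dyad(model_id, gen, model_id, gen,
                                n_trials=n_trials,
                                seed=int(sim_seed.generate_state(1)[0] % 2**31),
                                dyad_id=f"recovery{d:02d}")
        feats = session_features(session, player=1)
        for rep, fseed in enumerate(fit_seeds):
            fit = fit_participant(model_id, feats, n_starts=n_starts,
                                  seed=int(fseed.generate_state(1)[0] % 2**31))
            row = {"dataset": d, "rep": rep, "loglik": fit.loglik}
            row.update({f"gen_{k}": v for k, v in gen.items()})
            row.update({f"rec_{k}": v for k, v in fit.params.items()})
            rows.append(row)
    fits = pd.DataFrame(rows)

    stat_rows = []
    for p in spec.param_names:
        g, r = fits[f"gen_{p}"].to_numpy(), fits[f"rec_{p}"].to_numpy()
        rho = stats.spearmanr(g, r).statistic if np.ptp(g) > 0 else np.nan
        pear = stats.pearsonr(g, r).statistic if np.ptp(g) > 0 else np.nan
        stat_rows.append((p, rho, pear, float(np.mean(r - g)),
                          float(np.sqrt(np.mean((r - g) ** 2)))))
    return RecoveryReport(model_id, fits, pd.DataFrame(
        stat_rows, columns=["parameter", "spearman", "pearson", "bias", "rmse"]))
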