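"""Grid-based Bayesian belief tracking over the co-player's cooperativeness.

Beliefs live on a fixed theta grid (step 0.01).  The prior for a block is a
Gaussian centred on the context's typical cooperativeness (sigma = 0.05,
truncated to the grid); each observed co-player position updates it through a
Gaussian likelihood whose standard deviation tracks the running variability of
the observations.  The same machinery serves the model zoo's target and
betrayal beliefs and the Kullback-Leibler prediction-error regressors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DTHETA = 0.01
#: 101-node cooperativeness grid, endpoints included
THETA_GRID = np.round(np.linspace(0.0, 1.0, 101), 10)
#: grid for betrayal discrepancies (expected - observed theta)
DISCREPANCY_GRID = np.round(np.linspace(-1.0, 1.0, 201), 10)
#: prior standard deviation and fallback likelihood sigma
SIGMA_PRIOR = 0.05
#: likelihood sigma floored at the grid step
SIGMA_FLOOR = DTHETA
#: density floor applied before taking logs
DENSITY_FLOOR = 1e-12


def _normal_pdf_on_grid(grid: np.ndarray, mean: float, sigma: float) -> np.ndarray:
    log_pdf = -0.5 * ((grid - mean) / sigma) ** 2
    pdf = np.exp(log_pdf - log_pdf.max())
    return pdf / (pdf.sum() * _dx(grid))


def _dx(grid: np.ndarray) -> float:
    return float(grid[1] - grid[0])


@dataclass
class BeliefState:
    """A discretized belief: prior and posterior of the latest update."""

    grid: np.ndarray
    prior_pdf: np.ndarray
    posterior_pdf: np.ndarray
    sigma_obs: float
    obs_history: list[float] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return belief_mean(self)


def init_belief(prior_mean: float, sigma: float = SIGMA_PRIOR,
                grid: np.ndarray = THETA_GRID) -> BeliefState:
    """Fresh belief for a block: truncated Gaussian prior on the grid."""
    pdf = _normal_pdf_on_grid(grid, prior_mean, sigma)
    return BeliefState(grid, pdf.copy(), pdf.copy(), sigma_obs=SIGMA_PRIOR)


def running_obs_sigma(obs_history) -> float:
    """Likelihood sigma: sample SD (n-1 denominator) of the observations so
    far; before two observations exist falls back to the prior sigma, and it
    is floored at the grid step."""
    obs = np.asarray(list(obs_history), dtype=float)
    if obs.size < 2:
        return SIGMA_PRIOR
    return max(float(obs.std(ddof=1)), SIGMA_FLOOR)


def update_belief(belief: BeliefState, observed: float) -> BeliefState:
    """Bayes update: posterior ∝ current belief × Gaussian likelihood centred
    on the observation.  The previous posterior becomes the new prior.

    Computed in log space so far-apart prior and likelihood cannot underflow
    to an all-zero product.
    """
    grid = belief.grid
    if not grid[0] <= observed <= grid[-1]:
        raise ValueError(f"observation {observed} outside the belief grid")
    # likelihood width from the variability observed *before* this trial, so
    # an unexpected observation cannot discount its own surprise
    sigma = running_obs_sigma(belief.obs_history)
    history = belief.obs_history + [float(observed)]
    log_prior = np.log(np.maximum(belief.posterior_pdf, DENSITY_FLOOR))
    log_like = -0.5 * ((grid - observed) / sigma) ** 2
    log_post = log_prior + log_like
    post = np.exp(log_post - log_post.max())
    total = post.sum() * _dx(grid)
    if total <= 0 or not np.isfinite(total):
        raise FloatingPointError("degenerate belief update: zero posterior mass")
    post /= total
    return BeliefState(grid, belief.posterior_pdf.copy(), post, sigma, history)


def belief_mean(belief) -> float:
    """Expectation of the (posterior) belief by rectangle-rule quadrature."""
    if isinstance(belief, BeliefState):
        grid, pdf = belief.grid, belief.posterior_pdf
    else:
        grid, pdf = THETA_GRID, np.asarray(belief, dtype=float)
    return float((grid * pdf).sum() * _dx(grid))


def kld(prior_pdf: np.ndarray, posterior_pdf: np.ndarray,
        grid: np.ndarray = THETA_GRID) -> float:
    """KL(prior || posterior) in nats on the grid, with 0*log(0) := 0.

    The argument order (prior first) follows the regressor definition: the
    divergence quantifies how far the observation moved the belief.
    """
    p = np.asarray(prior_pdf, dtype=float)
    q = np.asarray(posterior_pdf, dtype=float)
    mask = p > 0
    q_floored = np.maximum(q, DENSITY_FLOOR)
    if np.any(mask & (q < DENSITY_FLOOR)):
        logger.debug("posterior density floored inside prior support")
    val = float((p[mask] * (np.log(p[mask]) - np.log(q_floored[mask]))).sum()
                * _dx(grid))
    return max(val, 0.0)


def kld_sign(prior_pdf: np.ndarray, posterior_pdf: np.ndarray,
             grid: np.ndarray = THETA_GRID) -> int:
    """+1 when the posterior mean exceeds the prior mean (co-player more
    cooperative than expected), -1 otherwise (including exact equality)."""
    p_mean = float((grid * np.asarray(prior_pdf)).sum() * _dx(grid))
    q_mean = float((grid * np.asarray(posterior_pdf)).sum() * _dx(grid))
    return 1 if q_mean > p_mean else -1
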