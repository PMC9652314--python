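# Methods notes

This note records the modelling assumptions, numerical choices and known
limitations of the package. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` compute.

## The game and its payoff theory

A trial draws a target `t ~ U(0, 1)`; the player strictly closer to it wins
`αR` and the other receives `(1 − α)R`, with `R = 1 − min(d₁, d₂)`. An exact
tie (measure zero for noisy players, every trial for two players at the same
position) splits `R` in half irrespective of `α`, which preserves reward
conservation (`r₁ + r₂ = R`) and makes the expected per-player reward of two
midpoint players equal the mutual-competition payoff `P = 3/8`.

The analytic matrix `R, T, S, P` integrates over the uniform target for
players offset symmetrically by `Δ` into opposite hemifields. Two exact
identities are useful checks: at `α = 0.5`, `T = S = 3/8 + Δ/4 − 3Δ²/8`; at
`α = 2`, `T − S = 3(Δ + Δ²)/2`. `T + S` is `α`-free, so the root of
`2R − (T + S) = Δ/2 − 5Δ²/4` sits at `Δ = 0.4` in every context. Note the
algebra places `2R > T + S` on `Δ < 0.4`; the package exposes the boundary
value and the signed gap rather than an inequality direction. The
Monte-Carlo payoff estimator runs the actual game engine with fixed agents
and reports standard errors of the mean; agreement with the closed forms is
asserted at 3 SE with 10 000 trials per cell.

## Belief machinery

Beliefs over the co-player's cooperativeness live on a 101-node grid
(`θ ∈ {0, 0.01, …, 1}`). The block prior is `N(prior_mean, 0.05)` truncated
to the grid and renormalized, with `prior_mean` 1 / 0.5 / 0 in the
cooperative / intermediate / punitive context. Each observed position
updates the belief through a Gaussian likelihood; its width is the sample
standard deviation (n − 1 denominator) of the co-player's positions observed
*before* the current trial, falling back to 0.05 until two observations
exist and floored at the grid step 0.01.

The exclusive window is a deliberate choice. With an inclusive window an
outlying observation inflates the very width used to interpret it, and the
KL divergence between prior and posterior *decreases* with the size of the
deviation — the opposite of a prediction-error signal. With the exclusive
window, KLD is monotone in the deviation for a fixed belief state. A related
caveat holds at the block level regardless: because the likelihood width
adapts to the running variability, a co-player who always makes large jumps
does not produce proportionally large average KLD. Surprise is relative to
experienced volatility.

Numerics: updates are computed in log space (no underflow for far-apart
prior and likelihood), densities are floored at 1e-12 before logs,
quadrature is the rectangle rule at the stated grid resolution, and
`0·log 0 := 0` in the KL sum. The divergence is evaluated as
KL(prior ‖ posterior), and its sign is +1 only when the posterior mean
strictly exceeds the prior mean (equality falls in the −1 branch).

## The model zoo

All 18 models predict the next choice mean in cooperation space; the
realized choice is Gaussian with SD = 1/Precision, clipped to [0, 1] in
simulation but *not* in likelihood evaluation. Parameter boxes follow the
fitting ranges: Precision (0, 10⁴] (optimized on a log₁₀ scale),
SocialBias and TargetBias [−1000, 1000], TitXTat [0, 2], Shift parameters
[0, 10]. The risk-sensitivity `q_risk` and betrayal-sensitivity boxes are
[0, 10], chosen so the tit-for-tat denominator `1 + q_risk·(2α − 1)` stays
positive for all contexts.

Family conventions:

* **B6–B8** include the additive SocialBias in the predicted mean: B6 is
  described throughout as a four-parameter model whose choices scatter
  around the "tit-for-tat + social-bias" position, and the parameter count
  is treated as authoritative.
* **B7/B8** track a belief over the discrepancy `expected − observed` on a
  [−1, 1] grid (prior `N(0, 0.05)`, likelihood width from the running
  discrepancy SD) and rectify its mean at zero: only unexpectedly
  *competitive* behaviour counts as expected betrayal. B7 adds
  `β_b · b(t)` to the social risk inside the tit-for-tat denominator; B8
  subtracts it from the predicted mean.
* **B4/B5** run the same grid learner over the (remapped) target position;
  since targets are uniform, this belief converges to an uninformative
  mean — the target term is a deliberate lesion control.
* **R1–R4** propagate the model's own predicted previous choice during
  likelihood evaluation; **R5/R6** anchor on the participant's observed
  previous choice. In generative simulation every reward model uses the
  realized previous choice. Wins shift the next choice toward cooperation
  by `Shift_win`, losses toward competition by `Shift_lose`; the
  direction-dependent variants (R2/R4/R6) keep moving in the previous
  movement direction after a win and reverse it after a loss, with a zero
  previous movement treated as movement toward cooperation. Ties count as
  wins for both players.
* Trial 1 of each block never enters any model's likelihood (uniform trial
  count across models keeps BIC comparable); generatively, every agent's
  first-trial mean is the context prior mean.

## Fitting and model comparison

The fitted objective follows the study's printed per-trial log-likelihood
verbatim: `log √(Precision/2π) − ½((choice − mean)·Precision)²`. Its
exponent corresponds to a Gaussian with SD = 1/Precision while its
normalizer corresponds to SD = 1/√Precision; the resulting ML precision is
`1/(√2 · RMS error)`, i.e. biased low by √2 relative to the generative
noise. This is reproduced intentionally (it leaves recovery rank
correlations untouched); `consistent=True` switches to the self-consistent
Gaussian.

Fitting is multi-start (20 restarts by default) bounded L-BFGS-B over the
parameter boxes, with starts drawn from a behaviourally plausible sub-box
(e.g. biases in [−2, 2], precision log-uniform in [1, 1000]); the best
likelihood wins and results are bit-for-bit reproducible given the seed.
BIC uses `k log(n) − 2·LL` with `k` the per-model parameter count, LL
summed over participants, and `n` the number of likelihood trials ×
participants (59 × 3 per participant after the trial-1 exclusion).

## Parameter recovery

The protocol simulates one dyad per generating set (both agents share the
set, 60 trials × 3 contexts), refits player 1 ten times with fresh starts,
and uses one reference set plus five randomly sampled sets — 60 fits. The
default reference (precision 20, social bias 0.1, tit-for-tat 0.8, risk
sensitivity 0.5) is a plausible mid-range player. Sampling ranges default to
precision log-uniform [10, 100], social bias U[0.05, 0.5], tit-for-tat
U[0.3, 0.9] and `q_risk` U[0, 2], with sets constrained to
`titxtat + social_bias ≤ 0.95`: outside this regime the noise-free
predictions leave [0, 1], the position bounds censor whole blocks at an
edge, and the generating parameters are unrecoverable *in principle* (the
refits then agree perfectly with one another on compensating optima, e.g.
`q_risk` at its bound). Recovery quality is summarized per parameter by
Spearman and Pearson correlations, bias and RMSE across the 60 fits.
`q_risk` is the least constrained parameter — it only enters through the
between-context scaling of the tit-for-tat factor, and single sessions can
leave it weakly identified — so its recovery correlation sits closest to
the acceptance margin.

## Regressors and design export

Per block and player the table carries the prior expected co-player
position (trial onset), the change in own cooperativeness (response; 0 on
trial 1), the unsigned and signed KL prediction error (co-player reveal),
and reward and ±1 win (target reveal). All six parametric columns are
z-scored within block, including the ±1 columns; a zero-variance column is
left at zero and logged. The four-bin grouping splits trials by
prediction-error sign and a rank-based within-sign median split on the
magnitude (group sizes within one; ties broken by trial order); a block
with a single sign degenerates to two groups with a warning.

Event timings emulate the task: a 4-s response sweep (response time =
4 × position when positions are supplied), a 1–1.5-s co-player reveal, a
1.5-s target epoch and 2–2.5-s inter-trial intervals. Export writes
three-column (onset, duration, weight) files, all as zero-duration sticks:
four unmodulated event markers and six parametric regressors. HRF
convolution is left to the consuming fMRI package.

The regressor table needs no fitted parameters: the Bayesian learner that
produces the prior expectation and the KL divergence is fully determined by
the data (fixed prior width, data-driven likelihood width), which is also
why a single belief trajectory can be shared across all 18 models' fits.

## Synthetic data

The generator is the study-design emulator: dyads play three 60-trial
blocks in the fixed order cooperative → competitive → intermediate
(`α = 0.5, 2, 1`), agents start on opposite hemifields (side assignment
randomized by seed) and keep their side, and beliefs reset at block
boundaries. Cohorts default to 25 dyads (50 participants). Behavioural
summaries report competitiveness as the distance from the closest edge
(`(1 − θ)/2`), the mean absolute inter-player distance, and a reciprocation
table binning co-player position changes (toward the midpoint = increase in
competition) into four within-sign median-split bins against the player's
next-trial change.

What the generator does not emulate: motor reaction-time structure (the
4-s sweep is abstracted into the Precision parameter), end-game effects,
session-to-session drift, and any individual-difference structure beyond
the sampled parameter vectors. Passing tests therefore show that the
*pipeline* is correct and identifiable under the modelled data-generating
process, not that the models are true of human players.

## Known limitations

* Quantities that depend on the original participant cohort (the absolute
  summed BIC of the winning model, observed-vs-predicted choice
  correlations, the empirical tit-for-tat/social-bias anticorrelation,
  mixed-model coefficients) cannot be reproduced from synthetic data and
  are not asserted anywhere; the property-based checks stand in for them.
* The verbatim likelihood's √2 precision bias is inherited by every fitted
  precision value.
* Choices clipped at the space boundary are evaluated under an unbounded
  Gaussian likelihood; heavily saturated sessions (fully cooperative or
  fully competitive throughout) therefore fit with compensating parameter
  values, which is why the recovery protocol constrains its generating
  regime.
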