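# spacedilemma

Simulation and behavioural modelling of the **Space Dilemma**, a continuous
two-player cooperation–competition game, for computational cognitive
scientists studying social learning in dyads.

Two players each commit to a position `x ∈ [0, 1]` on a line; a target is
drawn uniformly at random, the closer player wins the trial, and the trial
reward `R = 1 − min(d₁, d₂)` is split by a context factor `α`: the winner
receives `αR`, the loser `(1 − α)R`. Contexts `α = 0.5 / 1 / 2` make the game
cooperative, winner-take-all, or punitive. Mapping positions into
*cooperation space* `θ = |x − 0.5| / 0.5` (0 = competitive midpoint, 1 = a
fully cooperative edge) turns the game into a continuous, probabilistic
prisoner's dilemma: for players symmetrically offset by `Δ`, the expected
payoffs are

```
R(Δ)    = 3/8 + Δ/2 − Δ²                                   mutual cooperation
T(Δ, α) = α(3/8 + Δ/2 − Δ²/8) + (1 − α)(3/8 − 5Δ²/8)        temptation
S(Δ, α) = α(3/8 − 5Δ²/8) + (1 − α)(3/8 + Δ/2 − Δ²/8)        sucker
P       = 3/8                                               mutual competition
```

with the dyad-optimal offset at `Δ = 0.25` and `2R = T + S` at `Δ = 0.4`.

The package provides:

* `game` / `payoffs` — the environment, closed-loop block simulation, the
  analytic payoff matrix with a Monte-Carlo oracle, and dilemma
  classification;
* `beliefs` — grid-based Bayesian tracking of the co-player's
  cooperativeness (`dθ = 0.01`, Gaussian prior `σ = 0.05`, likelihood width
  tracking the observed variability) and Kullback–Leibler prediction errors;
* `models` — 18 behavioural models in three families (simple reactive
  S1–S4, Bayesian B1–B8, reward-driven R1–R6), each predicting the next
  choice in cooperation space with Gaussian response noise
  (SD = 1/Precision); the flagship model B6 reciprocates the *expected*
  co-player position scaled by `TitXTat / (1 + q_risk · (2α − 1))` plus a
  social bias;
* `inference` — maximum-likelihood fitting (bounded multi-start L-BFGS-B),
  summed-BIC model comparison, and the parameter-recovery protocol;
* `regressors` — trial-by-trial fMRI design quantities (prior expectation,
  change in own cooperation, unsigned/signed KL prediction error, reward,
  win), four-bin prediction-error groupings, synthetic event timings and
  three-column EV export;
* `synth` — synthetic dyads and cohorts generated by the model zoo, plus
  behavioural summaries (competitiveness, inter-player distance,
  reciprocation tables);
* a `space-dilemma` CLI with `simulate`, `fit`, `compare`, `recover`,
  `regressors`, `summarize` and `payoffs` subcommands.

## Worked example

```python
import spacedilemma as sd

m = sd.analytic_payoffs(0.25, 2.0)
print(f"R={m.R:.4f}  T={m.T:.4f}  S={m.S:.4f}  P={m.P:.4f}")
print("optimal delta:", sd.optimal_delta())
print("iterated-dilemma boundary:", round(sd.ipd_boundary(), 6))

params = {"precision": 20.0, "social_bias": 0.1, "titxtat": 0.8, "q_risk": 0.5}
partner = {"precision": 30.0, "social_bias": 0.15, "titxtat": 0.6, "q_risk": 1.0}
session = sd.generate_dyad("B6", params, "B6", partner, seed=42)
print(sd.behavioural_summary(session).per_block[
    ["context", "alpha", "mean_theta", "mean_distance"]].round(3).to_string(index=False))

fit = sd.fit_participant("B6", sd.session_features(session, 1),
                         n_starts=20, seed=0)
print({k: round(v, 3) for k, v in fit.params.items()}, "LL =", round(fit.loglik, 1))
```

prints

```
R=0.4375  T=0.6484  S=0.1797  P=0.3750
optimal delta: 0.25
iterated-dilemma boundary: 0.4
     context  alpha  mean_theta  mean_distance
 cooperative    0.5       0.659          0.659
 competitive    2.0       0.153          0.153
intermediate    1.0       0.267          0.267
{'precision': 13.502, 'social_bias': 0.07, 'titxtat': 0.835, 'q_risk': 0.265} LL = 23.5
```

At `Δ = 0.25` in the punitive context the payoff ordering `T > R > P > S`
marks a strong prisoner's dilemma. The simulated dyad is most cooperative
when the reward is shared (`α = 0.5`, mean θ 0.66) and collapses toward the
midpoint when losing is punished (`α = 2`, mean θ 0.15), and refitting
player 1's own generating model recovers its parameters (social bias
0.1 → 0.07, tit-for-tat 0.8 → 0.84, risk sensitivity 0.5 → 0.27, precision
20 → 13.5 — the printed likelihood's normalizer biases precision down by
√2; see `docs/methods.md`).

## Layout

```
src/spacedilemma/   game, payoffs, beliefs, models, inference, regressors,
                    synth, cli
tests/              unit, property and end-to-end acceptance tests
docs/methods.md     modelling and design notes
scripts/            acceptance.py
```
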