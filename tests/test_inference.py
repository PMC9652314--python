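import numpy as np
import pytest

from spacedilemma import (compare_models, fit_participant, generate_dyad,
                          model_bic, predict_means, recover_parameters,
                          session_features, trial_loglik)
from spacedilemma.inference import _negative_loglik


def test_trial_loglik_examples():
    # exponent vanishes when the choice equals the prediction
    assert trial_loglik(0.4, 0.4, 10.0) == pytest.approx(
        np.log(np.sqrt(10.0 / (2 * np.pi))))
    assert trial_loglik(0.4, 0.4, 2 * np.pi) == pytest.approx(0.0)
    assert trial_loglik(0.6, 0.5, 10.0) == pytest.approx(
        0.5 * np.log(10 / (2 * np.pi)) - 0.5, abs=1e-4)


def test_trial_loglik_consistent_mode_normalizer():
    # the self-consistent Gaussian differs only by 0.5*log(precision)
    p = 7.3
    diff = trial_loglik(0.4, 0.4, p, consistent=True) - trial_loglik(0.4, 0.4, p)
    assert diff == pytest.approx(0.5 * np.log(p))


def test_loglik_self_consistency(features_p1, b6_params):
    """The generating parameters beat perturbed ones on their own data."""
    nll_true = _negative_loglik("B6", b6_params, features_p1, False)
    for key, delta in (("titxtat", 0.3), ("social_bias", 0.2),
                       ("q_risk", 1.0)):
        perturbed = dict(b6_params)
        perturbed[key] += delta
        assert nll_true < _negative_loglik("B6", perturbed, features_p1, False)


def test_bic_arithmetic():
    from spacedilemma.inference import ParticipantFit

    fit = ParticipantFit("B6", {}, loglik=-100.0, n_trials=180, n_starts=1,
                         n_converged=1)
    res = model_bic([fit])
    assert res.k == 4 and res.n == 180
    assert res.bic == pytest.approx(4 * np.log(180) + 200.0)


def test_model_bic_rejects_mixed_inputs():
    from spacedilemma.inference import ParticipantFit

    a = ParticipantFit("B6", {}, -1.0, 180, 1, 1)
    b = ParticipantFit("B1", {}, -1.0, 180, 1, 1)
    with pytest.raises(ValueError):
        model_bic([a, b])
    c = ParticipantFit("B6", {}, -1.0, 90, 1, 1)
    with pytest.raises(ValueError):
        model_bic([a, c])


def test_fit_is_deterministic(features_p1):
    f1 = fit_participant("B3", features_p1, n_starts=5, seed=77)
    f2 = fit_participant("B3", features_p1, n_starts=5, seed=77)
    assert f1.params == f2.params
    assert f1.loglik == f2.loglik


def test_fit_recovers_b6_parameters_at_high_precision():
    gen = {"precision": 200.0, "social_bias": 0.1, "titxtat": 0.7,
           "q_risk": 0.5}
    session = generate_dyad("B6", gen, "B6", gen, seed=21)
    fit = fit_participant("B6", session_features(session, 1), n_starts=10,
                          seed=0)
    assert fit.params["titxtat"] == pytest.approx(0.7, abs=0.05)
    assert fit.params["social_bias"] == pytest.approx(0.1, abs=0.05)
    assert fit.params["q_risk"] == pytest.approx(0.5, abs=0.3)
    assert fit.n_trials == 177  # 3 blocks x 59 likelihood trials


def test_mirror_agent_data_identifies_mirror_model():
    """Choices generated by the pure-reciprocation rule are explained better
    by that rule than by a reward-shift rule."""
    s1 = {"precision": 40.0}
    partner = {"precision": 30.0, "social_bias": 0.2, "titxtat": 0.6,
               "q_risk": 0.5}
    session = generate_dyad("S1", s1, "B6", partner, seed=5)
    feats = session_features(session, 1)
    fit_s1 = fit_participant("S1", feats, n_starts=8, seed=1)
    fit_r1 = fit_participant("R1", feats, n_starts=8, seed=1)
    assert fit_s1.loglik > fit_r1.loglik


def test_constant_choice_participant_precision():
    """A near-constant player yields a precision tracking the inverse of the
    residual spread (1/sqrt(2) of it under the printed objective)."""
    gen = {"precision": 1000.0, "social_bias": 0.3, "titxtat": 0.0,
           "q_risk": 0.0}
    session = generate_dyad("B6", gen, "B6", gen, seed=3)
    fit = fit_participant("B6", session_features(session, 1), n_starts=8,
                          seed=2)
    assert fit.params["precision"] > 300.0


def test_compare_models_single_row(features_p1):
    table = compare_models([features_p1], ["B1"], n_starts=4, seed=0)
    assert len(table) == 1
    assert table.loc[0, "rank"] == 1
    assert table.loc[0, "k"] == 1
    assert table.loc[0, "n"] == 177


def test_recovery_report_structure():
    rep = recover_parameters("B6", seed=99, n_random=1, n_reps=2, n_starts=4,
                             n_trials=20)
    assert rep.n_fits == 4  # (1 reference + 1 random) x 2 repetitions
    assert set(rep.stats["parameter"]) == {"precision", "social_bias",
                                           "titxtat", "q_risk"}
    for p in rep.stats["parameter"]:
        assert (rep.fits[f"rec_{p}"] >= 0).all() or p == "social_bias"


def test_recovery_requires_ranges_for_other_models():
    with pytest.raises(ValueError):
        recover_parameters("S4", seed=0)


def test_fitted_anticorrelation_mirrors_generating_correlation():
    """Fitted tit-for-tat and social-bias estimates reproduce the
    correlation structure of the generating parameters: a strongly
    anticorrelated cohort fits as strongly anticorrelated, and the fitting
    procedure adds no artefactual anticorrelation of its own."""
    from scipy import stats

    from spacedilemma import get_spec
    from spacedilemma.inference import DEFAULT_B6_RANGES, _sample_params

    rng = np.random.default_rng(8)

    def anticorrelated(rng):
        t = rng.uniform(0.3, 0.9)
        b = float(np.clip(0.55 - 0.55 * t + rng.normal(0, 0.03), 0.05, 0.5))
        return {"precision": 30.0, "social_bias": b, "titxtat": t,
                "q_risk": 0.5}

    def from_default_ranges(rng):
        p = _sample_params(get_spec("B6"), DEFAULT_B6_RANGES, rng)
        p["precision"] = 30.0
        return p

    def fit_cohort(param_fn, seed0, n_dyads=8):
        gens, fits = [], []
        for d in range(n_dyads):
            p1, p2 = param_fn(rng), param_fn(rng)
            session = generate_dyad("B6", p1, "B6", p2, seed=seed0 + d)
            for player, gp in ((1, p1), (2, p2)):
                fit = fit_participant("B6", session_features(session, player),
                                      n_starts=10, seed=seed0 + 10 * d + player)
                gens.append(gp)
                fits.append(fit.params)
        r_gen = stats.pearsonr([g["titxtat"] for g in gens],
                               [g["social_bias"] for g in gens]).statistic
        r_fit = stats.pearsonr([f["titxtat"] for f in fits],
                               [f["social_bias"] for f in fits]).statistic
        return r_gen, r_fit

    r_gen, r_fit = fit_cohort(anticorrelated, seed0=100)
    assert r_fit < -0.8
    assert abs(r_fit - r_gen) < 0.2
    r_gen, r_fit = fit_cohort(from_default_ranges, seed0=300)
    assert abs(r_fit - r_gen) < 0.25  # no artefactual anticorrelation


def test_param_table_registry_export():
    from spacedilemma.models import param_table

    tab = param_table()
    assert len(tab) == 60  # total parameter count across the 18 models
    assert set(tab.columns) == {"model_id", "family", "parameter", "lower",
                                "upper", "log_scale"}
    assert (tab.groupby("model_id").size()["B6"]) == 4
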