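import numpy as np
import pytest

from spacedilemma import (Context, MODEL_IDS, MODEL_SPECS, ModelAgent,
                          compute_block_features, generate_dyad, get_spec,
                          predict_means, sample_choice, session_features,
                          social_risk, titxtat_factor)

EXPECTED_K = {"S1": 1, "S2": 2, "S3": 4, "S4": 3,
              "B1": 1, "B2": 2, "B3": 3, "B4": 4, "B5": 4, "B6": 4,
              "B7": 5, "B8": 5,
              "R1": 3, "R2": 3, "R3": 5, "R4": 5, "R5": 3, "R6": 3}


def _features(theta_self, theta_co, win=None, label="intermediate",
              targets=None):
    n = len(theta_self)
    if win is None:
        win = np.ones(n, dtype=bool)
    if targets is None:
        targets = np.full(n, 0.5)
    return compute_block_features(theta_self, theta_co, targets, win,
                                  Context.from_label(label))


def test_registry_has_all_models_with_expected_parameter_counts():
    assert set(MODEL_IDS) == set(EXPECTED_K)
    for mid, k in EXPECTED_K.items():
        assert MODEL_SPECS[mid].k == k, mid
        assert MODEL_SPECS[mid].param_names[0] == "precision"


def test_parameter_bounds():
    b6 = get_spec("B6")
    by_name = {p.name: p for p in b6.params}
    assert by_name["precision"].upper == 10000.0
    assert by_name["titxtat"].lower == 0.0 and by_name["titxtat"].upper == 2.0
    assert by_name["social_bias"].lower == -1000.0
    r1 = {p.name: p for p in get_spec("R1").params}
    assert r1["shift_win"].upper == 10.0 and r1["shift_lose"].upper == 10.0
    with pytest.raises(ValueError):
        b6.validate({"precision": 10.0, "social_bias": 0.0,
                     "titxtat": 3.0, "q_risk": 0.0})


@pytest.mark.parametrize("alpha, risk", [(0.5, 0.0), (1.0, 1.0), (2.0, 3.0)])
def test_social_risk(alpha, risk):
    assert social_risk(alpha) == pytest.approx(risk)


def test_titxtat_factor():
    p = {"titxtat": 1.0, "q_risk": 5.0}
    assert titxtat_factor(p, 0.5, "B6") == pytest.approx(1.0)  # zero risk
    p = {"titxtat": 1.0, "q_risk": 1.0}
    assert titxtat_factor(p, 2.0, "B6") == pytest.approx(0.25)
    assert titxtat_factor({"q_risk": 0.5}, 1.0, "B5") == pytest.approx(2 / 3)
    with pytest.raises(ValueError):
        titxtat_factor({"titxtat": 1.0, "q_risk": -2.0}, 1.0, "B6")


def test_simple_models_predictions():
    f = _features([0.5, 0.4, 0.6], [0.7, 0.2, 0.5])
    s1 = predict_means("S1", {"precision": 10.0}, f)
    assert np.isnan(s1[0])
    np.testing.assert_allclose(s1[1:], [0.7, 0.2])
    s4 = predict_means("S4", {"precision": 10.0, "social_bias": 0.1,
                              "titxtat": 0.5}, f)
    np.testing.assert_allclose(s4[1:], [0.1 + 0.35, 0.1 + 0.1])
    # S2: bias + own previous choice + co-player's previous change
    s2 = predict_means("S2", {"precision": 10.0, "social_bias": 0.1}, f)
    np.testing.assert_allclose(s2[1:], [0.1 + 0.5 + 0.0,
                                        0.1 + 0.4 + (0.2 - 0.7)])


def test_b6_prediction_combines_factor_and_bias():
    """Belief mean 0.6, TitXTat 1, zero social risk, bias 0.1 -> 0.7."""
    f = _features([0.5, 0.5], [0.6, 0.6], label="cooperative")
    f.belief_mean = np.array([0.6, 0.6])
    params = {"precision": 10.0, "social_bias": 0.1, "titxtat": 1.0,
              "q_risk": 1.0}
    mean = predict_means("B6", params, f)
    assert mean[1] == pytest.approx(0.7)


def test_b1_equals_belief_mean(features_p1):
    for f in features_p1:
        mean = predict_means("B1", {"precision": 10.0}, f)
        np.testing.assert_allclose(mean[1:], f.belief_mean[1:])


def test_b6_invariant_to_q_risk_under_equal_split(features_p1):
    f = next(x for x in features_p1 if x.context.alpha == 0.5)
    base = {"precision": 10.0, "social_bias": 0.1, "titxtat": 0.8}
    m0 = predict_means("B6", {**base, "q_risk": 0.0}, f)
    m1 = predict_means("B6", {**base, "q_risk": 7.3}, f)
    np.testing.assert_allclose(m0[1:], m1[1:])


def test_reward_model_shifts():
    # after a loss, choices move toward competition by shift_lose
    f = _features([0.5, 0.5], [0.5, 0.5], win=np.array([False, False]))
    r1 = predict_means("R1", {"precision": 10.0, "shift_win": 0.3,
                              "shift_lose": 0.2}, f)
    assert r1[1] == pytest.approx(0.3)
    f = _features([0.5, 0.5], [0.5, 0.5], win=np.array([True, True]))
    r1 = predict_means("R1", {"precision": 10.0, "shift_win": 0.3,
                              "shift_lose": 0.2}, f)
    assert r1[1] == pytest.approx(0.8)


def test_r1_recursion_uses_fitted_previous_value():
    f = _features([0.5, 0.9, 0.1], [0.5, 0.5, 0.5],
                  win=np.array([True, True, True]))
    r1 = predict_means("R1", {"precision": 10.0, "shift_win": 0.1,
                              "shift_lose": 0.2}, f)
    # anchored on the first observed choice, then self-propagating
    np.testing.assert_allclose(r1[1:], [0.6, 0.7])
    # R5 anchors each step on the observed previous choice instead
    r5 = predict_means("R5", {"precision": 10.0, "shift_win": 0.1,
                              "shift_lose": 0.2}, f)
    np.testing.assert_allclose(r5[1:], [0.6, 1.0])


def test_r2_direction_flips_after_loss():
    f = _features([0.5] * 4, [0.5] * 4,
                  win=np.array([True, False, True, True]))
    r2 = predict_means("R2", {"precision": 10.0, "shift_win": 0.1,
                              "shift_lose": 0.2}, f)
    # start direction +1: win -> +0.1; lose -> flip, -0.2; win -> keep, -0.1
    np.testing.assert_allclose(np.diff(np.concatenate([[0.5], r2[1:]])),
                               [0.1, -0.2, -0.1])


def test_betrayal_reduces_to_b6_when_coplayer_as_expected():
    """With the co-player exactly matching the belief mean every trial, the
    expected betrayal stays at zero and B7/B8 equal B6."""
    n = 8
    ts = np.full(n, 0.5)
    ctx = Context.from_label("intermediate")
    # co-player plays the current belief mean each trial
    from spacedilemma import belief_mean, init_belief, update_belief
    b = init_belief(ctx.prior_mean)
    co = []
    for _ in range(n):
        co.append(belief_mean(b))
        b = update_belief(b, co[-1])
    f = compute_block_features(ts, np.array(co), np.full(n, 0.5),
                               np.ones(n, dtype=bool), ctx)
    assert np.allclose(f.betrayal, 0.0, atol=1e-12)
    base = {"precision": 10.0, "social_bias": 0.1, "titxtat": 0.8,
            "q_risk": 0.5}
    m6 = predict_means("B6", base, f)
    m7 = predict_means("B7", {**base, "betrayal_sensitivity": 2.0}, f)
    m8 = predict_means("B8", {**base, "betrayal_sensitivity": 2.0}, f)
    np.testing.assert_allclose(m7[1:], m6[1:])
    np.testing.assert_allclose(m8[1:], m6[1:])


def test_betrayal_tracks_consistent_discrepancy():
    """A co-player consistently 0.2 more competitive than expected drives the
    expected betrayal toward 0.2; a more-cooperative one keeps it at zero."""
    n = 8
    from spacedilemma import belief_mean, init_belief, update_belief
    # start the descending trajectory from the cooperative prior so it never
    # clips at the competitive edge within the block
    for label, sign, target in (("cooperative", +1, 0.2),
                                ("intermediate", -1, 0.0)):
        ctx = Context.from_label(label)
        b = init_belief(ctx.prior_mean)
        co = []
        for _ in range(n):
            co.append(float(np.clip(belief_mean(b) - sign * 0.2, 0, 1)))
            b = update_belief(b, co[-1])
        f = compute_block_features(np.full(n, 0.5), np.array(co),
                                   np.full(n, 0.5), np.ones(n, dtype=bool),
                                   ctx)
        assert f.betrayal[-1] == pytest.approx(target, abs=0.05)


def test_sample_choice_statistics(rng):
    draws = np.array([sample_choice(0.5, 10.0, rng) for _ in range(20000)])
    assert draws.std() == pytest.approx(0.1, abs=0.01)
    assert np.all((draws >= 0) & (draws <= 1))
    assert sample_choice(0.5, 10000.0, rng) == pytest.approx(0.5, abs=1e-3)
    assert sample_choice(1.2, 10000.0, rng) == 1.0  # clipped at the edge


@pytest.mark.parametrize("model_id, params, atol", [
    ("B6", {"precision": 10000.0, "social_bias": 0.1, "titxtat": 0.7,
            "q_risk": 0.5}, 1e-3),
    ("S4", {"precision": 10000.0, "social_bias": 0.1, "titxtat": 0.7}, 1e-3),
    # the recursive fitted path accumulates the residual generative noise,
    # so its tolerance is looser
    ("R1", {"precision": 10000.0, "shift_win": 0.002, "shift_lose": 0.003},
     5e-3),
    ("R5", {"precision": 10000.0, "shift_win": 0.002, "shift_lose": 0.003},
     1e-3),
])
def test_generative_agent_consistent_with_fitting_path(model_id, params, atol):
    """In the noiseless limit the vectorized likelihood-side predictions
    reproduce the generative agent's realized choices."""
    other = {"precision": 50.0, "social_bias": 0.1, "titxtat": 0.6,
             "q_risk": 0.5}
    session = generate_dyad(model_id, params, "B6", other, n_trials=25,
                            seed=9)
    for f in session_features(session, player=1):
        mean = predict_means(model_id, params, f)
        interior = (mean[1:] > 0.01) & (mean[1:] < 0.99)
        np.testing.assert_allclose(mean[1:][interior],
                                   f.theta_self[1:][interior], atol=atol)


def test_agent_rejects_bad_inputs():
    with pytest.raises(ValueError):
        ModelAgent("nope", {"precision": 1.0})
    with pytest.raises(ValueError):
        ModelAgent("S1", {"precision": 1.0}, side="middle")
    agent = ModelAgent("S1", {"precision": 1.0})
    with pytest.raises(RuntimeError):
        agent.predict_next_mean()
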