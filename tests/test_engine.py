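"""Belief updating, free energies, and policy selection."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from pfcsim import (
    EngineSettings,
    TaskParams,
    build_task_model,
    expected_free_energy,
    free_energy,
    init_beliefs,
    likelihood_message,
    policy_posterior,
    predict_outcomes,
    safe_log,
    select_action,
    softmax_normalize,
    state_update,
)
from pfcsim.engine import NumericError, one_hot
from pfcsim.model import FactorSpec, GenerativeModel, ModalitySpec

finite_vectors = st.lists(
    st.floats(min_value=-30, max_value=30, allow_nan=False), min_size=2, max_size=6
).map(np.array)


class TestSoftmax:
    def test_symmetry(self):
        assert np.allclose(softmax_normalize(np.zeros(2)), [0.5, 0.5])

    def test_closed_form(self):
        assert np.allclose(softmax_normalize(np.array([np.log(3), 0.0])), [0.75, 0.25])

    @hsettings(deadline=None, derandomize=True)
    @given(finite_vectors, st.floats(min_value=-50, max_value=50, allow_nan=False))
    def test_shift_invariance_and_normalization(self, v, c):
        out = softmax_normalize(v)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(out, softmax_normalize(v + c), atol=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(NumericError):
            softmax_normalize(np.array([np.inf, 0.0]))


class TestSafeLog:
    def test_unit_probability(self):
        # exactly ln(1 + e^-16) = 1.13e-7
        assert safe_log(np.array([1.0]))[0] == pytest.approx(0.0, abs=1.2e-7)

    def test_zero_probability_hits_floor(self):
        assert safe_log(np.array([0.0]))[0] == pytest.approx(-16.0, abs=1e-12)

    @hsettings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=5),
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=5),
    )
    def test_monotone(self, a, b):
        k = min(len(a), len(b))
        lo = np.minimum(a[:k], b[:k])
        hi = np.maximum(a[:k], b[:k])
        assert np.all(safe_log(lo) <= safe_log(hi))

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            safe_log(np.array([-0.1]))


class TestLikelihoodMessage:
    def test_delay_observation_is_uninformative(self, task_model):
        obs = [one_hot(2, 3)] * 4  # all-null
        s = [np.full(2, 0.5), np.full(2, 0.5), np.array([1.0, 0.0, 0.0])]
        for n in range(3):
            msg = likelihood_message(task_model, obs, s, n, tau=2)
            assert np.ptp(msg) == pytest.approx(0.0, abs=1e-12)

    def test_rule_gates_stimulus_evidence(self, task_model):
        # attend-vision belief: vision=blue drives target=blue; audition is noise
        obs = [one_hot(2, 3), one_hot(0, 3), one_hot(1, 3), one_hot(2, 3)]
        s = [np.array([1.0, 0.0]), np.full(2, 0.5), np.array([1.0, 0.0, 0.0])]
        msg = likelihood_message(task_model, obs, s, n=1, tau=3)
        assert msg[0] - msg[1] > 10  # strongly favors blue despite audition=green

    def test_uncertain_rule_with_conflicting_stimuli_is_flat(self, task_model):
        obs = [one_hot(2, 3), one_hot(0, 3), one_hot(1, 3), one_hot(2, 3)]
        s = [np.full(2, 0.5), np.full(2, 0.5), np.array([1.0, 0.0, 0.0])]
        msg = likelihood_message(task_model, obs, s, n=1, tau=3)
        assert np.ptp(msg) == pytest.approx(0.0, abs=1e-12)

    def test_rejects_non_one_hot(self, task_model):
        obs = [np.array([0.5, 0.5, 0.0])] + [one_hot(2, 3)] * 3
        s = [np.full(2, 0.5), np.full(2, 0.5), np.array([1.0, 0.0, 0.0])]
        with pytest.raises(ValueError):
            likelihood_message(task_model, obs, s, n=0, tau=1)


class TestStateUpdate:
    def test_cue_concentrates_rule_belief(self, task_model, settings):
        beliefs = init_beliefs(task_model)
        obs = [[one_hot(0, 3)] + [one_hot(2, 3)] * 3]  # brown-noise cue
        state_update(task_model, beliefs, obs, t=1, settings=settings, record_trace=False)
        for pi in range(3):
            assert beliefs.s[0][pi, 0, 0] > 0.99

    def test_delay_maintains_rule_belief(self, task_model, settings):
        beliefs = init_beliefs(task_model)
        obs = [[one_hot(0, 3)] + [one_hot(2, 3)] * 3]
        state_update(task_model, beliefs, obs, t=1, settings=settings, record_trace=False)
        obs.append([one_hot(2, 3)] * 4)  # silent delay
        state_update(task_model, beliefs, obs, t=2, settings=settings, record_trace=False)
        for pi in range(3):
            assert beliefs.s[0][pi, 1] == pytest.approx(beliefs.s[0][pi, 0], abs=1e-3)

    def test_normalization_every_iteration(self, task_model, settings):
        beliefs = init_beliefs(task_model)
        obs = [[one_hot(1, 3)] + [one_hot(2, 3)] * 3]
        state_update(task_model, beliefs, obs, t=1, settings=settings, record_trace=True)
        for frame in beliefs.trace:
            for sn in frame.s:
                sums = sn.sum(axis=-1)
                assert np.allclose(sums, 1.0, atol=1e-9)
                assert np.all(sn > 0)

    def test_divergence_raises(self, task_model):
        beliefs = init_beliefs(task_model)
        beliefs.v[0][:] = 2e6  # absurd depolarization
        obs = [[one_hot(0, 3)] + [one_hot(2, 3)] * 3]
        with pytest.raises(NumericError):
            state_update(task_model, beliefs, obs, t=1, record_trace=False)


class TestPredictOutcomes:
    def test_delay_predictions_are_null(self, task_model):
        beliefs = init_beliefs(task_model)
        out = predict_outcomes(task_model, beliefs, pi=0)
        for g in range(4):
            assert out[g][1, 2] == pytest.approx(1.0)

    def test_feedback_prediction_from_matching_choice(self, task_model):
        beliefs = init_beliefs(task_model)
        for pi in range(3):
            beliefs.s[1][pi, 3] = [1.0, 0.0]        # target blue
            beliefs.s[2][pi, 3] = [0.0, 1.0, 0.0]   # chose blue
        out = predict_outcomes(task_model, beliefs, pi=0)
        assert out[3][3, 0] == pytest.approx(1.0)

    def test_predictions_normalized(self, task_model, settings):
        rng = np.random.default_rng(0)
        beliefs = init_beliefs(task_model)
        for n, sn in enumerate(beliefs.s):
            raw = rng.random(sn.shape)
            beliefs.s[n] = raw / raw.sum(axis=-1, keepdims=True)
        out = predict_outcomes(task_model, beliefs, pi=1)
        for g in range(4):
            assert np.allclose(out[g].sum(axis=-1), 1.0, atol=1e-9)


def _propagated_prior_beliefs(model):
    beliefs = init_beliefs(model)
    for n in range(len(model.factors)):
        for pi in range(model.n_policies):
            cur = model.D[n].copy()
            beliefs.s[n][pi, 0] = cur
            for tau in range(2, model.T + 1):
                u = model.policies[pi, tau - 2] if n == model.controlled_factor else 0
                cur = model.B[n][u] @ cur
                beliefs.s[n][pi, tau - 1] = cur
    return beliefs


class TestFreeEnergy:
    def test_zero_at_prior_with_no_observations(self, task_model, settings):
        beliefs = _propagated_prior_beliefs(task_model)
        for pi in range(3):
            assert free_energy(task_model, beliefs, [], 0, pi, settings) == 0.0

    def test_bound_against_enumeration(self):
        from _oracle import enumeration_smoother, random_small_model, sample_observations

        rng = np.random.default_rng(5)
        st_ = EngineSettings(n_iter=128)
        for deterministic in (False, True):
            for _ in range(8):
                model = random_small_model(rng, deterministic=deterministic)
                obs = sample_observations(model, rng)
                _, evidence = enumeration_smoother(model, obs)
                beliefs = init_beliefs(model)
                obs_oh = [
                    [one_hot(i, model.modalities[0].n) for i in row] for row in obs
                ]
                state_update(model, beliefs, obs_oh, model.T, st_, record_trace=False)
                F = free_energy(model, beliefs, obs_oh, model.T, 0, st_)
                if deterministic:
                    # the bound is tight for deterministic models
                    assert F == pytest.approx(-np.log(evidence), abs=1e-6)
                else:
                    # message-form complexity can undershoot the exact
                    # mean-field bound slightly (Jensen gap of ln(B s))
                    assert F >= -np.log(evidence) - 0.05


class TestExpectedFreeEnergy:
    def test_risk_per_term_is_log_cardinality(self):
        # one-hot prediction, normalized-uniform log-preferences, H = 0
        f = FactorSpec("x", ("a", "b", "c"))
        m = ModalitySpec("o", ("p", "q", "r"), "r")
        A = np.zeros((2, 3, 3))
        A[:, 0, 0] = A[:, 1, 1] = A[:, 2, 2] = 1.0  # deterministic
        model = GenerativeModel(
            factors=[f],
            modalities=[m],
            A=[A],
            B=[np.eye(3)[None]],
            C=[np.full((2, 3), np.log(1 / 3))],
            D=[np.array([1.0, 0.0, 0.0])],
            policies=np.zeros((1, 1), dtype=np.intp),
            T=2,
            controlled_factor=0,
        )
        beliefs = init_beliefs(model)
        for tau in range(2):
            beliefs.s[0][0, tau] = [1.0, 0.0, 0.0]
        G = expected_free_energy(model, beliefs, 0, t=1)
        assert G == pytest.approx(np.log(3), abs=1e-6)

    def test_correct_vs_wrong_choice_differs_by_twice_preference(
        self, task_model, intact_trial
    ):
        c = TaskParams().preference
        G = intact_trial.epochs[2].G  # after rule and target are inferred
        assert G[1] - G[2] == pytest.approx(-2 * c, abs=1e-3)  # blue is correct

    def test_flat_feedback_equalizes_policies(self, task_model, settings):
        from pfcsim import LesionConfig, TrialCondition, apply_lesion, run_trial

        medial = apply_lesion(task_model, LesionConfig("medial"))
        rec = run_trial(
            medial, settings, TrialCondition(0, 0), np.random.default_rng(3),
            record_trace=False,
        )
        G = rec.epochs[2].G
        assert np.ptp(G) < 1e-9


class TestPolicyPosterior:
    def test_uniform_under_equal_value(self):
        post = policy_posterior(np.zeros(3), np.zeros(3))
        assert np.allclose(post, 1 / 3)

    def test_closed_form_preference_gap(self):
        c = 3.0
        post = policy_posterior(np.zeros(3), np.array([0.0, 2 * c, 2 * c]))
        assert post[0] == pytest.approx(1 / (1 + 2 * np.exp(-2 * c)), abs=1e-12)

    @hsettings(deadline=None, derandomize=True)
    @given(finite_vectors, st.floats(min_value=-20, max_value=20, allow_nan=False))
    def test_shift_invariance(self, F, c):
        post1 = policy_posterior(F, np.zeros_like(F))
        post2 = policy_posterior(F + c, np.zeros_like(F))
        assert np.allclose(post1, post2, atol=1e-10)

    def test_prior_only_mode_ignores_F(self):
        s = EngineSettings(policy_value="prior")
        post = policy_posterior(np.array([0.0, 100.0]), np.zeros(2), s)
        assert np.allclose(post, 0.5)


class TestSelectAction:
    def test_picks_dominant_policy_action(self, task_model):
        post = np.array([0.99, 0.005, 0.005])
        assert select_action(post, task_model.policies, 3, 3) == 0

    def test_unanimous_stay_before_choice_point(self, task_model):
        post = np.full(3, 1 / 3)
        assert select_action(post, task_model.policies, 1, 3) == 0

    def test_exact_tie_resolves_to_lower_index(self, task_model):
        post = np.array([0.0, 0.5, 0.5])
        assert select_action(post, task_model.policies, 3, 3) == 1  # pick-blue

    def test_rejects_out_of_range_step(self, task_model):
        with pytest.raises(ValueError):
            select_action(np.full(3, 1 / 3), task_model.policies, 4, 3)


class TestTemporalCoding:
    def test_future_then_past_coding_of_the_rule(self, task_model, intact_trial):
        """Units for tau=1 hold predictions before the cue and memories after."""
        from pfcsim import init_beliefs

        # before the cue every unit is uninformed (predictions are uniform)
        fresh = init_beliefs(build_task_model())
        assert np.all(fresh.s[0] == 0.5)
        frames = intact_trial.beliefs.trace
        end_epoch1 = [f for f in frames if f.epoch == 1][-1]
        # after the cue, tau=1 units carry a concentrated memory of the rule
        assert np.all(end_epoch1.s[0][:, 0, 0] > 0.9)
        # and units for future steps predict it through the identity dynamics
        assert np.all(end_epoch1.s[0][:, 1:, 0] > 0.9)
        last = frames[-1]
        assert np.all(last.s[0][:, 0, 0] > 0.9)  # memory persists to trial end

    def test_descent_violations_are_reported_not_hidden(self, intact_trial):
        # decisive evidence in epoch 3 transiently raises F; the engine
        # records it rather than silently accepting it
        assert all(len(rec) == 3 for rec in intact_trial.beliefs.descent_violations)
        assert {e for e, _, _ in intact_trial.beliefs.descent_violations} <= {3, 4}


class TestEngineSettings:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_iter": 0},
            {"kappa": 0.0},
            {"kappa": 1.5},
            {"log_floor": 0.0},
            {"gamma": -1.0},
            {"message_mode": "thirds"},
            {"policy_value": "likelihood"},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EngineSettings(**kwargs)
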