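"""Stop-probability kernels, choice likelihood, and the model registry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beadsampling.choice import (
    BEST_MODEL_NAME,
    ChoiceParams,
    ChoiceState,
    build_choice_data,
    choice_loglik,
    combine_stages,
    decayed_ci_sequence,
    enumerate_registry,
    flexible_psec,
    get_model,
    stage_logit,
    stop_probability,
    update_decayed_ci,
)
from beadsampling.task import Condition, TrialRecord


def _tree_stop_probability(p1, p2, p_sec, trigger):
    """Exhaustive enumeration of the two-stage decision tree."""
    total = 0.0
    for s1 in (0, 1):  # stage-1 decision: 1 = stop
        pr1 = p1 if s1 else 1 - p1
        triggered = (s1 == 0) if trigger == "continue" else (s1 == 1)
        if not triggered:
            total += pr1 * s1
            continue
        # second thought recruited with p_sec, else stage-1 decision stands
        total += pr1 * (1 - p_sec) * s1
        for s2 in (0, 1):
            pr2 = p2 if s2 else 1 - p2
            total += pr1 * p_sec * pr2 * s2
    return total


class TestDecayedCI:
    @pytest.mark.parametrize(
        "alpha,beads,expected",
        [
            (1.0, "PPB", 1.0),  # plain pink-minus-blue count
            (0.0, "PPPB", -1.0),  # only the last bead survives
            (0.5, "PP", 1.5),  # 0.5*1 + 1
        ],
    )
    def test_recursion(self, alpha, beads, expected):
        ci = 0.0
        for b in beads:
            ci = update_decayed_ci(ci, b, alpha)
        assert ci == pytest.approx(expected)

    def test_sequence_matches_stepwise(self):
        beads = list("PBPPBP")
        seq = decayed_ci_sequence(beads, 0.7)
        assert seq[0] == 0.0
        assert len(seq) == len(beads) + 1

    def test_bounded_by_count_and_domain_error(self):
        rng = np.random.default_rng(0)
        beads = ["P" if rng.random() < 0.5 else "B" for _ in range(20)]
        for alpha in (0.0, 0.3, 1.0):
            seq = decayed_ci_sequence(beads, alpha)
            assert np.all(np.abs(seq) <= np.arange(len(seq)) + 1e-12)
        with pytest.raises(ValueError):
            update_decayed_ci(0.0, "P", 1.5)


class TestStageLogit:
    def test_zero_weights_give_half_stop_probability(self):
        state = ChoiceState(3, Condition(0.1, 0.6), ci_decayed=2.0)
        assert stage_logit(state, np.zeros(5), "cost") == 0.0
        assert stage_logit(state, np.zeros(6), "evidence") == 0.0

    def test_logit_ln3_gives_probability_three_quarters(self):
        # intercept-only evidence stage with weight ln 3
        state = ChoiceState(0, Condition(0.0, 0.6))
        w = np.zeros(6)
        w[0] = math.log(3.0)
        x = stage_logit(state, w, "evidence")
        assert 1 / (1 + math.exp(-x)) == pytest.approx(0.75)

    def test_irrelevant_weight_change_leaves_logit(self):
        state = ChoiceState(0, Condition(0.0, 0.6))  # j = 0 -> j DVs are 0
        w = np.array([0.5, 0.0, 0.0, 1.0, 1.0])
        w2 = w.copy()
        w2[3:] *= 2  # j and total-cost DVs are zero at j = 0
        assert stage_logit(state, w, "cost") == stage_logit(state, w2, "cost")

    def test_arity_mismatch(self):
        state = ChoiceState(1, Condition(0.1, 0.6))
        with pytest.raises(ValueError):
            stage_logit(state, np.zeros(4), "cost")


class TestStopProbability:
    @pytest.mark.parametrize("trigger", ["continue", "stop"])
    def test_psec_zero_reduces_to_stage1(self, trigger):
        assert combine_stages(0.2, 0.9, 0.0, trigger) == pytest.approx(0.2)

    def test_continue_triggered_example(self):
        assert combine_stages(0.2, 0.5, 1.0, "continue") == pytest.approx(0.6)

    def test_stop_triggered_example(self):
        assert combine_stages(0.4, 1.0, 0.5, "stop") == pytest.approx(0.4)

    def test_flexible_identity(self):
        for p1 in (0.1, 0.5, 0.9):
            assert flexible_psec(p1, 1.0, 0.0) == pytest.approx(p1)

    @given(
        p1=st.floats(0.0, 1.0),
        p2=st.floats(0.0, 1.0),
        p_sec=st.floats(0.0, 1.0),
        trigger=st.sampled_from(["continue", "stop"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_closed_form_equals_tree_enumeration(self, p1, p2, p_sec, trigger):
        closed = combine_stages(p1, p2, p_sec, trigger)
        tree = _tree_stop_probability(p1, p2, p_sec, trigger)
        assert closed == pytest.approx(tree, abs=1e-12)
        assert 0.0 <= closed <= 1.0
        if trigger == "continue":
            assert closed >= p1 - 1e-12
        else:
            assert closed <= p1 + 1e-12

    def test_full_spec_path(self):
        spec = get_model(BEST_MODEL_NAME)
        params = ChoiceParams(
            stage1_weights=np.array([-2.0, -1.0, 0.0, 0.1, 0.5]),
            stage2_weights=np.array([-1.0, 0.5, 0.4, 0.2, 0.1, 0.01]),
            second_thought=np.array([0.2, 0.5, 0.8]),
            alpha=0.9,
        )
        state = ChoiceState(4, Condition(0.1, 0.8), ci_decayed=2.5)
        p_stop, p1, p2, psec = stop_probability(spec, params, state)
        assert psec == pytest.approx(0.5)  # low-cost condition
        assert p_stop == pytest.approx(p1 + (1 - p1) * psec * p2)


class TestChoiceLoglik:
    def _one_trial(self, n_beads, cond=Condition(0.0, 0.6)):
        return TrialRecord(
            participant_id="p",
            trial_index=1,
            block_index=0,
            condition=cond,
            hidden_jar="dominant-pink",
            jar_side="left",
            beads=["P"] * n_beads,
            choice_dts=[0.5] * n_beads,
            judgment="left",
            correct=True,
        )

    def test_single_continue_with_even_odds(self):
        spec = get_model("Cost only")
        trial = self._one_trial(1)
        # zero weights -> p_stop = 0.5 for both choices (continue then stop)
        ll, cache = choice_loglik(spec, np.zeros(5), [trial])
        assert ll == pytest.approx(2 * math.log(0.5))

    def test_forced_stop_at_cap_is_excluded(self):
        spec = get_model("Cost only")
        trial = self._one_trial(20)
        data = build_choice_data([trial])
        assert data.n_choices == 20  # 20 continues, no stop choice
        assert (data.stop == 0).all()

    def test_loglik_approaches_bernoulli_entropy(self, rng):
        """Mean negative loglik per choice tends to the generative entropy."""
        spec = get_model("Cost only")
        theta = np.zeros(5)
        theta[:3] = math.log(0.25 / 0.75)  # p_stop = 0.25 at every state
        p = 0.25
        entropy = -(p * math.log(p) + (1 - p) * math.log(1 - p))
        trials = []
        for i in range(600):
            n = 0
            while n < 20 and rng.random() >= p:
                n += 1
            trials.append(self._one_trial(n))
        ll, _ = choice_loglik(spec, theta, trials)
        n_choices = build_choice_data(trials).n_choices
        assert -ll / n_choices == pytest.approx(entropy, rel=0.05)


class TestRegistry:
    def test_sixteen_models_twelve_two_stage(self):
        registry = enumerate_registry()
        assert len(registry) == 16
        assert sum(s.family == "two_stage" for s in registry) == 12
        assert len({s.name for s in registry}) == 16

    def test_best_model_parameter_structure(self):
        spec = get_model(BEST_MODEL_NAME)
        assert spec.family == "two_stage"
        assert spec.stage1_dvs == "cost"
        assert spec.stage2_dvs == "evidence"
        assert spec.trigger == "continue"
        assert spec.rule == "cost_cond"
        # 11 stage weights + 3 second-thought probabilities + 1 decay rate
        assert spec.n_stage1_weights + spec.n_stage2_weights == 11
        assert spec.n_rule_params == 3
        assert spec.decay
        assert spec.n_params == 15

    def test_all_two_stage_dimensions_enumerated(self):
        two_stage = [s for s in enumerate_registry() if s.family == "two_stage"]
        combos = {(s.stage1_dvs, s.trigger, s.rule) for s in two_stage}
        assert len(combos) == 12

    def test_param_names_match_arity(self):
        for spec in enumerate_registry():
            assert len(spec.param_names()) == spec.n_params
            assert len(spec.bounds()) == spec.n_params


class TestEquivalences:
    def test_two_stage_with_psec_zero_equals_one_stage(self, cost_first_trials):
        """p_sec = 0 collapses a two-stage model onto its first stage."""
        spec2 = get_model(BEST_MODEL_NAME)
        w1 = np.array([-2.0, -1.5, -0.5, 0.2, 0.8])
        theta2 = np.concatenate([w1, np.zeros(6), np.zeros(3), [1.0]])
        ll2, _ = choice_loglik(spec2, theta2, cost_first_trials)
        spec1 = get_model("Cost only")
        ll1, _ = choice_loglik(spec1, w1, cost_first_trials)
        assert ll2 == pytest.approx(ll1, abs=1e-9)

    def test_alpha_one_equals_plain_counts(self, cost_first_trials):
        """With alpha = 1 the decayed CI is the raw pink-minus-blue count."""
        spec = get_model("Cost + Evidence")
        theta = np.concatenate(
            [np.array([-2.0, -1.0, -0.5, 0.1, 0.5, 0.3, 0.4, 0.2, 0.1, 0.01]), [1.0]]
        )
        ll_decay, _ = choice_loglik(spec, theta, cost_first_trials)
        spec_plain = get_model("Cost + Evidence w/o decay")
        ll_plain, _ = choice_loglik(spec_plain, theta[:-1], cost_first_trials)
        assert ll_decay == pytest.approx(ll_plain, abs=1e-9)


class TestSimulationConsistency:
    def test_empirical_stop_frequency_matches_closed_form(self, rng):
        """Forward draws through the decision tree hit p_stop (99% CI)."""
        n_draws = 100_000
        p1, p2, psec = 0.3, 0.6, 0.4
        for trigger in ("continue", "stop"):
            stops = 0
            u = rng.random((n_draws, 3))
            if trigger == "continue":
                s1_stop = u[:, 0] < p1
                recruited = ~s1_stop & (u[:, 1] < psec)
                stops = s1_stop | (recruited & (u[:, 2] < p2))
            else:
                s1_stop = u[:, 0] < p1
                recruited = s1_stop & (u[:, 1] < psec)
                stops = (s1_stop & ~recruited) | (recruited & (u[:, 2] < p2))
            p_hat = stops.mean()
            p_true = combine_stages(p1, p2, psec, trigger)
            se = math.sqrt(p_true * (1 - p_true) / n_draws)
            assert abs(p_hat - p_true) < 2.58 * se
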