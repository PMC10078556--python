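"""Unit and property tests for the RSA recursion."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from altrsa import (
    AlternativeMixture,
    ModelConfig,
    UninterpretableUtteranceError,
    UnproducibleUtteranceError,
    Utterance,
    WorldPrior,
    core_alternatives,
    knowledge_state,
    literal_listener,
    numeral_alternatives,
    observation_model,
    pragmatic_listener,
    predict_condition_table,
    prob_not_all,
    speaker_distribution,
    speaker_utility,
    sweep,
)


def mixture(p):
    return AlternativeMixture(p)


class TestWorldPrior:
    def test_uniform(self):
        p = WorldPrior.uniform(3)
        assert p.n == 3
        assert np.allclose(p.as_array(), 0.25)

    @pytest.mark.parametrize(
        "weights", [(-0.1, 1.1), (0.4, 0.4), (0.5, 0.6)]
    )
    def test_invalid_weights_rejected(self, weights):
        with pytest.raises(ValueError):
            WorldPrior(weights)


class TestAlternativeSets:
    def test_core_inventory(self):
        alts = core_alternatives(3)
        assert [u.label for u in alts] == ["none", "some", "all"]
        assert alts["some"].meaning == {1, 2, 3}
        assert alts["all"].meaning == {3}

    def test_numeral_inventory_lower_bounded(self):
        alts = numeral_alternatives(3)
        assert [u.label for u in alts] == ["none", "some", "all", "one", "two", "three"]
        assert alts["two"].meaning == {2, 3}
        assert alts["one"].meaning == {1, 2, 3}

    def test_empty_meaning_rejected(self):
        with pytest.raises(ValueError):
            Utterance("nothing", frozenset())


class TestLiteralListener:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("all", [0, 0, 0, 1]),
            ("some", [0, 1 / 3, 1 / 3, 1 / 3]),
            ("two", [0, 0, 0.5, 0.5]),
        ],
    )
    def test_uniform_restriction(self, label, expected, uniform_prior):
        u = numeral_alternatives(3)[label]
        assert np.allclose(literal_listener(u, uniform_prior), expected)

    def test_uninterpretable_utterance_raises(self):
        prior = WorldPrior((1.0, 0.0, 0.0, 0.0))  # all mass on w=0
        with pytest.raises(UninterpretableUtteranceError):
            literal_listener(core_alternatives(3)["some"], prior)

    def test_degenerate_prior_allowed(self):
        prior = WorldPrior((0.0, 0.0, 0.0, 1.0))
        out = literal_listener(core_alternatives(3)["some"], prior)
        assert np.allclose(out, [0, 0, 0, 1])


class TestSpeakerUtility:
    def test_full_knowledge_examples(self, uniform_prior):
        alts = core_alternatives(3)
        s = knowledge_state(3, 3, 3, uniform_prior)
        assert speaker_utility(s, alts["all"], uniform_prior) == pytest.approx(0.0)
        assert speaker_utility(s, alts["some"], uniform_prior) == pytest.approx(
            math.log(1 / 3)
        )

    def test_false_in_supported_world_is_minus_inf(self, uniform_prior):
        s = knowledge_state(2, 2, 3, uniform_prior)  # support {2, 3}
        assert speaker_utility(s, core_alternatives(3)["all"], uniform_prior) == -np.inf


class TestSpeakerDistribution:
    def test_full_knowledge_alpha1(self, uniform_prior):
        s = knowledge_state(3, 3, 3, uniform_prior)
        probs = speaker_distribution(s, core_alternatives(3), 1.0, uniform_prior)
        # weights: none 0, some 1/3, all 1 -> renormalized
        assert np.allclose(probs, [0.0, 0.25, 0.75])

    def test_full_knowledge_alpha3(self, uniform_prior):
        s = knowledge_state(3, 3, 3, uniform_prior)
        probs = speaker_distribution(s, core_alternatives(3), 3.0, uniform_prior)
        assert probs[1] == pytest.approx(1 / 28)

    def test_alpha0_uniform_over_assertable(self, uniform_prior):
        s = knowledge_state(3, 3, 3, uniform_prior)
        probs = speaker_distribution(s, numeral_alternatives(3), 0.0, uniform_prior)
        # assertable in w=3: some, all, one, two, three (not none)
        assert np.allclose(probs, [0.0, 0.2, 0.2, 0.2, 0.2, 0.2])

    def test_mute_state_flagged_as_zero_vector(self, uniform_prior):
        # access 2, observed 0: support {0, 1}; none/some/all all unassertable
        s = knowledge_state(2, 0, 3, uniform_prior)
        probs = speaker_distribution(s, core_alternatives(3), 1.0, uniform_prior)
        assert not probs.any()
        # ... and stays mute with numerals (all require w >= 1)
        probs = speaker_distribution(s, numeral_alternatives(3), 1.0, uniform_prior)
        assert not probs.any()


class TestObservationModel:
    def test_all_have_property(self):
        assert observation_model(3, 2, 3)[2] == pytest.approx(1.0)

    def test_full_access_is_deterministic(self):
        for w in range(4):
            dist = observation_model(w, 3, 3)
            assert dist[w] == pytest.approx(1.0)

    def test_subset_enumeration_case(self):
        dist = observation_model(1, 2, 3)
        assert dist[0] == pytest.approx(1 / 3)
        assert dist[1] == pytest.approx(2 / 3)

    @given(
        n=st.integers(1, 6),
        w=st.integers(0, 6),
        a=st.integers(1, 6),
    )
    def test_sums_to_one(self, n, w, a):
        w, a = min(w, n), min(a, n)
        assert observation_model(w, a, n).sum() == pytest.approx(1.0, abs=1e-9)

    def test_range_violations(self):
        with pytest.raises(ValueError):
            observation_model(4, 2, 3)
        with pytest.raises(ValueError):
            observation_model(1, 0, 3)


class TestKnowledgeState:
    def test_full_access_point_mass(self, uniform_prior):
        s = knowledge_state(3, 2, 3, uniform_prior)
        assert s.support == (2,)
        assert s.belief == (1.0,)

    def test_partial_access_bayesian_update(self, uniform_prior):
        s = knowledge_state(2, 2, 3, uniform_prior)
        assert s.support == (2, 3)
        assert np.allclose(s.belief, [0.25, 0.75])

    def test_partial_access_symmetric_case(self, uniform_prior):
        s = knowledge_state(2, 1, 3, uniform_prior)
        assert s.support == (1, 2)
        assert np.allclose(s.belief, [0.5, 0.5])

    @given(a=st.integers(1, 4), o=st.integers(0, 4))
    def test_belief_sums_to_one(self, a, o):
        o = min(o, a)
        prior = WorldPrior.uniform(4)
        s = knowledge_state(a, o, 4, prior)
        assert sum(s.belief) == pytest.approx(1.0, abs=1e-9)
        assert set(s.support) <= set(range(5))


class TestPragmaticListener:
    def test_full_no_numerals_alpha3(self, alpha3_config):
        post = pragmatic_listener("some", 3, mixture(0.0), alpha3_config)
        # hand computation: weights (0, 1, 1, 1/28) -> P(not all) = 56/57
        assert prob_not_all(post, 3) == pytest.approx(56 / 57, abs=1e-12)

    def test_partial_no_numerals_is_five_eighths(self, alpha3_config):
        post = pragmatic_listener("some", 2, mixture(0.0), alpha3_config)
        assert prob_not_all(post, 3) == pytest.approx(0.625, abs=1e-12)

    def test_partial_with_numerals_alpha3(self, alpha3_config):
        post = pragmatic_listener("some", 2, mixture(1.0), alpha3_config)
        assert prob_not_all(post, 3) == pytest.approx(0.7966101694915, abs=1e-9)

    def test_posterior_normalized(self, alpha3_config):
        for access in (2, 3):
            for p in (0.0, 0.3, 1.0):
                post = pragmatic_listener("some", access, mixture(p), alpha3_config)
                assert post.sum() == pytest.approx(1.0, abs=1e-9)
                assert post[0] == 0.0  # w=0 never inflates "some"

    def test_unproducible_utterance(self):
        # prior mass only on w=3: "none" is uninterpretable/unproducible
        cfg = ModelConfig(n=3, prior=WorldPrior((0.0, 0.0, 0.0, 1.0)), alpha=1.0)
        with pytest.raises((UnproducibleUtteranceError, UninterpretableUtteranceError)):
            pragmatic_listener("none", 3, mixture(0.0), cfg)

    def test_missing_from_active_set_raises(self, alpha3_config):
        with pytest.raises(ValueError):
            pragmatic_listener("two", 2, mixture(0.0), alpha3_config)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0, 3.0, 10.0])
    def test_alpha_invariance_partial_no_numerals(self, alpha):
        """With only {none, some, all}, 'some' is the unique assertable
        utterance in every non-mute partial-knowledge state, so the speaker
        term cancels and alpha cannot matter."""
        cfg = ModelConfig(n=3, alpha=alpha)
        post = pragmatic_listener("some", 2, mixture(0.0), cfg)
        assert prob_not_all(post, 3) == pytest.approx(0.625, abs=1e-12)

    def test_alpha0_closed_forms(self):
        # uniform speaker over assertable utterances, full knowledge:
        # no numerals: weights (0, 1, 1, 1/2) -> P(not all) = 2 / 2.5
        cfg = ModelConfig(n=3, alpha=0.0)
        post = pragmatic_listener("some", 3, mixture(0.0), cfg)
        assert prob_not_all(post, 3) == pytest.approx(0.8, abs=1e-12)
        # with numerals: weights (0, 1/2, 1/3, 1/5)
        post = pragmatic_listener("some", 3, mixture(1.0), cfg)
        expected = (1 / 2 + 1 / 3) / (1 / 2 + 1 / 3 + 1 / 5)
        assert prob_not_all(post, 3) == pytest.approx(expected, abs=1e-12)


class TestPredictionTable:
    def test_full_cells_round_to_98_at_alpha3(self, alpha3_config):
        table = predict_condition_table(alpha3_config)
        assert table.percent_rounded["full_no_num"] == 98
        assert table.percent_rounded["full_with_num"] == 98

    def test_partial_cells_at_alpha3(self, alpha3_config):
        table = predict_condition_table(alpha3_config)
        assert table.cells[("partial", "no_numerals")] == pytest.approx(0.625)
        assert table.cells[("partial", "with_numerals")] == pytest.approx(
            0.7966101694915, abs=1e-9
        )

    @pytest.mark.parametrize("alpha", [1.0, 2.0, 3.0, 5.0, 7.0, 10.0])
    def test_interaction_sign(self, alpha):
        """Knowledgeability effect is strictly larger without numerals, and
        both effects are positive: the predicted crossover pattern."""
        table = predict_condition_table(ModelConfig(n=3, alpha=alpha))
        eff_no = table.knowledgeability_effect("no_numerals")
        eff_with = table.knowledgeability_effect("with_numerals")
        assert eff_no > eff_with > 0

    @pytest.mark.parametrize("alpha", [1.0, 2.0, 3.0, 4.0, 5.0])
    def test_full_knowledge_near_equality(self, alpha):
        table = predict_condition_table(ModelConfig(n=3, alpha=alpha))
        gap = abs(
            table.cells[("full", "with_numerals")]
            - table.cells[("full", "no_numerals")]
        )
        assert gap <= 0.02

    def test_partial_with_numerals_exceeds_without(self, alpha3_config):
        table = predict_condition_table(alpha3_config)
        assert (
            table.cells[("partial", "with_numerals")]
            > table.cells[("partial", "no_numerals")]
        )

    def test_table_round_trips_through_dict(self, alpha3_config):
        d = predict_condition_table(alpha3_config).to_dict()
        assert d["config"]["alpha"] == 3.0
        assert set(d["cells"]) == {
            "partial_no_num", "partial_with_num", "full_no_num", "full_with_num"
        }


class TestSweep:
    def test_matches_single_point_calls(self, alpha3_config):
        df = sweep([3.0], [0.0, 1.0], alpha3_config)
        table = predict_condition_table(alpha3_config)
        row0 = df[df.p_with_numerals == 0.0].iloc[0]
        row1 = df[df.p_with_numerals == 1.0].iloc[0]
        assert row0.p_not_all_partial == pytest.approx(
            table.cells[("partial", "no_numerals")]
        )
        assert row0.p_not_all_full == pytest.approx(
            table.cells[("full", "no_numerals")]
        )
        assert row1.p_not_all_partial == pytest.approx(
            table.cells[("partial", "with_numerals")]
        )

    def test_monotone_in_mixture_weight(self):
        df = sweep([3.0], np.linspace(0, 1, 11))
        vals = df.p_not_all_partial.to_numpy()
        assert np.all(np.diff(vals) >= -1e-12)

    def test_monotone_in_alpha_with_numerals(self):
        df = sweep([0.0, 0.5, 1.0, 2.0, 3.0, 5.0, 10.0], [1.0])
        vals = df.p_not_all_partial.to_numpy()
        assert np.all(np.diff(vals) >= -1e-12)

    def test_alpha0_row_interior(self):
        df = sweep([0.0], [0.0, 0.5, 1.0])
        for col in ("p_not_all_partial", "p_not_all_full"):
            assert ((df[col] > 0) & (df[col] < 1)).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep([], [0.0])
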