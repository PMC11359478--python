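"""Question weighting and confidence-adjusted disease scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cszprio import (
    DiseaseScore,
    Response,
    disease_scores,
    question_score,
    question_weight,
    question_weights,
    rank_diseases,
    score_bounds,
)

from conftest import make_config


def respond(p, d, q, v, conf="high"):
    return Response(
        participant_id=p, disease_id=d, question_id=q, answer_value=v, confidence=conf
    )


class TestQuestionWeight:
    @pytest.mark.parametrize(
        "triple, expected",
        [((0.4, 0.3, 0.2), 0.30), ((0.5, 0.5, 0.5), 0.5), ((0.65, 0.19, 0.27), 0.37)],
    )
    def test_arithmetic_mean(self, triple, expected):
        assert question_weight(*triple) == pytest.approx(expected)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            question_weight(-0.1, 0.5, 0.5)

    def test_per_question_lookup(self, minimal_config):
        weights = question_weights(
            minimal_config,
            {
                "hazard": {"hazard1": 0.65, "hazard2": 0.35},
                "transmission": {"transmission1": 0.19, "transmission2": 0.81},
                "outcome": {"outcome1": 0.27, "outcome2": 0.73},
            },
        )
        assert weights == {"q1": pytest.approx(0.37)}


class TestQuestionScore:
    def test_worked_example(self):
        assert round(question_score(0.37, 2, 3), 2) == 0.25
        assert question_score(0.37, 2, 3) == pytest.approx(0.24667, abs=1e-5)

    def test_extremes(self):
        assert question_score(0.42, 0, 3) == 0.0
        assert question_score(0.42, 3, 3) == pytest.approx(0.42)

    def test_out_of_range_answer_rejected(self):
        with pytest.raises(ValueError):
            question_score(0.37, 4, 3)


class TestScoreBounds:
    def test_worked_example_range(self):
        low, high = score_bounds(0.37, 2, 1, 3)
        assert (round(low, 2), round(high, 2)) == (0.12, 0.37)
        assert low == pytest.approx(0.12333, abs=1e-5)
        assert high == pytest.approx(0.37)

    def test_full_confidence_collapses_range(self):
        z = question_score(0.37, 2, 3)
        assert score_bounds(0.37, 2, 0, 3) == (pytest.approx(z), pytest.approx(z))

    def test_upper_bound_clamped_at_weight(self):
        _, high = score_bounds(0.5, 3, 1, 3)
        assert high == pytest.approx(0.5)  # not w * (M+1)/M

    def test_lower_bound_clamped_at_zero(self):
        low, _ = score_bounds(0.5, 1, 2, 3)
        assert low == 0.0

    def test_negative_confidence_rejected(self):
        with pytest.raises(ValueError):
            score_bounds(0.37, 2, -1, 3)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        w=st.floats(0.0, 1.0, allow_nan=False),
        m=st.integers(1, 6),
        data=st.data(),
    )
    def test_bound_ordering_invariant(self, w, m, data):
        v = data.draw(st.integers(0, m))
        c = data.draw(st.integers(0, 4))
        z = question_score(w, v, m)
        low, high = score_bounds(w, v, c, m)
        assert 0.0 <= low <= z <= high <= w + 1e-12


class TestDiseaseScores:
    def test_sum_over_participants_and_questions(self):
        config = make_config(n_questions=2, participants=("p1", "p2"))
        weights = {"q1": 0.25, "q2": 0.25}
        responses = [
            respond(p, "disease_a", q, 3) for p in ("p1", "p2") for q in ("q1", "q2")
        ]
        (score,) = disease_scores(responses, weights, config)
        assert score.score == pytest.approx(1.0)  # four maxed 0.25-weight answers
        assert score.normalized == pytest.approx(1.0)

    def test_all_maximum_answers_normalize_to_one(self):
        config = make_config(n_questions=3, participants=("p1", "p2", "p3"),
                             diseases=("d1", "d2"))
        weights = {"q1": 0.2, "q2": 0.5, "q3": 0.3}
        responses = [
            respond(p, d, q, 3)
            for p in config.participants for d in config.diseases for q in weights
        ]
        for s in disease_scores(responses, weights, config):
            assert s.normalized == pytest.approx(1.0)
            assert s.normalized_high == pytest.approx(1.0)

    def test_all_zero_answers_normalize_to_zero(self):
        config = make_config(n_questions=2, participants=("p1",))
        weights = {"q1": 0.4, "q2": 0.6}
        responses = [respond("p1", "disease_a", q, 0) for q in weights]
        (s,) = disease_scores(responses, weights, config)
        assert s.normalized == 0.0 and s.score == 0.0

    def test_duplicate_triple_rejected(self, minimal_config):
        responses = [respond("p1", "disease_a", "q1", 1)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            disease_scores(responses, {"q1": 0.5}, minimal_config)

    def test_missing_response_rejected_by_default(self, minimal_config):
        with pytest.raises(ValueError, match="missing"):
            disease_scores([], {"q1": 0.5}, minimal_config)

    def test_missing_response_imputed_on_request(self, minimal_config):
        (s,) = disease_scores([], {"q1": 0.6}, minimal_config, impute_missing=True)
        assert s.score == 0.0
        # imputed as answer 0 with low confidence (C=2): upper bound w*C/M
        assert s.score_high == pytest.approx(0.6 * 2 / 3)

    def test_zero_participants_impossible(self):
        with pytest.raises(Exception):
            make_config(participants=())

    def test_additivity_matches_brute_force_oracle(self):
        """Aggregation equals an explicit double loop applying the
        per-question scoring formulas."""
        rng = np.random.default_rng(11)
        config = make_config(n_questions=4, participants=("p1", "p2", "p3"),
                             diseases=("d1", "d2", "d3"))
        weights = {q.id: w for q, w in zip(config.questions, rng.dirichlet(np.ones(4)))}
        conf_labels = ["low", "medium", "high"]
        responses = [
            respond(p, d, q.id, int(rng.integers(0, q.max_value + 1)),
                    conf_labels[rng.integers(0, 3)])
            for p in config.participants for d in config.diseases for q in config.questions
        ]
        scores = {s.disease_id: s for s in disease_scores(responses, weights, config)}

        # oracle: independent accumulation from first principles
        for d in config.diseases:
            z = z_low = z_high = 0.0
            for r in responses:
                if r.disease_id != d:
                    continue
                q = config.question(r.question_id)
                w, M = weights[q.id], q.max_value
                C = config.confidence_value(r.confidence)
                z += w * r.answer_value / M
                z_low += w * max(r.answer_value - C, 0) / M
                z_high += w * min(r.answer_value + C, M) / M
            denom = len(config.participants) * sum(weights.values())
            s = scores[d]
            assert s.score == pytest.approx(z)
            assert s.score_low == pytest.approx(z_low)
            assert s.score_high == pytest.approx(z_high)
            assert s.normalized == pytest.approx(z / denom)

    def test_raising_one_answer_never_lowers_the_score(self):
        config = make_config(n_questions=2, participants=("p1", "p2"))
        weights = {"q1": 0.5, "q2": 0.5}
        base = [respond(p, "disease_a", q, 1) for p in ("p1", "p2") for q in weights]
        (s0,) = disease_scores(base, weights, config)
        bumped = [respond("p1", "disease_a", "q1", 2)] + base[1:]
        (s1,) = disease_scores(bumped, weights, config)
        assert s1.score >= s0.score
        assert s1.normalized >= s0.normalized


class TestRanking:
    def make_score(self, d, z, z_low=None):
        z_low = z if z_low is None else z_low
        return DiseaseScore(d, z, z_low, z, z, z_low, z)

    def test_descending_with_lexicographic_tiebreak(self):
        scores = [
            self.make_score("b_disease", 0.5),
            self.make_score("c_disease", 0.8),
            self.make_score("a_disease", 0.5),
        ]
        ranked = rank_diseases(scores)
        assert [(s.disease_id, s.rank) for s in ranked] == [
            ("c_disease", 1), ("a_disease", 2), ("b_disease", 3),
        ]

    def test_lower_bound_breaks_ties_first(self):
        scores = [
            self.make_score("a", 0.5, z_low=0.2),
            self.make_score("b", 0.5, z_low=0.4),
        ]
        assert [s.disease_id for s in rank_diseases(scores)] == ["b", "a"]

    def test_single_disease(self):
        (only,) = rank_diseases([self.make_score("only", 0.3)])
        assert only.rank == 1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        scores = [self.make_score(f"d{i}", float(z)) for i, z in enumerate(rng.random(10))]
        reference = [s.disease_id for s in rank_diseases(scores)]
        for _ in range(5):
            rng.shuffle(scores)
            assert [s.disease_id for s in rank_diseases(scores)] == reference

    def test_duplicate_disease_rejected(self):
        with pytest.raises(ValueError):
            rank_diseases([self.make_score("a", 0.5), self.make_score("a", 0.4)])
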