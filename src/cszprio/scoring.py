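"""Confidence-adjusted disease scoring and ranking.

Each scoring question q carries a weight ``w_q`` — the arithmetic mean of
the normalized weights of the hazard, transmission, and outcome criteria
it combines.  A participant's ordinal answer ``V`` (of maximum ``M``) with
confidence half-width ``C`` yields an initial score ``w_q * V / M`` and a
confidence range obtained by shifting the answer by ``±C`` (clamped to
``[0, M]``).  Disease totals sum the per-question scores over all
participants and questions; normalized totals divide by the attainable
maximum ``P * Σ_q w_q`` so a disease every expert maxes out scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .elicitation import Response, WorkshopConfig

__all__ = [
    "DiseaseScore",
    "question_weight",
    "question_weights",
    "question_score",
    "score_bounds",
    "disease_scores",
    "rank_diseases",
    "scores_to_frame",
]


@dataclass(frozen=True)
class DiseaseScore:
    """Aggregated initial/lower/upper scores for one disease."""

    disease_id: str
    score: float
    score_low: float
    score_high: float
    normalized: float
    normalized_low: float
    normalized_high: float
    rank: int | None = None


def question_weight(hazard_w: float, transmission_w: float, outcome_w: float) -> float:
    """Weight of a question: arithmetic mean of its three criterion weights."""
    for w in (hazard_w, transmission_w, outcome_w):
        if w < 0:
            raise ValueError(f"criterion weights must be non-negative, got {w}")
    return (hazard_w + transmission_w + outcome_w) / 3.0


def question_weights(
    config: WorkshopConfig,
    set_weights: Mapping[str, Mapping[str, float]],
) -> dict[str, float]:
    """Weight w_q for every configured question.

    ``set_weights`` maps each set kind ('hazard' | 'transmission' |
    'outcome') to its normalized criterion weights, e.g. the
    ``normalized_defuzzified`` column of the group weight tables.
    """
    out = {}
    for q in config.questions:
        try:
            out[q.id] = question_weight(
                set_weights["hazard"][q.hazard_id],
                set_weights["transmission"][q.transmission_id],
                set_weights["outcome"][q.outcome_id],
            )
        except KeyError as exc:
            raise KeyError(f"no weight available for criterion {exc} used by question {q.id!r}") from exc
    return out


def question_score(w_q: float, V: int, M: int) -> float:
    """Initial score of one answer: ``w_q * V / M``."""
    if M < 1:
        raise ValueError(f"maximum answer value must be >= 1, got {M}")
    if not (0 <= V <= M):
        raise ValueError(f"answer value {V} outside [0, {M}]")
    return w_q * V / M


def score_bounds(w_q: float, V: int, C: int, M: int) -> tuple[float, float]:
    """Confidence range of one answer.

    The answer value is shifted down/up by the confidence half-width C and
    clamped to the answer range, so bounds stay within ``[0, w_q]``:
    ``(w_q * max(V-C, 0) / M,  w_q * min(V+C, M) / M)``.
    """
    if C < 0:
        raise ValueError(f"confidence value must be non-negative, got {C}")
    question_score(w_q, V, M)  # validate V, M
    low = w_q * max(V - C, 0) / M
    high = w_q * min(V + C, M) / M
    return (low, high)


def disease_scores(
    responses: Iterable[Response],
    weights: Mapping[str, float],
    config: WorkshopConfig,
    *,
    impute_missing: bool = False,
) -> list[DiseaseScore]:
    """Aggregate per-question scores into disease totals.

    Every participant is expected to answer every question for every
    disease exactly once.  Duplicates are always an error; missing
    (participant, disease, question) triples are an error unless
    ``impute_missing`` is set, in which case they are scored as answer 0
    with low confidence.

    Raw totals sum ``Z``, ``Z_low``, ``Z_high`` over participants and
    questions; normalized totals divide by ``P * Σ_q w_q``.
    """
    participants = list(config.participants)
    if not participants:
        raise ValueError("a workshop needs at least one participant")
    qmax = {q.id: q.max_value for q in config.questions}
    for qid in weights:
        if qid not in qmax:
            raise KeyError(f"weight given for unknown question {qid!r}")
    missing_w = [qid for qid in qmax if qid not in weights]
    if missing_w:
        raise KeyError(f"no weight for questions {missing_w}")

    seen: set[tuple[str, str, str]] = set()
    totals: dict[str, list[float]] = {d: [0.0, 0.0, 0.0] for d in config.diseases}
    for r in responses:
        key = (r.participant_id, r.disease_id, r.question_id)
        if r.disease_id not in totals:
            raise KeyError(f"response for unknown disease {r.disease_id!r}")
        if key in seen:
            raise ValueError(f"duplicate response for {key}")
        seen.add(key)
        w_q = weights[r.question_id]
        M = qmax[r.question_id]
        C = config.confidence_value(r.confidence)
        z = question_score(w_q, r.answer_value, M)
        z_low, z_high = score_bounds(w_q, r.answer_value, C, M)
        t = totals[r.disease_id]
        t[0] += z
        t[1] += z_low
        t[2] += z_high

    expected = {
        (p, d, q.id) for p in participants for d in config.diseases for q in config.questions
    }
    absent = expected - seen
    if absent and not impute_missing:
        example = sorted(absent)[0]
        raise ValueError(
            f"{len(absent)} missing response(s), e.g. {example}; "
            "pass impute_missing=True to score them as answer 0 with low confidence"
        )
    for p, d, qid in absent:
        # V=0 with low confidence: initial and lower scores 0, upper w_q*C/M
        w_q = weights[qid]
        M = qmax[qid]
        C = config.confidence_value("low")
        _, z_high = score_bounds(w_q, 0, C, M)
        totals[d][2] += z_high

    denom = len(participants) * sum(weights[q.id] for q in config.questions)
    out = []
    for d in config.diseases:
        z, z_low, z_high = totals[d]
        out.append(
            DiseaseScore(
                disease_id=d,
                score=z,
                score_low=z_low,
                score_high=z_high,
                normalized=z / denom,
                normalized_low=z_low / denom,
                normalized_high=z_high / denom,
            )
        )
    return out


def rank_diseases(scores: Sequence[DiseaseScore]) -> list[DiseaseScore]:
    """Order diseases into a priority list.

    Descending by normalized score, ties broken by the lower estimate
    (descending) then disease id; ranks are 1-based without gaps.  The
    result is independent of input order.
    """
    ids = [s.disease_id for s in scores]
    if len(set(ids)) != len(ids):
        raise ValueError("one DiseaseScore per disease required")
    ordered = sorted(
        scores, key=lambda s: (-s.normalized, -s.normalized_low, s.disease_id)
    )
    return [
        DiseaseScore(**{**s.__dict__, "rank": i + 1}) for i, s in enumerate(ordered)
    ]


def scores_to_frame(
    scores: Sequence[DiseaseScore],
    *,
    n_participants: int | None = None,
    n_questions: int | None = None,
) -> pd.DataFrame:
    """Priority list as a DataFrame with full-precision and 2-dp columns."""
    from .fuzzy import round_display

    df = pd.DataFrame([s.__dict__ for s in scores])
    for col in ("normalized", "normalized_low", "normalized_high"):
        df[f"{col}_2dp"] = df[col].map(round_display)
    if n_participants is not None:
        df["n_participants"] = n_participants
    if n_questions is not None:
        df["n_questions"] = n_questions
    return df
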