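"""Seeded synthetic-workshop generator.

Emulates a full prioritization workshop so every pipeline stage can be
exercised end to end without real elicitation data: per-participant
near-consistent pairwise judgment matrices on the odd Saaty scale for all
three criterion sets, and ordinal answers driven by a latent per-disease
climate-sensitivity score with random confidence levels.

Generative model
----------------
* Judgments: each participant holds a true weight vector drawn from a
  Dirichlet distribution; the implied consistent ratios ``w_i / w_j`` are
  perturbed by multiplicative log-normal noise and snapped to the nearest
  odd-scale value in log space (ratios are multiplicative).  Matrices are
  redrawn until they pass the CR < 0.10 gate, within a retry budget.
* Answers: each disease carries a latent sensitivity ``s_d`` in [0, 1].
  A participant's answer to question q is a discretized logistic link on
  ``s_d``: logistic noise is added on the logit scale and the resulting
  propensity is rounded onto the question's ordinal value range, so the
  expected answer increases monotonically with ``s_d`` and noise -> 0
  recovers the deterministic rounding of ``s_d * M_q``.
* Confidence: i.i.d. draws from a configurable low/medium/high
  distribution.

Everything is driven by one integer seed; identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ahp import (
    CR_THRESHOLD,
    PairwiseComparisonMatrix,
    consistency,
    geometric_mean_weights,
)
from .elicitation import (
    AnswerOption,
    Criterion,
    CriterionSet,
    Question,
    Response,
    WorkshopConfig,
    save_config,
    write_judgments,
    write_responses,
)

__all__ = ["WorkshopSimConfig", "SyntheticWorkshop", "simulate_matrices",
           "simulate_responses", "simulate_workshop", "snap_to_scale"]

_ODD_SCALE = np.array([1 / 9, 1 / 7, 1 / 5, 1 / 3, 1.0, 3.0, 5.0, 7.0, 9.0])
_LOG_ODD_SCALE = np.log(_ODD_SCALE)


@dataclass(frozen=True)
class WorkshopSimConfig:
    """Study conditions for a simulated workshop.

    Defaults mirror the illustrative scoring scenario (10 participants,
    10 questions, 25 diseases) and the four-criterion demonstration of
    the weighting step; expert panels of 6-15 voters and 10-20 questions
    are the intended operating range.
    """

    n_participants: int = 10
    set_sizes: tuple[int, int, int] = (4, 4, 4)  # hazards, transmissions, outcomes
    n_questions: int = 10
    n_diseases: int = 25
    n_answer_options: int = 4  # ordinal values 0 .. n-1
    #: Dirichlet concentration for participants' true criterion weights.
    dirichlet_alpha: float = 1.0
    #: sd of multiplicative log-normal noise on judgment ratios (log scale).
    judgment_noise: float = 0.1
    #: sd of logistic noise on the answer propensity (logit scale).
    answer_noise: float = 0.5
    #: probabilities of (low, medium, high) confidence.
    confidence_probs: tuple[float, float, float] = (0.2, 0.5, 0.3)
    #: latent disease sensitivities are drawn Uniform(0, 1) unless given.
    sensitivities: tuple[float, ...] | None = None
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self):
        for name in ("n_participants", "n_questions", "n_diseases", "n_answer_options"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if any(s < 2 for s in self.set_sizes):
            raise ValueError("each criterion set needs at least 2 members for weighting")
        if abs(sum(self.confidence_probs) - 1.0) > 1e-9:
            raise ValueError("confidence probabilities must sum to 1")
        if self.sensitivities is not None and len(self.sensitivities) != self.n_diseases:
            raise ValueError("one latent sensitivity per disease required")


@dataclass(frozen=True)
class SyntheticWorkshop:
    """A complete generated workshop ready for the weighting and scoring pipeline."""

    config: WorkshopConfig
    sim_config: WorkshopSimConfig
    matrices: dict[tuple[str, str], PairwiseComparisonMatrix]  # (participant, set_id)
    responses: tuple[Response, ...]
    sensitivities: dict[str, float]  # disease_id -> latent s_d

    def judgments(self) -> dict[tuple[str, str], list[tuple[str, str, float]]]:
        """Upper-triangle judgments of every matrix, for CSV export."""
        out = {}
        for key, m in self.matrices.items():
            triples = []
            for i, j in itertools.combinations(range(m.order), 2):
                triples.append((m.criteria[i], m.criteria[j], float(m.values[i, j])))
            out[key] = triples
        return out

    def write(self, directory: str | Path) -> None:
        """Write the workshop as the file dialects the pipeline consumes:
        config.yaml, judgments.csv, responses.csv, sensitivities.csv."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_config(self.config, directory / "config.yaml")
        write_judgments(self.judgments(), directory / "judgments.csv")
        write_responses(self.responses, directory / "responses.csv")
        lines = ["disease_id,sensitivity"]
        lines += [f"{d},{s!r}" for d, s in self.sensitivities.items()]
        (directory / "sensitivities.csv").write_text("\n".join(lines) + "\n")


def snap_to_scale(ratio: float) -> float:
    """Snap a positive ratio to the nearest odd Saaty value in log space."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return float(_ODD_SCALE[np.argmin(np.abs(np.log(ratio) - _LOG_ODD_SCALE))])


def _simulate_one_matrix(
    rng: np.random.Generator,
    criteria: tuple[str, ...],
    set_id: str,
    sim: WorkshopSimConfig,
) -> PairwiseComparisonMatrix:
    n = len(criteria)
    for _ in range(sim.max_retries):
        w = rng.dirichlet(np.full(n, sim.dirichlet_alpha))
        a = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ratio = w[i] / w[j]
                noisy = ratio * np.exp(sim.judgment_noise * rng.standard_normal())
                snapped = snap_to_scale(noisy)
                a[i, j] = snapped
                a[j, i] = 1.0 / snapped
        matrix = PairwiseComparisonMatrix(set_id, criteria, a)
        if consistency(matrix, geometric_mean_weights(matrix)).acceptable:
            return matrix
    raise RuntimeError(
        f"failed to draw a CR < {CR_THRESHOLD} matrix for set {set_id!r} "
        f"within {sim.max_retries} retries (noise {sim.judgment_noise})"
    )


def _build_config(sim: WorkshopSimConfig) -> WorkshopConfig:
    kinds = ("hazard", "transmission", "outcome")
    sets = {}
    for kind, size in zip(kinds, sim.set_sizes):
        members = tuple(
            Criterion(id=f"{kind}_{i + 1:02d}", label=f"{kind} {i + 1}", set_id=kind)
            for i in range(size)
        )
        sets[kind] = CriterionSet(set_id=kind, members=members)
    options = tuple(
        AnswerOption(text=f"level {v}", value=v) for v in range(sim.n_answer_options)
    )
    rng = np.random.default_rng([sim.seed, 0xC0FFEE])
    questions = []
    for i in range(sim.n_questions):
        questions.append(
            Question(
                id=f"q{i + 1:02d}",
                text=f"synthetic question {i + 1}",
                hazard_id=str(rng.choice(sets["hazard"].ids)),
                transmission_id=str(rng.choice(sets["transmission"].ids)),
                outcome_id=str(rng.choice(sets["outcome"].ids)),
                options=options,
            )
        )
    return WorkshopConfig(
        hazards=sets["hazard"],
        transmissions=sets["transmission"],
        outcomes=sets["outcome"],
        questions=tuple(questions),
        diseases=tuple(f"disease_{i + 1:02d}" for i in range(sim.n_diseases)),
        participants=tuple(f"p{i + 1:02d}" for i in range(sim.n_participants)),
    )


def simulate_matrices(
    sim: WorkshopSimConfig, config: WorkshopConfig | None = None
) -> dict[tuple[str, str], PairwiseComparisonMatrix]:
    """Per-participant near-consistent pairwise matrices for all three sets.

    Keys are ``(participant_id, set_id)``; every matrix passes the
    CR < 0.10 gate by construction.
    """
    config = config or _build_config(sim)
    rng = np.random.default_rng([sim.seed, 1])
    out = {}
    for pid in config.participants:
        for set_id in ("hazard", "transmission", "outcome"):
            cset = config.criterion_set(set_id)
            out[(pid, set_id)] = _simulate_one_matrix(rng, cset.ids, set_id, sim)
    return out


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def simulate_responses(
    sim: WorkshopSimConfig, config: WorkshopConfig | None = None
) -> tuple[tuple[Response, ...], dict[str, float]]:
    """Latent-sensitivity-driven answers with random confidence levels.

    Returns the responses and the latent sensitivities ``s_d`` they were
    generated from (for parameter-recovery checks).
    """
    config = config or _build_config(sim)
    rng = np.random.default_rng([sim.seed, 2])
    if sim.sensitivities is not None:
        s = np.asarray(sim.sensitivities, dtype=float)
    else:
        s = rng.uniform(0.0, 1.0, size=sim.n_diseases)
    sensitivities = dict(zip(config.diseases, s.tolist()))
    labels = np.array(["low", "medium", "high"])
    responses = []
    for pid in config.participants:
        for d in config.diseases:
            for q in config.questions:
                x = _logit(sensitivities[d])
                if sim.answer_noise > 0:
                    x += sim.answer_noise * rng.logistic()
                p = 1.0 / (1.0 + np.exp(-x))
                value = int(round(q.min_value + p * (q.max_value - q.min_value)))
                conf = str(rng.choice(labels, p=list(sim.confidence_probs)))
                responses.append(
                    Response(
                        participant_id=pid,
                        disease_id=d,
                        question_id=q.id,
                        answer_value=value,
                        confidence=conf,  # type: ignore[arg-type]
                    )
                )
    return tuple(responses), sensitivities


def simulate_workshop(sim: WorkshopSimConfig) -> SyntheticWorkshop:
    """Generate a complete synthetic workshop (config, matrices, responses)."""
    config = _build_config(sim)
    matrices = simulate_matrices(sim, config)
    responses, sensitivities = simulate_responses(sim, config)
    return SyntheticWorkshop(
        config=config,
        sim_config=sim,
        matrices=matrices,
        responses=responses,
        sensitivities=sensitivities,
    )
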