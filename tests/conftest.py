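import pytest

from cszprio import (
    AnswerOption,
    Criterion,
    CriterionSet,
    Question,
    WorkshopConfig,
    example_hazard_matrix,
)


@pytest.fixture
def hazard_matrix():
    """The reconstructed 4-hazard example comparison matrix."""
    return example_hazard_matrix()


def make_config(
    *,
    n_questions: int = 1,
    diseases=("disease_a",),
    participants=("p1",),
    n_options: int = 4,
):
    """Minimal valid workshop configuration (2 criteria per set)."""
    def cset(kind):
        return CriterionSet(
            set_id=kind,
            members=(
                Criterion(id=f"{kind}1", label=f"{kind} one", set_id=kind),
                Criterion(id=f"{kind}2", label=f"{kind} two", set_id=kind),
            ),
        )

    options = tuple(AnswerOption(text=f"opt {v}", value=v) for v in range(n_options))
    questions = tuple(
        Question(
            id=f"q{i + 1}",
            text=f"question {i + 1}",
            hazard_id="hazard1",
            transmission_id="transmission1",
            outcome_id="outcome1",
            options=options,
        )
        for i in range(n_questions)
    )
    return WorkshopConfig(
        hazards=cset("hazard"),
        transmissions=cset("transmission"),
        outcomes=cset("outcome"),
        questions=questions,
        diseases=tuple(diseases),
        participants=tuple(participants),
    )


@pytest.fixture
def minimal_config():
    return make_config()
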