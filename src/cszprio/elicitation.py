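"""Workshop vocabulary and configuration.

A prioritization workshop is described by three criterion sets (climate
hazards, processes of transmission, health outcomes), a list of scoring
questions that each combine one criterion from every set, the diseases to
be ranked, and the participating experts.  This module defines those
domain objects, the nine-phrase linguistic judgment scale used for
pairwise comparison of criteria, and file I/O (YAML/JSON configuration,
long-format CSV responses, judgment CSV) with cross-reference validation.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "SET_KINDS",
    "LINGUISTIC_SCALE",
    "CONFIDENCE_LABELS",
    "DEFAULT_CONFIDENCE_VALUES",
    "Criterion",
    "CriterionSet",
    "AnswerOption",
    "Question",
    "Response",
    "WorkshopConfig",
    "ConfigError",
    "linguistic_to_intensity",
    "intensity_to_linguistic",
    "parse_intensity",
    "format_intensity",
    "load_config",
    "save_config",
    "default_vocabulary_config",
    "read_responses",
    "write_responses",
    "read_judgments",
    "write_judgments",
]

SET_KINDS = ("hazard", "transmission", "outcome")

#: Linguistic phrase -> intensity of importance (Saaty ratio scale).
#: Odd values only; even intermediates are accepted from numeric input
#: but never produced by the linguistic scale.
LINGUISTIC_SCALE: dict[str, float] = {
    "extremely less important": 1 / 9,
    "strongly less important": 1 / 7,
    "moderately less important": 1 / 5,
    "slightly less important": 1 / 3,
    "equally important": 1.0,
    "slightly more important": 3.0,
    "moderately more important": 5.0,
    "strongly more important": 7.0,
    "extremely more important": 9.0,
}

_INTENSITY_TO_LABEL = {v: k for k, v in LINGUISTIC_SCALE.items()}

CONFIDENCE_LABELS = ("low", "medium", "high")

#: Default half-widths C applied to an answer value: higher confidence gives
#: a tighter score range.  Only medium=1 is fixed by the scoring convention;
#: the rest is configurable per workshop.
DEFAULT_CONFIDENCE_VALUES: dict[str, int] = {"high": 0, "medium": 1, "low": 2}


class ConfigError(ValueError):
    """A workshop configuration file failed validation."""

    def __init__(self, message: str, *, locus: str | None = None):
        self.locus = locus
        super().__init__(f"{locus}: {message}" if locus else message)


def linguistic_to_intensity(label: str) -> float:
    """Map a linguistic judgment phrase to its intensity of importance.

    Matching is case-insensitive and whitespace-tolerant.

    >>> linguistic_to_intensity("Extremely more important")
    9.0
    """
    key = " ".join(label.strip().lower().split())
    try:
        return LINGUISTIC_SCALE[key]
    except KeyError:
        raise ConfigError(
            f"unknown linguistic judgment {label!r}; expected one of: "
            + ", ".join(repr(k) for k in LINGUISTIC_SCALE)
        ) from None


def intensity_to_linguistic(intensity: float, *, tol: float = 1e-9) -> str:
    """Inverse of :func:`linguistic_to_intensity` (odd-scale values only)."""
    for value, label in _INTENSITY_TO_LABEL.items():
        if abs(intensity - value) <= tol * max(1.0, value):
            return label
    raise ConfigError(f"intensity {intensity!r} is not on the linguistic scale")


def parse_intensity(token: str | float | int) -> float:
    """Parse a judgment intensity from a number, '1/7'-style fraction, or phrase."""
    if isinstance(token, (int, float)):
        value = float(token)
    else:
        text = token.strip()
        try:
            value = float(Fraction(text))
        except (ValueError, ZeroDivisionError):
            return linguistic_to_intensity(text)
    if value <= 0:
        raise ConfigError(f"judgment intensity must be positive, got {token!r}")
    return value


def format_intensity(value: float, *, tol: float = 1e-9) -> str:
    """Render an intensity, preserving '1/x' fractions for reciprocal values."""
    for d in range(1, 10):
        if abs(value - 1.0 / d) <= tol / d:
            return "1" if d == 1 else f"1/{d}"
    if abs(value - round(value)) <= tol:
        return str(int(round(value)))
    return repr(value)


class Criterion(BaseModel):
    """One prioritization criterion within a criterion set."""

    model_config = ConfigDict(frozen=True)

    id: str = Field(min_length=1)
    label: str = Field(min_length=1)
    set_id: Literal["hazard", "transmission", "outcome"]


class CriterionSet(BaseModel):
    """Ordered criteria of one kind; order fixes matrix row/column order."""

    model_config = ConfigDict(frozen=True)

    set_id: Literal["hazard", "transmission", "outcome"]
    members: tuple[Criterion, ...] = Field(min_length=1)

    @model_validator(mode="after")
    def _check_members(self) -> "CriterionSet":
        ids = [c.id for c in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate criterion ids in set {self.set_id!r}: {dupes}")
        for c in self.members:
            if c.set_id != self.set_id:
                raise ValueError(
                    f"criterion {c.id!r} declares set {c.set_id!r} inside set {self.set_id!r}"
                )
        return self

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.members)

    def __len__(self) -> int:
        return len(self.members)


class AnswerOption(BaseModel):
    """One ordinal answer to a scoring question (value 0 = least change)."""

    model_config = ConfigDict(frozen=True)

    text: str = Field(min_length=1)
    value: int = Field(ge=0)


class Question(BaseModel):
    """A scoring question combining one criterion from each of the three sets.

    The maximum option value ``M_q`` scales answers to the question weight
    ``w_q`` in scoring; option values must be consecutive integers starting
    at 0 or 1 so that the value/maximum ratio is meaningful.
    """

    model_config = ConfigDict(frozen=True)

    id: str = Field(min_length=1)
    text: str = Field(min_length=1)
    hazard_id: str
    transmission_id: str
    outcome_id: str
    options: tuple[AnswerOption, ...] = Field(min_length=2)

    @model_validator(mode="after")
    def _check_options(self) -> "Question":
        values = [o.value for o in self.options]
        start = values[0]
        if start not in (0, 1):
            raise ValueError(f"question {self.id!r}: option values must start at 0 or 1")
        if values != list(range(start, start + len(values))):
            raise ValueError(
                f"question {self.id!r}: option values must be consecutive integers, got {values}"
            )
        return self

    @property
    def max_value(self) -> int:
        """M_q: the maximum attainable answer value."""
        return self.options[-1].value

    @property
    def min_value(self) -> int:
        return self.options[0].value

    def criterion_ids(self) -> tuple[str, str, str]:
        return (self.hazard_id, self.transmission_id, self.outcome_id)


class Response(BaseModel):
    """One participant's answer and confidence for a (disease, question) pair."""

    model_config = ConfigDict(frozen=True)

    participant_id: str
    disease_id: str
    question_id: str
    answer_value: int = Field(ge=0)
    confidence: Literal["low", "medium", "high"]


class WorkshopConfig(BaseModel):
    """Fully validated elicitation configuration.

    Every question must reference an existing criterion in each of the
    three sets; disease and participant ids must be unique.
    """

    model_config = ConfigDict(frozen=True)

    hazards: CriterionSet
    transmissions: CriterionSet
    outcomes: CriterionSet
    questions: tuple[Question, ...] = Field(min_length=1)
    diseases: tuple[str, ...] = Field(min_length=1)
    participants: tuple[str, ...] = Field(min_length=1)
    confidence_values: dict[str, int] = Field(
        default_factory=lambda: dict(DEFAULT_CONFIDENCE_VALUES)
    )

    @field_validator("confidence_values")
    @classmethod
    def _check_confidence(cls, v: dict[str, int]) -> dict[str, int]:
        if set(v) != set(CONFIDENCE_LABELS):
            raise ValueError(f"confidence mapping must define exactly {CONFIDENCE_LABELS}")
        if any(c < 0 for c in v.values()):
            raise ValueError("confidence values must be non-negative integers")
        if not (v["high"] <= v["medium"] <= v["low"]):
            raise ValueError(
                "confidence values must be monotone: high <= medium <= low "
                f"(got {v})"
            )
        return v

    @model_validator(mode="after")
    def _check_cross_references(self) -> "WorkshopConfig":
        if self.hazards.set_id != "hazard":
            raise ValueError("hazards section must have set_id 'hazard'")
        if self.transmissions.set_id != "transmission":
            raise ValueError("transmissions section must have set_id 'transmission'")
        if self.outcomes.set_id != "outcome":
            raise ValueError("outcomes section must have set_id 'outcome'")
        for name, seq in (("diseases", self.diseases), ("participants", self.participants)):
            if len(set(seq)) != len(seq):
                raise ValueError(f"duplicate ids in {name}: {sorted(set(x for x in seq if list(seq).count(x) > 1))}")
        qids = [q.id for q in self.questions]
        if len(set(qids)) != len(qids):
            raise ValueError(f"duplicate question ids: {sorted({q for q in qids if qids.count(q) > 1})}")
        sets = {"hazard": self.hazards, "transmission": self.transmissions, "outcome": self.outcomes}
        for q in self.questions:
            for kind, ref in zip(SET_KINDS, q.criterion_ids()):
                if ref not in sets[kind].ids:
                    raise ValueError(
                        f"question {q.id!r} references unknown {kind} criterion {ref!r}"
                    )
        return self

    def criterion_set(self, set_id: str) -> CriterionSet:
        try:
            return {"hazard": self.hazards, "transmission": self.transmissions, "outcome": self.outcomes}[set_id]
        except KeyError:
            raise KeyError(f"unknown criterion set kind {set_id!r}") from None

    def question(self, question_id: str) -> Question:
        for q in self.questions:
            if q.id == question_id:
                return q
        raise KeyError(f"unknown question id {question_id!r}")

    def confidence_value(self, label: str) -> int:
        """Half-width C attached to a confidence label."""
        return self.confidence_values[label]


# ---------------------------------------------------------------------------
# Configuration file I/O


def _criterion_set_from_dict(set_id: str, entries: Sequence[Mapping], locus: str) -> CriterionSet:
    members = []
    for i, entry in enumerate(entries):
        try:
            members.append(
                Criterion(
                    id=str(entry["id"]),
                    label=str(entry.get("label", entry["id"])),
                    set_id=set_id,  # type: ignore[arg-type]
                )
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(str(exc), locus=f"{locus}[{i}]") from exc
    return CriterionSet(set_id=set_id, members=tuple(members))  # type: ignore[arg-type]


def _config_from_dict(raw: Mapping, source: str) -> WorkshopConfig:
    required = {"criteria", "questions", "diseases", "participants"}
    missing = required - set(raw)
    if missing:
        raise ConfigError(f"missing sections: {sorted(missing)}", locus=source)
    criteria = raw["criteria"]
    for kind, section in (("hazard", "hazards"), ("transmission", "transmissions"), ("outcome", "outcomes")):
        if section not in criteria:
            raise ConfigError(f"criteria section missing {section!r}", locus=source)
    questions = []
    for i, q in enumerate(raw["questions"]):
        locus = f"{source}:questions[{i}]"
        try:
            options = tuple(
                AnswerOption(text=str(o["text"]), value=int(o["value"])) for o in q["options"]
            )
            questions.append(
                Question(
                    id=str(q["id"]),
                    text=str(q.get("text", q["id"])),
                    hazard_id=str(q["hazard_id"]),
                    transmission_id=str(q["transmission_id"]),
                    outcome_id=str(q["outcome_id"]),
                    options=options,
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(str(exc), locus=locus) from exc
    try:
        return WorkshopConfig(
            hazards=_criterion_set_from_dict("hazard", criteria["hazards"], f"{source}:criteria.hazards"),
            transmissions=_criterion_set_from_dict(
                "transmission", criteria["transmissions"], f"{source}:criteria.transmissions"
            ),
            outcomes=_criterion_set_from_dict("outcome", criteria["outcomes"], f"{source}:criteria.outcomes"),
            questions=tuple(questions),
            diseases=tuple(str(d) for d in raw["diseases"]),
            participants=tuple(str(p) for p in raw["participants"]),
            confidence_values={str(k): int(v) for k, v in raw.get("confidence_values", DEFAULT_CONFIDENCE_VALUES).items()},
        )
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(str(exc), locus=source) from exc


def load_config(path: str | Path) -> WorkshopConfig:
    """Load and validate a workshop configuration from YAML or JSON.

    Raises :class:`ConfigError` with a file/record locus on schema
    violations, dangling criterion references, or duplicate ids.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ConfigError("top level must be a mapping", locus=str(path))
    return _config_from_dict(raw, str(path))


def config_to_dict(config: WorkshopConfig) -> dict:
    """Plain-dict form of a configuration (inverse of :func:`load_config`)."""
    return {
        "criteria": {
            section: [{"id": c.id, "label": c.label} for c in cset.members]
            for section, cset in (
                ("hazards", config.hazards),
                ("transmissions", config.transmissions),
                ("outcomes", config.outcomes),
            )
        },
        "questions": [
            {
                "id": q.id,
                "text": q.text,
                "hazard_id": q.hazard_id,
                "transmission_id": q.transmission_id,
                "outcome_id": q.outcome_id,
                "options": [{"text": o.text, "value": o.value} for o in q.options],
            }
            for q in config.questions
        ],
        "diseases": list(config.diseases),
        "participants": list(config.participants),
        "confidence_values": dict(config.confidence_values),
    }


def save_config(config: WorkshopConfig, path: str | Path) -> None:
    """Write a configuration to YAML (or JSON when the suffix is .json)."""
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def default_vocabulary_config(
    diseases: Sequence[str] = ("example_disease",),
    participants: Sequence[str] = ("p01",),
) -> WorkshopConfig:
    """Packaged default criterion vocabulary.

    Eight climate hazards, four biological transmission mechanisms and four
    health-outcome categories drawn from literature reviews of climate
    impacts on zoonotic transmission, with one template question.  Real
    workshops refine this vocabulary; it ships as a validated starting
    point and a self-test of the schema.
    """
    hazards = [
        ("warming", "Long-term changes in temperature"),
        ("precipitation", "Long-term changes in precipitation"),
        ("drought", "Droughts"),
        ("flooding", "Floods, storms, and cyclones"),
        ("heat_wave", "Heat waves"),
        ("sea_level", "Sea level rise"),
        ("fire", "Fires"),
        ("wind", "Wind speed"),
    ]
    transmissions = [
        ("exposure", "Geographic exposure to infected hosts and vectors"),
        ("population", "Change in host or vector population demographics"),
        ("evolution", "Evolutionary pressure on pathogens"),
        ("susceptibility", "Host susceptibility to infection"),
    ]
    outcomes = [
        ("severity", "Severity of disease"),
        ("control", "Ability to prevent and control"),
        ("transmissibility", "Transmissibility"),
        ("socioeconomic", "Socio-economic impacts"),
    ]
    options = (
        AnswerOption(text="No change in transmission", value=0),
        AnswerOption(text="Increased transmission in animals only", value=1),
        AnswerOption(text="Increased transmission in humans only", value=2),
        AnswerOption(text="Increased transmission in animals and humans", value=3),
    )
    question = Question(
        id="q01",
        text="Does warming impact the evolution of pathogens and lead to increased transmission?",
        hazard_id="warming",
        transmission_id="evolution",
        outcome_id="transmissibility",
        options=options,
    )
    mk = lambda set_id, pairs: CriterionSet(
        set_id=set_id,
        members=tuple(Criterion(id=i, label=l, set_id=set_id) for i, l in pairs),
    )
    return WorkshopConfig(
        hazards=mk("hazard", hazards),
        transmissions=mk("transmission", transmissions),
        outcomes=mk("outcome", outcomes),
        questions=(question,),
        diseases=tuple(diseases),
        participants=tuple(participants),
    )


# ---------------------------------------------------------------------------
# Responses and judgments CSV I/O

RESPONSE_COLUMNS = ["participant_id", "disease_id", "question_id", "answer_value", "confidence"]
JUDGMENT_COLUMNS = ["participant_id", "set_id", "criterion_a", "criterion_b", "judgment"]


def read_responses(path: str | Path, config: WorkshopConfig | None = None) -> list[Response]:
    """Read long-format answer/confidence records, optionally validating
    each against a workshop configuration (ids resolve, value within M_q)."""
    df = pd.read_csv(path, dtype=str)
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"responses file missing columns {sorted(missing)}", locus=str(path))
    responses = []
    for row in df.itertuples(index=True):
        locus = f"{path}:row {row.Index + 2}"  # header is line 1
        try:
            resp = Response(
                participant_id=row.participant_id,
                disease_id=row.disease_id,
                question_id=row.question_id,
                answer_value=int(row.answer_value),
                confidence=str(row.confidence).lower(),  # type: ignore[arg-type]
            )
        except ValueError as exc:
            raise ConfigError(str(exc), locus=locus) from exc
        if config is not None:
            _validate_response(resp, config, locus)
        responses.append(resp)
    return responses


def _validate_response(resp: Response, config: WorkshopConfig, locus: str) -> None:
    if resp.disease_id not in config.diseases:
        raise ConfigError(f"unknown disease {resp.disease_id!r}", locus=locus)
    if resp.participant_id not in config.participants:
        raise ConfigError(f"unknown participant {resp.participant_id!r}", locus=locus)
    try:
        q = config.question(resp.question_id)
    except KeyError as exc:
        raise ConfigError(str(exc), locus=locus) from exc
    if not (q.min_value <= resp.answer_value <= q.max_value):
        raise ConfigError(
            f"answer value {resp.answer_value} outside [{q.min_value}, {q.max_value}] "
            f"for question {q.id!r}",
            locus=locus,
        )


def write_responses(responses: Iterable[Response], path: str | Path) -> None:
    pd.DataFrame([r.model_dump() for r in responses], columns=RESPONSE_COLUMNS).to_csv(
        path, index=False
    )


def read_judgments(
    path: str | Path,
) -> dict[tuple[str, str], list[tuple[str, str, float]]]:
    """Read pairwise judgments keyed by (participant_id, set_id).

    The ``judgment`` column accepts a linguistic phrase, a decimal, or a
    '1/7'-style fraction.  A legacy ``linguistic_label`` column name is
    also accepted.
    """
    df = pd.read_csv(path, dtype=str)
    if "judgment" not in df.columns and "linguistic_label" in df.columns:
        df = df.rename(columns={"linguistic_label": "judgment"})
    missing = set(JUDGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"judgments file missing columns {sorted(missing)}", locus=str(path))
    out: dict[tuple[str, str], list[tuple[str, str, float]]] = {}
    for row in df.itertuples(index=True):
        locus = f"{path}:row {row.Index + 2}"
        try:
            intensity = parse_intensity(row.judgment)
        except ConfigError as exc:
            raise ConfigError(str(exc), locus=locus) from exc
        out.setdefault((row.participant_id, row.set_id), []).append(
            (row.criterion_a, row.criterion_b, intensity)
        )
    return out


def write_judgments(
    judgments: Mapping[tuple[str, str], Sequence[tuple[str, str, float]]],
    path: str | Path,
) -> None:
    rows = [
        {
            "participant_id": pid,
            "set_id": set_id,
            "criterion_a": a,
            "criterion_b": b,
            "judgment": format_intensity(x),
        }
        for (pid, set_id), triples in judgments.items()
        for a, b, x in triples
    ]
    pd.DataFrame(rows, columns=JUDGMENT_COLUMNS).to_csv(path, index=False)
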