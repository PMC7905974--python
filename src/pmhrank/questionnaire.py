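"""Questionnaire model for the 39-item Positive Mental Health (PMH) instrument.

The instrument measures six wellbeing factors:

====== =========================================
Factor Meaning
====== =========================================
F1     Personal satisfaction
F2     Prosocial attitude
F3     Self-control
F4     Autonomy
F5     Problem-solving and self-actualization
F6     Interpersonal relationship skills
====== =========================================

Each of the 39 items is a positively or negatively phrased statement
answered on a four-step frequency scale.  Positively phrased items score
3, 2, 1, 0 from "always or almost always" down to "never or almost never";
negatively phrased items score the reverse, so that a higher score always
means better mental health.  Every item provides evidence for exactly one
factor; the factor/item incidence of the default configuration is
:data:`DEFAULT_FACTOR_QUESTIONS`.

Only one item polarity is published for the original instrument (q1 is a
negative statement); the default configuration therefore marks q1 negative
and the rest positive, and real deployments should supply the full
polarity list in their questionnaire configuration file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ConfigurationError, ValidationError

__all__ = [
    "FACTORS",
    "FACTOR_NAMES",
    "FREQUENCY_TERMS",
    "DEFAULT_FACTOR_QUESTIONS",
    "Question",
    "FactorQuestionMap",
    "QuestionnaireConfig",
    "AnswerSheet",
    "score_raw_answer",
    "score_sheet",
    "questions_for_factor",
    "default_questionnaire",
]

FACTORS: tuple[str, ...] = ("F1", "F2", "F3", "F4", "F5", "F6")

FACTOR_NAMES: Mapping[str, str] = {
    "F1": "Personal satisfaction",
    "F2": "Prosocial attitude",
    "F3": "Self-control",
    "F4": "Autonomy",
    "F5": "Problem-solving and self-actualization",
    "F6": "Interpersonal relationship skills",
}

#: The four admissible frequency answers, from most to least frequent.
FREQUENCY_TERMS: tuple[str, ...] = (
    "always or almost always",
    "quite often",
    "sometimes",
    "never or almost never",
)

# score of each term for a positively phrased item, in FREQUENCY_TERMS order
_POSITIVE_SCORES: tuple[int, ...] = (3, 2, 1, 0)

_MAX_SCORE = 3

#: Factor -> item-number incidence of the default 39-item instrument.
DEFAULT_FACTOR_QUESTIONS: Mapping[str, tuple[int, ...]] = {
    "F1": (4, 6, 7, 12, 14, 31, 38, 39),
    "F2": (1, 3, 23, 25, 37),
    "F3": (2, 5, 21, 22, 26),
    "F4": (10, 13, 19, 33, 34),
    "F5": (15, 16, 17, 27, 28, 29, 32, 35, 36),
    "F6": (8, 9, 11, 18, 20, 24, 30),
}

#: Items known to be negatively phrased (the only polarity published).
DEFAULT_NEGATIVE_ITEMS: frozenset[str] = frozenset({"q1"})

_WS = re.compile(r"[\s_\-]+")


def _normalize_term(term: str) -> str:
    t = _WS.sub(" ", term.strip().lower())
    # common paraphrase of the lowest frequency step
    if t == "rarely or never":
        t = "never or almost never"
    return t


def score_raw_answer(answer: str, polarity: str) -> int:
    """Map one linguistic frequency answer to its numeric score in {0..3}.

    Parameters
    ----------
    answer
        One of :data:`FREQUENCY_TERMS` (case/whitespace-insensitive;
        hyphens and underscores are accepted as separators).
    polarity
        ``"positive"`` or ``"negative"``: the phrasing of the item.
        Positive items score (3, 2, 1, 0) over the four terms, negative
        items the reverse, so high scores always mean good mental health.
    """
    if polarity not in ("positive", "negative"):
        raise ConfigurationError(f"unknown polarity {polarity!r}")
    t = _normalize_term(answer)
    try:
        idx = FREQUENCY_TERMS.index(t)
    except ValueError:
        raise ConfigurationError(
            f"unknown answer term {answer!r}; expected one of {FREQUENCY_TERMS}"
        ) from None
    s = _POSITIVE_SCORES[idx]
    return s if polarity == "positive" else _MAX_SCORE - s


@dataclass(frozen=True)
class Question:
    """One questionnaire item: identifier, phrasing polarity and factor."""

    id: str
    factor: str
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if not self.id:
            raise ConfigurationError("question id must be non-empty")
        if self.factor not in FACTORS:
            raise ConfigurationError(
                f"question {self.id!r}: unknown factor {self.factor!r}"
            )
        if self.polarity not in ("positive", "negative"):
            raise ConfigurationError(
                f"question {self.id!r}: unknown polarity {self.polarity!r}"
            )


@dataclass(frozen=True)
class FactorQuestionMap:
    """Incidence of items on factors: for each factor, the ordered item ids
    that provide evidence about it.  Factor sets are disjoint."""

    by_factor: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for f, qids in self.by_factor.items():
            if f not in FACTORS:
                raise ConfigurationError(f"unknown factor {f!r}")
            for q in qids:
                if q in seen:
                    raise ConfigurationError(
                        f"item {q!r} assigned to both {seen[q]} and {f}"
                    )
                seen[q] = f

    def questions_for(self, factor_id: str) -> tuple[str, ...]:
        if factor_id not in self.by_factor:
            raise ConfigurationError(f"unknown factor {factor_id!r}")
        return tuple(self.by_factor[factor_id])

    @property
    def all_items(self) -> tuple[str, ...]:
        return tuple(q for f in FACTORS if f in self.by_factor for q in self.by_factor[f])

    def sizes(self) -> dict[str, int]:
        return {f: len(qs) for f, qs in self.by_factor.items()}


def questions_for_factor(factor_id: str, fq_map: FactorQuestionMap) -> tuple[str, ...]:
    """Ordered item ids with incidence 1 on ``factor_id``."""
    return fq_map.questions_for(factor_id)


@dataclass(frozen=True)
class QuestionnaireConfig:
    """A full questionnaire configuration: the ordered item list.

    Invariants enforced at construction: item ids are unique and every
    item maps to exactly one factor (by the :class:`Question` type).
    """

    questions: tuple[Question, ...]

    def __post_init__(self) -> None:
        ids = [q.id for q in self.questions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ConfigurationError(f"duplicate question ids: {dupes}")
        if not self.questions:
            raise ConfigurationError("questionnaire has no items")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(q.id for q in self.questions)

    def question(self, qid: str) -> Question:
        for q in self.questions:
            if q.id == qid:
                return q
        raise ConfigurationError(f"unknown question id {qid!r}")

    @property
    def factor_map(self) -> FactorQuestionMap:
        by: dict[str, list[str]] = {f: [] for f in FACTORS}
        for q in self.questions:
            by[q.factor].append(q.id)
        return FactorQuestionMap({f: tuple(v) for f, v in by.items() if v})


def default_questionnaire(
    negative_items: Iterable[str] = DEFAULT_NEGATIVE_ITEMS,
) -> QuestionnaireConfig:
    """The default 39-item configuration with the published factor map.

    ``negative_items`` lists ids of negatively phrased items (default:
    the one published example, ``q1``).
    """
    neg = set(negative_items)
    questions = []
    for f in FACTORS:
        for num in DEFAULT_FACTOR_QUESTIONS[f]:
            qid = f"q{num}"
            questions.append(
                Question(qid, f, "negative" if qid in neg else "positive")
            )
    # present items in numeric order, as administered
    questions.sort(key=lambda q: int(q.id[1:]))
    return QuestionnaireConfig(tuple(questions))


@dataclass(frozen=True)
class AnswerSheet:
    """One caregiver's numeric answers: item id -> score in [0, 3].

    Scores are integers when produced from linguistic answers by
    :func:`score_sheet`; fractional values in [0, 3] are accepted on input
    (e.g. when previously aggregated levels re-enter the pipeline).
    """

    caregiver_id: str
    scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {q: s for q, s in self.scores.items() if not 0.0 <= float(s) <= 3.0}
        if bad:
            raise ValidationError(
                f"sheet {self.caregiver_id!r}: scores out of [0, 3]: {bad}"
            )

    def validate(self, config: QuestionnaireConfig) -> None:
        """Check completeness against a configuration (raises on failure)."""
        missing = [q for q in config.item_ids if q not in self.scores]
        if missing:
            raise ValidationError(
                f"sheet {self.caregiver_id!r}: missing answers for {missing}"
            )
        extra = sorted(set(self.scores) - set(config.item_ids))
        if extra:
            raise ValidationError(
                f"sheet {self.caregiver_id!r}: unconfigured items {extra}"
            )

    def score_vector(self, item_ids: Iterable[str]) -> list[float]:
        """Scores for ``item_ids`` in the given order (KeyError if absent)."""
        return [float(self.scores[q]) for q in item_ids]


def score_sheet(
    caregiver_id: str,
    raw_answers: Mapping[str, str],
    config: QuestionnaireConfig,
) -> AnswerSheet:
    """Score a complete set of linguistic answers into an :class:`AnswerSheet`.

    Every configured item must be answered; missing or extra ids raise a
    :class:`~pmhrank.errors.ValidationError` naming them.
    """
    missing = [q for q in config.item_ids if q not in raw_answers]
    if missing:
        raise ValidationError(f"sheet {caregiver_id!r}: missing answers for {missing}")
    extra = sorted(set(raw_answers) - set(config.item_ids))
    if extra:
        raise ValidationError(f"sheet {caregiver_id!r}: unconfigured items {extra}")
    scores = {
        q.id: float(score_raw_answer(raw_answers[q.id], q.polarity))
        for q in config.questions
    }
    return AnswerSheet(caregiver_id, scores)
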