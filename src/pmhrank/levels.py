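"""Per-factor PMH competence levels via OWA aggregation.

A caregiver's level on factor *f_j* aggregates the scores of the items
with incidence on *f_j* using an Ordered Weighted Average (OWA): the
scores are sorted in descending order and dotted with a weight vector
``w``.  The weights come from the RIM (regular increasing monotone)
quantifier ``quant(x) = x**alpha``::

    w_i = (i/n)**alpha - ((i-1)/n)**alpha,   i = 1..n

``alpha`` sets the aggregation policy:

* ``alpha = 1`` — uniform weights, the arithmetic mean;
* ``alpha > 1`` — conjunctive ("all/most must be high"): weight shifts to
  the *lowest* scores, so a single low answer pulls the level down;
* ``alpha < 1`` — disjunctive ("at least one high is enough"): weight
  concentrates on the highest score (``alpha -> 0`` is the maximum).

The default ``alpha = 3`` models the conjunctive reading of competence:
a factor is only satisfied when essentially all of its items are.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .questionnaire import FACTORS, AnswerSheet, FactorQuestionMap, QuestionnaireConfig

__all__ = [
    "DEFAULT_ALPHA",
    "ALPHA_GRID",
    "HISTOGRAM_BINS",
    "OWAWeights",
    "LevelVector",
    "rim_quantifier_weights",
    "owa_aggregate",
    "compute_factor_level",
    "compute_level_vector",
    "cohort_level_histogram",
    "sweep_alpha",
    "round_half_up",
]

#: Conjunctive default selected for the deployed method.
DEFAULT_ALPHA: float = 3.0

#: The alpha values studied when calibrating the aggregation policy.
ALPHA_GRID: tuple[float, ...] = (0.2, 0.5, 0.7, 1.0, 1.5, 2.0, 3.0, 4.0)

#: Level histogram bins: [0,1), [1,2), [2,3] (upper bin closed).
HISTOGRAM_BINS: tuple[str, ...] = ("[0,1)", "[1,2)", "[2,3]")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, the convention of printed score
    tables (e.g. 2.125 -> 2.13), unlike banker's rounding."""
    q = decimal.Decimal(10) ** -ndigits
    return float(
        decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class OWAWeights:
    """An OWA weight vector generated from the RIM quantifier ``x**alpha``.

    ``weights[i-1]`` multiplies the *i*-th largest score.  Invariants:
    non-negative, sum to one; non-increasing for ``alpha < 1``,
    non-decreasing for ``alpha > 1``, uniform at ``alpha = 1``.
    """

    alpha: float
    n: int
    weights: tuple[float, ...]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


def rim_quantifier_weights(alpha: float, n: int) -> OWAWeights:
    """OWA weights from the quantifier ``quant(x) = x**alpha`` at length ``n``.

    ``alpha = 0`` is the existential limit: all weight on the maximum,
    i.e. ``(1, 0, ..., 0)`` (``quant(0) = 0`` by the quantifier boundary
    condition, ``quant(x > 0) = 1``).
    """
    if not np.isfinite(alpha) or alpha < 0:
        raise ParameterError(f"alpha must be a finite non-negative real, got {alpha}")
    if int(n) != n or n < 1:
        raise ParameterError(f"n must be a positive integer, got {n}")
    n = int(n)
    grid = np.arange(n + 1, dtype=float) / n
    quant = grid**alpha
    quant[0] = 0.0  # quant(0) = 0 also in the alpha = 0 limit
    w = np.diff(quant)
    return OWAWeights(alpha=float(alpha), n=n, weights=tuple(float(v) for v in w))


def owa_aggregate(scores: Sequence[float], weights: OWAWeights) -> float:
    """OWA of ``scores``: sort descending, dot with ``weights``.

    The result is bounded by ``[min(scores), max(scores)]`` and is
    idempotent on constant vectors.  Scores must lie in [0, 3] and match
    ``weights.n`` in length.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1 or len(s) != weights.n:
        raise ValidationError(
            f"expected {weights.n} scores for these weights, got shape {s.shape}"
        )
    if np.any(s < 0) or np.any(s > 3):
        raise ValidationError("scores must lie in [0, 3]")
    return float(np.sort(s)[::-1] @ weights.as_array())


@dataclass(frozen=True)
class LevelVector:
    """Per-factor PMH competence levels of one caregiver, each in [0, 3].

    ``incomplete`` flags vectors computed from a sheet with missing
    answers (permissive mode renormalizes the OWA over the answered
    subset of each factor's items).
    """

    caregiver_id: str
    levels: Mapping[str, float]
    alpha: float | None = None
    incomplete: bool = False

    def __post_init__(self) -> None:
        bad = {f: v for f, v in self.levels.items() if not 0.0 <= float(v) <= 3.0}
        if bad:
            raise ValidationError(
                f"levels of {self.caregiver_id!r} out of [0, 3]: {bad}"
            )
        unknown = set(self.levels) - set(FACTORS)
        if unknown:
            raise ValidationError(f"unknown factors {sorted(unknown)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.levels[f] for f in FACTORS], dtype=float)

    def __getitem__(self, factor_id: str) -> float:
        return float(self.levels[factor_id])


def _factor_scores(
    sheet: AnswerSheet,
    factor_id: str,
    fq_map: FactorQuestionMap,
    allow_incomplete: bool,
) -> list[float]:
    qids = fq_map.questions_for(factor_id)
    present = [q for q in qids if q in sheet.scores]
    if len(present) < len(qids) and not allow_incomplete:
        missing = [q for q in qids if q not in sheet.scores]
        raise ValidationError(
            f"sheet {sheet.caregiver_id!r}: missing answers for {missing} "
            f"(factor {factor_id})"
        )
    if not present:
        raise ValidationError(
            f"sheet {sheet.caregiver_id!r}: no answers at all for factor {factor_id}"
        )
    return sheet.score_vector(present)


def compute_factor_level(
    sheet: AnswerSheet,
    factor_id: str,
    fq_map: FactorQuestionMap,
    alpha: float = DEFAULT_ALPHA,
    *,
    allow_incomplete: bool = False,
) -> float:
    """OWA level of one caregiver on one factor.

    Weights are generated at the factor's item count.  With
    ``allow_incomplete=True`` a sheet may miss answers; the weights are
    then regenerated over the answered subset (quantifier renormalization).
    """
    scores = _factor_scores(sheet, factor_id, fq_map, allow_incomplete)
    w = rim_quantifier_weights(alpha, len(scores))
    return owa_aggregate(scores, w)


def compute_level_vector(
    sheet: AnswerSheet,
    config: QuestionnaireConfig,
    alpha: float = DEFAULT_ALPHA,
    *,
    allow_incomplete: bool = False,
) -> LevelVector:
    """All six factor levels of one caregiver at a common ``alpha``."""
    fq_map = config.factor_map
    if not allow_incomplete:
        sheet.validate(config)
    levels = {
        f: compute_factor_level(
            sheet, f, fq_map, alpha, allow_incomplete=allow_incomplete
        )
        for f in FACTORS
        if f in fq_map.by_factor
    }
    incomplete = any(q not in sheet.scores for q in config.item_ids)
    return LevelVector(sheet.caregiver_id, levels, alpha=float(alpha), incomplete=incomplete)


def cohort_level_histogram(levels: Iterable[LevelVector]) -> pd.DataFrame:
    """Per-factor counts of caregivers in the bins [0,1), [1,2), [2,3].

    Returns a DataFrame indexed by factor with one column per bin; counts
    in each row sum to the cohort size.
    """
    vecs = list(levels)
    if not vecs:
        raise ValidationError("empty cohort")
    edges = np.array([0.0, 1.0, 2.0, 3.0])
    data = {}
    for j, f in enumerate(FACTORS):
        vals = np.array([v.as_array()[j] for v in vecs])
        counts, _ = np.histogram(vals, bins=edges)  # last bin closed at 3
        data[f] = counts
    return pd.DataFrame(data, index=list(HISTOGRAM_BINS)).T


def sweep_alpha(
    sheets: Sequence[AnswerSheet],
    config: QuestionnaireConfig,
    alphas: Sequence[float] = ALPHA_GRID,
    factor: str | None = None,
) -> pd.DataFrame:
    """Aggregate every sheet at each ``alpha``; the policy-calibration sweep.

    With ``factor`` given, returns a caregiver x alpha table for that one
    factor; otherwise rows are a (caregiver, factor) MultiIndex.
    """
    fq_map = config.factor_map
    factors = [factor] if factor is not None else list(fq_map.by_factor)
    rows = {}
    for sheet in sheets:
        for f in factors:
            rows[(sheet.caregiver_id, f)] = [
                compute_factor_level(sheet, f, fq_map, a) for a in alphas
            ]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(alphas))
    df.index = pd.MultiIndex.from_tuples(df.index, names=["caregiver_id", "factor"])
    if factor is not None:
        df = df.droplevel("factor")
    return df
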