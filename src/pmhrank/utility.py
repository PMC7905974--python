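"""Reward-penalty marginal utilities and additive (MAUT) activity ranking.

Each intervention activity carries an impact vector over the six PMH
factors: +1 where the activity was designed to improve the factor, -1
where it was not.  Given a caregiver's level ``l`` on a factor, the
marginal utility of an activity on that factor is::

    impact = +1             ->  k_positive - l          (reward)
    impact = -1, l >= 2.5   ->  0                       (neutral: factor already good)
    impact = -1, l <  2.5   ->  l - k_negative          (penalty / opportunity cost)

so the lower the level of a factor an activity improves, the more urgent
the activity; an activity that ignores a weak factor is penalized.  The
marginal utility ranges over ``[-k_negative, k_positive]``; the deployed
calibration is ``k_positive = 4 > k_negative = 3`` (reward beats penalty)
with neutral threshold 2.5.

Overall utility is the Sum of Scores (SS) across factors — an additive
MAUT aggregation; dividing by the number of factors (Arithmetic Average)
induces the identical ranking.  Activities are proposed in descending
overall utility, a weak order (complete and transitive by construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .levels import LevelVector
from .questionnaire import FACTORS

__all__ = [
    "ImpactVector",
    "UtilityParams",
    "UtilityMatrix",
    "RankedPlan",
    "marginal_utility",
    "marginal_utility_matrix",
    "overall_utility",
    "rank_activities",
    "rank_for_levels",
]

_N_FACTORS = len(FACTORS)


@dataclass(frozen=True)
class ImpactVector:
    """Designed impact of one activity on the six PMH factors (+1/-1).

    Every catalogued activity improves at least one factor.
    """

    activity_id: str
    impacts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.activity_id:
            raise ValidationError("activity_id must be non-empty")
        if len(self.impacts) != _N_FACTORS:
            raise ValidationError(
                f"{self.activity_id}: expected {_N_FACTORS} impacts, "
                f"got {len(self.impacts)}"
            )
        if any(v not in (-1, 1) for v in self.impacts):
            raise ValidationError(f"{self.activity_id}: impacts must be -1 or +1")
        if all(v == -1 for v in self.impacts):
            raise ValidationError(
                f"{self.activity_id}: an activity must improve at least one factor"
            )

    def as_dict(self) -> dict[str, int]:
        return dict(zip(FACTORS, self.impacts))


@dataclass(frozen=True)
class UtilityParams:
    """Reward-penalty calibration of the marginal utility.

    ``k_positive``: utility of improving a factor at level 0 (maximum
    reward).  ``k_negative``: magnitude of the worst penalty, at level 0,
    for ignoring a factor.  ``neutral_threshold``: level at or above which
    a factor counts as satisfied, making a -1 impact neutral (utility 0).
    """

    k_positive: float = 4.0
    k_negative: float = 3.0
    neutral_threshold: float = 2.5

    def __post_init__(self) -> None:
        if self.k_positive <= 0:
            raise ParameterError(f"k_positive must be > 0, got {self.k_positive}")
        if self.k_negative <= 0:
            raise ParameterError(f"k_negative must be > 0, got {self.k_negative}")
        if not 0.0 <= self.neutral_threshold <= 3.0:
            raise ParameterError(
                f"neutral_threshold must lie in [0, 3], got {self.neutral_threshold}"
            )


def marginal_utility(
    level: float, impact: int, params: UtilityParams = UtilityParams()
) -> float:
    """Utility of one activity for one factor at competence ``level``.

    See the module docstring for the three branches; the result lies in
    ``[-k_negative, k_positive]``.
    """
    if not 0.0 <= level <= 3.0:
        raise ValidationError(f"level must lie in [0, 3], got {level}")
    if impact == 1:
        return params.k_positive - level
    if impact == -1:
        if level >= params.neutral_threshold:
            return 0.0
        return level - params.k_negative
    raise ValidationError(f"impact must be -1 or +1, got {impact}")


@dataclass(frozen=True)
class UtilityMatrix:
    """Marginal utilities (activities x factors) and their row sums for
    one caregiver."""

    caregiver_id: str
    marginals: pd.DataFrame  # index: activity_id, columns: F1..F6
    params: UtilityParams = UtilityParams()

    @property
    def overall(self) -> pd.Series:
        """Overall (Sum-of-Scores) utility per activity."""
        return self.marginals.sum(axis=1)


def marginal_utility_matrix(
    levels: LevelVector,
    catalogue: Sequence[ImpactVector],
    params: UtilityParams = UtilityParams(),
) -> UtilityMatrix:
    """Marginal utility of every catalogued activity on every factor."""
    if not catalogue:
        raise ValidationError("activity catalogue is empty")
    ids = [a.activity_id for a in catalogue]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate activity ids: {dupes}")
    lv = levels.as_array()
    rows = {
        a.activity_id: [
            marginal_utility(lv[j], a.impacts[j], params) for j in range(_N_FACTORS)
        ]
        for a in catalogue
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FACTORS))
    return UtilityMatrix(levels.caregiver_id, df, params)


def overall_utility(marginals: Sequence[float] | Mapping[str, float]) -> float:
    """Sum of Scores over the six per-factor marginal utilities."""
    if isinstance(marginals, Mapping):
        vals = [marginals[f] for f in FACTORS]
    else:
        vals = list(marginals)
    if len(vals) != _N_FACTORS:
        raise ValidationError(
            f"expected {_N_FACTORS} marginal utilities, got {len(vals)}"
        )
    return float(np.sum(np.asarray(vals, dtype=float)))


@dataclass(frozen=True)
class RankedPlan:
    """Personalized activity order for one caregiver.

    ``table`` has columns ``rank`` (1 = first proposed), ``activity_id``,
    ``overall_utility`` and the six per-factor marginals; rows sorted by
    rank.  The induced preference is a weak order (complete, transitive).
    """

    caregiver_id: str
    table: pd.DataFrame

    @property
    def activity_order(self) -> tuple[str, ...]:
        return tuple(self.table["activity_id"])

    def utility_of(self, activity_id: str) -> float:
        row = self.table[self.table["activity_id"] == activity_id]
        if row.empty:
            raise ValidationError(f"unknown activity {activity_id!r}")
        return float(row["overall_utility"].iloc[0])


def rank_activities(matrix: UtilityMatrix, tie_break: str = "id_desc") -> RankedPlan:
    """Rank activities by descending overall utility.

    Ties in utility are resolved deterministically by activity id,
    descending by default (``tie_break="id_desc"``, the order observed in
    the reference rankings) or ascending (``"id_asc"``).  Ranks are
    sequential 1..n after tie resolution.
    """
    if tie_break not in ("id_desc", "id_asc"):
        raise ParameterError(f"unknown tie_break {tie_break!r}")
    u = matrix.overall
    reverse = tie_break == "id_desc"
    order = sorted(
        u.index, key=lambda a: (-u[a], _id_key(a, reverse))
    )
    table = matrix.marginals.loc[order].copy()
    table.insert(0, "overall_utility", u.loc[order])
    table.insert(0, "activity_id", order)
    table.insert(0, "rank", np.arange(1, len(order) + 1))
    return RankedPlan(matrix.caregiver_id, table.reset_index(drop=True))


def _id_key(activity_id: str, reverse: bool):
    if not reverse:
        return activity_id
    # invert character order so that plain tuple sort yields descending ids
    return tuple(-ord(c) for c in activity_id)


def rank_for_levels(
    levels: LevelVector,
    catalogue: Sequence[ImpactVector],
    params: UtilityParams = UtilityParams(),
    tie_break: str = "id_desc",
) -> RankedPlan:
    """Convenience: marginal utilities then ranking in one call."""
    return rank_activities(marginal_utility_matrix(levels, catalogue, params), tie_break)
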