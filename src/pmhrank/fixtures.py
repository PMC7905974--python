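"""Reference worked-example data for the PMH personalization method.

These are the published worked-example tables of the method: the 39-item
factor map, the activity catalogue impacts, a five-user sample of raw F1
answers with their OWA aggregates over the alpha grid, a twelve-user
sample of level vectors, and the resulting utilities and rankings.  They
serve as ground truth for the regression/acceptance test-suite and for
the ``reproduce`` CLI command.

Index of the bundle returned by :func:`reference_fixtures`:

=================== =========================================================
key                 contents
=================== =========================================================
factor_question_map factor -> ordered item ids (the default incidence map)
factor_activity_map factor -> activity ids designed to improve it (20 acts)
sample_impacts      activity id -> 6-tuple of +1/-1 impacts (7-activity sample)
f1_answer_sample    caregiver -> F1 item scores (q4..q39), 5 users
alpha_sweep_levels  DataFrame: OWA F1 level per user x alpha (2 d.p.)
cohort_levels       caregiver -> LevelVector (12 users, alpha = 3 levels)
worked_marginals    DataFrame: marginal utilities of User 3 (7 x 6, 2 d.p.)
cohort_overall      DataFrame: overall utility per user x activity (2 d.p.)
cohort_rankings     caregiver -> ranked activity-id tuple
=================== =========================================================
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .levels import ALPHA_GRID, LevelVector
from .questionnaire import DEFAULT_FACTOR_QUESTIONS, FactorQuestionMap
from .utility import ImpactVector

__all__ = [
    "SAMPLE_IMPACTS",
    "FULL_CATALOGUE_FACTOR_ACTIVITIES",
    "sample_catalogue",
    "full_catalogue",
    "reference_fixtures",
]

#: Impacts of the 7-activity worked-example sample, F1..F6.
SAMPLE_IMPACTS: Mapping[str, tuple[int, ...]] = {
    "R1A1": (1, -1, -1, 1, -1, -1),
    "R1A2": (-1, -1, 1, -1, 1, -1),
    "R2A1": (1, 1, -1, -1, -1, -1),
    "R6A2": (-1, 1, -1, 1, -1, -1),
    "R7A1": (-1, -1, 1, 1, -1, -1),
    "R8A1": (-1, 1, -1, -1, 1, -1),
    "R9A3": (1, -1, -1, -1, -1, 1),
}

#: The full 20-activity catalogue, given as factor -> improving activities.
FULL_CATALOGUE_FACTOR_ACTIVITIES: Mapping[str, tuple[str, ...]] = {
    "F1": ("R1A1", "R2A1", "R2A2", "R5A1", "R5A2", "R6A3", "R9A1", "R9A3"),
    "F2": ("R2A1", "R2A2", "R3A1", "R6A2", "R8A1", "R8A2", "R9A2"),
    "F3": ("R1A2", "R3A2", "R4A1", "R4A2", "R7A1", "R7A2"),
    "F4": ("R1A1", "R3A2", "R5A1", "R5A2", "R6A1", "R6A2", "R6A3", "R7A1", "R7A2"),
    "F5": ("R1A2", "R4A1", "R4A2", "R8A1", "R8A2", "R9A1", "R9A2"),
    "F6": ("R3A1", "R6A1", "R9A2", "R9A3"),
}

_FACTOR_ORDER = ("F1", "F2", "F3", "F4", "F5", "F6")

# Raw F1 answers (q4, q6, q7, q12, q14, q31, q38, q39) of the 5-user sample.
_F1_ANSWER_SAMPLE = {
    "User 1": (3, 2, 3, 3, 3, 3, 0, 2),
    "User 4": (3, 2, 3, 2, 2, 2, 2, 2),
    "User 7": (1, 1, 0, 1, 2, 2, 0, 0),
    "User 10": (0, 1, 2, 2, 1, 2, 0, 0),
    "User 12": (3, 2, 3, 3, 3, 3, 3, 3),
}

# OWA F1 levels of the 5-user sample over the alpha grid (2 d.p.).
_ALPHA_SWEEP = {
    "User 1": (2.86, 2.66, 2.54, 2.38, 2.13, 1.92, 1.58, 1.32),
    "User 4": (2.76, 2.50, 2.38, 2.25, 2.13, 2.06, 2.02, 2.00),
    "User 7": (1.67, 1.29, 1.10, 0.88, 0.62, 0.45, 0.26, 0.16),
    "User 10": (1.73, 1.40, 1.22, 1.00, 0.72, 0.53, 0.30, 0.17),
    "User 12": (2.97, 2.94, 2.91, 2.88, 2.82, 2.77, 2.67, 2.59),
}

# Conjunctive (alpha = 3) level vectors of the 12-user sample, F1..F6.
_COHORT_LEVELS = {
    "User 1": (1.58, 2.51, 2.22, 1.06, 0.88, 1.82),
    "User 2": (2.05, 2.51, 1.07, 1.07, 1.79, 2.63),
    "User 3": (1.76, 3.00, 3.00, 1.54, 3.00, 1.36),
    "User 4": (2.02, 2.51, 2.06, 2.01, 2.47, 2.63),
    "User 5": (2.42, 3.00, 1.22, 2.51, 1.88, 3.00),
    "User 6": (3.00, 1.58, 2.51, 3.00, 3.00, 1.36),
    "User 7": (0.26, 1.24, 0.58, 0.58, 0.34, 1.65),
    "User 8": (3.00, 3.00, 2.51, 3.00, 2.70, 1.71),
    "User 9": (2.42, 2.22, 3.00, 2.51, 3.00, 1.39),
    "User 10": (0.30, 3.00, 1.22, 0.28, 0.21, 0.57),
    "User 11": (1.26, 1.58, 0.00, 0.52, 0.71, 0.71),
    "User 12": (2.67, 1.58, 2.06, 2.51, 2.30, 2.00),
}

# Marginal utilities of User 3 over the 7-activity sample (2 d.p.).
_WORKED_MARGINALS = {
    "R1A1": (2.24, 0.00, 0.00, 2.46, 0.00, -1.64),
    "R1A2": (-1.24, 0.00, 1.00, -1.46, 1.00, -1.64),
    "R2A1": (2.24, 1.00, 0.00, -1.46, 0.00, -1.64),
    "R6A2": (-1.24, 1.00, 0.00, 2.46, 0.00, -1.64),
    "R7A1": (-1.24, 0.00, 1.00, 2.46, 0.00, -1.64),
    "R8A1": (-1.24, 1.00, 0.00, -1.46, 1.00, -1.64),
    "R9A3": (2.24, 0.00, 0.00, -1.46, 0.00, 2.64),
}

# Overall utilities per user x activity (2 d.p.), activity order as below.
_SAMPLE_ACTIVITY_ORDER = ("R1A1", "R1A2", "R2A1", "R6A2", "R7A1", "R8A1", "R9A3")
_COHORT_OVERALL = {
    "User 1": (1.26, 0.37, -2.12, -1.08, 0.00, -0.71, -0.24),
    "User 2": (1.74, 2.26, -1.63, 0.33, 3.70, -1.11, -1.75),
    "User 3": (3.06, -2.34, 0.13, 0.58, 0.58, -2.34, 3.42),
    "User 4": (2.51, 1.49, 1.01, 1.03, 2.41, 0.11, 0.90),
    "User 5": (0.16, 4.33, -0.33, -1.00, 2.57, 0.76, -0.33),
    "User 6": (-1.07, -0.58, 1.78, 1.78, -0.58, 1.78, 2.22),
    "User 7": (-1.03, -1.18, -2.34, -2.99, -1.66, -2.51, -3.17),
    "User 8": (0.71, 1.49, 0.71, 0.71, 1.20, 1.01, 3.29),
    "User 9": (0.67, -0.97, 1.75, 1.08, -0.49, 0.59, 3.41),
    "User 10": (0.42, -1.27, -5.02, -4.98, -1.42, -4.84, -0.17),
    "User 11": (-2.78, -0.65, -4.89, -3.41, -0.26, -3.80, -3.16),
    "User 12": (-1.24, 1.22, 1.12, 1.28, 0.30, 2.19, 0.26),
}

# Published ranked orders (first proposed activity first).  The second
# entry of User 11's printed row is the misprint "RUA2"; from the utility
# values it can only denote R1A2, used here.
_COHORT_RANKINGS = {
    "User 1": ("R1A1", "R1A2", "R7A1", "R9A3", "R8A1", "R6A2", "R2A1"),
    "User 2": ("R7A1", "R1A2", "R1A1", "R6A2", "R8A1", "R2A1", "R9A3"),
    "User 3": ("R9A3", "R1A1", "R7A1", "R6A2", "R2A1", "R8A1", "R1A2"),
    "User 4": ("R1A1", "R7A1", "R1A2", "R6A2", "R2A1", "R9A3", "R8A1"),
    "User 5": ("R1A2", "R7A1", "R8A1", "R1A1", "R9A3", "R2A1", "R6A2"),
    "User 6": ("R9A3", "R8A1", "R6A2", "R2A1", "R7A1", "R1A2", "R1A1"),
    "User 7": ("R1A1", "R1A2", "R7A1", "R2A1", "R8A1", "R6A2", "R9A3"),
    "User 8": ("R9A3", "R1A2", "R7A1", "R8A1", "R6A2", "R2A1", "R1A1"),
    "User 9": ("R9A3", "R2A1", "R6A2", "R1A1", "R8A1", "R7A1", "R1A2"),
    "User 10": ("R1A1", "R9A3", "R1A2", "R7A1", "R8A1", "R6A2", "R2A1"),
    "User 11": ("R7A1", "R1A2", "R1A1", "R9A3", "R6A2", "R8A1", "R2A1"),
    "User 12": ("R8A1", "R6A2", "R1A2", "R2A1", "R7A1", "R9A3", "R1A1"),
}

#: Item ids of factor F1, the subject of the 5-user answer sample.
F1_ITEMS: tuple[str, ...] = tuple(f"q{n}" for n in DEFAULT_FACTOR_QUESTIONS["F1"])


def sample_catalogue() -> list[ImpactVector]:
    """The 7-activity worked-example catalogue as impact vectors."""
    return [ImpactVector(a, imp) for a, imp in SAMPLE_IMPACTS.items()]


def full_catalogue() -> list[ImpactVector]:
    """The complete 20-activity catalogue (+1 where an activity is listed
    as improving a factor, -1 otherwise)."""
    acts = sorted({a for v in FULL_CATALOGUE_FACTOR_ACTIVITIES.values() for a in v})
    return [
        ImpactVector(
            a,
            tuple(
                1 if a in FULL_CATALOGUE_FACTOR_ACTIVITIES[f] else -1
                for f in _FACTOR_ORDER
            ),
        )
        for a in acts
    ]


def reference_fixtures() -> dict:
    """The full reference bundle; see the module docstring for the index."""
    table6 = pd.DataFrame.from_dict(_ALPHA_SWEEP, orient="index", columns=list(ALPHA_GRID))
    table8 = pd.DataFrame.from_dict(_WORKED_MARGINALS, orient="index", columns=list(_FACTOR_ORDER))
    table9 = pd.DataFrame.from_dict(
        _COHORT_OVERALL, orient="index", columns=list(_SAMPLE_ACTIVITY_ORDER)
    )
    return {
        "factor_question_map": FactorQuestionMap(
            {
                f: tuple(f"q{n}" for n in nums)
                for f, nums in DEFAULT_FACTOR_QUESTIONS.items()
            }
        ),
        "factor_activity_map": dict(FULL_CATALOGUE_FACTOR_ACTIVITIES),
        "sample_impacts": dict(SAMPLE_IMPACTS),
        "f1_answer_sample": {
            u: dict(zip(F1_ITEMS, map(float, scores))) for u, scores in _F1_ANSWER_SAMPLE.items()
        },
        "alpha_sweep_levels": table6,
        "cohort_levels": {
            u: LevelVector(u, dict(zip(_FACTOR_ORDER, lv)), alpha=3.0)
            for u, lv in _COHORT_LEVELS.items()
        },
        "worked_marginals": table8,
        "cohort_overall": table9,
        "cohort_rankings": dict(_COHORT_RANKINGS),
    }
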