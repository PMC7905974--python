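"""Synthetic caregiver cohorts with known latent factor competence.

The generator draws, for each caregiver, a latent competence level per
PMH factor, then emits an answer sheet in which each item's score is the
rounded latent level of its factor plus a small random offset, truncated
to the admissible range [0..3]::

    score(item) = clamp(round(latent[factor]) + offset, 0, 3)

The offset distribution (default P(0)=0.6, P(-1)=P(+1)=0.2) models
answer noise: caregivers do not answer every item of a factor with
exactly the same frequency term.  Latent levels default to a uniform
draw over the grid {0, 1.5, 3} — weak / medium / strong profiles — which
exercises all three level-histogram bins.

A fraction of caregivers can additionally carry a "weak single item"
archetype: one factor is set to full competence but a single item of it
is answered at 0.  This is the signature case that separates conjunctive
aggregation (which flags the weakness) from the arithmetic mean (which
averages it away).

Known latent truth per caregiver is returned alongside the sheets so the
whole pipeline can be tested for recovery of the planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .questionnaire import FACTORS, AnswerSheet, QuestionnaireConfig

__all__ = ["CohortSpec", "generate_cohort"]

#: Default answer-noise model: score offset -> probability.
DEFAULT_NOISE: Mapping[int, float] = {-1: 0.2, 0: 0.6, 1: 0.2}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``latent_mode`` is ``"grid"`` (draw each factor level from
    ``latent_levels`` with probabilities ``latent_probs``, uniform if
    None) or ``"uniform"`` (continuous uniform on [0, 3]).
    ``weak_item_rate`` is the fraction of caregivers given the
    weak-single-item archetype.  The same ``seed`` always yields the
    identical cohort.
    """

    n_caregivers: int
    latent_mode: str = "grid"
    latent_levels: tuple[float, ...] = (0.0, 1.5, 3.0)
    latent_probs: tuple[float, ...] | None = None
    noise_offsets: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE)
    )
    weak_item_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_caregivers < 1:
            raise ValidationError("n_caregivers must be >= 1")
        if self.latent_mode not in ("grid", "uniform"):
            raise ValidationError(f"unknown latent_mode {self.latent_mode!r}")
        if any(not 0.0 <= v <= 3.0 for v in self.latent_levels):
            raise ValidationError("latent levels must lie in [0, 3]")
        if self.latent_probs is not None:
            if len(self.latent_probs) != len(self.latent_levels):
                raise ValidationError("latent_probs must match latent_levels")
            if abs(sum(self.latent_probs) - 1.0) > 1e-9:
                raise ValidationError("latent_probs must sum to 1")
        probs = list(self.noise_offsets.values())
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValidationError("noise offset probabilities must sum to 1")
        if any(int(o) != o for o in self.noise_offsets):
            raise ValidationError("noise offsets must be integers")
        if not 0.0 <= self.weak_item_rate <= 1.0:
            raise ValidationError("weak_item_rate must lie in [0, 1]")


def generate_cohort(
    spec: CohortSpec, config: QuestionnaireConfig
) -> tuple[list[AnswerSheet], pd.DataFrame]:
    """Generate answer sheets plus the latent truth table.

    Returns ``(sheets, truth)`` where ``truth`` has one row per caregiver
    with columns ``caregiver_id``, ``F1``..``F6`` (latent levels actually
    used, including any archetype override), ``weak_item`` (planted item
    id or empty string) and ``seed``.
    """
    rng = np.random.default_rng(spec.seed)
    fq_map = config.factor_map
    factors = [f for f in FACTORS if f in fq_map.by_factor]
    offsets = np.array(sorted(spec.noise_offsets), dtype=int)
    off_probs = np.array([spec.noise_offsets[o] for o in offsets], dtype=float)

    sheets: list[AnswerSheet] = []
    truth_rows: list[dict] = []
    for i in range(spec.n_caregivers):
        cid = f"synth{i + 1:04d}"
        if spec.latent_mode == "grid":
            latent = rng.choice(
                np.asarray(spec.latent_levels, dtype=float),
                size=len(factors),
                p=spec.latent_probs,
            )
        else:
            latent = rng.uniform(0.0, 3.0, size=len(factors))
        latent = dict(zip(factors, latent))

        weak_item = ""
        if spec.weak_item_rate and rng.random() < spec.weak_item_rate:
            f = factors[rng.integers(len(factors))]
            latent[f] = 3.0
            weak_item = str(rng.choice(list(fq_map.questions_for(f))))

        scores: dict[str, float] = {}
        for f in factors:
            base = int(round(latent[f]))
            for q in fq_map.questions_for(f):
                off = int(rng.choice(offsets, p=off_probs))
                scores[q] = float(np.clip(base + off, 0, 3))
        if weak_item:
            scores[weak_item] = 0.0

        sheets.append(AnswerSheet(cid, scores))
        truth_rows.append(
            {"caregiver_id": cid, **latent, "weak_item": weak_item, "seed": spec.seed}
        )
    return sheets, pd.DataFrame(truth_rows)
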