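"""File formats and the batch pipeline.

Conventions: UTF-8 CSV with a mandatory header row, comma separator,
"." decimal point.  Numeric artifacts are written at full ``repr``
precision so that write-then-read round-trips bit-identically; rounding
happens only when tables are displayed.  Any Unicode minus signs in
inputs are normalized to ASCII.

Formats
-------
questionnaire (YAML/JSON)
    ``{"items": [{"id": "q1", "factor": "F2", "polarity": "negative"}, ...]}``
answers (CSV)
    ``caregiver_id, q1..q39`` — numeric scores in [0, 3], or the four
    literal frequency terms in raw mode.
levels (CSV)
    ``caregiver_id, F1..F6``.
catalogue (JSON or CSV)
    per activity: ``activity_id`` and the six factor impacts (+1/-1).
plan (CSV)
    ``caregiver_id, rank, activity_id, overall_utility, g_F1..g_F6``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, ValidationError
from .levels import DEFAULT_ALPHA, LevelVector, compute_level_vector
from .questionnaire import (
    FACTORS,
    AnswerSheet,
    Question,
    QuestionnaireConfig,
    score_sheet,
)
from .utility import ImpactVector, RankedPlan, UtilityParams, rank_for_levels

__all__ = [
    "load_questionnaire",
    "save_questionnaire",
    "read_answers_csv",
    "write_answers_csv",
    "read_levels_csv",
    "write_levels_csv",
    "load_catalogue",
    "save_catalogue",
    "write_plan_csv",
    "RunConfig",
    "run_pipeline",
]

_MINUS = "−"  # unicode minus, as typeset in some source tables


def _normalize_cell(v):
    if isinstance(v, str):
        return v.replace(_MINUS, "-").strip()
    return v


def load_questionnaire(path: str | Path) -> QuestionnaireConfig:
    """Load a questionnaire configuration from YAML or JSON."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict) or "items" not in data:
        raise ConfigurationError(f"{path}: expected a mapping with an 'items' list")
    questions = []
    for entry in data["items"]:
        try:
            questions.append(
                Question(
                    id=str(entry["id"]),
                    factor=str(entry["factor"]),
                    polarity=str(entry.get("polarity", "positive")),
                )
            )
        except KeyError as e:
            raise ConfigurationError(f"{path}: item missing field {e}") from None
    return QuestionnaireConfig(tuple(questions))


def save_questionnaire(config: QuestionnaireConfig, path: str | Path) -> None:
    path = Path(path)
    data = {
        "items": [
            {"id": q.id, "factor": q.factor, "polarity": q.polarity}
            for q in config.questions
        ]
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


def read_answers_csv(
    path: str | Path,
    config: QuestionnaireConfig,
    raw: bool = False,
    *,
    validate: bool = True,
) -> list[AnswerSheet]:
    """Read per-caregiver answers; ``raw=True`` expects frequency terms
    and scores them per item polarity."""
    df = pd.read_csv(path, dtype=str).map(_normalize_cell)
    if df.empty:
        raise ValidationError(f"{path}: no caregiver rows")
    if "caregiver_id" not in df.columns:
        raise ValidationError(f"{path}: missing 'caregiver_id' column")
    item_cols = [c for c in df.columns if c != "caregiver_id"]
    sheets = []
    for _, row in df.iterrows():
        cid = row["caregiver_id"]
        answers = {c: row[c] for c in item_cols if pd.notna(row[c])}
        if raw:
            sheet = score_sheet(cid, answers, config)
        else:
            try:
                scores = {q: float(v) for q, v in answers.items()}
            except ValueError as e:
                raise ValidationError(f"{path}: caregiver {cid!r}: {e}") from None
            sheet = AnswerSheet(cid, scores)
            if validate:
                sheet.validate(config)
        sheets.append(sheet)
    return sheets


def write_answers_csv(
    sheets: Sequence[AnswerSheet], path: str | Path, item_ids: Sequence[str]
) -> None:
    rows = [
        {"caregiver_id": s.caregiver_id, **{q: s.scores[q] for q in item_ids if q in s.scores}}
        for s in sheets
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_levels_csv(levels: Iterable[LevelVector], path: str | Path) -> None:
    """Write level vectors at full precision (one row per caregiver)."""
    rows = [
        {"caregiver_id": lv.caregiver_id, **{f: lv.levels[f] for f in FACTORS}}
        for lv in levels
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_levels_csv(path: str | Path) -> list[LevelVector]:
    df = pd.read_csv(path, float_precision="round_trip").map(_normalize_cell)
    missing = [c for c in ("caregiver_id", *FACTORS) if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return [
        LevelVector(
            str(row["caregiver_id"]), {f: float(row[f]) for f in FACTORS}
        )
        for _, row in df.iterrows()
    ]


def load_catalogue(path: str | Path) -> list[ImpactVector]:
    """Load an activity catalogue from JSON (list of objects) or CSV."""
    path = Path(path)
    if path.suffix == ".json":
        entries = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(entries, list):
            raise ValidationError(f"{path}: expected a JSON list of activities")
    else:
        entries = pd.read_csv(path).map(_normalize_cell).to_dict(orient="records")
    catalogue = []
    for e in entries:
        try:
            catalogue.append(
                ImpactVector(
                    str(e["activity_id"]), tuple(int(e[f]) for f in FACTORS)
                )
            )
        except KeyError as k:
            raise ValidationError(f"{path}: activity entry missing field {k}") from None
    ids = [a.activity_id for a in catalogue]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate activity ids")
    return catalogue


def save_catalogue(catalogue: Sequence[ImpactVector], path: str | Path) -> None:
    path = Path(path)
    entries = [{"activity_id": a.activity_id, **a.as_dict()} for a in catalogue]
    if path.suffix == ".json":
        path.write_text(json.dumps(entries, indent=2), encoding="utf-8")
    else:
        pd.DataFrame(entries).to_csv(path, index=False)


def write_plan_csv(plans: Sequence[RankedPlan], path: str | Path) -> None:
    frames = []
    for p in plans:
        t = p.table.copy()
        t.insert(0, "caregiver_id", p.caregiver_id)
        t = t.rename(columns={f: f"g_{f}" for f in FACTORS})
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


@dataclass
class RunConfig:
    """Parameters and paths of one batch pipeline run.

    Defaults are the deployed calibration: conjunctive ``alpha = 3``,
    reward ``k_positive = 4`` > penalty ``k_negative = 3``, neutral
    threshold 2.5, display precision 2.
    """

    alpha: float = DEFAULT_ALPHA
    k_positive: float = 4.0
    k_negative: float = 3.0
    neutral_threshold: float = 2.5
    precision: int = 2
    tie_break: str = "id_desc"
    questionnaire_path: str | None = None
    answers_path: str | None = None
    levels_path: str | None = None
    catalogue_path: str | None = None
    out_dir: str = "."


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run levels -> marginal utilities -> ranking for a whole cohort.

    Caregiver levels come either from answer sheets (``answers_path`` +
    ``questionnaire_path``, aggregated at ``config.alpha``) or directly
    from ``levels_path``.  Writes ``levels.csv`` (when computed),
    ``plan.csv`` and a ``run_metadata.json`` sidecar recording every
    parameter and input digest needed to reproduce the run; returns the
    metadata dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = UtilityParams(
        config.k_positive, config.k_negative, config.neutral_threshold
    )

    inputs: dict[str, dict] = {}
    if config.levels_path:
        levels = read_levels_csv(config.levels_path)
        inputs["levels"] = {
            "path": str(config.levels_path),
            "sha256": _sha256(config.levels_path),
        }
    elif config.answers_path and config.questionnaire_path:
        questionnaire = load_questionnaire(config.questionnaire_path)
        sheets = read_answers_csv(config.answers_path, questionnaire)
        levels = [compute_level_vector(s, questionnaire, config.alpha) for s in sheets]
        write_levels_csv(levels, out / "levels.csv")
        inputs["questionnaire"] = {
            "path": str(config.questionnaire_path),
            "sha256": _sha256(config.questionnaire_path),
        }
        inputs["answers"] = {
            "path": str(config.answers_path),
            "sha256": _sha256(config.answers_path),
        }
    else:
        raise ValidationError(
            "need either levels_path, or answers_path plus questionnaire_path"
        )

    if not config.catalogue_path:
        raise ValidationError("catalogue_path is required")
    catalogue = load_catalogue(config.catalogue_path)
    inputs["catalogue"] = {
        "path": str(config.catalogue_path),
        "sha256": _sha256(config.catalogue_path),
    }

    plans = [
        rank_for_levels(lv, catalogue, params, config.tie_break) for lv in levels
    ]
    write_plan_csv(plans, out / "plan.csv")

    metadata = {
        "pmhrank_version": __version__,
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if not k.endswith("_path") and k != "out_dir"
        },
        "inputs": inputs,
        "n_caregivers": len(levels),
        "n_activities": len(catalogue),
        "outputs": sorted(
            p.name for p in (out / "levels.csv", out / "plan.csv") if p.exists()
        ),
    }
    (out / "run_metadata.json").write_text(
        json.dumps(metadata, indent=2), encoding="utf-8"
    )
    return metadata
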