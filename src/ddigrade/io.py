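"""Reading and writing the package's delimited-text tables and model bundles.

Tables are plain CSV/TSV (delimiter sniffed from the extension):

* drug table: ``drug_id,name,role,components[,arv_class]`` — the
  components cell joins one SMILES per active component with ``;``;
* pair table: ``arv_id,comed_id,grade`` — grade as a case-insensitive
  name (Green/Yellow/Amber/Red) or the integer code 0-3;
* predictions: ``arv_id,comed_id,p_green,p_yellow,p_amber,p_red,predicted``.

Row-level problems (bad SMILES, dangling ids, duplicate pairs, unknown
grade tokens) are collected per row and raised together so one bad row
never hides the others.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

import joblib
import pandas as pd
import yaml

from .grades import GRADE_ORDER, GradeLabel
from .records import (
    COMPONENT_SEPARATOR,
    DrugRecord,
    InvalidSmilesError,
    LabeledPair,
    PredictionRecord,
    RunConfig,
)

logger = logging.getLogger(__name__)

#: bumped whenever the persisted bundle layout changes
BUNDLE_FORMAT_VERSION = 1


class TableError(ValueError):
    """One or more rows of a delimited table failed validation.

    `row_errors` maps 1-based data-row numbers to messages.
    """

    def __init__(self, path, row_errors: dict[int, str]):
        self.path = path
        self.row_errors = dict(row_errors)
        lines = "; ".join(f"row {r}: {m}" for r, m in sorted(row_errors.items()))
        super().__init__(f"{path}: {lines}")


class BundleError(RuntimeError):
    """A persisted model bundle is unreadable or incompatible."""


def _delimiter(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_drug_table(path) -> list[DrugRecord]:
    """Load and validate a drug table.

    An unreadable file is fatal; invalid rows raise TableError listing
    every offending row and its first bad SMILES.
    """
    df = pd.read_csv(path, sep=_delimiter(path), dtype=str).fillna("")
    required = {"drug_id", "name", "role", "components"}
    missing = required - set(df.columns)
    if missing:
        raise TableError(path, {0: f"missing columns {sorted(missing)}"})

    records: list[DrugRecord] = []
    errors: dict[int, str] = {}
    seen: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        drug_id = row.drug_id.strip()
        if drug_id in seen:
            errors[i] = f"duplicate drug_id {drug_id!r} (first at row {seen[drug_id]})"
            continue
        seen[drug_id] = i
        components = tuple(
            s.strip() for s in row.components.split(COMPONENT_SEPARATOR) if s.strip()
        )
        arv_class = getattr(row, "arv_class", "") or None
        try:
            records.append(
                DrugRecord(
                    drug_id=drug_id,
                    name=row.name,
                    role=row.role.strip(),
                    components=components,
                    arv_class=arv_class,
                )
            )
        except (InvalidSmilesError, ValueError) as exc:
            errors[i] = str(exc)
    if errors:
        raise TableError(path, errors)
    logger.info("read %d drug records from %s", len(records), path)
    return records


def write_drug_table(records: list[DrugRecord], path) -> None:
    df = pd.DataFrame(
        {
            "drug_id": [r.drug_id for r in records],
            "name": [r.name for r in records],
            "role": [r.role for r in records],
            "components": [COMPONENT_SEPARATOR.join(r.components) for r in records],
            "arv_class": [r.arv_class or "" for r in records],
        }
    )
    df.to_csv(path, sep=_delimiter(path), index=False)


def read_pair_table(path, drugs: list[DrugRecord]) -> list[LabeledPair]:
    """Load a graded pair table, resolving ids against `drugs`.

    Dangling drug ids, duplicate (arv, comed) keys and unknown grade
    tokens are row-level errors, reported together.
    """
    df = pd.read_csv(path, sep=_delimiter(path), dtype=str).fillna("")
    required = {"arv_id", "comed_id", "grade"}
    missing = required - set(df.columns)
    if missing:
        raise TableError(path, {0: f"missing columns {sorted(missing)}"})

    known = {d.drug_id for d in drugs}
    pairs: list[LabeledPair] = []
    errors: dict[int, str] = {}
    first_seen: dict[tuple[str, str], int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        arv_id, comed_id = row.arv_id.strip(), row.comed_id.strip()
        key = (arv_id, comed_id)
        if key in first_seen:
            errors[i] = f"duplicate pair {key} (first at row {first_seen[key]})"
            continue
        first_seen[key] = i
        dangling = [d for d in key if d not in known]
        if dangling:
            errors[i] = f"unknown drug id(s) {dangling}"
            continue
        try:
            grade = GradeLabel.from_token(row.grade)
        except ValueError as exc:
            errors[i] = str(exc)
            continue
        pairs.append(LabeledPair(arv_id=arv_id, comed_id=comed_id, grade=grade))
    if errors:
        raise TableError(path, errors)
    counts = Counter(p.grade for p in pairs)
    logger.info(
        "read %d pairs from %s (per class: %s)",
        len(pairs),
        path,
        {g.display: counts.get(g, 0) for g in GRADE_ORDER},
    )
    return pairs


def write_pair_table(pairs: list[LabeledPair], path) -> None:
    df = pd.DataFrame(
        {
            "arv_id": [p.arv_id for p in pairs],
            "comed_id": [p.comed_id for p in pairs],
            "grade": [p.grade.display for p in pairs],
        }
    )
    df.to_csv(path, sep=_delimiter(path), index=False)


def write_predictions(predictions: list[PredictionRecord], path) -> None:
    rows = []
    for p in predictions:
        rows.append(
            {
                "arv_id": p.arv_id,
                "comed_id": p.comed_id,
                "p_green": f"{p.probabilities[0]:.9f}",
                "p_yellow": f"{p.probabilities[1]:.9f}",
                "p_amber": f"{p.probabilities[2]:.9f}",
                "p_red": f"{p.probabilities[3]:.9f}",
                "predicted": p.predicted.display,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def write_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def save_model(model, path, config: RunConfig | None = None) -> None:
    """Persist a trained classifier (with its featurizer snapshot) to one file."""
    bundle = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "config": (config or RunConfig()).to_dict(),
        "model": model,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(bundle, path)


def load_model(path):
    """Load a persisted classifier; returns (model, RunConfig).

    Raises BundleError for truncated/corrupt files or version mismatches.
    """
    try:
        bundle = joblib.load(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # joblib/pickle raise a zoo of types on corruption
        raise BundleError(f"corrupt model bundle {path}: {exc}") from exc
    if not isinstance(bundle, dict) or "format_version" not in bundle:
        raise BundleError(f"{path} is not a model bundle")
    if bundle["format_version"] != BUNDLE_FORMAT_VERSION:
        raise BundleError(
            f"bundle format {bundle['format_version']} != "
            f"supported {BUNDLE_FORMAT_VERSION}"
        )
    return bundle["model"], RunConfig.from_dict(bundle["config"])
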