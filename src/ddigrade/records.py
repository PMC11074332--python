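"""Core record types: drugs, labeled pairs, predictions, run configuration."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .grades import GradeLabel, N_GRADES

#: separator between component SMILES inside one table cell (one row per
#: marketed product, so a fixed-dose combination stays a single record)
COMPONENT_SEPARATOR = ";"

ROLE_ARV = "ARV"
ROLE_COMEDICATION = "comedication"
VALID_ROLES = (ROLE_ARV, ROLE_COMEDICATION)


class InvalidSmilesError(ValueError):
    """A SMILES string did not parse to a valid molecule."""


def parse_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"invalid SMILES: {smiles!r}")
    return mol


@dataclass(frozen=True)
class DrugRecord:
    """One marketed drug product.

    Fixed-dose combinations carry one SMILES per active component, in
    `components`; single agents carry exactly one.
    """

    drug_id: str
    name: str
    role: str
    components: tuple[str, ...]
    arv_class: str | None = None

    def __post_init__(self):
        if not self.components:
            raise ValueError(f"drug {self.drug_id!r}: no components")
        if self.role not in VALID_ROLES:
            raise ValueError(
                f"drug {self.drug_id!r}: role must be one of {VALID_ROLES}, "
                f"got {self.role!r}"
            )
        for smi in self.components:
            parse_smiles(smi)

    @property
    def is_combination(self) -> bool:
        return len(self.components) >= 2


@dataclass(frozen=True)
class LabeledPair:
    """A graded (ARV, comedication) pair; orientation is fixed ARV-first."""

    arv_id: str
    comed_id: str
    grade: GradeLabel


@dataclass(frozen=True)
class PredictionRecord:
    arv_id: str
    comed_id: str
    probabilities: tuple[float, float, float, float]
    predicted: GradeLabel

    def __post_init__(self):
        total = float(np.sum(self.probabilities))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, expected 1")
        if len(self.probabilities) != N_GRADES:
            raise ValueError("expected one probability per grade")


@dataclass
class RunConfig:
    """All knobs of a run; the defaults reproduce the published settings."""

    fingerprint_radius: int = 2
    fingerprint_bits: int = 1024
    featurizer_backend: str = "similarity"  # similarity | embedding-stub
    ensemble_size: int = 5
    network_preset: str = "sim"  # see ensemble.NETWORK_PRESETS
    seed: int = 0
    cv_folds: int = 5
    holdout_arv_count: int = 8
    train_both_orientations: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
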