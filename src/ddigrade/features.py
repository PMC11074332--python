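"""Structure-based featurization of drug pairs.

A drug is encoded as a Morgan (ECFP-style) circular fingerprint: atom
environments up to a bond radius (default 2) hashed to a fixed-length
binary vector (default 1024 bits).  A fixed-dose combination is the
bitwise union of its components' fingerprints — the only reading of
"merge while keeping the fingerprint size" that preserves length.

The learned representation of "similar structure implies similar
interactions" is the *similarity profile*: the vector of Tanimoto
coefficients of one drug against an ordered reference panel of drugs.
A pair feature concatenates the two profiles, ARV half first.

An alternative backend produces a deterministic 768-dimensional
pseudo-embedding per drug (a fixed seeded random projection of the
merged fingerprint), mirroring the dimensionality of transformer-based
molecular embedders without any external weights; a real embedder can
be plugged in behind the same transformer contract.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin

from .records import DrugRecord, parse_smiles

logger = logging.getLogger(__name__)

EMBEDDING_DIM = 768
#: seed of the frozen fingerprint->embedding projection; a constant, not a
#: run seed, so the same molecule always maps to the same embedding
_EMBED_PROJECTION_SEED = 768


def morgan_fingerprint(
    components: list[str] | tuple[str, ...],
    radius: int = 2,
    n_bits: int = 1024,
) -> np.ndarray:
    """Fingerprint of a drug product (all components merged by union).

    Returns a uint8 0/1 vector of length `n_bits`.  Invalid SMILES raise
    InvalidSmilesError naming the offending string.
    """
    if isinstance(components, str):
        components = [components]
    if not components:
        raise ValueError("no components to fingerprint")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    parts = []
    for smi in components:
        mol = parse_smiles(smi)
        parts.append(np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8))
    return merge_combination(parts)


def merge_combination(fps: list[np.ndarray]) -> np.ndarray:
    """Bitwise union of component fingerprints (commutative, associative,
    idempotent); all inputs must share one length."""
    if not fps:
        raise ValueError("no fingerprints to merge")
    lengths = {len(fp) for fp in fps}
    if len(lengths) != 1:
        raise ValueError(f"mixed fingerprint lengths {sorted(lengths)}")
    out = fps[0].astype(np.uint8, copy=True)
    for fp in fps[1:]:
        np.bitwise_or(out, fp.astype(np.uint8), out=out)
    return out


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a & b| / |a | b| of two binary vectors.

    Two all-zero vectors are defined as similarity 0.0 (with a warning);
    the 0/0 case cannot arise for valid molecules.
    """
    a = np.asarray(a, dtype=np.uint8)
    b = np.asarray(b, dtype=np.uint8)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.bitwise_or(a, b).sum())
    if union == 0:
        warnings.warn("tanimoto of two empty fingerprints defined as 0.0")
        return 0.0
    inter = int(np.bitwise_and(a, b).sum())
    return inter / union


@dataclass(frozen=True)
class ReferencePanel:
    """Frozen, ordered list of (drug_id, fingerprint) a profile is scored
    against.  Order is fixed at build time (lexicographic by drug_id) and
    persisted with any trained model, because weights depend on it."""

    drug_ids: tuple[str, ...]
    fingerprints: np.ndarray  # (R, n_bits) uint8

    def __post_init__(self):
        if len(self.drug_ids) != len(set(self.drug_ids)):
            raise ValueError("duplicate drug ids in panel")
        if self.fingerprints.shape[0] != len(self.drug_ids):
            raise ValueError("panel ids and fingerprints disagree in length")

    @property
    def size(self) -> int:
        return len(self.drug_ids)

    @property
    def n_bits(self) -> int:
        return self.fingerprints.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Panel as a table with hex-encoded bit strings (CSV-safe)."""
        hexes = [np.packbits(fp).tobytes().hex() for fp in self.fingerprints]
        return pd.DataFrame({"drug_id": self.drug_ids, "fingerprint_hex": hexes})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_bits: int) -> "ReferencePanel":
        fps = [
            np.unpackbits(np.frombuffer(bytes.fromhex(h), dtype=np.uint8))[:n_bits]
            for h in df["fingerprint_hex"]
        ]
        return cls(tuple(df["drug_id"]), np.asarray(fps, dtype=np.uint8))


def build_reference_panel(
    drugs: list[DrugRecord], radius: int = 2, n_bits: int = 1024
) -> ReferencePanel:
    """Fingerprint every drug and freeze the panel, ordered by drug_id."""
    if not drugs:
        raise ValueError("cannot build a reference panel from zero drugs")
    ordered = sorted(drugs, key=lambda d: d.drug_id)
    fps = np.asarray(
        [morgan_fingerprint(d.components, radius, n_bits) for d in ordered],
        dtype=np.uint8,
    )
    return ReferencePanel(tuple(d.drug_id for d in ordered), fps)


def similarity_profile(fp: np.ndarray, panel: ReferencePanel) -> np.ndarray:
    """Tanimoto of `fp` against every panel member, in panel order."""
    fp = np.asarray(fp, dtype=np.uint8)
    if fp.shape[0] != panel.n_bits:
        raise ValueError(
            f"fingerprint length {fp.shape[0]} != panel bits {panel.n_bits}"
        )
    inter = np.bitwise_and(panel.fingerprints, fp[None, :]).sum(axis=1)
    union = np.bitwise_or(panel.fingerprints, fp[None, :]).sum(axis=1)
    out = np.zeros(panel.size, dtype=float)
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    return out


def embed_smiles_stub(
    components: list[str] | tuple[str, ...],
    radius: int = 2,
    n_bits: int = 1024,
) -> np.ndarray:
    """Deterministic 768-d pseudo-embedding of a drug product.

    The merged fingerprint is projected through a frozen Gaussian matrix
    (seeded once, globally) and squashed with tanh, so identical molecules
    map to identical embeddings and similar fingerprints to nearby ones.
    This is a synthetic stand-in with the same shape contract as a
    transformer embedder; it carries purely structural information.
    """
    fp = morgan_fingerprint(components, radius, n_bits)
    rng = np.random.default_rng(_EMBED_PROJECTION_SEED)
    proj = rng.standard_normal((n_bits, EMBEDDING_DIM)) / np.sqrt(n_bits)
    return np.tanh(fp.astype(float) @ proj)


def _drug_lookup(drugs: list[DrugRecord]) -> dict[str, DrugRecord]:
    return {d.drug_id: d for d in drugs}


class SimilarityPairFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer: (arv_id, comed_id) pairs -> concatenated similarity profiles.

    Parameters
    ----------
    drugs : list of DrugRecord
        The drug universe; fit() freezes the reference panel over it
        (every drug record, single agents and combinations alike).
    radius, n_bits : fingerprint settings (defaults 2 / 1024).

    After fit: ``panel_`` (ReferencePanel), ``n_features_out_`` (= 2R).
    transform accepts an (n, 2) array-like of [arv_id, comed_id] or a
    DataFrame with those columns, and returns an (n, 2R) float matrix,
    ARV half first.
    """

    backend = "similarity"

    def __init__(self, drugs=None, radius: int = 2, n_bits: int = 1024):
        self.drugs = drugs
        self.radius = radius
        self.n_bits = n_bits

    def fit(self, X=None, y=None):
        if not self.drugs:
            raise ValueError("SimilarityPairFeaturizer needs a drug universe")
        self.panel_ = build_reference_panel(self.drugs, self.radius, self.n_bits)
        self._lookup = _drug_lookup(self.drugs)
        self._profile_cache: dict[str, np.ndarray] = {}
        self.n_features_out_ = 2 * self.panel_.size
        logger.info(
            "similarity featurizer: panel R=%d, pair feature length %d",
            self.panel_.size,
            self.n_features_out_,
        )
        return self

    def _profile_for(self, drug_id: str) -> np.ndarray:
        cached = self._profile_cache.get(drug_id)
        if cached is None:
            drug = self._lookup.get(drug_id)
            if drug is None:
                raise KeyError(f"unknown drug id {drug_id!r}")
            fp = morgan_fingerprint(drug.components, self.radius, self.n_bits)
            cached = similarity_profile(fp, self.panel_)
            self._profile_cache[drug_id] = cached
        return cached

    def transform(self, X) -> np.ndarray:
        ids = _pair_ids(X)
        return np.asarray(
            [
                np.concatenate([self._profile_for(a), self._profile_for(c)])
                for a, c in ids
            ]
        )


class StubEmbeddingPairFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer: pairs -> concatenated 768-d pseudo-embeddings (2x768)."""

    backend = "embedding-stub"

    def __init__(self, drugs=None, radius: int = 2, n_bits: int = 1024):
        self.drugs = drugs
        self.radius = radius
        self.n_bits = n_bits

    def fit(self, X=None, y=None):
        if not self.drugs:
            raise ValueError("StubEmbeddingPairFeaturizer needs a drug universe")
        self._lookup = _drug_lookup(self.drugs)
        self._cache: dict[str, np.ndarray] = {}
        self.n_features_out_ = 2 * EMBEDDING_DIM
        return self

    def _embedding_for(self, drug_id: str) -> np.ndarray:
        cached = self._cache.get(drug_id)
        if cached is None:
            drug = self._lookup.get(drug_id)
            if drug is None:
                raise KeyError(f"unknown drug id {drug_id!r}")
            cached = embed_smiles_stub(drug.components, self.radius, self.n_bits)
            self._cache[drug_id] = cached
        return cached

    def transform(self, X) -> np.ndarray:
        ids = _pair_ids(X)
        return np.asarray(
            [
                np.concatenate([self._embedding_for(a), self._embedding_for(c)])
                for a, c in ids
            ]
        )


FEATURIZER_BACKENDS = {
    "similarity": SimilarityPairFeaturizer,
    "embedding-stub": StubEmbeddingPairFeaturizer,
}


def make_featurizer(backend: str, drugs, radius: int = 2, n_bits: int = 1024):
    try:
        cls = FEATURIZER_BACKENDS[backend]
    except KeyError:
        raise ValueError(
            f"unknown featurizer backend {backend!r}; "
            f"choose from {sorted(FEATURIZER_BACKENDS)}"
        ) from None
    return cls(drugs=drugs, radius=radius, n_bits=n_bits)


def pair_features(arv, comed, featurizer) -> np.ndarray:
    """Feature vector of one (ARV, comedication) pair via a fitted featurizer."""
    arv_id = arv.drug_id if isinstance(arv, DrugRecord) else arv
    comed_id = comed.drug_id if isinstance(comed, DrugRecord) else comed
    return featurizer.transform([(arv_id, comed_id)])[0]


def _pair_ids(X) -> list[tuple[str, str]]:
    if isinstance(X, pd.DataFrame):
        return list(zip(X["arv_id"], X["comed_id"]))
    out = []
    for row in X:
        first, second = (getattr(row, "arv_id", None), getattr(row, "comed_id", None))
        if first is None:
            first, second = row[0], row[1]
        out.append((str(first), str(second)))
    return out
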