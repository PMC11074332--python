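"""Synthetic drug universes and graded pair tables.

The generator produces download-free datasets with the statistical
structure the method assumes:

* chemically valid SMILES from a small enumeration grammar (aromatic /
  heteroaromatic / aliphatic scaffolds crossed with substituent sets),
  including multi-component fixed-dose combinations;
* ARV / comedication roles and synthetic ARV classes;
* a heavily skewed grade distribution (default 72 / 7.6 / 16 / 4.4 %),
  realized *exactly* via quantile quotas rather than sampling;
* a tunable structure-to-grade signal: each drug carries a latent
  pharmacology vector that blends a fixed random projection of its
  fingerprint (weight ``signal``) with per-drug noise (weight
  ``1 - signal``); a pair's interaction score is a fixed bilinear form
  of the two latents, cut into grades at empirical quantiles.  At
  ``signal=1`` grades are a deterministic function of structure, so
  structurally similar drugs share interaction patterns; at
  ``signal=0`` grades are structure-independent and no classifier can
  beat chance on unseen drugs.

The "database-shape" preset reproduces the published bookkeeping: a
drug-anchored hold-out of 8 ARVs whose pair stratum is trimmed to 5,103
pairs graded exactly {3221, 358, 1146, 378}, a training stratum of
25,039 pairs at the global skew, and hence 30,142 pairs in total.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .features import morgan_fingerprint
from .grades import GRADE_ORDER, GradeLabel, N_GRADES
from .io import write_drug_table, write_pair_table
from .records import ROLE_ARV, ROLE_COMEDICATION, DrugRecord, LabeledPair

logger = logging.getLogger(__name__)

#: default grade skew, matching the shape of the real clinical database
DEFAULT_PROPORTIONS = (0.72, 0.076, 0.16, 0.044)

ARV_CLASSES = ("EntryInhibitor", "INSTI", "NNRTI", "NRTI", "PI")

#: small scaffolds give a diverse chemical space
_SCAFFOLDS = (
    "c1ccc({0})c({1})c1",
    "c1cc({0})ccc1{1}",
    "c1cc({0})ncc1{1}",
    "c1csc({0})c1{1}",
    "c1coc({0})c1{1}",
    "C({0})({1})c1ccccc1",
    "O=C(O{0})c1ccc({1})cc1",
    "CC({0})CC({1})O",
    "c1ccc2c(c1)oc({0})c2{1}",
    "C1CCC(CC1)({0}){1}",
)

#: large amide scaffolds whose slot {0} extends a peripheral alkoxy
#: tail: within one (scaffold, {1}) series the chain homologs are
#: near-identical analogs (Tanimoto > 0.9, often 1.0) — the
#: analog-series structure real comedication lists have
_ANALOG_SCAFFOLDS = (
    "CC(=O)Nc1ccc(OCCC{0})cc1C(=O)NCCc1ccc({1})cc1",
    "O=C(NCc1ccco1)c1cc({1})ccc1OCCC{0}",
    "CN1CCN(CC1)c1ccc(cc1)C(=O)Nc1ccc(OCCC{0})cc1{1}",
    "OC(=O)C1CCN(CC1)C(=O)COc1ccc2cc(OCCC{0})ccc2c1{1}",
)

_CHAIN_TAILS = ("C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC")

_SUBSTITUENTS = (
    "C", "CC", "CCC", "CCCC", "O", "OC", "OCC", "N", "NC", "N(C)C",
    "F", "Cl", "Br", "C#N", "C(F)(F)F", "C(=O)O", "C(=O)OC", "C(=O)N",
    "CO", "CCO",
)


@dataclass
class DatasetConfig:
    """Study conditions of one synthetic dataset.

    The default geometry (125 ARVs x 40 comedications = 5,000 pairs)
    favors many distinct anchor drugs, which is what unseen-drug
    generalization experiments need at this size; the database-shape
    preset instead mirrors the real database's few-ARVs / many-comeds
    shape.
    """

    n_arvs: int = 125
    n_comedications: int = 40
    combo_fraction: float = 0.2  # fraction of ARVs that are combinations
    grade_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    signal: float = 1.0  # structure->grade signal strength in [0, 1]
    latent_dim: int = 16
    seed: int = 0
    holdout_arv_count: int = 8
    #: optional exact per-grade counts for the held-out-ARV stratum
    exact_test_counts: tuple[int, ...] | None = None
    #: optional trimmed size of the training stratum
    train_size: int | None = None

    def __post_init__(self):
        if abs(sum(self.grade_proportions) - 1.0) > 1e-9:
            raise ValueError("grade proportions must sum to 1")
        if len(self.grade_proportions) != N_GRADES:
            raise ValueError(f"need {N_GRADES} grade proportions")
        if not 0.0 <= self.signal <= 1.0:
            raise ValueError("signal must lie in [0, 1]")
        if min(self.n_arvs, self.n_comedications, self.latent_dim) <= 0:
            raise ValueError("all counts must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def database_shape_config(seed: int = 0) -> DatasetConfig:
    """Preset reproducing the published split bookkeeping exactly."""
    return DatasetConfig(
        n_arvs=44,
        n_comedications=700,
        seed=seed,
        holdout_arv_count=8,
        exact_test_counts=(3221, 358, 1146, 378),
        train_size=25039,
    )


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def enumerate_smiles(limit: int | None = None) -> list[str]:
    """Deterministic enumeration of unique, valid, canonical SMILES."""
    seen: set[str] = set()
    out: list[str] = []
    analog_slot0 = _SUBSTITUENTS + tuple(
        c for c in _CHAIN_TAILS if c not in _SUBSTITUENTS
    )
    families = [(_SCAFFOLDS, _SUBSTITUENTS), (_ANALOG_SCAFFOLDS, analog_slot0)]
    for scaffolds, slot0_options in families:
        for scaffold in scaffolds:
            for s0 in slot0_options:
                for s1 in _SUBSTITUENTS:
                    smi = scaffold.format(s0, s1)
                    mol = Chem.MolFromSmiles(smi)
                    if mol is None:
                        continue
                    canonical = Chem.MolToSmiles(mol)
                    if canonical in seen:
                        continue
                    seen.add(canonical)
                    out.append(canonical)
                    if limit is not None and len(out) >= limit:
                        return out
    return out


def generate_drug_universe(config: DatasetConfig) -> list[DrugRecord]:
    """Seeded synthetic drug universe: single agents plus combination ARVs.

    Combination ARVs take 2-3 component molecules from a reserved pool;
    the number of combinations is round-half-up of
    ``combo_fraction * n_arvs``.
    """
    n_combo = int(np.floor(config.combo_fraction * config.n_arvs + 0.5))
    n_single = config.n_arvs - n_combo + config.n_comedications
    rng = _rng(config.seed, 1)
    # extra molecules reserved as combination components
    n_needed = n_single + 3 * n_combo
    pool = enumerate_smiles()
    if n_needed > len(pool):
        raise ValueError(
            f"requested {n_needed} molecules but the grammar "
            f"enumerates only {len(pool)}"
        )
    chosen = [pool[i] for i in rng.permutation(len(pool))[:n_needed]]
    component_pool = chosen[n_single:]

    records: list[DrugRecord] = []
    width = len(str(config.n_arvs + config.n_comedications))
    pool_cursor = 0
    for i in range(config.n_arvs):
        drug_id = f"arv{i:0{width}d}"
        arv_class = ARV_CLASSES[i % len(ARV_CLASSES)]
        if i < n_combo:
            n_parts = 2 + int(rng.integers(0, 2))  # 2 or 3 components
            components = tuple(
                component_pool[pool_cursor + j] for j in range(n_parts)
            )
            pool_cursor += n_parts
        else:
            components = (chosen[i - n_combo],)
        records.append(
            DrugRecord(
                drug_id=drug_id,
                name=f"ARV-{i}",
                role=ROLE_ARV,
                components=components,
                arv_class=arv_class,
            )
        )
    offset = config.n_arvs - n_combo
    for i in range(config.n_comedications):
        records.append(
            DrugRecord(
                drug_id=f"com{i:0{width}d}",
                name=f"Comedication-{i}",
                role=ROLE_COMEDICATION,
                components=(chosen[offset + i],),
            )
        )
    logger.info(
        "generated %d drugs (%d ARVs incl. %d combinations, %d comedications)",
        len(records), config.n_arvs, n_combo, config.n_comedications,
    )
    return records


def latent_pharmacology(
    drugs: list[DrugRecord], config: DatasetConfig
) -> dict[str, np.ndarray]:
    """Per-drug latent vectors blending structure and noise.

    latent = signal * standardize(P @ fp / sqrt(popcount)) + (1 - signal) * eps

    The projection P is fixed and seeded: its rows are the L2-normalized
    fingerprints of ``latent_dim`` seeded probe drugs drawn from the
    universe, so each structural coordinate is a cosine-style similarity
    to a probe — i.e. the latent lives in the same similarity geometry a
    Tanimoto profile measures, which is exactly the premise that
    structurally similar drugs share pharmacology.  Structural
    coordinates are standardized across the universe so the blend with
    unit-variance per-drug noise is balanced at every signal level.
    Deterministic given the drug list and config seed.
    """
    n_bits = 1024
    ordered = sorted(drugs, key=lambda d: d.drug_id)
    fps = {
        d.drug_id: morgan_fingerprint(d.components, n_bits=n_bits).astype(float)
        for d in ordered
    }
    probe_rng = _rng(config.seed, 2)
    ids = [d.drug_id for d in ordered]
    if len(ids) < config.latent_dim:
        raise ValueError("latent_dim exceeds the number of drugs")
    probe_ids = [ids[i] for i in probe_rng.permutation(len(ids))[:config.latent_dim]]
    proj = np.stack([fps[i] for i in probe_ids])
    proj /= np.sqrt(proj.sum(axis=1, keepdims=True))

    struct = np.stack(
        [proj @ fps[i] / np.sqrt(max(fps[i].sum(), 1.0)) for i in ids]
    )
    struct = (struct - struct.mean(axis=0)) / (struct.std(axis=0) + 1e-12)

    noise_rng = _rng(config.seed, 3)
    latents: dict[str, np.ndarray] = {}
    for row, drug_id in zip(struct, ids):
        noise = noise_rng.standard_normal(config.latent_dim)
        latents[drug_id] = config.signal * row + (1 - config.signal) * noise
    return latents


def quota_counts(n: int, proportions) -> list[int]:
    """Largest-remainder integer quotas for `n` items."""
    raw = np.asarray(proportions, dtype=float) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    return counts.tolist()


def _score_matrix(drugs, latents, config):
    """Raw interaction scores: a dense seeded bilinear form of the two
    latents, one row per ARV, one column per comedication (both in
    drug_id order)."""
    arvs = sorted((d for d in drugs if d.role == ROLE_ARV), key=lambda d: d.drug_id)
    comeds = sorted(
        (d for d in drugs if d.role == ROLE_COMEDICATION), key=lambda d: d.drug_id
    )
    bilinear = _rng(config.seed, 4).standard_normal(
        (config.latent_dim, config.latent_dim)
    ) / np.sqrt(config.latent_dim)
    U = np.stack([latents[d.drug_id] for d in arvs])
    V = np.stack([latents[d.drug_id] for d in comeds])
    return [d.drug_id for d in arvs], [d.drug_id for d in comeds], U @ bilinear @ V.T


def _standardize_columns(scores, reference_rows):
    """Standardize each comedication column by its location/scale over the
    reference ARV rows.  The per-comedication calibration makes grade ranks
    comparable across comedications and, with no structure signal, leaves
    an unseen ARV's grades exchangeable — chance-level by construction.
    Using only reference (training) rows keeps held-out rows from leaking
    into the calibration."""
    ref = scores[reference_rows]
    return (scores - ref.mean(axis=0)) / (ref.std(axis=0) + 1e-12)


def _score_pairs(drugs, latents, config, reference_arv_ids=None):
    """Column-calibrated scores flattened in (ARV, comedication) pair
    order; columns are standardized over `reference_arv_ids` (all ARVs
    when None)."""
    arv_ids, comed_ids, scores = _score_matrix(drugs, latents, config)
    if reference_arv_ids is None:
        rows = np.arange(len(arv_ids))
    else:
        reference = set(reference_arv_ids)
        rows = np.flatnonzero([a in reference for a in arv_ids])
    scores = _standardize_columns(scores, rows)
    pair_ids = [(a, c) for a in arv_ids for c in comed_ids]
    return pair_ids, scores.ravel()


def _grade_by_quota(pair_ids, scores, proportions) -> list[LabeledPair]:
    """Exact-quota grading: thresholds are empirical score quantiles, so
    realized counts match the target proportions up to largest-remainder
    rounding.  Lower scores map to milder grades."""
    counts = quota_counts(len(scores), proportions)
    order = np.argsort(scores, kind="stable")
    grades = np.empty(len(scores), dtype=int)
    start = 0
    for code, n in enumerate(counts):
        grades[order[start:start + n]] = code
        start += n
    return [
        LabeledPair(arv_id=a, comed_id=c, grade=GradeLabel(int(g)))
        for (a, c), g in zip(pair_ids, grades)
    ]


def grade_thresholds(scores, proportions) -> np.ndarray:
    """Three increasing cut points on the interaction score whose bins
    realize the target proportions on `scores` (empirical quantiles)."""
    cum = np.cumsum(np.asarray(proportions, dtype=float))[:-1]
    return np.quantile(np.asarray(scores, dtype=float), cum)


def _grade_by_thresholds(pair_ids, scores, thresholds) -> list[LabeledPair]:
    grades = np.searchsorted(thresholds, scores, side="right")
    return [
        LabeledPair(arv_id=a, comed_id=c, grade=GradeLabel(int(g)))
        for (a, c), g in zip(pair_ids, grades)
    ]


def grade_pairs(drugs: list[DrugRecord], config: DatasetConfig) -> list[LabeledPair]:
    """Grade every (ARV, comedication) pair at the target skew."""
    latents = latent_pharmacology(drugs, config)
    pair_ids, scores = _score_pairs(drugs, latents, config)
    return _grade_by_quota(pair_ids, scores, config.grade_proportions)


def structure_grade_agreement(
    drugs: list[DrugRecord],
    pairs: list[LabeledPair],
    similarity_threshold: float = 0.9,
    n_triples: int = 200,
    seed: int = 0,
) -> dict:
    """Counting oracle for the similarity premise.

    Samples triples (ARV, comed1, comed2) where the two comedications
    have fingerprint Tanimoto above `similarity_threshold`, and counts
    how often the two pairs (ARV, comed1) and (ARV, comed2) share a
    grade; compares against triples with randomly chosen comedication
    pairs.  With a strong structure signal the similar-comedication
    agreement rate should exceed the random-pair rate.
    """
    from .features import tanimoto

    grade_of = {(p.arv_id, p.comed_id): int(p.grade) for p in pairs}
    arv_ids = sorted({p.arv_id for p in pairs})
    comed_ids = sorted({p.comed_id for p in pairs})
    lookup = {d.drug_id: d for d in drugs}
    fps = {
        c: morgan_fingerprint(lookup[c].components) for c in comed_ids
    }
    similar = [
        (c1, c2)
        for i, c1 in enumerate(comed_ids)
        for c2 in comed_ids[i + 1:]
        if tanimoto(fps[c1], fps[c2]) > similarity_threshold
    ]
    if not similar:
        raise ValueError(
            f"no comedication pairs with Tanimoto > {similarity_threshold}"
        )
    rng = _rng(seed, 7)

    def agreement(comed_pairs) -> float:
        hits = total = 0
        for _ in range(n_triples):
            c1, c2 = comed_pairs[rng.integers(len(comed_pairs))]
            a = arv_ids[rng.integers(len(arv_ids))]
            g1, g2 = grade_of.get((a, c1)), grade_of.get((a, c2))
            if g1 is None or g2 is None:
                continue
            total += 1
            hits += g1 == g2
        return hits / total if total else float("nan")

    random_pairs = [
        (comed_ids[i], comed_ids[j])
        for i, j in zip(
            rng.integers(len(comed_ids), size=4 * n_triples),
            rng.integers(len(comed_ids), size=4 * n_triples),
        )
        if i != j
    ]
    return {
        "n_similar_pairs": len(similar),
        "similar_agreement": agreement(similar),
        "random_agreement": agreement(random_pairs),
    }


def select_holdout_arvs(drugs: list[DrugRecord], config: DatasetConfig) -> list[str]:
    """Seeded hold-out ARVs drawn round-robin across synthetic ARV classes,
    so every class is represented in the unseen-drug test set."""
    rng = _rng(config.seed, 5)
    by_class: dict[str, list[str]] = {}
    for d in sorted(drugs, key=lambda d: d.drug_id):
        if d.role == ROLE_ARV:
            by_class.setdefault(d.arv_class or "unknown", []).append(d.drug_id)
    for ids in by_class.values():
        rng.shuffle(ids)
    holdout: list[str] = []
    classes = sorted(by_class)
    i = 0
    while len(holdout) < config.holdout_arv_count:
        ids = by_class[classes[i % len(classes)]]
        if ids:
            holdout.append(ids.pop())
        i += 1
        if all(not v for v in by_class.values()):
            raise ValueError("holdout_arv_count exceeds number of ARVs")
    return sorted(holdout)


def make_benchmark_dataset(
    config: DatasetConfig, outdir: str | Path | None = None
) -> tuple[list[DrugRecord], list[LabeledPair], list[str]]:
    """Full benchmark dataset: drug table, graded pairs, hold-out manifest.

    Without stratum options every cross-product pair is graded at the
    global skew.  With ``exact_test_counts`` / ``train_size`` set, the
    held-out-ARV stratum and training stratum are independently trimmed
    (surplus pairs dropped at random, seeded — the real database is not
    a full cross-product either) and quota-graded, the test stratum at
    its exact per-grade counts.
    """
    drugs = generate_drug_universe(config)
    holdout = select_holdout_arvs(drugs, config)
    latents = latent_pharmacology(drugs, config)
    train_arvs = [
        d.drug_id
        for d in drugs
        if d.role == ROLE_ARV and d.drug_id not in set(holdout)
    ]
    pair_ids, scores = _score_pairs(
        drugs, latents, config, reference_arv_ids=train_arvs or None
    )

    if not holdout:
        pairs = _grade_by_quota(pair_ids, scores, config.grade_proportions)
    else:
        # the training stratum is quota-graded (exact counts); the
        # held-out-ARV stratum is graded with the *training-derived*
        # thresholds, so the two strata share one score->grade mapping
        # without coupling their class counts through a global quota.
        # An explicit test quota (database-shape preset) overrides this.
        holdout_set = set(holdout)
        is_test = np.array([a in holdout_set for a, _ in pair_ids])

        def _keep(idx, target, rng):
            if target > len(idx):
                raise ValueError(
                    f"stratum has {len(idx)} candidate pairs, "
                    f"cannot keep {target}"
                )
            return np.sort(rng.permutation(idx)[:target])

        rng = _rng(config.seed, 6)
        train_idx = np.flatnonzero(~is_test)
        test_idx = np.flatnonzero(is_test)
        train_keep = _keep(
            train_idx,
            config.train_size if config.train_size is not None else len(train_idx),
            rng,
        )
        pairs = _grade_by_quota(
            [pair_ids[i] for i in train_keep],
            scores[train_keep],
            config.grade_proportions,
        )
        if config.exact_test_counts is not None:
            target = int(sum(config.exact_test_counts))
            props = np.asarray(config.exact_test_counts) / target
            test_keep = _keep(test_idx, target, rng)
            pairs.extend(
                _grade_by_quota(
                    [pair_ids[i] for i in test_keep], scores[test_keep], props
                )
            )
        else:
            cuts = grade_thresholds(
                scores[train_keep], config.grade_proportions
            )
            pairs.extend(
                _grade_by_thresholds(
                    [pair_ids[i] for i in test_idx], scores[test_idx], cuts
                )
            )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_drug_table(drugs, outdir / "drugs.csv")
        write_pair_table(pairs, outdir / "pairs.csv")
        manifest = {
            "config": config.to_dict(),
            "holdout_arv_ids": holdout,
            "n_drugs": len(drugs),
            "n_pairs": len(pairs),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return drugs, pairs, holdout
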