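"""Majority-class undersampling into ensemble subsets, and inverse-frequency
class weights.

The grade distribution is heavily skewed (roughly 72% Green).  Instead of
discarding majority pairs, the majority class is shuffled and split into k
equal chunks — one per ensemble member — while every minority-class pair is
copied into all k subsets.  A remainder of ``n_majority mod k`` pairs is
dropped (and logged by position), so each subset carries
``floor(n_majority / k)`` majority pairs.

Class weights follow the inverse-frequency rule

    w_c = N_total / (n_present_classes * n_c)

so the weighted count ``n_c * w_c`` is identical for every present class;
absent classes get weight 0 and contribute nothing to the loss.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .grades import GRADE_ORDER, GradeLabel
from .records import LabeledPair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubsetPartition:
    """k index lists into the original pair list, one per ensemble member."""

    subset_indices: tuple[np.ndarray, ...]
    majority_class: int
    dropped_indices: np.ndarray

    @property
    def k(self) -> int:
        return len(self.subset_indices)


def partition_indices(y, k: int, seed: int) -> SubsetPartition:
    """Partition sample indices for k undersampling subsets.

    `y` is an integer label array.  The most frequent class is the
    majority (detected from data, not assumed); ties broken toward the
    lower grade code for determinism.
    """
    y = np.asarray(y)
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = Counter(int(v) for v in y)
    if not counts:
        raise ValueError("no pairs to partition")
    majority = max(counts, key=lambda c: (counts[c], -c))
    n_maj = counts[majority]
    if k > n_maj:
        raise ValueError(f"k={k} exceeds majority class size {n_maj}")

    maj_idx = np.flatnonzero(y == majority)
    min_idx = np.flatnonzero(y != majority)
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(maj_idx)
    chunk = n_maj // k
    dropped = shuffled[chunk * k:]
    if len(dropped):
        logger.info(
            "undersampling drops %d remainder majority pair(s): %s",
            len(dropped),
            dropped.tolist(),
        )
    subsets = tuple(
        np.sort(np.concatenate([shuffled[i * chunk:(i + 1) * chunk], min_idx]))
        for i in range(k)
    )
    logger.info(
        "partitioned %d pairs into %d subsets of %d (majority class %d: %d per subset)",
        len(y), k, len(subsets[0]), majority, chunk,
    )
    return SubsetPartition(subsets, majority, dropped)


def partition_majority(
    pairs: list[LabeledPair], k: int, seed: int
) -> list[list[LabeledPair]]:
    """Undersampling partition over LabeledPair lists (convenience wrapper)."""
    y = np.array([int(p.grade) for p in pairs])
    part = partition_indices(y, k, seed)
    return [[pairs[i] for i in idx] for idx in part.subset_indices]


def class_weights(counts: dict[GradeLabel | int, int]) -> dict[GradeLabel, float]:
    """Inverse-frequency weights from per-class counts.

    Uses the number of *present* classes in the denominator, so with all
    four grades present w_c = N / (4 * n_c).  Equal counts give all 1.0.
    """
    clean = {GradeLabel(int(c)): int(n) for c, n in counts.items()}
    total = sum(clean.values())
    if total == 0:
        raise ValueError("all class counts are zero")
    present = [c for c, n in clean.items() if n > 0]
    for grade in GRADE_ORDER:
        if clean.get(grade, 0) == 0:
            logger.warning("class %s absent; weight set to 0", grade.display)
    weights = {g: 0.0 for g in GRADE_ORDER}
    for c in present:
        weights[c] = total / (len(present) * clean[c])
    return weights


def weights_from_labels(y) -> np.ndarray:
    """Per-class weight vector (length 4) from a label array."""
    y = np.asarray(y)
    counts = {g: int(np.sum(y == int(g))) for g in GRADE_ORDER}
    w = class_weights(counts)
    return np.array([w[g] for g in GRADE_ORDER])
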