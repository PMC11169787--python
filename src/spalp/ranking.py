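"""Per-disease candidate ranking: score every miRNA, drop known positives,
sort descending and keep the top k."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import mlp
from .mlp import MLPModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedPredictions:
    disease: str
    entries: tuple[tuple[int, str, float], ...]  # (rank, mirna, score)

    def __post_init__(self) -> None:
        scores = [e[2] for e in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("scores must be non-increasing")
        if [e[0] for e in self.entries] != list(range(1, len(self.entries) + 1)):
            raise ValueError("ranks must be consecutive from 1")


def rank_candidates(
    scores: np.ndarray,
    mirna_names: tuple[str, ...],
    known_positive: set[int],
    disease: str,
    k: int,
) -> RankedPredictions:
    """Rank precomputed per-miRNA scores, excluding known positives.

    Ties are broken by lexicographic miRNA name (logged when a tie crosses
    the top-k boundary).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(mirna_names),):
        raise ValueError("one score per miRNA required")
    candidates = [
        (i, mirna_names[i], float(scores[i]))
        for i in range(len(mirna_names))
        if i not in known_positive
    ]
    if not candidates:
        logger.warning("all miRNAs are known positives for %r; empty ranking", disease)
        return RankedPredictions(disease=disease, entries=())
    candidates.sort(key=lambda c: (-c[2], c[1]))
    if k > len(candidates):
        logger.warning(
            "requested top %d but only %d candidates for %r", k, len(candidates), disease
        )
    top = candidates[:k]
    if len(candidates) > len(top) and top and candidates[len(top)][2] == top[-1][2]:
        logger.info("score tie at the top-%d boundary for %r", k, disease)
    entries = tuple(
        (rank, name, score) for rank, (_, name, score) in enumerate(top, start=1)
    )
    return RankedPredictions(disease=disease, entries=entries)


def rank_mirnas(
    model: MLPModel,
    features: np.ndarray,
    mirna_names: tuple[str, ...],
    known_positive: set[int],
    disease: str,
    k: int = 30,
) -> RankedPredictions:
    """Score all (miRNA, disease) feature rows with the classifier and rank.

    ``features`` has one fused row per miRNA, all for the same disease,
    ordered like ``mirna_names``.
    """
    if features.shape[0] != len(mirna_names):
        raise ValueError("one feature row per miRNA required")
    scores = mlp.predict_proba(model, features)
    return rank_candidates(scores, mirna_names, known_positive, disease, k)
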