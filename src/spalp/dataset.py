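"""Matrix decomposition, balanced negative sampling, and per-pair feature fusion.

Negatives are drawn from the unknown (zero) cells of the association
matrix: the unknown pairs are clustered by k-means on their raw adjacency
profiles and each cluster contributes a share proportional to its size, so
the sampled negatives cover the unknown space instead of concentrating in
one region. Downsampling balances negatives to the positive count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .io_formats import AdjacencyMatrix


@dataclass(frozen=True)
class PairSampleSet:
    """Aligned (miRNA index, disease index) pairs and binary labels."""

    pairs: tuple[tuple[int, int], ...]
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.pairs) != labels.shape[0]:
            raise ValueError("pairs and labels length mismatch")
        if labels.size and not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class FeatureTable:
    """One fused feature row per pair: [M[i] || Msim[i] || D[j] || Dsim[j]]."""

    matrix: np.ndarray
    labels: np.ndarray
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != self.labels.shape[0] != len(self.pairs):
            raise ValueError("feature rows, labels and pairs must align")
        if not np.isfinite(self.matrix).all():
            raise ValueError("non-finite feature values")


def decompose(md: AdjacencyMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Split MD into the raw miRNA features (MD) and disease features (MD^T)."""
    values = md.values.astype(float)
    return values, values.T.copy()


def _proportional_quota(cluster_sizes: np.ndarray, total: int) -> np.ndarray:
    """Per-cluster draw counts: round(total * size / n), adjusted on the
    largest clusters so the counts sum to exactly ``total``."""
    n = int(cluster_sizes.sum())
    quota = np.rint(total * cluster_sizes / n).astype(int)
    quota = np.minimum(quota, cluster_sizes)
    # largest clusters first, index as deterministic tie-break
    order = np.lexsort((np.arange(len(quota)), -cluster_sizes))
    diff = total - int(quota.sum())
    pos = 0
    while diff != 0:
        c = order[pos % len(order)]
        if diff > 0 and quota[c] < cluster_sizes[c]:
            quota[c] += 1
            diff -= 1
        elif diff < 0 and quota[c] > 0:
            quota[c] -= 1
            diff += 1
        pos += 1
    return quota


def sample_negatives(
    md: AdjacencyMatrix, n_clusters: int = 23, seed: int = 0
) -> list[tuple[int, int]]:
    """Cluster the unknown pairs and draw a balanced negative sample.

    Each unknown pair (i, j) is represented by the concatenation of MD row i
    and MD column j. k-means (k-means++ init, Lloyd, seeded) partitions the
    unknowns; cluster c contributes round(P * |c| / U) uniform draws without
    replacement, adjusted by +/-1 on the largest clusters so the total is
    exactly the positive count P.
    """
    values = md.values
    positives = int(values.sum())
    zero_rows, zero_cols = np.nonzero(values == 0)
    n_unknown = zero_rows.size
    if n_unknown < positives:
        raise ValueError(
            f"not enough unknown pairs ({n_unknown}) to balance {positives} positives"
        )
    if positives == 0:
        return []
    k = min(n_clusters, n_unknown)
    features = np.hstack(
        [values[zero_rows].astype(np.float32), values[:, zero_cols].T.astype(np.float32)]
    )
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=1,
        max_iter=100,
        tol=1e-4,
        algorithm="lloyd",
        random_state=seed,
    )
    assignment = km.fit_predict(features)
    cluster_sizes = np.bincount(assignment, minlength=k)
    quota = _proportional_quota(cluster_sizes, positives)
    rng = np.random.default_rng(seed)
    chosen: list[tuple[int, int]] = []
    for c in range(k):
        members = np.nonzero(assignment == c)[0]
        picked = rng.choice(members, size=quota[c], replace=False)
        chosen.extend(
            (int(zero_rows[idx]), int(zero_cols[idx])) for idx in np.sort(picked)
        )
    return chosen


def make_sample_set(
    md: AdjacencyMatrix, negatives: list[tuple[int, int]]
) -> PairSampleSet:
    """Positive pairs from MD followed by the sampled negatives."""
    rows, cols = np.nonzero(md.values)
    pos_pairs = list(zip(rows.tolist(), cols.tolist()))
    for i, j in negatives:
        if md.values[i, j] != 0:
            raise ValueError(f"negative pair ({i}, {j}) is a known positive")
    pairs = tuple(pos_pairs) + tuple(negatives)
    labels = np.concatenate(
        [np.ones(len(pos_pairs), dtype=np.int8), np.zeros(len(negatives), dtype=np.int8)]
    )
    return PairSampleSet(pairs=pairs, labels=labels)


def fuse_features(
    m_latent: np.ndarray,
    msim: np.ndarray,
    d_latent: np.ndarray,
    dsim: np.ndarray,
    samples: PairSampleSet,
) -> FeatureTable:
    """Build the fused per-pair feature table.

    Row for pair (i, j) is the concatenation of the miRNA latent feature,
    the miRNA similarity profile, the disease latent feature and the
    disease similarity profile; width = 2 * latent_dim + n_mirnas + n_diseases.
    """
    n_mirnas = msim.shape[0]
    n_diseases = dsim.shape[0]
    if m_latent.shape[0] != n_mirnas or d_latent.shape[0] != n_diseases:
        raise ValueError("latent feature row counts do not match similarity matrices")
    if samples.pairs:
        mi = np.array([p[0] for p in samples.pairs])
        dj = np.array([p[1] for p in samples.pairs])
        if mi.min() < 0 or mi.max() >= n_mirnas or dj.min() < 0 or dj.max() >= n_diseases:
            raise IndexError("pair index out of range")
        matrix = np.hstack([m_latent[mi], msim[mi], d_latent[dj], dsim[dj]])
    else:
        width = m_latent.shape[1] + n_mirnas + d_latent.shape[1] + n_diseases
        matrix = np.empty((0, width))
    return FeatureTable(matrix=matrix, labels=samples.labels, pairs=samples.pairs)
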