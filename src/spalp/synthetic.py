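"""Synthetic fixture data with planted group structure.

Generates a sparse binary bipartite association matrix whose miRNAs and
diseases fall into matched groups (within-group edges more likely), plus a
disease ontology forest whose subtrees mirror the groups, so DAG-based
semantic similarity is higher within groups than between them. A fraction
of positive edges is withheld as evaluation truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AssociationCatalog
from .similarity import DiseaseDAG


@dataclass(frozen=True)
class PlantedSpec:
    n_mirnas: int = 300
    n_diseases: int = 200
    n_groups: int = 6
    p_in: float = 0.3
    p_out: float = 0.01
    holdout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirnas, self.n_diseases, self.n_groups) < 1:
            raise ValueError("sizes and group count must be positive")
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if not 0.0 <= self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class PlantedDataset:
    catalog: AssociationCatalog  # held-out positives removed
    dag: DiseaseDAG
    heldout_pairs: tuple[tuple[int, int], ...]
    mirna_groups: np.ndarray
    disease_groups: np.ndarray


def _balanced_groups(n: int, n_groups: int) -> np.ndarray:
    """Contiguous balanced group labels; remainders go to the earliest groups."""
    sizes = np.full(n_groups, n // n_groups)
    sizes[: n % n_groups] += 1
    return np.repeat(np.arange(n_groups), sizes)


def generate_planted(spec: PlantedSpec) -> PlantedDataset:
    """Draw the planted association matrix, the group-coherent DAG and truth."""
    rng = np.random.default_rng(spec.seed)
    mirna_groups = _balanced_groups(spec.n_mirnas, spec.n_groups)
    disease_groups = _balanced_groups(spec.n_diseases, spec.n_groups)
    match = mirna_groups[:, None] == disease_groups[None, :]
    prob = np.where(match, spec.p_in, spec.p_out)
    edges = rng.random((spec.n_mirnas, spec.n_diseases)) < prob
    rows, cols = np.nonzero(edges)
    n_pos = rows.size
    if n_pos == 0:
        raise ValueError("planted spec produced zero positive edges")

    n_holdout = int(round(spec.holdout_fraction * n_pos))
    holdout_idx = rng.choice(n_pos, size=n_holdout, replace=False)
    holdout_mask = np.zeros(n_pos, dtype=bool)
    holdout_mask[holdout_idx] = True
    if not (~holdout_mask).any():
        raise ValueError("holdout removed every positive edge")

    mirna_names = tuple(f"mir-{i:04d}" for i in range(spec.n_mirnas))
    disease_names = tuple(f"dis-{j:04d}" for j in range(spec.n_diseases))
    training_pairs = frozenset(
        (int(i), int(j)) for i, j in zip(rows[~holdout_mask], cols[~holdout_mask])
    )
    heldout_pairs = tuple(
        sorted((int(i), int(j)) for i, j in zip(rows[holdout_mask], cols[holdout_mask]))
    )
    catalog = AssociationCatalog(
        mirna_names=mirna_names,
        disease_names=disease_names,
        positive_pairs=training_pairs,
    )
    dag = _group_forest(disease_names, disease_groups, spec.n_groups, rng)
    return PlantedDataset(
        catalog=catalog,
        dag=dag,
        heldout_pairs=heldout_pairs,
        mirna_groups=mirna_groups,
        disease_groups=disease_groups,
    )


def _group_forest(
    disease_names: tuple[str, ...],
    disease_groups: np.ndarray,
    n_groups: int,
    rng: np.random.Generator,
) -> DiseaseDAG:
    """One random-shaped subtree per group under a synthetic group root."""
    parents: dict[str, set[str]] = {}
    for g in range(n_groups):
        root = f"group-root-{g}"
        parents[root] = set()
        members = [disease_names[j] for j in np.nonzero(disease_groups == g)[0]]
        placed: list[str] = [root]
        for name in members:
            parent = placed[int(rng.integers(len(placed)))]
            parents[name] = {parent}
            placed.append(name)
    return DiseaseDAG(parents=parents)


def generate_random_dag(
    n_nodes: int, max_parents: int = 3, seed: int = 0
) -> DiseaseDAG:
    """Random DAG: topological order sampled, each non-root node gets 1..max_parents
    parents among earlier nodes."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_nodes)
    names = [f"node-{i:03d}" for i in range(n_nodes)]
    parents: dict[str, set[str]] = {}
    for pos, idx in enumerate(order):
        name = names[idx]
        if pos == 0:
            parents[name] = set()
            continue
        n_par = int(rng.integers(1, min(max_parents, pos) + 1))
        chosen = rng.choice(pos, size=n_par, replace=False)
        parents[name] = {names[order[c]] for c in chosen}
    return DiseaseDAG(parents=parents)


def sample_negative_pairs(
    forbidden: frozenset[tuple[int, int]] | set[tuple[int, int]],
    n_mirnas: int,
    n_diseases: int,
    count: int,
    seed: int,
) -> tuple[tuple[int, int], ...]:
    """Uniform pairs outside ``forbidden``, without replacement; deterministic."""
    total = n_mirnas * n_diseases
    forbidden_flat = {i * n_diseases + j for i, j in forbidden}
    available = np.array(
        sorted(set(range(total)) - forbidden_flat), dtype=np.int64
    )
    if count > available.size:
        raise ValueError("not enough non-positive pairs to sample")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(available, size=count, replace=False)
    return tuple(
        (int(flat // n_diseases), int(flat % n_diseases)) for flat in np.sort(chosen)
    )
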