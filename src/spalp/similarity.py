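"""Disease semantic similarity over an ontology DAG and miRNA functional similarity.

A disease term's semantic profile assigns each of its ancestors a
contribution that decays by a factor ``delta`` per hierarchy step; the
similarity of two terms is the ratio of their shared-ancestor contributions
to the sum of their semantic values. miRNA functional similarity is the
best-match average of disease similarities between the two miRNAs'
associated disease sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import networkx as nx
import numpy as np

from .io_formats import AssociationCatalog, SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class DiseaseDAG:
    """Directed acyclic parent/child graph over disease terms.

    ``parents`` maps every node to the set of its parent nodes; edges run
    parent -> child. Acyclicity is checked at construction.
    """

    parents: dict[str, set[str]]
    _children: dict[str, set[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for node, node_parents in self.parents.items():
            missing = node_parents - self.parents.keys()
            if missing:
                raise ValueError(f"node {node!r} references unknown parents {missing}")
        graph = nx.DiGraph()
        graph.add_nodes_from(self.parents)
        for child, node_parents in self.parents.items():
            graph.add_edges_from((p, child) for p in node_parents)
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            pass
        else:
            path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
            raise ValueError(f"graph contains a cycle: {path}")
        self._children = {node: set() for node in self.parents}
        for child, node_parents in self.parents.items():
            for parent in node_parents:
                self._children[parent].add(child)

    @property
    def nodes(self) -> set[str]:
        return set(self.parents)

    def __contains__(self, node: str) -> bool:
        return node in self.parents

    def children(self, node: str) -> set[str]:
        return self._children[node]

    def ancestors(self, node: str) -> set[str]:
        """All proper ancestors of ``node`` (excluding itself)."""
        seen: set[str] = set()
        stack = list(self.parents[node])
        while stack:
            current = stack.pop()
            if current in seen:
                continue
            seen.add(current)
            stack.extend(self.parents[current])
        return seen


@dataclass(frozen=True)
class SemanticProfile:
    """Per-ancestor semantic contributions of one disease term."""

    disease: str
    contributions: dict[str, float]
    delta: float

    @cached_property
    def semantic_value(self) -> float:
        return float(sum(self.contributions.values()))

    @property
    def terms(self) -> set[str]:
        return set(self.contributions)


def semantic_profile(dag: DiseaseDAG, disease: str, delta: float = 0.5) -> SemanticProfile:
    """Contribution of each ancestor-or-self term to ``disease``.

    The disease contributes 1 to itself; an ancestor ``t`` contributes
    ``delta`` times the largest contribution among its children that are
    themselves ancestors-or-self of the disease. Equivalently, the maximum
    over directed paths t ~> disease of ``delta ** path_length``.
    """
    if disease not in dag:
        raise KeyError(f"disease {disease!r} not in DAG")
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must lie in (0, 1), got {delta}")
    terms = dag.ancestors(disease) | {disease}
    contributions: dict[str, float] = {disease: 1.0}

    def contribution(t: str) -> float:
        if t in contributions:
            return contributions[t]
        value = delta * max(
            contribution(child) for child in dag.children(t) if child in terms
        )
        contributions[t] = value
        return value

    for t in terms:
        contribution(t)
    return SemanticProfile(disease=disease, contributions=contributions, delta=delta)


def disease_semantic_similarity(a: SemanticProfile, b: SemanticProfile) -> float:
    """Shared-ancestor contribution ratio; symmetric, in [0, 1], 1 on self."""
    if a.delta != b.delta:
        raise ValueError(
            f"profiles computed with different delta ({a.delta} vs {b.delta})"
        )
    if a.disease == b.disease:
        return 1.0
    shared = a.terms & b.terms
    if not shared:
        return 0.0
    numerator = sum(a.contributions[t] + b.contributions[t] for t in shared)
    return float(numerator / (a.semantic_value + b.semantic_value))


def disease_similarity_matrix(
    dag: DiseaseDAG,
    diseases: tuple[str, ...] | list[str],
    delta: float = 0.5,
) -> SimilarityMatrix:
    """Pairwise semantic similarity for an ordered disease list.

    Diseases absent from the DAG get similarity 0 to every other disease
    and 1 to themselves (logged).
    """
    diseases = tuple(diseases)
    profiles: dict[str, SemanticProfile] = {}
    for d in diseases:
        if d in dag:
            profiles[d] = semantic_profile(dag, d, delta)
        else:
            logger.warning("disease %r absent from DAG; similarity row set to 0", d)
    n = len(diseases)
    values = np.eye(n)
    for i in range(n):
        if diseases[i] not in profiles:
            continue
        for j in range(i + 1, n):
            if diseases[j] not in profiles:
                continue
            s = disease_semantic_similarity(profiles[diseases[i]], profiles[diseases[j]])
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(values=values, names=diseases)


def mirna_functional_similarity(
    catalog: AssociationCatalog, dsim: SimilarityMatrix
) -> SimilarityMatrix:
    """Best-match average similarity between two miRNAs' disease sets.

    For miRNAs u, v with associated disease index sets DT(u), DT(v):

        MISIM(u, v) = [ sum_{d in DT(u)} max_{d' in DT(v)} S(d, d')
                      + sum_{d in DT(v)} max_{d' in DT(u)} S(d, d') ]
                      / (|DT(u)| + |DT(v)|)

    A miRNA with no associated diseases gets similarity 0 to all others
    and 1 to itself (logged).
    """
    if tuple(dsim.names) != tuple(catalog.disease_names):
        raise ValueError("dsim names do not match catalog disease order")
    n = catalog.n_mirnas
    disease_sets: list[np.ndarray] = [np.array([], dtype=int) for _ in range(n)]
    by_mirna: dict[int, list[int]] = {}
    for i, j in catalog.positive_pairs:
        by_mirna.setdefault(i, []).append(j)
    for i, js in by_mirna.items():
        disease_sets[i] = np.array(sorted(js), dtype=int)
    for i in range(n):
        if disease_sets[i].size == 0:
            logger.warning(
                "miRNA %r has no associated diseases; similarity row set to 0",
                catalog.mirna_names[i],
            )
    s = dsim.values
    values = np.eye(n)
    for u in range(n):
        du = disease_sets[u]
        if du.size == 0:
            continue
        for v in range(u + 1, n):
            dv = disease_sets[v]
            if dv.size == 0:
                continue
            block = s[np.ix_(du, dv)]
            score = (block.max(axis=1).sum() + block.max(axis=0).sum()) / (
                du.size + dv.size
            )
            values[u, v] = values[v, u] = score
    return SimilarityMatrix(values=values, names=catalog.mirna_names)
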