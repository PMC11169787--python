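from __future__ import annotations

import numpy as np
import pytest

from spalp import synthetic
from spalp.io_formats import AssociationCatalog, SimilarityMatrix
from spalp.similarity import (
    DiseaseDAG,
    disease_semantic_similarity,
    disease_similarity_matrix,
    mirna_functional_similarity,
    semantic_profile,
)

from .oracles import profile_by_paths, similarity_by_paths


class TestSemanticProfile:
    def test_isolated_node(self):
        dag = DiseaseDAG(parents={"A": set()})
        prof = semantic_profile(dag, "A", 0.5)
        assert prof.contributions == {"A": 1.0}
        assert prof.semantic_value == 1.0

    def test_chain(self, chain_dag):
        prof = semantic_profile(chain_dag, "A", 0.5)
        assert prof.contributions == {"A": 1.0, "P": 0.5, "R": 0.25}
        assert prof.semantic_value == pytest.approx(1.75, abs=1e-12)

    def test_diamond_max_over_paths(self, diamond_dag):
        prof = semantic_profile(diamond_dag, "A", 0.5)
        assert prof.contributions["P1"] == 0.5
        assert prof.contributions["P2"] == 0.5
        assert prof.contributions["R"] == 0.25
        assert prof.semantic_value == pytest.approx(2.25, abs=1e-12)

    def test_unknown_disease_rejected(self, chain_dag):
        with pytest.raises(KeyError):
            semantic_profile(chain_dag, "missing", 0.5)

    @pytest.mark.parametrize("delta", [0.0, 1.0, -0.1])
    def test_invalid_delta_rejected(self, chain_dag, delta):
        with pytest.raises(ValueError):
            semantic_profile(chain_dag, "A", delta)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_path_enumeration_oracle(self, seed):
        dag = synthetic.generate_random_dag(20, max_parents=3, seed=seed)
        rng = np.random.default_rng(seed)
        disease = sorted(dag.nodes)[int(rng.integers(len(dag.nodes)))]
        prof = semantic_profile(dag, disease, 0.5)
        oracle = profile_by_paths(dag, disease, 0.5)
        assert prof.contributions.keys() == oracle.keys()
        for t, expected in oracle.items():
            assert prof.contributions[t] == pytest.approx(expected, abs=1e-12)


class TestDiseaseSemanticSimilarity:
    def test_self_similarity_is_one(self, chain_dag):
        prof = semantic_profile(chain_dag, "A", 0.5)
        assert disease_semantic_similarity(prof, prof) == 1.0

    def test_disjoint_components_zero(self):
        dag = DiseaseDAG(parents={"A": set(), "B": set()})
        pa = semantic_profile(dag, "A", 0.5)
        pb = semantic_profile(dag, "B", 0.5)
        assert disease_semantic_similarity(pa, pb) == 0.0

    def test_siblings_one_third(self, sibling_dag):
        pa = semantic_profile(sibling_dag, "A", 0.5)
        pb = semantic_profile(sibling_dag, "B", 0.5)
        assert disease_semantic_similarity(pa, pb) == pytest.approx(1 / 3, abs=1e-12)

    def test_mismatched_delta_rejected(self, sibling_dag):
        pa = semantic_profile(sibling_dag, "A", 0.5)
        pb = semantic_profile(sibling_dag, "B", 0.4)
        with pytest.raises(ValueError, match="delta"):
            disease_semantic_similarity(pa, pb)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_and_range(self, seed):
        dag = synthetic.generate_random_dag(15, max_parents=2, seed=seed)
        names = sorted(dag.nodes)
        profs = {n: semantic_profile(dag, n, 0.5) for n in names}
        for a in names[:6]:
            for b in names[:6]:
                s_ab = disease_semantic_similarity(profs[a], profs[b])
                s_ba = disease_semantic_similarity(profs[b], profs[a])
                assert s_ab == pytest.approx(s_ba, abs=1e-15)
                assert 0.0 <= s_ab <= 1.0


class TestDiseaseSimilarityMatrix:
    def test_single_disease(self):
        dag = DiseaseDAG(parents={"A": set()})
        m = disease_similarity_matrix(dag, ("A",), 0.5)
        assert m.values.tolist() == [[1.0]]

    def test_chain_matches_pairwise_oracle(self, chain_dag):
        names = ("R", "P", "A")
        m = disease_similarity_matrix(chain_dag, names, 0.5)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if a == b:
                    continue
                expected = similarity_by_paths(chain_dag, a, b, 0.5)
                assert m.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_random_dag_symmetric(self):
        dag = synthetic.generate_random_dag(25, max_parents=3, seed=7)
        names = tuple(sorted(dag.nodes))
        m = disease_similarity_matrix(dag, names, 0.5)
        assert np.allclose(m.values, m.values.T, atol=1e-12)
        assert np.all(np.diag(m.values) == 1.0)

    def test_disease_missing_from_dag(self, chain_dag, caplog):
        with caplog.at_level("WARNING", logger="spalp.similarity"):
            m = disease_similarity_matrix(chain_dag, ("A", "ghost"), 0.5)
        assert m.values[0, 1] == 0.0
        assert m.values[1, 1] == 1.0
        assert any("absent from DAG" in rec.message for rec in caplog.records)


class TestMirnaFunctionalSimilarity:
    def _catalog(self, pairs, n_mirnas=2, diseases=("A", "B", "P")):
        return AssociationCatalog(
            tuple(f"m{i}" for i in range(n_mirnas)), diseases, frozenset(pairs)
        )

    def test_identical_disease_sets_give_one(self, sibling_dag):
        catalog = self._catalog({(0, 0), (0, 1), (1, 0), (1, 1)})
        dsim = disease_similarity_matrix(sibling_dag, catalog.disease_names, 0.5)
        m = mirna_functional_similarity(catalog, dsim)
        assert m.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_components_zero(self):
        dag = DiseaseDAG(parents={"A": set(), "B": set()})
        catalog = self._catalog({(0, 0), (1, 1)}, diseases=("A", "B"))
        dsim = disease_similarity_matrix(dag, catalog.disease_names, 0.5)
        m = mirna_functional_similarity(catalog, dsim)
        assert m.values[0, 1] == 0.0

    def test_worked_seven_ninths(self, sibling_dag):
        # DT(m0) = {A}, DT(m1) = {A, B}, S(A,B) = 1/3
        catalog = self._catalog({(0, 0), (1, 0), (1, 1)}, diseases=("A", "B"))
        dsim = disease_similarity_matrix(sibling_dag, catalog.disease_names, 0.5)
        m = mirna_functional_similarity(catalog, dsim)
        assert m.values[0, 1] == pytest.approx(7 / 9, abs=1e-12)

    def test_empty_disease_set_logged(self, sibling_dag, caplog):
        catalog = self._catalog({(0, 0)})
        dsim = disease_similarity_matrix(sibling_dag, catalog.disease_names, 0.5)
        with caplog.at_level("WARNING", logger="spalp.similarity"):
            m = mirna_functional_similarity(catalog, dsim)
        assert m.values[1, 1] == 1.0
        assert m.values[0, 1] == 0.0
        assert any("no associated diseases" in rec.message for rec in caplog.records)

    def test_matrix_invariants(self, rng):
        dag = synthetic.generate_random_dag(12, max_parents=2, seed=3)
        names = tuple(sorted(dag.nodes))
        pairs = {
            (int(i), int(j))
            for i, j in zip(rng.integers(0, 8, 30), rng.integers(0, 12, 30))
        }
        catalog = AssociationCatalog(
            tuple(f"m{i}" for i in range(8)), names, frozenset(pairs)
        )
        dsim = disease_similarity_matrix(dag, names, 0.5)
        m = mirna_functional_similarity(catalog, dsim)
        assert isinstance(m, SimilarityMatrix)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 1.0)
        assert m.values.min() >= 0.0 and m.values.max() <= 1.0


class TestDagValidation:
    def test_cycle_rejected_at_construction(self):
        with pytest.raises(ValueError, match="cycle"):
            DiseaseDAG(parents={"A": {"B"}, "B": {"A"}})

    def test_unknown_parent_rejected(self):
        with pytest.raises(ValueError, match="unknown parents"):
            DiseaseDAG(parents={"A": {"ghost"}})
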