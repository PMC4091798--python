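"""True-path propagation, Fisher tests, and elim decorrelation."""
import networkx as nx
import numpy as np
import pytest
from scipy.stats import fisher_exact

from crosstx.enrichment import (OntologyDag, annotated_universe, fisher_classic,
                                fisher_two_sided, go_elim,
                                propagate_annotations, two_sided_fisher_p)
from crosstx.simulate import gen_annotations

from oracles import fisher_two_sided_enumeration, fisher_upper_tail


def three_level_dag():
    # root <- mid1, mid2 ; mid1 <- leafA, leafB ; mid2 <- leafC
    edges = [("mid1", "root"), ("mid2", "root"), ("leafA", "mid1"),
             ("leafB", "mid1"), ("leafC", "mid2")]
    return OntologyDag(edges)


class TestDag:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            OntologyDag([("a", "b"), ("b", "a")])

    def test_two_roots_rejected(self):
        with pytest.raises(ValueError, match="root"):
            OntologyDag([("a", "r1"), ("b", "r2")])

    def test_simulated_dags_are_single_rooted_and_acyclic(self):
        for seed in (1, 2, 3):
            edges, gene2term, _ = gen_annotations([f"g{i}" for i in range(20)],
                                                  n_terms=25, dag_depth=4,
                                                  seed=seed)
            dag = OntologyDag(edges)
            assert nx.is_directed_acyclic_graph(dag.graph)
            assert dag.root == "T0000"


class TestPropagation:
    def test_leaf_annotation_reaches_root(self):
        dag = three_level_dag()
        full = propagate_annotations(dag, {"g1": {"leafA"}})
        assert full["g1"] == {"leafA", "mid1", "root"}

    def test_idempotent(self):
        dag = three_level_dag()
        once = propagate_annotations(dag, {"g1": {"leafA"}, "g2": {"mid2"}})
        twice = propagate_annotations(dag, once)
        assert once == twice

    def test_term_sets_equal_descendant_union(self):
        genes = [f"g{i}" for i in range(30)]
        edges, gene2term, _ = gen_annotations(genes, n_terms=30, dag_depth=4,
                                              seed=8)
        dag = OntologyDag(edges)
        full = propagate_annotations(dag, gene2term)
        # oracle: gene set of a term = union over its DAG descendants' direct sets
        reverse = dag.graph.reverse()
        for term in dag.terms:
            below = nx.descendants(reverse, term) | {term}
            expected = {g for g, ts in gene2term.items() if ts & below}
            got = {g for g, ts in full.items() if term in ts}
            assert got == expected

    def test_unknown_term_raises(self):
        dag = three_level_dag()
        with pytest.raises(ValueError, match="unknown"):
            propagate_annotations(dag, {"g1": {"nope"}})


class TestFisherClassic:
    def test_study_equals_universe_all_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        annotations = {g: {"t1"} for g in list(universe)[:7]}
        out = fisher_classic(universe, annotations, universe)
        assert (out["p_value"] == 1.0).all()

    def test_full_overlap_matches_tail_enumeration(self):
        universe = {f"g{i}" for i in range(1000)}
        term_genes = {f"g{i}" for i in range(10)}
        study = term_genes | {f"g{i}" for i in range(100, 190)}
        annotations = {g: {"t"} for g in term_genes}
        out = fisher_classic(study, annotations, universe)
        row = out[out["id"] == "t"].iloc[0]
        assert row["p_value"] == pytest.approx(
            fisher_upper_tail(10, 1000, 10, 100), abs=1e-12)
        assert row["expected"] == pytest.approx(1.0, abs=1e-12)

    def test_super_uniform_under_random_study_sets(self):
        """One-sided Fisher p-values are conservative: P(p <= a) <= ~a."""
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(400)]
        annotations = {g: {"t"} for g in universe[:40]}
        pvals = []
        for _ in range(2000):
            study = set(rng.choice(universe, size=60, replace=False))
            out = fisher_classic(study, annotations, set(universe))
            pvals.append(out["p_value"].iloc[0])
        pvals = np.array(pvals)
        for alpha in (0.01, 0.05, 0.2):
            # allow Monte-Carlo slack of 3 binomial SDs
            slack = 3 * np.sqrt(alpha * (1 - alpha) / 2000)
            assert (pvals <= alpha).mean() <= alpha + slack


class TestElim:
    def _setup(self):
        dag = three_level_dag()
        universe = {f"g{i}" for i in range(100)}
        # leafA's genes are exactly the parent's study overlap
        direct = {f"g{i}": {"leafA"} for i in range(10)}
        direct.update({f"g{i}": {"mid1"} for i in range(10, 40)})
        annotations = propagate_annotations(dag, direct)
        study = {f"g{i}" for i in range(10)}
        return dag, study, annotations, universe

    def test_total_elimination_raises_parent_p_to_one(self):
        dag, study, annotations, universe = self._setup()
        out = go_elim(dag, study, annotations, universe, elim_cutoff=0.05)
        by_id = out.set_index("id")
        assert by_id.loc["leafA", "p_value"] < 0.05
        assert by_id.loc["mid1", "significant"] == 0
        assert by_id.loc["mid1", "p_value"] == 1.0
        # annotated counts keep the true propagated values
        assert by_id.loc["mid1", "annotated"] == 40

    def test_cutoff_zero_equals_classic(self):
        genes = [f"g{i}" for i in range(40)]
        edges, gene2term, _ = gen_annotations(genes, n_terms=20, dag_depth=3,
                                              seed=4)
        dag = OntologyDag(edges)
        annotations = propagate_annotations(dag, gene2term)
        universe = annotated_universe(annotations)
        study = set(list(universe)[:12])
        classic = fisher_classic(study, annotations, universe).set_index("id")
        elim = go_elim(dag, study, annotations, universe,
                       elim_cutoff=0.0).set_index("id")
        assert np.allclose(classic["p_value"],
                           elim.loc[classic.index, "p_value"], atol=1e-12)

    def test_three_level_dag_matches_manual_walkthrough(self):
        dag, study, annotations, universe = self._setup()
        out = go_elim(dag, study, annotations, universe,
                      elim_cutoff=0.01).set_index("id")
        # manual: leafA tested first, k=10/K=10 -> significant, its genes
        # removed from mid1 and root, both drop to overlap 0 -> p = 1
        assert out.loc["leafA", "p_value"] == pytest.approx(
            fisher_upper_tail(10, 100, 10, 10), abs=1e-12)
        assert out.loc["root", "p_value"] == 1.0


class TestFisherTwoSided:
    def test_modal_symmetric_table_p_one(self):
        # universe 20, family 10, study 10, overlap 5 is the mode
        assert two_sided_fisher_p(5, 10, 10, 20) == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        for k, big_k, n, big_n in [(8, 50, 901, 29000), (0, 40, 400, 2000),
                                   (12, 30, 100, 500)]:
            assert two_sided_fisher_p(k, big_k, n, big_n) == pytest.approx(
                fisher_two_sided_enumeration(k, big_n, big_k, n), abs=1e-12)

    def test_agrees_with_scipy_cross_check(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            big_n = int(rng.integers(50, 400))
            big_k = int(rng.integers(1, big_n // 2))
            n = int(rng.integers(1, big_n // 2))
            k = int(rng.integers(max(0, n + big_k - big_n), min(n, big_k) + 1))
            table = [[k, big_k - k], [n - k, big_n - big_k - (n - k)]]
            expected = fisher_exact(table, alternative="two-sided")[1]
            assert two_sided_fisher_p(k, big_k, n, big_n) == pytest.approx(
                expected, rel=1e-8, abs=1e-10)

    def test_depletion_detected(self):
        # zero overlap where ~10 expected: two-sidedness must flag it
        p = two_sided_fisher_p(0, 100, 200, 2000)
        assert p < 0.001

    def test_family_rows_and_universe_check(self):
        universe = {f"g{i}" for i in range(100)}
        families = {"F1": {f"g{i}" for i in range(10)}}
        study = {f"g{i}" for i in range(5, 25)}
        out = fisher_two_sided(study, families, universe)
        assert out.loc[0, "annotated"] == 10
        assert out.loc[0, "significant"] == 5
        assert out.loc[0, "expected"] == pytest.approx(2.0)
        with pytest.raises(ValueError, match="subset"):
            fisher_two_sided(study, {"F2": {"not_there"}}, universe)
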