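"""Overrepresentation analysis for ontology terms, protein domains and families.

GO-style terms live on an is_a DAG and obey the true-path rule: a gene
annotated to a term is implicitly annotated to every ancestor, so direct
annotations are propagated before testing. Term enrichment uses a one-sided
(upper-tail) hypergeometric test; to decorrelate nested terms the ``elim``
scheme processes terms leaves-to-root and removes the study genes of any
term significant at ``elim_cutoff`` from its ancestors' study overlap before
those are tested (annotated counts keep their true propagated values — only
the significant count can shrink).

Protein-domain and gene-family tables are flat, so misrepresentation in
either direction is of interest: a two-sided Fisher test by
minimum-likelihood summation over the full hypergeometric support.

Every row reports ``annotated`` (genes in the universe carrying the term),
``significant`` (study genes carrying it) and ``expected``
(annotated x |study| / |universe|).
"""
from __future__ import annotations

from math import comb
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

ENRICHMENT_COLUMNS = ["id", "annotated", "significant", "expected", "p_value"]


class OntologyDag:
    """A rooted is_a DAG over ontology terms (edges child -> parent)."""

    def __init__(self, edges: Iterable[tuple[str, str]], terms: Iterable[str] = ()):
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(terms)
        self.graph.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology contains a cycle")
        roots = [n for n in self.graph.nodes if self.graph.out_degree(n) == 0]
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, found {sorted(roots)}")
        self.root = roots[0]
        for node in self.graph.nodes:
            if node != self.root and not nx.has_path(self.graph, node, self.root):
                raise ValueError(f"term {node} cannot reach the root")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable by following is_a edges upward (excl. the term)."""
        return nx.descendants(self.graph, term)

    def depth_order(self) -> list[str]:
        """Terms ordered leaves-first (reverse topological order of child->parent)."""
        return list(nx.topological_sort(self.graph))


def propagate_annotations(dag: OntologyDag, direct: Mapping[str, Iterable[str]]
                          ) -> dict[str, set[str]]:
    """Apply the true-path rule: annotate every gene to all ancestors. Idempotent."""
    unknown = {t for terms in direct.values() for t in terms} - dag.terms
    if unknown:
        raise ValueError(f"annotations to unknown terms: {sorted(unknown)}")
    closure: dict[str, set[str]] = {}
    full: dict[str, set[str]] = {}
    for gene, terms in direct.items():
        out: set[str] = set()
        for term in terms:
            if term not in closure:
                closure[term] = {term} | dag.ancestors(term)
            out |= closure[term]
        full[gene] = out
    return full


def _term_gene_sets(annotations: Mapping[str, set[str]], universe: set[str]
                    ) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        if gene not in universe:
            continue
        for term in terms:
            sets.setdefault(term, set()).add(gene)
    return sets


def fisher_classic(study_set: set[str], annotations: Mapping[str, set[str]],
                   universe: set[str]) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation per term (no decorrelation)."""
    if not universe:
        raise ValueError("empty universe")
    if not study_set <= universe:
        raise ValueError("study set must be a subset of the universe")
    term_sets = _term_gene_sets(annotations, universe)
    n_univ, n_study = len(universe), len(study_set)
    rows = []
    for term in sorted(term_sets):
        annotated = len(term_sets[term])
        significant = len(term_sets[term] & study_set)
        expected = annotated * n_study / n_univ
        p = float(hypergeom.sf(significant - 1, n_univ, annotated, n_study))
        rows.append((term, annotated, significant, expected, min(p, 1.0)))
    return pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)


def go_elim(dag: OntologyDag, study_set: set[str],
            annotations: Mapping[str, set[str]], universe: set[str],
            elim_cutoff: float = 0.01) -> pd.DataFrame:
    """Leaves-to-root elimination testing.

    Terms are tested from the leaves upward; when a term's p-value is at or
    below ``elim_cutoff``, its study genes are removed from the study overlap
    of all its ancestors before those are tested. ``elim_cutoff = 0``
    reproduces :func:`fisher_classic` (on the shared term set). The
    ``annotated`` column always reports the true propagated count.
    """
    if not universe:
        raise ValueError("empty universe")
    if not study_set <= universe:
        raise ValueError("study set must be a subset of the universe")
    term_sets = _term_gene_sets(annotations, universe)
    n_univ, n_study = len(universe), len(study_set)
    eliminated: dict[str, set[str]] = {t: set() for t in term_sets}
    rows = []
    for term in dag.depth_order():
        if term not in term_sets:
            continue
        genes = term_sets[term]
        annotated = len(genes)
        overlap = (genes & study_set) - eliminated[term]
        significant = len(overlap)
        expected = annotated * n_study / n_univ
        p = float(hypergeom.sf(significant - 1, n_univ, annotated, n_study))
        p = min(p, 1.0)
        rows.append((term, annotated, significant, expected, p))
        if elim_cutoff > 0 and p <= elim_cutoff:
            removed = genes & study_set
            for ancestor in dag.ancestors(term):
                if ancestor in eliminated:
                    eliminated[ancestor] |= removed
    out = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    return out.sort_values("id", kind="stable").reset_index(drop=True)


def two_sided_fisher_p(k: int, big_k: int, n: int, big_n: int) -> float:
    """Minimum-likelihood two-sided Fisher p for a 2x2 table.

    Sums hypergeometric probabilities of every overlap in the support whose
    probability does not exceed the observed one. Computed in exact integer
    arithmetic (unnormalized weights are products of binomial coefficients),
    so ties are resolved exactly and the result is correct to the last bit of
    the final division.
    """
    lo = max(0, n + big_k - big_n)
    hi = min(n, big_k)
    if not lo <= k <= hi:
        raise ValueError("observed overlap outside the hypergeometric support")
    weights = {a: comb(big_k, a) * comb(big_n - big_k, n - a)
               for a in range(lo, hi + 1)}
    observed = weights[k]
    selected = sum(w for w in weights.values() if w <= observed)
    return min(selected / comb(big_n, n), 1.0)


def fisher_two_sided(study_set: set[str], family_sets: Mapping[str, set[str]],
                     universe: set[str]) -> pd.DataFrame:
    """Two-sided misrepresentation test per family/domain."""
    if not universe:
        raise ValueError("empty universe")
    if not study_set <= universe:
        raise ValueError("study set must be a subset of the universe")
    n_univ, n_study = len(universe), len(study_set)
    rows = []
    for family in sorted(family_sets):
        members = family_sets[family]
        if not members <= universe:
            raise ValueError(f"family {family!r} is not a subset of the universe")
        annotated = len(members)
        significant = len(members & study_set)
        expected = annotated * n_study / n_univ
        p = two_sided_fisher_p(significant, annotated, n_study, n_univ)
        rows.append((family, annotated, significant, expected, p))
    return pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)


def annotated_universe(annotations: Mapping[str, set[str]]) -> set[str]:
    """Genes with at least one (propagated) term — the default GO universe."""
    return {gene for gene, terms in annotations.items() if terms}
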