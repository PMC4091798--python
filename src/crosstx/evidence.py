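"""Cross-platform, cross-species evidence of expression and set algebra.

Each cell type is typically covered by one or two microarray hybridizations
and one RNA-seq library. Whether a gene counts as "expressed" in a cell type
is a declarative rule over two pieces of evidence: the number of arrays on
which it was called Present (``array_P``) and whether its RNA-seq counts
reached the read floor (``rnaseq``). Rules ship as presets mirroring the
common designs — P on two arrays or RNA-seq for a doubly-arrayed cell type,
P on one array or RNA-seq for singly-arrayed ones, and a strict conjunction
(RNA-seq AND at least one P call) for conservative species-exclusive sets.

Cross-species comparisons are anchored on the model-species gene ids via the
homology map; genes without a homologue keep their species-local id and can
therefore only ever appear in species-exclusive sets.

Rule mini-grammar (BNF)::

    expr   ::= term ("OR" term)*
    term   ::= factor ("AND" factor)*
    factor ::= comparison | "(" expr ")"
    comparison ::= IDENT OP INT | IDENT
    IDENT  ::= "array_P" | "rnaseq"
    OP     ::= ">=" | "<=" | ">" | "<" | "=="

A bare identifier is truthy (nonzero / True).
"""
from __future__ import annotations

import re
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

_TOKEN = re.compile(r"\s*(>=|<=|==|>|<|\(|\)|[A-Za-z_][A-Za-z_0-9]*|\d+)")
_FIELDS = ("array_P", "rnaseq")


class Rule:
    """A declarative expression predicate over an evidence record."""

    def __init__(self, expression: str):
        self.expression = expression
        self._tokens = self._tokenize(expression)
        self._pos = 0
        self._ast = self._parse_expr()
        if self._pos != len(self._tokens):
            raise ValueError(f"trailing tokens in rule {expression!r}")

    @staticmethod
    def _tokenize(expression: str) -> list[str]:
        tokens, pos = [], 0
        while pos < len(expression):
            match = _TOKEN.match(expression, pos)
            if not match:
                raise ValueError(f"cannot tokenize rule at {expression[pos:]!r}")
            tokens.append(match.group(1))
            pos = match.end()
        return tokens

    def _peek(self):
        return self._tokens[self._pos] if self._pos < len(self._tokens) else None

    def _next(self):
        token = self._peek()
        self._pos += 1
        return token

    def _parse_expr(self):
        node = self._parse_term()
        while self._peek() in ("OR", "or"):
            self._next()
            node = ("or", node, self._parse_term())
        return node

    def _parse_term(self):
        node = self._parse_factor()
        while self._peek() in ("AND", "and"):
            self._next()
            node = ("and", node, self._parse_factor())
        return node

    def _parse_factor(self):
        token = self._next()
        if token == "(":
            node = self._parse_expr()
            if self._next() != ")":
                raise ValueError(f"unbalanced parentheses in rule {self.expression!r}")
            return node
        if token not in _FIELDS:
            raise ValueError(f"unknown field {token!r} in rule {self.expression!r}")
        if self._peek() in (">=", "<=", ">", "<", "=="):
            op = self._next()
            value = self._next()
            if value is None or not value.isdigit():
                raise ValueError(f"expected integer after {op!r} in rule {self.expression!r}")
            return ("cmp", token, op, int(value))
        return ("truthy", token)

    def _eval(self, node, record: Mapping) -> bool:
        kind = node[0]
        if kind == "or":
            return self._eval(node[1], record) or self._eval(node[2], record)
        if kind == "and":
            return self._eval(node[1], record) and self._eval(node[2], record)
        if kind == "truthy":
            return bool(record[node[1]])
        _, field, op, value = node
        x = int(record[field])
        return {"<": x < value, "<=": x <= value, ">": x > value,
                ">=": x >= value, "==": x == value}[op]

    def __call__(self, array_P: int = 0, rnaseq: bool = False) -> bool:
        return self._eval(self._ast, {"array_P": array_P, "rnaseq": rnaseq})

    def __repr__(self):
        return f"Rule({self.expression!r})"


#: Rule presets for the standard designs: a doubly-arrayed germline founder
#: cell (P on both arrays, or RNA-seq), singly-arrayed gametes (P on the one
#: array, or RNA-seq), the strict conjunction used for conservative
#: species-exclusive calls, and an RNA-seq-only platform.
RULE_PRESETS: dict[str, str] = {
    "aic": "array_P>=2 OR rnaseq",
    "egg": "array_P>=1 OR rnaseq",
    "central": "array_P>=1 OR rnaseq",
    "aic_exclusive": "rnaseq AND array_P>=1",
    "rnaseq_only": "rnaseq",
    "array_any": "array_P>=1",
}


def get_rule(name_or_expression: str) -> Rule:
    return Rule(RULE_PRESETS.get(name_or_expression, name_or_expression))


def build_evidence(calls: pd.DataFrame, expressed: Mapping[str, set[str]],
                   homology: Mapping[str, str | None] | None,
                   design: pd.DataFrame) -> pd.DataFrame:
    """Combine platform evidence into one record per (gene, cell type).

    Parameters
    ----------
    calls:
        Long-format presence calls (``probeset, array, p, call``); probeset
        ids are taken to be anchored gene ids (one probeset per gene, as with
        gene-level custom array annotations).
    expressed:
        Per RNA-seq sample sets of expressed genes (read-floor rule), keyed
        by sample name, with species-local gene ids.
    homology:
        Mapping of species-local gene id -> anchored gene id (or None).
        ``None`` homologues (and a ``homology=None`` argument) keep the
        species-local id. Many-to-one homology unions the evidence.
    design:
        One row per sample: columns ``sample, platform`` ("array" or
        "rnaseq"), ``cell_type``.

    Returns a frame indexed by (gene, cell_type) with columns
    ``array_P, n_arrays, rnaseq, n_rnaseq``.
    """
    required = {"sample", "platform", "cell_type"}
    if not required <= set(design.columns):
        raise ValueError(f"design needs columns {sorted(required)}")
    if design["sample"].duplicated().any():
        raise ValueError("each sample must appear once in the design")
    sample_cell = dict(zip(design["sample"], design["cell_type"]))
    sample_platform = dict(zip(design["sample"], design["platform"]))
    known_arrays = {s for s, p in sample_platform.items() if p == "array"}
    unknown = set(calls["array"]) - known_arrays
    if unknown:
        raise ValueError(f"arrays absent from the design: {sorted(unknown)}")
    unknown = set(expressed) - {s for s, p in sample_platform.items() if p == "rnaseq"}
    if unknown:
        raise ValueError(f"rnaseq samples absent from the design: {sorted(unknown)}")

    def anchor(gene: str) -> str:
        if homology is None:
            return gene
        target = homology.get(gene)
        return gene if target is None else target

    records: dict[tuple[str, str], dict] = {}

    def record(gene: str, cell: str) -> dict:
        return records.setdefault((gene, cell), {"array_P": 0, "rnaseq": 0})

    p_calls = calls[calls["call"] == "P"]
    for probeset, array in zip(p_calls["probeset"], p_calls["array"]):
        record(probeset, sample_cell[array])["array_P"] += 1
    for sample, genes in expressed.items():
        cell = sample_cell[sample]
        anchored = {anchor(g) for g in genes}
        for gene in anchored:
            record(gene, cell)["rnaseq"] += 1

    arrays_per_cell = design[design["platform"] == "array"].groupby("cell_type")[
        "sample"].nunique()
    rnaseq_per_cell = design[design["platform"] == "rnaseq"].groupby("cell_type")[
        "sample"].nunique()
    rows = []
    for (gene, cell), rec in sorted(records.items()):
        rows.append((gene, cell, rec["array_P"], int(arrays_per_cell.get(cell, 0)),
                     rec["rnaseq"] > 0, int(rnaseq_per_cell.get(cell, 0))))
    out = pd.DataFrame(rows, columns=["gene", "cell_type", "array_P", "n_arrays",
                                      "rnaseq", "n_rnaseq"])
    return out.set_index(["gene", "cell_type"])


def expressed_under(evidence: pd.DataFrame, cell_type: str, rule: Rule | str) -> set[str]:
    """Genes of one cell type satisfying an expression rule."""
    rule = get_rule(rule) if isinstance(rule, str) else rule
    sub = evidence.xs(cell_type, level="cell_type")
    return {gene for gene, row in sub.iterrows()
            if rule(array_P=int(row["array_P"]), rnaseq=bool(row["rnaseq"]))}


def overlap_counts(sets: Mapping[str, set]) -> dict[str, int]:
    """Venn region cardinalities for 2 or 3 labelled sets.

    Region keys join the member labels with ``&`` (e.g. ``A``, ``A&B``).
    The regions partition the union.
    """
    labels = list(sets)
    if len(labels) not in (2, 3):
        raise ValueError("overlap_counts handles 2 or 3 sets")
    regions: dict[str, int] = {}
    universe = set().union(*sets.values())
    for r in range(1, len(labels) + 1):
        for inside in combinations(labels, r):
            members = set.intersection(*(sets[l] for l in inside))
            for label in labels:
                if label not in inside:
                    members = members - sets[label]
            regions["&".join(inside)] = len(members)
    assert sum(regions.values()) == len(universe)
    return regions


def exclusive_sets(evidence_a: pd.DataFrame, evidence_b: pd.DataFrame,
                   cell_type: str, rule_a: Rule | str, rule_b: Rule | str
                   ) -> tuple[set[str], set[str], set[str]]:
    """Split one cell type's genes into (A-only, B-only, shared).

    Both evidence tables must live on the anchored (shared) gene-id space.
    The three sets partition the union of genes expressed under either rule.
    """
    set_a = expressed_under(evidence_a, cell_type, rule_a)
    set_b = expressed_under(evidence_b, cell_type, rule_b)
    return set_a - set_b, set_b - set_a, set_a & set_b


def multi_sample_expressed(sample_evidence: Mapping[str, Iterable[str]],
                           min_samples: int = 2) -> set[str]:
    """Genes with evidence in at least ``min_samples`` independent samples.

    Each entry of ``sample_evidence`` is one sample's evidence set (an array's
    P-called genes, or an RNA-seq library's expressed genes).
    """
    if len(sample_evidence) < 2:
        raise ValueError("need at least two samples")
    tally: dict[str, int] = {}
    for genes in sample_evidence.values():
        for gene in set(genes):
            tally[gene] = tally.get(gene, 0) + 1
    return {gene for gene, n in tally.items() if n >= min_samples}
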