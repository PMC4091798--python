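"""Plain-text readers and writers shared by the pipeline stages.

All tabular formats are tab-delimited with a header row; matrices carry the
row-id in the first column. FASTA goes through Biopython so sequence handling
(wrapping, alphabet) follows the usual conventions.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROBE_COLUMNS = ["probeset_id", "probe_id", "sequence"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_probe_library(path: str | Path) -> pd.DataFrame:
    """Read a probe library TSV: ``probeset_id<TAB>probe_id<TAB>sequence``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe library is missing columns: {missing}")
    return df[PROBE_COLUMNS]


def write_probe_library(library: pd.DataFrame, path: str | Path) -> None:
    library[PROBE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a numeric matrix TSV (first column = row ids, header = column ids)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_gene_set(path: str | Path) -> set[str]:
    """Read a one-id-per-line text file into a set."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(genes):
            fh.write(f"{gene}\n")


def read_dag_edges(path: str | Path) -> list[tuple[str, str]]:
    """Read is_a edges as ``child<TAB>parent`` rows (header optional)."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "child" and parts[1] == "parent":
                continue
            if len(parts) != 2:
                raise ValueError(f"malformed DAG edge line: {line!r}")
            edges.append((parts[0], parts[1]))
    return edges


def write_dag_edges(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("child\tparent\n")
        for child, parent in edges:
            fh.write(f"{child}\t{parent}\n")


def read_gene2term(path: str | Path) -> dict[str, set[str]]:
    """Read direct gene→term annotations (``gene<TAB>term`` long format)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        mapping.setdefault(gene, set()).add(term)
    return mapping


def write_gene2term(mapping: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tterm\n")
        for gene in sorted(mapping):
            for term in sorted(mapping[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_families(path: str | Path) -> dict[str, set[str]]:
    """Read family membership (``family<TAB>gene`` long format) into family→genes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    fams: dict[str, set[str]] = {}
    for fam, gene in zip(df["family"], df["gene"]):
        fams.setdefault(fam, set()).add(gene)
    return fams


def write_families(families: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tgene\n")
        for fam in sorted(families):
            for gene in sorted(families[fam]):
                fh.write(f"{fam}\t{gene}\n")
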