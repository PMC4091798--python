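"""Closest-homologue assignment from PSL alignments.

A de novo transcriptome aligned against the reference cDNA of a related model
species yields many partial alignments per gene pair. The homologue of a gene
is the partner gene with the highest summed alignment score over all records
of the pair, provided the pair's total aligned length reaches a floor
(default 100 bp); otherwise the gene maps to none. Transcript-variant IDs of
the form ``comp<digits>_c<digits>_seq<digits>`` are collapsed to their gene
(``comp..._c...``) on both sides before summing.

PSL is BLAT's 21-column tab format with 0-based half-open coordinates. The
per-record score used here is the standard BLAT score
``matches + repMatches - misMatches - qNumInsert - tNumInsert``.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

PSL_COLUMNS = [
    "matches", "misMatches", "repMatches", "nCount",
    "qNumInsert", "qBaseInsert", "tNumInsert", "tBaseInsert",
    "strand", "qName", "qSize", "qStart", "qEnd",
    "tName", "tSize", "tStart", "tEnd",
    "blockCount", "blockSizes", "qStarts", "tStarts",
]
_INT_FIELDS = {c for c in PSL_COLUMNS if c not in
               {"strand", "qName", "tName", "blockSizes", "qStarts", "tStarts"}}

VARIANT_PATTERN = re.compile(r"^(comp\d+_c\d+)_seq\d+$")


@dataclass(frozen=True)
class PslRecord:
    matches: int
    misMatches: int
    repMatches: int
    nCount: int
    qNumInsert: int
    qBaseInsert: int
    tNumInsert: int
    tBaseInsert: int
    strand: str
    qName: str
    qSize: int
    qStart: int
    qEnd: int
    tName: str
    tSize: int
    tStart: int
    tEnd: int
    blockCount: int
    blockSizes: str
    qStarts: str
    tStarts: str

    def block_size_list(self) -> list[int]:
        return [int(x) for x in self.blockSizes.rstrip(",").split(",") if x]

    def validate(self) -> None:
        if not (0 <= self.qStart < self.qEnd <= self.qSize):
            raise ValueError(f"invalid query coordinates on {self.qName}")
        if not (0 <= self.tStart < self.tEnd <= self.tSize):
            raise ValueError(f"invalid target coordinates on {self.tName}")
        total = self.matches + self.misMatches + self.repMatches + self.nCount
        if sum(self.block_size_list()) != total:
            raise ValueError(
                f"block sizes inconsistent with match counts for {self.qName}->{self.tName}")


def read_psl(path: str | Path) -> list[PslRecord]:
    """Parse a PSL file; a 5-line psLayout header is auto-detected and skipped.

    Records violating the format invariants are rejected with a warning; a
    line with the wrong column count raises with its line number.
    """
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    if lines and lines[0].startswith("psLayout"):
        start = 5
    records: list[PslRecord] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 21:
            raise ValueError(f"line {lineno}: expected 21 PSL columns, got {len(parts)}")
        kwargs = {}
        for name, value in zip(PSL_COLUMNS, parts):
            kwargs[name] = int(value) if name in _INT_FIELDS else value
        record = PslRecord(**kwargs)
        try:
            record.validate()
        except ValueError as exc:
            warnings.warn(f"line {lineno}: rejected PSL record ({exc})")
            continue
        records.append(record)
    return records


def write_psl(records, path: str | Path, header: bool = False) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("psLayout version 3\n\n")
            fh.write("match\tmis-\trep.\tN's\tQ gap\tQ gap\tT gap\tT gap\tstrand\tQ\n")
            fh.write("\tmatch\tmatch\t\tcount\tbases\tcount\tbases\t\tname\n")
            fh.write("-" * 70 + "\n")
        for rec in records:
            fh.write("\t".join(str(getattr(rec, f.name)) for f in fields(PslRecord)) + "\n")


def psl_score(record: PslRecord) -> float:
    """Standard BLAT score: matches + repMatches - misMatches - qNumInsert - tNumInsert."""
    return float(record.matches + record.repMatches - record.misMatches
                 - record.qNumInsert - record.tNumInsert)


def variant_gene(variant_id: str, pattern: re.Pattern = VARIANT_PATTERN,
                 warn: bool = True) -> str:
    """Collapse a transcript-variant ID (``comp76373_c0_seq1``) to its gene ID.

    IDs that do not match the pattern pass through unchanged (their own gene),
    with a warning.
    """
    match = pattern.match(variant_id)
    if match:
        return match.group(1)
    if warn:
        warnings.warn(f"id {variant_id!r} has no variant suffix; treated as its own gene")
    return variant_id


def assign_homologues(records, min_total_len: int = 100, side: str = "query",
                      collapse: bool = True) -> pd.DataFrame:
    """Best-partner assignment by summed per-pair scores with a length floor.

    Per (query_gene, target_gene) pair, scores and aligned lengths are summed
    over all records; each query gene gets the target gene with the highest
    score sum among pairs whose aligned length reaches ``min_total_len``
    (query-side span by default, target-side with ``side='target'``). Ties
    break to the lexicographically smallest target. With ``side='target'`` the
    roles are swapped (each target gene gets its best query partner).

    Returns a DataFrame with columns
    ``query_gene, target_gene, score_sum, aligned_length`` where
    ``target_gene`` is NA when no pair passes the floor.
    """
    if side not in ("query", "target"):
        raise ValueError("side must be 'query' or 'target'")
    pairs: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        qg = variant_gene(rec.qName, warn=False) if collapse else rec.qName
        tg = variant_gene(rec.tName, warn=False) if collapse else rec.tName
        if side == "target":
            qg, tg = tg, qg
            length = rec.tEnd - rec.tStart
        else:
            length = rec.qEnd - rec.qStart
        entry = pairs.setdefault((qg, tg), [0.0, 0])
        entry[0] += psl_score(rec)
        entry[1] += length
    by_query: dict[str, list[tuple[str, float, int]]] = {}
    for (qg, tg), (score, length) in pairs.items():
        by_query.setdefault(qg, []).append((tg, score, length))
    rows = []
    for qg in sorted(by_query):
        candidates = by_query[qg]
        eligible = [c for c in candidates if c[2] >= min_total_len]
        if eligible:
            # highest score sum; lexicographically smallest target on ties
            best_score = max(c[1] for c in eligible)
            best = min((c for c in eligible if c[1] == best_score), key=lambda c: c[0])
            rows.append((qg, best[0], best[1], best[2]))
        else:
            top = max(candidates, key=lambda c: c[1])
            rows.append((qg, pd.NA, top[1], top[2]))
    return pd.DataFrame(rows, columns=["query_gene", "target_gene", "score_sum",
                                       "aligned_length"])


def homology_dict(assignment: pd.DataFrame) -> dict[str, str | None]:
    """Mapping query_gene -> target_gene (None where no homologue passed)."""
    return {q: (None if pd.isna(t) else t)
            for q, t in zip(assignment["query_gene"], assignment["target_gene"])}
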