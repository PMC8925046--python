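"""Readers and writers for every external representation.

Formats are deliberately plain: delimited two-column association tables
(TSV or CSV, picked by extension), FASTA / aligned FASTA via Biopython,
flat MeSH-style tree-code tables, BLAST outfmt-6-style identity tables, and
labelled TSV matrices for similarities and scores.  Matrix round-trips are
bit-exact (floats are written at full shortest-repr precision).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import (
    AlignedBlock,
    AssociationDataset,
    DistanceMatrix,
    ScoreMatrix,
    SequenceSet,
    SimilarityMatrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "load_associations",
    "load_fasta",
    "load_aligned_fasta",
    "load_tree_codes",
    "read_identity_table",
    "write_associations",
    "write_similarity",
    "read_similarity",
    "write_scores",
    "read_scores",
    "write_fasta",
    "write_tree_codes",
]

_TREE_CODE_RE = re.compile(r"^[A-Za-z0-9]+(\.[A-Za-z0-9]+)*$")

UNAVAILABLE = "unavailable"


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _read_rows(path: str | Path, min_fields: int) -> list[list[str]]:
    sep = _sep_for(path)
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split(sep)]
            if len(fields) < min_fields or any(
                not f for f in fields[:min_fields]
            ):
                raise ValueError(
                    f"{path}: line {lineno} has a missing field: {line!r}"
                )
            rows.append(fields)
    if not rows:
        raise ValueError(f"{path}: empty table")
    return rows


_HEADER_WORDS = {"microbe", "disease", "microbe_name", "disease_name", "code"}


def load_associations(path: str | Path) -> AssociationDataset:
    """Load a two-column (microbe, disease) table into a binary matrix.

    Duplicate pairs collapse to a single association (the count of collapsed
    rows is logged).  Names are sorted lexicographically so the matrix layout
    is independent of input row order.  An optional third column carries a
    sequence accession per microbe; the value ``unavailable`` flags microbes
    with no usable sequence.
    """
    rows = _read_rows(path, min_fields=2)
    if rows and rows[0][0].lower() in _HEADER_WORDS:
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: table holds only a header row")
    pairs = {(r[0], r[1]) for r in rows}
    n_dup = len(rows) - len(pairs)
    if n_dup:
        logger.info("collapsed %d duplicate association rows", n_dup)
    accessions: dict[str, str] = {}
    for r in rows:
        if len(r) >= 3 and r[2]:
            accessions[r[0]] = r[2]
    microbes = sorted({m for m, _ in pairs})
    diseases = sorted({d for _, d in pairs})
    mi = {m: i for i, m in enumerate(microbes)}
    di = {d: j for j, d in enumerate(diseases)}
    matrix = np.zeros((len(microbes), len(diseases)), dtype=np.int8)
    for m, d in pairs:
        matrix[mi[m], di[d]] = 1
    return AssociationDataset(
        microbes, diseases, matrix, accessions=accessions or None
    )


def load_fasta(
    path: str | Path, expected: list[str] | None = None
) -> SequenceSet:
    """Read FASTA records, uppercasing sequences.

    When ``expected`` names are given (e.g. the dataset's microbe labels),
    names absent from the file are flagged unavailable.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: FASTA record with malformed header")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty sequence for {rec.id!r}")
        records[rec.id] = seq
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    availability = {name: True for name in records}
    if expected is not None:
        for name in expected:
            availability.setdefault(name, name in records)
    return SequenceSet(records, availability)


def load_aligned_fasta(path: str | Path) -> AlignedBlock:
    sset = load_fasta(path)
    labels = list(sset.records)
    return AlignedBlock(labels, [sset.records[n] for n in labels])


def load_tree_codes(path: str | Path) -> dict[str, set[str]]:
    """Read a flat (disease, tree-code) table; a disease may repeat."""
    rows = _read_rows(path, min_fields=2)
    if rows and rows[0][0].lower() in _HEADER_WORDS:
        rows = rows[1:]
    codes: dict[str, set[str]] = {}
    for disease, code, *_ in rows:
        if not _TREE_CODE_RE.match(code):
            raise ValueError(f"{path}: invalid tree code {code!r} for {disease!r}")
        codes.setdefault(disease, set()).add(code)
    for disease, cset in codes.items():
        if not cset:
            raise ValueError(f"{path}: disease {disease!r} has no codes")
    if not codes:
        raise ValueError(f"{path}: no tree codes parsed")
    return codes


def read_identity_table(
    path: str | Path, names: list[str]
) -> SimilarityMatrix:
    """Ingest a BLAST tabular (outfmt-6-style) pairwise identity table.

    Only the first three columns (query, subject, percent identity) are
    used; extra columns are ignored.  The matrix is symmetrized by taking
    the maximum of the (i, j) and (j, i) records, missing pairs default to
    0 identity, and the diagonal is forced to the maximum observed
    self-identity (100 when no self hits are present).
    """
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    values = np.zeros((n, n))
    max_self = 0.0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: need >= 3 columns")
            q, s, pident = fields[0], fields[1], float(fields[2])
            if not 0.0 <= pident <= 100.0:
                raise ValueError(
                    f"{path}: line {lineno}: identity {pident} outside [0, 100]"
                )
            if q not in idx or s not in idx:
                continue
            i, j = idx[q], idx[s]
            if i == j:
                max_self = max(max_self, pident)
            values[i, j] = max(values[i, j], pident)
    values = np.maximum(values, values.T)
    np.fill_diagonal(values, max_self if max_self > 0 else 100.0)
    return SimilarityMatrix(list(names), values)


# ---------------------------------------------------------------------------
# writers


def write_associations(dataset: AssociationDataset, path: str | Path) -> None:
    sep = _sep_for(path)
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in dataset.positives():
            fields = [dataset.microbe_names[i], dataset.disease_names[j]]
            if dataset.accessions:
                fields.append(dataset.accessions.get(fields[0], ""))
            fh.write(sep.join(fields) + "\n")


def _write_named_frame(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    _write_named_frame(sim.to_frame(), path)


def read_similarity(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return SimilarityMatrix([str(c) for c in df.columns], df.to_numpy(float))


def write_scores(scores: ScoreMatrix, path: str | Path) -> None:
    _write_named_frame(scores.to_frame(), path)


def read_scores(path: str | Path, augmented: bool = False) -> ScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ScoreMatrix(
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(float),
        augmented=augmented,
    )


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.records.items():
            fh.write(f">{name}\n")
            for k in range(0, len(seq), 70):
                fh.write(seq[k : k + 70] + "\n")


def write_tree_codes(codes: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for disease in sorted(codes):
            for code in sorted(codes[disease]):
                fh.write(f"{disease}\t{code}\n")


def write_distance(dist: DistanceMatrix, path: str | Path) -> None:
    _write_named_frame(dist.to_frame(), path)
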