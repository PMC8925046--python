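"""Microbe-microbe similarity from marker-gene (16S rRNA) sequences.

Two complementary views of sequence relatedness are fused:

* **Sequence similarity (MSS)** — percent identity of a global pairwise
  alignment (match +1, mismatch -1, linear gap -2 by default), min-max
  normalized over the whole identity matrix.  Precomputed identity tables
  (BLAST tabular) can be ingested instead of aligning internally.
* **Evolutionary-distance similarity (MES)** — p-distance (fraction of
  differing sites) on a multiple alignment after terminal trimming and
  complete deletion of gap/ambiguous columns; similarity is 1 - p, again
  min-max normalized.

Microbes whose sequence is unavailable are imputed with the mean of the
available off-diagonal similarities.  The final microbe similarity is the
elementwise mean of MSS and MES.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from Bio import Align

from .containers import (
    AlignedBlock,
    DistanceMatrix,
    SequenceSet,
    SimilarityMatrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentScoring",
    "pairwise_identity",
    "identity_matrix",
    "sequence_similarity",
    "complete_deletion",
    "p_distance",
    "evolutionary_similarity",
    "impute_missing",
    "fuse_similarities",
    "build_microbe_similarity",
]


@dataclass(frozen=True)
class AlignmentScoring:
    """Global-alignment scoring scheme (linear gap penalty)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap
    aligner.extend_gap_score = scoring.gap
    return aligner


def pairwise_identity(
    a: str, b: str, scoring: AlignmentScoring | None = None
) -> float:
    """Percent identity of the optimal global alignment of two sequences.

    identity = 100 * matched columns / alignment length.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if "-" in a or "-" in b:
        raise ValueError("pairwise_identity expects ungapped sequences")
    aligner = _aligner(scoring or AlignmentScoring())
    alignment = next(iter(aligner.align(a, b)))
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / columns


def identity_matrix(
    seqs: SequenceSet,
    names: list[str] | None = None,
    scoring: AlignmentScoring | None = None,
) -> SimilarityMatrix:
    """All-vs-all percent identities for the available sequences."""
    if names is None:
        names = sorted(seqs.records)
    avail = [n for n in names if seqs.availability.get(n, False) and n in seqs.records]
    if not avail:
        raise ValueError("no available sequences to align")
    n = len(avail)
    values = np.zeros((n, n))
    np.fill_diagonal(values, 100.0)
    for (i, a), (j, b) in combinations(enumerate(avail), 2):
        ident = pairwise_identity(seqs.records[a], seqs.records[b], scoring)
        values[i, j] = values[j, i] = ident
    return SimilarityMatrix(avail, values)


def _minmax(values: np.ndarray, what: str) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        warnings.warn(
            f"{what}: constant matrix, min-max normalization degenerate; "
            "returning zeros",
            RuntimeWarning,
            stacklevel=3,
        )
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def sequence_similarity(iden: SimilarityMatrix) -> SimilarityMatrix:
    """Min-max normalize an identity matrix over all entries (diagonal too)."""
    return SimilarityMatrix(iden.names, _minmax(iden.values, "identity matrix"))


def complete_deletion(block: AlignedBlock) -> AlignedBlock:
    """Trim terminal gap overhangs, then drop every gap/'N' column.

    First, leading and trailing columns covered by any row's terminal gap
    run are removed (sequences trimmed down to common 5'/3' extent); then
    any remaining column containing '-' or 'N' in any row is deleted.
    """
    arr = block.as_array()
    n_rows, n_cols = arr.shape
    if n_cols == 0:
        raise ValueError("empty alignment")
    start, end = 0, n_cols
    for row in arr:
        non_gap = np.flatnonzero(row != b"-")
        if non_gap.size == 0:
            raise ValueError("alignment row is all gaps")
        start = max(start, int(non_gap[0]))
        end = min(end, int(non_gap[-1]) + 1)
    if start >= end:
        raise ValueError(
            "terminal trimming removed all columns; sequences do not overlap"
        )
    arr = arr[:, start:end]
    keep = ~np.any((arr == b"-") | (arr == b"N"), axis=0)
    if not keep.any():
        raise ValueError(
            "complete deletion removed every column; supply a less gapped "
            "alignment or fall back to pairwise identities"
        )
    arr = arr[:, keep]
    seqs = [row.tobytes().decode() for row in arr]
    return AlignedBlock(list(block.labels), seqs)


def p_distance(block: AlignedBlock) -> DistanceMatrix:
    """Proportion of differing sites for every sequence pair.

    Expects a complete-deletion block (no gaps or ambiguous sites).
    """
    arr = block.as_array()
    if arr.shape[1] == 0:
        raise ValueError("no sites to compare")
    if np.any((arr == b"-") | (arr == b"N")):
        raise ValueError("apply complete_deletion before p_distance")
    n = arr.shape[0]
    values = np.zeros((n, n))
    for i in range(n):
        diff = arr[i + 1 :] != arr[i]
        values[i, i + 1 :] = diff.mean(axis=1)
    values = values + values.T
    return DistanceMatrix(list(block.labels), values)


def evolutionary_similarity(dist: DistanceMatrix) -> SimilarityMatrix:
    """1 - p-distance, then global min-max normalization."""
    ed = 1.0 - dist.values
    return SimilarityMatrix(dist.names, _minmax(ed, "evolutionary distance"))


def impute_missing(
    sim: SimilarityMatrix, missing: set[str] | list[str]
) -> SimilarityMatrix:
    """Expand a similarity matrix to cover sequence-less microbes.

    Every off-diagonal cell in a missing microbe's row/column is set to the
    mean of the available microbes' off-diagonal similarities; the diagonal
    is 1.  Matrix rows for missing names may be absent from ``sim`` (they
    are appended) or present (they are overwritten).
    """
    missing = set(missing)
    all_names = sorted(set(sim.names) | missing)
    available = [n for n in all_names if n not in missing]
    if not available:
        raise ValueError("every microbe is missing; nothing to impute from")
    if len(available) == 1:
        mean = 0.0
        logger.warning("single available microbe; imputing 0 off-diagonal")
    else:
        sub = sim.reindex(available).values
        off = ~np.eye(len(available), dtype=bool)
        mean = float(sub[off].mean())
    n = len(all_names)
    idx = {name: i for i, name in enumerate(all_names)}
    values = np.full((n, n), mean)
    avail_idx = [idx[name] for name in available]
    if len(available) >= 1:
        sub = sim.reindex(available).values
        values[np.ix_(avail_idx, avail_idx)] = sub
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(all_names, values)


def fuse_similarities(
    mss: SimilarityMatrix, mes: SimilarityMatrix
) -> SimilarityMatrix:
    """Elementwise mean of the two sequence-derived similarities."""
    if mss.names != mes.names:
        raise ValueError("similarity matrices cover different name sets")
    return SimilarityMatrix(mss.names, (mss.values + mes.values) / 2.0)


def _pairwise_block(
    a_name: str, a: str, b_name: str, b: str, scoring: AlignmentScoring
) -> AlignedBlock:
    aligner = _aligner(scoring)
    alignment = next(iter(aligner.align(a, b)))
    return AlignedBlock(
        [a_name, b_name], [str(alignment[0]).upper(), str(alignment[1]).upper()]
    )


def build_microbe_similarity(
    seqs: SequenceSet,
    names: list[str],
    msa: AlignedBlock | None = None,
    identity: SimilarityMatrix | None = None,
    scoring: AlignmentScoring | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix, SimilarityMatrix]:
    """Full sequence-similarity pipeline: returns (MSS, MES, fused S_m).

    ``names`` is the full microbe roster (typically the association
    dataset's); microbes absent or flagged unavailable in ``seqs`` are mean
    imputed in both similarity views.  ``msa`` supplies a multiple alignment
    for the p-distance path; without one, each pair is globally aligned and
    complete deletion is applied per pair.  ``identity`` short-circuits the
    internal aligner with a precomputed identity matrix.
    """
    scoring = scoring or AlignmentScoring()
    avail = [
        n for n in names if seqs.availability.get(n, False) and n in seqs.records
    ]
    missing = [n for n in names if n not in avail]
    if not avail:
        raise ValueError("no microbe has an available sequence")

    if identity is None:
        identity = identity_matrix(seqs, avail, scoring)
    else:
        identity = identity.reindex(avail)
    mss = sequence_similarity(identity)

    if msa is not None:
        order = [lab for lab in msa.labels if lab in avail]
        sub = AlignedBlock(
            order,
            [msa.sequences[msa.labels.index(lab)] for lab in order],
        )
        dist = p_distance(complete_deletion(sub)).reindex(avail)
    else:
        n = len(avail)
        values = np.zeros((n, n))
        for (i, a), (j, b) in combinations(enumerate(avail), 2):
            block = _pairwise_block(
                a, seqs.records[a], b, seqs.records[b], scoring
            )
            pd_ij = p_distance(complete_deletion(block)).values[0, 1]
            values[i, j] = values[j, i] = pd_ij
        dist = DistanceMatrix(avail, values)
    mes = evolutionary_similarity(dist)

    if missing:
        mss = impute_missing(mss, missing)
        mes = impute_missing(mes, missing)
    mss = mss.reindex(list(names))
    mes = mes.reindex(list(names))
    return mss, mes, fuse_similarities(mss, mes)
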