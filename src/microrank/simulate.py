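"""Synthetic test worlds: planted-block networks, sequence families, hierarchies.

The generator emulates the three real inputs of the pipeline without any
download.  Microbes and diseases are partitioned into blocks; associations
occur with probability ``p_in`` inside a block and ``p_out`` across blocks,
so the network carries recoverable group structure.  Each block also gets a
random ancestral marker-gene sequence from which member sequences diverge by
i.i.d. substitutions at rate ``mu`` (the same block partition couples
network and sequences, making sequence similarity informative about
associations by construction).  Disease tree codes are drawn as a random
rooted forest of dot-delimited codes so prefix nesting mirrors a curated
hierarchy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import AlignedBlock, AssociationDataset, SequenceSet

__all__ = [
    "SyntheticSpec",
    "make_network",
    "make_sequences",
    "make_disease_dag",
    "make_world",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic study.

    nm, nd: numbers of microbes and diseases; n_blocks: planted groups;
    p_in / p_out: association probabilities within / across blocks;
    length: marker-gene length; mu: per-site substitution rate away from the
    block ancestor; branching / depth: disease-hierarchy shape;
    unavailable_fraction: share of microbes whose sequence is withheld.
    """

    nm: int = 60
    nd: int = 12
    n_blocks: int = 2
    p_in: float = 0.5
    p_out: float = 0.02
    length: int = 300
    mu: float = 0.05
    branching: int = 3
    depth: int = 3
    unavailable_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if self.p_in == self.p_out:
            warnings.warn(
                "p_in == p_out: network has no recoverable block structure",
                RuntimeWarning,
                stacklevel=2,
            )
        if not 0.0 <= self.mu <= 0.75:
            raise ValueError("mu must lie in [0, 0.75]")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.nm < 1 or self.nd < 1 or self.n_blocks < 1:
            raise ValueError("nm, nd, n_blocks must be positive")
        if self.branching < 1 or self.depth < 1:
            raise ValueError("branching and depth must be >= 1")
        if not 0.0 <= self.unavailable_fraction < 1.0:
            raise ValueError("unavailable_fraction must lie in [0, 1)")


def _blocks(n: int, n_blocks: int) -> np.ndarray:
    """Balanced block assignment 0..n_blocks-1 for n items."""
    return np.arange(n) % n_blocks


def microbe_name(i: int) -> str:
    return f"m{i:04d}"


def disease_name(j: int) -> str:
    return f"d{j:03d}"


def make_network(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[AssociationDataset, np.ndarray, np.ndarray]:
    """Planted-block bipartite association network.

    Returns the dataset plus the microbe and disease block assignments.
    Rows / columns that come out empty are resampled (every microbe and
    disease is guaranteed at least one association so cross-validation
    always has candidates).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mb = _blocks(spec.nm, spec.n_blocks)
    db = _blocks(spec.nd, spec.n_blocks)
    prob = np.where(mb[:, None] == db[None, :], spec.p_in, spec.p_out)
    matrix = (rng.random((spec.nm, spec.nd)) < prob).astype(np.int8)
    # resample empty rows / columns until connected (bounded)
    for _ in range(1000):
        empty_rows = np.flatnonzero(matrix.sum(axis=1) == 0)
        empty_cols = np.flatnonzero(matrix.sum(axis=0) == 0)
        if empty_rows.size == 0 and empty_cols.size == 0:
            break
        for i in empty_rows:
            matrix[i] = (rng.random(spec.nd) < prob[i]).astype(np.int8)
        for j in empty_cols:
            matrix[:, j] = (rng.random(spec.nm) < prob[:, j]).astype(np.int8)
    else:  # pragma: no cover - p_in > 0 guarantees eventual success
        raise RuntimeError("could not produce a network without empty rows")
    # final guarantee: force one deterministic positive if resampling stalls
    for i in np.flatnonzero(matrix.sum(axis=1) == 0):  # pragma: no cover
        matrix[i, int(rng.integers(spec.nd))] = 1
    dataset = AssociationDataset(
        [microbe_name(i) for i in range(spec.nm)],
        [disease_name(j) for j in range(spec.nd)],
        matrix,
    )
    return dataset, mb, db


def make_sequences(
    spec: SyntheticSpec,
    microbe_blocks: np.ndarray,
    rng: np.random.Generator | None = None,
    terminal_gaps: bool = False,
) -> SequenceSet:
    """Star-like sequence families: one random ancestor per block.

    Each microbe's sequence is its block ancestor with i.i.d. substitutions
    at rate ``mu`` (a substituted site takes one of the three other bases
    uniformly).  Sequences are emitted pre-aligned (equal length, gap-free);
    with ``terminal_gaps`` random 5'/3' gap padding is added to exercise
    terminal trimming.  A ``spec.unavailable_fraction`` share of microbes is
    flagged sequence-unavailable.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_blocks = int(microbe_blocks.max()) + 1
    ancestors = rng.integers(0, 4, size=(n_blocks, spec.length))
    records: dict[str, str] = {}
    for i, blk in enumerate(microbe_blocks):
        seq = ancestors[blk].copy()
        hit = rng.random(spec.length) < spec.mu
        # shift by 1..3 mod 4: uniform over the three other bases
        seq[hit] = (seq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        s = _BASES[seq].tobytes().decode()
        if terminal_gaps:
            left = int(rng.integers(0, max(2, spec.length // 10)))
            right = int(rng.integers(0, max(2, spec.length // 10)))
            s = "-" * left + s[left : spec.length - right] + "-" * right
        records[microbe_name(i)] = s
    availability = {name: True for name in records}
    n_missing = int(round(spec.unavailable_fraction * len(records)))
    if n_missing:
        names = sorted(records)
        for name in rng.choice(names, size=n_missing, replace=False):
            availability[str(name)] = False
    return SequenceSet(records, availability)


def aligned_block(seqs: SequenceSet) -> AlignedBlock:
    """View an equal-length sequence set as an alignment block."""
    labels = sorted(seqs.records)
    return AlignedBlock(labels, [seqs.records[n] for n in labels])


def make_disease_dag(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    disease_blocks: np.ndarray | None = None,
    n_roots: int | None = None,
) -> dict[str, set[str]]:
    """Random rooted forest of dot-delimited tree codes for the nd diseases.

    Each disease receives one code.  When ``disease_blocks`` is given, each
    block grows its own subtree (diseases of a block are placed under a
    common root whenever depth and branching allow), so hierarchy relatedness
    mirrors the planted group structure; without blocks, diseases attach to
    random earlier diseases with spare child slots.  With ``depth=1`` every
    disease is a root, so all diseases are unrelated.  ``n_roots`` caps the
    number of trees; an error is raised when the capped forest cannot hold
    nd diseases.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if n_roots is not None:
        per_level, level = [], n_roots
        for _ in range(spec.depth):
            per_level.append(level)
            level *= spec.branching
        if sum(per_level) < spec.nd:
            raise ValueError(
                f"tree capacity {sum(per_level)} below nd={spec.nd}; raise "
                "n_roots, branching or depth"
            )
    codes: dict[str, set[str]] = {}
    placed_by_block: dict[int, list[str]] = {}
    children: dict[str, int] = {}
    roots = 0
    for j in range(spec.nd):
        blk = int(disease_blocks[j]) if disease_blocks is not None else 0
        pool = placed_by_block.setdefault(blk, [])
        candidates = [
            c
            for c in pool
            if len(c.split(".")) < spec.depth
            and children.get(c, 0) < spec.branching
        ]
        if disease_blocks is not None:
            # keep each block one subtree whenever possible
            attach = bool(candidates) and spec.depth > 1
        else:
            attach = bool(candidates) and spec.depth > 1 and rng.random() < 0.7
        if not attach and n_roots is not None and roots >= n_roots:
            if not candidates:
                raise ValueError(
                    "tree capacity exhausted; raise n_roots, branching or depth"
                )
            attach = True
        if attach:
            parent = candidates[int(rng.integers(len(candidates)))]
            code = f"{parent}.{children.get(parent, 0) + 1:03d}"
            children[parent] = children.get(parent, 0) + 1
        else:
            roots += 1
            code = f"C{roots:02d}"
        codes[disease_name(j)] = {code}
        pool.append(code)
    return codes


def make_world(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[AssociationDataset, SequenceSet, dict[str, set[str]]]:
    """Generate a full coupled study: network, sequences and hierarchy."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    dataset, mb, db = make_network(spec, rng)
    seqs = make_sequences(spec, mb, rng)
    codes = make_disease_dag(spec, rng, disease_blocks=db)
    return dataset, seqs, codes
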