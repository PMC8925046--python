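"""Shared in-memory containers for association, sequence and similarity data.

The whole package works on three kinds of objects: a binary microbe x
disease association matrix with ordered name indices, sets of (optionally
aligned) nucleotide sequences keyed by microbe name, and square symmetric
named similarity / distance matrices with entries in [0, 1].  Everything is
dense: at the scale of a curated association catalogue (hundreds of microbes,
tens of diseases) sparse machinery buys nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AssociationDataset",
    "SequenceSet",
    "AlignedBlock",
    "SimilarityMatrix",
    "DistanceMatrix",
    "ScoreMatrix",
]

_SYMMETRY_TOL = 1e-9

SEQ_ALPHABET = set("ACGTN-")


@dataclass
class AssociationDataset:
    """Binary microbe-disease association network.

    Parameters
    ----------
    microbe_names, disease_names
        Ordered unique labels. Row ``i`` / column ``j`` of ``matrix``
        correspond to ``microbe_names[i]`` / ``disease_names[j]``.
    matrix
        ``nm x nd`` array with entries in {0, 1}; entry 1 marks a known
        association.
    accessions
        Optional per-microbe sequence accession strings (the literal value
        ``"unavailable"`` marks microbes without a usable marker-gene
        sequence).
    """

    microbe_names: list[str]
    disease_names: list[str]
    matrix: np.ndarray
    accessions: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.microbe_names = list(self.microbe_names)
        self.disease_names = list(self.disease_names)
        self.matrix = np.asarray(self.matrix)
        if len(set(self.microbe_names)) != len(self.microbe_names):
            raise ValueError("duplicate microbe names")
        if len(set(self.disease_names)) != len(self.disease_names):
            raise ValueError("duplicate disease names")
        if self.nm < 1 or self.nd < 1:
            raise ValueError("need at least one microbe and one disease")
        if self.matrix.shape != (self.nm, self.nd):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"({self.nm}, {self.nd})"
            )
        vals = np.unique(self.matrix)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("association matrix entries must be 0 or 1")
        self.matrix = self.matrix.astype(np.int8)

    @property
    def nm(self) -> int:
        return len(self.microbe_names)

    @property
    def nd(self) -> int:
        return len(self.disease_names)

    @property
    def n_assoc(self) -> int:
        return int(self.matrix.sum())

    def positives(self) -> np.ndarray:
        """Index pairs (microbe_idx, disease_idx) of every known association."""
        return np.argwhere(self.matrix == 1)

    def with_matrix(self, matrix: np.ndarray) -> "AssociationDataset":
        return AssociationDataset(
            self.microbe_names, self.disease_names, matrix, self.accessions
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=self.microbe_names, columns=self.disease_names
        )


@dataclass
class SequenceSet:
    """Nucleotide sequences keyed by microbe label, with availability flags.

    ``availability[name]`` is False for microbes whose marker-gene sequence
    could not be obtained; such microbes are later filled in by mean
    imputation on the similarity matrices.
    """

    records: dict[str, str]
    availability: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.records.items():
            bad = set(seq) - SEQ_ALPHABET
            if bad:
                raise ValueError(f"sequence {name!r} has invalid symbols {bad}")
        for name in self.records:
            self.availability.setdefault(name, True)

    @property
    def available(self) -> list[str]:
        return [n for n, ok in self.availability.items() if ok and n in self.records]

    @property
    def missing(self) -> list[str]:
        return [n for n, ok in self.availability.items() if not ok]

    def is_aligned(self) -> bool:
        lengths = {len(s) for s in self.records.values()}
        return len(lengths) <= 1


@dataclass
class AlignedBlock:
    """Equal-length gapped sequences, i.e. a multiple-sequence alignment."""

    labels: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences length mismatch")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("aligned block rows must have equal length")
        for lab, seq in zip(self.labels, self.sequences):
            bad = set(seq) - SEQ_ALPHABET
            if bad:
                raise ValueError(f"row {lab!r} has invalid symbols {bad}")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def as_array(self) -> np.ndarray:
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype="S1"
        ).reshape(len(self.sequences), self.n_columns)


class _NamedSquare:
    """Square named matrix base: symmetric, finite, label-indexed."""

    def __init__(self, names: list[str], values: np.ndarray):
        self.names = list(names)
        values = np.asarray(values, dtype=float)
        n = len(self.names)
        if values.shape != (n, n):
            raise ValueError(f"values shape {values.shape} != ({n}, {n})")
        if not np.all(np.isfinite(values)):
            raise ValueError("matrix entries must be finite")
        if np.max(np.abs(values - values.T), initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("matrix is not symmetric within tolerance")
        self.values = values
        self._index = {n: i for i, n in enumerate(self.names)}

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def reindex(self, names: list[str]):
        missing = [n for n in names if n not in self._index]
        if missing:
            raise KeyError(f"labels not covered by matrix: {missing}")
        idx = [self._index[n] for n in names]
        return type(self)(list(names), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def __eq__(self, other) -> bool:
        return (
            type(self) is type(other)
            and self.names == other.names
            and np.array_equal(self.values, other.values)
        )


class SimilarityMatrix(_NamedSquare):
    """Symmetric named similarity matrix.

    Serves every similarity role in the pipeline: disease semantic
    similarity, raw pairwise identities, normalized sequence similarity,
    evolutionary-distance similarity and their fusion.  Raw identity tables
    live on the 0-100 scale; all normalized roles live in [0, 1].
    """


class DistanceMatrix(_NamedSquare):
    """Symmetric p-distance matrix with zero diagonal, entries in [0, 1]."""

    def __init__(self, names: list[str], values: np.ndarray):
        super().__init__(names, values)
        if np.any(self.values < -_SYMMETRY_TOL) or np.any(self.values > 1 + _SYMMETRY_TOL):
            raise ValueError("p-distances must lie in [0, 1]")
        if np.max(np.abs(np.diag(self.values)), initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("distance diagonal must be zero")


@dataclass
class ScoreMatrix:
    """Predicted preference scores, diseases on rows, microbes on columns."""

    disease_names: list[str]
    microbe_names: list[str]
    values: np.ndarray
    augmented: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        shape = (len(self.disease_names), len(self.microbe_names))
        if self.values.shape != shape:
            raise ValueError(f"score shape {self.values.shape} != {shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scores must be finite")

    def row(self, disease: str) -> np.ndarray:
        try:
            d = self.disease_names.index(disease)
        except ValueError:
            raise KeyError(f"unknown disease {disease!r}") from None
        return self.values[d]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.disease_names, columns=self.microbe_names
        )
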