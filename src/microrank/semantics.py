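"""Disease semantic similarity from hierarchical tree codes.

Diseases are located in a taxonomy (MeSH-style) by dot-delimited tree codes
whose prefix nesting encodes ancestry: ``C18.654.726`` (overnutrition) is an
ancestor of ``C18.654.726.500`` (obesity).  Each disease ``d`` gets a weight
vector over the study's diseases,

    V_d(t) = 1                  if t = d,
    V_d(t) = 1 / (len(d, t)+1)  if t is a descendant of d,
    V_d(t) = 0                  otherwise,

where ``len(d, t)`` is the shortest descendant-path length, measured as the
difference in dot-segment depth along the codes (the taxonomy exists
independently of the studied disease subset, so intermediate levels count
even when no studied disease occupies them; multi-code diseases take the
minimum over code pairs).  Pairwise semantic similarity is the cosine of
these weight vectors.  Weights are kept as exact rationals until the cosine
step.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import networkx as nx
import numpy as np

from .containers import SimilarityMatrix

__all__ = [
    "DiseaseDag",
    "build_dag",
    "semantic_weight",
    "weight_vector",
    "disease_similarity",
    "disease_similarity_from_codes",
]


@dataclass
class DiseaseDag:
    """Hierarchy of diseases induced by tree-code prefix nesting.

    ``graph`` holds the direct parent->child edges (codes differing by
    exactly one segment); descendant queries use code arithmetic, not graph
    hops, so levels unoccupied by any studied disease still count toward
    path length.
    """

    graph: nx.DiGraph
    codes: dict[str, set[str]]
    code_index: dict[str, str]

    @property
    def diseases(self) -> list[str]:
        return sorted(self.codes)


def _segments(code: str) -> list[str]:
    return code.split(".")


def build_dag(codes: dict[str, set[str]]) -> DiseaseDag:
    """Build the disease hierarchy from per-disease tree-code sets.

    A direct edge u -> v exists iff some code of v equals a code of u plus
    exactly one extra segment.  A code claimed by two diseases is an error.
    """
    code_index: dict[str, str] = {}
    for disease, cset in codes.items():
        if not cset:
            raise ValueError(f"disease {disease!r} has no tree codes")
        for code in cset:
            other = code_index.get(code)
            if other is not None and other != disease:
                raise ValueError(
                    f"tree code {code!r} claimed by both {other!r} and {disease!r}"
                )
            code_index[code] = disease
    graph = nx.DiGraph()
    graph.add_nodes_from(codes)
    for child_d, child_codes in codes.items():
        for code in child_codes:
            segs = _segments(code)
            if len(segs) < 2:
                continue
            parent_code = ".".join(segs[:-1])
            parent_d = code_index.get(parent_code)
            if parent_d is not None and parent_d != child_d:
                graph.add_edge(parent_d, child_d)
    # prefix nesting cannot create cycles, but guard against pathological input
    if not nx.is_directed_acyclic_graph(graph):  # pragma: no cover
        raise ValueError("tree codes induce a cyclic hierarchy")
    return DiseaseDag(graph, {d: set(c) for d, c in codes.items()}, code_index)


def _descendant_len(dag: DiseaseDag, d: str, t: str) -> int | None:
    """Shortest code-depth difference making t a descendant of d, else None."""
    best: int | None = None
    for cd in dag.codes[d]:
        prefix = cd + "."
        depth_d = len(_segments(cd))
        for ct in dag.codes[t]:
            if ct.startswith(prefix):
                dist = len(_segments(ct)) - depth_d
                if best is None or dist < best:
                    best = dist
    return best


def semantic_weight(dag: DiseaseDag, d: str, t: str) -> Fraction:
    """Contribution of disease ``t`` to the weight vector of ``d``."""
    if d not in dag.codes or t not in dag.codes:
        raise KeyError(f"unknown disease in {(d, t)}")
    if t == d:
        return Fraction(1)
    length = _descendant_len(dag, d, t)
    if length is None:
        return Fraction(0)
    return Fraction(1, length + 1)


def weight_vector(
    dag: DiseaseDag, d: str, order: list[str] | None = None
) -> list[Fraction]:
    """Weight vector of ``d`` over all diseases, in ``order`` (default sorted)."""
    if order is None:
        order = dag.diseases
    return [semantic_weight(dag, d, t) for t in order]


def disease_similarity(
    vectors: dict[str, list[Fraction]], order: list[str] | None = None
) -> SimilarityMatrix:
    """Cosine similarity of weight vectors; diagonal exactly 1."""
    if order is None:
        order = sorted(vectors)
    mat = np.array(
        [[float(w) for w in vectors[d]] for d in order], dtype=float
    )
    norms = np.linalg.norm(mat, axis=1)
    if np.any(norms == 0):
        raise ValueError("weight vector with zero norm (missing self weight)")
    sim = (mat @ mat.T) / np.outer(norms, norms)
    sim = np.clip(sim, 0.0, 1.0)
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(list(order), sim)


def disease_similarity_from_codes(
    codes: dict[str, set[str]], order: list[str] | None = None
) -> SimilarityMatrix:
    """Convenience path: tree codes -> DAG -> weight vectors -> cosine matrix."""
    dag = build_dag(codes)
    if order is None:
        order = dag.diseases
    vectors = {d: weight_vector(dag, d, order) for d in order}
    return disease_similarity(vectors, order)
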