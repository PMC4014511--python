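"""Graph-based (Wang-style) semantic similarity between terms and genes.

Term similarity is computed from semantic contributions (S-values) of
shared ancestors in the ontology graph; gene similarity aggregates term
similarities with a best-match average (BMA) by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .ontology import RELATION_WEIGHTS, AnnotationSet, GoDag


@dataclass
class SValueMap:
    """Semantic contributions of a term's ancestor graph to the term itself."""

    term: str
    s_values: dict[str, float]

    @property
    def sv(self) -> float:
        """Sum of all S-values (>= 1, since S(term, term) = 1)."""
        return float(sum(self.s_values.values()))


def s_values(
    term: str,
    dag: GoDag,
    weights: dict[str, float] | None = None,
) -> SValueMap:
    """Compute S-values for *term* over its induced ancestor subgraph.

    ``S(term) = 1``; for an ancestor ``t``, ``S(t)`` is the maximum over
    child terms ``c`` of ``t`` (within the ancestor subgraph) of
    ``w(c -> t) * S(c)``, where ``w`` depends on the edge relation.
    """
    if term not in dag:
        raise KeyError(f"unknown term {term!r}")
    w = dict(RELATION_WEIGHTS)
    if weights:
        w.update(weights)

    sub = dag.ancestor_subgraph(term)
    sv: dict[str, float] = {term: 1.0}
    # Edges point child -> parent, so topological order visits children first.
    for node in nx.topological_sort(sub):
        if node == term:
            continue
        best = 0.0
        for child in sub.predecessors(node):
            rel = sub.edges[child, node]["relation"]
            best = max(best, w[rel] * sv[child])
        sv[node] = best
    return SValueMap(term, sv)


def term_similarity(
    a: str,
    b: str,
    dag: GoDag,
    weights: dict[str, float] | None = None,
    _cache: dict[str, SValueMap] | None = None,
) -> float:
    """Similarity in [0, 1] between two terms of the same namespace.

    ``sim = sum over shared ancestors t of (S_a(t) + S_b(t)) / (SV(a) + SV(b))``.
    """
    if a not in dag or b not in dag:
        raise KeyError(f"unknown term in pair ({a!r}, {b!r})")
    if dag.namespace(a) != dag.namespace(b):
        warnings.warn(f"terms {a} and {b} are in disjoint namespaces; similarity 0")
        return 0.0
    if _cache is not None:
        sa = _cache.get(a) or _cache.setdefault(a, s_values(a, dag, weights))
        sb = _cache.get(b) or _cache.setdefault(b, s_values(b, dag, weights))
    else:
        sa, sb = s_values(a, dag, weights), s_values(b, dag, weights)
    shared = sa.s_values.keys() & sb.s_values.keys()
    if not shared:
        return 0.0
    num = sum(sa.s_values[t] + sb.s_values[t] for t in shared)
    return min(1.0, float(num / (sa.sv + sb.sv)))


def _bma(sim_matrix: np.ndarray) -> float:
    # best-match average: mean of row maxima and column maxima pooled
    row_max = sim_matrix.max(axis=1)
    col_max = sim_matrix.max(axis=0)
    bma = (row_max.sum() + col_max.sum()) / (len(row_max) + len(col_max))
    return min(1.0, float(bma))


def gene_similarity(
    annots_a: set[str],
    annots_b: set[str],
    dag: GoDag,
    method: str = "BMA",
    weights: dict[str, float] | None = None,
    _cache: dict[str, SValueMap] | None = None,
) -> float:
    """Functional similarity between two genes from their annotation sets."""
    if not annots_a or not annots_b:
        raise ValueError("gene similarity requires non-empty annotation sets")
    ta, tb = sorted(annots_a), sorted(annots_b)
    m = np.empty((len(ta), len(tb)))
    for i, t1 in enumerate(ta):
        for j, t2 in enumerate(tb):
            m[i, j] = term_similarity(t1, t2, dag, weights, _cache=_cache)
    if method == "BMA":
        return _bma(m)
    if method == "max":
        return float(m.max())
    if method == "average":
        return float(m.mean())
    raise ValueError(f"unknown aggregation method {method!r}")


@dataclass
class GeneSimilarityMatrix:
    """Symmetric gene x gene similarity matrix with a method tag."""

    values: pd.DataFrame
    method: str = "BMA"

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def to_distance(self) -> pd.DataFrame:
        d = 1.0 - self.values
        np.fill_diagonal(d.values, 0.0)
        return d


def similarity_matrix(
    genes: list[str],
    annots: AnnotationSet,
    dag: GoDag,
    method: str = "BMA",
    weights: dict[str, float] | None = None,
) -> GeneSimilarityMatrix:
    """All-pairs gene similarity; each unordered pair computed once.

    Genes without annotations are excluded (they carry no functional
    signal and the pairwise measure is undefined for them).
    """
    kept = [g for g in genes if annots.terms_for(g)]
    cache: dict[str, SValueMap] = {}
    n = len(kept)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = gene_similarity(
                annots.terms_for(kept[i]),
                annots.terms_for(kept[j]),
                dag,
                method=method,
                weights=weights,
                _cache=cache,
            )
            mat[i, j] = mat[j, i] = s
    df = pd.DataFrame(mat, index=kept, columns=kept)
    return GeneSimilarityMatrix(df, method=method)
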