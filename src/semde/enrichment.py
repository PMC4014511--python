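"""Per-cluster over-representation of ontology terms and pathway gene sets.

Upper-tail hypergeometric test against a fixed chip background, with an
observed/expected enrichment score, a minimum-gene rule and BH correction
per cluster x collection analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .linmod import bh_adjust
from .ontology import AnnotationSet, GoDag


def hypergeom_tail(x: int, N: int, K: int, n: int) -> float:
    """P[X >= x] for X ~ Hypergeometric(N, K, n), by direct tail summation."""
    if x <= 0:
        return 1.0
    return float(stats.hypergeom.pmf(np.arange(x, min(K, n) + 1), N, K, n).sum())


@dataclass
class EnrichmentRow:
    term: str
    name: str
    n_overlap: int        # genes from the cluster annotated to the term
    n_cluster: int
    n_term_background: int
    n_background: int
    expected: float
    es: float             # enrichment score = observed / expected
    p: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def hypergeom_enrich(cluster_genes: set[str], term_genes: set[str],
                     background: set[str], min_genes: int = 5,
                     term: str = "", name: str = "") -> EnrichmentRow | None:
    """One term's over-representation row, or None if suppressed.

    Suppression: fewer than *min_genes* cluster genes in the term, or a
    term absent from the background.
    """
    if not background:
        raise ValueError("empty background")
    if not cluster_genes <= background:
        raise ValueError("cluster genes must be a subset of the background")
    N = len(background)
    K = len(term_genes & background)
    if K == 0:
        return None
    n = len(cluster_genes)
    x = len(cluster_genes & term_genes)
    if x < min_genes:
        return None
    expected = n * K / N
    return EnrichmentRow(
        term=term, name=name, n_overlap=x, n_cluster=n, n_term_background=K,
        n_background=N, expected=expected, es=x / expected,
        p=hypergeom_tail(x, N, K, n),
    )


def adjust_and_filter(rows: list[EnrichmentRow], alpha: float = 0.05) -> pd.DataFrame:
    """BH across the rows of one analysis; keep adjusted p <= alpha."""
    if not rows:
        return pd.DataFrame(columns=["term", "name", "n_overlap", "n_cluster",
                                     "n_term_background", "n_background",
                                     "expected", "es", "p", "padj"])
    df = pd.DataFrame([r.as_dict() for r in rows])
    df["padj"] = bh_adjust(df["p"].values)
    df = df[df["padj"] <= alpha]
    return df.sort_values(["padj", "p"]).reset_index(drop=True)


def propagate_annotations(annots: AnnotationSet, dag: GoDag) -> dict[str, set[str]]:
    """Term -> gene-set map with annotations propagated to ancestor terms."""
    term_genes: dict[str, set[str]] = {}
    anc_cache: dict[str, set[str]] = {}
    for gene, terms in annots.assignments.items():
        for t in terms:
            if t not in dag:
                continue
            if t not in anc_cache:
                anc_cache[t] = {t} | nx.descendants(dag.graph, t)
            for a in anc_cache[t]:
                term_genes.setdefault(a, set()).add(gene)
    return term_genes


def enrich_cluster(cluster_genes: set[str], term_gene_map: dict[str, set[str]],
                   background: set[str], min_genes: int = 5, alpha: float = 0.05,
                   names: dict[str, str] | None = None) -> pd.DataFrame:
    """Test every term with background support against one gene cluster."""
    names = names or {}
    rows = []
    for term in sorted(term_gene_map):
        row = hypergeom_enrich(cluster_genes & background, term_gene_map[term],
                               background, min_genes=min_genes, term=term,
                               name=names.get(term, term))
        if row is not None:
            rows.append(row)
    return adjust_and_filter(rows, alpha=alpha)


def enrich_all(assignments: pd.Series, annots: AnnotationSet, dag: GoDag | None,
               background: set[str], pathway_sets: dict[str, set[str]] | None = None,
               min_genes: int = 5, alpha: float = 0.05,
               propagate: bool = True) -> pd.DataFrame:
    """Run term and pathway enrichment for every cluster.

    Parameters
    ----------
    assignments :
        gene -> cluster-id series (from :func:`semde.cluster.cut_clusters`).
    propagate :
        If true (default), ontology annotations are propagated to ancestor
        terms for counting.
    """
    if dag is not None and propagate:
        go_map = propagate_annotations(annots, dag)
    else:
        go_map = {}
        for gene, terms in annots.assignments.items():
            for t in terms:
                go_map.setdefault(t, set()).add(gene)
    names = {}
    if dag is not None:
        names = {t: dag.graph.nodes[t].get("name", t) for t in dag.graph.nodes}

    collections = {"GO_BP": go_map}
    if pathway_sets:
        collections["pathways"] = pathway_sets

    frames = []
    for cluster_id in sorted(assignments.unique()):
        genes = set(assignments.index[assignments == cluster_id])
        for coll_name, term_map in collections.items():
            df = enrich_cluster(genes, term_map, background, min_genes=min_genes,
                                alpha=alpha, names=names if coll_name == "GO_BP" else None)
            df.insert(0, "collection", coll_name)
            df.insert(0, "cluster", int(cluster_id))
            frames.append(df)
    frames = [f for f in frames if len(f)]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if len(out):
        out = out.sort_values(["cluster", "collection", "padj"]).reset_index(drop=True)
    return out
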