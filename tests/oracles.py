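"""Independent brute-force oracles used by the test suite.

Every oracle here recomputes a quantity by a different route than the
package (exhaustive enumeration, direct summation, normal equations) so
the two can be compared without shared code paths.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


# ---------------------------------------------------------------------------
# semantic similarity

def all_paths_up(edges: dict[tuple[str, str], str], start: str, target: str):
    """All simple child->parent paths from start to target; edges maps
    (child, parent) -> relation."""
    children = {}
    for (c, p), rel in edges.items():
        children.setdefault(c, []).append((p, rel))
    paths = []

    def walk(node, acc):
        if node == target:
            paths.append(list(acc))
            return
        for parent, rel in children.get(node, []):
            acc.append(rel)
            walk(parent, acc)
            acc.pop()

    walk(start, [])
    return paths


def s_values_oracle(edges: dict[tuple[str, str], str], term: str) -> dict[str, float]:
    """S-value of each ancestor = max over root-ward paths of the product of
    edge weights along the path."""
    nodes = {term}
    frontier = [term]
    while frontier:
        node = frontier.pop()
        for (c, p) in edges:
            if c == node and p not in nodes:
                nodes.add(p)
                frontier.append(p)
    sv = {term: 1.0}
    for anc in nodes - {term}:
        best = 0.0
        for path in all_paths_up(edges, term, anc):
            best = max(best, math.prod(WEIGHTS[r] for r in path))
        if best > 0:
            sv[anc] = best
    return sv


def term_sim_oracle(edges, a: str, b: str) -> float:
    sa, sb = s_values_oracle(edges, a), s_values_oracle(edges, b)
    shared = sa.keys() & sb.keys()
    if not shared:
        return 0.0
    return sum(sa[t] + sb[t] for t in shared) / (sum(sa.values()) + sum(sb.values()))


def bma_oracle(edges, terms_a: set[str], terms_b: set[str]) -> float:
    ta, tb = sorted(terms_a), sorted(terms_b)
    m = [[term_sim_oracle(edges, x, y) for y in tb] for x in ta]
    rows = [max(row) for row in m]
    cols = [max(m[i][j] for i in range(len(ta))) for j in range(len(tb))]
    return (sum(rows) + sum(cols)) / (len(rows) + len(cols))


def random_dag_edges(rng, n_terms: int) -> dict[tuple[str, str], str]:
    """Random rooted DAG: term i attaches to 1-2 earlier terms."""
    edges = {}
    names = [f"T{i}" for i in range(n_terms)]
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.random() < 0.35 and i > 1)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            rel = "part_of" if rng.random() < 0.3 else "is_a"
            edges[(names[i], names[int(p)])] = rel
    return edges


# ---------------------------------------------------------------------------
# statistics

def bh_oracle(pvals) -> np.ndarray:
    """Direct step-up computation: p_(i) * m / i with the running minimum
    from the largest rank down."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return np.array(adj)


def hypergeom_tail_oracle(x: int, N: int, K: int, n: int) -> Fraction:
    """Exact upper-tail probability by combinatorial enumeration."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(max(x, 0), min(K, n) + 1):
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
    return acc


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coefficients via (X'X)^-1 X'y (pinv for robustness)."""
    return np.linalg.pinv(X.T @ X) @ X.T @ y


def lsmeans_grid_oracle(predict, factor_levels: dict[str, list], fixed: dict,
                        covariates: dict[str, float]) -> float:
    """Average model predictions over the full factor-level grid with equal
    weights; *predict* maps a {name: value} dict to a prediction."""
    names = sorted(factor_levels)
    preds = []
    for combo in itertools.product(*(factor_levels[n] for n in names)):
        row = dict(zip(names, combo))
        row.update(fixed)
        row.update(covariates)
        preds.append(predict(row))
    return float(np.mean(preds))


def kmeans1d_optimal(values: np.ndarray, k: int):
    """Exhaustive optimal 1-D k-partition (contiguous on sorted order)
    minimizing within-cluster SSE; returns labels aligned to input order."""
    order = np.argsort(values)
    x = values[order]
    n = len(x)
    best = (math.inf, None)
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        sse = 0.0
        for a, b in zip(bounds, bounds[1:]):
            seg = x[a:b]
            sse += ((seg - seg.mean()) ** 2).sum()
        if sse < best[0]:
            best = (sse, bounds)
    labels = np.empty(n, dtype=int)
    bounds = best[1]
    for ci, (a, b) in enumerate(zip(bounds, bounds[1:])):
        labels[order[a:b]] = ci
    return labels


def genorm_m_oracle(q: np.ndarray) -> np.ndarray:
    """M-values by an explicit two-loop recomputation (samples x refs)."""
    logq = np.log2(q)
    n_ref = q.shape[1]
    m = np.zeros(n_ref)
    for j in range(n_ref):
        sds = []
        for k in range(n_ref):
            if k == j:
                continue
            ratio = logq[:, j] - logq[:, k]
            sds.append(np.std(ratio, ddof=1))
        m[j] = np.mean(sds)
    return m
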