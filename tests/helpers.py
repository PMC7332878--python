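"""Independent oracles used by the test suite.

Each function here recomputes a quantity by brute force — direct
summation, exhaustive enumeration of paths or partitions — and never
calls the implementation path it is used to check.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import networkx as nx


def binomial_interval_99(n: int, p: float) -> tuple[int, int]:
    """Central 99% interval of Binomial(n, p) by direct tail summation."""
    # multiplicative recurrence avoids giant binomial-coefficient integers
    probs = [0.0] * (n + 1)
    probs[0] = (1 - p) ** n
    for k in range(n):
        probs[k + 1] = probs[k] * (n - k) / (k + 1) * p / (1 - p)
    lo = 0
    acc = 0.0
    while lo <= n and acc + probs[lo] <= 0.005:
        acc += probs[lo]
        lo += 1
    hi = n
    acc = 0.0
    while hi >= 0 and acc + probs[hi] <= 0.005:
        acc += probs[hi]
        hi -= 1
    return lo, hi


def hypergeom_upper_tail(k: int, m: int, n_set: int, n_query: int) -> Fraction:
    """P(overlap >= k) by exact summation over overlap values."""
    total = comb(m, n_query)
    acc = Fraction(0)
    for j in range(k, min(n_set, n_query) + 1):
        acc += Fraction(comb(n_set, j) * comb(m - n_set, n_query - j), total)
    return acc


def brute_betweenness(graph: nx.Graph) -> dict:
    """Normalized betweenness by explicit all-pairs shortest-path counting."""
    nodes = list(graph.nodes())
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            on_path = sum(1 for p in paths if v in p)
            score[v] += on_path / len(paths)
    norm = (n - 1) * (n - 2) / 2 if n > 2 else 1.0
    return {v: score[v] / norm for v in nodes}


def brute_closeness(graph: nx.Graph) -> dict:
    """Freeman closeness within each connected component, by explicit BFS."""
    out = {}
    for compset in nx.connected_components(graph):
        comp = graph.subgraph(compset)
        for v in comp:
            dists = nx.single_source_shortest_path_length(comp, v)
            total = sum(dists.values())
            out[v] = (len(comp) - 1) / total if total > 0 else 0.0
    return out


def brute_modularity_best_partition(graph: nx.Graph) -> float:
    """Max modularity over all partitions of the node set (tiny graphs only)."""
    nodes = list(graph.nodes())

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [first]] + part[i + 1:]
            yield part + [[first]]

    best = float("-inf")
    for part in partitions(nodes):
        q = nx.community.modularity(graph, [set(b) for b in part])
        best = max(best, q)
    return best


def brute_pairs_per_record(record_genes: dict[str, set[str]]
                           ) -> set[tuple[str, str]]:
    """All distinct unordered gene pairs co-occurring within any record."""
    pairs: set[tuple[str, str]] = set()
    for genes in record_genes.values():
        pairs.update(tuple(sorted(p)) for p in combinations(sorted(genes), 2))
    return pairs
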