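"""Independent brute-force oracles used only by the tests.

The maximal-clique / MCC oracle enumerates all 2^n vertex subsets directly,
so it shares no code path with the package's Bron-Kerbosch-based scoring.
"""

import math
from itertools import combinations


def brute_maximal_cliques(graph):
    """All maximal cliques by exhaustive subset enumeration (n <= ~14)."""
    nodes = list(graph.nodes)
    n = len(nodes)
    adj = {v: set(graph.adj[v]) for v in nodes}

    def is_clique(subset):
        return all(b in adj[a] for a, b in combinations(subset, 2))

    cliques = []
    for mask in range(1, 2**n):
        subset = [nodes[i] for i in range(n) if mask >> i & 1]
        if not is_clique(subset):
            continue
        if any(all(v in adj[u] for u in subset) for v in nodes if v not in subset):
            continue  # extendable, not maximal
        cliques.append(frozenset(subset))
    return set(cliques)


def brute_mcc(graph):
    """MCC by the subset-enumeration clique oracle; isolated nodes score 0."""
    scores = {v: 0 for v in graph.nodes}
    for clique in brute_maximal_cliques(graph):
        if len(clique) < 2:
            continue
        for v in clique:
            scores[v] += math.factorial(len(clique) - 1)
    return scores
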