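"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the algorithms used in the package: betweenness is
computed by enumerating every shortest path explicitly, and the FDR step-up is
the quadratic-time literal definition.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def all_shortest_paths(adjacency: dict, s, t) -> list[list]:
    """Every shortest s–t path, by BFS distances + backward DFS."""
    dist = {s: 0}
    queue = deque([s])
    while queue:
        u = queue.popleft()
        for v in adjacency[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    if t not in dist:
        return []
    paths = []

    def extend(partial):
        head = partial[-1]
        if head == t:
            paths.append(list(partial))
            return
        for v in adjacency[head]:
            if dist.get(v) == dist[head] + 1:
                partial.append(v)
                extend(partial)
                partial.pop()

    extend([s])
    return paths


def brute_force_betweenness(graph) -> dict:
    """Normalized betweenness by explicit shortest-path enumeration.

    Endpoints excluded, each unordered pair counted once, normalization
    (N-1)(N-2)/2; reachable pairs only. Exponential in the worst case — use on
    tiny graphs only.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    counts = {v: 0.0 for v in nodes}
    if n < 3:
        return counts
    adjacency = {v: sorted(graph.neighbors(v)) for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            paths = all_shortest_paths(adjacency, s, t)
            if not paths:
                continue
            for v in nodes:
                if v == s or v == t:
                    continue
                through = sum(v in path for path in paths)
                counts[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return {v: c / norm for v, c in counts.items()}


def brute_force_bh(p_values) -> np.ndarray:
    """Literal Benjamini–Hochberg step-up: q_i = min over j with p_j >= p_i of
    (m * p_j / rank_j), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for idx in range(m - 1, -1, -1):
        j = order[idx]
        running_min = min(running_min, m * p[j] / (idx + 1))
        adjusted[j] = running_min
    return np.minimum(adjusted, 1.0)
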