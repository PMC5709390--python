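"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's BFS/predecessor-DAG machinery:
distances come from boolean matrix powers (a Floyd–Warshall-style dynamic
program) and path counts/listings from exhaustive depth-first enumeration.
Only usable on small graphs.
"""

from __future__ import annotations

import numpy as np

from effectpaths.network_io import GENE, MolecularNetwork


def random_digraph(rng: np.random.Generator, n_nodes: int, p: float) -> MolecularNetwork:
    """Random directed network on nodes n00..n<k>, arc probability p."""
    net = MolecularNetwork()
    names = [f"n{i:02d}" for i in range(n_nodes)]
    for name in names:
        net.add_node(name, GENE)
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < p:
                net.add_arc(names[i], names[j], ["activation"])
    return net


def matrix_power_distances(net: MolecularNetwork) -> dict[tuple[str, str], int]:
    """All-pairs shortest distances via reachability of boolean matrix powers."""
    nodes = sorted(net.nodes())
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for u, v in net.arcs():
        adj[idx[u], idx[v]] = True
    dist: dict[tuple[str, str], int] = {(v, v): 0 for v in nodes}
    reach = np.eye(n, dtype=bool)
    for k in range(1, n):
        reach = reach @ adj
        for i in range(n):
            for j in range(n):
                if reach[i, j] and (nodes[i], nodes[j]) not in dist:
                    dist[(nodes[i], nodes[j])] = k
    return dist


def dfs_shortest_paths(net: MolecularNetwork, source: str, sink: str) -> list[list[str]]:
    """All shortest source→sink paths by exhaustive bounded DFS."""
    oracle_dist = matrix_power_distances(net)
    if (source, sink) not in oracle_dist:
        return []
    target_len = oracle_dist[(source, sink)]
    out: list[list[str]] = []
    stack = [source]

    def dfs(u: str) -> None:
        if len(stack) - 1 > target_len:
            return
        if u == sink and len(stack) - 1 == target_len:
            out.append(list(stack))
            return
        for v in sorted(net.successors(u)):
            if v not in stack:
                stack.append(v)
                dfs(v)
                stack.pop()

    dfs(source)
    return out


def pairwise_auroc(pos: list[float], neg: list[float]) -> float:
    """P(score_pos > score_neg) + 0.5 P(tie) over all positive×negative pairs."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
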