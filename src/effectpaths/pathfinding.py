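"""Unweighted shortest paths on the directed view of the molecular network.

Distances count edges: a path of k molecules has length k−1.  Unreachable
sinks are marked with :data:`UNREACHABLE`, which compares greater than any
finite distance and propagates through the scoring function as score 0.

Shortest-path *counts* are always exact, computed by dynamic programming on
the BFS predecessor DAG; the enumeration cap limits only how many paths are
listed, never distances, counts, or downstream scores.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

if TYPE_CHECKING:  # pragma: no cover
    from effectpaths.network_io import MolecularNetwork

#: Sentinel for "no path"; compares greater than every finite distance.
UNREACHABLE = math.inf

DEFAULT_PATH_CAP = 100


def is_unreachable(length: float) -> bool:
    return length == UNREACHABLE


@dataclass
class DistanceResult:
    """BFS distances from a single source; absent keys are unreachable."""

    source: str
    dist: dict[str, int]

    def __getitem__(self, node: str) -> float:
        return self.dist.get(node, UNREACHABLE)


@dataclass
class PathSet:
    """All (or a capped listing of) shortest paths between one node pair."""

    source: str
    sink: str
    length: float  # int or UNREACHABLE
    paths: list[list[str]] = field(default_factory=list)
    truncated: bool = False
    total_count: int = 0


def bfs_distances(
    network: "MolecularNetwork", source: str, stop_set: Iterable[str] | None = None
) -> DistanceResult:
    """Exact arc-following BFS distances from ``source``.

    With a ``stop_set``, the search stops once the minimum distance to any
    member is final — i.e. after the BFS level on which the first member is
    settled — so every reported distance is still exact.
    """
    if source not in network:
        raise KeyError(f"unknown source node {source!r}")
    stop = set(stop_set) if stop_set is not None else None
    dist = {source: 0}
    queue: deque[str] = deque([source])
    stop_level: int | None = 0 if stop is not None and source in stop else None
    while queue:
        u = queue.popleft()
        du = dist[u]
        if stop_level is not None and du >= stop_level:
            break
        for v in network.successors(u):
            if v not in dist:
                dist[v] = du + 1
                if stop is not None and stop_level is None and v in stop:
                    stop_level = du + 1
                queue.append(v)
    return DistanceResult(source=source, dist=dist)


def shortest_path_dag(
    network: "MolecularNetwork", source: str
) -> tuple[dict[str, int], dict[str, list[str]]]:
    """Full BFS from ``source`` plus the shortest-path predecessor DAG.

    ``preds[v]`` lists the in-neighbors u of v with dist[u] + 1 == dist[v];
    every shortest path from the source to v traverses only such arcs.
    """
    if source not in network:
        raise KeyError(f"unknown source node {source!r}")
    dist = bfs_distances(network, source).dist
    preds: dict[str, list[str]] = {v: [] for v in dist}
    for v in dist:
        dv = dist[v]
        for u in network.predecessors(v):
            if dist.get(u, UNREACHABLE) == dv - 1:
                preds[v].append(u)
    return dist, preds


def count_shortest_paths(
    dist: dict[str, int], preds: dict[str, list[str]], sink: str
) -> int:
    """Exact number of distinct shortest source→sink paths (never enumerates)."""
    if sink not in dist:
        return 0
    counts: dict[str, int] = {}

    def count(v: str) -> int:
        if dist[v] == 0:
            return 1
        if v not in counts:
            counts[v] = sum(count(u) for u in preds[v])
        return counts[v]

    # iterative topological accumulation to avoid recursion limits
    order = sorted((n for n in dist if dist[n] <= dist[sink]), key=dist.__getitem__)
    for v in order:
        counts[v] = 1 if dist[v] == 0 else sum(counts[u] for u in preds[v])
    return counts[sink]


def nodes_on_shortest_paths(
    dist: dict[str, int], preds: dict[str, list[str]], sink: str
) -> set[str]:
    """All nodes lying on at least one shortest source→sink path."""
    if sink not in dist:
        return set()
    seen = {sink}
    stack = [sink]
    while stack:
        v = stack.pop()
        for u in preds[v]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return seen


def enumerate_shortest_paths(
    network: "MolecularNetwork",
    source: str,
    sink: str,
    cap: int = DEFAULT_PATH_CAP,
) -> PathSet:
    """List up to ``cap`` shortest source→sink paths in lexicographic order.

    ``total_count`` is exact regardless of the cap; ``truncated`` is set iff
    more shortest paths exist than were listed.  An unreachable sink yields
    an empty :class:`PathSet` with length :data:`UNREACHABLE`.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if source not in network or sink not in network:
        raise KeyError("source and sink must be network nodes")
    dist, preds = shortest_path_dag(network, source)
    if sink not in dist:
        return PathSet(source=source, sink=sink, length=UNREACHABLE)
    total = count_shortest_paths(dist, preds, sink)
    on_path = nodes_on_shortest_paths(dist, preds, sink)
    # forward DFS over DAG arcs restricted to nodes on some shortest path,
    # visiting successors in node-id order -> lexicographic path listing
    succs: dict[str, list[str]] = {v: [] for v in on_path}
    for v in on_path:
        for u in preds[v]:
            if u in on_path:
                succs[u].append(v)
    for u in succs:
        succs[u].sort()
    paths: list[list[str]] = []
    stack: list[str] = [source]

    def dfs(u: str) -> bool:
        if u == sink:
            paths.append(list(stack))
            return len(paths) < cap
        for v in succs[u]:
            stack.append(v)
            more = dfs(v)
            stack.pop()
            if not more:
                return False
        return True

    dfs(source)
    return PathSet(
        source=source,
        sink=sink,
        length=dist[sink],
        paths=paths,
        truncated=total > len(paths),
        total_count=total,
    )
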