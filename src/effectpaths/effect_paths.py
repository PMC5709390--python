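"""Drug effect paths (DEPs) and hormone effect paths (HEPs).

A DEP is a shortest path from a drug target to that target's *nearest*
disease gene; the drug's mechanism-of-action molecule set M(d) is the union
of every node on every DEP (targets, intermediates, and disease genes alike,
since hormone crosstalk may land anywhere along the path).  When several
disease genes tie at the minimal distance from a target, all of them are
kept as DEP endpoints.

A HEP is one of the *very shortest* paths from any receptor of the hormone
onto any molecule of M(d); only receptor–molecule pairs achieving the global
minimum distance contribute, and they define the start set S and end set E
counted by the scoring function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from effectpaths.network_io import MolecularNetwork
from effectpaths.pathfinding import (
    DEFAULT_PATH_CAP,
    UNREACHABLE,
    PathSet,
    bfs_distances,
    enumerate_shortest_paths,
    is_unreachable,
    nodes_on_shortest_paths,
    shortest_path_dag,
)

logger = logging.getLogger(__name__)


@dataclass
class DEPEntry:
    """One drug target's shortest routes to its nearest disease gene(s)."""

    target: str
    nearest_distance: float  # int or UNREACHABLE
    nearest_disease_genes: frozenset[str]
    paths: list[PathSet] = field(default_factory=list)


@dataclass
class DEPSet:
    """All DEPs of one drug for one disease, plus the molecule set M(d).

    ``molecules`` is assembled from the full shortest-path structure
    (predecessor-DAG node sets), so the listing cap cannot change scores.
    """

    drug: str
    disease: str
    entries: list[DEPEntry]
    molecules: frozenset[str]
    unscorable: bool = False

    @property
    def n_paths(self) -> int:
        """Total number of distinct DEPs (exact, cap-independent)."""
        return sum(ps.total_count for e in self.entries for ps in e.paths)


@dataclass
class HEPSet:
    """The very-shortest receptor→M(d) paths for one hormone × drug × disease."""

    hormone: str
    drug: str
    disease: str
    min_length: float  # int or UNREACHABLE
    start_nodes: frozenset[str] = frozenset()
    end_nodes: frozenset[str] = frozenset()
    paths: list[PathSet] = field(default_factory=list)

    @property
    def n_paths(self) -> int:
        return sum(ps.total_count for ps in self.paths)


def infer_deps(
    network: MolecularNetwork,
    drug_targets: set[str] | frozenset[str],
    disease_genes: set[str] | frozenset[str],
    cap: int = DEFAULT_PATH_CAP,
    drug: str = "drug",
    disease: str = "disease",
) -> DEPSet:
    """Infer the DEP set: per target, all shortest paths to its nearest gene(s).

    Each target is treated independently: its minimal BFS distance over all
    disease genes defines that target's DEP length, and every disease gene at
    that distance contributes its shortest paths.  A target that *is* a
    disease gene yields a single zero-length DEP.  Targets with no reachable
    disease gene produce an entry with no paths and contribute nothing to
    M(d).  If no target is present in the network the DEPSet is flagged
    unscorable.
    """
    targets = sorted(t for t in drug_targets if t in network)
    genes = sorted(g for g in disease_genes if g in network)
    for missing in sorted(set(drug_targets) - set(targets)):
        logger.warning("drug target %s not in network; skipped", missing)
    for missing in sorted(set(disease_genes) - set(genes)):
        logger.warning("disease gene %s not in network; skipped", missing)
    if not targets or not genes:
        return DEPSet(
            drug=drug, disease=disease, entries=[], molecules=frozenset(), unscorable=True
        )
    entries: list[DEPEntry] = []
    molecules: set[str] = set()
    for target in targets:
        dist, preds = shortest_path_dag(network, target)
        dmin = min((dist.get(g, UNREACHABLE) for g in genes), default=UNREACHABLE)
        if is_unreachable(dmin):
            entries.append(
                DEPEntry(
                    target=target,
                    nearest_distance=UNREACHABLE,
                    nearest_disease_genes=frozenset(),
                )
            )
            continue
        nearest = frozenset(g for g in genes if dist.get(g, UNREACHABLE) == dmin)
        paths = [enumerate_shortest_paths(network, target, g, cap) for g in sorted(nearest)]
        for g in sorted(nearest):
            molecules |= nodes_on_shortest_paths(dist, preds, g)
        entries.append(
            DEPEntry(
                target=target,
                nearest_distance=int(dmin),
                nearest_disease_genes=nearest,
                paths=paths,
            )
        )
    return DEPSet(
        drug=drug, disease=disease, entries=entries, molecules=frozenset(molecules)
    )


def infer_heps(
    network: MolecularNetwork,
    receptors: set[str] | frozenset[str],
    dep: DEPSet,
    cap: int = DEFAULT_PATH_CAP,
    hormone: str = "hormone",
    receptor_distances: dict[str, dict[str, int]] | None = None,
) -> HEPSet:
    """Infer the HEP set: the globally shortest receptor→M(d) routes.

    One BFS per receptor (early-stopped against M(d) unless precomputed
    distances are supplied via ``receptor_distances``, keyed by receptor).
    The minimum over all (receptor, molecule) pairs defines ``min_length``;
    S and E collect exactly the participants of minimum-length pairs.  A
    receptor that is itself a DEP molecule gives ``min_length`` 0 with that
    node in both S and E.
    """
    present = sorted(r for r in receptors if r in network)
    for missing in sorted(set(receptors) - set(present)):
        logger.warning("receptor %s not in network; skipped", missing)
    empty = HEPSet(
        hormone=hormone, drug=dep.drug, disease=dep.disease, min_length=UNREACHABLE
    )
    if not present or not dep.molecules:
        return empty
    dists: dict[str, dict[str, int]] = {}
    for r in present:
        if receptor_distances is not None and r in receptor_distances:
            dists[r] = receptor_distances[r]
        else:
            dists[r] = bfs_distances(network, r, stop_set=dep.molecules).dist
    min_length = UNREACHABLE
    for r in present:
        dr = dists[r]
        for m in dep.molecules:
            d = dr.get(m, UNREACHABLE)
            if d < min_length:
                min_length = d
    if is_unreachable(min_length):
        return empty
    start = frozenset(
        r
        for r in present
        if any(dists[r].get(m, UNREACHABLE) == min_length for m in dep.molecules)
    )
    end = frozenset(
        m
        for m in dep.molecules
        if any(dists[r].get(m, UNREACHABLE) == min_length for r in present)
    )
    paths = [
        enumerate_shortest_paths(network, r, m, cap)
        for r in sorted(start)
        for m in sorted(end)
        if dists[r].get(m, UNREACHABLE) == min_length
    ]
    return HEPSet(
        hormone=hormone,
        drug=dep.drug,
        disease=dep.disease,
        min_length=int(min_length),
        start_nodes=start,
        end_nodes=end,
        paths=paths,
    )


def mechanism_report(dep: DEPSet, hep: HEPSet | None = None) -> dict:
    """Node-typed subgraph of all listed DEPs and HEPs, ready for rendering.

    Nodes are labeled with every role they play (drug_target, disease_gene,
    hormone_receptor, intermediate — roles union when they coincide); output
    ordering is deterministic.  An empty/unreachable HEP set yields a report
    with DEPs only and ``no_crosstalk_found`` set.
    """
    roles: dict[str, set[str]] = {}

    def tag(node: str, role: str) -> None:
        roles.setdefault(node, set()).add(role)

    dep_paths: list[list[str]] = []
    for entry in dep.entries:
        tag(entry.target, "drug_target")
        for g in entry.nearest_disease_genes:
            tag(g, "disease_gene")
        for ps in entry.paths:
            for path in ps.paths:
                dep_paths.append(path)
                for node in path[1:-1]:
                    tag(node, "intermediate")
    hep_paths: list[list[str]] = []
    no_crosstalk = hep is None or is_unreachable(hep.min_length)
    if hep is not None and not no_crosstalk:
        for r in hep.start_nodes:
            tag(r, "hormone_receptor")
        for ps in hep.paths:
            for path in ps.paths:
                hep_paths.append(path)
                for node in path[1:-1]:
                    tag(node, "intermediate")
    dep_paths.sort()
    hep_paths.sort()
    arcs = sorted(
        {
            (path[i], path[i + 1])
            for path in dep_paths + hep_paths
            for i in range(len(path) - 1)
        }
    )
    return {
        "drug": dep.drug,
        "disease": dep.disease,
        "hormone": hep.hormone if hep is not None else None,
        "nodes": [
            {"id": node, "roles": sorted(roles[node])} for node in sorted(roles)
        ],
        "arcs": [list(a) for a in arcs],
        "dep_paths": dep_paths,
        "n_deps": dep.n_paths,
        "hep_paths": hep_paths,
        "n_heps": hep.n_paths if hep is not None else 0,
        "hep_length": None if no_crosstalk else int(hep.min_length),
        "no_crosstalk_found": no_crosstalk,
    }
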