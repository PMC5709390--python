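"""Read, validate, filter, and assemble the heterogeneous molecular network.

Entities are genes (proteins, represented by their encoding gene) or chemical
compounds, identified by opaque strings — conventionally ``G:<entrez>`` and
``C:<kegg>`` but never validated against a registry.  Physical protein–protein
interactions and binding/dissociation events are treated as bidirectional and
materialized as reciprocal arcs; signaling and gene-regulatory interactions
keep their stated direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

GENE = "gene"
COMPOUND = "compound"
ENTITY_KINDS = frozenset({GENE, COMPOUND})

#: The eight curated signaling / regulatory relation labels plus physical PPI.
KEGG_RELATIONS = frozenset(
    {
        "activation",
        "inhibition",
        "expression",
        "repression",
        "phosphorylation",
        "dephosphorylation",
        "binding/association",
        "dissociation",
    }
)
RELATION_VOCABULARY = KEGG_RELATIONS | {"physical_ppi"}

#: Relations that are inherently symmetric: physical interaction and
#: (dis)association events.  The six remaining signaling/regulatory labels
#: are directed.
BIDIRECTIONAL_RELATIONS = frozenset(
    {"physical_ppi", "binding/association", "dissociation"}
)

EDGE_COLUMNS = ["src", "src_kind", "dst", "dst_kind", "relation", "directed", "provenance"]


class FormatError(ValueError):
    """A required column is missing or a table is empty after filtering."""


class NetworkConsistencyError(ValueError):
    """The same identifier was registered both as a gene and as a compound."""


def normalize_relation(label: str) -> str:
    """Map a raw relation label into the controlled vocabulary.

    Labels outside the vocabulary are retained, tagged ``other:<label>``.
    """
    label = label.strip()
    if label in RELATION_VOCABULARY or label.startswith("other:"):
        return label
    return f"other:{label}"


@dataclass(frozen=True)
class InteractionRecord:
    """One validated row of the molecular interaction edge table."""

    src: str
    src_kind: str
    dst: str
    dst_kind: str
    relation: str
    directed: bool
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.src == self.dst:
            raise ValueError(f"self-interaction rejected: {self.src}")
        for kind in (self.src_kind, self.dst_kind):
            if kind not in ENTITY_KINDS:
                raise ValueError(f"unknown entity kind {kind!r}")


class MolecularNetwork:
    """Mixed-direction graph of genes and compounds.

    Thin, validating wrapper over a :class:`networkx.DiGraph`.  Every node
    carries a ``kind`` attribute; every arc carries the set of relation labels
    supporting it.  Bidirectional interactions appear as reciprocal arcs.
    """

    def __init__(self) -> None:
        self._g = nx.DiGraph()

    # -- construction -----------------------------------------------------

    def add_node(self, node: str, kind: str) -> None:
        if kind not in ENTITY_KINDS:
            raise ValueError(f"unknown entity kind {kind!r}")
        existing = self._g.nodes.get(node)
        if existing is not None and existing["kind"] != kind:
            raise NetworkConsistencyError(
                f"{node!r} registered as both {existing['kind']} and {kind}"
            )
        self._g.add_node(node, kind=kind)

    def add_arc(
        self, src: str, dst: str, relations: Iterable[str], provenance: Iterable[str] = ()
    ) -> None:
        if src not in self._g or dst not in self._g:
            raise KeyError("arc endpoints must be registered nodes")
        if self._g.has_edge(src, dst):
            data = self._g.edges[src, dst]
            data["relations"] = data["relations"] | frozenset(relations)
            data["provenance"] = data["provenance"] | frozenset(provenance)
        else:
            self._g.add_edge(
                src, dst, relations=frozenset(relations), provenance=frozenset(provenance)
            )

    # -- queries ----------------------------------------------------------

    def __contains__(self, node: str) -> bool:
        return node in self._g

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_arcs(self) -> int:
        return self._g.number_of_edges()

    def nodes(self) -> Iterator[str]:
        return iter(self._g.nodes)

    def kind(self, node: str) -> str:
        return self._g.nodes[node]["kind"]

    def arcs(self) -> Iterator[tuple[str, str]]:
        return iter(self._g.edges)

    def relations(self, src: str, dst: str) -> frozenset[str]:
        return self._g.edges[src, dst]["relations"]

    def provenance(self, src: str, dst: str) -> frozenset[str]:
        return self._g.edges[src, dst]["provenance"]

    def has_arc(self, src: str, dst: str) -> bool:
        return self._g.has_edge(src, dst)

    def successors(self, node: str) -> Iterator[str]:
        return self._g.successors(node)

    def predecessors(self, node: str) -> Iterator[str]:
        return self._g.predecessors(node)

    def degree(self, node: str) -> int:
        """Number of incident arcs (in + out)."""
        return self._g.in_degree(node) + self._g.out_degree(node)

    def copy(self) -> "MolecularNetwork":
        out = MolecularNetwork()
        out._g = self._g.copy()
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularNetwork):
            return NotImplemented
        if set(self._g.nodes) != set(other._g.nodes):
            return False
        if any(self.kind(n) != other.kind(n) for n in self._g.nodes):
            return False
        if set(self._g.edges) != set(other._g.edges):
            return False
        return all(
            self.relations(u, v) == other.relations(u, v) for u, v in self._g.edges
        )

    def __repr__(self) -> str:
        return f"MolecularNetwork({self.n_nodes} nodes, {self.n_arcs} arcs)"


@dataclass
class AnnotationMaps:
    """Hormone→receptors, drug→targets, disease→genes, disease→drugs maps.

    Entities without at least one association are dropped at load time and
    recorded in :attr:`dropped` (a machine-readable audit of what was
    discarded and why).
    """

    receptors: dict[str, frozenset[str]]
    targets: dict[str, frozenset[str]]
    disease_genes: dict[str, frozenset[str]]
    disease_drugs: dict[str, frozenset[str]]
    dropped: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# loaders


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def load_interactions(
    path: str | Path, relation_filter: set[str] | frozenset[str] | None = None
) -> list[InteractionRecord]:
    """Load the edge table, dropping self-loops and malformed rows.

    Parameters
    ----------
    path
        Tab-separated edge table with header
        ``src  src_kind  dst  dst_kind  relation  directed  provenance``.
        Lines starting with ``#`` are ignored.
    relation_filter
        If given, only rows whose raw relation label is in this set survive
        (e.g. the eight curated signaling labels, excluding metabolic
        reactions).  Without a filter, labels outside the controlled
        vocabulary are retained tagged ``other:<label>``.
    """
    df = _read_tsv(path, EDGE_COLUMNS[:-1])  # provenance optional
    if "provenance" not in df.columns:
        df = df.assign(provenance="")
    records: list[InteractionRecord] = []
    n_self, n_bad, n_filtered = 0, 0, 0
    for row in df.itertuples(index=False):
        if relation_filter is not None and row.relation not in relation_filter:
            n_filtered += 1
            continue
        if row.src == row.dst:
            n_self += 1
            continue
        try:
            records.append(
                InteractionRecord(
                    src=row.src,
                    src_kind=row.src_kind,
                    dst=row.dst,
                    dst_kind=row.dst_kind,
                    relation=normalize_relation(row.relation),
                    directed=str(row.directed).strip() not in ("0", "false", "False"),
                    provenance=row.provenance,
                )
            )
        except ValueError as exc:
            n_bad += 1
            logger.warning("%s: malformed row skipped (%s)", path, exc)
    if n_self or n_bad or n_filtered:
        logger.info(
            "%s: %d records loaded, %d self-loops dropped, %d malformed, %d filtered",
            path, len(records), n_self, n_bad, n_filtered,
        )
    return records


def build_network(
    records: Iterable[InteractionRecord],
    bidirectional_relations: frozenset[str] | set[str] = BIDIRECTIONAL_RELATIONS,
) -> MolecularNetwork:
    """Assemble a :class:`MolecularNetwork` from validated records.

    A record contributes reciprocal arcs when its relation is inherently
    bidirectional or its ``directed`` flag is false; otherwise a single arc
    ``src → dst``.  Duplicate arcs merge by relation-label union.  An
    identifier seen as both gene and compound is a fatal inconsistency.
    """
    net = MolecularNetwork()
    for rec in records:
        net.add_node(rec.src, rec.src_kind)
        net.add_node(rec.dst, rec.dst_kind)
        prov = (rec.provenance,) if rec.provenance else ()
        net.add_arc(rec.src, rec.dst, [rec.relation], prov)
        if rec.relation in bidirectional_relations or not rec.directed:
            net.add_arc(rec.dst, rec.src, [rec.relation], prov)
    return net


def _load_map(
    path: str | Path,
    relation_filter: str | None = None,
    what: str = "association",
) -> tuple[dict[str, frozenset[str]], list[str]]:
    df = _read_tsv(path, ["entity_id", "associated_id"])
    if relation_filter is not None:
        if "relation" not in df.columns:
            raise FormatError(f"{path}: relation filter requested but no relation column")
        df = df[df["relation"] == relation_filter]
    out: dict[str, set[str]] = {}
    dropped: list[str] = []
    for row in df.itertuples(index=False):
        if not row.associated_id:
            dropped.append(row.entity_id)
            continue
        out.setdefault(row.entity_id, set()).add(row.associated_id)
    dropped = sorted(set(dropped) - set(out))
    for ent in dropped:
        logger.warning("%s: %s has no %s; dropped", path, ent, what)
    return {k: frozenset(v) for k, v in out.items()}, dropped


def load_annotations(
    receptor_path: str | Path,
    target_path: str | Path,
    disease_gene_path: str | Path,
    disease_drug_path: str | Path,
    disease_gene_relation: str | None = None,
) -> AnnotationMaps:
    """Load the four annotation maps from two-column TSV tables.

    Each table has columns ``entity_id  associated_id`` plus an optional
    third ``relation`` column; ``disease_gene_relation`` (e.g.
    ``"marker/mechanism"`` to keep only etiology associations) filters the
    disease-gene table on it.  Entities left without a single association are
    dropped with a warning and listed in the audit; an entirely empty map is
    fatal.
    """
    receptors, d1 = _load_map(receptor_path, what="receptor")
    targets, d2 = _load_map(target_path, what="target")
    disease_genes, d3 = _load_map(
        disease_gene_path, relation_filter=disease_gene_relation, what="disease gene"
    )
    disease_drugs, d4 = _load_map(disease_drug_path, what="treating drug")
    for name, mapping in (
        ("receptors", receptors),
        ("targets", targets),
        ("disease_genes", disease_genes),
        ("disease_drugs", disease_drugs),
    ):
        if not mapping:
            raise FormatError(f"annotation map {name!r} is empty after filtering")
    return AnnotationMaps(
        receptors=receptors,
        targets=targets,
        disease_genes=disease_genes,
        disease_drugs=disease_drugs,
        dropped={
            "receptors": d1,
            "targets": d2,
            "disease_genes": d3,
            "disease_drugs": d4,
        },
    )


def ablate_nodes(network: MolecularNetwork, nodes: Iterable[str]) -> MolecularNetwork:
    """Return a copy of the network with ``nodes`` and incident arcs removed.

    Identifiers absent from the network are ignored with a warning; the input
    network is never mutated.
    """
    out = network.copy()
    for node in nodes:
        if node in out:
            out._g.remove_node(node)
        else:
            logger.warning("ablate_nodes: %s not in network; ignored", node)
    return out


# ---------------------------------------------------------------------------
# writers


def write_network(network: MolecularNetwork, path: str | Path) -> None:
    """Serialize a network back to the edge-table dialect.

    Reciprocal arc pairs whose label sets match and consist only of
    bidirectional relations collapse back to a single ``directed=0`` row.
    Isolated nodes cannot be represented in an edge table.
    """
    rows: list[dict[str, object]] = []
    done: set[tuple[str, str]] = set()
    for u, v in sorted(network.arcs()):
        if (u, v) in done:
            continue
        rels = network.relations(u, v)
        prov = ";".join(sorted(network.provenance(u, v)))
        symmetric = (
            network.has_arc(v, u)
            and network.relations(v, u) == rels
            and rels <= BIDIRECTIONAL_RELATIONS
        )
        if symmetric:
            done.add((v, u))
        for rel in sorted(rels):
            rows.append(
                {
                    "src": u,
                    "src_kind": network.kind(u),
                    "dst": v,
                    "dst_kind": network.kind(v),
                    "relation": rel,
                    "directed": 0 if symmetric else 1,
                    "provenance": prov,
                }
            )
        done.add((u, v))
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_network(
    path: str | Path, relation_filter: set[str] | None = None
) -> MolecularNetwork:
    """Convenience composition of :func:`load_interactions` + :func:`build_network`."""
    return build_network(load_interactions(path, relation_filter))


def write_annotation_map(mapping: Mapping[str, Iterable[str]], path: str | Path) -> None:
    """Write a two-column annotation TSV (sorted, deterministic)."""
    rows = [
        {"entity_id": ent, "associated_id": assoc}
        for ent in sorted(mapping)
        for assoc in sorted(mapping[ent])
    ]
    pd.DataFrame(rows, columns=["entity_id", "associated_id"]).to_csv(
        path, sep="\t", index=False
    )
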