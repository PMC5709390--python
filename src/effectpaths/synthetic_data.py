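"""Synthetic molecular worlds with planted hormone–drug crosstalk signal.

Two generators:

* :func:`generate_worked_example` — the small worked example used throughout
  the documentation: one drug with two targets (T1, T2), one disease with
  two causal genes (S1, S2), one hormone with two receptors (R1, R2).  The
  drug has three DEPs (one of length 3 via T1, two of length 2 via T2) and
  the hormone's HEPs have length 2 (R1→M1→T2 and R1→M2→T2; R2's length-3
  route to S1 is not minimal and is excluded).

* :func:`generate_world` — parameterized random worlds in which gold
  hormone→drug pairs are wired to a drug target through a short fresh chain
  (length ``planted_hep_length``) while every other hormone–drug pair is
  either disconnected from that drug's DEP molecules or at least
  ``background_min_length`` arcs away.  Chains always use fresh intermediate
  nodes and the random filler subgraph never feeds into the planted
  machinery, so the length contract holds by construction (and is verified
  post hoc with the path-finding oracle in the test suite).

All generator output round-trips through the package's TSV writers/readers,
so tests exercise the real I/O path.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from effectpaths.benchmark import GoldPair, extract_gold_standard
from effectpaths.network_io import (
    COMPOUND,
    GENE,
    AnnotationMaps,
    MolecularNetwork,
    read_network,
    write_annotation_map,
    write_network,
)

DIRECTED_RELATIONS = (
    "activation",
    "inhibition",
    "expression",
    "repression",
    "phosphorylation",
    "dephosphorylation",
)
_GOLD_CLASSES = ("enhances", "disturbs", "adverse")


@dataclass(frozen=True)
class WorldParams:
    """Knobs of the random-world generator (all sizes in entities/arcs)."""

    n_genes: int = 40              # filler gene nodes in the random background
    n_compounds: int = 6           # filler compound nodes
    arc_density: float = 0.05      # filler arc probability per ordered pair
    ppi_fraction: float = 0.5      # fraction of filler arcs made reciprocal PPI
    n_hormones: int = 12
    n_drugs: int = 8
    n_diseases: int = 2
    n_gold_per_disease: int = 3
    max_receptors_per_hormone: int = 3
    max_targets_per_drug: int = 3
    max_dep_chain: int = 3         # DEP lengths drawn uniformly from 0..max
    planted_hep_length: int = 1    # HEP length wired for gold pairs
    background_min_length: int = 4 # minimal HEP length of any wired non-gold pair
    background_attach_prob: float = 0.5  # chance a non-gold pair is wired at all
    label_noise: float = 0.0       # fraction of gold pairs wired like background
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.arc_density <= 1):
            raise ValueError("arc_density must be in (0, 1]")
        if not (0 <= self.ppi_fraction <= 1 and 0 <= self.label_noise <= 1):
            raise ValueError("fractions must be in [0, 1]")
        for name in ("n_genes", "n_hormones", "n_drugs", "n_diseases",
                     "n_gold_per_disease", "max_receptors_per_hormone",
                     "max_targets_per_drug"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.planted_hep_length < 1:
            raise ValueError("planted_hep_length must be >= 1")
        if self.planted_hep_length >= self.background_min_length:
            raise ValueError("planted_hep_length must be < background_min_length")
        if self.n_drugs < self.n_diseases:
            raise ValueError("need at least one drug per disease")
        per_disease = -(-self.n_drugs // self.n_diseases)  # ceil
        if self.n_gold_per_disease > self.n_hormones * per_disease:
            raise ValueError("not enough hormone×drug pairs to plant the gold set")


@dataclass
class SyntheticWorld:
    """A complete generated study condition: network, annotations, labels."""

    network: MolecularNetwork
    maps: AnnotationMaps
    gold: frozenset[GoldPair]
    ddi_rows: list[dict]
    params: WorldParams | None = None
    noisy_gold: frozenset[tuple[str, str]] = frozenset()

    @property
    def gold_pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(g.pair for g in self.gold)

    def gold_for(self, disease: str) -> frozenset[tuple[str, str]]:
        drugs = self.maps.disease_drugs.get(disease, frozenset())
        return frozenset(p for p in self.gold_pairs if p[1] in drugs)

    def diseases(self) -> Iterator[str]:
        return iter(sorted(self.maps.disease_genes))


# ---------------------------------------------------------------------------
# worked-example fixture


def generate_worked_example() -> SyntheticWorld:
    """The deterministic worked example (14 nodes, all-directed arcs).

    Drug DRUG1 targets T1 and T2; disease DIS1 genes are S1 and S2; hormone
    HORM1 has receptors R1 and R2.  T1 reaches only S1 (length 3), T2 reaches
    only S2 (length 2, two parallel routes), so the drug has three DEPs.  R1
    reaches T2 in two arcs two ways; R2 reaches S1 in three arcs; the HEP
    length is therefore 2 with S = {R1} and E = {T2}.
    """
    arcs = [
        ("T1", "a1"), ("a1", "a2"), ("a2", "S1"),
        ("T2", "b1"), ("b1", "S2"), ("T2", "b2"), ("b2", "S2"),
        ("R1", "M1"), ("M1", "T2"), ("R1", "M2"), ("M2", "T2"),
        ("R2", "c1"), ("c1", "c2"), ("c2", "S1"),
    ]
    net = MolecularNetwork()
    for u, v in arcs:
        net.add_node(u, GENE)
        net.add_node(v, GENE)
        net.add_arc(u, v, ["activation"], ["fixture"])
    maps = AnnotationMaps(
        receptors={"HORM1": frozenset({"R1", "R2"})},
        targets={"DRUG1": frozenset({"T1", "T2"})},
        disease_genes={"DIS1": frozenset({"S1", "S2"})},
        disease_drugs={"DIS1": frozenset({"DRUG1"})},
    )
    return SyntheticWorld(network=net, maps=maps, gold=frozenset(), ddi_rows=[])


# ---------------------------------------------------------------------------
# random worlds


class _NodeFactory:
    def __init__(self, net: MolecularNetwork) -> None:
        self.net = net
        self.counter = 0

    def fresh(self, prefix: str, kind: str = GENE) -> str:
        self.counter += 1
        node = f"{prefix}{self.counter:04d}"
        self.net.add_node(node, kind)
        return node


def _chain(
    net: MolecularNetwork,
    factory: _NodeFactory,
    src: str,
    dst: str,
    length: int,
    rng: np.random.Generator,
    compound_prob: float = 0.2,
) -> None:
    """Directed chain src → … → dst of exactly ``length`` arcs, fresh middles."""
    if length < 1:
        raise ValueError("chain length must be >= 1")
    prev = src
    for _ in range(length - 1):
        kind = COMPOUND if rng.random() < compound_prob else GENE
        prefix = "C:x" if kind == COMPOUND else "G:x"
        mid = factory.fresh(prefix, kind)
        net.add_arc(prev, mid, [str(rng.choice(DIRECTED_RELATIONS))], ["synthetic"])
        prev = mid
    net.add_arc(prev, dst, [str(rng.choice(DIRECTED_RELATIONS))], ["synthetic"])


def generate_world(
    params: WorldParams | None = None, seed: int | None = None, **overrides
) -> SyntheticWorld:
    """Generate a random world with a planted gold/background separation.

    ``seed`` (or ``params.seed``) drives a single numpy Generator; two calls
    with the same parameters are identical.  The emitted DDI table contains
    the planted gold pairs plus unknown-class, reversed-direction, and
    non-hormone distractor rows, so gold-standard extraction is exercised for
    real and recovers exactly the planted set.
    """
    if params is None:
        params = WorldParams(**overrides)
    elif overrides:
        params = WorldParams(**{**asdict(params), **overrides})
    if seed is not None:
        params = WorldParams(**{**asdict(params), "seed": seed})
    params.validate()
    rng = np.random.default_rng(params.seed)

    net = MolecularNetwork()
    factory = _NodeFactory(net)

    # diseases and their drugs (round-robin assignment)
    diseases = [f"DIS{i + 1}" for i in range(params.n_diseases)]
    drugs = [f"DRUG{i + 1}" for i in range(params.n_drugs)]
    disease_drugs = {
        dis: frozenset(drugs[i] for i in range(params.n_drugs) if i % params.n_diseases == di)
        for di, dis in enumerate(diseases)
    }

    # drug targets wired to fresh disease genes through random-length chains;
    # disease genes are fresh per target so the DEP molecule sets of any two
    # drugs are disjoint and chains cannot shortcut across drugs
    targets: dict[str, frozenset[str]] = {}
    disease_genes: dict[str, set[str]] = {dis: set() for dis in diseases}
    for di, dis in enumerate(diseases):
        for drug in sorted(disease_drugs[dis]):
            t_nodes = [
                factory.fresh("G:T") for _ in range(int(rng.integers(1, params.max_targets_per_drug + 1)))
            ]
            targets[drug] = frozenset(t_nodes)
            for t in t_nodes:
                dep_len = int(rng.integers(0, params.max_dep_chain + 1))
                if dep_len == 0:
                    disease_genes[dis].add(t)  # target IS a disease gene
                else:
                    s = factory.fresh("G:S")
                    _chain(net, factory, t, s, dep_len, rng)
                    disease_genes[dis].add(s)

    # hormones and receptors
    hormones = [f"HORM{i + 1}" for i in range(params.n_hormones)]
    receptors = {
        h: frozenset(
            factory.fresh("G:R")
            for _ in range(int(rng.integers(1, params.max_receptors_per_hormone + 1)))
        )
        for h in hormones
    }

    # select gold pairs, then flip exactly round(label_noise * |gold|) of
    # them to background-style wiring so the realized noise fraction is
    # controlled rather than a Bernoulli draw per pair
    selected: list[tuple[str, str]] = []
    for dis in diseases:
        dis_drugs = sorted(disease_drugs[dis])
        universe = [(h, d) for h in hormones for d in dis_drugs]
        for k in rng.choice(len(universe), size=params.n_gold_per_disease, replace=False):
            selected.append(universe[k])
    n_flips = round(params.label_noise * len(selected))
    noisy: set[tuple[str, str]] = set()
    if n_flips:
        for k in rng.choice(len(selected), size=n_flips, replace=False):
            noisy.add(selected[k])
    gold: set[GoldPair] = set()
    for h, d in selected:
        r = sorted(receptors[h])[int(rng.integers(len(receptors[h])))]
        t = sorted(targets[d])[int(rng.integers(len(targets[d])))]
        length = (
            params.background_min_length + int(rng.integers(0, 2))
            if (h, d) in noisy
            else params.planted_hep_length
        )
        _chain(net, factory, r, t, length, rng)
        gold.add(
            GoldPair(
                hormone=h,
                drug=d,
                relation_class=str(rng.choice(_GOLD_CLASSES)),
                provenance="synthetic",
            )
        )

    # background wiring: long chains from some non-gold pairs, the rest stay
    # disconnected from the drug machinery entirely
    gold_pairs = {g.pair for g in gold}
    for h in hormones:
        for dis in diseases:
            for d in sorted(disease_drugs[dis]):
                if (h, d) in gold_pairs or rng.random() >= params.background_attach_prob:
                    continue
                r = sorted(receptors[h])[int(rng.integers(len(receptors[h])))]
                t = sorted(targets[d])[int(rng.integers(len(targets[d])))]
                length = params.background_min_length + int(rng.integers(0, 2))
                _chain(net, factory, r, t, length, rng)

    # random filler subgraph, sealed off from the planted machinery
    fillers = [factory.fresh("G:F") for _ in range(params.n_genes)] + [
        factory.fresh("C:F", COMPOUND) for _ in range(params.n_compounds)
    ]
    for i, u in enumerate(fillers):
        for j, v in enumerate(fillers):
            if i >= j or rng.random() >= params.arc_density:
                continue
            if rng.random() < params.ppi_fraction:
                net.add_arc(u, v, ["physical_ppi"], ["synthetic"])
                net.add_arc(v, u, ["physical_ppi"], ["synthetic"])
            else:
                net.add_arc(u, v, [str(rng.choice(DIRECTED_RELATIONS))], ["synthetic"])

    # Every node must carry at least one arc (the edge-table dialect cannot
    # express isolated nodes).  Unwired receptors and zero-length targets
    # point *into* the filler pool; fillers never point back at the planted
    # machinery, so these arcs cannot shorten any receptor→M(d) distance.
    for h in hormones:
        for r in sorted(receptors[h]):
            if net.degree(r) == 0:
                f = fillers[int(rng.integers(len(fillers)))]
                net.add_arc(r, f, ["activation"], ["synthetic"])
    for drug in sorted(targets):
        for t in sorted(targets[drug]):
            if net.degree(t) == 0:
                f = fillers[int(rng.integers(len(fillers)))]
                net.add_arc(t, f, ["activation"], ["synthetic"])
    isolated = [f for f in fillers if net.degree(f) == 0]
    if len(isolated) >= 2:
        for a, b in zip(isolated, isolated[1:]):
            net.add_arc(a, b, ["activation"], ["synthetic"])
    elif len(isolated) == 1:
        others = [f for f in fillers if f != isolated[0]]
        if others:
            net.add_arc(isolated[0], others[0], ["activation"], ["synthetic"])
        else:  # a single-filler world: hang the filler off a disease gene
            anchor = sorted(next(iter(disease_genes.values())))[0]
            net.add_arc(anchor, isolated[0], ["activation"], ["synthetic"])

    maps = AnnotationMaps(
        receptors=receptors,
        targets=targets,
        disease_genes={dis: frozenset(v) for dis, v in disease_genes.items()},
        disease_drugs=disease_drugs,
    )

    # DDI table: gold rows plus distractors that extraction must reject
    ddi_rows = [
        {
            "actor": g.hormone,
            "recipient": g.drug,
            "relation_class": g.relation_class,
            "provenance": "synthetic",
        }
        for g in sorted(gold, key=lambda g: g.pair)
    ]
    non_gold = [(h, d) for h in hormones for d in drugs if (h, d) not in gold_pairs]
    n_distract = min(3, len(non_gold))
    for k in rng.choice(len(non_gold), size=n_distract, replace=False):
        h, d = non_gold[k]
        ddi_rows.append(
            {"actor": h, "recipient": d, "relation_class": "unknown", "provenance": "synthetic"}
        )
    some_gold = sorted(gold, key=lambda g: g.pair)[0]
    ddi_rows.append(  # reversed direction: drug acting on hormone
        {
            "actor": some_gold.drug,
            "recipient": some_gold.hormone,
            "relation_class": "enhances",
            "provenance": "synthetic",
        }
    )
    ddi_rows.append(  # actor outside the hormone set
        {"actor": "NOTAHORMONE", "recipient": drugs[0], "relation_class": "disturbs",
         "provenance": "synthetic"}
    )

    return SyntheticWorld(
        network=net,
        maps=maps,
        gold=frozenset(gold),
        ddi_rows=ddi_rows,
        params=params,
        noisy_gold=frozenset(noisy),
    )


def verify_length_contract(world: SyntheticWorld) -> dict:
    """Post-hoc oracle check of the planted/background HEP-length contract.

    Recomputes every (hormone, disease-drug) HEP length with the path-finding
    machinery and checks that non-noisy gold pairs sit at
    ``planted_hep_length`` or shorter while every other pair is at least
    ``background_min_length`` away or disconnected.  Returns the violations
    (empty lists mean the contract holds).
    """
    from effectpaths.pathfinding import is_unreachable
    from effectpaths.scoring import hep_table

    if world.params is None:
        raise ValueError("world has no generation parameters to verify against")
    p = world.params
    gold_violations: list[tuple[str, str]] = []
    background_violations: list[tuple[str, str]] = []
    for disease in world.diseases():
        gold_here = world.gold_for(disease)
        for (h, d), hep in hep_table(world.network, world.maps, disease).items():
            length = hep.min_length
            if (h, d) in gold_here and (h, d) not in world.noisy_gold:
                if is_unreachable(length) or length > p.planted_hep_length:
                    gold_violations.append((h, d))
            elif (h, d) not in gold_here:
                if not is_unreachable(length) and length < p.background_min_length:
                    background_violations.append((h, d))
    return {
        "ok": not gold_violations and not background_violations,
        "gold_violations": sorted(gold_violations),
        "background_violations": sorted(background_violations),
    }


# ---------------------------------------------------------------------------
# file round-trip


WORLD_FILES = {
    "network": "network.tsv",
    "receptors": "receptors.tsv",
    "targets": "targets.tsv",
    "disease_genes": "disease_genes.tsv",
    "disease_drugs": "disease_drugs.tsv",
    "ddi": "ddi.tsv",
    "params": "params.json",
}


def write_world(world: SyntheticWorld, out_dir: str | Path) -> Path:
    """Serialize a world to the package's TSV dialects in ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_network(world.network, out / WORLD_FILES["network"])
    write_annotation_map(world.maps.receptors, out / WORLD_FILES["receptors"])
    write_annotation_map(world.maps.targets, out / WORLD_FILES["targets"])
    write_annotation_map(world.maps.disease_genes, out / WORLD_FILES["disease_genes"])
    write_annotation_map(world.maps.disease_drugs, out / WORLD_FILES["disease_drugs"])
    pd.DataFrame(
        world.ddi_rows, columns=["actor", "recipient", "relation_class", "provenance"]
    ).to_csv(out / WORLD_FILES["ddi"], sep="\t", index=False)
    meta = {
        "params": asdict(world.params) if world.params is not None else None,
        "noisy_gold": sorted(list(p) for p in world.noisy_gold),
    }
    (out / WORLD_FILES["params"]).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return out


def read_world(in_dir: str | Path) -> SyntheticWorld:
    """Load a world back from :func:`write_world` output.

    The gold set is re-extracted from the serialized DDI table (against all
    hormones and all drugs), so the round trip exercises the extraction path.
    """
    src = Path(in_dir)
    network = read_network(src / WORLD_FILES["network"])

    from effectpaths.network_io import load_annotations

    maps = load_annotations(
        src / WORLD_FILES["receptors"],
        src / WORLD_FILES["targets"],
        src / WORLD_FILES["disease_genes"],
        src / WORLD_FILES["disease_drugs"],
    )
    ddi = pd.read_csv(src / WORLD_FILES["ddi"], sep="\t", dtype=str, keep_default_na=False)
    all_drugs = {d for ds in maps.disease_drugs.values() for d in ds}
    gold = extract_gold_standard(ddi, maps.receptors.keys(), all_drugs)
    params = None
    noisy: frozenset[tuple[str, str]] = frozenset()
    meta_path = src / WORLD_FILES["params"]
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if meta.get("params") is not None:
            params = WorldParams(**meta["params"])
        noisy = frozenset(tuple(p) for p in meta.get("noisy_gold", []))
    return SyntheticWorld(
        network=network,
        maps=maps,
        gold=frozenset(gold),
        ddi_rows=ddi.to_dict("records"),
        params=params,
        noisy_gold=noisy,
    )
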