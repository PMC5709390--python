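"""The interference score i(h, d) and ranked candidate tables.

For a hormone h and drug d under a fixed disease,

    i(h, d) = alpha ** (-L) * n(S) * n(E)

where L is the HEP length (the minimal shortest-path distance from any
receptor of h to any molecule of the drug's DEPs), n(S) the number of
distinct receptors achieving L, and n(E) the number of distinct DEP
molecules achieving L.  alpha > 1 is the decay constant, default 8 (the
value at which ranking performance saturates).  No HEP at all means
infinite L and a score of exactly 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from effectpaths.effect_paths import HEPSet, infer_deps, infer_heps
from effectpaths.network_io import AnnotationMaps, MolecularNetwork
from effectpaths.pathfinding import DEFAULT_PATH_CAP, UNREACHABLE, bfs_distances, is_unreachable

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 8.0


@dataclass(frozen=True)
class PairScore:
    """Eq.-style interference score with its components."""

    hormone: str
    drug: str
    disease: str
    hep_length: float  # int or UNREACHABLE
    n_start: int
    n_end: int
    alpha: float
    score: float
    unscorable: bool = False  # drug had no usable DEPs


def score_from_hep(hep: HEPSet, alpha: float = DEFAULT_ALPHA) -> PairScore:
    """Closed-form evaluation of the decay score for one HEP set."""
    if alpha <= 1:
        raise ValueError(f"alpha must be > 1, got {alpha}")
    if is_unreachable(hep.min_length):
        return PairScore(
            hormone=hep.hormone,
            drug=hep.drug,
            disease=hep.disease,
            hep_length=UNREACHABLE,
            n_start=0,
            n_end=0,
            alpha=alpha,
            score=0.0,
        )
    n_s, n_e = len(hep.start_nodes), len(hep.end_nodes)
    return PairScore(
        hormone=hep.hormone,
        drug=hep.drug,
        disease=hep.disease,
        hep_length=int(hep.min_length),
        n_start=n_s,
        n_end=n_e,
        alpha=alpha,
        score=alpha ** (-hep.min_length) * n_s * n_e,
    )


def hep_table(
    network: MolecularNetwork,
    maps: AnnotationMaps,
    disease: str,
    hormones: set[str] | frozenset[str] | None = None,
    cap: int = DEFAULT_PATH_CAP,
) -> dict[tuple[str, str], HEPSet]:
    """HEP sets for every (hormone, disease-treating drug) pair of a disease.

    DEPs are computed once per drug and reused across hormones; full BFS
    distance maps are computed once per distinct receptor and shared.  Drugs
    with no usable DEP set map to unreachable HEP sets.
    """
    if disease not in maps.disease_genes:
        raise KeyError(f"unknown disease {disease!r}")
    if hormones is None:
        hormones = frozenset(maps.receptors)
    drugs = sorted(maps.disease_drugs.get(disease, frozenset()))
    genes = maps.disease_genes[disease]
    deps = {
        drug: infer_deps(
            network,
            maps.targets.get(drug, frozenset()),
            genes,
            cap=cap,
            drug=drug,
            disease=disease,
        )
        for drug in drugs
    }
    receptor_dists: dict[str, dict[str, int]] = {}
    for h in hormones:
        for r in maps.receptors.get(h, frozenset()):
            if r in network and r not in receptor_dists:
                receptor_dists[r] = bfs_distances(network, r).dist
    out: dict[tuple[str, str], HEPSet] = {}
    for h in sorted(hormones):
        receptors = maps.receptors.get(h, frozenset())
        for drug in drugs:
            out[(h, drug)] = infer_heps(
                network,
                receptors,
                deps[drug],
                cap=cap,
                hormone=h,
                receptor_distances=receptor_dists,
            )
    return out


def score_all_pairs(
    network: MolecularNetwork,
    maps: AnnotationMaps,
    disease: str,
    hormones: set[str] | frozenset[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    cap: int = DEFAULT_PATH_CAP,
) -> list[PairScore]:
    """One :class:`PairScore` per (hormone, disease-treating drug) pair.

    Deterministic: pairs are emitted in (hormone, drug) lexicographic order.
    Drugs whose DEP set is unscorable (no target in the network) keep their
    pairs in the output with score 0 and the ``unscorable`` flag so dataset
    sizes stay constant across evaluation replicates.
    """
    if disease not in maps.disease_genes:
        raise KeyError(f"unknown disease {disease!r}")
    genes = maps.disease_genes[disease]
    drugs = sorted(maps.disease_drugs.get(disease, frozenset()))
    unscorable = {
        drug
        for drug in drugs
        if infer_deps(
            network, maps.targets.get(drug, frozenset()), genes, cap=1, drug=drug,
            disease=disease,
        ).unscorable
    }
    heps = hep_table(network, maps, disease, hormones, cap=cap)
    out = []
    for (h, drug), hep in sorted(heps.items()):
        ps = score_from_hep(hep, alpha)
        if drug in unscorable:
            ps = PairScore(
                hormone=h, drug=drug, disease=disease, hep_length=UNREACHABLE,
                n_start=0, n_end=0, alpha=alpha, score=0.0, unscorable=True,
            )
        out.append(ps)
    return out


def rank_scores(scores: list[PairScore]) -> list[PairScore]:
    """Descending by score; ties broken by (hormone, drug) lexicographically."""
    return sorted(scores, key=lambda s: (-s.score, s.hormone, s.drug))


def select_candidates(
    scores: list[PairScore],
    gold: set[tuple[str, str]],
    top_k: int = 10,
    min_score: float = 1.0,
) -> list[PairScore]:
    """Unlabeled high-scoring pairs: rank ≤ top_k, score > min_score, not gold."""
    ranked = rank_scores(scores)
    return [
        s
        for rank, s in enumerate(ranked, start=1)
        if rank <= top_k and s.score > min_score and (s.hormone, s.drug) not in gold
    ]
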