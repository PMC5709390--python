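"""Gold-standard assembly, unlabeled sampling, and ranking evaluation.

Gold hormone→drug influence pairs come from a pre-classified directional
drug–drug-interaction table (classes: enhances / disturbs / adverse;
"unknown" rows are discarded).  Presumed-negative "unlabeled" pairs are
sampled uniformly from hormone × disease-treating-drug pairs outside the
gold set, in five replicates at 1/3/5/7/10 times the gold size.  Ranking
quality is measured by AUROC (midrank-corrected Mann–Whitney statistic) and
AUPR (non-interpolated step area).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from effectpaths.effect_paths import HEPSet
from effectpaths.network_io import AnnotationMaps, FormatError, MolecularNetwork
from effectpaths.pathfinding import DEFAULT_PATH_CAP, is_unreachable
from effectpaths.scoring import DEFAULT_ALPHA, PairScore, hep_table, score_from_hep

logger = logging.getLogger(__name__)

RELATION_CLASSES = frozenset({"enhances", "disturbs", "adverse"})
DEFAULT_MULTIPLIERS = (1, 3, 5, 7, 10)
DEFAULT_N_REPLICATES = 5


@dataclass(frozen=True)
class GoldPair:
    """A directed hormone→drug influence extracted from classified DDIs."""

    hormone: str
    drug: str
    relation_class: str
    provenance: str = ""
    direction: str = "hormone_affects_drug"

    def __post_init__(self) -> None:
        if self.relation_class not in RELATION_CLASSES:
            raise ValueError(f"relation_class must be one of {sorted(RELATION_CLASSES)}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.hormone, self.drug)


@dataclass
class EvaluationDataset:
    """Gold pairs plus replicated unlabeled samples at one size multiplier."""

    disease: str
    gold: frozenset[tuple[str, str]]
    unlabeled_replicates: list[frozenset[tuple[str, str]]]
    multiplier: int
    seeds: list[int]
    truncated: bool = False


@dataclass
class EvalMetrics:
    auroc: float
    aupr: float
    roc_points: list[tuple[float, float]]
    pr_points: list[tuple[float, float]]
    n_pos: int
    n_neg: int


def extract_gold_standard(
    ddi_table: str | Path | pd.DataFrame,
    hormones: Iterable[str],
    disease_drugs: Iterable[str],
) -> set[GoldPair]:
    """Keep directed actor→recipient rows with actor a hormone, recipient a
    disease-treating drug, and a known relation class.

    The table needs columns ``actor  recipient  relation_class`` (plus an
    optional ``provenance``); direction is preserved, so a drug acting on a
    hormone never becomes a gold pair.
    """
    if isinstance(ddi_table, pd.DataFrame):
        df = ddi_table
    else:
        df = pd.read_csv(ddi_table, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in ("actor", "recipient", "relation_class"):
        if col not in df.columns:
            raise FormatError(f"DDI table missing required column {col!r}")
    hormones = set(hormones)
    drugs = set(disease_drugs)
    out: set[GoldPair] = set()
    for row in df.itertuples(index=False):
        if row.relation_class == "unknown" or row.relation_class not in RELATION_CLASSES:
            continue
        if row.actor in hormones and row.recipient in drugs:
            out.add(
                GoldPair(
                    hormone=row.actor,
                    drug=row.recipient,
                    relation_class=row.relation_class,
                    provenance=getattr(row, "provenance", ""),
                )
            )
    if not out:
        logger.warning("gold standard extraction produced an empty set")
    return out


def _as_pairs(gold: Iterable[GoldPair | tuple[str, str]]) -> frozenset[tuple[str, str]]:
    return frozenset(g.pair if isinstance(g, GoldPair) else tuple(g) for g in gold)


def sample_unlabeled(
    hormones: Iterable[str],
    disease_drugs: Iterable[str],
    gold: Iterable[GoldPair | tuple[str, str]],
    multiplier: int,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
    disease: str = "",
) -> EvaluationDataset:
    """Uniform without-replacement samples of non-gold hormone×drug pairs.

    Replicate i uses seed + i, so a dataset is fully reproducible from its
    base seed.  If the pair universe is smaller than multiplier × |gold|,
    every replicate takes the whole universe and the dataset is flagged
    truncated.
    """
    gold_pairs = _as_pairs(gold)
    universe = sorted(
        (h, d)
        for h in set(hormones)
        for d in set(disease_drugs)
        if (h, d) not in gold_pairs
    )
    if not universe:
        raise ValueError("no non-gold pairs available to sample")
    want = multiplier * len(gold_pairs)
    take = min(want, len(universe))
    replicates = []
    seeds = []
    for i in range(n_replicates):
        rng = np.random.default_rng(seed + i)
        idx = rng.choice(len(universe), size=take, replace=False)
        replicates.append(frozenset(universe[j] for j in idx))
        seeds.append(seed + i)
    return EvaluationDataset(
        disease=disease,
        gold=gold_pairs,
        unlabeled_replicates=replicates,
        multiplier=multiplier,
        seeds=seeds,
        truncated=take < want,
    )


# ---------------------------------------------------------------------------
# metrics


def compute_auroc(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> EvalMetrics:
    """AUROC via the midrank Mann–Whitney statistic; AUPR via step area.

    ROC and precision–recall points are emitted at every distinct threshold
    (scores descending).  Requires at least one score in each class.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    auroc = float(u / (pos.size * neg.size))

    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    distinct = np.r_[np.nonzero(np.diff(scores))[0], scores.size - 1]
    tp = np.cumsum(labels)[distinct]
    fp = np.cumsum(1 - labels)[distinct]
    tpr = tp / pos.size
    fpr = fp / neg.size
    roc_points = [(0.0, 0.0)] + list(zip(fpr.tolist(), tpr.tolist()))
    precision = tp / (tp + fp)
    recall = tpr
    pr_points = list(zip(recall.tolist(), precision.tolist()))
    # non-interpolated area: sum precision * recall increment
    prev_recall = 0.0
    aupr = 0.0
    for r, p in pr_points:
        aupr += (r - prev_recall) * p
        prev_recall = r
    return EvalMetrics(
        auroc=auroc,
        aupr=float(aupr),
        roc_points=roc_points,
        pr_points=pr_points,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


def trapezoid_auroc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """ROC-curve trapezoidal area; rank-statistic cross-check."""
    m = compute_auroc(pos_scores, neg_scores)
    xs, ys = zip(*m.roc_points)
    return float(np.trapezoid(ys, xs))


# ---------------------------------------------------------------------------
# evaluation pipeline


def _score_lookup(
    heps: Mapping[tuple[str, str], HEPSet], alpha: float
) -> dict[tuple[str, str], float]:
    return {pair: score_from_hep(hep, alpha).score for pair, hep in heps.items()}


def evaluate_dataset(
    heps: Mapping[tuple[str, str], HEPSet],
    dataset: EvaluationDataset,
    alpha: float = DEFAULT_ALPHA,
) -> list[EvalMetrics]:
    """Per-replicate AUROC/AUPR of gold vs unlabeled pair scores.

    ``heps`` must cover every gold and unlabeled pair (see
    :func:`effectpaths.scoring.hep_table`); pairs missing from it count as
    score 0 (no crosstalk found).
    """
    scores = _score_lookup(heps, alpha)
    pos = [scores.get(p, 0.0) for p in sorted(dataset.gold)]
    out = []
    for replicate in dataset.unlabeled_replicates:
        neg = [scores.get(p, 0.0) for p in sorted(replicate)]
        out.append(compute_auroc(pos, neg))
    return out


def run_evaluation(
    network: MolecularNetwork,
    maps: AnnotationMaps,
    gold_by_disease: Mapping[str, Iterable[GoldPair | tuple[str, str]]],
    multipliers: Sequence[int] = DEFAULT_MULTIPLIERS,
    n_replicates: int = DEFAULT_N_REPLICATES,
    alpha: float = DEFAULT_ALPHA,
    cap: int = DEFAULT_PATH_CAP,
    seed: int = 0,
) -> list[dict]:
    """Full protocol: per disease × multiplier × replicate metric records.

    Each disease gets ``n_replicates`` independently sampled unlabeled sets
    at every multiplier (replicate seeds are derived from ``seed`` and kept
    disjoint across diseases and multipliers), and HEP sets are computed
    once per disease, then reused for every dataset.
    """
    records: list[dict] = []
    for di, disease in enumerate(sorted(gold_by_disease)):
        gold = _as_pairs(gold_by_disease[disease])
        if not gold:
            logger.warning("disease %s has no gold pairs; skipped", disease)
            continue
        heps = hep_table(network, maps, disease, cap=cap)
        for mi, mult in enumerate(multipliers):
            base_seed = seed + 1000 * di + 100 * mi
            dataset = sample_unlabeled(
                maps.receptors.keys(),
                maps.disease_drugs.get(disease, frozenset()),
                gold,
                multiplier=mult,
                n_replicates=n_replicates,
                seed=base_seed,
                disease=disease,
            )
            for rep, metrics in enumerate(evaluate_dataset(heps, dataset, alpha)):
                records.append(
                    {
                        "disease": disease,
                        "multiplier": mult,
                        "replicate": rep,
                        "seed": dataset.seeds[rep],
                        "alpha": alpha,
                        "auroc": metrics.auroc,
                        "aupr": metrics.aupr,
                        "n_pos": metrics.n_pos,
                        "n_neg": metrics.n_neg,
                        "truncated": dataset.truncated,
                    }
                )
    return records


def sweep_alpha(
    world,
    alphas: Sequence[float],
    datasets: Sequence[EvaluationDataset],
    cap: int = DEFAULT_PATH_CAP,
) -> pd.DataFrame:
    """Mean AUROC over datasets/replicates for each decay constant.

    HEP sets are computed once per disease; only the closed-form score is
    re-evaluated per alpha, so the sweep is cheap and the alpha ordering of
    any two pairs with equal n(S)·n(E) never changes.
    """
    if any(a <= 1 for a in alphas):
        raise ValueError("every alpha must be > 1")
    heps_by_disease = {
        ds.disease: hep_table(world.network, world.maps, ds.disease, cap=cap)
        for ds in datasets
    }
    rows = []
    for alpha in alphas:
        aurocs = []
        for ds in datasets:
            for m in evaluate_dataset(heps_by_disease[ds.disease], ds, alpha):
                aurocs.append(m.auroc)
        rows.append({"alpha": float(alpha), "mean_auroc": float(np.mean(aurocs))})
    return pd.DataFrame(rows)


def compare_hep_lengths(
    gold_heps: Sequence[HEPSet], unlabeled_heps: Sequence[HEPSet]
) -> dict:
    """Welch two-sample t-test and ≤1-length percentages, gold vs unlabeled.

    Unreachable lengths are excluded from the means and the test but counted
    as "not ≤ 1" in the percentages, which are taken over *all* pairs.
    """
    g = [float(h.min_length) for h in gold_heps]
    u = [float(h.min_length) for h in unlabeled_heps]
    g_fin = [x for x in g if not is_unreachable(x)]
    u_fin = [x for x in u if not is_unreachable(x)]
    out = {
        "mean_gold": float(np.mean(g_fin)) if g_fin else float("nan"),
        "mean_unlabeled": float(np.mean(u_fin)) if u_fin else float("nan"),
        "pct_le1_gold": 100.0 * sum(x <= 1 for x in g) / len(g) if g else float("nan"),
        "pct_le1_unlabeled": 100.0 * sum(x <= 1 for x in u) / len(u) if u else float("nan"),
        "n_gold": len(g),
        "n_unlabeled": len(u),
        "n_gold_unreachable": len(g) - len(g_fin),
        "n_unlabeled_unreachable": len(u) - len(u_fin),
        "t_stat": float("nan"),
        "p_value": float("nan"),
    }
    if len(g_fin) >= 2 and len(u_fin) >= 2:
        t, p = stats.ttest_ind(g_fin, u_fin, equal_var=False)
        out["t_stat"], out["p_value"] = float(t), float(p)
    return out


def ablation_rescore(
    network: MolecularNetwork,
    maps: AnnotationMaps,
    disease: str,
    nodes: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
    cap: int = DEFAULT_PATH_CAP,
) -> tuple[list[PairScore], list[PairScore]]:
    """Scores before and after removing ``nodes`` (e.g. shared receptors).

    Used for the robustness experiment in which promiscuous receptors are
    deleted from the network and the whole disease is rescored.
    """
    from effectpaths.network_io import ablate_nodes
    from effectpaths.scoring import score_all_pairs

    before = score_all_pairs(network, maps, disease, alpha=alpha, cap=cap)
    after = score_all_pairs(ablate_nodes(network, nodes), maps, disease, alpha=alpha, cap=cap)
    return before, after


def stratified_folds(
    gold: Iterable[tuple[str, str]],
    unlabeled: Iterable[tuple[str, str]],
    n_folds: int = 10,
    n_repeats: int = 30,
    seed: int = 0,
) -> list[list[dict]]:
    """Repeated stratified folds with an identical positive:unlabeled ratio.

    Returns ``n_repeats`` fold lists; each fold is a dict with ``test_gold``
    and ``test_unlabeled`` pair lists.  Harness only — no model fitting is
    required by the scoring method itself.
    """
    gold = sorted(set(gold))
    unlabeled = sorted(set(unlabeled))
    repeats = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(seed + rep)
        gperm = [gold[i] for i in rng.permutation(len(gold))]
        uperm = [unlabeled[i] for i in rng.permutation(len(unlabeled))]
        folds = []
        for k in range(n_folds):
            folds.append(
                {
                    "test_gold": gperm[k::n_folds],
                    "test_unlabeled": uperm[k::n_folds],
                }
            )
        repeats.append(folds)
    return repeats


# ---------------------------------------------------------------------------
# external interfaces


def scores_table(
    scores: Iterable[PairScore],
    labels: Mapping[tuple[str, str], str] | None = None,
    replicate: int | None = None,
    dataset_id: str = "",
) -> pd.DataFrame:
    """Flat scores table in the TSV dialect used by the CLI."""
    rows = []
    for s in scores:
        rows.append(
            {
                "disease": s.disease,
                "hormone": s.hormone,
                "drug": s.drug,
                "hep_length": "inf" if is_unreachable(s.hep_length) else int(s.hep_length),
                "n_start": s.n_start,
                "n_end": s.n_end,
                "alpha": s.alpha,
                "score": s.score,
                "label": (labels or {}).get((s.hormone, s.drug), "unknown"),
                "replicate": "" if replicate is None else replicate,
                "dataset_id": dataset_id,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "disease", "hormone", "drug", "hep_length", "n_start", "n_end",
            "alpha", "score", "label", "replicate", "dataset_id",
        ],
    )


def write_metrics_json(records: list[dict], path: str | Path) -> None:
    """Metrics report: per-record list plus aggregate means, sorted keys."""
    aggregate = {}
    if records:
        df = pd.DataFrame(records)
        aggregate = {
            "mean_auroc": float(df["auroc"].mean()),
            "mean_aupr": float(df["aupr"].mean()),
            "mean_auroc_by_multiplier": {
                str(k): float(v) for k, v in df.groupby("multiplier")["auroc"].mean().items()
            },
        }
    payload = {"records": records, "aggregate": aggregate}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
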