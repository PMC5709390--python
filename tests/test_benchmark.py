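import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import pairwise_auroc
from effectpaths.benchmark import (
    ablation_rescore,
    compare_hep_lengths,
    compute_auroc,
    evaluate_dataset,
    extract_gold_standard,
    run_evaluation,
    sample_unlabeled,
    stratified_folds,
    sweep_alpha,
    trapezoid_auroc,
)
from effectpaths.effect_paths import HEPSet
from effectpaths.network_io import FormatError
from effectpaths.pathfinding import UNREACHABLE
from effectpaths.scoring import hep_table


def ddi_frame(rows):
    return pd.DataFrame(rows, columns=["actor", "recipient", "relation_class"])


class TestGoldStandard:
    def test_direction_and_unknown_filtering(self):
        df = ddi_frame(
            [
                ("H1", "D1", "enhances"),
                ("D2", "H1", "disturbs"),   # reversed direction: drug acts on hormone
                ("H1", "D3", "unknown"),
            ]
        )
        gold = extract_gold_standard(df, {"H1"}, {"D1", "D2", "D3"})
        assert {g.pair for g in gold} == {("H1", "D1")}

    def test_drug_outside_disease_treating_set_excluded(self):
        df = ddi_frame([("H1", "D9", "adverse")])
        assert extract_gold_standard(df, {"H1"}, {"D1"}) == set()

    def test_empty_intersection_warns_but_returns_empty(self):
        df = ddi_frame([("X", "Y", "enhances")])
        assert extract_gold_standard(df, {"H1"}, {"D1"}) == set()

    def test_missing_relation_class_column_is_fatal(self):
        df = pd.DataFrame([{"actor": "H1", "recipient": "D1"}])
        with pytest.raises(FormatError):
            extract_gold_standard(df, {"H1"}, {"D1"})


class TestSampleUnlabeled:
    hormones = {f"H{i}" for i in range(10)}
    drugs = {f"D{i}" for i in range(5)}
    gold = {("H0", "D0"), ("H1", "D1"), ("H2", "D2")}

    def test_replicate_sizes_and_gold_disjointness(self):
        ds = sample_unlabeled(self.hormones, self.drugs, self.gold, multiplier=10, seed=4)
        assert len(ds.unlabeled_replicates) == 5
        for rep in ds.unlabeled_replicates:
            assert len(rep) == 30
            assert not rep & ds.gold
        assert not ds.truncated
        # independent samples should differ with overwhelming probability
        assert len(set(ds.unlabeled_replicates)) > 1

    def test_universe_smaller_than_request_takes_all_and_flags(self):
        ds = sample_unlabeled({"H0", "H1"}, {"D0"}, {("H0", "D0")}, multiplier=3, seed=0)
        assert ds.truncated
        assert all(rep == frozenset({("H1", "D0")}) for rep in ds.unlabeled_replicates)

    def test_forced_exact_universe_not_flagged(self):
        ds = sample_unlabeled({"H0", "H1"}, {"D0"}, {("H0", "D0")}, multiplier=1, seed=0)
        assert not ds.truncated
        assert all(rep == frozenset({("H1", "D0")}) for rep in ds.unlabeled_replicates)

    def test_same_seed_reproduces_exactly(self):
        a = sample_unlabeled(self.hormones, self.drugs, self.gold, multiplier=5, seed=9)
        b = sample_unlabeled(self.hormones, self.drugs, self.gold, multiplier=5, seed=9)
        assert a.unlabeled_replicates == b.unlabeled_replicates


class TestAuroc:
    def test_perfect_separation(self):
        m = compute_auroc([3.0, 2.5, 2.0], [1.0, 0.5, 0.0, 0.1])
        assert m.auroc == 1.0

    def test_full_tie_gives_half(self):
        m = compute_auroc([1.0] * 4, [1.0] * 6)
        assert m.auroc == 0.5

    def test_hand_listed_scores_match_exhaustive_pair_oracle(self):
        pos = [0.9, 0.8, 0.8, 0.5, 0.2, 0.0]
        neg = [0.8, 0.7, 0.5, 0.5, 0.4, 0.3, 0.2, 0.0, 0.0]
        m = compute_auroc(pos, neg)
        assert m.auroc == pytest.approx(pairwise_auroc(pos, neg), abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auroc([], [1.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_rank_statistic_equals_trapezoid_area(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.choice(np.linspace(0, 1, 7), size=12).tolist()
        neg = rng.choice(np.linspace(0, 1, 7), size=20).tolist()
        m = compute_auroc(pos, neg)
        assert m.auroc == pytest.approx(trapezoid_auroc(pos, neg), abs=1e-12)

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import average_precision_score, roc_auc_score

        rng = np.random.default_rng(12)
        pos = rng.normal(1, 1, size=25)
        neg = rng.normal(0, 1, size=40)
        m = compute_auroc(pos, neg)
        y = np.r_[np.ones(25), np.zeros(40)]
        s = np.r_[pos, neg]
        assert m.auroc == pytest.approx(roc_auc_score(y, s), abs=1e-12)
        assert m.aupr == pytest.approx(average_precision_score(y, s), abs=1e-12)

    def test_label_shuffle_null_centers_at_half(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=30)
        aurocs = []
        for _ in range(100):
            perm = rng.permutation(30)
            aurocs.append(compute_auroc(scores[perm[:10]], scores[perm[10:]]).auroc)
        assert np.mean(aurocs) == pytest.approx(0.5, abs=0.05)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    pos=st.lists(st.integers(min_value=0, max_value=5), min_size=1, max_size=10),
    neg=st.lists(st.integers(min_value=0, max_value=5), min_size=1, max_size=10),
)
def test_auroc_equals_pairwise_win_probability(pos, neg):
    pos, neg = [float(x) for x in pos], [float(x) for x in neg]
    assert compute_auroc(pos, neg).auroc == pytest.approx(pairwise_auroc(pos, neg), abs=1e-12)


class TestHepLengthComparison:
    def hep(self, length):
        return HEPSet(hormone="h", drug="d", disease="x", min_length=length)

    def test_hand_computed_welch_statistic(self):
        out = compare_hep_lengths(
            [self.hep(0), self.hep(0), self.hep(1)],
            [self.hep(2), self.hep(3), self.hep(2), self.hep(3)],
        )
        assert out["mean_gold"] == pytest.approx(1 / 3)
        assert out["mean_unlabeled"] == pytest.approx(2.5)
        assert out["pct_le1_gold"] == 100.0
        assert out["pct_le1_unlabeled"] == 0.0
        # Welch: t = (1/3 - 5/2) / sqrt((1/3)/3 + (1/3)/4) = -4.9135...
        assert out["t_stat"] == pytest.approx(-4.913538, abs=1e-5)
        assert out["t_stat"] < 0

    def test_unreachable_excluded_from_means_counted_in_percentages(self):
        out = compare_hep_lengths(
            [self.hep(0), self.hep(UNREACHABLE)],
            [self.hep(2), self.hep(2), self.hep(UNREACHABLE)],
        )
        assert out["mean_gold"] == 0.0
        assert out["pct_le1_gold"] == 50.0
        assert out["n_gold_unreachable"] == 1
        assert np.isnan(out["t_stat"])  # < 2 finite lengths in the gold group

    def test_identical_distributions_not_significant(self):
        heps = [self.hep(k % 3) for k in range(12)]
        out = compare_hep_lengths(heps, list(heps))
        assert out["p_value"] > 0.05

    def test_planted_world_gold_paths_shorter(self, planted_world):
        world = planted_world
        disease = next(world.diseases())
        heps = hep_table(world.network, world.maps, disease)
        gold = world.gold_for(disease)
        gold_heps = [h for p, h in heps.items() if p in gold]
        other_heps = [h for p, h in heps.items() if p not in gold]
        out = compare_hep_lengths(gold_heps, other_heps)
        assert out["mean_gold"] < out["mean_unlabeled"]
        assert out["pct_le1_gold"] > out["pct_le1_unlabeled"]


class TestEvaluationPipeline:
    def test_noiseless_world_perfect_in_every_replicate(self, planted_world):
        world = planted_world
        records = run_evaluation(
            world.network, world.maps,
            {d: world.gold_for(d) for d in world.diseases()}, seed=0,
        )
        assert len(records) == 2 * 5 * 5  # diseases x multipliers x replicates
        assert all(r["auroc"] == 1.0 for r in records)
        assert not any(r["truncated"] for r in records)

    def test_alpha_sweep_consistent_with_direct_evaluation(self, planted_world):
        world = planted_world
        disease = next(world.diseases())
        gold = world.gold_for(disease)
        ds = sample_unlabeled(
            world.maps.receptors.keys(), world.maps.disease_drugs[disease],
            gold, multiplier=3, seed=2, disease=disease,
        )
        table = sweep_alpha(world, [8.0], [ds])
        assert list(table.columns) == ["alpha", "mean_auroc"]
        assert len(table) == 1
        heps = hep_table(world.network, world.maps, disease)
        direct = np.mean([m.auroc for m in evaluate_dataset(heps, ds, alpha=8.0)])
        assert table["mean_auroc"][0] == pytest.approx(direct, abs=0)

    def test_alpha_sweep_rejects_degenerate_alpha(self, planted_world):
        with pytest.raises(ValueError):
            sweep_alpha(planted_world, [0.5], [])

    def test_receptor_ablation_changes_only_dependent_hormones(self, planted_world):
        world = planted_world
        disease = next(world.diseases())
        victim = sorted(world.gold_for(disease))[0][0]
        removed = world.maps.receptors[victim]
        before, after = ablation_rescore(world.network, world.maps, disease, removed)
        changed = {
            s1.hormone
            for s1, s2 in zip(before, after)
            if s1.score != s2.score
        }
        assert changed == {victim}

    def test_stratified_folds_preserve_ratio(self):
        gold = [(f"H{i}", "D") for i in range(10)]
        unlabeled = [(f"U{i}", "D") for i in range(100)]
        repeats = stratified_folds(gold, unlabeled, n_folds=10, n_repeats=3, seed=1)
        assert len(repeats) == 3
        for folds in repeats:
            assert len(folds) == 10
            for fold in folds:
                assert len(fold["test_gold"]) == 1
                assert len(fold["test_unlabeled"]) == 10
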