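"""Fold construction, SVM weight ranking, elimination schedule, aggregation."""

import numpy as np
import pandas as pd
import pytest

import canprio as cp
from canprio.errors import ConfigError
from canprio.rfe import elimination_count, pairwise_svm_weights


def _classes(n_samples, k):
    return {f"s{i:03d}": f"C{i % k}" for i in range(n_samples)}


def test_fold_plan_counts_200_runs():
    cfg = cp.RFEConfig(n_folds=4, n_repeats=50, seed=0)
    plan = cp.make_fold_plan(_classes(47, 7), cfg)
    assert plan.n_runs == 200
    assert len(plan.assignments) == 50


def test_fold_plan_balance_47_samples_7_classes():
    cfg = cp.RFEConfig(n_folds=4, n_repeats=3, seed=1)
    classes = _classes(47, 7)
    plan = cp.make_fold_plan(classes, cfg)
    for assignment in plan.assignments:
        sizes = sorted(
            sum(f == fold for f in assignment.values()) for fold in range(4)
        )
        assert sizes == [11, 12, 12, 12]
        for c in set(classes.values()):
            occ = [
                sum(1 for s, f in assignment.items() if f == fold and classes[s] == c)
                for fold in range(4)
            ]
            assert max(occ) - min(occ) <= 1


def test_fold_plan_multiple_of_folds_gives_identical_composition():
    cfg = cp.RFEConfig(n_folds=4, n_repeats=2, seed=2)
    classes = _classes(24, 3)  # every class has 8 = 2*4 members
    plan = cp.make_fold_plan(classes, cfg)
    for assignment in plan.assignments:
        comps = []
        for fold in range(4):
            comp = sorted(
                classes[s] for s, f in assignment.items() if f == fold
            )
            comps.append(comp)
        assert all(c == comps[0] for c in comps)


def test_fold_plan_singleton_class_errors():
    classes = {"s1": "A", "s2": "A", "s3": "B"}
    with pytest.raises(ConfigError, match="class B has 1 member"):
        cp.make_fold_plan(classes, cp.RFEConfig(seed=0))


def test_fold_plan_deterministic_under_seed():
    cfg = cp.RFEConfig(n_folds=4, n_repeats=5, seed=7)
    classes = _classes(30, 3)
    a = cp.make_fold_plan(classes, cfg)
    b = cp.make_fold_plan(classes, cfg)
    assert a.assignments == b.assignments
    assert a.training_sets == b.training_sets


def test_weight_ranking_prefers_separating_feature():
    rng = np.random.default_rng(0)
    y = ["A"] * 5 + ["B"] * 5
    f1 = np.array([0.0] * 5 + [1.0] * 5)
    f2 = rng.normal(size=10)  # pure noise
    X = pd.DataFrame({"f1": f1, "f2": f2})
    scores = cp.rank_features_by_weights(X, y, cost=1.0)
    assert scores["f1"] > scores["f2"]


def test_duplicate_feature_columns_score_equally():
    rng = np.random.default_rng(1)
    y = ["A"] * 6 + ["B"] * 6
    f = np.array([0.0] * 6 + [1.0] * 6) + rng.normal(0, 0.05, 12)
    X = pd.DataFrame({"fa": f, "fb": f, "noise": rng.normal(size=12)})
    scores = cp.rank_features_by_weights(X, y, cost=0.5)
    assert scores["fa"] == pytest.approx(scores["fb"], abs=1e-9)


def test_three_classes_yield_three_pairwise_classifiers():
    rng = np.random.default_rng(2)
    y = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
    X = rng.normal(size=(12, 5))
    W = pairwise_svm_weights(X, y, cost=0.01)
    assert W.shape == (3, 5)


def test_degenerate_training_set_errors():
    X = np.ones((6, 3))
    with pytest.raises(ConfigError, match="constant"):
        pairwise_svm_weights(X, ["A", "A", "A", "B", "B", "B"], cost=0.01)


@pytest.mark.parametrize(
    "start,expected_sizes",
    [(20, [18, 16, 15]), (16, [15]), (418, None)],
)
def test_elimination_schedule(start, expected_sizes):
    cfg = cp.RFEConfig(elimination_fraction=0.10, stop_n=15, seed=0)
    sizes = []
    n = start
    while n > cfg.stop_n:
        n -= elimination_count(n, cfg)
        sizes.append(n)
    if expected_sizes is not None:
        assert sizes == expected_sizes
    assert sizes[-1] == 15  # always lands exactly on the stop condition


def test_single_run_removes_down_to_stop_n():
    rng = np.random.default_rng(3)
    y = ["A"] * 10 + ["B"] * 10
    X = pd.DataFrame(
        rng.normal(size=(20, 30)), columns=[f"g{i:02d}" for i in range(30)]
    )
    X["g00"] += np.array([0.0] * 10 + [3.0] * 10)
    run = cp.rfe_single_run(X, y, cp.RFEConfig(stop_n=15, seed=0))
    assert len(run.final_features) == 15
    assert "g00" in run.final_features
    # elimination_step covers every starting feature, 0 only for survivors
    assert set(run.elimination_step) == set(X.columns)
    survivors = {f for f, s in run.elimination_step.items() if s == 0}
    assert survivors == run.final_features


def _planted_run(n_repeats=5, seed=0):
    """Small planted problem: 24 regions in 3 classes, 12 of 40 genes carry
    a class-specific bump."""
    cfg = cp.SyntheticConfig(
        n_genes=40, n_regions=24, k_region_clusters=3, k_gene_clusters=1,
        n_informative_genes=12, signal=3.0, noise_sd=0.3, seed=seed,
    )
    matrix, truth = cp.generate_expression(cfg)
    z = cp.zscore_rows(matrix)
    rcfg = cp.RFEConfig(n_repeats=n_repeats, stop_n=12, seed=seed)
    runs, ranking = cp.run_msvm_rfe(
        z.values, truth.region_labels, truth.gene_labels, rcfg
    )
    return runs, ranking, truth, rcfg


def test_selection_frequency_conservation_and_ranks():
    runs, ranking, truth, rcfg = _planted_run()
    assert ranking.table["frequency"].sum() == len(runs) * rcfg.stop_n
    assert sorted(ranking.table["rank"]) == list(range(1, len(ranking.table) + 1))
    # a gene never selected has frequency 0
    never = set(ranking.table.gene_id) - set().union(
        *(r.final_features for r in runs)
    )
    zero = set(ranking.table.loc[ranking.table.frequency == 0, "gene_id"])
    assert never == zero


def test_planted_genes_dominate_ranking():
    _, ranking, truth, rcfg = _planted_run()
    top = set(ranking.table.head(rcfg.stop_n).gene_id)
    assert len(top & truth.informative_genes) >= 10


def test_run_msvm_rfe_deterministic():
    _, r1, _, _ = _planted_run(n_repeats=2, seed=5)
    _, r2, _, _ = _planted_run(n_repeats=2, seed=5)
    pd.testing.assert_frame_equal(r1.table, r2.table)


def test_cloned_feature_gets_adjacent_rank():
    rng = np.random.default_rng(6)
    genes = [f"g{i:02d}" for i in range(10)]
    z = pd.DataFrame(
        rng.normal(size=(10, 16)), index=genes,
        columns=[f"s{i:02d}" for i in range(16)],
    )
    z.loc["g00"] = np.array([0.0] * 8 + [2.0] * 8) + rng.normal(0, 0.1, 16)
    z.loc["g01"] = z.loc["g00"]  # clone
    labels = {f"s{i:02d}": "A" if i < 8 else "B" for i in range(16)}
    cfg = cp.RFEConfig(n_folds=4, n_repeats=4, stop_n=3, seed=1)
    _, ranking = cp.run_msvm_rfe(z, labels, None, cfg)
    t = ranking.table.set_index("gene_id")
    assert abs(int(t.loc["g00", "rank"]) - int(t.loc["g01", "rank"])) == 1
    # tie broken toward the lexicographically smaller id
    if t.loc["g00", "frequency"] == t.loc["g01", "frequency"]:
        assert t.loc["g00", "rank"] < t.loc["g01", "rank"]


def test_permutation_null_breaks_planted_gene_dominance():
    _, ranking, truth, rcfg = _planted_run(n_repeats=3, seed=2)
    t = ranking.table.set_index("gene_id")
    informative_sum = t.loc[sorted(truth.informative_genes), "frequency"].sum()
    cfg = cp.SyntheticConfig(
        n_genes=40, n_regions=24, k_region_clusters=3, k_gene_clusters=1,
        n_informative_genes=12, signal=3.0, noise_sd=0.3, seed=2,
    )
    matrix, t2 = cp.generate_expression(cfg)
    z = cp.zscore_rows(matrix)
    rng = np.random.default_rng(0)
    regions = list(t2.region_labels)
    shuffled = dict(zip(regions, rng.permutation([t2.region_labels[r] for r in regions])))
    _, null_rank = cp.run_msvm_rfe(
        z.values, shuffled, None, cp.RFEConfig(n_repeats=3, stop_n=12, seed=2)
    )
    tn = null_rank.table.set_index("gene_id")
    null_sum = tn.loc[sorted(t2.informative_genes), "frequency"].sum()
    assert null_sum < 0.5 * informative_sum


def test_top_hub_partition():
    _, ranking, t, rcfg = _planted_run()
    # top_n = n_genes -> partition sizes equal the gene-cluster sizes
    part = cp.top_hub_genes(ranking, top_n=len(ranking.table))
    sizes = {c: len(g) for c, g in part.items()}
    want = {}
    for g, c in t.gene_labels.items():
        want[c] = want.get(c, 0) + 1
    assert sizes == want
    with pytest.raises(ConfigError):
        cp.top_hub_genes(ranking, top_n=0)
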