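"""Multiclass linear-SVM recursive feature elimination over repeated folds.

Regions are the observations (classified into their region-cluster label),
genes are the features. Within each repeat the regions are dealt into
stratified folds and every leave-one-fold-out combination becomes one RFE
run: linear one-vs-one soft-margin SVMs are fit, features are scored by the
summed squared weights across the pairwise classifiers, and the lowest-
scoring 10% (by default) are discarded until a fixed number survive. Genes
are then ranked by how often they survive across all runs, with the mean
elimination step breaking ties (later elimination, and survival in
particular, is better).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import ConfigError

__all__ = [
    "RFEConfig",
    "FoldPlan",
    "RFERun",
    "HubGeneRanking",
    "make_fold_plan",
    "pairwise_svm_weights",
    "rank_features_by_weights",
    "rfe_single_run",
    "run_msvm_rfe",
    "top_hub_genes",
]


@dataclass(frozen=True)
class RFEConfig:
    n_folds: int = 4
    n_repeats: int = 50
    elimination_fraction: float = 0.10
    stop_n: int = 15
    svm_cost: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.n_repeats < 1:
            raise ConfigError(f"n_repeats must be >= 1, got {self.n_repeats}")
        if not 0 < self.elimination_fraction < 1:
            raise ConfigError(
                f"elimination_fraction must be in (0, 1), got {self.elimination_fraction}"
            )
        if self.stop_n < 1:
            raise ConfigError(f"stop_n must be >= 1, got {self.stop_n}")
        if self.svm_cost <= 0:
            raise ConfigError(f"svm_cost must be > 0, got {self.svm_cost}")


@dataclass(frozen=True)
class TrainingSet:
    repeat: int
    holdout_fold: int
    sample_ids: tuple[str, ...]


@dataclass
class FoldPlan:
    """Stratified fold assignments per repeat plus the enumerated training sets."""

    n_folds: int
    assignments: list[dict[str, int]]  # per repeat: sample -> fold
    training_sets: list[TrainingSet]

    @property
    def n_runs(self) -> int:
        return len(self.training_sets)


@dataclass
class RFERun:
    run_id: str
    sample_ids: tuple[str, ...]
    final_features: frozenset[str]
    elimination_step: dict[str, int]  # 0 for survivors
    n_steps: int


@dataclass
class HubGeneRanking:
    """Aggregate per-gene selection statistics across all RFE runs."""

    table: pd.DataFrame  # gene_id, frequency, mean_elim_step, rank, cluster
    n_runs: int
    stop_n: int

    def top(self, n: int) -> pd.DataFrame:
        return self.table.nsmallest(n, "rank").sort_values("rank")


def make_fold_plan(
    sample_classes: Mapping[str, object], config: RFEConfig
) -> FoldPlan:
    """Deal samples into stratified folds, ``n_repeats`` times.

    Within each repeat, every class's members are shuffled and dealt
    round-robin to folds with a pointer that runs continuously across the
    (sorted) classes, so per-class fold occupancy and total fold sizes both
    differ by at most 1. Training sets are all (n_folds - 1)-subsets of folds.
    """
    by_class: dict[object, list[str]] = {}
    for s, c in sample_classes.items():
        by_class.setdefault(c, []).append(s)
    for c, members in by_class.items():
        if len(members) < 2:
            raise ConfigError(
                f"class {c} has 1 member; stratified folds with all-but-one-fold "
                "training cannot guarantee class presence"
            )
    rng = np.random.default_rng(config.seed)
    classes = sorted(by_class, key=str)
    assignments: list[dict[str, int]] = []
    training_sets: list[TrainingSet] = []
    fold_ids = list(range(config.n_folds))
    for rep in range(config.n_repeats):
        assignment: dict[str, int] = {}
        ptr = 0
        for c in classes:
            members = sorted(by_class[c])
            rng.shuffle(members)
            for s in members:
                assignment[s] = ptr % config.n_folds
                ptr += 1
        assignments.append(assignment)
        for train_folds in combinations(fold_ids, config.n_folds - 1):
            holdout = (set(fold_ids) - set(train_folds)).pop()
            samples = tuple(
                s for s in sorted(assignment) if assignment[s] in train_folds
            )
            training_sets.append(TrainingSet(rep, holdout, samples))
    return FoldPlan(config.n_folds, assignments, training_sets)


def pairwise_svm_weights(
    X: np.ndarray, y: Sequence[object], cost: float
) -> np.ndarray:
    """Weight matrix (one row per one-vs-one linear SVM) at the given cost."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ConfigError("training set must contain at least 2 classes")
    if np.allclose(X.std(axis=0), 0):
        raise ConfigError("degenerate training set: all features are constant")
    clf = SVC(C=cost, kernel="linear", decision_function_shape="ovo")
    clf.fit(X, y)
    return np.asarray(clf.coef_)


def rank_features_by_weights(
    X: pd.DataFrame, y: Sequence[object], cost: float
) -> pd.Series:
    """Feature score = sum over pairwise classifiers of squared weights."""
    W = pairwise_svm_weights(X.to_numpy(dtype=float), y, cost)
    return pd.Series((W**2).sum(axis=0), index=X.columns)


def elimination_count(n_remaining: int, config: RFEConfig) -> int:
    """Features to drop this iteration: ceil(fraction * remaining), at least 1,
    clamped so the loop lands exactly on ``stop_n``."""
    return min(
        max(1, math.ceil(config.elimination_fraction * n_remaining)),
        n_remaining - config.stop_n,
    )


def rfe_single_run(
    X: pd.DataFrame,
    y: Sequence[object],
    config: RFEConfig,
    run_id: str = "run",
) -> RFERun:
    """One recursive elimination pass from all features down to ``stop_n``.

    Score ties are broken by removing the lexicographically larger gene id
    first.
    """
    features = list(X.columns)
    if len(features) <= config.stop_n:
        raise ConfigError(
            f"need more than stop_n={config.stop_n} features, got {len(features)}"
        )
    elim: dict[str, int] = {f: 0 for f in features}
    remaining = list(features)
    step = 0
    while len(remaining) > config.stop_n:
        step += 1
        scores = rank_features_by_weights(X[remaining], y, config.svm_cost)
        m = elimination_count(len(remaining), config)
        # ascending score; ties -> lexicographically larger id removed first
        order = sorted(remaining, reverse=True)
        order.sort(key=lambda f: scores[f])  # stable

        for f in order[:m]:
            elim[f] = step
            remaining.remove(f)
    return RFERun(
        run_id=run_id,
        sample_ids=tuple(X.index),
        final_features=frozenset(remaining),
        elimination_step=elim,
        n_steps=step,
    )


def run_msvm_rfe(
    z_values: pd.DataFrame,
    region_labels: Mapping[str, object],
    gene_cluster_labels: Mapping[str, object] | None,
    config: RFEConfig,
) -> tuple[list[RFERun], HubGeneRanking]:
    """All RFE runs over the fold plan plus the aggregate hub-gene ranking.

    ``z_values`` is genes × regions (the z-scored matrix); regions become the
    observations. Aggregation: selection frequency (descending), then mean
    elimination step (descending; survivors count as one past the last step),
    then gene id.
    """
    missing = [r for r in z_values.columns if r not in region_labels]
    if missing:
        raise ConfigError(f"regions without class labels: {missing[:5]}")
    X_all = z_values.T  # regions x genes
    plan = make_fold_plan(
        {r: region_labels[r] for r in z_values.columns}, config
    )
    runs: list[RFERun] = []
    for ts in plan.training_sets:
        X = X_all.loc[list(ts.sample_ids)]
        y = [region_labels[r] for r in ts.sample_ids]
        runs.append(
            rfe_single_run(
                X, y, config, run_id=f"rep{ts.repeat:03d}_holdout{ts.holdout_fold}"
            )
        )

    genes = list(z_values.index)
    n_runs = len(runs)
    freq = {g: 0 for g in genes}
    step_sum = {g: 0.0 for g in genes}
    for run in runs:
        survivor_step = run.n_steps + 1
        for g in genes:
            s = run.elimination_step[g]
            step_sum[g] += s if s > 0 else survivor_step
        for g in run.final_features:
            freq[g] += 1
    mean_step = {g: step_sum[g] / n_runs for g in genes}
    ordered = sorted(genes, key=lambda g: (-freq[g], -mean_step[g], g))
    table = pd.DataFrame(
        {
            "gene_id": ordered,
            "frequency": [freq[g] for g in ordered],
            "mean_elim_step": [mean_step[g] for g in ordered],
            "rank": np.arange(1, len(ordered) + 1),
            "cluster": [
                (gene_cluster_labels or {}).get(g, None) for g in ordered
            ],
        }
    )
    return runs, HubGeneRanking(table=table, n_runs=n_runs, stop_n=config.stop_n)


def top_hub_genes(
    ranking: HubGeneRanking, top_n: int = 99
) -> dict[object, list[str]]:
    """The first ``top_n`` genes by aggregate rank, partitioned by gene cluster."""
    n_genes = len(ranking.table)
    if top_n <= 0:
        raise ConfigError(f"top_n must be positive, got {top_n}")
    if top_n > n_genes:
        raise ConfigError(f"top_n={top_n} exceeds the {n_genes} ranked genes")
    head = ranking.table.sort_values("rank").head(top_n)
    partition: dict[object, list[str]] = {}
    for _, row in head.iterrows():
        partition.setdefault(row["cluster"], []).append(row["gene_id"])
    return partition
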