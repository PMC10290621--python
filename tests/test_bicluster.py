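"""Z-scoring, Ward linkage (with a brute-force oracle), silhouette k-selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

import canprio as cp
from canprio.bicluster import to_newick
from canprio.errors import ConfigError


def brute_force_ward(X: np.ndarray):
    """Greedy agglomeration that exhaustively picks the merge with the smallest
    within-cluster sum-of-squares increase. Heights are sqrt(2 * deltaSS), the
    convention under which two singletons merge at their Euclidean distance.
    Returns a list of (frozenset_a, frozenset_b, height)."""
    clusters = {i: [i] for i in range(len(X))}
    merges = []
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                ma = X[clusters[a]].mean(axis=0)
                mb = X[clusters[b]].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                d_ss = na * nb / (na + nb) * float(((ma - mb) ** 2).sum())
                if best is None or d_ss < best[0]:
                    best = (d_ss, a, b)
        d_ss, a, b = best
        merges.append((frozenset(clusters[a]), frozenset(clusters[b]), np.sqrt(2 * d_ss)))
        clusters[min(a, b)] = clusters.pop(a) + clusters.pop(b)
    return merges


def mean_silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Direct evaluation of the silhouette formula (independent of sklearn)."""
    D = squareform(pdist(X))
    s = []
    for i in range(len(X)):
        same = (labels == labels[i]) & (np.arange(len(X)) != i)
        if not same.any():
            s.append(0.0)
            continue
        a = D[i, same].mean()
        b = min(
            D[i, labels == c].mean() for c in set(labels) if c != labels[i]
        )
        s.append((b - a) / max(a, b))
    return float(np.mean(s))


def _zmatrix(frame):
    return cp.zscore_rows(cp.ExpressionMatrix(frame))


def test_zscore_row_values_and_dropping():
    frame = pd.DataFrame(
        [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["g1", "gflat"],
        columns=["a", "b", "c"],
    )
    z = _zmatrix(frame)
    assert np.allclose(z.values.loc["g1"], [-1.0, 0.0, 1.0])
    assert z.dropped_rows == ["gflat"]
    retained = z.values.to_numpy()
    assert np.all(np.abs(retained.mean(axis=1)) < 1e-9)
    assert np.all(np.abs(retained.std(axis=1, ddof=1) - 1) < 1e-9)


def test_zscore_all_constant_errors():
    frame = pd.DataFrame([[1.0, 1.0]], index=["g"], columns=["a", "b"])
    with pytest.raises(ConfigError):
        _zmatrix(frame)


def test_ward_two_points_merge_at_euclidean_distance():
    frame = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"], columns=["x", "y"])
    tree = cp.ward_linkage(frame)
    assert tree.linkage[0, 2] == pytest.approx(5.0)


def test_ward_four_point_merge_order_and_cut():
    pts = pd.DataFrame({"x": [0.0, 0.1, 10.0, 10.1]}, index=list("abcd"))
    tree = cp.ward_linkage(pts)
    first_two = {frozenset(map(int, tree.linkage[i, :2])) for i in range(2)}
    assert first_two == {frozenset({0, 1}), frozenset({2, 3})}
    labels = cp.cut_tree(tree, 2)
    assert labels["a"] == labels["b"] != labels["c"] == labels["d"]
    # first-appearance numbering starts at 1 along the leaf ordering
    assert labels[tree.leaf_order()[0]] == 1


@pytest.mark.parametrize("n,dim,seed", [(5, 3, 0), (6, 2, 1), (7, 4, 2), (8, 5, 3)])
def test_ward_matches_brute_force_oracle(n, dim, seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, dim))
    frame = pd.DataFrame(X, index=[f"i{k}" for k in range(n)])
    tree = cp.ward_linkage(frame)
    oracle = brute_force_ward(X)
    # same heights, same merged leaf sets, same order
    members = {i: frozenset({i}) for i in range(n)}
    for step, (oa, ob, oh) in enumerate(oracle):
        a, b, h = int(tree.linkage[step, 0]), int(tree.linkage[step, 1]), tree.linkage[step, 2]
        sa, sb = members[a], members[b]
        members[n + step] = sa | sb
        assert {sa, sb} == {oa, ob}
        assert h == pytest.approx(oh, abs=1e-9)


def test_ward_heights_monotone(blockdiag_bundle):
    _, matrix, _, _ = blockdiag_bundle
    z = cp.zscore_rows(matrix)
    tree = cp.ward_linkage(z.values, axis="regions")
    assert np.all(np.diff(tree.linkage[:, 2]) >= -1e-12)


def test_cut_tree_bounds_and_nesting():
    rng = np.random.default_rng(4)
    frame = pd.DataFrame(rng.normal(size=(9, 3)), index=[f"i{k}" for k in range(9)])
    tree = cp.ward_linkage(frame)
    assert len(set(cp.cut_tree(tree, 1).values())) == 1
    assert len(set(cp.cut_tree(tree, 9).values())) == 9
    with pytest.raises(ConfigError):
        cp.cut_tree(tree, 0)
    # partitions nest as k decreases
    prev = cp.cut_tree(tree, 5)
    for k in (4, 3, 2):
        cur = cp.cut_tree(tree, k)
        for i in frame.index:
            for j in frame.index:
                if prev[i] == prev[j]:
                    assert cur[i] == cur[j]
        prev = cur


def _blobs(k, per=10, sep=50.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.concatenate([rng.normal(c * sep, 1.0, size=(per, 2)) for c in range(k)])
    return pd.DataFrame(X, index=[f"i{j}" for j in range(k * per)])


@pytest.mark.parametrize("k", [2, 3])
def test_silhouette_recovers_blob_count(k):
    frame = _blobs(k)
    tree = cp.ward_linkage(frame)
    assign = cp.silhouette_select_k(frame, tree, 2, 6)
    assert assign.k == k
    # profile values agree with a direct evaluation of the silhouette formula
    for kk, val in assign.silhouette_by_k.items():
        labels = cp.cut_tree(tree, kk)
        arr = np.array([labels[i] for i in frame.index])
        assert val == pytest.approx(mean_silhouette(frame.to_numpy(), arr), abs=1e-9)


def test_bicluster_recovers_planted_gene_clusters(two_gene_cluster_matrix):
    _, matrix, truth, regions = two_gene_cluster_matrix
    res = cp.bicluster(matrix, regions)
    assert res.genes.k == 2
    got = [res.genes.labels[g] for g in matrix.gene_ids]
    want = [truth.gene_labels[g] for g in matrix.gene_ids]
    assert adjusted_rand_score(want, got) == 1.0
    # naming follows mean expression in feedforward vs feedback regions
    assert set(res.gene_cluster_names.values()) == {"FF-ANS", "FB-ANS"}
    ff_cluster = next(c for c, n in res.gene_cluster_names.items() if n == "FF-ANS")
    ff_genes = res.genes.members(ff_cluster)
    assert {truth.gene_labels[g] for g in ff_genes} == {0}


def test_bicluster_recovers_planted_region_count(blockdiag_bundle):
    _, matrix, truth, _ = blockdiag_bundle
    res = cp.bicluster(matrix)
    assert res.regions.k == 7
    got = [res.regions.labels[r] for r in matrix.region_ids]
    want = [truth.region_labels[r] for r in matrix.region_ids]
    assert adjusted_rand_score(want, got) == 1.0


def test_clustering_invariant_to_positive_row_rescaling(two_gene_cluster_matrix):
    _, matrix, _, _ = two_gene_cluster_matrix
    rng = np.random.default_rng(5)
    scales = rng.uniform(0.1, 10.0, size=matrix.shape[0])
    scaled = cp.ExpressionMatrix(matrix.values.mul(scales, axis=0))
    a = cp.bicluster(matrix)
    b = cp.bicluster(scaled)
    assert a.genes.k == b.genes.k and a.regions.k == b.regions.k
    for axis in ("genes", "regions"):
        ids = matrix.gene_ids if axis == "genes" else matrix.region_ids
        la = [getattr(a, axis).labels[i] for i in ids]
        lb = [getattr(b, axis).labels[i] for i in ids]
        assert adjusted_rand_score(la, lb) == 1.0


def test_newick_round_trips_leaf_names():
    frame = _blobs(2, per=4)
    tree = cp.ward_linkage(frame)
    nwk = to_newick(tree)
    assert nwk.endswith(";")
    for leaf in frame.index:
        assert leaf in nwk
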