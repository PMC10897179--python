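"""Path-tree construction, split detection and per-node TF ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from timegrn import (
    SplitPathModel,
    log_ratio_transform,
    rank_tfs_at_node,
    top_k_union,
)
from timegrn.paths import PathNode


def test_log_ratio_identity_and_closed_form():
    tpm = pd.DataFrame({0: [1.0, 2.0], 1: [1.0, 2.0], 2: [3.0, 2.0]},
                       index=["a", "b"])
    out = log_ratio_transform(tpm, pseudo=1.0)
    assert (out[0] == 0).all()
    assert out.at["a", 1] == 0.0
    assert out.at["a", 2] == pytest.approx(1.0)  # log2(4/2)


def test_log_ratio_matches_cellwise_recomputation():
    rng = np.random.default_rng(5)
    tpm = pd.DataFrame(rng.uniform(0, 50, size=(5, 3)),
                       index=[f"g{i}" for i in range(5)], columns=[0, 1, 2])
    out = log_ratio_transform(tpm, pseudo=1.0)
    for g in tpm.index:
        for t in tpm.columns:
            expected = math.log2((tpm.at[g, t] + 1) / (tpm.at[g, 0] + 1))
            assert out.at[g, t] == pytest.approx(expected)


def test_negative_tpm_rejected():
    tpm = pd.DataFrame({0: [1.0], 1: [-0.5]}, index=["a"])
    with pytest.raises(ValueError, match="negative"):
        log_ratio_transform(tpm)


def _two_branch_ratios(n_per_branch=100, effect=2.0, sd=0.1, seed=7, T=4, t_b=1):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_branch
    means = np.zeros((n, T))
    means[:n_per_branch, t_b:] = effect
    means[n_per_branch:, t_b:] = -effect
    ratios = means + rng.normal(0, sd, size=(n, T))
    ratios[:, 0] = 0.0
    genes = [f"g{i:03d}" for i in range(n)]
    truth = np.array([0] * n_per_branch + [1] * n_per_branch)
    return pd.DataFrame(ratios, index=genes, columns=range(T)), truth


def test_constant_profiles_yield_no_split():
    ratios = pd.DataFrame(np.zeros((100, 4)), index=[f"g{i}" for i in range(100)])
    model = SplitPathModel(random_state=0).fit(ratios)
    assert model.n_splits_ == 0
    assert len(model.tree_.nodes_at(3)) == 1


def test_two_branch_data_gives_one_split_with_accurate_assignment():
    ratios, truth = _two_branch_ratios(seed=7)
    model = SplitPathModel(random_state=7).fit(ratios)
    tree = model.tree_
    assert tree.n_splits == 1
    assert tree.split_timepoints == [1]
    up, down = [n for n in tree.split_branches if n.timepoint == 1]
    genes = np.asarray(model.gene_ids_)
    got = np.where(np.isin(genes, list(up.genes)), 0, 1)
    truth_sorted = truth[np.argsort(np.asarray(ratios.index, object))]
    acc = max((got == truth_sorted).mean(), (got != truth_sorted).mean())
    assert acc >= 0.99
    assert up.mean_log2fc > down.mean_log2fc


def test_tiny_input_keeps_partition_property():
    ratios = pd.DataFrame([[0.0, 2.0], [0.0, -2.0]], index=["a", "b"])
    model = SplitPathModel(min_node_size=1, random_state=0).fit(ratios)
    tree = model.tree_
    assert tree.n_splits <= 1
    for t in (0, 1):
        genes = sorted(g for n in tree.nodes_at(t) for g in n.genes)
        assert genes == ["a", "b"]


def test_single_timepoint_gives_root_only():
    ratios = pd.DataFrame(np.zeros((30, 1)), index=[f"g{i}" for i in range(30)])
    model = SplitPathModel().fit(ratios)
    assert len(model.tree_.nodes) == 1
    assert model.tree_.root.timepoint == 0


def test_more_bic_margin_never_more_splits():
    ratios, _ = _two_branch_ratios(seed=3, sd=0.5)
    counts = [
        SplitPathModel(bic_margin=m, random_state=1).fit(ratios).n_splits_
        for m in (0.0, 5.0, 10.0, 100.0, 1e9)
    ]
    assert counts == sorted(counts, reverse=True)
    assert counts[-1] == 0


def _edges(rows):
    return pd.DataFrame(rows, columns=["tf", "gene", "timepoint", "score"])


def test_ranking_by_target_count_then_pvalue_then_name():
    node = PathNode(0, 1, tuple("abcde"), 0.0)
    universe = list("abcdefghij")
    edges = _edges(
        [("A", g, 1, 1.0) for g in "abcd"]
        + [("B", g, 1, 1.0) for g in "ab"]
        + [("C", g, 1, 1.0) for g in "ab"]
    )
    ranking = rank_tfs_at_node(node, edges, universe)
    assert list(ranking["tf"]) == ["A", "B", "C"]  # B vs C: lexicographic tie
    assert list(ranking["rank"]) == [1, 2, 3]
    assert ranking["n_targets_in_node"].tolist() == [4, 2, 2]


def test_ranking_enrichment_p_matches_exhaustive_enumeration():
    """Upper-tail p for a 5-gene node in a 20-gene universe, 4 draws."""
    universe = [f"g{i}" for i in range(20)]
    node = PathNode(0, 0, tuple(universe[:5]), 0.0)
    for k in range(5):
        targets = universe[:k] + universe[5 : 5 + (4 - k)]  # k inside the node
        edges = _edges([("T", g, 0, 1.0) for g in targets])
        p = rank_tfs_at_node(node, edges, universe)["enrichment_p"].iloc[0]
        total = math.comb(20, 4)
        expected = sum(
            math.comb(5, j) * math.comb(15, 4 - j) for j in range(k, 5)
        ) / total
        assert p == pytest.approx(expected, rel=1e-12)


def test_ranking_invariant_to_edge_row_order():
    rng = np.random.default_rng(2)
    universe = [f"g{i}" for i in range(30)]
    rows = [
        (f"T{i}", g, 2, 1.0)
        for i in range(5)
        for g in rng.choice(universe, size=rng.integers(1, 15), replace=False)
    ]
    node = PathNode(0, 2, tuple(universe[:12]), 0.0)
    a = rank_tfs_at_node(node, _edges(rows), universe)
    b = rank_tfs_at_node(node, _edges(rows[::-1]), universe)
    pd.testing.assert_frame_equal(a, b)


def test_empty_universe_is_an_error():
    node = PathNode(0, 0, ("a",), 0.0)
    with pytest.raises(ValueError, match="universe"):
        rank_tfs_at_node(node, _edges([]), [])


def test_top_k_union_rules():
    r1 = pd.DataFrame(
        {"tf": ["A", "B", "C"], "n_targets_in_node": [5, 3, 0],
         "enrichment_p": [0.01, 0.2, 1.0], "rank": [1, 2, 3]}
    )
    r2 = pd.DataFrame(
        {"tf": ["D", "E"], "n_targets_in_node": [4, 2],
         "enrichment_p": [0.05, 0.3], "rank": [1, 2]}
    )
    assert top_k_union([r1], k=20) == {"A", "B"}  # zero-target TF excluded
    assert top_k_union([r1, r2], k=20) == {"A", "B", "D", "E"}
    assert top_k_union([r1, r2], k=1) == {"A", "D"}


def test_split_tree_is_deterministic_across_row_orders():
    ratios, _ = _two_branch_ratios(seed=9)
    shuffled = ratios.sample(frac=1.0, random_state=4)
    a = SplitPathModel(random_state=0).fit(ratios)
    b = SplitPathModel(random_state=0).fit(shuffled)
    assert [sorted(n.genes) for n in a.tree_.nodes] == [
        sorted(n.genes) for n in b.tree_.nodes
    ]
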