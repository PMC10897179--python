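"""Time-series expression path tree with bifurcation (split) detection.

Genes start in a single path at the first time point.  Between consecutive
time points each path's genes either stay together or bifurcate into two
branches.  A bifurcation is accepted when a 2-component Gaussian mixture on
the per-gene step changes (delta of log2 ratio from t to t+1) beats the
1-component model by a BIC margin and both branches are large enough.  At
each split branch, TFs are ranked by how many of their predicted targets
(from the time-point-specific edge table) fall inside the branch, with an
upper-tail hypergeometric enrichment p-value as tie-breaker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

__all__ = [
    "PathNode",
    "PathTree",
    "SplitPathModel",
    "log_ratio_transform",
    "build_path_tree",
    "rank_tfs_at_node",
    "top_k_union",
]


def log_ratio_transform(
    tpm: pd.DataFrame, pseudo: float = 1.0
) -> pd.DataFrame:
    """log2((tpm + pseudo) / (tpm at t0 + pseudo)) per gene and time point.

    The first column is the reference time point and maps to all zeros.
    """
    if pseudo <= 0:
        raise ValueError("pseudo must be > 0")
    values = tpm.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("negative TPM values are not allowed")
    shifted = values + pseudo
    ratios = np.log2(shifted / shifted[:, [0]])
    return pd.DataFrame(ratios, index=tpm.index, columns=tpm.columns)


@dataclass
class PathNode:
    node_id: int
    timepoint: int
    genes: tuple[str, ...]
    mean_log2fc: float
    parent: int | None = None
    is_split_child: bool = False

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass
class PathTree:
    """Tree of expression paths; depth d holds the nodes at time point d."""

    nodes: list[PathNode] = field(default_factory=list)

    def node(self, node_id: int) -> PathNode:
        return self.nodes[node_id]

    def nodes_at(self, timepoint: int) -> list[PathNode]:
        return [n for n in self.nodes if n.timepoint == timepoint]

    def children(self, node_id: int) -> list[PathNode]:
        return [n for n in self.nodes if n.parent == node_id]

    @property
    def root(self) -> PathNode:
        return self.nodes[0]

    @property
    def split_branches(self) -> list[PathNode]:
        """Branch nodes created by a bifurcation (the split's children)."""
        return [n for n in self.nodes if n.is_split_child]

    @property
    def split_timepoints(self) -> list[int]:
        """Time points at which branches first separate, one per split."""
        return sorted(
            n.timepoint + 1
            for n in self.nodes
            if len(self.children(n.node_id)) > 1
        )

    @property
    def n_splits(self) -> int:
        return sum(
            1 for n in self.nodes if len(self.children(n.node_id)) > 1
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "node_id": n.node_id,
                    "timepoint": n.timepoint,
                    "parent": n.parent,
                    "n_genes": len(n.genes),
                    "mean_log2fc": n.mean_log2fc,
                    "is_split_child": n.is_split_child,
                }
                for n in self.nodes
            ]
        )


class SplitPathModel(BaseEstimator):
    """BIC-gated Gaussian-mixture bifurcation model over a time course.

    Parameters
    ----------
    bic_margin : float
        A node splits only when BIC(2-component) + bic_margin <
        BIC(1-component) for its step changes; larger values demand stronger
        evidence and can only reduce the number of splits.
    min_node_size : int
        Both branches of an accepted split must keep at least this many genes.
    max_children : int
        Only binary splits are supported.
    random_state : int
        Seeds the mixture initialisation; fits are deterministic given it.

    Attributes
    ----------
    tree_ : PathTree
        The fitted path tree (root covers every analysed gene at t0).
    n_splits_ : int
        Number of bifurcation events in the tree.
    labels_ : ndarray
        Leaf-path index per gene, aligned with ``gene_ids_``.
    """

    def __init__(
        self,
        bic_margin: float = 10.0,
        min_node_size: int = 10,
        max_children: int = 2,
        random_state: int = 0,
    ) -> None:
        self.bic_margin = bic_margin
        self.min_node_size = min_node_size
        self.max_children = max_children
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "SplitPathModel":
        """Fit the path tree on a genes x time points log2-ratio matrix."""
        if self.max_children != 2:
            raise ValueError("only binary splits are supported")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if isinstance(X, pd.DataFrame):
            ratios = X.sort_index()
            gene_ids = np.asarray(ratios.index, dtype=object)
            values = ratios.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            gene_ids = np.arange(values.shape[0], dtype=object)
        if values.ndim != 2 or values.shape[1] < 1:
            raise ValueError("X must be a genes x timepoints matrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("log ratios must be finite")
        row_of = {g: i for i, g in enumerate(gene_ids)}
        n_timepoints = values.shape[1]

        tree = PathTree()
        root = PathNode(
            node_id=0,
            timepoint=0,
            genes=tuple(gene_ids),
            mean_log2fc=float(values[:, 0].mean()) if len(gene_ids) else 0.0,
            parent=None,
        )
        tree.nodes.append(root)
        frontier = [root]
        for t in range(n_timepoints - 1):
            next_frontier: list[PathNode] = []
            for node in frontier:
                rows = np.array([row_of[g] for g in node.genes])
                deltas = values[rows, t + 1] - values[rows, t]
                assignment = self._try_split(deltas)
                if assignment is None:
                    groups = [np.ones(len(rows), dtype=bool)]
                    split = False
                else:
                    groups = [assignment == 0, assignment == 1]
                    split = True
                for mask in groups:
                    genes = tuple(np.asarray(node.genes, object)[mask])
                    child = PathNode(
                        node_id=len(tree.nodes),
                        timepoint=t + 1,
                        genes=genes,
                        mean_log2fc=float(values[rows[mask], t + 1].mean()),
                        parent=node.node_id,
                        is_split_child=split,
                    )
                    tree.nodes.append(child)
                    next_frontier.append(child)
            frontier = next_frontier

        self.gene_ids_ = gene_ids
        self.tree_ = tree
        self.n_splits_ = tree.n_splits
        leaves = frontier if n_timepoints > 1 else [root]
        labels = np.empty(len(gene_ids), dtype=int)
        for leaf_idx, leaf in enumerate(leaves):
            for g in leaf.genes:
                labels[row_of[g]] = leaf_idx
        self.labels_ = labels
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def _try_split(self, deltas: np.ndarray) -> np.ndarray | None:
        """Return branch labels (0 = larger mean step) or None for no split."""
        if len(deltas) < 2 * self.min_node_size:
            return None
        if np.ptp(deltas) == 0:  # identical steps: nothing to separate
            return None
        data = deltas.reshape(-1, 1)
        gm1 = GaussianMixture(
            n_components=1, random_state=self.random_state
        ).fit(data)
        gm2 = GaussianMixture(
            n_components=2, n_init=5, random_state=self.random_state
        ).fit(data)
        if gm2.bic(data) + self.bic_margin >= gm1.bic(data):
            return None
        labels = gm2.predict(data)
        sizes = np.bincount(labels, minlength=2)
        if sizes.min() < self.min_node_size:
            return None
        # deterministic branch order: branch 0 moves up more
        if gm2.means_.ravel()[0] < gm2.means_.ravel()[1]:
            labels = 1 - labels
        return labels


def build_path_tree(
    log_ratios: pd.DataFrame,
    bic_margin: float = 10.0,
    min_node_size: int = 10,
    max_children: int = 2,
    seed: int = 0,
) -> PathTree:
    """Functional wrapper over :class:`SplitPathModel`."""
    model = SplitPathModel(
        bic_margin=bic_margin,
        min_node_size=min_node_size,
        max_children=max_children,
        random_state=seed,
    )
    return model.fit(log_ratios).tree_


def rank_tfs_at_node(
    node: PathNode,
    edges: pd.DataFrame,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Rank TFs at a path node by target count within the node's gene set.

    For each TF with edges at the node's time point, count its predicted
    targets inside the node; the enrichment p-value is the upper tail of a
    hypergeometric draw of the TF's target set from the gene universe.
    Sorted by target count (desc), then p-value (asc), then tf id; ranks are
    1-based.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("gene universe must be non-empty")
    node_genes = node.gene_set & universe
    N, K = len(universe), len(node_genes)
    sub = edges[edges["timepoint"] == node.timepoint]
    rows = []
    for tf, grp in sub.groupby("tf"):
        targets = set(grp["gene"]) & universe
        n = len(targets)
        k = len(targets & node_genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((tf, k, p))
    ranking = pd.DataFrame(
        rows, columns=["tf", "n_targets_in_node", "enrichment_p"]
    )
    ranking = ranking.sort_values(
        ["n_targets_in_node", "enrichment_p", "tf"],
        ascending=[False, True, True],
    ).reset_index(drop=True)
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    ranking.insert(0, "node_id", node.node_id)
    return ranking


def top_k_union(
    rankings: Mapping[int, pd.DataFrame] | Sequence[pd.DataFrame],
    k: int = 20,
) -> set[str]:
    """Union of each split branch's k best-ranked TFs.

    TFs with zero targets inside the node are never included.
    """
    if isinstance(rankings, Mapping):
        tables = list(rankings.values())
    else:
        tables = list(rankings)
    out: set[str] = set()
    for table in tables:
        useful = table[table["n_targets_in_node"] > 0].sort_values("rank")
        out |= set(useful["tf"].head(k))
    return out
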