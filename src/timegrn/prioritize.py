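"""Candidate key-TF nomination: split-node top-k TFs that are SE-associated.

The candidate set is the plain intersection of (a) the union over split
branches of each branch's top-k ranked TFs and (b) the TFs associated with a
super-enhancer at any analysed time point.  The evidence table carries the
ranks and SE time points so downstream triage stays manual.
"""

from __future__ import annotations

from typing import Mapping, NamedTuple

import pandas as pd

__all__ = ["VennCounts", "venn_counts", "intersect_candidates"]


class VennCounts(NamedTuple):
    only_topk: int
    only_se: int
    both: int


def venn_counts(topk_tfs: set, se_tfs: set) -> VennCounts:
    """Disjoint two-set Venn counts; the three numbers sum to |union|."""
    topk_tfs, se_tfs = set(topk_tfs), set(se_tfs)
    both = topk_tfs & se_tfs
    return VennCounts(
        only_topk=len(topk_tfs - se_tfs),
        only_se=len(se_tfs - topk_tfs),
        both=len(both),
    )


def intersect_candidates(
    topk_tfs: set,
    se_tfs: set,
    rankings: Mapping[int, pd.DataFrame] | None = None,
    associations: pd.DataFrame | None = None,
    k: int = 20,
) -> pd.DataFrame:
    """Evidence table for the TFs in both the top-k union and the SE set.

    Columns: tf, best_rank, nodes_where_topk (list of (node_id, rank)),
    se_timepoints, max_tpm.  Sorted by best rank then tf id.  An empty
    intersection yields an empty table.
    """
    candidates = sorted(set(topk_tfs) & set(se_tfs))
    rows = []
    for tf in candidates:
        node_ranks: list[tuple[int, int]] = []
        if rankings:
            for node_id, table in rankings.items():
                hit = table[
                    (table["tf"] == tf) & (table["n_targets_in_node"] > 0)
                ]
                if len(hit) and int(hit["rank"].iloc[0]) <= k:
                    node_ranks.append((node_id, int(hit["rank"].iloc[0])))
        se_timepoints: list[int] = []
        max_tpm = float("nan")
        if associations is not None and len(associations):
            mine = associations[associations["tf"] == tf]
            if len(mine):
                se_timepoints = sorted(set(mine["timepoint"]))
                max_tpm = float(mine["tpm"].max())
        best = min((r for _, r in node_ranks), default=None)
        rows.append((tf, best, node_ranks, se_timepoints, max_tpm))
    table = pd.DataFrame(
        rows,
        columns=["tf", "best_rank", "nodes_where_topk", "se_timepoints", "max_tpm"],
    )
    if len(table):
        table = table.sort_values(
            ["best_rank", "tf"], na_position="last"
        ).reset_index(drop=True)
    return table
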