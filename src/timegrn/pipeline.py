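"""End-to-end candidate-TF discovery over one multi-omics data bundle."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .enhancers import associate_se_tfs, classify_se, se_tf_id_union, stitch_regions
from .io import timepoint_means
from .paths import (
    SplitPathModel,
    log_ratio_transform,
    rank_tfs_at_node,
    top_k_union,
)
from .prioritize import VennCounts, intersect_candidates, venn_counts
from .scoring import ScoringParams, build_edge_table
from .sim import SimData

__all__ = ["DiscoveryResult", "run_discovery", "discover_from_sim"]


@dataclass
class DiscoveryResult:
    edges: pd.DataFrame
    model: SplitPathModel
    rankings: dict[int, pd.DataFrame]
    topk_tfs: set[str]
    ses_by_timepoint: dict[int, pd.DataFrame]
    associations: pd.DataFrame
    se_tfs: set[str]
    candidates: pd.DataFrame
    venn: VennCounts

    @property
    def candidate_tfs(self) -> set[str]:
        return set(self.candidates["tf"]) if len(self.candidates) else set()


def run_discovery(
    annotation: pd.DataFrame,
    pfms,
    tpm: pd.DataFrame,
    accessibility,
    h3k27ac,
    scoring_params: ScoringParams | None = None,
    k: int = 20,
    gap: int = 12500,
    min_span: int = 10000,
    bic_margin: float = 10.0,
    min_node_size: int = 10,
    pseudo: float = 1.0,
    seed: int = 0,
) -> DiscoveryResult:
    """Run the full prioritization pipeline.

    Steps: TF->gene edge scoring per time point (expression-filtered), path
    tree with bifurcation detection on analysed genes (TPM >= threshold at
    >= 1 time point), per-branch TF ranking and top-k union, SE calling and
    SE->TF association per time point, and the final intersection.
    """
    params = scoring_params or ScoringParams()
    tpm_t = timepoint_means(tpm)
    analysed = tpm_t.index[(tpm_t >= params.tpm_min).any(axis=1)]

    edges = build_edge_table(annotation, accessibility, pfms, tpm_t, params)

    ratios = log_ratio_transform(tpm_t.loc[analysed], pseudo)
    model = SplitPathModel(
        bic_margin=bic_margin, min_node_size=min_node_size, random_state=seed
    ).fit(ratios)
    rankings = {
        node.node_id: rank_tfs_at_node(node, edges, analysed)
        for node in model.tree_.split_branches
    }
    topk = top_k_union(rankings, k=k)

    ses_by_timepoint: dict[int, pd.DataFrame] = {}
    association_tables = []
    for t in sorted(h3k27ac):
        ses = classify_se(stitch_regions(h3k27ac[t], gap=gap), min_span=min_span)
        ses_by_timepoint[t] = ses
        association_tables.append(
            associate_se_tfs(ses, annotation, tpm_t, t, tpm_min=params.tpm_min)
        )
    associations = (
        pd.concat(association_tables, ignore_index=True)
        if association_tables
        else pd.DataFrame(
            columns=["tf", "timepoint", "se_chrom", "se_start", "se_end", "tpm"]
        )
    )
    se_tfs = se_tf_id_union(association_tables)

    candidates = intersect_candidates(topk, se_tfs, rankings, associations, k=k)
    return DiscoveryResult(
        edges=edges,
        model=model,
        rankings=rankings,
        topk_tfs=topk,
        ses_by_timepoint=ses_by_timepoint,
        associations=associations,
        se_tfs=se_tfs,
        candidates=candidates,
        venn=venn_counts(topk, se_tfs),
    )


def discover_from_sim(sim: SimData, seed: int | None = None, **kwargs) -> DiscoveryResult:
    """Convenience wrapper running discovery on a simulated bundle."""
    return run_discovery(
        sim.annotation,
        sim.pfms,
        sim.tpm,
        sim.accessibility,
        sim.h3k27ac,
        seed=sim.config.seed if seed is None else seed,
        **kwargs,
    )
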