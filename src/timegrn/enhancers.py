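"""Super-enhancer calling from H3K27ac regions and SE->TF association.

Acetylation regions on the same chromosome are stitched when separated by at
most a fixed gap (12.5 kb by convention); a stitched region is a
super-enhancer when its span strictly exceeds 10 kb.  An SE is associated
with a TF at a time point when the TF's gene body overlaps the SE by at
least one base and the TF is expressed (TPM at that time point above
threshold).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "stitch_regions",
    "classify_se",
    "associate_se_tfs",
    "se_tf_id_union",
]

_REGION_COLS = ["chrom", "start", "end"]


def _as_region_frame(regions) -> pd.DataFrame:
    if isinstance(regions, pd.DataFrame):
        df = regions.copy()
    else:
        df = pd.DataFrame(list(regions), columns=_REGION_COLS)
    for col in _REGION_COLS:
        if col not in df.columns:
            raise ValueError(f"regions lack required column {col!r}")
    if "name" not in df.columns:
        df["name"] = [f"region_{i}" for i in range(len(df))]
    return df.reset_index(drop=True)


def stitch_regions(regions, gap: int = 12500) -> pd.DataFrame:
    """Merge regions whose inter-region distance is at most ``gap``.

    Input intervals are 0-based half-open; two intervals are stitched when
    start2 - end1 <= gap (chromosome-wise, after sorting).  Returns a sorted
    DataFrame with columns chrom, start, end, n_constituents,
    constituent_ids.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    df = _as_region_frame(regions)
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"malformed interval (start >= end) at line {bad[0]}")
    out = []
    for chrom, grp in df.sort_values(["chrom", "start", "end"]).groupby(
        "chrom", sort=True
    ):
        cur_start = cur_end = None
        members: list[str] = []
        for _, row in grp.iterrows():
            if cur_start is None:
                cur_start, cur_end = row["start"], row["end"]
                members = [row["name"]]
            elif row["start"] - cur_end <= gap:
                cur_end = max(cur_end, row["end"])
                members.append(row["name"])
            else:
                out.append((chrom, cur_start, cur_end, len(members), members))
                cur_start, cur_end = row["start"], row["end"]
                members = [row["name"]]
        if cur_start is not None:
            out.append((chrom, cur_start, cur_end, len(members), members))
    return pd.DataFrame(
        out,
        columns=["chrom", "start", "end", "n_constituents", "constituent_ids"],
    )


def classify_se(stitched: pd.DataFrame, min_span: int = 10000) -> pd.DataFrame:
    """Super-enhancers: stitched regions whose span strictly exceeds min_span.

    A region of exactly ``min_span`` bp is *not* an SE.
    """
    if stitched.empty:
        return stitched.copy()
    spans = stitched["end"] - stitched["start"]
    return stitched[spans > min_span].reset_index(drop=True)


def associate_se_tfs(
    ses: pd.DataFrame,
    annotation: pd.DataFrame,
    tpm_by_timepoint: pd.DataFrame,
    timepoint: int,
    tpm_min: float = 1.0,
) -> pd.DataFrame:
    """Associate SEs with TF genes expressed at one time point.

    One row per (TF, SE) pair where the TF gene body overlaps the SE by >= 1
    bp (half-open coordinates: abutting intervals do not overlap) and the
    TF's TPM at the time point is >= tpm_min.
    """
    if timepoint not in tpm_by_timepoint.columns:
        raise KeyError(f"time point {timepoint} absent from expression table")
    tfs = annotation[annotation["is_tf"]]
    rows = []
    for tf_id, gene in tfs.iterrows():
        tpm = tpm_by_timepoint.at[tf_id, timepoint] if tf_id in tpm_by_timepoint.index else 0.0
        if tpm < tpm_min:
            continue
        if ses.empty:
            continue
        on_chrom = ses[ses["chrom"] == gene["chrom"]]
        for _, se in on_chrom.iterrows():
            overlap = min(gene["end"], se["end"]) - max(gene["start"], se["start"])
            if overlap >= 1:
                rows.append(
                    (
                        tf_id,
                        timepoint,
                        se["chrom"],
                        se["start"],
                        se["end"],
                        float(tpm),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["tf", "timepoint", "se_chrom", "se_start", "se_end", "tpm"],
    )


def se_tf_id_union(associations: Iterable[pd.DataFrame]) -> set[str]:
    """TF ids associated with an SE at any analysed time point."""
    out: set[str] = set()
    for table in associations:
        if len(table):
            out |= set(table["tf"])
    return out
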