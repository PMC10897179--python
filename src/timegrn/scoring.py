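"""Time-point-specific TF->gene regulatory scoring from accessible chromatin.

A TF's regulatory influence on a gene at one time point is summarised as

    score(tf, gene, t) = sum over accessible regions r near the gene's TSS of
                         affinity(tf, r) * signal(r) * exp(-d(r, TSS) / d0)

where ``affinity`` is a TRAP-like soft-binding affinity (the logistic
transform of PFM log-odds scores summed over every window on both strands),
``signal`` is the region's accessibility signal (narrowPeak signalValue) and
``d`` is the distance from the region midpoint to the gene's TSS.  Regions
beyond a hard distance window contribute nothing.

Edges whose TF is unexpressed — TPM below threshold at *every* analysed time
point — are removed from the final edge table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

_BASES = "ACGT"
_CODES = {c: i for i, c in enumerate("ACGTN")}

__all__ = [
    "Pfm",
    "ScoredRegion",
    "ScoringParams",
    "log_odds_scan",
    "region_affinity",
    "tf_gene_score",
    "build_edge_table",
]


@dataclass(frozen=True)
class Pfm:
    """Position frequency matrix with 4 rows (A, C, G, T).

    Columns are renormalised to sum to one after adding ``pseudocount``; the
    log-odds used for scanning are log(p / background).
    """

    name: str
    matrix: np.ndarray
    pseudocount: float = 0.01
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 1:
            raise ValueError(f"PFM must be 4 x L with L >= 1, got {m.shape}")
        if np.any(m < 0):
            raise ValueError("PFM entries must be non-negative")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 probabilities summing to 1")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        """Columns renormalised to sum to 1 after pseudocount addition."""
        p = self.matrix + self.pseudocount
        return p / p.sum(axis=0, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        """4 x L log(p / background) matrix."""
        return np.log(self.probabilities / self.background[:, None])

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.matrix, axis=0))

    def reverse_complement(self) -> "Pfm":
        return Pfm(
            name=self.name,
            matrix=self.matrix[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            background=self.background[::-1].copy(),
        )


@dataclass
class ScoredRegion:
    """A scored genomic interval with its DNA sequence (0-based half-open)."""

    chrom: str
    start: int
    end: int
    signal: float = 1.0
    sequence: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.sequence and len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"sequence length {len(self.sequence)} != interval span "
                f"{self.end - self.start} for region {self.name or self.chrom}"
            )
        if self.signal < 0:
            raise ValueError("region signal must be non-negative")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class ScoringParams:
    """Tunables of the TF->gene score.

    lam/theta: scale and offset of the logistic bind probability applied to
    each window's log-odds score.  d0: exponential decay length of the
    TSS-distance weight (bp).  window: hard cutoff on midpoint-to-TSS
    distance (bp).  tpm_min: a TF below this TPM at every time point is
    treated as unexpressed and its edges dropped.  min_score: edges at or
    below this score are dropped from the edge table — the logistic bind
    probability is strictly positive on every window, so without a floor
    every (TF, gene) pair with any nearby region would count as a target.
    """

    lam: float = 1.0
    theta: float = 0.0
    d0: float = 5000.0
    window: float = 50000.0
    tpm_min: float = 1.0
    min_score: float = 0.05

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.d0 <= 0:
            raise ValueError("d0 must be > 0")
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.tpm_min < 0:
            raise ValueError("tpm_min must be >= 0")
        if self.min_score < 0:
            raise ValueError("min_score must be >= 0")


def encode_sequence(seq: str) -> np.ndarray:
    """Map ACGTN (case-insensitive) to integer codes 0..4."""
    try:
        return np.fromiter(
            (_CODES[c] for c in seq.upper()), dtype=np.intp, count=len(seq)
        )
    except KeyError as exc:
        raise ValueError(f"non-ACGTN character in sequence: {exc}") from None


def log_odds_scan(
    pfm: Pfm, region: ScoredRegion | str
) -> tuple[np.ndarray, np.ndarray]:
    """Score every window of the region on both strands.

    Returns (forward, reverse) arrays of length ``len(seq) - L + 1`` (empty
    when the sequence is shorter than the motif).  Each score is the sum of
    per-position log-odds; an N contributes 0 (background).
    """
    seq = region.sequence if isinstance(region, ScoredRegion) else region
    codes = encode_sequence(seq)
    L = pfm.length
    if codes.size < L:
        empty = np.empty(0)
        return empty, empty
    fwd = _scan(pfm.log_odds, codes)
    rev = _scan(pfm.reverse_complement().log_odds, codes)
    return fwd, rev


def _scan(log_odds: np.ndarray, codes: np.ndarray) -> np.ndarray:
    L = log_odds.shape[1]
    # row 4 scores N as background (zero contribution)
    lut = np.vstack([log_odds, np.zeros((1, L))])
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return lut[windows, np.arange(L)].sum(axis=1)


def region_affinity(
    pfm: Pfm, region: ScoredRegion | str, params: ScoringParams | None = None
) -> float:
    """TRAP-like soft-binding affinity of a TF for one region.

    Sum over all windows on both strands of the logistic bind probability
    1 / (1 + exp(-(s - theta) / lam)); 0.0 when no window fits.
    """
    params = params or ScoringParams()
    fwd, rev = log_odds_scan(pfm, region)
    scores = np.concatenate([fwd, rev])
    if scores.size == 0:
        return 0.0
    return float(expit((scores - params.theta) / params.lam).sum())


def tf_gene_score(
    affinities: Sequence[float],
    regions: Sequence[ScoredRegion],
    tss: int,
    params: ScoringParams | None = None,
) -> float:
    """Aggregate per-region affinities into one TF->gene score.

    Each region within ``params.window`` of the TSS contributes
    affinity * signal * exp(-d / d0), d being the midpoint-to-TSS distance.
    """
    params = params or ScoringParams()
    if len(affinities) != len(regions):
        raise ValueError("affinities and regions must align")
    total = 0.0
    for aff, region in zip(affinities, regions):
        d = abs(region.midpoint - tss)
        if d <= params.window:
            total += aff * region.signal * np.exp(-d / params.d0)
    return float(total)


def gene_tss(annotation: pd.DataFrame) -> pd.Series:
    """5'-most TSS per gene: start on '+' strand, end-1 on '-' strand."""
    return pd.Series(
        np.where(
            annotation["strand"] == "-",
            annotation["end"] - 1,
            annotation["start"],
        ),
        index=annotation.index,
    )


def expressed_tfs(
    tpm_by_timepoint: pd.DataFrame, tf_ids: Iterable[str], tpm_min: float = 1.0
) -> set[str]:
    """TFs with TPM >= tpm_min at one or more time points.

    A TF below threshold at *every* time point is unexpressed and excluded.
    """
    tf_ids = list(tf_ids)
    missing = [t for t in tf_ids if t not in tpm_by_timepoint.index]
    if missing:
        raise KeyError(
            f"TF(s) with motif absent from expression table: {missing}"
        )
    sub = tpm_by_timepoint.loc[tf_ids]
    keep = (sub >= tpm_min).any(axis=1)
    return set(sub.index[keep])


def build_edge_table(
    annotation: pd.DataFrame,
    regions_by_timepoint: Mapping[int, Sequence[ScoredRegion]],
    pfms: Mapping[str, Pfm],
    tpm_by_timepoint: pd.DataFrame,
    params: ScoringParams | None = None,
) -> pd.DataFrame:
    """Score all (TF, gene) pairs at every time point and filter by expression.

    Parameters
    ----------
    annotation
        Gene table indexed by gene_id with columns chrom, start, end, strand.
    regions_by_timepoint
        Accessible regions (with sequences and signals) per time point.
    pfms
        One motif per TF id.
    tpm_by_timepoint
        Genes x time points TPM (replicates already averaged).

    Returns
    -------
    DataFrame with columns tf, gene, timepoint, score; one row per positive
    score, sorted by (timepoint, tf, score descending).  Rows of TFs that are
    unexpressed (TPM < tpm_min at every time point) are removed.
    """
    params = params or ScoringParams()
    keep_tfs = sorted(
        expressed_tfs(tpm_by_timepoint, pfms.keys(), params.tpm_min)
    )
    tss = gene_tss(annotation)
    rows: list[tuple[str, str, int, float]] = []
    for timepoint in sorted(regions_by_timepoint):
        regions = list(regions_by_timepoint[timepoint])
        # affinity is a property of (TF, region): compute once per pair
        affinity = {
            tf: np.array(
                [region_affinity(pfms[tf], r, params) for r in regions]
            )
            for tf in keep_tfs
        }
        by_chrom: dict[str, list[int]] = {}
        for i, r in enumerate(regions):
            by_chrom.setdefault(r.chrom, []).append(i)
        for gene, ann in annotation.iterrows():
            idx = by_chrom.get(ann["chrom"], [])
            if not idx:
                continue
            local = [regions[i] for i in idx]
            for tf in keep_tfs:
                score = tf_gene_score(
                    affinity[tf][idx], local, int(tss.loc[gene]), params
                )
                if score > params.min_score:
                    rows.append((tf, gene, timepoint, score))
    edges = pd.DataFrame(rows, columns=["tf", "gene", "timepoint", "score"])
    edges = edges.sort_values(
        ["timepoint", "tf", "score"], ascending=[True, True, False]
    ).reset_index(drop=True)
    return edges
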