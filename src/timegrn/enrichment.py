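"""Gene-set overlap statistics: exact hypergeometric test and representation
factor.

Used to ask whether a query gene list (e.g. genes upregulated after a TF
knockdown) overlaps a target list (e.g. predicted microRNA targets expressed
in the experiment) more than expected by chance within a gene universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "OverlapResult",
    "hypergeom_overlap",
    "filter_expressed_targets",
    "deg_flags",
]


@dataclass(frozen=True)
class OverlapResult:
    """Exact upper-tail overlap test between two gene sets in a universe.

    N: universe size; K: target-set size; n: query-set size; k: overlap.
    p_upper = P(X >= k) for X ~ Hypergeometric(N, K, n).  The representation
    factor rf = k*N / (n*K) is the observed/expected overlap ratio; rf > 1
    means more overlap than chance.
    """

    N: int
    K: int
    n: int
    k: int
    p_upper: float
    rf: float

    def to_dict(self) -> dict:
        return {
            "universe": self.N,
            "targets": self.K,
            "query": self.n,
            "overlap": self.k,
            "p_upper": self.p_upper,
            "representation_factor": self.rf,
        }


def hypergeom_overlap(
    query: Iterable[str],
    targets: Iterable[str],
    universe: Iterable[str],
) -> OverlapResult:
    """Exact hypergeometric over-representation test of query vs targets.

    Ids outside the universe are dropped with a warning.  The p-value is the
    exact upper tail P(X >= k); no normal approximation.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("gene universe must be non-empty")
    query, targets = set(query), set(targets)
    for label, ids in (("query", query), ("targets", targets)):
        stray = ids - universe
        if stray:
            warnings.warn(
                f"{len(stray)} {label} id(s) outside the universe dropped "
                f"(e.g. {sorted(stray)[:3]})",
                stacklevel=2,
            )
    query &= universe
    targets &= universe
    N, K, n = len(universe), len(targets), len(query)
    k = len(query & targets)
    p_upper = float(hypergeom.sf(k - 1, N, K, n))
    rf = k * N / (n * K) if n * K > 0 else float("nan")
    return OverlapResult(N=N, K=K, n=n, k=k, p_upper=p_upper, rf=rf)


def filter_expressed_targets(
    target_ids: Iterable[str],
    tpm: pd.DataFrame,
    tpm_min: float = 1.0,
) -> set[str]:
    """Keep targets expressed (TPM >= tpm_min in >= 1 sample) in the data.

    Ids absent from the expression table are dropped with a warning.
    """
    target_ids = list(target_ids)
    missing = [t for t in target_ids if t not in tpm.index]
    if missing:
        warnings.warn(
            f"{len(missing)} target id(s) absent from expression table "
            f"dropped (e.g. {missing[:3]})",
            stacklevel=2,
        )
    present = [t for t in target_ids if t in tpm.index]
    if not present:
        return set()
    sub = tpm.loc[present]
    return set(sub.index[(sub >= tpm_min).any(axis=1)])


def deg_flags(
    table: pd.DataFrame,
    fdr_max: float = 0.05,
    lfc_min: float = 1.0,
    fdr_col: str = "fdr",
    lfc_col: str = "log2fc",
) -> pd.DataFrame:
    """Flag differentially expressed genes: FDR < fdr_max and |log2FC| > lfc_min.

    Both cutoffs are strict.  Adds boolean ``significant`` and ``up``/``down``
    direction columns.
    """
    out = table.copy()
    sig = (out[fdr_col] < fdr_max) & (out[lfc_col].abs() > lfc_min)
    out["significant"] = sig
    out["up"] = sig & (out[lfc_col] > 0)
    out["down"] = sig & (out[lfc_col] < 0)
    return out
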