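"""Readers and writers for the formats the pipeline consumes and emits.

All genomic coordinates are handled 0-based half-open in memory (BED
convention); GTF is converted to/from its native 1-based inclusive
convention at the file boundary.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.motifs import jaspar as jaspar_format
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scoring import Pfm, ScoredRegion

__all__ = [
    "write_gtf",
    "read_gtf",
    "write_jaspar",
    "read_jaspar",
    "write_fasta",
    "read_fasta",
    "write_narrowpeak",
    "read_narrowpeak",
    "write_bed6",
    "read_bed6",
    "write_matrix",
    "read_matrix",
    "timepoint_means",
]

_ANN_COLS = ["chrom", "start", "end", "strand", "is_tf"]


# ---------------------------------------------------------------- annotation

def write_gtf(annotation: pd.DataFrame, path) -> None:
    """Write the gene table as GTF; TFs get gene_biotype "tf_gene"."""
    lines = []
    for gene_id, row in annotation.iterrows():
        biotype = "tf_gene" if row["is_tf"] else "protein_coding"
        attrs = f'gene_id "{gene_id}"; gene_biotype "{biotype}";'
        lines.append(
            "\t".join(
                [
                    str(row["chrom"]),
                    "timegrn",
                    "gene",
                    str(int(row["start"]) + 1),
                    str(int(row["end"])),
                    ".",
                    row["strand"],
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_gtf(path) -> pd.DataFrame:
    """Read gene records from GTF into the 0-based annotation table."""
    rows = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if f[2] != "gene":
            continue
        attrs = dict(re.findall(r'(\w+) "([^"]*)"', f[8]))
        rows[attrs["gene_id"]] = {
            "chrom": f[0],
            "start": int(f[3]) - 1,
            "end": int(f[4]),
            "strand": f[6],
            "is_tf": attrs.get("gene_biotype") == "tf_gene",
        }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=_ANN_COLS)
    df.index.name = "gene_id"
    return df


# -------------------------------------------------------------------- motifs

def write_jaspar(pfms: Mapping[str, Pfm], path) -> None:
    records = []
    for name in sorted(pfms):
        pfm = pfms[name]
        counts = {
            base: list(np.round(pfm.matrix[i] * 100.0, 4))
            for i, base in enumerate("ACGT")
        }
        m = motifs.Motif(alphabet="ACGT", counts=counts)
        m.matrix_id = name
        m.name = name
        records.append(m)
    Path(path).write_text(jaspar_format.write(records, "jaspar"))


def read_jaspar(path, pseudocount: float = 0.01) -> dict[str, Pfm]:
    out: dict[str, Pfm] = {}
    with open(path) as handle:
        for m in motifs.parse(handle, "jaspar"):
            mat = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
            mat = mat / mat.sum(axis=0, keepdims=True)
            name = m.name or m.matrix_id
            out[name] = Pfm(name=name, matrix=mat, pseudocount=pseudocount)
    return out


# ----------------------------------------------------------------- sequences

def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
    }


# ------------------------------------------------------------------- regions

def write_narrowpeak(regions: Sequence[ScoredRegion], path) -> None:
    lines = []
    for r in regions:
        lines.append(
            "\t".join(
                [
                    r.chrom,
                    str(r.start),
                    str(r.end),
                    r.name or ".",
                    "0",
                    ".",
                    f"{r.signal:g}",
                    "-1",
                    "-1",
                    str((r.end - r.start) // 2),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_narrowpeak(path, sequences: Mapping[str, str] | None = None) -> list[ScoredRegion]:
    """Read narrowPeak regions; sequences (by region name) are optional."""
    regions = []
    for line in Path(path).read_text().splitlines():
        if not line:
            continue
        f = line.split("\t")
        name = f[3]
        seq = (sequences or {}).get(name, "")
        regions.append(
            ScoredRegion(
                chrom=f[0],
                start=int(f[1]),
                end=int(f[2]),
                name=name,
                signal=float(f[6]) if len(f) > 6 else 1.0,
                sequence=seq,
            )
        )
    return regions


def write_bed6(regions: pd.DataFrame, path) -> None:
    df = regions.copy()
    if "name" not in df:
        df["name"] = [f"region_{i}" for i in range(len(df))]
    if "score" not in df:
        df["score"] = 0
    if "strand" not in df:
        df["strand"] = "."
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return df


# ------------------------------------------------------------------ matrices

def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


_SAMPLE_RE = re.compile(r"^t(\d+)_rep(\d+)$")


def timepoint_means(matrix: pd.DataFrame) -> pd.DataFrame:
    """Average replicate columns named ``t{i}_rep{j}`` into one per time point.

    A matrix whose columns are already integer time points passes through.
    """
    if all(isinstance(c, (int, np.integer)) for c in matrix.columns):
        return matrix
    groups: dict[int, list[str]] = {}
    for col in matrix.columns:
        m = _SAMPLE_RE.match(str(col))
        if not m:
            raise ValueError(f"unrecognised sample column {col!r}")
        groups.setdefault(int(m.group(1)), []).append(col)
    out = pd.DataFrame(
        {t: matrix[cols].mean(axis=1) for t, cols in sorted(groups.items())}
    )
    out.index = matrix.index
    return out


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
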