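"""Miniature multi-omics benchmark generator with planted ground truth.

Emulates the data a time-course TF-prioritization analysis consumes: a small
annotated genome with TF and non-TF genes, a bifurcating time-course
expression matrix driven by a planted TF->gene edge set, motif-bearing
accessible regions near target TSSs, and stitched acetylation domains over
chosen TF loci.  Every entity is recorded in a ground-truth object so the
downstream modules can be scored against what was planted.

Expression model: each gene has a baseline log2 abundance; all genes share a
flat common profile until the bifurcation time point, after which each
planted branch shifts by its regulator's effect size (log2 units).  Counts
are negative binomial around these means; the emitted TPM is the
length-normalised rate scaled against the expected time-zero total so that
planted log2 ratios are preserved rather than distorted by compositional
renormalisation.

Motifs are deliberately sharp (near-consensus columns): with a miniature
genome of ~10^2 regions there is no room for the soft motif/background
separation that genome-scale scans average out, and sharp planted motifs
keep the planted-edge signal identifiable at this scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .scoring import Pfm, ScoredRegion

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimData",
    "simulate_annotation",
    "plan_truth",
    "simulate_expression",
    "simulate_accessibility",
    "simulate_h3k27ac",
    "simulate_all",
]

_BASES = np.array(list("ACGT"))

# deterministic gene placement uses slot centers with bounded jitter so that
# neighbouring loci stay far enough apart for acetylation clusters not to
# bleed into each other when stitched with the conventional 12.5 kb gap
_PLACEMENT_JITTER = 2000
_GENE_LEN_RANGE = (1500, 3000)


@dataclass
class SimConfig:
    """Study conditions of the synthetic benchmark.

    Defaults define the reference scenario: 50 genes (10 TFs) on 2
    chromosomes, 4 time points x 3 replicates, two planted regulators
    driving +2 / -2 log2 branches from time point 1, both also carrying a
    planted super-enhancer.
    """

    n_chromosomes: int = 2
    chrom_length: int = 1_200_000
    n_genes: int = 50
    n_tfs: int = 10
    n_timepoints: int = 4
    n_replicates: int = 3
    planted_regulators: dict[str, float] = field(
        default_factory=lambda: {"TF001": 2.0, "TF002": -2.0}
    )
    planted_se_tfs: tuple[str, ...] = ("TF001", "TF002")
    bifurcation_timepoint: int = 1
    n_silent_tfs: int = 2
    noise_sd: float = 0.1
    dispersion: float = 0.1
    library_size: int = 2_000_000
    motif_length: int = 15
    region_length: int = 300
    n_background_regions: int = 50
    se_timepoints: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs > self.n_genes:
            raise ValueError("n_tfs must not exceed n_genes")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        tf_ids = set(self.tf_ids)
        stray = set(self.planted_regulators) - tf_ids
        if stray:
            raise ValueError(f"planted regulators are not TFs: {sorted(stray)}")
        stray = set(self.planted_se_tfs) - tf_ids
        if stray:
            raise ValueError(f"planted SE-TFs are not TFs: {sorted(stray)}")

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{i:03d}" for i in range(1, self.n_tfs + 1)]

    @property
    def gene_ids(self) -> list[str]:
        return self.tf_ids + [
            f"G{i:03d}" for i in range(self.n_tfs + 1, self.n_genes + 1)
        ]

    @property
    def silent_tf_ids(self) -> list[str]:
        """Unexpressed background TFs (never planted ones)."""
        planted = set(self.planted_regulators) | set(self.planted_se_tfs)
        eligible = [t for t in reversed(self.tf_ids) if t not in planted]
        return sorted(eligible[: self.n_silent_tfs])

    @property
    def h3k27ac_timepoints(self) -> tuple[int, ...]:
        if self.se_timepoints is not None:
            return tuple(self.se_timepoints)
        return (self.n_timepoints - 2, self.n_timepoints - 1)


@dataclass
class GroundTruth:
    """What was planted, for scoring the pipeline's output against."""

    edge_set: list[tuple[str, str, int]]
    branch_membership: dict[str, str]
    branch_effects: dict[str, float]
    se_tf_ids: list[str]
    expected_candidates: list[str]
    bifurcation_timepoint: int

    def to_dict(self) -> dict:
        return {
            "edge_set": [list(e) for e in self.edge_set],
            "branch_membership": self.branch_membership,
            "branch_effects": self.branch_effects,
            "se_tf_ids": self.se_tf_ids,
            "expected_candidates": self.expected_candidates,
            "bifurcation_timepoint": self.bifurcation_timepoint,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            edge_set=[tuple(e) for e in d["edge_set"]],
            branch_membership=dict(d["branch_membership"]),
            branch_effects=dict(d["branch_effects"]),
            se_tf_ids=list(d["se_tf_ids"]),
            expected_candidates=list(d["expected_candidates"]),
            bifurcation_timepoint=int(d["bifurcation_timepoint"]),
        )


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_annotation(
    config: SimConfig,
) -> tuple[pd.DataFrame, dict[str, Pfm]]:
    """Place non-overlapping gene bodies and draw one sharp PFM per TF.

    Genes are laid out in equal slots per chromosome with a small random
    jitter, guaranteeing pairwise non-overlap and wide inter-gene gaps.
    Raises when the chromosomes cannot host the requested gene count.
    """
    rng = _rng(config, 1)
    gene_ids = config.gene_ids
    rows = []
    chunks = np.array_split(np.asarray(gene_ids, dtype=object), config.n_chromosomes)
    for ci, chunk in enumerate(chunks):
        if len(chunk) == 0:
            continue
        chrom = f"chr{ci + 1}"
        slot = config.chrom_length // len(chunk)
        if slot < _GENE_LEN_RANGE[1] + 2 * _PLACEMENT_JITTER + 2:
            raise ValueError(
                f"infeasible packing: {len(chunk)} genes cannot be placed "
                f"without overlap on a {config.chrom_length} bp chromosome"
            )
        for gi, gene_id in enumerate(chunk):
            length = int(rng.integers(*_GENE_LEN_RANGE, endpoint=True))
            jitter = int(
                rng.integers(-_PLACEMENT_JITTER, _PLACEMENT_JITTER, endpoint=True)
            )
            center = gi * slot + slot // 2 + jitter
            start = center - length // 2
            end = start + length
            if start < gi * slot or end > (gi + 1) * slot:
                raise ValueError("infeasible packing: gene overflows its slot")
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "is_tf": gene_id in set(config.tf_ids),
                }
            )
    annotation = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "is_tf"]
    ).set_index("gene_id")

    pfms: dict[str, Pfm] = {}
    for tf in config.tf_ids:
        dominant = rng.integers(0, 4, size=config.motif_length)
        matrix = np.full((4, config.motif_length), 0.001)
        matrix[dominant, np.arange(config.motif_length)] = 0.997
        pfms[tf] = Pfm(name=tf, matrix=matrix, pseudocount=0.001)
    return annotation, pfms


def plan_truth(annotation: pd.DataFrame, config: SimConfig) -> GroundTruth:
    """Assign genes to planted branches and derive the planted edge set.

    Every expressed gene belongs to one branch per planted regulator
    (round-robin, regulators seeded into their own branch); the regulator
    gains one edge to each branch member at the bifurcation time point.
    """
    regulators = sorted(config.planted_regulators)
    silent = set(config.silent_tf_ids)
    membership: dict[str, str] = {}
    edges: list[tuple[str, str, int]] = []
    if regulators:
        for r in regulators:
            membership[r] = r
        others = [
            g
            for g in annotation.index
            if g not in membership and g not in silent
        ]
        for i, g in enumerate(sorted(others)):
            membership[g] = regulators[i % len(regulators)]
        t_b = config.bifurcation_timepoint
        for r in regulators:
            for g in sorted(k for k, v in membership.items() if v == r):
                if g != r:
                    edges.append((r, g, t_b))
    se_tf_ids = sorted(set(config.planted_se_tfs))
    return GroundTruth(
        edge_set=edges,
        branch_membership=membership,
        branch_effects={r: config.planted_regulators[r] for r in regulators},
        se_tf_ids=se_tf_ids,
        expected_candidates=sorted(set(regulators) & set(se_tf_ids)),
        bifurcation_timepoint=config.bifurcation_timepoint,
    )


def simulate_expression(
    annotation: pd.DataFrame,
    config: SimConfig,
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw counts and TPM around branch mean trajectories.

    Returns (counts, tpm) with sample columns ``t{i}_rep{j}``.  Planted
    regulators are guaranteed to be expressed (TPM >= 1) while they act.
    """
    if truth.branch_effects and not (
        0 <= truth.bifurcation_timepoint < config.n_timepoints
    ):
        raise ValueError(
            f"bifurcation time point {truth.bifurcation_timepoint} outside "
            f"the {config.n_timepoints} analysed time points"
        )
    rng = _rng(config, 2)
    genes = list(annotation.index)
    n = len(genes)
    cols = [
        f"t{t}_rep{r}"
        for t in range(config.n_timepoints)
        for r in range(1, config.n_replicates + 1)
    ]
    if n == 0:
        empty = pd.DataFrame(index=pd.Index([], name="gene_id"), columns=cols)
        return empty, empty.copy()

    lengths = (annotation["end"] - annotation["start"]).to_numpy(float)
    regulators = set(truth.branch_effects)
    silent = set(config.silent_tf_ids)
    baseline = rng.uniform(5.0, 8.0, size=n)
    for i, g in enumerate(genes):
        if g in regulators:
            baseline[i] = rng.uniform(6.5, 8.0)
        elif g in silent:
            baseline[i] = -12.0  # effectively unexpressed at every time point

    effect = np.zeros(n)
    for i, g in enumerate(genes):
        branch = truth.branch_membership.get(g)
        if branch is not None:
            effect[i] = truth.branch_effects[branch]
    t_b = truth.bifurcation_timepoint

    mean_log2 = np.empty((n, config.n_timepoints))
    for t in range(config.n_timepoints):
        mean_log2[:, t] = baseline + (effect if t >= t_b else 0.0)

    scale = config.library_size / float((2.0 ** baseline * lengths).sum())
    counts = np.empty((n, len(cols)), dtype=np.int64)
    col = 0
    for t in range(config.n_timepoints):
        for _ in range(config.n_replicates):
            log2_w = mean_log2[:, t] + rng.normal(0.0, config.noise_sd, size=n)
            mu = np.maximum(2.0 ** log2_w * lengths * scale, 1e-8)
            r = 1.0 / config.dispersion
            counts[:, col] = rng.negative_binomial(r, r / (r + mu))
            col += 1
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=cols)

    # fixed-reference scaling keeps planted log2 ratios compositional-free
    rate = counts / lengths[:, None]
    reference_total = scale * float((2.0 ** baseline).sum())
    tpm_df = pd.DataFrame(
        rate / reference_total * 1e6,
        index=counts_df.index,
        columns=cols,
    )
    return counts_df, tpm_df


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_accessibility(
    annotation: pd.DataFrame,
    truth: GroundTruth,
    config: SimConfig,
    pfms: Mapping[str, Pfm],
) -> dict[int, list[ScoredRegion]]:
    """Accessible regions per time point, with sequences and signal values.

    Each planted edge (tf, gene, t) yields one high-signal region whose
    midpoint lies within 400 bp of the target gene's TSS and whose sequence
    carries one embedded consensus site of the TF's motif.  Background
    regions carry random sequence and lower signal, and are kept >= 2 kb
    away from planted TSSs so the planted region is always the nearest one.
    """
    rng = _rng(config, 3)
    half = config.region_length // 2
    chrom_of = annotation["chrom"].to_dict()
    tss = {
        g: (row["start"] if row["strand"] == "+" else row["end"] - 1)
        for g, row in annotation.iterrows()
    }
    out: dict[int, list[ScoredRegion]] = {
        t: [] for t in range(config.n_timepoints)
    }
    planted_centers: dict[int, list[tuple[str, int]]] = {
        t: [] for t in range(config.n_timepoints)
    }
    for i, (tf, gene, t) in enumerate(sorted(truth.edge_set)):
        center = tss[gene] + int(rng.integers(-400, 400, endpoint=True))
        start = center - half
        end = start + config.region_length
        if start < 0 or end > config.chrom_length:
            raise ValueError(
                f"cannot place accessible region near TSS of {gene}"
            )
        seq = list(_random_sequence(rng, config.region_length))
        consensus = pfms[tf].consensus
        offset = int(
            rng.integers(0, config.region_length - len(consensus), endpoint=True)
        )
        seq[offset : offset + len(consensus)] = consensus
        out[t].append(
            ScoredRegion(
                chrom=chrom_of[gene],
                start=start,
                end=end,
                signal=float(rng.uniform(5.0, 10.0)),
                sequence="".join(seq),
                name=f"t{t}_planted{i}",
            )
        )
        planted_centers[t].append((chrom_of[gene], center))

    chroms = sorted(set(annotation["chrom"])) or ["chr1"]
    for t in range(config.n_timepoints):
        taken = planted_centers[t]
        for i in range(config.n_background_regions):
            for _ in range(200):
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                center = int(
                    rng.integers(half, config.chrom_length - half, endpoint=True)
                )
                if all(
                    c != chrom or abs(center - p) >= 2000 for c, p in taken
                ):
                    break
            else:
                raise ValueError("cannot place background region")
            out[t].append(
                ScoredRegion(
                    chrom=chrom,
                    start=center - half,
                    end=center - half + config.region_length,
                    signal=float(rng.uniform(1.0, 3.0)),
                    sequence=_random_sequence(rng, config.region_length),
                    name=f"t{t}_bg{i}",
                )
            )
        out[t].sort(key=lambda r: (r.chrom, r.start, r.name))
    return out


# constituent geometry of a planted acetylation cluster: 6 x 2 kb regions
# separated by 1 kb -> stitched span 17 kb (> 10 kb); isolated regions are
# single 2 kb intervals (span <= 10 kb after stitching)
_SE_N_CONSTITUENTS = 6
_SE_CONSTITUENT_LEN = 2000
_SE_CONSTITUENT_GAP = 1000


def simulate_h3k27ac(
    annotation: pd.DataFrame,
    truth: GroundTruth,
    config: SimConfig,
) -> dict[int, pd.DataFrame]:
    """Acetylation region calls (BED-style) per analysed time point.

    Planted SE-TF loci receive a constituent cluster whose stitched span
    exceeds 10 kb, centred on the gene body; every other gene receives one
    isolated 2 kb region.
    """
    rng = _rng(config, 4)
    span = (
        _SE_N_CONSTITUENTS * _SE_CONSTITUENT_LEN
        + (_SE_N_CONSTITUENTS - 1) * _SE_CONSTITUENT_GAP
    )
    out: dict[int, pd.DataFrame] = {}
    se_set = set(truth.se_tf_ids)
    for t in config.h3k27ac_timepoints:
        rows = []
        for gene, ann in annotation.iterrows():
            mid = (ann["start"] + ann["end"]) // 2
            if gene in se_set:
                cluster_start = mid - span // 2
                if cluster_start < 0 or cluster_start + span > config.chrom_length:
                    raise ValueError(
                        f"gene body of {gene} cannot host a >10 kb cluster"
                    )
                for j in range(_SE_N_CONSTITUENTS):
                    s = cluster_start + j * (
                        _SE_CONSTITUENT_LEN + _SE_CONSTITUENT_GAP
                    )
                    rows.append(
                        {
                            "chrom": ann["chrom"],
                            "start": s,
                            "end": s + _SE_CONSTITUENT_LEN,
                            "name": f"t{t}_{gene}_c{j}",
                            "score": int(rng.integers(500, 1000)),
                            "strand": ".",
                        }
                    )
            else:
                s = mid - _SE_CONSTITUENT_LEN // 2
                rows.append(
                    {
                        "chrom": ann["chrom"],
                        "start": max(0, s),
                        "end": max(0, s) + _SE_CONSTITUENT_LEN,
                        "name": f"t{t}_{gene}_iso",
                        "score": int(rng.integers(100, 500)),
                        "strand": ".",
                    }
                )
        df = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        ).sort_values(["chrom", "start"]).reset_index(drop=True)
        out[t] = df
    return out


@dataclass
class SimData:
    """One fully simulated benchmark instance."""

    config: SimConfig
    annotation: pd.DataFrame
    pfms: dict[str, Pfm]
    truth: GroundTruth
    counts: pd.DataFrame
    tpm: pd.DataFrame
    accessibility: dict[int, list[ScoredRegion]]
    h3k27ac: dict[int, pd.DataFrame]


def simulate_all(config: SimConfig | None = None) -> SimData:
    """Run the full generator under one configuration."""
    config = config or SimConfig()
    annotation, pfms = simulate_annotation(config)
    truth = plan_truth(annotation, config)
    counts, tpm = simulate_expression(annotation, config, truth)
    accessibility = simulate_accessibility(annotation, truth, config, pfms)
    h3k27ac = simulate_h3k27ac(annotation, truth, config)
    return SimData(
        config=config,
        annotation=annotation,
        pfms=pfms,
        truth=truth,
        counts=counts,
        tpm=tpm,
        accessibility=accessibility,
        h3k27ac=h3k27ac,
    )


def write_all(sim: SimData, outdir) -> None:
    """Write every simulated table in its standard on-disk format."""
    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_gtf(sim.annotation, outdir / "genes.gtf")
    io.write_jaspar(sim.pfms, outdir / "motifs.jaspar")
    io.write_matrix(sim.counts, outdir / "counts.tsv")
    io.write_matrix(sim.tpm, outdir / "tpm.tsv")
    for t, regions in sim.accessibility.items():
        io.write_narrowpeak(regions, outdir / f"accessibility_t{t}.narrowPeak")
        io.write_fasta(
            {r.name: r.sequence for r in regions},
            outdir / f"accessibility_t{t}.fa",
        )
    for t, bed in sim.h3k27ac.items():
        io.write_bed6(bed, outdir / f"h3k27ac_t{t}.bed")
    io.write_json(sim.truth.to_dict(), outdir / "ground_truth.json")
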