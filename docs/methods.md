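# Methods

## Scope and data model

`timegrn` reimplements, as a reusable library, an integrative
TF-prioritization analysis for differentiation time courses: time-point
specific TF→gene regulatory scoring from chromatin accessibility, a
time-series expression bifurcation model with per-node TF ranking,
super-enhancer (SE) calling from H3K27ac region calls with SE→TF
association, intersection-based candidate nomination, and exact set-overlap
statistics for target validation. Upstream read-level processing (alignment,
peak calling, footprint detection, differential expression) is out of scope:
region calls, expression matrices, motif models and gene annotation are
consumed as inputs in their standard formats (narrowPeak/BED6, TSV, JASPAR
PFM, GTF, FASTA).

All genomic intervals are 0-based half-open in memory; GTF is converted at
the file boundary. Time points are integers `0..T−1`; expression sample
columns are named `t{i}_rep{j}` and replicates are averaged per time point
before any downstream computation.

## TF→gene scoring

A motif is a 4×L position frequency matrix; columns are renormalised after
adding a pseudocount (default 0.01) and scored as log(p/background) with a
uniform background by default. Every window of a region's sequence is scored
on both strands; `N` bases contribute zero (background). The region affinity
is TRAP-like — the sum over windows of the logistic bind probability
`1/(1+exp(−(s−θ)/λ))` — rather than a hard binding-site call, because
binding strength is treated as a graded quantity. Defaults θ = 0, λ = 1.

The TF→gene score at a time point sums, over regions whose midpoint lies
within `window` (default 50 kb) of the gene's 5'-most TSS,
`affinity × signal × exp(−d/d0)` with decay length `d0` = 5 kb. These two
lengths are conventional for affinity-based regulatory scoring and are
config-exposed; no published values were available to reproduce. Region
signal is the narrowPeak `signalValue` (1.0 when absent).

Two filters make the edge table usable:

- **Expression filter.** A TF with TPM < 1 at *every* analysed time point is
  unexpressed and all its edges are removed; a single time point at or above
  threshold retains it. A TF with a motif but missing from the expression
  table is an error, not a silent drop.
- **Edge floor.** The logistic affinity is strictly positive on every
  window, so a literal "score > 0" rule would make every TF a nominal target
  of every gene that has any nearby region and would flatten the per-node
  target-count ranking into ties. Rows with score ≤ `min_score` (default
  0.05, config-exposed) are therefore dropped; the default sits two orders
  of magnitude below a single strong binding site adjacent to a TSS.

## Expression path tree

Expression is transformed to `log2((TPM+1)/(TPM_t0+1))` per gene. Genes
analysed are those with TPM ≥ 1 at one or more time points, mirroring the TF
expression rule gene-wide.

The bifurcation model replaces an input–output HMM with an observable
equivalent: a greedy, per-time-point refinement. For each node at time `t`,
the per-gene steps `Δ = ratio(t+1) − ratio(t)` are fit with 1- and
2-component Gaussian mixtures (scikit-learn, seeded, 5 initialisations); the
node splits iff `BIC(2) + bic_margin < BIC(1)` and both children keep at
least `min_node_size` genes. Genes go to the child with the higher
responsibility. Defaults: binary splits only, `bic_margin` = 10 (strong
evidence on the BIC scale), `min_node_size` = 10. A split is labelled with
the *child* time point — the time at which the branches first separate — and
the two branch nodes are flagged. Genes are processed in sorted-id order so
the tree is invariant to input row order; the larger-mean branch is always
child 0. This model keeps exactly the contract downstream selection
consumes — split nodes plus per-node TF ranking — without hidden-state path
probabilities.

At each split branch, every TF with edges at that time point is ranked by
the number of its targets inside the branch (descending), tie-broken by the
upper-tail hypergeometric enrichment p-value of that count (node genes as
successes in the analysed-gene universe, the TF's target-set size as draws),
then lexicographically. The prioritized pool is the union over branches of
each branch's top-20 TFs; TFs with zero targets in a branch are never
included. `k` = 20 follows the published selection rule.

## Super-enhancers

H3K27ac regions are stitched per chromosome when the inter-region distance
is ≤ 12.5 kb (the ROSE/HOMER convention; the gap is config-exposed). A
stitched region is an SE iff its span strictly exceeds 10 kb — so 10,001 bp
qualifies and 10,000 bp does not. No signal-ranked elbow cutoff, input
subtraction or promoter exclusion is applied; the size rule is the entire
definition. An SE associates with a TF at a time point when the TF gene body
overlaps it by at least 1 bp (half-open; abutting intervals do not overlap)
and the TF has TPM ≥ 1 at that time point. Gene-body overlap rather than
nearest-gene assignment is deliberate: SEs can span clustered loci, and the
association should not steal an SE from a TF because another gene's TSS is
closer.

## Candidate nomination and overlap statistics

Candidates are the plain set intersection of the top-20 union with the
SE-associated TFs (set semantics, deduplicated). The evidence table carries
each candidate's branch ranks, SE time points and maximal associated TPM so
that the subsequent literature-driven triage stays a human decision. Venn
counts are reported as (only top-k, only SE, both).

Overlap significance between gene lists uses the exact hypergeometric upper
tail `P(X ≥ k)` (scipy, no normal approximation) and the representation
factor `RF = k·N/(n·K)`; ids outside the declared universe are dropped with
a warning. The universe is the caller's choice; the natural one is the set
of genes expressed in the experiment. Differential-expression flags use
strict cutoffs FDR < 0.05 and |log2FC| > 1.

## Synthetic benchmark

The generator emulates the study design at desk scale and is itself part of
the tested surface.

- **Genome and annotation.** Default 50 genes (first 10 are TFs) in equal
  slots on two 1.2 Mb chromosomes, gene bodies 1.5–3 kb with ±2 kb placement
  jitter. The wide slots guarantee non-overlap and keep neighbouring
  acetylation clusters from stitching together; infeasible packings raise.
- **Motifs.** One PFM per TF, 15 columns, each column 0.997 on a random
  dominant base. At genome scale, soft motifs are separable from background
  by averaging over thousands of regions; in a miniature genome with ~10²
  regions the same softness would drown the planted signal in chance
  near-matches, so the planted motifs are deliberately sharp. With 15
  near-consensus columns the probability that background sequence scores
  like a planted site is negligible at the simulated scale.
- **Expression.** Each gene has a baseline log2 abundance (uniform 5–8;
  regulators 6.5–8 so they stay expressed while acting; two designated
  silent TFs far below threshold to exercise the expression filter). All
  genes share a flat profile until the bifurcation time point (default 1),
  after which each planted branch shifts by its regulator's effect (default
  ±2 log2). Every expressed gene belongs to one branch (round-robin);
  branch members are the regulator's planted targets at the bifurcation
  time point. Counts are negative binomial (dispersion 0.1) around
  `TPM × length`-proportional means scaled to the library size; per-sample
  log-normal noise (σ = 0.1 log2 units) models biological variability.
  Emitted TPM is the length-normalised rate scaled against the *expected
  time-zero total* rather than per-sample totals: with half the genome
  shifting +2 and half −2, per-sample renormalisation would shift every
  log2 ratio by about −1.1 and the planted effect sizes would no longer be
  recoverable from the emitted table. The fixed-reference scaling keeps the
  planted ratios identifiable, which is the property the benchmark exists
  to test; it does not emulate the compositional distortion of real
  sequencing, and recovery results here do not speak to that problem.
- **Accessibility.** One 300 bp region per planted edge, midpoint within
  400 bp of the target TSS, signal 5–10, with the TF's consensus embedded
  once at a random offset; 50 background regions per time point with random
  sequence and signal 1–3, kept ≥ 2 kb from planted TSSs so the planted
  region is always the nearest.
- **H3K27ac.** At the last two time points (configurable), each planted
  SE-TF locus receives six 2 kb constituents separated by 1 kb (stitched
  span 17 kb > 10 kb) centred on the gene body; every other gene gets one
  isolated 2 kb region (span ≤ 10 kb after stitching).
- **Determinism.** All draws derive from numbered child streams of the
  config seed; identical configs produce byte-identical output files.

What passing recovery tests shows — and does not. The benchmark plants
clean, well-separated branches, a noiseless motif→region correspondence and
exact SE geometry; it contains no batch effects, mappability artefacts,
motif families with shared binding preferences, indirect regulation or
compositional library effects. Perfect recovery here demonstrates the
pipeline's logic is correct, not that it would achieve similar operating
characteristics on real differentiation data.

## Problem sizes and numerics

The reference evaluation uses the default scenario (50 genes, 10 TFs, 4 time
points × 3 replicates) over 20 seeds, plus 20 all-null seeds, chosen so the
entire suite and the acceptance script each run in well under a minute on a
single CPU while leaving the recovery rates' sampling error far below the
pass margins. Mixture fits use scikit-learn's default covariance
regularisation; nodes with identical steps or fewer than `2·min_node_size`
genes never split. Hypergeometric tails are computed via the survival
function at `k−1`. Ranking ties are resolved deterministically (count, then
p, then id), and all set outputs are reported sorted.

## Known limitations

- The path model is greedy and binary; a three-way divergence appears as two
  stacked binary splits at successive time points.
- SE calling implements only the size rule; datasets where the published SE
  list depended on signal ranking will not be reproduced exactly.
- The TRAP-like affinity parameterisation (θ, λ, d0, window) is
  conventional, not fitted; absolute scores are only comparable within one
  parameter setting.
- The generator's TPM table is fixed-reference scaled (see above); analyses
  sensitive to compositional normalisation need real normalisation upstream.
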