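"""Motif scanning, TRAP-like affinity and the distance-decayed TF->gene
score, each checked against closed forms or independent enumerations."""

import math

import numpy as np
import pandas as pd
import pytest

from timegrn import (
    Pfm,
    ScoredRegion,
    ScoringParams,
    build_edge_table,
    log_odds_scan,
    region_affinity,
    tf_gene_score,
)

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
COMP = str.maketrans("ACGTN", "TGCAN")


def scan_oracle(matrix, seq, pseudocount=0.01, bg=0.25):
    """Position-by-position enumeration, independent of the vectorised scan."""
    matrix = np.asarray(matrix, float)
    probs = (matrix + pseudocount) / (matrix + pseudocount).sum(axis=0)
    L = matrix.shape[1]
    out = []
    for i in range(len(seq) - L + 1):
        s = 0.0
        for j, base in enumerate(seq[i : i + L]):
            if base != "N":
                s += math.log(probs[BASE_INDEX[base], j] / bg)
        out.append(s)
    return out


def revcomp_scan_oracle(matrix, seq, **kw):
    """Scores of the motif on the reverse-complement strand, window-aligned."""
    rc = seq.translate(COMP)[::-1]
    return scan_oracle(matrix, rc, **kw)[::-1]


EXAMPLE_PFM = [[0.7, 0.1], [0.1, 0.7], [0.1, 0.1], [0.1, 0.1]]


def test_uniform_pfm_scores_zero_everywhere():
    pfm = Pfm("u", np.full((4, 3), 0.25))
    fwd, rev = log_odds_scan(pfm, "ACGTNACG")
    assert np.allclose(fwd, 0.0) and np.allclose(rev, 0.0)
    assert len(fwd) == 6


def test_sequence_shorter_than_motif_gives_no_windows():
    pfm = Pfm("p", np.full((4, 5), 0.25))
    fwd, rev = log_odds_scan(pfm, "ACG")
    assert fwd.size == 0 and rev.size == 0
    assert region_affinity(pfm, "ACG") == 0.0


def test_example_pfm_matches_position_enumeration():
    pfm = Pfm("ac", EXAMPLE_PFM)
    fwd, rev = log_odds_scan(pfm, "ACGT")
    assert np.allclose(fwd, scan_oracle(EXAMPLE_PFM, "ACGT"))
    assert np.allclose(rev, revcomp_scan_oracle(EXAMPLE_PFM, "ACGT"))


def test_invalid_character_rejected():
    pfm = Pfm("p", EXAMPLE_PFM)
    with pytest.raises(ValueError, match="non-ACGTN"):
        log_odds_scan(pfm, "ACXT")


def test_random_scans_match_enumeration_oracle():
    rng = np.random.default_rng(42)
    for _ in range(100):
        L = int(rng.integers(1, 9))
        mat = rng.dirichlet(np.ones(4), size=L).T
        n = int(rng.integers(L, 40))
        seq = "".join(rng.choice(list("ACGTN"), size=n, p=[0.24] * 4 + [0.04]))
        pfm = Pfm("r", mat)
        fwd, rev = log_odds_scan(pfm, seq)
        assert np.allclose(fwd, scan_oracle(mat, seq))
        assert np.allclose(rev, revcomp_scan_oracle(mat, seq))


def test_forward_scan_agrees_with_biopython_pssm():
    from Bio import motifs
    from Bio.Seq import Seq

    rng = np.random.default_rng(3)
    mat = rng.dirichlet(np.ones(4), size=6).T
    seq = "".join(rng.choice(list("ACGT"), size=30))
    pfm = Pfm("x", mat, pseudocount=0.05)
    counts = {b: list(mat[i]) for i, b in enumerate("ACGT")}
    motif = motifs.Motif(alphabet="ACGT", counts=counts)
    pssm = motif.counts.normalize(pseudocounts=0.05).log_odds(
        {b: 0.25 for b in "ACGT"}
    )
    expected = pssm.calculate(Seq(seq))  # biopython works in log2
    fwd, _ = log_odds_scan(pfm, seq)
    assert np.allclose(fwd / math.log(2), expected, atol=1e-4)


def test_uniform_affinity_is_half_the_window_count():
    pfm = Pfm("u", np.full((4, 4), 0.25))
    seq = "ACGTACGTACGT"  # 12 bp, 9 windows per strand
    assert region_affinity(pfm, seq, ScoringParams(theta=0.0, lam=1.0)) == pytest.approx(9.0)


def test_affinity_matches_logistic_enumeration_on_toy_sequence():
    seq = "ACGTACCAGGTTACGTACCA"  # 20 bp fixture
    params = ScoringParams(theta=0.5, lam=2.0)
    pfm = Pfm("ac", EXAMPLE_PFM)
    scores = scan_oracle(EXAMPLE_PFM, seq) + revcomp_scan_oracle(EXAMPLE_PFM, seq)
    expected = sum(1 / (1 + math.exp(-(s - 0.5) / 2.0)) for s in scores)
    assert region_affinity(pfm, seq, params) == pytest.approx(expected)
    assert region_affinity(pfm, seq, params) > 0  # at least one window exists


def _region(chrom, start, end, signal=1.0):
    return ScoredRegion(chrom, start, end, signal=signal, sequence="A" * (end - start))


def test_tf_gene_score_closed_forms():
    params = ScoringParams(d0=5000, window=50000)
    tss = 100_000
    on_tss = _region("chr1", tss - 50, tss + 50)
    assert tf_gene_score([2.0], [on_tss], tss, params) == pytest.approx(2.0)
    at_d0 = _region("chr1", tss + 5000 - 50, tss + 5000 + 50)
    assert tf_gene_score([2.0, 1.0], [on_tss, at_d0], tss, params) == pytest.approx(
        2.0 + math.exp(-1), abs=1e-5
    )
    far = _region("chr1", tss + 60_000 - 50, tss + 60_000 + 50)
    assert tf_gene_score([5.0], [far], tss, params) == 0.0


def test_score_decays_monotonically_with_distance():
    params = ScoringParams()
    tss = 200_000
    scores = [
        tf_gene_score([1.5], [_region("chr1", tss + d - 50, tss + d + 50)], tss, params)
        for d in range(0, 49_000, 1000)
    ]
    assert all(a >= b for a, b in zip(scores, scores[1:]))


def test_score_is_additive_over_disjoint_region_sets():
    rng = np.random.default_rng(8)
    params = ScoringParams()
    tss = 150_000
    regions = [
        _region("chr1", tss + int(d) - 50, tss + int(d) + 50, signal=float(s))
        for d, s in zip(rng.integers(-40_000, 40_000, 12), rng.uniform(0.5, 5, 12))
    ]
    affinities = list(rng.uniform(0, 3, 12))
    whole = tf_gene_score(affinities, regions, tss, params)
    part = tf_gene_score(affinities[:5], regions[:5], tss, params) + tf_gene_score(
        affinities[5:], regions[5:], tss, params
    )
    assert whole == pytest.approx(part)


def _sharp(name, consensus):
    mat = np.full((4, len(consensus)), 0.001)
    for j, b in enumerate(consensus):
        mat[BASE_INDEX[b], j] = 0.997
    return Pfm(name, mat, pseudocount=0.001)


def _edge_fixture():
    ann = pd.DataFrame(
        {"chrom": ["chr1"], "start": [1000], "end": [2000], "strand": ["+"], "is_tf": [False]},
        index=pd.Index(["G1"], name="gene_id"),
    )
    pfms = {"TFA": _sharp("TFA", "ACGTACGTACGT"), "TFB": _sharp("TFB", "TTGGCCAATTGG")}
    seq = "".join(
        np.random.default_rng(0).choice(list("ACGT"), size=200)
    )
    seq = pfms["TFA"].consensus + seq[12:100] + pfms["TFB"].consensus + seq[112:]
    region = ScoredRegion("chr1", 900, 1100, signal=2.0, sequence=seq[:200])
    tpm = pd.DataFrame(
        {0: [0.5, 1.2, 5.0], 1: [0.2, 0.0, 5.0], 2: [0.9, 0.0, 5.0], 3: [0.3, 0.0, 5.0]},
        index=pd.Index(["TFA", "TFB", "G1"], name="gene_id"),
    )
    return ann, pfms, tpm, region


def test_unexpressed_tf_edges_removed_iff_tpm_below_1_at_every_timepoint():
    ann, pfms, tpm, region = _edge_fixture()
    edges = build_edge_table(ann, {0: [region]}, pfms, tpm, ScoringParams())
    tfs = set(edges["tf"])
    assert "TFA" not in tfs  # TPM < 1 at every time point
    assert "TFB" in tfs  # expressed at one time point is enough


def test_tf_with_motif_missing_from_expression_is_an_error():
    ann, pfms, tpm, region = _edge_fixture()
    with pytest.raises(KeyError, match="TFB"):
        build_edge_table(ann, {0: [region]}, pfms, tpm.drop(index="TFB"), ScoringParams())


def test_empty_region_set_gives_empty_edge_table():
    ann, pfms, tpm, _ = _edge_fixture()
    edges = build_edge_table(ann, {0: []}, pfms, tpm, ScoringParams())
    assert len(edges) == 0
    assert list(edges.columns) == ["tf", "gene", "timepoint", "score"]


def test_planted_edges_separate_from_background_scores(default_sim, default_result):
    """Median planted score beats the 95th percentile of non-planted pairs."""
    t_b = default_sim.truth.bifurcation_timepoint
    edges = default_result.edges
    at_tb = edges[edges["timepoint"] == t_b]
    lookup = {(r.tf, r.gene): r.score for r in at_tb.itertuples()}
    planted = {(tf, g) for tf, g, t in default_sim.truth.edge_set if t == t_b}
    planted_scores = [lookup.get(p, 0.0) for p in planted]
    tf_ids = [t for t in default_sim.config.tf_ids]
    background = [
        lookup.get((tf, g), 0.0)
        for tf in tf_ids
        for g in default_sim.annotation.index
        if (tf, g) not in planted
    ]
    assert np.median(planted_scores) > np.percentile(background, 95)
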