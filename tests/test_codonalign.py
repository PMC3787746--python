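"""Codon-alignment construction: affine DP against a full-table oracle,
frame repair, consensus rules and codon-column filtering."""
import numpy as np
import pytest
from Bio.Seq import Seq

from waxbill import codonalign, codons, synthgen
from waxbill.codonalign import AlignScores


# ---------------------------------------------------------------------------
# exhaustive affine-DP oracle (plain python, no banding, no tricks)

def oracle_semiglobal_score(q, r, match, mismatch, open_, ext):
    """Optimal semiglobal affine score (free end gaps on r); gap of length
    L costs open_ + L * ext."""
    NEG = float("-inf")
    m, n = len(q), len(r)
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        H[0][j] = 0.0
    for i in range(1, m + 1):
        E[i][0] = -(open_ + i * ext)
        H[i][0] = E[i][0]
        for j in range(1, n + 1):
            E[i][j] = max(H[i - 1][j] - open_ - ext, E[i - 1][j] - ext)
            F[i][j] = max(H[i][j - 1] - open_ - ext, F[i][j - 1] - ext)
            s = match if q[i - 1] == r[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    return max(H[m])


def test_exact_substring_aligns_without_gaps(small_study):
    ref = small_study["reference"]
    cds = ref.cds_sequences[ref.genes[0].gene_id]
    frag = cds[90:290]
    ca = codonalign.align_affine(frag, cds, scores=AlignScores())
    assert len(ca.columns) == 200
    assert all(f >= 0 and r >= 0 for f, r in ca.columns)
    assert ca.score == 200 * AlignScores().match
    assert ca.columns[0] == (0, 90)


def test_dp_score_matches_exhaustive_oracle(rng):
    scores = AlignScores(match=1, mismatch=-1, gap_open=1, gap_ext=1)
    cases = [("ACGT", "ACGGT")]
    for _ in range(25):
        m = rng.integers(5, 30)
        n = rng.integers(5, 40)
        q = "".join("ACGT"[b] for b in rng.integers(0, 4, m))
        r = "".join("ACGT"[b] for b in rng.integers(0, 4, n))
        cases.append((q, r))
    for q, r in cases:
        ca = codonalign.align_affine(q, r, scores=scores)
        expected = oracle_semiglobal_score(q, r, 1, -1, 1, 1)
        assert ca.score == pytest.approx(expected), (q, r)


def test_single_reference_insertion_example():
    """ACGT vs ACGGT: two optimal alignments exist (one gap column, or one
    mismatch) at the oracle score of 2; the deterministic tie-break prefers
    the diagonal, and a cheaper gap flips the choice to the gap column."""
    scores = AlignScores(match=1, mismatch=-1, gap_open=1, gap_ext=1)
    ca = codonalign.align_affine("ACGT", "ACGGT", scores=scores)
    assert ca.score == oracle_semiglobal_score("ACGT", "ACGGT", 1, -1, 1, 1) == 2
    assert not any(f < 0 or r < 0 for f, r in ca.columns)  # diagonal wins tie
    cheap_gap = AlignScores(match=1, mismatch=-2, gap_open=0.5, gap_ext=0.5)
    ca2 = codonalign.align_affine("ACGT", "ACGGT", scores=cheap_gap)
    gap_cols = [(f, r) for f, r in ca2.columns if f < 0]
    assert len(gap_cols) == 1  # the extra reference base sits in a gap column


def test_coordinates_strictly_increasing(small_study):
    ref = small_study["reference"]
    cds = ref.cds_sequences[ref.genes[1].gene_id]
    frag = cds[10:200] + "A" + cds[200:350]  # one inserted base
    ca = codonalign.align_affine(frag, cds)
    fpos = [f for f, _ in ca.columns if f >= 0]
    rpos = [r for _, r in ca.columns if r >= 0]
    assert fpos == sorted(set(fpos))
    assert rpos == sorted(set(rpos))


@pytest.mark.parametrize("n_extra", [1, 2])
def test_repair_frame_removes_insertions(small_study, n_extra):
    ref = small_study["reference"]
    cds = ref.cds_sequences[ref.genes[0].gene_id]
    frag = cds[0:150] + "G" * n_extra + cds[150:300]
    ca = codonalign.repair_frame(codonalign.align_affine(frag, cds))
    assert all(r >= 0 for _, r in ca.columns)
    # downstream translation stays in frame: rebuilt sequence equals CDS
    rebuilt = "".join(ca.fragment_seq[f] for f, r in ca.columns if f >= 0)
    assert rebuilt == cds[:300]
    protein = Seq(rebuilt).translate()
    assert "*" not in protein


def test_repair_frame_is_identity_without_insertions(small_study):
    ref = small_study["reference"]
    cds = ref.cds_sequences[ref.genes[0].gene_id]
    ca = codonalign.align_affine(cds[30:330], cds)
    assert codonalign.repair_frame(ca).columns == ca.columns


def _coord(gene, seq, cols, score=100.0, fid="f"):
    return codonalign.CoordAlignment(fid, gene, seq, cols, score)


def test_consensus_majority_and_tie_rules():
    # positions 0..3 of a 6 bp reference
    a1 = _coord("g", "AAAA", [(i, i) for i in range(4)], score=10, fid="f1")
    a2 = _coord("g", "AAAC", [(i, i) for i in range(4)], score=20, fid="f2")
    a3 = _coord("g", "AAAG", [(i, i) for i in range(4)], score=15, fid="f3")
    cons = codonalign.build_consensus([a1, a2, a3], 6, "sp")
    assert cons.chars[:3] == "AAA"
    assert cons.support[0] == 3
    # position 3: C/G/A tie at count 1 -> highest score wins (C, score 20)
    assert cons.chars[3] == "C"
    # uncovered positions are '-'
    assert cons.chars[4:] == "--"


def test_consensus_two_to_one_majority():
    a1 = _coord("g", "T", [(0, 0)], fid="f1")
    a2 = _coord("g", "T", [(0, 0)], fid="f2")
    a3 = _coord("g", "C", [(0, 0)], score=999, fid="f3")
    cons = codonalign.build_consensus([a1, a2, a3], 1, "sp")
    assert cons.chars == "T"


def test_consensus_requires_alignments():
    with pytest.raises(ValueError):
        codonalign.build_consensus([], 10, "sp")


def _consensus_from_seq(gene, species, seq):
    return codonalign.SpeciesConsensus(gene, species, seq,
                                       np.ones(len(seq), dtype=int))


def test_codon_alignment_drops_gapped_columns_and_stop():
    ref = "ATG" + "AAA" * 99 + "TAA"  # 101 codons with terminal stop
    other = "ATG" + "AAA" * 40 + "-AA" + "AAA" * 58 + "TAA"
    aln = codonalign.build_codon_alignment(
        ref, [_consensus_from_seq("g", "sp", other)], min_len=150)
    # terminal stop gone, one gapped codon column gone
    assert aln.n_codons == 99
    assert 41 not in aln.column_map
    for row in aln.rows.values():
        assert "-" not in row
        assert "*" not in str(Seq(row).translate())


def test_min_length_rejection_at_297bp():
    ref = "ATG" + "AAA" * 99 + "TAA"
    # only the first 99 codons covered -> 99*3 = 297 bp survive
    other = "ATG" + "AAA" * 98 + "-" * 3 + "TAA"
    aln = codonalign.build_codon_alignment(
        ref, [_consensus_from_seq("g", "sp", other)], min_len=300)
    assert aln is None
    aln = codonalign.build_codon_alignment(
        ref, [_consensus_from_seq("g", "sp", other)], min_len=297)
    assert aln is not None and aln.length_bp == 297


def test_consensus_length_mismatch_is_an_error():
    with pytest.raises(ValueError, match="length"):
        codonalign.build_codon_alignment(
            "ATGAAATAA", [_consensus_from_seq("g", "sp", "ATGAAA")])


def test_end_to_end_error_free_fragments_recover_truth(small_config):
    """With error-free, deeply covering fragments, the codon alignment rows
    equal the true evolved CDS minus the terminal stop."""
    import dataclasses
    cfg = dataclasses.replace(small_config, fragment_error_sub=0.0,
                              fragment_error_indel=0.0, fragment_coverage=8.0)
    ref = synthgen.build_reference(cfg)
    truth = synthgen.evolve_orthologs(ref, cfg)
    _, fragments, _ = synthgen.make_diploid_and_reads(ref, truth, cfg)
    gene = ref.genes[0].gene_id
    cds = truth.sequence(cfg.ingroup_b, gene)
    cdna_focal_len = len(ref.cdna_sequences[gene])
    aligned = []
    for fid, seq in fragments["waxbill"]:
        if fid.split("|")[1] != gene:
            continue
        if fid.split("|")[-1] == "-":
            seq = synthgen.revcomp(seq)
        ca = codonalign.align_affine(seq, ref.utr5[gene] + cds + ref.utr3[gene],
                                     fid, gene)
        aligned.append(codonalign.repair_frame(ca))
    cons = codonalign.build_consensus(aligned, cdna_focal_len, "waxbill")
    u5 = len(ref.utr5[gene])
    clen = len(cds)
    cds_cons = codonalign.SpeciesConsensus(
        gene, "waxbill", cons.chars[u5:u5 + clen], cons.support[u5:u5 + clen])
    aln = codonalign.build_codon_alignment(cds, [cds_cons],
                                           reference_name="zebrafinch")
    truth_wax = truth.sequence("waxbill", gene)
    for k_out, k_cds in enumerate(aln.column_map):
        assert aln.rows["waxbill"][3 * k_out:3 * k_out + 3] == \
            truth_wax[3 * k_cds:3 * k_cds + 3]
    # full coverage: every codon column except the stop survives
    if "-" not in cons.chars[u5:u5 + clen]:
        assert aln.rows["waxbill"] == truth_wax[:-3]


def test_pairwise_mode_retains_at_least_as_many_genes(small_study):
    """Two-species alignments keep >= the genes kept by the three-species
    mode on the same consensuses (degraded coverage simulated by masking)."""
    ref = small_study["reference"]
    rng = np.random.default_rng(0)
    kept_pair = kept_trio = 0
    for g in ref.genes:
        cds = ref.cds_sequences[g.gene_id]
        def masked():
            chars = list(cds)
            # independent coverage holes per species
            for _ in range(rng.integers(0, 3)):
                start = int(rng.integers(0, len(cds) - 60))
                for i in range(start, start + 60):
                    chars[i] = "-"
            return "".join(chars)
        c1 = _consensus_from_seq(g.gene_id, "sp1", masked())
        c2 = _consensus_from_seq(g.gene_id, "sp2", masked())
        if codonalign.build_codon_alignment(cds, [c1]) is not None:
            kept_pair += 1
        if codonalign.build_codon_alignment(cds, [c1, c2]) is not None:
            kept_trio += 1
    assert kept_pair >= kept_trio
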