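"""Heterozygous SNP discovery: read filters, the depth-based caller,
compartment classification and chromosome density."""
import numpy as np
import pytest

from waxbill import snpscan, synthgen
from waxbill.snpscan import SnpCall, SnpParams


@pytest.mark.parametrize("read, kept", [
    ("ACGT" * 24 + "ACG", False),          # 99 bp -> too short
    (("A" * 130 + "CGT" * 23 + "A"), False),  # 65% A -> homopolymer
    ("ACGTTGCA" * 19, True),               # 152 bp, max base 25%
])
def test_read_filters(read, kept):
    report = snpscan.filter_reads([("r1", read)])
    assert (len(report.kept) == 1) == kept
    assert report.n_short + report.n_homopolymer == (0 if kept else 1)


def _mk_reads(consensus, pos, bases, n_each, flank=60):
    """Reads covering `pos` mid-read, carrying the given bases there."""
    reads = []
    lo, hi = pos - flank, pos + flank
    for base in bases:
        for k in range(n_each):
            chunk = consensus[lo:pos] + base + consensus[pos + 1:hi]
            reads.append(chunk)
    return reads


@pytest.fixture(scope="module")
def consensus():
    rng = np.random.default_rng(77)
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=400))


def test_balanced_het_site_is_called(consensus):
    pos = 200
    a1 = consensus[pos]
    a2 = "A" if a1 != "A" else "G"
    reads = _mk_reads(consensus, pos, [a1, a2], 3)
    calls = snpscan.call_het_snps({"g": reads}, {"g": consensus})
    site = [c for c in calls if c.transcript_pos == pos]
    assert len(site) == 1
    assert {site[0].allele1, site[0].allele2} == {a1, a2}
    assert (site[0].depth1, site[0].depth2) == (3, 3)


def test_low_minor_depth_not_called(consensus):
    pos = 200
    a1 = consensus[pos]
    a2 = "A" if a1 != "A" else "G"
    reads = _mk_reads(consensus, pos, [a1], 5) + _mk_reads(consensus, pos, [a2], 1)
    calls = snpscan.call_het_snps({"g": reads}, {"g": consensus})
    assert not [c for c in calls if c.transcript_pos == pos]


def test_homozygous_error_free_reads_give_no_calls(consensus):
    reads = [consensus[i:i + 150] for i in range(0, 250, 10)]
    calls = snpscan.call_het_snps({"g": reads}, {"g": consensus})
    assert calls == []


def test_triallelic_position_skipped(consensus):
    pos = 200
    bases = [b for b in "ACGT" if b != consensus[pos]][:3]
    reads = _mk_reads(consensus, pos, bases, 3)
    calls = snpscan.call_het_snps({"g": reads}, {"g": consensus})
    assert not [c for c in calls if c.transcript_pos == pos]


def test_read_end_positions_masked(consensus):
    """A variant carried only in the first end_mask bases never piles up."""
    pos = 100
    a2 = "A" if consensus[pos] != "A" else "G"
    reads = [a2 + consensus[pos + 1:pos + 140]] * 6  # variant at read pos 0
    calls = snpscan.call_het_snps({"g": reads}, {"g": consensus})
    assert not [c for c in calls if c.transcript_pos == pos]


# ---------------------------------------------------------------------------
# classification

@pytest.fixture(scope="module")
def annotation(small_study):
    ref = small_study["reference"]
    return ref.genes, dict(ref.chromosomes)


def _call_at(chrom, pos):
    return SnpCall("g0001", 0, "A", "C", 3, 3, chrom=chrom, position=pos)


def test_classify_precedence_examples(annotation):
    genes, lens = annotation
    g = genes[0]
    cds_pos = g.cds_intervals[0][0]
    out = snpscan.classify_snp(_call_at(g.chrom, cds_pos), genes, lens)
    assert out.compartment == "CDS"
    # 500 bp downstream of the transcript end on the 3' side
    if g.strand == "+":
        p3 = g.transcript[1] + 500
    else:
        p3 = g.transcript[0] - 500
    out = snpscan.classify_snp(_call_at(g.chrom, p3), genes, lens)
    assert out.compartment == "flank3"
    intron_pos = g.intron_intervals[0][0]
    out = snpscan.classify_snp(_call_at(g.chrom, intron_pos), genes, lens)
    assert out.compartment == "intron"


def test_classify_far_from_genes_is_intergenic(annotation):
    genes, lens = annotation
    chrom = genes[0].chrom
    spans = [g.transcript for g in genes if g.chrom == chrom]
    pos = max(e for _, e in spans) + 5000
    assert pos < lens[chrom]
    out = snpscan.classify_snp(_call_at(chrom, pos), genes, lens)
    assert out.compartment == "intergenic"


def test_classify_beyond_chromosome_raises(annotation):
    genes, lens = annotation
    chrom = genes[0].chrom
    with pytest.raises(ValueError, match="beyond"):
        snpscan.classify_snp(_call_at(chrom, lens[chrom] + 10), genes, lens)


def _oracle_compartment(genes, params, chrom, pos):
    """Independent membership check with explicit precedence."""
    found = {}
    for g in genes:
        if g.chrom != chrom:
            continue
        for name, ivals in (("CDS", g.cds_intervals),
                            ("UTR5", g.utr5_intervals),
                            ("UTR3", g.utr3_intervals),
                            ("intron", g.intron_intervals)):
            if any(s <= pos < e for s, e in ivals):
                found.setdefault(name, True)
        s, e = g.transcript
        before = max(0, s - params.flank_bp) <= pos < s
        after = e <= pos < e + params.flank_bp
        if g.strand == "+":
            if before:
                found.setdefault("flank5", True)
            if after:
                found.setdefault("flank3", True)
        else:
            if before:
                found.setdefault("flank3", True)
            if after:
                found.setdefault("flank5", True)
    for name in ("CDS", "UTR5", "UTR3", "intron", "flank5", "flank3"):
        if name in found:
            return name
    return "intergenic"


def test_classification_agrees_with_membership_oracle(annotation, rng):
    genes, lens = annotation
    params = SnpParams()
    chroms = sorted(lens)
    for _ in range(1000):
        chrom = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(0, lens[chrom]))
        got = snpscan.classify_snp(_call_at(chrom, pos), genes, lens,
                                   params).compartment
        assert got == _oracle_compartment(genes, params, chrom, pos)


def test_lift_calls_land_in_exons(small_study):
    ref = small_study["reference"]
    g = ref.genes[0]
    call = SnpCall(g.gene_id, 10, "A", "C", 3, 3)
    lifted = snpscan.lift_calls([call], ref.genes)[0]
    assert lifted.chrom == g.chrom
    assert lifted.position == g.to_genome(10)


# ---------------------------------------------------------------------------
# density

def test_density_arithmetic_and_zero_rows():
    calls = [_call_at("c1", i) for i in range(10)]
    fit = snpscan.chromosome_density(calls, [("c1", 5000), ("c2", 8000)])
    by = {r.chrom: r for r in fit.rows}
    assert by["c1"].snps_per_kb == pytest.approx(2.0)
    assert by["c2"].snp_count == 0
    assert by["c2"].snps_per_kb == 0.0
    with pytest.raises(ValueError, match="length"):
        snpscan.chromosome_density(calls, [("c1", 0)])


def test_density_scales_linearly_under_uniform_rate(rng):
    """Counts proportional to length give r^2 >= 0.98 at 1000+ SNPs."""
    chroms = [(f"c{i}", int(2e5 * (i + 1))) for i in range(10)]
    rate = 2e-4
    calls = []
    for name, length in chroms:
        n = rng.poisson(rate * length)
        calls += [_call_at(name, int(p)) for p in rng.integers(0, length, n)]
    assert len(calls) >= 1000
    fit = snpscan.chromosome_density(calls, chroms)
    assert fit.r_squared >= 0.98
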