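"""Reference-free heterozygous SNP discovery and chromosomal mapping.

A DIAL-style depth-based caller for a single diploid individual: reads are
filtered (length and homopolymer content), aligned to the focal species'
own assembled consensus per gene, and a site is called heterozygous when
exactly two alleles each reach a minimum read depth, with read-end and
indel-adjacent positions masked. Calls are lifted onto the reference
genome (assuming conserved synteny, as when waxbill SNPs are placed on the
zebra finch assembly) and classified into genomic compartments
(CDS > UTR > intron > 1-kb flank > intergenic), and per-chromosome SNP
density is summarized with a linear count-vs-length fit.

Only within-individual heterozygous sites are discoverable here; the
caller is biased toward high-frequency polymorphisms by design.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import linregress

from ._align import semiglobal_align
from .synthgen import GeneModel, revcomp


@dataclass(frozen=True)
class SnpParams:
    min_read_len: int = 100
    homopolymer_frac: float = 0.60
    min_allele_depth: int = 2
    min_total_depth: int = 4
    end_mask: int = 5
    indel_mask: int = 3
    flank_bp: int = 1000

    def __post_init__(self):
        if not 0 < self.homopolymer_frac <= 1:
            raise ValueError("homopolymer_frac must be in (0, 1]")
        for f in ("min_read_len", "min_allele_depth", "min_total_depth",
                  "end_mask", "indel_mask", "flank_bp"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass
class SnpCall:
    gene_id: Optional[str]
    transcript_pos: int
    allele1: str
    allele2: str
    depth1: int
    depth2: int
    chrom: Optional[str] = None
    position: Optional[int] = None  # genomic, 0-based
    compartment: Optional[str] = None

    def __post_init__(self):
        if self.allele1 == self.allele2:
            raise ValueError("heterozygous call needs two distinct alleles")


@dataclass
class ChromDensityRow:
    chrom: str
    length: int
    snp_count: int

    @property
    def snps_per_kb(self) -> float:
        return 1000.0 * self.snp_count / self.length


@dataclass
class ReadFilterReport:
    kept: list
    n_short: int
    n_homopolymer: int


def filter_reads(reads: Sequence[tuple[str, str]],
                 params: SnpParams = SnpParams()) -> ReadFilterReport:
    """Drop reads shorter than min_read_len or with any one nucleotide
    making up >= homopolymer_frac of the read."""
    kept, n_short, n_homo = [], 0, 0
    for rid, seq in reads:
        if len(seq) < params.min_read_len:
            n_short += 1
            continue
        top = max(Counter(seq.upper()).values())
        if top / len(seq) >= params.homopolymer_frac:
            n_homo += 1
            continue
        kept.append((rid, seq))
    return ReadFilterReport(kept, n_short, n_homo)


_SEED_K = 15


def _kmer_positions(consensus: str, k: int = _SEED_K) -> dict[str, int]:
    """First occurrence of each consensus k-mer (plenty for seeding reads
    on low-repeat transcripts)."""
    out: dict[str, int] = {}
    for i in range(len(consensus) - k + 1):
        out.setdefault(consensus[i : i + k], i)
    return out


def _locate_read(seq: str, kmers: dict[str, int], k: int = _SEED_K):
    """Orient the read against the consensus and estimate its diagonal from
    shared k-mers. Returns (oriented_seq, diagonal) or None."""
    best = None
    for cand in (seq, revcomp(seq)):
        diags = [kmers[cand[i : i + k]] - i
                 for i in range(0, max(1, len(cand) - k + 1), 4)
                 if cand[i : i + k] in kmers]
        if diags and (best is None or len(diags) > best[2]):
            best = (cand, int(np.median(diags)), len(diags))
    if best is None:
        return None
    return best[0], best[1]


def _pileup_read(seq: str, consensus: str, diag: int, params: SnpParams,
                 counts: dict[int, Counter]) -> None:
    lo = max(0, diag - 60)
    hi = min(len(consensus), diag + len(seq) + 60)
    window = consensus[lo:hi]
    _, cols = semiglobal_align(seq, window)
    cols = [(f, r + lo if r >= 0 else -1) for f, r in cols]
    # consensus positions near an alignment gap are masked
    masked: set[int] = set()
    last_ref = -1
    for f, r in cols:
        if r >= 0:
            last_ref = r
        if f < 0 or r < 0:
            anchor = r if r >= 0 else last_ref
            if anchor < 0:
                anchor = 0
            for d in range(-params.indel_mask, params.indel_mask + 1):
                masked.add(anchor + d)
    for f, r in cols:
        if f < 0 or r < 0 or r in masked:
            continue
        if f < params.end_mask or f >= len(seq) - params.end_mask:
            continue
        base = seq[f]
        if base in "ACGT":
            counts.setdefault(r, Counter())[base] += 1


def call_het_snps(reads_by_gene: dict[str, list[str]],
                  consensus_by_gene: dict[str, str],
                  params: SnpParams = SnpParams()) -> list[SnpCall]:
    """Depth-based heterozygote calls per consensus position: exactly two
    alleles each at depth >= min_allele_depth, total depth >=
    min_total_depth; sites with three or more alleles at depth are skipped
    as error-rich. Positions are in spliced-transcript coordinates."""
    calls: list[SnpCall] = []
    for gene_id in sorted(reads_by_gene):
        consensus = consensus_by_gene.get(gene_id)
        if consensus is None:
            continue
        counts: dict[int, Counter] = {}
        kmers = _kmer_positions(consensus)
        for seq in reads_by_gene[gene_id]:
            located = _locate_read(seq.upper(), kmers)
            if located is None:
                continue
            _pileup_read(located[0], consensus, located[1], params, counts)
        for pos in sorted(counts):
            c = counts[pos]
            total = sum(c.values())
            if total < params.min_total_depth:
                continue
            at_depth = [(b, n) for b, n in c.items()
                        if n >= params.min_allele_depth]
            if len(at_depth) != 2:
                continue
            at_depth.sort(key=lambda bn: (-bn[1], bn[0]))
            (a1, d1), (a2, d2) = at_depth
            calls.append(SnpCall(gene_id, pos, a1, a2, d1, d2))
    return calls


def lift_calls(calls: Sequence[SnpCall], genes: Sequence[GeneModel]) -> list[SnpCall]:
    """Project transcript-space calls onto genome coordinates through the
    gene models (alleles stay in transcript orientation)."""
    by_id = {g.gene_id: g for g in genes}
    out = []
    for call in calls:
        model = by_id.get(call.gene_id)
        if model is None or call.transcript_pos >= model.spliced_length:
            continue
        out.append(replace(call, chrom=model.chrom,
                           position=model.to_genome(call.transcript_pos)))
    return out


def _flanks(model: GeneModel, flank_bp: int):
    s, e = model.transcript
    left = (max(0, s - flank_bp), s)
    right = (e, e + flank_bp)
    if model.strand == "+":
        return left, right  # (flank5, flank3)
    return right, left


def classify_snp(call: SnpCall, genes: Sequence[GeneModel],
                 chrom_lengths: dict[str, int],
                 params: SnpParams = SnpParams()) -> SnpCall:
    """Assign a genomic compartment with precedence CDS > UTR5/UTR3 >
    intron > flank5/flank3 (within flank_bp, strand-aware) > intergenic."""
    if call.chrom is None or call.position is None:
        raise ValueError("call must be lifted to genome coordinates first")
    length = chrom_lengths.get(call.chrom)
    if length is not None and not 0 <= call.position < length:
        raise ValueError(
            f"position {call.position} beyond chromosome {call.chrom} "
            f"length {length}")
    pos = call.position
    best_rank = 99
    best = ("intergenic", None)
    order = ["CDS", "UTR5", "UTR3", "intron", "flank5", "flank3"]
    for model in genes:
        if model.chrom != call.chrom:
            continue
        f5, f3 = _flanks(model, params.flank_bp)
        groups = [
            ("CDS", model.cds_intervals),
            ("UTR5", model.utr5_intervals),
            ("UTR3", model.utr3_intervals),
            ("intron", model.intron_intervals),
            ("flank5", (f5,)),
            ("flank3", (f3,)),
        ]
        for name, intervals in groups:
            if any(s <= pos < e for s, e in intervals):
                rank = order.index(name)
                if rank < best_rank:
                    best_rank = rank
                    best = (name, model.gene_id)
                break
    compartment, gene = best
    return replace(call, compartment=compartment,
                   gene_id=gene if gene is not None else call.gene_id)


def compartment_fractions(calls: Sequence[SnpCall]) -> dict[str, float]:
    counts = Counter(c.compartment or "unclassified" for c in calls)
    total = sum(counts.values())
    return {k: counts[k] / total for k in sorted(counts)} if total else {}


@dataclass
class DensityFit:
    rows: list[ChromDensityRow]
    slope: float
    intercept: float
    r_squared: float


def chromosome_density(calls: Sequence[SnpCall],
                       chromosomes: Sequence[tuple[str, int]]) -> DensityFit:
    """Per-chromosome SNP counts, densities and the least-squares fit of
    count against chromosome length (rows with zero calls included)."""
    for name, length in chromosomes:
        if length <= 0:
            raise ValueError(f"chromosome {name} has non-positive length")
    counts = Counter(c.chrom for c in calls if c.chrom is not None)
    rows = [ChromDensityRow(name, length, counts.get(name, 0))
            for name, length in chromosomes]
    lengths = np.array([r.length for r in rows], dtype=float)
    if len(rows) >= 2 and np.ptp(lengths) > 0:
        fit = linregress(lengths, [r.snp_count for r in rows])
        slope, intercept, r2 = fit.slope, fit.intercept, fit.rvalue ** 2
    else:
        slope = intercept = r2 = float("nan")
    return DensityFit(rows, slope, intercept, r2)
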