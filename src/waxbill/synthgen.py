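"""Synthetic three-taxon transcriptome study generator.

Emulates the study design this package analyzes: an annotated reference
songbird gene set (zebra-finch-like), two estrildid ingroup lineages and a
more divergent outgroup evolved under a GY94 codon process with per-gene
omega, chromosome-class effects (fast-Z, slow-4A), a diploid focal
individual with planted heterozygous sites, and 454-style transcript
fragments and reads with substitution and homopolymer-indel errors.

Every downstream stage (ortholog matching, codon alignment, rate
estimation, SNP calling, enrichment) can be exercised against the truth
tables returned here.

Coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import codons


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class ChromosomeSpec:
    """One row of the chromosome plan."""
    name: str
    length: int
    n_genes: int
    omega_multiplier: float = 1.0
    het_rate: float = 0.002  # heterozygous sites per transcript bp


def default_chromosome_plan() -> list[ChromosomeSpec]:
    """Default avian-style plan: four autosomes plus Z (elevated omega, low
    heterozygosity) and the 4A microchromosome (reduced omega, high
    heterozygosity). Class multipliers: Z omega x1.5 / het x0.3, 4A omega
    x0.6 / het x5 on an autosomal baseline of 0.002 het sites per bp."""
    base_het = 0.002
    rows = [
        ("1", 60, 1.0, base_het),
        ("2", 50, 1.0, base_het),
        ("3", 40, 1.0, base_het),
        ("4", 40, 1.0, base_het),
        ("4A", 30, 0.6, base_het * 5.0),
        ("Z", 50, 1.5, base_het * 0.3),
    ]
    return [
        ChromosomeSpec(name, n * 30_000, n, om, het) for name, n, om, het in rows
    ]


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation parameters.

    Branch lengths are expected substitutions per codon; the two ingroup
    branches default to 0.15 each (pairwise ingroup divergence 0.3,
    a 10-15 Myr estrildid split), the outgroup to 0.5. Per-gene omega is
    Gamma(shape=omega_shape, mean=omega_mean); the default mean 0.13 is the
    genome-wide dN/dS reported for these finches. Read error rates are
    454-like: substitutions are rare (1e-3) and homopolymer indels dominate.
    """
    seed: int
    chromosome_plan: tuple[ChromosomeSpec, ...] = tuple(default_chromosome_plan())
    n_genes: Optional[int] = None  # validated against the plan when given
    codons_per_gene: int = 500
    utr5_len: int = 150
    utr3_len: int = 300
    # species / tree
    ingroup_a: str = "waxbill"
    ingroup_b: str = "zebrafinch"
    outgroup: str = "greattit"
    t_ingroup_a: float = 0.15
    t_ingroup_b: float = 0.15
    t_outgroup: float = 0.5
    kappa: float = 2.0
    # per-gene omega law
    omega_mean: float = 0.13
    omega_shape: float = 2.0
    omega_fixed: Optional[float] = None  # overrides the gamma law when set
    # optional focal-branch omega multipliers: gene id -> {species: multiplier}
    branch_multipliers: dict = field(default_factory=dict)
    # fragments ("isotigs": 400-800 bp cDNA fragments, near error-free)
    fragment_mean_len: int = 600
    fragment_len_sd: int = 100
    fragment_coverage: float = 2.5
    fragment_error_sub: float = 2e-4
    fragment_error_indel: float = 5e-4
    # 454-style reads
    read_mean_len: int = 350
    read_len_sd: int = 50
    read_coverage: float = 15.0
    read_error_sub: float = 1e-3
    read_error_homopolymer_indel: float = 4e-3
    # synthetic functional term map
    n_terms: int = 25

    def __post_init__(self):
        plan = tuple(
            c if isinstance(c, ChromosomeSpec) else ChromosomeSpec(*c)
            for c in self.chromosome_plan
        )
        object.__setattr__(self, "chromosome_plan", plan)
        if not plan:
            raise ValueError("chromosome_plan is empty")
        total = sum(c.n_genes for c in plan)
        if self.n_genes is None:
            object.__setattr__(self, "n_genes", total)
        elif self.n_genes != total:
            raise ValueError(
                f"n_genes={self.n_genes} does not match chromosome_plan total {total}"
            )
        if self.codons_per_gene < 100:
            raise ValueError("codons_per_gene must be >= 100")
        for name in ("t_ingroup_a", "t_ingroup_b", "t_outgroup"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for c in plan:
            if c.length <= 0 or c.n_genes < 0 or c.het_rate < 0 or c.omega_multiplier < 0:
                raise ValueError(f"invalid chromosome spec {c.name}")
        for name in (
            "kappa", "omega_mean", "omega_shape", "fragment_coverage",
            "read_coverage", "fragment_error_sub", "fragment_error_indel",
            "read_error_sub", "read_error_homopolymer_indel",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def species(self) -> tuple[str, str, str]:
        return (self.ingroup_a, self.ingroup_b, self.outgroup)

    def branch_length(self, species: str) -> float:
        return {
            self.ingroup_a: self.t_ingroup_a,
            self.ingroup_b: self.t_ingroup_b,
            self.outgroup: self.t_outgroup,
        }[species]


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


# ---------------------------------------------------------------------------
# reference annotation

@dataclass(frozen=True)
class GeneModel:
    """Annotated gene: genomic sub-intervals (0-based half-open) plus the
    exon blocks needed to lift transcript coordinates onto the genome."""
    gene_id: str
    chrom: str
    strand: str
    transcript: tuple[int, int]
    cds_intervals: tuple[tuple[int, int], ...]
    utr5_intervals: tuple[tuple[int, int], ...]
    utr3_intervals: tuple[tuple[int, int], ...]
    intron_intervals: tuple[tuple[int, int], ...]
    # transcript-order blocks: (spliced_start, spliced_end, genomic_offset)
    _blocks: tuple[tuple[int, int, int], ...]

    def __post_init__(self):
        for group in (self.cds_intervals, self.utr5_intervals,
                      self.utr3_intervals, self.intron_intervals):
            for s, e in group:
                if not (self.transcript[0] <= s < e <= self.transcript[1]):
                    raise ValueError(
                        f"{self.gene_id}: sub-interval ({s},{e}) outside transcript"
                    )

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e, _ in self._blocks)

    @property
    def span(self) -> int:
        return self.transcript[1] - self.transcript[0]

    def to_genome(self, pos: int) -> int:
        """Genomic coordinate of a spliced-transcript position (5'->3')."""
        if not 0 <= pos < self.spliced_length:
            raise ValueError(f"transcript position {pos} out of range")
        start = self.transcript[0]
        for a, b, off in self._blocks:
            if a <= pos < b:
                if self.strand == "+":
                    return start + off + (pos - a)
                return start + self.span - off - 1 - (pos - a)
        raise AssertionError("unreachable")


def _build_gene_model(gene_id, chrom, strand, tx_start, u5, clen, u3,
                      splice_points, intron_lens):
    """Lay out one gene. splice_points are spliced-transcript coordinates
    (all inside the CDS); intron_lens has one entry per splice point."""
    spliced_len = u5 + clen + u3
    bounds = [0, *splice_points, spliced_len]
    blocks = []
    introns_plus = []
    off = 0
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        blocks.append((a, b, off))
        off += b - a
        if i < len(intron_lens):
            introns_plus.append((off, off + intron_lens[i]))
            off += intron_lens[i]
    span = off

    def g_interval(x, y):
        """Map a spliced sub-interval [x,y) within one block to genomic."""
        for a, b, o in blocks:
            if a <= x < b:
                lo, hi = o + (x - a), o + (y - a)
                if strand == "+":
                    return (tx_start + lo, tx_start + hi)
                return (tx_start + span - hi, tx_start + span - lo)
        raise AssertionError("unreachable")

    def typed(lo, hi):
        out = []
        for a, b, _ in blocks:
            s, e = max(a, lo), min(b, hi)
            if s < e:
                out.append(g_interval(s, e))
        return tuple(sorted(out))

    if strand == "+":
        g_introns = tuple(
            sorted((tx_start + s, tx_start + e) for s, e in introns_plus))
    else:
        g_introns = tuple(
            sorted((tx_start + span - e, tx_start + span - s)
                   for s, e in introns_plus))
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        transcript=(tx_start, tx_start + span),
        cds_intervals=typed(u5, u5 + clen),
        utr5_intervals=typed(0, u5),
        utr3_intervals=typed(u5 + clen, spliced_len),
        intron_intervals=g_introns,
        _blocks=tuple(blocks),
    )


@dataclass
class ReferenceBundle:
    """Reference species annotation: chromosome sizes, gene models and the
    CDS / spliced cDNA sequences (cDNA = UTR5 + CDS incl. stop + UTR3)."""
    chromosomes: list[tuple[int, int]]
    genes: list[GeneModel]
    cds_sequences: dict[str, str]
    cdna_sequences: dict[str, str]
    utr5: dict[str, str]
    utr3: dict[str, str]

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __post_init__(self):
        self._by_id = {g.gene_id: g for g in self.genes}

    @property
    def chrom_of(self) -> dict[str, str]:
        return {g.gene_id: g.chrom for g in self.genes}


_STOPS = ("TAA", "TAG", "TGA")
_BASE_P = np.array([0.27, 0.23, 0.23, 0.27])


def _random_seq(rng, n: int) -> str:
    return "".join(codons.BASES[i] for i in rng.choice(4, size=n, p=_BASE_P))


def _random_cds(rng, n_codons: int) -> str:
    """ATG + (n_codons-1) random sense codons + one stop codon."""
    body = []
    while len(body) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in codons.STOP_CODONS:
            body.append(c)
    return "ATG" + "".join(body) + _STOPS[rng.integers(3)]


def build_reference(config: SimConfig) -> ReferenceBundle:
    """Generate the reference annotation bundle deterministically from the
    config seed. Raises a sizing error naming any chromosome too short to
    host its genes."""
    rng = _stage_rng(config.seed, 0)
    genes, cds, cdna, u5s, u3s = [], {}, {}, {}, {}
    gid = 0
    chroms = [(c.name, c.length) for c in config.chromosome_plan]
    for spec in config.chromosome_plan:
        models = []
        spans = []
        for _ in range(spec.n_genes):
            gid += 1
            gene_id = f"g{gid:04d}"
            seq = _random_cds(rng, config.codons_per_gene)
            clen = len(seq)  # includes the terminal stop codon
            n_introns = int(rng.integers(1, 4))
            intron_lens = [int(rng.integers(200, 601)) for _ in range(n_introns)]
            lo, hi = config.utr5_len + 1, config.utr5_len + clen - 1
            pts = sorted(int(p) for p in rng.choice(
                np.arange(lo, hi), size=n_introns, replace=False))
            strand = "+" if rng.random() < 0.5 else "-"
            models.append((gene_id, seq, strand, pts, intron_lens))
            spans.append(config.utr5_len + clen + config.utr3_len + sum(intron_lens))
        total = sum(spans)
        gap = (spec.length - total) // (spec.n_genes + 1) if spec.n_genes else 0
        if spec.n_genes and gap < 200:
            raise ValueError(
                f"chromosome {spec.name} too short ({spec.length} bp) for "
                f"{spec.n_genes} genes spanning {total} bp")
        pos = gap
        for (gene_id, seq, strand, pts, intron_lens), span in zip(models, spans):
            model = _build_gene_model(
                gene_id, spec.name, strand, pos, config.utr5_len,
                len(seq), config.utr3_len, pts, intron_lens)
            genes.append(model)
            utr5 = _random_seq(rng, config.utr5_len)
            utr3 = _random_seq(rng, config.utr3_len)
            cds[gene_id] = seq
            u5s[gene_id], u3s[gene_id] = utr5, utr3
            cdna[gene_id] = utr5 + seq + utr3
            pos += span + gap
    return ReferenceBundle(chroms, genes, cds, cdna, u5s, u3s)


# ---------------------------------------------------------------------------
# ortholog evolution

@dataclass
class GeneTruth:
    gene_id: str
    omega: float  # gene omega including its chromosome-class multiplier
    branch_omegas: dict[str, float]
    sequences: dict[str, str]  # evolved CDS incl. terminal stop, per taxon
    events: dict[str, tuple[int, int]]  # (synonymous, nonsynonymous) per taxon


@dataclass
class OrthologTruth:
    species: tuple[str, str, str]
    pi: np.ndarray  # F3x4 frequencies used by the generator
    genes: dict[str, GeneTruth]

    def sequence(self, species: str, gene_id: str) -> str:
        return self.genes[gene_id].sequences[species]


def evolve_orthologs(reference: ReferenceBundle, config: SimConfig) -> OrthologTruth:
    """Evolve each reference CDS along the three branches of the unrooted
    star tree (rooted at the internal node by convention). Substitutions are
    drawn from the GY94 process with the gene's omega times any per-branch
    multiplier; substitutions into stop codons never occur; the terminal
    stop codon is held fixed."""
    rng = _stage_rng(config.seed, 1)
    pi = codons.f3x4(reference.cds_sequences[g.gene_id][:-3] for g in reference.genes)
    chrom_mult = {c.name: c.omega_multiplier for c in config.chromosome_plan}
    genes: dict[str, GeneTruth] = {}
    q_cache: dict[float, np.ndarray] = {}

    def q_for(om: float) -> np.ndarray:
        key = round(om, 12)
        if key not in q_cache:
            q_cache[key], _ = codons.build_q(config.kappa, om, pi)
        return q_cache[key]

    for model in reference.genes:
        gid = model.gene_id
        seq = reference.cds_sequences[gid]
        states = codons.codons_to_indices(seq[:-3])
        stop = seq[-3:]
        if config.omega_fixed is not None:
            base = config.omega_fixed
        else:
            base = rng.gamma(config.omega_shape,
                             config.omega_mean / config.omega_shape)
        omega_g = base * chrom_mult[model.chrom]
        mults = config.branch_multipliers.get(gid, {})
        seqs, events, branch_om = {}, {}, {}
        for sp in config.species:
            om = omega_g * float(mults.get(sp, 1.0))
            branch_om[sp] = om
            new, n_syn, n_non = codons.evolve_codons(
                states, config.branch_length(sp), q_for(om), rng)
            seqs[sp] = codons.indices_to_codons(new) + stop
            events[sp] = (n_syn, n_non)
        genes[gid] = GeneTruth(gid, omega_g, branch_om, seqs, events)
    return OrthologTruth(config.species, pi, genes)


# ---------------------------------------------------------------------------
# diploid individual, fragments and reads

@dataclass
class DiploidTruth:
    """Planted heterozygous sites of the focal individual, per gene, in
    spliced-transcript coordinates, plus both haplotype cDNAs."""
    species: str
    sites: dict[str, list[tuple[int, str, str]]]  # gene -> [(pos, a1, a2)]
    haplotypes: dict[str, tuple[str, str]]

    @property
    def n_sites(self) -> int:
        return sum(len(v) for v in self.sites.values())


_OTHER = {b: [x for x in codons.BASES if x != b] for b in codons.BASES}
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _apply_sub_errors(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    out = list(seq)
    for pos in rng.choice(len(seq), size=n, replace=False):
        out[pos] = _OTHER[out[pos]][rng.integers(3)]
    return "".join(out)


def _apply_homopolymer_indels(seq: str, rate: float, rng) -> str:
    """454-style indel errors: each homopolymer run of length >= 3 gains or
    loses one base with the given probability."""
    if rate <= 0:
        return seq
    out = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run = seq[i:j]
        if j - i >= 3 and rng.random() < rate:
            run = run + seq[i] if rng.random() < 0.5 else run[:-1]
        out.append(run)
        i = j
    return "".join(out)


def _sample_pieces(hap_seqs, coverage, mean_len, sd_len, min_len,
                   sub_rate, indel_rate, rng):
    """Draw Poisson-coverage pieces (fragments or reads) from haplotype
    sequences; returns [(hap_index, start, strand, seq)]."""
    L = len(hap_seqs[0])
    n = rng.poisson(coverage * L / mean_len)
    pieces = []
    for _ in range(n):
        length = int(np.clip(round(rng.normal(mean_len, sd_len)), min_len, L))
        start = int(rng.integers(0, L - length + 1))
        hap = int(rng.integers(len(hap_seqs)))
        seq = hap_seqs[hap][start:start + length]
        seq = _apply_sub_errors(seq, sub_rate, rng)
        seq = _apply_homopolymer_indels(seq, indel_rate, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        pieces.append((hap, start, strand, seq))
    return pieces


def make_diploid_and_reads(reference: ReferenceBundle, truth: OrthologTruth,
                           config: SimConfig):
    """Plant heterozygous sites in the focal individual and sequence it.

    Returns (DiploidTruth, fragments, reads) where fragments maps species ->
    [(id, seq)] (focal-species isotig-like fragments from one haplotype,
    plus outgroup fragments), and reads is [(id, seq)] for the focal
    individual drawn evenly from both haplotypes with 454-style errors.
    Fragment/read ids encode their true origin gene for the truth tables.
    """
    rng = _stage_rng(config.seed, 2)
    focal = config.ingroup_a
    het_by_chrom = {c.name: c.het_rate for c in config.chromosome_plan}
    for c in config.chromosome_plan:
        if c.het_rate > 0.1:
            raise ValueError(
                f"chromosome {c.name}: het_rate {c.het_rate}/bp exceeds 0.1 "
                "(biologically absurd density)")

    sites: dict[str, list[tuple[int, str, str]]] = {}
    haplotypes: dict[str, tuple[str, str]] = {}
    fragments: dict[str, list[tuple[str, str]]] = {focal: [], config.outgroup: []}
    reads: list[tuple[str, str]] = []

    for model in reference.genes:
        gid = model.gene_id
        base = (reference.utr5[gid] + truth.sequence(focal, gid)
                + reference.utr3[gid])
        L = len(base)
        n_sites = rng.binomial(L, het_by_chrom[model.chrom])
        positions = sorted(int(p) for p in rng.choice(L, size=n_sites, replace=False))
        h1, h2 = list(base), list(base)
        gene_sites = []
        for pos in positions:
            ref_b = base[pos]
            alt_b = _OTHER[ref_b][rng.integers(3)]
            if rng.random() < 0.5:
                h1[pos] = alt_b
            else:
                h2[pos] = alt_b
            gene_sites.append((pos, *sorted((ref_b, alt_b))))
        h1s, h2s = "".join(h1), "".join(h2)
        sites[gid] = gene_sites
        haplotypes[gid] = (h1s, h2s)

        for k, (hap, start, strand, seq) in enumerate(_sample_pieces(
                (h1s,), config.fragment_coverage, config.fragment_mean_len,
                config.fragment_len_sd, 150, config.fragment_error_sub,
                config.fragment_error_indel, rng)):
            fragments[focal].append(
                (f"{focal}|{gid}|frag{k:04d}|{start}|{strand}", seq))
        out_cdna = (reference.utr5[gid] + truth.sequence(config.outgroup, gid)
                    + reference.utr3[gid])
        for k, (hap, start, strand, seq) in enumerate(_sample_pieces(
                (out_cdna,), config.fragment_coverage,
                config.fragment_mean_len, config.fragment_len_sd, 150,
                config.fragment_error_sub, config.fragment_error_indel, rng)):
            fragments[config.outgroup].append(
                (f"{config.outgroup}|{gid}|frag{k:04d}|{start}|{strand}", seq))
        for k, (hap, start, strand, seq) in enumerate(_sample_pieces(
                (h1s, h2s), config.read_coverage, config.read_mean_len,
                config.read_len_sd, 40, config.read_error_sub,
                config.read_error_homopolymer_indel, rng)):
            reads.append((f"{focal}|{gid}|read{k:05d}|h{hap + 1}|{start}|{strand}", seq))

    return DiploidTruth(focal, sites, haplotypes), fragments, reads


# ---------------------------------------------------------------------------
# desk-scale alignment simulators (truth in, estimator out)

def _stationary_pi() -> np.ndarray:
    counts = np.tile(_BASE_P, (3, 1))
    return codons.f3x4_from_counts(counts)


def _draw_omegas(rng, n, omega_mean, omega_shape, omega_fixed):
    if omega_fixed is not None:
        return np.full(n, float(omega_fixed))
    return rng.gamma(omega_shape, omega_mean / omega_shape, size=n)


def simulate_pair_alignments(n_genes: int, n_codons: int, t_total: float,
                             kappa: float = 2.0, omega_mean: float = 0.13,
                             omega_shape: float = 2.0,
                             omega_fixed: Optional[float] = None,
                             seed: int = 0,
                             species: tuple[str, str] = ("a", "b")):
    """Two-taxon ortholog alignments evolved from a common ancestor under
    GY94 (each branch t_total/2). Returns (alignments, true_omegas)."""
    from .codonalign import CodonAlignment

    rng = np.random.default_rng(seed)
    pi = _stationary_pi()
    omegas = _draw_omegas(rng, n_genes, omega_mean, omega_shape, omega_fixed)
    alignments = []
    for g, om in enumerate(omegas):
        q, _ = codons.build_q(kappa, float(om), pi)
        anc = rng.choice(codons.N_SENSE, size=n_codons, p=pi)
        a, _, _ = codons.evolve_codons(anc, t_total / 2.0, q, rng)
        b, _, _ = codons.evolve_codons(anc, t_total / 2.0, q, rng)
        rows = {species[0]: codons.indices_to_codons(a),
                species[1]: codons.indices_to_codons(b)}
        alignments.append(CodonAlignment(f"g{g + 1:04d}", species, rows,
                                         tuple(range(n_codons))))
    return alignments, omegas.tolist()


def simulate_trio_alignments(n_genes: int, n_codons: int,
                             t_a: float = 0.15, t_b: float = 0.15,
                             t_out: float = 0.5, kappa: float = 2.0,
                             omega_mean: float = 0.13,
                             omega_shape: float = 2.0,
                             omega_fixed: Optional[float] = None,
                             focal_multiplier: float = 1.0,
                             seed: int = 0,
                             species: tuple[str, str, str] = ("a", "b", "out")):
    """Three-taxon star-tree alignments; the first species' branch omega is
    multiplied by focal_multiplier. Returns (alignments, true_omegas)."""
    from .codonalign import CodonAlignment

    rng = np.random.default_rng(seed)
    pi = _stationary_pi()
    omegas = _draw_omegas(rng, n_genes, omega_mean, omega_shape, omega_fixed)
    alignments = []
    for g, om in enumerate(omegas):
        q_bg, _ = codons.build_q(kappa, float(om), pi)
        q_focal, _ = codons.build_q(kappa, float(om) * focal_multiplier, pi)
        anc = rng.choice(codons.N_SENSE, size=n_codons, p=pi)
        leaves = {}
        for sp, t, q in zip(species, (t_a, t_b, t_out),
                            (q_focal, q_bg, q_bg)):
            s, _, _ = codons.evolve_codons(anc, t, q, rng)
            leaves[sp] = codons.indices_to_codons(s)
        alignments.append(CodonAlignment(f"g{g + 1:04d}", species, leaves,
                                         tuple(range(n_codons))))
    return alignments, omegas.tolist()


# ---------------------------------------------------------------------------
# synthetic functional term map

def make_term_map(reference: ReferenceBundle, config: SimConfig) -> list[tuple[str, str, str]]:
    """Random flat gene->term annotation (synthetic stand-in for a GO-style
    term map): rows of (gene_id, term_id, description)."""
    rng = _stage_rng(config.seed, 3)
    gene_ids = [g.gene_id for g in reference.genes]
    rows = []
    for t in range(1, config.n_terms + 1):
        size = int(rng.integers(2, max(3, len(gene_ids) // 3)))
        members = rng.choice(len(gene_ids), size=min(size, len(gene_ids)),
                             replace=False)
        term = f"T{t:03d}"
        for m in sorted(members):
            rows.append((gene_ids[m], term, f"synthetic term {t}"))
    rows.sort()
    return rows


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["chromosome_plan"] = [asdict(c) for c in config.chromosome_plan]
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "chromosome_plan" in d and d["chromosome_plan"] is not None:
        d["chromosome_plan"] = tuple(
            ChromosomeSpec(**c) if isinstance(c, dict) else ChromosomeSpec(*c)
            for c in d["chromosome_plan"])
    else:
        d.pop("chromosome_plan", None)
    return SimConfig(**d)
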