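# waxbill

Comparative molecular evolution of songbird brain transcriptomes, packaged
as a tested, reusable Python library with a thin command-line pipeline.

The scientific setting is the transcriptome-era comparison of closely
related passerines: a de-novo-assembled brain transcriptome of a focal
estrildid finch (violet-eared-waxbill-like) is matched against the
annotated gene set of a reference species (zebra-finch-like) and a second
assembled transcriptome of an outgroup songbird (great-tit-like). From
fragmented, error-bearing transcripts the package reconstructs per-gene
codon alignments, measures protein evolutionary rates, discovers
within-individual heterozygous SNPs, and asks the downstream questions:
which genes evolve fast, which lineages differ, how do the Z chromosome
and the 4A microchromosome deviate, and which functional categories are
over- or under-represented. It is aimed at molecular evolution researchers
who want each analysis step available as an importable, seedable function
rather than a chain of external tools.

## What it computes

* **Ortholog matching** (`waxbill.orthomatch`): k-mer-seeded local
  alignment with Karlin–Altschul statistics. The bit score is
  S' = (λS − ln K)/ln 2 and the e-value E = K·m·n·e^(−λS); fragments pass
  with E ≤ 10⁻⁵ and aligned length ≥ 300 bp, best hit per fragment.
* **Codon alignment** (`waxbill.codonalign`): fragments are aligned to the
  annotated reference transcript (semiglobal affine DP), insertions that
  would break the annotated reading frame are discarded as sequencing
  errors, fragments are collapsed to a majority-rule per-species consensus,
  and codon columns with gaps, ambiguities or stops are removed
  (alignments < 300 bp are rejected).
* **Rates and tests** (`waxbill.ratesel`):
  * NG86 counting (pathway-averaged S/N sites and differences,
    Jukes–Cantor corrected) — also the independent cross-check oracle;
  * pairwise ML ω = dN/dS under GY94 with F3x4 codon frequencies
    (parameters t, κ, ω);
  * 3-taxon branch models: the null shares one ω across the star tree, the
    alternative frees the focal branch; 2ΔlnL is referred to χ²(1) and
    q-values control the FDR (Benjamini–Hochberg or Storey);
  * genome-wide ω by bootstrap concatenation — 1000 replicates of 150
    randomly chosen alignments by default, ML re-estimation per replicate.
* **SNP discovery** (`waxbill.snpscan`): DIAL-style depth-based
  heterozygote calling from single-individual reads (reads < 100 bp or
  ≥ 60% one nucleotide are filtered; a site needs two alleles at depth ≥ 2
  with read ends and indel-adjacent positions masked), plus lifting onto
  the reference genome, compartment classification
  (CDS > UTR > intron > 1-kb flank > intergenic) and per-chromosome
  density with a linear count-vs-size fit.
* **Enrichment and summaries** (`waxbill.enrichstats`): ω > 1 / ω > 0.8 /
  top-decile gene lists, Fisher-exact and hypergeometric term
  over/under-representation with BH adjustment, chromosome-level ANOVA and
  one-tailed Welch contrasts, cross-depth ω correlation, N50 and length
  statistics.
* **Synthetic studies** (`waxbill.synthgen`): a generator that emulates
  the whole design — reference annotation (GFF3 + FASTA), three lineages
  evolved under GY94 with per-gene Gamma ω (mean 0.13), fast-Z (ω ×1.5,
  heterozygosity ×0.3) and slow-4A (ω ×0.6, heterozygosity ×5) chromosome
  classes, a diploid focal individual, and 454-like fragments and reads —
  with truth tables for every stage.

## Worked example

`examples/03_rates_and_branch_tests.py` simulates alignments with known ω
and runs the estimators:

```
g0001: NG86 omega=0.167 (S=574, N=1826) | ML omega=0.209, t=0.322, kappa=2.34, lnL=-4181.2
branch LRT: 2*dlnL=63.11, p=1.96e-15, accelerated (focal omega 1.18 vs background 0.16)
bootstrap genome-wide omega: 0.105 (sd 0.010; true gene mean 0.118)
```

The first line shows counting and ML agreeing on strong purifying
selection (ω ≈ 0.2 against a simulated 0.2); the branch test detects a
5-fold focal acceleration at p ≈ 10⁻¹⁵; the bootstrap line is the
genome-wide ω with its replicate spread. The other example scripts cover
simulation (`01`), ortholog matching (`02`), SNP discovery (`04`) and the
full pipeline (`05`), each printing the numbers it computes and what they
mean.

The same thing from the shell:

```bash
waxbill run-all --seed 17 --out-dir runs/demo   # all stages
waxbill simulate --seed 17 --out-dir runs/demo  # or stage by stage
```

A run directory contains `sim/` (FASTA, GFF3, truth tables), `match/`,
`align/`, `rates/`, `snps/` (VCF, density), `enrich/`, a `report.json`
with nine result sections and a `manifest.json` with per-stage record
counts. Identical config and seed reproduce every file byte for byte.

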