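# Methods

This note documents the models and procedures implemented in `waxbill`,
the defaults and why they were chosen, the numerical choices, and what the
synthetic generator does and does not emulate.

## The codon substitution model

All rate estimation and simulation uses the Goldman–Yang (GY94) codon
model over the 61 sense codons of the standard code. The instantaneous
rate from codon *i* to *j* is zero unless the codons differ at exactly one
position, and otherwise

> q_ij = π_j · κ^[transition] · ω^[nonsynonymous]

with π the F3x4 codon frequencies (products of position-specific
nucleotide frequencies, renormalized over sense codons), κ the
transition/transversion ratio and ω = dN/dS. Substitutions into stop
codons have rate zero, so neither the simulator nor the likelihood ever
visits a stop. The matrix is scaled so that one unit of branch length is
one expected substitution *per codon*. The model is time-reversible, so
transition probabilities P(t) = e^{Qt} are computed through a symmetric
eigendecomposition (π^{1/2}-similarity transform followed by `eigh`),
which is exact, stable and fast enough to sit inside an optimizer loop.
F3x4 frequencies are always estimated from the alignment being analyzed
(concatenated, for bootstrap replicates), matching common likelihood
practice; a 10⁻⁸ floor on position-specific base frequencies guards
degenerate small inputs.

dN and dS are derived from the MLE as t·ρ_N / (3·ρ_N^{ω=1}) and the
synonymous analogue, where ρ_N is the nonsynonymous fraction of the total
rate; with this convention dN/dS equals ω̂ identically.

### Pairwise estimation

`ml_pairwise` maximizes Σ n_ij log(π_i P_ij(t)) over (t, κ, ω) with
bounds t ∈ [10⁻⁶, 50], κ ∈ [0.1, 99], ω ∈ [10⁻⁴, 99], using bounded
L-BFGS-B from three starts (the NG86 counting estimate, ω = 0.1, ω = 1.0);
ties on likelihood keep the smallest ω for determinism, and estimates
within 10⁻³ of a bound are flagged. Alignments shorter than 30 codons are
refused as insufficient data. The NG86 counting estimator (pathway-averaged
site and difference counts with Jukes–Cantor correction; mutations to stop
codons count as nonsynonymous so sites sum to three per codon, and
difference pathways through stops are excluded with a fallback to all
pathways when every route is blocked) serves both as the optimizer's
initializer and as an independent cross-check in the test suite.

### Branch tests

The three-taxon tree is an unrooted star with one internal node; root
placement is unidentifiable with three leaves, so the generator and the
likelihood both place the root at the internal node. The null model fits
(t₁, t₂, t₃, κ, ω); the alternative adds one free ω on the focal branch.
The likelihood sums over the internal state by pruning, with site
patterns collapsed. Branch lengths are re-optimized under both models.
The alternative optimization starts at the null optimum (with the focal ω
initialized at the shared ω̂), which guarantees the nesting inequality
lnL_alt ≥ lnL_null by construction. p-values use the χ²(1) upper tail,
computed as erfc(√(LRT/2)); the direction (accelerated/decelerated) is
read off the fitted focal versus background ω.

### Genome-wide ω by bootstrap concatenation

Each replicate draws `genes_per_rep` alignments (default 150, 1000
replicates) without replacement, concatenates them (implemented as summing
codon-pair count matrices and F3x4 base counts, which is exact for this
likelihood) and re-fits (t, κ, ω). One property worth knowing: under a
spread of per-gene ω the concatenated estimate converges to a flux-ratio
functional that sits somewhat below the arithmetic gene-mean ω (about 0.116
versus a gene mean of 0.13 under the default Gamma law) — a real property
of concatenation estimators, not an implementation artifact; the estimator
is unbiased when ω is homogeneous (the test suite checks both).

### Multiple testing

Benjamini–Hochberg step-up q-values, with a Storey variant that rescales
by π₀ = min(1, #{p > 0.5}/(0.5·m)). Storey is the pipeline default for
branch tests; BH is used across enrichment terms.

## Ortholog matching

The search is blastn-like: an 11-mer index of the reference cDNA set
(N-containing words skipped), query seeds collected on both strands,
seeds grouped per reference sequence into a diagonal band, and a local
affine-gap Smith–Waterman extension over the banded window. Scoring
defaults are +1/−2 with gap open 5 / extend 2, a regime suited to the
90–98% identity of recently diverged birds. λ is solved from
Σ p_i p_j e^{λ s_ij} = 1 under the database base composition; K uses the
standard lattice series approximation for ungapped scores, and the gapped
search reuses the ungapped pair. The resulting K agrees with published
ungapped values to within a factor of ~1.5, which is ample for the
e-value's role here: a pass/fail filter at 10⁻⁵ together with the 300-bp
minimum hit length, followed by a best-e-value (then score, then gene id)
assignment rule. Exact gapped Karlin–Altschul statistics are deliberately
out of scope.

## Codon alignment from fragments

A trusted annotated reference frame makes multiple sequence alignment
unnecessary: each fragment is aligned pairwise to the reference transcript
by semiglobal affine DP (free end gaps on the reference side; gap of
length L costs open + L·ext; tie-breaks prefer match > mismatch >
gap-in-fragment > gap-in-reference deterministically). Columns where the
fragment has a base but the reference has a gap are insertions that would
disrupt the annotated frame and are discarded as sequencing errors —
454 homopolymer artifacts in practice. Per species, overlapping fragments
are collapsed by majority rule on the reference grid (ties resolved by the
best-scoring fragment, then alphabetically — ambiguity codes are never
emitted, since downstream filtering would drop those columns anyway).
Stacked consensuses are trimmed to the CDS, the terminal stop codon is
removed, and every codon column containing a gap, non-ACGT character or
stop in any row is deleted; genes below 300 bp after filtering are
rejected. Pairwise (two-species) alignments therefore always retain at
least as many genes as the three-species intersection.

## Heterozygous SNP discovery

The caller emulates reference-free single-individual SNP discovery: reads
are filtered (length ≥ 100 bp; no single nucleotide ≥ 60% of the read),
oriented and placed on the focal species' own per-gene consensus by shared
15-mers, aligned with the same affine DP, and piled up. The first and last
5 aligned bases of each read and positions within 3 bp of an alignment gap
are masked. A site is called heterozygous when exactly two alleles each
reach depth 2 and total depth is ≥ 4; sites with three or more alleles at
depth are skipped as error-rich. Only within-individual heterozygosity is
discoverable this way, and the depth thresholds bias discovery toward
high-frequency polymorphisms — an inherent property of the design, not a
defect. Calls are lifted to genome coordinates through the gene models
(conserved synteny assumed, alleles kept in transcript orientation) and
classified with precedence CDS > UTR5/UTR3 > intron > 1-kb strand-aware
flank > intergenic. A telomere compartment is not modeled (the annotation
carries no such features); such positions fall into intergenic.

## Synthetic data: what it emulates, what it does not

The generator reproduces the study design at desk scale: an annotated
reference (multi-exon genes with UTRs and introns on named chromosomes),
three lineages diverged on a star tree, a diploid focal individual,
transcript fragments ("isotigs") and 454-like reads, plus a flat synthetic
gene→term map. Defaults, chosen once as field-realistic values:

| parameter | default | rationale |
|---|---|---|
| per-gene ω | Gamma(shape 2, mean 0.13) | genome-wide ω of these finches; shape 2 gives a realistic right-skewed spread |
| κ | 2.0 | typical vertebrate transition bias |
| ingroup branches | 0.15 + 0.15 subs/codon | ~10–15 Myr estrildid split (pairwise 0.3) |
| outgroup branch | 0.5 | deeper songbird divergence |
| Z class | ω ×1.5, het ×0.3 | fast-Z and reduced diploid polymorphism, desk-scale recoverable |
| 4A class | ω ×0.6, het ×5 | the inverse microchromosome pattern |
| autosomal het | 0.002 / bp | songbird transcriptome-scale heterozygosity |
| fragments | 600 ± 100 bp, 2.5×, near error-free | nebulized 400–800 bp cDNA, assembled consensus quality |
| reads | 350 ± 50 bp, 15×, sub 10⁻³, homopolymer indel 4×10⁻³ | 454 length and error profile (indel-dominated) |

Simulation is an exact stochastic (Gillespie) realization of the same
GY94 matrix the estimators fit — deliberate model consistency, so
recovery tests probe the estimators rather than model mismatch. Not
emulated: indels in the true ortholog evolution (frame-disrupting
insertions arise only as sequencing errors), UTR/noncoding divergence
(UTRs are shared across taxa), alternative splicing, paralogy, intergenic
transcription, base-quality scores (the caller is depth-based; FASTQ
qualities are accepted and ignored), and assembly itself (fragments stand
in for assembled isotigs). Passing tests therefore demonstrate correctness
of the analysis machinery under a faithful generative model, not
robustness to assembly artifacts or paralogous confusion in real data.

## Pipeline, determinism and problem sizes

Every stage reads and writes files in a run directory (GFF3 and VCF are
1-based on disk; everything in memory is 0-based half-open), so stages can
be re-run independently. All randomness derives from the single config
seed through named SeedSequence spawns; identical config and seed
reproduce every output byte for byte. The test suite runs the full system
at reduced problem sizes chosen to keep the default run quick — e.g.
300 genes × 500 codons for rate-recovery checks, 200 bootstrap replicates
of 50 alignments for the genome-wide ω check, 20-seed repetitions for the
chromosome-pattern checks, and a 30-gene end-to-end determinism run —
sizes at which the expected effects are comfortably resolvable.

## Known limitations

* Branch-site and site-heterogeneous codon models are out of scope; ω is
  constant across sites within a gene.
* Gapped local-alignment statistics are approximated by the ungapped
  Karlin–Altschul pair.
* The consensus step resolves conflicting fragments (possible paralogs or
  isoforms) by majority rule; no paralog disambiguation beyond best-hit
  assignment is attempted.
* The SNP caller reports no genotype likelihoods; depth thresholds are the
  only evidence model.
* With three taxa the root is unidentifiable and branch lengths near zero
  can sit on the optimizer bound; such fits are flagged rather than
  polished.
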