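"""Rate estimation: NG86 against an independent enumeration oracle, GY94
ML behaviour, branch-model LRTs, q-values and the bootstrap estimator."""
import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from waxbill import codons, ratesel, synthgen
from waxbill.codonalign import CodonAlignment


# ---------------------------------------------------------------------------
# independent NG86 oracle (Biopython translation + permutation enumeration)

STOPS = {"TAA", "TAG", "TGA"}


def oracle_sites(codon):
    syn = 0.0
    aa = str(Seq(codon).translate())
    for pos, base in enumerate(codon):
        for alt in "ACGT":
            if alt == base:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if mutant not in STOPS and str(Seq(mutant).translate()) == aa:
                syn += 1 / 3
    return syn


def oracle_differences(c1, c2):
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    all_paths, open_paths = [], []
    for order in itertools.permutations(diff_pos):
        cur, steps, blocked = c1, [], False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            steps.append((cur, nxt))
            if nxt in STOPS and nxt != c2:
                blocked = True
            cur = nxt
        all_paths.append(steps)
        if not blocked:
            open_paths.append(steps)
    usable = open_paths or all_paths
    syn = non = 0.0
    for steps in usable:
        for a, b in steps:
            if (a not in STOPS and b not in STOPS
                    and str(Seq(a).translate()) == str(Seq(b).translate())):
                syn += 1
            else:
                non += 1
    return syn / len(usable), non / len(usable)


def test_ng86_site_counts_match_oracle_for_all_codons():
    for i, codon in enumerate(codons.SENSE_CODONS):
        assert ratesel.SYN_SITES[i] == pytest.approx(oracle_sites(codon),
                                                     abs=1e-9)


def test_ng86_differences_match_oracle_for_all_pairs():
    for i, c1 in enumerate(codons.SENSE_CODONS):
        for j, c2 in enumerate(codons.SENSE_CODONS):
            sd, nd = oracle_differences(c1, c2)
            assert ratesel.PAIR_SD[i, j] == pytest.approx(sd, abs=1e-9), (c1, c2)
            assert ratesel.PAIR_ND[i, j] == pytest.approx(nd, abs=1e-9), (c1, c2)


@pytest.mark.parametrize("pair, sd, nd", [
    (("TTTGAT", "TTCGAT"), 1.0, 0.0),   # Phe TTT->TTC synonymous
    (("ATGAAA", "ATGAGA"), 0.0, 1.0),   # Lys->Arg nonsynonymous
])
def test_ng86_single_difference_examples(pair, sd, nd):
    ng = ratesel.ng86(pair)
    assert ng.Sd == pytest.approx(sd)
    assert ng.Nd == pytest.approx(nd)
    assert ng.S + ng.N == pytest.approx(3 * 2)


def test_ng86_identical_sequences():
    ng = ratesel.ng86(("ATGAAACCC", "ATGAAACCC"))
    assert ng.Sd == ng.Nd == 0
    assert ng.dS == ng.dN == 0.0 or ng.dS_zero
    assert ng.omega is None
    assert ng.dS_zero


def test_ng86_rejects_unequal_lengths():
    with pytest.raises(ValueError):
        ratesel.ng86(("ATGAAA", "ATG"))


# ---------------------------------------------------------------------------
# GY94 pairwise ML

def test_ml_identical_rows_hits_zero_divergence_boundary(rng):
    seq = codons.indices_to_codons(rng.choice(61, size=200))
    r = ratesel.ml_pairwise((seq, seq))
    assert r.t <= 1e-4
    assert r.boundary
    pi = codons.f3x4([seq, seq])
    expected = sum(math.log(pi[i]) for i in codons.codons_to_indices(seq))
    assert r.lnl == pytest.approx(expected, abs=0.01)


def test_ml_recovers_simulated_parameters():
    alns, _ = synthgen.simulate_pair_alignments(
        n_genes=1, n_codons=1000, t_total=0.3, omega_fixed=0.2, seed=5)
    r = ratesel.ml_pairwise(alns[0])
    assert 0.12 <= r.omega <= 0.30
    assert 0.2 <= r.t <= 0.45
    assert 1.2 <= r.kappa <= 3.2


def test_ml_and_ng86_concord_on_moderate_divergence():
    alns, _ = synthgen.simulate_pair_alignments(
        n_genes=5, n_codons=800, t_total=0.3, omega_fixed=0.4, seed=11)
    for aln in alns:
        ml = ratesel.ml_pairwise(aln)
        ng = ratesel.ng86(aln)
        assert ml.omega == pytest.approx(ng.omega, rel=0.25)


def test_ml_refuses_tiny_alignments():
    with pytest.raises(ValueError, match="insufficient"):
        ratesel.ml_pairwise(("ATGAAA", "ATGAAA"))


def test_omega_equals_dn_over_ds():
    alns, _ = synthgen.simulate_pair_alignments(
        n_genes=1, n_codons=500, t_total=0.3, omega_fixed=0.3, seed=2)
    r = ratesel.ml_pairwise(alns[0])
    assert r.omega == pytest.approx(r.dN / r.dS, rel=1e-6)


# ---------------------------------------------------------------------------
# branch tests

def test_branch_test_nesting_and_validation():
    alns, _ = synthgen.simulate_trio_alignments(
        n_genes=3, n_codons=200, omega_fixed=0.2, seed=8)
    for aln in alns:
        res = ratesel.branch_test(aln, "a")
        assert res.lnl_alt >= res.lnl_null - 1e-6
        assert 0.0 <= res.p <= 1.0
        assert res.df == 1
    with pytest.raises(ValueError, match="focal"):
        ratesel.branch_test(alns[0], "nosuch")


def test_branch_test_detects_strong_acceleration():
    alns, _ = synthgen.simulate_trio_alignments(
        n_genes=1, n_codons=1000, omega_fixed=0.15, focal_multiplier=5.0,
        seed=9)
    res = ratesel.branch_test(alns[0], "a")
    assert res.p < 0.05
    assert res.direction == "accelerated"
    assert res.omega_focal > res.omega_background


# ---------------------------------------------------------------------------
# multiple testing

def test_bh_worked_example():
    assert ratesel.adjust_fdr([0.01, 0.02, 0.03, 0.04]) == \
        pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_edge_cases():
    assert ratesel.adjust_fdr([0.37]) == [0.37]
    assert ratesel.adjust_fdr([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]
    with pytest.raises(ValueError):
        ratesel.adjust_fdr([0.5, 1.5])


def test_bh_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests
    p = rng.random(200)
    ours = ratesel.adjust_fdr(p.tolist(), "bh")
    theirs = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(ours, theirs)


def test_storey_scales_by_pi0(rng):
    p = np.concatenate([rng.random(50) * 0.05, rng.random(150)])
    bh = np.array(ratesel.adjust_fdr(p.tolist(), "bh"))
    st = np.array(ratesel.adjust_fdr(p.tolist(), "storey"))
    pi0 = min(1.0, (p > 0.5).sum() / (0.5 * len(p)))
    assert np.allclose(st, np.minimum(bh * pi0, 1.0))
    assert np.all(st <= bh + 1e-12)


def test_bh_monotone_in_rank(rng):
    p = rng.random(100)
    q = np.array(ratesel.adjust_fdr(p.tolist(), "bh"))
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all((q >= 0) & (q <= 1))


# ---------------------------------------------------------------------------
# bootstrap genome-wide omega

def test_bootstrap_degenerate_pool_has_zero_sd():
    alns, _ = synthgen.simulate_pair_alignments(
        n_genes=1, n_codons=400, t_total=0.3, omega_fixed=0.2, seed=4)
    s = ratesel.bootstrap_genome_omega(alns, n_reps=5, genes_per_rep=1, seed=1)
    assert s.sd == pytest.approx(0.0, abs=1e-12)
    assert len(set(s.omegas)) == 1


def test_bootstrap_deterministic_given_seed():
    alns, _ = synthgen.simulate_pair_alignments(
        n_genes=12, n_codons=300, t_total=0.3, seed=6)
    s1 = ratesel.bootstrap_genome_omega(alns, n_reps=8, genes_per_rep=5, seed=7)
    s2 = ratesel.bootstrap_genome_omega(alns, n_reps=8, genes_per_rep=5, seed=7)
    assert s1.omegas == s2.omegas
    assert s1.mean == s2.mean


def test_bootstrap_pool_too_small():
    alns, _ = synthgen.simulate_pair_alignments(
        n_genes=3, n_codons=300, t_total=0.3, seed=6)
    with pytest.raises(ValueError, match="genes_per_rep"):
        ratesel.bootstrap_genome_omega(alns, n_reps=2, genes_per_rep=5)
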