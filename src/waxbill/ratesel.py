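"""Molecular-evolution rate estimation.

* ``ng86``: Nei-Gojobori counting of synonymous/nonsynonymous sites and
  differences with pathway averaging and Jukes-Cantor correction (also the
  module's fast initializer and independent cross-check for the ML path).
* ``ml_pairwise``: maximum-likelihood pairwise dN/dS under GY94 with F3x4
  codon frequencies estimated from the alignment at hand (codeml-style
  pairwise estimator).
* ``branch_test``: 3-taxon branch-model likelihood-ratio test on the
  unrooted star tree: null has one omega shared by all branches, the
  alternative gives the focal branch its own omega; 2*dlnL is referred to
  chi-square with one degree of freedom.
* ``adjust_fdr``: Benjamini-Hochberg and Storey q-values.
* ``bootstrap_genome_omega``: genome-wide omega by concatenating randomly
  chosen alignments per bootstrap replicate (default 1000 reps x 150
  alignments) and re-estimating omega on each concatenation.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from . import codons
from .codonalign import CodonAlignment

_BOUNDS_T = (1e-6, 50.0)
_BOUNDS_K = (0.1, 99.0)
_BOUNDS_W = (1e-4, 99.0)


# ---------------------------------------------------------------------------
# NG86 counting

def _syn_site_fractions() -> np.ndarray:
    """Synonymous site count per codon (out of 3): per position, the
    fraction of the 3 alternative bases that give a synonymous change.
    Changes to stop codons count as nonsynonymous (so sites sum to 3)."""
    out = np.zeros(codons.N_SENSE)
    for i, cod in enumerate(codons.SENSE_CODONS):
        syn = 0.0
        for pos in range(3):
            for b in codons.BASES:
                if b == cod[pos]:
                    continue
                alt = cod[:pos] + b + cod[pos + 1 :]
                if alt not in codons.STOP_CODONS and \
                        codons.AMINO_ACID[codons.CODON_INDEX[alt]] == codons.AMINO_ACID[i]:
                    syn += 1.0 / 3.0
        out[i] = syn
    return out


def _pathway_tables():
    """(61,61) expected synonymous / nonsynonymous differences per ordered
    codon pair, averaged over all minimal substitution pathways; pathways
    passing through a stop codon are excluded (with a fallback to all
    pathways, stop steps counted as nonsynonymous, if every path is
    blocked)."""
    sd = np.zeros((codons.N_SENSE, codons.N_SENSE))
    nd = np.zeros_like(sd)

    def aa(codon):
        return None if codon in codons.STOP_CODONS else \
            codons.AMINO_ACID[codons.CODON_INDEX[codon]]

    for i, ci in enumerate(codons.SENSE_CODONS):
        for j, cj in enumerate(codons.SENSE_CODONS):
            if i == j:
                continue
            diff = [p for p in range(3) if ci[p] != cj[p]]
            paths = []
            for order in itertools.permutations(diff):
                cur = ci
                steps = []
                blocked = False
                for p in order:
                    nxt = cur[:p] + cj[p] + cur[p + 1 :]
                    steps.append((cur, nxt))
                    if nxt in codons.STOP_CODONS and nxt != cj:
                        blocked = True
                    cur = nxt
                paths.append((blocked, steps))
            usable = [s for blocked, s in paths if not blocked]
            if not usable:
                usable = [s for _, s in paths]
            s_tot = n_tot = 0.0
            for steps in usable:
                for a, b in steps:
                    if aa(a) is not None and aa(a) == aa(b):
                        s_tot += 1
                    else:
                        n_tot += 1
            sd[i, j] = s_tot / len(usable)
            nd[i, j] = n_tot / len(usable)
    return sd, nd


SYN_SITES = _syn_site_fractions()
PAIR_SD, PAIR_ND = _pathway_tables()


@dataclass
class NgCounts:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: Optional[float]
    dN: Optional[float]
    omega: Optional[float]
    dS_zero: bool


def _jc(p: float) -> Optional[float]:
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _pair_rows(pair) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pair, CodonAlignment):
        if len(pair.species) != 2:
            raise ValueError("pairwise estimator needs a two-row alignment")
        a, b = (pair.rows[s] for s in pair.species)
    else:
        a, b = pair
    if len(a) != len(b):
        raise ValueError("unequal row lengths")
    return codons.codons_to_indices(a), codons.codons_to_indices(b)


def ng86_from_counts(counts: np.ndarray) -> NgCounts:
    """NG86 from a (61,61) codon-pair count matrix."""
    n_codons = counts.sum()
    if n_codons == 0:
        raise ValueError("empty alignment")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    S = 0.5 * (float(row @ SYN_SITES) + float(col @ SYN_SITES))
    N = 3.0 * n_codons - S
    Sd = float((counts * PAIR_SD).sum())
    Nd = float((counts * PAIR_ND).sum())
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jc(pS)
    dN = _jc(pN)
    dS_zero = Sd == 0 or dS is None
    omega = (dN / dS) if (dS not in (None, 0.0) and dN is not None) else None
    return NgCounts(S, N, Sd, Nd, pS, pN, dS, dN, omega, dS_zero)


def codon_pair_counts(pair) -> np.ndarray:
    ia, ib = _pair_rows(pair)
    counts = np.zeros((codons.N_SENSE, codons.N_SENSE))
    np.add.at(counts, (ia, ib), 1.0)
    return counts


def ng86(pair) -> NgCounts:
    """Nei-Gojobori counting estimate for a two-row codon alignment (a
    CodonAlignment or a pair of in-frame stop-free strings)."""
    return ng86_from_counts(codon_pair_counts(pair))


# ---------------------------------------------------------------------------
# GY94 pairwise ML

@dataclass
class RateResult:
    gene_id: str
    method: str  # "counting" | "ml"
    omega: Optional[float]
    dN: Optional[float]
    dS: Optional[float]
    t: Optional[float]
    kappa: Optional[float]
    lnl: Optional[float]
    dS_zero: bool = False
    boundary: bool = False


def _sparse_counts(counts: np.ndarray):
    ii, jj = np.nonzero(counts)
    return ii, jj, counts[ii, jj]


def _pair_lnl(ii, jj, nn, pi, t, kappa, omega):
    q, _ = codons.build_q(kappa, omega, pi)
    p = codons.SpectralQ(q, pi).transition(t)
    return float(nn @ np.log(pi[ii] * p[ii, jj]))


def _ng_t_init(ng: NgCounts, n_codons: float) -> float:
    dN = ng.dN if ng.dN is not None else ng.pN
    dS = ng.dS if ng.dS is not None else ng.pS
    t = (ng.S * dS + ng.N * dN) / n_codons
    return float(np.clip(t, 1e-4, 10.0))


def _ml_fit_counts(counts: np.ndarray, pi: np.ndarray,
                   ng: Optional[NgCounts] = None):
    """Maximize GY94 pairwise likelihood over (t, kappa, omega); three
    restarts (counting init, omega=0.1, omega=1.0); ties keep smallest
    omega. Returns (t, kappa, omega, lnl, boundary)."""
    ii, jj, nn = _sparse_counts(counts)
    n_codons = counts.sum()
    if ng is None:
        ng = ng86_from_counts(counts)
    t0 = _ng_t_init(ng, n_codons)
    w0 = ng.omega if ng.omega is not None else 0.2
    w0 = float(np.clip(w0, 1e-3, 50.0))

    def nll(x):
        return -_pair_lnl(ii, jj, nn, pi, *x)

    best = None
    bounds = [_BOUNDS_T, _BOUNDS_K, _BOUNDS_W]
    for w_start in (w0, 0.1, 1.0):
        res = minimize(nll, x0=[t0, 2.0, w_start], method="L-BFGS-B",
                       bounds=bounds, options={"ftol": 1e-12, "maxiter": 200})
        cand = (-res.fun, res.x)
        if best is None or cand[0] > best[0] + 1e-6 or \
                (abs(cand[0] - best[0]) <= 1e-6 and cand[1][2] < best[1][2]):
            best = cand
    lnl, (t, kappa, omega) = best
    boundary = any(
        min(x - lo, hi - x) < 1e-3
        for x, (lo, hi) in zip((t, kappa, omega), bounds))
    return t, kappa, omega, lnl, boundary


def _dn_ds(t, kappa, omega, pi):
    _, rho_n = codons.build_q(kappa, omega, pi)
    rho1_n = codons.site_fractions(kappa, pi)
    dN = t * rho_n / (3.0 * rho1_n)
    dS = t * (1.0 - rho_n) / (3.0 * (1.0 - rho1_n))
    return dN, dS


def ml_pairwise(pair, gene_id: Optional[str] = None,
                min_codons: int = 30) -> RateResult:
    """codeml-style pairwise (t, kappa, omega) ML estimate under GY94/F3x4,
    with frequencies taken from the alignment being analyzed."""
    if isinstance(pair, CodonAlignment):
        rows = [pair.rows[s] for s in pair.species]
        gene_id = gene_id or pair.gene_id
    else:
        rows = list(pair)
        gene_id = gene_id or "pair"
    if len(rows) != 2:
        raise ValueError("pairwise estimator needs exactly two rows")
    if len(rows[0]) // 3 < min_codons:
        raise ValueError(
            f"insufficient data: {len(rows[0]) // 3} codons < {min_codons}")
    counts = codon_pair_counts(rows)
    pi = codons.f3x4(rows)
    ng = ng86_from_counts(counts)
    t, kappa, omega, lnl, boundary = _ml_fit_counts(counts, pi, ng)
    dN, dS = _dn_ds(t, kappa, omega, pi)
    return RateResult(gene_id, "ml", omega, dN, dS, t, kappa, lnl,
                      dS_zero=ng.dS_zero, boundary=boundary)


def counting_rate(pair, gene_id: Optional[str] = None) -> RateResult:
    """NG86 counting estimate wrapped as a RateResult."""
    if isinstance(pair, CodonAlignment):
        gene_id = gene_id or pair.gene_id
    ng = ng86(pair)
    return RateResult(gene_id or "pair", "counting", ng.omega, ng.dN, ng.dS,
                      None, None, None, dS_zero=ng.dS_zero)


# ---------------------------------------------------------------------------
# branch-model LRT

@dataclass
class BranchTestResult:
    gene_id: str
    focal: str
    lnl_null: float
    lnl_alt: float
    lrt: float
    df: int
    p: float
    direction: str  # "accelerated" | "decelerated"
    omega_background: float
    omega_focal: float
    q: Optional[float] = None


def _patterns(rows: Sequence[str]):
    idx = np.stack([codons.codons_to_indices(r) for r in rows])
    pats, counts = np.unique(idx, axis=1, return_counts=True)
    return pats, counts.astype(float)


def _star_lnl(pats, counts, pi, ts, kappa, omegas):
    """Likelihood of a 3-leaf star tree rooted at the internal node
    (Felsenstein pruning over the single internal state)."""
    uniq: dict[float, codons.SpectralQ] = {}
    prod = None
    for b in range(3):
        om = omegas[b]
        if om not in uniq:
            q, _ = codons.build_q(kappa, om, pi)
            uniq[om] = codons.SpectralQ(q, pi)
        p = uniq[om].transition(ts[b])
        col = p[:, pats[b]]
        prod = col if prod is None else prod * col
    like = pi @ prod
    return float(counts @ np.log(like))


def branch_test(trio: CodonAlignment, focal: str) -> BranchTestResult:
    """LRT of a focal-branch omega against a shared-omega null on a 3-taxon
    unrooted star tree; p from the chi-square(1) upper tail."""
    if len(trio.species) != 3:
        raise ValueError("branch test needs a three-row alignment")
    if focal not in trio.species:
        raise ValueError(f"focal species {focal!r} not in alignment")
    rows = [trio.rows[s] for s in trio.species]
    focal_idx = trio.species.index(focal)
    pats, counts = _patterns(rows)
    pi = codons.f3x4(rows)

    # pairwise counting initialization for branch lengths
    d = {}
    for a, b in itertools.combinations(range(3), 2):
        ng = ng86((rows[a], rows[b]))
        d[(a, b)] = _ng_t_init(ng, len(rows[0]) / 3)
    t0 = []
    for i in range(3):
        j, k = [x for x in range(3) if x != i]
        dij = d[tuple(sorted((i, j)))]
        dik = d[tuple(sorted((i, k)))]
        djk = d[tuple(sorted((j, k)))]
        t0.append(float(np.clip(0.5 * (dij + dik - djk), 1e-4, 10.0)))
    ngs = [ng86((rows[a], rows[b])).omega for a, b in itertools.combinations(range(3), 2)]
    w0 = float(np.clip(np.mean([w for w in ngs if w is not None] or [0.2]),
                       1e-3, 50.0))

    bounds5 = [_BOUNDS_T] * 3 + [_BOUNDS_K, _BOUNDS_W]

    def nll_null(x):
        return -_star_lnl(pats, counts, pi, x[:3], x[3], (x[4], x[4], x[4]))

    res0 = minimize(nll_null, x0=[*t0, 2.0, w0], method="L-BFGS-B",
                    bounds=bounds5, options={"ftol": 1e-12, "maxiter": 300})
    lnl_null = -res0.fun
    x_null = res0.x

    def nll_alt(x):
        om = [x[4]] * 3
        om[focal_idx] = x[5]
        return -_star_lnl(pats, counts, pi, x[:3], x[3], tuple(om))

    x0_alt = [*x_null, x_null[4]]
    res1 = minimize(nll_alt, x0=x0_alt, method="L-BFGS-B",
                    bounds=bounds5 + [_BOUNDS_W],
                    options={"ftol": 1e-12, "maxiter": 300})
    lnl_alt = max(-res1.fun, lnl_null)  # nesting: alt can never be worse
    lrt = 2.0 * (lnl_alt - lnl_null)
    p = math.erfc(math.sqrt(max(lrt, 0.0) / 2.0))
    om_bg, om_focal = float(res1.x[4]), float(res1.x[5])
    direction = "accelerated" if om_focal >= om_bg else "decelerated"
    return BranchTestResult(trio.gene_id, focal, lnl_null, lnl_alt, lrt, 1,
                            p, direction, om_bg, om_focal)


# ---------------------------------------------------------------------------
# multiple testing

def adjust_fdr(pvalues: Sequence[float], method: str = "bh") -> list[float]:
    """Benjamini-Hochberg step-up q-values; Storey variant rescales by
    pi0 = min(1, #{p > 0.5} / (0.5 m)). Output order matches input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    if method == "bh":
        return q.tolist()
    if method == "storey":
        pi0 = min(1.0, float((p > 0.5).sum()) / (0.5 * m))
        return np.minimum(q * pi0, 1.0).tolist()
    raise ValueError(f"unknown FDR method {method!r}")


# ---------------------------------------------------------------------------
# bootstrap genome-wide omega

@dataclass
class BootstrapSummary:
    species_pair: tuple[str, str]
    n_reps: int
    genes_per_rep: int
    omegas: list[float]
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    seed: int


def bootstrap_genome_omega(alignments: Sequence[CodonAlignment],
                           n_reps: int = 1000, genes_per_rep: int = 150,
                           seed: int = 0) -> BootstrapSummary:
    """Genome-wide omega by bootstrap concatenation: each replicate
    concatenates ``genes_per_rep`` alignments sampled without replacement
    from the pool and re-estimates (t, kappa, omega) by ML on the
    concatenation (F3x4 from the concatenated alignment)."""
    pool = list(alignments)
    if len(pool) < genes_per_rep:
        raise ValueError(
            f"pool of {len(pool)} alignments < genes_per_rep={genes_per_rep}")
    sp = pool[0].species
    if any(a.species != sp for a in pool):
        raise ValueError("all alignments must share the same species pair")
    per_gene_counts = []
    per_gene_base = []
    for a in pool:
        rows = [a.rows[s] for s in sp]
        per_gene_counts.append(codon_pair_counts(rows))
        per_gene_base.append(codons.position_base_counts(rows))
    rng = np.random.default_rng(seed)
    omegas = []
    for _ in range(n_reps):
        pick = rng.choice(len(pool), size=genes_per_rep, replace=False)
        counts = sum(per_gene_counts[i] for i in pick)
        base = sum(per_gene_base[i] for i in pick)
        pi = codons.f3x4_from_counts(base)
        _, _, omega, _, _ = _ml_fit_counts(counts, pi)
        omegas.append(float(omega))
    arr = np.array(omegas)
    return BootstrapSummary((sp[0], sp[1]), n_reps, genes_per_rep, omegas,
                            float(arr.mean()), float(arr.std(ddof=1)) if n_reps > 1 else 0.0,
                            float(np.percentile(arr, 2.5)),
                            float(np.percentile(arr, 97.5)), seed)
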