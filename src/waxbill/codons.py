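"""Codon-level machinery shared by the simulator and the rate estimators.

Holds the universal genetic code (via Biopython's codon table), F3x4 codon
frequencies, and the Goldman-Yang (GY94) codon substitution model: rate
matrix construction, transition probabilities through a symmetric
eigendecomposition (the model is time-reversible), and an exact stochastic
simulator of the substitution process used to evolve ortholog sets.

Conventions
-----------
* 61 sense codons of the standard code, lexicographic (ACGT) order.
* Branch lengths t are expected substitutions *per codon* (the rate matrix
  is scaled so that -sum_i pi_i Q_ii = 1).
* Substitutions into stop codons have rate zero, so evolution never creates
  an internal stop.
"""
from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable
from scipy.linalg import eigh

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_PURINES = {"A", "G"}

_standard = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_standard.stop_codons)
ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]
N_SENSE = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACID = [_standard.forward_table[c] for c in SENSE_CODONS]

# (61, 3) array of base indices per codon position
CODON_NT = np.array([[BASE_INDEX[b] for b in c] for c in SENSE_CODONS], dtype=np.int64)


def is_transition(a: str, b: str) -> bool:
    """True when the base change a->b is a transition (purine<->purine or
    pyrimidine<->pyrimidine)."""
    return a != b and ((a in _PURINES) == (b in _PURINES))


def _pair_tables():
    one = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    ts = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    syn = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            one[i, j] = True
            ts[i, j] = is_transition(ci[p], cj[p])
            syn[i, j] = AMINO_ACID[i] == AMINO_ACID[j]
    return one, ts, syn


#: boolean (61,61) tables over ordered sense-codon pairs one nucleotide apart
ONE_DIFF, IS_TRANSITION, IS_SYNONYMOUS = _pair_tables()


def codons_to_indices(seq: str) -> np.ndarray:
    """Encode an in-frame, stop-free nucleotide string as sense-codon indices."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for k in range(0, len(seq), 3):
        codon = seq[k : k + 3]
        try:
            out[k // 3] = CODON_INDEX[codon]
        except KeyError:
            raise ValueError(f"codon {codon!r} at position {k} is a stop or ambiguous")
    return out


def indices_to_codons(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)


def position_base_counts(seqs) -> np.ndarray:
    """(3, 4) counts of nucleotides by codon position over in-frame sequences."""
    counts = np.zeros((3, 4), dtype=float)
    for seq in seqs:
        for k, base in enumerate(seq):
            b = BASE_INDEX.get(base)
            if b is not None:
                counts[k % 3, b] += 1
    return counts


def f3x4_from_counts(counts: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """F3x4 sense-codon frequencies from (3,4) position-specific base counts.

    A small floor keeps every sense codon at positive frequency even when a
    base is absent at a position in the data (degenerate small inputs).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3, 4):
        raise ValueError("expected (3, 4) position-by-base counts")
    pos = counts + floor
    pos = pos / pos.sum(axis=1, keepdims=True)
    pi = pos[0, CODON_NT[:, 0]] * pos[1, CODON_NT[:, 1]] * pos[2, CODON_NT[:, 2]]
    return pi / pi.sum()


def f3x4(seqs) -> np.ndarray:
    """F3x4 frequencies computed directly from sequences."""
    return f3x4_from_counts(position_base_counts(seqs))


def build_q(kappa: float, omega: float, pi: np.ndarray):
    """GY94 rate matrix scaled to one expected substitution per codon per
    unit branch length.

    Off-diagonal rate i->j (single-nucleotide changes only):
    pi_j * kappa^[transition] * omega^[nonsynonymous]; zero otherwise.

    Returns (Q, rho_n) where rho_n is the nonsynonymous fraction of the
    total substitution rate (used for dN/dS bookkeeping).
    """
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    rate = np.where(ONE_DIFF, pi[None, :], 0.0)
    rate = rate * np.where(IS_TRANSITION, kappa, 1.0)
    rate = rate * np.where(ONE_DIFF & ~IS_SYNONYMOUS, omega, 1.0)
    total = (pi[:, None] * rate).sum()
    if total <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    nonsyn = (pi[:, None] * np.where(~IS_SYNONYMOUS, rate, 0.0)).sum()
    q = rate / total
    np.fill_diagonal(q, -q.sum(axis=1))
    return q, nonsyn / total


def site_fractions(kappa: float, pi: np.ndarray):
    """Proportion of mutational opportunity that is nonsynonymous under
    omega = 1 (codeml-style ML definition of nonsynonymous sites)."""
    _, rho1 = build_q(kappa, 1.0, pi)
    return rho1


class SpectralQ:
    """Eigendecomposition of a reversible GY94 rate matrix, for fast
    transition probabilities P(t) = exp(Qt) at many t."""

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        s = np.sqrt(pi)
        b = (q * s[:, None]) / s[None, :]
        b = 0.5 * (b + b.T)  # symmetric up to rounding
        w, v = eigh(b)
        self._w = w
        self._left = v / s[:, None]
        self._right = (v * s[:, None]).T

    def transition(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be >= 0")
        p = (self._left * np.exp(self._w * t)) @ self._right
        np.clip(p, 1e-300, None, out=p)
        return p


def transition_matrix(kappa: float, omega: float, pi: np.ndarray, t: float) -> np.ndarray:
    q, _ = build_q(kappa, omega, pi)
    return SpectralQ(q, pi).transition(t)


def evolve_codons(states: np.ndarray, t: float, q: np.ndarray, rng: np.random.Generator):
    """Evolve codon states for time t under rate matrix q by exact
    (Gillespie) simulation, vectorized over codons.

    Returns (new_states, n_synonymous_events, n_nonsynonymous_events).
    """
    states = np.array(states, dtype=np.int64, copy=True)
    if t == 0 or states.size == 0:
        return states, 0, 0
    exit_rate = -np.diag(q)
    jump = q.copy()
    np.fill_diagonal(jump, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump = np.nan_to_num(jump / exit_rate[:, None])
    jump_cum = np.cumsum(jump, axis=1)
    jump_cum[:, -1] = 1.0

    n_syn = 0
    n_non = 0
    active = np.arange(states.size)
    remain = np.full(states.size, float(t))
    while active.size:
        r = exit_rate[states[active]]
        draw = rng.exponential(1.0, active.size)
        wait = np.where(r > 0, draw / np.where(r > 0, r, 1.0), np.inf)
        hit = wait < remain[active]
        active = active[hit]
        if not active.size:
            break
        remain[active] -= wait[hit]
        u = rng.random(active.size)
        rows = jump_cum[states[active]]
        new = (rows < u[:, None]).sum(axis=1)
        syn_mask = IS_SYNONYMOUS[states[active], new]
        n_syn += int(syn_mask.sum())
        n_non += int((~syn_mask).sum())
        states[active] = new
    return states, n_syn, n_non
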