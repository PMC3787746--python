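"""Ortholog assignment by k-mer-seeded local alignment.

Each assembled transcript fragment is searched against the reference cDNA
set (both strands), seed hits are grouped per reference sequence and
extended with affine-gap Smith-Waterman, and significance is scored with
Karlin-Altschul statistics: bit score S' = (lambda*S - ln K)/ln 2 and
e-value E = K*m*n*exp(-lambda*S). Fragments are then assigned to the best
surviving reference gene after the study's hit filters (e-value <= 1e-5,
aligned length >= 300 bp), mirroring a best-BLAST-hit protocol.

lambda is the unique positive root of sum_ij p_i p_j exp(lambda*s_ij) = 1
under the database base composition; K uses the standard lattice series
approximation for ungapped scores, and the gapped search reuses the
ungapped pair (the e-value's role here is the filter threshold, not exact
gapped statistics).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from ._align import encode, local_align
from .synthgen import revcomp


@dataclass(frozen=True)
class MatchParams:
    k: int = 11
    max_evalue: float = 1e-5
    min_hit_len: int = 300
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = 5.0
    gap_ext: float = 2.0

    def __post_init__(self):
        if self.k < 8:
            raise ValueError("seed word length k must be >= 8")
        if self.max_evalue <= 0 or self.min_hit_len <= 0:
            raise ValueError("max_evalue and min_hit_len must be positive")


def karlin_lambda(match: float, mismatch: float, freqs: np.ndarray) -> float:
    """Unique positive root of sum_ij p_i p_j exp(lambda*s_ij) = 1."""
    p_match = float((freqs ** 2).sum())
    p_mis = 1.0 - p_match
    expected = p_match * match + p_mis * mismatch
    if expected >= 0:
        raise ValueError("expected score must be negative for local statistics")

    def f(lam):
        return p_match * math.exp(lam * match) + p_mis * math.exp(lam * mismatch) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    return brentq(f, 1e-9, hi, xtol=1e-12)


def karlin_k(match: float, mismatch: float, freqs: np.ndarray,
             lam: Optional[float] = None, max_terms: int = 80) -> float:
    """Karlin-Altschul K for an integer-lattice match/mismatch score via the
    standard series approximation."""
    if lam is None:
        lam = karlin_lambda(match, mismatch, freqs)
    mi, ms = int(round(match)), int(round(mismatch))
    delta = math.gcd(abs(mi), abs(ms)) if ms else abs(mi)
    p_match = float((freqs ** 2).sum())
    probs = {mi: p_match, ms: 1.0 - p_match}
    lo, hi = min(probs), max(probs)
    base = np.zeros(hi - lo + 1)
    for s, p in probs.items():
        base[s - lo] = p
    h_prime = sum(p * s * math.exp(lam * s) for s, p in probs.items())

    sigma = 0.0
    dist = np.array([1.0])
    offset = 0  # score value of dist[0]
    for k in range(1, max_terms + 1):
        dist = np.convolve(dist, base)
        offset += lo
        scores = offset + np.arange(dist.size)
        neg = scores < 0
        term = float((dist[neg] * np.exp(lam * scores[neg])).sum()
                     + dist[~neg].sum())
        sigma += term / k
        if term / k < 1e-10:
            break
    return (delta * lam * math.exp(-2.0 * sigma)
            / (h_prime * (1.0 - math.exp(-lam * delta))))


@dataclass
class Hit:
    fragment_id: str
    gene_id: str
    raw_score: float
    bit_score: float
    evalue: float
    frag_interval: tuple[int, int]  # 0-based half-open, on the original fragment
    ref_interval: tuple[int, int]
    identity: float  # percent
    strand: str
    length: int  # alignment length including gaps
    mismatches: int
    gap_opens: int


@dataclass
class OrthologAssignment:
    """fragment id -> winning gene id (or None) with the winning Hit."""
    assigned: dict[str, Optional[str]]
    hits: dict[str, Optional[Hit]]

    @property
    def n_assigned(self) -> int:
        return sum(1 for g in self.assigned.values() if g is not None)


class KmerIndex:
    """Exact k-mer lookup over the reference cDNA set (forward strand only;
    query strands are handled at search time)."""

    def __init__(self, sequences, params: MatchParams):
        if not isinstance(sequences, dict):
            pairs = list(sequences)
            seen = set()
            for sid, _ in pairs:
                if sid in seen:
                    raise ValueError(f"duplicate sequence id {sid!r}")
                seen.add(sid)
            sequences = dict(pairs)
        if not sequences:
            raise ValueError("empty reference sequence set")
        ids = list(sequences)
        self.params = params
        self.ids: list[str] = []
        self.seqs: list[str] = []
        k = params.k
        self._map: dict[str, list[tuple[int, int]]] = {}
        for sid in ids:
            seq = sequences[sid].upper()
            if len(seq) < k:
                warnings.warn(f"sequence {sid} shorter than k={k}; skipped")
                continue
            idx = len(self.ids)
            self.ids.append(sid)
            self.seqs.append(seq)
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._map.setdefault(kmer, []).append((idx, i))
        self.total_length = sum(len(s) for s in self.seqs)
        counts = np.zeros(4)
        for s in self.seqs:
            e = encode(s)
            counts += np.bincount(e[e < 4], minlength=4)
        self.base_freqs = counts / counts.sum() if counts.sum() else np.full(4, 0.25)
        self.lam = karlin_lambda(params.match, params.mismatch, self.base_freqs)
        self.k_param = karlin_k(params.match, params.mismatch, self.base_freqs,
                                self.lam)

    def lookup(self, kmer: str):
        return self._map.get(kmer, ())

    def n_kmers(self, sid: str) -> int:
        idx = self.ids.index(sid)
        seq = self.seqs[idx]
        k = self.params.k
        return sum(1 for i in range(len(seq) - k + 1)
                   if "N" not in seq[i : i + k])


def index_reference(sequences: dict[str, str],
                    params: MatchParams = MatchParams()) -> KmerIndex:
    return KmerIndex(sequences, params)


def _hit_from_alignment(index, params, fragment_id, query, strand, seq_idx,
                        window_start, score, cols, orig_len):
    qpos = [c[0] for c in cols if c[0] >= 0]
    rpos = [c[1] for c in cols if c[1] >= 0]
    if not qpos or not rpos:
        return None
    seq = index.seqs[seq_idx]
    matches = mismatches = gap_opens = 0
    prev_gap = False
    for qi, ri in cols:
        if qi < 0 or ri < 0:
            if not prev_gap:
                gap_opens += 1
            prev_gap = True
            continue
        prev_gap = False
        if query[qi] == seq[window_start + ri]:
            matches += 1
        else:
            mismatches += 1
    length = len(cols)
    identity = 100.0 * matches / length
    evalue = (index.k_param * orig_len * index.total_length
              * math.exp(-index.lam * score))
    bit = (index.lam * score - math.log(index.k_param)) / math.log(2.0)
    qs, qe = qpos[0], qpos[-1] + 1
    if strand == "-":
        qs, qe = orig_len - qe, orig_len - qs
    return Hit(
        fragment_id=fragment_id, gene_id=index.ids[seq_idx],
        raw_score=score, bit_score=bit, evalue=evalue,
        frag_interval=(qs, qe),
        ref_interval=(window_start + rpos[0], window_start + rpos[-1] + 1),
        identity=identity, strand=strand, length=length,
        mismatches=mismatches, gap_opens=gap_opens)


def search(fragment: str, index: KmerIndex,
           params: Optional[MatchParams] = None,
           fragment_id: str = "query") -> list[Hit]:
    """Seeded local search of one fragment against the index, both strands.
    Returns hits sorted by ascending e-value (one best hit per reference
    sequence and strand)."""
    params = params or index.params
    if not fragment:
        raise ValueError("empty fragment")
    k = params.k
    if len(fragment) < k:
        raise ValueError(f"fragment shorter than k={k}")
    fragment = fragment.upper()
    hits = []
    for strand in "+-":
        query = fragment if strand == "+" else revcomp(fragment)
        seeds: dict[int, list[int]] = {}
        for i in range(len(query) - k + 1):
            for seq_idx, pos in index.lookup(query[i : i + k]):
                seeds.setdefault(seq_idx, []).append(pos - i)
        for seq_idx in sorted(seeds):
            diags = sorted(seeds[seq_idx])
            ref_len = len(index.seqs[seq_idx])
            span = diags[-1] - diags[0]
            if span > 3 * len(query):
                # repeats: keep the densest diagonal band
                arr = np.array(diags)
                best_lo, best_n = arr[0], 1
                for d in arr:
                    n = int(((arr >= d) & (arr <= d + len(query))).sum())
                    if n > best_n:
                        best_lo, best_n = d, n
                diags = [d for d in diags
                         if best_lo <= d <= best_lo + len(query)]
            lo = max(0, diags[0] - 32)
            hi = min(ref_len, diags[-1] + len(query) + 32)
            window = index.seqs[seq_idx][lo:hi]
            score, cols = local_align(query, window, params.match,
                                      params.mismatch, params.gap_open,
                                      params.gap_ext)
            if not cols:
                continue
            hit = _hit_from_alignment(index, params, fragment_id, query,
                                      strand, seq_idx, lo, score, cols,
                                      len(fragment))
            if hit is not None:
                hits.append(hit)
    hits.sort(key=lambda h: (h.evalue, -h.raw_score, h.gene_id, h.strand))
    return hits


def assign_orthologs(hits_by_fragment: dict[str, list[Hit]],
                     params: MatchParams = MatchParams()) -> OrthologAssignment:
    """Apply the hit filters (aligned length >= min_hit_len, e-value <=
    max_evalue) and keep the single best surviving hit per fragment
    (ascending e-value, ties by higher raw score then gene id)."""
    assigned: dict[str, Optional[str]] = {}
    winners: dict[str, Optional[Hit]] = {}
    for frag_id, hits in hits_by_fragment.items():
        ok = [h for h in hits
              if h.length >= params.min_hit_len and h.evalue <= params.max_evalue]
        if not ok:
            assigned[frag_id] = None
            winners[frag_id] = None
            continue
        best = min(ok, key=lambda h: (h.evalue, -h.raw_score, h.gene_id))
        assigned[frag_id] = best.gene_id
        winners[frag_id] = best
    return OrthologAssignment(assigned, winners)


def hits_to_tabular(hits: list[Hit]) -> list[str]:
    """Conventional 12-column tab-separated hit lines (1-based inclusive
    coordinates; minus-strand hits have sstart > send)."""
    lines = []
    for h in hits:
        qs, qe = h.frag_interval[0] + 1, h.frag_interval[1]
        ss, se = h.ref_interval[0] + 1, h.ref_interval[1]
        if h.strand == "-":
            ss, se = se, ss
        lines.append("\t".join([
            h.fragment_id, h.gene_id, f"{h.identity:.2f}", str(h.length),
            str(h.mismatches), str(h.gap_opens), str(qs), str(qe),
            str(ss), str(se), f"{h.evalue:.3g}", f"{h.bit_score:.1f}"]))
    return lines
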