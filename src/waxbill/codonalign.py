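"""From assigned fragments to gap-free in-frame codon alignments.

The reference species' annotated transcript provides a trusted reading
frame, so instead of a multiple sequence alignment each fragment is aligned
pairwise to the reference transcript (semiglobal affine DP), insertions
that would disrupt the reference frame are discarded as sequencing errors,
fragments of one species are collapsed into a per-gene majority-rule
consensus on the reference coordinate grid, and the stacked consensuses are
trimmed to the reference CDS, stripped of the terminal stop codon and of
every codon column containing a gap, ambiguity or stop in any row. Genes
whose surviving alignment is shorter than ``min_len`` (300 bp) are
rejected.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import codons
from ._align import semiglobal_align


@dataclass(frozen=True)
class AlignScores:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 5.0
    gap_ext: float = 2.0


@dataclass
class CoordAlignment:
    """Pairing of fragment positions and reference positions (gap markers
    -1 on either side), plus the fragment sequence in reference-forward
    orientation."""
    fragment_id: str
    gene_id: str
    fragment_seq: str
    columns: list[tuple[int, int]]
    score: float

    def __post_init__(self):
        last_f = last_r = -1
        for f, r in self.columns:
            if f >= 0:
                if f <= last_f:
                    raise ValueError("fragment positions not strictly increasing")
                last_f = f
            if r >= 0:
                if r <= last_r:
                    raise ValueError("reference positions not strictly increasing")
                last_r = r


@dataclass
class SpeciesConsensus:
    """Per-gene, per-species consensus on the reference coordinate grid.
    chars is a string over {A,C,G,T,-}; support[i] counts fragments
    contributing a base at position i (0 -> '-')."""
    gene_id: str
    species: str
    chars: str
    support: np.ndarray


@dataclass
class CodonAlignment:
    """Gap-free, in-frame, stop-free codon matrix for one gene. Rows are
    keyed by species id (the reference species first in ``species``);
    column_map[k] is the reference CDS codon index of matrix column k."""
    gene_id: str
    species: tuple[str, ...]
    rows: dict[str, str]
    column_map: tuple[int, ...]

    @property
    def length_bp(self) -> int:
        return len(self.column_map) * 3

    @property
    def n_codons(self) -> int:
        return len(self.column_map)

    def pair(self, a: str, b: str) -> "CodonAlignment":
        return CodonAlignment(self.gene_id, (a, b),
                              {a: self.rows[a], b: self.rows[b]},
                              self.column_map)


def align_affine(fragment: str, cds: str, fragment_id: str = "frag",
                 gene_id: str = "gene",
                 scores: AlignScores = AlignScores()) -> CoordAlignment:
    """Optimal semiglobal affine alignment of a fragment against a
    reference transcript window (no end penalties on the reference side).
    Ties prefer match > mismatch > gap-in-fragment > gap-in-reference."""
    if not fragment or not cds:
        raise ValueError("empty sequence")
    score, cols = semiglobal_align(fragment, cds, scores.match,
                                   scores.mismatch, scores.gap_open,
                                   scores.gap_ext)
    return CoordAlignment(fragment_id, gene_id, fragment.upper(), cols, score)


def repair_frame(alignment: CoordAlignment) -> CoordAlignment:
    """Delete every column where the fragment has a base but the reference
    has a gap (an insertion that would disrupt the annotated reading
    frame); such extra bases are treated as sequencing errors. Deletions
    relative to the reference are kept (resolved at the codon stage)."""
    kept = [(f, r) for f, r in alignment.columns if r >= 0]
    return replace(alignment, columns=kept)


def build_consensus(alignments: list[CoordAlignment], ref_length: int,
                    species: str) -> SpeciesConsensus:
    """Majority-rule consensus over frame-repaired fragment alignments of
    one gene and species. Ties go to the base supported by the
    highest-scoring fragment, then to the lexicographically smallest base;
    uncovered positions are '-'."""
    if not alignments:
        raise ValueError("no alignments to build a consensus from")
    gene_id = alignments[0].gene_id
    for a in alignments:
        if a.gene_id != gene_id:
            raise ValueError("alignments span multiple genes")
    counts: dict[int, dict[str, list]] = {}
    for a in alignments:
        for f, r in a.columns:
            if f < 0 or r < 0:
                continue
            if r >= ref_length:
                raise ValueError(
                    f"{gene_id}: reference position {r} beyond length {ref_length}")
            base = a.fragment_seq[f]
            slot = counts.setdefault(r, {}).setdefault(base, [0, -np.inf])
            slot[0] += 1
            slot[1] = max(slot[1], a.score)
    chars = []
    support = np.zeros(ref_length, dtype=int)
    for pos in range(ref_length):
        votes = counts.get(pos)
        if not votes:
            chars.append("-")
            continue
        support[pos] = sum(v[0] for v in votes.values())
        best = min(votes.items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))
        chars.append(best[0] if best[0] in "ACGT" else "-")
    return SpeciesConsensus(gene_id, species, "".join(chars), support)


def build_codon_alignment(reference_cds: str,
                          consensuses: list[SpeciesConsensus],
                          reference_name: str = "reference",
                          min_len: int = 300) -> Optional[CodonAlignment]:
    """Stack the reference CDS and 1+ species consensuses (already on the
    CDS coordinate grid), drop the terminal stop codon, then drop every
    codon column containing '-', an ambiguity code or a stop codon in any
    row. Returns None when the surviving alignment is shorter than
    ``min_len`` bp."""
    if len(reference_cds) % 3:
        raise ValueError("reference CDS length not a multiple of 3")
    for c in consensuses:
        if len(c.chars) != len(reference_cds):
            raise ValueError(
                f"{c.gene_id}/{c.species}: consensus length {len(c.chars)} "
                f"!= CDS length {len(reference_cds)}")
    names = [reference_name] + [c.species for c in consensuses]
    seqs = [reference_cds.upper()] + [c.chars.upper() for c in consensuses]
    n_codons = len(reference_cds) // 3
    # drop the reference-frame terminal stop codon
    last = n_codons
    if reference_cds[-3:].upper() in codons.STOP_CODONS:
        last = n_codons - 1
    kept_cols = []
    kept_rows = [[] for _ in seqs]
    for k in range(last):
        column = [s[3 * k : 3 * k + 3] for s in seqs]
        if any(any(ch not in "ACGT" for ch in cod) for cod in column):
            continue
        if any(cod in codons.STOP_CODONS for cod in column):
            continue
        kept_cols.append(k)
        for row, cod in zip(kept_rows, column):
            row.append(cod)
    if 3 * len(kept_cols) < min_len:
        return None
    rows = {name: "".join(parts) for name, parts in zip(names, kept_rows)}
    gene_id = consensuses[0].gene_id if consensuses else "gene"
    return CodonAlignment(gene_id, tuple(names), rows, tuple(kept_cols))
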