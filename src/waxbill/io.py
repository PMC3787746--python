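"""File formats: FASTA/FASTQ, a GFF3 subset for the generated gene models,
minimal VCF for heterozygous calls, TSV tables and YAML configs.

Parsing of FASTA/FASTQ goes through Bio.SeqIO; writing is done here so
that rewriting a parsed file reproduces it byte for byte (70-column FASTA
wrap, fixed column orders). GFF3 and VCF are 1-based inclusive on disk;
everything in memory is 0-based half-open.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .snpscan import SnpCall
from .synthgen import GeneModel

# ---------------------------------------------------------------------------
# FASTA / FASTQ

def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.description, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def read_reads(path) -> list[tuple[str, str]]:
    """Reads in FASTA or FASTQ (auto-detected); quality strings, when
    present, are ignored (the SNP caller is depth-based)."""
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [(rec.description, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), fmt)]


# ---------------------------------------------------------------------------
# GFF3 (subset: gene/mRNA/exon/UTR/CDS/intron features of the generator)

_GFF_SOURCE = "waxbill"


def _gff_line(chrom, ftype, start, end, strand, attrs, phase="."):
    return (f"{chrom}\t{_GFF_SOURCE}\t{ftype}\t{start + 1}\t{end}\t.\t"
            f"{strand}\t{phase}\t{attrs}")


def _exon_intervals(model: GeneModel) -> list[tuple[int, int]]:
    out = []
    tx_start, tx_end = model.transcript
    span = model.span
    for a, b, off in model._blocks:
        if model.strand == "+":
            out.append((tx_start + off, tx_start + off + (b - a)))
        else:
            out.append((tx_start + span - off - (b - a), tx_start + span - off))
    return sorted(out)


def write_gff3(genes: Sequence[GeneModel], chromosomes: Sequence[tuple[str, int]],
               path) -> None:
    lines = ["##gff-version 3"]
    for name, length in chromosomes:
        lines.append(f"##sequence-region {name} 1 {length}")
    for g in genes:
        s, e = g.transcript
        lines.append(_gff_line(g.chrom, "gene", s, e, g.strand, f"ID={g.gene_id}"))
        tid = f"{g.gene_id}.t1"
        lines.append(_gff_line(g.chrom, "mRNA", s, e, g.strand,
                               f"ID={tid};Parent={g.gene_id}"))
        for a, b in _exon_intervals(g):
            lines.append(_gff_line(g.chrom, "exon", a, b, g.strand, f"Parent={tid}"))
        # CDS phase: cumulative coding length in transcript order
        cds_tx_order = sorted(g.cds_intervals, reverse=(g.strand == "-"))
        cum = 0
        phases = {}
        for a, b in cds_tx_order:
            phases[(a, b)] = (3 - cum % 3) % 3
            cum += b - a
        for a, b in sorted(g.cds_intervals):
            lines.append(_gff_line(g.chrom, "CDS", a, b, g.strand,
                                   f"Parent={tid}", str(phases[(a, b)])))
        for ftype, ivals in (("five_prime_UTR", g.utr5_intervals),
                             ("three_prime_UTR", g.utr3_intervals),
                             ("intron", g.intron_intervals)):
            for a, b in sorted(ivals):
                lines.append(_gff_line(g.chrom, ftype, a, b, g.strand,
                                       f"Parent={tid}"))
    Path(path).write_text("\n".join(lines) + "\n")


def _blocks_from_exons(exons: list[tuple[int, int]], strand: str,
                       transcript: tuple[int, int]):
    tx_start, tx_end = transcript
    span = tx_end - tx_start
    order = exons if strand == "+" else exons[::-1]
    blocks = []
    sp = 0
    for a, b in order:
        off = (a - tx_start) if strand == "+" else (tx_end - b)
        blocks.append((sp, sp + (b - a), off))
        sp += b - a
    return tuple(blocks)


def read_gff3(path):
    """Parse a GFF3 file written by write_gff3 back into gene models and
    chromosome sizes. Raises on malformed records with the line number."""
    chromosomes: list[tuple[str, int]] = []
    raw: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                chromosomes.append((parts[1], int(parts[3])))
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            try:
                iv = (int(start) - 1, int(end))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad coordinates")
            tags = dict(kv.split("=", 1) for kv in attrs.split(";") if kv)
            if ftype == "gene":
                gid = tags["ID"]
                raw[gid] = {"chrom": chrom, "strand": strand, "transcript": iv,
                            "exon": [], "CDS": [], "five_prime_UTR": [],
                            "three_prime_UTR": [], "intron": []}
                order.append(gid)
            elif ftype == "mRNA":
                continue
            else:
                gid = tags["Parent"].rsplit(".t1", 1)[0]
                if gid not in raw:
                    raise ValueError(f"{path}:{lineno}: orphan feature {gid}")
                if ftype in raw[gid]:
                    raw[gid][ftype].append(iv)
    genes = []
    for gid in order:
        d = raw[gid]
        exons = sorted(d["exon"])
        genes.append(GeneModel(
            gene_id=gid, chrom=d["chrom"], strand=d["strand"],
            transcript=d["transcript"],
            cds_intervals=tuple(sorted(d["CDS"])),
            utr5_intervals=tuple(sorted(d["five_prime_UTR"])),
            utr3_intervals=tuple(sorted(d["three_prime_UTR"])),
            intron_intervals=tuple(sorted(d["intron"])),
            _blocks=_blocks_from_exons(exons, d["strand"], d["transcript"]),
        ))
    return genes, chromosomes


# ---------------------------------------------------------------------------
# VCF (minimal single-sample het calls)

def write_vcf(calls: Sequence[SnpCall], chromosomes: Sequence[tuple[str, int]],
              path) -> None:
    lines = ["##fileformat=VCFv4.2"]
    for name, length in chromosomes:
        lines.append(f"##contig=<ID={name},length={length}>")
    for tag, desc in (
        ("DP1", "Read depth of REF allele"),
        ("DP2", "Read depth of ALT allele"),
        ("GENE", "Gene id or NA"),
        ("COMPARTMENT", "Genomic compartment"),
        ("TPOS", "0-based transcript position"),
    ):
        typ = "Integer" if tag.startswith(("DP", "TP")) else "String"
        lines.append(f'##INFO=<ID={tag},Number=1,Type={typ},Description="{desc}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for c in sorted(calls, key=lambda c: (c.chrom or "", c.position or 0)):
        info = (f"DP1={c.depth1};DP2={c.depth2};GENE={c.gene_id or 'NA'};"
                f"COMPARTMENT={c.compartment or 'NA'};TPOS={c.transcript_pos}")
        lines.append(f"{c.chrom}\t{(c.position or 0) + 1}\t.\t{c.allele1}\t"
                     f"{c.allele2}\t.\tPASS\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path):
    calls: list[SnpCall] = []
    chromosomes: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##contig"):
                inner = line[line.index("<") + 1 : line.rindex(">")]
                kv = dict(p.split("=", 1) for p in inner.split(","))
                chromosomes.append((kv["ID"], int(kv["length"])))
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}:{lineno}: expected 8 VCF columns")
            chrom, pos, _, ref, alt, _, _, info = parts[:8]
            tags = dict(kv.split("=", 1) for kv in info.split(";") if "=" in kv)
            gene = tags.get("GENE")
            calls.append(SnpCall(
                gene_id=None if gene in (None, "NA") else gene,
                transcript_pos=int(tags.get("TPOS", -1)),
                allele1=ref, allele2=alt,
                depth1=int(tags.get("DP1", 0)), depth2=int(tags.get("DP2", 0)),
                chrom=chrom, position=int(pos) - 1,
                compartment=None if tags.get("COMPARTMENT") in (None, "NA")
                else tags["COMPARTMENT"]))
    return calls, chromosomes


# ---------------------------------------------------------------------------
# TSV / YAML

def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_yaml(obj, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())
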