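"""End-to-end orchestration: simulate -> match -> align -> rates -> snps ->
enrich -> report.

Each stage reads its inputs from, and writes its outputs to, a run
directory, so any stage can be re-run from files alone. A YAML config
carries every threshold (defaults are the study's: e-value 1e-5, 300 bp
minimum hit and alignment lengths, 1000 bootstrap reps of 150 alignments,
1 kb flanks, 100 bp / 60% homopolymer read filters). Identical config and
seed give byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import codonalign, enrichstats, io, orthomatch, ratesel, snpscan, synthgen

log = logging.getLogger("waxbill")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s %(stage)s] %(message)s"))
    log.addHandler(_h)
    log.propagate = False
log.setLevel(logging.INFO)


def _log(stage: str, msg: str) -> None:
    log.info(msg, extra={"stage": stage})


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"[{stage}] {msg}")
        self.stage = stage


@dataclass
class PipelineConfig:
    sim: synthgen.SimConfig
    match: orthomatch.MatchParams = orthomatch.MatchParams()
    read_assign: orthomatch.MatchParams = orthomatch.MatchParams(
        max_evalue=1e-3, min_hit_len=50)
    align_min_len: int = 300
    rates_method: str = "ml"  # per-gene pairwise estimator: ml | counting
    branch_focals: tuple[str, ...] = ()
    fdr_method: str = "storey"
    n_reps: int = 1000
    genes_per_rep: int = 150
    bootstrap_pairs: tuple[tuple[str, str], ...] = ()
    snp: snpscan.SnpParams = snpscan.SnpParams()
    contrasts: tuple[tuple[str, str, str], ...] = (
        ("Z", "greater", "rest"), ("4A", "less", "rest"))
    make_figures: bool = True

    def __post_init__(self):
        if not self.branch_focals:
            self.branch_focals = (self.sim.ingroup_a, self.sim.ingroup_b)
        if not self.bootstrap_pairs:
            self.bootstrap_pairs = (
                (self.sim.ingroup_b, self.sim.ingroup_a),
                (self.sim.ingroup_b, self.sim.outgroup),
                (self.sim.ingroup_a, self.sim.outgroup))
        self.contrasts = tuple(
            c for c in self.contrasts
            if c[0] in {x.name for x in self.sim.chromosome_plan})


def config_to_dict(cfg: PipelineConfig) -> dict:
    d = {
        "simulate": synthgen.config_to_dict(cfg.sim),
        "match": asdict(cfg.match),
        "read_assign": asdict(cfg.read_assign),
        "align": {"min_len": cfg.align_min_len},
        "rates": {"method": cfg.rates_method,
                  "branch_focals": list(cfg.branch_focals),
                  "fdr_method": cfg.fdr_method,
                  "n_reps": cfg.n_reps, "genes_per_rep": cfg.genes_per_rep,
                  "bootstrap_pairs": [list(p) for p in cfg.bootstrap_pairs]},
        "snps": asdict(cfg.snp),
        "enrich": {"contrasts": [list(c) for c in cfg.contrasts]},
        "report": {"make_figures": cfg.make_figures},
    }
    return d


def config_from_dict(d: dict) -> PipelineConfig:
    sim = synthgen.config_from_dict(d["simulate"])
    kw: dict = {"sim": sim}
    if "match" in d:
        kw["match"] = orthomatch.MatchParams(**d["match"])
    if "read_assign" in d:
        kw["read_assign"] = orthomatch.MatchParams(**d["read_assign"])
    if "align" in d:
        kw["align_min_len"] = d["align"].get("min_len", 300)
    rates = d.get("rates", {})
    for src, dst in (("method", "rates_method"), ("fdr_method", "fdr_method"),
                     ("n_reps", "n_reps"), ("genes_per_rep", "genes_per_rep")):
        if src in rates:
            kw[dst] = rates[src]
    if "branch_focals" in rates:
        kw["branch_focals"] = tuple(rates["branch_focals"])
    if "bootstrap_pairs" in rates:
        kw["bootstrap_pairs"] = tuple(tuple(p) for p in rates["bootstrap_pairs"])
    if "snps" in d:
        kw["snp"] = snpscan.SnpParams(**d["snps"])
    if "enrich" in d and "contrasts" in d["enrich"]:
        kw["contrasts"] = tuple(tuple(c) for c in d["enrich"]["contrasts"])
    if "report" in d:
        kw["make_figures"] = d["report"].get("make_figures", True)
    return PipelineConfig(**kw)


def load_config(path) -> PipelineConfig:
    return config_from_dict(io.read_yaml(path))


def config_hash(cfg: PipelineConfig) -> str:
    canon = json.dumps(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _derived_seed(cfg: PipelineConfig, k: int) -> int:
    ss = np.random.SeedSequence(cfg.sim.seed, spawn_key=(100 + k,))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# stage: simulate

def stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    sim = cfg.sim
    d = out / "sim"
    d.mkdir(parents=True, exist_ok=True)
    reference = synthgen.build_reference(sim)
    truth = synthgen.evolve_orthologs(reference, sim)
    diploid, fragments, reads = synthgen.make_diploid_and_reads(
        reference, truth, sim)
    term_rows = synthgen.make_term_map(reference, sim)

    io.write_fasta(((g, s) for g, s in sorted(reference.cds_sequences.items())),
                   d / "ancestor_cds.fasta")
    # search database: annotated transcript set of the reference taxon
    db_cds = {g: truth.sequence(sim.ingroup_b, g)
              for g in sorted(reference.cds_sequences)}
    db_cdna = {g: reference.utr5[g] + db_cds[g] + reference.utr3[g]
               for g in db_cds}
    io.write_fasta(sorted(db_cds.items()), d / "db_cds.fasta")
    io.write_fasta(sorted(db_cdna.items()), d / "db_cdna.fasta")
    for sp in sim.species:
        io.write_fasta(((f"{sp}|{g}", truth.sequence(sp, g))
                        for g in sorted(truth.genes)),
                       d / f"truth_cds_{sp}.fasta")
    io.write_gff3(reference.genes, reference.chromosomes, d / "genes.gff3")
    for sp, frs in fragments.items():
        io.write_fasta(frs, d / f"fragments_{sp}.fasta")
    io.write_fasta(reads, d / f"reads_{sim.ingroup_a}.fasta")

    gene_rows = []
    for gid in sorted(truth.genes):
        g = truth.genes[gid]
        row = {"gene": gid, "chrom": reference.gene(gid).chrom,
               "omega": g.omega}
        for sp in sim.species:
            row[f"omega_{sp}"] = g.branch_omegas[sp]
            row[f"syn_{sp}"], row[f"nonsyn_{sp}"] = g.events[sp]
        gene_rows.append(row)
    io.write_tsv(pd.DataFrame(gene_rows), d / "truth_genes.tsv")
    snp_rows = [{"gene": gid, "chrom": reference.gene(gid).chrom,
                 "transcript_pos": pos,
                 "genome_pos": reference.gene(gid).to_genome(pos),
                 "allele1": a1, "allele2": a2}
                for gid in sorted(diploid.sites)
                for pos, a1, a2 in diploid.sites[gid]]
    io.write_tsv(pd.DataFrame(
        snp_rows, columns=["gene", "chrom", "transcript_pos", "genome_pos",
                           "allele1", "allele2"]), d / "truth_snps.tsv")
    io.write_tsv(pd.DataFrame(term_rows, columns=["gene", "term", "description"]),
                 d / "term_map.tsv")
    io.write_yaml(config_to_dict(cfg), d / "config.yaml")
    counts = {"genes": len(reference.genes),
              "planted_snps": diploid.n_sites,
              "reads": len(reads)}
    counts.update({f"fragments_{sp}": len(v) for sp, v in fragments.items()})
    _log("simulate", f"{counts}")
    return counts


# ---------------------------------------------------------------------------
# stage: match

def _query_species(cfg: PipelineConfig) -> list[str]:
    return [cfg.sim.ingroup_a, cfg.sim.outgroup]


def stage_match(cfg: PipelineConfig, out: Path) -> dict:
    d = out / "match"
    d.mkdir(parents=True, exist_ok=True)
    db = dict(io.read_fasta(out / "sim" / "db_cdna.fasta"))
    index = orthomatch.index_reference(db, cfg.match)
    counts = {}
    for sp in _query_species(cfg):
        frags = io.read_fasta(out / "sim" / f"fragments_{sp}.fasta")
        all_hits: dict[str, list[orthomatch.Hit]] = {}
        for fid, seq in frags:
            all_hits[fid] = orthomatch.search(seq, index, cfg.match, fid)
        assignment = orthomatch.assign_orthologs(all_hits, cfg.match)
        lines = orthomatch.hits_to_tabular(
            [h for hits in all_hits.values() for h in hits])
        (d / f"hits_{sp}.tsv").write_text("\n".join(lines) + "\n" if lines else "")
        rows = []
        for fid in sorted(assignment.assigned):
            gene = assignment.assigned[fid]
            hit = assignment.hits[fid]
            rows.append({"fragment": fid, "gene": gene or "NA",
                         "strand": hit.strand if hit else "NA",
                         "evalue": hit.evalue if hit else float("nan"),
                         "identity": hit.identity if hit else float("nan")})
        io.write_tsv(pd.DataFrame(
            rows, columns=["fragment", "gene", "strand", "evalue", "identity"]),
            d / f"assignments_{sp}.tsv")
        counts[f"assigned_{sp}"] = assignment.n_assigned
        counts[f"fragments_{sp}"] = len(frags)
        _log("match", f"{sp}: {assignment.n_assigned}/{len(frags)} fragments assigned")
    return counts


# ---------------------------------------------------------------------------
# stage: align

def _cds_window(model: synthgen.GeneModel) -> tuple[int, int]:
    """CDS start/end inside the spliced transcript (cDNA coordinates)."""
    u5 = sum(e - s for s, e in model.utr5_intervals)
    clen = sum(e - s for s, e in model.cds_intervals)
    return u5, u5 + clen


def stage_align(cfg: PipelineConfig, out: Path) -> dict:
    sim = cfg.sim
    d = out / "align"
    d.mkdir(parents=True, exist_ok=True)
    db_cdna = dict(io.read_fasta(out / "sim" / "db_cdna.fasta"))
    db_cds = dict(io.read_fasta(out / "sim" / "db_cds.fasta"))
    genes, _ = io.read_gff3(out / "sim" / "genes.gff3")
    by_id = {g.gene_id: g for g in genes}

    consensuses: dict[str, dict[str, codonalign.SpeciesConsensus]] = {}
    for sp in _query_species(cfg):
        frags = dict(io.read_fasta(out / "sim" / f"fragments_{sp}.fasta"))
        asg = io.read_tsv(out / "match" / f"assignments_{sp}.tsv")
        per_gene: dict[str, list[codonalign.CoordAlignment]] = {}
        for _, row in asg.iterrows():
            if row["gene"] == "NA":
                continue
            seq = frags[row["fragment"]]
            if row["strand"] == "-":
                seq = synthgen.revcomp(seq)
            ca = codonalign.align_affine(seq, db_cdna[row["gene"]],
                                         row["fragment"], row["gene"])
            per_gene.setdefault(row["gene"], []).append(
                codonalign.repair_frame(ca))
        cons: dict[str, codonalign.SpeciesConsensus] = {}
        for gene_id in sorted(per_gene):
            cons[gene_id] = codonalign.build_consensus(
                per_gene[gene_id], len(db_cdna[gene_id]), sp)
        consensuses[sp] = cons
        io.write_fasta(((g, c.chars) for g, c in sorted(cons.items())),
                       d / f"consensus_{sp}.fasta")

    def cds_slice(sp: str, gene_id: str):
        c = consensuses[sp].get(gene_id)
        if c is None:
            return None
        lo, hi = _cds_window(by_id[gene_id])
        return codonalign.SpeciesConsensus(gene_id, sp, c.chars[lo:hi],
                                           c.support[lo:hi])

    sets = {
        f"{sim.ingroup_b}_{sim.ingroup_a}": (sim.ingroup_a,),
        f"{sim.ingroup_b}_{sim.outgroup}": (sim.outgroup,),
        "trio": (sim.ingroup_a, sim.outgroup),
    }
    counts = {"genes_with_fragments": len(
        set().union(*(set(c) for c in consensuses.values())))}
    manifest_rows = []
    for label, species in sets.items():
        records = []
        kept = rejected = 0
        for gene_id in sorted(db_cds):
            slices = [cds_slice(sp, gene_id) for sp in species]
            if any(s is None for s in slices):
                continue
            aln = codonalign.build_codon_alignment(
                db_cds[gene_id], slices, reference_name=sim.ingroup_b,
                min_len=cfg.align_min_len)
            if aln is None:
                rejected += 1
                continue
            kept += 1
            for sp in aln.species:
                records.append((f"{gene_id}|{sp}", aln.rows[sp]))
            manifest_rows.append({"set": label, "gene": gene_id,
                                  "species": ";".join(aln.species),
                                  "length_bp": aln.length_bp})
        io.write_fasta(records, d / f"codon_{label}.fasta")
        counts[f"aligned_{label}"] = kept
        counts[f"rejected_{label}"] = rejected
        _log("align", f"{label}: {kept} genes aligned, {rejected} rejected "
             f"(< {cfg.align_min_len} bp)")
    io.write_tsv(pd.DataFrame(
        manifest_rows, columns=["set", "gene", "species", "length_bp"]),
        d / "manifest.tsv")
    return counts


def _read_codon_set(path) -> dict[str, codonalign.CodonAlignment]:
    rows: dict[str, dict[str, str]] = {}
    order: dict[str, list[str]] = {}
    for rid, seq in io.read_fasta(path):
        gene_id, sp = rid.split("|")
        rows.setdefault(gene_id, {})[sp] = seq
        order.setdefault(gene_id, []).append(sp)
    out = {}
    for gene_id, row in rows.items():
        n = len(next(iter(row.values()))) // 3
        out[gene_id] = codonalign.CodonAlignment(
            gene_id, tuple(order[gene_id]), row, tuple(range(n)))
    return out


# ---------------------------------------------------------------------------
# stage: rates

def stage_rates(cfg: PipelineConfig, out: Path) -> dict:
    sim = cfg.sim
    d = out / "rates"
    d.mkdir(parents=True, exist_ok=True)
    pair_ba = _read_codon_set(out / "align" /
                              f"codon_{sim.ingroup_b}_{sim.ingroup_a}.fasta")
    pair_bo = _read_codon_set(out / "align" /
                              f"codon_{sim.ingroup_b}_{sim.outgroup}.fasta")
    trio = _read_codon_set(out / "align" / "codon_trio.fasta")

    rows = []
    for gene_id in sorted(pair_ba):
        aln = pair_ba[gene_id]
        if cfg.rates_method == "ml":
            r = ratesel.ml_pairwise(aln)
        else:
            r = ratesel.counting_rate(aln)
        rows.append({"gene": gene_id, "method": r.method, "omega": r.omega,
                     "dN": r.dN, "dS": r.dS, "t": r.t, "kappa": r.kappa,
                     "lnl": r.lnl, "dS_zero": r.dS_zero,
                     "boundary": r.boundary})
    io.write_tsv(pd.DataFrame(rows, columns=[
        "gene", "method", "omega", "dN", "dS", "t", "kappa", "lnl",
        "dS_zero", "boundary"]), d / "rates.tsv")

    deep_rows = [{"gene": g, "omega": ratesel.counting_rate(a).omega}
                 for g, a in sorted(pair_bo.items())]
    io.write_tsv(pd.DataFrame(deep_rows, columns=["gene", "omega"]),
                 d / "rates_deep.tsv")

    bt_rows = []
    for focal in cfg.branch_focals:
        results = [ratesel.branch_test(trio[g], focal) for g in sorted(trio)]
        qs = ratesel.adjust_fdr([r.p for r in results], cfg.fdr_method)
        for r, q in zip(results, qs):
            r.q = q
            bt_rows.append({"gene": r.gene_id, "focal": focal,
                            "lnl_null": r.lnl_null, "lnl_alt": r.lnl_alt,
                            "lrt": r.lrt, "p": r.p, "q": r.q,
                            "direction": r.direction,
                            "omega_background": r.omega_background,
                            "omega_focal": r.omega_focal})
    io.write_tsv(pd.DataFrame(bt_rows, columns=[
        "gene", "focal", "lnl_null", "lnl_alt", "lrt", "p", "q", "direction",
        "omega_background", "omega_focal"]), d / "branch_tests.tsv")

    pools = {f"{sim.ingroup_b}_{sim.ingroup_a}": pair_ba,
             f"{sim.ingroup_b}_{sim.outgroup}": pair_bo}
    # ingroup_a vs outgroup pairs come from the trio alignments
    pools[f"{sim.ingroup_a}_{sim.outgroup}"] = {
        g: a.pair(sim.ingroup_a, sim.outgroup) for g, a in trio.items()}
    summaries = {}
    for k, (sp_a, sp_b) in enumerate(cfg.bootstrap_pairs):
        label = f"{sp_a}_{sp_b}"
        pool = pools.get(label)
        if pool is None:
            raise PipelineError("rates", f"no alignment pool for pair {label}")
        if len(pool) < cfg.genes_per_rep:
            raise PipelineError(
                "rates", f"bootstrap pool for {label} has {len(pool)} genes "
                f"< genes_per_rep={cfg.genes_per_rep}")
        summary = ratesel.bootstrap_genome_omega(
            list(pool.values()), cfg.n_reps, cfg.genes_per_rep,
            seed=_derived_seed(cfg, k))
        io.write_tsv(pd.DataFrame(
            {"rep": range(1, cfg.n_reps + 1), "omega": summary.omegas}),
            d / f"bootstrap_{label}.tsv")
        summaries[label] = {"mean": summary.mean, "sd": summary.sd,
                            "ci_low": summary.ci_low, "ci_high": summary.ci_high,
                            "n_reps": summary.n_reps,
                            "genes_per_rep": summary.genes_per_rep}
        _log("rates", f"bootstrap {label}: mean omega {summary.mean:.4f} "
             f"(sd {summary.sd:.4f})")
    (d / "bootstrap_summary.json").write_text(
        json.dumps(summaries, sort_keys=True, indent=1) + "\n")
    return {"genes_rated": len(rows),
            "branch_tests": len(bt_rows),
            "bootstrap_pairs": len(summaries)}


# ---------------------------------------------------------------------------
# stage: snps

def stage_snps(cfg: PipelineConfig, out: Path) -> dict:
    sim = cfg.sim
    d = out / "snps"
    d.mkdir(parents=True, exist_ok=True)
    reads = io.read_reads(out / "sim" / f"reads_{sim.ingroup_a}.fasta")
    report = snpscan.filter_reads(reads, cfg.snp)
    cons_records = io.read_fasta(out / "align" / f"consensus_{sim.ingroup_a}.fasta")
    consensus = {g: seq for g, seq in cons_records}
    genes, chromosomes = io.read_gff3(out / "sim" / "genes.gff3")

    index = orthomatch.index_reference(
        {g: s.replace("-", "N") for g, s in consensus.items()}, cfg.read_assign)
    by_gene: dict[str, list[str]] = {}
    n_unassigned = 0
    for rid, seq in report.kept:
        hits = orthomatch.search(seq, index, cfg.read_assign, rid)
        ok = [h for h in hits if h.length >= cfg.read_assign.min_hit_len
              and h.evalue <= cfg.read_assign.max_evalue]
        if not ok:
            n_unassigned += 1
            continue
        by_gene.setdefault(ok[0].gene_id, []).append(seq)
    calls = snpscan.call_het_snps(by_gene, consensus, cfg.snp)
    lifted = snpscan.lift_calls(calls, genes)
    classified = [snpscan.classify_snp(c, genes, dict(chromosomes), cfg.snp)
                  for c in lifted]
    io.write_vcf(classified, chromosomes, d / "snps.vcf")
    fractions = snpscan.compartment_fractions(classified)
    io.write_tsv(pd.DataFrame(
        [{"compartment": k, "fraction": v} for k, v in fractions.items()],
        columns=["compartment", "fraction"]), d / "compartments.tsv")
    fit = snpscan.chromosome_density(classified, chromosomes)
    io.write_tsv(pd.DataFrame(
        [{"chrom": r.chrom, "length": r.length, "snp_count": r.snp_count,
          "snps_per_kb": r.snps_per_kb} for r in fit.rows]),
        d / "density.tsv")
    (d / "density_fit.json").write_text(json.dumps(
        {"slope": fit.slope, "intercept": fit.intercept,
         "r_squared": fit.r_squared}, sort_keys=True) + "\n")
    _log("snps", f"{len(classified)} het SNPs called "
         f"({report.n_short} short / {report.n_homopolymer} homopolymer "
         f"reads filtered, {n_unassigned} unassigned)")
    return {"reads_in": len(reads), "reads_kept": len(report.kept),
            "reads_filtered_short": report.n_short,
            "reads_filtered_homopolymer": report.n_homopolymer,
            "reads_unassigned": n_unassigned,
            "snps_called": len(classified)}


# ---------------------------------------------------------------------------
# stage: enrich

def stage_enrich(cfg: PipelineConfig, out: Path) -> dict:
    d = out / "enrich"
    d.mkdir(parents=True, exist_ok=True)
    rates = io.read_tsv(out / "rates" / "rates.tsv")
    deep = io.read_tsv(out / "rates" / "rates_deep.tsv")
    branch = io.read_tsv(out / "rates" / "branch_tests.tsv")
    term_df = io.read_tsv(out / "sim" / "term_map.tsv")
    genes, _ = io.read_gff3(out / "sim" / "genes.gff3")
    chrom_by_gene = {g.gene_id: g.chrom for g in genes}

    omega = {r["gene"]: (None if pd.isna(r["omega"]) else float(r["omega"]))
             for _, r in rates.iterrows()}
    universe = sorted(omega)
    term_map = {t: (grp["description"].iloc[0], set(grp["gene"]))
                for t, grp in term_df.groupby("term")}

    lists, n_undefined = enrichstats.select_rate_classes(omega)
    for focal, grp in branch.groupby("focal"):
        results = [ratesel.BranchTestResult(
            r["gene"], focal, r["lnl_null"], r["lnl_alt"], r["lrt"], 1,
            r["p"], r["direction"], r["omega_background"], r["omega_focal"],
            q=r["q"]) for _, r in grp.iterrows()]
        for gl in enrichstats.branch_classes(results):
            lists.append(replace(gl, label=f"{gl.label}_{focal}"))
    list_rows = [{"label": gl.label, "threshold": gl.threshold,
                  "n_genes": len(gl.gene_ids),
                  "genes": ";".join(gl.gene_ids)} for gl in lists]
    io.write_tsv(pd.DataFrame(
        list_rows, columns=["label", "threshold", "n_genes", "genes"]),
        d / "gene_lists.tsv")
    for gl in lists:
        df = enrichstats.term_enrichment(gl, universe, term_map)
        io.write_tsv(df, d / f"enrichment_{gl.label}.tsv")

    anova, contrasts = enrichstats.omega_chromosome_stats(
        omega, chrom_by_gene, cfg.contrasts)
    stats_obj = {
        "anova": {"f": anova.f, "p": anova.p, "groups": anova.groups},
        "contrasts": [asdict(c) for c in contrasts],
        "n_undefined_omega": n_undefined,
    }
    (d / "chromosome_stats.json").write_text(
        json.dumps(stats_obj, sort_keys=True, indent=1) + "\n")

    deep_omega = {r["gene"]: (None if pd.isna(r["omega"]) else float(r["omega"]))
                  for _, r in deep.iterrows()}
    try:
        corr = enrichstats.depth_correlation(omega, deep_omega)
        corr_obj = asdict(corr)
    except ValueError as exc:
        corr_obj = {"error": str(exc)}
    (d / "correlation.json").write_text(
        json.dumps(corr_obj, sort_keys=True) + "\n")
    _log("enrich", f"{len(lists)} gene lists; ANOVA p={anova.p:.3g}")
    return {"gene_lists": len(lists), "anova_p": anova.p}


# ---------------------------------------------------------------------------
# stage: report

def stage_report(cfg: PipelineConfig, out: Path) -> dict:
    sim = cfg.sim
    report: dict = {}
    frag_lengths = {}
    for sp in _query_species(cfg):
        lengths = [len(s) for _, s in
                   io.read_fasta(out / "sim" / f"fragments_{sp}.fasta")]
        st = enrichstats.assembly_stats(lengths)
        frag_lengths[sp] = lengths
        report.setdefault("assembly", {})[sp] = asdict(st)
    match_counts = {}
    for sp in _query_species(cfg):
        asg = io.read_tsv(out / "match" / f"assignments_{sp}.tsv")
        n = int((asg["gene"] != "NA").sum())
        match_counts[sp] = {"fragments": len(asg), "assigned": n,
                            "rate": n / len(asg) if len(asg) else 0.0}
    report["ortholog_assignment"] = match_counts
    rates = io.read_tsv(out / "rates" / "rates.tsv")
    report["pairwise_rates"] = {
        "n_genes": len(rates),
        "mean_omega": float(rates["omega"].mean()),
        "median_omega": float(rates["omega"].median()),
        "n_omega_gt_1": int((rates["omega"] > 1).sum()),
    }
    branch = io.read_tsv(out / "rates" / "branch_tests.tsv")
    bt = {}
    for focal, grp in branch.groupby("focal"):
        bt[focal] = {
            "n_tested": len(grp),
            "n_p_lt_0.05": int((grp["p"] < 0.05).sum()),
            "n_q_lt_0.05": int((grp["q"] < 0.05).sum()),
            "accelerated_p_lt_0.05": int(
                ((grp["p"] < 0.05) & (grp["direction"] == "accelerated")).sum()),
            "decelerated_p_lt_0.05": int(
                ((grp["p"] < 0.05) & (grp["direction"] == "decelerated")).sum()),
        }
    report["branch_tests"] = bt
    report["bootstrap_omega"] = json.loads(
        (out / "rates" / "bootstrap_summary.json").read_text())
    comp = io.read_tsv(out / "snps" / "compartments.tsv")
    report["snp_compartments"] = {
        r["compartment"]: r["fraction"] for _, r in comp.iterrows()}
    dens = io.read_tsv(out / "snps" / "density.tsv")
    report["chromosome_density"] = {
        "rows": dens.to_dict("records"),
        "fit": json.loads((out / "snps" / "density_fit.json").read_text()),
    }
    report["chromosome_omega"] = json.loads(
        (out / "enrich" / "chromosome_stats.json").read_text())
    report["depth_correlation"] = json.loads(
        (out / "enrich" / "correlation.json").read_text())
    enr = {}
    for gl in io.read_tsv(out / "enrich" / "gene_lists.tsv")["label"]:
        df = io.read_tsv(out / "enrich" / f"enrichment_{gl}.tsv")
        enr[gl] = df.head(5).to_dict("records") if len(df) else []
    report["enrichment_top"] = enr
    (out / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=1, default=float) + "\n")
    if cfg.make_figures:
        _figures(out, frag_lengths, dens)
    return {"sections": 9}


def _figures(out: Path, frag_lengths: dict, dens: pd.DataFrame) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # pragma: no cover - plotting is best-effort
        return
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for sp, lengths in frag_lengths.items():
        ax.hist(lengths, bins=30, alpha=0.5, label=sp)
    ax.set_xlabel("fragment length (bp)")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(fig_dir / "fragment_lengths.png", dpi=100)
    plt.close(fig)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(dens["length"] / 1e3, dens["snp_count"])
    for _, r in dens.iterrows():
        ax.annotate(r["chrom"], (r["length"] / 1e3, r["snp_count"]),
                    fontsize=8)
    ax.set_xlabel("chromosome length (kb)")
    ax.set_ylabel("SNPs detected")
    fig.tight_layout()
    fig.savefig(fig_dir / "snp_density.png", dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# orchestration

STAGES = {
    "simulate": stage_simulate,
    "match": stage_match,
    "align": stage_align,
    "rates": stage_rates,
    "snps": stage_snps,
    "enrich": stage_enrich,
    "report": stage_report,
}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict[str, dict]

    def validate(self) -> None:
        sim = self.stages.get("simulate", {})
        aln = self.stages.get("align", {})
        rates = self.stages.get("rates", {})
        n_genes = sim.get("genes")
        for key, val in aln.items():
            if key.startswith("aligned_") and n_genes is not None:
                if val > n_genes:
                    raise ValueError(f"{key}={val} exceeds gene count {n_genes}")
        if rates and aln:
            pools = [v for k, v in aln.items() if k.startswith("aligned_")]
            if pools and rates.get("genes_rated", 0) > max(pools):
                raise ValueError("genes rated exceeds genes aligned")


def run_stage(name: str, cfg: PipelineConfig, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        return STAGES[name](cfg, out)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc


def run_pipeline(cfg: PipelineConfig, out_dir) -> RunManifest:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = {}
    for name in STAGES:
        _log(name, "starting")
        stages[name] = run_stage(name, cfg, out)
    manifest = RunManifest(config_hash(cfg), cfg.sim.seed, stages)
    manifest.validate()
    (out / "manifest.json").write_text(
        json.dumps(asdict(manifest), sort_keys=True, indent=1) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# round-trip check

def io_roundtrip(path):
    """Parse a supported artifact file, rewrite it, and verify the rewrite
    parses to an equal object. Returns the parsed object."""
    import tempfile

    path = Path(path)
    suffix = path.suffix.lower()
    with tempfile.TemporaryDirectory() as tmp:
        tmp_path = Path(tmp) / path.name
        if suffix in (".fasta", ".fa", ".fastq", ".fq"):
            obj = io.read_reads(path)
            io.write_fasta(obj, tmp_path)
            again = io.read_fasta(tmp_path)
        elif suffix == ".gff3":
            obj = io.read_gff3(path)
            io.write_gff3(obj[0], obj[1], tmp_path)
            again = io.read_gff3(tmp_path)
        elif suffix == ".vcf":
            obj = io.read_vcf(path)
            io.write_vcf(obj[0], obj[1], tmp_path)
            again = io.read_vcf(tmp_path)
        elif suffix in (".tsv", ".txt"):
            obj = io.read_tsv(path)
            io.write_tsv(obj, tmp_path)
            again = io.read_tsv(tmp_path)
        elif suffix in (".yaml", ".yml"):
            obj = io.read_yaml(path)
            io.write_yaml(obj, tmp_path)
            again = io.read_yaml(tmp_path)
        else:
            raise ValueError(f"unsupported format: {path.name}")
        if isinstance(obj, pd.DataFrame):
            if not obj.equals(again):
                raise ValueError(f"round-trip mismatch for {path.name}")
        elif obj != again:
            raise ValueError(f"round-trip mismatch for {path.name}")
    return obj
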