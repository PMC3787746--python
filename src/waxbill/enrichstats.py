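"""Downstream statistics: rate-class gene lists, term over/under-
representation (Fisher exact + one-sided hypergeometric, BH-adjusted),
chromosome-level omega contrasts (one-way ANOVA and one-tailed Welch
t-tests), cross-depth omega correlation, and assembly summary statistics
(mean length and N50)."""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ratesel import adjust_fdr


# ---------------------------------------------------------------------------
# gene lists

@dataclass
class GeneList:
    label: str  # omega_gt_1 | omega_gt_0.8 | top_decile | accelerated_focal | ...
    gene_ids: list[str]
    threshold: Optional[float]


def select_rate_classes(omega_by_gene: dict[str, Optional[float]]):
    """Gene lists for omega > 1, omega > 0.8 and the top decile (threshold
    at the 90th percentile, ties included). Undefined omegas are excluded;
    their count is returned alongside the lists."""
    if not omega_by_gene:
        raise ValueError("empty rate table")
    usable = {g: w for g, w in omega_by_gene.items()
              if w is not None and np.isfinite(w)}
    n_undefined = len(omega_by_gene) - len(usable)
    if not usable:
        raise ValueError("no usable estimates")
    genes = sorted(usable)
    values = np.array([usable[g] for g in genes])
    q90 = float(np.percentile(values, 90))
    lists = [
        GeneList("omega_gt_1", [g for g in genes if usable[g] > 1.0], 1.0),
        GeneList("omega_gt_0.8", [g for g in genes if usable[g] > 0.8], 0.8),
        GeneList("top_decile", [g for g in genes if usable[g] >= q90], q90),
    ]
    return lists, n_undefined


def branch_classes(results, alpha: float = 0.05, use_q: bool = True):
    """Accelerated / decelerated gene lists from branch-test results at the
    given (q- or p-) threshold."""
    acc, dec = [], []
    for r in results:
        score = r.q if use_q else r.p
        if score is not None and score < alpha:
            (acc if r.direction == "accelerated" else dec).append(r.gene_id)
    return [GeneList("accelerated_focal", sorted(acc), alpha),
            GeneList("decelerated_focal", sorted(dec), alpha)]


# ---------------------------------------------------------------------------
# term enrichment

def term_enrichment(gene_list: GeneList, universe: Sequence[str],
                    term_map: dict[str, tuple[str, set[str]]]) -> pd.DataFrame:
    """Per-term 2x2 Fisher exact test (two-sided) plus the one-sided
    hypergeometric p for the observed direction, BH-adjusted across terms.

    term_map: term id -> (description, set of member genes). The layout of
    the output mirrors the familiar total/expected/observed table: expected
    = total * |list| / |universe|.
    """
    universe = set(universe)
    listed = set(gene_list.gene_ids) & universe
    M, n_list = len(universe), len(listed)
    rows = []
    for term in sorted(term_map):
        desc, members = term_map[term]
        members = set(members) & universe
        total = len(members)
        if total == 0:
            continue
        observed = len(members & listed)
        expected = total * n_list / M if M else 0.0
        table = [[observed, n_list - observed],
                 [total - observed, (M - n_list) - (total - observed)]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        if observed >= expected:
            direction = "over"
            p_hyper = float(stats.hypergeom.sf(observed - 1, M, total, n_list))
        else:
            direction = "under"
            p_hyper = float(stats.hypergeom.cdf(observed, M, total, n_list))
        rows.append((term, desc, total, expected, observed, float(p),
                     p_hyper, direction))
    df = pd.DataFrame(rows, columns=["term", "description", "total",
                                     "expected", "observed", "p", "p_hyper",
                                     "direction"])
    df["p_adj"] = adjust_fdr(df["p"].tolist(), "bh") if len(df) else []
    return df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# chromosome-level rate statistics

@dataclass
class AnovaResult:
    f: float
    p: float
    groups: dict[str, int]  # chromosome -> n genes


@dataclass
class ContrastResult:
    group_a: str
    group_b: str
    alternative: str  # "greater" | "less" (one-tailed, a vs b)
    t: float
    p: float
    n_a: int
    n_b: int


def _resolve_group(name, by_chrom):
    if name == "rest":
        raise ValueError("'rest' only allowed as the second group")
    if name not in by_chrom:
        raise ValueError(f"chromosome {name!r} absent from the rate table")
    return by_chrom[name]


def omega_chromosome_stats(omega_by_gene: dict[str, float],
                           chrom_by_gene: dict[str, str],
                           contrasts: Sequence[tuple[str, str, str]] = ()):
    """One-way ANOVA of omega across chromosomes plus one-tailed Welch
    t-tests for ordered contrasts (group_a, 'greater'|'less', group_b);
    group_b may be 'rest' for all other chromosomes pooled."""
    by_chrom: dict[str, list[float]] = {}
    for g, w in omega_by_gene.items():
        if w is None or not np.isfinite(w):
            continue
        by_chrom.setdefault(chrom_by_gene[g], []).append(float(w))
    groups = {c: v for c, v in by_chrom.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 chromosomes with >= 2 genes each")
    f, p = stats.f_oneway(*groups.values())
    anova = AnovaResult(float(f), float(p),
                        {c: len(v) for c, v in sorted(groups.items())})
    results = []
    for a, alternative, b in contrasts:
        va = _resolve_group(a, by_chrom)
        if b == "rest":
            vb = [w for c, v in by_chrom.items() if c != a for w in v]
        else:
            vb = _resolve_group(b, by_chrom)
        t, pt = stats.ttest_ind(va, vb, equal_var=False,
                                alternative=alternative)
        if math.isnan(t) and np.mean(va) == np.mean(vb):
            t, pt = 0.0, 0.5  # degenerate zero-variance tie
        results.append(ContrastResult(a, b, alternative, float(t), float(pt),
                                      len(va), len(vb)))
    return anova, results


# ---------------------------------------------------------------------------
# cross-depth correlation

@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    n_dropped: int


def depth_correlation(omega_shallow: dict[str, Optional[float]],
                      omega_deep: dict[str, Optional[float]]) -> CorrelationResult:
    """Pearson correlation of per-gene omega between a shallow and a deeper
    species comparison, over genes present (and defined) in both."""
    shared = sorted(set(omega_shallow) & set(omega_deep))
    pairs = [(omega_shallow[g], omega_deep[g]) for g in shared]
    clean = [(a, b) for a, b in pairs
             if a is not None and b is not None
             and np.isfinite(a) and np.isfinite(b)]
    if len(clean) < 3:
        raise ValueError(f"only {len(clean)} shared genes with defined omega")
    x, y = zip(*clean)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(clean),
                             len(pairs) - len(clean))


# ---------------------------------------------------------------------------
# assembly statistics

@dataclass
class AssemblyStats:
    n_sequences: int
    total_bp: int
    mean_length: float
    n50: int


def assembly_stats(lengths: Sequence[int]) -> AssemblyStats:
    """N50: the length at which the descending cumulative sum first reaches
    half the total."""
    if not len(lengths):
        raise ValueError("no sequence lengths")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if arr[-1] <= 0:
        raise ValueError("sequence lengths must be positive")
    total = int(arr.sum())
    csum = np.cumsum(arr)
    n50 = int(arr[np.searchsorted(csum, total / 2)])
    return AssemblyStats(len(arr), total, float(arr.mean()), n50)
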