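"""Enrichment and summary statistics: hypergeometric oracles, gene-list
selection, chromosome contrasts, correlation and N50."""
from math import comb

import numpy as np
import pytest
from scipy import stats

from waxbill import enrichstats
from waxbill.enrichstats import GeneList


def test_rate_class_selection():
    omega = {f"g{i}": 0.1 for i in range(9)}
    omega["g9"] = 2.0
    lists, n_undef = enrichstats.select_rate_classes(omega)
    by = {gl.label: gl for gl in lists}
    assert by["omega_gt_1"].gene_ids == ["g9"]
    assert set(by["omega_gt_0.8"].gene_ids) == {"g9"}
    assert n_undef == 0


def test_top_decile_has_at_least_ten_percent(rng):
    omega = {f"g{i:03d}": float(w) for i, w in enumerate(rng.random(100))}
    lists, _ = enrichstats.select_rate_classes(omega)
    top = next(gl for gl in lists if gl.label == "top_decile")
    assert len(top.gene_ids) >= 10
    assert min(omega[g] for g in top.gene_ids) >= top.threshold


def test_all_undefined_omegas_is_an_error():
    with pytest.raises(ValueError, match="usable"):
        enrichstats.select_rate_classes({"g1": None, "g2": float("nan")})
    with pytest.raises(ValueError):
        enrichstats.select_rate_classes({})


def _enrich(universe_n, term_genes, list_genes):
    universe = [f"g{i}" for i in range(universe_n)]
    gl = GeneList("test", [f"g{i}" for i in list_genes], None)
    tm = {"T1": ("t", {f"g{i}" for i in term_genes})}
    return enrichstats.term_enrichment(gl, universe, tm).iloc[0]


def test_hypergeometric_over_representation_example():
    # universe 10, term 5, list 2 fully inside the term: C(5,2)/C(10,2)
    row = _enrich(10, range(5), range(2))
    assert row["p_hyper"] == pytest.approx(comb(5, 2) / comb(10, 2))
    assert row["direction"] == "over"
    assert row["expected"] == pytest.approx(5 * 2 / 10)


def test_hypergeometric_under_representation_example():
    # list of 5 avoiding a 5-gene term entirely: C(5,5)/C(10,5)
    row = _enrich(10, range(5), range(5, 10))
    assert row["p_hyper"] == pytest.approx(comb(5, 5) / comb(10, 5))
    assert row["direction"] == "under"


def test_symmetric_table_fisher_p_is_one():
    # [[1,1],[1,1]]: universe 4, list 2, term 2, observed 1
    row = _enrich(4, range(2), [0, 2])
    assert row["p"] == pytest.approx(1.0)


def test_empty_list_gives_p_one_rows():
    universe = [f"g{i}" for i in range(10)]
    gl = GeneList("empty", [], None)
    tm = {"T1": ("t", set(universe[:4]))}
    df = enrichstats.term_enrichment(gl, universe, tm)
    assert df.iloc[0]["observed"] == 0
    assert df.iloc[0]["p"] == pytest.approx(1.0)


def _oracle_fisher_two_sided(a, b, c, d):
    """Exhaustive enumeration: sum of probabilities of all tables with the
    same margins whose probability <= the observed table's."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def prob(x):
        return (comb(row1, x) * comb(n - row1, col1 - x)) / comb(n, col1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        if prob(x) <= p_obs * (1 + 1e-9):
            total += prob(x)
    return min(total, 1.0)


def test_fisher_matches_enumeration_on_small_margins():
    for n_list in range(0, 9):
        for total in range(0, 9):
            for obs in range(0, min(n_list, total) + 1):
                M = 12
                table = [[obs, n_list - obs],
                         [total - obs, (M - n_list) - (total - obs)]]
                if min(min(r) for r in table) < 0:
                    continue
                _, p = stats.fisher_exact(table)
                assert p == pytest.approx(
                    _oracle_fisher_two_sided(*table[0], *table[1]), abs=1e-9)


def test_random_lists_control_false_positives(rng):
    """Uniform-random gene lists: mean fraction of terms with adjusted
    p < 0.05 stays at or below 0.05."""
    universe = [f"g{i}" for i in range(60)]
    tm = {}
    for t in range(15):
        members = rng.choice(60, size=12, replace=False)
        tm[f"T{t}"] = ("t", {f"g{i}" for i in members})
    fracs = []
    for _ in range(100):
        pick = rng.choice(60, size=10, replace=False)
        gl = GeneList("rand", [f"g{i}" for i in pick], None)
        df = enrichstats.term_enrichment(gl, universe, tm)
        fracs.append((df["p_adj"] < 0.05).mean())
    assert np.mean(fracs) <= 0.05


def test_anova_identical_groups():
    omega = {f"a{i}": v for i, v in enumerate([1.0, 2.0, 3.0])}
    omega.update({f"b{i}": v for i, v in enumerate([1.0, 2.0, 3.0])})
    chrom = {g: ("c1" if g.startswith("a") else "c2") for g in omega}
    anova, contrasts = enrichstats.omega_chromosome_stats(
        omega, chrom, [("c1", "greater", "c2")])
    assert anova.f == pytest.approx(0.0)
    assert anova.p == pytest.approx(1.0)
    assert contrasts[0].t == pytest.approx(0.0)
    assert contrasts[0].p == pytest.approx(0.5)


def test_contrast_against_rest_and_missing_chromosome(rng):
    omega = {}
    chrom = {}
    for c, shift in (("Z", 0.5), ("c1", 0.0), ("c2", 0.0)):
        for i in range(50):
            g = f"{c}_{i}"
            omega[g] = float(rng.normal(0.13 + shift, 0.05))
            chrom[g] = c
    anova, contrasts = enrichstats.omega_chromosome_stats(
        omega, chrom, [("Z", "greater", "rest")])
    assert anova.p < 0.05
    assert contrasts[0].p < 0.05
    with pytest.raises(ValueError, match="nosuch"):
        enrichstats.omega_chromosome_stats(omega, chrom,
                                           [("nosuch", "less", "rest")])


def test_correlation_exact_lines():
    x = {f"g{i}": float(i) for i in range(1, 10)}
    y2 = {g: 2 * v for g, v in x.items()}
    yneg = {g: -v for g, v in x.items()}
    assert enrichstats.depth_correlation(x, y2).r == pytest.approx(1.0)
    assert enrichstats.depth_correlation(x, yneg).r == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        enrichstats.depth_correlation({"g1": 1.0, "g2": 2.0}, {"g1": 1.0})


def test_correlation_recovers_rho(rng):
    rho, n = 0.35, 2000
    cov = [[1, rho], [rho, 1]]
    xy = rng.multivariate_normal([0, 0], cov, size=n)
    x = {f"g{i}": xy[i, 0] for i in range(n)}
    y = {f"g{i}": xy[i, 1] for i in range(n)}
    res = enrichstats.depth_correlation(x, y)
    assert 0.30 <= res.r <= 0.40
    assert res.p < 0.001


@pytest.mark.parametrize("lengths, n50", [
    ([8, 4, 3, 3, 2, 2, 2], 4),
    ([1234], 1234),
    ([7, 7, 7, 7], 7),
])
def test_n50_examples(lengths, n50):
    st = enrichstats.assembly_stats(lengths)
    assert st.n50 == n50
    assert st.total_bp == sum(lengths)
    assert min(lengths) <= st.n50 <= max(lengths)


def test_assembly_stats_validation():
    with pytest.raises(ValueError):
        enrichstats.assembly_stats([])
    with pytest.raises(ValueError):
        enrichstats.assembly_stats([10, 0])
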