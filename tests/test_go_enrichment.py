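"""Fisher test, group aggregation, BY correction, median ratio, table."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
import scipy.stats
from statsmodels.stats.multitest import multipletests

from mycohet import go_enrichment as ge
from mycohet.config import EnrichmentConfig, InputError


def enumeration_fisher(table) -> Fraction:
    """Exact two-sided Fisher p by full enumeration of all tables with
    the observed margins, in rational arithmetic."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(n - r1, c1 - a), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        pk = Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
        if pk <= p_obs:
            total += pk
    return total


def _profile(name, group, gene_terms, clade="c1"):
    return ge.SpeciesProfile(species=name, clade=clade, group=group,
                             gene_terms={g: frozenset(t) for g, t in
                                         gene_terms.items()})


# -- Fisher -----------------------------------------------------------------

def test_fisher_degenerate_table_is_one():
    assert ge.fisher_exact_two_sided([[0, 5], [0, 5]]) == 1.0


def test_fisher_known_value_17_over_35():
    assert ge.fisher_exact_two_sided([[3, 1], [1, 3]]) == pytest.approx(17 / 35)


def test_fisher_negative_count_rejected():
    with pytest.raises(InputError):
        ge.fisher_exact_two_sided([[-1, 2], [3, 4]])


@pytest.mark.parametrize("seed", range(3))
def test_fisher_matches_enumeration_and_scipy_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    for _ in range(50):
        tbl = rng.integers(0, 40, size=(2, 2)).tolist()
        p = ge.fisher_exact_two_sided(tbl)
        assert p == pytest.approx(float(enumeration_fisher(tbl)), rel=1e-9)
        assert p == pytest.approx(scipy.stats.fisher_exact(tbl)[1], rel=1e-7)


# -- pairwise tests and grouping --------------------------------------------

def _two_group_profiles(counts_h, counts_a, n_h=50, n_a=50):
    """Profiles where 'T' annotates the first k genes of each species."""
    profs = []
    for i, k in enumerate(counts_h):
        genes = {f"g{j}": {"T"} if j < k else {"B"} for j in range(n_h)}
        profs.append(_profile(f"h{i}", "heterotroph", genes))
    for i, k in enumerate(counts_a):
        genes = {f"g{j}": {"T"} if j < k else {"B"} for j in range(n_a)}
        profs.append(_profile(f"a{i}", "autotroph", genes))
    return profs


def test_identical_profiles_give_p_one():
    tests = ge.pairwise_term_tests(_two_group_profiles([10, 10], [10, 10, 10]))
    assert all(t.p == pytest.approx(1.0) for t in tests["T"])


def test_pair_count_is_heterotrophs_times_autotrophs():
    tests = ge.pairwise_term_tests(_two_group_profiles([10, 5], [10, 10, 10]))
    assert len(tests["T"]) == 6


def test_term_absent_everywhere_not_tested():
    tests = ge.pairwise_term_tests(_two_group_profiles([0, 0], [0, 0]))
    assert "T" not in tests
    assert "B" in tests  # still tested: margins differ from zero


def test_term_zero_in_one_species_still_tested():
    tests = ge.pairwise_term_tests(_two_group_profiles([0], [10]))
    assert len(tests["T"]) == 1  # total loss is exactly the interesting case


def test_group_significance_bonferroni_max_rule():
    ps = [.001, .002, .004, .02, .03, .04]
    tests = [ge.TermPairTest("T", f"h{i}", "a", ((1, 9), (5, 5)), p, 0.1, 0.5)
             for i, p in enumerate(ps)]
    p_group, direction = ge.group_significance(tests)
    assert p_group == pytest.approx(6 * 0.04)
    assert direction == ge.UNDER


def test_group_significance_single_pair_identity():
    t = ge.TermPairTest("T", "h", "a", ((5, 5), (1, 9)), 0.01, 0.5, 0.1)
    assert ge.group_significance([t]) == (pytest.approx(0.01), ge.OVER)


def test_group_significance_mixed_directions():
    t1 = ge.TermPairTest("T", "h1", "a", ((5, 5), (1, 9)), 0.01, 0.5, 0.1)
    t2 = ge.TermPairTest("T", "h2", "a", ((1, 9), (5, 5)), 0.01, 0.1, 0.5)
    assert ge.group_significance([t1, t2]) == (1.0, ge.MIXED)


# -- Benjamini-Yekutieli ----------------------------------------------------

def by_direct_formula(p):
    """Independent step-up implementation straight from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    c_m = sum(1.0 / k for k in range(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum.accumulate(
        (m * c_m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def test_by_single_p_unchanged():
    assert ge.benjamini_yekutieli([0.2]) == pytest.approx([0.2])


def test_by_two_value_example():
    assert ge.benjamini_yekutieli([0.01, 0.04]) == pytest.approx([0.03, 0.06])


def test_by_rejects_out_of_range():
    with pytest.raises(InputError):
        ge.benjamini_yekutieli([0.5, 1.5])


@pytest.mark.parametrize("seed", range(5))
def test_by_matches_direct_formula_and_dominates_bh(seed):
    rng = np.random.default_rng(seed)
    p = rng.random(rng.integers(1, 200))
    q = ge.benjamini_yekutieli(p)
    assert q == pytest.approx(by_direct_formula(p))
    bh = multipletests(p, method="fdr_bh")[1]
    assert (q >= bh - 1e-12).all()
    # step-up construction: q monotone non-decreasing in sorted-p order
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


# -- median ratio of fractions ----------------------------------------------

def _ratio_tests(h_fracs, a_fracs):
    return [ge.TermPairTest("T", f"h{i}", f"a{j}", ((0, 0), (0, 0)), 1.0, fh, fa)
            for i, fh in enumerate(h_fracs) for j, fa in enumerate(a_fracs)]


def test_median_ratio_identical_fractions_is_one():
    assert ge.median_ratio_of_fractions(_ratio_tests([0.3, 0.3], [0.3])) == 1.0


def test_median_ratio_worked_example():
    got = ge.median_ratio_of_fractions(
        _ratio_tests([0.01, 0.02], [0.04, 0.05, 0.04]))
    assert got == pytest.approx(0.325)


def test_median_ratio_all_heterotroph_zero():
    assert ge.median_ratio_of_fractions(_ratio_tests([0.0], [0.1, 0.2])) == 0.0


def test_median_ratio_infinite_when_autotroph_zero():
    assert math.isinf(ge.median_ratio_of_fractions(_ratio_tests([0.1], [0.0])))


def test_median_ratio_no_eligible_pairs_is_error():
    with pytest.raises(InputError):
        ge.median_ratio_of_fractions(_ratio_tests([0.0], [0.0]))


# -- organellar exclusion ---------------------------------------------------

def test_exclude_organellar_identity_and_counts():
    prof = _profile("s", "autotroph", {f"g{i}": {"T"} for i in range(10)})
    assert ge.exclude_organellar(prof, []).n_total == 10
    cut = ge.exclude_organellar(prof, ["g0", "g1", "nope"])
    assert cut.n_total == 8
    assert cut.term_counts()["T"] == 8


def test_all_genes_excluded_raises_downstream():
    profs = _two_group_profiles([5], [5])
    empty = [ge.exclude_organellar(p, [f"g{i}" for i in range(50)])
             for p in profs]
    with pytest.raises(InputError, match="no annotated genes"):
        ge.pairwise_term_tests(empty)


# -- enrichment table --------------------------------------------------------

def test_enrichment_table_structure_and_ranking(small_study):
    profs = ge.profiles_from_study(small_study.inventories)
    cfg = EnrichmentConfig(
        organellar_exclusion_list=tuple(small_study.inventories.organellar_genes))
    tbl = ge.enrichment_table(profs, cfg)
    tested = ge.pairwise_term_tests(
        [ge.exclude_organellar(p, cfg.organellar_exclusion_list) for p in profs])
    assert len(tbl) == len(tested)  # one row per tested term
    assert (tbl["q"] >= tbl["p_group"] - 1e-12).all()
    assert tbl["q"].is_monotonic_increasing
    # planted depletion: planted terms rank first
    planted = small_study.dag.photosynthesis_like
    assert set(tbl.head(len(planted))["term"]) == planted
    assert (tbl.head(len(planted))["direction"] == ge.UNDER).all()
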