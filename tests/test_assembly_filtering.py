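"""Filtering cascade: isoforms, coverage, ORF selection, taxonomy, RBH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycohet.assembly_filtering import (
    CONTAMINANT, PLANT, classify_taxonomy, filter_low_coverage,
    find_candidate_orfs, reciprocal_best_hits, run_filtering,
    select_major_isoforms, sum_gene_expression,
)
from mycohet.config import FilterConfig, InputError

STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def brute_force_orfs(seq: str) -> list[tuple[str, int, int]]:
    """All maximal stop-free codon runs over six frames as
    (strand, n_codons, start_on_scanned_strand)."""
    out = []
    for strand, s in (("+", seq), ("-", seq[::-1].translate(_COMP))):
        for frame in range(3):
            codons = [s[i:i + 3] for i in range(frame, len(s) - 2, 3)]
            run = 0
            for i, c in enumerate(codons):
                if c in STOPS:
                    if run:
                        out.append((strand, run, frame + 3 * (i - run) + 1))
                    run = 0
                else:
                    run += 1
            if run:
                out.append((strand, run, frame + 3 * (len(codons) - run) + 1))
    return out


# -- major isoforms ---------------------------------------------------------

def _records(rows):
    return pd.DataFrame(rows, columns=["transcript_id", "gene_id", "mapped_reads",
                                       "mean_coverage", "fpkm"])


def test_major_isoform_picks_most_reads_and_breaks_ties_lexicographically():
    df = _records([("i2", "g", 100, 5, 1), ("i1", "g", 50, 5, 1),
                   ("j2", "h", 10, 5, 1), ("j1", "h", 10, 5, 1)])
    assert select_major_isoforms(df) == {"i2", "j1"}


def test_major_isoform_one_per_gene(small_study):
    tbl = small_study.transcripts.table
    sp = tbl[tbl["species"] == small_study.inventories.species[0].species]
    major = select_major_isoforms(sp)
    assert len(major) == sp["gene_id"].nunique()


def test_duplicate_transcript_id_is_input_error():
    df = _records([("i1", "g", 1, 1, 1), ("i1", "g", 2, 1, 1)])
    with pytest.raises(InputError, match="i1"):
        select_major_isoforms(df)


# -- coverage ---------------------------------------------------------------

@pytest.mark.parametrize("cov,kept", [(3.0, True), (2.999, False), (10.0, True)])
def test_coverage_threshold_inclusive(cov, kept):
    df = _records([("i", "g", 1, cov, 1)])
    out = filter_low_coverage(df, FilterConfig())
    assert (len(out) == 1) is kept


def test_coverage_filter_empty_input():
    assert len(filter_low_coverage(_records([]), FilterConfig())) == 0


def test_coverage_filter_idempotent_and_order_invariant(small_study):
    tbl = small_study.transcripts.table
    cfg = FilterConfig()
    once = filter_low_coverage(tbl, cfg)
    twice = filter_low_coverage(once, cfg)
    assert once.equals(twice)
    shuffled = tbl.sample(frac=1.0, random_state=0)
    assert set(filter_low_coverage(shuffled, cfg)["transcript_id"]) \
        == set(once["transcript_id"])


# -- ORF selection ----------------------------------------------------------

# a 32-codon ORF (incl. ATG) whose five alternative frames all contain
# in-core stops, so the reading-frame run is the unique longest ORF
CORE32 = ("ATGCGTTTAGTCTACAAGAATCCTCCTAGTATTGGTAACACCACTACAAACAAGGTGTTCAAC"
          "CCTCAAAGATCGTTGAGGGTTAGTGACGTAAAA")


def test_orf_boundary_thirty_codons_including_start():
    seq = "ATG" + "CTA" * 29 + "TAA"
    orf = find_candidate_orfs("t", seq, min_cds_aa=30)
    assert orf is not None
    assert orf.aa_length == 30
    assert (orf.start, orf.end, orf.strand) == (1, 90, "+")
    assert orf.aa_length == (orf.end - orf.start + 1) // 3


def test_orf_stop_saturated_sequence_yields_none():
    seq = "TAATAGTGA" * 12  # every plus-strand frame is wall-to-wall stops
    longest = max(n for _, n, _ in brute_force_orfs(seq))
    assert find_candidate_orfs("t", seq, min_cds_aa=longest + 1) is None
    # the only stop-free stretches live on the reverse strand
    assert find_candidate_orfs("t", seq, min_cds_aa=1).strand == "-"


def test_orf_illegal_characters_rejected():
    with pytest.raises(InputError, match="t1"):
        find_candidate_orfs("t1", "ATGXXTAA")


def test_orf_domain_hit_rescues_short_orf():
    seq = "TAA" + "ATG" + "GCT" * 8 + "TAG"
    assert find_candidate_orfs("t", seq, min_cds_aa=30) is None
    orf = find_candidate_orfs("t", seq, min_cds_aa=30, domain_hits=[(4, 30, "+")])
    assert orf is not None and orf.has_domain and orf.aa_length < 30


def test_orf_five_prime_complete_requires_upstream_stop_or_context():
    orf = find_candidate_orfs("t", "TAA" + CORE32 + "TAG", min_cds_aa=30)
    assert (orf.strand, orf.frame, orf.aa_length) == ("+", 0, 32)
    assert orf.five_prime_complete  # ATG with an in-frame stop upstream
    edge = find_candidate_orfs("t", CORE32 + "TAG", min_cds_aa=30)
    assert (edge.strand, edge.aa_length) == ("+", 32)
    assert not edge.five_prime_complete  # ATG flush with the transcript edge


@pytest.mark.parametrize("seed", range(5))
def test_orf_selection_matches_brute_force_on_random_2kb(seed):
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))
    orf = find_candidate_orfs("t", seq, min_cds_aa=30)
    best = max(brute_force_orfs(seq), key=lambda t: t[1])
    assert orf is not None
    assert orf.aa_length == best[1]


# -- taxonomy classification ------------------------------------------------

def _hits(rows):
    return pd.DataFrame(rows, columns=["qseqid", "sseqid", "bitscore", "evalue",
                                       "lineage"])


FUNGUS = "Eukaryota;Fungi;Ascomycota"
PLANT_LIN = "Eukaryota;Viridiplantae;Streptophyta;Orchidaceae"


def test_best_hit_decides_contamination():
    hits = _hits([("q", "f", 200.0, 1e-30, FUNGUS), ("q", "p", 150.0, 1e-20, PLANT_LIN)])
    assert classify_taxonomy(hits, FilterConfig()) == CONTAMINANT


def test_no_hits_is_plant():
    assert classify_taxonomy(_hits([]), FilterConfig()) == PLANT


def test_tie_at_top_with_plant_hit_is_plant():
    hits = _hits([("q", "f", 200.0, 1e-30, FUNGUS), ("q", "p", 200.0, 1e-30, PLANT_LIN)])
    assert classify_taxonomy(hits, FilterConfig()) == PLANT


def test_evalue_filter_applied_before_best_hit():
    hits = _hits([("q", "f", 500.0, 1e-3, FUNGUS),  # above threshold: ignored
                  ("q", "p", 100.0, 1e-20, PLANT_LIN)])
    assert classify_taxonomy(hits, FilterConfig()) == PLANT


# -- reciprocal best hits ---------------------------------------------------

def brute_force_rbh(ab: pd.DataFrame, ba: pd.DataFrame) -> set[tuple[str, str]]:
    pairs = set()
    for a in ab["qseqid"].unique():
        sub = ab[ab["qseqid"] == a]
        top = sub[sub["bitscore"] == sub["bitscore"].max()]
        if len(top) != 1:
            continue
        b = top["sseqid"].iloc[0]
        back = ba[ba["qseqid"] == b]
        if len(back) == 0:
            continue
        btop = back[back["bitscore"] == back["bitscore"].max()]
        if len(btop) == 1 and btop["sseqid"].iloc[0] == a:
            pairs.add((a, b))
    return pairs


def test_rbh_perfect_mutual_bests():
    ab = pd.DataFrame(dict(qseqid=["a1", "a2"], sseqid=["b1", "b2"],
                           bitscore=[100.0, 90.0]))
    ba = pd.DataFrame(dict(qseqid=["b1", "b2"], sseqid=["a1", "a2"],
                           bitscore=[100.0, 90.0]))
    assert {(p.gene_a, p.gene_b) for p in reciprocal_best_hits(ab, ba)} \
        == {("a1", "b1"), ("a2", "b2")}


def test_rbh_asymmetric_best_yields_no_pair():
    ab = pd.DataFrame(dict(qseqid=["a"], sseqid=["b"], bitscore=[100.0]))
    ba = pd.DataFrame(dict(qseqid=["b"], sseqid=["a2"], bitscore=[100.0]))
    assert reciprocal_best_hits(ab, ba) == []


def test_rbh_tied_best_disqualifies_query():
    ab = pd.DataFrame(dict(qseqid=["a", "a"], sseqid=["b1", "b2"],
                           bitscore=[100.0, 100.0]))
    ba = pd.DataFrame(dict(qseqid=["b1"], sseqid=["a"], bitscore=[100.0]))
    assert reciprocal_best_hits(ab, ba) == []


def test_rbh_matches_brute_force_on_random_50_gene_tables():
    rng = np.random.default_rng(42)
    genes_a = [f"a{i}" for i in range(50)]
    genes_b = [f"b{i}" for i in range(50)]
    rows_ab = [(a, rng.choice(genes_b), float(rng.integers(50, 500)))
               for a in genes_a for _ in range(rng.integers(1, 4))]
    rows_ba = [(b, rng.choice(genes_a), float(rng.integers(50, 500)))
               for b in genes_b for _ in range(rng.integers(1, 4))]
    ab = pd.DataFrame(rows_ab, columns=["qseqid", "sseqid", "bitscore"])
    ba = pd.DataFrame(rows_ba, columns=["qseqid", "sseqid", "bitscore"])
    got = {(p.gene_a, p.gene_b) for p in reciprocal_best_hits(ab, ba)}
    assert got == brute_force_rbh(ab, ba)


# -- gene expression --------------------------------------------------------

def test_fpkm_sums_over_isoforms():
    df = _records([("i1", "g", 1, 5, 1.5), ("i2", "g", 1, 5, 2.5),
                   ("j1", "h", 1, 5, 4.25)])
    sums = sum_gene_expression(df)
    assert sums["g"] == pytest.approx(4.0)
    assert sums["h"] == pytest.approx(4.25)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.tuples(st.sampled_from("abcd"),
                          st.floats(0, 1e3, allow_nan=False)), min_size=1,
                max_size=30))
def test_fpkm_totals_conserved(rows):
    df = pd.DataFrame([(f"t{i}", g, 1, 5.0, f) for i, (g, f) in enumerate(rows)],
                      columns=["transcript_id", "gene_id", "mapped_reads",
                               "mean_coverage", "fpkm"])
    assert sum_gene_expression(df).sum() == pytest.approx(df["fpkm"].sum())


# -- cascade on noise-free data ---------------------------------------------

def test_cascade_recovers_planted_plant_inventory(noise_free_study):
    study = noise_free_study
    cfg = FilterConfig()
    tax = study.hits.taxonomy
    for spec in study.inventories.species[:2]:
        tbl = study.transcripts.table
        sp_tbl = tbl[tbl["species"] == spec.species]
        rep = run_filtering(sp_tbl, study.transcripts.sequences,
                            tax[tax["qseqid"].isin(sp_tbl["transcript_id"])], cfg)
        assert rep.plant_genes == study.inventories.present_genes(spec.species)
        assert rep.n_contaminant == int(sp_tbl["is_contaminant"].sum())
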