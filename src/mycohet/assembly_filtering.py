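"""Post-assembly filtering and 1-1 orthology.

The filtering cascade mirrors standard transcriptome post-processing for
gene-content comparisons: keep the major (most-read) isoform per gene,
drop low-coverage transcripts, pick one CDS per transcript (longest
qualifying ORF over six frames), classify each CDS as plant or
contaminant from its best taxonomic hit, and compute 1-1 orthologs by
reciprocal best hits against a reference proteome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import FilterConfig, InputError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

PLANT = "PLANT"
CONTAMINANT = "CONTAMINANT"


@dataclass(frozen=True)
class OrfCall:
    """A selected candidate CDS on a transcript.

    Coordinates are 1-based inclusive on the forward transcript; ORFs on
    the reverse strand are reported in transcript coordinates with
    ``strand='-'``.  ``frame`` is the offset (0..2) on the scanned strand.
    """

    transcript_id: str
    start: int
    end: int
    strand: str
    frame: int
    aa_length: int
    has_domain: bool = False
    five_prime_complete: bool = False


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    bit_ab: float
    bit_ba: float


def select_major_isoforms(records: pd.DataFrame) -> set[str]:
    """One transcript per gene: the isoform with the most mapped reads.

    Ties break to the lexicographically smallest transcript_id.
    """
    if records["transcript_id"].duplicated().any():
        dup = records.loc[records["transcript_id"].duplicated(), "transcript_id"].iloc[0]
        raise InputError(f"duplicated transcript_id: {dup}")
    if records.empty:
        return set()
    ordered = records.sort_values(
        ["gene_id", "mapped_reads", "transcript_id"],
        ascending=[True, False, True], kind="mergesort")
    return set(ordered.drop_duplicates("gene_id", keep="first")["transcript_id"])


def filter_low_coverage(records: pd.DataFrame, config: FilterConfig) -> pd.DataFrame:
    """Keep transcripts with mean coverage >= threshold (inclusive)."""
    return records[records["mean_coverage"] >= config.min_mean_coverage]


def _orf_runs(seq: str) -> list[tuple[int, int, int, bool, bool]]:
    """Stop-free codon runs on one strand.

    Yields (frame, start_codon_index, n_codons, starts_with_atg,
    preceded_by_stop) with start measured in codons within the frame.
    """
    runs = []
    n = len(seq)
    for frame in range(3):
        codons = [seq[i:i + 3] for i in range(frame, n - 2, 3)]
        start = 0
        preceded = False
        for i, c in enumerate(codons + ["TAA"]):  # sentinel stop flushes last run
            if c in STOP_CODONS and i < len(codons) or i == len(codons):
                if i > start:
                    runs.append((frame, start, i - start,
                                 codons[start] == "ATG", preceded))
                start = i + 1
                preceded = True
        del codons
    return runs


def find_candidate_orfs(transcript_id: str, sequence: str, min_cds_aa: int = 30,
                        domain_hits: Iterable[tuple[int, int, str]] = (),
                        ) -> OrfCall | None:
    """Select the longest qualifying ORF over all six frames.

    An ORF is a maximal stop-free codon run (5'-partial runs allowed); it
    qualifies if it is at least ``min_cds_aa`` codons long or overlaps a
    supplied domain hit ``(start, end, strand)`` in transcript
    coordinates.  Equal lengths break deterministically: forward strand
    first, then lower frame, then smaller start.
    """
    seq = sequence.upper()
    if not seq or set(seq) - set("ACGTN"):
        raise InputError(f"illegal characters in sequence of {transcript_id}")
    n = len(seq)
    hits = list(domain_hits)
    candidates: list[tuple[int, int, int, OrfCall]] = []
    for strand, s in (("+", seq), ("-", seq[::-1].translate(_COMPLEMENT))):
        for frame, start_codon, n_codons, atg, preceded in _orf_runs(s):
            s_pos = frame + 3 * start_codon + 1           # 1-based on scanned strand
            e_pos = frame + 3 * (start_codon + n_codons)  # inclusive
            if strand == "+":
                start, end = s_pos, e_pos
            else:
                start, end = n - e_pos + 1, n - s_pos + 1
            has_domain = any(
                hs <= end and he >= start and hstrand == strand
                for hs, he, hstrand in hits)
            if n_codons >= min_cds_aa or has_domain:
                five_prime = atg and (preceded or s_pos >= 4)
                call = OrfCall(transcript_id=transcript_id, start=start, end=end,
                               strand=strand, frame=frame, aa_length=n_codons,
                               has_domain=has_domain, five_prime_complete=five_prime)
                order = (0 if strand == "+" else 1, frame, start)
                candidates.append((-n_codons, *order, call))
    if not candidates:
        return None
    return min(candidates, key=lambda t: t[:4])[-1]


def classify_taxonomy(hits: pd.DataFrame, config: FilterConfig) -> str:
    """PLANT unless the single best hit (by bit score) is outside the
    plant clade.  No hits at all -> PLANT; a bit-score tie that includes
    at least one plant hit -> PLANT."""
    if len(hits) == 0:
        return PLANT
    ok = hits[hits["evalue"] <= config.contamination_evalue_max]
    if len(ok) == 0:
        return PLANT
    top = ok[ok["bitscore"] == ok["bitscore"].max()]
    is_plant = top["lineage"].str.split(";").map(
        lambda lin: config.plant_clade_name in [x.strip() for x in lin])
    return PLANT if is_plant.any() else CONTAMINANT


def _unique_best(hits: pd.DataFrame) -> dict[str, tuple[str, float]]:
    """query -> (subject, bitscore) when the top bit score is unique."""
    best: dict[str, tuple[str, float]] = {}
    for q, grp in hits.groupby("qseqid"):
        m = grp["bitscore"].max()
        top = grp[grp["bitscore"] == m]
        if len(top) == 1:
            best[q] = (top["sseqid"].iloc[0], float(m))
    return best


def reciprocal_best_hits(hits_ab: pd.DataFrame, hits_ba: pd.DataFrame,
                         ) -> list[OrthologPair]:
    """(a, b) pairs where b is a's unique best subject and vice versa.

    A bit-score tie for a query's best subject disqualifies that query:
    1-1 orthology requires a unique mutual best.
    """
    best_ab = _unique_best(hits_ab)
    best_ba = _unique_best(hits_ba)
    pairs = []
    for a, (b, bit_ab) in best_ab.items():
        back = best_ba.get(b)
        if back is not None and back[0] == a:
            pairs.append(OrthologPair(gene_a=a, gene_b=b, bit_ab=bit_ab,
                                      bit_ba=back[1]))
    return sorted(pairs, key=lambda p: p.gene_a)


def sum_gene_expression(records: pd.DataFrame) -> pd.Series:
    """Gene-level FPKM: the sum over all of the gene's isoforms."""
    return records.groupby("gene_id")["fpkm"].sum()


@dataclass
class FilterReport:
    species: str
    n_input: int
    n_after_major_isoform: int
    n_after_coverage: int
    n_with_cds: int
    n_plant: int
    n_contaminant: int
    plant_genes: set[str]
    sub_min_cds_rescued: int  # ORFs below min length accepted via a domain hit


def run_filtering(records: pd.DataFrame, sequences: Mapping[str, str],
                  taxonomy_hits: pd.DataFrame, config: FilterConfig,
                  domain_hits: Mapping[str, Sequence[tuple[int, int, str]]] | None = None,
                  ) -> FilterReport:
    """The full cascade for one species' transcript table."""
    domain_hits = domain_hits or {}
    species = records["species"].iloc[0] if len(records) else ""
    n_input = len(records)
    major = select_major_isoforms(records)
    step1 = records[records["transcript_id"].isin(major)]
    step2 = filter_low_coverage(step1, config)

    hit_groups = dict(tuple(taxonomy_hits.groupby("qseqid"))) if len(taxonomy_hits) else {}
    empty_hits = taxonomy_hits.iloc[0:0]
    plant_genes: set[str] = set()
    n_with_cds = n_plant = n_cont = rescued = 0
    for row in step2.itertuples(index=False):
        orf = find_candidate_orfs(row.transcript_id, sequences[row.transcript_id],
                                  min_cds_aa=config.min_cds_aa,
                                  domain_hits=domain_hits.get(row.transcript_id, ()))
        if orf is None:
            continue
        n_with_cds += 1
        if orf.aa_length < config.min_cds_aa:
            rescued += 1
        verdict = classify_taxonomy(hit_groups.get(row.transcript_id, empty_hits),
                                    config)
        if verdict == PLANT:
            n_plant += 1
            plant_genes.add(row.gene_id)
        else:
            n_cont += 1
    return FilterReport(
        species=species, n_input=n_input, n_after_major_isoform=len(step1),
        n_after_coverage=len(step2), n_with_cds=n_with_cds, n_plant=n_plant,
        n_contaminant=n_cont, plant_genes=plant_genes, sub_min_cds_rescued=rescued)
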