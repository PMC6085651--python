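"""Synthetic study generator.

Emulates the inputs of a comparative transcriptome study of fully
mycoheterotrophic plants against photosynthetic references:

* a rooted is_a ontology with a block of "photosynthesis-like" leaf terms;
* per-species gene inventories where heterotrophs preferentially lose the
  genes annotated with planted terms, with a tunable fraction of losses
  shared across all heterotrophs (the parallelism the overlap test detects);
* assembled transcripts with isoform structure, negative-binomial read
  counts, log-normal coverage, planted ORFs and contaminant transcripts
  from non-plant taxa;
* BLAST-tabular-like hit tables (taxonomic best hits; directional tables
  against a reference proteome wired to be reciprocal best hits up to a
  corruption fraction);
* TargetP-like and DualPred-like targeting prediction tables.

Everything is driven by a single integer seed: child streams are spawned
deterministically per stage, so regenerating any stage with the same
config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig
from .ontology import GoDag, propagate_annotations

# Toy taxonomy fixture: best-hit lineages used by the contamination
# classifier. Plants descend from Streptophyta; contaminants do not.
PLANT_LINEAGES = (
    "cellular organisms;Eukaryota;Viridiplantae;Streptophyta;Magnoliopsida;Orchidaceae",
    "cellular organisms;Eukaryota;Viridiplantae;Streptophyta;Magnoliopsida;Ericales",
    "cellular organisms;Eukaryota;Viridiplantae;Streptophyta;Magnoliopsida;Brassicales",
)
CONTAMINANT_LINEAGES = (
    "cellular organisms;Eukaryota;Opisthokonta;Fungi;Basidiomycota;Russulaceae",
    "cellular organisms;Eukaryota;Opisthokonta;Fungi;Ascomycota;Helotiales",
    "cellular organisms;Bacteria;Proteobacteria;Gammaproteobacteria;Pseudomonadales",
    "cellular organisms;Bacteria;Actinobacteria;Streptomycetales",
)

#: configured mixture of TargetP-style reliability classes 1..4 for a
#: supported (non-noise) organellar call.
RELIABILITY_MIXTURE = (0.4, 0.3, 0.2, 0.1)

STOP_CODONS = ("TAA", "TAG", "TGA")


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    """Deterministic per-stage child stream of the config seed."""
    ss = np.random.SeedSequence(config.seed,
                                spawn_key=(zlib.crc32(stage.encode()) % (2 ** 31),))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

def build_synthetic_dag(config: SimulationConfig) -> GoDag:
    """Random rooted is_a DAG with ``planted_terms`` photosynthesis-like leaves.

    Terms are laid out level by level up to ``dag_depth``; every non-root
    term receives one or two parents drawn from shallower levels, so the
    graph is acyclic by construction.  Planted terms are chosen among the
    leaves (preferring the deepest) and flagged, not structurally special —
    under equal loss probabilities they are statistically null like any
    other term.
    """
    config.validate()
    rng = _rng(config, "dag")
    n = config.n_terms
    ids = [f"SYN:{i:07d}" for i in range(1, n + 1)]
    dag = GoDag()
    dag.add_term(ids[0], name="root", namespace="synthetic")
    # depth per non-root term: cycle through 1..dag_depth-ish, then shuffle
    depths = 1 + rng.integers(0, config.dag_depth, size=n - 1)
    by_depth: dict[int, list[str]] = {0: [ids[0]]}
    order = np.argsort(depths, kind="stable")
    for idx in order:
        term = ids[idx + 1]
        d = int(depths[idx])
        shallower = [t for dd in range(d) for t in by_depth.get(dd, [])]
        n_par = 1 if len(shallower) == 1 else int(1 + rng.integers(0, 2))
        parents = rng.choice(len(shallower), size=min(n_par, len(shallower)),
                             replace=False)
        dag.add_term(term, name=f"synthetic term {term}", namespace="synthetic",
                     parents=[shallower[int(p)] for p in parents])
        by_depth.setdefault(d, []).append(term)
    # planted photosynthesis-like terms: deepest leaves first
    def depth_of(t: str) -> int:
        return 0 if t == ids[0] else int(depths[ids.index(t) - 1])

    leaves = sorted(dag.leaves(), key=lambda t: (-depth_of(t), t))
    if config.planted_terms > len(leaves):
        raise ConfigError(
            f"planted_terms: only {len(leaves)} leaves available for "
            f"{config.planted_terms} planted terms")
    dag.photosynthesis_like = set(leaves[: config.planted_terms])
    for t in dag.photosynthesis_like:
        dag.names[t] = f"photosynthesis-like {t}"
    return dag.validate()


# ---------------------------------------------------------------------------
# inventories and annotation
# ---------------------------------------------------------------------------

@dataclass
class SpeciesSpec:
    species: str
    clade: str
    group: str  # "heterotroph" | "autotroph"


@dataclass
class Inventories:
    """Planted truth: who carries which genes, and how they are annotated."""

    species: list[SpeciesSpec]
    genes: list[str]
    direct_annotation: dict[str, frozenset[str]]      # gene -> direct terms
    propagated_annotation: dict[str, frozenset[str]]  # gene -> closed terms
    presence: pd.DataFrame      # bool, index=genes, columns=species
    organellar_genes: list[str]
    planted_genes: list[str]    # genes carrying >=1 photosynthesis-like direct term

    def present_genes(self, species: str) -> set[str]:
        col = self.presence[species]
        return set(col.index[col])


def _species_specs(config: SimulationConfig) -> list[SpeciesSpec]:
    specs = []
    for c in range(config.n_clades):
        clade = f"clade{c + 1}"
        for h in range(config.n_hetero):
            specs.append(SpeciesSpec(f"{clade}_het{h + 1}", clade, "heterotroph"))
        for a in range(config.n_auto):
            specs.append(SpeciesSpec(f"{clade}_aut{a + 1}", clade, "autotroph"))
    return specs


def simulate_inventories(config: SimulationConfig, dag: GoDag) -> Inventories:
    """Draw per-species gene inventories and the gene -> GO annotation.

    Autotrophs carry the full gene set.  A gene annotated with a planted
    (photosynthesis-like) term is lost in each heterotroph with
    probability ``loss_p_planted``, any other gene with
    ``loss_p_background``.  With probability ``shared_loss_frac`` a gene's
    loss indicator is drawn once and shared by *all* heterotrophs
    (correlated loss); otherwise it is drawn independently per species.
    """
    config.validate()
    rng = _rng(config, "inventories")
    genes = [f"g{i:05d}" for i in range(1, config.n_genes + 1)]
    specs = _species_specs(config)

    planted = sorted(dag.photosynthesis_like)
    background_terms = sorted(dag.terms - dag.photosynthesis_like - dag.roots())
    if not background_terms:
        background_terms = sorted(dag.roots())

    direct: dict[str, frozenset[str]] = {}
    planted_genes: list[str] = []
    n_planted_genes = int(round(config.planted_gene_frac * config.n_genes)) if planted else 0
    for i, gene in enumerate(genes):
        if i < n_planted_genes:
            k_planted = int(1 + rng.integers(0, min(2, len(planted))))
            chosen = list(rng.choice(planted, size=k_planted, replace=False))
            k_bg = int(1 + rng.integers(0, 2))
            chosen += list(rng.choice(background_terms,
                                      size=min(k_bg, len(background_terms)),
                                      replace=False))
            planted_genes.append(gene)
        else:
            k = int(1 + rng.integers(0, 4))
            chosen = list(rng.choice(background_terms,
                                     size=min(k, len(background_terms)),
                                     replace=False))
        direct[gene] = frozenset(chosen)

    planted_set = set(planted_genes)
    p_loss = np.where([g in planted_set for g in genes],
                      config.loss_p_planted, config.loss_p_background)

    heteros = [s.species for s in specs if s.group == "heterotroph"]
    shared_mask = rng.random(config.n_genes) < config.shared_loss_frac
    shared_loss = rng.random(config.n_genes) < p_loss

    presence = pd.DataFrame(True, index=genes, columns=[s.species for s in specs])
    for sp in heteros:
        indep_loss = rng.random(config.n_genes) < p_loss
        lost = np.where(shared_mask, shared_loss, indep_loss)
        presence[sp] = ~lost

    n_org = int(round(config.organellar_frac * config.n_genes))
    organellar = list(rng.choice(genes, size=n_org, replace=False)) if n_org else []

    propagated = propagate_annotations(direct, dag)
    return Inventories(
        species=specs, genes=genes, direct_annotation=direct,
        propagated_annotation=propagated, presence=presence,
        organellar_genes=sorted(organellar), planted_genes=planted_genes,
    )


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

_NON_STOP_CODONS = None


def _non_stop_codons() -> list[str]:
    global _NON_STOP_CODONS
    if _NON_STOP_CODONS is None:
        bases = "ACGT"
        _NON_STOP_CODONS = [a + b + c for a in bases for b in bases for c in bases
                            if a + b + c not in STOP_CODONS]
    return _NON_STOP_CODONS


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons-2) random non-stop codons + stop codon."""
    codons = _non_stop_codons()
    body = rng.integers(0, len(codons), size=max(n_codons - 2, 0))
    stop = STOP_CODONS[int(rng.integers(0, 3))]
    return "ATG" + "".join(codons[i] for i in body) + stop


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@dataclass
class TranscriptSet:
    """Transcript table plus sequences; ``table`` columns:

    species, transcript_id, gene_id, mapped_reads, mean_coverage, fpkm,
    is_major (truth), source_taxon (truth lineage used by the hit
    simulator), is_contaminant (truth).
    """

    table: pd.DataFrame
    sequences: dict[str, str] = field(default_factory=dict)
    cds: dict[str, str] = field(default_factory=dict)  # per-gene planted CDS


def simulate_transcripts(config: SimulationConfig, inventories: Inventories,
                         ) -> TranscriptSet:
    config.validate()
    rng = _rng(config, "transcripts")
    # one planted CDS per gene, shared across species (orthologs)
    gene_cds = {
        g: _random_cds(rng, int(rng.integers(config.min_cds_codons,
                                             config.max_cds_codons + 1)))
        for g in inventories.genes
    }
    rows: list[dict] = []
    seqs: dict[str, str] = {}

    def nb_draw(size: int) -> np.ndarray:
        r = config.nb_dispersion
        p = r / (r + config.nb_mean)
        return rng.negative_binomial(r, p, size=size)

    for spec in inventories.species:
        present = [g for g in inventories.genes
                   if inventories.presence.at[g, spec.species]]
        n_iso = 1 + rng.poisson(config.isoform_lambda, size=len(present))
        plant_rows: list[dict] = []
        for g, k in zip(present, n_iso):
            reads = nb_draw(int(k))
            cov = np.exp(rng.normal(config.cov_mu, config.cov_sigma, size=int(k)))
            major = int(np.argmax(reads))  # ties: first (lowest isoform index)
            for j in range(int(k)):
                tid = f"{spec.species}|{g}.i{j + 1}"
                utr5 = _random_nt(rng, int(rng.integers(0, 31)))
                utr3 = _random_nt(rng, int(rng.integers(0, 61)))
                seqs[tid] = utr5 + gene_cds[g] + utr3
                plant_rows.append(dict(
                    species=spec.species, transcript_id=tid, gene_id=g,
                    mapped_reads=int(reads[j]), mean_coverage=float(cov[j]),
                    is_major=(j == major),
                    source_taxon=PLANT_LINEAGES[int(rng.integers(0, len(PLANT_LINEAGES)))],
                    is_contaminant=False,
                ))
        # contaminant transcripts so they make up contamination_frac of the total
        if config.contamination_frac > 0:
            n_plant = len(plant_rows)
            n_cont = int(round(config.contamination_frac * n_plant
                               / (1.0 - config.contamination_frac)))
        else:
            n_cont = 0
        cont_reads = nb_draw(n_cont)
        cont_cov = np.exp(rng.normal(config.cov_mu, config.cov_sigma, size=n_cont))
        for i in range(n_cont):
            cid = f"{spec.species}|CONT{i + 1:05d}"
            gid = f"{spec.species}_CONT{i + 1:05d}"
            seqs[cid] = _random_nt(rng, 30) + _random_cds(
                rng, int(rng.integers(config.min_cds_codons, config.max_cds_codons + 1)))
            plant_rows.append(dict(
                species=spec.species, transcript_id=cid, gene_id=gid,
                mapped_reads=int(cont_reads[i]), mean_coverage=float(cont_cov[i]),
                is_major=True,
                source_taxon=CONTAMINANT_LINEAGES[
                    int(rng.integers(0, len(CONTAMINANT_LINEAGES)))],
                is_contaminant=True,
            ))
        # per-species FPKM from reads and transcript lengths
        df = pd.DataFrame(plant_rows)
        lengths_kb = df["transcript_id"].map(lambda t: len(seqs[t]) / 1000.0)
        total_m = max(df["mapped_reads"].sum(), 1) / 1e6
        df["fpkm"] = df["mapped_reads"] / lengths_kb / total_m
        rows.extend(df.to_dict("records"))

    table = pd.DataFrame(rows)[
        ["species", "transcript_id", "gene_id", "mapped_reads", "mean_coverage",
         "fpkm", "is_major", "source_taxon", "is_contaminant"]]
    return TranscriptSet(table=table, sequences=seqs, cds=gene_cds)


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

@dataclass
class HitTables:
    """``taxonomy``: best-hit rows per transcript CDS (qseqid, sseqid,
    bitscore, evalue, lineage).  ``forward``/``reverse``: directional hit
    tables per species against the reference proteome (gene-level ids)."""

    taxonomy: pd.DataFrame
    forward: dict[str, pd.DataFrame]
    reverse: dict[str, pd.DataFrame]
    true_pairs: dict[str, set[tuple[str, str]]]  # species -> {(gene, ref_gene)}


def reference_protein_id(gene: str) -> str:
    return f"AT_{gene}"


def simulate_hit_tables(config: SimulationConfig, transcripts: TranscriptSet,
                        inventories: Inventories) -> HitTables:
    config.validate()
    rng = _rng(config, "hits")
    tbl = transcripts.table

    # taxonomy best hits: contaminants hit non-plant lineages, plants hit
    # Streptophyta, flipped with probability hit_noise
    n = len(tbl)
    flip = rng.random(n) < config.hit_noise
    tax_rows = []
    for (row, fl) in zip(tbl.itertuples(index=False), flip):
        is_cont = bool(row.is_contaminant) ^ bool(fl)
        if is_cont:
            lineage = CONTAMINANT_LINEAGES[int(rng.integers(0, len(CONTAMINANT_LINEAGES)))]
            sseq = f"contam_prot_{int(rng.integers(0, 10 ** 6)):06d}"
        else:
            lineage = row.source_taxon if not row.is_contaminant else \
                PLANT_LINEAGES[int(rng.integers(0, len(PLANT_LINEAGES)))]
            sseq = f"plant_prot_{int(rng.integers(0, 10 ** 6)):06d}"
        best_bit = float(200 + rng.integers(0, 400))
        tax_rows.append(dict(qseqid=row.transcript_id, sseqid=sseq,
                             bitscore=best_bit, evalue=10.0 ** -float(rng.integers(10, 60)),
                             lineage=lineage))
        # a weaker second hit from the other kingdom, never the best
        other = PLANT_LINEAGES if is_cont else CONTAMINANT_LINEAGES
        tax_rows.append(dict(qseqid=row.transcript_id,
                             sseqid=f"second_{int(rng.integers(0, 10 ** 6)):06d}",
                             bitscore=best_bit - float(10 + rng.integers(0, 50)),
                             evalue=10.0 ** -float(rng.integers(6, 10)),
                             lineage=other[int(rng.integers(0, len(other)))]))
    taxonomy = pd.DataFrame(tax_rows)

    # directional ortholog hit tables per species (gene level)
    forward: dict[str, pd.DataFrame] = {}
    reverse: dict[str, pd.DataFrame] = {}
    true_pairs: dict[str, set[tuple[str, str]]] = {}
    all_refs = [reference_protein_id(g) for g in inventories.genes]
    for spec in inventories.species:
        sp = spec.species
        present = sorted(inventories.present_genes(sp))
        corrupted = rng.random(len(present)) < config.rbh_corruption
        f_rows, r_rows = [], []
        pairs: set[tuple[str, str]] = set()
        for g, bad in zip(present, corrupted):
            ref = reference_protein_id(g)
            top = float(500 + rng.integers(0, 500))
            if bad:
                # best forward hit points at a random wrong reference protein
                wrong = all_refs[int(rng.integers(0, len(all_refs)))]
                if wrong == ref:
                    wrong = all_refs[(all_refs.index(ref) + 1) % len(all_refs)]
                f_rows.append(dict(qseqid=g, sseqid=wrong, bitscore=top,
                                   evalue=1e-50))
                f_rows.append(dict(qseqid=g, sseqid=ref, bitscore=top - 30.0,
                                   evalue=1e-40))
            else:
                f_rows.append(dict(qseqid=g, sseqid=ref, bitscore=top, evalue=1e-50))
                pairs.add((g, ref))
            r_rows.append(dict(qseqid=ref, sseqid=g, bitscore=top, evalue=1e-50))
            # background off-target noise hits, always below the best
            if len(present) > 1:
                other = present[int(rng.integers(0, len(present)))]
                if other != g:
                    r_rows.append(dict(qseqid=ref, sseqid=other,
                                       bitscore=top - float(50 + rng.integers(0, 100)),
                                       evalue=1e-20))
        forward[sp] = pd.DataFrame(f_rows)
        reverse[sp] = pd.DataFrame(r_rows)
        true_pairs[sp] = pairs
    return HitTables(taxonomy=taxonomy, forward=forward, reverse=reverse,
                     true_pairs=true_pairs)


# ---------------------------------------------------------------------------
# targeting predictions
# ---------------------------------------------------------------------------

@dataclass
class TargetingTruth:
    signals: dict[str, str]      # protein_id -> planted signal
    predictions: pd.DataFrame    # one row per protein x variant x tool


def assign_targeting_signals(config: SimulationConfig, protein_ids: list[str],
                             rng: np.random.Generator | None = None) -> dict[str, str]:
    rng = rng if rng is not None else _rng(config, "signals")
    cuts = np.cumsum([config.frac_dual, config.frac_plastid_signal,
                      config.frac_mito_signal, config.frac_secretory])
    u = rng.random(len(protein_ids))
    labels = np.select(
        [u < cuts[0], u < cuts[1], u < cuts[2], u < cuts[3]],
        ["dual", "plastid", "mitochondrion", "secretory"], default="none")
    return dict(zip(protein_ids, labels))


def _classA_row(rng, signal: str, noise: float) -> tuple[str, int]:
    """TargetP-like (localization, reliability class)."""
    if rng.random() < noise:
        signal = ["plastid", "mitochondrion", "secretory", "none"][int(rng.integers(0, 4))]
    if signal == "none":
        return "other", 5
    loc = signal if signal != "dual" else ("plastid", "mitochondrion")[int(rng.integers(0, 2))]
    rc = 1 + int(rng.choice(4, p=RELIABILITY_MIXTURE))
    return loc, rc


def _classB_row(rng, signal: str, noise: float) -> tuple[float, str]:
    """DualPred-like (dual_score, single_call)."""
    if rng.random() < noise:
        signal = ["dual", "plastid", "mitochondrion", "none"][int(rng.integers(0, 4))]
    if signal == "dual":
        return float(0.5 + 0.5 * rng.random()), "plastid"
    score = float(0.5 * rng.random())
    if signal in ("plastid", "mitochondrion"):
        return score, signal
    return score, "other"


def simulate_targeting(config: SimulationConfig, protein_ids: list[str],
                       signals: dict[str, str] | None = None) -> TargetingTruth:
    """Emit classA/classB prediction rows per protein and variant.

    All proteins get a ``full`` variant; a random ~20% get a ``truncated``
    (alternative translation start) variant and proteins may get one
    ``isoform`` variant.  Non-noise variant rows agree with the planted
    signal of the protein.
    """
    config.validate()
    rng = _rng(config, "targeting")
    if signals is None:
        signals = assign_targeting_signals(config, protein_ids, rng)
    rows = []
    for pid in protein_ids:
        sig = signals[pid]
        variants = ["full"]
        if rng.random() < 0.2:
            variants.append("truncated")
        if rng.random() < 0.2:
            variants.append("isoform:1")
        for var in variants:
            loc, rc = _classA_row(rng, sig, config.targeting_noise)
            rows.append(dict(protein_id=pid, variant=var, tool="classA",
                             localization=loc, reliability=rc,
                             dual_score=np.nan, single_call=""))
            score, call = _classB_row(rng, sig, config.targeting_noise)
            rows.append(dict(protein_id=pid, variant=var, tool="classB",
                             localization="", reliability=0,
                             dual_score=score, single_call=call))
    return TargetingTruth(signals=dict(signals), predictions=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# ribosomal-substitute search inputs and branch-model fits
# ---------------------------------------------------------------------------

@dataclass
class SubstituteInputs:
    """Inputs for the plastome-lost ribosomal substitute search."""

    hmm_hits: pd.DataFrame                    # protein_id, family, evalue
    family_to_lost_gene: dict[str, str]
    one_to_one_orthologs: dict[str, set[str]]  # lost gene -> 1-1 ortholog proteins
    planted_substitutes: dict[str, str]        # lost gene -> planted substitute protein


def simulate_substitute_inputs(config: SimulationConfig, n_lost: int = 5,
                               ) -> SubstituteInputs:
    """A toy family/HMM-hit structure around ``n_lost`` lost plastid genes.

    Each lost ribosomal gene gets: its own 1-1 ortholog protein (to be
    excluded), one true substitute (a distant homolog hitting the family
    well below the e-value threshold) and one decoy hit above it.
    """
    config.validate()
    rng = _rng(config, "substitutes")
    rows, fam_map, orthos, planted = [], {}, {}, {}
    for i in range(1, n_lost + 1):
        lost = f"rpl{i:02d}"
        fam = f"FAM{i:05d}"
        fam_map[fam] = lost
        ortho = f"prot_ortho_{lost}"
        orthos[lost] = {ortho}
        rows.append(dict(protein_id=ortho, family=fam,
                         evalue=10.0 ** -float(rng.integers(30, 60))))
        sub = f"prot_sub_{lost}"
        planted[lost] = sub
        rows.append(dict(protein_id=sub, family=fam,
                         evalue=10.0 ** -float(rng.integers(8, 25))))
        rows.append(dict(protein_id=f"prot_decoy_{lost}", family=fam,
                         evalue=10.0 ** -float(2 + rng.random() * 2)))  # above 1e-5
    return SubstituteInputs(hmm_hits=pd.DataFrame(rows),
                            family_to_lost_gene=fam_map,
                            one_to_one_orthologs=orthos,
                            planted_substitutes=planted)


def simulate_branch_fits(config: SimulationConfig, n_select_genes: int = 50,
                         relaxed_frac: float = 0.2) -> pd.DataFrame:
    """Branch-model likelihood fits for a subset of genes.

    Null genes get a free-model improvement of chi-square(1)/2 (the LRT
    null), relaxed genes a large planted improvement with an elevated
    heterotroph dN/dS.  Columns match the selection stage's input
    contract; a ``true_shift`` column records the planted truth.
    """
    config.validate()
    rng = _rng(config, "branch_fits")
    rows = []
    for i in range(1, n_select_genes + 1):
        gene = f"sel_g{i:04d}"
        relaxed = rng.random() < relaxed_frac
        lnl0 = -1000.0 - 200.0 * rng.random()
        if relaxed:
            delta = 8.0 + rng.exponential(6.0)
            dnds_h = 0.3 + 0.5 * rng.random()
            dnds_a = 0.05 + 0.1 * rng.random()
        else:
            delta = rng.chisquare(1) / 2.0
            dnds_a = 0.05 + 0.1 * rng.random()
            dnds_h = dnds_a * (0.9 + 0.2 * rng.random())
        ds = float(0.05 + rng.random() * 0.6)
        common = dict(gene_id=gene, dnds_hetero=round(dnds_h, 4),
                      dnds_auto=round(dnds_a, 4), dS=round(ds, 3),
                      true_shift="relaxed" if relaxed else "none")
        rows.append(dict(model_label="constrained", lnL=lnl0, n_params=40, **common))
        rows.append(dict(model_label="free", lnL=lnl0 + delta, n_params=41, **common))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundle + file output
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    config: SimulationConfig
    dag: GoDag
    inventories: Inventories
    transcripts: TranscriptSet
    hits: HitTables
    targeting: TargetingTruth
    substitutes: SubstituteInputs
    branch_fits: pd.DataFrame


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Run every generator stage under the single config seed."""
    dag = build_synthetic_dag(config)
    inv = simulate_inventories(config, dag)
    tx = simulate_transcripts(config, inv)
    hits = simulate_hit_tables(config, tx, inv)
    # targeting predictions for the reference proteome (one protein per gene)
    prot_ids = [reference_protein_id(g) for g in inv.genes]
    targ = simulate_targeting(config, prot_ids)
    subs = simulate_substitute_inputs(config)
    fits = simulate_branch_fits(config)
    return SyntheticStudy(config=config, dag=dag, inventories=inv,
                          transcripts=tx, hits=hits, targeting=targ,
                          substitutes=subs, branch_fits=fits)


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every simulated input to text files; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["ontology"] = out / "ontology.obo"
    study.dag.to_obo(paths["ontology"])

    ann = pd.DataFrame(
        [(g, t) for g, terms in sorted(study.inventories.direct_annotation.items())
         for t in sorted(terms)], columns=["gene_id", "term_id"])
    paths["annotation"] = out / "annotation.tsv"
    ann.to_csv(paths["annotation"], sep="\t", index=False)

    paths["presence"] = out / "presence.tsv"
    pres = study.inventories.presence.astype(int)
    pres.insert(0, "has_reference_ortholog", 1)
    pres.to_csv(paths["presence"], sep="\t", index_label="gene_id")

    paths["organellar"] = out / "organellar_genes.txt"
    paths["organellar"].write_text(
        "\n".join(study.inventories.organellar_genes) + "\n")

    paths["transcripts"] = out / "transcripts.tsv"
    study.transcripts.table.to_csv(paths["transcripts"], sep="\t", index=False)

    paths["fasta"] = out / "transcripts.fasta"
    with open(paths["fasta"], "w") as fh:
        for tid, seq in study.transcripts.sequences.items():
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")

    paths["taxonomy_hits"] = out / "taxonomy_hits.tsv"
    study.hits.taxonomy.to_csv(paths["taxonomy_hits"], sep="\t", index=False)
    for sp, df in study.hits.forward.items():
        p = out / f"hits_{sp}_vs_ref.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"forward:{sp}"] = p
    for sp, df in study.hits.reverse.items():
        p = out / f"hits_ref_vs_{sp}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"reverse:{sp}"] = p

    paths["targeting"] = out / "targeting_predictions.tsv"
    study.targeting.predictions.to_csv(paths["targeting"], sep="\t", index=False)

    paths["hmm_hits"] = out / "hmm_hits.tsv"
    study.substitutes.hmm_hits.to_csv(paths["hmm_hits"], sep="\t", index=False)
    paths["orthogroups"] = out / "orthogroups.tsv"
    pd.DataFrame(
        [(lost, ";".join(sorted(m)))
         for lost, m in sorted(study.substitutes.one_to_one_orthologs.items())],
        columns=["lost_gene", "members"],
    ).to_csv(paths["orthogroups"], sep="\t", index=False)
    paths["family_map"] = out / "family_to_lost_gene.tsv"
    pd.DataFrame(sorted(study.substitutes.family_to_lost_gene.items()),
                 columns=["family", "lost_gene"],
                 ).to_csv(paths["family_map"], sep="\t", index=False)

    paths["branch_fits"] = out / "branch_fits.tsv"
    study.branch_fits.to_csv(paths["branch_fits"], sep="\t", index=False)

    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(
        {"config": dataclasses.asdict(study.config)}, indent=2) + "\n")
    return paths
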