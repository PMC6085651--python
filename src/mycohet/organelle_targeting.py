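"""Reconciliation of two organelle-targeting predictors.

classA is a TargetP-style predictor: a localization call (plastid,
mitochondrion, secretory or other) with a reliability class 1-5, 1 being
the most confident; a call is accepted when the class is at most
``max_reliability``.  classB is a DualPred-style predictor: a dual-
targeting score in [0, 1] (dual when >= ``dual_threshold``) plus a
single-compartment call.  A conclusion supported by only one of the two
tools is reported as *contradictory* rather than accepted, so downstream
candidate lists can distinguish solid from single-tool evidence.

Proteins may be scored as several sequence variants: the full protein, a
truncation at an alternative downstream start codon (dual targeting via
alternative translation initiation), and alternative isoforms.  The
per-protein verdict is the highest-precedence verdict over variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .config import InputError, TargetingConfig

PLASTID, MITO, SECRETORY = "plastid", "mitochondrion", "secretory"
DUAL, NONE, CONTRADICTORY = "dual", "none", "contradictory"

#: verdict precedence across sequence variants, strongest first
PRECEDENCE = (DUAL, PLASTID, MITO, SECRETORY, CONTRADICTORY, NONE)


@dataclass(frozen=True)
class TargetingVerdict:
    protein_id: str
    verdict: str
    supporting_variant: str


def truncate_at_alt_start(protein_seq: str, offset: int = 25) -> str | None:
    """Suffix from the first methionine after the first ``offset`` residues.

    The returned sequence keeps that Met as its new initiator (1-based
    position >= offset+1 in the input); None when no such Met exists.
    """
    if not protein_seq:
        raise InputError("empty protein sequence")
    pos = protein_seq.find("M", offset)  # 0-based index >= offset
    if pos == -1:
        return None
    return protein_seq[pos:]


def reconcile_predictions(class_a: Mapping, class_b: Mapping,
                          config: TargetingConfig | None = None) -> str:
    """Verdict for one protein variant from one row of each tool.

    classA rows need ``localization`` and ``reliability``; classB rows
    need ``dual_score`` and ``single_call``.
    """
    config = (config or TargetingConfig()).validate()
    try:
        loc = class_a["localization"]
        rc = int(class_a["reliability"])
        score = float(class_b["dual_score"])
        call = class_b["single_call"]
    except (KeyError, TypeError, ValueError) as exc:
        raise InputError(f"malformed prediction row: {exc}") from exc

    a_accepted = loc in (PLASTID, MITO, SECRETORY) and rc <= config.max_reliability
    b_dual = score >= config.dual_threshold

    if a_accepted:
        if b_dual:
            # dual plus a single-organelle transit peptide is non-contradictory
            return DUAL if loc in (PLASTID, MITO) else CONTRADICTORY
        agrees = call == loc or (loc == SECRETORY and call == "other")
        return loc if agrees else CONTRADICTORY
    # classA rejects: any organellar support from classB alone is single-tool
    if b_dual or call in (PLASTID, MITO):
        if config.accept_single_tool:
            return DUAL if b_dual else call
        return CONTRADICTORY
    return NONE


def aggregate_protein_verdict(protein_id: str,
                              variant_verdicts: Mapping[str, str],
                              ) -> TargetingVerdict:
    """Combine variant verdicts by precedence (dual strongest).

    Ties on the winning verdict resolve to the lexicographically first
    variant name, making the result independent of row order.
    """
    if not variant_verdicts:
        raise InputError(f"no variant verdicts for {protein_id}")
    bad = set(variant_verdicts.values()) - set(PRECEDENCE)
    if bad:
        raise InputError(f"unknown verdict(s) {sorted(bad)} for {protein_id}")
    for verdict in PRECEDENCE:
        hits = sorted(v for v, w in variant_verdicts.items() if w == verdict)
        if hits:
            return TargetingVerdict(protein_id=protein_id, verdict=verdict,
                                    supporting_variant=hits[0])
    raise AssertionError("unreachable")


def verdicts_from_predictions(predictions: pd.DataFrame,
                              config: TargetingConfig | None = None,
                              ) -> dict[str, TargetingVerdict]:
    """Per-protein verdicts from a long prediction table.

    Expects one classA and one classB row per protein x variant (columns:
    protein_id, variant, tool, localization, reliability, dual_score,
    single_call).
    """
    config = (config or TargetingConfig()).validate()
    out: dict[str, TargetingVerdict] = {}
    for pid, grp in predictions.groupby("protein_id"):
        variant_verdicts: dict[str, str] = {}
        for var, rows in grp.groupby("variant"):
            a = rows[rows["tool"] == "classA"]
            b = rows[rows["tool"] == "classB"]
            if len(a) != 1 or len(b) != 1:
                raise InputError(
                    f"protein {pid} variant {var}: need exactly one row per tool")
            variant_verdicts[str(var)] = reconcile_predictions(
                a.iloc[0], b.iloc[0], config)
        out[str(pid)] = aggregate_protein_verdict(str(pid), variant_verdicts)
    return out


def find_candidate_substitutes(hmm_hits: pd.DataFrame,
                               family_to_lost_gene: Mapping[str, str],
                               one_to_one_orthologs: Mapping[str, set[str]],
                               verdicts: Mapping[str, TargetingVerdict],
                               evalue_max: float = 1e-5) -> pd.DataFrame:
    """Nominate nuclear substitutes for ribosomal genes lost from the plastome.

    For each lost plastid gene, candidate proteins are those hitting the
    gene's protein family (HMM hit at e <= ``evalue_max``) while *not*
    being 1-1 orthologs of the plastid gene itself — i.e. more distant
    homologs that could take over the function if they are imported.
    ``one_to_one_orthologs`` maps each lost gene to the protein ids that
    are its 1-1 orthologs.  Candidates whose targeting verdict is plastid
    or dual are flagged import-capable; contradictory ones single-tool.
    """
    rows = []
    for hit in hmm_hits.itertuples(index=False):
        if hit.evalue > evalue_max:
            continue
        lost_gene = family_to_lost_gene.get(hit.family)
        if lost_gene is None:
            continue  # family not mapped to a lost gene: skipped
        if hit.protein_id in one_to_one_orthologs.get(lost_gene, set()):
            continue
        v = verdicts.get(hit.protein_id)
        verdict = v.verdict if v else NONE
        rows.append(dict(
            lost_gene=lost_gene, family=hit.family, protein_id=hit.protein_id,
            evalue=hit.evalue, verdict=verdict,
            import_capable=verdict in (PLASTID, DUAL),
            single_tool=verdict == CONTRADICTORY))
    cols = ["lost_gene", "family", "protein_id", "evalue", "verdict",
            "import_capable", "single_tool"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["lost_gene", "evalue", "protein_id"]).reset_index(drop=True)
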