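"""Group-wise GO-term enrichment between heterotroph and autotroph species.

The procedure, per clade:

1. propagate each gene's direct GO terms to all is_a ancestors;
2. drop organelle-encoded genes (their loss is a property of the plastid
   or mitochondrial genome, not of the nuclear gene set under study);
3. for every GO term and every heterotroph x autotroph species pair,
   compare the number of genes carrying the term via a two-sided Fisher
   exact test on the 2x2 table (with-term / without-term x species);
4. aggregate the pairwise p-values per term with a Bonferroni-style
   group rule that additionally requires every pair to deviate in the
   same direction;
5. control the FDR over terms with the Benjamini-Yekutieli step-up
   procedure, which remains valid under the strong positive dependence
   among nested GO terms;
6. report a median ratio of per-species annotated-gene fractions as the
   effect size.

The Fisher test is computed in-package by the point-probability method
(sum of all tables, at the observed margins, whose probability does not
exceed the observed table's, with a 1e-7 relative tie tolerance) using
log-gamma arithmetic; this matches the convention of mainstream
statistical implementations while being fast enough to run hundreds of
simulated studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .config import EnrichmentConfig, InputError
from .ontology import GoDag, propagate_annotations

UNDER, OVER, MIXED = "under", "over", "mixed"


@dataclass
class SpeciesProfile:
    """One species' propagated annotation within its clade."""

    species: str
    clade: str
    group: str  # "heterotroph" | "autotroph"
    gene_terms: dict[str, frozenset[str]]
    _counts: dict[str, int] | None = field(default=None, repr=False, compare=False)

    @property
    def n_total(self) -> int:
        """Number of genes with at least one GO term."""
        return sum(1 for t in self.gene_terms.values() if t)

    def term_counts(self) -> dict[str, int]:
        if self._counts is None:
            counts: dict[str, int] = {}
            for terms in self.gene_terms.values():
                for t in terms:
                    counts[t] = counts.get(t, 0) + 1
            self._counts = counts
        return self._counts


@dataclass(frozen=True)
class TermPairTest:
    term: str
    hetero_species: str
    auto_species: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p: float
    hetero_fraction: float
    auto_fraction: float


def exclude_organellar(profile: SpeciesProfile, exclusion: Iterable[str],
                       ) -> SpeciesProfile:
    """Drop organelle-encoded genes; n_total is recomputed implicitly."""
    excl = set(exclusion)
    if not excl:
        return profile
    kept = {g: t for g, t in profile.gene_terms.items() if g not in excl}
    return replace(profile, gene_terms=kept, _counts=None)


# ---------------------------------------------------------------------------
# Fisher's exact test (two-sided, point-probability method)
# ---------------------------------------------------------------------------

def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table.

    Sums the hypergeometric point probabilities of every table with the
    observed margins whose probability is at most the observed one (with
    relative tolerance 1e-7 for floating-point ties).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise InputError("negative count in 2x2 table")
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)
    logpmf = (gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
              + gammaln(n - r1 + 1) - gammaln(c1 - k + 1)
              - gammaln(n - r1 - c1 + k + 1)
              - gammaln(n + 1) + gammaln(c1 + 1) + gammaln(n - c1 + 1))
    log_obs = logpmf[a - lo]
    keep = logpmf <= log_obs + math.log1p(1e-7)
    return float(min(1.0, np.exp(logpmf[keep]).sum()))


# ---------------------------------------------------------------------------
# pairwise tests and group aggregation
# ---------------------------------------------------------------------------

def pairwise_term_tests(profiles: Sequence[SpeciesProfile],
                        terms: Iterable[str] | None = None,
                        ) -> dict[str, list[TermPairTest]]:
    """All heterotroph x autotroph Fisher tests, grouped by term.

    A term x pair test is skipped when the term annotates zero genes in
    both species of the pair; a term with no tests at all is omitted.
    """
    heteros = [p for p in profiles if p.group == "heterotroph"]
    autos = [p for p in profiles if p.group == "autotroph"]
    if not heteros or not autos:
        raise InputError("need at least one heterotroph and one autotroph profile")
    if any(p.n_total == 0 for p in profiles):
        empty = next(p.species for p in profiles if p.n_total == 0)
        raise InputError(f"species {empty} has no annotated genes after exclusion")
    if terms is None:
        terms = set().union(*(p.term_counts().keys() for p in profiles))
    out: dict[str, list[TermPairTest]] = {}
    for term in sorted(terms):
        tests = []
        for h in heteros:
            ch = h.term_counts().get(term, 0)
            nh = h.n_total
            for a in autos:
                ca = a.term_counts().get(term, 0)
                na = a.n_total
                if ch == 0 and ca == 0:
                    continue
                tbl = ((ch, nh - ch), (ca, na - ca))
                tests.append(TermPairTest(
                    term=term, hetero_species=h.species, auto_species=a.species,
                    table=tbl, p=fisher_exact_two_sided(tbl),
                    hetero_fraction=ch / nh, auto_fraction=ca / na))
        if tests:
            out[term] = tests
    return out


def group_significance(tests: Sequence[TermPairTest], rule: str = "max",
                       ) -> tuple[float, str]:
    """Bonferroni-style aggregation of one term's pairwise p-values.

    Each pair's direction is the sign of (heterotroph fraction -
    autotroph fraction); equal fractions are compatible with either
    direction.  If the non-zero directions agree the aggregate is
    ``n_pairs * max(p)`` (or ``n_pairs * min(p)`` under rule="min"),
    capped at 1; if they conflict the term is "mixed" with p 1.
    """
    if not tests:
        raise InputError("group_significance requires at least one pairwise test")
    signs = {np.sign(t.hetero_fraction - t.auto_fraction) for t in tests}
    nonzero = signs - {0.0}
    if len(nonzero) > 1:
        return 1.0, MIXED
    n = len(tests)
    ps = [t.p for t in tests]
    p_group = min(1.0, n * (max(ps) if rule == "max" else min(ps)))
    if not nonzero:
        return p_group, MIXED
    return p_group, UNDER if nonzero.pop() < 0 else OVER


def benjamini_yekutieli(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli step-up q-values, valid under dependence."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def median_ratio_of_fractions(tests: Sequence[TermPairTest]) -> float:
    """Median over pairs of (heterotroph fraction / autotroph fraction).

    An autotroph fraction of 0 against a positive heterotroph fraction
    gives an infinite ratio; the median is infinite when either central
    element is infinite.
    """
    ratios = []
    for t in tests:
        if t.hetero_fraction == 0 and t.auto_fraction == 0:
            continue
        if t.auto_fraction == 0:
            ratios.append(math.inf)
        else:
            ratios.append(t.hetero_fraction / t.auto_fraction)
    if not ratios:
        raise InputError("no eligible pairs for the ratio of fractions")
    ratios.sort()
    m = len(ratios)
    if m % 2 == 1:
        return ratios[m // 2]
    lo, hi = ratios[m // 2 - 1], ratios[m // 2]
    if math.isinf(hi):
        return math.inf
    return (lo + hi) / 2.0


def enrichment_table(profiles: Sequence[SpeciesProfile],
                     config: EnrichmentConfig | None = None,
                     ) -> pd.DataFrame:
    """One clade's full enrichment: one row per tested term.

    Columns: term, per-species counts, n_pairs, p_group, q, median_ratio,
    direction, significant.  Sorted by q then median ratio.
    """
    config = (config or EnrichmentConfig()).validate()
    profiles = [exclude_organellar(p, config.organellar_exclusion_list)
                for p in profiles]
    by_term = pairwise_term_tests(profiles)
    rows = []
    for term, tests in by_term.items():
        p_group, direction = group_significance(tests, rule=config.group_rule)
        row = {"term": term, "n_pairs": len(tests), "p_group": p_group,
               "direction": direction,
               "median_ratio": median_ratio_of_fractions(tests)}
        for prof in profiles:
            row[f"count_{prof.species}"] = prof.term_counts().get(term, 0)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["q"] = benjamini_yekutieli(df["p_group"].to_numpy())
    df["significant"] = df["q"] <= config.alpha
    return df.sort_values(["q", "median_ratio"], kind="mergesort").reset_index(drop=True)


def profiles_from_study(inventories, gene_sets: Mapping[str, set[str]] | None = None,
                        ) -> list[SpeciesProfile]:
    """Build per-species profiles from a synthetic study's inventories.

    ``gene_sets`` overrides the per-species gene sets (e.g. the recovered
    inventories after filtering); by default the planted presence matrix
    is used.
    """
    ann = inventories.propagated_annotation
    profiles = []
    for spec in inventories.species:
        genes = (gene_sets[spec.species] if gene_sets is not None
                 else inventories.present_genes(spec.species))
        gene_terms = {g: ann[g] for g in genes if g in ann}
        profiles.append(SpeciesProfile(species=spec.species, clade=spec.clade,
                                       group=spec.group, gene_terms=gene_terms))
    return profiles


def clade_enrichment(profiles: Sequence[SpeciesProfile],
                     config: EnrichmentConfig | None = None,
                     ) -> dict[str, pd.DataFrame]:
    """Run the enrichment separately for every clade present."""
    clades = sorted({p.clade for p in profiles})
    return {c: enrichment_table([p for p in profiles if p.clade == c], config)
            for c in clades}


__all__ = [
    "SpeciesProfile", "TermPairTest", "exclude_organellar",
    "fisher_exact_two_sided", "pairwise_term_tests", "group_significance",
    "benjamini_yekutieli", "median_ratio_of_fractions", "enrichment_table",
    "profiles_from_study", "clade_enrichment", "propagate_annotations",
    "GoDag", "UNDER", "OVER", "MIXED",
]
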