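"""Parallelism of gene losses between independently heterotrophic lineages.

The analysis restricts itself to a *core* gene set — genes with a 1-1
ortholog in the reference proteome that are present in every
photosynthetic species — so that assembly-quality and lineage-specific
effects are removed.  For each pair of heterotrophs it then compares the
sets of core genes each has lost: the observed overlap percentage, the
percentage expected if losses were independent draws, and an upper-tail
hypergeometric p-value computed in log space so that values far below
the float underflow horizon are still meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .config import InputError

LOG10_E = math.log10(math.e)


@dataclass(frozen=True)
class LossOverlapResult:
    species_a: str
    species_b: str
    n_core: int
    n_lost_a: int
    n_lost_b: int
    n_shared: int
    overlap_pct: float
    expected_pct: float
    p_hypergeom: float
    log10_p: float


@dataclass
class PresenceMatrix:
    """Gene x species presence calls plus the reference-ortholog flag."""

    presence: pd.DataFrame                 # bool, index=genes, columns=species
    groups: Mapping[str, str]              # species -> heterotroph/autotroph
    has_reference_ortholog: pd.Series      # bool per gene

    def __post_init__(self) -> None:
        if self.presence.index.duplicated().any():
            raise InputError("duplicate gene ids in presence matrix")
        if self.presence.columns.duplicated().any():
            raise InputError("duplicate species ids in presence matrix")

    def autotrophs(self) -> list[str]:
        return [s for s in self.presence.columns if self.groups[s] == "autotroph"]

    def heterotrophs(self) -> list[str]:
        return [s for s in self.presence.columns if self.groups[s] == "heterotroph"]


def core_gene_set(matrix: PresenceMatrix) -> set[str]:
    """Genes with a reference ortholog present in *every* autotroph."""
    autos = matrix.autotrophs()
    if not autos:
        raise InputError("presence matrix contains no autotroph species")
    keep = matrix.has_reference_ortholog & matrix.presence[autos].all(axis=1)
    return set(matrix.presence.index[keep])


def hypergeometric_upper_tail(N: int, K: int, n: int, k: int,
                              ) -> tuple[float, float]:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), with its log10.

    Summed in log space via log-gamma, so the log10 of the tail is
    accurate far below the smallest representable double.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise InputError(f"inconsistent hypergeometric counts N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0, 0.0
    hi = min(K, n)
    i = np.arange(k, hi + 1)
    logpmf = (gammaln(K + 1) - gammaln(i + 1) - gammaln(K - i + 1)
              + gammaln(N - K + 1) - gammaln(n - i + 1) - gammaln(N - K - n + i + 1)
              - gammaln(N + 1) + gammaln(n + 1) + gammaln(N - n + 1))
    log_p = float(logsumexp(logpmf))
    log_p = min(log_p, 0.0)
    return math.exp(log_p), log_p * LOG10_E


def loss_overlap(core: set[str], lost_a: set[str], lost_b: set[str],
                 species_a: str = "A", species_b: str = "B",
                 denominator: str = "max") -> LossOverlapResult:
    """Observed and expected overlap of two loss sets within the core.

    ``overlap_pct`` is 100 * |A∩B| / max(|A|, |B|) (configurable to the
    smaller set via ``denominator="min"``); ``expected_pct`` replaces the
    intersection with its independence expectation |A|*|B|/N.
    """
    if not lost_a or not lost_b:
        raise InputError("overlap undefined for an empty loss set")
    if not (lost_a <= core and lost_b <= core):
        raise InputError("loss sets must be subsets of the core gene set")
    N = len(core)
    na, nb = len(lost_a), len(lost_b)
    shared = len(lost_a & lost_b)
    denom = max(na, nb) if denominator == "max" else min(na, nb)
    overlap_pct = 100.0 * shared / denom
    expected_pct = 100.0 * (na * nb / N) / denom
    p, log10p = hypergeometric_upper_tail(N, na, nb, shared)
    return LossOverlapResult(
        species_a=species_a, species_b=species_b, n_core=N, n_lost_a=na,
        n_lost_b=nb, n_shared=shared, overlap_pct=overlap_pct,
        expected_pct=expected_pct, p_hypergeom=p, log10_p=log10p)


def pairwise_loss_overlaps(matrix: PresenceMatrix,
                           denominator: str = "max") -> list[LossOverlapResult]:
    """Overlap statistics for every pair of heterotroph species."""
    core = core_gene_set(matrix)
    lost = {sp: {g for g in core if not matrix.presence.at[g, sp]}
            for sp in matrix.heterotrophs()}
    results = []
    for a, b in combinations(matrix.heterotrophs(), 2):
        results.append(loss_overlap(core, lost[a], lost[b], species_a=a,
                                    species_b=b, denominator=denominator))
    return results


def venn_counts(core: set[str], losses: Mapping[str, set[str]]) -> dict[str, int]:
    """The seven region counts of a three-set loss Venn diagram."""
    if len(losses) != 3:
        raise InputError("venn_counts requires exactly three loss sets")
    (sa, A), (sb, B), (sc, C) = sorted(losses.items())
    return {
        f"{sa}_only": len(A - B - C),
        f"{sb}_only": len(B - A - C),
        f"{sc}_only": len(C - A - B),
        f"{sa}&{sb}": len((A & B) - C),
        f"{sa}&{sc}": len((A & C) - B),
        f"{sb}&{sc}": len((B & C) - A),
        f"{sa}&{sb}&{sc}": len(A & B & C),
    }


def matrix_from_inventories(inventories) -> PresenceMatrix:
    """Presence matrix straight from a synthetic study's planted truth."""
    groups = {s.species: s.group for s in inventories.species}
    flags = pd.Series(True, index=inventories.presence.index)
    return PresenceMatrix(presence=inventories.presence.astype(bool),
                          groups=groups, has_reference_ortholog=flags)


def read_presence_tsv(path) -> PresenceMatrix:
    """Read a gene x species 0/1 TSV with a has_reference_ortholog column.

    Heterotroph species are recognized by a ``het`` substring in the
    column name, matching the synthetic generator's naming; supply a
    PresenceMatrix directly for other conventions.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if "has_reference_ortholog" not in df.columns:
        raise InputError("presence TSV lacks a has_reference_ortholog column")
    flags = df.pop("has_reference_ortholog").astype(bool)
    groups = {c: ("heterotroph" if "het" in c else "autotroph") for c in df.columns}
    return PresenceMatrix(presence=df.astype(bool), groups=groups,
                          has_reference_ortholog=flags)
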