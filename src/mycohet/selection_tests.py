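"""Likelihood-ratio tests over externally fitted branch models of dN/dS.

The upstream codon-model fitting (e.g. a two-ratio branch model where
heterotroph terminal branches get their own dN/dS against a constrained
one-ratio model) is out of scope; this module consumes the fitted log
likelihoods and classifies each gene's selection shift on the
heterotroph branches after Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import chi2

from .config import InputError

RELAXED, INTENSIFIED, NO_SHIFT = "relaxed", "intensified", "none"

P_FLOOR = 1e-300  # keep log-scale reporting finite


@dataclass(frozen=True)
class LrtResult:
    gene_id: str
    statistic: float
    df: int
    p: float
    p_adjusted: float
    shift: str


def likelihood_ratio_test(lnl_constrained: float, lnl_free: float,
                          df: int = 1) -> tuple[float, float]:
    """2*(lnL_free - lnL_constrained) against a chi-square(df) upper tail.

    A free-model likelihood slightly below the constrained one is an
    optimizer artifact: the statistic is clamped to 0 with a warning.
    """
    if df < 1:
        raise InputError("likelihood ratio test needs df >= 1")
    delta = 2.0 * (lnl_free - lnl_constrained)
    if delta < -2e-6:
        warnings.warn(
            f"free lnL {lnl_free} below constrained {lnl_constrained}; "
            "statistic clamped to 0 (optimizer artifact)", stacklevel=2)
    stat = max(0.0, delta)
    p = max(float(chi2.sf(stat, df)), P_FLOOR)
    return stat, p


def bonferroni_adjust(p: float, m: int) -> float:
    """min(1, p * m)."""
    if m < 1:
        raise InputError("Bonferroni m must be >= 1")
    return min(1.0, p * m)


def classify_selection_shift(dnds_hetero: float, dnds_auto: float,
                             p_adjusted: float, alpha: float = 0.05) -> str:
    """Significant increase of dN/dS on heterotroph branches -> relaxed;
    significant decrease -> intensified; otherwise no shift."""
    if p_adjusted > alpha or dnds_hetero == dnds_auto:
        return NO_SHIFT
    return RELAXED if dnds_hetero > dnds_auto else INTENSIFIED


def analyze_fits(fits: pd.DataFrame, m: int | None = None,
                 alpha: float = 0.05, ds_saturation: float = 0.5,
                 ) -> pd.DataFrame:
    """Per-gene LRT table from a long model-fit table.

    ``fits`` has one row per gene x model with columns gene_id,
    model_label (constrained/free), lnL, n_params, dnds_hetero,
    dnds_auto, and optionally dS.  df per gene is the parameter-count
    difference, falling back to 1 (the usual two-ratio vs one-ratio
    contrast).  ``m`` defaults to the number of genes tested.  Genes with
    dS above ``ds_saturation`` are flagged, not corrected.
    """
    required = {"gene_id", "model_label", "lnL"}
    missing = required - set(fits.columns)
    if missing:
        raise InputError(f"fits table lacks columns: {sorted(missing)}")
    genes = sorted(fits["gene_id"].unique())
    m_eff = m if m is not None else len(genes)
    rows = []
    for gene in genes:
        grp = fits[fits["gene_id"] == gene]
        con = grp[grp["model_label"] == "constrained"]
        free = grp[grp["model_label"] == "free"]
        if len(con) != 1 or len(free) != 1:
            raise InputError(f"gene {gene}: need one constrained and one free fit")
        con, free = con.iloc[0], free.iloc[0]
        if "n_params" in grp.columns and pd.notna(con.get("n_params")) \
                and pd.notna(free.get("n_params")):
            df_gene = int(free["n_params"]) - int(con["n_params"])
            if df_gene < 1:
                raise InputError(f"gene {gene}: free model must add parameters")
        else:
            df_gene = 1
        stat, p = likelihood_ratio_test(con["lnL"], free["lnL"], df_gene)
        p_adj = bonferroni_adjust(p, m_eff)
        dnds_h = float(free.get("dnds_hetero", float("nan")))
        dnds_a = float(free.get("dnds_auto", float("nan")))
        shift = classify_selection_shift(dnds_h, dnds_a, p_adj, alpha)
        rows.append(dict(gene_id=gene, statistic=stat, df=df_gene, p=p,
                         p_adjusted=p_adj, dnds_hetero=dnds_h, dnds_auto=dnds_a,
                         shift=shift,
                         ds_saturated=bool(free.get("dS", 0) and
                                           float(free.get("dS", 0)) > ds_saturation)))
    return pd.DataFrame(rows)
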