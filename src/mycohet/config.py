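"""Configuration objects shared across pipeline stages.

Each config is a plain dataclass with a ``validate`` method that raises
:class:`ConfigError` naming the offending field, so the CLI can map any
configuration problem to a dedicated exit code.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any


class ConfigError(ValueError):
    """Invalid configuration value; the message names the field."""


class InputError(ValueError):
    """Malformed or inconsistent input data."""


def _check(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {msg}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study generator.

    The defaults emulate the design of the comparative study the pipeline
    targets: per clade, a pair (or single) of fully mycoheterotrophic
    species compared against three photosynthetic references, with a
    planted block of photosynthesis-like GO terms whose member genes are
    preferentially lost in the heterotrophs.
    """

    seed: int = 0
    n_genes: int = 2000
    n_terms: int = 150
    dag_depth: int = 5
    n_clades: int = 2
    n_auto: int = 3          # autotroph (photosynthetic reference) species per clade
    n_hetero: int = 2        # heterotroph species per clade
    planted_terms: int = 8   # photosynthesis-like leaf terms
    planted_gene_frac: float = 0.15  # fraction of genes in the photosynthesis module
    loss_p_planted: float = 0.9
    loss_p_background: float = 0.1
    shared_loss_frac: float = 0.6    # probability a loss is drawn once for all heterotrophs
    contamination_frac: float = 0.2
    isoform_lambda: float = 0.7      # mean extra isoforms per gene (Poisson)
    nb_mean: float = 200.0           # negative-binomial read-count mean
    nb_dispersion: float = 0.5       # negative-binomial size parameter
    cov_mu: float = 2.0              # log-scale mean of per-transcript coverage
    cov_sigma: float = 1.0           # log-scale sd of per-transcript coverage
    frac_plastid_signal: float = 0.15
    frac_mito_signal: float = 0.10
    frac_dual: float = 0.05
    frac_secretory: float = 0.05
    organellar_frac: float = 0.02    # genes flagged as plastome/chondrome-encoded
    hit_noise: float = 0.0           # P(best taxonomy hit points to the wrong kingdom)
    rbh_corruption: float = 0.0      # P(a gene's directional best hit is corrupted)
    targeting_noise: float = 0.0     # P(a targeting prediction contradicts the signal)
    min_cds_codons: int = 40
    max_cds_codons: int = 200

    _PROB_FIELDS = (
        "loss_p_planted", "loss_p_background", "shared_loss_frac",
        "contamination_frac", "planted_gene_frac", "frac_plastid_signal",
        "frac_mito_signal", "frac_dual", "frac_secretory", "organellar_frac",
        "hit_noise", "rbh_corruption", "targeting_noise",
    )

    def validate(self) -> "SimulationConfig":
        for name in self._PROB_FIELDS:
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, name, f"probability must lie in [0, 1], got {v}")
        _check(self.n_genes >= 1, "n_genes", "must be >= 1")
        _check(self.n_terms >= 1, "n_terms", "must be >= 1")
        _check(self.dag_depth >= 1, "dag_depth", "must be >= 1")
        _check(self.n_terms >= self.dag_depth, "n_terms", "must be >= dag_depth")
        _check(self.n_clades >= 1, "n_clades", "must be >= 1")
        _check(self.n_hetero >= 1, "n_hetero", "must be >= 1")
        _check(self.n_auto >= 2, "n_auto", "must be >= 2")
        _check(self.planted_terms >= 0, "planted_terms", "must be >= 0")
        _check(self.planted_terms <= self.n_terms - 1, "planted_terms",
               "must leave at least the root unplanted")
        _check(self.isoform_lambda >= 0, "isoform_lambda", "must be >= 0")
        _check(self.nb_mean > 0, "nb_mean", "must be > 0")
        _check(self.nb_dispersion > 0, "nb_dispersion", "must be > 0")
        _check(self.cov_sigma >= 0, "cov_sigma", "must be >= 0")
        _check(self.frac_plastid_signal + self.frac_mito_signal
               + self.frac_dual + self.frac_secretory <= 1.0,
               "frac_plastid_signal", "targeting signal fractions must sum to <= 1")
        _check(3 <= self.min_cds_codons <= self.max_cds_codons,
               "min_cds_codons", "need 3 <= min_cds_codons <= max_cds_codons")
        return self

    @classmethod
    def noise_free(cls, **overrides: Any) -> "SimulationConfig":
        """A configuration with every corrupting process switched off.

        Coverage is made deterministic and above the default filter
        threshold, so the filtering pipeline should recover the planted
        plant inventory exactly.
        """
        base = dict(hit_noise=0.0, rbh_corruption=0.0, targeting_noise=0.0,
                    cov_sigma=0.0, cov_mu=2.5)
        base.update(overrides)
        return cls(**base).validate()


@dataclass
class FilterConfig:
    """Post-assembly filtering thresholds."""

    min_mean_coverage: float = 3.0
    min_cds_aa: int = 30
    contamination_evalue_max: float = 1e-5
    plant_clade_name: str = "Streptophyta"

    def validate(self) -> "FilterConfig":
        _check(self.min_mean_coverage > 0, "min_mean_coverage", "must be > 0")
        _check(self.min_cds_aa > 0, "min_cds_aa", "must be > 0")
        _check(self.contamination_evalue_max > 0, "contamination_evalue_max", "must be > 0")
        _check(bool(self.plant_clade_name), "plant_clade_name", "must be non-empty")
        return self


@dataclass
class EnrichmentConfig:
    """Group-wise GO enrichment settings."""

    alpha: float = 0.05
    organellar_exclusion_list: tuple[str, ...] = ()
    #: "max": p_group = n_pairs * max(p) requiring all pair directions to agree;
    #: "min": n_pairs * min(p). The conservative "max" rule is the default.
    group_rule: str = "max"

    def validate(self) -> "EnrichmentConfig":
        _check(0 < self.alpha < 1, "alpha", "must lie in (0, 1)")
        _check(self.group_rule in ("max", "min"), "group_rule", "must be 'max' or 'min'")
        return self


@dataclass
class TargetingConfig:
    """Organelle-targeting reconciliation settings."""

    max_reliability: int = 4     # TargetP-style class accepted if <= this (1 = best)
    dual_threshold: float = 0.5  # DualPred-style score called dual if >= this
    truncation_offset: int = 25  # first Met strictly after this many residues
    #: if True, a call supported by only one of the two tools is accepted
    #: instead of being labelled contradictory.
    accept_single_tool: bool = False

    def validate(self) -> "TargetingConfig":
        _check(1 <= self.max_reliability <= 5, "max_reliability", "must lie in 1..5")
        _check(0 < self.dual_threshold <= 1, "dual_threshold", "must lie in (0, 1]")
        _check(self.truncation_offset >= 0, "truncation_offset", "must be >= 0")
        return self


@dataclass
class PipelineConfig:
    """Top-level orchestration config; round-trips through JSON."""

    outdir: str = "mycohet_out"
    seed: int = 0
    alpha: float = 0.05
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filtering: FilterConfig = field(default_factory=FilterConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    targeting: TargetingConfig = field(default_factory=TargetingConfig)

    def validate(self) -> "PipelineConfig":
        _check(0 < self.alpha < 1, "alpha", "must lie in (0, 1)")
        self.simulation.validate()
        self.filtering.validate()
        self.enrichment.validate()
        self.targeting.validate()
        return self

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["enrichment"]["organellar_exclusion_list"] = list(
            d["enrichment"]["organellar_exclusion_list"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = SimulationConfig(**d.pop("simulation", {}))
        filt = FilterConfig(**d.pop("filtering", {}))
        enr = d.pop("enrichment", {})
        enr = EnrichmentConfig(**{**enr, "organellar_exclusion_list":
                                  tuple(enr.get("organellar_exclusion_list", ()))})
        targ = TargetingConfig(**d.pop("targeting", {}))
        return cls(simulation=sim, filtering=filt, enrichment=enr, targeting=targ, **d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        try:
            return cls.from_dict(json.loads(Path(path).read_text()))
        except (TypeError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot parse pipeline config {path}: {exc}") from exc
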