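"""Configuration for the synthetic study generator.

A :class:`SimConfig` fixes every parameter of the simulated study: the gene
map, the TWAS panels, the liability-threshold case-control model, the
expression-correlation block structure, and the drug-gene interaction
database.  All generators are pure functions of ``(config, seed)``.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Any

import yaml

__all__ = ["SimConfig"]


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic transcriptomic case-control study.

    Defaults describe the study conditions the package is designed around:
    two array platforms of 2000 cases + 2000 controls each, a lifetime
    disease prevalence of 1/300, a true expression score explaining 5 % of
    liability variance, and gene-gene correlation confined to 500 kb blocks.
    """

    # gene map and panels
    n_genes: int = 1000
    n_panels: int = 4
    panel_strata: tuple[str, ...] = ("blood", "blood", "brain", "brain")
    n_signal_genes: int = 50
    signal_z_mean: float = 6.0
    panel_sign_agreement: float = 1.0

    # target cohorts (per platform)
    n_cases: int = 2000
    n_controls: int = 2000
    n_platforms: int = 2
    prevalence_K: float = 1.0 / 300.0
    target_liability_r2: float = 0.05

    # correlation structure
    block_size: int = 5
    within_block_r: float = 0.5
    cross_panel_r: float = 0.9
    window_bp: int = 500_000

    # drug-gene interaction database
    n_drugs: int = 200
    genes_per_drug_mean: float = 8.0
    n_enriched_drugs: int = 10
    n_deleterious_drugs: int = 0

    # fine-mapping credible sets
    n_credible_sets: int = 5
    n_decoy_credible_sets: int = 3

    # nuisance structure
    null_heidi_small_frac: float = 0.5
    platform_shift: float = 0.2
    platform_dropout: float = 0.10

    # clinical phenotypes of cases (effects per SD of the true score)
    onset_site_beta: float = 0.4
    onset_age_beta: float = 2.0
    onset_age_mean: float = 60.0
    onset_age_sd: float = 10.0
    survival_beta: float = -4.0
    survival_mean: float = 36.0
    survival_sd: float = 12.0
    survival_units: str = "months"

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence_K < 1.0:
            raise ValueError("prevalence_K must lie in (0, 1)")
        if not 0.0 <= self.target_liability_r2 < 1.0:
            raise ValueError("target_liability_r2 must lie in [0, 1)")
        if not abs(self.within_block_r) < 1.0:
            raise ValueError("|within_block_r| must be < 1")
        if not abs(self.cross_panel_r) < 1.0:
            raise ValueError("|cross_panel_r| must be < 1")
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes cannot exceed n_genes")
        for name in ("n_genes", "n_panels", "n_cases", "n_controls",
                     "n_platforms", "block_size", "window_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_signal_genes", "n_drugs", "n_enriched_drugs",
                     "n_deleterious_drugs", "n_credible_sets",
                     "n_decoy_credible_sets"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.panel_strata) != self.n_panels:
            raise ValueError("panel_strata must have n_panels entries")
        if any(s not in ("blood", "brain") for s in self.panel_strata):
            raise ValueError("panel strata must be 'blood' or 'brain'")
        if not 0.0 <= self.panel_sign_agreement <= 1.0:
            raise ValueError("panel_sign_agreement must lie in [0, 1]")
        if self.platform_dropout * self.n_platforms > 0.9:
            raise ValueError("platform_dropout too large for disjoint "
                             "per-platform dropout sets")

    # -- panel naming -----------------------------------------------------
    @property
    def panels(self) -> tuple[str, ...]:
        """Panel labels, e.g. ``blood_0 blood_1 brain_2 brain_3``."""
        return tuple(f"{s}_{i}" for i, s in enumerate(self.panel_strata))

    # -- (de)serialisation ------------------------------------------------
    def replace(self, **kwargs: Any) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["panel_strata"] = list(self.panel_strata)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        if "panel_strata" in d:
            d["panel_strata"] = tuple(d["panel_strata"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """SHA-256 of the canonical JSON form (used in run manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
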