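"""Configuration objects for the synthetic study and the scoring pipeline.

Every knob of the generator and of the score computation lives in one of the
frozen dataclasses below, so that a (config, seed) pair fully determines the
outputs. Configs round-trip through plain dictionaries (and hence YAML).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace
from typing import Sequence

import yaml

__all__ = [
    "EffectModel",
    "SimulationConfig",
    "ScoringConfig",
    "config_hash",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class EffectModel:
    """Coefficients linking gene covariates to the fitness effect of loss.

    The latent deleteriousness of gene *g* is

        d_g = intercept + b_expr * z(log2 expression) + b_degree * z(log2 degree)
              + b_heteromer * [g in heteromer pair] - b_paralog * [g paralog]
              + eps,   eps ~ N(0, noise_sd)

    and the fitness effect (log2 depletion per population doubling, <= 0
    meaning deleterious) is ``f_g = -softplus(d_g)``. Positive ``b_expr`` /
    ``b_degree`` make highly expressed, highly connected genes more
    deleterious to lose; ``b_paralog`` buffers duplicated genes, emulating
    paralog compensation.
    """

    intercept: float = 0.0
    b_expr: float = 0.35
    b_degree: float = 0.35
    b_heteromer: float = 0.4
    b_paralog: float = 0.8
    noise_sd: float = 0.4


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic screen generator.

    Defaults emulate a scaled-down version of a multi-screen CRISPR
    loss-of-function meta-analysis: three screen datasets of 3 + 3 + 1 cell
    lines, ~2,000 genes of which 60% sit in 600 paralog pairs, 5 guides per
    gene and negative-binomial sequencing counts.
    """

    n_genes: int = 2000
    paralog_fraction: float = 0.6
    singleton_fraction: float = 0.25
    heteromer_fraction_of_pairs: float = 0.15
    homomer_rate: float = 0.2
    ancestral_homomer_rate: float = 0.5
    n_cell_lines: Sequence[int] = (3, 3, 1)
    guides_per_gene: int = 5
    multi_hit_rate: float = 0.2
    multi_hit_ds_max: float = 1.0
    ds_scale: float = 1.5
    ds_max: float = 5.0
    n_age_groups: int = 5
    library_size: float = 500.0
    count_dispersion: float = 0.15
    doublings: float = 8.0
    effect_model: EffectModel = field(default_factory=EffectModel)
    asymmetry_coupling: float = 0.6
    # expression model (log2 scale)
    expr_mean: float = 3.0
    expr_sd: float = 1.5
    het_expr_shift: float = 1.0
    pair_halfdiff_sd: float = 1.2
    het_pair_halfdiff_sd: float = 0.4
    coexpr_weight: float = 0.2
    het_coexpr_weight: float = 0.6
    line_effect_sd: float = 0.3
    expr_noise_sd: float = 0.5
    # degree model (natural-log scale of partner counts)
    degree_log_mean: float = 2.1
    degree_log_sd: float = 0.8
    het_degree_shift: float = 0.7
    degree_slack: float = 0.35
    # protein expression
    protein_line_fraction: float = 0.1
    protein_slope: float = 1.0
    protein_noise_sd: float = 0.5
    het_protein_shared_sd: float = 0.5
    # gene sets
    n_gene_sets: int = 30
    min_set_pairs: int = 10
    seed: int = 1

    @property
    def n_datasets(self) -> int:
        return len(tuple(self.n_cell_lines))

    @property
    def n_pairs(self) -> int:
        return int(self.n_genes * self.paralog_fraction) // 2

    def validate(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        for name in (
            "paralog_fraction",
            "singleton_fraction",
            "heteromer_fraction_of_pairs",
            "homomer_rate",
            "ancestral_homomer_rate",
            "multi_hit_rate",
            "protein_line_fraction",
            "coexpr_weight",
            "het_coexpr_weight",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_pairs < 1:
            raise ValueError("paralog_fraction yields zero paralog pairs")
        if self.paralog_fraction + self.singleton_fraction > 1.0:
            raise ValueError("paralog_fraction + singleton_fraction exceeds 1")
        if self.guides_per_gene < 1 or any(n < 1 for n in self.n_cell_lines):
            raise ValueError("counts must be >= 1")
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        if self.doublings <= 0:
            raise ValueError("doublings must be > 0")

    def replace(self, **kw) -> "SimulationConfig":
        if "effect_model" in kw and isinstance(kw["effect_model"], dict):
            kw["effect_model"] = replace(self.effect_model, **kw["effect_model"])
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_cell_lines"] = list(self.n_cell_lines)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "effect_model" in d and isinstance(d["effect_model"], dict):
            d["effect_model"] = EffectModel(**d["effect_model"])
        if "n_cell_lines" in d:
            d["n_cell_lines"] = tuple(d["n_cell_lines"])
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class ScoringConfig:
    """Constants of the fold-change/CRISPR-score computation.

    ``pseudocount`` stabilises log fold changes of low-count guides;
    ``scale_total`` is the per-sample read total after library-size
    normalization. The sign convention is fixed so that a lower CRISPR score
    means a more deleterious loss-of-function.
    """

    pseudocount: float = 5.0
    scale_total: float = 1e7
    zscore_ddof: int = 0
    gene_summary: str = "mean"  # or "median"

    def validate(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.scale_total <= 0:
            raise ValueError("scale_total must be > 0")
        if self.gene_summary not in ("mean", "median"):
            raise ValueError("gene_summary must be 'mean' or 'median'")


def config_hash(cfg) -> str:
    """Stable short hash of a config (or any JSON-serialisable dict)."""
    d = cfg.to_dict() if hasattr(cfg, "to_dict") else asdict(cfg)
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def load_config(path) -> SimulationConfig:
    with open(path, encoding="utf-8") as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh))
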