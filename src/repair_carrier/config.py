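"""YAML configuration: threshold overrides, VCF annotation field mapping,
and simulation parameters."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from .qc_filters import QCThresholds
from .synthetic_cohorts import QCNoise, ScoreNoise, SimulationConfig
from .tier_classifier import ClassifierThresholds

__all__ = [
    "load_yaml",
    "qc_thresholds_from",
    "classifier_thresholds_from",
    "simulation_config_from",
    "vcf_field_map_from",
]


def load_yaml(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def qc_thresholds_from(cfg: Mapping) -> QCThresholds:
    section = cfg.get("qc", {})
    return QCThresholds(
        min_frac_bases_20x=section.get("min_frac_bases_20x", 0.30),
        min_allele_fraction=section.get("min_allele_fraction", 0.3),
        min_depth=section.get("min_depth", 12),
        max_read_pos_rank_sum_excl=section.get("max_read_pos_rank_sum_excl", -1.7),
    )


def classifier_thresholds_from(cfg: Mapping) -> ClassifierThresholds:
    section = cfg.get("classifier", {})
    return ClassifierThresholds(
        max_maf=section.get("max_maf", 0.01),
        min_cadd=section.get("min_cadd", 20.0),
        min_revel=section.get("min_revel", 0.75),
    )


def vcf_field_map_from(cfg: Mapping) -> Optional[dict]:
    return cfg.get("vcf_fields")


def simulation_config_from(cfg: Mapping, seed: Optional[int] = None) -> SimulationConfig:
    """Build a SimulationConfig from a YAML mapping; CLI seed wins over file seed."""
    section = cfg.get("simulation", cfg)
    kwargs = {}
    for key in (
        "n_cases",
        "n_controls",
        "variant_catalog_size_per_gene",
        "frac_low_coverage_samples",
        "noise_variants_per_sample",
        "control_noise_variant_rate",
    ):
        if key in section:
            kwargs[key] = section[key]
    if "per_gene_tier_rates" in section:
        kwargs["per_gene_tier_rates"] = {
            g: (float(v[0]), float(v[1]))
            for g, v in section["per_gene_tier_rates"].items()
        }
    if "score_noise" in section:
        kwargs["score_noise"] = ScoreNoise(**section["score_noise"])
    if "qc_noise" in section:
        kwargs["qc_noise"] = QCNoise(**section["qc_noise"])
    kwargs["seed"] = seed if seed is not None else section.get("seed", 0)
    return SimulationConfig(**kwargs)
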