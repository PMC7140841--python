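"""Variant prioritisation: panel restriction, rarity filter, and
Tier 1 / Tier 2 / neutral classification.

The decision procedure, applied to each variant in order:

1. Pre-filter: off-panel genes, intergenic variants, and common variants
   (reference-population MAF > 0.01) are EXCLUDED. An absent MAF is not
   evidence of commonness and does not exclude.
2. ClinVar benign precedence: a variant asserted benign or likely benign,
   with no coexisting pathogenic / likely-pathogenic assertion, is NEUTRAL
   regardless of scores.
3. Tier 1 — protein-truncating variants (stopgain, frameshift indel,
   splice-altering) whose CADD phred is >= 20 *or unannotated* (CADD is
   typically not computed for indels upstream), provided ClinVar asserts
   pathogenic / likely pathogenic, or the truncation disrupts a
   UniProt-reported protein domain.
4. Tier 2 — missense variants asserted pathogenic / likely pathogenic by
   ClinVar, or scoring CADD phred >= 20 *and* REVEL >= 0.75.
5. Anything else is NEUTRAL.

Mixed multi-submitter ClinVar strings count as pathogenic/likely-pathogenic
when any code is 4 or 5; benign precedence applies only when no such code
coexists. All score comparisons are inclusive (>=); the MAF cut is strictly
greater-than.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .variant_model import (
    FuncClass,
    GenePanel,
    RegionClass,
    VariantRecord,
)

__all__ = [
    "Tier",
    "TierReason",
    "ClassifierThresholds",
    "TierAssignment",
    "prefilter",
    "classify",
    "classify_cohort",
]


class Tier(enum.Enum):
    TIER1 = "TIER1"
    TIER2 = "TIER2"
    NEUTRAL = "NEUTRAL"
    EXCLUDED = "EXCLUDED"

    @property
    def is_damaging(self) -> bool:
        return self in (Tier.TIER1, Tier.TIER2)


class TierReason(enum.Enum):
    OFF_PANEL = "off_panel"
    INTERGENIC = "intergenic"
    COMMON = "common"
    CLINVAR_BENIGN = "clinvar_benign"
    TRUNCATING_PLP = "truncating_plp"
    TRUNCATING_DOMAIN = "truncating_domain"
    MISSENSE_PLP = "missense_plp"
    MISSENSE_SCORES = "missense_scores"
    NO_RULE_MET = "no_rule_met"


_VALID_REASONS = {
    Tier.TIER1: {TierReason.TRUNCATING_PLP, TierReason.TRUNCATING_DOMAIN},
    Tier.TIER2: {TierReason.MISSENSE_PLP, TierReason.MISSENSE_SCORES},
    Tier.EXCLUDED: {TierReason.OFF_PANEL, TierReason.INTERGENIC, TierReason.COMMON},
    Tier.NEUTRAL: {TierReason.CLINVAR_BENIGN, TierReason.NO_RULE_MET},
}


@dataclass(frozen=True)
class ClassifierThresholds:
    """Classification thresholds: MAF rarity cut, CADD phred and REVEL minima."""

    max_maf: float = 0.01
    min_cadd: float = 20.0
    min_revel: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 < self.max_maf <= 0.5:
            raise ValueError("max_maf must lie in (0, 0.5]")
        if not 0.0 <= self.min_revel <= 1.0:
            raise ValueError("min_revel must lie in [0, 1]")


@dataclass(frozen=True)
class TierAssignment:
    """Classification outcome for one variant, with a machine-readable reason."""

    variant_key: str
    tier: Tier
    reason: TierReason

    def __post_init__(self) -> None:
        if self.reason not in _VALID_REASONS[self.tier]:
            raise ValueError(f"reason {self.reason} invalid for tier {self.tier}")


def prefilter(
    variant: VariantRecord,
    panel: GenePanel,
    thr: ClassifierThresholds = ClassifierThresholds(),
) -> Optional[TierAssignment]:
    """Exclusion rules applied before tier classification.

    Returns an EXCLUDED assignment, or ``None`` when the variant survives.
    """
    if variant.gene not in panel:
        return TierAssignment(variant.variant_key, Tier.EXCLUDED, TierReason.OFF_PANEL)
    if variant.region_class is RegionClass.INTERGENIC:
        return TierAssignment(variant.variant_key, Tier.EXCLUDED, TierReason.INTERGENIC)
    if variant.maf is not None and variant.maf > thr.max_maf:
        return TierAssignment(variant.variant_key, Tier.EXCLUDED, TierReason.COMMON)
    return None


def classify(
    variant: VariantRecord, thr: ClassifierThresholds = ClassifierThresholds()
) -> TierAssignment:
    """Assign a tier to a variant that survived :func:`prefilter`.

    Total and deterministic: every variant receives exactly one assignment.
    """
    key = variant.variant_key
    if variant.has_benign and not variant.has_plp:
        return TierAssignment(key, Tier.NEUTRAL, TierReason.CLINVAR_BENIGN)

    if variant.func_class.is_truncating:
        cadd_ok = variant.cadd_phred is None or variant.cadd_phred >= thr.min_cadd
        if cadd_ok:
            if variant.has_plp:
                return TierAssignment(key, Tier.TIER1, TierReason.TRUNCATING_PLP)
            if variant.disrupts_domain:
                return TierAssignment(key, Tier.TIER1, TierReason.TRUNCATING_DOMAIN)
    elif variant.func_class is FuncClass.MISSENSE:
        if variant.has_plp:
            return TierAssignment(key, Tier.TIER2, TierReason.MISSENSE_PLP)
        if (
            variant.cadd_phred is not None
            and variant.cadd_phred >= thr.min_cadd
            and variant.revel is not None
            and variant.revel >= thr.min_revel
        ):
            return TierAssignment(key, Tier.TIER2, TierReason.MISSENSE_SCORES)

    return TierAssignment(key, Tier.NEUTRAL, TierReason.NO_RULE_MET)


def classify_cohort(
    variants: Iterable[VariantRecord],
    panel: GenePanel,
    thr: ClassifierThresholds = ClassifierThresholds(),
) -> list[TierAssignment]:
    """Pre-filter then classify each variant; order-preserving."""
    out = []
    for v in variants:
        assignment = prefilter(v, panel, thr)
        if assignment is None:
            assignment = classify(v, thr)
        out.append(assignment)
    return out
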