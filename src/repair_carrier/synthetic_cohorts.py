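"""Synthetic case cohorts and control allele-count tables.

The generator emulates the statistical structure the analysis assumes: each
individual independently carries a qualifying (Tier 1 / Tier 2) mutation per
gene with a configured Bernoulli probability, carriers are assigned a
variant from a per-gene catalog whose annotations *guarantee* the intended
tier under default thresholds, and additional noise variants (common,
ClinVar-benign, sub-threshold scores, off-panel, intergenic) exercise every
exclusion and neutrality rule. Control cohorts are summarised as
ExAC-style allele counts: per gene and tier a Binomial(n_controls, rate)
carrier count split multinomially across the catalog variants.

Intended-tier annotations are constructed by inverting the classifier's
decision rules (drawing each score from the required side of its threshold)
rather than by rejection sampling, so the generator-classifier contract is
deterministic. All randomness flows from `SimulationConfig.seed` through
three named child streams (catalog, cases, controls); the catalog stream is
shared by the case and control generators, so both cohorts draw from the
same variant catalog for a given seed.

Default rates are the per-gene carrier rates observed in the 122-man lethal
case cohort; default cohort sizes (122 cases, 6192 controls) and the
low-coverage sample fraction (10 of 192 sequenced) match the study design
the package models.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .qc_filters import QCThresholds
from .tier_classifier import ClassifierThresholds, Tier
from .variant_model import (
    ClinVarCode,
    CohortGenotypes,
    ControlGeneCounts,
    FilterStatus,
    FuncClass,
    GenePanel,
    RegionClass,
    SampleCoverageQC,
    VariantCallQC,
    VariantRecord,
)

__all__ = [
    "ScoreNoise",
    "QCNoise",
    "SimulationConfig",
    "STUDY_TIER1_RATES",
    "STUDY_TIER2_RATES",
    "study_config",
    "build_variant_catalog",
    "simulate_case_cohort",
    "simulate_control_counts",
]

# Per-gene carrier rates observed among the 122 lethal cases (carriers / 122).
STUDY_TIER1_RATES = {
    "ATM": 4 / 122,
    "CHEK2": 5 / 122,
    "FANCM": 2 / 122,
    "NTHL1": 2 / 122,
    "ERCC3": 1 / 122,
    "RAD18": 1 / 122,
}
STUDY_TIER2_RATES = {
    "ATM": 2 / 122,
    "CHEK2": 1 / 122,
    "ERCC3": 1 / 122,
    "POLG": 5 / 122,
    "TP53": 2 / 122,
    "BRCA1": 1 / 122,
    "HLTF": 1 / 122,
    "POLL": 1 / 122,
    "MRE11A": 1 / 122,
    "RECQL": 1 / 122,
    "FAN1": 1 / 122,
    "NEIL1": 1 / 122,
    "RECQL5": 1 / 122,
    "MUTYH": 0.0,
}


@dataclass(frozen=True)
class ScoreNoise:
    """Annotation-score sampling ranges.

    CADD and REVEL ranges straddle the classification thresholds (20 and
    0.75); the generator draws from the sub-range on the side the intended
    class requires. MAF is log10-uniform; the rare range stays below the
    0.01 commonness cut, the common range above it.
    """

    cadd_range: tuple[float, float] = (5.0, 45.0)
    revel_range: tuple[float, float] = (0.0, 1.0)
    maf_rare_log10: tuple[float, float] = (-6.0, -2.5)
    maf_common: tuple[float, float] = (0.0101, 0.05)
    maf_missing_prob: float = 0.2


@dataclass(frozen=True)
class QCNoise:
    """Call- and sample-level QC field distributions.

    Passing calls draw allele fraction from a Beta centred at 0.5 (folded
    into the passing range), depth as 12 + Poisson so the mean is
    ``depth_mean``, and readPosRankSum from a standard normal folded above
    the -1.7 cut; readPosRankSum is missing with higher probability for
    indels. The ``frac_fail_*`` knobs inject calls that fail exactly one QC
    rule each.
    """

    af_beta: tuple[float, float] = (20.0, 20.0)
    depth_mean: float = 60.0
    rprs_missing_prob_snv: float = 0.1
    rprs_missing_prob_indel: float = 0.9
    frac_fail_vqsr: float = 0.0
    frac_fail_allele_fraction: float = 0.0
    frac_fail_depth: float = 0.0
    frac_fail_rprs: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped simulation parameters; defaults emulate the modelled design."""

    seed: int = 0
    n_cases: int = 122
    n_controls: int = 6192
    per_gene_tier_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            g: (STUDY_TIER1_RATES.get(g, 0.0), STUDY_TIER2_RATES.get(g, 0.0))
            for g in sorted(set(STUDY_TIER1_RATES) | set(STUDY_TIER2_RATES))
        }
    )
    variant_catalog_size_per_gene: int = 3
    score_noise: ScoreNoise = ScoreNoise()
    qc_noise: QCNoise = QCNoise()
    frac_low_coverage_samples: float = 10 / 192
    noise_variants_per_sample: float = 2.0
    control_noise_variant_rate: float = 5e-4

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("cohort sizes must be positive")
        if not 0.0 <= self.frac_low_coverage_samples <= 1.0:
            raise ValueError("frac_low_coverage_samples must lie in [0, 1]")
        for gene, (t1, t2) in self.per_gene_tier_rates.items():
            if not (0.0 <= t1 <= 1.0 and 0.0 <= t2 <= 1.0):
                raise ValueError(f"{gene}: carrier probabilities must lie in [0, 1]")
            if t1 + t2 > 1.0:
                raise ValueError(f"{gene}: tier rates sum to {t1 + t2} > 1")

    def panel(self) -> GenePanel:
        return GenePanel(frozenset(self.per_gene_tier_rates))


_THR = ClassifierThresholds()  # generator inverts the default decision rules

_TRUNCATING_CLASSES = (
    FuncClass.STOPGAIN,
    FuncClass.FRAMESHIFT_INSERTION,
    FuncClass.FRAMESHIFT_DELETION,
    FuncClass.SPLICING,
)
_BASES = ("A", "C", "G", "T")


def _rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    """Named child streams: (catalog, cases, controls)."""
    return (
        np.random.default_rng([seed, 0]),
        np.random.default_rng([seed, 1]),
        np.random.default_rng([seed, 2]),
    )


def _draw_maf(rng: np.random.Generator, sn: ScoreNoise, common: bool) -> Optional[float]:
    if common:
        return float(rng.uniform(*sn.maf_common))
    if rng.random() < sn.maf_missing_prob:
        return None
    lo, hi = sn.maf_rare_log10
    return float(10.0 ** rng.uniform(lo, hi))


def _snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return _BASES[ref], _BASES[alt]


def _make_tier1(
    rng: np.random.Generator, gene: str, idx: int, sn: ScoreNoise
) -> VariantRecord:
    func = _TRUNCATING_CLASSES[rng.integers(len(_TRUNCATING_CLASSES))]
    if func in (FuncClass.STOPGAIN, FuncClass.SPLICING):
        ref, alt = _snv_alleles(rng)
        cadd = float(rng.uniform(_THR.min_cadd, sn.cadd_range[1]))
    else:  # frameshift indels: CADD typically unannotated upstream
        ins = func is FuncClass.FRAMESHIFT_INSERTION
        seq = "".join(_BASES[i] for i in rng.integers(0, 4, rng.integers(1, 4)))
        ref, alt = ("-", seq) if ins else (seq, "-")
        cadd = None
    if rng.random() < 0.5:
        clinvar = frozenset(
            {ClinVarCode.PATHOGENIC}
            if rng.random() < 0.5
            else {ClinVarCode.PATHOGENIC, ClinVarCode.LIKELY_PATHOGENIC}
        )
        domain = None
    else:
        clinvar = frozenset()
        domain = True
    return VariantRecord(
        variant_key=f"sim:{gene}:T1:{idx}:{ref}:{alt}",
        gene=gene,
        func_class=func,
        ref=ref,
        alt=alt,
        clinvar_codes=clinvar,
        cadd_phred=cadd,
        revel=None,
        maf=_draw_maf(rng, sn, common=False),
        disrupts_domain=domain,
    )


def _make_tier2(
    rng: np.random.Generator, gene: str, idx: int, sn: ScoreNoise
) -> VariantRecord:
    ref, alt = _snv_alleles(rng)
    if rng.random() < 0.5:  # ClinVar-supported, scores may sit anywhere
        clinvar = frozenset(
            {ClinVarCode.PATHOGENIC, ClinVarCode.UNCERTAIN}
            if rng.random() < 0.5
            else {ClinVarCode.LIKELY_PATHOGENIC}
        )
        cadd = float(rng.uniform(*sn.cadd_range))
        revel = float(rng.uniform(*sn.revel_range))
    else:  # score-supported: both scores on the damaging side
        clinvar = frozenset()
        cadd = float(rng.uniform(_THR.min_cadd, sn.cadd_range[1]))
        revel = float(rng.uniform(_THR.min_revel, sn.revel_range[1]))
    return VariantRecord(
        variant_key=f"sim:{gene}:T2:{idx}:{ref}:{alt}",
        gene=gene,
        func_class=FuncClass.MISSENSE,
        ref=ref,
        alt=alt,
        clinvar_codes=clinvar,
        cadd_phred=cadd,
        revel=revel,
        maf=_draw_maf(rng, sn, common=False),
    )


def _make_noise(
    rng: np.random.Generator, gene: str, idx: int, sn: ScoreNoise
) -> VariantRecord:
    """A variant that must come out EXCLUDED or NEUTRAL under default rules."""
    kind = rng.integers(5)
    ref, alt = _snv_alleles(rng)
    key = f"sim:{gene}:N{kind}:{idx}:{ref}:{alt}"
    if kind == 0:  # common
        return VariantRecord(
            key, gene, FuncClass.MISSENSE, ref=ref, alt=alt,
            cadd_phred=float(rng.uniform(*sn.cadd_range)),
            revel=float(rng.uniform(*sn.revel_range)),
            maf=_draw_maf(rng, sn, common=True),
        )
    if kind == 1:  # ClinVar benign
        return VariantRecord(
            key, gene, FuncClass.MISSENSE, ref=ref, alt=alt,
            clinvar_codes=frozenset(
                {ClinVarCode.BENIGN} if rng.random() < 0.5 else {ClinVarCode.LIKELY_BENIGN}
            ),
            cadd_phred=float(rng.uniform(*sn.cadd_range)),
            revel=float(rng.uniform(*sn.revel_range)),
            maf=_draw_maf(rng, sn, common=False),
        )
    if kind == 2:  # sub-threshold scores
        low_cadd = rng.random() < 0.5
        return VariantRecord(
            key, gene, FuncClass.MISSENSE, ref=ref, alt=alt,
            cadd_phred=float(
                rng.uniform(sn.cadd_range[0], np.nextafter(_THR.min_cadd, -np.inf))
            )
            if low_cadd
            else float(rng.uniform(_THR.min_cadd, sn.cadd_range[1])),
            revel=float(rng.uniform(_THR.min_revel, sn.revel_range[1]))
            if low_cadd
            else float(
                rng.uniform(sn.revel_range[0], np.nextafter(_THR.min_revel, -np.inf))
            ),
            maf=_draw_maf(rng, sn, common=False),
        )
    if kind == 3:  # off-panel gene
        return VariantRecord(
            f"sim:{gene}:N3:{idx}:{ref}:{alt}", f"OFFPANEL_{gene}", FuncClass.MISSENSE,
            ref=ref, alt=alt,
            cadd_phred=float(rng.uniform(*sn.cadd_range)),
            revel=float(rng.uniform(*sn.revel_range)),
            maf=_draw_maf(rng, sn, common=False),
        )
    return VariantRecord(  # intergenic
        key, gene, FuncClass.OTHER, ref=ref, alt=alt,
        maf=_draw_maf(rng, sn, common=False),
        region_class=RegionClass.INTERGENIC,
    )


def build_variant_catalog(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> dict[str, dict[str, list[VariantRecord]]]:
    """Per-gene catalog: intended-Tier-1, intended-Tier-2 and noise variants.

    Deterministic given ``cfg.seed`` (the catalog child stream is used when
    ``rng`` is not supplied), and shared by the case and control generators.
    """
    if rng is None:
        rng = _rngs(cfg.seed)[0]
    sn = cfg.score_noise
    k = cfg.variant_catalog_size_per_gene
    catalog: dict[str, dict[str, list[VariantRecord]]] = {}
    for gene in sorted(cfg.per_gene_tier_rates):
        catalog[gene] = {
            "TIER1": [_make_tier1(rng, gene, i, sn) for i in range(k)],
            "TIER2": [_make_tier2(rng, gene, i, sn) for i in range(k)],
            "NOISE": [_make_noise(rng, gene, i, sn) for i in range(k)],
        }
    return catalog


def _draw_call_qc(
    rng: np.random.Generator, qn: QCNoise, is_indel: bool, thr: QCThresholds
) -> VariantCallQC:
    """Draw QC fields; a single uniform decides which (if any) rule fails."""
    u = rng.random()
    fail_vqsr = u < qn.frac_fail_vqsr
    u -= qn.frac_fail_vqsr
    fail_af = 0 <= u < qn.frac_fail_allele_fraction
    u -= qn.frac_fail_allele_fraction
    fail_depth = 0 <= u < qn.frac_fail_depth
    u -= qn.frac_fail_depth
    fail_rprs = 0 <= u < qn.frac_fail_rprs

    if fail_af:
        af = float(thr.min_allele_fraction * rng.uniform(0.1, 0.99))
    else:
        raw = rng.beta(*qn.af_beta)
        af = raw if raw >= thr.min_allele_fraction else float(
            min(1.0, 2 * thr.min_allele_fraction - raw)
        )
    if fail_depth:
        depth = int(rng.integers(0, thr.min_depth))
    else:
        depth = int(thr.min_depth + rng.poisson(max(qn.depth_mean - thr.min_depth, 0.0)))
    missing_p = qn.rprs_missing_prob_indel if is_indel else qn.rprs_missing_prob_snv
    if fail_rprs:
        rprs: Optional[float] = float(
            thr.max_read_pos_rank_sum_excl - rng.exponential(0.5)
        )
    elif rng.random() < missing_p:
        rprs = None
    else:
        raw = float(rng.normal(0.0, 1.0))
        cut = thr.max_read_pos_rank_sum_excl
        rprs = raw if raw > cut else 2 * cut - raw + 0.01
    return VariantCallQC(
        allele_fraction=af,
        depth=depth,
        read_pos_rank_sum=rprs,
        filter_status=FilterStatus.FAIL if fail_vqsr else FilterStatus.PASS,
    )


def simulate_case_cohort(
    cfg: SimulationConfig, qc_thresholds: QCThresholds = QCThresholds()
) -> CohortGenotypes:
    """Simulate per-individual genotype calls for a case cohort.

    Draw order per sample: coverage QC, then per-gene Tier 1 and Tier 2
    Bernoulli carrier indicators (genes in sorted order) with catalog
    variant choice and call QC, then a Poisson number of noise variants.
    """
    rng = _rngs(cfg.seed)[1]
    catalog = build_variant_catalog(cfg)
    genes = sorted(cfg.per_gene_tier_rates)
    samples: list[SampleCoverageQC] = []
    calls: list[tuple[str, VariantRecord, VariantCallQC]] = []
    for i in range(cfg.n_cases):
        sid = f"{cfg.seed}-case-{i:04d}"
        if rng.random() < cfg.frac_low_coverage_samples:
            frac = float(rng.uniform(0.05, 0.29))
        else:
            frac = float(rng.uniform(0.60, 0.99))
        samples.append(SampleCoverageQC(sample_id=sid, frac_bases_ge_20x=frac))
        seen: set[str] = set()
        for gene in genes:
            t1, t2 = cfg.per_gene_tier_rates[gene]
            for rate, pool in ((t1, "TIER1"), (t2, "TIER2")):
                if rate > 0 and rng.random() < rate:
                    variants = catalog[gene][pool]
                    rec = variants[rng.integers(len(variants))]
                    if rec.variant_key in seen:
                        continue
                    seen.add(rec.variant_key)
                    is_indel = rec.func_class in (
                        FuncClass.FRAMESHIFT_INSERTION,
                        FuncClass.FRAMESHIFT_DELETION,
                    )
                    calls.append(
                        (sid, rec, _draw_call_qc(rng, cfg.qc_noise, is_indel, qc_thresholds))
                    )
        n_noise = int(rng.poisson(cfg.noise_variants_per_sample))
        if n_noise > 0:
            noise_pool = [v for g in genes for v in catalog[g]["NOISE"]]
            idx = rng.choice(len(noise_pool), size=min(n_noise, len(noise_pool)), replace=False)
            for j in sorted(idx):
                rec = noise_pool[j]
                if rec.variant_key in seen:
                    continue
                seen.add(rec.variant_key)
                calls.append(
                    (sid, rec, _draw_call_qc(rng, cfg.qc_noise, False, qc_thresholds))
                )
    return CohortGenotypes(
        cohort_label=f"simulated-cases-seed{cfg.seed}", samples=samples, calls=calls
    )


def simulate_control_counts(cfg: SimulationConfig) -> ControlGeneCounts:
    """Simulate an ExAC-style control allele-count table.

    Per gene and tier the carrier count is Binomial(n_controls, rate),
    split multinomially across the gene's catalog variants of that tier;
    noise variants receive small Binomial counts. The covered-persons
    denominator is ``n_controls`` for every row.
    """
    rng = _rngs(cfg.seed)[2]
    catalog = build_variant_catalog(cfg)
    rows: list[tuple[str, VariantRecord, int, int]] = []
    for gene in sorted(cfg.per_gene_tier_rates):
        t1, t2 = cfg.per_gene_tier_rates[gene]
        for rate, pool in ((t1, "TIER1"), (t2, "TIER2")):
            variants = catalog[gene][pool]
            total = int(rng.binomial(cfg.n_controls, rate)) if rate > 0 else 0
            split = rng.multinomial(total, np.full(len(variants), 1.0 / len(variants)))
            for rec, ac in zip(variants, split):
                rows.append((gene, rec, int(ac), cfg.n_controls))
        for rec in catalog[gene]["NOISE"]:
            ac = int(rng.binomial(cfg.n_controls, cfg.control_noise_variant_rate))
            rows.append((rec.gene, rec, ac, cfg.n_controls))
    return ControlGeneCounts(
        population_label=f"simulated-controls-seed{cfg.seed}", rows=rows
    )


def study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A configuration emulating the modelled study design."""
    return dataclasses.replace(SimulationConfig(seed=seed), **overrides)
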