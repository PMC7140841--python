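"""Sample- and call-level quality filters applied before variant prioritisation.

Two stages, both simple hard filters:

* whole samples are dropped when less than 30% of target bases reach 20x
  coverage;
* individual genotype calls are dropped when they fail upstream variant
  quality recalibration (FAIL flag), have an allele fraction below 0.3,
  a read depth below 12, or a readPosRankSum of -1.7 or lower.

readPosRankSum is frequently unannotated (homozygous and many indel calls);
an absent value is non-disqualifying — requiring it would silently discard
most frameshift calls. "Coverage" in the call filter means per-sample read
depth at the site. The three call-level conditions form a single conjunction,
so their order is irrelevant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .variant_model import CohortGenotypes, FilterStatus, VariantCallQC

__all__ = ["QCThresholds", "filter_samples", "filter_calls", "call_passes"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Hard QC thresholds.

    min_frac_bases_20x : sample kept iff fraction of bases at >=20x is >= this
    min_allele_fraction : call kept iff allele fraction >= this
    min_depth : call kept iff depth >= this
    max_read_pos_rank_sum_excl : call dropped iff readPosRankSum <= this
        (absent value never disqualifies)
    """

    min_frac_bases_20x: float = 0.30
    min_allele_fraction: float = 0.3
    min_depth: int = 12
    max_read_pos_rank_sum_excl: float = -1.7

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_frac_bases_20x <= 1.0:
            raise ValueError("min_frac_bases_20x must lie in [0, 1]")


def filter_samples(
    cohort: CohortGenotypes, thr: QCThresholds = QCThresholds()
) -> tuple[CohortGenotypes, list[str]]:
    """Drop samples with insufficient coverage, together with all their calls.

    Exclusion is strict less-than: a sample at exactly the threshold is kept.
    Returns the retained cohort and the excluded sample ids.
    """
    excluded = [
        s.sample_id
        for s in cohort.samples
        if s.frac_bases_ge_20x < thr.min_frac_bases_20x
    ]
    excluded_set = set(excluded)
    retained = CohortGenotypes(
        cohort_label=cohort.cohort_label,
        samples=[s for s in cohort.samples if s.sample_id not in excluded_set],
        calls=[c for c in cohort.calls if c[0] not in excluded_set],
    )
    logger.info(
        "%s: excluded %d/%d samples below %.0f%% bases at 20x",
        cohort.cohort_label,
        len(excluded),
        len(cohort.samples),
        thr.min_frac_bases_20x * 100,
    )
    return retained, excluded


def call_passes(qc: VariantCallQC, thr: QCThresholds = QCThresholds()) -> bool:
    """Single-conjunction call-retention predicate."""
    return (
        qc.filter_status is FilterStatus.PASS
        and qc.allele_fraction >= thr.min_allele_fraction
        and qc.depth >= thr.min_depth
        and (
            qc.read_pos_rank_sum is None
            or qc.read_pos_rank_sum > thr.max_read_pos_rank_sum_excl
        )
    )


def filter_calls(
    cohort: CohortGenotypes, thr: QCThresholds = QCThresholds()
) -> CohortGenotypes:
    """Drop calls failing VQSR, allele fraction, depth, or readPosRankSum rules."""
    removed = {"vqsr": 0, "allele_fraction": 0, "depth": 0, "read_pos_rank_sum": 0}
    retained = []
    for sample_id, rec, qc in cohort.calls:
        if call_passes(qc, thr):
            retained.append((sample_id, rec, qc))
            continue
        if qc.filter_status is not FilterStatus.PASS:
            removed["vqsr"] += 1
        elif qc.allele_fraction < thr.min_allele_fraction:
            removed["allele_fraction"] += 1
        elif qc.depth < thr.min_depth:
            removed["depth"] += 1
        else:
            removed["read_pos_rank_sum"] += 1
    logger.info("%s: call filter removed %s", cohort.cohort_label, removed)
    return CohortGenotypes(
        cohort_label=cohort.cohort_label, samples=list(cohort.samples), calls=retained
    )
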