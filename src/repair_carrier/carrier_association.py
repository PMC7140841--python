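"""Carrier counting and case/control association statistics.

Cases are counted as distinct individuals carrying at least one qualifying
variant of a tier (a man with two Tier 1 hits counts once). Control cohorts
arrive as ExAC-style per-variant allele counts; their per-gene carrier count
is the sum of allele counts over qualifying variants, under the assumption
that each individual carries at most one deleterious mutation per gene (a
slight overestimate). The pan-gene "ALL" row sums per-gene carrier counts
for controls but counts distinct individuals for cases.

Association is a two-sided Fisher's exact test by the minimum-likelihood
convention: the p-value sums the hypergeometric probabilities of all tables
with the observed margins whose point probability does not exceed that of
the observed table (relative tie tolerance 1e-7). No multiple-testing
adjustment is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.special import gammaln

from .tier_classifier import Tier, TierAssignment
from .variant_model import CohortGenotypes, ControlGeneCounts, VariantRecord

__all__ = [
    "ALL_GENES",
    "CarrierCount",
    "AssociationResult",
    "case_carriers",
    "control_carriers",
    "fisher_two_sided",
    "expected_carriers",
    "associate",
    "build_association_table",
    "render_p",
]

ALL_GENES = "ALL"

_TIE_REL_TOL = 1e-7


@dataclass(frozen=True)
class CarrierCount:
    """Carriers of qualifying variants of one tier in one gene (or ALL)."""

    gene: str
    tier: Tier
    n_carriers: int
    n_total: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0 <= self.n_carriers <= self.n_total:
            raise ValueError(
                f"n_carriers={self.n_carriers} outside [0, n_total={self.n_total}]"
            )

    @property
    def rate(self) -> float:
        return self.n_carriers / self.n_total


@dataclass(frozen=True)
class AssociationResult:
    """One 2x2 carrier comparison: case cohort vs a comparison cohort."""

    gene: str
    tier: Tier
    comparison_label: str
    table: tuple[int, int, int, int]  # a=case carriers, b=case non, c=comp carriers, d=comp non
    p_value: float

    @property
    def case_rate(self) -> float:
        a, b, _, _ = self.table
        return a / (a + b)

    @property
    def comparison_rate(self) -> float:
        _, _, c, d = self.table
        return c / (c + d)

    @property
    def p_rendered(self) -> str:
        return render_p(self.p_value)


def render_p(p: float, floor: float = 0.0005, decimals: int = 3) -> str:
    """Render a p-value for reports: 3 d.p., values below 0.0005 as ``<0.001``."""
    if p < floor:
        return "<0.001"
    return f"{p:.{decimals}f}"


# ---------------------------------------------------------------------------
# carrier counting


def _qualifying_keys(
    assignments: Iterable[TierAssignment], tier: Tier
) -> set[str]:
    if tier not in (Tier.TIER1, Tier.TIER2):
        raise ValueError(f"{tier} is not a burden category (use TIER1 or TIER2)")
    return {a.variant_key for a in assignments if a.tier is tier}


def case_carriers(
    cohort: CohortGenotypes,
    assignments: Sequence[TierAssignment],
    tier: Tier,
    gene: Optional[str] = None,
) -> CarrierCount:
    """Count distinct case individuals carrying >= 1 qualifying variant.

    ``assignments`` must cover every variant appearing in the cohort's calls.
    """
    assigned = {a.variant_key for a in assignments}
    missing = {rec.variant_key for _, rec, _ in cohort.calls} - assigned
    if missing:
        raise ValueError(
            f"assignments do not cover {len(missing)} cohort variant(s), "
            f"e.g. {sorted(missing)[:3]}"
        )
    qualifying = _qualifying_keys(assignments, tier)
    carriers = {
        sample_id
        for sample_id, rec, _ in cohort.calls
        if rec.variant_key in qualifying
        and (gene is None or rec.gene.upper() == gene.upper())
    }
    return CarrierCount(
        gene=gene.upper() if gene else ALL_GENES,
        tier=tier,
        n_carriers=len(carriers),
        n_total=cohort.n_samples,
        label=cohort.cohort_label,
    )


def control_carriers(
    counts: ControlGeneCounts,
    assignments: Sequence[TierAssignment],
    tier: Tier,
    gene: Optional[str] = None,
) -> CarrierCount:
    """Estimate control carriers from allele counts.

    Per gene: the sum of allele counts over qualifying variants (capped at
    the denominator), assuming at most one deleterious mutation per
    individual per gene. For ``gene=None`` (ALL): the sum of per-gene
    counts, which may double-count individuals mutated in two genes.

    The denominator is the cohort-level covered-persons value; rows must
    agree on it.
    """
    qualifying = _qualifying_keys(assignments, tier)
    denominators = {covered for _, _, _, covered in counts.rows}
    if len(denominators) > 1:
        raise ValueError(
            f"inconsistent covered-persons denominators across rows: {sorted(denominators)}"
        )
    if not denominators:
        raise ValueError("control table has no rows; denominator unknown")
    n_total = denominators.pop()

    per_gene: dict[str, int] = {}
    for g, rec, ac, _ in counts.rows:
        if rec.variant_key not in qualifying:
            continue
        if gene is not None and g.upper() != gene.upper():
            continue
        per_gene[g.upper()] = per_gene.get(g.upper(), 0) + ac
    n_carriers = sum(min(c, n_total) for c in per_gene.values())
    return CarrierCount(
        gene=gene.upper() if gene else ALL_GENES,
        tier=tier,
        n_carriers=min(n_carriers, n_total),
        n_total=n_total,
        label=counts.population_label,
    )


# ---------------------------------------------------------------------------
# Fisher's exact test (two-sided, minimum-likelihood convention)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric point probabilities of all tables with the observed
    margins whose probability is <= that of the observed table, with a 1e-7
    relative tolerance for ties. Returns a value in (0, 1].
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0:
            raise ValueError(f"negative table entry {name}={v}")
    r1, r2, k = a + b, c + d, a + c
    if r1 < 1 or r2 < 1:
        raise ValueError("each row margin must be >= 1")
    lo, hi = max(0, k - r2), min(r1, k)
    support = np.arange(lo, hi + 1)
    # log hypergeometric pmf over the support, up to a constant
    logpmf = (
        gammaln(r1 + 1)
        - gammaln(support + 1)
        - gammaln(r1 - support + 1)
        + gammaln(r2 + 1)
        - gammaln(k - support + 1)
        - gammaln(r2 - k + support + 1)
    )
    logpmf -= logpmf.max()
    pmf = np.exp(logpmf)
    pmf /= pmf.sum()
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_REL_TOL)].sum())
    return min(p, 1.0)


def expected_carriers(rate: float, n: int) -> float:
    """Expected number of carriers among ``n`` individuals at a given carrier rate."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if n <= 0:
        raise ValueError("n must be positive")
    return rate * n


# ---------------------------------------------------------------------------
# report assembly


def associate(case: CarrierCount, comparison: CarrierCount) -> AssociationResult:
    """Fisher comparison of two carrier counts for the same gene and tier."""
    if case.tier is not comparison.tier:
        raise ValueError("tier mismatch between case and comparison counts")
    a = case.n_carriers
    b = case.n_total - case.n_carriers
    c = comparison.n_carriers
    d = comparison.n_total - comparison.n_carriers
    return AssociationResult(
        gene=case.gene,
        tier=case.tier,
        comparison_label=comparison.label,
        table=(a, b, c, d),
        p_value=fisher_two_sided(a, b, c, d),
    )


Comparison = Union[CohortGenotypes, ControlGeneCounts]


def _comparison_count(
    comp: Comparison,
    assignments: Sequence[TierAssignment],
    tier: Tier,
    gene: Optional[str],
) -> CarrierCount:
    if isinstance(comp, ControlGeneCounts):
        return control_carriers(comp, assignments, tier, gene)
    return case_carriers(comp, assignments, tier, gene)


def build_association_table(
    case_cohort: CohortGenotypes,
    comparison_cohorts: Sequence[Comparison],
    assignments: Sequence[TierAssignment],
) -> list[AssociationResult]:
    """Assemble the full gene x tier x comparison association table.

    For each gene with at least one qualifying variant in any cohort, and
    for the pan-gene ALL row, per tier and per comparison cohort: the 2x2
    carrier table and the two-sided Fisher p-value. All cohorts must have
    been classified with identical thresholds; case and comparison genotype
    cohorts must not share sample ids.
    """
    case_ids = {s.sample_id for s in case_cohort.samples}
    for comp in comparison_cohorts:
        if isinstance(comp, CohortGenotypes):
            overlap = case_ids & {s.sample_id for s in comp.samples}
            if overlap:
                raise ValueError(
                    f"sample ids shared between case and comparison cohorts: "
                    f"{sorted(overlap)[:3]}"
                )

    by_key = {a.variant_key: a for a in assignments}

    def qualifying_genes(tier: Tier) -> set[str]:
        genes: set[str] = set()
        pools: list[Iterable[VariantRecord]] = [case_cohort.variants()]
        pools += [
            comp.observed_variants()
            if isinstance(comp, ControlGeneCounts)
            else comp.variants()
            for comp in comparison_cohorts
        ]
        for pool in pools:
            for rec in pool:
                asg = by_key.get(rec.variant_key)
                if asg is not None and asg.tier is tier:
                    genes.add(rec.gene.upper())
        return genes

    results: list[AssociationResult] = []
    for tier in (Tier.TIER1, Tier.TIER2):
        genes = sorted(qualifying_genes(tier))
        if not genes:
            continue
        for gene in genes + [None]:  # None -> ALL row
            case_count = case_carriers(case_cohort, assignments, tier, gene)
            for comp in comparison_cohorts:
                comp_count = _comparison_count(comp, assignments, tier, gene)
                results.append(associate(case_count, comp_count))
    return results
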