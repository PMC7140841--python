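"""End-to-end orchestration: QC filtering, classification, association, reports.

``run_pipeline`` wires the stages together the way the analysis runs on a
real cohort: sample-level coverage exclusion, call-level QC filtering,
panel/rarity/tier classification of every variant seen in any cohort, then
gene-level carrier association of the case cohort against each comparison
cohort. It writes a per-variant assignment TSV, an association TSV and a
JSON run summary with per-stage counts (records in = retained + removed at
every stage).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from . import qc_filters, tier_classifier
from .carrier_association import build_association_table
from .qc_filters import QCThresholds
from .tier_classifier import ClassifierThresholds, Tier
from .variant_model import (
    CohortGenotypes,
    ControlGeneCounts,
    GenePanel,
    read_cohort_genotypes,
    read_control_counts,
    read_gene_panel,
    write_assignments,
    write_association_report,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and rendering options for one pipeline run."""

    cases_path: Union[str, Path]
    panel_path: Union[str, Path]
    out_dir: Union[str, Path]
    comparisons: Sequence[tuple[str, Union[str, Path]]] = ()
    qc: QCThresholds = field(default_factory=QCThresholds)
    classifier: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    seed: Optional[int] = None

    def validate_paths(self) -> None:
        missing = [
            str(p)
            for p in [self.cases_path, self.panel_path]
            + [p for _, p in self.comparisons]
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input path(s): {', '.join(missing)}")


def _read_comparison(label: str, path: Union[str, Path]):
    """Auto-detect a comparison table: genotype cohort vs allele-count summary."""
    with open(path) as fh:
        header = fh.readline()
        while header.startswith("#"):
            header = fh.readline()
    cols = [c.strip().lower() for c in header.rstrip("\n").split("\t")]
    if "allele_count" in cols:
        return read_control_counts(path, label)
    if "sample_id" in cols:
        return read_cohort_genotypes(path, label)
    raise ValueError(
        f"{path}: cannot identify comparison table type "
        "(expected an allele_count or sample_id column)"
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute filter -> classify -> associate and write reports.

    Returns the run summary (also written as ``run_summary.json``).
    """
    cfg.validate_paths()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cases_raw = read_cohort_genotypes(cfg.cases_path, "cases")
    panel = read_gene_panel(cfg.panel_path)
    comparisons = [_read_comparison(label, p) for label, p in cfg.comparisons]

    cases_cov, excluded = qc_filters.filter_samples(cases_raw, cfg.qc)
    cases = qc_filters.filter_calls(cases_cov, cfg.qc)

    variants = {rec.variant_key: rec for _, rec, _ in cases.calls}
    for comp in comparisons:
        for rec in comp.variants():
            variants.setdefault(rec.variant_key, rec)
    records = list(variants.values())
    assignments = tier_classifier.classify_cohort(records, panel, cfg.classifier)
    tier_counts = {t.name: 0 for t in Tier}
    for a in assignments:
        tier_counts[a.tier.name] += 1

    write_assignments(list(zip(records, assignments)), out_dir / "assignments.tsv")

    results = []
    if comparisons:
        results = build_association_table(cases, comparisons, assignments)
        write_association_report(results, out_dir / "association.tsv")

    summary = {
        "thresholds": {
            "qc": {
                "min_frac_bases_20x": cfg.qc.min_frac_bases_20x,
                "min_allele_fraction": cfg.qc.min_allele_fraction,
                "min_depth": cfg.qc.min_depth,
                "max_read_pos_rank_sum_excl": cfg.qc.max_read_pos_rank_sum_excl,
            },
            "classifier": {
                "max_maf": cfg.classifier.max_maf,
                "min_cadd": cfg.classifier.min_cadd,
                "min_revel": cfg.classifier.min_revel,
            },
        },
        "seed": cfg.seed,
        "stages": {
            "samples": {
                "in": cases_raw.n_samples,
                "removed": len(excluded),
                "retained": cases_cov.n_samples,
            },
            "calls": {
                "in": len(cases_cov.calls),
                "removed": len(cases_cov.calls) - len(cases.calls),
                "retained": len(cases.calls),
            },
            "classification": {
                "in": len(records),
                "by_tier": tier_counts,
            },
        },
        "excluded_samples": excluded,
        "n_association_rows": len(results),
        "outputs": {
            "assignments": str(out_dir / "assignments.tsv"),
            "association": str(out_dir / "association.tsv") if comparisons else None,
        },
    }
    (out_dir / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info(
        "pipeline: %d/%d samples retained, %d/%d calls retained, %d variants classified",
        cases_cov.n_samples,
        cases_raw.n_samples,
        len(cases.calls),
        len(cases_cov.calls),
        len(records),
    )
    return summary
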