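"""Packaged reference datasets.

Three small text fixtures ship with the package:

* the table of potentially damaging variants observed in the lethal
  prostate-cancer case cohort, with published annotations and tiers;
* the per-gene carrier counts by tier for the four cohorts (122 lethal
  cases, 60 unselected cases, 3307 Finnish and 6192 Swedish population
  controls);
* a default DNA-repair gene panel (the 17 observed genes plus a canonical
  extension; the original 175-gene panel is not published).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .carrier_association import CarrierCount
from .tier_classifier import Tier
from .variant_model import GenePanel, VariantRecord, read_gene_panel, read_variant_table

__all__ = [
    "data_path",
    "load_case_variants",
    "load_case_variant_table",
    "load_default_panel",
    "load_carrier_counts",
    "COHORT_SIZES",
]

COHORT_SIZES = {"lethal": 122, "unselected": 60, "finnish": 3307, "swedish": 6192}


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("repair_carrier").joinpath("data", name))


def load_case_variants() -> list[VariantRecord]:
    """The 31 potentially damaging case variants as parsed records."""
    return read_variant_table(data_path("lethal_case_variants.tsv"), dialect="TSV")


def load_case_variant_table() -> pd.DataFrame:
    """The case-variant fixture as a raw DataFrame (includes reported_tier)."""
    return pd.read_csv(
        data_path("lethal_case_variants.tsv"),
        sep="\t",
        dtype=str,
        comment="#",
        keep_default_na=False,
    )


def load_default_panel() -> GenePanel:
    return read_gene_panel(data_path("dna_repair_panel.txt"))


def load_carrier_counts() -> dict[str, list[CarrierCount]]:
    """Published per-gene carrier counts, keyed by cohort label.

    Each value is a list of :class:`CarrierCount` (genes plus the ALL row)
    for both tiers, with the cohort's covered-persons denominator.
    """
    df = pd.read_csv(
        data_path("cohort_carrier_counts.tsv"), sep="\t", comment="#"
    )
    out: dict[str, list[CarrierCount]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.cohort, []).append(
            CarrierCount(
                gene=row.gene,
                tier=Tier[row.tier],
                n_carriers=int(row.carriers),
                n_total=int(row.n_total),
                label=row.cohort,
            )
        )
    return out
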