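"""Domain types and I/O for annotated variant tables, cohort genotypes and
control allele-count summaries.

The data model mirrors what a downstream-of-ANNOVAR exome pipeline hands to a
variant prioritisation step: one record per annotated variant carrying its
functional class, ClinVar submitter codes, CADD phred and REVEL scores, the
reference-population minor allele frequency, and (for truncating variants) a
flag for whether the truncation disrupts a UniProt-reported protein domain.

Coordinates follow the 1-based VCF convention. No left-alignment or other
normalisation is performed here: inputs are assumed pre-normalised upstream.
"""

from __future__ import annotations

import dataclasses
import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "FuncClass",
    "ClinVarCode",
    "RegionClass",
    "VariantRecord",
    "VariantCallQC",
    "FilterStatus",
    "SampleCoverageQC",
    "CohortGenotypes",
    "ControlGeneCounts",
    "GenePanel",
    "VariantTableError",
    "read_variant_table",
    "read_gene_panel",
    "write_assignments",
    "read_assignments",
    "write_association_report",
    "write_cohort_genotypes",
    "read_cohort_genotypes",
    "write_control_counts",
    "read_control_counts",
]

MISSING_TOKENS = {"-", ".", "", "na", "nan", "none"}


class FuncClass(enum.Enum):
    """Functional consequence class of a variant."""

    STOPGAIN = "stopgain"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    SPLICING = "splicing"
    MISSENSE = "missense"
    OTHER = "other"

    @property
    def is_truncating(self) -> bool:
        """Protein-truncating classes: stopgain, frameshift indels, splice-altering."""
        return self in _TRUNCATING


_TRUNCATING = frozenset(
    {
        FuncClass.STOPGAIN,
        FuncClass.FRAMESHIFT_INSERTION,
        FuncClass.FRAMESHIFT_DELETION,
        FuncClass.SPLICING,
    }
)

# accepted spellings in TSV input (ANNOVAR-ish and human-readable)
_FUNC_CLASS_TOKENS: dict[str, FuncClass] = {
    "stopgain": FuncClass.STOPGAIN,
    "stop_gain": FuncClass.STOPGAIN,
    "nonsense": FuncClass.STOPGAIN,
    "frameshift ins": FuncClass.FRAMESHIFT_INSERTION,
    "frameshift_ins": FuncClass.FRAMESHIFT_INSERTION,
    "frameshift insertion": FuncClass.FRAMESHIFT_INSERTION,
    "frameshift_insertion": FuncClass.FRAMESHIFT_INSERTION,
    "frameshift del": FuncClass.FRAMESHIFT_DELETION,
    "frameshift_del": FuncClass.FRAMESHIFT_DELETION,
    "frameshift deletion": FuncClass.FRAMESHIFT_DELETION,
    "frameshift_deletion": FuncClass.FRAMESHIFT_DELETION,
    "splicing": FuncClass.SPLICING,
    "splice": FuncClass.SPLICING,
    "missense": FuncClass.MISSENSE,
    "nonsynonymous snv": FuncClass.MISSENSE,
    "other": FuncClass.OTHER,
}


class ClinVarCode(enum.IntEnum):
    """ClinVar clinical-significance assertion codes.

    5 = pathogenic, 4 = likely pathogenic, 3 = uncertain significance,
    2 = likely benign, 1 = benign. A variant may carry several codes from
    different submitters; precedence is decided by the classifier, not here.
    """

    BENIGN = 1
    LIKELY_BENIGN = 2
    UNCERTAIN = 3
    LIKELY_PATHOGENIC = 4
    PATHOGENIC = 5


class RegionClass(enum.Enum):
    EXONIC_OR_SPLICING = "exonic_or_splicing"
    INTERGENIC = "intergenic"
    OTHER_NONCODING = "other_noncoding"


class FilterStatus(enum.Enum):
    """Outcome of upstream variant-quality recalibration (consumed, not computed)."""

    PASS = "PASS"
    FAIL = "FAIL"


class VariantTableError(ValueError):
    """Raised on malformed variant-table input; names the offending line/column."""


@dataclass(frozen=True)
class VariantRecord:
    """One annotated germline variant.

    Parameters
    ----------
    variant_key
        Stable identifier; ``chrom:pos:ref:alt`` (1-based, VCF convention)
        when coordinates are known, otherwise derived from gene/rsid/protein
        change. The genome build travels in ``build``.
    gene
        HGNC-style gene symbol.
    func_class
        Functional consequence class.
    clinvar_codes
        Set of submitter assertions (possibly empty).
    cadd_phred, revel, maf
        Deleteriousness scores and reference-population minor allele
        frequency; ``None`` when unannotated.
    disrupts_domain
        For truncating variants: truncation occurs before or within a
        UniProt-reported protein domain. ``None`` is treated as unknown
        (classifier reads it as false).
    """

    variant_key: str
    gene: str
    func_class: FuncClass
    rsid: Optional[str] = None
    protein_change: Optional[str] = None
    ref: Optional[str] = None
    alt: Optional[str] = None
    clinvar_codes: frozenset[ClinVarCode] = frozenset()
    cadd_phred: Optional[float] = None
    revel: Optional[float] = None
    maf: Optional[float] = None
    disrupts_domain: Optional[bool] = None
    region_class: RegionClass = RegionClass.EXONIC_OR_SPLICING
    build: str = "hg19"

    def __post_init__(self) -> None:
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"cadd_phred must be non-negative, got {self.cadd_phred}")
        if self.revel is not None and not 0.0 <= self.revel <= 1.0:
            raise ValueError(f"revel must lie in [0, 1], got {self.revel}")
        if self.maf is not None and not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"maf must lie in [0, 0.5], got {self.maf}")
        if not isinstance(self.clinvar_codes, frozenset):
            object.__setattr__(self, "clinvar_codes", frozenset(self.clinvar_codes))
        if (
            self.func_class is FuncClass.MISSENSE
            and self.ref is not None
            and self.alt is not None
            and (len(self.ref) != 1 or len(self.alt) != 1)
        ):
            raise ValueError(
                f"missense variant {self.variant_key} must be a single-nucleotide "
                f"substitution (ref={self.ref!r}, alt={self.alt!r})"
            )

    @property
    def has_plp(self) -> bool:
        """Any pathogenic / likely-pathogenic ClinVar assertion present."""
        return bool(
            self.clinvar_codes
            & {ClinVarCode.PATHOGENIC, ClinVarCode.LIKELY_PATHOGENIC}
        )

    @property
    def has_benign(self) -> bool:
        return bool(
            self.clinvar_codes & {ClinVarCode.BENIGN, ClinVarCode.LIKELY_BENIGN}
        )


@dataclass(frozen=True)
class VariantCallQC:
    """Per-sample call-level QC fields for one genotype call."""

    allele_fraction: float
    depth: int
    read_pos_rank_sum: Optional[float] = None
    filter_status: FilterStatus = FilterStatus.PASS

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError(f"allele_fraction must lie in [0, 1], got {self.allele_fraction}")
        if self.depth < 0:
            raise ValueError(f"depth must be non-negative, got {self.depth}")


@dataclass(frozen=True)
class SampleCoverageQC:
    """Per-sample sequencing coverage summary.

    ``frac_bases_ge_20x`` is the fraction of target bases covered by at
    least 20 reads, the statistic used for whole-sample exclusion.
    """

    sample_id: str
    frac_bases_ge_20x: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_bases_ge_20x <= 1.0:
            raise ValueError(
                f"frac_bases_ge_20x must lie in [0, 1], got {self.frac_bases_ge_20x}"
            )


@dataclass
class CohortGenotypes:
    """Per-individual genotype calls for one case cohort."""

    cohort_label: str
    samples: list[SampleCoverageQC]
    calls: list[tuple[str, VariantRecord, VariantCallQC]]

    def __post_init__(self) -> None:
        ids = {s.sample_id for s in self.samples}
        if len(ids) != len(self.samples):
            raise ValueError("duplicate sample_id in cohort samples")
        seen: set[tuple[str, str]] = set()
        for sample_id, rec, _ in self.calls:
            if sample_id not in ids:
                raise ValueError(f"call references unknown sample {sample_id!r}")
            key = (sample_id, rec.variant_key)
            if key in seen:
                raise ValueError(f"duplicate call {key}")
            seen.add(key)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def variants(self) -> list[VariantRecord]:
        """Distinct variant records appearing in calls (first-seen order)."""
        out: dict[str, VariantRecord] = {}
        for _, rec, _ in self.calls:
            out.setdefault(rec.variant_key, rec)
        return list(out.values())


@dataclass
class ControlGeneCounts:
    """ExAC-style per-variant allele counts for a control population.

    Each row is (gene, variant, allele_count, covered_persons); the carrier
    estimate downstream assumes at most one deleterious mutation per
    individual per gene.
    """

    population_label: str
    rows: list[tuple[str, VariantRecord, int, int]]

    def __post_init__(self) -> None:
        for gene, rec, ac, covered in self.rows:
            if ac < 0:
                raise ValueError(f"negative allele count for {rec.variant_key}")
            if covered <= 0:
                raise ValueError(f"covered_persons must be positive for {rec.variant_key}")
            if ac > 2 * covered:
                raise ValueError(
                    f"allele_count {ac} exceeds 2 x covered_persons {covered} "
                    f"for {rec.variant_key}"
                )

    def variants(self) -> list[VariantRecord]:
        out: dict[str, VariantRecord] = {}
        for _, rec, _, _ in self.rows:
            out.setdefault(rec.variant_key, rec)
        return list(out.values())

    def observed_variants(self) -> list[VariantRecord]:
        """Variants with a non-zero allele count (actually seen in the population)."""
        out: dict[str, VariantRecord] = {}
        for _, rec, ac, _ in self.rows:
            if ac > 0:
                out.setdefault(rec.variant_key, rec)
        return list(out.values())


@dataclass(frozen=True)
class GenePanel:
    """Set of gene symbols defining the analysis panel (case-normalised)."""

    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene panel is empty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# parsing helpers

# scientific notation as typeset in publications: "2.5 × 10−5" (multiplication
# sign, unicode minus, optional superscript markers)
_TYPESET_SCI = re.compile(
    r"^\s*(?P<mant>[0-9]*\.?[0-9]+)\s*[x×*]\s*10\s*\^?\s*(?P<exp>[−\-+]?[0-9]+)\s*\^?\s*$"
)


def parse_number(token: object) -> Optional[float]:
    """Parse a possibly missing, possibly typeset numeric token.

    Accepts plain floats, e-notation, and the typeset form ``a × 10−b``
    (with the unicode minus and multiplication signs). Missing tokens
    ("-", ".", "", NA) map to ``None``.
    """
    if token is None or (isinstance(token, float) and pd.isna(token)):
        return None
    s = str(token).strip()
    if s.lower() in MISSING_TOKENS:
        return None
    m = _TYPESET_SCI.match(s)
    if m:
        exp = int(m.group("exp").replace("−", "-"))
        return float(m.group("mant")) * 10.0**exp
    return float(s.replace("−", "-"))


def parse_clinvar_codes(token: object) -> frozenset[ClinVarCode]:
    """Parse a multi-submitter ClinVar code string like ``"5,4,3"`` into a set."""
    if token is None or (isinstance(token, float) and pd.isna(token)):
        return frozenset()
    s = str(token).strip()
    if s.lower() in MISSING_TOKENS:
        return frozenset()
    codes = set()
    for part in re.split(r"[,;|]", s):
        part = part.strip()
        if not part or part in MISSING_TOKENS:
            continue
        try:
            codes.add(ClinVarCode(int(float(part))))
        except ValueError as exc:
            raise VariantTableError(f"unknown ClinVar code {part!r} in {s!r}") from exc
    return frozenset(codes)


def parse_func_class(token: str) -> FuncClass:
    key = str(token).strip().lower().replace("-", " ")
    try:
        return _FUNC_CLASS_TOKENS[key]
    except KeyError:
        accepted = ", ".join(sorted(set(_FUNC_CLASS_TOKENS)))
        raise VariantTableError(
            f"unknown functional class token {token!r}; accepted tokens: {accepted}"
        ) from None


def _parse_bool(token: object) -> Optional[bool]:
    if token is None or (isinstance(token, float) and pd.isna(token)):
        return None
    s = str(token).strip().lower()
    if s in MISSING_TOKENS:
        return None
    if s in {"true", "t", "yes", "1", "1.0"}:
        return True
    if s in {"false", "f", "no", "0", "0.0"}:
        return False
    raise VariantTableError(f"cannot parse boolean token {token!r}")


_REGION_TOKENS = {
    "exonic": RegionClass.EXONIC_OR_SPLICING,
    "exonic_or_splicing": RegionClass.EXONIC_OR_SPLICING,
    "splicing": RegionClass.EXONIC_OR_SPLICING,
    "intergenic": RegionClass.INTERGENIC,
    "other_noncoding": RegionClass.OTHER_NONCODING,
    "intronic": RegionClass.OTHER_NONCODING,
    "utr": RegionClass.OTHER_NONCODING,
}


def _missing(token: object) -> bool:
    if token is None or (isinstance(token, float) and pd.isna(token)):
        return True
    return str(token).strip().lower() in MISSING_TOKENS


def _opt_str(token: object) -> Optional[str]:
    return None if _missing(token) else str(token).strip()


def _parse_allele(token: object) -> Optional[str]:
    """Alleles keep "-" literally (deletion/insertion convention); empty is absent."""
    if token is None or (isinstance(token, float) and pd.isna(token)):
        return None
    s = str(token).strip()
    return s or None


def _fmt_allele(value: Optional[str]) -> str:
    return "" if value is None else value


def make_variant_key(
    gene: str,
    rsid: Optional[str],
    protein_change: Optional[str],
    ref: Optional[str],
    alt: Optional[str],
    chrom: Optional[str] = None,
    pos: Optional[int] = None,
) -> str:
    """Build ``chrom:pos:ref:alt`` when coordinates are known, else a stable
    surrogate from gene / rsid / protein change."""
    if chrom is not None and pos is not None:
        return f"{chrom}:{pos}:{ref or '-'}:{alt or '-'}"
    parts = [gene, rsid or protein_change or "novel", ref or "-", alt or "-"]
    return ":".join(parts)


# ---------------------------------------------------------------------------
# readers


def read_variant_table(
    path: Union[str, Path],
    dialect: str = "TSV",
    *,
    vcf_field_map: Optional[Mapping[str, str]] = None,
) -> list[VariantRecord]:
    """Read an annotated variant table.

    Parameters
    ----------
    path
        TSV file (header must name at least gene, type, clinvar, cadd,
        revel, maf columns) or a VCF 4.x file.
    dialect
        ``"TSV"`` or ``"VCF"``.
    vcf_field_map
        For VCF input: mapping from logical field names (gene, cadd, revel,
        maf, clinvar, func_class, domain) to INFO keys. Defaults are shipped
        in :mod:`repair_carrier.config`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect.upper()
    if dialect == "TSV":
        return _read_variant_tsv(path)
    if dialect == "VCF":
        return _read_variant_vcf(path, vcf_field_map)
    raise ValueError(f"unknown dialect {dialect!r}; expected TSV or VCF")


_REQUIRED_TSV_COLUMNS = ("gene", "type", "clinvar", "cadd", "revel", "maf")


def _read_variant_tsv(path: Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing_cols = [c for c in _REQUIRED_TSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise VariantTableError(
            f"{path}: missing required column(s) {missing_cols}; "
            f"header must name {list(_REQUIRED_TSV_COLUMNS)}"
        )
    records: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        row_d = dict(zip(df.columns, row))
        try:
            gene = str(row_d["gene"]).strip()
            func_class = parse_func_class(row_d["type"])
            ref = _parse_allele(row_d.get("ref"))
            alt = _parse_allele(row_d.get("alt"))
            rsid = _opt_str(row_d.get("rsid"))
            protein_change = _opt_str(row_d.get("protein_change"))
            chrom = _opt_str(row_d.get("chrom"))
            pos_s = _opt_str(row_d.get("pos"))
            pos = int(pos_s) if pos_s is not None else None
            key = _opt_str(row_d.get("variant_key")) or make_variant_key(
                gene, rsid, protein_change, ref, alt, chrom, pos
            )
            region_tok = _opt_str(row_d.get("region"))
            region = (
                _REGION_TOKENS[region_tok.lower()]
                if region_tok is not None
                else RegionClass.EXONIC_OR_SPLICING
            )
            records.append(
                VariantRecord(
                    variant_key=key,
                    gene=gene,
                    func_class=func_class,
                    rsid=rsid,
                    protein_change=protein_change,
                    ref=ref,
                    alt=alt,
                    clinvar_codes=parse_clinvar_codes(row_d["clinvar"]),
                    cadd_phred=parse_number(row_d["cadd"]),
                    revel=parse_number(row_d["revel"]),
                    maf=parse_number(row_d["maf"]),
                    disrupts_domain=_parse_bool(row_d.get("domain")),
                    region_class=region,
                )
            )
        except VariantTableError:
            raise
        except (ValueError, KeyError) as exc:
            raise VariantTableError(f"{path}: malformed row at line {i}: {exc}") from exc
    return records


_DEFAULT_VCF_FIELD_MAP = {
    "gene": "GENE",
    "func_class": "FUNC",
    "clinvar": "CLNSIG_CODES",
    "cadd": "CADD_PHRED",
    "revel": "REVEL",
    "maf": "MAF",
    "domain": "DOMAIN",
    "region": "REGION",
}


def _read_variant_vcf(
    path: Path, field_map: Optional[Mapping[str, str]]
) -> list[VariantRecord]:
    from cyvcf2 import VCF

    fm = dict(_DEFAULT_VCF_FIELD_MAP)
    if field_map:
        fm.update(field_map)
    records: list[VariantRecord] = []
    for v in VCF(str(path)):
        alt = v.ALT[0] if v.ALT else "-"
        gene = v.INFO.get(fm["gene"])
        if gene is None:
            raise VariantTableError(
                f"{path}: record {v.CHROM}:{v.POS} lacks INFO/{fm['gene']}"
            )
        func_tok = v.INFO.get(fm["func_class"], "other")
        region_tok = v.INFO.get(fm["region"])
        domain_tok = v.INFO.get(fm["domain"])
        records.append(
            VariantRecord(
                variant_key=f"{v.CHROM}:{v.POS}:{v.REF}:{alt}",
                gene=str(gene),
                func_class=parse_func_class(str(func_tok)),
                rsid=v.ID,
                ref=v.REF,
                alt=alt,
                clinvar_codes=parse_clinvar_codes(v.INFO.get(fm["clinvar"])),
                cadd_phred=parse_number(v.INFO.get(fm["cadd"])),
                revel=parse_number(v.INFO.get(fm["revel"])),
                maf=parse_number(v.INFO.get(fm["maf"])),
                disrupts_domain=_parse_bool(domain_tok),
                region_class=(
                    _REGION_TOKENS[str(region_tok).lower()]
                    if region_tok is not None
                    else RegionClass.EXONIC_OR_SPLICING
                ),
            )
        )
    return records


def read_gene_panel(path: Union[str, Path]) -> GenePanel:
    """Read a gene panel: one symbol per line, ``#`` comments allowed."""
    path = Path(path)
    genes: set[str] = set()
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.add(line.upper())
    if not genes:
        raise VariantTableError(f"{path}: gene panel contains no gene symbols")
    return GenePanel(frozenset(genes))


# ---------------------------------------------------------------------------
# writers

_ASSIGNMENT_COLUMNS = [
    "variant_key",
    "gene",
    "rsid",
    "type",
    "ref",
    "alt",
    "protein_change",
    "clinvar",
    "cadd",
    "revel",
    "maf",
    "domain",
    "region",
    "tier",
    "reason",
]


def _fmt(value: object) -> str:
    if value is None:
        return "-"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_assignments(assignments: Sequence, path: Union[str, Path]) -> None:
    """Write (VariantRecord, TierAssignment) pairs as a TSV.

    Layout mirrors a per-variant prioritisation table: annotation columns
    followed by the assigned tier and machine-readable reason. Missing
    values are rendered as ``-``; the file round-trips through
    :func:`read_assignments`.
    """
    rows = []
    for rec, assignment in assignments:
        rows.append(
            {
                "variant_key": rec.variant_key,
                "gene": rec.gene,
                "rsid": _fmt(rec.rsid),
                "type": rec.func_class.value,
                "ref": _fmt_allele(rec.ref),
                "alt": _fmt_allele(rec.alt),
                "protein_change": _fmt(rec.protein_change),
                "clinvar": ",".join(str(int(c)) for c in sorted(rec.clinvar_codes, reverse=True))
                or "-",
                "cadd": _fmt(rec.cadd_phred),
                "revel": _fmt(rec.revel),
                "maf": _fmt(rec.maf),
                "domain": _fmt(rec.disrupts_domain),
                "region": rec.region_class.value,
                "tier": assignment.tier.name,
                "reason": assignment.reason.name,
            }
        )
    df = pd.DataFrame(rows, columns=_ASSIGNMENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_assignments(path: Union[str, Path]):
    """Read a TSV written by :func:`write_assignments`.

    Returns a list of ``(VariantRecord, TierAssignment)`` pairs.
    """
    from .tier_classifier import Tier, TierAssignment, TierReason

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = dict(zip(df.columns, row))
        rec = VariantRecord(
            variant_key=d["variant_key"],
            gene=d["gene"],
            func_class=FuncClass(d["type"]),
            rsid=_opt_str(d["rsid"]),
            protein_change=_opt_str(d["protein_change"]),
            ref=_parse_allele(d["ref"]),
            alt=_parse_allele(d["alt"]),
            clinvar_codes=parse_clinvar_codes(d["clinvar"]),
            cadd_phred=parse_number(d["cadd"]),
            revel=parse_number(d["revel"]),
            maf=parse_number(d["maf"]),
            disrupts_domain=_parse_bool(d["domain"]),
            region_class=RegionClass(d["region"]),
        )
        assignment = TierAssignment(
            variant_key=d["variant_key"],
            tier=Tier[d["tier"]],
            reason=TierReason[d["reason"]],
        )
        out.append((rec, assignment))
    return out


_COHORT_COLUMNS = [
    "sample_id",
    "frac_bases_ge_20x",
    "variant_key",
    "gene",
    "type",
    "ref",
    "alt",
    "protein_change",
    "clinvar",
    "cadd",
    "revel",
    "maf",
    "domain",
    "region",
    "allele_fraction",
    "depth",
    "read_pos_rank_sum",
    "filter",
]


def write_cohort_genotypes(cohort: CohortGenotypes, path: Union[str, Path]) -> None:
    """Write a cohort genotype table as one TSV.

    One row per genotype call; samples without calls appear once with all
    call fields missing so that per-sample coverage QC round-trips.
    """
    rows = []
    with_calls = {sample_id for sample_id, _, _ in cohort.calls}
    frac = {s.sample_id: s.frac_bases_ge_20x for s in cohort.samples}
    for s in cohort.samples:
        if s.sample_id not in with_calls:
            rows.append(
                {"sample_id": s.sample_id, "frac_bases_ge_20x": repr(s.frac_bases_ge_20x)}
            )
    for sample_id, rec, qc in cohort.calls:
        rows.append(
            {
                "sample_id": sample_id,
                "frac_bases_ge_20x": repr(frac[sample_id]),
                "variant_key": rec.variant_key,
                "gene": rec.gene,
                "type": rec.func_class.value,
                "ref": _fmt_allele(rec.ref),
                "alt": _fmt_allele(rec.alt),
                "protein_change": _fmt(rec.protein_change),
                "clinvar": ",".join(
                    str(int(c)) for c in sorted(rec.clinvar_codes, reverse=True)
                )
                or "-",
                "cadd": _fmt(rec.cadd_phred),
                "revel": _fmt(rec.revel),
                "maf": _fmt(rec.maf),
                "domain": _fmt(rec.disrupts_domain),
                "region": rec.region_class.value,
                "allele_fraction": repr(qc.allele_fraction),
                "depth": str(qc.depth),
                "read_pos_rank_sum": _fmt(qc.read_pos_rank_sum),
                "filter": qc.filter_status.value,
            }
        )
    df = pd.DataFrame(rows, columns=_COHORT_COLUMNS).fillna("-")
    df.to_csv(path, sep="\t", index=False)


def read_cohort_genotypes(path: Union[str, Path], cohort_label: str) -> CohortGenotypes:
    """Read a cohort genotype TSV written by :func:`write_cohort_genotypes`."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    samples: dict[str, SampleCoverageQC] = {}
    calls: list[tuple[str, VariantRecord, VariantCallQC]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = dict(zip(df.columns, row))
        sid = str(d["sample_id"]).strip()
        if sid not in samples:
            frac = parse_number(d["frac_bases_ge_20x"])
            if frac is None:
                raise VariantTableError(
                    f"{path}: line {i}: missing frac_bases_ge_20x for sample {sid}"
                )
            samples[sid] = SampleCoverageQC(sample_id=sid, frac_bases_ge_20x=frac)
        if _missing(d.get("variant_key")):
            continue
        try:
            rec = VariantRecord(
                variant_key=str(d["variant_key"]),
                gene=str(d["gene"]),
                func_class=parse_func_class(d["type"]),
                ref=_parse_allele(d.get("ref")),
                alt=_parse_allele(d.get("alt")),
                protein_change=_opt_str(d.get("protein_change")),
                clinvar_codes=parse_clinvar_codes(d.get("clinvar")),
                cadd_phred=parse_number(d.get("cadd")),
                revel=parse_number(d.get("revel")),
                maf=parse_number(d.get("maf")),
                disrupts_domain=_parse_bool(d.get("domain")),
                region_class=RegionClass(d.get("region", "exonic_or_splicing")),
            )
            af = parse_number(d["allele_fraction"])
            depth = parse_number(d["depth"])
            if af is None or depth is None:
                raise ValueError("allele_fraction and depth are required per call")
            qc = VariantCallQC(
                allele_fraction=af,
                depth=int(depth),
                read_pos_rank_sum=parse_number(d.get("read_pos_rank_sum")),
                filter_status=FilterStatus(d.get("filter", "PASS")),
            )
        except VariantTableError:
            raise
        except (ValueError, KeyError) as exc:
            raise VariantTableError(f"{path}: malformed row at line {i}: {exc}") from exc
        calls.append((sid, rec, qc))
    return CohortGenotypes(
        cohort_label=cohort_label, samples=list(samples.values()), calls=calls
    )


def write_control_counts(counts: ControlGeneCounts, path: Union[str, Path]) -> None:
    """Write a control allele-count table as a TSV."""
    rows = []
    for gene, rec, ac, covered in counts.rows:
        rows.append(
            {
                "gene": gene,
                "variant_key": rec.variant_key,
                "type": rec.func_class.value,
                "ref": _fmt_allele(rec.ref),
                "alt": _fmt_allele(rec.alt),
                "clinvar": ",".join(
                    str(int(c)) for c in sorted(rec.clinvar_codes, reverse=True)
                )
                or "-",
                "cadd": _fmt(rec.cadd_phred),
                "revel": _fmt(rec.revel),
                "maf": _fmt(rec.maf),
                "domain": _fmt(rec.disrupts_domain),
                "region": rec.region_class.value,
                "allele_count": str(ac),
                "covered_persons": str(covered),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_control_counts(path: Union[str, Path], population_label: str) -> ControlGeneCounts:
    """Read a control allele-count TSV written by :func:`write_control_counts`."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    rows = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = dict(zip(df.columns, row))
        try:
            rec = VariantRecord(
                variant_key=str(d["variant_key"]),
                gene=str(d["gene"]),
                func_class=parse_func_class(d["type"]),
                ref=_parse_allele(d.get("ref")),
                alt=_parse_allele(d.get("alt")),
                clinvar_codes=parse_clinvar_codes(d.get("clinvar")),
                cadd_phred=parse_number(d.get("cadd")),
                revel=parse_number(d.get("revel")),
                maf=parse_number(d.get("maf")),
                disrupts_domain=_parse_bool(d.get("domain")),
                region_class=RegionClass(d.get("region", "exonic_or_splicing")),
            )
            rows.append(
                (str(d["gene"]), rec, int(d["allele_count"]), int(d["covered_persons"]))
            )
        except VariantTableError:
            raise
        except (ValueError, KeyError) as exc:
            raise VariantTableError(f"{path}: malformed row at line {i}: {exc}") from exc
    return ControlGeneCounts(population_label=population_label, rows=rows)


def write_association_report(results: Sequence, path: Union[str, Path]) -> None:
    """Write association results as a TSV, one row per gene x tier x comparison."""
    rows = []
    for r in results:
        rows.append(
            {
                "gene": r.gene,
                "tier": r.tier.name,
                "comparison": r.comparison_label,
                "a": r.table[0],
                "b": r.table[1],
                "c": r.table[2],
                "d": r.table[3],
                "rate_case_pct": f"{r.case_rate * 100:.2f}",
                "rate_comp_pct": f"{r.comparison_rate * 100:.2f}",
                "p_value": r.p_rendered,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "tier",
            "comparison",
            "a",
            "b",
            "c",
            "d",
            "rate_case_pct",
            "rate_comp_pct",
            "p_value",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
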