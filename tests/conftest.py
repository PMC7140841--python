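import pytest

from repair_carrier import datasets
from repair_carrier.variant_model import (
    CohortGenotypes,
    FilterStatus,
    FuncClass,
    SampleCoverageQC,
    VariantCallQC,
    VariantRecord,
)


@pytest.fixture(scope="session")
def case_variants():
    """The 31 packaged case-variant records."""
    return datasets.load_case_variants()


@pytest.fixture(scope="session")
def default_panel():
    return datasets.load_default_panel()


@pytest.fixture(scope="session")
def carrier_counts():
    """Published per-cohort carrier counts keyed by cohort label."""
    return datasets.load_carrier_counts()


def make_variant(key="chr1:100:A:T", gene="ATM", func=FuncClass.MISSENSE, **kw):
    kw.setdefault("ref", "A")
    kw.setdefault("alt", "T")
    return VariantRecord(variant_key=key, gene=gene, func_class=func, **kw)


def make_call_qc(af=0.5, depth=40, rprs=None, status=FilterStatus.PASS):
    return VariantCallQC(
        allele_fraction=af, depth=depth, read_pos_rank_sum=rprs, filter_status=status
    )


def make_cohort(n_samples=4, calls=(), frac=0.9, label="test"):
    samples = [
        SampleCoverageQC(sample_id=f"s{i}", frac_bases_ge_20x=frac)
        for i in range(n_samples)
    ]
    return CohortGenotypes(cohort_label=label, samples=samples, calls=list(calls))
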