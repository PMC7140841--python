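"""Variant-table parsing, panel reading, and round-trip I/O."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repair_carrier.tier_classifier import Tier, TierAssignment, TierReason
from repair_carrier.variant_model import (
    ClinVarCode,
    FuncClass,
    RegionClass,
    VariantRecord,
    VariantTableError,
    parse_clinvar_codes,
    parse_number,
    read_assignments,
    read_cohort_genotypes,
    read_gene_panel,
    read_variant_table,
    write_assignments,
    write_cohort_genotypes,
)

from conftest import make_call_qc, make_cohort, make_variant


class TestParsing:
    @pytest.mark.parametrize(
        "token,expected",
        [
            ("2.5e-5", 2.5e-5),
            ("2.5 × 10−5", 2.5e-5),
            ("1.8 × 10−3", 1.8e-3),
            ("3.0 × 10^−4^", 3.0e-4),
            ("0.01", 0.01),
            ("-", None),
            (".", None),
            ("", None),
        ],
    )
    def test_numeric_tokens_including_typeset_scientific_notation(self, token, expected):
        got = parse_number(token)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected)

    def test_multi_submitter_clinvar_string_becomes_code_set(self):
        assert parse_clinvar_codes("5,4,3") == {
            ClinVarCode.PATHOGENIC,
            ClinVarCode.LIKELY_PATHOGENIC,
            ClinVarCode.UNCERTAIN,
        }
        assert parse_clinvar_codes("-") == frozenset()

    def test_unknown_clinvar_code_rejected(self):
        with pytest.raises(VariantTableError, match="ClinVar"):
            parse_clinvar_codes("7")


class TestVariantTable:
    def test_packaged_fixture_parses_completely(self, case_variants):
        assert len(case_variants) == 31
        truncating = [v for v in case_variants if v.func_class.is_truncating]
        missense = [v for v in case_variants if v.func_class is FuncClass.MISSENSE]
        assert len(truncating) == 11
        assert len(missense) == 20

    def test_stopgain_row_with_scores(self, case_variants):
        v = next(v for v in case_variants if v.protein_change == "Q852X")
        assert v.gene == "ATM"
        assert v.func_class is FuncClass.STOPGAIN
        assert v.clinvar_codes == {ClinVarCode.PATHOGENIC}
        assert v.cadd_phred == 35
        assert v.revel is None
        assert v.maf == pytest.approx(2.5e-5)

    def test_frameshift_row_with_all_scores_missing(self, case_variants):
        v = next(v for v in case_variants if v.protein_change == "S2611fs")
        assert v.func_class is FuncClass.FRAMESHIFT_DELETION
        assert v.clinvar_codes == frozenset()
        assert v.cadd_phred is None and v.revel is None and v.maf is None

    def test_empty_data_section_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("gene\ttype\tclinvar\tcadd\trevel\tmaf\n")
        assert read_variant_table(p) == []

    def test_missing_required_column_is_an_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene\ttype\tclinvar\n")
        with pytest.raises(VariantTableError, match="missing required column"):
            read_variant_table(p)

    def test_unknown_func_class_token_lists_accepted_tokens(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "gene\ttype\tclinvar\tcadd\trevel\tmaf\nATM\tweird\t-\t-\t-\t-\n"
        )
        with pytest.raises(VariantTableError, match="accepted tokens"):
            read_variant_table(p)

    def test_malformed_row_names_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "gene\ttype\tclinvar\tcadd\trevel\tmaf\n"
            "ATM\tmissense\t-\t30\t0.8\t1e-4\n"
            "ATM\tmissense\t-\tnot_a_number\t0.8\t1e-4\n"
        )
        with pytest.raises(VariantTableError, match="line 3"):
            read_variant_table(p)

    def test_vcf_dialect_with_mapped_info_keys(self, tmp_path):
        vcf = tmp_path / "test.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=GENE,Number=1,Type=String,Description="gene">\n'
            '##INFO=<ID=FUNC,Number=1,Type=String,Description="class">\n'
            '##INFO=<ID=CADD_PHRED,Number=1,Type=Float,Description="cadd">\n'
            '##INFO=<ID=REVEL,Number=1,Type=Float,Description="revel">\n'
            '##INFO=<ID=MAF,Number=1,Type=Float,Description="maf">\n'
            '##INFO=<ID=CLNSIG_CODES,Number=1,Type=String,Description="clinvar">\n'
            "##contig=<ID=chr11>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr11\t108121410\trs758081262\tC\tT\t.\t.\t"
            "GENE=ATM;FUNC=stopgain;CADD_PHRED=35;CLNSIG_CODES=5;MAF=2.5e-5\n"
        )
        (rec,) = read_variant_table(vcf, dialect="VCF")
        assert rec.variant_key == "chr11:108121410:C:T"
        assert rec.gene == "ATM"
        assert rec.func_class is FuncClass.STOPGAIN
        assert rec.clinvar_codes == {ClinVarCode.PATHOGENIC}
        assert rec.cadd_phred == pytest.approx(35)
        assert rec.revel is None


class TestGenePanel:
    def test_comments_and_duplicates(self, tmp_path):
        p = tmp_path / "panel.txt"
        p.write_text("# header\nATM\natm\nCHEK2  # trailing comment\n")
        panel = read_gene_panel(p)
        assert len(panel) == 2
        assert "ATM" in panel and "Atm" in panel

    def test_only_comments_is_an_error(self, tmp_path):
        p = tmp_path / "panel.txt"
        p.write_text("# nothing\n# here\n")
        with pytest.raises(VariantTableError, match="no gene symbols"):
            read_gene_panel(p)

    def test_default_panel_covers_observed_genes(self, default_panel, case_variants):
        assert all(v.gene in default_panel for v in case_variants)


class TestRecordInvariants:
    def test_revel_and_maf_ranges_enforced(self):
        with pytest.raises(ValueError):
            make_variant(revel=1.2)
        with pytest.raises(ValueError):
            make_variant(maf=0.6)

    def test_missense_must_be_single_nucleotide(self):
        with pytest.raises(ValueError, match="single-nucleotide"):
            make_variant(ref="AT", alt="G", func=FuncClass.MISSENSE)


# hypothesis strategies for assignment round-trips
_variants = st.builds(
    make_variant,
    key=st.from_regex(r"chr[0-9]{1,2}:[0-9]{1,6}:A:T", fullmatch=True),
    gene=st.sampled_from(["ATM", "CHEK2", "BRCA2", "TP53"]),
    func=st.sampled_from([FuncClass.STOPGAIN, FuncClass.MISSENSE, FuncClass.SPLICING]),
    clinvar_codes=st.frozensets(st.sampled_from(list(ClinVarCode)), max_size=3),
    cadd_phred=st.one_of(st.none(), st.floats(0, 60, allow_nan=False)),
    revel=st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
    maf=st.one_of(st.none(), st.floats(0, 0.5, allow_nan=False)),
    disrupts_domain=st.one_of(st.none(), st.booleans()),
    protein_change=st.one_of(st.none(), st.just("Q852X")),
    region_class=st.sampled_from(list(RegionClass)),
)

_tiers = st.sampled_from(
    [
        (Tier.TIER1, TierReason.TRUNCATING_PLP),
        (Tier.TIER2, TierReason.MISSENSE_SCORES),
        (Tier.NEUTRAL, TierReason.NO_RULE_MET),
        (Tier.EXCLUDED, TierReason.COMMON),
    ]
)


class TestRoundTrips:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(_variants, _tiers), max_size=8))
    def test_assignment_tsv_round_trip(self, tmp_path_factory, pairs):
        # deduplicate keys; one logical record per variant
        seen, unique = set(), []
        for rec, (tier, reason) in pairs:
            if rec.variant_key not in seen:
                seen.add(rec.variant_key)
                unique.append(
                    (rec, TierAssignment(rec.variant_key, tier, reason))
                )
        path = tmp_path_factory.mktemp("rt") / "assignments.tsv"
        write_assignments(unique, path)
        back = read_assignments(path)
        assert back == unique

    def test_empty_assignments_write_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_assignments([], path)
        assert path.read_text().count("\n") == 1
        assert read_assignments(path) == []

    def test_cohort_genotype_round_trip(self, tmp_path):
        v1 = make_variant("chr1:1:A:T", cadd_phred=33.5, revel=0.8, maf=1e-4)
        v2 = make_variant(
            "chr2:2:G:-", gene="CHEK2", func=FuncClass.FRAMESHIFT_DELETION,
            ref="G", alt="-", clinvar_codes=frozenset({ClinVarCode.PATHOGENIC}),
        )
        cohort = make_cohort(
            n_samples=3,
            calls=[
                ("s0", v1, make_call_qc(af=0.45, depth=33, rprs=-0.5)),
                ("s1", v2, make_call_qc(af=0.51, depth=20)),
            ],
        )
        path = tmp_path / "cohort.tsv"
        write_cohort_genotypes(cohort, path)
        back = read_cohort_genotypes(path, "test")
        assert back.n_samples == 3
        assert sorted(back.samples, key=lambda s: s.sample_id) == sorted(
            cohort.samples, key=lambda s: s.sample_id
        )
        assert back.calls == cohort.calls
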