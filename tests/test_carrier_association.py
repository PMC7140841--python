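"""Carrier counting, Fisher's exact test, and the published regression suite."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from repair_carrier.carrier_association import (
    CarrierCount,
    associate,
    build_association_table,
    case_carriers,
    control_carriers,
    expected_carriers,
    fisher_two_sided,
    render_p,
)
from repair_carrier.tier_classifier import Tier, TierAssignment, TierReason
from repair_carrier.variant_model import ControlGeneCounts

from conftest import make_call_qc, make_cohort, make_variant
from oracles import fisher_oracle


def _t1(key):
    return TierAssignment(key, Tier.TIER1, TierReason.TRUNCATING_PLP)


def _t2(key):
    return TierAssignment(key, Tier.TIER2, TierReason.MISSENSE_SCORES)


class TestCaseCarriers:
    def test_individual_with_two_qualifying_variants_counts_once(self):
        v1 = make_variant("k1", gene="ATM")
        v2 = make_variant("k2", gene="ATM")
        cohort = make_cohort(
            n_samples=5,
            calls=[("s0", v1, make_call_qc()), ("s0", v2, make_call_qc())],
        )
        out = case_carriers(cohort, [_t1("k1"), _t1("k2")], Tier.TIER1, gene="ATM")
        assert out.n_carriers == 1
        assert out.n_total == 5

    def test_distinct_carriers_in_distinct_genes_counted_in_all(self):
        calls, assignments = [], []
        for i, gene in enumerate(["ATM", "CHEK2", "TP53"]):
            v = make_variant(f"k{i}", gene=gene)
            calls.append((f"s{i}", v, make_call_qc()))
            assignments.append(_t1(f"k{i}"))
        cohort = make_cohort(n_samples=6, calls=calls)
        assert case_carriers(cohort, assignments, Tier.TIER1).n_carriers == 3

    def test_no_qualifying_variants_gives_zero_rate(self):
        cohort = make_cohort(n_samples=4)
        out = case_carriers(cohort, [], Tier.TIER1)
        assert out.n_carriers == 0 and out.rate == 0.0

    def test_uncovered_variant_is_an_error(self):
        cohort = make_cohort(
            n_samples=2, calls=[("s0", make_variant("k1"), make_call_qc())]
        )
        with pytest.raises(ValueError, match="do not cover"):
            case_carriers(cohort, [], Tier.TIER1)

    def test_neutral_is_not_a_burden_category(self):
        with pytest.raises(ValueError, match="burden"):
            case_carriers(make_cohort(), [], Tier.NEUTRAL)


def _control(rows, label="ctrl"):
    return ControlGeneCounts(population_label=label, rows=rows)


class TestControlCarriers:
    def test_allele_counts_sum_within_gene(self):
        v1, v2 = make_variant("k1"), make_variant("k2")
        counts = _control([("ATM", v1, 3, 1000), ("ATM", v2, 2, 1000)])
        out = control_carriers(counts, [_t1("k1"), _t1("k2")], Tier.TIER1, gene="ATM")
        assert out.n_carriers == 5 and out.n_total == 1000

    @pytest.mark.parametrize(
        "per_gene,total",
        [([0, 0, 4, 89, 24, 60], 177), ([3, 0, 10, 44, 39, 5], 101)],
    )
    def test_all_row_sums_per_gene_counts(self, per_gene, total):
        genes = ["ERCC3", "RAD18", "ATM", "FANCM", "NTHL1", "CHEK2"]
        rows, assignments = [], []
        for g, ac in zip(genes, per_gene):
            v = make_variant(f"k{g}", gene=g)
            rows.append((g, v, ac, 6192))
            assignments.append(_t1(f"k{g}"))
        out = control_carriers(_control(rows), assignments, Tier.TIER1)
        assert out.n_carriers == total

    def test_non_qualifying_variants_ignored(self):
        v1, v2 = make_variant("k1"), make_variant("k2")
        counts = _control([("ATM", v1, 3, 1000), ("ATM", v2, 7, 1000)])
        out = control_carriers(counts, [_t1("k1"), _t2("k2")], Tier.TIER1)
        assert out.n_carriers == 3

    def test_inconsistent_denominators_rejected(self):
        counts = _control(
            [("ATM", make_variant("k1"), 1, 1000), ("ATM", make_variant("k2"), 1, 999)]
        )
        with pytest.raises(ValueError, match="denominator"):
            control_carriers(counts, [_t1("k1"), _t1("k2")], Tier.TIER1)


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((1, 121, 0, 6192), 0.019),
            ((1, 121, 0, 3307), 0.036),
            ((0, 122, 0, 60), 1.0),
            ((2, 120, 7, 6185), 0.012),
        ],
    )
    def test_published_three_decimal_values(self, table, expected):
        assert round(fisher_two_sided(*table), 3) == expected

    def test_matches_exact_enumeration_oracle(self):
        for table in [(5, 117, 1, 6191), (3, 4, 2, 9), (0, 8, 5, 3), (7, 0, 0, 7)]:
            assert fisher_two_sided(*table) == pytest.approx(
                float(fisher_oracle(*table)), rel=1e-9
            )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 25)] * 4))
    def test_matches_scipy_and_symmetry(self, table):
        a, b, c, d = table
        if a + b == 0 or c + d == 0:
            return
        p = fisher_two_sided(a, b, c, d)
        assert p == pytest.approx(scipy_fisher([[a, b], [c, d]])[1], rel=1e-6, abs=1e-12)
        # row swap and column swap leave the two-sided p unchanged
        assert p == pytest.approx(fisher_two_sided(c, d, a, b), rel=1e-9)
        assert p == pytest.approx(fisher_two_sided(b, a, d, c), rel=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 30)] * 4))
    def test_p_at_least_point_probability_and_in_unit_interval(self, table):
        a, b, c, d = table
        if a + b == 0 or c + d == 0:
            return
        from scipy.stats import hypergeom

        p = fisher_two_sided(a, b, c, d)
        point = hypergeom.pmf(a, a + b + c + d, a + b, a + c)
        assert point * (1 - 1e-9) <= p <= 1.0

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            fisher_two_sided(-1, 2, 3, 4)


class TestExpectedCarriers:
    def test_external_cohort_rate_projected_onto_study_size(self):
        assert round(expected_carriers(0.0093, 122), 1) == 1.1

    def test_linearity_and_bounds(self):
        assert expected_carriers(0.0, 50) == 0.0
        assert expected_carriers(1.0, 7) == 7.0
        assert expected_carriers(0.2, 10) * 3 == pytest.approx(expected_carriers(0.2, 30))
        with pytest.raises(ValueError):
            expected_carriers(1.5, 10)


# Published carrier-rate table: expected rendered p-values per gene, tier and
# comparison cohort (unselected cases, Finnish controls, Swedish controls).
PUBLISHED_P = {
    ("TIER1", "ERCC3"): ("1.000", "0.036", "0.075"),
    ("TIER1", "RAD18"): ("1.000", "0.036", "0.019"),
    ("TIER1", "ATM"): ("0.304", "<0.001", "<0.001"),
    ("TIER1", "FANCM"): ("1.000", "0.772", "0.223"),
    ("TIER1", "NTHL1"): ("1.000", "0.236", "0.187"),
    ("TIER1", "CHEK2"): ("0.173", "0.080", "<0.001"),
    ("TIER1", "ALL"): ("0.003", "0.004", "<0.001"),
    ("TIER2", "MUTYH"): ("0.330", "0.633", "0.406"),
    ("TIER2", "ERCC3"): ("0.552", "0.195", "0.093"),
    ("TIER2", "HLTF"): ("1.000", "0.534", "0.177"),
    ("TIER2", "POLL"): ("1.000", "0.441", "0.433"),
    ("TIER2", "MRE11A"): ("1.000", "0.036", "0.019"),
    ("TIER2", "ATM"): ("1.000", "0.098", "0.114"),
    ("TIER2", "RECQL"): ("1.000", "0.036", "0.239"),
    ("TIER2", "FAN1"): ("1.000", "0.103", "0.283"),
    ("TIER2", "NEIL1"): ("1.000", "0.135", "0.283"),
    ("TIER2", "POLG"): ("0.173", "0.555", "0.429"),
    ("TIER2", "TP53"): ("1.000", "0.012", "0.012"),
    ("TIER2", "BRCA1"): ("1.000", "0.103", "0.111"),
    ("TIER2", "RECQL5"): ("1.000", "0.135", "0.038"),
    ("TIER2", "CHEK2"): ("0.552", "0.103", "0.433"),
    ("TIER2", "ALL"): ("0.123", "0.148", "0.011"),
}


class TestPublishedRegression:
    def test_every_published_p_value_reproduced(self, carrier_counts):
        lethal = {(c.tier.name, c.gene): c for c in carrier_counts["lethal"]}
        comps = {
            label: {(c.tier.name, c.gene): c for c in carrier_counts[label]}
            for label in ("unselected", "finnish", "swedish")
        }
        for (tier, gene), expected in PUBLISHED_P.items():
            for label, exp in zip(("unselected", "finnish", "swedish"), expected):
                res = associate(lethal[(tier, gene)], comps[label][(tier, gene)])
                assert res.p_rendered == exp, f"{tier} {gene} vs {label}"

    def test_rendering_floor(self):
        assert render_p(0.0004999) == "<0.001"
        assert render_p(0.0005) == "0.001"
        assert render_p(0.9996) == "1.000"


class TestBuildAssociationTable:
    def test_symmetric_cohorts_give_p_one(self):
        from repair_carrier.variant_model import CohortGenotypes, SampleCoverageQC

        v = make_variant("k1", gene="ATM")
        case = make_cohort(n_samples=4, calls=[("s0", v, make_call_qc())], label="case")
        comp = CohortGenotypes(
            "comp",
            [SampleCoverageQC(f"c{i}", 0.9) for i in range(4)],
            [("c0", v, make_call_qc())],
        )
        results = build_association_table(case, [comp], [_t1("k1")])
        assert results and all(r.p_value == pytest.approx(1.0) for r in results)

    def test_overlapping_sample_ids_rejected(self):
        case = make_cohort(n_samples=2, label="case")
        comp = make_cohort(n_samples=2, label="comp")  # same s0/s1 ids
        with pytest.raises(ValueError, match="shared"):
            build_association_table(case, [comp], [])

    def test_rows_cover_genes_and_all(self):
        v1 = make_variant("k1", gene="ATM")
        v2 = make_variant("k2", gene="CHEK2")
        case = make_cohort(
            n_samples=6,
            calls=[("s0", v1, make_call_qc()), ("s1", v2, make_call_qc())],
            label="case",
        )
        ctrl = _control([("ATM", v1, 4, 1000), ("CHEK2", v2, 0, 1000)])
        results = build_association_table(case, [ctrl], [_t1("k1"), _t1("k2")])
        keys = {(r.tier.name, r.gene) for r in results}
        assert keys == {("TIER1", "ATM"), ("TIER1", "CHEK2"), ("TIER1", "ALL")}
        all_row = next(r for r in results if r.gene == "ALL")
        assert all_row.table == (2, 4, 4, 996)
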