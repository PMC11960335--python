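"""Exact-test and phasing statistics against independent oracles."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from comphet.stats import (
    ContingencyTable,
    aggregate_frequency_test,
    ascertain_control_compound_het,
    carrier_burden_test,
    contingency_test,
    fisher_exact_two_tailed,
    odds_ratio_woolf,
    phase_by_transmission,
)


def fisher_oracle(a, b, c, d):
    """Exact-rational minimum-likelihood two-sided p by enumeration."""
    N, K, n = a + b + c + d, a + b, a + c
    k_min, k_max = max(0, n - (N - K)), min(K, n)
    nums = [comb(K, k) * comb(N - K, n - k) for k in range(k_min, k_max + 1)]
    obs = nums[a - k_min]
    return float(Fraction(sum(x for x in nums if x <= obs), comb(N, n)))


def test_fisher_enumeration_example():
    """(1,9,11,3): the sum over the 13 same-margin tables no likelier than
    the observed one is ~2.76e-3."""
    p = fisher_exact_two_tailed((1, 9, 11, 3))
    assert p == pytest.approx(fisher_oracle(1, 9, 11, 3), rel=1e-12)
    assert p == pytest.approx(2.7594561852200833e-3, rel=1e-9)


def test_fisher_degenerate_margin():
    assert fisher_exact_two_tailed((0, 10, 0, 20)) == 1.0
    assert fisher_exact_two_tailed((10, 0, 20, 0)) == 1.0


@settings(max_examples=150, deadline=None)
@given(st.tuples(*[st.integers(0, 40)] * 4))
def test_fisher_matches_exact_oracle_and_scipy(cells):
    a, b, c, d = cells
    if a + b == 0 or c + d == 0:
        return
    p = fisher_exact_two_tailed((a, b, c, d))
    assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-10, abs=1e-300)
    assert p == pytest.approx(scipy_fisher([[a, b], [c, d]])[1], rel=1e-7, abs=1e-300)


def test_fisher_large_margin_stability():
    """Log-space evaluation stays exact at reference-population scale."""
    p = fisher_exact_two_tailed((10, 572, 189, 250470 - 189))
    assert p == pytest.approx(scipy_fisher([[10, 572], [189, 250470 - 189]])[1], rel=1e-9)
    assert p < 0.001


def test_negative_cell_rejected():
    with pytest.raises(ValueError):
        fisher_exact_two_tailed((-1, 5, 5, 5))


# ---------------------------------------------------------------------------
# odds ratio + Woolf interval
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "table,orr,lo,hi",
    [
        ((10, 572, 189, 250470 - 189), 23.15, 12.19, 43.96),
        ((5, 286, 9, 1933), 3.75, 1.25, 11.28),
    ],
)
def test_woolf_reproduces_published_intervals(table, orr, lo, hi):
    est, ci_lo, ci_hi, corrected = odds_ratio_woolf(table)
    assert not corrected
    assert round(est, 2) == orr
    assert round(ci_lo, 2) == lo
    assert round(ci_hi, 2) == hi


def test_symmetric_table_gives_unit_or():
    est, lo, hi, _ = odds_ratio_woolf((7, 7, 7, 7))
    assert est == pytest.approx(1.0)
    assert lo * hi == pytest.approx(1.0)  # symmetric about 1 in log space


def test_zero_cell_haldane_correction_and_undefined_diagonal():
    est, lo, hi, corrected = odds_ratio_woolf((0, 10, 5, 5))
    assert corrected and est is not None and lo < est < hi
    est2, lo2, hi2, _ = odds_ratio_woolf((0, 10, 5, 0))
    assert est2 is None and lo2 is None
    # p is still computable for the undefined-OR table
    res = contingency_test((0, 10, 5, 0))
    assert res.odds_ratio is None and 0 <= res.p_value <= 1


@settings(max_examples=60, deadline=None)
@given(st.tuples(*[st.integers(1, 60)] * 4))
def test_row_exchange_inverts_or_and_preserves_p(cells):
    """Swapping the table's rows maps OR -> 1/OR, flips and inverts the CI,
    and leaves the p-value unchanged."""
    a, b, c, d = cells
    p1 = fisher_exact_two_tailed((a, b, c, d))
    p2 = fisher_exact_two_tailed((c, d, a, b))
    assert p1 == pytest.approx(p2, rel=1e-12)
    or1, lo1, hi1, _ = odds_ratio_woolf((a, b, c, d))
    or2, lo2, hi2, _ = odds_ratio_woolf((c, d, a, b))
    assert or2 == pytest.approx(1 / or1)
    assert lo2 == pytest.approx(1 / hi1)
    assert hi2 == pytest.approx(1 / lo1)


def test_ci_brackets_or_when_all_cells_positive():
    res = contingency_test((3, 17, 11, 29))
    assert res.ci_low <= res.odds_ratio <= res.ci_high


# ---------------------------------------------------------------------------
# aggregate frequency comparison
# ---------------------------------------------------------------------------

def test_aggregate_counts_and_statistics(study_annotations):
    """Reference numerators are the per-variant column sums (189/71/151/61);
    with the published single-denominator totals the four comparisons give
    the published ORs."""
    from comphet import study

    case_ac, case_an = study.case_allele_counts()
    assert (case_ac, case_an) == (10, 582)
    summary = aggregate_frequency_test(
        case_ac, case_an, study_annotations.values(),
        reference_allele_number=study.PRINTED_REFERENCE_AN,
    )
    assert summary.reference_counts["all"] == (189, 250470)
    assert summary.reference_counts["control"] == (71, 106914)
    assert summary.reference_counts["eas_all"] == (151, 18324)
    assert summary.reference_counts["eas_control"] == (61, 9036)
    assert round(summary.per_population["all"].odds_ratio, 2) == 23.15
    assert round(summary.per_population["eas_control"].odds_ratio, 2) == 2.57


def test_aggregate_min_an_mode_is_conservative(study_annotations):
    """Without an override the denominator is the smallest allele number
    among variants observed in that population."""
    summary = aggregate_frequency_test(10, 582, study_annotations.values())
    assert summary.reference_counts["all"][1] == 250470
    assert summary.reference_counts["eas_control"][1] == 8972


def test_aggregate_identical_frequency_gives_unit_or():
    from comphet.models import AnnotationRecord, PopulationFrequency, Variant

    v = Variant("1", 1, "A", "G", gene="G")
    rec = AnnotationRecord(
        variant=v,
        frequencies={"all": PopulationFrequency(v.key, "all", 100, 10000, 0)},
    )
    summary = aggregate_frequency_test(10, 1000, [rec], populations=("all",))
    assert summary.per_population["all"].odds_ratio == pytest.approx(1.0)


def test_aggregate_empty_variant_set_rejected():
    with pytest.raises(ValueError):
        aggregate_frequency_test(1, 100, [])


# ---------------------------------------------------------------------------
# transmission phasing
# ---------------------------------------------------------------------------

def phasing_oracle(child_a, child_b):
    """Enumerate the double-het parent's two diplotype configurations and
    the transmissible haplotypes; the other parent contributes ref alleles."""
    if child_a is None or child_b is None:
        return "unresolved"
    consistent = set()
    for phase, haplotypes in (("cis", [(1, 1), (0, 0)]), ("trans", [(1, 0), (0, 1)])):
        for hap in haplotypes:
            if (bool(hap[0]), bool(hap[1])) == (child_a, child_b):
                consistent.add(phase)
    assert len(consistent) == 1  # the four child states partition cleanly
    return consistent.pop()


@pytest.mark.parametrize(
    "child_a,child_b",
    list(itertools.product((False, True, None), repeat=2)),
)
def test_phasing_matches_diplotype_enumeration(child_a, child_b):
    assert phase_by_transmission(child_a, child_b) == (
        "unresolved" if None in (child_a, child_b) else phasing_oracle(child_a, child_b)
    )


def test_ascertainment_counts_only_trans():
    pairs = [("p1", ("1", 1, "A", "G"), ("1", 2, "C", "T")),
             ("p2", ("1", 1, "A", "G"), ("1", 2, "C", "T")),
             ("p3", ("1", 1, "A", "G"), ("1", 2, "C", "T"))]
    carrier = {
        ("p1", ("1", 1, "A", "G")): True, ("p1", ("1", 2, "C", "T")): False,   # trans
        ("p2", ("1", 1, "A", "G")): True, ("p2", ("1", 2, "C", "T")): True,    # cis
        ("p3", ("1", 1, "A", "G")): None, ("p3", ("1", 2, "C", "T")): True,    # unresolved
    }
    result = ascertain_control_compound_het(pairs, carrier)
    assert result.trans_parent_ids == ["p1"]
    assert len(result.cis_carriers) == 1
    assert len(result.unresolved) == 1


# ---------------------------------------------------------------------------
# carrier burden
# ---------------------------------------------------------------------------

def test_burden_reproduces_published_summary():
    burden = carrier_burden_test(5, 291, 9, 1942)
    r = burden.result
    assert round(r.odds_ratio, 2) == 3.75
    assert round(r.ci_low, 2) == 1.25
    assert round(r.ci_high, 2) == 11.28
    assert round(r.p_value, 3) == 0.027


def test_burden_null_table():
    burden = carrier_burden_test(0, 100, 0, 100)
    assert burden.result.p_value == 1.0
    # zero cells exercise the Haldane–Anscombe path; corrected OR is unity
    assert burden.result.corrected
    assert burden.result.odds_ratio == pytest.approx(1.0)


def test_burden_validates_cohort_sizes():
    with pytest.raises(ValueError):
        carrier_burden_test(10, 5, 0, 100)
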