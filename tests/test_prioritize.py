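"""Filter-cascade tests: MAF boundaries, consequence classes, inheritance
classification against brute-force enumeration, compound-het pairing,
stratified criteria, exclusions and recurrence."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comphet.io import HET, HOM_ALT, HOM_REF, MISSING
from comphet.models import (
    AnnotationRecord,
    PopulationFrequency,
    Variant,
)
from comphet.prioritize import (
    CandidateVariant,
    FilterConfig,
    GeneProfile,
    apply_stratified_criteria,
    classify_inheritance,
    exclude_known_gene_carriers,
    filter_by_consequence,
    find_compound_het_pairs,
    gene_profile_filter,
    prefilter_by_maf,
    prioritize_cohort,
    screen_recurrent_genes,
)


def make_record(freq_all=0.0, consequence="missense", gene="G1", pos=100, ac_control=0):
    an = 1_000_000
    variant = Variant(
        "1", pos, "A", "G", gene=gene, consequence=consequence,
        protein_pos=10 if consequence in ("missense", "inframe_indel") else None,
        ref_aa="A" if consequence == "missense" else None,
        alt_aa="V" if consequence == "missense" else None,
    )
    freqs = {
        "all": PopulationFrequency(variant.key, "all", int(round(freq_all * an)), an, 0),
        "control": PopulationFrequency(variant.key, "control", ac_control, 100000, 0),
    }
    return AnnotationRecord(variant=variant, frequencies=freqs)


@pytest.mark.parametrize(
    "maf,kept",
    [(6e-3, False), (0.0, True), (5e-3, True), (5.001e-3, False), (1e-4, True)],
)
def test_prefilter_maf_boundary_is_strict(maf, kept):
    """Variants are dropped only when MAF is strictly above 5e-3."""
    rec = make_record(freq_all=maf)
    assert prefilter_by_maf(rec, FilterConfig())[0] is kept


@pytest.mark.parametrize(
    "consequence,kept",
    [
        ("missense", True), ("canonical_splice", True), ("nonsense", True),
        ("frameshift", True), ("inframe_indel", True), ("initiation_codon", True),
        ("other", False),
    ],
)
def test_consequence_filter(consequence, kept):
    rec = make_record(consequence=consequence)
    assert filter_by_consequence(rec.variant)[0] is kept


# ---------------------------------------------------------------------------
# inheritance classification
# ---------------------------------------------------------------------------

def oracle_classify(child, father, mother):
    """Independent enumeration oracle for diploid trio classification."""
    t = {0: {0}, 1: {0, 1}, 2: {1}}
    consistent = any(f + m == child for f in t[father] for m in t[mother])
    if not consistent:
        if child == 1 and father == 0 and mother == 0:
            return "de_novo"
        return "inconsistent"
    if child == 2:
        return "homozygous"
    if child == 0:
        return "none"
    return "inherited_het"


@pytest.mark.parametrize("combo", list(itertools.product((0, 1, 2), repeat=3)))
def test_classification_matches_enumeration_and_is_exclusive(combo):
    """Over all 27 diploid combinations the classifier agrees with the
    enumeration oracle; categories are mutually exclusive by construction."""
    child, father, mother = combo
    inheritance, origin = classify_inheritance(child, father, mother)
    assert inheritance == oracle_classify(child, father, mother)
    if inheritance == "inherited_het":
        father_can, mother_can = father >= 1, mother >= 1
        expected = (
            "unresolved" if (father_can and mother_can)
            else "paternal" if father_can else "maternal"
        )
        assert origin == expected


def test_forced_classifications():
    assert classify_inheritance(HET, HET, HOM_REF) == ("inherited_het", "paternal")
    assert classify_inheritance(HET, HOM_REF, HOM_REF) == ("de_novo", "unresolved")
    assert classify_inheritance(HOM_ALT, HET, HET) == ("homozygous", "both")
    assert classify_inheritance(HET, MISSING, HOM_REF)[0] == "unresolvable"


# ---------------------------------------------------------------------------
# pairing + stratified criteria
# ---------------------------------------------------------------------------

def _cands(records, origins):
    return [
        CandidateVariant(rec.variant, "p1", "inherited_het", origin)
        for rec, origin in zip(records, origins)
    ]


def test_pairing_requires_opposite_origins():
    a = make_record(freq_all=1e-4, pos=1)
    b = make_record(freq_all=1e-4, pos=2)
    ann = {a.variant.key: a, b.variant.key: b}
    cfg = FilterConfig()
    pairs = find_compound_het_pairs("p1", "G1", _cands([a, b], ["paternal", "maternal"]), ann, cfg)
    assert len(pairs) == 1
    assert pairs[0].product_frequency == pytest.approx(1e-8)
    assert not find_compound_het_pairs("p1", "G1", _cands([a, b], ["paternal", "paternal"]), ann, cfg)
    assert not find_compound_het_pairs("p1", "G1", _cands([a, b], ["unresolved", "maternal"]), ann, cfg)


def test_three_het_gene_yields_all_cross_origin_pairs_flagged():
    recs = [make_record(freq_all=1e-4, pos=p) for p in (1, 2, 3)]
    ann = {r.variant.key: r for r in recs}
    pairs = find_compound_het_pairs(
        "p1", "G1", _cands(recs, ["paternal", "paternal", "maternal"]), ann, FilterConfig()
    )
    assert len(pairs) == 2
    assert all(p.shares_variant for p in pairs)


def test_stratified_criteria():
    cfg = FilterConfig()
    dn = make_record(freq_all=0.0, ac_control=1)
    cand = CandidateVariant(dn.variant, "p1", "de_novo", "unresolved")
    assert not apply_stratified_criteria(cand, {dn.variant.key: dn}, cfg)[0]
    dn0 = make_record(freq_all=0.0, ac_control=0)
    cand0 = CandidateVariant(dn0.variant, "p1", "de_novo", "unresolved")
    assert apply_stratified_criteria(cand0, {dn0.variant.key: dn0}, cfg)[0]
    # pair above the product threshold is dropped: 2e-3 * 2e-3 = 4e-6
    a = make_record(freq_all=2e-3, pos=1)
    b = make_record(freq_all=2e-3, pos=2)
    ann = {a.variant.key: a, b.variant.key: b}
    pair = find_compound_het_pairs(
        "p1", "G1", _cands([a, b], ["paternal", "maternal"]), ann, cfg
    )[0]
    ok, reason = apply_stratified_criteria(pair, ann, cfg)
    assert not ok and "product" in reason


def test_case_pair_products_from_reference_counts(by_hgvs, study_annotations):
    """The five case pairs all pass the 1e-6 frequency-product rule; the
    first case's product multiplies to ~1.55e-9."""
    from comphet.study import CASE_PAIRS

    cfg = FilterConfig()
    for case_id, (pat, mat) in CASE_PAIRS.items():
        fa = by_hgvs[pat].frequency("all")
        fb = by_hgvs[mat].frequency("all")
        assert fa * fb < cfg.comphet_product_max
    f1 = by_hgvs["c.10948A>G"].frequency("all") * by_hgvs["c.3371C>T"].frequency("all")
    assert f1 == pytest.approx(1.55e-9, rel=5e-3)


# ---------------------------------------------------------------------------
# exclusions, profiles, recurrence
# ---------------------------------------------------------------------------

def test_known_gene_exclusion():
    rec = make_record(gene="SCN1A")
    ann = {rec.variant.key: rec}
    from comphet.prioritize import TrioCandidates
    from comphet.models import Trio

    tc = {
        "p1": TrioCandidates(Trio("p1", "f1", "m1")),
        "p2": TrioCandidates(Trio("p2", "f2", "m2")),
    }
    cfg = FilterConfig(known_gene_list=frozenset({"SCN1A"}))
    kept, excluded = exclude_known_gene_carriers(tc, {"p1": {rec.variant.key}}, ann, cfg)
    assert excluded == ["p1"] and set(kept) == {"p2"}
    kept2, excluded2 = exclude_known_gene_carriers(tc, {"p1": {rec.variant.key}}, ann, FilterConfig())
    assert not excluded2 and set(kept2) == {"p1", "p2"}


def test_gene_profile_policy():
    cfg_pass = FilterConfig(unknown_facet_passes=True)
    cfg_fail = FilterConfig(unknown_facet_passes=False)
    good = GeneProfile("G", True, False, True, True)
    assert gene_profile_filter(good, cfg_pass)[0]
    conflicted = GeneProfile("G", True, True, True, True)
    assert not gene_profile_filter(conflicted, cfg_pass)[0]
    unknown = GeneProfile("G", True, False, None, True)
    assert gene_profile_filter(unknown, cfg_pass)[0]
    assert not gene_profile_filter(unknown, cfg_fail)[0]


def test_recurrence_counts_genes_and_variants(study_cohort, study_annotations, by_hgvs):
    per_proband, report, excluded = prioritize_cohort(study_cohort, study_annotations)
    assert not excluded
    assert report.gene_counts() == [("MDN1", 5)]
    assert report.recurrent_genes() == ["MDN1"]
    assert report.variant_count(by_hgvs["c.13924C>T"].variant.key) == 2
    assert report.variant_count(by_hgvs["c.2162A>G"].variant.key) == 1


def test_single_carrier_gene_not_recurrent():
    from comphet.prioritize import TrioCandidates
    from comphet.models import Trio

    rec = make_record()
    tc = TrioCandidates(Trio("p1", "f1", "m1"))
    tc.singletons = [CandidateVariant(rec.variant, "p1", "de_novo", "unresolved")]
    report = screen_recurrent_genes({"p1": tc})
    assert report.gene_counts() == [("G1", 1)]
    assert report.recurrent_genes() == []


# ---------------------------------------------------------------------------
# monotonicity property
# ---------------------------------------------------------------------------

@settings(max_examples=30, deadline=None)
@given(
    maf_max=st.floats(min_value=1e-4, max_value=5e-3),
    product_max=st.floats(min_value=1e-9, max_value=5e-5),
)
def test_tightening_thresholds_never_enlarges_candidate_set(maf_max, product_max):
    """Decreasing either threshold can only shrink the surviving set."""
    from comphet import study

    cohort = study.study_cohort()
    annotations = study.study_annotations()
    base = FilterConfig()
    tight = FilterConfig(prefilter_maf_max=maf_max, comphet_product_max=min(product_max, maf_max / 2))
    n_pairs = lambda cfg: sum(
        len(tc.pairs) for tc in prioritize_cohort(cohort, annotations, cfg)[0].values()
    )
    assert n_pairs(tight) <= n_pairs(base)
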