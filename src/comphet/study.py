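"""Worked-example dataset: five trios, nine variants in one target gene.

This module reconstructs, as an in-memory fixture, the published worked
example the pipeline validates against: five unrelated probands each
carrying a compound-heterozygous pair in a single AAA-ATPase gene (eight
missense variants and one splice variant; one missense variant shared by two
cases), together with the per-variant allele counts in four reference
populations.

Genomic coordinates are synthetic (only cDNA- and protein-level names are
published); every operation downstream keys variants by the synthetic
(chrom, pos, ref, alt) tuple, so the coordinates are identity plumbing only.
The splice variant's protein-level localization residue (1302, the codon of
the exonic base its intron abuts) is likewise a fixture input.
"""

from __future__ import annotations

import numpy as np

from .io import HET, HOM_REF, Cohort
from .models import (
    POPULATIONS,
    AnnotationRecord,
    PopulationFrequency,
    Trio,
    Variant,
    VariantKey,
)

TARGET_GENE = "MDN1"
TRANSCRIPT = "NM_014611"
CHROM = "6"

#: Case cohort design: probands, diploid allele number, control parents.
N_CASE_PROBANDS = 291
CASE_ALLELE_NUMBER = 2 * N_CASE_PROBANDS  # 582
N_CONTROL_PARENTS = 1942
CONTROL_COMPHET_PARENTS = 9
CASE_COMPHET_PROBANDS = 5

#: Printed reference-population allele numbers used for the aggregate totals
#: row (the published single-denominator convention).
PRINTED_REFERENCE_AN = {
    "all": 250470,
    "control": 106914,
    "eas_all": 18324,
    "eas_control": 9036,
}

# hgvs_c, hgvs_p, protein_pos, ref_aa, alt_aa, consequence,
# (ac, an) per population in order all/control/eas_all/eas_control,
# hbond_changes, ddg, splice_residue, splice_length_effect
_VARIANT_ROWS = [
    ("c.2162A>G", "p.His721Arg", 721, "H", "R", "missense",
     (6, 282232), (3, 109224), (5, 19926), (2, 9036), 0, None, None, False),
    ("c.2633G>A", "p.Arg878His", 878, "R", "H", "missense",
     (8, 277878), (2, 106914), (3, 19834), (1, 8972), 4, -1.86, None, False),
    ("c.2954C>T", "p.Ser985Leu", 985, "S", "L", "missense",
     None, None, None, None, 3, None, None, False),
    ("c.3371C>T", "p.Thr1124Met", 1124, "T", "M", "missense",
     (2, 251410), (1, 109394), (0, 18390), (0, 9044), 0, None, None, False),
    ("c.10948A>G", "p.Lys3650Glu", 3650, "K", "E", "missense",
     (55, 282826), (18, 120280), (41, 19948), (15, 9962), 2, None, None, False),
    ("c.13396G>T", "p.Val4466Leu", 4466, "V", "L", "missense",
     None, None, None, None, 0, None, None, False),
    ("c.13924C>T", "p.Leu4642Phe", 4642, "L", "F", "missense",
     (19, 282816), (9, 109408), (19, 19954), (9, 9064), 0, None, None, False),
    ("c.14573A>G", "p.Tyr4858Cys", 4858, "Y", "C", "missense",
     (10, 250470), (4, 109132), (10, 18324), (4, 9022), 0, None, None, False),
    ("c.3904+4T>C", "", None, None, None, "canonical_splice",
     (89, 277064), (34, 118528), (73, 19308), (30, 9950), 0, None, 1302, True),
]

#: Per-case compound-het pairs (hgvs_c of the paternal- then the
#: maternal-assigned allele; the first-listed variant of each published pair
#: is assigned to the father — the pairing logic is origin-symmetric).
CASE_PAIRS = {
    "case1": ("c.10948A>G", "c.3371C>T"),
    "case2": ("c.2954C>T", "c.13924C>T"),
    "case3": ("c.2162A>G", "c.14573A>G"),
    "case4": ("c.13924C>T", "c.2633G>A"),
    "case5": ("c.3904+4T>C", "c.13396G>T"),
}

CASE_SEX = {"case1": "male", "case2": "male", "case3": "male", "case4": "female", "case5": "male"}


def study_annotations() -> dict[VariantKey, AnnotationRecord]:
    """The nine study variants with their reference-population counts."""
    records: dict[VariantKey, AnnotationRecord] = {}
    for i, row in enumerate(_VARIANT_ROWS):
        (hgvs_c, hgvs_p, ppos, ref_aa, alt_aa, consequence,
         f_all, f_ctrl, f_eas, f_easctrl, hbonds, ddg, splice_residue, splice_len) = row
        change = hgvs_c.split(">")
        ref, alt = change[0][-1], change[1][0]
        variant = Variant(
            chrom=CHROM,
            pos=90_400_000 + i * 1000,  # synthetic coordinate
            ref=ref,
            alt=alt,
            gene=TARGET_GENE,
            transcript=TRANSCRIPT,
            hgvs_c=hgvs_c,
            hgvs_p=hgvs_p,
            protein_pos=ppos,
            ref_aa=ref_aa,
            alt_aa=alt_aa,
            consequence=consequence,
        )
        frequencies = {}
        for pop, counts in zip(POPULATIONS, (f_all, f_ctrl, f_eas, f_easctrl)):
            if counts is None:
                ac, an = 0, PRINTED_REFERENCE_AN[pop]
            else:
                ac, an = counts
            frequencies[pop] = PopulationFrequency(variant.key, pop, ac, an, 0)
        verdicts = {"MutationTaster": "damaging"} if consequence == "missense" else {}
        records[variant.key] = AnnotationRecord(
            variant=variant,
            insilico_verdicts=verdicts,
            ddg=ddg,
            hbond_changes=hbonds if consequence == "missense" else None,
            frequencies=frequencies,
            splice_residue=splice_residue,
            splice_length_effect=splice_len,
        )
    return records


def variant_by_hgvs(annotations: dict[VariantKey, AnnotationRecord] | None = None) -> dict[str, AnnotationRecord]:
    annotations = annotations or study_annotations()
    return {rec.variant.hgvs_c: rec for rec in annotations.values()}


def study_cohort() -> Cohort:
    """The five published trios: each proband het at both pair members, the
    father het at the paternal-assigned allele, the mother at the maternal
    one, and every other genotype hom-ref."""
    annotations = study_annotations()
    by_hgvs = variant_by_hgvs(annotations)
    variants = [annotations[k].variant for k in sorted(annotations)]
    col = {v.hgvs_c: j for j, v in enumerate(variants)}

    trios, samples, sexes, rows = [], [], {}, []
    for case_id, (pat, mat) in CASE_PAIRS.items():
        pid, fid, mid = case_id, f"{case_id}_fa", f"{case_id}_mo"
        trios.append(Trio(pid, fid, mid, proband_sex=CASE_SEX[case_id], affected=True))
        child = np.full(len(variants), HOM_REF, dtype=np.int8)
        father = np.full(len(variants), HOM_REF, dtype=np.int8)
        mother = np.full(len(variants), HOM_REF, dtype=np.int8)
        child[col[pat]] = child[col[mat]] = HET
        father[col[pat]] = HET
        mother[col[mat]] = HET
        for sid, g, s in (
            (pid, child, CASE_SEX[case_id]),
            (fid, father, "male"),
            (mid, mother, "female"),
        ):
            samples.append(sid)
            sexes[sid] = s
            rows.append(g)
    assert by_hgvs  # nine variants present
    return Cohort(
        trios=trios,
        samples=samples,
        variants=variants,
        genotypes=np.stack(rows),
        sample_sex=sexes,
    )


def case_allele_counts() -> tuple[int, int]:
    """(aggregate case allele count, case allele number): each pair member
    contributes one allele per carrier proband."""
    counts: dict[str, int] = {}
    for pat, mat in CASE_PAIRS.values():
        counts[pat] = counts.get(pat, 0) + 1
        counts[mat] = counts.get(mat, 0) + 1
    return sum(counts.values()), CASE_ALLELE_NUMBER
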