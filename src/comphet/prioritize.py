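"""Case-by-case trio variant-filtering cascade.

The cascade mirrors a recessive-oriented trio WES workflow: a population MAF
pre-filter, a consequence filter, inheritance-pattern classification within
the trio, stratified frequency criteria (strict absence for de novo /
homozygous / hemizygous candidates, a frequency-product rule for biallelic
pairs), exclusion of probands explained by known disease genes, gene-profile
refinement, and cross-cohort recurrence screening.

Boundary semantics are strict inequalities: a variant is dropped when its
MAF is *more than* the pre-filter threshold, and a biallelic pair is kept
when its frequency product is *below* the product threshold.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .io import HEMI, HET, HOM_ALT, HOM_REF, MISSING, Cohort, transmissible_alleles
from .models import AnnotationRecord, Trio, Variant, VariantKey

KEEP_CONSEQUENCES = frozenset(
    {"canonical_splice", "nonsense", "frameshift", "inframe_indel", "missense", "initiation_codon"}
)

INHERITANCE_CLASSES = (
    "de_novo",
    "homozygous",
    "hemizygous",
    "inherited_het",
    "compound_het_member",
)


@dataclass
class FilterConfig:
    """Thresholds and policies of the filtering cascade.

    ``prefilter_maf_max`` — variants with reference-population MAF above this
    are excluded up front.  ``comphet_product_max`` — a biallelic pair
    qualifies when the product of its two allele frequencies is below this;
    the default 1e-6 is well under the expected occurrence of one individual
    in a reference cohort of ~1.4e5 individuals (1/141456 ~= 7e-6).
    """

    prefilter_maf_max: float = 5e-3
    comphet_product_max: float = 1e-6
    reference_cohort_individuals: int = 141456
    #: population whose allele count must be zero for de novo / hom / hemi
    strict_absence_population: str = "control"
    #: population whose frequencies enter the biallelic product rule
    product_population: str = "all"
    #: gene symbols with established disease association; probands carrying a
    #: flagged pathogenic variant in one of these are excluded from the cohort
    known_gene_list: frozenset[str] = frozenset()
    #: policy for unknown gene-profile facets: True = pass, False = fail
    unknown_facet_passes: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.comphet_product_max < self.prefilter_maf_max):
            raise ValueError("require 0 < comphet_product_max < prefilter_maf_max")
        if self.reference_cohort_individuals <= 0:
            raise ValueError("reference_cohort_individuals must be positive")
        self.known_gene_list = frozenset(self.known_gene_list)


@dataclass
class GeneProfile:
    """Four gene-level facets used for candidate refinement: brain
    expression, absence of a conflicting established association, intolerance
    to (biallelic) variation, and a phenotype upon genetic manipulation.
    ``None`` marks an unknown facet, resolved by the config policy."""

    gene: str
    brain_expressed: Optional[bool] = None
    conflicting_association: Optional[bool] = None
    intolerance_ok: Optional[bool] = None
    manipulation_phenotype: Optional[bool] = None


@dataclass
class CandidateVariant:
    variant: Variant
    proband_id: str
    inheritance: str
    parental_origin: str  # {paternal, maternal, both, unresolved}
    passed_filters: list[tuple[str, bool, str]] = field(default_factory=list)

    def record(self, name: str, passed: bool, reason: str = "") -> None:
        self.passed_filters.append((name, passed, reason))


@dataclass
class CompoundHetPair:
    proband_id: str
    gene: str
    variant_a: Variant  # paternal origin
    variant_b: Variant  # maternal origin
    product_frequency: float
    shares_variant: bool = False  # >2 qualifying hets in the gene

    def __post_init__(self) -> None:
        if self.variant_a.key == self.variant_b.key:
            raise ValueError("compound-het pair must contain two distinct variants")

    @property
    def keys(self) -> tuple[VariantKey, VariantKey]:
        return (self.variant_a.key, self.variant_b.key)


# ---------------------------------------------------------------------------
# Single-variant filters
# ---------------------------------------------------------------------------

def prefilter_by_maf(
    annotation: AnnotationRecord, config: FilterConfig, population: str = "all"
) -> tuple[bool, str]:
    """Keep unless MAF is strictly above ``prefilter_maf_max`` (absent = 0)."""
    maf = annotation.frequency(population)
    if maf > config.prefilter_maf_max:
        return False, f"MAF {maf:.3g} > {config.prefilter_maf_max:.3g} in {population}"
    return True, f"MAF {maf:.3g} <= {config.prefilter_maf_max:.3g}"


def filter_by_consequence(variant: Variant) -> tuple[bool, str]:
    """Keep canonical-splice, nonsense, frameshift, in-frame indel, missense
    and initiation-codon variants; drop everything else."""
    if variant.consequence in KEEP_CONSEQUENCES:
        return True, variant.consequence
    return False, f"consequence {variant.consequence} not retained"


# ---------------------------------------------------------------------------
# Inheritance classification
# ---------------------------------------------------------------------------

def classify_inheritance(
    proband: int, father: int, mother: int, proband_sex: str = "male", on_sex_chrom: bool = False
) -> tuple[str, str]:
    """Classify a trio genotype configuration at one biallelic site.

    Returns ``(inheritance, parental_origin)`` where inheritance is one of
    ``de_novo``, ``homozygous``, ``hemizygous``, ``inherited_het``,
    ``none`` (proband carries no alternate allele), ``unresolvable``
    (missing call) or ``inconsistent`` (not explainable by transmission plus
    at most one de novo allele).  Categories are mutually exclusive.
    """
    if MISSING in (proband, father, mother):
        return "unresolvable", "unresolved"
    if proband == HEMI:
        if not (on_sex_chrom and proband_sex == "male"):
            return "inconsistent", "unresolved"
        return "hemizygous", "maternal"
    if father == HEMI or mother == HEMI:
        # parental hemizygous calls occur on sex chromosomes; the diploid
        # transmission model below does not apply there
        return "unresolvable", "unresolved"
    father_can = 1 in transmissible_alleles(father)
    mother_can = 1 in transmissible_alleles(mother)
    consistent = any(
        f + m == proband
        for f in transmissible_alleles(father)
        for m in transmissible_alleles(mother)
    )
    if not consistent:
        if proband == HET and not father_can and not mother_can:
            return "de_novo", "unresolved"
        return "inconsistent", "unresolved"
    if proband == HOM_ALT:
        return "homozygous", "both"
    if proband == HET:
        if father_can and mother_can:
            return "inherited_het", "unresolved"
        if father_can:
            return "inherited_het", "paternal"
        return "inherited_het", "maternal"
    return "none", "unresolved"


# ---------------------------------------------------------------------------
# Compound-het pairing
# ---------------------------------------------------------------------------

def find_compound_het_pairs(
    proband_id: str,
    gene: str,
    candidates: Iterable[CandidateVariant],
    annotations: dict[VariantKey, AnnotationRecord],
    config: FilterConfig,
) -> list[CompoundHetPair]:
    """Form all (paternal het, maternal het) pairs within one gene.

    Variants sharing an origin never pair; hets of unresolved origin cannot
    anchor a pair.  The product frequency uses the configured population with
    absent variants contributing 0.  With three or more qualifying hets all
    cross-origin pairs are formed and flagged as sharing variants.
    """
    paternal = [c for c in candidates if c.inheritance == "inherited_het" and c.parental_origin == "paternal"]
    maternal = [c for c in candidates if c.inheritance == "inherited_het" and c.parental_origin == "maternal"]
    pairs = []
    sharing = len(paternal) > 1 or len(maternal) > 1
    for pa in paternal:
        for ma in maternal:
            if pa.variant.key == ma.variant.key:
                continue
            fa = annotations[pa.variant.key].frequency(config.product_population)
            fb = annotations[ma.variant.key].frequency(config.product_population)
            pairs.append(
                CompoundHetPair(
                    proband_id=proband_id,
                    gene=gene,
                    variant_a=pa.variant,
                    variant_b=ma.variant,
                    product_frequency=fa * fb,
                    shares_variant=sharing and (len(paternal) * len(maternal) > 1),
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# Stratified frequency criteria
# ---------------------------------------------------------------------------

def apply_stratified_criteria(
    candidate: CandidateVariant | CompoundHetPair,
    annotations: dict[VariantKey, AnnotationRecord],
    config: FilterConfig,
) -> tuple[bool, str]:
    """De novo / homozygous / hemizygous candidates must be absent from the
    strict-absence population; a biallelic pair must have frequency product
    strictly below ``comphet_product_max``."""
    if isinstance(candidate, CompoundHetPair):
        if candidate.product_frequency < config.comphet_product_max:
            return True, f"product {candidate.product_frequency:.3g} < {config.comphet_product_max:.3g}"
        return False, f"product {candidate.product_frequency:.3g} >= {config.comphet_product_max:.3g}"
    if candidate.inheritance in ("de_novo", "homozygous", "hemizygous"):
        ac = annotations[candidate.variant.key].allele_count(config.strict_absence_population)
        if ac == 0:
            return True, f"absent in {config.strict_absence_population}"
        return False, f"AC {ac} in {config.strict_absence_population}"
    # plain inherited hets only qualify through pairing
    return False, "inherited het outside a biallelic pair"


def gene_profile_filter(profile: Optional[GeneProfile], config: FilterConfig) -> tuple[bool, str]:
    """Keep iff brain-expressed, no conflicting association, tolerant-metric
    OK and manipulation phenotype present; unknown facets resolved by the
    config policy."""
    if profile is None:
        ok = config.unknown_facet_passes
        return ok, "no profile" + (" (unknown=pass)" if ok else " (unknown=fail)")
    u = config.unknown_facet_passes

    def facet(value: Optional[bool]) -> bool:
        return u if value is None else value

    checks = {
        "brain_expressed": facet(profile.brain_expressed),
        "no_conflicting_association": (
            u if profile.conflicting_association is None else not profile.conflicting_association
        ),
        "intolerance_ok": facet(profile.intolerance_ok),
        "manipulation_phenotype": facet(profile.manipulation_phenotype),
    }
    failed = [k for k, v in checks.items() if not v]
    if failed:
        return False, "failed: " + ",".join(failed)
    return True, "all facets favourable"


# ---------------------------------------------------------------------------
# Cohort-level screening
# ---------------------------------------------------------------------------

@dataclass
class TrioCandidates:
    trio: Trio
    singletons: list[CandidateVariant] = field(default_factory=list)
    pairs: list[CompoundHetPair] = field(default_factory=list)

    def genes(self) -> set[str]:
        return {c.variant.gene for c in self.singletons} | {p.gene for p in self.pairs}


def exclude_known_gene_carriers(
    per_proband: dict[str, TrioCandidates],
    flagged_pathogenic: dict[str, set[VariantKey]],
    annotations: dict[VariantKey, AnnotationRecord],
    config: FilterConfig,
) -> tuple[dict[str, TrioCandidates], list[str]]:
    """Remove probands carrying a flagged pathogenic variant in a known gene.

    ``flagged_pathogenic`` maps proband id to the variant keys flagged
    pathogenic for that sample (an input annotation, e.g. clinical
    assertions); exclusion fires when a flagged key lies in a listed gene.
    """
    if not config.known_gene_list:
        return dict(per_proband), []
    excluded = []
    kept = {}
    for pid, tc in per_proband.items():
        hit = any(
            annotations[k].variant.gene in config.known_gene_list
            for k in flagged_pathogenic.get(pid, set())
            if k in annotations
        )
        if hit:
            excluded.append(pid)
        else:
            kept[pid] = tc
    return kept, sorted(excluded)


@dataclass
class RecurrenceReport:
    gene_carriers: dict[str, list[str]]  # gene -> sorted proband ids
    variant_carriers: dict[VariantKey, list[str]]

    def gene_counts(self) -> list[tuple[str, int]]:
        """Per-gene proband counts, count-descending then gene symbol."""
        return sorted(
            ((g, len(p)) for g, p in self.gene_carriers.items()),
            key=lambda gc: (-gc[1], gc[0]),
        )

    def recurrent_genes(self, min_probands: int = 2) -> list[str]:
        return [g for g, n in self.gene_counts() if n >= min_probands]

    def variant_count(self, key: VariantKey) -> int:
        return len(self.variant_carriers.get(key, []))


def screen_recurrent_genes(per_proband: dict[str, TrioCandidates]) -> RecurrenceReport:
    """Count, per gene and per variant, the unrelated probands carrying
    qualifying genotypes."""
    gene_carriers: dict[str, set[str]] = defaultdict(set)
    variant_carriers: dict[VariantKey, set[str]] = defaultdict(set)
    for pid, tc in per_proband.items():
        for c in tc.singletons:
            gene_carriers[c.variant.gene].add(pid)
            variant_carriers[c.variant.key].add(pid)
        for p in tc.pairs:
            gene_carriers[p.gene].add(pid)
            variant_carriers[p.variant_a.key].add(pid)
            variant_carriers[p.variant_b.key].add(pid)
    return RecurrenceReport(
        gene_carriers={g: sorted(s) for g, s in gene_carriers.items()},
        variant_carriers={k: sorted(s) for k, s in variant_carriers.items()},
    )


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def prioritize_trio(
    trio: Trio,
    cohort: Cohort,
    annotations: dict[VariantKey, AnnotationRecord],
    config: FilterConfig,
) -> TrioCandidates:
    """Run the per-trio cascade: MAF pre-filter, consequence filter,
    inheritance classification, pairing, stratified frequency criteria."""
    from .io import SEX_CHROMOSOMES

    per_gene_hets: dict[str, list[CandidateVariant]] = defaultdict(list)
    singletons: list[CandidateVariant] = []
    for v in cohort.variants:
        ann = annotations.get(v.key)
        if ann is None:
            continue
        variant = ann.variant  # carries gene/consequence; VCF copy may not
        proband, father, mother = cohort.trio_codes(trio, v.key)
        if proband in (HOM_REF, MISSING):
            continue
        keep, _ = prefilter_by_maf(ann, config)
        if not keep:
            continue
        keep, _ = filter_by_consequence(variant)
        if not keep:
            continue
        inheritance, origin = classify_inheritance(
            proband, father, mother, trio.proband_sex, variant.chrom in SEX_CHROMOSOMES
        )
        if inheritance in ("none", "unresolvable", "inconsistent"):
            continue
        cand = CandidateVariant(variant, trio.proband_id, inheritance, origin)
        if inheritance == "inherited_het":
            per_gene_hets[variant.gene].append(cand)
        else:
            ok, reason = apply_stratified_criteria(cand, annotations, config)
            cand.record("stratified", ok, reason)
            if ok:
                singletons.append(cand)

    pairs: list[CompoundHetPair] = []
    for gene, hets in per_gene_hets.items():
        for pair in find_compound_het_pairs(trio.proband_id, gene, hets, annotations, config):
            ok, _ = apply_stratified_criteria(pair, annotations, config)
            if ok:
                pairs.append(pair)
                for member in hets:
                    if member.variant.key in pair.keys:
                        member.inheritance = "compound_het_member"
    return TrioCandidates(trio=trio, singletons=singletons, pairs=pairs)


def prioritize_cohort(
    cohort: Cohort,
    annotations: dict[VariantKey, AnnotationRecord],
    config: Optional[FilterConfig] = None,
    gene_profiles: Optional[dict[str, GeneProfile]] = None,
    flagged_pathogenic: Optional[dict[str, set[VariantKey]]] = None,
) -> tuple[dict[str, TrioCandidates], RecurrenceReport, list[str]]:
    """Run the cascade over every trio and screen for recurrence.

    Returns (per-proband candidates after all filters, recurrence report,
    probands excluded as known-gene carriers).
    """
    config = config or FilterConfig()
    per_proband = {
        t.proband_id: prioritize_trio(t, cohort, annotations, config) for t in cohort.trios
    }
    per_proband, excluded = exclude_known_gene_carriers(
        per_proband, flagged_pathogenic or {}, annotations, config
    )
    if gene_profiles is not None:
        for tc in per_proband.values():
            tc.singletons = [
                c for c in tc.singletons
                if gene_profile_filter(gene_profiles.get(c.variant.gene), config)[0]
            ]
            tc.pairs = [
                p for p in tc.pairs
                if gene_profile_filter(gene_profiles.get(p.gene), config)[0]
            ]
    report = screen_recurrent_genes(per_proband)
    return per_proband, report, excluded
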