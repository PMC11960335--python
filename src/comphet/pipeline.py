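"""End-to-end orchestration: prioritization, control ascertainment, excess
statistics, impact scoring — over either the worked-example fixture or a
synthetic cohort."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .impact import (
    DomainMap,
    HydrophobicityScale,
    ScoreBreakdown,
    StabilityThresholds,
    biallelic_subregional_pattern,
    case_severity_score,
    default_domain_map,
    variant_characteristic_score,
)
from .io import HET, MISSING, Cohort
from .models import AnnotationRecord, VariantKey
from .prioritize import (
    FilterConfig,
    RecurrenceReport,
    TrioCandidates,
    filter_by_consequence,
    prefilter_by_maf,
    prioritize_cohort,
)
from .simulate import SimulationConfig, TruthTable, simulate_control_parent_cohort, simulate_population_frequencies, simulate_trio_cohort
from .stats import (
    AggregateFrequencySummary,
    BurdenSummary,
    ControlAscertainment,
    aggregate_frequency_test,
    ascertain_control_compound_het,
    carrier_burden_test,
)


def control_comphet_ascertainment(
    cohort: Cohort,
    annotations: dict[VariantKey, AnnotationRecord],
    gene: str,
    config: Optional[FilterConfig] = None,
) -> ControlAscertainment:
    """Find control parents carrying a qualifying trans pair in *gene*.

    A parent qualifies when heterozygous at two filter-passing variants of
    the gene whose frequency product satisfies the biallelic rule; the pair
    is then phased by which members the anchoring child inherited.
    """
    config = config or FilterConfig()
    qualifying = [
        k
        for k, rec in annotations.items()
        if rec.variant.gene == gene
        and prefilter_by_maf(rec, config)[0]
        and filter_by_consequence(rec.variant)[0]
    ]
    qualifying.sort()
    parent_pairs = []
    child_carrier: dict[tuple[str, VariantKey], Optional[bool]] = {}
    for trio in cohort.trios:
        for parent_id in (trio.father_id, trio.mother_id):
            hets = [k for k in qualifying if cohort.genotype_code(parent_id, k) == HET]
            for i in range(len(hets)):
                for j in range(i + 1, len(hets)):
                    ka, kb = hets[i], hets[j]
                    product = annotations[ka].frequency(config.product_population) * annotations[
                        kb
                    ].frequency(config.product_population)
                    if product >= config.comphet_product_max:
                        continue
                    parent_pairs.append((parent_id, ka, kb))
                    for k in (ka, kb):
                        code = cohort.genotype_code(trio.proband_id, k)
                        child_carrier[(parent_id, k)] = None if code == MISSING else code >= HET
    return ascertain_control_compound_het(parent_pairs, child_carrier)


@dataclass
class ImpactReport:
    breakdowns: dict[str, list[ScoreBreakdown]]  # case id -> pair member scores
    pattern: dict[str, bool]  # case id -> subregional pattern flag

    def case_totals(self) -> dict[str, int]:
        return {cid: sum(b.total for b in bs) for cid, bs in self.breakdowns.items()}

    def ranking(self):
        return case_severity_score(self.breakdowns)


def score_case_pairs(
    per_proband: dict[str, TrioCandidates],
    annotations: dict[VariantKey, AnnotationRecord],
    domain_map: Optional[DomainMap] = None,
    scale: Optional[HydrophobicityScale] = None,
    thresholds: Optional[StabilityThresholds] = None,
) -> ImpactReport:
    """Impact-score every proband's compound-het pair members."""
    domain_map = domain_map or default_domain_map()
    breakdowns: dict[str, list[ScoreBreakdown]] = {}
    pattern: dict[str, bool] = {}
    for pid, tc in per_proband.items():
        if not tc.pairs:
            continue
        pair = tc.pairs[0]
        breakdowns[pid] = [
            variant_characteristic_score(annotations[k], domain_map, scale, thresholds)
            for k in pair.keys
        ]
        pattern[pid] = biallelic_subregional_pattern(
            pair.variant_a, pair.variant_b, domain_map, annotations
        )
    return ImpactReport(breakdowns, pattern)


@dataclass
class SyntheticStudyResult:
    per_proband: dict[str, TrioCandidates]
    recurrence: RecurrenceReport
    excluded_probands: list[str]
    ascertainment: ControlAscertainment
    burden: BurdenSummary
    case_truth: TruthTable
    control_truth: TruthTable
    target_gene: str

    @property
    def case_carriers(self) -> list[str]:
        return sorted(
            pid
            for pid, tc in self.per_proband.items()
            if any(p.gene == self.target_gene for p in tc.pairs)
        )

    @property
    def sensitivity(self) -> float:
        planted = set(self.case_truth.carriers("case_trans"))
        if not planted:
            return 1.0
        return len(planted & set(self.case_carriers)) / len(planted)

    @property
    def false_recurrent_genes(self) -> list[str]:
        return [g for g in self.recurrence.recurrent_genes() if g != self.target_gene]


def run_synthetic_study(
    sim_config: Optional[SimulationConfig] = None,
    filter_config: Optional[FilterConfig] = None,
) -> SyntheticStudyResult:
    """Simulate cohorts, run the full cascade on the case trios, ascertain
    control compound hets by transmission, and compute the carrier burden."""
    sim_config = sim_config or SimulationConfig()
    filter_config = filter_config or FilterConfig(
        known_gene_list=frozenset({sim_config.known_gene})
        if sim_config.planted_known_gene_carriers
        else frozenset()
    )
    annotations = simulate_population_frequencies(sim_config)
    case_cohort, case_truth = simulate_trio_cohort(sim_config, annotations)
    control_cohort, control_truth = simulate_control_parent_cohort(sim_config, annotations)

    per_proband, recurrence, excluded = prioritize_cohort(
        case_cohort,
        annotations,
        filter_config,
        flagged_pathogenic=case_truth.flagged_pathogenic(),
    )
    ascertainment = control_comphet_ascertainment(
        control_cohort, annotations, sim_config.target_gene, filter_config
    )
    case_carriers = sorted(
        pid
        for pid, tc in per_proband.items()
        if any(p.gene == sim_config.target_gene for p in tc.pairs)
    )
    n_cases = sim_config.n_case_trios - len(excluded)
    burden = carrier_burden_test(
        len(case_carriers),
        n_cases,
        len(ascertainment.trans_parent_ids),
        sim_config.n_control_parents,
    )
    return SyntheticStudyResult(
        per_proband=per_proband,
        recurrence=recurrence,
        excluded_probands=excluded,
        ascertainment=ascertainment,
        burden=burden,
        case_truth=case_truth,
        control_truth=control_truth,
        target_gene=sim_config.target_gene,
    )


@dataclass
class WorkedExampleResult:
    per_proband: dict[str, TrioCandidates]
    recurrence: RecurrenceReport
    aggregate: AggregateFrequencySummary
    burden: BurdenSummary
    impact: ImpactReport
    annotations: dict[VariantKey, AnnotationRecord] = field(repr=False, default_factory=dict)


def run_worked_example(filter_config: Optional[FilterConfig] = None) -> WorkedExampleResult:
    """Run prioritization, excess statistics and impact scoring on the
    five-trio worked-example fixture."""
    from . import study

    annotations = study.study_annotations()
    cohort = study.study_cohort()
    config = filter_config or FilterConfig()
    per_proband, recurrence, _ = prioritize_cohort(cohort, annotations, config)
    case_ac, case_an = study.case_allele_counts()
    aggregate = aggregate_frequency_test(
        case_ac,
        case_an,
        annotations.values(),
        reference_allele_number=study.PRINTED_REFERENCE_AN,
    )
    burden = carrier_burden_test(
        study.CASE_COMPHET_PROBANDS,
        study.N_CASE_PROBANDS,
        study.CONTROL_COMPHET_PARENTS,
        study.N_CONTROL_PARENTS,
    )
    impact = score_case_pairs(per_proband, annotations)
    return WorkedExampleResult(per_proband, recurrence, aggregate, burden, impact, annotations)
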