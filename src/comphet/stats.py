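"""Excess-of-variants statistics.

Two-sided Fisher's exact test (minimum-likelihood definition, computed in
log-space so gnomAD-scale margins are exact to float precision), Woolf
(log-normal) confidence intervals for the odds ratio with Haldane–Anscombe
correction on zero cells, aggregate allele-frequency comparisons against
reference populations, transmission-based ascertainment of compound
heterozygotes in a parent cohort, and the carrier-level burden test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

from .models import POPULATIONS, AnnotationRecord, VariantKey

#: relative tolerance when comparing point probabilities for the
#: minimum-likelihood two-sided p-value (guards float ties)
_REL_TIE_EPS = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: a = case variant alleles (or carriers), b = case
    non-variant, c = reference variant, d = reference non-variant."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell in contingency table")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("contingency table has an empty row")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass
class ContingencyResult:
    table: ContingencyTable
    p_value: float
    odds_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    alpha: float = 0.05
    corrected: bool = False  # Haldane–Anscombe 0.5 applied


def _log_hypergeom_pmf(ks: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeom(N population, K successes, n draws)."""
    ks = np.asarray(ks)
    return (
        gammaln(K + 1) - gammaln(ks + 1) - gammaln(K - ks + 1)
        + gammaln(N - K + 1) - gammaln(n - ks + 1) - gammaln(N - K - n + ks + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def fisher_exact_two_tailed(table: ContingencyTable | tuple[int, int, int, int]) -> float:
    """Two-sided Fisher's exact p (minimum-likelihood definition).

    Conditioning on the margins, sums the hypergeometric point probabilities
    of every table no more likely than the observed one.  Degenerate margins
    (a zero row or column) give p = 1.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(*table)
    a, b, c, d = table.cells
    N = a + b + c + d
    K = a + b  # row-1 margin
    n = a + c  # column-1 margin
    k_min, k_max = max(0, n - (N - K)), min(K, n)
    if k_min == k_max:
        return 1.0
    ks = np.arange(k_min, k_max + 1)
    logpmf = _log_hypergeom_pmf(ks, N, K, n)
    log_obs = logpmf[a - k_min]
    mask = logpmf <= log_obs + math.log1p(_REL_TIE_EPS)
    p = float(np.exp(logsumexp(logpmf[mask])))
    return min(1.0, max(0.0, p))


def odds_ratio_woolf(
    table: ContingencyTable | tuple[int, int, int, int], alpha: float = 0.05
) -> tuple[Optional[float], Optional[float], Optional[float], bool]:
    """Odds ratio with Woolf (log-normal) CI.

    OR = (a*d)/(b*c); CI = exp(ln OR ± z_{1-alpha/2} * sqrt(1/a+1/b+1/c+1/d)).
    Any zero cell triggers the Haldane–Anscombe 0.5 correction (flagged);
    two zero cells on a diagonal leave the OR undefined (None).
    Returns (odds_ratio, ci_low, ci_high, corrected).
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(*table)
    a, b, c, d = (float(x) for x in table.cells)
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        return None, None, None, False
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(norm.ppf(1 - alpha / 2))
    return orr, orr * math.exp(-z * se), orr * math.exp(z * se), corrected


def contingency_test(
    table: ContingencyTable | tuple[int, int, int, int], alpha: float = 0.05
) -> ContingencyResult:
    """Fisher p plus Woolf OR/CI in one result."""
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(*table)
    p = fisher_exact_two_tailed(table)
    orr, lo, hi, corrected = odds_ratio_woolf(table, alpha)
    return ContingencyResult(table, p, orr, lo, hi, alpha, corrected)


# ---------------------------------------------------------------------------
# Aggregate allele-frequency comparison
# ---------------------------------------------------------------------------

@dataclass
class AggregateFrequencySummary:
    case_allele_count: int
    case_allele_number: int
    per_population: dict[str, ContingencyResult]
    reference_counts: dict[str, tuple[int, int]]  # population -> (AC, AN)


def aggregate_frequency_test(
    case_allele_count: int,
    case_allele_number: int,
    annotations: Iterable[AnnotationRecord],
    populations: Sequence[str] = POPULATIONS,
    reference_allele_number: Optional[dict[str, int]] = None,
    alpha: float = 0.05,
) -> AggregateFrequencySummary:
    """Compare the case cohort's aggregate allele count for an identified
    variant set against each reference population.

    The reference numerator per population is the sum of per-variant allele
    counts.  Because per-variant allele numbers differ within a population,
    the single denominator is, by default, the minimum per-variant allele
    number of that population (conservative: the largest aggregate frequency
    the data support); pass ``reference_allele_number`` to override with
    externally fixed totals.
    """
    annotations = list(annotations)
    if not annotations:
        raise ValueError("empty variant set")
    per_population = {}
    reference_counts = {}
    for pop in populations:
        ref_ac = sum(rec.allele_count(pop) for rec in annotations)
        if reference_allele_number and pop in reference_allele_number:
            ref_an = reference_allele_number[pop]
        else:
            # only variants observed in the population contribute an AN;
            # absent variants carry a default AN which must not drive the min
            observed = [
                rec.frequencies[pop].allele_number
                for rec in annotations
                if rec.allele_count(pop) > 0
            ]
            ref_an = min(observed) if observed else max(
                rec.frequencies[pop].allele_number for rec in annotations
            )
        table = ContingencyTable(
            case_allele_count,
            case_allele_number - case_allele_count,
            ref_ac,
            ref_an - ref_ac,
        )
        per_population[pop] = contingency_test(table, alpha)
        reference_counts[pop] = (ref_ac, ref_an)
    return AggregateFrequencySummary(
        case_allele_count, case_allele_number, per_population, reference_counts
    )


# ---------------------------------------------------------------------------
# Transmission phasing in the control parent cohort
# ---------------------------------------------------------------------------

def phase_by_transmission(
    child_carries_a: Optional[bool], child_carries_b: Optional[bool]
) -> str:
    """Phase a double-het parent's variant pair from one child's genotypes.

    Absent intragenic recombination the child inherits exactly one parental
    haplotype, so: exactly one of the pair in the child => the variants lie
    on opposite haplotypes (*trans*); both or neither => same haplotype
    (*cis*); a missing child genotype at either site => *unresolved*.
    Assumes the other parent carries neither variant (rare-variant regime).
    """
    if child_carries_a is None or child_carries_b is None:
        return "unresolved"
    return "trans" if child_carries_a != child_carries_b else "cis"


@dataclass
class ControlAscertainment:
    trans_carriers: list[tuple[str, VariantKey, VariantKey]]
    cis_carriers: list[tuple[str, VariantKey, VariantKey]]
    unresolved: list[tuple[str, VariantKey, VariantKey]]

    @property
    def trans_parent_ids(self) -> list[str]:
        return sorted({p for p, _, _ in self.trans_carriers})


def ascertain_control_compound_het(
    parent_pairs: Iterable[tuple[str, VariantKey, VariantKey]],
    child_carrier: dict[tuple[str, VariantKey], Optional[bool]],
) -> ControlAscertainment:
    """Classify each double-het parent's candidate pair by transmission.

    ``parent_pairs`` yields (parent_id, variant_a, variant_b) for parents
    heterozygous at both sites of a qualifying same-gene pair;
    ``child_carrier[(parent_id, key)]`` states whether that parent's child
    carries the variant (None = missing call).  Only trans pairs count as
    compound-het carriers; unresolved pairs are reported separately.
    """
    trans, cis, unresolved = [], [], []
    for parent_id, ka, kb in parent_pairs:
        phase = phase_by_transmission(
            child_carrier.get((parent_id, ka)), child_carrier.get((parent_id, kb))
        )
        {"trans": trans, "cis": cis, "unresolved": unresolved}[phase].append(
            (parent_id, ka, kb)
        )
    return ControlAscertainment(trans, cis, unresolved)


# ---------------------------------------------------------------------------
# Carrier-level burden
# ---------------------------------------------------------------------------

@dataclass
class BurdenSummary:
    case_carriers: int
    n_cases: int
    control_carriers: int
    n_controls: int
    result: ContingencyResult = field(init=False)

    def __post_init__(self) -> None:
        if self.case_carriers > self.n_cases or self.control_carriers > self.n_controls:
            raise ValueError("carriers exceed cohort size")
        self.result = contingency_test(
            ContingencyTable(
                self.case_carriers,
                self.n_cases - self.case_carriers,
                self.control_carriers,
                self.n_controls - self.control_carriers,
            )
        )


def carrier_burden_test(
    case_carriers: int, n_cases: int, control_carriers: int, n_controls: int
) -> BurdenSummary:
    """Compare compound-het carrier frequency between cases and controls."""
    return BurdenSummary(case_carriers, n_cases, control_carriers, n_controls)
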