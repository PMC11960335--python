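"""Synthetic trio cohorts with planted compound-heterozygous signal.

Emulates the statistical structure the downstream analysis assumes: a case
cohort of affected trios (default 291 probands), an asymptomatic control
cohort of parents anchored by one child per family (default 1942 parents =
971 families), gnomAD-style population frequency tables over four reference
populations, per-variant annotations, and age-indexed expression series with
three developmental peaks.

All randomness flows from a single seed through named substreams, so adding
a generator does not perturb the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

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

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    Cohort sizes default to the study design: 291 affected probands with
    both parents, and 1942 asymptomatic control parents (971 child-anchored
    families); 5 case probands and 9 control parents carry a trans pair in
    the target gene.
    """

    n_case_trios: int = 291
    n_control_parents: int = 1942
    n_background_genes: int = 30
    variants_per_gene: int = 8
    target_gene: str = "MDN1"
    n_target_variants: int = 12
    planted_comphet_cases: int = 5
    planted_comphet_control_parents: int = 9
    planted_cis_control_parents: int = 3
    planted_known_gene_carriers: int = 0
    known_gene: str = "SCN1A"
    #: log10 MAF range for background variants (upper end exercises the
    #: 5e-3 pre-filter) and for the deliberately rare target-gene variants
    maf_log10_range: tuple[float, float] = (-4.5, -2.2)
    target_maf_log10_range: tuple[float, float] = (-5.5, -4.2)
    #: reference allele numbers, of the order of a large exome aggregate
    population_sizes: dict[str, int] = field(
        default_factory=lambda: {"all": 250000, "control": 109000, "eas_all": 19000, "eas_control": 9000}
    )
    #: East-Asian slices drawn with enriched frequencies (log-mean shift)
    eas_log_enrichment: float = 0.7
    population_sigma: float = 0.3
    consequence_mix: dict[str, float] = field(
        default_factory=lambda: {
            "missense": 0.60,
            "other": 0.25,
            "nonsense": 0.05,
            "frameshift": 0.05,
            "canonical_splice": 0.05,
        }
    )
    mendelian_error_rate: float = 0.0
    recombination_rate: float = 0.0  # reserved; intragenic recombination off
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control_parents % 2:
            raise ValueError("n_control_parents must be even (two parents per family)")
        if self.planted_comphet_cases > self.n_case_trios:
            raise ValueError("planted case carriers exceed cohort size")
        planted_parents = self.planted_comphet_control_parents + self.planted_cis_control_parents
        if planted_parents > self.n_control_parents:
            raise ValueError("planted control carriers exceed cohort size")
        if self.planted_known_gene_carriers > self.n_case_trios:
            raise ValueError("planted known-gene carriers exceed cohort size")
        for pop, size in self.population_sizes.items():
            if size <= 0:
                raise ValueError(f"population size for {pop} must be positive")
        total = sum(self.consequence_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"consequence_mix must sum to 1, got {total}")
        if any(p < 0 or p > 1 for p in self.consequence_mix.values()):
            raise ValueError("consequence_mix probabilities must lie in [0, 1]")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named random substream: one independent generator per purpose."""
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(name.encode())]))


@dataclass
class PlantedSignal:
    carrier_id: str
    kind: str  # {case_trans, control_trans, control_cis, known_gene}
    gene: str
    key_a: Optional[VariantKey] = None
    key_b: Optional[VariantKey] = None
    phase: str = ""  # {trans, cis}
    inheritance: str = ""  # e.g. "paternal+maternal" for a case pair


@dataclass
class TruthTable:
    planted: list[PlantedSignal] = field(default_factory=list)

    def carriers(self, kind: str) -> list[str]:
        return sorted({p.carrier_id for p in self.planted if p.kind == kind})

    def flagged_pathogenic(self) -> dict[str, set[VariantKey]]:
        out: dict[str, set[VariantKey]] = {}
        for p in self.planted:
            if p.kind == "known_gene" and p.key_a is not None:
                out.setdefault(p.carrier_id, set()).add(p.key_a)
        return out


# ---------------------------------------------------------------------------
# Variant universe + population frequencies
# ---------------------------------------------------------------------------

def simulate_population_frequencies(config: SimulationConfig) -> dict[VariantKey, AnnotationRecord]:
    """Draw a variant universe with coherent per-population counts.

    Each variant has a shared base frequency (log-uniform over the configured
    MAF spectrum) and per-population multipliers (log-normal, with an
    East-Asian enrichment shift), so subpopulation counts are correlated but
    drawn independently per population — reference subsets overlap, so no
    nesting constraint is imposed across populations.  Allele counts are
    binomial in the population's allele number.
    """
    rng = substream(config.seed, "population_frequencies")
    genes: list[tuple[str, str, int]] = [(config.target_gene, "6", config.n_target_variants)]
    if config.planted_known_gene_carriers or config.known_gene:
        genes.append((config.known_gene, "2", 2))
    for g in range(config.n_background_genes):
        genes.append((f"GENE{g + 1:03d}", str(g % 22 + 1), config.variants_per_gene))

    consequences = list(config.consequence_mix)
    probs = np.array([config.consequence_mix[c] for c in consequences])
    annotations: dict[VariantKey, AnnotationRecord] = {}
    for gi, (gene, chrom, n_var) in enumerate(genes):
        base_pos = 1_000_000 * (gi + 1)
        for vi in range(n_var):
            if gene == config.target_gene:
                lo, hi = config.target_maf_log10_range
                # alternate between the AAA2-AAA3 stretch and the linker so
                # planted pairs exercise the subregional pattern
                protein_pos = int(rng.integers(700, 1300)) if vi % 2 == 0 else int(rng.integers(2400, 4700))
                consequence = "missense"
            else:
                lo, hi = config.maf_log10_range
                consequence = str(rng.choice(consequences, p=probs))
                protein_pos = int(rng.integers(1, 2000)) if consequence in ("missense", "inframe_indel") else None
            base_f = 10.0 ** rng.uniform(lo, hi)
            ref, alt = (str(b) for b in rng.choice(list("ACGT"), size=2, replace=False))
            ref_aa, alt_aa = (str(a) for a in rng.choice(list(AMINO_ACIDS), size=2, replace=False))
            variant = Variant(
                chrom=chrom,
                pos=base_pos + vi * 997,
                ref=ref,
                alt=alt,
                gene=gene,
                transcript=f"NM_{gi:06d}",
                protein_pos=protein_pos if consequence in ("missense", "inframe_indel") else None,
                ref_aa=ref_aa if consequence == "missense" else None,
                alt_aa=alt_aa if consequence == "missense" else None,
                consequence=consequence,
            )
            frequencies = {}
            for pop in POPULATIONS:
                shift = config.eas_log_enrichment if pop.startswith("eas") else 0.0
                mult = float(np.exp(rng.normal(shift, config.population_sigma)))
                f_pop = min(0.05, base_f * mult)
                an = config.population_sizes[pop]
                ac = int(rng.binomial(an, f_pop))
                hom = min(int(rng.binomial(an // 2, f_pop * f_pop)), ac // 2)
                frequencies[pop] = PopulationFrequency(variant.key, pop, ac, an, hom)
            annotations[variant.key] = AnnotationRecord(
                variant=variant,
                insilico_verdicts={"CADD": "damaging"} if consequence == "missense" else {},
                hbond_changes=int(rng.integers(0, 3)) if consequence == "missense" else None,
                frequencies=frequencies,
            )
    return annotations


def _generating_frequency(record: AnnotationRecord) -> float:
    return record.frequency("all")


def _draw_background(
    rng: np.random.Generator, n_individuals: int, freqs: np.ndarray
) -> np.ndarray:
    """Hardy–Weinberg diploid genotypes, individuals x variants."""
    return rng.binomial(2, freqs[None, :], size=(n_individuals, len(freqs))).astype(np.int8)


def _transmit(rng: np.random.Generator, parent: np.ndarray) -> np.ndarray:
    """One transmitted allele per (individual, variant): Bernoulli(g/2)."""
    return (rng.random(parent.shape) < parent / 2.0).astype(np.int8)


def _select_planted_pair(
    config: SimulationConfig,
    annotations: dict[VariantKey, AnnotationRecord],
    index: int,
) -> tuple[VariantKey, VariantKey]:
    """Pick the index-th planted (AAA-side, linker-side) target-gene pair,
    enforcing the frequency-product rule the plant must satisfy."""
    target = [
        rec for rec in annotations.values() if rec.variant.gene == config.target_gene
    ]
    target.sort(key=lambda r: r.variant.pos)
    side_a = [r for r in target if r.variant.protein_pos and r.variant.protein_pos <= 1310]
    side_b = [r for r in target if r.variant.protein_pos and r.variant.protein_pos > 1310]
    if not side_a or not side_b:
        raise ValueError("target gene lacks variants on both subregional sides")
    ra = side_a[index % len(side_a)]
    rb = side_b[(index // len(side_a)) % len(side_b)]
    product = _generating_frequency(ra) * _generating_frequency(rb)
    if product >= 1e-6:
        raise ValueError(
            f"infeasible plant: frequency product {product:.3g} violates the 1e-6 rule"
        )
    return ra.variant.key, rb.variant.key


# ---------------------------------------------------------------------------
# Case trios
# ---------------------------------------------------------------------------

def simulate_trio_cohort(
    config: SimulationConfig, annotations: dict[VariantKey, AnnotationRecord]
) -> tuple[Cohort, TruthTable]:
    """Simulate the affected-trio cohort with planted trans pairs.

    All trios are Mendelian-consistent unless ``mendelian_error_rate > 0``;
    exactly ``planted_comphet_cases`` probands carry a compound-het pair in
    the target gene, one allele inherited from each asymptomatic parent.
    """
    rng = substream(config.seed, "trio_cohort")
    variants = [annotations[k].variant for k in sorted(annotations)]
    keys = [v.key for v in variants]
    col = {k: j for j, k in enumerate(keys)}
    freqs = np.array([_generating_frequency(annotations[k]) for k in keys])

    n = config.n_case_trios
    fathers = _draw_background(rng, n, freqs)
    mothers = _draw_background(rng, n, freqs)
    children = _transmit(rng, fathers) + _transmit(rng, mothers)

    truth = TruthTable()
    for i in range(config.planted_comphet_cases):
        ka, kb = _select_planted_pair(config, annotations, i)
        ja, jb = col[ka], col[kb]
        fathers[i, ja], fathers[i, jb] = HET, HOM_REF
        mothers[i, ja], mothers[i, jb] = HOM_REF, HET
        children[i, ja], children[i, jb] = HET, HET
        truth.planted.append(
            PlantedSignal(
                carrier_id=f"case{i:03d}",
                kind="case_trans",
                gene=config.target_gene,
                key_a=ka,
                key_b=kb,
                phase="trans",
                inheritance="paternal+maternal",
            )
        )

    if config.planted_known_gene_carriers:
        kg_keys = sorted(
            k for k, rec in annotations.items() if rec.variant.gene == config.known_gene
        )
        if not kg_keys:
            raise ValueError("no known-gene variant to plant")
        start = config.planted_comphet_cases
        for i in range(start, start + config.planted_known_gene_carriers):
            jk = col[kg_keys[0]]
            children[i, jk] = HET
            fathers[i, jk] = HET
            truth.planted.append(
                PlantedSignal(
                    carrier_id=f"case{i:03d}",
                    kind="known_gene",
                    gene=config.known_gene,
                    key_a=kg_keys[0],
                )
            )

    if config.mendelian_error_rate > 0:
        flip = rng.random(children.shape) < config.mendelian_error_rate
        children = np.where(flip, rng.integers(0, 3, size=children.shape, dtype=np.int8), children)

    trios, samples, sexes, rows = [], [], {}, []
    for i in range(n):
        pid, fid, mid = f"case{i:03d}", f"case{i:03d}_fa", f"case{i:03d}_mo"
        sex = "male" if rng.random() < 0.5 else "female"
        trios.append(Trio(pid, fid, mid, proband_sex=sex, affected=True))
        for sid, g, s in ((pid, children[i], sex), (fid, fathers[i], "male"), (mid, mothers[i], "female")):
            samples.append(sid)
            sexes[sid] = s
            rows.append(g)
    cohort = Cohort(
        trios=trios,
        samples=samples,
        variants=variants,
        genotypes=np.stack(rows),
        sample_sex=sexes,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Control parent cohort
# ---------------------------------------------------------------------------

def simulate_control_parent_cohort(
    config: SimulationConfig, annotations: dict[VariantKey, AnnotationRecord]
) -> tuple[Cohort, TruthTable]:
    """Simulate child-anchored control families (parents asymptomatic).

    ``planted_comphet_control_parents`` parents carry a trans pair in the
    target gene (their child inherits exactly one of the pair); additionally
    ``planted_cis_control_parents`` parents carry cis pairs (child inherits
    both or neither) to exercise the phase-discrimination logic.
    """
    rng = substream(config.seed, "control_cohort")
    variants = [annotations[k].variant for k in sorted(annotations)]
    keys = [v.key for v in variants]
    col = {k: j for j, k in enumerate(keys)}
    freqs = np.array([_generating_frequency(annotations[k]) for k in keys])

    n_fam = config.n_control_parents // 2
    fathers = _draw_background(rng, n_fam, freqs)
    mothers = _draw_background(rng, n_fam, freqs)
    children = _transmit(rng, fathers) + _transmit(rng, mothers)

    truth = TruthTable()

    def plant(i: int, use_father: bool, phase: str, pair_index: int) -> None:
        ka, kb = _select_planted_pair(config, annotations, pair_index)
        ja, jb = col[ka], col[kb]
        parent = fathers if use_father else mothers
        other = mothers if use_father else fathers
        parent[i, ja], parent[i, jb] = HET, HET
        other[i, ja], other[i, jb] = HOM_REF, HOM_REF
        if phase == "trans":
            # child inherits exactly one haplotype: one of the pair
            if i % 2 == 0:
                children[i, ja], children[i, jb] = HET, HOM_REF
            else:
                children[i, ja], children[i, jb] = HOM_REF, HET
        else:  # cis: both variants co-reside, child gets both or neither
            g = HET if i % 2 == 0 else HOM_REF
            children[i, ja], children[i, jb] = g, g
        parent_id = f"ctrl{i:03d}_{'fa' if use_father else 'mo'}"
        truth.planted.append(
            PlantedSignal(
                carrier_id=parent_id,
                kind="control_trans" if phase == "trans" else "control_cis",
                gene=config.target_gene,
                key_a=ka,
                key_b=kb,
                phase=phase,
            )
        )

    n_trans = config.planted_comphet_control_parents
    n_cis = config.planted_cis_control_parents
    if n_trans + n_cis > n_fam:
        raise ValueError("more planted parents than families")
    for i in range(n_trans):
        plant(i, use_father=(i % 2 == 0), phase="trans", pair_index=i)
    for j in range(n_cis):
        i = n_trans + j
        plant(i, use_father=(i % 2 == 0), phase="cis", pair_index=j)

    trios, samples, sexes, rows = [], [], {}, []
    for i in range(n_fam):
        cid, fid, mid = f"ctrl{i:03d}_ch", f"ctrl{i:03d}_fa", f"ctrl{i:03d}_mo"
        sex = "male" if rng.random() < 0.5 else "female"
        trios.append(Trio(cid, fid, mid, proband_sex=sex, affected=False))
        for sid, g, s in ((cid, children[i], sex), (fid, fathers[i], "male"), (mid, mothers[i], "female")):
            samples.append(sid)
            sexes[sid] = s
            rows.append(g)
    cohort = Cohort(
        trios=trios,
        samples=samples,
        variants=variants,
        genotypes=np.stack(rows),
        sample_sex=sexes,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Expression series
# ---------------------------------------------------------------------------

#: log10 post-conception-day positions and heights of the three
#: developmental expression peaks the template encodes: fetal (~100 days),
#: infancy (~2 years post conception) and adulthood (~30 years).
EXPRESSION_PEAKS_LOG10_DAYS = (2.0, 2.9, 4.05)
_PEAK_HEIGHTS = (3.5, 2.8, 3.5)
_PEAK_WIDTHS = (0.22, 0.25, 0.30)
_BASELINE_RPKM = 5.0


def expression_template(log10_age_days: np.ndarray) -> np.ndarray:
    """Smooth three-peak developmental expression template (RPKM)."""
    t = np.asarray(log10_age_days, dtype=float)
    out = np.full_like(t, _BASELINE_RPKM)
    for mu, h, w in zip(EXPRESSION_PEAKS_LOG10_DAYS, _PEAK_HEIGHTS, _PEAK_WIDTHS):
        out = out + h * np.exp(-(((t - mu) / w) ** 2))
    return out


def simulate_expression_series(
    config: SimulationConfig,
    regions: tuple[str, ...] = ("cortex", "hippocampus", "cerebellum"),
    n_points: int = 48,
    noise_scale: float = 0.05,
    log10_age_range: tuple[float, float] = (1.7, 4.35),
):
    """Age-indexed RPKM series per brain region: the three-peak template
    plus additive Gaussian noise of ``noise_scale`` x template amplitude.

    Ages form a fixed developmental stage grid (uniform on the log axis),
    as in stage-structured expression resources, shared across regions.
    """
    from .expression import ExpressionSeries

    rng = substream(config.seed, "expression")
    lo, hi = log10_age_range
    series = []
    for region in regions:
        ages = np.linspace(lo, hi, n_points)
        template = expression_template(ages)
        amplitude = float(template.max() - template.min())
        noise = rng.normal(0.0, noise_scale * amplitude, n_points) if noise_scale > 0 else 0.0
        rpkm = np.clip(template + noise, 0.0, None)
        series.append(ExpressionSeries(region, ages, rpkm))
    return series
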