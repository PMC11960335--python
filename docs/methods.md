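# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the choices made where the design was genuinely open.

## Filtering cascade

The prioritization model is a case-by-case recessive-oriented trio cascade.
Boundary semantics are strict everywhere: a variant is removed when its
reference minor allele frequency is *more than* `prefilter_maf_max`
(default 5×10⁻³, evaluated on the full reference population, absent = 0),
and a biallelic pair survives when its frequency product is *below*
`comphet_product_max` (default 10⁻⁶ — well under the expected occurrence of
a single individual in a reference cohort of ~1.4×10⁵ people, 1/141456 ≈
7×10⁻⁶). Six consequence classes are retained (canonical splice, nonsense,
frameshift, in-frame indel, missense, initiation codon); everything else,
including synonymous and deep-intronic calls, is dropped.

Inheritance classification operates on diploid genotype codes and is
verified exhaustively against transmission enumeration over all 27 trio
combinations. Two related but distinct notions are kept apart on purpose:

* the *reader's* Mendelian-inconsistency flag marks any configuration
  unreachable by pure transmission (including the single-event de novo
  configuration het child of two hom-ref parents), because at read time the
  flag is a data-quality signal;
* the *classifier* interprets exactly that single-allele-gain configuration
  as `de_novo`, and excludes every other non-transmissible configuration
  from all categories.

A compound-het pair requires one unambiguously paternal and one
unambiguously maternal inherited het in the same gene; hets whose origin
cannot be resolved (both parents carriers, or a missing parental genotype)
never anchor a pair — conservative, since phase cannot be established. With
three or more qualifying hets all cross-origin pairs are formed and flagged
as sharing variants. Stratified criteria: de novo / homozygous / hemizygous
candidates must have allele count zero in the strict-absence population
(default the control subset — both the absence population and the
product-rule population, default the full reference, are configurable,
because published workflows are typically ambiguous about which subset each
rule used). Recurrence is screened at both gene level (number of unrelated
probands with qualifying genotypes; ≥ 2 flags a gene recurrent, and gene
recurrence drives candidate nomination) and variant level (to surface a
variant shared by two cases).

## Excess statistics

The two-sided Fisher test uses the minimum-likelihood definition:
conditioning on both margins, p is the sum of hypergeometric point
probabilities not exceeding that of the observed table (relative tie
tolerance 10⁻⁷). Point probabilities are computed in log space via
`gammaln`, so reference-scale margins (hundreds of thousands of alleles)
are exact to float precision; an exact-integer enumeration oracle checks
every table with N ≤ 60 in the test suite. Degenerate margins give p = 1.

The odds-ratio interval is Woolf's log-normal approximation without
continuity correction, OR = ad/bc and
CI = exp(ln OR ± z₁₋α/₂·√(1/a+1/b+1/c+1/d)); this exactly reproduces all
six published intervals the worked example validates against. With any
zero cell the Haldane–Anscombe 0.5 is added to all four cells and the
result flagged `corrected`; with two zero cells on a diagonal the OR is
reported as undefined while p is still computed.

Aggregate-frequency comparison: the case numerator is the summed allele
count of the identified variant set over 2×(probands) case chromosomes; the
reference numerator is the per-variant column sum. Because per-variant
allele numbers differ within a population, a single reference denominator
must be chosen: the default is the *minimum* allele number among variants
observed in that population (conservative — it maximizes the reference
frequency), with an explicit override for externally fixed totals, which
the worked example uses since its published totals follow the min-AN
convention in three populations out of four. No multiple-testing correction
is applied across the four population comparisons (raw p-values are
reported, matching the source workflow); reports note this.

Control compound hets are ascertained by transmission phasing: absent
intragenic recombination a child inherits exactly one parental haplotype,
so a double-het parent whose child carries exactly one of the pair is a
trans carrier; both-or-neither means cis; a missing child genotype leaves
the pair unresolved, excluded from the numerator and reported separately.
The burden test then compares carrier counts (case probands vs control
parents) in a 2×2 exact test.

## Protein impact

The domain map is an ordered list of non-overlapping 1-based inclusive
residue intervals over the 5696-residue protein; uncovered residues are
`inter-domain`, and positions within `vicinity_window` (default 100)
residues of the linker carry a vicinity mark. The shipped default map is a
synthetic configuration consistent with the protein's architecture (AAA1–6
ring through residue ~2300, long linker to ~4770, C-terminal MIDAS); no
published per-residue annotation is bundled, so boundary-dependent outputs
always state the map used. The biallelic subregional pattern is true iff
one pair member lies in AAA2/AAA3 and the other in the linker or its
vicinity, order-independently; a splice variant localizes through the
annotated residue of the exon boundary it abuts (an input column).

Hydrophobicity uses the Fauchère–Pliska octanol–water scale. The default
alteration criterion is a magnitude threshold |Δ| ≥ 1.0 scale units rather
than a category change: a pure category rule cannot reproduce the study
classification (Thr→Met crosses the standard category boundary yet is a
published negative), whereas the 1.0-unit threshold classifies all eight
missense variants as published (three positives: Ser→Leu Δ=+1.74, His→Arg
Δ=−1.14, Arg→His Δ=+1.14; largest negative: Thr→Met Δ=+0.97). Category
mode remains available. Stability classes use strict ±0.5 kcal/mol ΔΔG
bounds.

The characteristic score grants one point per altered characteristic —
AAA-domain location, any hydrogen-bond change, hydrophobicity alteration,
destabilizing ΔΔG, and qualifying (non-missense coding) variant type — and
a flat five points to a splice variant that may change protein length.
Hydrogen-bond scoring is per variant, not per bond (per-bond is a config
switch): per-bond counting would invert the documented low/high case
ordering. Case severity is the pair-member sum, ranked descending with a
deterministic tie-break on case id.

## LOWESS and peak detection

The smoother is Cleveland's LOWESS: for each evaluation point the
⌈frac·n⌉ nearest neighbours (frac default 0.3) receive tricube weights in
distance scaled by the k-th nearest distance, a weighted straight line is
fitted and evaluated at the point; `robust_iters` bisquare passes
down-weight outliers by (1−(r/6s)²)² with s the median absolute residual.
Duplicate ages are averaged with a warning; fewer than three points is an
error; a degenerate local design falls back to the weighted mean. The
implementation is written in full here because the package pins the
textbook definition exactly (the suite checks 10⁻⁸ agreement with an
independent naive quadratic-time implementation); general-purpose library
smoothers use performance-motivated windowing variants that deviate from
that definition by visible margins.

Peaks are interior local maxima with prominence ≥ 10% of the curve range
(default), plus a boundary maximum when the curve rises into an endpoint by
at least the threshold — this captures a plateau peak at the edge of the
observed age range (adulthood) that interior-only detection would miss.
The age axis is log₁₀ post-conception days, since developmental sampling
is dense early and sparse late; a linear axis is a caller choice.

## Synthetic cohorts

The generator emulates the study design: 291 affected trios; 1942
asymptomatic control parents in 971 child-anchored families; four
reference populations with allele numbers of order 2.5×10⁵ / 1.1×10⁵ /
1.9×10⁴ / 9×10³; five case probands and nine control parents planted with
trans pairs in the target gene (plus three cis control parents to exercise
phase discrimination). Per-variant base frequencies are log-uniform
(background 10⁻⁴·⁵–10⁻²·², so the upper tail exercises the 5×10⁻³
pre-filter; target gene 10⁻⁵·⁵–10⁻⁴·², keeping every plantable pair under
the 10⁻⁶ product rule — an infeasible plant raises an error); population
multipliers are log-normal with an East-Asian log-mean shift of 0.7 to
emulate the subpopulation enrichment visible in the study counts. Genotypes
are Hardy–Weinberg draws for parents with Mendelian transmission to
children; a `mendelian_error_rate` knob (default 0) injects genotype
errors, and no intragenic recombination is simulated between pair members
(matching the phasing logic's assumption; the knob is reserved). All
randomness flows from one seed through named substreams (seed × CRC32 of
the stream name), so adding a generator leaves others' draws unchanged.

Expression series are a fixed stage grid of 48 points, uniform in log₁₀
post-conception days over [1.7, 4.35], as in stage-structured developmental
resources, with a smooth three-peak template (fetal ≈ 100 days, infancy ≈
2 years, adulthood ≈ 30 years post conception; Gaussian bumps of widths
0.22/0.25/0.30 log-units on a baseline of 5 RPKM) plus additive Gaussian
noise scaled to the template amplitude (default 5%).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequencing and calling error beyond the single
genotype-error knob, linkage between variants, population structure within
a cohort, relatedness, ascertainment bias in who gets sequenced, overlap
between reference subsets, and real per-variant allele-number variation
(each population has one allele number). Planted-recovery results
therefore demonstrate the correctness of the pipeline's logic under its own
assumptions, not its robustness to real-world artefacts.

## Problem sizes and determinism

Default validation runs use 30 background genes × 8 variants plus 12
target-gene variants per cohort, 20 seeds for planted-signal recovery, and
2000 null replicates for the type-I-error calibration of the burden test;
these sizes give stable results while keeping a full validation run in
seconds. The null calibration checks a one-sided bound (empirical size ≤
6% at α = 0.05): Fisher's exact test is conservative by construction, so
its true size sits below the nominal level and a two-sided band around 5%
would be inappropriate for the method itself.

## Known limitations

Non-trio families, X-linked special-casing beyond basic male hemizygosity,
ACMG-style pathogenicity classification, regression-based burden
frameworks (SKAT and relatives), population-structure correction, and
transcript re-annotation are all out of scope; consequences, in-silico
verdicts, ΔΔG, hydrogen-bond counts and splice-residue localizations are
consumed as annotation inputs, never computed.
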