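# comphet

Trio-based compound-heterozygote prioritization and excess-of-variants
analysis for nominating recessive susceptibility genes, with protein
subregional impact scoring and developmental expression profiling.

## The problem

In trio whole-exome studies of disorders with incomplete penetrance — the
motivating application is epilepsy susceptibility, where five unrelated
probands carried biallelic variants in the same giant AAA-ATPase gene — a
candidate gene is nominated by a case-by-case filtering cascade and then
defended statistically against population references. `comphet` implements
that full arc as a tested, reusable library and CLI:

1. **Prioritization** (`comphet.prioritize`): per-trio cascade — exclude
   variants with reference MAF > 5×10⁻³; keep canonical-splice, nonsense,
   frameshift, in-frame indel, missense and initiation-codon consequences;
   classify inheritance (de novo / homozygous / hemizygous / inherited het,
   with parental origin) against brute-force-verified Mendelian logic; form
   compound-het pairs from one paternal plus one maternal het per gene;
   apply stratified frequency criteria — de novo/hom/hemi candidates must be
   absent from the control reference, a biallelic pair must satisfy
   f(a)·f(b) < 10⁻⁶; exclude probands explained by known disease genes;
   refine by gene profile; screen gene- and variant-level recurrence.
2. **Excess statistics** (`comphet.stats`): two-sided Fisher's exact test
   (minimum-likelihood definition, log-space hypergeometric), odds ratios
   with Woolf intervals exp(ln OR ± z·√(1/a+1/b+1/c+1/d)) and
   Haldane–Anscombe correction for zero cells; aggregate allele-frequency
   comparison of the identified variant set against four reference
   populations; ascertainment of compound heterozygotes among control
   parents by *transmission phasing* — a double-het parent whose child
   inherited exactly one of the pair carries it in trans, both-or-neither
   means cis; and the carrier-level burden test.
3. **Protein impact** (`comphet.impact`): domain-map localization on the
   5696-residue protein (AAA1–6 ring, long linker, MIDAS), the biallelic
   subregional pattern (one allele in AAA2–AAA3, the other in the linker or
   its 100-residue vicinity), hydrophobicity alteration on the
   Fauchère–Pliska scale (|Δ| ≥ 1.0 units), ΔΔG stability classes
   (±0.5 kcal/mol), and the characteristic point score (1 point per altered
   characteristic; 5 for a splice variant that may change protein length).
4. **Expression profiling** (`comphet.expression`): LOWESS smoothing
   (tricube k-NN local linear with bisquare robustness passes) of
   age-indexed RPKM series per brain region and peak detection with
   prominence and boundary-rise rules.
5. **Synthetic cohorts** (`comphet.simulate`): seeded generators for the
   full study design — 291 case trios and 1942 control parents in 971
   child-anchored families, four-population frequency tables with East-Asian
   enrichment, planted trans (and cis) pairs, and three-peak developmental
   expression series — so the whole pipeline is testable end to end without
   any external download.

## Worked example

The bundled worked example (`comphet.study`) reconstructs five trios and
nine variants of one target gene, with per-variant allele counts in four
reference populations:

```python
import comphet as ch

res = ch.run_worked_example()
for pop, r in res.aggregate.per_population.items():
    ac, an = res.aggregate.reference_counts[pop]
    print(f"{pop:12s} 10/582 vs {ac}/{an}  OR={r.odds_ratio:.2f} "
          f"(95% CI {r.ci_low:.2f}-{r.ci_high:.2f})  p={r.p_value:.3g}")
b = res.burden.result
print(f"burden 5/291 vs 9/1942: OR={b.odds_ratio:.2f} "
      f"(95% CI {b.ci_low:.2f}-{b.ci_high:.2f}) p={b.p_value:.3f}")
print("case scores:", dict(sorted(res.impact.case_totals().items())))
```

prints

```
all          10/582 vs 189/250470  OR=23.15 (95% CI 12.19-43.96)  p=5.98e-11
control      10/582 vs 71/106914  OR=26.31 (95% CI 13.50-51.26)  p=2.67e-11
eas_all      10/582 vs 151/18324  OR=2.10 (95% CI 1.10-4.01)  p=0.0339
eas_control  10/582 vs 61/9036  OR=2.57 (95% CI 1.31-5.05)  p=0.00997
burden 5/291 vs 9/1942: OR=3.75 (95% CI 1.25-11.28) p=0.027
case scores: {'case1': 2, 'case2': 3, 'case3': 2, 'case4': 4, 'case5': 5}
```

Reading: the cases' aggregate allele count (10 alleles over 582 case
chromosomes) is in 23-fold excess over the full reference population; the
compound-het carrier frequency (5 of 291 probands vs 9 of 1942 control
parents, the latter ascertained by transmission phasing) gives OR 3.75 with
an exact p of 0.027; and the per-case severity scores separate the mild
presentations (low scores) from the refractory ones (high scores), with the
splice-carrying case topping the ranking at 5 points.

## CLI

```bash
comphet --seed 7 --out-dir sim simulate
comphet --out-dir pri prioritize --vcf sim/cases.vcf --ped sim/cases.ped \
        --annotations sim/annotations.tsv
comphet --out-dir exc excess --vcf sim/controls.vcf --ped sim/controls.ped \
        --annotations sim/annotations.tsv --gene MDN1 \
        --case-ac 10 --case-an 582 --case-carriers 5 --n-cases 291
comphet --out-dir imp impact --vcf sim/cases.vcf --ped sim/cases.ped \
        --annotations sim/annotations.tsv
comphet --out-dir expr expression
comphet --seed 7 --out-dir all_out all
```

Every stage writes deterministic TSVs plus a `manifest.json` recording the
seed, configuration and library versions. Domain-map and hydrophobicity
configurations ship as YAML under `configs/`.

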