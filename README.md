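# hlabag

Attribute-bagging HLA imputation with population-specific reference
panels, and the evaluation machinery needed to decide whether a matched
panel is worth building.

## The problem

The classical HLA genes (HLA-A, -B, -C, -DRB1, -DQA1, -DQB1, -DPB1) are
the most polymorphic loci in the human genome and the strongest single
genetic factor in autoimmune disease and transplantation. Typing them
directly is expensive, but the strong linkage disequilibrium (LD) between
MHC-region SNPs and HLA alleles lets a model trained on a *reference
panel* — a cohort with both SNP genotypes and clinical-grade HLA types —
impute two-field HLA allele pairs (e.g. `A*02:01/A*01:01`) from cheap
array genotypes, with a posterior probability per call.

LD structure differs between populations. In a relatively isolated
population, haplotypes that are common locally may be rare or absent in a
generic (e.g. pan-European) reference, and calls on their carriers fail
silently. `hlabag` implements the full study design for quantifying this
effect: build a matched and a generic panel, impute a common test set,
and compare error behaviour with bootstrap, permutation, ROC and
threshold-sweep statistics; then validate imputed allele frequencies
against an independent reference and replicate known HLA–disease
associations by logistic regression on allele dosages.

## The model

Per locus, the imputation model is an ensemble of `n_classifiers` bagged
classifiers. Classifier *c* holds a SNP subset S_c (about sqrt(m) of the
m candidate SNPs, refined by a few greedy grow/swap moves that must raise
out-of-bag accuracy) and an *extended-haplotype* frequency table
f_c(h, a) over pairs of (SNP allele pattern h over S_c, HLA allele a),
fitted by an EM algorithm on a bootstrap resample: phase over S_c is
latent, each individual is distributed over all extended-haplotype pairs
consistent with its genotype and its known unordered HLA pair, and
missing SNP sites are marginalised.

For a target genotype G the classifier scores each unordered allele pair
{a1, a2} under Hardy–Weinberg pairing,

    P_c({a1,a2} | G)  ∝  Σ  f_c(h1,a1) · f_c(h2,a2)

summed over ordered pattern pairs (h1, h2) consistent with G (the sum
doubles heterozygous pairs automatically). Classifier posteriors are
normalised and averaged with weights proportional to out-of-bag
accuracy; the call is the argmax pair with its combined posterior. Only
alleles present in the reference can ever be called.

Everything downstream consumes the per-call error count (0/1/2 wrongly
imputed alleles against truth, by multiset matching) and the posterior.

## Worked example

```python
from hlabag import (SimulationConfig, RunConfig, simulate_population,
                    derive_enriched_population, sample_cohort,
                    HLAImputationModel, count_errors)

sim = SimulationConfig()                      # 50 SNPs, 8 alleles per locus
base = simulate_population(sim, seed=1, loci=("A", "B", "C"))
isolate = derive_enriched_population(base, sim, seed=2)   # +8 enriched haplotypes/locus

ref  = sample_cohort(isolate, 800, sim, seed=3, sample_prefix="F")
test = sample_cohort(isolate, 200, sim, seed=4, sample_prefix="T")

results = HLAImputationModel.from_cohort(ref, RunConfig(n_classifiers=25)).fit(seed=5)
print(results.summary())
calls = results.impute(test.genotypes)
err = count_errors(test.truth, calls.calls)
print(f"errors: {err.total_errors} / {2 * err.n_calls} alleles "
      f"({100 * err.error_rate:.2f}%)")
```

This prints the per-locus model summary and then

```
Attribute-bagging HLA imputation model
======================================================
locus    alleles classifiers SNPs used  mean OOB acc
------------------------------------------------------
A              8          25        50         0.989
B              8          25        49         0.985
C              8          25        49         0.991
------------------------------------------------------
distinct SNPs used across loci: 148
errors: 2 / 1200 alleles (0.17%)
```

— the matched panel imputes its own population essentially perfectly,
while the same test cohort imputed with a panel trained on `base` (which
lacks the enriched haplotypes) shows an error rate around 10–15%,
concentrated in enriched-haplotype carriers. A thin CLI (`hlabag
simulate | harmonize | train | impute | evaluate | validate-freq |
associate`) chains the same stages through files.

## Layout

- `hlabag.io` — VCF/TSV genotype, HLA-typing, phenotype and call tables
- `hlabag.harmonize` — cross-platform, cross-build SNP harmonization
- `hlabag.simulate` — two-population synthetic MHC generator
- `hlabag.em` / `hlabag.model` — EM core and the attribute-bagging engine
- `hlabag.evaluation` — errors, bootstraps, permutation tests, ROC, sweeps
- `hlabag.frequency` — batch allele-frequency validation
- `hlabag.association` — allele-dosage logistic regression
- `hlabag.workflows` — end-to-end study designs
- `docs/methods.md` — modelling assumptions, parameter defaults, limitations
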