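# Methods

## Imputation model

Each HLA locus is modelled independently by an ensemble of bagged
classifiers (attribute bagging: every classifier sees a random subset of
the SNPs). A classifier is trained as follows:

1. Bootstrap-resample the reference cohort (out-of-bag samples are kept
   for accuracy estimation).
2. Draw a random SNP subset of size ceil(sqrt(m)) from the m candidate
   SNPs of the locus.
3. Fit an extended-haplotype frequency table on the in-bag samples by EM
   (below).
4. Apply up to `greedy_moves` (default 5) refinement moves; each move
   either adds a random SNP or swaps a random member for a random
   non-member, refits the table, and is kept only if the classifier's
   out-of-bag allele accuracy strictly increases.

Subset sizes are capped at 25 SNPs, the bound at which haplotype-pattern
enumeration stays exact. Candidate SNPs per locus should be the SNPs
flanking the gene; the `locus_snps` mapping carries this and defaults to
all SNPs, which is only sensible for single-locus matrices.

At prediction time each classifier scores unordered allele pairs under
Hardy–Weinberg pairing of its table haplotypes, restricted to extended
haplotypes actually in the table; a classifier whose subset is entirely
missing for a sample, or which assigns zero to every pair, abstains for
that sample. Per-classifier posteriors are normalised then combined by a
weighted arithmetic mean with weights proportional to out-of-bag
accuracy (`classifier_weighting="uniform"` switches to plain averaging).
Argmax ties break to the lexicographically smallest allele-pair label.
Samples with no usable classifier receive a flagged call with posterior
0. Alleles absent from the reference panel cannot be called — the
fundamental limitation of reference-based imputation; enlarging and
diversifying the panel is the only remedy.

## EM for extended-haplotype frequencies

Genotypes over a SNP subset are unphased; the HLA allele pair of each
reference sample is known but its assignment to the two SNP haplotypes is
not. The EM treats the ordered pair of extended haplotypes as the latent
variable: the E-step distributes each individual over all consistent
ordered pairs in proportion to the product of current frequencies, the
M-step re-estimates frequencies from expected counts. Missing SNP sites
are marginalised by expanding both alleles on each haplotype.
Individuals are collapsed to unique (genotype pattern, HLA pair) keys, so
the per-iteration cost is independent of cohort size. Iteration stops
when the largest absolute frequency change falls below `em_tol` (1e-8) or
at `em_max_iter` (500); frequencies below `freq_prune` (1e-9) are then
pruned and the table renormalised. Pair expansions whose responsibility
has collapsed below 1e-14 are dropped every 16 iterations; their future
contribution is orders of magnitude below the stopping tolerance. The
likelihood is unimodal in none of these problems a priori, so
`n_restarts` random Dirichlet starts are available; in practice the
uniform start attains the same optimum (the test suite checks this
against a brute-force simplex search on small problems).

An individual whose heterozygous-plus-missing sites would expand to more
than 4096 ordered pairs is dropped from that classifier with a logged
count; with subsets of at most 25 SNPs this is rare and bounded.

## Synthetic data

The generator emulates the two-population situation that motivates
population-specific panels:

- Per locus, a shared pool of `n_shared_haplotypes` (30) haplotypes over
  `n_snps` (50) biallelic SNPs, SNP vectors uniform-random, HLA labels
  covering `n_alleles` (8) two-field alleles, frequencies from a
  symmetric Dirichlet(0.8). LD is strong by construction: only 30 of the
  2^50 possible SNP patterns exist, so patterns tag alleles tightly.
- The target isolate adds `n_enriched_haplotypes` (8) *enriched rare*
  haplotypes per locus: a shared haplotype mutated at 10–30% of sites,
  labelled with a random existing allele, carrying total frequency
  `enriched_mass` (0.15). The generic population carries them at
  frequency zero. This is the mechanism by which a generic panel errs on
  isolate samples: the carrier's SNP pattern is absent from the panel's
  tables, and the call falls back on whatever shared patterns can explain
  the genotype.
- Cohorts draw two haplotypes i.i.d. per locus per sample; genotypes are
  the allele sums, then each site flips with probability
  `genotype_noise` (0.002; 0→1, 2→1, 1→0/2 equally). Truth typing and
  haplotype identities are recorded pre-noise.
- Phenotypes: case status is Bernoulli(logistic(intercept + Σ
  dosage·logOR + covariate terms)) with age ~ N(55,10), sex ~
  Bernoulli(0.5), BMI ~ N(27,4) and standard-normal PCs. Covariate
  effects apply to mean-centred covariates so the intercept keeps its
  logit-prevalence meaning (default intercept = logit(0.1)).

What the generator does *not* emulate: coalescent genealogy, cross-locus
LD (loci are independent blocks — single-locus models never use
cross-locus information, so this only removes cost; the
`recombination_prob` field is consequently inert), genotyping batch
effects, allele-frequency differences beyond the enriched set, and
genome-build duality (synthetic manifests are generated consistent, so
harmonization is exercised by planted mismatches). Passing tests
therefore demonstrate the machinery and its statistical behaviour under
a faithful LD-and-enrichment mechanism, not real-MHC error rates.

## Evaluation conventions

- The error unit is the allele: a call scores 0, 1 or 2 against truth by
  maximum multiset matching of unordered pairs; flagged calls score 2.
  Per-sample errors are sums over loci.
- Bootstraps resample samples (all loci of a sample move together, since
  errors within an individual are dependent).
- The permutation null for panel comparisons swaps each sample's paired
  records between panels independently with probability 1/2 (both panels
  impute the same samples, so the design is paired). P-values are
  two-sided with the +1 convention and can never be zero. In the
  threshold-sweep variant, a threshold retaining nothing contributes
  zero to the statistic.
- ROC: correct calls (zero errors) are positives, the posterior is the
  score; one and two errors form one negative category. The AUC uses the
  rank formula with tie correction and equals the trapezoidal area under
  the empirical curve to machine precision.
- Best-posterior panel selection is 10-fold cross-validated per locus:
  the panel with the higher mean posterior on nine folds is scored on
  the tenth.
- Enriched-carrier attribution: a sample is a carrier if any of its true
  haplotypes (any locus) is enriched; reported is the carrier share of
  all errors next to the carrier fraction of the cohort.
- Frequency validation: per-batch mean absolute deviation from the
  reference over the union of alleles (absent = 0), and the Spearman
  correlation of that deviation with the batch's retained allele count
  (undefined inputs are reported as undefined, not coerced).
- Association: maximum-likelihood logistic regression of status on
  allele dosage plus age, sex, BMI and the first `n_pcs` (10) PCs; Wald
  test and CI on the dosage coefficient; Newton with a BFGS retry;
  perfect separation, non-convergence, exploding standard errors or a
  constant dosage column yield flagged results, never exceptions. The
  scan uses best-guess dosage by default (posterior-expected dosage is
  available), a fixed significance threshold `alpha_assoc` (5e-5) and an
  allele-frequency floor of 0.5% against separation artifacts.

## Design choices on open points

- Strand harmonization: allele sets may match directly or after
  complementation; palindromic (A/T, C/G) SNPs are always excluded as
  strand-ambiguous, because identity and strand flip are
  indistinguishable for them. SNP identity is by rsID only; positions may
  differ between builds.
- Missing genotypes: marginalised in EM during training; at prediction a
  classifier abstains per sample when its whole subset is missing.
  Absent SNP columns are treated as missing for all samples.
- Batched imputation is purely an orchestration device: near-equal
  contiguous batches, concatenating to exactly the unbatched output,
  with the batch label kept for per-batch frequency validation.
- HLA allele names are normalised by truncation to two fields rather
  than rejection, matching the two-field resolution target throughout.

## Problem sizes and calibration findings

The study-scale experiments run seven loci with simulation defaults,
reference cohorts of 800 per population, a 200-sample test cohort and 25
classifiers per locus, replicated over 20 seeds; the calibration and ROC
analyses impute 2000 samples; association recovery uses n = 4000 at 10%
prevalence. These sizes make the full suite reproducible on a single CPU
in well under half an hour while leaving every comparison amply powered.

One empirical finding is worth stating plainly: the combined posterior
is *conservative* in the well-specified (matched-panel) case. Calls with
combined posterior 0.7–0.9 are empirically correct essentially always.
This is a known property of linear opinion pools — each classifier's
posterior is honest for its own SNP subset, and averaging posteriors of
weakly informative classifiers cannot reach the sharpness of the Bayes
posterior on their pooled evidence; exact-consistency scoring under
genotype noise adds a further downward pull. The posterior therefore
*ranks* calls by correctness very well (ROC AUC 0.88–0.94 for the
misspecified generic panel, where errors exist) but should be read as a
lower bound on accuracy, not an unbiased probability. Conversely, under
panel–population mismatch the posterior is overconfident on
enriched-haplotype carriers: confidently wrong calls are exactly the
failure mode a population-specific panel removes.

## Known limitations

- Two-field resolution only; no G/P group handling.
- No amino-acid or SNP fine-mapping outputs.
- The engine assumes error-free genotypes at scoring time; a per-site
  genotype error model would sharpen both accuracy and calibration but
  changes the scoring contract.
- `bestpp` selection assumes both panels called every test sample.
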