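# Methods

`wblup` implements a family of genomic-prediction methods that differ only in
how per-SNP variance is allocated, plus the machinery needed to compare them
honestly on simulated cattle-like data: a genotype/trait simulator with known
truth, REML variance-component estimation, a regional genome scan, two
Bayesian mixture samplers, pedigree-genomic (single-step) evaluation, an LMM
association scan, and a fixed train/validation evaluation harness.

## Models

### GBLUP and standardized GBLUP

The base model is `y = 1 mu + g + e` with `g ~ N(0, G sigma_g^2)` and
`e ~ N(0, I sigma_e^2)`, where `y` holds trait deviations (phenotypes
pre-corrected for fixed effects). Two GRMs are supported: the
allele-frequency-weighted form `G = X X' / sum_j 2 f_j (1 - f_j)` on centered
dosages `x_ij = s_ij - 2 f_j`, and the standardized form
`GS = (1/m) W W'` on unit-variance dosages
`w_ij = x_ij / sqrt(2 f_j (1 - f_j))`, under which every SNP is expected to
contribute equally to the genetic variance and low-MAF SNPs get relatively
larger effects. Frequencies default to in-sample values over the full
(train + validation) genotype set; a train-only option exists.

### Weighted GRMs and the trace contract

All weighting strategies share one algebraic convention: a diagonal matrix
`D >= 0` with `tr(D) = m` inserted into the standardized GRM,
`Gw = (1/m) W D W'`. Keeping the trace at `m` keeps the mean SNP weight at 1,
so `sigma_g^2` retains its interpretation across strategies and iterations.
Group-based weights (regional scan, WPIP) come from per-group variances via
`d_i = (sigma_k^2 / m_k) / (sigma_T^2 / m)` for the group `k` containing SNP
`i`, whose trace is `m` by construction.

### Adaptive regional scan (AM-BLUP) and its refinement (BAM-BLUP)

Each chromosome is tiled with 1 Mb chunks overlapping by 50%. A chunk is
tested by a restricted likelihood-ratio test of its own variance component on
top of a background kernel built from all SNPs outside the chunk. Because the
tested component sits on the boundary of the parameter space, the default
null distribution is the mixture `1/2 chi2_0 + 1/2 chi2_1`; a plain `chi2_1`
convention is available (it doubles every p-value, so the genome-wide seed
threshold `thr1 = 1e-5` becomes effectively twice as strict).

Regions grow around seed chunks (`p < thr1`) over contiguous chunks with
`p < thr2 = 0.01`; overlapping grown regions coalesce. A joint REML fit of
background + K region kernels yields the per-region variances and the AM
weight vector above. With no seeds the procedure degenerates exactly to the
standardized GBLUP.

The refinement replaces `thr1` with an empirical threshold — the 5% quantile
(linear, type-7 interpolation) of the minimum chunk p-value over permuted
phenotypes (genotypes untouched) — merges significant regions less than 10 Mb
apart, and reduces each region to a bootstrap confidence set: individuals are
resampled with replacement, the region window with the largest LRT is flagged
per sample (ties leftmost; the background kernel, built from SNPs outside the
region, is shared across the region's windows within a sample and refitted
per sample), and the CI is the smallest set of windows, by descending flag
count, reaching 95% of the draws. The CI is by construction a subset of the
region's windows, so it can only shrink the region.

Numerics: the scan and the permutations run on an exact-REML fast path. The
full standardized GRM is eigendecomposed once per dataset; in that basis the
per-chunk covariance is diagonal plus a rank-`mc` update, the residual
variance is profiled out analytically, and the remaining variance *ratios*
are maximized on the log scale (bounded Brent for the null, Nelder-Mead with
a coarse seed grid plus explicit boundary checks for the full model). This is
the same REML objective as the dense average-information path and agrees with
it to ~1e-9 in the test suite; it is what makes 1000-individual, 250-chunk
scans take seconds rather than hours. Bootstrap samples cannot reuse the
dataset eigendecomposition (rows are resampled), so each sample
eigendecomposes its background kernel once and treats windows as low-rank
updates.

### REML

General variance-component estimation (used for multi-kernel region fits,
weighted-GRM fits, GWAS nulls and the dense reference path) is
average-information REML with EM fallback steps whenever an AI proposal
leaves the parameter space or decreases the restricted likelihood, an
active-set non-negativity constraint (components pinned at zero re-enter on a
positive gradient), and convergence on relative parameter change (1e-6) or
likelihood change (1e-8). Initialization splits half the phenotypic variance
equally among kernels. `V` is built and factorized densely — appropriate for
the few-thousand-individual problems this package targets.

### Bayesian mixtures (BSLMM- and BayesR-style)

Both samplers are single-site Gibbs on standardized genotypes with conjugate
updates; chains are deterministic under their seed and the inner loops are
JIT-compiled.

* Two-component model: `beta_j ~ pi N(0, sigma_b^2 + sigma_a^2) +
  (1 - pi) N(0, sigma_b^2)`. The polygenic part is carried as per-SNP small
  effects (equivalent to its GRM formulation, one code path). Variances are
  updated on the grouped parametrization (small-class variance, large-class
  variance with an ordering floor) with scaled-inverse-chi-square draws;
  `pi ~ Beta(1 + k, m/100 + m - k)`. The PIP of a SNP is its posterior
  frequency in the large class. Forcing `pi = 0` degenerates the model to
  ridge/GBLUP, which the tests exploit.
* Four-component model: class variances fixed at `(0, 1e-4, 1e-3, 1e-2) x
  sigma_g^2`, with `sigma_g^2` resampled every iteration so class variances
  track it; mixing proportions get a flat Dirichlet prior. The per-SNP
  posterior variance — the BRPV weight source — is the average over retained
  iterations of the class variance occupied at that iteration.

Defaults are 10,000 iterations, 2,000 burn-in, thinning 10; the comparison
harness uses 3,000/1,000/5 at its desk scale, where doubling the chain moves
PIPs by well under 0.05 RMS. Chain length and priors are package choices (the
sampler internals of the original tools are not reproduced); sensitivity is
reported by the consistency test, not asserted beyond it.

Exact permutation-equivariance of PIPs under SNP reordering cannot hold for a
sequential sampler (the update order changes the random-number stream); the
property is verified statistically (posterior mass follows the permutation).

### Other weighting strategies

* WPIP: non-overlapping, chromosome-breaking 25-SNP windows scored by
  cumulative PIP; windows above 0.5 are kept and pruned to the smallest
  PIP-ranked SNP subset carrying 95% of the window PIP; each retained
  window's variance is estimated by multi-kernel REML next to a background
  kernel and converted to weights by the AM rule. An empty selection is
  uniform weights.
* IW: ten iterations of back-solving SNP effects from the current weighted
  GBLUP (`beta = (1/m) D W' G^-1 g_hat` on the training block), mapping
  `t = |beta|/sd(beta)` through the nonlinearA weight `1.125^(t-2)`, capping
  and renormalizing. The 2.6 cap is enforced as a hard ceiling on the final
  weight jointly with the trace contract (water-filling): this matches the
  worked points (2 sd -> 1, 12 sd -> 2.6) and makes a cap of 1 exactly
  uniform, i.e. reweighting impossible.
* BRPV: weights proportional to the four-class posterior SNP variances,
  rescaled to trace `m`.

### Single-step GBLUP

Henderson's tabular `A`, and `H^-1 = A^-1 + [[0,0],[0, Gadj^-1 - A22^-1]]`
with `Gadj` tuned to `A22` (two-coefficient match of mean diagonal and mean
off-diagonal) and blended `0.95 Gadj + 0.05 A22` — conventional defaults, as
the tuning used in the original evaluations is not public. EBVs solve the
standard mixed-model equations with `lambda = sigma_e^2 / sigma_g^2`;
any weighted GRM can be supplied. Everything is dense; pedigrees up to a few
thousand animals are the intended scale.

### Association scan

Score test per SNP in the LMM: null components fitted once genome-wide
(intercept + one GRM; no leave-one-chromosome-out, so proximal contamination
is accepted), statistic `(w'Py)^2 / (w'Pw) ~ chi2_1`, Bonferroni threshold
`alpha / m`, and peaks split when significant SNPs are more than 10 Mb apart
or change chromosome.

### Evaluation

Validation individuals are the most recent generation; their phenotypes never
enter any fit (a leakage test mutates them and asserts unchanged
predictions). Metrics: predictive ability `cor(TD, g_hat)`; reliability
`REL = cor^2 / h2`, which may exceed 1 and is reported as-is; MSE (raw and
standardized by `var(TD)`); and the slope of TD regressed on predictions
(below 1 means inflated prediction scale). The `h2` in the denominator comes
from the training-set REML of the standardized GBLUP baseline so all methods
share one denominator.

## The simulator and what it does (not) show

Founder haplotypes follow a first-order Markov chain along each chromosome
with neighbor-allele correlation `0.95 exp(-d / 100 kb)` (clipped to the
Frechet-feasible range for the marginal frequencies); descendants receive
gametes by gene-drop with Haldane recombination at 1 cM/Mb through a
discrete-generation pedigree (default fractions 0.25/0.30/0.30/0.15 of
`n = 1000`; the last generation is the validation set, ~15% of individuals,
mimicking a date cutoff). MAF is uniform on (0.05, 0.5); SNPs fixed by drift
are dropped. The default genome is 5 chromosomes of 25 Mb with 400 SNPs each
— about 16 SNPs/Mb, the density of a medium-density cattle array — so a 1 Mb
chunk holds ~16 SNPs and a genome holds ~245 chunks, which matters: chunk-test
power and multiplicity both depend on SNPs-per-chunk and chunks-per-genome,
and an unrealistically dense desk genome understates scan power.

Traits put large effects on a few SNPs inside declared 1 Mb regions and small
effects on all remaining SNPs; component effects are rescaled in-sample (and
the residual orthogonalized in-sample) so each region's share of the genetic
variance and the heritability (default h2 = 0.4) are hit exactly, making
parameter-recovery tests sharp. Default trait architectures span the range
reported for beef-cattle muscularity and conformation traits: a many-region
muscling-like trait (5 regions, 18% of genetic variance jointly), a
two-large-regions skin-thickness-like trait (6.5% each), and a purely
polygenic trait.

Not emulated: demography and selection history, sex chromosomes,
genotyping-error and imputation-error structure, multi-trait genetic
correlations, and contemporary-group fixed-effect structure (trait deviations
are simulated directly). Passing tests therefore demonstrate internal
correctness and the expected relative behavior of methods under a known
architecture — not absolute reliabilities on real cattle data, which sit much
lower (the harness's validation generation is heavily related to training).

## Problem sizes used by the acceptance checks

Chosen as desk-scale study conditions: oracle checks at n of tens; REML
recovery at n = 1000 (10 replicates) and region-share recovery on the true
partition (5 replicates); null calibration from 20 pure-noise traits (~40
chunks each) plus one 2000-SNP association scan; permutation thresholds at
100 permutations; scan detection at n = 1000, m = 2000 with 20 replicates and
a 10%-of-genetic-variance QTL; bootstrap refinement at n = 800, m = 800, 12
replicates of 200 resamples; directional method comparisons over 8-10 seeds
at n = 600; and one end-to-end default scenario (1000 x 2000, 3 traits, 8
methods).

## Known limitations

* Dense linear algebra throughout; nothing here is meant for 600k-animal
  pedigrees or 50k+ panels.
* The bootstrap refinement is the slowest stage (one eigendecomposition per
  resample); its desk-scale replicate counts are correspondingly modest.
* Reliability uses a genomic REML h2, not an external/pedigree value; with a
  mis-specified h2 the REL scale shifts for all methods equally.
* The samplers' absolute posterior probabilities depend on prior choices
  (documented above); rankings and the resulting weights are what the tests
  pin down.
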