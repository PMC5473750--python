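# Methods

This note documents the statistical model, the numerical choices, and the
synthetic-data generator behind `mpqtl`, together with the design decisions
taken where the procedure was genuinely open.

## The mapping population and its genotype representation

The package targets multiparent advanced-intercross populations of
budding yeast: four haploid founders (labelled NA, WA, WE, SA) are crossed
pairwise into F1 hybrids, the hybrids' spores are pooled, and the
population is propagated by repeated rounds of sporulation and random
spore mating — 12 generations in the design the defaults mirror — before
haploid segregants are sampled and sequenced.  Genotypes are
*founder-of-origin* calls: at each segregating site a segregant carries
the allele of exactly one founder, so a marker is a categorical variable
with up to four states rather than a biallelic dosage.  Missing calls use
the reserved token `.` ("NA" is a founder label and therefore cannot
denote missingness; genotype TSVs are parsed with pandas NA handling

disabled).  Coordinates are 1-based inclusive internally; BED export
converts to 0-based half-open.

## Genome scan

### Model

For trait vector `y` (n segregants) and tested site `k`:

```
y = X b + X_k b_k + u + e,    u ~ N(0, A(c) sigma_a^2),    e ~ N(0, I sigma_e^2)
```

* `X` — covariate design.  The LYS2/URA3 auxotrophy markers define up to
  four membership combinations (a full indicator block; rows sum to one,
  so it spans the intercept; empty combinations are dropped and the
  effective count recorded).  Mating type is added as an extra indicator
  column only where it increases the design rank: with four auxotrophy
  combinations and a balanced mating-type segregation the extra column is
  frequently collinear, and the model lists it alongside the auxotrophies
  without defining an extra dimension for it.
* `X_k` — founder-allele membership at the site among segregants with a
  non-missing call; `q` is the number of distinct founder alleles observed
  (testable markers have 2 ≤ q ≤ 4).  Allele effects are coded with
  sum-to-zero contrasts so the joint design stays full rank; the Wald
  statistic does not depend on which allele anchors the contrasts (tested
  over all choices).
* `A(c)` — leave-one-chromosome-out kinship (below), `c` the chromosome of
  site `k`.

Segregants missing the phenotype or the marker call are dropped per
(trait, marker) pair and the effective n recorded; no imputation is
attempted because none is defined for founder mosaics.

### LOCO allele-sharing kinship

`A(c)[i, j]` is the proportion of segregating sites on chromosomes other
than `c` at which `i` and `j` carry the same founder label, computed
pairwise-complete over jointly observed sites; the diagonal is 1 by
definition.  Excluding the tested chromosome prevents the tested signal
from being absorbed by the polygenic term.  All sites are used, unweighted
and without linkage pruning.  A pair with zero jointly observed
off-chromosome sites is a hard error (the model is undefined for it).
Allele-share matrices need not be positive semi-definite in finite
samples; negative eigenvalues are truncated at zero inside the fitter,
which defines the PSD covariance actually used.

### REML and the Wald test

With `A = U diag(d) U'`, rotating `y` and the fixed design by `U'` turns
the marginal covariance into `sigma_e^2 * diag(gamma d + 1)` with
`gamma = sigma_a^2 / sigma_e^2`, and the restricted likelihood profiles
down to a 1-D function of `gamma`.  The profile is evaluated on a 21-point
grid of `log10 gamma` over [−5, 5] and refined by bounded scalar
minimization (absolute tolerance 1e−7 in `log10 gamma`); ties and flat
profiles (e.g. `A = I`, where only the total variance is identified) break
toward smaller `sigma_a^2` and are flagged non-identifiable.  The default
scan mode re-optimizes the ratio at every marker under the joint
covariate + allele design (per-position model fit); a `fast` mode
estimates the variance components once per trait × chromosome under the
covariates-only model and reuses them across markers, trading exactness
for speed.  The eigendecomposition is cached per (chromosome,
missingness-pattern), so the per-marker cost is a handful of weighted
least-squares solves.

The allele block is tested with a Wald statistic
`b_hat' Var(b_hat)^{-1} b_hat` under `V = sigma_a^2 A + sigma_e^2 I` at
the REML estimates, referred to a chi-square with q − 1 degrees of
freedom.  Treating the variance components as known makes the chi-square
reference mildly anti-conservative in finite samples: at n = 165 the
pooled null rejection rate measured over 6,000 unlinked markers is 0.058
at nominal 0.05 (the exact small-sample reference would be roughly
F(q−1, n−p)).  The chi-square convention is retained because it is the
test the scan is defined around; the bias is documented rather than
silently corrected.

### FDR, QTL calling, merging

Per trait, the full vector of tested-marker p-values is adjusted with the
Benjamini–Hochberg step-up; adjustment never crosses traits.  Markers at
q ≤ 0.5 — a deliberately permissive, candidate-generating threshold —
are grouped per chromosome into maximal runs (a configurable number of
interspersed non-significant markers may be bridged; default 0), each run
becoming a region from its first to last significant marker with the
minimum-p marker as peak.  Regions from different traits whose intervals
overlap by at least 1 bp merge transitively into major QTL regions that
report the union interval, the union of traits, and the strongest peak.
Merging is idempotent.  How support intervals were delimited before
overlap-merging is not fully specified in the original analyses; the
run-based rule here is the package's documented convention.

## Nitrogen phenotypes

Consumption of each source is initial − final concentration; negative
values (measurement noise) are retained but flagged.  Conversion to YAN
units multiplies by a per-source nitrogen mass fraction computed on the
compound *as supplied* — salt and hydrate forms (arginine
monohydrochloride, histidine monohydrochloride monohydrate, lysine
monohydrochloride) use the full salt mass, since recipe concentrations
are salt masses.  Two accounting modes exist: `total` counts every N atom
(default; e.g. glutamine 2 × 14.007 / 146.15 ≈ 0.1917 mg N/mg), while
`alpha_amino` counts one nitrogen per amino acid.  The shipped
300 mgN/L must recipe (120 mgN/L ammonium + 19 amino acids) balances to
its stated 180 mgN/L amino-acid budget only under alpha-amino accounting
with proline excluded (~183.5 mgN/L); both modes are exposed and the
recipe budget is verified in the tests under the alpha-amino mode.
Proline is carried in the composition but excludable from YAN totals, as
it is not assimilated anaerobically.

Transgression is summarized as the percentage of segregants above the
maximum (below the minimum) founder mean by more than a margin, default
one pooled founder standard deviation; the criterion has no field
standard, so the margin is a named, reported parameter and a margin of 0
reduces to simple range exceedance.  Positive and negative fractions are
reported separately.

## BSR-seq arm

SNP filtering requires the SNP to be observed in all four pools and to
reach ≥ `min_reads` (default 10) in every pool.  The depth rule is read as
*total* per-pool depth by default: requiring 10 reads of each allele in
every pool would discard pool-fixed SNPs, which are precisely the most
informative under extreme-pool enrichment; a strict per-allele mode is
available.  Removal reasons are tallied.

Allele-frequency testing sums the replicate pools within condition and
applies a two-sided Fisher exact test to the (ref, alt) × (HLA, LLA)
table — the contrast is defined between conditions, and replicate
presence is already enforced at the filter stage.  A per-replicate mode
(reporting the more conservative of the two replicate-pair tests) exists
for sensitivity analysis.  Tables with a zero margin are uninformative
and return p = 1 with a degeneracy flag.  Multiple testing uses Storey
q-values: `pi0(lambda) = #{p > lambda} / (m (1 − lambda))` on the grid
0.05…0.95, smoothed by a cubic spline and evaluated at the largest
lambda, clipped into (0, 1]; q-values are the step-up values scaled by
`pi0`, hence never above the BH values.  A plain BH mode is switchable.

Bulk expression ratios normalize pool counts to equal totals, sum within
condition, add a pseudocount of 1, and flag genes beyond the ratio
threshold (default 5) in either direction; the original normalization is
unstated, so total-count scaling is the package's documented choice.
Differential expression itself is consumed as an external gene list, not
recomputed.

Cross-referencing flags a gene as `in_QTL` when its interval extended by
a flank (default 15 kb up- and downstream) contains a marker with
−log10 p above the threshold (default 6) for any trait, and as
`AF_significant` when a q-significant SNP lies inside the unflanked
interval; candidates must be `in_QTL` plus at least one of the
allele-frequency, expression-ratio, or DE-list flags.  A mismatch between
annotation and marker chromosome names is an error listing the unmatched
names rather than a silent empty result.

## Synthetic-data generator

The generator emulates the study design, not any particular dataset.

* **AIL.**  Founders are paired ((NA, WA), (WE, SA)) into F1 hybrids;
  spores of both crosses are pooled; `generations − 1` rounds of random
  mating follow at a per-generation population size of 1,000 (a knob —
  the original propagation scheme's round sizes are unstated).  Per
  meiosis, crossover counts are Poisson with mean equal to the chromosome
  map length (default 0.35 cM/kb uniform, yeast-typical) and breakpoints
  are uniform with no interference — the simplest model consistent with
  fine-grained mosaics, and interference is irrelevant to testing the
  scan.  Haploid segregants are single gametes of the final generation;
  founder-of-origin is read off at evenly spaced markers (default 120 bp
  over the 16 real yeast chromosome lengths, ~100k sites; tests and
  validation experiments use sparser maps).  Selection on mating type or
  auxotrophies during the intercross is *not* simulated; covariate states
  are assigned randomly afterwards, since the scan needs covariate
  structure, not its ancestral origin.
* **Unlinked panel.**  An independent-uniform-founder-draw panel is
  provided for experiments whose statistics assume independent markers
  (null calibration via Kolmogorov–Smirnov, kinship concentration
  checks).  Linked AIL markers share mosaics, which would invalidate the
  independence assumption of those reference distributions without making
  the scan itself miscalibrated.
* **Traits.**  `y` = covariate effects + founder-allele QTL lookups +
  polygenic draw with covariance `sigma_a^2 A` (genome-wide allele
  sharing) + Gaussian residuals, with
  `sigma_a^2 = h2/(1−h2) sigma_e^2`.  A QTL's deviations (summing to
  zero) may be rescaled so its realized variance is a requested fraction
  of the realized QTL-plus-background total; the rescaling ignores the
  (small) sampling covariance between the QTL term and the background,
  so realized shares scatter within a few percent of the target.
* **Pools.**  The top and bottom `n_per_pool` (default 8) segregants by
  trait value form the high/low pools; each condition's two replicate
  pools contain the *same* individuals with Dirichlet-drawn RNA-mixture
  weights (concentration 50 around equal) — mirroring replicate pools
  mixed from equal RNA masses of the same individuals rather than
  independent resampling.  Per SNP a random 1–3 founders carry the
  alternative allele (overridable, e.g. to align a causal SNP with the
  causal founder); each pool's true reference frequency is the weighted
  founder-indicator mean; depths are negative-binomial (mean 100,
  size 10) and reference reads binomial.  Gene counts are Poisson around
  log-normal expression with optional HLA/LLA fold-change hooks.

All generators are deterministic functions of their config seed.

What passing tests on these synthetics do *not* show: robustness to real
RNA-seq artefacts (mapping bias toward the reference allele, expression-
driven allele-frequency distortion, overdispersion beyond the NB depth
model), to genotyping error in founder assignment, or to selection-driven
allele-frequency distortion during the intercross.

## Validation experiment sizes

The experiments in `scripts/acceptance.py` (shared by the acceptance
tests) use: a 20-segregant 2-chromosome instance for oracle equivalence;
a 400-segregant AIL over four 1-Mb chromosomes (2,000 markers, 50 trait
seeds) for REML recovery; a 165-segregant 16×125-marker unlinked panel
for null calibration; 20 seeds of a 165-segregant, 1,000-marker AIL with
a 25%-variance QTL for power/localization; every 2×2 table with margins
≤ 30 for Fisher exactness; 1,000 F12 segregants over the full yeast
genome for founder proportions; and 20 seeds of a 3-chromosome,
150-SNP BSR chain with a 50%-variance WE-aligned QTL.  These sizes are
the package's chosen validation conditions and are fixed in the script.

## Known limitations

* Variance components are treated as known in the Wald test (see the
  calibration note above); no permutation or empirical-null thresholds.
* No epistasis, multi-QTL modelling, or interval mapping between markers.
* Region support intervals end at the outermost significant marker; no
  LOD-drop-style extension.
* The Storey smoother uses a generic cubic smoothing spline, not a
  re-implementation of any specific package's spline defaults; for small
  m (< ~20 p-values) the estimator falls back to the raw value at the
  largest lambda.
* Expression simulation has no mean–variance trend or gene length model;
  it exists to exercise the ratio bookkeeping, not to benchmark DE
  methods.
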