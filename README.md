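# mpqtl

QTL mapping and bulk-segregant RNA-seq analysis for a four-founder
*Saccharomyces cerevisiae* advanced-intercross population, built around
nitrogen-consumption traits in wine fermentation.

Multiparent yeast populations such as SGRP-4X — 165 haploid F12 segregants
descended from four founder strains (NA, WA, WE, SA) through 12 generations
of intercrossing — carry fine-grained founder mosaics that break linkage
blocks and expose small-effect variants.  `mpqtl` implements the full
analysis chain for such a population:

* **Genome scan.**  At every segregating site *k* the linear mixed model

  ```
  y = X b + X_k b_k + u + e,   u ~ N(0, A sigma_a^2),   e ~ N(0, I sigma_e^2)
  ```

  is fitted by REML, where `X` encodes the mating-type and LYS2/URA3
  auxotrophy covariates, `X_k` the founder-of-origin allele membership at
  the site (up to 4 alleles), and `A` the leave-one-chromosome-out (LOCO)
  kinship: the proportion of shared parental alleles at segregating sites
  on all *other* chromosomes.  The allele block is tested with a Wald
  chi-square on q−1 degrees of freedom; per-trait p-value vectors are
  BH-adjusted, markers at q ≤ 0.5 form QTL regions, and regions from
  different traits are merged on bp overlap into major QTL.

* **Nitrogen phenotypes.**  Consumption of each nitrogen source is
  initial − final concentration in a 300 mgN/L synthetic must (120 mgN/L
  ammonium + a 19-amino-acid mixture); conversion to yeast-assimilable
  nitrogen (YAN, mgN/L) uses per-source nitrogen mass fractions, and
  transgressive segregation is summarized against founder replicates.

* **BSR-seq arm.**  Pooled SNP read counts from two high- (HLA) and two
  low- (LLA) ammonium-consumption replicate pools are filtered (≥ 10 reads
  per pool, present in all four pools), tested for allele-frequency
  differences with Fisher's exact test (replicates summed per condition),
  FDR-adjusted with Storey q-values, combined with bulk expression ratios
  (flagged beyond 5-fold), and cross-referenced with the scan: candidate
  genes are those whose ±15 kb interval contains a marker with
  −log10 p > 6 plus allele-frequency, expression-ratio, or
  differential-expression evidence.

* **Synthetic data.**  A generator for the whole study design: an F12 AIL
  with Poisson crossovers and uniform breakpoints, traits drawn from the
  scan's own generative model (covariates + founder-allele QTL effects +
  polygenic term with allele-sharing covariance + residuals), and pooled
  allele/expression counts with Dirichlet RNA-mixture weights, negative-
  binomial depths and binomial allele sampling.  Every stage of the
  pipeline is therefore testable without external data.

## Worked example

`examples/` contains one short script per capability.  Running
`python examples/02_genome_scan.py` simulates 165 segregants on three 1-Mb
chromosomes, plants a QTL explaining 25% of the variance of an "arginine"
trait at chr2:500000 (NA allele up), and scans:

```
tested 300 markers in 165 segregants
peak: chr2.500000 (Wald=30.5, df=3, p=1.07e-06, q=0.000322)
  NA-allele effect deviation at peak: +0.78
6 merged QTL regions at q <= 0.5; the causal interval:
  QTL5: chr2:490000-530000, peak chr2.500000
```

The scan recovers the planted site exactly: the Wald statistic (30.5 on 3
df, one per non-reference founder allele) peaks at the causal marker, the
estimated NA-allele deviation is positive as planted, and the permissive
q ≤ 0.5 threshold also admits a handful of weaker regions — the intended
behaviour of a candidate-generating screen.  `examples/03_bsr_seq.py`
chains the same machinery into the pooled arm:

```
150 SNPs simulated, 150 pass the >=10-reads-in-every-pool filter
strongest SNP: chr2:500000 (HLA ref/alt 0/197, LLA 222/0, p=3.99e-125, q=1.43e-123, LLA-enriched for ref)
97 SNPs significant at FDR <= 0.001
```

The causal SNP (alt allele on the WE founder, which raises consumption) is
alt-fixed in the high pools and ref-fixed in the low pools, giving the
chromosome's minimum Fisher p.

A thin CLI mirrors the library (`mpqtl simulate | kinship | scan |
call-qtl | bsr | crossref | full`); `mpqtl full --config run.yaml` writes
scan TSVs, a region BED, the allele-frequency table, the candidate list, a
log and a config snapshot into a run directory.

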