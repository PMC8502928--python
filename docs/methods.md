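# Methods

## The scan

hapsweep detects recent positive selection on the human X chromosome from
phased haplotypes. The footprint it targets is extended haplotype
homozygosity (EHH): around a selected allele that has risen quickly in
frequency, chromosomes carry unusually long identical haplotypes. At a
core SNP, for a carrier class of n chromosomes,

    EHH(x) = Σ_h C(n_h, 2) / C(n, 2)

where the n_h count chromosomes falling in each distinct haplotype class
over the interval from the core out to distance x. Three statistics are
built on integrals of this decay curve:

* **iHS** = ln(iHH_A / iHH_D), where iHH integrates EHH against genetic
  distance (cM) separately for ancestral-allele (A) and derived-allele
  (D) carriers. Incomplete hard sweeps produce long derived haplotypes
  and large negative raw values.
* **nSL** is the same log-ratio with distance counted in segregating
  sites (one unit per SNP). It needs no genetic map, is robust to
  recombination-rate variation, and is more sensitive to soft sweeps.
* **iHH12** integrates EHH12, computed over *all* haplotypes with the
  two most frequent classes pooled: EHH12 = [C(n₁+n₂,2) + Σ_{h≥3}
  C(n_h,2)] / C(n,2). Pooling makes it sensitive to both hard and soft
  sweeps, where the sweeping material is split across two major
  haplotypes.

Raw scores depend strongly on derived allele frequency, so each
statistic is z-scored within equal-width DAF bins (default 100),
separately per population. The population-variance denominator (n) is
used: this is definitional z-scoring of the observed distribution, not
inference about a superpopulation.

Windowed **Tajima's D** (10-kb non-overlapping windows) complements the
haplotype statistics for old, completed sweeps: D = (π − S/a₁) /
√(e₁S + e₂S(S−1)) with the standard constants; undefined when S = 0.

## EHH numerical rules

* Extension stops when EHH falls below the truncation cutoff (default
  0.05). The trapezoidal integral runs down to the linearly interpolated
  crossing of the cutoff; area below the cutoff is excluded. Once EHH
  reaches exactly 0 the walk also stops (the curve is non-increasing, so
  no further area can accrue) — this matters only when the cutoff is 0.
* An inter-SNP gap larger than 20 kb before the cutoff is reached
  invalidates the core site (missing score, reason "gap") rather than
  truncating the integral: conservative, because a long gap hides an
  unknown amount of haplotype breakdown.
* Reaching the chromosome (or simulated-locus) end with EHH still above
  the cutoff is likewise a missing score (reason "edge"). On 600-kb
  simulated loci this removes a substantial fraction of cores — both the
  calibration and the scanned data pass through the identical rule, so
  thresholds remain comparable.
* Physical extension is capped at 1 Mb for iHS/iHH12 and 200 sites for
  nSL; hitting a cap truncates the integral without failing the site.
* Sites are scored only after a strict MAF > 0.05 filter; monomorphic
  columns (e.g. after subsetting one population) must be removed first.
* The walk itself tracks haplotype classes as compact integer labels
  refined one site at a time (counting sort, numba-compiled), and both
  the plain and top-2-pooled homozygosities come from one pass. The
  test suite holds this path to exact (1e-12) agreement with an
  exhaustive pair-enumeration oracle.

## Standardization and the reference model

`standardize` by default fits DAF-bin moments on the data being scored
(per-population self-standardization, appropriate for chromosome-scale
input). A fitted `StandardizationModel` can instead be supplied as a
frozen reference. The pipeline fits the reference on the pooled neutral
calibration batch and applies it to both the calibration windows and the
scanned data. On short simulated loci this is not optional: a 200-kb
swept region is a third of a 600-kb locus, its SNPs dominate their own
frequency bins, and self-standardization would subtract the sweep from
itself. The frozen neutral reference reproduces what chromosome-wide
normalization achieves on real data, where any single sweep is a
negligible fraction of the input. Bins with fewer than two reference
values (or zero variance) yield missing z-scores.

## Window calling and calibration

Per-SNP standardized scores are summarized in 20-kb windows sliding by
16 kb (20% overlap). Windows with 20 or fewer scored SNPs are removed.
The window mean uses |z| for iHS and nSL (two-sided statistics) and the
raw z for iHH12 (one-sided). A window is a candidate when its mean
strictly exceeds the 99th (respectively 99.9th) empirical percentile of
the same summary computed on neutral simulations, pooled over replicates
per population; percentiles use linear interpolation. No p-values are
attached to windows — the percentile is the evidence scale.

Per population, 99th-percentile candidate windows of the three
statistics are unioned and merged when overlapping by ≥ 1 bp (bookended
regions stay separate); regions overlapping across populations coalesce
into shared regions classified as unique (one population), continental
(several populations, one continental group) or cross-continental.

## The neutral model

Calibration uses a three-deme coalescent model of the X chromosome
(Sub-Saharan Africa, Europe, East Asia) derived from the Gravel autosomal
model with sizes scaled by the 3/4 factor of X-linked inheritance. All
parameters are stored in ms/msms units — sizes relative to N0 =
10,538.25, growth and migration per 4·N0 generations, event times in
4·N0 generations — and converted explicitly for the msprime backend:

| quantity | value | unit |
|---|---|---|
| sample sizes AFR/EUR/ASI | 152 / 153 / 149 | chromosomes |
| present sizes | 2.204 / 3.2542 / 7.4055 | ×N0 |
| growth | 0 / 56.61 / 96 | per 4N0 gen |
| migration AFR↔EUR, AFR↔ASI, EUR↔ASI | 0.3542 / 0.1462 / 1.3562 | ×4N0 |
| t = 0.0464: ASI joins EUR; EUR size → 0.2939·N0; AFR↔EUR migration → 4.9314 | | 4N0 gen |
| t = 0.14022: EUR joins AFR | | 4N0 gen |
| t = 0.364: AFR size → N0 | | 4N0 gen |
| locus | 600,000 | bp |
| μ = 1.25e-8, r = 1.3e-8 | | /bp/gen |

θ = 4·N0·μ·L = 316.1475 and ρ = 4·N0·r·L = 328.7934 are always derived,
never set. The msprime demography runs at ploidy 2 with haploid sample
sets, which reproduces the ms convention that two lineages coalesce in
2·N0 generations on average; an explicit unit-conversion layer holds the
mapping in one place. Mutations are infinite-sites binary; float
positions are floored to integer bp and rare duplicate positions dropped
(first kept). The single-deme constant-size reduction of the same engine
is held to Watterson's E[S] = θ·Σ 1/i within 3 SE and to the θ/i
unfolded SFS via a Hotelling T² test on per-replicate class counts —
per-replicate vectors are used because SFS classes within a replicate
share one genealogy and a pooled-count chi-square would see inflated
variance.

## Sweep injection

Power testing needs haplotype structure, not a selection simulation: one
donor haplotype's alleles within ±span of a core site are copied onto
randomly chosen recipients until the core derived frequency equals
round(f·n)/n (existing carriers are preferred, making small targets a
fixed point; surplus carriers are flipped to ancestral at the core
only). Recipients keep their own alleles outside the span, so EHH decays
at the natural background rate beyond the span edge. Detection in the
power tests means: any 99th-percentile candidate window overlapping the
injected span. The window containing the core itself is frequently
discarded by the >20-SNP rule — the injection pushes span SNPs to
extreme frequencies and out of the MAF band — while neighbouring span
windows carry z-scores far above threshold.

## Annotation fixtures and enrichment

The XCI-escape analysis tests whether genes escaping X inactivation are
over-represented among genes overlapped (≥ 1 bp) by candidate windows:
a 2×2 Fisher exact test of {escape, inactive} × {selected, not},
"variable"-status genes excluded by default. The Fisher p-value is
computed by exact integer hypergeometric enumeration (two-sided: sum of
probabilities ≤ the observed table's, ties compared exactly on integer
numerators, no floating-point fuzz). Zero cells give infinite/zero odds
ratios without continuity correction; a zero row/column margin leaves a
single admissible table, hence p = 1.

The fixture generator plants a known escape-selection odds ratio ω into
a 59 escape / 381 inactive gene universe (baseline selection probability
0.10 for inactive genes; escape odds multiplied by ω) and emits the gene
table, candidate regions covering exactly the selected genes, a
cell-line-specific enhancer table, and a per-SNP score/deleteriousness
table with planted extreme SNPs. Recovery tests hold the downstream
machinery to calibrated type-I error at ω = 1 and high power at ω = 5.

SNP prioritization keeps SNPs in the extreme 1% tail of a statistic
(|z| for iHS/nSL, z for iHH12, inclusive at the quantile) with a
PHRED-scaled deleteriousness score ≥ 10 (inclusive). Candidate windows
are partitioned genic / partial / intergenic by coverage of the merged
gene spans, with per-window genic/intergenic SNP counts. Functional
overlap reports the proportion of SNPs inside elements per context
against a background set, as odds ratios.

Consensus enhancers collapse cell-type-specific records that target the
same gene and whose intervals overlap or whose covered scan windows
(20-kb/16-kb grid, configurable) form a contiguous run, to (min start,
max end), cell lines unioned, database support maximized. The operation
is idempotent and per-gene outputs are disjoint. The enhancer–gene
association is a Pearson chi-squared without continuity correction on
enhancer-selected × target-gene-selected, with observed-vs-expected
cells, mean enhancer–gene distances per cell, and top hits restricted to
database support ≥ 3; an expected cell below 1 triggers a warning
recommending the exact test.

## Problem sizes and statistical tests in the suite

Desk-scale runs use reduced sizes, chosen once: calibration and power
use the African deme subsampled to 60 haplotypes with 30 calibration,
30 evaluation and 16 sweep replicates; the demo pipeline runs all three
demes at full chromosome counts with ~12+6 replicates; closed-form
simulator checks use n = 10, θ = 10, 2,000 replicates; enrichment
recovery uses 300 null and 200 alternative fixture seeds; the Fisher
oracle sweep enumerates every 2×2 table with grand total ≤ 60.

Candidate-rate calibration is asserted against binomial confidence
intervals at a cluster-corrected effective sample size: windows within a
replicate share one genealogy and all windows share an estimated
threshold, so flag counts are overdispersed relative to independent
draws (measured design effect ≈ 2–4). The design effect is estimated
from per-replicate counts and both the count and the sample size are
deflated by it before applying the exact binomial bounds.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the method assumes:
neutral haplotypes under the printed demography, polarized alleles, a
uniform recombination map, and sweeps as literal haplotype copies.
It does not emulate ascertainment bias, phasing or polarization error,
gaps and accessibility masks, recombination hotspots, background
selection, or the soft-sweep diversity of real adaptive processes.
Passing tests therefore demonstrate internal correctness and
calibration of the machinery — not field performance on cohort data,
where those nuisances dominate false-positive behaviour.

## Known limitations

* 600-kb simulated loci make edge failures common relative to a real
  chromosome; thresholds remain internally consistent because
  calibration and evaluation share the rule, but absolute missingness
  rates are higher than a chromosome-scale run would show.
* The sweep injector produces a single-donor (hard-sweep-like) pattern;
  it can under-represent the iHS signal of very soft sweeps.
* Standardization bins at extreme DAF can be sparse in small samples;
  affected SNPs are reported missing rather than poorly scaled.
* The chi-squared association is asymptotic; small fixtures trigger the
  exact-test warning by design.
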