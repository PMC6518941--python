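# Methods

This note documents the models and procedures implemented in fjordflow,
the defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the numerical choices a user should know about
before trusting or changing a result.

## Genotype filtering

Genotype-level masking always precedes site-level filters, so site
summaries (missingness, allele counts, heterozygote excess, mean depth)
are computed on surviving calls only. Thresholds are strict in the
directions stated: a genotype needs DP > 3 and GQ > 20; with the optional
landscape masking `mask_dp_below=7`, a DP = 7 call survives. A site is
kept iff missingness < 0.20, minor-allele count > 2, MAF > 0.03 (called
genotypes only), one-sided heterozygote-excess exact p ≥ 0.001 and mean
DP < 30. The heterozygote test uses the Levene conditional distribution
of heterozygote counts given allele counts, restricted to the excess
direction — a deficit never removes a site. LD pruning is greedy and
left-to-right within sliding 10-kb physical windows (drop the later site
of any pair with r² > 0.8), which makes the operation idempotent. The
exact rule ordering used by any particular external toolchain is not
asserted; this package's ordering is fixed and documented here.
Caller-level annotation filters (FS, MQRankSum, QD, ...) belong to variant
calling and are out of scope.

## Windowed scan statistics

Windows tile each chromosome as nonoverlapping [0, w), [w, 2w), ... with
the final partial window kept and flagged. Per window:

* **FST** — Weir–Cockerham (1984) two-population diploid variance
  components a (among populations), b (among individuals within) and c
  (within individuals, from observed heterozygosity), combined as the
  ratio of sums Σa / Σ(a+b+c). Ratio-of-sums is less biased than
  averaging per-site ratios and is the standard windowed form. Negative
  window values are retained, not clamped, so genome-wide summaries stay
  unbiased.
* **dxy** = Σ_sites [p_A(1−p_B) + p_B(1−p_A)] / L with L the window
  length in bp — unreported sites are assumed invariant. **π** likewise
  per bp, with the n/(n−1) small-sample factor at each site.
* **df** divides the count of fixed differences (|p_A − p_B| = 1) by the
  number of *variant* sites used in the window, because a per-bp "
  proportion" would not be a proportion. Users wanting a per-bp rate can
  divide by window length themselves.
* **r²** is the mean squared Pearson correlation of genotype dosages over
  SNP pairs, pairwise-complete over missing calls; large windows subsample
  pairs (cap 2000) with a fixed seed.

A site enters a between-population statistic only with ≥ 4 called
chromosomes in each population — a tolerance choice to keep frequency
estimates meaningful. On Balding–Nichols simulations the genome-wide
estimator recovers the generating F within Monte-Carlo error for
F ∈ {0.02, 0.05, 0.1} (calibration test in the suite).

## Inversion karyotyping

Region-restricted PCA uses the smartPCA normalisation: dosages are
mean-centred per SNP and scaled by √(p(1−p)) with the shrunk frequency
p = (1+Σg)/(2+2n); missing dosages are imputed to the column mean before
scaling. Karyotype states are called by 1-D k-means on PC1 with k chosen
from {1, 2, 3} by silhouette; k = 1 is selected when the best silhouette
over k ∈ {2, 3} falls below 0.7, a floor chosen because k-means attains
silhouettes around 0.6 on *unstructured* one-dimensional scores, whereas
genuine arrangement clusters score well above 0.8. With k = 3 the middle
cluster is heterozygous; a sanity check requires the het cluster to have
the highest mean observed heterozygosity across region SNPs, otherwise
all calls are flagged low-confidence.

Which homozygote cluster is *ancestral* is not identifiable from the
genotype matrix alone — the two arrangements enter symmetrically. The
package follows the convention that the ancestral arrangement is the more
common one (the larger homozygote cluster is labelled anc, ties to the
lower-PC1 cluster). This matches the usual situation in which inverted
arrangements segregate at minority frequency, but it will mislabel a
sample where the inverted arrangement is locally in the majority; in that
case orient the calls with reference individuals of known karyotype.

Arrangement frequencies are counted at chromosome level (2 per diploid,
het contributing one of each), because the over-representation test is
about arrangement frequency, not genotype frequency. The bootstrap test
draws, per population × region × arrangement, B replicates of
Binomial(2n_pop, q_pooled) under the null that the population's
arrangement frequency equals the pooled frequency across all supplied
populations; the one-sided p is (1 + #{replicate ≥ observed}) / (B + 1),
never exactly zero. The Bonferroni family is all tests performed in the
invocation (population-region-arrangement triples); B defaults to 10⁶ and
values below 10³ are rejected as unstable. Being a one-sided test on a
binomial lattice, its realized level sits slightly below nominal
(≈ 4.7 % at a few hundred chromosomes for α = 0.05); the calibration test
measures this under conditions where the pooled frequency is effectively
external (a 150-fish population inside a 10,000-fish pool).

The Hardy–Weinberg test is the two-sided exact test: sum the Levene
conditional probabilities of all heterozygote counts at most as probable
as the observed one. The combination census enumerates the 3³ = 27 state
triples across three regions; the coverage probability — the chance that
an iid sample of N individuals contains all 27 — is estimated by Monte
Carlo with the triple probability taken as the product of per-region
genotype frequencies (regions segregate independently), returning exact 0
for N < 27 or any zero-frequency genotype.

Whole-genome genotype-class assignment (e.g. fjord-type vs North-Sea-type
within one sampling site) takes PC1–PC2 scores computed on
inversion-free chromosomes, forms class centroids from reference-labelled
individuals, and assigns an individual to its nearest centroid only when
that distance is < τ (default 0.5) times the distance to the second
nearest — otherwise "intermediate", mirroring how admixed individuals are
excluded from genotype-class models.

## Telemetry metrics

Timestamps are UTC internally; calendar days and months are bucketed in a
configurable local zone (default Europe/Oslo). Day/night is classified by
solar elevation (> 0 = day) from the standard NOAA solar-position
formulas — accurate to a few minutes at sunrise/sunset, and degrading
gracefully into polar day or night.

* **False detections**: any fish-day with fewer than two detections is
  dropped — isolated hits are the signature of code collisions.
* **Post-mortem truncation**: scanning a fish's depth series, the record
  is cut at the earliest time t* after which every trailing 24-h window
  has depth SD below 0.5 m through the end; such fish are candidate dead.
  A transmitter lying on the seabed produces exactly this signature.
* **COA**: per 30-min bin, the detection-weighted mean of detecting
  receiver positions and depths. Note COAs are biased toward the array
  interior when the fish is at the edge, because all detecting receivers
  lie inward of it — this matters for dispersal calls (below).
* **DVM** per fish-month: the mean over days of (day mean depth − night
  mean depth); positive = deeper by day. Days lacking either phase are
  skipped. Computed from COA-binned depths.
* **Daytime depth** per fish-month: the mean over days of daily daytime
  mean depths — days weighted equally regardless of detection count.
* **Home range** per fish-month (needs ≥ 20 distinct days of presence and
  ≥ 30 COAs): COAs are projected to local planar metres
  (equirectangular about the array centroid), a 2-D Gaussian KDE with
  per-axis normal-reference bandwidth h = σ·n^(−1/6) is evaluated on a
  256×256 grid padded by 3 bandwidths, and the area is that of the
  highest-density cells accumulating 95 % of the mass. For bivariate
  normal positions this converges to π·χ²₂(0.95)·σ² and the suite checks
  it within 15 %.
* **Fate**: dead if the truncation rule fired, or if transmissions ceased
  more than 7 days before battery end while the track ended interior;
  dispersed if the track ends at its outermost COA (within 10 % of the
  array radius), shows a clear outward run over its final day, its last
  detections come from a top-quintile-radius receiver, and silence
  follows. Otherwise alive. The published study classified fates by
  visual inspection; these rules are a reproducible stand-in validated on
  generator truth (fate accuracy ≈ 96 % across seeded cohorts, death day
  within ±0.2 days). Days survived run from tagging to last valid
  detection, or to battery end for alive fish (a configurable choice —
  study end would be the alternative).
* **Relative longevity** S = days survived / mean days survived over
  non-dispersed fish, so mean(S) = 1 exactly; dispersed fish are excluded
  because their fate is unobserved.

## Behaviour and fitness models

Behavioural traits (log home range — natural log, taken before fitting —
mean daytime depth, DVM) are modelled with Gaussian linear mixed models
carrying a fish-ID random intercept. All fits for model comparison use
maximum likelihood, not REML, so AICs are comparable across fixed-effect
structures; AIC = −2ℓ + 2k with k counting fixed effects plus the two
variance parameters. Model selection follows a two-step ladder: first the
body-size/sex structure is chosen with all inversion terms of interest
retained, then the inversion structure; ties go to fewer parameters.
Factors use treatment contrasts with ancestral arrangement, female sex
and feeding season coded zero; the spawning season is January–April.

Variance partitions report ICC = σ²_id/(σ²_id + σ²_res) and a marginal R²
equal to the variance of the fixed-effect predictions over the total
model variance (fixed + random-intercept + residual), the Nakagawa-style
quantity. Published "variance explained" percentages are treated as this
marginal R² — a documented interpretation, not an asserted equivalence.

Fitness is modelled with the Lande–Arnold approach: an OLS regression of
relative longevity on inversion states (or genotype class), body length
and sex. Coefficients are selection differentials on the fitted scale;
multiple R² is reported. Quadratic (stabilising/disruptive) gradients are
out of scope.

## Synthetic-data generators

The generators define the conditions under which the package's claims are
tested; they are first-class, tested code.

**Genotypes.** Ancestral allele frequencies are Uniform(0.05, 0.95); each
population draws its frequency from Beta(p(1−F)/F, (1−p)(1−F)/F)
(Balding–Nichols), degenerating to p exactly at F = 0; genotypes are
Binomial(2, p_pop). An inversion is one non-recombining bi-allelic
arrangement locus: each individual draws two arrangement labels at its
population's inverted-arrangement frequency, and each label indexes its
own haplotype-pool allele frequencies whose mean absolute difference is
the configured pool divergence (realised exactly for divergence ≤ 0.45 by
shifting toward the freer side of the unit interval). This reproduces the
three-cluster PCA signature and elevated region LD without simulating
recombination maps; it does not produce the within-arrangement LD decay,
breakpoint effects or mutation-age structure of real inversions. Mean
read depth is Poisson around 9.84 per genotype, matching a low-coverage
resequencing panel; genotypes are masked missing at the configured rate,
independently of depth.

**Telemetry.** Thirty-three receivers on a regular grid over a 3 km × 1 km
rectangle (the real array geometry is not machine-readable; the geometry
is schematic by design). Fish positions follow a reflected random walk
(step SD 25 m per transmission); transmissions occur every 110–250 s;
each receiver detects a transmission with probability exp(−d/ρ), ρ = 400 m
— any monotone decay suffices for the metrics tested. Depth is mean +
diel sinusoid + mean-reverting (OU) noise. The `diel_amplitude_m`
parameter is the *expected day-minus-night contrast at equinox*: the
sinusoid is scaled by π/2 so that the parameter equals the DVM a
downstream analysis should recover (within ~5 % across the year as day
length varies). Dying fish transmit their last depth, exactly constant,
from a uniform death day; dispersing fish swim at 0.15 m/s straight to
the outermost receiver and fall silent on arrival. Not emulated: tides,
temperature-driven detection-range variation, receiver outages, depth
sensor quantisation — so passing tests demonstrate the estimators, not
robustness to every field artefact.

**Trait tables.** Monthly trait rows are generated exactly under the
mixed model: response = Xβ + fish intercept + noise, with covariates
drawn per fish (inversion states at Hardy–Weinberg with inverted
frequencies 0.3/0.2/0.3 for LG02/LG07/LG12, body length ~ Normal(46, 10)
clipped to 30–75 cm, sex and genotype class balanced). Covariate draws
are rejection-sampled until every modelled factor level is observed, so
the design is always identifiable — a conditioning that leaves coefficient
recovery unbiased. The recovery studies use the published point estimates
as generating values: the depth study sets the fjord-type effect to
+3.67 m with total variance 25 m² split to ICC 0.23; the home-range study
uses the published eight-coefficient model with total variance 0.8 and
ICC 0.25 (log-scale SD ≈ 0.9); the longevity study uses the published
survival coefficients with residual SD 0.40, which together with an LG12
inverted-arrangement frequency of 0.30 reproduces the published
standard-error magnitudes at 64 fish.

## Numerical choices and degenerate inputs

* Seeds: every stochastic routine takes an explicit seed and is
  bit-reproducible; replicate seeds are derived linearly and kept below
  2³¹.
* Missing statistics are NaN, never 0 (e.g. a window with no usable FST
  site).
* Degenerate inputs raise with a named cause: zero-variance PCA regions,
  zero receivers, all-dispersed cohorts, unobserved factor levels,
  non-positive variance components, B < 1000 bootstrap replicates.
* MixedLM fits fall back from the default optimizer to Powell on
  singular-Hessian failures; a near-zero among-fish variance is reported
  via a `singular` flag rather than silenced.
* The pipeline caches stages on a content hash of parameters and input
  names; deleting an artefact regenerates it and its downstream stages
  only. No stage mutates its inputs.

## Problem sizes

The test suite and the acceptance script run simulations at desk scale,
chosen to hold Monte-Carlo error well below the assertion tolerances: 200
replicates for each parameter-recovery study (MC SE 0.01–0.06 on the
recovered coefficients), 2,000 tables for the bootstrap calibration,
4–5,000 SNPs for FST calibration, and cohorts of 8–12 fish over 40–70
days for telemetry truth checks. Larger panels change nothing but the
error bars.

## Known limitations

* The windowed scan assumes unreported sites are invariant; applying it
  to a variants-only VCF from a restricted callable region will deflate
  dxy and π.
* Karyotype orientation relies on the majority convention (above).
* The fate classifier's thresholds (0.5 m / 24 h depth-variance rule,
  7-day silence, outward-run geometry) were validated on the generator,
  not on field data; real arrays with irregular geometry may need the
  quantile parameters adjusted.
* The bootstrap over-representation test is conservative at small
  chromosome counts, as any one-sided lattice test is.
* `assign_genotype_class` assumes the reference classes are separable on
  PC1–PC2; with more than ~4 classes or curved clusters a mixture model
  would be preferable.
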