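# Methods

## The statistical model

dmrank tests for differentially methylated regions (DMRs) between groups
of methylation-array samples. The input is a probe × sample matrix of
beta values (methylation fractions in [0, 1]) with genomic coordinates
per probe, and a grouping of samples. Testing proceeds in three stages.

**1. Directional per-probe rank tests.** For every unordered pair of
sample groups and every probe, two one-sided Mann–Whitney U tests are
performed: one for higher methylation in the first group, one for higher
methylation in the second. Keeping both one-sided p-values (rather than
a single two-sided one) lets each direction be combined separately
across a region, so a region's call carries its direction. Rank tests
need no normality assumption and are invariant to monotone transforms,
so testing on beta values and on M-values gives identical p-values;
betas are used, and M-values enter only through the optional
`beta_to_m` convenience (logit2 with clamping at `eps = 1e-6`).

When the pooled sample size is at most 16 and the probe's values are
tie-free, the exact permutation null of U is used (p = the fraction of
the C(n_a+n_b, n_a) group labelings with U at least as large as
observed). Otherwise the normal approximation with tie-corrected
variance and a 0.5 continuity correction applies. The switch point is an
implementation choice — exactness where it is cheap, the standard
approximation elsewhere. A degenerate probe (all pooled values
identical) gets p = 1 in both directions. p-values are floored at the
smallest positive double so downstream z-transforms stay finite.

**2. Spatially correlated combination per region.** Probe p-values are
mapped onto fixed, user-supplied or generated regions (half-open
intervals; a probe at position p belongs to [s, e) iff s ≤ p < e;
overlapping regions share probes). Neighbouring probes are correlated,
so the Stouffer–Liptak combination is used with a covariance estimated
from the data: z_i = Φ⁻¹(1 − p_i), C = Σ z_i / √(Σ_ij σ_ij), combined
p = 1 − Φ(C). The σ_ij come from the autocorrelation function (ACF) of
the genome-wide z-scores of the same pair and direction being combined,
binned by genomic distance. Default bins: (0,1], (1,51], (51,101],
(101,201], (201,501], (501,1001] bp; distances beyond 1001 bp are
treated as uncorrelated. Per bin, the Pearson correlation over all
intra-chromosomal probe pairs in that distance range is used; bins with
fewer than 30 pairs or zero variance contribute 0, and negative
estimates are truncated at 0 so that the effective test count never
drops below independence (a conservative floor). The ACF is estimated
genome-wide (not per chromosome); both the bins and this choice are
configurable, since no convention is canonical.

Inputs to Φ⁻¹ are clamped to [1e-16, 1 − 1e-16]. If a region's
covariance sum is not positive the combination falls back to the
independence denominator √k.

**3. Sidak correction and filtering.** A 1-step Sidak correction turns
each combined p into a family-wise q-value: q = 1 − (1 − p)^m with
m = max(1, ⌊total tested span / region span⌋) — the number of regions
of this size that would fit into the tested genome. This length-based m
follows the convention of span-sized correction for region testing; a
count-based alternative (m = number of tested regions) is available via
`sidak_by_count`. The evaluation uses expm1/log1p for stability at
small p, and q ≥ p is enforced. A region is called when its smaller
directional q is ≤ `q_cutoff` and |median change| ≥
`min_abs_median_change` (the conventional effect filter is 0.05, i.e. a
5 % methylation difference). Per probe the change is the difference of
group median betas, second group of the pair minus first (pairs ordered
lexicographically); the region reports the min/median/max over its
probes. Output ordering is ascending q with (chrom, start) tie-break.

## Gene set enrichment

Regions carrying a `gene_name` are collapsed to one score per gene: the
region with the smallest q wins (ties: larger |median change|, then
region name), and the default score is sign(change_median) × (−log10 q)
(`metric="signed_change"` uses the raw change instead — the ranking
metric is genuinely open, so both are exposed). Genes are sorted by
descending score with alphabetical tie-break, giving a deterministic
pre-ranked list in which hypermethylation in the second group sits at
the top.

The enrichment score is the classic weighted Kolmogorov–Smirnov running
sum: a hit at rank i adds |score_i|^w / Σ_hits |score|^w, a miss
subtracts 1/(N − N_hit); ES is the signed maximum deviation, w defaults
to 1 (0 and 2 supported; w = 0 is the unweighted KS statistic). If all
hit weights are zero the hit steps fall back to 1/N_hit. Significance
uses a gene-label permutation null: n_perm (default 1000) random
same-size subsets of the ranked universe, p = (1 + #{|ES_null| ≥
|ES_obs|}) / (n_perm + 1). A phenotype-permutation null would require
rerunning the whole region pipeline per shuffle; the gene-label null is
the standard pre-ranked compromise and is documented as such. The
leading edge is the set members at ranks ≤ peak for positive ES and
ranks > peak for negative ES; sets with p_perm ≤ 0.05 (configurable)
enter a Jaccard overlap matrix. No normalized ES or cross-set FDR is
computed by default; Benjamini–Hochberg across sets can be applied
downstream.

## Region generation

Tilings partition each chromosome into fixed half-open windows with the
final partial window kept, so the tiled bases always sum to the genome
length. Promoter regions are `span_bp` windows (default 2000) anchored
at each gene's TSS from a GTF: `downstream` covers the span starting at
the TSS base in the direction of transcription ([TSS, TSS+span) on plus
strands, [end−span, end) on minus strands), `upstream` the mirrored
window excluding the TSS. Both orientations exist because annotation
practice uses either; the default is downstream. Exon regions come from
the same reader with identical intervals deduplicated across
transcripts.

## Quality control and normalization

The detection-p filter is two-step: (1) samples whose fraction of
failed probes (detection p > `probe_p_cutoff`, default 0.01) exceeds
`sample_fail_fraction` (default 0.1) are dropped; (2) among surviving
samples, any probe that failed in any sample is dropped. The
"any failing sample" rule for probes (rather than a per-probe failure
fraction) is a deliberate strict contract and is stated here because
conventions differ. Missing beta values are rejected at load time —
rank tests and median summaries assume complete columns, and failing
loudly beats silent imputation. The optional cross-sample quantile
normalization replaces each sample's sorted values by the across-sample
mean of sorted values (ties receive the mean of the reference values
they span) and re-clamps to [0, 1]; it is a convenience, not a
replacement for array-specific normalization performed upstream.

## The synthetic-data generator

`simulate_dataset` emulates the statistical structure the pipeline
assumes, at desk scale. Defaults: 2000 probes on 2 chromosomes, probe
spacing 20 bp + Exponential(mean 380 bp), two groups ("case",
"control") of 8 samples, a 50/50 mixture of Beta(2,10) (unmethylated)
and Beta(10,2) (methylated) baseline modes, a probe-level random effect
with sd 0.05 shared across samples and exponential-decay spatial
correlation of length 500 bp (an Ornstein–Uhlenbeck walk along each
chromosome, which yields exactly exp(−d/L) autocorrelation), i.i.d.
Gaussian noise with sd 0.05 per sample, and truncation to [0, 1].
Spiked regions add `delta_beta` to the affected group's betas for all
member probes; `spiked_config` plants 10 five-probe regions of
delta 0.25 spread over the genome. Inside a spiked region the baseline
is drawn from the mode compatible with the delta's sign
(hypermethylation starts from the unmethylated mode and vice versa) —
without this, truncation at the [0, 1] boundary shrinks the realized
delta well below its nominal value. Residual truncation bias from the
noise term remains and is small (the realized mean within-region
group-median difference is 0.25 ± 0.01 over seeds). Detection p-values
are ~Uniform(0, 1e-3) with a configurable failure rate drawn from
Uniform(0.05, 1).

The generator is beta-scale, so deltas read directly as methylation-
fraction changes. What it does **not** emulate: Infinium type-I/type-II
probe chemistry, dye bias, batch effects, cell-type composition, copy-
number artifacts, or heavy-tailed per-sample outliers. Passing tests on
this generator therefore demonstrate the statistical machinery (type-I
error control, power at a 25 % methylation shift, direction calling) —
not robustness to array-specific technical artifacts, which upstream
normalization must handle.

## Numerical and output conventions

All coordinates are 0-based half-open; probe positions are width-1
points. Group pairs are ordered lexicographically; change = second −
first, and both directional p/q are always reported so no orientation
information is lost. BED tracks encode q as score = min(1000,
round(−10 log10 q)) with strand '+' when the second group of the pair
is higher; the per-probe significance track colors probes on a
blue→red ramp over −log10 of the probe-count-Sidak-corrected smaller
directional p, saturating at 1e-5. Pipeline outputs are deterministic:
a rerun with the same inputs and seed is byte-identical.

Problem sizes in the test suite and acceptance script follow the
desk-scale study conditions: 2000 probes and 8 vs 8 samples per
simulation, 20 seeds for the null type-I error check, 10 spiked regions
at delta 0.25 for the recovery check, 200 random draws for the
rank-test enumeration check, and 100 random instances for the
enrichment-score cross-check.

## Known limitations

- Fixed regions only: there is no de-novo region growing or
  peak-finding; region boundaries must come from tilings, annotation or
  the user.
- The ACF is pooled genome-wide; arrays with strongly
  chromosome-specific correlation structure would violate this.
- The length-based Sidak m is an interpretive choice; with highly
  variable region sizes the count-based flag may be preferable.
- The permutation null for enrichment permutes gene labels, not
  phenotypes, so it conditions on the observed ranking.
- Sample covariates (age, sex, batch) are not modeled; the rank test
  compares groups marginally.
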