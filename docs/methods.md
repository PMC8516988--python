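# Methods

## Scope and data model

`m6array` analyses two-color MeRIP (methylated-RNA immunoprecipitation)
microarrays. Each array measures, per probe, a Cy5 intensity for the
immunoprecipitated (IP, methylated) RNA fraction and a Cy3 intensity for the
supernatant (Sup, unmethylated) fraction, plus a Present/Marginal/Absent
(P/M/A) QC flag. Samples belong to a patient group (T) or a control group
(N). Three derived quantities drive everything downstream, all computed on
spike-in-normalized intensities:

* **m6A methylation level** (% Modified): `IP / (IP + Sup)`, a within-sample
  ratio in [0, 1];
* **m6A quantity**: the linear-scale normalized IP intensity, an absolute
  measure of methylated transcript;
* **RNA expression level**: the linear-scale total `IP + Sup`.

The elementwise identity `expression x meth_level = m6a_quantity` is
maintained exactly through every normalization step (see below).

## Normalization

**Spike-in scaling.** For each sample and channel, log2 intensities are
shifted by the mean log2 intensity of the spike-in control probes in that
sample/channel — equivalently, linear intensities are divided by the
spike-ins' geometric mean. This removes per-array, per-channel scale (dye)
effects: a multiplicative bias applied uniformly to all probes of a channel,
spike-ins included, cancels exactly, and the methylation level becomes
invariant to such biases (tested). By default each channel is normalized
against its own spike-in mean; a shared IP+Sup spike-in mean is available via
`shared_spike_mean=True` for designs where the spike-in mix is not balanced
between channels.

**Quantile normalization.** Between-sample quantile normalization
(sorted-mean substitution: every sample's value distribution is replaced by
the mean of the sorted per-sample vectors, values assigned by rank) is
applied to the linear expression (IP+Sup) matrix over all non-spike-in
probes, before the QC flag screen. Ties receive the average rank and are
linearly interpolated into the reference; this matches
`limma::normalizeQuantiles`, against which the implementation was verified on
tie-containing fixtures. Two numerical caveats are deliberate:

* With within-column ties the operation is *not* exactly idempotent and the
  columns do not share a literal sorted multiset — tie-averaging inserts
  values between reference quantiles. On continuous intensity data ties do
  not occur and both properties hold to machine precision (property-tested on
  tie-free matrices).
* The per-(probe, sample) rescaling implied by quantile normalization is
  treated as a total-abundance adjustment: the same factor is applied to the
  m6A quantity, so the `expression x level = quantity` identity is preserved,
  while the methylation level — a within-sample ratio — is untouched.
* Quantile normalization assumes most probes are unchanged between samples.
  When a large fraction of probes carries true group differences it
  compresses fold changes toward zero (visible in simulations with 20%
  planted effects, where a −3 log2 shift reads back around −2.5 to −2.9).
  `quantify(..., quantile_norm=False)` disables the step; the noiseless
  closed-form recovery of planted effects is exact in that mode.

**QC flag screen.** A probe is kept when it is flagged P or M in at least
`min_present` samples (default 1), both groups pooled, generalizing the
"at least 1 in 10 samples" rule to whatever number of samples is loaded.
Filtering happens after quantile normalization so the reference distribution
reflects the whole array. Totals below the floor `2^-20` on the linear scale
are marked missing (NaN), never zero, and excluded pairwise downstream.

## Differential analysis

Per probe, fold changes are T relative to N: the linear ratio of group-mean
methylation levels, and the difference of group means of log2 quantity and
log2 expression (negative log2 FC = lower in patients). P-values come from
two-sided unpaired t-tests — pooled-variance Student by default, Welch
selectable — applied to the methylation level, log2 quantity and log2
expression respectively. Degenerate zero-variance inputs take documented
limits (equal constant groups p = 1, unequal p = 0). Raw p-values are
reported; Benjamini–Hochberg q-values are an optional extra column, never a
filter.

Regulation classes combine two independently assessed axes. The methylation
axis calls Hypo/Hyper from the m6A-quantity contrast by default
(`fc_basis="meth_level"` switches to the methylation-ratio contrast with
configurable ratio bounds); the expression axis calls up/down from the
expression contrast. Both axes must individually pass `alpha` (default 0.05)
with a fold change beyond `fc_log2_min` (default 0, i.e. sign-only) for a
combined label (Hypo-down, Hypo-up, Hyper-down, Hyper-up); everything else is
`ns`. Defaults are sign-only because published array studies of this design
report p < 0.05 as the significance rule without printed fold-change cutoffs;
both knobs are exposed.

Top tables are stable sorts (ties broken by probe id) within a regulation
subset — e.g. the top-20 hypo-methylated mRNAs by ascending log2 m6A fold
change. Sample clustering is agglomerative (average linkage, Euclidean) on
the methylation-level matrix, with rows pre-sorted by label so distance ties
break by item id and the tree is input-order invariant; output is a Newick
tree plus the leaf order.

## Association and enrichment statistics

Pearson correlation reports the sample r with a two-sided p from the exact
t-transform `t = r sqrt((n-2)/(1-r^2))` on n−2 df — appropriate at the n ≈ 20
scale of regulator-vs-methylation comparisons and cross-checked against
`scipy.stats.pearsonr`. Cohort tables can be re-tested from printed summaries
alone: a pooled-variance t-test from (mean, SD, n) pairs, and a 1-df Pearson
chi-square (optional Yates correction, off by default) for 2x2 categorical
contrasts such as sex ratios; the summary t-test is constructively verified
to equal the raw-data test on vectors with matching moments.

Over-representation of a hit list against GMT gene sets uses the one-sided
hypergeometric upper tail (identical to one-sided Fisher exact), after
intersecting each set with the background; the enrichment score is
`-log10(p)`. The recommended background is the set of unique gene symbols
measurable on the array after the flag screen — the measurable universe —
and the pipeline uses exactly that. No graph-aware GO decorrelation is
attempted; terms are treated as flat sets.

## Synthetic arrays and what they do (not) show

The generator emulates an 8 x 60 K-style two-color epitranscriptomic array at
toy scale. Per probe: a lognormal total abundance (log2 mean 10, SD 2), a
baseline methylation level uniform on [0.2, 0.8] (keeping % Modified away
from boundary saturation), iid Gaussian log2 noise per channel (default SD
0.5), spike-ins at a fixed nominal level in both channels, and per-cell
absent-flag probability 0.05 (present calls split 90% P / 10% M). Planted
effects act only in group T: a log2 shift on the IP channel of
`round(frac_diff_meth x n_probes)` seeded-sampled probes (default −3), and a
log2 shift on both channels of an independently sampled expression set
(default −1). Default group sizes are 5 + 5 arrays, matching the two-group
design the pipeline targets; noise magnitudes are the package's choice of a
realistic regime, since no empirical noise model accompanies such arrays.
Optional per-sample per-channel dye effects (off by default) exist solely to
demonstrate that spike-in normalization removes them.

Because noise is Gaussian on the log2 scale and probes are independent, the
t-test is exactly calibrated here; passing the type-I and power suites shows
the pipeline arithmetic is right, not that real arrays meet those
assumptions. The generator has no probe-sequence effects, no spatial
artifacts, no correlated probes, and no background signal — conclusions
about such artifacts are out of reach of these tests.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale, chosen so the full suite
completes in seconds while keeping binomial error bands tight: null
calibration on 2000 probes x (5+5) (99% band around the nominal 0.05 is
±0.0126), power curves at 400 probes x {3,5} per group x three effect sizes,
planted-recovery runs at 600 probes, and the end-to-end pipeline at 150–400
probes. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical config + seed reproduce every output
byte-for-byte, and the run manifest records config, seed and version (no
timestamps) to keep reruns comparable.

## Known limitations

* The tab-delimited input dialect is this package's own (documented in
  `m6array.io`); vendor feature-extraction exports must be mapped to it.
* Quantile normalization's fold-change compression under many-changed-probes
  conditions is inherent to the method, not corrected for.
* No background subtraction, within-array loess, or moderated
  (empirical-Bayes) test statistics — the design targets plain unpaired
  t-tests on normalized intensities.
* Genomic loci are carried as annotation only and never enter computation.
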