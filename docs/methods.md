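# Methods

This note documents the models, defaults and design decisions behind
`nucleoamp`, in the order data flow through the package.

## Synthetic cfDNA generative model

The simulator (`nucleoamp.simulate`) stands in for plasma WGS and
amplicon sequencing data. It emulates the features of real cfDNA that
the downstream statistics depend on, and nothing more.

**Nucleosome landscape.** Dyads are laid along a single synthetic contig
at a mean spacing of 190 bp (typical nucleosome repeat length) with
Gaussian jitter (sd 20 bp by default). Each dyad carries an *occupancy
weight* in [0.1, 0.9] (fraction of cells with a nucleosome at that
position) and a *positional sd* in [5, 25] bp (cell-to-cell spread of
the dyad position). Both are drawn uniformly; real chromatin has
correlated, sequence-driven structure that this deliberately ignores.

**Fragments.** Each fragment is mononucleosomal with probability 0.85,
otherwise dinucleosomal — the canonical plasma proportions. Mono
fragments center on one dyad chosen proportionally to occupancy, with
the center jittered by that dyad's positional sd; di fragments center
between two adjacent dyads. Lengths are discretized normals truncated
at 1 bp: mode 167 bp (sd 20) and 350 bp (sd 35). Only the modes are
well established; the sds are package defaults chosen to give the
familiar sharp mono peak and broad di shoulder. The known shortening of
tumor-derived fragments is exposed as `tumor_mode_shift` (bp subtracted
from the mono mode), off by default. Fragments extending past the
contig are discarded rather than clipped, so lengths are never
distorted.

**Amplicon panels.** Amplicon outer coordinates (including primers) are
placed uniformly; lengths are uniform on 100–200 bp; GC fractions are
uniform on [0.25, 0.75] and independent of length and position, so any
length–GC confounding in results is genuine, not generative. Primer
lengths are uniform on 18–27 bp.

**Count matrices.** The expected count of amplicon *i* is

    E[count_i] = baseline · g(gc_i) · A(len_i)

with baseline 2000 reads, `g` a quadratic in GC (default coefficients
(−6, 6, −0.5), peaking at 1.0 for 50 % GC, floored at 0.05) and `A` the
*template-availability factor*

    A(len) = min(1, S(len) / S(mono_mode)),   S(x) = P(L ≥ x)

under the mono/di length mixture. The saturation below the mono mode
encodes that PCR is not template-limited while amplicons are shorter
than the typical fragment; availability only starts to bite once the
amplicon outgrows the ~167 bp mode, which is what produces the
flat-then-shock length–coverage relationship. Availability is a
function of amplicon length only; the landscape influences counts
through the variability channel instead. Per-sample counts multiply the
expectation by mean-one log-normal noise `exp(s_i·z − s_i²/2)` with

    s_i = occupancy_noise_sd · ((1 − stability_i) + 1.0 · |gc_i − 0.5|)

where `stability_i` is the mean occupancy weight of dyads whose
protected interval (±73 bp, one nucleosome half-width) overlaps the
amplicon. Inter-sample coverage variability is thus driven primarily by
nucleosome-occupancy instability, with a weaker contribution from
extreme GC; `occupancy_noise_sd` defaults to 0.5, giving realized CVs
mostly in the 5–50 % range at 10 samples. Counts are real-valued
expectations times noise (no Poisson re-sampling), so switching the
noise off yields exactly identical samples, which the tests exploit.
The simulator emits the generative truth (availability, stability,
noise scale, analytic CV) for recovery tests; it does not emulate
base-level sequencing error, mappability, multi-contig genomes or tumor
clonal structure, so passing tests demonstrate correct *inference
machinery*, not performance on real plasma data.

## Fragmentation maps

Coordinates are 0-based half-open everywhere (BED conventions on disk).
The processing chain is fixed: read pairs → outer-span fragments →
length filter → dyad trim → per-base overlap counts → square-pulse
smoothing.

* **Length filter**: inclusive 80–250 bp, retaining the mononucleosome
  population and excluding dinucleosome fragments.
* **Dyad trim**: each fragment is replaced by the 40 bp window centered
  on its midpoint (`floor((start+end)/2)`, a deterministic tie-break
  for even lengths). This reading — the central 40 bp window, i.e.
  dyad ± 20 — is chosen because it yields a set of equal-length
  fragments; trimming 40 bp off each end would not. Fragments shorter
  than the window are a hard error listing offenders.
* **Smoothing**: centered moving average of width 21 bp (odd widths
  only). Edges use the truncated window renormalized by its actual
  size rather than zero-padding, so coverage is not artificially
  depressed where amplicons sit near region boundaries. The filter is
  linear and conserves interior window means; it is not idempotent.
* **Peak calling**: dyad positions are binned per base and smoothed
  with a Gaussian kernel (default bandwidth 30 bp); peaks are strict
  local maxima. Stringency is peak density over the mean density of
  flanking positions within half the background window (default
  1000 bp) on each side, excluding positions within one bandwidth of
  the peak — a sharply positioned nucleosome over a flat background
  scores ≫ 1, uniform scatter scores ≈ 1. The bandwidth and background
  defaults are package choices, config-exposed.
* **Interception test**: the statistic is the number of amplicons
  containing ≥ 1 peak position (point-in-interval). The null
  redistributes each amplicon independently by a uniform circular shift
  within the mapped region; `p = (1 + #{null ≥ obs}) / (n_perm + 1)`.
  Peaks outside the declared region are excluded, so a region that
  cannot be intercepted under any shift yields p = 1. The choice of a
  shift permutation null (rather than, e.g., spacing-preserving
  rotation of the whole panel) is a documented design decision.

## Amplicon features

Feature A (spanning fragments) is computed on length-filtered,
*untrimmed* fragments — a fragment must contain the whole amplicon,
primers included, to serve as PCR template — while features B–D are
computed on the smoothed dyad-trimmed track, matching the processing
chain order. Feature C is defined as the absolute difference between
the smoothed signal at the two amplicon boundaries; the alternative
reading (an out-vs-in step at each boundary) is not implemented but the
definition is isolated in one function for easy swapping. Feature D is
the unnormalized sum of absolute deviations from the line joining the
boundary values (per-length normalization is an option). Robustness is
the per-amplicon cross-sample CV of each feature (sample sd, n−1),
averaged over amplicons; zero-mean amplicons are skipped and counted.

## Coverage statistics

GC-band normalization uses fixed-width 5 % bands anchored at 0 % (not
quantile bins), with 100 % folded into the top band, and is applied per
sample: the equation is written per read count, and pooling across
samples would mix library sizes. Normalization is idempotent and
preserves within-band rank order; a band with zero median is an error
naming the band. Regressions are ordinary least squares
(`scipy.stats.linregress`), with the slope's two-sided t-test; the
broken-stick variant fits the two segments independently with the
breakpoint fixed at 170 bp — the package asserts the breakpoint rather
than estimating it, since the scientific question is whether coverage
is flat *below* the mono mode. Equal-frequency discretization splits at
empirical quantiles with ties deterministically pulled to the lower
group; if ties make k non-empty groups impossible it errors rather than
silently rebalancing. ANOVA is one-way fixed-effects
(`scipy.stats.f_oneway`). Uniformity is the per-amplicon cross-sample
CV with the n−1 sd.

## Prediction

**RReliefF** follows the regression Relief formulation: for each
sampled instance, the k = 10 nearest neighbors (Manhattan distance on
min-max-scaled features) contribute accumulated probabilities of
differing feature and target values, combined as
`W = N_dC&dF/N_dC − (N_dF − N_dC&dF)/(N − N_dC)`. Neighbors are
weighted uniformly (1/k) rather than by exponentially decaying rank — a
simpler variant that preserves the estimator's ordering properties;
duplicated features provably receive identical weights. Iterations
default to all instances in seeded random order. Constant features get
weight 0 with a warning.

**Targets.** Continuous depth (mean count) and uniformity (CV) are
split into tertiles by the equal-frequency discretizer; the positive
class is the lowest depth tertile or the highest CV tertile.

**SVM.** RBF kernel with C = 1 and scikit-learn's `gamma="scale"`
(1 / (n_features · var)); the defaults matter little because all
conclusions are paired comparisons under identical settings. Features
are standardized with training-fold statistics only; out-of-fold
decision scores from stratified 3-fold CV are pooled and scored by
AUROC. Precision is taken at the natural decision threshold 0. The 95 %
CI is a percentile bootstrap (1000 resamples) over amplicons of the
pooled scores by default; a CI over CV repetitions is available
(`ci_method="cv_repeats"`), since CIs as tight as a few thousandths are
only achievable as repeat-spread, not amplicon-bootstrap, and the
appropriate choice depends on the question asked. Feature-set
comparisons share fold seeds between the two sets, making ΔAUROC a
paired measurement; identical sets give Δ = 0 exactly.

## Panel comparison

Filters run before classification, and unclassified variants never
reach comparison statistics. Wilcoxon signed-rank drops zero
differences (the original treatment) and uses the exact sign-flip null
for ≤ 25 untied pairs, the normal approximation otherwise. The
geometric mean ratio is `exp(mean log(af₁/af₂))` with a t interval on
the log scale. The enrichment ratio is the tail-mass ratio
`P(L ≥ amplicon − deletion) / P(L ≥ amplicon)`; it accepts the
package's empirical `LengthDistribution` (closed tail, `P(L ≥ x)`) or
any scipy frozen distribution, is always ≥ 1, and returns exactly 1
for a zero-length deletion. Amplicon length includes primers, because
template matching requires both primer sites on the fragment.

The Poisson hotspot screen uses `λ = total_reads · e(context)` with
`e = base_error · multiplier`: the multiplier doubles per homopolymer
base beyond 3 (capped at 16×) and is 4× larger for indels, and
`p = P(Poisson(λ) ≥ alt_reads)`. The multiplier table is a package
default, fully overridable — no published form of the context function
exists, so the shipped table is calibrated only in the sense that the
screen's false positive rate on error-only data stays at or below the
nominal level (Poisson discreteness makes it conservative). The
p-value is non-increasing in alternative reads and non-decreasing in
homopolymer length.

## Numerical and testing choices

* All randomness flows through `numpy.random.default_rng` seeds; equal
  seeds give identical outputs, byte-for-byte on disk.
* GC factors are floored at 0.05 and availability at the survival
  ratio, keeping expected counts strictly positive.
* Tests run at deliberately modest problem sizes — contigs of 0.1–0.6
  Mb, panels of 25–200 amplicons, 50 k fragments, 10 samples, 20
  replicates for the directional recoveries, 1000 replicates for
  type-I calibration — the smallest sizes at which the targeted effects
  are stable, keeping the whole suite under a minute of compute.
* The qualitative recoveries mirror the expected science: a
  significantly negative full-range length–coverage slope with a
  non-significant ≤ 170 bp restriction, and a ≥ 0.05 mean AUROC gain
  from adding nucleosome-instability information to GC when predicting
  uniformity classes, versus a < 0.03 change when depth is generated
  from GC alone.

## Known limitations

* The generator's uniform, independent occupancy/positional parameters
  and single contig make absolute numbers (R², CV percentages, AUROCs)
  generator-dependent; only directions and calibrations transfer to
  real data.
* The peak caller is a generic Gaussian-KDE local-maximum detector;
  it does not reproduce any specific published nucleosome-calling
  software's output.
* BAM ingestion handles the common proper-pair case only; exotic flag
  combinations and supplementary alignments are ignored.
* The Poisson screen's context multiplier table is heuristic; with real
  instrument data it should be re-estimated from error-only sites.
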