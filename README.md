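# nucleoamp

Nucleosome-guided cfDNA fragmentation analysis for amplicon panel design.

## The problem

Cell-free DNA (cfDNA) in plasma is not randomly fragmented: apoptotic
nucleases cut between nucleosomes, so fragment lengths pile up at the
mononucleosome size (~167 bp, with a minor dinucleosome mode near 350 bp)
and fragment midpoints concentrate at nucleosome dyads. For amplicon-based
liquid-biopsy panels this matters twice over: an amplicon longer than the
typical cfDNA fragment has almost no intact template to amplify, and an
amplicon whose primers fall between nucleosome peaks sits in a local
minimum of the fragmentation map, with low and unstable coverage across
samples. `nucleoamp` implements the analysis pipeline that quantifies
these effects so they can inform primer placement:

* **Fragmentation maps** — paired reads are collapsed to fragment outer
  spans, restricted to the mononucleosome range (80–250 bp inclusive),
  replaced by the 40 bp window centered on each fragment midpoint (the
  dyad proxy), counted per base, and smoothed with a 21 bp square-pulse
  kernel. Nucleosome peaks are called from dyad density with positional
  *stringency* scores, and a circular-shift permutation test asks whether
  a panel's amplicons intercept the peaks more often than chance.
* **Fragmentation features per amplicon** — the spanning-fragment count
  (Feature A), depth range (B, signal amplitude), depth change (C,
  boundary-to-boundary difference) and depth shape (D, area between the
  signal and its linear approximation), plus GC content.
* **Coverage statistics** — GC-band median normalization
  (`r̃ᵢ = rᵢ · m / m_GC` within 5 % GC bands, per sample), ordinary and
  broken-stick least squares of coverage on amplicon length (breakpoint
  170 bp), quadratic GC regressions, equal-frequency discretization with
  one-way ANOVA, and the per-amplicon coefficient of inter-sample
  variation (coverage uniformity).
* **Prediction** — RReliefF feature ranking against continuous targets
  and an RBF-kernel SVM under stratified 3-fold cross-validation that
  predicts worst-tertile coverage depth (lowest third) or uniformity
  (highest-CV third), with paired AUROC comparisons between GC-only and
  combined feature sets.
* **Panel comparison** — variant read-support filters (≥ 20 total,
  ≥ 4 alternative reads), hotspot/germline classification (≥ 10 COSMIC
  samples; population MAF ≥ 5 %), bootstrap allele-frequency
  normalization, Wilcoxon signed-rank / Pearson / geometric-mean-ratio
  statistics for allele frequencies shared by two panels, the
  fragment-length enrichment ratio
  `P(L ≥ amplicon − deletion) / P(L ≥ amplicon)` for deletion alleles,
  and a Poisson hotspot screen with context-dependent error rates.

Because the real patient and pooled-plasma datasets are not shipped, the
package includes a first-class synthetic-data module
(`nucleoamp.simulate`) that generates nucleosome landscapes, cfDNA
fragment populations, amplicon panels and per-sample count matrices with
known generative truth; every downstream stage is tested against it.

## Worked example

```python
import nucleoamp as na
from nucleoamp.stats import (CountMatrix, gc_normalize,
                             length_coverage_regression, coverage_uniformity)
from nucleoamp.predict import compare_feature_sets, define_target_classes

landscape = na.generate_nucleosome_landscape(400_000, mean_spacing=190, seed=1)
cfg = na.SimulationConfig(seed=1, n_samples=10)
panel = na.generate_amplicon_panel(landscape, 150, seed=1)
counts, truth = na.simulate_amplicon_counts(panel, landscape, cfg)

norm = gc_normalize(CountMatrix.from_panel(counts, panel))
mean_cov = norm.counts.mean(axis=1)
full = length_coverage_regression(norm.length, mean_cov)
short = length_coverage_regression(norm.length, mean_cov, max_length=170)
print(f"full-range slope {full.slope:.2f} (p = {full.pvalue:.2g}, n = {full.n})")
print(f"<=170 bp slope   {short.slope:.2f} (p = {short.pvalue:.2f}, n = {short.n})")

cv = coverage_uniformity(counts)
y = define_target_classes(cv.to_numpy(), "uniformity")
cmp = compare_feature_sets(truth[["gc"]], truth[["gc", "instability"]], y,
                           replicates=5, seed=1)
print(f"AUROC gc-only {cmp.auroc_first.mean():.3f} -> combined "
      f"{cmp.auroc_second.mean():.3f} (mean gain {cmp.mean_delta_auroc:+.3f})")
```

prints

```
full-range slope -11.21 (p = 2.7e-29, n = 150)
<=170 bp slope   -2.23 (p = 0.08, n = 97)
AUROC gc-only 0.563 -> combined 0.838 (mean gain +0.275)
```

Read: over the full 100–200 bp panel, normalized coverage falls steeply
with amplicon length (template availability collapses once amplicons
outgrow the ~167 bp fragment mode), while restricting to amplicons of
≤ 170 bp leaves no significant length effect — short amplicons are
equally tolerated. For predicting which amplicons land in the
worst-uniformity tertile, adding the nucleosome-instability signal to GC
content raises the out-of-fold AUROC substantially.

A command-line interface mirrors the library:

```sh
nucleoamp simulate --config sim.cfg --outdir sim/
nucleoamp fragmap  --fragments sim/fragments.bed --region sim1:0-50000 \
                   --out track.bedgraph --peaks-out peaks.bed
nucleoamp features --fragments sim/fragments.bed --panel sim/panel.tsv --out features.tsv
nucleoamp stats    --counts sim/counts.tsv --panel sim/panel.tsv --out stats.tsv
nucleoamp predict  --features features.tsv --counts sim/counts.tsv \
                   --target uniformity --out report.json
```

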