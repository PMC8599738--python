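# Methods

This note documents the models, estimators and numerical choices behind
`enhancerkit`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where several reasonable options existed.

## Coordinate and format conventions

All coordinates are 0-based half-open (BED-native) everywhere inside the
package; formats with other conventions are converted at the parser
boundary. narrowPeak column 10 is converted to an absolute summit
coordinate on input. Chromosome names are taken verbatim (no "chr"
normalization). Unstranded records are scanned on both strands downstream.

## Differential count model (`signal_stats`)

Counts are modeled as negative binomial with variance
`V(mu) = mu + phi * mu^2`. The test deliberately replaces a full
DESeq2-style fit with a small, fully documented procedure — no Cook's
distance outlier handling, no independent filtering, no posterior
fold-change shrinkage; its contract is *calibration*, verified by
simulation (see below), not bit-compatibility with any external tool.

* **Normalization.** `median_ratio` (DESeq-style median of ratios to the
  per-region geometric mean, over regions nonzero in all samples) is the
  default for H3K27ac; `total` (column sum / mean column sum) is used for
  TF and accessibility signal under perturbation, where global loss is part
  of the effect being measured. Note the flip side: median-ratio
  normalization absorbs a change planted in the majority of regions, so
  landscapes need a stable-peak majority — real ones have it, and the
  generator plants one.
* **Fold change.** `log2((m2 + 0.5) / (m1 + 0.5))` on normalized group
  means. The 0.5 pseudocount avoids infinities at zero counts and is
  configurable.
* **Dispersion.** Pooled method-of-moments per region,
  `phi_hat = sum_g (var_g - m_g * mean(1/s_j)) / (G * bm^2)`, where `bm`
  is the contrast-free pooled base mean. The raw estimate keeps its sign;
  a trend `phi(mu) = a1/mu + a0` is fitted to the raw estimates by
  non-negative least squares (non-negativity inside the fit — post-hoc
  clipping of an unconstrained fit misbehaves when `1/mu` is nearly
  constant across regions); the final dispersion is
  `max(0.5 * phi_hat + 0.5 * trend, 1e-8)`. With single-replicate groups
  the test falls back to a fixed prior `phi = 0.1` with a warning.
* **Wald statistic and its reference.** `z = log2fc / SE` with the
  delta-method SE evaluated at the pooled mean (evaluating it at the
  per-group means leaks the tested difference into the SE and inflates the
  tails). Because exactly half of the variance estimate is the
  deterministic trend and half a chi-square-distributed moments estimate,
  the null law of `z` is the scale mixture
  `z | W ~ Normal(0, 1 / (0.5 + 0.5 W))`, `W ~ chi2_nu / nu`, with
  `nu = sum_g (n_g - 1)` moment-matched to the NB fourth central moment
  `mu4 = V (1 + 6 phi mu + 6 phi^2 mu^2) + 3 V^2`. Two-sided p-values are
  computed against that mixture by 512-point midpoint quadrature. This is
  the moderated-t idea with prior weight equal to the shrinkage weight; a
  plain normal reference is measurably anti-conservative at 2+2
  replicates (type-I ≈ 0.065–0.08 at nominal 0.05), while the mixture
  reference is calibrated: across 30 simulation seeds (5,000 null regions,
  2+2 replicates, mu = 100, phi = 0.05) the empirical type-I error at 0.05
  stayed within [0.045, 0.062] and the p-distribution passed a KS test
  against U(0,1) at alpha = 0.01 in 29/30 seeds.
* **Multiple testing.** Benjamini–Hochberg step-up, implemented directly
  (sorted `p * n / rank` with a running minimum) and property-tested
  against the brute-force definition.

`fraction_significant_loss` counts regions with
`log2fc <= -log2(2)` **and** `padj < 0.05` — the "significant ≥ 2-fold
decrease" criterion used to quantify TF dependence under perturbation.

`rank_sum_compare` enumerates all rank splits exactly (midranks under
ties) when the combined sample size is ≤ 20, using the two-sided rule
`P(|U - mu| >= |u_obs - mu|)`; larger samples use the tie-corrected normal
approximation.

`fisher_exact_2x2` works in exact integer arithmetic: hypergeometric
weights are binomial-coefficient integers and the two-sided sum includes
tables whose weight is `<=` the observed weight under exact integer
comparison, so there is no floating tie tolerance; the only error left is
float summation (< 1e-15 relative).

## Enhancer definition and classification (`enhancer_classify`)

* **Distal filter:** a peak is distal when its edge-to-TSS distance to the
  nearest TSS is strictly greater than 2,500 bp (strict ">"; a peak at
  exactly 2.5 kb is removed).
* **Lineage enhancers:** distal peaks with `log2fc >= 1` and
  `padj <= 0.05` between stages (both thresholds configurable).
* **Temporal classes:** an enhancer is bound at a stage when ≥ 1 peak of
  the classifying TFs overlaps it within `slop` bp (default 0 — direct
  interval overlap of the enhancer interval itself, the natural reading;
  a window around the peak center is available through `slop`). "Bound by
  the TFs" means bound by **any** of them (union rule; intersection
  available). Both stages → I, late only → II, early only → III, neither →
  excluded. Class III is reported but excluded downstream.
* **Target genes:** nearest expressed gene (FPKM ≥ 1) by edge-to-TSS
  distance on the same chromosome; exact distance ties go to the
  lexicographically smaller gene id; enhancers with no expressed gene on
  their chromosome are flagged unassigned.
* **Cross-TF overlap fractions** use ±100 bp slop and the exact two-sided
  Fisher test.

## Super-enhancers (`super_enhancer`)

Single-linkage stitching at edge-to-edge gap ≤ 12,500 bp (edge gap, the
ROSE convention, not center distance). The stitched signal is the sum of
member enhancers' size-factor-normalized H3K27ac counts (no input-track
subtraction). For the cutoff, regions are sorted ascending by signal, both
axes rescaled to [0, 1], and the cutoff is the curve point minimizing
`y - x` — the point where a slope-1 line is tangent to the rank curve from
below; ties go to the highest rank (fewest supers). Regions with signal
strictly above the cutoff signal are super-enhancers. A constant signal
vector has no curvature and returns zero super-enhancers with a warning.

## Motif architecture (`motif_architecture`)

* **Scores** are log-odds in bits against the PWM background. JASPAR PFMs
  get probabilities `(count + pc * b) / (colsum + pc)` with `pc = 0.1`
  distributed by background. Production background is 40.9% GC
  (hg19-like); uniform background is used in oracle tests.
* **Exact p-values.** Scores are discretized at 1e-3 bits; the null score
  distribution under the i.i.d. background is built column by column by
  dynamic programming and suffix-summed into an upper-tail table. A
  window's p-value is the tail at its integer score, so DP p-values agree
  with full 4^w enumeration up to float summation order. Default report
  threshold p ≤ 1e-4 (the common scanner default).
* **Strand handling.** The minus strand is scanned with the
  reverse-complement PWM; hits are reported at their leftmost plus-strand
  offset, so reverse-complementing a sequence mirrors offsets and flips
  strands exactly. Opposite-strand hits at one position are distinct hits
  but one "region with ≥ 1 occurrence".
* **Positional analysis.** Summits flanked by ±500 bp; a hit's position is
  its motif center (symmetric under strand). The profile is the fraction
  of regions with ≥ 1 hit centered at each offset; the central-enrichment
  test is a one-sided Fisher test on regions with a hit centered within
  ±window/2 (window = 100 bp).
* Known-PWM differential enrichment replaces de novo motif discovery,
  which is out of scope.

## Loop calling (`loop_caller`)

* **Balancing.** Damped symmetric scaling `w <- w / sqrt(rowsum / mean)`,
  which converges to the Knight–Ruiz fixed point for symmetric
  non-negative matrices; tolerance 1e-6 on relative row sums, 3,000
  iterations max, bins with < 1 nonzero entry masked first.
* **Donut background only** (no lower-left/horizontal/vertical
  backgrounds): donut bins at Chebyshev distance in (2, 5] from the pixel,
  clipped to the strict upper triangle and unmasked bins; each donut bin's
  balanced count is divided by the genome-wide distance expectation
  `e(d)` at its own distance, and the mean ratio rescales `e(j - i)`. The
  donut geometry is configurable; (2, 5) is a HiCCUPS-like scale for
  10-kb bins.
* **Raw-scale test.** `E_raw = E_KR / (w_i * w_j)`; `p = P(X >= obs)`,
  `X ~ Poisson(E_raw)`, on the raw integer count.
* **Candidate pipeline.** Candidates are pixels with `p < 0.01` inside a
  configurable distance window (defaults 2 bins to 2 Mb — a literal
  "distance < 10 kb" rule is not executable at 10-kb bins); isolated
  candidates (no 8-connected candidate neighbor) are dropped as likely
  false positives; surviving candidates are collapsed by single linkage at
  Chebyshev ≤ 2 bins (20 kb), keeping the most significant pixel (ties:
  higher observed/expected, then lexicographic); the final list keeps
  `p < 1e-5`. Intra-chromosomal only.

## Permutation tests (`permutation`)

Each region is relocated uniformly on its own chromosome with length
preserved (no exclusion list by default). The statistic is the number of
regions overlapping ≥ 1 feature; with `r` null draws ≥ observed over `N`
iterations (default 10,000), the one-sided enrichment p-value is
`(r + 1) / (N + 1)` — never zero. Note that at a fixed seed, adding
features increases both the observed statistic and every null draw, so the
p-value itself is not monotone in the feature set; the monotone quantities
are the statistic and the null draws.

## Synthetic data (`synthetic_data`)

The generator plants every input the pipeline consumes, with truth tables,
at defaults mirroring the pancreatic landscape scale: 561/1,422/118
class I/II/III enhancers plus 473 never-bound lineage enhancers (2,574
total), 167 super-enhancer clusters of 3 members at 10× signal, 5,000
stable distal peaks, 200 TSS-proximal peaks, NB counts at mean 100 and
dispersion 0.05 with a planted 4-fold H3K27ac gain, perturbation TF-signal
loss in 3% of class I and 23% of class II enhancers (4-fold), and a
300-bin 10-kb Hi-C map with `d^-1` decay and ten 5-fold loops.

Layout geometry guarantees exactness of the planted truth: units are
placed left to right with inter-unit gaps ≥ 35 kb and own-gene TSS
distances ≤ ~32 kb, so each unit's planted gene is provably its enhancers'
nearest TSS, isolated enhancers never stitch (> 12.5 kb apart), proximal
peaks sit < 2.5 kb from their TSS and everything else sits farther. TF
peaks (width 200 bp) are placed inside their enhancers with ±100 bp
jitter, FOXA1 always and FOXA2 in ~70% of bound enhancers, at exactly the
stages the class dictates — classification recovery on generator output is
therefore exact by construction, which is the point: it tests the
bookkeeping of the classifier, not its robustness.

Motif instances are drawn from the PWM by rejection sampling (capped at
1e5 draws) conditional on the log-odds score falling in a quantile band of
the PWM's own emission-score distribution — primed-class sequences get
strong bands (0.9–1.0) at near-central positions (Gaussian offset,
sigma = 30 bp), unprimed-class sequences weak bands (0.3–0.5) at dispersed
positions (sigma = 250 bp), emulating "abundant, strong, central" vs
"fewer, degenerate, dispersed". Background bases are i.i.d. at 40.9% GC.

Hi-C loops are planted as a focal 3×3 patch — the center pixel at the full
fold enrichment and its 8 neighbors at half enrichment — which is how
focal loops look at 10-kb resolution and what the caller's
neighboring-candidate filter presumes; a strictly single-pixel spike is,
by construction, removed by that filter. The patch radius (1) stays inside
the donut inner exclusion (2), so background estimation is unaffected.

**What the generator does not emulate:** read-level noise and mappability
artifacts, copy-number and GC biases, overlapping/nested peaks, ambiguous
enhancer–gene geometry (every planted gene is nearest by construction),
fragment-level Hi-C ligation noise, and inter-chromosomal contacts.
Passing tests on generator output therefore demonstrate correctness of the
algorithms and their bookkeeping under the stated model, not robustness to
the full messiness of real data.

## Problem sizes and determinism

The bundled demo runs at full default scale (~7,800 peaks, ~2,000 motif
windows of 1 kb, a 300-bin contact map, 10,000 permutation iterations) in
well under a minute on one CPU; the test suite uses smaller landscapes
(50/100/10 classes, 200–400 Hi-C bins, 20-seed replicates) chosen so each
statistical check retains comfortable Monte Carlo margins. All stages
consume `numpy` Generators seeded from a single configured seed; reruns of
the same config are byte-identical (`summary.json` is compared as bytes in
the tests), with volatile information (timings, tracebacks) confined to
`run.log`.

## Known limitations

* The NB test's mixture reference assumes the within-group sample variance
  is chi-square-like; at very low means (< ~5 counts) discreteness makes
  p-values conservative.
* The moments dispersion estimator needs ≥ 2 replicates per group; the
  single-replicate fallback (`phi = 0.1`) is a loud, documented prior, not
  an estimate.
* `rose_cutoff` requires ≥ 3 stitched regions and meaningful curvature;
  rank-curve geometry is undefined otherwise.
* The loop caller reports one pixel per collapsed cluster and does not
  model anchor width beyond one bin.
* Exact rank-sum enumeration is limited to combined n ≤ 20 (C(20,10) =
  184,756 splits); beyond that the tie-corrected normal approximation is
  used.
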