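# enhancerkit

Tools for classifying **primed vs unprimed lineage enhancers** from
two-stage differentiation experiments, in the style of studies of pioneer
transcription factors (FOXA1/FOXA2) during endodermal organ induction.

During differentiation of a progenitor (e.g. primitive gut tube, "GT") into
an organ lineage (e.g. late pancreatic progenitors, "PP2"), enhancers that
activate upon induction split into classes by when pioneer TFs occupy them:

* **class I (primed)** — TF-bound at both the early and late stage;
* **class II (unprimed)** — TF-bound only at the late stage;
* **class III** — TF-bound only at the early stage (small group, reported
  but excluded from downstream analyses by default).

`enhancerkit` implements the complete computational path from count tables
and peak calls to that classification and its downstream characterisation:

| stage | module | method |
|---|---|---|
| differential H3K27ac | `signal_stats` | NB Wald test, median-ratio or total-count normalization |
| enhancer definition | `enhancer_classify` | distal filter (> 2.5 kb from any TSS), fold ≥ 2 at FDR ≤ 0.05 |
| temporal classes | `enhancer_classify` | peak-overlap occupancy at each stage, union rule over TFs |
| target genes | `enhancer_classify` | nearest expressed gene (FPKM ≥ 1) |
| super-enhancers | `super_enhancer` | ROSE: stitch within 12.5 kb, rank-curve slope-1 tangent cutoff |
| motif architecture | `motif_architecture` | PWM log-odds scanning with exact DP p-values; abundance (Fisher), strength (rank-sum), position around ATAC summits (±500 bp, central Fisher) |
| chromatin loops | `loop_caller` | KR-balanced 10-kb matrices, donut-only local background, Poisson tail, neighbor filter, 20-kb collapse |
| overlap significance | `permutation` | 10,000 per-chromosome shuffles, p = (r+1)/(N+1) |
| synthetic data | `synthetic_data` | planted-truth generator for every input above |

## The statistics at the core

**Differential signal.** Counts \(K_{ij}\sim\mathrm{NB}(\mu_i s_j,\phi_i)\)
with \(\mathrm{Var}=\mu+\phi\mu^2\). Per region,
\(\log_2\mathrm{FC}=\log_2\frac{\bar m_2+0.5}{\bar m_1+0.5}\) on
size-factor-normalized means; \(\phi\) is a pooled moments estimate shrunk
50/50 toward a fitted trend \(\phi(\mu)=a_1/\mu+a_0\); the Wald statistic
\(z=\log_2\mathrm{FC}/\mathrm{SE}\) is referred to its exact null law under
the model — a scale mixture \(z\mid W\sim N(0,1/(0.5+0.5W))\),
\(W\sim\chi^2_\nu/\nu\) — rather than to a plain normal, which makes the
test calibrated down to 2+2 replicates (see `docs/methods.md`).

**Motif scoring.** \(s=\sum_j \log_2 p_j(b_j)/\pi(b_j)\) in bits, both
strands; p-values are exact upper tails of the score distribution under the
i.i.d. background, computed by dynamic programming on a 10⁻³-bit grid.

**Loop calling.** For pixel \((i,j)\) the expected balanced count is
\(E_{KR}=\overline{K(i',j')/e(|i'-j'|)}\cdot e(j-i)\) over the donut annulus
(Chebyshev radius 2–5 bins), converted to raw scale by \(1/(w_iw_j)\) and
tested with a Poisson upper tail.

## Worked example

The bundled demo simulates a full-scale landscape (2,574 lineage enhancers
with 561/1,422/118 planted class I/II/III labels among ~7,800 distal peaks,
167 planted super-enhancer clusters, 10 planted chromatin loops) and runs
every stage:

```python
from enhancerkit import run_pipeline, demo_config

summary = run_pipeline(demo_config(seed=42), "demo_run")
```

or equivalently `enhancerkit run --seed 42 --out demo_run`. Key entries of
the printed `summary.json` (seed 42):

```json
"class_counts":               {"I": 503, "II": 1295, "III": 109},
"classification_agreement":   1.0,
"n_lineage_enhancers":        2337,
"n_super_enhancers":          178,
"se_single_class_fraction":   0.814607,
"loops":                      {"n_planted": 10, "n_planted_recovered": 10},
"perturbation_loss_fraction": {"class_I": 0.024955, "class_II": 0.207454},
"permutation":                {"observed_overlap": 503, "pvalue": 0.0001}
```

Reading: of the 2,574 planted lineage enhancers, 2,337 pass the
differential H3K27ac test (the NB test has ~92% power at the planted
4-fold gain), and **every one** of them receives its true temporal class
(`classification_agreement = 1.0`). 178 stitched regions rank above the
ROSE inflection point, 81% of them containing a single enhancer class. All
10 planted loops are recovered at their exact pixels. Under knockdown of
the cooperating lineage TF, 2.5% of class I but 20.7% of class II
enhancers show a significant ≥ 2-fold loss of TF signal (planted: 3% and
23%; unprimed enhancers depend on the lineage TF, primed ones do not).
Class I enhancers overlap early-stage FOXA binding sites far in excess of
the shuffled null (503/503 observed vs 1.7 expected, p = 1/10,001).

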