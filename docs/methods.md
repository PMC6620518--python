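# Methods

This note documents the models, conventions, and numerical choices behind
`assayval`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Scope and stance

The package implements the *analysis* layer of an analytical-verification
study for a continuous-score molecular classifier: count mixing and LOD,
interferent titration, effect testing, variance-component reproducibility,
bootstrap CIs, noise-tolerance acceptance specifications, and agreement
statistics. The wet-lab pipeline (extraction, library preparation,
sequencing, alignment, counting, fusion calling) is out of scope; inputs
start at the gene-by-sample count matrix or the replicate-level score
table. Production classifiers of this kind are proprietary ensembles, so
all end-to-end behavior is exercised through a declared linear surrogate —
a stand-in chosen for transparency, not a reconstruction.

## Synthetic data generator

**Counts.** Negative-binomial counts with per-gene baseline means drawn
lognormal(4, 1) (a realistic bulk RNA-seq magnitude spread), gene-wise
dispersion α (variance μ + αμ²; default α = 0.1, typical of bulk
technical-plus-biological dispersion), and multiplicative lognormal
library-size factors with coefficient of variation 0.2. Informative genes
carry a class-dependent log2-fold change (default ±effect_size with random
sign). This is the simplest model consistent with the count data such
assays produce; it does not emulate GC/length bias, correlated gene
modules, or batch effects, so passing tests demonstrate correctness of the
estimators, not robustness to those real-data features.

**Scores.** `S_ijk = class mean + sample deviation + run + sample:run +
residual`, all effects independent centered Gaussians with configurable
SDs, on a declared score range (default 8 units, classes symmetric about
the 0 threshold). Fully crossed balanced designs; a `drop_one` flag
reproduces the common situation of one assay lost to QC. With
`n_runs = n_reps = 1` and `n_labs = 2` the residual acts as independent
per-laboratory noise, which is how paired-lab sets are generated.

**Interferents.** Blood-like profiles put 90% of their mass on a 5%
marker-gene block (hemoglobin-dominated whole-blood RNA); gDNA-like
profiles are near-uniform background (the dominant effect of genomic DNA
contamination being depth dilution of the transcriptome signal).

Every generator takes an explicit integer seed; there is no global random
state, and seeded outputs are bit-reproducible.

## Reference study conditions

The recovery studies in `assayval.studies` freeze one set of "truths"
emulating the reproducibility profile of a clinically deployed thyroid
benign/malignant classifier on an 8-unit score range:

| quantity | truth | design |
|---|---|---|
| pooled intra-run SD | 0.069 | 15 samples × 3 runs × 3 replicates |
| pooled inter-run SD | 0.274 | same |
| inter-laboratory pooled SD | 0.130 | 40 samples, 2 labs |
| inter-class (biological) SD | 1.452 | 191 samples, 2 classes |

The run/interaction split of the inter-run variance is not identifiable
from pooled SDs, so the non-residual variance (0.274² − 0.069²) is split
evenly between the two components. The 15-sample table is generated as 8
samples per class with one sample dropped (the design sizes of such
studies are odd because positive and negative arms need not be equal).
For the inter-class truth, class means sit 2.4 units apart with
within-class spread chosen so the SD of per-sample means is exactly 1.452.

## Normalization

Median-of-ratios size factors: reference genes are those with strictly
positive counts in every sample; each sample's factor is the median over
reference genes of count / (across-sample geometric mean), with the
geometric mean computed in log space. Counts may be real-valued so that
convex mixtures normalize identically to raw counts. The classifier-facing
transform is `log2(count/factor + 1)`.

Because the pseudo-reference includes every sample, size factors are
identified only up to a common gauge: scaling one sample's counts by c
multiplies its factor by exactly c *relative to the others* (and every
depth-corrected profile is unchanged up to one common constant), which is
the exact form of the scale-invariance property the tests assert.

## Surrogate classifier

A ridge-regularized diagonal centroid discriminant:
`w_g = (c_pos,g − c_neg,g) / (v_g + λ)` with `v_g` the pooled within-class
variance, affinely rescaled so the class mean scores sit at ±range/4 and
the threshold at 0. Ties at the threshold are called negative — a rule-out
test should not emit a positive call on a knife edge. The score is linear
in the profile, so for any convex mixture
`score(p·x1 + (1−p)·x2) = p·score(x1) + (1−p)·score(x2)` exactly; this is
what makes closed-form LOD and interference oracles possible.

## Mixing and LOD

Parents are rescaled to a common total before mixing so the mixing
fraction is an RNA *mass* fraction (physical titrations combine equal
total RNA mass, not equal sequencing depth); the convex combination is
kept real-valued. For in-silico titrations the whole series plus both
parents is normalized with freshly computed size factors (normalizing
within the series, rather than against a larger cohort, is recorded in the
series metadata). The p = 0 point is a negative control; if it scores
positive the pair is flagged invalid and no LOD is reported.

LOD uses a contiguity rule — the smallest fraction called positive *at
itself and every larger tested fraction* — so a single non-monotone blip
cannot shrink the LOD. Discrete dilution designs apply the same rule on
the dilution scale (LOD = 100% − largest tolerated dilution), with the
100% point treated as a pure-diluent control, never an LOD point.
Interference levels mirror this: largest level correct at itself and all
smaller levels, with a level-0 failure reported as a baseline failure.

## Sigmoid fits

Score-versus-fraction curves are summarized with a 4-parameter logistic
(lower/upper asymptote, inflection, slope) fit by least squares; four
parameters are identifiable from the five-point titration designs used in
practice. The canonical orientation keeps lower ≤ upper with direction
carried by the slope sign; flat or non-convergent data fall back to a
constant fit flagged degenerate. Threshold crossings are solved
analytically from the fitted parameters and reported only inside [0, 1].

## Effect model and variance components

The experimental-effect model is fitted as a balanced
randomized-complete-block two-way ANOVA (samples as blocks), with the
fixed effect tested by F = MS(condition)/MS(residual). On the balanced
designs these studies use, this F test coincides with the mixed-model test
of the fixed effect; unbalanced data are rejected with guidance rather
than silently refit (no general REML engine is included — a documented
limitation).

Reproducibility variance components come from equating balanced-ANOVA
mean squares to their expectations: σ̂²_ε = MS_E,
σ̂²_int = (MS_int − MS_E)/K, σ̂²_run = (MS_run − MS_int)/(I·K). Negative
solutions are truncated at zero (raw values are retained for
diagnostics); components a design cannot identify (single run, single
replicate) are reported absent, never zero. Derived summaries: intra-run
SD = σ̂_ε (identically the pooled within-cell SD), inter-run SD =
√(σ̂²_run + σ̂²_int + σ̂²_ε) — the composition "all experimental
variability other than sample effects", an interpretation recorded here
deliberately. On balanced designs with interior solutions these estimators
coincide with REML, which is how the test suite cross-checks them against
an independent numerical likelihood oracle.

The inter-class (biological) SD is defined as the SD of per-sample mean
scores pooled over both classes. The two-laboratory comparison requires
each sample scored exactly once per lab, uses the per-sample pair SD
(|a−b|/√2) pooled across samples — so independent per-lab noise of SD s
yields a pooled SD of s, while noise confined to one lab yields s/√2, a
√2 relation that is documented and tested — and tests the lab effect with
the block ANOVA using laboratory as the condition.

## Bootstrap

CIs for SD statistics use a percentile (2.5/97.5) block bootstrap that
resamples whole samples with replacement, because replicates within a
sample are dependent; B = 2000 by default (B ≥ 200 enforced). Named
statistics run on a vectorized path (per-sample sums of squares and
degrees of freedom) that makes repeated CIs cheap; arbitrary callables are
supported on a general path, with undefined resamples redrawn and counted.
Percentile intervals for spread statistics at ~15 blocks are known to sit
slightly below nominal coverage; the coverage test asserts the band
0.90–0.99 rather than 0.95 exactly.

## Noise-tolerance specification

Noise is injected into *scores only* (post-classifier), never counts.
Default grid 0.36–2.10 step 0.02 with 1,000 repetitions per σ and medians
across repetitions; the random stream is split per grid point so each σ is
independently reproducible. The specification is the largest grid σ at
which every required metric's median meets its minimum — even if an
isolated smaller σ fails by finite-replicate noise; a strict-monotone
variant is available behind a flag. NPV/PPV use a supplied prevalence or
the sample composition by default (which convention applies is a study
choice, so it is a config field, not a constant).

For the reference margin study (point-mass classes at ±2, threshold 0,
sensitivity ≥ 0.90) the median sensitivity at σ has the closed form
Φ(2/σ), putting the expected specification at the largest grid σ with
Φ(2/σ) ≥ 0.90, i.e. 1.56 (crossing at 2/z₀.₉₀ ≈ 1.5606). The study uses
500 samples per class: the requirement boundary 0.9·n must sit clear of
the binomial median at the first failing grid point, and an exact
binomial calculation shows n = 500 minimizes the probability that
finite-replicate noise flips the determined grid point, given how close
the true crossing (1.5606) lies to the grid value 1.56.

## Problem sizes and defaults

Recovery studies use 200 seeds and report medians; the effect-model
calibration uses 1,000 null datasets (10 samples × 2 conditions ×
triplicate) and 300 power datasets; the estimator-vs-REML cross-check uses
50 small balanced instances; bootstrap coverage uses 500 simulations at
B = 400 (the library default B = 2000 is unnecessary for a coverage
estimate and 500 × 2000 resamples would dominate the suite's runtime).
These sizes are the package's own choices balancing Monte-Carlo precision
against a test suite that runs in well under a minute per study.

## Known limitations

- The surrogate classifier shares only the *interface* of production
  ensemble classifiers; absolute LOD or interference numbers from the
  synthetic pipeline characterize the surrogate, not any real assay.
- No unbalanced-design REML; operator/reagent-lot/day are folded into
  "run" rather than modeled as separate crossed factors.
- The count generator omits batch effects and gene-gene correlation;
  blood/gDNA profiles are stylized.
- PPA/NPA are reported without exact binomial CIs.
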