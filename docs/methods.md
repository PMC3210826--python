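# Methods

This note documents the statistical models implemented in `toxsetpipe`,
the defaults chosen where the methods literature leaves latitude, what the
synthetic-data generator does and does not emulate, and the package's known
limitations.

## Two-color normalization

A common-reference design is assumed: each experimental sample (red, Cy5)
is co-hybridized against one universal reference (green, Cy3), and all
inference is on log-ratios, M = log2(R/G), with A = ½·log2(R·G). Dye bias
appears as a smooth trend of M in A and is removed per array by LOWESS:
M′ = M − f̂(A), where f̂ is a robust locally weighted linear regression
(`statsmodels` smoother).

* **Span** defaults to 0.4 of the probes per local window with three
  robustifying reweighting passes — a common choice for MA normalization;
  it is exposed (`span=`, `--span`) because the appropriate value depends
  on the curvature of the bias.
* Probes non-positive in either channel have no defined log-ratio; they
  are excluded from smoothing and returned as missing rather than dropped,
  and the count is logged per array.
* Because the local fit is linear, a constant or linear bias is removed
  exactly; for the default synthetic bias curve (mild quadratic on top of
  a dominant linear trend) the residual after normalization stays below 1%
  of the bias amplitude on the interior 10–90% intensity range, which the
  tests verify on noiseless data.

## Single-channel preprocessing

Quantile normalization maps each array's order statistics to the
across-array mean of sorted columns; ties receive the average of the values
assigned to the tied ranks. The operation preserves within-column rank
order and is idempotent.

Present calls use the labelled negative-control probes: per sample,
threshold = trimmed mean + 3 × trimmed SD of the control signals, and a
probe is present iff its signal is **strictly** greater. The trim fraction
is not standardised anywhere; the default removes 5% from each tail
(`trim=0.05`), enough to defuse a wild control probe without discarding
most of the controls. The trimmed SD uses the sample convention (ddof=1)
on the retained core. Technical replicate probes collapse to the median
per target and sample.

Array-level QC flags arrays whose median Spearman correlation with all
other arrays falls below a threshold (default 0.5). The flag is advisory:
the pipeline records exclusions in the run log but never drops an array on
its own, since published exclusion criteria are rarely quantitative.

## Differential expression

The estimator is a per-gene fixed-effect two-group model on normalized
log-ratios (or log2 intensities). In a common-reference design with one
sample per array, an array term would be confounded with the sample, so
the full mixed-model machinery reduces to this two-group contrast with no
loss; likewise a "sample identity" random effect with one array per sample
degenerates into the residual, so the single-channel analysis uses the
fixed-effect F1 test.

**Fs statistic.** With X_g = ln(residual MS of gene g) and ν residual
degrees of freedom,

    σ̃²_g = exp( X̄ + B·(X_g − X̄) ),
    B = max(0, 1 − (G − 3)·ψ₁(ν/2) / Σ_g (X_g − X̄)² ),

where ψ₁ is the trigamma function, the theoretical variance of
ln(χ²_ν/ν), and G the number of genes with positive residual MS. Fs =
MS_treatment / σ̃²_g. This is the log-scale James–Stein form that leaves
the shrinkage centre at the mean log variance; the published variant adds
a multiplicative bias-correction constant to the centre, which we omit so
that the estimator has the two natural limits the tests pin down: a single
gene (G = 1) gives the ordinary F, and a panel with identical residual
variances gives Fs ≡ F exactly. With G ≤ 3 the James–Stein factor is
undefined and no shrinkage is applied. Genes with zero residual MS shrink
to zero variance (Fs = ∞ when a treatment effect exists), mirroring the
ordinary F.

**Permutation p-values.** Residuals of the intercept-only (null) fit are
shuffled as whole sample columns — the treatment label pattern stays
fixed, the data columns move — so gene–gene correlation survives into the
null. p = (1 + #{stat* ≥ stat}) / (n_perm + 1): the add-one convention
keeps p-values off zero and counts ties conservatively. The null is
gene-specific by default; a pooled-across-genes mode is available for
stability at small permutation counts (under homoscedastic nulls both
modes target the same distribution). Note that with few samples per group
the column-shuffling null occasionally reproduces the observed split, so
the attainable minimum p is bounded below by the number of distinct
group-preserving arrangements — a property of the scheme, not a defect.

**FDR and fold change.** Benjamini–Hochberg step-up (via `statsmodels`,
verified in the tests against a brute-force double-loop oracle), applied
in input order with missing values passed through. Fold changes come from
the least-square means, FC = 2^(LSmean_t − LSmean_c), reported signed:
values below 1 become −1/FC, so |FC| ≥ 1 and sign encodes direction.

## Gene-set tests

Both tests are self-contained and make no distributional or
gene-independence assumptions; under the null with exchangeable samples
the rank-test permutation is exact, which the simulations confirm up to
within-set correlation 0.6.

* **Rank-based:** all measured genes are ranked within each sample
  (average ranks on ties), so the statistic reflects where set members sit
  in the whole array's intensity distribution; for each set gene the mean
  rank per group is computed and D is the Euclidean distance between the
  two group vectors. The distance metric and ranking scope are not
  standardised in the methods literature; Euclidean distance mirrors the
  design-based test, and the scope is exposed (`rank_scope=global` vs
  `within-set`). Being rank-based, the test is invariant to any strictly
  monotone per-sample transform. One caveat of global ranking: ranks are
  relative, so if a large fraction of the measured genes is strongly
  perturbed, the ranks of unperturbed genes shift too (a competitive-test
  artifact).
* **Design-based:** D is the Euclidean distance between group mean vectors
  on the expression scale. The null removes the treatment effect by
  centring each gene at its grand mean and bootstrap-resamples whole
  residual sample-columns with replacement, honouring group sizes — the
  resampling unit retains inter-gene correlation; an independent per-gene
  resampling mode exists for comparison.

Both use the add-one p-value convention with ties counted as exceedances.
Internally both tests operate on columns in design-table order, making
results exactly invariant to the matrix's column order and to gene
renaming. The enrichment report gives raw per-set p-values (the classic
table layout); a BH column is included for convenience, not applied by
default.

## qPCR quantification

Technical replicate wells are averaged first. Housekeeping aggregation is
the arithmetic mean of housekeeping Ct values — equivalent to the
geometric mean of housekeeping expression, the convention most stable
across kits. Amplification efficiency defaults to 2.0 per cycle and may be
supplied per gene; standard-curve estimation of efficiencies is out of
scope. The REST-style test randomizes sample-to-group allocation with
fixed group sizes on the ΔCt values and compares |log ratio| two-sidedly;
since efficiency is a per-gene constant this equals comparing |ΔΔCt|. The
null depends only on the pooled ΔCt multiset and the group sizes, so
equal-sized designs give the same p after a label swap.

## Dosimetry

Plain unit-checked arithmetic. Deposition fractions are caller-supplied —
aerosol deposition modelling itself is out of scope — with one documented
example set (72.5/48/356/267 µg regional deposition out of 840 µg
inhaled). Reporting precision follows convention: mg to 3 decimals, mg/kg
and % to the nearest integer, cm² to 2 decimals. The exposure-regimen
product uses the measured mean concentration (42.4 mg/m³), which yields
0.83952 mg ≈ 0.840 mg per animal; derived report quantities propagate the
unrounded value.

## Synthetic-data generator

The generator is the package's test bed: every downstream stage can be run
against data whose differential genes, perturbed pathways, variances and
dye bias are known.

* Gene-wise variances are drawn from a scaled inverse-chi-square
  (ν₀ = 5, s₀² = 0.05 by default), the right-skewed shape seen in real
  array data, which is what makes the Fs shrinkage estimator's benefit
  visible.
* Within-pathway dependence is injected as equicorrelation through one
  shared latent factor per set — the simplest structure that violates
  gene-independence assumptions; a gene in several sets loads on its first
  set's factor.
* Dye bias is an additive polynomial trend of M in centred A, default
  (0.3, −0.35, −0.02): a dominant linear component with mild curvature,
  like the banana-shaped MA clouds of real two-color scans.
* Baseline log2 abundances are uniform on (6, 14); single-channel arrays
  add a background floor N(6, 0.5²) on the log2 scale shared by negative
  controls and (as a noise component) by target probes, with targets
  sitting a configurable margin above it.
* Ct tables follow Ct = baseline − log2(expression) + N(0, 0.25²) per
  well, with duplicate wells and zero treatment effect on housekeeping
  genes.
* All randomness flows from one integer seed through a single
  `numpy.random.Generator`; fixed seed ⇒ bit-identical output.

What it does **not** emulate: spatial array artifacts, print-tip effects,
scanner saturation, background subtraction (the pipeline takes
non-background-subtracted data as given), batch effects, or heavy-tailed
outlier contamination. Passing tests therefore demonstrate correctness of
the statistics under a clean generative model, not robustness to every
failure mode of real scans.

## Problem sizes and numerical choices

The simulation-based checks use 500 null datasets (1000 genes, 8 samples
per group, 500 resamples) for the level of the set tests, 200 runs for
their power against a 2-log2-unit shift on one 50-gene set among ten, and
400 null Ct datasets for the REST test's level — sizes at which the 99%
binomial band around the nominal 0.05 is a few percentage points wide and
the whole suite runs in well under a minute per check. Tolerances follow
the quantity being tested: exact assertions for closed-form arithmetic,
1e-10 for algebraic identities, 3×SE bands for Monte-Carlo means, and 99%
binomial confidence bands for rejection rates. Permutation and bootstrap
p-values live on the grid k/(B+1), so uniformity checks use B large enough
(≥500) that the grid spacing is far below the KS critical value.

## Known limitations

* Only two treatment groups; dye-swap designs and multi-factor layouts are
  not modelled.
* The permutation and bootstrap schemes assume exchangeable samples within
  the design; paired or blocked structures are not supported.
* Gene identifiers are opaque, case-sensitive strings; no symbol aliasing
  or annotation mapping is attempted.
* The rank-based test's global ranking is mildly competitive (see above);
  use `rank_scope="within-set"` to assess sensitivity.
* REST is implemented as its core fixed-reallocation randomization on
  ΔCt; the pairwise efficiency-corrected variant is out of scope.
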