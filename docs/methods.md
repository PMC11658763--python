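# Methods

## The model

For one gene or transcript, let `Y_ij` be the aligned length (nt) of read
`i` in library `j`, `cond_j ∈ {0,1}` the library's condition (0 = declared
reference/control) and optionally extra per-library covariates. The mixed
model is

    Y_ij = β0 + β_cond·cond_j + u_j + ε_ij,
    u_j ~ N(0, σ²_lib),  ε_ij ~ N(0, σ²),

with one random intercept per library. `β_cond` is the treated-minus-control
mean length difference; negative means shorter under treatment. With
`logscale` the response is `log2(Y)` and `β_cond` a log₂ fold change (lengths
are ≥ 1 nt by construction, so no offset is needed). The random intercept
absorbs replicate-level length shifts (flow-cell and prep effects) and
prevents deep libraries from dominating: without it, reads within a library
are treated as independent and the effective sample size is overstated
(pseudoreplication). Two simpler models are provided — OLS/pooled t-test and
Wilcoxon rank-sum — but they share that weakness, which the simulation study
below makes visible.

Assumptions: Gaussian read lengths around the library-shifted condition mean;
a single library variance common to both conditions; libraries nested within
condition; reads independent given their library.

## Fitting and inference

The random-intercept model has a single variance ratio θ = σ²_lib/σ².
Profiling: for fixed θ, the GLS estimate of β and the residual variance are
closed-form via per-library sufficient statistics (`V_j⁻¹ = I − c_j·J` with
`c_j = θ/(1+n_jθ)`), so the (restricted) log-likelihood reduces to a
one-dimensional function of log θ, maximized by bounded scalar search on
log θ ∈ [−15, 15] and compared explicitly against the θ = 0 boundary. A
boundary fit coincides exactly with OLS and is flagged (`status="boundary"`);
an outright failure (e.g. rank deficiency) falls back to the fixed-effects
fit, flagged `fallback_ols`, so no feature is silently dropped. Each
evaluation is O(n), giving ~3 ms per gene; the fitter reproduces lme4's
estimates (β, SE, σ²_lib, σ²) to all printed digits under both REML and ML
(cross-checked in the test suite via Rscript, and against a dense-matrix
likelihood oracle).

Defaults, and why:

* **REML, not ML** (`reml=True`, switchable). ML variance estimates are
  biased low when the number of libraries is small; with 6 libraries this
  bias propagates into the Wald SE.
* **t reference with Satterthwaite degrees of freedom**
  (`df_method="satterthwaite"`). The library effect dominates the sampling
  variance of β_cond, so its uncertainty carries roughly the few-groups df
  (≈ 4 for a 3-vs-3 design), not the thousands-of-reads df; a normal
  reference yields null rejection rates of 0.13–0.19 at α = 0.05 under the
  validation design below, versus 0.04–0.05 for REML with Satterthwaite.
  The df is computed as `2·Var(β̂_k)² / Var(Var(β̂_k))`, with the
  variance-component covariance taken as the inverse observed REML
  information (finite differences on (σ²_lib, σ²)); it reproduces
  lmerTest's analytic df to all printed digits in the cross-check tests.
  Simpler alternatives are exposed: `between_within`
  (df = n_libraries − n_fixed_params, exact under balance) and `normal`.
  Boundary fits (σ̂²_lib = 0) carry the OLS residual df.
* **Wilcoxon**: exact null distribution when the smaller group has ≤ 8
  observations and the data are tie-free, otherwise normal approximation with
  tie and continuity correction. The reported estimate is the difference of
  group medians, a descriptive companion to a rank-based p.
* **Multiple testing**: Benjamini–Hochberg step-up across all features with a
  finite p (default), plain Bonferroni behind a flag. Adjusted p-values are
  clipped to [0,1] and never smaller than the raw p.
* Two-sided tests throughout; direction is read off the estimate's sign.

## Ingest conventions

Read length is the *reference-aligned span* on the transcript
(`three_p − five_p`, 0-based half-open), not the basecalled query length:
soft-clipped adapter and poly(A) bases are excluded, so the span measures the
templated RNA. Only primary mapped alignments contribute. Poly(A) QC joining
keeps exactly the reads tagged `PASS`; reads absent from the QC table are
dropped (unknown ≠ pass). The minimum-read filter (default 5) applies per
condition — both sides must reach the threshold, since a test needs
observations in each group. Adapter status comes from an external read-ID
list produced by upstream trimming; this module never inspects sequence.

## Simulation design

The generator draws from the fitted model itself: per gene, each library gets
`u_l ~ N(0, (0.10·L)²)`; control reads are `N(L + u_l, (0.20·L)²)` and
treated reads `N(pL + u_l, (0.20·pL)²)` for shortening proportion `p`,
truncated below at 1 nt by resampling (vanishingly rare at these SDs;
resampling rather than clipping keeps the distribution smooth). Defaults:
`L = 1000` nt, 3 control + 3 treated libraries, 1000 genes per cell, counts
10–200 reads per library per gene, proportions 0.5–1.0 with 1.0 the null.
Because all variances scale with `L`, a single true length loses no
generality. The residual SD is proportional to the *condition-specific* mean
(treated reads are shorter and proportionally less variable); the grand-mean
reading is available via `err_mean="grand"`. Lengths are rounded to integer
nucleotides when emitted as a length table.

Seeding: one master seed spawns a `SeedSequence` substream per gene, and each
grid cell derives its seed from (study seed, count, proportion), so any cell
is reproducible in isolation and adding cells never perturbs the others.
Identical seed + scenario gives byte-identical summary TSVs.

What the generator does *not* emulate: basecalling error, alignment
artifacts, 3'-end variation, non-Gaussian length multimodality (e.g. discrete
decay intermediates), or expression-dependent library composition. Passing
tests therefore demonstrate correctness of the statistics under the model's
own assumptions, not robustness to every artifact of real nanopore data.

Under this design the mixed model holds the null rejection rate at α and
recovers the true difference without visible bias at counts ≥ 50, while the
pooled t-test and Wilcoxon reject 20–80% of null genes depending on depth —
the expected pseudoreplication failure, and the reason the LMM is the
default.

## Transcript anatomy

* **Meta-length**: transcripts are divided into 20 equal bins (0–19). The 5'
  end maps to `floor(five_p·20/L)`; the half-open 3' end to the bin
  containing its exclusive endpoint, `ceil(three_p·20/L) − 1`. Both are pure
  functions of the coordinate/length ratio, making meta-coordinates exactly
  invariant under joint scaling of read coordinates and transcript length.
  Meta-length = (bin3 − bin5 + 1)·5%, so a full-length read is exactly 100%
  and a single-bin read 5%; the bin-difference-only alternative (full length
  = 95%) was rejected because percentages should saturate at 100.
* **TSS calling**: read 5' ends are pooled across replicates; the TSS is the
  position inside the annotated 5' UTR (coordinate < CDS start) with maximal
  5'-end count, requiring ≥ 5 supporting reads (configurable). Ties break
  toward the 5'-most position, favoring the longest plausible start.
  Transcripts without a UTR annotation are skipped with a log entry.
* **Composition**: reference-transcript bases (U as T) are tallied at offsets
  in a ±10 nt window (configurable) around each read 5' end; offsets falling
  outside the transcript are skipped, not padded, and frequencies are
  normalized per offset over counted bases only.

## Numerical and degenerate-input policy

Zero residual variance (constant lengths) is an explicit
undefined-statistic error, surfaced per feature as a flagged result rather
than a silent p = 0 or a dropped row. Constant data under Wilcoxon returns
p = 1. The condition factor's reference level is always declared, never
inferred from sort order. Validation errors carry row numbers and offending
identifiers.

## Problem sizes

The validation suite and the acceptance script run the full published-scale
design — 1000 genes per grid cell over counts {10, 50, 100, 200} and
proportions {0.5, 0.7, 0.9, 1.0} — which completes in a few minutes on one
CPU thanks to the profiled-likelihood fitter. The estimate-recovery check
alone uses 3000 genes per cell (counts {50, 200} × proportions
{0.5, 0.7, 0.9}): a ±5 nt accuracy band at proportion 0.9 needs a
Monte-Carlo SE of the mean estimate well below 5 nt, which 1000 genes
(SE ≈ 2.7 nt) cannot deliver. Monte-Carlo checks of
monotonicity (power in depth, power in effect size) and of bias shrinkage
compare noisy estimates, so they carry a two-standard-error allowance; rate
checks against α use three binomial standard errors at 1000 genes
(≈ [0.029, 0.071]).

## Known limitations

* Two-condition designs only; no paired or longitudinal structure.
* One random intercept (library); no crossed or nested random effects, and
  library variance is assumed equal across conditions.
* The Satterthwaite df relies on a quadratic approximation of the REML
  surface; very small variance ratios near (but not at) the boundary can
  make it unstable, in which case the computation falls back to
  between-within df.
* All coordinates are transcript-space; genome-space (spliced) analyses are
  out of scope.
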