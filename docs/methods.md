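# Methods

This note records the statistical model behind `dyncross`, the defaults
that matter, the design choices that were genuinely open, and what the
synthetic benchmarks can and cannot establish.

## Observation model and preprocessing

Each gene's measurements under one condition are treated as noisy
discrete observations of a smooth signal:

    Y_ij(t_k) − μ_ij = X_ij(t_k) + E_ij(t_k),   E i.i.d., mean 0, variance σ²

with a single noise variance shared across genes (homoscedastic by
default; per-gene noise would be a straightforward extension but is not
the model the test assumes).  Replicates are collapsed by their
per-gene, per-time **median** — robust to single outlying arrays — before
any smoothing.  Values are expressed as fold change over the control
baseline at time 0 and log2-transformed by default (`log2=False` gives
raw ratios); profiles are then centered by their temporal mean μ_ij.
The log2 default exists because every downstream rule (rank
correlations, the 1.96 range cutoff) presumes a scale where up- and
down-regulation are symmetric.  A control baseline of exactly zero is an
error, never clamped.  Cells missing in some replicates use the median
of the present ones; a gene missing an entire time point is dropped with
a logged warning.

## Smoothing and the dynamic-gene test

The smooth signal is estimated by a natural cubic smoothing spline
(Reinsch/Green–Silverman form), with the penalty weight λ selected by
generalized cross-validation over a fixed grid of 50 log-spaced values
spanning 1e−8…1e8 — wide enough to range from near-interpolation to a
near-linear fit on hour-scale grids, and fixed so results are exactly
reproducible.  Because the smoother matrix does not depend on the data
scale, the selected λ (hence the F-ratio below) is invariant to
rescaling a profile.

Two numerical choices deserve note:

* **Residual-df guard.**  For testing, the λ grid is restricted to
  smoothers with effective degrees of freedom ≤ K − 2.  On some noisy
  profiles plain GCV degenerates to interpolation (edf → K), which
  leaves the F-ratio with no residual degrees of freedom and a
  meaningless p-value.
* **Derivative boundary condition.**  Derivatives (needed by the ODE
  stage) are computed from the *not-a-knot* cubic interpolant of the
  smoothed values.  The natural spline's zero-curvature end condition is
  an artifact of the roughness penalty; carrying it into differentiation
  produces errors two orders of magnitude larger, spread well into the
  interior through the tridiagonal solve.

A gene is a **dynamic response gene** when `H₀: X(t) ≡ 0` is rejected.
The statistic compares the null RSS (Σy² on the centered profile; the
centering mean absorbs one df) with the spline fit's RSS at its
effective df.  Two null distributions are implemented:

* `method="permutation"` (default): shuffle the time labels, refit
  everything, recompute F; `p = (1 + #{F_perm ≥ F_obs})/(B + 1)` with
  B = 199.  This is exact under i.i.d. noise.  It is the default because
  the adaptive λ selection makes the parametric reference visibly
  anticonservative (simulated null rejection ~0.10–0.12 at nominal
  0.05), while the permutation version sits on the nominal level.
* `method="f"`: the F(edf − 1, K − edf) reference; fast, adequate for
  ranking, not for calibrated error control.

Multiple testing uses Benjamini–Hochberg FDR at α = 0.05 by default
(`bonferroni` and `none` are available).  At least 8 time points are
required; the 14-point/24-hour default design is comfortably above that.
Attainable p-values are floor-limited (permutation resolution 1/200;
few residual df in the parametric form), so "significance" claims below
~1e−3 per gene are not meaningful at this K.

Genes are additionally ranked by profile interquartile range
(linear-interpolation quantiles; ties broken by gene id), and the top
3,000 genes by F-ratio per condition feed the clustering stage so module
counts are comparable across conditions with very different numbers of
dynamic genes.

## Iterative hierarchical clustering

IHC reconstructs temporal modules in three phases: (1) average-linkage
hierarchical clustering on the distance 1 − ρ_Spearman, cut at
1 − 0.7; then iterate (2a) merge any two clusters whose mean curves
correlate at ρ ≥ 0.7, best pair first; (2b) reassign every gene to its
best-correlating cluster mean provided ρ ≥ 0.7, otherwise it becomes a
singleton; (2c) recompute means — until the partition stabilizes or 100
iterations.  Spearman (not Pearson) is used throughout for consistency
with the cross-condition comparison machinery.  Reassignment ties go to
the smaller cluster index; a constant profile (undefined ρ) is treated
as similar to nothing and drifts to a singleton.  Modules are numbered
by size, GRM1 largest; "large-size" modules have ≥ 70 members
(boundary inclusive).  Cross-condition module matching is greedy on the
mean-curve ρ, which on well-separated modules coincides with the optimal
assignment (verified against brute force in the tests).

## Sparse linear-ODE network

Module mean curves enter per-target rate equations
`dM_q/dt = α₀q + Σ_p α_pq M_p`.  The response is the analytic spline
derivative of the smoothed mean curve (no finite differences); the
design holds the smoothed curves; the first and last time points are
excluded from the regression because the derivative estimate is least
reliable at the window boundaries.

Support selection is the genuinely hard part of this regime (K ≈ 14
observations, Q ≈ 10 correlated regressors).  The implementation scores
the best candidate support of each size 0…3 — found exhaustively for
Q ≤ 12, along the lasso (LARS) path above that — with an extended BIC,

    RSS/σ̂² + df·log K + 2γ·log C(Q, df),   γ = 2,

where σ̂² is referenced to the best model at the *largest* candidate
size.  Profiling the variance per candidate (the classical log-RSS BIC)
collapses toward the saturated model whenever the derivatives are nearly
noiseless, and the fully saturated fit has too few residual df to
estimate σ² honestly; the max-candidate-size reference avoids both
failure modes.  The winner is pruned backward: drop the weakest
coefficient while its |t| < 2 *or* its contribution is under 5% of the
response sd (terms below that absorb smoothing bias, not regulation).
Finally OLS refits the surviving support; coefficients below 1e−8 are
zeroed.  Edge sign encodes stimulation (+) vs inhibition (−);
self-regulation is allowed.  The selector is pluggable
(`selector="none"` keeps the full support, `fixed_support` refits a
given topology).

## Network statistics

All metrics ignore self-loops and treat edges as unweighted.
Betweenness is the unnormalized shortest-path count form, summed over
ordered pairs s ≠ t with both endpoints distinct from v and at least one
path; endpoints never count as pass-throughs (Brandes' algorithm, which
the tests verify against exhaustive path enumeration).  Density is
(non-self edges)/(n(n−1)).  The clustering coefficient is computed on
the undirected projection — directed clustering has several inequivalent
definitions and nothing downstream depends on the distinction — with
degree-<2 nodes contributing 0 and the mean over all nodes.  "Important"
modules are those in the top k = 20 (ties at the cutoff included) or at
the 95th percentile of in-degree, out-degree or betweenness; both modes
exist because both conventions are in circulation, and neither is
privileged.

## Cross-talk and co-activation rules

On smoothed centered curves (raw-curve mode available):

* differential activity between two conditions: Spearman ρ < 0.7
  (strict, with a 1e−9 guard so a ρ that equals 0.7 in exact arithmetic
  is not pushed over the edge by floating point);
* significant variation: range ≥ 1.96, the two-sided 5% normal critical
  value, meaningful because profiles live on the standardized
  (log2 fold-change, centered) scale;
* cross-talk (all six): differential SHH vs CTRL; variation under SHH;
  differential EGF vs CTRL; variation under EGF; differential EGF+SHH
  vs SHH; differential EGF+SHH vs EGF;
* co-activation (all three): *no* differential SHH vs CTRL; *no*
  differential EGF vs CTRL; differential EGF+SHH vs SHH.  (As printed,
  the co-activation list has no variation requirement of its own; the
  stricter reading is not imposed.)

The first rules of the two lists conflict, so the classes are mutually
exclusive by construction.  One reading of "differential" was genuinely
open: a statistically flat profile carries no rank information — after
smoothing it becomes an arbitrary gentle trend whose ρ with a real
response is spurious (empirically it can exceed 0.7 against monotone
templates).  The default therefore declares two curves differential when
ρ < 0.7 **or** exactly one of them shows significant variation
(`differential_mode="rho_or_variation"`); the ρ-only literal rule
remains available (`"rho"`).  A truly constant curve (undefined ρ) is
differential with a flag under both modes.

Screening is two-stage, mirroring how module-level structure guides
gene-level claims: modules are clustered under a reference condition
(SHH by default), each module's per-condition mean curves are
classified, and the genes inside qualifying modules are re-classified
individually; a gene keeps a label only when both stages agree.  Genes
missing under some condition are reported as unevaluable, never dropped
silently.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the analysis
assumes: 4 conditions × 14 time points over 24 h × 3 replicates;
centered log2 fold-change scale (μ_ij = 0 by construction); smooth
per-gene signals (random natural cubic splines through 6 control
points) plus i.i.d. Gaussian noise with one σ.  Defaults: template
range 3.0 (≈ 8-fold swing, typical of strongly responsive genes, and
above the 1.96 variation cutoff), noise sd 0.3 (a realistic
replicate-level log2 dispersion for array data), 500 genes of which 300
dynamic in 5 modules.  Since the real study reports no amplitude or
variance scale, these are calibration choices, not measured values.
Templates are drawn until pairwise ρ < 0.5 — stricter than the 0.7 rule
by a margin that survives noise.  Cross-talk genes are flat under CTRL,
follow template A under SHH, B under EGF and a dissimilar C under
co-stimulation; co-activation genes share one template under
CTRL/SHH/EGF and switch only under co-stimulation; background dynamic
genes keep their module template everywhere.

Planted ODE systems need care: from a single trajectory of a *generic*
sparse random system the fast modes die immediately and the design of
module curves is numerically rank-deficient (condition numbers 1e13+),
so no method could recover the support — the failure is in the data, not
the estimator.  The generator therefore builds identifiable systems:
modules paired into antisymmetric rotation blocks with stratified
frequencies (purely imaginary spectrum — every mode persists and the
frequencies decorrelate the curves), plus acyclic feed-forward couplings
between consecutive blocks (nilpotent, spectrum unchanged).  Non-root
modules have exactly two regulators, root-block modules one.
Coefficient magnitudes are uniform in [0.5, 1] with random signs on the
couplings; observation noise sd 0.02 on the sampled curves.

What passing the synthetic benchmarks does **not** show: robustness to
probe-level artifacts, normalization residue, heteroscedastic or
autocorrelated noise, unequal time grids across replicates, modules with
overlapping membership, or nonlinear/time-varying regulation.  Real
microarray data contain all of these; the benchmarks certify the
pipeline's logic under its own model, nothing stronger.

## Problem sizes and determinism

The bundled tests and the acceptance script run at desk scale — 10,000
null genes for calibration, 1,000 genes for detection recovery, 250
profiles for clustering, 10-module networks, 500-gene studies — sizes at
which every stage completes in seconds while leaving the statistical
questions intact.  All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical config + seed reproduces every
artifact byte for byte, and the tests assert this end to end.

## Known limitations

* The permutation test's p-resolution is 1/(B+1); with B = 199 the
  smallest attainable p is 0.005, which matters if α ≪ 0.05.
* IHC is a fixed-point iteration without a global objective; it can in
  principle cycle (capped at max_iter) and its module count is only
  empirically monotone in the similarity threshold.
* The ODE stage identifies regulation only up to what one trajectory
  exposes; strongly collinear module dynamics in real data will yield
  sparse but non-unique supports, and the condition number is logged as
  a warning for exactly this reason.
* Per-subject structure is collapsed before fitting (replicates are
  medians); subject-level mixed effects are out of scope.
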