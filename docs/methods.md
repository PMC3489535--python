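# Methods

## Data model and design inference

The unit of observation is one quantified LC-MS feature (peptide
sequence + charge) in one run. Input is a long-format delimited table
with columns `ProteinName, FeatureName, <factors…|Condition>,
BioReplicate, Run, Intensity`. A condition is the cross of the declared
factor levels, joined by `:` in declared factor order; factor- and
condition-level order is first appearance in the file, and the first
level of everything is the reference cell of the treatment coding.
Intensities must be positive on the raw scale; a missing peak is an
empty cell or an absent row (both accepted; canonical output writes
explicit empty cells). Log transform defaults to base 2 so contrast
estimates read directly as log2 fold changes; bases 10 and e are
supported.

The experimental structure is inferred, not declared: every run maps to
one (condition, subject, technical-replicate) triple; re-use of a
subject identifier across conditions switches the model to its
repeated-measures variant. A dataset is *balanced* when every condition
has the same number of runs, technical replication is uniform and no
cells are missing — the regime in which the closed-form df and power
expressions hold.

## Normalization

Two optional normalizations operate on the log scale:

* **constant** — each run is shifted so all run medians equal the median
  of the per-run medians (mean-equalization available via
  `center="mean"`). Shift invariance guarantees within-run differences
  are untouched. The exact published recipe behind "constant
  normalization" is not fully specified in the literature this package
  follows; median equalization is this package's documented choice.
* **quantile** — the r-th smallest value in each run is replaced by the
  mean over runs of the r-th smallest values; requires a complete table
  with equally sized runs (the noise-floor-reporting regime), ties
  averaged.

## Per-protein models

`y_ijkl = μ + F_i + C_j + (F×C)_ij + S(C)_k(j) + ε_ijkl` with
`ε ~ N(0, σ²_Error)`. Feature terms (and the feature×condition
interaction, which models interferences) exist only for proteins with
≥ 2 features; single-feature proteins and feature-level analysis use the
same machinery without them. A separate design matrix is built per
protein because feature counts differ.

**Subject terms.** In the nested (factorial) case, subject fixed effects
are included in the reduced scope whenever they are identifiable — i.e.
when there is technical replication (L ≥ 2) or at least two features.
With a single feature and single runs the subject effect is confounded
with the error and is dropped with a warning; in that degenerate case the
reduced-scope contrast test coincides *exactly* with the classical pooled
two-sample t-test, which is the sense in which the naive analysis is a
special case of the model. When subject terms are identifiable, the
balanced residual df equals the closed form `IJK(L-1) + (I-1)J(K-1)`.
For repeated measures the nested term is replaced by a global subject
term; with L = 1 any subject×condition interaction is absorbed into the
error (this is an interpretation of the time-course variant of the
model, chosen here and configurable only by pre-filtering the data).

**Reduced scope** is fit by weighted least squares;
`Cov(θ̂) = σ̂²(X'WX)⁻¹`, `σ̂² = weighted RSS / (n − p)`. Rank deficiency
caused by missing cells is resolved greedily in term-priority order
(intercept, condition, feature, subject, interaction), so aliasing drops
interaction/subject columns first; dropped interaction columns are
pinned to zero in all linear combinations, and an aliased condition
column marks that condition untestable for this protein rather than
failing the batch.

**Expanded scope** replaces the fixed subject effects by a random
intercept `S ~ N(0, σ²_S)`. Because there is exactly one variance
component, the marginal covariance is block diagonal by subject and the
REML criterion is profiled in closed form over λ = σ²_S/σ²_Error: each
block contributes `(I + λJ)⁻¹ = I − λ/(1+n_sλ)·J` and
`log|I + λJ| = log(1 + n_s λ)`. The 1-D profile is maximized by a
bounded search on log₁₀λ (range 10⁻⁸–10⁴) compared against the λ = 0
boundary; σ̂²_S is therefore floored at zero, where the fit degenerates
to OLS on the fixed effects with a warning. statsmodels `MixedLM` serves
as an independent oracle in the test suite, not as the implementation.

**Iterative least squares / loess weighting** (reduced scope): fit,
smooth |residual| against fitted value with a loess curve (statsmodels
`lowess`, local-linear), set each observation's weight to
1/(predicted |residual|)², refit, and stop when the maximum relative
coefficient change falls below `tol` or after `max_iter` refits.
Defaults: span 0.75, max_iter 10, tol 10⁻³. The loess prediction is
floored at 10⁻⁶ before inversion and weights are rescaled to mean 1
(WLS point estimates and t statistics are invariant to weight scale);
one loess curve is fit per protein. The originating literature states no
constants for this procedure; these are the package's defaults.

## Inference

A comparison is a zero-sum map condition → coefficient (±1 pairwise,
±1/2 to average over levels of another factor). Each condition mean is
the linear combination: intercept + condition effect + the average of
the feature (and interaction) terms over the protein's features + (in
the reduced scope) the average of the subject effects over the subjects
observed in that condition. Contrast estimate `c'θ̂`, standard error
`sqrt(c'Cov(θ̂)c)`, two-sided p from Student t.

Degrees of freedom: reduced scope uses the residual df of the weighted
fit (equal to the printed balanced formula whenever subject terms are
identifiable, and well-defined for unbalanced data). The expanded scope
uses a **Satterthwaite approximation**: `df = 2g²/(∇g' A ∇g)` where
`g(σ²_Error, σ²_S) = c'Cov(θ̂)c`, the gradient is computed by central
finite differences, and `A` is the inverse observed REML information
(finite-difference Hessian of the closed-form REML log-likelihood). At
the σ²_S = 0 boundary or a degenerate information matrix the df falls
back to n − p. The df method for the expanded scope is not prescribed by
the originating framework ("appropriate degrees of freedom"); the
Satterthwaite choice is this package's and the fallback is documented
here.

FDR is controlled per comparison label across proteins with
Benjamini–Hochberg (statsmodels `multipletests`); a brute-force step-up
oracle validates it in the tests. If SE = 0 (noise-free or saturated
fits) the p-value is set to 0 when the estimate is non-zero and 1
otherwise, with a `degenerate` status.

## Quantification

Condition-level estimates use the same condition-mean combination with a
t-based CI at the inference df (default level 0.95; reported on the log
scale — exponentiation is left to the user so that SEs remain
interpretable). Sample-level estimates use the subject's own fixed
effect (reduced) or shift the condition mean by the BLUP
`n_s σ̂²_S/(σ̂² + n_s σ̂²_S) · (mean residual of the subject)` (expanded);
with σ̂²_S = 0 the sample estimate collapses to the condition estimate.
The subject-level expanded-scope quantity is a documented extension of
the condition-level linear-combination rule. Estimates are comparable
across conditions and samples within a protein, never between proteins
(relative, not absolute, quantification).

## Missing peaks

Scattered missingness is tolerated by the model as long as each feature
keeps at least one intensity per condition; such cells are never
imputed. A feature missing entirely in ≥ 1 condition triggers one of
three treatments, applied uniformly to all affected proteins in a run:

1. `impute_min`: fill the empty (feature, condition) cells with the
   average minimum log-intensity across runs. The per-run minimum is
   taken over all observed values of the run and averaged over **all
   runs of the experiment** (the global pool); the sentence defining
   this value is ambiguous between a global and a per-condition pool, so
   the pool is switchable (`pool="condition"`). Imputed cells are
   flagged in the output and in the comparison status column.
2. `no_interaction`: keep the data, drop the feature×condition
   interaction (assume no interference).
3. `remove_feature`: drop the feature; a protein losing all its features
   is skipped with a recorded status.

## Power and sample size

For balanced designs, `δ ≥ sqrt(σ²_Error/(IKL)) · (t_{1-β,df} +
t_{1-α/2,df})` with `df = IJK(L-1) + (I-1)J(K-1)` and
`α = (1-β)q / (1 + (1-q) m0/m1)`. Minimal sample size searches the
smallest integer K meeting a target δ and exposes the δ-vs-K curve. The
expanded-scope variant uses `σ²_Error/(IKL) + σ²_S/K` with
between-subject df `J(K-1)`; the exact expanded/time-course formulas are
not printed in the main text this framework derives from, so this
variant is labeled an interpretation and kept configurable. Data-driven
defaults from a fitted analysis: σ̂² = median residual variance, I =
median feature count, and m0/m1 = (#non-significant)/(#significant) at
the user's q, floored at 1. Power for unbalanced future designs is out
of scope.

## Synthetic data

The generators produce data from exactly the model above, on the log2
scale, with a complete truth ledger (condition means, feature offsets,
subject effects, differential flags) so the expected value of every cell
is determined. The factorial emulator reproduces the 2×2×2 × K=2 × L=3
(48-run) structure with 2–19 features per protein; the time-course
emulator reproduces 14 repeated-measures disease subjects (with week
dropout; the first two subjects are kept complete so no week empties
out) plus 29 single-visit controls (43 subjects), single runs, and an
optional constant noise floor standing in for absent peaks. Defaults —
σ_Error = 0.3, σ_S = 0.3 (log2), baseline N(17, 1.5), feature offsets
N(0, 2), differential fraction 0.2 with log2 effects {0.5, 1, 2} — are
chosen as realistic desk-scale values; no variance magnitudes are
published for the archetype datasets, so these defaults are synthetic by
construction. An `error_sd_slope` option makes the error SD grow with
the expected abundance for heteroscedasticity studies;
`inject_missing` and `inject_interference` add condition-empty/random
missingness and profile distortions.

What passing tests on these data do **not** show about real data: real
LC-MS intensities are not exactly Normal on the log scale, interferences
are not additive constants, missingness is abundance-dependent rather
than random, and run-order or batch effects are absent from the
generator entirely.

## Scope trade-off and the null used for calibration checks

The reduced scope tests contrasts against technical error only: when
true between-subject variation exists, it gains sensitivity but loses
specificity — on an artificial split of one condition's biological
replicates it will declare differences (which are real subject
differences) while the expanded scope declares essentially none. The
calibration test suite therefore checks each scope against its own null:
the expanded-vs-reduced discovery-count ordering is verified on a split
with σ_S > 0, and empirical-FDR control is verified on data where the
null holds at the technical level (σ_S = 0) for both scopes, plus under
σ_S > 0 for the expanded scope. Population-level FDR control by the
reduced scope under σ_S > 0 is *not* claimed — the trade-off is the
point, not a defect.

## Problem sizes and numerical notes

Simulation-based checks use 150–1000 proteins per scenario and 200
replicate fits for variance-component recovery; these sizes put
Monte-Carlo error comfortably inside the asserted bands while keeping
the suite desk-scale. Deterministic seeds are fixed in the tests and
threaded from `--seed` in `scripts/acceptance.py`. Degenerate inputs:
saturated fits report σ̂² = 0 and a flagged SE = 0 path; a protein with
no observed cells, or none left after feature removal, is quarantined
with a recorded reason and never aborts a batch; proteins are always
processed in sorted order so all outputs are byte-deterministic.

## Known limitations

No moderated/empirical-Bayes variance shrinkage, censored-likelihood or
presence/absence treatment of missingness, robust regression, or
per-feature-per-condition variance parameters (deliberately excluded —
the last would explode the parameter count). Upstream signal processing
(feature detection, alignment, identification, protein grouping) and
downstream clustering/classification of quantified profiles are out of
scope; the quantification TSV is shaped to feed such tools.
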