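# Methods

This note documents the statistical machinery implemented in `arqsar`, the
choices made where conventions vary, and what the synthetic benchmarks do and
do not demonstrate.

## Data model and curation

Descriptor tables are dense numeric matrices (compounds × descriptors) with
unique, order-preserving labels; missing or non-finite cells are load-time
errors, not imputation targets, because descriptor generators emit complete
matrices and a silent fill would corrupt leverage and regression algebra
downstream.

Curation applies two filters before variable selection:

* **Constant / near-constant removal.** A column is dropped when its sample
  standard deviation is zero, or when its SD divided by the largest column SD
  falls below a fraction (default `1e-4`). The relative form makes the rule
  scale-free across heterogeneous descriptor families; the default only
  removes columns that are numerically constant for all practical purposes.
* **Pairwise-correlation pruning** (cutoff |r| > 0.98, Pearson). Applied
  iteratively: while any pair exceeds the cutoff, the worst-offending pair is
  found and the member with the larger mean absolute correlation against all
  other surviving columns is dropped (ties drop the later column). Iteration
  guarantees the survivor set contains no above-cutoff pair — a one-pass
  variant does not — and the greedy "most redundant member" rule keeps the
  column that carries more independent information. The procedure is fully
  deterministic and every drop is reported with its partner and r.

## OLS and the Friedman lack-of-fit score

Subset models are ordinary least squares with an always-included intercept.
The genetic search scores a p-descriptor subset by

    LOF = SSE / (1 − (c + d·p)/n)²

with c = p + 1 basis functions (descriptors + intercept) and smoothness
d = 0.5. LOF is strictly increasing in SSE and, at fixed SSE, in p, so it is
a size-penalised SSE; c and d are configurable but the defaults are the
conventional ones. The penalty denominator must be positive: (c + d·p) ≥ n
is rejected as degenerate.

Two OLS paths exist deliberately. The public `fit_ols` solves by
rank-revealing least squares and raises on rank deficiency. The GA inner
loop, which evaluates ~10⁴–10⁵ subsets, precomputes the full Gram matrix
(X̃ᵀX̃, X̃ᵀy including the intercept column) once and solves each subset's
normal equations by Cholesky factorisation in O(p³), treating factorisation
failure as infinite fitness. A test asserts both paths agree.

## Genetic algorithm

A minimal generational GA over fixed-size descriptor subsets: tournament
selection (size 2), uniform subset crossover (each gene drawn from either
parent; duplicate genes repaired by random resampling from unused indices),
per-gene mutation replacing an index with a random unused one (probability
0.05), elitism (2), crossover probability 0.9 (a standard generational GA
setting; the value is configurable). Defaults: population 200, up to 10000
generations, early stop after 500 generations without improvement of the
best LOF. Elitism makes the best LOF non-increasing across generations. All
randomness flows from one seeded generator; a run is a pure function of
(data, config).

One detail matters on wide tables (hundreds of columns, tens of rows): the
population is kept **duplicate-free**. A child identical to an existing
member is pushed through additional single-gene mutations until novel
(bounded, so tiny search spaces where duplicates are unavoidable still
work). Without this the population collapses onto a single chromosome whose
single-swap neighbourhood is quickly exhausted, and the search stalls in
local optima far above the planted optimum; with it, the planted-subset
benchmark below passes.

The model size is fixed per run (the shipped published model has p = 4);
scanning sizes is an outer loop, not a GA degree of freedom.

## Validation statistics

* R² = 1 − SS_res/SS_tot; RMSE uses the 1/n convention (no d.o.f.
  correction) — this is the convention under which the published training
  RMSE reconstructs from the shipped activity table.
* Q²(LOO) = 1 − PRESS/SS_tot with LOO residuals computed by the exact
  hat-matrix identity e_i/(1 − h_ii); a brute-force n-refit oracle is kept in
  the code (`q2_loo_refit`) and equality to 1e-10 is asserted in tests.
  Points with leverage 1 make LOO undefined and raise.
* Q²(LMO): random out-groups of a given fraction (default 30%, 1000
  iterations, seeded). The default aggregation is the mean of per-iteration
  Q² values; a `pooled` aggregation (summing numerator and denominator over
  iterations before the ratio) is provided because per-iteration ratios are
  heavy-tailed for very small out-groups — pooled LMO at out-group size 1
  converges to Q²(LOO), the mean does not.
* External predictivity: Q²F1 (training-mean reference), Q²F2
  (external-mean reference), Q²F3 (per-compound training variance
  reference), and Lin's CCC. All are invariant to a common shift of y and ŷ,
  and CCC ≤ |Pearson r| with equality when means and variances match.
* Y-scrambling: permute y, refit the same subset, record R² and Q²(LOO) per
  iteration (default 5000). A real structure–activity relationship shows the
  unscrambled R² far above the scrambled distribution.

When checking against the shipped 2-decimal activity table, metrics are
compared within ±0.005 (rounding of the printed predictions); in pipeline
use they are computed from full-precision predictions. Two documented
anomalies in the shipped table: the training-set fit statistics (R² 0.760,
RMSE 0.226) reconstruct only when training compound 7's predicted value is
corrected from the printed 6.76 to 5.76 (as printed, R² ≈ 0.43) — the
correction is an explicit opt-in flag, never silent; and the published
prediction-set RMSE of 0.270 does not reconstruct from the table at all
(the table gives ≈ 0.163), so it is surfaced nowhere as a check.

## Applicability domain

Leverage h = x̃(X̃ᵀX̃)⁻¹x̃ᵀ with the intercept-augmented design, so training
leverages are the hat diagonal and sum to p + 1, matching the p + 1 in the
cutoff h\* = 3(p+1)/n. Standardized residuals divide by the sample SD
(ddof = 1) of the training residuals, with |value| > 2.5 flagged; external
compounds are standardized on the training scale. Williams points carry
(h, standardized residual, flags) for labelled compounds; Insubria points
carry (h, predicted activity, flag) for unlabelled screening compounds, with
the same h\*. Leverage is invariant to invertible affine recoding of the
descriptor columns and monotone in the distance from the training centroid
along a fixed direction — both tested numerically.

## Virtual screening

`predict` is a pure affine map matched by exact descriptor name; `screen`
attaches leverages and Y/N domain flags and ranks by descending prediction
with ties broken by ascending compound id (deterministic reports). Where a
published screen's descriptor values are unavailable but its predictions and
flags are printed (the shipped 110-compound table), ranking and hit
reporting run on those numbers via `results_from_predictions`; the package
is explicit that such predictions are consumed, not reproduced.

## MM/GBSA bookkeeping

Energy composition is pure addition over a per-complex term table:
ΔE_MM = ΔE_val + ΔE_ele + ΔE_vdw, ΔG_sol = ΔG_p + ΔG_np,
ΔE_bind = ΔE_MM + ΔG_sol, ΔG_bind = ΔE_bind + (−TΔS). The entropy column is
stored with the −TΔS sign so no hidden negation exists. ΔE_val defaults to 0
(single-trajectory convention, internal terms cancel). When a table already
carries ΔE_MM or ΔG_sol (published tables round each intermediate sum
independently), the given value is kept and only missing compositions are
computed; self-consistency of the two routes is asserted at the 2-decimal
print tolerance (≤ 0.015 kcal/mol). The nonpolar term ΔG_np = γ·SASA + β
uses γ = 0.0072 kcal mol⁻¹ Å⁻², β = 0.92 kcal mol⁻¹. Per-residue
decomposition filtering keeps residues with |total| ≥ 1.5 kcal/mol by
default, sorted by magnitude. No MD, GB, SASA or normal-mode computation
happens here — inputs are term tables exported from MD post-processing.

## Synthetic data

The generator emulates the statistical shape the pipeline assumes, not
chemistry: standardized Gaussian descriptor columns (defaults 29 train /
7 external / 110 screen rows × 358 columns), a planted linear signal on 4
random columns with intercept 6.5 and coefficients ±0.5–0.65 so simulated
activities land on a realistic pIC50 scale (~4.5–8.5), Gaussian noise
(default SD 0.2 pIC50 units), optional near-duplicate column pairs
(|r| ≈ 0.999) for pruning tests, and screening rows constructed inside and
outside the training leverage domain of the true-descriptor design (inside
rows by rejection sampling, outliers by scaling a random direction from the
training centroid outward until h > h\*, verified before return). Ground
truth (column names, coefficients, noise) is returned and written as sidecar
JSON.

What passing the synthetic benchmarks shows: the GA can recover an exact
sparse linear signal at the published-study n/p ratio (18 of 20 seeded replicates at
noise SD 0.2), the validation statistics behave as theory predicts, and the
domain machinery flags constructed extrapolations exactly. What it does not
show: performance on real descriptor families (correlated, heavy-tailed,
block-structured), robustness to activity measurement error beyond i.i.d.
Gaussian noise, or anything about descriptor semantics.

## Numerical and interface choices

* Exact name matching everywhere; compound ids are case-sensitive strings.
* Model JSON round-trips losslessly (floats serialised as JSON doubles).
* Seeds: every stochastic operation (GA, LMO, scrambling, simulation) takes
  an explicit seed and reports it; CLI reports echo the effective
  configuration, so reruns are byte-identical.
* Test and benchmark problem sizes (population 60–200, a few hundred
  generations, 50-instance oracle sweeps, 200 scrambling iterations) were
  chosen so the full suite runs in a few minutes on one core while still
  exercising the study-scale 29 × 358 search.
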