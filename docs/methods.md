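# Methods

## The model and its assumptions

`signda` tests, taxon by taxon, whether the relative abundance of a taxon
differs between two groups, without distributional assumptions on the
counts. All information enters through two tie-aware sign transforms
computed against a reference frame (RF) — a set `T_R` of taxa whose
relative abundances are approximately invariant across samples and
conditions, summarised per sample by `R_i = median{N_it : t in T_R}`.

With `I{a ≼ b} = I{a < b} + ½·I{a = b}`:

* the **S-sign** `I_i^S = I{N_i ≼ R̃_i}` indicates whether the taxon sits
  below a rescaled reference in sample *i*;
* the **R-sign** `I_ij^R = I{N_i/R_i ≼ N_j/R_j}` compares the taxon's
  relative abundance between samples *i* and *j*. It is evaluated in the
  cross-multiplied integer form `I{R_j·N_i ≼ R_i·N_j}`, so zeros never
  require pseudocounts and ties are detected exactly.

Both transforms are scale-invariant (rescaling any sample's counts
rescales `R_i` identically and cancels), subcompositionally coherent
(they depend only on the target taxon and the RF), and permutation
invariant — the three conditions for valid compositional analysis. The
validity of every downstream test is conditional on the RF containing no
differentially abundant taxa; this is an assumption about the data, not
a property the selector can guarantee (see *Limitations*).

Four null hypotheses are tested through regression models on the signs:

* **marginal-S** — `P{N ≼ R | A=0} = P{N ≼ R | A=1}`, via logistic
  regression of `I^S` on the group indicator `A`;
* **conditional-S** — the same equality at fixed library size `l`, via
  logistic regression on `A` and `L` (plus optional covariates);
* **marginal-R** — `P{N/R ≼ N*/R* | A=0, A*=1} = ½`, via a probabilistic
  index model (PIM) with pair covariate `A*−A`;
* **conditional-R** — the same at equal library sizes, via a PIM with
  pair covariates `(A*−A, L*−L, …)`.

In each case `H0: β_A = 0` and inference is a two-sided Wald test.

## Estimation details

**Logistic engine.** Newton–Raphson from `β = 0`, convergence when the
max score component is below 1e-8, 50 iterations maximum. S-sign ties
(`y = 0.5`) enter the Bernoulli log-likelihood as fractional responses —
a quasi-likelihood choice that preserves the estimating-equation mean
structure `E[I^S] = expit(x'β)`; ties are rare in practice. Separation is
declared when a coefficient passes |β| > 15 or the fitted probabilities
saturate (within 1e-8 of 0/1) at every non-tied observation; the policy
(`firth="auto"`) then refits with Firth's penalised likelihood
`l(β) + ½ log det I(β)`, whose estimates are finite for any full-rank
design. Firth can also be forced on or off. Covariates are centred and
scaled internally for conditioning; coefficients are reported on the
original scale.

**PIM engine.** Each unordered sample pair enters once, oriented `i < j`;
the reverse orientation is algebraically redundant because
`(I_ji, Z_ji) = (1−I_ij, −Z_ij)`. For the purely marginal model,
same-group pairs carry zero score and are skipped; conditional models
retain them because they inform the covariate coefficients. The
estimating equation `Σ Z_ij (I_ij − expit(Z_ij'β)) = 0` is solved by
Newton iteration (same tolerances as the logistic engine). The variance
is the U-statistic sandwich `A⁻¹ B A⁻ᵀ`: `A` is the derivative of the
estimating function, and `B` sums score cross-products over all ordered
couples of pairs sharing at least one sample index (including each pair
with itself), computed in O(pairs) by accumulating per-sample score sums.
A probabilistic index of exactly 0 or 1 on the informative pairs has no
finite solution; such fits are capped at ±15 on the logit scale, flagged,
and propagate as untestable (NA p) rather than as spurious certainties.
The marginal fit reproduces the tie-aware Mann–Whitney proportion
exactly, which is the identity the tests lean on as an oracle.

**Regression-imputation (RI) estimators.** Both RI estimators fit the
conditional model and then standardise its predictions over the empirical
covariate distribution, so the estimand keeps the *marginal*
interpretation while covariate information sharpens it. For S-signs:
`π̂(a) = n⁻¹ Σ_i p̂(a, L_i)` and
`exp(β̂_A^RI) = [π̂(1)/(1−π̂(1))]/[π̂(0)/(1−π̂(0))]`, with variance
`σ̂² = n⁻² Σ IC_i²` from the influence curve combining the two
group-specific residual-plus-prediction terms. For R-signs:
`β̂_A^RI = [n(n−1)]⁻¹ Σ_{i≠j} p̂(L_j, L_i)` (a probability, not a log
odds), with an influence curve built from observed cross-group
comparisons, the `−2β̂` centring, and a group-imbalance correction from
the predictions; the test statistic is `(β̂_A^RI − ½)/σ̂`. The variance
uses the squared influence contributions, `σ̂² = n⁻² Σ IC_i²` — the form
an influence-function variance requires and the form the S-sign analogue
takes; it is validated two ways in the tests: against the ground-truth
Monte-Carlo spread of the estimator over fresh datasets, and against a
nonparametric bootstrap (which resamples samples with replacement and
recomputes the per-sample reference on each resampled table). By default
the RI estimators use only the library size as auxiliary covariate: the
required independence `A ⫫ L` holds by design because sequencing depth is
technical; adding biological covariates shifts the validity burden onto a
randomised group assignment and is therefore behind an explicit argument.

**Reference frame.** The automatic selector filters to candidate taxa
present in ≥ 80% of samples with mean count > 5, computes pairwise
log-ratio variances over samples where both counts are positive (no
pseudocounts — candidates are high-prevalence by construction), connects
pairs below the 0.25 quantile of those variances, and returns the largest
connected component with at least 3 taxa. For sparse data the prevalence
threshold drops to 60% (the benchmark harness retries automatically).
This is a deliberately simple invariance heuristic, not a reimplementation
of any published network selector; any externally chosen taxon list can
be supplied instead and flows through identically. Because the raw
reference is usually far above a rare taxon's counts, the S-sign
reference is rescaled per taxon by `median(target)/median(R)` (medians
over all samples, groups pooled — a group-specific adjustment would break
the null's interpretation); for majority-zero taxa the median adjustment
degenerates and the arithmetic mean of the target counts is used instead,
flagged on the result. R-signs use the raw `R_i`: any taxon-specific
rescaling cancels in the pairwise ratios.

**Testing policy.** RF taxa are excluded from testing (a taxon should not
be compared against a reference containing itself). Failed or degenerate
fits keep their rows with NA p-values and are excluded from the BH
family. BH adjustment is the standard step-up procedure; discoveries are
`p_adj ≤ α` with `α = 0.05` by default.

## The simulator

`simulate_dataset` draws counts NB with mean `L_i · π_{g,t}` and variance
`μ + φμ²`. The default parameter pool is synthetic: log10 mean abundances
follow a t(3) distribution (heavy tails spanning ~4 orders of magnitude,
as in real amplicon data), overdispersion decreases log-linearly in the
mean with lognormal noise (rank correlation < 0), and library sizes are
lognormal (σ = 0.6) around a median of 1977 reads — the median depth of
the human-gut dataset that motivated the defaults. The pool is rescaled
so a taxon's expected count at the median library roughly equals its pool
mean, which makes the candidate filter behave as it would on real data.
Mean–dispersion pairs are resampled jointly (both from the same pool
entry) to preserve their relationship. A `da_fraction` of taxa get their
group-1 mean multiplied by `FC^±1` (direction random, 50/50); with
`compositional_renorm` on (default), group-1 proportions are renormalised
so that raising some taxa suppresses the rest — the compositional
compensation that makes high-DA settings hard; raw scaling is available
for clean null checks.

What the simulator does *not* emulate: taxonomic correlation structure,
zero-inflation beyond what NB sparsity produces, batch effects, or
group-dependent sequencing depth. Passing tests on these data therefore
demonstrate calibration and internal correctness under an idealised
two-group NB world, not performance on any particular real study.

**Problem sizes.** The acceptance script uses 100 replicates of
250-taxon, 25-samples-per-group datasets for both the null (type-I) and
the FC = 5 / 10% DA (FDR) scenarios; the test suite runs the same checks
at 30 replicates (and the 70%-DA breakdown at 8) with
Monte-Carlo-standard-error-based bands, sizes chosen to keep the default
suite fast while leaving the Monte-Carlo error well below the effects
being checked.

**Evaluation conventions.** Sensitivity counts every truly-DA taxon that
survives the prevalence trim in its denominator, so DA taxa absorbed into
the RF (hence untested) count as misses. FDR uses `FP/max(1, D)` (zero
discoveries give 0). Type-I error is the fraction of *raw* p-values at or
below α among tested true-null taxa.

## Numerical choices

* Even-length medians are the mean of the two middle order statistics.
* R-sign comparisons are exact integer cross-multiplications; ties are
  exact, never floating-point-approximate.
* Newton solvers start at 0, stop at max-score 1e-8, cap at 50
  iterations; the Firth fit adds step-halving on the penalised
  likelihood.
* Logit-scale estimates are capped at ±15; fitted-probability saturation
  is declared at 1e-8.
* An estimate of exactly 0 with a degenerate (zero) variance yields
  p = 1, not NaN: an all-ties taxon is evidence of no effect, not a
  failure.
* Tiny negative pairwise variances from floating-point cancellation are
  absorbed by a 1e-12 tolerance in the RF selector's edge threshold.
* All randomness flows from user-supplied seeds through
  `numpy.random.default_rng`; identical invocations are bit-reproducible.

## Design choices that were genuinely open

* **Fractional-response likelihood for S-sign ties** rather than dropping
  or randomising ties: keeps `E[I^S] = p` exact and is the natural
  quasi-likelihood extension.
* **Firth as fallback, not default**: on well-behaved data ML and Firth
  agree to O(1/n), and ML keeps the familiar likelihood machinery; Firth
  engages exactly where it is needed (separation, non-convergence). A
  `firth="always"` switch exists.
* **Squared influence contributions in the RI-R variance** (see above),
  validated empirically against Monte-Carlo truth and bootstrap.
* **Pooled-sample medians in the S-sign reference adjustment** — a
  group-specific adjustment would change the null hypothesis being
  tested.
* **RF taxa excluded from testing**, with an override flag, and recorded
  per row (`rf_flag`).
* **BIOM support** is a minimal HDF5 reader (observation-major CSR) —
  enough to ingest standard BIOM 2.1 tables without further dependencies;
  TSV/CSV are the primary formats.

## Known limitations

* Everything is conditional on the RF: when most taxa are differentially
  abundant and compositional compensation is strong, no invariance-based
  selector can find a clean RF, DA taxa enter it, and the FDR inflates.
  The test suite reproduces this breakdown deliberately at 70% DA. Prior
  biological knowledge via `user_reference_frame` is the only reliable
  escape.
* The sandwich and influence-curve variances are asymptotic; at 25
  samples per group the pooled type-I error of the R-sign tests runs a
  few tenths of a percentage point above nominal.
* Strongly separated taxa under the PIM (probabilistic index exactly 0
  or 1) are reported as untestable rather than significant; with small
  samples and huge effects this costs sensitivity.
* Two-group designs only; no longitudinal or multi-group support.
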