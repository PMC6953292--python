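# Methods

## Model

`mspls` models Q data sources ("blocks") X_1, …, X_Q measured on the same n
samples. Each block q receives a latent variable (LV)

    zeta_q = X_q w_q,        w_q in R^{p_q},

normalized to unit sample variance. The hypothesized dependency structure is
a binary connectivity matrix C with c[q, q'] = 1 iff block q is a *response*
for block q'. Row q of C therefore lists the explanatory sources of block q;
column q lists its responses. Blocks without responses use the univariate
"Mode A" outer update (per-variable regression of each manifest variable on
the re-estimated LV); blocks with responses use the penalized multivariate
"Mode B" update.

The fitted model maximizes, per block q', a sum of squared correlations:

* blocks with responses: sum over their response LVs r of
  cor(zeta_r, zeta_q')^2 (CCA-like; bounded by the number of responses);
* terminal blocks (no responses): sum over their own p_q' variables and
  their M_q' explanatory LVs of cor(zeta_m, x_q'(i))^2 (RDA-like; bounded by
  p_q' · M_q').

A symmetric pair of low-dimensional blocks fitted without penalty reproduces
the first canonical correlation; a single explanatory block driving a
terminal block reproduces the redundancy-analysis solution. Both facts are
enforced as tests against independent eigenvalue oracles.

## Estimation loop

Starting from all-ones weights (normalized), each iteration runs:

(a) LVs from current weights, unit variance;
(b) inner coefficients Theta: ordinary multiple regression of each LV on its
    column-bound explanatory LVs, then, for every block with responses, the
    incoming coefficients are *overwritten* by plain correlations with each
    response LV (so mutually-dependent pairs carry correlation entries);
(c) re-estimated LVs Z~ = Z Theta;
(d) outer-weight updates (Mode A or penalized Mode B);
(e) convergence: CRT = sum_q ||w_q_new − w_q_old||², stop when CRT < gamma
    (default 1e-6, max_iter 500; non-convergence is a warning, not an error).

Two engine conventions that the algorithm statement leaves open:

* **Weight normalization and sign.** After every update w_q is rescaled to
  unit Euclidean norm and sign-aligned so its largest-magnitude entry is
  positive. Without this, scale drift of penalized weights and arbitrary sign
  flips dominate CRT and can stall convergence; the LVs inherit the weight
  sign. The model itself is invariant to both choices.
* **Scale of the penalized update.** The Mode B update receives the
  re-estimated LV rescaled to unit variance and divided by n−1, so the score
  vector X_q' z~ entering the elastic net / soft thresholding is exactly the
  vector of correlations between the block's variables and the re-estimated
  LV. This is load-bearing: the raw Z~ column's scale grows by an order of
  magnitude between the all-ones start (inner coefficients near 0) and
  convergence (near 1), so a lambda fixed on the raw scale is either fatal in
  the first iteration or non-selective at convergence — no sparse model is
  reachable. On the correlation scale, lambda has one meaning across
  iterations, across cross-validation folds, and across sample sizes.

## Penalties

Mode B solves

    min_w  w' [(X'X + λ2 I) / (1 + λ2)] w − 2 z~' X w + λ1 ||w||₁

by cyclic coordinate descent (`enet_update`; convergence when the largest
coordinate change in a sweep is < 1e-8; λ1 = 0 is solved exactly by the
normal equations, and is refused for p > n when λ2 = 0). In the λ2 → ∞ limit
the minimizer is coordinatewise soft thresholding, `ust_update`:

    w_j = sign(c_j) · max(|c_j| − λ1/2, 0),   c_j = x_j' z~,

the default for genuinely high-dimensional blocks. The threshold constant
λ1/2 follows from differentiating the limiting objective. A penalty that
zeroes an entire block raises `EmptyModelError` ("λ1 too large") in a direct
fit; cross-validation instead scores that λ as −inf, and resampling
procedures score such refits as objective 0 (a model that selects nothing
captures no association).

`lambda_for_cardinality` inverts the UST threshold to hit a requested number
of retained variables; boundary ties keep all tied variables (deterministic,
never an arbitrary drop) and warn.

## Penalty selection and inference

* **Cross-validation** (`cross_validate`): samples are partitioned once
  (seeded, via scikit-learn's KFold). Per fold, training columns are
  standardized with training means/sds; held-out rows are standardized with
  the *training* parameters and projected onto the fitted weights; the
  objective branch of a designated block (default: the first terminal block)
  is evaluated on held-out data. The λ1 with the best mean held-out objective
  wins; exact ties go to the largest (sparsest) λ1. The default grid is 20
  log-spaced values spanning [0.01·λmax, λmax], with λmax twice the largest
  variable–LV correlation magnitude after one warm-start pass from the
  all-ones weights (the smallest value that already empties every penalized
  block at that pass).
* **Permutation test** (`permutation_test`): each block's rows are permuted
  independently, destroying cross-block association while preserving each
  block's internal correlation structure; the model is refitted at the fixed
  penalty; p = (1 + #{null ≥ observed}) / (B + 1), hence never below
  1/(B+1). Non-converged refits still contribute (counted); emptied refits
  contribute 0 (counted).
* **Bootstrap** (`bootstrap_ci`): one with-replacement index vector per
  replicate applied to *every* block (preserving cross-block association),
  blocks re-standardized, model refitted at the fixed penalty; empirical
  (inverse-CDF) quantiles of the objective are reported.

## Multiple components

`deflate_block` removes the rank-1 projection of a block onto its LV:
X_res = X − z (z'z)⁻¹ z' X. `extract_components` chains fits on residuals;
by default blocks *with* responses are deflated while terminal blocks stay
original, so successive explanatory LV sets are orthogonal within each
deflated block yet always target the same responses. Residuals are not
re-standardized: the correlations driving the fit are scale-free, and
keeping residual column variances makes explained-variance accounting exact —
component α explains cor(zeta, x_res)² · var(x_res) of a column's original
(unit) variance, and these fractions sum to ≤ 1 across components. The
per-block explained-variance scalar is the average squared LV–variable
correlation (mean communality), used uniformly for Mode A and Mode B blocks.

## Synthetic data generator

`simulate_dataset` emulates a three-block design: X1, X2 with 1000 variables
each drawn from N(0, Σ), where Σ is the identity except for a 10×10
cross-block H between the first ten variables of each block, H_ij i.i.d.
N(0.3, sd 0.05); association weights 0.7/0.6 on those ten variables define
generative LVs z1 = X1 w1, z2 = X2 w2 (used unnormalized); the first ten
columns of the 100-variable response block X3 are N(0.8·z1 + 0.7·z2,
sd √(1−0.3²)), the remaining ninety are standard normal. Blocks are
standardized before analysis. 0.05 is read as the standard deviation of H
(a variance reading is available via `h_sd`).

**Positive-semidefiniteness repair.** The stated Σ is far from PSD: with
H ≈ 0.3·J the 20×20 core [[I, H'], [H, I]] has top singular value of H near
3, giving eigenvalues ≈ 4 and ≈ −2. The generator applies the smallest
repair that makes the recipe samplable — eigenvalues clipped at 0 with
eigenvectors fixed (equivalently, the convention used by common multivariate-
normal samplers when handed an indefinite matrix) — and reports diagnostics
(`SigmaReport`: minimum eigenvalue before/after, mean cross-correlation
before/after). Two consequences worth knowing:

* the achieved cross-block correlations shrink from ≈ 0.30 to ≈ 0.18;
* the clipped direction is exactly the contrast between the two associated
  sub-blocks, so its variance is zero and the generative LVs z1, z2 become
  almost perfectly correlated. The planted signal is therefore effectively
  rank one and *stronger* per variable than the nominal 0.3 cross-correlation
  suggests.

What the generator does not emulate: heavy tails, batch structure, missing
data, block-specific scales, or any within-block correlation beyond the
planted sub-block. A green recovery test therefore establishes that the
estimator finds a low-rank cross-block signal among independent noise — not
that it survives the pathologies of real omics data.

## Recovery study and known result discrepancies

`run_study` repeats generate → cross-validate (UST) → fit → score. TPR is
the fraction of planted variables selected, relative to min(k, #selected);
TNR the fraction of irrelevant variables excluded. Child seeds are split
from the master seed, so studies are reproducible end to end.

Measured behaviour under the defaults (120 replicates per sample size): TPR
rises with n (≈ 0.76, 0.94, 1.00 at n = 50, 100, 250) and TNR ≈ 0.90, 0.99,
0.995. At n = 50 the cross-validated penalty genuinely favours retaining
~50–120 variables (the held-out objective keeps rising toward the sparse end
of the grid but peaks before the ~10-variable regime), so the strictest
exclusion claim (TNR ≥ 0.99 at *every* n) holds only for n ≥ 100 in this
implementation of the stated world.

The absolute level of the terminal-block objective on simulated data is
≈ 19–20 under the defaults, with a hard ceiling: 180 of its 200 squared
correlations pair a fitted LV with an i.i.d. N(0,1) response column that is
independent of X1 and X2 by construction, so their expected contribution is
≈ 180/(n−1) and vanishes as n grows, capping the objective near 20 + 180/(n−1).
Published values several times larger — and *increasing* with n — are not
attainable from the stated generator and objective in any implementation;
they would require essentially all response columns to carry signal. The
acceptance checks for those levels are therefore expected to stay red, and
the repair diagnostics above are reported alongside them.

## Numerical choices

* Standardization uses sample sd (denominator n−1); constant columns are a
  hard error so variable indices stay stable for recovery bookkeeping.
* Missing values are rejected, not imputed.
* Singular inner regressions (collinear LVs) raise rather than fall back to
  a pseudo-inverse, to surface pathological connectivity early.
* Coordinate-descent tolerance 1e-8 per sweep; engine tolerance gamma 1e-6
  on CRT; max_iter 500.
* Bootstrap quantiles are empirical (inverse-CDF); the p-value formula is
  the standard unbiased-conservative (1 + exceedances)/(B + 1).
* All randomness flows through `numpy.random.default_rng` seeds recorded in
  results; replicate child seeds are drawn once from the master generator.

## Limitations

Linear relations only; a single homogeneous population; no missing-data
handling; inner-model schemes other than the regression/correlation scheme
are out of scope, as are per-variable bootstrap standard errors and
cross-block orthogonality constraints.
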