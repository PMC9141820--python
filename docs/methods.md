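# Methods

## Estimation problem

The estimator targets a correlation matrix that is sparse and of low rank.
For a correlation matrix R and a symmetric binary mask W with unit
diagonal, the fit minimizes the masked squared Frobenius loss

    f(Y | R, W) = sum_{i != j} (r_ij - w_ij y_i' y_j)^2

over p × d factors Y whose rows lie on the unit sphere, so YY' has unit
diagonal and rank at most d. The diagonal terms are excluded: under the
constraints both sides equal 1 there.

### MM algorithm

The row subproblem is the quadratic f_i(y_i) = y_i' B_i y_i - 2 y_i' c_i
with B_i = sum_{j != i} w_ij y_j y_j' and c_i = sum_{j != i} w_ij r_ij y_j.
Since B_i - lambda_i I is negative semi-definite for lambda_i the largest
eigenvalue of B_i, the quadratic is majorized at the current iterate by a
linear function whose spherical minimizer is the closed-form update

    y_i <- (lambda_i y_i - B_i y_i + c_i) / || lambda_i y_i - B_i y_i + c_i ||.

Cycling over rows (Gauss–Seidel: B_i is rebuilt from the freshest rows,
which is the natural reading of the inner loop and preserves the descent
guarantee either way) yields a non-increasing objective trace; the
iteration stops when the decrease over a full sweep falls below an
absolute tolerance `eps` (default 1e-6; a relative variant exists but is
off by default). Default `max_iter` is 1000 sweeps. Neither default is
prescribed by theory; 1e-6 is far below any loss difference that matters
for threshold selection at p ≈ 100.

Numerical choices:

* lambda_i uses a closed form for d ≤ 2 and a symmetric eigensolver for
  larger d (B_i is d × d, so this is cheap).
* If the update direction has norm below 1e-12 (an isolated variable with
  no retained neighbours, or exact cancellation) the previous row is kept:
  the objective is flat in that row, so any unit vector is optimal.
* Initial rows are standard-normal d-vectors normalized to unit length.
  The loss is non-convex (for d = 1 it contains the ±1 sign problem), so
  fits restart from `n_starts` independent initializations and keep the
  lowest final objective. Starts are drawn sequentially from one
  generator: with a fixed seed, start sets are nested in `n_starts` and
  the best objective is monotone in it.
* The hot loop (sweeps and objective) is numba-compiled; a pure-numpy
  single-row reference implementation (`mm.update_row`) backs the
  majorization and hand-example tests independently of the kernels.

## Proportional thresholding

The threshold h(alpha) is the empirical alpha-quantile of the strict
upper triangle of R, using the lower-order-statistic (type-1) convention:
the ceil(alpha·m)-th of the m = p(p-1)/2 sorted off-diagonal values
(minimum at alpha = 0, maximum at alpha = 1). The mask keeps r_ij ≥
h(alpha) — a signed, one-sided rule: negative correlations are never
retained, trading completeness for heatmap interpretability. Ties sit on
the "keep" side of the non-strict inequality. The diagonal never enters
the quantile pool and is always retained. Sample correlations are
explicitly symmetrized ((R + R')/2) before thresholding because BLAS
rounding makes `corrcoef` output asymmetric at the last ulp, which would
otherwise produce asymmetric masks at quantile boundaries.

The sparse low-rank operator builds the mask from the *original* R (never
from a low-rank approximation), runs the multistart MM fit, and returns
W ⊙ YY' with the diagonal set to exactly 1 and exact zeros off the mask
support — sparsity is structural, not a numerical tolerance.

## Cross-validation for the threshold

Data are split at random into n1 = n − floor(n / ln n) fitting rows and
n2 = floor(n / ln n) holdout rows (natural logarithm — the convention of
the thresholding literature; the holdout is small but grows slowly with
n). For each candidate alpha and each of K splits (default K = 5), the
loss is the squared Frobenius distance between the estimate built from
the fitting part's correlations and the holdout correlation matrix:

* rank-aware CV: estimate = W ⊙ YY' with Y fit by multistart MM at rank d
  against (R1, W); because a low-rank fit cannot chase every retained
  noisy correlation, its holdout loss penalizes dense masks more, and the
  argmin lands at sparser thresholds;
* tandem CV: estimate = W ⊙ R1, no rank involved; the classical recipe.

Splits are redrawn independently for every (alpha, k) pair, which is the
literal reading of the nested CV loops; a `common_splits` option reuses
one set of K splits across the grid (a variance-reduction device) but is
off by default. Ties in the argmin go to the largest alpha — the sparser
model, consistent with the method's purpose. A split that produces a
constant column (correlation undefined) is redrawn, up to 20 attempts;
with continuous data this never triggers. Inside the CV the number of
multistarts defaults to the same `n_starts` as the final fit and is
configurable downward for speed.

The final estimate recomputes the threshold and mask on the full-data
sample correlation at the chosen alpha and refits the rank-d factor by
multistart MM, so the estimate's support always equals the full-data mask
support at the chosen threshold.

## Simulation models

Three population correlation structures at p = 100 (1-based indices):

1. banded: r_ij = (1 − |i−j|/10)+ — read as the positive part, which is
   what makes the model sparse and positive semi-definite (smallest
   eigenvalue ≈ 0.002 at p = 100);
2. autoregressive: r_ij = 0.3^|i−j| — dense, so support-recovery rates
   against it are undefined (FPR is reported as NaN);
3. block: five 20-variable blocks with within-block correlation 0.4 plus
   connector entries 0.4 linking the last variable of block k to every
   member of block k+1 (both orientations, symmetrized, k = 1..4), and
   unit diagonal. The connector notation admits more than one reading;
   this one keeps the matrix positive semi-definite (smallest eigenvalue
   ≈ 0.207) and matches the intended block-plus-single-row/column
   pattern.

Samples are i.i.d. N(0, R) rows via an eigendecomposition factorization;
eigenvalues in [−1e−8, 0) are clipped to zero, anything lower is an
error. Everything is deterministic given a seed.

The two-class expression fixture emulates a four-class microarray
screening design with n = 64 samples: 40 "informative" genes receive
per-class mean shifts (N(0,1)) and share a latent factor inducing
within-group correlation 0.3; 60 "non-informative" genes are independent
unit noise, so the population cross-group correlation is exactly zero and
any estimated cross-group nonzero is a false positive. It reproduces the
qualitative structure of real expression data (class-driven correlation
among discriminative genes, a clean null between groups) but not its
heavier tails, batch effects, or correlated noise among uninformative
genes — passing tests on it demonstrate correct mechanics and the
relative ordering of methods, not field performance.

## Evaluation indices

Accuracy uses relative Frobenius- and spectral-norm errors against the
true matrix. Support recovery uses TPR (fraction of truly nonzero cells
estimated nonzero) and FPR (fraction of truly zero cells estimated
nonzero), counted over **all** cells — the convention of the reference
tables, whose printed values are only mutually consistent under it. The
unit diagonal is trivially recovered, so it inflates TPR slightly (by
p / (N⁺ + p) relative weight) and cannot affect FPR, since diagonal
entries are never truly zero; an off-diagonal-only variant is available
(`include_diagonal=False`). The sparsity index, by contrast, is defined
with denominator p² − p and therefore always excludes the diagonal, and
FPR is undefined (NaN) against a dense truth. "Zero" means exactly zero:
the estimators produce structural zeros through the mask; a tolerance
flag exists for matrices imported from other software. In the grouped
workflow, within-class sparsity counts ordered within-class pairs
excluding the diagonal (the same p² − p convention), and between-class
FPR uses the denominator 2·|IS|·|NS|.

## Scaled-down study profile

The replication study behind the acceptance checks uses 20 replications
per cell with 5 multistarts (inside CV and for final fits), K = 5, and
the standard candidate grids (0.66–0.86 step 0.02 for models 1–2;
0.66–0.82 for model 3, where higher thresholds leave too few entries to
fit a stable factor; 0.50–0.83 step 0.01 for the real-data-sized grouped
workflow). These sizes keep a full factorial sweep at desk scale;
comparisons of replicate means use three Monte-Carlo standard errors of
the run's own spread. The full-size profile (100 replications, 50 starts)
is available by setting `n_reps`/`n_starts` on the `Scenario`. Raising
the multistart count from 5 to 30 was checked not to move the scenario
means materially.

## Known limitations

* Only positive correlations are thresholded; strongly negative structure
  is invisible to the estimator by design.
* The rank d is user-supplied; no rank-selection rule is provided.
* No positive-semidefiniteness repair is applied to the masked estimate
  W ⊙ YY' (the Hadamard product of two PSD-structured factors need not be
  PSD).
* Against a dense truth (model 2) the CV loss decreases monotonically in
  alpha, so the chosen threshold sits at the top of the candidate grid
  and the support-recovery indices are deterministic given the grid
  (TPR and off-diagonal sparsity are then complementary up to the
  diagonal counts).
* The CV holdout size floor(n / ln n) is very small for n below ~30;
  correlation estimates from a handful of rows make threshold selection
  noisy there.
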