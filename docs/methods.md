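# Methods

## Model

`pqifgene` analyzes a binary disease trait measured repeatedly over a grid
of T visits with a population-averaged (marginal) logistic model

    E(Y_it) = mu_it,   logit(mu_it) = x_it' beta,

where the covariate vector x_it mixes time-varying environmental variables
(age, smoking) and time-invariant gene scores.  Genes enter the model as
weighted-sum (WSS) burden scores: for a gene with J variants with
additive-coded dosages G_ij and sample minor-allele frequencies p_j,

    C_i = sum_j G_ij / sqrt(p_j (1 - p_j)),

so rare variants (MAF < 5%) dominate the score.  Under this collapsing a
single coefficient per gene captures the synergistic effect of its rare and
common variants, at the cost of assuming a shared effect direction.

## Estimation: quadratic inference functions

Within-subject correlation is not estimated.  Instead the inverse working
correlation is expanded on basis matrices, R^{-1} ~ a_0 I + a_1 M_1, with
M_1 the off-diagonal-ones matrix (exchangeable) or the first sub/super
diagonal matrix (AR(1); the corner-correction matrix of the three-term
expansion is omitted, keeping one non-identity basis for every structure).
The per-subject extended score stacks one quasi-score block per basis
matrix, and the estimator minimizes the GMM quadratic form

    Q_n(beta) = psibar_n' Cbar_n^{-1} psibar_n,
    Cbar_n    = (1/n) sum_i psi_i psi_i'.

n·Q_n is the chi-square-scale inference-function statistic; at the true
coefficients its expectation is the number of moment conditions, a property
the test suite checks by simulation.

Subjects with missing visits are handled by selection matrices H_i that
restrict mu, Y, the variance function A and the basis matrices to the
observed rows/columns.  H_i is implemented as the |observed| x T row
selector so that A* = H A H' remains invertible.  Balanced groups of
subjects sharing an observation pattern are processed vectorized.

### Numerics

* Newton-Raphson with the Gauss-Newton derivatives grad = 2 J' C^{-1} psibar
  and Hess = 2 J' C^{-1} J, Cbar re-evaluated at every iterate.
* Step halving (up to 20 times) accepts a step when it decreases the
  objective *or* the gradient-residual norm.  Monotone decrease of Q_n
  alone is not a usable criterion: the fixed point of the estimating
  equation differs from the exact minimizer of Q_n by rounding-level
  amounts because Cbar varies with beta, and insisting on descent stalls
  the iteration just above tight tolerances.
* Convergence: max |Delta beta| < 1e-12 (unpenalized), 200 iterations;
  typical fits converge in 8-15 iterations.
* Cbar is ridged by 1e-8 x (mean eigenvalue) before factorization; a
  condition number above 1e12 raises an error.  A fitted mean numerically
  at 0 or 1 raises an error naming the subject.
* Initialization: pooled logistic regression on the stacked observations
  (independence working model).
* Standard errors: sqrt(diag((n J' C^{-1} J)^{-1})) at the optimum.
* The identity link (A = I) is supported for continuous traits; the logit
  link is the tested path.

## Penalized estimation and tuning

The penalized objective adds a SCAD penalty, U_n = n·Q_n + n sum_j
p_lam(|beta_j|), with a = 3.7 and the intercept never penalized.  SCAD is
flat-slope lam up to lam, decays linearly to zero slope at a·lam, and
leaves larger coefficients unpenalized (near-unbiasedness).  The non-convex
penalty is iterated by local quadratic approximation: the update solves

    [H + Pi(beta)] step = g + Pi(beta) beta

over the active coordinates, Pi = diag(p'(|b_j|)/|b_j|); the n factors of
the objective and the penalty cancel against each other.  A coordinate
whose magnitude falls below delta = 1e-4 (covariates are standardized) is
set to exact zero and removed from the active set for the current lambda —
the classic LQA one-way-door, accepted deliberately.  LQA converges only
linearly for coordinates in the soft-threshold regime, so the penalized
iteration allows up to 500 iterations at tolerance 1e-10.  At lam = 0 the
iteration reduces exactly to the unpenalized fit.

The tuning parameter is chosen on an equally spaced grid [0.01, lam_max]
by minimizing BIQIF = n·Q_n(beta_hat) + df·log(n), df counting all nonzero
coefficients including the unpenalized intercept.  Q_n is always evaluated
in the full p-dimensional score space (zeros kept in beta) so values are
comparable across active sets.  Ties go to the larger lambda (sparser
model).  Path fits are warm-started from the previous lambda's solution;
coordinates zeroed there are re-seeded at the unpenalized estimate, since
an exact zero cannot re-enter an LQA iteration.  When lam_max is not
supplied it defaults by sample size (0.35 / 0.25 / 0.2 for n <= 200 /
<= 300 / larger), or can be found by bisection as the smallest lambda
emptying the penalized active set.

## Synthetic data generator

The generator emulates a longitudinal sequencing cohort:

* **Genotypes** — per gene, 10 SNPs in a 6:4 rare:common split; rare MAFs
  ~ Uniform(0.005, 0.05), common ~ Uniform(0.05, 0.5); dosages
  Binomial(2, MAF) under Hardy-Weinberg.  Real sequencing data have linkage
  disequilibrium, site-frequency spectra skewed toward singletons and
  population structure, none of which is modelled: passing tests show the
  estimator's statistical behavior under idealized genotypes, not
  robustness to those features.  The MAF laws are the main lever moving
  absolute MSE magnitudes; they are configurable on the scenario.
* **Covariates** — baseline age ~ Normal(53.30, 15.91^2) truncated to
  [20.3, 96.72] years, advancing exactly +3.9 y at exam 2 and +6.9 y at
  exam 3; smoking Bernoulli(0.229) at exam 1 with absorbing per-exam quit
  probability 0.0145.
* **Responses** — with standardized predictors, logit(mu_it) = beta_0 +
  x_it' beta (beta_0 = 0, giving ~50% marginal prevalence).  Correlated
  binary vectors come from the Emrich-Piedmonte construction: for each
  visit pair the latent-normal correlation solving
  Phi_2(z_t, z_s; r) = mu_t mu_s + rho_ts sqrt(mu_t(1-mu_t)mu_s(1-mu_s))
  is found by monotone bisection (the bivariate normal CDF is evaluated via
  Owen's T function), a per-subject latent correlation matrix is assembled
  and Cholesky-factored, and thresholded Gaussian draws deliver binary
  margins mu_it with binary-scale correlations rho (exchangeable) or
  rho^|t-s| (AR(1)).  rho is interpreted on the binary scale; infeasible
  (margins, rho) pairs raise an error reporting the Frechet bounds rather
  than silently truncating.
* **Scenarios** — scenario 1: q = 4 signals, beta = (0.9, -0.7, -0.6, 0.5)
  on age and three causal genes, rho = 0.4; scenario 2: q = 6, beta =
  (0.9, -0.7, -0.7, -0.6, -0.6, 0.5), rho = 0.7.  Columns are ordered
  (age, causal genes, smoke, noise genes); smoking is a genuine covariate
  with zero true effect.  Panels are balanced; the unbalanced estimation
  path is exercised separately by masking visits.

## Study harness and metrics

Per replicate: simulate a dataset, fit the full QIF, the BIQIF-tuned
penalized QIF, and the oracle QIF (true support only, zeros elsewhere).
Metrics over R replicates:

* TMSE = (1/R) sum_r ||beta_hat^(r) - beta||^2 / p over all p covariates
  (intercept excluded);
* NMSE = the same restricted to the zero-effect noise-gene coordinates;
* TP / FP rates = per-replicate fractions of selected true-support / null
  coordinates, averaged (the denominators are a package choice; selection
  frequencies per variable are also reported);
* non-convergent replicates are counted and excluded from the averages,
  erroring out beyond 50% failures.

Per-replicate seeds are drawn once from the master seed, making replicates
independent of execution order and runs bit-for-bit reproducible.

### Problem sizes used in the shipped experiments

The packaged acceptance experiments run the n = 500, p = 20, rho = 0.4
scenario-1 cell and the n = 300, p = 20, rho = 0.5 misspecification cell at
50 replicates with a 20-point lambda grid — sizes at which the Monte-Carlo
error of TMSE is a few percent and a full study completes in minutes on one
core.  Larger replicate counts and the 100-point grid are plain parameter
changes on `run_study`.

## Known limitations

* QIF inherits the small-sample weakness of optimally weighted GMM: with
  (1+S)·p moment conditions, Cbar is noisy when n is only a few times that
  count, and the non-identity bases (two score blocks) can then produce
  visibly more variable estimates than the independence basis on identical
  data.  This is amplified by the heavy-leverage tails of standardized WSS
  scores built from very rare variants.  Comparisons of working structures
  at n ~ 300 with p = 20 should expect the independence basis to look best
  in TMSE even when the data are truly correlated; the gap closes as n
  grows.
* The LQA active set cannot re-grow within a lambda; pathological warm
  starts could miss a coordinate at one grid point (mitigated by re-seeding
  from the unpenalized estimate at each lambda).
* Burden collapsing loses power when variant effects within a gene have
  opposing directions; no adaptive-direction or variance-component
  alternative is provided.
* Only independence, exchangeable and AR(1) working bases are built in;
  family/kinship correlation structures are out of scope.
* MAFs are estimated from the analyzed sample itself; no external reference
  panel is consulted.
* The EP generator solves one latent correlation per subject and visit
  pair; for T much larger than the three-visit design this becomes the
  dominant simulation cost.
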