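# Methods

## Model

Observations are modelled as a zero-mean Gaussian process with additive
Gaussian noise,

    y_i = f(x_i) + e_i,   e_i ~ N(0, sigma_n^2),   f ~ GP(0, sigma_f^2 k),

with inputs x in R^D (spatial coordinates, time, or arbitrary covariates)
and k a correlation kernel with k(x, x) <= 1. Instead of choosing k from a
named family, the kernel is represented by a finite frequency sample and
the sample itself is treated as the kernel's parameters.

**Stationary case.** A stationary kernel is the Fourier transform of a
spectral probability measure (Bochner). Drawing m frequencies
omega_1..omega_m from that measure and stacking them into Omega (m x D)
gives the random Fourier feature map

    Phi = [cos(X Omega^T) | sin(X Omega^T)]          (n x 2m),

whose scaled Gram matrix K = (sigma_f^2/m) Phi Phi^T is a Monte-Carlo
estimate of the kernel matrix. Taking the real part of the Fourier
representation symmetrises the spectral measure, so *any* finite frequency
set defines a valid kernel — which is what makes the frequencies learnable
parameters rather than fixed Monte-Carlo dust.

**Nonstationary case.** General (nonstationary) positive-definite kernels
are characterised by a spectral measure on the product space R^D x R^D.
Sampling frequency *pairs* (omega^1_k, omega^2_k) and symmetrising the
measure over the pair and its diagonal components yields the feature map

    Phi = [cos(X (Omega^1)^T) + cos(X (Omega^2)^T) |
           sin(X (Omega^1)^T) + sin(X (Omega^2)^T)]  (n x 2m),

with kernel matrix K = (sigma_f^2/(4m)) Phi Phi^T. When Omega^1 = Omega^2
every term doubles and the construction reduces *exactly* to the
stationary map (the measure collapses onto the diagonal); when they
differ, the kernel depends on locations and not just lags. The package
carries the divisor (m or 4m) with the feature map so both cases share one
code path.

## Reduced-rank inference

All GP quantities are computed through the 2m x 2m matrix
A = Phi^T Phi + (s sigma_n^2/sigma_f^2) I (s the divisor above), its
Cholesky factor R, and the solves R a1 = Phi^T y, R^T a2 = a1:

    log p(y) = -(||y||^2 - ||a1||^2)/(2 sigma_n^2) - sum_i log R_ii
               + m log(s sigma_n^2/sigma_f^2) - (n/2) log(2 pi sigma_n^2)
    mean(x*) = phi*^T a2
    var(x*)  = sigma_n^2 (1 + ||R^{-1} phi*||^2)

at O(n m^2) cost. These identities are derived from the dense GP
equations under K via the Woodbury and determinant lemmas and are *exact*,
not approximate: the test suite checks agreement with a dense O(n^3)
oracle to 1e-8 relative error on random instances, and the predictive
variance provably never drops below the noise floor sigma_n^2. The
variance reported is for a new *observation* (it includes sigma_n^2).

A numerical note: some published statements of the low-rank predictive
carry a sigma_f^2/m prefactor that is inconsistent with the ridge term in
A; this package takes the dense equations under K as normative and uses
the prefactor-free identities above, which agree with them to machine
precision.

## Spectral families

Families are defined operationally by their sampling distribution; the
kernel each induces is that distribution's characteristic function, and
the tests enforce exactly this contract (closed form for the Gaussian and
Laplacian families, one-dimensional quadrature over the chi-square mixing
variable for the Student-t family):

| family            | frequency law                          | implied kernel                         |
|-------------------|----------------------------------------|----------------------------------------|
| gaussian          | N(0, diag(1/l_d^2))                    | exp(-0.5 sum_d (d_d/l_d)^2) (ARD SE)   |
| laplacian_cauchy  | independent Cauchy(0, 1/l_d) per dim   | prod_d exp(-|d_d|/l_d) (exponential)   |
| matern_t          | multivariate t, df lambda, scale 1/l_d | Matern-type; heavier t tails = rougher |
| mixture           | Gaussian mixture                       | dense in all spectral densities        |
| copula            | Gaussian copula + target marginals     | non-separable, per-dim marginals       |

`lengthscales` are in the units of the corresponding input dimension. The
Student-t family's user-facing parameter is its degrees of freedom; no
exact identification with a Matern smoothness index is claimed (the
normative object is the characteristic function). Separable nonstationary
measures are built per dimension (`sample_product_measure`), non-separable
ones through correlated latent Gaussians, mixtures, or the Gaussian
copula.

## Training

Frequencies (Omega^1, Omega^2 — or a single Omega in stationary mode) and
the log hyperparameters log sigma_n^2, log sigma_f^2 are optimised jointly
by ADAM (beta1=0.9, beta2=0.999, eps=1e-8) on the negative log marginal
likelihood, full batch. Gradients are computed in closed form: with
beta = A^{-1} Phi^T y,

    dL/dPhi = (y - Phi beta) beta^T / sigma_n^2 - Phi A^{-1},

chained through the cos/sin entries onto the frequency matrices, and
dL/dr = -||beta||^2/(2 sigma_n^2) - tr(A^{-1})/2 + m/r for the ridge
r = s sigma_n^2/sigma_f^2 path of the hyperparameter gradients. The test
suite verifies every gradient block against central finite differences at
1e-5 relative tolerance.

Two regularisers control the heavily over-parameterised kernel:

* **Gaussian dropout** (`dropout_sigma_p`, default 0.05): each step
  evaluates the objective at frequencies multiplied elementwise by
  independent N(1, sigma_p^2) draws, resampled every step, with the noise
  factor entering the chain rule. The unit-mean multiplicative form keeps
  the expected frequencies — hence the covariance estimate — unbiased.
  Evaluation and prediction always use noise-free frequencies.
* **Early stopping** (`patience`, default 10 evaluations; `eval_interval`,
  default 25 steps): a `split_fraction` (default 0.7) train/validation
  split is scored by validation MSE with noise-free frequencies;
  optimisation halts once the MSE has failed to improve for more than
  `patience` consecutive evaluations, and the best-validation checkpoint
  (not the last iterate) is refit and returned. `patience = 0` therefore
  stops at the first non-improving evaluation.

Initialisation draws frequencies from `init_spec` (default: unit-scale
Gaussian on standardised inputs — a valid stationary-like kernel);
sigma_f^2 starts at var(y) and sigma_n^2 at 0.1 var(y). Inputs are
z-scored per dimension by default (`standardize`), with the transform
stored in the fitted model, so frequency magnitudes are comparable across
covariates; this is toggleable. `learn_frequencies=False` gives the
vanilla random-feature baseline in which frequencies stay fixed at their
draw and only the hyperparameters are optimised.

The learning rate and sigma_p are the two knobs not regularised by the
marginal likelihood; `random_search` samples them log-uniformly and scores
each sample by cross-validated test MSE (the full protocol uses 500
samples; the package leaves the budget to the caller). The feature count
starts at m0 = ceil(log(n) sqrt(n)) (natural log; 47 at n = 100) and
doubles until the relative improvement in cross-validated MSE falls below
1%, returning the last count before the curve flattens.

## Evaluation

`cross_validate` repeats: random 70/30 split from a run-indexed substream,
the full training procedure on the 70% (including its internal
early-stopping split), scoring on the 30% — 20 runs by default. Point
scores are MSE and Pearson correlation (undefined for constant inputs and
reported as missing); probabilistic scores are the closed-form Gaussian
CRPS, sigma [z(2 Phi(z) - 1) + 2 phi(z) - 1/sqrt(pi)], verified against
direct quadrature of the defining integral, and the PIT Phi((y - mu)/sigma),
uniform under perfect calibration. For a calibrated Gaussian predictive
the analytic expected CRPS is sigma/sqrt(pi), which the calibration study
uses as its reference.

## Synthetic data

Three generators provide ground-truthed data; each is a pure function of
(parameters, seed) and the returned truth is sufficient to rebuild the
exact generating covariance.

* `gen_from_frequency_kernel`: exact multivariate-normal draws from
  sigma_f^2 K + sigma_n^2 I with K built from supplied frequencies — the
  model's own family, used for well-specified recovery and calibration
  checks (a 1e-8 sigma_f^2 jitter is added before factorisation).
* `gen_warped_field`: a stationary squared-exponential GP composed with a
  monotone exponential input warp, giving an effective lengthscale that
  varies by a factor e^strength across the unit square.
* `gen_trend_series`: 1-D segments with differing lengthscales joined
  continuously plus linear drift — a stock-like series whose roughness
  changes over time.

What these do *not* emulate: real marginal distributions (fat-tailed
returns, bounded temperatures), irregular spatial sampling designs,
covariate measurement error, or non-Gaussian observation noise. Passing
the bundled studies therefore demonstrates correctness of the algebra and
the advantage of frequency learning under known nonstationarity, not
field performance on any particular real dataset.

## Bundled studies and problem sizes

* *Nonstationary advantage* (`experiments.nonstationary_advantage`):
  n = 1000 points on [0,1], responses drawn from a chirp-like kernel whose
  product-space measure sits on the ray omega^2 = 3 omega^1 (8 generating
  pairs, base lengthscale 0.25, sigma_f^2 = 1, sigma_n^2 = 1e-4 — noise
  low enough that kernel misspecification dominates the held-out error).
  Per seed, the learned nonstationary model (16 pairs) is compared against
  the vanilla fixed-frequency stationary baseline (32 frequencies — equal
  frequency budget) on a 70/30 split; both use ADAM at rate 0.05 for up to
  400 steps, evaluation every 25, patience 5, dropout 0.05. The ray
  construction is chosen because its location-dependent frequency content
  is exactly the structure a single stationary spectrum cannot represent.
* *Calibration study* (`experiments.calibration_study`): 20 seeds of
  n = 150 two-dimensional points from a known paired-frequency kernel,
  conditioned with the true frequencies and hyperparameters; PIT KS
  uniformity per seed and pooled mean CRPS against the analytic
  expectation.

## Numerical choices

* Cholesky factorisations use an escalating jitter ladder starting at
  1e-10 trace(A)/dim, growing tenfold for up to three retries before a
  hard error.
* sigma_f^2 = 0 is handled as the exact no-signal limit (i.i.d.-noise
  likelihood, zero predictive mean, variance sigma_n^2) rather than
  through the ridge, which would be infinite.
* Feature columns are ordered all-cos then all-sin; the ordering is frozen
  because model files serialise frequencies and the predictive rebuilds
  the map.
* Hyperparameters are optimised on the log scale to enforce positivity.
* All samplers derive per-purpose substreams from one root seed via
  `numpy` seed sequences, so every pipeline stage is reproducible from a
  single integer.

## Limitations

* Full-batch gradients: each step is O(n m^2 + m^3), fine for n in the
  tens of thousands at moderate m but not for streaming data; mini-batch
  support would require a stochastic treatment of the marginal likelihood.
* The marginal-likelihood surface over frequencies is highly multimodal;
  ADAM finds good local optima from the default initialisation on smooth
  data, but data dominated by frequencies far from the initial spectral
  scale can stall (visible as an occasional lost seed in the advantage
  study).
* Gaussian observation model only; non-Gaussian likelihoods would need
  variational or MCMC machinery that is out of scope here.
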