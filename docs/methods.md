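# Methods

## Model and estimation

The package treats the per-stimulus activity patterns of two regions as
columns of X ∈ R^{N_X×N_s} (input region) and Y ∈ R^{N_Y×N_s} (output
region) and assumes the mapping between them is linear, Y = TX + E. The
estimate is the ridge solution T̂_λ = YX′(XX′+λI)⁻¹, computed through a
Cholesky solve of (XX′+λI) rather than an explicit inverse.

**Z-scoring convention.** Columns are z-scored across voxels with the
population (divide-by-N) variance, so every normalised column has mean 0
and squared norm exactly N. This convention is load-bearing: it turns the
per-stimulus denominators ‖Y·i‖² of the cross-validation criterion into
the constant N_Y, so the λ selection can drop them and the
goodness-of-fit denominator becomes N_Y·N_s exactly. Sample-variance
(divide-by-N−1) z-scoring would break this identity, which is why it is
not offered. Normalisation is re-applied per analysis subset (e.g. after
restricting to face stimuli) so the identity holds for whatever set of
stimuli is actually analysed.

**λ selection.** Leave-one-stimulus-out cross-validation with the
leverage shortcut: Λ(α) = ‖A(α)(I−H(α))Y′‖²_F, where
H(α) = X′(XX′+αI)⁻¹X is the N_s×N_s hat matrix of the ridge fit on
stimulus space and A(α) = diag(1/(1−h_ii)). (The identity inside H acts
on voxel space, N_X×N_X; the outer identity is necessarily N_s×N_s — the
only dimensionally consistent reading, verified in the tests against the
explicit refit-per-stimulus loop to 1e−8.) The search is a grid argmin
over 61 log-spaced candidates on [1e−2, 1e4]; the grid is a package
choice — practice shows selected optima fall well inside this envelope —
with a warning when the argmin lands on an endpoint, and ties broken
toward the smallest λ (less shrinkage at equal cross-validation error).
For α > 0 all leverages satisfy h_ii ≤ max_k d_k/(d_k+α) < 1, so the
weights are always defined; the leverage check remains as a numerical
guard. A seeded k-fold variant (default k = 10) is provided; k = N_s
reproduces the leave-one-out selection exactly.

Internally a single symmetric eigendecomposition XX′ = QDQ′ is shared
across the whole candidate grid (and across all Monte Carlo simulations,
where X and λ are fixed), so each additional candidate or simulation
costs only matrix products.

**Goodness-of-fit.** GOF = 100·(1 − Λ(λ)/(N_Y·N_s)) is the
cross-validated percentage of output-pattern variance explained. It is
deliberately not clipped below zero: a negative cross-validated GOF
(fit worse than predicting zero) is diagnostic and should be visible.
The per-stimulus vector 100·(1 − r_i/N_Y), whose mean is the overall
GOF, supports per-stimulus contrasts such as the animate/inanimate
contingency test (Fisher exact, two-sided, ties at the mean counted as
"not above").

## Transformation metrics

**Density curve and RDD.** T̂ is divided by its maximum absolute value;
d(P) is the fraction of entries whose absolute value strictly exceeds
P ∈ [0,1], evaluated on 101 evenly spaced thresholds (enough to resolve
the decay rates that occur in practice without destabilising the fit).
The strict inequality means exact zeros never count, so d(0) = 1 exactly
when the matrix has no exact zeros — true of every ridge estimate — and
d(0) < 1 flags exact zeros. d(1) = 0 always. RDD is the exponent b of
a·exp(bP) fitted to d by non-linear least squares
(`scipy.optimize.curve_fit`, initialised at a = first ordinate, b = −1,
with a > 0 bounded; fixed initialisation makes repeated fits
bit-identical). The max-abs normalisation makes RDD invariant to
rescaling T̂.

**Singular-value spectrum and RDSV.** The descending singular values of
T̂, truncated to P = min(rank X, rank Y), are fitted with the same
exponential against their integer index k = 1..P; RDSV is the fitted b.
The integer-index abscissa mirrors the density-curve construction; users
comparing spectra of different lengths can rescale b by P themselves.
The simulated ground-truth transformations use singular values exp(b·k)
on the same abscissa, so the noise-free closed loop recovers b exactly.

**Polar diagnostic.** For square T the polar factors T = P1·R = R·P2 are
built from the SVD (R = UV′, P1 = UΣU′, P2 = VΣV′). P1 and P2 are the
symmetric PSD *square roots* of TT′ and T′T — the form the decomposition
theorem requires, and the one under which eig(P1) equals the singular
values of T (the documented identity and test invariant).

## Monte Carlo calibration

Because the ridge estimate is smooth, RDD/RDSV confound the true
transformation's structure with the noise level; the calibration removes
the confound by simulating the whole estimation pipeline at known ground
truths. For each level (sparsity percent, or singular-value decay b) and
each noise fraction γ:

1. draw T with exactly round(s·N_Y·N_X/100) zeros at uniform positions
   and standard-normal nonzeros (sparsity), or T = U Σ_b V′ with
   prescribed spectrum exp(b·k) and bases from the SVD of a
   standard-normal matrix (deformation);
2. build Ỹ = (1−γ)TX/‖TX‖_F + γE/‖E‖_F with i.i.d. standard-normal E,
   then demean and standardise each stimulus column;
3. re-estimate T̂ at the *fixed* λ selected on the data under study, and
   record the decay metric and GOF;
4. average over n_sims draws per (level, γ) cell.

An observed (decay, GOF) point is then located by linearly interpolating
each level's mean-decay-versus-mean-GOF curve at the observed GOF and
returning the two adjacent levels whose interpolated decays enclose the
observed decay. A point shallower than the lowest sparsity curve is
flagged *not sparse*; a point whose GOF lies outside every curve's range
triggers an extrapolation warning. Linear interpolation in GOF is a
package choice; visual placement between curves has no canonical rule.

Default conditions: sparsity levels {50, 60, 70, 80, 90,
99}%, decay levels {0, −0.01, −0.1, −1}, γ from 0 to 0.9 in steps of
0.1, n_sims = 1000 per cell (configurable; the test suite uses 200, and
2–25 for smoke checks). Reproducibility: every (level, γ) cell draws
from its own seeded stream keyed on (seed, kind, level index, γ index),
so results are bit-identical regardless of evaluation order, and a fixed
`SimulationConfig` + seed reproduces the grid exactly.

## What the synthetic data emulate — and what they do not

The generator produces z-scored i.i.d. standard-normal input patterns
(real patterns in this paradigm are themselves consistent with standard
normality), couples regions through an exactly linear ground-truth T,
and mixes in isotropic Gaussian noise at a controlled fraction γ.
It does not emulate: spatial autocorrelation between neighbouring
voxels, stimulus-category structure in the patterns (category selectors
operate on labels, not on induced covariance), session-specific
scanner drifts, shared intrinsic fluctuations between regions (the very
confound the across-sessions averaging exists to suppress), or
non-linear coupling. Passing tests therefore establish that the
estimator and metrics behave correctly under the stated model — not that
real fMRI transformations are linear, nor that real-data sparsity
estimates inherit the simulation's recovery rates.

Two identifiability limits, measured with this package and consistent
with the method's own qualifications, are worth stating explicitly:

* At high noise (γ ≳ 0.6, cross-validated GOF near or below zero) the
  mean-RDD calibration curves for all sparsity levels collapse to within
  a fraction of the single-realisation spread; adjacent 10% sparsity
  windows are then not recoverable from one realisation at any problem
  size we tested. Sparsity bracketing should be trusted only in the
  positive-GOF regime.
* The calibration curves for singular-value decays 0 and −0.01
  practically coincide; the deformation bracket can distinguish decay
  *decades* (0 vs −0.1 vs −1), not neighbours at the resolution of 0.01.

## Numerical and design choices

* Linear solves use Cholesky factorisation of XX′+λI; λ = 0 is admitted
  only when XX′ is invertible.
* Degenerate inputs are errors, never silently handled: constant columns
  (zero variance) in z-scoring or correlation, all-zero matrices in the
  density normalisation, missing/non-finite cells in file loading.
* File formats: delimited text (comma/tab autodetected, optional header
  row and id column) and an HDF5 container; voxels-as-rows is canonical,
  with an explicit `transpose` flag instead of orientation guessing.
  Missing data are rejected, not imputed.
* Permutation test: stimulus columns of X are shuffled, λ is re-selected
  inside each permutation by default (the honest null; a fast mode
  reuses the observed λ), nulls are pooled across subjects, and the
  two-sample Kolmogorov–Smirnov p-value is reported. With very few
  subjects the K-S comparison is fragile, so the empirical null
  percentile of each observed GOF is reported alongside.
* LPRD uses Pearson correlation between the lower triangles of the two
  dissimilarity matrices by default, with Spearman as an option.
* Across-sessions metrics are the plain arithmetic means of the two
  directional fits; both directions are retained in the result object.

## Problem sizes used by the test suite

The parameter-recovery experiment runs at the toy scale used throughout
the package's own simulations — 128-voxel regions, 96 stimuli, square
128×128 ground-truth transformations — with n_sims = 200 calibration
draws per cell and 20 independent observation seeds per condition. The
deformation recovery grid uses the decade levels {0, −0.1, −1} (see the
identifiability note above). The acceptance script runs the density
computation at the full study sizes (224×96 input, 316×96 output).
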