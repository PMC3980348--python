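# Methods

## The model

Given a case/control phenotype vector `y ∈ R^n` and one or two
samples-by-variables matrices (for instance a SNP genotype matrix
`X1 ∈ R^{n×p1}` coded 0/1/2 and an fMRI voxel matrix `X2 ∈ R^{n×p2}`),
the fused sparse model is

    y = [α1·X1, α2·X2] δ + ε ,   α1 + α2 = 1,  α1, α2 > 0,

with every column scaled to unit L2 norm before weighting. The nonzero
entries of the sparse coefficient vector `δ` mark the phenotype-associated
variables; the weight `α1` steers how much of the selection budget each
modality receives.

In the regimes this package targets, `p` is vastly larger than `n`
(hundreds of samples against ~10^5–10^6 variables). Once `p` exceeds
roughly `35·n` the design cannot satisfy the restricted-isometry condition
under which one-shot sparse recovery is guaranteed, and a single sparse
regression returns at most `n` variables regardless of how many are truly
associated.

## The windowed selector

Instead of one global solve, the selector repeats:

1. shuffle all `p` column indices (Fisher–Yates) and cut the permutation
   into consecutive windows of length `k` (the last window may be
   shorter); every column is visited exactly once per pass;
2. for each window, sparse-code `y` on the window's columns with
   orthogonal matching pursuit (OMP) under the residual budget
   `eps = tau_omp · ||y||_2` and the atom cap `min(n, k)`;
3. add the window solution into a running accumulator
   `δ_l(I_l) = δ_{l-1}(I_l) + δ̂_l`;
4. after every step from `l = 2` on, record
   `c_l = ||δ_l/l − δ_{l-1}/(l−1)||_2`; stop when `c_l ≤ α` (checked only
   once at least `min_passes` complete passes have run, so no column can
   be missed) or when `l` reaches `max_steps`.

The result is the averaged vector `δ = δ_l / l`. Because the average
changes by `O(1/l)` per step, the tolerance `α` effectively sets a pass
budget; runs that reach `max_steps` first are reported (`converged =
False`, a `RuntimeWarning`) but still return the averaged vector, which
is a valid — just less settled — ranking.

The window length `k` is the resolution control. At `k = p` every step
solves the same full-design problem, the average is constant, and the
support can hold at most `n` variables. Shrinking `k` removes strong
columns from most windows, so weaker columns get selected in their
place: the support grows, and the variables found at coarse resolution
tend to reappear at finer resolution (measured nesting fraction ≈ 0.88
on 100×10^4 white noise over 10 seeds). The per-window solver for the
L0 penalty is OMP; `norm_order=1` switches to a LARS/lasso homotopy path
with the same stopping contract. Fractional pseudo-norms between 0 and 1
are not implemented.

## Sparsity control after the solve

The entries of `δ` are ranked by amplitude. Two trimming rules:

* **top-N**: keep the `N` largest amplitudes (ties broken by ascending
  column index, so results are reproducible);
* **residual threshold**: keep the shortest prefix whose truncated
  expansion satisfies `||y − X δ^(m)||_2 ≤ tau · ||y||_2`, where
  `δ^(m)` zeroes all but the top `m` entries.

The truncated residual deliberately reuses the accumulated coefficients
without a least-squares refit on the retained support: with more
retained columns than samples a refit reaches residual zero and the
curve would carry no information. As a consequence the curve need not be
strictly monotone — dropping to `m` terms can raise the residual by at
most the first omitted amplitude — but in practice the rises are tiny
(≲ 10^-4 of `||y||` at the scales above).

## Phenotype coding and normalization

Cases are coded +1 and controls −1 (a symmetric coding, so correlations
are two-sided). Inside the solver, `y` is centered and scaled to unit L2
norm; this makes `eps = tau_omp · ||y||` and the convergence tolerance
`α` scale-free. Design columns are mean-centered before unit
normalization: without centering, allele-frequency intercepts dominate
the correlation between a genotype column and the centered phenotype.
Columns that are constant (monomorphic SNPs) become zero after
centering; they are kept in place, flagged unselectable, and can never
be picked (their correlation with any residual is exactly zero), so
column indices remain stable across runs.

## Classification and validation

The sparse-representation classifier (SRC) codes a unit-normalized test
sample over a dictionary whose columns are unit-normalized training
samples, then assigns the class whose own atoms reconstruct it best.
Three design choices depart from the textbook construction, each forced
by a measurable failure mode on synthetic data:

* **Positive-correlation atom selection.** Centered two-class data is
  antipodal: −1 times a control reconstructs a case exactly, so
  magnitude-based atom selection is uninformative (perfectly separable
  planted data classified at chance). Atoms are therefore selected by
  largest signed correlation; the coefficient refit stays unconstrained.
* **Class-balanced dictionary.** Residual comparison favors the class
  with more columns; in leave-one-out folds the held-out sample's class
  always has one fewer training sample, which biases null-data accuracy
  below chance. The majority class is subsampled (seeded) to the
  minority size.
* **Per-class refit residuals.** The class residual is the projection
  residual of the test vector on the class-restricted coding support.
  Splitting the *joint* coefficient vector by class is unstable when
  near-parallel atoms from different classes carry large cancelling
  coefficients.

Coding stops at a residual of `0.05·||x||` or `min(dim, n_train)` atoms.
Ties in the class-residual comparison go to the class listed first.

Validation is leave-one-out: for each sample, the fused design is
rebuilt from the remaining `n−1` samples (centering, scaling and
weighting refit), the windowed selection is rerun with a fold-specific
seed, the classifier is fit on the training rows restricted to the
selected variables, and the held-out sample is mapped through the
training-fitted transform before classification. The held-out sample
therefore never influences selection, normalization or the dictionary.
The classification ratio (CR) is the fraction of folds predicted
correctly. Two methods evaluated over the same weight-factor grid are
compared with a two-sided Wilcoxon signed-rank test, exact for up to 25
informative pairs; identical CR vectors return p = 1.

## Synthetic data

Two generators define the test conditions:

* **White noise**: i.i.d. standard normal entries with balanced labels
  carrying no signal — the null against which selection counts,
  residual curves and chance-level classification are calibrated. The
  reference configuration is 100 samples (50/50) by 10^6 variables; the
  property suites run a 100×10^4 version.
* **Planted signal**: `q` columns carry a true effect — continuous columns
  whose class means differ by `effect` noise-SDs (Cohen's d), or
  Hardy–Weinberg genotype columns (Binomial(2, f), f uniform in the MAF
  range) whose case allele frequency is shifted by `effect`. Truth
  tables record the signal columns for recovery scoring.

Generation is chunked column-wise (16 384 columns per chunk) with a
counter-based seeding scheme, so the 100×10^6 matrix is produced
incrementally and regeneration with the same seed is bit-identical.

The generators deliberately omit linkage disequilibrium between SNPs and
spatial autocorrelation between voxels. Passing recovery and calibration
tests therefore demonstrates correctness of the machinery under
independent columns, not performance under the correlated designs of
real imaging-genetics data; in particular the tendency to select
spatially clustered voxels cannot be probed without a spatially
correlated generator.

## Numerical choices

* OMP maintains an incremental Cholesky factor of the selected Gram
  matrix (two triangular solves per iteration); a final least-squares
  refit on the completed support guards against drift on
  ill-conditioned supports. A candidate whose squared distance to the
  selected span falls below 10^-12 is treated as dependent and stops the
  pursuit.
* The weight grid is computed in exact decimal arithmetic
  (`0.3, 0.32, …, 0.6`), so grid endpoints and membership are exact and
  the span must be an integer multiple of the step.
* Default parameters: `tau_omp = 0.3` (the residual budget used for the
  real-data analyses the model derives from), `α = 1e-3`, `min_passes =
  1`, `max_steps = 50·⌈p/k⌉`, SRC coding residual `0.05`.
* Per-fold and per-component seeds are derived through
  `numpy.random.SeedSequence`, keeping every derived seed below 2^31.

## Problem sizes used by the test and acceptance suites

The suites are sized for a single CPU: the OMP/brute-force comparison
uses 50 instances of 8×12 (mutual coherence ≤ 0.45, obtained by
row-subsampling random orthogonal matrices); the resolution sweep and
curve-shape checks use 100×10^4 white noise over 10 seeds; recovery uses
n = 100, p = 2000, q = 10, d = 2 over 10 seeds; classifier calibration
uses n = 30 (separable) and n = 40 over 10–20 permuted-noise seeds. The
acceptance script additionally runs the full-scale 100×10^6 white-noise
curve with k = 2·10^4.

## Known limitations

* The convergence tolerance is absolute and interacts with the `O(1/l)`
  decay of the average: for small `α` the `max_steps` cap is the
  operative stop. This is by design (bounded runtime) but means
  `converged=False` is common and benign.
* Selections at small `k` on null data can cover every column; the
  amplitude ranking, not the support size, is then the informative
  output.
* Exactly duplicated columns are selected exchangeably only in
  distribution (the within-window order is randomized per pass), not
  deterministically.
* At most two modalities are fused; the generalization to more blocks is
  mechanical but untested here.
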