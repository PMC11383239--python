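# Methods

## Model and objective

Given column-standardised views **X** ∈ ℝⁿˣᵖˣ and **Y** ∈ ℝⁿˣᵖʸ over the
same n samples, the first canonical pair maximises
corr(**Xa**, **Yb**) = ⟨**Xa**, **Yb**⟩ / (‖**Xa**‖₂‖**Yb**‖₂). Sparsity
is imposed through the constraint set ‖**a**‖₂² ≤ 1, ‖**a**‖₁ ≤ c_x
(and analogously for **b**). For 1 < c < √p the L1 and L2 constraints
interact and zero out coefficients; at c = 1 the solution is maximally
sparse (a single nonzero), and at c ≥ √p the L1 constraint is inactive,
so sweeping c from 1 to p covers the full regularisation range. Budgets
outside [1, p] are clamped to that interval.

Only the first canonical pair is modelled; higher-order pairs, kernel
variants and more than two views are out of scope.

### PMD-CCA

Treats **XᵀX** and **YᵀY** as diagonal and maximises the numerator
⟨**Xa**, **Yb**⟩ alone. With **M** = **XᵀY**, the a-update for fixed
**b** has the closed form a ← S(**Mb**, Δ)/‖S(**Mb**, Δ)‖₂, where S is
elementwise soft-thresholding and Δ ≥ 0 is the smallest threshold that
brings the L1 norm within budget. Δ is located by bisection on
‖w‖₁ − c with tolerance 1e-8; when entries tie exactly at the maximum
the L1 target can be unreachable, in which case the projection falls
back to the unit vector on the first argmax (deterministic). Updates
alternate from the leading singular-vector pair of **M** until the
maximal absolute coefficient change falls below `tol` (default 1e-6)
or `max_iter` (default 200) is reached; non-convergence is flagged on
the returned model, not raised. The reported correlation is always the
full cosine objective, so PMD-CCA and SCCA-EC values are comparable.

### SCCA-EC

Optimises the full correlation objective under the same constraints by
alternating projected gradient ascent: for fixed **b**, a gradient step
on corr(**Xa**, **Yb**) with backtracking line search (step halved until
the projected candidate does not decrease the objective, floor 1e-10),
followed by the same soft-threshold-to-L1-then-L2-renormalise
projection. Because the objective is scale-invariant the renormalisation
cannot change it. The exact step-size policy of the published
projected-gradient algorithm this follows is not specified in detail
anywhere we could rely on, so the backtracking rule here is this
package's own concrete choice; it guarantees a monotone objective
sequence, which the test suite checks. Convergence is declared when the
relative objective improvement over a full sweep drops below `tol`.

Both solvers enforce a sign convention of non-negative correlation by
flipping **b** if needed; CCA is sign-indeterminate. A coefficient
counts as "selected" iff its magnitude exceeds 1e-10, guarding against
float noise in nominally zero entries.

## Stability selection

`2 · n_splits` subsamples are formed by randomly splitting the samples
in half `n_splits` times (default 50 → 100 subsamples of size ⌊n/2⌋;
for odd n one sample per split is left out). The budget grid has
`grid_size` (default 100) pairs c_x,i = p_x^((i−1)/(m−1)),
c_y,i = p_y^((i−1)/(m−1)) — log-spaced so the sparse end, where
selection is informative, is sampled more densely. Each subsample is
re-standardised before solving, since subsample means and variances
differ from the full data; a column that is constant within a subsample
is centred but not rescaled, making it identically zero and hence
unselectable while remaining countable. Counts are accumulated per
subsample and reduced by summation, so results are bit-identical for
any `n_jobs`. A solver failure in one (subsample, budget) cell counts
as no selection for every variable in that cell and is logged.

The stability score is the unweighted mean of a variable's selection
probability over the grid *indices* (equivalently, the area under the
stability path in index space). Because the grid is log-spaced, this
weights the sparse end more heavily than a mean in c-space would — the
intended emphasis.

Top-k selection ranks all p_x + p_y variables jointly and keeps the
top k; ties break deterministically (X view first, then ascending
index). A CCA model needs at least one variable per view, so if the
top-k set leaves a view empty its single best variable replaces the
globally lowest-ranked pick; threshold selection instead raises, since
silently altering τ would misrepresent the rule. The refit sets the
budgets to the restricted dimensions — the point at which no further
sparsity is induced — and re-embeds the coefficients into full-length
vectors.

## Synthetic data

Two generators plant a known sparse cross-view dependency; ground-truth
coefficients are U[0, 1] draws on uniformly random supports of size
p_x_true = 10 and p_y_true = 15 (defaults).

* **Single latent**: one factor Z_i ~ N(0, 1) per sample;
  X_ij ~ N(Z_i a_j, noise_var), same for Y, with noise_var = 0.5.
  "N(μ, 0.5)" is read in the standard variance parametrisation; the
  standard-deviation reading is one `noise_var` change away. The
  population correlation between a true column and the factor is
  a_j/√(a_j² + noise_var), which the tests verify at large n.
* **Multivariate**: joint draws from N(0, Σ) with unit diagonal, 0.5
  within-view correlation among true variables, and cross-view block
  **a**_true **b**_trueᵀ. The rank-one cross block is not constrained by
  the diagonal blocks, so Σ can be indefinite for some coefficient
  draws; it is repaired by clipping eigenvalues from below at 1e-8 and
  re-symmetrising (the Frobenius magnitude of the repair is available
  from `build_covariance(..., return_repair=True)`). Rejecting
  indefinite draws instead would bias the ground-truth distribution,
  which is why clipping was chosen.

Scenario difficulty is set by the true sparsity s_x ∈ {1/2, 1/4, 1/10}
of the X view with s_y = s_x/2, giving view dimensions
(20, 60), (40, 120), (100, 300); training sets have n = 50 samples and
test sets 100. These generators emulate the dimensionality, sparsity
and view asymmetry of paired omics tables, but not their compositional
structure, zero inflation, heavy tails or batch effects — passing tests
demonstrate correct recovery of planted linear-Gaussian structure, not
performance guarantees on real abundance data.

## Metrics and tuning

* **Recovery AUC**: rank AUC (midrank ties) of an importance score —
  |coefficients| for base solvers, stability scores for the pipeline —
  against the true support.
* **Balanced accuracy**: (sensitivity + specificity)/2 of a hard
  selection.
* **Stability**: the Nogueira et al. estimator
  Φ = 1 − mean_f(s_f²) / ((k̄/d)(1 − k̄/d)) with s_f² the unbiased
  (M/(M−1)) variance of variable f's selection indicator across the M
  selections and k̄ the mean selection size; Φ = 1 iff all sets are
  identical, its lower bound is −1/(M−1), and its expectation under
  uniformly random selection is 0. Selections are concatenated X|Y
  masks of length p_x + p_y. The estimator is undefined (raises) when
  selections are on average empty or full.
* **Test correlation**: frozen (a, b) applied to a held-out set
  standardised with its own statistics.

Tuning maximises the mean held-out correlation over repeated k-fold CV
(default 10 rounds × 3 folds). Base solvers: exhaustive 15 × 15 grid,
evenly spaced over [1, p_x] × [1, p_y], ties to the sparsest pair.
Threshold: 100 candidates spanning [min score, max score], infeasible
candidates skipped, ties to the larger τ. Top-k: interval-thirds
(ternary) probing of k ∈ [2, p_x + p_y] with all probes cached and the
best evaluated k returned (ties to the smaller k); this assumes an
approximately unimodal CV curve in k, a heuristic rather than a
guarantee. CV tie-breaking always prefers the sparser model. A failed
fold fit scores 0 and is logged. All fold assignments, subsample draws
and data draws derive deterministically from one run-level seed.

The benchmark orchestrator (`run_simulation_study`) runs
`n_truths × n_repeats` train/test pairs per scenario, averages AUC,
balanced accuracy and test correlation over all runs, computes
stability within each ground truth's repeats, and reports failures
per cell.

## Problem sizes in the shipped checks

The test suite exercises the full pipeline at a reduced but
representative scale chosen by this package: the s_x = 1/2 single-latent
scenario (20 + 60 variables, n = 50), a stability loop of 40 subsamples
× 30 grid points, 10 replicates, CV with 3 rounds × 3 folds and a 7 × 7
base-tuning grid. At this scale the stability scores recover the
planted variables with mean AUC ≈ 0.92 and the top-k pipeline's
selection stability clearly exceeds the CV-tuned base solver's — the
method's central claim. Unit tests verify the solvers against
independent oracles (dense SVD of **XᵀY** for PMD-CCA with inactive
constraints; a generalised-eigenvalue classical-CCA solution for
SCCA-EC) and the counting loop against a direct re-implementation.

## Real-data application layer

Abundance tables are preprocessed with the generalised log transform
glog(x) = log(x + √(x² + 10⁻⁸)) — finite at zero (glog(0) = log 10⁻⁴),
≈ log(2x) for large x — then zero-variance variables are removed and
columns standardised, in that order. The fitted model's correlation
decomposes exactly into pairwise shares
a_j **X**_jᵀ **Y**_k b_k / ⟨**Xa**, **Yb**⟩, which sum to 1; rows of
this matrix sum to each X-variable's marginal share. A per-sample
disease score is the sum of canonical variables **Xa** + **Yb**; since
canonical signs are arbitrary, a status AUC below 0.5 flips the score.
Coefficients from two models that share one view (e.g. two alternative
metagenome representations each fitted against metabolites) can be
compared directly via the correlation of their projections and the same
share decomposition; that decomposition is undefined (returned as
`None`) when the total inner product is exactly zero.

Views entering through files are aligned on shared sample IDs in
first-file order, with unmatched IDs dropped and reported. Tables are
written with 10 significant digits; every output file embeds the run
seed and a hash of the configuration, so equal hashes imply equal
numeric outputs.

## Known limitations

* Only the first canonical pair; no deflation for further pairs.
* SCCA-EC's projected gradient can stall at non-global stationary
  points on ill-conditioned data; the SVD initialisation makes this
  rare in practice but it is not excluded.
* The stability loop costs |subsamples| × |grid| solver fits; the
  defaults (100 × 100) are intended for p up to a few thousand with the
  PMD base, and `n_jobs` parallelises over subsamples without changing
  results.
* Gaussian simulation only; no compositional or zero-inflated
  generators.
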