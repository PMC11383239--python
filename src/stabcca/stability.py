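"""Stability selection for sparse CCA.

The stability loop perturbs the data by repeated half-subsampling and
sweeps a logarithmic grid of sparsity budgets from the maximally sparse
point (1, 1) to the unconstrained point (p_x, p_y). For every
(subsample, budget) cell a sparse-CCA model is fitted and each
variable's selection (nonzero coefficient) is recorded. The resulting
selection-probability matrices P_X, P_Y — a variable's *stability path*
over the budget grid — summarise how robustly each variable enters the
model across sparsity levels and data perturbations.

A variable's *stability score* is the area under its stability path:
the mean selection probability over the sampled grid. Variables are then
chosen either as the k highest-scoring overall ("top-k") or as all
variables scoring above a threshold tau ("threshold"), and a final
unpenalised CCA model is refitted on the selected columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .solvers import (
    NONZERO_TOL,
    CanonicalModel,
    SCCAParams,
    solve,
)
from .views import as_matrix, standardize_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "SubsampleSet",
    "ParameterGrid",
    "StabilityPath",
    "SelectionResult",
    "make_subsamples",
    "make_parameter_grid",
    "stability_cca",
    "stability_scores",
    "select_top_k",
    "select_threshold",
    "refit",
    "StabilityCCA",
]


@dataclass
class SubsampleSet:
    """Row-index subsets used to perturb the data.

    Generated as ``n_splits`` random half-splits of the samples with
    both halves kept, so the default 50 splits yield 100 subsamples of
    size floor(n/2). Within one split the halves are disjoint; for odd n
    one sample is left out of the split entirely.
    """

    index_subsets: list[np.ndarray]
    seed: int

    def __len__(self) -> int:
        return len(self.index_subsets)


@dataclass
class ParameterGrid:
    """Ordered (c_x, c_y) budget pairs from (1, 1) to (p_x, p_y).

    Log-spaced: ``c_x[i] = p_x ** (i / (m - 1))``, so the sparse end of
    the path is sampled more densely.
    """

    c_x: np.ndarray
    c_y: np.ndarray

    def __post_init__(self):
        self.c_x = np.asarray(self.c_x, dtype=float)
        self.c_y = np.asarray(self.c_y, dtype=float)
        if self.c_x.shape != self.c_y.shape:
            raise ValueError("c_x and c_y sequences must have equal length")

    @property
    def m(self) -> int:
        return len(self.c_x)

    def pairs(self):
        return list(zip(self.c_x, self.c_y))


@dataclass
class StabilityPath:
    """Selection probabilities over the budget grid, per view.

    ``p_x_probs[i, j]`` is the fraction of subsamples in which variable
    j of the X view had a nonzero coefficient at budget pair i; every
    entry is an integer multiple of 1/n_subsamples.
    """

    p_x_probs: np.ndarray
    p_y_probs: np.ndarray
    grid: ParameterGrid
    method: str
    n_subsamples: int
    n_failures: int = 0


@dataclass
class SelectionResult:
    """Chosen variable subsets plus the refitted unpenalised model."""

    selected_x: np.ndarray
    selected_y: np.ndarray
    strategy: str
    hyperparameter: float
    refit: CanonicalModel
    names_x: list[str] = field(default_factory=list)
    names_y: list[str] = field(default_factory=list)


def make_subsamples(n: int, n_splits: int = 50, seed: int = 0) -> SubsampleSet:
    """Draw ``2 * n_splits`` half-subsamples of size floor(n/2).

    Each split permutes the sample indices and keeps both halves, so the
    halves of one split are disjoint and (for even n) cover all samples.
    Reproducible from ``seed``.
    """
    if n < 4:
        raise ValueError(f"need n >= 4 samples to form half-subsamples, got {n}")
    rng = np.random.default_rng(seed)
    half = n // 2
    subsets: list[np.ndarray] = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        subsets.append(np.sort(perm[:half]))
        subsets.append(np.sort(perm[half : 2 * half]))
    return SubsampleSet(subsets, seed)


def make_parameter_grid(p_x: int, p_y: int, m: int = 100) -> ParameterGrid:
    """Log-spaced budget grid from (1, 1) to (p_x, p_y) with m points."""
    if p_x < 2 or p_y < 2:
        raise ValueError("need at least 2 variables per view for a budget grid")
    if m < 2:
        raise ValueError("grid size m must be at least 2")
    expo = np.arange(m) / (m - 1)
    return ParameterGrid(float(p_x) ** expo, float(p_y) ** expo)


def _count_one_subsample(X, Y, idx, grid, method, max_iter, tol):
    """Selection-count matrices (m x p) contributed by one subsample."""
    Xs = standardize_matrix(X[idx])
    Ys = standardize_matrix(Y[idx])
    m = grid.m
    count_x = np.zeros((m, X.shape[1]), dtype=np.int64)
    count_y = np.zeros((m, Y.shape[1]), dtype=np.int64)
    failures = 0
    for i, (cx, cy) in enumerate(grid.pairs()):
        params = SCCAParams(c_x=cx, c_y=cy, max_iter=max_iter, tol=tol, method=method)
        try:
            model = solve(Xs, Ys, params)
        except (ValueError, np.linalg.LinAlgError) as exc:
            failures += 1
            logger.warning("solver failed at grid index %d on a subsample: %s", i, exc)
            continue
        count_x[i] = np.abs(model.a) > NONZERO_TOL
        count_y[i] = np.abs(model.b) > NONZERO_TOL
    return count_x, count_y, failures


def stability_cca(
    X,
    Y,
    method: str = "pmd",
    subsamples: SubsampleSet | None = None,
    grid: ParameterGrid | None = None,
    *,
    n_splits: int = 50,
    grid_size: int = 100,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    n_jobs: int = 1,
) -> StabilityPath:
    """Run the stability-selection loop over subsamples and budget grid.

    For every subsample the rows are re-standardised (subsample means
    and variances differ from the full data) and a sparse-CCA model is
    fitted at every budget pair; a failed solve contributes no
    selections for that cell. Counts are accumulated per subsample and
    reduced by summation, so the result is independent of execution
    order (and of ``n_jobs``).
    """
    X = as_matrix(X)
    Y = as_matrix(Y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("views have mismatched sample counts")
    if subsamples is None:
        subsamples = make_subsamples(X.shape[0], n_splits=n_splits, seed=seed)
    if grid is None:
        grid = make_parameter_grid(X.shape[1], Y.shape[1], m=grid_size)
    for idx in subsamples.index_subsets:
        if len(idx) < 4:
            raise ValueError("each subsample needs at least 4 rows")

    if n_jobs == 1:
        parts = [
            _count_one_subsample(X, Y, idx, grid, method, max_iter, tol)
            for idx in subsamples.index_subsets
        ]
    else:
        parts = Parallel(n_jobs=n_jobs)(
            delayed(_count_one_subsample)(X, Y, idx, grid, method, max_iter, tol)
            for idx in subsamples.index_subsets
        )
    count_x = sum(p[0] for p in parts)
    count_y = sum(p[1] for p in parts)
    n_failures = sum(p[2] for p in parts)
    n_sub = len(subsamples)
    return StabilityPath(
        count_x / n_sub, count_y / n_sub, grid, method, n_sub, n_failures
    )


def stability_scores(path: StabilityPath) -> tuple[np.ndarray, np.ndarray]:
    """Per-variable stability score: area under the stability path.

    The unweighted mean of the selection probability over the grid
    indices; values lie in [0, 1] and values near one mark variables
    selected almost always, even in very sparse models.
    """
    return path.p_x_probs.mean(axis=0), path.p_y_probs.mean(axis=0)


def select_top_k(scores_x, scores_y, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Select the k highest-scoring variables, ranked jointly over views.

    Ties are broken deterministically: X view before Y view, then
    ascending variable index. A CCA model needs at least one variable
    per view, so if the joint top-k leaves a view empty, that view's
    single best variable replaces the globally lowest-ranked pick.
    """
    scores_x = np.asarray(scores_x, dtype=float)
    scores_y = np.asarray(scores_y, dtype=float)
    p_x, p_y = len(scores_x), len(scores_y)
    if k < 2:
        raise ValueError("k must be at least 2 (one variable per view)")
    k = min(k, p_x + p_y)
    # entries: (score, view, index); sort by -score, view order, index
    entries = [(scores_x[j], 0, j) for j in range(p_x)]
    entries += [(scores_y[j], 1, j) for j in range(p_y)]
    entries.sort(key=lambda e: (-e[0], e[1], e[2]))
    chosen = entries[:k]
    views = {v for _, v, _ in chosen}
    if 0 not in views or 1 not in views:
        missing = 0 if 0 not in views else 1
        best_missing = next(e for e in entries if e[1] == missing)
        chosen = chosen[:-1] + [best_missing]
    sel_x = np.array(sorted(j for _, v, j in chosen if v == 0), dtype=int)
    sel_y = np.array(sorted(j for _, v, j in chosen if v == 1), dtype=int)
    return sel_x, sel_y


def select_threshold(scores_x, scores_y, tau: float) -> tuple[np.ndarray, np.ndarray]:
    """Select all variables with stability score strictly above tau."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    sel_x = np.flatnonzero(np.asarray(scores_x, dtype=float) > tau)
    sel_y = np.flatnonzero(np.asarray(scores_y, dtype=float) > tau)
    if len(sel_x) == 0:
        raise ValueError(f"threshold {tau} leaves the X view empty; lower tau")
    if len(sel_y) == 0:
        raise ValueError(f"threshold {tau} leaves the Y view empty; lower tau")
    return sel_x, sel_y


def refit(X, Y, selection, method: str = "pmd", **solver_kw) -> CanonicalModel:
    """Unpenalised CCA refit on the selected columns.

    The budgets are set to the restricted dimensions — the point at
    which no further sparsity is induced — and the coefficients are
    re-embedded into full-length vectors with zeros elsewhere.
    """
    X = as_matrix(X)
    Y = as_matrix(Y)
    sel_x, sel_y = (np.asarray(s, dtype=int) for s in selection)
    if len(sel_x) == 0 or len(sel_y) == 0:
        raise ValueError("refit needs a non-empty selection in both views")
    Xr = X[:, sel_x]
    Yr = Y[:, sel_y]
    params = SCCAParams(
        c_x=float(len(sel_x)), c_y=float(len(sel_y)), method=method, **solver_kw
    )
    sub = solve(Xr, Yr, params)
    a = np.zeros(X.shape[1])
    b = np.zeros(Y.shape[1])
    a[sel_x] = sub.a
    b[sel_y] = sub.b
    return CanonicalModel(a, b, sub.correlation, method, sub.n_iter, sub.converged)


class StabilityCCA(BaseEstimator):
    """Stability-selection wrapper around a sparse-CCA base solver.

    Fitting runs the base solver (``method='pmd'`` or ``'ec'``) on
    ``2 * n_splits`` half-subsamples across a log-spaced grid of
    ``grid_size`` sparsity-budget pairs, records per-variable selection
    probabilities, and reduces them to stability scores. If a selection
    ``strategy`` is given, the scored variables are selected ("top_k"
    with hyperparameter ``k``, or "threshold" with ``tau``) and an
    unpenalised CCA model is refitted on them.

    Parameters
    ----------
    method : {'pmd', 'ec'}, default 'pmd'
        Base sparse-CCA solver.
    n_splits : int, default 50
        Number of random half-splits; both halves are used, giving
        ``2 * n_splits`` subsamples.
    grid_size : int, default 100
        Number of (c_x, c_y) budget pairs between (1, 1) and (p_x, p_y).
    strategy : {'top_k', 'threshold', None}, default 'top_k'
        Variable-selection rule applied to the stability scores; None
        computes the path and scores only.
    k : int, default 10
        Number of variables (jointly over views) for 'top_k'.
    tau : float, default 0.5
        Score threshold for 'threshold'.
    scale : bool, default True
        Standardise the full data before the loop (each subsample is
        additionally re-standardised internally).
    random_state : int, default 0
        Seed for the subsample draws.
    n_jobs : int, default 1
        Parallelism over subsamples (joblib); results are independent
        of this value.

    Attributes
    ----------
    path_ : StabilityPath
        Selection-probability matrices over the grid.
    scores_x_, scores_y_ : ndarray
        Stability scores per variable (mean selection probability).
    selected_x_, selected_y_ : ndarray
        Selected variable indices (when a strategy is set).
    x_weights_, y_weights_ : ndarray
        Refitted canonical coefficients, full length, zeros off-support.
    correlation_ : float
        Canonical correlation of the refitted model on training data.
    """

    def __init__(
        self,
        method: str = "pmd",
        *,
        n_splits: int = 50,
        grid_size: int = 100,
        strategy: str | None = "top_k",
        k: int = 10,
        tau: float = 0.5,
        scale: bool = True,
        max_iter: int = 200,
        tol: float = 1e-6,
        random_state: int = 0,
        n_jobs: int = 1,
    ):
        self.method = method
        self.n_splits = n_splits
        self.grid_size = grid_size
        self.strategy = strategy
        self.k = k
        self.tau = tau
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.n_jobs = n_jobs

    def fit(self, X, Y):
        X = np.asarray(as_matrix(X), dtype=float)
        Y = np.asarray(as_matrix(Y), dtype=float)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("views have mismatched sample counts")
        self._x_mean = X.mean(axis=0)
        self._y_mean = Y.mean(axis=0)
        if self.scale:
            xsd = X.std(axis=0)
            ysd = Y.std(axis=0)
            self._x_std = np.where(xsd > 0, xsd, 1.0)
            self._y_std = np.where(ysd > 0, ysd, 1.0)
        else:
            self._x_std = np.ones(X.shape[1])
            self._y_std = np.ones(Y.shape[1])
        Xs = (X - self._x_mean) / self._x_std
        Ys = (Y - self._y_mean) / self._y_std

        self.path_ = stability_cca(
            Xs,
            Ys,
            method=self.method,
            n_splits=self.n_splits,
            grid_size=self.grid_size,
            seed=self.random_state,
            max_iter=self.max_iter,
            tol=self.tol,
            n_jobs=self.n_jobs,
        )
        self.scores_x_, self.scores_y_ = stability_scores(self.path_)

        if self.strategy is not None:
            if self.strategy == "top_k":
                sel = select_top_k(self.scores_x_, self.scores_y_, self.k)
                hyper = float(self.k)
            elif self.strategy == "threshold":
                sel = select_threshold(self.scores_x_, self.scores_y_, self.tau)
                hyper = float(self.tau)
            else:
                raise ValueError(f"unknown strategy {self.strategy!r}")
            model = refit(
                Xs, Ys, sel, method=self.method, max_iter=self.max_iter, tol=self.tol
            )
            self.selected_x_, self.selected_y_ = sel
            self.x_weights_ = model.a
            self.y_weights_ = model.b
            self.correlation_ = model.correlation
            self.selection_ = SelectionResult(
                sel[0], sel[1], self.strategy, hyper, model
            )
        return self

    def transform(self, X, Y=None):
        """Project data onto the refitted canonical directions."""
        check_is_fitted(self, "x_weights_")
        u = ((np.asarray(X, dtype=float) - self._x_mean) / self._x_std) @ self.x_weights_
        if Y is None:
            return u
        v = ((np.asarray(Y, dtype=float) - self._y_mean) / self._y_std) @ self.y_weights_
        return u, v
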