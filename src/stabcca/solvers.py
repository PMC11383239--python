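"""Sparse canonical correlation analysis solvers.

Two solvers for the first pair of sparse canonical coefficients (a, b)
under joint L1/L2 constraints ||a||_2 <= 1, ||a||_1 <= c_x (and likewise
for b):

* **PMD-CCA** — penalised-matrix-decomposition CCA. Treats the
  within-view covariances as diagonal and maximises the cross-covariance
  <Xa, Yb> by exact alternating updates: each half-step is a
  soft-threshold-and-renormalise projection of X^T Y b (resp. Y^T X a).
* **SCCA-EC** — sparse CCA with elastic-net-style constraints. Keeps the
  full correlation objective corr(Xa, Yb) and alternates projected
  gradient ascent steps with backtracking line search, projecting onto
  the same L1/L2 constraint set after every step.

Both interact sparsity through the L1 budget: at c = 1 the coefficient
vector is maximally sparse (a single nonzero), while c >= sqrt(p) leaves
the L1 constraint inactive and no sparsity is imposed.

Solvers operate on column-standardised matrices; use
:func:`stabcca.views.standardize` (or the estimators' ``scale=True``)
beforehand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import svd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .views import as_matrix, standardize_matrix

__all__ = [
    "NONZERO_TOL",
    "SCCAParams",
    "CanonicalModel",
    "init_coefficients",
    "l1_l2_truncate",
    "canonical_correlation",
    "pmd_cca",
    "scca_ec",
    "PMDCCA",
    "SCCAEC",
]

#: a coefficient counts as selected iff its magnitude exceeds this
NONZERO_TOL = 1e-10


@dataclass
class SCCAParams:
    """Hyperparameters of a sparse-CCA solve.

    c_x, c_y are the L1 budgets for a and b. The meaningful range is
    [1, p]; values outside are clamped. ``None`` means "no sparsity"
    (the budget is set to the view's dimension).
    """

    c_x: float | None = None
    c_y: float | None = None
    max_iter: int = 200
    tol: float = 1e-6
    method: str = "pmd"


@dataclass
class CanonicalModel:
    """First pair of canonical coefficients and their correlation."""

    a: np.ndarray
    b: np.ndarray
    correlation: float
    method: str
    n_iter: int
    converged: bool = True

    @property
    def selected_x(self) -> np.ndarray:
        """Indices of X-variables with a nonzero coefficient."""
        return np.flatnonzero(np.abs(self.a) > NONZERO_TOL)

    @property
    def selected_y(self) -> np.ndarray:
        return np.flatnonzero(np.abs(self.b) > NONZERO_TOL)


def _clamp_budget(c: float | None, p: int) -> float:
    if c is None:
        return float(p)
    return float(min(max(c, 1.0), p))


def init_coefficients(X, Y) -> tuple[np.ndarray, np.ndarray]:
    """Leading singular-vector pair of the cross-covariance X^T Y.

    The first left/right singular vectors of X^T Y are a good, cheap
    initialisation for both alternating solvers. If X^T Y is (numerically)
    zero the SVD direction is arbitrary; uniform unit vectors are
    returned with a warning.
    """
    X = as_matrix(X)
    Y = as_matrix(Y)
    M = X.T @ Y
    if np.abs(M).max(initial=0.0) < 1e-14:
        warnings.warn(
            "cross-covariance X^T Y is numerically zero; "
            "falling back to uniform initial coefficients",
            UserWarning,
            stacklevel=2,
        )
        a = np.full(X.shape[1], 1.0 / np.sqrt(X.shape[1]))
        b = np.full(Y.shape[1], 1.0 / np.sqrt(Y.shape[1]))
        return a, b
    U, _, Vt = svd(M, full_matrices=False)
    return U[:, 0].copy(), Vt[0].copy()


def _soft(v: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - delta, 0.0)


def l1_l2_truncate(v, c: float, tol: float = 1e-8) -> np.ndarray:
    """Project onto the intersection of the unit L2 ball and the L1 ball.

    Returns ``w = S(v, delta) / ||S(v, delta)||_2`` where ``S`` is
    elementwise soft-thresholding and ``delta >= 0`` is the smallest
    threshold for which ``||w||_1 <= c``, located by bisection
    (tolerance ``tol`` on ``||w||_1 - c``). ``delta = 0`` whenever the
    L2-normalised input already satisfies the L1 budget.

    Parameters
    ----------
    v : array-like, not identically zero
    c : float
        L1 budget; values below 1 are clamped to 1 (budgets < 1 are
        infeasible jointly with the unit-L2 normalisation).
    """
    v = np.asarray(v, dtype=float)
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("cannot truncate an all-zero vector")
    c = max(float(c), 1.0)
    w = v / nv
    if np.abs(w).sum() <= c + tol:
        return w
    lo, hi = 0.0, float(np.abs(v).max())
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        s = _soft(v, mid)
        ns = np.linalg.norm(s)
        if ns == 0.0:
            hi = mid
            continue
        l1 = np.abs(s).sum() / ns
        if l1 > c:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    s = _soft(v, hi)
    ns = np.linalg.norm(s)
    if ns == 0.0:
        # ties at the maximum can make ||w||_1 = c unreachable; fall back
        # to the maximally sparse feasible point (unit mass on the argmax)
        w = np.zeros_like(v)
        j = int(np.argmax(np.abs(v)))
        w[j] = np.sign(v[j]) or 1.0
        return w
    return s / ns


def canonical_correlation(X, Y, a, b) -> float:
    """Correlation of the canonical variables u = Xa and v = Yb.

    Computed as the cosine of u and v, which equals their Pearson
    correlation when the columns of X and Y are mean-centred.
    """
    u = as_matrix(X) @ np.asarray(a, dtype=float)
    v = as_matrix(Y) @ np.asarray(b, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-300 or nv < 1e-300:
        raise ValueError("degenerate coefficients: a canonical variable is zero")
    return float(u @ v / (nu * nv))


def _finalize(X, Y, a, b, method, n_iter, converged) -> CanonicalModel:
    # sign convention: canonical correlation reported non-negative
    try:
        corr = canonical_correlation(X, Y, a, b)
    except ValueError:
        return CanonicalModel(a, b, 0.0, method, n_iter, converged=False)
    if corr < 0:
        b = -b
        corr = -corr
    return CanonicalModel(a, b, corr, method, n_iter, converged)


def pmd_cca(X, Y, params: SCCAParams | None = None) -> CanonicalModel:
    """PMD-CCA: alternating exact maximisation of <Xa, Yb>.

    a <- truncate(X^T Y b, c_x), b <- truncate(Y^T X a, c_y), starting
    from the leading singular pair of X^T Y, until the largest absolute
    coefficient change drops below ``params.tol`` or ``params.max_iter``
    is reached. The reported correlation is the full cosine objective,
    for comparability with SCCA-EC.
    """
    X = as_matrix(X)
    Y = as_matrix(Y)
    if params is None:
        params = SCCAParams()
    c_x = _clamp_budget(params.c_x, X.shape[1])
    c_y = _clamp_budget(params.c_y, Y.shape[1])
    M = X.T @ Y
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        a, b = init_coefficients(X, Y)
    a = l1_l2_truncate(a, c_x)
    b = l1_l2_truncate(b, c_y)
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        Mb = M @ b
        a_new = l1_l2_truncate(Mb, c_x) if np.linalg.norm(Mb) > 0 else a
        Ma = M.T @ a_new
        b_new = l1_l2_truncate(Ma, c_y) if np.linalg.norm(Ma) > 0 else b
        delta = max(np.abs(a_new - a).max(), np.abs(b_new - b).max())
        a, b = a_new, b_new
        if delta < params.tol:
            converged = True
            break
    return _finalize(X, Y, a, b, "pmd", it, converged)


def _corr_objective(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-300 or nv < 1e-300:
        return -np.inf
    return float(u @ v / (nu * nv))


def _ec_half_step(Z, w, other_proj, c, step0=1.0, floor=1e-10):
    """One projected-gradient ascent step on corr(Zw, other_proj) in w.

    Backtracks the step size (halving, down to *floor*) until the
    projected candidate does not decrease the objective; the projection
    is harmless for the objective because corr is scale-invariant.
    """
    u = Z @ w
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(other_proj)
    f0 = _corr_objective(u, other_proj)
    grad = Z.T @ other_proj / (nu * nv) - (u @ other_proj) / (nu**3 * nv) * (Z.T @ u)
    gn = np.linalg.norm(grad)
    if gn < 1e-14:
        return w, f0
    eta = step0
    while eta >= floor:
        cand_raw = w + eta * grad
        if np.linalg.norm(cand_raw) < 1e-300:
            eta *= 0.5
            continue
        cand = l1_l2_truncate(cand_raw, c)
        f = _corr_objective(Z @ cand, other_proj)
        if f >= f0 - 1e-12:
            return cand, f
        eta *= 0.5
    return w, f0


def scca_ec(X, Y, params: SCCAParams | None = None) -> CanonicalModel:
    """SCCA-EC: alternating projected gradient ascent on corr(Xa, Yb).

    Unlike PMD-CCA the within-view covariances are not approximated as
    diagonal: the full, scale-invariant correlation objective is
    maximised. Stops when the relative objective improvement over a full
    (a, b) sweep drops below ``params.tol``.
    """
    X = as_matrix(X)
    Y = as_matrix(Y)
    if params is None:
        params = SCCAParams(method="ec")
    c_x = _clamp_budget(params.c_x, X.shape[1])
    c_y = _clamp_budget(params.c_y, Y.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        a, b = init_coefficients(X, Y)
    a = l1_l2_truncate(a, c_x)
    b = l1_l2_truncate(b, c_y)
    f_prev = _corr_objective(X @ a, Y @ b)
    if not np.isfinite(f_prev):
        warnings.warn("degenerate start; reinitialising", UserWarning, stacklevel=2)
        a, b = init_coefficients(X, Y)
        f_prev = _corr_objective(X @ a, Y @ b)
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        a, _ = _ec_half_step(X, a, Y @ b, c_x)
        b, f = _ec_half_step(Y, b, X @ a, c_y)
        if abs(f - f_prev) < params.tol * max(abs(f_prev), 1e-12):
            f_prev = f
            converged = True
            break
        f_prev = f
    return _finalize(X, Y, a, b, "ec", it, converged)


_SOLVERS = {"pmd": pmd_cca, "ec": scca_ec}


def solve(X, Y, params: SCCAParams) -> CanonicalModel:
    """Dispatch to the solver named by ``params.method``."""
    try:
        fn = _SOLVERS[params.method.lower()]
    except KeyError:
        raise ValueError(f"unknown method {params.method!r}; use 'pmd' or 'ec'") from None
    return fn(X, Y, params)


class _BaseSparseCCA(BaseEstimator):
    """Shared fit/transform machinery of the two sparse-CCA estimators."""

    _method: str = ""

    def __init__(self, c_x=None, c_y=None, *, scale=True, max_iter=200, tol=1e-6):
        self.c_x = c_x
        self.c_y = c_y
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol

    def _validate_pair(self, X, Y):
        X = check_array(as_matrix(X), dtype=float, ensure_min_samples=2)
        Y = check_array(as_matrix(Y), dtype=float, ensure_min_samples=2)
        if X.shape[0] != Y.shape[0]:
            raise ValueError(
                f"views have mismatched sample counts: {X.shape[0]} vs {Y.shape[0]}"
            )
        return X, Y

    def _prepare(self, X, which: str):
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        if self.scale:
            sd = X.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
        else:
            sd = np.ones(X.shape[1])
        setattr(self, f"_{which}_mean", mean)
        setattr(self, f"_{which}_std", sd)
        return (X - mean) / sd

    def fit(self, X, Y):
        """Fit the first sparse canonical pair on two aligned views."""
        X, Y = self._validate_pair(X, Y)
        Xs = self._prepare(X, "x")
        Ys = self._prepare(Y, "y")
        params = SCCAParams(
            c_x=self.c_x,
            c_y=self.c_y,
            max_iter=self.max_iter,
            tol=self.tol,
            method=self._method,
        )
        model = solve(Xs, Ys, params)
        self.x_weights_ = model.a
        self.y_weights_ = model.b
        self.correlation_ = model.correlation
        self.n_iter_ = model.n_iter
        self.converged_ = model.converged
        self.n_features_in_ = X.shape[1]
        self.model_ = model
        return self

    def transform(self, X, Y=None):
        """Project new data onto the fitted canonical directions."""
        check_is_fitted(self, "x_weights_")
        u = ((np.asarray(X, dtype=float) - self._x_mean) / self._x_std) @ self.x_weights_
        if Y is None:
            return u
        v = ((np.asarray(Y, dtype=float) - self._y_mean) / self._y_std) @ self.y_weights_
        return u, v

    def fit_transform(self, X, Y):
        return self.fit(X, Y).transform(X, Y)


class PMDCCA(_BaseSparseCCA):
    """Penalised-matrix-decomposition sparse CCA (diagonal-covariance).

    Parameters
    ----------
    c_x, c_y : float or None
        L1 budgets for the X and Y coefficient vectors; ``None`` imposes
        no sparsity. At ``c = 1`` a single variable is selected per view.
    scale : bool, default True
        Standardise each column before fitting (recommended; the solver
        assumes standardised input).
    max_iter, tol :
        Alternating-update iteration cap and convergence tolerance on
        the maximal absolute coefficient change.

    Attributes
    ----------
    x_weights_, y_weights_ : ndarray
        Canonical coefficient vectors a, b.
    correlation_ : float
        Canonical correlation corr(Xa, Yb) on the training data.
    """

    _method = "pmd"


class SCCAEC(_BaseSparseCCA):
    """Sparse CCA with elastic-net constraints on the full correlation.

    Same constraint set and interface as :class:`PMDCCA`, but the
    within-view covariances are not approximated: the correlation
    corr(Xa, Yb) itself is maximised by alternating projected gradient
    ascent with backtracking line search.
    """

    _method = "ec"
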