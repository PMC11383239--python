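"""Application layer for real two-view omics data.

Preprocessing (generalised log transform of abundance tables) and
post-hoc interpretation of a fitted canonical pair: the decomposition of
the canonical correlation into per-variable-pair contributions, a
per-sample disease score built from the canonical variables, and the
comparison of coefficient vectors taken from two models that share one
view (e.g. a species-metabolites and an enzymes-metabolites model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .solvers import NONZERO_TOL, CanonicalModel
from .views import as_matrix

__all__ = [
    "ContributionMatrix",
    "glog_transform",
    "pairwise_contributions",
    "canonical_disease_score",
    "cross_model_correlation",
]

GLOG_OFFSET = 1e-8


@dataclass
class ContributionMatrix:
    """Pairwise shares of the canonical correlation.

    Entry (j, k) is the fraction of the total canonical correlation due
    to the correlation between X-variable j and Y-variable k; entries
    sum to 1.
    """

    values: np.ndarray
    row_indices: np.ndarray
    col_indices: np.ndarray
    row_names: list[str] = field(default_factory=list)
    col_names: list[str] = field(default_factory=list)


def glog_transform(x) -> np.ndarray:
    """Generalised log: glog(x) = log(x + sqrt(x^2 + 1e-8)).

    A smooth, strictly increasing variance-stabilising transform for
    abundance data; behaves like log(2x) for x >> 1e-4 while remaining
    finite at zero (glog(0) = log(1e-4)). Negative inputs are allowed by
    the formula but unusual for abundances, so they trigger a warning.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("glog input must be finite")
    if (x < 0).any():
        warnings.warn(
            "glog applied to negative values; abundances are expected >= 0",
            UserWarning,
            stacklevel=2,
        )
    return np.log(x + np.sqrt(x * x + GLOG_OFFSET))


def _coef_pair(model):
    if isinstance(model, CanonicalModel):
        return model.a, model.b
    a, b = model
    return np.asarray(a, dtype=float), np.asarray(b, dtype=float)


def pairwise_contributions(X, Y, model, names_x=None, names_y=None) -> ContributionMatrix:
    """Decompose the canonical correlation into per-pair shares.

    Entry (j, k) = a_j X_j^T Y_k b_k / <Xa, Yb>. Only variables with a
    nonzero coefficient appear, which keeps the matrix small for sparse
    models; the entries always sum to 1 since summing the numerator over
    all (j, k) reconstructs <Xa, Yb>.
    """
    X = as_matrix(X)
    Y = as_matrix(Y)
    a, b = _coef_pair(model)
    total = float((X @ a) @ (Y @ b))
    if abs(total) < 1e-300:
        raise ValueError("total inner product <Xa, Yb> is zero")
    sel_x = np.flatnonzero(np.abs(a) > NONZERO_TOL)
    sel_y = np.flatnonzero(np.abs(b) > NONZERO_TOL)
    cross = X[:, sel_x].T @ Y[:, sel_y]
    vals = (a[sel_x][:, None] * cross * b[sel_y][None, :]) / total
    return ContributionMatrix(
        vals,
        sel_x,
        sel_y,
        [names_x[j] for j in sel_x] if names_x is not None else [f"x{j+1}" for j in sel_x],
        [names_y[k] for k in sel_y] if names_y is not None else [f"y{k+1}" for k in sel_y],
    )


def canonical_disease_score(X, Y, model) -> np.ndarray:
    """Per-sample score: the sum of the canonical variables, Xa + Yb.

    Paired with a binary status label this score feeds a ROC analysis
    (e.g. via :func:`stabcca.evaluation.recovery_auc`). The sign of a
    canonical pair is arbitrary, so callers should flip the score when
    the resulting AUC falls below 0.5.
    """
    a, b = _coef_pair(model)
    return as_matrix(X) @ a + as_matrix(Y) @ b


def cross_model_correlation(view1, coeff1, view2, coeff2, names1=None, names2=None):
    """Correlate canonical variables taken from two different models.

    Both coefficient vectors are typically fitted against a common third
    view (e.g. species and enzymes each against metabolites); the
    returned correlation is the cosine of view1 @ coeff1 and
    view2 @ coeff2, plus the pairwise contribution decomposition of that
    correlation over the two coefficient supports.
    """
    V1 = as_matrix(view1)
    V2 = as_matrix(view2)
    c1 = np.asarray(coeff1, dtype=float)
    c2 = np.asarray(coeff2, dtype=float)
    u = V1 @ c1
    v = V2 @ c2
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-300 or nv < 1e-300:
        raise ValueError("degenerate projection in cross-model comparison")
    corr = float(u @ v / (nu * nv))
    if abs(u @ v) < 1e-300:
        # zero total correlation: the share decomposition is undefined
        return corr, None
    contrib = pairwise_contributions(V1, V2, (c1, c2), names1, names2)
    return corr, contrib
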