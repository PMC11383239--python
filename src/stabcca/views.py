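"""Two-view data containers and standardisation.

A *view* is one omics block — e.g. metagenomic species abundances or
metabolite intensities — stored as a samples x variables matrix. The two
views of a study share their sample rows but have disjoint variable sets.
All solvers in :mod:`stabcca.solvers` expect column-standardised input
(mean zero, unit variance where the variance is nonzero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ViewMatrix", "standardize", "standardize_matrix", "as_matrix"]


@dataclass
class ViewMatrix:
    """A samples x variables real matrix with row/column labels.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_variables)
        Dense numeric data; no missing values allowed.
    variable_names : list of str
        Column labels, one per variable.
    sample_ids : list of str
        Row labels, one per sample.
    """

    values: np.ndarray
    variable_names: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 2 or p < 1:
            raise ValueError(f"need at least 2 samples and 1 variable, got {n} x {p}")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain NaN or infinite entries")
        if not self.variable_names:
            self.variable_names = [f"v{j + 1}" for j in range(p)]
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1}" for i in range(n)]
        if len(self.variable_names) != p:
            raise ValueError("variable_names length does not match number of columns")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]


def as_matrix(view) -> np.ndarray:
    """Return the underlying ndarray of a ViewMatrix or array-like."""
    if isinstance(view, ViewMatrix):
        return view.values
    return np.asarray(view, dtype=float)


def standardize_matrix(X, ddof: int = 0) -> np.ndarray:
    """Column-standardise an array, keeping all columns.

    Zero-variance columns are centred but not rescaled (their scale is
    taken as 1), so they become identically zero and can never be
    selected by a sparse solver. This is the behaviour required inside
    the stability loop, where a subsample may render a column constant
    while the variable must remain countable.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd


def standardize(view: ViewMatrix) -> ViewMatrix:
    """Standardise a view: centre, scale to unit variance, drop constants.

    Columns with zero variance carry no information and are removed
    (their names are reported via a warning). Raises if *every* column
    is constant, since the view is then degenerate.

    Returns a new :class:`ViewMatrix`; the input is left untouched.
    """
    X = view.values
    if X.shape[0] < 2:
        raise ValueError("standardize requires at least 2 samples")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns have zero variance; degenerate view")
    dropped = [n for n, k in zip(view.variable_names, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} zero-variance column(s): {dropped}",
            UserWarning,
            stacklevel=2,
        )
    Xk = X[:, keep]
    Z = (Xk - Xk.mean(axis=0)) / Xk.std(axis=0)
    return ViewMatrix(
        Z,
        [n for n, k in zip(view.variable_names, keep) if k],
        list(view.sample_ids),
    )
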