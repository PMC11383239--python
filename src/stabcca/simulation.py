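"""Synthetic two-view benchmark data with known cross-view structure.

Two generative models produce sample-aligned views X (n x p_x) and
Y (n x p_y) whose dependence is carried by sparse ground-truth
coefficient vectors a_true, b_true with supports of size p_x_true and
p_y_true (nonzero entries drawn from U[0, 1]):

* **single latent** — one standard-normal factor Z per sample drives
  both views: X_ij ~ N(Z_i * a_j_true, noise_var), and likewise for Y.
* **multivariate** — samples are joint draws from N(0, Sigma) where the
  within-view blocks have unit diagonal with 0.5 correlation among true
  variables, and the cross-view block is the rank-one outer product
  a_true b_true^T. Because that outer product is not constrained by the
  diagonal blocks, Sigma can be indefinite for some ground-truth draws;
  it is then repaired by clipping eigenvalues from below at 1e-8.

Scenario difficulty is controlled by the true sparsity s_x of the X
view (fraction of variables carrying signal), with s_y = s_x / 2 and
p = p_true / s per view. The study scenarios use p_x_true = 10,
p_y_true = 15, s_x in {1/2, 1/4, 1/10} and n = 50 training samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .views import ViewMatrix

__all__ = [
    "GroundTruth",
    "ScenarioConfig",
    "scenario_dimensions",
    "make_ground_truth",
    "simulate_single_latent",
    "build_covariance",
    "simulate_multivariate",
    "simulate",
]

DEFAULT_P_X_TRUE = 10
DEFAULT_P_Y_TRUE = 15


@dataclass
class GroundTruth:
    """True coefficient vectors and their supports."""

    a_true: np.ndarray
    b_true: np.ndarray
    support_x: np.ndarray
    support_y: np.ndarray
    seed: int

    @property
    def p_x(self) -> int:
        return len(self.a_true)

    @property
    def p_y(self) -> int:
        return len(self.b_true)

    def truth_mask(self) -> np.ndarray:
        """Concatenated X|Y binary indicator of the true variables."""
        mask = np.zeros(self.p_x + self.p_y, dtype=int)
        mask[self.support_x] = 1
        mask[self.p_x + self.support_y] = 1
        return mask


@dataclass
class ScenarioConfig:
    """One benchmark scenario.

    s_x is the true sparsity of the X view (p_x_true / p_x); the Y view
    is twice as sparse (s_y = s_x / 2). noise_var is the variance of the
    additive Gaussian noise in the single-latent model.
    """

    s_x: float = 0.5
    model: str = "single_latent"
    n_train: int = 50
    n_test: int = 100
    noise_var: float = 0.5
    p_x_true: int = DEFAULT_P_X_TRUE
    p_y_true: int = DEFAULT_P_Y_TRUE

    @property
    def s_y(self) -> float:
        return self.s_x / 2.0

    def dimensions(self) -> tuple[int, int]:
        return scenario_dimensions(self.s_x, self.p_x_true, self.p_y_true)


def scenario_dimensions(
    s_x: float,
    p_x_true: int = DEFAULT_P_X_TRUE,
    p_y_true: int = DEFAULT_P_Y_TRUE,
) -> tuple[int, int]:
    """View dimensions (p_x, p_y) implied by the true sparsity s_x."""
    if not 0 < s_x <= 1:
        raise ValueError("s_x must lie in (0, 1]")
    s_y = s_x / 2.0
    raw_x = p_x_true / s_x
    raw_y = p_y_true / s_y
    p_x = round(raw_x)
    p_y = round(raw_y)
    if abs(raw_x - p_x) > 1e-9 or abs(raw_y - p_y) > 1e-9:
        warnings.warn(
            f"s_x={s_x} gives non-integer dimensions ({raw_x}, {raw_y}); rounding",
            UserWarning,
            stacklevel=2,
        )
    return p_x, p_y


def make_ground_truth(
    p_x: int,
    p_y: int,
    p_x_true: int = DEFAULT_P_X_TRUE,
    p_y_true: int = DEFAULT_P_Y_TRUE,
    seed: int = 0,
) -> GroundTruth:
    """Draw random supports and U[0, 1] coefficients on them."""
    if p_x_true > p_x or p_y_true > p_y:
        raise ValueError("true support cannot exceed the view dimension")
    rng = np.random.default_rng(seed)
    support_x = np.sort(rng.choice(p_x, size=p_x_true, replace=False))
    support_y = np.sort(rng.choice(p_y, size=p_y_true, replace=False))
    a = np.zeros(p_x)
    b = np.zeros(p_y)
    a[support_x] = rng.uniform(0.0, 1.0, size=p_x_true)
    b[support_y] = rng.uniform(0.0, 1.0, size=p_y_true)
    return GroundTruth(a, b, support_x, support_y, seed)


def _label_views(X, Y, prefix_x="x", prefix_y="y") -> tuple[ViewMatrix, ViewMatrix]:
    n = X.shape[0]
    ids = [f"s{i + 1}" for i in range(n)]
    vx = ViewMatrix(X, [f"{prefix_x}{j + 1}" for j in range(X.shape[1])], ids)
    vy = ViewMatrix(Y, [f"{prefix_y}{j + 1}" for j in range(Y.shape[1])], ids)
    return vx, vy


def simulate_single_latent(
    gt: GroundTruth,
    n: int = 50,
    noise_var: float = 0.5,
    seed: int = 0,
) -> tuple[ViewMatrix, ViewMatrix]:
    """Single-latent-factor model: one factor Z drives both views.

    X_ij ~ N(Z_i a_j_true, noise_var) with Z_i ~ N(0, 1); the same Z_i
    enters the Y view. Null variables are pure N(0, noise_var) noise.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    sd = np.sqrt(noise_var)
    X = np.outer(z, gt.a_true) + sd * rng.standard_normal((n, gt.p_x))
    Y = np.outer(z, gt.b_true) + sd * rng.standard_normal((n, gt.p_y))
    return _label_views(X, Y)


def build_covariance(gt: GroundTruth, return_repair: bool = False):
    """Joint (p_x + p_y)-dimensional covariance of the multivariate model.

    Within-view blocks: unit diagonal, 0.5 between pairs of true
    variables, 0 elsewhere. Cross block: a_true b_true^T. If the
    assembled matrix is not positive semi-definite it is repaired by
    clipping eigenvalues from below at 1e-8 and re-symmetrising; with
    ``return_repair=True`` the Frobenius distance of the repair is also
    returned.
    """
    p_x, p_y = gt.p_x, gt.p_y

    def within(p, support):
        S = np.eye(p)
        if len(support) > 1:
            S[np.ix_(support, support)] = 0.5
            S[support, support] = 1.0
        return S

    sigma = np.zeros((p_x + p_y, p_x + p_y))
    sigma[:p_x, :p_x] = within(p_x, gt.support_x)
    sigma[p_x:, p_x:] = within(p_y, gt.support_y)
    cross = np.outer(gt.a_true, gt.b_true)
    sigma[:p_x, p_x:] = cross
    sigma[p_x:, :p_x] = cross.T

    vals, vecs = np.linalg.eigh(sigma)
    if vals.min() < 0:
        clipped = np.maximum(vals, 1e-8)
        repaired = (vecs * clipped) @ vecs.T
        repaired = 0.5 * (repaired + repaired.T)
        dist = float(np.linalg.norm(repaired - sigma))
    else:
        repaired = sigma
        dist = 0.0
    if return_repair:
        return repaired, dist
    return repaired


def simulate_multivariate(
    gt: GroundTruth,
    n: int = 50,
    seed: int = 0,
) -> tuple[ViewMatrix, ViewMatrix]:
    """Joint Gaussian model: n draws from N(0, Sigma), split into views."""
    sigma = build_covariance(gt)
    # Cholesky of the (repaired, hence PSD) covariance; tiny jitter for
    # numerically semi-definite cases
    jitter = 0.0
    for _ in range(6):
        try:
            L = np.linalg.cholesky(sigma + jitter * np.eye(sigma.shape[0]))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10)
    else:  # pragma: no cover - clipping guarantees PSD well before this
        raise np.linalg.LinAlgError("covariance could not be factorised")
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, sigma.shape[0]))
    D = Z @ L.T
    return _label_views(D[:, : gt.p_x], D[:, gt.p_x :])


def simulate(
    gt: GroundTruth,
    cfg: ScenarioConfig,
    n: int | None = None,
    seed: int = 0,
) -> tuple[ViewMatrix, ViewMatrix]:
    """Dispatch on ``cfg.model`` ('single_latent' or 'multivariate')."""
    n = cfg.n_train if n is None else n
    if cfg.model == "single_latent":
        return simulate_single_latent(gt, n=n, noise_var=cfg.noise_var, seed=seed)
    if cfg.model == "multivariate":
        return simulate_multivariate(gt, n=n, seed=seed)
    raise ValueError(f"unknown model {cfg.model!r}")
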