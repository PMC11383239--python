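"""Evaluation metrics and hyperparameter-tuning protocols.

Metrics for the two-view benchmark: ranking-based recovery AUC of a
variable-importance score against the known support, balanced accuracy
of a hard selection, the Nogueira et al. stability estimator over
repeated selections, and out-of-sample canonical correlation. Tuning
follows repeated k-fold cross-validation with held-out canonical
correlation as the objective: a 15 x 15 budget grid for the base
solvers, a 100-point threshold sweep for threshold selection, and a
shrinking-interval (ternary) search over k for top-k selection.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score, roc_auc_score
from sklearn.model_selection import KFold

from .simulation import ScenarioConfig, make_ground_truth, simulate
from .solvers import NONZERO_TOL, CanonicalModel, SCCAParams, solve
from .stability import (
    refit,
    select_threshold,
    select_top_k,
    stability_cca,
    stability_scores,
)
from .views import as_matrix, standardize_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "recovery_auc",
    "balanced_accuracy",
    "nogueira_stability",
    "test_correlation",
    "cv_correlation",
    "tune_base",
    "tune_threshold",
    "tune_k",
    "run_simulation_study",
]


def recovery_auc(scores, truth_mask) -> float:
    """Rank-based AUC of an importance score against the true support.

    Equals the probability that a uniformly chosen true variable scores
    above a uniformly chosen null variable (ties counted half).
    """
    truth = np.asarray(truth_mask).astype(int)
    if truth.min() == truth.max():
        raise ValueError("truth mask must contain both classes")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


def balanced_accuracy(selected_mask, truth_mask) -> float:
    """(sensitivity + specificity) / 2 of a hard selection."""
    truth = np.asarray(truth_mask).astype(int)
    if truth.min() == truth.max():
        raise ValueError("truth mask must contain both classes")
    return float(balanced_accuracy_score(truth, np.asarray(selected_mask).astype(int)))


def nogueira_stability(masks) -> float:
    """Stability of M selected variable sets over d variables.

    Phi = 1 - mean_f(s_f^2) / ((kbar/d) (1 - kbar/d)) where s_f^2 is the
    unbiased (M/(M-1)) sample variance of variable f's selection
    indicator and kbar the mean selected-set size. Ranges from
    -1/(M-1) (disjoint same-size sets covering the variable space) to 1
    (identical sets); its expectation under uniformly random selection
    is 0. Undefined (raises) when the average set is empty or full.
    """
    Z = np.asarray(masks, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise ValueError("need at least M=2 masks of equal length")
    M, d = Z.shape
    phat = Z.mean(axis=0)
    s2 = M / (M - 1) * phat * (1 - phat)
    kbar = Z.sum(axis=1).mean()
    denom = (kbar / d) * (1 - kbar / d)
    if denom == 0:
        raise ValueError(
            "stability undefined: selections are on average empty or full"
        )
    return float(1 - s2.mean() / denom)


def _coef_pair(model) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(model, CanonicalModel):
        return model.a, model.b
    a, b = model
    return np.asarray(a, dtype=float), np.asarray(b, dtype=float)


def test_correlation(model, X_test, Y_test, scale: bool = True) -> float:
    """Out-of-sample canonical correlation of frozen coefficients.

    The test views are standardised with their own statistics (constant
    columns are left on scale 1), then corr(X a, Y b) is evaluated.
    """
    a, b = _coef_pair(model)
    X = as_matrix(X_test)
    Y = as_matrix(Y_test)
    if scale:
        X = standardize_matrix(X)
        Y = standardize_matrix(Y)
    u = X @ a
    v = Y @ b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-300 or nv < 1e-300:
        raise ValueError("degenerate projection on the test set")
    return float(u @ v / (nu * nv))


def cv_correlation(X, Y, fit_procedure, rounds: int = 10, folds: int = 3,
                   seed: int = 0) -> float:
    """Mean held-out canonical correlation over repeated k-fold CV.

    ``fit_procedure(X_train, Y_train)`` must return a coefficient pair
    (a, b); it receives raw (unstandardised) rows and is responsible for
    its own preprocessing. A failed fold fit scores 0 and is logged.
    """
    X = as_matrix(X)
    Y = as_matrix(Y)
    if X.shape[0] < 2 * folds:
        raise ValueError("too few samples for the requested fold count")
    values = []
    for r in range(rounds):
        kf = KFold(n_splits=folds, shuffle=True,
                   random_state=(seed * 1009 + r) % (2**31))
        for tr, te in kf.split(X):
            try:
                ab = fit_procedure(X[tr], Y[tr])
                values.append(test_correlation(ab, X[te], Y[te]))
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("fold fit failed (%s); scoring 0", exc)
                values.append(0.0)
    return float(np.mean(values))


def _solver_fit(method, c_x, c_y, max_iter, tol):
    params = SCCAParams(c_x=c_x, c_y=c_y, max_iter=max_iter, tol=tol, method=method)

    def fit(Xtr, Ytr):
        m = solve(standardize_matrix(Xtr), standardize_matrix(Ytr), params)
        return m.a, m.b

    return fit


def _refit_fit(selection, method, max_iter, tol):
    def fit(Xtr, Ytr):
        m = refit(
            standardize_matrix(Xtr),
            standardize_matrix(Ytr),
            selection,
            method=method,
            max_iter=max_iter,
            tol=tol,
        )
        return m.a, m.b

    return fit


def tune_base(
    X,
    Y,
    method: str = "pmd",
    grid_size: int = 15,
    cv_rounds: int = 10,
    cv_folds: int = 3,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> SCCAParams:
    """Grid-search the (c_x, c_y) budgets of a base solver by CV.

    Evenly spaced values in [1, p_x] x [1, p_y]; ties in the CV
    objective go to the sparsest pair (smallest c_x + c_y, then c_x).
    """
    X = as_matrix(X)
    Y = as_matrix(Y)
    cx_grid = np.linspace(1.0, X.shape[1], grid_size)
    cy_grid = np.linspace(1.0, Y.shape[1], grid_size)
    pairs = sorted(itertools.product(cx_grid, cy_grid), key=lambda p: (p[0] + p[1], p[0]))
    best, best_val = None, -np.inf
    for cx, cy in pairs:
        val = cv_correlation(
            X, Y, _solver_fit(method, cx, cy, max_iter, tol),
            rounds=cv_rounds, folds=cv_folds, seed=seed,
        )
        if val > best_val + 1e-12:
            best, best_val = (cx, cy), val
    return SCCAParams(c_x=best[0], c_y=best[1], max_iter=max_iter, tol=tol,
                      method=method)


def tune_threshold(
    scores_x,
    scores_y,
    X,
    Y,
    method: str = "pmd",
    n_candidates: int = 100,
    cv_rounds: int = 10,
    cv_folds: int = 3,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> float:
    """CV-tune the stability-score threshold tau.

    Candidates span [min score, max score] inclusive; each feasible
    candidate's selection is refitted per CV fold. Ties go to the larger
    (sparser) tau; candidates emptying a view are skipped.
    """
    all_scores = np.concatenate([np.asarray(scores_x), np.asarray(scores_y)])
    lo, hi = float(all_scores.min()), float(all_scores.max())
    if hi - lo < 1e-15:
        raise ValueError("stability scores are constant; no threshold to tune")
    candidates = np.linspace(lo, hi, n_candidates)
    best_tau, best_val = None, -np.inf
    for tau in candidates:
        try:
            sel = select_threshold(scores_x, scores_y, float(tau))
        except ValueError:
            continue
        val = cv_correlation(
            X, Y, _refit_fit(sel, method, max_iter, tol),
            rounds=cv_rounds, folds=cv_folds, seed=seed,
        )
        if val >= best_val - 1e-12:
            # ascending sweep: >= keeps the larger (sparser) tau on ties
            if val > best_val + 1e-12 or best_tau is None or tau > best_tau:
                best_tau, best_val = float(tau), max(val, best_val)
    if best_tau is None:
        raise ValueError("every candidate threshold left a view empty")
    return best_tau


def tune_k(
    scores_x,
    scores_y,
    X,
    Y,
    method: str = "pmd",
    cv_rounds: int = 10,
    cv_folds: int = 3,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> int:
    """Search the top-k size by interval-thirds probing of the CV curve.

    Probes two interior points of [2, p_x + p_y], discards the third of
    the interval behind the worse probe, and stops when the interval
    shrinks to length 3, exhaustively evaluating the remainder. Assumes
    (heuristically) a unimodal CV curve in k; all evaluated k are
    remembered and the best one returned (ties to smaller k).
    """
    p_total = len(scores_x) + len(scores_y)
    lo, hi = 2, p_total
    cache: dict[int, float] = {}

    def value(k: int) -> float:
        if k not in cache:
            sel = select_top_k(scores_x, scores_y, k)
            cache[k] = cv_correlation(
                X, Y, _refit_fit(sel, method, max_iter, tol),
                rounds=cv_rounds, folds=cv_folds, seed=seed,
            )
        return cache[k]

    while hi - lo > 3:
        m1 = lo + (hi - lo) // 3
        m2 = hi - (hi - lo) // 3
        if m2 == m1:
            m2 += 1
        if value(m1) < value(m2):
            lo = m1 + 1
        else:
            hi = m2 - 1
    for k in range(lo, hi + 1):
        value(k)
    return min(cache, key=lambda k: (-cache[k], k))


def _sub_seed(*parts) -> int:
    """Deterministic 31-bit seed derived from integer tags."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


@dataclass
class _CellAccumulator:
    values: dict
    masks_by_truth: dict
    n_runs: int = 0
    n_failures: int = 0

    def add(self, metric, value):
        self.values.setdefault(metric, []).append(value)


def run_simulation_study(
    scenarios=None,
    methods=("pmd", "ec"),
    strategies=("base", "top_k", "threshold"),
    n_truths: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    n_splits: int = 50,
    grid_size: int = 100,
    cv_rounds: int = 10,
    cv_folds: int = 3,
    tune_grid_size: int = 15,
    n_thresholds: int = 100,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Full factorial benchmark of base solvers vs stability selection.

    For each scenario, ``n_truths`` random ground truths are drawn with
    ``n_repeats`` independent train/test pairs each. Recovery AUC,
    balanced accuracy and test correlation are averaged over all
    truth x repeat runs; the Nogueira stability is computed within each
    ground truth's ``n_repeats`` selections (concatenated X|Y masks)
    and averaged over truths. Individual run failures are logged,
    excluded from the averages and counted in the output.

    Returns a tidy frame with columns
    ``scenario (s_x), model, method, strategy, metric, value``.
    """
    if scenarios is None:
        scenarios = [ScenarioConfig(s_x=s) for s in (1 / 2, 1 / 4, 1 / 10)]
    rows = []
    for sc_i, cfg in enumerate(scenarios):
        p_x, p_y = cfg.dimensions()
        cells = {
            (method, strategy): _CellAccumulator({}, {})
            for method in methods
            for strategy in strategies
        }
        for t in range(n_truths):
            gt = make_ground_truth(
                p_x, p_y, cfg.p_x_true, cfg.p_y_true,
                seed=_sub_seed(seed, sc_i, t, 0),
            )
            truth = gt.truth_mask()
            for r in range(n_repeats):
                Xtr, Ytr = simulate(gt, cfg, n=cfg.n_train,
                                    seed=_sub_seed(seed, sc_i, t, r, 1))
                Xte, Yte = simulate(gt, cfg, n=cfg.n_test,
                                    seed=_sub_seed(seed, sc_i, t, r, 2))
                Xs = standardize_matrix(Xtr.values)
                Ys = standardize_matrix(Ytr.values)
                run_seed = _sub_seed(seed, sc_i, t, r, 3)
                for method in methods:
                    path_scores = None
                    for strategy in strategies:
                        cell = cells[(method, strategy)]
                        cell.n_runs += 1
                        try:
                            if strategy == "base":
                                params = tune_base(
                                    Xtr.values, Ytr.values, method,
                                    grid_size=tune_grid_size,
                                    cv_rounds=cv_rounds, cv_folds=cv_folds,
                                    seed=run_seed, max_iter=max_iter, tol=tol,
                                )
                                model = solve(Xs, Ys, params)
                                score = np.concatenate(
                                    [np.abs(model.a), np.abs(model.b)]
                                )
                                mask = (score > NONZERO_TOL).astype(int)
                                corr = test_correlation(model, Xte, Yte)
                            else:
                                if path_scores is None:
                                    path = stability_cca(
                                        Xs, Ys, method=method,
                                        n_splits=n_splits, grid_size=grid_size,
                                        seed=run_seed, max_iter=max_iter, tol=tol,
                                    )
                                    path_scores = stability_scores(path)
                                sx, sy = path_scores
                                if strategy == "top_k":
                                    k = tune_k(
                                        sx, sy, Xtr.values, Ytr.values, method,
                                        cv_rounds=cv_rounds, cv_folds=cv_folds,
                                        seed=run_seed, max_iter=max_iter, tol=tol,
                                    )
                                    sel = select_top_k(sx, sy, k)
                                elif strategy == "threshold":
                                    tau = tune_threshold(
                                        sx, sy, Xtr.values, Ytr.values, method,
                                        n_candidates=n_thresholds,
                                        cv_rounds=cv_rounds, cv_folds=cv_folds,
                                        seed=run_seed, max_iter=max_iter, tol=tol,
                                    )
                                    sel = select_threshold(sx, sy, tau)
                                else:
                                    raise ValueError(
                                        f"unknown strategy {strategy!r}"
                                    )
                                model = refit(Xs, Ys, sel, method=method,
                                              max_iter=max_iter, tol=tol)
                                score = np.concatenate([sx, sy])
                                mask = np.zeros(p_x + p_y, dtype=int)
                                mask[sel[0]] = 1
                                mask[p_x + np.asarray(sel[1])] = 1
                                corr = test_correlation(model, Xte, Yte)
                            cell.add("auc", recovery_auc(score, truth))
                            cell.add("ba", balanced_accuracy(mask, truth))
                            cell.add("test_correlation", corr)
                            cell.masks_by_truth.setdefault(t, []).append(mask)
                        except (ValueError, np.linalg.LinAlgError) as exc:
                            cell.n_failures += 1
                            logger.warning(
                                "run failed (scenario=%s method=%s strategy=%s "
                                "truth=%d repeat=%d): %s",
                                cfg.s_x, method, strategy, t, r, exc,
                            )
        for (method, strategy), cell in cells.items():
            stab_vals = []
            for t, masks in cell.masks_by_truth.items():
                if len(masks) >= 2:
                    try:
                        stab_vals.append(nogueira_stability(np.array(masks)))
                    except ValueError as exc:
                        logger.warning("stability undefined for truth %d: %s", t, exc)
            record = dict(cell.values)
            if stab_vals:
                record["stability"] = stab_vals
            for metric, vals in record.items():
                rows.append(
                    {
                        "scenario": cfg.s_x,
                        "model": cfg.model,
                        "method": method,
                        "strategy": strategy,
                        "metric": metric,
                        "value": float(np.mean(vals)),
                    }
                )
            for metric, val in (("n_runs", cell.n_runs),
                                ("n_failures", cell.n_failures)):
                rows.append(
                    {
                        "scenario": cfg.s_x,
                        "model": cfg.model,
                        "method": method,
                        "strategy": strategy,
                        "metric": metric,
                        "value": float(val),
                    }
                )
    return pd.DataFrame(rows)
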