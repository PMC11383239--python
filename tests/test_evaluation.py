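"""Tests for evaluation metrics and hyperparameter-tuning protocols."""

import numpy as np
import pytest

import stabcca.evaluation as ev
from stabcca import test_correlation as held_out_correlation
from stabcca import (
    ScenarioConfig,
    balanced_accuracy,
    cv_correlation,
    nogueira_stability,
    pmd_cca,
    recovery_auc,
    run_simulation_study,
    standardize_matrix,
    tune_base,
    tune_k,
    tune_threshold,
)


def auc_pair_counting(scores, truth):
    """Brute-force AUC over all (true, null) pairs, ties counted half."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRecoveryAUC:
    def test_perfect_ranking(self):
        assert recovery_auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_chance_level_for_independent_scores(self, rng):
        scores = rng.standard_normal(4000)
        truth = rng.integers(0, 2, 4000)
        assert recovery_auc(scores, truth) == pytest.approx(0.5, abs=0.03)

    def test_matches_pair_counting_oracle(self, rng):
        scores = rng.integers(0, 5, 20).astype(float)  # force ties
        truth = rng.integers(0, 2, 20)
        truth[0], truth[1] = 0, 1
        assert recovery_auc(scores, truth) == pytest.approx(
            auc_pair_counting(scores, truth), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.uniform(0.1, 2, 30)
        truth = (rng.uniform(size=30) < 0.4).astype(int)
        truth[:2] = [0, 1]
        assert recovery_auc(scores, truth) == pytest.approx(
            recovery_auc(np.log(scores) * 3 + 1, truth), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            recovery_auc([1, 2, 3], [1, 1, 1])


class TestBalancedAccuracy:
    def test_exact_selection(self):
        assert balanced_accuracy([1, 0, 1], [1, 0, 1]) == 1.0

    def test_complement_selection(self):
        assert balanced_accuracy([0, 1, 0], [1, 0, 1]) == 0.0

    def test_confusion_arithmetic(self):
        truth = [1, 1, 1, 0, 0, 0, 0, 0]
        selected = [1, 1, 0, 1, 0, 0, 0, 0]
        assert balanced_accuracy(selected, truth) == pytest.approx(
            (2 / 3 + 4 / 5) / 2, abs=1e-12
        )


class TestNogueiraStability:
    def test_identical_nontrivial_masks_give_one(self):
        masks = np.tile([1, 0, 1, 0, 0], (10, 1))
        assert nogueira_stability(masks) == 1.0

    def test_random_selection_has_mean_near_zero(self):
        rng = np.random.default_rng(42)
        vals = [
            nogueira_stability(rng.integers(0, 2, size=(10, 20)))
            for _ in range(1000)
        ]
        assert abs(np.mean(vals)) <= 0.05

    def test_two_disjoint_half_masks_reach_lower_bound(self):
        masks = np.array([[1, 1, 0, 0], [0, 0, 1, 1]])
        assert nogueira_stability(masks) == pytest.approx(-1.0, abs=1e-12)

    def test_permutation_invariance(self, rng):
        masks = rng.integers(0, 2, size=(6, 12))
        masks[0, 0] = 1
        masks[1, 0] = 0
        base = nogueira_stability(masks)
        assert nogueira_stability(masks[rng.permutation(6)]) == pytest.approx(base)
        assert nogueira_stability(masks[:, rng.permutation(12)]) == pytest.approx(base)

    def test_degenerate_masks_rejected(self):
        with pytest.raises(ValueError, match="empty or full"):
            nogueira_stability(np.zeros((3, 5)))
        with pytest.raises(ValueError):
            nogueira_stability(np.ones((2, 4)))


class TestTestCorrelation:
    def test_training_set_reproduces_training_correlation(self, std_views):
        X, Y = std_views
        m = pmd_cca(X, Y)
        assert held_out_correlation(m, X, Y) == pytest.approx(m.correlation, abs=1e-10)

    def test_single_variable_pair_is_pearson(self, rng):
        Xte = rng.standard_normal((40, 1))
        Yte = 0.3 * Xte + rng.standard_normal((40, 1))
        r = np.corrcoef(Xte[:, 0], Yte[:, 0])[0, 1]
        assert held_out_correlation(([1.0], [1.0]), Xte, Yte) == pytest.approx(r, abs=1e-10)

    def test_pure_noise_correlations_stay_small(self):
        # permutation-null: frozen random coefficients on independent data
        vals = []
        for s in range(100):
            rng = np.random.default_rng(s)
            a = rng.standard_normal(5)
            b = rng.standard_normal(7)
            vals.append(
                abs(
                    held_out_correlation(
                        (a, b), rng.standard_normal((100, 5)), rng.standard_normal((100, 7))
                    )
                )
            )
        assert np.quantile(vals, 0.99) < 0.35


class TestCVCorrelation:
    def test_deterministic_fit_equals_mean_of_direct_evaluations(self, rng):
        X = rng.standard_normal((30, 3))
        Y = rng.standard_normal((30, 4))
        a = rng.standard_normal(3)
        b = rng.standard_normal(4)
        calls = []

        def fixed_fit(Xtr, Ytr):
            calls.append(len(Xtr))
            return a, b

        got = cv_correlation(X, Y, fixed_fit, rounds=2, folds=3, seed=1)
        assert len(calls) == 6
        # recompute directly with the same fold structure
        from sklearn.model_selection import KFold

        expected = []
        for r in range(2):
            kf = KFold(3, shuffle=True, random_state=(1 * 1009 + r) % (2**31))
            for _, te in kf.split(X):
                expected.append(held_out_correlation((a, b), X[te], Y[te]))
        assert got == pytest.approx(np.mean(expected), abs=1e-12)

    def test_same_seed_reproducible(self, rng):
        X = rng.standard_normal((24, 3))
        Y = rng.standard_normal((24, 3))

        def fit(Xtr, Ytr):
            m = pmd_cca(standardize_matrix(Xtr), standardize_matrix(Ytr))
            return m.a, m.b

        assert cv_correlation(X, Y, fit, 2, 3, seed=5) == cv_correlation(
            X, Y, fit, 2, 3, seed=5
        )

    def test_failing_fold_scores_zero(self, rng):
        X = rng.standard_normal((12, 2))
        Y = rng.standard_normal((12, 2))

        def broken(Xtr, Ytr):
            raise ValueError("no fit")

        assert cv_correlation(X, Y, broken, rounds=1, folds=3, seed=0) == 0.0


class TestTuneBase:
    def test_flat_cv_surface_returns_sparsest_pair(self, rng, monkeypatch):
        monkeypatch.setattr(ev, "cv_correlation", lambda *a, **k: 0.7)
        X = rng.standard_normal((20, 15))
        Y = rng.standard_normal((20, 6))
        params = tune_base(X, Y, "pmd", grid_size=15, cv_rounds=1, cv_folds=2)
        assert params.c_x == pytest.approx(1.0)
        assert params.c_y == pytest.approx(1.0)

    def test_grid_is_even_with_exact_endpoints(self, rng, monkeypatch):
        seen = []

        def spy(X, Y, fit, **kw):
            return 0.0

        monkeypatch.setattr(ev, "cv_correlation", spy)
        real_solver_fit = ev._solver_fit

        def record(method, cx, cy, mi, tl):
            seen.append((cx, cy))
            return real_solver_fit(method, cx, cy, mi, tl)

        monkeypatch.setattr(ev, "_solver_fit", record)
        X = rng.standard_normal((10, 15))
        Y = rng.standard_normal((10, 8))
        tune_base(X, Y, "pmd", grid_size=15, cv_rounds=1, cv_folds=2)
        cxs = sorted({c for c, _ in seen})
        np.testing.assert_allclose(cxs, np.arange(1, 16), atol=1e-12)
        cys = sorted({c for _, c in seen})
        assert cys[0] == 1.0 and cys[-1] == 8.0


class TestTuneThreshold:
    def test_candidates_span_score_range_inclusive(self, rng, monkeypatch):
        taus = []

        def spy_select(sx, sy, tau):
            taus.append(tau)
            raise ValueError("skip")

        monkeypatch.setattr(ev, "select_threshold", spy_select)
        sx = np.array([0.2, 0.8])
        sy = np.array([0.4, 0.6])
        with pytest.raises(ValueError, match="every candidate"):
            tune_threshold(sx, sy, rng.standard_normal((12, 2)),
                           rng.standard_normal((12, 2)), "pmd")
        assert len(taus) == 100
        assert taus[0] == pytest.approx(0.2)
        assert taus[-1] == pytest.approx(0.8)

    def test_forced_choice_returns_only_feasible_tau(self, rng):
        X = rng.standard_normal((18, 2))
        Y = rng.standard_normal((18, 2))
        # only tau below 0.5 keeps both views non-empty
        tau = tune_threshold([0.9, 0.1], [0.5, 0.2], X, Y, "pmd",
                             n_candidates=5, cv_rounds=1, cv_folds=3, seed=0)
        assert tau < 0.5

    def test_constant_scores_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            tune_threshold([0.5, 0.5], [0.5, 0.5], rng.standard_normal((12, 2)),
                           rng.standard_normal((12, 2)), "pmd")


class TestTuneK:
    def _patch_cv(self, monkeypatch, value_of_k, probed):
        def fake_cv(X, Y, fit, **kw):
            a, b = fit(X, Y)
            k = int((np.abs(a) > 0).sum() + (np.abs(b) > 0).sum())
            probed.append(k)
            return value_of_k(k)

        monkeypatch.setattr(ev, "cv_correlation", fake_cv)

        def fake_refit_fit(selection, method, mi, tl):
            def fit(X, Y):
                a = np.zeros(X.shape[1])
                b = np.zeros(Y.shape[1])
                a[np.asarray(selection[0], dtype=int)] = 1
                b[np.asarray(selection[1], dtype=int)] = 1
                return a, b

            return fit

        monkeypatch.setattr(ev, "_refit_fit", fake_refit_fit)

    def test_monotone_curve_returns_maximum_k(self, rng, monkeypatch):
        probed = []
        self._patch_cv(monkeypatch, lambda k: float(k), probed)
        sx = rng.uniform(size=8)
        sy = rng.uniform(size=12)
        k = tune_k(sx, sy, rng.standard_normal((10, 8)), rng.standard_normal((10, 12)), "pmd")
        assert k == 20
        assert min(probed) >= 2 and max(probed) <= 20

    def test_tiny_range_is_exhaustive(self, rng, monkeypatch):
        probed = []
        self._patch_cv(monkeypatch, lambda k: 1.0, probed)
        k = tune_k([0.9, 0.1], [0.8, 0.2], rng.standard_normal((10, 2)),
                   rng.standard_normal((10, 2)), "pmd")
        assert sorted(set(probed)) == [2, 3, 4]
        assert k == 2  # flat curve: tie goes to the sparsest k


@pytest.fixture(scope="module")
def smoke_table():
    return run_simulation_study(
            scenarios=[ScenarioConfig(s_x=0.5)],
            methods=("pmd",),
            strategies=("base", "top_k"),
            n_truths=2,
            n_repeats=2,
            seed=3,
            n_splits=4,
            grid_size=6,
            cv_rounds=1,
            cv_folds=3,
            tune_grid_size=3,
            n_thresholds=10,
        )


class TestRunSimulationStudy:
    def test_report_is_well_formed(self, smoke_table):
        df = smoke_table
        assert set(df.columns) == {
            "scenario", "model", "method", "strategy", "metric", "value",
        }
        runs = df[df.metric == "n_runs"]
        assert (runs.value == 4).all()
        for metric in ("auc", "ba", "test_correlation"):
            vals = df[df.metric == metric].value
            assert len(vals) == 2  # one per strategy
            assert (vals >= -1).all() and (vals <= 1).all()

    def test_fixed_seed_reproducible(self, smoke_table):
        again = run_simulation_study(
            scenarios=[ScenarioConfig(s_x=0.5)],
            methods=("pmd",),
            strategies=("base", "top_k"),
            n_truths=2,
            n_repeats=2,
            seed=3,
            n_splits=4,
            grid_size=6,
            cv_rounds=1,
            cv_folds=3,
            tune_grid_size=3,
            n_thresholds=10,
        )
        np.testing.assert_allclose(
            smoke_table.value.to_numpy(), again.value.to_numpy(), atol=0
        )
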