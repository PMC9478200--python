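"""NIPALS PLS1, LOOCV rank screening, interval division and SiPLS."""

import itertools

import numpy as np
import pytest

from nirquant import (
    SpectraSet, WavenumberGrid, apply_pretreatments, divide_intervals,
    fit_pls, interval_mask, loocv_curve, parse_steps, pls_predict,
    pls_scores, select_rank, sipls_search,
)


def _linear_problem(rng, n=30, p=5, noise=0.0):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + 1.5 + noise * rng.normal(size=n)
    return X, y


class TestFitPLS:
    def test_full_rank_matches_ordinary_least_squares(self, rng):
        X, y = _linear_problem(rng)
        model = fit_pls(X, y, A=5)
        design = np.column_stack([np.ones(len(y)), X])
        beta_ols, *_ = np.linalg.lstsq(design, y, rcond=None)
        ols_pred = design @ beta_ols
        np.testing.assert_allclose(pls_predict(model, X, 5), ols_pred,
                                   atol=1e-8)

    def test_first_factor_closed_form(self, rng):
        X, y = _linear_problem(rng)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w = Xc.T @ yc
        t_expected = Xc @ (w / np.linalg.norm(w))
        model = fit_pls(X, y, A=1)
        np.testing.assert_allclose(model.T[:, 0], t_expected, atol=1e-10)

    def test_constant_y_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="constant"):
            fit_pls(X, np.ones(10), A=2)

    def test_scores_are_orthogonal(self, rng):
        X, y = _linear_problem(rng, n=25, p=10, noise=0.5)
        model = fit_pls(X, y, A=8)
        gram = model.T.T @ model.T
        norms = np.sqrt(np.diag(gram))
        off = gram - np.diag(np.diag(gram))
        assert np.all(np.abs(off) <= 1e-8 * np.outer(norms, norms))

    def test_coefficients_reproduce_deflation_recursion(self, rng):
        X, y = _linear_problem(rng, n=20, p=8, noise=0.3)
        model = fit_pls(X, y, A=6)
        for a in range(1, model.rank + 1):
            fitted_recursion = model.y_mean + model.T[:, :a] @ model.q[:a]
            np.testing.assert_allclose(pls_predict(model, X, a),
                                       fitted_recursion, atol=1e-10)

    def test_rank_truncated_with_warning_on_degenerate_design(self, rng):
        X = np.tile(rng.normal(size=(12, 1)), (1, 6))  # rank-1 design
        y = X[:, 0] + 0.01 * rng.normal(size=12)
        with pytest.warns(UserWarning, match="truncated"):
            model = fit_pls(X, y, A=5)
        assert model.rank < 5


class TestPLSPredictAndScores:
    def test_mean_row_predicts_mean_and_scores_zero(self, rng):
        X, y = _linear_problem(rng)
        model = fit_pls(X, y, A=3)
        np.testing.assert_allclose(pls_predict(model, X.mean(axis=0), 3),
                                   model.y_mean, atol=1e-10)
        np.testing.assert_allclose(pls_scores(model, X.mean(axis=0), 3),
                                   0.0, atol=1e-10)

    def test_rank_zero_is_the_null_model(self, rng):
        X, y = _linear_problem(rng)
        model = fit_pls(X, y, A=3)
        np.testing.assert_allclose(pls_predict(model, X, 0), model.y_mean)

    def test_training_scores_reproduce_stored_T(self, rng):
        X, y = _linear_problem(rng, n=15, p=7, noise=0.2)
        model = fit_pls(X, y, A=5)
        np.testing.assert_allclose(pls_scores(model, X, 5), model.T,
                                   atol=1e-10)
        assert pls_scores(model, X, 0).shape == (15, 0)

    def test_width_mismatch_refused(self, rng):
        X, y = _linear_problem(rng)
        model = fit_pls(X, y, A=2)
        with pytest.raises(ValueError, match="mismatch"):
            pls_predict(model, np.zeros((2, 7)), 2)

    def test_shift_equivariance_in_y(self, rng):
        X, y = _linear_problem(rng, noise=0.2)
        m1 = fit_pls(X, y, A=4)
        m2 = fit_pls(X, y + 100.0, A=4)
        np.testing.assert_allclose(pls_predict(m2, X, 4),
                                   pls_predict(m1, X, 4) + 100.0, atol=1e-8)


class TestLOOCV:
    def test_matches_explicit_refit_loop(self, rng):
        X, y = _linear_problem(rng, n=5, p=4, noise=0.5)
        result = loocv_curve(X, y, A_max=3)
        preds_oracle = np.zeros((5, 4))
        for i in range(5):
            keep = np.arange(5) != i
            model = fit_pls(X[keep], y[keep], 3)
            for a in range(4):
                preds_oracle[i, a] = pls_predict(model, X[i], min(a, model.rank))[0]
        np.testing.assert_allclose(result.predictions, preds_oracle, atol=1e-12)
        np.testing.assert_allclose(
            result.rmsecv,
            np.sqrt(((preds_oracle - y[:, None]) ** 2).mean(axis=0)),
            atol=1e-12)

    def test_rank_zero_equals_leave_one_out_mean(self, rng):
        X, y = _linear_problem(rng, n=8, p=3, noise=1.0)
        result = loocv_curve(X, y, A_max=2)
        n = y.size
        loo_means = (n * y.mean() - y) / (n - 1)
        np.testing.assert_allclose(result.rmsecv[0],
                                   np.sqrt(np.mean((y - loo_means) ** 2)),
                                   atol=1e-12)

    def test_noiseless_linear_recovery(self, rng):
        X, y = _linear_problem(rng, n=20, p=4, noise=0.0)
        result = loocv_curve(X, y, A_max=4)
        assert result.rmsecv[4] <= 1e-8

    def test_no_leakage_from_the_left_out_sample(self, coarse_grid, rng):
        n = 8
        matrix = rng.normal(1.0, 0.2, (n, coarse_grid.n_points))
        spectra = SpectraSet(tuple(f"s{i}" for i in range(n)), coarse_grid,
                             matrix)
        y = rng.normal(9.0, 2.0, n)
        steps = parse_steps("msc")
        base = loocv_curve(spectra, y, 3, steps)
        corrupted = y.copy()
        corrupted[4] += 50.0
        perturbed = loocv_curve(spectra, corrupted, 3, steps)
        # the fold that leaves sample 4 out trains without its y, so its
        # held-out prediction cannot change
        np.testing.assert_allclose(perturbed.predictions[4],
                                   base.predictions[4], atol=1e-10)


class TestSelectRank:
    def test_joint_minimum(self):
        assert select_rank([3, 2, 1, 1.5], [3, 2, 1, 1.5]) == 3

    def test_flat_curves_tie_break_to_rank_one(self):
        assert select_rank([1.0, 1.0, 1.0], [2.0, 2.0, 2.0]) == 1

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            rmsecv = rng.uniform(0.5, 3.0, size=10)
            rmsep = rng.uniform(0.5, 3.0, size=10)
            best = min(range(10), key=lambda a: (rmsecv[a] + rmsep[a], a))
            assert select_rank(rmsecv, rmsep) == best + 1


class TestIntervals:
    def test_equal_width_edges(self):
        ivs = divide_intervals((9000.0, 4000.0), 5)
        expected = [(8000.0, 9000.0), (7000.0, 8000.0), (6000.0, 7000.0),
                    (5000.0, 6000.0), (4000.0, 5000.0)]
        assert list(ivs) == expected

    def test_single_interval_is_whole_window(self):
        assert list(divide_intervals((4000.0, 9000.0), 1)) == [(4000.0, 9000.0)]

    def test_custom_edges_contain_selected_band(self):
        ivs = divide_intervals((9000.0, 4000.0),
                               edges=[9000.0, 7500.0, 4250.0, 4000.0])
        assert len(ivs) == 3
        assert (4250.0, 7500.0) in list(ivs)

    def test_masks_partition_the_window(self, coarse_grid):
        ivs = divide_intervals((9000.0, 4000.0), 5)
        masks = [interval_mask(coarse_grid, ivs, [m]) for m in range(5)]
        union = np.logical_or.reduce(masks)
        assert union.all()
        assert sum(m.sum() for m in masks) == coarse_grid.n_points


class TestSiPLS:
    def _dataset(self, rng, bands_interval=2, n=24):
        # all analyte signal confined to one interval of the working range
        grid = WavenumberGrid.from_range(9000.0, 4000.0, 40.0)
        ivs = divide_intervals((9000.0, 4000.0), 5)
        lo, hi = list(ivs)[bands_interval]
        center = 0.5 * (lo + hi)
        pure = np.exp(-((grid.values - center) / 80.0) ** 2)
        conc = rng.uniform(2.0, 12.0, n)
        X = np.outer(conc, pure) + rng.normal(0, 0.002, (n, grid.n_points))
        ids = tuple(f"s{i}" for i in range(n))
        return SpectraSet(ids, grid, X), conc, ivs

    def test_evaluates_all_31_combinations(self, rng):
        spectra, y, ivs = self._dataset(rng)
        cal = spectra.subset(spectra.sample_ids[:16])
        val = spectra.subset(spectra.sample_ids[16:])
        best, report = sipls_search(cal, y[:16], ivs, 3, val, y[16:])
        assert len(report) == 2 ** 5 - 1
        assert len({r.members for r in report}) == 31

    def test_winner_contains_the_signal_interval(self, rng):
        spectra, y, ivs = self._dataset(rng, bands_interval=2)
        cal = spectra.subset(spectra.sample_ids[:16])
        val = spectra.subset(spectra.sample_ids[16:])
        best, _ = sipls_search(cal, y[:16], ivs, 3, val, y[16:])
        assert 2 in best.members

    def test_matches_manual_enumeration_on_two_intervals(self, rng):
        spectra, y, _ = self._dataset(rng, n=18)
        ivs = divide_intervals((9000.0, 4000.0), 2)
        cal = spectra.subset(spectra.sample_ids[:12])
        val = spectra.subset(spectra.sample_ids[12:])
        best, report = sipls_search(cal, y[:12], ivs, 2, val, y[12:])
        # manual oracle: run the three combinations by hand
        oracle = {}
        for members in [(0,), (1,), (0, 1)]:
            mask = interval_mask(spectra.grid, ivs, members)
            Xc, Xv = cal.absorbance[:, mask], val.absorbance[:, mask]
            cv = loocv_curve(Xc, y[:12], 2)
            rank = int(np.argmin(cv.rmsecv[1:])) + 1
            model = fit_pls(Xc, y[:12], rank)
            yhat = pls_predict(model, Xv, min(rank, model.rank))
            oracle[members] = (rank, cv.rmsecv[rank],
                               float(np.sqrt(np.mean((yhat - y[12:]) ** 2))))
        assert len(report) == 3
        for rec in report:
            rank, rmsecv, rmsep = oracle[rec.members]
            assert rec.rank == rank
            assert rec.rmsecv == pytest.approx(rmsecv, abs=1e-12)
            assert rec.rmsep_val == pytest.approx(rmsep, abs=1e-12)
        manual_best = min(oracle.items(),
                          key=lambda kv: (kv[1][1], len(kv[0]), kv[1][0]))[0]
        assert best.members == manual_best
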