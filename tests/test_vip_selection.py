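import numpy as np
import pandas as pd
import pytest

from gestclock._enet import cd_path, enet_coef_path, lambda_path
from gestclock.vip_selection import (EnetFitRecord, coefficient_summary,
                                     fit_bootstrap_enet, run_vip,
                                     select_nzero_elbow,
                                     select_stable_variables, summarize_vip)


def _standardized_xy(rng, n=80, p=4, signal=(1.0, 0.0, 0.0, 0.0), noise=0.5):
    X = rng.standard_normal((n, p))
    y = X @ np.array(signal[:p]) + noise * rng.standard_normal(n)
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    y = (y - y.mean()) / y.std(ddof=1)
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(p)]), y


class TestEnetSolver:
    def test_matches_sklearn_elastic_net(self, rng):
        """Cross-check the compiled path solver against an independent
        implementation at several mixing/penalty values."""
        sklearn = pytest.importorskip("sklearn.linear_model")
        X, y = _standardized_xy(rng, n=150, p=6,
                                signal=(0.8, -0.5, 0.3, 0, 0, 0))
        Xa = X.to_numpy()
        for alpha in (0.1, 0.5, 1.0):
            lams = lambda_path(Xa.T @ y / len(y), alpha)
            ours = enet_coef_path(Xa, y, alpha, lams)
            for li in (0, 40, 99):
                sk = sklearn.ElasticNet(alpha=lams[li], l1_ratio=alpha,
                                        fit_intercept=True, tol=1e-12,
                                        max_iter=500_000).fit(Xa, y)
                np.testing.assert_allclose(ours[li], sk.coef_, atol=1e-6)

    def test_ridge_closed_form(self, rng):
        X, y = _standardized_xy(rng, n=100, p=5, signal=(0.5, 0.4, 0, 0, 0))
        Xa = X.to_numpy()
        n = len(y)
        lams = lambda_path(Xa.T @ y / n, 0.0)
        ours = enet_coef_path(Xa, y, 0.0, lams)
        G = Xa.T @ Xa / n
        c = Xa.T @ y / n
        for li in (0, 50, 99):
            expect = np.linalg.solve(G + lams[li] * np.eye(5), c)
            np.testing.assert_allclose(ours[li], expect, atol=1e-10)

    def test_largest_lambda_zeroes_everything_for_lasso(self, rng):
        X, y = _standardized_xy(rng)
        Xa = X.to_numpy()
        lams = lambda_path(Xa.T @ y / len(y), 1.0)
        coefs = enet_coef_path(Xa, y, 1.0, lams)
        assert np.all(coefs[0] == 0.0)


class TestFitBootstrapEnet:
    def test_ridge_records_have_all_coefficients(self, rng):
        X, y = _standardized_xy(rng)
        recs = fit_bootstrap_enet(X, y, B=2, alpha_grid=(0.0,), n_lambda=20,
                                  k_folds=5, seed=1)
        assert all(r.nzero == X.shape[1] for r in recs)
        assert all(r.alpha == 0.0 for r in recs)

    def test_single_true_predictor_enters_first(self, rng):
        # y is exactly x1: the nzero=1 best model must select x1
        X, y = _standardized_xy(rng, n=50, p=3, signal=(1.0, 0.0, 0.0),
                                noise=0.0)
        recs = fit_bootstrap_enet(X, y, B=1, n_lambda=50, k_folds=5, seed=2)
        one = [r for r in recs if r.nzero == 1]
        assert one, "no single-variable model on the path"
        for r in one:
            coefs = dict(zip(r.variables, r.coefficients))
            assert coefs["x0"] != 0.0

    def test_fixed_seed_reproduces_records_exactly(self, rng):
        X, y = _standardized_xy(rng, n=60)
        a = fit_bootstrap_enet(X, y, B=3, n_lambda=30, k_folds=5, seed=9)
        b = fit_bootstrap_enet(X, y, B=3, n_lambda=30, k_folds=5, seed=9)
        assert a == b

    def test_min_cvm_retained_per_group(self, rng):
        X, y = _standardized_xy(rng, n=60)
        recs = fit_bootstrap_enet(X, y, B=4, n_lambda=30, k_folds=5, seed=3)
        seen = set()
        for r in recs:
            key = (r.bootstrap_index, r.nzero)
            assert key not in seen, "duplicate (bootstrap, nzero) group"
            seen.add(key)

    def test_small_sample_recommends_fewer_folds(self, rng):
        X, y = _standardized_xy(rng, n=30)
        with pytest.raises(ValueError, match="folds"):
            fit_bootstrap_enet(X, y, B=1, k_folds=10, seed=0)

    def test_constant_outcome_raises(self, rng):
        X, _ = _standardized_xy(rng)
        with pytest.raises(ValueError, match="constant"):
            fit_bootstrap_enet(X, np.ones(len(X)), B=1, seed=0)

    def test_column_permutation_permutes_outputs(self, rng):
        X, y = _standardized_xy(rng, n=70, p=4, signal=(0.9, -0.6, 0.2, 0.0))
        perm = ["x2", "x0", "x3", "x1"]
        a = run_vip(X, y, B=8, n_lambda=30, k_folds=5, seed=4)
        b = run_vip(X[perm], y, B=8, n_lambda=30, k_folds=5, seed=4)
        assert a.elbow.nzero == b.elbow.nzero
        assert sorted(a.selection.stable_variables) == sorted(
            b.selection.stable_variables)
        pd.testing.assert_frame_equal(
            a.vip.table[list(X.columns)].sort_index(),
            b.vip.table[list(X.columns)].sort_index())


class TestSummarizeVIP:
    def _records(self, entries, variables=("u", "v")):
        recs = []
        for b, nzero, cvm, coefs in entries:
            recs.append(EnetFitRecord(bootstrap_index=b, alpha=0.5, lam=0.1,
                                      nzero=nzero, cvm=cvm,
                                      coefficients=tuple(coefs),
                                      variables=tuple(variables)))
        return recs

    def test_vip_percentage_arithmetic(self):
        # variable u non-zero in 83 of 100 contributing bootstraps -> 83%
        entries = [(b, 2, 1.0, (0.5 if b <= 83 else 0.0, 0.2))
                   for b in range(1, 101)]
        vip = summarize_vip(self._records(entries))
        assert vip.table.loc[2, "u"] == pytest.approx(83.0)
        assert vip.table.loc[2, "v"] == pytest.approx(100.0)
        assert vip.table.loc[2, "median_cvm"] == pytest.approx(1.0)

    def test_low_coverage_nzero_excluded_from_curve(self):
        entries = [(b, 1, 1.0, (0.5, 0.0)) for b in range(1, 11)]
        entries += [(b, 2, 0.9, (0.5, 0.1)) for b in range(1, 5)]  # 40%
        vip = summarize_vip(self._records(entries))
        assert list(vip.table.index) == [1]
        assert list(vip.excluded.index) == [2]

    def test_empty_records_raise(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_vip([])

    def test_single_nzero_table_falls_back(self):
        entries = [(b, 3, 1.0, (0.5, 0.1)) for b in range(1, 11)]
        vip = summarize_vip(self._records(entries))
        choice = select_nzero_elbow(vip)
        assert choice.nzero == 3
        assert choice.method == "argmin_fallback"


def _chord_distance_oracle(curve):
    """Brute-force farthest-point-below-chord on min-max scaled axes,
    via the explicit perpendicular point-to-line distance formula."""
    pts = sorted(curve)
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    x = (x - x[0]) / (x[-1] - x[0])
    yr = y.max() - y.min()
    y = (y - y.min()) / yr if yr > 0 else np.zeros_like(y)
    # chord as a*x + b*y + c = 0
    a = y[-1] - y[0]
    b = -(x[-1] - x[0])
    c = -(a * x[0] + b * y[0])
    norm = np.hypot(a, b)
    best, best_d = None, -1.0
    for i in range(1, len(pts) - 1):
        d = abs(a * x[i] + b * y[i] + c) / norm
        below = y[i] < y[0] + (y[-1] - y[0]) * (x[i] - x[0]) / (x[-1] - x[0])
        if below and d > best_d + 1e-12:
            best, best_d = pts[i][0], d
    return best


class TestElbow:
    def test_documented_example(self):
        curve = [(1, 10.0), (2, 4.0), (3, 3.0), (4, 2.8), (5, 2.7)]
        assert select_nzero_elbow(curve).nzero == 2

    def test_linear_curve_ties_to_smallest_interior(self):
        curve = [(1, 5.0), (2, 4.0), (3, 3.0), (4, 2.0)]
        choice = select_nzero_elbow(curve)
        assert choice.nzero == 2
        assert "degenerate" in choice.note

    def test_length_one_curve_flagged_fallback(self):
        choice = select_nzero_elbow([(4, 1.0)])
        assert choice.nzero == 4
        assert choice.method == "argmin_fallback"

    def test_non_decreasing_curve_falls_back_to_argmin(self):
        choice = select_nzero_elbow([(1, 1.0), (2, 1.5), (3, 2.0), (4, 2.0)])
        assert choice.nzero == 1
        assert choice.method == "argmin_fallback"

    def test_agrees_with_brute_force_on_random_curves(self):
        rng = np.random.default_rng(77)
        for _ in range(1000):
            m = rng.integers(3, 15)
            nz = np.sort(rng.choice(np.arange(0, 30), size=m, replace=False))
            # monotone-ish decreasing curve with noise
            cvm = np.sort(rng.uniform(0.2, 2.0, m))[::-1]
            cvm += rng.normal(0, 0.02, m)
            curve = list(zip(nz.tolist(), cvm.tolist()))
            choice = select_nzero_elbow(curve)
            if choice.method == "elbow" and not choice.note:
                assert choice.nzero == _chord_distance_oracle(curve)


class TestStabilityAndSummary:
    def _vip_with_row(self, vips, nzero=9):
        variables = tuple(vips)
        df = pd.DataFrame({"coverage": 100, "median_cvm": 1.0, **vips},
                          index=pd.Index([nzero], name="nzero"))
        from gestclock.vip_selection import VIPTable
        return VIPTable(variables=variables, table=df,
                        excluded=df.iloc[:0], B=100, min_coverage=0.5)

    def test_strict_threshold_boundary(self):
        vip = self._vip_with_row({"a": 75.0, "b": 75.1})
        assert select_stable_variables(vip, 9) == ["b"]

    def test_reported_stable_set_pattern(self):
        # the VIP pattern reported for term cord blood: five of seven clear 75%
        vips = {"smoking": 97.0, "mental": 83.0, "delivery": 87.0,
                "length": 95.0, "sex": 84.0, "bmi": 60.0, "parity": 40.0}
        vip = self._vip_with_row(vips)
        assert sorted(select_stable_variables(vip, 9)) == sorted(
            ["smoking", "mental", "delivery", "length", "sex"])

    def test_empty_stable_set_allowed(self):
        vip = self._vip_with_row({"a": 10.0, "b": 50.0})
        assert select_stable_variables(vip, 9) == []

    def test_missing_nzero_raises(self):
        vip = self._vip_with_row({"a": 80.0})
        with pytest.raises(ValueError, match="nzero"):
            select_stable_variables(vip, 3)

    def test_percentile_interpolation_example(self):
        recs = [EnetFitRecord(bootstrap_index=b, alpha=0.5, lam=0.1, nzero=1,
                              cvm=1.0, coefficients=(c,), variables=("u",))
                for b, c in enumerate([0.2, 0.3, 0.4], start=1)]
        sel = coefficient_summary(recs, 1, ["u"])
        assert sel.median_coefficients["u"] == pytest.approx(0.3)
        assert sel.ci95["u"][0] == pytest.approx(0.205)
        assert sel.ci95["u"][1] == pytest.approx(0.395)
        assert sel.prediction_vector["u"] == pytest.approx(0.3)

    def test_single_bootstrap_degenerate_ci_flagged(self):
        recs = [EnetFitRecord(bootstrap_index=1, alpha=0.5, lam=0.1, nzero=1,
                              cvm=1.0, coefficients=(0.4,), variables=("u",))]
        sel = coefficient_summary(recs, 1, ["u"])
        assert sel.ci95["u"] == (pytest.approx(0.4), pytest.approx(0.4))
        assert any("degenerate" in n for n in sel.notes)

    def test_never_selected_variable_omitted(self):
        recs = [EnetFitRecord(bootstrap_index=b, alpha=0.5, lam=0.1, nzero=1,
                              cvm=1.0, coefficients=(0.3, 0.0),
                              variables=("u", "w")) for b in (1, 2)]
        sel = coefficient_summary(recs, 1, ["u"])
        assert "w" not in sel.median_coefficients
        assert any("never non-zero" in n for n in sel.notes)
        assert sel.prediction_vector["w"] == 0.0

    def test_ci_contains_median(self, rng):
        vals = rng.normal(0.3, 0.05, 25)
        recs = [EnetFitRecord(bootstrap_index=b, alpha=0.5, lam=0.1, nzero=1,
                              cvm=1.0, coefficients=(float(v),),
                              variables=("u",))
                for b, v in enumerate(vals, start=1)]
        sel = coefficient_summary(recs, 1, ["u"])
        lo, hi = sel.ci95["u"]
        assert lo <= sel.median_coefficients["u"] <= hi
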