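import numpy as np
import pytest

from ramandx import classify as cl
from ramandx import preprocess as pp
from ramandx import synthetic_data as sd
from ramandx.spectra_io import Label, SpectrumMeta, SpectrumSet


def newton_logistic_oracle(x, y, max_iter=200, tol=1e-12):
    """Plain unpenalized Newton-Raphson MLE on the raw design (with intercept)."""
    design = np.column_stack([np.ones(len(y)), x])
    theta = np.zeros(design.shape[1])
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-design @ theta))
        grad = design.T @ (y - p)
        hess = (design * (p * (1 - p))[:, None]).T @ design
        step = np.linalg.solve(hess, grad)
        theta = theta + step
        if np.max(np.abs(step)) < tol:
            break
    return theta


def toy_nonseparable(seed=0, n=20, p=3):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    logits = 0.5 + x @ np.array([1.0, -0.5, 0.25])
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logits))).astype(float)
    # ensure both classes and non-separability (oracle converges finitely)
    assert 0 < y.sum() < n
    return x, y


def labelled_set(x, y, groups=None):
    n, m = x.shape
    axis = 1000.0 + np.arange(float(m))
    metas = [
        SpectrumMeta(
            f"s{i}",
            sample_id=(groups[i] if groups is not None else f"g{i % 2}"),
            label=Label.TUMOR if y[i] == 1 else Label.NORMAL,
        )
        for i in range(n)
    ]
    return SpectrumSet(axis, x, metas)


class TestFitRidgeLogistic:
    def test_lambda_zero_matches_newton_oracle(self):
        x, y = toy_nonseparable(seed=1)
        theta = newton_logistic_oracle(x, y)
        model = cl.fit_ridge_logistic(x, y, 0.0)
        # map model (standardized space) back to raw coordinates
        beta_raw = model.coefficients / model.column_scales
        intercept_raw = model.intercept - np.sum(
            model.coefficients * model.column_centers / model.column_scales
        )
        assert model.converged
        np.testing.assert_allclose(beta_raw, theta[1:], atol=1e-6)
        assert intercept_raw == pytest.approx(theta[0], abs=1e-6)

    def test_huge_lambda_collapses_to_prevalence(self):
        x, y = toy_nonseparable(seed=2)
        model = cl.fit_ridge_logistic(x, y, 1e8)
        assert np.max(np.abs(model.coefficients)) < 1e-4
        prevalence_logit = np.log(y.mean() / (1 - y.mean()))
        assert model.intercept == pytest.approx(prevalence_logit, abs=1e-3)

    def test_row_duplication_with_doubled_lambda(self):
        x, y = toy_nonseparable(seed=3)
        m1 = cl.fit_ridge_logistic(x, y, 2.5)
        m2 = cl.fit_ridge_logistic(np.vstack([x, x]), np.concatenate([y, y]), 5.0)
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, atol=1e-6)
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-6)

    def test_monotone_shrinkage(self):
        x, y = toy_nonseparable(seed=4)
        norms = [
            np.linalg.norm(cl.fit_ridge_logistic(x, y, lam).coefficients)
            for lam in (0.01, 0.1, 1.0, 10.0, 100.0)
        ]
        assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))

    def test_wide_matrix_matches_tall_solution_route(self):
        # p > n triggers the reduced-space solve; check against direct IRLS
        rng = np.random.default_rng(5)
        x = rng.normal(size=(15, 40))
        y = (rng.random(15) < 0.5).astype(float)
        if y.sum() in (0, 15):
            y[0] = 1 - y[0]
        model = cl.fit_ridge_logistic(x, y, 1.0)
        zx = (x - model.column_centers) / model.column_scales
        b0, beta, _, _ = cl._irls(zx, y, 1.0)
        np.testing.assert_allclose(model.coefficients, beta, atol=1e-6)
        assert model.intercept == pytest.approx(b0, abs=1e-6)

    def test_single_class_rejected(self):
        x = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError, match="single class"):
            cl.fit_ridge_logistic(x, np.ones(5), 1.0)

    def test_separable_unpenalized_flagged_not_converged(self):
        x = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        model = cl.fit_ridge_logistic(x, y, 0.0)
        assert not model.converged

    def test_row_order_invariance(self):
        x, y = toy_nonseparable(seed=6)
        perm = np.random.default_rng(1).permutation(len(y))
        m1 = cl.fit_ridge_logistic(x, y, 0.5)
        m2 = cl.fit_ridge_logistic(x[perm], y[perm], 0.5)
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, atol=1e-7)

    def test_probabilities_strictly_inside_unit_interval(self):
        x, y = toy_nonseparable(seed=7)
        model = cl.fit_ridge_logistic(x, y, 0.1)
        probs = model.predict_proba(x * 100)
        assert np.all(probs > 0) and np.all(probs < 1)


class TestSelectLambda:
    def test_single_value_grid(self):
        x, y = toy_nonseparable(seed=8)
        assert cl.select_lambda_loocv(x, y, np.array([3.0])) == 3.0

    def test_empty_grid_rejected(self):
        x, y = toy_nonseparable(seed=8)
        with pytest.raises(ValueError):
            cl.select_lambda_loocv(x, y, np.array([]))

    def test_noise_labels_prefer_heavy_penalty(self):
        grid = cl.default_lambda_grid(num=9)
        upper_half = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(size=(24, 10))
            y = (rng.random(24) < 0.5).astype(float)
            if y.sum() < 2 or y.sum() > 22:
                y[:2] = [0, 1]
            lam = cl.select_lambda_loocv(x, y, grid)
            if lam >= np.median(grid):
                upper_half += 1
        assert upper_half >= 16  # >= 80% of replicates

    def test_strong_signal_prefers_lighter_penalty(self):
        grid = cl.default_lambda_grid(num=9)
        noise_lams, signal_lams = [], []
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            x = rng.normal(size=(24, 10))
            y_noise = (rng.random(24) < 0.5).astype(float)
            if y_noise.sum() < 2 or y_noise.sum() > 22:
                y_noise[:2] = [0, 1]
            y_signal = (x[:, 0] + 0.2 * rng.normal(size=24) > 0).astype(float)
            noise_lams.append(cl.select_lambda_loocv(x, y_noise, grid))
            signal_lams.append(cl.select_lambda_loocv(x, y_signal, grid))
        assert np.median(signal_lams) < np.median(noise_lams)


class TestLeaveGroupOut:
    def test_two_groups_two_folds_and_fold_independence(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(12, 6))
        x[:6, 0] += 2.0
        y = np.array([1.0] * 6 + [0.0] * 6)
        groups = ["a", "a", "a", "b", "b", "b"] * 2
        sset = labelled_set(x, y, groups)
        grid = np.array([1.0])
        preds = cl.leave_group_out_predict(sset, grid)
        assert {p.fold_group for p in preds} == {"a", "b"}
        assert len(preds) == 12
        # out-of-fold independence: perturbing the held-out group's rows
        # must not change that fold's fitted model, so its new predictions
        # equal the unperturbed-training model applied to the new rows
        is_b = np.array(groups) == "b"
        x2 = x.copy()
        x2[is_b] += rng.normal(size=(is_b.sum(), 6)) * 5
        preds2 = cl.leave_group_out_predict(labelled_set(x2, y, groups), grid)
        model_a = cl.fit_ridge_logistic(x[~is_b], y[~is_b], 1.0)
        expected = model_a.predict_proba(x2[is_b])
        got = [p.probability for p in preds2 if p.fold_group == "b"]
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_borderline_excluded_entirely(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(13, 6))
        metas = []
        for i in range(13):
            label = Label.BORDERLINE if i == 12 else (
                Label.TUMOR if i < 6 else Label.NORMAL
            )
            metas.append(SpectrumMeta(f"s{i}", f"g{i % 3}", label))
        sset = SpectrumSet(1000.0 + np.arange(6.0), x, metas)
        preds = cl.leave_group_out_predict(sset, np.array([1.0]))
        assert len(preds) == 12
        assert all(p.true_label != Label.BORDERLINE for p in preds)

    def test_all_same_label_rejected(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(6, 4))
        sset = labelled_set(x, np.ones(6), ["a", "a", "a", "b", "b", "b"])
        with pytest.raises(ValueError, match="same label"):
            cl.leave_group_out_predict(sset, np.array([1.0]))

    def test_single_class_training_fold_raises_unless_allowed(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(8, 4))
        # group 'a' holds every normal: removing it leaves tumor-only training
        groups = ["a"] * 4 + ["b", "b", "c", "c"]
        y = np.array([0.0] * 4 + [1.0] * 4)
        sset = labelled_set(x, y, groups)
        with pytest.raises(ValueError, match="single-class"):
            cl.leave_group_out_predict(sset, np.array([1.0]))
        preds = cl.leave_group_out_predict(sset, np.array([1.0]), allow_degenerate=True)
        assert {p.fold_group for p in preds} == {"b", "c"}

    def test_probability_half_called_normal(self):
        pred = cl.CVPrediction("s", Label.NORMAL, 0.5, Label.NORMAL, "g", 1.0)
        assert pred.call == Label.NORMAL  # construction mirrors the strict rule

    def test_cell_design_recovery(self, strong_cell_set):
        grid = cl.default_lambda_grid(num=9)
        preds = cl.leave_group_out_predict(strong_cell_set, grid)
        metrics = cl.confusion_metrics(preds)
        assert metrics.sensitivity >= 0.95
        assert metrics.specificity >= 0.70

    def test_top_coefficients_inside_effect_windows(self, strong_cell_set):
        y = (strong_cell_set.labels == "tumor").astype(float)
        model = cl.fit_ridge_logistic(strong_cell_set.matrix, y, 1.0)
        axis = strong_cell_set.axis
        windows = [
            (b.center - b.width, b.center + b.width)
            for b in sd.default_bands(2.0)
            if b.tumor_effect > 1
        ]
        inside = np.zeros(axis.size, dtype=bool)
        for lo, hi in windows:
            inside |= (axis >= lo) & (axis <= hi)
        coef = model.coefficients
        top = np.argsort(np.abs(coef))[-int(0.1 * coef.size):]
        frac_top_inside = np.abs(coef[top][inside[top]]).sum() / np.abs(coef[top]).sum()
        assert frac_top_inside > inside.mean()


class TestConfusionMetrics:
    @staticmethod
    def _preds(tp, fn, tn, fp):
        preds = []
        mk = lambda i, true, call: cl.CVPrediction(
            f"s{i}", true, 0.9 if call == Label.TUMOR else 0.1, call, "g", 1.0
        )
        i = 0
        for _ in range(tp):
            preds.append(mk(i, Label.TUMOR, Label.TUMOR)); i += 1
        for _ in range(fn):
            preds.append(mk(i, Label.TUMOR, Label.NORMAL)); i += 1
        for _ in range(tn):
            preds.append(mk(i, Label.NORMAL, Label.NORMAL)); i += 1
        for _ in range(fp):
            preds.append(mk(i, Label.NORMAL, Label.TUMOR)); i += 1
        return preds

    def test_printed_rates_reproduced(self):
        m = cl.confusion_metrics(self._preds(57, 1, 30, 10))
        assert m.sensitivity_pct == 98.3
        assert m.specificity_pct == 75.0

    def test_all_correct(self):
        m = cl.confusion_metrics(self._preds(5, 0, 5, 0))
        assert m.sensitivity_pct == 100.0 and m.specificity_pct == 100.0

    def test_degenerate_directions(self):
        m = cl.confusion_metrics(self._preds(0, 5, 5, 0))
        assert m.sensitivity_pct == 0.0 and m.specificity_pct == 100.0

    def test_borderline_rejected(self):
        bad = [cl.CVPrediction("s", Label.BORDERLINE, 0.6, Label.TUMOR, "g", 1.0)]
        with pytest.raises(ValueError, match="borderline"):
            cl.confusion_metrics(bad)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cl.confusion_metrics([])

    def test_rounding_is_half_up(self):
        # 31/40 = 77.5% exactly; 57/58 = 98.275...% -> 98.3
        m = cl.confusion_metrics(self._preds(57, 1, 31, 9))
        assert m.specificity_pct == 77.5
        assert m.sensitivity_pct == 98.3
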