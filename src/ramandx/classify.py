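"""L2-penalized logistic tumor-probability model with nested cross-validation.

The fit minimizes the summed negative log-likelihood plus
``lambda * ||coefficients||^2`` (intercept unpenalized) by Newton/IRLS on
columns standardized with training-fold statistics. When the number of
wavenumbers exceeds the number of spectra the optimum lies in the row
span, so the solve is carried out in the reduced space of a thin SVD —
identical solution, n-sized linear algebra.

Model selection is leave-one-out predictive log-likelihood over a penalty
grid; out-of-sample evaluation is leave-group-out: every spectrum from one
biological source (cell or mouse) forms a fold, with the penalty reselected
from that fold's training portion only. Probabilities strictly greater
than 0.5 are called tumor. Borderline spectra are excluded from both
training and testing by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import scipy.linalg as sla

from .spectra_io import Label, SpectrumSet

__all__ = [
    "RidgeLogisticModel",
    "CVPrediction",
    "ConfusionMetrics",
    "default_lambda_grid",
    "fit_ridge_logistic",
    "select_lambda_loocv",
    "leave_group_out_predict",
    "confusion_metrics",
]

MAX_ITER = 100
TOL = 1e-8


def default_lambda_grid(
    lo: float = 1e-4, hi: float = 1e4, num: int = 25
) -> np.ndarray:
    return np.logspace(np.log10(lo), np.log10(hi), num)


@dataclass
class RidgeLogisticModel:
    intercept: float
    coefficients: np.ndarray  # in standardized-column space
    lam: float
    converged: bool
    n_iter: int
    column_centers: np.ndarray
    column_scales: np.ndarray

    def decision(self, x: np.ndarray) -> np.ndarray:
        z = (np.atleast_2d(x) - self.column_centers) / self.column_scales
        return self.intercept + z @ self.coefficients

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        # clamped into the open interval: a saturated sigmoid would
        # otherwise round to exactly 0 or 1 in floating point
        return np.clip(_sigmoid(self.decision(x)), 1e-12, 1.0 - 1e-12)


@dataclass
class CVPrediction:
    spectrum_id: str
    true_label: Label
    probability: float
    call: Label
    fold_group: str
    lambda_selected: float


@dataclass
class ConfusionMetrics:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @staticmethod
    def _pct(x: float) -> float:
        return float(
            Decimal(repr(100.0 * x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
        )

    @property
    def sensitivity_pct(self) -> float:
        """Sensitivity as a percentage, rounded half-up to one decimal."""
        return self._pct(self.sensitivity)

    @property
    def specificity_pct(self) -> float:
        return self._pct(self.specificity)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
        }


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _standardize_columns(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # population sd so that duplicating rows leaves the scaling unchanged
    centers = x.mean(axis=0)
    scales = x.std(axis=0, ddof=0)
    scales = np.where(scales > 0, scales, 1.0)
    return (x - centers) / scales, centers, scales


def _irls(
    z: np.ndarray,
    y: np.ndarray,
    lam: float,
    w0: np.ndarray | None = None,
    tol: float = TOL,
) -> tuple[float, np.ndarray, bool, int]:
    """Newton/IRLS for logistic NLL + lam * ||w||^2 on features ``z``.

    Returns (intercept, weights, converged, n_iter). ``w0`` warm-starts the
    weights (intercept warm-started at the prevalence logit).
    """
    n, r = z.shape
    theta = np.zeros(r + 1)
    p_bar = min(max(y.mean(), 1e-12), 1 - 1e-12)
    theta[0] = np.log(p_bar / (1 - p_bar))
    if w0 is not None:
        theta[1:] = w0
    design = np.column_stack([np.ones(n), z])
    penalty = np.full(r + 1, 2.0 * lam)
    penalty[0] = 0.0
    diag = np.arange(r + 1)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        p = _sigmoid(design @ theta)
        grad = design.T @ (p - y) + penalty * theta
        w_diag = np.maximum(p * (1.0 - p), 1e-12)
        hess = (design * w_diag[:, None]).T @ design
        hess[diag, diag] += penalty
        try:
            step = sla.solve(hess, grad, assume_a="pos", check_finite=False)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        theta = theta - step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    return float(theta[0]), theta[1:], converged, it


def _reduce(zx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Thin SVD reduction: returns (scores U*S, basis V) with X = scores @ V.T."""
    u, s, vt = np.linalg.svd(zx, full_matrices=False)
    keep = s > s[0] * 1e-12 if s.size and s[0] > 0 else s > 0
    return u[:, keep] * s[keep], vt[keep].T


def fit_ridge_logistic(
    x: np.ndarray, y: np.ndarray, lam: float
) -> RidgeLogisticModel:
    """Fit the penalized logistic model on raw intensities ``x``.

    Columns are centered/scaled internally with the training statistics,
    which are frozen on the model for prediction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("x must be 2-D with one row per label")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        if classes.size < 2:
            raise ValueError("training data contains a single class")
        raise ValueError("labels must be coded 0/1")
    zx, centers, scales = _standardize_columns(x)
    n, p = zx.shape
    if p > n:
        scores, basis = _reduce(zx)
        b0, w, converged, n_iter = _irls(scores, y, lam)
        beta = basis @ w
    else:
        b0, beta, converged, n_iter = _irls(zx, y, lam)
    return RidgeLogisticModel(
        intercept=b0,
        coefficients=beta,
        lam=lam,
        converged=converged,
        n_iter=n_iter,
        column_centers=centers,
        column_scales=scales,
    )


def _loocv_loglik(
    x: np.ndarray, y: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Per-lambda summed leave-one-out predictive log-likelihood."""
    n = x.shape[0]
    total = np.zeros(grid.size)
    # warm-start chain runs from the most to the least penalized fit
    order = np.argsort(grid)[::-1]
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        y_tr = y[keep]
        if y_tr.min() == y_tr.max():
            continue  # held-out point removes the last member of a class
        zx, centers, scales = _standardize_columns(x[keep])
        scores, basis = _reduce(zx)
        z_i = ((x[i] - centers) / scales) @ basis
        w = None
        for g in order:
            b0, w, _, _ = _irls(scores, y_tr, grid[g], w0=w, tol=1e-6)
            eta = b0 + z_i @ w
            p_i = float(_sigmoid(np.array([eta]))[0])
            p_i = min(max(p_i, 1e-300), 1 - 1e-16)
            total[g] += np.log(p_i) if y[i] == 1 else np.log1p(-p_i)
    return total


def select_lambda_loocv(
    x: np.ndarray, y: np.ndarray, grid: np.ndarray | None = None
) -> float:
    """Penalty maximizing leave-one-out predictive log-likelihood.

    Ties are broken toward the larger penalty.
    """
    grid = default_lambda_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    if x.shape[0] < 3:
        raise ValueError("leave-one-out selection needs n >= 3")
    grid = np.sort(grid)
    scores = _loocv_loglik(np.asarray(x, dtype=float), np.asarray(y, dtype=float), grid)
    best = np.flatnonzero(scores >= scores.max() - 1e-12)[-1]
    return float(grid[best])


def leave_group_out_predict(
    sset: SpectrumSet,
    grid: np.ndarray | None = None,
    allow_degenerate: bool = False,
) -> list[CVPrediction]:
    """Out-of-fold tumor probabilities under leave-group-out CV.

    One fold per ``sample_id``; the penalty is reselected by inner LOOCV on
    each fold's training portion. Borderline and unknown spectra are
    excluded from both training and testing. Probabilities strictly above
    0.5 are called tumor (exactly 0.5 is normal).
    """
    labels = sset.labels
    usable = np.isin(labels, [Label.TUMOR.value, Label.NORMAL.value])
    if not usable.any():
        raise ValueError("no tumor/normal spectra to cross-validate")
    work = sset.subset(usable)
    y = (work.labels == Label.TUMOR.value).astype(float)
    if np.unique(y).size < 2:
        raise ValueError("all usable spectra carry the same label")
    groups = work.sample_ids
    unique_groups = list(dict.fromkeys(groups))
    if len(unique_groups) < 2:
        raise ValueError("leave-group-out needs at least 2 distinct sample_ids")
    grid = default_lambda_grid() if grid is None else np.asarray(grid, dtype=float)
    predictions: list[CVPrediction] = []
    for g in unique_groups:
        test = groups == g
        train = ~test
        y_tr = y[train]
        if np.unique(y_tr).size < 2:
            if allow_degenerate:
                continue
            raise ValueError(
                f"training portion for fold {g!r} is single-class; "
                "pass allow_degenerate=True to skip such folds"
            )
        lam = select_lambda_loocv(work.matrix[train], y_tr, grid)
        model = fit_ridge_logistic(work.matrix[train], y_tr, lam)
        probs = model.predict_proba(work.matrix[test])
        for idx, prob in zip(np.flatnonzero(test), probs):
            meta = work.metas[idx]
            predictions.append(
                CVPrediction(
                    spectrum_id=meta.spectrum_id,
                    true_label=meta.label,
                    probability=float(prob),
                    call=Label.TUMOR if prob > 0.5 else Label.NORMAL,
                    fold_group=g,
                    lambda_selected=lam,
                )
            )
    return predictions


def confusion_metrics(predictions: list[CVPrediction]) -> ConfusionMetrics:
    """Confusion counts and rates; tumor is the positive class."""
    if not predictions:
        raise ValueError("no predictions to summarize")
    tp = fn = tn = fp = 0
    for pred in predictions:
        if pred.true_label not in (Label.TUMOR, Label.NORMAL):
            raise ValueError(
                f"prediction {pred.spectrum_id!r} carries label "
                f"{pred.true_label.value!r}; borderline/unknown must be "
                "excluded upstream"
            )
        if pred.true_label == Label.TUMOR:
            if pred.call == Label.TUMOR:
                tp += 1
            else:
                fn += 1
        else:
            if pred.call == Label.TUMOR:
                fp += 1
            else:
                tn += 1
    return ConfusionMetrics(tp=tp, fn=fn, tn=tn, fp=fp)
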