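"""Per-wavenumber two-group statistics with a permutation-based FDR.

The t-statistic is oriented tumor minus normal. The FDR at a threshold c
on |t| is

    FDR(c) = E_perm[ #{k : |t*_k| >= c} ] / max(1, #{k : |t_k| >= c})

and the per-wavenumber q-value is the minimum of FDR over all observed
thresholds c' <= |t_j|, clipped to [0, 1], which enforces monotonicity of
q in |t|. Exhaustive mode enumerates every distinct assignment of the
group sizes to spectra; sampled mode draws B random assignments and always
includes the observed labeling among them.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .spectra_io import BandTable, Label, SpectrumSet

__all__ = [
    "DifferentialResult",
    "tstat_per_wavenumber",
    "permutation_fdr",
    "summarize_bands",
]

EXHAUSTIVE_CAP = 10_000


@dataclass
class DifferentialResult:
    axis: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    n_tumor: int
    n_normal: int
    n_permutations: int
    permutation_mode: str  # exhaustive | sampled
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.axis.size == self.t.size == self.p.size == self.q.size):
            raise ValueError("axis, t, p and q must share one length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavenumber": self.axis, "t": self.t, "p": self.p, "q": self.q}
        )


def _two_group_matrices(sset: SpectrumSet) -> tuple[np.ndarray, np.ndarray]:
    labels = sset.labels
    x_tumor = sset.matrix[labels == Label.TUMOR.value]
    x_normal = sset.matrix[labels == Label.NORMAL.value]
    if x_tumor.shape[0] < 2 or x_normal.shape[0] < 2:
        raise ValueError(
            "need at least 2 tumor and 2 normal spectra "
            f"(got {x_tumor.shape[0]} and {x_normal.shape[0]})"
        )
    return x_tumor, x_normal


def _tstat_columns(
    x: np.ndarray, is_tumor: np.ndarray, welch: bool = False
) -> np.ndarray:
    """Vectorised per-column t for one or many label assignments.

    ``is_tumor`` may be a boolean vector (n,) or matrix (B, n); returns a
    t array of shape (m,) or (B, m). Columns where both groups are
    constant and equal give t = 0.
    """
    is_tumor = np.atleast_2d(is_tumor).astype(float)
    n1 = is_tumor.sum(axis=1, keepdims=True)
    n0 = is_tumor.shape[1] - n1
    sum1 = is_tumor @ x
    sum0 = x.sum(axis=0, keepdims=True) - sum1
    sumsq1 = is_tumor @ (x**2)
    sumsq0 = (x**2).sum(axis=0, keepdims=True) - sumsq1
    mean1, mean0 = sum1 / n1, sum0 / n0
    var1 = (sumsq1 - n1 * mean1**2) / (n1 - 1)
    var0 = (sumsq0 - n0 * mean0**2) / (n0 - 1)
    var1 = np.maximum(var1, 0.0)
    var0 = np.maximum(var0, 0.0)
    if welch:
        se = np.sqrt(var1 / n1 + var0 / n0)
    else:
        pooled = ((n1 - 1) * var1 + (n0 - 1) * var0) / (n1 + n0 - 2)
        se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mean1 - mean0) / se, 0.0)
    return t if t.shape[0] > 1 else t[0]


def tstat_per_wavenumber(
    sset: SpectrumSet, welch: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample t (tumor minus normal) and two-sided p per wavenumber.

    Pooled-variance by default; Welch on request. Borderline and unknown
    spectra are ignored.
    """
    x_tumor, x_normal = _two_group_matrices(sset)
    n1, n0 = x_tumor.shape[0], x_normal.shape[0]
    x = np.vstack([x_tumor, x_normal])
    is_tumor = np.zeros(n1 + n0, dtype=bool)
    is_tumor[:n1] = True
    t = _tstat_columns(x, is_tumor, welch=welch)
    if welch:
        v1 = x_tumor.var(axis=0, ddof=1)
        v0 = x_normal.var(axis=0, ddof=1)
        num = (v1 / n1 + v0 / n0) ** 2
        den = (v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = np.where(den > 0, num / den, n1 + n0 - 2)
    else:
        df = n1 + n0 - 2
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, np.minimum(p, 1.0)


def _assignment_matrix_exhaustive(n: int, n1: int) -> np.ndarray:
    rows = np.zeros((comb(n, n1), n), dtype=bool)
    for b, idx in enumerate(combinations(range(n), n1)):
        rows[b, list(idx)] = True
    return rows


def _assignment_matrix_sampled(
    n: int, n1: int, b: int, rng: np.random.Generator
) -> np.ndarray:
    order = np.argsort(rng.random((b, n)), axis=1)
    rows = np.zeros((b, n), dtype=bool)
    np.put_along_axis(rows, order[:, :n1], True, axis=1)
    return rows


def _fdr_from_tmatrix(t_obs: np.ndarray, t_perm: np.ndarray) -> np.ndarray:
    """q-values from observed t (m,) and permutation t matrix (B, m)."""
    abs_obs = np.abs(t_obs)
    all_perm = np.sort(np.abs(t_perm).ravel())
    b = t_perm.shape[0]
    # closed thresholds: count >= c, with a tiny relative nudge so that
    # ties between numerically-equivalent assignments are not lost to
    # floating-point round-off
    thr = abs_obs * (1.0 - 1e-10) - 1e-12
    # mean over permutations of #{k : |t*| >= c}, for each observed c
    n_null = (all_perm.size - np.searchsorted(all_perm, thr, side="left")) / b
    sorted_obs = np.sort(abs_obs)
    n_called = abs_obs.size - np.searchsorted(sorted_obs, thr, side="left")
    fdr = n_null / np.maximum(1, n_called)
    # q_j = min over thresholds c' <= |t_j| of FDR(c'), clipped to [0, 1]
    order = np.argsort(abs_obs, kind="stable")
    q = np.empty_like(fdr)
    q[order] = np.minimum.accumulate(fdr[order])
    return np.clip(q, 0.0, 1.0)


def permutation_fdr(
    sset: SpectrumSet,
    b: int = 1000,
    seed: int = 0,
    welch: bool = False,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
) -> DifferentialResult:
    """Label-permutation FDR for the per-wavenumber t-statistics.

    Enumerates all distinct label assignments when their number is at most
    ``exhaustive_cap``; otherwise samples ``b`` assignments (plus the
    observed one) from ``seed``.
    """
    x_tumor, x_normal = _two_group_matrices(sset)
    n1, n0 = x_tumor.shape[0], x_normal.shape[0]
    n = n1 + n0
    x = np.vstack([x_tumor, x_normal])
    observed = np.zeros(n, dtype=bool)
    observed[:n1] = True
    t_obs = _tstat_columns(x, observed, welch=welch)
    if welch:
        _, p = tstat_per_wavenumber(sset, welch=True)
    else:
        p = 2.0 * stats.t.sf(np.abs(t_obs), n - 2)
    n_distinct = comb(n, n1)
    if n_distinct <= exhaustive_cap:
        assignments = _assignment_matrix_exhaustive(n, n1)
        mode = "exhaustive"
        used_seed = None
    else:
        if b < 1:
            raise ValueError("sampled mode needs B >= 1")
        rng = np.random.default_rng(seed)
        assignments = np.vstack(
            [observed, _assignment_matrix_sampled(n, n1, b, rng)]
        )
        mode = "sampled"
        used_seed = seed
    t_perm = _tstat_columns(x, assignments, welch=welch)
    q = _fdr_from_tmatrix(t_obs, t_perm)
    axis = sset.axis
    return DifferentialResult(
        axis=axis,
        t=t_obs,
        p=np.minimum(p, 1.0),
        q=q,
        n_tumor=n1,
        n_normal=n0,
        n_permutations=assignments.shape[0],
        permutation_mode=mode,
        seed=used_seed,
    )


def summarize_bands(
    result: DifferentialResult, bands: BandTable, alpha: float = 0.05
) -> pd.DataFrame:
    """Band-window roll-up of the per-wavenumber q-values.

    A window is "elevated in tumor" when at least half of its wavenumbers
    reach q < alpha with positive (tumor minus normal) t.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    rows = []
    for lo, hi, assignment in bands:
        inside = (result.axis >= lo) & (result.axis <= hi)
        if not inside.any():
            import warnings

            warnings.warn(
                f"band [{lo}, {hi}] lies outside the result axis; skipped",
                stacklevel=2,
            )
            continue
        q = result.q[inside]
        t = result.t[inside]
        frac_pass = float(np.mean((q < alpha) & (t > 0)))
        rows.append(
            {
                "lo": lo,
                "hi": hi,
                "assignment": assignment,
                "n_wavenumbers": int(inside.sum()),
                "frac_significant_positive": frac_pass,
                "mean_t": float(t.mean()),
                "elevated_in_tumor": frac_pass >= 0.5,
            }
        )
    return pd.DataFrame(rows)
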