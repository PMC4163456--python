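"""PCA scores and per-cluster covariance ellipsoids.

The decomposition is the thin SVD of the column-centered matrix, which is
numerically preferable to an eigendecomposition of the covariance when the
axis is much longer than the number of spectra. The sign convention makes
each loading's largest-magnitude element positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectra_io import Label, SpectrumSet

__all__ = ["PCAResult", "ClusterEllipsoid", "pca", "cluster_ellipsoids"]


@dataclass
class PCAResult:
    loadings: np.ndarray  # k x p, orthonormal rows
    scores: np.ndarray  # n x k
    explained_variance: np.ndarray  # k, descending
    center: np.ndarray  # p


@dataclass
class ClusterEllipsoid:
    label: Label
    center: np.ndarray  # 3
    covariance: np.ndarray  # 3 x 3
    scale: str = "1sd"  # 1sd | 95pct

    @property
    def axis_factor(self) -> float:
        if self.scale == "95pct":
            return float(np.sqrt(stats.chi2.ppf(0.95, df=3)))
        return 1.0

    def semi_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """(lengths, directions): eigen-decomposition scaled per the rule."""
        vals, vecs = np.linalg.eigh(self.covariance)
        vals = np.maximum(vals, 0.0)
        return np.sqrt(vals)[::-1] * self.axis_factor, vecs[:, ::-1]


def pca(data: SpectrumSet | np.ndarray, k: int = 3) -> PCAResult:
    """First ``k`` principal components of the centered spectrum matrix."""
    x = data.matrix if isinstance(data, SpectrumSet) else np.asarray(data, float)
    n, p = x.shape
    if not (1 <= k <= min(n, p)):
        raise ValueError(f"k must lie in [1, {min(n, p)}] for a {n} x {p} matrix")
    center = x.mean(axis=0)
    u, s, vt = np.linalg.svd(x - center, full_matrices=False)
    # sign convention: largest-|.| element of each loading is positive
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    scores = u * s
    explained = s**2 / max(n - 1, 1)
    return PCAResult(
        loadings=vt[:k].copy(),
        scores=scores[:, :k].copy(),
        explained_variance=explained[:k].copy(),
        center=center,
    )


def cluster_ellipsoids(
    result: PCAResult,
    labels: np.ndarray | list,
    scale: str = "1sd",
    which: tuple[str, ...] = (Label.TUMOR.value, Label.NORMAL.value),
) -> list[ClusterEllipsoid]:
    """Mean and covariance of the first three score coordinates per cluster."""
    if result.scores.shape[1] < 3:
        raise ValueError("ellipsoids need at least 3 principal components")
    if scale not in ("1sd", "95pct"):
        raise ValueError(f"unknown ellipsoid scale {scale!r}")
    labels = np.asarray([l.value if isinstance(l, Label) else str(l) for l in labels])
    if labels.size != result.scores.shape[0]:
        raise ValueError("labels must match the number of score rows")
    ellipsoids = []
    for value in which:
        members = result.scores[labels == value, :3]
        if members.shape[0] == 0:
            continue
        if members.shape[0] < 4:
            raise ValueError(
                f"cluster {value!r} has {members.shape[0]} members; need >= 4"
            )
        ellipsoids.append(
            ClusterEllipsoid(
                label=Label.parse(value),
                center=members.mean(axis=0),
                covariance=np.cov(members, rowvar=False),
                scale=scale,
            )
        )
    return ellipsoids
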