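"""Band-intensity chemical mapping of gridded spectra.

A map is built by integrating one band window per spectrum (trapezoidal
rule on the native axis, with interpolated window endpoints) and arranging
the values on the stage grid inferred from the x/y coordinates: origin at
the minimum coordinate, row-major layout with y as the outer axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .spectra_io import Label, Spectrum, SpectrumSet

__all__ = [
    "ChemicalMap",
    "DEFAULT_LIPID_BAND",
    "band_intensity",
    "build_chemical_map",
    "threshold_map",
]

#: C-H2 lipid band; the documented alternative is the 1050-1100 lipid window
DEFAULT_LIPID_BAND = (1440.0, 1460.0)


@dataclass
class ChemicalMap:
    nx: int
    ny: int
    step_um: float
    values: np.ndarray  # ny x nx
    band: tuple[float, float]
    mask: np.ndarray | None = None  # ny x nx label strings

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.ny, self.nx):
            raise ValueError("values shape must be (ny, nx)")
        if self.step_um <= 0:
            raise ValueError("step_um must be positive")
        if self.mask is not None and np.shape(self.mask) != (self.ny, self.nx):
            raise ValueError("mask shape must be (ny, nx)")


def band_intensity(s: Spectrum, band: tuple[float, float]) -> float:
    """Trapezoidal integral of intensity over the closed window [lo, hi].

    Single-position bands (lo == hi) return the linearly interpolated
    intensity at that Raman shift.
    """
    lo, hi = float(band[0]), float(band[1])
    if lo > hi:
        raise ValueError("band window must satisfy lo <= hi")
    w, y = s.wavenumbers, s.intensities
    if lo < w[0] or hi > w[-1]:
        raise ValueError(f"band [{lo}, {hi}] lies outside the axis [{w[0]}, {w[-1]}]")
    if lo == hi:
        return float(np.interp(lo, w, y))
    inside = (w > lo) & (w < hi)
    nodes = np.concatenate(([lo], w[inside], [hi]))
    values = np.concatenate(
        ([np.interp(lo, w, y)], y[inside], [np.interp(hi, w, y)])
    )
    return float(np.trapezoid(values, nodes))


def _grid_positions(coords: np.ndarray, step: float, what: str) -> np.ndarray:
    """Snap coordinates to integer grid indices; error when off-grid."""
    origin = coords.min()
    idx = (coords - origin) / step
    snapped = np.rint(idx)
    if np.any(np.abs(idx - snapped) > 0.01):
        bad = np.flatnonzero(np.abs(idx - snapped) > 0.01)[:5]
        raise ValueError(
            f"{what} coordinates not aligned to the grid at rows {bad.tolist()}"
        )
    return snapped.astype(int)


def build_chemical_map(
    sset: SpectrumSet, band: tuple[float, float] = DEFAULT_LIPID_BAND
) -> ChemicalMap:
    """Arrange per-spectrum band intensities on the stage grid.

    Placement uses coordinates, not input order; the grid must be complete
    (every node present exactly once, tolerance 1% of the step).
    """
    xs = np.array([m.x_um for m in sset.metas], dtype=object)
    ys = np.array([m.y_um for m in sset.metas], dtype=object)
    if any(v is None for v in xs) or any(v is None for v in ys):
        raise ValueError("all spectra need x_um/y_um stage coordinates")
    xs = xs.astype(float)
    ys = ys.astype(float)
    ux, uy = np.unique(xs), np.unique(ys)

    def _step(u: np.ndarray) -> float | None:
        return float(np.median(np.diff(u))) if u.size > 1 else None

    steps = [v for v in (_step(ux), _step(uy)) if v is not None]
    step = float(np.median(steps)) if steps else 1.0
    ix = _grid_positions(xs, step, "x") if ux.size > 1 else np.zeros(xs.size, int)
    iy = _grid_positions(ys, step, "y") if uy.size > 1 else np.zeros(ys.size, int)
    nx, ny = ix.max() + 1, iy.max() + 1
    if sset.n_spectra != nx * ny:
        raise ValueError(
            f"incomplete grid: {sset.n_spectra} spectra for a {nx} x {ny} raster"
        )
    values = np.full((ny, nx), np.nan)
    mask = np.empty((ny, nx), dtype=object)
    spectra = sset.to_spectra()
    for s, i, j in zip(spectra, ix, iy):
        if not np.isnan(values[j, i]):
            raise ValueError(f"duplicate grid node at index ({j}, {i})")
        values[j, i] = band_intensity(s, band)
        mask[j, i] = s.meta.label.value
    if np.isnan(values).any():
        missing = [tuple(t) for t in np.argwhere(np.isnan(values))[:5]]
        raise ValueError(f"missing grid nodes at (row, col) {missing}")
    all_unknown = all(m.label == Label.UNKNOWN for m in sset.metas)
    return ChemicalMap(
        nx=int(nx),
        ny=int(ny),
        step_um=step,
        values=values,
        band=(float(band[0]), float(band[1])),
        mask=None if all_unknown else mask,
    )


def _otsu_threshold(values: np.ndarray) -> float:
    """Threshold maximizing between-class variance; calls are value > t."""
    flat = np.sort(values.ravel())
    candidates = np.unique(flat)[:-1]  # highest level cannot be a split
    if candidates.size == 0:
        raise ValueError("Otsu thresholding needs a non-constant map")
    n = flat.size
    best_t, best_v = candidates[0], -np.inf
    for t in candidates:
        upper = flat > t
        n1 = int(upper.sum())
        n0 = n - n1
        m1, m0 = flat[upper].mean(), flat[~upper].mean()
        v = (n0 / n) * (n1 / n) * (m1 - m0) ** 2
        if v > best_v + 1e-15:
            best_v, best_t = v, t
    return float(best_t)


def threshold_map(
    cmap: ChemicalMap, rule: str = "otsu", q: float = 0.5
) -> tuple[np.ndarray, dict | None]:
    """Binary tumor-call image plus pixel metrics when a mask is present.

    ``otsu`` maximizes between-class variance; ``quantile`` calls the top
    ``ceil(n * (1 - q))`` pixels positive, ties broken by row-major index.
    Borderline/unknown pixels are excluded from the metrics.
    """
    values = cmap.values
    n = values.size
    if rule == "otsu":
        binary = values > _otsu_threshold(values)
    elif rule == "quantile":
        if not (0.0 < q < 1.0):
            raise ValueError("quantile q must lie in (0, 1)")
        m = ceil(n * (1.0 - q))
        flat = values.ravel()
        order = np.lexsort((np.arange(n), -flat))  # by value desc, then index
        binary = np.zeros(n, dtype=bool)
        binary[order[:m]] = True
        binary = binary.reshape(values.shape)
    else:
        raise ValueError(f"unknown thresholding rule {rule!r}")
    metrics = None
    if cmap.mask is not None:
        mask = np.asarray(cmap.mask)
        tumor = mask == Label.TUMOR.value
        normal = mask == Label.NORMAL.value
        tp = int((binary & tumor).sum())
        fn = int((~binary & tumor).sum())
        fp = int((binary & normal).sum())
        tn = int((~binary & normal).sum())
        metrics = {
            "tp": tp,
            "fn": fn,
            "fp": fp,
            "tn": tn,
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        }
    return binary, metrics
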