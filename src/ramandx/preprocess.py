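"""Spectral preprocessing chain.

Order of the full chain: cosmic-ray removal -> background subtraction ->
reference-band (phenylalanine, ~1004 cm^-1) normalization -> fingerprint
crop -> optional resampling -> standardization. Each step is also exposed
on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .spectra_io import Spectrum, SpectrumSet

__all__ = [
    "PreprocessConfig",
    "PreprocessError",
    "remove_cosmic_rays",
    "subtract_background",
    "normalize_phenylalanine",
    "filter_fingerprint",
    "resample_to_grid",
    "standardize",
    "preprocess_spectra",
]

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    despike_window: int = 7  # points, odd
    despike_z: float = 8.0  # MAD units
    despike_rel_floor: float = 0.005  # noise floor as fraction of dynamic range
    baseline_mode: str = "iterative_poly"  # reference_subtract | iterative_poly | als
    poly_order: int = 5
    poly_max_iter: int = 100
    als_lambda: float = 1e5
    als_p: float = 0.01
    als_max_iter: int = 10
    phe_center: float = 1004.0
    phe_halfwidth: float = 5.0
    fingerprint: tuple[float, float] = (580.0, 1800.0)
    standardize_mode: str = "per_spectrum"  # per_spectrum | per_wavenumber | none

    def __post_init__(self) -> None:
        if self.despike_window < 3 or self.despike_window % 2 == 0:
            raise PreprocessError("despike_window must be odd and >= 3")
        if self.phe_halfwidth <= 0:
            raise PreprocessError("phe_halfwidth must be positive")
        if self.fingerprint[0] >= self.fingerprint[1]:
            raise PreprocessError("fingerprint window must satisfy lo < hi")
        if self.baseline_mode not in ("reference_subtract", "iterative_poly", "als"):
            raise PreprocessError(f"unknown baseline_mode {self.baseline_mode!r}")
        if self.standardize_mode not in ("per_spectrum", "per_wavenumber", "none"):
            raise PreprocessError(f"unknown standardize_mode {self.standardize_mode!r}")


def _running_median(y: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    padded = np.pad(y, half, mode="edge")
    view = np.lib.stride_tricks.sliding_window_view(padded, window)
    return np.median(view, axis=1)


def remove_cosmic_rays(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Replace narrow high outliers from a running-median fit by interpolation.

    Points whose residual from the running median exceeds ``despike_z``
    robust standard deviations (1.4826 * MAD, floored at a small fraction
    of the spectrum's dynamic range so noiseless smooth spectra are left
    alone) are flagged; runs longer than ``despike_window`` are treated as
    genuine features, not spikes.
    """
    cfg = cfg or PreprocessConfig()
    y = s.intensities
    if y.size <= cfg.despike_window:
        raise PreprocessError("spectrum shorter than the despike window")
    med = _running_median(y, cfg.despike_window)
    resid = y - med
    sigma = 1.4826 * np.median(np.abs(resid))
    dynamic = float(np.max(y) - np.min(y))
    sigma = max(sigma, cfg.despike_rel_floor * dynamic, 1e-300)
    flagged = resid > cfg.despike_z * sigma  # cosmic rays are positive spikes
    if not flagged.any():
        return s.with_intensities(y.copy())
    # ignore runs longer than the window: too wide to be a detector hit
    runs = np.flatnonzero(np.diff(np.concatenate(([0], flagged.view(np.int8), [0]))))
    for start, stop in zip(runs[::2], runs[1::2]):
        if stop - start > cfg.despike_window:
            flagged[start:stop] = False
    if flagged.all():
        raise PreprocessError("every point flagged as a spike; degenerate spectrum")
    if not flagged.any():
        return s.with_intensities(y.copy())
    good = ~flagged
    cleaned = y.copy()
    cleaned[flagged] = np.interp(
        s.wavenumbers[flagged], s.wavenumbers[good], y[good]
    )
    return s.with_intensities(cleaned)


def _iterative_poly_baseline(
    w: np.ndarray, y: np.ndarray, order: int, max_iter: int
) -> np.ndarray:
    """Modified-polyfit baseline: refit with peak points clipped to the fit."""
    u = (w - w[0]) / (w[-1] - w[0]) * 2.0 - 1.0  # conditioning
    work = y.copy()
    prev_above = None
    fit = np.polynomial.polynomial.polyval(
        u, np.polynomial.polynomial.polyfit(u, work, order)
    )
    for _ in range(max_iter):
        above = work > fit
        work = np.minimum(work, fit)
        fit = np.polynomial.polynomial.polyval(
            u, np.polynomial.polynomial.polyfit(u, work, order)
        )
        if prev_above is not None and np.array_equal(above, prev_above):
            break
        prev_above = above
    return fit


def _als_baseline(
    y: np.ndarray, lam: float, p: float, max_iter: int
) -> np.ndarray:
    """Asymmetric least squares baseline (second-difference penalty)."""
    n = y.size
    d = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    penalty = lam * (d.T @ d)
    weights = np.ones(n)
    z = y.copy()
    for _ in range(max_iter):
        w_mat = sp.diags(weights)
        z = spla.spsolve((w_mat + penalty).tocsc(), weights * y)
        weights = np.where(y > z, p, 1.0 - p)
    return z


def subtract_background(
    s: Spectrum,
    cfg: PreprocessConfig | None = None,
    reference: Spectrum | None = None,
) -> Spectrum:
    """Remove the background by reference subtraction or baseline estimation.

    Output is not clipped: small negative intensities are expected.
    """
    cfg = cfg or PreprocessConfig()
    if cfg.baseline_mode == "reference_subtract":
        if reference is None:
            raise PreprocessError("reference_subtract mode needs a reference spectrum")
        if reference.wavenumbers.shape != s.wavenumbers.shape or not np.allclose(
            reference.wavenumbers, s.wavenumbers
        ):
            raise PreprocessError("reference spectrum is on a different axis")
        return s.with_intensities(s.intensities - reference.intensities)
    if cfg.baseline_mode == "iterative_poly":
        baseline = _iterative_poly_baseline(
            s.wavenumbers, s.intensities, cfg.poly_order, cfg.poly_max_iter
        )
    else:
        baseline = _als_baseline(
            s.intensities, cfg.als_lambda, cfg.als_p, cfg.als_max_iter
        )
    return s.with_intensities(s.intensities - baseline)


def estimate_baseline(s: Spectrum, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """The baseline that :func:`subtract_background` would remove."""
    cfg = cfg or PreprocessConfig()
    if cfg.baseline_mode == "iterative_poly":
        return _iterative_poly_baseline(
            s.wavenumbers, s.intensities, cfg.poly_order, cfg.poly_max_iter
        )
    if cfg.baseline_mode == "als":
        return _als_baseline(s.intensities, cfg.als_lambda, cfg.als_p, cfg.als_max_iter)
    raise PreprocessError("no baseline estimate in reference_subtract mode")


def normalize_phenylalanine(
    s: Spectrum, cfg: PreprocessConfig | None = None
) -> Spectrum:
    """Divide by the maximum intensity within the reference-band window."""
    cfg = cfg or PreprocessConfig()
    lo, hi = cfg.phe_center - cfg.phe_halfwidth, cfg.phe_center + cfg.phe_halfwidth
    if s.wavenumbers[0] > lo or s.wavenumbers[-1] < hi:
        raise PreprocessError(
            f"axis does not cover the reference window [{lo}, {hi}] cm^-1"
        )
    window = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    peak = float(np.max(s.intensities[window]))
    if peak <= 0:
        raise PreprocessError("reference-band maximum is non-positive")
    return s.with_intensities(s.intensities / peak)


def filter_fingerprint(
    spectra: Sequence[Spectrum] | SpectrumSet, cfg: PreprocessConfig | None = None
) -> list[Spectrum]:
    """Drop spectra not covering the fingerprint range; crop survivors to it."""
    cfg = cfg or PreprocessConfig()
    lo, hi = cfg.fingerprint
    if isinstance(spectra, SpectrumSet):
        spectra = spectra.to_spectra()
    kept = []
    for s in spectra:
        if s.wavenumbers[0] <= lo and s.wavenumbers[-1] >= hi:
            kept.append(s.crop(lo, hi))
    dropped = len(spectra) - len(kept)
    if dropped:
        logger.info("fingerprint filter dropped %d of %d spectra", dropped, len(spectra))
    if not kept:
        logger.warning("fingerprint filter removed every spectrum")
    return kept


def resample_to_grid(
    spectra: Sequence[Spectrum] | SpectrumSet, grid: np.ndarray
) -> SpectrumSet:
    """Linearly interpolate every spectrum onto ``grid`` (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    if isinstance(spectra, SpectrumSet):
        spectra = spectra.to_spectra()
    rows = []
    for s in spectra:
        if s.wavenumbers[0] > grid[0] or s.wavenumbers[-1] < grid[-1]:
            raise PreprocessError(
                f"spectrum {s.meta.spectrum_id!r} does not span the target grid"
            )
        rows.append(np.interp(grid, s.wavenumbers, s.intensities))
    return SpectrumSet(grid, np.vstack(rows), [replace(s.meta) for s in spectra])


def standardize(sset: SpectrumSet, cfg: PreprocessConfig | None = None) -> SpectrumSet:
    """Zero-mean unit-variance scaling (sd with the n-1 denominator).

    ``per_spectrum`` scales each row across wavenumbers (SNV);
    ``per_wavenumber`` scales each column across spectra (autoscaling).
    """
    cfg = cfg or PreprocessConfig()
    x = sset.matrix
    if cfg.standardize_mode == "none":
        return SpectrumSet(sset.axis.copy(), x.copy(), [replace(m) for m in sset.metas])
    if cfg.standardize_mode == "per_spectrum":
        mean = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        zero = np.flatnonzero(sd.ravel() == 0)
        if zero.size:
            raise PreprocessError(
                f"constant spectrum cannot be standardized: "
                f"{sset.metas[zero[0]].spectrum_id!r}"
            )
    else:
        if sset.n_spectra < 2:
            raise PreprocessError("per_wavenumber standardization needs n >= 2")
        mean = x.mean(axis=0, keepdims=True)
        sd = x.std(axis=0, ddof=1, keepdims=True)
        zero = np.flatnonzero(sd.ravel() == 0)
        if zero.size:
            raise PreprocessError(
                f"zero-variance column at {sset.axis[zero[0]]} cm^-1"
            )
    return SpectrumSet(
        sset.axis.copy(), (x - mean) / sd, [replace(m) for m in sset.metas]
    )


def preprocess_spectra(
    spectra: Sequence[Spectrum] | SpectrumSet,
    cfg: PreprocessConfig | None = None,
    reference: Spectrum | None = None,
    grid: np.ndarray | None = None,
) -> SpectrumSet:
    """Run the full chain and assemble the result on a shared grid."""
    cfg = cfg or PreprocessConfig()
    if isinstance(spectra, SpectrumSet):
        spectra = spectra.to_spectra()
    cleaned = [
        normalize_phenylalanine(
            subtract_background(remove_cosmic_rays(s, cfg), cfg, reference), cfg
        )
        for s in spectra
    ]
    kept = filter_fingerprint(cleaned, cfg)
    if not kept:
        raise PreprocessError("no spectra survive the fingerprint filter")
    if grid is None:
        grid = kept[0].wavenumbers
    sset = resample_to_grid(kept, grid)
    return standardize(sset, cfg)
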