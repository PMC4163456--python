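"""Synthetic Raman spectrum generator.

Builds spectra as a sum of pseudo-Voigt band components on a smooth
autofluorescence-like baseline, with Gaussian noise, sparse cosmic-ray
spikes, and a per-sample multiplicative (lognormal) amplitude effect that
induces within-sample correlation. Tumor-class spectra multiply selected
band amplitudes by a configurable effect factor; borderline spectra sit at
the geometric mean of tumor and normal amplitudes.

Default experiment designs mirror the acquisition layouts the pipeline is
meant to analyse: 58 tumor-cell spectra from 4 cells vs 40 normal spectra
from 2 cells; 123 tissue spectra from 6 mice; and a 12 x 22 stage map at a
300 um step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .spectra_io import Label, Spectrum, SpectrumMeta, SpectrumSet, default_band_table

__all__ = [
    "BandComponent",
    "GenerativeConfig",
    "SampleRecord",
    "ExperimentDesign",
    "EllipseRegion",
    "default_bands",
    "default_config",
    "default_cell_design",
    "default_tissue_design",
    "simulate_spectrum",
    "simulate_cell_experiment",
    "simulate_tissue_experiment",
    "simulate_map",
]

#: reference band left untouched by the tumor effect (normalization anchor)
REFERENCE_CENTER = 1004.0


@dataclass
class BandComponent:
    """One spectral band: position, FWHM, base amplitude and tumor effect."""

    center: float
    width: float  # FWHM, cm^-1
    amplitude_normal: float
    tumor_effect: float = 1.0
    shape: str = "pseudo_voigt"
    eta: float = 0.5  # Lorentzian fraction for pseudo-Voigt

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude_normal < 0:
            raise ValueError("amplitude_normal must be >= 0")
        if self.tumor_effect < 0:
            raise ValueError("tumor_effect must be >= 0")
        if self.shape not in ("gaussian", "lorentzian", "pseudo_voigt"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        """Unit-peak-height line shape evaluated on ``axis``."""
        u = (axis - self.center) / self.width
        gauss = np.exp(-4.0 * np.log(2.0) * u**2)
        lorentz = 1.0 / (1.0 + 4.0 * u**2)
        if self.shape == "gaussian":
            return gauss
        if self.shape == "lorentzian":
            return lorentz
        return self.eta * lorentz + (1.0 - self.eta) * gauss


def default_bands(tumor_effect: float = 1.5, fwhm: float = 15.0) -> list[BandComponent]:
    """One component per packaged band-table row.

    Range windows become a single component centred at the midpoint whose
    FWHM spans the window; the 1004 cm^-1 reference band keeps effect 1.
    """
    bands = []
    for lo, hi, assignment in default_band_table():
        center = 0.5 * (lo + hi)
        width = max(hi - lo, fwhm)
        effect = 1.0 if center == REFERENCE_CENTER else tumor_effect
        amplitude = 2.0 if center == REFERENCE_CENTER else 1.0
        bands.append(
            BandComponent(
                center=center,
                width=width,
                amplitude_normal=amplitude,
                tumor_effect=effect,
            )
        )
    return bands


@dataclass
class GenerativeConfig:
    """All knobs of the generative model, plus the master seed."""

    bands: list[BandComponent] = field(default_factory=default_bands)
    baseline_coeffs: tuple[float, ...] = (10.0, 2.0, 1.0)  # quadratic in u=(v-lo)/(hi-lo)
    noise_sd: float = 0.05
    cosmic_rate: float = 0.05  # expected spikes per spectrum
    cosmic_amplitude: float = 50.0  # in multiples of noise_sd
    group_sd: float = 0.1  # between-sample log-amplitude jitter
    seed: int = 0
    axis_lo: float = 580.0
    axis_hi: float = 1800.0
    axis_step: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.cosmic_rate < 0 or self.group_sd < 0:
            raise ValueError("noise_sd, cosmic_rate and group_sd must be >= 0")
        if self.axis_step <= 0 or self.axis_hi <= self.axis_lo:
            raise ValueError("axis must satisfy lo < hi with positive step")

    @property
    def axis(self) -> np.ndarray:
        n = int(round((self.axis_hi - self.axis_lo) / self.axis_step)) + 1
        return self.axis_lo + self.axis_step * np.arange(n)

    def baseline(self, axis: np.ndarray) -> np.ndarray:
        u = (axis - self.axis_lo) / (self.axis_hi - self.axis_lo)
        return np.polynomial.polynomial.polyval(u, self.baseline_coeffs)


def default_config(tumor_effect: float = 1.5, **kwargs) -> GenerativeConfig:
    return GenerativeConfig(bands=default_bands(tumor_effect=tumor_effect), **kwargs)


@dataclass
class SampleRecord:
    sample_id: str
    label: Label
    n_spectra: int

    def __post_init__(self) -> None:
        if not isinstance(self.label, Label):
            self.label = Label.parse(str(self.label))
        if self.n_spectra < 1:
            raise ValueError("each sample record needs n_spectra >= 1")


@dataclass
class ExperimentDesign:
    """Per-sample spectrum counts; one sample may carry several classes."""

    records: list[SampleRecord]

    @property
    def n_spectra(self) -> int:
        return sum(r.n_spectra for r in self.records)

    @property
    def sample_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            if r.sample_id not in seen:
                seen.append(r.sample_id)
        return seen


def default_cell_design() -> ExperimentDesign:
    """58 tumor spectra from 4 cells and 40 normal spectra from 2 cells."""
    return ExperimentDesign(
        [
            SampleRecord("glioma_cell_1", Label.TUMOR, 15),
            SampleRecord("glioma_cell_2", Label.TUMOR, 15),
            SampleRecord("glioma_cell_3", Label.TUMOR, 14),
            SampleRecord("glioma_cell_4", Label.TUMOR, 14),
            SampleRecord("astrocyte_1", Label.NORMAL, 20),
            SampleRecord("astrocyte_2", Label.NORMAL, 20),
        ]
    )


def default_tissue_design() -> ExperimentDesign:
    """123 spectra from 6 brains, tumor and normal areas mixed per brain."""
    records = []
    counts = [21, 21, 21, 20, 20, 20]  # sums to 123
    for i, n in enumerate(counts, start=1):
        n_tumor = (n + 1) // 2
        records.append(SampleRecord(f"mouse_{i}", Label.TUMOR, n_tumor))
        records.append(SampleRecord(f"mouse_{i}", Label.NORMAL, n - n_tumor))
    return ExperimentDesign(records)


def _class_factor(band: BandComponent, label: Label, attenuation: float) -> float:
    effect = 1.0 + (band.tumor_effect - 1.0) * attenuation
    if label == Label.TUMOR:
        return effect
    if label == Label.NORMAL:
        return 1.0
    if label == Label.BORDERLINE:
        return float(np.sqrt(effect))
    raise ValueError(f"cannot simulate class {label!r}")


def clean_signal(
    label: Label, cfg: GenerativeConfig, sample_effect: float = 0.0,
    attenuation: float = 1.0,
) -> np.ndarray:
    """Deterministic part of the model: band sum plus baseline."""
    axis = cfg.axis
    signal = cfg.baseline(axis).astype(float)
    scale = float(np.exp(sample_effect))
    for band in cfg.bands:
        amp = band.amplitude_normal * _class_factor(band, label, attenuation) * scale
        signal = signal + amp * band.profile(axis)
    return signal


def simulate_spectrum(
    label: Label | str,
    cfg: GenerativeConfig,
    sample_effect: float = 0.0,
    rng: np.random.Generator | None = None,
    attenuation: float = 1.0,
    meta: SpectrumMeta | None = None,
) -> Spectrum:
    """Draw one spectrum of the given class.

    ``sample_effect`` is the sample-level log-amplitude offset;
    ``attenuation`` in (0, 1] shrinks every band's tumor effect toward 1.
    """
    label = label if isinstance(label, Label) else Label.parse(str(label))
    if not (0.0 < attenuation <= 1.0):
        raise ValueError("attenuation must lie in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    axis = cfg.axis
    y = clean_signal(label, cfg, sample_effect, attenuation)
    y = y + rng.normal(0.0, cfg.noise_sd, size=axis.size) if cfg.noise_sd > 0 else y
    n_spikes = rng.poisson(cfg.cosmic_rate) if cfg.cosmic_rate > 0 else 0
    if n_spikes:
        positions = rng.integers(0, axis.size, size=n_spikes)
        y = y.copy()
        y[positions] += cfg.cosmic_amplitude * cfg.noise_sd
    if meta is None:
        meta = SpectrumMeta(spectrum_id="spectrum", label=label)
    return Spectrum(axis, y, meta)


def _simulate_design(
    design: ExperimentDesign,
    cfg: GenerativeConfig,
    attenuation: float,
) -> SpectrumSet:
    rng = np.random.default_rng(cfg.seed)
    effects = {
        sid: (rng.normal(0.0, cfg.group_sd) if cfg.group_sd > 0 else 0.0)
        for sid in design.sample_ids
    }
    spectra = []
    counter = 0
    for record in design.records:
        for _ in range(record.n_spectra):
            meta = SpectrumMeta(
                spectrum_id=f"s{counter:04d}",
                sample_id=record.sample_id,
                label=record.label,
            )
            spectra.append(
                simulate_spectrum(
                    record.label,
                    cfg,
                    sample_effect=effects[record.sample_id],
                    rng=rng,
                    attenuation=attenuation,
                    meta=meta,
                )
            )
            counter += 1
    return SpectrumSet.from_spectra(spectra)


def simulate_cell_experiment(
    design: ExperimentDesign | None = None, cfg: GenerativeConfig | None = None
) -> SpectrumSet:
    """Simulate the single-cell acquisition design (default: 58 vs 40)."""
    design = design or default_cell_design()
    cfg = cfg or default_config()
    return _simulate_design(design, cfg, attenuation=1.0)


def simulate_tissue_experiment(
    design: ExperimentDesign | None = None,
    cfg: GenerativeConfig | None = None,
    attenuation: float = 0.5,
) -> SpectrumSet:
    """Simulate the tissue design (default: 123 spectra over 6 mice).

    ``attenuation`` in (0, 1] shrinks band effects toward 1, modelling the
    extra compositional heterogeneity of tissue spots relative to cells.
    """
    if not (0.0 < attenuation <= 1.0):
        raise ValueError("attenuation must lie in (0, 1]")
    design = design or default_tissue_design()
    cfg = cfg or default_config()
    return _simulate_design(design, cfg, attenuation)


@dataclass
class EllipseRegion:
    """Elliptical tumor region in stage coordinates (um)."""

    cx: float
    cy: float
    rx: float
    ry: float

    def __post_init__(self) -> None:
        if self.rx <= 0 or self.ry <= 0:
            raise ValueError("ellipse axes must be positive")

    def radius(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return np.sqrt(((x - self.cx) / self.rx) ** 2 + ((y - self.cy) / self.ry) ** 2)


def simulate_map(
    nx: int,
    ny: int,
    step_um: float,
    region: EllipseRegion | None,
    cfg: GenerativeConfig | None = None,
    border_frac: float = 0.25,
    attenuation: float = 1.0,
) -> tuple[SpectrumSet, np.ndarray]:
    """Simulate a raster map of ``nx * ny`` spectra at ``step_um`` spacing.

    Nodes inside ``region`` are tumor, nodes within a relative border ring
    of width ``border_frac`` are borderline, the rest normal. Returns the
    spectra (with stage coordinates) and the ny x nx ground-truth label
    mask in row-major (y outer, x inner) order. ``region=None`` means no
    tumor anywhere.
    """
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    cfg = cfg or default_config()
    rng = np.random.default_rng(cfg.seed)
    sample_effect = rng.normal(0.0, cfg.group_sd) if cfg.group_sd > 0 else 0.0
    mask = np.empty((ny, nx), dtype=object)
    spectra = []
    for j in range(ny):
        for i in range(nx):
            x, y = i * step_um, j * step_um
            if region is None:
                label = Label.NORMAL
            else:
                r = float(region.radius(np.array(x), np.array(y)))
                if r <= 1.0:
                    label = Label.TUMOR
                elif r <= 1.0 + border_frac:
                    label = Label.BORDERLINE
                else:
                    label = Label.NORMAL
            mask[j, i] = label.value
            meta = SpectrumMeta(
                spectrum_id=f"px_{j:03d}_{i:03d}",
                sample_id="map",
                label=label,
                x_um=x,
                y_um=y,
            )
            spectra.append(
                simulate_spectrum(
                    label, cfg, sample_effect=sample_effect, rng=rng,
                    attenuation=attenuation, meta=meta,
                )
            )
    return SpectrumSet.from_spectra(spectra), mask
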