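"""Plain-text I/O and core domain objects for Raman spectra.

The exchange formats are deliberately simple text files:

* two-column ASCII: one ``wavenumber intensity`` pair per line, one
  spectrum per file (whitespace or comma separated);
* matrix CSV: header row of wavenumbers, one spectrum per row, spectrum
  id in the first column;
* metadata CSV: ``spectrum_id,sample_id,label[,x_um,y_um,...]``;
* band-table CSV: ``lo,hi,assignment``.

All wavenumber axes are stored ascending internally; files written with a
descending axis are reversed on read.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Label",
    "SpectrumMeta",
    "Spectrum",
    "SpectrumSet",
    "BandTable",
    "SpectrumFormatError",
    "MetadataError",
    "read_spectrum_file",
    "read_metadata",
    "write_metadata",
    "read_band_table",
    "default_band_table",
    "write_spectrumset",
    "read_spectrumset",
]


class SpectrumFormatError(ValueError):
    """Raised when a spectrum file or object violates the format contract."""


class MetadataError(ValueError):
    """Raised when per-spectrum metadata is malformed."""


class Label(str, Enum):
    TUMOR = "tumor"
    NORMAL = "normal"
    BORDERLINE = "borderline"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, value: str) -> "Label":
        try:
            return cls(value)
        except ValueError:
            allowed = ", ".join(m.value for m in cls)
            raise MetadataError(
                f"invalid label {value!r}; allowed values: {allowed}"
            ) from None


@dataclass
class SpectrumMeta:
    """Per-spectrum annotations: provenance, class label, stage position."""

    spectrum_id: str
    sample_id: str = ""
    label: Label = Label.UNKNOWN
    x_um: float | None = None
    y_um: float | None = None
    acquisition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.label, Label):
            self.label = Label.parse(str(self.label))


def _validate_axis(wavenumbers: np.ndarray) -> np.ndarray:
    w = np.asarray(wavenumbers, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise SpectrumFormatError("wavenumber axis must be 1-D with length >= 2")
    if not np.all(np.diff(w) > 0):
        raise SpectrumFormatError("wavenumber axis must be strictly increasing")
    return w


@dataclass
class Spectrum:
    """A single spectrum: intensities on a strictly increasing axis (cm^-1)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: SpectrumMeta = field(default_factory=lambda: SpectrumMeta("spectrum"))

    def __post_init__(self) -> None:
        self.wavenumbers = _validate_axis(self.wavenumbers)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != self.wavenumbers.shape:
            raise SpectrumFormatError(
                "intensities and wavenumbers must have the same length"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise SpectrumFormatError("intensities contain non-finite values")

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return Spectrum(self.wavenumbers.copy(), intensities, replace(self.meta))

    def crop(self, lo: float, hi: float) -> "Spectrum":
        """Restrict to the closed interval [lo, hi]."""
        keep = (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        return Spectrum(self.wavenumbers[keep], self.intensities[keep], replace(self.meta))


@dataclass
class SpectrumSet:
    """Spectra sharing one wavenumber axis, with aligned metadata rows."""

    axis: np.ndarray
    matrix: np.ndarray
    metas: list[SpectrumMeta]

    def __post_init__(self) -> None:
        self.axis = _validate_axis(self.axis)
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.size == 0:
            self.matrix = self.matrix.reshape(0, self.axis.size)
        if self.matrix.shape[1] != self.axis.size:
            raise SpectrumFormatError("matrix columns must match the axis length")
        if self.matrix.shape[0] != len(self.metas):
            raise SpectrumFormatError("number of metadata rows must match spectra")
        ids = [m.spectrum_id for m in self.metas]
        if len(set(ids)) != len(ids):
            raise MetadataError("spectrum_id values must be unique within a set")

    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    @property
    def labels(self) -> np.ndarray:
        return np.array([m.label.value for m in self.metas])

    @property
    def sample_ids(self) -> np.ndarray:
        return np.array([m.sample_id for m in self.metas])

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectrumSet":
        if not spectra:
            raise SpectrumFormatError("cannot build a SpectrumSet from zero spectra")
        axis = spectra[0].wavenumbers
        for s in spectra[1:]:
            if s.wavenumbers.shape != axis.shape or not np.allclose(
                s.wavenumbers, axis
            ):
                raise SpectrumFormatError(
                    f"spectrum {s.meta.spectrum_id!r} is not on the shared axis"
                )
        matrix = np.vstack([s.intensities for s in spectra])
        return cls(axis.copy(), matrix, [replace(s.meta) for s in spectra])

    def to_spectra(self) -> list[Spectrum]:
        return [
            Spectrum(self.axis.copy(), self.matrix[i].copy(), replace(self.metas[i]))
            for i in range(self.n_spectra)
        ]

    def subset(self, mask: np.ndarray) -> "SpectrumSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectrumSet(
            self.axis.copy(),
            self.matrix[idx].copy(),
            [replace(self.metas[i]) for i in idx],
        )


@dataclass
class BandTable:
    """Raman-shift windows mapped to chemical assignments.

    Single-position bands are stored with ``lo == hi``; all windows are
    closed intervals in cm^-1.
    """

    lo: np.ndarray
    hi: np.ndarray
    assignment: list[str]

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        if self.lo.shape != self.hi.shape or len(self.assignment) != self.lo.size:
            raise SpectrumFormatError("band table columns must have equal length")
        if np.any(self.lo > self.hi):
            bad = int(np.argmax(self.lo > self.hi))
            raise SpectrumFormatError(
                f"band row {bad}: lo={self.lo[bad]} exceeds hi={self.hi[bad]}"
            )
        if np.any(self.lo < 400) or np.any(self.hi > 2000):
            raise SpectrumFormatError("band bounds must lie within [400, 2000] cm^-1")

    def __len__(self) -> int:
        return self.lo.size

    def __iter__(self):
        return iter(zip(self.lo, self.hi, self.assignment))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lo": self.lo, "hi": self.hi, "assignment": self.assignment}
        )


# ---------------------------------------------------------------------------
# readers / writers


def _ensure_ascending(w: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if w.size >= 2 and w[0] > w[-1]:
        return w[::-1].copy(), y[..., ::-1].copy()
    return w, y


def read_spectrum_file(path: str | Path, dialect: str = "two_column") -> SpectrumSet:
    """Read spectra from a plain-text file into a :class:`SpectrumSet`.

    ``two_column`` files hold one spectrum; ``matrix_csv`` files hold one
    spectrum per row with the wavenumber axis in the header. Files written
    with a descending axis are normalised to ascending order.
    """
    path = Path(path)
    if dialect == "two_column":
        w: list[float] = []
        y: list[float] = []
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.replace(",", " ").split()
                try:
                    wv, iv = float(parts[0]), float(parts[1])
                except (IndexError, ValueError):
                    raise SpectrumFormatError(
                        f"{path}: malformed numeric field on line {lineno}: {line!r}"
                    ) from None
                w.append(wv)
                y.append(iv)
        wa, ya = _ensure_ascending(np.array(w), np.array(y))
        meta = SpectrumMeta(spectrum_id=path.stem)
        spectrum = Spectrum(wa, ya, meta)
        return SpectrumSet(spectrum.wavenumbers, spectrum.intensities[None, :], [meta])

    if dialect == "matrix_csv":
        frame = pd.read_csv(path, index_col=0)
        try:
            axis = frame.columns.to_numpy(dtype=float)
        except ValueError as exc:
            raise SpectrumFormatError(
                f"{path}: header must contain numeric wavenumbers ({exc})"
            ) from None
        matrix = frame.to_numpy(dtype=float)
        axis, matrix = _ensure_ascending(axis, matrix)
        if not np.all(np.diff(axis) > 0):
            raise SpectrumFormatError(f"{path}: wavenumber axis is not monotone")
        metas = [SpectrumMeta(spectrum_id=str(i)) for i in frame.index]
        return SpectrumSet(axis, matrix, metas)

    raise ValueError(f"unknown dialect {dialect!r}")


_META_CORE = ("spectrum_id", "sample_id", "label", "x_um", "y_um")


def read_metadata(path: str | Path) -> list[SpectrumMeta]:
    """Read per-spectrum metadata; extra columns land in ``acquisition``."""
    frame = pd.read_csv(path, dtype={"spectrum_id": str, "sample_id": str})
    for col in ("spectrum_id", "sample_id", "label"):
        if col not in frame.columns:
            raise MetadataError(f"metadata is missing required column {col!r}")
    if frame["spectrum_id"].duplicated().any():
        dupes = frame.loc[frame["spectrum_id"].duplicated(), "spectrum_id"].tolist()
        raise MetadataError(f"duplicate spectrum_id values: {dupes}")
    extra = [c for c in frame.columns if c not in _META_CORE]
    metas = []
    for _, row in frame.iterrows():
        def _coord(key: str) -> float | None:
            if key not in frame.columns or pd.isna(row[key]):
                return None
            return float(row[key])

        metas.append(
            SpectrumMeta(
                spectrum_id=str(row["spectrum_id"]),
                sample_id=str(row["sample_id"]),
                label=Label.parse(str(row["label"])),
                x_um=_coord("x_um"),
                y_um=_coord("y_um"),
                acquisition={
                    c: row[c] for c in extra if not pd.isna(row[c])
                },
            )
        )
    return metas


def _fmt(v: float) -> str:
    return format(float(v), ".17g")


def write_metadata(metas: Iterable[SpectrumMeta], path: str | Path) -> None:
    metas = list(metas)
    extra_keys: list[str] = []
    for m in metas:
        for k in m.acquisition:
            if k not in extra_keys:
                extra_keys.append(k)
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_META_CORE) + extra_keys)
        for m in metas:
            writer.writerow(
                [
                    m.spectrum_id,
                    m.sample_id,
                    m.label.value,
                    "" if m.x_um is None else _fmt(m.x_um),
                    "" if m.y_um is None else _fmt(m.y_um),
                ]
                + [m.acquisition.get(k, "") for k in extra_keys]
            )


def read_band_table(path: str | Path) -> BandTable:
    frame = pd.read_csv(path)
    for col in ("lo", "hi", "assignment"):
        if col not in frame.columns:
            raise SpectrumFormatError(f"band table is missing column {col!r}")
    return BandTable(
        frame["lo"].to_numpy(dtype=float),
        frame["hi"].to_numpy(dtype=float),
        [str(a) for a in frame["assignment"]],
    )


def default_band_table() -> BandTable:
    """The packaged band-assignment table (fingerprint-region windows)."""
    with resources.as_file(
        resources.files("ramandx.data").joinpath("band_table.csv")
    ) as p:
        return read_band_table(p)


def write_spectrumset(
    sset: SpectrumSet, spectra_path: str | Path, meta_path: str | Path
) -> None:
    """Write a set as matrix CSV plus metadata CSV (joined on spectrum_id)."""
    with Path(spectra_path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["spectrum_id"] + [_fmt(w) for w in sset.axis])
        for meta, row in zip(sset.metas, sset.matrix):
            writer.writerow([meta.spectrum_id] + [_fmt(v) for v in row])
    write_metadata(sset.metas, meta_path)


def read_spectrumset(
    spectra_path: str | Path, meta_path: str | Path | None = None
) -> SpectrumSet:
    """Read a matrix CSV and (optionally) join its metadata CSV."""
    sset = read_spectrum_file(spectra_path, dialect="matrix_csv")
    if meta_path is None:
        return sset
    by_id = {m.spectrum_id: m for m in read_metadata(meta_path)}
    metas = []
    for m in sset.metas:
        if m.spectrum_id not in by_id:
            raise MetadataError(
                f"spectrum {m.spectrum_id!r} has no metadata row"
            )
        metas.append(by_id[m.spectrum_id])
    return SpectrumSet(sset.axis, sset.matrix, metas)
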