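"""Spectrum data model, CSV I/O, resampling and amplitude read-off.

A :class:`Spectrum` is a sampled absorbance curve A(λ) on a strictly
increasing, uniformly spaced wavelength grid (nm, absorbance in AU).
Every downstream stage — band simulation, Fourier self-deconvolution,
ratio spectra, calibration — operates on this container, so its
invariants are enforced eagerly at construction time.

Ratio spectra carry an optional boolean ``mask`` marking wavelengths
where the divisor fell below the safe floor; masked points are excluded
from amplitude read-offs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .errors import MaskedWavelengthError, RangeError, SpectrumFormatError

__all__ = [
    "Spectrum",
    "WavelengthGrid",
    "DEFAULT_GRID",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "resample",
    "amplitude_at",
    "measure_fwhm",
    "peak_position",
]

#: Tolerance (nm) on wavelength-step uniformity.
_STEP_TOL = 1e-9

_CSV_HEADER = ("wavelength_nm", "absorbance")


@dataclass(frozen=True)
class WavelengthGrid:
    """A uniform wavelength grid: ``start`` to ``stop`` nm in steps of ``step`` nm."""

    start: float
    stop: float
    step: float

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(f"grid start must precede stop: {self.start} >= {self.stop}")
        if not self.step > 0:
            raise ValueError(f"grid step must be positive: {self.step}")
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-6:
            raise ValueError(
                f"(stop - start)/step = {n} is not a whole number; "
                "the grid would not land on stop"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    def wavelengths(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)


#: Default working grid: 200–450 nm at 0.1 nm, wide enough for the
#: 221/271/361 nm bands of the thiazide/triamterene system with margin.
DEFAULT_GRID = WavelengthGrid(200.0, 450.0, 0.1)


@dataclass
class Spectrum:
    """A sampled absorbance curve on a uniform wavelength grid.

    Parameters
    ----------
    wavelengths
        Strictly increasing, uniformly spaced grid in nm (length >= 2).
    absorbances
        Absorbance values in AU; all finite; same length as the grid.
    meta
        Free-form labels (analyte, concentration, solvent, processing log).
    mask
        Optional boolean array; ``True`` marks unreliable points
        (e.g. near-zero divisor in a ratio spectrum).
    """

    wavelengths: np.ndarray
    absorbances: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.wavelengths.ndim != 1 or self.absorbances.ndim != 1:
            raise ValueError("wavelengths and absorbances must be one-dimensional")
        if self.wavelengths.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if self.wavelengths.size != self.absorbances.size:
            raise ValueError(
                f"length mismatch: {self.wavelengths.size} wavelengths vs "
                f"{self.absorbances.size} absorbances"
            )
        dw = np.diff(self.wavelengths)
        if np.any(dw <= 0):
            i = int(np.argmax(dw <= 0))
            raise ValueError(f"wavelengths not increasing at index {i + 1}")
        if np.any(np.abs(dw - dw[0]) > _STEP_TOL):
            i = int(np.argmax(np.abs(dw - dw[0]) > _STEP_TOL))
            raise ValueError(f"wavelength step not uniform at index {i + 1}")
        if not np.all(np.isfinite(self.absorbances)):
            raise ValueError("absorbances must all be finite")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.wavelengths.shape:
                raise ValueError("mask must match the wavelength grid")

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    @property
    def step(self) -> float:
        return float((self.wavelengths[-1] - self.wavelengths[0]) / (len(self) - 1))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def grid(self) -> WavelengthGrid:
        lo, hi = self.span
        return WavelengthGrid(lo, hi, self.step)

    def copy(self, **overrides: Any) -> "Spectrum":
        kwargs: dict[str, Any] = dict(
            wavelengths=self.wavelengths.copy(),
            absorbances=self.absorbances.copy(),
            meta=dict(self.meta),
            mask=None if self.mask is None else self.mask.copy(),
        )
        kwargs.update(overrides)
        return Spectrum(**kwargs)


def amplitude_at(s: Spectrum, wavelength: float) -> float:
    """Linearly interpolated absorbance of ``s`` at ``wavelength`` (nm).

    Raises
    ------
    RangeError
        If the wavelength lies outside the spectrum's span.
    MaskedWavelengthError
        If either bracketing grid point is masked.
    """
    lo, hi = s.span
    if wavelength < lo - _STEP_TOL or wavelength > hi + _STEP_TOL:
        raise RangeError(
            f"wavelength {wavelength} nm outside spectrum span [{lo}, {hi}] nm"
        )
    if s.mask is not None:
        pos = (wavelength - lo) / s.step
        i = int(np.clip(np.floor(pos), 0, len(s) - 2))
        if s.mask[i] or s.mask[i + 1]:
            raise MaskedWavelengthError(
                f"wavelength {wavelength} nm falls in a masked region "
                "(divisor below floor)"
            )
    return float(np.interp(wavelength, s.wavelengths, s.absorbances))


def resample(s: Spectrum, g: WavelengthGrid) -> Spectrum:
    """Resample ``s`` onto grid ``g`` by linear interpolation (no extrapolation)."""
    lo, hi = s.span
    if g.start < lo - _STEP_TOL or g.stop > hi + _STEP_TOL:
        raise RangeError(
            f"target grid [{g.start}, {g.stop}] nm extends beyond "
            f"spectrum span [{lo}, {hi}] nm"
        )
    w = g.wavelengths()
    a = np.interp(w, s.wavelengths, s.absorbances)
    return Spectrum(w, a, meta=dict(s.meta))


def read_spectrum_csv(path: str | Path) -> Spectrum:
    """Read a spectrum from a two-column CSV file.

    Dialect: optional ``# key: value`` metadata lines, then the header
    ``wavelength_nm,absorbance``, then numeric rows. Wavelengths must be
    strictly increasing on a uniform step.
    """
    path = Path(path)
    meta: dict[str, Any] = {}
    wavelengths: list[float] = []
    absorbances: list[float] = []
    header_seen = False
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].lstrip().startswith("#"):
                text = ",".join(row).lstrip().lstrip("#").strip()
                if ":" in text:
                    key, _, value = text.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                got = tuple(c.strip() for c in row[:2])
                if got != _CSV_HEADER:
                    raise SpectrumFormatError(
                        f"{path}: line {lineno}: expected header "
                        f"{','.join(_CSV_HEADER)!r}, got {','.join(row)!r}"
                    )
                header_seen = True
                continue
            if len(row) < 2:
                raise SpectrumFormatError(f"{path}: line {lineno}: expected two columns")
            try:
                w = float(row[0])
                a = float(row[1])
            except ValueError as exc:
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: non-numeric cell: {exc}"
                ) from None
            if wavelengths and w <= wavelengths[-1]:
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: wavelengths not increasing "
                    f"({w} after {wavelengths[-1]})"
                )
            wavelengths.append(w)
            absorbances.append(a)
    if not header_seen:
        raise SpectrumFormatError(f"{path}: missing header {','.join(_CSV_HEADER)!r}")
    if len(wavelengths) < 2:
        raise SpectrumFormatError(f"{path}: fewer than two data rows")
    dw = np.diff(wavelengths)
    bad = np.abs(dw - dw[0]) > _STEP_TOL
    if np.any(bad):
        i = int(np.argmax(bad))
        raise SpectrumFormatError(
            f"{path}: wavelength step changes at data row {i + 2} "
            f"({dw[i]} vs {dw[0]} nm)"
        )
    return Spectrum(np.array(wavelengths), np.array(absorbances), meta=meta)


def write_spectrum_csv(s: Spectrum, path: str | Path) -> None:
    """Write ``s`` to CSV so that ``read_spectrum_csv`` round-trips it exactly."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        for key, value in s.meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write(",".join(_CSV_HEADER) + "\n")
        for w, a in zip(s.wavelengths, s.absorbances):
            fh.write(f"{float(w)!r},{float(a)!r}\n")


def peak_position(s: Spectrum) -> float:
    """Wavelength of the global absorbance maximum (grid resolution)."""
    return float(s.wavelengths[int(np.argmax(s.absorbances))])


def measure_fwhm(s: Spectrum) -> float:
    """Numeric full width at half maximum of the dominant band of ``s``.

    Finds the global maximum and walks outward to the half-maximum
    crossings, refining each by linear interpolation. Intended for
    single-band (or well-separated) test spectra.
    """
    a = s.absorbances
    w = s.wavelengths
    i_pk = int(np.argmax(a))
    half = a[i_pk] / 2.0
    if a[i_pk] <= 0:
        raise ValueError("spectrum maximum is not positive; no band to measure")

    def _cross(idx_range: range) -> float:
        prev = i_pk
        for i in idx_range:
            if a[i] <= half:
                # linear interpolation between i and prev
                frac = (half - a[i]) / (a[prev] - a[i])
                return float(w[i] + frac * (w[prev] - w[i]))
            prev = i
        raise ValueError("band does not fall to half maximum inside the grid")

    left = _cross(range(i_pk - 1, -1, -1))
    right = _cross(range(i_pk + 1, len(a)))
    return right - left
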