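"""The five spectral-resolution methods for a two-component UV mixture.

Given a mixture spectrum A(λ) = c_a·a_a(λ) + c_b·a_b(λ) the module
recovers (c_a, c_b) by five independent routes:

ACM  (absorption correction)
    The interferent (TRIM) is read at its no-contribution point
    (361 nm, where the analyte is silent) and its contribution at the
    analyte's λmax (271 nm) is subtracted using the correction factor
    F_ac = a_interferent(271)/a_interferent(361).

ISM  (isoabsorptive point)
    At the isoabsorptive wavelength both analytes share the same
    absorptivity, so a single calibration there reads the *summed*
    concentration; the interferent read at 361 nm is subtracted.

FSD  (Fourier self-deconvolution)
    The spectrum is sharpened by dividing its Fourier transform by the
    transform of an assumed Lorentzian lineshape — multiplication by
    exp(πσ|x|) with an apodization taper D(L, x) to bound noise
    amplification — and the narrowed bands are read directly.

RDF  (ratio difference)
    The mixture is divided by a standard spectrum of the interferent;
    the interferent collapses to a constant that cancels in the
    amplitude difference ΔP = P(λ1) − P(λ2).

RDM  (ratio derivative)
    First derivative of the same ratio spectrum (Savitzky–Golay); the
    constant interferent term differentiates to zero and the analyte is
    read at a single wavelength.

All five are linear in concentration, so ordinary straight-line
calibration applies to each method's signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    DegenerateDivisorError,
    DegenerateSpectraError,
    IsoPointNotFoundError,
    MaskedWavelengthError,
    RangeError,
    StabilityError,
)
from .spectra import Spectrum, amplitude_at
from .validation import CalibrationModel

__all__ = [
    "AcmConfig",
    "FSDConfig",
    "RatioConfig",
    "ResolvedConcentrations",
    "IsoPoint",
    "compute_fac",
    "acm_resolve",
    "find_isoabsorptive_point",
    "ism_resolve",
    "fsd",
    "ratio_spectrum",
    "rdf_delta",
    "ratio_derivative",
    "find_zero_crossings",
    "AcmMethod",
    "IsmMethod",
    "FsdMethod",
    "RatioChannel",
    "RatioMethod",
    "resolve_all",
]

_MAX_EXP = 700.0  # exp overflow guard for float64


# ---------------------------------------------------------------------------
# configuration containers


@dataclass
class AcmConfig:
    """Absorption-correction settings.

    ``lambda_interfering`` is the analyte's λmax where the interferent
    still absorbs (default 271 nm); ``lambda_free`` the interferent's
    no-contribution read-off (default 361 nm). ``f_ac`` is the measured
    correction factor; ``noise_tolerance`` (AU) sets the flagging
    threshold for negative corrected absorbances.
    """

    lambda_interfering: float = 271.0
    lambda_free: float = 361.0
    f_ac: float | None = None
    floor: float = 1e-6
    noise_tolerance: float = 0.002

    def __post_init__(self) -> None:
        if self.lambda_interfering == self.lambda_free:
            raise ValueError("interfering and free wavelengths must differ")
        if self.f_ac is not None and self.f_ac <= 0:
            raise ValueError("f_ac must be positive when set")


@dataclass
class FSDConfig:
    """Fourier self-deconvolution settings.

    ``sigma`` (nm) is the rate of the Fourier-domain sharpening kernel
    exp(πσ|x|), x in cycles/nm — it undoes a Lorentzian lineshape of
    half width σ/2, so a Lorentzian band of HWHM γ narrows to HWHM
    γ − σ/2. The user-facing ``nominal_fwhm`` knob maps to σ =
    nominal_fwhm/2 when ``sigma`` is not given. ``apod_halfwidth``
    (cycles/nm) truncates the Fourier domain through the apodization
    taper ``apod_shape`` (boxcar, triangular, or bessel-like).
    """

    sigma: float | None = None
    nominal_fwhm: float = 40.0
    apod_halfwidth: float = 0.05
    apod_shape: str = "triangular"

    def __post_init__(self) -> None:
        if self.sigma is None:
            self.sigma = self.nominal_fwhm / 2.0
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.apod_halfwidth <= 0:
            raise ValueError("apod_halfwidth L must be positive")
        if self.apod_shape not in ("boxcar", "triangular", "bessel"):
            raise ValueError(f"unknown apodization shape {self.apod_shape!r}")


@dataclass
class RatioConfig:
    """Ratio-spectra settings for one analyte channel.

    ``divisor_analyte``/``divisor_concentration`` identify the standard
    used as divisor (defaults of the study: TRIM 10 µg/mL to determine
    HCTZ, HCTZ 4 µg/mL to determine TRIM). ``rdf_pair`` are the
    amplitude-difference wavelengths, ``rdm_wavelength`` the derivative
    read-off. ``smoothing_window`` (points, 0 = off) applies an equal
    Savitzky–Golay smoothing to numerator and divisor before division;
    ``derivative_window``/``derivative_polyorder`` control the
    derivative filter.
    """

    divisor_analyte: str = "TRIM"
    divisor_concentration: float = 10.0
    rdf_pair: tuple[float, float] = (273.0, 293.0)
    rdm_wavelength: float = 283.0
    derivative_window: int = 151
    derivative_polyorder: int = 2
    divisor_floor: float = 0.01
    smoothing_window: int = 51
    smoothing_polyorder: int = 2

    def __post_init__(self) -> None:
        if self.rdf_pair[0] == self.rdf_pair[1]:
            raise ValueError("rdf_pair wavelengths must differ")
        if self.divisor_concentration <= 0:
            raise ValueError("divisor_concentration must be positive")
        if self.derivative_window % 2 == 0 or self.derivative_window <= self.derivative_polyorder:
            raise ValueError("derivative_window must be odd and exceed the polyorder")
        if self.divisor_floor <= 0:
            raise ValueError("divisor_floor must be positive")
        if self.smoothing_window and (
            self.smoothing_window % 2 == 0 or self.smoothing_window <= self.smoothing_polyorder
        ):
            raise ValueError("smoothing_window must be odd and exceed the polyorder")


@dataclass
class ResolvedConcentrations:
    """Per-analyte concentration estimates from one method, with intermediates."""

    method: str
    concentrations: dict[str, float]
    intermediates: dict[str, float | str] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    failed: bool = False

    def flag_negative(self) -> None:
        for analyte, conc in self.concentrations.items():
            if conc < 0:
                self.flags.append(f"negative-estimate:{analyte}")


# ---------------------------------------------------------------------------
# ACM


def compute_fac(pure_interferent: Spectrum, cfg: AcmConfig) -> float:
    """Correction factor F_ac = A(λ_interfering)/A(λ_free) of a pure standard.

    Concentration-independent under Beer–Lambert: both absorbances scale
    with the same concentration.
    """
    a_free = amplitude_at(pure_interferent, cfg.lambda_free)
    if a_free <= cfg.floor:
        raise DegenerateDivisorError(
            f"interferent absorbance at {cfg.lambda_free} nm is {a_free:g} AU "
            f"(<= floor {cfg.floor:g}); F_ac undefined"
        )
    return amplitude_at(pure_interferent, cfg.lambda_interfering) / a_free


def acm_resolve(
    mixture: Spectrum,
    cfg: AcmConfig,
    calib_interferent_at_free: CalibrationModel,
    calib_analyte_at_interfering: CalibrationModel,
) -> ResolvedConcentrations:
    """Absorption-correction resolution of a two-component mixture.

    The interferent is read directly at its free wavelength; its
    contribution at the analyte wavelength is removed as
    A_corr = A(λ_interfering) − F_ac·A(λ_free) before inverting the
    analyte calibration.
    """
    if cfg.f_ac is None:
        raise ValueError("AcmConfig.f_ac is not set; call compute_fac first")
    a_free = amplitude_at(mixture, cfg.lambda_free)
    a_int = amplitude_at(mixture, cfg.lambda_interfering)
    corrected = a_int - cfg.f_ac * a_free
    c_interferent = float(calib_interferent_at_free.to_concentration(a_free))
    c_analyte = float(calib_analyte_at_interfering.to_concentration(corrected))
    result = ResolvedConcentrations(
        method="ACM",
        concentrations={
            calib_analyte_at_interfering.analyte or "analyte": c_analyte,
            calib_interferent_at_free.analyte or "interferent": c_interferent,
        },
        intermediates={
            "A_free": a_free,
            "A_interfering": a_int,
            "corrected_absorbance": corrected,
            "f_ac": cfg.f_ac,
        },
    )
    if corrected < -3.0 * cfg.noise_tolerance:
        result.flags.append("corrected-absorbance-negative")
    result.flag_negative()
    return result


# ---------------------------------------------------------------------------
# ISM


@dataclass(frozen=True)
class IsoPoint:
    """An isoabsorptive crossing: the selected wavelength plus all candidates."""

    wavelength: float
    candidates: tuple[float, ...]


def find_isoabsorptive_point(
    unit_a: Spectrum,
    unit_b: Spectrum,
    window: tuple[float, float],
    tol: float = 1e-12,
) -> IsoPoint:
    """Locate the isoabsorptive point of two unit-concentration spectra.

    Scans ``window`` for sign changes of a_a(λ) − a_b(λ) and refines each
    bracketing pair by linear interpolation. If several crossings exist
    the one with the largest local slope difference (sharpest crossing)
    is selected; all candidates are reported.
    """
    if len(unit_a) != len(unit_b) or not np.allclose(
        unit_a.wavelengths, unit_b.wavelengths
    ):
        raise ValueError("unit spectra must share one wavelength grid")
    lo, hi = window
    span_lo, span_hi = unit_a.span
    if lo < span_lo or hi > span_hi or lo >= hi:
        raise RangeError(f"window [{lo}, {hi}] nm invalid for span [{span_lo}, {span_hi}] nm")
    w = unit_a.wavelengths
    sel = (w >= lo) & (w <= hi)
    diff = unit_a.absorbances[sel] - unit_b.absorbances[sel]
    ww = w[sel]
    if np.max(np.abs(diff)) < tol:
        raise DegenerateSpectraError(
            "spectra identical within tolerance over the window; "
            "no unique isoabsorptive point"
        )
    crossings: list[tuple[float, float]] = []  # (wavelength, |slope difference|)
    step = unit_a.step
    for i in range(diff.size - 1):
        d0, d1 = diff[i], diff[i + 1]
        if d0 == 0.0:
            crossings.append((float(ww[i]), abs((d1 - d0) / step)))
        elif d0 * d1 < 0:
            lam = float(ww[i] + step * d0 / (d0 - d1))
            crossings.append((lam, abs((d1 - d0) / step)))
    if diff[-1] == 0.0:
        crossings.append((float(ww[-1]), abs((diff[-1] - diff[-2]) / step)))
    if not crossings:
        raise IsoPointNotFoundError(f"no sign change of the difference in [{lo}, {hi}] nm")
    best = max(crossings, key=lambda c: c[1])
    return IsoPoint(wavelength=best[0], candidates=tuple(c[0] for c in crossings))


def ism_resolve(
    mixture: Spectrum,
    lambda_iso: float,
    calib_iso: CalibrationModel,
    calib_free: CalibrationModel,
    lambda_free: float = 361.0,
    other_analyte: str = "HCTZ",
) -> ResolvedConcentrations:
    """Isoabsorptive-point resolution.

    ``calib_iso`` (built from a single analyte at the isoabsorptive
    wavelength) reads the summed concentration; ``calib_free`` reads the
    interferent at its free wavelength; the difference is the other
    analyte. The conservation c_other + c_free = c_total is exact by
    construction.
    """
    a_iso = amplitude_at(mixture, lambda_iso)
    a_free = amplitude_at(mixture, lambda_free)
    c_total = float(calib_iso.to_concentration(a_iso))
    c_free = float(calib_free.to_concentration(a_free))
    c_other = c_total - c_free
    result = ResolvedConcentrations(
        method="ISM",
        concentrations={
            other_analyte: c_other,
            calib_free.analyte or "interferent": c_free,
        },
        intermediates={
            "lambda_iso": lambda_iso,
            "A_iso": a_iso,
            "A_free": a_free,
            "c_total": c_total,
        },
    )
    result.flag_negative()
    return result


# ---------------------------------------------------------------------------
# FSD


def _apodization(shape: str, f: np.ndarray, L: float) -> np.ndarray:
    af = np.abs(f)
    inside = af <= L
    if shape == "boxcar":
        return inside.astype(float)
    if shape == "triangular":
        return np.where(inside, 1.0 - af / L, 0.0)
    # bessel-like: smooth quartic taper (1 - (x/L)^2)^2
    return np.where(inside, (1.0 - (af / L) ** 2) ** 2, 0.0)


def fsd(s: Spectrum, cfg: FSDConfig) -> Spectrum:
    """Fourier self-deconvolution of a spectrum.

    The mean-detrended signal is zero-padded to the next power of two,
    transformed, multiplied by D(L, x)·exp(πσ|x|) (the inverse transform
    of a Lorentzian lineshape of HWHM σ/2, tapered by the apodization),
    and transformed back; the real part on the original grid is returned
    with the mean restored. A boxcar taper with σ = 0 and L at or beyond
    the Nyquist frequency is the identity. The operator is linear.
    """
    n = len(s)
    step = s.step
    f_nyq = 0.5 / step
    sigma = float(cfg.sigma or 0.0)
    max_arg = np.pi * sigma * min(cfg.apod_halfwidth, f_nyq)
    if max_arg > _MAX_EXP:
        raise StabilityError(
            f"exp(pi*sigma*L) with sigma={sigma} nm, L={cfg.apod_halfwidth} "
            "cycles/nm overflows; reduce sigma or the apodization half-width"
        )
    nfft = 1 << int(np.ceil(np.log2(n)))
    mean = float(s.absorbances.mean())
    padded = np.zeros(nfft)
    padded[:n] = s.absorbances - mean
    spec = np.fft.fft(padded)
    freqs = np.fft.fftfreq(nfft, d=step)
    kernel = _apodization(cfg.apod_shape, freqs, cfg.apod_halfwidth) * np.exp(
        np.pi * sigma * np.abs(freqs)
    )
    out = np.fft.ifft(spec * kernel).real[:n] + mean
    meta = dict(s.meta)
    meta["fsd"] = (
        f"sigma={sigma}nm L={cfg.apod_halfwidth}cyc/nm apod={cfg.apod_shape}"
    )
    return Spectrum(s.wavelengths.copy(), out, meta=meta)


# ---------------------------------------------------------------------------
# ratio spectra (RDF / RDM)


def ratio_spectrum(
    mixture: Spectrum,
    divisor_unit: Spectrum,
    divisor_conc: float,
    floor: float,
    smooth_window: int = 0,
    smooth_polyorder: int = 2,
) -> Spectrum:
    """Pointwise quotient of a mixture by a divisor standard spectrum.

    The divisor is ``divisor_unit`` scaled to ``divisor_conc``.
    Wavelengths where the divisor falls below ``floor`` (AU) are masked:
    their quotient is not meaningful and downstream read-offs there
    raise. When ``smooth_window`` > 0 an identical Savitzky–Golay
    smoothing is applied to numerator and divisor before dividing —
    equal treatment keeps a pure divisor-analyte mixture's ratio exactly
    constant.
    """
    if len(mixture) != len(divisor_unit) or not np.allclose(
        mixture.wavelengths, divisor_unit.wavelengths
    ):
        raise ValueError("mixture and divisor must share one wavelength grid")
    if divisor_conc <= 0:
        raise ValueError("divisor concentration must be positive")
    if floor <= 0:
        raise ValueError("divisor floor must be positive")
    num = mixture.absorbances
    den = divisor_unit.absorbances * divisor_conc
    if smooth_window:
        num = savgol_filter(num, smooth_window, smooth_polyorder)
        den = savgol_filter(den, smooth_window, smooth_polyorder)
    mask = den < floor
    ratio = np.zeros_like(num)
    np.divide(num, den, out=ratio, where=~mask)
    meta = dict(mixture.meta)
    meta["divisor"] = f"{divisor_unit.meta.get('analyte', '?')} {divisor_conc:g} ug/mL"
    meta["n_masked"] = int(mask.sum())
    return Spectrum(mixture.wavelengths.copy(), ratio, meta=meta, mask=mask)


def rdf_delta(ratio: Spectrum, lambda1: float, lambda2: float) -> float:
    """Amplitude difference ΔP = P(λ1) − P(λ2) of a ratio spectrum.

    The divisor analyte contributes a constant to the ratio spectrum, so
    it cancels exactly in ΔP; the difference is proportional to the
    other analyte's concentration.
    """
    return amplitude_at(ratio, lambda1) - amplitude_at(ratio, lambda2)


def ratio_derivative(ratio: Spectrum, window: int, polyorder: int) -> Spectrum:
    """Savitzky–Golay first derivative of a ratio spectrum (per nm).

    The constant divisor-analyte term differentiates away. Masked
    regions propagate, dilated by the filter half-width, since the
    sliding fit mixes in masked values near a mask edge.
    """
    n = len(ratio)
    if window % 2 == 0 or window <= polyorder or window >= n:
        raise ValueError(
            f"derivative window must be odd, > polyorder and < spectrum length; "
            f"got window={window}, polyorder={polyorder}, n={n}"
        )
    deriv = savgol_filter(
        ratio.absorbances, window, polyorder, deriv=1, delta=ratio.step
    )
    mask = ratio.mask
    if mask is not None and mask.any():
        half = window // 2
        dilated = np.convolve(mask.astype(int), np.ones(2 * half + 1, dtype=int), "same") > 0
        mask = dilated
    meta = dict(ratio.meta)
    meta["derivative"] = f"savgol window={window} polyorder={polyorder} deriv=1"
    return Spectrum(ratio.wavelengths.copy(), deriv, meta=meta, mask=mask)


# ---------------------------------------------------------------------------
# calibrated method bundles and the one-shot resolver


@dataclass
class AcmMethod:
    """Calibrated absorption-correction method."""

    cfg: AcmConfig
    calib_interferent_at_free: CalibrationModel
    calib_analyte_at_interfering: CalibrationModel
    name: str = "ACM"

    def resolve(self, mixture: Spectrum) -> ResolvedConcentrations:
        res = acm_resolve(
            mixture, self.cfg, self.calib_interferent_at_free, self.calib_analyte_at_interfering
        )
        res.method = self.name
        return res


@dataclass
class IsmMethod:
    """Calibrated isoabsorptive-point method."""

    lambda_iso: float
    calib_iso: CalibrationModel
    calib_free: CalibrationModel
    lambda_free: float = 361.0
    other_analyte: str = "HCTZ"
    name: str = "ISM"

    def resolve(self, mixture: Spectrum) -> ResolvedConcentrations:
        res = ism_resolve(
            mixture,
            self.lambda_iso,
            self.calib_iso,
            self.calib_free,
            lambda_free=self.lambda_free,
            other_analyte=self.other_analyte,
        )
        res.method = self.name
        return res


def find_zero_crossings(s: Spectrum, window: tuple[float, float]) -> list[float]:
    """Zero crossings of a spectrum inside ``window``, linearly refined.

    Deconvolution gives the interferent an oscillating residue; reading
    the analyte at a zero crossing of the interferent's deconvoluted
    spectrum removes its contribution regardless of concentration (the
    transform is linear), exactly as in zero-crossing derivative
    spectrophotometry.
    """
    lo, hi = window
    w = s.wavelengths
    a = s.absorbances
    sel = (w >= lo) & (w <= hi)
    ww, aa = w[sel], a[sel]
    out: list[float] = []
    step = s.step
    for i in range(aa.size - 1):
        if aa[i] == 0.0:
            out.append(float(ww[i]))
        elif aa[i] * aa[i + 1] < 0:
            out.append(float(ww[i] + step * aa[i] / (aa[i] - aa[i + 1])))
    return out


@dataclass
class FsdMethod:
    """Calibrated Fourier self-deconvolution method.

    The primary analyte is read at a wavelength where the deconvoluted
    interferent vanishes (a zero crossing of its deconvoluted unit
    spectrum). The secondary analyte is read in its own band region with
    a correction for the primary analyte's small deconvoluted residue
    there: A_corr = A(λ2) − leak_slope·c_primary. Calibrations must have
    been fitted on standards deconvoluted with the same ``cfg``.
    """

    cfg: FSDConfig
    primary_analyte: str
    lambda_primary: float
    calib_primary: CalibrationModel
    secondary_analyte: str
    lambda_secondary: float
    calib_secondary: CalibrationModel
    leak_slope: float = 0.0  # deconvoluted primary amplitude per µg/mL at λ2
    name: str = "FSD"

    def resolve(self, mixture: Spectrum) -> ResolvedConcentrations:
        decon = fsd(mixture, self.cfg)
        amp1 = amplitude_at(decon, self.lambda_primary)
        c1 = float(self.calib_primary.to_concentration(amp1))
        amp2_raw = amplitude_at(decon, self.lambda_secondary)
        amp2 = amp2_raw - self.leak_slope * c1
        c2 = float(self.calib_secondary.to_concentration(amp2))
        res = ResolvedConcentrations(
            method=self.name,
            concentrations={self.primary_analyte: c1, self.secondary_analyte: c2},
            intermediates={
                f"amplitude@{self.lambda_primary:.1f}nm": amp1,
                f"amplitude@{self.lambda_secondary:.1f}nm": amp2_raw,
                "leak_corrected_amplitude": amp2,
                "leak_slope": self.leak_slope,
            },
        )
        res.flag_negative()
        return res


@dataclass
class RatioChannel:
    """One analyte channel of a ratio-spectra method (its divisor + calibration)."""

    analyte: str
    cfg: RatioConfig
    divisor_unit: Spectrum
    calibration: CalibrationModel

    def make_ratio(self, mixture: Spectrum) -> Spectrum:
        return ratio_spectrum(
            mixture,
            self.divisor_unit,
            self.cfg.divisor_concentration,
            self.cfg.divisor_floor,
            smooth_window=self.cfg.smoothing_window,
            smooth_polyorder=self.cfg.smoothing_polyorder,
        )

    def rdf_signal(self, mixture: Spectrum) -> float:
        return rdf_delta(self.make_ratio(mixture), *self.cfg.rdf_pair)

    def rdm_signal(self, mixture: Spectrum) -> float:
        deriv = ratio_derivative(
            self.make_ratio(mixture),
            self.cfg.derivative_window,
            self.cfg.derivative_polyorder,
        )
        return amplitude_at(deriv, self.cfg.rdm_wavelength)


@dataclass
class RatioMethod:
    """A ratio-spectra method (difference or derivative) over two channels."""

    channels: list[RatioChannel]
    mode: str = "difference"  # or "derivative"
    name: str = "RDF"

    def resolve(self, mixture: Spectrum) -> ResolvedConcentrations:
        concentrations: dict[str, float] = {}
        intermediates: dict[str, float | str] = {}
        for ch in self.channels:
            if self.mode == "difference":
                signal = ch.rdf_signal(mixture)
                intermediates[f"deltaP_{ch.analyte}"] = signal
            else:
                signal = ch.rdm_signal(mixture)
                intermediates[f"derivative_amplitude_{ch.analyte}"] = signal
            concentrations[ch.analyte] = float(ch.calibration.to_concentration(signal))
        res = ResolvedConcentrations(
            method=self.name, concentrations=concentrations, intermediates=intermediates
        )
        res.flag_negative()
        return res


def resolve_all(mixture: Spectrum, methods: Sequence) -> list[ResolvedConcentrations]:
    """Run every calibrated method on one mixture.

    A method whose preconditions fail is reported as a structured
    failure; the remaining methods still run.
    """
    results: list[ResolvedConcentrations] = []
    for method in methods:
        try:
            results.append(method.resolve(mixture))
        except Exception as exc:  # noqa: BLE001 - structured failure report
            results.append(
                ResolvedConcentrations(
                    method=getattr(method, "name", type(method).__name__),
                    concentrations={},
                    flags=[f"failed: {exc}"],
                    failed=True,
                )
            )
    return results
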