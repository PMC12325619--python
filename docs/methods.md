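# Methods

## The measurement model

A blank-corrected UV absorbance spectrum of a two-component solution is
modelled as

    A(λ) = c_H · a_H(λ) + c_T · a_T(λ) + ε(λ)

with concentrations c in µg/mL, unit-concentration absorptivity curves
a(λ) in AU·mL/µg, and ε i.i.d. Gaussian measurement noise in AU
(homoscedastic across wavelength). Beer–Lambert additivity and linearity
are exact in the generator; every resolution method below is a linear
functional of A, so each method's signal is exactly linear in its
analyte's concentration and ordinary least-squares calibration is the
correct model. Spectra live on a uniform wavelength grid (default
200–450 nm at 0.1 nm); all read-offs use linear interpolation so
non-integer wavelengths (e.g. 266.8 nm) are addressable on any grid.

## The synthetic system

The HCTZ/TRIM presets are gaussian band sums with the wavelength anchors
of the real system and tuned widths/amplitudes (no molar absorptivities
are published for this solvent system):

* HCTZ: bands at 271 nm (FWHM 30, peak 0.0690) and 221 nm (FWHM 22,
  peak 0.085). The gaussian tail makes a_H(361) ≈ 10⁻¹² — the
  "no-contribution point" where TRIM is read directly.
* TRIM: main band at 361 nm (FWHM 40, peak 0.0803) and a secondary band
  at 255 nm (FWHM 52, peak 0.075). The secondary band is shaped so that
  (a) the unit spectra cross at ≈266.7 nm (the isoabsorptive point of
  the real system sits at 266.8 nm), (b) the global maximum stays at
  361 nm, and (c) the TRIM divisor stays above the masking floor across
  the 273–293 nm ratio-difference window.

The absorbance scale is anchored to the published absorption-correction
calibration slopes (0.0690 and 0.0803 AU·mL/µg at 271/361 nm).
Solvent effects enter as a multiplicative FWHM broadening plus an
additive center shift; the mapping from an interaction-energy magnitude
to a broadening factor (1 + k·|E|, k = 0.02 per kcal/mol) encodes the
direction only and is illustrative. The solvent pre-selection rule
(exclude exothermic solvation, then rank by ascending interaction
energy, ties to lower dielectric) operates on a descriptor table and is
independent of the spectral model.

Default noise is 0.002 AU, which puts replicate %RSD of the
direct-read methods in the few-tenths-of-a-percent range typical of a
validated UV assay. What the generator does **not** emulate: baseline
drift, stray light, wavelength-registration error, heteroscedastic
(signal-proportional) noise, excipient absorption beyond an optional
constant offset, and divisor-standard measurement error (see below).
Passing tests therefore demonstrate correctness of the algebra and
robustness to additive white noise, not ruggedness against instrument
systematics.

## The five methods and their numerical choices

**Absorption correction (ACM).** F_ac is taken as the ratio of the two
fitted TRIM calibration slopes (271/361 nm) rather than a single
spectrum's amplitude ratio — same quantity under Beer–Lambert, lower
variance. Corrected absorbances below −3× the noise tolerance flag the
result; negative concentration estimates are always flagged, never
clipped.

**Isoabsorptive point (ISM).** The crossing of the two unit spectra is
located by sign-change search with linear refinement inside a window
(260–273 nm by default; the presets have additional crossings near 232
and 291 nm that are irrelevant to the method). If several crossings
fall in the window the sharpest (largest slope difference) is chosen
and all are reported. The total-concentration calibration is built from
one analyte's standards at λiso, valid for the sum by the isoabsorptive
property; c_H + c_T = c_total is an algebraic identity of the method.

**Fourier self-deconvolution (FSD).** The mean-detrended signal is
zero-padded to the next power of two, transformed with an FFT, and
multiplied by D(L, x)·exp(πσ|x|), x in cycles/nm — the inverse of a
Lorentzian lineshape transform of HWHM σ/2, tapered by a boxcar,
triangular (default) or quartic "bessel-like" apodization of half-width
L. A Lorentzian band of HWHM γ therefore narrows to γ − σ/2; the
operator is linear and is the identity for σ = 0 with a full-domain
boxcar. An exponent guard raises a stability error before exp overflow.
The user-facing `nominal_fwhm` knob maps to σ = nominal_fwhm/2; the
vendor convention behind the study's dialog setting is not recoverable,
so deconvoluted amplitudes are not comparable across implementations.

*Read-off selection.* On gaussian bands the Lorentzian-kernel
deconvolution leaves an oscillating residue rather than a cleanly
narrowed peak, and because the isoabsorptive crossing pins
a_T ≈ a_H near 267 nm, no fixed wavelength is zero-order selective for
HCTZ. The pipeline therefore reads HCTZ at a **zero crossing of the
deconvoluted TRIM unit spectrum** nearest the nominal 299 nm (the
default settings put it at ≈299.2 nm): by linearity the interferent
vanishes there at any concentration, exactly as in zero-crossing
derivative spectrophotometry. TRIM is read at 366 nm with a correction
for the small deconvoluted HCTZ residue, whose slope is fitted on the
same pure-HCTZ standards (absorption-correction logic in deconvoluted
space). Defaults: σ = 20 nm, L = 0.05 cycles/nm, triangular taper —
chosen so a zero crossing exists near 299 nm with a usable HCTZ
amplitude and bounded noise gain.

**Ratio spectra (RDF/RDM).** The mixture is divided pointwise by the
divisor standard (TRIM 10 µg/mL for HCTZ; HCTZ 4 µg/mL for TRIM);
wavelengths where the divisor falls below 0.01 AU are masked and
propagate (dilated by the filter half-width) through the derivative;
read-offs in masked regions raise. An optional equal Savitzky–Golay
smoothing (window 51, polyorder 2) is applied to numerator and divisor
before division — equal treatment keeps the divisor-analyte term
exactly constant, so the cancellation identities are preserved while
read-off noise drops about five-fold. The ratio derivative uses a
Savitzky–Golay first derivative with window 151 points (±7.5 nm) and
polyorder 2: at 0.1 nm pitch a sub-nanometre derivative kernel would
amplify 0.002 AU noise to tens of percent RSD, whereas ±7.5 nm matches
the effective Δλ practitioners use for derivative spectrophotometry;
since the filter is linear it cannot bias a linear calibration.

*Divisor idealization.* The pipeline divides by the noise-free model
unit spectrum of the divisor analyte. A single measured divisor would
carry a seed-fixed multiplicative perturbation whose interferent-scaled
part is not absorbed by calibration (≈1% at the most unbalanced
mixture); physically this corresponds to recording the divisor standard
carefully (averaged scans), consistent with the divisor-optimization
premise of the method. Divisor measurement error is thus a known
limitation of the simulation, not of the algebra.

## Calibration and statistics

Calibrations are OLS on (concentration, signal) with r as the Pearson
correlation and σ_resid on n−2 degrees of freedom; LOD/LOQ follow the
3.3σ/S and 10σ/S convention (their ratio is identically 10/3.3, which
also matches the published limits to rounding). Recovery is
100·found/taken; standard addition scores the recovery of the added
amount against the pre-analysed base. The method comparison uses the
classic pooled-variance Student t (df n₁+n₂−2; Welch available behind a
flag) and the variance-ratio F with the larger variance in the
numerator; one-way ANOVA reports the SS/df/MS decomposition, F, p and
η² = SS_between/SS_total, with the all-identical edge case reported as
"F undefined" rather than a division error. Report tables round to 2
decimals for statistics; full precision is kept internally.

The simulated study compares each method's dosage-form recoveries to a
reference method drawn as unbiased with 1% recovery SD (its raw data
are external). Because the synthetic TRIM channels are more precise
than that reference, the F test can flag a variance difference there —
an honest consequence of the noise model, reported as-is.

## Study design (pipeline defaults)

Calibration ranges mirror the validated ranges per method (HCTZ 1–18,
2–16, 4–18, 1–18, 1–18 µg/mL for FSD/ISM/ACM/RDF/RDM; TRIM 2–12, 2–14,
2–14, 1–14, 1–14), sampled at 7 evenly spaced levels in triplicate.
The mixture panel is (4,6), (6,6), (4,12), (4,8), (8,6) µg/mL, each
resolved in triplicate; the dosage-form analogue is (4, 6) µg/mL; the
standard addition spikes 2/4/6 µg/mL onto the pre-analysed base. One
seeded generator drives every random draw in a fixed order, so a report
bundle (CSV tables with a config hash, JSON run log) is bit-reproducible
from its configuration. A full study runs in well under a second; the
twenty-seed acceptance sweep in ~10 s.

## Greenness scorers

The AGREE-style scorer is the weighted mean of twelve principle scores
in [0,1] (equal weights by default; a weight vector is accepted since
the official tool supports one). The GAPI-style summary counts
green/yellow/red labels over fifteen criteria in five domains (sample
handling, reagents/solvents, instrumentation, waste, safety; default
grouping 3+3+3+3+3, configurable). Shipped profiles are illustrative:
published scores of specific methods are not reproducible because their
principle-level inputs are not disclosed.

## Known limitations

* Deconvoluted-amplitude scales are implementation-specific; only the
  operator's mathematical properties (identity, linearity, narrowing,
  peak preservation) are portable.
* The generator's gaussian bands understate real UV band tails; methods
  relying on tail behaviour (FSD read-off placement) are validated
  against the synthetic system, not against instrument data.
* Noise is additive and white; heteroscedastic or correlated noise
  would degrade the ratio channels first.
* Two-component mixtures only; higher-order mixtures and
  second-derivative methods are out of scope.
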