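# uvresolve

Resolution and quantitation of two-component drug mixtures by UV
spectrophotometry, with the full validation-statistics battery and
analytical-greenness scoring — built around the hydrochlorothiazide
(HCTZ) / triamterene (TRIM) antihypertensive combination in ethanol.

The two drugs' UV spectra overlap heavily (HCTZ peaks at 271 and 221 nm,
TRIM's main n→π* band at 361 nm plus a secondary band under HCTZ's λmax),
so a single-wavelength read-off cannot quantify them in a tablet extract.
The package implements five independent resolution methods for a mixture
spectrum A(λ) = c_H·a_H(λ) + c_T·a_T(λ):

| Method | Principle | Read-off |
|---|---|---|
| ACM | absorption correction: subtract the interferent's contribution via F_ac = a_T(271)/a_T(361) | A(361); A(271) − F_ac·A(361) |
| ISM | isoabsorptive point: at λiso (≈266.8 nm) both analytes share one absorptivity, so one calibration reads c_H + c_T | A(λiso); A(361) |
| FSD | Fourier self-deconvolution: multiply the spectrum's Fourier transform by D(L,x)·exp(πσ\|x\|) to narrow bands, then read where the deconvoluted interferent crosses zero | deconvoluted amplitudes (≈299, 366 nm) |
| RDF | ratio difference: divide by a standard spectrum of the interferent; it becomes a constant that cancels in ΔP = P(λ1) − P(λ2) | ΔP(273–293) for HCTZ, ΔP(244–274) for TRIM |
| RDM | ratio derivative: first derivative of the same ratio spectrum kills the constant | amplitude at 283 nm (HCTZ), 251 nm (TRIM) |

All five signals are linear in concentration, so each is calibrated by
ordinary least squares with ICH-style figures of merit
(r, LOD = 3.3σ/S, LOQ = 10σ/S). The validation layer adds recovery and
precision summaries, standard addition, pooled-variance t and
variance-ratio F comparisons against a reference method, and one-way
ANOVA with η² effect sizes. A simplified AGREE (12-principle weighted
mean in [0,1]) and GAPI (15 criteria, green/yellow/red over five
domains) scorer covers the greenness assessment. Because no spectra are
deposited with the study, a synthetic generator reproduces the system's
band structure (Beer–Lambert additivity, the 266.8 nm crossing, the
361 nm no-contribution point, additive Gaussian noise, solvent-dependent
band broadening) so every stage is testable end to end.

## Worked example

```python
from uvresolve import StudyConfig, run_study

report = run_study(StudyConfig(noise_sd=0.002, seed=1))
print(f"isoabsorptive point: {report.lambda_iso:.2f} nm")
print(f"correction factor F_ac: {report.f_ac:.4f}")
print(report.mixture_summary.round(3).to_string(index=False))
```

prints

```
isoabsorptive point: 266.70 nm
correction factor F_ac: 0.7189
method analyte  mean_recovery  sd_recovery
   FSD    HCTZ        100.101        0.205
   FSD    TRIM        100.016        0.046
   ISM    HCTZ        100.060        0.522
   ISM    TRIM         99.956        0.235
   ACM    HCTZ         99.683        0.271
   ACM    TRIM         99.956        0.235
   RDF    HCTZ         99.910        1.224
   RDF    TRIM         99.978        0.039
   RDM    HCTZ         98.681        0.818
   RDM    TRIM         99.987        0.041
```

i.e. with 0.002 AU instrument noise, triplicate determinations of the
five laboratory mixtures (4–8 µg/mL HCTZ against 6–12 µg/mL TRIM) are
recovered at 98.7–100.1% by every method; the isoabsorptive point is
located by sign-change search on the unit spectra, and F_ac is the ratio
of the fitted TRIM slopes at 271 and 361 nm. `run_study` also produces
calibration, assay (t/F vs. a simulated reference), standard-addition
and ANOVA tables; `report.save(outdir)` writes them as CSV with a config
hash so a bundle can be reproduced bit for bit.

The same workflow is scriptable from the shell:

```bash
uvresolve simulate --analyte HCTZ:4 --analyte TRIM:6 --noise-sd 0.002 --seed 3 --out mix.csv
uvresolve resolve --mixture mix.csv
uvresolve run-study --seed 1 --outdir study/
uvresolve report --outdir study/
```

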