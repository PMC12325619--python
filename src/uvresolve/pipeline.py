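"""End-to-end simulated study: calibrate, resolve, validate, report.

:func:`run_study` reproduces the workflow of a two-component UV assay
development campaign on synthetic data: generate unit spectra for the
two analytes, locate the isoabsorptive point, calibrate all five
resolution methods on simulated standards, resolve a panel of
laboratory-style mixtures and a dosage-form analogue, run the accuracy /
precision / comparison statistics, and emit wide per-method tables plus
a run log. Everything is driven by one seed, so a report bundle is
bit-reproducible from its recorded configuration.

:func:`build_method_suite` performs only the calibration stage and
returns the five ready-to-use method objects, for callers that want to
resolve their own spectra.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import IsoPointNotFoundError
from .greenness import (
    EXAMPLE_AGREE_DIRECT_UV,
    EXAMPLE_AGREE_REFERENCE,
    EXAMPLE_GAPI_DIRECT_UV,
    agree_score,
    gapi_summary,
)
from .methods import (
    AcmConfig,
    AcmMethod,
    FSDConfig,
    FsdMethod,
    IsmMethod,
    RatioChannel,
    RatioConfig,
    RatioMethod,
    find_isoabsorptive_point,
    find_zero_crossings,
    fsd,
    resolve_all,
)
from .spectra import DEFAULT_GRID, Spectrum, WavelengthGrid, amplitude_at
from .synthetic import (
    ETHANOL,
    AnalyteModel,
    SolventModel,
    absorptivity_spectrum,
    preset_hctz,
    preset_trim,
    simulate_measurement,
)
from .validation import (
    CalibrationModel,
    fit_calibration,
    mean_sd,
    one_way_anova,
    recovery_percent,
    standard_addition,
    two_sample_t_f,
)

__all__ = [
    "StudyConfig",
    "StudyReport",
    "MethodSuite",
    "build_method_suite",
    "run_study",
    "METHOD_NAMES",
]

METHOD_NAMES = ("FSD", "ISM", "ACM", "RDF", "RDM")
_ANALYTES = ("HCTZ", "TRIM")


def _default_ranges() -> dict[str, dict[str, tuple[float, float]]]:
    """Calibration ranges (µg/mL) per method per analyte."""
    return {
        "FSD": {"HCTZ": (1.0, 18.0), "TRIM": (2.0, 12.0)},
        "ISM": {"HCTZ": (2.0, 16.0), "TRIM": (2.0, 14.0)},
        "ACM": {"HCTZ": (4.0, 18.0), "TRIM": (2.0, 14.0)},
        "RDF": {"HCTZ": (1.0, 18.0), "TRIM": (1.0, 14.0)},
        "RDM": {"HCTZ": (1.0, 18.0), "TRIM": (1.0, 14.0)},
    }


@dataclass
class StudyConfig:
    """Full specification of a simulated study.

    The defaults encode the study conditions: five laboratory mixtures
    (HCTZ, TRIM) = (4,6), (6,6), (4,12), (4,8), (8,6) µg/mL, a (4, 6)
    µg/mL dosage-form analogue, 0.002 AU additive noise, triplicate
    determinations, and the per-method calibration ranges and read-off
    wavelengths of the HCTZ/TRIM assay.
    """

    grid: WavelengthGrid = DEFAULT_GRID
    solvent: SolventModel = ETHANOL
    noise_sd: float = 0.002
    seed: int = 0
    n_replicates: int = 3
    n_calibration_levels: int = 7
    n_calibration_replicates: int = 3
    calibration_ranges: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_ranges
    )
    mixtures: list[tuple[float, float]] = field(
        default_factory=lambda: [(4.0, 6.0), (6.0, 6.0), (4.0, 12.0), (4.0, 8.0), (8.0, 6.0)]
    )
    dosage_form: tuple[float, float] = (4.0, 6.0)
    excipient_offset: float = 0.0
    standard_addition_added: tuple[float, ...] = (2.0, 4.0, 6.0)
    reference_recovery_sd: float = 1.0
    iso_window: tuple[float, float] = (260.0, 273.0)
    fsd_cfg: FSDConfig = field(default_factory=FSDConfig)
    fsd_read: dict[str, float] = field(
        default_factory=lambda: {"HCTZ": 299.0, "TRIM": 366.0}
    )
    acm_cfg: AcmConfig = field(default_factory=AcmConfig)
    ratio_cfg: dict[str, RatioConfig] = field(
        default_factory=lambda: {
            "HCTZ": RatioConfig(
                divisor_analyte="TRIM",
                divisor_concentration=10.0,
                rdf_pair=(273.0, 293.0),
                rdm_wavelength=283.0,
            ),
            "TRIM": RatioConfig(
                divisor_analyte="HCTZ",
                divisor_concentration=4.0,
                rdf_pair=(244.0, 274.0),
                rdm_wavelength=251.0,
            ),
        }
    )

    def calibration_levels(self, method: str, analyte: str) -> np.ndarray:
        lo, hi = self.calibration_ranges[method][analyte]
        return np.linspace(lo, hi, self.n_calibration_levels)

    def to_dict(self) -> dict:
        """JSON/YAML-serialisable summary used for the config hash and logs."""
        return {
            "grid": [self.grid.start, self.grid.stop, self.grid.step],
            "solvent": [self.solvent.name, self.solvent.broadening_factor, self.solvent.shift],
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "n_replicates": self.n_replicates,
            "n_calibration_levels": self.n_calibration_levels,
            "n_calibration_replicates": self.n_calibration_replicates,
            "calibration_ranges": {
                m: {a: list(r) for a, r in d.items()}
                for m, d in self.calibration_ranges.items()
            },
            "mixtures": [list(m) for m in self.mixtures],
            "dosage_form": list(self.dosage_form),
            "excipient_offset": self.excipient_offset,
            "standard_addition_added": list(self.standard_addition_added),
            "reference_recovery_sd": self.reference_recovery_sd,
            "iso_window": list(self.iso_window),
            "fsd": {
                "sigma": self.fsd_cfg.sigma,
                "L": self.fsd_cfg.apod_halfwidth,
                "apod": self.fsd_cfg.apod_shape,
            },
            "fsd_read": dict(self.fsd_read),
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        """Build a config from a YAML file overriding the scalar defaults.

        Recognised keys: noise_sd, seed, n_replicates,
        n_calibration_levels, n_calibration_replicates, mixtures,
        dosage_form, excipient_offset, standard_addition_added,
        reference_recovery_sd, calibration_ranges.
        """
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in (
            "noise_sd",
            "seed",
            "n_replicates",
            "n_calibration_levels",
            "n_calibration_replicates",
            "excipient_offset",
            "reference_recovery_sd",
        ):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "mixtures" in raw:
            cfg.mixtures = [tuple(map(float, m)) for m in raw["mixtures"]]
        if "dosage_form" in raw:
            cfg.dosage_form = tuple(map(float, raw["dosage_form"]))
        if "standard_addition_added" in raw:
            cfg.standard_addition_added = tuple(map(float, raw["standard_addition_added"]))
        if "calibration_ranges" in raw:
            for method, per_analyte in raw["calibration_ranges"].items():
                for analyte, rng in per_analyte.items():
                    cfg.calibration_ranges[method][analyte] = tuple(map(float, rng))
        return cfg


def _simulate(
    cfg: StudyConfig,
    rng: np.random.Generator,
    models: dict[str, AnalyteModel],
    comp: Sequence[tuple[str, float]],
    offset: float = 0.0,
) -> Spectrum:
    spec = simulate_measurement(
        [(models[name], conc) for name, conc in comp],
        cfg.solvent,
        cfg.noise_sd,
        rng,
        cfg.grid,
    )
    if offset:
        spec = Spectrum(spec.wavelengths, spec.absorbances + offset, meta=spec.meta)
    return spec


def _calibrate_signals(
    cfg: StudyConfig,
    rng: np.random.Generator,
    models: dict[str, AnalyteModel],
    analyte: str,
    levels: np.ndarray,
    signal_fns: dict[str, Callable[[Spectrum], float]],
    labels: dict[str, tuple[str, str]],
) -> dict[str, CalibrationModel]:
    """Simulate pure standards of ``analyte`` and fit one calibration per signal.

    Signal functions sharing a key set read the same simulated spectra,
    so signals taken at two wavelengths (e.g. the two absorption-
    correction reads) come from identical measurements, as on a real
    instrument.
    """
    concs: list[float] = []
    signals: dict[str, list[float]] = {key: [] for key in signal_fns}
    for conc in levels:
        for _ in range(cfg.n_calibration_replicates):
            spec = _simulate(cfg, rng, models, [(analyte, float(conc))])
            concs.append(float(conc))
            for key, fn in signal_fns.items():
                signals[key].append(fn(spec))
    out = {}
    for key, values in signals.items():
        label, analyte_name = labels[key]
        out[key] = fit_calibration(concs, values, label=label, analyte=analyte_name)
    return out


@dataclass
class MethodSuite:
    """The five calibrated methods plus the quantities fixed during calibration."""

    methods: list
    calibrations: dict[tuple[str, str], CalibrationModel]
    channels: dict[tuple[str, str], RatioChannel]
    unit_spectra: dict[str, Spectrum]
    lambda_iso: float
    iso_candidates: tuple[float, ...]
    f_ac: float
    lambda_fsd_primary: float
    lambda_fsd_secondary: float
    fsd_leak_slope: float


def build_method_suite(cfg: StudyConfig, rng: np.random.Generator) -> MethodSuite:
    """Calibrate all five resolution methods on simulated pure standards.

    Fixes the study's derived quantities along the way: the
    isoabsorptive wavelength (from the unit spectra), the absorption
    correction factor F_ac (ratio of the fitted TRIM slopes at the two
    wavelengths), and the deconvoluted read-off for HCTZ (zero crossing
    of the deconvoluted TRIM unit spectrum nearest the nominal
    wavelength) together with the deconvoluted HCTZ leak slope at the
    TRIM read-off.
    """
    models = {"HCTZ": preset_hctz(), "TRIM": preset_trim()}
    unit = {
        name: absorptivity_spectrum(model, cfg.solvent, cfg.grid)
        for name, model in models.items()
    }

    iso = find_isoabsorptive_point(unit["HCTZ"], unit["TRIM"], cfg.iso_window)
    lam_iso = iso.wavelength

    fsd_cfg = cfg.fsd_cfg
    acm_cfg = cfg.acm_cfg
    calibs: dict[tuple[str, str], CalibrationModel] = {}

    # TRIM standards over the ACM range: read 361 nm (direct) and 271 nm
    # (for F_ac) on the same simulated spectra.
    trim_acm = _calibrate_signals(
        cfg,
        rng,
        models,
        "TRIM",
        cfg.calibration_levels("ACM", "TRIM"),
        {
            "trim_free": lambda s: amplitude_at(s, acm_cfg.lambda_free),
            "trim_interf": lambda s: amplitude_at(s, acm_cfg.lambda_interfering),
        },
        {
            "trim_free": (f"TRIM@{acm_cfg.lambda_free:g}nm", "TRIM"),
            "trim_interf": (f"TRIM@{acm_cfg.lambda_interfering:g}nm", "TRIM"),
        },
    )
    calibs[("ACM", "TRIM")] = trim_acm["trim_free"]
    calibs[("ISM", "TRIM")] = trim_acm["trim_free"]  # same zero-order read-off
    f_ac = trim_acm["trim_interf"].slope / trim_acm["trim_free"].slope
    acm_cfg.f_ac = f_ac

    calibs[("ACM", "HCTZ")] = _calibrate_signals(
        cfg,
        rng,
        models,
        "HCTZ",
        cfg.calibration_levels("ACM", "HCTZ"),
        {"read": lambda s: amplitude_at(s, acm_cfg.lambda_interfering)},
        {"read": (f"HCTZ@{acm_cfg.lambda_interfering:g}nm", "HCTZ")},
    )["read"]

    calibs[("ISM", "HCTZ")] = _calibrate_signals(
        cfg,
        rng,
        models,
        "HCTZ",
        cfg.calibration_levels("ISM", "HCTZ"),
        {"read": lambda s: amplitude_at(s, lam_iso)},
        {"read": (f"HCTZ@{lam_iso:.1f}nm(iso)", "HCTZ")},
    )["read"]

    # FSD read-offs: HCTZ at a zero crossing of the deconvoluted TRIM
    # unit spectrum (the interferent vanishes there at any concentration),
    # TRIM in its own band region corrected for the deconvoluted HCTZ
    # residue via a leak slope fitted on the same pure-HCTZ standards.
    trim_fsd_unit = fsd(unit["TRIM"], fsd_cfg)
    nominal_h = cfg.fsd_read["HCTZ"]
    crossings = find_zero_crossings(trim_fsd_unit, (nominal_h - 20.0, nominal_h + 35.0))
    if not crossings:
        raise IsoPointNotFoundError(
            "no zero crossing of the deconvoluted interferent near "
            f"{nominal_h:g} nm; adjust the deconvolution settings"
        )
    lam_fsd_h = min(crossings, key=lambda lam: abs(lam - nominal_h))
    lam_fsd_t = cfg.fsd_read["TRIM"]

    hctz_fsd = _calibrate_signals(
        cfg,
        rng,
        models,
        "HCTZ",
        cfg.calibration_levels("FSD", "HCTZ"),
        {
            "read": lambda s: amplitude_at(fsd(s, fsd_cfg), lam_fsd_h),
            "leak": lambda s: amplitude_at(fsd(s, fsd_cfg), lam_fsd_t),
        },
        {
            "read": (f"HCTZ@{lam_fsd_h:.1f}nm(FSD)", "HCTZ"),
            "leak": (f"HCTZ@{lam_fsd_t:g}nm(FSD leak)", "HCTZ"),
        },
    )
    calibs[("FSD", "HCTZ")] = hctz_fsd["read"]
    fsd_leak_slope = hctz_fsd["leak"].slope
    calibs[("FSD", "TRIM")] = _calibrate_signals(
        cfg,
        rng,
        models,
        "TRIM",
        cfg.calibration_levels("FSD", "TRIM"),
        {"read": lambda s: amplitude_at(fsd(s, fsd_cfg), lam_fsd_t)},
        {"read": (f"TRIM@{lam_fsd_t:g}nm(FSD)", "TRIM")},
    )["read"]

    # Ratio channels use the model unit spectrum of the divisor analyte.
    channels: dict[tuple[str, str], RatioChannel] = {}
    for method in ("RDF", "RDM"):
        for analyte in _ANALYTES:
            rcfg = cfg.ratio_cfg[analyte]
            channel = RatioChannel(
                analyte=analyte,
                cfg=rcfg,
                divisor_unit=unit[rcfg.divisor_analyte],
                calibration=CalibrationModel(slope=1.0),  # placeholder until fitted
            )
            signal = channel.rdf_signal if method == "RDF" else channel.rdm_signal
            lam_txt = (
                f"dP{rcfg.rdf_pair[0]:g}-{rcfg.rdf_pair[1]:g}nm"
                if method == "RDF"
                else f"d/dl@{rcfg.rdm_wavelength:g}nm"
            )
            channel.calibration = _calibrate_signals(
                cfg,
                rng,
                models,
                analyte,
                cfg.calibration_levels(method, analyte),
                {"sig": lambda s, fn=signal: fn(s)},
                {"sig": (f"{analyte} {lam_txt}", analyte)},
            )["sig"]
            calibs[(method, analyte)] = channel.calibration
            channels[(method, analyte)] = channel

    methods = [
        FsdMethod(
            cfg=fsd_cfg,
            primary_analyte="HCTZ",
            lambda_primary=lam_fsd_h,
            calib_primary=calibs[("FSD", "HCTZ")],
            secondary_analyte="TRIM",
            lambda_secondary=lam_fsd_t,
            calib_secondary=calibs[("FSD", "TRIM")],
            leak_slope=fsd_leak_slope,
        ),
        IsmMethod(
            lambda_iso=lam_iso,
            calib_iso=calibs[("ISM", "HCTZ")],
            calib_free=calibs[("ISM", "TRIM")],
            lambda_free=acm_cfg.lambda_free,
            other_analyte="HCTZ",
        ),
        AcmMethod(
            cfg=acm_cfg,
            calib_interferent_at_free=calibs[("ACM", "TRIM")],
            calib_analyte_at_interfering=calibs[("ACM", "HCTZ")],
        ),
        RatioMethod(
            channels=[channels[("RDF", "HCTZ")], channels[("RDF", "TRIM")]],
            mode="difference",
            name="RDF",
        ),
        RatioMethod(
            channels=[channels[("RDM", "HCTZ")], channels[("RDM", "TRIM")]],
            mode="derivative",
            name="RDM",
        ),
    ]
    return MethodSuite(
        methods=methods,
        calibrations=calibs,
        channels=channels,
        unit_spectra=unit,
        lambda_iso=lam_iso,
        iso_candidates=iso.candidates,
        f_ac=f_ac,
        lambda_fsd_primary=lam_fsd_h,
        lambda_fsd_secondary=lam_fsd_t,
        fsd_leak_slope=fsd_leak_slope,
    )


@dataclass
class StudyReport:
    """Report bundle produced by :func:`run_study`."""

    config: StudyConfig
    lambda_iso: float
    f_ac: float
    calibrations: dict[tuple[str, str], CalibrationModel]
    calibration_table: pd.DataFrame
    mixture_table: pd.DataFrame
    mixture_summary: pd.DataFrame
    assay_table: pd.DataFrame
    standard_addition_table: pd.DataFrame
    anova_table: pd.DataFrame
    greenness: dict
    log: dict

    def mean_recovery(self, method: str, analyte: str) -> float:
        row = self.mixture_summary[
            (self.mixture_summary["method"] == method)
            & (self.mixture_summary["analyte"] == analyte)
        ]
        return float(row["mean_recovery"].iloc[0])

    def save(self, outdir: str | Path) -> None:
        """Write every table as CSV with a metadata header, plus the run log."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = (
            f"# config_hash: {self.config.config_hash()}\n"
            f"# seed: {self.config.seed}\n"
            f"# noise_sd: {self.config.noise_sd}\n"
        )
        tables = {
            "calibration_table.csv": self.calibration_table,
            "mixture_table.csv": self.mixture_table,
            "mixture_summary.csv": self.mixture_summary,
            "assay_table.csv": self.assay_table,
            "standard_addition_table.csv": self.standard_addition_table,
            "anova_table.csv": self.anova_table,
        }
        for name, frame in tables.items():
            with (outdir / name).open("w") as fh:
                fh.write(header)
                frame.to_csv(fh, index=False)
        with (outdir / "run_log.json").open("w") as fh:
            json.dump(self.log, fh, indent=2, default=str)
        with (outdir / "greenness.json").open("w") as fh:
            json.dump(self.greenness, fh, indent=2)


def run_study(cfg: StudyConfig, outdir: str | Path | None = None) -> StudyReport:
    """Execute the full simulated study described by ``cfg``.

    Deterministic for a fixed config (one seeded generator drives every
    random draw in a fixed order). Returns the report bundle; also
    writes it to ``outdir`` when given.
    """
    rng = np.random.default_rng(cfg.seed)
    models = {"HCTZ": preset_hctz(), "TRIM": preset_trim()}
    suite = build_method_suite(cfg, rng)
    methods = suite.methods

    calib_rows = []
    for (method, analyte), model in sorted(suite.calibrations.items()):
        calib_rows.append(
            {
                "method": method,
                "analyte": analyte,
                "label": model.label,
                "slope": model.slope,
                "intercept": model.intercept,
                "r": model.r,
                "sigma_resid": model.sigma_resid,
                "lod": model.lod,
                "loq": model.loq,
                "n": model.n,
                "range_low": model.conc_range[0],
                "range_high": model.conc_range[1],
            }
        )
    calibration_table = pd.DataFrame(calib_rows)

    # --- laboratory mixtures ----------------------------------------------
    mixture_rows = []
    per_method_recoveries: dict[tuple[str, str], list[float]] = {
        (m, a): [] for m in METHOD_NAMES for a in _ANALYTES
    }
    for c_hctz, c_trim in cfg.mixtures:
        rep_results: dict[tuple[str, str], list[float]] = {
            (m, a): [] for m in METHOD_NAMES for a in _ANALYTES
        }
        for _ in range(cfg.n_replicates):
            spec = _simulate(cfg, rng, models, [("HCTZ", c_hctz), ("TRIM", c_trim)])
            for res in resolve_all(spec, methods):
                if res.failed:
                    continue
                for analyte, truth in zip(_ANALYTES, (c_hctz, c_trim)):
                    rep_results[(res.method, analyte)].append(
                        recovery_percent(res.concentrations[analyte], truth)
                    )
        row = {"HCTZ_conc": c_hctz, "TRIM_conc": c_trim}
        for (method, analyte), recs in rep_results.items():
            mean_rec = float(np.mean(recs))
            row[f"{analyte}_{method}"] = mean_rec
            per_method_recoveries[(method, analyte)].append(mean_rec)
        mixture_rows.append(row)
    mixture_table = pd.DataFrame(mixture_rows)

    summary_rows = []
    for (method, analyte), recs in per_method_recoveries.items():
        mean, sd = mean_sd(recs)
        summary_rows.append(
            {"method": method, "analyte": analyte, "mean_recovery": mean, "sd_recovery": sd}
        )
    mixture_summary = pd.DataFrame(summary_rows)

    # --- dosage-form assay with reference comparison -----------------------
    dosage_recs: dict[tuple[str, str], list[float]] = {
        (m, a): [] for m in METHOD_NAMES for a in _ANALYTES
    }
    for _ in range(cfg.n_replicates):
        spec = _simulate(
            cfg,
            rng,
            models,
            [("HCTZ", cfg.dosage_form[0]), ("TRIM", cfg.dosage_form[1])],
            offset=cfg.excipient_offset,
        )
        for res in resolve_all(spec, methods):
            if res.failed:
                continue
            for analyte, truth in zip(_ANALYTES, cfg.dosage_form):
                dosage_recs[(res.method, analyte)].append(
                    recovery_percent(res.concentrations[analyte], truth)
                )
    # the reference assay is simulated as an unbiased method with the
    # configured recovery scatter (its raw data are external to this study)
    reference = {
        analyte: list(rng.normal(100.0, cfg.reference_recovery_sd, cfg.n_replicates))
        for analyte in _ANALYTES
    }
    assay_rows = []
    for analyte in _ANALYTES:
        ref = reference[analyte]
        ref_mean, ref_sd = mean_sd(ref)
        for method in METHOD_NAMES:
            recs = dosage_recs[(method, analyte)]
            mean, sd = mean_sd(recs)
            cmp_res = two_sample_t_f(recs, ref)
            assay_rows.append(
                {
                    "analyte": analyte,
                    "method": method,
                    "n": len(recs),
                    "mean_recovery": mean,
                    "rsd": 100.0 * sd / mean,
                    "variance": sd**2,
                    "t_stat": abs(cmp_res.t_stat),
                    "t_crit": cmp_res.t_crit,
                    "f_stat": cmp_res.f_stat,
                    "f_crit": cmp_res.f_crit,
                    "verdict": cmp_res.verdict,
                    "reference_mean": ref_mean,
                    "reference_rsd": 100.0 * ref_sd / ref_mean,
                }
            )
    assay_table = pd.DataFrame(assay_rows)

    # --- standard addition -------------------------------------------------
    base = {"HCTZ": cfg.dosage_form[0], "TRIM": cfg.dosage_form[1]}
    addition_rows = []
    for analyte in _ANALYTES:
        other = "TRIM" if analyte == "HCTZ" else "HCTZ"
        for method_name in METHOD_NAMES:
            method_obj = next(m for m in methods if m.name == method_name)
            found_totals = []
            for added in cfg.standard_addition_added:
                reps = []
                for _ in range(cfg.n_replicates):
                    spec = _simulate(
                        cfg,
                        rng,
                        models,
                        [(analyte, base[analyte] + added), (other, base[other])],
                        offset=cfg.excipient_offset,
                    )
                    reps.append(method_obj.resolve(spec).concentrations[analyte])
                found_totals.append(float(np.mean(reps)))
            sa = standard_addition(base[analyte], cfg.standard_addition_added, found_totals)
            for added, total, rec in zip(sa.added, found_totals, sa.recoveries):
                addition_rows.append(
                    {
                        "analyte": analyte,
                        "method": method_name,
                        "base_taken": base[analyte],
                        "added": added,
                        "total_found": total,
                        "recovery_of_added": rec,
                    }
                )
            addition_rows.append(
                {
                    "analyte": analyte,
                    "method": method_name,
                    "base_taken": base[analyte],
                    "added": np.nan,
                    "total_found": np.nan,
                    "recovery_of_added": sa.mean,
                }
            )
    standard_addition_table = pd.DataFrame(addition_rows)

    # --- one-way ANOVA across methods + reference --------------------------
    anova_rows = []
    for analyte in _ANALYTES:
        groups = [dosage_recs[(m, analyte)] for m in METHOD_NAMES]
        groups.append(reference[analyte])
        res = one_way_anova(groups)
        anova_rows.append(
            {
                "analyte": analyte,
                "ss_between": res.ss_between,
                "df_between": res.df_between,
                "ms_between": res.ms_between,
                "ss_within": res.ss_within,
                "df_within": res.df_within,
                "ms_within": res.ms_within,
                "f": res.f,
                "p": res.p,
                "eta_squared": res.eta_squared,
            }
        )
    anova_table = pd.DataFrame(anova_rows)

    # --- greenness ----------------------------------------------------------
    greenness = {
        "agree_direct_uv": round(agree_score(EXAMPLE_AGREE_DIRECT_UV), 2),
        "agree_reference": round(agree_score(EXAMPLE_AGREE_REFERENCE), 2),
        "gapi_direct_uv_counts": gapi_summary(EXAMPLE_GAPI_DIRECT_UV).counts,
        "note": "illustrative example profiles; principle-level inputs are method-specific",
    }

    n_masked = {
        f"{method}:{analyte}": int(
            ch.make_ratio(suite.unit_spectra[analyte]).meta["n_masked"]
        )
        for (method, analyte), ch in suite.channels.items()
    }
    log = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "lambda_iso": suite.lambda_iso,
        "iso_candidates": list(suite.iso_candidates),
        "f_ac": suite.f_ac,
        "fsd_read_hctz_nm": suite.lambda_fsd_primary,
        "fsd_read_trim_nm": suite.lambda_fsd_secondary,
        "fsd_leak_slope": suite.fsd_leak_slope,
        "masked_points_per_ratio_channel": n_masked,
    }

    report = StudyReport(
        config=cfg,
        lambda_iso=suite.lambda_iso,
        f_ac=suite.f_ac,
        calibrations=suite.calibrations,
        calibration_table=calibration_table,
        mixture_table=mixture_table,
        mixture_summary=mixture_summary,
        assay_table=assay_table,
        standard_addition_table=standard_addition_table,
        anova_table=anova_table,
        greenness=greenness,
        log=log,
    )
    if outdir is not None:
        report.save(outdir)
    return report
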