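"""Synthetic absorptivity spectra, mixture measurements and solvent ranking.

The generator produces unit-concentration (absorptivity) spectra from a
parametric band model and noisy Beer–Lambert mixture measurements, so the
whole resolution/validation pipeline can be exercised without instrument
data. The built-in presets emulate the hydrochlorothiazide (HCTZ) /
triamterene (TRIM) system in ethanol:

* HCTZ absorbs with maxima at 271 nm and 221 nm and is spectroscopically
  silent at 361 nm (the "no-contribution" point used to read TRIM).
* TRIM's main band sits at 361 nm, with a secondary band at shorter
  wavelengths that produces an isoabsorptive crossing with HCTZ near
  266.8 nm and supports the 244–293 nm ratio-spectra working regions.

Band positions (271/221/361 nm) and the crossing anchor are measured
facts of the system; band widths and absorptivities are tuned constants
chosen to reproduce that structure (no molar absorptivities are published
for this solvent system). The absorptivity scale is anchored so that the
unit absorbances at the absorption-correction wavelengths are
a_HCTZ(271) = 0.0690 and a_TRIM(361) = 0.0803 AU·mL/µg.

Solvent effects are modelled as a multiplicative band broadening plus an
additive center shift — stronger solute–solvent interaction broadens the
bands — and :func:`rank_solvents` implements the in-silico solvent
pre-selection rule: exclude solvents with exothermic solvation, then rank
the rest by ascending interaction-energy magnitude with the analyte of
interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .spectra import Spectrum, WavelengthGrid

__all__ = [
    "Band",
    "AnalyteModel",
    "SolventModel",
    "SolventDescriptors",
    "SolventVerdict",
    "ETHANOL",
    "preset_hctz",
    "preset_trim",
    "absorptivity_spectrum",
    "simulate_measurement",
    "broadening_from_interaction",
    "rank_solvents",
]

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class Band:
    """A single absorption band of peak-normalised gaussian or lorentzian shape.

    ``peak_absorptivity`` is the band height at its center for a
    1 µg/mL solution (AU·mL/µg); ``fwhm`` is the full width at half
    maximum in nm.
    """

    center: float
    fwhm: float
    peak_absorptivity: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"band fwhm must be positive, got {self.fwhm}")
        if self.peak_absorptivity < 0:
            raise ValueError("peak_absorptivity must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def evaluate(self, wavelengths: np.ndarray, solvent: "SolventModel") -> np.ndarray:
        center = self.center + solvent.shift
        fwhm = self.fwhm * solvent.broadening_factor
        x = wavelengths - center
        if self.shape == "gaussian":
            return self.peak_absorptivity * np.exp(-4.0 * _LN2 * (x / fwhm) ** 2)
        gamma = fwhm / 2.0  # lorentzian HWHM
        return self.peak_absorptivity * gamma**2 / (x**2 + gamma**2)


@dataclass
class AnalyteModel:
    """A named analyte as a sum of bands (unit-concentration scale)."""

    name: str
    bands: list[Band]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError(f"analyte {self.name!r} needs at least one band")


@dataclass(frozen=True)
class SolventModel:
    """Solvent effect on band structure.

    ``broadening_factor`` multiplies every band FWHM (stronger
    solute–solvent interaction -> broader bands); ``shift`` is an
    additive displacement of band centers in nm.
    """

    name: str
    broadening_factor: float = 1.0
    shift: float = 0.0

    def __post_init__(self) -> None:
        if self.broadening_factor <= 0:
            raise ValueError("broadening_factor must be positive")


#: Reference solvent of the study: ethanol, defined as the unit condition.
ETHANOL = SolventModel("ethanol", broadening_factor=1.0, shift=0.0)


def preset_hctz() -> AnalyteModel:
    """Hydrochlorothiazide model: bands at 271 and 221 nm.

    The 271 nm absorptivity (0.0690 AU·mL/µg) anchors the absorbance
    scale; the gaussian tails make the 361 nm absorptivity < 1e-10 of the
    271 nm value, reproducing the no-contribution point used to read TRIM.
    """
    return AnalyteModel(
        name="HCTZ",
        bands=[
            Band(center=271.0, fwhm=30.0, peak_absorptivity=0.0690),
            Band(center=221.0, fwhm=22.0, peak_absorptivity=0.0850),
        ],
    )


def preset_trim() -> AnalyteModel:
    """Triamterene model: dominant band at 361 nm plus a 255 nm band.

    The secondary band width/height are tuned so the unit-concentration
    spectrum crosses the HCTZ preset between 265 and 268.5 nm (the
    isoabsorptive point of the real system sits at 266.8 nm) while the
    global maximum stays at 361 nm.
    """
    return AnalyteModel(
        name="TRIM",
        bands=[
            Band(center=361.0, fwhm=40.0, peak_absorptivity=0.0803),
            Band(center=255.0, fwhm=52.0, peak_absorptivity=0.0750),
        ],
    )


def absorptivity_spectrum(
    m: AnalyteModel, solv: SolventModel, g: WavelengthGrid
) -> Spectrum:
    """Unit-concentration absorptivity spectrum of ``m`` in solvent ``solv`` on ``g``.

    Bands shifted outside the grid are still evaluated (their in-grid tail
    is kept) but a warning is recorded in the metadata.
    """
    w = g.wavelengths()
    a = np.zeros_like(w)
    warnings: list[str] = []
    for band in m.bands:
        center = band.center + solv.shift
        if not (g.start <= center <= g.stop):
            warnings.append(
                f"band center {center:.1f} nm (shifted) outside grid "
                f"[{g.start}, {g.stop}] nm"
            )
        a += band.evaluate(w, solv)
    meta = {"analyte": m.name, "solvent": solv.name, "kind": "absorptivity"}
    if warnings:
        meta["warnings"] = warnings
    return Spectrum(w, a, meta=meta)


def simulate_measurement(
    components: Sequence[tuple[AnalyteModel, float]],
    solv: SolventModel,
    noise_sd: float,
    seed: int | np.random.Generator,
    g: WavelengthGrid,
) -> Spectrum:
    """Simulate a blank-corrected mixture measurement.

    A(λ) = Σ_i c_i · a_i(λ) + ε(λ) with ε i.i.d. N(0, noise_sd²) — i.e.
    Beer–Lambert additivity plus homoscedastic instrument noise. With
    ``noise_sd == 0`` the output is the exact weighted sum of the
    component unit spectra regardless of the seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for model, conc in components:
        if conc < 0:
            raise ValueError(
                f"negative concentration {conc} µg/mL for {model.name!r}"
            )
    w = g.wavelengths()
    a = np.zeros_like(w)
    labels = []
    for model, conc in components:
        a += conc * absorptivity_spectrum(model, solv, g).absorbances
        labels.append(f"{model.name}={conc:g}")
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sd, size=w.size)
    meta = {
        "solvent": solv.name,
        "composition": "+".join(labels) if labels else "blank",
        "noise_sd": noise_sd,
    }
    return Spectrum(w, a, meta=meta)


def broadening_from_interaction(interaction_energy: float, k: float = 0.02) -> float:
    """Map a solute–solvent interaction-energy magnitude to a broadening factor.

    Illustrative linear rule ``1 + k·|E|``: stronger interaction, broader
    bands. The direction is physical, the functional form and ``k``
    (per kcal/mol) are demonstration choices only.
    """
    return 1.0 + k * abs(interaction_energy)


_DESCRIPTOR_COLUMNS = (
    "solvent",
    "analyte",
    "solvation_energy",
    "hb_capacity",
    "interaction_energy",
    "dipole",
    "dielectric",
)


@dataclass
class SolventDescriptors:
    """Per-(solvent, analyte) descriptor table from in-silico simulations.

    Columns: solvent, analyte, solvation_energy (kcal/mol; negative =
    exothermic), hb_capacity, interaction_energy (kcal/mol magnitude),
    dipole (Debye), dielectric (ɛ).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _DESCRIPTOR_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataError(f"descriptor table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SolventDescriptors":
        return cls(pd.read_csv(path))

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "SolventDescriptors":
        return cls(pd.DataFrame.from_records(list(records)))

    def solvents(self) -> list[str]:
        """Solvent names in first-appearance order."""
        return list(dict.fromkeys(self.table["solvent"]))

    def row(self, solvent: str, analyte: str) -> pd.Series:
        sel = self.table[
            (self.table["solvent"] == solvent) & (self.table["analyte"] == analyte)
        ]
        if sel.empty:
            raise DataError(f"no descriptor row for solvent {solvent!r}, analyte {analyte!r}")
        row = sel.iloc[0]
        for col in _DESCRIPTOR_COLUMNS[2:]:
            if pd.isna(row[col]):
                raise DataError(f"missing {col!r} for solvent {solvent!r}, analyte {analyte!r}")
        return row


@dataclass(frozen=True)
class SolventVerdict:
    """Outcome of the solvent pre-selection rule for one solvent."""

    solvent: str
    verdict: str  # "candidate" or "excluded"
    rationale: str
    rank: int | None = None
    interaction_energy: float | None = None


def rank_solvents(
    d: SolventDescriptors, analyte_of_interest: str
) -> list[SolventVerdict]:
    """Apply the in-silico solvent pre-selection rule.

    Solvents whose solvation energy is exothermic (negative) for *any*
    analyte in the table are excluded outright. The remaining candidates
    are ranked by ascending interaction-energy magnitude with
    ``analyte_of_interest`` — the least-interacting solvent broadens that
    analyte's bands least and heads the list. Ties break on lower
    dielectric constant, then input order.

    Returns ranked candidates first (``rank`` 1, 2, ...), then excluded
    solvents in input order.
    """
    analytes = list(dict.fromkeys(d.table["analyte"]))
    if analyte_of_interest not in analytes:
        raise DataError(f"analyte {analyte_of_interest!r} absent from descriptor table")
    candidates: list[tuple[float, float, int, str, float]] = []
    excluded: list[SolventVerdict] = []
    for order, solvent in enumerate(d.solvents()):
        rows = {a: d.row(solvent, a) for a in analytes}
        exo = [a for a in analytes if rows[a]["solvation_energy"] < 0]
        if exo:
            excluded.append(
                SolventVerdict(
                    solvent=solvent,
                    verdict="excluded",
                    rationale=(
                        "exothermic solvation for "
                        + ", ".join(exo)
                        + " (strong solvent binding; expected band broadening)"
                    ),
                )
            )
            continue
        row = rows[analyte_of_interest]
        energy = abs(float(row["interaction_energy"]))
        candidates.append((energy, float(row["dielectric"]), order, solvent, energy))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    ranked = [
        SolventVerdict(
            solvent=name,
            verdict="candidate",
            rationale=(
                f"|interaction energy| with {analyte_of_interest} = {energy:g} kcal/mol"
            ),
            rank=i + 1,
            interaction_energy=energy,
        )
        for i, (_, _, _, name, energy) in enumerate(candidates)
    ]
    return ranked + excluded
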