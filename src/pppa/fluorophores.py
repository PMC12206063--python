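"""Photophysical models of fluorescent proteins and reference absorbers.

The pump-probe contrast mechanism is driven by four spectral quantities per
species: the molar extinction ``epsilon(lambda)`` (absorption), the normalized
fluorescence emission spectrum, the stimulated-emission cross section
``sigma_e(lambda)``, and the excited-state lifetime ``tau``.  This module
provides containers for those quantities, unit conversions between molar
extinction, absorption cross section and absorption coefficient, and presets
for the three red fluorescent proteins used throughout the package
(Katushka, mNeptune, mCardinal) plus a non-fluorescent CrCl3/CoCl2 reference
absorber.

The preset spectra are *synthetic surrogates*: measured spectra for these
proteins are not tabulated anywhere in machine-readable form, so the presets
use Gaussian band shapes (main band + vibronic shoulder) whose peak
wavelengths, peak extinctions, lifetimes and concentrations are set to
literature-typical values.  Peak positions are chosen so that the Katushka
absorption band lies exactly 20 nm blue of the mNeptune/mCardinal bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23  # 1/mol
LN10 = float(np.log(10.0))
#: h*c in J*nm, so that HC_JNM / lambda_nm is a photon energy in joules.
HC_JNM = 1.98644586e-16

PRESET_NAMES = ("katushka", "mneptune", "mcardinal")

__all__ = [
    "SpectrumCurve",
    "FluorophoreModel",
    "AbsorberModel",
    "build_preset",
    "build_nonfluorescent",
    "extinction_to_cross_section",
    "absorption_coefficient",
    "synthesize_absorption",
    "synthesize_emission",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class SpectrumCurve:
    """A nonnegative spectral curve on a strictly ascending wavelength grid.

    Evaluation outside the tabulated grid returns 0 (spectra are assumed to
    have decayed to baseline at the grid edges).
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength grid must be 1-D with >= 2 points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if vals.shape != wl.shape:
            raise ValueError("values and wavelengths must have equal shape")
        if np.any(vals < 0):
            raise ValueError("spectral values must be nonnegative")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)

    def __call__(self, lambda_nm):
        return np.interp(lambda_nm, self.wavelengths_nm, self.values,
                         left=0.0, right=0.0)

    @property
    def peak_wavelength_nm(self) -> float:
        return float(self.wavelengths_nm[int(np.argmax(self.values))])

    @property
    def peak_value(self) -> float:
        return float(np.max(self.values))

    def scaled(self, factor: float) -> "SpectrumCurve":
        if factor < 0:
            raise ValueError("scale factor must be nonnegative")
        return SpectrumCurve(self.wavelengths_nm, self.values * factor)

    @classmethod
    def from_csv(cls, path) -> "SpectrumCurve":
        """Read a curve from a two-column CSV (wavelength_nm, value)."""
        df = pd.read_csv(path)
        if "wavelength_nm" not in df.columns:
            raise ValueError(f"{path}: expected a 'wavelength_nm' column")
        value_col = [c for c in df.columns if c != "wavelength_nm"][0]
        return cls(df["wavelength_nm"].to_numpy(), df[value_col].to_numpy())

    def to_csv(self, path, value_name: str = "value") -> None:
        pd.DataFrame({"wavelength_nm": self.wavelengths_nm,
                      value_name: self.values}).to_csv(path, index=False)


def extinction_to_cross_section(extinction):
    """Convert molar extinction (M^-1 cm^-1) to absorption cross section (cm^2).

    sigma = ln(10) * epsilon * 1000 / N_A  (the factor 1000 converts litres
    to cm^3 in the molar concentration).
    """
    eps = np.asarray(extinction, dtype=float)
    if np.any(eps < 0):
        raise ValueError("extinction must be nonnegative")
    sigma = LN10 * eps * 1000.0 / AVOGADRO
    return float(sigma) if np.isscalar(extinction) else sigma


@dataclass(frozen=True)
class FluorophoreModel:
    """One fluorescent species in solution.

    Parameters
    ----------
    extinction : SpectrumCurve
        Molar extinction spectrum, M^-1 cm^-1.
    emission : SpectrumCurve
        Fluorescence emission spectrum, normalized to unit peak.
    se_cross_section : SpectrumCurve
        Stimulated-emission cross section, cm^2.
    lifetime_ns : float
        Excited-state (fluorescence) lifetime tau, ns.
    quantum_yield : float
        Fluorescence quantum yield, in [0, 1].
    concentration_uM : float
        Molar concentration of the solution, micromolar.
    """

    name: str
    extinction: SpectrumCurve
    emission: SpectrumCurve
    se_cross_section: SpectrumCurve
    lifetime_ns: float
    quantum_yield: float
    concentration_uM: float
    fluorescent: bool = field(default=True, init=False)

    def __post_init__(self) -> None:
        if self.lifetime_ns <= 0:
            raise ValueError("lifetime must be positive")
        if not 0.0 <= self.quantum_yield <= 1.0:
            raise ValueError("quantum yield must lie in [0, 1]")
        if self.concentration_uM < 0:
            raise ValueError("concentration must be nonnegative")
        if self.emission.peak_wavelength_nm <= self.extinction.peak_wavelength_nm:
            raise ValueError("Stokes shift must be positive "
                             "(emission peak must be red of absorption peak)")

    # -- derived quantities -------------------------------------------------
    @property
    def number_density_cm3(self) -> float:
        """Molecules per cm^3 at the model concentration."""
        return self.concentration_uM * 1e-6 * AVOGADRO / 1000.0

    @property
    def emission_peak_nm(self) -> float:
        return self.emission.peak_wavelength_nm

    @property
    def gap_energy_J(self) -> float:
        """Effective electronic gap energy: photon energy at the emission peak."""
        return HC_JNM / self.emission_peak_nm

    def sigma_a(self, lambda_nm):
        """Absorption cross section at lambda, cm^2."""
        return extinction_to_cross_section(1.0) * self.extinction(lambda_nm)

    def sigma_e(self, lambda_nm):
        """Stimulated-emission cross section at lambda, cm^2."""
        return self.se_cross_section(lambda_nm)

    def mua(self, lambda_nm):
        """Absorption coefficient of the solution at lambda, cm^-1."""
        return absorption_coefficient(self, lambda_nm)


def absorption_coefficient(model: FluorophoreModel, lambda_nm) -> float:
    """mu_a(lambda) = ln(10) * epsilon(lambda) * c, in cm^-1 (c in mol/L).

    Wavelengths outside the tabulated extinction grid evaluate to 0 and emit
    a logged warning.
    """
    wl = np.asarray(lambda_nm, dtype=float)
    grid = model.extinction.wavelengths_nm
    if np.any(wl < grid[0]) or np.any(wl > grid[-1]):
        logger.warning(
            "wavelength %s nm outside extinction grid [%g, %g] of %s; "
            "treating extinction as 0", lambda_nm, grid[0], grid[-1], model.name
        )
    mua = LN10 * model.extinction(lambda_nm) * model.concentration_uM * 1e-6
    return float(mua) if np.isscalar(lambda_nm) else mua


@dataclass(frozen=True)
class AbsorberModel:
    """A non-fluorescent absorber described directly by mu_a(lambda), cm^-1."""

    name: str
    mua_curve: SpectrumCurve
    fluorescent: bool = field(default=False, init=False)

    def mua(self, lambda_nm):
        return self.mua_curve(lambda_nm)


# ---------------------------------------------------------------------------
# Synthetic band shapes
# ---------------------------------------------------------------------------

def _gaussian(lambda_nm, center_nm, fwhm_nm):
    s = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((lambda_nm - center_nm) / s) ** 2)

# Composite absorption shape: main band + 0.3-amplitude vibronic shoulder
# 30 nm to the blue.  The shoulder pulls the composite maximum slightly blue
# of the main-band center; _SHOULDER_OFFSET is that constant shape offset,
# used to re-center so the composite peaks exactly at the nominal wavelength.
_ABS_FWHM = 60.0
_EM_FWHM = 70.0
_SHOULDER_SHIFT = 30.0
_SHOULDER_AMP = 0.3


def _abs_shape(lambda_nm, center_nm):
    return (_gaussian(lambda_nm, center_nm, _ABS_FWHM)
            + _SHOULDER_AMP * _gaussian(lambda_nm, center_nm - _SHOULDER_SHIFT,
                                        _ABS_FWHM))


def _shoulder_offset() -> float:
    x = np.linspace(-40.0, 20.0, 60001)
    return float(-x[int(np.argmax(_abs_shape(x, 0.0)))])


_ABS_PEAK_OFFSET = _shoulder_offset()


def synthesize_absorption(peak_nm: float, peak_extinction: float,
                          grid_nm: np.ndarray | None = None) -> SpectrumCurve:
    """Synthetic molar-extinction spectrum peaking at ``peak_nm``.

    Main Gaussian band (FWHM 60 nm) plus a 0.3-amplitude vibronic shoulder
    30 nm to the blue, re-centered so the composite maximum sits at
    ``peak_nm`` with value ``peak_extinction`` (M^-1 cm^-1).
    """
    if grid_nm is None:
        grid_nm = np.arange(440.0, 761.0, 1.0)
    center = peak_nm + _ABS_PEAK_OFFSET
    shape = _abs_shape(grid_nm, center)
    shape = shape / _abs_shape(np.array([peak_nm]), center)[0]
    return SpectrumCurve(grid_nm, peak_extinction * shape)


def synthesize_emission(peak_nm: float,
                        grid_nm: np.ndarray | None = None) -> SpectrumCurve:
    """Synthetic unit-peak Gaussian emission spectrum (FWHM 70 nm)."""
    if grid_nm is None:
        grid_nm = np.arange(440.0, 761.0, 1.0)
    return SpectrumCurve(grid_nm, _gaussian(grid_nm, peak_nm, _EM_FWHM))


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _preset_dir():
    return resources.files("pppa") / "data" / "presets"


def build_preset(name: str, data_dir=None) -> FluorophoreModel:
    """Load one of the shipped fluorescent-protein presets.

    Valid names: ``katushka``, ``mneptune``, ``mcardinal``.  Spectra are read
    from the packaged CSV files (columns ``wavelength_nm``, value); photo-
    physical scalars from the companion YAML.  ``data_dir`` overrides the
    packaged data location, accepting user files in the same dialect.
    """
    key = name.strip().lower()
    if key not in PRESET_NAMES:
        raise ValueError(
            f"unknown fluorophore preset {name!r}; valid presets: "
            + ", ".join(PRESET_NAMES)
        )
    base = Path(data_dir) if data_dir is not None else _preset_dir()
    with (base / f"{key}.yaml").open("r") as fh:
        meta = yaml.safe_load(fh)
    extinction = SpectrumCurve.from_csv(base / f"{key}_absorption.csv")
    emission = SpectrumCurve.from_csv(base / f"{key}_emission.csv")
    sigma_peak = extinction_to_cross_section(float(meta["peak_extinction_M_cm"]))
    se_ratio = float(meta.get("se_peak_ratio", 1.0))
    se = emission.scaled(sigma_peak * se_ratio)
    return FluorophoreModel(
        name=meta["name"],
        extinction=extinction,
        emission=emission,
        se_cross_section=se,
        lifetime_ns=float(meta["lifetime_ns"]),
        quantum_yield=float(meta["quantum_yield"]),
        concentration_uM=float(meta["concentration_uM"]),
    )


def build_nonfluorescent(level=None, name: str = "crcl3_cocl2",
                         grid_nm: np.ndarray | None = None) -> AbsorberModel:
    """Build a non-fluorescent reference absorber (CrCl3/CoCl2 surrogate).

    ``level`` may be None (default spectrum rising smoothly from 1 cm^-1 at
    500 nm to 4 cm^-1 at 680 nm), a scalar mu_a in cm^-1 (flat spectrum), or
    a SpectrumCurve in cm^-1.
    """
    if isinstance(level, SpectrumCurve):
        return AbsorberModel(name=name, mua_curve=level)
    if grid_nm is None:
        grid_nm = np.arange(440.0, 761.0, 1.0)
    if level is None:
        mua = 1.0 + 3.0 * np.clip((grid_nm - 500.0) / 180.0, 0.0, 1.0)
    else:
        level = float(level)
        if level < 0:
            raise ValueError("mu_a must be nonnegative")
        mua = np.full_like(grid_nm, level, dtype=float)
    return AbsorberModel(name=name, mua_curve=SpectrumCurve(grid_nm, mua))
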