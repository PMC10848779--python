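"""Wavelength-resolved bookkeeping for irradiation experiments.

Absorption and emission spectra, photon flux of a polychromatic source,
competitive (inner-filter) Beer-Lambert absorption and the absorbed photon /
energy rates that drive the photokinetic model.

Conventions
-----------
* Wavelengths are vacuum nanometres on strictly increasing grids within
  [200, 700] nm.
* Molar absorption coefficients are decadic, M^-1 cm^-1.
* Emission densities are probability densities over wavelength (nm^-1),
  normalised to unit trapezoid integral.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import HC_J_M

WAVELENGTH_BOUNDS_NM = (200.0, 700.0)

#: Default common wavelength grid: 1 nm spacing over 220-340 nm.  The 15 nm
#: wide LED band and the 266 nm probe are both well resolved at this spacing.
DEFAULT_GRID_NM = np.arange(220.0, 341.0, 1.0)

MOLAR_ABSORPTION = "molar_absorption"
EMISSION_DENSITY = "emission_density"
_KINDS = (MOLAR_ABSORPTION, EMISSION_DENSITY)

_EMISSION_NORM_TOL = 1e-6


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-resolved quantity on a strictly increasing grid.

    Parameters
    ----------
    wavelengths_nm :
        Strictly increasing wavelengths within [200, 700] nm.
    values :
        Nonnegative values; molar absorption coefficients (M^-1 cm^-1) or a
        normalised emission density (nm^-1) depending on ``kind``.
    kind :
        ``"molar_absorption"`` or ``"emission_density"``.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if self.kind not in _KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}; expected one of {_KINDS}")
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be equal-length 1-D arrays")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two grid points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if wl[0] < WAVELENGTH_BOUNDS_NM[0] or wl[-1] > WAVELENGTH_BOUNDS_NM[1]:
            raise ValueError(f"wavelengths must lie within {WAVELENGTH_BOUNDS_NM} nm")
        if np.any(vals < 0):
            raise ValueError("spectrum values must be nonnegative")
        if self.kind == EMISSION_DENSITY:
            integral = np.trapezoid(vals, wl)
            if abs(integral - 1.0) > _EMISSION_NORM_TOL:
                raise ValueError(
                    f"emission density must integrate to 1 (got {integral:.8f})"
                )

    def value_at(self, wavelength_nm: float) -> float:
        """Linear interpolation; 0 outside the tabulated support."""
        return float(
            np.interp(wavelength_nm, self.wavelengths_nm, self.values, left=0.0, right=0.0)
        )

    @property
    def support_nm(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])


@dataclass(frozen=True)
class Beam:
    """A polychromatic light source at the sample position.

    ``emission`` is the normalised spectral shape; ``power_W`` the total
    average radiant power actually reaching the sample.
    """

    emission: Spectrum
    power_W: float

    def __post_init__(self):
        if self.emission.kind != EMISSION_DENSITY:
            raise ValueError("beam emission must be an emission_density spectrum")
        if self.power_W < 0 or not np.isfinite(self.power_W):
            # zero power is allowed (a switched-off source: q = 0 everywhere)
            raise ValueError("beam power must be finite and nonnegative")


@dataclass(frozen=True)
class SampleCell:
    """Irradiated cuvette geometry (well mixed, uniform path)."""

    path_length_cm: float = 1.0
    volume_L: float = 200e-6
    temperature_note: str = "ambient"

    def __post_init__(self):
        if not self.path_length_cm > 0:
            raise ValueError("path length must be positive")
        if not self.volume_L > 0:
            raise ValueError("cell volume must be positive")


def gaussian_emission(
    center_nm: float = 285.0,
    fwhm_nm: float = 15.0,
    grid_nm: np.ndarray | None = None,
) -> Spectrum:
    """Gaussian emission profile truncated at +/- 3 sigma and renormalised.

    Default models the irradiation LED: centered at 285 nm, 15 nm FWHM.
    """
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if grid_nm is None:
        grid_nm = DEFAULT_GRID_NM
    grid_nm = np.asarray(grid_nm, dtype=float)
    vals = np.exp(-0.5 * ((grid_nm - center_nm) / sigma) ** 2)
    vals[np.abs(grid_nm - center_nm) > 3.0 * sigma] = 0.0
    integral = np.trapezoid(vals, grid_nm)
    if integral <= 0:
        raise ValueError("emission band does not overlap the wavelength grid")
    return Spectrum(grid_nm, vals / integral, EMISSION_DENSITY)


def resample_to_grid(spectrum: Spectrum, grid_nm: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto a new wavelength grid.

    Outside the original support the value is 0.  Emission densities are
    renormalised to unit integral on the new grid.  The grid may extend at
    most 5 nm beyond the original support on either side.
    """
    grid_nm = np.asarray(grid_nm, dtype=float)
    if grid_nm.ndim != 1 or grid_nm.size < 2 or not np.all(np.diff(grid_nm) > 0):
        raise ValueError("target grid must be a strictly increasing 1-D array")
    lo, hi = spectrum.support_nm
    if grid_nm[0] < lo - 5.0 or grid_nm[-1] > hi + 5.0:
        raise ValueError(
            f"target grid [{grid_nm[0]}, {grid_nm[-1]}] nm extends more than 5 nm "
            f"beyond the spectrum support [{lo}, {hi}] nm"
        )
    vals = np.interp(grid_nm, spectrum.wavelengths_nm, spectrum.values, left=0.0, right=0.0)
    if spectrum.kind == EMISSION_DENSITY:
        integral = np.trapezoid(vals, grid_nm)
        if integral <= 0:
            raise ValueError("resampled emission has zero integral on the target grid")
        vals = vals / integral
    return Spectrum(grid_nm, vals, spectrum.kind)


@dataclass(frozen=True)
class PhotonFlux:
    """Spectral photon rate q(lambda) of a beam (photons s^-1 nm^-1)."""

    wavelengths_nm: np.ndarray
    flux_per_nm: np.ndarray

    @property
    def total_photon_rate(self) -> float:
        """Total photons s^-1 emitted by the source."""
        return float(np.trapezoid(self.flux_per_nm, self.wavelengths_nm))

    @property
    def power_W(self) -> float:
        """Energy closure: integral of q(lambda) * hc/lambda."""
        e_ph = HC_J_M / (self.wavelengths_nm * 1e-9)
        return float(np.trapezoid(self.flux_per_nm * e_ph, self.wavelengths_nm))


def photon_flux_density(beam: Beam) -> PhotonFlux:
    """Spectral photon rate q(lambda) = P * s(lambda) * lambda / (h c).

    Since s(lambda) is normalised, integral q * (hc/lambda) dlambda recovers
    the beam power exactly (trapezoid rule on the emission grid).
    """
    wl = beam.emission.wavelengths_nm
    q = beam.power_W * beam.emission.values * (wl * 1e-9) / HC_J_M
    return PhotonFlux(wl, q)


@dataclass(frozen=True)
class AbsorptionPartition:
    """Competitive absorption of a beam by a mixture of chromophores.

    Attributes
    ----------
    A_species :
        (n_species, n_wavelengths) decadic absorbances epsilon_i * c_i * l.
    A_total :
        Summed absorbance spectrum.
    photon_rate_per_species :
        R_i, photons s^-1 absorbed by each species (inner-filter corrected).
    energy_dose_rate_W :
        Radiant power (W = J s^-1) absorbed by the whole sample; integrating
        it over time gives the absorbed dose in J.
    """

    wavelengths_nm: np.ndarray
    A_species: np.ndarray
    A_total: np.ndarray
    photon_rate_per_species: np.ndarray
    energy_dose_rate_W: float

    @property
    def total_absorbed_photon_rate(self) -> float:
        return float(self.photon_rate_per_species.sum())


def absorption_partition(
    epsilons: list[Spectrum],
    concentrations_M: np.ndarray,
    cell: SampleCell,
    beam: Beam,
) -> AbsorptionPartition:
    """Partition the absorbed photon stream among competing absorbers.

    Per species i, R_i = integral q(lambda) (1 - 10^-A_tot) (A_i / A_tot)
    dlambda; the absorbed fraction times the species' share of the total
    absorbance.  For A_tot -> 0 the factor is evaluated by its series limit
    ln(10) * A_i to avoid 0/0.

    All epsilon spectra and the beam emission must share one wavelength grid.
    """
    conc = np.asarray(concentrations_M, dtype=float)
    if len(epsilons) != conc.size:
        raise ValueError("need one concentration per epsilon spectrum")
    if np.any(conc < 0):
        raise ValueError("concentrations must be nonnegative")
    wl = beam.emission.wavelengths_nm
    for eps in epsilons:
        if eps.kind != MOLAR_ABSORPTION:
            raise ValueError("epsilons must be molar_absorption spectra")
        if eps.wavelengths_nm.shape != wl.shape or not np.allclose(
            eps.wavelengths_nm, wl
        ):
            raise ValueError(
                "epsilon spectra must be resampled to the beam emission grid"
            )

    eps_mat = np.vstack([eps.values for eps in epsilons])  # (n_species, n_wl)
    A_species = eps_mat * conc[:, None] * cell.path_length_cm
    A_total = A_species.sum(axis=0)

    q = photon_flux_density(beam)
    # fraction-of-total share, series-expanded where optically thin
    factor = np.empty_like(A_total)
    thin = A_total < 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        factor[~thin] = (1.0 - 10.0 ** (-A_total[~thin])) / A_total[~thin]
    factor[thin] = np.log(10.0)
    absorbed_spectral = q.flux_per_nm * factor * A_species  # per species, per nm
    R_i = np.trapezoid(absorbed_spectral, wl, axis=1)

    e_ph = HC_J_M / (wl * 1e-9)
    energy_rate = float(
        np.trapezoid(q.flux_per_nm * (1.0 - 10.0 ** (-A_total)) * e_ph, wl)
    )
    return AbsorptionPartition(wl, A_species, A_total, R_i, energy_rate)


def effective_epsilon(epsilon: Spectrum, beam: Beam) -> float:
    """Photon-weighted mean molar absorption coefficient over the beam band.

    epsilon_bar = integral s(lambda) lambda eps(lambda) dlambda /
                  integral s(lambda) lambda dlambda

    (weighting by s * lambda because the photon rate, not the power, drives
    photochemistry).  Raises if the beam emission lies entirely outside the
    spectrum support.
    """
    wl = beam.emission.wavelengths_nm
    support = beam.emission.values > 0
    lo, hi = epsilon.support_nm
    if wl[support].size == 0 or wl[support][-1] < lo or wl[support][0] > hi:
        raise ValueError("beam outside spectrum support")
    eps_vals = np.interp(wl, epsilon.wavelengths_nm, epsilon.values, left=0.0, right=0.0)
    w = beam.emission.values * wl
    return float(np.trapezoid(w * eps_vals, wl) / np.trapezoid(w, wl))


def read_spectrum_csv(path: str | Path, kind: str) -> Spectrum:
    """Read a two-column ``wavelength_nm,value`` CSV (header required)."""
    df = pd.read_csv(path, comment="#")
    if not {"wavelength_nm", "value"}.issubset(df.columns):
        raise ValueError("spectrum CSV needs columns wavelength_nm,value")
    return Spectrum(df["wavelength_nm"].to_numpy(), df["value"].to_numpy(), kind)


def write_spectrum_csv(spectrum: Spectrum, path: str | Path, header_note: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        pd.DataFrame(
            {"wavelength_nm": spectrum.wavelengths_nm, "value": spectrum.values}
        ).to_csv(fh, index=False)
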