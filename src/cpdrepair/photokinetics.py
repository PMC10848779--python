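"""Reversible photoreaction kinetics under polychromatic irradiation.

The model: a damaged oligomer (carrying a cyclobutane pyrimidine dimer, CPD)
and its repaired counterpart interconvert photochemically.  Each absorbed
photon converts the absorbing molecule with probability given by the channel
quantum yield:

    damaged  --(phi_repair  per photon absorbed by damaged)-->  repaired
    repaired --(phi_damage  per photon absorbed by repaired)--> damaged
    repaired --(phi_side    per photon absorbed by repaired)--> side product

Photon absorption rates come from the competitive Beer-Lambert partition in
:mod:`cpdrepair.spectra`, so the kinetics automatically include inner-filter
effects and the spectral overlap between the source and each species.  Under
continuous irradiation the two reversible channels balance at a
photostationary state (PSS); with an optically thin sample the PSS repair
fraction has the closed form

    f_pss = phi_repair * eps_bar_D / (phi_repair * eps_bar_D
                                      + phi_damage * eps_bar_R)

with eps_bar the photon-weighted mean absorption coefficients over the
source band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .constants import AVOGADRO_PER_MOL
from .spectra import (
    AbsorptionPartition,
    Beam,
    SampleCell,
    Spectrum,
    absorption_partition,
    effective_epsilon,
    resample_to_grid,
)

PROBE_NM = 266.0

DAMAGED = "damaged"
REPAIRED = "repaired"
SIDE = "side"
SPECIES_ORDER = (DAMAGED, REPAIRED, SIDE)


@dataclass(frozen=True)
class PhotoSpecies:
    """One photoactive species with its absorption spectrum.

    ``epsilon_probe_266`` defaults to the spectrum interpolated at the 266 nm
    probe; if given explicitly it must agree with the spectrum within 1%.
    """

    label: str
    epsilon: Spectrum
    epsilon_probe_266: float | None = None

    def __post_init__(self):
        if self.label not in SPECIES_ORDER:
            raise ValueError(f"species label must be one of {SPECIES_ORDER}")
        interp = self.epsilon.value_at(PROBE_NM)
        if self.epsilon_probe_266 is None:
            object.__setattr__(self, "epsilon_probe_266", interp)
        else:
            ref = max(abs(interp), 1e-30)
            if abs(self.epsilon_probe_266 - interp) > 0.01 * ref:
                raise ValueError(
                    f"epsilon_probe_266={self.epsilon_probe_266} disagrees with the "
                    f"spectrum at 266 nm ({interp:.1f}) by more than 1%"
                )


@dataclass(frozen=True)
class ReactionScheme:
    """Species plus per-channel quantum yields (fraction per absorbed photon)."""

    damaged: PhotoSpecies
    repaired: PhotoSpecies
    phi_repair: float
    phi_damage: float
    phi_side: float = 0.0
    side: PhotoSpecies | None = None

    def __post_init__(self):
        for name in ("phi_repair", "phi_damage", "phi_side"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.phi_damage + self.phi_side > 1.0:
            raise ValueError("phi_damage + phi_side exceeds 1 (same-origin channels)")
        if self.damaged.label != DAMAGED or self.repaired.label != REPAIRED:
            raise ValueError("species labels must match their roles")
        if self.phi_side > 0 and self.side is None:
            raise ValueError("phi_side > 0 requires a side PhotoSpecies")

    @property
    def species(self) -> list[PhotoSpecies]:
        out = [self.damaged, self.repaired]
        if self.side is not None:
            out.append(self.side)
        return out

    @property
    def n_species(self) -> int:
        return 3 if self.side is not None else 2


@dataclass(frozen=True)
class TimeCourse:
    """Simulated (or reconstructed) irradiation time course.

    ``repair_fraction`` is c_repaired divided by the total initial oligomer
    concentration (equal to c_repaired / c_damaged(t=0) for the standard
    pure-damaged start).
    """

    times_s: np.ndarray
    concentrations_M: dict[str, np.ndarray]
    cumulative_dose_J: np.ndarray
    probe_absorbance_266: np.ndarray
    repair_fraction: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.cumulative_dose_J) < -1e-15):
            raise ValueError("cumulative dose must be non-decreasing")

    @property
    def total_concentration_M(self) -> np.ndarray:
        return sum(self.concentrations_M.values())


def _partition(
    scheme: ReactionScheme, concentrations_M: np.ndarray, beam: Beam, cell: SampleCell
) -> AbsorptionPartition:
    wl = beam.emission.wavelengths_nm
    eps = []
    for sp in scheme.species:
        e = sp.epsilon
        if e.wavelengths_nm.shape != wl.shape or not np.array_equal(e.wavelengths_nm, wl):
            e = resample_to_grid(e, wl)
        eps.append(e)
    return absorption_partition(eps, concentrations_M, cell, beam)


def rate_vector(
    concentrations_M: np.ndarray,
    scheme: ReactionScheme,
    beam: Beam,
    cell: SampleCell,
) -> np.ndarray:
    """dC/dt (M s^-1), ordered (damaged, repaired[, side]).

    Total oligomer concentration is conserved; the damaged+repaired subtotal
    decreases at phi_side * R_repaired / (N_A * V) when the irreversible side
    channel is open.
    """
    conc = np.asarray(concentrations_M, dtype=float)
    if conc.size != scheme.n_species:
        raise ValueError(f"expected {scheme.n_species} concentrations, got {conc.size}")
    if np.any(conc < 0):
        raise ValueError("negative concentration input")
    part = _partition(scheme, conc, beam, cell)
    R_dam, R_rep = part.photon_rate_per_species[0], part.photon_rate_per_species[1]
    scale = 1.0 / (AVOGADRO_PER_MOL * cell.volume_L)
    d_rep = (scheme.phi_repair * R_dam - (scheme.phi_damage + scheme.phi_side) * R_rep) * scale
    d_dam = (-scheme.phi_repair * R_dam + scheme.phi_damage * R_rep) * scale
    if scheme.n_species == 3:
        return np.array([d_dam, d_rep, scheme.phi_side * R_rep * scale])
    return np.array([d_dam, d_rep])


def probe_absorbance(
    scheme: ReactionScheme, concentrations_M: np.ndarray, cell: SampleCell
) -> float:
    """Total decadic absorbance at the 266 nm probe (OD)."""
    eps266 = np.array([sp.epsilon_probe_266 for sp in scheme.species])
    return float(np.dot(eps266, concentrations_M) * cell.path_length_cm)


def simulate_time_course(
    scheme: ReactionScheme,
    beam: Beam,
    cell: SampleCell,
    c0_M: np.ndarray,
    t_grid_s: np.ndarray,
    rtol: float = 1e-8,
    atol_M: float = 1e-12,
) -> TimeCourse:
    """Integrate the photokinetic ODEs and the absorbed-energy dose.

    The damaged concentration is eliminated through the conservation law
    c_damaged = c_total(0) - c_repaired - c_side, so total oligomer
    concentration is conserved exactly.  Integration is adaptive (LSODA,
    stiffness-switching); failures raise with the solver diagnostics.
    """
    t_grid_s = np.asarray(t_grid_s, dtype=float)
    if t_grid_s[0] != 0 or np.any(np.diff(t_grid_s) <= 0):
        raise ValueError("time grid must increase from 0")
    c0 = np.asarray(c0_M, dtype=float)
    if c0.size != scheme.n_species or np.any(c0 < 0):
        raise ValueError("invalid initial concentrations")
    c_tot = float(c0.sum())
    n_free = scheme.n_species - 1  # repaired [, side]

    def unpack(y):
        rep = y[0]
        side = y[1] if n_free == 2 else 0.0
        dam = c_tot - rep - side
        conc = np.array([max(dam, 0.0), max(rep, 0.0)] + ([max(side, 0.0)] if n_free == 2 else []))
        return conc

    def rhs(t, y):
        conc = unpack(y)
        part = _partition(scheme, conc, beam, cell)
        R_dam, R_rep = part.photon_rate_per_species[0], part.photon_rate_per_species[1]
        scale = 1.0 / (AVOGADRO_PER_MOL * cell.volume_L)
        d_rep = (
            scheme.phi_repair * R_dam - (scheme.phi_damage + scheme.phi_side) * R_rep
        ) * scale
        out = [d_rep]
        if n_free == 2:
            out.append(scheme.phi_side * R_rep * scale)
        out.append(part.energy_dose_rate_W)
        return out

    y0 = [c0[1]] + ([c0[2]] if n_free == 2 else []) + [0.0]
    if t_grid_s.size == 1:
        sol_y = np.array(y0)[:, None]
    else:
        atol = [atol_M] * n_free + [1e-10]
        sol = solve_ivp(
            rhs,
            (0.0, t_grid_s[-1]),
            y0,
            method="LSODA",
            t_eval=t_grid_s,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"photokinetic integration failed: {sol.message} "
                f"(reached t={sol.t[-1] if sol.t.size else 0.0:.3g} s, "
                f"last state {sol.y[:, -1] if sol.t.size else y0})"
            )
        sol_y = sol.y

    rep = sol_y[0]
    side = sol_y[1] if n_free == 2 else np.zeros_like(rep)
    dam = np.clip(c_tot - rep - side, 0.0, None)
    conc = {DAMAGED: dam, REPAIRED: rep}
    if scheme.n_species == 3:
        conc[SIDE] = side
    conc_mat = np.vstack([conc[sp.label] for sp in scheme.species])
    eps266 = np.array([sp.epsilon_probe_266 for sp in scheme.species])
    probe = eps266 @ conc_mat * cell.path_length_cm
    return TimeCourse(
        times_s=t_grid_s,
        concentrations_M=conc,
        cumulative_dose_J=sol_y[-1],
        probe_absorbance_266=probe,
        repair_fraction=rep / c_tot,
    )


def thin_relaxation_rate_per_s(
    scheme: ReactionScheme, beam: Beam, cell: SampleCell
) -> float:
    """Optically thin relaxation rate k of the two-state scheme (s^-1).

    In the thin limit the repair fraction follows f(t) = f_pss (1 - e^{-kt})
    with k = ln10 * l * q_tot * (phi_r eps_bar_D + phi_d eps_bar_R)/(N_A V).
    """
    from .constants import HC_J_M

    eps_bar_D = effective_epsilon(scheme.damaged.epsilon, beam)
    eps_bar_R = effective_epsilon(scheme.repaired.epsilon, beam)
    wl = beam.emission.wavelengths_nm
    q_tot = beam.power_W * np.trapezoid(beam.emission.values * wl * 1e-9 / HC_J_M, wl)
    return float(
        np.log(10.0)
        * cell.path_length_cm
        * q_tot
        * (scheme.phi_repair * eps_bar_D + scheme.phi_damage * eps_bar_R)
        / (AVOGADRO_PER_MOL * cell.volume_L)
    )


def pss_fraction(
    scheme: ReactionScheme,
    beam: Beam,
    cell: SampleCell,
    mode: str = "analytic_thin",
    c_total_M: float = 30e-6,
    tol: float = 1e-7,
) -> float:
    """Photostationary repair fraction.

    ``analytic_thin``: closed form valid in the optically thin limit, using
    photon-weighted mean absorption coefficients over the beam band.
    ``ode_limit``: integrate the full model (from a pure-damaged start at
    ``c_total_M``) until the fraction change per characteristic time falls
    below ``tol``.
    """
    if scheme.phi_side > 0:
        raise ValueError("no stationary state: irreversible channel present")
    eps_bar_D = effective_epsilon(scheme.damaged.epsilon, beam)
    eps_bar_R = effective_epsilon(scheme.repaired.epsilon, beam)
    num = scheme.phi_repair * eps_bar_D
    den = num + scheme.phi_damage * eps_bar_R
    if den == 0:
        raise ValueError("both photochemical channels are inactive")
    f_analytic = num / den
    if mode == "analytic_thin":
        return f_analytic
    if mode != "ode_limit":
        raise ValueError(f"unknown mode {mode!r}")

    k_relax = thin_relaxation_rate_per_s(scheme, beam, cell)
    if k_relax <= 0:
        raise ValueError("zero relaxation rate; cannot reach a stationary state")
    tau = 1.0 / k_relax
    horizon = 12.0 * tau
    c0 = np.array([c_total_M, 0.0])
    for _ in range(8):
        t_grid = np.linspace(0.0, horizon, 61)
        tc = simulate_time_course(scheme, beam, cell, c0, t_grid)
        if abs(tc.repair_fraction[-1] - tc.repair_fraction[-6]) < tol:
            return float(tc.repair_fraction[-1])
        horizon *= 2.0
    raise RuntimeError("photostationary state not reached within the dose horizon")
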