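"""Synthetic experiment generator for the self-repair analysis pipeline.

Emulates the irradiation study the pipeline is built for: a ~30 uM aqueous
solution of a damaged (CPD-carrying) tetranucleotide irradiated by a 285 nm
LED (15 nm FWHM, 0.36 mW at the sample), monitored through 266 nm
difference absorbance and analytical HPLC (damaged peak 8.4 min, repaired
peak 9.9 min).  Every observable is generated from the forward photokinetic
model with known ("truth") parameters, so each analysis stage can be tested
by parameter recovery.

Species absorption spectra are parametric Gaussian bands: both oligomers
share a purine absorption band that carries the 285 nm excitation; the
repaired oligomer additionally has the thymine band near 266 nm that the
cyclobutane dimer bleaches, and its amplitude *is* the configured
delta_eps_266.  The amplitudes are fixture choices (the literature 266 nm
coefficients are not built in), scaled to give a few tens of mOD recovery
at 266 nm within 10 minutes of irradiation.

By default phi_damage is not set directly: it is calibrated so that the
analytic photostationary fraction equals the scenario's target level
(a derived quantity, recorded as such in the scenario truth).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import chromatography as chrom_mod
from .chromatography import Chromatogram, ChromatogramConfig, synthesize_chromatogram
from .photokinetics import (
    DAMAGED,
    REPAIRED,
    SIDE,
    PhotoSpecies,
    ReactionScheme,
    TimeCourse,
    pss_fraction,
    simulate_time_course,
    thin_relaxation_rate_per_s,
)
from .spectra import (
    DEFAULT_GRID_NM,
    EMISSION_DENSITY,
    MOLAR_ABSORPTION,
    Beam,
    SampleCell,
    Spectrum,
    absorption_partition,
    effective_epsilon,
    gaussian_emission,
)
from .yield_extraction import DoseResponse

#: Measured self-repair quantum yields (%), the scenario truth defaults.
SEQUENCE_DEFAULTS = {
    "TTAG": {"phi_repair_percent": 0.58, "target_pss_fraction": 0.40},
    "GATT": {"phi_repair_percent": 0.44, "target_pss_fraction": 0.33},
}


class ScenarioConfig(BaseModel, frozen=True):
    """Full description of one synthetic irradiation experiment."""

    sequence_label: Literal["TTAG", "GATT"] = "TTAG"
    c0_M: float = Field(30e-6, gt=0)

    beam_center_nm: float = Field(285.0, gt=0)
    beam_fwhm_nm: float = Field(15.0, gt=0)
    beam_power_mW: float = Field(0.36, gt=0)

    path_length_cm: float = Field(1.0, gt=0)
    volume_L: float = Field(200e-6, gt=0)

    phi_repair: Optional[float] = Field(None, ge=0, le=1)
    phi_damage: Optional[float] = Field(None, ge=0, le=1)
    phi_side: float = Field(0.0, ge=0, le=1)
    target_pss_fraction: Optional[float] = Field(None, gt=0, lt=1)

    # parametric absorption bands (M^-1 cm^-1, nm)
    delta_eps_266: float = Field(16000.0, ge=0)
    purine_band_amp: float = Field(27000.0, gt=0)
    purine_band_center_nm: float = Field(257.0, gt=0)
    purine_band_fwhm_nm: float = Field(31.0, gt=0)
    t_band_center_nm: float = Field(266.0, gt=0)
    t_band_fwhm_nm: float = Field(25.0, gt=0)

    sigma_OD: float = Field(1e-3, ge=0)
    chrom_noise_frac: float = Field(0.01, ge=0)
    schedule_s: tuple[float, ...] = tuple(np.arange(0.0, 601.0, 60.0))
    rng_seed: int = 0

    @model_validator(mode="after")
    def _fill_sequence_defaults(self):
        defaults = SEQUENCE_DEFAULTS[self.sequence_label]
        if self.phi_repair is None:
            object.__setattr__(
                self, "phi_repair", defaults["phi_repair_percent"] / 100.0
            )
        if self.target_pss_fraction is None and self.phi_damage is None:
            object.__setattr__(
                self, "target_pss_fraction", defaults["target_pss_fraction"]
            )
        sched = np.asarray(self.schedule_s, float)
        if sched.size < 2 or sched[0] != 0 or np.any(np.diff(sched) <= 0):
            raise ValueError("schedule_s must increase strictly from 0")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _gaussian_band(grid, amp, center, fwhm):
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)


def species_spectra(config: ScenarioConfig, grid_nm=None) -> dict[str, Spectrum]:
    """Parametric molar absorption spectra for damaged/repaired/side species."""
    grid = np.asarray(grid_nm if grid_nm is not None else DEFAULT_GRID_NM, float)
    purine = _gaussian_band(
        grid, config.purine_band_amp, config.purine_band_center_nm, config.purine_band_fwhm_nm
    )
    t_band = _gaussian_band(
        grid, config.delta_eps_266, config.t_band_center_nm, config.t_band_fwhm_nm
    )
    return {
        DAMAGED: Spectrum(grid, purine, MOLAR_ABSORPTION),
        REPAIRED: Spectrum(grid, purine + t_band, MOLAR_ABSORPTION),
        SIDE: Spectrum(grid, 0.5 * purine, MOLAR_ABSORPTION),
    }


def calibrate_phi_damage(
    phi_repair: float, eps_bar_damaged: float, eps_bar_repaired: float, f_target: float
) -> float:
    """phi_damage that puts the analytic thin-limit PSS at ``f_target``."""
    if not 0 < f_target < 1:
        raise ValueError("target PSS fraction must lie in (0, 1)")
    return phi_repair * eps_bar_damaged * (1.0 - f_target) / (f_target * eps_bar_repaired)


def generate_scenario(
    config: ScenarioConfig,
) -> tuple[ReactionScheme, Beam, SampleCell]:
    """Materialise the reaction scheme, beam and cell for a scenario.

    When ``phi_damage`` is not given it is calibrated so the analytic
    photostationary fraction equals ``target_pss_fraction``.
    """
    if config.delta_eps_266 == 0:
        warnings.warn("probe-blind scenario: delta_eps_266 = 0", stacklevel=2)
    spectra = species_spectra(config)
    beam = Beam(
        gaussian_emission(config.beam_center_nm, config.beam_fwhm_nm),
        config.beam_power_mW * 1e-3,
    )
    cell = SampleCell(config.path_length_cm, config.volume_L)
    phi_damage = config.phi_damage
    if phi_damage is None:
        eps_bar_D = effective_epsilon(spectra[DAMAGED], beam)
        eps_bar_R = effective_epsilon(spectra[REPAIRED], beam)
        phi_damage = calibrate_phi_damage(
            config.phi_repair, eps_bar_D, eps_bar_R, config.target_pss_fraction
        )
    scheme = ReactionScheme(
        damaged=PhotoSpecies(DAMAGED, spectra[DAMAGED]),
        repaired=PhotoSpecies(REPAIRED, spectra[REPAIRED]),
        phi_repair=config.phi_repair,
        phi_damage=phi_damage,
        phi_side=config.phi_side,
        side=PhotoSpecies(SIDE, spectra[SIDE]) if config.phi_side > 0 else None,
    )
    return scheme, beam, cell


@dataclass(frozen=True)
class SimulatedExperiment:
    """Noisy observables plus the noiseless truth that generated them."""

    config: ScenarioConfig
    scheme: ReactionScheme
    beam: Beam
    cell: SampleCell
    truth_time_course: TimeCourse
    dose_response: DoseResponse
    difference_spectra: np.ndarray  # (n_times, n_wavelengths), OD vs t=0
    grid_nm: np.ndarray
    chromatograms: tuple[Chromatogram, ...]
    true_phi_repair: float
    true_phi_damage: float
    true_pss_fraction_analytic: float


def simulate_experiment(config: ScenarioConfig) -> SimulatedExperiment:
    """Forward-simulate one irradiation experiment and its noisy readouts.

    Gaussian noise of ``sigma_OD`` is added independently to every
    absorbance point (dose response and difference spectra); chromatograms
    are synthesised from the true composition at each exposure with
    amplitude noise ``chrom_noise_frac`` of the maximum signal.  All
    randomness comes from ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    scheme, beam, cell = generate_scenario(config)
    t_grid = np.asarray(config.schedule_s, float)
    c0 = np.zeros(scheme.n_species)
    c0[0] = config.c0_M
    tc = simulate_time_course(scheme, beam, cell, c0, t_grid)

    delta_A_clean = tc.probe_absorbance_266 - tc.probe_absorbance_266[0]
    noise = rng.normal(0.0, config.sigma_OD, size=delta_A_clean.size) if config.sigma_OD else 0.0
    dr = DoseResponse(tc.cumulative_dose_J, delta_A_clean + noise)

    grid = scheme.damaged.epsilon.wavelengths_nm
    eps_mat = np.vstack([sp.epsilon.values for sp in scheme.species])
    conc_mat = np.vstack([tc.concentrations_M[sp.label] for sp in scheme.species])
    A_lambda = (conc_mat.T @ eps_mat) * cell.path_length_cm  # (n_times, n_wl)
    diff = A_lambda - A_lambda[0]
    if config.sigma_OD:
        diff = diff + rng.normal(0.0, config.sigma_OD, size=diff.shape)

    chroms = []
    peak_max = 1.0 / (chrom_mod.DEFAULT_PEAK_SIGMA_MIN * np.sqrt(2 * np.pi))
    for i in range(t_grid.size):
        total = tc.total_concentration_M[i]
        comp = {
            "damaged": float(tc.concentrations_M[DAMAGED][i] / total),
            "repaired": float(tc.concentrations_M[REPAIRED][i] / total),
        }
        resid = 1.0 - sum(comp.values())
        comp["damaged"] += resid  # side product not injected; renormalise
        cfg = ChromatogramConfig(noise_sigma=config.chrom_noise_frac * peak_max)
        chroms.append(synthesize_chromatogram(comp, cfg, rng=rng))

    return SimulatedExperiment(
        config=config,
        scheme=scheme,
        beam=beam,
        cell=cell,
        truth_time_course=tc,
        dose_response=dr,
        difference_spectra=diff,
        grid_nm=grid,
        chromatograms=tuple(chroms),
        true_phi_repair=scheme.phi_repair,
        true_phi_damage=scheme.phi_damage,
        true_pss_fraction_analytic=pss_fraction(scheme, beam, cell, "analytic_thin")
        if scheme.phi_side == 0
        else float("nan"),
    )


def long_dose_schedule(
    config: ScenarioConfig, dose_multiple: float = 5.0, n_points: int = 41
) -> tuple[float, ...]:
    """Exposure times reaching ``dose_multiple`` characteristic doses.

    The characteristic dose D0 of the saturating approach to the PSS maps to
    the thin-limit relaxation time 1/k; the schedule spans dose_multiple/k.
    """
    scheme, beam, cell = generate_scenario(config)
    k = thin_relaxation_rate_per_s(scheme, beam, cell)
    t_end = dose_multiple / k
    return tuple(np.linspace(0.0, t_end, n_points))


# --------------------------------------------------- stacked-pair ensembles

ANTI_CHI_DEG = -120.0
SYN_CHI_DEG = 60.0
CLASS_CHI_DEG = {"anti": ANTI_CHI_DEG, "syn": SYN_CHI_DEG}


def _rotation(axis, angle_rad):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.cos(angle_rad / 2.0)
    b, c, d = -axis * np.sin(angle_rad / 2.0)
    return np.array(
        [
            [a * a + b * b - c * c - d * d, 2 * (b * c + a * d), 2 * (b * d - a * c)],
            [2 * (b * c - a * d), a * a + c * c - b * b - d * d, 2 * (c * d + a * b)],
            [2 * (b * d + a * c), 2 * (c * d - a * b), a * a + d * d - b * b - c * c],
        ]
    )


def _place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF placement: position D with |CD|=bond, angle(BCD), dihedral(ABCD)."""
    theta = np.radians(angle_deg)
    phi = np.radians(dihedral_deg)
    b2 = c - b
    b2n = b2 / np.linalg.norm(b2)
    n = np.cross(b - a, b2)
    n = n / np.linalg.norm(n)
    m = np.cross(n, b2n)
    d_local = np.array(
        [-bond * np.cos(theta), bond * np.cos(phi) * np.sin(theta), bond * np.sin(phi) * np.sin(theta)]
    )
    return c + d_local[0] * b2n + d_local[1] * m + d_local[2] * n


def _regular_polygon_extension(p0, p1, n_sides, normal):
    """Vertices completing a regular n-gon from edge p0->p1, turning left
    about ``normal``."""
    verts = [p0, p1]
    edge = p1 - p0
    exterior = 2.0 * np.pi / n_sides
    rot = _rotation(normal, exterior)
    for _ in range(n_sides - 2):
        edge = rot @ edge
        verts.append(verts[-1] + edge)
    return verts


def build_idealized_purine(
    base_type: str, chi_deg: float, residue_id: int = 1
) -> "NucleotideStructure":
    """Idealised planar purine with a minimal sugar stub realising chi.

    The base is a regular hexagon (bond 1.39 A) with a fused regular
    pentagon sharing the C4-C5 edge; C1' extends from N9 in the base plane
    and O4' is placed so that the O4'-C1'-N9-C4 dihedral equals ``chi_deg``.
    """
    from .stack_geometry import NucleotideStructure, dihedral_deg as _dihed

    bond = 1.39
    hex_names = ("N1", "C2", "N3", "C4", "C5", "C6")
    atoms: dict[str, np.ndarray] = {}
    for i, name in enumerate(hex_names):
        ang = np.pi / 3.0 * i
        atoms[name] = np.array([bond * np.cos(ang), bond * np.sin(ang), 0.0])
    z = np.array([0.0, 0.0, 1.0])
    c4, c5 = atoms["C4"], atoms["C5"]
    # pentagon on the far side of the hexagon centre (origin)
    mid = (c4 + c5) / 2.0
    for normal in (z, -z):
        verts = _regular_polygon_extension(c4, c5, 5, normal)
        centroid = np.mean(verts, axis=0)
        if np.dot(centroid - mid, mid) > 0:  # pentagon outside the hexagon
            break
    atoms["N7"], atoms["C8"], atoms["N9"] = verts[2], verts[3], verts[4]

    n9, c8 = atoms["N9"], atoms["C8"]
    ring_centroid = np.mean([atoms[k] for k in ("C4", "C5", "N7", "C8", "N9")], axis=0)
    out_dir = n9 - ring_centroid
    out_dir /= np.linalg.norm(out_dir)
    atoms["C1'"] = n9 + 1.47 * out_dir
    o4 = _place_atom(atoms["C4"], n9, atoms["C1'"], 1.42, 108.0, chi_deg)
    atoms["O4'"] = o4
    nuc = NucleotideStructure(residue_id, base_type, atoms)
    # the NeRF frame convention is verified here rather than assumed
    realised = _dihed(atoms["O4'"], atoms["C1'"], n9, atoms["C4"])
    if abs((realised - chi_deg + 180.0) % 360.0 - 180.0) > 1e-6:
        o4 = _place_atom(atoms["C4"], n9, atoms["C1'"], 1.42, 108.0, -chi_deg)
        atoms["O4'"] = o4
        nuc = NucleotideStructure(residue_id, base_type, atoms)
    return nuc


@dataclass(frozen=True)
class StackedEnsemble:
    frames: list
    true_classes: list[tuple[str, str]]


def generate_stacked_frames(
    n_frames: int,
    class_probabilities: dict[tuple[str, str], float],
    geometry_noise_deg: float = 0.0,
    rise_A: float = 3.4,
    twist_deg: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> StackedEnsemble:
    """Idealised stacked A/G pairs with known syn/anti class labels.

    Classes are (orientation of base 1, orientation of base 2) with chi at
    -120 deg (anti) or +60 deg (syn) plus Gaussian angular noise; base 2 is
    stacked ``rise_A`` above base 1 with an optional helical twist.
    """
    probs = np.array(list(class_probabilities.values()), float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class probabilities must sum to 1")
    keys = list(class_probabilities.keys())
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    draws = rng.choice(len(keys), size=n_frames, p=probs)
    frames, labels = [], []
    rot = _rotation([0.0, 0.0, 1.0], np.radians(twist_deg))
    for idx in draws:
        cls = keys[idx]
        chi1 = CLASS_CHI_DEG[cls[0]] + (rng.normal(0.0, geometry_noise_deg) if geometry_noise_deg else 0.0)
        chi2 = CLASS_CHI_DEG[cls[1]] + (rng.normal(0.0, geometry_noise_deg) if geometry_noise_deg else 0.0)
        base1 = build_idealized_purine("A", chi1, residue_id=1)
        base2 = build_idealized_purine("G", chi2, residue_id=2)
        shifted = {
            name: rot @ xyz + np.array([0.0, 0.0, rise_A])
            for name, xyz in base2.atoms.items()
        }
        from .stack_geometry import NucleotideStructure

        frames.append((base1, NucleotideStructure(2, "G", shifted)))
        labels.append(cls)
    return StackedEnsemble(frames, labels)


def write_ensemble_pdb(ensemble: StackedEnsemble, path: str | Path) -> None:
    """Write the frames as a multi-model PDB (one model per frame)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    arrays = []
    for a, b in ensemble.frames:
        atoms = []
        for nuc in (a, b):
            res_name = "D" + nuc.base_type
            for name, xyz in nuc.atoms.items():
                at = struc.Atom(
                    xyz,
                    chain_id="A",
                    res_id=nuc.residue_id,
                    res_name=res_name,
                    atom_name=name,
                    element=name[0],
                )
                atoms.append(at)
        arrays.append(struc.array(atoms))
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def write_fixture_dir(exp: SimulatedExperiment, out_dir: str | Path) -> None:
    """Write an experiment's observables as CSV/JSON with provenance headers."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"seed={exp.config.rng_seed} config_sha={exp.config.config_hash()}"
    with (out / "dose_response.csv").open("w") as fh:
        fh.write(f"# {header}\n")
        pd.DataFrame(
            {"dose_J": exp.dose_response.doses_J, "delta_A_266": exp.dose_response.delta_A_266}
        ).to_csv(fh, index=False)
    tc = exp.truth_time_course
    with (out / "time_course.csv").open("w") as fh:
        fh.write(f"# {header}\n")
        cols = {
            "time_s": tc.times_s,
            "dose_J": tc.cumulative_dose_J,
            "c_damaged_M": tc.concentrations_M[DAMAGED],
            "c_repaired_M": tc.concentrations_M[REPAIRED],
            "c_side_M": tc.concentrations_M.get(SIDE, np.zeros_like(tc.times_s)),
            "dA266_OD": tc.probe_absorbance_266 - tc.probe_absorbance_266[0],
            "repair_fraction": tc.repair_fraction,
        }
        pd.DataFrame(cols).to_csv(fh, index=False)
    for i, chrom in enumerate(exp.chromatograms):
        chrom_mod.write_chromatogram_csv(
            chrom, out / f"chromatogram_{i:02d}.csv", header_note=header
        )
    (out / "scenario.json").write_text(
        json.dumps({"header": header, "config": exp.config.model_dump()}, indent=2, default=list)
    )
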