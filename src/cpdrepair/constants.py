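"""Physical constants (CODATA 2018 exact values where defined)."""

PLANCK_J_S = 6.62607015e-34
"""Planck constant h (J s)."""

SPEED_OF_LIGHT_M_S = 2.99792458e8
"""Speed of light c (m s^-1)."""

AVOGADRO_PER_MOL = 6.02214076e23
"""Avogadro constant N_A (mol^-1)."""

HC_J_M = PLANCK_J_S * SPEED_OF_LIGHT_M_S
"""h*c (J m): photon energy E = HC_J_M / wavelength_m."""

EV_NM = 1239.84198
"""Energy-wavelength conversion constant (eV nm): E[eV] = EV_NM / lambda[nm]."""


def photon_energy_J(wavelength_nm: float) -> float:
    """Energy of a single photon at the given vacuum wavelength."""
    return HC_J_M / (wavelength_nm * 1e-9)
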