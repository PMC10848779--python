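"""Forward photokinetics: rates, conservation, closed forms, PSS."""

import numpy as np
import pytest

from cpdrepair.constants import AVOGADRO_PER_MOL, HC_J_M
from cpdrepair.photokinetics import (
    DAMAGED,
    REPAIRED,
    SIDE,
    PhotoSpecies,
    ReactionScheme,
    pss_fraction,
    rate_vector,
    simulate_time_course,
    thin_relaxation_rate_per_s,
)
from cpdrepair.spectra import Beam, SampleCell, gaussian_emission
from tests.conftest import flat_epsilon


def two_state_scheme(eps_d=3000.0, eps_r=6000.0, phi_r=0.005, phi_d=0.004):
    return ReactionScheme(
        damaged=PhotoSpecies(DAMAGED, flat_epsilon(eps_d)),
        repaired=PhotoSpecies(REPAIRED, flat_epsilon(eps_r)),
        phi_repair=phi_r,
        phi_damage=phi_d,
    )


class TestRateVector:
    def test_zero_power_gives_zero_rates(self, led_beam, cell):
        scheme = two_state_scheme()
        off = Beam(led_beam.emission, 0.0)
        rates = rate_vector(np.array([30e-6, 0.0]), scheme, off, cell)
        np.testing.assert_array_equal(rates, 0.0)

    def test_one_way_reaction_conserves_mass(self, led_beam, cell):
        scheme = two_state_scheme(phi_d=0.0)
        rates = rate_vector(np.array([30e-6, 0.0]), scheme, led_beam, cell)
        assert rates[1] > 0
        assert rates[0] == pytest.approx(-rates[1], rel=1e-12)

    def test_hand_evaluated_single_wavelength_case(self, narrow_beam, cell):
        """A_tot = 0.1, P = 0.36 mW at 285 nm, phi_repair = 0.005.

        dc_rep/dt = phi * q_tot * (1 - 10^-0.1) / (N_A V)."""
        c0 = 30e-6
        scheme = two_state_scheme(eps_d=0.1 / c0, phi_r=0.005, phi_d=0.0)
        rates = rate_vector(np.array([c0, 0.0]), scheme, narrow_beam, cell)
        q_tot = 0.36e-3 * 285e-9 / HC_J_M
        expected = 0.005 * q_tot * (1.0 - 10.0**-0.1) / (AVOGADRO_PER_MOL * cell.volume_L)
        assert rates[1] == pytest.approx(expected, rel=1e-3)

    def test_negative_concentration_rejected(self, led_beam, cell):
        with pytest.raises(ValueError, match="negative"):
            rate_vector(np.array([-1e-6, 0.0]), two_state_scheme(), led_beam, cell)

    def test_side_channel_drains_reversible_pool(self, led_beam, cell):
        scheme = ReactionScheme(
            damaged=PhotoSpecies(DAMAGED, flat_epsilon(3000.0)),
            repaired=PhotoSpecies(REPAIRED, flat_epsilon(6000.0)),
            phi_repair=0.005,
            phi_damage=0.002,
            phi_side=0.001,
            side=PhotoSpecies(SIDE, flat_epsilon(1000.0)),
        )
        rates = rate_vector(np.array([15e-6, 15e-6, 0.0]), scheme, led_beam, cell)
        assert rates.sum() == pytest.approx(0.0, abs=1e-12 * np.abs(rates).max())
        assert rates[2] > 0  # side product grows


class TestSimulate:
    def test_single_time_point_returns_initial_state(self, led_beam, cell):
        tc = simulate_time_course(
            two_state_scheme(), led_beam, cell, np.array([30e-6, 0.0]), np.array([0.0])
        )
        assert tc.cumulative_dose_J[0] == 0.0
        assert tc.concentrations_M[DAMAGED][0] == 30e-6
        assert tc.repair_fraction[0] == 0.0

    def test_one_way_repair_fraction_approaches_one(self, led_beam, cell):
        scheme = two_state_scheme(phi_d=0.0, phi_r=0.01)
        k = thin_relaxation_rate_per_s(scheme, led_beam, cell)
        t = np.linspace(0.0, 15.0 / k, 30)
        tc = simulate_time_course(scheme, led_beam, cell, np.array([30e-6, 0.0]), t)
        assert np.all(np.diff(tc.repair_fraction) >= -1e-12)
        assert tc.repair_fraction[-1] > 0.999

    def test_closed_form_two_state_exponential(self, narrow_beam, cell):
        """Optically thin + monochromatic: f(t) = f_pss (1 - e^{-kt})."""
        c0 = 1e-7  # peak A ~ 6e-4: deep in the optically thin regime
        scheme = two_state_scheme(eps_d=3000.0, eps_r=6000.0, phi_r=0.004, phi_d=0.003)
        k = thin_relaxation_rate_per_s(scheme, narrow_beam, cell)
        f_pss = pss_fraction(scheme, narrow_beam, cell, "analytic_thin")
        t = np.linspace(0.0, 3.0 / k, 16)
        tc = simulate_time_course(scheme, narrow_beam, cell, np.array([c0, 0.0]), t)
        expected = f_pss * (1.0 - np.exp(-k * t))
        np.testing.assert_allclose(tc.repair_fraction[1:], expected[1:], rtol=1e-3)

    def test_mass_conservation_with_side_channel(self, led_beam, cell):
        scheme = ReactionScheme(
            damaged=PhotoSpecies(DAMAGED, flat_epsilon(3000.0)),
            repaired=PhotoSpecies(REPAIRED, flat_epsilon(6000.0)),
            phi_repair=0.005,
            phi_damage=0.002,
            phi_side=0.002,
            side=PhotoSpecies(SIDE, flat_epsilon(1000.0)),
        )
        t = np.linspace(0.0, 3600.0, 20)
        tc = simulate_time_course(
            scheme, led_beam, cell, np.array([30e-6, 0.0, 0.0]), t
        )
        np.testing.assert_allclose(tc.total_concentration_M, 30e-6, atol=1e-9)
        assert tc.concentrations_M[SIDE][-1] > 0

    def test_monotone_approach_no_overshoot(self, led_beam, cell):
        """Two-state repair fraction never overshoots its plateau."""
        rng = np.random.default_rng(7)
        for _ in range(8):
            scheme = two_state_scheme(
                eps_d=rng.uniform(500, 2e4),
                eps_r=rng.uniform(500, 2e4),
                phi_r=rng.uniform(1e-4, 0.05),
                phi_d=rng.uniform(1e-4, 0.05),
            )
            k = thin_relaxation_rate_per_s(scheme, led_beam, cell)
            t = np.linspace(0.0, 10.0 / k, 40)
            tc = simulate_time_course(
                scheme, led_beam, cell, np.array([30e-6, 0.0]), t
            )
            assert np.all(np.diff(tc.repair_fraction) >= -1e-10)

    def test_dose_scale_invariance(self, led_beam, cell):
        """Half power, double duration: same fraction-vs-dose curve."""
        scheme = two_state_scheme()
        k = thin_relaxation_rate_per_s(scheme, led_beam, cell)
        t = np.linspace(0.0, 4.0 / k, 25)
        tc1 = simulate_time_course(scheme, led_beam, cell, np.array([30e-6, 0.0]), t)
        half = Beam(led_beam.emission, led_beam.power_W / 2.0)
        tc2 = simulate_time_course(scheme, half, cell, np.array([30e-6, 0.0]), 2.0 * t)
        np.testing.assert_allclose(tc2.cumulative_dose_J, tc1.cumulative_dose_J, rtol=1e-6)
        np.testing.assert_allclose(tc2.repair_fraction, tc1.repair_fraction, rtol=1e-6, atol=1e-9)


class TestPssFraction:
    def test_no_damage_channel_gives_unity(self, led_beam, cell):
        scheme = two_state_scheme(phi_d=0.0)
        assert pss_fraction(scheme, led_beam, cell, "analytic_thin") == 1.0

    def test_symmetric_scheme_gives_half(self, led_beam, cell):
        scheme = two_state_scheme(eps_d=4000.0, eps_r=4000.0, phi_r=0.01, phi_d=0.01)
        assert pss_fraction(scheme, led_beam, cell, "analytic_thin") == pytest.approx(0.5)

    def test_side_channel_forbids_stationary_state(self, led_beam, cell):
        scheme = ReactionScheme(
            damaged=PhotoSpecies(DAMAGED, flat_epsilon(3000.0)),
            repaired=PhotoSpecies(REPAIRED, flat_epsilon(6000.0)),
            phi_repair=0.005,
            phi_damage=0.002,
            phi_side=0.001,
            side=PhotoSpecies(SIDE, flat_epsilon(1000.0)),
        )
        with pytest.raises(ValueError, match="irreversible channel"):
            pss_fraction(scheme, led_beam, cell)

    def test_analytic_matches_ode_when_optically_thin(self, led_beam, cell):
        """Randomised schemes, peak A_tot <= 0.05: modes agree within 1%."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            eps_d = rng.uniform(500, 1500)
            eps_r = rng.uniform(500, 1500)
            scheme = two_state_scheme(
                eps_d=eps_d,
                eps_r=eps_r,
                phi_r=rng.uniform(1e-3, 0.02),
                phi_d=rng.uniform(1e-3, 0.02),
            )
            f_an = pss_fraction(scheme, led_beam, cell, "analytic_thin")
            f_ode = pss_fraction(scheme, led_beam, cell, "ode_limit", c_total_M=30e-6)
            assert f_ode == pytest.approx(f_an, rel=0.01)

    def test_independent_of_starting_composition(self, led_beam, cell):
        scheme = two_state_scheme()
        k = thin_relaxation_rate_per_s(scheme, led_beam, cell)
        t = np.linspace(0.0, 14.0 / k, 41)
        from_damaged = simulate_time_course(
            scheme, led_beam, cell, np.array([30e-6, 0.0]), t
        )
        from_repaired = simulate_time_course(
            scheme, led_beam, cell, np.array([0.0, 30e-6]), t
        )
        assert abs(
            from_damaged.repair_fraction[-1] - from_repaired.repair_fraction[-1]
        ) < 1e-4
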