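"""Sharp-interface droplet theory: profiles, kinetics, critical ratio."""

import math

import numpy as np
import pytest

from pyresim.droplet import (
    DropletParams,
    critical_k,
    equilibrium_radius,
    k_tilde_from_pde,
    k_tilde_to_pde,
    passive_growth,
    profile_inside,
    profile_outside,
    radius_rate,
    req_approx,
)


@pytest.fixture
def dp():
    return DropletParams(phi_plus=0.9, phi_minus=0.01, k_tilde_d=0.1)


def ode_residual(profile_fn, r, R, dp, h=1e-3):
    """Residual of 0 = lap(phi) - phi + k(1-phi) in spherical symmetry.

    Richardson-extrapolated central differences (h and h/2) remove the
    leading O(h^2) discretization error so the residual probes the
    closed-form solution itself.
    """
    def lap(hh):
        f = lambda x: profile_fn(np.asarray(x), R, dp)
        d2 = (f(r + hh) - 2 * f(r) + f(r - hh)) / hh**2
        d1 = (f(r + hh) - f(r - hh)) / (2 * hh)
        return d2 + 2.0 * d1 / r

    lap_rich = (4.0 * lap(h / 2) - lap(h)) / 3.0
    phi = profile_fn(np.asarray(r), R, dp)
    return lap_rich - phi + dp.k_tilde_d * (1.0 - phi)


class TestConventions:
    def test_k_ratio_inversion_roundtrip(self):
        assert k_tilde_to_pde(k_tilde_from_pde(0.14)) == pytest.approx(0.14)

    def test_phi_inf_reaction_balance(self, dp):
        assert dp.phi_inf == pytest.approx(0.1 / 1.1, rel=1e-14)

    def test_invalid_binodal_rejected(self):
        with pytest.raises(ValueError):
            DropletParams(0.2, 0.5, 0.1)


class TestProfiles:
    def test_interface_boundary_values_exact(self, dp):
        R = 2.5
        assert profile_inside(R, R, dp) == pytest.approx(dp.phi_plus,
                                                         abs=1e-14)
        assert profile_outside(R, R, dp) == pytest.approx(dp.phi_minus,
                                                          abs=1e-14)

    def test_regular_at_origin(self, dp):
        R = 2.0
        v0 = profile_inside(0.0, R, dp)
        v_eps = profile_inside(1e-8, R, dp)
        assert np.isfinite(v0) and v0 == pytest.approx(float(v_eps),
                                                       rel=1e-6)

    def test_far_field_approaches_reaction_balance(self, dp):
        assert profile_outside(500.0, 2.0, dp) == pytest.approx(dp.phi_inf,
                                                                abs=1e-12)

    def test_domain_errors(self, dp):
        with pytest.raises(ValueError):
            profile_inside(3.0, 2.0, dp)
        with pytest.raises(ValueError):
            profile_outside(1.0, 2.0, dp)

    @pytest.mark.parametrize("R", [0.5, 2.0, 8.0])
    def test_profiles_solve_the_reaction_diffusion_ode(self, dp, R):
        r_in = np.linspace(0.2, R * 0.98, 20)
        assert np.abs(ode_residual(profile_inside, r_in, R, dp)).max() < 1e-8
        r_out = np.linspace(R * 1.02, R + 10.0, 20)
        assert np.abs(ode_residual(profile_outside, r_out, R, dp)).max() < 1e-8


class TestRadiusKinetics:
    def test_small_radius_limit_matches_series(self, dp):
        """As R -> 0 the rate behaves as (1 - B/(c^2 dphi)) / R with
        B = k(phi+ - 1) + phi+, from expanding coth."""
        k, c = dp.k_tilde_d, math.sqrt(1.0 + dp.k_tilde_d)
        B = k * (dp.phi_plus - 1.0) + dp.phi_plus
        coeff = 1.0 - B / (c * c * (dp.phi_plus - dp.phi_minus))
        for R in (1e-4, 1e-5):
            assert radius_rate(R, dp) == pytest.approx(coeff / R, rel=1e-2)

    def test_fixed_point_is_root_and_stable(self, dp):
        R_eq = equilibrium_radius(dp)
        assert R_eq is not None
        assert radius_rate(R_eq, dp) == pytest.approx(0.0, abs=1e-9)
        assert radius_rate(0.9 * R_eq, dp) > 0 > radius_rate(1.1 * R_eq, dp)

    def test_no_fixed_point_above_critical_ratio(self, dp):
        k_c = critical_k(dp.phi_plus, dp.phi_minus)
        above = DropletParams(dp.phi_plus, dp.phi_minus, 2.0 * k_c)
        assert equilibrium_radius(above) is None

    def test_equilibrium_radius_increases_with_k(self, dp):
        ks = np.linspace(0.05, 0.5, 8)
        radii = [equilibrium_radius(
            DropletParams(dp.phi_plus, dp.phi_minus, k)) for k in ks]
        assert all(r is not None for r in radii)
        assert (np.diff(radii) > 0).all()

    def test_invalid_radius_rejected(self, dp):
        with pytest.raises(ValueError):
            radius_rate(0.0, dp)


class TestCriticalRatio:
    def test_symmetric_binodal_gives_unity(self):
        assert critical_k(0.95, 0.05) == pytest.approx(1.0, rel=1e-12)

    def test_increasing_in_dense_binodal(self):
        assert critical_k(0.9, 0.01) > critical_k(0.7, 0.01)

    @pytest.mark.parametrize("pp", [0.7, 0.8, 0.9])
    @pytest.mark.parametrize("pm", [0.01, 0.05, 0.1])
    def test_numeric_bisection_agrees_with_analytic(self, pp, pm):
        ka = critical_k(pp, pm, "analytic")
        kn = critical_k(pp, pm, "numeric")
        assert kn == pytest.approx(ka, rel=0.05)


class TestEquilibriumRadiusApproximation:
    def test_vanishes_without_dephosphorylation(self):
        assert req_approx(DropletParams(0.9, 0.0, 0.0)) == 0.0

    def test_arithmetic_value(self):
        # frozen from a high-precision symbolic evaluation at k = 0.1
        dp = DropletParams(0.9, 0.001, 0.1)
        assert req_approx(dp) == pytest.approx(0.6844820539343521,
                                               abs=1e-12)

    def test_dimensional_scaling(self):
        dp = DropletParams(0.9, 0.001, 0.1, D=60.0, k_s_to_ns=2100.0)
        ell = math.sqrt(60.0 / 2100.0)
        assert req_approx(dp) == pytest.approx(ell * 0.6844820539343521,
                                               rel=1e-12)

    def test_matches_numeric_fixed_point_well_below_critical(self):
        """The closed form is a small-k~ approximation: within 10% of the
        exact fixed point for k~ <= 0.2, degrading smoothly above."""
        errs = {}
        for k in (0.05, 0.1, 0.2, 0.3):
            dpk = DropletParams(0.95, 1e-3, k)
            errs[k] = abs(req_approx(dpk) - equilibrium_radius(dpk)) \
                / equilibrium_radius(dpk)
        assert errs[0.05] < 0.05
        assert errs[0.1] < 0.10
        assert errs[0.2] < 0.10
        assert errs[0.3] < 0.25  # outside the approximation's regime
        assert errs[0.05] < errs[0.1] < errs[0.2] < errs[0.3]


class TestPassiveGrowth:
    def test_initial_radius_at_time_zero(self):
        assert passive_growth(1.5, 0.2, 0.05, 0.9, 0.0) == 1.5

    def test_saturated_bath_square_root(self):
        # phi_inf = phi_plus -> R = R_init + sqrt(2 t)
        t = np.linspace(0.0, 5.0, 11)
        R = passive_growth(1.0, 0.9, 0.05, 0.9, t)
        assert np.allclose(R, 1.0 + np.sqrt(2.0 * t))

    def test_loglog_slope_is_half(self):
        t = np.geomspace(1e-3, 1e3, 200)
        R = passive_growth(2.0, 0.3, 0.05, 0.9, t)
        slope = np.polyfit(np.log(t), np.log(R - 2.0), 1)[0]
        assert slope == pytest.approx(0.5, abs=1e-6)

    def test_undersaturated_bath_rejected(self):
        with pytest.raises(ValueError):
            passive_growth(1.0, 0.04, 0.05, 0.9, 1.0)


class TestFluxScaling:
    def test_asymptotic_flux_scalings(self, dp):
        """Interior conversion scales with droplet volume (~R^3, from the
        small-R expansion); the exterior diffusive loading scales with
        surface area (~R^2 with a 1/(cR) correction) — the mismatch of
        the two powers is the size-selection mechanism."""
        k, c = dp.k_tilde_d, math.sqrt(1.0 + dp.k_tilde_d)

        def j_in(R):
            # surface-integrated flux just inside the interface
            h = 1e-8 * R
            grad = (profile_inside(R, R, dp)
                    - profile_inside(R - h, R, dp)) / h
            return -4.0 * math.pi * R**2 * grad

        small = np.array([0.01, 0.02, 0.04])
        vals = np.array([j_in(R) for R in small])
        exponent = np.polyfit(np.log(small), np.log(-vals), 1)[0]
        assert exponent == pytest.approx(3.0, abs=0.05)
        # prefactor: 4 pi [k(1-phi+) - phi+] / 3
        pref = vals[0] / small[0] ** 3
        expected = 4.0 * math.pi * (k * (1 - dp.phi_plus) - dp.phi_plus) / 3.0
        assert pref == pytest.approx(expected, rel=1e-2)

        def j_out(R):
            h = 1e-8 * R
            grad = (profile_outside(R + h, R, dp)
                    - profile_outside(R, R, dp)) / h
            return -4.0 * math.pi * R**2 * grad

        big = np.array([20.0, 40.0, 80.0])
        vals_out = np.array([j_out(R) for R in big])
        # exact closed form: 4 pi R^2 [k(phi- - 1) + phi-]/sqrt(1+k) (1 + 1/(cR))
        B = k * (dp.phi_minus - 1.0) + dp.phi_minus
        expected_out = (4.0 * math.pi * big**2 * B / c
                        * (1.0 + 1.0 / (c * big)))
        assert np.allclose(vals_out, expected_out, rtol=1e-4)
        exponent_out = np.polyfit(np.log(big), np.log(-vals_out), 1)[0]
        assert exponent_out == pytest.approx(2.0, abs=0.05)
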