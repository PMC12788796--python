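"""Assembly equilibrium: closed-form oracles and threshold behaviour."""

import math

import numpy as np
import pytest

from oligosep.equilibrium import (
    GelationError,
    assembly_threshold,
    distribution_from_monomer,
    distribution_statistics,
    effective_free_energy,
    equilibrium_distribution,
    threshold_curve,
)
from oligosep.thermo import (
    MixtureSpec,
    SizeDistribution,
    exchange_chemical_potentials,
    free_energy_density,
)


def geometric_closed_form(phi_1, spec):
    """Independent closed form for d=1, class 1: phi_i = i*phi_1^i*z^(i-1)
    with z = exp(1 - delta_omega/T) (geometric series in i)."""
    i = np.arange(1, spec.M + 1, dtype=float)
    z = math.exp(1.0 - spec.delta_omega / spec.T)
    return i * phi_1**i * z ** (i - 1.0)


def solve_closed_form(phi_tot, spec):
    """Root of the geometric-series conservation equation (oracle)."""
    from scipy.optimize import brentq

    z = math.exp(1.0 - spec.delta_omega / spec.T)

    def total(phi_1):
        x = phi_1 * z
        M = spec.M
        # sum_i i x^i = x(1 - (M+1)x^M + M x^(M+1))/(1-x)^2
        if abs(x - 1.0) < 1e-12:
            ssum = M * (M + 1) / 2.0
        else:
            ssum = x * (1 - (M + 1) * x**M + M * x ** (M + 1)) / (1 - x) ** 2
        return ssum / z

    # bracket within the series radius (x = phi_1*z < 1 at the solution)
    hi = min(phi_tot, 1.0 / z)
    return brentq(lambda p: total(p) - phi_tot, 1e-300, hi, xtol=1e-300,
                  rtol=8.9e-16, maxiter=300)


class TestDistributionFromMonomer:
    def test_dimer_value_with_equal_internal_energies(self):
        # all omega_i equal, class 1, M=2, phi_1=0.1 -> phi_2 = 2*0.01*e
        spec = MixtureSpec(M=2, d=1, e_int=0.0, T=1.0)
        d = distribution_from_monomer(0.1, 0.12, spec)
        assert d.phi[1] == pytest.approx(2 * 0.01 * math.e, rel=1e-14)

    def test_monomers_dominate_in_dilute_limit(self):
        spec = MixtureSpec(M=6, d=1, e_int=-2.0, T=0.8)
        d = distribution_from_monomer(1e-8, 1e-7, spec)
        assert np.all(d.phi[1:] / d.phi[0] < 1e-3)

    def test_matches_geometric_closed_form(self):
        spec = MixtureSpec(M=40, d=1, e_int=-3.0, T=0.8)
        d = distribution_from_monomer(2e-3, 0.05, spec)
        np.testing.assert_allclose(
            d.phi, geometric_closed_form(2e-3, spec), rtol=1e-12
        )

    def test_overflow_names_offending_size(self):
        spec = MixtureSpec(M=300, d=1, e_int=-8.0, T=0.5)
        with pytest.raises(OverflowError, match=r"i=\d+"):
            distribution_from_monomer(0.5, 0.6, spec)


class TestEquilibriumDistribution:
    def test_single_species_is_trivial(self):
        spec = MixtureSpec(M=1, chi=1.0, T=0.5)
        assert equilibrium_distribution(0.3, spec).phi[0] == 0.3

    def test_dimer_quadratic_formula(self):
        """M=2 closed form: phi_1 solves phi_1 + 2 z phi_1^2 = phi_tot."""
        spec = MixtureSpec(M=2, d=1, e_int=-1.5, T=0.6)
        z = math.exp(1.0 - spec.delta_omega / spec.T)
        phi_tot = 0.2
        phi_1 = (-1 + math.sqrt(1 + 8 * z * phi_tot)) / (4 * z)
        d = equilibrium_distribution(phi_tot, spec)
        assert d.phi[0] == pytest.approx(phi_1, rel=1e-12)

    @pytest.mark.parametrize("phi_tot", [1e-4, 1e-2, 0.3, 0.9])
    def test_closed_form_oracle_large_truncation(self, phi_tot):
        spec = MixtureSpec(M=500, d=1, e_int=-3.0, T=0.8)
        d = equilibrium_distribution(phi_tot, spec)
        p1 = solve_closed_form(phi_tot, spec)
        assert d.phi[0] == pytest.approx(p1, rel=1e-10)
        assert d.phi_tot == pytest.approx(phi_tot, abs=1e-12)

    @pytest.mark.parametrize(
        "spec_name", ["linear_spec", "class2_spec"]
    )
    def test_conservation_and_chemical_equilibrium(self, spec_name, request):
        spec = request.getfixturevalue(spec_name)
        for phi_tot in [0.01, 0.2, 0.6]:
            d = equilibrium_distribution(phi_tot, spec)
            assert abs(d.phi_tot - phi_tot) < 1e-12
            mu = exchange_chemical_potentials(d, spec, on_zero="neginf")
            finite = np.isfinite(mu)
            assert np.max(np.abs(mu[finite] - mu[0])) < 1e-8 * spec.T

    def test_total_is_monotone_in_monomer_fraction(self):
        spec = MixtureSpec(M=30, d=1, e_int=-2.0, T=0.7)
        phis = np.geomspace(1e-6, 0.015, 40)
        totals = [distribution_from_monomer(p, 0.3, spec).phi_tot for p in phis]
        assert np.all(np.diff(totals) > 0)

    def test_beyond_gel_point_raises_with_gelation_message(self):
        spec = MixtureSpec(M=200, d=3, e_int=-1.5, T=0.6)
        with pytest.raises(GelationError, match="gelation"):
            equilibrium_distribution(0.9, spec)


class TestAssemblyThreshold:
    def fd_dlog_di(self, phi_1, phi_tot, spec, h=1e-6):
        """Continuous-i derivative of ln(phi_i) at i=1 by central difference
        of the analytic size dependence (independent oracle)."""
        def lnphi(i):
            dw = spec.delta_omega * (1 - i ** (-1.0 / spec.d))
            b = dw
            if spec.interaction_class.value == "class2":
                b += (spec.chi_prime - spec.chi) * (1 - i ** (-1.0 / spec.d)) * (
                    1 - phi_tot
                )
            return math.log(i) + i * math.log(phi_1) + i * (1 - b / spec.T) - 1

        return (lnphi(1 + h) - lnphi(1 - h)) / (2 * h)

    def test_derivative_flips_sign_across_threshold(self):
        spec = MixtureSpec(M=100, d=1, e_int=-3.0, T=0.8)
        star = assembly_threshold(0.8, spec)
        lo = equilibrium_distribution(star * 0.8, spec)
        hi = equilibrium_distribution(min(star * 1.2, 0.95), spec)
        assert self.fd_dlog_di(lo.phi[0], lo.phi_tot, spec) < 0
        assert self.fd_dlog_di(hi.phi[0], hi.phi_tot, spec) > 0

    def test_monomers_dominate_below_threshold(self):
        spec = MixtureSpec(M=100, d=1, e_int=-3.0, T=0.8)
        star = assembly_threshold(0.8, spec)
        below = equilibrium_distribution(star * 0.02, spec)
        assert below.monomer_fraction() > 0.9

    def test_monomer_fraction_saturates_above_threshold(self):
        spec = MixtureSpec(M=100, d=1, e_int=-3.0, T=0.8)
        star = assembly_threshold(0.8, spec)
        above = equilibrium_distribution(min(star * 20, 0.9), spec)
        assert above.phi[0] < star

    def test_no_threshold_for_single_species(self):
        with pytest.raises(ValueError):
            assembly_threshold(0.8, MixtureSpec(M=1))

    def test_curve_interpolates_monotonically(self):
        spec = MixtureSpec(M=100, d=1, e_int=-3.0, T=0.8)
        curve = threshold_curve(spec, np.array([0.6, 0.8, 1.0]))
        assert np.all(np.diff(curve.phi_star) > 0)  # threshold rises with T
        mid = curve(0.7)
        assert curve.phi_star[0] < mid < curve.phi_star[1]


class TestEffectiveFreeEnergy:
    def test_single_species_reduces_to_flory_huggins(self):
        spec = MixtureSpec(M=1, chi=1.0, T=0.5, omega_inf=0.0)
        phi = 0.3
        bare = spec.T * (
            phi * math.log(phi) + (1 - phi) * math.log(1 - phi)
        ) + spec.chi * phi * (1 - phi)
        assert effective_free_energy(phi, spec) == pytest.approx(bare, rel=1e-12)

    def test_smooth_across_assembly_threshold(self):
        """No phase transition at phi* for d=1: the numerical second
        derivative is continuous across the threshold."""
        spec = MixtureSpec(M=200, d=1, e_int=-3.0, T=0.8)
        star = assembly_threshold(0.8, spec)
        h = 1e-4

        def fpp(phi):
            return (
                effective_free_energy(phi + h, spec)
                - 2 * effective_free_energy(phi, spec)
                + effective_free_energy(phi - h, spec)
            ) / h**2

        left, right = fpp(star * (1 - 0.02)), fpp(star * (1 + 0.02))
        mid = fpp(star)
        assert abs(left - mid) < 0.2 * abs(mid)
        assert abs(right - mid) < 0.2 * abs(mid)

    def test_truncation_convergence(self):
        base = MixtureSpec(M=50, d=1, e_int=-2.0, T=0.8)
        for phi_tot in [0.05, 0.3]:
            f50 = effective_free_energy(phi_tot, base)
            f200 = effective_free_energy(phi_tot, base.with_size(200))
            assert f50 == pytest.approx(f200, abs=1e-8)


class TestDistributionStatistics:
    def test_monomer_dominated_peak(self):
        spec = MixtureSpec(M=20, d=1, e_int=-1.0, T=0.8)
        d = equilibrium_distribution(1e-4, spec)
        assert distribution_statistics(d).i_max == 1

    def test_mean_size_scales_as_sqrt_phi_tot(self):
        """Above the threshold, peak and mean grow like sqrt(phi_tot)."""
        spec = MixtureSpec(M=600, d=1, e_int=-6.0, T=1.0)
        phis = np.geomspace(0.03, 0.3, 6)
        means = []
        for p in phis:
            means.append(distribution_statistics(equilibrium_distribution(p, spec)).mean_size)
        slope = np.polyfit(np.log(phis), np.log(means), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.05)

    def test_tail_is_exponential(self):
        spec = MixtureSpec(M=80, d=1, e_int=-3.0, T=0.8)
        d = equilibrium_distribution(0.01, spec)
        stats = distribution_statistics(d)
        assert stats.tail_decay_rate > 0
        assert stats.tail_r2 > 0.999

    def test_tail_fit_unavailable_for_tiny_truncation(self):
        d = SizeDistribution(np.array([0.2, 0.01]))
        stats = distribution_statistics(d)
        assert stats.tail_decay_rate is None
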