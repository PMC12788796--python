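"""Mass-action assembly kinetics: detailed balance, conservation, fluxes."""

import warnings

import numpy as np
import pytest

from oligosep.equilibrium import equilibrium_distribution
from oligosep.kinetics import (
    RateForm,
    RateModel,
    TwoPhaseState,
    embed_monomer_coexistence,
    exchange_fluxes,
    integrate,
    net_rates,
    pair_rate,
    referenced_rate_model,
    step,
    volume_change_map,
)
from oligosep.kinetics import _derivatives, flash_projection
from oligosep.phases import common_tangent
from oligosep.thermo import MixtureSpec, SizeDistribution


@pytest.fixture
def kin_spec():
    """Shallow-quench class-1 mixture used for kinetics runs."""
    return MixtureSpec(M=10, d=1, chi=1.0, e_int=-0.1, T=0.48)


@pytest.fixture
def rates():
    return RateModel(dt_factor=5.0)


def equilibrium_two_phase(phi_tot, spec):
    """Full thermodynamic equilibrium as a TwoPhaseState (static oracle)."""
    ct = common_tangent(phi_tot, spec)
    return TwoPhaseState(ct.phase_I.phi.copy(), ct.phase_II.phi.copy(), ct.v_I)


class TestPairRates:
    def test_vanishes_at_assembly_equilibrium(self, kin_spec, rates):
        st = equilibrium_distribution(0.3, kin_spec)
        for i, j in [(1, 1), (2, 3), (4, 5)]:
            assert pair_rate(i, j, st, kin_spec, rates) == pytest.approx(0.0, abs=1e-13)

    def test_symmetric_in_partners(self, kin_spec, rates):
        rng = np.random.default_rng(5)
        st = SizeDistribution(rng.uniform(0.005, 0.05, 10))
        for i, j in [(1, 2), (3, 4), (2, 6)]:
            assert pair_rate(i, j, st, kin_spec, rates) == pytest.approx(
                pair_rate(j, i, st, kin_spec, rates), rel=1e-12
            )

    def test_positive_for_favourable_association(self, rates):
        """Abundant monomers with a depleted dimer pool drive net
        association (the product-state chemical potential is lower)."""
        spec = MixtureSpec(M=3, d=1, e_int=-2.0, T=0.5)
        st = SizeDistribution(np.array([0.3, 1e-9, 1e-9]))
        assert pair_rate(1, 1, st, spec, rates) > 0

    def test_truncation_closure(self, kin_spec, rates):
        st = SizeDistribution(np.full(10, 0.02))
        assert pair_rate(6, 7, st, kin_spec, rates) == 0.0


class TestNetRates:
    def test_volume_conserving(self, kin_spec, rates):
        rng = np.random.default_rng(9)
        st = SizeDistribution(rng.uniform(0.002, 0.05, 10))
        r = net_rates(st, kin_spec, rates)
        assert abs(r.sum()) < 1e-12 * np.abs(r).max()

    def test_zero_at_assembly_equilibrium(self, kin_spec, rates):
        st = equilibrium_distribution(0.35, kin_spec)
        r = net_rates(st, kin_spec, rates)
        assert np.max(np.abs(r)) < 1e-12

    def test_monomer_dimer_hand_expansion(self, rates):
        """M=2: the only reaction is 2 monomers <-> 1 dimer, consuming two
        monomer volumes per event: r_1 = -2 dr_11, r_2 = +2 dr_11."""
        spec = MixtureSpec(M=2, d=1, e_int=-1.0, T=0.45)
        st = SizeDistribution(np.array([0.2, 0.05]))
        dr11 = pair_rate(1, 1, st, spec, rates)
        r = net_rates(st, spec, rates)
        assert r[0] == pytest.approx(-2 * dr11, rel=1e-12)
        assert r[1] == pytest.approx(2 * dr11, rel=1e-12)

    def test_rate_model_validation(self):
        with pytest.raises(ValueError):
            RateModel(k_tilde=-1.0)
        with pytest.raises(ValueError):
            RateModel(k_ij_form=RateForm.CUSTOM)
        asym = RateModel(k_ij_form=RateForm.CUSTOM, custom_k=lambda i, j: i + 2 * j)
        with pytest.raises(ValueError, match="symmetric"):
            asym.k_matrix(4)

    def test_referenced_rates_share_equilibria(self, kin_spec):
        """The activity-referenced coefficients rescale channels but keep
        detailed balance: rates still vanish at assembly equilibrium."""
        st = equilibrium_distribution(0.3, kin_spec)
        rm = referenced_rate_model(kin_spec, mu_ref=-0.5)
        r = net_rates(st, kin_spec, rm)
        assert np.max(np.abs(r)) < 1e-10


class TestExchangeFluxes:
    def test_zero_at_full_thermodynamic_equilibrium(self, kin_spec, rates):
        state = equilibrium_two_phase(0.4, kin_spec)
        logK = rates.log_k_matrix(kin_spec.M)
        r_I = net_rates(SizeDistribution(state.phi_I), kin_spec, rates)
        r_II = net_rates(SizeDistribution(state.phi_II), kin_spec, rates)
        u, u_s = exchange_fluxes(state, r_I, r_II, kin_spec)
        assert np.max(np.abs(u)) < 1e-10
        assert abs(u_s) < 1e-10

    def test_fluxes_preserve_phase_equilibrium_vs_zeroed(self, kin_spec):
        """One Euler step with the solved fluxes keeps the phases at
        equilibrium; zeroing the fluxes degrades the residual >= 10x."""
        rates = RateModel()
        state = embed_monomer_coexistence(0.4, kin_spec)
        for _ in range(200):  # move off the singular trace-floor embedding
            state = step(state, kin_spec, rates)
        state = flash_projection(state, kin_spec)
        dy_I, dy_II, dv, r_I, r_II = _derivatives(state, kin_spec, rates)
        dt = 0.1 * rates.t0
        v = state.v_I + dt * dv
        with_flux = TwoPhaseState(
            (state.v_I * state.phi_I + dt * dy_I) / v,
            ((1 - state.v_I) * state.phi_II + dt * dy_II) / (1 - v),
            float(v),
        )
        res_flux = with_flux.phase_equilibrium_residual(kin_spec)
        assert res_flux < 1e-6
        # same reactions, no diffusive exchange
        no_flux = TwoPhaseState(
            state.phi_I + dt * r_I, state.phi_II + dt * r_II, state.v_I
        )
        res_no = no_flux.phase_equilibrium_residual(kin_spec)
        assert res_no > 10 * res_flux


class TestStepAndConservation:
    def test_stationary_at_thermodynamic_equilibrium(self, kin_spec, rates):
        state = equilibrium_two_phase(0.4, kin_spec)
        nxt = step(state, kin_spec, rates)
        assert np.max(np.abs(nxt.phi_I - state.phi_I)) < 1e-12
        assert np.max(np.abs(nxt.phi_II - state.phi_II)) < 1e-12
        assert abs(nxt.v_I - state.v_I) < 1e-12

    def test_global_conservation_over_many_steps(self, kin_spec, rates):
        state = embed_monomer_coexistence(0.4, kin_spec)
        phi0 = state.phi_tot
        for _ in range(2000):
            state = step(state, kin_spec, rates)
        assert abs(state.phi_tot - phi0) < 1e-12

    def test_free_energy_decreases_along_transient(self, kin_spec):
        rates = RateModel()  # dt = t0: accurate explicit steps
        state = embed_monomer_coexistence(0.4, kin_spec)
        F = [state.total_free_energy(kin_spec)]
        for _ in range(500):
            state = step(state, kin_spec, rates)
            F.append(state.total_free_energy(kin_spec))
        F = np.asarray(F)
        assert np.all(np.diff(F) <= 1e-12 * np.abs(F[:-1]))

    def test_flash_projection_restores_equilibrium_exactly(self, kin_spec, rates):
        state = embed_monomer_coexistence(0.4, kin_spec)
        for _ in range(300):
            state = step(state, kin_spec, rates)
        psi0 = state.psi
        proj = flash_projection(state, kin_spec)
        assert proj.phase_equilibrium_residual(kin_spec) < 1e-10
        np.testing.assert_allclose(proj.psi, psi0, rtol=0, atol=1e-14)


class TestIntegrate:
    def test_rejects_planar_and_spherical_assemblies(self, rates):
        spec = MixtureSpec(M=10, d=2, e_int=-0.5, T=0.5)
        state = TwoPhaseState(np.full(10, 0.02), np.full(10, 0.01), 0.3)
        with pytest.raises(ValueError, match="d=1"):
            integrate(state, spec, rates, t_end=1.0)

    def test_dense_phase_grows_for_class1(self, kin_spec, rates):
        init = embed_monomer_coexistence(0.4, kin_spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = integrate(init, kin_spec, rates, t_end=500, record_every=200)
        assert traj.v_I[-1] > traj.v_I[0]
        assert np.all(np.diff(traj.times) > 0)

    def test_embedding_is_at_phase_equilibrium(self, kin_spec):
        init = embed_monomer_coexistence(0.4, kin_spec)
        assert init.phase_equilibrium_residual(kin_spec) < 1e-10
        # trace species present in both phases at the floor scale
        assert np.all(init.phi_I[1:] > 0)
        assert np.all(init.phi_II[1:] > 0)

    def test_embedding_outside_binodal_rejected(self, kin_spec):
        with pytest.raises(ValueError):
            embed_monomer_coexistence(0.05, kin_spec)


class TestVolumeChangeMap:
    def test_monomer_only_mixture_is_neutral(self):
        """When assemblies cannot form (M=1) the initial and final
        coexistence coincide: every demixed point is NEUTRAL."""
        spec = MixtureSpec(M=1, chi=1.0, T=0.45, omega_inf=0.0)
        df = volume_change_map(spec, [0.3, 0.5, 0.7], [0.45])
        assert set(df["label"]) == {"NEUTRAL"}

    def test_labels_outside_initial_binodal(self, kin_spec):
        df = volume_change_map(kin_spec, [0.01, 0.4], [0.48])
        by_phi = dict(zip(df["phi_tot"], df["label"]))
        assert by_phi[0.01] == "not-demixed-initially"
        assert by_phi[0.4] in ("GROW", "SHRINK")

    def test_class1_grow_then_shrink_ordering(self):
        spec = MixtureSpec(M=60, d=1, chi=1.0, e_int=-1.0, T=0.45)
        df = volume_change_map(spec, np.arange(0.25, 0.76, 0.1), [0.45])
        labels = [l for l in df.sort_values("phi_tot")["label"]
                  if l in ("GROW", "SHRINK")]
        assert "GROW" in labels and "SHRINK" in labels
        switch = labels.index("SHRINK")
        assert all(l == "GROW" for l in labels[:switch])
        assert all(l == "SHRINK" for l in labels[switch:])
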