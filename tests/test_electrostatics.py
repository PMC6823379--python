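"""Charge-density binning, symmetrization and the double integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import poreflux as pf
from poreflux.errors import ContractError
from poreflux.units import EPS0_E_PER_V_NM

from conftest import make_scripted_trajectory


def profile_from(rho_by_species, z_lo=-8.0, z_hi=8.0):
    arrs = {k: np.asarray(v, float) for k, v in rho_by_species.items()}
    n = len(next(iter(arrs.values())))
    return pf.ChargeDensityProfile(
        bin_edges=np.linspace(z_lo, z_hi, n + 1), rho_by_species=arrs)


class TestChargeDensityProfile:
    def test_single_fixed_charge_lands_in_its_bin(self):
        # +1 charge at z = 5.05 in a 10 nm box, 100 slices of 0.1 nm
        traj = make_scripted_trajectory([[5.05, 5.05, 5.05]])
        prof = pf.charge_density_profile(traj, n_slices=100)
        rho = prof.rho_by_species["K+"]
        hits = np.flatnonzero(rho)
        assert hits.size == 1
        k = int(hits[0])
        assert prof.bin_edges[k] == pytest.approx(5.0)
        # density = 1 / (L_x L_y dz) = 1 / (5*5*0.1)
        assert rho[k] == pytest.approx(1.0 / 2.5)
        assert prof.net_charge() == pytest.approx(1.0, abs=1e-9)

    def test_neutral_system_has_zero_net_charge(self, rng):
        species = (pf.IonSpecies("K+", +1, 2.54, 20),
                   pf.IonSpecies("CL-", -1, 2.45, 20))
        z = rng.uniform(0, 10, size=(40, 5))
        traj = make_scripted_trajectory(
            z, species=species, species_index=[0] * 20 + [1] * 20)
        prof = pf.charge_density_profile(traj, n_slices=50)
        assert prof.net_charge() == pytest.approx(0.0, abs=1e-9)

    def test_coarse_profile_is_volume_average_of_fine(self, rng):
        species = (pf.IonSpecies("K+", +1, 2.54, 30),)
        z = rng.uniform(0, 10, size=(30, 4))
        traj = make_scripted_trajectory(z, species=species,
                                        species_index=[0] * 30)
        fine = pf.charge_density_profile(traj, n_slices=100)
        coarse = pf.charge_density_profile(traj, n_slices=50)
        merged = fine.rho_by_species["K+"].reshape(50, 2).mean(axis=1)
        np.testing.assert_allclose(coarse.rho_by_species["K+"], merged,
                                   rtol=1e-9, atol=1e-12)

    def test_empty_selection_rejected(self):
        traj = make_scripted_trajectory([[1.0, 2.0]])
        with pytest.raises(ContractError):
            pf.charge_density_profile(traj, frame_range=slice(0, 0))


class TestSymmetrize:
    def test_even_profile_is_fixed_point(self):
        z = np.linspace(-7.96, 7.96, 200)
        prof = profile_from({"A": np.cos(z)})
        sym = pf.symmetrize_profile(prof, z_center=0.0)
        np.testing.assert_allclose(sym.rho_by_species["A"], np.cos(z),
                                   atol=1e-12)

    def test_odd_profile_cancels(self):
        z = np.linspace(-7.96, 7.96, 200)
        prof = profile_from({"A": np.sin(z)})
        sym = pf.symmetrize_profile(prof, z_center=0.0)
        np.testing.assert_allclose(sym.rho_by_species["A"], 0.0, atol=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_idempotent(self, seed):
        r = np.random.default_rng(seed).normal(size=60)
        prof = profile_from({"A": r})
        once = pf.symmetrize_profile(prof)
        twice = pf.symmetrize_profile(once)
        np.testing.assert_allclose(twice.rho_by_species["A"],
                                   once.rho_by_species["A"], atol=1e-12)


class TestPotentialFromDensity:
    def test_zero_density_zero_potential(self):
        prof = profile_from({"A": np.zeros(100)})
        pot = pf.potential_from_density(prof)
        assert not pot.psi.any()

    def test_capacitor_drop(self):
        sigma, d = 0.05, 4.0
        fx = pf.make_density_fixture("capacitor", sigma=sigma, separation=d,
                                     width=0.5, n=1601)
        prof = profile_from({"fix": fx.rho})
        # fixture grid holds bin centers; rebuild matching edges
        dz = fx.grid[1] - fx.grid[0]
        prof = pf.ChargeDensityProfile(bin_edges=fx.bin_edges,
                                       rho_by_species={"fix": fx.rho})
        pot = pf.potential_from_density(prof)
        drop = abs(pot.psi[-1] - pot.psi[0])
        assert drop == pytest.approx(sigma * d / EPS0_E_PER_V_NM, rel=5e-3)

    def test_gaussian_dipole_converges_second_order(self):
        errs, hs = [], []
        for n in (201, 401, 801):
            fx = pf.make_density_fixture("gaussian_dipole", n=n)
            prof = pf.ChargeDensityProfile(bin_edges=fx.bin_edges,
                                           rho_by_species={"fix": fx.rho})
            pot = pf.potential_from_density(prof)
            ref = fx.closed_form_potential(pot.z_grid)
            ref = ref - ref[0]
            errs.append(np.max(np.abs(pot.psi - ref)))
            hs.append(fx.grid[1] - fx.grid[0])
        order = np.polyfit(np.log(hs), np.log(errs), 1)[0]
        assert 1.8 < order < 2.3

    def test_linearity(self, rng):
        r1, r2 = rng.normal(size=80), rng.normal(size=80)
        a, b = 2.5, -1.3
        psi = lambda r: pf.potential_from_density(
            profile_from({"A": r})).psi
        np.testing.assert_allclose(psi(a * r1 + b * r2),
                                   a * psi(r1) + b * psi(r2), atol=1e-9)

    def test_component_closure(self, rng):
        prof = profile_from({"A": rng.normal(size=60),
                             "B": rng.normal(size=60)})
        pot = pf.potential_from_density(prof)
        pot = pf.add_external_field(pot, pf.FieldSpec(0.01))
        total = sum(pot.components.values())
        np.testing.assert_allclose(pot.psi, total, atol=1e-12)

    def test_symmetric_neutral_density_gives_symmetric_potential(self):
        z = np.linspace(-8, 8, 161)
        rho = (1.0 - 2.0 * z ** 2) * np.exp(-z ** 2)  # even, net-neutral
        prof = pf.ChargeDensityProfile(
            bin_edges=np.linspace(-8.05, 8.05, 162),
            rho_by_species={"A": rho})
        pot = pf.potential_from_density(prof)
        np.testing.assert_allclose(pot.psi, pot.psi[::-1], atol=1e-9)


class TestExternalField:
    def test_zero_field_unchanged(self):
        prof = profile_from({"A": np.zeros(50)})
        pot = pf.potential_from_density(prof)
        pot2 = pf.add_external_field(pot, pf.FieldSpec(0.0))
        np.testing.assert_allclose(pot2.psi, pot.psi)

    def test_linear_ramp_span(self):
        # 0.02 V/nm over 16 nm spans 0.32 V end to end
        prof = pf.ChargeDensityProfile(
            bin_edges=np.linspace(0.0, 16.0, 101),
            rho_by_species={"A": np.zeros(100)})
        pot = pf.add_external_field(pf.potential_from_density(prof),
                                    pf.FieldSpec(0.02))
        span = pot.psi[0] - pot.psi[-1]
        assert span == pytest.approx(0.02 * (pot.z_grid[-1] - pot.z_grid[0]),
                                     rel=1e-12)

    def test_add_then_subtract_restores(self, rng):
        prof = profile_from({"A": rng.normal(size=64)})
        pot = pf.potential_from_density(prof)
        back = pf.add_external_field(
            pf.add_external_field(pot, pf.FieldSpec(0.03)),
            pf.FieldSpec(-0.03))
        np.testing.assert_allclose(back.psi, pot.psi, atol=1e-15)


class TestPotentialBias:
    @pytest.mark.parametrize("e, lz, mv", [
        (0.01, 16.0, 160.0),
        (0.02, 18.5, 370.0),
        (0.0, 18.5, 0.0),
    ])
    def test_bias_values(self, e, lz, mv):
        assert pf.potential_bias(pf.FieldSpec(e),
                                 pf.BoxGeometry(10, 10, lz)) == \
            pytest.approx(mv, rel=1e-12)
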