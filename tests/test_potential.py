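"""Pair-potential construction: closed forms, term properties, tabulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microemu.potential import (
    PotentialParams,
    barrier_height,
    bjerrum_length,
    debye_length,
    steric_contact_amplitude,
    tabulate,
    total_potential,
    u_core,
    u_coulomb,
    u_steric,
    u_vdw,
)


class TestElectrostaticLengths:
    def test_bjerrum_water_room_temperature(self):
        # e^2/(4 pi eps0 eps_r kB T) with CODATA constants
        assert bjerrum_length(298.15, 80.0) == pytest.approx(7.0057, abs=2e-3)

    def test_bjerrum_scalings(self):
        base = bjerrum_length(298.15, 80.0)
        assert bjerrum_length(298.15, 160.0) == pytest.approx(base / 2)
        assert bjerrum_length(596.30, 80.0) == pytest.approx(base / 2)

    def test_debye_length_saline_water(self):
        # 1:1 electrolyte at the sample salinity, 0.2 mol/l
        assert debye_length(0.2) == pytest.approx(6.8669, abs=2e-3)
        # rule of thumb kappa^-1 ~ 3.04/sqrt(c) Angstrom at room temperature
        assert debye_length(0.2) == pytest.approx(3.04 / np.sqrt(0.2), rel=0.015)

    def test_debye_sqrt_scaling(self):
        assert debye_length(0.05) == pytest.approx(2 * debye_length(0.2))

    @pytest.mark.parametrize("bad", [(-1.0, 80.0), (298.15, 0.0)])
    def test_bjerrum_invalid(self, bad):
        with pytest.raises(ValueError):
            bjerrum_length(*bad)

    def test_debye_invalid(self):
        with pytest.raises(ValueError):
            debye_length(0.0)


class TestTerms:
    def test_core_contact_and_far_field(self, default_params):
        p = default_params
        assert u_core(p.sigma, p) == pytest.approx(1.0)
        assert u_core(3 * p.sigma, p) < 1e-10
        r = np.linspace(0.3 * p.sigma, p.sigma, 50)
        assert np.all(np.diff(u_core(r, p)) < 0)

    def test_vdw_negative_and_vanishing(self, default_params):
        p = default_params
        r = np.linspace(p.sigma + p.vdw_inner_gap + 1e-9, 10 * p.R, 200)
        v = u_vdw(r, p)
        assert np.all(v < 0)
        assert np.all(np.diff(v) > 0)  # monotone toward zero
        assert u_vdw(1e6, p) == pytest.approx(0.0, abs=1e-12)

    def test_vdw_far_field_asymptote(self, default_params):
        p = default_params
        r = 20 * p.R
        asym = -(16.0 / 9.0) * p.A_H * p.R**6 / r**6
        assert u_vdw(r, p) == pytest.approx(asym, rel=0.05)

    def test_coulomb_contact_value(self, default_params):
        # renormalized DLVO prefactor evaluated at r = sigma with defaults
        assert u_coulomb(124.0, default_params) == pytest.approx(9.4934, abs=5e-3)

    def test_coulomb_is_yukawa(self, default_params):
        p = default_params
        r = np.linspace(p.sigma, p.R_c, 64)
        const = u_coulomb(r, p) * r * np.exp(r / p.kappa_inv)
        assert np.allclose(const, const[0], rtol=1e-12)

    def test_coulomb_zero_charge(self):
        p = PotentialParams(Z_eff=0.0)
        assert np.all(u_coulomb(np.linspace(100, 200, 10), p) == 0)

    @pytest.mark.parametrize("n_p, contact", [(4, 2.6), (8, 5.2), (12, 7.8)])
    def test_steric_contact_amplitudes(self, n_p, contact):
        p = PotentialParams(N_p=n_p)
        assert steric_contact_amplitude(n_p) == pytest.approx(contact)
        assert u_steric(p.sigma, p) == pytest.approx(contact)

    def test_steric_decay_shape(self):
        p = PotentialParams(N_p=4)
        r = p.sigma + p.lambda_steric
        expected = p.V_steric_contact * (p.sigma / r) * np.exp(-1.0)
        assert u_steric(r, p) == pytest.approx(expected)

    def test_steric_vanishes_bare(self, default_params):
        assert np.all(u_steric(np.linspace(100, 240, 20), default_params) == 0)

    def test_negative_r_rejected(self, default_params):
        for f in (u_core, u_vdw, u_coulomb, u_steric, total_potential):
            with pytest.raises(ValueError):
                f(-1.0, default_params)


class TestTotal:
    def test_zero_at_cutoff(self, default_params):
        assert total_potential(default_params.R_c, default_params) == pytest.approx(0.0, abs=1e-14)

    def test_additivity(self, default_params, rng):
        p = default_params
        r = rng.uniform(0.95 * p.sigma, p.R_c, size=64)
        parts = u_core(r, p) + u_vdw(r, p) + u_coulomb(r, p) + u_steric(r, p)
        shift = parts - total_potential(r, p)
        assert np.allclose(shift, shift[0], rtol=1e-12)

    def test_pure_core_when_other_terms_off(self):
        p = PotentialParams(A_H=0.0, Z_eff=0.0, N_p=0)
        r = np.linspace(0.95 * p.sigma, 0.99 * p.R_c, 32)
        expected = u_core(r, p) - u_core(np.array(p.R_c), p)
        assert np.allclose(total_potential(r, p), expected)

    def test_barrier_monotone_in_grafting(self, default_params):
        barriers = [barrier_height(default_params.with_n_p(n)) for n in (0, 4, 8, 12)]
        assert np.all(np.diff(barriers) > 0)

    @given(n_p=st.integers(min_value=0, max_value=40))
    @settings(max_examples=20, deadline=None)
    def test_steric_contact_nondecreasing_in_np(self, n_p):
        assert steric_contact_amplitude(n_p + 1) >= steric_contact_amplitude(n_p)


class TestTabulation:
    def test_force_consistency_and_cutoff(self, pot_np4):
        p = pot_np4.params
        assert pot_np4.U[-1] == pytest.approx(0.0, abs=1e-12)
        dU = np.gradient(pot_np4.U, pot_np4.r)
        mask = np.ones_like(pot_np4.r, dtype=bool)
        mask[:2] = mask[-2:] = False
        h = pot_np4.r[1] - pot_np4.r[0]
        mask &= np.abs(pot_np4.r - (p.sigma + p.vdw_inner_gap)) > 2 * h
        err = np.max(np.abs(pot_np4.F[mask] + dU[mask]))
        assert err < 1e-3 * np.max(np.abs(pot_np4.F))

    def test_grid_convergence(self, params_np4):
        # outside the steep core region, doubling the grid leaves the
        # interpolated energy unchanged to < 1e-6 k_BT
        coarse = tabulate(params_np4, n_points=4096)
        fine = tabulate(params_np4, n_points=8192)
        mids = 0.5 * (coarse.r[:-1] + coarse.r[1:])
        r_mid = mids[mids > 1.3 * params_np4.sigma][::17]
        assert np.max(np.abs(coarse.energy(r_mid) - fine.energy(r_mid))) < 1e-6

    def test_invalid_grid_rejected(self, params_np4):
        with pytest.raises(ValueError):
            tabulate(params_np4, n_points=100)
        with pytest.raises(ValueError):
            tabulate(params_np4, r_min=5 * params_np4.R)

    def test_reduced_view(self, pot_np4):
        red = pot_np4.to_reduced()
        assert red.r[-1] == pytest.approx(4.0)
        # energies unchanged, forces rescaled by R
        assert np.allclose(red.U, pot_np4.U)
        assert np.allclose(red.F, pot_np4.F * pot_np4.params.R)


class TestParams:
    def test_invariants(self):
        with pytest.raises(ValueError):
            PotentialParams(R=-1)
        with pytest.raises(ValueError):
            PotentialParams(lambda_steric=0)
        with pytest.raises(ValueError):
            PotentialParams(N_p=-2)
        with pytest.raises(ValueError):
            PotentialParams(R_c_factor=1.5)

    def test_derived_fields_follow_inputs(self):
        p_hot = PotentialParams(T=596.30)
        p_ref = PotentialParams()
        assert p_hot.l_B == pytest.approx(p_ref.l_B / 2)
        assert p_ref.sigma == 2 * p_ref.R
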