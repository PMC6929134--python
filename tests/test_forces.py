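"""Force kernels against analytic results and numerical energy gradients."""

import numpy as np
import pytest

from polymag import ModelParams
from polymag.builder import DipoleSet
from polymag.forces import (PairEnergyParams, WCA_CUT, area_energy,
                            area_forces, bending_energy, bending_forces,
                            bond_energy, bond_forces, dipolar_energy,
                            dipolar_forces_torques, stretch_energy,
                            stretch_forces, total_forces, wca_energy,
                            wca_forces, zeeman_torques)
from polymag.mesh import build_icosphere

from conftest import numerical_gradient


def _pair_params(lambda_dd=5.0, dp=0.3):
    return PairEnergyParams.from_model(ModelParams(q=6.0,
                                                   lambda_dd=lambda_dd,
                                                   dp=dp))


def _dipoles(positions, orientations, dp=0.3, lambda_dd=5.0):
    e = np.asarray(orientations, dtype=float)
    e = e / np.linalg.norm(e, axis=1)[:, None]
    mu = np.sqrt(lambda_dd * dp**3)
    return DipoleSet(positions=np.asarray(positions, dtype=float),
                     orientations=e, mu=mu, dp=dp)


# ---------------------------------------------------------------------------
# elastic terms
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def shell():
    return build_icosphere(radius=1.0, target_edge=0.6)


class TestShellElasticity:

    def test_rest_state_is_force_free(self, shell):
        pos = shell.bead_positions
        assert np.abs(stretch_forces(shell, pos, 100.0)).max() < 1e-9
        assert np.abs(area_forces(shell, pos, 100.0)).max() < 1e-9
        assert np.abs(bending_forces(shell, pos, 100.0)).max() < 1e-9

    def test_single_stretched_edge_is_hookean(self):
        import polymag._kernels as K
        p2 = np.array([[0.0, 0, 0], [1.05, 0, 0]])
        F2 = np.zeros_like(p2)
        E, err = K.stretch_kernel(p2, np.array([[0, 1]], dtype=np.int64),
                                  np.array([1.0]), 80.0, F2)
        assert err == 0
        assert F2[1, 0] == pytest.approx(-80.0 * 0.05, rel=1e-12)
        assert np.allclose(F2[0], -F2[1])
        assert E == pytest.approx(0.5 * 80.0 * 0.05**2, rel=1e-12)

    @pytest.mark.parametrize("term_f,term_e,k", [
        (stretch_forces, stretch_energy, 37.0),
        (area_forces, area_energy, 61.0),
        (bending_forces, bending_energy, 11.0),
    ])
    def test_force_equals_minus_numeric_gradient(self, shell, term_f,
                                                 term_e, k):
        rng = np.random.default_rng(12)
        pos = shell.bead_positions + 0.03 * rng.normal(
            size=shell.bead_positions.shape)
        F = term_f(shell, pos, k)
        G = numerical_gradient(lambda x: term_e(shell, x, k), pos)
        scale = max(np.abs(F).max(), 1.0)
        assert np.abs(F + G).max() / scale < 1e-5

    def test_newtons_third_law_global(self, shell):
        rng = np.random.default_rng(5)
        pos = shell.bead_positions + 0.05 * rng.normal(
            size=shell.bead_positions.shape)
        for f in (stretch_forces, area_forces, bending_forces):
            assert np.abs(f(shell, pos, 50.0).sum(axis=0)).max() < 1e-9

    def test_dilated_triangle_restoring_force_inward(self, shell):
        pos = shell.bead_positions * 1.1  # isotropic dilation grows areas
        F = area_forces(shell, pos, 10.0)
        # restoring force points inward (against the dilation direction)
        radial = np.einsum("ij,ij->i", F, pos)
        assert np.all(radial < 0)

    def test_degenerate_triangle_raises(self, shell):
        pos = shell.bead_positions.copy()
        t = shell.triangles[0]
        pos[t[1]] = pos[t[0]]  # zero-area triangle, zero-length edge
        with pytest.raises(FloatingPointError):
            area_forces(shell, pos, 10.0)
        with pytest.raises(FloatingPointError):
            stretch_forces(shell, pos, 10.0)


class TestIntershellBonds:
    def test_bond_hooke_and_balance(self, coarse_system, coarse_params):
        asm, _ = coarse_system
        pos = asm.all_positions()
        k = 50.0
        assert np.abs(bond_forces(asm, pos, k)).max() < 1e-9  # built at h
        n = asm.n_beads_per_shell
        i, j = asm.intershell_bonds[0]
        x = 0.07
        u = pos[j + n] - pos[i]
        pos2 = pos.copy()
        pos2[j + n] += x * u / np.linalg.norm(u)
        F = bond_forces(asm, pos2, k)
        assert np.linalg.norm(F[j + n]) == pytest.approx(k * x, rel=1e-9)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-10)
        # gradient check on the perturbed pair only (cheap):
        h = 1e-6
        for d in range(3):
            pp = pos2.copy()
            pp[i, d] += h
            pm = pos2.copy()
            pm[i, d] -= h
            g = (bond_energy(asm, pp, k) - bond_energy(asm, pm, k)) / (2 * h)
            assert -g == pytest.approx(F[i, d], abs=1e-5)


# ---------------------------------------------------------------------------
# WCA
# ---------------------------------------------------------------------------

class TestWCA:
    def test_zero_at_and_beyond_cutoff(self):
        sigma = 0.475
        for r in (WCA_CUT * sigma, WCA_CUT * sigma + 1e-12, 2 * sigma):
            pa = np.array([[0.0, 0, 0]])
            pb = np.array([[r, 0, 0]])
            Fa, Fb = wca_forces(pa, 0.3, pb, 0.65)
            assert np.all(Fa == 0) and np.all(Fb == 0)
            assert wca_energy(pa, 0.3, pb, 0.65) == 0.0

    def test_force_at_contact_distance(self):
        # |F| = 24 eps / sigma at r = sigma (closed-form derivative)
        sigma = 0.5
        pa = np.array([[0.0, 0, 0]])
        pb = np.array([[sigma, 0, 0]])
        Fa, _ = wca_forces(pa, sigma, pb, sigma, epsilon=1.3)
        assert np.linalg.norm(Fa[0]) == pytest.approx(24 * 1.3 / sigma,
                                                      rel=1e-12)
        assert Fa[0, 0] < 0  # repulsive: pushes a away from b

    def test_force_matches_numeric_gradient(self):
        sigma = 0.4
        r = 1.05 * sigma
        pb = np.array([[r, 0.01, -0.02]])

        def U(pa):
            return wca_energy(pa, sigma, pb, sigma, epsilon=2.0)

        pa = np.array([[0.0, 0, 0]])
        Fa, _ = wca_forces(pa, sigma, pb, sigma, epsilon=2.0)
        G = numerical_gradient(U, pa, h=1e-8)
        assert np.abs(Fa + G).max() / np.abs(Fa).max() < 1e-6

    def test_intra_species_pair_sum_zero(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 1.0, (20, 3))
        F, _ = wca_forces(pos, 0.3)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-10)


# ---------------------------------------------------------------------------
# dipolar + Zeeman
# ---------------------------------------------------------------------------

class TestDipolar:
    def test_head_to_tail_attraction_magnitude(self):
        # co-aligned dipoles along their axis: F = -6 C / r^4 (attractive)
        lam, dp, r = 5.0, 0.3, 0.5
        C = lam * dp**3
        d = _dipoles([[0, 0, 0], [0, 0, r]], [[0, 0, 1], [0, 0, 1]],
                     dp=dp, lambda_dd=lam)
        F, T = dipolar_forces_torques(d, _pair_params(lam, dp))
        assert F[0, 2] == pytest.approx(6 * C / r**4, rel=1e-12)
        assert F[1, 2] == pytest.approx(-6 * C / r**4, rel=1e-12)
        assert np.abs(T).max() < 1e-12  # aligned pair exerts no torque

    def test_side_by_side_repulsion(self):
        d = _dipoles([[0, 0, 0], [0.5, 0, 0]], [[0, 0, 1], [0, 0, 1]])
        F, _ = dipolar_forces_torques(d, _pair_params())
        assert F[0, 0] < 0 and F[1, 0] > 0  # pushed apart

    def test_repulsion_window_boundary_at_arccos_inv_sqrt3(self):
        """The radial force of a co-aligned pair changes sign where
        1 - 3 cos^2(theta) does, i.e. at theta = arccos(1/sqrt 3)."""
        pp = _pair_params()
        r = 0.6

        def radial_force(theta):
            pos2 = [r * np.sin(theta), 0.0, r * np.cos(theta)]
            d = _dipoles([[0, 0, 0], pos2], [[0, 0, 1], [0, 0, 1]])
            F, _ = dipolar_forces_torques(d, pp)
            return F[1] @ (np.asarray(pos2) / r)

        lo, hi = 0.1, np.pi / 2  # attraction at pole, repulsion at equator
        assert radial_force(lo) < 0 < radial_force(hi)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if radial_force(mid) < 0:
                lo = mid
            else:
                hi = mid
        theta_star = 0.5 * (lo + hi)
        assert theta_star == pytest.approx(np.arccos(1 / np.sqrt(3)),
                                           abs=1e-9)
        # the repulsion window half-width about the equator is ~35 degrees
        assert 90 - np.rad2deg(theta_star) == pytest.approx(35.26, abs=0.01)

    def test_forces_match_numeric_gradient_and_sum_to_zero(self):
        rng = np.random.default_rng(8)
        pos = rng.uniform(0, 1.2, (6, 3))
        e = rng.normal(size=(6, 3))
        d = _dipoles(pos, e)
        pp = _pair_params()
        F, _ = dipolar_forces_torques(d, pp)
        G = numerical_gradient(
            lambda x: dipolar_energy(d, pp, positions=x), pos)
        assert np.abs(F + G).max() / np.abs(F).max() < 1e-5
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-9)

    def test_pair_angular_momentum_balance(self):
        """Torques + force moments about the origin cancel for a pair."""
        d = _dipoles([[0.1, -0.2, 0.0], [0.5, 0.3, 0.4]],
                     [[1, 0.3, 0], [0, 1, -0.5]])
        pp = _pair_params()
        F, T = dipolar_forces_torques(d, pp)
        L = (T.sum(axis=0)
             + np.cross(d.positions, F).sum(axis=0))
        assert np.abs(L).max() < 1e-12

    def test_coincident_centers_raise(self):
        d = _dipoles([[0, 0, 0], [0, 0, 0]], [[0, 0, 1], [0, 0, 1]])
        with pytest.raises(FloatingPointError):
            dipolar_forces_torques(d, _pair_params())


class TestZeeman:
    def test_torque_magnitudes(self):
        d = _dipoles([[0, 0, 0], [1, 0, 0], [2, 0, 0]],
                     [[0, 0, 1], [1, 0, 0], [0, 0, 1]])
        T = zeeman_torques(d, xi=7.0, field_direction=(0, 0, 1))
        assert np.abs(T[0]).max() < 1e-15          # parallel: zero
        assert np.linalg.norm(T[1]) == pytest.approx(7.0, rel=1e-12)  # perp
        assert np.abs(zeeman_torques(d, 0.0, (0, 0, 1))).max() == 0.0

    def test_lambda_round_trip(self):
        for lam in (0.3, 5.0, 42.0):
            pp = _pair_params(lambda_dd=lam)
            assert pp.lambda_dd() == pytest.approx(lam, rel=1e-12)


# ---------------------------------------------------------------------------
# total force assembly
# ---------------------------------------------------------------------------

class TestTotalForces:
    def test_stress_free_assembly_without_mnps_is_quiet(self):
        p = ModelParams(q=6.0, phi=1e-9, coarsen=2.5)
        from polymag.builder import build_system
        asm, dip = build_system(p)
        Fb, Fm, Tm, E = total_forces(asm, dip, p)
        assert np.abs(Fb).max() < 1e-8

    def test_total_force_sums_to_zero(self, coarse_system, coarse_params):
        asm, dip = coarse_system
        Fb, Fm, Tm, E = total_forces(asm, dip, coarse_params, xi=10.0)
        # a uniform field exerts torque only: no net translational force
        assert np.abs(Fb.sum(axis=0) + Fm.sum(axis=0)).max() < 1e-8

    def test_gradient_descent_lowers_energy(self, coarse_system,
                                            coarse_params):
        asm, dip = coarse_system
        p = coarse_params
        rng = np.random.default_rng(1)
        pos_b = asm.all_positions() + 0.01 * rng.normal(
            size=(2 * asm.n_beads_per_shell, 3))
        pos_m = dip.positions.copy()
        energies = []
        for _ in range(4):
            Fb, Fm, _, E = total_forces(asm, dip, p, positions_beads=pos_b,
                                        positions_mnps=pos_m, xi=0.0)
            energies.append(E)
            step = 1e-5
            pos_b = pos_b + step * Fb
            pos_m = pos_m + step * Fm
        assert all(b < a for a, b in zip(energies, energies[1:]))
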