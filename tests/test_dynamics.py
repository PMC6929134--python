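"""Integrator: symplectic limit, thermostat statistics, determinism."""

import numpy as np
import pytest

import polymag._kernels as K
from polymag import ModelParams
from polymag.builder import build_system
from polymag.dynamics import (LangevinIntegrator, RunProtocol, equilibrate,
                              simulate_free_dipoles)


def test_energy_conserved_without_thermostat():
    """zeta = 0, noise off: velocity-Verlet limit conserves the energy of a
    single harmonic bond to O(dt^2) over 1e4 steps."""
    pos_b = np.array([[0.0, 0, 0], [1.3, 0, 0]])
    vel_b = np.array([[0.0, 0.1, 0], [0.0, -0.1, 0]])
    edges = np.array([[0, 1]], dtype=np.int64)
    l0 = np.array([1.0])
    k = 50.0
    z0 = np.zeros((0, 3))
    zi = np.zeros((0, 2), dtype=np.int64)
    zt = np.zeros((0, 3), dtype=np.int64)
    zq = np.zeros((0, 4), dtype=np.int64)
    ze = np.zeros(0)
    F_b = np.zeros_like(pos_b)
    em = np.zeros((0, 3))
    dt = 0.002

    def total_energy():
        l = np.linalg.norm(pos_b[1] - pos_b[0])
        return 0.5 * k * (l - 1.0) ** 2 + 0.5 * np.sum(vel_b**2)

    E0 = total_energy()
    _, _, _, err = K.run_chunk(
        10_000, dt, pos_b, vel_b, z0, z0, em, em,
        edges, l0, k, zt, ze, 0.0, zi, 1.0, 0.0, zq, ze, 0.0,
        ze, 0.0, 0.3, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0,
        0.0, 0.0, 1.0, 0.009, 1.0,
        F_b, em, em, em, 1e9)
    assert err == 0
    assert total_energy() == pytest.approx(E0, rel=5e-4)


def test_translational_equipartition():
    """Free particles with the thermostat: <v_d^2> = kBT/m within 2 %."""
    p = ModelParams(q=6.0, phi=1e-9, dt=0.004)
    rng = np.random.default_rng(0)
    n = 400
    pos = rng.uniform(0, 50.0, (n, 3))
    vel = np.zeros((n, 3))
    e = np.tile(np.array([0.0, 0.0, 1.0]), (n, 1))
    om = np.zeros((n, 3))
    zb = np.zeros((0, 3))
    K.seed_rng(123)
    samples = []
    for it in range(60):
        _, _, _, err = K.run_chunk(
            100, p.dt, zb, zb, pos, vel, e, om,
            np.zeros((0, 2), np.int64), np.zeros(0), 0.0,
            np.zeros((0, 3), np.int64), np.zeros(0), 0.0,
            np.zeros((0, 2), np.int64), 1.0, 0.0,
            np.zeros((0, 4), np.int64), np.zeros(0), 0.0,
            np.zeros(0), 0.0, 0.3, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0,
            p.zeta_t, p.zeta_r, p.mass, p.inertia, p.kBT,
            zb, np.zeros((n, 3)), np.zeros((n, 3)), np.zeros((n, 3)), 1e9)
        assert err == 0
        if it >= 10:
            samples.append(np.mean(vel**2))
    assert np.mean(samples) == pytest.approx(p.kBT / p.mass, rel=0.02)


def test_rotational_equipartition_and_unit_norm():
    """<omega_d^2> = kBT/I for free rotors; orientations stay unit."""
    p = ModelParams(q=6.0)
    e, _ = simulate_free_dipoles(n=300, xi=0.0, n_steps=4_000, params=p,
                                 seed=4)
    assert np.abs(np.linalg.norm(e, axis=1) - 1.0).max() < 1e-9
    # re-run measuring omega through the integrator state
    rng = np.random.default_rng(1)
    n = 300
    om = rng.normal(0, np.sqrt(p.kBT / p.inertia), (n, 3))
    ee = rng.normal(size=(n, 3))
    ee /= np.linalg.norm(ee, axis=1)[:, None]
    pos = rng.uniform(0, 1000.0, (n, 3))
    vel = np.zeros((n, 3))
    zb = np.zeros((0, 3))
    K.seed_rng(77)
    samples = []
    for it in range(60):
        _, _, _, err = K.run_chunk(
            100, p.dt, zb, zb, pos, vel, ee, om,
            np.zeros((0, 2), np.int64), np.zeros(0), 0.0,
            np.zeros((0, 3), np.int64), np.zeros(0), 0.0,
            np.zeros((0, 2), np.int64), 1.0, 0.0,
            np.zeros((0, 4), np.int64), np.zeros(0), 0.0,
            np.zeros(0), 0.0, 0.3, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0,
            0.0, p.zeta_r, p.mass, p.inertia, p.kBT,
            zb, np.zeros((n, 3)), np.zeros((n, 3)), np.zeros((n, 3)), 1e9)
        assert err == 0
        if it >= 10:
            samples.append(np.mean(om**2))
    assert np.mean(samples) == pytest.approx(p.kBT / p.inertia, rel=0.02)


@pytest.mark.parametrize("xi", [1.0, 5.0, 10.0])
def test_free_dipole_langevin_magnetization(xi):
    """<e.h> of non-interacting dipoles matches L(xi) = coth(xi) - 1/xi."""
    _, samples = simulate_free_dipoles(n=400, xi=xi, n_steps=20_000,
                                       seed=3, burn_in=4_000)
    L = 1.0 / np.tanh(xi) - 1.0 / xi
    assert np.mean(samples) == pytest.approx(L, abs=0.02)


def test_field_off_magnetization_statistically_zero():
    e, samples = simulate_free_dipoles(n=400, xi=0.0, n_steps=20_000,
                                       seed=6, burn_in=4_000)
    n_eff = 400 * len(samples)
    assert abs(np.mean(samples)) < 3.0 / np.sqrt(n_eff) + 0.01


def test_deterministic_trajectories():
    p = ModelParams(q=6.0, coarsen=2.5, phi=0.05, seed=5)
    runs = []
    for _ in range(2):
        asm, dip = build_system(p, orientation_seed=9)
        integ = LangevinIntegrator(asm, dip, p, seed=13)
        integ.run(500)
        runs.append((integ.state.pos_beads.copy(),
                     integ.state.pos_mnps.copy(),
                     integ.state.orientations.copy(),
                     integ.potential_energy))
    assert np.array_equal(runs[0][0], runs[1][0])
    assert np.array_equal(runs[0][1], runs[1][1])
    assert np.array_equal(runs[0][2], runs[1][2])
    assert runs[0][3] == runs[1][3]


def test_perturbed_shell_relaxes_to_thermal_radius():
    """A radially squeezed empty shell relaxes back to the mean radius of
    an unperturbed thermal control replica (mechanical equilibrium; soft
    springs swell a little thermally, so the control is the reference)."""
    p = ModelParams(q=6.0, phi=1e-9, coarsen=2.5, seed=2)

    def mean_outer_radius(squeeze):
        asm, dip = build_system(p)
        integ = LangevinIntegrator(asm, dip, p, seed=8)
        if squeeze:
            integ.state.pos_beads *= 0.93
        n = asm.n_beads_per_shell
        rs = []
        for _ in range(4):
            integ.run(5_000)
            rs.append(np.linalg.norm(integ.state.pos_beads[n:],
                                     axis=1).mean())
        return np.mean(rs[2:])  # discard transient

    assert mean_outer_radius(True) == pytest.approx(
        mean_outer_radius(False), rel=0.02)


def test_equilibration_detector_and_protocol_validation():
    p = ModelParams(q=6.0, phi=1e-9, coarsen=2.5, seed=2)
    asm, dip = build_system(p)
    integ = LangevinIntegrator(asm, dip, p, seed=8)
    proto = RunProtocol(n_steps_max=40_000, equil_window=5_000,
                        equil_tolerance=5e-3, sample_interval=500,
                        production_steps=2_000)
    trace, converged = equilibrate(integ, proto)
    assert converged
    assert len(trace) >= 2 * proto.equil_window // proto.sample_interval
    with pytest.raises(ValueError):
        RunProtocol(equil_window=1_000, sample_interval=500)
    with pytest.raises(ValueError):
        RunProtocol(equil_tolerance=0.0)


def test_timestep_abort():
    p = ModelParams(q=6.0, phi=1e-9, coarsen=2.5, seed=2, dt=0.2)
    asm, dip = build_system(p)
    integ = LangevinIntegrator(asm, dip, p, seed=8)
    integ.state.pos_beads *= 0.7  # large squeeze + huge dt -> blow-up
    with pytest.raises((RuntimeError, FloatingPointError)):
        for _ in range(20):
            integ.run(200)
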