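"""Langevin integration of the coupled translational/rotational dynamics.

Translations follow the underdamped Langevin equation
``m r'' = F - zeta r' + f(t)`` integrated with the BAOAB splitting; MNP
orientations are unit vectors rotated by the angular velocity, which obeys
the rotational analogue with friction ``zeta_r`` and torque from the dipolar
field plus the Zeeman term.  Noise amplitudes satisfy fluctuation-
dissipation, so the stationary distribution is Boltzmann at ``kBT``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .builder import DipoleSet, MembraneAssembly
from .forces import ForceField
from .params import ModelParams

__all__ = ["SystemState", "RunProtocol", "LangevinIntegrator", "equilibrate",
           "simulate_free_dipoles"]


@dataclass
class SystemState:
    """Full dynamical state of the model."""

    pos_beads: np.ndarray
    vel_beads: np.ndarray
    pos_mnps: np.ndarray
    vel_mnps: np.ndarray
    orientations: np.ndarray
    angular_vel: np.ndarray
    xi: float = 0.0
    time: float = 0.0

    def check(self) -> None:
        for a in (self.pos_beads, self.vel_beads, self.pos_mnps,
                  self.vel_mnps, self.orientations, self.angular_vel):
            if not np.all(np.isfinite(a)):
                raise FloatingPointError("non-finite value in system state")
        if len(self.orientations):
            norms = np.linalg.norm(self.orientations, axis=1)
            if np.abs(norms - 1.0).max() > 1e-9:
                raise FloatingPointError("moment orientation lost unit norm")

    def copy(self) -> "SystemState":
        return SystemState(self.pos_beads.copy(), self.vel_beads.copy(),
                           self.pos_mnps.copy(), self.vel_mnps.copy(),
                           self.orientations.copy(), self.angular_vel.copy(),
                           self.xi, self.time)


@dataclass
class RunProtocol:
    """Equilibration/production schedule.

    Equilibrium is declared when the relative change of the windowed mean
    total energy between consecutive windows drops below the tolerance.
    """

    n_steps_max: int = 400_000
    equil_window: int = 50_000
    equil_tolerance: float = 1e-3
    sample_interval: int = 1_000
    production_steps: int = 20_000

    def __post_init__(self) -> None:
        if self.equil_tolerance <= 0:
            raise ValueError("equil_tolerance must be positive")
        if self.equil_window < 10 * self.sample_interval:
            raise ValueError("window must span at least 10 samples")


class LangevinIntegrator:
    """Drives one replica of the assembled system."""

    def __init__(self, assembly: MembraneAssembly, dipoles: DipoleSet,
                 params: ModelParams, seed: int,
                 field_direction=(0.0, 0.0, 1.0),
                 thermal_velocities: bool = True) -> None:
        self.params = params
        self.ff = ForceField(assembly, dipoles, params, field_direction)
        rng = np.random.default_rng(seed)
        n_b, n_m = self.ff.n_beads, dipoles.n
        p = params
        sv = np.sqrt(p.kBT / p.mass) if thermal_velocities else 0.0
        so = np.sqrt(p.kBT / p.inertia) if thermal_velocities else 0.0
        self.state = SystemState(
            pos_beads=np.ascontiguousarray(assembly.all_positions(), float),
            vel_beads=rng.normal(0.0, sv or 0.0, (n_b, 3)) if sv else np.zeros((n_b, 3)),
            pos_mnps=np.ascontiguousarray(dipoles.positions, float),
            vel_mnps=rng.normal(0.0, sv or 0.0, (n_m, 3)) if sv else np.zeros((n_m, 3)),
            orientations=np.ascontiguousarray(dipoles.orientations, float),
            angular_vel=rng.normal(0.0, so or 0.0, (n_m, 3)) if so else np.zeros((n_m, 3)),
            xi=params.xi,
        )
        K.seed_rng(int(seed) % 2**31)
        self.overlap_count = 0
        self.potential_energy = np.nan

    # -- energies -----------------------------------------------------------
    def kinetic_energy(self) -> float:
        p = self.params
        ke = 0.5 * p.mass * (np.sum(self.state.vel_beads**2)
                             + np.sum(self.state.vel_mnps**2))
        ke += 0.5 * p.inertia * np.sum(self.state.angular_vel**2)
        return float(ke)

    def total_energy(self) -> float:
        return self.potential_energy + self.kinetic_energy()

    # -- integration --------------------------------------------------------
    def run(self, n_steps: int) -> float:
        """Integrate n_steps; returns the final potential energy."""
        s, p, ff = self.state, self.params, self.ff
        hx, hy, hz = ff.field_direction
        E, vmax, ov, err = K.run_chunk(
            n_steps, p.dt,
            s.pos_beads, s.vel_beads, s.pos_mnps, s.vel_mnps,
            s.orientations, s.angular_vel,
            ff.edges, ff.l0, p.k_stretch, ff.tris, ff.A0, p.k_area,
            ff.bonds, p.h, p.k_bond,
            ff.quads, ff.theta0, p.k_bend,
            ff.sig_mb, p.wca_epsilon, ff.pair.sigma[("mnp", "mnp")],
            ff.pair.dipole_prefactor, ff.pair.mu, s.xi * p.kBT,
            hx, hy, hz,
            p.zeta_t, p.zeta_r, p.mass, p.inertia, p.kBT,
            ff._F_b, ff._F_m, ff._T_m, ff._B,
            0.25 * p.dp)
        if err == 100:
            raise RuntimeError(
                f"timestep too large: per-step displacement {vmax * p.dt:.3g}"
                f" exceeds 0.25 dp = {0.25 * p.dp:.3g}")
        if err != 0:
            raise FloatingPointError(
                f"degenerate geometry during integration (code {err})")
        self.overlap_count += ov
        self.potential_energy = E
        s.time += n_steps * p.dt
        s.check()
        return E


def equilibrate(integ: LangevinIntegrator, protocol: RunProtocol
                ) -> tuple[np.ndarray, bool]:
    """Run until the windowed mean total energy stabilises.

    Returns (energy trace sampled every ``sample_interval`` steps,
    converged flag).  Non-convergence within ``n_steps_max`` is flagged,
    not raised; partial results remain usable.
    """
    trace = []
    per_window = protocol.equil_window // protocol.sample_interval
    steps = 0
    prev_mean = None
    while steps < protocol.n_steps_max:
        integ.run(protocol.sample_interval)
        steps += protocol.sample_interval
        trace.append(integ.total_energy())
        if len(trace) % per_window == 0:
            mean = float(np.mean(trace[-per_window:]))
            if prev_mean is not None:
                scale = max(abs(prev_mean), 1.0)
                if abs(mean - prev_mean) / scale < protocol.equil_tolerance:
                    return np.asarray(trace), True
            prev_mean = mean
    return np.asarray(trace), False


def simulate_free_dipoles(n: int, xi: float, n_steps: int,
                          params: ModelParams | None = None,
                          seed: int = 0, sample_interval: int = 200,
                          burn_in: int = 2_000
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Rotational Langevin dynamics of n non-interacting dipoles in a field.

    Returns (orientations at the end, samples of the mean projection
    <e . hhat> taken every ``sample_interval`` steps after burn-in).  The
    stationary mean projection of a free dipole is the Langevin function
    L(xi) = coth(xi) - 1/xi.
    """
    p = params or ModelParams(q=6.0)
    rng = np.random.default_rng(seed)
    e = rng.normal(size=(n, 3))
    e /= np.linalg.norm(e, axis=1)[:, None]
    om = rng.normal(0.0, np.sqrt(p.kBT / p.inertia), (n, 3))
    pos = rng.uniform(0, 1000.0, (n, 3))  # far apart; interactions are off
    vel = np.zeros((n, 3))
    pos_b = np.zeros((0, 3))
    vel_b = np.zeros((0, 3))
    edges = np.zeros((0, 2), dtype=np.int64)
    tris = np.zeros((0, 3), dtype=np.int64)
    bonds = np.zeros((0, 2), dtype=np.int64)
    z = np.zeros(0)
    F_b = np.zeros((0, 3))
    F_m = np.zeros((n, 3))
    T_m = np.zeros((n, 3))
    B = np.zeros((n, 3))
    K.seed_rng(seed % 2**31)
    samples = []
    done = 0
    while done < burn_in + n_steps:
        chunk = min(sample_interval, burn_in + n_steps - done)
        _, _, _, err = K.run_chunk(
            chunk, p.dt, pos_b, vel_b, pos, vel, e, om,
            edges, z, 0.0, tris, z, 0.0, bonds, p.h, 0.0,
            np.zeros((0, 4), dtype=np.int64), z, 0.0,
            z, 0.0, p.dp, 0.0, 0.0, xi * p.kBT, 0.0, 0.0, 1.0,
            0.0, p.zeta_r, p.mass, p.inertia, p.kBT,
            F_b, F_m, T_m, B, 1e9)
        if err:
            raise FloatingPointError(f"integration error (code {err})")
        done += chunk
        if done > burn_in:
            samples.append(float(e[:, 2].mean()))
    return e, np.asarray(samples)
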