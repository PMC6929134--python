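"""Forces and torques of the magnetopolymersome model.

Per-term operations (edge stretching, triangle-area restoring, intershell
bonds, WCA sterics, dipole-dipole forces/torques, Zeeman torque) are thin
wrappers over the numba kernels in :mod:`polymag._kernels`; every force is
the exact gradient of the corresponding potential term.  :class:`ForceField`
bundles the assembled topology for the integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .builder import DipoleSet, MembraneAssembly
from .mesh import TriangulatedShell, bending_quads
from .params import ModelParams

__all__ = [
    "PairEnergyParams", "ForceField",
    "stretch_forces", "area_forces", "bond_forces", "bending_forces",
    "wca_forces", "dipolar_forces_torques", "zeeman_torques", "total_forces",
    "stretch_energy", "area_energy", "bond_energy", "bending_energy",
    "wca_energy", "dipolar_energy", "zeeman_energy", "dihedral_angles",
]

WCA_CUT = K.WCA_CUT


@dataclass
class PairEnergyParams:
    """Pair-interaction constants derived from a :class:`ModelParams`.

    ``dipole_prefactor`` is the reduced mu0*mu^2, fixed by the dipolar
    coupling constant lambda = mu0 mu^2 / (dp^3 kBT); the round trip
    lambda -> mu -> lambda is an identity.
    """

    wca_epsilon: float
    sigma: dict = field(default_factory=dict)  # (species_a, species_b) -> contact distance
    dipole_prefactor: float = 0.0
    dp: float = 0.3
    kBT: float = 1.0

    @classmethod
    def from_model(cls, p: ModelParams) -> "PairEnergyParams":
        sig = {
            ("mnp", "mnp"): p.dp,
            ("mnp", "inner"): 0.5 * (p.dp + p.din),
            ("mnp", "outer"): 0.5 * (p.dp + p.dout),
        }
        for (a, b), s in list(sig.items()):
            sig[(b, a)] = s
        return cls(wca_epsilon=p.wca_epsilon, sigma=sig,
                   dipole_prefactor=p.lambda_dd * p.kBT * p.dp**3,
                   dp=p.dp, kBT=p.kBT)

    @property
    def mu(self) -> float:
        return math.sqrt(self.dipole_prefactor)

    def lambda_dd(self) -> float:
        """Recover lambda from the stored moment (round-trip identity)."""
        return self.mu**2 / (self.dp**3 * self.kBT)


# ---------------------------------------------------------------------------
# per-term operations
# ---------------------------------------------------------------------------

def _check(err: int, what: str) -> None:
    if err:
        raise FloatingPointError(f"degenerate geometry in {what} "
                                 "(zero-length edge / zero-area triangle / "
                                 "coincident dipoles)")


def stretch_forces(shell: TriangulatedShell, positions: np.ndarray,
                   k_stretch: float) -> np.ndarray:
    F = np.zeros_like(positions)
    _, err = K.stretch_kernel(positions, shell.edges, shell.rest_lengths,
                              k_stretch, F)
    _check(err, "stretch_forces")
    return F


def stretch_energy(shell: TriangulatedShell, positions: np.ndarray,
                   k_stretch: float) -> float:
    E, err = K.stretch_kernel(positions, shell.edges, shell.rest_lengths,
                              k_stretch, np.zeros_like(positions))
    _check(err, "stretch_energy")
    return E


def area_forces(shell: TriangulatedShell, positions: np.ndarray,
                k_area: float) -> np.ndarray:
    F = np.zeros_like(positions)
    _, err = K.area_kernel(positions, shell.triangles, shell.ref_areas,
                           k_area, F)
    _check(err, "area_forces")
    return F


def area_energy(shell: TriangulatedShell, positions: np.ndarray,
                k_area: float) -> float:
    E, err = K.area_kernel(positions, shell.triangles, shell.ref_areas,
                           k_area, np.zeros_like(positions))
    _check(err, "area_energy")
    return E


def dihedral_angles(positions: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Signed dihedral angle about each shared edge (zero when coplanar)."""
    p = positions
    i, j, k, l = quads.T
    e = p[j] - p[i]
    n1 = np.cross(e, p[k] - p[i])
    n2 = np.cross(-e, p[l] - p[j])
    nn = np.linalg.norm(n1, axis=1) * np.linalg.norm(n2, axis=1)
    c = np.einsum("ij,ij->i", n1, n2) / nn
    s = np.einsum("ij,ij->i", np.cross(n1, n2), e) / (
        nn * np.linalg.norm(e, axis=1))
    return np.arctan2(s, c)


def _shell_quads_theta0(shell: TriangulatedShell
                        ) -> tuple[np.ndarray, np.ndarray]:
    quads = bending_quads(shell.triangles)
    return quads, dihedral_angles(shell.bead_positions, quads)


def bending_forces(shell: TriangulatedShell, positions: np.ndarray,
                   k_bend: float) -> np.ndarray:
    F = np.zeros_like(positions)
    quads, theta0 = _shell_quads_theta0(shell)
    _, err = K.bend_kernel(positions, quads, theta0, k_bend, F)
    _check(err, "bending_forces")
    return F


def bending_energy(shell: TriangulatedShell, positions: np.ndarray,
                   k_bend: float) -> float:
    quads, theta0 = _shell_quads_theta0(shell)
    E, err = K.bend_kernel(positions, quads, theta0, k_bend,
                           np.zeros_like(positions))
    _check(err, "bending_energy")
    return E


def _global_bonds(assembly: MembraneAssembly) -> np.ndarray:
    n = assembly.n_beads_per_shell
    b = assembly.intershell_bonds
    return np.column_stack([b[:, 0], b[:, 1] + n]).astype(np.int64)


def bond_forces(assembly: MembraneAssembly, positions: np.ndarray,
                k_bond: float) -> np.ndarray:
    """positions: stacked inner+outer bead coordinates."""
    F = np.zeros_like(positions)
    _, err = K.bond_kernel(positions, _global_bonds(assembly),
                           assembly.bond_rest_length, k_bond, F)
    _check(err, "bond_forces")
    return F


def bond_energy(assembly: MembraneAssembly, positions: np.ndarray,
                k_bond: float) -> float:
    E, err = K.bond_kernel(positions, _global_bonds(assembly),
                           assembly.bond_rest_length, k_bond,
                           np.zeros_like(positions))
    _check(err, "bond_energy")
    return E


def _sigma_array(diam_a: float, diam_b, n: int) -> np.ndarray:
    db = np.broadcast_to(np.asarray(diam_b, dtype=float), (n,))
    return 0.5 * (diam_a + db)


def wca_forces(positions_a: np.ndarray, diameter_a: float,
               positions_b: np.ndarray | None = None,
               diameter_b: float | np.ndarray | None = None,
               epsilon: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Purely repulsive WCA forces.

    Cross-species when ``positions_b`` is given (returns forces on a and b);
    intra-species otherwise (returns the same array twice).
    """
    if positions_b is None:
        F = np.zeros_like(positions_a)
        B = np.zeros_like(positions_a)
        e0 = np.zeros_like(positions_a)  # unused orientations
        _, _, _, err = K.mnp_mnp_kernel(positions_a, e0, 0.0, 0.0, epsilon,
                                        float(diameter_a), F, B)
        _check(err, "wca_forces")
        return F, F
    F_a = np.zeros_like(positions_a)
    F_b = np.zeros_like(positions_b)
    sig = _sigma_array(diameter_a, diameter_b, len(positions_b))
    K.wca_cross_kernel(positions_a, positions_b, sig, epsilon, F_a, F_b)
    return F_a, F_b


def wca_energy(positions_a: np.ndarray, diameter_a: float,
               positions_b: np.ndarray | None = None,
               diameter_b: float | np.ndarray | None = None,
               epsilon: float = 1.0) -> float:
    if positions_b is None:
        e0 = np.zeros_like(positions_a)
        _, Ew, _, err = K.mnp_mnp_kernel(positions_a, e0, 0.0, 0.0, epsilon,
                                         float(diameter_a),
                                         np.zeros_like(positions_a),
                                         np.zeros_like(positions_a))
        _check(err, "wca_energy")
        return Ew
    sig = _sigma_array(diameter_a, diameter_b, len(positions_b))
    E, _ = K.wca_cross_kernel(positions_a, positions_b, sig, epsilon,
                              np.zeros_like(positions_a),
                              np.zeros_like(positions_b))
    return E


def dipolar_forces_torques(dipoles: DipoleSet, params: PairEnergyParams,
                           positions: np.ndarray | None = None,
                           orientations: np.ndarray | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs dipole-dipole forces and torques (open boundaries).

    The torque on i is mu e_i x B_i with B_i the summed dipolar field of
    all other particles; the external-field torque is added separately by
    :func:`zeeman_torques`.
    """
    pos = dipoles.positions if positions is None else positions
    e = dipoles.orientations if orientations is None else orientations
    F = np.zeros_like(pos)
    B = np.zeros_like(pos)
    _, _, _, err = K.mnp_mnp_kernel(pos, e, params.dipole_prefactor,
                                    params.mu, 0.0, dipoles.dp, F, B)
    _check(err, "dipolar_forces_torques")
    T = params.mu * np.cross(e, B)
    return F, T


def dipolar_energy(dipoles: DipoleSet, params: PairEnergyParams,
                   positions: np.ndarray | None = None,
                   orientations: np.ndarray | None = None) -> float:
    pos = dipoles.positions if positions is None else positions
    e = dipoles.orientations if orientations is None else orientations
    Ed, _, _, err = K.mnp_mnp_kernel(pos, e, params.dipole_prefactor,
                                     params.mu, 0.0, dipoles.dp,
                                     np.zeros_like(pos), np.zeros_like(pos))
    _check(err, "dipolar_energy")
    return Ed


def zeeman_torques(dipoles: DipoleSet, xi: float, field_direction,
                   kBT: float = 1.0,
                   orientations: np.ndarray | None = None) -> np.ndarray:
    """Torque xi kBT (e x hhat); a uniform field exerts no net force."""
    e = dipoles.orientations if orientations is None else orientations
    h = np.asarray(field_direction, dtype=float)
    h = h / np.linalg.norm(h)
    return xi * kBT * np.cross(e, h)


def zeeman_energy(dipoles: DipoleSet, xi: float, field_direction,
                  kBT: float = 1.0,
                  orientations: np.ndarray | None = None) -> float:
    e = dipoles.orientations if orientations is None else orientations
    h = np.asarray(field_direction, dtype=float)
    h = h / np.linalg.norm(h)
    return float(-xi * kBT * (e @ h).sum())


# ---------------------------------------------------------------------------
# assembled force field
# ---------------------------------------------------------------------------

class ForceField:
    """Assembled topology + constants; evaluates all terms in one call."""

    def __init__(self, assembly: MembraneAssembly, dipoles: DipoleSet,
                 params: ModelParams,
                 field_direction=(0.0, 0.0, 1.0)) -> None:
        self.params = params
        self.pair = PairEnergyParams.from_model(params)
        n = assembly.n_beads_per_shell
        inner, outer = assembly.inner, assembly.outer
        self.edges = np.vstack([inner.edges, outer.edges + n]).astype(np.int64)
        self.l0 = np.concatenate([inner.rest_lengths, outer.rest_lengths])
        self.tris = np.vstack([inner.triangles,
                               outer.triangles + n]).astype(np.int64)
        self.A0 = np.concatenate([inner.ref_areas, outer.ref_areas])
        self.bonds = _global_bonds(assembly)
        qi, ti = _shell_quads_theta0(inner)
        qo, to = _shell_quads_theta0(outer)
        self.quads = np.vstack([qi, qo + n]).astype(np.int64)
        self.theta0 = np.concatenate([ti, to])
        self.sig_mb = np.concatenate([
            np.full(n, self.pair.sigma[("mnp", "inner")]),
            np.full(n, self.pair.sigma[("mnp", "outer")]),
        ])
        h = np.asarray(field_direction, dtype=float)
        self.field_direction = h / np.linalg.norm(h)
        self.n_beads = 2 * n
        self.n_mnp = dipoles.n
        # workspaces
        self._F_b = np.zeros((self.n_beads, 3))
        self._F_m = np.zeros((max(self.n_mnp, 1), 3))
        self._T_m = np.zeros((max(self.n_mnp, 1), 3))
        self._B = np.zeros((max(self.n_mnp, 1), 3))

    def compute(self, pos_b: np.ndarray, pos_m: np.ndarray, e: np.ndarray,
                xi: float) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                    float, int]:
        """Returns (bead forces, MNP forces, MNP torques, E_pot, overlaps)."""
        p = self.params
        hx, hy, hz = self.field_direction
        E, ov, err = K.compute_all(
            pos_b, pos_m, e,
            self.edges, self.l0, p.k_stretch,
            self.tris, self.A0, p.k_area,
            self.bonds, p.h, p.k_bond,
            self.quads, self.theta0, p.k_bend,
            self.sig_mb, p.wca_epsilon, self.pair.sigma[("mnp", "mnp")],
            self.pair.dipole_prefactor, self.pair.mu, xi * p.kBT,
            hx, hy, hz,
            self._F_b, self._F_m, self._T_m, self._B)
        _check(err, "total force evaluation")
        return self._F_b, self._F_m, self._T_m, E, ov


def total_forces(assembly: MembraneAssembly, dipoles: DipoleSet,
                 params: ModelParams,
                 positions_beads: np.ndarray | None = None,
                 positions_mnps: np.ndarray | None = None,
                 orientations: np.ndarray | None = None,
                 xi: float | None = None,
                 field_direction=(0.0, 0.0, 1.0)
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Total per-element forces, MNP torques and potential energy."""
    ff = ForceField(assembly, dipoles, params, field_direction)
    pos_b = assembly.all_positions() if positions_beads is None else positions_beads
    pos_m = dipoles.positions if positions_mnps is None else positions_mnps
    e = dipoles.orientations if orientations is None else orientations
    F_b, F_m, T_m, E, _ = ff.compute(np.ascontiguousarray(pos_b),
                                     np.ascontiguousarray(pos_m),
                                     np.ascontiguousarray(e),
                                     params.xi if xi is None else xi)
    return F_b.copy(), F_m.copy(), T_m.copy(), E
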