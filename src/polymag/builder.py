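"""Assembly of the initial model magnetopolymersome.

The membrane is two nested triangulated spherical shells with an equal
number of beads, tied together by sparse harmonic springs of rest length
``h`` between subtending nodes; the intershell gap confines a monolayer of
dipolar magnetic nanoparticles (MNPs) seeded uniformly over the gap
mid-surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import TriangulatedShell, icosphere_level_for_edge, _shell_from_level
from .params import ModelParams

__all__ = ["MembraneAssembly", "DipoleSet", "build_membrane", "seed_mnps",
           "build_system"]


@dataclass
class MembraneAssembly:
    inner: TriangulatedShell
    outer: TriangulatedShell
    intershell_bonds: np.ndarray  # (B, 2): (inner node idx, outer node idx)
    bond_rest_length: float

    @property
    def n_beads_per_shell(self) -> int:
        return self.inner.n_beads

    def all_positions(self) -> np.ndarray:
        """Stacked bead positions, inner shell first."""
        return np.vstack([self.inner.bead_positions, self.outer.bead_positions])


@dataclass
class DipoleSet:
    positions: np.ndarray     # (N, 3)
    orientations: np.ndarray  # (N, 3) unit vectors
    mu: float                 # reduced moment magnitude
    dp: float

    @property
    def n(self) -> int:
        return len(self.positions)


def build_membrane(params: ModelParams) -> MembraneAssembly:
    """Two nested shells plus intershell springs, stress free as built.

    Both shells use the same icosphere subdivision (equal bead counts); the
    level is the coarsest whose *outer* mean edge does not exceed the outer
    bead diameter (times the optional coarsening factor), so that adjacent
    beads touch or overlap and the shell is a closed steric wall for the
    MNPs.  A fraction ``cb`` of node indices is sampled without replacement
    and each sampled inner node is bonded to the outer node of the same
    index, which is its radially subtending mutual nearest node.
    """
    level = icosphere_level_for_edge(params.r_outer,
                                     params.dout * params.coarsen)
    outer = _shell_from_level(params.r_outer, level, params.dout)
    inner = _shell_from_level(params.r_inner, level, params.din)

    n = inner.n_beads
    n_bonds = math.ceil(params.cb * n)
    rng = np.random.default_rng(params.seed)
    idx = np.sort(rng.choice(n, size=n_bonds, replace=False))
    bonds = np.column_stack([idx, idx]).astype(np.int64)
    return MembraneAssembly(inner=inner, outer=outer, intershell_bonds=bonds,
                            bond_rest_length=params.h)


def _relax_overlaps(pos: np.ndarray, dp: float, r_lo: float, r_hi: float,
                    min_dist: float, max_iter: int = 500) -> np.ndarray:
    """Push apart overlapping MNPs, clamping radii to the allowed band."""
    pos = pos.copy()
    for _ in range(max_iter):
        pairs = cKDTree(pos).query_pairs(min_dist, output_type="ndarray")
        if len(pairs) == 0:
            break
        d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
        dist = np.linalg.norm(d, axis=1)
        dist = np.where(dist < 1e-12, 1e-12, dist)
        push = 0.55 * (min_dist - dist) / dist
        for (i, j), dv, p in zip(pairs, d, push):
            pos[i] += p * dv
            pos[j] -= p * dv
        r = np.linalg.norm(pos, axis=1)
        pos *= (np.clip(r, r_lo, r_hi) / r)[:, None]
    return pos


def seed_mnps(assembly: MembraneAssembly, params: ModelParams,
              rng_seed: int | None = None) -> DipoleSet:
    """Uniformly seed the MNP monolayer in the intershell gap.

    The count follows from the volume fraction ``phi`` of the gap layer;
    positions are sampled uniformly on the gap mid-surface with radial
    jitter inside the band accessible to MNP centers, then relaxed by
    soft-core pushes; orientations are isotropic.
    """
    n = params.n_mnp()
    mu = math.sqrt(params.lambda_dd * params.kBT * params.dp**3)
    if n == 0:
        return DipoleSet(positions=np.zeros((0, 3)),
                         orientations=np.zeros((0, 3)), mu=mu, dp=params.dp)

    r_lo = params.gap_inner_radius + params.dp / 2.0
    r_hi = params.gap_outer_radius - params.dp / 2.0
    r_mid = 0.5 * (r_lo + r_hi)
    # monolayer feasibility: disc coverage of the mid-surface
    coverage = n * (math.pi / 4.0) * params.dp**2 / (4.0 * math.pi * r_mid**2)
    if coverage > 0.8:
        phi_max = 0.8 / coverage * params.phi
        raise ValueError(
            f"phi = {params.phi} infeasible for a monolayer at q = {params.q}"
            f" (disc coverage {coverage:.2f}); maximum feasible phi "
            f"~ {phi_max:.3f}"
        )

    rng = np.random.default_rng(params.seed if rng_seed is None else rng_seed)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1)[:, None]
    radii = rng.uniform(r_lo, r_hi, size=n)
    pos = u * radii[:, None]
    pos = _relax_overlaps(pos, params.dp, r_lo, r_hi, 0.9 * params.dp)

    e = rng.normal(size=(n, 3))
    e /= np.linalg.norm(e, axis=1)[:, None]
    return DipoleSet(positions=pos, orientations=e, mu=mu, dp=params.dp)


def build_system(params: ModelParams,
                 orientation_seed: int | None = None
                 ) -> tuple[MembraneAssembly, DipoleSet]:
    """Build the membrane and its MNP load.

    ``orientation_seed`` re-draws only the moment orientations (replicas
    differ solely in the initial orientational distribution); geometry and
    MNP positions always derive from ``params.seed``.
    """
    assembly = build_membrane(params)
    dip = seed_mnps(assembly, params)
    if orientation_seed is not None and dip.n:
        rng = np.random.default_rng(orientation_seed)
        e = rng.normal(size=(dip.n, 3))
        dip.orientations = e / np.linalg.norm(e, axis=1)[:, None]
    return assembly, dip
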