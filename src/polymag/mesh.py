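"""Triangulated spherical shells.

A shell is a closed genus-0 triangular mesh whose vertices are the centers of
the polymer beads.  Meshes are subdivided icosahedra projected to the sphere
(near-uniform, valence 6 with twelve valence-5 defects), generated through
:mod:`trimesh` and stored with per-edge rest lengths and per-triangle
reference areas taken from the built geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import trimesh

__all__ = ["TriangulatedShell", "build_icosphere", "icosphere_level_for_edge",
           "bending_quads"]


def bending_quads(triangles: np.ndarray) -> np.ndarray:
    """Dihedral quadruples (i, j, k, l) for every shared edge.

    The edge i-j appears as the directed edge (i, j) in the triangle
    (i, j, k) and as (j, i) in (j, i, l); a consistently oriented closed
    2-manifold yields exactly one partner per directed edge.
    """
    directed: dict[tuple[int, int], int] = {}
    for a, b, c in triangles:
        for i, j, opp in ((a, b, c), (b, c, a), (c, a, b)):
            if (i, j) in directed:
                raise ValueError("mesh is not consistently oriented")
            directed[(int(i), int(j))] = int(opp)
    quads = []
    for (i, j), k in directed.items():
        if i < j:
            if (j, i) not in directed:
                raise ValueError("mesh has a boundary edge")
            quads.append((i, j, k, directed[(j, i)]))
    return np.asarray(quads, dtype=np.int64)


@dataclass
class TriangulatedShell:
    bead_positions: np.ndarray  # (V, 3)
    triangles: np.ndarray       # (F, 3) int, outward oriented
    edges: np.ndarray           # (E, 2) int, unique
    rest_lengths: np.ndarray    # (E,)
    ref_areas: np.ndarray       # (F,)
    bead_diameter: float

    @property
    def n_beads(self) -> int:
        return len(self.bead_positions)

    def euler_characteristic(self) -> int:
        return self.n_beads - len(self.edges) + len(self.triangles)

    def edge_lengths(self, positions: np.ndarray | None = None) -> np.ndarray:
        p = self.bead_positions if positions is None else positions
        d = p[self.edges[:, 0]] - p[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    def triangle_areas(self, positions: np.ndarray | None = None) -> np.ndarray:
        p = self.bead_positions if positions is None else positions
        a, b, c = (p[self.triangles[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def total_area(self, positions: np.ndarray | None = None) -> float:
        return float(self.triangle_areas(positions).sum())


@lru_cache(maxsize=16)
def _unit_icosphere(level: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = trimesh.creation.icosphere(subdivisions=level, radius=1.0)
    if m.volume < 0:  # enforce outward orientation
        m.invert()
    return (np.asarray(m.vertices, dtype=float),
            np.asarray(m.faces, dtype=np.int64),
            np.asarray(m.edges_unique, dtype=np.int64))


@lru_cache(maxsize=16)
def _unit_mean_edge(level: int) -> float:
    v, _, e = _unit_icosphere(level)
    return float(np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1).mean())


def icosphere_level_for_edge(radius: float, max_edge: float,
                             max_level: int = 7) -> int:
    """Smallest subdivision level whose mean edge is <= ``max_edge``."""
    if not radius > 0 or not max_edge > 0:
        raise ValueError("radius and max_edge must be positive")
    for level in range(max_level + 1):
        if radius * _unit_mean_edge(level) <= max_edge:
            return level
    raise ValueError(
        f"no icosphere level <= {max_level} reaches mean edge {max_edge} "
        f"at radius {radius}"
    )


def _shell_from_level(radius: float, level: int, bead_diameter: float
                      ) -> TriangulatedShell:
    v, f, e = _unit_icosphere(level)
    pos = v * radius
    shell = TriangulatedShell(
        bead_positions=pos,
        triangles=f.copy(),
        edges=e.copy(),
        rest_lengths=np.linalg.norm(pos[e[:, 0]] - pos[e[:, 1]], axis=1),
        ref_areas=np.empty(len(f)),
        bead_diameter=bead_diameter,
    )
    shell.ref_areas = shell.triangle_areas()
    return shell


def build_icosphere(radius: float, target_edge: float,
                    bead_diameter: float | None = None) -> TriangulatedShell:
    """Closed triangulated sphere with mean edge length near ``target_edge``.

    The subdivision level is the one whose mean edge length is closest (in
    log ratio) to the target; vertices lie exactly on the sphere of the given
    radius.  Rest lengths and reference areas are recorded from the built
    geometry, so the mesh is stress free as constructed.
    """
    if not radius > target_edge > 0:
        raise ValueError(
            f"need radius > target_edge > 0, got radius={radius}, "
            f"target_edge={target_edge} (sphere must host >= 12 vertices)"
        )
    best, best_err = 0, np.inf
    for level in range(8):
        err = abs(np.log(radius * _unit_mean_edge(level) / target_edge))
        if err < best_err:
            best, best_err = level, err
    return _shell_from_level(radius, best,
                             bead_diameter if bead_diameter is not None
                             else target_edge)
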