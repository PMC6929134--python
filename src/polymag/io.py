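"""Trajectory and assembly export.

Extended-XYZ records: one line per element with a species tag (``SI`` inner
bead, ``SO`` outer bead, ``MNP`` nanoparticle), position and, for MNPs, the
moment unit vector.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .builder import DipoleSet, MembraneAssembly

__all__ = ["write_xyz_frame", "write_assembly_xyz"]


def write_xyz_frame(fh, pos_beads: np.ndarray, pos_mnps: np.ndarray,
                    orientations: np.ndarray, n_inner: int,
                    comment: str = "") -> None:
    n_total = len(pos_beads) + len(pos_mnps)
    fh.write(f"{n_total}\n")
    fh.write(f'Properties=species:S:1:pos:R:3:moment:R:3 {comment}\n')
    for i, p in enumerate(pos_beads):
        tag = "SI" if i < n_inner else "SO"
        fh.write(f"{tag} {p[0]:.8g} {p[1]:.8g} {p[2]:.8g} 0 0 0\n")
    for p, e in zip(pos_mnps, orientations):
        fh.write(f"MNP {p[0]:.8g} {p[1]:.8g} {p[2]:.8g} "
                 f"{e[0]:.8g} {e[1]:.8g} {e[2]:.8g}\n")


def write_assembly_xyz(path: str | Path, assembly: MembraneAssembly,
                       dipoles: DipoleSet, comment: str = "") -> None:
    with open(path, "w") as fh:
        write_xyz_frame(fh, assembly.all_positions(), dipoles.positions,
                        dipoles.orientations, assembly.n_beads_per_shell,
                        comment=comment)
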