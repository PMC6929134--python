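"""Model parameters for the magnetopolymersome (MPS) model.

All quantities are in reduced units: the intershell spring rest length ``h``
is the unit of length, the thermal energy ``kBT`` the unit of energy, and the
bead mass the unit of mass.  The dimensionless vesicle size is ``q = D/h``
with ``D`` the outer diameter of the initial (spherical) geometry.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = ["ModelParams"]


@dataclass
class ModelParams:
    """Nondimensional run configuration of a model magnetopolymersome.

    Parameters
    ----------
    q
        Outer diameter of the vesicle over the intershell distance, ``D/h``.
    h
        Intershell spring rest length; the length unit (1 by definition).
    dp
        Magnetic nanoparticle (MNP) diameter.
    hgap
        Radial gap between the shell bead surfaces accessible to the MNPs;
        must equal ``h - (din + dout)/2``.
    din, dout
        Inner/outer shell bead diameters.  Default ``h - hgap`` each, which
        satisfies the gap constraint exactly.
    cb
        Membrane connectivity: fraction of shell nodes tied to the subtending
        node of the other shell by an elastic spring of rest length ``h``.
    phi
        MNP volume fraction of the intershell space they can move in.
    lambda_dd
        Dipolar coupling constant: contact head-to-tail pair energy over
        ``kBT`` (up to the conventional factor 2).
    xi
        Langevin field parameter: Zeeman energy ``mu*H0`` over ``kBT``.
    kBT
        Thermal energy (1 by definition of reduced units).
    zeta_t, zeta_r
        Translational / rotational friction coefficients of the Langevin
        thermostat.  ``zeta_r`` defaults to ``zeta_t * dp**2 / 3``.
    mass
        Bead and MNP mass.
    inertia
        MNP moment of inertia; defaults to the solid sphere ``mass*dp**2/10``.
    k_stretch, k_area, k_bond
        Elastic constants of the in-shell edge springs, the triangle-area
        restoring term and the intershell bonds.  The defaults encode a
        *fluid* amphiphilic membrane: stiff against local area change
        (k_area) but soft against in-plane shear (k_stretch), which is what
        lets the vesicle elongate at conserved total area.
    k_bend
        Dihedral bending constant of the shells (energy per squared radian
        of deviation from the as-built dihedral angles).  A thermalized
        triangulated surface with zero bending rigidity crumples
        entropically, so the default sits above the ~1 kBT crumpling
        threshold while staying small against the area stiffness.
    wca_epsilon
        Energy scale of the soft (WCA) steric repulsion.
    dt
        Integration timestep.
    seed
        Base RNG seed; fixes the assembly and the MNP positions.
    n_replicas
        Number of replicas, differing only in the initial orientations of the
        MNP moments (and in their thermal noise streams).
    coarsen
        Mesh coarsening factor (> 1 relaxes the maximum mesh edge length for
        cheaper, lower-resolution shells; coarse shells may become porous to
        the MNPs and are meant for quick smoke runs only).
    """

    q: float
    h: float = 1.0
    dp: float = 0.3
    hgap: float = 0.35
    din: float | None = None
    dout: float | None = None
    cb: float = 0.2
    phi: float = 0.11
    lambda_dd: float = 5.0
    xi: float = 0.0
    kBT: float = 1.0
    zeta_t: float = 1.0
    zeta_r: float | None = None
    mass: float = 1.0
    inertia: float | None = None
    k_stretch: float = 20.0
    k_area: float = 500.0
    k_bond: float = 50.0
    k_bend: float = 5.0
    wca_epsilon: float = 1.0
    dt: float = 0.002
    seed: int = 0
    n_replicas: int = 10
    coarsen: float = 1.0

    def __post_init__(self) -> None:
        if self.din is None:
            self.din = self.h - self.hgap
        if self.dout is None:
            self.dout = self.h - self.hgap
        if self.zeta_r is None:
            self.zeta_r = self.zeta_t * self.dp**2 / 3.0
        if self.inertia is None:
            self.inertia = self.mass * self.dp**2 / 10.0
        self.validate()

    # -- geometry helpers ---------------------------------------------------
    @property
    def r_outer(self) -> float:
        """Outer shell node radius D/2.

        Placing the *nodes* on the sphere of diameter D makes the basic-state
        cavity (the polyhedron over the inner-shell nodes at D/2 - h)
        approximately the sphere of diameter D - 2h.
        """
        return self.q * self.h / 2.0

    @property
    def r_inner(self) -> float:
        """Inner shell node radius, one spring length below the outer one."""
        return self.r_outer - self.h

    @property
    def gap_inner_radius(self) -> float:
        """Inner radius of the intershell space open to MNPs."""
        return self.r_inner + self.din / 2.0

    @property
    def gap_outer_radius(self) -> float:
        return self.r_outer - self.dout / 2.0

    def gap_volume(self) -> float:
        """Volume of the spherical layer the MNPs are allowed to move in."""
        return 4.0 * math.pi / 3.0 * (self.gap_outer_radius**3 - self.gap_inner_radius**3)

    def n_mnp(self) -> int:
        """MNP count from the volume fraction of the accessible gap."""
        v_p = math.pi / 6.0 * self.dp**3
        return int(round(self.phi * self.gap_volume() / v_p))

    def realized_phi(self) -> float:
        v_p = math.pi / 6.0 * self.dp**3
        return self.n_mnp() * v_p / self.gap_volume()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.q < 4:
            raise ValueError(f"q = {self.q} < 4: no positive cavity radius")
        if not 0 < self.cb <= 1:
            raise ValueError(f"cb = {self.cb} outside (0, 1]")
        if not 0 < self.phi < 0.6:
            raise ValueError(f"phi = {self.phi} outside (0, 0.6)")
        if self.dp >= self.hgap:
            raise ValueError(
                f"dp = {self.dp} >= hgap = {self.hgap}: monolayer does not fit"
            )
        gap = self.h - (self.din + self.dout) / 2.0
        if abs(gap - self.hgap) > 1e-9 * self.h:
            raise ValueError(
                f"hgap = {self.hgap} inconsistent with h - (din+dout)/2 = {gap}"
            )
        if self.r_inner <= 0:
            raise ValueError("inner shell radius <= 0: geometry inconsistent")
        for name in ("h", "dp", "kBT", "zeta_t", "zeta_r", "mass", "inertia",
                     "k_stretch", "k_area", "k_bond", "wca_epsilon", "dt",
                     "coarsen"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k_bend < 0:
            raise ValueError("k_bend must be non-negative")

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "ModelParams":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValueError(f"{path}: expected a mapping of parameters")
        return cls.from_dict(d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
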