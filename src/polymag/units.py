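"""Dimensional <-> reduced parameter conversion (Gaussian units).

The material formulas are evaluated in Gaussian units (emu, Oe, erg, cm)
since magnetization and field strength are conventionally quoted that way
for ferrite nanoparticles.  The dipolar coupling constant is
``lambda = mu^2 / (dp^3 kBT)`` and the Langevin field parameter
``xi = mu H0 / kBT``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["KB_ERG", "DimensionalInputs", "moment_from_material",
           "lambda_from_material", "xi_from_field", "field_from_xi",
           "reduced_from_dimensional", "dimensional_from_reduced"]

KB_ERG = 1.380649e-16  # Boltzmann constant, erg/K
NM_TO_CM = 1e-7


@dataclass
class DimensionalInputs:
    """Laboratory-frame material parameters."""

    dp_nm: float = 15.0        # nanoparticle diameter
    M_emu_cc: float = 500.0    # saturation magnetization of the ferrite
    T_K: float = 300.0         # temperature
    H0_Oe: float = 0.0         # applied field
    h_nm: float = 50.0         # intershell distance (the length unit)

    def __post_init__(self) -> None:
        for name in ("dp_nm", "M_emu_cc", "T_K", "h_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.H0_Oe < 0:
            raise ValueError("H0_Oe must be non-negative")


def moment_from_material(dp_nm: float, M_emu_cc: float) -> float:
    """Magnetic moment mu = (pi/6) M dp^3 of a uniformly magnetized
    sphere, in emu."""
    return math.pi / 6.0 * M_emu_cc * (dp_nm * NM_TO_CM) ** 3


def lambda_from_material(dp_nm: float, M_emu_cc: float, T_K: float) -> float:
    """Dipolar coupling constant lambda = mu^2 / (dp^3 kBT)."""
    mu = moment_from_material(dp_nm, M_emu_cc)
    return mu**2 / ((dp_nm * NM_TO_CM) ** 3 * KB_ERG * T_K)


def xi_from_field(mu_emu: float, H0_Oe: float, T_K: float) -> float:
    """Langevin field parameter xi = mu H0 / kBT.

    This is the literal evaluation of the Zeeman-to-thermal energy ratio.
    """
    return mu_emu * H0_Oe / (KB_ERG * T_K)


def field_from_xi(mu_emu: float, xi: float, T_K: float) -> float:
    """Inverse of :func:`xi_from_field`: field strength in Oe."""
    return xi * KB_ERG * T_K / mu_emu


def reduced_from_dimensional(d: DimensionalInputs) -> dict:
    """Reduced parameters (lambda, xi, dp/h, mu) from lab-frame inputs."""
    mu = moment_from_material(d.dp_nm, d.M_emu_cc)
    return {
        "lambda_dd": lambda_from_material(d.dp_nm, d.M_emu_cc, d.T_K),
        "xi": xi_from_field(mu, d.H0_Oe, d.T_K),
        "dp": d.dp_nm / d.h_nm,
        "mu_emu": mu,
    }


def dimensional_from_reduced(lambda_dd: float, xi: float, dp: float,
                             T_K: float = 300.0, h_nm: float = 50.0) -> DimensionalInputs:
    """Invert :func:`reduced_from_dimensional` at a given T and h."""
    dp_nm = dp * h_nm
    dp_cm = dp_nm * NM_TO_CM
    mu = math.sqrt(lambda_dd * dp_cm**3 * KB_ERG * T_K)
    M = mu / (math.pi / 6.0 * dp_cm**3)
    H0 = xi * KB_ERG * T_K / mu if mu > 0 else 0.0
    return DimensionalInputs(dp_nm=dp_nm, M_emu_cc=M, T_K=T_K, H0_Oe=H0,
                             h_nm=h_nm)
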