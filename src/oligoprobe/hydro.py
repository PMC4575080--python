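"""Hydrodynamic back-of-envelope chain for oligomer stoichiometry.

Empirical chain-length scaling of the hydrodynamic radius (globular
Rh = 4.75 N^0.29, chemically denatured Rh = 2.21 N^0.57, both in angstrom
with N the residue count; Wilkins et al. 1999 calibration), equivalent-
sphere volumes, subunit-count bounds for an oligomer of known volume, and
the Stokes-Einstein-Debye rotational correlation time
tau_m = 4 pi eta r^3 / (3 kB T).
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .constants import ANGSTROM, KB, water_viscosity
from .datatypes import StoichiometryBounds

__all__ = [
    "Conformation",
    "rh_empirical",
    "sphere_volume",
    "subunit_bounds",
    "tau_m_sed",
]


class Conformation(str, Enum):
    GLOBULAR = "globular"
    DENATURED = "denatured"


#: (prefactor, exponent) of Rh = A * N^nu in angstrom.
_SCALING = {
    Conformation.GLOBULAR: (4.75, 0.29),
    Conformation.DENATURED: (2.21, 0.57),
}


def rh_empirical(n_residues: int, conformation: Conformation | str) -> float:
    """Empirical hydrodynamic radius (angstrom) of a single chain.

    Returns the unrounded value; display conventions round to the nearest
    angstrom.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    a, nu = _SCALING[Conformation(conformation)]
    return a * float(n_residues) ** nu


def sphere_volume(r: float) -> float:
    """Volume (angstrom^3) of a sphere of radius r (angstrom)."""
    if r < 0:
        raise ValueError("radius must be nonnegative")
    return 4.0 / 3.0 * np.pi * r**3


def subunit_bounds(v_olig: float, v_glob: float, v_denat: float) -> StoichiometryBounds:
    """Subunit-count bracket for an oligomer of volume v_olig built from
    monomers whose volume lies between the compact (globular) and expanded
    (denatured) estimates.

    n_min = round(v_olig/v_denat), n_max = round(v_olig/v_glob), both
    clamped to >= 1.
    """
    if min(v_olig, v_glob, v_denat) <= 0:
        raise ValueError("volumes must be positive")
    if v_denat <= v_glob:
        raise ValueError(
            "denatured monomer volume must exceed the globular one"
        )
    n_min = max(1, round(v_olig / v_denat))
    n_max = max(1, round(v_olig / v_glob))
    return StoichiometryBounds(
        v_oligomer=float(v_olig),
        v_monomer_globular=float(v_glob),
        v_monomer_denatured=float(v_denat),
        n_min=int(n_min),
        n_max=int(n_max),
    )


def tau_m_sed(
    rh: float, temperature: float, viscosity: float | str = "water"
) -> float:
    """Rotational correlation time (seconds) of a sphere of hydrodynamic
    radius rh (angstrom) from the Stokes-Einstein-Debye relation.

    viscosity is in Pa*s, or the string "water" to interpolate the dynamic
    viscosity of water at the given temperature (0-40 C supported).
    """
    if rh <= 0:
        raise ValueError("rh must be positive")
    if not (273.0 < temperature < 373.0):
        raise ValueError("temperature must be between 273 and 373 K")
    eta = water_viscosity(temperature) if viscosity == "water" else float(viscosity)
    r_m = rh * ANGSTROM
    return 4.0 * np.pi * eta * r_m**3 / (3.0 * KB * temperature)
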