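"""Physical constants and solvent properties shared across the analysis stages.

All internal units are SI unless a function's signature says otherwise;
lengths at API boundaries are in angstroms, matching how hydrodynamic and
scattering results are reported in the structural-biology literature.
"""

from __future__ import annotations

import numpy as np

#: Boltzmann constant, J/K.
KB = 1.380649e-23

#: Vacuum permeability, T^2 m^3 / J.
MU0 = 4.0e-7 * np.pi

#: Reduced Planck constant, J s.
HBAR = 1.054571817e-34

#: 1H gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_H = 2.6752218744e8

#: 15N gyromagnetic ratio, rad s^-1 T^-1 (negative).
GAMMA_N = -2.7126189e7

#: Angstrom in meters.
ANGSTROM = 1.0e-10

#: Gas constant in cal mol^-1 K^-1 (hydrogen-exchange Arrhenius corrections
#: are conventionally tabulated in kcal/mol).
R_CAL = 1.987


def water_viscosity(temperature_k: float) -> float:
    """Dynamic viscosity of water in Pa*s between 0 and 40 degrees C.

    Uses the Kestin-type correlation anchored at 20 degrees C
    (eta_20 = 1.0016 mPa*s):

        log10(eta_t / eta_20) = (20 - t)/(t + 96)
            * [1.2364 - 1.37e-3 (20 - t) + 5.7e-6 (20 - t)^2]

    with t in Celsius.  Accurate to ~0.1% over the supported range, which
    comfortably covers chromatography and NMR sample temperatures.
    """
    t_c = temperature_k - 273.15
    if not (0.0 <= t_c <= 40.0):
        raise ValueError(
            f"water viscosity table covers 0-40 C; got {t_c:.2f} C"
        )
    dt = 20.0 - t_c
    exponent = dt / (t_c + 96.0) * (1.2364 - 1.37e-3 * dt + 5.7e-6 * dt * dt)
    return 1.0016e-3 * 10.0 ** exponent
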