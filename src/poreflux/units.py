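"""Unit conventions and physical constants.

Internal unit system (everything in the package uses these; conversions
happen only here):

==============  ==========
quantity        unit
==============  ==========
length          nm
time            ns
charge          e (elementary charges)
current         pA
potential       V (bias values reported in mV)
field           V/nm
diffusion       nm^2/ns  (1 nm^2/ns = 1e-9 m^2/s)
temperature     K
conductivity    S/m
==============  ==========

In these units the thermal energy k_B*T is carried in eV so that a drift
velocity is simply ``q[e] * E[V/nm] * D[nm^2/ns] / kBT[eV]`` in nm/ns.
"""

from __future__ import annotations

import math

#: elementary charge, C
E_CHARGE = 1.602176634e-19

#: Boltzmann constant, J/K
K_B_J = 1.380649e-23

#: Boltzmann constant, eV/K
K_B_EV = 8.617333262e-5

#: 1 e/ns expressed in pA  (1.602176634e-19 C / 1e-9 s = 1.602176634e-10 A)
PA_PER_E_NS = 160.2176634

#: vacuum permittivity in e / (V nm): eps0[C/(V m)] / e[C] * 1e-9 m/nm
EPS0_E_PER_V_NM = 8.8541878128e-12 / E_CHARGE * 1e-9

#: multiply pA / (V/nm * nm^2) by this to get S/m
#: (1e-12 A) / (1e9 V/m * 1e-18 m^2) = 1e-3 S/m
KAPPA_PA_VNM_NM2_TO_S_M = 1e-3


def unit_current(e_per_ns: float) -> float:
    """Convert a current from e/ns to pA.

    This fixes the unit contract for every current the package reports.
    """
    if not math.isfinite(e_per_ns):
        raise ValueError(f"current must be finite, got {e_per_ns}")
    return e_per_ns * PA_PER_E_NS


def thermal_energy_ev(temperature: float) -> float:
    """k_B*T in eV for a temperature in K."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return K_B_EV * temperature
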