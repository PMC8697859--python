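"""Unit conventions and conversion factors.

All quantities in the package live in a single, fixed unit system set at the
I/O boundary:

* distances in angstrom (Å),
* vibrational wavenumbers in cm⁻¹,
* energies in electronvolt (eV),
* masses in unified atomic mass units (u).

Every conversion factor used anywhere in the package is defined here.
"""

from __future__ import annotations

import math

import scipy.constants as _sc

#: 1 cm⁻¹ expressed in eV (hc · 100 cm / e).
CM1_TO_EV: float = 1.239841984e-4

#: 1 eV in joule.
EV_TO_J: float = _sc.electron_volt

#: 1 u in kg.
U_TO_KG: float = _sc.atomic_mass

#: 1 Å in m.
ANGSTROM_TO_M: float = 1e-10

#: Speed of light in cm/s (for angular frequency → wavenumber).
C_CM_PER_S: float = _sc.c * 100.0


def force_constant_to_wavenumber(k_ev_per_a2: float, mass_u: float) -> float:
    """Convert a harmonic force constant to a vibrational wavenumber.

    Parameters
    ----------
    k_ev_per_a2:
        Force constant in eV/Å².
    mass_u:
        Reduced mass in u.

    Returns
    -------
    float
        Harmonic wavenumber ω_e in cm⁻¹, via ω = √(k/m) / (2πc).
    """
    if k_ev_per_a2 < 0 or mass_u <= 0:
        raise ValueError("force constant must be >= 0 and mass > 0")
    k_si = k_ev_per_a2 * EV_TO_J / ANGSTROM_TO_M**2
    omega = math.sqrt(k_si / (mass_u * U_TO_KG))  # rad/s
    return omega / (2.0 * math.pi * C_CM_PER_S)
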