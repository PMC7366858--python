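"""Physical constants and unit conversions.

Internal unit system: length Å, time fs, mass amu, energy kcal/mol,
charge e.  Velocities are Å/fs, forces kcal/mol/Å.
"""

import math

#: Coulomb constant, kcal·Å/(mol·e²)
COULOMB_K = 332.0637

#: Boltzmann constant, kcal/mol/K
KB = 0.0019872041

#: 1 amu·Å²/fs² expressed in kcal/mol (1e-3 kg/mol · 1e10 m²/s² / 4184 J/kcal)
KE_CONV = 1.0e7 / 4184.0

#: speed of light, cm/s
C_LIGHT_CM = 2.99792458e10

#: Avogadro-scale conversion of a mass-weighted Hessian eigenvalue
#: (kcal/mol/Å²/amu) to angular frequency squared (s⁻²)
_OMEGA2_SI = 4184.0 / (1.0e-3 * 1.0e-20)


def eigenvalue_to_wavenumber(eigval: float) -> float:
    """Convert a mass-weighted Hessian eigenvalue (kcal/mol/Å²/amu) to cm⁻¹."""
    if eigval <= 0.0:
        return 0.0
    omega = math.sqrt(eigval * _OMEGA2_SI)  # rad/s
    return omega / (2.0 * math.pi * C_LIGHT_CM)
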