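"""Physical constants and unit conversions.

Energies are carried in kcal/mol, lengths in angstrom, masses in amu and
time in fs throughout the package.  The integrator works in the internal
"MD unit" system (amu, A, fs), whose energy unit is amu*A^2/fs^2; KCAL_TO_MDU
converts kcal/mol into it.
"""

import numpy as np
from scipy import constants as _c

#: Coulomb prefactor e^2/(4 pi eps0) in kcal/mol * A / e^2
COULOMB = _c.e**2 / (4.0 * np.pi * _c.epsilon_0 * 1e-10) * _c.N_A / 4184.0

#: Boltzmann constant in kcal/mol/K
KB = _c.k * _c.N_A / 4184.0

#: 1 kcal/mol expressed in amu*A^2/fs^2
KCAL_TO_MDU = 4184.0 / _c.N_A / _c.atomic_mass * 1e-10

#: hbar in amu*A^2/fs
HBAR_MDU = _c.hbar / (_c.atomic_mass * 1e-20) * 1e-15

#: Boltzmann constant in amu*A^2/fs^2 / K
KB_MDU = KB * KCAL_TO_MDU

#: Avogadro constant times 1e-24 (molecules/mol * cm^3/A^3), used for densities
AVOGADRO_PER_A3 = _c.N_A * 1e-24

ATOMIC_MASS = {"O": 15.999, "H": 1.008}

#: molar mass of H2O in g/mol
WATER_MOLAR_MASS = ATOMIC_MASS["O"] + 2.0 * ATOMIC_MASS["H"]

#: 1 atm in kcal/mol/A^3
ATM_TO_KCAL_A3 = _c.atm * 1e-30 * _c.N_A / 4184.0
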