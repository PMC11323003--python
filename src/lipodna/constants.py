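"""Physical constants and unit conventions.

Lengths are nanometres everywhere inside the package; the scattering
boundary converts to ångström (the convention of diffraction work).
Energies are in units of k_B T, charges in units of the elementary
charge e.  All constants come from :mod:`scipy.constants` (CODATA).
"""

from scipy.constants import (
    Avogadro as N_A,
    Boltzmann as K_B,
    elementary_charge as E_CHARGE,
    epsilon_0 as EPS_0,
)

#: nanometre in metres
NM = 1e-9
#: ångström per nanometre
ANGSTROM_PER_NM = 10.0

#: particles per nm^3 for a 1 mol/L solution
PER_NM3_PER_MOLAR = N_A * 1e3 * NM**3  # = N_A * 1000 / 1e27

__all__ = [
    "N_A",
    "K_B",
    "E_CHARGE",
    "EPS_0",
    "NM",
    "ANGSTROM_PER_NM",
    "PER_NM3_PER_MOLAR",
]
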