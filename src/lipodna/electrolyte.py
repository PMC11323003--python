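"""Closed-form electrolyte electrostatics.

Ionic strength, Bjerrum length, Debye screening length and the
dimensionless ion-ion coupling parameter Γ = l_B / d.  The Bjerrum
length is implemented in SI form,

    l_B(q) = q² e² / (4π ε₀ ε_r k_B T),

which corresponds to the Gaussian-units expression q²/(ε_r k_B T)
often written in the electrolyte literature.  The Debye length is

    κ⁻¹ = (8π l_B(1e) n_I)^(-1/2),   n_I = N_A · I,

with I = ½ Σ c_i z_i² the ionic strength (molar, converted to a number
density).  Γ compares the pair Coulomb energy of two ions at their
typical separation d with thermal energy: Γ > 1 marks the strongly
coupled regime where ion-ion correlations matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import E_CHARGE, EPS_0, K_B, NM, PER_NM3_PER_MOLAR

__all__ = [
    "IonSpecies",
    "ElectrolyteCondition",
    "ionic_strength",
    "bjerrum_length",
    "debye_length",
    "coupling_parameter",
    "mgcl2",
    "LIPID_EPSILON_R",
    "SOLUTION_EPSILON_R",
    "DEFAULT_TEMPERATURE",
]

#: relative permittivity computed for the membrane-confined DNA system
LIPID_EPSILON_R = 40.1
#: relative permittivity computed for the DNA-in-solution system
SOLUTION_EPSILON_R = 92.2
#: default absolute temperature (K), standard for bilayer simulations
DEFAULT_TEMPERATURE = 300.0


@dataclass(frozen=True)
class IonSpecies:
    """One ionic species: a label, a molar concentration and an integer valence."""

    label: str
    concentration: float  # mol/L
    valence: int

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"negative concentration for {self.label!r}")


@dataclass(frozen=True)
class ElectrolyteCondition:
    """Solvent and salt context for all electrostatic quantities."""

    species: tuple[IonSpecies, ...]
    epsilon_r: float = SOLUTION_EPSILON_R
    temperature: float = field(default=DEFAULT_TEMPERATURE)

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("an electrolyte needs at least one ion species")
        if self.epsilon_r <= 0:
            raise ValueError("epsilon_r must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")


def mgcl2(
    concentration: float = 0.05,
    epsilon_r: float = 78.5,
    temperature: float = DEFAULT_TEMPERATURE,
) -> ElectrolyteCondition:
    """A fully dissociated MgCl₂ solution (default ~50 mM, the study's salt)."""
    return ElectrolyteCondition(
        species=(
            IonSpecies("MG", concentration, +2),
            IonSpecies("CL", 2.0 * concentration, -1),
        ),
        epsilon_r=epsilon_r,
        temperature=temperature,
    )


def ionic_strength(cond: ElectrolyteCondition) -> float:
    """Ionic strength I = ½ Σ c_i z_i² in mol/L."""
    return 0.5 * sum(s.concentration * s.valence**2 for s in cond.species)


def bjerrum_length(charge: float, cond: ElectrolyteCondition) -> float:
    """Bjerrum length of a charge ``charge`` (in units of e), in nm.

    The separation at which the pair energy of two such charges equals
    k_B T.  Scales exactly as charge² and as 1/(ε_r T).
    """
    if charge == 0:
        raise ValueError("Bjerrum length is undefined for zero charge")
    q = charge * E_CHARGE
    return q * q / (4.0 * math.pi * EPS_0 * cond.epsilon_r * K_B * cond.temperature) / NM


def debye_length(cond: ElectrolyteCondition) -> float:
    """Debye screening length κ⁻¹ in nm.

    Raises for zero ionic strength rather than returning an infinite
    screening length.
    """
    i_molar = ionic_strength(cond)
    if i_molar <= 0:
        raise ValueError("zero ionic strength: screening length is infinite")
    n_i = i_molar * PER_NM3_PER_MOLAR  # ions/nm^3 equivalent
    kappa_sq = 8.0 * math.pi * bjerrum_length(1.0, cond) * n_i
    return 1.0 / math.sqrt(kappa_sq)


def debye_kappa(cond: ElectrolyteCondition) -> float:
    """Inverse Debye length κ in nm⁻¹."""
    return 1.0 / debye_length(cond)


def coupling_parameter(
    q1: float, q2: float, separation: float, cond: ElectrolyteCondition
) -> float:
    """Ion-ion coupling parameter Γ = l_B(q1,q2) / d (dimensionless).

    ``l_B(q1,q2) = |q1 q2| e² / (4π ε₀ ε_r k_B T)`` is the pair Bjerrum
    length; ``separation`` is the typical distance d between the ions of
    interest, in nm.  Reported as a positive coupling strength for
    unlike pairs as well.
    """
    if separation <= 0:
        raise ValueError("ion separation must be positive")
    pair_lb = abs(q1 * q2) * bjerrum_length(1.0, cond)
    return pair_lb / separation
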