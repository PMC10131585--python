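"""Thermodynamic state and physical constants.

Units throughout the package: distances in angstrom, angles in degrees,
energies in kcal/mol, temperatures in kelvin, concentrations in mol/L.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant in kcal mol^-1 K^-1 (MD-package convention).
KB_KCAL = 0.0019872

#: Avogadro's number, mol^-1 (CODATA exact value).
AVOGADRO = 6.02214076e23

#: Electrostatic conversion factor, kcal A mol^-1 e^-2.
COULOMB_CONSTANT = 332.0636


def standard_volume_A3() -> float:
    """Volume per molecule at the 1 mol/L standard concentration, in A^3.

    1 L = 1e27 A^3, so V = 1e27 / N_A = 1660.539 A^3.
    """
    return 1.0e27 / AVOGADRO


@dataclass(frozen=True)
class ThermoState:
    """Temperature and derived inverse temperature.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Must be positive. 300 K is the
        default used for free-energy work; 310 K is typical for
        physiological-temperature contact simulations.
    """

    temperature: float = 300.0
    kB: float = KB_KCAL

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def kT(self) -> float:
        """kB*T in kcal/mol."""
        return self.kB * self.temperature

    @property
    def beta(self) -> float:
        """Inverse temperature 1/(kB*T) in mol/kcal."""
        return 1.0 / self.kT
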