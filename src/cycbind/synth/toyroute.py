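"""Separable toy binding model for end-to-end geometric-route checks.

The model factorizes the bound and free states over the route's
coordinates: a conformational coordinate c with the same PMF in both
states, isotropic Euler orientation (Theta, Phi, Psi) and polar direction
(theta, phi) angles, and a radial separation PMF W(r). Every stage PMF is
derived deterministically from this one analytic surface, so the assembled
standard free energy has a closed form,

    dG0 = -kT ln(4 pi r*^2 I C0),   I = int_a^{r*} e^{-beta (W - W(r*))} dr,

independent of every restraint force constant: the apply costs on the free
ligand are repaid exactly by the release legs and the stage-3 surface
factor. Doubling the force constants must therefore leave the total
unchanged, which is the sharpest self-consistency check the route offers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from cycbind.georoute import (
    RestraintDefinition,
    SeparationInputs,
    StageResult,
    assemble_standard_free_energy,
    orientational_restraint_analytic,
    restraint_free_energy,
    separation_term,
    GeometricRouteResult,
)
from cycbind.pmf import PMFProfile
from cycbind.thermo import ThermoState, standard_volume_A3


def _radial_pmf(grid: np.ndarray, well_depth: float, well_center: float,
                well_width: float) -> np.ndarray:
    """Gaussian well fading to a flat plateau at large r."""
    return -well_depth * np.exp(-0.5 * ((grid - well_center) / well_width) ** 2)


@dataclass
class ToyBindingModel:
    """Analytic separable binding surface with designable restraint stiffness."""

    k_conf: float = 10.0      # kcal/mol/A^2 on the conformational coordinate
    k_orient: float = 0.05    # kcal/mol/deg^2 on each Euler angle
    k_dir: float = 0.05       # kcal/mol/deg^2 on each polar direction angle
    conf_kappa: float = 0.5   # curvature of the free-ligand conformational PMF
    conf_center: float = 2.0
    well_depth: float = 6.0
    well_center: float = 17.5
    well_width: float = 0.6
    r_star: float = 26.0
    a: float = 16.0
    thermo: ThermoState = field(default_factory=ThermoState)

    def conformational_pmf(self) -> PMFProfile:
        grid = np.arange(-6.0, 10.0 + 1e-12, 0.005)
        w = 0.5 * self.conf_kappa * (grid - self.conf_center) ** 2
        return PMFProfile(grid, w, "raw")

    def radial_pmf(self) -> PMFProfile:
        grid = np.arange(self.a, self.r_star + 1e-12, 0.005)
        return PMFProfile(grid, _radial_pmf(grid, self.well_depth, self.well_center,
                                            self.well_width), "raw")

    def _flat_angle_pmf(self) -> PMFProfile:
        grid = np.arange(-180.0, 180.0 + 1e-9, 0.02)
        return PMFProfile(grid, np.zeros_like(grid), "raw")

    def _polar_angle_pmf(self) -> PMFProfile:
        # Jacobian-inclusive PMF of an isotropic polar angle: -kT ln sin(theta)
        grid = np.arange(0.05, 180.0 - 0.05 + 1e-9, 0.02)
        w = -self.thermo.kT * np.log(np.sin(np.deg2rad(grid)))
        return PMFProfile(grid, w, "raw")

    def stages(self) -> List[StageResult]:
        th = self.thermo
        u_conf = RestraintDefinition("rmsd", self.conf_center, self.k_conf, "A")
        eulers = {
            "euler_Theta": RestraintDefinition("euler_Theta", 90.0, self.k_orient, "deg"),
            "euler_Phi": RestraintDefinition("euler_Phi", 0.0, self.k_orient, "deg"),
            "euler_Psi": RestraintDefinition("euler_Psi", 0.0, self.k_orient, "deg"),
        }
        u_theta = RestraintDefinition("polar_theta", 90.0, self.k_dir, "deg")
        u_phi = RestraintDefinition("polar_phi", 0.0, self.k_dir, "deg")

        conf = self.conformational_pmf()
        flat = self._flat_angle_pmf()
        polar = self._polar_angle_pmf()
        sep = SeparationInputs(W=self.radial_pmf(), r_star=self.r_star, a=self.a,
                               u_dir=(u_theta, u_phi))

        s1 = StageResult(1, restraint_free_energy(conf, u_conf, "apply", th), method="quadrature")
        s2_res = orientational_restraint_analytic(eulers, th)
        s2 = StageResult(2, s2_res.free_energy, method="analytic")
        s3 = separation_term(sep, th)
        s4 = StageResult(4, restraint_free_energy(flat, u_phi, "release", th), method="quadrature")
        s5 = StageResult(5, restraint_free_energy(polar, u_theta, "release", th), method="quadrature")
        s6 = StageResult(6, restraint_free_energy(flat, eulers["euler_Psi"], "release", th), method="quadrature")
        s7 = StageResult(7, restraint_free_energy(flat, eulers["euler_Phi"], "release", th), method="quadrature")
        s8_pmf = self._polar_angle_pmf()
        s8 = StageResult(8, restraint_free_energy(s8_pmf, eulers["euler_Theta"], "release", th), method="quadrature")
        s9 = StageResult(9, restraint_free_energy(conf, u_conf, "release", th), method="quadrature")
        return [s1, s2, s3, s4, s5, s6, s7, s8, s9]

    def assemble(self) -> GeometricRouteResult:
        return assemble_standard_free_energy(self.stages(), self.thermo)

    def analytic_total(self) -> float:
        """Closed-form dG0 of the separable model (restraint-free)."""
        th = self.thermo
        W = self.radial_pmf()
        w_star = W.value_at(self.r_star)
        integrand = np.exp(-th.beta * (W.w - w_star))
        i_val = float(np.trapezoid(integrand, W.grid))
        c0 = 1.0 / standard_volume_A3()
        return -th.kT * math.log(4.0 * math.pi * self.r_star**2 * i_val * c0)
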