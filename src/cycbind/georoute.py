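"""Geometric-route assembly of the standard binding free energy.

The route computes an absolute peptide:protein binding free energy in nine
stages: apply a conformational (RMSD) restraint to the free ligand (stage
1), apply orientational Euler-angle restraints (stage 2, analytic), bind
the restrained ligand via a radial separation PMF with directional
restraints (stage 3, carrying the standard-state correction), then release
the directional, orientational, and conformational restraints on the bound
complex (stages 4-9). Because the initial and final states are the
unrestrained free ligand and unrestrained complex, the stage sum is the
standard binding free energy dG0, convertible to a dissociation constant by
K_D = C0 * exp(dG0 / kBT).

The free energy of applying a restraint u on a coordinate with PMF w is

    dG_apply = -kT ln [ int exp(-beta (w + u)) dxi / int exp(-beta w) dxi ]

and releasing is the exact negative. The stage-3 separation term is
-kT ln(S* I C0) with I = int_a^{r*} exp(-beta (W(r) - W(r*))) dr and
S* = r*^2 int int sin(theta) exp(-beta u_dir(theta, phi)) dtheta dphi; the
r*^2 geometric factor lives entirely in S*, and I carries no r^2 weight.

Angles are handled in degrees at the interface, converted to radians
inside integrands; polar/Euler Jacobians (sin terms) are written
explicitly. Angular PMFs supplied by users are assumed Jacobian-inclusive,
as colvar-based ABF output is.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from scipy import integrate

from cycbind.pmf import PMFProfile
from cycbind.thermo import ThermoState, standard_volume_A3

DEG = math.pi / 180.0

#: Stage layout of the staged route (reversed numbering convention:
#: restraints are applied to the free ligand first).
STAGE_LABELS = {
    1: ("Ligand", "Apply conform. restraint", "dG_apply_RMSD"),
    2: ("Ligand", "Apply orient. restraints", "dG_apply_ThetaPhiPsi"),
    3: ("Complex", "Binding of restrained ligand", "-kT ln(S* I C0)"),
    4: ("Complex", "Release phi direct. restraint", "dG_release_phi"),
    5: ("Complex", "Release theta direct. restraint", "dG_release_theta"),
    6: ("Complex", "Release Psi orient. restraint", "dG_release_Psi"),
    7: ("Complex", "Release Phi orient. restraint", "dG_release_Phi"),
    8: ("Complex", "Release Theta orient. restraint", "dG_release_Theta"),
    9: ("Complex", "Release conform. restraint", "dG_release_RMSD"),
}

COORDINATES = (
    "rmsd", "euler_Theta", "euler_Phi", "euler_Psi",
    "polar_theta", "polar_phi", "distance_r",
)

#: Default restraint force constants when a manifest omits them:
#: 10 kcal/mol/A^2 on distance-like coordinates, 0.1 kcal/mol/deg^2 on angles.
DEFAULT_FORCE_CONSTANTS = {"distance": 10.0, "angle": 0.1}


@dataclass(frozen=True)
class RestraintDefinition:
    """Harmonic bias u(xi) = (k/2)(xi - center)^2 on a named coordinate."""

    coordinate: str
    center: float
    force_constant: float
    units: str = "A"  # 'A' or 'deg'

    def __post_init__(self):
        if self.coordinate not in COORDINATES:
            raise ValueError(f"unknown coordinate {self.coordinate!r}")
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")

    def energy(self, xi):
        return 0.5 * self.force_constant * (np.asarray(xi, dtype=float) - self.center) ** 2


@dataclass
class StageResult:
    stage_id: int
    free_energy: float
    uncertainty: float = 0.0
    method: str = ""

    def __post_init__(self):
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")


def restraint_free_energy(
    pmf: PMFProfile,
    restraint: RestraintDefinition,
    direction: str = "apply",
    thermo: ThermoState = ThermoState(),
    boundary_tol: float = 1e-6,
) -> float:
    """Free energy of applying (or releasing) a harmonic restraint.

    Trapezoid quadrature on the PMF grid. The PMF must cover essentially all
    of the restrained Boltzmann weight: if the boundary bins carry more than
    ``boundary_tol`` of the total weight the domain is too small and the
    call is refused.
    """
    if direction not in ("apply", "release"):
        raise ValueError("direction must be 'apply' or 'release'")
    if restraint.force_constant == 0:
        return 0.0  # identical integrands; exact, and no coverage question
    beta = thermo.beta
    x = pmf.grid
    w = pmf.w - pmf.w.min()
    u = restraint.energy(x)
    e_unres = np.exp(-beta * w)
    e_res = np.exp(-beta * (w + u))
    z_unres = np.trapezoid(e_unres, x)
    z_res = np.trapezoid(e_res, x)
    dx0 = x[1] - x[0]
    dx1 = x[-1] - x[-2]
    boundary_weight = 0.5 * (e_res[0] * dx0 + e_res[-1] * dx1)
    if boundary_weight > boundary_tol * z_res:
        raise ValueError(
            "restrained weight does not vanish at the PMF boundary "
            f"(fraction {boundary_weight / z_res:.2e}); extend the PMF domain"
        )
    dg_apply = -thermo.kT * math.log(z_res / z_unres)
    return dg_apply if direction == "apply" else -dg_apply


def orientational_restraint_analytic(
    restraints: Dict[str, RestraintDefinition],
    thermo: ThermoState = ThermoState(),
) -> StageResult:
    """Free energy of restraining the three Euler angles of a free ligand.

    dG = -kT ln [ int sin(Theta) exp(-beta (u_Theta + u_Phi + u_Psi)) /
                  int sin(Theta) ] over Theta in [0, 180] deg and Phi, Psi
    in [-180, 180] deg. The integrand is separable, so the triple integral
    factorizes into three adaptive 1-D quadratures. Exact (no simulation):
    the uncertainty is zero.
    """
    for key in ("euler_Theta", "euler_Phi", "euler_Psi"):
        if key not in restraints:
            raise ValueError(f"missing restraint for {key}")
    beta = thermo.beta
    if all(restraints[k].force_constant == 0 for k in
           ("euler_Theta", "euler_Phi", "euler_Psi")):
        warnings.warn("all Euler force constants are zero; orientational stage is 0")
        return StageResult(stage_id=2, free_energy=0.0, uncertainty=0.0, method="analytic")

    u_t = restraints["euler_Theta"]
    num_t, _ = integrate.quad(
        lambda th: math.sin(th * DEG) * math.exp(-beta * u_t.energy(th)), 0.0, 180.0,
        limit=200)
    den_t, _ = integrate.quad(lambda th: math.sin(th * DEG), 0.0, 180.0)
    total = -thermo.kT * math.log(num_t / den_t)
    for key in ("euler_Phi", "euler_Psi"):
        u = restraints[key]
        num, _ = integrate.quad(lambda a: math.exp(-beta * u.energy(a)), -180.0, 180.0,
                                limit=200)
        total += -thermo.kT * math.log(num / 360.0)
    return StageResult(stage_id=2, free_energy=total, uncertainty=0.0, method="analytic")


@dataclass
class SeparationInputs:
    """Inputs for the stage-3 binding term of the restrained ligand."""

    W: PMFProfile
    r_star: float = 26.0
    a: float = 16.0
    u_dir: Tuple[RestraintDefinition, RestraintDefinition] = None  # (theta, phi)
    C0_inv_volume: float = field(default_factory=standard_volume_A3)

    def __post_init__(self):
        if not self.a < self.r_star:
            raise ValueError("need a < r_star")
        if self.u_dir is None:
            self.u_dir = (
                RestraintDefinition("polar_theta", 90.0, 0.0, "deg"),
                RestraintDefinition("polar_phi", 0.0, 0.0, "deg"),
            )


def separation_term(
    inputs: SeparationInputs,
    thermo: ThermoState = ThermoState(),
) -> StageResult:
    """Stage-3 term -kT ln(S* I C0).

    I integrates the radial PMF referenced to its value at r*; S* is the
    directional-restraint surface factor at r*, r*^2 times the restrained
    solid-angle integral (4 pi r*^2 when unrestrained).
    """
    beta = thermo.beta
    W = inputs.W
    if W.grid[0] > inputs.a + 1e-9 or W.grid[-1] < inputs.r_star - 1e-9:
        raise ValueError(
            f"W must cover [{inputs.a}, {inputs.r_star}]; support is "
            f"[{W.grid[0]}, {W.grid[-1]}]"
        )
    w_star = W.value_at(inputs.r_star)
    mask = (W.grid >= inputs.a - 1e-9) & (W.grid <= inputs.r_star + 1e-9)
    r = W.grid[mask]
    wv = W.w[mask]
    integrand = np.exp(-beta * (wv - w_star))
    i_val = float(np.trapezoid(integrand, r))

    u_theta, u_phi = inputs.u_dir
    ang_theta, _ = integrate.quad(
        lambda th: math.sin(th * DEG) * math.exp(-beta * u_theta.energy(th)) * DEG,
        0.0, 180.0, limit=200)
    ang_phi, _ = integrate.quad(
        lambda ph: math.exp(-beta * u_phi.energy(ph)) * DEG, -180.0, 180.0, limit=200)
    s_star = inputs.r_star**2 * ang_theta * ang_phi

    c0 = 1.0 / inputs.C0_inv_volume
    dg = -thermo.kT * math.log(s_star * i_val * c0)
    return StageResult(stage_id=3, free_energy=dg, method="separation")


def deltaG_to_kd(deltaG0: float, thermo: ThermoState = ThermoState()) -> float:
    """Dissociation constant (mol/L) from the standard binding free energy."""
    if not math.isfinite(deltaG0):
        raise ValueError("deltaG0 must be finite")
    return math.exp(deltaG0 / thermo.kT)


def kd_to_deltaG(kd: float, thermo: ThermoState = ThermoState()) -> float:
    """Inverse of :func:`deltaG_to_kd` (kd in mol/L)."""
    if kd <= 0:
        raise ValueError("kd must be > 0")
    return thermo.kT * math.log(kd)


@dataclass
class GeometricRouteResult:
    stages: List[StageResult]
    total: float
    total_uncertainty: float
    kd: float

    def as_table(self) -> str:
        lines = ["stage\tsystem\taction\tfree_energy\tuncertainty"]
        for s in sorted(self.stages, key=lambda s: s.stage_id):
            system, action, _ = STAGE_LABELS[s.stage_id]
            lines.append(
                f"{s.stage_id}\t{system}\t{action}\t{s.free_energy:+.2f}\t{s.uncertainty:.2f}"
            )
        lines.append(
            f"Total\t—\tSum\t{self.total:+.2f}\t{self.total_uncertainty:.2f}"
        )
        return "\n".join(lines)


def reference_stages() -> List[StageResult]:
    """The packaged nine-stage table for the lead peptide : receptor complex.

    These printed stage free energies (with half-split uncertainties) are
    inputs: stages 1 and 3-9 required microsecond-scale trajectories and
    stage 2's restraint parameters are not recorded, so none of them is
    recomputed here.
    """
    import io
    from importlib import resources

    import pandas as pd

    text = resources.files("cycbind").joinpath("data/stage_free_energies.tsv").read_text()
    df = pd.read_csv(io.StringIO(text), sep="\t")
    return [
        StageResult(stage_id=int(r.stage), free_energy=float(r.free_energy),
                    uncertainty=float(r.uncertainty), method=str(r.term))
        for r in df.itertuples(index=False)
    ]


def assemble_standard_free_energy(
    stages: Iterable[StageResult],
    thermo: ThermoState = ThermoState(),
) -> GeometricRouteResult:
    """Sum the nine stage free energies into dG0, with quadrature uncertainty.

    Stage uncertainties are treated as independent, so the total uncertainty
    is sqrt(sum u_i^2), reported at full precision (rounding happens only in
    display).
    """
    stages = list(stages)
    ids = sorted(s.stage_id for s in stages)
    if ids != list(range(1, 10)):
        raise ValueError(f"need exactly stages 1-9 once each, got ids {ids}")
    total = float(sum(s.free_energy for s in stages))
    unc = float(math.sqrt(sum(s.uncertainty**2 for s in stages)))
    kd = deltaG_to_kd(total, thermo)
    return GeometricRouteResult(stages=stages, total=total, total_uncertainty=unc, kd=kd)
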