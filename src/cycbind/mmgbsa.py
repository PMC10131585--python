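"""Single-trajectory MM-GBSA rescoring.

The binding score differences molecular-mechanics and implicit-solvent terms
between the complex and its separated parts, with the parts excised
unchanged from the complex frame so every bonded term cancels exactly:

    dG = dE_coulomb + dE_LJ + dG_GB + dG_SASA

The polar solvation term uses the OBC model II generalized Born variant
(Hawkins-Cramer-Truhlar pairwise descreening with tanh rescaling,
alpha/beta/gamma = 1.0/0.8/4.85, Born offset 0.09 A) with solvent
dielectric 78.5; the nonpolar term is surface tension (0.00542
kcal mol^-1 A^-2) times the Shrake-Rupley solvent-accessible surface area.
No conformational-entropy term is included: the score is a screening
statistic, not a rigorous binding free energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from cycbind.geometry import receptor_frame_rmsd
from cycbind.structure import ParamStructure
from cycbind.thermo import COULOMB_CONSTANT
from cycbind.trajectory import Trajectory


@dataclass(frozen=True)
class GBParameters:
    solvent_dielectric: float = 78.5
    solute_dielectric: float = 1.0
    surface_tension: float = 0.00542  # kcal mol^-1 A^-2
    sasa_offset: float = 0.0
    probe_radius: float = 1.4
    born_offset: float = 0.09
    coulomb_constant: float = COULOMB_CONSTANT
    obc_alpha: float = 1.0
    obc_beta: float = 0.8
    obc_gamma: float = 4.85
    descreen_scale: float = 0.8  # uniform HCT descreening scale factor
    kappa: float = 0.0  # Debye-Hueckel screening, 1/A; 0 = salt-free GB

    def __post_init__(self):
        if self.solvent_dielectric < 1 or self.solute_dielectric < 1:
            raise ValueError("dielectrics must be >= 1")
        if self.surface_tension < 0 or self.probe_radius < 0:
            raise ValueError("surface_tension and probe_radius must be >= 0")


@dataclass
class EnergyBreakdown:
    e_coulomb: float
    e_lj: float
    g_gb: float
    g_sasa: float
    total: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        s = self.e_coulomb + self.e_lj + self.g_gb + self.g_sasa
        if self.total is None:
            self.total = s
        elif abs(self.total - s) > 1e-9:
            raise ValueError("total must equal the sum of components")


def _pair_distances(coord: np.ndarray) -> np.ndarray:
    diff = coord[:, None, :] - coord[None, :, :]
    return np.sqrt((diff**2).sum(-1))


def born_radii(structure: ParamStructure, params: GBParameters = GBParameters()) -> np.ndarray:
    """Effective Born radii by HCT pairwise descreening + OBC-II tanh rescaling.

    For an isolated atom the descreening integral vanishes and the effective
    radius reduces to the offset-reduced intrinsic radius.
    """
    r_int = np.asarray(structure.gb_radius, dtype=float)
    if np.any(r_int <= params.born_offset):
        bad = np.nonzero(r_int <= params.born_offset)[0]
        raise ValueError(
            f"intrinsic GB radii must exceed the Born offset {params.born_offset}; "
            f"offending atoms: {bad.tolist()}"
        )
    rho = r_int - params.born_offset
    n = r_int.size
    dist = _pair_distances(structure.coord)
    s_rho = params.descreen_scale * rho  # descreening radius of the neighbor

    integral = np.zeros(n)
    for i in range(n):
        r = dist[i]
        sk = s_rho
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        mask &= rho[i] < (r + sk)  # neighbor sphere not fully inside atom i
        if not mask.any():
            continue
        rm, skm = r[mask], sk[mask]
        lower = np.maximum(np.abs(rm - skm), rho[i])
        upper = rm + skm
        term = 0.5 * (
            1.0 / lower
            - 1.0 / upper
            + 0.25 * (rm - skm**2 / rm) * (1.0 / upper**2 - 1.0 / lower**2)
            + 0.5 / rm * np.log(lower / upper)
        )
        engulfed = rho[i] < (skm - rm)
        term = term + np.where(engulfed, 2.0 * (1.0 / rho[i] - 1.0 / lower), 0.0)
        integral[i] = term.sum()

    psi = integral * rho
    tanh_arg = params.obc_alpha * psi - params.obc_beta * psi**2 + params.obc_gamma * psi**3
    inv_a = 1.0 / rho - np.tanh(tanh_arg) / r_int
    if np.any(inv_a <= 0):
        raise ValueError("non-physical (negative) effective Born radius encountered")
    return 1.0 / inv_a


def gb_energy(
    structure: ParamStructure,
    radii: Optional[np.ndarray] = None,
    params: GBParameters = GBParameters(),
) -> float:
    """Still-style generalized Born polar solvation energy (kcal/mol).

    G = -1/2 * ke * (1/eps_in - 1/eps_solv) * sum_ij qi qj / f_GB with
    f_GB = sqrt(r^2 + ai aj exp(-r^2 / (4 ai aj))), including i = j self
    terms (f_GB(0) = ai).
    """
    q = np.asarray(structure.charge, dtype=float)
    if q.shape[0] != structure.n_atoms:
        raise ValueError("missing charges")
    if radii is None:
        radii = born_radii(structure, params)
    a = np.asarray(radii, dtype=float)
    r2 = _pair_distances(structure.coord) ** 2
    aiaj = a[:, None] * a[None, :]
    f = np.sqrt(r2 + aiaj * np.exp(-r2 / (4.0 * aiaj)))
    prefac = -0.5 * params.coulomb_constant * (
        1.0 / params.solute_dielectric - 1.0 / params.solvent_dielectric
    )
    qq = q[:, None] * q[None, :]
    if params.kappa > 0:
        # Debye-Hueckel screened variant; kappa = 0 reproduces plain GB
        screen = np.exp(-params.kappa * f) / params.solvent_dielectric
        prefac_mat = -0.5 * params.coulomb_constant * (
            1.0 / params.solute_dielectric - screen
        )
        return float((prefac_mat * qq / f).sum())
    return float(prefac * (qq / f).sum())


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sasa(
    structure: ParamStructure,
    params: GBParameters = GBParameters(),
    n_points: int = 960,
):
    """Shrake-Rupley solvent-accessible surface area.

    Returns (per_atom, total) in A^2. Each atom's sphere has radius
    gb_radius + probe_radius; the point set is a fixed golden spiral, so the
    estimate is deterministic for a given ``n_points``.
    """
    if n_points < 32:
        raise ValueError("n_points < 32 is below the accuracy floor")
    radii = np.asarray(structure.gb_radius, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("SASA needs positive radii")
    ext = radii + params.probe_radius
    coord = structure.coord
    n = coord.shape[0]
    unit = _sphere_points(n_points)
    dist = _pair_distances(coord)
    per_atom = np.zeros(n)
    for i in range(n):
        neighbors = np.nonzero((dist[i] < ext[i] + ext) & (np.arange(n) != i))[0]
        pts = coord[i] + ext[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = ((pts - coord[j]) ** 2).sum(axis=1)
            exposed &= d2 > ext[j] ** 2
        per_atom[i] = 4.0 * np.pi * ext[i] ** 2 * exposed.mean()
    return per_atom, float(per_atom.sum())


def sasa_energy(structure: ParamStructure, params: GBParameters = GBParameters(),
                n_points: int = 960) -> float:
    _, total = sasa(structure, params, n_points)
    return params.surface_tension * total + params.sasa_offset


def _cross_coulomb_lj(structure: ParamStructure, mask_a, mask_b, params: GBParameters):
    ca, cb = structure.coord[mask_a], structure.coord[mask_b]
    d = np.sqrt(((ca[:, None, :] - cb[None, :, :]) ** 2).sum(-1))
    qa, qb = structure.charge[mask_a], structure.charge[mask_b]
    e_coul = params.coulomb_constant / params.solute_dielectric * (
        (qa[:, None] * qb[None, :]) / d
    ).sum()
    eps = np.sqrt(structure.lj_eps[mask_a][:, None] * structure.lj_eps[mask_b][None, :])
    rmin = structure.lj_rmin_half[mask_a][:, None] + structure.lj_rmin_half[mask_b][None, :]
    ratio6 = (rmin / d) ** 6
    e_lj = (eps * (ratio6**2 - 2.0 * ratio6)).sum()
    return float(e_coul), float(e_lj)


def mmgbsa_score(
    complex_frame: ParamStructure,
    receptor_mask: np.ndarray,
    ligand_mask: np.ndarray,
    params: GBParameters = GBParameters(),
    n_points: int = 960,
) -> EnergyBreakdown:
    """Single-trajectory MM-GBSA binding score for one frame.

    Receptor and ligand geometries are excised unchanged from the complex
    frame, so intra-part terms cancel and only the inter-part Coulomb/LJ
    interaction plus the GB and SASA desolvation differences remain.
    """
    receptor_mask = np.asarray(receptor_mask, dtype=bool)
    ligand_mask = np.asarray(ligand_mask, dtype=bool)
    if receptor_mask.shape != (complex_frame.n_atoms,) or ligand_mask.shape != (complex_frame.n_atoms,):
        raise ValueError("masks must have one entry per atom")
    if np.any(receptor_mask & ligand_mask):
        raise ValueError("receptor and ligand masks overlap")
    if not np.all(receptor_mask | ligand_mask):
        raise ValueError("masks must partition the atom set")

    receptor = complex_frame.subset(receptor_mask)
    ligand = complex_frame.subset(ligand_mask)

    e_coul, e_lj = _cross_coulomb_lj(complex_frame, receptor_mask, ligand_mask, params)
    g_gb = (
        gb_energy(complex_frame, params=params)
        - gb_energy(receptor, params=params)
        - gb_energy(ligand, params=params)
    )
    g_sasa = (
        sasa_energy(complex_frame, params, n_points)
        - sasa_energy(receptor, params, n_points)
        - sasa_energy(ligand, params, n_points)
    )
    return EnergyBreakdown(e_coulomb=e_coul, e_lj=e_lj, g_gb=g_gb, g_sasa=g_sasa)


@dataclass
class ScreenResult:
    """Per-frame MM-GBSA screen over the bound portion of a trajectory."""

    per_frame: List[EnergyBreakdown]
    mean: float
    sem: float
    time_bound: float
    bound_mask: np.ndarray

    @property
    def n_bound(self) -> int:
        return int(np.asarray(self.bound_mask).sum())


def screen_trajectory(
    traj: Trajectory,
    topology: ParamStructure,
    receptor_mask: np.ndarray,
    ligand_mask: np.ndarray,
    params: GBParameters = GBParameters(),
    rmsd_stop: float = 25.0,
    n_points: int = 960,
) -> ScreenResult:
    """Screen a trajectory: MM-GBSA over frames before the ligand dissociates.

    A frame is bound while the ligand's CA-atom displacement (receptor-frame
    aligned, no ligand fitting) stays at or below ``rmsd_stop`` (25 A
    default); all frames from the first exceedance on are discarded. The
    mean and SEM of the per-frame totals are taken over bound frames only,
    treating frames as independent.
    """
    traj.check_congruent(topology)
    receptor_mask = np.asarray(receptor_mask, dtype=bool)
    ligand_mask = np.asarray(ligand_mask, dtype=bool)
    ca_sel = ligand_mask & (topology.name == "CA")
    if not ca_sel.any():
        ca_sel = ligand_mask
    reference = traj.frames[0]
    n_frames = len(traj)
    bound_mask = np.zeros(n_frames, dtype=bool)
    for i, frame in enumerate(traj.frames):
        disp = receptor_frame_rmsd(reference, frame, receptor_mask, ca_sel)
        if disp > rmsd_stop:
            break
        bound_mask[i] = True

    per_frame: List[EnergyBreakdown] = []
    for i in np.nonzero(bound_mask)[0]:
        per_frame.append(
            mmgbsa_score(topology.with_coord(traj.frames[i]), receptor_mask,
                         ligand_mask, params, n_points)
        )
    time_bound = bound_mask.sum() * traj.frame_interval
    if per_frame:
        totals = np.array([b.total for b in per_frame])
        mean = float(totals.mean())
        sem = float(totals.std(ddof=1) / np.sqrt(totals.size)) if totals.size > 1 else 0.0
    else:
        mean, sem = float("nan"), float("nan")
    return ScreenResult(per_frame=per_frame, mean=mean, sem=sem,
                        time_bound=float(time_bound), bound_mask=bound_mask)
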