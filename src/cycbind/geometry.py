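"""Geometric analyses: Kabsch superposition and RMSD, interface residues,
contact distance series and occupancies.

The screening RMSD convention: the trajectory frame is first aligned on the
receptor atoms (the receptor defines the lab frame) and the peptide's
displacement is then measured without fitting the peptide onto itself, so
rigid drift of the peptide away from the site counts in full. Both fitted
and unfitted RMSD modes are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from cycbind.structure import ParamStructure


@dataclass
class RigidTransform:
    """x -> rotation @ (x - mobile_centroid) + ref_centroid"""

    rotation: np.ndarray
    mobile_centroid: np.ndarray
    ref_centroid: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords) - self.mobile_centroid) @ self.rotation.T + self.ref_centroid


def _kabsch(reference: np.ndarray, mobile: np.ndarray) -> RigidTransform:
    ref_c = reference.mean(axis=0)
    mob_c = mobile.mean(axis=0)
    h = (mobile - mob_c).T @ (reference - ref_c)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])  # no reflections
    rot = vt.T @ diag @ u.T
    return RigidTransform(rotation=rot, mobile_centroid=mob_c, ref_centroid=ref_c)


def superpose_and_rmsd(
    reference: np.ndarray,
    mobile: np.ndarray,
    selection: Optional[np.ndarray] = None,
    fit: bool = True,
) -> Tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch, proper rotation only).

    With ``fit=True`` the transform is computed on the selection and the
    RMSD is evaluated after applying it; with ``fit=False`` the identity
    transform is returned and the RMSD is computed in the fixed frame.
    """
    reference = np.asarray(reference, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if reference.shape != mobile.shape:
        raise ValueError(f"coordinate shape mismatch: {reference.shape} vs {mobile.shape}")
    if selection is not None:
        selection = np.asarray(selection, dtype=bool)
        ref_sel, mob_sel = reference[selection], mobile[selection]
    else:
        ref_sel, mob_sel = reference, mobile
    if fit:
        if ref_sel.shape[0] < 3:
            raise ValueError("fitting needs >= 3 atoms in the selection")
        transform = _kabsch(ref_sel, mob_sel)
        moved = transform.apply(mob_sel)
    else:
        transform = RigidTransform(np.eye(3), np.zeros(3), np.zeros(3))
        moved = mob_sel
    rmsd = float(np.sqrt(((moved - ref_sel) ** 2).sum(axis=1).mean()))
    return transform, rmsd


def receptor_frame_rmsd(
    reference: np.ndarray,
    frame: np.ndarray,
    receptor_sel: np.ndarray,
    ligand_sel: np.ndarray,
) -> float:
    """Ligand displacement after aligning the frame on the receptor selection."""
    transform, _ = superpose_and_rmsd(reference, frame, selection=receptor_sel, fit=True)
    moved = transform.apply(np.asarray(frame, dtype=float))
    lig = np.asarray(ligand_sel, dtype=bool)
    d = moved[lig] - np.asarray(reference, dtype=float)[lig]
    return float(np.sqrt((d**2).sum(axis=1).mean()))


def interface_residues(
    structure: ParamStructure,
    chain_a: str,
    chain_b: str,
    cutoff: float = 5.0,
) -> Dict[str, List[int]]:
    """Residues of each chain with any atom within ``cutoff`` of the other chain.

    The definition is symmetric; the default 5 A cutoff is the conventional
    definition of an X-ray interface footprint.
    """
    mask_a = structure.chain_mask(chain_a)
    mask_b = structure.chain_mask(chain_b)
    ca, cb = structure.coord[mask_a], structure.coord[mask_b]
    if ca.shape[0] == 0 or cb.shape[0] == 0:
        raise ValueError("both chains must be non-empty")
    d = np.sqrt(((ca[:, None, :] - cb[None, :, :]) ** 2).sum(-1))
    close = d <= cutoff
    res_a = structure.res_id[mask_a]
    res_b = structure.res_id[mask_b]
    hit_a = sorted(set(res_a[close.any(axis=1)].tolist()))
    hit_b = sorted(set(res_b[close.any(axis=0)].tolist()))
    return {chain_a: hit_a, chain_b: hit_b}


@dataclass
class ContactSeries:
    """Per-frame minimum distance between two atom groups."""

    times: np.ndarray
    distances: np.ndarray
    threshold: float = 2.2

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.times.shape != self.distances.shape:
            raise ValueError("times and distances must have equal length")
        if np.any(self.distances < 0):
            raise ValueError("distances must be >= 0")

    def __len__(self) -> int:
        return self.times.size


def contact_distance_series(
    frames: Sequence[np.ndarray],
    group_a: np.ndarray,
    group_b: np.ndarray,
    frame_interval: float = 0.2,
) -> ContactSeries:
    """Minimum cross-pair distance between two atom groups per frame.

    ``frame_interval`` is ns per frame (0.2 ns = the 200 ps trajectory
    output stride used for screening).
    """
    ga = np.asarray(group_a)
    gb = np.asarray(group_b)
    if ga.dtype == bool:
        ga = np.nonzero(ga)[0]
    if gb.dtype == bool:
        gb = np.nonzero(gb)[0]
    if ga.size == 0 or gb.size == 0:
        raise ValueError("atom groups must be non-empty")
    mins = []
    for f in frames:
        f = np.asarray(f, dtype=float)
        d = np.sqrt(((f[ga][:, None, :] - f[gb][None, :, :]) ** 2).sum(-1))
        mins.append(d.min())
    times = frame_interval * np.arange(len(mins))
    return ContactSeries(times=times, distances=np.asarray(mins))


def contact_occupancy(
    series: ContactSeries,
    threshold: float,
    bound_mask: Optional[np.ndarray] = None,
) -> float:
    """Fraction of (masked) frames with minimum distance below ``threshold``.

    This is the number a statement like "the salt bridge was present
    (minimum distance < 2.2 A) 91% of the time while bound" reports.
    """
    if bound_mask is None:
        bound_mask = np.ones(len(series), dtype=bool)
    bound_mask = np.asarray(bound_mask, dtype=bool)
    if bound_mask.shape != series.distances.shape:
        raise ValueError("mask length must equal series length")
    if not bound_mask.any():
        raise ValueError("mask selects no frames")
    sel = series.distances[bound_mask]
    return float((sel < threshold).mean())
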