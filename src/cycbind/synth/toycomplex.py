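"""Small charged two-chain structures with a designable interface.

The construction is deterministic given the seed and places atoms so that
the number of inter-chain atom pairs within 5 A equals ``interface_pairs``
exactly: each requested pair is realized as an isolated "bridge" (one
receptor atom, one ligand atom ~4.5 A apart, bridges >= 12 A from each
other), while the remaining atoms form bulk clusters kept far from the
interface. Every structure satisfies a 2.4 A minimum interatomic distance
and zero net charge per chain.
"""

from __future__ import annotations

import numpy as np

from cycbind.structure import ParamStructure

_CONTACT_CUTOFF = 5.0
_MIN_SEP = 2.4


def _bulk_positions(n: int, origin: np.ndarray, direction: float, rng) -> np.ndarray:
    """Jittered cubic-grid cluster growing away from the interface plane."""
    if n == 0:
        return np.zeros((0, 3))
    side = int(np.ceil(n ** (1.0 / 3.0)))
    pts = []
    for ix in range(side):
        for iy in range(side):
            for iz in range(side):
                if len(pts) >= n:
                    break
                base = origin + np.array([direction * 3.0 * ix, 3.0 * iy, 3.0 * iz])
                pts.append(base + rng.uniform(-0.25, 0.25, size=3))
    return np.asarray(pts[:n])


def build_toy_complex(
    n_receptor_atoms: int,
    n_ligand_atoms: int,
    interface_pairs: int,
    seed: int = 0,
) -> ParamStructure:
    """Two-chain toy structure (receptor chain 'A', ligand chain 'B')."""
    if n_receptor_atoms < 1 or n_ligand_atoms < 1:
        raise ValueError("atom counts must be >= 1")
    if interface_pairs < 0:
        raise ValueError("interface_pairs must be >= 0")
    if interface_pairs > min(n_receptor_atoms, n_ligand_atoms):
        raise ValueError(
            f"cannot pack {interface_pairs} interface pairs with "
            f"{n_receptor_atoms} receptor and {n_ligand_atoms} ligand atoms"
        )
    rng = np.random.default_rng(seed)

    rec_pts, lig_pts = [], []
    for p in range(interface_pairs):
        r = np.array([0.0, 12.0 * p, 0.0]) + rng.uniform(-0.3, 0.3, size=3)
        offset = np.array([4.5, 0.0, 0.0]) + rng.uniform(-0.2, 0.2, size=3)
        rec_pts.append(r)
        lig_pts.append(r + offset)
    rec_bulk = _bulk_positions(n_receptor_atoms - interface_pairs,
                               np.array([-8.0, 0.0, 0.0]), -1.0, rng)
    lig_bulk = _bulk_positions(n_ligand_atoms - interface_pairs,
                               np.array([12.5, 0.0, 0.0]), +1.0, rng)
    rec = np.vstack([np.asarray(rec_pts).reshape(-1, 3), rec_bulk])
    lig = np.vstack([np.asarray(lig_pts).reshape(-1, 3), lig_bulk])
    coords = np.vstack([rec, lig])
    n = coords.shape[0]

    # verify the construction by exhaustive pair scan
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(n, k=1)
    if dist[iu].min() < _MIN_SEP:
        raise RuntimeError("toy complex packing violated the 2.4 A minimum separation")
    cross = dist[: rec.shape[0], rec.shape[0]:]
    n_contacts = int((cross < _CONTACT_CUTOFF).sum())
    if n_contacts != interface_pairs:
        raise RuntimeError(
            f"toy complex realized {n_contacts} interface pairs, wanted {interface_pairs}"
        )

    chain_id = np.array(["A"] * rec.shape[0] + ["B"] * lig.shape[0])
    charge = rng.normal(0.0, 0.25, size=n)
    for ch in ("A", "B"):
        m = chain_id == ch
        charge[m] -= charge[m].mean()  # exact zero net charge per chain
    gb_radius = rng.uniform(1.1, 2.1, size=n)
    lj_eps = rng.uniform(0.05, 0.2, size=n)
    lj_rmin_half = rng.uniform(1.3, 2.1, size=n)

    res_id = np.empty(n, dtype=int)
    name = np.empty(n, dtype="U4")
    for ch in ("A", "B"):
        idx = np.nonzero(chain_id == ch)[0]
        for k, i in enumerate(idx):
            res_id[i] = k // 4 + 1
            name[i] = f"X{k % 4}"
    return ParamStructure(
        serial=np.arange(1, n + 1), name=name,
        res_name=np.full(n, "TOY"), res_id=res_id, chain_id=chain_id,
        coord=coords, element=np.full(n, "C"), charge=charge,
        gb_radius=gb_radius, lj_eps=lj_eps, lj_rmin_half=lj_rmin_half,
        bonds=[], provenance=f"build_toy_complex(seed={seed}), net charge 0 per chain",
    )
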