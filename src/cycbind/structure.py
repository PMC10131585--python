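"""Parameterized structures: PDB I/O, per-atom force-field parameters, and
head-to-tail cyclic topology.

A :class:`ParamStructure` couples PDB-style atom records with the per-atom
parameters MM-GBSA needs (partial charge, intrinsic GB radius, Lennard-Jones
epsilon and rmin/2). Parameters come from a user-supplied table keyed on
(residue name, atom name); PDB parsing and writing go through biotite, with
explicit bonds carried in CONECT records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

PARAM_COLUMNS = ["resname", "atomname", "charge", "gb_radius", "lj_eps", "lj_rmin_half"]

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


class ParamTable:
    """(residue name, atom name) -> charge / GB radius / LJ parameters."""

    def __init__(self, entries: Optional[Dict[Tuple[str, str], Tuple[float, float, float, float]]] = None):
        self.entries = dict(entries or {})

    def add(self, resname: str, atomname: str, charge: float, gb_radius: float,
            lj_eps: float, lj_rmin_half: float) -> None:
        self.entries[(resname, atomname)] = (charge, gb_radius, lj_eps, lj_rmin_half)

    def lookup(self, resname: str, atomname: str):
        return self.entries.get((resname, atomname))

    @classmethod
    def from_tsv(cls, path) -> "ParamTable":
        df = pd.read_csv(path, sep="\t")
        missing = set(PARAM_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"parameter table missing columns: {sorted(missing)}")
        table = cls()
        for row in df.itertuples(index=False):
            table.add(str(row.resname), str(row.atomname), float(row.charge),
                      float(row.gb_radius), float(row.lj_eps), float(row.lj_rmin_half))
        return table

    def to_tsv(self, path) -> None:
        rows = [
            {"resname": rn, "atomname": an, "charge": c, "gb_radius": r,
             "lj_eps": e, "lj_rmin_half": h}
            for (rn, an), (c, r, e, h) in self.entries.items()
        ]
        pd.DataFrame(rows, columns=PARAM_COLUMNS).to_csv(path, sep="\t", index=False)


@dataclass
class ParamStructure:
    """Atoms with coordinates and MM-GBSA parameters, plus explicit bonds.

    ``bonds`` holds atom-index pairs, including any head-to-tail cyclization
    bond; (chain, residue number, atom name) triples must be unique.
    """

    serial: np.ndarray
    name: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    coord: np.ndarray
    element: np.ndarray
    charge: np.ndarray
    gb_radius: np.ndarray
    lj_eps: np.ndarray
    lj_rmin_half: np.ndarray
    bonds: List[Tuple[int, int]] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        n = len(self.name)
        self.serial = np.asarray(self.serial, dtype=int)
        self.name = np.asarray(self.name, dtype="U4")
        self.res_name = np.asarray(self.res_name, dtype="U4")
        self.res_id = np.asarray(self.res_id, dtype=int)
        self.chain_id = np.asarray(self.chain_id, dtype="U4")
        self.coord = np.asarray(self.coord, dtype=float).reshape(n, 3)
        self.element = np.asarray(self.element, dtype="U2")
        for attr in ("charge", "gb_radius", "lj_eps", "lj_rmin_half"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
            if getattr(self, attr).shape != (n,):
                raise ValueError(f"{attr} must have one value per atom")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("coordinates must be finite")
        keys = list(zip(self.chain_id, self.res_id, self.name))
        if len(set(keys)) != n:
            seen, dups = set(), set()
            for k in keys:
                (dups if k in seen else seen).add(k)
            raise ValueError(f"duplicate (chain, residue, atom name) records: {sorted(dups)}")
        self.bonds = [tuple(sorted((int(i), int(j)))) for i, j in self.bonds]
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) out of range for {n} atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.name)

    def chains(self) -> List[str]:
        out: List[str] = []
        for c in self.chain_id:
            if c not in out:
                out.append(c)
        return out

    def chain_mask(self, chain: str) -> np.ndarray:
        if chain not in self.chain_id:
            raise ValueError(f"unknown chain id {chain!r}; have {self.chains()}")
        return self.chain_id == chain

    def atom_index(self, chain: str, res_id: int, name: str) -> int:
        hit = np.nonzero((self.chain_id == chain) & (self.res_id == res_id) & (self.name == name))[0]
        if hit.size != 1:
            raise ValueError(f"atom ({chain}, {res_id}, {name}) not found")
        return int(hit[0])

    def subset(self, mask: np.ndarray) -> "ParamStructure":
        mask = np.asarray(mask, dtype=bool)
        idx_map = {old: new for new, old in enumerate(np.nonzero(mask)[0])}
        bonds = [
            (idx_map[i], idx_map[j]) for i, j in self.bonds if i in idx_map and j in idx_map
        ]
        return ParamStructure(
            serial=self.serial[mask], name=self.name[mask], res_name=self.res_name[mask],
            res_id=self.res_id[mask], chain_id=self.chain_id[mask], coord=self.coord[mask],
            element=self.element[mask], charge=self.charge[mask], gb_radius=self.gb_radius[mask],
            lj_eps=self.lj_eps[mask], lj_rmin_half=self.lj_rmin_half[mask],
            bonds=bonds, provenance=self.provenance,
        )

    def with_coord(self, coord: np.ndarray) -> "ParamStructure":
        return replace(self, coord=np.asarray(coord, dtype=float))

    def to_atom_array(self) -> struc.AtomArray:
        arr = struc.AtomArray(self.n_atoms)
        arr.coord = self.coord.astype(np.float32)
        arr.atom_name = self.name
        arr.res_name = self.res_name
        arr.res_id = self.res_id
        arr.chain_id = self.chain_id
        arr.element = self.element
        return arr


def _prevalidate_pdb(lines: Sequence[str]) -> None:
    for ln, line in enumerate(lines, start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                int(line[6:11])
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except (ValueError, IndexError):
                raise ValueError(f"malformed ATOM record at line {ln}: {line.rstrip()!r}")


def _parse_conect(lines: Sequence[str], serial_to_index: Dict[int, int]) -> List[Tuple[int, int]]:
    bonds = set()
    for line in lines:
        if not line.startswith("CONECT"):
            continue
        fields = [line[i:i + 5] for i in range(6, len(line.rstrip()), 5)]
        serials = [int(f) for f in fields if f.strip()]
        if not serials:
            continue
        a = serials[0]
        for b in serials[1:]:
            if a in serial_to_index and b in serial_to_index:
                bonds.add(tuple(sorted((serial_to_index[a], serial_to_index[b]))))
    return sorted(bonds)


def read_structure(path, param_table: ParamTable) -> ParamStructure:
    """Read a PDB file and attach per-atom parameters from ``param_table``.

    Raises if any (residue name, atom name) pair has no table entry, listing
    the offending atoms.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    _prevalidate_pdb(lines)
    pdb_file = pdbio.PDBFile.read(str(path))
    arr = pdb_file.get_structure(model=1)
    n = arr.array_length()

    missing = []
    params = np.zeros((n, 4))
    for i in range(n):
        entry = param_table.lookup(str(arr.res_name[i]), str(arr.atom_name[i]))
        if entry is None:
            missing.append((str(arr.chain_id[i]), int(arr.res_id[i]),
                            str(arr.res_name[i]), str(arr.atom_name[i])))
        else:
            params[i] = entry
    if missing:
        raise ValueError(f"no parameters for atoms: {missing}")

    serial = np.arange(1, n + 1)
    serial_to_index = {int(s): i for i, s in enumerate(serial)}
    bonds = _parse_conect(lines, serial_to_index)
    return ParamStructure(
        serial=serial, name=arr.atom_name, res_name=arr.res_name, res_id=arr.res_id,
        chain_id=arr.chain_id, coord=np.asarray(arr.coord, dtype=float),
        element=arr.element, charge=params[:, 0], gb_radius=params[:, 1],
        lj_eps=params[:, 2], lj_rmin_half=params[:, 3], bonds=bonds,
        provenance=f"read from {path.name}",
    )


def write_structure(structure: ParamStructure, path) -> None:
    """Write a PDB file with CONECT records for the structure's bonds."""
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(structure.to_atom_array())
    lines = [ln for ln in pdb_file.lines if not ln.startswith("END")]
    for i, j in structure.bonds:
        lines.append(f"CONECT{i + 1:>5d}{j + 1:>5d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def param_table_for(structure: ParamStructure) -> ParamTable:
    """Parameter table covering every (residue, atom) of ``structure``."""
    table = ParamTable()
    for i in range(structure.n_atoms):
        table.add(str(structure.res_name[i]), str(structure.name[i]),
                  float(structure.charge[i]), float(structure.gb_radius[i]),
                  float(structure.lj_eps[i]), float(structure.lj_rmin_half[i]))
    return table


def cyclize_head_to_tail(structure: ParamStructure, chain: str) -> ParamStructure:
    """Add the trans head-to-tail peptide bond closing ``chain``.

    Joins the first residue's backbone N to the last residue's backbone C.
    Idempotent: re-cyclizing an already cyclic chain changes nothing. The
    chain must have at least 3 residues (a shorter ring is sterically
    impossible for an amide backbone).
    """
    mask = structure.chain_mask(chain)
    res_ids = sorted(set(structure.res_id[mask].tolist()))
    if len(res_ids) < 3:
        raise ValueError(
            f"chain {chain!r} has {len(res_ids)} residues; head-to-tail "
            "cyclization needs >= 3"
        )
    first, last = res_ids[0], res_ids[-1]
    try:
        i_n = structure.atom_index(chain, first, "N")
    except ValueError:
        raise ValueError(f"residue {first} of chain {chain!r} lacks a backbone N atom")
    try:
        i_c = structure.atom_index(chain, last, "C")
    except ValueError:
        raise ValueError(f"residue {last} of chain {chain!r} lacks a backbone C atom")
    bond = tuple(sorted((i_n, i_c)))
    if bond in structure.bonds:
        return structure
    return replace(structure, bonds=structure.bonds + [bond])


def build_extended_peptide(sequence: str, chain: str = "P") -> ParamStructure:
    """Backbone-only (N, CA, C, O) peptide laid out along x, one residue per
    3.8 A. A geometric scaffold for topology and bookkeeping tests, not a
    physical conformation.
    """
    sequence = sequence.strip().upper()
    bad = [c for c in sequence if c not in _AA3]
    if bad:
        raise ValueError(f"non-canonical residues in sequence: {bad}")
    names, resn, resi, coords, elements = [], [], [], [], []
    for i, aa in enumerate(sequence):
        x0 = 3.8 * i
        for nm, el, off in (
            ("N", "N", (0.0, 0.0, 0.0)),
            ("CA", "C", (1.2, 0.8, 0.0)),
            ("C", "C", (2.4, 0.0, 0.0)),
            ("O", "O", (2.4, -1.23, 0.0)),
        ):
            names.append(nm)
            elements.append(el)
            resn.append(_AA3[aa])
            resi.append(i + 1)
            coords.append((x0 + off[0], off[1], off[2]))
    n = len(names)
    bonds = []
    for i in range(len(sequence)):
        base = 4 * i
        bonds += [(base, base + 1), (base + 1, base + 2), (base + 2, base + 3)]
        if i + 1 < len(sequence):
            bonds.append((base + 2, base + 4))  # C(i) - N(i+1)
    return ParamStructure(
        serial=np.arange(1, n + 1), name=names, res_name=resn, res_id=resi,
        chain_id=[chain] * n, coord=np.asarray(coords), element=elements,
        charge=np.zeros(n), gb_radius=np.full(n, 1.5), lj_eps=np.full(n, 0.1),
        lj_rmin_half=np.full(n, 1.8), bonds=bonds,
        provenance=f"extended backbone for {sequence}",
    )
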