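"""PDB structure I/O, receptor/ligand designation and rigid-body decoy poses.

Structures are plain hierarchical records (atoms grouped into residues and
chains) with Cartesian coordinates in Angstrom throughout.  Input structures
are assumed to be already protonated; a validation pass warns when fewer than
a quarter of the atoms are hydrogens.

Decoy poses can be supplied either as full complex PDB files or as a table of
rigid-body transforms (TSV, one row per decoy: a row-major 3x3 rotation and a
translation in Angstrom) applied to the ligand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

import gemmi

__all__ = [
    "Atom",
    "ProteinStructure",
    "ComplexPartition",
    "RigidTransform",
    "DecoyTransform",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "assign_partners",
    "apply_transform",
    "read_decoy_transforms",
    "write_decoy_transforms",
]

_WATERS = {"HOH", "WAT", "DOD"}


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted as a protein structure."""


@dataclass(frozen=True)
class Atom:
    """One atom record: identity plus Cartesian coordinates in Angstrom."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    icode: str
    chain_id: str
    coords: np.ndarray

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)


@dataclass
class ProteinStructure:
    """Ordered atom list with residue/chain bookkeeping.

    Residue atom sets are contiguous in the atom order; ``residues`` yields
    ``(residue_id, res_name, atom index slice)`` in order of appearance.
    """

    atoms: list[Atom]
    _coords: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("structure must contain at least one atom")

    @property
    def coords(self) -> np.ndarray:
        if self._coords is None:
            self._coords = np.array([a.coords for a in self.atoms], dtype=float)
        return self._coords

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    @property
    def residues(self) -> list[tuple[tuple[str, int, str], str, slice]]:
        out = []
        start = 0
        for i in range(1, len(self.atoms) + 1):
            if i == len(self.atoms) or self.atoms[i].residue_id != self.atoms[start].residue_id:
                a = self.atoms[start]
                out.append((a.residue_id, a.res_name, slice(start, i)))
                start = i
        return out

    @property
    def n_res(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def with_coords(self, coords: np.ndarray) -> "ProteinStructure":
        """Same topology, new coordinates (shape ``(n_atoms, 3)``)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coords shape {coords.shape} != ({len(self.atoms)}, 3)")
        atoms = [replace(a, coords=coords[k].copy()) for k, a in enumerate(self.atoms)]
        return ProteinStructure(atoms, _coords=coords.copy())

    def hydrogen_fraction(self) -> float:
        n_h = sum(1 for a in self.atoms if a.element == "H")
        return n_h / len(self.atoms)


@dataclass(frozen=True)
class ComplexPartition:
    """A binary complex split into receptor (larger) and ligand (smaller)."""

    receptor: ProteinStructure
    ligand: ProteinStructure

    def __post_init__(self):
        rc = set(self.receptor.chains)
        lc = set(self.ligand.chains)
        if rc & lc:
            raise ValueError(f"receptor and ligand share chain ids: {sorted(rc & lc)}")

    @property
    def combined(self) -> ProteinStructure:
        return ProteinStructure(list(self.receptor.atoms) + list(self.ligand.atoms))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        _check_rotation(R, tol=1e-8)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass(frozen=True)
class DecoyTransform:
    decoy_id: str
    transform: RigidTransform


def _check_rotation(R: np.ndarray, tol: float) -> None:
    if not np.all(np.isfinite(R)):
        raise ValueError("rotation matrix contains non-finite entries")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise ValueError("rotation matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("rotation matrix is a reflection (det < 0)")


def read_pdb(path, model_policy: str = "first") -> ProteinStructure:
    """Read ATOM records of a PDB file into a :class:`ProteinStructure`.

    HETATM records, waters and alternate locations other than 'A'/blank are
    dropped.  ``model_policy`` selects the first model of a multi-model file
    (``"first"``) or refuses it (``"error"``).
    """
    if model_policy not in ("first", "error"):
        raise ValueError(f"unknown model_policy {model_policy!r}")
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise PDBParseError(f"{path}: no ATOM records")
    if len(st) > 1 and model_policy == "error":
        raise PDBParseError(f"{path}: {len(st)} models present (model_policy='error')")
    model = st[0]

    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            if residue.het_flag != "A" or residue.name in _WATERS:
                continue
            for atom in residue:
                if atom.altloc not in ("", "\0", "A"):
                    continue
                el = atom.element.name.upper() if atom.element else ""
                if not el:
                    el = atom.name.strip()[:1]
                atoms.append(
                    Atom(
                        serial=atom.serial,
                        name=atom.name.strip(),
                        element=el,
                        res_name=residue.name.strip(),
                        res_seq=residue.seqid.num,
                        icode=(residue.seqid.icode or "").strip(),
                        chain_id=chain.name.strip() or " ",
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    )
                )
    if not atoms:
        raise PDBParseError(f"{path}: no ATOM records")
    s = ProteinStructure(atoms)
    if s.hydrogen_fraction() < 0.25:
        warnings.warn(
            f"{path}: only {100 * s.hydrogen_fraction():.0f}% of atoms are hydrogens; "
            "structures are expected to be protonated",
            stacklevel=2,
        )
    return s


def write_pdb(s: ProteinStructure, path) -> None:
    """Write a structure as fixed-column ATOM records (one model)."""
    st = gemmi.Structure()
    model = gemmi.Model(1)
    for chain_id in s.chains:
        chain = gemmi.Chain(chain_id)
        for res_id, res_name, sl in s.residues:
            if res_id[0] != chain_id:
                continue
            residue = gemmi.Residue()
            residue.name = res_name
            residue.seqid = gemmi.SeqId(res_id[1], res_id[2] or " ")
            residue.het_flag = "A"
            for a in s.atoms[sl]:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.serial = a.serial
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.coords)
                residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def assign_partners(
    a: ProteinStructure, b: ProteinStructure, override: str | None = None
) -> ComplexPartition:
    """Designate receptor and ligand: the smaller protein is the ligand.

    Ties on residue count are broken by atom count, then by input order
    (first argument becomes the receptor).  ``override`` forces the choice
    (``"a-receptor"`` or ``"b-receptor"``).
    """
    if override == "a-receptor":
        return ComplexPartition(a, b)
    if override == "b-receptor":
        return ComplexPartition(b, a)
    if override is not None:
        raise ValueError(f"unknown override {override!r}")
    key_a = (a.n_res, a.n_atoms)
    key_b = (b.n_res, b.n_atoms)
    if key_b > key_a:
        return ComplexPartition(b, a)
    return ComplexPartition(a, b)


def apply_transform(s: ProteinStructure, t: RigidTransform) -> ProteinStructure:
    """Map every coordinate x -> R x + t; topology unchanged."""
    return s.with_coords(t.apply(s.coords))


_TRANSFORM_COLS = [
    "decoy_id",
    "r11", "r12", "r13", "r21", "r22", "r23", "r31", "r32", "r33",
    "t1", "t2", "t3",
]


def read_decoy_transforms(path) -> list[DecoyTransform]:
    """Read the decoy transform table (TSV with header, row-major rotation)."""
    df = pd.read_csv(path, sep="\t", dtype={"decoy_id": str})
    missing = [c for c in _TRANSFORM_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        R = np.array([getattr(row, c) for c in _TRANSFORM_COLS[1:10]]).reshape(3, 3)
        t = np.array([getattr(row, c) for c in _TRANSFORM_COLS[10:]])
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-4) or np.linalg.det(R) < 0:
            raise ValueError(f"{path}: decoy {row.decoy_id!r}: rotation not a proper rotation")
        out.append(DecoyTransform(str(row.decoy_id), RigidTransform(_project_so3(R), t)))
    return out


def write_decoy_transforms(decoys: list[DecoyTransform], path) -> None:
    rows = []
    for d in decoys:
        rows.append(
            [d.decoy_id, *d.transform.rotation.ravel(), *d.transform.translation]
        )
    pd.DataFrame(rows, columns=_TRANSFORM_COLS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def _project_so3(R: np.ndarray) -> np.ndarray:
    """Nearest proper rotation (cleans up TSV round-off before validation)."""
    U, _, Vt = np.linalg.svd(R)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt
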