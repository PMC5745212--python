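"""Per-atom parameter assignment: 21 SASA atom types, radii, LJ terms, charges.

Every atom of the 20 standard amino acids is mapped to exactly one of 21
solvation atom types.  The classification is evaluated from the packaged
residue-topology table (bond lists per residue), never from 3-D geometry, so
typing is deterministic and conformation independent.  The environment
predicates follow the published footnote definitions: sp3 vs sp2 carbons,
carbons attached to exactly one oxygen vs two, ring membership, and the
identity of the heavy atom a hydrogen is bonded to.

The type catalogue (element / environment):

====  =========================================================
 id   definition
====  =========================================================
  1   sp3 C bonded only to C/H (aliphatic)
  2   sp3 C with at least one N/O/S neighbour
  3   ring sp2 C bonded only to C/H
  4   ring sp2 C with an N/O/S neighbour
  5   sp2 C attached to exactly one O (carbonyl/amide carbon)
  6   sp2 C attached to two O (carboxylate carbon)
  7   acyclic sp2 C with no O (guanidinium carbon)
  8   backbone amide N
  9   side-chain amide N
 10   aromatic ring N
 11   sp3 ammonium N (Lys NZ, N-terminus)
 12   guanidinium N
 13   carbonyl O
 14   carboxylate O
 15   hydroxyl O
 16   thiol S
 17   thioether S
 18   H on sp3 C
 19   H on sp2/aromatic C
 20   H on N
 21   H on O or S
====  =========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._templates import (
    CTERM_OXT_CHARGE,
    LJ_CLASSES,
    NTERM_H_CHARGE,
    RESIDUE_ALIASES,
    RESIDUE_TEMPLATES,
    STANDARD_RESIDUES,
)
from .structures_io import ProteinStructure

__all__ = [
    "N_SASA_TYPES",
    "FFAtomParam",
    "SasaRadiusTable",
    "SolvationWeights",
    "SasaTypeRules",
    "FFParamTable",
    "ParameterError",
    "load_parameter_set",
    "assign_sasa_types",
    "assign_ff_params",
]

N_SASA_TYPES = 21

# Bondi van der Waals radii (Angstrom) for the five protein elements.
DEFAULT_SASA_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

# Default per-type surface coefficients (kcal/mol/A^2): calibration defaults,
# meant to be refit against a polar-solvation target set via fit_weights.
# Polar/charged surface lowers (more negative) the polar solvation energy.
DEFAULT_TYPE_WEIGHTS = np.array([
    0.005, -0.010, 0.005, -0.020, -0.060, -0.080, -0.080,
    -0.120, -0.130, -0.110, -0.350, -0.250,
    -0.160, -0.450, -0.140,
    -0.030, -0.020,
    0.002, 0.002, -0.060, -0.080,
])
DEFAULT_W0 = -10.51       # kcal/mol per residue
DEFAULT_CONSTANT = 59.78  # kcal/mol


class ParameterError(KeyError):
    """Raised when an atom cannot be parameterized."""


@dataclass(frozen=True)
class FFAtomParam:
    """LJ half-minimum distance (A), well depth (kcal/mol) and charge (e)."""

    rmin_half: float
    epsilon: float
    charge: float

    def __post_init__(self):
        if not self.rmin_half > 0:
            raise ValueError("rmin_half must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if abs(self.charge) >= 2:
            raise ValueError("|charge| must be < 2 e")


@dataclass(frozen=True)
class SasaRadiusTable:
    radii: dict[str, float]

    def __post_init__(self):
        for el in ("H", "C", "N", "O", "S"):
            if el not in self.radii:
                raise ParameterError(f"missing SASA radius for element {el}")
        for el, r in self.radii.items():
            if not 0.5 < r < 3.0:
                raise ValueError(f"radius for {el} out of range: {r}")

    def __getitem__(self, element: str) -> float:
        try:
            return self.radii[element]
        except KeyError:
            raise ParameterError(f"no SASA radius for element {element!r}") from None


@dataclass(frozen=True)
class SolvationWeights:
    """Coefficients of the linear SASA polar-solvation model."""

    w0: float
    w: np.ndarray
    constant: float

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.shape != (N_SASA_TYPES,):
            raise ValueError(f"need {N_SASA_TYPES} per-type weights, got {w.shape}")
        if not (np.isfinite(w).all() and np.isfinite(self.w0) and np.isfinite(self.constant)):
            raise ValueError("solvation weights must be finite")


# ----------------------------------------------------------------------------
# Template expansion: internal + terminal residue variants
# ----------------------------------------------------------------------------

def _variant_template(res_name: str, nterm: bool, cterm: bool) -> dict:
    """Atom table and bonds for a residue variant, charges renormalized
    exactly onto the variant's formal charge."""
    base = RESIDUE_TEMPLATES[res_name]
    atoms = {name: [el, cls, q] for name, el, cls, q in base["atoms"]}
    bonds = list(base["bonds"])
    target = float(base["formal_charge"])
    if nterm:
        target += 1.0
        atoms.pop("H", None)
        bonds = [b for b in bonds if "H" not in b]
        atoms["N"][1] = "N3"
        h_names = ("H2", "H3") if res_name == "PRO" else ("H1", "H2", "H3")
        for h in h_names:
            atoms[h] = ["H", "H", NTERM_H_CHARGE]
            bonds.append(("N", h))
    if cterm:
        target -= 1.0
        atoms["O"][1] = "O2"
        atoms["OXT"] = ["O", "O2", CTERM_OXT_CHARGE]
        bonds.append(("C", "OXT"))
    adjust = "CB" if "CB" in atoms else "CA"
    residual = target - sum(v[2] for v in atoms.values())
    atoms[adjust][2] += residual
    return {"atoms": atoms, "bonds": bonds, "formal_charge": target}


def _type_variant(tpl: dict) -> dict[str, int]:
    """Map every atom of a residue variant to its type id via the topology."""
    atoms, bonds = tpl["atoms"], tpl["bonds"]
    g = nx.Graph(bonds)
    g.add_nodes_from(atoms)
    ring_atoms = set().union(*nx.cycle_basis(g), set())

    def el(n):
        return atoms[n][0]

    def sp3(n):
        return atoms[n][1] == "CT"

    types: dict[str, int] = {}
    for name, (element, lj_class, _q) in atoms.items():
        nbrs = list(g.neighbors(name))
        nbr_el = [el(n) for n in nbrs]
        if element == "C":
            if sp3(name):
                t = 2 if any(e in "NOS" for e in nbr_el) else 1
            elif name in ring_atoms:
                t = 4 if any(e in "NOS" for e in nbr_el) else 3
            else:
                n_o = nbr_el.count("O")
                if n_o == 1:
                    t = 5
                elif n_o >= 2:
                    t = 6
                else:
                    t = 7
        elif element == "N":
            if name in ring_atoms and res_is_aromatic_n(atoms, name):
                t = 10
            elif lj_class == "N3":
                t = 11
            elif any(
                el(n) == "C" and not sp3(n) and n not in ring_atoms
                and not any(el(m) == "O" for m in g.neighbors(n))
                for n in nbrs
            ):
                t = 12
            elif name == "N":
                t = 8
            else:
                t = 9
        elif element == "O":
            if any(e == "H" for e in nbr_el):
                t = 15
            else:
                parent = next(n for n in nbrs if el(n) == "C")
                n_o = sum(1 for m in g.neighbors(parent) if el(m) == "O")
                t = 14 if n_o >= 2 else 13
        elif element == "S":
            t = 16 if "H" in nbr_el else 17
        elif element == "H":
            heavy = nbrs[0]
            he = el(heavy)
            if he == "C":
                t = 18 if sp3(heavy) else 19
            elif he == "N":
                t = 20
            else:
                t = 21
        else:
            raise ParameterError(f"unsupported element {element!r} for atom {name}")
        types[name] = t
    return types


def res_is_aromatic_n(atoms: dict, name: str) -> bool:
    # Every ring N in the standard residues (His, Trp) is aromatic; Pro's
    # backbone N sits in a saturated ring and keeps its amide type.
    return atoms[name][1] == "NA"


_VARIANTS = (
    ("internal", False, False),
    ("nterm", True, False),
    ("cterm", False, True),
    ("single", True, True),
)


def _build_catalogue():
    """Precompute per-(residue, variant) type and ff-param lookup tables."""
    types: dict[tuple[str, str], dict[str, int]] = {}
    ff: dict[tuple[str, str], dict[str, FFAtomParam]] = {}
    for res in STANDARD_RESIDUES:
        for vname, nt, ct in _VARIANTS:
            tpl = _variant_template(res, nt, ct)
            types[(res, vname)] = _type_variant(tpl)
            ff[(res, vname)] = {
                name: FFAtomParam(*LJ_CLASSES[cls], q)
                for name, (_el, cls, q) in tpl["atoms"].items()
            }
    return types, ff


_TYPE_CATALOGUE, _FF_CATALOGUE = _build_catalogue()


@dataclass(frozen=True)
class SasaTypeRules:
    """Total, single-valued atom -> type-id rules over the standard residues."""

    table: dict = field(default_factory=lambda: _TYPE_CATALOGUE)

    def type_of(self, res_name: str, atom_name: str, variant: str = "internal") -> int:
        res = RESIDUE_ALIASES.get(res_name, res_name)
        if res not in STANDARD_RESIDUES:
            raise ParameterError(f"nonstandard residue {res_name!r}")
        try:
            return self.table[(res, variant)][atom_name]
        except KeyError:
            raise ParameterError(
                f"no SASA type rule for atom {atom_name!r} of {res_name} ({variant})"
            ) from None


@dataclass(frozen=True)
class FFParamTable:
    table: dict = field(default_factory=lambda: _FF_CATALOGUE)

    def params_of(self, res_name: str, atom_name: str, variant: str = "internal") -> FFAtomParam:
        res = RESIDUE_ALIASES.get(res_name, res_name)
        if res not in STANDARD_RESIDUES:
            raise ParameterError(f"nonstandard residue {res_name!r}")
        try:
            return self.table[(res, variant)][atom_name]
        except KeyError:
            raise ParameterError(
                f"no force-field entry for atom {atom_name!r} of {res_name} ({variant})"
            ) from None


# ----------------------------------------------------------------------------
# Parameter-set loading
# ----------------------------------------------------------------------------

def load_parameter_set(config: str = "hawkrank-default"):
    """Return ``(type rules, ff table, radius table, solvation weights)``.

    ``config`` is the packaged default name or the path of a structured text
    file whose ``[sasa_radii]`` / ``[solvation_weights]`` sections override
    the defaults (``element value`` lines, and ``w0`` / ``constant`` /
    ``w1..w21`` lines respectively).
    """
    radii = dict(DEFAULT_SASA_RADII)
    w0, constant = DEFAULT_W0, DEFAULT_CONSTANT
    w = DEFAULT_TYPE_WEIGHTS.copy()
    if config != "hawkrank-default":
        radii, w0, w, constant = _parse_config_file(config, radii, w0, w, constant)
    return (
        SasaTypeRules(),
        FFParamTable(),
        SasaRadiusTable(radii),
        SolvationWeights(w0=w0, w=w, constant=constant),
    )


def _parse_config_file(path, radii, w0, w, constant):
    section = None
    radii_seen: dict[str, float] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#")[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1].strip().lower()
                if section == "sasa_radii":
                    radii_seen = {}
                continue
            key, *vals = line.replace("=", " ").split()
            if section == "sasa_radii":
                radii_seen[key.upper()] = float(vals[0])
            elif section == "solvation_weights":
                if key == "w0":
                    w0 = float(vals[0])
                elif key == "constant":
                    constant = float(vals[0])
                elif key.startswith("w"):
                    idx = int(key[1:])
                    if not 1 <= idx <= N_SASA_TYPES:
                        raise ParameterError(f"{path}: weight index {idx} out of 1..21")
                    w[idx - 1] = float(vals[0])
                else:
                    raise ParameterError(f"{path}: unknown solvation key {key!r}")
            elif section in ("sasa_types", "ff_params"):
                raise ParameterError(
                    f"{path}: [{section}] overrides are not supported; the packaged "
                    "topology-derived tables are authoritative"
                )
            else:
                raise ParameterError(f"{path}: line outside a known section: {line!r}")
    if radii_seen:
        radii = radii_seen  # a user radius table must be complete
    return radii, w0, w, constant


# ----------------------------------------------------------------------------
# Per-structure assignment
# ----------------------------------------------------------------------------

def _residue_variant(res_name: str, atom_names: set[str]) -> str:
    res = RESIDUE_ALIASES.get(res_name, res_name)
    nterm = ("H1" in atom_names and "H2" in atom_names) or (
        res == "PRO" and "H2" in atom_names and "H3" in atom_names
    )
    cterm = "OXT" in atom_names
    if nterm and cterm:
        return "single"
    if nterm:
        return "nterm"
    if cterm:
        return "cterm"
    return "internal"


def _iter_residue_variants(s: ProteinStructure):
    for res_id, res_name, sl in s.residues:
        names = {a.name for a in s.atoms[sl]}
        yield res_id, res_name, sl, _residue_variant(res_name, names)


def assign_sasa_types(s: ProteinStructure, rules: SasaTypeRules) -> np.ndarray:
    """Type id (1..21) for every atom, in atom order.

    Raises :class:`ParameterError` on nonstandard residues or unmatched
    atom names.
    """
    out = np.empty(s.n_atoms, dtype=int)
    for res_id, res_name, sl, variant in _iter_residue_variants(s):
        for k in range(sl.start, sl.stop):
            a = s.atoms[k]
            try:
                out[k] = rules.type_of(res_name, a.name, variant)
            except ParameterError as e:
                raise ParameterError(
                    f"chain {a.chain_id} {res_name} {a.res_seq}{a.icode}: {e.args[0]}"
                ) from None
    return out


def assign_ff_params(s: ProteinStructure, table: FFParamTable) -> list[FFAtomParam]:
    """Force-field parameters for every atom, in atom order.

    Terminal residues are detected from their protonation state (ammonium
    hydrogens / OXT) and receive the terminal parameter variants.
    """
    out: list[FFAtomParam] = []
    for res_id, res_name, sl, variant in _iter_residue_variants(s):
        for k in range(sl.start, sl.stop):
            a = s.atoms[k]
            try:
                out.append(table.params_of(res_name, a.name, variant))
            except ParameterError as e:
                raise ParameterError(
                    f"chain {a.chain_id} {res_name} {a.res_seq}{a.icode}: {e.args[0]}"
                ) from None
    return out
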