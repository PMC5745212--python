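"""Synthetic toy structures, decoy sets and solvation datasets.

Everything downstream is testable without external data: the generators
emit real residue and atom names (so the typing and force-field tables are
exercised authentically), standard formats (PDB, the decoy-transform TSV),
and are deterministic under their seeds.

The toy geometry is idealized, not physical: Calpha atoms follow an
extended strand, a helix, or a seeded random walk with ~3.8 A spacing, and
side-chain/hydrogen positions are laid out from the residue bond topology
with bonded-scale distances.  That is sufficient for surface, pair-energy
and RMSD arithmetic, which is all the toys are for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._templates import RESIDUE_TEMPLATES
from .parameters import SolvationWeights, load_parameter_set
from .sasa import SasaProfile, fibonacci_sphere, structure_profile
from .solvation_model import predict_psol
from .structures_io import (
    Atom,
    ComplexPartition,
    DecoyTransform,
    ProteinStructure,
    RigidTransform,
    apply_transform,
)

__all__ = [
    "ToySpec",
    "DecoySetSpec",
    "ALL20",
    "make_toy_protein",
    "make_toy_complex",
    "make_decoy_set",
    "make_solvation_dataset",
]

ALL20 = sorted(RESIDUE_TEMPLATES)

_DIRS = fibonacci_sphere(24)
_CA_SPACING = 3.8  # A


@dataclass(frozen=True)
class ToySpec:
    n_res: int
    fold: str = "extended"   # extended | helix | random-walk
    seed: int = 0
    sequence: tuple[str, ...] | None = None
    chain_id: str = "A"

    def __post_init__(self):
        if self.n_res < 1:
            raise ValueError("n_res must be >= 1")
        if self.fold not in ("extended", "helix", "random-walk"):
            raise ValueError(f"unknown fold {self.fold!r}")


@dataclass(frozen=True)
class DecoySetSpec:
    n_decoys: int
    schedule: tuple[tuple[float, float], ...]   # (rotation deg, translation A)
    seed: int = 0

    def __post_init__(self):
        if not self.schedule:
            raise ValueError("perturbation schedule must be non-empty")
        for rot, trans in self.schedule:
            if rot < 0 or trans < 0:
                raise ValueError("perturbation magnitudes must be >= 0")


def _local_layout(res_name: str) -> dict[str, np.ndarray]:
    """Deterministic per-residue-type atom offsets from the bond topology.

    BFS from CA (N for PRO ordering stability is irrelevant); each atom sits
    at its parent plus a bonded-scale step in a fixed lattice direction.
    """
    tpl = RESIDUE_TEMPLATES[res_name]
    atoms = {name: el for name, el, _cls, _q in tpl["atoms"]}
    order = {name: k for k, (name, *_rest) in enumerate(tpl["atoms"])}
    adj: dict[str, list[str]] = {name: [] for name in atoms}
    for a, b in tpl["bonds"]:
        adj[a].append(b)
        adj[b].append(a)

    root = "CA"
    pos = {root: np.zeros(3)}
    queue = [root]
    depth = {root: 0}
    while queue:
        parent = queue.pop(0)
        for k, child in enumerate(sorted(adj[parent], key=order.get)):
            if child in pos:
                continue
            step = 1.0 if atoms[child] == "H" else 1.5
            d = _DIRS[(order[child] * 5 + depth[parent] * 7 + k) % len(_DIRS)]
            pos[child] = pos[parent] + step * d
            depth[child] = depth[parent] + 1
            queue.append(child)
    # break any accidental coincidences deterministically
    placed: dict[tuple, str] = {}
    for name in sorted(pos, key=order.get):
        key = tuple(np.round(pos[name], 3))
        bump = 0
        while key in placed:
            bump += 1
            pos[name] = pos[name] + np.array([0.11, 0.07, 0.05]) * bump
            key = tuple(np.round(pos[name], 3))
        placed[key] = name
    return pos


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _ca_trace(spec: ToySpec, rng: np.random.Generator) -> np.ndarray:
    i = np.arange(spec.n_res)
    if spec.fold == "extended":
        return np.column_stack([_CA_SPACING * i, np.zeros_like(i), np.zeros_like(i)]).astype(float)
    if spec.fold == "helix":
        theta = np.deg2rad(100.0) * i
        # radius/rise chosen so consecutive Calphas sit ~3.8 A apart
        radius, rise = 2.3, 1.5
        xy = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
        return np.column_stack([xy, rise * i]).astype(float)
    steps = rng.normal(size=(spec.n_res - 1, 3)) if spec.n_res > 1 else np.empty((0, 3))
    if len(steps):
        steps = _CA_SPACING * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])


def make_toy_protein(spec: ToySpec) -> ProteinStructure:
    """All-atom toy chain with standard residue/atom naming.

    Consecutive Calpha-Calpha distances are ~3.8 A (exact for the extended
    fold); every atom is parameterizable by the packaged tables.
    """
    rng = np.random.default_rng(spec.seed)
    seq = list(spec.sequence) if spec.sequence else ["ALA", "SER", "LEU", "GLY", "VAL"]
    ca = _ca_trace(spec, rng)

    atoms: list[Atom] = []
    serial = 1
    for r in range(spec.n_res):
        res_name = seq[r % len(seq)]
        layout = _local_layout(res_name)
        # orient each residue differently so side chains spread out
        M = _rotation_about(np.array([0.3, 0.5, 0.8]), np.deg2rad(67.0) * r)
        tpl = RESIDUE_TEMPLATES[res_name]
        for name, el, _cls, _q in tpl["atoms"]:
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=el,
                    res_name=res_name,
                    res_seq=r + 1,
                    icode="",
                    chain_id=spec.chain_id,
                    coords=ca[r] + M @ layout[name],
                )
            )
            serial += 1
    return ProteinStructure(atoms)


def make_toy_complex(
    n_rec: int = 12,
    n_lig: int = 8,
    gap: float = 1.0,
    seed: int = 0,
    rec_sequence: tuple[str, ...] | None = None,
    lig_sequence: tuple[str, ...] | None = None,
) -> ComplexPartition:
    """Two toy chains placed side by side with a surface gap of ~``gap`` A."""
    rec = make_toy_protein(ToySpec(n_rec, "helix", seed, rec_sequence, chain_id="R"))
    lig = make_toy_protein(ToySpec(n_lig, "helix", seed + 1, lig_sequence, chain_id="L"))
    # shift the ligand along +x so the bounding boxes just clear by `gap`
    dx = rec.coords[:, 0].max() - lig.coords[:, 0].min() + gap
    lig = apply_transform(lig, RigidTransform(np.eye(3), np.array([dx, 0.0, 0.0])))
    return ComplexPartition(rec, lig)


def make_decoy_set(
    native: ComplexPartition, spec: DecoySetSpec
) -> tuple[list[DecoyTransform], pd.DataFrame]:
    """Rigid-body ligand perturbations with analytic reference L_RMSDs.

    Decoy k applies schedule entry ``k % len(schedule)``: a rotation of the
    stated magnitude about a random axis through the ligand Calpha centroid
    plus a translation of the stated magnitude in a random direction.  The
    receptor never moves, so the reference L_RMSD is computed directly from
    the applied transform - an oracle independent of the evaluation module.
    """
    rng = np.random.default_rng(spec.seed)
    lig_ca = np.array([a.coords for a in native.ligand.atoms if a.name == "CA"])
    center = lig_ca.mean(axis=0)

    decoys: list[DecoyTransform] = []
    rows = []
    for k in range(spec.n_decoys):
        rot_deg, trans_mag = spec.schedule[k % len(spec.schedule)]
        axis = rng.normal(size=3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        R = _rotation_about(axis, np.deg2rad(rot_deg))
        t = center - R @ center + trans_mag * direction
        tf = RigidTransform(R, t)
        moved = tf.apply(lig_ca)
        l_rmsd = float(np.sqrt(((moved - lig_ca) ** 2).sum(axis=1).mean()))
        decoy_id = f"d{k:04d}"
        decoys.append(DecoyTransform(decoy_id, tf))
        rows.append([decoy_id, rot_deg, trans_mag, l_rmsd])
    ref = pd.DataFrame(rows, columns=["decoy_id", "rot_deg", "trans_A", "l_rmsd_true"])
    return decoys, ref


def make_solvation_dataset(
    n: int,
    planted: SolvationWeights,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 960,
) -> tuple[list[SasaProfile], np.ndarray]:
    """Planted-weight regression dataset: diverse toys, linear targets.

    Targets are the planted linear surface model evaluated on each toy's
    true profile, plus Gaussian noise of standard deviation ``noise_sd``
    (kcal/mol).  A stand-in for a polar-solvation target set computed with a
    continuum-electrostatics model on real proteins.
    """
    if n < 30:
        raise ValueError("need n >= 30 rows")
    rng = np.random.default_rng(seed)
    rules, _ff, radii, _w = load_parameter_set()
    profiles: list[SasaProfile] = []
    folds = ("extended", "helix", "random-walk")
    for k in range(n):
        n_res = int(rng.integers(6, 17))
        sequence = tuple(rng.choice(ALL20, size=n_res))
        spec = ToySpec(
            n_res,
            folds[int(rng.integers(3))],
            seed=int(rng.integers(2**31 - 1)),
            sequence=sequence,
        )
        s = make_toy_protein(spec)
        profiles.append(structure_profile(s, rules, radii, n_points=n_points))
    targets = np.array([predict_psol(p, planted) for p in profiles])
    targets = targets + rng.normal(0.0, noise_sd, size=n)
    return profiles, targets
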