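"""Intermolecular pair enumeration and the split vdW / Coulomb terms.

Only receptor-ligand atom pairs enter the energies; intramolecular terms are
never computed.  The van der Waals potential is a softened 6-12 form: the
classical Lennard-Jones well for r >= 0.89 sigma (attractive sum) and a
linear ramp 10 (1 - r / 0.89 sigma) closer in (repulsive sum), with a 12 A
interaction cutoff.  Electrostatics is the bare Coulomb term 332 qi qj /
(eps r) with eps = 1, each pair routed to the attractive sum when negative
and to the repulsive sum otherwise.  Sums are accumulated with exact
(fsum) compensation in fixed atom order for reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .parameters import FFAtomParam
from .structures_io import ComplexPartition

__all__ = [
    "PairList",
    "build_pairlist",
    "vdw_energy",
    "elec_energy",
    "DEFAULT_CUTOFF",
    "COULOMB_CONSTANT",
    "REPULSIVE_ONSET",
]

DEFAULT_CUTOFF = 12.0      # A, vdW interaction cutoff
COULOMB_CONSTANT = 332.0   # kcal A / (mol e^2)
REPULSIVE_ONSET = 0.89     # fraction of sigma where the linear ramp begins


@dataclass(frozen=True)
class PairList:
    """Receptor-ligand atom pairs within the cutoff.

    ``i`` indexes receptor atoms, ``j`` ligand atoms (each in its own
    structure's atom order); ``r`` is the interatomic distance in A.
    """

    i: np.ndarray
    j: np.ndarray
    r: np.ndarray
    cutoff: float | None

    def __len__(self) -> int:
        return len(self.r)


def build_pairlist(
    part: ComplexPartition, cutoff: float | None = DEFAULT_CUTOFF
) -> PairList:
    """All receptor-ligand pairs with r_ij strictly below ``cutoff``.

    ``cutoff=None`` enumerates every cross pair (used for un-truncated
    electrostatics).  Coincident atoms (r = 0) are an error.
    """
    rc = part.receptor.coords
    lc = part.ligand.coords
    if cutoff is None:
        ii, jj = np.meshgrid(
            np.arange(len(rc)), np.arange(len(lc)), indexing="ij"
        )
        i, j = ii.ravel(), jj.ravel()
    else:
        tree_r = cKDTree(rc)
        tree_l = cKDTree(lc)
        pairs = tree_r.query_ball_tree(tree_l, cutoff)
        i = np.array(
            [k for k, js in enumerate(pairs) for _ in js], dtype=int
        )
        j = np.array([jj for js in pairs for jj in js], dtype=int)
    if len(i) == 0:
        return PairList(i=np.empty(0, int), j=np.empty(0, int), r=np.empty(0), cutoff=cutoff)
    r = np.linalg.norm(rc[i] - lc[j], axis=1)
    if cutoff is not None:
        keep = r < cutoff
        i, j, r = i[keep], j[keep], r[keep]
    if np.any(r == 0.0):
        k = int(np.argmin(r))
        raise ValueError(
            f"coincident atoms: receptor atom {i[k]} and ligand atom {j[k]} overlap"
        )
    # fixed, reproducible order
    order = np.lexsort((j, i))
    return PairList(i=i[order], j=j[order], r=r[order], cutoff=cutoff)


def _per_atom_arrays(params: list[FFAtomParam]):
    return (
        np.array([p.rmin_half for p in params]),
        np.array([p.epsilon for p in params]),
        np.array([p.charge for p in params]),
    )


def vdw_energy(
    pairs: PairList,
    rec_params: list[FFAtomParam],
    lig_params: list[FFAtomParam],
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[float, float]:
    """(attractive, repulsive) van der Waals sums in kcal/mol.

    sigma_ij is the sum of the two atoms' rmin/2 values and eps_ij their
    geometric-mean well depth.  Pairs at exactly r = 0.89 sigma fall on the
    attractive branch.
    """
    rh_r, eps_r, _ = _per_atom_arrays(rec_params)
    rh_l, eps_l, _ = _per_atom_arrays(lig_params)
    sigma = rh_r[pairs.i] + rh_l[pairs.j]
    eps = np.sqrt(eps_r[pairs.i] * eps_l[pairs.j])
    r = pairs.r

    onset = REPULSIVE_ONSET * sigma
    attr_mask = (r >= onset) & (r < cutoff)
    repu_mask = r < onset

    sr6 = (sigma[attr_mask] / r[attr_mask]) ** 6
    e_attr = eps[attr_mask] * (sr6 * sr6 - 2.0 * sr6)
    e_repu = 10.0 * (1.0 - r[repu_mask] / onset[repu_mask])
    return math.fsum(e_attr), math.fsum(e_repu)


def elec_energy(
    pairs: PairList,
    rec_params: list[FFAtomParam],
    lig_params: list[FFAtomParam],
    dielectric: float = 1.0,
) -> tuple[float, float]:
    """(attractive, repulsive) Coulomb sums in kcal/mol.

    Per-pair energies below zero accumulate into the attractive sum; zero or
    positive ones (including uncharged pairs) into the repulsive sum.
    """
    _, _, q_r = _per_atom_arrays(rec_params)
    _, _, q_l = _per_atom_arrays(lig_params)
    if np.any(pairs.r == 0.0):
        raise ValueError("coincident atoms in pair list")
    e = COULOMB_CONSTANT * q_r[pairs.i] * q_l[pairs.j] / (dielectric * pairs.r)
    neg = e < 0.0
    return math.fsum(e[neg]), math.fsum(e[~neg])
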