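"""Docking-evaluation statistics: RMSDs, hit calling, SR and MSR.

L_RMSD is the Calpha RMSD of the ligand after least-squares superposition of
the receptors; I_RMSD the Calpha RMSD over the native interface residues
(any atom within 10 A of the other partner) after superposing those
residues.  A decoy is a hit when L_RMSD < 10 A or I_RMSD < 4 A.  Rankings
are summarized by the success rate SR(N) and by the modified success rate:
per case F = sum over hits in the top N of (1 + 1/rank), divided by the
case's total hit count; Y averages F over cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .sasa import DEFAULT_N_POINTS, DEFAULT_PROBE, compute_sasa
from .structures_io import ComplexPartition, ProteinStructure

__all__ = [
    "RmsdPair",
    "RankedCase",
    "EvalSummary",
    "interface_residues",
    "compute_rmsds",
    "classify_hit",
    "success_rate",
    "msr",
    "buried_area_pct",
    "kabsch",
]

L_RMSD_HIT = 10.0   # A
I_RMSD_HIT = 4.0    # A
INTERFACE_CUTOFF = 10.0  # A, inclusive


@dataclass(frozen=True)
class RmsdPair:
    l_rmsd: float
    i_rmsd: float


@dataclass(frozen=True)
class RankedCase:
    """One benchmark system: hit flags in rank order (rank = index + 1).

    ``n_hits_total`` is the case's hit count over the full considered decoy
    list; it defaults to the hits present in ``hits_by_rank``.
    """

    case_id: str
    hits_by_rank: np.ndarray
    n_hits_total: int | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "hits_by_rank", np.asarray(self.hits_by_rank, dtype=bool)
        )

    @property
    def hit_count(self) -> int:
        if self.n_hits_total is not None:
            return int(self.n_hits_total)
        return int(self.hits_by_rank.sum())

    def first_hit_rank(self) -> int | None:
        w = np.flatnonzero(self.hits_by_rank)
        return int(w[0]) + 1 if len(w) else None


@dataclass(frozen=True)
class EvalSummary:
    sr_at_n: dict[int, float]
    F_per_case: dict[str, float]
    Y: float


def kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t mapping mobile onto ref."""
    mobile = np.asarray(mobile, float)
    ref = np.asarray(ref, float)
    cm, cr = mobile.mean(axis=0), ref.mean(axis=0)
    H = (mobile - cm).T @ (ref - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, cr - R @ cm


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def interface_residues(
    part: ComplexPartition, cutoff: float = INTERFACE_CUTOFF
) -> tuple[set, set]:
    """Residues of each partner with any atom within ``cutoff`` (inclusive)
    of any atom of the other partner."""
    rec, lig = part.receptor, part.ligand
    tree_l = cKDTree(lig.coords)
    d_rec, _ = tree_l.query(rec.coords)
    tree_r = cKDTree(rec.coords)
    d_lig, _ = tree_r.query(lig.coords)

    def collect(s: ProteinStructure, dmin: np.ndarray) -> set:
        out = set()
        for res_id, _name, sl in s.residues:
            if np.any(dmin[sl] <= cutoff):
                out.add(res_id)
        return out

    return collect(rec, d_rec), collect(lig, d_lig)


def _ca_map(s: ProteinStructure) -> dict:
    return {a.residue_id: a.coords for a in s.atoms if a.name == "CA"}


def _paired_cas(native: ProteinStructure, decoy: ProteinStructure, label: str):
    nat, dec = _ca_map(native), _ca_map(decoy)
    common = [k for k in nat if k in dec]
    dropped = (set(nat) | set(dec)) - set(common)
    if dropped:
        warnings.warn(
            f"{label}: dropping {len(dropped)} unpaired residues from the RMSD",
            stacklevel=3,
        )
    return (
        np.array([nat[k] for k in common]),
        np.array([dec[k] for k in common]),
        common,
    )


def compute_rmsds(native: ComplexPartition, decoy: ComplexPartition) -> RmsdPair:
    """L_RMSD and I_RMSD of a decoy against the native complex.

    Calpha atoms are paired by (chain, residue number, insertion code); the
    interface set is defined on the native complex only.
    """
    nat_rec, dec_rec, _ = _paired_cas(native.receptor, decoy.receptor, "receptor")
    nat_lig, dec_lig, _ = _paired_cas(native.ligand, decoy.ligand, "ligand")
    if len(nat_rec) < 3:
        raise ValueError(f"receptor superposition needs >= 3 Calpha pairs, got {len(nat_rec)}")

    # L_RMSD: superpose receptors, measure the ligand
    R, t = kabsch(dec_rec, nat_rec)
    l_rmsd = _rmsd(dec_lig @ R.T + t, nat_lig)

    # I_RMSD: superpose the native-defined interface Calphas
    rec_if, lig_if = interface_residues(native)
    nat_if, dec_if = [], []
    for nat_s, dec_s, keep in (
        (native.receptor, decoy.receptor, rec_if),
        (native.ligand, decoy.ligand, lig_if),
    ):
        nat_ca, dec_ca = _ca_map(nat_s), _ca_map(dec_s)
        for k in nat_ca:
            if k in keep and k in dec_ca:
                nat_if.append(nat_ca[k])
                dec_if.append(dec_ca[k])
    nat_if, dec_if = np.array(nat_if), np.array(dec_if)
    if len(nat_if) < 3:
        raise ValueError(f"interface superposition needs >= 3 Calpha pairs, got {len(nat_if)}")
    R, t = kabsch(dec_if, nat_if)
    i_rmsd = _rmsd(dec_if @ R.T + t, nat_if)
    return RmsdPair(l_rmsd=l_rmsd, i_rmsd=i_rmsd)


def classify_hit(r: RmsdPair) -> bool:
    """Hit: L_RMSD < 10 A or I_RMSD < 4 A."""
    return r.l_rmsd < L_RMSD_HIT or r.i_rmsd < I_RMSD_HIT


def success_rate(cases: list[RankedCase], N: int) -> float:
    """Fraction of cases with at least one hit in the top N ranks."""
    if not cases:
        raise ValueError("empty case list")
    if N < 1:
        raise ValueError("N must be >= 1")
    good = sum(1 for c in cases if c.hits_by_rank[:N].any())
    return good / len(cases)


def case_f(case: RankedCase, N: int) -> float:
    """F statistic of one case at depth N."""
    hit_ranks = np.flatnonzero(case.hits_by_rank[:N]) + 1
    if case.hit_count == 0:
        raise ValueError(f"case {case.case_id}: no hits in the considered decoys")
    return float(np.sum(1.0 + 1.0 / hit_ranks) / case.hit_count)


def msr(cases: list[RankedCase], N: int) -> EvalSummary:
    """Modified success rate at depth N.

    Cases without any hit in the considered decoy list are excluded with a
    warning; cases whose hits all lie below rank N contribute F = 0.
    """
    if not cases:
        raise ValueError("empty case list")
    F: dict[str, float] = {}
    kept = []
    for c in cases:
        if c.hit_count == 0:
            warnings.warn(
                f"case {c.case_id}: no hits in the considered decoys; excluded from MSR",
                stacklevel=2,
            )
            continue
        kept.append(c)
        F[c.case_id] = case_f(c, N)
    if not kept:
        raise ValueError("no case has any hit; MSR undefined")
    Y = float(np.mean(list(F.values())))
    return EvalSummary(sr_at_n={N: success_rate(kept, N)}, F_per_case=F, Y=Y)


def perfect_f(hit_count: int) -> float:
    """Closed-form maximal F: all hits at ranks 1..HIT."""
    j = np.arange(1, hit_count + 1)
    return float(np.sum(1.0 + 1.0 / j) / hit_count)


def buried_area_pct(
    part: ComplexPartition,
    radii,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> float:
    """Interface (buried) area as a percentage of the complex surface area:
    100 (SASA_rec + SASA_lig - SASA_com) / SASA_com."""
    a_rec = compute_sasa(part.receptor, radii, probe, n_points).total
    a_lig = compute_sasa(part.ligand, radii, probe, n_points).total
    a_com = compute_sasa(part.combined, radii, probe, n_points).total
    if a_com == 0:
        raise ValueError("complex SASA is zero")
    return 100.0 * (a_rec + a_lig - a_com) / a_com
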