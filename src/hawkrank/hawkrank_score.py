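"""The HawkRank score: a weighted sum of five interface energy terms.

    score = w1 dE_vdw_attr + w2 dE_vdw_repu + w3 dE_elec_attr
          + w4 dE_elec_repu + w5 dE_pdsol

Lower scores mark better poses; favourable terms carry negative values and
all five weights are applied with positive sign.  The published weights
(0.850, 0.0005, 1.887, 1.853, 0.9303) ship as the default.  For rigid-body
decoy sets the receptor and ligand surface profiles are computed once and
cached - only the complex surface changes between poses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import pair_energies, solvation_model
from .parameters import (
    FFParamTable,
    SasaRadiusTable,
    SasaTypeRules,
    SolvationWeights,
    assign_ff_params,
    load_parameter_set,
)
from .sasa import DEFAULT_N_POINTS, DEFAULT_PROBE, structure_profile
from .structures_io import (
    ComplexPartition,
    DecoyTransform,
    ProteinStructure,
    apply_transform,
)

__all__ = ["ScoringWeights", "ScoreBreakdown", "ParameterBundle",
           "score_complex", "rank_decoys", "DEFAULT_WEIGHTS"]


@dataclass(frozen=True)
class ScoringWeights:
    w_vdw_attr: float
    w_vdw_repu: float
    w_elec_attr: float
    w_elec_repu: float
    w_pdsol: float

    def __post_init__(self):
        if any(w < 0 for w in self.as_array()):
            raise ValueError("scoring weights must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.w_vdw_attr, self.w_vdw_repu, self.w_elec_attr,
             self.w_elec_repu, self.w_pdsol]
        )


DEFAULT_WEIGHTS = ScoringWeights(0.850, 0.0005, 1.887, 1.853, 0.9303)


@dataclass(frozen=True)
class ScoreBreakdown:
    dE_vdw_attr: float
    dE_vdw_repu: float
    dE_elec_attr: float
    dE_elec_repu: float
    dE_pdsol: float
    total: float

    @classmethod
    def from_terms(cls, terms: np.ndarray, weights: ScoringWeights) -> "ScoreBreakdown":
        terms = np.asarray(terms, dtype=float)
        return cls(*terms, total=float(weights.as_array() @ terms))

    def terms(self) -> np.ndarray:
        return np.array(
            [self.dE_vdw_attr, self.dE_vdw_repu, self.dE_elec_attr,
             self.dE_elec_repu, self.dE_pdsol]
        )


@dataclass
class ParameterBundle:
    """Everything needed to parameterize one complex."""

    rules: SasaTypeRules
    ff: FFParamTable
    radii: SasaRadiusTable
    solvation: SolvationWeights
    probe: float = DEFAULT_PROBE
    n_points: int = DEFAULT_N_POINTS

    @classmethod
    def default(cls) -> "ParameterBundle":
        return cls(*load_parameter_set("hawkrank-default"))


def score_complex(
    part: ComplexPartition,
    weights: ScoringWeights = DEFAULT_WEIGHTS,
    params: ParameterBundle | None = None,
    elec_cutoff: bool = True,
    cancel_intercept: bool = False,
    _cache: dict | None = None,
) -> ScoreBreakdown:
    """Five energy terms and the weighted total for one docked pose.

    ``_cache`` may carry precomputed receptor/ligand ff params and surface
    profiles (rigid-body decoys: those never change between poses).
    """
    params = params or ParameterBundle.default()
    cache = _cache if _cache is not None else {}
    if "rec_ff" not in cache:
        cache["rec_ff"] = assign_ff_params(part.receptor, params.ff)
        cache["lig_ff"] = assign_ff_params(part.ligand, params.ff)
        cache["rec_prof"] = structure_profile(
            part.receptor, params.rules, params.radii, params.probe, params.n_points
        )
        cache["lig_prof"] = structure_profile(
            part.ligand, params.rules, params.radii, params.probe, params.n_points
        )

    pairs = pair_energies.build_pairlist(part, pair_energies.DEFAULT_CUTOFF)
    vdw_a, vdw_r = pair_energies.vdw_energy(pairs, cache["rec_ff"], cache["lig_ff"])
    if elec_cutoff:
        elec_pairs = pairs
    else:
        elec_pairs = pair_energies.build_pairlist(part, None)
    elec_a, elec_r = pair_energies.elec_energy(elec_pairs, cache["rec_ff"], cache["lig_ff"])

    com_prof = structure_profile(
        part.combined, params.rules, params.radii, params.probe, params.n_points
    )
    pdsol = solvation_model.desolvation_energy(
        com_prof, cache["rec_prof"], cache["lig_prof"], params.solvation,
        cancel_intercept=cancel_intercept,
    )
    return ScoreBreakdown.from_terms(
        np.array([vdw_a, vdw_r, elec_a, elec_r, pdsol]), weights
    )


_RANK_COLS = ["decoy_id", "dE_vdw_attr", "dE_vdw_repu", "dE_elec_attr",
              "dE_elec_repu", "dE_pdsol", "total", "rank", "status"]


def rank_decoys(
    receptor: ProteinStructure,
    ligand: ProteinStructure,
    decoys,
    weights: ScoringWeights = DEFAULT_WEIGHTS,
    params: ParameterBundle | None = None,
    elec_cutoff: bool = True,
    cancel_intercept: bool = False,
) -> pd.DataFrame:
    """Score every decoy and rank ascending by total (rank 1 = best).

    ``decoys`` is either a list of :class:`DecoyTransform` applied to the
    ligand or a list of ``(decoy_id, ComplexPartition)`` pairs.  Ties keep
    input order (stable sort); unscorable decoys are reported with an error
    status and excluded from the ranking.
    """
    decoys = list(decoys)
    if not decoys:
        raise ValueError("need at least one decoy")
    params = params or ParameterBundle.default()
    cache: dict = {}
    rows = []
    for d in decoys:
        if isinstance(d, DecoyTransform):
            decoy_id = d.decoy_id
            part = ComplexPartition(receptor, apply_transform(ligand, d.transform))
        else:
            decoy_id, part = d
        try:
            bd = score_complex(
                part, weights, params,
                elec_cutoff=elec_cutoff, cancel_intercept=cancel_intercept,
                _cache=cache if isinstance(d, DecoyTransform) else None,
            )
            rows.append([decoy_id, *bd.terms(), bd.total, np.nan, "ok"])
        except Exception as e:  # noqa: BLE001 - per-decoy fault isolation
            rows.append([decoy_id, *([np.nan] * 6), np.nan, f"error: {e}"])
    df = pd.DataFrame(rows, columns=_RANK_COLS)
    ok = df["status"] == "ok"
    order = df.loc[ok, "total"].argsort(kind="stable")
    ranks = np.empty(int(ok.sum()), dtype=int)
    ranks[order] = np.arange(1, int(ok.sum()) + 1)
    df.loc[ok, "rank"] = ranks
    df = df.sort_values(
        ["rank"], kind="stable", na_position="last"
    ).reset_index(drop=True)
    return df
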