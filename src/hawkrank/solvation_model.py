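"""Linear SASA polar-solvation model, its least-squares fit, and desolvation.

The model predicts the polar component of a protein's solvation free energy
from its surface composition:

    psol = w0 * N_res + sum_i w_i * SASA_i + constant      (kcal/mol)

with one coefficient per solvation atom type (i = 1..21).  Fitting is
ordinary least squares on a seeded 50/50 train/test split, mirroring how the
model is parameterized against generalized-Born targets.  The desolvation
term of a docked pose is the complex psol minus the sum of the partners'
psol values, evaluated with the same coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .parameters import N_SASA_TYPES, SolvationWeights
from .sasa import SasaProfile

__all__ = ["SolvationFit", "predict_psol", "fit_weights", "desolvation_energy"]


@dataclass(frozen=True)
class SolvationFit:
    weights: SolvationWeights
    r_train: float
    r_test: float
    train_idx: np.ndarray
    test_idx: np.ndarray


def predict_psol(p: SasaProfile, w: SolvationWeights) -> float:
    """Polar solvation free energy (kcal/mol) of one structure."""
    return float(w.w0 * p.n_res + w.w @ p.by_type + w.constant)


def _design(profiles: list[SasaProfile]) -> np.ndarray:
    return np.column_stack(
        [
            np.array([p.n_res for p in profiles], dtype=float),
            np.array([p.by_type for p in profiles]),
            np.ones(len(profiles)),
        ]
    )


_COLUMN_NAMES = ["n_res"] + [f"sasa_type_{i}" for i in range(1, N_SASA_TYPES + 1)] + ["intercept"]


def _safe_pearson(pred: np.ndarray, obs: np.ndarray) -> float:
    if np.std(pred) == 0 or np.std(obs) == 0:
        # a degenerate (constant) side: call it perfect iff residual-free
        return 1.0 if np.max(np.abs(pred - obs)) < 1e-8 else 0.0
    return float(stats.pearsonr(pred, obs)[0])


def fit_weights(
    profiles: list[SasaProfile],
    targets,
    split: float = 0.5,
    seed: int = 0,
) -> SolvationFit:
    """Ordinary least squares for (w0, w1..w21, constant).

    The rows are randomly split into a training fraction ``split`` and a
    held-out remainder; the fit uses the training rows only and both Pearson
    correlations are reported.  A rank-deficient design raises, naming the
    collinear columns - no silent regularization.
    """
    targets = np.asarray(targets, dtype=float)
    if len(profiles) < 30:
        raise ValueError(f"need >= 30 rows to fit, got {len(profiles)}")
    if len(profiles) != len(targets) or not np.isfinite(targets).all():
        raise ValueError("targets must be finite and match the profiles")

    X = _design(profiles)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(profiles))
    n_train = int(round(split * len(profiles)))
    train, test = np.sort(perm[:n_train]), np.sort(perm[n_train:])

    Xt = X[train]
    rank = np.linalg.matrix_rank(Xt)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(Xt)
        bad = [
            _COLUMN_NAMES[k]
            for k in range(X.shape[1])
            if k >= R.shape[0] or abs(R[k, k]) < 1e-8 * max(1.0, abs(R[0, 0]))
        ]
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad or 'undetermined'}"
        )
    beta, *_ = np.linalg.lstsq(Xt, targets[train], rcond=None)
    weights = SolvationWeights(w0=float(beta[0]), w=beta[1:-1], constant=float(beta[-1]))
    r_train = _safe_pearson(Xt @ beta, targets[train])
    r_test = _safe_pearson(X[test] @ beta, targets[test]) if len(test) else float("nan")
    return SolvationFit(weights, r_train, r_test, train, test)


def desolvation_energy(
    com: SasaProfile,
    rec: SasaProfile,
    lig: SasaProfile,
    w: SolvationWeights,
    cancel_intercept: bool = False,
) -> float:
    """Polar desolvation of complex formation (kcal/mol).

    Literally psol(com) - (psol(lig) + psol(rec)): for a zero-contact pose
    the surface terms cancel and the value equals minus the fitted constant.
    ``cancel_intercept=True`` adds the constant back so separated partners
    score exactly zero.
    """
    if com.n_res != rec.n_res + lig.n_res:
        raise ValueError(
            f"residue-count mismatch: complex has {com.n_res}, "
            f"partners sum to {rec.n_res + lig.n_res}"
        )
    de = predict_psol(com, w) - (predict_psol(lig, w) + predict_psol(rec, w))
    if cancel_intercept:
        de += w.constant
    return de
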