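"""Genetic-algorithm training of the five scoring weights.

A real-coded GA searches the weight box ([0, 3] for the vdW-attractive,
electrostatic and desolvation weights, [0, 0.001] for the vdW-repulsive one)
with tournament selection, blend (BLX-alpha) crossover, Gaussian mutation
clipped to the bounds and elitism.  Per-decoy energy vectors are precomputed
once, so a candidate weight vector only reweights cached five-term vectors.

The objective is the ranking statistic the trained function is judged by:
by default the MSR integrated value Y at depth N = 500 over the training
cases (alternatives: SR at N, mean reciprocal first-hit rank).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hawkrank_score import ScoringWeights

__all__ = ["GAConfig", "TrainingCase", "fitness", "train_weights"]

DEFAULT_BOUNDS = (
    (0.0, 3.0),     # vdW attractive
    (0.0, 0.001),   # vdW repulsive (deliberately tiny: soft-clash ramp)
    (0.0, 3.0),     # electrostatic attractive
    (0.0, 3.0),     # electrostatic repulsive
    (0.0, 3.0),     # polar desolvation
)


@dataclass(frozen=True)
class GAConfig:
    population: int = 200
    iterations: int = 1500
    elite_fraction: float = 0.2
    bounds: tuple = DEFAULT_BOUNDS
    seed: int = 0
    N: int = 500
    objective: str = "msr"          # msr | sr | mrr
    tournament_size: int = 3
    crossover_alpha: float = 0.5
    mutation_prob: float = 0.2
    mutation_sigma_frac: float = 0.05

    def __post_init__(self):
        if not 0 < self.elite_fraction < 1:
            raise ValueError("elite_fraction must lie in (0, 1)")
        for lo, hi in self.bounds:
            if not 0 <= lo < hi:
                raise ValueError(f"invalid bound ({lo}, {hi})")


@dataclass(frozen=True)
class TrainingCase:
    """Per-decoy five-term energy vectors plus hit flags for one system."""

    case_id: str
    energies: np.ndarray   # (n_decoys, 5)
    hits: np.ndarray       # (n_decoys,) bool

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        h = np.asarray(self.hits, dtype=bool)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "hits", h)
        if e.ndim != 2 or e.shape[1] != 5 or e.shape[0] != h.shape[0] or e.shape[0] < 1:
            raise ValueError("energies must be (n_decoys, 5) matching hits")
        if not np.isfinite(e).all():
            raise ValueError("energy vectors must be finite")


def _case_f_from_scores(scores: np.ndarray, hits: np.ndarray, N: int) -> float:
    order = np.argsort(scores, kind="stable")
    hit_ranks = np.flatnonzero(hits[order][:N]) + 1
    n_hits = int(hits.sum())
    if n_hits == 0:
        return np.nan
    return float(np.sum(1.0 + 1.0 / hit_ranks) / n_hits)


def fitness(
    weights: ScoringWeights | np.ndarray,
    cases: list[TrainingCase],
    N: int = 500,
    objective: str = "msr",
) -> float:
    """Ranking quality of one weight vector over the training cases
    (higher is better); deterministic in its inputs."""
    w = weights.as_array() if isinstance(weights, ScoringWeights) else np.asarray(weights)
    vals = []
    for c in cases:
        if not c.hits.any():
            continue
        scores = c.energies @ w
        if objective == "msr":
            vals.append(_case_f_from_scores(scores, c.hits, N))
        elif objective == "sr":
            order = np.argsort(scores, kind="stable")
            vals.append(float(c.hits[order][:N].any()))
        elif objective == "mrr":
            order = np.argsort(scores, kind="stable")
            first = np.flatnonzero(c.hits[order])
            vals.append(1.0 / (first[0] + 1) if len(first) else 0.0)
        else:
            raise ValueError(f"unknown objective {objective!r}")
    if not vals:
        raise ValueError("no case has any hit")
    return float(np.mean(vals))


def _population_fitness(pop: np.ndarray, cases, N, objective) -> np.ndarray:
    out = np.zeros(len(pop))
    usable = 0
    for c in cases:
        if not c.hits.any():
            continue
        usable += 1
        scores = c.energies @ pop.T            # (n_decoys, pop)
        order = np.argsort(scores, axis=0, kind="stable")
        hits_sorted = c.hits[order]            # (n_decoys, pop)
        if objective == "msr":
            top = hits_sorted[:N]
            ranks = np.arange(1, top.shape[0] + 1)[:, None]
            contrib = np.where(top, 1.0 + 1.0 / ranks, 0.0).sum(axis=0)
            out += contrib / c.hits.sum()
        elif objective == "sr":
            out += hits_sorted[:N].any(axis=0)
        elif objective == "mrr":
            first = np.argmax(hits_sorted, axis=0)
            out += 1.0 / (first + 1)
        else:
            raise ValueError(f"unknown objective {objective!r}")
    if usable == 0:
        raise ValueError("no case has any hit")
    return out / usable


@dataclass
class TrainingResult:
    weights: ScoringWeights
    best_fitness: float
    history: np.ndarray   # best-so-far fitness per generation


def train_weights(cases: list[TrainingCase], cfg: GAConfig = GAConfig()) -> TrainingResult:
    """Run the GA and return the best weight vector ever seen.

    Fully reproducible under ``cfg.seed``; best-so-far fitness is
    non-decreasing across generations (elitism).
    """
    if not cases:
        raise ValueError("empty training-case list")
    rng = np.random.default_rng(cfg.seed)
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    n_genes = len(cfg.bounds)
    pop = rng.uniform(lo, hi, size=(cfg.population, n_genes))
    sigma = cfg.mutation_sigma_frac * (hi - lo)
    n_elite = int(np.ceil(cfg.elite_fraction * cfg.population))

    fit = _population_fitness(pop, cases, cfg.N, cfg.objective)
    best_idx = int(np.argmax(fit))
    best_w, best_f = pop[best_idx].copy(), float(fit[best_idx])
    history = [best_f]

    for _gen in range(cfg.iterations):
        elite_idx = np.argsort(fit, kind="stable")[::-1][:n_elite]
        new_pop = [pop[k].copy() for k in elite_idx]
        while len(new_pop) < cfg.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, cfg.population, size=cfg.tournament_size)
                parents.append(pop[contenders[np.argmax(fit[contenders])]])
            p1, p2 = parents
            cmin, cmax = np.minimum(p1, p2), np.maximum(p1, p2)
            d = cmax - cmin
            child = rng.uniform(
                cmin - cfg.crossover_alpha * d, cmax + cfg.crossover_alpha * d
            )
            mutate = rng.random(n_genes) < cfg.mutation_prob
            child = child + mutate * rng.normal(0.0, sigma)
            new_pop.append(np.clip(child, lo, hi))
        pop = np.array(new_pop)
        fit = _population_fitness(pop, cases, cfg.N, cfg.objective)
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_f:
            best_f = float(fit[gen_best])
            best_w = pop[gen_best].copy()
        history.append(best_f)

    return TrainingResult(
        weights=ScoringWeights(*best_w),
        best_fitness=best_f,
        history=np.array(history),
    )
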