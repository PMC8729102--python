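"""Evolutionary co-optimisation of a feature subset and a balanced data split.

The selector ("training with input selection and testing") evolves candidate
solutions, each a boolean feature mask together with an assignment of every
record to one of two halves A/B.  A candidate's fitness is its *ab/ba*
cross-validation performance: a backprop classifier is trained on A and scored
on B, then trained on B and scored on A, and the two scores are averaged.
A plain generational genetic algorithm with tournament selection, uniform
crossover, bit-flip mutation and elitism drives the search; halves are kept
within a 40–60 % balance by repair.  The original evolutionary engine the
approach derives from is proprietary; this is a standard-GA approximation
whose contract is feature recovery on planted data, not bit-equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import json
import numpy as np
from scipy.stats import rankdata

from .mlp import MLPSpec, BackpropClassifier

__all__ = [
    "GASpec",
    "Candidate",
    "TwistResults",
    "TwistSelector",
    "roc_auc",
    "evaluate_ab_ba",
    "twist_run",
]


@dataclass(frozen=True)
class GASpec:
    """Genetic-algorithm settings."""

    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.02
    elitism_count: int = 2
    tournament_size: int = 2
    balance: tuple[float, float] = (0.4, 0.6)

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("crossover_rate", "mutation_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.elitism_count < 0 or self.elitism_count >= self.population_size:
            raise ValueError("elitism_count must lie in [0, population_size)")


@dataclass
class Candidate:
    """One GA individual: feature mask + A/B split assignment."""

    mask: np.ndarray       # bool, per feature
    split: np.ndarray      # bool, per record; True = half A
    fitness: Optional[float] = None


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve, rank (Mann–Whitney) formulation, ties as 1/2."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate_ab_ba(
    candidate: Candidate,
    X: np.ndarray,
    y: np.ndarray,
    mlp_spec: Optional[MLPSpec] = None,
    metric: str = "accuracy",
) -> float:
    """Mean of the two train/test scores (A→B then B→A) for a candidate.

    Returns 0.0 (penalty) when either half lacks one of the outcome classes.
    ``metric`` is ``"accuracy"`` (default) or ``"auc"``.
    """
    if metric not in ("accuracy", "auc"):
        raise ValueError("metric must be 'accuracy' or 'auc'")
    mask, split = candidate.mask, candidate.split
    if not mask.any():
        return 0.0
    Xa, ya = X[split][:, mask], y[split]
    Xb, yb = X[~split][:, mask], y[~split]
    for half in (ya, yb):
        if len(half) == 0 or len(np.unique(half)) < 2:
            return 0.0
    scores = []
    for (Xtr, ytr, Xte, yte) in ((Xa, ya, Xb, yb), (Xb, yb, Xa, ya)):
        clf = BackpropClassifier(mlp_spec).fit(Xtr, ytr)
        if metric == "accuracy":
            scores.append(clf.score(Xte, yte))
        else:
            scores.append(roc_auc(clf.predict_proba(Xte), yte))
    return float(np.mean(scores))


@dataclass
class TwistResults:
    """Best candidate found, the search history, and the final ROC evaluation."""

    mask: np.ndarray
    split: np.ndarray
    fitness: float
    history: list[float]               # elite fitness per generation
    feature_names: list[str]
    auc_ab: float
    auc_ba: float

    @property
    def selected_features(self) -> list[str]:
        return [n for n, m in zip(self.feature_names, self.mask) if m]

    @property
    def auc_mean(self) -> float:
        return (self.auc_ab + self.auc_ba) / 2.0

    def summary(self) -> str:
        lines = [
            "Evolutionary feature selection",
            "=" * 44,
            f"selected features ({int(self.mask.sum())}/{len(self.mask)}): "
            + ", ".join(self.selected_features),
            f"fitness (mean ab/ba accuracy): {self.fitness:.4f}",
            f"final ROC AUC: ab={self.auc_ab:.4f}  ba={self.auc_ba:.4f}  "
            f"mean={self.auc_mean:.4f}",
            f"generations: {len(self.history)}",
        ]
        return "\n".join(lines)

    def to_json(self, path: Optional[str | Path] = None) -> str:
        payload = json.dumps(
            {
                "selected_features": self.selected_features,
                "mask": self.mask.astype(int).tolist(),
                "fitness": self.fitness,
                "history": self.history,
                "auc": {"ab": self.auc_ab, "ba": self.auc_ba, "mean": self.auc_mean},
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


class TwistSelector:
    """GA-driven selector over (feature mask, balanced A/B split) candidates."""

    def __init__(
        self,
        X,
        y,
        feature_names: Optional[Sequence[str]] = None,
        ga_spec: Optional[GASpec] = None,
        mlp_spec: Optional[MLPSpec] = None,
        metric: str = "accuracy",
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y).ravel().astype(int)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be 2-D with rows matching y")
        if len(self.X) < 20:
            raise ValueError("need at least 20 records")
        if len(np.unique(self.y)) < 2:
            raise ValueError("y contains a single class")
        self.p = self.X.shape[1]
        self.feature_names = (
            list(feature_names) if feature_names is not None
            else [f"x{j}" for j in range(self.p)]
        )
        if len(self.feature_names) != self.p:
            raise ValueError("feature_names length must match X columns")
        self.ga_spec = ga_spec if ga_spec is not None else GASpec()
        self.mlp_spec = mlp_spec if mlp_spec is not None else MLPSpec()
        self.metric = metric

    # -- candidate plumbing -------------------------------------------------

    def _repair(self, cand: Candidate, rng: np.random.Generator) -> Candidate:
        if not cand.mask.any():
            cand.mask[rng.integers(self.p)] = True
        lo, hi = self.ga_spec.balance
        n = len(cand.split)
        frac = cand.split.mean()
        while frac < lo or frac > hi:
            majority = ~cand.split if frac < lo else cand.split
            idx = np.flatnonzero(majority)
            cand.split[rng.choice(idx)] ^= True
            frac = cand.split.mean()
        return cand

    def _random_candidate(self, rng: np.random.Generator) -> Candidate:
        mask = rng.random(self.p) < 0.5
        split = np.zeros(len(self.y), dtype=bool)
        split[rng.permutation(len(self.y))[: len(self.y) // 2]] = True
        return self._repair(Candidate(mask=mask, split=split), rng)

    def _fitness(self, cand: Candidate, cache: dict) -> float:
        key = (cand.mask.tobytes(), cand.split.tobytes())
        if key not in cache:
            cache[key] = evaluate_ab_ba(cand, self.X, self.y, self.mlp_spec, self.metric)
        return cache[key]

    # -- the GA -------------------------------------------------------------

    def fit(self, seed: int = 0, population: Optional[list[Candidate]] = None) -> TwistResults:
        """Run the GA; ``population`` overrides the random initial population."""
        ga = self.ga_spec
        rng = np.random.default_rng(seed)
        cache: dict = {}

        if self.p == 1:
            # degenerate: the mask is forced, no search over features needed
            cand = self._random_candidate(rng)
            cand.mask[:] = True
            cand.fitness = self._fitness(cand, cache)
            return self._finalize(cand, [cand.fitness])

        if population is None:
            population = [self._random_candidate(rng) for _ in range(ga.population_size)]
        for cand in population:
            cand.fitness = self._fitness(cand, cache)

        history: list[float] = []
        for _ in range(ga.generations):
            population.sort(key=lambda c: c.fitness, reverse=True)
            history.append(population[0].fitness)
            next_gen = [
                Candidate(mask=c.mask.copy(), split=c.split.copy(), fitness=c.fitness)
                for c in population[: ga.elitism_count]
            ]
            while len(next_gen) < ga.population_size:
                p1 = self._tournament(population, rng)
                p2 = self._tournament(population, rng)
                child = self._crossover(p1, p2, rng)
                self._mutate(child, rng)
                self._repair(child, rng)
                child.fitness = self._fitness(child, cache)
                next_gen.append(child)
            population = next_gen
        population.sort(key=lambda c: c.fitness, reverse=True)
        history.append(population[0].fitness)
        return self._finalize(population[0], history)

    def _tournament(self, population: list[Candidate], rng: np.random.Generator) -> Candidate:
        picks = rng.integers(len(population), size=self.ga_spec.tournament_size)
        return max((population[i] for i in picks), key=lambda c: c.fitness)

    def _crossover(self, p1: Candidate, p2: Candidate, rng: np.random.Generator) -> Candidate:
        if rng.random() < self.ga_spec.crossover_rate:
            take = rng.random(self.p) < 0.5
            mask = np.where(take, p1.mask, p2.mask)
            take_s = rng.random(len(p1.split)) < 0.5
            split = np.where(take_s, p1.split, p2.split)
        else:
            mask, split = p1.mask.copy(), p1.split.copy()
        return Candidate(mask=mask.copy(), split=split.copy())

    def _mutate(self, cand: Candidate, rng: np.random.Generator) -> None:
        r = self.ga_spec.mutation_rate
        if r <= 0:
            return
        flip_m = rng.random(self.p) < r
        cand.mask ^= flip_m
        flip_s = rng.random(len(cand.split)) < r
        cand.split ^= flip_s

    def _finalize(self, best: Candidate, history: list[float]) -> TwistResults:
        mask, split = best.mask, best.split
        aucs = []
        for (tr, te) in ((split, ~split), (~split, split)):
            clf = BackpropClassifier(self.mlp_spec).fit(self.X[tr][:, mask], self.y[tr])
            aucs.append(roc_auc(clf.predict_proba(self.X[te][:, mask]), self.y[te]))
        return TwistResults(
            mask=mask.copy(),
            split=split.copy(),
            fitness=float(best.fitness),
            history=[float(f) for f in history],
            feature_names=self.feature_names,
            auc_ab=float(aucs[0]),
            auc_ba=float(aucs[1]),
        )


def twist_run(
    X,
    y,
    ga_spec: Optional[GASpec] = None,
    mlp_spec: Optional[MLPSpec] = None,
    feature_names: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> TwistResults:
    """Functional wrapper around :class:`TwistSelector`."""
    return TwistSelector(
        X, y, feature_names=feature_names, ga_spec=ga_spec, mlp_spec=mlp_spec
    ).fit(seed=seed)
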