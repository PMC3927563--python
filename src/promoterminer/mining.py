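"""Inheritable genetic-algorithm feature mining with an RBF-SVM fitness.

The mining algorithm searches for small informative descriptor subsets.
A chromosome carries one binary gene per descriptor plus two 4-bit genes
indexing the SVM hyperparameters (gamma, C) into the grid 2^-7..2^8.
For each cardinality r from r_start to r_end the GA evolves a population
whose chromosomes all carry exactly r ones; the best solution of stage r
seeds stage r+1 by flipping one random 0-gene to 1 in every individual
(the inheritance step).  Fitness is stratified 10-fold cross-validation
accuracy of the SVM on the selected columns, memoized within a run.

Recombination is orthogonal-array crossover: the positions where two
parents differ are grouped into at most seven contiguous factors, an L8
two-level array enumerates candidate children taking each factor wholly
from one parent or the other, candidates are repaired to exactly r ones,
and one child is composed from the per-factor main effects while the
other is the best evaluated array row.

Because the search is stochastic, R independent runs are aggregated by
appearance frequency: Af_j counts the runs selecting descriptor j, a run's
ratio weights its selected descriptors by their cross-run frequencies, and
the consensus best solution is the most accurate run among those whose
ratio exceeds the mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from ._oa import two_level_oa
from .model import PARAM_GRID, cv_accuracy

FitnessFn = Callable[["Chromosome"], float]


@dataclass
class Chromosome:
    """Binary feature mask plus 4-bit (gamma, C) hyperparameter genes."""

    mask: np.ndarray  # bool, one gene per feature
    gamma_gene: int
    cost_gene: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        for g in (self.gamma_gene, self.cost_gene):
            if not 0 <= g <= 15:
                raise ValueError(f"parameter gene {g} outside [0, 15]")

    @property
    def gamma(self) -> float:
        return PARAM_GRID[self.gamma_gene]

    @property
    def C(self) -> float:
        return PARAM_GRID[self.cost_gene]

    @property
    def cardinality(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "Chromosome":
        return Chromosome(self.mask.copy(), self.gamma_gene, self.cost_gene)

    def key(self) -> tuple:
        return (self.mask.tobytes(), self.gamma_gene, self.cost_gene)


@dataclass
class IGAConfig:
    """GA settings.  Defaults are the full-scale settings (population 20,
    stages r = 30..100, 60 generations per stage); tests and examples use
    smaller values."""

    N_pop: int = 20
    r_start: int = 30
    r_end: int = 100
    G_max: int = 60
    p_s: float = 0.2
    p_c: float = 0.8
    p_m: float = 0.05
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_s", "p_c", "p_m"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.r_start > self.r_end:
            raise ValueError("r_start must be <= r_end")
        if self.N_pop % 2:
            raise ValueError("N_pop must be even")


@dataclass
class StageBest:
    r: int
    selected: list[int]
    C: float
    gamma: float
    fitness: float


@dataclass
class MiningResult:
    """Outcome of one mining run: the most accurate solution over all
    cardinality stages, plus per-stage bests and the fitness trace."""

    selected_indices: list[int]
    C: float
    gamma: float
    fitness: float
    per_stage: list[StageBest]
    trace: list[float]  # best fitness after each generation
    n_evaluations: int
    seed: int

    @property
    def m(self) -> int:
        return len(self.selected_indices)

    def mask(self, n_features: int) -> np.ndarray:
        out = np.zeros(n_features, dtype=bool)
        out[self.selected_indices] = True
        return out

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MiningResult":
        d = json.loads(Path(path).read_text())
        d["per_stage"] = [StageBest(**s) for s in d["per_stage"]]
        return cls(**d)


class FitnessEvaluator:
    """Memoized 10-fold CV accuracy of the SVM encoded by a chromosome.

    Fold assignment is derived from the run seed, so re-evaluating the
    same chromosome always returns the identical value.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, folds: int = 10,
                 seed: int = 0) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.folds = folds
        self.seed = seed
        self._cache: dict[tuple, float] = {}
        self.n_evaluations = 0

    def __call__(self, chrom: Chromosome) -> float:
        if chrom.cardinality == 0:
            raise ValueError("chromosome selects zero features")
        key = chrom.key()
        if key not in self._cache:
            self._cache[key] = cv_accuracy(
                self.X[:, chrom.mask], self.y, chrom.C, chrom.gamma,
                folds=self.folds, seed=self.seed)
            self.n_evaluations += 1
        return self._cache[key]


# ---------------------------------------------------------------------------
# operators

def init_population(config: IGAConfig, n_features: int,
                    rng: np.random.Generator) -> list[Chromosome]:
    """Population of N_pop chromosomes with exactly r_start ones each."""
    if config.r_start > n_features:
        raise ValueError("r_start exceeds the number of features")
    pop = []
    for _ in range(config.N_pop):
        mask = np.zeros(n_features, dtype=bool)
        mask[rng.choice(n_features, size=config.r_start, replace=False)] = True
        pop.append(Chromosome(mask, int(rng.integers(16)),
                              int(rng.integers(16))))
    return pop


def rank_selection(population: list[Chromosome], fitnesses: Sequence[float],
                   p_s: float) -> list[Chromosome]:
    """Replace the worst floor(p_s * N) individuals by copies of the best
    floor(p_s * N)."""
    n_rep = int(p_s * len(population))
    if n_rep == 0:
        return [c.copy() for c in population]
    order = np.argsort(fitnesses)  # ascending
    worst = order[:n_rep]
    best = order[::-1][:n_rep]
    out = [c.copy() for c in population]
    for w, b in zip(worst, best):
        out[w] = population[b].copy()
    return out


def _repair(mask: np.ndarray, r: int, rng: np.random.Generator) -> np.ndarray:
    """Flip randomly chosen genes so the mask has exactly r ones."""
    mask = mask.copy()
    ones = np.flatnonzero(mask)
    if ones.size > r:
        drop = rng.choice(ones, size=ones.size - r, replace=False)
        mask[drop] = False
    elif ones.size < r:
        zeros = np.flatnonzero(~mask)
        add = rng.choice(zeros, size=r - ones.size, replace=False)
        mask[add] = True
    return mask


def _param_crossover(a: Chromosome, b: Chromosome, rng: np.random.Generator
                     ) -> tuple[tuple[int, int], tuple[int, int]]:
    """One-point crossover on the 8-bit concatenation (gamma_gene ||
    cost_gene) of the two parents."""
    bits_a = [(a.gamma_gene >> i) & 1 for i in range(4)] + \
             [(a.cost_gene >> i) & 1 for i in range(4)]
    bits_b = [(b.gamma_gene >> i) & 1 for i in range(4)] + \
             [(b.cost_gene >> i) & 1 for i in range(4)]
    cut = int(rng.integers(1, 8))
    child_a = bits_a[:cut] + bits_b[cut:]
    child_b = bits_b[:cut] + bits_a[cut:]

    def decode(bits: list[int]) -> tuple[int, int]:
        g = sum(bit << i for i, bit in enumerate(bits[:4]))
        c = sum(bit << i for i, bit in enumerate(bits[4:]))
        return g, c

    return decode(child_a), decode(child_b)


def oa_crossover(parent_a: Chromosome, parent_b: Chromosome,
                 fitnessfn: FitnessFn, r: int,
                 rng: np.random.Generator) -> tuple[Chromosome, Chromosome]:
    """Orthogonal-array crossover (see module docstring for the scheme).

    Both returned children carry exactly r ones.  Identical parents are
    returned as copies without spending evaluations.
    """
    if parent_a.cardinality != r or parent_b.cardinality != r:
        raise ValueError("both parents must have exactly r ones")
    diff = np.flatnonzero(parent_a.mask != parent_b.mask)
    if diff.size == 0:
        return parent_a.copy(), parent_b.copy()

    (ga, ca), (gb, cb) = _param_crossover(parent_a, parent_b, rng)

    n_factors = min(7, diff.size)
    factors = np.array_split(diff, n_factors)
    oa = two_level_oa(n_factors)

    candidates: list[Chromosome] = []
    fits: list[float] = []
    for row in oa:
        mask = parent_a.mask.copy()
        for level, block in zip(row, factors):
            if level == 1:  # take this factor from parent b
                mask[block] = parent_b.mask[block]
        mask = _repair(mask, r, rng)
        cand = Chromosome(mask, gb, cb)
        candidates.append(cand)
        fits.append(fitnessfn(cand))
    fits_arr = np.array(fits)

    # per-factor main effects: mean fitness at level 0 (parent a) vs 1
    composed = parent_a.mask.copy()
    for j, block in enumerate(factors):
        lvl0 = fits_arr[oa[:, j] == 0].mean()
        lvl1 = fits_arr[oa[:, j] == 1].mean()
        if lvl1 > lvl0:
            composed[block] = parent_b.mask[block]
        # else keep parent a's genes (already in place)
    composed = _repair(composed, r, rng)
    child_a = Chromosome(composed, ga, ca)
    fitnessfn(child_a)

    child_b = candidates[int(np.argmax(fits_arr))].copy()
    return child_a, child_b


def swap_mutation(chrom: Chromosome, rng: np.random.Generator) -> Chromosome:
    """Exchange one random 1-gene with one random 0-gene (cardinality
    preserved); with probability 0.5 one parameter gene is re-randomized.
    All-ones or all-zeros masks are returned unchanged."""
    out = chrom.copy()
    ones = np.flatnonzero(out.mask)
    zeros = np.flatnonzero(~out.mask)
    if ones.size == 0 or zeros.size == 0:
        return out
    out.mask[rng.choice(ones)] = False
    out.mask[rng.choice(zeros)] = True
    if rng.random() < 0.5:
        if rng.random() < 0.5:
            out.gamma_gene = int(rng.integers(16))
        else:
            out.cost_gene = int(rng.integers(16))
    return out


# ---------------------------------------------------------------------------
# the mining run

def run_iga(X: np.ndarray, y: np.ndarray, config: IGAConfig) -> MiningResult:
    """One full inheritable-GA mining run over r = r_start .. r_end.

    ``X`` must already be scaled to [0, 1].  Bit-reproducible for a fixed
    config (all randomness flows from config.seed).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_features = X.shape[1]
    rng = np.random.default_rng(config.seed)
    evaluator = FitnessEvaluator(X, y, config.cv_folds, seed=config.seed)

    pop = init_population(config, n_features, rng)
    per_stage: list[StageBest] = []
    trace: list[float] = []

    for r in range(config.r_start, config.r_end + 1):
        for _gen in range(config.G_max):
            fits = [evaluator(c) for c in pop]
            best_i = int(np.argmax(fits))

            pop = rank_selection(pop, fits, config.p_s)
            fits = [evaluator(c) for c in pop]
            best_i = int(np.argmax(fits))

            # crossover on p_c*N parents, best individual protected
            n_parents = int(config.p_c * config.N_pop) // 2 * 2
            others = [i for i in range(len(pop)) if i != best_i]
            rng.shuffle(others)
            chosen = others[:min(n_parents, len(others) - (len(others) % 2))]
            for a_i, b_i in zip(chosen[0::2], chosen[1::2]):
                child_a, child_b = oa_crossover(
                    pop[a_i], pop[b_i], evaluator, r, rng)
                pop[a_i], pop[b_i] = child_a, child_b

            # mutation on round(p_m*N) random individuals, best protected
            n_mut = int(round(config.p_m * config.N_pop))
            fits = [evaluator(c) for c in pop]
            best_i = int(np.argmax(fits))
            mut_pool = [i for i in range(len(pop)) if i != best_i]
            rng.shuffle(mut_pool)
            for i in mut_pool[:n_mut]:
                pop[i] = swap_mutation(pop[i], rng)

            fits = [evaluator(c) for c in pop]
            trace.append(max(fits))

        fits = [evaluator(c) for c in pop]
        best = pop[int(np.argmax(fits))]
        per_stage.append(StageBest(
            r=r, selected=np.flatnonzero(best.mask).tolist(),
            C=best.C, gamma=best.gamma, fitness=max(fits)))

        if r < config.r_end:
            # inheritance: flip one random 0-gene to 1 in every individual
            for i, c in enumerate(pop):
                zeros = np.flatnonzero(~c.mask)
                if zeros.size:
                    nc = c.copy()
                    nc.mask[rng.choice(zeros)] = True
                    pop[i] = nc

    champion = max(per_stage, key=lambda s: s.fitness)
    return MiningResult(
        selected_indices=champion.selected, C=champion.C,
        gamma=champion.gamma, fitness=champion.fitness,
        per_stage=per_stage, trace=trace,
        n_evaluations=evaluator.n_evaluations, seed=config.seed)


# ---------------------------------------------------------------------------
# multi-run consensus

@dataclass
class AppearanceFrequencies:
    Af: np.ndarray        # per-feature count of runs selecting it
    AF: int               # total appearance mass
    Af_run: np.ndarray    # per-run frequency-weighted mass
    ratios: np.ndarray    # per-run ratio Af_run / AF
    mean_ratio: float


def appearance_frequency(masks: Sequence[np.ndarray]
                         ) -> AppearanceFrequencies:
    """Cross-run appearance statistics.

    Af_j counts how many of the R runs selected feature j; AF is the sum of
    all Af_j.  A run's mass weights each of its selected features by that
    feature's Af_j, so runs agreeing with the consensus score high ratios.
    """
    A = np.vstack([np.asarray(m, dtype=bool) for m in masks]).astype(int)
    Af = A.sum(axis=0)
    AF = int(Af.sum())
    Af_run = A @ Af
    ratios = Af_run / AF if AF else np.zeros(len(masks))
    return AppearanceFrequencies(Af, AF, Af_run, ratios,
                                 float(ratios.mean()))


@dataclass
class RunEnsemble:
    """R independent mining runs plus the appearance-frequency consensus."""

    results: list[MiningResult]
    n_features: int
    frequencies: AppearanceFrequencies = field(init=False)
    best_index: int = field(init=False)

    def __post_init__(self) -> None:
        masks = [res.mask(self.n_features) for res in self.results]
        self.frequencies = appearance_frequency(masks)
        self.best_index = _select_best_index(
            self.frequencies.ratios,
            [res.fitness for res in self.results])

    @property
    def best(self) -> MiningResult:
        return self.results[self.best_index]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_features": self.n_features,
            "Af": self.frequencies.Af.tolist(),
            "AF": self.frequencies.AF,
            "ratios": self.frequencies.ratios.tolist(),
            "mean_ratio": self.frequencies.mean_ratio,
            "best_index": self.best_index,
            "runs": [asdict(r) for r in self.results],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _select_best_index(ratios: np.ndarray, fitnesses: Sequence[float]) -> int:
    above = np.flatnonzero(ratios > np.mean(ratios))
    pool = above if above.size else np.arange(len(fitnesses))
    fits = np.asarray(fitnesses)[pool]
    return int(pool[int(np.argmax(fits))])


def select_best_solution(ensemble: RunEnsemble) -> MiningResult:
    """The most accurate run among those whose appearance-frequency ratio
    exceeds the mean (fallback: global fitness maximum)."""
    return ensemble.best


def mine_ensemble(X: np.ndarray, y: np.ndarray, config: IGAConfig,
                  R: int = 20) -> RunEnsemble:
    """R independent mining runs with seeds derived from config.seed."""
    if R < 1:
        raise ValueError("need at least one run")
    seeds = [int(s.generate_state(1)[0] % 2**31)
             for s in np.random.SeedSequence(config.seed).spawn(R)]
    results = []
    for s in seeds:
        cfg = IGAConfig(**{**asdict(config), "seed": s})
        results.append(run_iga(X, y, cfg))
    return RunEnsemble(results, n_features=np.asarray(X).shape[1])


# ---------------------------------------------------------------------------
# rank-based-selection baseline

@dataclass
class RBSResult:
    ranking: list[int]            # features by single-feature accuracy, best first
    sets_by_size: dict[int, list[int]]
    accuracy_trace: list[float]   # greedy 10-CV accuracy per added feature
    C: float
    gamma: float


def rbs_baseline(X: np.ndarray, y: np.ndarray,
                 r_start: int = 30, r_end: int = 100,
                 folds: int = 10, seed: int = 0,
                 C_grid: Sequence[float] = PARAM_GRID,
                 gamma_grid: Sequence[float] = PARAM_GRID,
                 top_pool: int = 100) -> RBSResult:
    """Rank-based selection: rank features by single-feature SVM accuracy
    (grid-searched C, gamma), keep the top pool, seed with the top r_start
    and greedily add the feature maximizing 10-CV accuracy up to r_end.

    (C, gamma) for the greedy stage are grid-searched once on the seed set.
    """
    from .model import grid_search

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[1]
    pool_size = min(top_pool, n)
    r_end = min(r_end, pool_size)
    r_start = min(r_start, r_end)

    single_acc = np.empty(n)
    for j in range(n):
        _, _, acc = grid_search(X[:, [j]], y, folds, seed, C_grid, gamma_grid)
        single_acc[j] = acc
    ranking = sorted(range(n), key=lambda j: (-single_acc[j], j))
    pool = ranking[:pool_size]

    current = list(pool[:r_start])
    C, gamma, acc = grid_search(X[:, current], y, folds, seed,
                                C_grid, gamma_grid)
    sets_by_size = {r_start: list(current)}
    trace = [acc]
    remaining = [j for j in pool if j not in current]
    for _size in range(r_start + 1, r_end + 1):
        best_j, best_acc = None, -1.0
        for j in remaining:
            a = cv_accuracy(X[:, current + [j]], y, C, gamma, folds, seed)
            if a > best_acc:
                best_j, best_acc = j, a
        assert best_j is not None
        current.append(best_j)
        remaining.remove(best_j)
        sets_by_size[_size] = list(current)
        trace.append(best_acc)
    return RBSResult(ranking, sets_by_size, trace, C, gamma)
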