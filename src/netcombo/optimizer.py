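"""Five-objective genetic optimization of drug combinations.

A combination is a subset x of the drug universe, encoded as a binary
chromosome. Five objectives are maximized simultaneously:

* ``moa``      — (1/|x|) * sum of pairwise HIM distances within x
* ``smiles``   — (1/|x|) * sum of pairwise Levenshtein distances within x
* ``targets``  — (1/|x|) * sum of pairwise target shortest-path distances
* ``coverage`` — mean effect score of the members (sum available via config)
* ``neg_size`` — -|x| (prefer minimal combinations)

Pairwise criteria are normalized by the combination size |x|, not the pair
count; a config flag switches to pair-count normalization. Combinations
with fewer than two drugs are invalid and carry a sentinel objective vector
dominated by every valid one, so selection purges them without repair.

The search follows a fixed design: population 100, 20 offspring per
generation, each produced by one-point crossover (probability 0.70, two
random parents, first child kept) or bit-swap mutation (probability 0.30;
each position fires with probability 0.10 and exchanges its bit with a
uniformly chosen other position, conserving the popcount). Parents and
offspring compete under NSGA-II selection (fast non-dominated sorting,
crowding-distance truncation). A Hall of Fame keeps the 10 best
non-dominated solutions found anywhere in the run, truncated by crowding
distance, and is updated at the end of every generation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import DrugFeatureTables

logger = logging.getLogger(__name__)

__all__ = [
    "GAConfig",
    "OptimizerState",
    "StabilityResult",
    "OBJECTIVE_NAMES",
    "SENTINEL",
    "evaluate_combination",
    "initialize_population",
    "one_point_crossover",
    "swap_mutation",
    "fast_nondominated_sort",
    "crowding_distance",
    "nsga2_select",
    "HallOfFame",
    "run_optimizer",
    "stability_analysis",
]

OBJECTIVE_NAMES = ("moa", "smiles", "targets", "coverage", "neg_size")
N_OBJECTIVES = len(OBJECTIVE_NAMES)

#: worst-case objective vector for invalid (|x| < 2) combinations; finite so
#: crowding-distance arithmetic stays well defined, dominated by any valid one
SENTINEL = np.full(N_OBJECTIVES, -1e18)


@dataclass
class GAConfig:
    """Genetic-algorithm parameters (defaults are the published design)."""

    population_size: int = 100
    offspring: int = 20
    p_crossover: float = 0.70
    p_mutation: float = 0.30
    p_bit_init: float = 0.30
    p_swap: float = 0.10
    hof_size: int = 10
    generations: int = 2000
    coverage_agg: str = "mean"  # or "sum"
    pair_norm: str = "size"  # 1/|x| as published, or "pairs"

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for name in ("p_crossover", "p_mutation", "p_bit_init", "p_swap"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.coverage_agg not in ("mean", "sum"):
            raise ValueError("coverage_agg must be 'mean' or 'sum'")
        if self.pair_norm not in ("size", "pairs"):
            raise ValueError("pair_norm must be 'size' or 'pairs'")


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

class _FeatureArrays:
    """Numpy views of the feature tables for fast repeated evaluation."""

    def __init__(self, feats: DrugFeatureTables):
        self.drug_ids = feats.drug_ids
        self.him = feats.him.to_numpy(dtype=float)
        self.lev = feats.lev.to_numpy(dtype=float)
        self.sp = feats.sp.to_numpy(dtype=float)
        self.es = feats.es.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.drug_ids)


def evaluate_combination(
    bits: np.ndarray,
    feats: DrugFeatureTables | _FeatureArrays,
    config: GAConfig | None = None,
) -> np.ndarray:
    """Objective vector (moa, smiles, targets, coverage, neg_size) for x."""
    if not isinstance(feats, _FeatureArrays):
        feats = _FeatureArrays(feats)
    if config is None:
        config = GAConfig()
    idx = np.flatnonzero(bits)
    n = len(idx)
    if n < 2:
        return SENTINEL.copy()
    sub = np.ix_(idx, idx)
    iu = np.triu_indices(n, k=1)
    denom = float(n) if config.pair_norm == "size" else float(len(iu[0]))
    moa = feats.him[sub][iu].sum() / denom
    smiles = feats.lev[sub][iu].sum() / denom
    targets = feats.sp[sub][iu].sum() / denom
    es = feats.es[idx]
    coverage = es.mean() if config.coverage_agg == "mean" else es.sum()
    return np.array([moa, smiles, targets, coverage, -float(n)])


# ---------------------------------------------------------------------------
# variation operators
# ---------------------------------------------------------------------------

def initialize_population(
    n: int, length: int, p_one: float = 0.30, rng: np.random.Generator | None = None
) -> np.ndarray:
    """n chromosomes of the given length, bits i.i.d. Bernoulli(p_one)."""
    if not 0 <= p_one <= 1:
        raise ValueError(f"p_one must lie in [0, 1], got {p_one}")
    if rng is None:
        rng = np.random.default_rng()
    return (rng.random((n, length)) < p_one).astype(np.int8)


def one_point_crossover(p1: np.ndarray, p2: np.ndarray, cut: int) -> np.ndarray:
    """First child of a one-point crossover: p1[:cut] ++ p2[cut:]."""
    length = len(p1)
    if len(p2) != length:
        raise ValueError("parents must have equal length")
    if not 1 <= cut < length:
        raise ValueError(f"cut must lie in [1, {length - 1}], got {cut}")
    return np.concatenate([p1[:cut], p2[cut:]])


def swap_mutation(
    chrom: np.ndarray,
    p_swap: float = 0.10,
    rng: np.random.Generator | None = None,
    trigger_log: list | None = None,
) -> np.ndarray:
    """Sequential bit-swap mutation; the popcount is conserved.

    Each position fires independently with probability ``p_swap``; a firing
    position exchanges its current value with a uniformly chosen *other*
    position. ``trigger_log``, when given, receives the number of positions
    that fired (used by operator-frequency diagnostics).
    """
    if rng is None:
        rng = np.random.default_rng()
    length = len(chrom)
    if length < 2:
        raise ValueError("chromosome must have length >= 2")
    out = chrom.copy()
    fires = np.flatnonzero(rng.random(length) < p_swap)
    if trigger_log is not None:
        trigger_log.append(len(fires))
    for i in fires:
        j = int(rng.integers(length - 1))
        if j >= i:
            j += 1  # uniform over the other positions
        out[i], out[j] = out[j], out[i]
    return out


# ---------------------------------------------------------------------------
# NSGA-II selection
# ---------------------------------------------------------------------------

def _dominance_matrix(objs: np.ndarray) -> np.ndarray:
    """dom[i, j] = True iff vector i Pareto-dominates vector j (maximize)."""
    ge = (objs[:, None, :] >= objs[None, :, :]).all(axis=2)
    gt = (objs[:, None, :] > objs[None, :, :]).any(axis=2)
    return ge & gt


def fast_nondominated_sort(objs: np.ndarray) -> list[np.ndarray]:
    """Partition indices into Pareto fronts (front 0 = non-dominated)."""
    dom = _dominance_matrix(objs)
    n_dominators = dom.sum(axis=0).astype(int)
    fronts: list[np.ndarray] = []
    remaining = np.ones(len(objs), dtype=bool)
    while remaining.any():
        current = np.flatnonzero(remaining & (n_dominators == 0))
        if len(current) == 0:  # cannot happen with a strict partial order
            raise RuntimeError("dominance relation is not a strict partial order")
        fronts.append(current)
        remaining[current] = False
        n_dominators -= dom[current].sum(axis=0)
    return fronts


def crowding_distance(objs: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance within one front (boundary points infinite)."""
    n, m = objs.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for k in range(m):
        order = np.argsort(objs[:, k], kind="stable")
        vals = objs[order, k]
        span = vals[-1] - vals[0]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0:
            dist[order[1:-1]] += (vals[2:] - vals[:-2]) / span
    return dist


def nsga2_select(objs: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k survivors under NSGA-II ranking.

    Fronts are admitted in order; the partially admitted front is truncated
    by descending crowding distance with index order as the deterministic
    tie-break.
    """
    if k > len(objs):
        raise ValueError(f"cannot select {k} from a pool of {len(objs)}")
    chosen: list[int] = []
    for front in fast_nondominated_sort(objs):
        if len(chosen) + len(front) <= k:
            chosen.extend(front.tolist())
            if len(chosen) == k:
                break
        else:
            crowd = crowding_distance(objs[front])
            order = sorted(range(len(front)), key=lambda i: (-crowd[i], front[i]))
            chosen.extend(front[i] for i in order[: k - len(chosen)])
            break
    return np.array(chosen, dtype=int)


# ---------------------------------------------------------------------------
# Hall of Fame
# ---------------------------------------------------------------------------

class HallOfFame:
    """Pareto archive of the best solutions seen anywhere in the run.

    The archive keeps every mutually non-dominated (chromosome, objectives)
    pair encountered (duplicates by chromosome are ignored); the public
    ``members`` view truncates it to ``capacity`` by descending crowding
    distance. Invalid combinations (sentinel objectives) are never admitted.
    """

    def __init__(self, capacity: int = 10):
        self.capacity = capacity
        self._bits: list[tuple[int, ...]] = []
        self._objs: np.ndarray = np.empty((0, N_OBJECTIVES))

    def update(self, population: np.ndarray, objs: np.ndarray) -> None:
        for bits, obj in zip(population, objs):
            if obj[0] <= SENTINEL[0]:
                continue
            key = tuple(int(b) for b in bits)
            if key in self._bits:
                continue
            if len(self._objs):
                ge = (self._objs >= obj).all(axis=1)
                gt = (self._objs > obj).any(axis=1)
                if (ge & gt).any():
                    continue  # dominated by an archived solution
                le = (self._objs <= obj).all(axis=1)
                lt = (self._objs < obj).any(axis=1)
                keep = ~(le & lt)
                # equal vectors with different chromosomes are all retained
                self._bits = [b for b, k in zip(self._bits, keep) if k]
                self._objs = self._objs[keep]
            self._bits.append(key)
            self._objs = np.vstack([self._objs, obj[None, :]])

    @property
    def archive_size(self) -> int:
        return len(self._bits)

    def members(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """The <= capacity best archive members, crowding-truncated."""
        n = len(self._bits)
        if n <= self.capacity:
            order = range(n)
        else:
            crowd = crowding_distance(self._objs)
            order = sorted(range(n), key=lambda i: (-crowd[i], i))[: self.capacity]
        return [
            (np.array(self._bits[i], dtype=np.int8), self._objs[i].copy())
            for i in order
        ]

    def dominates_any_member(self, obj: np.ndarray) -> bool:
        """True if ``obj`` dominates some current HoF member (for testing)."""
        for _, member in self.members():
            if (obj >= member).all() and (obj > member).any():
                return True
        return False


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

@dataclass
class OptimizerState:
    """Final population, Hall of Fame and per-generation traces of a run."""

    population: np.ndarray
    objectives: np.ndarray
    generation: int
    hof: HallOfFame
    traces: pd.DataFrame
    rng_seed: int | None
    operator_counts: dict[str, int]
    drug_ids: list[str]

    def hof_combinations(self) -> list[dict]:
        """Decoded HoF: drug lists plus objective vectors."""
        out = []
        for bits, obj in self.hof.members():
            out.append(
                {
                    "drugs": [d for d, b in zip(self.drug_ids, bits) if b],
                    "objectives": dict(zip(OBJECTIVE_NAMES, map(float, obj))),
                }
            )
        return out

    def write_hof_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.hof_combinations(), fh, indent=2)

    def write_traces_tsv(self, path: str | Path) -> None:
        self.traces.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_optimizer(
    feats: DrugFeatureTables,
    config: GAConfig | None = None,
    seed: int | None = None,
) -> OptimizerState:
    """Run the genetic algorithm and return its final state.

    Every generation produces exactly ``config.offspring`` new individuals,
    each by crossover (probability ``p_crossover``) or mutation; the union
    of parents and offspring is reduced back to ``population_size`` by
    NSGA-II selection, and the Hall of Fame is updated.
    """
    if config is None:
        config = GAConfig()
    arrays = _FeatureArrays(feats)
    length = len(arrays)
    if length < 2:
        raise ValueError("the drug universe must contain at least 2 drugs")
    rng = np.random.default_rng(seed)

    pop = initialize_population(config.population_size, length, config.p_bit_init, rng)
    objs = np.array([evaluate_combination(c, arrays, config) for c in pop])
    hof = HallOfFame(config.hof_size)
    hof.update(pop, objs)
    operator_counts = {"crossover": 0, "mutation": 0}
    trace_rows = []

    for gen in range(1, config.generations + 1):
        children = np.empty((config.offspring, length), dtype=np.int8)
        for o in range(config.offspring):
            if rng.random() < config.p_crossover:
                operator_counts["crossover"] += 1
                i, j = rng.choice(config.population_size, size=2, replace=False)
                cut = int(rng.integers(1, length))
                children[o] = one_point_crossover(pop[i], pop[j], cut)
            else:
                operator_counts["mutation"] += 1
                parent = pop[int(rng.integers(config.population_size))]
                children[o] = swap_mutation(parent, config.p_swap, rng)
        child_objs = np.array(
            [evaluate_combination(c, arrays, config) for c in children]
        )
        pool = np.vstack([pop, children])
        pool_objs = np.vstack([objs, child_objs])
        survivors = nsga2_select(pool_objs, config.population_size)
        pop, objs = pool[survivors], pool_objs[survivors]
        hof.update(children, child_objs)

        valid = objs[:, 0] > SENTINEL[0]
        for k, name in enumerate(OBJECTIVE_NAMES):
            col = objs[valid, k] if valid.any() else np.array([np.nan])
            trace_rows.append(
                (gen, name, float(np.min(col)), float(np.mean(col)), float(np.max(col)))
            )

    traces = pd.DataFrame(
        trace_rows, columns=["generation", "objective", "min", "mean", "max"]
    )
    return OptimizerState(
        population=pop,
        objectives=objs,
        generation=config.generations,
        hof=hof,
        traces=traces,
        rng_seed=seed,
        operator_counts=operator_counts,
        drug_ids=arrays.drug_ids,
    )


# ---------------------------------------------------------------------------
# stability across runs
# ---------------------------------------------------------------------------

@dataclass
class StabilityResult:
    """Aggregate of repeated optimizer runs with distinct seeds."""

    states: list[OptimizerState]
    frequency: pd.DataFrame  # drug_a, drug_b, count over all HoF solutions
    jaccard: np.ndarray  # run x run Jaccard of HoF drug-pair sets

    def write_frequency_tsv(self, path: str | Path) -> None:
        self.frequency.to_csv(path, sep="\t", index=False)


def _hof_pair_multiset(state: OptimizerState) -> list[tuple[str, str]]:
    pairs = []
    for combo in state.hof_combinations():
        for a, b in combinations(sorted(combo["drugs"]), 2):
            pairs.append((a, b))
    return pairs


def stability_analysis(
    feats: DrugFeatureTables,
    config: GAConfig | None = None,
    n_runs: int = 10,
    seeds: Sequence[int] | None = None,
    seed: int | None = None,
) -> StabilityResult:
    """Run the optimizer ``n_runs`` times and aggregate HoF combinations.

    The combination-frequency network weighs a drug pair by the number of
    HoF solutions (across all runs) containing both drugs; per-run overlap
    is summarized as the Jaccard index of the runs' drug-pair sets.
    """
    if n_runs < 2:
        raise ValueError("stability analysis needs n_runs >= 2")
    if seeds is None:
        ss = np.random.SeedSequence(seed)
        seeds = [int(s) for s in ss.generate_state(n_runs) % (2**31)]
    elif len(seeds) != n_runs:
        raise ValueError("len(seeds) must equal n_runs")
    states = [run_optimizer(feats, config, seed=s) for s in seeds]

    counts: dict[tuple[str, str], int] = {}
    for state in states:
        for pair in _hof_pair_multiset(state):
            counts[pair] = counts.get(pair, 0) + 1
    frequency = pd.DataFrame(
        [(a, b, c) for (a, b), c in sorted(counts.items())],
        columns=["drug_a", "drug_b", "count"],
    )

    pair_sets = [set(_hof_pair_multiset(s)) for s in states]
    jac = np.ones((n_runs, n_runs))
    for i, j in combinations(range(n_runs), 2):
        union = pair_sets[i] | pair_sets[j]
        inter = pair_sets[i] & pair_sets[j]
        jac[i, j] = jac[j, i] = len(inter) / len(union) if union else 1.0
    return StabilityResult(states=states, frequency=frequency, jaccard=jac)
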