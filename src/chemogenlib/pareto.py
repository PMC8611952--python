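"""Multiobjective subset selection by an elitist genetic algorithm.

The final library is a fixed-size subset of the candidate pool (all
bioactive molecules linked to the selected representative scaffolds),
optimised simultaneously for three maximisation objectives:

* O1 — the number of distinct protein entries covered (biological
  profile breadth);
* O2 — the number of distinct representative scaffolds present
  (chemical diversity);
* O3 — the mean number of subset molecules hitting each covered protein
  (redundancy of coverage).

Subsets are evolved with non-dominated sorting, crowding-distance
selection and elitist survival (the NSGA-II scheme): individuals are
fixed-size molecule sets, crossover preserves shared molecules and
refills from the parents' symmetric difference, and mutation swaps an
included molecule for an excluded one.  The chosen library is the
first-front subset that lexicographically maximises (O1, O2, O3), and a
final completion pass appends, for every coverable protein the subset
missed, the bioactive candidate whose scaffold is carried by the most
pool molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .config import ConfigError, PipelineConfig


@dataclass(frozen=True)
class Objectives:
    """The (O1, O2, O3) maximisation triple of a candidate subset."""

    ui_coverage: int
    scaffold_count: int
    mean_hits: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.ui_coverage, self.scaffold_count, self.mean_hits)


@dataclass
class LibrarySubset:
    """A candidate compound set with its objective triple."""

    molecule_ids: tuple[str, ...]
    objectives: Objectives
    creation_index: int = 0


@dataclass
class ParetoFront:
    rank: int
    subsets: list[LibrarySubset] = field(default_factory=list)


class ObjectiveEvaluator:
    """Vectorised objective computation over a fixed candidate pool.

    Precomputes the boolean molecule-by-protein activity matrix and the
    molecule -> representative-scaffold index so that evaluating one
    subset is a couple of numpy reductions.
    """

    def __init__(
        self,
        pool: Sequence[str],
        molecule_targets: Mapping[str, set[str]],
        molecule_scaffolds: Mapping[str, str],
        representative_scaffolds: Iterable[str],
    ) -> None:
        self.pool = list(pool)
        self.mol_index = {m: i for i, m in enumerate(self.pool)}
        ui_ids = sorted(set().union(*(molecule_targets.get(m, set()) for m in self.pool)) or set())
        self.ui_ids = ui_ids
        ui_index = {u: j for j, u in enumerate(ui_ids)}
        self.activity = np.zeros((len(self.pool), len(ui_ids)), dtype=bool)
        for i, m in enumerate(self.pool):
            for u in molecule_targets.get(m, ()):  # molecules may hit nothing
                self.activity[i, ui_index[u]] = True
        reps = {s: j for j, s in enumerate(sorted(set(representative_scaffolds)))}
        self.n_reps = len(reps)
        self.scaffold_of = np.full(len(self.pool), -1, dtype=int)
        for i, m in enumerate(self.pool):
            s = molecule_scaffolds.get(m)
            if s in reps:
                self.scaffold_of[i] = reps[s]

    def evaluate_indices(self, idx: np.ndarray) -> Objectives:
        if len(idx) == 0:
            return Objectives(0, 0, 0.0)
        hits = self.activity[idx].sum(axis=0)
        covered = int((hits > 0).sum())
        scaffolds = self.scaffold_of[idx]
        n_scaffolds = int(len(np.unique(scaffolds[scaffolds >= 0])))
        mean_hits = float(hits.sum() / covered) if covered else 0.0
        return Objectives(covered, n_scaffolds, mean_hits)

    def evaluate(self, molecule_ids: Iterable[str]) -> Objectives:
        idx = np.array([self.mol_index[m] for m in molecule_ids], dtype=int)
        return self.evaluate_indices(idx)


def subset_objectives(
    subset: Iterable[str],
    molecule_targets: Mapping[str, set[str]],
    molecule_scaffolds: Mapping[str, str],
    representative_scaffolds: Iterable[str],
) -> Objectives:
    """Objective triple of an arbitrary subset (convenience wrapper)."""
    subset = list(subset)
    ev = ObjectiveEvaluator(subset, molecule_targets, molecule_scaffolds, representative_scaffolds)
    return ev.evaluate(subset)


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """Pareto domination for maximisation: a >= b everywhere, > somewhere."""
    a = tuple(a)
    b = tuple(b)
    return all(x >= y for x, y in zip(a, b)) and any(x > y for x, y in zip(a, b))


def nondominated_sort(objectives: Sequence[Sequence[float]]) -> list[list[int]]:
    """Fast non-dominated sort; returns index lists, best front first."""
    n = len(objectives)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    counts = [0] * n
    fronts: list[list[int]] = [[]]
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(objectives[i], objectives[j]):
                dominated_by[i].append(j)
                counts[j] += 1
            elif dominates(objectives[j], objectives[i]):
                dominated_by[j].append(i)
                counts[i] += 1
    for i in range(n):
        if counts[i] == 0:
            fronts[0].append(i)
    current = 0
    while fronts[current]:
        nxt: list[int] = []
        for i in fronts[current]:
            for j in dominated_by[i]:
                counts[j] -= 1
                if counts[j] == 0:
                    nxt.append(j)
        current += 1
        fronts.append(nxt)
    return [f for f in fronts if f]


def crowding_distance(objectives: Sequence[Sequence[float]]) -> np.ndarray:
    """NSGA-II crowding distance within one front."""
    n = len(objectives)
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    obj = np.asarray(objectives, dtype=float)
    for m in range(obj.shape[1]):
        order = np.argsort(obj[:, m], kind="stable")
        lo, hi = obj[order[0], m], obj[order[-1], m]
        dist[order[0]] = dist[order[-1]] = np.inf
        if hi == lo:
            continue
        for pos in range(1, n - 1):
            dist[order[pos]] += (obj[order[pos + 1], m] - obj[order[pos - 1], m]) / (hi - lo)
    return dist


def _make_child(
    a: np.ndarray,
    b: np.ndarray,
    activity: np.ndarray,
    subset_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Set-preserving recombination with coverage-greedy repair.

    The child keeps the parents' intersection and is repaired to the
    exact subset size from their symmetric difference.  Repair scans the
    shuffled candidates and first admits those that cover at least one
    protein entry the child does not cover yet (the standard greedy
    repair of set-covering recombination); remaining slots are filled
    randomly.
    """
    sa, sb = set(a.tolist()), set(b.tolist())
    common = sorted(sa & sb)
    symdiff = np.array(sorted(sa ^ sb), dtype=int)
    need = subset_size - len(common)
    if need <= 0:
        return np.array(common[:subset_size], dtype=int)
    rng.shuffle(symdiff)
    covered = activity[common].any(axis=0) if common else np.zeros(activity.shape[1], dtype=bool)
    chosen: list[int] = []
    leftovers: list[int] = []
    for cand in symdiff:
        if len(chosen) == need:
            break
        if (activity[cand] & ~covered).any():
            chosen.append(int(cand))
            covered |= activity[cand]
        else:
            leftovers.append(int(cand))
    if len(chosen) < need:
        chosen.extend(leftovers[: need - len(chosen)])
    child = np.array(common + chosen, dtype=int)
    child.sort()
    return child


def _mutate(
    idx: np.ndarray, pool_size: int, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Swap included for excluded molecules; `rate` is the expected number
    of swaps per individual."""
    n_swaps = rng.poisson(rate)
    if n_swaps == 0:
        return idx
    members = set(idx.tolist())
    for _ in range(int(n_swaps)):
        out = int(rng.integers(pool_size))
        if out in members:
            continue
        drop = int(rng.choice(np.array(sorted(members))))
        members.discard(drop)
        members.add(out)
    out_idx = np.array(sorted(members), dtype=int)
    return out_idx


@dataclass
class GAResult:
    fronts: list[ParetoFront]
    chosen: LibrarySubset
    history: list[dict]  # per-generation best objectives


def ga_select(
    pool: Sequence[str],
    molecule_targets: Mapping[str, set[str]],
    molecule_scaffolds: Mapping[str, str],
    representative_scaffolds: Iterable[str],
    cfg: PipelineConfig,
) -> GAResult:
    """Evolve fixed-size subsets of the pool and return the Pareto fronts.

    Fully reproducible from ``cfg.rng_seed``.  With ``subset_size`` equal
    to the pool size the single possible subset is returned unchanged.
    """
    pool = list(pool)
    n = len(pool)
    k = cfg.subset_size
    if n < k:
        raise ConfigError(f"pool of {n} molecules is smaller than subset_size={k}")
    ev = ObjectiveEvaluator(pool, molecule_targets, molecule_scaffolds, representative_scaffolds)
    rng = np.random.default_rng(cfg.rng_seed)

    if n == k:
        idx = np.arange(n)
        obj = ev.evaluate_indices(idx)
        subset = LibrarySubset(tuple(pool), obj, creation_index=0)
        return GAResult([ParetoFront(1, [subset])], subset, [])

    pop_size = cfg.ga_population
    population = [
        np.sort(rng.choice(n, size=k, replace=False)) for _ in range(pop_size)
    ]
    objs = [ev.evaluate_indices(ind) for ind in population]
    history = []

    for generation in range(cfg.ga_iterations):
        # binary tournaments on (rank, -crowding)
        triples = [o.as_tuple() for o in objs]
        fronts_idx = nondominated_sort(triples)
        rank = np.empty(len(population), dtype=int)
        crowd = np.empty(len(population))
        for r, front in enumerate(fronts_idx):
            rank[front] = r
            crowd[front] = crowding_distance([triples[i] for i in front])

        def tournament() -> int:
            i, j = rng.integers(len(population)), rng.integers(len(population))
            if rank[i] != rank[j]:
                return int(i if rank[i] < rank[j] else j)
            return int(i if crowd[i] >= crowd[j] else j)

        offspring = []
        for _ in range(pop_size):
            pa, pb = population[tournament()], population[tournament()]
            child = _make_child(pa, pb, ev.activity, k, rng)
            child = _mutate(child, n, cfg.ga_mutation_rate, rng)
            offspring.append(child)
        off_objs = [ev.evaluate_indices(ind) for ind in offspring]

        # elitist survival over parents + offspring
        combined = population + offspring
        combined_objs = objs + off_objs
        triples = [o.as_tuple() for o in combined_objs]
        fronts_idx = nondominated_sort(triples)
        survivors: list[int] = []
        for front in fronts_idx:
            if len(survivors) + len(front) <= pop_size:
                survivors.extend(front)
            else:
                crowd_front = crowding_distance([triples[i] for i in front])
                order = sorted(
                    range(len(front)), key=lambda p: -crowd_front[p]
                )
                survivors.extend(front[p] for p in order[: pop_size - len(survivors)])
                break
        population = [combined[i] for i in survivors]
        objs = [combined_objs[i] for i in survivors]
        best = max(objs, key=lambda o: o.as_tuple())
        history.append(
            {
                "generation": generation + 1,
                "best_O1": best.ui_coverage,
                "best_O2": best.scaffold_count,
                "best_O3": best.mean_hits,
            }
        )

    triples = [o.as_tuple() for o in objs]
    fronts_idx = nondominated_sort(triples)
    fronts = []
    for r, front in enumerate(fronts_idx, start=1):
        subsets = [
            LibrarySubset(
                tuple(pool[i] for i in population[p]), objs[p], creation_index=p
            )
            for p in front
        ]
        fronts.append(ParetoFront(rank=r, subsets=subsets))
    chosen = choose_final(fronts[0])
    return GAResult(fronts, chosen, history)


def choose_final(front1: ParetoFront) -> LibrarySubset:
    """Pick the library from the first front.

    Lexicographic maximisation over (O1, O2, O3); remaining ties go to
    the lowest creation index so the pick is deterministic under a fixed
    seed.
    """
    if not front1.subsets:
        raise ValueError("empty Pareto front")
    return max(
        front1.subsets,
        key=lambda s: (*s.objectives.as_tuple(), -s.creation_index),
    )


def complete_coverage(
    chosen: Iterable[str],
    pool: Iterable[str],
    all_ui: Iterable[str],
    molecule_targets: Mapping[str, set[str]],
    molecule_scaffolds: Mapping[str, str],
    scaffold_molecule_counts: Mapping[str, int],
    molecule_inchikeys: Mapping[str, str] | None = None,
) -> tuple[list[str], list[str], list[str]]:
    """Append molecules so every coverable protein entry is covered.

    For each protein entry with at least one bioactive pool candidate but
    no chosen molecule, add the candidate whose scaffold is shared by the
    most pool molecules (ties: more targets, then smallest InChIKey /
    molecule id).  Returns (final_library, additions, uncoverable_ui).
    """
    chosen = list(chosen)
    chosen_set = set(chosen)
    pool = list(pool)
    molecule_inchikeys = molecule_inchikeys or {}
    covered: set[str] = set()
    for m in chosen:
        covered |= molecule_targets.get(m, set())
    additions: list[str] = []
    uncoverable: list[str] = []
    for ui in sorted(set(all_ui)):
        if ui in covered:
            continue
        candidates = [m for m in pool if ui in molecule_targets.get(m, set())]
        if not candidates:
            uncoverable.append(ui)
            continue

        def key(m: str):
            scaffold = molecule_scaffolds.get(m)
            reach = scaffold_molecule_counts.get(scaffold, 0) if scaffold else 0
            n_targets = len(molecule_targets.get(m, ()))
            ident = molecule_inchikeys.get(m, m)
            return (-reach, -n_targets, ident)

        best = min(candidates, key=key)
        if best not in chosen_set:
            additions.append(best)
            chosen_set.add(best)
        covered |= molecule_targets.get(best, set())
    return chosen + additions, additions, uncoverable
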