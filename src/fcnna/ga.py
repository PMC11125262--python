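"""Genetic-algorithm electrode selection.

A chromosome is a duplicate-free, sorted subset of the electrode universe
(22 channels by default); its fitness f(x) is the cross-subject test
accuracy of the classifier trained on those channels only.  Each generation:
three parents are drawn by fitness-proportional roulette selection
(p_i = f_i / sum_j f_j, without replacement), the two fitter parents produce
two children by a two-segment crossover, the third parent is mutated with
probability 0.5, and the three children replace the three least-fit members
of the population (size stays at n = 6), so the best chromosome always
survives.  The full procedure runs several independent times; the collected
records feed two selection modes: one *fixed* channel set shared by all
subjects (best mean within-subject accuracy, ties to fewer channels) and a
*variable* per-subject set (per-subject best).

Crossover convention (reproducing the reference worked example exactly):
child1 = parent1[0..p1] + parent2[p2..end], child2 = parent2[0..p3] +
parent1[p4..end], segment ends inclusive, duplicates dropped keeping the
first occurrence, result sorted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .montage import to_user_indices

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Chromosome:
    """A candidate electrode subset (0-based, strictly increasing genes)."""

    genes: tuple

    def __post_init__(self):
        genes = tuple(int(g) for g in self.genes)
        if len(genes) == 0:
            raise ConfigurationError("chromosome must carry at least one gene")
        if len(set(genes)) != len(genes):
            raise ConfigurationError(f"duplicate genes in {genes}")
        if list(genes) != sorted(genes):
            genes = tuple(sorted(genes))
        object.__setattr__(self, "genes", genes)

    def __len__(self):
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def validate_universe(self, universe) -> None:
        bad = set(self.genes) - set(universe)
        if bad:
            raise ConfigurationError(
                f"genes {sorted(bad)} outside the channel universe")

    def to_user(self):
        """1-based channel numbers for user-facing I/O."""
        return to_user_indices(self.genes)


@dataclass
class GAConfig:
    population_size: int = 6
    generations: int = 3
    mutation_prob: float = 0.5
    selected_parents: int = 3
    children_per_generation: int = 3
    fitness_epochs: int = 300
    runs: int = 3
    init_length_range: tuple = (4, 16)
    fitness_threshold: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.generations < 1 or self.population_size < 2:
            raise ConfigurationError("need generations >= 1 and population "
                                     ">= 2")
        if self.children_per_generation >= self.population_size:
            raise ConfigurationError(
                "children_per_generation must be < population_size")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ConfigurationError("mutation_prob must be in [0, 1]")
        lo, hi = self.init_length_range
        if lo < 1 or hi < lo:
            raise ConfigurationError(
                f"invalid init_length_range {self.init_length_range}")


@dataclass
class FitnessRecord:
    chromosome: Chromosome
    fitness: float
    context: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.fitness <= 1.0:
            raise ConfigurationError(
                f"fitness must be an accuracy in [0, 1], got {self.fitness}")


# Operators ---------------------------------------------------------

def init_population(cfg: GAConfig, universe, rng: np.random.Generator):
    """n random chromosomes; lengths uniform in ``init_length_range``."""
    universe = list(universe)
    if not universe:
        raise ConfigurationError("channel universe is empty")
    lo, hi = cfg.init_length_range
    if hi > len(universe):
        raise ConfigurationError(
            f"init_length_range {cfg.init_length_range} exceeds universe "
            f"size {len(universe)}")
    pop = []
    for _ in range(cfg.population_size):
        length = int(rng.integers(lo, hi + 1))
        genes = rng.choice(universe, size=length, replace=False)
        pop.append(Chromosome(tuple(int(g) for g in genes)))
    return pop


def selection_probabilities(fitnesses) -> np.ndarray:
    """Roulette-wheel weights p_i = f_i / sum_j f_j."""
    f = np.asarray(fitnesses, dtype=float)
    if (f < 0).any():
        raise ConfigurationError("fitness values must be >= 0")
    total = f.sum()
    if total <= 0:
        logger.warning("all-zero fitness; falling back to uniform selection")
        return np.full(len(f), 1.0 / len(f))
    return f / total


def roulette_select(population, fitnesses, k: int,
                    rng: np.random.Generator):
    """k distinct parents drawn sequentially with fitness-proportional
    weights (without replacement)."""
    if k > len(population):
        raise ConfigurationError("cannot select more parents than the "
                                 "population holds")
    remaining = list(range(len(population)))
    f = np.asarray(fitnesses, dtype=float)
    chosen = []
    for _ in range(k):
        p = selection_probabilities(f[remaining])
        pick = remaining[int(rng.choice(len(remaining), p=p))]
        chosen.append(pick)
        remaining.remove(pick)
    return [population[i] for i in chosen]


def _dedup_sorted(genes):
    seen, out = set(), []
    for g in genes:
        if g not in seen:
            seen.add(g)
            out.append(g)
    return tuple(sorted(out))


def crossover(parent1: Chromosome, parent2: Chromosome,
              cut1=None, cut2=None, cut3=None, cut4=None,
              rng: np.random.Generator | None = None):
    """Two-segment crossover; cut positions drawn uniformly when omitted."""
    p1, p2 = list(parent1), list(parent2)
    if cut1 is None:
        if rng is None:
            raise ConfigurationError("random cuts need an rng")
        cut1 = int(rng.integers(0, len(p1)))
        cut2 = int(rng.integers(0, len(p2)))
        cut3 = int(rng.integers(0, len(p2)))
        cut4 = int(rng.integers(0, len(p1)))
    for cut, parent, name in ((cut1, p1, "cut1"), (cut2, p2, "cut2"),
                              (cut3, p2, "cut3"), (cut4, p1, "cut4")):
        if not 0 <= cut < len(parent):
            raise ConfigurationError(
                f"{name}={cut} out of range for parent of length {len(parent)}")
    child1 = Chromosome(_dedup_sorted(p1[:cut1 + 1] + p2[cut2:]))
    child2 = Chromosome(_dedup_sorted(p2[:cut3 + 1] + p1[cut4:]))
    return child1, child2


def mutate(parent: Chromosome, cfg: GAConfig, universe,
           rng: np.random.Generator) -> Chromosome:
    """With probability ``mutation_prob`` replace a few genes with channels
    not previously employed on this parent; length is preserved."""
    if rng.random() >= cfg.mutation_prob:
        return parent
    unused = sorted(set(universe) - set(parent.genes))
    if not unused:
        logger.warning("mutation skipped: chromosome spans the full universe")
        return parent
    k_max = max(1, math.ceil(len(parent) / 2))
    k = int(rng.integers(1, k_max + 1))
    k = min(k, len(unused), len(parent))
    replace_pos = rng.choice(len(parent), size=k, replace=False)
    new_genes = list(parent.genes)
    replacements = rng.choice(unused, size=k, replace=False)
    for pos, rep in zip(replace_pos, replacements):
        new_genes[pos] = int(rep)
    return Chromosome(_dedup_sorted(new_genes))


def next_generation(population, records, cfg: GAConfig, universe,
                    rng: np.random.Generator):
    """One generational step: roulette-select 3 parents, cross the two
    fittest, mutate the third, replace the 3 least-fit members."""
    if isinstance(records[0], FitnessRecord):
        fit = {r.chromosome.genes: r.fitness for r in records}
    else:
        fit = {c.genes: float(f) for c, f in zip(population, records)}
    missing = [c for c in population if c.genes not in fit]
    if missing:
        raise ConfigurationError("records do not cover the population")
    fitnesses = [fit[c.genes] for c in population]
    parents = roulette_select(population, fitnesses, cfg.selected_parents, rng)
    parents = sorted(parents, key=lambda c: fit[c.genes], reverse=True)
    child1, child2 = crossover(parents[0], parents[1], rng=rng)
    child3 = mutate(parents[2], cfg, universe, rng)
    order = np.argsort(fitnesses)  # ascending: least fit first
    survivors = [population[i] for i in
                 sorted(order[cfg.children_per_generation:])]
    return survivors + [child1, child2, child3][:cfg.children_per_generation]


def run_ga(fitness_fn, universe, cfg: GAConfig):
    """Execute ``cfg.runs`` independent GA runs; return records ranked by
    fitness (descending) with run/generation provenance.

    ``fitness_fn(chromosome) -> float`` computes f(x); each distinct
    chromosome is evaluated once per run (fitness cache).  A run stops early
    once ``fitness_threshold`` is reached.
    """
    root = np.random.SeedSequence(cfg.seed)
    all_records = []
    for run_idx, run_ss in enumerate(root.spawn(cfg.runs)):
        rng = np.random.default_rng(run_ss)
        cache: dict = {}

        def fitness(ch: Chromosome, generation: int) -> float:
            if ch.genes not in cache:
                f = float(fitness_fn(ch))
                cache[ch.genes] = f
                all_records.append(FitnessRecord(
                    chromosome=ch, fitness=f,
                    context={"run": run_idx, "generation": generation}))
            return cache[ch.genes]

        population = init_population(cfg, universe, rng)
        for gen in range(cfg.generations):
            fitnesses = [fitness(c, gen) for c in population]
            best = max(fitnesses)
            if cfg.fitness_threshold is not None and \
                    best >= cfg.fitness_threshold:
                logger.info("run %d reached fitness threshold %.3f at "
                            "generation %d", run_idx, best, gen)
                break
            if gen < cfg.generations - 1:
                records = [FitnessRecord(chromosome=c, fitness=f)
                           for c, f in zip(population, fitnesses)]
                population = next_generation(population, records, cfg,
                                             universe, rng)
    return sorted(all_records, key=lambda r: r.fitness, reverse=True)


def top_candidates(records, k: int = 3, per_run: bool = True):
    """The best chromosomes from ranked records (top-k per run by default)."""
    out, seen = [], set()
    if per_run:
        by_run: dict = {}
        for r in records:
            by_run.setdefault(r.context.get("run", 0), []).append(r)
        pools = [sorted(v, key=lambda r: r.fitness, reverse=True)[:k]
                 for _, v in sorted(by_run.items())]
        flat = [r for pool in pools for r in pool]
    else:
        flat = records[:k]
    for r in sorted(flat, key=lambda r: r.fitness, reverse=True):
        if r.chromosome.genes not in seen:
            seen.add(r.chromosome.genes)
            out.append(r.chromosome)
    return out


# Fixed / variable channel selection --------------------------------

def _within_subject_grid(candidates, dataset, model_config_fn, train_cfg):
    """Within-subject evaluation of every candidate for every subject.

    ``model_config_fn(n_channels)`` builds a model configuration for the
    reduced channel count.  Returns {candidate genes: {subject: report}}.
    """
    from .preprocessing import select_channels
    from .training import run_split, within_subject_split

    subjects = sorted({s for s, _ in dataset.keys()})
    grid: dict = {}
    for cand in candidates:
        reduced = {key: select_channels(ts, cand)
                   for key, ts in dataset.items()}
        per_subject = {}
        for subj in subjects:
            plan = within_subject_split(reduced, subj)
            _, report, _ = run_split(reduced, plan,
                                     model_config_fn(len(cand)), train_cfg)
            per_subject[subj] = report
        grid[cand.genes] = per_subject
    return grid


def select_fixed_channels(candidates, dataset, model_config_fn, train_cfg):
    """One shared electrode set: best mean within-subject accuracy, ties
    broken toward fewer channels.  Returns (winner, report grid)."""
    if not candidates:
        raise ConfigurationError("need at least one candidate channel set")
    grid = _within_subject_grid(candidates, dataset, model_config_fn,
                                train_cfg)
    def score(cand):
        reports = grid[cand.genes].values()
        mean_acc = float(np.mean([r.accuracy for r in reports]))
        return (-mean_acc, len(cand))
    winner = min(candidates, key=score)
    return winner, grid


def select_variable_channels(candidates, dataset, model_config_fn, train_cfg):
    """Per-subject best electrode set.  Returns {subject: (chromosome,
    report)} with provenance of which candidate won."""
    if not candidates:
        raise ConfigurationError("need at least one candidate channel set")
    grid = _within_subject_grid(candidates, dataset, model_config_fn,
                                train_cfg)
    subjects = sorted({s for s, _ in dataset.keys()})
    out = {}
    for subj in subjects:
        best = max(candidates,
                   key=lambda c: grid[c.genes][subj].accuracy)
        out[subj] = (best, grid[best.genes][subj])
    return out


def make_model_fitness(dataset, test_subject, model_config_fn, train_cfg):
    """Default fitness: cross-subject test accuracy on the chromosome's
    channels, training the classifier for ``train_cfg.epochs`` epochs."""
    from .preprocessing import select_channels
    from .training import cross_subject_split, run_split

    def fitness(chromosome: Chromosome) -> float:
        reduced = {key: select_channels(ts, chromosome)
                   for key, ts in dataset.items()}
        plan = cross_subject_split(reduced, test_subject)
        _, report, _ = run_split(reduced, plan,
                                 model_config_fn(len(chromosome)), train_cfg)
        return report.accuracy

    return fitness
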