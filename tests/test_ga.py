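"""Genetic-algorithm operators: the printed crossover example, roulette
frequencies against the fitness-proportional weights, mutation statistics,
chromosome legality under every operator, and elitist monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcnna.errors import ConfigurationError
from fcnna.ga import (Chromosome, FitnessRecord, GAConfig, crossover,
                      init_population, mutate, next_generation,
                      roulette_select, run_ga, selection_probabilities,
                      top_candidates)

UNIVERSE = list(range(1, 23))  # 1-based channel labels as genes


def test_crossover_worked_example():
    """Parents [1,3,7,15,19,22] and [2,7,15,21] with cuts (3,2,2,4) yield
    children [1,3,7,15,21] and [2,7,15,19,22]."""
    c1, c2 = crossover(Chromosome((1, 3, 7, 15, 19, 22)),
                       Chromosome((2, 7, 15, 21)), 3, 2, 2, 4)
    assert c1.genes == (1, 3, 7, 15, 21)
    assert c2.genes == (2, 7, 15, 19, 22)


def test_crossover_identical_parents(rng):
    """Identical parents can only recombine into subsets of themselves; when
    the two segments jointly cover every position the child is the parent
    itself (cut gaps may drop interior genes, as in the reference worked
    example where child 2 skips one position)."""
    p = Chromosome((2, 5, 9, 14))
    for _ in range(20):
        c1, c2 = crossover(p, p, rng=rng)
        assert set(c1) <= set(p) and set(c2) <= set(p)
    # covering cuts: second segment starts at or before the first segment end
    c1, c2 = crossover(p, p, 2, 1, 3, 0)
    assert c1.genes == p.genes and c2.genes == p.genes


def test_crossover_cut_out_of_range():
    with pytest.raises(ConfigurationError):
        crossover(Chromosome((1, 2)), Chromosome((3, 4)), 5, 0, 0, 0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(data=st.data())
def test_crossover_children_within_parent_union(data):
    g1 = data.draw(st.sets(st.integers(1, 22), min_size=1, max_size=12))
    g2 = data.draw(st.sets(st.integers(1, 22), min_size=1, max_size=12))
    p1, p2 = Chromosome(tuple(g1)), Chromosome(tuple(g2))
    cuts = (data.draw(st.integers(0, len(p1) - 1)),
            data.draw(st.integers(0, len(p2) - 1)),
            data.draw(st.integers(0, len(p2) - 1)),
            data.draw(st.integers(0, len(p1) - 1)))
    c1, c2 = crossover(p1, p2, *cuts)
    union = set(p1) | set(p2)
    for child in (c1, c2):
        assert set(child) <= union
        assert len(set(child.genes)) == len(child.genes)
        assert list(child.genes) == sorted(child.genes)


def test_chromosome_legality_rules():
    with pytest.raises(ConfigurationError):
        Chromosome(())
    with pytest.raises(ConfigurationError):
        Chromosome((1, 1, 2))
    assert Chromosome((5, 2, 9)).genes == (2, 5, 9)  # sorted on entry
    assert Chromosome((3,)).to_user() == [4]          # 0-based -> 1-based


def test_init_population(rng):
    cfg = GAConfig(seed=0)
    pop = init_population(cfg, UNIVERSE, rng)
    assert len(pop) == 6
    for c in pop:
        assert 4 <= len(c) <= 16
        assert set(c) <= set(UNIVERSE)
    forced = init_population(GAConfig(init_length_range=(22, 22)),
                             UNIVERSE, np.random.default_rng(1))
    assert all(c.genes == tuple(UNIVERSE) for c in forced)
    same1 = init_population(cfg, UNIVERSE, np.random.default_rng(42))
    same2 = init_population(cfg, UNIVERSE, np.random.default_rng(42))
    assert [c.genes for c in same1] == [c.genes for c in same2]


def test_init_range_exceeding_universe():
    with pytest.raises(ConfigurationError):
        init_population(GAConfig(init_length_range=(4, 30)), UNIVERSE,
                        np.random.default_rng(0))


def test_selection_probabilities():
    assert np.allclose(selection_probabilities([0.5, 0.5]), [0.5, 0.5])
    assert np.allclose(selection_probabilities([1.0, 0.0, 0.0]), [1, 0, 0])
    p = selection_probabilities([0.2, 0.3, 0.5])
    assert np.allclose(p, [0.2, 0.3, 0.5]) and p.sum() == pytest.approx(1.0)
    # all-zero fitness falls back to uniform
    assert np.allclose(selection_probabilities([0.0, 0.0]), [0.5, 0.5])
    with pytest.raises(ConfigurationError):
        selection_probabilities([-0.1, 0.5])


def test_roulette_frequencies_match_weights():
    """Empirical single-draw frequencies converge to f_i / sum f_j."""
    rng = np.random.default_rng(2024)
    pop = [Chromosome((i,)) for i in range(3)]
    fitnesses = [0.2, 0.3, 0.5]
    counts = np.zeros(3)
    n = 100_000
    for _ in range(n):
        pick = roulette_select(pop, fitnesses, 1, rng)[0]
        counts[pick.genes[0]] += 1
    assert np.abs(counts / n - np.array(fitnesses)).max() < 0.01


def test_roulette_dominant_parent_first():
    rng = np.random.default_rng(7)
    pop = [Chromosome((i,)) for i in range(6)]
    fitnesses = [0.99, 0.01, 0.01, 0.01, 0.01, 0.01]
    first_hits = sum(
        roulette_select(pop, fitnesses, 3, rng)[0].genes[0] == 0
        for _ in range(1000))
    assert first_hits >= 900


def test_roulette_without_replacement():
    rng = np.random.default_rng(3)
    pop = [Chromosome((i,)) for i in range(6)]
    fitnesses = [0.5] * 6
    sel = roulette_select(pop, fitnesses, 6, rng)
    assert sorted(c.genes[0] for c in sel) == list(range(6))
    sel3 = roulette_select(pop, fitnesses, 3, rng)
    assert len({c.genes for c in sel3}) == 3


def test_mutation_statistics():
    """With probability 0.5 the mutation fires in about half of the calls,
    replacements come from unused channels, and length is preserved."""
    cfg = GAConfig(mutation_prob=0.5, seed=0)
    rng = np.random.default_rng(99)
    parent = Chromosome((0, 1, 2))
    universe = list(range(22))
    fired = 0
    for _ in range(1000):
        child = mutate(parent, cfg, universe, rng)
        assert len(child) == len(parent)
        assert set(child) <= set(universe)
        if child.genes != parent.genes:
            fired += 1
            assert set(child) - set(parent), "no new gene introduced"
    assert 450 <= fired <= 550


def test_mutation_prob_zero_is_identity(rng):
    cfg = GAConfig(mutation_prob=0.0)
    parent = Chromosome((3, 4, 5))
    for _ in range(20):
        assert mutate(parent, cfg, list(range(22)), rng).genes == parent.genes


def test_mutation_full_universe_skipped(rng):
    cfg = GAConfig(mutation_prob=1.0)
    parent = Chromosome(tuple(range(22)))
    assert mutate(parent, cfg, list(range(22)), rng).genes == parent.genes


def test_next_generation_properties(rng):
    cfg = GAConfig(seed=0)
    universe = list(range(22))
    pop = init_population(cfg, universe, rng)
    fitnesses = [0.1, 0.9, 0.3, 0.5, 0.2, 0.7]
    records = [FitnessRecord(chromosome=c, fitness=f)
               for c, f in zip(pop, fitnesses)]
    for _ in range(100):
        new_pop = next_generation(pop, records, cfg, universe, rng)
        assert len(new_pop) == cfg.population_size
        # the generation's best chromosome survives replacement
        best = pop[int(np.argmax(fitnesses))]
        assert any(c.genes == best.genes for c in new_pop)
        for c in new_pop:
            assert set(c) <= set(universe)
            assert list(c.genes) == sorted(set(c.genes))


def _stub_fitness(informative=frozenset({3, 7, 11, 15})):
    """Deterministic toy fitness: overlap fraction with a target set plus a
    small size penalty (no model training)."""
    def fitness(ch: Chromosome) -> float:
        hit = len(set(ch) & informative) / len(informative)
        return max(0.0, min(1.0, 0.1 + 0.8 * hit - 0.005 * len(ch)))
    return fitness


def test_run_ga_monotone_best_fitness():
    cfg = GAConfig(generations=5, runs=2, seed=13)
    records = run_ga(_stub_fitness(), list(range(22)), cfg)
    for run in (0, 1):
        best_by_gen = {}
        for r in records:
            if r.context["run"] == run:
                g = r.context["generation"]
                best_by_gen[g] = max(best_by_gen.get(g, 0.0), r.fitness)
        running = [max(best_by_gen[g2] for g2 in range(g + 1))
                   for g in sorted(best_by_gen)]
        assert running == sorted(running), "best-so-far fitness decreased"


def test_run_ga_deterministic():
    cfg = GAConfig(generations=3, runs=1, seed=5)
    a = run_ga(_stub_fitness(), list(range(22)), cfg)
    b = run_ga(_stub_fitness(), list(range(22)), cfg)
    assert [(r.chromosome.genes, r.fitness) for r in a] == \
        [(r.chromosome.genes, r.fitness) for r in b]


def test_run_ga_threshold_stops_early():
    cfg = GAConfig(generations=50, runs=1, seed=5, fitness_threshold=0.5)
    records = run_ga(_stub_fitness(), list(range(22)), cfg)
    gens = {r.context["generation"] for r in records}
    assert max(gens) < 49


def test_run_ga_ranked_and_top_candidates():
    cfg = GAConfig(generations=3, runs=2, seed=1)
    records = run_ga(_stub_fitness(), list(range(22)), cfg)
    fits = [r.fitness for r in records]
    assert fits == sorted(fits, reverse=True)
    cands = top_candidates(records, k=3)
    assert 1 <= len(cands) <= 6
    assert cands[0].genes == records[0].chromosome.genes
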