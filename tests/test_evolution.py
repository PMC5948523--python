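import numpy as np
import pytest

import gramnas.evolution as evo
from gramnas.evolution import (
    EvolutionConfig,
    HallOfFame,
    Individual,
    adjust_fitness,
    crossover,
    evolve,
    mutate,
    similarity,
    tournament_select,
    update_hall_of_fame,
)
from gramnas.grammar import (
    Chromosome,
    ConvLayerSpec,
    DenseLayerSpec,
    TopologySpec,
    decode,
    random_chromosome,
)


def make_spec(**overrides):
    base = dict(
        batch_size=25, window_size=8, window_step=1,
        conv_layers=(ConvLayerSpec(8, 2, 1, "linear"),),
        dense_layers=(DenseLayerSpec("feedforward", 128, 0.0, "linear", "none"),),
        optimizer="SGD", learning_rate=1e-3,
    )
    base.update(overrides)
    return TopologySpec(**base)


def make_individual(spec, fn=None):
    from gramnas.grammar import DerivationResult

    derivation = DerivationResult(
        phenotype=spec, codons_used=10, tree=None, complete=True
    )
    chromosome = Chromosome(codons=tuple(range(10)))
    return Individual(chromosome=chromosome, derivation=derivation,
                      nominal_fitness=fn)


def random_individual(grammar, rng, fn=None):
    while True:
        ch = random_chromosome(256, 100, rng)
        derivation = decode(ch, grammar)
        if derivation.complete:
            return Individual(chromosome=ch, derivation=derivation,
                              nominal_fitness=fn)


class TestSimilarity:
    def test_self_similarity_is_one(self):
        ind = make_individual(make_spec())
        assert similarity(ind, ind) == 1.0

    def test_different_layer_counts_give_zero(self):
        two_conv = make_spec(
            conv_layers=(ConvLayerSpec(8, 2, 1, "linear"),
                         ConvLayerSpec(8, 2, 1, "linear"))
        )
        three_conv = make_spec(
            conv_layers=(ConvLayerSpec(8, 2, 1, "linear"),) * 3
        )
        assert similarity(make_individual(two_conv),
                          make_individual(three_conv)) == 0.0

    def test_half_matching_slots(self):
        # 1 conv + 1 dense spec has 3 + 4 + 5 + 2 = 14 slots; differ in 7
        a = make_individual(make_spec())
        b = make_individual(
            make_spec(
                batch_size=50, window_size=16, window_step=2,
                conv_layers=(ConvLayerSpec(16, 3, 2, "ReLU"),),
            )
        )
        assert similarity(a, b) == pytest.approx(0.5)

    def test_symmetric_and_bounded(self, grammar, rng):
        inds = [random_individual(grammar, rng) for _ in range(10)]
        for a in inds:
            for b in inds:
                s = similarity(a, b)
                assert 0.0 <= s <= 1.0
                assert s == similarity(b, a)
            assert similarity(a, a) == 1.0

    def test_incomplete_derivation_rejected(self, grammar):
        from gramnas.grammar import DerivationResult

        bad = Individual(
            chromosome=Chromosome(codons=(0,)),
            derivation=DerivationResult(None, 1, None, False),
        )
        with pytest.raises(ValueError):
            similarity(bad, bad)


class TestAdjustFitness:
    def test_all_dissimilar_keeps_nominal(self):
        pop = [
            make_individual(make_spec(conv_layers=(ConvLayerSpec(8, 2, 1, "linear"),) * k),
                            fn=0.5 + 0.1 * k)
            for k in range(1, 4)
        ]
        adjust_fitness(pop)
        for ind in pop:
            assert ind.adjusted_fitness == pytest.approx(ind.nominal_fitness)

    def test_identical_population_zeroed(self):
        pop = [make_individual(make_spec(), fn=0.8) for _ in range(5)]
        adjust_fitness(pop)
        for ind in pop:
            assert ind.adjusted_fitness == pytest.approx(0.0)

    def test_three_member_hand_case(self, monkeypatch):
        pop = [make_individual(make_spec(), fn=f) for f in (0.8, 0.6, 0.4)]
        sims = {(0, 1): 0.5, (0, 2): 0.25, (1, 2): 0.0}

        def fake_sim(a, b):
            i, j = pop.index(a), pop.index(b)
            return sims[tuple(sorted((i, j)))]

        monkeypatch.setattr(evo, "similarity", fake_sim)
        adjust_fitness(pop)
        assert pop[0].adjusted_fitness == pytest.approx(0.8 * (1 - 0.375))
        assert pop[1].adjusted_fitness == pytest.approx(0.6 * (1 - 0.25))
        assert pop[2].adjusted_fitness == pytest.approx(0.4 * (1 - 0.125))

    def test_matches_direct_loop_oracle(self, grammar, rng):
        # 100 random populations of size <= 10, 1e-12 agreement with the
        # nested-loop statement of the sharing formula
        for _ in range(100):
            n = int(rng.integers(2, 11))
            pop = [
                random_individual(grammar, rng, fn=float(rng.random()))
                for _ in range(n)
            ]
            adjust_fitness(pop)
            for i, ind in enumerate(pop):
                penalty = sum(
                    similarity(ind, other)
                    for j, other in enumerate(pop) if j != i
                ) / (n - 1)
                expected = ind.nominal_fitness * (1.0 - penalty)
                assert ind.adjusted_fitness == pytest.approx(expected, abs=1e-12)

    def test_fa_never_exceeds_fn(self, grammar, rng):
        pop = [random_individual(grammar, rng, fn=float(rng.random()))
               for _ in range(8)]
        adjust_fitness(pop)
        for ind in pop:
            assert ind.adjusted_fitness <= ind.nominal_fitness + 1e-12

    def test_singleton_population(self):
        pop = [make_individual(make_spec(), fn=0.7)]
        adjust_fitness(pop)
        assert pop[0].adjusted_fitness == 0.7


class TestTournament:
    def test_best_wins_when_present(self, rng):
        pop = [make_individual(make_spec(), fn=f) for f in (0.1, 0.9, 0.5)]
        for ind in pop:
            ind.adjusted_fitness = ind.nominal_fitness
        # with replacement, the best wins any tournament containing it:
        # P = 1 - (2/3)^3 ~ 0.704
        n_trials = 2000
        wins = sum(
            tournament_select(pop, 3, rng) is pop[1] for _ in range(n_trials)
        )
        p = 1 - (2 / 3) ** 3
        se = np.sqrt(p * (1 - p) / n_trials)
        assert abs(wins / n_trials - p) < 3 * se

    def test_tau_one_is_uniform(self, rng):
        pop = [make_individual(make_spec(), fn=float(i)) for i in range(4)]
        for ind in pop:
            ind.adjusted_fitness = ind.nominal_fitness
        counts = np.zeros(4)
        for _ in range(4000):
            counts[pop.index(tournament_select(pop, 1, rng))] += 1
        assert (counts > 800).all()

    def test_selection_frequency_closed_form(self, rng):
        # P(best selected) = 1 - ((|P|-1)/|P|)^tau for tau-with-replacement
        pop = [make_individual(make_spec(), fn=i / 10) for i in range(10)]
        for ind in pop:
            ind.adjusted_fitness = ind.nominal_fitness
        n_trials = 100_000
        hits = sum(
            tournament_select(pop, 3, rng) is pop[-1] for _ in range(n_trials)
        )
        p = 1 - (9 / 10) ** 3
        se = np.sqrt(p * (1 - p) / n_trials)
        assert abs(hits / n_trials - p) < 3 * se


class TestCrossover:
    def _evaluated(self, grammar, rng):
        return random_individual(grammar, rng)

    def test_rate_zero_returns_parents(self, grammar, rng):
        p1, p2 = self._evaluated(grammar, rng), self._evaluated(grammar, rng)
        c1, c2 = crossover(p1, p2, 0.0, rng)
        assert c1 == p1.chromosome and c2 == p2.chromosome

    def test_single_point_mechanics(self, rng):
        from gramnas.grammar import DerivationResult

        def ind(codons):
            return Individual(
                chromosome=Chromosome(codons=codons),
                derivation=DerivationResult(None, len(codons), None, True),
            )

        p1, p2 = ind((1, 1, 1, 1, 1)), ind((2, 2, 2, 2, 2))
        seen = set()
        for _ in range(200):
            c1, c2 = crossover(p1, p2, 1.0, rng)
            cut = next(
                i for i in range(1, 5)
                if c1.codons[:i] == (1,) * i and c1.codons[i:] == (2,) * (5 - i)
            )
            assert c2.codons == (2,) * cut + (1,) * (5 - cut)
            seen.add(cut)
        assert seen == {1, 2, 3, 4}

    def test_cut_point_within_effective_region(self, grammar, rng):
        # even at capacity 100, the exchanged tails start inside min(used)
        for _ in range(1000):
            p1, p2 = self._evaluated(grammar, rng), self._evaluated(grammar, rng)
            used = min(p1.derivation.codons_used, p2.derivation.codons_used)
            c1, c2 = crossover(p1, p2, 1.0, rng)
            assert c1.codons[used:] == p2.chromosome.codons[used:]
            assert c2.codons[used:] == p1.chromosome.codons[used:]
            assert len(c1) == len(p1.chromosome)

    def test_degenerate_effective_region(self, rng):
        from gramnas.grammar import DerivationResult

        short = Individual(
            chromosome=Chromosome(codons=(5,) * 10),
            derivation=DerivationResult(None, 1, None, True),
        )
        other = Individual(
            chromosome=Chromosome(codons=(6,) * 10),
            derivation=DerivationResult(None, 8, None, True),
        )
        c1, c2 = crossover(short, other, 1.0, rng)
        assert c1 == short.chromosome and c2 == other.chromosome


class TestMutate:
    def test_rate_zero_is_identity(self, rng):
        ch = Chromosome(codons=tuple(range(100)), codon_size=256)
        assert mutate(ch, 0.0, rng) == ch

    def test_rate_one_binary_flips_half(self, rng):
        ch = Chromosome(codons=(0,) * 100, codon_size=2, capacity=100)
        ones = [sum(mutate(ch, 1.0, rng).codons) for _ in range(200)]
        # each codon redrawn uniformly from {0,1}: expect ~50 ones
        assert abs(np.mean(ones) - 50) < 3 * np.sqrt(25 / 200)

    def test_mutated_position_count_binomial_mean(self, rng):
        ch = Chromosome(codons=(7,) * 100, codon_size=256, capacity=100)
        alpha = 0.015
        changed = []
        for _ in range(10_000):
            m = mutate(ch, alpha, rng)
            changed.append(sum(a != b for a, b in zip(m.codons, ch.codons)))
        # replacement may redraw the same value (p = 1/256)
        expected = 100 * alpha * (1 - 1 / 256)
        se = np.sqrt(100 * alpha * (1 - alpha) / 10_000)
        assert abs(np.mean(changed) - expected) < 3 * se

    def test_codons_stay_in_range(self, rng):
        ch = Chromosome(codons=(0,) * 50, codon_size=4, capacity=50)
        for _ in range(50):
            m = mutate(ch, 0.5, rng)
            assert all(0 <= c < 4 for c in m.codons)


class TestHallOfFame:
    def test_insert_into_empty(self):
        hof = HallOfFame(max_size=20)
        update_hall_of_fame(hof, make_individual(make_spec(), fn=0.5))
        assert len(hof) == 1

    def test_duplicate_phenotype_not_inserted(self):
        hof = HallOfFame(max_size=20)
        update_hall_of_fame(hof, make_individual(make_spec(), fn=0.5))
        update_hall_of_fame(hof, make_individual(make_spec(), fn=0.5))
        assert len(hof) == 1

    def test_duplicate_with_better_fitness_updates(self):
        hof = HallOfFame(max_size=20)
        update_hall_of_fame(hof, make_individual(make_spec(), fn=0.5))
        update_hall_of_fame(hof, make_individual(make_spec(), fn=0.7))
        assert len(hof) == 1
        assert hof.entries[0].nominal_fitness == 0.7

    def test_thirty_inserts_keep_top_twenty(self):
        # sort-and-truncate oracle
        hof = HallOfFame(max_size=20)
        fns = [(k + 1) / 30 for k in range(30)]
        for k, fn in enumerate(fns):
            spec = make_spec(batch_size=25 + k)  # distinct phenotypes
            update_hall_of_fame(hof, make_individual(spec, fn=fn))
        assert len(hof) == 20
        kept = [e.nominal_fitness for e in hof.entries]
        assert kept == sorted(fns, reverse=True)[:20]


class TestEvolve:
    def test_constant_fitness_stalls(self, micro_grammar):
        config = EvolutionConfig(
            population_size=6, max_generations=50, stall_generations=5, seed=0
        )
        hof, history = evolve(config, lambda spec: 0.5, micro_grammar)
        assert len(history) == config.stall_generations + 1
        assert history[-1].best_nominal == 0.5

    def test_optimizable_landscape_reaches_one(self, micro_grammar):
        # fitness counts matched target hyperparameters; the loop should
        # assemble the full target within 50 generations
        target = {"batch_size": 50, "window_size": 16, "optimizer": "RMSProp"}

        def fitness(spec):
            hits = sum(getattr(spec, k) == v for k, v in target.items())
            return hits / len(target)

        config = EvolutionConfig(
            population_size=20, max_generations=50, stall_generations=50, seed=3
        )
        hof, history = evolve(config, fitness, micro_grammar)
        assert max(h.best_nominal for h in history) == 1.0

    def test_seeded_determinism(self, micro_grammar):
        def fitness(spec):
            return (spec.batch_size + spec.window_size) / 100.0

        config = EvolutionConfig(
            population_size=8, max_generations=10, stall_generations=10, seed=42
        )
        hof1, hist1 = evolve(config, fitness, micro_grammar)
        hof2, hist2 = evolve(config, fitness, micro_grammar)
        assert hist1 == hist2
        assert [e.phenotype for e in hof1.entries] == [
            e.phenotype for e in hof2.entries
        ]

    def test_best_nominal_monotone_with_elitism(self, micro_grammar):
        def fitness(spec):
            return (spec.window_size == 16) * 0.5 + (spec.optimizer == "Adam") * 0.5

        config = EvolutionConfig(
            population_size=10, max_generations=20, stall_generations=20, seed=5
        )
        _, history = evolve(config, fitness, micro_grammar)
        bests = [h.best_nominal for h in history]
        assert all(b2 >= b1 for b1, b2 in zip(bests, bests[1:]))

    def test_raising_fitness_scores_zero(self, micro_grammar):
        def fitness(spec):
            raise RuntimeError("boom")

        config = EvolutionConfig(
            population_size=4, max_generations=3, stall_generations=2, seed=0
        )
        hof, history = evolve(config, fitness, micro_grammar)
        assert history[0].best_nominal == 0.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EvolutionConfig(population_size=1)
        with pytest.raises(ValueError):
            EvolutionConfig(tournament_size=0)
        with pytest.raises(ValueError):
            EvolutionConfig(elite_size=50, population_size=50)

    def test_table_defaults(self):
        config = EvolutionConfig()
        assert config.population_size == 50
        assert config.max_generations == 100
        assert config.stall_generations == 30
        assert config.tournament_size == 3
        assert config.crossover_rate == 0.7
        assert config.mutation_rate == 0.015
        assert config.elite_size == 1
        assert config.codon_size == 256
        assert config.chromosome_capacity == 100
        assert config.hall_of_fame_size == 20
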