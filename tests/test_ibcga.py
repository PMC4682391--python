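"""Chromosome encoding, GA operators, and the inheritable search loop."""

import itertools

import numpy as np
import pytest

from seqaffinity.encoding import fit_scaling
from seqaffinity.ibcga import (
    Chromosome,
    FitnessEvaluator,
    FitnessValue,
    Individual,
    SearchConfig,
    decode_parameter,
    evaluate_fitness,
    mutate,
    oa_crossover,
    repair,
    run_ibcga,
    tournament_select,
)


def chrom(mask_bits, c_gene=7, gamma_gene=7):
    return Chromosome(np.array(mask_bits, dtype=bool), c_gene, gamma_gene)


class TestDecodeParameter:
    @pytest.mark.parametrize(
        "gene,value", [(0, 2**-7), (7, 1.0), (15, 256.0)]
    )
    def test_grid_endpoints_and_center(self, gene, value):
        assert decode_parameter(gene) == pytest.approx(value)

    def test_grid_cardinality(self):
        grid = {decode_parameter(g) for g in range(16)}
        assert len(grid) == 16

    @pytest.mark.parametrize("gene", [-1, 16])
    def test_out_of_range_rejected(self, gene):
        with pytest.raises(ValueError):
            decode_parameter(gene)


class TestFitnessOrdering:
    def test_accuracy_dominates(self):
        assert FitnessValue(90.0, 20) > FitnessValue(89.0, 5)

    def test_ties_broken_by_fewer_features(self):
        assert FitnessValue(90.0, 10) > FitnessValue(90.0, 14)
        assert FitnessValue(90.0, 10) == FitnessValue(90.0, 10)


class TestTournamentSelect:
    def test_singleton_population(self, rng):
        ind = Individual(chrom([1, 0]), FitnessValue(50.0, 1))
        assert tournament_select([ind], rng) is ind

    def test_better_of_two_wins(self, rng):
        a = Individual(chrom([1, 0]), FitnessValue(90.0, 1))
        b = Individual(chrom([0, 1]), FitnessValue(80.0, 1))
        wins = sum(tournament_select([a, b], rng) is a for _ in range(200))
        # a wins unless b is drawn twice: P = 1 - 1/4
        assert 120 < wins < 180

    def test_win_rate_matches_pair_enumeration(self, rng):
        pop = [
            Individual(chrom([1, 0, 0]), FitnessValue(90.0, 1)),
            Individual(chrom([0, 1, 0]), FitnessValue(80.0, 1)),
            Individual(chrom([0, 0, 1]), FitnessValue(70.0, 1)),
        ]
        n = 10_000
        wins = sum(tournament_select(pop, rng) is pop[0] for _ in range(n))
        # best of 3 wins 5 of the 9 equally likely ordered draws
        assert abs(wins / n - 5 / 9) < 0.02


class TestRepair:
    def test_noop_when_popcount_matches(self, rng):
        mask = np.array([1, 1, 0, 0], bool)
        assert (repair(mask, 2, rng) == mask).all()

    def test_surplus_bits_cleared_from_existing_ones(self, rng):
        mask = np.zeros(30, bool)
        mask[:12] = True
        out = repair(mask, 10, rng)
        assert out.sum() == 10
        assert not out[12:].any()  # cleared bits were previously set

    def test_deficit_bits_added(self, rng):
        mask = np.zeros(30, bool)
        mask[:8] = True
        out = repair(mask, 10, rng)
        assert out.sum() == 10
        assert out[:8].all()

    def test_impossible_target_rejected(self, rng):
        with pytest.raises(ValueError):
            repair(np.zeros(4, bool), 5, rng)


class TestMutate:
    def test_elite_untouched(self, rng):
        c = chrom([1, 0, 1, 0], 3, 9)
        out = mutate(c, rng, is_elite=True, mutation_rate=1.0)
        assert out is c

    def test_swap_preserves_popcount(self, rng):
        mask = np.zeros(40, bool)
        mask[:10] = True
        for _ in range(50):
            out = mutate(chrom(mask), rng, False, mutation_rate=1.0)
            assert out.mask.sum() == 10

    def test_full_mask_mutates_parameters_only(self, rng):
        c = chrom([1, 1, 1], 7, 7)
        for _ in range(20):
            out = mutate(c, rng, False, mutation_rate=1.0)
            assert out.mask.all()
            assert 0 <= out.c_gene <= 15 and 0 <= out.gamma_gene <= 15


def additive_fitness(weights, c_bonus=0.0, gamma_bonus=0.0):
    """Fitness linear in mask bits (plus optional parameter-gene terms)."""

    def f(ch):
        acc = float(weights @ ch.mask)
        acc += c_bonus * ch.c_gene + gamma_bonus * ch.gamma_gene
        return FitnessValue(acc, ch.num_features)

    return f


class TestOACrossover:
    def test_identical_parents_short_circuit(self, rng):
        calls = []

        def f(ch):
            calls.append(1)
            return FitnessValue(1.0, ch.num_features)

        p = chrom([1, 0, 1, 0], 2, 3)
        child, _ = oa_crossover(p, p.copy(), f, rng, target_r=2)
        assert child == p
        assert len(calls) <= 1  # only the returned fitness, no search

    def test_at_most_nine_evaluations(self, rng):
        evals = set()

        def f(ch):
            evals.add(ch.key())
            return FitnessValue(float(ch.mask.sum()), ch.num_features)

        p1 = chrom([1] * 6 + [0] * 6, 0, 0)
        p2 = chrom([0] * 6 + [1] * 6, 15, 15)
        oa_crossover(p1, p2, f, rng, target_r=None)
        assert len(evals) <= 9

    def test_additive_fitness_returns_exhaustive_optimum(self, rng):
        """With <= 7 differing factors and additive fitness the child must be
        the optimum over all parent-level combinations."""
        for trial in range(200):
            n = int(rng.integers(6, 16))
            weights = rng.normal(size=n)
            m1 = rng.random(n) < 0.5
            m2 = m1.copy()
            ndiff = int(rng.integers(1, 6))
            flip = rng.choice(n, size=ndiff, replace=False)
            m2[flip] = ~m2[flip]
            p1 = chrom(m1, int(rng.integers(16)), int(rng.integers(16)))
            p2 = chrom(m2, p1.c_gene, p1.gamma_gene)
            f = additive_fitness(weights)
            child, fit = oa_crossover(p1, p2, f, rng, target_r=None)
            # brute force over all 2^ndiff parent-level combinations
            best = -np.inf
            for combo in itertools.product([0, 1], repeat=ndiff):
                mask = m1.copy()
                for bit, src in zip(flip, combo):
                    mask[bit] = m2[bit] if src else m1[bit]
                best = max(best, float(weights @ mask))
            assert fit.cv_accuracy == pytest.approx(best, abs=1e-9), f"trial {trial}"

    def test_parameter_genes_are_atomic_factors(self, rng):
        p1 = chrom([1, 0, 1, 0], 0, 0)
        p2 = chrom([1, 0, 1, 0], 15, 15)
        f = additive_fitness(np.zeros(4), c_bonus=1.0, gamma_bonus=2.0)
        child, _ = oa_crossover(p1, p2, f, rng, target_r=2)
        assert (child.c_gene, child.gamma_gene) == (15, 15)


class TestEvaluateFitness:
    def test_separable_data_reaches_100(self, planted_small):
        sc = planted_small["scaled"]
        truth = planted_small["truth"]
        # direct construction: well separated clouds on two columns
        import pandas as pd
        from seqaffinity.encoding import FeatureMatrix

        rng = np.random.default_rng(0)
        n = 60
        X = rng.normal(scale=0.2, size=(n, 4))
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        X[y == 1, :2] += 3.0
        m = FeatureMatrix(
            pd.DataFrame(X, index=[f"c{i}" for i in range(n)],
                         columns=list("abcd"))
        )
        ch = Chromosome(np.array([1, 1, 0, 0], bool), 10, 7)
        fit = evaluate_fitness(ch, fit_scaling(m), y, folds=10, seed=0)
        assert fit.cv_accuracy == pytest.approx(100.0)

    def test_deterministic_for_same_seed(self, planted_small):
        sc, labels = planted_small["scaled"], planted_small["labels"]
        mask = np.zeros(len(sc.property_ids), bool)
        mask[:8] = True
        ch = Chromosome(mask, 9, 6)
        a = evaluate_fitness(ch, sc, labels, folds=10, seed=4)
        b = evaluate_fitness(ch, sc, labels, folds=10, seed=4)
        assert a == b and a.cv_accuracy == b.cv_accuracy

    def test_zero_column_mask_rejected(self, planted_small):
        sc, labels = planted_small["scaled"], planted_small["labels"]
        ch = Chromosome(np.zeros(len(sc.property_ids), bool), 7, 7)
        with pytest.raises(ValueError):
            evaluate_fitness(ch, sc, labels, folds=10, seed=0)

    def test_permuted_labels_are_chance_level(self, planted_small):
        sc = planted_small["scaled"]
        y = np.r_[np.ones(60, int), np.zeros(60, int)]
        rng = np.random.default_rng(5)
        mask = np.zeros(len(sc.property_ids), bool)
        mask[:10] = True
        accs = []
        for s in range(20):
            perm = rng.permutation(y)
            accs.append(
                evaluate_fitness(Chromosome(mask, 7, 4), sc, perm, 10, s).cv_accuracy
            )
        assert abs(np.mean(accs) - 50.0) < 5.0


def test_fast_cv_path_agrees_with_public_svc_path(planted_small):
    """The low-level libsvm fitness path must reproduce the SVC-based CV
    accuracy exactly (same folds, same parameters)."""
    from seqaffinity import ibcga as mod
    from seqaffinity.models import train_classifier

    sc, labels = planted_small["scaled"], planted_small["labels"]
    ev = mod.FitnessEvaluator(sc, labels, folds=10, seed=2)
    rng = np.random.default_rng(0)
    for cg, gg in [(7, 4), (11, 8), (14, 10)]:
        mask = np.zeros(len(sc.property_ids), bool)
        mask[rng.choice(len(mask), size=8, replace=False)] = True
        ch = Chromosome(mask, cg, gg)
        fast = ev(ch)
        Xs = np.ascontiguousarray(ev.X[:, np.flatnonzero(mask)])
        correct = 0
        for tr, te in ev.folds:
            clf = train_classifier(Xs[tr], ev.y[tr], ch.c, ch.gamma)
            correct += int((clf.predict(Xs[te]) == ev.y[te]).sum())
        assert fast.cv_accuracy == pytest.approx(100.0 * correct / len(ev.y))


@pytest.fixture(scope="module")
def small_run(planted_small):
    cfg = SearchConfig(
        population_size=20,
        generations_per_stage=8,
        r_start=4,
        r_end=6,
        cv_folds=5,
        seed=3,
    )
    res = run_ibcga(planted_small["scaled"], planted_small["labels"], cfg)
    return cfg, res


class TestRunIbcga:
    def test_single_stage_when_rstart_equals_rend(self, planted_small):
        cfg = SearchConfig(
            population_size=12, generations_per_stage=4,
            r_start=4, r_end=4, cv_folds=5, seed=1,
        )
        res = run_ibcga(planted_small["scaled"], planted_small["labels"], cfg)
        assert len(res.stage_bests) == 1
        assert res.best.chromosome.num_features == 4

    def test_stage_popcounts_match_r(self, small_run):
        _, res = small_run
        assert [s.r for s in res.stage_bests] == [4, 5, 6]
        for s in res.stage_bests:
            assert s.chromosome.num_features == s.r

    def test_best_fitness_nondecreasing_within_stage(self, small_run):
        _, res = small_run
        for r in (4, 5, 6):
            accs = [acc for (rr, gen, acc) in res.generation_log if rr == r]
            assert all(b >= a - 1e-9 for a, b in zip(accs, accs[1:]))

    def test_overall_best_is_max_of_stage_bests(self, small_run):
        _, res = small_run
        assert res.best.fitness == max(s.fitness for s in res.stage_bests)

    def test_reproducible_from_seed(self, planted_small, small_run):
        cfg, res = small_run
        res2 = run_ibcga(planted_small["scaled"], planted_small["labels"], cfg)
        assert res.to_dict() == res2.to_dict()

    def test_recovers_planted_columns_on_small_problem(self, planted_small):
        """3 planted among 60: the search should find most of them."""
        cfg = SearchConfig(
            population_size=30, generations_per_stage=15,
            r_start=3, r_end=5, cv_folds=10, seed=2,
        )
        res = run_ibcga(planted_small["scaled"], planted_small["labels"], cfg)
        overlap = set(res.best.property_ids) & set(
            planted_small["truth"].informative_ids
        )
        assert len(overlap) >= 2

    def test_invalid_config_rejected(self, planted_small):
        cfg = SearchConfig(r_start=0)
        with pytest.raises(ValueError):
            run_ibcga(planted_small["scaled"], planted_small["labels"], cfg)
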