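import numpy as np
import pytest

from promoterminer.mining import (AppearanceFrequencies, Chromosome,
                                  FitnessEvaluator, IGAConfig, MiningResult,
                                  RunEnsemble, StageBest,
                                  appearance_frequency, init_population,
                                  oa_crossover, rank_selection, rbs_baseline,
                                  run_iga, swap_mutation)
from promoterminer.synth import generate_feature_matrix

TINY = IGAConfig(N_pop=6, r_start=3, r_end=5, G_max=2, cv_folds=4, seed=0)


def chrom(mask, g=7, c=7):
    return Chromosome(np.asarray(mask, dtype=bool), g, c)


class TestChromosome:
    def test_parameter_decoding_spans_the_grid(self):
        lo = chrom([1, 0], g=0, c=0)
        hi = chrom([1, 0], g=15, c=15)
        assert lo.gamma == 2.0 ** -7 and lo.C == 2.0 ** -7
        assert hi.gamma == 2.0 ** 8 and hi.C == 2.0 ** 8

    def test_invalid_gene_rejected(self):
        with pytest.raises(ValueError):
            chrom([1], g=16)


class TestInitPopulation:
    def test_cardinality_and_determinism(self):
        cfg = IGAConfig(N_pop=20, r_start=30, r_end=30, G_max=1, seed=5)
        pop1 = init_population(cfg, 167, np.random.default_rng(5))
        pop2 = init_population(cfg, 167, np.random.default_rng(5))
        assert all(c.cardinality == 30 for c in pop1)
        assert all(np.array_equal(a.mask, b.mask) for a, b in zip(pop1, pop2))

    def test_boundary_all_ones(self):
        cfg = IGAConfig(N_pop=2, r_start=10, r_end=10, G_max=1)
        pop = init_population(cfg, 10, np.random.default_rng(0))
        assert all(c.mask.all() for c in pop)

    def test_r_start_too_large(self):
        cfg = IGAConfig(N_pop=2, r_start=11, r_end=11, G_max=1)
        with pytest.raises(ValueError):
            init_population(cfg, 10, np.random.default_rng(0))


class TestRankSelection:
    def test_zero_fraction_is_identity(self):
        pop = [chrom([1, 0]), chrom([0, 1])]
        out = rank_selection(pop, [0.9, 0.1], p_s=0.0)
        assert [tuple(c.mask) for c in out] == [(1, 0), (0, 1)]

    def test_worst_replaced_by_best(self):
        pop = [chrom([1, 0, 0, 0]), chrom([0, 1, 0, 0]),
               chrom([0, 0, 1, 0]), chrom([0, 0, 0, 1])]
        out = rank_selection(pop, [0.9, 0.8, 0.7, 0.1], p_s=0.25)
        assert np.array_equal(out[3].mask, pop[0].mask)
        assert np.array_equal(out[1].mask, pop[1].mask)

    def test_mean_fitness_never_decreases(self):
        rng = np.random.default_rng(6)
        fits = rng.random(10).tolist()
        pop = [chrom(rng.random(8) < 0.5) for _ in range(10)]
        lookup = {c.key(): f for c, f in zip(pop, fits)}
        out = rank_selection(pop, fits, p_s=0.3)
        assert np.mean([lookup[c.key()] for c in out]) >= np.mean(fits)


class TestOACrossover:
    def test_identical_parents_no_evaluation(self):
        calls = []
        a = chrom([1, 1, 0, 0])
        ca, cb = oa_crossover(a, a.copy(), lambda c: calls.append(1) or 0.5,
                              r=2, rng=np.random.default_rng(0))
        assert not calls
        assert np.array_equal(ca.mask, a.mask)

    def test_children_have_exactly_r_ones(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            m1 = np.zeros(30, dtype=bool)
            m2 = np.zeros(30, dtype=bool)
            m1[rng.choice(30, 8, replace=False)] = True
            m2[rng.choice(30, 8, replace=False)] = True
            ca, cb = oa_crossover(chrom(m1), chrom(m2),
                                  lambda c: float(c.mask[:5].sum()), r=8,
                                  rng=rng)
            assert ca.cardinality == 8 and cb.cardinality == 8

    def test_wrong_cardinality_rejected(self):
        with pytest.raises(ValueError):
            oa_crossover(chrom([1, 1, 0]), chrom([1, 0, 0]),
                         lambda c: 0.5, r=2, rng=np.random.default_rng(0))

    def test_composition_beats_parents_on_additive_fitness(self):
        """On an additive objective (fraction of planted genes selected)
        the main-effect-composed child should usually match or beat the
        better parent."""
        rng = np.random.default_rng(123)
        n, r = 40, 10
        planted = set(range(12))

        def fitness(c):
            return len(set(np.flatnonzero(c.mask)) & planted) / len(planted)

        wins = 0
        trials = 100
        for _ in range(trials):
            m1 = np.zeros(n, dtype=bool)
            m2 = np.zeros(n, dtype=bool)
            m1[rng.choice(n, r, replace=False)] = True
            m2[rng.choice(n, r, replace=False)] = True
            pa, pb = chrom(m1), chrom(m2)
            ca, _ = oa_crossover(pa, pb, fitness, r=r, rng=rng)
            if fitness(ca) >= max(fitness(pa), fitness(pb)):
                wins += 1
        assert wins >= 60


class TestSwapMutation:
    def test_swap_moves_exactly_one_one(self):
        rng = np.random.default_rng(8)
        out = swap_mutation(chrom([1, 1, 0, 0]), rng)
        assert out.cardinality == 2
        assert tuple(out.mask.astype(int)) in \
            {(1, 0, 1, 0), (1, 0, 0, 1), (0, 1, 1, 0), (0, 1, 0, 1)}

    def test_cardinality_preserved(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            mask = rng.random(15) < 0.4
            if not mask.any() or mask.all():
                continue
            before = int(mask.sum())
            assert swap_mutation(chrom(mask), rng).cardinality == before

    def test_saturated_masks_are_noops(self):
        rng = np.random.default_rng(10)
        assert swap_mutation(chrom([1, 1, 1]), rng).mask.all()
        full = swap_mutation(chrom([1, 1, 1]), rng)
        assert full.cardinality == 3


class TestFitness:
    def test_separable_data_high_fitness(self, separable_matrix):
        X, y = separable_matrix
        ev = FitnessEvaluator(X, y, folds=10, seed=0)
        c = chrom(np.ones(X.shape[1], dtype=bool), g=7, c=10)
        assert ev(c) >= 0.95

    def test_permuted_labels_near_chance(self, separable_matrix):
        X, y = separable_matrix
        rng = np.random.default_rng(11)
        y_perm = rng.permutation(y)
        ev = FitnessEvaluator(X, y_perm, folds=10, seed=0)
        c = chrom(np.ones(X.shape[1], dtype=bool), g=7, c=7)
        assert abs(ev(c) - 0.5) <= 0.15

    def test_cache_hit_identical_and_free(self, separable_matrix):
        X, y = separable_matrix
        ev = FitnessEvaluator(X, y, folds=5, seed=0)
        c = chrom(np.ones(X.shape[1], dtype=bool))
        first = ev(c)
        n_eval = ev.n_evaluations
        assert ev(c.copy()) == first
        assert ev.n_evaluations == n_eval

    def test_zero_features_rejected(self, separable_matrix):
        X, y = separable_matrix
        ev = FitnessEvaluator(X, y)
        with pytest.raises(ValueError):
            ev(chrom(np.zeros(X.shape[1], dtype=bool)))


@pytest.fixture(scope="module")
def tiny_run():
    X, y, _ = generate_feature_matrix(60, 20, 5, effect=2.0, seed=3)
    cfg = IGAConfig(N_pop=6, r_start=5, r_end=5, G_max=3,
                    cv_folds=4, seed=17)
    return run_iga(X, y, cfg), X, y, cfg


class TestRunIGA:
    def test_cardinality_contract(self, tiny_run):
        result, *_ = tiny_run
        assert result.m == 5
        assert all(len(s.selected) == s.r for s in result.per_stage)

    def test_reproducible(self, tiny_run):
        result, X, y, cfg = tiny_run
        again = run_iga(X, y, cfg)
        assert again.selected_indices == result.selected_indices
        assert again.fitness == result.fitness
        assert again.trace == result.trace

    def test_best_fitness_monotone_within_stage(self, tiny_run):
        result, _, _, cfg = tiny_run
        per_stage = np.array(result.trace).reshape(-1, cfg.G_max)
        for stage in per_stage:
            assert np.all(np.diff(stage) >= 0)

    def test_json_roundtrip(self, tiny_run, tmp_path):
        result, *_ = tiny_run
        result.to_json(tmp_path / "run.json")
        back = MiningResult.from_json(tmp_path / "run.json")
        assert back.selected_indices == result.selected_indices
        assert back.per_stage == result.per_stage


class TestAppearanceFrequency:
    def test_feature_in_19_of_20_runs(self):
        masks = []
        for k in range(20):
            m = np.zeros(5, dtype=bool)
            m[0] = k != 3  # selected in 19 runs
            m[1] = True
            masks.append(m)
        freq = appearance_frequency(masks)
        assert freq.Af[0] == 19
        assert freq.AF == freq.Af.sum()

    def test_single_run_carries_all_mass(self):
        freq = appearance_frequency([np.array([True, False, True])])
        assert freq.ratios.tolist() == [1.0]

    def test_hand_enumerated_two_run_case(self):
        m1 = np.array([True, True, False])
        m2 = np.array([False, True, True])
        freq = appearance_frequency([m1, m2])
        assert freq.Af.tolist() == [1, 2, 1]
        assert freq.AF == 4
        assert freq.ratios.tolist() == [0.75, 0.75]


def _fake_result(selected, fitness, n=6):
    return MiningResult(selected_indices=selected, C=1.0, gamma=1.0,
                        fitness=fitness, per_stage=[], trace=[],
                        n_evaluations=0, seed=0)


class TestSelectBest:
    def test_identical_runs_fall_back_to_first_max(self):
        results = [_fake_result([0, 1], 0.8), _fake_result([0, 1], 0.8)]
        ens = RunEnsemble(results, n_features=6)
        assert ens.best_index == 0

    def test_only_above_mean_candidates_eligible(self):
        # run 0 overlaps the consensus, run 1 is an outlier with higher
        # fitness; the consensus run must win
        results = [_fake_result([0, 1, 2], 0.7),
                   _fake_result([0, 1, 2], 0.69),
                   _fake_result([3, 4, 5], 0.99)]
        ens = RunEnsemble(results, n_features=6)
        ratios = ens.frequencies.ratios
        assert ratios[0] > ens.frequencies.mean_ratio
        assert ratios[2] < ens.frequencies.mean_ratio
        assert ens.best_index == 0


class TestRBSBaseline:
    def test_single_informative_feature_ranks_first(self):
        X, y, truth = generate_feature_matrix(60, 6, 1, effect=3.0, seed=21)
        res = rbs_baseline(X, y, r_start=2, r_end=4, folds=4, seed=0,
                           C_grid=[1.0], gamma_grid=[1.0])
        assert res.ranking[0] == truth[0]

    def test_output_sizes_and_trace(self):
        X, y, _ = generate_feature_matrix(60, 6, 2, effect=2.0, seed=22)
        res = rbs_baseline(X, y, r_start=2, r_end=5, folds=4, seed=0,
                           C_grid=[1.0], gamma_grid=[1.0])
        assert sorted(res.sets_by_size) == [2, 3, 4, 5]
        assert len(res.accuracy_trace) == 4
        for r, s in res.sets_by_size.items():
            assert len(s) == r
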