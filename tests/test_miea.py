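"""Immune-EA operators and the full clustering loop."""

import numpy as np
import pytest

from mieaclust import (
    MIEAClustering,
    MIEAConfig,
    Vaccine,
    contingency,
    crossover,
    decode,
    encode,
    evaluate_chromosome,
    extract_vaccine,
    f_measure,
    fitness,
    immune_select,
    init_population,
    mutate,
    reverse_segment,
    run_miea,
    select,
    vaccinate,
)


class TestEncoding:
    def test_round_trip(self):
        V = np.array([[1.0, 2.0], [3.0, 4.0]])
        genes = encode(V)
        np.testing.assert_array_equal(genes, [1, 2, 3, 4])
        np.testing.assert_array_equal(decode(genes, 2, 2), V)

    def test_single_center_is_verbatim(self):
        V = np.array([[7.0, 8.0, 9.0]])
        np.testing.assert_array_equal(encode(V), [7, 8, 9])

    def test_row_major_layout(self):
        genes = np.arange(6.0)
        V = decode(genes, 3, 2)
        # center i occupies genes[i*p:(i+1)*p]
        for i in range(3):
            np.testing.assert_array_equal(V[i], genes[i * 2 : (i + 1) * 2])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            decode(np.ones(5), 2, 3)


class TestInitPopulation:
    def test_constant_feature_gene_is_constant(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
        pop = init_population(X, 2, 20, rng=0)
        np.testing.assert_array_equal(pop[:, 1], 3.0)
        np.testing.assert_array_equal(pop[:, 3], 3.0)

    def test_determinism(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        a = init_population(X, 3, 10, rng=42)
        b = init_population(X, 3, 10, rng=42)
        assert np.array_equal(a, b)

    def test_uniform_within_range(self):
        X = np.array([[0.0], [10.0]])
        pop = init_population(X, 1, 10_000, rng=1)
        assert pop.min() >= 0 and pop.max() <= 10
        assert abs(pop.mean() - 5.0) < 0.2


class TestSelect:
    def test_equal_fitness_is_uniform(self):
        pop = np.arange(4.0).reshape(4, 1)
        picked = select(pop, np.full(4, 0.3), "roulette", 20_000, rng=0)
        freqs = np.bincount(picked.ravel().astype(int), minlength=4) / 20_000
        assert np.abs(freqs - 0.25).max() < 0.02

    def test_roulette_frequencies_track_fitness(self):
        pop = np.array([[0.0], [1.0]])
        picked = select(pop, np.array([0.8, 0.2]), "roulette", 10_000, rng=1)
        frac_first = (picked.ravel() == 0).mean()
        assert abs(frac_first - 0.8) < 0.02

    def test_rank_invariant_to_monotone_rescaling(self):
        pop = np.arange(5.0).reshape(5, 1)
        f = np.array([0.1, 0.5, 0.3, 0.9, 0.2])
        a = select(pop, f, "rank", 1000, rng=np.random.default_rng(2))
        b = select(pop, f**3, "rank", 1000, rng=np.random.default_rng(2))
        assert np.array_equal(a, b)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select(np.empty((0, 2)), np.empty(0), "roulette", 1, rng=0)


class TestCrossover:
    def test_pc_zero_copies_parents(self):
        p1, p2 = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        c1, c2 = crossover(p1, p2, 0.0, rng=0)
        np.testing.assert_array_equal(c1, p1)
        np.testing.assert_array_equal(c2, p2)

    def test_positionwise_gene_conservation(self):
        rng = np.random.default_rng(3)
        p1, p2 = rng.normal(size=8), rng.normal(size=8)
        for s in range(20):
            c1, c2 = crossover(p1, p2, 1.0, rng=s)
            for pos in range(8):
                assert {c1[pos], c2[pos]} == {p1[pos], p2[pos]}

    def test_one_point_cut_shapes(self):
        p1, p2 = np.ones(4), np.full(4, 2.0)
        seen = set()
        for s in range(60):
            c1, _ = crossover(p1, p2, 1.0, rng=s)
            seen.add(tuple(c1))
        # all three cut positions occur, incl. the hand-traced cut after pos 2
        assert (1.0, 1.0, 2.0, 2.0) in seen
        assert seen == {(1, 2, 2, 2), (1, 1, 2, 2), (1, 1, 1, 2)}

    def test_two_point_and_uniform_conserve(self):
        p1, p2 = np.arange(6.0), np.arange(6.0) + 10
        for op in ("two_point", "uniform"):
            c1, c2 = crossover(p1, p2, 1.0, rng=4, op=op)
            for pos in range(6):
                assert {c1[pos], c2[pos]} == {p1[pos], p2[pos]}

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            crossover(np.ones(3), np.ones(4), 1.0, rng=0)


class TestMutate:
    def test_pm_zero_is_identity(self):
        a = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(mutate(a, 0.0, a * 0, a * 0 + 9, rng=0), a)

    def test_pm_one_stays_in_bounds(self):
        lo, hi = np.zeros(50), np.full(50, 2.0)
        out = mutate(np.full(50, 5.0), 1.0, lo, hi, rng=1)
        assert (out >= lo).all() and (out <= hi).all()
        assert not np.array_equal(out, np.full(50, 5.0))

    def test_binomial_mutation_count(self):
        lo, hi = np.zeros(100), np.ones(100)
        a = np.full(100, 0.5)
        rng = np.random.default_rng(5)
        changed = 0
        trials = 10_000
        for _ in range(trials):
            changed += int((mutate(a, 0.01, lo, hi, rng) != a).sum())
        assert abs(changed / trials - 1.0) < 0.05

    def test_segment_reversal_permutes_genes(self):
        a = np.arange(10.0)
        out = reverse_segment(a, rng=2)
        assert sorted(out) == sorted(a)
        assert not np.array_equal(out, a)  # seed 2 reverses a non-trivial slice


class TestVaccine:
    def test_full_fraction_reproduces_elite(self):
        elite = np.array([4.0, 5.0, 6.0, 7.0])
        H = extract_vaccine(elite, 0.9, 1.0, rng=0)
        assert H.positions.size == 4
        out = vaccinate(np.zeros(4), H, 1.0, rng=0)
        np.testing.assert_array_equal(out, elite)

    def test_values_come_from_elite(self):
        elite = np.random.default_rng(6).normal(size=12)
        H = extract_vaccine(elite, 0.5, 0.4, rng=1)
        np.testing.assert_array_equal(H.values, elite[H.positions])
        assert H.source_fitness == 0.5

    def test_ceiling_size(self):
        H = extract_vaccine(np.zeros(8), 0.1, 0.25, rng=2)
        assert H.positions.size == 2

    def test_vaccinate_pv_zero_identity(self):
        a = np.array([9.0, 9.0])
        H = Vaccine(np.array([0]), np.array([1.0]), 0.5)
        np.testing.assert_array_equal(vaccinate(a, H, 0.0, rng=0), a)

    def test_vaccinate_overwrites_positions(self):
        H = Vaccine(np.array([0, 2]), np.array([1.0, 3.0]), 0.5)
        out = vaccinate(np.full(4, 9.0), H, 1.0, rng=0)
        np.testing.assert_array_equal(out, [1, 9, 3, 9])

    def test_position_out_of_range(self):
        H = Vaccine(np.array([5]), np.array([1.0]), 0.5)
        with pytest.raises(ValueError, match="out of range"):
            vaccinate(np.zeros(3), H, 1.0, rng=0)

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            Vaccine(np.array([1, 1]), np.array([0.0, 0.0]), 0.5)


class TestImmuneSelect:
    def test_tie_accepts_vaccinated(self):
        a = np.array([1.0, 2.0])
        out = immune_select(a, a.copy(), lambda c: 0.5)
        np.testing.assert_array_equal(out, a)

    def test_returns_fitter(self):
        fvals = {0.0: 0.5, 1.0: 0.9}
        out = immune_select(np.array([0.0]), np.array([1.0]), lambda c: fvals[c[0]])
        assert out[0] == 1.0

    def test_never_degrades_on_random_pairs(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 2))

        def f(chrom):
            return evaluate_chromosome(chrom, X, 2, 2.0)[2]

        for _ in range(100):
            a, b = rng.normal(size=4), rng.normal(size=4)
            kept = immune_select(a, b, f)
            assert f(kept) == pytest.approx(max(f(a), f(b)))


class TestRunMiea:
    def test_separable_limit_recovers_labels(self, separable_toy):
        res = run_miea(separable_toy, MIEAConfig(c=3, seed=1, max_gens=60))
        cont = contingency(separable_toy.labels, res.hard_labels)
        assert f_measure(cont) == 1.0

    def test_elite_history_non_increasing(self, three_gaussians):
        for seed in range(3):
            res = run_miea(three_gaussians, MIEAConfig(c=3, seed=seed, max_gens=30))
            assert (np.diff(res.J_history) <= 0).all()

    def test_determinism(self, three_gaussians):
        cfg = MIEAConfig(c=3, seed=9, max_gens=20)
        a = run_miea(three_gaussians, cfg)
        b = run_miea(three_gaussians, cfg)
        assert np.array_equal(a.best_chromosome, b.best_chromosome)
        assert np.array_equal(a.J_history, b.J_history)
        assert np.array_equal(a.hard_labels, b.hard_labels)

    def test_result_respects_feature_bounds(self, three_gaussians):
        res = run_miea(three_gaussians, MIEAConfig(c=3, seed=2, max_gens=20))
        lo = three_gaussians.features.min(axis=0)
        hi = three_gaussians.features.max(axis=0)
        assert (res.prototypes >= lo).all() and (res.prototypes <= hi).all()

    def test_fitness_matches_objective(self, three_gaussians):
        res = run_miea(three_gaussians, MIEAConfig(c=3, seed=3, max_gens=15))
        assert res.f_best == pytest.approx(fitness(res.J_history[-1]))

    def test_stall_stop_triggers_when_enabled(self, separable_toy):
        res = run_miea(
            separable_toy,
            MIEAConfig(c=3, seed=4, max_gens=500, tau=1e-3, patience=5),
        )
        assert res.generations_run < 500

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            MIEAConfig(p_c=1.5)
        with pytest.raises(ValueError):
            MIEAConfig(pop_size=1)
        with pytest.raises(ValueError):
            MIEAConfig(m=1.0)


class TestMIEAClusteringEstimator:
    def test_sklearn_interface(self, three_gaussians):
        from sklearn.base import clone

        est = MIEAClustering(n_clusters=3, max_gens=10, random_state=0)
        cloned = clone(est)
        labels = cloned.fit_predict(three_gaussians.features)
        assert labels.shape == (300,)
        assert set(labels.tolist()) <= {0, 1, 2}
        assert cloned.cluster_centers_.shape == (3, 2)

    def test_predict_consistent_with_fit(self, three_gaussians):
        est = MIEAClustering(n_clusters=3, max_gens=10, random_state=1)
        est.fit(three_gaussians.features)
        assert np.array_equal(est.predict(three_gaussians.features), est.labels_)

    def test_cluster_bound_error(self):
        with pytest.raises(ValueError, match="c <= n-1"):
            MIEAClustering(n_clusters=5, random_state=0).fit(np.eye(4))
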