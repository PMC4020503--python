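import math

import numpy as np
import pytest

from arealscan.geo import RegionMap
from arealscan.registry import ExpectedCounts
from arealscan.scan import (
    ClusterResult,
    ReplicateDistribution,
    ScanConfig,
    Window,
    attach_pvalues,
    circular_windows,
    gumbel_pvalue,
    mc_pvalue,
    monte_carlo_null,
    poisson_llr,
    relative_risk,
    run_scan,
    scan,
)
from conftest import oracle_best_circular, oracle_circular_windows, oracle_llr


def expected_counts(E, periods=("all",)):
    E = np.asarray(E, dtype=float)
    return ExpectedCounts(
        tuple(f"R{i}" for i in range(len(E))), periods, E[:, None], int(round(E.sum()))
    )


class TestPoissonLlr:
    def test_primary_cluster_rounded_inputs(self):
        # frozen by direct evaluation of the closed form on the printed,
        # rounded inputs (the unrounded-E value is lower; see docs)
        assert poisson_llr(1300, 1118, 3526) == pytest.approx(21.12780541, abs=1e-6)

    def test_n_equal_E_is_zero(self):
        assert poisson_llr(50, 50.0, 100) == 0.0

    def test_n_below_E_is_zero(self):
        assert poisson_llr(10, 50.0, 100) == 0.0

    def test_all_cases_inside(self):
        N, E = 20, 4.0
        assert poisson_llr(N, E, N) == pytest.approx(N * math.log(N / E))

    def test_errors(self):
        with pytest.raises(ValueError):
            poisson_llr(5, 0.0, 10)
        with pytest.raises(ValueError):
            poisson_llr(11, 5.0, 10)

    def test_monotone_in_n_above_E(self):
        E, N = 10.0, 200
        vals = [poisson_llr(n, E, N) for n in range(11, 100)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            N = int(rng.integers(1, 500))
            n = int(rng.integers(0, N + 1))
            E = float(rng.uniform(0.1, N - 0.05))
            assert poisson_llr(n, E, N) == pytest.approx(oracle_llr(n, E, N))


class TestRelativeRisk:
    def test_primary_cluster(self):
        rr = relative_risk(1300, 1118, 3526)
        assert round(rr, 2) == 1.26
        assert rr == pytest.approx(1.257861635, abs=1e-6)

    def test_secondary_cluster_rounded_inputs(self):
        assert relative_risk(65, 38, 3526) == pytest.approx(1.7238705, abs=1e-6)

    def test_n_equal_E_is_one(self):
        assert relative_risk(25, 25.0, 100) == pytest.approx(1.0)

    def test_all_inside_is_infinite_sentinel(self):
        assert relative_risk(10, 3.0, 10) == math.inf

    def test_empty_window_zero(self):
        assert relative_risk(0, 3.0, 10) == 0.0


class TestCircularWindows:
    def test_three_equidistant_singletons_only(self):
        # equilateral triangle, equal weights, cap 0.34: any pair exceeds it
        m = RegionMap(
            ("A", "B", "C"),
            np.array([[0.0, 0.0], [1.0, 0.0], [0.5, math.sqrt(3) / 2]]),
        )
        wins = circular_windows(m, [1.0, 1.0, 1.0], max_fraction=0.34)
        assert sorted(w.members for w in wins) == [("A",), ("B",), ("C",)]

    def test_five_region_line_matches_brute_force(self, line_map):
        weights = [1.0] * 5
        wins = circular_windows(line_map, weights, max_fraction=0.5)
        got = {frozenset(w.members) for w in wins}
        want = oracle_circular_windows(
            line_map.coords, line_map.region_ids, weights, 0.5
        )
        assert got == want
        assert all(w.size <= 2 for w in wins)

    def test_random_maps_match_brute_force(self, random_map):
        rng = np.random.default_rng(12)
        for seed in range(5):
            m = random_map(9, seed=seed)
            weights = rng.uniform(0.5, 2.0, size=9)
            got = {
                frozenset(w.members)
                for w in circular_windows(m, weights, max_fraction=0.5)
            }
            want = oracle_circular_windows(m.coords, m.region_ids, weights, 0.5)
            assert got == want

    def test_heavy_center_keeps_singleton(self):
        m = RegionMap(("A", "B", "C"), np.array([[0.0, 0], [1, 0], [2, 0.1]]))
        wins = circular_windows(m, [6.0, 2.0, 2.0], max_fraction=0.5)
        assert ("A",) in [w.members for w in wins]

    def test_members_are_nested_nearest_neighbors(self, random_map):
        m = random_map(10, seed=2)
        wins = circular_windows(m, np.ones(10), max_fraction=0.5)
        by_center = {}
        for w in wins:
            by_center.setdefault(w.center, []).append(w)
        for center, group in by_center.items():
            group.sort(key=lambda w: w.size)
            for a, b in zip(group, group[1:]):
                assert set(a.members) <= set(b.members)

    def test_bad_fraction_rejected(self, line_map):
        with pytest.raises(ValueError):
            circular_windows(line_map, [1.0] * 5, max_fraction=0.6)
        with pytest.raises(ValueError):
            circular_windows(line_map, [1.0] * 5, max_fraction=0.0)


class TestScan:
    def test_null_data_no_clusters(self, line_map):
        E = expected_counts([4.0, 4.0, 4.0, 4.0, 4.0])
        wins = circular_windows(line_map, np.ones(5), 0.5)
        # ExpectedCounts regions are R0..R4; rebuild windows on those ids
        wins = [Window(tuple(f"R{line_map.region_ids.index(m)}" for m in w.members),
                       f"R{line_map.region_ids.index(w.center)}", w.radius_rank)
                for w in wins]
        results = scan([4, 4, 4, 4, 4], E, wins)
        assert results == []

    def test_single_hot_region_is_rank_one(self):
        rng = np.random.default_rng(0)
        ids = tuple(f"R{i}" for i in range(10))
        m = RegionMap(ids, rng.uniform(0, 1, (10, 2)))
        E_vec = np.full(10, 5.0)
        obs = np.full(10, 5)
        obs[3] = 20
        E_vec = E_vec * obs.sum() / E_vec.sum()
        E = expected_counts(E_vec)
        wins = circular_windows(m, np.ones(10), 0.5)
        results = scan(obs, E, wins)
        best_llr, best_fam = oracle_best_circular(
            m.coords, ids, np.ones(10), obs, E_vec, obs.sum()
        )
        assert results[0].llr == pytest.approx(best_llr)
        assert frozenset(results[0].members) == best_fam
        assert "R3" in results[0].members

    def test_rank1_matches_brute_force_on_small_maps(self, random_map):
        rng = np.random.default_rng(100)
        for seed in range(8):
            n = int(rng.integers(4, 9))
            m = random_map(n, seed=seed)
            weights = rng.uniform(0.5, 2.0, size=n)
            E_vec = rng.uniform(1.0, 6.0, size=n)
            obs = rng.poisson(E_vec * rng.choice([1.0, 1.0, 3.0], size=n))
            if obs.sum() == 0:
                continue
            E_vec = E_vec * obs.sum() / E_vec.sum()
            E = ExpectedCounts(m.region_ids, ("all",), E_vec[:, None], int(obs.sum()))
            wins = circular_windows(m, weights, 0.5)
            results = scan(obs, E, wins)
            best_llr, best_fam = oracle_best_circular(
                m.coords, m.region_ids, weights, obs, E_vec, obs.sum()
            )
            if best_llr <= 0:
                assert results == []
            else:
                assert results[0].llr == pytest.approx(best_llr)
                assert frozenset(results[0].members) == best_fam

    def test_secondary_clusters_disjoint(self, random_map):
        m = random_map(20, seed=42)
        rng = np.random.default_rng(1)
        E_vec = rng.uniform(2, 6, size=20)
        obs = rng.poisson(E_vec) + rng.integers(0, 10, size=20)
        E_vec = E_vec * obs.sum() / E_vec.sum()
        E = ExpectedCounts(m.region_ids, ("all",), E_vec[:, None], int(obs.sum()))
        results = scan(obs, E, circular_windows(m, np.ones(20), 0.5))
        used = set()
        for r in results:
            assert used.isdisjoint(r.members)
            used.update(r.members)

    def test_unconditioned_expected_rejected(self):
        E = ExpectedCounts(("R0", "R1"), ("all",), np.array([[1.0], [1.0]]), 2)
        wins = [Window(("R0",), "R0", 1)]
        with pytest.raises(ValueError, match="N"):
            scan([2, 1], E, wins)  # observed total != N

    def test_whole_area_window_scores_zero(self):
        E = expected_counts([3.0, 7.0])
        wins = [Window(("R0", "R1"), "R0", 2)]
        assert scan([3, 7], E, wins) == []


class TestMonteCarlo:
    def test_zero_total_all_zero(self):
        E = ExpectedCounts(("R0", "R1"), ("all",), np.zeros((2, 1)), 0)
        dist = monte_carlo_null(E, [Window(("R0",), "R0", 1)], R=25, seed=0)
        assert np.all(dist.max_llr == 0)

    def test_trinomial_enumeration_two_regions(self):
        # E = (1,1), N = 2, singleton windows.  The max llr is 2*ln2 when
        # both cases land in one region (prob 1/2) and 0 otherwise.
        E = ExpectedCounts(("R0", "R1"), ("all",), np.array([[1.0], [1.0]]), 2)
        wins = [Window(("R0",), "R0", 1), Window(("R1",), "R1", 1)]
        dist = monte_carlo_null(E, wins, R=8000, seed=7)
        vals = np.unique(np.round(dist.max_llr, 12))
        assert set(vals) <= {0.0, round(2 * math.log(2), 12)}
        frac = np.mean(dist.max_llr > 0)
        assert frac == pytest.approx(0.5, abs=0.02)  # 3 sd ~ 0.017

    def test_seed_determinism(self):
        E = expected_counts([5.0, 5.0, 5.0])
        wins = [Window((f"R{i}",), f"R{i}", 1) for i in range(3)]
        d1 = monte_carlo_null(E, wins, R=50, seed=123)
        d2 = monte_carlo_null(E, wins, R=50, seed=123)
        np.testing.assert_array_equal(d1.max_llr, d2.max_llr)

    def test_different_seeds_differ(self):
        E = expected_counts([5.0, 5.0, 5.0])
        wins = [Window((f"R{i}",), f"R{i}", 1) for i in range(3)]
        d1 = monte_carlo_null(E, wins, R=50, seed=1)
        d2 = monte_carlo_null(E, wins, R=50, seed=2)
        assert not np.array_equal(d1.max_llr, d2.max_llr)


class TestPValues:
    def make_dist(self, values, seed=None):
        return ReplicateDistribution(np.asarray(values, float), seed, len(values))

    def test_floor_with_999_replicates(self):
        dist = self.make_dist(np.linspace(0, 5, 999))
        assert mc_pvalue(10.0, dist) == pytest.approx(0.001)

    def test_observed_zero_gives_one(self):
        dist = self.make_dist(np.linspace(0, 5, 999))
        assert mc_pvalue(0.0, dist) == 1.0

    def test_median_rank(self):
        # observed above exactly 499 of 999 maxima -> 500 exceed -> p = 0.5+1/1000... rank formula
        vals = np.arange(999, dtype=float)
        assert mc_pvalue(499.5, self.make_dist(vals)) == pytest.approx(0.5)

    def test_values_on_grid(self):
        dist = self.make_dist(np.arange(9, dtype=float))
        ps = {mc_pvalue(x, dist) for x in np.linspace(-1, 10, 40)}
        assert ps <= {k / 10 for k in range(1, 11)}

    def test_gumbel_at_location(self):
        rng = np.random.default_rng(5)
        draws = rng.gumbel(loc=2.0, scale=0.5, size=999)
        dist = self.make_dist(np.clip(draws, 0, None))
        m = np.mean(dist.max_llr)
        s = np.std(dist.max_llr, ddof=1)
        beta = s * math.sqrt(6) / math.pi
        mu = m - 0.5772156649015329 * beta
        assert gumbel_pvalue(mu, dist) == pytest.approx(1 - math.exp(-1), abs=1e-9)

    def test_gumbel_monotone_decreasing(self):
        rng = np.random.default_rng(6)
        dist = self.make_dist(np.abs(rng.gumbel(3, 1, size=999)))
        xs = np.linspace(0, 10, 50)
        ps = [gumbel_pvalue(x, dist) for x in xs]
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_gumbel_parameter_recovery(self):
        rng = np.random.default_rng(7)
        draws = rng.gumbel(loc=2.0, scale=0.5, size=10_000)
        m, s = float(np.mean(draws)), float(np.std(draws, ddof=1))
        beta = s * math.sqrt(6) / math.pi
        mu = m - 0.5772156649015329 * beta
        assert mu == pytest.approx(2.0, abs=0.03)
        assert beta == pytest.approx(0.5, abs=0.03)

    def test_gumbel_zero_variance_errors(self):
        dist = self.make_dist(np.full(100, 2.0))
        with pytest.raises(ValueError, match="Monte Carlo"):
            gumbel_pvalue(1.0, dist)

    def test_gumbel_needs_replicates(self):
        with pytest.raises(ValueError, match="10 replicates"):
            gumbel_pvalue(1.0, self.make_dist([1.0, 2.0]))


class TestRunScan:
    def test_attaches_pvalues_against_max_distribution(self):
        rng = np.random.default_rng(8)
        ids = tuple(f"R{i}" for i in range(12))
        m = RegionMap(ids, rng.uniform(0, 1, (12, 2)))
        E_vec = np.full(12, 10.0)
        obs = rng.poisson(10.0, size=12)
        obs[5] += 40
        E_vec = E_vec * obs.sum() / E_vec.sum()
        E = ExpectedCounts(ids, ("all",), E_vec[:, None], int(obs.sum()))
        wins = circular_windows(m, np.ones(12), 0.5)
        results, dist = run_scan(obs, E, wins, ScanConfig(replicates=199, seed=3, gumbel=True))
        assert results[0].p_mc == mc_pvalue(results[0].llr, dist)
        assert results[0].p_gumbel is not None
        assert results[0].p_mc <= 0.05
        for r in results:
            assert r.p_mc in {k / 200 for k in range(1, 201)}
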