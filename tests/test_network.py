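import datetime as dt
import itertools

import numpy as np
import pytest

import oracles
from comigrate.io import SeasonCounts
from comigrate.network import (
    EmptyNetworkError,
    build_network,
    filter_low_abundance,
    holm_adjust,
    spearman_lag1,
)
from comigrate.simulate import simulate
from conftest import two_group_scenario


def season_from_matrix(mat, year=2015, missing=()):
    mat = np.asarray(mat)
    days = tuple(dt.date(year, 4, 1) + dt.timedelta(days=i) for i in range(mat.shape[1]))
    species = tuple(f"sp{i}" for i in range(mat.shape[0]))
    return SeasonCounts(
        year, days, mat, species, frozenset(days[i] for i in missing)
    )


class TestFilterLowAbundance:
    def season_with_totals(self, totals):
        mat = np.zeros((len(totals), 5), dtype=int)
        mat[:, 0] = totals
        return season_from_matrix(mat)

    def test_quantile_threshold_hand_computed(self):
        # totals (10, 20, 30, 40): the 25th linear-interpolation percentile
        # is 17.5, so three species survive
        sc = self.season_with_totals([10, 20, 30, 40])
        assert filter_low_abundance(sc, q=0.25) == ["sp1", "sp2", "sp3"]

    def test_equal_totals_all_retained(self):
        sc = self.season_with_totals([7, 7, 7, 7])
        assert filter_low_abundance(sc) == ["sp0", "sp1", "sp2", "sp3"]

    def test_zero_total_species_always_dropped(self):
        sc = self.season_with_totals([0, 0, 0, 100])
        assert filter_low_abundance(sc) == ["sp3"]

    def test_pooled_reference_distribution(self):
        sc = self.season_with_totals([10, 20, 30, 40])
        retained = filter_low_abundance(
            sc, q=0.25, reference_totals=np.array([35, 36, 37, 38])
        )
        assert retained == ["sp3"]

    def test_too_few_species_rejected(self):
        sc = season_from_matrix(np.ones((3, 5), dtype=int))
        with pytest.raises(ValueError, match="4 species"):
            filter_low_abundance(sc)


class TestSpearmanLag1:
    def test_perfect_lagged_agreement(self):
        a = np.arange(1.0, 13.0)
        b = np.concatenate([a[1:], [99.0]])  # b_t = a_{t+1}
        rho, p = spearman_lag1(a, b)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_reversal(self):
        a = np.arange(1.0, 13.0)
        b = np.arange(24.0, 0.0, -2.0)
        rho, _ = spearman_lag1(a, b)
        assert rho == pytest.approx(-1.0)

    def test_tied_series_matches_brute_force(self):
        a = np.array([0, 0, 1, 3, 3, 7, 5, 5, 2, 1, 0, 0], dtype=float)
        b = np.array([1, 0, 0, 2, 4, 4, 9, 6, 6, 2, 1, 1], dtype=float)
        rho, p = spearman_lag1(a, b)
        rho_o, p_o = oracles.spearman_lag1_brute(a, b)
        assert rho == pytest.approx(rho_o, abs=1e-12)
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_constant_series_undefined(self):
        a = np.full(12, 3.0)
        b = np.arange(12.0)
        rho, p = spearman_lag1(a, b)
        assert np.isnan(rho) and np.isnan(p)

    def test_missing_days_drop_adjacent_pairs(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(5, 20).astype(float)
        b = rng.poisson(5, 20).astype(float)
        valid = np.ones(20, dtype=bool)
        valid[7] = False  # kills lag pairs at t=7 and t=8
        rho, _ = spearman_lag1(a, b, valid=valid)
        keep = [t for t in range(1, 20) if t != 7 and t != 8]
        rho_o, _ = oracles.spearman_lag1_brute(
            np.concatenate([[0], a[keep]]), np.concatenate([b[[t - 1 for t in keep]], [0]])
        )
        assert rho == pytest.approx(rho_o, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="lag pairs"):
            spearman_lag1(np.arange(5.0), np.arange(5.0))


class TestHolm:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.02, 0.03]), [0.03, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]).tolist() == [0.2]

    def test_all_zeros(self):
        assert holm_adjust([0.0, 0.0, 0.0]).tolist() == [0.0, 0.0, 0.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    def test_random_vectors_match_step_down_formula(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 12))
            np.testing.assert_allclose(
                holm_adjust(p), oracles.holm_brute(list(p)), atol=1e-15
            )


class TestBuildNetwork:
    def test_planted_groups_give_within_group_cliques(self):
        sc = two_group_scenario(noise="none", jitter=0.0, year_noise=0.0,
                                sep_sigmas=5.0, season_length=60)
        seasons, truth = simulate(sc)
        net = build_network(seasons[0])
        groups = {sp: truth[sp] for sp in net.species}
        expected = {
            frozenset((i, j))
            for i, j in itertools.combinations(range(net.n_nodes), 2)
            if groups[net.species[i]] == groups[net.species[j]]
        }
        assert net.edges == expected

    def test_unattainable_threshold_empties_edges(self):
        sc = two_group_scenario(noise="poisson")
        seasons, _ = simulate(sc)
        net = build_network(seasons[0], r_min=1.01)
        assert net.n_edges == 0

    def test_species_order_invariance(self):
        sc = two_group_scenario(noise="poisson", seed=5)
        seasons, _ = simulate(sc)
        season = seasons[0]
        perm = [3, 0, 6, 2, 7, 5, 1, 4]
        shuffled = SeasonCounts(
            season.year,
            season.days,
            season.counts[perm],
            tuple(season.species[i] for i in perm),
            season.missing_days,
        )
        e1 = set(map(frozenset, build_network(season).edge_list()))
        e2 = set(map(frozenset, build_network(shuffled).edge_list()))
        assert e1 == e2

    def test_matrices_match_brute_force_per_pair(self, rng):
        """Vectorized rho/p matrices equal explicit rank-then-Pearson plus
        step-down Holm over the same family, on random small instances."""
        for _ in range(10):
            n_sp = int(rng.integers(4, 7))
            mat = rng.poisson(4.0, size=(n_sp, 15))
            mat[:, 0] += 1  # guard against all-constant rows
            season = season_from_matrix(mat)
            try:
                net = build_network(season, q=0.0)
            except EmptyNetworkError:
                continue
            idx = {sp: i for i, sp in enumerate(season.species)}
            raw = {}
            for a in net.species:
                for b in net.species:
                    if a == b:
                        continue
                    i, j = idx[a], idx[b]
                    rho_o, p_o = oracles.spearman_lag1_brute(
                        mat[i].astype(float), mat[j].astype(float)
                    )
                    ia, ib = net.species.index(a), net.species.index(b)
                    if np.isnan(rho_o):
                        assert np.isnan(net.rho[ia, ib])
                    else:
                        assert net.rho[ia, ib] == pytest.approx(rho_o, abs=1e-12)
                        assert net.p_raw[ia, ib] == pytest.approx(p_o, abs=1e-12)
                        raw[(ia, ib)] = p_o
            adj = oracles.holm_brute([raw[k] for k in sorted(raw)])
            for (k, p_adj_o) in zip(sorted(raw), adj):
                assert net.p_adj[k] == pytest.approx(p_adj_o, abs=1e-12)

    def test_adjusted_never_below_raw_and_thresholds_monotone(self):
        sc = two_group_scenario(noise="poisson", seed=3, jitter=2.0)
        seasons, _ = simulate(sc)
        net = build_network(seasons[0])
        ok = ~np.isnan(net.p_raw)
        assert (net.p_adj[ok] >= net.p_raw[ok] - 1e-15).all()
        n_strict = build_network(seasons[0], r_min=0.7).n_edges
        n_loose_alpha = build_network(seasons[0], alpha=0.5).n_edges
        assert n_strict <= net.n_edges <= n_loose_alpha

    def test_symmetrization_and_is_subset_of_or(self):
        sc = two_group_scenario(noise="poisson", seed=9, jitter=2.0)
        seasons, _ = simulate(sc)
        e_or = build_network(seasons[0], symmetrization="or").edges
        e_and = build_network(seasons[0], symmetrization="and").edges
        assert e_and <= e_or

    def test_too_few_retained_species(self):
        mat = np.zeros((4, 20), dtype=int)
        mat[0] = np.arange(20)
        with pytest.raises(EmptyNetworkError):
            build_network(season_from_matrix(mat))
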