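import numpy as np
import pandas as pd
import pytest

from comigrate.permanova import (
    drop_singleton_levels,
    gower_center,
    pairwise_permanova,
    permanova,
)


def dist_from_points(x):
    x = np.asarray(x, dtype=float)
    return np.abs(x[:, None] - x[None, :])


class TestGowerCenter:
    def test_zero_matrix(self):
        np.testing.assert_allclose(gower_center(np.zeros((4, 4))), 0.0)

    def test_row_sums_vanish(self, rng):
        x = rng.normal(size=(6, 3))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        g = gower_center(d)
        np.testing.assert_allclose(g.sum(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(g.sum(axis=1), 0.0, atol=1e-10)

    def test_three_point_line_trace(self):
        # points 0, 1, 2 on a line: pairwise d = (1, 1, 2)
        d = dist_from_points([0.0, 1.0, 2.0])
        g = gower_center(d)
        assert np.trace(g) == pytest.approx((1 + 1 + 4) / 3.0, abs=1e-12)

    @pytest.mark.parametrize(
        "bad",
        [
            np.array([[0.0, 1.0], [2.0, 0.0]]),       # asymmetric
            np.array([[0.0, -1.0], [-1.0, 0.0]]),     # negative
            np.array([[1.0, 0.5], [0.5, 0.0]]),       # nonzero diagonal
        ],
    )
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            gower_center(bad)


class TestPermanova:
    def test_all_equal_distances_two_groups_F_is_one(self):
        d = np.ones((4, 4)) - np.eye(4)
        res = permanova(
            d, grouping={"g": np.array(list("AABB"))}, terms=("g",), exact=True
        )
        row = res.term("g")
        assert row["F"] == pytest.approx(1.0, abs=1e-12)
        assert res.table.loc["Total", "SS"] == pytest.approx(1.5, abs=1e-12)
        assert res.table.loc["Residual", "SS"] == pytest.approx(1.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)

    def test_separated_groups_exact_enumeration_p(self):
        # two groups of 2: within-distance 0.1, between 1.0; only the true
        # split maximizes F, and 8 of the 24 label permutations realize it
        d = np.full((4, 4), 1.0)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.1
        np.fill_diagonal(d, 0.0)
        res = permanova(
            d, grouping={"g": np.array(list("AABB"))}, terms=("g",), exact=True
        )
        assert res.term("g")["F"] > 10
        assert res.term("g")["p"] == pytest.approx(1 / 3, abs=1e-12)

    def test_relabeling_invariance_under_exact_enumeration(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=7)
        d = dist_from_points(x)
        g = np.array(list("AABBBCC"))
        res1 = permanova(d, grouping={"g": g}, terms=("g",), exact=True)
        perm = rng.permutation(7)
        res2 = permanova(
            d[np.ix_(perm, perm)], grouping={"g": g[perm]}, terms=("g",), exact=True
        )
        assert res1.term("g")["F"] == pytest.approx(res2.term("g")["F"], abs=1e-10)
        assert res1.term("g")["p"] == pytest.approx(res2.term("g")["p"], abs=1e-12)

    def test_euclidean_distance_reproduces_classical_anova(self, rng):
        """One-way PERMANOVA on |x_i - x_j| equals the classical one-way
        ANOVA F on the 1-D coordinates."""
        from scipy.stats import f_oneway

        x = rng.normal(size=15)
        groups = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        res = permanova(
            dist_from_points(x), grouping={"g": groups}, terms=("g",), n_perm=99
        )
        f_classic = f_oneway(x[:5], x[5:10], x[10:]).statistic
        assert res.term("g")["F"] == pytest.approx(f_classic, abs=1e-9)

    def test_one_way_statistic_matches_skbio(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        x = rng.normal(size=(12, 3))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        groups = ["a"] * 6 + ["b"] * 6
        res = permanova(d, grouping={"g": np.array(groups)}, terms=("g",), n_perm=9)
        ref = skbio_permanova(DistanceMatrix(d), groups, permutations=9)
        assert res.term("g")["F"] == pytest.approx(ref["test statistic"], abs=1e-9)

    def test_two_factor_partition_sums_to_total(self, rng):
        x = rng.normal(size=(16, 2))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        grouping = {
            "f1": np.repeat(["u", "v"], 8),
            "f2": np.tile(np.repeat(["p", "q"], 4), 2),
        }
        res = permanova(d, grouping=grouping, terms=("f1", "f2"), n_perm=99)
        t = res.table
        assert t.loc["f1", "SS"] + t.loc["f2", "SS"] + t.loc["Residual", "SS"] == (
            pytest.approx(t.loc["Total", "SS"], abs=1e-9)
        )
        r2 = t.loc[["f1", "f2", "Residual"], "R2"].sum()
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_aliased_factor_rejected(self):
        d = dist_from_points(np.arange(6.0))
        grouping = {
            "f1": np.array(list("AAABBB")),
            "dup": np.array(list("AAABBB")),
        }
        with pytest.raises(ValueError, match="dup"):
            permanova(d, grouping=grouping, terms=("f1", "dup"), n_perm=9)

    def test_singleton_level_rejected_and_droppable(self):
        d = dist_from_points(np.arange(5.0))
        traits = pd.DataFrame(
            {"niche": ["x", "x", "y", "y", "z"]},
            index=[f"s{i}" for i in range(5)],
        )
        dd = pd.DataFrame(d, index=traits.index, columns=traits.index)
        with pytest.raises(ValueError, match="singleton"):
            permanova(dd, traits, terms=("niche",), n_perm=9)
        keep = drop_singleton_levels(traits, "niche")
        assert keep == ["s0", "s1", "s2", "s3"]
        permanova(dd.loc[keep, keep], traits, terms=("niche",), n_perm=9)

    def test_seeded_p_values_are_reproducible(self, rng):
        d = dist_from_points(rng.normal(size=10))
        g = {"g": np.repeat(["a", "b"], 5)}
        r1 = permanova(d, grouping=g, terms=("g",), n_perm=199, seed=5)
        r2 = permanova(d, grouping=g, terms=("g",), n_perm=199, seed=5)
        assert r1.term("g")["p"] == r2.term("g")["p"]


class TestPairwisePermanova:
    def block_distance(self, sizes, within, between, labels):
        n = sum(sizes)
        d = np.full((n, n), between, dtype=float)
        start = 0
        for size in sizes:
            d[start:start + size, start:start + size] = within
            start += size
        np.fill_diagonal(d, 0.0)
        names = [f"s{i}" for i in range(n)]
        traits = pd.DataFrame({"area": labels}, index=names)
        return pd.DataFrame(d, index=names, columns=names), traits

    def test_separated_level_has_smaller_p(self):
        labels = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        d, traits = self.block_distance([4, 4, 4], 0.1, 0.1, labels)
        # move level C far from A and B; A and B stay exchangeable
        d.iloc[8:, :8] = 2.0
        d.iloc[:8, 8:] = 2.0
        table = pairwise_permanova(d, traits, "area", n_perm=999, seed=0)
        table = table.set_index(["level_a", "level_b"])
        assert table.loc[("A", "C"), "p_raw"] < table.loc[("A", "B"), "p_raw"]
        assert table.loc[("B", "C"), "p_raw"] < table.loc[("A", "B"), "p_raw"]

    def test_singleton_level_skipped(self, caplog):
        labels = ["A"] * 3 + ["B"] * 3 + ["C"]
        d, traits = self.block_distance([3, 3, 1], 0.2, 1.0, labels)
        table = pairwise_permanova(d, traits, "area", n_perm=99)
        tested = set(map(tuple, table[["level_a", "level_b"]].to_numpy()))
        assert tested == {("A", "B")}

    def test_holm_adjustment_across_pairs(self):
        labels = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        d, traits = self.block_distance([4, 4, 4], 0.1, 1.5, labels)
        table = pairwise_permanova(d, traits, "area", n_perm=199, seed=1)
        assert (table["p_adj"] >= table["p_raw"] - 1e-15).all()

    def test_exchangeable_levels_give_null_behaviour(self):
        """Identical levels: pairwise F hovers near 1 and p is roughly
        uniform over independent seeds."""
        rng = np.random.default_rng(0)
        fs, ps = [], []
        for rep in range(120):
            x = rng.normal(size=20)
            d = dist_from_points(x)
            names = [f"s{i}" for i in range(20)]
            traits = pd.DataFrame(
                {"area": ["A"] * 10 + ["B"] * 10}, index=names
            )
            dd = pd.DataFrame(d, index=names, columns=names)
            table = pairwise_permanova(dd, traits, "area", n_perm=99, seed=rep)
            fs.append(table["F"].iloc[0])
            ps.append(table["p_raw"].iloc[0])
        assert 0.7 < np.mean(fs) < 1.5  # E[F] ~ df2/(df2-2) = 18/16
        assert 0.35 < np.mean(ps) < 0.65
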