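"""Tree slicing, collapse, dissimilarities, BDTT profiles and nulls."""

import numpy as np
import pandas as pd
import pytest

from coproscope.bdtt import (bdtt_profile, collapse_table, envelope_null,
                             leaf_shuffle_null, lineage_association,
                             slice_tree, sorensen_matrix, unweighted_unifrac,
                             ward_spearman_clustering)
from coproscope.hosts import ecology_distance_matrix
from coproscope.simulate import CommunitySimSpec, simulate_scenario
from coproscope.trees import CalibratedTree, cophenetic_distances


class TestSliceTree:
    def test_leaf_and_root_slices(self, four_leaf_tree):
        assert slice_tree(four_leaf_tree, 0.0).n_clades == 4
        assert slice_tree(four_leaf_tree, 3.0).n_clades == 1
        assert slice_tree(four_leaf_tree, 99.0).n_clades == 1

    def test_intermediate_slice_by_hand(self, four_leaf_tree):
        # at age 1.5: (A,B) joined at age 1 -> one clade; C and D still
        # separate (they join at age 2)
        a = slice_tree(four_leaf_tree, 1.5)
        assert a.n_clades == 3
        assert a.mapping["A"] == a.mapping["B"]
        assert len({a.mapping["A"], a.mapping["C"], a.mapping["D"]}) == 3

    def test_negative_age_rejected(self, four_leaf_tree):
        with pytest.raises(ValueError):
            slice_tree(four_leaf_tree, -1.0)

    def test_clade_count_non_increasing_in_age(self):
        from coproscope.simulate import simulate_calibrated_tree
        t = simulate_calibrated_tree(40, 100.0, seed=3)
        counts = [slice_tree(t, a).n_clades
                  for a in np.linspace(0, 100, 11)]
        assert counts == sorted(counts, reverse=True)


class TestCollapse:
    def test_hand_sums(self, four_leaf_tree):
        table = pd.DataFrame([[2, 3, 5, 0]], index=["h1"],
                             columns=list("ABCD"))
        out = collapse_table(table, slice_tree(four_leaf_tree, 1.5))
        assert sorted(out.loc["h1"].tolist()) == [0, 5, 5]

    def test_identity_and_total_conservation(self, four_leaf_tree):
        table = pd.DataFrame([[2, 3, 5, 7], [1, 0, 0, 4]],
                             index=["h1", "h2"], columns=list("ABCD"))
        ident = collapse_table(table, slice_tree(four_leaf_tree, 0.0))
        assert np.array_equal(np.sort(ident.to_numpy(), axis=1),
                              np.sort(table.to_numpy(), axis=1))
        for age in (0.0, 1.5, 2.5, 3.0):
            out = collapse_table(table, slice_tree(four_leaf_tree, age))
            np.testing.assert_array_equal(out.sum(axis=1),
                                          table.sum(axis=1))

    def test_unknown_taxon_rejected(self, four_leaf_tree):
        table = pd.DataFrame([[1]], index=["h1"], columns=["Z"])
        with pytest.raises(ValueError, match="Z"):
            collapse_table(table, slice_tree(four_leaf_tree, 0.0))


class TestSorensen:
    def test_examples(self):
        t = pd.DataFrame([[1, 1, 1, 0], [0, 1, 1, 1]],
                         index=["h1", "h2"], columns=list("wxyz"))
        d = sorensen_matrix(t)
        assert d["h1", "h2"] == pytest.approx(1 / 3)
        ident = pd.DataFrame([[1, 1], [5, 2]], index=["a", "b"],
                             columns=["x", "y"])
        assert sorensen_matrix(ident)["a", "b"] == 0.0
        disjoint = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"],
                                columns=["x", "y"])
        assert sorensen_matrix(disjoint)["a", "b"] == 1.0

    def test_empty_host_flagged_distance_one(self):
        t = pd.DataFrame([[1, 1], [0, 0]], index=["a", "b"],
                         columns=["x", "y"])
        with pytest.warns(UserWarning, match="empty"):
            d = sorensen_matrix(t)
        assert d["a", "b"] == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sorensen_matrix(pd.DataFrame(np.zeros((2, 3))))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.integers(0, 2, (5, 12)))
        t.iloc[0, 0] = 1    # guard against an all-empty host
        d = sorensen_matrix(t)
        pres = t.to_numpy() > 0
        for i in range(5):
            for j in range(5):
                a = np.sum(pres[i] & pres[j])
                b = np.sum(pres[i] & ~pres[j])
                c = np.sum(~pres[i] & pres[j])
                if 2 * a + b + c:
                    assert d.data[i, j] == pytest.approx(
                        1 - 2 * a / (2 * a + b + c), abs=1e-9)


def brute_force_unifrac(table, ctree):
    """Oracle: enumerate every branch; unweighted UniFrac for each pair."""
    pres = table.to_numpy() > 0
    taxa = list(table.columns)
    branches = []
    for node in ctree.tree.preorder(include_self=False):
        tips = {t.name for t in node.tips()} or {node.name}
        branches.append((node.length or 0.0, tips))
    n = table.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            si = {t for t, p in zip(taxa, pres[i]) if p}
            sj = {t for t, p in zip(taxa, pres[j]) if p}
            uniq = tot = 0.0
            for length, tips in branches:
                a, b = bool(tips & si), bool(tips & sj)
                if a or b:
                    tot += length
                    if a != b:
                        uniq += length
            out[i, j] = uniq / tot if tot else 0.0
    return out


class TestUniFrac:
    def test_identical_and_disjoint(self, four_leaf_tree):
        same = pd.DataFrame([[1, 1, 0, 0]] * 2, index=["a", "b"],
                            columns=list("ABCD"))
        assert unweighted_unifrac(same, four_leaf_tree)["a", "b"] == 0.0
        cherry = CalibratedTree.from_newick("(A:1,B:1);")
        two = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"],
                           columns=["A", "B"])
        assert unweighted_unifrac(two, cherry)["a", "b"] == \
            pytest.approx(1.0)

    def test_matches_branch_enumeration_oracle(self, four_leaf_tree):
        table = pd.DataFrame([[1, 1, 0, 0], [1, 0, 1, 0]],
                             index=["h1", "h2"], columns=list("ABCD"))
        d = unweighted_unifrac(table, four_leaf_tree)
        oracle = brute_force_unifrac(table, four_leaf_tree)
        np.testing.assert_allclose(d.data, oracle, atol=1e-9)
        # hand value: unique branches B(1)+C(2)+(CD)(1), union total 7
        assert d["h1", "h2"] == pytest.approx(4 / 7, abs=1e-9)

    def test_oracle_on_random_8_leaf_trees(self):
        from coproscope.simulate import simulate_calibrated_tree
        rng = np.random.default_rng(1)
        for seed in range(5):
            t = simulate_calibrated_tree(8, 50.0, seed)
            table = pd.DataFrame(rng.integers(0, 2, (4, 8)),
                                 columns=t.leaf_names)
            table.iloc[:, 0] = 1
            d = unweighted_unifrac(table, t)
            np.testing.assert_allclose(d.data, brute_force_unifrac(table, t),
                                       atol=1e-9)

    def test_empty_host_rejected(self, four_leaf_tree):
        table = pd.DataFrame([[1, 1, 0, 0], [0, 0, 0, 0]],
                             index=["a", "b"], columns=list("ABCD"))
        with pytest.raises(ValueError, match="b"):
            unweighted_unifrac(table, four_leaf_tree)

    def test_star_topology_congruent_with_sorensen_ordering(self):
        """Equal-length star tree: UniFrac and Sørensen rank host pairs
        identically (the leaf-level congruence check)."""
        from coproscope.stats import mantel_test
        star = CalibratedTree.from_newick(
            "((t0:1,t1:1,t2:1,t3:1):0,(t4:1,t5:1,t6:1,t7:1):0);")
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.integers(0, 2, (6, 8)),
                             columns=star.leaf_names)
        table.iloc[:, 0] = 1
        uf = unweighted_unifrac(table, star)
        so = sorensen_matrix(table)
        res = mantel_test(uf.data, so.filter(uf.ids).data)
        assert res.p <= 0.05 and res.r > 0.9


@pytest.fixture(scope="module")
def scenario():
    spec = CommunitySimSpec(seed=4)
    tree, host_tree, table, meta = simulate_scenario(spec)
    hosts = [m.host_id for m in meta]
    factors = {
        "phylogeny": cophenetic_distances(host_tree).filter(hosts),
        "ecology": ecology_distance_matrix(meta),
    }
    return spec, tree, table, factors


class TestBdttProfile:
    def test_profile_recovers_planted_signals(self, scenario):
        spec, tree, table, factors = scenario
        ages = [0.0, 100.0, 500.0, 700.0]
        prof = bdtt_profile(tree, table, factors, ages, n_perm=199,
                            n_shuffles=199, seed=0)
        df = prof.to_frame().set_index(["factor", "age"])
        assert df.loc[("phylogeny", 0.0), "r2"] > \
            df.loc[("phylogeny", 0.0), "env_hi"]
        deep = df.loc[("ecology", 500.0)], df.loc[("ecology", 700.0)]
        assert any(row["r2"] > row["env_hi"] for row in deep)
        # R^2 is r squared, p within (0, 1]
        assert np.allclose(df["r2"], df["r"] ** 2)
        assert ((df["p"] > 0) & (df["p"] <= 1)).all()
        assert (df["env_lo"] <= df["env_hi"]).all()

    def test_ages_must_be_sorted(self, scenario):
        _, tree, table, factors = scenario
        with pytest.raises(ValueError):
            bdtt_profile(tree, table, factors, [100.0, 0.0], n_perm=9,
                         n_shuffles=9, seed=0)

    def test_deterministic_given_seed(self, scenario):
        _, tree, table, factors = scenario
        a = bdtt_profile(tree, table, factors, [0.0, 500.0], n_perm=49,
                         n_shuffles=49, seed=7).to_frame()
        b = bdtt_profile(tree, table, factors, [0.0, 500.0], n_perm=49,
                         n_shuffles=49, seed=7).to_frame()
        pd.testing.assert_frame_equal(a, b)


class TestEnvelope:
    def test_bounds_ordered_and_min_max_for_few_shuffles(self):
        rng = np.random.default_rng(0)
        from skbio.stats.distance import DistanceMatrix
        d1 = rng.random((8, 8)); d1 = (d1 + d1.T) / 2; np.fill_diagonal(d1, 0)
        d2 = rng.random((8, 8)); d2 = (d2 + d2.T) / 2; np.fill_diagonal(d2, 0)
        dm1 = DistanceMatrix(d1)
        dm2 = DistanceMatrix(d2)
        lo, hi = envelope_null(dm1, dm2, n_shuffles=10, seed=1)
        assert lo <= hi
        lo2, hi2 = envelope_null(dm1, dm2, n_shuffles=1000, seed=1)
        assert lo2 <= hi2
        # the 10-shuffle protocol uses min/max, so it is at least as wide
        # as interior percentiles of the same small sample would be
        assert hi2 <= 1.0 and lo2 >= 0.0


class TestLeafShuffleNull:
    def test_leaf_slice_identical_deeper_degraded(self):
        spec = CommunitySimSpec(seed=6)
        tree, host_tree, table, meta = simulate_scenario(spec)
        hosts = [m.host_id for m in meta]
        factors = {"ecology": ecology_distance_matrix(meta)}
        ages = [0.0, 500.0]
        obs = bdtt_profile(tree, table, factors, ages, n_perm=199,
                           n_shuffles=49, seed=1).to_frame()
        null = leaf_shuffle_null(tree, table, factors, ages, n_perm=199,
                                 n_shuffles=49, seed=1).to_frame()
        obs = obs.set_index("age")
        null = null.set_index("age")
        # age 0: slicing returns the leaves themselves; label shuffling
        # cannot change leaf-level composition
        assert null.loc[0.0, "r2"] == pytest.approx(obs.loc[0.0, "r2"],
                                                    abs=1e-12)
        # the planted deep ecology signal does not survive leaf shuffling
        assert null.loc[500.0, "r2"] < obs.loc[500.0, "r2"]


class TestLineageAssociation:
    def test_wolf_only_clade_is_an_ecology_hit(self, study_meta):
        hosts = [m.host_id for m in study_meta]
        wolf = np.array([1.0 if m.group == "wolf" else 0.0
                         for m in study_meta])
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"wolfclade": wolf,
                              **{f"n{k}": rng.integers(0, 2, len(hosts))
                                 for k in range(5)}}, index=hosts)
        factors = {"ecology": ecology_distance_matrix(study_meta)}
        hits = lineage_association({100.0: table}, factors, n_perm=999,
                                   seed=0)
        row = hits[hits.clade == "wolfclade"].iloc[0]
        assert row.p <= 0.01
        assert row.hit

    def test_constant_clade_skipped(self, study_meta):
        hosts = [m.host_id for m in study_meta]
        table = pd.DataFrame({"everywhere": np.ones(len(hosts)),
                              "x": [1, 0] * 5}, index=hosts)
        factors = {"ecology": ecology_distance_matrix(study_meta)}
        hits = lineage_association({0.0: table}, factors, n_perm=99, seed=0)
        assert "everywhere" not in set(hits.clade)

    def test_null_false_hit_rate_controlled(self, study_meta):
        hosts = [m.host_id for m in study_meta]
        rng = np.random.default_rng(1)
        frac = []
        for s in range(20):
            table = pd.DataFrame(rng.integers(0, 2, (len(hosts), 50)),
                                 index=hosts)
            d = rng.random((10, 10)); d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            from skbio.stats.distance import DistanceMatrix
            factors = {"noise": DistanceMatrix(d, ids=hosts)}
            hits = lineage_association({0.0: table}, factors, n_perm=199,
                                       seed=s)
            frac.append(hits["hit"].mean() if len(hits) else 0.0)
        assert np.mean(frac) <= 0.05


class TestWardSpearman:
    def test_identical_profiles_distance_zero(self):
        t = pd.DataFrame([[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]],
                         index=["a", "b", "c"])
        res = ward_spearman_clustering(t, n_clusters=2)
        assert res.distance["a", "b"] == pytest.approx(0.0)
        assert res.clusters["a"] == res.clusters["b"]

    def test_anticorrelated_distance_two(self):
        t = pd.DataFrame([[1, 2, 3, 4], [4, 3, 2, 1]], index=["a", "b"])
        res = ward_spearman_clustering(t)
        assert res.distance["a", "b"] == pytest.approx(2.0)

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(3)
        block1 = rng.random((6, 10)) + np.linspace(0, 3, 10)
        block2 = rng.random((6, 10)) + np.linspace(3, 0, 10)
        t = pd.DataFrame(np.vstack([block1, block2]),
                         index=[f"w{i}" for i in range(6)]
                         + [f"d{i}" for i in range(6)])
        res = ward_spearman_clustering(t, n_clusters=2)
        w = {res.clusters[f"w{i}"] for i in range(6)}
        d = {res.clusters[f"d{i}"] for i in range(6)}
        assert len(w) == 1 and len(d) == 1 and w != d

    def test_constant_profile_dropped(self):
        t = pd.DataFrame([[1, 1, 1], [1, 2, 3], [3, 2, 1]],
                         index=["flat", "up", "down"])
        with pytest.warns(UserWarning, match="flat"):
            res = ward_spearman_clustering(t)
        assert res.dropped == ["flat"]
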