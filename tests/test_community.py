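import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from icecore import community
from icecore.io import ICE_SAMPLE

from conftest import ladder_newick, make_table, tree_from_string


def unifrac_branch_oracle(tree, counts_a, counts_b):
    """Per-branch enumeration of normalized weighted UniFrac.

    Walks every branch, computes the fraction of each sample's reads
    descending from it, and accumulates the weighted L1 difference and the
    normalizing mass independently of the library implementation.
    """
    tot_a, tot_b = sum(counts_a.values()), sum(counts_b.values())
    num = den = 0.0
    for node in tree.traverse(include_self=False):
        tips = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        pa = sum(counts_a.get(t, 0) for t in tips) / tot_a
        pb = sum(counts_b.get(t, 0) for t in tips) / tot_b
        num += node.length * abs(pa - pb)
        den += node.length * (pa + pb)
    return num / den


class TestRarefy:
    def test_depth_equal_total_is_identity(self, toy_table):
        depth = int(toy_table.counts.loc["IceA"].sum())
        sub = community.rarefy(toy_table.subset_otus(toy_table.otu_ids), depth, seed=0)
        # every sample in the toy table has the same total
        pd.testing.assert_frame_equal(sub.counts, toy_table.counts)

    def test_seed_contract(self, toy_table):
        a = community.rarefy(toy_table, 50, seed=1)
        b = community.rarefy(toy_table, 50, seed=1)
        c = community.rarefy(toy_table, 50, seed=2)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        assert not a.counts.equals(c.counts)

    def test_never_increases_counts(self, toy_table):
        sub = community.rarefy(toy_table, 20, seed=3)
        assert (sub.counts.to_numpy() <= toy_table.counts.to_numpy()).all()
        assert (sub.counts.sum(axis=1) == 20).all()

    def test_underdepth_errors_or_drops(self, toy_table):
        with pytest.raises(ValueError, match="fewer than"):
            community.rarefy(toy_table, 10**6, seed=0)
        with pytest.warns(UserWarning, match="dropping"):
            sub = community.rarefy(toy_table, 10**6, seed=0, drop_under=True)
        assert sub.sample_ids == []

    def test_hypergeometric_mean(self):
        # OTU with proportion p retains ~p*d reads on average
        t = make_table({"s": {"a": 300, "b": 700}})
        d, n_seeds = 100, 1000
        draws = np.array(
            [community.rarefy(t, d, seed=s).counts.loc["s", "a"] for s in range(n_seeds)]
        )
        N, K = 1000, 300
        mean = d * K / N
        var = d * (K / N) * (1 - K / N) * (N - d) / (N - 1)
        se = np.sqrt(var / n_seeds)
        assert abs(draws.mean() - mean) < 3 * se


class TestMajorTaxa:
    def test_boundary_inclusive(self):
        t = make_table(
            {"s": {"a": 50, "b": 50}},
            taxonomy={"a": "B;P;C;O;F;G1", "b": "B;P;C;O;F;G2"},
        )
        sel, _ = community.major_taxa(t, level="genus", min_pct=50)
        assert sorted(sel) == ["G1", "G2"]

    def test_threshold_rules(self):
        t = make_table(
            {"s1": {"a": 6, "b": 994}, "s2": {"a": 0, "b": 1000}},
            taxonomy={"a": "B;P;C;O;F;G", "b": "B;P;C;O;F;H"},
        )
        sel_05, _ = community.major_taxa(t, level="genus", min_pct=0.5)
        sel_10, _ = community.major_taxa(t, level="genus", min_pct=1.0)
        assert "G" in sel_05 and "G" not in sel_10

    def test_renormalized_profile_sums_to_100(self, toy_table):
        _, prof = community.major_taxa(
            toy_table, level="otu", min_pct=5.0, renormalize=True
        )
        assert np.allclose(prof.sum(axis=1), 100.0)

    def test_unclassified_genus_keyed_by_family(self, toy_table):
        sel, _ = community.major_taxa(toy_table, level="genus", min_pct=1.0)
        assert "Comamonadaceae;unclassified" in sel

    @pytest.mark.parametrize("bad", [0, 100, -3])
    def test_min_pct_validated(self, toy_table, bad):
        with pytest.raises(ValueError):
            community.major_taxa(toy_table, min_pct=bad)


class TestSharedOtus:
    def test_identical_samples_all_shared(self):
        t = make_table({"s1": {"a": 5, "b": 5}, "s2": {"a": 5, "b": 5}})
        assert community.shared_otus(t, "s1", "s2", min_pct=1.0) == (2, 0, 0)

    def test_disjoint_samples(self):
        t = make_table({"s1": {"a": 5, "b": 0}, "s2": {"a": 0, "b": 5}})
        assert community.shared_otus(t, "s1", "s2", min_pct=1.0) == (0, 1, 1)

    def test_constructed_five_otu_case(self):
        t = make_table(
            {
                "s1": {"a": 30, "b": 30, "c": 30, "d": 10, "e": 0},
                "s2": {"a": 20, "b": 40, "c": 30, "d": 0, "e": 10},
            }
        )
        assert community.shared_otus(t, "s1", "s2", min_pct=1.0) == (3, 1, 1)

    def test_unknown_sample_rejected(self, toy_table):
        with pytest.raises(ValueError, match="unknown sample"):
            community.shared_otus(toy_table, "IceA", "nope")


class TestWeightedUnifrac:
    def test_self_distance_zero(self, toy_table):
        tree = tree_from_string(ladder_newick(toy_table.otu_ids))
        dm = community.weighted_unifrac(toy_table, tree)
        assert np.allclose(np.diag(dm.data), 0.0)
        assert dm.data.min() >= 0 and dm.data.max() <= 1

    def test_disjoint_single_otu_samples_maximal(self):
        t = make_table({"s1": {"a": 10, "b": 0}, "s2": {"a": 0, "b": 10}})
        tree = tree_from_string("(a:1,b:1);")
        dm = community.weighted_unifrac(t, tree)
        assert dm["s1", "s2"] == pytest.approx(1.0)

    def test_four_leaf_hand_case(self):
        t = make_table({"s1": {"A": 10, "B": 0, "C": 0, "D": 0},
                        "s2": {"A": 0, "B": 0, "C": 10, "D": 0}})
        tree = tree_from_string("((A:1,B:1):1,(C:1,D:1):1);")
        dm = community.weighted_unifrac(t, tree)
        assert dm["s1", "s2"] == pytest.approx(1.0)

    def test_matches_branch_oracle_on_random_counts(self):
        rng = np.random.default_rng(8)
        tree_str = "((A:0.5,B:1.5):1,(C:1,D:2):0.25);"
        for _ in range(20):
            ca = {k: int(v) for k, v in zip("ABCD", rng.integers(0, 40, 4))}
            cb = {k: int(v) for k, v in zip("ABCD", rng.integers(0, 40, 4))}
            if sum(ca.values()) == 0 or sum(cb.values()) == 0:
                continue
            t = make_table({"s1": ca, "s2": cb})
            dm = community.weighted_unifrac(t, tree_from_string(tree_str))
            want = unifrac_branch_oracle(tree_from_string(tree_str), ca, cb)
            assert dm["s1", "s2"] == pytest.approx(want, abs=1e-12)

    def test_missing_otu_rejected(self):
        t = make_table({"s1": {"a": 1, "z": 1}, "s2": {"a": 1, "z": 0}})
        tree = tree_from_string("(a:1,b:1);")
        with pytest.raises(ValueError, match="missing from the tree"):
            community.weighted_unifrac(t, tree)


class TestPcoa:
    @staticmethod
    def _dm_from_points(pts, ids):
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        return DistanceMatrix(d, ids=ids)

    def test_collinear_points_one_axis(self):
        pts = np.array([[0.0, 0], [1, 0], [2, 0], [5, 0]])
        res = community.pcoa(self._dm_from_points(pts, list("abcd")), n_axes=1)
        assert res.explained_pct[0] == pytest.approx(100.0)

    def test_reconstructs_pairwise_distances(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 2))
        ids = [f"s{i}" for i in range(6)]
        dm = self._dm_from_points(pts, ids)
        res = community.pcoa(dm, n_axes=2)
        coords = res.coordinates.to_numpy()
        rec = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        assert np.allclose(rec, dm.data, atol=1e-9)

    def test_id_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(5, 2))
        ids = list("abcde")
        dm = self._dm_from_points(pts, ids)
        res = community.pcoa(dm, n_axes=2)
        perm = [3, 1, 4, 0, 2]
        dm_p = self._dm_from_points(pts[perm], [ids[i] for i in perm])
        res_p = community.pcoa(dm_p, n_axes=2)
        for sid in ids:
            a = np.abs(res.coordinates.loc[sid].to_numpy())
            b = np.abs(res_p.coordinates.loc[sid].to_numpy())
            assert np.allclose(a, b, atol=1e-9)  # axes are sign-ambiguous

    def test_axis_overrequest_truncates_with_warning(self):
        pts = np.array([[0.0, 0], [1, 0], [2, 0]])
        dm = self._dm_from_points(pts, list("abc"))
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            res = community.pcoa(dm, n_axes=3)
        assert res.coordinates.shape[1] < 3


class TestAnosim:
    @staticmethod
    def _separated_dm():
        # two groups, every between-distance larger than every within-distance
        d = np.array(
            [
                [0, 1, 1, 9, 9, 9],
                [1, 0, 1, 9, 9, 9],
                [1, 1, 0, 9, 9, 9],
                [9, 9, 9, 0, 1, 1],
                [9, 9, 9, 1, 0, 1],
                [9, 9, 9, 1, 1, 0],
            ],
            dtype=float,
        )
        return DistanceMatrix(d, ids=list("abcdef"))

    def test_perfect_separation_r_one(self):
        r, p = community.anosim(
            self._separated_dm(), ["g1"] * 3 + ["g2"] * 3, n_perm=99, seed=0
        )
        assert r == pytest.approx(1.0)
        assert 0 < p <= 1

    def test_p_never_zero(self):
        _, p = community.anosim(
            self._separated_dm(), ["g1"] * 3 + ["g2"] * 3, n_perm=99, seed=0
        )
        assert p >= 1 / 100

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than two"):
            community.anosim(self._separated_dm(), ["g1"] * 5 + ["g2"], n_perm=9, seed=0)

    def test_default_permutations_999(self):
        import inspect

        assert inspect.signature(community.anosim).parameters["n_perm"].default == 999


class TestMantel:
    @staticmethod
    def _random_dm(rng, ids):
        pts = rng.normal(size=(len(ids), 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        return DistanceMatrix(d, ids=ids)

    def test_identical_matrices_r_one(self):
        dm = self._random_dm(np.random.default_rng(1), list("abcde"))
        r, p = community.mantel(dm, dm, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_r_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        ids = list("abcde")
        d1, d2 = self._random_dm(rng, ids), self._random_dm(rng, ids)
        r, _ = community.mantel(d1, d2, n_perm=9, seed=0)
        # brute force: explicit pair enumeration + Pearson formula
        xs, ys = [], []
        for i in range(5):
            for j in range(i + 1, 5):
                xs.append(d1.data[i, j])
                ys.append(d2.data[i, j])
        xs, ys = np.array(xs), np.array(ys)
        want = np.sum((xs - xs.mean()) * (ys - ys.mean())) / np.sqrt(
            np.sum((xs - xs.mean()) ** 2) * np.sum((ys - ys.mean()) ** 2)
        )
        assert r == pytest.approx(want, abs=1e-12)

    def test_id_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="same ids"):
            community.mantel(
                self._random_dm(rng, list("abcde")),
                self._random_dm(rng, list("vwxyz")),
                n_perm=9,
                seed=0,
            )
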