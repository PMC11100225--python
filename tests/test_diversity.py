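import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from rhizolink.diversity import (
    DistanceMatrix,
    alpha_diversity,
    anosim,
    bray_curtis,
    kruskal_wallis,
    nmds,
    pcoa,
)

from conftest import make_table


def dm(points, ids=None):
    points = np.asarray(points, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(ids, squareform(pdist(points)))


class TestAlpha:
    @pytest.mark.parametrize(
        "counts, chao1, shannon, simpson",
        [
            ([10, 10, 10, 10], 4.0, np.log(4), 0.75),
            ([7], 1.0, 0.0, 0.0),
            # S_obs=4, F1=2, F2=1 -> 4 + 2*1/(2*2)
            ([5, 1, 1, 2], 4.5, None, None),
        ],
    )
    def test_index_formulas(self, counts, chao1, shannon, simpson):
        t = make_table(np.array(counts, dtype=float)[:, None])
        res = alpha_diversity(t).per_sample.iloc[0]
        assert res["chao1"] == pytest.approx(chao1)
        if shannon is not None:
            assert res["shannon"] == pytest.approx(shannon)
        if simpson is not None:
            assert res["simpson"] == pytest.approx(simpson)

    def test_matches_independent_reference_implementation(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 30, size=(12, 5)).astype(float)
        counts[0] += 1
        res = alpha_diversity(make_table(counts)).per_sample
        for j in range(5):
            col = counts[:, j].astype(int)
            assert res["chao1"].iloc[j] == pytest.approx(skbio_alpha.chao1(col, bias_corrected=True))
            assert res["shannon"].iloc[j] == pytest.approx(skbio_alpha.shannon(col, base=np.e))
            assert res["simpson"].iloc[j] == pytest.approx(skbio_alpha.simpson(col))

    def test_merging_equal_taxa_drops_shannon_by_mixing_term(self):
        """Merging two equal-abundance taxa (fraction p each) lowers H by 2p ln 2."""
        t1 = make_table([[20.0], [20.0], [60.0]])
        t2 = make_table([[40.0], [60.0]])
        h1 = alpha_diversity(t1).per_sample["shannon"].iloc[0]
        h2 = alpha_diversity(t2).per_sample["shannon"].iloc[0]
        p = 0.2
        assert h1 - h2 == pytest.approx(2 * p * np.log(2))

    def test_relative_table_rejected_for_chao1(self):
        t = make_table([[0.5], [0.5]], kind="relative")
        with pytest.raises(ValueError, match="counts"):
            alpha_diversity(t)

    def test_invariant_ranges(self):
        rng = np.random.default_rng(1)
        t = make_table(rng.integers(0, 9, size=(20, 8)).astype(float) + 0.0)
        res = alpha_diversity(t).per_sample
        obs = (t.values > 0).sum(axis=0)
        assert (res["shannon"] >= 0).all()
        assert ((res["simpson"] >= 0) & (res["simpson"] < 1)).all()
        assert (res["chao1"].to_numpy() >= obs - 1e-12).all()


class TestKruskalWallis:
    def test_symmetric_groups_give_zero(self):
        h, _ = kruskal_wallis([np.array([1, 2, 3]), np.array([1, 2, 3])])
        assert h == pytest.approx(0.0)

    def test_hand_computed_ranks(self):
        # ranks 1..4; R1=3, R2=7; H = 12/(4*5) * (9/2 + 49/2) - 3*5 = 2.4
        h, _ = kruskal_wallis([np.array([1, 2]), np.array([3, 4])])
        assert h == pytest.approx(2.4)

    def test_all_identical_degenerate(self):
        h, p = kruskal_wallis([np.array([2, 2]), np.array([2]), np.array([2, 2])])
        assert (h, p) == (0.0, 1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([np.array([1, 2, 3])])


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        d = bray_curtis(make_table([[3, 3], [1, 1]]))
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_support_one(self):
        d = bray_curtis(make_table([[3, 0], [0, 5]]))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_half(self):
        d = bray_curtis(make_table([[1, 0], [1, 1], [0, 1]]))
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_zero_sum_sample_rejected(self):
        with pytest.raises(ValueError, match="zero-sum"):
            bray_curtis(make_table([[1, 0], [1, 0]]))

    def test_entries_bounded(self):
        rng = np.random.default_rng(0)
        d = bray_curtis(make_table(rng.random((10, 6)) + 1e-3))
        assert ((d.values >= 0) & (d.values <= 1)).all()


class TestPcoa:
    def test_two_points_at_half_distance(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        res = pcoa(d, k=1)
        np.testing.assert_allclose(np.abs(res.coordinates[:, 0]), [1.0, 1.0], atol=1e-12)

    def test_zero_distances_zero_coordinates(self):
        d = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        res = pcoa(d, k=2)
        np.testing.assert_allclose(res.coordinates, 0.0, atol=1e-12)

    def test_recovers_planar_configuration(self):
        """Euclidean distances of 4 planar points are reproduced exactly."""
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 2.0], [-1.0, 1.0]])
        res = pcoa(dm(pts), k=2)
        got = squareform(pdist(res.coordinates))
        np.testing.assert_allclose(got, squareform(pdist(pts)), atol=1e-8)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_agrees_with_reference_implementation(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        skbio_dm = pytest.importorskip("skbio").DistanceMatrix
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((8, 3))
        d = dm(pts)
        mine = pcoa(d, k=3)
        ref = skbio_ord.pcoa(skbio_dm(d.values, ids=d.sample_ids))
        np.testing.assert_allclose(
            np.abs(mine.coordinates), np.abs(ref.samples.to_numpy()[:, :3]), atol=1e-8
        )


class TestNmds:
    def test_three_points_embed_exactly(self):
        rng = np.random.default_rng(2)
        res = nmds(dm(rng.standard_normal((3, 2))), k=2, n_restarts=5, seed=0)
        assert res.stress < 1e-6

    def test_planar_configuration_low_stress(self):
        rng = np.random.default_rng(3)
        res = nmds(dm(rng.standard_normal((10, 2))), k=2, n_restarts=10, seed=0)
        assert res.stress < 0.01

    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        d = dm(rng.standard_normal((8, 4)))
        a = nmds(d, seed=42, n_restarts=5)
        b = nmds(d, seed=42, n_restarts=5)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        assert a.stress == b.stress

    def test_dimension_bound(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            nmds(dm(rng.standard_normal((4, 2))), k=4)


class TestAnosim:
    def test_equal_distances_zero_r(self):
        v = np.ones((6, 6)) - np.eye(6)
        d = DistanceMatrix([f"s{i}" for i in range(6)], v)
        res = anosim(d, np.array(["A"] * 3 + ["B"] * 3), n_perm=99, seed=0)
        assert res.R == pytest.approx(0.0)

    def test_separated_clusters_high_r_low_p(self):
        rng = np.random.default_rng(6)
        pts = np.vstack([rng.normal(0, 0.05, (8, 2)), rng.normal(5, 0.05, (8, 2))])
        res = anosim(dm(pts), np.array(["A"] * 8 + ["B"] * 8), n_perm=999, seed=0)
        assert res.R >= 0.9
        assert res.p <= 0.01

    def test_p_respects_permutation_floor(self):
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(0, 0.05, (5, 2)), rng.normal(9, 0.05, (5, 2))])
        res = anosim(dm(pts), np.array(["A"] * 5 + ["B"] * 5), n_perm=99, seed=0)
        assert res.p >= 1 / 100

    def test_agrees_with_reference_implementation(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        skbio_dm = pytest.importorskip("skbio").DistanceMatrix
        rng = np.random.default_rng(8)
        pts = rng.standard_normal((12, 3))
        d = dm(pts)
        labels = np.array(["A", "B", "C"] * 4)
        mine = anosim(d, labels, n_perm=999, seed=0)
        ref = skbio_dist.anosim(
            skbio_dm(d.values, ids=d.sample_ids), labels.tolist(), permutations=0
        )
        assert mine.R == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_singleton_group_warns(self):
        rng = np.random.default_rng(9)
        d = dm(rng.standard_normal((5, 2)))
        with pytest.warns(RuntimeWarning, match="size 1"):
            anosim(d, np.array(["A", "A", "B", "B", "C"]), n_perm=49, seed=0)
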