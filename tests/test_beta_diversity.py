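"""CLR/Aitchison geometry, PCoA, and ANOSIM with permutation inference."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.ordination import pcoa as skbio_pcoa

from aerotransfer import (
    FeatureTable,
    Metadata,
    SampleRecord,
    ValidationError,
    aitchison_distance,
    anosim,
    clr_array,
    clr_transform,
    generate_study,
    pairwise_anosim,
    pcoa,
)
from conftest import small_paired_scenario


class TestCLR:
    def test_equal_parts_map_to_zero(self):
        t = FeatureTable(np.array([[1], [1], [1], [1]]), list("abcd"), ["s"])
        np.testing.assert_allclose(clr_transform(t, pseudocount=7.0).to_numpy(), 0.0)

    def test_two_part_closed_form(self):
        np.testing.assert_allclose(
            clr_array(np.array([[1.0, np.e**2]])), [[-1.0, 1.0]], atol=1e-12
        )

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(1)
        t = FeatureTable(rng.integers(0, 50, (40, 6)),
                         [f"f{i}" for i in range(40)], [f"s{j}" for j in range(6)])
        clr = clr_transform(t, pseudocount=0.5)
        np.testing.assert_allclose(clr.sum(axis=1), 0.0, atol=1e-9)

    def test_scale_invariance_of_compositions(self):
        x = np.array([[3.0, 5.0, 12.0]])
        np.testing.assert_allclose(clr_array(x), clr_array(10 * x), atol=1e-12)

    def test_zero_counts_need_pseudocount(self):
        t = FeatureTable(np.array([[0], [5]]), ["a", "b"], ["s"])
        with pytest.raises(ValueError, match="pseudocount"):
            clr_transform(t, pseudocount=0.0)


class TestAitchison:
    def test_identical_samples_distance_zero(self):
        t = FeatureTable(np.array([[4, 4], [9, 9]]), ["a", "b"], ["s1", "s2"])
        dm = aitchison_distance(clr_transform(t, 0.5))
        assert dm["s1", "s2"] == pytest.approx(0.0, abs=1e-12)

    def test_two_part_closed_form(self):
        # d = |ln(x1/x2) - ln(y1/y2)| / sqrt(2) = 2/sqrt(2) = sqrt(2)
        clr = clr_array(np.array([[1.0, 1.0], [1.0, np.e**2]]))
        dm = aitchison_distance(
            __import__("pandas").DataFrame(clr, index=["x", "y"])
        )
        assert dm["x", "y"] == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_metric_properties(self):
        rng = np.random.default_rng(2)
        t = FeatureTable(rng.integers(0, 100, (30, 6)),
                         [f"f{i}" for i in range(30)], [f"s{j}" for j in range(6)])
        dm = aitchison_distance(clr_transform(t, 0.5))
        d = dm.data
        assert np.all(d >= 0) and np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-9

    def test_feature_permutation_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 100, (20, 4))
        ids = [f"f{i}" for i in range(20)]
        sids = [f"s{j}" for j in range(4)]
        t1 = FeatureTable(counts, ids, sids)
        perm = rng.permutation(20)
        t2 = FeatureTable(counts[perm], [ids[i] for i in perm], sids)
        d1 = aitchison_distance(clr_transform(t1, 0.5)).data
        d2 = aitchison_distance(clr_transform(t2, 0.5)).data
        np.testing.assert_allclose(d1, d2, atol=1e-10)

    def test_count_scaling_invariance_in_small_pseudocount_limit(self):
        counts = np.array([[3, 30], [7, 70], [9, 90]])
        t = FeatureTable(counts, ["a", "b", "c"], ["s1", "s2"])
        dm = aitchison_distance(clr_transform(t, pseudocount=1e-9))
        assert dm["s1", "s2"] == pytest.approx(0.0, abs=1e-6)


class TestPCoA:
    def test_two_samples_embed_at_half_distance(self):
        dm = DistanceMatrix(np.array([[0.0, 3.0], [3.0, 0.0]]), ["a", "b"])
        ord_res = pcoa(dm, n_axes=2)
        coords = ord_res.coordinates["PC1"].to_numpy()
        np.testing.assert_allclose(sorted(coords), [-1.5, 1.5], atol=1e-12)

    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), [str(i) for i in range(10)])
        ord_res = pcoa(dm, n_axes=9)
        recon = squareform(pdist(ord_res.coordinates.to_numpy()))
        np.testing.assert_allclose(recon, dm.data, atol=1e-8)

    def test_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 4))
        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, [str(i) for i in range(8)])
        ord_res = pcoa(dm)
        n = 8
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d**2) @ j
        assert ord_res.eigenvalues.sum() == pytest.approx(np.trace(b), abs=1e-8)
        assert np.all(np.diff(ord_res.eigenvalues) <= 1e-12)
        assert ord_res.proportion_explained.sum() <= 1 + 1e-12

    def test_aitchison_matrix_has_no_negative_eigenvalues(self):
        rng = np.random.default_rng(6)
        t = FeatureTable(rng.integers(0, 200, (50, 12)),
                         [f"f{i}" for i in range(50)], [f"s{j}" for j in range(12)])
        dm = aitchison_distance(clr_transform(t, 0.5))
        ord_res = pcoa(dm)
        assert ord_res.eigenvalues.min() >= -1e-9

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(9, 5))
        dm = DistanceMatrix(squareform(pdist(pts)), [str(i) for i in range(9)])
        ours = pcoa(dm, n_axes=3).coordinates.to_numpy()
        ref = skbio_pcoa(dm, method="eigh").samples.to_numpy()[:, :3]
        for k in range(3):  # axes defined up to sign
            assert min(
                np.abs(ours[:, k] - ref[:, k]).max(),
                np.abs(ours[:, k] + ref[:, k]).max(),
            ) < 1e-8

    def test_degenerate_all_equal_distances(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(d, list("abcd"))
        ord_res = pcoa(dm)
        # symmetric simplex: equal positive eigenvalues, embedding exists
        assert ord_res.eigenvalues[0] == pytest.approx(ord_res.eigenvalues[2])


def _brute_force_anosim(d: np.ndarray, labels: list[str]):
    """Independent oracle: explicit rank table, all distinct label orderings."""
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    vals = d[iu]
    order = np.argsort(vals, kind="mergesort")
    ranks = np.empty(len(vals))
    # average ranks on ties, computed by grouping sorted values
    sorted_vals = vals[order]
    i = 0
    while i < len(vals):
        j = i
        while j < len(vals) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j

    def r_stat(lab):
        lab = np.asarray(lab)
        within = (lab[iu[0]] == lab[iu[1]])
        return (ranks[~within].mean() - ranks[within].mean()) / (n * (n - 1) / 4)

    r_obs = r_stat(labels)
    perms = sorted(set(itertools.permutations(labels)))
    hits = sum(r_stat(p) >= r_obs - 1e-12 for p in perms)
    return r_obs, hits / len(perms)


class TestAnosim:
    def test_worked_four_sample_example(self):
        d = np.array(
            [
                [0, 1, 3, 4],
                [1, 0, 5, 6],
                [3, 5, 0, 2],
                [4, 6, 2, 0],
            ],
            dtype=float,
        )
        dm = DistanceMatrix(d, list("abcd"))
        res = anosim(dm, ["g1", "g1", "g2", "g2"], method="exact")
        assert res.R == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 3)

    def test_matches_brute_force_on_small_instances(self):
        rng = np.random.default_rng(8)
        for n, sizes in [(6, (3, 3)), (7, (3, 4)), (8, (4, 4)), (8, (2, 3, 3))]:
            pts = rng.normal(size=(n, 3))
            d = squareform(pdist(pts))
            labels = [f"g{k}" for k, c in enumerate(sizes) for _ in range(c)]
            dm = DistanceMatrix(d, [str(i) for i in range(n)])
            res = anosim(dm, labels, method="exact")
            r_ref, p_ref = _brute_force_anosim(d, labels)
            assert res.R == pytest.approx(r_ref, abs=1e-12)
            assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_r_matches_reference_implementation(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(14, 4))
        dm = DistanceMatrix(squareform(pdist(pts)), [str(i) for i in range(14)])
        labels = ["a"] * 7 + ["b"] * 7
        res = anosim(dm, labels, n_permutations=99, seed=1, method="permutation")
        ref = skbio_anosim(dm, grouping=labels, permutations=0)
        assert res.R == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_null_mean_r_is_centered(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(16, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), [str(i) for i in range(16)])
        rs = []
        for _ in range(500):
            labels = rng.permutation(["a"] * 8 + ["b"] * 8)
            rs.append(anosim(dm, labels, n_permutations=1, seed=0,
                             method="permutation").R)
        assert abs(np.mean(rs)) < 0.05

    def test_all_tied_distances_give_r_zero(self):
        d = np.full((6, 6), 1.0)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(d, [str(i) for i in range(6)])
        res = anosim(dm, ["a"] * 3 + ["b"] * 3, method="exact")
        assert res.R == pytest.approx(0.0, abs=1e-12)

    def test_group_size_validation(self):
        d = np.full((3, 3), 1.0)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(d, list("abc"))
        with pytest.raises(ValidationError, match="fewer than 2"):
            anosim(dm, ["x", "x", "y"])
        with pytest.raises(ValidationError, match="2 groups"):
            anosim(dm, ["x", "x", "x"])


class TestPairwiseAnosim:
    def test_disjoint_supports_give_r_one(self):
        counts = np.zeros((8, 8), dtype=int)
        counts[:4, :4] = 50  # first 4 samples use features 0-3 only
        counts[4:, 4:] = 50
        t = FeatureTable(counts, [f"f{i}" for i in range(8)],
                         [f"s{j}" for j in range(8)])
        meta = Metadata(
            [SampleRecord(f"s{j}", "cow_home") for j in range(4)]
            + [SampleRecord(f"s{j}", "pig_home") for j in range(4, 8)]
        )
        dm = aitchison_distance(clr_transform(t, 0.5))
        df = pairwise_anosim(dm, meta, [("cow_home", "pig_home")],
                             n_permutations=99, seed=0)
        assert len(df) == 1
        assert df.R.iloc[0] == pytest.approx(1.0)

    def test_identical_generators_stay_null(self):
        # same base profile (divergence 0), no transfer: R ~ 0 and p > 0.05
        # in at least 90% of 100 replicates
        calm = 0
        for rep in range(100):
            sc = small_paired_scenario(
                seed=3000 + rep, n_farms=8, tau=0.0, n_features=120,
                depth=1500.0, divergence=0.0,
            )
            table, meta, _, _ = generate_study(sc)
            dm = aitchison_distance(clr_transform(table, 0.5))
            df = pairwise_anosim(dm, meta, [("cow_home", "cow_stable")],
                                 n_permutations=99, seed=rep)
            calm += df.p_value.iloc[0] > 0.05
        assert calm >= 90

    def test_r_monotone_in_environment_divergence(self):
        means = []
        for w in (0.0, 0.05, 0.15, 0.4, 1.0):
            rs = []
            for rep in range(50):
                sc = small_paired_scenario(
                    seed=4000 + rep, n_farms=8, tau=0.0, n_features=120,
                    depth=1500.0, divergence=w,
                )
                table, meta, _, _ = generate_study(sc)
                dm = aitchison_distance(clr_transform(table, 0.5))
                labels = [meta.environment_of(s) for s in table.sample_ids]
                rs.append(
                    anosim(dm, labels, n_permutations=1, seed=0,
                           method="permutation").R
                )
            means.append(np.mean(rs))
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:])), means

    def test_unknown_environment_rejected(self, tiny_table, tiny_metadata):
        dm = aitchison_distance(clr_transform(tiny_table, 0.5))
        with pytest.raises(ValidationError):
            pairwise_anosim(dm, tiny_metadata, [("cow_home", "nowhere")])
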