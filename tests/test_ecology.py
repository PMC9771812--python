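import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from tmeco.core_tables import ClusterCountTable
from tmeco.ecology import (
    bray_curtis,
    group_dissimilarity,
    kde_enrichment,
    knn_neighbours,
    patient_specificity,
    rarefied_dissimilarity,
    shannon_entropy,
)


def _table(counts: dict, meta: dict | None = None) -> ClusterCountTable:
    frame = pd.DataFrame(counts).T
    frame.index.name = "sample_id"
    frame.columns = pd.Index([f"k{i}" for i in range(frame.shape[1])], name="cluster")
    meta_df = pd.DataFrame(meta).T if meta else pd.DataFrame(index=frame.index)
    return ClusterCountTable(counts=frame, meta=meta_df)


class TestShannonEntropy:
    def test_degenerate_distribution_is_zero(self):
        assert shannon_entropy([100, 0, 0]) == 0.0

    @pytest.mark.parametrize("n_clusters", [2, 5, 17])
    def test_uniform_attains_log_c(self, n_clusters):
        assert shannon_entropy([7] * n_clusters) == pytest.approx(np.log(n_clusters), abs=1e-12)

    def test_direct_formula_evaluation(self):
        assert shannon_entropy([50, 25, 25]) == pytest.approx(1.0397207708399179)

    def test_bounds_and_relabelling(self, rng):
        counts = rng.integers(1, 100, 6)
        h = shannon_entropy(counts)
        assert 0 <= h <= np.log(6)
        assert shannon_entropy(counts[::-1]) == pytest.approx(h)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            shannon_entropy([0, 0])


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        assert bray_curtis([3, 4, 5], [3, 4, 5]) == 0.0
        assert bray_curtis([3, 0, 0], [0, 4, 5]) == 1.0

    def test_direct_formula_value(self):
        assert bray_curtis([10, 0, 5], [4, 6, 5]) == pytest.approx(0.4)

    def test_agrees_with_scipy(self, rng):
        for _ in range(20):
            x = rng.integers(0, 50, 8)
            y = rng.integers(0, 50, 8)
            if x.sum() == 0 or y.sum() == 0:
                continue
            assert bray_curtis(x, y) == pytest.approx(scipy_braycurtis(x, y))

    def test_symmetry_and_integer_scale_invariance(self, rng):
        x = rng.integers(0, 30, 5)
        y = rng.integers(1, 30, 5)
        assert bray_curtis(x, y) == pytest.approx(bray_curtis(y, x))
        assert bray_curtis(3 * x, 3 * y) == pytest.approx(bray_curtis(x, y))

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [1, 2])


class TestRarefiedDissimilarity:
    def test_identical_composition_yields_small_d(self):
        table = _table({"s1": [800] * 5, "s2": [800] * 5})
        dmat = rarefied_dissimilarity(table, n_cells=400, iterations=100, seed=0)
        assert dmat.values.loc["s1", "s2"] < 0.1

    def test_disjoint_single_cluster_samples_give_one(self):
        table = _table({"s1": [500, 0], "s2": [0, 500]})
        dmat = rarefied_dissimilarity(table, n_cells=400, iterations=20, seed=0)
        assert dmat.values.loc["s1", "s2"] == 1.0

    def test_fixed_seed_reproducible(self):
        table = _table({"s1": [300, 200, 100], "s2": [100, 200, 300], "s3": [200] * 3})
        a = rarefied_dissimilarity(table, n_cells=400, iterations=10, seed=3)
        b = rarefied_dissimilarity(table, n_cells=400, iterations=10, seed=3)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_small_samples_dropped_with_warning(self):
        table = _table({"s1": [500, 100], "s2": [300, 200], "tiny": [10, 10]})
        with pytest.warns(UserWarning, match="tiny"):
            dmat = rarefied_dissimilarity(table, n_cells=400, iterations=5, seed=0)
        assert "tiny" not in dmat.values.index

    def test_too_few_survivors_error(self):
        table = _table({"s1": [500, 100], "tiny": [10, 10]})
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                rarefied_dissimilarity(table, n_cells=400, iterations=5, seed=0)

    def test_iteration_mean_converged(self):
        """Entrywise sd of the iteration mean is small at 100 iterations."""
        table = _table({"s1": [500, 300, 200], "s2": [200, 300, 500]})
        reps = [
            rarefied_dissimilarity(table, n_cells=400, iterations=100, seed=s)
            .values.loc["s1", "s2"]
            for s in range(8)
        ]
        assert np.std(reps) < 0.01


class TestGroupDissimilarity:
    @pytest.fixture
    def dmat_meta(self):
        table = _table(
            {
                "p1_a": [400, 50, 50],
                "p1_b": [50, 400, 50],
                "p2_a": [400, 50, 50],
                "p2_c": [50, 50, 400],
            }
        )
        meta = pd.DataFrame(
            {
                "patient_id": ["p1", "p1", "p2", "p2"],
                "site": ["adnexa", "ascites", "adnexa", "omentum"],
            },
            index=table.counts.index,
        )
        dmat = rarefied_dissimilarity(table, n_cells=400, iterations=5, seed=0)
        return dmat, meta

    def test_pair_counting(self, dmat_meta):
        dmat, meta = dmat_meta
        intra = group_dissimilarity(dmat, meta, scheme="intra_patient")
        inter = group_dissimilarity(dmat, meta, scheme="inter_patient")
        assert len(intra) == 2  # (p1_a,p1_b) and (p2_a,p2_c)
        assert len(inter) == 4
        assert len(intra) + len(inter) == 6  # all i<j pairs

    def test_site_pair_filter_matches_enumeration(self, dmat_meta):
        dmat, meta = dmat_meta
        got = group_dissimilarity(
            dmat, meta, scheme="intra_patient", pair_filter=("site", "adnexa", "ascites")
        )
        expected = [
            frozenset((i, j))
            for i, j in itertools.combinations(meta.index, 2)
            if meta.loc[i, "patient_id"] == meta.loc[j, "patient_id"]
            and {meta.loc[i, "site"], meta.loc[j, "site"]} == {"adnexa", "ascites"}
        ]
        assert [frozenset((a, b)) for a, b in zip(got["sample_i"], got["sample_j"])] == expected

    def test_empty_group_warns(self, dmat_meta):
        dmat, meta = dmat_meta
        with pytest.warns(UserWarning):
            out = group_dissimilarity(
                dmat, meta, scheme="intra_patient", pair_filter=("site", "bowel", "bowel")
            )
        assert out.empty


class TestKdeEnrichment:
    @pytest.fixture
    def embedding(self, rng):
        a = rng.normal([0, 0], 1, size=(300, 2))
        b = rng.normal([6, 0], 1, size=(300, 2))
        return pd.DataFrame(
            {
                "x": np.r_[a[:, 0], b[:, 0]],
                "y": np.r_[a[:, 1], b[:, 1]],
                "group": ["a"] * 300 + ["b"] * 300,
            }
        )

    def test_identical_groups_give_zero_field(self, embedding):
        emb = embedding.copy()
        emb["group"] = "a"
        emb2 = pd.concat([emb, emb.assign(group="b")])
        _, _, field = kde_enrichment(emb2, "group", "a", "b", grid_size=50)
        np.testing.assert_allclose(field, 0.0, atol=1e-15)

    def test_sign_structure_around_centroids(self, embedding):
        gx, gy, field = kde_enrichment(embedding, "group", "a", "b", grid_size=60)
        ia = np.argmin(np.abs(gx - 0))
        ib = np.argmin(np.abs(gx - 6))
        iy = np.argmin(np.abs(gy - 0))
        assert field[ia, iy] > 0 > field[ib, iy]

    def test_field_integrates_to_zero(self, embedding):
        _, _, field = kde_enrichment(embedding, "group", "a", "b", grid_size=40)
        assert abs(field.sum()) < 1e-10


class TestKnnNeighbours:
    def test_collinear_points(self):
        emb = pd.DataFrame({"x": [0.0, 1.0, 3.0], "y": [0.0, 0.0, 0.0]})
        nbrs = knn_neighbours(emb, k=1)
        assert nbrs[1, 0] == 0  # middle point's neighbour is the nearer endpoint

    def test_matches_brute_force(self, rng):
        emb = pd.DataFrame(rng.uniform(0, 10, size=(200, 2)), columns=["x", "y"])
        nbrs = knn_neighbours(emb, k=5)
        xy = emb.to_numpy()
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        for i in range(200):
            expected = np.lexsort((np.arange(200), d2[i]))[:5]
            np.testing.assert_array_equal(np.sort(nbrs[i]), np.sort(expected))

    def test_k_equals_n_minus_one_is_complete(self):
        emb = pd.DataFrame({"x": [0.0, 1.0, 2.0, 5.0], "y": [0.0] * 4})
        nbrs = knn_neighbours(emb, k=3)
        for i in range(4):
            assert set(nbrs[i]) == set(range(4)) - {i}

    def test_k_too_large_errors(self):
        emb = pd.DataFrame({"x": [0.0, 1.0], "y": [0.0, 0.0]})
        with pytest.raises(ValueError):
            knn_neighbours(emb, k=2)


class TestPatientSpecificity:
    def test_matched_fractions_score_zero(self):
        # 4 cells, 2 patients; each cell has 1 same-patient and 1 other neighbour
        neighbours = np.array([[1, 2], [0, 3], [3, 0], [2, 1]])
        labels = pd.Series(["p1", "p1", "p2", "p2"])
        out = patient_specificity(neighbours, labels)
        np.testing.assert_allclose(out["score"], 0.0)

    def test_fully_private_neighbourhood(self):
        # all k neighbours same patient, global fraction 0.25, tiny pseudocount
        labels = pd.Series(["p1"] * 2 + ["p2"] * 2 + ["p3"] * 2 + ["p4"] * 2)
        neighbours = np.array([[1], [0], [3], [2], [5], [4], [7], [6]])
        out = patient_specificity(neighbours, labels, pseudocount=1e-12)
        np.testing.assert_allclose(out["score"], np.log2(1 / 0.25), atol=1e-9)

    def test_permutation_null_centres_on_zero(self, rng):
        emb = pd.DataFrame(rng.uniform(0, 10, size=(400, 2)), columns=["x", "y"])
        labels = pd.Series(rng.choice(["p1", "p2", "p3", "p4"], 400))
        nbrs = knn_neighbours(emb, k=20)
        out = patient_specificity(nbrs, labels)
        assert abs(out["score"].mean()) < 0.1

    def test_missing_label_errors(self):
        with pytest.raises(ValueError):
            patient_specificity(np.array([[1], [0]]), pd.Series(["p1", None]))
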