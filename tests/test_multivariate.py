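import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conceptome import (fisher_exact_2x2, factor_association_scan,
                        hier_cluster, pca, quadrant_classification)
from conceptome.datamodel import ValidationError
from conceptome.multivariate import PCAResult, orient_dimension
from conceptome.preprocess import ScaledMatrix


def _scaled(values, genes=None, samples=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestPCA:
    def test_rank_one_data_puts_all_variance_on_dim1(self, rng):
        base = rng.normal(size=12)
        res = pca(_scaled(np.vstack([base, 2 * base])))
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-8)

    def test_isotropic_two_genes_split_variance(self, rng):
        values = rng.normal(size=(2, 500))
        res = pca(_scaled(values))
        assert res.variance_fraction[0] == pytest.approx(0.5, abs=0.05)

    def test_reconstruction_reproduces_centered_input(self, rng):
        values = rng.normal(size=(6, 10))
        res = pca(_scaled(values))
        recon = res.coordinates.to_numpy() @ res.loadings.to_numpy().T
        centered = values.T - values.T.mean(axis=0, keepdims=True)
        np.testing.assert_allclose(recon, centered, atol=1e-8)

    def test_variance_fractions_match_covariance_eigenvalues(self, rng):
        values = rng.normal(size=(8, 25))
        res = pca(_scaled(values))
        X = values.T - values.T.mean(axis=0, keepdims=True)
        eig = np.sort(np.linalg.eigvalsh(X.T @ X))[::-1]
        np.testing.assert_allclose(res.variance_fraction[:8],
                                   (eig / eig.sum())[:8], atol=1e-8)

    def test_sign_convention_largest_loading_positive(self, rng):
        values = rng.normal(size=(5, 9))
        res = pca(_scaled(values))
        for d in res.loadings.columns:
            col = res.loadings[d].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_loadings_orthonormal(self, rng):
        values = rng.normal(size=(5, 9))
        res = pca(_scaled(values))
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_fewer_than_two_genes_rejected(self, rng):
        with pytest.raises(ValidationError):
            pca(_scaled(rng.normal(size=(1, 5))))


def _meta_for(samples, conditions):
    return pd.DataFrame({"sample_id": samples, "tissue": "embryo",
                         "condition": conditions,
                         "somite_pairs": 5 + np.arange(len(samples)) % 5,
                         "conceptus_id": samples, "sex": "unknown"})


class TestQuadrant:
    def _pca_with_dim2(self, coords2, samples):
        coords = pd.DataFrame({"Dim1": np.zeros(len(samples)),
                               "Dim2": coords2}, index=samples)
        return PCAResult(coordinates=coords,
                         variance_fraction=np.array([0.5, 0.3]),
                         loadings=pd.DataFrame())

    def test_counts_and_margins(self):
        samples = [f"s{j}" for j in range(6)]
        meta = _meta_for(samples, ["diabetic"] * 3 + ["normal"] * 3)
        res = self._pca_with_dim2([1, 2, -1, -2, 3, 0], samples)
        quad = quadrant_classification(res, meta, dim=2)
        # zero coordinate counts as positive
        assert quad.counts.loc["diabetic"].tolist() == [2, 1]
        assert quad.counts.loc["normal"].tolist() == [2, 1]
        assert quad.counts.to_numpy().sum() == 6

    def test_balanced_symmetric_coordinates_give_p_one(self):
        samples = [f"s{j}" for j in range(8)]
        meta = _meta_for(samples, ["diabetic"] * 4 + ["normal"] * 4)
        res = self._pca_with_dim2([1, 1, -1, -1, 1, 1, -1, -1], samples)
        quad = quadrant_classification(res, meta, dim=2)
        assert quad.pvalue == pytest.approx(1.0)

    def test_invariant_to_positive_rescaling(self):
        samples = [f"s{j}" for j in range(6)]
        meta = _meta_for(samples, ["diabetic"] * 3 + ["normal"] * 3)
        base = [1.0, 2.0, -1.0, -2.0, 3.0, -4.0]
        q1 = quadrant_classification(self._pca_with_dim2(base, samples),
                                     meta, dim=2)
        q2 = quadrant_classification(
            self._pca_with_dim2([17.3 * c for c in base], samples), meta, dim=2)
        pd.testing.assert_frame_equal(q1.counts, q2.counts)


def fisher_enumeration(table):
    """Full hypergeometric enumeration over the support of the margins."""
    a, b, c, d = np.asarray(table).ravel()
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {k: stats.hypergeom.pmf(k, n, c1, r1) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


class TestFisherExact:
    def test_study_quadrant_table(self):
        orr, p = fisher_exact_2x2([[23, 10], [9, 24]])
        assert round(p, 4) == 0.0012

    def test_uniform_table_is_one(self):
        _, p = fisher_exact_2x2([[1, 1], [1, 1]])
        assert p == pytest.approx(1.0)

    def test_diagonal_table_enumerates_to_point_one(self):
        # margins 3/3 over N=6: only the two extreme tables are as unlikely
        orr, p = fisher_exact_2x2([[3, 0], [0, 3]])
        assert p == pytest.approx(0.1, rel=1e-7)
        assert np.isinf(orr)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 201))
        a_b = int(rng.integers(0, n + 1))
        r1 = a_b
        c1 = int(rng.integers(0, n + 1))
        lo, hi = max(0, r1 + c1 - n), min(r1, c1)
        a = int(rng.integers(lo, hi + 1))
        table = [[a, r1 - a], [c1 - a, n - r1 - c1 + a]]
        _, p = fisher_exact_2x2(table)
        assert p == pytest.approx(fisher_enumeration(table), rel=1e-7)


class TestFactorScan:
    def test_separating_factor_detected_on_dim1(self, rng):
        n = 40
        group = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        values = rng.normal(size=(20, n)) + 3 * group[None, :]
        samples = [f"s{j}" for j in range(n)]
        meta = _meta_for(samples, np.where(group == 1, "diabetic", "normal"))
        res = pca(_scaled(values, samples=samples))
        scan = factor_association_scan(res, meta, "condition", max_dim=3,
                                       n_permutations=200, seed=0)
        assert abs(scan.loc[0, "statistic"]) > 0.8
        assert scan.loc[0, "pvalue"] < 0.01

    def test_shuffled_factor_gives_unremarkable_pvalues(self, rng):
        values = rng.normal(size=(20, 40))
        samples = [f"s{j}" for j in range(40)]
        cond = rng.permutation(["diabetic"] * 20 + ["normal"] * 20)
        meta = _meta_for(samples, cond)
        res = pca(_scaled(values, samples=samples))
        scan = factor_association_scan(res, meta, "condition", max_dim=5,
                                       n_permutations=500, seed=1)
        assert scan["pvalue"].min() > 0.001

    def test_constant_factor_yields_nan(self, rng):
        values = rng.normal(size=(5, 10))
        samples = [f"s{j}" for j in range(10)]
        meta = _meta_for(samples, ["normal"] * 10)
        res = pca(_scaled(values, samples=samples))
        with pytest.warns(UserWarning, match="constant"):
            scan = factor_association_scan(res, meta, "condition", max_dim=2)
        assert scan["statistic"].isna().all()


def average_linkage_oracle(dist):
    """Exhaustive agglomeration: merge the closest pair, averaging by size."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
            if best is None or d < best[0] - 1e-15:
                best = (d, i, j)
        d, i, j = best
        merges.append((frozenset(clusters[i] + clusters[j]), d))
        clusters[min(i, j)] = clusters.pop(i) + clusters.pop(j)
        if max(i, j) in clusters:
            clusters.pop(max(i, j))
    return merges


class TestHierCluster:
    def test_identical_samples_merge_first_at_zero(self, rng):
        values = rng.normal(size=(10, 4))
        values[:, 1] = values[:, 0]
        df = pd.DataFrame(values, columns=list("abcd"))
        res = hier_cluster(df, axis="samples")
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(res.linkage_matrix[0, :2].astype(int)) == {0, 1}

    def test_anticorrelated_profiles_at_distance_two(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
                          index=["up", "down"])
        res = hier_cluster(df, axis="genes")
        assert res.linkage_matrix[0, 2] == pytest.approx(2.0)

    def test_nan_rows_rejected_with_advice(self):
        df = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValidationError, match="NaN"):
            hier_cluster(df, axis="genes")

    @pytest.mark.parametrize("n_items", [4, 5, 6])
    def test_merges_match_exhaustive_oracle(self, n_items, rng):
        values = rng.normal(size=(n_items, 12))
        df = pd.DataFrame(values, index=[f"g{i}" for i in range(n_items)])
        res = hier_cluster(df, axis="genes")
        # recompute the distance matrix the implementation clusters on
        centered = values - values.mean(axis=1, keepdims=True)
        unit = centered / np.linalg.norm(centered, axis=1, keepdims=True)
        dist = 1 - unit @ unit.T
        np.fill_diagonal(dist, 0)
        expected = average_linkage_oracle(dist)
        clusters = {i: frozenset([i]) for i in range(n_items)}
        for row, (exp_set, exp_h) in zip(res.linkage_matrix, expected):
            i, j, h, _ = row
            merged = clusters[int(i)] | clusters[int(j)]
            clusters[len(clusters)] = merged
            assert merged == exp_set
            assert h == pytest.approx(exp_h, abs=1e-10)


class TestOrientDimension:
    def test_normal_mean_becomes_positive(self, rng):
        samples = [f"s{j}" for j in range(6)]
        meta = _meta_for(samples, ["normal"] * 3 + ["diabetic"] * 3)
        coords = pd.DataFrame({"Dim1": [-2.0, -1.0, -3.0, 2.0, 1.0, 3.0]},
                              index=samples)
        res = PCAResult(coords, np.array([1.0]),
                        pd.DataFrame({"Dim1": [1.0]}, index=["g"]))
        out = orient_dimension(res, meta, dim=1)
        assert out.coordinates.loc[samples[:3], "Dim1"].mean() > 0
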