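import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conceptome import (CountMatrix, ValidationError, bh_adjust,
                        classify_fold_changes, de_test, estimate_dispersion,
                        estimate_size_factors, null_config, simulate_dataset)


def _cm(rows, genes=None, samples=None):
    rows = np.asarray(rows)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{j}" for j in range(rows.shape[1])]
    return CountMatrix(pd.DataFrame(rows, index=genes, columns=samples))


def bh_bruteforce(p):
    """Independent step-up oracle: sort, scale by m/rank, cummin from the top."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestSizeFactors:
    def test_doubled_sample_gives_sqrt2_factors(self):
        cm = _cm([[2, 4], [8, 16], [1, 2]])
        sf = estimate_size_factors(cm)
        np.testing.assert_allclose(sf.to_numpy(),
                                   [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_identical_samples_give_unit_factors(self):
        sf = estimate_size_factors(_cm([[5, 5], [9, 9]]))
        np.testing.assert_allclose(sf.to_numpy(), [1.0, 1.0])

    def test_fallback_to_library_ratios_without_common_genes(self):
        cm = _cm([[4, 0], [0, 8]])
        sf = estimate_size_factors(cm)
        np.testing.assert_allclose(sf.to_numpy(),
                                   [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)


class TestDispersion:
    def test_poisson_gene_estimates_at_floor(self, rng):
        y = rng.poisson(50, size=(400, 40))
        cm = _cm(y)
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = estimate_dispersion(cm, sf)
        # Poisson variance equals the mean, so raw alpha piles up near zero
        assert np.nanmedian(disp["raw"]) < 0.01

    def test_nb_dispersion_recovered(self, rng):
        alpha = 0.1
        mu = 100.0
        size = 1 / alpha
        y = rng.negative_binomial(size, size / (size + mu), size=(600, 66))
        cm = _cm(y)
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = estimate_dispersion(cm, sf)
        assert 0.05 <= np.nanmedian(disp["final"]) <= 0.2

    def test_all_zero_gene_marked_na(self):
        cm = _cm([[0, 0, 0, 0, 0, 0], [5, 6, 7, 5, 6, 7]])
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = estimate_dispersion(cm, sf)
        assert np.isnan(disp.loc["g0", "final"])
        assert np.isfinite(disp.loc["g1", "final"])


class TestBHAdjust:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_and_tied_pvalues_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], bh_adjust([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=1, max_size=300))
    def test_matches_bruteforce_oracle(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), bh_bruteforce(pvals),
                                   rtol=1e-12)


class TestDETest:
    def _meta(self, n_samples, n_normal):
        cond = ["normal"] * n_normal + ["diabetic"] * (n_samples - n_normal)
        return pd.DataFrame({
            "sample_id": [f"s{j}" for j in range(n_samples)],
            "tissue": "embryo", "condition": cond,
            "somite_pairs": 5 + np.arange(n_samples) % 5,
            "conceptus_id": [f"c{j}" for j in range(n_samples)],
            "sex": "unknown"})

    def test_label_swap_negates_log2fc_and_keeps_p(self, rng):
        y = rng.poisson(40, size=(50, 12))
        cm = _cm(y)
        meta = self._meta(12, 6)
        res, _ = de_test(cm, meta)
        swapped = meta.copy()
        swapped["condition"] = swapped["condition"].map(
            {"normal": "diabetic", "diabetic": "normal"})
        res2, _ = de_test(cm, swapped)
        np.testing.assert_allclose(res2["log2fc"], -res["log2fc"], atol=1e-8)
        np.testing.assert_allclose(res2["pvalue"], res["pvalue"], atol=1e-10)

    def test_planted_fold_change_recovered(self):
        # 30 genes at true log2FC = 1 among a null majority (so size-factor
        # normalization is anchored), at the study's group size n = 33
        rng = np.random.default_rng(42)
        n, alpha = 33, 0.05
        size = 1 / alpha
        mu = rng.uniform(40, 150, size=230)
        y_n = rng.negative_binomial(size, size / (size + mu[:, None]),
                                    size=(230, n))
        mu_d = mu.copy()
        mu_d[:30] *= 2.0
        y_d = rng.negative_binomial(size, size / (size + mu_d[:, None]),
                                    size=(230, n))
        cm = _cm(np.hstack([y_n, y_d]))
        res, _ = de_test(cm, self._meta(2 * n, n))
        planted = res["log2fc"].to_numpy()[:30]
        assert abs(planted.mean() - 1.0) < 0.3
        assert np.abs(planted - 1.0).max() < 1.0

    def test_all_zero_gene_excluded_and_reported(self):
        y = np.full((3, 12), 20)
        y[1] = 0
        res, excluded = de_test(_cm(y), self._meta(12, 6))
        assert excluded == ["g1"]
        assert "g1" not in set(res["gene_id"])

    def test_too_few_samples_per_condition_rejected(self, rng):
        y = rng.poisson(10, size=(5, 4))
        with pytest.raises(ValidationError):
            de_test(_cm(y), self._meta(4, 2))

    def test_agrees_with_statsmodels_glm_fit(self, rng):
        """Dual route: the vectorized IRLS against statsmodels NB GLM."""
        import statsmodels.api as sm
        y = rng.negative_binomial(20, 20 / (20 + 60.0), size=(8, 30))
        cm = _cm(y)
        meta = self._meta(30, 15)
        sf = estimate_size_factors(cm)
        disp = estimate_dispersion(cm, sf,
                                   condition=meta.set_index("sample_id")
                                   .loc[cm.sample_ids, "condition"])
        res, _ = de_test(cm, meta)
        X = sm.add_constant((meta["condition"] == "diabetic").astype(float))
        for i, gene in enumerate(cm.gene_ids):
            fam = sm.families.NegativeBinomial(
                alpha=max(disp.loc[gene, "final"], 1e-8))
            fit = sm.GLM(y[i], X, family=fam,
                         offset=np.log(sf.to_numpy())).fit()
            assert res.loc[res["gene_id"] == gene, "log2fc"].iloc[0] == \
                pytest.approx(fit.params.iloc[1] / np.log(2), abs=1e-4)


class TestFoldChangeCategories:
    def _res(self, lfcs, sig):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(lfcs))],
                             "log2fc": lfcs, "significant": sig})

    def test_category_boundaries(self):
        res = self._res([0.6, -0.1, 0.2, 5.0], [True, True, True, False])
        counts = classify_fold_changes(res)
        assert counts["up>1.5x"] == 1       # 2^0.6 = 1.52 > 1.5
        assert counts["up<=1.5x"] == 1      # 2^0.2 = 1.15
        assert counts["down<=1.5x"] == 1
        assert counts["n_significant"] == 3  # non-significant gene ignored

    def test_no_significant_genes(self):
        counts = classify_fold_changes(self._res([1.0], [False]))
        assert counts["n_significant"] == 0
        assert counts["n_up"] == counts["n_down"] == 0
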