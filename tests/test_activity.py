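import numpy as np
import pandas as pd
import pytest

from scnova.activity import (
    NBDifferential,
    NEClassifier,
    compute_size_factors,
    estimate_dispersions,
    gene_features,
    mask_scna_genes,
    nb_wald_test,
    plsda_alt_mode,
    retain_by_ne_probability,
    train_ne_classifier,
)
from scnova.stats import bh_adjust
from conftest import make_fragments


class TestGeneFeatures:
    def test_uniform_coverage_gives_equal_bins(self):
        rows = [("chr1", i * 150, i * 150 + 150, "c1", "W", ".", 30, 0, 0) for i in range(20)]
        fs = make_fragments(rows)
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"], "start": [300], "end": [2700], "strand": ["+"]})
        f = gene_features(fs, genes, n_bins=10, chrom_lengths={"chr1": 3_000})
        no = f.loc["g", [f"no_{i}" for i in range(10)]].to_numpy(float)
        np.testing.assert_allclose(no, no[0])

    def test_300bp_gene_150_bins_are_2bp_means(self):
        rows = [("chr1", 100, 250, "c1", "W", ".", 30, 0, 0)]  # covers first half of gene
        fs = make_fragments(rows)
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"], "start": [100], "end": [400], "strand": ["+"]})
        f = gene_features(fs, genes, n_bins=150, chrom_lengths={"chr1": 1_000})
        no = f.loc["g", [f"no_{i}" for i in range(150)]].to_numpy(float)
        np.testing.assert_allclose(no[:75], 1.0)
        np.testing.assert_allclose(no[75:], 0.0)

    def test_gc_lookup_and_log_length(self):
        fs = make_fragments([("chr1", 0, 150, "c1", "W", ".", 30, 0, 0)])
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"], "start": [0], "end": [1000], "strand": ["+"]})
        gc = {"chr1": np.array([1.0])}
        f = gene_features(fs, genes, gc=gc, n_bins=5, chrom_lengths={"chr1": 1_000})
        np.testing.assert_allclose(f.loc["g", [f"gc_{i}" for i in range(5)]].to_numpy(float), 1.0)
        assert f.loc["g", "log_length"] == pytest.approx(np.log(1000))

    def test_zero_length_gene_rejected(self):
        fs = make_fragments([("chr1", 0, 150, "c1", "W", ".", 30, 0, 0)])
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"], "start": [10], "end": [10], "strand": ["+"]})
        with pytest.raises(ValueError):
            gene_features(fs, genes)


class TestNEClassifier:
    def _training_data(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        ne = rng.random(n) < 0.5
        # silent genes have uniformly higher NO in every bin
        no = rng.normal(np.where(ne[:, None], 8.0, 3.0), 1.0, size=(n, 10))
        X = pd.DataFrame(no, columns=[f"no_{i}" for i in range(10)], index=[f"g{i}" for i in range(n)])
        return X, ne.astype(int)

    def test_separable_training_accuracy(self):
        X, y = self._training_data()
        model = train_ne_classifier(X, y, seed=0)
        pred = (model.predict_proba(X) >= 0.5).astype(int)
        assert (pred.to_numpy() == y).mean() >= 0.95

    def test_retrain_same_seed_identical(self):
        X, y = self._training_data(seed=1)
        p1 = train_ne_classifier(X, y, seed=3).predict_proba(X)
        p2 = train_ne_classifier(X, y, seed=3).predict_proba(X)
        pd.testing.assert_series_equal(p1, p2)

    def test_single_class_labels_rejected(self):
        X, y = self._training_data()
        with pytest.raises(ValueError, match="both"):
            train_ne_classifier(X, np.zeros_like(y))

    def test_logistic_matches_unregularized_mle_on_1d(self):
        # oracle: statsmodels Logit (unpenalized ML) on the same feature
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        p = 1 / (1 + np.exp(-(0.5 + 2.0 * x)))
        y = (rng.random(300) < p).astype(int)
        X = pd.DataFrame({"no_0": x})
        model = train_ne_classifier(X, y, C=1e8, seed=0)
        ref = sm.Logit(y, sm.add_constant((x - x.mean()) / x.std(ddof=1))).fit(disp=0)
        mine = model.predict_proba(X).to_numpy()
        theirs = ref.predict()
        np.testing.assert_allclose(mine, theirs, atol=1e-4)


class TestNEFilter:
    @pytest.mark.parametrize(
        "probs,expected_retained",
        [
            ({"clone1": [0.95], "clone2": [0.92]}, []),  # NE everywhere -> removed
            ({"clone1": [0.95], "clone2": [0.89]}, ["g0"]),  # one clone below -> retained
            ({"clone1": [0.9], "clone2": [0.9]}, []),  # boundary is inclusive
            ({"clone1": [0.1], "clone2": [0.2]}, ["g0"]),
        ],
    )
    def test_filter_boundary_behavior(self, probs, expected_retained):
        df = pd.DataFrame(probs, index=["g0"])
        assert retain_by_ne_probability(df, 0.9) == expected_retained

    def test_no_clones_rejected(self):
        with pytest.raises(ValueError):
            retain_by_ne_probability(pd.DataFrame(index=["g0"]))


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        k = pd.DataFrame({"a": [5, 10, 3], "b": [5, 10, 3]})
        np.testing.assert_allclose(compute_size_factors(k), 1.0)

    def test_scaled_column_recovers_ratio(self):
        base = np.array([10, 20, 30, 40])
        k = pd.DataFrame({"ref": base, "double": 2 * base})
        s = compute_size_factors(k)
        assert s["double"] / s["ref"] == pytest.approx(2.0)

    def test_3x2_matches_brute_force(self):
        k = pd.DataFrame({"a": [4, 9, 16], "b": [1, 3, 4]})
        gm = np.exp(np.log(k.to_numpy()).mean(axis=1))
        expected = np.median(k.to_numpy() / gm[:, None], axis=0)
        np.testing.assert_allclose(compute_size_factors(k).to_numpy(), expected)

    def test_no_all_positive_gene_raises(self):
        k = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            compute_size_factors(k)


class TestDispersions:
    def test_poisson_counts_give_near_zero_alpha(self):
        rng = np.random.default_rng(0)
        mu = rng.uniform(10, 60, 200)
        k = pd.DataFrame(rng.poisson(np.tile(mu[:, None], (1, 100))))
        d = estimate_dispersions(k, size_factors=pd.Series(1.0, index=k.columns))
        assert d.median() < 0.05

    def test_nb_alpha_recovery(self):
        rng = np.random.default_rng(1)
        alpha = 0.5
        mu = rng.uniform(20, 60, 200)
        lam = np.tile(mu[:, None], (1, 100))
        k = pd.DataFrame(rng.negative_binomial(1 / alpha, 1 / (1 + alpha * lam)))
        d = estimate_dispersions(k, size_factors=pd.Series(1.0, index=k.columns))
        assert 0.3 <= d.median() <= 0.7

    def test_constant_gene_zero_dispersion(self):
        k = pd.DataFrame({"a": [7, 2], "b": [7, 2], "c": [7, 2]})
        d = estimate_dispersions(k, size_factors=pd.Series(1.0, index=k.columns))
        assert d.iloc[0] == 0.0


class TestNBWald:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(2)
        half = rng.poisson(20, size=(30, 10))
        k = pd.DataFrame(np.hstack([half, half]), columns=[f"c{i}" for i in range(20)])
        groups = np.array(["a"] * 10 + ["b"] * 10)
        res = nb_wald_test(k, groups, size_factors=pd.Series(1.0, index=k.columns))
        assert res.frame["stat"].abs().max() < 1e-6
        assert res.frame["p"].min() > 1 - 1e-6

    def test_poisson_limit_matches_closed_form(self):
        rng = np.random.default_rng(3)
        k = pd.DataFrame(rng.poisson(25, size=(40, 30)), columns=[f"c{i}" for i in range(30)])
        groups = np.array(["a"] * 15 + ["b"] * 15)
        s = pd.Series(1.0, index=k.columns)
        res = nb_wald_test(k, groups, size_factors=s, dispersions=pd.Series(0.0, index=k.index))
        y = k.to_numpy()
        closed = np.log2(y[:, 15:].mean(axis=1)) - np.log2(y[:, :15].mean(axis=1))
        np.testing.assert_allclose(res.frame["log2fc"].to_numpy(), closed, atol=1e-8)

    def test_statsmodels_glm_oracle(self):
        # independent NB-GLM fit with the same fixed dispersion and offset
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        y = rng.negative_binomial(5, 0.2, size=24).astype(float)
        k = pd.DataFrame([y], index=["g"], columns=[f"c{i}" for i in range(24)])
        groups = np.array(["a"] * 12 + ["b"] * 12)
        s = pd.Series(rng.lognormal(0, 0.1, 24), index=k.columns)
        alpha = 0.25
        res = NBDifferential(k, groups, size_factors=s, dispersions=pd.Series([alpha], index=["g"])).fit()
        X = sm.add_constant((groups == "b").astype(float))
        ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=np.log(s.to_numpy())).fit()
        assert res.frame["log2fc"].iloc[0] == pytest.approx(ref.params[1] / np.log(2), rel=1e-5)
        assert res.frame["se"].iloc[0] == pytest.approx(ref.bse[1] / np.log(2), rel=1e-4)

    def test_all_zero_group_flagged_na(self):
        k = pd.DataFrame({"c1": [0], "c2": [0], "c3": [4], "c4": [6]}, index=["g"])
        res = nb_wald_test(k, np.array(["a", "a", "b", "b"]), size_factors=pd.Series(1.0, index=k.columns))
        assert np.isnan(res.frame["p"].iloc[0])

    def test_score_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(5)
        k = pd.DataFrame(rng.poisson(30, size=(20, 20)), columns=[f"c{i}" for i in range(20)])
        k.iloc[:5, 10:] *= 2
        groups = np.array(["a"] * 10 + ["b"] * 10)
        swapped = np.where(groups == "a", "b", "a")
        s = pd.Series(1.0, index=k.columns)
        d = pd.Series(0.01, index=k.index)
        r1 = nb_wald_test(k, groups, s, d).frame
        r2 = nb_wald_test(k, swapped, s, d).frame
        np.testing.assert_allclose(r1["score"], -r2["score"], atol=1e-6)
        np.testing.assert_allclose(r1["log2fc"], -r2["log2fc"], atol=1e-8)


class TestPLSDAAltMode:
    def _data(self, fold=3.0, seed=0, n_genes=30):
        rng = np.random.default_rng(seed)
        base = rng.uniform(2, 6, n_genes)
        x = pd.DataFrame(
            rng.normal(np.tile(base[:, None], (1, 40)), 0.4),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"c{i}" for i in range(40)],
        )
        x.iloc[0, 20:] += np.log2(fold)
        groups = np.array(["a"] * 20 + ["b"] * 20)
        return x, groups

    def test_powered_gene_detected(self):
        x, groups = self._data()
        res = plsda_alt_mode(x, groups, n_perm=499, seed=0)
        assert res.frame.loc[res.frame["gene_id"] == "g0", "q"].iloc[0] < 0.1

    def test_p_floor_and_vip_identity(self):
        x, groups = self._data()
        res = plsda_alt_mode(x, groups, n_perm=99, seed=1)
        assert (res.frame["p"] >= 1 / 100).all()
        assert (res.frame["stat"] ** 2).sum() == pytest.approx(len(x), rel=1e-9)

    def test_small_group_warns(self):
        x, _ = self._data()
        groups = np.array(["a"] + ["b"] * 39)
        with pytest.warns(UserWarning, match="< 2 cells"):
            plsda_alt_mode(x, groups, n_perm=19, seed=0)


class TestMaskSCNA:
    genes = pd.DataFrame(
        {"gene_id": ["g1", "g2", "g3"], "chrom": ["chr1"] * 3, "start": [0, 1000, 2000], "end": [500, 1500, 2500], "strand": ["+"] * 3}
    )

    def _cn(self, rows):
        return pd.DataFrame(rows, columns=["scope", "chrom", "start", "end", "haplotype", "cn"])

    def test_no_somatic_change_is_identity(self):
        cn = self._cn([("germline", "chr1", 0, 3000, "BOTH", 2)])
        assert mask_scna_genes(self.genes, cn, "a", "b") == ["g1", "g2", "g3"]

    def test_gene_in_subclonal_deletion_removed(self):
        cn = self._cn(
            [
                ("a", "chr1", 0, 3000, "BOTH", 2),
                ("b", "chr1", 0, 1400, "BOTH", 1),
                ("b", "chr1", 1400, 3000, "BOTH", 2),
            ]
        )
        assert mask_scna_genes(self.genes, cn, "a", "b") == ["g3"]

    def test_gene_ending_at_segment_boundary_retained(self):
        # deletion starts exactly where g1 ends: half-open, no overlap
        cn = self._cn(
            [
                ("a", "chr1", 0, 3000, "BOTH", 2),
                ("b", "chr1", 0, 500, "BOTH", 2),
                ("b", "chr1", 500, 900, "BOTH", 1),
                ("b", "chr1", 900, 3000, "BOTH", 2),
            ]
        )
        assert "g1" in mask_scna_genes(self.genes, cn, "a", "b")


class TestBH:
    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(6)
        p = rng.random(50)
        q = bh_adjust(p)
        order = np.argsort(p)
        m = len(p)
        brute = np.empty(m)
        for rank, idx in enumerate(order, start=1):
            candidates = [p[j] * m / (list(order).index(j) + 1) for j in order[rank - 1:]]
            brute[idx] = min(1.0, min(candidates))
        np.testing.assert_allclose(q, brute, atol=1e-12)

    def test_nan_propagation(self):
        q = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and np.isfinite(q[0])

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(7)
        p = rng.random(30)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
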