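from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scnova.fragments import classify_strand_states
from scnova.haplo import (
    HaplotypeCounts,
    SVCall,
    cre_exact_test,
    haplotype_unit_counts,
    local_scan,
    sliding_window_scan,
    tad_outlier_test,
)
from scnova.haplo import test_haplotype_no as haplotype_wilcoxon  # alias: keep pytest from collecting it
from conftest import make_fragments


def mixed_state_fragments(cell="c1", chrom="chr1", n_h1=15, n_h2=15, start=0):
    """Fragments giving the cell a WC state on the chromosome."""
    rows = [(chrom, start + 100 * i, start + 100 * i + 150, cell, "W", "H1", 30, 0, 0) for i in range(n_h1)]
    rows += [(chrom, start + 100 * (i + n_h1), start + 100 * (i + n_h1) + 150, cell, "C", "H2", 30, 0, 0) for i in range(n_h2)]
    return rows


class TestHaplotypeUnitCounts:
    units = pd.DataFrame({"unit_id": ["u1"], "chrom": ["chr1"], "start": [0], "end": [10_000]})

    def test_ww_chromosome_contributes_nothing(self):
        rows = [("chr1", 100 * i, 100 * i + 150, "c1", "W", "H1", 30, 0, 0) for i in range(30)]
        fs = make_fragments(rows)
        states = classify_strand_states(fs, min_fragments=10)
        hc = haplotype_unit_counts(fs, self.units, states)
        assert hc.counts.empty

    def test_direct_count_on_wc_chromosome(self):
        fs = make_fragments(mixed_state_fragments(n_h1=10, n_h2=20))
        states = classify_strand_states(fs, min_fragments=10)
        hc = haplotype_unit_counts(fs, self.units, states)
        row = hc.counts.iloc[0]
        # the unit covers only the first 10 kb: exactly the 10 H1 fragments
        assert row["h1"] == 10

    def test_counts_conserve_total(self):
        rows = mixed_state_fragments(n_h1=12, n_h2=12)
        # strip some tags to unphased
        for i in (0, 5):
            rows[i] = rows[i][:5] + (".",) + rows[i][6:]
        fs = make_fragments(rows)
        states = classify_strand_states(fs, min_fragments=10)
        units = pd.DataFrame({"unit_id": ["u"], "chrom": ["chr1"], "start": [0], "end": [100_000]})
        hc = haplotype_unit_counts(fs, units, states)
        row = hc.counts.iloc[0]
        assert row["h1"] + row["h2"] + row["unphased"] == len(rows)

    def test_removing_mixed_cells_empties_counts(self, sim_haplo_effect):
        _, genome, frags, truth, _ = sim_haplo_effect
        states = classify_strand_states(frags)
        mixed = states.entries[states.entries["state"].isin(["WC", "CW"])]
        keep_cells = set(states.entries["cell"]) - set(mixed["cell"])
        sub = frags.subset(frags.df["cell"].isin(keep_cells).to_numpy())
        units = genome.genes.rename(columns={"gene_id": "unit_id"})[["unit_id", "chrom", "start", "end"]]
        hc = haplotype_unit_counts(sub, units, classify_strand_states(sub))
        assert hc.counts.empty


class TestWilcoxon:
    def _hc(self, h1_values, h2_values):
        counts = pd.DataFrame(
            {
                "unit_id": ["u"] * len(h1_values),
                "cell": [f"c{i}" for i in range(len(h1_values))],
                "h1": h1_values,
                "h2": h2_values,
                "unphased": 0,
            }
        )
        cn = pd.DataFrame({"unit_id": ["u"], "cn_h1": [1], "cn_h2": [1]})
        units = pd.DataFrame({"unit_id": ["u"], "chrom": ["chr1"], "start": [0], "end": [100]})
        return HaplotypeCounts(counts, cn, units)

    def test_identical_samples_give_p_one(self):
        res = haplotype_wilcoxon(self._hc([3, 5, 7, 9, 11], [3, 5, 7, 9, 11]))
        assert res["p"].iloc[0] == pytest.approx(1.0)
        assert res["effect"].iloc[0] == pytest.approx(0.0)

    def test_exact_enumeration_oracle_4v4(self):
        x = [12, 34, 22, 51]
        y = [9, 40, 65, 29]
        res = haplotype_wilcoxon(self._hc(x, y), min_cells=4)
        allv = np.array(x + y, dtype=float)
        ranks = stats.rankdata(allv)
        ws = np.array([ranks[list(idx)].sum() for idx in combinations(range(8), 4)])
        w_obs = ranks[:4].sum()
        p_enum = min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))
        assert res["p"].iloc[0] == pytest.approx(p_enum, abs=1e-12)

    def test_label_swap_inverts_effect_and_preserves_p(self):
        rng = np.random.default_rng(0)
        h1 = rng.poisson(20, 10)
        h2 = rng.poisson(40, 10)
        r1 = haplotype_wilcoxon(self._hc(h1, h2))
        r2 = haplotype_wilcoxon(self._hc(h2, h1))
        assert r1["p"].iloc[0] == pytest.approx(r2["p"].iloc[0], abs=0)
        assert r1["effect"].iloc[0] == pytest.approx(-r2["effect"].iloc[0])

    def test_too_few_cells_is_na(self):
        res = haplotype_wilcoxon(self._hc([5, 6], [1, 2]), min_cells=5)
        assert np.isnan(res["p"].iloc[0])

    def test_cn_normalization_removes_dosage_effect(self):
        # H1 on one copy, H2 duplicated: raw 1:2, CN-normalized balanced
        rng = np.random.default_rng(1)
        h1 = rng.poisson(20, 12)
        h2 = rng.poisson(40, 12)
        hc = self._hc(h1, h2)
        hc.cn.loc[0, "cn_h2"] = 2
        res = haplotype_wilcoxon(hc)
        assert res["p"].iloc[0] > 0.05

    def test_powered_recovery_and_null_calibration(self, sim_haplo_effect):
        _, genome, frags, truth, eff_genes = sim_haplo_effect
        states = classify_strand_states(frags)
        units = genome.genes.rename(columns={"gene_id": "unit_id"})[["unit_id", "chrom", "start", "end"]]
        hc = haplotype_unit_counts(frags, units, states)
        res = haplotype_wilcoxon(hc)
        affected = res["unit_id"].isin(eff_genes)
        assert (res.loc[affected, "q"] < 0.1).mean() >= 0.8
        # effect sign: H1 has 2x occupancy -> positive log2 effect
        assert (res.loc[affected, "effect"] > 0).mean() >= 0.9
        null_rate = (res.loc[~affected, "p"] < 0.05).mean()
        n_null = (~affected).sum()
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_null)
        assert null_rate <= 0.05 + ci


class TestLocalScan:
    units = pd.DataFrame(
        {
            "unit_id": ["near", "far", "other_chrom"],
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [900_000, 2_100_000, 900_000],
            "end": [950_000, 2_150_000, 950_000],
        }
    )
    results = pd.DataFrame({"unit_id": ["near", "far", "other_chrom"], "n_cells": 10, "effect": [1.0, 0.5, 0.2], "stat": 1.0, "p": [0.001, 0.2, 0.5], "q": [0.003, 0.3, 0.5]})

    def test_radius_inclusion(self):
        sv = SVCall("sv", "DEL", "chr1", 0, 1, haplotype="H1")
        out = local_scan([sv], self.results, self.units, radius=1_000_000)
        assert set(out["unit_id"]) == {"near"}  # 0.9 Mb in, 1.1 Mb (next chrom 2.1Mb) out

    def test_no_svs_empty_report(self):
        out = local_scan([], self.results, self.units)
        assert out.empty

    def test_selection_equals_brute_force_filter(self):
        sv = SVCall("sv", "DUP", "chr1", 500_000, 1_500_000, haplotype="H2")
        radius = 700_000
        out = local_scan([sv], self.results, self.units, radius=radius)
        expected = set()
        for bp in (500_000, 1_500_000):
            for _, u in self.units.iterrows():
                if u["chrom"] == "chr1" and u["start"] < bp + radius and u["end"] > bp - radius:
                    expected.add(u["unit_id"])
        assert set(out["unit_id"]) == expected

    def test_fdr_readjusted_within_scan_set(self):
        sv = SVCall("sv", "DEL", "chr1", 0, 2_200_000, haplotype="H1")
        out = local_scan([sv], self.results, self.units, radius=1_000_000)
        sub = self.results[self.results["unit_id"].isin(out["unit_id"])]
        from scnova.stats import bh_adjust

        expected_q = bh_adjust(sub["p"])
        np.testing.assert_allclose(np.sort(out["q_local"]), np.sort(expected_q))


class TestSlidingWindow:
    def _frags(self, n_h1, n_h2, lo=0, hi=50_000):
        rng = np.random.default_rng(3)
        rows = []
        for i, s in enumerate(rng.integers(lo, hi - 160, n_h1)):
            rows.append(("chr1", int(s), int(s) + 150, "c1", "W", "H1", 30, 0, 0))
        for i, s in enumerate(rng.integers(lo, hi - 160, n_h2)):
            rows.append(("chr1", int(s), int(s) + 150, "c1", "C", "H2", 30, 0, 0))
        return make_fragments(rows)

    def test_balanced_window_fc_one_p_one(self):
        fs = self._frags(40, 40)
        prof = sliding_window_scan(fs, "chr1", 25_000, (0, 50_000), window=50_000, step=50_000, n_perm=49, seed=0)
        row = prof.windows.iloc[0]
        assert row["h1"] == row["h2"] == 40
        assert row["fc"] == pytest.approx(1.0)
        assert row["p_analytic"] == pytest.approx(1.0)

    def test_lrt_and_fc_closed_form(self):
        fs = self._frags(40, 10)
        prof = sliding_window_scan(fs, "chr1", 25_000, (0, 50_000), window=50_000, step=50_000, n_perm=49, seed=0)
        row = prof.windows.iloc[0]
        expected = 2 * (40 * np.log(40 / 25) + 10 * np.log(10 / 25))
        assert row["lrt"] == pytest.approx(expected)
        assert row["fc"] == pytest.approx(4.0)
        assert row["p_analytic"] == pytest.approx(stats.chi2.sf(expected, 1))

    def test_permutation_p_floor(self):
        fs = self._frags(60, 5)
        prof = sliding_window_scan(fs, "chr1", 25_000, (0, 50_000), window=25_000, step=5_000, n_perm=99, seed=1)
        p = prof.windows["p_perm"].dropna()
        assert (p >= 1 / 100).all()

    def test_empty_window_is_na(self):
        fs = self._frags(10, 10, lo=0, hi=20_000)
        prof = sliding_window_scan(fs, "chr1", 0, (0, 100_000), window=20_000, step=20_000, n_perm=19, seed=0)
        tail = prof.windows.iloc[-1]
        assert tail["h1"] + tail["h2"] == 0 and np.isnan(tail["p_analytic"])

    def test_window_must_cover_step(self):
        fs = self._frags(5, 5)
        with pytest.raises(ValueError):
            sliding_window_scan(fs, "chr1", 0, (0, 50_000), window=1_000, step=2_000)


class TestCREExact:
    def _frags_at(self, n_h1, n_h2, start=1_000):
        rows = [("chr1", start, start + 150, "c1", "W", "H1", 30, 0, 0)] * n_h1
        rows += [("chr1", start, start + 150, "c1", "C", "H2", 30, 0, 0)] * n_h2
        return make_fragments(rows)

    cres = pd.DataFrame({"chrom": ["chr1"], "start": [900], "end": [1_400], "cre_id": ["cre1"]})

    def test_balanced_counts_p_one(self):
        res = cre_exact_test(self._frags_at(15, 15), self.cres)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_extreme_imbalance_closed_form(self):
        res = cre_exact_test(self._frags_at(0, 20), self.cres)
        assert res["p"].iloc[0] == pytest.approx(2 * 0.5**20, rel=1e-9)

    def test_cn_adjusted_null_matches_brute_force_binomial(self):
        n1, n2 = 5, 15
        res = cre_exact_test(self._frags_at(n1, n2), self.cres, cn_h1=1, cn_h2=2)
        n, p0 = n1 + n2, 1 / 3
        pmf = np.array([stats.binom.pmf(k, n, p0) for k in range(n + 1)])
        p_obs = pmf[n1]
        expected = pmf[pmf <= p_obs * (1 + 1e-12)].sum()
        assert res["p"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_zero_counts_is_na(self):
        fs = self._frags_at(3, 3, start=50_000)
        res = cre_exact_test(fs, self.cres)
        assert np.isnan(res["p"].iloc[0])


class TestTADOutlier:
    def _profile(self, logfcs, window=10_000):
        n = len(logfcs)
        wdf = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n) * window,
                "end": (np.arange(n) + 1) * window,
                "h1": 10,
                "h2": 10,
                "fc": 2.0 ** np.asarray(logfcs),
                "p_analytic": 0.5,
                "p_perm": 0.5,
            }
        )
        from scnova.haplo import WindowProfile

        return WindowProfile(wdf, "chr1", 0, 0.5, 10)

    def test_identical_distributions(self):
        prof = self._profile([1, 2, 3, 1, 2, 3])
        tads = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 30_000], "end": [30_000, 60_000], "tad_id": ["t1", "t2"]})
        res = tad_outlier_test(prof, tads)
        assert res["stat"].iloc[0] == pytest.approx(0.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_disjoint_supports_give_d_one(self):
        prof = self._profile([0.1, 0.2, 0.3, 5.0, 6.0, 7.0])
        tads = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 30_000], "end": [30_000, 60_000], "tad_id": ["t1", "t2"]})
        res = tad_outlier_test(prof, tads)
        assert res["stat"].iloc[0] == pytest.approx(1.0)

    def test_d_statistic_matches_ecdf_brute_force(self):
        vals = [0.5, 1.5, 0.7, 2.2, 0.1, 1.1, 0.9, 1.8, 0.3]
        prof = self._profile(vals)
        tads = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 40_000], "end": [40_000, 90_000], "tad_id": ["t1", "t2"]})
        res = tad_outlier_test(prof, tads)
        inside = np.array(vals[:4])
        outside = np.array(vals[4:])
        grid = np.concatenate([inside, outside])
        d_brute = max(abs((inside <= g).mean() - (outside <= g).mean()) for g in grid)
        assert res.loc[res["unit_id"] == "t1", "stat"].iloc[0] == pytest.approx(d_brute)

    def test_small_tad_is_na(self):
        prof = self._profile([1, 2, 3, 4, 5])
        tads = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 20_000], "end": [20_000, 60_000], "tad_id": ["t1", "t2"]})
        res = tad_outlier_test(prof, tads)
        assert np.isnan(res.loc[res["unit_id"] == "t1", "p"].iloc[0])
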