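import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from snepscan import synthetic as syn
from snepscan import genediv as gd
from snepscan.align import AlignmentBlock, build_curs
from snepscan.synthetic.reads import ReadSet, SampleId


class TestBodyBinWidths:
    def test_exact_multiples(self):
        w = gd.body_bin_widths(1_000)
        assert (w == 10).all()

    def test_uneven_split_left_heavy(self):
        # 550 bp -> first 50 bins of 6 bp, then 50 bins of 5 bp
        w = gd.body_bin_widths(550)
        assert set(w) == {5, 6}
        assert (w[:50] == 6).all() and (w[50:] == 5).all()

    @settings(max_examples=60, deadline=None)
    @given(st.integers(101, 20_000))
    def test_partition_sums_to_length(self, length):
        w = gd.body_bin_widths(length)
        assert w.sum() == length
        assert len(w) == 100
        assert w.max() - w.min() <= 1


class TestGeneBinIntervals:
    def test_plus_strand_layout(self):
        iv = gd._gene_bin_intervals(10_000, 11_000, "+")
        assert iv.shape == (600, 2)
        assert iv[249].tolist() == [9_990, 10_000]  # bin 250 abuts the TSS
        assert iv[250].tolist() == [10_000, 10_010]  # bin 251 starts the body
        assert iv[349][1] == 11_000
        assert iv[0][0] == 10_000 - 2_500
        assert iv[-1][1] == 11_000 + 2_500

    def test_minus_strand_is_mirror(self):
        plus = gd._gene_bin_intervals(10_000, 11_000, "+")
        minus = gd._gene_bin_intervals(10_000, 11_000, "-")
        # bin k of the minus gene covers the reflected interval
        for k in (0, 250, 349, 599):
            lo, hi = minus[k]
            plo, phi = plus[k]
            assert lo == 10_000 + 11_000 - phi
            assert hi == 10_000 + 11_000 - plo


def uniform_readset(length=40_000, n=200_000, seed=0):
    rng = np.random.default_rng(seed)
    samples = {}
    for strain in ("S1", "S2"):
        for assay, mark in (("MNase", None), ("ChIP", "m1")):
            for rep in (1, 2):
                samples[SampleId(strain, assay, mark, rep)] = np.sort(
                    rng.integers(0, length, size=n)
                )
    return ReadSet("chrI", samples, {"S1": length, "S2": length}, {}, seed)


def identity_curs(length=40_000):
    return build_curs([AlignmentBlock("chrI", 0, length, "chrI", 0, length)])


class TestBinGenes:
    def test_uniform_coverage_flat_profile(self):
        rs = uniform_readset()
        genes = syn.make_genes(1, 40_000, 6)
        prof = gd.bin_genes(rs, genes, identity_curs())
        p = prof.data[("S1", "MNase")]
        assert p.shape == (len(prof.genes), 600)
        body = p[:, 250:350]
        assert np.nanstd(body) / np.nanmean(body) < 0.25
        assert np.nanmean(body) == pytest.approx(np.nanmean(p[:, :250]), rel=0.1)

    def test_minus_strand_profile_is_reversed_plus(self):
        length = 40_000
        rng = np.random.default_rng(3)
        starts = np.sort(rng.integers(0, length, size=100_000))
        samples = {
            SampleId("S1", "MNase", None, r): starts for r in (1, 2)
        }
        rs = ReadSet("chrI", samples, {"S1": length, "S2": length}, {}, 0)
        gplus = pd.DataFrame(
            [("g", "chrI", 10_000, 11_000, "+", 10_000, 11_000)],
            columns=["gene_id", "contig", "start", "end", "strand", "tss", "tes"],
        ).set_index("gene_id")
        gminus = gplus.copy()
        gminus["strand"] = "-"
        a = gd.bin_genes(rs, gplus, identity_curs()).data[("S1", "MNase")][0]
        b = gd.bin_genes(rs, gminus, identity_curs()).data[("S1", "MNase")][0]
        np.testing.assert_allclose(a, b[::-1], rtol=1e-9)

    def test_short_and_outside_genes_excluded(self):
        rs = uniform_readset()
        genes = pd.DataFrame(
            [
                ("short", "chrI", 5_000, 5_050, "+", 5_000, 5_050),
                ("outside", "chrI", 50_000, 52_000, "+", 50_000, 52_000),
                ("ok", "chrI", 10_000, 12_000, "+", 10_000, 12_000),
            ],
            columns=["gene_id", "contig", "start", "end", "strand", "tss", "tes"],
        ).set_index("gene_id")
        prof = gd.bin_genes(rs, genes, identity_curs())
        assert list(prof.genes.index) == ["ok"]
        assert set(prof.excluded.index) == {"short", "outside"}
        assert prof.excluded.loc["short", "reason"] == "too_short"


class TestDifferentialPatterns:
    def test_identical_strains_zero_vectors(self):
        rs = uniform_readset()
        genes = syn.make_genes(1, 40_000, 6)
        prof = gd.bin_genes(rs, genes, identity_curs())
        prof.data[("S2", "MNase")] = prof.data[("S1", "MNase")]
        prof.data[("S2", "m1")] = prof.data[("S1", "m1")]
        pat = gd.differential_patterns(prof, ("S1", "S2"), marks=["m1"])
        assert pat.vectors.shape[1] == 200
        np.testing.assert_allclose(pat.vectors, 0.0, atol=1e-12)
        assert pat.tree[:, 2].max() == pytest.approx(0.0, abs=1e-9)

    def test_two_planted_groups_recovered_by_cut(self):
        rng = np.random.default_rng(0)
        n_genes = 30
        base = rng.normal(0, 0.05, size=(n_genes, 600))
        up = np.zeros((n_genes, 600))
        up[:15, 250:350] = 2.0  # opposite body differences
        up[15:, 250:350] = -2.0

        class FakeProfiles:
            genes = pd.DataFrame(index=[f"g{i}" for i in range(n_genes)])
            marks = ["m1"]
            data = {
                ("S1", "m1"): np.exp(base + up),
                ("S2", "m1"): np.exp(base),
                ("S1", "MNase"): np.ones((n_genes, 600)),
                ("S2", "MNase"): np.ones((n_genes, 600)),
            }
            log_ratio = gd.GeneProfiles.log_ratio

        pat = gd.differential_patterns(FakeProfiles(), ("S1", "S2"))
        clusters = pat.cut(2)
        assert clusters.iloc[:15].nunique() == 1
        assert clusters.iloc[15:].nunique() == 1
        assert clusters.iloc[0] != clusters.iloc[-1]


class TestEpidiv:
    def test_identical_strains_zero(self):
        y1 = np.random.default_rng(0).normal(size=(5, 100))
        y = np.stack([y1, y1])
        assert gd.epidiv(y).epidiv == pytest.approx(0.0, abs=1e-20)

    def test_null_follows_f_distribution(self):
        # oracle: under iid noise, epidiv ~ F(df1, df2); mean ~ df2/(df2-2)
        rng = np.random.default_rng(4)
        S, M, B = 2, 5, 100
        vals = [gd.epidiv(rng.normal(size=(S, M, B))).epidiv for _ in range(500)]
        df2 = (M - 1) * (B - 1)
        assert np.mean(vals) == pytest.approx(df2 / (df2 - 2), rel=0.05)
        ks = stats.kstest(vals, "f", args=((S - 1) * (M - 1), df2))
        assert ks.pvalue > 0.01

    def test_planted_offset_exceeds_null(self):
        rng = np.random.default_rng(2)
        null99 = np.quantile(
            [gd.epidiv(rng.normal(size=(2, 5, 100))).epidiv for _ in range(200)], 0.99
        )
        y = rng.normal(size=(2, 5, 100))
        y[1, 2, :] += 1.0  # one strain, one mark, uniform offset
        assert gd.epidiv(y).epidiv > 2 * null99

    def test_anova_accounting(self):
        y = np.random.default_rng(3).normal(size=(3, 4, 50))
        res = gd.epidiv(y)
        t = res.table
        assert t["ss"].sum() == pytest.approx(((y - y.mean()) ** 2).sum(), rel=1e-8)
        assert t["df"].sum() == y.size - 1

    def test_residual_df_formula(self):
        y = np.random.default_rng(4).normal(size=(2, 5, 600))
        t = gd.epidiv(y).table
        assert t.loc["residual", "df"] == 4 * 599

    def test_bin_reorder_invariance(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(2, 5, 80))
        perm = rng.permutation(80)
        assert gd.epidiv(y).epidiv == pytest.approx(gd.epidiv(y[:, :, perm]).epidiv)

    def test_missing_cells_rejected(self):
        y = np.random.default_rng(6).normal(size=(2, 5, 10))
        y[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            gd.epidiv(y)


class TestDeltaSelect:
    def test_constant_profile_zero_delta(self):
        d = np.full((1, 600), 3.0)
        delta, sel = gd.delta_select(d)
        assert delta[0] == 0.0 and not sel[0]

    def test_planted_r2_elevation(self):
        d = np.zeros((1, 600))
        d[0, 283:333] = 12.0
        delta, sel = gd.delta_select(d, cutoff=10)
        assert delta[0] == 12.0 and sel[0]

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_direct_median_oracle(self, seed):
        d = np.random.default_rng(seed).normal(size=(3, 600))
        delta, _ = gd.delta_select(d)
        for i in range(3):
            expect = np.median(d[i, 283:333]) - np.median(d[i, 250:266])
            assert delta[i] == pytest.approx(expect)


class TestSubsetShiftTest:
    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            v = rng.normal(size=400)
            mask = np.zeros(400, dtype=bool)
            mask[rng.choice(400, 50, replace=False)] = True
            ps.append(gd.subset_shift_test(v, mask)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_shifted_subset_power(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=2_000)
        mask = np.zeros(2_000, dtype=bool)
        mask[:500] = True
        v[mask] += 1.0
        _, p = gd.subset_shift_test(v, mask)
        assert p < 1e-6

    def test_degenerate_subsets_rejected(self):
        v = np.ones(10)
        with pytest.raises(ValueError, match="empty"):
            gd.subset_shift_test(v, np.zeros(10, dtype=bool))
        with pytest.raises(ValueError, match="whole"):
            gd.subset_shift_test(v, np.ones(10, dtype=bool))


class TestQtlScan:
    def test_planted_qtl_detected(self):
        c = syn.generate_cross(0, 60, 200, 120, effect=2.0, n_genes=50)
        scan = gd.qtl_scan(c.values, c.genotypes, seed=0)
        assert scan.scores.iloc[120] > scan.threshold

    def test_threshold_reproducible(self):
        c = syn.generate_cross(1, 60, 100, 50, effect=1.0, n_genes=30)
        a = gd.qtl_scan(c.values, c.genotypes, seed=5)
        b = gd.qtl_scan(c.values, c.genotypes, seed=5)
        assert a.threshold == b.threshold
        pd.testing.assert_series_equal(a.scores, b.scores)

    def test_monomorphic_marker_masked(self):
        c = syn.generate_cross(2, 30, 20, 5, effect=1.0, n_genes=10)
        c.genotypes.iloc[:, 7] = 1
        scan = gd.qtl_scan(c.values, c.genotypes, seed=1)
        assert np.isnan(scan.scores.iloc[7])

    def test_too_few_segregants_refused(self):
        geno = pd.DataFrame([[0], [1]], columns=["m0"])
        vals = {"g": np.random.default_rng(0).normal(size=(2, 4))}
        with pytest.raises(ValueError, match="fewer than 10"):
            gd.qtl_scan(vals, geno)

    def test_at_most_two_metaphenotypes(self):
        c = syn.generate_cross(3, 40, 50, 10, effect=1.5, n_genes=40)
        scan = gd.qtl_scan(c.values, c.genotypes, seed=2)
        assert scan.metaphenotypes.shape[1] <= 2


class TestCovariateAssoc:
    def test_self_correlation_is_one(self):
        v = pd.Series(np.random.default_rng(0).normal(size=100))
        res = gd.covariate_assoc(v, v)
        assert res.kind == "spearman"
        assert res.statistic == pytest.approx(1.0)

    def test_independent_covariate_small_rho(self):
        rng = np.random.default_rng(1)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            v = pd.Series(rng.normal(size=3_000))
            c = pd.Series(rng.normal(size=3_000))
            if abs(gd.covariate_assoc(v, c).statistic) >= 0.06:
                hits += 1
        assert hits <= 1

    def test_binary_covariate_wilcoxon_power(self):
        rng = np.random.default_rng(2)
        v = pd.Series(np.concatenate([rng.normal(0, 1, 500), rng.normal(0.5, 1, 500)]))
        c = pd.Series([0] * 500 + [1] * 500)
        res = gd.covariate_assoc(v, c)
        assert res.kind == "wilcoxon" and res.pvalue < 0.01

    def test_constant_covariate_rejected(self):
        v = pd.Series(np.arange(20.0))
        with pytest.raises(ValueError, match="constant"):
            gd.covariate_assoc(v, pd.Series(np.ones(20)))

    def test_too_few_genes_rejected(self):
        v = pd.Series(np.arange(5.0))
        with pytest.raises(ValueError, match=">= 10"):
            gd.covariate_assoc(v, v + 1)
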