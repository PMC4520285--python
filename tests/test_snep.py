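import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from snepscan import synthetic as syn
from snepscan import nucmap as nm
from snepscan.snep import (
    call_sneps,
    estimate_dispersions,
    extract_counts,
    size_factors,
    test_interaction,
    test_interaction_table,
    test_occupancy,
)


def count_table(data: dict) -> pd.DataFrame:
    df = pd.DataFrame(data)
    df.columns = pd.MultiIndex.from_tuples(
        df.columns, names=["strain", "assay", "replicate"]
    )
    return df


class TestExtractCounts:
    @pytest.fixture()
    def matched(self, small_readset, small_landscape):
        maps = {s: nm.build_map(small_readset, s) for s in small_landscape.strains}
        return nm.match_maps(maps["S1"], maps["S2"], small_landscape.cur_set)

    def test_zero_reads_zero_count(self, matched, small_readset):
        counts, _ = extract_counts(small_readset, matched)
        assert (counts >= 0).all().all()
        assert counts.to_numpy().dtype.kind in "iu"

    def test_order_invariance(self, matched, small_readset):
        a, _ = extract_counts(small_readset, matched)
        import copy

        rev = copy.copy(small_readset)
        rev.samples = dict(reversed(list(small_readset.samples.items())))
        b, _ = extract_counts(rev, matched)
        pd.testing.assert_frame_equal(a, b)

    def test_counts_match_generative_expectation(self, matched, small_readset,
                                                 small_landscape):
        # read starts sit at the 5' edge (dyad - 73) with Gaussian jitter,
        # so the [dyad-73, dyad+74) window captures ~the right half of the
        # start cloud; matched pairs are additionally occupancy-biased high
        counts, _ = extract_counts(small_readset, matched)
        mnase = counts.xs("MNase", axis=1, level="assay")
        pair_rows = counts.index.str.startswith("pair:")
        per_pair = mnase.loc[pair_rows].mean(axis=1)
        depth = {
            sid: len(v) for sid, v in small_readset.samples.items() if sid.assay == "MNase"
        }
        naive = np.mean(list(depth.values())) / len(small_landscape.table)
        assert 0.45 * naive < per_pair.mean() < 0.8 * naive


class TestSizeFactors:
    def test_identical_samples_equal_factors(self):
        c = count_table(
            {("S1", "MNase", 1): [10, 20, 30], ("S1", "MNase", 2): [10, 20, 30]}
        )
        sf = size_factors(c)
        assert sf.iloc[0] == pytest.approx(sf.iloc[1])

    def test_proportional_columns_closed_form(self):
        # oracle: B = 3A exactly -> factor ratio 3 by median-of-ratios algebra
        a = np.array([10, 25, 40, 55])
        c = count_table({("S1", "MNase", 1): a, ("S1", "MNase", 2): 3 * a})
        sf = size_factors(c)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(3.0)

    def test_single_sample_factor_one(self):
        c = count_table({("S1", "MNase", 1): [5, 10, 20]})
        assert size_factors(c).iloc[0] == 1.0

    def test_fallback_without_all_positive_row(self):
        c = count_table(
            {("S1", "MNase", 1): [0, 10], ("S1", "MNase", 2): [10, 0]}
        )
        with pytest.warns(UserWarning, match="falling back"):
            sf = size_factors(c)
        assert (sf > 0).all()


class TestInteraction:
    def test_pure_occupancy_difference_not_snep(self):
        # ChIP fold change mirrors MNase fold change -> interaction ~ 0
        counts, _, _ = syn.simulate_count_table(
            1, 2_000, depth=300, dispersion=0.02, n_replicates=3,
            occupancy_lfc={i: -1.0 for i in range(400)},
        )
        res = test_interaction_table(counts)
        assert (res["p_interaction"].iloc[:400] < 0.01).mean() < 0.02
        mn = counts.xs("MNase", axis=1, level="assay", drop_level=False)
        occ = [test_occupancy(mn.iloc[i]) for i in range(20)]
        assert np.median(occ) < 0.01  # occupancy difference is detected

    def test_planted_snep_power(self):
        # 4x ChIP difference at equal occupancy, depth 200, 4 replicates
        counts, _, _ = syn.simulate_count_table(
            2, 2_000, depth=200, dispersion=0.05, n_replicates=4,
            planted_lfc={i: 2.0 for i in range(100)},
        )
        res = test_interaction_table(counts)
        assert (res["p_interaction"].iloc[:100] < 1e-4).mean() >= 0.8
        assert (res["direction"].iloc[:100] == 1).mean() >= 0.99

    def test_null_type_one_error_rate(self):
        counts, _, _ = syn.simulate_count_table(3, 5_000, depth=200, dispersion=0.05)
        res = test_interaction_table(counts)
        rate = (res["p_interaction"] < 0.01).mean()
        assert 0.005 <= rate <= 0.02

    def test_occupancy_null_uniform(self):
        counts, _, _ = syn.simulate_count_table(4, 2_000, depth=200, dispersion=0.05)
        sf = size_factors(counts)
        disp = estimate_dispersions(counts, sf)
        mn = counts.xs("MNase", axis=1, level="assay", drop_level=False)
        ps = [
            test_occupancy(mn.iloc[i], sf=sf[mn.columns], alpha=disp[i])
            for i in range(500)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_eviction_detected_by_occupancy_test(self):
        # 50% eviction planted in a 10% subset so size factors stay honest
        counts, _, _ = syn.simulate_count_table(
            5, 2_000, depth=200, dispersion=0.02, n_replicates=3,
            occupancy_lfc={i: -1.0 for i in range(200)},
        )
        sf = size_factors(counts)
        disp = estimate_dispersions(counts, sf)
        mn = counts.xs("MNase", axis=1, level="assay", drop_level=False)
        ps = np.array(
            [test_occupancy(mn.iloc[i], sf=sf[mn.columns], alpha=disp[i]) for i in range(200)]
        )
        assert (ps < 0.01).mean() >= 0.9

    def test_all_zero_chip_is_insufficient_signal(self):
        counts, _, _ = syn.simulate_count_table(6, 10, depth=100)
        chip_cols = [c for c in counts.columns if c[1] == "ChIP"]
        counts.loc[counts.index[0], chip_cols] = 0
        res = test_interaction_table(counts)
        assert res["status"].iloc[0] == "insufficient_signal"
        assert np.isnan(res["p_interaction"].iloc[0])

    def test_single_replicate_rejected(self):
        c = count_table(
            {
                ("S1", "MNase", 1): [10],
                ("S1", "ChIP", 1): [10],
                ("S2", "MNase", 1): [10],
                ("S2", "ChIP", 1): [10],
            }
        )
        with pytest.raises(ValueError, match="replicates"):
            test_interaction_table(c)

    def test_occupancy_single_replicate_rejected(self):
        s = pd.Series(
            [10, 12],
            index=pd.MultiIndex.from_tuples(
                [("S1", "MNase", 1), ("S2", "MNase", 1)],
                names=["strain", "assay", "replicate"],
            ),
        )
        with pytest.raises(ValueError, match="insufficient replicates"):
            test_occupancy(s)

    def test_scale_invariance_global_size_factor_rescaling(self):
        # rescaling every size factor by one constant shifts all offsets by
        # log(c), which the intercept absorbs: p-values exactly unchanged
        counts, _, _ = syn.simulate_count_table(7, 50, depth=200, dispersion=0.05)
        sf = size_factors(counts)
        disp = estimate_dispersions(counts, sf)
        a = test_interaction_table(counts, sf=sf, dispersions=disp)
        b = test_interaction_table(counts, sf=sf * 7.5, dispersions=disp)
        np.testing.assert_allclose(a["p_interaction"], b["p_interaction"], atol=1e-6)

    def test_scale_invariance_approximate_under_nb(self):
        # with NB overdispersion the likelihood is not exactly scale
        # equivariant; p-values must still agree closely
        counts, _, _ = syn.simulate_count_table(7, 50, depth=200, dispersion=0.05)
        sf = size_factors(counts)
        disp = estimate_dispersions(counts, sf)
        a = test_interaction_table(counts, sf=sf, dispersions=disp)
        scaled = counts.copy()
        col = scaled.columns[0]
        scaled[col] = scaled[col] * 3
        sf2 = sf.copy()
        sf2[col] = sf2[col] * 3
        b = test_interaction_table(scaled, sf=sf2, dispersions=disp)
        np.testing.assert_allclose(a["p_interaction"], b["p_interaction"], atol=0.05)

    def test_strain_label_symmetry(self):
        counts, _, _ = syn.simulate_count_table(
            8, 100, depth=200, planted_lfc={i: 1.5 for i in range(30)}
        )
        sf = size_factors(counts)
        disp = estimate_dispersions(counts, sf)
        a = test_interaction_table(counts, strains=("S1", "S2"), sf=sf, dispersions=disp)
        b = test_interaction_table(counts, strains=("S2", "S1"), sf=sf, dispersions=disp)
        np.testing.assert_allclose(
            a["p_interaction"], b["p_interaction"], rtol=1e-5, atol=1e-8
        )
        mask = a["direction"] != 0
        assert (a["direction"][mask] == -b["direction"][mask]).all()

    def test_wald_option_agrees_roughly(self):
        counts, _, _ = syn.simulate_count_table(
            9, 1_000, depth=200, dispersion=0.02, n_replicates=4,
            planted_lfc={i: 2.5 for i in range(20)},
        )
        lrt = test_interaction_table(counts)
        wald = test_interaction_table(counts, wald=True)
        both = (lrt["p_interaction"] < 1e-4) & (wald["p_interaction"] < 1e-4)
        assert both.iloc[:20].mean() > 0.8


class TestCallSneps:
    def test_all_ones_no_calls(self):
        assert not call_sneps(np.ones(10)).any()

    def test_hand_enumerated_three_vector(self):
        # BH step-up by hand: thresholds 1/3, 2/3, 3/3 of 1e-4;
        # only 1e-8 <= 0.333e-4 passes
        calls = call_sneps(np.array([1e-8, 0.5, 0.9]), fdr=0.0001)
        assert calls.tolist() == [True, False, False]

    def test_empty_input(self):
        assert call_sneps(np.array([])).size == 0

    def test_nan_never_called(self):
        calls = call_sneps(np.array([np.nan, 1e-9]), fdr=0.01)
        assert calls.tolist() == [False, True]

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60),
        st.sampled_from([0.0001, 0.01, 0.05, 0.2]),
    )
    def test_agrees_with_reference_implementation(self, pvals, fdr):
        p = np.array(pvals)
        mine = call_sneps(p, fdr=fdr)
        ref = multipletests(p, alpha=fdr, method="fdr_bh")[0]
        assert mine.tolist() == ref.tolist()


class TestDispersions:
    def test_floor_applied(self):
        c = count_table(
            {
                ("S1", "MNase", 1): [100, 200],
                ("S1", "MNase", 2): [100, 200],
                ("S2", "MNase", 1): [100, 200],
                ("S2", "MNase", 2): [100, 200],
            }
        )
        d = estimate_dispersions(c, size_factors(c))
        assert (d >= 1e-8).all()

    def test_recovers_magnitude(self):
        counts, _, _ = syn.simulate_count_table(11, 5_000, depth=500, dispersion=0.1,
                                                n_replicates=3)
        d = estimate_dispersions(counts, size_factors(counts))
        assert 0.05 < np.median(d) < 0.2
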