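"""Window statistics: tiling, counting, baseline, exact test, combination,
FDR, region merging and the end-to-end pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from allelic import (
    AlleleCall,
    ChromSpec,
    EnhancerSpec,
    PipelineConfig,
    ReadSim,
    bh_fdr,
    binom_twosided,
    call_regions,
    chromosome_baseline,
    count_window,
    count_windows,
    exact_allelic_test,
    fisher_combine,
    make_windows,
    run_pipeline,
    simulate_chip_reads,
)
from allelic.assign import assign_reads

from oracles import bh_stepup, binom_twosided_enum, chi2_sf_even_df


class TestMakeWindows:
    def test_stated_tiling_convention(self):
        w = make_windows(1000, sizes=(250,), step_fraction=0.5)
        assert w["start"].tolist() == [0, 125, 250, 375, 500, 625, 750]
        assert (w["end"] - w["start"] == 250).all()

    def test_short_chromosome_gives_empty_with_warning(self):
        with pytest.warns(UserWarning, match="below smallest window"):
            w = make_windows(100, sizes=(250,))
        assert w.empty

    @pytest.mark.parametrize("length", [10_000, 9_999, 12_345])
    def test_window_count_follows_closed_form(self, length):
        sizes = (250, 500, 1000)
        w = make_windows(length, sizes=sizes, step_fraction=0.5)
        for s in sizes:
            expected = (length - s) // (s // 2) + 1
            assert (w["size"] == s).sum() == expected
        assert (w["end"] <= length).all()
        assert (w["start"] >= 0).all() and (w["start"] < w["end"]).all()


class TestCountWindow:
    def _calls(self):
        mk = lambda i, start, call: AlleleCall(f"r{i}", "c", start, start + 50, 0, call, 1)
        return [
            mk(0, 10, "A1"), mk(1, 20, "A1"), mk(2, 30, "A1"), mk(3, 40, "A2"),
            mk(4, 99, "A1"),   # start 1 bp before window [100, 200)
            mk(5, 150, "CONFLICT"), mk(6, 160, "NONINFORMATIVE"),
        ]

    def test_start_point_rule_and_category_filter(self):
        calls = self._calls()
        assert count_window(calls, (0, 50)) == (3, 1)
        # read starting 1 bp before the window is not counted even though it
        # overlaps it; conflict/noninformative never counted
        assert count_window(calls, (100, 200)) == (0, 0)
        assert count_window(calls, (500, 600)) == (0, 0)

    def test_vectorised_counts_match_scalar_rule(self, trisomic_sim):
        _, _, reads, snps, _ = trisomic_sim
        calls = assign_reads(reads, snps)
        windows = {"chr15": make_windows(500_000, sizes=(500,), step_fraction=0.5)}
        counts = count_windows(calls, windows)
        block = calls.blocks[(0, "chr15")]
        from allelic.assign import CALL_A1, CALL_A2

        sub = counts[(counts.clone == 0)].set_index("start")
        for ws in (0, 250, 124_750, 499_500):
            in_win = (block.starts >= ws) & (block.starts < ws + 500)
            assert sub.loc[ws, "c1"] == int(np.sum(in_win & (block.call == CALL_A1)))
            assert sub.loc[ws, "c2"] == int(np.sum(in_win & (block.call == CALL_A2)))


class TestBaseline:
    def _counts(self, fractions, total=100, chrom="c", clone=0):
        rows = []
        for i, f in enumerate(fractions):
            c1 = int(round(f * total))
            rows.append(
                {"chrom": chrom, "start": i * 500, "end": i * 500 + 500,
                 "size": 500, "clone": clone, "c1": c1, "c2": total - c1}
            )
        return pd.DataFrame(rows)

    def test_median_of_window_fractions(self):
        base = chromosome_baseline(self._counts([0.30, 0.33, 0.36]), min_total=10)
        assert base.iloc[0]["rho"] == pytest.approx(0.33)

    def test_windows_below_min_total_are_skipped(self):
        counts = self._counts([0.5, 0.5], total=5)
        base = chromosome_baseline(counts, min_total=10)
        assert base.empty

    def test_extreme_window_moves_median_one_order_statistic(self):
        fractions = [0.30, 0.32, 0.34, 0.36, 0.38]
        rho0 = chromosome_baseline(self._counts(fractions)).iloc[0]["rho"]
        rho1 = chromosome_baseline(self._counts(fractions + [0.99])).iloc[0]["rho"]
        # median moves from the middle value to the average of neighbours
        assert rho0 == pytest.approx(0.34)
        assert rho1 == pytest.approx(0.35)

    def test_pooled_baseline_merges_clones(self):
        counts = pd.concat(
            [self._counts([0.2, 0.2, 0.2], clone=0), self._counts([0.4, 0.4, 0.4], clone=1)],
            ignore_index=True,
        )
        per_clone = chromosome_baseline(counts, pooled_clones=False)
        pooled = chromosome_baseline(counts, pooled_clones=True)
        assert sorted(per_clone["rho"]) == [pytest.approx(0.2), pytest.approx(0.4)]
        assert pooled["rho"].tolist() == pytest.approx([0.3, 0.3])


class TestExactTest:
    def test_modal_outcome_gives_p_one(self):
        assert exact_allelic_test(5, 5, 0.5) == 1.0

    def test_frozen_enumeration_values(self):
        # values computed with the exact integer enumeration oracle
        assert exact_allelic_test(20, 10, 0.5) == pytest.approx(
            0.09873714670538902, rel=1e-12
        )
        assert exact_allelic_test(0, 30, 1 / 3) == pytest.approx(
            6.689743084062613e-06, rel=1e-12
        )

    @pytest.mark.parametrize("a,b", [(1, 9), (1, 2), (1, 1)])
    @pytest.mark.parametrize("n", [1, 2, 7, 35, 120])
    def test_matches_enumeration_oracle(self, a, b, n):
        rho = a / (a + b)
        mine = binom_twosided(np.arange(n + 1), n, rho)
        for k in range(n + 1):
            assert mine[k] == pytest.approx(binom_twosided_enum(k, n, a, b), rel=1e-11)

    def test_matches_scipy_binomtest(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(1, 400))
            k = int(rng.integers(0, n + 1))
            rho = float(rng.uniform(0.05, 0.95))
            expected = sps.binomtest(k, n, rho, alternative="two-sided").pvalue
            assert binom_twosided(k, n, rho)[0] == pytest.approx(expected, rel=1e-7)

    @given(
        n=st.integers(1, 300),
        frac=st.floats(0.0, 1.0),
        rho=st.floats(0.01, 0.99),
    )
    def test_p_in_unit_interval_and_mirror_symmetry(self, n, frac, rho):
        k = int(round(frac * n))
        p = binom_twosided(k, n, rho)[0]
        assert 0.0 < p <= 1.0
        mirrored = binom_twosided(n - k, n, 1.0 - rho)[0]
        assert p == pytest.approx(mirrored, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            exact_allelic_test(0, 0, 0.5)
        with pytest.raises(ValueError):
            exact_allelic_test(3, 2, 0.0)


class TestFisherCombine:
    def test_single_p_identity(self):
        _, df, p = fisher_combine([0.05])
        assert df == 2 and p == pytest.approx(0.05, rel=1e-12)

    def test_all_ones_give_chi2_zero(self):
        chi2, df, p = fisher_combine([1.0, 1.0, 1.0])
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == 1.0

    def test_three_clone_example(self):
        chi2, df, p = fisher_combine([0.05, 0.05, 0.05])
        assert chi2 == pytest.approx(17.974, abs=1e-3)
        assert df == 6
        assert p == pytest.approx(0.0063, abs=1e-4)

    def test_matches_even_df_closed_form(self):
        rng = np.random.default_rng(3)
        for k in (1, 2, 3, 5):
            pvals = rng.uniform(1e-6, 1.0, size=(20, k))
            chi2, df, pc = fisher_combine(pvals)
            for x, p in zip(chi2, pc):
                assert p == pytest.approx(chi2_sf_even_df(x, df), rel=1e-10)

    def test_zero_p_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            _, _, p = fisher_combine([0.0, 0.5])
        assert p > 0

    def test_clone_permutation_invariance(self):
        a = fisher_combine([0.01, 0.2, 0.7])[2]
        b = fisher_combine([0.7, 0.01, 0.2])[2]
        assert a == b


class TestBhFdr:
    def test_hand_enumerated_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        p = [0.005, 0.011, 0.02, 0.04, 0.9]
        assert bh_fdr(p) == pytest.approx(bh_stepup(p))

    def test_identical_and_single_p_fixed_points(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
        assert bh_fdr([0.07]) == pytest.approx([0.07])

    def test_empty_input_gives_empty_output(self):
        assert bh_fdr([]).size == 0

    @given(st.lists(st.floats(1e-10, 1.0), min_size=1, max_size=40))
    def test_matches_hand_step_up_and_stays_in_unit_interval(self, p):
        q = bh_fdr(p)
        assert np.all((q > 0) & (q <= 1))
        assert q == pytest.approx(bh_stepup(p), rel=1e-12)


class TestCallRegions:
    def _tests_df(self, rows):
        cols = ["chrom", "start", "end", "q", "fold", "pooled_fraction", "rho_bar", "n_total"]
        return pd.DataFrame(rows, columns=cols)

    def test_no_significant_windows_gives_empty(self):
        df = self._tests_df([("c", 0, 500, 0.9, 1.0, 0.33, 0.33, 100)])
        assert call_regions(df, 0.05, "A1_up").empty

    def test_overlapping_windows_merge_to_one_region(self):
        df = self._tests_df(
            [
                ("c", 0, 500, 1e-4, 2.0, 0.66, 0.33, 100),
                ("c", 250, 750, 1e-5, 2.1, 0.7, 0.33, 300),
                ("c", 750, 1250, 1e-3, 1.9, 0.6, 0.33, 100),  # book-ended
                ("c", 5000, 5500, 1e-3, 2.0, 0.66, 0.33, 100),  # separate
            ]
        )
        regions = call_regions(df, 0.05, "A1_up")
        assert len(regions) == 2
        first = regions.iloc[0]
        assert (first["start"], first["end"]) == (0, 1250)
        assert first["min_q"] == pytest.approx(1e-5)
        expected_fold = np.average([2.0, 2.1, 1.9], weights=[100, 300, 100])
        assert first["mean_fold"] == pytest.approx(expected_fold)

    def test_direction_filter(self):
        df = self._tests_df(
            [
                ("c", 0, 500, 1e-4, 0.5, 0.17, 0.33, 100),  # A2-shifted
                ("c", 1000, 1500, 1e-4, 2.0, 0.66, 0.33, 100),
            ]
        )
        up = call_regions(df, 0.05, "A1_up")
        down = call_regions(df, 0.05, "A2_up")
        assert len(up) == 1 and up.iloc[0]["start"] == 1000
        assert len(down) == 1 and down.iloc[0]["start"] == 0


class TestPipeline:
    @pytest.fixture(scope="class")
    def enhancer_run(self):
        chrom = ChromSpec("chr15", 1_000_000, 1, 2, snp_density=2.0)
        enh = EnhancerSpec("chr15", 400_000, 410_000, a1_fraction=2 / 3, coverage_mult=5.0)
        sim = ReadSim(read_length=100, background_rate=1.0, error_rate=0.001,
                      n_clones=3, seed=17)
        reads, snps, truth = simulate_chip_reads([chrom], [enh], sim)
        result = run_pipeline(reads, snps, PipelineConfig(q_threshold=0.01))
        return reads, snps, truth, result

    def test_truth_region_recovered_with_twofold_signal(self, enhancer_run):
        _, _, truth, result = enhancer_run
        t = truth.iloc[0]
        overlapping = result.regions[
            (result.regions.start < t.end) & (result.regions.end > t.start)
        ]
        assert len(overlapping) == 1
        region = overlapping.iloc[0]
        inter = min(region.end, t.end) - max(region.start, t.start)
        union = max(region.end, t.end) - min(region.start, t.start)
        assert inter / union >= 0.5
        assert region.mean_fold == pytest.approx(2.0, abs=0.25)
        assert region.min_q < 0.01

    def test_rerun_is_deterministic(self, enhancer_run):
        reads, snps, _, result = enhancer_run
        again = run_pipeline(reads, snps, PipelineConfig(q_threshold=0.01))
        pd.testing.assert_frame_equal(result.windows, again.windows)
        pd.testing.assert_frame_equal(result.regions, again.regions)

    def test_clone_label_permutation_leaves_combined_stats_unchanged(self, enhancer_run):
        reads, snps, _, result = enhancer_run
        from allelic import ReadSet

        permuted = ReadSet(
            blocks={(2 - c, ch): b for (c, ch), b in reads.blocks.items()},
            read_length=reads.read_length,
            n_clones=reads.n_clones,
        )
        other = run_pipeline(permuted, snps, PipelineConfig(q_threshold=0.01))
        np.testing.assert_allclose(
            result.windows["p_combined"], other.windows["p_combined"], rtol=1e-12
        )
        pd.testing.assert_frame_equal(result.regions, other.regions)

    def test_emitted_intervals_are_valid_bed(self, enhancer_run, tmp_path):
        from allelic import write_regions_bed

        _, _, _, result = enhancer_run
        w = result.windows
        assert (w["start"] < w["end"]).all() and (w["start"] >= 0).all()
        assert (w["end"] <= 1_000_000).all()
        path = tmp_path / "regions.bed"
        write_regions_bed(result.regions, str(path))
        fields = [line.split("\t") for line in path.read_text().splitlines()]
        assert all(len(f) == 6 for f in fields)
        assert all(int(f[1]) < int(f[2]) for f in fields)

    def test_attrition_is_logged_in_report(self, enhancer_run):
        _, _, _, result = enhancer_run
        stages = result.report["stages"]
        testing = stages["testing"]
        assert testing["windows_tested"] + testing["windows_dropped_min_total"] + \
            testing["windows_dropped_no_baseline"] == testing["windows_total"]

    def test_clone_count_mismatch_rejected(self, enhancer_run):
        reads, snps, _, _ = enhancer_run
        with pytest.raises(ValueError, match="clone count mismatch"):
            run_pipeline(reads, snps, PipelineConfig(n_clones=5))

    def test_null_run_calls_no_confident_regions(self):
        chrom = ChromSpec("chrN", 400_000, 1, 2, snp_density=2.0)
        sim = ReadSim(background_rate=1.0, error_rate=0.001, n_clones=3, seed=23)
        reads, snps, _ = simulate_chip_reads([chrom], [], sim)
        result = run_pipeline(reads, snps, PipelineConfig(q_threshold=0.01))
        assert result.regions.empty
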