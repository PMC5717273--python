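import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

import methkit as mk
from methkit.dmr import DmrParams

from conftest import make_sample, uniform_sample


def exact_fisher(a, b, c, d):
    """Integer-arithmetic two-sided Fisher oracle (same-denominator compare)."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    obs = nums[a - lo]
    return sum(x for x in nums if x <= obs) / math.comb(r1 + r2, c1)


class TestFisher:
    def test_balanced_table(self):
        assert mk.fisher_exact_two_sided(5, 5, 5, 5) == 1.0

    def test_extreme_table_closed_form(self):
        # only the two corner tables have probability <= observed
        p = mk.fisher_exact_two_sided(0, 10, 10, 0)
        assert p == pytest.approx(2 / 184756, rel=1e-10)

    def test_matches_enumeration(self):
        assert mk.fisher_exact_two_sided(30, 70, 10, 90) == pytest.approx(
            exact_fisher(30, 70, 10, 90), abs=1e-10)

    def test_all_zero_rejected(self):
        with pytest.raises(mk.MethylomeError):
            mk.fisher_exact_two_sided(0, 0, 0, 0)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.tuples(*[st.integers(0, 60)] * 4))
    def test_symmetry_and_range(self, table):
        a, b, c, d = table
        if a + b + c + d == 0:
            return
        p = mk.fisher_exact_two_sided(a, b, c, d)
        assert 0 < p <= 1
        # swapping rows or columns leaves the two-sided p unchanged
        assert p == pytest.approx(mk.fisher_exact_two_sided(c, d, a, b), rel=1e-9)
        assert p == pytest.approx(mk.fisher_exact_two_sided(b, a, d, c), rel=1e-9)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        q = mk.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert mk.bh_fdr([0.37])[0] == 0.37

    def test_out_of_range_rejected(self):
        with pytest.raises(mk.MethylomeError):
            mk.bh_fdr([0.5, 1.5])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_dominates_p_and_matches_statsmodels(self, ps):
        p = np.array(ps)
        q = mk.bh_fdr(p)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, ref, atol=1e-12)


def paired_window_samples(n_sites=12, a=(3, 7), b=(1, 9), spacing=50):
    """Two samples sharing n_sites sites in one window with fixed counts."""
    positions = [1 + i * spacing for i in range(n_sites)]
    sa = uniform_sample("c1", positions, *a)
    sb = uniform_sample("c1", positions, *b)
    return sa, sb


class TestScanWindows:
    def test_example_fold_and_difference(self):
        sa, sb = paired_window_samples()  # site MLs 0.30 vs 0.10
        windows = mk.scan_windows(sa, sb, DmrParams(window=1000, step=1000))
        assert len(windows) == 1
        w = windows.iloc[0]
        assert w["n_sites"] == 12
        assert w["ml_a"] == pytest.approx(0.3)
        assert w["ml_b"] == pytest.approx(0.1)
        assert w["fold_change"] == pytest.approx(3.0)
        assert w["difference"] == pytest.approx(0.2)
        assert w["p"] == pytest.approx(
            exact_fisher(12 * 3, 12 * 7, 12 * 1, 12 * 9), abs=1e-10)

    def test_exactly_ten_shared_sites_dropped(self):
        sa, sb = paired_window_samples(n_sites=10)
        assert len(mk.scan_windows(sa, sb, DmrParams(window=1000, step=1000))) == 0
        sa, sb = paired_window_samples(n_sites=11)
        assert len(mk.scan_windows(sa, sb, DmrParams(window=1000, step=1000))) == 1

    def test_sites_must_be_deep_in_both_samples(self):
        positions = list(range(1, 1 + 14 * 50, 50))
        sa = uniform_sample("c1", positions, 5, 5)
        rows = [("c1", p, "+", 1, 1, "CG", "CGA") for p in positions[:3]]
        rows += [("c1", p, "+", 3, 7, "CG", "CGA") for p in positions[3:]]
        sb = make_sample(rows)
        windows = mk.scan_windows(sa, sb, DmrParams(window=1000, step=1000))
        assert len(windows) == 1
        assert windows.iloc[0]["n_sites"] == 11  # 3 shallow-in-B sites excluded

    def test_identical_samples_filtered_out(self):
        sa, _ = paired_window_samples()
        windows = mk.scan_windows(sa, sa, DmrParams(window=1000, step=1000))
        assert (windows["fold_change"] == 1.0).all()
        assert (windows["difference"] == 0.0).all()
        assert len(mk.select_potential_dmrs(windows)) == 0

    def test_nonconversion_correction_applied(self):
        sa, sb = paired_window_samples()
        raw = mk.scan_windows(sa, sb, DmrParams(window=1000, step=1000))
        corrected = mk.scan_windows(
            sa, sb, DmrParams(window=1000, step=1000), r_a=0.1, r_b=0.0)
        assert corrected.iloc[0]["ml_a"] == pytest.approx((0.3 - 0.1) / 0.9)
        assert corrected.iloc[0]["ml_b"] == raw.iloc[0]["ml_b"]


class TestSelectPotential:
    def frame(self, **overrides):
        base = dict(chrom="c1", start=1, end=1000, n_sites=12,
                    ml_a=0.3, ml_b=0.1, fold_change=3.0, difference=0.2, p=1e-6)
        base.update(overrides)
        return pd.DataFrame([base])

    def test_passing_window_retained(self):
        kept = mk.select_potential_dmrs(self.frame())
        assert len(kept) == 1 and kept.iloc[0]["q"] == 1e-6

    def test_boundaries_are_strict(self):
        assert len(mk.select_potential_dmrs(self.frame(fold_change=2.0))) == 0
        assert len(mk.select_potential_dmrs(self.frame(difference=0.1))) == 0
        assert len(mk.select_potential_dmrs(self.frame(p=0.05))) == 0


class TestMergeAndRetest:
    def test_overlapping_windows_merge_to_union(self):
        sa, sb = paired_window_samples(n_sites=40, spacing=40)  # spans 1..1561
        params = DmrParams(window=1000, step=100)
        windows = mk.scan_windows(sa, sb, params)
        potential = mk.select_potential_dmrs(windows, params)
        assert len(potential) > 1
        final = mk.call_dmrs(sa, sb, params=params)
        assert len(final) == 1
        d = final[0]
        assert d.start == 1
        assert d.direction == "hyper"
        # merged region passes the effect-size filters
        assert d.fold_change > 2 and d.difference > 0.1

    def test_disjoint_regions_unchanged(self, small_dataset, small_dmrs):
        regions = [(d.chrom, d.start, d.end) for d in small_dmrs]
        out = mk.merge_and_retest(
            small_dmrs, small_dataset.sample_a, small_dataset.sample_b)
        assert [(d.chrom, d.start, d.end) for d in out] == sorted(regions)

    def test_idempotent(self, small_dataset, small_dmrs):
        once = mk.merge_and_retest(
            small_dmrs, small_dataset.sample_a, small_dataset.sample_b)
        twice = mk.merge_and_retest(
            once, small_dataset.sample_a, small_dataset.sample_b)
        assert once == twice

    def test_final_set_nonoverlapping_sorted(self, small_dmrs):
        for d1, d2 in zip(small_dmrs, small_dmrs[1:]):
            assert (d1.chrom, d1.start) <= (d2.chrom, d2.start)
            if d1.chrom == d2.chrom:
                assert d1.end < d2.start

    def test_every_final_dmr_passes_filters(self, small_dmrs):
        assert small_dmrs
        for d in small_dmrs:
            assert d.fold_change > 2.0
            assert d.difference > 0.1
            assert d.p < 0.05 and d.q < 0.05
            assert d.direction == ("hyper" if d.ml_a > d.ml_b else "hypo")


class TestCallDmrs:
    def test_identical_samples_no_dmrs(self, small_dataset):
        assert mk.call_dmrs(small_dataset.sample_a, small_dataset.sample_a) == []

    def test_label_swap_flips_directions(self, small_dataset, small_dmrs):
        swapped = mk.call_dmrs(
            small_dataset.sample_b, small_dataset.sample_a,
            small_dataset.lambda_b, small_dataset.lambda_a)
        assert len(swapped) == len(small_dmrs)
        flip = {"hyper": "hypo", "hypo": "hyper"}
        for d, s in zip(small_dmrs, swapped):
            assert (d.chrom, d.start, d.end) == (s.chrom, s.start, s.end)
            assert s.direction == flip[d.direction]
            assert s.ml_a == pytest.approx(d.ml_b)
            assert s.ml_b == pytest.approx(d.ml_a)
            assert s.p == pytest.approx(d.p, rel=1e-9)

    def test_planted_regions_recovered(self, small_dataset, small_dmrs):
        ev = mk.evaluate_calls(small_dmrs, small_dataset.truth, 0.3)
        assert ev.sensitivity >= 0.8
        assert ev.precision >= 0.8

    def test_direction_matches_truth(self, small_dataset, small_dmrs):
        ev = mk.evaluate_calls(small_dmrs, small_dataset.truth, 0.3)
        by_pos = {(d.chrom, d.start): d for d in small_dmrs}
        for row in ev.hits.itertuples(index=False):
            if row.recovered:
                call = by_pos[(row.chrom, row.call_start)]
                assert call.direction == row.direction


class TestDmrLevelSummary:
    def test_single_dmr(self):
        from conftest import dummy_dmr
        summary = mk.dmr_level_summary([dummy_dmr("c1", 1, 100, ml_a=0.4)])
        assert (summary.loc["A"] == 0.4).all()

    def test_quartiles_linear_interpolation(self):
        from conftest import dummy_dmr
        dmrs = [dummy_dmr("c1", i * 200 + 1, i * 200 + 100, ml_a=ml)
                for i, ml in enumerate([0.1, 0.2, 0.3, 0.4])]
        summary = mk.dmr_level_summary(dmrs)
        assert summary.loc["A", "median"] == pytest.approx(0.25)
        assert summary.loc["A", "q1"] == pytest.approx(0.175)

    def test_invariant_under_reordering(self):
        from conftest import dummy_dmr
        dmrs = [dummy_dmr("c1", i * 200 + 1, i * 200 + 100, ml_a=ml, ml_b=1 - ml)
                for i, ml in enumerate([0.5, 0.1, 0.9, 0.3])]
        a = mk.dmr_level_summary(dmrs)
        b = mk.dmr_level_summary(dmrs[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_empty_is_error(self):
        with pytest.raises(mk.MethylomeError):
            mk.dmr_level_summary([])


def test_params_validation():
    with pytest.raises(mk.MethylomeError):
        DmrParams(window=100, step=200)
    with pytest.raises(mk.MethylomeError):
        DmrParams(min_fold=0.0)
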