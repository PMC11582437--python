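import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ricewash.processing_factors import (
    PFResult,
    build_pf_table,
    compare_groups,
    compute_pf,
    compute_reduction,
    minimal_reduction_bound,
    pf_table_from_summaries,
    summarize_reductions,
    summary_ttest,
)
from ricewash.quantification import batch_quantify, fit_study_curves


class TestPointEstimates:
    @pytest.mark.parametrize(
        "ca, cb, pf",
        [(8.86, 32.9, 0.27), (24.1, 24.1, 1.00), (12.0, 12.0, 1.0)],
    )
    def test_pf_is_ratio_of_means(self, ca, cb, pf):
        assert compute_pf(ca, cb) == pytest.approx(pf, abs=0.005)

    @pytest.mark.parametrize(
        "ca, cb, red",
        [(11.8, 34.5, 65.8), (10.0, 10.0, 0.0), (31.7, 37.3, 15.01)],
    )
    def test_reduction_percent(self, ca, cb, red):
        assert compute_reduction(ca, cb) == pytest.approx(red, abs=0.05)

    def test_increase_gives_negative_reduction(self):
        assert compute_reduction(12.0, 10.0) == pytest.approx(-20.0)

    def test_nonpositive_unprocessed_mean_rejected(self):
        with pytest.raises(ValueError):
            compute_pf(1.0, 0.0)
        with pytest.raises(ValueError):
            compute_reduction(1.0, -2.0)

    @given(
        ca=st.floats(min_value=0, max_value=100),
        cb=st.floats(min_value=0.1, max_value=100),
    )
    def test_reduction_pf_identity(self, ca, cb):
        assert compute_reduction(ca, cb) == pytest.approx(
            100 * (1 - compute_pf(ca, cb)), abs=1e-9
        )

    @given(
        cb=st.floats(min_value=1, max_value=100),
        ca1=st.floats(min_value=0, max_value=100),
        delta=st.floats(min_value=1e-3, max_value=50),
    )
    def test_reduction_strictly_decreasing_in_washed_mean(self, cb, ca1, delta):
        assert compute_reduction(ca1 + delta, cb) < compute_reduction(ca1, cb)


class TestMinimalBound:
    @pytest.mark.parametrize(
        "cb, loq, bound",
        [(7.42, 5, 32.6), (10.4, 10, 3.85), (10.0, 10.0, 0.0)],
    )
    def test_bound_from_loq(self, cb, loq, bound):
        assert minimal_reduction_bound(cb, loq) == pytest.approx(bound, abs=0.05)

    def test_uninformative_bound_rejected(self):
        with pytest.raises(ValueError):
            minimal_reduction_bound(4.0, 5.0)

    @given(
        cb=st.floats(min_value=10, max_value=60),
        true_ca=st.floats(min_value=0.01, max_value=4.9),
    )
    def test_bound_never_exceeds_true_reduction(self, cb, true_ca):
        # whenever the washed concentration is genuinely below the LOQ the
        # censored bound is conservative
        loq = 5.0
        assert minimal_reduction_bound(cb, loq) <= compute_reduction(true_ca, cb)


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        res = compare_groups([10.0, 11.0, 12.0], [10.0, 11.0, 12.0])
        assert res.t == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_clear_shift_with_realized_replicates(self):
        # replicate sets realizing mean 16.1 sd 0.21 vs mean 15.2 sd 0.31:
        # pooled t = 4.16 on 4 df, p ≈ 0.014
        before = [16.1 - 0.21, 16.1, 16.1 + 0.21]
        after = [15.2 - 0.31, 15.2, 15.2 + 0.31]
        res = compare_groups(before, after)
        assert res.t == pytest.approx(4.163, abs=0.01)
        assert res.p_value == pytest.approx(0.0141, abs=0.002)
        assert res.significant and not res.welch_used

    def test_alpha_zero_never_significant(self):
        res = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], alpha=0.0)
        assert not res.significant

    def test_zero_variance_conventions(self):
        equal = compare_groups([5.0, 5.0], [5.0, 5.0])
        assert equal.p_value == 1.0 and not equal.significant
        shifted = compare_groups([5.0, 5.0], [4.0, 4.0])
        assert shifted.p_value == 0.0 and shifted.significant

    def test_group_size_validated(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])


class TestSummaryTtest:
    def test_equal_means_give_p_one(self):
        t, df, p = summary_ttest(10.0, 1.0, 3, 10.0, 1.0, 3)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        # pooled SE = sqrt((0.21² + 0.31²)/2 · 2/3) = 0.2162
        t, df, p = summary_ttest(16.1, 0.21, 3, 15.2, 0.31, 3)
        assert t == pytest.approx(0.9 / 0.21618, abs=0.01)
        assert df == 4
        assert p < 0.05

    @given(
        data=st.lists(st.floats(min_value=1, max_value=50), min_size=3, max_size=6),
        shift=st.floats(min_value=-5, max_value=5),
    )
    def test_agrees_with_replicate_t(self, data, shift):
        a = np.asarray(data)
        b = a + shift + np.linspace(0, 1, a.size)  # break exact ties
        t_sum, _, p_sum = summary_ttest(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
        )
        from scipy import stats

        t_raw, p_raw = stats.ttest_ind(a, b, equal_var=True)
        assert t_sum == pytest.approx(float(t_raw), rel=1e-9, abs=1e-9)
        assert p_sum == pytest.approx(float(p_raw), rel=1e-9, abs=1e-9)

    def test_zero_sd_equal_means_convention(self):
        _, _, p = summary_ttest(5.0, 0.0, 3, 5.0, 0.0, 3)
        assert p == 1.0


class TestBuildPfTable:
    def test_noiseless_closure_recovers_true_pf(self, registry):
        from ricewash.simulate import SimConfig, simulate_study

        pf_true = {"Diazinon": 0.85, "Cadusafos": 0.34}
        cfg = SimConfig(
            seed=5, analytes=("Diazinon", "Cadusafos"), true_pf=pf_true,
            wash_levels=(50.0,),  # keeps the washed truth above both LOQs
            cv_repeatability=0.0, cv_reproducibility=0.0, rt_jitter_sd=0.0,
        )
        study = simulate_study(cfg, registry)
        curves = fit_study_curves(study.injections)
        batch = batch_quantify(study.injections, curves, study.registry)
        results = build_pf_table(batch.table, study.registry)
        for r in results:
            assert r.pf == pytest.approx(pf_true[r.analyte], rel=1e-9)

    def test_censored_washed_group_reports_bound(self, registry):
        from ricewash.simulate import SimConfig, simulate_study

        # washed truth 50·0.65·0.1 = 3.25, below every LOQ in play
        cfg = SimConfig(
            seed=5, analytes=("Diazinon",), true_pf=0.1, wash_levels=(50.0,),
            cv_repeatability=0.0, cv_reproducibility=0.0, rt_jitter_sd=0.0,
        )
        study = simulate_study(cfg, registry)
        batch = batch_quantify(
            study.injections, fit_study_curves(study.injections), study.registry
        )
        (res,) = build_pf_table(batch.table, study.registry)
        assert res.ca_censored and not res.cb_censored
        assert res.is_bound and res.pf is None
        assert res.reduction_pct == pytest.approx(
            minimal_reduction_bound(50 * 0.65, 10.0), rel=1e-9
        )
        assert res.reduction_label().startswith("> ")

    def test_both_groups_censored_undefined(self, registry):
        from ricewash.simulate import SimConfig, simulate_study

        cfg = SimConfig(
            seed=5, analytes=("Pirimiphos-ethyl",), true_pf=0.5, wash_levels=(20.0,),
            cv_repeatability=0.0, cv_reproducibility=0.0, rt_jitter_sd=0.0,
        )  # LOQ 50: both groups sit far below
        study = simulate_study(cfg, registry)
        batch = batch_quantify(
            study.injections, fit_study_curves(study.injections), study.registry
        )
        (res,) = build_pf_table(batch.table, study.registry)
        assert res.cb_censored and res.ca_censored
        assert res.pf is None and res.reduction_pct is None
        assert res.pf_label() == "–" and res.reduction_label() == "–"


class TestSummaries:
    def make_result(self, red, is_bound=False, undefined=False):
        return PFResult(
            analyte="X", level=50.0, n=3, cb_mean=30.0, cb_sd=1.0,
            ca_mean=None if undefined else 30 * (1 - red / 100), ca_sd=1.0,
            cb_censored=undefined, ca_censored=is_bound,
            pf=None if (is_bound or undefined) else 1 - red / 100,
            reduction_pct=None if undefined else red,
            is_bound=is_bound, p_value=None, significant=False,
        )

    def test_empty_input_all_zero(self):
        s = summarize_reductions([])
        assert s.counts == (0, 0, 0, 0)
        assert s.fractions == (0.0, 0.0, 0.0, 0.0)

    def test_single_mid_range_reduction(self):
        s = summarize_reductions([self.make_result(50.0)])
        assert dict(zip(s.labels, s.counts))["40–60"] == 1

    def test_bounds_and_undefined_counted_separately(self):
        results = [
            self.make_result(50.0),
            self.make_result(45.0, is_bound=True),
            self.make_result(0.0, undefined=True),
        ]
        s = summarize_reductions(results)
        assert s.n_numeric == 1 and s.n_bounds == 1 and s.n_undefined == 1
        assert sum(s.counts) == 1

    def test_defined_bins_sum_to_numeric_count(self):
        results = [self.make_result(r) for r in (5, 25, 45, 65, 95, -10)]
        s = summarize_reductions(results)
        assert sum(s.counts) == s.n_numeric == 6


class TestFromSummaries:
    def test_published_style_rows(self, registry):
        frame = pd.DataFrame(
            [
                dict(pesticide="Diazinon", level_ug_kg=20.0, n=3,
                     cb_mean=16.1, cb_sd=0.21, cb_censored=False,
                     ca_mean=15.2, ca_sd=0.31, ca_censored=False),
                dict(pesticide="Boscalid", level_ug_kg=20.0, n=3,
                     cb_mean=7.42, cb_sd=0.84, cb_censored=False,
                     ca_mean=None, ca_sd=None, ca_censored=True),
            ]
        )
        diazinon, boscalid = pf_table_from_summaries(frame, registry)
        assert diazinon.pf == pytest.approx(15.2 / 16.1, rel=1e-9)
        assert diazinon.significant
        assert boscalid.is_bound
        assert boscalid.reduction_pct == pytest.approx(32.6, abs=0.05)

    def test_unknown_analyte_needs_override(self, registry):
        row = dict(pesticide="Metrobromuron", level_ug_kg=20.0, n=3,
                   cb_mean=15.0, cb_sd=1.0, cb_censored=False,
                   ca_mean=None, ca_sd=None, ca_censored=True)
        (no_loq,) = pf_table_from_summaries(pd.DataFrame([row]), registry)
        assert no_loq.reduction_pct is None
        (with_loq,) = pf_table_from_summaries(
            pd.DataFrame([row]), registry, loq_overrides={"Metrobromuron": 10.0}
        )
        assert with_loq.is_bound
        assert with_loq.reduction_pct == pytest.approx(100 * (1 - 10 / 15), rel=1e-9)
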