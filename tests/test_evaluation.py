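"""Aggregation, Tukey statistics, repeatability, ranking and the
end-to-end report: parameter-recovery checks on generated screens."""

import numpy as np
import pytest

from sfcscreen import (
    DEFAULT_GRADIENT,
    DesignBlock,
    EffectModel,
    PeakDescriptor,
    PeakTable,
    ScreenDesign,
    aggregate_by_factor,
    default_design,
    default_effects,
    default_panel,
    generate_screen,
    rank_conditions,
    repeatability,
    run_screen_evaluation,
    summarize_condition,
    tukey_five_number,
)


def is_peak(tr, area):
    return PeakDescriptor(
        analyte_id="caffeine", tr=tr, height=100.0, area=area, base_width=10.0
    )


class TestTukeyFiveNumber:
    def test_1_to_100(self):
        st = tukey_five_number(list(range(1, 101)))
        assert st.median == pytest.approx(50.5)
        assert st.q1 == pytest.approx(25.75)
        assert st.q3 == pytest.approx(75.25)
        assert st.iqr == pytest.approx(49.5)
        assert st.n == 100

    def test_constant_sample(self):
        st = tukey_five_number([7.0] * 10)
        assert st.median == st.q1 == st.q3 == st.whisker_low == st.whisker_high == 7.0
        assert st.iqr == 0.0

    def test_outlier_excluded_from_whisker(self):
        st = tukey_five_number([1, 2, 3, 4, 100])
        assert st.whisker_high == 4.0
        assert st.whisker_low == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tukey_five_number([])


def simple_table(widths, condition_id="c", analytes=None, spacing=40.0):
    peaks = tuple(
        PeakDescriptor(
            analyte_id=(analytes[i] if analytes else f"p{i}"),
            tr=100.0 + i * spacing,
            height=100.0,
            area=500.0,
            base_width=float(w),
        )
        for i, w in enumerate(widths)
    )
    return PeakTable(condition_id=condition_id, peaks=peaks)


class TestSummarizeCondition:
    def test_subset_equal_to_all_when_table_is_subset_only(self):
        tab = simple_table([10, 12, 14], analytes=["uracil", "proline", "adenine"])
        s_all = summarize_condition(tab, DEFAULT_GRADIENT, subset=None)
        s_sub = summarize_condition(
            tab, DEFAULT_GRADIENT, subset=("uracil", "proline", "adenine")
        )
        assert s_all.median_width == s_sub.median_width
        assert s_sub.n_subset == 3

    def test_single_peak_condition(self):
        s = summarize_condition(simple_table([10.0]), DEFAULT_GRADIENT)
        assert s.sum_rs == 0.0
        assert s.nrp is None
        assert s.pc_rs == 1.0

    def test_empty_subset_flags_incomparable(self):
        tab = simple_table([10, 12, 14])
        s = summarize_condition(tab, DEFAULT_GRADIENT, subset=("nothing",))
        assert not s.comparable
        assert s.median_width == pytest.approx(12.0)  # falls back to all peaks

    def test_planted_median_recovered(self):
        # 30 widths drawn around median 12.6 s; recovered median must sit
        # inside the bootstrap 95% interval of the sample
        rng = np.random.default_rng(4)
        widths = 12.6 * rng.lognormal(0.0, 0.15, 30)
        s = summarize_condition(simple_table(widths), DEFAULT_GRADIENT)
        boots = [
            np.median(rng.choice(widths, widths.size, replace=True))
            for _ in range(2000)
        ]
        lo, hi = np.percentile(boots, [2.5, 97.5])
        assert lo <= s.median_width <= hi

    def test_sum_rs_uses_all_peaks_even_with_subset(self):
        tab = simple_table([10, 12, 14, 16], analytes=["uracil", "a", "b", "c"])
        s = summarize_condition(tab, DEFAULT_GRADIENT, subset=("uracil",))
        full = summarize_condition(tab, DEFAULT_GRADIENT, subset=None)
        assert s.sum_rs == full.sum_rs
        assert s.nrp == full.nrp


class TestRepeatability:
    def test_direct_rsd(self):
        reps = [is_peak(100.0, a) for a in (90.0, 100.0, 110.0)]
        r = repeatability(reps)
        assert r.rsd_area == pytest.approx(10.0)
        assert r.n_replicates == 3

    def test_constant_tr_zero_rsd(self):
        reps = [is_peak(100.0, a) for a in (90.0, 100.0, 110.0)]
        assert repeatability(reps).rsd_tr == 0.0

    def test_scale_invariance_of_area_rsd(self):
        rng = np.random.default_rng(8)
        areas = rng.lognormal(5.0, 0.1, 20)
        r1 = repeatability([is_peak(100.0, a) for a in areas])
        r2 = repeatability([is_peak(100.0, 3.7 * a) for a in areas])
        assert r1.rsd_area == pytest.approx(r2.rsd_area, rel=1e-12)

    def test_planted_cv_recovered(self):
        # lognormal areas with CV 16%: at n = 30 the RSD estimate should
        # land within [12%, 20%]
        rng = np.random.default_rng(21)
        cv = 0.16
        sig = np.sqrt(np.log1p(cv * cv))
        areas = 1000.0 * rng.lognormal(-0.5 * sig**2, sig, 30)
        r = repeatability([is_peak(100.0, a) for a in areas])
        assert 12.0 <= r.rsd_area <= 20.0

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            repeatability([is_peak(100.0, 100.0)])


class TestAggregateByFactor:
    DESIGN = ScreenDesign(
        blocks=(
            DesignBlock(
                "b", ("Diol", "BEH"), ("water", "formic acid"), (35.0, 40.0)
            ),
        )
    )

    def test_planted_width_ratio_recovered(self):
        effects = EffectModel(
            width_multipliers={"additive": {"formic acid": 2.0}},
            default_elution_probability=1.0,
        )
        ds = generate_screen(self.DESIGN, default_panel(), effects, seed=31)
        agg = aggregate_by_factor(ds, "additive")
        ratio = agg["formic acid"].median / agg["water"].median
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_single_condition_equals_own_stats(self):
        design = ScreenDesign(
            blocks=(DesignBlock("one", ("Diol",), ("water",), (40.0,)),)
        )
        ds = generate_screen(design, default_panel(), EffectModel(), seed=2)
        agg = aggregate_by_factor(ds, "column")
        own = tukey_five_number(ds.tables[ds.conditions[0].condition_id].widths())
        assert agg["Diol"] == own

    def test_restriction_bookkeeping(self):
        # restricting to the Torus block with 3 modifiers reproduces that
        # comparison's levels and n values
        ds = generate_screen(
            default_design(),
            default_panel(),
            default_effects(),
            seed=6,
        )
        torus = ("2-PIC", "Diol", "DEA", "1-AA")
        modifiers = ("water", "ammonium formate", "formic acid")
        agg = aggregate_by_factor(
            ds,
            "column",
            restrict=lambda c: c.column in torus and c.additive in modifiers,
        )
        assert set(agg) == set(torus)
        for col in torus:
            expected_n = sum(
                len(ds.tables[c.condition_id])
                for c in ds.conditions
                if c.column == col and c.additive in modifiers
            )
            assert agg[col].n == expected_n

    def test_excluding_column_leaves_other_levels_unchanged(self):
        ds = generate_screen(self.DESIGN, default_panel(), EffectModel(), seed=13)
        full = aggregate_by_factor(ds, "column")
        without = aggregate_by_factor(
            ds, "column", restrict=lambda c: c.column != "BEH"
        )
        assert "BEH" not in without
        assert without["Diol"] == full["Diol"]

    def test_unknown_factor_rejected(self):
        ds = generate_screen(self.DESIGN, default_panel(), EffectModel(), seed=1)
        with pytest.raises(ValueError, match="factor"):
            aggregate_by_factor(ds, "flow_rate")


class TestRankConditions:
    def make_summary(self, cid, median, sum_rs=5.0, nrp=0.5):
        return summarize_condition(
            simple_table(
                [median] * 3, condition_id=cid, spacing=median * sum_rs / 2.0
            ),
            DEFAULT_GRADIENT,
        )

    def test_single_condition(self):
        s = self.make_summary("only", 10.0)
        assert rank_conditions([s]) == [s]

    def test_narrower_first(self):
        a = self.make_summary("wide", 20.0)
        b = self.make_summary("narrow", 10.0)
        assert [s.condition_id for s in rank_conditions([a, b])][0] == "narrow"

    def test_output_is_stable_permutation(self):
        rng = np.random.default_rng(3)
        summaries = [
            self.make_summary(f"c{i}", float(rng.uniform(5, 30))) for i in range(20)
        ]
        ranked = rank_conditions(summaries)
        assert sorted(s.condition_id for s in ranked) == sorted(
            s.condition_id for s in summaries
        )
        shuffled = list(summaries)
        rng.shuffle(shuffled)
        assert [s.condition_id for s in rank_conditions(shuffled)] == [
            s.condition_id for s in ranked
        ]

    def test_dominating_column_tops_ranking(self):
        effects = EffectModel(
            width_multipliers={"column": {"Diol": 0.4}},
            default_elution_probability=1.0,
        )
        ds = generate_screen(
            TestAggregateByFactor.DESIGN, default_panel(), effects, seed=41
        )
        report = run_screen_evaluation(ds, subset=None, exclude_columns=())
        n_diol_conditions = sum(1 for c in ds.conditions if c.column == "Diol")
        top = report.ranking[:n_diol_conditions]
        assert all(cid.startswith("Diol|") for cid in top)


class TestEndToEnd:
    def test_full_screen_report(self):
        ds = generate_screen(
            default_design(),
            default_panel(),
            default_effects(),
            seed=1,
        )
        report = run_screen_evaluation(ds)
        assert len(report.summaries) == 264
        assert len(report.ranking) == 264
        df = report.to_frame()
        assert df.shape[0] == 264
        # internal-standard retention is tightly repeatable by construction
        assert max(r.rsd_tr for r in report.repeatability.values()) < 2.0

    def test_rerun_is_byte_identical(self):
        ds1 = generate_screen(
            TestAggregateByFactor.DESIGN, default_panel(), default_effects(), seed=77
        )
        ds2 = generate_screen(
            TestAggregateByFactor.DESIGN, default_panel(), default_effects(), seed=77
        )
        r1 = run_screen_evaluation(ds1)
        r2 = run_screen_evaluation(ds2)
        assert r1.digest() == r2.digest()
        assert r1.to_frame().equals(r2.to_frame())

    def test_uniform_effects_rank_by_condition_id(self):
        # no planted differences: ties broken deterministically by id
        effects = EffectModel(default_elution_probability=1.0, width_noise_cv=0.0,
                              tr_jitter_rsd=0.0)
        ds = generate_screen(
            TestAggregateByFactor.DESIGN, default_panel(), effects, seed=9
        )
        report = run_screen_evaluation(ds, subset=None)
        assert list(report.ranking) == sorted(report.ranking)
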