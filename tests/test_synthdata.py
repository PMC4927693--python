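"""Generator correctness: EMG shape, areas, noise, design enumeration and
reproducibility of the screen-level draws."""

import numpy as np
import pytest

from sfcscreen import (
    ALKYLAMINES,
    Condition,
    DesignBlock,
    EffectModel,
    EMGPeakSpec,
    NoiseModel,
    ScreenDesign,
    TORUS_COLUMNS,
    default_design,
    default_effects,
    default_panel,
    generate_screen,
    make_emg_trace,
    simulate_chromatogram,
)

GRID = np.arange(0.0, 200.0 + 0.025, 0.05)


class TestEMGTrace:
    def test_gaussian_limit_apex(self):
        spec = EMGPeakSpec("x", 100.0, 2.0, 1e-6, 1000.0)
        trace = make_emg_trace(spec, GRID)
        assert trace.max() == pytest.approx(1000.0, rel=1e-3)
        assert GRID[trace.argmax()] == pytest.approx(100.0, abs=0.05)

    def test_zero_amplitude_gives_zero_trace(self):
        spec = EMGPeakSpec("x", 100.0, 2.0, 1.0, 0.0)
        assert np.all(make_emg_trace(spec, GRID) == 0.0)

    def test_tailing_peak_matches_convolution_oracle(self):
        # independent oracle: discrete convolution of the Gaussian trace
        # with a normalised exponential decay kernel
        sigma, tau, amp, mu = 2.0, 4.0, 1000.0, 100.0
        trace = make_emg_trace(EMGPeakSpec("x", mu, sigma, tau, amp), GRID)
        step = 0.05
        gauss = amp * np.exp(-0.5 * ((GRID - mu) / sigma) ** 2)
        kt = np.arange(0.0, 12.0 * tau, step)
        kernel = np.exp(-kt / tau)
        kernel /= kernel.sum()
        oracle = np.convolve(gauss, kernel)[: GRID.size]
        assert np.max(np.abs(trace - oracle)) < 1e-2 * trace.max()
        # tailing delays and lowers the apex relative to the Gaussian centre
        assert GRID[trace.argmax()] > mu
        assert trace.max() < amp

    def test_gaussian_limit_fwhm(self):
        sigma = 3.0
        spec = EMGPeakSpec("x", 100.0, sigma, sigma * 1e-4, 500.0)
        trace = make_emg_trace(spec, GRID)
        above = GRID[trace >= trace.max() / 2.0]
        fwhm = above[-1] - above[0]
        assert fwhm == pytest.approx(2.355 * sigma, rel=0.01)

    def test_area_conserved_for_zero_tau(self):
        for sigma in (1.0, 2.0, 5.0):
            spec = EMGPeakSpec("x", 100.0, sigma, 0.0, 1000.0)
            area = np.trapezoid(make_emg_trace(spec, GRID), GRID)
            assert area == pytest.approx(1000.0 * sigma * np.sqrt(2 * np.pi), rel=5e-3)

    def test_trace_nonnegative_even_with_heavy_tail(self):
        spec = EMGPeakSpec("x", 50.0, 1.0, 30.0, 1000.0)
        assert np.all(make_emg_trace(spec, GRID) >= 0.0)

    def test_non_uniform_grid_rejected(self):
        bad = np.array([0.0, 1.0, 2.0, 3.5, 4.0])
        with pytest.raises(ValueError, match="uniform"):
            make_emg_trace(EMGPeakSpec("x", 2.0, 1.0, 0.0, 1.0), bad)

    def test_invariants_rejected(self):
        with pytest.raises(ValueError):
            EMGPeakSpec("x", 10.0, -1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            EMGPeakSpec("x", 10.0, 1.0, -0.5, 1.0)


class TestSimulateChromatogram:
    def test_noise_free_area(self):
        chrom = simulate_chromatogram(
            [EMGPeakSpec("x", 100.0, 2.0, 0.0, 1000.0)], NoiseModel(0, 0, 0), 200.0
        )
        area = np.trapezoid(chrom.intensity, chrom.time)
        assert area == pytest.approx(1000.0 * 2.0 * np.sqrt(2 * np.pi), rel=1e-3)

    def test_noise_sd_recovered(self):
        chrom = simulate_chromatogram([], NoiseModel(5.0, 0.0, 42), 500.0, step=0.05)
        assert chrom.time.size >= 10_000
        assert np.std(chrom.intensity) == pytest.approx(5.0, rel=0.10)

    def test_identical_seed_bit_identical(self):
        peaks = [EMGPeakSpec("x", 100.0, 2.0, 1.0, 800.0)]
        a = simulate_chromatogram(peaks, NoiseModel(5.0, 0.1, 7), 200.0)
        b = simulate_chromatogram(peaks, NoiseModel(5.0, 0.1, 7), 200.0)
        assert np.array_equal(a.intensity, b.intensity)

    def test_out_of_window_peak_flagged(self):
        with pytest.warns(UserWarning, match="truncated"):
            chrom = simulate_chromatogram(
                [EMGPeakSpec("late", 195.0, 3.0, 0.0, 100.0)], NoiseModel(0, 0, 0), 200.0
            )
        assert chrom.truncated == ("late",)


class TestDesign:
    def test_default_design_has_264_unique_conditions(self):
        conds = default_design().conditions()
        assert len(conds) == 264
        assert len({c.condition_id for c in conds}) == 264

    def test_alkylamine_conditions_are_uv_only(self):
        for cond in default_design().conditions():
            if cond.additive in ALKYLAMINES:
                assert cond.detection == "UV"

    def test_55C_restricted_to_torus_columns(self):
        for cond in default_design().conditions():
            if cond.temperature == 55.0:
                assert cond.column in TORUS_COLUMNS
        with pytest.raises(ValueError, match="Torus"):
            Condition("BEH", "water", 55.0)

    def test_duplicate_condition_rejected(self):
        block = DesignBlock("b", ("Diol",), ("water",), (40.0,))
        with pytest.raises(ValueError, match="duplicate"):
            ScreenDesign(blocks=(block, block))

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            ScreenDesign(blocks=())


SMALL_DESIGN = ScreenDesign(
    blocks=(
        DesignBlock(
            "small", ("Diol", "BEH"), ("water", "formic acid"), (35.0, 40.0)
        ),
    )
)


class TestGenerateScreen:
    def test_one_table_per_condition(self):
        ds = generate_screen(
            default_design(), default_panel(), default_effects(), seed=3
        )
        assert len(ds.conditions) == 264
        assert set(ds.tables) == {c.condition_id for c in ds.conditions}
        for cid in ds.tables:
            assert len(ds.standards[cid]) >= 4

    def test_determinism(self):
        a = generate_screen(SMALL_DESIGN, default_panel(), default_effects(), seed=11)
        b = generate_screen(SMALL_DESIGN, default_panel(), default_effects(), seed=11)
        for cid in a.tables:
            assert a.tables[cid].peaks == b.tables[cid].peaks
            assert a.standards[cid] == b.standards[cid]

    def test_zero_elution_probability_removes_compound(self):
        panel = default_panel()
        effects = EffectModel(
            elution_probability={
                ("uracil", add): 0.0
                for add in ("water", "formic acid")
            }
        )
        ds = generate_screen(SMALL_DESIGN, panel, effects, seed=5)
        for table in ds.tables.values():
            assert all(p.analyte_id != "uracil" for p in table.peaks)

    def test_elution_probability_calibration(self):
        # 20 compounds x 50 MS conditions = 1000 Bernoulli draws at p = 0.75
        design = ScreenDesign(
            blocks=(
                DesignBlock(
                    "cal",
                    ("Diol", "BEH", "2-PIC", "DEA", "1-AA"),
                    ("water", "formic acid", "acetic acid", "ammonium formate",
                     "ammonium acetate"),
                    (35.0, 40.0),
                ),
            )
        )
        effects = EffectModel(default_elution_probability=0.75)
        ds = generate_screen(design, default_panel(), effects, seed=2024)
        n_obs = sum(len(t) for t in ds.tables.values())
        frac = n_obs / (20 * 50)
        assert 0.72 <= frac <= 0.78

    def test_width_multiplier_recovered(self):
        # one additive gets 2x widths; median ratio across many peaks ~ 2
        panel = default_panel()
        effects = EffectModel(
            width_multipliers={"additive": {"formic acid": 2.0}},
            default_elution_probability=1.0,
            width_noise_cv=0.10,
        )
        ds = generate_screen(SMALL_DESIGN, panel, effects, seed=17)
        wide, narrow = [], []
        for cond in ds.conditions:
            widths = ds.tables[cond.condition_id].widths()
            (wide if cond.additive == "formic acid" else narrow).extend(widths)
        ratio = np.median(wide) / np.median(narrow)
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            generate_screen(SMALL_DESIGN, default_panel(), EffectModel(), seed=None)

    def test_effect_model_invariants(self):
        with pytest.raises(ValueError):
            EffectModel(width_multipliers={"additive": {"water": 0.0}})
        with pytest.raises(ValueError):
            EffectModel(elution_probability={("x", "water"): 1.5})
        with pytest.raises(ValueError):
            EffectModel(is_area_cv_base=-0.1)
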