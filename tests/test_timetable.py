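"""Molecular timetable: bundle, TIG selection, phase prediction."""

import math

import numpy as np
import pandas as pd
import pytest

from circatime import (
    LineEffect,
    SimulationConfig,
    TimetableError,
    TimetableModel,
    build_cosine_bundle,
    circular_difference,
    generate_static_cohort,
    predict_time,
    predict_times,
    rhythmicity_score,
    select_tigs,
)

INCREMENT = 1.0 / 6.0  # 10 minutes


def brute_force_best_wave(values, times, peaks, period=24.0):
    """Independent scan: plain per-wave Pearson correlation via corrcoef."""
    best = (-2.0, None)
    for peak in peaks:
        wave = np.cos(2 * np.pi * (np.asarray(times) - peak) / period)
        r = np.corrcoef(values, wave)[0, 1]
        if r > best[0]:
            best = (r, peak)
    return best


class TestCosineBundle:
    @pytest.mark.parametrize(
        "period,increment,n", [(24.0, INCREMENT, 144), (24.0, 6.0, 4), (20.0, INCREMENT, 120)]
    )
    def test_wave_count(self, period, increment, n):
        assert build_cosine_bundle(period, increment).n_waves == n

    def test_six_hour_increment_peaks(self):
        b = build_cosine_bundle(24.0, 6.0)
        np.testing.assert_allclose(b.peak_times, [0.0, 6.0, 12.0, 18.0])

    def test_wave_values_at_peak_and_antipode(self):
        b = build_cosine_bundle(24.0, 6.0)
        w = b.wave_matrix(np.array([6.0, 18.0]))
        assert w[1, 0] == pytest.approx(1.0)  # wave peaking at 6, evaluated at 6
        assert w[1, 1] == pytest.approx(-1.0)

    def test_nondivisible_increment_rejected(self):
        with pytest.raises(TimetableError):
            build_cosine_bundle(24.0, 0.7)


class TestRhythmicityScore:
    def test_pure_cosine_scores_one_at_its_phase(self):
        t = np.arange(0, 48, 2.0)
        trace = np.cos(2 * np.pi * (t - 6.0) / 24.0)
        r, peak = rhythmicity_score(trace, t, build_cosine_bundle())
        assert r == pytest.approx(1.0)
        assert peak == pytest.approx(6.0)

    def test_constant_trace_rejected(self):
        with pytest.raises(TimetableError):
            rhythmicity_score(np.ones(10), np.arange(10) * 2.0, build_cosine_bundle())

    def test_matches_brute_force_scan_on_noisy_trace(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 48, 2.0)
        trace = np.cos(2 * np.pi * (t - 13.3) / 24.0) + rng.normal(0, 0.5, t.size)
        bundle = build_cosine_bundle()
        r, peak = rhythmicity_score(trace, t, bundle)
        r_bf, peak_bf = brute_force_best_wave(trace, t, bundle.peak_times)
        assert r == pytest.approx(r_bf, abs=1e-12)
        assert peak == peak_bf


class TestSelectTigs:
    def test_low_cv_gene_excluded_even_if_rhythmic(self):
        # amplitude/mesor = 0.1 -> noiseless CV ~= 0.07 < 0.20 despite r = 1
        cfg = SimulationConfig(
            n_genes=4, cycler_fraction=1.0, amplitude=10.0, mesor=100.0,
            amplitude_to_noise=math.inf, duration_hours=24.0, replicates=1,
        )
        from circatime import generate_reference_timecourse

        matrix, _ = generate_reference_timecourse(cfg)
        with pytest.raises(TimetableError):  # nothing survives the CV filter
            select_tigs(matrix)

    def test_weakly_correlated_gene_excluded(self, noisy_reference):
        matrix, truth = noisy_reference
        model = select_tigs(matrix)
        assert (model.tigs["r_max"] > 0.5).all()
        assert (model.tigs["cv"] > 0.20).all()

    def test_noiseless_cyclers_all_selected_with_accurate_mpt(self, noiseless_reference):
        matrix, truth = noiseless_reference
        model = select_tigs(matrix)
        assert set(model.gene_ids) == set(truth.index[truth["is_cycling"]])
        err = [
            abs(circular_difference(model.tigs.loc[g, "mpt_hours"], truth.loc[g, "phase_hours"]))
            for g in model.gene_ids
        ]
        assert max(err) <= INCREMENT

    def test_per_regime_mode_requires_passing_both_days(self, noisy_reference):
        matrix, truth = noisy_reference
        unified = select_tigs(matrix, mode="LDDD_05")
        both = select_tigs(matrix, mode="LD_DD_05")
        assert set(both.gene_ids) <= set(unified.gene_ids)
        # MPT of overlapping genes comes from the unified fit
        common = both.gene_ids.intersection(unified.gene_ids)
        pd.testing.assert_series_equal(
            both.tigs.loc[common, "mpt_hours"], unified.tigs.loc[common, "mpt_hours"]
        )

    def test_model_with_single_tig_is_unusable(self):
        tigs = pd.DataFrame({"mpt_hours": [4.0], "r_max": [0.9], "cv": [0.5]},
                            index=["g1"])
        with pytest.raises(TimetableError):
            TimetableModel(tigs, build_cosine_bundle())


class TestPredictTime:
    def test_self_consistency_at_zt8(self, noiseless_reference):
        matrix, _ = noiseless_reference
        model = select_tigs(matrix)
        sid = matrix.sample_ids[list(matrix.times).index(8.0)]
        pred = predict_time(model, matrix.values[sid], harvest_time_hours=8.0)
        assert abs(circular_difference(pred.predicted_time_hours, 8.0)) <= INCREMENT
        assert pred.r_at_max == pytest.approx(1.0)

    def test_advanced_line_harvested_at_8_predicts_14(self, noiseless_config, noiseless_reference):
        matrix, _ = noiseless_reference
        model = select_tigs(matrix)
        cfg = SimulationConfig(**{**noiseless_config.__dict__, "start_time_hours": 8.0})
        cohort, _ = generate_static_cohort(cfg, [LineEffect("adv", phase_offset_hours=6.0)])
        pred = predict_time(model, cohort.values["adv"])
        assert abs(circular_difference(pred.predicted_time_hours, 14.0)) <= INCREMENT

    def test_phase_recovery_everywhere_on_the_grid(self, noiseless_reference):
        matrix, _ = noiseless_reference
        model = select_tigs(matrix)
        res = predict_times(model, matrix.values)
        err = np.abs(circular_difference(
            res["predicted_time_hours"].to_numpy(), matrix.harvest_times
        ))
        assert err.max() <= INCREMENT

    def test_shift_equivariance_noiseless(self, noiseless_config, noiseless_reference):
        matrix, _ = noiseless_reference
        model = select_tigs(matrix)
        base = predict_times(model, matrix.values)["predicted_time_hours"].to_numpy()
        for delta in (3.0, 7.5, 13.0):
            cohort, _ = generate_static_cohort(
                noiseless_config,
                [LineEffect(f"d{i}", phase_offset_hours=delta) for i in range(12)],
                interval_minutes=120.0,
            )
            shifted = predict_times(model, cohort.values)["predicted_time_hours"].to_numpy()
            np.testing.assert_allclose(
                circular_difference(shifted, (base + delta) % 24.0), 0.0, atol=1e-9
            )

    def test_argmax_matches_fine_exhaustive_scan(self, noisy_reference):
        matrix, _ = noisy_reference
        model = select_tigs(matrix)
        sid = matrix.sample_ids[17]
        sample = matrix.values.loc[model.gene_ids, sid].to_numpy()
        mpt = model.tigs["mpt_hours"].to_numpy()
        best = (-2.0, None)
        for phi in np.arange(0, 24, 1.0 / 60.0):  # 1-minute scan
            template = np.cos(2 * np.pi * (mpt - phi) / 24.0)
            r = np.corrcoef(sample, template)[0, 1]
            if r > best[0]:
                best = (r, phi)
        pred = predict_time(model, matrix.values[sid])
        assert abs(circular_difference(pred.predicted_time_hours, best[1])) <= INCREMENT

    def test_zero_variance_sample_rejected(self, noiseless_reference):
        matrix, _ = noiseless_reference
        model = select_tigs(matrix)
        flat = pd.Series(1.0, index=matrix.gene_ids)
        with pytest.raises(TimetableError):
            predict_time(model, flat)

    def test_monotone_degradation_with_noise(self):
        """Mean |error| over a cohort does not improve as ANR drops (in expectation)."""
        from circatime import generate_reference_timecourse

        anr_levels = [math.inf, 8.0, 4.0, 2.0, 1.0]
        mean_err = np.zeros(len(anr_levels))
        n_seeds = 20
        for seed in range(n_seeds):
            for j, anr in enumerate(anr_levels):
                cfg = SimulationConfig(
                    n_genes=20, cycler_fraction=1.0, amplitude_to_noise=anr,
                    duration_hours=24.0, replicates=1, seed=seed,
                )
                ref, _ = generate_reference_timecourse(
                    SimulationConfig(n_genes=20, cycler_fraction=1.0,
                                     amplitude_to_noise=anr, seed=seed + 1000)
                )
                model = select_tigs(ref)
                cohort, lt = generate_static_cohort(
                    cfg, [LineEffect(f"l{i}") for i in range(12)], interval_minutes=120.0
                )
                res = predict_times(model, cohort.values.loc[model.gene_ids])
                err = np.abs(circular_difference(
                    res["predicted_time_hours"].to_numpy(),
                    cohort.harvest_times,
                ))
                mean_err[j] += err.mean() / n_seeds
        assert np.all(np.diff(mean_err) >= -0.05)  # non-decreasing up to MC jitter


class TestPersistence:
    def test_model_round_trip(self, tmp_path, noiseless_reference):
        matrix, _ = noiseless_reference
        model = select_tigs(matrix)
        model.save(tmp_path / "tt.tsv")
        loaded = TimetableModel.load(tmp_path / "tt.tsv")
        pd.testing.assert_frame_equal(loaded.tigs, model.tigs)
        assert loaded.bundle.n_waves == model.bundle.n_waves
        res_a = predict_times(model, matrix.values)
        res_b = predict_times(loaded, matrix.values)
        pd.testing.assert_frame_equal(res_a, res_b)
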