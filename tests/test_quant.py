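import numpy as np
import pytest

from herbfp.defaults import CALIBRATIONS
from herbfp.errors import NotLocatedError, ValidationError
from herbfp.peaks import Peak
from herbfp.quant import (CalibrationCurve, DurabilityCondition, compute_rcf,
                          durability_study, esm_quantify, fit_calibration,
                          locate_peak_by_rrt, qams_quantify,
                          relative_deviation, round_half_away,
                          validation_metrics)
from herbfp.synthetic import (ConstituentSpec, default_constituents,
                              simulate_calibration_series)

MAC_A = CalibrationCurve(analyte="macrostemonoside_a", slope=2223.2,
                         intercept=-117.7, r_squared=0.9970,
                         c_min=21.42, c_max=72.31)


def line_points(slope, intercept, levels):
    return [(c, slope * c + intercept) for c in levels]


class TestFitCalibration:
    def test_exact_line_recovered(self):
        pts = line_points(2463.0, -127.53, np.linspace(6.62, 109.11, 5))
        curve = fit_calibration(pts, analyte="adenosine")
        assert curve.slope == pytest.approx(2463.0, abs=1e-9)
        assert curve.intercept == pytest.approx(-127.53, abs=1e-6)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert (curve.c_min, curve.c_max) == (pytest.approx(6.62),
                                              pytest.approx(109.11))

    def test_two_points_r2_is_one(self):
        curve = fit_calibration([(1.0, 100.0), (2.0, 157.0)])
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_slope_within_tolerance(self):
        spec = ConstituentSpec(id="a", retention_time=40.0,
                               response_slope=2223.2,
                               response_intercept=-117.7)
        series = simulate_calibration_series(
            spec, np.linspace(21.42, 72.31, 5), replicate_cv=0.01, seed=6)
        assert fit_calibration(series).slope == pytest.approx(2223.2,
                                                              rel=0.03)

    def test_equal_concentrations_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            fit_calibration([(5.0, 10.0), (5.0, 11.0)])

    def test_single_point_rejected(self):
        with pytest.raises(ValidationError):
            fit_calibration([(5.0, 10.0)])


class TestEsmQuantify:
    def test_inverse_of_line(self):
        res = esm_quantify(2223.2 * 50.0 - 117.7, MAC_A)
        assert res.content == pytest.approx(50.0, abs=1e-10)
        assert not res.extrapolated and not res.clipped

    def test_area_equal_intercept_gives_zero(self):
        res = esm_quantify(MAC_A.intercept, MAC_A)
        assert res.content == 0.0

    def test_area_below_intercept_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            res = esm_quantify(MAC_A.intercept - 100.0, MAC_A)
        assert res.content == 0.0 and res.clipped

    def test_out_of_range_flagged_extrapolated(self):
        res = esm_quantify(MAC_A.predict(100.0), MAC_A)
        assert res.extrapolated

    def test_round_trip_with_simulated_series(self):
        spec = ConstituentSpec(id="a", retention_time=40.0,
                               response_slope=2223.2,
                               response_intercept=-117.7)
        series = simulate_calibration_series(
            spec, np.linspace(21.42, 72.31, 5), replicate_cv=0.0)
        curve = fit_calibration(series)
        for conc, area in series.itertuples(index=False):
            assert esm_quantify(area, curve).content == pytest.approx(
                conc, abs=1e-9)

    def test_mass_volume_conversion(self):
        res = esm_quantify(MAC_A.predict(50.0), MAC_A, sample_mass=1.0,
                           extract_volume=4.0)
        assert res.content == pytest.approx(200.0)
        assert res.concentration == pytest.approx(50.0)


class TestComputeRcf:
    def test_identical_response_gives_unity(self):
        pts = line_points(1000.0, 0.0, [10.0, 20.0, 30.0])
        rec = compute_rcf(pts, pts)
        assert rec.mean_rcf == pytest.approx(1.0)
        assert rec.rcf_rsd == pytest.approx(0.0)

    def test_intercept_free_equals_slope_ratio(self):
        # oracle: per-level (A_s/C_s)/(A_i/C_i) with intercept-free lines
        # collapses to the slope ratio 2223.2/861.0 at every level
        levels_s = np.linspace(21.42, 72.31, 5)
        levels_i = np.linspace(25.83, 81.35, 5)
        rec = compute_rcf(line_points(2223.2, 0.0, levels_s),
                          line_points(861.0, 0.0, levels_i))
        expected = 2223.2 / 861.0
        assert np.allclose(rec.per_level_rcf, expected)
        assert rec.mean_rcf == pytest.approx(expected, abs=1e-9)
        assert rec.mean_rcf == pytest.approx(2.582, abs=5e-4)

    def test_full_lines_near_published_values(self):
        # with intercepts over the calibrated ranges the mean RCF lands
        # within 2% (T) / 3% (U) of the published 2.56 / 1.74
        a = CALIBRATIONS["macrostemonoside_a"]
        ref = line_points(a["slope"], a["intercept"],
                          np.linspace(a["c_min"], a["c_max"], 5))
        t = CALIBRATIONS["macrostemonoside_t"]
        rec_t = compute_rcf(ref, line_points(
            t["slope"], t["intercept"],
            np.linspace(t["c_min"], t["c_max"], 5)))
        assert rec_t.mean_rcf == pytest.approx(2.56, rel=0.02)
        u = CALIBRATIONS["macrostemonoside_u"]
        rec_u = compute_rcf(ref, line_points(
            u["slope"], u["intercept"],
            np.linspace(u["c_min"], u["c_max"], 5)))
        assert rec_u.mean_rcf == pytest.approx(1.74, rel=0.03)

    def test_ratio_invariance_under_global_scaling(self):
        levels = [10.0, 20.0, 30.0, 40.0]
        ref = line_points(2000.0, -50.0, levels)
        ana = line_points(900.0, -30.0, levels)
        base = compute_rcf(ref, ana)
        scaled = compute_rcf([(c, 7.3 * a) for c, a in ref],
                             [(c, 7.3 * a) for c, a in ana])
        assert np.allclose(scaled.per_level_rcf, base.per_level_rcf)

    def test_mismatched_levels_rejected(self):
        with pytest.raises(ValidationError, match="mismatched"):
            compute_rcf(line_points(1.0, 0.0, [1, 2, 3]),
                        line_points(1.0, 0.0, [1, 2, 3, 4]))

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValidationError):
            compute_rcf(line_points(1.0, 0.0, [1, 2]),
                        line_points(1.0, 0.0, [1, 2]))

    def test_rrt_statistics(self):
        pts = line_points(1000.0, 0.0, [10.0, 20.0, 30.0])
        rec = compute_rcf(pts, pts, ref_times=[40.0, 40.0, 40.0],
                          analyte_times=[37.58, 37.57, 37.59])
        assert rec.mean_rrt == pytest.approx(37.58 / 40.0, abs=1e-3)
        assert rec.rrt_rsd < 0.1


def mk_peak(apex, area=100.0):
    return Peak(apex_time=apex, left_bound=apex - 0.1,
                right_bound=apex + 0.1, height=10.0, area=area, snr=50.0)


class TestLocatePeakByRrt:
    def test_reference_itself_rrt_one(self):
        ref = mk_peak(40.0)
        loc = locate_peak_by_rrt([ref], ref, expected_rrt=1.0)
        assert loc.rrt == pytest.approx(1.0)

    def test_picks_nearest_rrt_candidate(self):
        ref = mk_peak(40.0)
        candidates = [mk_peak(37.58), mk_peak(41.0)]
        loc = locate_peak_by_rrt(candidates, ref, expected_rrt=0.9394)
        assert loc.peak.apex_time == pytest.approx(37.58)
        assert loc.rrt == pytest.approx(0.9395, abs=1e-4)

    def test_tolerance_violation_raises(self):
        ref = mk_peak(40.0)
        candidates = [mk_peak(0.95 * 40.0)]
        with pytest.raises(NotLocatedError, match="nearest candidate"):
            locate_peak_by_rrt(candidates, ref, expected_rrt=0.9394,
                               tolerance=0.005)

    def test_empty_peak_list(self):
        with pytest.raises(NotLocatedError):
            locate_peak_by_rrt([], mk_peak(40.0), 1.0)


class TestQamsQuantify:
    def test_unity_rcf_equal_areas(self):
        res = qams_quantify(a_i=500.0, a_s=500.0, c_s=42.0, rcf=1.0)
        assert res.content == pytest.approx(42.0)

    def test_exact_round_trip_with_compute_rcf(self):
        # noiseless intercept-free responses: QAMS recovers C_i exactly
        levels_s = np.array([20.0, 30.0, 40.0, 50.0, 60.0])
        levels_i = np.array([25.0, 35.0, 45.0, 55.0, 65.0])
        slope_s, slope_i = 2223.2, 861.0
        rec = compute_rcf(line_points(slope_s, 0.0, levels_s),
                          line_points(slope_i, 0.0, levels_i))
        c_i, c_s = 47.3, 39.1
        res = qams_quantify(a_i=slope_i * c_i, a_s=slope_s * c_s, c_s=c_s,
                            rcf=rec.mean_rcf)
        assert res.content == pytest.approx(c_i, rel=1e-10)

    def test_end_to_end_agreement_with_esm(self):
        # full response lines with intercepts: QAMS and ESM agree within 1%
        a = CALIBRATIONS["macrostemonoside_a"]
        t = CALIBRATIONS["macrostemonoside_t"]
        rcf = compute_rcf(
            line_points(a["slope"], a["intercept"],
                        np.linspace(a["c_min"], a["c_max"], 5)),
            line_points(t["slope"], t["intercept"],
                        np.linspace(t["c_min"], t["c_max"], 5))).mean_rcf
        curve_a = CalibrationCurve("a", a["slope"], a["intercept"],
                                   a["r_squared"], a["c_min"], a["c_max"])
        curve_t = CalibrationCurve("t", t["slope"], t["intercept"],
                                   t["r_squared"], t["c_min"], t["c_max"])
        c_s_true, c_i_true = 46.9, 53.6
        a_s = curve_a.predict(c_s_true)
        a_i = curve_t.predict(c_i_true)
        esm = esm_quantify(a_i, curve_t).content
        qams = qams_quantify(a_i, a_s,
                             esm_quantify(a_s, curve_a).concentration,
                             rcf).content
        assert qams == pytest.approx(esm, rel=0.01)

    def test_missing_reference_area_rejected(self):
        with pytest.raises(ValidationError, match="A_s"):
            qams_quantify(a_i=10.0, a_s=0.0, c_s=1.0, rcf=1.0)


class TestRelativeDeviation:
    @pytest.mark.parametrize("esm,qams,expected", [
        (102.20, 101.73, -0.46),
        (79.35, 80.11, 0.96),
        (100.0, 100.0, 0.00),
    ])
    def test_examples(self, esm, qams, expected):
        assert relative_deviation(esm, qams) == pytest.approx(expected,
                                                              abs=1e-12)

    def test_zero_esm_rejected(self):
        with pytest.raises(ValidationError):
            relative_deviation(0.0, 10.0)

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(0.005, 2) == 0.01
        assert round_half_away(-0.005, 2) == -0.01
        assert round_half_away(1.005, 2) == 1.01


class TestDurability:
    @staticmethod
    def named(idx):
        return next(c for c in default_constituents() if c.id == idx)

    def test_retention_only_perturbation_rsd_zero(self):
        factors = {"column_temperature": [
            DurabilityCondition("25_C", rt_scale=1.02),
            DurabilityCondition("30_C", rt_scale=1.01),
            DurabilityCondition("35_C"),
        ]}
        res = durability_study(
            self.named("macrostemonoside_a"),
            [self.named("macrostemonoside_t")],
            factors=factors, area_noise_cv=0.0, seed=0)
        assert float(res.rsd.to_numpy().max()) == pytest.approx(0.0,
                                                                abs=1e-10)

    def test_global_bias_leaves_rcf_unchanged(self):
        factors = {"flow_rate": [
            DurabilityCondition("a", area_scale=1.05),
            DurabilityCondition("b", area_scale=1.0),
        ]}
        res = durability_study(
            self.named("macrostemonoside_a"),
            [self.named("macrostemonoside_t")],
            factors=factors, area_noise_cv=0.0, seed=0)
        assert float(res.rsd.to_numpy().max()) == pytest.approx(0.0,
                                                                abs=1e-10)

    def test_default_factors_below_bound_across_seeds(self):
        internal = self.named("macrostemonoside_a")
        analytes = [self.named("macrostemonoside_t"),
                    self.named("macrostemonoside_u")]
        below = 0
        for seed in range(10):
            res = durability_study(internal, analytes, area_noise_cv=0.01,
                                   seed=seed)
            below += float(res.rsd.to_numpy().max()) < 2.0
        assert below >= 9   # >= 95% nominal; allow one unlucky seed in ten

    def test_empty_factor_skipped_with_warning(self):
        factors = {"empty": [],
                   "flow_rate": [DurabilityCondition("a"),
                                 DurabilityCondition("b")]}
        with pytest.warns(UserWarning, match="empty"):
            res = durability_study(
                self.named("macrostemonoside_a"),
                [self.named("macrostemonoside_t")],
                factors=factors, area_noise_cv=0.0, seed=0)
        assert list(res.rsd.index) == ["flow_rate"]

    def test_verdicts_reported_per_factor(self):
        res = durability_study(
            self.named("macrostemonoside_a"),
            [self.named("macrostemonoside_t"),
             self.named("macrostemonoside_u")], seed=1)
        assert set(res.verdicts) == {"column", "flow_rate",
                                     "column_temperature",
                                     "injection_volume"}
        assert all(res.verdicts.values())


class TestValidationMetrics:
    def test_identical_replicates_zero_rsd(self):
        assert validation_metrics([100.0, 100.0, 100.0])["rsd"] == 0.0

    def test_known_rsd(self):
        # sd((98,100,102)) = 2, mean = 100 -> RSD 2.00 %
        out = validation_metrics([98.0, 100.0, 102.0])
        assert out["rsd"] == pytest.approx(2.0, abs=1e-12)

    def test_recovery_formula(self):
        out = validation_metrics([1.0, 1.0], base=50.0, spiked=50.0,
                                 measured_total=101.63)
        assert out["recovery"] == pytest.approx(103.26, abs=1e-10)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValidationError):
            validation_metrics([1.0, -1.0])

    def test_single_replicate_rejected(self):
        with pytest.raises(ValidationError):
            validation_metrics([1.0])
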