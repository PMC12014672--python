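"""Normalization, SSD fit, fit quality, and QC exclusion tests."""

import numpy as np
import pytest

import sigwash as sw
from sigwash.errors import (
    DegenerateBaselineError,
    InvalidInputError,
    UnderdeterminedFitError,
    UndefinedDeviationError,
)
from sigwash.fitting import MIN_POINTS, NormalizedTimeCourse
from sigwash.model import double_sigmoid


def make_timecourse(pwt, t_stim=60.0, pattern="tonic", times=None):
    pwt = np.asarray(pwt, float)
    if times is None:
        times = np.arange(0.0, 15.0 * len(pwt), 15.0)
    return sw.TimeCourse(animal_id="r1", pattern=pattern, cohort=1,
                         t_stim_min=t_stim, times=times, pwt=pwt)


def simulated_ntc(p, t_stim=90.0, noise_sd=0.0, rng=None):
    """Forward-simulate a normalized target directly from the model."""
    times = np.arange(0.0, t_stim + 30.0 + 1.0, 15.0)
    f = double_sigmoid(times, p)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=times.size)
    return NormalizedTimeCourse(times=times, f_target=f, baseline_pwt=6.0,
                                t_stim_min=t_stim)


class TestNormalization:
    def test_worked_example(self):
        tc = make_timecourse([6, 6, 12, 12, 12, 9, 6])
        ntc = sw.normalize_timecourse(tc)
        np.testing.assert_allclose(ntc.f_target, [0, 0, 1, 1, 1, 0.5, 0])
        assert ntc.f_target[0] == 0.0
        assert ntc.baseline_pwt == 6.0

    def test_group_mean_time_course(self):
        # group means of a tonic series normalize to ~0.22/0.90/0.85/0.98
        tc = make_timecourse([5.9, 7.2, 11.2, 10.9, 11.7, 9.0, 7.0])
        ntc = sw.normalize_timecourse(tc)
        np.testing.assert_allclose(
            ntc.f_target[:5], [0.0, 0.22034, 0.89831, 0.84746, 0.98305],
            atol=5e-6)

    def test_scale_invariance(self):
        base = [6, 6, 12, 12, 12, 9, 6]
        ref = sw.normalize_timecourse(make_timecourse(base)).f_target
        for c in (0.5, 2.0, 4.0):  # binary scalings: exactly invariant
            scaled = sw.normalize_timecourse(
                make_timecourse(np.asarray(base) * c)).f_target
            np.testing.assert_array_equal(scaled, ref)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            make_timecourse([0.0, 6, 12, 12, 12, 9, 6])  # PWT must be > 0
        tc_no_zero = sw.TimeCourse.__new__(sw.TimeCourse)  # bypass validation
        object.__setattr__(tc_no_zero, "times", np.array([15.0, 30.0, 45.0]))
        object.__setattr__(tc_no_zero, "pwt", np.array([6.0, 6.0, 6.0]))
        object.__setattr__(tc_no_zero, "t_stim_min", 60.0)
        with pytest.raises(InvalidInputError):
            sw.normalize_timecourse(tc_no_zero)


class TestInitialParams:
    @pytest.mark.parametrize("t_stim, t1, t2", [
        (60.0, 15.0, 75.0),
        (90.0, 22.5, 112.5),
        (120.0, 30.0, 150.0),
    ])
    def test_values(self, t_stim, t1, t2):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = sw.initial_params(t_stim)
        assert (p.I, p.a1, p.a2) == (1.0, 0.5, -0.5)
        assert (p.t_mid1, p.t_mid2) == (t1, t2)

    def test_nonstandard_duration_warns(self):
        with pytest.warns(UserWarning):
            sw.initial_params(45.0)

    def test_invalid_duration(self):
        with pytest.raises(InvalidInputError):
            sw.initial_params(-60.0)


class TestPercentDeviation:
    @pytest.mark.parametrize("fit, target, expected", [
        ([0, 1, 1], [0, 1, 1], 0.0),
        ([0, 1, 0], [0, 1, 1], 50.0),   # SSD=1, SSR=2
        ([0, 0, 0], [0, 1, 1], 100.0),  # null fit: deviance = signal power
    ])
    def test_examples(self, fit, target, expected):
        assert sw.percent_deviation(fit, target) == pytest.approx(expected)

    def test_all_zero_target_is_undefined(self):
        with pytest.raises(UndefinedDeviationError):
            sw.percent_deviation([0, 0, 0], [0, 0, 0])

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            sw.percent_deviation([0, 1], [0, 1, 1])


class TestFit:
    def test_noiseless_recovery(self):
        p_star = sw.SigmoidParams(I=1.2, a1=0.4, a2=-0.3, t_mid1=20, t_mid2=80)
        fr = sw.fit_double_sigmoid(simulated_ntc(p_star))
        rel = np.abs(fr.params.as_array() - p_star.as_array()) \
            / np.abs(p_star.as_array())
        assert np.max(rel) < 1e-3
        assert fr.dev_pct < 0.1
        assert fr.converged

    def test_flat_target_flagged_small_scale(self):
        ntc = NormalizedTimeCourse(times=np.arange(0, 121, 15.0),
                                   f_target=np.zeros(9), baseline_pwt=6.0,
                                   t_stim_min=90.0)
        fr = sw.fit_double_sigmoid(ntc)
        qc = sw.apply_exclusion(fr)
        assert abs(fr.params.I) < 0.1
        assert qc.excluded and (qc.small_scale or qc.negative_scale)

    def test_inverted_response_yields_negative_scale(self):
        # worsening thresholds: response runs opposite to the expected sign
        p_neg = sw.SigmoidParams(I=-0.5, a1=0.4, a2=-0.3, t_mid1=20, t_mid2=80)
        fr = sw.fit_double_sigmoid(simulated_ntc(p_neg))
        qc = sw.apply_exclusion(fr)
        assert fr.params.I < 0
        assert qc.excluded and qc.negative_scale

    def test_never_worse_than_initialization(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = sw.SigmoidParams(I=float(rng.uniform(0.3, 1.5)),
                                 a1=float(rng.uniform(0.1, 0.5)),
                                 a2=float(-rng.uniform(0.1, 0.5)),
                                 t_mid1=float(rng.uniform(10, 40)),
                                 t_mid2=float(rng.uniform(60, 110)))
            ntc = simulated_ntc(p, noise_sd=0.3, rng=rng)
            fr = sw.fit_double_sigmoid(ntc)
            init = sw.initial_params(90.0)
            ssd_init = float(np.sum(
                (double_sigmoid(ntc.times, init) - ntc.f_target) ** 2))
            assert fr.ssd <= ssd_init + 1e-12

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        p = sw.SigmoidParams(I=0.9, a1=0.2, a2=-0.2, t_mid1=25, t_mid2=100)
        ntc = simulated_ntc(p, noise_sd=0.2, rng=rng)
        a = sw.fit_double_sigmoid(ntc)
        b = sw.fit_double_sigmoid(ntc)
        np.testing.assert_array_equal(a.params.as_array(), b.params.as_array())
        assert a.ssd == b.ssd

    def test_underdetermined_grid_rejected(self):
        ntc = NormalizedTimeCourse(times=np.arange(0, 75, 15.0),
                                   f_target=np.zeros(5), baseline_pwt=6.0,
                                   t_stim_min=60.0)
        assert len(ntc.times) < MIN_POINTS
        with pytest.raises(UnderdeterminedFitError):
            sw.fit_double_sigmoid(ntc)

    def test_missing_interior_timepoint_still_fits(self):
        p = sw.SigmoidParams(I=1.0, a1=0.3, a2=-0.3, t_mid1=20, t_mid2=80)
        times = np.array([0.0, 15.0, 30.0, 60.0, 75.0, 90.0, 105.0, 120.0])
        ntc = NormalizedTimeCourse(times=times,
                                   f_target=double_sigmoid(times, p),
                                   baseline_pwt=6.0, t_stim_min=90.0)
        fr = sw.fit_double_sigmoid(ntc)
        assert fr.n_points == 8
        assert fr.dev_pct < 0.1

    def test_end_to_end_scale_invariance(self):
        """Rescaled raw PWT (binary factor) gives bit-identical fits."""
        rng = np.random.default_rng(9)
        p = sw.SigmoidParams(I=1.0, a1=0.3, a2=-0.25, t_mid1=20, t_mid2=85)
        base = 6.0 * (1.0 + double_sigmoid(np.arange(0, 121, 15.0), p)) \
            + rng.normal(0, 0.5, 9)
        tc1 = make_timecourse(base, t_stim=90.0)
        tc2 = make_timecourse(base * 2.0, t_stim=90.0)
        fr1, qc1 = sw.fit_timecourse(tc1)
        fr2, qc2 = sw.fit_timecourse(tc2)
        np.testing.assert_array_equal(fr1.params.as_array(),
                                      fr2.params.as_array())
        assert fr1.metrics == fr2.metrics
        assert qc1 == qc2


class TestExclusion:
    # inputs (dev_pct, I) spanning every reachable flag combination,
    # including both boundaries of the scale rule
    CASES = [
        (10.0, 1.00, dict(excluded=False, high_deviation=False,
                          small_scale=False, negative_scale=False)),
        (60.0, 1.00, dict(excluded=True, high_deviation=True,
                          small_scale=False, negative_scale=False)),
        (10.0, 0.05, dict(excluded=True, high_deviation=False,
                          small_scale=True, negative_scale=False)),
        (60.0, 0.05, dict(excluded=True, high_deviation=True,
                          small_scale=True, negative_scale=False)),
        (10.0, -0.5, dict(excluded=True, high_deviation=False,
                          small_scale=False, negative_scale=True)),
        (60.0, -0.5, dict(excluded=True, high_deviation=True,
                          small_scale=False, negative_scale=True)),
        (20.0, 0.00, dict(excluded=True, high_deviation=False,
                          small_scale=True, negative_scale=False)),
        (50.0, 0.10, dict(excluded=False, high_deviation=False,
                          small_scale=False, negative_scale=False)),
    ]

    @pytest.mark.parametrize("dev, i_hat, expected", CASES)
    def test_truth_table(self, dev, i_hat, expected):
        p = sw.SigmoidParams(I=i_hat, a1=0.5, a2=-0.5, t_mid1=15, t_mid2=75)
        fr = sw.FitResult(params=p, ssd=1.0, ssr=10.0, dev_pct=dev,
                          metrics=sw.temporal_metrics(p, 60.0),
                          converged=True, n_points=7, t_stim_min=60.0)
        qc = sw.apply_exclusion(fr)
        for field, value in expected.items():
            assert getattr(qc, field) == value, field

    def test_exclusion_iff_any_flag(self):
        for dev, i_hat, expected in self.CASES:
            flags = (expected["high_deviation"] or expected["small_scale"]
                     or expected["negative_scale"])
            assert expected["excluded"] == flags
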