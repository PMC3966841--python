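"""Decay-fit oracles, prediction intervals and treatment-window arithmetic."""

import math

import numpy as np
import pytest
from scipy import stats

from retnathist import natural_history as nh
from retnathist import synthdata as sd

SLOPE = math.log10(22.0 / 139.0) / 52.0  # through printed endpoints (31, 139), (83, 22)
INTERCEPT = math.log10(139.0) - SLOPE * 31.0


def cohort(scatter=0.0, seed=0, n_per_age=5, ages=None, floor=0.0):
    params = sd.ERGCohortParams(
        intercept_log=INTERCEPT, slope_log=SLOPE, scatter_sd=scatter,
        noise_floor=floor, ages=ages or list(range(31, 84, 4)),
        n_per_age=n_per_age, seed=seed,
    )
    return sd.gen_erg_cohort(params)


# ------------------------------------------------------------------- fit_decay


def test_fit_recovers_exact_line_noise_free():
    fit = nh.fit_decay(cohort(scatter=0.0))
    assert fit.slope == pytest.approx(SLOPE, abs=1e-9)
    assert fit.intercept == pytest.approx(INTERCEPT, abs=1e-7)
    assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)


def test_fit_two_point_slope_oracle():
    recs = [
        nh.ERGRecord("a", 31.0, "UV", 139.0),
        nh.ERGRecord("b", 83.0, "UV", 22.0),
        nh.ERGRecord("c", 31.0, "UV", 139.0),
        nh.ERGRecord("d", 83.0, "UV", 22.0),
    ]
    fit = nh.fit_decay(recs)
    # oracle: log10(22/139)/52 = -0.015396
    assert fit.slope == pytest.approx(-0.015396, abs=1e-6)


def test_fit_constant_amplitudes_zero_slope():
    recs = [nh.ERGRecord(f"m{i}", 20.0 + 10 * i, "UV", 55.0) for i in range(5)]
    assert nh.fit_decay(recs).slope == pytest.approx(0.0, abs=1e-12)


def test_fit_rejects_mixed_stimuli():
    recs = [
        nh.ERGRecord("a", 31.0, "UV", 100.0),
        nh.ERGRecord("b", 40.0, "M", 50.0),
        nh.ERGRecord("c", 50.0, "UV", 80.0),
    ]
    with pytest.raises(ValueError, match="stimuli"):
        nh.fit_decay(recs)


def test_fit_all_at_floor_errors():
    recs = [nh.ERGRecord(f"m{i}", 30.0 + i, "UV", 5.0) for i in range(4)]
    with pytest.raises(ValueError, match="floor"):
        nh.fit_decay(recs, noise_floor=5.0)


def test_floor_policies_differ():
    df = cohort(scatter=0.0, ages=[31, 51, 71, 91, 111], n_per_age=2)
    floor = 15.0
    drop = nh.fit_decay(df, floor_policy="drop", noise_floor=floor)
    censor = nh.fit_decay(df, floor_policy="censor-at-floor", noise_floor=floor)
    assert drop.n < censor.n
    assert censor.slope > drop.slope  # censoring flattens the tail


# -------------------------------------------------------------- percent_per_day


def test_percent_per_day_printed_rate():
    fit = nh.fit_decay(cohort())
    # 100*(1 - 10**-0.0153960) = 3.48 %/day (rounded to ~4%/day in prose)
    assert nh.percent_per_day(fit) == pytest.approx(3.48, abs=0.01)


def test_percent_per_day_zero_and_extreme():
    f0 = nh.DecayFit(0.0, 2.0, 0.0, 0.0, n=3)
    assert nh.percent_per_day(f0) == 0.0
    f1 = nh.DecayFit(-1.0, 2.0, 0.0, 0.0, n=3)
    assert nh.percent_per_day(f1) == pytest.approx(90.0)


# ------------------------------------------------------------ predict_amplitude


def test_predict_printed_p65_interval():
    # 1.4 log uV at P65 with constant +/-0.4 half-width -> (10.0, 25.1, 63.1) uV
    fit = nh.DecayFit(
        slope=SLOPE, intercept=1.4 - SLOPE * 65.0, residual_sd=0.2,
        pi95_halfwidth=0.4, n=95, age_mean=57.0, age_sxx=1e4, age_range=(31.0, 83.0),
    )
    mean, lo, hi = nh.predict_amplitude(fit, 65.0, mode="constant")
    assert mean == pytest.approx(25.1, abs=0.05)
    assert lo == pytest.approx(10.0, abs=0.05)
    assert hi == pytest.approx(63.1, abs=0.05)


def test_predict_zero_halfwidth_degenerate():
    fit = nh.DecayFit(SLOPE, INTERCEPT, 0.0, 0.0, n=10, age_mean=57.0,
                      age_sxx=1e4, age_range=(31.0, 83.0))
    mean, lo, hi = nh.predict_amplitude(fit, 50.0, mode="constant")
    assert lo == pytest.approx(mean)
    assert hi == pytest.approx(mean)


def test_predict_zero_slope_age_independent():
    fit = nh.DecayFit(0.0, 1.5, 0.1, 0.2, n=10, age_mean=50.0,
                      age_sxx=1e4, age_range=(30.0, 80.0))
    m1, *_ = nh.predict_amplitude(fit, 40.0)
    m2, *_ = nh.predict_amplitude(fit, 70.0)
    assert m1 == pytest.approx(m2)


def test_predict_monotone_decreasing_when_decaying():
    fit = nh.fit_decay(cohort(scatter=0.1, seed=3))
    ages = np.linspace(31, 83, 27)
    means = [nh.predict_amplitude(fit, a)[0] for a in ages]
    assert all(a > b for a, b in zip(means, means[1:]))


def test_predict_warns_on_extrapolation():
    fit = nh.fit_decay(cohort())
    with pytest.warns(UserWarning, match="outside the fitted range"):
        nh.predict_amplitude(fit, 200.0)


# ------------------------------------------------------------------ plan_window


def test_plan_window_printed_thresholds():
    # Expected untreated mean 1.4 log uV at P65, asym 0.3 -> 50.1 / 12.6 uV
    fit = nh.DecayFit(
        slope=SLOPE, intercept=1.4 - SLOPE * 65.0, residual_sd=0.2,
        pi95_halfwidth=0.4, n=95, age_mean=57.0, age_sxx=1e4, age_range=(31.0, 83.0),
    )
    window = nh.plan_window(fit, inject_age=37.0, assess_delay=28.0, asym_log=0.3)
    assert window.assess_age == 65.0
    assert window.expected_untreated_mean == pytest.approx(25.1, abs=0.05)
    assert window.efficacy_threshold == pytest.approx(50.1, abs=0.05)
    assert window.toxicity_threshold == pytest.approx(12.6, abs=0.05)


def test_plan_window_thresholds_collapse_as_asym_vanishes():
    fit = nh.fit_decay(cohort())
    w = nh.plan_window(fit, 37.0, 28.0, asym_log=1e-9)
    assert w.efficacy_threshold == pytest.approx(w.expected_untreated_mean, rel=1e-6)
    assert w.toxicity_threshold == pytest.approx(w.expected_untreated_mean, rel=1e-6)


def test_plan_window_doubling_asym_squares_ratio():
    fit = nh.fit_decay(cohort())
    w1 = nh.plan_window(fit, 37.0, 28.0, asym_log=0.3)
    w2 = nh.plan_window(fit, 37.0, 28.0, asym_log=0.6)
    r1 = w1.efficacy_threshold / w1.toxicity_threshold
    r2 = w2.efficacy_threshold / w2.toxicity_threshold
    assert r2 == pytest.approx(r1**2, rel=1e-9)


def test_plan_window_thresholds_symmetric_in_log():
    fit = nh.fit_decay(cohort(scatter=0.15, seed=9))
    w = nh.plan_window(fit, 37.0, 28.0, asym_log=0.3)
    assert w.efficacy_threshold * w.toxicity_threshold == pytest.approx(
        w.expected_untreated_mean**2, rel=1e-9
    )


def test_plan_window_too_late_warns():
    fit = nh.fit_decay(cohort())
    with pytest.warns(UserWarning, match="too late"):
        w = nh.plan_window(fit, 37.0, 28.0, noise_floor=1000.0)
    assert w.too_late


# --------------------------------------------------------- classify_interocular


@pytest.fixture
def window():
    fit = nh.DecayFit(
        slope=SLOPE, intercept=1.4 - SLOPE * 65.0, residual_sd=0.2,
        pi95_halfwidth=0.4, n=95, age_mean=57.0, age_sxx=1e4, age_range=(31.0, 83.0),
    )
    return nh.plan_window(fit, 37.0, 28.0, asym_log=0.3)


def test_classify_efficacy(window):
    assert nh.classify_interocular(60.0, 25.0, window) is nh.Outcome.EFFICACY


def test_classify_within(window):
    assert nh.classify_interocular(25.1, 25.0, window) is nh.Outcome.WITHIN_ASYMMETRY


def test_classify_toxicity(window):
    assert nh.classify_interocular(10.0, 25.0, window) is nh.Outcome.TOXICITY


def test_classify_rejects_nonpositive(window):
    with pytest.raises(ValueError):
        nh.classify_interocular(0.0, 25.0, window)


# --------------------------------------------------------------- property suites


def test_slope_ci_coverage_over_200_cohorts():
    hits = 0
    n_runs = 200
    for seed in range(n_runs):
        df = cohort(scatter=0.2, seed=seed, n_per_age=7, ages=list(range(31, 84, 4)))
        fit = nh.fit_decay(df)
        se = fit.residual_sd / math.sqrt(fit.age_sxx)
        tq = stats.t.ppf(0.975, fit.n - 2)
        if abs(fit.slope - SLOPE) <= tq * se:
            hits += 1
    assert hits / n_runs >= 0.90


def test_percent_per_day_roundtrip_noise_free():
    rate = 2.5  # % per day
    slope = math.log10(1 - rate / 100.0)
    params = sd.ERGCohortParams(
        intercept_log=2.5, slope_log=slope, scatter_sd=0.0, ages=[30, 40, 50, 60], n_per_age=2
    )
    fit = nh.fit_decay(sd.gen_erg_cohort(params))
    assert nh.percent_per_day(fit) == pytest.approx(rate, abs=1e-9)
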