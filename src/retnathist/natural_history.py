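"""Log-linear ERG amplitude decay fits and treatment-window planning.

Amplitudes decline exponentially with age, i.e. linearly on log-linear axes;
all logs are base 10.  The fit carries a 95% prediction interval used to set
interocular-difference thresholds for treatment efficacy and toxicity.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ERGRecord",
    "DecayFit",
    "TreatmentWindow",
    "Outcome",
    "fit_decay",
    "percent_per_day",
    "predict_amplitude",
    "plan_window",
    "classify_interocular",
]


@dataclass
class ERGRecord:
    animal_id: str
    age: float  # days
    stimulus: str  # "UV" or "M"
    amplitude: float  # uV
    genotype: str = ""

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.stimulus not in ("UV", "M"):
            raise ValueError(f"unknown stimulus {self.stimulus!r}")


@dataclass
class DecayFit:
    """OLS fit of log10(amplitude) on age."""

    slope: float  # log10 uV / day
    intercept: float  # log10 uV at age 0
    residual_sd: float  # log10 uV
    pi95_halfwidth: float  # log10 uV, at the design centre
    n: int
    stimulus: str = "UV"
    age_mean: float = 0.0
    age_sxx: float = 0.0  # sum of squared age deviations
    age_range: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("a decay fit needs n >= 3")
        if self.pi95_halfwidth < 0:
            raise ValueError("pi95_halfwidth must be >= 0")

    def log_mean_at(self, age: float) -> float:
        return self.intercept + self.slope * age


class Outcome(enum.Enum):
    EFFICACY = "efficacy"
    TOXICITY = "toxicity"
    WITHIN_ASYMMETRY = "within_asymmetry"


@dataclass
class TreatmentWindow:
    inject_age: float  # days
    assess_age: float  # days
    expected_untreated_mean: float  # uV
    efficacy_threshold: float  # uV
    toxicity_threshold: float  # uV
    asym_log: float  # log10 units
    too_late: bool = False  # expected mean at/below the noise floor

    def __post_init__(self) -> None:
        if not (self.toxicity_threshold < self.expected_untreated_mean < self.efficacy_threshold):
            raise ValueError("thresholds must bracket the expected untreated mean")


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.rename(
            columns={"age_days": "age", "amplitude_uV": "amplitude"}, errors="ignore"
        )
        return df[["age", "stimulus", "amplitude"]].copy()
    return pd.DataFrame(
        [(r.age, r.stimulus, r.amplitude) for r in records],
        columns=["age", "stimulus", "amplitude"],
    )


def fit_decay(
    records,
    floor_policy: str = "drop",
    noise_floor: float = 0.0,
) -> DecayFit:
    """Fit log10(amplitude) = intercept + slope * age by OLS.

    ``records`` is a sequence of :class:`ERGRecord` or a tidy DataFrame with
    columns ``age_days``/``age``, ``stimulus``, ``amplitude_uV``/``amplitude``
    holding a single stimulus.  ``floor_policy`` handles records at or below
    ``noise_floor``: ``"drop"`` removes them before fitting,
    ``"censor-at-floor"`` keeps them clamped at the floor value.

    The 95% prediction-interval half-width is the t-quantile times the
    prediction SE for a new observation at the design centre.
    """
    df = _records_frame(records)
    stimuli = df["stimulus"].unique()
    if len(stimuli) != 1:
        raise ValueError(f"records mix stimuli {sorted(stimuli)}; fit one at a time")
    if floor_policy not in ("drop", "censor-at-floor"):
        raise ValueError(f"unknown floor_policy {floor_policy!r}")
    amp = df["amplitude"].to_numpy(dtype=float)
    age = df["age"].to_numpy(dtype=float)
    at_floor = amp <= noise_floor
    if floor_policy == "drop":
        keep = ~at_floor & (amp > 0)
        amp, age = amp[keep], age[keep]
    else:
        if noise_floor <= 0 and np.any(amp <= 0):
            raise ValueError("cannot censor at a non-positive floor")
        amp = np.maximum(amp, noise_floor)
    if amp.size < 3:
        raise ValueError("fewer than 3 records above the noise floor")
    y = np.log10(amp)
    n = y.size
    xbar = age.mean()
    sxx = float(((age - xbar) ** 2).sum())
    if sxx == 0:
        raise ValueError("all records share one age; slope undefined")
    slope = float(((age - xbar) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * xbar)
    resid = y - (intercept + slope * age)
    dof = n - 2
    s = float(np.sqrt((resid**2).sum() / dof))
    tq = float(stats.t.ppf(0.975, dof))
    halfwidth = tq * s * float(np.sqrt(1.0 + 1.0 / n))
    return DecayFit(
        slope=slope,
        intercept=intercept,
        residual_sd=s,
        pi95_halfwidth=halfwidth,
        n=n,
        stimulus=str(stimuli[0]),
        age_mean=float(xbar),
        age_sxx=sxx,
        age_range=(float(age.min()), float(age.max())),
    )


def percent_per_day(fit: DecayFit) -> float:
    """Daily fractional amplitude loss, 100 * (1 - 10**slope)."""
    if fit.slope > 0:
        raise ValueError("percent_per_day is defined for non-positive slopes")
    return 100.0 * (1.0 - 10.0**fit.slope)


def predict_amplitude(fit: DecayFit, age: float, mode: str = "exact") -> tuple:
    """Predicted mean amplitude and 95% prediction interval at ``age`` (uV).

    ``mode="exact"`` uses the age-dependent prediction SE; ``"constant"``
    applies the design-centre half-width at every age.  Extrapolating more
    than 20% beyond the fitted age range warns.
    """
    lo_age, hi_age = fit.age_range
    span = max(hi_age - lo_age, 1e-12)
    if age < lo_age - 0.2 * span or age > hi_age + 0.2 * span:
        warnings.warn(
            f"age {age} is far outside the fitted range {fit.age_range}", stacklevel=2
        )
    log_mean = fit.log_mean_at(age)
    if mode == "constant":
        hw = fit.pi95_halfwidth
    elif mode == "exact":
        dof = fit.n - 2
        tq = float(stats.t.ppf(0.975, dof))
        se = fit.residual_sd * np.sqrt(1.0 + 1.0 / fit.n + (age - fit.age_mean) ** 2 / fit.age_sxx)
        hw = tq * float(se)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return 10.0**log_mean, 10.0 ** (log_mean - hw), 10.0 ** (log_mean + hw)


def plan_window(
    fit: DecayFit,
    inject_age: float,
    assess_delay: float,
    asym_log: float = 0.3,
    noise_floor: float = 0.0,
) -> TreatmentWindow:
    """Derive the uniocular treatment plan from the natural-history fit.

    Assessment happens ``assess_delay`` days after injection; the untreated
    eye is expected at the fitted mean for that age, and the interocular
    asymmetry bound ``asym_log`` (log10 units) sets the efficacy (above) and
    toxicity (below) thresholds.
    """
    if asym_log <= 0:
        raise ValueError("asym_log must be positive")
    assess_age = inject_age + assess_delay
    mean, _, _ = predict_amplitude(fit, assess_age)
    log_mean = np.log10(mean)
    window = TreatmentWindow(
        inject_age=inject_age,
        assess_age=assess_age,
        expected_untreated_mean=float(mean),
        efficacy_threshold=float(10.0 ** (log_mean + asym_log)),
        toxicity_threshold=float(10.0 ** (log_mean - asym_log)),
        asym_log=asym_log,
        too_late=bool(mean <= noise_floor),
    )
    if window.too_late:
        warnings.warn(
            f"expected untreated mean {mean:.1f} uV is at/below the noise floor; "
            "assessment window is too late",
            stacklevel=2,
        )
    return window


def classify_interocular(treated: float, untreated: float, window: TreatmentWindow) -> Outcome:
    """Classify the treated eye against the interocular-asymmetry thresholds."""
    if treated <= 0 or untreated <= 0:
        raise ValueError("amplitudes must be positive")
    if treated > window.efficacy_threshold:
        return Outcome.EFFICACY
    if treated < window.toxicity_threshold:
        return Outcome.TOXICITY
    return Outcome.WITHIN_ASYMMETRY
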