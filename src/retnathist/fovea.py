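"""Foveal-island structural metrics and structure-function regressions.

Two scalar parameters summarise a foveal ONL thickness profile: the 5-sample
average over the foveal pit and +/-0.15, +/-0.3 mm eccentricity, and the
width of the central island at half-maximum ONL.  Regression utilities test
whether a fitted slope differs from zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FovealProfile",
    "PatientRecord",
    "IslandWidth",
    "RegressionResult",
    "foveal_onl_average",
    "island_width_half_max",
    "normal_limits",
    "regression_with_slope_test",
    "ACUITY_CODES",
]

#: Ordinal plotting codes for off-scale acuity categories (beyond logMAR).
#: For plotting/binning only; never fed to regressions unless explicitly asked.
ACUITY_CODES = {"HM": 2.3, "LP": 2.6, "NLP": 2.9}

#: Eccentricities (mm) of the 5 samples entering the foveal ONL average.
FOVEAL_SAMPLE_ECC = (-0.30, -0.15, 0.0, 0.15, 0.30)


@dataclass
class FovealProfile:
    """ONL thickness (um) versus signed eccentricity (mm) along one meridian."""

    eccentricity: np.ndarray
    onl: np.ndarray
    meridian: str = "horizontal"

    def __post_init__(self) -> None:
        self.eccentricity = np.asarray(self.eccentricity, dtype=float)
        self.onl = np.asarray(self.onl, dtype=float)
        if self.eccentricity.shape != self.onl.shape or self.eccentricity.ndim != 1:
            raise ValueError("eccentricity and onl must be matching 1-D arrays")
        if np.any(np.diff(self.eccentricity) <= 0):
            raise ValueError("eccentricities must be strictly increasing")
        if np.any(self.onl < 0):
            raise ValueError("ONL thickness must be >= 0")
        if self.meridian not in ("horizontal", "vertical"):
            raise ValueError(f"unknown meridian {self.meridian!r}")


@dataclass
class PatientRecord:
    id: str
    age: float  # years
    acuity: float  # logMAR, off-scale categories per ACUITY_CODES
    foveal_onl: float  # um
    island_width: Optional[float] = None  # mm; None when undefined

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.foveal_onl < 0:
            raise ValueError("foveal_onl must be >= 0")
        if self.island_width is not None and self.island_width < 0:
            raise ValueError("island_width must be >= 0 or undefined")


class IslandWidth(NamedTuple):
    width_mm: float  # nan when undefined
    defined: bool


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    p_slope: float


def foveal_onl_average(profile: FovealProfile) -> float:
    """Mean ONL over the foveal pit and two samples each side (0.15, 0.3 mm).

    Off-grid eccentricities are obtained by linear interpolation.  Raises if
    the profile does not cover +/-0.3 mm.
    """
    x, y = profile.eccentricity, profile.onl
    if x[0] > -0.30 or x[-1] < 0.30:
        raise ValueError(
            f"profile covers [{x[0]:.2f}, {x[-1]:.2f}] mm; +/-0.3 mm required"
        )
    samples = np.interp(FOVEAL_SAMPLE_ECC, x, y)
    return float(samples.mean())


def island_width_half_max(profile: FovealProfile) -> IslandWidth:
    """Retinal distance between the two outermost half-maximum crossings.

    The half level is half of the profile's global maximum.  On each side of
    the peak the *outermost* crossing is used (satellite bumps do not shrink
    the island), located by linear interpolation between grid points.  When
    either side never falls below the half level the width is undefined and
    flagged (mirrors profiles with no delimitable island).
    """
    x, y = profile.eccentricity, profile.onl
    peak = float(y.max())
    if peak <= 0:
        return IslandWidth(float("nan"), False)
    half = peak / 2.0
    ipk = int(np.argmax(y))

    def outermost(side: str) -> float:
        if side == "right":
            xs, ys = x[ipk:], y[ipk:]
        else:
            xs, ys = x[: ipk + 1][::-1], y[: ipk + 1][::-1]
        below = ys < half
        if not below.any():
            return float("nan")
        # outermost crossing = last index (from the peak outward) where the
        # profile passes from >= half to < half
        idx = np.nonzero((ys[:-1] >= half) & (ys[1:] < half))[0]
        if idx.size == 0:
            return float("nan")
        i = idx[-1]
        frac = (ys[i] - half) / (ys[i] - ys[i + 1])
        return float(xs[i] + frac * (xs[i + 1] - xs[i]))

    right = outermost("right")
    left = outermost("left")
    if np.isnan(right) or np.isnan(left):
        return IslandWidth(float("nan"), False)
    return IslandWidth(abs(right - left), True)


def normal_limits(mean: float, sd: float) -> float:
    """Lower limit of normal: mean - 2*SD."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return mean - 2.0 * sd


def regression_with_slope_test(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS of y on x with a two-sided t-test of slope = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_slope=float(res.pvalue),
    )
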