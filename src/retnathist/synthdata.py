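"""Synthetic OCT volumes, ERG cohorts and foveal profiles with known ground truth.

The OCT phantom renders a layered retina as a sum of Gaussian reflectivity
bands along each A-scan.  The three outer bands (OPL peak, S+ band, RPE peak)
are given equal reflectivity and width so that the two signal troughs that
bound the photoreceptor (ONL+) lamina fall exactly midway between adjacent
band centres; the configured ONL+ and total thicknesses are therefore exact
ground truth, independent of the pixel grid.

Pseudorosettes are hyperreflective ellipsoidal inclusions placed laterally by
a per-sector point process with a minimum-separation constraint, rendered as
a compact axial bump inside the ONL+ lamina so they read as an extra
prominent peak in affected LRPs and as bright spots in integrated en-face
maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from retnathist.core import DEFAULT_ORIENTATION, OCTVolume
from retnathist.fovea import FovealProfile

__all__ = [
    "BandSpec",
    "OCTPhantomParams",
    "OCTGroundTruth",
    "ERGCohortParams",
    "FovealPhantomParams",
    "FovealPhantom",
    "RosettePlacementError",
    "gen_oct_volume",
    "gen_erg_cohort",
    "gen_foveal_profile",
    "default_bands",
]

SECTORS = ("superior", "inferior", "nasal", "temporal")

#: Fraction of the ONL+ lamina (sclerad of its vitreal trough) where the
#: rosette axial centre sits; offset from the S+ band so the rosette forms a
#: separate resolvable peak.
ROSETTE_AXIAL_FRAC = 0.30


class RosettePlacementError(RuntimeError):
    """Raised when non-overlapping rosette placement fails after bounded retries."""


@dataclass(frozen=True)
class BandSpec:
    """One reflectivity band: centre depth is relative to the retina top."""

    name: str
    depth_um: float
    reflectivity: float
    width_um: float


def default_bands(onl_plus_um: float = 65.0, total_um: float = 197.4) -> tuple:
    """Band template for the given mean geometry.

    Depths are measured from the vitreoretinal interface.  The OPL, S+ and
    RPE bands share reflectivity and width so inter-band troughs are exact
    midpoints; the choroidal band sclerad of the RPE makes the RPE the
    second hyperreflective band from the scleral side.
    """
    return (
        BandSpec("vitreoretinal_interface", 0.0, 1.0, 7.0),
        BandSpec("inner_band", 32.0, 0.7, 7.0),
        BandSpec("opl_peak", total_um - 2.0 * onl_plus_um, 0.9, 7.0),
        BandSpec("s_plus", total_um - onl_plus_um, 0.9, 7.0),
        BandSpec("rpe_peak", total_um, 0.9, 7.0),
        BandSpec("choroid", total_um + 40.0, 0.75, 9.0),
    )


@dataclass(frozen=True)
class OCTPhantomParams:
    """Geometry, optics and pathology of one synthetic eye."""

    n_bscans: int = 8
    n_lrps_per_bscan: int = 200
    axial_px: int = 512
    axial_scale: float = 1.6  # um / pixel
    lateral_scale: float = 0.0075  # mm / pixel within a B-scan
    bscan_spacing: float = 0.0075  # mm between B-scans
    field_diameter: float = 1.5  # mm
    scan_axis: str = "vertical"
    repeats: int = 1
    layer_depths: tuple = ()  # BandSpec template; default derived from thickness
    onl_thickness_mean: float = 65.0
    onl_thickness_sd: float = 0.0
    total_thickness_mean: float = 197.4
    total_thickness_sd: float = 0.0
    top_offset_um: float = 120.0  # depth of the vitreoretinal interface
    rpe_curvature_amplitude: float = 0.0  # um
    rosette_density_by_sector: Mapping[str, float] = field(default_factory=dict)
    rosette_count_by_sector: Mapping[str, int] = field(default_factory=dict)
    rosette_radius: float = 0.025  # mm (lateral exclusion radius)
    rosette_reflectivity: float = 1.5
    rosette_axial_sigma: float = 7.0  # um
    noise_sd: float = 0.0
    seed: int = 0

    def bands(self) -> tuple:
        if self.layer_depths:
            return tuple(self.layer_depths)
        return default_bands(self.onl_thickness_mean, self.total_thickness_mean)

    def validate(self) -> None:
        if min(self.n_bscans, self.n_lrps_per_bscan, self.axial_px, self.repeats) < 1:
            raise ValueError("counts must be >= 1")
        if min(self.axial_scale, self.lateral_scale, self.field_diameter) <= 0:
            raise ValueError("scales and field diameter must be positive")
        if self.onl_thickness_sd < 0 or self.total_thickness_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.scan_axis not in ("vertical", "horizontal"):
            raise ValueError(f"unknown scan_axis {self.scan_axis!r}")
        bands = self.bands()
        depths = [b.depth_um for b in bands]
        if any(b >= a for a, b in zip(depths[1:], depths)) is False and depths != sorted(depths):
            raise ValueError("band depths must strictly increase vitreal to sclerad")
        if any(d2 <= d1 for d1, d2 in zip(depths, depths[1:])):
            raise ValueError("band depths must strictly increase vitreal to sclerad")
        for d in dict(self.rosette_density_by_sector).values():
            if d < 0:
                raise ValueError("rosette densities must be >= 0")
        for c in dict(self.rosette_count_by_sector).values():
            if c < 0:
                raise ValueError("rosette counts must be >= 0")
        deepest = self.top_offset_um + self.rpe_curvature_amplitude + depths[-1] + 3 * bands[-1].width_um
        if deepest >= self.axial_px * self.axial_scale:
            raise ValueError(
                f"axial range {self.axial_px * self.axial_scale:.0f} um too shallow "
                f"for deepest band at {deepest:.0f} um"
            )


@dataclass
class OCTGroundTruth:
    """Exact per-A-scan geometry of a rendered phantom (all maps in um)."""

    onl_plus_map: np.ndarray  # (n_bscans, n_ascans)
    total_thickness_map: np.ndarray
    rpe_depth_map: np.ndarray  # depth of the RPE band centre from the volume top
    rosette_centroids: list  # of (x_mm, y_mm, sector)

    def __post_init__(self) -> None:
        if np.any(self.onl_plus_map > self.total_thickness_map):
            raise ValueError("onl_plus_map must be <= total_thickness_map everywhere")


def _sector_of(x: float, y: float) -> str:
    """Quadrant sector of a point; +y superior, +x nasal."""
    ang = math.degrees(math.atan2(y, x)) % 360.0
    if 45.0 <= ang < 135.0:
        return "superior"
    if 135.0 <= ang < 225.0:
        return "temporal"
    if 225.0 <= ang < 315.0:
        return "inferior"
    return "nasal"


def _in_sector(x: np.ndarray, y: np.ndarray, sector: str) -> np.ndarray:
    if sector == "all":
        return np.ones_like(x, dtype=bool)
    if sector == "superior":
        return y > 0
    if sector == "inferior":
        return y < 0
    if sector == "nasal":
        return x > 0
    if sector == "temporal":
        return x < 0
    raise ValueError(f"unknown sector {sector!r}")


def _place_rosettes(params: OCTPhantomParams, rng: np.random.Generator) -> list:
    """Sample non-overlapping rosette centres; returns [(x_mm, y_mm, sector)].

    Counts per sector come from ``rosette_count_by_sector`` when given,
    otherwise Poisson draws from ``rosette_density_by_sector`` (per mm^2 of
    hemifield/quadrant area).  Pairs closer than twice the rosette radius are
    rejected, bounded at 1000 retries per rosette.
    """
    radius = params.field_diameter / 2.0
    requested: list = []
    counts = dict(params.rosette_count_by_sector)
    if counts:
        requested = sorted(counts.items())
    else:
        dens = dict(params.rosette_density_by_sector)
        for sector in sorted(dens):
            frac = 1.0 if sector == "all" else (0.5 if sector in ("superior", "inferior", "nasal", "temporal") else None)
            if frac is None:
                raise ValueError(f"unknown sector {sector!r}")
            area = frac * math.pi * radius**2
            requested.append((sector, int(rng.poisson(dens[sector] * area))))
    placed_x: list = []
    placed_y: list = []
    out: list = []
    min_sep = 2.0 * params.rosette_radius
    for sector, n in requested:
        for _ in range(int(n)):
            for _attempt in range(1000):
                r = radius * math.sqrt(rng.uniform())
                th = rng.uniform(0.0, 2.0 * math.pi)
                x, y = r * math.cos(th), r * math.sin(th)
                if not _in_sector(np.array(x), np.array(y), sector):
                    continue
                if r < 0.09 + params.rosette_radius:  # keep clear of the ONH disk
                    continue
                if r > radius - params.rosette_radius:
                    continue
                if placed_x:
                    d2 = (np.array(placed_x) - x) ** 2 + (np.array(placed_y) - y) ** 2
                    if d2.min() < min_sep**2:
                        continue
                placed_x.append(x)
                placed_y.append(y)
                out.append((x, y, sector if sector != "all" else _sector_of(x, y)))
                break
            else:
                raise RosettePlacementError(
                    f"could not place rosette {len(out) + 1} in sector {sector!r} "
                    f"after 1000 retries (density too high for non-overlap)"
                )
    return out


def _lateral_grids(params: OCTPhantomParams):
    """(x_mm, y_mm) arrays of shape (n_bscans, n_ascans); +x nasal, +y superior."""
    a = np.arange(params.n_lrps_per_bscan) - (params.n_lrps_per_bscan - 1) / 2.0
    b = np.arange(params.n_bscans) - (params.n_bscans - 1) / 2.0
    a_mm = a * params.lateral_scale
    b_mm = b * params.bscan_spacing
    if params.scan_axis == "horizontal":
        x = np.broadcast_to(a_mm[None, :], (params.n_bscans, params.n_lrps_per_bscan))
        y = np.broadcast_to(b_mm[:, None], x.shape)
    else:  # vertical: A-scan axis runs inferior -> superior
        y = np.broadcast_to(a_mm[None, :], (params.n_bscans, params.n_lrps_per_bscan))
        x = np.broadcast_to(b_mm[:, None], y.shape)
    return np.ascontiguousarray(x), np.ascontiguousarray(y)


def gen_oct_volume(params: OCTPhantomParams) -> tuple:
    """Render one synthetic eye; returns ``(OCTVolume, OCTGroundTruth)``.

    Deterministic for a fixed ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    # Per-eye thickness draws.  The total draw is floored so the inner
    # retina keeps room for the inner band (avoids band collisions).
    onl = params.onl_thickness_mean + params.onl_thickness_sd * rng.standard_normal()
    total = params.total_thickness_mean + params.total_thickness_sd * rng.standard_normal()
    onl = max(onl, 10.0)
    total = max(total, 2.0 * onl + 50.0)

    bands = default_bands(onl, total) if not params.layer_depths else params.bands()

    x_mm, y_mm = _lateral_grids(params)
    # Smooth curvature field shifts the whole retina axially.
    curv = params.rpe_curvature_amplitude * np.sin(2.0 * np.pi * x_mm / 1.9) * np.cos(
        2.0 * np.pi * y_mm / 2.3
    )

    rosettes = _place_rosettes(params, rng)
    # Depth (from retina top) of the rosette centre, inside the ONL+ lamina.
    t1_rel = total - 1.5 * onl  # trough sclerad of the OPL peak
    rosette_depth_rel = t1_rel + ROSETTE_AXIAL_FRAC * onl
    rosette_lat_sigma = params.rosette_radius / 2.0  # mm

    z = np.arange(params.axial_px) * params.axial_scale  # um
    n_frames = params.n_bscans * params.repeats
    data = np.empty((n_frames, params.n_lrps_per_bscan, params.axial_px), dtype=np.float32)

    rx = np.array([r[0] for r in rosettes])
    ry = np.array([r[1] for r in rosettes])

    for b in range(params.n_bscans):
        top = params.top_offset_um + curv[b]  # (n_ascans,)
        clean = np.zeros((params.n_lrps_per_bscan, params.axial_px), dtype=np.float64)
        for band in bands:
            centre = top + band.depth_um
            clean += band.reflectivity * np.exp(
                -0.5 * ((z[None, :] - centre[:, None]) / band.width_um) ** 2
            )
        if len(rosettes):
            d2 = (x_mm[b][:, None] - rx[None, :]) ** 2 + (y_mm[b][:, None] - ry[None, :]) ** 2
            near = d2 < (3.0 * rosette_lat_sigma) ** 2
            for j in np.nonzero(near.any(axis=1))[0]:
                ks = np.nonzero(near[j])[0]
                amp = params.rosette_reflectivity * np.exp(
                    -0.5 * d2[j, ks] / rosette_lat_sigma**2
                )
                zc = top[j] + rosette_depth_rel
                clean[j] += amp.sum() * np.exp(
                    -0.5 * ((z - zc) / params.rosette_axial_sigma) ** 2
                )
        for rep in range(params.repeats):
            frame = clean
            if params.noise_sd > 0:
                frame = clean + params.noise_sd * rng.standard_normal(clean.shape)
            data[b * params.repeats + rep] = frame.astype(np.float32)

    onh = ((params.n_bscans - 1) / 2.0, (params.n_lrps_per_bscan - 1) / 2.0)
    volume = OCTVolume(
        data=data,
        axial_scale=params.axial_scale,
        lateral_scale=params.lateral_scale,
        bscan_spacing=params.bscan_spacing,
        scan_axis=params.scan_axis,
        onh_center=onh,
        repeats=params.repeats,
        orientation=dict(DEFAULT_ORIENTATION),
        meta={"seed": params.seed, "generator": "gen_oct_volume"},
    )
    shape2 = (params.n_bscans, params.n_lrps_per_bscan)
    truth = OCTGroundTruth(
        onl_plus_map=np.full(shape2, onl),
        total_thickness_map=np.full(shape2, total),
        rpe_depth_map=params.top_offset_um + curv + total,
        rosette_centroids=rosettes,
    )
    return volume, truth


# --------------------------------------------------------------------------- #
# ERG cohorts
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ERGCohortParams:
    """Log-linear amplitude decay with log-normal inter-animal scatter."""

    intercept_log: float  # log10 uV at age 0
    slope_log: float  # log10 uV per day, <= 0 for decay
    scatter_sd: float = 0.0  # log10 uV
    noise_floor: float = 0.0  # uV
    ages: Sequence[float] = ()
    n_per_age: int = 1
    stimulus: str = "UV"
    #: draw the per-animal scatter by shuffled stratified quantiles within each
    #: age group (marginally still N(0, scatter_sd^2); cohort-level draw noise
    #: is strongly reduced, useful for recovery benchmarks)
    stratified_scatter: bool = False
    seed: int = 0

    def validate(self) -> None:
        if len(self.ages) == 0:
            raise ValueError("ages must be non-empty")
        if self.slope_log > 0:
            raise ValueError("slope_log must be <= 0 for a decay")
        if self.scatter_sd < 0 or self.noise_floor < 0:
            raise ValueError("scatter_sd and noise_floor must be >= 0")
        if self.n_per_age < 1:
            raise ValueError("n_per_age must be >= 1")


def gen_erg_cohort(params: ERGCohortParams) -> pd.DataFrame:
    """Simulate b-wave amplitudes; returns a tidy table.

    amplitude = max(noise_floor, 10**(intercept + slope*age + eps)),
    eps ~ N(0, scatter_sd^2) per animal.

    Columns: ``animal_id, age_days, stimulus, amplitude_uV``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    from scipy.special import ndtri  # local import keeps module load light

    rows = []
    k = 0
    for age in params.ages:
        n = params.n_per_age
        if params.scatter_sd == 0:
            eps = np.zeros(n)
        elif params.stratified_scatter:
            eps = params.scatter_sd * ndtri((rng.permutation(n) + rng.uniform(size=n)) / n)
        else:
            eps = params.scatter_sd * rng.standard_normal(n)
        for j in range(n):
            k += 1
            amp = 10.0 ** (params.intercept_log + params.slope_log * age + eps[j])
            rows.append((f"m{k:04d}", float(age), params.stimulus, max(params.noise_floor, amp)))
    return pd.DataFrame(rows, columns=["animal_id", "age_days", "stimulus", "amplitude_uV"])


# --------------------------------------------------------------------------- #
# Human foveal profiles
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class FovealPhantomParams:
    """A central ONL island on a flat baseline, sampled along one meridian."""

    peak_onl: float = 100.0  # um at eccentricity 0
    island_shape: str = "gaussian"  # gaussian | triangular | table
    shape_scale: float = 0.2  # mm: sigma (gaussian) or half-base (triangular)
    baseline_onl: float = 0.0  # um; 0 for LCA-like, > 0 for normal-like
    sample_spacing: float = 0.05  # mm
    extent: float = 1.5  # mm each side of the fovea
    noise_sd: float = 0.0  # um
    meridian: str = "horizontal"
    table_values: Optional[Sequence[float]] = None  # for island_shape="table"
    seed: int = 0

    def validate(self) -> None:
        if self.peak_onl < 0 or self.baseline_onl < 0:
            raise ValueError("peak and baseline ONL must be >= 0")
        if self.extent <= 0 or self.sample_spacing <= 0:
            raise ValueError("extent and sample_spacing must be positive")
        if self.island_shape not in ("gaussian", "triangular", "table"):
            raise ValueError(f"unknown island_shape {self.island_shape!r}")
        if self.island_shape == "table" and self.table_values is None:
            raise ValueError("table shape requires table_values")


@dataclass
class FovealPhantom:
    profile: FovealProfile
    true_half_max_width: float  # mm; nan when undefined (no half-max crossing)
    params: FovealPhantomParams


def _island_values(p: FovealPhantomParams, x: np.ndarray) -> np.ndarray:
    h = p.peak_onl - p.baseline_onl
    if p.island_shape == "gaussian":
        return p.baseline_onl + h * np.exp(-0.5 * (x / p.shape_scale) ** 2)
    if p.island_shape == "triangular":
        return p.baseline_onl + h * np.clip(1.0 - np.abs(x) / p.shape_scale, 0.0, None)
    vals = np.asarray(p.table_values, dtype=float)
    if vals.size != x.size:
        raise ValueError(f"table_values length {vals.size} != grid length {x.size}")
    return vals


def _analytic_width(p: FovealPhantomParams, x: np.ndarray, vals: np.ndarray) -> float:
    peak = float(vals.max())
    half = peak / 2.0
    if peak <= 0 or p.island_shape != "table" and p.baseline_onl >= half:
        return float("nan")
    h = p.peak_onl - p.baseline_onl
    if p.island_shape == "gaussian":
        if h <= 0:
            return float("nan")
        return 2.0 * p.shape_scale * math.sqrt(2.0 * math.log(h / (half - p.baseline_onl)))
    if p.island_shape == "triangular":
        if h <= 0:
            return float("nan")
        return 2.0 * p.shape_scale * (1.0 - (half - p.baseline_onl) / h)
    # table: numeric outermost half-max crossings on a dense linear interpolant
    xf = np.linspace(x[0], x[-1], 20001)
    vf = np.interp(xf, x, vals)
    above = vf >= half
    if not above.any() or above.all():
        return float("nan")
    lo = np.argmax(above)
    hi = len(above) - 1 - np.argmax(above[::-1])
    if lo == 0 or hi == len(above) - 1:
        return float("nan")
    return float(xf[hi] - xf[lo])


def gen_foveal_profile(params: FovealPhantomParams) -> FovealPhantom:
    """Sample a foveal ONL thickness profile on a symmetric grid about 0."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(math.floor(params.extent / params.sample_spacing + 1e-9))
    x = params.sample_spacing * np.arange(-n, n + 1, dtype=float)
    vals = _island_values(params, x)
    width = _analytic_width(params, x, vals)
    if params.noise_sd > 0:
        vals = vals + params.noise_sd * rng.standard_normal(vals.shape)
    vals = np.clip(vals, 0.0, None)
    profile = FovealProfile(eccentricity=x, onl=vals, meridian=params.meridian)
    return FovealPhantom(profile=profile, true_half_max_width=width, params=params)


def cohort_phantoms(base: OCTPhantomParams, n_eyes: int, seed: int) -> list:
    """Independent per-eye phantoms sharing ``base`` with derived seeds."""
    seeds = np.random.SeedSequence(seed).generate_state(n_eyes)
    return [replace(base, seed=int(s)) for s in seeds]
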