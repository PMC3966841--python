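"""Reference cohort designs for end-to-end validation studies.

These functions wire the full pipeline (simulate -> flatten -> segment ->
exclude -> summarise, and simulate -> integrate -> detect -> sector-count)
into the cohort designs used for benchmarking: a young and an old
thickness cohort, a spot-count cohort, and an ERG decay cohort.

Per-eye parameters are drawn by stratified (quantile-balanced) sampling from
the configured normal distributions: marginally each eye still follows
N(mean, sd), but the Monte-Carlo error of the cohort mean is strongly
reduced, so recovered cohort statistics reflect pipeline accuracy rather
than draw noise.
"""

from __future__ import annotations

import math
import numpy as np
from scipy.special import ndtri

from retnathist import enface, natural_history, oct_layers, synthdata

__all__ = [
    "stratified_normal",
    "thickness_cohort_study",
    "spot_count_study",
    "erg_decay_study",
    "treatment_plan_study",
    "ERG_ENDPOINTS",
]

#: (age_days, mean_amplitude_uV) endpoints of the reference UV-cone decay line.
ERG_ENDPOINTS = ((31.0, 139.0), (83.0, 22.0))


def stratified_normal(n: int, mean: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """n draws from N(mean, sd) via shuffled stratified quantiles."""
    u = rng.uniform(size=n)
    q = (rng.permutation(n) + u) / n
    return mean + sd * ndtri(q)


def _recover_eye(params: synthdata.OCTPhantomParams) -> tuple:
    """Run one eye through the thickness pipeline; returns (onl_mean, total_mean)."""
    vol, _ = synthdata.gen_oct_volume(params)
    rpe = oct_layers.find_rpe_map(vol)
    flat, _ = oct_layers.flatten(vol, rpe)
    seg = oct_layers.segment_volume(flat, rosette_mode="none")
    onl, tot = oct_layers.volume_profiles(flat, seg)
    # spot-footprint rosette exclusion from the strip en-face map
    emap = enface.integrate_slab(
        flat, *enface.default_slab(flat.meta["rpe_target_um"], params.onl_thickness_mean)
    )
    spots = enface.detect_spots(emap, threshold_mode="robust")
    footprint = enface.spot_footprint_mask(
        onl.positions, spots, footprint_radius_mm=1.5 * params.rosette_radius,
        axis=params.scan_axis,
    )
    onl = oct_layers.exclude_regions(onl, footprint)
    tot = oct_layers.exclude_regions(tot, footprint)
    return float(onl.valid_values().mean()), float(tot.valid_values().mean())


def thickness_cohort_study(
    n_eyes: int,
    onl_mean: float,
    onl_sd: float,
    total_mean: float,
    total_sd: float,
    seed: int,
    noise_sd: float = 0.04,
    rosettes_per_eye: int = 6,
) -> dict:
    """Simulate and re-measure a cohort of vertical-meridian scans.

    Returns per-eye recovered ONL+ and total-thickness means plus the
    configured per-eye ground truths.
    """
    rng = np.random.default_rng(seed)
    # shared quantile ranks: thicker retinas get thicker ONL, which keeps the
    # band geometry feasible (total > 2*ONL + inner-retina margin) without
    # clamping that would bias the cohort means
    z = ndtri((rng.permutation(n_eyes) + rng.uniform(size=n_eyes)) / n_eyes)
    onl_draws = np.maximum(onl_mean + onl_sd * z, 15.0)
    tot_draws = np.maximum(total_mean + total_sd * z, 2.0 * onl_draws + 50.0)
    eye_seeds = rng.integers(0, 2**31 - 1, size=n_eyes)
    onl_rec, tot_rec = [], []
    for k in range(n_eyes):
        params = synthdata.OCTPhantomParams(
            n_bscans=4,
            n_lrps_per_bscan=200,
            scan_axis="vertical",
            lateral_scale=1.5 / 200,
            bscan_spacing=0.012,
            onl_thickness_mean=float(onl_draws[k]),
            onl_thickness_sd=0.0,
            total_thickness_mean=float(tot_draws[k]),
            total_thickness_sd=0.0,
            rpe_curvature_amplitude=10.0,
            noise_sd=noise_sd,
            rosette_count_by_sector={"all": rosettes_per_eye},
            seed=int(eye_seeds[k]),
        )
        o, t = _recover_eye(params)
        onl_rec.append(o)
        tot_rec.append(t)
    return {
        "onl_recovered": np.array(onl_rec),
        "total_recovered": np.array(tot_rec),
        "onl_truth": onl_draws,
        "total_truth": tot_draws,
    }


def spot_count_study(
    n_eyes: int,
    superior_mean: float,
    superior_sd: float,
    inferior_mean: float,
    inferior_sd: float,
    seed: int,
    raster: int = 256,
) -> dict:
    """Plant hemifield-specific pseudorosette counts and re-count them.

    Returns planted and detected per-eye superior/inferior counts.
    """
    rng = np.random.default_rng(seed)
    sup_draws = np.clip(np.rint(stratified_normal(n_eyes, superior_mean, superior_sd, rng)), 0, None)
    inf_draws = np.clip(np.rint(stratified_normal(n_eyes, inferior_mean, inferior_sd, rng)), 0, None)
    eye_seeds = rng.integers(0, 2**31 - 1, size=n_eyes)
    detected = {"superior": [], "inferior": []}
    for k in range(n_eyes):
        params = synthdata.OCTPhantomParams(
            n_bscans=raster,
            n_lrps_per_bscan=raster,
            axial_px=256,
            scan_axis="horizontal",
            lateral_scale=1.5 / raster,
            bscan_spacing=1.5 / raster,
            onl_thickness_mean=66.4,
            total_thickness_mean=197.4,
            top_offset_um=100.0,
            rpe_curvature_amplitude=12.0,
            noise_sd=0.05,
            rosette_count_by_sector={
                "superior": int(sup_draws[k]),
                "inferior": int(inf_draws[k]),
            },
            seed=int(eye_seeds[k]),
        )
        vol, _ = synthdata.gen_oct_volume(params)
        rpe = oct_layers.find_rpe_map(vol)
        flat, _ = oct_layers.flatten(vol, rpe)
        emap = enface.integrate_slab(
            flat, *enface.default_slab(flat.meta["rpe_target_um"], 66.4)
        )
        spots = enface.detect_spots(emap)
        tab = enface.sector_stats(spots, field_radius=0.75, scheme="halves").set_index("sector")
        detected["superior"].append(int(tab.loc["superior", "count"]))
        detected["inferior"].append(int(tab.loc["inferior", "count"]))
    return {
        "superior_detected": np.array(detected["superior"]),
        "inferior_detected": np.array(detected["inferior"]),
        "superior_planted": sup_draws,
        "inferior_planted": inf_draws,
    }


def erg_decay_line() -> tuple:
    """(slope, intercept) of the log10-linear line through the reference endpoints."""
    (a0, y0), (a1, y1) = ERG_ENDPOINTS
    slope = math.log10(y1 / y0) / (a1 - a0)
    intercept = math.log10(y0) - slope * a0
    return slope, intercept


def erg_decay_study(seed: int, scatter_sd: float = 0.2, n_per_age: int = 7) -> dict:
    """Simulate a decay cohort on the reference line and refit it.

    Ages span P31-P83 every 4 days (~98 records at the default density).
    Returns the fit plus predicted means at both endpoint ages with their
    standard errors (delta method, uV scale).
    """
    slope, intercept = erg_decay_line()
    params = synthdata.ERGCohortParams(
        intercept_log=intercept,
        slope_log=slope,
        scatter_sd=scatter_sd,
        noise_floor=1.0,
        ages=list(range(31, 84, 4)),
        n_per_age=n_per_age,
        stimulus="UV",
        stratified_scatter=True,
        seed=seed,
    )
    df = synthdata.gen_erg_cohort(params)
    fit = natural_history.fit_decay(df, noise_floor=1.0)
    out = {"fit": fit, "n": fit.n}
    for age, _ in ERG_ENDPOINTS:
        mean, _, _ = natural_history.predict_amplitude(fit, age)
        se_log = fit.residual_sd * math.sqrt(
            1.0 / fit.n + (age - fit.age_mean) ** 2 / fit.age_sxx
        )
        out[age] = {"mean_uV": mean, "se_uV": math.log(10.0) * mean * se_log}
    return out


def treatment_plan_study(assess_log_mean: float = 1.4, asym_log: float = 0.3) -> natural_history.TreatmentWindow:
    """Treatment window from a given expected log-amplitude at the P65 assessment."""
    slope, _ = erg_decay_line()
    fit = natural_history.DecayFit(
        slope=slope,
        intercept=assess_log_mean - slope * 65.0,
        residual_sd=0.2,
        pi95_halfwidth=0.4,
        n=98,
        age_mean=57.0,
        age_sxx=2e4,
        age_range=(31.0, 83.0),
    )
    return natural_history.plan_window(
        fit, inject_age=37.0, assess_delay=28.0, asym_log=asym_log
    )
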