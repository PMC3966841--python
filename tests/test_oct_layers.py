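"""Segmentation, flattening, montage and cohort statistics."""

import numpy as np
import pytest

from retnathist import oct_layers as ol
from retnathist import synthdata as sd
from retnathist.core import LRP, OCTVolume

from conftest import CLEAN_BANDS, make_banded_lrp

# ---------------------------------------------------------------- extract_lrps


def make_repeat_volume(repeats=4, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.uniform(0, 1, size=(2, 10, 32)).astype(np.float32)
    frames = []
    for b in range(2):
        for _ in range(repeats):
            f = base[b] + (jitter * rng.standard_normal((10, 32))).astype(np.float32)
            frames.append(f)
    return OCTVolume(
        np.stack(frames), axial_scale=1.6, lateral_scale=0.0075, repeats=repeats
    ), base


def test_extract_identical_repeats_idempotent():
    vol, base = make_repeat_volume(repeats=4, jitter=0.0)
    lrps = ol.extract_lrps(vol)
    np.testing.assert_allclose(lrps[0][0].reflectivity, base[0, 0], rtol=1e-6)


def test_extract_pointwise_mean():
    data = np.zeros((2, 1, 3), dtype=np.float32)
    data[0, 0] = [1.0, 1.0, 1.0]
    data[1, 0] = [3.0, 3.0, 3.0]
    vol = OCTVolume(data, axial_scale=1.0, lateral_scale=0.01, repeats=2)
    lrps = ol.extract_lrps(vol, repeats=2)
    np.testing.assert_allclose(lrps[0][0].reflectivity, 2.0)


def test_extract_bad_repeat_count_errors():
    vol, _ = make_repeat_volume(repeats=4)
    with pytest.raises(ValueError, match="divide"):
        ol.extract_lrps(vol, repeats=3)


# -------------------------------------------------------------------- find_rpe


def test_find_rpe_second_from_sclerad():
    lrp = make_banded_lrp([(160, 1.0, 7), (320, 0.9, 7), (400, 0.9, 7), (440, 0.8, 7)],
                          axial_px=512)
    assert ol.find_rpe(lrp) == pytest.approx(400.0, abs=2.0)


def test_find_rpe_single_peak_fails():
    lrp = make_banded_lrp([(200, 1.0, 7)], axial_px=400)
    assert np.isnan(ol.find_rpe(lrp))


def test_find_rpe_matches_bruteforce_oracle():
    rng = np.random.default_rng(4)
    for _ in range(25):
        n_peaks = rng.integers(3, 6)
        depths = np.sort(rng.choice(np.arange(60, 460, 40), n_peaks, replace=False))
        depths = depths + rng.uniform(-5, 5, n_peaks)
        amps = rng.uniform(0.5, 1.0, n_peaks)
        lrp = make_banded_lrp([(d, a, 6.0) for d, a in zip(depths, amps)], axial_px=512)
        got = ol.find_rpe(lrp, min_prominence=0.2, smooth_sigma=0.0)
        # oracle: enumerate local maxima above threshold, take 2nd deepest
        y = lrp.reflectivity
        maxima = [
            i for i in range(1, y.size - 1)
            if y[i] > y[i - 1] and y[i] >= y[i + 1] and y[i] > 0.3
        ]
        oracle = sorted(maxima)[-2] * lrp.axial_scale
        assert got == pytest.approx(oracle, abs=1.0)


# --------------------------------------------------------------------- flatten


def test_flatten_sinusoidal_curvature():
    params = sd.OCTPhantomParams(
        n_bscans=2, n_lrps_per_bscan=150, rpe_curvature_amplitude=20.0, seed=8
    )
    vol, truth = sd.gen_oct_volume(params)
    rpe = ol.find_rpe_map(vol)
    flat, shifts = ol.flatten(vol, rpe)
    rpe_after = ol.find_rpe_map(flat)
    assert np.nanstd(rpe_after) <= vol.axial_scale  # RPE depth SD <= 1 pixel


def test_flatten_identity_on_flat_volume(clean_volume):
    vol, _ = clean_volume
    rpe = ol.find_rpe_map(vol)
    _, shifts = ol.flatten(vol, rpe)
    assert np.all(shifts == 0)


def test_flatten_shift_map_matches_negated_curvature():
    params = sd.OCTPhantomParams(
        n_bscans=3, n_lrps_per_bscan=120, rpe_curvature_amplitude=18.0, seed=9
    )
    vol, truth = sd.gen_oct_volume(params)
    rpe = ol.find_rpe_map(vol)
    flat, shifts = ol.flatten(vol, rpe)
    curvature = truth.rpe_depth_map - truth.rpe_depth_map.mean()
    expected = -curvature / vol.axial_scale
    assert np.abs(shifts - expected).max() <= 1.5  # within ~1 pixel


def test_flatten_too_many_failures_errors(clean_volume):
    vol, _ = clean_volume
    rpe = ol.find_rpe_map(vol)
    rpe[:, : int(0.2 * rpe.shape[1])] = np.nan
    with pytest.raises(ValueError, match="failed"):
        ol.flatten(vol, rpe)


# ------------------------------------------------------------- segment_onl_plus


def test_segment_constructed_troughs(clean_lrp):
    # troughs at 180 and 245 um by construction -> ONL+ = 65 um
    rpe = ol.find_rpe(clean_lrp)
    seg = ol.segment_onl_plus(clean_lrp, rpe)
    assert seg.quality_flag is ol.QualityFlag.OK
    assert seg.opl_sclerad_trough == pytest.approx(180.0, abs=1.0)
    assert seg.pre_rpe_trough == pytest.approx(245.0, abs=1.0)
    assert seg.onl_plus_um == pytest.approx(65.0, abs=2.0)


def test_segment_total_thickness(clean_lrp):
    # interface at 48 um, RPE at 280 um -> total 232 um
    rpe = ol.find_rpe(clean_lrp)
    seg = ol.segment_onl_plus(clean_lrp, rpe)
    assert seg.vitreoretinal_interface == pytest.approx(48.0, abs=1.0)
    assert seg.total_um == pytest.approx(232.0, abs=2.0)


def test_segment_rosette_extra_peak_flagged():
    bands = CLEAN_BANDS + [(192, 1.4, 4.0)]  # sharp inclusion inside the ONL+ lamina
    lrp = make_banded_lrp(bands)
    rpe = ol.find_rpe(lrp)
    seg = ol.segment_onl_plus(lrp, rpe)
    assert seg.quality_flag is ol.QualityFlag.EXCLUDED_ROSETTE


def test_segment_missing_opl_fails():
    lrp = make_banded_lrp([(48, 1.0, 7), (280, 0.9, 7), (330, 0.75, 9)])
    rpe = ol.find_rpe(lrp)
    seg = ol.segment_onl_plus(lrp, rpe)
    assert seg.quality_flag is ol.QualityFlag.FAILED


def test_segment_recovers_ground_truth_over_cohort(clean_volume):
    vol, truth = clean_volume
    seg = ol.segment_volume(vol)
    assert seg["ok"].all()
    err = np.abs(seg["onl_plus_um"] - truth.onl_plus_map)
    assert (err <= vol.axial_scale).mean() == 1.0


def test_boundary_ordering_invariant(curved_noisy_volume):
    vol, _ = curved_noisy_volume
    rpe = ol.find_rpe_map(vol)
    flat, _ = ol.flatten(vol, rpe)
    frames = ol.averaged_frames(flat)
    rpe_flat = ol.find_rpe_map(flat)
    for b in range(frames.shape[0]):
        for a in range(0, frames.shape[1], 7):
            seg = ol.segment_onl_plus(LRP(frames[b, a], vol.axial_scale), rpe_flat[b, a])
            if seg.quality_flag is ol.QualityFlag.OK:
                assert (
                    seg.vitreoretinal_interface
                    < seg.opl_sclerad_trough
                    < seg.pre_rpe_trough
                    < seg.rpe_peak
                )


def test_flatten_then_segment_commutes_with_segment_then_shift():
    params = sd.OCTPhantomParams(
        n_bscans=2, n_lrps_per_bscan=100, rpe_curvature_amplitude=15.0, seed=14
    )
    vol, _ = sd.gen_oct_volume(params)
    rpe = ol.find_rpe_map(vol)
    flat, _ = ol.flatten(vol, rpe)
    seg_flat = ol.segment_volume(flat)
    seg_raw = ol.segment_volume(vol, rpe_map=rpe)
    both = seg_flat["ok"] & seg_raw["ok"]
    diff = np.abs(seg_flat["onl_plus_um"][both] - seg_raw["onl_plus_um"][both])
    assert diff.max() <= vol.axial_scale  # thickness commutes within 1 pixel


def test_monotonicity_in_configured_thickness():
    means = []
    for onl in (55.0, 65.0, 75.0):
        params = sd.OCTPhantomParams(n_bscans=1, n_lrps_per_bscan=80,
                                     onl_thickness_mean=onl, seed=2)
        vol, _ = sd.gen_oct_volume(params)
        seg = ol.segment_volume(vol)
        means.append(np.nanmean(seg["onl_plus_um"]))
    assert means[0] < means[1] < means[2]


# ------------------------------------------------------------- montage_profiles


def segment_profile(center, length=1.5, spacing=0.01, value=60.0):
    n = int(round(length / spacing)) + 1
    pos = center - length / 2 + spacing * np.arange(n)
    return ol.ThicknessProfile(pos, np.full(n, value), np.ones(n, bool))


def test_montage_coverage_union():
    segs = [segment_profile(c) for c in (-0.8, 0.0, 0.8)]
    merged = ol.montage_profiles(segs, [0.0, 0.0, 0.0])
    coverage = merged.positions[-1] - merged.positions[0]
    assert coverage == pytest.approx(3.1, abs=0.02)


def test_montage_identical_overlap_unchanged():
    segs = [segment_profile(0.0, value=60.0), segment_profile(0.5, value=60.0)]
    merged = ol.montage_profiles(segs, [0.0, 0.0])
    assert np.allclose(merged.values[merged.mask], 60.0)


def test_montage_overlap_mean():
    segs = [segment_profile(0.0, value=60.0), segment_profile(0.5, value=64.0)]
    merged = ol.montage_profiles(segs, [0.0, 0.0])
    overlap = (merged.positions > -0.2) & (merged.positions < 0.2)
    assert np.allclose(merged.values[overlap & merged.mask], 62.0)


def test_montage_disjoint_errors():
    segs = [segment_profile(0.0, length=0.5), segment_profile(2.0, length=0.5)]
    with pytest.raises(ValueError, match="overlap"):
        ol.montage_profiles(segs, [0.0, 0.0])


# -------------------------------------------------------------- exclude_regions


def test_exclude_only_onh_zone():
    prof = segment_profile(0.0)
    out = ol.exclude_regions(prof)
    zone = np.abs(prof.positions) < 0.09
    assert not out.mask[zone].any()
    assert out.mask[~zone].all()


def test_exclude_rosette_mask_half():
    prof = segment_profile(0.0)
    rosettes = prof.positions > 0
    out = ol.exclude_regions(prof, rosette_mask=rosettes)
    assert not out.mask[prof.positions > 0].any()
    assert out.mask[(prof.positions < -0.09)].all()


def test_exclude_all_positions_errors():
    prof = segment_profile(0.0, length=0.1)
    with pytest.raises(ValueError, match="excluded"):
        ol.exclude_regions(prof)


def test_masked_mean_closer_to_truth_with_spiky_artifacts():
    pos = np.linspace(-1.2, 1.2, 241)
    truth = 66.0
    values = np.full(pos.size, truth)
    spikes = np.zeros(pos.size, bool)
    spikes[::17] = True
    values[spikes] += 40.0  # rosette-like spikes
    prof = ol.ThicknessProfile(pos, values, np.ones(pos.size, bool))
    masked = ol.exclude_regions(prof, rosette_mask=spikes)
    unmasked = ol.exclude_regions(prof)
    err_masked = abs(masked.valid_values().mean() - truth)
    err_unmasked = abs(unmasked.valid_values().mean() - truth)
    assert err_masked < err_unmasked
    assert err_masked < 1e-9


# -------------------------------------------------------------- profile_mean_sd


def test_mean_sd_constant():
    s = ol.profile_mean_sd([segment_profile(0.0, value=66.4)])
    assert s.mean == pytest.approx(66.4)
    assert s.sd == pytest.approx(0.0)


def test_mean_sd_per_eye():
    s = ol.profile_mean_sd(
        [segment_profile(0.0, value=60.0), segment_profile(0.0, value=70.0)], per_eye=True
    )
    assert s.mean == pytest.approx(65.0)
    assert s.n == 2


def test_mean_sd_matches_flat_oracle():
    rng = np.random.default_rng(3)
    profiles = []
    allvals = []
    for _ in range(5):
        n = rng.integers(20, 60)
        pos = np.cumsum(rng.uniform(0.005, 0.02, n))
        vals = rng.uniform(40, 90, n)
        mask = rng.uniform(size=n) > 0.3
        if not mask.any():
            mask[0] = True
        profiles.append(ol.ThicknessProfile(pos, vals, mask))
        allvals.append(vals[mask])
    s = ol.profile_mean_sd(profiles)
    flat = np.concatenate(allvals)
    assert s.mean == pytest.approx(flat.mean())
    assert s.sd == pytest.approx(flat.std(ddof=1))


def test_mean_sd_empty_errors():
    with pytest.raises(ValueError):
        ol.profile_mean_sd([])


# --------------------------------------------------------- fraction_vs_baseline


def test_fraction_printed_cohorts():
    young = ol.CohortSummary(66.4, 7.6, 35, "P31-41")
    old = ol.CohortSummary(54.7, 7.0, 12, "P83-89")
    # 54.7/66.4 = 0.824 (~80% remaining at 3 months)
    assert ol.fraction_vs_baseline(old, young) == pytest.approx(0.824, abs=5e-4)


def test_fraction_identity_and_zero():
    base = ol.CohortSummary(66.4, 7.6, 35)
    assert ol.fraction_vs_baseline(base, base) == pytest.approx(1.0)
    assert ol.fraction_vs_baseline(ol.CohortSummary(0.0, 0.0, 1), base) == 0.0


def test_fraction_zero_baseline_errors():
    with pytest.raises(ValueError):
        ol.fraction_vs_baseline(ol.CohortSummary(5.0, 1.0, 3), ol.CohortSummary(0.0, 0.0, 1))


# -------------------------------------------------------------- compare_groups


def test_compare_identical_groups():
    t, p = ol.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_compare_separated_groups():
    a = [1.0, 2.0, 3.0]
    b = [11.0, 12.01, 13.02]
    _, p = ol.compare_groups(a, b)
    assert p < 0.05


def test_compare_small_groups_rejected():
    with pytest.raises(ValueError):
        ol.compare_groups([1.0], [1.0, 2.0])


def test_compare_matches_permutation_oracle():
    rng = np.random.default_rng(17)
    a = rng.normal(0.0, 1.0, 30)
    b = rng.normal(0.6, 1.0, 30)
    t_obs, p_welch = ol.compare_groups(a, b)

    pooled = np.concatenate([a, b])
    n_shuffles = 100_000
    order = np.argsort(rng.random((n_shuffles, pooled.size)), axis=1)
    shuffled = pooled[order]
    ga, gb = shuffled[:, :30], shuffled[:, 30:]
    va, vb = ga.var(axis=1, ddof=1), gb.var(axis=1, ddof=1)
    t_perm = (ga.mean(axis=1) - gb.mean(axis=1)) / np.sqrt(va / 30 + vb / 30)
    p_perm = np.mean(np.abs(t_perm) >= abs(t_obs))
    mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / n_shuffles) + 0.005
    assert p_welch == pytest.approx(p_perm, abs=max(0.01, mc_err))


# --------------------------------------------------------- cohort recovery


def test_cohort_mean_recovery_within_2sem():
    """35-eye synthetic young cohort recovers the configured mean ONL+."""
    cfg_mean, cfg_sd = 66.4, 7.6
    base = sd.OCTPhantomParams(
        n_bscans=2, n_lrps_per_bscan=150, onl_thickness_mean=cfg_mean,
        onl_thickness_sd=cfg_sd, total_thickness_mean=197.4, total_thickness_sd=13.0,
        rpe_curvature_amplitude=10.0, noise_sd=0.04,
    )
    eye_means = []
    for p in sd.cohort_phantoms(base, 35, seed=100):
        vol, _ = sd.gen_oct_volume(p)
        rpe = ol.find_rpe_map(vol)
        flat, _ = ol.flatten(vol, rpe)
        onl, _ = ol.volume_profiles(flat)
        onl = ol.exclude_regions(onl)
        eye_means.append(onl.valid_values().mean())
    sem = cfg_sd / np.sqrt(35)
    assert abs(np.mean(eye_means) - cfg_mean) <= 2 * sem
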