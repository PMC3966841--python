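"""LRP extraction, RPE alignment and outer-retina boundary segmentation.

Boundary definitions follow the reflectivity-profile conventions used for
murine SD-OCT: the RPE is the second hyperreflective band from the scleral
side; total retinal thickness runs from the vitreoretinal interface to the
RPE peak; photoreceptor (ONL+) thickness runs from the trough sclerad of the
OPL peak to the trough vitreal to the RPE band.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace as _dc_replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, signal, stats

from retnathist.core import LRP, OCTVolume

__all__ = [
    "QualityFlag",
    "LayerSegmentation",
    "ThicknessProfile",
    "CohortSummary",
    "extract_lrps",
    "find_rpe",
    "find_rpe_map",
    "flatten",
    "segment_onl_plus",
    "segment_volume",
    "volume_profiles",
    "montage_profiles",
    "exclude_regions",
    "profile_mean_sd",
    "fraction_vs_baseline",
    "compare_groups",
]

#: Default peak/trough prominence threshold as a fraction of dynamic range.
PROMINENCE_FRAC = 0.10
#: Gaussian pre-smoothing (pixels) applied before extremum detection.
SMOOTH_SIGMA_PX = 1.5
#: Half-width (mm) of the optic-nerve-head exclusion zone (0.18 mm total).
ONH_HALFWIDTH_MM = 0.09
#: Expected number of prominent peaks strictly between the vitreoretinal
#: interface and the RPE in clean anatomy (inner band, OPL, S+); more peaks
#: indicate a hyperreflective rosette inclusion.
EXPECTED_INNER_PEAKS = 3


class QualityFlag(enum.Enum):
    OK = "ok"
    EXCLUDED_ROSETTE = "excluded_rosette"
    EXCLUDED_ONH = "excluded_onh"
    FAILED = "failed"


@dataclass
class LayerSegmentation:
    """Boundary depths (um from the volume top) for one A-scan."""

    vitreoretinal_interface: float
    opl_sclerad_trough: float
    pre_rpe_trough: float
    rpe_peak: float
    quality_flag: QualityFlag = QualityFlag.OK

    def __post_init__(self) -> None:
        if self.quality_flag is QualityFlag.OK:
            b = (
                self.vitreoretinal_interface,
                self.opl_sclerad_trough,
                self.pre_rpe_trough,
                self.rpe_peak,
            )
            if not (b[0] < b[1] < b[2] < b[3]):
                raise ValueError(f"boundaries not strictly ordered: {b}")

    @property
    def onl_plus_um(self) -> float:
        return self.pre_rpe_trough - self.opl_sclerad_trough

    @property
    def total_um(self) -> float:
        return self.rpe_peak - self.vitreoretinal_interface


@dataclass
class ThicknessProfile:
    """Thickness (um) versus signed position (mm) relative to the ONH."""

    positions: np.ndarray
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.positions.shape == self.values.shape == self.mask.shape):
            raise ValueError("positions, values and mask must share shape")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(~np.isfinite(self.values[self.mask])):
            raise ValueError("values must be finite where mask is true")

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class CohortSummary:
    mean: float
    sd: float
    n: int
    group_label: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0 or self.n < 1:
            raise ValueError("sd must be >= 0 and n >= 1")


# --------------------------------------------------------------------------- #
# LRP extraction and peak utilities
# --------------------------------------------------------------------------- #


def extract_lrps(volume: OCTVolume, repeats: Optional[int] = None) -> list:
    """Average stored repeat frames into one LRP per A-scan location.

    Returns a nested list ``[b_scan][a_scan] -> LRP``.  ``repeats`` must
    divide the number of stored repeat frames (default: use all of them).
    """
    stored = volume.repeats
    if repeats is None:
        repeats = stored
    if repeats < 1 or stored % repeats:
        raise ValueError(f"repeats={repeats} does not divide stored repeat count {stored}")
    arr = volume.data.reshape(volume.n_bscans, stored, volume.n_ascans, volume.axial_px)
    mean = arr[:, :repeats].mean(axis=1)
    positions = volume.ascan_positions_mm()
    out = []
    for b in range(volume.n_bscans):
        out.append(
            [
                LRP(mean[b, a], volume.axial_scale, lateral_position=float(positions[a]))
                for a in range(volume.n_ascans)
            ]
        )
    return out


def averaged_frames(volume: OCTVolume, repeats: Optional[int] = None) -> np.ndarray:
    """Repeat-averaged reflectivity, shape (n_bscans, n_ascans, axial_px)."""
    stored = volume.repeats
    if repeats is None:
        repeats = stored
    if repeats < 1 or stored % repeats:
        raise ValueError(f"repeats={repeats} does not divide stored repeat count {stored}")
    arr = volume.data.reshape(volume.n_bscans, stored, volume.n_ascans, volume.axial_px)
    return arr[:, :repeats].mean(axis=1)


def _smooth(profile: np.ndarray, sigma: float = SMOOTH_SIGMA_PX) -> np.ndarray:
    if sigma <= 0:
        return np.asarray(profile, dtype=float)
    return ndimage.gaussian_filter1d(np.asarray(profile, dtype=float), sigma)


def _prominence(profile: np.ndarray, min_prominence: Optional[float]) -> float:
    if min_prominence is not None:
        return float(min_prominence)
    return PROMINENCE_FRAC * float(np.ptp(profile))


def _peaks(profile: np.ndarray, prominence: float) -> np.ndarray:
    # height floor rejects low-lying noise wiggles in signal-free regions
    height = float(profile.min()) + 2.0 * prominence
    idx, _ = signal.find_peaks(profile, prominence=prominence, height=height)
    return idx


def find_rpe(
    lrp: LRP, min_prominence: Optional[float] = None, smooth_sigma: float = SMOOTH_SIGMA_PX
) -> float:
    """Depth (um) of the RPE: second qualifying peak from the scleral side.

    Returns ``nan`` when fewer than two sufficiently prominent peaks exist
    (failed segmentation is a flag, not an exception).
    """
    prof = _smooth(lrp.reflectivity, smooth_sigma)
    prom = _prominence(prof, min_prominence)
    idx = _peaks(prof, prom)
    if idx.size < 2:
        return float("nan")
    return float(idx[-2] * lrp.axial_scale)


def find_rpe_map(
    volume: OCTVolume, min_prominence: Optional[float] = None, repeats: Optional[int] = None
) -> np.ndarray:
    """Per-A-scan RPE depth map (um), nan where detection fails."""
    frames = averaged_frames(volume, repeats)
    nb, na, _ = frames.shape
    out = np.full((nb, na), np.nan)
    for b in range(nb):
        sm = ndimage.gaussian_filter1d(frames[b].astype(float), SMOOTH_SIGMA_PX, axis=1)
        for a in range(na):
            prof = sm[a]
            prom = _prominence(prof, min_prominence)
            idx = _peaks(prof, prom)
            if idx.size >= 2:
                out[b, a] = idx[-2] * volume.axial_scale
    return out


def flatten(
    volume: OCTVolume,
    rpe_depths: np.ndarray,
    target_um: Optional[float] = None,
    max_failed_frac: float = 0.10,
):
    """Shift each A-scan by an integer pixel count so the RPE is flat.

    ``rpe_depths`` is the (n_bscans, n_ascans) map in um; nan entries are
    interpolated along the A-scan axis.  More than ``max_failed_frac``
    failures is an error.  Returns ``(flattened_volume, shift_map_px)``.
    """
    rpe = np.array(rpe_depths, dtype=float)
    if rpe.shape != (volume.n_bscans, volume.n_ascans):
        raise ValueError("rpe_depths shape mismatch")
    bad = ~np.isfinite(rpe)
    if bad.mean() > max_failed_frac:
        raise ValueError(
            f"{bad.mean():.0%} of A-scans failed RPE detection (> {max_failed_frac:.0%})"
        )
    for b in range(rpe.shape[0]):
        row = rpe[b]
        miss = ~np.isfinite(row)
        if miss.any():
            ok = np.nonzero(~miss)[0]
            if ok.size == 0:
                raise ValueError(f"B-scan {b}: no valid RPE depths to interpolate from")
            row[miss] = np.interp(np.nonzero(miss)[0], ok, row[ok])
    if target_um is None:
        target_um = float(np.median(rpe))
    shift_px = np.rint((target_um - rpe) / volume.axial_scale).astype(int)

    data = volume.data.copy()
    nz = data.shape[2]
    for b in range(volume.n_bscans):
        for a in range(volume.n_ascans):
            s = shift_px[b, a]
            if s == 0:
                continue
            for rep in range(volume.repeats):
                f = b * volume.repeats + rep
                col = np.roll(data[f, a], s)
                if s > 0:
                    col[:s] = 0.0
                else:
                    col[nz + s :] = 0.0
                data[f, a] = col
    flat = _dc_replace(volume, data=data)
    flat.meta = dict(volume.meta, flattened=True, rpe_target_um=target_um)
    return flat, shift_px


# --------------------------------------------------------------------------- #
# Boundary segmentation
# --------------------------------------------------------------------------- #


def segment_onl_plus(
    lrp: LRP,
    rpe_um: float,
    min_prominence: Optional[float] = None,
    smooth_sigma: float = SMOOTH_SIGMA_PX,
    expected_inner_peaks: int = EXPECTED_INNER_PEAKS,
    rosette_mode: str = "extra_peak",
) -> LayerSegmentation:
    """Segment outer-retinal boundaries on one LRP given its RPE depth.

    The vitreoretinal interface is the first prominent peak from the vitreal
    end; the S+ band is the prominent peak immediately vitreal to the RPE and
    the OPL peak the one vitreal to that.  The ONL+ boundaries are the signal
    troughs between OPL and S+ (sclerad of the OPL peak) and between S+ and
    the RPE (vitreal to the RPE band), reported at integer pixels.

    When ``rosette_mode == "extra_peak"``, an A-scan carrying more prominent
    peaks between the interface and the RPE than ``expected_inner_peaks`` is
    flagged ``EXCLUDED_ROSETTE`` (hyperreflective inclusion).
    """
    failed = LayerSegmentation(0.0, 0.0, 0.0, 0.0, QualityFlag.FAILED)
    if not np.isfinite(rpe_um):
        return failed
    scale = lrp.axial_scale
    prof = _smooth(lrp.reflectivity, smooth_sigma)
    prom = _prominence(prof, min_prominence)
    idx = _peaks(prof, prom)
    if idx.size < 4:
        return failed
    rpe_px = int(round(rpe_um / scale))
    k = int(np.argmin(np.abs(idx - rpe_px)))
    if abs(idx[k] - rpe_px) > max(3, int(8 / scale)):
        return failed
    rpe_i = idx[k]
    vitreal = idx[:k]  # peaks vitreal of the RPE
    if vitreal.size < 3:
        return failed
    flag = QualityFlag.OK
    if rosette_mode == "extra_peak" and vitreal.size - 1 > expected_inner_peaks:
        flag = QualityFlag.EXCLUDED_ROSETTE
    vri_i = vitreal[0]
    splus_i = vitreal[-1]
    opl_i = vitreal[-2]
    t1_i = opl_i + int(np.argmin(prof[opl_i : splus_i + 1]))
    t2_i = splus_i + int(np.argmin(prof[splus_i : rpe_i + 1]))
    if not (vri_i < t1_i < t2_i < rpe_i):
        return failed
    return LayerSegmentation(
        vitreoretinal_interface=vri_i * scale,
        opl_sclerad_trough=t1_i * scale,
        pre_rpe_trough=t2_i * scale,
        rpe_peak=rpe_i * scale,
        quality_flag=flag,
    )


def segment_volume(
    volume: OCTVolume,
    rpe_map: Optional[np.ndarray] = None,
    min_prominence: Optional[float] = None,
    rosette_mode: str = "extra_peak",
    repeats: Optional[int] = None,
) -> dict:
    """Segment every A-scan; returns maps of thickness and quality.

    Keys: ``onl_plus_um``, ``total_um`` (nan where not OK-flagged),
    ``ok`` / ``rosette`` boolean maps, ``rpe_map``.
    """
    frames = averaged_frames(volume, repeats)
    nb, na, _ = frames.shape
    if rpe_map is None:
        rpe_map = find_rpe_map(volume, min_prominence, repeats)
    onl = np.full((nb, na), np.nan)
    tot = np.full((nb, na), np.nan)
    ok = np.zeros((nb, na), dtype=bool)
    rosette = np.zeros((nb, na), dtype=bool)
    for b in range(nb):
        for a in range(na):
            lrp = LRP(frames[b, a], volume.axial_scale)
            seg = segment_onl_plus(
                lrp, rpe_map[b, a], min_prominence, rosette_mode=rosette_mode
            )
            if seg.quality_flag is QualityFlag.OK:
                ok[b, a] = True
                onl[b, a] = seg.onl_plus_um
                tot[b, a] = seg.total_um
            elif seg.quality_flag is QualityFlag.EXCLUDED_ROSETTE:
                rosette[b, a] = True
    return {"onl_plus_um": onl, "total_um": tot, "ok": ok, "rosette": rosette, "rpe_map": rpe_map}


def volume_profiles(volume: OCTVolume, seg: Optional[dict] = None, **kw) -> tuple:
    """Collapse a segmented volume into meridian thickness profiles.

    A-scan positions along the scan axis form the profile grid; values are
    means over parallel B-scans of OK-flagged A-scans.  Returns
    ``(onl_plus_profile, total_profile)`` (no exclusions applied yet).
    """
    if seg is None:
        seg = segment_volume(volume, **kw)
    positions = volume.ascan_positions_mm()
    with np.errstate(invalid="ignore"):
        onl = np.nanmean(seg["onl_plus_um"], axis=0)
        tot = np.nanmean(seg["total_um"], axis=0)
    mask = seg["ok"].any(axis=0)
    onl = np.where(mask, onl, np.nan)
    tot = np.where(mask, tot, np.nan)
    return (
        ThicknessProfile(positions, onl, mask),
        ThicknessProfile(positions, tot, mask),
    )


# --------------------------------------------------------------------------- #
# Profiles, montage, exclusion and cohort statistics
# --------------------------------------------------------------------------- #


def montage_profiles(segments: Sequence[ThicknessProfile], onh_offsets: Sequence[float]) -> ThicknessProfile:
    """Merge overlapping meridian segments into one profile.

    Each segment's positions are shifted by its acquisition offset (mm);
    valid samples are binned onto a common grid at the finest input spacing
    and averaged where segments overlap.
    """
    if len(segments) != len(onh_offsets):
        raise ValueError("one offset per segment required")
    if len(segments) == 0:
        raise ValueError("no segments")
    spacing = min(float(np.diff(s.positions).min()) for s in segments)
    shifted = [s.positions + off for s, off in zip(segments, onh_offsets)]
    intervals = [(p.min(), p.max()) for p in shifted]
    if len(segments) > 1:
        order = np.argsort([iv[0] for iv in intervals])
        for i, j in zip(order[:-1], order[1:]):
            if intervals[j][0] > intervals[i][1] + spacing / 2:
                raise ValueError(
                    f"segments {i} and {j} do not overlap "
                    f"({intervals[i]} vs {intervals[j]} mm)"
                )
    lo = min(iv[0] for iv in intervals)
    hi = max(iv[1] for iv in intervals)
    n = int(round((hi - lo) / spacing)) + 1
    grid = lo + spacing * np.arange(n)
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for seg, pos in zip(segments, shifted):
        v = seg.values[seg.mask]
        p = pos[seg.mask]
        gi = np.rint((p - lo) / spacing).astype(int)
        keep = (gi >= 0) & (gi < n)
        np.add.at(acc, gi[keep], v[keep])
        np.add.at(cnt, gi[keep], 1)
    mask = cnt > 0
    vals = np.where(mask, acc / np.maximum(cnt, 1), np.nan)
    return ThicknessProfile(grid, vals, mask)


def exclude_regions(
    profile: ThicknessProfile,
    rosette_mask: Optional[np.ndarray] = None,
    onh_halfwidth: float = ONH_HALFWIDTH_MM,
) -> ThicknessProfile:
    """Mask out rosette-flagged positions and the ONH exclusion zone."""
    mask = profile.mask.copy()
    if rosette_mask is not None:
        rosette_mask = np.asarray(rosette_mask, dtype=bool)
        if rosette_mask.shape != mask.shape:
            raise ValueError("rosette_mask must align with the profile grid")
        mask &= ~rosette_mask
    mask &= np.abs(profile.positions) >= onh_halfwidth
    if not mask.any():
        raise ValueError("all positions excluded")
    return ThicknessProfile(profile.positions, profile.values, mask)


def profile_mean_sd(
    profiles: Sequence[ThicknessProfile], per_eye: bool = False, group_label: str = ""
) -> CohortSummary:
    """Mean/SD over all valid points, or over per-eye means (``per_eye``)."""
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    if per_eye:
        vals = np.array([float(p.valid_values().mean()) for p in profiles])
    else:
        vals = np.concatenate([p.valid_values() for p in profiles])
    if vals.size == 0:
        raise ValueError("no valid points")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return CohortSummary(mean=float(vals.mean()), sd=sd, n=len(profiles), group_label=group_label)


def fraction_vs_baseline(group: CohortSummary, baseline: CohortSummary) -> float:
    """Group mean normalised to the baseline (youngest-age) mean."""
    if baseline.mean <= 0:
        raise ValueError("baseline mean must be positive")
    return group.mean / baseline.mean


def compare_groups(a: Sequence[float], b: Sequence[float], welch: bool = True) -> tuple:
    """Unpaired two-tailed t-test; Welch by default. Returns ``(t, p)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)
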