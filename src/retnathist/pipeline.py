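"""End-to-end orchestration: config validation, staged runs, provenance.

A run config is a YAML/JSON mapping with a ``seed``, an ``output_dir`` and an
ordered ``stages`` list; each stage is ``{name: {params...}}``.  Stage seeds
are derived deterministically from the run seed (SeedSequence spawn keyed by
stage index), so re-running an identical config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from retnathist import __version__, enface, fovea, io, natural_history, oct_layers, synthdata

__all__ = ["RunConfig", "ConfigError", "StageError", "run_pipeline", "load_config"]

log = logging.getLogger("retnathist")


class ConfigError(ValueError):
    """Config failed schema validation (exit code 1 at the CLI)."""


class StageError(RuntimeError):
    """A stage failed at run time (exit code 2 at the CLI)."""


#: stage name -> (required params, optional params)
STAGE_SCHEMAS = {
    "simulate_oct": (
        set(),
        {
            "n_eyes",
            "n_bscans",
            "n_lrps_per_bscan",
            "axial_px",
            "axial_scale",
            "lateral_scale",
            "bscan_spacing",
            "scan_axis",
            "repeats",
            "onl_thickness_mean",
            "onl_thickness_sd",
            "total_thickness_mean",
            "total_thickness_sd",
            "rpe_curvature_amplitude",
            "rosette_density_by_sector",
            "rosette_count_by_sector",
            "noise_sd",
        },
    ),
    "segment": (set(), {"rosette_mode", "min_prominence"}),
    "enface": (set(), {"scheme", "threshold_mode", "min_area", "onl_plus_hint_um"}),
    "simulate_erg": (
        {"intercept_log", "slope_log", "ages"},
        {"scatter_sd", "noise_floor", "n_per_age", "stimulus", "stratified_scatter"},
    ),
    "fit_decay": (set(), {"stimulus", "floor_policy", "noise_floor", "erg_csv"}),
    "plan_window": ({"inject_age", "assess_delay"}, {"asym_log", "noise_floor"}),
    "fovea": ({"profile_csv"}, set()),
}


@dataclass
class RunConfig:
    seed: int
    output_dir: Path
    stages: list  # of (name, params)
    log_level: str = "INFO"
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(source) -> RunConfig:
    """Parse and validate a config mapping, YAML text, or file path."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        raw = yaml.safe_load(Path(source).read_text())
    elif isinstance(source, str):
        raw = yaml.safe_load(source)
    else:
        raw = source
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    for key in ("seed", "output_dir", "stages"):
        if key not in raw:
            raise ConfigError(f"config missing required field {key!r}")
    if not isinstance(raw["seed"], int):
        raise ConfigError("field 'seed' must be an integer")
    if not isinstance(raw["stages"], list) or not raw["stages"]:
        raise ConfigError("field 'stages' must be a non-empty list")
    stages = []
    for i, entry in enumerate(raw["stages"]):
        if isinstance(entry, str):
            name, params = entry, {}
        elif isinstance(entry, dict) and len(entry) == 1:
            name, params = next(iter(entry.items()))
            params = params or {}
        else:
            raise ConfigError(f"stages[{i}] must be a stage name or one-key mapping")
        if name not in STAGE_SCHEMAS:
            raise ConfigError(f"stages[{i}]: unknown stage {name!r}")
        required, optional = STAGE_SCHEMAS[name]
        unknown = set(params) - required - optional
        if unknown:
            raise ConfigError(f"stages[{i}] ({name}): unknown parameter(s) {sorted(unknown)}")
        missing = required - set(params)
        if missing:
            raise ConfigError(f"stages[{i}] ({name}): missing parameter(s) {sorted(missing)}")
        stages.append((name, dict(params)))
    return RunConfig(
        seed=raw["seed"],
        output_dir=Path(raw["output_dir"]),
        stages=stages,
        log_level=str(raw.get("log_level", "INFO")),
        raw=raw,
    )


def _stage_seed(run_seed: int, stage_index: int) -> int:
    return int(np.random.SeedSequence(entropy=run_seed, spawn_key=(stage_index,)).generate_state(1)[0])


def _write_provenance(path: Path, cfg: RunConfig) -> None:
    prov = {"config_hash": cfg.config_hash, "seed": cfg.seed, "version": __version__}
    Path(str(path) + ".provenance.json").write_text(json.dumps(prov, indent=2))


def run_pipeline(source, log_stream=None) -> dict:
    """Execute the configured stages in order; returns the stats report.

    Artifacts are written under ``output_dir``; each carries a provenance
    sidecar with the config hash and seed.  Validation failures raise
    :class:`ConfigError` before anything runs; a failing stage raises
    :class:`StageError` with earlier outputs preserved.
    """
    cfg = load_config(source)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": cfg.config_hash, "seed": cfg.seed, "version": __version__}
    ctx: dict = {}
    for i, (name, params) in enumerate(cfg.stages):
        seed = _stage_seed(cfg.seed, i)
        log.info("stage %d: %s (seed %d)", i, name, seed)
        try:
            _STAGE_RUNNERS[name](params, seed, out, ctx, report, cfg)
        except (ConfigError,):
            raise
        except Exception as exc:  # noqa: BLE001 - partial outputs stay on disk
            raise StageError(f"stage {i} ({name}) failed: {exc}") from exc
    report_path = out / "report.json"
    report_path.write_text(json.dumps(io._jsonable(report), indent=2, default=float))
    _write_provenance(report_path, cfg)
    return report


# --------------------------------------------------------------------------- #
# Stage runners
# --------------------------------------------------------------------------- #


def _run_simulate_oct(params, seed, out, ctx, report, cfg):
    n_eyes = int(params.pop("n_eyes", 1))
    base = synthdata.OCTPhantomParams(**params, seed=seed)
    eyes = synthdata.cohort_phantoms(base, n_eyes, seed)
    ctx["volumes"], ctx["truths"] = [], []
    for k, p in enumerate(eyes):
        vol, truth = synthdata.gen_oct_volume(p)
        path = io.write_volume(vol, out / f"eye{k:03d}.tiff")
        _write_provenance(path, cfg)
        cent = pd.DataFrame(truth.rosette_centroids, columns=["x_mm", "y_mm", "sector"])
        io.write_table(cent, out / f"eye{k:03d}_centroids.csv", "centroids")
        truth_json = {
            "onl_plus_mean_um": float(np.mean(truth.onl_plus_map)),
            "total_mean_um": float(np.mean(truth.total_thickness_map)),
            "n_rosettes": len(truth.rosette_centroids),
        }
        (out / f"eye{k:03d}_truth.json").write_text(json.dumps(truth_json, indent=2))
        ctx["volumes"].append(vol)
        ctx["truths"].append(truth)
    report["simulate_oct"] = {"n_eyes": n_eyes}


def _run_segment(params, seed, out, ctx, report, cfg):
    if "volumes" not in ctx:
        raise StageError("segment requires a prior simulate_oct stage")
    summaries = []
    ctx["profiles"] = []
    for k, vol in enumerate(ctx["volumes"]):
        rpe = oct_layers.find_rpe_map(vol, params.get("min_prominence"))
        flat, _ = oct_layers.flatten(vol, rpe)
        seg = oct_layers.segment_volume(
            flat, min_prominence=params.get("min_prominence"),
            rosette_mode=params.get("rosette_mode", "extra_peak"),
        )
        onl, tot = oct_layers.volume_profiles(flat, seg)
        onl = oct_layers.exclude_regions(onl)
        tot = oct_layers.exclude_regions(tot)
        df = pd.DataFrame(
            {
                "position_mm": onl.positions,
                "onl_plus_um": onl.values,
                "total_um": tot.values,
                "mask": onl.mask.astype(int),
            }
        )
        path = io.write_table(df, out / f"eye{k:03d}_profile.csv", "profile")
        _write_provenance(path, cfg)
        ctx["profiles"].append((onl, tot))
    onl_summary = oct_layers.profile_mean_sd(
        [p[0] for p in ctx["profiles"]], per_eye=True, group_label="onl_plus"
    )
    tot_summary = oct_layers.profile_mean_sd(
        [p[1] for p in ctx["profiles"]], per_eye=True, group_label="total"
    )
    summaries = {
        "onl_plus": vars(onl_summary),
        "total": vars(tot_summary),
    }
    report["segment"] = summaries


def _run_enface(params, seed, out, ctx, report, cfg):
    if "volumes" not in ctx:
        raise StageError("enface requires a prior simulate_oct stage")
    scheme = params.get("scheme", "quadrants")
    tables = []
    for k, vol in enumerate(ctx["volumes"]):
        rpe = oct_layers.find_rpe_map(vol)
        flat, _ = oct_layers.flatten(vol, rpe)
        slab = enface.default_slab(
            flat.meta["rpe_target_um"], params.get("onl_plus_hint_um", 70.0)
        )
        emap = enface.integrate_slab(flat, *slab)
        spots = enface.detect_spots(
            emap,
            threshold_mode=params.get("threshold_mode", "otsu"),
            min_area=params.get("min_area", 2e-4),
        )
        io.write_table(spots.to_frame(), out / f"eye{k:03d}_spots.csv", "spots")
        tab = enface.sector_stats(spots, field_radius=0.75, scheme=scheme)
        path = io.write_table(tab, out / f"eye{k:03d}_sectors.csv", "sectors")
        _write_provenance(path, cfg)
        tables.append(tab.set_index("sector")["count"].to_dict())
    report["enface"] = {"scheme": scheme, "counts_per_eye": tables}


def _run_simulate_erg(params, seed, out, ctx, report, cfg):
    p = synthdata.ERGCohortParams(**params, seed=seed)
    df = synthdata.gen_erg_cohort(p)
    path = io.write_table(df, out / "erg.csv", "erg")
    _write_provenance(path, cfg)
    ctx["erg"] = df
    report["simulate_erg"] = {"n_records": len(df)}


def _run_fit_decay(params, seed, out, ctx, report, cfg):
    if "erg_csv" in params:
        df = io.read_table(params["erg_csv"], "erg")
    elif "erg" in ctx:
        df = ctx["erg"]
    else:
        raise StageError("fit_decay needs erg_csv or a prior simulate_erg stage")
    if "stimulus" in params:
        df = df[df["stimulus"] == params["stimulus"]]
    fit = natural_history.fit_decay(
        df,
        floor_policy=params.get("floor_policy", "drop"),
        noise_floor=params.get("noise_floor", 0.0),
    )
    ctx["fit"] = fit
    fit_json = {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "residual_sd": fit.residual_sd,
        "pi95": fit.pi95_halfwidth,
        "n": fit.n,
        "stimulus": fit.stimulus,
        "percent_per_day": natural_history.percent_per_day(fit),
    }
    path = out / "decay_fit.json"
    path.write_text(json.dumps(fit_json, indent=2))
    _write_provenance(path, cfg)
    report["fit_decay"] = fit_json


def _run_plan_window(params, seed, out, ctx, report, cfg):
    if "fit" not in ctx:
        raise StageError("plan_window requires a prior fit_decay stage")
    window = natural_history.plan_window(
        ctx["fit"],
        inject_age=params["inject_age"],
        assess_delay=params["assess_delay"],
        asym_log=params.get("asym_log", 0.3),
        noise_floor=params.get("noise_floor", 0.0),
    )
    wj = {k: (v.item() if isinstance(v, np.generic) else v) for k, v in vars(window).items()}
    path = out / "window.json"
    path.write_text(json.dumps(wj, indent=2))
    _write_provenance(path, cfg)
    report["plan_window"] = wj


def _run_fovea(params, seed, out, ctx, report, cfg):
    df = io.read_table(params["profile_csv"], "foveal_profile")
    profile = fovea.FovealProfile(
        df["eccentricity_mm"].to_numpy(), df["onl_um"].to_numpy()
    )
    avg = fovea.foveal_onl_average(profile)
    width = fovea.island_width_half_max(profile)
    fj = {
        "foveal_onl_average_um": avg,
        "island_width_mm": None if not width.defined else width.width_mm,
        "island_width_defined": width.defined,
    }
    path = out / "fovea.json"
    path.write_text(json.dumps(fj, indent=2))
    _write_provenance(path, cfg)
    report["fovea"] = fj


_STAGE_RUNNERS = {
    "simulate_oct": _run_simulate_oct,
    "segment": _run_segment,
    "enface": _run_enface,
    "simulate_erg": _run_simulate_erg,
    "fit_decay": _run_fit_decay,
    "plan_window": _run_plan_window,
    "fovea": _run_fovea,
}
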