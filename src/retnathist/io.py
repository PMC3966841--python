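"""Readers and writers: multi-page TIFF volumes with JSON sidecars, CSV tables.

Every volume travels with a ``<name>.json`` sidecar carrying scales,
orientation and provenance; writers and readers round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from retnathist.core import OCTVolume

__all__ = [
    "write_volume",
    "read_volume",
    "write_table",
    "read_table",
    "TABLE_SCHEMAS",
]

SIDECAR_KEYS = [
    "axial_scale",
    "lateral_scale",
    "bscan_spacing",
    "scan_axis",
    "onh_center",
    "repeats",
    "orientation",
    "n_pages",
]

TABLE_SCHEMAS = {
    "erg": ["animal_id", "age_days", "stimulus", "amplitude_uV"],
    "profile": ["position_mm", "onl_plus_um", "total_um", "mask"],
    "spots": ["x_mm", "y_mm", "area_mm2", "sector"],
    "sectors": ["sector", "count", "density_per_mm2"],
    "patients": ["id", "age_years", "acuity_code", "foveal_onl_um", "island_width_mm"],
    "foveal_profile": ["eccentricity_mm", "onl_um"],
    "centroids": ["x_mm", "y_mm", "sector"],
}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_volume(volume: OCTVolume, path) -> Path:
    """Write a volume as multi-page TIFF (one page per stored frame) + sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.data, photometric="minisblack")
    sidecar = {
        "axial_scale": volume.axial_scale,
        "lateral_scale": volume.lateral_scale,
        "bscan_spacing": volume.bscan_spacing,
        "scan_axis": volume.scan_axis,
        "onh_center": list(volume.onh_center),
        "repeats": volume.repeats,
        "orientation": volume.orientation,
        "n_pages": int(volume.data.shape[0]),
        "meta": _jsonable(volume.meta),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_volume(path) -> OCTVolume:
    """Read a TIFF volume; the JSON sidecar is required."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar_path.name}; required metadata keys: "
            + ", ".join(SIDECAR_KEYS)
        )
    sidecar = json.loads(sidecar_path.read_text())
    missing = [k for k in SIDECAR_KEYS if k not in sidecar]
    if missing:
        raise ValueError(f"sidecar {sidecar_path.name} missing keys: {', '.join(missing)}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != sidecar["n_pages"]:
        raise ValueError(
            f"TIFF has {data.shape[0]} pages but sidecar declares {sidecar['n_pages']}"
        )
    return OCTVolume(
        data=data,
        axial_scale=sidecar["axial_scale"],
        lateral_scale=sidecar["lateral_scale"],
        bscan_spacing=sidecar["bscan_spacing"],
        scan_axis=sidecar["scan_axis"],
        onh_center=tuple(sidecar["onh_center"]),
        repeats=sidecar["repeats"],
        orientation=sidecar["orientation"],
        meta=sidecar.get("meta", {}),
    )


def write_table(df: pd.DataFrame, path, schema: str) -> Path:
    """Write a CSV table after checking it matches a named column schema."""
    cols = TABLE_SCHEMAS[schema]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"table missing columns for schema {schema!r}: {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df[cols].to_csv(path, index=False)
    return path


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a CSV table, validating the header against a named schema."""
    cols = TABLE_SCHEMAS[schema]
    df = pd.read_csv(path)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(
            f"{Path(path).name}: header mismatch for schema {schema!r}; missing {missing}"
        )
    return df
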