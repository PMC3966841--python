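"""Shared data containers for OCT volumes and reflectivity profiles."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Orientation convention recorded in every volume sidecar: positive vertical
#: axis = superior (dorsal), positive horizontal axis = nasal.
DEFAULT_ORIENTATION = {"vertical_positive": "superior", "horizontal_positive": "nasal"}


@dataclass
class OCTVolume:
    """A raster of B-scans of longitudinal reflectivity profiles (LRPs).

    ``data`` has shape ``(n_frames, n_ascans, axial_px)`` where
    ``n_frames = n_bscans * repeats``; consecutive blocks of ``repeats``
    frames image the same B-scan location.

    Attributes
    ----------
    data : ndarray
        Reflectivity, arbitrary units, float32.
    axial_scale : float
        Axial sampling in micrometres per pixel.
    lateral_scale : float
        Within-B-scan lateral sampling in millimetres per pixel.
    bscan_spacing : float
        Spacing between adjacent B-scan locations in millimetres.
    scan_axis : str
        Anatomical axis the within-B-scan lateral dimension runs along,
        ``"vertical"`` (superior/inferior) or ``"horizontal"`` (nasal/temporal).
    onh_center : tuple
        ``(bscan_index, ascan_index)`` of the optic nerve head, in pixels
        (fractional allowed).
    repeats : int
        Number of stored repeat frames per B-scan location.
    orientation : dict
        Anatomical sign convention of the two lateral axes.
    meta : dict
        Free-form provenance (seed, generator parameters, config hash...).
    """

    data: np.ndarray
    axial_scale: float
    lateral_scale: float
    bscan_spacing: float = 0.0
    scan_axis: str = "vertical"
    onh_center: tuple = (0.0, 0.0)
    repeats: int = 1
    orientation: dict = field(default_factory=lambda: dict(DEFAULT_ORIENTATION))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got shape {self.data.shape}")
        if self.axial_scale <= 0 or self.lateral_scale <= 0:
            raise ValueError("axial_scale and lateral_scale must be positive")
        if self.repeats < 1 or self.data.shape[0] % self.repeats:
            raise ValueError(
                f"{self.data.shape[0]} stored frames not divisible by repeats={self.repeats}"
            )

    @property
    def n_bscans(self) -> int:
        return self.data.shape[0] // self.repeats

    @property
    def n_ascans(self) -> int:
        return self.data.shape[1]

    @property
    def axial_px(self) -> int:
        return self.data.shape[2]

    @property
    def axial_extent_um(self) -> float:
        return self.axial_px * self.axial_scale

    def ascan_positions_mm(self) -> np.ndarray:
        """Signed within-B-scan lateral positions (mm) relative to the ONH."""
        idx = np.arange(self.n_ascans, dtype=float)
        return (idx - self.onh_center[1]) * self.lateral_scale

    def bscan_positions_mm(self) -> np.ndarray:
        """Signed B-scan-axis positions (mm) relative to the ONH."""
        idx = np.arange(self.n_bscans, dtype=float)
        return (idx - self.onh_center[0]) * self.bscan_spacing


@dataclass
class LRP:
    """A single longitudinal reflectivity profile (one A-scan location)."""

    reflectivity: np.ndarray
    axial_scale: float
    lateral_position: float = 0.0

    def __post_init__(self) -> None:
        self.reflectivity = np.asarray(self.reflectivity, dtype=float)
        if self.reflectivity.ndim != 1 or self.reflectivity.size < 3:
            raise ValueError("an LRP needs at least 3 axial samples")
        if self.axial_scale <= 0:
            raise ValueError("axial_scale must be positive")

    @property
    def depths_um(self) -> np.ndarray:
        return np.arange(self.reflectivity.size) * self.axial_scale
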