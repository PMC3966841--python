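"""Shared fixtures: small phantoms generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from retnathist.core import LRP
from retnathist import synthdata as sd


def make_banded_lrp(bands, axial_px=420, axial_scale=1.0, noise_sd=0.0, seed=0):
    """LRP that is a sum of Gaussian bands: bands = [(depth, amp, width), ...]."""
    z = np.arange(axial_px) * axial_scale
    prof = np.zeros(axial_px)
    for depth, amp, width in bands:
        prof += amp * np.exp(-0.5 * ((z - depth) / width) ** 2)
    if noise_sd:
        prof += np.random.default_rng(seed).normal(0, noise_sd, axial_px)
    return LRP(prof, axial_scale)


#: Clean anatomy on a 1 um grid: vri 48, inner 100, OPL 150, S+ 210, RPE 280,
#: choroid 330.  Troughs fall exactly at 180 and 245 -> ONL+ = 65 um.
CLEAN_BANDS = [
    (48, 1.0, 7.0),
    (100, 0.7, 7.0),
    (150, 0.9, 7.0),
    (210, 0.9, 7.0),
    (280, 0.9, 7.0),
    (330, 0.75, 9.0),
]


@pytest.fixture
def clean_lrp():
    return make_banded_lrp(CLEAN_BANDS)


@pytest.fixture
def clean_volume():
    """Noise-free, rosette-free, flat-RPE phantom (ONL+ 65, total 197.4)."""
    params = sd.OCTPhantomParams(
        n_bscans=2, n_lrps_per_bscan=120, onl_thickness_mean=65.0,
        total_thickness_mean=197.4, noise_sd=0.0, seed=11,
    )
    return sd.gen_oct_volume(params)


@pytest.fixture
def curved_noisy_volume():
    params = sd.OCTPhantomParams(
        n_bscans=3, n_lrps_per_bscan=150, onl_thickness_mean=66.4,
        total_thickness_mean=197.4, rpe_curvature_amplitude=20.0,
        noise_sd=0.05, seed=21,
    )
    return sd.gen_oct_volume(params)
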