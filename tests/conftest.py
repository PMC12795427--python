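"""Shared fixtures: desk-scale phantoms reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from retquant import layer_analysis as la
from retquant import octa_density as od
from retquant import synthetic_data as syn


def noisefree_config(**overrides) -> syn.PhantomConfig:
    """Phantom config with no speckle, noise, vessels or spatial variation."""
    kw = dict(
        n_fast=96,
        n_slow=80,
        n_depth=256,
        seed=0,
        speckle_contrast=0.0,
        noise_floor=0.0,
        layer_variation_um=0.0,
        surface_undulation_um=0.0,
        snr_falloff=0.0,
        vessel_density={"SVP": 0.0, "ICP": 0.0, "DCP": 0.0},
    )
    kw.update(overrides)
    return syn.PhantomConfig(**kw)


def truth_in_flat_frame(truth, flat: la.FlattenResult) -> dict[str, np.ndarray]:
    """Ground-truth surfaces expressed in the flattened volume's frame."""
    shift_um = flat.shift_px * truth.dz_um
    return {name: s - shift_um for name, s in truth.surfaces_um.items()}


@pytest.fixture(scope="session")
def phantom_small():
    """Speckled phantom with vessels in all plexuses, flat SNR profile."""
    cfg = syn.PhantomConfig(n_fast=96, n_slow=80, n_depth=224, seed=7, snr_falloff=0.0)
    vol, truth = syn.generate_phantom(cfg)
    return cfg, vol, truth


@pytest.fixture(scope="session")
def segmented_small(phantom_small):
    cfg, vol, truth = phantom_small
    flat = la.flatten_volume(vol)
    surfaces = la.segment_layers(flat.volume, onh_center_um=truth.onh_center_um)
    return flat, surfaces


@pytest.fixture(scope="session")
def enfaces_small(phantom_small, segmented_small):
    cfg, vol, truth = phantom_small
    flat, surfaces = segmented_small
    decorr = od.compute_octa(flat.volume)
    return od.project_slabs(decorr, flat.volume, surfaces, onh_center_um=truth.onh_center_um)
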