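"""OCTA contrast, slab projection, binarization, SNR zones and gated density."""

import numpy as np
import pytest

from retquant import layer_analysis as la
from retquant import octa_density as od
from retquant import synthetic_data as syn


def _bare_volume(arr, dz=1.5):
    return la.OCTVolume(intensity=arr, dx_um=2.0, dy_um=2.0, dz_um=dz)


# ---------------------------------------------------------------------------
# compute_octa


def test_identical_repeats_give_zero_decorrelation():
    rng = np.random.default_rng(0)
    frame = rng.rayleigh(1.0, size=(24, 20, 64)).astype(np.float32)
    vol = _bare_volume(np.stack([frame] * 4))
    assert od.compute_octa(vol).max() == 0.0


def test_single_repeat_rejected():
    vol = _bare_volume(np.ones((1, 8, 8, 32), dtype=np.float32))
    with pytest.raises(ValueError, match="repeats"):
        od.compute_octa(vol)


def test_five_repeats_average_the_four_adjacent_pairs():
    cfg = syn.PhantomConfig(n_fast=48, n_slow=40, n_depth=224, seed=5, snr_falloff=0.0)
    vol, _ = syn.generate_phantom(cfg)
    full = od.compute_octa(vol)
    pair_maps = []
    for r in range(4):
        pair = la.OCTVolume(
            intensity=vol.intensity[r : r + 2],
            dx_um=vol.dx_um, dy_um=vol.dy_um, dz_um=vol.dz_um,
        )
        pair_maps.append(od.compute_octa(pair))
    assert np.allclose(np.mean(pair_maps, axis=0), full, atol=1e-5)


def test_vessel_voxels_decorrelate_much_more_than_static(phantom_small, enfaces_small):
    _, _, truth = phantom_small
    svp = enfaces_small["SVP"]
    mask = truth.vessel_masks["SVP"]
    assert svp.decorr[mask].mean() - svp.decorr[~mask].mean() >= 0.5


# ---------------------------------------------------------------------------
# project_slabs


def test_all_zero_decorrelation_projects_to_zero(phantom_small, segmented_small):
    _, vol, truth = phantom_small
    flat, surfaces = segmented_small
    zeros = np.zeros(vol.shape, dtype=np.float32)
    enf = od.project_slabs(zeros, flat.volume, surfaces)
    for p in od.SLAB_SURFACES:
        assert enf[p].decorr.max() == 0.0


def test_vessels_confined_to_their_slab():
    cfg = syn.PhantomConfig(
        n_fast=96, n_slow=80, n_depth=224, seed=6, snr_falloff=0.0,
        vessel_density={"SVP": 0.2, "ICP": 0.0, "DCP": 0.0},
    )
    vol, truth = syn.generate_phantom(cfg)
    flat = la.flatten_volume(vol)
    surfaces = la.segment_layers(flat.volume, onh_center_um=truth.onh_center_um)
    decorr = od.compute_octa(flat.volume)
    enf = od.project_slabs(decorr, flat.volume, surfaces, onh_center_um=truth.onh_center_um)
    assert enf["SVP"].decorr[truth.vessel_masks["SVP"]].mean() > 0.8
    assert np.percentile(enf["ICP"].decorr, 99) < 0.1
    assert np.percentile(enf["DCP"].decorr, 99) < 0.1


def test_slab_projection_bounded_by_full_depth_projection(
    phantom_small, segmented_small
):
    _, vol, truth = phantom_small
    flat, surfaces = segmented_small
    decorr = od.compute_octa(flat.volume)
    full_max = decorr.max(axis=-1)
    enf = od.project_slabs(decorr, flat.volume, surfaces)
    for p in od.SLAB_SURFACES:
        assert np.all(enf[p].decorr <= full_max + 1e-6)


# ---------------------------------------------------------------------------
# binarization and exclusions


def _enface(decorr, signal, floor=1.0, dx=2.0, dy=2.0, center=None):
    shape = decorr.shape
    if center is None:
        center = ((shape[0] - 1) / 2 * dx, (shape[1] - 1) / 2 * dy)
    return od.AngioEnface(
        plexus="SVP", decorr=decorr, mean_signal=signal,
        noise_floor=floor, dx_um=dx, dy_um=dy, onh_center_um=center,
    )


def test_uniform_low_signal_background_gives_empty_mask():
    rng = np.random.default_rng(1)
    enface = _enface(
        rng.uniform(0, 0.05, (64, 64)), np.full((64, 64), 2.0), floor=1.0
    )
    mask = od.binarize_vessels(enface)
    assert not mask.vessel.any()  # 2x the floor is below the 10x signal gate


def test_border_margin_is_zeroed_everywhere():
    rng = np.random.default_rng(2)
    enface = _enface(rng.uniform(0, 1, (64, 64)), np.full((64, 64), 100.0))
    mask = od.binarize_vessels(enface, margin_px=10)
    assert not mask.vessel[:10, :].any()
    assert not mask.vessel[-10:, :].any()
    assert not mask.vessel[:, :10].any()
    assert not mask.vessel[:, -10:].any()
    assert mask.excluded[:10, :].all()


def test_single_bright_tube_recovered_with_good_precision_recall():
    n = 96
    decorr = np.zeros((n, n), dtype=float)
    truth = np.zeros((n, n), dtype=bool)
    rows = np.arange(n)
    center_col = (n // 2 + 6 * np.sin(rows / 11.0)).astype(int)
    for i in rows:
        truth[i, center_col[i] - 2 : center_col[i] + 3] = True
    decorr[truth] = 0.9
    rng = np.random.default_rng(3)
    decorr += rng.uniform(0, 0.03, size=decorr.shape)
    enface = _enface(decorr, np.full((n, n), 50.0), floor=1.0)
    mask = od.binarize_vessels(enface, margin_px=4)
    from scipy import ndimage

    interior = np.ones_like(truth)
    interior[:4] = interior[-4:] = False
    interior[:, :4] = interior[:, -4:] = False
    eroded = ndimage.binary_erosion(truth) & interior
    got = mask.vessel & interior
    recall = (got & eroded).sum() / eroded.sum()
    precision = (got & ndimage.binary_dilation(truth)).sum() / max(got.sum(), 1)
    assert recall >= 0.8
    assert precision >= 0.8


def test_onh_cutout_matches_brute_force_count():
    n, dx, dy = 64, 2.0, 2.0
    vessel = np.ones((n, n), dtype=bool)
    mask = od.VesselMask(
        vessel=vessel, excluded=np.zeros_like(vessel), border_margin_px=0
    )
    center = ((n - 1) / 2 * dx, (n - 1) / 2 * dy)
    cut = od.cut_onh(mask, center, dx, dy, radius_um=100.0)
    brute = sum(
        1
        for i in range(n)
        for j in range(n)
        if np.hypot(i * dx - center[0], j * dy - center[1]) < 100.0
    )
    assert (~cut.vessel).sum() == brute
    assert cut.excluded.sum() == brute


def test_onh_cutout_radius_zero_is_identity():
    rng = np.random.default_rng(4)
    vessel = rng.random((32, 32)) > 0.5
    mask = od.VesselMask(vessel=vessel, excluded=np.zeros_like(vessel), border_margin_px=0)
    cut = od.cut_onh(mask, (10.0, 10.0), 2.0, 2.0, radius_um=0.0)
    assert np.array_equal(cut.vessel, vessel)
    assert not cut.excluded.any()


def test_onh_cutout_at_corner_removes_quarter_disc():
    n, d = 64, 2.0
    vessel = np.ones((n, n), dtype=bool)
    mask = od.VesselMask(vessel=vessel, excluded=np.zeros_like(vessel), border_margin_px=0)
    cut = od.cut_onh(mask, (0.0, 0.0), d, d, radius_um=40.0)
    brute = sum(
        1 for i in range(n) for j in range(n) if np.hypot(i * d, j * d) < 40.0
    )
    assert (~cut.vessel).sum() == brute


# ---------------------------------------------------------------------------
# SNR sector map


def test_uniform_signal_gives_constant_zone_snr():
    enface = _enface(np.zeros((64, 64)), np.full((64, 64), 30.0), floor=2.0)
    grid = od.snr_sector_map(enface, ring_width_um=20.0)
    for snr in grid.zone_snr.values():
        assert snr == pytest.approx(15.0)


def test_radially_decaying_signal_has_nonincreasing_ring_snr():
    n, d = 96, 2.0
    center = ((n - 1) / 2 * d, (n - 1) / 2 * d)
    dist = la.radial_distance_um((n, n), center, d, d)
    signal = 100.0 / (1.0 + dist / 30.0)
    enface = _enface(np.zeros((n, n)), signal, floor=1.0, center=center)
    grid = od.snr_sector_map(enface, ring_width_um=20.0)
    for q in range(4):
        rings = sorted(r for (qq, r) in grid.zone_snr if qq == q)
        snrs = [grid.zone_snr[(q, r)] for r in rings]
        assert all(a >= b - 1e-9 for a, b in zip(snrs, snrs[1:]))


def test_max_ring_index_for_centered_onh_is_seven():
    """1000 um field, centered ONH, 100 um rings: corners at ~707 um."""
    n = 100
    dx = 1000.0 / n
    center = ((n - 1) / 2 * dx, (n - 1) / 2 * dx)
    enface = _enface(
        np.zeros((n, n)), np.ones((n, n)), floor=1.0, dx=dx, dy=dx, center=center
    )
    grid = od.snr_sector_map(enface, ring_width_um=100.0)
    assert grid.ring.max() == 7


# ---------------------------------------------------------------------------
# gated density


def _grid_one_zone(shape, snr):
    quad = np.zeros(shape, dtype=np.int8)
    ring = np.zeros(shape, dtype=np.int32)
    return od.SectorGrid(
        quadrant=quad, ring=ring, ring_width_um=100.0,
        zone_snr={(0, 0): snr}, zone_n={(0, 0): int(np.prod(shape))},
    )


def test_all_vessel_mask_gives_100_percent():
    shape = (40, 40)
    mask = od.VesselMask(
        vessel=np.ones(shape, bool), excluded=np.zeros(shape, bool), border_margin_px=0
    )
    res = od.gated_vessel_density(mask, _grid_one_zone(shape, 25.0), "SVP")
    assert res.density_pct == pytest.approx(100.0)


def test_checkerboard_zone_gives_exactly_50_percent():
    shape = (40, 40)
    vessel = np.indices(shape).sum(axis=0) % 2 == 0
    mask = od.VesselMask(
        vessel=vessel, excluded=np.zeros(shape, bool), border_margin_px=0
    )
    res = od.gated_vessel_density(mask, _grid_one_zone(shape, 25.0), "SVP")
    assert res.density_pct == pytest.approx(50.0)
    assert res.n_positive == res.n_negative == 800


def test_no_included_zone_is_missing_not_zero():
    shape = (40, 40)
    mask = od.VesselMask(
        vessel=np.ones(shape, bool), excluded=np.zeros(shape, bool), border_margin_px=0
    )
    res = od.gated_vessel_density(mask, _grid_one_zone(shape, 5.0), "SVP")
    assert res.missing
    assert res.density_pct is None


def test_dcp_gate_admits_every_zone_the_svp_gate_admits():
    rng = np.random.default_rng(5)
    shape = (64, 64)
    quad = rng.integers(0, 4, size=shape).astype(np.int8)
    ring = rng.integers(0, 3, size=shape).astype(np.int32)
    zone_snr = {
        (q, r): float(rng.uniform(5, 40)) for q in range(4) for r in range(3)
    }
    zone_n = {k: int(((quad == k[0]) & (ring == k[1])).sum()) for k in zone_snr}
    grid = od.SectorGrid(
        quadrant=quad, ring=ring, ring_width_um=100.0,
        zone_snr=zone_snr, zone_n=zone_n,
    )
    vessel = rng.random(shape) > 0.7
    mask = od.VesselMask(
        vessel=vessel, excluded=np.zeros(shape, bool), border_margin_px=0
    )
    svp = od.gated_vessel_density(mask, grid, "SVP")
    dcp = od.gated_vessel_density(mask, grid, "DCP")
    assert dcp.n_zones_included >= svp.n_zones_included
    assert dcp.n_positive + dcp.n_negative >= svp.n_positive + svp.n_negative


def test_gating_is_local_to_each_zone():
    """Dropping some zones below the gate never changes the counts
    contributed by the remaining zones."""
    shape = (60, 60)
    quad = (np.indices(shape)[0] // 30).astype(np.int8)  # two zones: 0 and 1
    ring = np.zeros(shape, dtype=np.int32)
    vessel = np.random.default_rng(6).random(shape) > 0.6
    mask = od.VesselMask(
        vessel=vessel, excluded=np.zeros(shape, bool), border_margin_px=0
    )

    def run(snr_b):
        grid = od.SectorGrid(
            quadrant=quad, ring=ring, ring_width_um=100.0,
            zone_snr={(0, 0): 30.0, (1, 0): snr_b},
            zone_n={(0, 0): 1800, (1, 0): 1800},
        )
        return od.gated_vessel_density(mask, grid, "SVP")

    both = run(30.0)
    only_a = run(5.0)
    in_a = quad == 0
    assert only_a.n_positive == int((vessel & in_a).sum())
    assert only_a.n_negative == int((~vessel & in_a).sum())
    assert both.n_positive == int(vessel.sum())


def test_density_invariant_under_quadrant_relabeling():
    shape = (60, 60)
    rng = np.random.default_rng(7)
    quad = rng.integers(0, 4, size=shape).astype(np.int8)
    ring = np.zeros(shape, dtype=np.int32)
    vessel = rng.random(shape) > 0.65
    mask = od.VesselMask(
        vessel=vessel, excluded=np.zeros(shape, bool), border_margin_px=0
    )
    zone_snr = {(q, 0): 25.0 for q in range(4)}
    zone_n = {(q, 0): int((quad == q).sum()) for q in range(4)}
    g1 = od.SectorGrid(quad, ring, 100.0, zone_snr, zone_n)
    perm = (2, 3, 1, 0)
    quad2 = np.vectorize(lambda q: perm[q])(quad).astype(np.int8)
    zone_n2 = {(q, 0): int((quad2 == q).sum()) for q in range(4)}
    g2 = od.SectorGrid(quad2, ring, 100.0, zone_snr, zone_n2)
    r1 = od.gated_vessel_density(mask, g1, "SVP")
    r2 = od.gated_vessel_density(mask, g2, "SVP")
    assert r1.density_pct == pytest.approx(r2.density_pct)
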