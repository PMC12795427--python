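"""Retinal layer segmentation and en-face thickness mapping for volumetric OCT.

The pipeline operates on reconstructed OCT intensity volumes of the mouse
retina acquired around the optic nerve head (ONH).  An auxiliary
depolarization channel (from polarization-sensitive acquisition) marks the
retinal pigment epithelium (RPE), which is used as the flattening reference:
every A-scan is shifted axially so that the depolarizing RPE sits at a common
depth.  Boundary surfaces are then located by an axial intensity-gradient
search within anatomically ordered bands, smoothed laterally and projected
onto the set of ordered surfaces.  Thickness maps for the six sublayers
(RNFL/GCL complex, IPL, INL, OPL, photoreceptor complex, RPE), the inner and
outer retinal complexes (IRL = RNFL/GCL + IPL + INL, ORL = OPL + PRC + RPE)
and the total retina (ILM to posterior RPE) are derived from the surfaces,
and summarised over an annulus (default 200-600 um from the ONH) split into
four sectors by the diagonals of the square field of view.

Physical coordinates: en-face origin at the (fast=0, slow=0) corner, pixel
centers at ``index * spacing`` micrometers.  The annulus membership test is
half-open, ``r_in <= r < r_out``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "LAYERS",
    "SURFACES",
    "COMPLEXES",
    "SECTORS",
    "OCTVolume",
    "FlattenResult",
    "LayerSurfaces",
    "ThicknessMap",
    "SectorSummary",
    "FlattenError",
    "SegmentationError",
    "flatten_volume",
    "segment_layers",
    "thickness_maps",
    "annulus_sector_average",
    "detect_onh_center",
    "sector_labels",
]

#: Retinal sublayers, ordered anterior to posterior.
LAYERS = ("RNFL_GCL", "IPL", "INL", "OPL", "PRC", "RPE")

#: Boundary surfaces, ordered anterior to posterior.  Surface k is the
#: anterior face of ``LAYERS[k]``; the last entry is the posterior RPE face.
SURFACES = (
    "ILM",
    "RNFL_GCL/IPL",
    "IPL/INL",
    "INL/OPL",
    "OPL/PRC",
    "PRC/RPE",
    "RPE_POST",
)

#: Derived layer complexes (inner/outer retina and the full retina).
COMPLEXES = ("TOTAL", "IRL", "ORL")

#: Sector names in image-frame order: top, right, bottom, left of the
#: en-face grid.  True anatomical orientation depends on eye laterality.
SECTORS = ("superior", "nasal", "inferior", "temporal")


class FlattenError(RuntimeError):
    """Raised when a volume cannot be flattened (e.g. too little depolarizing
    signal to localise the RPE, emulating a quality exclusion)."""


class SegmentationError(RuntimeError):
    """Raised when the boundary search produces an inconsistent ordering."""


@dataclass
class OCTVolume:
    """Reconstructed OCT intensity volume with optional depolarization channel.

    Parameters
    ----------
    intensity
        Linear-scale amplitude, shape ``(repeats, fast, slow, depth)``.
    depolarization
        Degree of polarization scrambling in ``[0, 1]``, shape
        ``(fast, slow, depth)``; marks the RPE band.  Optional.
    dx_um, dy_um, dz_um
        Pixel spacings along fast, slow and depth axes in micrometers.
    """

    intensity: np.ndarray
    dx_um: float
    dy_um: float
    dz_um: float
    depolarization: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 4:
            raise ValueError(
                "intensity must have shape (repeats, fast, slow, depth), got "
                f"{self.intensity.shape}"
            )
        for name in ("dx_um", "dy_um", "dz_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.depolarization is not None:
            self.depolarization = np.asarray(self.depolarization)
            if self.depolarization.shape != self.intensity.shape[1:]:
                raise ValueError(
                    "depolarization shape must match intensity lateral/depth dims"
                )

    @property
    def n_repeats(self) -> int:
        return self.intensity.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        """En-face-major shape ``(fast, slow, depth)``."""
        return self.intensity.shape[1:]

    def mean_intensity(self) -> np.ndarray:
        """Repeat-averaged intensity, shape ``(fast, slow, depth)``."""
        return self.intensity.mean(axis=0)


@dataclass
class FlattenResult:
    """Output of :func:`flatten_volume`."""

    volume: OCTVolume
    rpe_depth_um: np.ndarray  # original-frame RPE depth per A-scan
    shift_px: np.ndarray  # fractional axial shift applied per A-scan
    reference_px: int  # depth index the RPE was moved to
    valid: np.ndarray  # A-scans with usable depolarizing signal

    def __iter__(self):
        # allow ``flat, rpe = flatten_volume(vol)`` unpacking
        return iter((self.volume, self.rpe_depth_um))


@dataclass
class LayerSurfaces:
    """Per-boundary depth maps (um) on the en-face grid.

    ``depth_um[name]`` gives the depth of surface ``name`` (one of
    :data:`SURFACES`) at every en-face position, in the frame of the volume
    they were segmented from.  Surfaces are strictly ordered in depth at
    every position outside the ONH exclusion disc.
    """

    depth_um: dict[str, np.ndarray]
    dx_um: float
    dy_um: float
    dz_um: float
    onh_center_um: tuple[float, float] | None = None
    onh_radius_um: float = 100.0
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = [s for s in SURFACES if s not in self.depth_um]
        if missing:
            raise ValueError(f"missing surfaces: {missing}")
        if self.valid is None:
            self.valid = np.ones(self.depth_um[SURFACES[0]].shape, dtype=bool)

    def check_ordering(self, where: np.ndarray | None = None) -> None:
        """Raise :class:`SegmentationError` if surfaces are not ordered."""
        if where is None:
            where = np.ones(self.depth_um[SURFACES[0]].shape, dtype=bool)
        for upper, lower in zip(SURFACES[:-1], SURFACES[1:]):
            bad = (self.depth_um[lower] <= self.depth_um[upper]) & where
            if bad.any():
                raise SegmentationError(
                    f"surface ordering violated: {lower} not below {upper} at "
                    f"{int(bad.sum())} pixels"
                )


@dataclass
class ThicknessMap:
    """En-face thickness map (um) for one layer or layer complex."""

    layer: str
    values_um: np.ndarray
    dx_um: float
    dy_um: float
    onh_center_um: tuple[float, float] | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.values_um.shape, dtype=bool)


@dataclass
class SectorSummary:
    """Annulus summary: per-sector and overall mean thickness."""

    layer: str
    r_in_um: float
    r_out_um: float
    sector_mean_um: dict[str, float]
    sector_n: dict[str, int]
    overall_mean_um: float
    n_pixels: int


# ---------------------------------------------------------------------------
# flattening


def _inpaint_nearest(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid entries with the nearest valid value (euclidean)."""
    if valid.all():
        return values
    idx = ndimage.distance_transform_edt(
        ~valid, return_distances=False, return_indices=True
    )
    return values[tuple(idx)]


def _depol_band(
    depol: np.ndarray, level: float = 0.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sub-pixel anterior edge, posterior edge and validity of the
    depolarizing band in every A-scan.

    The band is where the depolarization channel exceeds ``level`` times its
    per-A-scan maximum; both edges are refined by linear interpolation of
    the threshold crossing, which centers the estimate on the true edge
    (the raw first/last above-threshold indices are biased by the one-pixel
    axial sampling of the channel).
    """
    n_depth = depol.shape[-1]
    peak = depol.max(axis=-1)
    valid = peak > 0.05
    thresh = np.maximum(level * peak, 1e-6)
    above = depol >= thresh[..., None]
    any_above = above.any(axis=-1)
    valid &= any_above

    k_top = above.argmax(axis=-1)
    k_bot = n_depth - 1 - above[..., ::-1].argmax(axis=-1)

    def _val(idx):
        return np.take_along_axis(depol, idx[..., None], axis=-1)[..., 0]

    v_top = _val(k_top)
    v_prev = np.where(k_top > 0, _val(np.maximum(k_top - 1, 0)), 0.0)
    denom = v_top - v_prev
    frac = np.where(np.abs(denom) > 1e-9, (thresh - v_prev) / np.where(
        np.abs(denom) > 1e-9, denom, 1.0), 0.5)
    top = k_top - 1 + np.clip(frac, 0.0, 1.0)

    v_bot = _val(k_bot)
    v_next = np.where(k_bot < n_depth - 1, _val(np.minimum(k_bot + 1, n_depth - 1)), 0.0)
    denom_b = v_bot - v_next
    frac_b = np.where(np.abs(denom_b) > 1e-9, (v_bot - thresh) / np.where(
        np.abs(denom_b) > 1e-9, denom_b, 1.0), 0.5)
    bottom = k_bot + np.clip(frac_b, 0.0, 1.0)
    return top, bottom, valid


def flatten_volume(
    vol: OCTVolume,
    reference_px: int | None = None,
    smooth_sigma_px: float = 2.0,
    max_invalid_frac: float = 0.3,
) -> FlattenResult:
    """Flatten a volume with respect to the depolarizing RPE.

    The RPE depth of every A-scan is the depolarization-weighted centroid
    depth, laterally smoothed; each A-scan is shifted (integer pixels) so
    that the RPE sits at a common reference depth.  A-scans without a
    depolarizing signal (e.g. inside the ONH) are in-painted from their
    nearest valid neighbours.

    Raises
    ------
    FlattenError
        If no depolarization channel is present or more than
        ``max_invalid_frac`` of the A-scans carry no depolarizing signal.
    """
    if vol.depolarization is None:
        raise FlattenError("flattening requires a depolarization channel")
    depol = vol.depolarization
    n_fast, n_slow, n_depth = vol.shape

    weight = depol.sum(axis=-1)
    valid = weight > 0.05 * max(float(weight.max()), 1e-12)
    invalid_frac = 1.0 - valid.mean()
    if invalid_frac > max_invalid_frac:
        raise FlattenError(
            f"{invalid_frac:.0%} of A-scans have no depolarizing signal "
            f"(limit {max_invalid_frac:.0%}); volume excluded"
        )

    z = np.arange(n_depth, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        centroid = (depol * z).sum(axis=-1) / np.where(valid, weight, np.nan)
    centroid = _inpaint_nearest(centroid, valid)
    if smooth_sigma_px > 0:
        centroid = ndimage.gaussian_filter(centroid, smooth_sigma_px)

    if reference_px is None:
        reference_px = int(round(float(np.median(centroid))))
    shift = centroid - reference_px  # fractional: shifted by linear interp

    base = np.floor(shift)
    frac = (shift - base).astype(np.float32)[..., None]
    idx0 = z[None, None, :].astype(np.int64) + base.astype(np.int64)[:, :, None]
    idx1 = idx0 + 1
    oob0 = (idx0 < 0) | (idx0 >= n_depth)
    oob1 = (idx1 < 0) | (idx1 >= n_depth)
    idx0 = np.clip(idx0, 0, n_depth - 1)
    idx1 = np.clip(idx1, 0, n_depth - 1)

    def _shift_one(a: np.ndarray) -> np.ndarray:
        lo = np.take_along_axis(a, idx0, axis=-1)
        lo[oob0] = 0.0
        hi = np.take_along_axis(a, idx1, axis=-1)
        hi[oob1] = 0.0
        return (1.0 - frac) * lo + frac * hi

    out = np.empty_like(vol.intensity)
    for r in range(vol.n_repeats):
        out[r] = _shift_one(vol.intensity[r])
    depol_out = _shift_one(depol.astype(np.float32))

    flat = OCTVolume(
        intensity=out,
        depolarization=depol_out,
        dx_um=vol.dx_um,
        dy_um=vol.dy_um,
        dz_um=vol.dz_um,
    )
    return FlattenResult(
        volume=flat,
        rpe_depth_um=centroid * vol.dz_um,
        shift_px=shift,
        reference_px=reference_px,
        valid=valid,
    )  # shift_px is fractional; original depth = flat depth + shift * dz


# ---------------------------------------------------------------------------
# segmentation

#: Interior boundary search-band centers as fractions of the ILM-to-RPE span,
#: with half-widths and the expected axial gradient sign at the boundary.
#: Fractions follow typical murine retina proportions (plexiform layers
#: bright, nuclear layers dark).
_INTERIOR_BANDS: dict[str, tuple[float, float, int]] = {
    "RNFL_GCL/IPL": (0.156, 0.075, -1),
    "IPL/INL": (0.330, 0.075, -1),
    "INL/OPL": (0.458, 0.045, +1),
    "OPL/PRC": (0.514, 0.045, -1),
}

#: Total retinal thickness prior (um) used to locate the ILM above the RPE.
_TOTAL_PRIOR_UM = (140.0, 320.0)


def _band_argmax(
    signal: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    """Per-A-scan argmax of ``signal`` restricted to ``lo <= z <= hi``,
    refined to sub-pixel precision by a parabola through the extremum and
    its axial neighbours."""
    n_depth = signal.shape[-1]
    z = np.arange(n_depth)
    inside = (z[None, None, :] >= lo[..., None]) & (z[None, None, :] <= hi[..., None])
    masked = np.where(inside, signal, -np.inf)
    k = masked.argmax(axis=-1)
    km = np.clip(k - 1, 0, n_depth - 1)
    kp = np.clip(k + 1, 0, n_depth - 1)
    g0 = np.take_along_axis(signal, k[..., None], axis=-1)[..., 0]
    gm = np.take_along_axis(signal, km[..., None], axis=-1)[..., 0]
    gp = np.take_along_axis(signal, kp[..., None], axis=-1)[..., 0]
    denom = gm - 2.0 * g0 + gp
    with np.errstate(divide="ignore", invalid="ignore"):
        offset = 0.5 * (gm - gp) / denom
    offset = np.where(np.abs(denom) > 1e-12, offset, 0.0)
    return k + np.clip(offset, -0.5, 0.5)


def segment_layers(
    flat: OCTVolume,
    onh_center_um: tuple[float, float] | None = None,
    onh_radius_um: float = 100.0,
    median_window_px: int = 15,
    bands: dict[str, tuple[float, float, int]] | None = None,
) -> LayerSurfaces:
    """Segment the seven retinal boundary surfaces of a flattened volume.

    The depolarizing band gives the anterior and posterior RPE faces
    directly.  The ILM is the strongest positive axial gradient within a
    total-thickness prior band above the RPE; the four interior boundaries
    are signed gradient extrema within proportional bands between ILM and
    RPE.  Boundary maps are median-smoothed laterally and projected onto the
    ordered set.
    """
    if flat.depolarization is None:
        raise SegmentationError("segmentation requires the depolarization channel")
    bands = _INTERIOR_BANDS if bands is None else bands
    dz = flat.dz_um

    top, bottom, valid = _depol_band(flat.depolarization)
    top = _inpaint_nearest(top.astype(np.float64), valid)
    bottom = _inpaint_nearest(bottom.astype(np.float64), valid)
    prc_rpe = top
    rpe_post = bottom

    mean_i = flat.mean_intensity().astype(np.float64)
    smooth = ndimage.gaussian_filter(mean_i, sigma=(1.0, 1.0, 1.0))
    grad = np.gradient(smooth, axis=-1)

    lo = np.maximum(prc_rpe - _TOTAL_PRIOR_UM[1] / dz, 0)
    hi = np.maximum(prc_rpe - _TOTAL_PRIOR_UM[0] / dz, 0)
    ilm = _band_argmax(grad, lo, hi).astype(np.float64)

    raw: dict[str, np.ndarray] = {"ILM": ilm}
    span = prc_rpe - ilm
    for name, (center, half, sign) in bands.items():
        c = ilm + center * span
        w = np.maximum(half * span, 3.0)
        raw[name] = _band_argmax(sign * grad, c - w, c + w).astype(np.float64)
    raw["PRC/RPE"] = prc_rpe
    raw["RPE_POST"] = rpe_post

    # sanity check before smoothing: gross inversions indicate a failed search
    order = list(SURFACES)
    for upper, lower in zip(order[:-1], order[1:]):
        frac_bad = float(((raw[lower] - raw[upper]) < -2.0).mean())
        if frac_bad > 0.2:
            raise SegmentationError(
                f"boundary search failed: {lower} above {upper} in "
                f"{frac_bad:.0%} of A-scans"
            )

    window = max(3, min(median_window_px, min(ilm.shape)))
    if window % 2 == 0:
        window -= 1
    surfaces: dict[str, np.ndarray] = {}
    prev = None
    for name in order:
        m = ndimage.median_filter(raw[name], size=window, mode="nearest")
        if prev is not None:
            m = np.maximum(m, prev + 0.5)  # projection onto ordered set
        surfaces[name] = m
        prev = m

    return LayerSurfaces(
        depth_um={k: v * dz for k, v in surfaces.items()},
        dx_um=flat.dx_um,
        dy_um=flat.dy_um,
        dz_um=dz,
        onh_center_um=onh_center_um,
        onh_radius_um=onh_radius_um,
        valid=valid,
    )


def detect_onh_center(vol: OCTVolume) -> tuple[float, float]:
    """Convenience ONH locator: centroid of the depolarization gap.

    The ONH carries no depolarizing RPE signal, so the centroid of the
    missing-signal region approximates its center.  This is a helper for
    interactive use; the analysis operations take the ONH center as an
    explicit annotation and never call this silently.
    """
    if vol.depolarization is None:
        raise ValueError("ONH detection requires the depolarization channel")
    weight = vol.depolarization.sum(axis=-1)
    gap = weight < 0.05 * max(float(weight.max()), 1e-12)
    if not gap.any():
        raise ValueError("no depolarization gap found")
    ci, cj = ndimage.center_of_mass(gap)
    return float(ci * vol.dx_um), float(cj * vol.dy_um)


# ---------------------------------------------------------------------------
# thickness maps


def thickness_maps(surfaces: LayerSurfaces) -> dict[str, ThicknessMap]:
    """Build the nine en-face thickness maps from ordered surfaces.

    Returns maps for TOTAL, IRL, ORL and the six sublayers.  The composition
    identities TOTAL = IRL + ORL, IRL = RNFL/GCL + IPL + INL and
    ORL = OPL + PRC + RPE hold exactly (pixel-wise) by construction.
    """
    d = surfaces.depth_um
    sub = {
        layer: d[SURFACES[k + 1]] - d[SURFACES[k]]
        for k, layer in enumerate(LAYERS)
    }
    irl = sub["RNFL_GCL"] + sub["IPL"] + sub["INL"]
    orl = sub["OPL"] + sub["PRC"] + sub["RPE"]
    total = irl + orl  # == RPE_POST - ILM since sublayers telescope

    valid = surfaces.valid.copy()
    if surfaces.onh_center_um is not None and surfaces.onh_radius_um > 0:
        n_fast, n_slow = total.shape
        x = np.arange(n_fast)[:, None] * surfaces.dx_um
        y = np.arange(n_slow)[None, :] * surfaces.dy_um
        cx, cy = surfaces.onh_center_um
        valid &= np.hypot(x - cx, y - cy) >= surfaces.onh_radius_um

    def _map(name: str, vals: np.ndarray) -> ThicknessMap:
        return ThicknessMap(
            layer=name,
            values_um=vals,
            dx_um=surfaces.dx_um,
            dy_um=surfaces.dy_um,
            onh_center_um=surfaces.onh_center_um,
            valid=valid,
        )

    out = {"TOTAL": _map("TOTAL", total), "IRL": _map("IRL", irl), "ORL": _map("ORL", orl)}
    for layer in LAYERS:
        out[layer] = _map(layer, sub[layer])
    return out


# ---------------------------------------------------------------------------
# annulus / sector statistics


def sector_labels(
    shape: tuple[int, int],
    center_um: tuple[float, float],
    dx_um: float,
    dy_um: float,
) -> np.ndarray:
    """Quadrant-by-diagonals sector index map (0..3, order :data:`SECTORS`).

    Sectors are bounded by the two diagonal lines through ``center_um``.
    With the angle ``phi = atan2(dy, dx)`` (dy along the slow axis, i.e.
    image rows increase toward "inferior"):

    - nasal (right):    -pi/4 <= phi < pi/4
    - inferior (bottom): pi/4 <= phi < 3 pi/4
    - temporal (left):   phi >= 3 pi/4 or phi < -3 pi/4
    - superior (top):   -3 pi/4 <= phi < -pi/4

    All bounds are half-open so every pixel belongs to exactly one sector.
    """
    n_fast, n_slow = shape
    x = np.arange(n_fast)[:, None] * dx_um - center_um[0]
    y = np.arange(n_slow)[None, :] * dy_um - center_um[1]
    phi = np.arctan2(np.broadcast_to(y, (n_fast, n_slow)),
                     np.broadcast_to(x, (n_fast, n_slow)))
    labels = np.empty((n_fast, n_slow), dtype=np.int8)
    q = np.pi / 4
    labels[(phi >= -3 * q) & (phi < -q)] = 0  # superior
    labels[(phi >= -q) & (phi < q)] = 1  # nasal
    labels[(phi >= q) & (phi < 3 * q)] = 2  # inferior
    labels[(phi >= 3 * q) | (phi < -3 * q)] = 3  # temporal
    return labels


def radial_distance_um(
    shape: tuple[int, int],
    center_um: tuple[float, float],
    dx_um: float,
    dy_um: float,
) -> np.ndarray:
    """Physical distance (um) of every pixel center from ``center_um``."""
    n_fast, n_slow = shape
    x = np.arange(n_fast)[:, None] * dx_um - center_um[0]
    y = np.arange(n_slow)[None, :] * dy_um - center_um[1]
    return np.hypot(x, y)


def annulus_sector_average(
    tmap: ThicknessMap,
    r_in_um: float = 200.0,
    r_out_um: float = 600.0,
) -> SectorSummary:
    """Mean thickness in the ONH annulus, overall and per diagonal sector.

    A pixel contributes iff ``r_in <= dist(ONH center) < r_out`` in physical
    micrometers (anisotropic spacings respected) and it is valid.  The
    overall mean equals the pixel-count-weighted mean of the sector means.
    """
    if not r_in_um < r_out_um:
        raise ValueError(f"r_in ({r_in_um}) must be < r_out ({r_out_um})")
    if tmap.onh_center_um is None:
        raise ValueError("thickness map has no ONH center annotation")

    dist = radial_distance_um(
        tmap.values_um.shape, tmap.onh_center_um, tmap.dx_um, tmap.dy_um
    )
    inside = (dist >= r_in_um) & (dist < r_out_um) & tmap.valid
    if not inside.any():
        raise ValueError("annulus contains no valid pixels inside the field of view")

    labels = sector_labels(
        tmap.values_um.shape, tmap.onh_center_um, tmap.dx_um, tmap.dy_um
    )
    sector_mean: dict[str, float] = {}
    sector_n: dict[str, int] = {}
    total_sum = 0.0
    total_n = 0
    for k, name in enumerate(SECTORS):
        sel = inside & (labels == k)
        n = int(sel.sum())
        sector_n[name] = n
        if n:
            s = float(tmap.values_um[sel].sum())
            sector_mean[name] = s / n
            total_sum += s
            total_n += n
        else:
            sector_mean[name] = float("nan")
    return SectorSummary(
        layer=tmap.layer,
        r_in_um=r_in_um,
        r_out_um=r_out_um,
        sector_mean_um=sector_mean,
        sector_n=sector_n,
        overall_mean_um=total_sum / total_n,
        n_pixels=total_n,
    )
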