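"""Synthetic inputs with known ground truth for the whole pipeline.

Three generators emulate the study's data sources:

* :func:`generate_phantom` — layered retinal OCT volumes around an ONH with
  repeated B-scans, a depolarizing RPE band, vessels of known area density
  in three plexuses (with decorrelating speckle across repeats) and a
  radially varying signal level.
* :func:`generate_cohort` — a longitudinal animal cohort whose layer
  thicknesses follow a random-intercept model with configurable group
  effects, plus a latent spatial-memory ability constructed to have a
  configurable correlation with final-timepoint INL thickness.
* :func:`generate_trajectory` — Morris-water-maze swim paths from a
  parameterised drift/thigmotaxis/floating model in which higher memory
  ability yields stronger homing toward the (remembered) platform.

The generator defaults encode the emulated study conditions: a 1 x 1 mm
field of view at 512 x 400 acquisition sampling (desk-scale default grid
256 x 200 x 384), timepoints at 12/20/24/36 weeks with the published
dropout pattern (64 -> 48 -> 48 -> 27 animals), a 1 m pool with an 8 cm
platform in the NW quadrant, and 14 Hz tracking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layer_analysis import LAYERS, SURFACES, OCTVolume
from .mwm_metrics import PoolGeometry, Trajectory

__all__ = [
    "PLEXUSES",
    "PhantomConfig",
    "PhantomTruth",
    "CohortConfig",
    "BehaviorConfig",
    "TABLE4_SCHEDULE",
    "generate_phantom",
    "generate_cohort",
    "generate_trajectory",
]

#: Vascular plexuses, superficial to deep.
PLEXUSES = ("SVP", "ICP", "DCP")

#: Slab hosting each plexus, as (upper surface, lower surface) names.
PLEXUS_SLABS = {
    "SVP": ("ILM", "RNFL_GCL/IPL"),
    "ICP": ("RNFL_GCL/IPL", "INL/OPL"),
    "DCP": ("INL/OPL", "OPL/PRC"),
}


class ConfigError(ValueError):
    """A generator configuration violates an invariant."""


# ---------------------------------------------------------------------------
# phantom


@dataclass
class PhantomConfig:
    """Configuration of a layered retinal phantom.

    Layer thickness means follow typical murine values (total ~223 um,
    IRL ~97 um).  ``layer_variation_um`` is the amplitude of the smooth
    spatial modulation of each layer's thickness; ``surface_undulation_um``
    modulates the depth of the whole stack; ``tilt_um`` adds a plane
    ``a * x/FOV + b * y/FOV`` to every surface.
    """

    n_fast: int = 256
    n_slow: int = 200
    n_depth: int = 384
    fov_um: tuple[float, float] = (1000.0, 1000.0)
    dz_um: float = 1.5
    n_repeats: int = 5
    ilm_depth_um: float = 60.0
    layer_mean_um: dict[str, float] = field(
        default_factory=lambda: {
            "RNFL_GCL": 33.0,
            "IPL": 37.0,
            "INL": 27.0,
            "OPL": 12.0,
            "PRC": 103.0,
            "RPE": 11.0,
        }
    )
    layer_variation_um: float = 2.0
    surface_undulation_um: float = 6.0
    tilt_um: tuple[float, float] = (0.0, 0.0)
    onh_center_um: tuple[float, float] = (500.0, 500.0)
    onh_radius_um: float = 75.0
    reflectivity: dict[str, float] = field(
        default_factory=lambda: {
            "vitreous": 0.0,
            "RNFL_GCL": 0.90,
            "IPL": 0.50,
            "INL": 0.25,
            "OPL": 0.55,
            "PRC": 0.35,
            "RPE": 0.95,
            "below": 0.10,
        }
    )
    vessel_density: dict[str, float] = field(
        default_factory=lambda: {"SVP": 0.20, "ICP": 0.09, "DCP": 0.12}
    )
    vessel_radius_um: tuple[float, float] = (3.5, 8.0)  # capillary-scale
    noise_floor: float = 0.003
    snr_falloff: float = 0.4
    speckle_contrast: float = 1.0
    vessel_decorrelation: float = 0.9
    seed: int = 0

    @property
    def dx_um(self) -> float:
        return self.fov_um[0] / self.n_fast

    @property
    def dy_um(self) -> float:
        return self.fov_um[1] / self.n_slow

    def validate(self) -> None:
        for name, v in self.layer_mean_um.items():
            if v <= 0:
                raise ConfigError(f"layer_mean_um[{name!r}] must be > 0, got {v}")
        for name, d in self.vessel_density.items():
            if not 0.0 <= d <= 1.0:
                raise ConfigError(f"vessel_density[{name!r}] must be in [0, 1]")
        if not (
            0 <= self.onh_center_um[0] <= self.fov_um[0]
            and 0 <= self.onh_center_um[1] <= self.fov_um[1]
        ):
            raise ConfigError("onh_center_um must lie inside the field of view")
        total = self.ilm_depth_um + sum(self.layer_mean_um.values())
        extent = self.n_depth * self.dz_um
        if total + 3 * self.surface_undulation_um + abs(self.tilt_um[0]) + abs(
            self.tilt_um[1]
        ) >= extent:
            raise ConfigError(
                f"layer stack ({total:.0f} um) does not fit in the depth extent "
                f"({extent:.0f} um); field n_depth"
            )
        if not 0.0 <= self.vessel_decorrelation <= 1.0:
            raise ConfigError("vessel_decorrelation must be in [0, 1]")
        if not 0.0 <= self.speckle_contrast <= 1.0:
            raise ConfigError("speckle_contrast must be in [0, 1]")
        if self.noise_floor < 0:
            raise ConfigError("noise_floor must be >= 0")
        if self.n_repeats < 1:
            raise ConfigError("n_repeats must be >= 1")


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside a phantom volume."""

    surfaces_um: dict[str, np.ndarray]  # keys = layer_analysis.SURFACES
    vessel_masks: dict[str, np.ndarray]  # per plexus, en-face bool
    vessel_density: dict[str, float]  # realized area fraction per plexus
    onh_center_um: tuple[float, float]
    onh_radius_um: float
    dx_um: float
    dy_um: float
    dz_um: float


def _smooth_field(
    rng: np.random.Generator, shape: tuple[int, int], amplitude: float,
    scale_px: float = 24.0,
) -> np.ndarray:
    """Smooth zero-mean random field with max amplitude ~``amplitude``."""
    if amplitude == 0:
        return np.zeros(shape)
    from scipy import ndimage

    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, scale_px, mode="wrap")
    peak = np.abs(f).max()
    if peak < 1e-12:
        return np.zeros(shape)
    return f * (amplitude / peak)


def _sparse_start(
    mask: np.ndarray, rng: np.random.Generator, blocks: int = 8
) -> tuple[float, float]:
    """Random position inside one of the least-vascularised blocks.

    Capillary beds are space-filling: perfusion demands locally homogeneous
    vessel coverage, so new tubes preferentially grow where coverage is
    still sparse rather than by independent uniform seeding (which clumps).
    """
    n_fast, n_slow = mask.shape
    bi = np.array_split(np.arange(n_fast), blocks)
    bj = np.array_split(np.arange(n_slow), blocks)
    dens = np.array(
        [[mask[np.ix_(r, c)].mean() for c in bj] for r in bi]
    )
    pick = int(np.argsort(dens, axis=None)[0])
    i, j = divmod(pick, blocks)
    return (
        float(rng.uniform(bi[i][0], bi[i][-1] + 1)),
        float(rng.uniform(bj[j][0], bj[j][-1] + 1)),
    )


def _stamp_tube(
    mask: np.ndarray,
    rng: np.random.Generator,
    radius_px: float,
    n_steps: int,
    step_px: float = 2.0,
    heading_noise: float = 0.5,
) -> None:
    """Stamp one smoothed random-walk tube into ``mask`` (in place)."""
    n_fast, n_slow = mask.shape
    x, y = _sparse_start(mask, rng)
    theta = rng.uniform(0, 2 * math.pi)
    r = max(1, int(math.ceil(radius_px)))
    # precompute disc offsets
    off = np.arange(-r, r + 1)
    oi, oj = np.meshgrid(off, off, indexing="ij")
    disc = oi * oi + oj * oj <= radius_px * radius_px
    di, dj = oi[disc], oj[disc]
    for _ in range(n_steps):
        theta += rng.normal(0, heading_noise)
        x = (x + step_px * math.cos(theta)) % n_fast
        y = (y + step_px * math.sin(theta)) % n_slow
        ii = (int(round(x)) + di) % n_fast
        jj = (int(round(y)) + dj) % n_slow
        mask[ii, jj] = True


def _vessel_mask(
    rng: np.random.Generator,
    shape: tuple[int, int],
    target: float,
    radius_px_range: tuple[float, float],
) -> np.ndarray:
    """Union of random-walk tubes reaching ``target`` area fraction.

    Tube length shrinks with the remaining deficit so the realized density
    lands within a small fraction of the target; granularity (and hence the
    density error) scales down with grid size.
    """
    mask = np.zeros(shape, dtype=bool)
    if target <= 0:
        return mask
    n_px = mask.size
    step_px = 2.0
    # stop tolerance = half the area of the smallest stampable tube, so the
    # realized-density error scales down with grid size
    r_min = max(radius_px_range[0], 1.0)
    stop = 0.5 * (2.0 * r_min * step_px * 6.0) / n_px
    for _ in range(20_000):
        cur = mask.mean()
        deficit = target - cur
        if deficit <= stop:
            break
        radius = rng.uniform(*radius_px_range)
        # marginal area of a tube ~ 2 r * step * n_steps; aim at ~60% of the
        # deficit so the final tubes are short
        n_steps = int(np.clip(0.6 * deficit * n_px / (2 * radius * step_px), 6, 16))
        _stamp_tube(mask, rng, radius, n_steps, step_px=step_px)
    return mask


def generate_phantom(config: PhantomConfig) -> tuple[OCTVolume, PhantomTruth]:
    """Generate a phantom volume with repeats plus its ground truth.

    Voxel amplitude = layer reflectivity x radial SNR multiplier x
    multiplicative speckle + additive Rayleigh noise at the configured
    floor.  The depolarization channel marks the RPE band only (absent
    inside the ONH disc).  Voxels inside vessel masks decorrelate across
    repeats at the configured level; all other voxels share one speckle
    realization across repeats.  Identical seeds give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nf, ns, nd = config.n_fast, config.n_slow, config.n_depth
    dx, dy, dz = config.dx_um, config.dy_um, config.dz_um

    # --- boundary surfaces (um) -------------------------------------------
    x_norm = (np.arange(nf)[:, None] * dx) / config.fov_um[0]
    y_norm = (np.arange(ns)[None, :] * dy) / config.fov_um[1]
    base = (
        config.ilm_depth_um
        + _smooth_field(rng, (nf, ns), config.surface_undulation_um)
        + config.tilt_um[0] * x_norm
        + config.tilt_um[1] * y_norm
    )
    surfaces: dict[str, np.ndarray] = {"ILM": base.copy()}
    depth = base
    for layer in LAYERS:
        thick = config.layer_mean_um[layer] + _smooth_field(
            rng, (nf, ns), config.layer_variation_um, scale_px=16.0
        )
        thick = np.maximum(thick, 1.0)
        depth = depth + thick
        name = SURFACES[SURFACES.index(_surface_below(layer))]
        surfaces[name] = depth.copy()

    # --- vessels ----------------------------------------------------------
    r_px = (config.vessel_radius_um[0] / dx, config.vessel_radius_um[1] / dx)
    vessel_masks = {
        p: _vessel_mask(rng, (nf, ns), config.vessel_density[p], r_px)
        for p in PLEXUSES
    }
    realized = {p: float(m.mean()) for p, m in vessel_masks.items()}

    # --- voxel labels -----------------------------------------------------
    z_um = np.arange(nd, dtype=np.float32) * dz
    label = np.zeros((nf, ns, nd), dtype=np.int8)
    for name in SURFACES:
        label += (z_um[None, None, :] >= surfaces[name][..., None]).astype(np.int8)
    refl_lut = np.array(
        [config.reflectivity["vitreous"]]
        + [config.reflectivity[l] for l in LAYERS]
        + [config.reflectivity["below"]],
        dtype=np.float32,
    )
    amplitude = refl_lut[label]

    # --- radial SNR falloff ----------------------------------------------
    cx, cy = config.fov_um[0] / 2, config.fov_um[1] / 2
    rr = np.hypot(
        np.arange(nf)[:, None] * dx - cx, np.arange(ns)[None, :] * dy - cy
    )
    r_corner = math.hypot(cx, cy)
    mult = 1.0 - config.snr_falloff * (rr / r_corner) ** 2
    mult = np.maximum(mult, 0.15).astype(np.float32)
    amplitude *= mult[..., None]

    # --- vessel voxels: central 60% of the hosting slab -------------------
    vessel3d = np.zeros((nf, ns, nd), dtype=bool)
    for p in PLEXUSES:
        upper, lower = PLEXUS_SLABS[p]
        top = surfaces[upper] + 0.2 * (surfaces[lower] - surfaces[upper])
        bot = surfaces[upper] + 0.8 * (surfaces[lower] - surfaces[upper])
        in_slab = (z_um[None, None, :] >= top[..., None]) & (
            z_um[None, None, :] < bot[..., None]
        )
        vessel3d |= in_slab & vessel_masks[p][..., None]

    # --- speckle + repeats ------------------------------------------------
    c = config.speckle_contrast
    ray_scale = math.sqrt(2.0 / math.pi)  # Rayleigh with unit mean

    def _speckle(size) -> np.ndarray:
        if c == 0:
            return np.ones(size, dtype=np.float32)
        s = rng.rayleigh(ray_scale, size=size).astype(np.float32)
        return (1.0 - c) + c * s

    s0 = _speckle((nf, ns, nd))
    d = config.vessel_decorrelation
    n_vessel = int(vessel3d.sum())
    out = np.empty((config.n_repeats, nf, ns, nd), dtype=np.float32)
    for r in range(config.n_repeats):
        s_r = s0
        if d > 0 and n_vessel:
            s_r = s0.copy()
            s_ind = _speckle((n_vessel,))
            s_r[vessel3d] = (1.0 - d) * s0[vessel3d] + d * s_ind
        frame = amplitude * s_r
        if config.noise_floor > 0:
            frame = frame + rng.rayleigh(
                config.noise_floor, size=frame.shape
            ).astype(np.float32)
        out[r] = frame

    # --- depolarization channel ------------------------------------------
    rpe_band = label == 6
    ox, oy = config.onh_center_um
    onh = (
        np.hypot(np.arange(nf)[:, None] * dx - ox, np.arange(ns)[None, :] * dy - oy)
        < config.onh_radius_um
    )
    depol = (rpe_band & ~onh[..., None]).astype(np.float32)

    vol = OCTVolume(
        intensity=out, depolarization=depol, dx_um=dx, dy_um=dy, dz_um=dz
    )
    truth = PhantomTruth(
        surfaces_um=surfaces,
        vessel_masks=vessel_masks,
        vessel_density=realized,
        onh_center_um=config.onh_center_um,
        onh_radius_um=config.onh_radius_um,
        dx_um=dx,
        dy_um=dy,
        dz_um=dz,
    )
    return vol, truth


def _surface_below(layer: str) -> str:
    """Name of the surface at the posterior face of ``layer``."""
    idx = LAYERS.index(layer)
    return SURFACES[idx + 1]


# ---------------------------------------------------------------------------
# cohort

_GROUPS = (("tg", "m"), ("tg", "f"), ("ntg", "m"), ("ntg", "f"))


@dataclass
class CohortConfig:
    """Longitudinal cohort with random-intercept structure.

    ``n_per_cell`` animals per genotype x sex cell (default 16 -> 64 total).
    Thicknesses follow ``group baseline + group slope * (week - first week)
    + mouse intercept + eye effect + residual``.  ``rho_inl_memory`` sets
    the population correlation between final-timepoint INL thickness
    (eyes averaged) and the latent memory ability, per group.
    ``dropout`` maps a week to the number of animals removed *after* that
    week (default reproduces 64 -> 48 -> 48 -> 27).
    """

    n_per_cell: int = 16
    weeks: tuple[int, ...] = (12, 20, 24, 36)
    layer_baseline_um: dict[str, float] = field(
        default_factory=lambda: {
            "TOTAL": 223.0,
            "IRL": 96.0,
            "ORL": 127.0,
            "RNFL_GCL": 32.0,
            "IPL": 37.0,
            "INL": 27.0,
            "OPL": 11.5,
            "PRC": 104.0,
            "RPE": 11.0,
        }
    )
    #: additive group offsets (genotype, sex) -> um, applied to every layer
    group_offset_um: dict[tuple[str, str], float] = field(
        default_factory=lambda: {g: 0.0 for g in _GROUPS}
    )
    #: per-week slope (um/week) per group; default mild thickening
    group_slope_um_per_week: dict[tuple[str, str], float] = field(
        default_factory=lambda: {g: 0.24 for g in _GROUPS}
    )
    intercept_sd_um: float = 5.0
    eye_sd_um: float = 0.8
    residual_sd_um: float = 2.0
    rho_inl_memory: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("tg", "f"): 0.87,
            ("tg", "m"): 0.10,
            ("ntg", "f"): 0.25,
            ("ntg", "m"): 0.25,
        }
    )
    dropout: dict[int, int] = field(default_factory=lambda: {12: 16, 24: 21})
    weight_mean_g: dict[str, float] = field(
        default_factory=lambda: {"m": 32.0, "f": 25.0}
    )
    weight_sd_g: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("intercept_sd_um", "eye_sd_um", "residual_sd_um"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for g, r in self.rho_inl_memory.items():
            if abs(r) > 1:
                raise ConfigError(f"|rho_inl_memory[{g}]| must be <= 1")
        if list(self.weeks) != sorted(set(self.weeks)):
            raise ConfigError("weeks must be strictly increasing")
        if self.n_per_cell < 0:
            raise ConfigError("n_per_cell must be >= 0")


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the long-format cohort table and the latent-ability table.

    Returns
    -------
    cohort : DataFrame
        Columns ``animal_id, genotype, sex, eye, week, layer, thickness_um``.
        Dropout removes the configured numbers of animals after the stated
        weeks (stratified across groups).
    animals : DataFrame
        One row per animal: ``animal_id, genotype, sex, ability, weight_g``.
        Ability is standard normal with the configured correlation to the
        animal's final-week INL thickness (eyes averaged), constructed via a
        shared latent factor; it is defined for every animal, including
        those that drop out.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    weeks = list(config.weeks)
    layers = list(config.layer_baseline_um)
    eyes = ("OD", "OS")

    animals: list[dict] = []
    idx = 0
    for genotype, sex in _GROUPS:
        for _ in range(config.n_per_cell):
            animals.append(
                {
                    "animal_id": f"{genotype}{sex}{idx:03d}",
                    "genotype": genotype,
                    "sex": sex,
                }
            )
            idx += 1

    n = len(animals)
    rows = []
    negative_clipped = 0
    # per-animal random intercepts, per layer
    intercepts = rng.normal(0, config.intercept_sd_um, size=(n, len(layers)))
    eye_effects = rng.normal(0, config.eye_sd_um, size=(n, 2, len(layers)))
    final_inl_mouse = np.zeros(n)

    for a, animal in enumerate(animals):
        g = (animal["genotype"], animal["sex"])
        offset = config.group_offset_um.get(g, 0.0)
        slope = config.group_slope_um_per_week.get(g, 0.0)
        for w in weeks:
            for e, eye in enumerate(eyes):
                resid = rng.normal(0, config.residual_sd_um, size=len(layers))
                for li, layer in enumerate(layers):
                    val = (
                        config.layer_baseline_um[layer]
                        + offset
                        + slope * (w - weeks[0])
                        + intercepts[a, li]
                        + eye_effects[a, e, li]
                        + resid[li]
                    )
                    if val < 0:
                        val = 0.0
                        negative_clipped += 1
                    rows.append(
                        {
                            "animal_id": animal["animal_id"],
                            "genotype": animal["genotype"],
                            "sex": animal["sex"],
                            "eye": eye,
                            "week": w,
                            "layer": layer,
                            "thickness_um": val,
                        }
                    )
                    if layer == "INL" and w == weeks[-1]:
                        final_inl_mouse[a] += val / 2.0  # eye average

    cohort = pd.DataFrame(rows)
    if negative_clipped:
        cohort.attrs["negative_clipped"] = negative_clipped

    # latent ability: rho * standardized(final INL) + sqrt(1-rho^2) * noise.
    # The population SD of the mouse-averaged final INL is known analytically,
    # so the construction hits the target correlation exactly in population.
    li_inl = layers.index("INL") if "INL" in layers else None
    sd_final = math.sqrt(
        config.intercept_sd_um**2
        + (config.eye_sd_um**2 + config.residual_sd_um**2) / 2.0
    )
    ability = np.empty(n)
    for a, animal in enumerate(animals):
        g = (animal["genotype"], animal["sex"])
        rho = config.rho_inl_memory.get(g, 0.0)
        if li_inl is None or sd_final == 0:
            z = 0.0
        else:
            mu = (
                config.layer_baseline_um["INL"]
                + config.group_offset_um.get(g, 0.0)
                + config.group_slope_um_per_week.get(g, 0.0)
                * (weeks[-1] - weeks[0])
            )
            z = (final_inl_mouse[a] - mu) / sd_final
        ability[a] = rho * z + math.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal()

    animal_df = pd.DataFrame(animals)
    animal_df["ability"] = ability
    animal_df["weight_g"] = [
        rng.normal(config.weight_mean_g[a["sex"]], config.weight_sd_g)
        for a in animals
    ]

    # dropout: remove animals after the stated weeks, stratified round-robin
    # over the four groups so the remaining cohort stays near-balanced
    removed: set[str] = set()
    active = [a["animal_id"] for a in animals]
    by_group: dict[tuple[str, str], list[str]] = {g: [] for g in _GROUPS}
    for a in animals:
        by_group[(a["genotype"], a["sex"])].append(a["animal_id"])
    week_after: dict[str, int | None] = {aid: None for aid in active}
    for week, count in sorted(config.dropout.items()):
        pool = {g: [aid for aid in ids if aid not in removed]
                for g, ids in by_group.items()}
        order = [g for g in _GROUPS for _ in range(config.n_per_cell)]
        taken = 0
        gi = 0
        while taken < count:
            g = _GROUPS[gi % len(_GROUPS)]
            gi += 1
            if pool[g]:
                k = int(rng.integers(len(pool[g])))
                aid = pool[g].pop(k)
                removed.add(aid)
                week_after[aid] = week
                taken += 1
            elif all(not v for v in pool.values()):
                break

    def _keep(row) -> bool:
        wa = week_after[row.animal_id]
        return wa is None or row.week <= wa

    last_week = {
        aid: (wa if wa is not None else weeks[-1]) for aid, wa in week_after.items()
    }
    cohort = cohort[cohort["week"] <= cohort["animal_id"].map(last_week)]
    cohort = cohort.reset_index(drop=True)
    animal_df["last_week"] = animal_df["animal_id"].map(last_week)
    return cohort, animal_df


# ---------------------------------------------------------------------------
# Morris water maze trajectories

#: Start quadrants per day and trial, plus the fixed NW platform; the probe
#: day (5) has a single trial starting in SE and no platform.
TABLE4_SCHEDULE: dict[int, list[str]] = {
    1: ["NE", "SE", "SW", "SE"],
    2: ["SW", "NE", "SE", "SW"],
    3: ["SE", "SW", "NE", "SW"],
    4: ["NE", "SE", "SW", "NE"],
    5: ["SE"],
}


@dataclass
class BehaviorConfig:
    """Parameterised swim model.

    Each frame the heading relaxes toward a weighted blend of a drift
    toward the platform (weight logistic in ``day * (day_gain + slope *
    ability)``, scaled by ``memory_gain`` — increasing in ability x day, and
    average animals still improve over training days), attraction toward the wall (``thigmotaxis_weight``)
    and the previous heading perturbed by ``heading_noise`` radians.
    Floating is injected as explicit low-speed episodes.  On the probe day
    the platform is absent; the drift aims at the remembered platform
    position and switches off within 1.5 platform radii so the animal
    re-crosses the target zone instead of parking on it.
    """

    pool_radius_m: float = 0.5
    platform_quadrant: str = "NW"
    platform_radius_m: float = 0.04
    speed_mean_m_s: float = 0.18
    speed_sd_m_s: float = 0.04
    memory_gain: float = 0.35
    memory_slope: float = 0.35
    memory_day_gain: float = 0.25
    memory_offset: float = -1.5
    probe_drift_factor: float = 0.5
    thigmotaxis_weight: float = 0.12
    heading_noise: float = 0.45
    floating_rate_per_min: float = 0.6
    floating_duration_s: tuple[float, float] = (1.5, 4.0)  # lognormal-ish range
    trial_cap_s: float = 60.0
    frame_rate_hz: float = 14.0
    schedule: dict[int, list[str]] = field(
        default_factory=lambda: {d: list(q) for d, q in TABLE4_SCHEDULE.items()}
    )
    ability_support: tuple[float, float] = (-4.0, 4.0)
    seed: int = 0

    def validate(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ConfigError("frame_rate_hz must be > 0")
        if self.trial_cap_s <= 0:
            raise ConfigError("trial_cap_s must be > 0")
        geom = self.geometry()  # raises if platform is outside the pool
        del geom

    def geometry(self) -> PoolGeometry:
        return PoolGeometry.with_platform_in(
            self.platform_quadrant,
            pool_radius=self.pool_radius_m,
            platform_radius=self.platform_radius_m,
        )


_QUAD_ANGLE = {"NE": math.pi / 4, "NW": 3 * math.pi / 4,
               "SW": 5 * math.pi / 4, "SE": 7 * math.pi / 4}


def _start_point(quadrant: str, radius: float, rng: np.random.Generator) -> tuple[float, float]:
    ang = _QUAD_ANGLE[quadrant] + rng.uniform(-0.3, 0.3)
    r = radius - 0.02
    return r * math.cos(ang), r * math.sin(ang)


def generate_trajectory(
    ability: float,
    day: int,
    trial: int,
    config: BehaviorConfig,
    seed: int | None = None,
    start_quadrant: str | None = None,
) -> Trajectory:
    """Simulate one MWM trial.

    Training trials (days 1-4) end at platform contact or the trial cap;
    probe trials (day 5) last exactly the cap duration with the platform
    absent.  ``seed`` overrides ``config.seed``; ``start_quadrant``
    overrides the schedule (e.g. ``"random"``-ised starts for symmetry
    studies are obtained by passing an explicit quadrant).
    """
    config.validate()
    lo, hi = config.ability_support
    if not lo <= ability <= hi:
        raise ConfigError(
            f"ability {ability} outside configured support [{lo}, {hi}]"
        )
    if day not in config.schedule:
        raise ConfigError(f"day {day} not in the schedule")
    quads = config.schedule[day]
    if not 1 <= trial <= len(quads):
        raise ConfigError(f"trial {trial} not in the day-{day} schedule")
    if start_quadrant is None:
        start_quadrant = quads[trial - 1]

    rng = np.random.default_rng(config.seed if seed is None else seed)
    geom = config.geometry()
    probe = day == 5
    dt = 1.0 / config.frame_rate_hz
    n_max = int(round(config.trial_cap_s * config.frame_rate_hz))
    px, py = geom.platform_center
    r_pool = config.pool_radius_m
    r_inner = r_pool - 0.01

    # drift weight toward the platform: logistic in ability x day
    w_mem = config.memory_gain / (
        1.0
        + math.exp(
            -(
                day * (config.memory_day_gain + config.memory_slope * ability)
                + config.memory_offset
            )
        )
    )
    if probe:
        w_mem *= config.probe_drift_factor  # partial memory expression
    w_thig = config.thigmotaxis_weight
    w_prev = max(0.0, 1.0 - w_mem - w_thig)

    # pre-drawn randomness
    noise = rng.normal(0.0, config.heading_noise, size=n_max + 1)
    speeds = np.clip(
        rng.normal(config.speed_mean_m_s, config.speed_sd_m_s, size=n_max + 1),
        0.03,
        None,
    )
    # floating episodes: Poisson count over the cap, uniform onsets
    n_eps = rng.poisson(config.floating_rate_per_min * config.trial_cap_s / 60.0)
    slow = np.zeros(n_max + 1, dtype=bool)
    d_lo, d_hi = config.floating_duration_s
    for _ in range(n_eps):
        onset = rng.uniform(0, config.trial_cap_s)
        dur = math.exp(rng.uniform(math.log(d_lo), math.log(d_hi)))
        i0 = int(onset / dt)
        i1 = min(n_max + 1, i0 + max(1, int(dur / dt)))
        slow[i0:i1] = True

    x, y = _start_point(start_quadrant, r_pool, rng)
    theta = math.atan2(-y, -x) + rng.uniform(-0.5, 0.5)  # roughly inward
    xs = [x]
    ys = [y]
    search_off_r = 1.5 * geom.platform_radius
    reengage_r = 4.0 * geom.platform_radius
    homing = True  # probe-day hysteresis: swim off after a visit, then return

    for i in range(1, n_max + 1):
        dpx, dpy = px - x, py - y
        d_plat = math.hypot(dpx, dpy)
        w = w_mem
        if probe:
            if d_plat < search_off_r:
                homing = False
            elif d_plat > reengage_r:
                homing = True
            if not homing:
                w = 0.0  # searching: overshoot and re-cross the empty target
        theta_n = theta + noise[i]
        hx, hy = math.cos(theta_n), math.sin(theta_n)
        ux, uy = (dpx / d_plat, dpy / d_plat) if d_plat > 1e-9 else (hx, hy)
        r_here = math.hypot(x, y)
        if r_here > 1e-9:
            wx, wy = x / r_here, y / r_here
        else:
            wx, wy = hx, hy
        vx = w_prev * hx + w * ux + w_thig * wx
        vy = w_prev * hy + w * uy + w_thig * wy
        norm = math.hypot(vx, vy)
        if norm < 1e-12:
            vx, vy, norm = hx, hy, 1.0
        speed = 0.005 if slow[i] else speeds[i]
        x += vx / norm * speed * dt
        y += vy / norm * speed * dt
        r_new = math.hypot(x, y)
        if r_new > r_inner:
            # clip to the pool and reflect the heading off the wall tangent
            x *= r_inner / r_new
            y *= r_inner / r_new
            nx, ny = x / r_inner, y / r_inner
            dot = vx * nx + vy * ny
            vx, vy = vx - 2 * dot * nx, vy - 2 * dot * ny
        theta = math.atan2(vy, vx)
        xs.append(x)
        ys.append(y)
        if not probe and math.hypot(x - px, y - py) <= geom.platform_radius:
            break

    t = np.arange(len(xs)) * dt
    return Trajectory(
        t_s=t,
        x_m=np.array(xs),
        y_m=np.array(ys),
        rate_hz=config.frame_rate_hz,
        day=day,
        trial=trial,
    )
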