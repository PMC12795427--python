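"""File formats: HDF5/TIFF phantom volumes, CSV tables, YAML geometry."""

from __future__ import annotations

import pathlib

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .layer_analysis import OCTVolume, SECTORS, SectorSummary
from .mwm_metrics import PoolGeometry, Trajectory
from .octa_density import DensityResult
from .synthetic_data import PhantomTruth

__all__ = [
    "save_volume_h5",
    "load_volume_h5",
    "save_volume_tiff",
    "save_truth",
    "save_thickness_tiff",
    "save_trajectory_csv",
    "load_trajectory_csv",
    "save_pool_yaml",
    "load_pool_yaml",
    "sector_summaries_frame",
    "densities_frame",
]


def save_volume_h5(path, vol: OCTVolume) -> None:
    """Write a volume: datasets ``intensity`` (repeats, fast, slow, depth)
    and ``depolarization`` (fast, slow, depth); spacings as attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("intensity", data=vol.intensity, compression="gzip")
        if vol.depolarization is not None:
            f.create_dataset(
                "depolarization", data=vol.depolarization, compression="gzip"
            )
        f.attrs["dx_um"] = vol.dx_um
        f.attrs["dy_um"] = vol.dy_um
        f.attrs["dz_um"] = vol.dz_um


def load_volume_h5(path) -> OCTVolume:
    with h5py.File(path, "r") as f:
        depol = f["depolarization"][()] if "depolarization" in f else None
        return OCTVolume(
            intensity=f["intensity"][()],
            depolarization=depol,
            dx_um=float(f.attrs["dx_um"]),
            dy_um=float(f.attrs["dy_um"]),
            dz_um=float(f.attrs["dz_um"]),
        )


def save_volume_tiff(path, vol: OCTVolume) -> None:
    """Multi-page TIFF of the repeat-averaged volume (one page per B-scan)."""
    pages = vol.mean_intensity().transpose(1, 0, 2).astype(np.float32)
    tifffile.imwrite(path, pages)


def save_truth(path_h5, truth: PhantomTruth, path_csv=None) -> None:
    """Ground truth as HDF5 (surfaces + masks) and optional densities CSV."""
    with h5py.File(path_h5, "w") as f:
        g = f.create_group("surfaces_um")
        for name, arr in truth.surfaces_um.items():
            g.create_dataset(name.replace("/", "|"), data=arr)
        m = f.create_group("vessel_masks")
        for plexus, arr in truth.vessel_masks.items():
            m.create_dataset(plexus, data=arr.astype(np.uint8))
        f.attrs["onh_center_um"] = truth.onh_center_um
        f.attrs["onh_radius_um"] = truth.onh_radius_um
        for k in ("dx_um", "dy_um", "dz_um"):
            f.attrs[k] = getattr(truth, k)
    if path_csv is not None:
        pd.DataFrame(
            [
                {"plexus": p, "density_fraction": d}
                for p, d in truth.vessel_density.items()
            ]
        ).to_csv(path_csv, index=False)


def save_thickness_tiff(path, values_um: np.ndarray) -> None:
    tifffile.imwrite(path, values_um.astype(np.float32))


def save_trajectory_csv(path, traj: Trajectory) -> None:
    pd.DataFrame({"t_s": traj.t_s, "x_m": traj.x_m, "y_m": traj.y_m}).to_csv(
        path, index=False
    )


def load_trajectory_csv(path, rate_hz: float = 14.0, **labels) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(
        t_s=df["t_s"].to_numpy(),
        x_m=df["x_m"].to_numpy(),
        y_m=df["y_m"].to_numpy(),
        rate_hz=rate_hz,
        **labels,
    )


def save_pool_yaml(path, geom: PoolGeometry) -> None:
    data = {
        "pool_center_m": list(geom.pool_center),
        "pool_radius_m": geom.pool_radius,
        "platform_center_m": list(geom.platform_center),
        "platform_radius_m": geom.platform_radius,
        "wall_zone_width_m": geom.wall_zone_width,
        "target_radius_m": geom.target_radius,
    }
    pathlib.Path(path).write_text(yaml.safe_dump(data))


def load_pool_yaml(path) -> PoolGeometry:
    data = yaml.safe_load(pathlib.Path(path).read_text())
    return PoolGeometry(
        pool_center=tuple(data["pool_center_m"]),
        pool_radius=data["pool_radius_m"],
        platform_center=tuple(data["platform_center_m"]),
        platform_radius=data["platform_radius_m"],
        wall_zone_width=data["wall_zone_width_m"],
        target_radius=data.get("target_radius_m"),
    )


def sector_summaries_frame(
    summaries: dict[str, SectorSummary], volume_id: str = ""
) -> pd.DataFrame:
    """Tidy sector-summary table: volume_id, layer, sector, mean_um, n_pixels."""
    rows = []
    for layer, s in summaries.items():
        for sector in SECTORS:
            rows.append(
                {
                    "volume_id": volume_id,
                    "layer": layer,
                    "sector": sector,
                    "mean_um": s.sector_mean_um[sector],
                    "n_pixels": s.sector_n[sector],
                }
            )
        rows.append(
            {
                "volume_id": volume_id,
                "layer": layer,
                "sector": "overall",
                "mean_um": s.overall_mean_um,
                "n_pixels": s.n_pixels,
            }
        )
    return pd.DataFrame(rows)


def densities_frame(
    results: dict[str, DensityResult], volume_id: str = ""
) -> pd.DataFrame:
    rows = []
    for plexus, r in results.items():
        rows.append(
            {
                "volume_id": volume_id,
                "plexus": plexus,
                "density_pct": r.density_pct,
                "n_pos": r.n_positive,
                "n_neg": r.n_negative,
                "n_zones_included": r.n_zones_included,
                "n_zones_excluded": r.n_zones_excluded,
            }
        )
    return pd.DataFrame(rows)
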