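"""File I/O: HDF5 force-volume containers, TIFF maps, CSV tables.

Container layout (HDF5): datasets ``/force`` (ny, nx, n_samples) in pN and
``/z`` (n_samples) in nm, with attributes pixel_size_nm,
spring_constant_N_per_m, fast_axis and direction.  Height and modulus maps
go to 32-bit float TIFF with a JSON metadata description.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .morphometry import PoreRecord
from .reconstruction import HeightMap
from .synthetic import ForceVolumeMap, GroundTruth

__all__ = [
    "save_force_volume",
    "load_force_volume",
    "save_height_map",
    "load_height_map",
    "save_modulus_map",
    "save_ground_truth",
    "pores_to_frame",
    "frame_to_pores",
]


def save_force_volume(path, fvmap: ForceVolumeMap) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("force", data=fvmap.force.astype(np.float32), compression="gzip")
        f.create_dataset("z", data=fvmap.z.astype(np.float64))
        f.attrs["pixel_size_nm"] = fvmap.pixel_size
        f.attrs["spring_constant_N_per_m"] = fvmap.spring_constant
        f.attrs["fast_axis"] = fvmap.fast_axis
        f.attrs["direction"] = fvmap.direction
        for key, val in fvmap.metadata.items():
            f.attrs[f"meta_{key}"] = val


def load_force_volume(path) -> ForceVolumeMap:
    with h5py.File(path, "r") as f:
        meta = {
            k[5:]: (v.item() if hasattr(v, "item") else v)
            for k, v in f.attrs.items()
            if k.startswith("meta_")
        }
        return ForceVolumeMap(
            force=f["force"][...].astype(np.float64),
            z=f["z"][...],
            pixel_size=float(f.attrs["pixel_size_nm"]),
            spring_constant=float(f.attrs["spring_constant_N_per_m"]),
            fast_axis=str(f.attrs.get("fast_axis", "x")),
            direction=str(f.attrs.get("direction", "approach")),
            metadata=meta,
        )


def save_height_map(path, hmap: HeightMap) -> None:
    desc = json.dumps(
        {
            "pixel_size_nm": hmap.pixel_size,
            "load_force_pN": hmap.load_force,
            "fast_axis": hmap.fast_axis,
            "units": "nm",
        }
    )
    tifffile.imwrite(path, hmap.heights.astype(np.float32), description=desc)


def load_height_map(path) -> HeightMap:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(np.float64)
        desc = tf.pages[0].description
    meta = json.loads(desc) if desc else {}
    return HeightMap(
        heights=data,
        valid_mask=np.isfinite(data),
        pixel_size=float(meta.get("pixel_size_nm", 1.0)),
        load_force=float(meta.get("load_force_pN", 1.0)),
        fast_axis=str(meta.get("fast_axis", "x")),
        metadata=meta,
    )


def save_modulus_map(path, modulus_pa: np.ndarray, pixel_size_nm: float) -> None:
    desc = json.dumps({"pixel_size_nm": pixel_size_nm, "units": "Pa"})
    tifffile.imwrite(path, modulus_pa.astype(np.float32), description=desc)


def save_ground_truth(outdir, truth: GroundTruth) -> None:
    """Ground truth to JSON (pore table, scalars) plus TIFF masks/maps."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = [
        {
            "x_nm": p.x_nm,
            "y_nm": p.y_nm,
            "radius_nm": p.radius_nm,
            "rim_width_nm": p.rim_width_nm,
            "collapse_force_pn": p.collapse_force_pn,
            "sieve_plate_id": p.sieve_plate_id,
            "in_nucleus": p.in_nucleus,
        }
        for p in truth.pore_table
    ]
    payload = {
        "pixel_size_nm": truth.pixel_size,
        "true_porosity_per_um2": truth.true_porosity,
        "true_enlargement_fold": truth.true_enlargement,
        "n_rejected": truth.n_rejected,
        "cell_area_um2": truth.cell_area_um2,
        "pore_table": table,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    tifffile.imwrite(outdir / "true_height_nm.tif", truth.true_height_map.astype(np.float32))
    tifffile.imwrite(outdir / "true_modulus_Pa.tif", truth.true_modulus_map.astype(np.float32))
    for name, mask in (
        ("cell_mask", truth.cell_mask),
        ("nuclear_mask", truth.nuclear_mask),
        ("pore_mask", truth.pore_mask),
        ("rim_mask", truth.rim_mask),
    ):
        tifffile.imwrite(outdir / f"{name}.tif", mask.astype(np.uint8))


_PORE_COLUMNS = {
    "centroid_x_nm": "centroid_x_nm",
    "centroid_y_nm": "centroid_y_nm",
    "diameter_fast_axis_nm": "diameter_fast_axis_nm",
    "depth_nm": "depth_nm",
    "area_nm2": "area_nm2",
    "circularity": "circularity",
    "in_nuclear_region": "in_nuclear_region",
    "sieve_plate_id": "sieve_plate_id",
    "criterion": "criterion",
    "load_force_pn": "load_force_pn",
}


def pores_to_frame(pores: list[PoreRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(p, a) for a, c in _PORE_COLUMNS.items()} for p in pores],
        columns=list(_PORE_COLUMNS.values()),
    )


def frame_to_pores(df: pd.DataFrame) -> list[PoreRecord]:
    out = []
    for _, row in df.iterrows():
        plate = row.get("sieve_plate_id")
        out.append(
            PoreRecord(
                centroid_x_nm=float(row["centroid_x_nm"]),
                centroid_y_nm=float(row["centroid_y_nm"]),
                diameter_fast_axis_nm=float(row["diameter_fast_axis_nm"]),
                depth_nm=float(row["depth_nm"]),
                area_nm2=float(row["area_nm2"]),
                circularity=float(row["circularity"]),
                in_nuclear_region=bool(row.get("in_nuclear_region", False)),
                sieve_plate_id=None if pd.isna(plate) else int(plate),
                criterion=str(row.get("criterion", "half-depth")),
                load_force_pn=float(row["load_force_pn"])
                if not pd.isna(row.get("load_force_pn"))
                else None,
            )
        )
    return out
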