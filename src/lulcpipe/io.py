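"""Artifact serialization.

Categorical rasters are written as ESRI ASCII grids (plain text, readable
by any GIS); the composite stack as a NetCDF cube (xarray); sample sites as
CSV and GeoJSON points; run parameters as flat ``key = value`` text. All
writers are deterministic so byte-level digests are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .synthetic import VIStack


def write_ascii_grid(path: str | Path, arr: np.ndarray, pixel_size: float,
                     nodata: int = -9999) -> Path:
    path = Path(path)
    rows, cols = arr.shape
    header = (f"ncols {cols}\nnrows {rows}\nxllcorner 0.0\nyllcorner 0.0\n"
              f"cellsize {pixel_size}\nNODATA_value {nodata}\n")
    with open(path, "w") as fh:
        fh.write(header)
        for row in arr:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")
    return path


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float]:
    lines = Path(path).read_text().splitlines()
    meta = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value"):
        k, v = lines[i].split()
        meta[k.lower()] = float(v)
        i += 1
    arr = np.array([[int(float(x)) for x in ln.split()] for ln in lines[i:]])
    return arr, meta["cellsize"]


def stack_to_dataset(stack: VIStack) -> xr.Dataset:
    dims = ("time", "y", "x")
    data = {var: (dims, stack.values[var]) for var in stack.variables}
    if stack.contamination is not None:
        data["contamination"] = (dims, stack.contamination.astype(np.int8))
    r, c = stack.shape
    coords = {
        "year": ("time", stack.year_of),
        "period": ("time", stack.period_of),
        "y": np.arange(r) * stack.pixel_size,
        "x": np.arange(c) * stack.pixel_size,
    }
    ds = xr.Dataset(data, coords=coords)
    ds.attrs["pixel_size_m"] = stack.pixel_size
    return ds


def write_stack(stack: VIStack, path: str | Path) -> Path:
    path = Path(path)
    stack_to_dataset(stack).to_netcdf(path, engine="scipy")
    return path


def read_stack(path: str | Path) -> VIStack:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    contamination = None
    if "contamination" in ds:
        contamination = ds["contamination"].to_numpy().astype(bool)
    variables = [v for v in ds.data_vars if v != "contamination"]
    return VIStack(
        values={v: ds[v].to_numpy() for v in variables},
        year_of=ds["year"].to_numpy(),
        period_of=ds["period"].to_numpy(),
        pixel_size=float(ds.attrs["pixel_size_m"]),
        contamination=contamination,
    )


def sites_to_geojson(sites: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    features = []
    for _, s in sites.iterrows():
        props = {k: (int(v) if isinstance(v, (np.integer, int)) else v)
                 for k, v in s.items() if k not in ("x", "y")}
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(s["x"]), float(s["y"])]},
            "properties": props,
        })
    doc = {"type": "FeatureCollection", "features": features}
    path.write_text(json.dumps(doc, sort_keys=True))
    return path


def write_flat_config(params: dict, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"{k} = {v}" for k, v in sorted(params.items())]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_flat_config(path: str | Path) -> dict[str, str]:
    out = {}
    for ln in Path(path).read_text().splitlines():
        if "=" in ln:
            k, v = ln.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def sha256_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


__all__ = ["read_ascii_grid", "read_flat_config", "read_stack",
           "sha256_digest", "sites_to_geojson", "stack_to_dataset",
           "write_ascii_grid", "write_flat_config", "write_stack"]
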