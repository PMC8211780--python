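"""File formats: single-band TIFF rasters, plot CSVs, YAML configuration.

Rasters are plain north-up TIFFs (row/col grid, no geodesy) with a JSON blob
in the ImageDescription tag carrying the no-data value and any category
labels, so a write-then-read round trip is value-identical including
metadata.  Plot tables are schema-validated CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic_landscape import Landscape

RASTER_NODATA = -9999.0
PLOT_COLUMNS = ["plot_id", "row", "col", "year", "gsv_gt", "snag_volume", "source", "plot_area"]


def write_raster(path, array: np.ndarray, nodata=None, meta: dict | None = None) -> None:
    """Write a single-band raster; NaNs are stored as the declared no-data value."""
    path = Path(path)
    arr = np.asarray(array)
    header = {"nodata": nodata, **(meta or {})}
    if arr.dtype.kind == "f":
        arr = arr.astype(np.float32)
        if nodata is not None:
            arr = np.where(np.isnan(arr), np.float32(nodata), arr)
    elif arr.dtype.kind == "b":
        arr = arr.astype(np.uint8)
        header["dtype"] = "bool"
    tifffile.imwrite(path, arr, description=json.dumps(header))


def read_raster(path) -> tuple[np.ndarray, dict]:
    """Read a raster written by :func:`write_raster`; no-data comes back as NaN."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, json.JSONDecodeError):
                meta = {}
    if meta.get("dtype") == "bool":
        arr = arr.astype(bool)
    nodata = meta.get("nodata")
    if nodata is not None and arr.dtype.kind == "f":
        arr = arr.astype(np.float64)
        arr[arr == np.float64(np.float32(nodata))] = np.nan
    return arr, meta


def check_aligned(layers: dict[str, np.ndarray]) -> None:
    """Raise naming the first layer whose grid disagrees with the others."""
    ref_name, ref = next(iter(layers.items()))
    for name, arr in layers.items():
        if np.shape(arr) != np.shape(ref):
            raise ValueError(
                f"layer {name!r} has shape {np.shape(arr)}, "
                f"expected {np.shape(ref)} (as {ref_name!r})"
            )


def write_landscape(landscape: Landscape, out_dir) -> None:
    """Persist a landscape as one TIFF per layer plus a landscape.json sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_raster(out / "true_gsv.tif", landscape.true_gsv, nodata=RASTER_NODATA)
    write_raster(out / "map_gb.tif", landscape.map_gb, nodata=RASTER_NODATA)
    write_raster(out / "map_cci.tif", landscape.map_cci, nodata=RASTER_NODATA)
    write_raster(out / "zone.tif", landscape.zone.astype(np.uint8),
                 meta={"labels": list(landscape.zones)})
    write_raster(out / "pft.tif", landscape.pft.astype(np.uint8),
                 meta={"labels": list(landscape.pfts)})
    write_raster(out / "region.tif", landscape.region.astype(np.uint16))
    write_raster(out / "forest_mask.tif", landscape.forest_mask)
    with open(out / "landscape.json", "w") as fh:
        json.dump(
            {
                "pixel_area": landscape.pixel_area,
                "zones": list(landscape.zones),
                "pfts": list(landscape.pfts),
                "map_epoch": landscape.map_epoch,
            },
            fh,
            indent=2,
        )


def read_landscape(in_dir) -> Landscape:
    d = Path(in_dir)
    with open(d / "landscape.json") as fh:
        meta = json.load(fh)
    layers = {
        name: read_raster(d / f"{name}.tif")[0]
        for name in ("true_gsv", "map_gb", "map_cci", "zone", "pft", "region", "forest_mask")
    }
    check_aligned(layers)
    return Landscape(
        true_gsv=layers["true_gsv"],
        map_gb=layers["map_gb"],
        map_cci=layers["map_cci"],
        zone=layers["zone"],
        pft=layers["pft"],
        region=layers["region"],
        forest_mask=layers["forest_mask"].astype(bool),
        pixel_area=meta["pixel_area"],
        zones=tuple(meta["zones"]),
        pfts=tuple(meta["pfts"]),
        map_epoch=meta.get("map_epoch", 2014),
    )


def read_plots(path) -> pd.DataFrame:
    """Schema-validated plot table; malformed rows are reported by line number."""
    path = Path(path)
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{path}: plot table is empty")
    missing = set(PLOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    problems = []
    for col in ("gsv_gt", "snag_volume", "plot_area"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0)
        for i in df.index[bad]:
            problems.append(f"line {i + 2}: {col}={df.loc[i, col]!r} must be a nonnegative number")
        df[col] = vals
    bad_source = ~df["source"].isin(["NFI", "FOS"])
    for i in df.index[bad_source]:
        problems.append(f"line {i + 2}: source={df.loc[i, 'source']!r} must be NFI or FOS")
    if problems:
        raise ValueError(f"{path}: malformed rows:\n" + "\n".join(problems))
    df["row"] = df["row"].astype(int)
    df["col"] = df["col"].astype(int)
    df["year"] = df["year"].astype(int)
    return df


def write_plots(plots: pd.DataFrame, path) -> None:
    plots.to_csv(path, index=False, columns=[c for c in plots.columns])


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
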