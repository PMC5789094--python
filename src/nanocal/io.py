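"""Reading and writing localization tables, images and configs.

CSV dialect: ``#`` metadata header lines (``# key = value``) followed by a
``frame,x_nm,y_nm,photons,sigma_nm,source,ruler,mark`` table; coordinates
are written at 3 decimals (nm).  The HDF5 mirror stores full-precision
columns under ``/locs`` with metadata (pixel size, frame time, seed, config
echo) as attributes of a ``/meta`` group, so a write/read round trip is
bit-exact.  Pixel size and frame time are mandatory in both formats.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .tables import COLUMNS, LocalizationTable, empty_frame


class SchemaError(ValueError):
    pass


REQUIRED_META = ("pixel_size", "frame_time")


def write_localizations(table: LocalizationTable, path: Union[str, Path]) -> None:
    """Write a table as metadata-headed CSV (.csv) or HDF5 (.h5/.hdf5)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        _write_hdf5(table, path)
    else:
        _write_csv(table, path)


def read_localizations(path: Union[str, Path]) -> LocalizationTable:
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _read_hdf5(path)
    return _read_csv(path)


def _write_csv(table: LocalizationTable, path: Path) -> None:
    meta = table.metadata()
    buf = _io.StringIO()
    for k, v in meta.items():
        buf.write(f"# {k} = {v}\n")
    df = table.df.copy()
    for c in ("x_nm", "y_nm", "sigma_nm"):
        df[c] = df[c].map(lambda v: f"{v:.3f}")
    df["photons"] = df["photons"].map(lambda v: f"{v:.1f}")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def _read_csv(path: Path) -> LocalizationTable:
    meta = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    missing = [k for k in REQUIRED_META if k not in meta]
    if missing:
        raise SchemaError(f"{path}: missing mandatory metadata {missing}")
    df = pd.read_csv(path, skiprows=n_header)
    if len(df) == 0:
        df = empty_frame()
    field = None
    if "field_width_nm" in meta:
        field = (float(meta["field_width_nm"]), float(meta["field_height_nm"]))
    return LocalizationTable(
        df=df, pixel_size=float(meta["pixel_size"]),
        frame_time=float(meta["frame_time"]),
        seed=int(meta["seed"]) if "seed" in meta else None,
        field_size=field)


def _write_hdf5(table: LocalizationTable, path: Path,
                config_echo: Optional[dict] = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("locs")
        for c in COLUMNS:
            data = table.df[c].to_numpy()
            if c == "source":
                data = data.astype("S")
            g.create_dataset(c, data=data)
        m = f.create_group("meta")
        for k, v in table.metadata().items():
            m.attrs[k] = v
        if config_echo is not None:
            m.attrs["config"] = json.dumps(config_echo)


def _read_hdf5(path: Path) -> LocalizationTable:
    with h5py.File(path, "r") as f:
        if "meta" not in f:
            raise SchemaError(f"{path}: missing /meta group")
        meta = dict(f["meta"].attrs)
        missing = [k for k in REQUIRED_META if k not in meta]
        if missing:
            raise SchemaError(f"{path}: missing mandatory metadata {missing}")
        cols = {}
        for c in COLUMNS:
            arr = f["locs"][c][()]
            if c == "source":
                arr = np.char.decode(arr.astype("S"), "utf-8")
            cols[c] = arr
    df = pd.DataFrame(cols)
    field = None
    if "field_width_nm" in meta:
        field = (float(meta["field_width_nm"]), float(meta["field_height_nm"]))
    return LocalizationTable(
        df=df, pixel_size=float(meta["pixel_size"]),
        frame_time=float(meta["frame_time"]),
        seed=int(meta["seed"]) if "seed" in meta else None,
        field_size=field)


def write_tiff(image: np.ndarray, path: Union[str, Path]) -> None:
    tifffile.imwrite(str(path), np.asarray(image))


def read_tiff(path: Union[str, Path]) -> np.ndarray:
    return tifffile.imread(str(path))


def read_config(path: Union[str, Path]) -> dict:
    """Read a structured-text (YAML) config with per-module sections."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a mapping of sections")
    return data
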