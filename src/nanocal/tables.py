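"""Localization tables — the pipeline's common currency.

A :class:`LocalizationTable` wraps a pandas DataFrame with one row per
single-molecule localization and mandatory acquisition metadata (pixel size,
frame time).  Column conventions follow the usual SMLM table layout
(ThunderSTORM-style): ``frame, x_nm, y_nm, photons, sigma_nm, source``
plus ground-truth bookkeeping columns ``ruler`` and ``mark`` where the table
came from the simulator (-1 for false positives).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

COLUMNS = ["frame", "x_nm", "y_nm", "photons", "sigma_nm", "source",
           "ruler", "mark"]

#: source labels
SOURCE_SITE = "site"
SOURCE_MERGED = "merged"
SOURCE_FALSE_POSITIVE = "false_positive"


def empty_frame() -> pd.DataFrame:
    return pd.DataFrame({
        "frame": pd.Series(dtype=np.int64),
        "x_nm": pd.Series(dtype=float),
        "y_nm": pd.Series(dtype=float),
        "photons": pd.Series(dtype=float),
        "sigma_nm": pd.Series(dtype=float),
        "source": pd.Series(dtype=object),
        "ruler": pd.Series(dtype=np.int64),
        "mark": pd.Series(dtype=np.int64),
    })


@dataclass
class LocalizationTable:
    """Single-molecule localizations plus camera/acquisition metadata.

    Attributes
    ----------
    df
        One row per localization; columns per :data:`COLUMNS`.
    pixel_size
        Object-space pixel size (nm/pixel).
    frame_time
        Camera integration time (s).
    seed
        Seed of the generating simulation, if any.
    field_size
        (width, height) of the field of view in nm, if known.
    """

    df: pd.DataFrame
    pixel_size: float
    frame_time: float
    seed: Optional[int] = None
    field_size: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.pixel_size is None or not self.pixel_size > 0:
            raise ValueError("LocalizationTable.pixel_size must be > 0")
        if self.frame_time is None or not self.frame_time > 0:
            raise ValueError("LocalizationTable.frame_time must be > 0")
        missing = [c for c in ("frame", "x_nm", "y_nm", "photons") if c not in self.df.columns]
        if missing:
            raise ValueError(f"LocalizationTable missing columns: {missing}")
        for c, default in (("sigma_nm", np.nan), ("source", SOURCE_SITE),
                           ("ruler", -1), ("mark", -1)):
            if c not in self.df.columns:
                self.df[c] = default
        self.df = self.df[COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) localization coordinates in nm."""
        return self.df[["x_nm", "y_nm"]].to_numpy(dtype=float)

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each localization's frame midpoint (s)."""
        return (self.df["frame"].to_numpy(dtype=float) + 0.5) * self.frame_time

    def with_df(self, df: pd.DataFrame) -> "LocalizationTable":
        return LocalizationTable(df=df.copy(), pixel_size=self.pixel_size,
                                 frame_time=self.frame_time, seed=self.seed,
                                 field_size=self.field_size)

    def metadata(self) -> dict:
        meta = {"pixel_size": float(self.pixel_size),
                "frame_time": float(self.frame_time)}
        if self.seed is not None:
            meta["seed"] = int(self.seed)
        if self.field_size is not None:
            meta["field_width_nm"] = float(self.field_size[0])
            meta["field_height_nm"] = float(self.field_size[1])
        return meta


@dataclass
class GroundTruth:
    """Ground truth of a simulated nanoruler field.

    ``rulers`` has one row per ruler: ``ruler, cx_nm, cy_nm, angle_rad,
    distance_nm``.  Per-localization source labels live in the table itself
    (``source``, ``ruler``, ``mark`` columns), so every emitted localization
    carries exactly one source label.
    """

    rulers: pd.DataFrame

    @property
    def distances(self) -> np.ndarray:
        return self.rulers["distance_nm"].to_numpy(dtype=float)
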