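"""Two-colour channel registration and its quantitative evaluation.

The green channel is mapped onto the red channel by the six-coefficient
affine model

    x_red = a * x_green + b * y_green + c
    y_red = d * x_green + e * y_green + f

solved from matched bead coordinates (exactly determined with three
non-collinear pairs, least squares with more).  Registration quality over
the field of view is judged from the correlation image — the element-wise
product of 10 nm-binned red and green renderings — summed in fixed-size
tiles (correlation density, normalized to the maximum tile): a valid
correction is uniform within counting noise, a bad one shows structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd


class RegistrationError(ValueError):
    pass


@dataclass
class ChannelTransform:
    """Affine green -> red mapping; a, b, d, e dimensionless, c, f in nm."""

    a: float = 1.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0
    e: float = 1.0
    f: float = 0.0

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.a, self.b, self.c, self.d, self.e, self.f])):
            raise RegistrationError("transform coefficients must be finite")

    @classmethod
    def identity(cls) -> "ChannelTransform":
        return cls()

    @classmethod
    def shift(cls, cx: float, cy: float) -> "ChannelTransform":
        return cls(c=cx, f=cy)

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.d, self.e]])

    @property
    def offset(self) -> np.ndarray:
        return np.array([self.c, self.f])

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return xy @ self.matrix.T + self.offset

    def inverse(self) -> "ChannelTransform":
        M = self.matrix
        if abs(np.linalg.det(M)) < 1e-15:
            raise RegistrationError("transform is singular")
        Minv = np.linalg.inv(M)
        off = -Minv @ self.offset
        return ChannelTransform(a=Minv[0, 0], b=Minv[0, 1], c=off[0],
                                d=Minv[1, 0], e=Minv[1, 1], f=off[1])

    def coefficients(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.e, self.f])

    def to_text(self) -> str:
        return " ".join(repr(float(v)) for v in self.coefficients())

    @classmethod
    def from_text(cls, text: str) -> "ChannelTransform":
        vals = [float(t) for t in text.split()]
        if len(vals) != 6:
            raise RegistrationError("transform record must hold 6 values")
        return cls(a=vals[0], b=vals[1], c=vals[2],
                   d=vals[3], e=vals[4], f=vals[5])


def solve_channel_transform(green: np.ndarray, red: np.ndarray
                            ) -> Tuple[ChannelTransform, float]:
    """Solve the affine coefficients from matched green/red pairs.

    With exactly three non-collinear pairs the system is determined and
    solved exactly; with more pairs a least-squares solution is returned.

    Returns
    -------
    (transform, rms_residual_nm)

    Raises
    ------
    RegistrationError
        Fewer than three pairs, mismatched lengths, or (near-)collinear
        bead positions.
    """
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    if green.shape != red.shape or green.ndim != 2 or green.shape[1] != 2:
        raise RegistrationError("green and red must be matching (n, 2) arrays")
    n = len(green)
    if n < 3:
        raise RegistrationError(f"need >= 3 matched pairs, got {n}")
    A = np.column_stack([green, np.ones(n)])
    # collinearity check on the design matrix
    s = np.linalg.svd(A, compute_uv=False)
    if s[-1] < 1e-9 * max(s[0], 1.0):
        raise RegistrationError("bead positions are collinear or degenerate")
    coef_x, *_ = np.linalg.lstsq(A, red[:, 0], rcond=None)
    coef_y, *_ = np.linalg.lstsq(A, red[:, 1], rcond=None)
    t = ChannelTransform(a=coef_x[0], b=coef_x[1], c=coef_x[2],
                         d=coef_y[0], e=coef_y[1], f=coef_y[2])
    resid = red - t.apply(green)
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1)))) if n else 0.0
    return t, rms


def apply_transform(table, transform: ChannelTransform):
    """Map a localization table's coordinates; all other fields untouched."""
    df = table.df.copy()
    xy = transform.apply(df[["x_nm", "y_nm"]].to_numpy(dtype=float))
    df["x_nm"] = xy[:, 0]
    df["y_nm"] = xy[:, 1]
    return table.with_df(df)


def correlation_image(red_image: np.ndarray, green_image: np.ndarray
                      ) -> np.ndarray:
    """Element-wise product of equally binned red and green images.

    Regions present in only one channel multiply to 0; co-localized
    structures give positive values.
    """
    red_image = np.asarray(red_image, dtype=float)
    green_image = np.asarray(green_image, dtype=float)
    if red_image.shape != green_image.shape:
        raise RegistrationError(
            f"channel images must share shape and binning, got "
            f"{red_image.shape} vs {green_image.shape}")
    return red_image * green_image


@dataclass
class CorrelationMap:
    """Tile-summed correlation density over the field of view."""

    tile_sums: np.ndarray        #: (n_ty, n_tx), raw sums
    normalized: np.ndarray       #: tile_sums / max, in [0, 1]
    tile_px: int                 #: tile edge length in bins
    cv: float                    #: coefficient of variation of tile sums

    def to_frame(self) -> pd.DataFrame:
        ty, tx = np.indices(self.tile_sums.shape)
        return pd.DataFrame({"tile_x": tx.ravel(), "tile_y": ty.ravel(),
                             "sum": self.tile_sums.ravel(),
                             "normalized": self.normalized.ravel()})


def correlation_density(product_image: np.ndarray, bin_nm: float = 10.0,
                        tile_um: float = 1.6) -> CorrelationMap:
    """Tile the correlation image and normalize to the maximum tile.

    Tiles form a non-overlapping grid anchored at the image origin; partial
    edge tiles are dropped.  The uniformity statistic is the coefficient of
    variation of the raw tile sums (0 for a perfectly uniform field).
    """
    img = np.asarray(product_image, dtype=float)
    tile_px = int(round(tile_um * 1000.0 / bin_nm))
    if tile_px < 1:
        raise RegistrationError("tile smaller than one bin")
    n_ty, n_tx = img.shape[0] // tile_px, img.shape[1] // tile_px
    if n_ty < 1 or n_tx < 1:
        raise RegistrationError(
            f"field {img.shape} smaller than one {tile_px}-bin tile")
    core = img[:n_ty * tile_px, :n_tx * tile_px]
    sums = core.reshape(n_ty, tile_px, n_tx, tile_px).sum(axis=(1, 3))
    peak = sums.max()
    normalized = sums / peak if peak > 0 else np.zeros_like(sums)
    mean = sums.mean()
    cv = float(sums.std(ddof=1) / mean) if (sums.size > 1 and mean > 0) else 0.0
    return CorrelationMap(tile_sums=sums, normalized=normalized,
                          tile_px=tile_px, cv=cv)
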