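"""Pixel-size calibration from a stage-micrometre grating image.

The object-space pixel size P (nm/pixel) carries the traceability chain:
SI -> calibrated micrometre pitches (reference lengths with expanded
uncertainties, k = 2) -> P -> nanoruler distance.  Line centres are located
to sub-pixel precision, per-interval pixel sizes P_i = L_ref,i / dc_i are
averaged, and u(P) combines three separately reported components:

* reference:   the calibrated pitch uncertainties, halved to standard and
  propagated through the mean (independent between intervals);
* field variation:  the scatter of the P_i, treated as an uncertainty
  contribution rather than corrected — optics distortion makes the local
  magnification position-dependent, and a measured structure may sit
  anywhere in the field, so this term does NOT shrink with the number of
  intervals;
* line fit:    sub-pixel centre-location uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd


class CalibrationError(ValueError):
    pass


@dataclass
class PixelCalibration:
    """Calibrated pixel size with its decomposed uncertainty."""

    pixel_size: float            #: P, nm/pixel
    u_pixel_size: float          #: u(P), nm/pixel (standard)
    interval_pitches_px: np.ndarray
    interval_pixel_sizes: np.ndarray
    reference_lengths_nm: np.ndarray
    reference_U_k2_nm: np.ndarray
    u_reference: float           #: component (nm/pixel)
    u_field_variation: float     #: component (nm/pixel)
    u_line_fit: float            #: component (nm/pixel)
    per_interval_reference_contrib: np.ndarray  #: (U_i/2)/dc_i / n, nm/pixel

    @property
    def expanded_relative(self) -> float:
        """Expanded (k = 2) relative uncertainty of P."""
        return 2.0 * self.u_pixel_size / self.pixel_size

    def summary(self) -> str:
        lines = [
            "Pixel-size calibration",
            f"  P                    : {self.pixel_size:.3f} nm/pixel",
            f"  u(P)                 : {self.u_pixel_size:.4f} nm/pixel",
            f"  expanded (k=2), rel. : {100 * self.expanded_relative:.2f} %",
            "  components (nm/pixel):",
            f"    reference pitches  : {self.u_reference:.4f}",
            f"    field variation    : {self.u_field_variation:.4f}",
            f"    line-centre fit    : {self.u_line_fit:.4f}",
            f"  intervals            : {len(self.interval_pitches_px)}",
        ]
        return "\n".join(lines)

    def components_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": ["reference", "field_variation", "line_fit"],
            "u_nm_per_px": [self.u_reference, self.u_field_variation,
                            self.u_line_fit],
        })


def locate_lines(image: np.ndarray,
                 row_band: Optional[Tuple[int, int]] = None,
                 min_prominence_frac: float = 0.2,
                 ) -> np.ndarray:
    """Sub-pixel centres of the grating's dark lines, in pixels.

    Columns are averaged over a row band to a 1D profile; each valley deeper
    than ``min_prominence_frac`` of the profile's dynamic range is refined
    with a parabola through the minimum and its two neighbours.  Centres are
    returned strictly increasing.

    Raises
    ------
    CalibrationError
        If fewer than two lines are detected (e.g. a flat image).
    """
    from scipy.signal import find_peaks

    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise CalibrationError("expected a 2D grayscale image")
    if row_band is None:
        row_band = (0, img.shape[0])
    profile = img[row_band[0]:row_band[1]].mean(axis=0)
    rng_dyn = profile.max() - profile.min()
    if rng_dyn <= 0:
        raise CalibrationError("flat image: no lines detected")
    inverted = profile.max() - profile
    peaks, _ = find_peaks(inverted, prominence=min_prominence_frac * rng_dyn)
    if len(peaks) < 2:
        raise CalibrationError(f"need >= 2 lines, detected {len(peaks)}")
    centers = []
    for p in peaks:
        if p == 0 or p == len(profile) - 1:
            centers.append(float(p))
            continue
        y0, y1, y2 = inverted[p - 1], inverted[p], inverted[p + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        centers.append(float(p + np.clip(delta, -0.5, 0.5)))
    centers = np.asarray(sorted(centers))
    return centers


def _line_center_uncertainty(image: np.ndarray,
                             row_band: Optional[Tuple[int, int]] = None
                             ) -> float:
    """Crude per-centre uncertainty (px) from row-to-row centre scatter.

    Each row of the band gives its own centre estimates; their scatter over
    rows, divided by sqrt(n_rows), bounds the uncertainty of the band-mean
    centre.  Falls back to 0 for perfectly uniform images.
    """
    img = np.asarray(image, dtype=float)
    if row_band is None:
        row_band = (0, img.shape[0])
    rows = img[row_band[0]:row_band[1]]
    n_rows = len(rows)
    if n_rows < 4:
        return 0.0
    # noise level of the band-averaged profile, estimated from row variance
    col_sd = rows.std(axis=0, ddof=1).mean() / math.sqrt(n_rows)
    profile = rows.mean(axis=0)
    curv = np.abs(np.diff(profile, 2)).max()
    if curv <= 0:
        return 0.0
    # parabolic-interpolation error propagation: delta = (y0-y2)/(2(y0-2y1+y2))
    return float(math.sqrt(1.5) * col_sd / curv)


def calibrate_pixel_size(centers_px: Sequence[float],
                         reference_lengths_nm: Sequence[float],
                         reference_U_k2_nm: Sequence[float],
                         line_center_u_px: float = 0.0,
                         ) -> PixelCalibration:
    """Pixel size and uncertainty from line centres and calibrated pitches.

    Parameters
    ----------
    centers_px
        Strictly increasing sub-pixel line centres (n_lines).
    reference_lengths_nm, reference_U_k2_nm
        Calibrated length and expanded (k = 2) uncertainty of each of the
        n_lines - 1 intervals; expanded values are halved to standard.
    line_center_u_px
        Standard uncertainty of a single line centre (pixels).
    """
    centers = np.asarray(centers_px, dtype=float)
    L = np.asarray(reference_lengths_nm, dtype=float)
    U = np.asarray(reference_U_k2_nm, dtype=float)
    if len(centers) < 2:
        raise CalibrationError("need at least two line centres")
    d = np.diff(centers)
    if np.any(d <= 0):
        raise CalibrationError("line centres must be strictly increasing")
    if len(L) != len(d) or len(U) != len(d):
        raise CalibrationError(
            f"{len(d)} intervals but {len(L)} reference lengths / "
            f"{len(U)} uncertainties")
    n = len(d)
    P_i = L / d
    P = float(P_i.mean())
    # (a) reference: independent standard uncertainties U_i/2, sensitivity 1/n
    per_int_ref = (U / 2.0) / d / n
    u_ref = float(np.sqrt(np.sum(per_int_ref ** 2)))
    # (b) field variation / distortion: scatter of P_i, NOT averaged down
    u_field = float(P_i.std(ddof=1)) if n > 1 else 0.0
    # (c) line-centre fit: each pitch uses two centres -> sqrt(2)*u_c,
    #     independent-ish between intervals
    u_line = float(np.sqrt(np.sum((math.sqrt(2.0) * line_center_u_px
                                   * P_i / d / n) ** 2)))
    u_P = math.sqrt(u_ref ** 2 + u_field ** 2 + u_line ** 2)
    return PixelCalibration(pixel_size=P, u_pixel_size=u_P,
                            interval_pitches_px=d, interval_pixel_sizes=P_i,
                            reference_lengths_nm=L, reference_U_k2_nm=U,
                            u_reference=u_ref, u_field_variation=u_field,
                            u_line_fit=u_line,
                            per_interval_reference_contrib=per_int_ref)


def calibrate_from_image(image: np.ndarray,
                         reference_lengths_nm: Sequence[float],
                         reference_U_k2_nm: Sequence[float],
                         row_band: Optional[Tuple[int, int]] = None,
                         ) -> PixelCalibration:
    """Convenience wrapper: locate lines, estimate centre noise, calibrate."""
    centers = locate_lines(image, row_band=row_band)
    u_c = _line_center_uncertainty(image, row_band=row_band)
    return calibrate_pixel_size(centers, reference_lengths_nm,
                                reference_U_k2_nm, line_center_u_px=u_c)


def read_reference_pitches(path) -> Tuple[np.ndarray, np.ndarray]:
    """Read a reference-pitch CSV (interval_id, length_nm, U_k2_nm)."""
    df = pd.read_csv(path)
    required = {"interval_id", "length_nm", "U_k2_nm"}
    if not required.issubset(df.columns):
        raise CalibrationError(
            f"reference pitch file must have columns {sorted(required)}")
    df = df.sort_values("interval_id")
    return (df["length_nm"].to_numpy(dtype=float),
            df["U_k2_nm"].to_numpy(dtype=float))
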