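"""Drift and resolution benchmarking.

Long acquisitions reveal a microscope's mechanical stability: a structure's
localization transient (per-frame positions over hours) shows residual
drift, a windowed-centroid estimate can subtract it, and Gaussian fits of
cross-section spot profiles through the rendered image quantify the
resolution that survives the acquisition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from skimage.measure import profile_line

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))   # 2.3548...


class DriftError(ValueError):
    pass


@dataclass
class DriftTrace:
    """Estimated sample drift over the acquisition.

    The trace starts at (0, 0) by construction; ``rate_nmh`` is the slope of
    a straight-line fit in nm/h with its standard error.
    """

    t_s: np.ndarray
    dx_nm: np.ndarray
    dy_nm: np.ndarray
    method: str                        #: "fiducial" or "structure-centroid"
    rate_nmh: Tuple[float, float]
    rate_u_nmh: Tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.t_s) and (abs(self.dx_nm[0]) > 1e-9 or abs(self.dy_nm[0]) > 1e-9):
            raise ValueError("drift trace must start at (0, 0)")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("trace timestamps must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t_s, "dx_nm": self.dx_nm,
                             "dy_nm": self.dy_nm})


def localization_transient(indices: np.ndarray, table) -> pd.DataFrame:
    """Per-frame positions of one structure over the acquisition.

    Parameters
    ----------
    indices : array of row positions (e.g. ``candidate.indices``); empty
        input yields an empty series.
    table : LocalizationTable

    Returns
    -------
    DataFrame ``t_s, frame, x_nm, y_nm`` sorted by frame.
    """
    idx = np.asarray(indices, dtype=np.int64)
    sub = table.df.iloc[idx]
    out = pd.DataFrame({
        "t_s": (sub["frame"].to_numpy(dtype=float) + 0.5) * table.frame_time,
        "frame": sub["frame"].to_numpy(),
        "x_nm": sub["x_nm"].to_numpy(),
        "y_nm": sub["y_nm"].to_numpy(),
    })
    return out.sort_values("frame").reset_index(drop=True)


def _linear_rate(t_s: np.ndarray, v: np.ndarray) -> Tuple[float, float]:
    """Slope in nm/h with standard error from a least-squares line."""
    if len(t_s) < 3:
        return 0.0, math.inf
    t_h = t_s / 3600.0
    A = np.column_stack([t_h, np.ones_like(t_h)])
    coef, res, *_ = np.linalg.lstsq(A, v, rcond=None)
    dof = len(t_h) - 2
    if dof > 0 and len(res):
        s2 = float(res[0]) / dof
        cov = s2 * np.linalg.inv(A.T @ A)
        return float(coef[0]), float(math.sqrt(max(cov[0, 0], 0.0)))
    return float(coef[0]), math.inf


def estimate_drift(table, labels: Optional[np.ndarray] = None,
                   window_frames: int = 500,
                   method: str = "structure-centroid") -> DriftTrace:
    """Windowed-centroid drift estimate.

    Frames are grouped into windows of ``window_frames``.  With ``labels``
    (per-row structure assignment, -1 = unassigned) each structure's
    windowed centroid is taken relative to that structure's own overall
    centroid, and the per-window drift is the localization-count-weighted
    mean over structures — this removes the structure-position spread that
    would otherwise drown the estimate.  Without labels all localizations
    are treated as a single reference structure (fiducial-style).
    """
    df = table.df
    if len(df) == 0:
        raise DriftError("cannot estimate drift from an empty table")
    if window_frames < 1:
        raise DriftError("window_frames must be >= 1")
    frames = df["frame"].to_numpy()
    win = frames // window_frames
    x = df["x_nm"].to_numpy(dtype=float)
    y = df["y_nm"].to_numpy(dtype=float)
    lab = (np.zeros(len(df), dtype=np.int64) if labels is None
           else np.asarray(labels, dtype=np.int64))
    ok = lab >= 0
    if not ok.any():
        raise DriftError("no labelled localizations to track")
    sub = pd.DataFrame({"win": win[ok], "lab": lab[ok], "x": x[ok], "y": y[ok]})
    per_struct = sub.groupby("lab")[["x", "y"]].mean()
    g = sub.groupby(["win", "lab"])
    cent = g[["x", "y"]].mean()
    cnt = g.size().rename("n")
    rel = cent - per_struct.reindex(cent.index.get_level_values("lab")).to_numpy()
    rel = rel.join(cnt)
    agg = rel.groupby(level="win").apply(
        lambda d: pd.Series({
            "dx": np.average(d["x"], weights=d["n"]),
            "dy": np.average(d["y"], weights=d["n"]),
        }))
    wins = agg.index.to_numpy()
    t_s = (wins + 0.5) * window_frames * table.frame_time
    dx = agg["dx"].to_numpy()
    dy = agg["dy"].to_numpy()
    dx = dx - dx[0]
    dy = dy - dy[0]
    rx, ux = _linear_rate(t_s, dx)
    ry, uy = _linear_rate(t_s, dy)
    return DriftTrace(t_s=t_s, dx_nm=dx, dy_nm=dy, method=method,
                      rate_nmh=(rx, ry), rate_u_nmh=(ux, uy))


def estimate_and_correct_drift(table, labels: Optional[np.ndarray] = None,
                               window_frames: int = 500):
    """Estimate drift, interpolate it per frame and subtract it.

    Returns ``(corrected_table, DriftTrace)``.
    """
    trace = estimate_drift(table, labels=labels, window_frames=window_frames)
    df = table.df.copy()
    t = (df["frame"].to_numpy(dtype=float) + 0.5) * table.frame_time
    df["x_nm"] = df["x_nm"].to_numpy() - np.interp(t, trace.t_s, trace.dx_nm)
    df["y_nm"] = df["y_nm"].to_numpy() - np.interp(t, trace.t_s, trace.dy_nm)
    return table.with_df(df), trace


# ---------------------------------------------------------------------------
# cross-section resolution analysis
# ---------------------------------------------------------------------------

@dataclass
class PeakFit:
    center_nm: float
    sigma_nm: float
    fwhm_nm: float
    amplitude: float


def _gauss(x, amp, mu, sigma, off):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + off


def cross_section_fwhm(image: np.ndarray,
                       start_nm: Tuple[float, float],
                       end_nm: Tuple[float, float],
                       bin_nm: float,
                       width_nm: float = 20.0,
                       min_peak_frac: float = 0.25) -> List[PeakFit]:
    """Gaussian spot widths along a cross-section of a rendered image.

    The intensity profile along the segment (averaged perpendicular over
    ``width_nm``) is scanned for peaks rising at least ``min_peak_frac`` of
    the dynamic range above background; each peak gets its own Gaussian fit
    and FWHM = 2*sqrt(2 ln 2) * sigma.

    Raises
    ------
    DriftError
        If no peak rises above background (e.g. a flat profile).
    """
    from scipy.signal import find_peaks

    img = np.asarray(image, dtype=float)
    p0 = (start_nm[1] / bin_nm - 0.5, start_nm[0] / bin_nm - 0.5)  # (row, col)
    p1 = (end_nm[1] / bin_nm - 0.5, end_nm[0] / bin_nm - 0.5)
    lw = max(int(round(width_nm / bin_nm)), 1)
    prof = profile_line(img, p0, p1, linewidth=lw, order=1,
                        mode="constant", reduce_func=np.mean)
    s_nm = np.arange(len(prof)) * bin_nm
    base = np.percentile(prof, 10)
    dyn = prof.max() - base
    if dyn <= 0:
        raise DriftError("flat cross-section: no peak above background")
    peaks, _ = find_peaks(prof, height=base + min_peak_frac * dyn,
                          prominence=min_peak_frac * dyn)
    if len(peaks) == 0:
        raise DriftError("no peak above background in cross-section")
    # fit window half-width: half the spacing to the nearest peak, else all
    fits: List[PeakFit] = []
    for i, p in enumerate(peaks):
        if len(peaks) > 1:
            gaps = [abs(p - q) for q in peaks if q != p]
            half = max(min(gaps) // 2, 3)
        else:
            half = len(prof)
        lo, hi = max(p - half, 0), min(p + half + 1, len(prof))
        xw, yw = s_nm[lo:hi], prof[lo:hi]
        try:
            popt, _ = curve_fit(
                _gauss, xw, yw,
                p0=[prof[p] - base, s_nm[p], max(2 * bin_nm, 1.0), base],
                maxfev=10_000)
        except RuntimeError:
            continue
        sigma = abs(float(popt[2]))
        center = float(popt[1])
        # discard degenerate fits: centre outside its window or width
        # broader than the window itself
        if not (s_nm[lo] - bin_nm <= center <= s_nm[hi - 1] + bin_nm):
            continue
        if sigma > (s_nm[hi - 1] - s_nm[lo]) or popt[0] <= 0:
            continue
        fits.append(PeakFit(center_nm=center, sigma_nm=sigma,
                            fwhm_nm=FWHM_PER_SIGMA * sigma,
                            amplitude=float(popt[0])))
    if not fits:
        raise DriftError("no cross-section peak could be fitted")
    fits.sort(key=lambda f: f.center_nm)
    return fits
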