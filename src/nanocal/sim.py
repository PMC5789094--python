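"""Monte-Carlo generator of DNA-PAINT localization data with ground truth.

The generator models the blinking of a DNA-PAINT binding site as a two-state
renewal process (exponential ON/OFF dwells with means ``t_on``/``t_off``),
discretizes events onto camera frames, draws photon counts, merges emitters
that are simultaneously ON within a diffraction-limited radius, and adds
localization noise ``sigma_psf / sqrt(N_photons)``, drift and false
positives.  Everything downstream (picking, distance fitting, registration,
drift benchmarking) consumes its output, and every output carries a full
:class:`~nanocal.tables.GroundTruth`.

Also houses the synthetic stage-micrometre grating images used for
pixel-size calibration, matched bead fields for two-colour registration,
the super-resolution renderer and the origami design-distance rule.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import erf

from .config import ConfigError, SimConfig
from .tables import (GroundTruth, LocalizationTable, SOURCE_FALSE_POSITIVE,
                     SOURCE_MERGED, SOURCE_SITE, empty_frame)

# nm per nucleotide along the double helix / between adjacent helix centres
BASE_RISE_NM = 0.34
HELIX_PITCH_NM = 3.0

# fixed spawn-key prefixes so per-ruler substreams never collide with the
# field-level streams (placement, false positives)
_STREAM_RULER = 1
_STREAM_PLACEMENT = 2
_STREAM_FP = 3


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# blinking kinetics
# ---------------------------------------------------------------------------

def simulate_binding_events(config: SimConfig,
                            sites: np.ndarray,
                            rng: Optional[np.random.Generator] = None
                            ) -> pd.DataFrame:
    """Simulate ON intervals of every binding site over the acquisition.

    Each site alternates dark (mean dwell ``t_off``) and bright (mean dwell
    ``t_on``) states, starting dark; dwells are exponential.  Events are
    truncated to ``[0, n_frames * frame_time]``.

    Parameters
    ----------
    config : SimConfig
    sites : (n_sites, 2) array
        Site positions (nm); only the count matters here, positions are
        carried by index.
    rng : numpy Generator, optional
        Substream to use; defaults to a stream derived from ``config.seed``.

    Returns
    -------
    DataFrame with columns ``site`` (index into ``sites``), ``t_start``,
    ``t_end`` (s), one row per bright event, ordered by site then time.
    """
    config.validate()
    sites = np.asarray(sites, dtype=float)
    if sites.size == 0:
        return pd.DataFrame({"site": pd.Series(dtype=int),
                             "t_start": pd.Series(dtype=float),
                             "t_end": pd.Series(dtype=float)})
    if rng is None:
        rng = _rng(config.seed, _STREAM_RULER, 0)
    T = config.total_time
    cycle = config.t_on + config.t_off
    out_site: List[np.ndarray] = []
    out_t0: List[np.ndarray] = []
    out_t1: List[np.ndarray] = []
    for s in range(len(sites)):
        # draw enough renewal cycles in one go, extend if unlucky
        n_guess = int(T / cycle * 1.5 + 10)
        offs = rng.exponential(config.t_off, n_guess)
        ons = rng.exponential(config.t_on, n_guess)
        while offs.sum() + ons.sum() < T:
            offs = np.concatenate([offs, rng.exponential(config.t_off, n_guess)])
            ons = np.concatenate([ons, rng.exponential(config.t_on, n_guess)])
        edges = np.empty(2 * len(offs))
        edges[0::2] = offs
        edges[1::2] = ons
        cum = np.cumsum(edges)
        t0 = cum[0::2]  # end of each OFF dwell = start of the ON event
        t1 = cum[1::2]
        keep = t0 < T
        t0, t1 = t0[keep], np.minimum(t1[keep], T)
        out_site.append(np.full(len(t0), s, dtype=int))
        out_t0.append(t0)
        out_t1.append(t1)
    return pd.DataFrame({"site": np.concatenate(out_site),
                         "t_start": np.concatenate(out_t0),
                         "t_end": np.concatenate(out_t1)})


# ---------------------------------------------------------------------------
# events -> localizations
# ---------------------------------------------------------------------------

def _events_to_frame_entries(events: pd.DataFrame, config: SimConfig
                             ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand bright events into per-frame (frame, site, overlap) triples.

    ``overlap`` is the fraction of the frame's integration window during
    which the site was ON.
    """
    if len(events) == 0:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
                np.empty(0))
    ft = config.frame_time
    t0 = events["t_start"].to_numpy()
    t1 = events["t_end"].to_numpy()
    site = events["site"].to_numpy()
    f0 = np.floor(t0 / ft).astype(np.int64)
    f1 = np.minimum(np.ceil(t1 / ft).astype(np.int64) - 1, config.n_frames - 1)
    f1 = np.maximum(f1, f0)
    counts = f1 - f0 + 1
    frames = np.concatenate([np.arange(a, b + 1) for a, b in zip(f0, f1)])
    sites = np.repeat(site, counts)
    ev_t0 = np.repeat(t0, counts)
    ev_t1 = np.repeat(t1, counts)
    win_lo = frames * ft
    win_hi = win_lo + ft
    overlap = (np.minimum(ev_t1, win_hi) - np.maximum(ev_t0, win_lo)) / ft
    good = overlap > 0
    return frames[good], sites[good], overlap[good]


def _merge_clusters(pos: np.ndarray, radius: float) -> List[np.ndarray]:
    """Group points by chaining pairwise distances below ``radius``.

    Small inputs only (sites of one structure simultaneously ON in one
    frame); a simple union-find is plenty.
    """
    n = len(pos)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1]) < radius:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [np.asarray(g) for g in groups.values()]


def events_to_localizations(events: pd.DataFrame,
                            config: SimConfig,
                            site_positions: np.ndarray,
                            rng: Optional[np.random.Generator] = None,
                            ruler_id: int = -1,
                            field_size: Optional[Tuple[float, float]] = None,
                            site_marks: Optional[np.ndarray] = None,
                            ) -> pd.DataFrame:
    """Turn bright events into a localization table fragment.

    Per frame, every ON site emits ``Poisson(photons_per_frame * overlap)``
    photons; frames below ``config.min_photons`` are discarded.  Sites that
    are simultaneously ON and closer than the merge radius yield ONE
    localization at their photon-weighted centroid, labelled ``merged`` —
    the distance-shortening mechanism of a high duty cycle.  Positions then
    acquire isotropic Gaussian noise ``sigma_psf/sqrt(N)`` and the linear
    drift offset of their frame.  With ``photons_per_frame = inf`` the
    generator is exact: no photon noise, no localization noise.
    """
    config.validate()
    site_positions = np.asarray(site_positions, dtype=float)
    if rng is None:
        rng = _rng(config.seed, _STREAM_RULER, max(ruler_id, 0))
    if site_marks is None:
        site_marks = np.full(len(site_positions), -1, dtype=int)

    frames, sites, overlap = _events_to_frame_entries(events, config)
    noiseless = math.isinf(config.photons_per_frame)
    if noiseless:
        photons = np.full(len(frames), np.inf)
    else:
        photons = rng.poisson(config.photons_per_frame * overlap).astype(float)
        keep = photons >= config.min_photons
        frames, sites, photons = frames[keep], sites[keep], photons[keep]

    rows_frame: List[int] = []
    rows_x: List[float] = []
    rows_y: List[float] = []
    rows_ph: List[float] = []
    rows_src: List[str] = []
    rows_mark: List[int] = []

    if len(frames):
        order = np.argsort(frames, kind="stable")
        frames, sites, photons = frames[order], sites[order], photons[order]
        uniq, starts, counts = np.unique(frames, return_index=True,
                                         return_counts=True)
        merge_r = config.merge_radius_nm
        # singles: vectorized fast path
        single = counts == 1
        sidx = starts[single]
        rows_frame.extend(frames[sidx].tolist())
        rows_x.extend(site_positions[sites[sidx], 0].tolist())
        rows_y.extend(site_positions[sites[sidx], 1].tolist())
        rows_ph.extend(photons[sidx].tolist())
        rows_src.extend([SOURCE_SITE] * len(sidx))
        rows_mark.extend(site_marks[sites[sidx]].tolist())
        # frames with >= 2 ON sites: merge within radius
        for u, st, ct in zip(uniq[~single], starts[~single], counts[~single]):
            idx = slice(st, st + ct)
            pos = site_positions[sites[idx]]
            ph = photons[idx]
            for grp in _merge_clusters(pos, merge_r):
                w = ph[grp]
                if noiseless:
                    w = np.ones_like(w)
                centroid = np.average(pos[grp], axis=0, weights=w)
                rows_frame.append(int(u))
                rows_x.append(float(centroid[0]))
                rows_y.append(float(centroid[1]))
                rows_ph.append(float(ph[grp].sum()))
                if len(grp) == 1:
                    rows_src.append(SOURCE_SITE)
                    rows_mark.append(int(site_marks[sites[idx]][grp[0]]))
                else:
                    rows_src.append(SOURCE_MERGED)
                    marks = set(site_marks[sites[idx]][grp].tolist())
                    rows_mark.append(marks.pop() if len(marks) == 1 else -1)

    frame_arr = np.asarray(rows_frame, dtype=np.int64)
    x = np.asarray(rows_x)
    y = np.asarray(rows_y)
    ph_arr = np.asarray(rows_ph)
    if noiseless:
        sigma_loc = np.zeros(len(x))
    else:
        sigma_loc = config.sigma_psf / np.sqrt(np.maximum(ph_arr, 1.0))
        noise = rng.normal(size=(len(x), 2)) * sigma_loc[:, None]
        x = x + noise[:, 0]
        y = y + noise[:, 1]
    # linear drift (nm/h), applied at the frame midpoint
    vx, vy = config.drift_velocity
    if vx or vy:
        t_h = (frame_arr + 0.5) * config.frame_time / 3600.0
        x = x + vx * t_h
        y = y + vy * t_h

    df = pd.DataFrame({"frame": frame_arr, "x_nm": x, "y_nm": y,
                       "photons": ph_arr, "sigma_nm": sigma_loc,
                       "source": rows_src,
                       "ruler": np.full(len(x), ruler_id, dtype=np.int64),
                       "mark": np.asarray(rows_mark, dtype=np.int64)})

    if config.fp_density > 0 and field_size is not None:
        df = pd.concat([df, _false_positives(config, field_size, rng)],
                       ignore_index=True)
    return df


def _false_positives(config: SimConfig, field_size: Tuple[float, float],
                     rng: np.random.Generator) -> pd.DataFrame:
    area_um2 = field_size[0] * field_size[1] / 1e6
    n = rng.poisson(config.fp_density * area_um2 * config.n_frames)
    x = rng.uniform(0, field_size[0], n)
    y = rng.uniform(0, field_size[1], n)
    ph = np.maximum(rng.exponential(2 * config.min_photons, n),
                    config.min_photons)
    return pd.DataFrame({"frame": rng.integers(0, config.n_frames, n),
                         "x_nm": x, "y_nm": y, "photons": ph,
                         "sigma_nm": config.sigma_psf / np.sqrt(ph),
                         "source": [SOURCE_FALSE_POSITIVE] * n,
                         "ruler": np.full(n, -1, dtype=np.int64),
                         "mark": np.full(n, -1, dtype=np.int64)})


# ---------------------------------------------------------------------------
# nanoruler fields
# ---------------------------------------------------------------------------

def _ruler_sites(config: SimConfig, center: np.ndarray, angle: float,
                 distance: float, rng: np.random.Generator
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Active site positions of one two-mark ruler, plus per-site mark ids."""
    layout = config.sites_per_mark
    c, s = math.cos(angle), math.sin(angle)
    R = np.array([[c, -s], [s, c]])
    pos = []
    marks = []
    for mark_id, sign in ((0, -0.5), (1, +0.5)):
        mark_center = center + R @ np.array([sign * distance, 0.0])
        world = (R @ layout.T).T + mark_center
        active = rng.random(len(world)) < config.site_activity_prob
        pos.append(world[active])
        marks.append(np.full(active.sum(), mark_id, dtype=int))
    return np.vstack(pos), np.concatenate(marks)


def generate_nanoruler_field(config: SimConfig, n_rulers: int,
                             field_size: Tuple[float, float] = (20_000.0, 20_000.0),
                             min_separation: Optional[float] = None,
                             ) -> Tuple[LocalizationTable, GroundTruth]:
    """Simulate a field of two-mark nanorulers with known ground truth.

    Rulers land at uniform random positions (rejection-sampled to keep a
    minimum spacing) with uniform random orientations; each ruler's true
    distance is drawn from ``Normal(true_distance_mean, true_distance_sd)``.

    Raises
    ------
    ConfigError
        If the field cannot hold ``n_rulers`` at the minimum spacing.
    """
    config.validate()
    if n_rulers < 1:
        raise ConfigError("n_rulers must be >= 1")
    if min_separation is None:
        min_separation = 4.0 * config.true_distance_mean
    margin = config.true_distance_mean
    w, h = field_size
    if w <= 2 * margin or h <= 2 * margin:
        raise ConfigError("field_size too small for even one ruler")
    usable = (w - 2 * margin) * (h - 2 * margin)
    if n_rulers * min_separation ** 2 > 0.6 * usable:
        raise ConfigError(
            f"field {w:.0f}x{h:.0f} nm too small for {n_rulers} rulers at "
            f"minimum spacing {min_separation:.0f} nm")

    place_rng = _rng(config.seed, _STREAM_PLACEMENT)
    centers = np.empty((n_rulers, 2))
    placed = 0
    attempts = 0
    while placed < n_rulers:
        attempts += 1
        if attempts > 200 * n_rulers:
            raise ConfigError("could not place rulers at the requested "
                              "minimum spacing; enlarge the field")
        cand = np.array([place_rng.uniform(margin, w - margin),
                         place_rng.uniform(margin, h - margin)])
        if placed and (np.hypot(*(centers[:placed] - cand).T).min()
                       < min_separation):
            continue
        centers[placed] = cand
        placed += 1

    parts = []
    angles = np.empty(n_rulers)
    distances = np.empty(n_rulers)
    for k in range(n_rulers):
        rk = _rng(config.seed, _STREAM_RULER, k)
        angles[k] = rk.uniform(0, math.pi)
        d = config.true_distance_mean
        if config.true_distance_sd > 0:
            d = rk.normal(config.true_distance_mean, config.true_distance_sd)
        distances[k] = d
        sites, marks = _ruler_sites(config, centers[k], angles[k], d, rk)
        if len(sites) == 0:
            continue
        ev = simulate_binding_events(config, sites, rng=rk)
        parts.append(events_to_localizations(ev, config, sites, rng=rk,
                                             ruler_id=k, site_marks=marks))
    if config.fp_density > 0:
        parts.append(_false_positives(config, field_size,
                                      _rng(config.seed, _STREAM_FP)))
    df = (pd.concat(parts, ignore_index=True) if parts else empty_frame())
    df = df.sort_values(["frame", "x_nm", "y_nm"], kind="stable").reset_index(drop=True)
    table = LocalizationTable(df=df, pixel_size=config.pixel_size,
                              frame_time=config.frame_time, seed=config.seed,
                              field_size=tuple(field_size))
    truth = GroundTruth(rulers=pd.DataFrame({
        "ruler": np.arange(n_rulers), "cx_nm": centers[:, 0],
        "cy_nm": centers[:, 1], "angle_rad": angles,
        "distance_nm": distances}))
    return table, truth


def generate_fiducial_field(config: SimConfig,
                            positions: np.ndarray,
                            field_size: Optional[Tuple[float, float]] = None,
                            ) -> LocalizationTable:
    """Simulate point fiducial markers (one binding site each).

    With ``t_on >> total_time`` a marker is bright in every frame — the
    constant-signal beads used for drift tracking.  Each marker's
    localizations carry its index in the ``ruler`` column.
    """
    config.validate()
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    parts = []
    for i, p in enumerate(positions):
        rng = _rng(config.seed, _STREAM_RULER, i)
        site = p.reshape(1, 2)
        ev = simulate_binding_events(config, site, rng=rng)
        parts.append(events_to_localizations(ev, config, site, rng=rng,
                                             ruler_id=i))
    df = (pd.concat(parts, ignore_index=True) if parts else empty_frame())
    df = df.sort_values(["frame", "x_nm", "y_nm"], kind="stable").reset_index(drop=True)
    return LocalizationTable(df=df, pixel_size=config.pixel_size,
                             frame_time=config.frame_time, seed=config.seed,
                             field_size=field_size)


# ---------------------------------------------------------------------------
# stage-micrometre grating images
# ---------------------------------------------------------------------------

def generate_micrometre_image(pitch_nm: float = 10_000.0,
                              n_lines: int = 11,
                              pixel_size: float = 100.0,
                              line_width_nm: float = 2_000.0,
                              edge_blur_nm: float = 800.0,
                              noise: float = 100.0,
                              distortion: float = 0.0,
                              height_px: int = 64,
                              margin_px: float = 20.0,
                              seed: int = 0,
                              ) -> Tuple[np.ndarray, dict]:
    """Render a synthetic stage-micrometre grating (dark lines, bright bg).

    ``distortion`` imposes a smooth linear magnification gradient across the
    field, scaled so the standard deviation of the per-interval pitches (in
    pixels) is ``distortion`` relative — the dominant real-world uncertainty
    of pixel-size calibration with widefield optics.

    Returns
    -------
    image : uint16 (height_px, width) array
    truth : dict with ``centers_px`` (sub-pixel line centres),
        ``pixel_size``, ``pitch_nm``, ``interval_scale`` (per-interval local
        magnification factors).
    """
    if n_lines < 2:
        raise ConfigError("n_lines must be >= 2")
    nominal_px = pitch_nm / pixel_size
    n_int = n_lines - 1
    if n_int > 1 and distortion > 0:
        ramp = np.linspace(-1.0, 1.0, n_int)
        # normalise the ramp to unit std so std(scale) == distortion exactly
        scale = 1.0 + distortion * ramp / np.std(ramp)
    else:
        scale = np.ones(n_int)
    centers = margin_px + np.concatenate([[0.0], np.cumsum(nominal_px * scale)])
    width = int(math.ceil(centers[-1] + margin_px))
    xs = np.arange(width, dtype=float)
    sigma_b = max(edge_blur_nm / pixel_size, 0.35)  # floor keeps valleys smooth
    half_w = 0.5 * line_width_nm / pixel_size
    profile = np.zeros(width)
    for c in centers:
        profile += 0.5 * (erf((xs - (c - half_w)) / (math.sqrt(2) * sigma_b))
                          - erf((xs - (c + half_w)) / (math.sqrt(2) * sigma_b)))
    img_1d = 30000.0 - 20000.0 * profile
    image = np.tile(img_1d, (height_px, 1))
    if noise > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise, image.shape)
    image = np.clip(image, 0, 65535).astype(np.uint16)
    truth = {"centers_px": centers, "pixel_size": pixel_size,
             "pitch_nm": pitch_nm, "interval_scale": scale}
    return image, truth


# ---------------------------------------------------------------------------
# bead fields for channel registration
# ---------------------------------------------------------------------------

def generate_bead_pairs(n: int, transform, noise_nm: float = 0.0,
                        field_size: Tuple[float, float] = (40_000.0, 40_000.0),
                        seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Matched green/red bead coordinates related by a channel transform.

    Green positions are uniform over the field; red = transform(green) plus
    isotropic Gaussian noise of SD ``noise_nm``.
    """
    rng = np.random.default_rng(seed)
    green = np.column_stack([rng.uniform(0, field_size[0], n),
                             rng.uniform(0, field_size[1], n)])
    red = transform.apply(green)
    if noise_nm > 0:
        red = red + rng.normal(0.0, noise_nm, red.shape)
    return green, red


# ---------------------------------------------------------------------------
# rendering and design rule
# ---------------------------------------------------------------------------

def render_sr_image(table: LocalizationTable, bin_nm: float = 10.0,
                    field_size: Optional[Tuple[float, float]] = None
                    ) -> np.ndarray:
    """2D localization-count histogram (super-resolution rendering).

    Bins are half-open ``[i*bin, (i+1)*bin)``: a localization exactly on a
    bin boundary belongs to the higher bin.  The image sum equals the number
    of in-field localizations.  Returned array is indexed ``[iy, ix]``.
    """
    if bin_nm <= 0:
        raise ConfigError("bin_nm must be > 0")
    if field_size is None:
        field_size = table.field_size
    xy = table.xy
    if field_size is None:
        if len(xy) == 0:
            raise ConfigError("empty table and no field_size given")
        field_size = (float(xy[:, 0].max()) + bin_nm,
                      float(xy[:, 1].max()) + bin_nm)
    nx = int(math.ceil(field_size[0] / bin_nm))
    ny = int(math.ceil(field_size[1] / bin_nm))
    img = np.zeros((ny, nx), dtype=np.int64)
    if len(xy):
        ix = np.floor(xy[:, 0] / bin_nm).astype(np.int64)
        iy = np.floor(xy[:, 1] / bin_nm).astype(np.int64)
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        np.add.at(img, (iy[ok], ix[ok]), 1)
    return img


def design_distance(helix_separation: int, base_separation: int) -> float:
    """Design intermark distance of a rectangular origami (nm).

    Marks offset by ``base_separation`` nucleotides along the helix axis
    (0.34 nm each) and ``helix_separation`` helices across (3 nm each)
    combine Euclideanly.

    >>> design_distance(0, 100)
    34.0
    """
    if helix_separation < 0 or base_separation < 0:
        raise ConfigError("separations must be >= 0")
    return float(math.hypot(helix_separation * HELIX_PITCH_NM,
                            base_separation * BASE_RISE_NM))
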