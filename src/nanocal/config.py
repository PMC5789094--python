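"""Configuration objects for the simulation and analysis pipeline.

All distances are in nanometres, all times in seconds, unless a field name
says otherwise.  Configurations are plain dataclasses validated eagerly so
that an invalid value fails with a message naming the offending field before
any simulation work starts.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np


class ConfigError(ValueError):
    """Raised when a configuration field holds an invalid value."""


def _default_site_layout() -> np.ndarray:
    """Default binding-site layout of one fluorescent mark.

    Nine single-stranded docking sites on a 3x3 grid with 5 nm pitch,
    mimicking a mark made of nine staple-strand protrusions on a rectangular
    origami.  Coordinates are mark-local (nm), centred on the mark centre.
    """
    g = np.array([-5.0, 0.0, 5.0])
    xx, yy = np.meshgrid(g, g)
    return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class SimConfig:
    """Ground-truth description of a simulated DNA-PAINT experiment.

    Parameters
    ----------
    t_on, t_off
        Mean bright/dark dwell times of a binding site (s).  Blinking is a
        two-state renewal process with exponentially distributed dwells; the
        duty cycle is ``t_on / (t_on + t_off)``.
    frame_time
        Camera integration time per frame (s).
    n_frames
        Number of acquired frames.
    photons_per_frame
        Mean detected photons from a site that is ON for a whole frame.
        ``math.inf`` switches the generator into a noise-free limit in which
        localizations sit exactly on the emitter position.
    sigma_psf
        Standard deviation of the point-spread function (nm).  Localization
        precision of a single event is ``sigma_psf / sqrt(N_photons)``.
    pixel_size
        Object-space camera pixel size (nm/pixel).
    merge_radius
        Two emitters simultaneously ON and closer than this (nm) are fused
        into one localization at their photon-weighted centroid — the
        mechanism by which a high duty cycle shortens measured distances.
        ``None`` selects the default ``2.5 * sigma_psf``.
    site_layout
        (n_sites, 2) mark-local coordinates (nm) of the docking sites of one
        mark; default is a 3x3 grid with 5 nm pitch.
    true_distance_mean, true_distance_sd
        Mean and Gaussian spread of the per-ruler intermark distance (nm).
        ``sd = 0`` gives identical rulers; ``sd > 0`` models inhomogeneous
        broadening (structural variation between rulers).
    site_activity_prob
        Probability that a docking site is present and active (labeling
        efficiency).
    fp_density
        False-positive localizations per um^2 per frame.
    drift_velocity
        Linear stage drift (nm/h, nm/h).
    min_photons
        Detection threshold: a frame yields a localization only if its
        photon count reaches this value.
    seed
        Master seed; identical configs with identical seeds produce
        bit-identical output.
    """

    t_on: float = 0.2
    t_off: float = 200.0
    frame_time: float = 0.1
    n_frames: int = 10_000
    photons_per_frame: float = 400.0
    sigma_psf: float = 100.0
    pixel_size: float = 100.0
    merge_radius: Optional[float] = None
    site_layout: Optional[np.ndarray] = None
    true_distance_mean: float = 60.0
    true_distance_sd: float = 0.0
    site_activity_prob: float = 0.85
    fp_density: float = 0.0
    drift_velocity: Tuple[float, float] = (0.0, 0.0)
    min_photons: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("t_on", "t_off", "frame_time", "photons_per_frame",
                     "sigma_psf", "pixel_size"):
            v = getattr(self, name)
            if not (v > 0):
                raise ConfigError(f"SimConfig.{name} must be > 0, got {v!r}")
        if not (isinstance(self.n_frames, (int, np.integer)) and self.n_frames > 0):
            raise ConfigError(f"SimConfig.n_frames must be a positive integer, "
                              f"got {self.n_frames!r}")
        if self.true_distance_mean <= 0:
            raise ConfigError("SimConfig.true_distance_mean must be > 0, "
                              f"got {self.true_distance_mean!r}")
        for name in ("true_distance_sd", "fp_density", "min_photons"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigError(f"SimConfig.{name} must be >= 0, got {v!r}")
        if not (0.0 <= self.site_activity_prob <= 1.0):
            raise ConfigError("SimConfig.site_activity_prob must lie in [0, 1], "
                              f"got {self.site_activity_prob!r}")
        if self.merge_radius is not None and self.merge_radius < 0:
            raise ConfigError(f"SimConfig.merge_radius must be >= 0, "
                              f"got {self.merge_radius!r}")
        if len(self.drift_velocity) != 2:
            raise ConfigError("SimConfig.drift_velocity must be a (vx, vy) pair")
        if self.site_layout is not None:
            arr = np.asarray(self.site_layout, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
                raise ConfigError("SimConfig.site_layout must be an (n, 2) array")

    @property
    def merge_radius_nm(self) -> float:
        return 2.5 * self.sigma_psf if self.merge_radius is None else self.merge_radius

    @property
    def sites_per_mark(self) -> np.ndarray:
        if self.site_layout is None:
            return _default_site_layout()
        return np.asarray(self.site_layout, dtype=float)

    @property
    def duty_cycle(self) -> float:
        return self.t_on / (self.t_on + self.t_off)

    @property
    def total_time(self) -> float:
        return self.n_frames * self.frame_time

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.site_layout is not None:
            d["site_layout"] = np.asarray(self.site_layout).tolist()
        d["drift_velocity"] = list(self.drift_velocity)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("site_layout") is not None:
            d["site_layout"] = np.asarray(d["site_layout"], dtype=float)
        if "drift_velocity" in d:
            d["drift_velocity"] = tuple(d["drift_velocity"])
        return cls(**d)


@dataclass
class PickingConfig:
    """Parameters of structure picking (clustering + acceptance filters).

    Defaults target 60 nm-class two-mark rulers: clustering radius 1.5x the
    nominal distance with a 10-neighbour density requirement, then filters in
    fixed order count -> size -> bimodality -> edge.
    """

    cluster_radius: float = 90.0        # nm, DBSCAN eps
    min_cluster_size: int = 10          # DBSCAN min_samples
    min_localizations: int = 20
    max_localizations: int = 100_000
    min_radius_gyration: float = 5.0    # nm
    max_radius_gyration: float = 60.0   # nm
    bimodality_threshold: float = 3.0   # PCA variance ratio lambda1/lambda2
    edge_margin: float = 100.0          # nm

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.cluster_radius <= 0:
            raise ConfigError("PickingConfig.cluster_radius must be > 0")
        if self.min_cluster_size < 1:
            raise ConfigError("PickingConfig.min_cluster_size must be >= 1")
        if not self.min_localizations < self.max_localizations:
            raise ConfigError("PickingConfig: min_localizations must be < "
                              "max_localizations")
        if not self.min_radius_gyration < self.max_radius_gyration:
            raise ConfigError("PickingConfig: min_radius_gyration must be < "
                              "max_radius_gyration")
        if self.bimodality_threshold <= 0:
            raise ConfigError("PickingConfig.bimodality_threshold must be > 0")
        if self.edge_margin < 0:
            raise ConfigError("PickingConfig.edge_margin must be >= 0")

    def replace(self, **kw) -> "PickingConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PickingConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown PickingConfig keys: {sorted(unknown)}")
        return cls(**d)
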