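"""Structure picking: density-based clustering plus acceptance filters.

Candidate nanorulers are found by DBSCAN over localization coordinates and
then filtered in a fixed order — localization count, cluster size (radius of
gyration), bimodality along the principal axis, distance to the field edge —
recording the first failed filter per candidate.  The module also quantifies
the picking-bias uncertainty u(dd_fp) by comparing the mean distance under
two different picking configurations (e.g. a permissive "automated" arm vs a
strict "manual-like" arm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .config import PickingConfig
from .tables import LocalizationTable

REJECTION_REASONS = ("too_few_locs", "too_many_locs", "too_large",
                     "too_small", "not_bimodal", "edge")


@dataclass
class NanorulerCandidate:
    """A clustered group of localizations that may be a nanoruler."""

    candidate_id: int
    indices: np.ndarray          #: row positions into the table
    centroid: np.ndarray         #: (2,) nm
    radius_gyration: float       #: nm
    count: int
    accepted: bool = False
    rejection_reason: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.accepted and self.rejection_reason:
            raise ValueError("accepted candidate cannot carry a rejection reason")


def _radius_of_gyration(xy: np.ndarray) -> float:
    c = xy.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((xy - c) ** 2, axis=1))))


def cluster_localizations(table: LocalizationTable,
                          config: Optional[PickingConfig] = None
                          ) -> List[NanorulerCandidate]:
    """Group localizations into candidate structures with DBSCAN.

    Every localization belongs to at most one candidate; sub-threshold
    density regions are left unassigned (noise).  An empty table yields an
    empty list rather than an error.  Clusters are ordered by centroid
    (x, then y) so the result is independent of table row order.
    """
    cfg = config or PickingConfig()
    xy = table.xy
    if len(xy) == 0:
        return []
    labels = DBSCAN(eps=cfg.cluster_radius,
                    min_samples=cfg.min_cluster_size).fit_predict(xy)
    cands: List[NanorulerCandidate] = []
    for lab in np.unique(labels):
        if lab < 0:
            continue
        idx = np.flatnonzero(labels == lab)
        pts = xy[idx]
        cands.append(NanorulerCandidate(
            candidate_id=-1, indices=idx, centroid=pts.mean(axis=0),
            radius_gyration=_radius_of_gyration(pts), count=len(idx)))
    cands.sort(key=lambda c: (round(c.centroid[0], 6), round(c.centroid[1], 6)))
    for i, c in enumerate(cands):
        c.candidate_id = i
    return cands


def _bimodality_ratio(xy: np.ndarray) -> float:
    """Variance along the first principal axis over the second."""
    centred = xy - xy.mean(axis=0)
    cov = centred.T @ centred / max(len(xy) - 1, 1)
    vals = np.linalg.eigvalsh(cov)
    lo, hi = float(vals[0]), float(vals[1])
    return hi / max(lo, 1e-12)


def filter_candidates(candidates: List[NanorulerCandidate],
                      table: LocalizationTable,
                      config: Optional[PickingConfig] = None
                      ) -> List[NanorulerCandidate]:
    """Apply the acceptance filters in fixed order, in place.

    Order: localization count -> radius of gyration -> bimodality -> field
    edge.  The first failed filter is recorded as the rejection reason.
    """
    cfg = config or PickingConfig()
    xy = table.xy
    if table.field_size is not None:
        xlo, ylo = 0.0, 0.0
        xhi, yhi = table.field_size
    elif len(xy):
        xlo, ylo = xy.min(axis=0)
        xhi, yhi = xy.max(axis=0)
    else:
        xlo = ylo = xhi = yhi = 0.0
    for c in candidates:
        reason = ""
        if c.count < cfg.min_localizations:
            reason = "too_few_locs"
        elif c.count > cfg.max_localizations:
            reason = "too_many_locs"
        elif c.radius_gyration > cfg.max_radius_gyration:
            reason = "too_large"
        elif c.radius_gyration < cfg.min_radius_gyration:
            reason = "too_small"
        elif _bimodality_ratio(xy[c.indices]) < cfg.bimodality_threshold:
            reason = "not_bimodal"
        elif (c.centroid[0] - xlo < cfg.edge_margin
              or xhi - c.centroid[0] < cfg.edge_margin
              or c.centroid[1] - ylo < cfg.edge_margin
              or yhi - c.centroid[1] < cfg.edge_margin):
            reason = "edge"
        c.rejection_reason = reason
        c.accepted = reason == ""
    return candidates


def candidates_to_frame(candidates: List[NanorulerCandidate]) -> pd.DataFrame:
    """Candidate export table (id, centroid, count, accepted, reason)."""
    return pd.DataFrame({
        "id": [c.candidate_id for c in candidates],
        "cx_nm": [c.centroid[0] for c in candidates],
        "cy_nm": [c.centroid[1] for c in candidates],
        "rg_nm": [c.radius_gyration for c in candidates],
        "count": [c.count for c in candidates],
        "accepted": [c.accepted for c in candidates],
        "reason": [c.rejection_reason for c in candidates],
    })


class TooFewStructuresError(ValueError):
    def __init__(self, n_a: int, n_b: int, minimum: int):
        super().__init__(
            f"picking-bias estimate needs >= {minimum} accepted structures "
            f"per arm, got {n_a} (A) and {n_b} (B)")
        self.n_a, self.n_b = n_a, n_b


def estimate_fp_uncertainty(table: LocalizationTable,
                            config_a: PickingConfig,
                            config_b: PickingConfig,
                            min_structures: int = 30,
                            min_per_mark: int = 5) -> float:
    """Standard-uncertainty surrogate for picking bias, u(dd_fp), in nm.

    Runs the pick + fit pipeline under two picking configurations (an
    automated arm and a stricter manual-like arm) and returns the absolute
    difference of the ensemble mean distances.  Identical configurations
    give exactly 0.
    """
    from .distfit import ensemble_stats, measure_field

    means = []
    counts = []
    for cfg in (config_a, config_b):
        fits, _ = measure_field(table, cfg, min_per_mark=min_per_mark)
        counts.append(len(fits))
        means.append(ensemble_stats(fits, table.pixel_size).mean_nm
                     if fits else math.nan)
    if min(counts) < min_structures:
        raise TooFewStructuresError(counts[0], counts[1], min_structures)
    return abs(means[0] - means[1])
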