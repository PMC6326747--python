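"""Association analyses on ROI-level parameter maps.

Once the inversion has produced one scalar per region (recurrent strength,
subcortical input), these maps are compared against external hierarchy
proxies: transfer onto resting-state networks or cortical-type groupings
via overlap weights, averaging across hemispheres, grouping regions into
equal-area zones ordered by parameter value, meta-analytic activation
profiles over those zones, and map-map correlations with FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ROIMap",
    "ZoneAssignment",
    "transfer_to_networks",
    "hemispheric_average",
    "assign_zones",
    "zone_activation_profile",
    "correlate_maps",
    "fdr_bh",
]


@dataclass
class ROIMap:
    """One scalar per region, optionally with surface areas (mm^2)."""

    values: np.ndarray
    roi_labels: list[str] = field(default_factory=list)
    areas: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("ROI map must be one scalar per region")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ROI map contains non-finite values")
        if not self.roi_labels:
            self.roi_labels = [f"ROI{i + 1:03d}" for i in range(self.values.size)]
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("ROI labels must be unique")
        if len(self.roi_labels) != self.values.size:
            raise ValueError("label / value length mismatch")
        if self.areas is not None:
            self.areas = np.asarray(self.areas, dtype=float)
            if self.areas.shape != self.values.shape or np.any(self.areas <= 0):
                raise ValueError("areas must be positive, one per region")

    @property
    def n(self) -> int:
        return self.values.size

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.roi_labels)


@dataclass
class ZoneAssignment:
    """Zone index 1..K per ROI; zone index increases with map value."""

    zones: np.ndarray
    n_zones: int
    roi_labels: list[str] = field(default_factory=list)


def transfer_to_networks(roi_map: ROIMap, weights: pd.DataFrame) -> pd.Series:
    """Overlap-weighted mean of an ROI map onto networks (or cortical types).

    ``weights`` has one row per ROI and one column per network; entries are
    nonnegative overlap weights (e.g. shared vertex counts or areas), so the
    result equals vertex-level averaging done at ROI resolution.
    """
    w = weights.loc[roi_map.roi_labels].to_numpy(dtype=float)
    if np.any(w < 0):
        raise ValueError("overlap weights must be nonnegative")
    colsum = w.sum(axis=0)
    dead = colsum <= 0
    if np.any(dead):
        bad = ", ".join(np.asarray(weights.columns)[dead][:5])
        raise ValueError(f"network(s) with zero total weight: {bad}")
    return pd.Series((w * roi_map.values[:, None]).sum(axis=0) / colsum,
                     index=weights.columns)


def hemispheric_average(roi_map: ROIMap,
                        lr_pairs: Sequence[tuple[str, str]]) -> ROIMap:
    """Average corresponding left/right parcels into one value per pair.

    Output labels are the left-hemisphere labels stripped of their prefix
    when an ``lh_``/``rh_`` convention is detected, else the left label.
    """
    s = roi_map.as_series()
    values, labels = [], []
    for left, right in lr_pairs:
        if left not in s.index or right not in s.index:
            missing = left if left not in s.index else right
            raise ValueError(f"hemisphere label {missing!r} not in map")
        values.append(0.5 * (s[left] + s[right]))
        labels.append(left[3:] if left.lower().startswith(("lh_", "rh_")) else left)
    return ROIMap(np.asarray(values), labels)


def assign_zones(roi_map: ROIMap, n_zones: int) -> ZoneAssignment:
    """Group ROIs into ``n_zones`` zones of increasing map value with
    approximately equal surface area.

    ROIs are sorted ascending by map value (ties broken by label for
    determinism) and split into contiguous runs; the split minimizes the
    sum of squared deviations of zone areas from the equal share
    total/n_zones, found exactly by dynamic programming. Zone 1 holds the
    lowest values.
    """
    if roi_map.areas is None:
        raise ValueError("zone assignment requires per-ROI surface areas")
    n = roi_map.n
    if not 1 <= n_zones <= n:
        raise ValueError(f"n_zones must be in [1, {n}]")
    order = sorted(range(n), key=lambda i: (roi_map.values[i], roi_map.roi_labels[i]))
    areas = roi_map.areas[order]
    csum = np.concatenate([[0.0], np.cumsum(areas)])
    target = csum[-1] / n_zones

    # cost[i][j]: optimal cost of packing sorted ROIs i..n-1 into zones j..K
    INF = np.inf
    cost = np.full((n + 1, n_zones + 1), INF)
    split = np.zeros((n + 1, n_zones + 1), dtype=int)
    cost[n, n_zones] = 0.0
    for j in range(n_zones - 1, -1, -1):
        for i in range(n - 1, -1, -1):
            best = INF
            arg = -1
            for e in range(i + 1, n + 1):
                tail = cost[e, j + 1]
                if tail == INF:
                    continue
                c = (csum[e] - csum[i] - target) ** 2 + tail
                if c < best:
                    best, arg = c, e
            cost[i, j] = best
            split[i, j] = arg
    zones_sorted = np.empty(n, dtype=int)
    i = 0
    for j in range(n_zones):
        e = split[i, j]
        zones_sorted[i:e] = j + 1
        i = e
    zones = np.empty(n, dtype=int)
    zones[np.asarray(order)] = zones_sorted
    return ZoneAssignment(zones=zones, n_zones=n_zones,
                          roi_labels=list(roi_map.roi_labels))


def zone_activation_profile(components: Sequence[ROIMap], zones: ZoneAssignment,
                            areas: np.ndarray, total: float = 100_000.0):
    """Average normalized activation strength of each component per zone.

    Each component map is rescaled to sum to ``total`` over the cortex;
    a zone's score is the within-zone sum divided by the zone's surface
    area. Returns ``(profile, order)`` where ``profile`` is a components x
    zones table whose rows are sorted by the zone index of their peak score
    (components peaking in low-value zones first), and ``order`` is that
    row order.
    """
    areas = np.asarray(areas, dtype=float)
    K = zones.n_zones
    zone_area = np.array([areas[zones.zones == z].sum() for z in range(1, K + 1)])
    rows = {}
    for idx, comp in enumerate(components):
        vals = comp.values
        if np.any(vals < 0):
            raise ValueError("activation maps must be nonnegative")
        s = vals.sum()
        if s <= 0:
            raise ValueError(f"component {idx} is identically zero")
        norm = vals * (total / s)
        scores = np.array([norm[zones.zones == z].sum() for z in range(1, K + 1)])
        scores /= zone_area
        rows[f"component{idx + 1}"] = scores
    profile = pd.DataFrame(rows, index=[f"zone{z}" for z in range(1, K + 1)]).T
    peak = profile.to_numpy().argmax(axis=1)
    order = np.argsort(peak, kind="stable")
    return profile.iloc[order], order


def correlate_maps(a: ROIMap, b: ROIMap):
    """Pearson correlation of two ROI maps with a two-sided t-test p-value."""
    if a.roi_labels != b.roi_labels:
        raise ValueError("ROI maps must share the same labels in the same order")
    if a.n < 3:
        raise ValueError("need at least 3 regions")
    if a.values.std() == 0 or b.values.std() == 0:
        raise ValueError("correlation undefined for a constant map")
    res = stats.pearsonr(a.values, b.values)
    return float(res.statistic), float(res.pvalue)


def fdr_bh(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at FDR level ``q``."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
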