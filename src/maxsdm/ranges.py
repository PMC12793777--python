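"""Suitability classification, area accounting, change maps, centroids, overlap.

Suitability maps are cut into four classes at p = 0.2 / 0.4 / 0.6
(left-closed intervals: unsuitable < 0.2 ≤ low < 0.4 ≤ moderate < 0.6 ≤
extreme) and, for binary range questions, thresholded at the conservative
p ≥ 0.2 bound.  Areas are spherical-cell sums reported in 10⁴ km², the
conventional unit for country-scale range tables.  Range dynamics between
scenarios are summarised as per-class percent change, gain/loss/stable
change maps, area-weighted centroid tracks with haversine shift distances,
and two-species overlap as a percentage of the union of the two ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import EARTH_RADIUS_KM, GridSpec, Layer, cell_areas_map
from .maxent import SuitabilityMap

__all__ = [
    "ClassifiedMap",
    "AreaReport",
    "CentroidTrack",
    "OverlapReport",
    "CLASS_LABELS",
    "classify",
    "binary_suitable",
    "area_report",
    "change_map",
    "centroid",
    "centroid_distance_km",
    "centroid_track",
    "overlap",
]

CLASS_LABELS = {0: "unsuitable", 1: "low", 2: "moderate", 3: "extreme"}
CHANGE_CODES = {0: "never", 1: "gain", 2: "loss", 3: "stable"}
NODATA_CODE = -1


@dataclass
class ClassifiedMap:
    grid: GridSpec
    codes: np.ndarray  # int codes 0..3; NODATA_CODE where invalid
    thresholds: tuple[float, float, float]

    @property
    def mask(self) -> np.ndarray:
        return self.codes != NODATA_CODE

    def to_layer(self, name: str = "classes") -> Layer:
        v = self.codes.astype(float)
        v[self.codes == NODATA_CODE] = self.grid.nodata
        return Layer(self.grid, v, name)


@dataclass
class AreaReport:
    """Per-class areas in 10⁴ km² with optional percent change vs a baseline.

    ``change`` entries are None when the baseline class area is zero but the
    future one is not (undefined relative change, never ±inf).
    """

    areas: dict[str, float]                      # low / moderate / extreme / total
    change_pct: dict[str, float | None] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.areas["total"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in ("extreme", "moderate", "low", "total"):
            rows.append(
                {
                    "class": cls,
                    "area_1e4_km2": round(self.areas[cls], 2),
                    "change_pct": (
                        round(self.change_pct[cls], 2)
                        if self.change_pct.get(cls) is not None
                        else None
                    ),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class CentroidTrack:
    points: list[tuple[str, float, float]]       # (scenario, lon, lat)
    distances_km: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (label, lon, lat) in enumerate(self.points):
            rows.append(
                {
                    "scenario": label,
                    "lon": round(lon, 2),
                    "lat": round(lat, 2),
                    "shift_km": round(self.distances_km[i - 1], 2) if i else None,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class OverlapReport:
    area_a: float
    area_b: float
    intersection: float
    percentage: float                            # 100·I / (A + B − I)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "area_a_1e4_km2": round(self.area_a, 2),
                    "area_b_1e4_km2": round(self.area_b, 2),
                    "overlap_1e4_km2": round(self.intersection, 2),
                    "overlap_pct_of_union": round(self.percentage, 2),
                }
            ]
        )


def classify(
    smap: SuitabilityMap, thresholds: tuple[float, float, float] = (0.2, 0.4, 0.6)
) -> ClassifiedMap:
    """Cut suitability into 4 classes with left-closed intervals."""
    t1, t2, t3 = thresholds
    if not (0.0 < t1 < t2 < t3 < 1.0):
        raise ValueError("thresholds must be strictly increasing within (0, 1)")
    v = smap.values
    codes = np.full(smap.grid.shape, NODATA_CODE, dtype=int)
    m = smap.mask
    codes[m] = 0
    codes[m & (v >= t1)] = 1
    codes[m & (v >= t2)] = 2
    codes[m & (v >= t3)] = 3
    return ClassifiedMap(smap.grid, codes, thresholds)


def binary_suitable(
    smap: SuitabilityMap, threshold: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """(suitable mask, validity mask) at an inclusive threshold p ≥ t."""
    valid = smap.mask
    mask = valid & (smap.values >= threshold)
    return mask, valid


def _area_1e4(mask: np.ndarray, grid: GridSpec) -> float:
    return float(cell_areas_map(grid)[mask].sum()) / 1e4


def area_report(
    cmap: ClassifiedMap, baseline: AreaReport | None = None
) -> AreaReport:
    """Class areas in 10⁴ km² and percent change against a baseline report.

    Percent change is computed from full-precision areas; rounding to two
    decimals happens only at presentation.
    """
    grid = cmap.grid
    areas = {
        "low": _area_1e4(cmap.codes == 1, grid),
        "moderate": _area_1e4(cmap.codes == 2, grid),
        "extreme": _area_1e4(cmap.codes == 3, grid),
    }
    areas["total"] = areas["low"] + areas["moderate"] + areas["extreme"]
    report = AreaReport(areas=areas)
    if baseline is not None:
        for cls, a in areas.items():
            base = baseline.areas[cls]
            if base == 0.0:
                report.change_pct[cls] = None if a != 0.0 else 0.0
            else:
                report.change_pct[cls] = 100.0 * (a - base) / base
    return report


def percent_change(baseline: float, future: float) -> float | None:
    """100·(future − baseline)/baseline; None when undefined."""
    if baseline == 0.0:
        return 0.0 if future == 0.0 else None
    return 100.0 * (future - baseline) / baseline


def change_map(
    current: np.ndarray, future: np.ndarray, valid: np.ndarray | None = None
) -> np.ndarray:
    """Per-cell transition codes: 0 never, 1 gain, 2 loss, 3 stable.

    Invalid cells (outside ``valid``) carry NODATA_CODE.  Gain/loss/stable/
    never partition the valid grid.
    """
    if current.shape != future.shape:
        raise ValueError("current and future masks are on different grids")
    codes = np.zeros(current.shape, dtype=int)
    codes[future & ~current] = 1
    codes[current & ~future] = 2
    codes[current & future] = 3
    if valid is not None:
        codes[~valid] = NODATA_CODE
    return codes


def centroid(
    mask: np.ndarray, grid: GridSpec, weights: np.ndarray | None = None
) -> tuple[float, float]:
    """Cell-area-weighted mean center (lon, lat) of a mask.

    ``weights`` (e.g. suitability values) multiply the km² cell areas when
    a suitability-weighted rather than binary centroid is wanted.
    """
    if not mask.any():
        raise ValueError("cannot take the centroid of an empty mask")
    w = cell_areas_map(grid)
    if weights is not None:
        w = w * weights
    lon, lat = grid.cell_centers()
    lon2d = np.broadcast_to(lon, grid.shape)
    lat2d = np.broadcast_to(lat[:, None], grid.shape)
    wm = w[mask]
    return (
        float(np.average(lon2d[mask], weights=wm)),
        float(np.average(lat2d[mask], weights=wm)),
    )


def centroid_distance_km(c1: tuple[float, float], c2: tuple[float, float]) -> float:
    """Haversine great-circle distance in km on a sphere of R = 6371 km."""
    lon1, lat1 = np.radians(c1)
    lon2, lat2 = np.radians(c2)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def centroid_track(
    masks: list[tuple[str, np.ndarray]], grid: GridSpec
) -> CentroidTrack:
    """Centroids of a scenario sequence plus successive shift distances."""
    points = [(label, *centroid(mask, grid)) for label, mask in masks]
    dists = [
        centroid_distance_km(points[i][1:], points[i + 1][1:])
        for i in range(len(points) - 1)
    ]
    return CentroidTrack(points=points, distances_km=dists)


def overlap(mask_a: np.ndarray, mask_b: np.ndarray, grid: GridSpec) -> OverlapReport:
    """Two-species range overlap: intersection area as a % of the union."""
    if mask_a.shape != mask_b.shape or mask_a.shape != grid.shape:
        raise ValueError("masks are on different grids")
    a = _area_1e4(mask_a, grid)
    b = _area_1e4(mask_b, grid)
    i = _area_1e4(mask_a & mask_b, grid)
    union = a + b - i
    pct = 100.0 * i / union if union > 0 else 0.0
    return OverlapReport(area_a=a, area_b=b, intersection=i, percentage=pct)
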