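"""Range-shift impact statistics.

The three headline statistics of the analysis:

* latitudinal centroid, the abundance-weighted mean cell latitude
  ``Lbar = sum_i L_i Abd_i / sum_i Abd_i``, and its inter-period
  difference converted to kilometres with the package-wide constant
  111.32 km per degree;
* range area and its loss/gain between periods under the no-dispersal /
  full-dispersal conventions;
* Schoener's D overlap, ``D = 1 - 0.5 * sum_i |p_x,i - p_y,i|`` after
  normalizing each map to a probability distribution, with percent change
  damped by adding 0.1 to the baseline D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GridError, KM_PER_DEGREE, SuitabilityMap, cell_area_km2

#: Offset added to baseline D in percent-change to damp near-zero baselines.
OVERLAP_OFFSET = 0.1


@dataclass
class CentroidResult:
    species: str
    model: str
    scenario: str
    centroid_baseline: float
    centroid_future: float
    shift_km: float


@dataclass
class OverlapResult:
    threatened: str
    commercial: str
    model: str
    threshold: float
    D_baseline: float
    D_future: float
    pct_change: float


@dataclass
class RangeChangeResult:
    species: str
    model: str
    area_baseline_km2: float
    loss_pct: float
    gain_pct: float
    net_pct: float


def latitudinal_centroid(smap: SuitabilityMap, area_weighted: bool = False) -> float:
    """Abundance-weighted mean latitude of the distribution, in degrees N.

    By convention the weights are raw suitability/abundance values; set
    ``area_weighted`` to additionally weight by cell area (a documented
    deviation from the unweighted definition).
    """
    w = np.where(np.isfinite(smap.values), smap.values, 0.0)
    lat = smap.spec.lat_centers[:, None] * np.ones((1, smap.spec.n_lon))
    if area_weighted:
        w = w * cell_area_km2(lat, smap.spec.resolution)
    total = w.sum()
    if total <= 0:
        raise GridError("centroid of an all-zero map is undefined")
    return float((lat * w).sum() / total)


def centroid_shift_km(centroid_baseline: float, centroid_future: float) -> float:
    """Degrees of centroid displacement converted to km; positive = poleward (N)."""
    if not (np.isfinite(centroid_baseline) and np.isfinite(centroid_future)):
        raise GridError("centroids must be finite")
    return (centroid_future - centroid_baseline) * KM_PER_DEGREE


def range_area(smap: SuitabilityMap, t: float = 0.0) -> float:
    """Total area (km^2) of cells whose thresholded suitability is positive."""
    if not (0 <= t <= 1):
        raise GridError("threshold must lie in [0, 1]")
    with np.errstate(invalid="ignore"):
        occupied = np.isfinite(smap.values) & (smap.values >= t) & (smap.values > 0)
    areas = cell_area_km2(smap.spec.lat_centers, smap.spec.resolution)[:, None]
    return float((occupied * areas).sum())


def range_change(
    current: SuitabilityMap, future: SuitabilityMap, t: float = 0.0,
) -> RangeChangeResult:
    """Percent range loss (cells left) and gain (cells entered) vs the baseline area."""
    if current.spec != future.spec:
        raise GridError("maps are on different grids")
    with np.errstate(invalid="ignore"):
        cur = np.isfinite(current.values) & (current.values >= t) & (current.values > 0)
        fut = np.isfinite(future.values) & (future.values >= t) & (future.values > 0)
    areas = cell_area_km2(current.spec.lat_centers, current.spec.resolution)[:, None]
    area_cur = float((cur * areas).sum())
    if area_cur <= 0:
        raise GridError("baseline range area is zero")
    loss = float(((cur & ~fut) * areas).sum()) / area_cur * 100.0
    gain = float(((fut & ~cur) * areas).sum()) / area_cur * 100.0
    return RangeChangeResult(
        species=current.species,
        model=current.model,
        area_baseline_km2=area_cur,
        loss_pct=loss,
        gain_pct=gain,
        net_pct=gain - loss,
    )


def schoener_d(map_x: SuitabilityMap, map_y: SuitabilityMap) -> float:
    """Schoener's D between two maps normalized to probability distributions.

    Both maps are normalized to sum 1 over the cells that are non-missing
    in both (raw suitabilities are not probabilities, so the normalization
    is part of the statistic here); D = 1 - 0.5 * sum |p_x - p_y|, in
    [0, 1], 0 for disjoint supports and 1 for identical distributions.
    """
    if map_x.spec != map_y.spec:
        raise GridError("maps are on different grids")
    shared = np.isfinite(map_x.values) & np.isfinite(map_y.values)
    x = map_x.values[shared]
    y = map_y.values[shared]
    sx, sy = x.sum(), y.sum()
    if sx <= 0 or sy <= 0:
        raise GridError("Schoener's D needs positive total suitability on shared cells")
    d = 1.0 - 0.5 * np.abs(x / sx - y / sy).sum()
    return float(min(max(d, 0.0), 1.0))


def overlap_change_pct(d_baseline: float, d_future: float) -> float:
    """Percent change in overlap relative to (baseline D + 0.1).

    The 0.1 offset keeps percentages bounded when the baseline overlap is
    near zero.
    """
    for d in (d_baseline, d_future):
        if not (0 <= d <= 1):
            raise GridError("D values must lie in [0, 1]")
    return 100.0 * (d_future - d_baseline) / (d_baseline + OVERLAP_OFFSET)
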