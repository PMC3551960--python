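"""Habitat suitability inside protected-area polygons.

Candidate conservation areas arrive as lon/lat polygons, are rasterized
by the cell-center-in-polygon rule (boundary inclusive), and the species'
relative habitat suitability is min-max standardized over the pooled set
of all protected-area cells in BOTH periods per species and model. The
both-period pooling keeps the per-cell 2050-1985 deltas on one scale and
bounded in [-1, 1]; pooling only the baseline would let future values
escape the unit interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GridError, GridSpec, SuitabilityMap, mask_from_polygon


@dataclass
class ProtectedArea:
    name: str
    polygon: object  # shapely geometry
    cells: np.ndarray  # boolean membership on the grid

    @property
    def n_cells(self) -> int:
        return int(self.cells.sum())


@dataclass
class RHSReport:
    """Standardized suitability change inside one protected area."""

    species: str
    model: str
    area: str
    mean_baseline: float
    mean_delta: float
    n_cells: int


def rasterize_area(polygon, spec: GridSpec, name: str = "") -> ProtectedArea:
    """Cells whose centers fall inside (or on the boundary of) the polygon."""
    mask = mask_from_polygon(polygon, spec, name)
    if not mask.member.any():
        raise GridError(f"polygon '{name}' contains no cell centers")
    return ProtectedArea(name=name, polygon=polygon, cells=mask.member)


def standardize_rhs(
    baseline: SuitabilityMap, future: SuitabilityMap, areas: list[ProtectedArea]
) -> tuple[np.ndarray, np.ndarray]:
    """Min-max rescale suitability over all area cells pooled across both periods.

    Returns per-cell standardized arrays (NaN outside areas) for the
    baseline and future periods; the pooled minimum maps to 0 and the
    pooled maximum to 1 exactly.
    """
    if not areas:
        raise GridError("need at least one protected area")
    member = np.zeros(baseline.spec.shape, dtype=bool)
    for a in areas:
        member |= a.cells
    pooled = np.concatenate([baseline.values[member], future.values[member]])
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size < 2 or np.isclose(pooled.min(), pooled.max()):
        raise GridError("pooled protected-area values are constant; cannot standardize")
    lo, hi = pooled.min(), pooled.max()

    def std(values: np.ndarray) -> np.ndarray:
        out = np.full(values.shape, np.nan)
        ok = member & np.isfinite(values)
        out[ok] = (values[ok] - lo) / (hi - lo)
        return out

    return std(baseline.values), std(future.values)


def rhs_change(
    std_baseline: np.ndarray,
    std_future: np.ndarray,
    areas: list[ProtectedArea],
    species: str = "",
    model: str = "",
) -> list[RHSReport]:
    """Per-area mean baseline suitability and mean per-cell 2050-1985 delta."""
    delta = std_future - std_baseline
    reports = []
    for a in areas:
        ok = a.cells & np.isfinite(delta)
        reports.append(
            RHSReport(
                species=species,
                model=model,
                area=a.name,
                mean_baseline=float(np.nanmean(std_baseline[ok])) if ok.any() else np.nan,
                mean_delta=float(np.nanmean(delta[ok])) if ok.any() else np.nan,
                n_cells=int(ok.sum()),
            )
        )
    return reports
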