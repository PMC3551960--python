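"""Clipping, suitability thresholds and dispersal scenarios.

Projections are clipped to allowed basins and to 1.5x the species'
maximum depth (the inflation allows for observed deepening with warming
while keeping the same cut in both periods). Thresholds — three fixed
values plus the ROC-derived max sensitivity+specificity cutoff — zero out
cells below the cutoff; dispersal scenarios then either leave the future
range free (full dispersal) or confine it to the thresholded current
range (no dispersal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import EnvGrid, GridError, RegionMask, SuitabilityMap
from .occurrences import PresenceGrid

#: Fixed suitability thresholds explored by the sensitivity analysis.
DEFAULT_FIXED_THRESHOLDS = (0.05, 0.5, 0.7)


@dataclass
class ClipRule:
    allowed_regions: list[str] = field(default_factory=list)
    max_depth: float = 1000.0
    depth_inflation: float = 1.5

    def __post_init__(self) -> None:
        if self.max_depth <= 0:
            raise GridError("max_depth must be > 0")
        if self.depth_inflation < 1:
            raise GridError("depth_inflation must be >= 1")


@dataclass
class ThresholdSpec:
    kind: str  # 'fixed' | 'max_ss'
    value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "max_ss"):
            raise GridError(f"unknown threshold kind '{self.kind}'")
        if self.kind == "fixed" and not (self.value is not None and 0 <= self.value <= 1):
            raise GridError("fixed threshold needs a value in [0, 1]")


@dataclass
class ThresholdResult:
    value: float
    sensitivity: float
    specificity: float
    warning: str | None = None


def apply_clip(
    smap: SuitabilityMap,
    rule: ClipRule,
    depth: EnvGrid | None = None,
    regions: list[RegionMask] | None = None,
) -> SuitabilityMap:
    """Zero suitability outside allowed regions and beyond the inflated depth.

    An empty ``allowed_regions`` list means no region clip. The same rule
    must be applied to the baseline and future map of a species so the
    inter-period comparison is not an artefact of the clip.
    """
    values = smap.values.copy()
    if rule.allowed_regions:
        by_label = {r.label: r for r in (regions or [])}
        missing = [lbl for lbl in rule.allowed_regions if lbl not in by_label]
        if missing:
            raise GridError(f"unknown region labels: {missing}")
        allowed = np.zeros(smap.spec.shape, dtype=bool)
        for lbl in rule.allowed_regions:
            allowed |= by_label[lbl].member
        values[~allowed & np.isfinite(values)] = 0.0
    if depth is not None:
        cut = rule.max_depth * rule.depth_inflation
        with np.errstate(invalid="ignore"):
            too_deep = depth.values > cut
        values[too_deep & np.isfinite(values)] = 0.0
    return smap.with_values(values)


def apply_threshold(smap: SuitabilityMap, t: float) -> SuitabilityMap:
    """Zero cells with suitability below t; cells at or above t are unchanged."""
    if not (0 <= t <= 1):
        raise GridError("threshold must lie in [0, 1]")
    values = smap.values.copy()
    with np.errstate(invalid="ignore"):
        values[values < t] = 0.0
    return smap.with_values(values)


def select_max_ss_threshold(
    smap: SuitabilityMap, test_presence: PresenceGrid, background: RegionMask
) -> ThresholdResult:
    """ROC threshold maximizing sensitivity + specificity on held-out cells.

    Candidates are the unique predicted values at test-presence cells.
    Sensitivity counts test presences with suitability >= t; specificity
    counts background non-presence cells below t. Ties take the smallest t.
    A map with no discrimination returns its constant value with a warning.
    """
    pres = test_presence.present & np.isfinite(smap.values)
    if not pres.any():
        raise GridError("test presence set is empty")
    bg_abs = background.member & ~test_presence.present & np.isfinite(smap.values)
    if not bg_abs.any():
        raise GridError("background minus presences is empty")
    pres_vals = smap.values[pres]
    abs_vals = smap.values[bg_abs]
    candidates = np.unique(pres_vals)
    if len(np.unique(np.concatenate([pres_vals, abs_vals]))) == 1:
        return ThresholdResult(
            value=float(candidates[0]), sensitivity=1.0, specificity=0.0,
            warning="no discrimination: all predictions identical",
        )
    best = None
    for t in candidates:  # ascending, so ties keep the smallest t
        sens = float((pres_vals >= t).mean())
        spec = float((abs_vals < t).mean())
        if best is None or sens + spec > best[0] + 1e-12:
            best = (sens + spec, t, sens, spec)
    _, t, sens, spec = best
    return ThresholdResult(value=float(t), sensitivity=sens, specificity=spec)


def apply_dispersal_scenario(
    current: SuitabilityMap,
    future: SuitabilityMap,
    scenario: str,
    t: float = 0.0,
) -> SuitabilityMap:
    """Impose a dispersal assumption on the projected future map.

    full_dispersal returns the future map unchanged; no_dispersal zeroes
    future suitability outside the thresholded current range, i.e. the
    species cannot colonize newly suitable habitat.
    """
    if current.spec != future.spec:
        raise GridError("current and future maps are on different grids")
    if scenario == "full_dispersal":
        return future
    if scenario != "no_dispersal":
        raise GridError(f"unknown dispersal scenario '{scenario}'")
    cur_range = apply_threshold(current, t).values > 0
    values = future.values.copy()
    values[~cur_range & np.isfinite(values)] = 0.0
    return future.with_values(values)
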