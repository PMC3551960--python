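"""Synthetic environmental scenarios, virtual species and protected areas.

The generator emulates a temperate shelf sea: a linear latitudinal SST
gradient warmed by a prescribed delta in the future period, bottom
temperature tracking the surface (shallow shelf), depth increasing away
from a coastal strip toward a mean near 90 m, plus salinity, primary
productivity, sea-ice and distance-to-coast layers derived
deterministically from the seed. Virtual species carry a known trapezoidal
environmental envelope, so every downstream fit can be checked against a
ground truth that real occurrence archives never provide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .envelope import Trapezoid, trapezoid_suitability
from .grids import EnvGrid, EnvStack, GridError, GridSpec, KM_PER_DEGREE


@dataclass
class ScenarioParams:
    """Knobs of the synthetic shelf-sea scenario.

    Defaults follow the emulated system: a 0.5-degree shelf-sea grid,
    surface warming of 1.27 degC between the baseline and future periods
    (the upper of the two multi-model warming estimates for the region),
    near-identical surface and bottom temperatures, and a mean depth of
    about 90 m.
    """

    spec: GridSpec = field(default_factory=lambda: GridSpec(45.0, 65.0, -10.0, 10.0, 0.5))
    sst_equator: float = 16.0  # degC at the southern edge
    sst_pole: float = 6.0  # degC at the northern edge
    warming_delta: float = 1.27  # degC, future minus baseline mean
    sbt_offset: float = 0.5  # degC, SST minus SBT
    shelf_depth: float = 40.0  # m at the coast
    depth_slope: float = 0.05  # m per km of distance to coast
    noise_sd: float = 0.3  # degC of cell-level SST noise
    land_fraction: float = 0.1  # westernmost columns treated as land
    baseline_label: str = "1985"
    future_label: str = "2050"
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.warming_delta):
            raise GridError("warming_delta must be finite")
        if self.noise_sd < 0:
            raise GridError("noise_sd must be >= 0")
        if not (0 <= self.land_fraction < 1):
            raise GridError("land_fraction must lie in [0, 1)")


@dataclass
class VirtualSpecies:
    """A species with a known trapezoidal envelope per variable."""

    name: str
    true_envelope: dict[str, Trapezoid]
    depth_limit: float = 400.0
    detectability: float = 1.0

    def __post_init__(self) -> None:
        for var, (a, b, c, d) in self.true_envelope.items():
            if not (a <= b <= c <= d):
                raise GridError(f"envelope for '{var}' not ordered")
        if not (0 <= self.detectability <= 1):
            raise GridError("detectability must lie in [0, 1]")

    def true_suitability(self, env: EnvStack) -> np.ndarray:
        """Product-rule suitability from the true envelope, with the depth cut."""
        env.require(self.true_envelope)
        suit = np.ones(env.spec.shape)
        for var, trap in self.true_envelope.items():
            suit = suit * trapezoid_suitability(env[var].values, trap)
        if "depth" in env.layers:
            depth = env["depth"].values
            with np.errstate(invalid="ignore"):
                suit[depth > self.depth_limit] = 0.0
        return suit


def make_env_scenario(params: ScenarioParams) -> tuple[EnvStack, EnvStack]:
    """Generate the baseline and future environmental stacks.

    Baseline SST is linear in latitude plus N(0, noise_sd) cell noise;
    future SST is baseline plus a spatially uniform warming delta. The two
    stacks share the land mask and every non-temperature layer except SBT.
    """
    spec = params.spec
    if spec.n_lat < 2:
        raise GridError("scenario grid needs at least 2 latitude rows")
    rng = np.random.default_rng(params.seed)
    lat = spec.lat_centers[:, None] * np.ones((1, spec.n_lon))

    n_land = int(round(params.land_fraction * spec.n_lon))
    land = np.zeros(spec.shape, dtype=bool)
    if n_land:
        land[:, :n_land] = True

    # distance to coast: km east of the land strip (western boundary if none)
    col_km = (np.arange(spec.n_lon) - n_land + 0.5) * spec.resolution * KM_PER_DEGREE
    dist_coast = np.maximum(col_km, 0.0)[None, :] * np.ones((spec.n_lat, 1))

    frac = (lat - spec.lat_min - spec.resolution / 2) / max(
        (spec.lat_max - spec.lat_min - spec.resolution), 1e-12
    )
    sst = params.sst_equator + (params.sst_pole - params.sst_equator) * frac
    sst = sst + rng.normal(0.0, params.noise_sd, size=spec.shape)
    sbt = sst - params.sbt_offset
    depth = params.shelf_depth + params.depth_slope * dist_coast
    salinity = 34.0 + 0.05 * (lat - lat.mean())
    npp = np.maximum(800.0 - 0.4 * dist_coast, 50.0)
    ice = np.clip((-1.0 - sst) / 2.0, 0.0, 1.0)  # only forms if SST < -1 degC

    def _stack(label: str, sst_field: np.ndarray, sbt_field: np.ndarray) -> EnvStack:
        fields = {
            "sst": (sst_field, "degC"),
            "sbt": (sbt_field, "degC"),
            "salinity": (salinity, "psu"),
            "npp": (npp, "mgC m-2 day-1"),
            "ice": (np.clip((-1.0 - sst_field) / 2.0, 0, 1), ""),
            "depth": (depth, "m"),
            "dist_coast": (dist_coast, "km"),
        }
        layers = {}
        for name, (vals, units) in fields.items():
            v = vals.copy()
            v[land] = np.nan
            layers[name] = EnvGrid(spec=spec, variable=name, values=v, units=units)
        return EnvStack(period_label=label, layers=layers)

    baseline = _stack(params.baseline_label, sst, sbt)
    future = _stack(params.future_label, sst + params.warming_delta, sbt + params.warming_delta)
    return baseline, future


def sample_occurrences(
    species: VirtualSpecies, env: EnvStack, n: int, seed: int = 0
) -> pd.DataFrame:
    """Sample presence records proportional to the species' true suitability.

    Cells are drawn with replacement with probability proportional to true
    suitability times detectability; each record is jittered uniformly
    within its cell and assigned a year uniform in 1971-2000 (the training
    climate window) and source 'synthetic'.
    """
    if n < 1:
        raise GridError("n must be >= 1")
    if species.detectability <= 0:
        raise GridError(f"species '{species.name}' has zero detectability")
    suit = species.true_suitability(env)
    suit = np.where(np.isfinite(suit), suit, 0.0)
    total = suit.sum()
    if total <= 0:
        raise GridError(f"species '{species.name}' has no suitable cells in this environment")
    rng = np.random.default_rng(seed)
    p = (suit * species.detectability).ravel()
    p = p / p.sum()
    idx = rng.choice(p.size, size=n, replace=True, p=p)
    spec = env.spec
    i, j = np.unravel_index(idx, spec.shape)
    res = spec.resolution
    lat = spec.lat_min + (i + rng.uniform(0, 1, size=n)) * res
    lon = spec.lon_min + (j + rng.uniform(0, 1, size=n)) * res
    return pd.DataFrame(
        {
            "species": species.name,
            "lon": lon,
            "lat": lat,
            "year": rng.integers(1971, 2001, size=n),
            "source": "synthetic",
        }
    )


def make_protected_areas(
    spec: GridSpec, n_areas: int, seed: int = 0, min_cells: int = 4
) -> dict[str, Polygon]:
    """Place non-overlapping rectangular protected-area polygons.

    Each polygon snaps to cell edges and covers at least ``min_cells`` grid
    cells; labels run cSAC_1..n. Raises if the grid cannot host the
    requested number of disjoint areas.
    """
    if n_areas < 1:
        raise GridError("n_areas must be >= 1")
    rng = np.random.default_rng(seed)
    res = spec.resolution
    placed: list[Polygon] = []
    out: dict[str, Polygon] = {}
    attempts = 0
    while len(placed) < n_areas:
        attempts += 1
        if attempts > 200 * n_areas:
            raise GridError(f"grid too small to place {n_areas} disjoint areas")
        h = int(rng.integers(2, 5))
        w = int(rng.integers(2, 5))
        if h * w < min_cells or h > spec.n_lat or w > spec.n_lon:
            continue
        i0 = int(rng.integers(0, spec.n_lat - h + 1))
        j0 = int(rng.integers(0, spec.n_lon - w + 1))
        poly = shapely.box(
            spec.lon_min + j0 * res,
            spec.lat_min + i0 * res,
            spec.lon_min + (j0 + w) * res,
            spec.lat_min + (i0 + h) * res,
        )
        # keep a one-cell buffer so rasterized areas never share cells
        if any(poly.buffer(res / 2).intersects(p) for p in placed):
            continue
        placed.append(poly)
        out[f"cSAC_{len(placed)}"] = poly
    return out
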