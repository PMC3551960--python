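"""Trapezoidal bioclimatic envelope model (AquaMaps-style).

For each environmental variable the species gets a trapezoid
``(min_abs, pref_min, pref_max, max_abs)``: suitability is 0 outside the
absolute limits, 1 inside the preferred range, and ramps linearly in
between. Per-variable suitabilities are combined by geometric mean
(default) or product. The percentile/buffer parameterisation is a
reconstruction of the published AquaMaps algorithm, not a transcription:
the exact envelope constants of that software are not restated here and
both knobs are exposed in the API.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .grids import EnvStack, GridError, SuitabilityMap
from .occurrences import PresenceGrid

Trapezoid = tuple[float, float, float, float]


def trapezoid_suitability(values, trap: Trapezoid):
    """Evaluate the trapezoid response; NaN propagates, zero-width ramps are steps."""
    v = np.asarray(values, dtype=float)
    min_abs, pref_min, pref_max, max_abs = (float(x) for x in trap)
    if not (min_abs <= pref_min <= pref_max <= max_abs):
        raise ValueError(f"invalid trapezoid {trap}")
    out = np.zeros_like(v, dtype=float)
    with np.errstate(invalid="ignore"):
        inside = (v >= min_abs) & (v <= max_abs)
        out[inside] = 1.0
        if pref_min > min_abs:
            left = inside & (v < pref_min)
            out[left] = (v[left] - min_abs) / (pref_min - min_abs)
        if pref_max < max_abs:
            right = inside & (v > pref_max)
            out[right] = (max_abs - v[right]) / (max_abs - pref_max)
    out[~np.isfinite(v)] = np.nan
    return out if out.ndim else float(out)


def combine_suitability(per_variable: list[np.ndarray], rule: str) -> np.ndarray:
    """Combine per-variable suitabilities: 'product' or 'geometric_mean'."""
    stacked = np.stack(per_variable)
    prod = np.prod(stacked, axis=0)
    if rule == "product":
        return prod
    if rule == "geometric_mean":
        return np.power(prod, 1.0 / len(per_variable))
    raise ValueError(f"unknown combination rule '{rule}'")


@dataclass
class EnvelopeModel:
    species: str
    trapezoids: dict[str, Trapezoid]
    combination_rule: str = "geometric_mean"
    percentiles: tuple[float, float] = (10.0, 90.0)
    buffer_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.trapezoids:
            raise ValueError("envelope model needs at least one variable")
        for var, trap in self.trapezoids.items():
            a, b, c, d = trap
            if not (a <= b <= c <= d):
                raise ValueError(f"trapezoid for '{var}' not ordered: {trap}")

    @property
    def variables_used(self) -> list[str]:
        return list(self.trapezoids)

    def to_json(self) -> str:
        return json.dumps(
            {
                "species": self.species,
                "trapezoids": {k: list(v) for k, v in self.trapezoids.items()},
                "combination_rule": self.combination_rule,
                "percentiles": list(self.percentiles),
                "buffer_fraction": self.buffer_fraction,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "EnvelopeModel":
        d = json.loads(text)
        return cls(
            species=d["species"],
            trapezoids={k: tuple(v) for k, v in d["trapezoids"].items()},
            combination_rule=d["combination_rule"],
            percentiles=tuple(d["percentiles"]),
            buffer_fraction=d["buffer_fraction"],
        )


def fit_envelope(
    presence: PresenceGrid,
    env: EnvStack,
    percentiles: tuple[float, float] = (10.0, 90.0),
    buffer_fraction: float = 0.0,
    variables: list[str] | None = None,
    combination_rule: str = "geometric_mean",
    min_presences: int = 5,
) -> EnvelopeModel:
    """Fit per-variable trapezoids from values at presence cells.

    pref_min/pref_max are the low/high percentiles (linear interpolation)
    of the variable at presence cells; the absolute limits are the observed
    min/max widened by ``buffer_fraction`` of the preferred range.
    """
    if variables is None:
        variables = [v for v in sorted(env.layers) if v != "depth"]
    env.require(variables)
    low, high = percentiles
    traps: dict[str, Trapezoid] = {}
    for var in variables:
        vals = env[var].values[presence.present]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise GridError(f"variable '{var}' entirely missing at presence cells")
        if vals.size < min_presences:
            raise GridError(
                f"need >= {min_presences} presence cells with data for '{var}', got {vals.size}"
            )
        pref_min, pref_max = np.percentile(vals, [low, high])
        pad = buffer_fraction * (pref_max - pref_min)
        traps[var] = (float(vals.min() - pad), float(pref_min), float(pref_max), float(vals.max() + pad))
    return EnvelopeModel(
        species=presence.species,
        trapezoids=traps,
        combination_rule=combination_rule,
        percentiles=(float(low), float(high)),
        buffer_fraction=float(buffer_fraction),
    )


def predict_envelope(model: EnvelopeModel, env: EnvStack) -> SuitabilityMap:
    """Project an envelope model onto an environmental stack."""
    env.require(model.variables_used)
    per_var = [
        trapezoid_suitability(env[var].values, model.trapezoids[var])
        for var in model.variables_used
    ]
    values = combine_suitability(per_var, model.combination_rule)
    return SuitabilityMap(
        spec=env.spec,
        values=values,
        species=model.species,
        model="envelope",
        period=env.period_label,
    )
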