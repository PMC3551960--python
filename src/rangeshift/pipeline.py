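"""Config-driven orchestration of the full projection experiment.

One run crosses species x model x threshold x dispersal scenario on a
baseline and a future environmental stack: occurrence QC and gridding,
model fitting (trapezoidal envelope, maxent, dynamic simulation),
projection to both periods, clipping, threshold selection, dispersal
scenarios, centroid / range-area / overlap metrics and the
protected-area suitability report. Everything is driven by one YAML
config and a single seed; identical config + seed reproduces identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dbem as dbem_mod
from . import envelope as env_mod
from . import maxent as max_mod
from . import metrics as met
from . import postprocess as post
from . import protected as prot
from .grids import (
    EnvStack,
    GridError,
    RegionMask,
    SuitabilityMap,
    read_env_stack,
    read_occurrences,
    read_polygons,
    mask_from_polygon,
    write_env_stack,
)
from .occurrences import aggregate_to_grid, qc_filter, split_train_test
from .synthetic import (
    ScenarioParams,
    VirtualSpecies,
    make_env_scenario,
    make_protected_areas,
    sample_occurrences,
)

VALID_MODELS = ("envelope", "maxent", "dbem")


@dataclass
class SpeciesConfig:
    name: str
    group: str = "threatened"  # 'threatened' | 'commercial'
    max_depth: float = 1000.0
    allowed_regions: list[str] = field(default_factory=list)


@dataclass
class PipelineConfig:
    baseline_env: str
    future_env: str
    occurrences: str
    output_dir: str
    species: list[SpeciesConfig]
    models: list[str] = field(default_factory=lambda: list(VALID_MODELS))
    areas: str | None = None
    regions: str | None = None
    variables: list[str] = field(default_factory=lambda: ["sst", "sbt"])
    fixed_thresholds: list[float] = field(default_factory=lambda: list(post.DEFAULT_FIXED_THRESHOLDS))
    use_max_ss: bool = True
    dispersal_scenarios: list[str] = field(default_factory=lambda: ["no_dispersal", "full_dispersal"])
    train_fraction: float = 0.75
    depth_inflation: float = 1.5
    dbem_growth: float = 0.5
    dbem_dispersal: float = 0.1
    dbem_bins: int = 20
    baseline_year: int = 1985
    future_year: int = 2050
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.models or any(m not in VALID_MODELS for m in self.models):
            raise GridError(f"models must be a non-empty subset of {VALID_MODELS}")
        if not self.species:
            raise GridError("need at least one species")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        species = [SpeciesConfig(**s) for s in raw.pop("species")]
        return cls(species=species, **raw)

    def to_yaml(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if k != "species"}
        d["species"] = [s.__dict__ for s in self.species]
        return yaml.safe_dump(d, sort_keys=True)


def _fit_predict(
    model_name: str,
    presence,
    baseline: EnvStack,
    future: EnvStack,
    cfg: PipelineConfig,
) -> tuple[SuitabilityMap, SuitabilityMap]:
    """Fit one model family and project it to both periods."""
    if model_name == "envelope":
        m = env_mod.fit_envelope(presence, baseline, variables=cfg.variables)
        return env_mod.predict_envelope(m, baseline), env_mod.predict_envelope(m, future)
    if model_name == "maxent":
        m = max_mod.fit_maxent(presence, baseline, variables=cfg.variables)
        return max_mod.predict_maxent(m, baseline), max_mod.predict_maxent(m, future)
    if model_name == "dbem":
        seed_model = env_mod.fit_envelope(presence, baseline, variables=cfg.variables)
        seed_map = env_mod.predict_envelope(seed_model, baseline)
        params = dbem_mod.DBEMParams(
            intrinsic_growth=cfg.dbem_growth,
            dispersal_fraction=cfg.dbem_dispersal,
            n_bins=cfg.dbem_bins,
            start_year=cfg.baseline_year,
            end_year=cfg.future_year,
        )
        series = dbem_mod.build_env_series(
            baseline, future, cfg.baseline_year, cfg.future_year
        )
        end_map, _traj = dbem_mod.run_dbem(seed_map, series, params, variables=cfg.variables)
        profiles = dbem_mod.derive_profiles(seed_map, baseline, cfg.dbem_bins, cfg.variables)
        K0 = dbem_mod.carrying_capacity(profiles, baseline)
        sea = baseline.sea_mask
        base_vals = np.full(K0.shape, np.nan)
        base_vals[sea] = K0[sea] / K0[sea].max() if K0[sea].max() > 0 else 0.0
        base_map = SuitabilityMap(
            spec=baseline.spec, values=base_vals,
            species=presence.species, model="dbem", period=baseline.period_label,
        )
        return base_map, end_map
    raise GridError(f"unknown model '{model_name}'")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full experiment matrix; returns (and writes) the manifest."""
    out = Path(config.output_dir)
    (out / "maps").mkdir(parents=True, exist_ok=True)
    baseline = read_env_stack(config.baseline_env)
    future = read_env_stack(config.future_env)
    records = read_occurrences(config.occurrences)
    spec = baseline.spec

    regions: list[RegionMask] = []
    if config.regions:
        regions = [
            mask_from_polygon(geom, spec, name)
            for name, geom in read_polygons(config.regions).items()
        ]
    areas: list[prot.ProtectedArea] = []
    if config.areas:
        areas = [
            prot.rasterize_area(geom, spec, name)
            for name, geom in read_polygons(config.areas).items()
        ]

    sea_region = RegionMask(spec=spec, member=baseline.sea_mask, label="sea")
    manifest: dict = {
        "config_hash": hashlib.sha256(config.to_yaml().encode()).hexdigest(),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
        "outputs": [],
        "maps": [],
    }

    clipped: dict[tuple[str, str, str], SuitabilityMap] = {}
    thr_rows, cent_rows, range_rows, rhs_rows = [], [], [], []
    thresholds_by_sm: dict[tuple[str, str], list[tuple[str, float]]] = {}

    for s_idx, sp in enumerate(config.species):
        sp_records = records[records["species"] == sp.name]
        if sp_records.empty:
            raise GridError(f"[prep/{sp.name}] no occurrence records")
        try:
            filtered, drop_log = qc_filter(sp_records, baseline)
            presence = aggregate_to_grid(filtered, spec, species=sp.name)
            train, test = split_train_test(
                presence, config.train_fraction, seed=config.seed + 1000 + s_idx
            )
        except GridError as exc:
            raise GridError(f"[prep/{sp.name}] {exc}") from exc
        manifest["stages"][f"prep/{sp.name}"] = {
            "records_in": int(len(sp_records)),
            "records_kept": int(len(filtered)),
            "dropped": drop_log,
            "presence_cells": presence.n_cells,
            "train_cells": train.n_cells,
            "test_cells": test.n_cells,
        }
        rule = post.ClipRule(
            allowed_regions=sp.allowed_regions,
            max_depth=sp.max_depth,
            depth_inflation=config.depth_inflation,
        )
        for model_name in config.models:
            try:
                base_map, fut_map = _fit_predict(model_name, train, baseline, future, config)
                depth = baseline.layers.get("depth")
                base_map = post.apply_clip(base_map, rule, depth, regions)
                fut_map = post.apply_clip(fut_map, rule, depth, regions)
            except GridError as exc:
                raise GridError(f"[fit/{sp.name}/{model_name}] {exc}") from exc
            clipped[(sp.name, model_name, "baseline")] = base_map
            clipped[(sp.name, model_name, "future")] = fut_map
            for period, smap in (("baseline", base_map), ("future", fut_map)):
                p = out / "maps" / f"{sp.name}_{model_name}_{period}.nc"
                _write_map(smap, p)
                manifest["maps"].append(str(p.relative_to(out)))

            thresholds: list[tuple[str, float]] = [
                ("fixed", float(t)) for t in config.fixed_thresholds
            ]
            if config.use_max_ss:
                res = post.select_max_ss_threshold(base_map, test, sea_region)
                if res.warning:
                    manifest["warnings"].append(f"{sp.name}/{model_name}: {res.warning}")
                thresholds.append(("max_ss", res.value))
                thr_rows.append(
                    {
                        "species": sp.name, "model": model_name,
                        "threshold": res.value, "sensitivity": res.sensitivity,
                        "specificity": res.specificity,
                    }
                )
            thresholds_by_sm[(sp.name, model_name)] = thresholds

            for kind, t in thresholds:
                base_t = post.apply_threshold(base_map, t)
                for scenario in config.dispersal_scenarios:
                    fut_s = post.apply_dispersal_scenario(base_map, fut_map, scenario, t)
                    fut_t = post.apply_threshold(fut_s, t)
                    try:
                        c1 = met.latitudinal_centroid(base_t)
                        c2 = met.latitudinal_centroid(fut_t)
                        shift = met.centroid_shift_km(c1, c2)
                    except GridError:
                        c1 = c2 = shift = np.nan
                    cent_rows.append(
                        {
                            "species": sp.name, "group": sp.group, "model": model_name,
                            "scenario": scenario, "threshold_kind": kind, "threshold": t,
                            "centroid_baseline": c1, "centroid_future": c2,
                            "shift_km": shift,
                        }
                    )
                try:
                    rc = met.range_change(base_map, fut_map, t)
                    range_rows.append(
                        {
                            "species": sp.name, "model": model_name,
                            "threshold_kind": kind, "threshold": t,
                            "area_baseline_km2": rc.area_baseline_km2,
                            "loss_pct": rc.loss_pct, "gain_pct": rc.gain_pct,
                            "net_pct": rc.net_pct,
                        }
                    )
                except GridError as exc:
                    manifest["warnings"].append(f"{sp.name}/{model_name}/t={t}: {exc}")

            if areas:
                try:
                    std_b, std_f = prot.standardize_rhs(base_map, fut_map, areas)
                    for rep in prot.rhs_change(std_b, std_f, areas, sp.name, model_name):
                        rhs_rows.append(rep.__dict__)
                except GridError as exc:
                    manifest["warnings"].append(f"{sp.name}/{model_name}/rhs: {exc}")

    # species-overlap analysis: threatened x commercial per model and threshold
    overlap_rows = []
    threatened = [s.name for s in config.species if s.group == "threatened"]
    commercial = [s.name for s in config.species if s.group == "commercial"]
    for model_name in config.models:
        for tn in threatened:
            for cn in commercial:
                shared = [
                    (k, t) for (k, t) in thresholds_by_sm.get((tn, model_name), [])
                    if (k, t) in thresholds_by_sm.get((cn, model_name), []) or k == "fixed"
                ]
                for kind, t in shared:
                    try:
                        bx = post.apply_threshold(clipped[(tn, model_name, "baseline")], t)
                        by = post.apply_threshold(clipped[(cn, model_name, "baseline")], t)
                        fx = post.apply_threshold(clipped[(tn, model_name, "future")], t)
                        fy = post.apply_threshold(clipped[(cn, model_name, "future")], t)
                        d1 = met.schoener_d(bx, by)
                        d2 = met.schoener_d(fx, fy)
                        overlap_rows.append(
                            {
                                "threatened": tn, "commercial": cn, "model": model_name,
                                "threshold_kind": kind, "threshold": t,
                                "D_baseline": d1, "D_future": d2,
                                "pct_change": met.overlap_change_pct(d1, d2),
                            }
                        )
                    except GridError as exc:
                        manifest["warnings"].append(
                            f"overlap/{tn}x{cn}/{model_name}/t={t}: {exc}"
                        )

    tables = {
        "centroids.csv": pd.DataFrame(cent_rows),
        "range_changes.csv": pd.DataFrame(range_rows),
        "overlaps.csv": pd.DataFrame(overlap_rows),
        "thresholds.csv": pd.DataFrame(thr_rows),
        "rhs.csv": pd.DataFrame(rhs_rows),
    }
    for name, df in tables.items():
        df.to_csv(out / name, index=False, float_format="%.10g")
        manifest["outputs"].append(name)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# demo fixture set

DEMO_SPECIES = (
    # (name, group, sst trapezoid)
    ("virt_threat_1", "threatened", (6.5, 8.0, 10.5, 12.0)),
    ("virt_threat_2", "threatened", (7.5, 9.5, 12.0, 13.5)),
    ("virt_comm_1", "commercial", (8.0, 10.0, 13.0, 15.0)),
    ("virt_comm_2", "commercial", (7.0, 8.5, 11.5, 13.0)),
)


def make_demo(outdir, seed: int = 0, n_occurrences: int = 300) -> Path:
    """Materialize a complete synthetic dataset plus a ready-to-run config.

    Writes baseline/future NetCDF stacks, an occurrence CSV for two
    threatened and two commercial virtual species, six protected-area
    polygons, a study-region polygon and ``config.yaml``; returns the
    config path.
    """
    import shapely

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = ScenarioParams(seed=seed)
    baseline, future = make_env_scenario(params)
    write_env_stack(baseline, outdir / "baseline.nc")
    write_env_stack(future, outdir / "future.nc")

    tables = []
    for k, (name, _group, trap) in enumerate(DEMO_SPECIES):
        sp = VirtualSpecies(
            name=name,
            true_envelope={"sst": trap, "sbt": tuple(v - params.sbt_offset for v in trap)},
        )
        tables.append(sample_occurrences(sp, baseline, n_occurrences, seed=seed + 10 + k))
    pd.concat(tables, ignore_index=True).to_csv(outdir / "occurrences.csv", index=False)

    from .grids import write_polygons

    areas = make_protected_areas(baseline.spec, n_areas=6, seed=seed + 99)
    write_polygons(areas, outdir / "areas.geojson")
    spec = baseline.spec
    study = shapely.box(spec.lon_min, spec.lat_min, spec.lon_max, spec.lat_max)
    write_polygons({"study_region": study}, outdir / "regions.geojson")

    config = PipelineConfig(
        baseline_env=str(outdir / "baseline.nc"),
        future_env=str(outdir / "future.nc"),
        occurrences=str(outdir / "occurrences.csv"),
        areas=str(outdir / "areas.geojson"),
        regions=str(outdir / "regions.geojson"),
        output_dir=str(outdir / "results"),
        species=[
            SpeciesConfig(name=name, group=group, max_depth=400.0)
            for name, group, _ in DEMO_SPECIES
        ],
        seed=seed,
    )
    cfg_path = outdir / "config.yaml"
    cfg_path.write_text(config.to_yaml())
    return cfg_path


def _write_map(smap: SuitabilityMap, path: Path) -> None:
    import xarray as xr

    da = xr.DataArray(
        smap.values,
        coords={"lat": smap.spec.lat_centers, "lon": smap.spec.lon_centers},
        dims=("lat", "lon"),
        name="suitability",
        attrs={"species": smap.species, "model": smap.model, "period": smap.period},
    )
    da.to_dataset().to_netcdf(path, engine="scipy")


def read_map(path) -> SuitabilityMap:
    import xarray as xr

    from .grids import _spec_from_coords

    with xr.open_dataset(path, engine="scipy") as ds:
        spec = _spec_from_coords(
            np.asarray(ds["lat"].values, float), np.asarray(ds["lon"].values, float)
        )
        da = ds["suitability"]
        return SuitabilityMap(
            spec=spec,
            values=np.asarray(da.values, float),
            species=str(da.attrs.get("species", "")),
            model=str(da.attrs.get("model", "")),
            period=str(da.attrs.get("period", "")),
        )
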