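"""Occurrence QC, gridding to binary presence, and train/test splitting.

The QC stage implements a minimal, individually switchable rule set
(coordinate validity, land cells, per-cell duplicates, year window); the
full survey-grade protocol applied to real OBIS/GBIF/ICES archives is out
of scope. Aggregation marks a cell present when at least one record falls
in its half-open interval [edge, edge+res) on both axes. Splitting is by
cell, not record, so spatially duplicated records cannot leak between the
training and evaluation sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import EnvStack, GridError, GridSpec


@dataclass
class PresenceGrid:
    """Binary presence per grid cell for one species."""

    spec: GridSpec
    present: np.ndarray
    species: str
    n_records: int = 0

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != self.spec.shape:
            raise GridError("presence grid shape does not match spec")
        if self.n_records < int(self.present.sum()):
            raise GridError("n_records cannot be smaller than the number of present cells")

    @property
    def n_cells(self) -> int:
        return int(self.present.sum())


def qc_filter(
    records: pd.DataFrame,
    env: EnvStack,
    year_window: tuple[int, int] = (1971, 2000),
    drop_invalid_coords: bool = True,
    drop_on_land: bool = True,
    drop_duplicates: bool = True,
    drop_outside_years: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the QC rules; returns the surviving records and per-rule drop counts.

    Rules run in a fixed order (coords, land, years, duplicates) and each can
    be disabled. Idempotent: running the filter twice drops nothing new.
    """
    required = {"species", "lon", "lat"}
    missing = required - set(records.columns)
    if missing:
        raise GridError(f"occurrence table missing columns: {sorted(missing)}")
    df = records.copy()
    log: dict[str, int] = {}
    spec = env.spec
    sea = env.sea_mask

    if drop_invalid_coords:
        ok = (
            np.isfinite(df["lon"]) & np.isfinite(df["lat"])
            & (df["lat"] > -90) & (df["lat"] < 90)
            & (df["lon"] >= -180) & (df["lon"] < 180)
        )
        log["invalid_coords"] = int((~ok).sum())
        df = df[ok]

    if drop_on_land:
        inside = spec.contains(df["lon"].to_numpy(), df["lat"].to_numpy())
        on_sea = np.zeros(len(df), dtype=bool)
        if len(df):
            lat_i = np.floor((df["lat"].to_numpy() - spec.lat_min) / spec.resolution).astype(int)
            lon_i = np.floor((df["lon"].to_numpy() - spec.lon_min) / spec.resolution).astype(int)
            on_sea[inside] = sea[lat_i[inside], lon_i[inside]]
        # records outside the grid are retained here; aggregation handles them
        keep = on_sea | ~inside
        log["on_land"] = int((~keep).sum())
        df = df[keep]

    if drop_outside_years and "year" in df.columns:
        lo, hi = year_window
        ok = df["year"].between(lo, hi)
        log["outside_years"] = int((~ok).sum())
        df = df[ok]

    if drop_duplicates:
        inside = spec.contains(df["lon"].to_numpy(), df["lat"].to_numpy())
        lat_i = np.full(len(df), -1)
        lon_i = np.full(len(df), -1)
        if len(df):
            lat_i[inside] = np.floor((df["lat"].to_numpy()[inside] - spec.lat_min) / spec.resolution).astype(int)
            lon_i[inside] = np.floor((df["lon"].to_numpy()[inside] - spec.lon_min) / spec.resolution).astype(int)
        key = pd.DataFrame({"species": df["species"].to_numpy(), "i": lat_i, "j": lon_i})
        dup = key.duplicated().to_numpy() & (lat_i >= 0)
        log["duplicate_cell"] = int(dup.sum())
        df = df[~dup]

    return df.reset_index(drop=True), log


def aggregate_to_grid(records: pd.DataFrame, spec: GridSpec, species: str | None = None) -> PresenceGrid:
    """Binary presence grid; records outside the grid are dropped with a warning."""
    import warnings

    if species is None:
        uniq = records["species"].unique() if len(records) else np.array([""])
        species = str(uniq[0]) if len(uniq) else ""
    present = np.zeros(spec.shape, dtype=bool)
    if len(records):
        lon = records["lon"].to_numpy(dtype=float)
        lat = records["lat"].to_numpy(dtype=float)
        inside = spec.contains(lon, lat)
        n_out = int((~inside).sum())
        if n_out:
            warnings.warn(f"{n_out} records outside grid bounds dropped", stacklevel=2)
        i = np.floor((lat[inside] - spec.lat_min) / spec.resolution).astype(int)
        j = np.floor((lon[inside] - spec.lon_min) / spec.resolution).astype(int)
        present[i, j] = True
        n_records = int(inside.sum())
    else:
        n_records = 0
    return PresenceGrid(spec=spec, present=present, species=species, n_records=n_records)


def split_train_test(
    presence: PresenceGrid, train_fraction: float = 0.75, seed: int = 0
) -> tuple[PresenceGrid, PresenceGrid]:
    """Randomly partition present cells into train and test presence grids."""
    cells = np.argwhere(presence.present)
    n = len(cells)
    if n < 4:
        raise GridError(f"need >= 4 present cells to split, got {n}")
    n_train = int(round(train_fraction * n))
    if n_train <= 0 or n_train >= n:
        raise GridError(f"train_fraction {train_fraction} leaves an empty train or test set")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train = np.zeros(presence.spec.shape, dtype=bool)
    test = np.zeros(presence.spec.shape, dtype=bool)
    tr = cells[order[:n_train]]
    te = cells[order[n_train:]]
    train[tr[:, 0], tr[:, 1]] = True
    test[te[:, 0], te[:, 1]] = True
    return (
        PresenceGrid(presence.spec, train, presence.species, n_records=n_train),
        PresenceGrid(presence.spec, test, presence.species, n_records=n - n_train),
    )
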