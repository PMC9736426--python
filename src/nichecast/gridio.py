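"""Plain-text I/O for grids, occurrences, masks and hulls.

Grids use the 6-line-header ESRI ASCII dialect (ncols/nrows/xllcorner/
yllcorner/cellsize/NODATA_value) so any GIS can ingest them; occurrences
travel as CSV with columns species,row,col,presence,region,design; strata,
regions and protection regimes as integer grids; hulls as GeoJSON polygons
in PC coordinates.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping

from .exceptions import LoadError
from .synthetic import (
    EnvStack,
    OccurrenceSet,
    ProtectionMask,
    StrataMap,
    VARIABLES,
)

NODATA = -9999.0

OCC_COLUMNS = ["species", "row", "col", "presence", "region", "design"]


def write_ascii_grid(path: Path, array: np.ndarray, cell_size: float,
                     fmt: str = "%.6f") -> None:
    rows, cols = array.shape
    header = (
        f"ncols {cols}\nnrows {rows}\nxllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize {cell_size}\nNODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, array, fmt=fmt)


def read_ascii_grid(path: Path) -> tuple[np.ndarray, float]:
    path = Path(path)
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        array = np.loadtxt(fh)
    rows, cols = int(header["nrows"]), int(header["ncols"])
    if array.shape != (rows, cols):
        raise LoadError(f"{path}: data shape {array.shape} != header ({rows}, {cols})")
    return array, header["cellsize"]


# ---------------------------------------------------------------------------
# environment stacks

_REGION_CODES = {"native": 1, "invaded": 2, "other": 3}
_CODE_REGIONS = {v: k for k, v in _REGION_CODES.items()}


def write_env_stack(directory: Path, env: EnvStack) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, layer in env.variables.items():
        p = directory / f"{name}_{env.scenario}.asc"
        write_ascii_grid(p, layer, env.cell_size)
        written.append(p)
    codes = np.vectorize(_REGION_CODES.__getitem__)(env.region_mask)
    p = directory / "region.asc"
    write_ascii_grid(p, codes.astype(float), env.cell_size, fmt="%d")
    written.append(p)
    return written


def read_env_stack(directory: Path, scenario: str,
                   variables: tuple[str, ...] = VARIABLES) -> EnvStack:
    directory = Path(directory)
    layers = {}
    cell_size = None
    for name in variables:
        p = directory / f"{name}_{scenario}.asc"
        if not p.exists():
            raise LoadError(f"missing layer file {p}")
        layers[name], cell_size = read_ascii_grid(p)
    region_codes, _ = read_ascii_grid(directory / "region.asc")
    shapes = {a.shape for a in layers.values()} | {region_codes.shape}
    if len(shapes) != 1:
        raise LoadError(f"layers in {directory} do not align: {shapes}")
    region = np.vectorize(_CODE_REGIONS.__getitem__)(region_codes.astype(int))
    env = EnvStack(
        grid_shape=region_codes.shape, cell_size=cell_size,
        variables=layers, scenario=scenario, region_mask=region.astype("<U8"),
    )
    env.validate()
    return env


# ---------------------------------------------------------------------------
# occurrences

def occurrences_to_frame(sets: list[OccurrenceSet]) -> pd.DataFrame:
    frames = []
    for occ in sets:
        frames.append(pd.DataFrame({
            "species": occ.species, "row": occ.rows, "col": occ.cols,
            "presence": occ.presence, "region": occ.region, "design": occ.design,
        }))
    return pd.concat(frames, ignore_index=True)[OCC_COLUMNS]


def write_occurrences(path: Path, sets: list[OccurrenceSet]) -> None:
    occurrences_to_frame(sets).to_csv(path, index=False)


def read_occurrences(path: Path, grid_shape: tuple[int, int],
                     merge_map: dict[str, str] | None = None) -> list[OccurrenceSet]:
    """Load occurrence sets, applying an optional species-merge map.

    The merge map handles taxonomic pooling (records of a hard-to-separate
    taxon reassigned to a more widespread one) before sets are assembled.
    Rows outside the grid raise a :class:`LoadError` naming the row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in OCC_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing columns {missing}")
    rows_, cols_ = grid_shape
    bad = (df["row"] < 0) | (df["row"] >= rows_) | (df["col"] < 0) | (df["col"] >= cols_)
    if bad.any():
        raise LoadError(f"{path}: occurrence outside grid at row {int(bad.idxmax())}")
    if merge_map:
        df["species"] = df["species"].map(lambda s: merge_map.get(s, s))
    out = []
    for (species, region, design), grp in df.groupby(
            ["species", "region", "design"], sort=True):
        out.append(OccurrenceSet(
            species=species,
            rows=grp["row"].to_numpy(int), cols=grp["col"].to_numpy(int),
            presence=grp["presence"].to_numpy(int),
            region=region, design=design,
        ))
    return out


# ---------------------------------------------------------------------------
# strata & protection

def write_strata(path: Path, strata: StrataMap, cell_size: float) -> None:
    write_ascii_grid(path, strata.labels.astype(float), cell_size, fmt="%d")


def read_strata(path: Path) -> StrataMap:
    labels, _ = read_ascii_grid(path)
    labels = labels.astype(int)
    return StrataMap(labels=labels, k=int(labels.max()))


def write_protection(directory: Path, pm: ProtectionMask, cell_size: float) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(directory / "regime.asc", pm.regime.astype(float), cell_size, fmt="%d")
    rows = []
    for species, grid in sorted(pm.targeted.items()):
        for r, c in np.argwhere(grid):
            rows.append({"species": species, "row": int(r), "col": int(c)})
    pd.DataFrame(rows, columns=["species", "row", "col"]).to_csv(
        directory / "targeted.csv", index=False)


def read_protection(directory: Path, species_list: list[str]) -> ProtectionMask:
    directory = Path(directory)
    regime, _ = read_ascii_grid(directory / "regime.asc")
    regime = regime.astype(int)
    targeted = {s: np.zeros(regime.shape, dtype=bool) for s in species_list}
    df = pd.read_csv(directory / "targeted.csv")
    for _, row in df.iterrows():
        s = row["species"]
        if s not in targeted:
            raise LoadError(f"{directory / 'targeted.csv'}: unknown species label {s!r}")
        targeted[s][int(row["row"]), int(row["col"])] = True
    return ProtectionMask(regime=regime, targeted=targeted)


# ---------------------------------------------------------------------------
# hulls

def write_hulls_geojson(path: Path, hulls: list) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"species": h.species, "area": h.area},
            "geometry": mapping(h.polygon),
        }
        for h in hulls
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
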