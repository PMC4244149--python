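"""File formats: occurrence CSVs and ESRI ASCII grid rasters.

Occurrences travel as CSV with header ``species,longitude,latitude`` (WGS84
decimal degrees). Rasters travel as ESRI ASCII grids (one layer per ``.asc``
file); a multi-layer :class:`~nichecmp.grids.EnvGrid` is a directory of
``.asc`` files plus a ``layers.json`` manifest recording layer order. The
ASCII grid header carries the lattice geometry (ncols, nrows, corner, cell
size, nodata value), so round-trips preserve alignment exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, SchemaError, ValidationError
from .grids import EnvGrid, OccurrenceSet

__all__ = [
    "read_occurrences",
    "write_occurrences",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_envgrid",
    "write_envgrid",
]

log = logging.getLogger(__name__)

OCC_COLUMNS = ["species", "longitude", "latitude"]
DEFAULT_NODATA = -9999.0


def read_occurrences(path: str | Path, grid: EnvGrid) -> dict[str, OccurrenceSet]:
    """Read and validate an occurrence CSV, snapping records to the grid.

    Rows are grouped by species; records sharing a grid cell are collapsed to
    one unique record (with a WARNING naming the species and count); rows
    with missing or non-numeric coordinates are rejected with their line
    numbers; coordinates off-grid raise listing the offenders.
    """
    df = pd.read_csv(path)
    missing = [c for c in OCC_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"occurrence CSV {path} lacks column(s) {missing}")
    coords = df[["longitude", "latitude"]].apply(pd.to_numeric, errors="coerce")
    bad = coords.isna().any(axis=1) | df["species"].isna()
    if bad.any():
        lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]  # header = line 1
        raise ValidationError(f"malformed occurrence rows at line(s) {lines} of {path}")
    out: dict[str, OccurrenceSet] = {}
    for species, sub in df.groupby("species", sort=True):
        records = sub[["longitude", "latitude"]].to_numpy(dtype=float)
        occ = OccurrenceSet.from_records(str(species), records, grid)
        dropped = len(records) - len(occ)
        if dropped:
            log.warning(
                "%s: collapsed %d duplicate record(s) sharing a grid cell", species, dropped
            )
        out[str(species)] = occ
    return out


def write_occurrences(occs: dict[str, OccurrenceSet] | list[OccurrenceSet], path: str | Path) -> None:
    """Write occurrence sets to a ``species,longitude,latitude`` CSV."""
    sets = list(occs.values()) if isinstance(occs, dict) else list(occs)
    rows = [
        {"species": o.species_name, "longitude": lon, "latitude": lat}
        for o in sets
        for lon, lat in o.records
    ]
    pd.DataFrame(rows, columns=OCC_COLUMNS).to_csv(path, index=False)


# -- ESRI ASCII grids ---------------------------------------------------------


def write_ascii_grid(
    path: str | Path,
    values: np.ndarray,
    cell_size: float,
    origin: tuple[float, float],
    nodata_mask: np.ndarray | None = None,
    nodata_value: float = DEFAULT_NODATA,
) -> None:
    """Write one layer as an ESRI ASCII grid (row 0 = northernmost)."""
    values = np.asarray(values, dtype=float)
    n_rows, n_cols = values.shape
    out = values.copy()
    if nodata_mask is not None:
        out[np.asarray(nodata_mask, bool)] = nodata_value
    out[~np.isfinite(out)] = nodata_value
    xll = origin[0]
    yll = origin[1] - n_rows * cell_size
    header = (
        f"ncols {n_cols}\nnrows {n_rows}\n"
        f"xllcorner {xll!r}\nyllcorner {yll!r}\n"
        f"cellsize {cell_size!r}\nNODATA_value {nodata_value!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path):
    """Read an ESRI ASCII grid.

    Returns ``(values, nodata_mask, cell_size, origin)`` with nodata cells
    set to NaN in ``values`` and ``origin`` the NW outer corner.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise SchemaError(f"{path} lacks ASCII-grid header field {key!r}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise SchemaError(f"{path}: data block {values.shape} != header ({n_rows}, {n_cols})")
    nodata_value = header.get("nodata_value", DEFAULT_NODATA)
    mask = values == nodata_value
    values = values.copy()
    values[mask] = np.nan
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + n_rows * cell)
    return values, mask, cell, origin


def write_envgrid(grid: EnvGrid, directory: str | Path) -> None:
    """Write a multi-layer grid as one .asc per layer plus layers.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, name in enumerate(grid.layer_names):
        write_ascii_grid(
            directory / f"{name}.asc", grid.values[i], grid.cell_size, grid.origin,
            nodata_mask=grid.nodata_mask,
        )
    (directory / "layers.json").write_text(json.dumps({"layers": grid.layer_names}, indent=2))


def read_envgrid(source: str | Path | list[str | Path]) -> EnvGrid:
    """Assemble an EnvGrid from a layer directory or explicit .asc paths.

    All layers must share shape, cell size and origin; any mismatch is an
    alignment error (no resampling is attempted).
    """
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        directory = Path(source)
        manifest = json.loads((directory / "layers.json").read_text())
        paths = [directory / f"{name}.asc" for name in manifest["layers"]]
        names = list(manifest["layers"])
    else:
        paths = [Path(p) for p in np.atleast_1d(source)]
        names = [p.stem for p in paths]
    layers, masks = [], []
    geometry = None
    for p in paths:
        values, mask, cell, origin = read_ascii_grid(p)
        geo = (values.shape, cell, origin)
        if geometry is None:
            geometry = geo
        elif (
            geo[0] != geometry[0]
            or not np.isclose(geo[1], geometry[1])
            or not np.allclose(geo[2], geometry[2])
        ):
            raise AlignmentError(
                f"layer {p} geometry {geo} does not match first layer {geometry}"
            )
        layers.append(values)
        masks.append(mask)
    nodata = np.any(masks, axis=0)
    values = np.stack(layers)
    values[:, nodata] = 0.0  # shared mask; masked values are never read
    return EnvGrid(
        values=values, layer_names=names, cell_size=geometry[1], origin=geometry[2],
        nodata_mask=nodata,
    )
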