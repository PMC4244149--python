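"""Lattice containers: environmental grids, occurrence sets, remnant masks.

Coordinate convention (fixed for the whole package):

* cell-center registration; row 0 is the **northernmost** row;
* ``origin`` is the (longitude, latitude) of the outer north-west corner;
* a point maps to the cell ``row = floor((origin_lat - lat) / cell_size)``,
  ``col = floor((lon - origin_lon) / cell_size)`` (half-open cell intervals);
* cells are addressed by the linear id ``row * n_cols + col``.

All geographic handling is lattice-based in decimal degrees (WGS84); layers
combined in one :class:`EnvGrid` must share shape, cell size and origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, ArgumentError, ValidationError

__all__ = ["EnvGrid", "OccurrenceSet", "RemnantMask"]


@dataclass
class EnvGrid:
    """A multi-layer environmental raster on a shared geographic lattice.

    Parameters
    ----------
    values
        Array of shape ``(n_layers, n_rows, n_cols)``; finite on every
        non-nodata cell.
    nodata_mask
        Boolean ``(n_rows, n_cols)``; ``True`` marks cells with no data,
        shared across layers.
    layer_names
        Ordered, distinct layer names.
    cell_size
        Cell edge length in decimal degrees.
    origin
        ``(longitude, latitude)`` of the north-west cell's outer corner.
    """

    values: np.ndarray
    layer_names: list[str]
    cell_size: float
    origin: tuple[float, float]
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ArgumentError("values must have shape (n_layers, n_rows, n_cols)")
        n_layers = self.values.shape[0]
        if len(self.layer_names) != n_layers:
            raise ArgumentError("layer_names length must equal number of layers")
        if len(set(self.layer_names)) != n_layers:
            raise ArgumentError("layer_names must be distinct")
        if self.cell_size <= 0:
            raise ArgumentError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape[1:], dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape[1:]:
            raise AlignmentError("nodata_mask shape must match layer shape")
        valid = self.values[:, ~self.nodata_mask]
        if valid.size and not np.all(np.isfinite(valid)):
            raise ArgumentError("non-nodata cells must hold finite values")

    # -- shape ---------------------------------------------------------------

    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    @property
    def n_rows(self) -> int:
        return self.values.shape[1]

    @property
    def n_cols(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    # -- coordinate mapping --------------------------------------------------

    def cell_center(self, cell_ids: np.ndarray) -> np.ndarray:
        """Return ``(n, 2)`` lon/lat centers of the given linear cell ids."""
        cell_ids = np.atleast_1d(np.asarray(cell_ids, dtype=int))
        rows, cols = np.divmod(cell_ids, self.n_cols)
        lon = self.origin[0] + (cols + 0.5) * self.cell_size
        lat = self.origin[1] - (rows + 0.5) * self.cell_size
        return np.column_stack([lon, lat])

    def cell_id_of(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Snap lon/lat points to linear cell ids; off-grid points raise."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        cols = np.floor((lon - self.origin[0]) / self.cell_size).astype(int)
        rows = np.floor((self.origin[1] - lat) / self.cell_size).astype(int)
        bad = (rows < 0) | (rows >= self.n_rows) | (cols < 0) | (cols >= self.n_cols)
        if np.any(bad):
            offenders = [(float(lon[i]), float(lat[i])) for i in np.flatnonzero(bad)]
            raise ValidationError(f"coordinates fall outside the grid: {offenders}")
        return rows * self.n_cols + cols

    # -- value access --------------------------------------------------------

    def env_at(self, cell_ids: np.ndarray) -> np.ndarray:
        """Environmental values at cells, shape ``(n, n_layers)``."""
        cell_ids = np.atleast_1d(np.asarray(cell_ids, dtype=int))
        rows, cols = np.divmod(cell_ids, self.n_cols)
        return self.values[:, rows, cols].T

    def table(self, mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to ``(cell_ids, values)`` over ``mask & ~nodata`` cells."""
        keep = ~self.nodata_mask if mask is None else (np.asarray(mask, bool) & ~self.nodata_mask)
        if keep.shape != self.shape:
            raise AlignmentError("mask shape must match grid shape")
        ids = np.flatnonzero(keep.ravel())
        return ids, self.env_at(ids)

    def copy_with(self, values: np.ndarray, layer_names: list[str]) -> "EnvGrid":
        """New grid on the same lattice with different layers."""
        return EnvGrid(
            values=values,
            layer_names=layer_names,
            cell_size=self.cell_size,
            origin=self.origin,
            nodata_mask=self.nodata_mask.copy(),
        )

    def same_lattice(self, other: "EnvGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class OccurrenceSet:
    """One species' presence records snapped to grid cells.

    ``records`` keeps the raw (longitude, latitude) points; ``cell_ids``
    holds the deduplicated linear cell indices ("unique occurrence records").
    """

    species_name: str
    records: np.ndarray  # (n, 2) lon/lat
    cell_ids: np.ndarray  # (m,) unique linear indices

    def __post_init__(self) -> None:
        self.records = np.asarray(self.records, dtype=float).reshape(-1, 2)
        self.cell_ids = np.asarray(self.cell_ids, dtype=int)
        if self.cell_ids.size != np.unique(self.cell_ids).size:
            raise ArgumentError("cell_ids must be deduplicated")
        if self.cell_ids.size < 1:
            raise ArgumentError("an OccurrenceSet needs at least one cell")

    def __len__(self) -> int:
        return int(self.cell_ids.size)

    @classmethod
    def from_records(cls, species_name: str, records: np.ndarray, grid: EnvGrid) -> "OccurrenceSet":
        """Snap raw lon/lat records to the grid, deduplicating by cell."""
        records = np.asarray(records, dtype=float).reshape(-1, 2)
        ids = grid.cell_id_of(records[:, 0], records[:, 1])
        on_nodata = grid.nodata_mask.ravel()[ids]
        if np.any(on_nodata):
            offenders = [tuple(map(float, records[i])) for i in np.flatnonzero(on_nodata)]
            raise ValidationError(f"records fall on nodata cells: {offenders}")
        # keep first-seen order of unique cells
        _, first = np.unique(ids, return_index=True)
        unique_ids = ids[np.sort(first)]
        return cls(species_name=species_name, records=records, cell_ids=unique_ids)


@dataclass
class RemnantMask:
    """Fine-resolution boolean habitat-remnant raster.

    The fine lattice refines a coarse :class:`EnvGrid` by an integer factor;
    each fine cell represents ``cell_area_km2`` of ground.
    """

    mask: np.ndarray  # (fine_rows, fine_cols) boolean, True = remnant
    cell_size: float  # fine cell edge, degrees
    cell_area_km2: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ArgumentError("remnant mask must be 2-D")
        if self.cell_area_km2 <= 0:
            raise ArgumentError("cell_area_km2 must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def fine_factor_for(self, grid: EnvGrid) -> int:
        """Refinement factor relative to a coarse grid; must divide evenly."""
        fr, fc = self.mask.shape
        if fr % grid.n_rows or fc % grid.n_cols or fr // grid.n_rows != fc // grid.n_cols:
            raise AlignmentError(
                f"fine grid {self.mask.shape} does not evenly refine coarse grid {grid.shape}"
            )
        return fr // grid.n_rows
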