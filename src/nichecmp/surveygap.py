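"""Survey-gap prioritization over fine-resolution habitat-remnant masks.

Consensus predictions (coarse climate lattice) are downscaled to the remnant
raster's resolution by nearest-neighbor replication; remnant patches are
labeled by connected components and filtered by a minimum area (default
16 km²); priority cells are those predicted suitable, inside a large-enough
remnant, and not already holding a known occurrence — the places a field
survey is most likely to add a new record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .enm import ConsensusMap
from .errors import AlignmentError, ArgumentError
from .grids import EnvGrid, OccurrenceSet, RemnantMask

__all__ = [
    "PriorityResult",
    "downscale",
    "patch_areas",
    "priority_cells",
    "occurrence_fine_mask",
]


@dataclass
class PriorityResult:
    """Priority mask plus the counts and parameters behind it."""

    mask: np.ndarray  # fine-grid boolean
    n_predicted: int  # fine cells with consensus >= cut
    n_remnant_eligible: int  # fine remnant cells in large-enough patches
    n_priority: int
    min_patch_km2: float
    consensus_cut: float
    connectivity: int

    def to_dict(self) -> dict:
        return {
            "n_predicted": self.n_predicted,
            "n_remnant_eligible": self.n_remnant_eligible,
            "n_priority": self.n_priority,
            "min_patch_km2": self.min_patch_km2,
            "consensus_cut": self.consensus_cut,
            "connectivity": self.connectivity,
        }


def downscale(consensus: ConsensusMap | np.ndarray, fine_factor: int) -> np.ndarray:
    """Replicate each coarse cell into a fine_factor × fine_factor block."""
    if not isinstance(fine_factor, (int, np.integer)) or fine_factor < 1:
        raise ArgumentError("fine_factor must be an integer >= 1")
    values = consensus.fraction if isinstance(consensus, ConsensusMap) else np.asarray(consensus)
    return np.kron(values, np.ones((fine_factor, fine_factor), dtype=values.dtype))


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ArgumentError("connectivity must be 4 or 8")


def patch_areas(remnants: RemnantMask, connectivity: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Label remnant patches; return (labels, per-patch area in km²).

    ``labels`` is 0 on non-remnant cells and 1..n_patches elsewhere;
    ``areas[i]`` is the area of patch ``i + 1``.
    """
    labels, n = ndimage.label(remnants.mask, structure=_structure(connectivity))
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return labels, counts * remnants.cell_area_km2


def occurrence_fine_mask(
    occ: OccurrenceSet, grid: EnvGrid, fine_factor: int
) -> np.ndarray:
    """Fine-grid mask of cells containing a known occurrence record."""
    mask = np.zeros((grid.n_rows * fine_factor, grid.n_cols * fine_factor), dtype=bool)
    fine_size = grid.cell_size / fine_factor
    lon, lat = occ.records[:, 0], occ.records[:, 1]
    cols = np.floor((lon - grid.origin[0]) / fine_size).astype(int)
    rows = np.floor((grid.origin[1] - lat) / fine_size).astype(int)
    keep = (rows >= 0) & (rows < mask.shape[0]) & (cols >= 0) & (cols < mask.shape[1])
    mask[rows[keep], cols[keep]] = True
    return mask


def priority_cells(
    fine_consensus: np.ndarray,
    remnants: RemnantMask,
    known_occurrence_mask: np.ndarray | None = None,
    min_patch_km2: float = 16.0,
    consensus_cut: float = 0.5,
    connectivity: int = 8,
    exclude_known: bool = True,
) -> PriorityResult:
    """Flag fine cells worth surveying.

    priority = (consensus >= consensus_cut)
             ∩ (remnant patch area >= min_patch_km2)
             ∖ (cells with a known occurrence, if ``exclude_known``)
    """
    fine_consensus = np.asarray(fine_consensus, dtype=float)
    if fine_consensus.shape != remnants.mask.shape:
        raise AlignmentError(
            f"consensus {fine_consensus.shape} and remnants {remnants.mask.shape} are misaligned"
        )
    predicted = fine_consensus >= consensus_cut
    labels, areas = patch_areas(remnants, connectivity)
    big = np.flatnonzero(areas >= min_patch_km2) + 1
    eligible = np.isin(labels, big)
    priority = predicted & eligible
    if exclude_known and known_occurrence_mask is not None:
        known = np.asarray(known_occurrence_mask, dtype=bool)
        if known.shape != priority.shape:
            raise AlignmentError("known-occurrence mask misaligned with fine grid")
        priority &= ~known
    return PriorityResult(
        mask=priority,
        n_predicted=int(predicted.sum()),
        n_remnant_eligible=int(eligible.sum()),
        n_priority=int(priority.sum()),
        min_patch_km2=float(min_patch_km2),
        consensus_cut=float(consensus_cut),
        connectivity=int(connectivity),
    )
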