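"""Schoener's D niche overlap and its randomization tests.

Overlap between two species is measured on cell-aligned occupancy surfaces
``Z1``, ``Z2`` (see :mod:`nichecmp.envspace`) as

    D = 1 − ½ Σ |Z1 − Z2|,

ranging from 0 (disjoint niches) to 1 (identical niches). Two randomization
routines ask different questions about an observed D:

* the **equivalency test** pools the two occurrence sets and re-assigns them
  at random while maintaining the original sample sizes — are the two sets
  interchangeable descriptions of one niche?
* the **similarity test** relocates one species' occupancy at random over its
  own background (keeping the other unchanged), in both directions 1→2 and
  2→1 — does the observed overlap exceed what the available environments
  alone would produce?

p-values use the add-one rule p = (count + 1) / (reps + 1), so reps = 100
gives the familiar granularity 1/101, 2/101, ... (0.0099, 0.0198, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .envspace import (
    PcaModel,
    _silverman,
    fit_pca,
    kernel_density_surface,
    occupancy_from_densities,
    score_bounds,
)
from .errors import AlignmentError, ArgumentError, NormalizationError, SupportError
from .grids import EnvGrid, OccurrenceSet

__all__ = [
    "OverlapResult",
    "schoener_d",
    "equivalency_test",
    "similarity_test",
    "compare_pair",
]


def schoener_d(Z1: np.ndarray, Z2: np.ndarray) -> float:
    """Schoener's D between two normalized, cell-aligned occupancy surfaces."""
    Z1 = np.asarray(Z1, dtype=float)
    Z2 = np.asarray(Z2, dtype=float)
    if Z1.shape != Z2.shape:
        raise AlignmentError(f"surfaces are misaligned: {Z1.shape} vs {Z2.shape}")
    for i, Z in enumerate((Z1, Z2), 1):
        if abs(Z.sum() - 1.0) > 1e-6:
            raise NormalizationError(f"surface {i} sums to {Z.sum():.6g}, not 1")
    return float(max(0.0, 1.0 - 0.5 * np.abs(Z1 - Z2).sum()))


@dataclass
class OverlapResult:
    """One full pairwise comparison: observed D plus the three tests."""

    pair: tuple[str, str]
    D_obs: float
    null_equivalency: np.ndarray
    null_similarity_12: np.ndarray
    null_similarity_21: np.ndarray
    p_equivalency: float
    p_similarity_12: float
    p_similarity_21: float
    reps: int
    alternative: dict = field(default_factory=dict)  # per-test tail
    seed: int | None = None
    settings: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flat summary row (pair, D, p_equiv, p_sim_12, p_sim_21)."""
        return {
            "pair": f"{self.pair[0]} vs {self.pair[1]}",
            "D": self.D_obs,
            "p_equiv": self.p_equivalency,
            "p_sim_12": self.p_similarity_12,
            "p_sim_21": self.p_similarity_21,
        }


def permutation_p(null: np.ndarray, observed: float, alternative: str) -> float:
    """Add-one permutation p-value: (count + 1) / (reps + 1)."""
    null = np.asarray(null, dtype=float)
    if alternative == "lower":
        count = int(np.sum(null <= observed))
    elif alternative == "greater":
        count = int(np.sum(null >= observed))
    else:
        raise ArgumentError("alternative must be 'lower' or 'greater'")
    return (count + 1) / (null.size + 1)


class _PairSpace:
    """Shared environmental space for one species pair.

    Fixes the PCA (calibrated on the union of the two backgrounds), the
    common axis bounds, and the two background availability surfaces once, so
    the randomization loops only re-smooth occurrence scores.
    """

    def __init__(
        self,
        occ1: OccurrenceSet,
        occ2: OccurrenceSet,
        background1: np.ndarray,
        background2: np.ndarray,
        grid: EnvGrid,
        model: PcaModel | None = None,
        R: int = 100,
        bandwidth: tuple[float, float] | None = None,
        availability_floor: float = 1e-6,
    ) -> None:
        if model is None:
            model = fit_pca(grid, background1 | background2)
        self.model = model
        self.R = R
        self.bandwidth = bandwidth
        self.floor = availability_floor
        _, bg1_env = grid.table(background1)
        _, bg2_env = grid.table(background2)
        bg1_scores = model.transform(bg1_env, 2)
        bg2_scores = model.transform(bg2_env, 2)
        self.bounds = score_bounds([bg1_scores, bg2_scores])
        self.E1 = kernel_density_surface(bg1_scores, self.bounds, R, bandwidth)
        self.E2 = kernel_density_surface(bg2_scores, self.bounds, R, bandwidth)
        self.cells1 = np.asarray(occ1.cell_ids, dtype=int)
        self.cells2 = np.asarray(occ2.cell_ids, dtype=int)
        self.scores1 = model.transform(grid.env_at(occ1.cell_ids), 2)
        self.scores2 = model.transform(grid.env_at(occ2.cell_ids), 2)
        self.Z1 = self.occupancy(self.scores1, self.E1)
        self.Z2 = self.occupancy(self.scores2, self.E2)
        self.D_obs = schoener_d(self.Z1, self.Z2)

    def occupancy(self, occ_scores: np.ndarray, E: np.ndarray) -> np.ndarray:
        bw = self.bandwidth if self.bandwidth is not None else _silverman(occ_scores)
        O = kernel_density_surface(occ_scores, self.bounds, self.R, tuple(bw))
        return occupancy_from_densities(O, E, self.floor)

    # -- randomizations ------------------------------------------------------

    def equivalency_null(self, reps: int, rng: np.random.Generator) -> np.ndarray:
        """Pool occurrences, re-assign keeping sizes; each pseudo-set keeps
        its own species' background.

        Observed occurrence sets hold unique cells, so the re-assignment
        preserves that structure: a cell recorded for both species
        contributes one copy to each pseudo-set, and only singleton records
        are shuffled. Without this constraint a shared cell could land twice
        in one pseudo-set, doubling its kernel mass — a configuration the
        observed data can never produce — and the test would be
        conservative rather than exchangeable under a shared niche.
        """
        pooled_cells = np.concatenate([self.cells1, self.cells2])
        pooled_scores = np.vstack([self.scores1, self.scores2])
        n1 = self.scores1.shape[0]
        unique, first_idx, counts = np.unique(
            pooled_cells, return_index=True, return_counts=True
        )
        dup_scores = pooled_scores[first_idx[counts == 2]]
        single_scores = pooled_scores[first_idx[counts == 1]]
        n_dup = dup_scores.shape[0]
        null = np.empty(reps)
        for r in range(reps):
            idx = rng.permutation(single_scores.shape[0])
            Zp1 = self.occupancy(
                np.vstack([dup_scores, single_scores[idx[: n1 - n_dup]]]), self.E1
            )
            Zp2 = self.occupancy(
                np.vstack([dup_scores, single_scores[idx[n1 - n_dup:]]]), self.E2
            )
            null[r] = schoener_d(Zp1, Zp2)
        return null

    def similarity_null(
        self, randomized: int, reps: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Translate the randomized species' occupancy over its background.

        Each rep draws a support cell of that species' availability surface
        uniformly, shifts the observed occupancy so its centroid lands there,
        zeroes mass off-grid or off-support, and renormalizes.
        """
        if randomized == 1:
            Z_rand, E_rand, Z_fixed = self.Z1, self.E1, self.Z2
        else:
            Z_rand, E_rand, Z_fixed = self.Z2, self.E2, self.Z1
        support = E_rand >= self.floor * E_rand.max()
        targets = np.argwhere(support)
        if targets.size == 0:
            raise SupportError("background support admits no translation")
        ii, jj = np.indices(Z_rand.shape)
        ci = int(round(float((ii * Z_rand).sum())))
        cj = int(round(float((jj * Z_rand).sum())))
        null = np.empty(reps)
        for r in range(reps):
            for _ in range(1000):
                ti, tj = targets[rng.integers(targets.shape[0])]
                shifted = _shift2d(Z_rand, ti - ci, tj - cj)
                shifted[~support] = 0.0
                total = shifted.sum()
                if total > 0:
                    null[r] = schoener_d(shifted / total, Z_fixed)
                    break
            else:
                raise SupportError("no admissible translation retained any mass")
        return null


def _shift2d(arr: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Shift a 2-D array by (dr, dc), zero-filling mass that falls off-grid."""
    out = np.zeros_like(arr)
    R, C = arr.shape
    r0, r1 = max(0, dr), min(R, R + dr)
    c0, c1 = max(0, dc), min(C, C + dc)
    if r0 < r1 and c0 < c1:
        out[r0:r1, c0:c1] = arr[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
    return out


def _check_pair(occ1: OccurrenceSet, occ2: OccurrenceSet, reps: int) -> None:
    if reps < 1:
        raise ArgumentError("reps must be >= 1")
    if len(occ1) < 2 or len(occ2) < 2:
        raise ArgumentError("each species needs at least 2 occurrence cells")


def equivalency_test(
    occ1: OccurrenceSet,
    occ2: OccurrenceSet,
    background1: np.ndarray,
    background2: np.ndarray,
    grid: EnvGrid,
    reps: int = 100,
    alternative: str = "lower",
    seed: int | None = None,
    **space_kwargs,
) -> tuple[np.ndarray, float]:
    """Niche equivalency test; returns (null D values, p)."""
    _check_pair(occ1, occ2, reps)
    space = _PairSpace(occ1, occ2, background1, background2, grid, **space_kwargs)
    null = space.equivalency_null(reps, np.random.default_rng(seed))
    return null, permutation_p(null, space.D_obs, alternative)


def similarity_test(
    occ_fixed: OccurrenceSet,
    occ_randomized: OccurrenceSet,
    background_fixed: np.ndarray,
    background_randomized: np.ndarray,
    grid: EnvGrid,
    reps: int = 100,
    alternative: str = "greater",
    seed: int | None = None,
    **space_kwargs,
) -> tuple[np.ndarray, float]:
    """Niche similarity test (randomizing the second species); returns (null, p)."""
    _check_pair(occ_fixed, occ_randomized, reps)
    space = _PairSpace(
        occ_fixed, occ_randomized, background_fixed, background_randomized, grid, **space_kwargs
    )
    null = space.similarity_null(2, reps, np.random.default_rng(seed))
    return null, permutation_p(null, space.D_obs, alternative)


def compare_pair(
    occ1: OccurrenceSet,
    occ2: OccurrenceSet,
    background1: np.ndarray,
    background2: np.ndarray,
    grid: EnvGrid,
    reps: int = 100,
    seed: int | None = None,
    equivalency_alternative: str = "lower",
    similarity_alternative: str = "greater",
    model: PcaModel | None = None,
    R: int = 100,
    bandwidth: tuple[float, float] | None = None,
    availability_floor: float = 1e-6,
) -> OverlapResult:
    """Full pairwise comparison: D plus equivalency and both similarity tests.

    All three tests share one environmental space (PCA calibrated on the
    union of the two backgrounds, common axis bounds), so the D values are
    directly comparable across tests. Both one-tailed p-values can be
    recomputed from the stored null distributions; the reported tails are the
    requested ``*_alternative`` arguments.
    """
    _check_pair(occ1, occ2, reps)
    space = _PairSpace(
        occ1, occ2, background1, background2, grid,
        model=model, R=R, bandwidth=bandwidth, availability_floor=availability_floor,
    )
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(3)]
    null_eq = space.equivalency_null(reps, rngs[0])
    null_12 = space.similarity_null(2, reps, rngs[1])  # 1 fixed, 2 randomized
    null_21 = space.similarity_null(1, reps, rngs[2])  # 2 fixed, 1 randomized
    return OverlapResult(
        pair=(occ1.species_name, occ2.species_name),
        D_obs=space.D_obs,
        null_equivalency=null_eq,
        null_similarity_12=null_12,
        null_similarity_21=null_21,
        p_equivalency=permutation_p(null_eq, space.D_obs, equivalency_alternative),
        p_similarity_12=permutation_p(null_12, space.D_obs, similarity_alternative),
        p_similarity_21=permutation_p(null_21, space.D_obs, similarity_alternative),
        reps=reps,
        alternative={
            "equivalency": equivalency_alternative,
            "similarity": similarity_alternative,
        },
        seed=seed,
        settings={
            "R": R,
            "bandwidth": bandwidth,
            "availability_floor": availability_floor,
        },
    )
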