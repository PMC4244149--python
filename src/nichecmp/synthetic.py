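"""Virtual landscapes, species truths, occurrence samples, remnant masks.

The generator emulates the statistical structure the downstream analysis
assumes: several spatially smooth, inter-correlated climate-like layers over a
lattice; two disjoint range regions standing in for major forested biomes;
species with Gaussian (unimodal) niches in raw environmental units; occurrence
samples drawn proportionally to suitability; and a fine binary habitat-remnant
mask. Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .errors import ArgumentError, GeometryError, SamplingError
from .grids import EnvGrid, OccurrenceSet, RemnantMask

__all__ = [
    "SpeciesTruth",
    "Scenario",
    "SCENARIO_NAMES",
    "generate_landscape",
    "make_biome_masks",
    "sample_occurrences",
    "generate_scenario",
    "generate_remnants",
]

SCENARIO_NAMES = ("divergent_allopatric", "conserved_allopatric", "sympatric_shared")


@dataclass
class SpeciesTruth:
    """The (synthetic) true Grinnellian niche of a species.

    Suitability of a cell is the multivariate-Gaussian density of its
    environment under ``(niche_centroid, niche_covariance)``, restricted to
    ``range_mask``. The Gaussian gives a unimodal niche with closed-form
    control over separation between species.
    """

    name: str
    niche_centroid: np.ndarray
    niche_covariance: np.ndarray
    range_mask: np.ndarray

    def __post_init__(self) -> None:
        self.niche_centroid = np.asarray(self.niche_centroid, dtype=float)
        self.niche_covariance = np.asarray(self.niche_covariance, dtype=float)
        c = self.niche_covariance
        if c.shape != (self.niche_centroid.size, self.niche_centroid.size):
            raise ArgumentError("covariance shape must match centroid length")
        if not np.allclose(c, c.T):
            raise ArgumentError("niche covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(c) <= 0):
            raise ArgumentError("niche covariance must be positive-definite")
        self.range_mask = np.asarray(self.range_mask, dtype=bool)

    def suitability(self, grid: EnvGrid) -> np.ndarray:
        """Gaussian-density suitability per cell (0 outside range/nodata)."""
        flat = grid.values.reshape(grid.n_layers, -1).T
        dens = np.zeros(grid.n_cells)
        ok = (self.range_mask & ~grid.nodata_mask).ravel()
        dens[ok] = stats.multivariate_normal.pdf(
            flat[ok], mean=self.niche_centroid, cov=self.niche_covariance
        )
        return dens.reshape(grid.shape)


@dataclass
class Scenario:
    """One generated comparison scenario: landscape, truths, samples, backgrounds."""

    name: str
    grid: EnvGrid
    truths: tuple[SpeciesTruth, SpeciesTruth]
    occurrences: tuple[OccurrenceSet, OccurrenceSet]
    backgrounds: tuple[np.ndarray, np.ndarray]


def generate_landscape(
    n_rows: int,
    n_cols: int,
    n_layers: int,
    smoothness: float = 0.3,
    correlation: float = 0.0,
    seed: int | None = None,
    layer_prefix: str = "env",
    cell_size: float = 1 / 12,
    origin: tuple[float, float] = (-75.0, 10.0),
) -> EnvGrid:
    """Generate spatially smooth, inter-correlated environmental layers.

    Each layer is built as a latitudinal linear trend plus Gaussian-filtered
    white noise; the per-layer base fields are then whitened and linearly
    mixed so every layer pair realizes (near-exactly) the requested Pearson
    ``correlation``, reproducing the strong collinearity of real bioclimatic
    variables. Layers get distinct means and scales, as climate variables in
    different units would have.

    Parameters
    ----------
    smoothness
        Fraction of the shorter grid edge used as the Gaussian filter sigma
        (scaled by 1/4); larger values give smoother fields.
    correlation
        Target pairwise inter-layer correlation, in ``[-1, 1]``; for more
        than two layers it must exceed ``-1/(n_layers-1)`` for the implied
        correlation matrix to be valid.
    """
    if n_rows < 8 or n_cols < 8:
        raise ArgumentError("grid must be at least 8x8")
    if n_layers < 2:
        raise ArgumentError("need at least 2 layers")
    if not -1.0 <= correlation <= 1.0:
        raise ArgumentError("correlation must be in [-1, 1]")
    if n_layers > 2 and correlation < -1.0 / (n_layers - 1):
        raise ArgumentError(
            f"equicorrelation {correlation} is infeasible for {n_layers} layers"
        )
    rng = np.random.default_rng(seed)
    sigma = max(smoothness, 0.0) * min(n_rows, n_cols) / 4.0

    # base fields: latitudinal trend (random strength/sign) + smoothed noise
    lat_trend = np.linspace(1.0, -1.0, n_rows)[:, None] * np.ones((1, n_cols))
    base = np.empty((n_layers, n_rows, n_cols))
    for i in range(n_layers):
        noise = rng.standard_normal((n_rows, n_cols))
        if sigma > 0:
            noise = ndimage.gaussian_filter(noise, sigma, mode="reflect")
        noise = (noise - noise.mean()) / noise.std()
        w = rng.uniform(0.2, 0.6) * rng.choice([-1.0, 1.0])
        base[i] = w * lat_trend + np.sqrt(1.0 - w * w) * noise

    # whiten realized fields, then impose the target equicorrelation exactly
    flat = base.reshape(n_layers, -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    cov = flat @ flat.T / flat.shape[1]
    white = np.linalg.solve(np.linalg.cholesky(cov), flat)
    if correlation == 1.0:
        mixed = np.broadcast_to(white[0], white.shape).copy()
    else:
        target = np.full((n_layers, n_layers), correlation)
        np.fill_diagonal(target, 1.0)
        mixed = np.linalg.cholesky(target) @ white

    means = 10.0 * (1.0 + np.arange(n_layers))
    scales = 1.0 + 0.5 * np.arange(n_layers)
    values = means[:, None] + scales[:, None] * mixed
    return EnvGrid(
        values=values.reshape(n_layers, n_rows, n_cols),
        layer_names=[f"{layer_prefix}{i + 1}" for i in range(n_layers)],
        cell_size=cell_size,
        origin=origin,
    )


def make_biome_masks(
    grid: EnvGrid,
    geometry: str = "east_west",
    gap: int = 2,
    rectangles: tuple[tuple[int, int, int, int], tuple[int, int, int, int]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the grid into two disjoint biome masks.

    ``east_west`` splits columns into a western and an eastern block separated
    by ``gap`` empty columns. ``custom`` takes two half-open row/col
    rectangles ``(r0, r1, c0, c1)``. Each mask must cover at least 10% of the
    non-nodata cells and the two must be disjoint.
    """
    valid = ~grid.nodata_mask
    if geometry == "east_west":
        half = (grid.n_cols - gap) // 2
        if half < 1:
            raise GeometryError("grid too narrow for an east/west split")
        mask_a = np.zeros(grid.shape, dtype=bool)
        mask_b = np.zeros(grid.shape, dtype=bool)
        mask_a[:, :half] = True
        mask_b[:, half + gap:] = True
    elif geometry == "custom":
        if rectangles is None:
            raise ArgumentError("custom geometry requires two rectangles")
        masks = []
        for r0, r1, c0, c1 in rectangles:
            m = np.zeros(grid.shape, dtype=bool)
            m[r0:r1, c0:c1] = True
            masks.append(m)
        mask_a, mask_b = masks
    else:
        raise ArgumentError(f"unknown geometry {geometry!r}")

    mask_a &= valid
    mask_b &= valid
    if np.any(mask_a & mask_b):
        raise GeometryError("biome masks overlap")
    floor = 0.10 * valid.sum()
    if mask_a.sum() < max(floor, 1) or mask_b.sum() < max(floor, 1):
        raise GeometryError("each biome mask needs >= 10% of non-nodata cells")
    return mask_a, mask_b


def sample_occurrences(
    truth: SpeciesTruth,
    grid: EnvGrid,
    n: int,
    seed: int | None = None,
    bias: np.ndarray | None = None,
) -> OccurrenceSet:
    """Draw ``n`` occurrence cells without replacement, weight ∝ suitability.

    Records are placed at cell centers (occurrences are snapped to the grid
    anyway, and within-cell duplicates would be collapsed). ``bias`` is an
    optional per-cell weight multiplier emulating uneven sampling effort;
    it defaults to off.
    """
    if n < 1:
        raise ArgumentError("n must be >= 1")
    weights = truth.suitability(grid).ravel()
    if bias is not None:
        bias = np.asarray(bias, dtype=float).ravel()
        if bias.size != weights.size:
            raise ArgumentError("bias raster must match grid size")
        if np.any(bias < 0):
            raise ArgumentError("bias weights must be non-negative")
        weights = weights * bias
    positive = np.flatnonzero(weights > 0)
    if positive.size < n:
        raise SamplingError(
            f"only {positive.size} cells have positive sampling weight; need {n}"
        )
    rng = np.random.default_rng(seed)
    p = weights[positive] / weights[positive].sum()
    cells = rng.choice(positive, size=n, replace=False, p=p)
    return OccurrenceSet(
        species_name=truth.name,
        records=grid.cell_center(cells),
        cell_ids=cells,
    )


def generate_scenario(
    name: str,
    n_per_species: int = 50,
    seed: int | None = None,
    n_rows: int = 48,
    n_cols: int = 48,
    n_layers: int = 5,
    smoothness: float = 0.15,
    correlation: float = 0.6,
    separation: float = 3.0,
    niche_sd_factor: float = 0.35,
) -> Scenario:
    """Generate one of the three comparison classes the analysis contrasts.

    ``divergent_allopatric``
        Disjoint ranges; niche centroids separated by ``separation`` (default
        3.0) Mahalanobis units under the shared niche covariance, placed
        symmetrically about the background mean along the background's first
        principal environmental axis so both remain inside available
        environments.
    ``conserved_allopatric``
        Disjoint ranges; identical centroid and covariance (a conserved niche
        expressed in two biomes).
    ``sympatric_shared``
        Identical range masks and identical niche (the shared biome mask is
        duplicated for both species).

    Each species' background is its own biome mask (the shared mask,
    duplicated, for the sympatric case). Niche spread is ``niche_sd_factor``
    times the background standard deviation per layer (0.35: the species
    occupies a modest fraction of the available environmental space, as a
    habitat specialist would). The default ``smoothness`` here is smaller
    than :func:`generate_landscape`'s generic default so that the noise
    correlation length stays well below the biome width: both biomes then
    offer statistically comparable environments, the premise under which a
    conserved niche is reciprocally predictable across regions.
    """
    if name not in SCENARIO_NAMES:
        raise ArgumentError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    if n_per_species < 20:
        raise ArgumentError("n_per_species must be >= 20 (unique-records floor)")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]

    grid = generate_landscape(
        n_rows, n_cols, n_layers, smoothness=smoothness, correlation=correlation, seed=seeds[0]
    )
    mask_a, mask_b = make_biome_masks(grid, "east_west")
    union = mask_a | mask_b
    _, env_union = grid.table(union)
    mu = env_union.mean(axis=0)
    sd = env_union.std(axis=0, ddof=1)
    cov = np.diag((niche_sd_factor * sd) ** 2)

    if name == "divergent_allopatric":
        # separate along the background's leading environmental axis
        c = np.cov(env_union.T)
        evals, evecs = np.linalg.eigh(c)
        u = evecs[:, -1]
        maha = np.sqrt(u @ np.linalg.solve(cov, u))
        delta = separation * u / maha
        cent1, cent2 = mu - delta / 2.0, mu + delta / 2.0
        ranges = (mask_a, mask_b)
        backgrounds = (mask_a, mask_b)
    elif name == "conserved_allopatric":
        cent1 = cent2 = mu
        ranges = (mask_a, mask_b)
        backgrounds = (mask_a, mask_b)
    else:  # sympatric_shared
        cent1 = cent2 = mu
        ranges = (union, union.copy())
        backgrounds = (union, union.copy())

    truths = (
        SpeciesTruth("species_1", cent1, cov, ranges[0]),
        SpeciesTruth("species_2", cent2, cov, ranges[1]),
    )
    occs = (
        sample_occurrences(truths[0], grid, n_per_species, seed=seeds[1]),
        sample_occurrences(truths[1], grid, n_per_species, seed=seeds[2]),
    )
    return Scenario(name=name, grid=grid, truths=truths, occurrences=occs, backgrounds=backgrounds)


def generate_remnants(
    grid: EnvGrid,
    fine_factor: int,
    coverage: float,
    patchiness: float = 2.0,
    seed: int | None = None,
    cell_area_km2: float | None = None,
) -> RemnantMask:
    """Generate a patchy fine-resolution habitat-remnant mask.

    A Gaussian-filtered noise field is thresholded at the ``1 - coverage``
    quantile, so the realized remnant fraction equals ``coverage`` (up to
    ties) while remnants form contiguous patches whose scale grows with
    ``patchiness`` (the filter sigma in fine cells).
    """
    if not isinstance(fine_factor, (int, np.integer)) or fine_factor < 1:
        raise ArgumentError("fine_factor must be an integer >= 1")
    if not 0.0 < coverage <= 1.0:
        raise ArgumentError("coverage must be in (0, 1]")
    fr, fc = grid.n_rows * fine_factor, grid.n_cols * fine_factor
    fine_size = grid.cell_size / fine_factor
    if cell_area_km2 is None:
        cell_area_km2 = (fine_size * 111.32) ** 2
    if coverage == 1.0:
        mask = np.ones((fr, fc), dtype=bool)
    else:
        rng = np.random.default_rng(seed)
        fld = ndimage.gaussian_filter(rng.standard_normal((fr, fc)), patchiness, mode="reflect")
        mask = fld >= np.quantile(fld, 1.0 - coverage)
    return RemnantMask(
        mask=mask, cell_size=fine_size, cell_area_km2=float(cell_area_km2), origin=grid.origin
    )
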