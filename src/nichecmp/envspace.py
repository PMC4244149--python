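"""Background-calibrated PCA and 2-D environmental-space occupancy surfaces.

The "PCA-env" is a correlation-matrix PCA calibrated on the environmental
values of the study background. Its leading components serve as decorrelated
environmental layers for the distribution models; its first two axes span the
plane on which occurrence and background kernel densities are gridded for the
niche-overlap statistics.

For a species the environmental space holds three aligned R×R surfaces:

``O``  smoothed density of the species' occurrence scores,
``E``  smoothed density of the background (available) environment scores,
``Z``  occupancy ``O/E`` on the available support, renormalized — the
       sampling-bias-corrected description of the realized niche.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import (
    ArgumentError,
    BandwidthError,
    DegenerateInputError,
    SchemaError,
)
from .grids import EnvGrid, OccurrenceSet

__all__ = [
    "PcaModel",
    "EnvSpaceGrid",
    "fit_pca",
    "select_components",
    "project_grid",
    "build_env_space",
    "score_bounds",
]


@dataclass
class PcaModel:
    """Correlation-matrix PCA fitted on a calibration background.

    ``loadings`` has one unit-length column per component; the sign of each
    component is fixed by making its largest-magnitude loading positive, so
    repeated fits are bit-reproducible.
    """

    layer_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # (n_layers, n_components)
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: np.ndarray, k: int | None = None) -> np.ndarray:
        """Scores of raw-unit rows on the first ``k`` components."""
        k = self.n_components if k is None else k
        Xs = (np.asarray(X, dtype=float) - self.means) / self.sds
        return Xs @ self.loadings[:, :k]

    def to_json(self) -> str:
        return json.dumps(
            {
                "layer_names": self.layer_names,
                "means": self.means.tolist(),
                "sds": self.sds.tolist(),
                "loadings": self.loadings.tolist(),
                "eigenvalues": self.eigenvalues.tolist(),
                "variance_fractions": self.variance_fractions.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PcaModel":
        d = json.loads(text)
        return cls(
            layer_names=list(d["layer_names"]),
            means=np.asarray(d["means"], float),
            sds=np.asarray(d["sds"], float),
            loadings=np.asarray(d["loadings"], float),
            eigenvalues=np.asarray(d["eigenvalues"], float),
            variance_fractions=np.asarray(d["variance_fractions"], float),
        )


def fit_pca(grid: EnvGrid, background_mask: np.ndarray | None = None) -> PcaModel:
    """Fit the PCA on the environmental space of the calibration background.

    Layers are standardized by their background mean and (ddof=1) standard
    deviation, so this is a PCA of the background correlation matrix.
    """
    _, X = grid.table(background_mask)
    if X.shape[0] < 3:
        raise DegenerateInputError("need at least 3 background cells")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        bad = [grid.layer_names[i] for i in zero]
        raise DegenerateInputError(f"zero-variance layer(s) on background: {bad}")
    Xs = (X - means) / sds
    # SVD of the standardized matrix: eigenvalues of the correlation matrix
    _, svals, vt = np.linalg.svd(Xs, full_matrices=False)
    eigenvalues = svals**2 / (X.shape[0] - 1)
    loadings = vt.T
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    return PcaModel(
        layer_names=list(grid.layer_names),
        means=means,
        sds=sds,
        loadings=loadings,
        eigenvalues=eigenvalues,
        variance_fractions=eigenvalues / eigenvalues.sum(),
    )


def select_components(model: PcaModel, target_fraction: float = 0.97) -> int:
    """Smallest k whose cumulative variance fraction reaches the target."""
    if not 0.0 < target_fraction <= 1.0:
        raise ArgumentError("target_fraction must be in (0, 1]")
    cum = np.cumsum(model.variance_fractions)
    reached = np.flatnonzero(cum >= target_fraction - 1e-12)
    return int(reached[0]) + 1 if reached.size else model.n_components


def project_grid(grid: EnvGrid, model: PcaModel, k: int | None = None) -> EnvGrid:
    """Project a grid onto the first ``k`` components as new layers."""
    if list(grid.layer_names) != list(model.layer_names):
        raise SchemaError(
            f"grid layers {grid.layer_names} do not match model variables {model.layer_names}"
        )
    k = model.n_components if k is None else k
    if k > model.n_components:
        raise ArgumentError("k exceeds the number of components")
    ids, X = grid.table()
    scores = model.transform(X, k)
    values = np.full((k, grid.n_cells), np.nan)
    values[:, ids] = scores.T
    return grid.copy_with(
        values.reshape(k, grid.n_rows, grid.n_cols),
        [f"PC{i + 1}" for i in range(k)],
    )


@dataclass
class EnvSpaceGrid:
    """R×R occupancy surfaces over the first two PCA-env axes."""

    resolution: int
    bounds: tuple[float, float, float, float]  # (x_min, x_max, y_min, y_max)
    O: np.ndarray  # occurrence density, sums to 1
    E: np.ndarray  # background (availability) density, sums to 1
    Z: np.ndarray  # corrected occupancy, sums to 1, 0 off availability support

    def aligned_with(self, other: "EnvSpaceGrid") -> bool:
        return self.resolution == other.resolution and np.allclose(self.bounds, other.bounds)


def _silverman(points: np.ndarray) -> np.ndarray:
    """Per-axis Silverman bandwidth for a 2-D Gaussian product kernel."""
    n = points.shape[0]
    sd = points.std(axis=0, ddof=1) if n > 1 else np.zeros(2)
    return sd * n ** (-1.0 / 6.0)


def _grid_axes(bounds, R):
    x = np.linspace(bounds[0], bounds[1], R + 1)
    y = np.linspace(bounds[2], bounds[3], R + 1)
    return (x[:-1] + x[1:]) / 2.0, (y[:-1] + y[1:]) / 2.0


def kernel_density_surface(
    points: np.ndarray,
    bounds: tuple[float, float, float, float],
    R: int,
    bandwidth: tuple[float, float] | None = None,
) -> np.ndarray:
    """Gaussian product-kernel density of 2-D points on an R×R grid.

    The product kernel is separable, so the surface is assembled as an outer
    product of per-axis kernel matrices — O(n·R) exponentials instead of
    O(n·R²) — which keeps the randomization tests cheap. The result is
    normalized to sum to 1.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    bw = _silverman(points) if bandwidth is None else np.asarray(bandwidth, float)
    if np.any(bw <= 0):
        raise BandwidthError(
            "kernel bandwidth is zero (all points coincide on an axis); "
            "pass an explicit floor bandwidth"
        )
    xc, yc = _grid_axes(bounds, R)
    kx = np.exp(-0.5 * ((xc[None, :] - points[:, 0:1]) / bw[0]) ** 2)  # (n, R)
    ky = np.exp(-0.5 * ((yc[None, :] - points[:, 1:2]) / bw[1]) ** 2)  # (n, R)
    surface = kx.T @ ky  # (R, R): [i, j] = density at (xc[i], yc[j])
    total = surface.sum()
    if total <= 0:
        raise BandwidthError("all kernel mass fell outside the grid bounds")
    return surface / total


def score_bounds(
    score_sets: list[np.ndarray], expand: float = 0.05
) -> tuple[float, float, float, float]:
    """Common axis bounds: min/max over all score sets, expanded per side."""
    pts = np.vstack([np.asarray(s, float).reshape(-1, 2) for s in score_sets])
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = np.maximum(hi - lo, 1e-12)
    lo, hi = lo - expand * span, hi + expand * span
    return float(lo[0]), float(hi[0]), float(lo[1]), float(hi[1])


def occupancy_from_densities(
    O: np.ndarray, E: np.ndarray, availability_floor: float
) -> np.ndarray:
    """Z = O/E on the availability support, renormalized to sum to 1."""
    support = E >= availability_floor * E.max()
    Z = np.where(support, O / np.where(support, E, 1.0), 0.0)
    total = Z.sum()
    if total <= 0:
        raise DegenerateInputError("occurrence density has no mass on the availability support")
    return Z / total


def build_env_space(
    occ: OccurrenceSet,
    background_mask: np.ndarray,
    grid: EnvGrid,
    model: PcaModel,
    R: int = 100,
    bounds: tuple[float, float, float, float] | None = None,
    bandwidth: tuple[float, float] | None = None,
    availability_floor: float = 1e-6,
) -> EnvSpaceGrid:
    """Build the O/E/Z surfaces for one species against its background.

    Occurrence-cell and background-cell scores on PCA axes 1–2 are smoothed
    onto a shared R×R grid with a Gaussian product kernel (per-axis Silverman
    bandwidth unless overridden). ``Z`` is zero wherever availability falls
    below ``availability_floor × max(E)``.

    When two species are compared, pass the same ``bounds`` (e.g. from
    :func:`score_bounds` over both backgrounds) so their surfaces are
    cell-aligned.
    """
    bg_ids, bg_env = grid.table(background_mask)
    if bg_ids.size == 0:
        raise ArgumentError("background mask is empty")
    occ_scores = model.transform(grid.env_at(occ.cell_ids), 2)
    bg_scores = model.transform(bg_env, 2)
    if bounds is None:
        bounds = score_bounds([bg_scores])
    O = kernel_density_surface(occ_scores, bounds, R, bandwidth)
    E = kernel_density_surface(bg_scores, bounds, R, bandwidth)
    Z = occupancy_from_densities(O, E, availability_floor)
    return EnvSpaceGrid(resolution=R, bounds=bounds, O=O, E=E, Z=Z)
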